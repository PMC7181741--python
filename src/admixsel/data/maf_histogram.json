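{
 "bin_width": 0.01,
 "hist": [
  0.004166666666666667,
  0.008333333333333333,
  0.012499999999999999,
  0.016666666666666666,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332,
  0.020833333333333332
 ]
}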