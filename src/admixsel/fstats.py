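"""Admixture f-statistics: f3 admixture test, f4, and the F4-ratio
ancestry-proportion estimator, with block-jackknife standard errors.

f3(C; A, B) averages (c-a)(c-b) over variants, with the finite-sample
correction -c(1-c)/(n_C - 1) that removes the upward bias from sampling
noise in the target frequency; a significantly negative value indicates C
descends from a mixture of populations related to A and B.  f4(A,B;C,D)
averages (a-b)(c-d) and needs no correction.  Standard errors come from a
leave-one-block-out jackknife over contiguous genomic blocks, which is
robust to LD between nearby variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import GenotypeMatrix, panel_frequencies

#: One-tailed 1% significance threshold for the f3 admixture Z-score.
F3_Z_THRESHOLD: float = -2.33

#: Default jackknife block size: 5 Mb (~5 cM under a 1 cM = 1 Mb map),
#: comfortably above the LD scale of array data.
DEFAULT_BLOCK_BP: int = 5_000_000


@dataclass
class FStatResult:
    statistic: str  # "f3" | "f4"
    estimate: float
    std_err: float
    z: float
    n_snps: int
    n_blocks: int
    significant: bool | None = None  # f3 only: z < F3_Z_THRESHOLD


@dataclass
class RatioResult:
    alpha: float
    std_err: float
    numerator: FStatResult
    denominator: FStatResult


def _block_ids(variants, block_size_bp: int) -> np.ndarray:
    """Contiguous block label per variant: (chrom, pos // block)."""
    keys = list(zip(variants["chrom"], variants["pos"] // block_size_bp))
    _, ids = np.unique(np.array([f"{c}|{b}" for c, b in keys]), return_inverse=True)
    return ids


def _freq(G: GenotypeMatrix, pop: str):
    panel = panel_frequencies(G, pop)
    return panel.freq, panel.n_obs


def _jackknife(terms: np.ndarray, blocks: np.ndarray):
    """Delete-one-block jackknife mean and SE of ``mean(terms)``."""
    uniq = np.unique(blocks)
    g = len(uniq)
    if g < 2:
        raise ValueError("need at least 2 jackknife blocks; shrink block_size_bp")
    total = terms.sum()
    n = len(terms)
    block_sums = np.array([terms[blocks == b].sum() for b in uniq])
    block_n = np.array([(blocks == b).sum() for b in uniq])
    theta_j = (total - block_sums) / (n - block_n)
    theta_bar = theta_j.mean()
    se = np.sqrt((g - 1) / g * ((theta_j - theta_bar) ** 2).sum())
    return total / n, se, g


def f3(G: GenotypeMatrix, target: str, sourceA: str, sourceB: str,
       block_size_bp: int = DEFAULT_BLOCK_BP) -> FStatResult:
    """Three-population admixture test f3(target; sourceA, sourceB)."""
    a, _ = _freq(G, sourceA)
    b, _ = _freq(G, sourceB)
    c, n_c = _freq(G, target)
    usable = (
        ~np.isnan(a) & ~np.isnan(b) & ~np.isnan(c) & (n_c >= 2)
    )
    if not usable.any():
        raise ValueError("no usable variants for f3")
    a, b, c, n_c = a[usable], b[usable], c[usable], n_c[usable]
    terms = (c - a) * (c - b) - c * (1.0 - c) / (n_c - 1)
    blocks = _block_ids(G.variants[usable], block_size_bp)
    est, se, g = _jackknife(terms, blocks)
    z = est / se if se > 0 else np.nan
    return FStatResult("f3", est, se, z, int(usable.sum()), g,
                       significant=bool(z < F3_Z_THRESHOLD))


def f4(G: GenotypeMatrix, A: str, B: str, C: str, D: str,
       block_size_bp: int = DEFAULT_BLOCK_BP) -> FStatResult:
    """f4(A, B; C, D) = mean (a-b)(c-d) with block-jackknife SE."""
    a, _ = _freq(G, A)
    b, _ = _freq(G, B)
    c, _ = _freq(G, C)
    d, _ = _freq(G, D)
    usable = ~(np.isnan(a) | np.isnan(b) | np.isnan(c) | np.isnan(d))
    if not usable.any():
        raise ValueError("no usable variants for f4")
    terms = (a - b)[usable] * (c - d)[usable]
    blocks = _block_ids(G.variants[usable], block_size_bp)
    est, se, g = _jackknife(terms, blocks)
    z = est / se if se > 0 else np.nan
    return FStatResult("f4", est, se, z, int(usable.sum()), g)


def f4_ratio(G: GenotypeMatrix, outgroup: str, asian_proxy: str,
             papuan_proxy: str, admixed: str, asian_source_proxy: str,
             block_size_bp: int = DEFAULT_BLOCK_BP) -> RatioResult:
    """Mixture proportion alpha of the ``asian_proxy``-related ancestry.

    alpha = f4(asian_proxy, outgroup; admixed, papuan_proxy)
          / f4(asian_proxy, outgroup; asian_source_proxy, papuan_proxy)

    The SE jackknifes the ratio itself: both f4 sums are recomputed with
    each block deleted.
    """
    num = f4(G, asian_proxy, outgroup, admixed, papuan_proxy, block_size_bp)
    den = f4(G, asian_proxy, outgroup, asian_source_proxy, papuan_proxy, block_size_bp)
    if not np.isfinite(den.z) or abs(den.z) <= 3:
        raise ValueError(
            "denominator f4 is consistent with 0 (|Z| <= 3): the assumed "
            "phylogeny is uninformative for an ancestry ratio"
        )

    a, _ = _freq(G, asian_proxy)
    o, _ = _freq(G, outgroup)
    x, _ = _freq(G, admixed)
    s, _ = _freq(G, asian_source_proxy)
    p, _ = _freq(G, papuan_proxy)
    usable = ~(np.isnan(a) | np.isnan(o) | np.isnan(x) | np.isnan(s) | np.isnan(p))
    w = (a - o)[usable]
    num_terms = w * (x - p)[usable]
    den_terms = w * (s - p)[usable]
    blocks = _block_ids(G.variants[usable], block_size_bp)
    uniq = np.unique(blocks)
    g = len(uniq)
    num_total, den_total = num_terms.sum(), den_terms.sum()
    ratios = np.empty(g)
    for i, bid in enumerate(uniq):
        inb = blocks == bid
        ratios[i] = (num_total - num_terms[inb].sum()) / (den_total - den_terms[inb].sum())
    alpha = num_total / den_total
    se = np.sqrt((g - 1) / g * ((ratios - ratios.mean()) ** 2).sum())
    return RatioResult(alpha, se, num, den)
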