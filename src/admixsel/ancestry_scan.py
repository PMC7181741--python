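"""Genome-wide ancestry-excess outlier scan.

Summarizes the per-position mean ancestry track, flags positions beyond
mean +/- 2 or 3 SD, runs Grubbs' outlier test on the extremes, calls
maximal contiguous outlier regions, and compares observed region lengths
to a simulated neutral null.

A caveat stated up front: Grubbs' test assumes independent observations,
while an ancestry track is massively autocorrelated; its nominal p-value is
reported for comparability, but the calibrated test of region lengths is
the simulation null (:func:`region_length_null`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Flag codes for ScanSummary.flags.
WITHIN, HIGH_2SD, HIGH_3SD, LOW_2SD, LOW_3SD = 0, 1, 2, -1, -2


@dataclass
class ScanSummary:
    mean: float
    sd: float  # population SD (denominator N)
    flags: np.ndarray  # one code per position

    @property
    def thresholds(self) -> dict:
        return {
            "+2sd": self.mean + 2 * self.sd,
            "+3sd": self.mean + 3 * self.sd,
            "-2sd": self.mean - 2 * self.sd,
            "-3sd": self.mean - 3 * self.sd,
        }


@dataclass
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    side: str  # "high" (excess first ancestry) | "low"
    n_variants: int
    extreme_value: float
    extreme_pos: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class GrubbsResult:
    G: float
    p_value: float
    index: int
    side: str


@dataclass
class NullSummary:
    mean: float
    sd: float
    lengths_high: np.ndarray
    lengths_low: np.ndarray
    n_replicates: int

    def mean_length(self, side: str = "high") -> float:
        lens = self.lengths_high if side == "high" else self.lengths_low
        return float(lens.mean()) if len(lens) else float("nan")

    def max_length(self, side: str = "high") -> float:
        lens = self.lengths_high if side == "high" else self.lengths_low
        return float(lens.max()) if len(lens) else float("nan")


def summarize_track(mean_track: np.ndarray) -> ScanSummary:
    """Genome-wide mean/SD of the track and per-position outlier flags.

    Flags use strict inequality beyond the thresholds ("outside k SD");
    the SD uses denominator N (immaterial at genome scale, but fixed).
    """
    x = np.asarray(mean_track, dtype=float)
    if x.size == 0:
        raise ValueError("empty track")
    mean = float(x.mean())
    sd = float(x.std())
    flags = np.full(x.shape, WITHIN, dtype=np.int8)
    flags[x > mean + 2 * sd] = HIGH_2SD
    flags[x > mean + 3 * sd] = HIGH_3SD
    flags[x < mean - 2 * sd] = LOW_2SD
    flags[x < mean - 3 * sd] = LOW_3SD
    return ScanSummary(mean, sd, flags)


def grubbs_test(values: np.ndarray, side: str = "two-sided") -> GrubbsResult:
    """Grubbs' test for a single outlier.

    G = max |x - mean| / s (sample SD).  The p-value uses the t-based bound
    p = N * P(t_{N-2} >= tau) with
    tau = sqrt(N (N-2) G^2 / ((N-1)^2 - N G^2)), doubled for the two-sided
    test and clipped to [0, 1]; when G reaches its algebraic maximum tau is
    undefined and p = 0.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate input: zero variance")
    dev = x - x.mean()
    if side == "two-sided":
        i = int(np.argmax(np.abs(dev)))
        G = abs(dev[i]) / s
    elif side == "max":
        i = int(np.argmax(dev))
        G = dev[i] / s
    elif side == "min":
        i = int(np.argmin(dev))
        G = -dev[i] / s
    else:
        raise ValueError("side must be 'two-sided', 'max' or 'min'")
    out_side = "max" if dev[i] > 0 else "min"
    denom = (n - 1) ** 2 - n * G**2
    if denom <= 0:
        return GrubbsResult(float(G), 0.0, i, out_side)
    tau = np.sqrt(n * (n - 2) * G**2 / denom)
    p = n * stats.t.sf(tau, n - 2)
    if side == "two-sided":
        p *= 2
    return GrubbsResult(float(G), float(min(1.0, p)), i, out_side)


def call_regions(positions: np.ndarray, chroms: np.ndarray, values: np.ndarray,
                 summary: ScanSummary, side: str = "high",
                 sd_multiplier: float = 3.0) -> list[Region]:
    """Maximal runs of consecutive same-chromosome positions beyond the
    threshold on one side (strict inequality, gap tolerance 0).

    Singleton runs yield zero-length regions (start == end, n_variants 1).
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    chroms = np.asarray(chroms)
    if side == "high":
        beyond = values > summary.mean + sd_multiplier * summary.sd
    elif side == "low":
        beyond = values < summary.mean - sd_multiplier * summary.sd
    else:
        raise ValueError("side must be 'high' or 'low'")
    regions: list[Region] = []
    i, n = 0, len(values)
    while i < n:
        if not beyond[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and beyond[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        vals = values[i:j + 1]
        k = int(np.argmax(vals)) if side == "high" else int(np.argmin(vals))
        regions.append(
            Region(
                chrom=str(chroms[i]),
                start_bp=int(positions[i]),
                end_bp=int(positions[j]),
                side=side,
                n_variants=j - i + 1,
                extreme_value=float(vals[k]),
                extreme_pos=int(positions[i + k]),
            )
        )
        i = j + 1
    return regions


def region_length_null(tracks, sd_multiplier: float = 3.0) -> NullSummary:
    """Null distribution of contiguous outlier-region lengths.

    ``tracks`` is a sequence of (positions, values) pairs, one per
    independent simulation window; the mean/SD thresholds are computed from
    the simulated values themselves (pooled over windows), and regions are
    called within windows only (they never span windows).
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one simulated track")
    pooled = np.concatenate([np.asarray(v, dtype=float) for _, v in tracks])
    summary = summarize_track(pooled)
    lengths = {"high": [], "low": []}
    for wi, (pos, vals) in enumerate(tracks):
        chroms = np.full(len(pos), wi)
        for side in ("high", "low"):
            for r in call_regions(pos, chroms, vals, summary, side, sd_multiplier):
                lengths[side].append(r.length)
    return NullSummary(
        summary.mean, summary.sd,
        np.asarray(lengths["high"], dtype=float),
        np.asarray(lengths["low"], dtype=float),
        n_replicates=len(tracks),
    )


def compare_observed_to_null(observed: list[Region], null: NullSummary) -> list[dict]:
    """Per observed region: does it exceed the longest null region, and what
    fraction of null regions (same side) are at least as long."""
    report = []
    for r in observed:
        lens = null.lengths_high if r.side == "high" else null.lengths_low
        if len(lens) == 0:
            report.append(
                {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
                 "side": r.side, "length": r.length, "no_null_regions": True,
                 "exceeds_null_max": None, "null_exceedance_fraction": None}
            )
            continue
        report.append(
            {"chrom": r.chrom, "start_bp": r.start_bp, "end_bp": r.end_bp,
             "side": r.side, "length": r.length, "no_null_regions": False,
             "exceeds_null_max": bool(r.length > lens.max()),
             "null_exceedance_fraction": float((lens >= r.length).mean())}
        )
    return report


def regions_to_bed(regions: list[Region]) -> str:
    """BED text (0-based half-open) from internal 1-based inclusive regions."""
    lines = [
        f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.side}\t{r.extreme_value:.4f}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
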