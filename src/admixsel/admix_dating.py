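"""Admixture dating from the exponential decay of ancestry-weighted LD.

A single admixture pulse T generations ago leaves linkage disequilibrium
between variant pairs proportional to exp(-T * d) at genetic distance d
Morgans.  The weighted-LD statistic A(d) correlates the per-pair genotype
correlation in the admixed population with weights derived from the allele
frequency difference of the two source panels; fitting A(d) = A0 *
exp(-n*d/100) + c over distance bins (d in cM) recovers n, the number of
generations since admixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .genodata import MISSING, AlleleFrequencyPanel, GenotypeMatrix


@dataclass
class LDDecayCurve:
    bin_centers: np.ndarray  # cM
    A: np.ndarray            # weighted-LD statistic per bin (NaN if no pairs)
    pair_counts: np.ndarray


@dataclass
class DatingResult:
    generations: float       # decay constant per Morgan
    amplitude: float
    offset: float
    fit_min_cm: float
    fit_max_cm: float
    std_err: float | None = None

    def years(self, generation_time: float = 30.0) -> float:
        return self.generations * generation_time


class FitFailureError(RuntimeError):
    """The decay curve does not support an exponential fit."""


def weighted_ld_curve(G_admixed: GenotypeMatrix, panelA: AlleleFrequencyPanel,
                      panelB: AlleleFrequencyPanel,
                      genetic_pos_cm: np.ndarray | None = None,
                      bin_cm: float = 0.1, max_cm: float = 20.0) -> LDDecayCurve:
    """Binned weighted-LD statistic of the admixed population.

    For each intra-chromosome pair (i, j) with genetic distance d <= max_cm,
    the pair contributes w_i * w_j * rho_ij to its distance bin, where
    w = panelA.freq - panelB.freq and rho is the sample correlation of
    dosages.  Each bin reports sum(w_i w_j rho_ij) / sum(|w_i w_j|).

    ``genetic_pos_cm`` defaults to the 1 cM = 1 Mb map (pos / 1e6).
    """
    w = panelA.freq - panelB.freq
    if np.isnan(w).any():
        raise ValueError("panel frequencies must be defined at every variant")
    pos_cm = (
        np.asarray(genetic_pos_cm, dtype=float)
        if genetic_pos_cm is not None
        else G_admixed.variants["pos"].to_numpy() / 1e6
    )
    n_bins = int(np.ceil(max_cm / bin_cm))
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    chroms = G_admixed.variants["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if len(idx) < 2:
            continue
        rho = _dosage_correlation(G_admixed.calls[:, idx])
        d = np.abs(pos_cm[idx][:, None] - pos_cm[idx][None, :])
        wprod = w[idx][:, None] * w[idx][None, :]
        iu, ju = np.triu_indices(len(idx), k=1)
        dd, rr, ww = d[iu, ju], rho[iu, ju], wprod[iu, ju]
        ok = (dd > 0) & (dd <= max_cm) & ~np.isnan(rr)
        b = np.minimum((dd[ok] / bin_cm).astype(int), n_bins - 1)
        np.add.at(num, b, ww[ok] * rr[ok])
        np.add.at(den, b, np.abs(ww[ok]))
        np.add.at(counts, b, 1)

    if counts.sum() == 0:
        raise ValueError("no usable variant pairs within max_cm")
    with np.errstate(invalid="ignore", divide="ignore"):
        # den == 0 with pairs present means all weights vanish (identical
        # panels): the statistic is 0, not undefined
        A = np.where(den > 0, num / den, np.where(counts > 0, 0.0, np.nan))
    centers = (np.arange(n_bins) + 0.5) * bin_cm
    return LDDecayCurve(centers, A, counts)


def _dosage_correlation(calls: np.ndarray) -> np.ndarray:
    """Pairwise-complete sample correlation between dosage columns."""
    x = calls.astype(float)
    if (calls == MISSING).any():
        x[calls == MISSING] = np.nan
        mask = ~np.isnan(x)
        x0 = np.where(mask, x, 0.0)
        n = mask.T.astype(float) @ mask.astype(float)
        s = x0.T @ mask.astype(float)
        ss = (x0 * x0).T @ mask.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_i = s / n
            cov = (x0.T @ x0) / n - mean_i * mean_i.T
            var_i = ss / n - mean_i**2
            rho = cov / np.sqrt(var_i * var_i.T)
        return rho
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(x, rowvar=False)


def fit_decay(curve: LDDecayCurve, fit_min_cm: float = 0.5,
              max_cm: float | None = None) -> DatingResult:
    """Least-squares exponential fit A(d) = A0 * exp(-n d / 100) + c.

    ``d`` is in cM, so the decay constant ``n`` is per Morgan: the number of
    generations since the admixture pulse.  Bins below ``fit_min_cm`` are
    excluded (background LD contaminates short distances).
    """
    use = (curve.bin_centers >= fit_min_cm) & (curve.pair_counts > 0) & ~np.isnan(curve.A)
    if max_cm is not None:
        use &= curve.bin_centers <= max_cm
    if use.sum() < 5:
        raise FitFailureError("need at least 5 populated bins in the fit range")
    d = curve.bin_centers[use]
    y = curve.A[use]
    if np.ptp(y) == 0:
        raise FitFailureError("curve is flat: no decaying admixture LD")

    def model(d, A0, n, c):
        return A0 * np.exp(-n * d / 100.0) + c

    a0_guess = max(y[0] - y[-1], 1e-6)
    try:
        popt, _ = curve_fit(
            model, d, y, p0=(a0_guess, 50.0, float(y[-1])),
            maxfev=20000,
            bounds=((-np.inf, 1e-9, -np.inf), (np.inf, 1e5, np.inf)),
        )
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitFailureError(f"exponential fit did not converge: {exc}") from exc
    A0, n, c = popt
    if A0 <= 0:
        raise FitFailureError("fitted amplitude is not positive: no decaying admixture LD")
    resid = y - model(d, *popt)
    flat = y - y.mean()
    if (resid**2).sum() > 0.999 * (flat**2).sum():
        raise FitFailureError("curve is not distinguishable from flat")
    return DatingResult(float(n), float(A0), float(c),
                        float(fit_min_cm), float(d.max()))
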