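"""EHH / iHS scan for recent positive selection on phased haplotypes.

EHH(x) at a flanking variant x is the probability that two randomly drawn
carrier haplotypes of the core allele are identical at every variant from
the core out to x.  iHH integrates EHH over genetic distance (trapezoid,
truncated where EHH first falls below a cutoff); the unstandardized score
is ln(iHH_ancestral / iHH_derived), standardized to zero mean and unit SD
within derived-allele-frequency bins, with a two-sided Gaussian p-value.
Long, unusually homozygous haplotypes around a high-frequency derived
allele (strongly negative or positive iHS after standardization) signal an
incomplete selective sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


#: Haplotype entries: 0/1 alleles; -1 marks a missing allele call.
HAP_MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes with ancestral-allele polarity.

    ``haps`` is (n_haplotypes, n_variants) int8 in {0, 1, HAP_MISSING};
    ``derived_is_alt[v]`` says whether the 1-coded allele at variant v is
    the derived one.  ``genetic_pos`` is in Morgans (defaults to the
    1 cM = 1 Mb map when built from physical positions).
    """

    haps: np.ndarray
    variants: pd.DataFrame  # chrom, pos (1-based)
    derived_is_alt: np.ndarray
    genetic_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.derived_is_alt = np.asarray(self.derived_is_alt, dtype=bool)
        if self.genetic_pos is None:
            self.genetic_pos = self.variants["pos"].to_numpy() * 1e-8
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        if not np.isin(self.haps, (0, 1, HAP_MISSING)).all():
            raise ValueError("haplotype entries must be 0/1/missing")

    @property
    def n_haps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haps.shape[1]

    def derived_freq(self) -> np.ndarray:
        ok = self.haps != HAP_MISSING
        alt = np.where(ok, self.haps, 0).sum(axis=0) / ok.sum(axis=0)
        return np.where(self.derived_is_alt, alt, 1.0 - alt)


@dataclass
class EHHCurve:
    """EHH values at the core (value 1) and outward on one side."""

    indices: np.ndarray       # variant indices, core first
    genetic_pos: np.ndarray   # Morgans at those variants
    ehh: np.ndarray


class UndefinedScoreError(ValueError):
    """Fewer than 2 carrier haplotypes: EHH is undefined for this core."""


def ehh(H: HaplotypeMatrix, core: int, allele: str,
        stop_below: float | None = None) -> tuple[EHHCurve, EHHCurve]:
    """Left and right EHH curves for one core allele.

    ``allele`` is "ancestral" or "derived".  Haplotypes with a missing call
    in the extended window are dropped from the homozygosity count at that
    and all further flanks (pairwise-complete convention).  With
    ``stop_below`` set, each side stops at the first flank whose EHH falls
    below that value (the iHS integral never looks further).
    """
    code = _allele_code(H, core, allele)
    carriers = np.flatnonzero(H.haps[:, core] == code)
    if len(carriers) < 2:
        raise UndefinedScoreError(
            f"core {core}: fewer than 2 carriers of the {allele} allele"
        )
    left = _ehh_one_side(H, core, carriers, -1, stop_below)
    right = _ehh_one_side(H, core, carriers, +1, stop_below)
    return left, right


def _allele_code(H: HaplotypeMatrix, core: int, allele: str) -> int:
    if allele not in ("ancestral", "derived"):
        raise ValueError("allele must be 'ancestral' or 'derived'")
    derived_code = 1 if H.derived_is_alt[core] else 0
    return derived_code if allele == "derived" else 1 - derived_code


def _ehh_one_side(H: HaplotypeMatrix, core: int, carriers: np.ndarray,
                  step: int, stop_below: float | None):
    chroms = H.variants["chrom"].to_numpy()
    j = core + step
    lim = j
    while 0 <= lim < H.n_variants and chroms[lim] == chroms[core]:
        lim += step
    flank = np.arange(j, lim, step)
    sub = np.ascontiguousarray(H.haps[np.ix_(carriers, flank)])
    vals = _ehh_kernel(sub, -1.0 if stop_below is None else float(stop_below))
    idx = np.r_[core, flank[: len(vals)]]
    return EHHCurve(idx, H.genetic_pos[idx], np.r_[1.0, vals])


def _ehh_kernel_py(haps: np.ndarray, stop_below: float) -> np.ndarray:
    """Prefix-homozygosity along columns of ``haps`` (carriers x flanks)."""
    n_c, L = haps.shape
    group = np.zeros(n_c, dtype=np.int64)
    alive = np.ones(n_c, dtype=np.bool_)
    out = np.empty(L)
    used = 0
    denom = n_c * (n_c - 1)
    for col in range(L):
        for h in range(n_c):
            if haps[h, col] < 0:
                alive[h] = False
        key = np.empty(n_c, dtype=np.int64)
        for h in range(n_c):
            key[h] = group[h] * 2 + haps[h, col] if alive[h] else -1 - h
        order = np.argsort(key, kind="mergesort")
        gid = 0
        prev = key[order[0]]
        for r in range(n_c):
            k = key[order[r]]
            if k != prev:
                gid += 1
                prev = k
            group[order[r]] = gid
        s = 0
        counts = np.zeros(gid + 1, dtype=np.int64)
        for h in range(n_c):
            if alive[h]:
                counts[group[h]] += 1
        for c in counts:
            s += c * (c - 1)
        hom = s / denom
        out[used] = hom
        used += 1
        if hom < stop_below:
            break
    return out[:used]


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _ehh_kernel = njit(cache=True)(_ehh_kernel_py)
except Exception:  # pragma: no cover
    _ehh_kernel = _ehh_kernel_py


def ihh(left: EHHCurve, right: EHHCurve, cutoff: float = 0.05):
    """Integrated EHH (Morgans), truncated at the cutoff on each side.

    Returns ``(value, edge_truncated)``; ``edge_truncated`` is True when a
    side reaches the chromosome edge before EHH drops below the cutoff, in
    which case the core should be excluded from standardization.
    """
    total = 0.0
    truncated = False
    for curve in (left, right):
        total_side, hit = _ihh_one_side(curve, cutoff)
        total += total_side
        truncated |= hit
    return total, truncated


def _ihh_one_side(curve: EHHCurve, cutoff: float):
    e = curve.ehh
    g = curve.genetic_pos
    if e[0] < cutoff:
        return 0.0, False
    area = 0.0
    for k in range(1, len(e)):
        d = abs(g[k] - g[k - 1])
        area += 0.5 * (e[k] + e[k - 1]) * d
        if e[k] < cutoff:
            return area, False
    # ran off the end of the curve without dropping below cutoff
    return area, True


def ihs_scan(H: HaplotypeMatrix, min_maf: float = 0.01, cutoff: float = 0.05,
             bin_width: float = 0.02, min_bin_cores: int = 10) -> pd.DataFrame:
    """Genome-wide iHS with frequency-bin standardization.

    Cores must pass the folded MAF filter and have >= 2 carriers of both
    alleles; cores whose EHH hits a chromosome edge before the cutoff are
    flagged and excluded from standardization.  Standardization bins span
    the derived frequency in ``bin_width`` steps; bins with fewer than
    ``min_bin_cores`` usable cores are merged with their neighbor.

    Returns a DataFrame with columns chrom, pos, daf, ihh_a, ihh_d,
    uihs (ln iHH_A/iHH_D), ihs (standardized), p_value, edge_truncated.
    """
    daf = H.derived_freq()
    maf = np.minimum(daf, 1 - daf)
    rows = []
    for core in np.flatnonzero(maf >= min_maf):
        try:
            la, ra = ehh(H, core, "ancestral", stop_below=cutoff)
            ld, rd = ehh(H, core, "derived", stop_below=cutoff)
        except UndefinedScoreError:
            continue
        ihh_a, trunc_a = ihh(la, ra, cutoff)
        ihh_d, trunc_d = ihh(ld, rd, cutoff)
        if ihh_a <= 0 or ihh_d <= 0:
            continue
        rows.append(
            {
                "index": core,
                "chrom": H.variants["chrom"].iloc[core],
                "pos": int(H.variants["pos"].iloc[core]),
                "daf": daf[core],
                "ihh_a": ihh_a,
                "ihh_d": ihh_d,
                "uihs": float(np.log(ihh_a / ihh_d)),
                "edge_truncated": bool(trunc_a or trunc_d),
            }
        )
    if not rows:
        raise ValueError("no scorable cores (all edge-truncated or filtered)")
    df = pd.DataFrame(rows)
    usable = ~df["edge_truncated"]
    if not usable.any():
        raise ValueError("every core is edge-truncated; nothing to standardize")
    df["ihs"] = np.nan
    bin_ids = _merged_freq_bins(df.loc[usable, "daf"].to_numpy(), bin_width, min_bin_cores)
    u = df.loc[usable, "uihs"].to_numpy()
    z = np.empty_like(u)
    for b in np.unique(bin_ids):
        inb = bin_ids == b
        mu, sd = u[inb].mean(), u[inb].std()
        z[inb] = (u[inb] - mu) / sd if sd > 0 else 0.0
    df.loc[usable, "ihs"] = z
    df["p_value"] = 2 * stats.norm.sf(np.abs(df["ihs"]))
    return df.drop(columns="index").reset_index(drop=True)


def _merged_freq_bins(daf: np.ndarray, bin_width: float, min_cores: int) -> np.ndarray:
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    ids = np.clip(np.digitize(daf, edges) - 1, 0, len(edges) - 2)
    # merge sparse bins into the next non-empty bin to the right (last bin
    # merges leftward)
    uniq = np.unique(ids)
    remap = {b: b for b in uniq}
    counts = {b: int((ids == b).sum()) for b in uniq}
    ordered = sorted(uniq)
    for i, b in enumerate(ordered):
        if counts[b] < min_cores and i + 1 < len(ordered):
            nxt = ordered[i + 1]
            counts[nxt] += counts[b]
            counts[b] = 0
            for k, v in remap.items():
                if v == b:
                    remap[k] = nxt
    # a trailing sparse bin merges into the previous surviving bin
    last = ordered[-1]
    if counts[last] and counts[last] < min_cores:
        prev = [b for b in ordered if counts[b] >= min_cores and b != last]
        if prev:
            tgt = prev[-1]
            counts[tgt] += counts[last]
            for k, v in remap.items():
                if v == last:
                    remap[k] = tgt
    return np.array([remap[b] for b in ids])


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def read_phased_vcf(path, ancestral_tsv=None, rec_per_bp: float = 1e-8) -> HaplotypeMatrix:
    """Read phased GT haplotypes from a VCF.

    Ancestral alleles come from the INFO/AA tag, overridden by an optional
    sidecar TSV with columns (chrom, pos, ancestral_allele).  Variants
    without ancestral information or with unphased genotypes are dropped.
    ``rec_per_bp`` converts physical to genetic positions (default the
    1 cM = 1 Mb map).
    """
    from cyvcf2 import VCF

    aa_map = {}
    if ancestral_tsv is not None:
        side = pd.read_csv(ancestral_tsv, sep="\t",
                           names=["chrom", "pos", "aa"], dtype={"chrom": str})
        aa_map = {(r.chrom, int(r.pos)): str(r.aa).upper() for r in side.itertuples()}

    haps_cols, chroms, poss, der_is_alt = [], [], [], []
    vcf = VCF(str(path))
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        aa = aa_map.get((v.CHROM, v.POS))
        if aa is None:
            info_aa = v.INFO.get("AA")
            aa = str(info_aa).upper() if info_aa is not None else None
        if aa not in (v.REF.upper(), v.ALT[0].upper()):
            continue
        gts = np.asarray(v.genotype.array())
        if not (gts[:, 2] > 0).all():  # phased flag per sample
            continue
        col = gts[:, :2].reshape(-1).astype(np.int8)
        col[col < 0] = HAP_MISSING
        haps_cols.append(col)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        der_is_alt.append(aa == v.REF.upper())
    if not haps_cols:
        raise ValueError("no usable phased biallelic variants with ancestral info")
    haps = np.column_stack(haps_cols)
    variants = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64)})
    return HaplotypeMatrix(
        haps, variants, np.asarray(der_is_alt),
        genetic_pos=np.asarray(poss, dtype=float) * rec_per_bp,
    )


def from_sim_window(window, rec_per_bp: float) -> HaplotypeMatrix:
    """Pooled haplotypes of a simulated window (allele 0 ancestral)."""
    haps = window.pooled()
    variants = pd.DataFrame(
        {"chrom": [f"w{window.index}"] * window.n_sites, "pos": window.positions}
    )
    return HaplotypeMatrix(
        haps, variants, np.ones(window.n_sites, dtype=bool),
        genetic_pos=(window.positions - 1) * rec_per_bp,
    )
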