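"""Synthetic inputs for the pipeline.

Two generators live here:

* :func:`simulate_windows` — neutral coalescent-with-recombination windows
  under a three-population history (two sources split ``t_div`` generations
  ago; an admixed deme formed by a single pulse ``t_adm`` generations ago
  with source-1 fraction ``m_papuan``), with optional SNP-array-style
  ascertainment that matches a target minor-allele-frequency histogram.
  This is the null model for the ancestry-excess scan.

* :func:`simulate_tract_admixture` — a fast tract-copying generator: ancestry
  tracts follow a Markov jump process along the genetic map (switch rate
  ``T`` per Morgan, stationary mixture ``m``) and alleles are drawn from
  panel frequencies.  The true per-site ancestry dosage is recorded, which
  makes it the oracle for validating the local-ancestry HMM, f3 and the
  admixture-LD dating.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import msprime
import numpy as np
import pandas as pd

from .genodata import AlleleFrequencyPanel, GenotypeMatrix

#: Haploid sample sizes mirroring the study design (Papuan-side source,
#: admixed, Asian-side source).
DEFAULT_CHROMS = {"Gidra": 48, "Munda": 40, "CHB": 90}


@dataclass
class DemographyConfig:
    """All symbols of the neutral simulation.

    Defaults give the standard preset: per-population diploid size 1000,
    source split 1667 generations ago (50 kyr at 30 yr/generation), a single
    admixture pulse 77 generations ago with Papuan fraction 0.5137, mutation
    rate 1.2e-8 and recombination rate 1.3e-8 per base per generation,
    independent 2 Mb windows (1500 of them tile a 3 Gb genome), and 146,090
    ascertained SNPs genome-wide.  The lower-recombination variant
    (``rec=8.5e-9``) models the reduced crossover rate of the HLA region.
    """

    Ne: float = 1000.0
    t_div: float = 1667.0
    t_adm: float = 77.0
    m_papuan: float = 0.5137
    mu: float = 1.2e-8
    rec: float = 1.3e-8
    window_bp: int = 2_000_000
    n_windows: int = 1500
    chroms: dict = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    n_snps_target: int = 146_090
    seed: int = 1
    #: optional extra demes: outgroup split at 4*t_div and an Asian-side
    #: sister ("TWN") split at t_adm, used by the f4-ratio validation
    with_outgroup: bool = False
    outgroup_chroms: int = 40
    twn_chroms: int = 40

    def __post_init__(self) -> None:
        if not self.t_adm < self.t_div:
            raise ValueError("t_adm must be < t_div")
        if not 0.0 <= self.m_papuan <= 1.0:
            raise ValueError("m_papuan must lie in [0, 1]")
        if min(self.mu, self.rec) < 0 or self.Ne <= 0:
            raise ValueError("rates must be >= 0 and Ne > 0")
        if any(n <= 0 for n in self.chroms.values()):
            raise ValueError("sample sizes must be positive")


@dataclass
class SimWindow:
    """One simulated window: phased haplotypes partitioned by population."""

    index: int
    haplotypes: dict  # population -> (n_hap, n_sites) int8 array, 0=ancestral
    positions: np.ndarray  # 1-based bp within [1, window_bp]
    genetic_pos: np.ndarray  # Morgans, = (positions - 1) * rec

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def pooled(self) -> np.ndarray:
        return np.vstack([self.haplotypes[p] for p in self.haplotypes])


@dataclass
class TractTruth:
    """True ancestry tracts of the tract-copying generator.

    ``tracts[h]`` is a list of ``(start_bp, end_bp, ancestry)`` with
    ancestry in {"P", "A"}; consecutive haplotype pairs form individuals.
    ``dosage`` is the per-(individual, site) true Papuan dosage in {0,1,2}.
    """

    tracts: list
    dosage: np.ndarray


# ---------------------------------------------------------------------------
# Coalescent windows
# ---------------------------------------------------------------------------

def _demography(cfg: DemographyConfig) -> msprime.Demography:
    dem = msprime.Demography()
    for name in ("Gidra", "CHB", "Munda"):
        dem.add_population(name=name, initial_size=cfg.Ne)
    dem.add_population(name="ANC", initial_size=cfg.Ne)
    if cfg.with_outgroup:
        dem.add_population(name="TWN", initial_size=cfg.Ne)
        dem.add_population(name="OUT", initial_size=cfg.Ne)
        dem.add_population(name="ROOT", initial_size=cfg.Ne)
    dem.add_admixture(
        time=cfg.t_adm,
        derived="Munda",
        ancestral=["Gidra", "CHB"],
        proportions=[cfg.m_papuan, 1.0 - cfg.m_papuan],
    )
    if cfg.with_outgroup:
        dem.add_population_split(time=cfg.t_adm, derived=["TWN"], ancestral="CHB")
        dem.add_population_split(time=cfg.t_div, derived=["Gidra", "CHB"], ancestral="ANC")
        dem.add_population_split(time=4 * cfg.t_div, derived=["ANC", "OUT"], ancestral="ROOT")
    else:
        dem.add_population_split(time=cfg.t_div, derived=["Gidra", "CHB"], ancestral="ANC")
    dem.sort_events()
    return dem


def _sample_sets(cfg: DemographyConfig) -> dict:
    chroms = dict(cfg.chroms)
    if cfg.with_outgroup:
        chroms["TWN"] = cfg.twn_chroms
        chroms["OUT"] = cfg.outgroup_chroms
    for pop, n in chroms.items():
        if n % 2:
            raise ValueError(f"haploid sample size for {pop} must be even")
    return chroms


def simulate_windows(cfg: DemographyConfig):
    """Yield :class:`SimWindow` replicates under the configured history.

    Windows are independent (they stand for well-separated genomic chunks).
    Only biallelic segregating sites are retained; allele 0 is ancestral.
    Deterministic given ``cfg.seed``.
    """
    chroms = _sample_sets(cfg)
    dem = _demography(cfg)
    samples = [
        msprime.SampleSet(n // 2, population=pop, ploidy=2)
        for pop, n in chroms.items()
    ]
    ss = np.random.SeedSequence(cfg.seed)
    anc_seed, mut_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) + 1
                          for s in ss.spawn(2))
    replicates = msprime.sim_ancestry(
        samples=samples,
        demography=dem,
        sequence_length=cfg.window_bp,
        recombination_rate=cfg.rec,
        num_replicates=cfg.n_windows,
        random_seed=anc_seed,
    )
    bounds = np.cumsum([0] + list(chroms.values()))
    pops = list(chroms)
    for index, ts in enumerate(replicates):
        mts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=(mut_seed + index) % (2**31 - 1) + 1,
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix()  # (sites, haps), 0/1 under binary model
        pos = np.array([int(s.position) + 1 for s in mts.sites()], dtype=np.int64)
        # collapse possible duplicate discrete positions: keep first
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = np.diff(pos) > 0
        seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < geno.shape[1])
        keep &= seg
        geno = geno[keep]
        pos = pos[keep]
        haps = {
            pop: np.ascontiguousarray(geno[:, bounds[i]:bounds[i + 1]].T, dtype=np.int8)
            for i, pop in enumerate(pops)
        }
        yield SimWindow(index, haps, pos, (pos - 1) * cfg.rec)


# ---------------------------------------------------------------------------
# Array-style ascertainment
# ---------------------------------------------------------------------------

def default_maf_histogram() -> np.ndarray:
    """Package default target MAF histogram (50 bins of width 0.01 on
    (0, 0.5]): flat above 0.05 with a linear taper below.  Replaceable by
    any user histogram of the same shape."""
    with resources.files("admixsel.data").joinpath("maf_histogram.json").open() as fh:
        payload = json.load(fh)
    hist = np.asarray(payload["hist"], dtype=float)
    return hist / hist.sum()


def load_maf_histogram(path) -> np.ndarray:
    with open(path) as fh:
        payload = json.load(fh)
    hist = np.asarray(payload["hist"], dtype=float)
    if len(hist) != 50 or (hist < 0).any():
        raise ValueError("histogram must have 50 non-negative bins of width 0.01")
    return hist / hist.sum()


def pooled_folded_maf(window: SimWindow) -> np.ndarray:
    pooled = window.pooled()
    f = pooled.mean(axis=0)
    return np.minimum(f, 1.0 - f)


def ascertain_variants(windows, target_hist, n_target: int, seed: int):
    """Subsample sites so the pooled folded MAF matches ``target_hist``.

    Per-bin quotas use largest-remainder rounding of ``n_target *
    target_hist``; sites are drawn without replacement within each bin.  A
    bin whose quota exceeds its supply is capped at the supply with a
    warning.  Genotypes at retained sites are untouched.
    """
    windows = list(windows)
    target_hist = np.asarray(target_hist, dtype=float)
    if not np.isclose(target_hist.sum(), 1.0):
        raise ValueError("target_hist must sum to 1")
    total_sites = sum(w.n_sites for w in windows)
    if n_target > total_sites:
        raise ValueError(f"n_target={n_target} exceeds available sites {total_sites}")

    # bin index of every site: bin b covers (b/100, (b+1)/100]
    bins, owners = [], []
    for wi, w in enumerate(windows):
        maf = pooled_folded_maf(w)
        b = np.ceil(maf * 100).astype(int) - 1  # maf in (0, .5] -> 0..49
        bins.append(b)
        owners.append(np.full(w.n_sites, wi))
    bins = np.concatenate(bins) if bins else np.empty(0, int)
    owners = np.concatenate(owners) if owners else np.empty(0, int)
    flat_index = np.concatenate([np.arange(w.n_sites) for w in windows]) if windows else np.empty(0, int)

    quota = _largest_remainder(n_target * target_hist)
    rng = np.random.default_rng(seed)
    chosen = []
    for b in range(len(target_hist)):
        pool = np.flatnonzero(bins == b)
        q = quota[b]
        if q > len(pool):
            warnings.warn(
                f"MAF bin {b}: demand {q} exceeds supply {len(pool)}; capped",
                stacklevel=2,
            )
            q = len(pool)
        if q:
            chosen.append(rng.choice(pool, size=q, replace=False))
    chosen = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, int)

    out = []
    for wi, w in enumerate(windows):
        sel = flat_index[chosen[owners[chosen] == wi]]
        sel.sort()
        out.append(
            SimWindow(
                w.index,
                {p: h[:, sel] for p, h in w.haplotypes.items()},
                w.positions[sel],
                w.genetic_pos[sel],
            )
        )
    return out


def _largest_remainder(raw: np.ndarray) -> np.ndarray:
    base = np.floor(raw).astype(int)
    short = int(round(raw.sum())) - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# Haplotypes -> genotypes
# ---------------------------------------------------------------------------

def haplotypes_to_genotypes(window: SimWindow, chrom_label: str | None = None) -> GenotypeMatrix:
    """Pair consecutive haplotypes into diploid individuals.

    No missingness is introduced; column sums of genotypes equal the
    haplotype allele counts by construction.
    """
    chrom = chrom_label if chrom_label is not None else f"w{window.index}"
    calls, sample_ids, pops = [], [], []
    for pop, haps in window.haplotypes.items():
        if haps.shape[0] % 2:
            raise ValueError(f"odd haplotype count for {pop}")
        dosage = haps[0::2] + haps[1::2]
        calls.append(dosage)
        n_ind = haps.shape[0] // 2
        sample_ids += [f"{pop}_{window.index}_{k}" for k in range(n_ind)]
        pops += [pop] * n_ind
    return GenotypeMatrix.from_arrays(
        np.vstack(calls), chrom, window.positions, sample_ids, pops,
        ids=[f"{chrom}:{p}" for p in window.positions],
    )


# ---------------------------------------------------------------------------
# Tract-copying admixture generator (known truth)
# ---------------------------------------------------------------------------

def simulate_tract_admixture(panelP: AlleleFrequencyPanel, panelA: AlleleFrequencyPanel,
                             genetic_pos: np.ndarray, T: float, m: float,
                             n_ind: int, seed: int,
                             population: str = "admixed"):
    """Generate admixed diploid genotypes with known ancestry truth.

    Each haplotype's ancestry along a chromosome is a two-state Markov jump
    process on the genetic map: switch points arrive as a Poisson process
    with rate ``T`` per Morgan and the ancestry after every switch point is
    Papuan with probability ``m`` (so Papuan tracts are exponential with
    mean ``1/(T*(1-m))`` Morgans).  Alleles are independent Bernoulli draws
    from the local ancestry's panel frequency.

    Parameters
    ----------
    genetic_pos : array of Morgans, one per shared panel variant; chromosome
        structure is taken from ``panelP.variants["chrom"]``.
    """
    if not panelP.variants[["chrom", "pos"]].equals(panelA.variants[["chrom", "pos"]]):
        raise ValueError("panels must share variants")
    if T <= 0 or not 0.0 <= m <= 1.0:
        raise ValueError("need T > 0 and 0 <= m <= 1")
    rng = np.random.default_rng(seed)
    n_var = len(panelP.freq)
    gpos = np.asarray(genetic_pos, dtype=float)
    fP = np.where(np.isnan(panelP.freq), 0.5, panelP.freq)
    fA = np.where(np.isnan(panelA.freq), 0.5, panelA.freq)
    chrom_codes, chrom_starts = _chrom_runs(panelP.variants["chrom"].to_numpy())

    hap_anc = np.empty((2 * n_ind, n_var), dtype=np.int8)  # 1 = Papuan
    tracts = [[] for _ in range(2 * n_ind)]
    pos_bp = panelP.variants["pos"].to_numpy()
    for h in range(2 * n_ind):
        for c0, c1 in zip(chrom_starts[:-1], chrom_starts[1:]):
            g = gpos[c0:c1]
            anc = 1 if rng.random() < m else 0
            span_start = pos_bp[c0]
            length = g[-1] - g[0]
            # switch points of the Poisson process along this chromosome
            n_sw = rng.poisson(T * length) if length > 0 else 0
            sw = np.sort(rng.uniform(g[0], g[-1], size=n_sw))
            cur = anc
            seg_start = span_start
            site_anc = np.empty(c1 - c0, dtype=np.int8)
            si = 0
            boundary = list(sw) + [np.inf]
            bi = 0
            for si in range(c1 - c0):
                while g[si] > boundary[bi]:
                    new = 1 if rng.random() < m else 0
                    if new != cur:
                        bp_here = _interp_bp(boundary[bi], g, pos_bp[c0:c1])
                        tracts[h].append((seg_start, bp_here, "P" if cur else "A"))
                        seg_start = bp_here
                        cur = new
                    bi += 1
                site_anc[si] = cur
            # flush remaining switch points beyond the last site (no effect on sites)
            tracts[h].append((seg_start, pos_bp[c1 - 1], "P" if cur else "A"))
            hap_anc[h, c0:c1] = site_anc

    freq = np.where(hap_anc == 1, fP[None, :], fA[None, :])
    alleles = (rng.random(freq.shape) < freq).astype(np.int8)
    calls = alleles[0::2] + alleles[1::2]
    dosage_truth = hap_anc[0::2] + hap_anc[1::2]

    G = GenotypeMatrix(
        panelP.variants.copy(),
        pd.DataFrame(
            {
                "sample_id": [f"{population}_{k}" for k in range(n_ind)],
                "population": [population] * n_ind,
            }
        ),
        calls,
    )
    return G, TractTruth(tracts, dosage_truth)


def _interp_bp(g, gvec, bpvec):
    """Physical position of a genetic-map coordinate, linear within the map."""
    return float(np.interp(g, gvec, bpvec))


def _chrom_runs(chrom: np.ndarray):
    codes = pd.factorize(chrom)[0]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    return codes, np.r_[starts, len(chrom)]


# ---------------------------------------------------------------------------
# Random diverged panels (drift-only, Balding–Nichols style)
# ---------------------------------------------------------------------------

def diverged_panels(n_variants: int, fst: float, seed: int,
                    spacing_bp: int = 20_000, chrom_bp: int = 100_000_000,
                    n_obs: int = 100):
    """Two source panels drifted apart from common ancestral frequencies.

    Ancestral frequencies are uniform on (0.05, 0.95); each panel's
    frequency is Beta-distributed around the ancestral value with
    Balding–Nichols variance parameter ``fst``.  Variants are laid out every
    ``spacing_bp`` on consecutive chromosomes of ``chrom_bp``.
    """
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_variants)
    lam = (1.0 - fst) / fst
    fP = rng.beta(p0 * lam, (1 - p0) * lam)
    fA = rng.beta(p0 * lam, (1 - p0) * lam)
    per_chrom = chrom_bp // spacing_bp
    idx = np.arange(n_variants)
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in idx], dtype=object)
    pos = (idx % per_chrom + 1) * spacing_bp
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"v{i}" for i in idx],
         "a1": "A", "a2": "G"}
    )
    n_obs_arr = np.full(n_variants, n_obs)
    return (
        AlleleFrequencyPanel(variants, fP, n_obs_arr),
        AlleleFrequencyPanel(variants, fA, n_obs_arr),
    )


def panel_to_genotypes(panel: AlleleFrequencyPanel, n_ind: int, seed: int,
                       population: str) -> GenotypeMatrix:
    """Draw diploid genotypes binomially from panel frequencies (HWE)."""
    rng = np.random.default_rng(seed)
    f = np.where(np.isnan(panel.freq), 0.5, panel.freq)
    calls = rng.binomial(2, f[None, :], size=(n_ind, len(f))).astype(np.int8)
    return GenotypeMatrix(
        panel.variants.copy(),
        pd.DataFrame(
            {
                "sample_id": [f"{population}_{k}" for k in range(n_ind)],
                "population": [population] * n_ind,
            }
        ),
        calls,
    )


# ---------------------------------------------------------------------------
# VCF export of phased window haplotypes
# ---------------------------------------------------------------------------

def write_window_vcf(window: SimWindow, path, chrom_label: str | None = None) -> None:
    """Write phased haplotypes of one window as an uncompressed VCF.

    Allele 0 is written as REF=A (ancestral), allele 1 as ALT=G, with the
    ancestral allele recorded in INFO/AA.
    """
    chrom = chrom_label if chrom_label is not None else f"w{window.index}"
    names, cols = [], []
    for pop, haps in window.haplotypes.items():
        n_ind = haps.shape[0] // 2
        names += [f"{pop}_{window.index}_{k}" for k in range(n_ind)]
        cols.append(haps)
    haps = np.vstack(cols)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for s in range(window.n_sites):
            gts = "\t".join(
                f"{haps[2 * k, s]}|{haps[2 * k + 1, s]}" for k in range(len(names))
            )
            fh.write(
                f"{chrom}\t{window.positions[s]}\t{chrom}:{window.positions[s]}\t"
                f"A\tG\t.\tPASS\tAA=A\tGT\t{gts}\n"
            )
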