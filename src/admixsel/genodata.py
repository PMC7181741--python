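"""Genotype containers, text-format I/O, QC filters and panel allele frequencies.

Conventions used throughout the package:

* Coordinates are 1-based inclusive (PLINK/VCF convention); the length of a
  region is ``end_pos - start_pos`` in bp.
* Diploid genotypes are stored as dosages of the alt-like allele,
  ``{0, 1, 2}``, with :data:`MISSING` (``-1``) as the missing sentinel.
  Missing is never conflated with dosage 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid call.  Distinct from dosage 0.
MISSING: int = -1

#: Strand-ambiguous (palindromic) allele pairs dropped when merging datasets.
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

VARIANT_COLUMNS = ["chrom", "pos", "id", "a1", "a2"]


class MalformedInputError(ValueError):
    """Raised when a text input violates the declared format."""


class TriallelicVariantError(ValueError):
    """Raised when more than two distinct alleles are observed at a variant."""


def _as_variant_frame(chrom, pos, vid, a1, a2) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "id": np.asarray(vid, dtype=object),
            "a1": np.asarray(a1, dtype=object),
            "a2": np.asarray(a2, dtype=object),
        }
    )
    return df


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid dosage matrix with population labels.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``chrom, pos, id, a1, a2``; within each chromosome the rows
        are sorted by ``pos`` strictly increasing.  ``a2`` is the counted
        (alt-like) allele.
    samples : pandas.DataFrame
        Columns ``sample_id, population``.
    calls : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if (self.samples["population"].astype(str) == "").any():
            raise ValueError("population labels must be non-empty")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        if (self.variants["a1"] == self.variants["a2"]).any():
            raise ValueError("the two alleles of a variant must be distinct")
        for _, pos in self.variants.groupby("chrom", sort=False)["pos"]:
            if not (np.diff(pos.to_numpy()) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")

    # -- basic introspection ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_mask(self, population: str) -> np.ndarray:
        mask = (self.samples["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown population label: {population!r}")
        return mask

    # -- subsetting ---------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.variants.iloc[index], self.samples, self.calls[:, index]
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.variants, self.samples[mask], self.calls[mask])

    @staticmethod
    def from_arrays(calls, chrom, pos, sample_ids, populations, ids=None,
                    a1=None, a2=None) -> "GenotypeMatrix":
        """Convenience constructor with synthetic ids/alleles by default."""
        calls = np.asarray(calls, dtype=np.int8)
        n_var = calls.shape[1]
        chrom = np.broadcast_to(np.asarray(chrom, dtype=object), (n_var,))
        if ids is None:
            ids = [f"{c}:{p}" for c, p in zip(chrom, pos)]
        if a1 is None:
            a1 = ["A"] * n_var
        if a2 is None:
            a2 = ["G"] * n_var
        variants = _as_variant_frame(chrom, pos, ids, a1, a2)
        samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
        return GenotypeMatrix(variants, samples, calls)

    @staticmethod
    def stack_samples(*parts: "GenotypeMatrix") -> "GenotypeMatrix":
        """Stack matrices that share an identical variant table."""
        first = parts[0]
        for p in parts[1:]:
            if not first.variants[["chrom", "pos", "a1", "a2"]].equals(
                p.variants[["chrom", "pos", "a1", "a2"]]
            ):
                raise ValueError("variant tables differ; intersect first")
        samples = pd.concat([p.samples for p in parts], ignore_index=True)
        calls = np.vstack([p.calls for p in parts])
        return GenotypeMatrix(first.variants, samples, calls)


@dataclass
class AlleleFrequencyPanel:
    """Per-variant alt-allele frequencies of a reference panel.

    ``freq`` is NaN where every call is missing (``n_obs == 0``).
    ``n_obs`` counts non-missing *alleles* (2 per genotyped diploid sample).
    """

    variants: pd.DataFrame
    freq: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        defined = self.n_obs > 0
        f = self.freq[defined]
        if f.size and ((f < 0).any() or (f > 1).any()):
            raise ValueError("frequencies must lie in [0, 1]")
        if (self.n_obs < 0).any():
            raise ValueError("n_obs must be non-negative")

    def smoothed(self, pseudocount: float = 0.5) -> np.ndarray:
        """Pseudocount-smoothed frequency, strictly inside (0, 1).

        ``(freq * n_obs + pseudocount) / (n_obs + 2 * pseudocount)`` — a
        Jeffreys-like shrinkage that keeps panel-fixed sites usable as HMM
        emission probabilities.  Sites with ``n_obs == 0`` shrink to 0.5.
        """
        n = self.n_obs.astype(float)
        counts = np.where(np.isnan(self.freq), 0.0, self.freq) * n
        return (counts + pseudocount) / (n + 2.0 * pseudocount)


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_plink_text(ped_source, map_source, allele_key=None) -> GenotypeMatrix:
    """Read a text PED/MAP pair into a :class:`GenotypeMatrix`.

    The MAP file has 4 whitespace-separated columns (chrom, id, cM, bp); each
    PED row has 6 metadata columns followed by two allele columns per MAP
    variant.  ``"0"`` alleles encode missing.  The alt-like (counted) allele
    is the minor allele in the file, ties broken lexicographically, unless
    ``allele_key`` maps variant id -> counted allele.  The PED family ID
    (first column) is used as the population label.
    """
    map_rows = _read_lines(map_source)
    chrom, vid, pos = [], [], []
    for i, line in enumerate(map_rows):
        parts = line.split()
        if len(parts) != 4:
            raise MalformedInputError(f"MAP row {i + 1}: expected 4 columns, got {len(parts)}")
        chrom.append(parts[0])
        vid.append(parts[1])
        pos.append(int(parts[3]))
    n_var = len(vid)

    ped_rows = _read_lines(ped_source)
    sample_ids, pops = [], []
    raw = np.empty((len(ped_rows), 2 * n_var), dtype=object)
    for i, line in enumerate(ped_rows):
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise MalformedInputError(
                f"PED row {i + 1}: expected {6 + 2 * n_var} columns "
                f"(6 metadata + 2 per variant), got {len(parts)}"
            )
        pops.append(parts[0])
        sample_ids.append(parts[1])
        raw[i] = parts[6:]

    n_samples = len(ped_rows)
    calls = np.full((n_samples, n_var), MISSING, dtype=np.int8)
    a1_out, a2_out = [], []
    for j in range(n_var):
        al1 = raw[:, 2 * j]
        al2 = raw[:, 2 * j + 1]
        observed = [a for a in np.unique(np.concatenate([al1, al2])) if a != "0"]
        if len(observed) > 2:
            raise TriallelicVariantError(
                f"variant {vid[j]}: more than two alleles observed: {observed}"
            )
        alt = _choose_alt(vid[j], observed, al1, al2, allele_key)
        ref = next((a for a in observed if a != alt), _other_allele(alt))
        missing = (al1 == "0") | (al2 == "0")
        dosage = (al1 == alt).astype(np.int8) + (al2 == alt).astype(np.int8)
        calls[:, j] = np.where(missing, MISSING, dosage)
        a1_out.append(ref)
        a2_out.append(alt)

    variants = _as_variant_frame(chrom, pos, vid, a1_out, a2_out)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops})
    return GenotypeMatrix(variants, samples, calls)


def _choose_alt(vid, observed, al1, al2, allele_key):
    if allele_key is not None and vid in allele_key:
        return allele_key[vid]
    if not observed:
        return "A"  # fully missing variant; allele labels are arbitrary
    if len(observed) == 1:
        return observed[0]
    counts = {a: int((al1 == a).sum() + (al2 == a).sum()) for a in observed}
    # minor allele; ties broken lexicographically
    return min(observed, key=lambda a: (counts[a], a))


def _other_allele(alt):
    return "A" if alt != "A" else "G"


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    return [ln for ln in text.splitlines() if ln.strip()]


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_variant_callrate(G: GenotypeMatrix, min_rate: float,
                            per_population: bool = True) -> GenotypeMatrix:
    """Keep variants whose non-missing call fraction is >= ``min_rate``.

    With ``per_population`` the criterion must hold in every population
    separately (PLINK ``--geno`` applied per panel), otherwise over all
    samples pooled.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must lie in [0, 1]")
    present = called_mask(G.calls)
    if per_population:
        keep = np.ones(G.n_variants, dtype=bool)
        for pop in G.populations():
            mask = G.sample_mask(pop)
            rate = present[mask].mean(axis=0)
            keep &= rate >= min_rate
    else:
        keep = present.mean(axis=0) >= min_rate
    if not keep.any():
        warnings.warn("call-rate filter removed every variant", stacklevel=2)
    return G.take_variants(keep)


def called_mask(calls: np.ndarray) -> np.ndarray:
    """Boolean mask of non-missing calls."""
    return calls != MISSING


def filter_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep variants with folded (minor) allele frequency >= ``min_maf``,
    computed over non-missing calls across all samples."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    present = called_mask(G.calls)
    n_alleles = 2 * present.sum(axis=0)
    alt = np.where(present, G.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alt / n_alleles
    maf = np.minimum(f, 1.0 - f)
    keep = np.where(n_alleles > 0, maf >= min_maf, False)
    return G.take_variants(keep)


def panel_frequencies(G: GenotypeMatrix, population: str) -> AlleleFrequencyPanel:
    """Alt-allele frequency of one population: sum(dosage) / (2 x called)."""
    mask = G.sample_mask(population)
    calls = G.calls[mask]
    present = called_mask(calls)
    n_obs = 2 * present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, alt / n_obs, np.nan)
    return AlleleFrequencyPanel(G.variants, freq, n_obs)


# ---------------------------------------------------------------------------
# Dataset merging
# ---------------------------------------------------------------------------

def intersect_on_variants(G1: GenotypeMatrix, G2: GenotypeMatrix):
    """Restrict both matrices to shared variants, aligning counted alleles.

    Variants are matched on (chrom, pos, unordered allele pair); where the
    second dataset counts the opposite allele its dosages are flipped
    (2 - dosage).  Strand-ambiguous A/T and C/G variants are dropped because
    their orientation cannot be verified across array datasets.
    """
    key1 = {}
    for i, row in enumerate(G1.variants.itertuples(index=False)):
        key1[(row.chrom, row.pos)] = (i, row.a1, row.a2)
    idx1, idx2, flip = [], [], []
    for j, row in enumerate(G2.variants.itertuples(index=False)):
        hit = key1.get((row.chrom, row.pos))
        if hit is None:
            continue
        i, a1, a2 = hit
        if {row.a1, row.a2} != {a1, a2}:
            continue
        if frozenset((a1, a2)) in _PALINDROMIC:
            continue
        idx1.append(i)
        idx2.append(j)
        flip.append(row.a2 != a2)
    if not idx1:
        raise ValueError("no shared variants between the two datasets")
    order = np.argsort(idx1, kind="stable")
    idx1 = np.asarray(idx1)[order]
    idx2 = np.asarray(idx2)[order]
    flip = np.asarray(flip)[order]

    out1 = G1.take_variants(idx1)
    out2 = G2.take_variants(idx2)
    calls2 = out2.calls.copy()
    fl = np.flatnonzero(flip)
    sub = calls2[:, fl]
    calls2[:, fl] = np.where(sub == MISSING, MISSING, 2 - sub)
    variants2 = out1.variants  # adopt G1's allele orientation and ids
    return out1, GenotypeMatrix(variants2, out2.samples, calls2)


# ---------------------------------------------------------------------------
# Package TSV dialect
# ---------------------------------------------------------------------------

def write_tsv(G: GenotypeMatrix, prefix: str) -> None:
    """Write ``<prefix>.geno.tsv`` (sample_id, population, one column per
    variant id; cells 0/1/2/NA) and ``<prefix>.sites.tsv`` (variant table)."""
    sites = G.variants[VARIANT_COLUMNS]
    sites.to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
    geno = pd.DataFrame(
        np.where(G.calls == MISSING, None, G.calls),
        columns=G.variants["id"],
    )
    geno.insert(0, "population", G.samples["population"])
    geno.insert(0, "sample_id", G.samples["sample_id"])
    geno.to_csv(f"{prefix}.geno.tsv", sep="\t", index=False, na_rep="NA")


def read_tsv(prefix: str) -> GenotypeMatrix:
    sites = pd.read_csv(f"{prefix}.sites.tsv", sep="\t", dtype={"chrom": str, "id": str})
    geno = pd.read_csv(f"{prefix}.geno.tsv", sep="\t", dtype={"sample_id": str})
    samples = geno[["sample_id", "population"]]
    body = geno.drop(columns=["sample_id", "population"])
    if list(body.columns) != list(sites["id"].astype(str)):
        raise MalformedInputError("geno.tsv variant columns do not match sites.tsv")
    calls = body.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    return GenotypeMatrix(sites, samples, calls)
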