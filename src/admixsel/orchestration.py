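"""Config-driven pipeline runner.

Two entry points mirror the two halves of the analysis:

* :func:`run_neutral_null_study` — the simulation study: coalescent windows
  under the three-population history, array-style ascertainment, local
  ancestry of the admixed individuals, the pooled track summary, and the
  null distribution of contiguous outlier-region lengths.

* :func:`run_admixture_characterization` — f3 admixture test, F4-ratio
  ancestry proportion, and weighted-LD admixture dating on a genotype
  dataset containing a target, two source proxies and (optionally) an
  outgroup.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import admix_dating, ancestry_scan, fstats
from .genodata import GenotypeMatrix, panel_frequencies
from .local_ancestry import LAIModel, fit_dosage, population_mean_track
from .synthetic_data import (
    DemographyConfig,
    ascertain_variants,
    default_maf_histogram,
    haplotypes_to_genotypes,
    simulate_windows,
)

logger = logging.getLogger("admixsel")

GENERATION_TIME_YEARS: float = 30.0

#: Full-scale window count the genome-wide SNP target refers to (3 Gb).
FULL_SCALE_WINDOWS: int = 1500


def years_to_generations(years: float, generation_time: float = GENERATION_TIME_YEARS) -> int:
    """E.g. 50,000 years at 30 yr/generation -> 1667 generations."""
    return int(round(years / generation_time))


def generations_to_years(generations: float,
                         generation_time: float = GENERATION_TIME_YEARS) -> float:
    """E.g. 77 generations -> 2,310 years."""
    return generations * generation_time


def preset_demography(name: str, n_windows: int | None = None,
                      seed: int = 1) -> DemographyConfig:
    """Named presets of the simulation study.

    ``paper2020`` is the standard genome-average recombination rate;
    ``paper2020-hla`` lowers it to the HLA-region rate (8.5e-9).
    ``*-outgroup`` variants add an outgroup deme (split 4x the source split
    time) and an Asian-side sister deme for the F4-ratio check.
    """
    base = {"seed": seed}
    if n_windows is not None:
        base["n_windows"] = n_windows
    if name == "paper2020":
        return DemographyConfig(**base)
    if name == "paper2020-hla":
        return DemographyConfig(rec=8.5e-9, **base)
    if name == "paper2020-outgroup":
        return DemographyConfig(with_outgroup=True, **base)
    raise KeyError(f"unknown preset: {name}")


@dataclass
class PipelineConfig:
    preset: str = "paper2020"
    n_windows: int = 300
    lai_T: float = 77.0
    lai_em_steps: int = 20
    scan_sd: float = 3.0
    dating_bin_cm: float = 0.1
    dating_max_cm: float = 20.0
    out_dir: str | None = None
    master_seed: int = 1

    def stage_seed(self, index: int) -> int:
        """Deterministic per-stage seed: child ``index`` of the master
        SeedSequence (a fixed counter scheme, so stages can be rerun
        independently)."""
        child = np.random.SeedSequence(self.master_seed).spawn(index + 1)[index]
        return int(child.generate_state(1)[0] % (2**31 - 1))


@dataclass
class NullStudyResult:
    scan: ancestry_scan.ScanSummary
    null: ancestry_scan.NullSummary
    tracks: list           # (positions, mean_track values) per window
    m_hat: float
    n_sites: int
    config: PipelineConfig


def run_neutral_null_study(cfg: PipelineConfig) -> NullStudyResult:
    """Simulate the neutral demography and scan the inferred ancestry track.

    Chain: simulate_windows -> ascertain_variants -> haplotypes_to_genotypes
    -> panel_frequencies (sources) -> fit_dosage (admixed) ->
    population_mean_track -> summarize_track -> region_length_null.
    Deterministic given ``cfg.master_seed``.
    """
    t0 = time.time()
    dem = preset_demography(cfg.preset, n_windows=cfg.n_windows,
                            seed=cfg.stage_seed(0))
    n_target = int(round(dem.n_snps_target * cfg.n_windows / FULL_SCALE_WINDOWS))
    logger.info("simulating %d windows (%s)", cfg.n_windows, cfg.preset)
    windows = list(simulate_windows(dem))
    _stage_done("simulate", t0)

    t0 = time.time()
    windows = ascertain_variants(windows, default_maf_histogram(), n_target,
                                 seed=cfg.stage_seed(1))
    windows = [w for w in windows if w.n_sites > 0]
    _stage_done("ascertain", t0)

    t0 = time.time()
    tracks = []
    all_geno, panels_p, panels_a = [], [], []
    for w in windows:
        G = haplotypes_to_genotypes(w)
        all_geno.append(G)
    # windows are independent chromosomes of one dataset; fit the HMM
    # jointly so EM shares the genome-wide mixture proportion
    merged = _concat_windows(all_geno)
    panel_p = panel_frequencies(merged, "Gidra")
    panel_a = panel_frequencies(merged, "CHB")
    admixed = merged.take_samples(merged.sample_mask("Munda"))
    model = LAIModel(panel_p, panel_a, T=cfg.lai_T, em_steps=cfg.lai_em_steps,
                     genetic_pos=_window_genetic_pos(windows, dem.rec))
    track = fit_dosage(admixed, model)
    mean_track = population_mean_track(track)
    _stage_done("local-ancestry", t0)

    t0 = time.time()
    offsets = np.r_[0, np.cumsum([w.n_sites for w in windows])]
    tracks = [
        (windows[i].positions, mean_track[offsets[i]:offsets[i + 1]])
        for i in range(len(windows))
    ]
    scan = ancestry_scan.summarize_track(mean_track)
    null = ancestry_scan.region_length_null(tracks, sd_multiplier=cfg.scan_sd)
    _stage_done("scan", t0)

    result = NullStudyResult(scan, null, tracks, track.m_hat,
                             int(len(mean_track)), cfg)
    if cfg.out_dir is not None:
        _write_null_artifacts(result)
    return result


def _concat_windows(parts: list[GenotypeMatrix]) -> GenotypeMatrix:
    variants = pd.concat([p.variants for p in parts], ignore_index=True)
    calls = np.hstack([p.calls for p in parts])
    # sample tables are per-window; adopt population labels from the first
    samples = parts[0].samples.copy()
    samples["sample_id"] = [
        f"{pop}_{k}" for pop, k in zip(samples["population"],
                                       samples.groupby("population").cumcount())
    ]
    return GenotypeMatrix(variants, samples, calls)


def _window_genetic_pos(windows, rec: float) -> np.ndarray:
    return np.concatenate([(w.positions - 1) * rec for w in windows])


def _stage_done(name: str, t0: float) -> None:
    logger.info("stage %-16s %.1fs", name, time.time() - t0)


def _write_null_artifacts(result: NullStudyResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for wi, (pos, vals) in enumerate(result.tracks):
        for p, v in zip(pos, vals):
            rows.append((f"w{wi}", p, v))
    pd.DataFrame(rows, columns=["chrom", "pos", "mean_papuan"]).to_csv(
        out / "track.tsv", sep="\t", index=False
    )
    summary = {
        "preset": result.config.preset,
        "n_windows": result.config.n_windows,
        "n_sites": result.n_sites,
        "m_hat": result.m_hat,
        "track_mean": result.scan.mean,
        "track_sd": result.scan.sd,
        "null_mean_length_high_bp": result.null.mean_length("high"),
        "null_max_length_high_bp": result.null.max_length("high"),
        "null_mean_length_low_bp": result.null.mean_length("low"),
        "null_max_length_low_bp": result.null.max_length("low"),
        "null_region_count_high": int(len(result.null.lengths_high)),
        "null_region_count_low": int(len(result.null.lengths_low)),
        "master_seed": result.config.master_seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    regions = []
    for wi, (pos, vals) in enumerate(result.tracks):
        chroms = np.full(len(pos), f"w{wi}", dtype=object)
        for side in ("high", "low"):
            regions += ancestry_scan.call_regions(
                pos, chroms, vals, result.scan, side, result.config.scan_sd
            )
    (out / "regions.bed").write_text(ancestry_scan.regions_to_bed(regions))
    manifest = dataclasses.asdict(result.config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_admixture_characterization(
    G: GenotypeMatrix, target: str, sourceA: str, sourceB: str,
    outgroup: str | None = None, asian_source_proxy: str | None = None,
    block_size_bp: int = fstats.DEFAULT_BLOCK_BP,
    genetic_pos_cm: np.ndarray | None = None,
    date_admixture: bool = True,
) -> dict:
    """f3 + (optional) F4-ratio + (optional) weighted-LD dating report.

    ``sourceA`` plays the Asian-related proxy and ``sourceB`` the
    Papuan-related proxy.  The report mirrors the f3-table columns
    (f3, std. err, Z, SNPs) and adds alpha and the dated generations.
    """
    report: dict = {"target": target, "sources": [sourceA, sourceB]}
    res = fstats.f3(G, target, sourceA, sourceB, block_size_bp)
    report["f3"] = {
        "f3": res.estimate, "std. err": res.std_err, "Z": res.z,
        "SNPs": res.n_snps, "significant": res.significant,
    }
    if outgroup is not None and asian_source_proxy is not None:
        ratio = fstats.f4_ratio(G, outgroup, sourceA, sourceB, target,
                                asian_source_proxy, block_size_bp)
        report["f4_ratio"] = {
            "alpha_asian": ratio.alpha, "std_err": ratio.std_err,
            "alpha_papuan": 1.0 - ratio.alpha,
        }
    elif outgroup is not None or asian_source_proxy is not None:
        logger.warning("F4 ratio skipped: need both outgroup and asian_source_proxy")
    if date_admixture:
        panelA = panel_frequencies(G, sourceA)
        panelB = panel_frequencies(G, sourceB)
        admixed = G.take_samples(G.sample_mask(target))
        curve = admix_dating.weighted_ld_curve(
            admixed, panelA, panelB, genetic_pos_cm=genetic_pos_cm
        )
        try:
            fit = admix_dating.fit_decay(curve)
            report["dating"] = {
                "generations": fit.generations,
                "years": fit.years(),
                "amplitude": fit.amplitude,
            }
        except admix_dating.FitFailureError as exc:
            report["dating"] = {"error": str(exc)}
    return report
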