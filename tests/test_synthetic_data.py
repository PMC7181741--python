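import numpy as np
import pytest

from admixsel.synthetic_data import (
    DemographyConfig,
    SimWindow,
    ascertain_variants,
    default_maf_histogram,
    diverged_panels,
    haplotypes_to_genotypes,
    pooled_folded_maf,
    simulate_tract_admixture,
    simulate_windows,
)


def _single_pop_cfg(**kw):
    """Degenerate history: everything collapses to one population."""
    base = dict(t_div=1.0, t_adm=0.5, m_papuan=0.0, window_bp=100_000,
                chroms={"Gidra": 2, "Munda": 2, "CHB": 6}, n_windows=50, seed=1)
    base.update(kw)
    return DemographyConfig(**base)


class TestSimulateWindows:
    def test_zero_mutation_rate_gives_no_sites(self):
        cfg = _single_pop_cfg(mu=0.0, n_windows=3)
        for w in simulate_windows(cfg):
            assert w.n_sites == 0

    def test_watterson_expected_segregating_sites(self):
        # n = 10 haploids, Ne = 1000, L = 1e5:
        # E[S] = 4 Ne mu L sum_{i<10} 1/i ~ 13.58
        cfg = _single_pop_cfg(n_windows=400, seed=9)
        S = np.array([w.n_sites for w in simulate_windows(cfg)])
        expected = 4 * 1000 * 1.2e-8 * 1e5 * sum(1 / i for i in range(1, 10))
        se = S.std() / np.sqrt(len(S))
        assert abs(S.mean() - expected) < 4 * se + 0.5

    def test_neutral_sfs_skewed_toward_rare(self):
        # folded site-frequency spectrum of a neutral sample is dominated
        # by rare variants: count sites by minor-allele count
        cfg = _single_pop_cfg(n_windows=150, seed=13)
        counts = np.zeros(6)
        for w in simulate_windows(cfg):
            pooled = w.pooled()
            k = np.minimum(pooled.sum(axis=0), pooled.shape[0] - pooled.sum(axis=0))
            for kk in k:
                counts[kk] += 1
        assert counts[1] > counts[2] > counts[4]

    def test_seed_determinism_bit_identical(self):
        cfg = DemographyConfig(n_windows=2, seed=77)
        w1 = list(simulate_windows(cfg))
        w2 = list(simulate_windows(DemographyConfig(n_windows=2, seed=77)))
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.positions, b.positions)
            for pop in a.haplotypes:
                np.testing.assert_array_equal(a.haplotypes[pop], b.haplotypes[pop])

    def test_source_heterozygosities_symmetric(self):
        # symmetric history: the two source populations drift equally
        cfg = DemographyConfig(n_windows=30, seed=3)
        hg, hc = [], []
        for w in simulate_windows(cfg):
            for pop, acc in (("Gidra", hg), ("CHB", hc)):
                h = w.haplotypes[pop]
                f = h.mean(axis=0)
                acc.append((2 * f * (1 - f)).mean())
        assert np.mean(hg) == pytest.approx(np.mean(hc), rel=0.1)


class TestAscertainment:
    @staticmethod
    def _fake_windows(rng, n_windows=5, n_sites=4000, n_hap=40):
        out = []
        for i in range(n_windows):
            f = rng.uniform(0.01, 0.99, size=n_sites)
            haps = (rng.random((n_hap, n_sites)) < f).astype(np.int8)
            seg = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < n_hap)
            haps = haps[:, seg]
            pos = np.sort(rng.choice(2_000_000, size=seg.sum(), replace=False)) + 1
            out.append(SimWindow(i, {"X": haps}, pos, (pos - 1) * 1e-8))
        return out

    def test_mass_in_one_bin_restricts_output(self, rng):
        ws = self._fake_windows(rng)
        hist = np.zeros(50)
        hist[45:] = 1 / 5  # (0.45, 0.50]
        out = ascertain_variants(ws, hist, 500, seed=4)
        for w in out:
            maf = pooled_folded_maf(w)
            assert ((maf > 0.45) & (maf <= 0.5)).all()

    def test_zero_target_empty_and_conservation(self, rng):
        ws = self._fake_windows(rng, n_windows=2)
        out = ascertain_variants(ws, default_maf_histogram(), 0, seed=1)
        assert all(w.n_sites == 0 for w in out)
        out2 = ascertain_variants(ws, default_maf_histogram(), 200, seed=1)
        for w_in, w_out in zip(ws, out2):
            sel = np.searchsorted(w_in.positions, w_out.positions)
            np.testing.assert_array_equal(w_in.haplotypes["X"][:, sel],
                                          w_out.haplotypes["X"])

    def test_output_histogram_close_to_target(self, rng):
        # enough haplotypes that the MAF grid resolves the 0.01-wide bins
        ws = self._fake_windows(rng, n_windows=10, n_sites=30_000, n_hap=200)
        target = default_maf_histogram()
        out = ascertain_variants(ws, target, 10_000, seed=6)
        maf = np.concatenate([pooled_folded_maf(w) for w in out])
        # same (open, closed] binning the ascertainment uses
        b = np.ceil(maf * 100).astype(int) - 1
        got = np.bincount(b, minlength=50).astype(float)
        got = got / got.sum()
        tv = 0.5 * np.abs(got - target).sum()
        assert tv < 0.02

    def test_excess_demand_is_capped_with_warning(self, rng):
        ws = self._fake_windows(rng, n_windows=1, n_sites=500, n_hap=10)
        hist = np.zeros(50)
        hist[0] = 1.0  # demand everything from the rarest bin
        with pytest.warns(UserWarning, match="capped"):
            out = ascertain_variants(ws, hist, 400, seed=2)
        assert sum(w.n_sites for w in out) <= 400


class TestHaplotypesToGenotypes:
    def test_pairing_and_conservation(self, rng):
        cfg = _single_pop_cfg(n_windows=1, seed=21)
        w = next(iter(simulate_windows(cfg)))
        G = haplotypes_to_genotypes(w)
        assert G.n_samples == 5  # (2 + 2 + 6) / 2
        pooled = w.pooled()
        np.testing.assert_array_equal(G.calls.sum(axis=0), pooled.sum(axis=0))

    def test_default_preset_individual_counts(self):
        cfg = DemographyConfig(n_windows=1, seed=22)
        G = haplotypes_to_genotypes(next(iter(simulate_windows(cfg))))
        counts = G.samples["population"].value_counts()
        assert counts["Gidra"] == 24 and counts["Munda"] == 20 and counts["CHB"] == 45

    def test_odd_haplotype_count_errors(self, rng):
        w = SimWindow(0, {"X": np.zeros((3, 4), dtype=np.int8)},
                      np.arange(1, 5), np.arange(4) * 1e-8)
        with pytest.raises(ValueError, match="odd"):
            haplotypes_to_genotypes(w)


class TestTractAdmixture:
    def test_m_equal_one_is_all_papuan(self):
        pP, pA = diverged_panels(500, 0.3, 31)
        gpos = (pP.variants["pos"].to_numpy() - 1) * 1e-8
        G, truth = simulate_tract_admixture(pP, pA, gpos, T=77, m=1.0, n_ind=5, seed=2)
        assert (truth.dosage == 2).all()
        for tr in truth.tracts:
            assert all(a == "P" for _, _, a in tr)

    def test_mean_papuan_tract_length(self):
        pP, pA = diverged_panels(20_000, 0.3, 32, spacing_bp=20_000)
        gpos = (pP.variants["pos"].to_numpy() - 1) * 1e-8
        _, truth = simulate_tract_admixture(pP, pA, gpos, T=77, m=0.5137,
                                            n_ind=40, seed=3)
        lens = [
            (e - s) * 1e-8
            for tr in truth.tracts
            for (s, e, a) in tr
            if a == "P"
        ]
        expected = 1.0 / (77 * (1 - 0.5137))  # Morgans
        # edge tracts are censored at chromosome ends; allow a loose band
        assert np.mean(lens) == pytest.approx(expected, rel=0.15)

    def test_genomewide_dosage_mean_near_m(self):
        pP, pA = diverged_panels(5000, 0.3, 33)
        gpos = (pP.variants["pos"].to_numpy() - 1) * 1e-8
        _, truth = simulate_tract_admixture(pP, pA, gpos, T=77, m=0.3,
                                            n_ind=50, seed=4)
        assert truth.dosage.mean() / 2 == pytest.approx(0.3, abs=0.03)

    def test_tracts_tile_without_gaps(self):
        pP, pA = diverged_panels(1000, 0.3, 34)
        gpos = (pP.variants["pos"].to_numpy() - 1) * 1e-8
        _, truth = simulate_tract_admixture(pP, pA, gpos, T=30, m=0.5, n_ind=3, seed=5)
        for tr in truth.tracts:
            for (s0, e0, _), (s1, _, _) in zip(tr, tr[1:]):
                assert e0 == s1

    def test_seed_determinism(self):
        pP, pA = diverged_panels(300, 0.3, 35)
        gpos = (pP.variants["pos"].to_numpy() - 1) * 1e-8
        g1, t1 = simulate_tract_admixture(pP, pA, gpos, 77, 0.5, 4, seed=9)
        g2, t2 = simulate_tract_admixture(pP, pA, gpos, 77, 0.5, 4, seed=9)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        np.testing.assert_array_equal(t1.dosage, t2.dosage)


def test_config_invariants_enforced():
    with pytest.raises(ValueError, match="t_adm"):
        DemographyConfig(t_div=10, t_adm=20)
    with pytest.raises(ValueError, match="m_papuan"):
        DemographyConfig(m_papuan=1.5)
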