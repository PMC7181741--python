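import io

import numpy as np
import pandas as pd
import pytest

from admixsel.genodata import (
    MISSING,
    GenotypeMatrix,
    MalformedInputError,
    TriallelicVariantError,
    filter_maf,
    filter_variant_callrate,
    intersect_on_variants,
    panel_frequencies,
    read_plink_text,
    read_tsv,
    write_tsv,
)
from conftest import random_genotypes

TOY_MAP = """\
1 rs1 0 1000
1 rs2 0 2000
1 rs3 0 3000
"""

TOY_PED = """\
FAM1 ind1 0 0 1 0 A A A G G G
FAM1 ind2 0 0 2 0 A A 0 0 G G
"""


class TestReadPlinkText:
    def test_minor_allele_dosage_encoding(self):
        G = read_plink_text(io.StringIO(TOY_PED), io.StringIO(TOY_MAP))
        # rs1 is monomorphic A; rs3 monomorphic G; rs2 has one A/G het
        assert list(G.variants["id"]) == ["rs1", "rs2", "rs3"]
        # at rs2 the minor allele is G (counts A=1, G=1 -> lexicographic tie
        # break picks A as alt? minor with tie -> 'A')
        assert G.calls[0, 0] in (0, 2)  # monomorphic column is constant
        assert G.calls[1, 1] == MISSING

    def test_explicit_allele_key_orients_dosage(self):
        G = read_plink_text(io.StringIO(TOY_PED), io.StringIO(TOY_MAP),
                            allele_key={"rs2": "G"})
        assert G.calls[0, 1] == 1  # A G -> one copy of G

    def test_dosage_of_known_genotypes(self):
        ped = "F a 0 0 0 0 A A A G G G\n"
        mp = TOY_MAP
        G = read_plink_text(io.StringIO(ped), io.StringIO(mp),
                            allele_key={"rs1": "G", "rs2": "G", "rs3": "G"})
        assert list(G.calls[0]) == [0, 1, 2]

    def test_population_from_family_id(self):
        G = read_plink_text(io.StringIO(TOY_PED), io.StringIO(TOY_MAP))
        assert G.populations() == ["FAM1"]

    def test_malformed_ped_row_reports_row(self):
        bad = "FAM1 ind1 0 0 1 0 A A A G G G A\n"
        with pytest.raises(MalformedInputError, match="PED row 1"):
            read_plink_text(io.StringIO(bad), io.StringIO(TOY_MAP))

    def test_triallelic_variant_rejected(self):
        ped = "F a 0 0 0 0 A G 0 0 0 0\nF b 0 0 0 0 C A 0 0 0 0\n"
        with pytest.raises(TriallelicVariantError, match="rs1"):
            read_plink_text(io.StringIO(ped), io.StringIO(TOY_MAP))


class TestFilters:
    def test_callrate_19_of_20_retained_at_095(self, rng):
        # one variant, three populations of 20 samples, 19 calls each
        calls = np.zeros((60, 1), dtype=np.int8)
        for start in (0, 20, 40):
            calls[start] = MISSING
        G = GenotypeMatrix.from_arrays(
            calls, "chr1", [100], [f"s{i}" for i in range(60)],
            ["P1"] * 20 + ["P2"] * 20 + ["P3"] * 20,
        )
        out = filter_variant_callrate(G, 0.95, per_population=True)
        assert out.n_variants == 1

    def test_fully_missing_in_one_population_removed(self, rng):
        calls = np.zeros((8, 1), dtype=np.int8)
        calls[4:] = MISSING
        G = GenotypeMatrix.from_arrays(
            calls, "chr1", [100], [f"s{i}" for i in range(8)],
            ["P1"] * 4 + ["P2"] * 4,
        )
        assert filter_variant_callrate(G, 0.95).n_variants == 0
        assert filter_variant_callrate(G, 0.5, per_population=False).n_variants == 1

    def test_callrate_matches_bruteforce_recount(self, rng):
        G = random_genotypes(rng, n_samples=30, n_variants=200, missing_rate=0.08)
        out = filter_variant_callrate(G, 0.92, per_population=True)
        expected = []
        for j in range(G.n_variants):
            ok = True
            for pop in G.populations():
                mask = G.sample_mask(pop)
                col = G.calls[mask, j]
                if (col != MISSING).mean() < 0.92:
                    ok = False
            if ok:
                expected.append(G.variants["id"].iloc[j])
        assert list(out.variants["id"]) == expected

    def test_maf_bruteforce_recount_and_monomorphic(self, rng):
        G = random_genotypes(rng, n_samples=40, n_variants=300, missing_rate=0.05)
        # force a monomorphic and a rare variant
        G.calls[:, 0] = 0
        G.calls[:, 1] = 0
        G.calls[0, 1] = 1
        out = filter_maf(G, 0.05)
        kept = set(out.variants["id"])
        assert G.variants["id"].iloc[0] not in kept
        assert G.variants["id"].iloc[1] not in kept
        for j in range(G.n_variants):
            col = G.calls[:, j]
            obs = col[col != MISSING]
            f = obs.sum() / (2 * len(obs)) if len(obs) else 0.0
            expect_keep = len(obs) > 0 and min(f, 1 - f) >= 0.05
            assert (G.variants["id"].iloc[j] in kept) == expect_keep

    def test_filters_idempotent(self, rng):
        G = random_genotypes(rng, n_samples=30, n_variants=150, missing_rate=0.1)
        once = filter_maf(filter_variant_callrate(G, 0.9), 0.05)
        twice = filter_maf(filter_variant_callrate(once, 0.9), 0.05)
        assert list(once.variants["id"]) == list(twice.variants["id"])
        np.testing.assert_array_equal(once.calls, twice.calls)


class TestPanelFrequencies:
    def test_simple_frequency_and_nobs(self):
        calls = np.array([[0], [1], [2]], dtype=np.int8)
        G = GenotypeMatrix.from_arrays(calls, "chr1", [10], list("abc"), ["P"] * 3)
        panel = panel_frequencies(G, "P")
        assert panel.freq[0] == pytest.approx(0.5)
        assert panel.n_obs[0] == 6

    def test_all_missing_gives_undefined(self):
        calls = np.full((3, 1), MISSING, dtype=np.int8)
        G = GenotypeMatrix.from_arrays(calls, "chr1", [10], list("abc"), ["P"] * 3)
        panel = panel_frequencies(G, "P")
        assert panel.n_obs[0] == 0
        assert np.isnan(panel.freq[0])

    def test_unknown_population_errors(self, toy_genotypes):
        with pytest.raises(KeyError):
            panel_frequencies(toy_genotypes, "NOPE")

    def test_matches_naive_loop(self, rng):
        G = random_genotypes(rng, n_samples=20, n_variants=80, missing_rate=0.15)
        panel = panel_frequencies(G, "POP1")
        mask = G.sample_mask("POP1")
        for j in range(G.n_variants):
            col = G.calls[mask, j]
            obs = col[col != MISSING]
            if len(obs) == 0:
                assert np.isnan(panel.freq[j])
            else:
                assert panel.freq[j] == pytest.approx(obs.sum() / (2 * len(obs)))

    def test_pooled_population_is_weighted_not_averaged(self, rng):
        G = random_genotypes(rng, n_samples=9, n_variants=40, missing_rate=0.2,
                             populations=("A", "A", "B"))
        both = G.samples.copy()
        both["population"] = "ALL"
        pooled = GenotypeMatrix(G.variants, both, G.calls)
        pa = panel_frequencies(G, "A")
        pb = panel_frequencies(G, "B")
        pall = panel_frequencies(pooled, "ALL")
        num = np.nan_to_num(pa.freq) * pa.n_obs + np.nan_to_num(pb.freq) * pb.n_obs
        den = pa.n_obs + pb.n_obs
        np.testing.assert_allclose(pall.freq[den > 0], (num / den)[den > 0])

    def test_smoothed_strictly_inside_unit_interval(self, rng):
        G = random_genotypes(rng, n_samples=6, n_variants=50, missing_rate=0.3)
        panel = panel_frequencies(G, "POP1")
        s = panel.smoothed()
        assert ((s > 0) & (s < 1)).all()


class TestIntersect:
    @staticmethod
    def _make(chrom, pos, a1, a2, calls):
        return GenotypeMatrix.from_arrays(
            np.asarray(calls, dtype=np.int8), chrom, pos,
            [f"x{i}" for i in range(np.asarray(calls).shape[0])],
            ["P"] * np.asarray(calls).shape[0], a1=a1, a2=a2,
        )

    def test_allele_flip_recodes_dosage(self):
        g1 = self._make("chr1", [100], ["A"], ["G"], [[0]])
        g2 = self._make("chr1", [100], ["G"], ["A"], [[2]])
        o1, o2 = intersect_on_variants(g1, g2)
        assert o2.calls[0, 0] == 0
        assert o2.variants["a2"].iloc[0] == "G"

    def test_palindromic_dropped_and_no_shared_errors(self):
        g1 = self._make("chr1", [100, 200], ["A", "A"], ["T", "G"], [[1, 1]])
        g2 = self._make("chr1", [100, 200], ["A", "A"], ["T", "G"], [[1, 1]])
        o1, o2 = intersect_on_variants(g1, g2)
        assert list(o1.variants["pos"]) == [200]
        g3 = self._make("chr2", [999], ["A"], ["G"], [[1]])
        with pytest.raises(ValueError, match="no shared"):
            intersect_on_variants(g1, g3)

    def test_shared_set_matches_bruteforce(self, rng):
        pos1 = sorted(rng.choice(1000, size=300, replace=False) + 1)
        pos2 = sorted(rng.choice(1000, size=300, replace=False) + 1)
        g1 = self._make("chr1", pos1, ["C"] * 300, ["T"] * 300,
                        rng.integers(0, 3, (4, 300)))
        g2 = self._make("chr1", pos2, ["C"] * 300, ["T"] * 300,
                        rng.integers(0, 3, (4, 300)))
        shared = sorted(set(pos1) & set(pos2))
        assert shared  # dense draw guarantees overlap
        o1, o2 = intersect_on_variants(g1, g2)
        assert list(o1.variants["pos"]) == shared
        assert list(o2.variants["pos"]) == shared


def test_tsv_round_trip_exact(tmp_path, rng):
    G = random_genotypes(rng, n_samples=10, n_variants=30, missing_rate=0.2)
    prefix = str(tmp_path / "toy")
    write_tsv(G, prefix)
    back = read_tsv(prefix)
    np.testing.assert_array_equal(G.calls, back.calls)
    assert list(G.variants["pos"]) == list(back.variants["pos"])
    assert list(G.variants["chrom"]) == list(back.variants["chrom"])
    assert list(G.samples["population"]) == list(back.samples["population"])
    assert list(G.samples["sample_id"]) == list(back.samples["sample_id"])
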