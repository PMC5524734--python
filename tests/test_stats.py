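"""Per-locus statistics: frequencies, He, PIC, NE-PP, theta."""

import itertools

import numpy as np
import pytest

import pedtrace as pt
from pedtrace.matrix import MISSING


def _nepp_oracle(p):
    """Independent enumeration: gamete sets instead of transmission probs."""
    q = 1 - p
    w = {0: p * p, 1: 2 * p * q, 2: q * q}

    def compatible(go, gm, gf):
        # offspring inherits one allele (0 or 1 copies of B) from each parent
        gametes = {0: {0}, 1: {0, 1}, 2: {1}}
        return any(a + b == go for a in gametes[gm] for b in gametes[gf])

    return sum(
        w[gm] * w[gf] * w[go]
        for gm, gf, go in itertools.product(range(3), repeat=3)
        if compatible(go, gm, gf)
    )


class TestAlleleFreqs:
    def test_counting_rules(self):
        m = pt.GenotypeMatrix(
            ["a", "b", "c"], ["L1", "L2", "L3"],
            np.array([[0, 0, 0], [1, 0, 1], [2, 0, MISSING]], np.int8),
        )
        p = pt.allele_freqs(m)
        assert p[0] == pytest.approx(0.5)        # AA, AB, BB
        assert p[1] == pytest.approx(1.0)        # all AA
        assert p[2] == pytest.approx(3 / 4)      # AA, AB over 4 called alleles

    def test_all_missing_locus_raises(self):
        m = pt.GenotypeMatrix(["a"], ["L1"], np.array([[MISSING]], np.int8))
        with pytest.raises(ValueError, match="all genotypes missing"):
            pt.allele_freqs(m)


class TestScalarStatistics:
    @pytest.mark.parametrize("p,he", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0)])
    def test_expected_heterozygosity(self, p, he):
        assert pt.expected_heterozygosity(p) == pytest.approx(he)

    @pytest.mark.parametrize("p,value", [(0.5, 0.375), (0.0, 0.0)])
    def test_pic_values(self, p, value):
        assert pt.pic(p) == pytest.approx(value, abs=1e-12)

    def test_pic_at_low_he_locus(self):
        # He = 0.081 inverts to p ~ 0.0423; PIC prints as 0.078
        p = pt.maf_from_he(0.081)
        assert round(float(pt.pic(p)), 3) == 0.078

    @pytest.mark.parametrize("he", [0.5, 0.081, 0.007, 0.0])
    def test_maf_from_he_round_trips(self, he):
        p = pt.maf_from_he(he)
        assert 0 <= p <= 0.5
        assert pt.expected_heterozygosity(p) == pytest.approx(he, abs=1e-12)

    def test_pic_bounded_by_he_and_symmetric(self):
        grid = np.linspace(0.0, 1.0, 101)
        assert np.all(pt.pic(grid) <= pt.expected_heterozygosity(grid) + 1e-15)
        assert np.allclose(pt.pic(grid), pt.pic(1 - grid))
        assert np.allclose(pt.expected_heterozygosity(grid),
                           pt.expected_heterozygosity(1 - grid))


class TestNonExclusion:
    def test_balanced_locus_value(self):
        assert pt.nepp_locus(0.5) == pytest.approx(0.71875, abs=1e-15)
        assert round(pt.nepp_locus(0.5), 3) == 0.719

    def test_quarter_frequency_against_independent_oracle(self):
        # frozen from the gamete-set enumeration oracle
        assert _nepp_oracle(0.25) == pytest.approx(0.761230468750, abs=1e-12)
        assert pt.nepp_locus(0.25) == pytest.approx(0.761230468750, abs=1e-12)

    def test_limit_toward_monomorphism(self):
        assert pt.nepp_locus(1e-6) == pytest.approx(1.0, abs=1e-4)
        with pytest.warns(UserWarning, match="monomorphic"):
            assert pt.nepp_locus(0.0) == 1.0

    def test_enumeration_matches_closed_form_on_grid(self):
        for p in np.arange(0.01, 1.0, 0.01):
            assert abs(pt.nepp_locus(p) - pt.nepp_closed_form(p)) < 1e-12

    def test_combined_product(self):
        one = pt.combined_nepp([0.71875])
        assert one == pytest.approx(0.71875)
        assert pt.combined_nepp([0.71875, 0.71875]) == pytest.approx(0.516602, abs=1e-6)

    def test_combined_non_increasing_as_loci_append(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.7, 1.0, size=20)
        partials = [pt.combined_nepp(vals[: k + 1]) for k in range(20)]
        assert np.all(np.diff(partials) <= 0)


class TestPublishedPanelFixture:
    def test_internal_consistency_of_fixture(self):
        # printed He determines p; PIC and NE-PP recomputed from p must
        # match the printed columns within 3-d.p. rounding slack
        tab = pt.load_table1_fixture()
        assert len(tab) == 36
        p = pt.maf_from_he(tab["he"].to_numpy())
        assert np.all(np.abs(pt.pic(p) - tab["pic"]) <= 0.002)
        nepp = np.array([pt.nepp_locus(x) for x in p])
        dev = np.abs(nepp - tab["nepp"])
        # A-005 prints NE-PP 0.718, below the biallelic minimum 0.71875
        # (attained at p = 0.5): no allele frequency reproduces it, so the
        # printed value must carry a rounding/typesetting slip; it still
        # agrees to ~2e-3.  Every other row reproduces within 0.002.
        a005 = tab["locus"] == "A-005"
        assert float(tab.loc[a005, "nepp"].iloc[0]) < 0.71875
        assert np.all(dev[~a005.to_numpy()] <= 0.002)
        assert np.all(dev <= 0.003)

    def test_combined_panel_non_exclusion(self):
        tab = pt.load_table1_fixture()
        total = pt.combined_nepp(tab["nepp"])
        assert f"{total:.1e}" == "3.1e-05"


class TestLocusSummary:
    def test_heterozygous_pair(self):
        m = pt.GenotypeMatrix(["a", "b"], ["L1"], np.array([[1], [1]], np.int8))
        row = pt.locus_summary(m).iloc[0]
        assert row["ho"] == 1.0 and row["he"] == pytest.approx(0.5)

    def test_monomorphic_conventions(self):
        m = pt.GenotypeMatrix(["a", "b"], ["L1"], np.array([[0], [0]], np.int8))
        row = pt.locus_summary(m).iloc[0]
        assert row["pic"] == 0.0 and row["nepp"] == 1.0 and row["maf"] == 0.0

    def test_ho_tracks_he_under_hwe(self):
        freqs = np.linspace(0.15, 0.5, 10)
        m = pt.generate_parents(freqs, 5000, seed=1)
        s = pt.locus_summary(m)
        se = np.sqrt(s["he"] * (1 - s["he"]) / 5000)
        assert np.all(np.abs(s["ho"] - s["he"]) < 4 * se)


class TestFst:
    @staticmethod
    def _wc_oracle(groups):
        """Independently coded single-locus Weir–Cockerham variance components."""
        ni = np.array([len(grp) for grp in groups], float)
        pi = np.array([np.mean([2 - x for x in grp]) / 2 for grp in groups])
        hi = np.array([np.mean([x == 1 for x in grp]) for grp in groups])
        r = len(groups)
        nbar = ni.mean()
        nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
        pbar = (ni * pi).sum() / (r * nbar)
        s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ni * hi).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        return a / (a + b + c)

    def test_opposite_fixed_families_fully_differentiated(self):
        m = pt.GenotypeMatrix(
            [f"i{k}" for k in range(8)], ["L1"],
            np.array([[0]] * 4 + [[2]] * 4, np.int8),
        )
        labels = ["f1"] * 4 + ["f2"] * 4
        assert pt.fst_per_locus(m, labels)["theta"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_locus_flagged_zero(self):
        m = pt.GenotypeMatrix(
            [f"i{k}" for k in range(4)], ["L1"], np.zeros((4, 1), np.int8)
        )
        df = pt.fst_per_locus(m, ["a", "a", "b", "b"])
        assert df["theta"].iloc[0] == 0.0 and bool(df["monomorphic"].iloc[0])

    def test_toy_dataset_matches_variance_component_oracle(self):
        groups = [[0, 1, 1, 2], [1, 2, 2, 2]]
        m = pt.GenotypeMatrix(
            [f"i{k}" for k in range(8)], ["L1"],
            np.array([[g] for grp in groups for g in grp], np.int8),
        )
        labels = ["f1"] * 4 + ["f2"] * 4
        theta = pt.fst_per_locus(m, labels)["theta"].iloc[0]
        assert theta == pytest.approx(self._wc_oracle(groups), abs=1e-12)

    def test_requires_two_families_of_two(self):
        m = pt.GenotypeMatrix(["a", "b"], ["L1"], np.array([[0], [2]], np.int8))
        with pytest.raises(ValueError, match="fewer than two"):
            pt.fst_per_locus(m, ["f1", "f2"])
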