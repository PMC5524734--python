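"""Exclusion and likelihood parentage assignment."""

import numpy as np
import pandas as pd
import pytest

import pedtrace as pt
from pedtrace.matrix import MISSING


class TestLocusMismatch:
    @pytest.mark.parametrize(
        "g_o,g_m,g_f,expected",
        [
            (1, 0, 0, 1),  # AB from AA x AA: one allele must change
            (2, 0, 0, 2),  # BB from AA x AA
            (0, 0, 1, 0),  # AA possible from AA x AB
            (0, 2, 2, 2),
            (1, 0, 2, 0),
            (0, 0, 2, 1),  # AA vs obligate AB
            (MISSING, 0, 0, 0),  # missing offspring locus is uninformative
        ],
    )
    def test_examples(self, g_o, g_m, g_f, expected):
        assert pt.locus_mismatch(g_o, g_m, g_f) == expected

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            pt.locus_mismatch(0, MISSING, 0)


def _one_locus_setup(parent_rows, offspring_rows):
    parents = pt.GenotypeMatrix(
        [f"p{k}" for k in range(len(parent_rows))], ["L1"],
        np.array([[g] for g in parent_rows], np.int8),
    )
    offspring = pt.GenotypeMatrix(
        [f"o{k}" for k in range(len(offspring_rows))], ["L1"],
        np.array([[g] for g in offspring_rows], np.int8),
    )
    return parents, offspring


class TestExclusionAssign:
    def test_error_free_data_fully_recovered(self, small_population, small_progeny):
        parents, design, _ = small_population
        progeny, truth = small_progeny
        res = pt.exclusion_assign(progeny, parents, design, tolerance_alleles=0)
        overall, _ = pt.evaluate_assignment(res, truth)
        assert overall["wrong_pct"] == 0.0
        assert overall["unassigned_pct"] == 0.0

    def test_single_mismatch_within_tolerance(self):
        parents, offspring = _one_locus_setup([0, 0], [1])  # AB child, AA x AA
        design = pt.MatingDesign([pt.Cross("C1", "p0", "p1")])
        res = pt.exclusion_assign(offspring, parents, design, tolerance_alleles=1)
        row = res.iloc[0]
        assert row["status"] == "assigned"
        assert row["assigned_cross"] == "C1"
        assert row["mismatch_alleles"] == 1
        # at tolerance 0 the same child is unassigned
        res0 = pt.exclusion_assign(offspring, parents, design, tolerance_alleles=0)
        assert res0.iloc[0]["status"] == "unassigned"

    def test_duplicated_candidate_crosses_are_ambiguous(self):
        parents, offspring = _one_locus_setup([0, 2, 0, 2], [1])
        design = pt.MatingDesign(
            [pt.Cross("C1", "p0", "p1"), pt.Cross("C2", "p2", "p3")]
        )
        res = pt.exclusion_assign(offspring, parents, design)
        assert res.iloc[0]["status"] == "ambiguous"
        assert res.iloc[0]["assigned_cross"] is None

    def test_perturbation_distance_bounds_mismatch_total(self, small_population,
                                                         small_progeny):
        # if injected noise adds allele distance d, the true-cross total <= d
        parents, design, _ = small_population
        progeny, truth = small_progeny
        perturbed, cells = pt.inject_errors(progeny, 0.05, seed=13, return_cells=True)
        dist = np.abs(
            perturbed.genotypes.astype(int) - progeny.genotypes.astype(int)
        ).sum(axis=1)
        from pedtrace.assignment import mismatch_totals

        totals = mismatch_totals(perturbed, parents, design)
        cross_pos = {c: k for k, c in enumerate(design.cross_ids)}
        true_idx = [cross_pos[c] for c in truth["cross_id"]]
        true_totals = totals[np.arange(len(truth)), true_idx]
        assert np.all(true_totals <= dist)


class TestLikelihood:
    def test_certain_cross_has_zero_loglik(self):
        ll = pt.likelihood_of_cross(
            np.array([1, 1, 1]), np.array([0, 0, 0]), np.array([2, 2, 2]),
            freqs=np.full(3, 0.5), epsilon=0.0,
        )
        assert ll == 0.0

    def test_het_cross_quarter_probability(self):
        ll = pt.likelihood_of_cross(
            np.array([0]), np.array([1]), np.array([1]),
            freqs=np.array([0.5]), epsilon=0.0,
        )
        assert ll == pytest.approx(np.log(0.25))

    def test_incompatible_locus_is_minus_inf_at_zero_epsilon(self):
        ll = pt.likelihood_of_cross(
            np.array([2]), np.array([0]), np.array([0]),
            freqs=np.array([0.5]), epsilon=0.0,
        )
        assert np.isneginf(ll)

    def test_obligate_cross_beats_segregating_cross(self):
        # all-heterozygote child: AA x BB (prob 1/locus) vs AB x AB (1/2)
        parents = pt.GenotypeMatrix(
            ["m1", "f1", "m2", "f2"], ["L1", "L2", "L3"],
            np.array([[0] * 3, [2] * 3, [1] * 3, [1] * 3], np.int8),
        )
        offspring = pt.GenotypeMatrix(["o1"], ["L1", "L2", "L3"],
                                      np.ones((1, 3), np.int8))
        design = pt.MatingDesign(
            [pt.Cross("CX", "m1", "f1"), pt.Cross("CY", "m2", "f2")]
        )
        res = pt.likelihood_assign(offspring, parents, design,
                                   freqs=np.full(3, 0.5), epsilon=0.0)
        assert res.iloc[0]["assigned_cross"] == "CX"
        assert res.iloc[0]["loglik_best"] == pytest.approx(0.0)
        assert res.iloc[0]["loglik_second"] == pytest.approx(3 * np.log(0.5))

    def test_identical_crosses_tie_ambiguous(self):
        parents, offspring = _one_locus_setup([0, 2, 0, 2], [1])
        design = pt.MatingDesign(
            [pt.Cross("C1", "p0", "p1"), pt.Cross("C2", "p2", "p3")]
        )
        res = pt.likelihood_assign(offspring, parents, design,
                                   freqs=np.array([0.5]))
        assert res.iloc[0]["status"] == "ambiguous"

    def test_error_free_two_cross_recovery(self):
        # two disjoint crosses, clean offspring: truth recovered everywhere
        parents = pt.generate_parents(np.full(36, 0.4), 4, seed=21)
        design = pt.MatingDesign(
            [pt.Cross("C1", "P001", "P002"), pt.Cross("C2", "P003", "P004")]
        )
        progeny, truth = pt.simulate_progeny_dataset(parents, design, 50, seed=22)
        res = pt.likelihood_assign(progeny, parents, design, epsilon=0.01)
        overall, _ = pt.evaluate_assignment(res, truth)
        assert overall["correct_pct"] == 100.0

    def test_methods_agree_on_clean_data(self, small_population, small_progeny):
        parents, design, _ = small_population
        progeny, truth = small_progeny
        excl = pt.exclusion_assign(progeny, parents, design, 0)
        lik = pt.likelihood_assign(progeny, parents, design)
        merged = excl.merge(lik, on="individual_id", suffixes=("_e", "_l"))
        both = (merged["status_e"] == "assigned") & (merged["status_l"] == "assigned")
        assert (merged.loc[both, "assigned_cross_e"]
                == merged.loc[both, "assigned_cross_l"]).all()


class TestParentErrorClassification:
    def test_wrong_father_wrong_mother_and_both(self):
        g_mother = np.zeros(10, np.int8)        # AA everywhere
        g_father = np.full(10, 2, np.int8)      # BB everywhere
        child_of_mother = np.zeros(10, np.int8)  # shares A with mother, conflicts BB dad
        assert pt.classify_parentage_error(child_of_mother, g_mother, g_father) == \
            "wrong_father"
        assert pt.classify_parentage_error(child_of_mother, g_father, g_mother) == \
            "wrong_mother"
        half_conflict = np.array([0] * 5 + [2] * 5, np.int8)
        assert pt.classify_parentage_error(half_conflict, g_mother, g_father) == \
            "wrong_both"

    def test_compatible_with_both_is_undetermined(self):
        g = np.ones(10, np.int8)
        assert pt.classify_parentage_error(g, g, g) == "undetermined"

    def test_classify_against_putative_flags_planted_error(self, small_population):
        parents, design, _ = small_population
        progeny, truth = pt.simulate_progeny_dataset(parents, design, 3, seed=31)
        # reassign one individual's putative cross to one with a different father
        victim = truth.iloc[0]["individual_id"]
        true_cross = design[truth.iloc[0]["cross_id"]]
        other = next(
            c.cross_id for c in design
            if c.mother_id == true_cross.mother_id and c.father_id != true_cross.father_id
        ) if any(c.mother_id == true_cross.mother_id and c.cross_id != true_cross.cross_id
                 for c in design) else None
        put = truth.rename(columns={})
        if other is not None:
            put = put.copy()
            put.loc[put["individual_id"] == victim, "cross_id"] = other
        cls = pt.classify_against_putative(progeny, parents, design, put)
        lut = dict(zip(cls["individual_id"], cls["parent_error_class"]))
        if other is not None:
            assert lut[victim] in {"wrong_father", "undetermined"}
        # all untouched individuals are fully compatible with their true cross
        untouched = [i for i in lut if i != victim]
        assert all(lut[i] == "correct_pair" for i in untouched)


class TestEvaluate:
    def test_percentages_partition(self, small_population, small_progeny):
        parents, design, _ = small_population
        progeny, truth = small_progeny
        res = pt.exclusion_assign(progeny, parents, design)
        overall, per_cross = pt.evaluate_assignment(res, truth)
        total = (overall["wrong_pct"] + overall["correct_pct"]
                 + overall["ambiguous_pct"] + overall["unassigned_pct"])
        assert total == pytest.approx(100.0)
        assert set(per_cross["cross_id"]) <= set(design.cross_ids)

    def test_single_error_counts_one_percent(self):
        truth = pd.DataFrame(
            {"individual_id": [f"o{k}" for k in range(100)],
             "cross_id": ["C1"] * 100}
        )
        res = pd.DataFrame(
            {
                "individual_id": truth["individual_id"],
                "status": ["assigned"] * 100,
                "assigned_cross": ["C1"] * 99 + ["C2"],
            }
        )
        overall, _ = pt.evaluate_assignment(res, truth)
        assert overall["wrong_pct"] == pytest.approx(1.0)
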