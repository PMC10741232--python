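"""MDR: cell tables, risk labels, CV, search, metrics, entropy."""

import math
import warnings

import numpy as np
import pytest

import candigene as cg
from tests.conftest import null_panel


def small_panel(case_geno, ctrl_geno):
    case_geno = np.atleast_2d(np.asarray(case_geno, dtype=np.int8))
    ctrl_geno = np.atleast_2d(np.asarray(ctrl_geno, dtype=np.int8))
    m = case_geno.shape[1]
    snps = [cg.SnpMeta(f"s{j}", "1", j + 1, "A", "a") for j in range(m)]
    geno = np.vstack([case_geno, ctrl_geno])
    phen = np.r_[np.ones(len(case_geno)), np.zeros(len(ctrl_geno))].astype(np.int8)
    return cg.GenotypePanel(
        snps=snps, samples=[f"i{i}" for i in range(len(geno))],
        genotypes=geno, phenotype=phen,
    )


class TestCellsAndLabels:
    def test_hand_counted_single_snp_table(self):
        panel = small_panel([[0], [0], [1]], [[0], [1], [1]])
        table = cg.cell_counts(panel, ("s0",))
        assert table.cells == {(0,): (2, 1), (1,): (1, 2)}
        assert table.threshold == pytest.approx(1.0)

    def test_missing_individual_leaves_other_cells_untouched(self):
        panel = small_panel([[0], [0], [cg.MISSING]], [[0], [1], [1]])
        table = cg.cell_counts(panel, ("s0",))
        assert table.cells[(0,)] == (2, 1)
        assert table.n_cases == 2

    def test_two_locus_table_has_at_most_nine_cells(self):
        rng = np.random.default_rng(0)
        panel = small_panel(
            rng.integers(0, 3, (50, 2)), rng.integers(0, 3, (40, 2))
        )
        table = cg.cell_counts(panel, ("s0", "s1"))
        assert len(table.cells) <= 9

    def test_threshold_rule_and_tie_goes_high(self):
        panel = small_panel([[0]] * 10 + [[1]] * 2, [[0]] * 5 + [[1]] * 2)
        model = cg.classify_cells(cg.cell_counts(panel, ("s0",)))
        # cell 0: 10 cases/5 controls, ratio 2.0 >= 12/7 -> high
        assert model.label[(0,)] == "high"
        # cell 1: 2/2 = 1.0 < 12/7 -> low
        assert model.label[(1,)] == "low"
        # unseen cell follows the default empty-cell policy
        assert model.predict((2,)) == "low"

    def test_zero_control_cell_with_cases_is_high(self):
        panel = small_panel([[0], [1]], [[1], [1]])
        model = cg.classify_cells(cg.cell_counts(panel, ("s0",)))
        assert model.label[(0,)] == "high"


class TestBalancedAccuracy:
    def test_perfect_separation_scores_one(self):
        panel = small_panel([[2]] * 8, [[0]] * 8)
        model = cg.classify_cells(cg.cell_counts(panel, ("s0",)))
        assert cg.balanced_accuracy(model, panel) == pytest.approx(1.0)

    def test_all_high_model_scores_half(self):
        panel = small_panel([[0], [1]], [[0], [1]])
        model = cg.RiskModel(("s0",), {(0,): "high", (1,): "high"}, 1.0)
        assert cg.balanced_accuracy(model, panel) == pytest.approx(0.5)

    def test_hand_worked_sensitivity_specificity(self):
        # 8/10 cases in high cells, 6/10 controls in low cells -> BA 0.7
        panel = small_panel([[0]] * 8 + [[1]] * 2, [[0]] * 4 + [[1]] * 6)
        model = cg.RiskModel(("s0",), {(0,): "high", (1,): "low"}, 1.0)
        assert cg.balanced_accuracy(model, panel) == pytest.approx(0.7)


class TestCrossValidation:
    def test_same_seed_reproduces_folds_and_results(self, xor_panel):
        r1 = cg.cross_validate(xor_panel, ("L1", "L2"), seed=5)
        r2 = cg.cross_validate(xor_panel, ("L1", "L2"), seed=5)
        assert [(f.training_ba, f.testing_ba) for f in r1] == [
            (f.training_ba, f.testing_ba) for f in r2
        ]

    def test_strong_signal_testing_tracks_training(self, xor_panel):
        res = cg.cross_validate(xor_panel, ("L1", "L2"), seed=1)
        train = np.nanmean([f.training_ba for f in res])
        test = np.nanmean([f.testing_ba for f in res])
        assert train > 0.6
        assert abs(train - test) < 0.1

    def test_training_ba_at_least_half_by_construction(self):
        """Labels are chosen to fit the training data, so training BA >= 0.5."""
        for seed in range(20):
            panel = null_panel(seed, n_cases=40, n_controls=40)
            res = cg.cross_validate(panel, ("S0", "S1"), seed=seed)
            for f in res:
                if not math.isnan(f.training_ba):
                    assert f.training_ba >= 0.5 - 1e-12

    def test_null_panels_center_testing_ba_near_half(self):
        bas = []
        for seed in range(60):
            panel = null_panel(seed, n_cases=60, n_controls=60)
            res = cg.cross_validate(panel, ("S0", "S1"), seed=seed)
            bas.append(np.nanmean([f.testing_ba for f in res]))
        assert 0.42 <= float(np.mean(bas)) <= 0.58


class TestSearch:
    def test_enumeration_counts(self, xor_panel):
        reports, _ = cg.mdr_search(xor_panel, k_range=(2,), seed=0)
        assert len(reports) == 6  # C(4,2)

    def test_planted_pair_wins_with_high_cvc(self, xor_panel):
        reports, best = cg.mdr_search(xor_panel, k_range=(1, 2, 3), seed=0)
        assert set(best.combo) == {"L1", "L2"}
        assert best.cvc >= 8
        assert best.testing_ba > 0.6

    def test_fully_penetrant_snp_is_a_perfect_k1_model(self):
        panel = small_panel([[2, 0], [2, 1], [2, 2]] * 10, [[0, 0], [0, 1], [0, 2]] * 10)
        reports, best = cg.mdr_search(panel, k_range=(1, 2), seed=0)
        assert best.combo == ("s0",)
        assert best.testing_ba == pytest.approx(1.0)
        assert best.cvc == 10

    def test_permutation_p_lower_bound_and_null_behaviour(self):
        panel = null_panel(3, n_cases=60, n_controls=60)
        p = cg.permutation_pvalue(panel, ("S0", "S1"), n_perm=99, seed=3)
        assert p >= 1 / 100
        with pytest.raises(ValueError):
            cg.permutation_pvalue(panel, ("S0", "S1"), n_perm=10)

    def test_search_permutation_p_small_for_planted_signal(self, xor_panel):
        _, best = cg.mdr_search(xor_panel, k_range=(1, 2), seed=0, n_perm=99)
        assert best.perm_p == pytest.approx(0.01, abs=1e-9)


class TestClassMetrics:
    def test_perfect_separation_metrics(self):
        panel = small_panel([[2]] * 10, [[0]] * 10)
        model = cg.classify_cells(cg.cell_counts(panel, ("s0",)))
        m = cg.class_metrics(model, panel)
        assert m.precision == 1.0 and m.f1 == 1.0
        assert m.mcc == pytest.approx(1.0)
        assert m.pr_auc == pytest.approx(1.0)

    def test_f1_formula(self):
        # precision 0.5, sensitivity 0.5 -> F1 0.5
        panel = small_panel([[0]] * 5 + [[1]] * 5, [[0]] * 5 + [[1]] * 5)
        model = cg.RiskModel(("s0",), {(0,): "high", (1,): "low"}, 1.0)
        m = cg.class_metrics(model, panel)
        assert m.precision == pytest.approx(0.5)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)

    def test_mcc_bounded(self, xor_panel):
        model = cg.classify_cells(cg.cell_counts(xor_panel, ("L1", "L2")))
        m = cg.class_metrics(model, xor_panel)
        assert -1.0 <= m.mcc <= 1.0
        assert 0.0 <= m.pr_auc <= 1.0

    def test_pr_auc_matches_sklearn_average_precision(self):
        """Our step-interpolated AP equals sklearn's on the same cell scores."""
        from sklearn.metrics import average_precision_score

        for seed in range(10):
            panel = null_panel(seed, n_cases=50, n_controls=100, mafs=(0.3, 0.4))
            combo = ("S0", "S1")
            model = cg.classify_cells(cg.cell_counts(panel, combo))
            ours = cg.class_metrics(model, panel).pr_auc
            # rebuild the per-individual scores (cell case proportion)
            g = panel.genotypes[:, [panel.snp_index(s) for s in combo]]
            cell = g[:, 0] * 1 + g[:, 1] * 3
            y = panel.phenotype
            scores = np.array([
                y[cell == c].mean() if (cell == c).any() else 0.0 for c in cell
            ])
            ref = average_precision_score(y, scores)
            assert ours == pytest.approx(ref, abs=1e-9)


class TestEntropy:
    def test_independent_class_gives_near_zero_ig(self):
        panel = null_panel(1, n_cases=200, n_controls=200)
        rep = cg.entropy_analysis(panel)
        assert all(v < 1.5 for v in rep.main_ig.values())  # plug-in bias bound
        assert all(abs(v) < 1.5 for v in rep.pair_ig.values())

    def test_noiseless_xor_is_pure_synergy(self):
        """C = parity of two dosages: no main effects, large pairwise IG."""
        rng = np.random.default_rng(2)
        # HWE dosages at MAF 0.5: P(odd dosage) = 1/2, so parity of one
        # locus alone carries no information about the class
        geno = rng.choice(3, size=(600, 2), p=(0.25, 0.5, 0.25))
        phen = ((geno[:, 0] + geno[:, 1]) % 2).astype(np.int8)
        snps = [cg.SnpMeta(f"s{j}", "1", j + 1, "A", "a") for j in range(2)]
        panel = cg.GenotypePanel(
            snps=snps, samples=[f"i{i}" for i in range(600)],
            genotypes=geno.astype(np.int8), phenotype=phen,
        )
        rep = cg.entropy_analysis(panel)
        assert rep.pair_ig[("s0", "s1")] > 50.0
        assert all(v < 5.0 for v in rep.main_ig.values())

    def test_duplicated_snp_is_redundant(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, size=400)
        phen = (col >= 1).astype(np.int8)  # associated SNP
        geno = np.column_stack([col, col]).astype(np.int8)
        snps = [cg.SnpMeta("a", "1", 1, "A", "a"), cg.SnpMeta("b", "1", 2, "C", "c")]
        panel = cg.GenotypePanel(
            snps=snps, samples=[f"i{i}" for i in range(400)],
            genotypes=geno, phenotype=phen,
        )
        rep = cg.entropy_analysis(panel)
        assert rep.pair_ig[("a", "b")] < -50.0  # full redundancy

    def test_constant_snp_excluded_from_clustering(self):
        rng = np.random.default_rng(6)
        geno = np.column_stack([
            np.zeros(100), rng.integers(0, 3, 100), rng.integers(0, 3, 100)
        ]).astype(np.int8)
        snps = [cg.SnpMeta(s, "1", i + 1, "A", "a") for i, s in enumerate("xyz")]
        panel = cg.GenotypePanel(
            snps=snps, samples=[f"i{i}" for i in range(100)],
            genotypes=geno,
            phenotype=rng.integers(0, 2, 100).astype(np.int8),
        )
        rep = cg.entropy_analysis(panel)
        assert rep.main_ig["x"] == 0.0
        assert "x" not in rep.leaves
        assert rep.newick().endswith(";")
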