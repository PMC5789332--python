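"""Fold changes, ANOVA/Tukey testing, BH correction and DE calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboflux import diffexpr, synthetic

from conftest import make_expr


def _design(groups, n_rep):
    samples = [f"{g}_{r}" for g in groups for r in range(n_rep)]
    return pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)


class TestFoldChanges:
    def test_identical_groups_give_unit_fc(self):
        design = _design(("CTRL", "NMO"), 2)
        m = make_expr([[4, 4, 4, 4], [9, 9, 9, 9]], ["a", "b"], list(design.index))
        fc = diffexpr.fold_changes(m, design).set_index("gene")
        assert (fc["fc"] == 1.0).all()

    def test_exact_halving(self):
        design = _design(("CTRL", "NMO"), 2)
        m = make_expr([[4.0, 4.0, 2.0, 2.0]], ["a"], list(design.index))
        fc = diffexpr.fold_changes(m, design)
        assert fc.loc[0, "fc"] == pytest.approx(0.5, rel=1e-15)

    def test_geometric_vs_arithmetic_dialect(self):
        design = _design(("CTRL", "NMO"), 2)
        m = make_expr([[1.0, 4.0, 2.0, 2.0]], ["a"], list(design.index))
        geo = diffexpr.fold_changes(m, design, method="geometric").loc[0, "fc"]
        ari = diffexpr.fold_changes(m, design, method="arithmetic").loc[0, "fc"]
        assert geo == pytest.approx(1.0)       # gm(2,2)/gm(1,4) = 2/2
        assert ari == pytest.approx(2.0 / 2.5)  # 2 / 2.5

    def test_nonpositive_expression_rejected(self):
        design = _design(("CTRL", "NMO"), 1)
        m = make_expr([[0.0, 1.0]], ["a"], list(design.index))
        with pytest.raises(ValueError, match="strictly positive"):
            diffexpr.fold_changes(m, design)

    def test_planted_grid_recovery(self):
        # planted fc grid, n=4, CV 0.1: median absolute log2 error small
        grid = {"Hk1": 0.25, "Gapdh": 0.5, "Pgk1": 1.0, "Pgam1": 2.0, "Eno1": 4.0}
        errors = []
        for seed in range(60):
            cfg = synthetic.SyntheticConfig(
                n_genes=12, seed=seed, planted_fc={"NMO": grid},
                groups=("CTRL", "NMO"), replicate_cv=0.1,
            )
            matrix, design, _ = synthetic.generate_experiment(cfg)
            bg = matrix - 100.0  # true background level; isolates fc noise
            fc = diffexpr.fold_changes(bg.clip(lower=1e-9), design).set_index("gene")
            for g, planted in grid.items():
                errors.append(abs(np.log2(fc.loc[g, "fc"] / planted)))
        assert np.median(errors) < 0.15


class TestAnovaTukey:
    def test_tukey_two_groups_equals_pooled_t(self, rng):
        design = _design(("CTRL", "NMO"), 5)
        m = make_expr(np.exp2(rng.normal(8, 1, (6, 10))),
                      [f"g{i}" for i in range(6)], list(design.index))
        result = diffexpr.anova_tukey(m, design)
        log2x = np.log2(m.to_numpy())
        for i, gene in enumerate(m.index):
            t = stats.ttest_ind(log2x[i, :5], log2x[i, 5:], equal_var=True)
            row = result[result.gene == gene].iloc[0]
            assert row["p_tukey"] == pytest.approx(t.pvalue, abs=1e-9)
            assert row["p_anova"] == pytest.approx(t.pvalue, abs=1e-9)

    def test_type_one_error_calibration(self, rng):
        # identical distributions in 6 groups of 4: rejection rate ~ alpha
        n_sim, reject = 1000, 0
        for _ in range(n_sim):
            groups = rng.normal(size=(6, 4))
            if stats.f_oneway(*groups).pvalue < 0.05:
                reject += 1
        assert 0.035 <= reject / n_sim <= 0.065

    def test_large_shift_detected(self):
        # 8-fold shift at n=4 and CV 0.1 is essentially always significant
        detected = 0
        n_runs = 40
        for seed in range(n_runs):
            cfg = synthetic.SyntheticConfig(
                n_genes=10, seed=seed, planted_fc={"NMO": {"Gapdh": 8.0}},
                groups=("CTRL", "NMO", "PPMS"), replicate_cv=0.1,
            )
            matrix, design, _ = synthetic.generate_experiment(cfg)
            result = diffexpr.anova_tukey(matrix, design)
            row = result[(result.gene == "Gapdh") & (result.group == "NMO")].iloc[0]
            detected += row["p_tukey"] < 0.01 and row["p_anova"] < 0.01
        assert detected / n_runs >= 0.99

    def test_singleton_group_rejected(self):
        design = pd.Series(["CTRL", "CTRL", "NMO"], index=["a", "b", "c"])
        m = make_expr([[1.0, 2.0, 3.0]], ["g"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="NMO"):
            diffexpr.anova_tukey(m, design)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = diffexpr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert diffexpr.bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(diffexpr.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserving(self, rng):
        p = rng.uniform(size=30)
        q = diffexpr.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_step_up_definition_on_all_subsets(self):
        pool = [0.001, 0.011, 0.11, 0.32, 0.64, 0.99]

        def brute(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            q = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                q[i] = running
            return q

        for r in range(1, len(pool) + 1):
            for subset in itertools.combinations(pool, r):
                np.testing.assert_allclose(
                    diffexpr.bh_fdr(list(subset)), brute(list(subset)), rtol=1e-12
                )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.bh_fdr([0.5, 1.5])


class TestCalls:
    @pytest.mark.parametrize(
        "fc,p,q,expected",
        [
            (0.3, 0.001, 0.02, "down"),
            (0.3, 0.02, 0.02, "nc"),     # omnibus/contrast p fails
            (1.9, 0.0001, 0.001, "nc"),  # fold change fails
            (2.0, 0.001, 0.05, "up"),
            (0.5, 0.009, 0.09, "down"),
            (4.0, 0.001, 0.2, "nc"),     # FDR fails
        ],
    )
    def test_threshold_rules(self, fc, p, q, expected):
        assert diffexpr.call_de(fc, p, q) == expected

    def test_reciprocal_fc_swaps_up_and_down(self, rng):
        for _ in range(200):
            fc = float(np.exp2(rng.uniform(-3, 3)))
            p, q = float(rng.uniform(0, 0.02)), float(rng.uniform(0, 0.15))
            call = diffexpr.call_de(fc, p, q)
            swapped = diffexpr.call_de(1.0 / fc, p, q)
            assert {call, swapped} in ({"up", "down"}, {"nc"})

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.call_de(np.nan, 0.5, 0.5)


def test_de_table_structure(small_experiment):
    _, matrix, design, _ = small_experiment
    from metaboflux import preprocess, refgenes

    corrected, _ = preprocess.normexp_correct_matrix(matrix)
    expr = refgenes.normalize_to_controls(
        preprocess.percentile75_normalize(corrected)
    )
    table = diffexpr.de_table(expr, design)
    assert set(table.columns) == {"gene", "group", "fc", "p_anova", "p_tukey", "q", "call"}
    assert set(table["group"]) == {"RMS_GMminus", "RMS_GMplus", "SPINAL", "PPMS", "NMO"}
    assert table["fc"].gt(0).all()
    assert table[["p_anova", "p_tukey", "q"]].apply(lambda c: c.between(0, 1)).all().all()
    called = table[table["call"] != "nc"]
    assert ((called["fc"] >= 2) | (called["fc"] <= 0.5)).all()
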