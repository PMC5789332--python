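"""geNorm / NormFinder stability and control-gene normalization."""

import numpy as np
import pandas as pd
import pytest

from metaboflux import refgenes, synthetic

from conftest import make_expr


def brute_force_genorm_m(expr: pd.DataFrame) -> pd.Series:
    """Independent double-loop oracle: sd of pairwise log2 ratios."""
    log2x = np.log2(expr.to_numpy(dtype=float))
    genes = list(expr.index)
    out = {}
    for j, gj in enumerate(genes):
        sds = []
        for k, _ in enumerate(genes):
            if k == j:
                continue
            sds.append(np.std(log2x[j] - log2x[k], ddof=1))
        out[gj] = np.mean(sds)
    return pd.Series(out)


class TestGenormM:
    def test_constant_ratio_pair_contributes_zero(self, rng):
        a = rng.uniform(10, 100, 6)
        noisy = rng.uniform(10, 100, 6)
        m = make_expr(np.vstack([a, 3 * a, noisy]), ["A", "B", "C"],
                      [f"s{i}" for i in range(6)])
        log2x = np.log2(m.to_numpy())
        assert np.std(log2x[0] - log2x[1], ddof=1) == pytest.approx(0, abs=1e-12)
        values = refgenes.genorm_m(m)
        # A and B only differ from each other's M through gene C
        expected = brute_force_genorm_m(m)
        assert values["A"] == pytest.approx(expected["A"], abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        m = make_expr(rng.uniform(5, 500, (4, 5)),
                      ["w", "x", "y", "z"], [f"s{i}" for i in range(5)])
        got = refgenes.genorm_m(m)
        want = brute_force_genorm_m(m)
        np.testing.assert_allclose(got[want.index], want, atol=1e-12)

    def test_invariant_under_per_sample_scaling(self, rng):
        m = make_expr(rng.uniform(5, 500, (5, 6)),
                      list("abcde"), [f"s{i}" for i in range(6)])
        scaled = m * rng.uniform(0.5, 2.0, 6)
        np.testing.assert_allclose(
            refgenes.genorm_m(m), refgenes.genorm_m(scaled), atol=1e-10
        )

    def test_fewer_than_three_candidates_rejected(self, rng):
        m = make_expr(rng.uniform(1, 10, (2, 4)), ["a", "b"], list("wxyz"))
        with pytest.raises(ValueError, match="at least 3"):
            refgenes.genorm_m(m)


class TestGenormRank:
    def test_three_candidates_single_exclusion(self, rng):
        m = make_expr(rng.uniform(5, 500, (3, 6)), list("abc"),
                      [f"s{i}" for i in range(6)])
        ranking = refgenes.genorm_rank(m)
        assert len(ranking.exclusion_order) == 1
        assert len(ranking.final_controls) == 2
        assert set(ranking.exclusion_order) | set(ranking.final_controls) == set("abc")

    def test_gene_order_permutation_invariant(self, rng):
        m = make_expr(rng.uniform(5, 500, (6, 8)), list("fbdace"),
                      [f"s{i}" for i in range(8)])
        shuffled = m.sample(frac=1, random_state=1)
        r1, r2 = refgenes.genorm_rank(m), refgenes.genorm_rank(shuffled)
        assert r1.final_controls == r2.final_controls
        assert r1.exclusion_order == r2.exclusion_order

    def test_stable_pair_selected_from_perturbed_panel(self):
        # Tfrc/B2m flat, the other 8 candidates drift with treatment
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            cfg = synthetic.SyntheticConfig(
                n_genes=10,
                seed=seed,
                gene_ids=refgenes.DEFAULT_REFERENCE_PANEL,
                planted_fc=synthetic.reference_panel_fc(rng),
            )
            matrix, _, _ = synthetic.generate_experiment(cfg)
            ranking = refgenes.genorm_rank(matrix)
            hits += ranking.final_controls == ("B2m", "Tfrc")
        assert hits / n_runs >= 0.95


class TestNormFinder:
    @staticmethod
    def _design(groups, n_rep):
        samples = [f"{g}_{r}" for g in groups for r in range(n_rep)]
        return pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)

    def _expr(self, rng, effects, resid_sd, groups=("a", "b", "c"), n_rep=4):
        """Linear-scale matrix with per-gene group effects (log2) planted."""
        design = self._design(groups, n_rep)
        rows = []
        for gene_effects, sd in zip(effects, resid_sd):
            log2row = [
                gene_effects[groups.index(design[s])] + rng.normal(0, sd)
                for s in design.index
            ]
            rows.append(np.exp2(np.array(log2row) + 10))
        genes = [f"g{i}" for i in range(len(effects))]
        return make_expr(rows, genes, list(design.index)), design

    def test_group_tracking_gene_ranks_less_stable(self, rng):
        effects = [(0, 0, 0), (0, 0, 0), (-1, 0, 1), (0, 0, 0)]
        resid = [0.1, 0.1, 0.1, 0.1]
        expr, design = self._expr(rng, effects, resid)
        ranking = refgenes.normfinder_stability(expr, design)
        assert ranking.stability["g2"] > ranking.stability["g0"]
        assert "g2" not in ranking.final_controls

    def test_identical_genes_have_zero_stability(self):
        design = self._design(("a", "b"), 3)
        expr = make_expr(np.full((4, 6), 128.0), list("wxyz"), list(design.index))
        ranking = refgenes.normfinder_stability(expr, design)
        np.testing.assert_allclose(ranking.stability, 0.0, atol=1e-12)

    def test_variance_component_recovery(self):
        # planted intergroup tau2 and residual sigma2, recovered on average;
        # planted components sit well above the truncation floor (negative
        # moment estimates clipped to 0 inflate near-zero components)
        tau = np.array([0.0, 0.35, 0.6, 0.45, 0.5])
        sigma = np.array([0.1, 0.2, 0.1, 0.3, 0.2])
        groups, n_rep, n_runs = ("a", "b", "c"), 4, 500
        inter = np.zeros(5)
        intra = np.zeros(5)
        rng = np.random.default_rng(12)
        for _ in range(n_runs):
            effects = [rng.normal(0, t, len(groups)) for t in tau]
            expr, design = self._expr(rng, effects, sigma, groups, n_rep)
            comp = refgenes.normfinder_components(expr, design)
            inter += comp["intergroup"].to_numpy()
            intra += comp["intragroup"].to_numpy()
        inter /= n_runs
        intra /= n_runs
        np.testing.assert_allclose(intra, sigma**2, rtol=0.25)
        np.testing.assert_allclose(inter[1:], tau[1:] ** 2, rtol=0.25)
        # the truly stable gene stays near zero (small positive residue is
        # the truncation floor)
        assert inter[0] < 0.03

    def test_singleton_group_rejected(self, rng):
        design = pd.Series(["a", "a", "b"], index=["s1", "s2", "s3"])
        expr = make_expr(rng.uniform(1, 10, (3, 3)), list("xyz"), list(design.index))
        with pytest.raises(ValueError, match="fewer than 2"):
            refgenes.normfinder_stability(expr, design)

    def test_invariant_under_per_gene_scaling(self, rng):
        expr, design = self._expr(
            rng, [(0, 0.5, 0), (0, 0, 0), (0.2, 0, -0.2)], [0.1, 0.2, 0.1]
        )
        scaled = expr.mul(pd.Series([3.0, 0.5, 7.0], index=expr.index), axis=0)
        a = refgenes.normfinder_stability(expr, design).stability
        b = refgenes.normfinder_stability(scaled, design).stability
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestNormalizeToControls:
    def test_unit_controls_are_identity(self):
        m = make_expr([[1.0, 1.0], [1.0, 1.0], [5.0, 7.0]],
                      ["Tfrc", "B2m", "x"], ["s1", "s2"])
        out = refgenes.normalize_to_controls(m)
        pd.testing.assert_frame_equal(out, m)

    def test_sample_scale_removed(self, rng):
        base = rng.uniform(5, 50, (4, 3))
        m = make_expr(base, ["Tfrc", "B2m", "x", "y"], list("abc"))
        doubled = m.copy()
        doubled["b"] = 2 * doubled["b"]
        out1 = refgenes.normalize_to_controls(m)
        out2 = refgenes.normalize_to_controls(doubled)
        pd.testing.assert_frame_equal(out1, out2)

    def test_idempotent(self, rng):
        m = make_expr(rng.uniform(1, 100, (5, 4)),
                      ["Tfrc", "B2m", "x", "y", "z"], list("abcd"))
        once = refgenes.normalize_to_controls(m)
        twice = refgenes.normalize_to_controls(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_absent_or_nonpositive_control_rejected(self, rng):
        m = make_expr(rng.uniform(1, 10, (2, 2)), ["Tfrc", "x"], ["s1", "s2"])
        with pytest.raises(KeyError, match="B2m"):
            refgenes.normalize_to_controls(m)
        m2 = make_expr([[1.0, 0.0], [2.0, 2.0], [3.0, 3.0]],
                       ["Tfrc", "B2m", "x"], ["s1", "s2"])
        with pytest.raises(ValueError, match="Tfrc.*s2"):
            refgenes.normalize_to_controls(m2)

    def test_planted_ratio_survives_normalization(self, table5_planted):
        cfg = synthetic.SyntheticConfig(
            n_genes=40, seed=23, planted_fc={"PPMS": {"Gapdh": 0.5}},
            replicate_cv=0.05, n_replicates_per_group=8,
        )
        matrix, design, _ = synthetic.generate_experiment(cfg)
        normed = refgenes.normalize_to_controls(matrix)
        ppms = normed.loc["Gapdh", design[design == "PPMS"].index].mean()
        ctrl = normed.loc["Gapdh", design[design == "CTRL"].index].mean()
        assert ppms / ctrl == pytest.approx(0.5, rel=0.2)
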