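"""Global efficiency and the stepwise-CV held-out prediction framework."""

import numpy as np
import pandas as pd
import pytest

from frustnet.benchmarks import bruteforce_global_efficiency
from frustnet.connectivity import ThresholdedGraph
from frustnet.efficiency import (build_efficiency_table, evaluate_heldout,
                                 fdr_correct, global_efficiency,
                                 run_prediction, stepwise_cv_select,
                                 stratified_split, PredictionResult)
from frustnet.modularity import Partition


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(1.0 - np.eye(7)) == pytest.approx(1.0)

    def test_three_node_path(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        assert global_efficiency(A) == pytest.approx(5 / 6)

    def test_isolated_node_contributes_zero(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        assert global_efficiency(A) == pytest.approx(2 / 6)

    def test_subset_restriction(self):
        A = 1.0 - np.eye(6)
        A[0, :] = A[:, 0] = 0.0  # node 0 cut off
        assert global_efficiency(A, [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 16))
            A = (rng.random((n, n)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            assert global_efficiency(A) == pytest.approx(
                bruteforce_global_efficiency(A), abs=1e-12)

    def test_monotone_under_edge_addition(self, rng):
        n = 10
        A = (rng.random((n, n)) < 0.2).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        e = global_efficiency(A)
        free = [(i, j) for i in range(n) for j in range(i + 1, n) if not A[i, j]]
        for i, j in free[:10]:
            B = A.copy()
            B[i, j] = B[j, i] = 1.0
            assert global_efficiency(B) >= e - 1e-12

    def test_tiny_subset_rejected(self):
        with pytest.raises(ValueError):
            global_efficiency(np.zeros((4, 4)), [2])


def synthetic_efficiency_problem(rng, n=66, p_eff=6, slope=0.0, target=0):
    """Predictor table of standardized pseudo-efficiency columns plus an
    outcome linearly linked to one column."""
    X = rng.standard_normal((n, p_eff))
    cols = [f"post-RS:M{j + 1}" for j in range(p_eff)]
    table = pd.DataFrame(X, columns=cols,
                         index=pd.Index([f"sub-{i:03d}" for i in range(n)],
                                        name="subject"))
    y = slope * X[:, target] + rng.standard_normal(n)
    phen = pd.DataFrame({"outcome": y}, index=table.index)
    return table, phen


class TestBuildEfficiencyTable:
    def _graphs(self, rng, within_edges, m2_edges=1):
        # single 12-node graph: module = nodes 0..5, vary intra-module edges
        A = np.zeros((12, 12))
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        for i, j in pairs[:within_edges]:
            A[i, j] = A[j, i] = 1.0
        m2 = [(i, j) for i in range(6, 12) for j in range(i + 1, 12)]
        for i, j in m2[:m2_edges]:
            A[i, j] = A[j, i] = 1.0
        return ThresholdedGraph(A, 0.1, "sub-001", "post-RS")

    def test_module_efficiency_increases_with_intra_module_edges(self, rng):
        part = Partition(np.array([1] * 6 + [2] * 6))
        effs = []
        for w in (4, 8, 12, 15):
            g = self._graphs(rng, w)
            effs.append(global_efficiency(g, part.members(1)))
        assert all(b >= a for a, b in zip(effs, effs[1:]))
        assert effs[-1] > effs[0]

    def test_table_layout_and_covariate_passthrough(self, rng):
        part = Partition(np.array([1] * 6 + [2] * 6))
        graphs = {(f"sub-{i:03d}", "post-RS"): self._graphs(rng, 8 + i, 2 + i)
                  for i in range(1, 4)}
        cov = pd.DataFrame({"age": [10.0, 11.0, 12.0]},
                           index=pd.Index([f"sub-{i:03d}" for i in range(1, 4)],
                                          name="subject"))
        table = build_efficiency_table(graphs, {"post-RS": part}, cov)
        assert list(table.columns) == ["post-RS:M1", "post-RS:M2", "age"]
        np.testing.assert_array_equal(table["age"], cov["age"])

    def test_missing_condition_rejected(self, rng):
        part = Partition(np.array([1] * 6 + [2] * 6))
        graphs = {("sub-001", "post-RS"): self._graphs(rng, 8)}
        with pytest.raises(ValueError):
            build_efficiency_table(graphs, {"post-RS": part, "pre-RS": part})

    def test_zero_variance_column_dropped(self, rng):
        part = Partition(np.array([1] * 6 + [2] * 6))
        graphs = {(f"sub-{i:03d}", "post-RS"): self._graphs(rng, 8)
                  for i in range(1, 4)}
        table = build_efficiency_table(graphs, {"post-RS": part})
        assert table.shape[1] == 0  # identical graphs -> all columns constant


class TestStratifiedSplit:
    def test_deterministic_given_seed(self, rng):
        _, phen = synthetic_efficiency_problem(rng)
        s1 = stratified_split(phen, "outcome", 48, 18, seed=5)
        s2 = stratified_split(phen, "outcome", 48, 18, seed=5)
        assert s1.train_ids == s2.train_ids and s1.test_ids == s2.test_ids

    def test_train_test_outcome_distributions_match(self, rng):
        gaps = []
        for s in range(30):
            _, phen = synthetic_efficiency_problem(rng)
            rec = stratified_split(phen, "outcome", 48, 18, seed=s)
            y = phen["outcome"]
            gaps.append(abs(y[rec.train_ids].mean() - y[rec.test_ids].mean())
                        / y.std())
        assert np.mean(gaps) < 0.25

    def test_constant_outcome_still_splits(self, rng):
        phen = pd.DataFrame({"outcome": np.zeros(66)},
                            index=[f"s{i}" for i in range(66)])
        rec = stratified_split(phen, "outcome", 48, 18, seed=0)
        assert len(rec.train_ids) == 48 and len(rec.test_ids) == 18

    def test_wrong_sizes_rejected(self, rng):
        _, phen = synthetic_efficiency_problem(rng)
        with pytest.raises(ValueError):
            stratified_split(phen, "outcome", 48, 10, seed=0)


class TestStepwiseSelection:
    def test_noiseless_two_predictor_recovery(self, rng):
        table, _ = synthetic_efficiency_problem(rng)
        y = 2.0 * table["post-RS:M2"] - 1.5 * table["post-RS:M5"]
        model = stepwise_cv_select(table, y, k=5, repeats=2, seed=0)
        assert sorted(model.predictors) == ["post-RS:M2", "post-RS:M5"]
        coef = dict(zip(model.predictors, model.coef))
        assert coef["post-RS:M2"] == pytest.approx(2.0, abs=1e-8)
        assert coef["post-RS:M5"] == pytest.approx(-1.5, abs=1e-8)

    def test_pure_noise_yields_near_null_heldout_r(self, rng):
        rs = []
        for s in range(30):
            table, phen = synthetic_efficiency_problem(rng, slope=0.0)
            res = run_prediction(table, phen, "outcome", train_n=48, test_n=18,
                                 k=5, repeats=2, n_perm=50, seed=s)
            if not res.failed:
                rs.append(res.r)
        assert abs(np.mean(rs)) < 0.2 if rs else True

    def test_planted_slope_selected_majority_of_seeds(self, rng):
        hits = 0
        for s in range(12):
            table, phen = synthetic_efficiency_problem(rng, slope=0.7, target=2)
            model = stepwise_cv_select(
                (table - table.mean()) / table.std(), phen["outcome"],
                k=5, repeats=2, seed=s)
            hits += "post-RS:M3" in model.predictors
        assert hits > 6


class TestHeldoutEvaluation:
    def test_perfect_model_r_one_p_floor(self, rng):
        table, _ = synthetic_efficiency_problem(rng, n=20)
        y = 3.0 * table["post-RS:M1"]
        model = stepwise_cv_select(table, y, k=5, repeats=1, seed=0)
        res = evaluate_heldout(model, table, y, n_perm=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 201)

    def test_intercept_only_flagged_failure(self, rng):
        table, _ = synthetic_efficiency_problem(rng, n=20)
        from frustnet.efficiency import StepwiseModel
        model = StepwiseModel([], np.empty(0), 0.0, 1.0)
        res = evaluate_heldout(model, table, rng.standard_normal(20),
                               n_perm=50, seed=0)
        assert res.failed and np.isnan(res.r) and res.p == 1.0


class TestFdrCorrect:
    def _results(self, ps):
        return [PredictionResult(f"o{i}", [], np.empty(0), 0.1, 0.01, 1.0,
                                 p, None, 100) for i, p in enumerate(ps)]

    def test_equal_ps_unchanged(self):
        out = fdr_correct(self._results([0.04] * 5))
        assert all(r.q == pytest.approx(0.04) for r in out)

    def test_single_small_p_scaled_by_m(self):
        out = fdr_correct(self._results([0.002, 0.8, 0.9, 0.95, 1.0]))
        assert out[0].q == pytest.approx(0.01)

    def test_matches_bruteforce_step_up(self, rng):
        ps = rng.uniform(size=7)
        out = fdr_correct(self._results(list(ps)))
        m = len(ps)
        order = np.argsort(ps)
        q_sorted = ps[order] * m / (np.arange(m) + 1)
        # step-up: running minimum from the largest rank down
        for i in range(m - 2, -1, -1):
            q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
        expect = np.empty(m)
        expect[order] = np.minimum(q_sorted, 1.0)
        for r, e in zip(out, expect):
            assert r.q == pytest.approx(max(e, r.p), abs=1e-12)
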