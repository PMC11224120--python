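"""Variation of information, Q contrasts, permutation inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from frustnet.benchmarks import bruteforce_vin
from frustnet.modularity import Partition
from frustnet.reconfiguration import (condition_vin_test, hedges_g_paired,
                                      module_vin, module_vin_test, q_contrast,
                                      variation_of_information)


class TestVariationOfInformation:
    def test_identical_up_to_relabeling_is_zero(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        b = np.array([7, 7, 1, 1, 4, 4])
        assert variation_of_information(a, b) == 0.0

    def test_one_module_vs_singletons_is_one(self):
        n = 12
        assert variation_of_information(
            np.ones(n, dtype=int), np.arange(n)) == pytest.approx(1.0)

    def test_matches_bruteforce_contingency(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 25))
            a = Partition(rng.integers(1, 5, size=n)).labels
            b = Partition(rng.integers(1, 5, size=n)).labels
            assert variation_of_information(a, b) == pytest.approx(
                bruteforce_vin(a, b), abs=1e-12)

    def test_metric_properties(self, rng):
        # symmetry and triangle inequality on random partition triples
        for _ in range(40):
            n = int(rng.integers(4, 16))
            a, b, c = (rng.integers(1, 4, size=n) for _ in range(3))
            dab = variation_of_information(a, b)
            dba = variation_of_information(b, a)
            dac = variation_of_information(a, c)
            dcb = variation_of_information(c, b)
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-12

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information(np.array([1]), np.array([1]))

    @given(st.integers(2, 30), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bounded_and_zero_iff_identical(self, n, seed):
        r = np.random.default_rng(seed)
        a = r.integers(1, 6, size=n)
        b = r.integers(1, 6, size=n)
        v = variation_of_information(a, b)
        assert -1e-12 <= v <= 1 + 1e-12
        assert variation_of_information(a, a) == 0.0
        if v == 0.0:
            # zero implies the partitions coincide up to relabeling
            from frustnet.modularity import canonical_labels
            assert np.array_equal(canonical_labels(a), canonical_labels(b))


class TestModuleVin:
    def setup_method(self):
        self.ref = Partition(np.array([1] * 6 + [2] * 6))

    def test_intact_module_zero(self):
        p = Partition(np.array([1] * 6 + [2] * 6))
        assert module_vin(self.ref, p, p, 1) == 0.0

    def test_module_split_to_singletons_is_one(self):
        p1 = Partition(np.array([1] * 6 + [2] * 6))
        p2 = Partition(np.r_[np.arange(1, 7), np.full(6, 7)])
        assert module_vin(self.ref, p1, p2, 1) == pytest.approx(1.0)

    def test_matches_restricted_bruteforce(self, rng):
        for _ in range(25):
            p1 = Partition(rng.integers(1, 4, size=12))
            p2 = Partition(rng.integers(1, 4, size=12))
            members = self.ref.members(1)
            expect = bruteforce_vin(Partition(p1.labels[members]).labels,
                                    Partition(p2.labels[members]).labels)
            assert module_vin(self.ref, p1, p2, 1) == pytest.approx(expect, abs=1e-12)

    def test_small_module_rejected(self):
        ref = Partition(np.array([1] * 9 + [2] * 3))
        with pytest.raises(ValueError):
            module_vin(ref, ref, ref, 2)


def make_q_table(rng, n_sub=20, densities=(0.05, 0.10), shift=0.0):
    rows = []
    base = rng.standard_normal((n_sub, len(densities))) * 0.05 + 0.4
    for cond, delta in (("A", 0.0), ("B", shift)):
        noise = rng.standard_normal((n_sub, len(densities))) * 0.02
        for s in range(n_sub):
            for j, d in enumerate(densities):
                rows.append({"subject": s, "condition": cond, "density": d,
                             "q": base[s, j] + delta + noise[s, j]})
    return pd.DataFrame(rows)


class TestQContrast:
    def test_self_contrast_null(self, rng):
        qt = make_q_table(rng)
        res = q_contrast(qt, "A", "A", n_perm=200, seed=0)
        assert np.allclose(res.t, 0.0)
        assert np.all(res.p == 1.0)
        assert np.allclose(res.hedges_g, 0.0)

    def test_constant_shift_detected_at_floor(self, rng):
        qt = make_q_table(rng, shift=-0.5)
        res = q_contrast(qt, "A", "B", n_perm=500, seed=0)
        assert np.all(res.p == pytest.approx(1 / 501))
        assert np.all(res.hedges_g > 3)  # direction: A - B = +0.5

    def test_matches_textbook_t_and_g(self, rng):
        qt = make_q_table(rng, shift=-0.05)
        res = q_contrast(qt, "A", "B", n_perm=100, seed=0)
        wide = qt.pivot_table(index="subject", columns=["condition", "density"],
                              values="q")
        for j, d in enumerate(res.densities):
            diff = (wide[("A", d)] - wide[("B", d)]).to_numpy()
            t_ref = stats.ttest_rel(wide[("A", d)], wide[("B", d)]).statistic
            n = len(diff)
            g_ref = diff.mean() / diff.std(ddof=1) * (1 - 3 / (4 * (n - 1) - 1))
            assert res.t[j] == pytest.approx(t_ref)
            assert res.hedges_g[j] == pytest.approx(g_ref)

    def test_fwer_never_below_raw(self, rng):
        qt = make_q_table(rng, shift=-0.03)
        res = q_contrast(qt, "A", "B", n_perm=300, seed=1)
        assert np.all(res.p_fwer >= res.p - 1e-12)

    def test_hedges_g_zero_variance_conventions(self):
        assert hedges_g_paired(np.zeros(10)) == 0.0
        assert np.isnan(hedges_g_paired(np.full(10, 0.3)))


def flip_nodes(labels, nodes, rng):
    out = labels.copy()
    for i in nodes:
        choices = [m for m in np.unique(labels) if m != labels[i]]
        out[i] = rng.choice(choices)
    return out


class TestConditionVinTest:
    def test_identical_conditions_give_large_p(self, rng):
        base = np.repeat([1, 2, 3], 8)
        parts = [Partition(flip_nodes(base, rng.choice(24, 2, replace=False), rng))
                 for _ in range(12)]
        res = condition_vin_test(parts, parts, n_perm=60, seed=0,
                                 consensus_restarts=8)
        assert res.p > 0.5

    def test_planted_reconfiguration_detected(self):
        # subject partitions estimated from graphs carry realistic
        # fragmentation heterogeneity; a planted 25%-node reassignment is
        # discriminated from an unchanged condition pair
        from frustnet.benchmarks import (_rest_cohort_config,
                                         _subject_partitions)
        from frustnet.synthetic import generate_cohort, PRE_RS, POST_RS
        cfg = _rest_cohort_config(5, 20, 40, 4, 300)
        series, _, _ = generate_cohort(cfg)
        parts, _ = _subject_partitions(series, 0.10, 30, 5)
        subs = sorted({s for s, _ in parts})
        pre = [parts[(s, PRE_RS)] for s in subs]
        post = [parts[(s, POST_RS)] for s in subs]
        ctrl = [parts[(s, "rest-ctrl")] for s in subs]
        changed = condition_vin_test(pre, post, n_perm=100, seed=1,
                                     consensus_restarts=8)
        null = condition_vin_test(pre, ctrl, n_perm=100, seed=2,
                                  consensus_restarts=8)
        assert changed.vin > 0.2
        assert null.vin < 0.1
        assert changed.p <= 0.1
        assert null.p > 0.3

    def test_mismatched_subjects_rejected(self):
        p = Partition(np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError):
            condition_vin_test([p, p], [p], n_perm=10, seed=0)


class TestModuleVinTest:
    def test_identical_partitions_all_zero(self):
        ref = Partition(np.repeat([1, 2, 3], 6))
        parts = [ref] * 8
        results, table = module_vin_test(ref, parts, parts, n_perm=50, seed=0)
        assert all(r.mean_vin == 0.0 for r in results)

    def test_reconfigured_module_ranks_highest(self, rng):
        # reconfiguration concentrated in module 1: its members scatter in
        # condition B while modules 2 and 3 stay intact
        ref = Partition(np.repeat([1, 2, 3], 8))
        pa, pb = [], []
        for _ in range(10):
            pa.append(Partition(flip_nodes(ref.labels, rng.choice(24, 1), rng)))
            lb = ref.labels.copy()
            movers = ref.members(1)[:5]
            lb[movers] = [2, 3, 2, 3, 2]
            pb.append(Partition(flip_nodes(lb, rng.choice(24, 1), rng)))
        results, table = module_vin_test(ref, pa, pb, n_perm=200, seed=0)
        assert results[0].module_id == 1
        assert (table["p_fwer"] >= table["p_perm"] - 1e-12).all()
        # module 1 vs others significantly higher
        m1_rows = table[(table.module_a == 1) | (table.module_b == 1)]
        assert (m1_rows["p_fwer"] < 0.05).all()
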