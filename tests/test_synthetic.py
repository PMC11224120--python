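"""Generator behaviour: event schedules, HRF regressor, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist

from frustnet.synthetic import (CohortConfig, block_correlation,
                                generate_cohort, generate_event_schedule,
                                hrf_regressor, make_planted_partitions)


class TestEventSchedule:
    def test_all_rigged_means_every_feedback_is_fnr(self):
        ev = generate_event_schedule(20, rigged_fraction=1.0, seed=0)
        fb = ev[ev.phase == "feedback"]
        assert (fb.event_type == "FNR").all()
        antic = ev[(ev.phase == "anticipation") & (ev.trial > 0)]
        assert (antic.event_type == "FNR+1").all()

    def test_zero_rigged_means_no_fnr(self):
        ev = generate_event_schedule(20, rigged_fraction=0.0, seed=0)
        assert not (ev.event_type == "FNR").any()
        assert not (ev.event_type == "FNR+1").any()

    def test_fnr_count_binomial_around_60_percent(self):
        counts = [
            (generate_event_schedule(50, 0.6, seed=s).query(
                "phase == 'feedback' and event_type == 'FNR'").shape[0])
            for s in range(200)
        ]
        # direct count oracle: mean 30, sd sqrt(50*.6*.4) ~ 3.46
        assert abs(np.mean(counts) - 30) < 1.0
        assert 2.0 < np.std(counts) < 5.0

    def test_n_plus_one_labels_follow_previous_feedback(self):
        ev = generate_event_schedule(30, 0.5, seed=3)
        fb = ev[ev.phase == "feedback"].set_index("trial").event_type
        antic = ev[(ev.phase == "anticipation") & (ev.trial > 0)].set_index("trial").event_type
        for t, lab in antic.items():
            assert lab == {"FNR": "FNR+1", "Reward": "Reward+1"}[fb.loc[t - 1]]

    def test_onsets_strictly_increasing(self):
        ev = generate_event_schedule(15, 0.6, seed=1)
        assert (np.diff(ev.onset) > 0).all()

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValueError):
            generate_event_schedule(1, 0.6, seed=0)


class TestHrfRegressor:
    def test_single_impulse_proportional_to_kernel(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [0.1]})
        r = hrf_regressor(ev, 20, 1.0)
        t = np.arange(20)
        kernel = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
        c = np.corrcoef(r[1:], kernel[1:])[0, 1]
        assert c > 0.999
        assert 4 <= np.argmax(r) <= 7  # peak lag ~5-6 s

    def test_linearity_two_separated_impulses(self):
        e1 = pd.DataFrame({"onset": [2.0], "duration": [0.5]})
        e2 = pd.DataFrame({"onset": [40.0], "duration": [0.5]})
        both = pd.concat([e1, e2], ignore_index=True)
        n, tr = 60, 1.0
        np.testing.assert_allclose(hrf_regressor(both, n, tr),
                                   hrf_regressor(e1, n, tr) + hrf_regressor(e2, n, tr),
                                   atol=1e-12)

    def test_dense_train_matches_naive_convolution(self):
        rng = np.random.default_rng(0)
        onsets = np.sort(rng.uniform(0, 80, size=25))
        ev = pd.DataFrame({"onset": onsets, "duration": np.full(25, 1.0)})
        n, tr, os_ = 50, 2.0, 16
        r = hrf_regressor(ev, n, tr, oversample=os_)
        # naive O(T*K) loop on the same fine grid
        dt = tr / os_
        n_fine = int(np.ceil(n * tr / dt)) + 1
        box = np.zeros(n_fine)
        for on, du in zip(ev.onset, ev.duration):
            i0 = int(np.round(on / dt))
            i1 = max(i0 + 1, int(np.round((on + du) / dt)))
            box[i0:min(i1, n_fine)] += 1.0
        t = np.arange(0, 32.0, dt)
        kernel = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
        kernel /= kernel.max()
        naive = np.zeros(n_fine)
        for i in range(n_fine):
            acc = 0.0
            for j in range(len(kernel)):
                if 0 <= i - j < n_fine:
                    acc += box[i - j] * kernel[j]
            naive[i] = acc * dt
        idx = np.round(np.arange(n) * tr / dt).astype(int)
        np.testing.assert_allclose(r, naive[idx], atol=1e-10)

    def test_empty_events_zero_vector(self):
        assert not hrf_regressor(pd.DataFrame({"onset": [], "duration": []}), 10, 2.0).any()

    def test_onset_beyond_run_rejected(self):
        ev = pd.DataFrame({"onset": [100.0], "duration": [1.0]})
        with pytest.raises(ValueError):
            hrf_regressor(ev, 10, 2.0)


class TestPlantedStructure:
    def test_partitions_cover_all_nodes(self):
        parts = make_planted_partitions(116)
        for p in parts.values():
            assert p.n_nodes == 116
            assert sorted(np.unique(p.labels)) == list(range(1, p.n_modules + 1))

    def test_unchanged_conditions_share_baseline(self):
        parts = make_planted_partitions(60, ("pre-RS", "FNR", "post-RS"), n_modules=5)
        assert np.array_equal(parts["pre-RS"].labels, parts["FNR"].labels)
        assert not np.array_equal(parts["pre-RS"].labels, parts["post-RS"].labels)

    def test_block_correlation_positive_definite(self):
        labels = np.repeat([1, 2, 3], 10)
        R = block_correlation(labels, 0.6, 0.05)
        assert np.linalg.eigvalsh(R)[0] > 0
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_inconsistent_correlations_rejected(self):
        with pytest.raises(ValueError):
            block_correlation(np.repeat([1, 2], 5), 1.2, 0.05)

    def test_sample_correlation_converges_to_planted_blocks(self):
        # max |sample corr - planted corr| shrinks as T grows
        conditions = ("pre-RS",)
        parts = make_planted_partitions(24, conditions, n_modules=2, seed=0)
        devs = {}
        for T in (200, 2000):
            cfg = CohortConfig(n_subjects=1, n_nodes=24, conditions=conditions,
                               n_volumes_rest=T, planted_partitions=parts,
                               corr_jitter_sd=0.0, confound_loading_sd=0.0,
                               phenotype_effects={}, seed=4)
            series, _, _ = generate_cohort(cfg)
            R = block_correlation(parts["pre-RS"].labels, 0.6, 0.05)
            devs[T] = np.abs(np.corrcoef(series[0].data) - R).max()
        assert devs[2000] < devs[200]
        assert devs[2000] < 0.12

    def test_same_seed_bit_identical(self):
        cfg1 = CohortConfig(n_subjects=2, n_nodes=12, conditions=("pre-RS", "FNR"),
                            n_volumes_rest=50, n_trials=5, n_runs=1, seed=9)
        cfg2 = CohortConfig(n_subjects=2, n_nodes=12, conditions=("pre-RS", "FNR"),
                            n_volumes_rest=50, n_trials=5, n_runs=1, seed=9)
        s1, p1, g1 = generate_cohort(cfg1)
        s2, p2, g2 = generate_cohort(cfg2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.data, b.data)
            np.testing.assert_array_equal(a.confounds, b.confounds)
        pd.testing.assert_frame_equal(p1, p2)
        assert g1 == g2

    def test_null_phenotypes_independent_of_network_jitter(self):
        # zero-slope outcomes are drawn from a separate stream: correlation
        # with the latent within-module jitter is ~0 across replicates
        cors = []
        for s in range(25):
            cfg = CohortConfig(n_subjects=30, n_nodes=12, conditions=("pre-RS",),
                               n_volumes_rest=10, phenotype_effects={}, seed=s)
            _, phen, gt = generate_cohort(cfg)
            deltas = np.array(gt["deltas"]["pre-RS"])[:, 0]
            cors.append(np.corrcoef(phen["anxiety"], deltas)[0, 1])
        assert abs(np.mean(cors)) < 0.08

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            CohortConfig(within_module_corr=0.1, between_module_corr=0.3)
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2, n_nodes=10, conditions=("pre-RS",),
                         planted_partitions={"pre-RS":
                                             make_planted_partitions(8, ("pre-RS",))["pre-RS"]})
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=2, n_nodes=12, conditions=("pre-RS",),
                         phenotype_effects={"accuracy": (99, "pre-RS", 0.5)})

    def test_effect_linked_phenotype_tracks_latent_jitter(self):
        cfg = CohortConfig(n_subjects=200, n_nodes=12, conditions=("pre-RS",),
                           n_volumes_rest=10,
                           phenotype_effects={"accuracy": (1, "pre-RS", 0.8)},
                           seed=3)
        _, phen, gt = generate_cohort(cfg)
        z = np.array(gt["deltas"]["pre-RS"])[:, 0] / cfg.corr_jitter_sd
        r = np.corrcoef(phen["accuracy"], z)[0, 1]
        # slope 0.8 with unit noise -> r ~ 0.8/sqrt(1.64) ~ 0.62
        assert 0.45 < r < 0.8
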