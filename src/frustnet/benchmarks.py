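"""Validation experiments: oracle agreement, planted recovery, error control.

These are the package's own calibration studies, shared by the test suite and
the acceptance script. The brute-force metric implementations here are kept
deliberately naive (explicit loops, no shared code with the analysis modules)
so they can serve as independent oracles.
"""

from __future__ import annotations

import numpy as np

from .connectivity import cohort_connectivity, threshold_proportional
from .efficiency import build_efficiency_table, run_prediction, run_prediction_family
from .modularity import Partition, best_partition, group_consensus
from .reconfiguration import condition_vin_test, q_contrast, variation_of_information
from .synthetic import (CohortConfig, PRE_RS, POST_RS, PRIMARY_OUTCOMES,
                        generate_cohort, make_planted_partitions)

REST_CTRL = "rest-ctrl"   # extra no-change resting condition for null contrasts


# ---------------------------------------------------------------------------
# brute-force metric oracles
# ---------------------------------------------------------------------------


def bruteforce_modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman Q by explicit edge counting (independent of modularity_q)."""
    n = adj.shape[0]
    two_e = 0.0
    for i in range(n):
        for j in range(n):
            two_e += adj[i, j]
    q = 0.0
    for m in set(labels.tolist()):
        e_mm = 0.0
        d_m = 0.0
        for i in range(n):
            if labels[i] == m:
                for j in range(n):
                    d_m += adj[i, j]
                    if labels[j] == m:
                        e_mm += adj[i, j]
        q += e_mm / two_e - (d_m / two_e) ** 2
    return q


def bruteforce_vin(l1: np.ndarray, l2: np.ndarray) -> float:
    """Normalized VI from an explicitly enumerated contingency table."""
    n = len(l1)
    counts: dict[tuple, int] = {}
    c1: dict[int, int] = {}
    c2: dict[int, int] = {}
    for a, b in zip(l1.tolist(), l2.tolist()):
        counts[(a, b)] = counts.get((a, b), 0) + 1
        c1[a] = c1.get(a, 0) + 1
        c2[b] = c2.get(b, 0) + 1
    vi = 0.0
    for (a, b), nab in counts.items():
        p = nab / n
        vi += -p * (np.log(nab / c1[a]) + np.log(nab / c2[b]))
    return vi / np.log(n)


def bruteforce_global_efficiency(adj: np.ndarray, subset=None) -> float:
    """E_glob via an explicit Floyd-Warshall on the induced subgraph."""
    if subset is not None:
        idx = list(subset)
        adj = adj[np.ix_(idx, idx)]
    n = adj.shape[0]
    INF = float("inf")
    d = [[0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    tot = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and d[i][j] < INF:
                tot += 1.0 / d[i][j]
    return tot / (n * (n - 1))


def metric_oracle_suite(seed: int = 0, n_graphs: int = 200) -> dict:
    """Max |difference| between the analysis metrics and the brute-force
    oracles over random graphs/partitions of <= 20 nodes, plus closed forms."""
    from .efficiency import global_efficiency
    from .modularity import modularity_q
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0AC1]))
    dq = dv = de = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(4, 21))
        p = rng.uniform(0.2, 0.8)
        A = (rng.random((n, n)) < p).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0:
            A[0, 1] = A[1, 0] = 1.0
        k = int(rng.integers(1, min(n, 6) + 1))
        labels = rng.integers(1, k + 1, size=n).astype(np.int64)
        labels2 = rng.integers(1, k + 1, size=n).astype(np.int64)
        dq = max(dq, abs(modularity_q(A, labels) - bruteforce_modularity(A, labels)))
        dv = max(dv, abs(variation_of_information(labels, labels2)
                         - bruteforce_vin(Partition(labels).labels,
                                          Partition(labels2).labels)))
        de = max(de, abs(global_efficiency(A) - bruteforce_global_efficiency(A)))
    # closed forms
    k_cliques = 4
    csize = 5
    n = k_cliques * csize
    A = np.zeros((n, n))
    labels = np.empty(n, dtype=np.int64)
    for c in range(k_cliques):
        idx = slice(c * csize, (c + 1) * csize)
        A[idx, idx] = 1.0
        labels[idx] = c + 1
    np.fill_diagonal(A, 0.0)
    closed = {
        "q_cliques": abs(modularity_q(A, labels) - (1 - 1 / k_cliques)),
        "vin_extreme": abs(variation_of_information(
            np.ones(10, np.int64), np.arange(1, 11, dtype=np.int64)) - 1.0),
        "eglob_complete": abs(global_efficiency(1.0 - np.eye(6)) - 1.0),
        "eglob_path3": abs(global_efficiency(np.array(
            [[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)) - 5.0 / 6.0),
    }
    return {"max_dq": dq, "max_dvin": dv, "max_deglob": de,
            "max_closed_form": max(closed.values()), "n_graphs": n_graphs}


# ---------------------------------------------------------------------------
# planted-partition recovery
# ---------------------------------------------------------------------------


def _rest_cohort_config(seed, n_subjects, n_nodes, n_modules, T,
                        reassign_post=0.25, **kwargs):
    """Resting-only cohort with an unchanged control condition and a
    reconfigured post-task condition."""
    conditions = (PRE_RS, REST_CTRL, POST_RS)
    parts = make_planted_partitions(
        n_nodes, conditions, n_modules=n_modules,
        reassign_fractions={REST_CTRL: 0.0, POST_RS: reassign_post}, seed=seed)
    return CohortConfig(n_subjects=n_subjects, n_nodes=n_nodes,
                        conditions=conditions, n_volumes_rest=T,
                        planted_partitions=parts, phenotype_effects={},
                        seed=seed, **kwargs)


def _subject_partitions(series, density, n_restarts, seed):
    matrices = cohort_connectivity(series)
    graphs = {k: threshold_proportional(cm, density) for k, cm in matrices.items()}
    keys = sorted(graphs)
    seeds = np.random.SeedSequence([seed, 0x5B1]).spawn(len(keys))
    parts = {}
    for key, child in zip(keys, seeds):
        parts[key] = best_partition(graphs[key], n_restarts, seed=child).best_partition
    return parts, graphs


def planted_recovery_experiment(seed: int = 0, n_subjects: int = 20,
                                n_nodes: int = 60, n_modules: int = 5,
                                T: int = 500, density: float = 0.10,
                                n_restarts: int = 100, n_perm: int = 500,
                                consensus_restarts: int = 30,
                                test_consensus_restarts: int = 15) -> dict:
    """Recovery of planted partitions and detection of a 25%-node reassignment.

    Within/between correlations 0.6/0.05 (config defaults), modules of 12
    nodes, series length T. Reports the group-consensus-vs-planted VIn per
    condition, the permutation p for the reconfigured pair (expected at the
    floor 1/(n_perm+1)) and for the unchanged pair (expected well above .05).
    """
    cfg = _rest_cohort_config(seed, n_subjects, n_nodes, n_modules, T)
    series, _, _ = generate_cohort(cfg)
    parts, _ = _subject_partitions(series, density, n_restarts, seed)
    subjects = sorted({s for s, _ in parts})
    ss = np.random.SeedSequence([seed, 0x5B2])
    cseeds = ss.spawn(len(cfg.conditions) + 2)
    recovery = {}
    for cond, child in zip(cfg.conditions, cseeds):
        cons = group_consensus([parts[(s, cond)] for s in subjects], seed=child,
                               n_restarts=consensus_restarts)
        recovery[cond] = variation_of_information(cons.partition,
                                                  cfg.planted_partitions[cond])
    pre = [parts[(s, PRE_RS)] for s in subjects]
    post = [parts[(s, POST_RS)] for s in subjects]
    ctrl = [parts[(s, REST_CTRL)] for s in subjects]
    res_change = condition_vin_test(pre, post, PRE_RS, POST_RS, density=density,
                                    n_perm=n_perm, seed=cseeds[-2],
                                    consensus_restarts=test_consensus_restarts)
    res_null = condition_vin_test(pre, ctrl, PRE_RS, REST_CTRL, density=density,
                                  n_perm=n_perm, seed=cseeds[-1],
                                  consensus_restarts=test_consensus_restarts)
    return {"recovery_vin": recovery,
            "recovery_vin_max": max(recovery.values()),
            "p_reconfigured_pair": res_change.p,
            "vin_reconfigured_pair": res_change.vin,
            "p_unchanged_pair": res_null.p,
            "p_floor": 1.0 / (n_perm + 1.0),
            "n_perm": n_perm}


# ---------------------------------------------------------------------------
# type-I error of the permutation tests
# ---------------------------------------------------------------------------


def type_one_error_experiment(seed: int = 0, n_replicates: int = 200,
                              n_subjects: int = 12, n_nodes: int = 40,
                              n_modules: int = 4, T: int = 150,
                              density: float = 0.10,
                              densities=(0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
                              n_restarts: int = 12, vin_perms: int = 99,
                              q_perms: int = 500,
                              consensus_restarts: int = 8,
                              alpha: float = 0.05) -> dict:
    """Empirical rejection rates on replicate null cohorts (no reconfiguration).

    Both resting conditions share the planted partition, so any rejection is
    a false positive. Reports the rejection rate of the condition VIn test at
    the analysis density, the per-density rejection rate of the paired-Q
    contrast, and the familywise rate of its max-|t| correction across the
    density ladder.
    """
    import pandas as pd
    rep_seeds = np.random.SeedSequence([seed, 0x71E]).spawn(n_replicates)
    vin_rej = q_rej = fwer_rej = 0
    for rs in rep_seeds:
        child = int(rs.generate_state(1)[0] % (2 ** 31))
        conditions = (PRE_RS, REST_CTRL)
        parts0 = make_planted_partitions(n_nodes, conditions, n_modules=n_modules,
                                         reassign_fractions={REST_CTRL: 0.0},
                                         seed=child)
        cfg = CohortConfig(n_subjects=n_subjects, n_nodes=n_nodes,
                           conditions=conditions, n_volumes_rest=T,
                           planted_partitions=parts0, phenotype_effects={},
                           seed=child)
        series, _, _ = generate_cohort(cfg)
        matrices = cohort_connectivity(series)
        rows = []
        subject_parts = {}
        keys = sorted(matrices)
        kseeds = np.random.SeedSequence([child, 0x71F]).spawn(len(keys))
        for (sid, cond), ks in zip(keys, kseeds):
            dseeds = ks.spawn(len(densities))
            for d, ds in zip(densities, dseeds):
                g = threshold_proportional(matrices[(sid, cond)], d)
                res = best_partition(g, n_restarts, seed=ds)
                rows.append({"subject": sid, "condition": cond, "density": d,
                             "q": res.q_max})
                if d == density:
                    subject_parts[(sid, cond)] = res.best_partition
        q_table = pd.DataFrame(rows)
        qc = q_contrast(q_table, PRE_RS, REST_CTRL, n_perm=q_perms, seed=child + 1)
        j = int(np.argmin(np.abs(qc.densities - density)))
        q_rej += qc.p[j] <= alpha
        fwer_rej += (qc.p_fwer <= alpha).any()
        subjects = sorted({s for s, _ in subject_parts})
        vt = condition_vin_test([subject_parts[(s, PRE_RS)] for s in subjects],
                                [subject_parts[(s, REST_CTRL)] for s in subjects],
                                n_perm=vin_perms, seed=child + 2,
                                consensus_restarts=consensus_restarts)
        vin_rej += vt.p <= alpha
    return {"vin_reject_rate": vin_rej / n_replicates,
            "q_reject_rate": q_rej / n_replicates,
            "q_fwer_rate": fwer_rej / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


# ---------------------------------------------------------------------------
# prediction-framework calibration
# ---------------------------------------------------------------------------


def _prediction_cohort_config(seed, slope, n_subjects=66, n_nodes=60,
                              n_modules=5, T=270, target_module=1):
    conditions = (PRE_RS, POST_RS)
    parts = make_planted_partitions(n_nodes, conditions, n_modules=n_modules,
                                    seed=seed)
    effects = {}
    if slope:
        effects = {"youth_irritability": (target_module, POST_RS, slope)}
    return CohortConfig(n_subjects=n_subjects, n_nodes=n_nodes,
                        conditions=conditions, n_volumes_rest=T,
                        planted_partitions=parts, phenotype_effects=effects,
                        seed=seed)


def _efficiency_inputs(cfg, seed, density, n_restarts, consensus_restarts):
    series, phenotypes, _ = generate_cohort(cfg)
    parts, graphs = _subject_partitions(series, density, n_restarts, seed)
    subjects = sorted({s for s, _ in parts})
    cseeds = np.random.SeedSequence([seed, 0x9E1]).spawn(len(cfg.conditions))
    consensus = {}
    for cond, child in zip(cfg.conditions, cseeds):
        consensus[cond] = group_consensus([parts[(s, cond)] for s in subjects],
                                          seed=child,
                                          n_restarts=consensus_restarts).partition
    covars = phenotypes[["age", "sex", "medication_load", "scanner"]
                        + [f"mean_fd_{c}" for c in cfg.conditions]]
    table = build_efficiency_table(graphs, consensus, covars)
    return table, phenotypes, consensus


def _matched_column(consensus, cfg, condition, module) -> str:
    """Efficiency-table column of the consensus module best matching the
    planted module (maximum node overlap)."""
    planted = set(cfg.planted_partitions[condition].members(module).tolist())
    part = consensus[condition]
    best_m, best_ov = None, -1
    for m in part.large_modules():
        ov = len(planted & set(part.members(m).tolist()))
        if ov > best_ov:
            best_m, best_ov = m, ov
    return f"{condition}:M{best_m}"


def prediction_recovery_experiment(seed: int = 0, n_seeds: int = 50,
                                   slope: float = 0.6, density: float = 0.10,
                                   n_restarts: int = 15,
                                   consensus_restarts: int = 20,
                                   cv_repeats: int = 5, n_perm: int = 500) -> dict:
    """Does the framework find a planted module-efficiency effect?

    One post-task module's within-module connectivity is linked to one
    outcome with standardized slope ``slope`` in cohorts of 66 split 48/18.
    Reports how often the matching efficiency column is selected and the
    median held-out r across replicate cohorts.
    """
    rep_seeds = np.random.SeedSequence([seed, 0xA11]).spawn(n_seeds)
    selected = 0
    rs_list = []
    for child_ss in rep_seeds:
        child = int(child_ss.generate_state(1)[0] % (2 ** 31))
        cfg = _prediction_cohort_config(child, slope)
        table, phenotypes, consensus = _efficiency_inputs(
            cfg, child, density, n_restarts, consensus_restarts)
        target = _matched_column(consensus, cfg, POST_RS, 1)
        res = run_prediction(table, phenotypes, "youth_irritability",
                             train_n=48, test_n=18, repeats=cv_repeats,
                             n_perm=n_perm, seed=child)
        if target in res.predictors:
            selected += 1
        if not res.failed:
            rs_list.append(res.r)
    return {"selection_rate": selected / n_seeds,
            "median_heldout_r": float(np.median(rs_list)) if rs_list else np.nan,
            "n_seeds": n_seeds, "slope": slope}


def null_prediction_experiment(seed: int = 0, n_cohorts: int = 40,
                               density: float = 0.10, n_restarts: int = 15,
                               consensus_restarts: int = 20,
                               cv_repeats: int = 3, n_perm: int = 300,
                               alpha: float = 0.05,
                               with_leaky_control: bool = True) -> dict:
    """Error control of the full family under a null cohort (zero slopes).

    Reports the familywise rejection rate after BH-FDR across the 5 primary
    outcomes, the mean held-out r of honest models (should be ~0), and the
    mean held-out r of the deliberately leaky variant (selection on the full
    sample), which demonstrates the optimism leakage produces.
    """
    rep_seeds = np.random.SeedSequence([seed, 0xB22]).spawn(n_cohorts)
    family_rej = 0
    honest_r = []
    leaky_r = []
    for child_ss in rep_seeds:
        child = int(child_ss.generate_state(1)[0] % (2 ** 31))
        cfg = _prediction_cohort_config(child, slope=0.0)
        table, phenotypes, _ = _efficiency_inputs(
            cfg, child, density, n_restarts, consensus_restarts)
        results = run_prediction_family(table, phenotypes, PRIMARY_OUTCOMES,
                                        train_n=48, test_n=18,
                                        repeats=cv_repeats, n_perm=n_perm,
                                        seed=child)
        if any(r.q is not None and r.q <= alpha for r in results.values()):
            family_rej += 1
        honest_r.extend(r.r for r in results.values() if not r.failed)
        if with_leaky_control:
            leaky = run_prediction(table, phenotypes, "youth_irritability",
                                   train_n=48, test_n=18, repeats=cv_repeats,
                                   n_perm=n_perm, seed=child, leak_selection=True)
            if not leaky.failed:
                leaky_r.append(leaky.r)
    return {"family_reject_rate": family_rej / n_cohorts,
            "mean_null_heldout_r": float(np.mean(honest_r)) if honest_r else np.nan,
            "mean_leaky_heldout_r": float(np.mean(leaky_r)) if leaky_r else np.nan,
            "n_cohorts": n_cohorts, "alpha": alpha}


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def determinism_check(seed: int, out_dir) -> dict:
    """Run the demo pipeline twice with the same config; compare output hashes."""
    from pathlib import Path
    from .pipeline import demo_config, run_pipeline
    out = Path(out_dir)
    cfg1 = demo_config(seed)
    cfg2 = demo_config(seed)
    m1 = run_pipeline(cfg1, out / "run1")["manifest"]
    m2 = run_pipeline(cfg2, out / "run2")["manifest"]
    identical = m1["outputs"] == m2["outputs"] and m1["config_sha256"] == m2["config_sha256"]
    return {"identical": bool(identical), "n_outputs": len(m1["outputs"])}
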