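"""End-to-end orchestration: simulate -> connect -> modularity -> reconfig -> predict.

A run is driven by a :class:`RunConfig` (YAML-serialisable). Every stochastic
stage derives its randomness from the stage seeds recorded in the config, so
rerunning a config reproduces every output byte for byte. Two profiles are
provided: ``demo_config`` (desk-scale: reduced restart/permutation counts)
and ``paper_config`` (1,000 restarts / 5,000 permutations, the protocol the
statistics are defined with).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import cohort_connectivity, threshold_proportional, DEFAULT_DENSITIES
from .efficiency import build_efficiency_table, run_prediction_family
from .io import save_cohort, save_connectivity, save_partition_table, _config_dict, cohort_config_from_dict
from .modularity import best_partition, consensus_partition, group_probability_matrix
from .reconfiguration import (condition_vin_test, module_vin_test, q_contrast,
                              variation_of_information)
from .synthetic import (CohortConfig, PRIMARY_OUTCOMES, NULL_OUTCOMES,
                        generate_cohort)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all seeds explicit)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    densities: tuple = DEFAULT_DENSITIES
    analysis_density: float = 0.10
    lag_volumes: int = 2
    n_restarts: int = 1000
    consensus_restarts: int = 100
    tau: float = 0.4
    vin_perms: int = 5000
    q_perms: int = 5000
    predict_perms: int = 5000
    cv_folds: int = 10
    cv_repeats: int = 20
    train_n: int | None = None
    test_n: int | None = None
    vin_test_pairs: tuple | None = None   # default: every condition vs the first
    #: how the group probability matrix is built per condition/density:
    #: "best" = co-assignment of subjects' best-Q partitions (default),
    #: "agreement" = mean of subjects' restart agreement matrices
    group_source: str = "best"
    seed_modularity: int | None = None
    seed_reconfig: int | None = None
    seed_predict: int | None = None

    def __post_init__(self):
        self.densities = tuple(self.densities)
        if self.analysis_density not in self.densities:
            self.densities = tuple(sorted(set(self.densities) | {self.analysis_density}))
        if self.train_n is None or self.test_n is None:
            n = self.cohort.n_subjects
            self.train_n = int(round(n * 48 / 66))
            self.test_n = n - self.train_n
        for name in ("seed_modularity", "seed_reconfig", "seed_predict"):
            if getattr(self, name) is None:
                raise ValueError(f"RunConfig requires an explicit {name}")
        if self.group_source not in ("best", "agreement"):
            raise ValueError("group_source must be 'best' or 'agreement'")
        if self.vin_test_pairs is None:
            ref = self.cohort.conditions[0]
            self.vin_test_pairs = tuple((ref, c) for c in self.cohort.conditions[1:])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = _config_dict(self.cohort)
        d["densities"] = list(self.densities)
        d["vin_test_pairs"] = [list(p) for p in self.vin_test_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = cohort_config_from_dict(d["cohort"])
        if d.get("vin_test_pairs"):
            d["vin_test_pairs"] = tuple(tuple(p) for p in d["vin_test_pairs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def demo_config(seed: int = 0, **cohort_kwargs) -> RunConfig:
    """Desk-scale profile: small cohort, reduced restart/permutation counts."""
    kw = dict(n_subjects=12, n_nodes=40, n_volumes_rest=200, n_trials=30,
              n_runs=1, seed=seed)
    kw.update(cohort_kwargs)
    return RunConfig(cohort=CohortConfig(**kw), n_restarts=50,
                     consensus_restarts=20, vin_perms=200, q_perms=500,
                     predict_perms=500, cv_repeats=5,
                     seed_modularity=seed + 1, seed_reconfig=seed + 2,
                     seed_predict=seed + 3)


def paper_config(seed: int = 0, **cohort_kwargs) -> RunConfig:
    """Published protocol: 1,000 Louvain restarts, 5,000 permutations."""
    return RunConfig(cohort=CohortConfig(seed=seed, **cohort_kwargs),
                     seed_modularity=seed + 1, seed_reconfig=seed + 2,
                     seed_predict=seed + 3)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_modularity(matrices: dict, config: RunConfig):
    """Subject-level Louvain consensus and group structure, per density.

    Returns (q_table, subject_best, subject_consensus, group_partitions):
    ``q_table`` tidy with subject/condition/density/q; ``subject_best`` maps
    (subject, condition, density) -> best-Q Partition; ``subject_consensus``
    the consensus over each subject's restarts at the analysis density (used
    for paired per-module tests); ``group_partitions`` maps
    (condition, density) -> group ConsensusResult.
    """
    ss = np.random.SeedSequence([config.seed_modularity, 0x3C1])
    rows = []
    subject_best = {}
    subject_consensus = {}
    agreement_sum: dict = {}
    keys = sorted(matrices)
    seeds = ss.spawn(len(keys))
    for (sid, cond), child in zip(keys, seeds):
        cm = matrices[(sid, cond)]
        dseeds = child.spawn(len(config.densities) + 1)
        for density, ds in zip(config.densities, dseeds):
            graph = threshold_proportional(cm, density)
            res = best_partition(graph, config.n_restarts, seed=ds, density=density)
            rows.append({"subject": sid, "condition": cond, "density": density,
                         "q": res.q_max})
            subject_best[(sid, cond, density)] = res.best_partition
            if config.group_source == "agreement":
                key = (cond, density)
                if key in agreement_sum:
                    agreement_sum[key] += res.agreement.values
                else:
                    agreement_sum[key] = res.agreement.values.copy()
            if density == config.analysis_density:
                cons = consensus_partition(res.agreement, seed=dseeds[-1],
                                           tau=config.tau,
                                           n_restarts=config.consensus_restarts)
                subject_consensus[(sid, cond)] = cons.partition
    q_table = pd.DataFrame(rows)

    conditions = sorted({c for _, c in keys})
    subjects = sorted({s for s, _ in keys})
    group_partitions = {}
    gseeds = np.random.SeedSequence([config.seed_modularity, 0x3C2]).spawn(
        len(conditions) * len(config.densities))
    i = 0
    for cond in conditions:
        for density in config.densities:
            if config.group_source == "agreement":
                agreement = agreement_sum[(cond, density)] / len(subjects)
                np.fill_diagonal(agreement, 1.0)
            else:
                parts = [subject_best[(sid, cond, density)] for sid in subjects]
                agreement = group_probability_matrix(parts)
            group_partitions[(cond, density)] = consensus_partition(
                agreement, seed=gseeds[i], tau=config.tau,
                n_restarts=config.consensus_restarts)
            i += 1
    return q_table, subject_best, subject_consensus, group_partitions


def stage_reconfiguration(q_table, subject_best, subject_consensus,
                          group_partitions, config: RunConfig):
    """Q contrasts, the VIn table, condition VIn tests and per-module tests."""
    conditions = list(config.cohort.conditions)
    subjects = sorted({s for s, _, _ in subject_best})
    ss = np.random.SeedSequence([config.seed_reconfig, 0x7D2])

    contrasts = []
    pair_seeds = ss.spawn(len(config.vin_test_pairs) * 2 + 1)
    for i, (ca, cb) in enumerate(config.vin_test_pairs):
        qc = q_contrast(q_table, ca, cb, n_perm=config.q_perms,
                        seed=pair_seeds[2 * i])
        contrasts.append(qc.to_frame())
    q_contrasts = pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()

    # descriptive VIn between group consensus partitions, all pairs x densities
    vin_rows = []
    for i, ca in enumerate(conditions):
        for cb in conditions[i + 1:]:
            for density in config.densities:
                vin_rows.append({
                    "condition_a": ca, "condition_b": cb, "density": density,
                    "vin": variation_of_information(
                        group_partitions[(ca, density)].partition,
                        group_partitions[(cb, density)].partition)})
    vin_table = pd.DataFrame(vin_rows)

    vin_tests = []
    for i, (ca, cb) in enumerate(config.vin_test_pairs):
        parts_a = [subject_best[(s, ca, config.analysis_density)] for s in subjects]
        parts_b = [subject_best[(s, cb, config.analysis_density)] for s in subjects]
        res = condition_vin_test(parts_a, parts_b, ca, cb,
                                 density=config.analysis_density,
                                 n_perm=config.vin_perms,
                                 seed=pair_seeds[2 * i + 1], tau=config.tau,
                                 consensus_restarts=max(10, config.consensus_restarts // 5))
        vin_tests.append({"condition_a": ca, "condition_b": cb,
                          "density": res.density, "vin": res.vin, "p_perm": res.p})
    vin_tests = pd.DataFrame(vin_tests)

    reference = group_partitions[(conditions[0], config.analysis_density)].partition
    module_rows = []
    mseeds = pair_seeds[-1].spawn(len(config.vin_test_pairs))
    for (ca, cb), ms in zip(config.vin_test_pairs, mseeds):
        parts_a = [subject_consensus[(s, ca)] for s in subjects]
        parts_b = [subject_consensus[(s, cb)] for s in subjects]
        results, _pairwise = module_vin_test(reference, parts_a, parts_b, ca, cb,
                                             n_perm=config.vin_perms, seed=ms)
        for r in results:
            module_rows.append({"condition_a": ca, "condition_b": cb,
                                "module": r.module_id, "mean_vin": r.mean_vin})
    module_vin_table = pd.DataFrame(module_rows)
    return q_contrasts, vin_table, vin_tests, module_vin_table


def module_flow_table(group_partitions, conditions, density) -> pd.DataFrame:
    """Node counts flowing between modules of consecutive conditions (a plain
    text substitute for an alluvial diagram)."""
    rows = []
    for ca, cb in zip(conditions[:-1], conditions[1:]):
        pa = group_partitions[(ca, density)].partition
        pb = group_partitions[(cb, density)].partition
        for ma in sorted(pa.module_sizes):
            for mb in sorted(pb.module_sizes):
                n = int(np.sum((pa.labels == ma) & (pb.labels == mb)))
                if n:
                    rows.append({"from_condition": ca, "from_module": ma,
                                 "to_condition": cb, "to_module": mb, "n_nodes": n})
    return pd.DataFrame(rows)


def stage_prediction(matrices, group_partitions, phenotypes, config: RunConfig):
    """Efficiency table at the analysis density and the outcome model family."""
    density = config.analysis_density
    graphs = {key: threshold_proportional(cm, density) for key, cm in matrices.items()}
    consensus = {cond: group_partitions[(cond, density)].partition
                 for cond in config.cohort.conditions}
    covar_cols = (["age", "sex", "medication_load", "scanner"] +
                  [f"mean_fd_{c}" for c in config.cohort.conditions])
    table = build_efficiency_table(graphs, consensus, phenotypes[covar_cols])
    results = run_prediction_family(
        table, phenotypes,
        primary_outcomes=[o for o in PRIMARY_OUTCOMES if o in phenotypes],
        null_outcomes=[o for o in NULL_OUTCOMES if o in phenotypes],
        train_n=config.train_n, test_n=config.test_n, k=config.cv_folds,
        repeats=config.cv_repeats, n_perm=config.predict_perms,
        seed=config.seed_predict)
    pred_table = pd.DataFrame([r.to_dict() for r in results.values()])
    return table, pred_table, results


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage, writing per-stage artifacts and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    with open(out / "config.yaml", "w") as f:
        yaml.safe_dump(config.to_dict(), f)

    logger.info("stage simulate")
    series, phenotypes, ground_truth = generate_cohort(config.cohort)
    save_cohort(out / "cohort.h5", series, phenotypes, ground_truth, config.cohort)
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    with open(out / "ground_truth.json", "w") as f:
        json.dump(ground_truth, f)

    logger.info("stage connect")
    matrices = cohort_connectivity(series, config.lag_volumes)
    save_connectivity(out / "connectivity.h5", matrices)

    logger.info("stage modularity")
    q_table, subject_best, subject_consensus, group_partitions = stage_modularity(
        matrices, config)
    q_table.to_csv(out / "q_table.csv", index=False)
    save_partition_table(out / "group_consensus.csv", [
        {"condition": cond, "density": density,
         "converged": group_partitions[(cond, density)].converged,
         "labels": group_partitions[(cond, density)].partition.labels}
        for (cond, density) in sorted(group_partitions)])
    save_partition_table(out / "subject_partitions.csv", [
        {"subject": s, "condition": c, "kind": "consensus",
         "labels": p.labels} for (s, c), p in sorted(subject_consensus.items())])

    logger.info("stage reconfig")
    q_contrasts, vin_table, vin_tests, module_vin_table = stage_reconfiguration(
        q_table, subject_best, subject_consensus, group_partitions, config)
    q_contrasts.to_csv(out / "q_contrasts.csv", index=False)
    vin_table.to_csv(out / "vin_table.csv", index=False)
    vin_tests.to_csv(out / "vin_tests.csv", index=False)
    module_vin_table.to_csv(out / "module_vin.csv", index=False)
    module_flow_table(group_partitions, list(config.cohort.conditions),
                      config.analysis_density).to_csv(out / "module_flow.csv", index=False)

    logger.info("stage predict")
    eff_table, pred_table, _results = stage_prediction(
        matrices, group_partitions, phenotypes, config)
    eff_table.to_csv(out / "efficiency.tsv", sep="\t")
    pred_table.to_csv(out / "predictions.csv", index=False)

    manifest = {
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict()).encode()).hexdigest(),
        "seeds": {"cohort": config.cohort.seed,
                  "modularity": config.seed_modularity,
                  "reconfig": config.seed_reconfig,
                  "predict": config.seed_predict},
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return {"q_table": q_table, "q_contrasts": q_contrasts, "vin_table": vin_table,
            "vin_tests": vin_tests, "module_vin": module_vin_table,
            "efficiency": eff_table, "predictions": pred_table,
            "manifest": manifest}
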