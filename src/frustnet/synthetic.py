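"""Synthetic cohort generator with planted modular ground truth.

Emulates the data layout of a frustration-induction fMRI study — two resting
scans flanking a rigged attention-orienting task — at the level the analysis
consumes: per subject and condition a node x time residual-like series, a
confound matrix, a trial-event table, and a phenotype table. Nothing at the
voxel/image level is simulated.

The generative model is deliberately the simplest one whose downstream
behaviour is analytically predictable:

* each condition has a planted partition of the nodes; the series for that
  condition is drawn from a block correlation matrix (compound symmetry
  within modules, constant correlation between, unit diagonal);
* per-subject jitter on the within-module correlation of each (module,
  condition) block is the latent variable that drives module connectivity —
  and therefore module global efficiency — up or down for that subject;
* phenotypes are linear in that latent jitter (standardized slope) plus unit
  Gaussian noise, so a phenotype can only be predicted from the series by
  actually running the connectivity -> modules -> efficiency pipeline;
* task series additionally carry hemodynamically convolved event coactivation
  and every series carries motion-like and drift confounds, which the
  connectivity builder is expected to regress away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .modularity import Partition

logger = logging.getLogger(__name__)

PRE_RS = "pre-RS"
POST_RS = "post-RS"
FNR = "FNR"
FNR1 = "FNR+1"
REWARD = "Reward"
REWARD1 = "Reward+1"
#: the six experimental conditions in paradigm order
DEFAULT_CONDITIONS = (PRE_RS, REWARD, REWARD1, FNR, FNR1, POST_RS)
TASK_CONDITIONS = (REWARD, REWARD1, FNR, FNR1)

PRIMARY_OUTCOMES = ("youth_irritability", "parent_irritability",
                    "frustration_change", "rt_difference", "accuracy")
NULL_OUTCOMES = ("anxiety", "inattention", "hyperactivity")


# ---------------------------------------------------------------------------
# trial timing and event schedules
# ---------------------------------------------------------------------------

#: per-trial phase durations in seconds (cue, target, anticipation, feedback,
#: inter-trial interval); total 8 s per trial
DEFAULT_TIMING = {"cue": 0.5, "target": 0.5, "anticipation": 2.0,
                  "feedback": 1.0, "iti": 4.0}


def generate_event_schedule(n_trials: int, rigged_fraction: float = 0.6,
                            seed=0, timing: dict | None = None) -> pd.DataFrame:
    """Trial-event table for one frustration-task run.

    Each trial contributes cue, target, anticipation and feedback rows
    (onset/duration in seconds). Feedback is labelled ``FNR`` (rigged loss)
    with probability ``rigged_fraction`` — the rigged task deducts the reward
    after 60% of correct responses by default — else ``Reward``. The
    anticipation phase of trial N+1 inherits ``FNR+1`` / ``Reward+1`` from
    trial N's feedback; trial 1's anticipation is unlabelled.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials to define N+1 events")
    if not 0.0 <= rigged_fraction <= 1.0:
        raise ValueError("rigged_fraction must be in [0, 1]")
    timing = dict(DEFAULT_TIMING, **(timing or {}))
    rng = np.random.default_rng(seed)
    rigged = rng.random(n_trials) < rigged_fraction
    trial_len = sum(timing.values())
    rows = []
    for t in range(n_trials):
        t0 = t * trial_len
        feedback = FNR if rigged[t] else REWARD
        if t == 0:
            antic = "none"
        else:
            antic = FNR1 if rigged[t - 1] else REWARD1
        rows.append((t, t0, timing["cue"], "cue", "none"))
        rows.append((t, t0 + timing["cue"], timing["target"], "target", "none"))
        rows.append((t, t0 + timing["cue"] + timing["target"],
                     timing["anticipation"], "anticipation", antic))
        rows.append((t, t0 + timing["cue"] + timing["target"] + timing["anticipation"],
                     timing["feedback"], "feedback", feedback))
    return pd.DataFrame(rows, columns=["trial", "onset", "duration", "phase",
                                       "event_type"])


def hrf_regressor(events: pd.DataFrame, n_volumes: int,
                  repetition_time: float, oversample: int = 16) -> np.ndarray:
    """Canonical double-gamma haemodynamic regressor for an event set.

    A boxcar built from (onset, duration) rows is convolved with the
    canonical response (gamma peak at 6 s minus a 1/6-weighted undershoot
    peaking at 16 s) on a fine grid and sampled at volume acquisition times.
    An empty event set yields the zero vector.
    """
    if len(events) == 0:
        return np.zeros(n_volumes)
    onsets = np.asarray(events["onset"], float)
    durations = np.asarray(events["duration"], float)
    run_len = n_volumes * repetition_time
    if (onsets >= run_len).any():
        raise ValueError("event onset beyond the end of the run")
    dt = repetition_time / oversample
    n_fine = int(np.ceil(run_len / dt)) + 1
    box = np.zeros(n_fine)
    for on, du in zip(onsets, durations):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + du) / dt)))
        box[i0:min(i1, n_fine)] += 1.0
    t = np.arange(0, 32.0, dt)
    kernel = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    kernel /= kernel.max()
    conv = np.convolve(box, kernel)[:n_fine] * dt
    vol_idx = np.round(np.arange(n_volumes) * repetition_time / dt).astype(int)
    return conv[vol_idx]


# ---------------------------------------------------------------------------
# planted partitions and block covariance
# ---------------------------------------------------------------------------


def make_planted_partitions(n_nodes: int, conditions=DEFAULT_CONDITIONS,
                            n_modules: int | None = None,
                            reassign_fractions: dict | None = None,
                            seed: int = 0) -> dict[str, Partition]:
    """Per-condition planted partitions with condition-specific reconfiguration.

    A baseline partition into near-equal contiguous modules defines the
    pre-task resting state. Each other condition reassigns a stated fraction
    of nodes to different modules (drawn deterministically from ``seed``).
    Defaults mirror the qualitative pattern of the frustration paradigm: no
    change during the frustrating feedback itself, progressively larger
    recomposition in the anticipation phases, and a persistent change in the
    post-task resting state.
    """
    if n_modules is None:
        n_modules = 7 if n_nodes >= 84 else max(2, n_nodes // 12)
    base = np.array_split(np.arange(n_nodes), n_modules)
    labels0 = np.empty(n_nodes, dtype=np.int64)
    for m, idx in enumerate(base, start=1):
        labels0[idx] = m
    fractions = {PRE_RS: 0.0, FNR: 0.0, REWARD: 0.10, FNR1: 0.15,
                 REWARD1: 0.25, POST_RS: 0.20}
    fractions.update(reassign_fractions or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9DA2]))
    out = {}
    for cond in conditions:
        frac = fractions.get(cond, 0.0)
        labels = labels0.copy()
        n_move = int(round(frac * n_nodes))
        if n_move:
            movers = rng.choice(n_nodes, size=n_move, replace=False)
            for node in movers:
                choices = [m for m in range(1, n_modules + 1) if m != labels0[node]]
                labels[node] = choices[rng.integers(len(choices))]
        out[cond] = Partition(labels)
    return out


def block_correlation(labels: np.ndarray, within, between: float) -> np.ndarray:
    """Compound-symmetry block correlation matrix.

    ``within`` may be a scalar or a per-module mapping. If the smallest
    eigenvalue is not positive the matrix is shrunk toward the identity until
    it is (a warning is logged); grossly inconsistent settings raise.
    """
    labels = np.asarray(labels)
    n = labels.size
    R = np.full((n, n), float(between))
    for m in np.unique(labels):
        idx = labels == m
        w = within[m] if isinstance(within, dict) else within
        if not 0.0 <= w < 1.0:
            raise ValueError(f"within-module correlation {w} outside [0, 1)")
        R[np.ix_(idx, idx)] = w
    np.fill_diagonal(R, 1.0)
    eigmin = np.linalg.eigvalsh(R)[0]
    if eigmin <= 1e-10:
        lam = min(0.98, (1.0 - 1e-6) / (1.0 - eigmin))
        if lam < 0.5:
            raise ValueError("block covariance is far from positive definite; "
                             "check within/between correlation settings")
        logger.warning("shrinking block covariance toward identity (lambda=%.3f)", lam)
        R = lam * R + (1 - lam) * np.eye(n)
    return R


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------


def _default_effects(conditions) -> dict[str, tuple[int, str, float]]:
    """Default phenotype links: outcome -> (module, condition, standardized
    slope). Magnitudes follow the scale of standardized coefficients reported
    for post-task module efficiency in irritability work (|beta| ~ 0.25-0.4);
    null outcomes carry no link."""
    wanted = {
        "youth_irritability": (1, POST_RS, -0.25),
        "parent_irritability": (2, POST_RS, 0.40),
        "frustration_change": (1, POST_RS, 0.25),
        "rt_difference": (2, FNR1, 0.40),
        "accuracy": (3, FNR1, -0.30),
    }
    return {k: v for k, v in wanted.items() if v[1] in conditions}


@dataclass
class CohortConfig:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_subjects: int = 66
    n_nodes: int = 116
    conditions: tuple = DEFAULT_CONDITIONS
    n_volumes_rest: int = 270          # 9 min at TR = 2 s
    n_trials: int = 50
    n_runs: int = 2
    repetition_time: float = 2.0
    rigged_fraction: float = 0.6
    planted_partitions: dict | None = None
    within_module_corr: float = 0.6
    between_module_corr: float = 0.05
    corr_jitter_sd: float = 0.08
    noise_sd: float = 1.0              # overall series scale; correlations unaffected
    coactivation_amplitude: float = 1.0
    confound_loading_sd: float = 0.3
    timing: dict = field(default_factory=lambda: dict(DEFAULT_TIMING))
    phenotype_effects: dict | None = None
    seed: int = 0

    def __post_init__(self):
        self.conditions = tuple(self.conditions)
        if self.planted_partitions is None:
            self.planted_partitions = make_planted_partitions(
                self.n_nodes, self.conditions, seed=self.seed)
        if self.phenotype_effects is None:
            self.phenotype_effects = _default_effects(self.conditions)
        self.validate()

    def validate(self):
        if not 0.0 <= self.between_module_corr < self.within_module_corr < 1.0:
            raise ValueError("require within_module_corr > between_module_corr >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if set(self.planted_partitions) != set(self.conditions):
            raise ValueError("planted_partitions must cover exactly the conditions")
        for cond, part in self.planted_partitions.items():
            if part.n_nodes != self.n_nodes:
                raise ValueError(f"planted partition for {cond} does not cover "
                                 f"all {self.n_nodes} nodes")
        for outcome, (module, cond, _slope) in self.phenotype_effects.items():
            if cond not in self.planted_partitions:
                raise ValueError(f"effect for {outcome} references unknown condition {cond}")
            if module not in self.planted_partitions[cond].module_sizes:
                raise ValueError(f"effect for {outcome} references module {module} "
                                 f"absent from condition {cond}")

    @property
    def n_trials_total(self) -> int:
        return self.n_trials * self.n_runs

    @property
    def n_volumes_task(self) -> int:
        trial_len = sum(self.timing.values())
        return int(np.ceil(self.n_trials_total * trial_len / self.repetition_time))


@dataclass
class SubjectConditionSeries:
    """One subject's node x time series for one condition, with nuisance
    context: confound regressors (regressor x time), the trial-event table for
    task conditions, and the repetition time."""

    subject_id: str
    condition: str
    data: np.ndarray
    confounds: np.ndarray
    repetition_time: float
    events: pd.DataFrame | None = None

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be node x time")
        if self.confounds is not None and self.confounds.shape[1] != self.data.shape[1]:
            raise ValueError("confounds and data disagree on time dimension")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _motion_confounds(rng, n_volumes: int, n_motion: int = 6):
    """AR(1) motion-like series with occasional spikes, plus a linear drift."""
    innov = rng.standard_normal((n_motion, n_volumes)) * 0.3
    spikes = (rng.random((n_motion, n_volumes)) < 0.02) * rng.standard_normal(
        (n_motion, n_volumes)) * 1.5
    motion = np.empty((n_motion, n_volumes))
    motion[:, 0] = innov[:, 0]
    for t in range(1, n_volumes):
        motion[:, t] = 0.9 * motion[:, t - 1] + innov[:, t] + spikes[:, t]
    drift = np.linspace(-1.0, 1.0, n_volumes)[None, :]
    conf = np.vstack([motion, drift])
    fd = float(np.abs(np.diff(motion, axis=1)).sum(axis=0).mean()) * 0.1
    return conf, fd


def generate_cohort(config: CohortConfig):
    """Generate the cohort: series list, phenotype table, ground-truth record.

    All randomness descends from ``config.seed`` through a seed tree, so two
    calls with the same config are bit-identical. The ground-truth record
    holds the planted partitions, the per-(subject, condition, module)
    within-correlation jitter (the latent phenotype driver), and the effects.
    """
    cfg = config
    root = np.random.SeedSequence([cfg.seed, 0xF4C7])
    ss_subjects, ss_pheno = root.spawn(2)
    sub_seeds = ss_subjects.spawn(cfg.n_subjects)

    module_ids = {c: sorted(cfg.planted_partitions[c].module_sizes)
                  for c in cfg.conditions}
    deltas = {c: np.zeros((cfg.n_subjects, len(module_ids[c]))) for c in cfg.conditions}

    series: list[SubjectConditionSeries] = []
    fd_records: dict[str, dict[str, float]] = {}
    for s, sseed in enumerate(sub_seeds):
        sid = f"sub-{s + 1:03d}"
        ss_sched, ss_cond = sseed.spawn(2)
        schedule = generate_event_schedule(cfg.n_trials_total, cfg.rigged_fraction,
                                           seed=ss_sched, timing=cfg.timing)
        cond_seeds = ss_cond.spawn(len(cfg.conditions))
        fd_records[sid] = {}
        for cond, cs in zip(cfg.conditions, cond_seeds):
            rng = np.random.default_rng(cs)
            part = cfg.planted_partitions[cond]
            is_task = cond in TASK_CONDITIONS
            n_vol = cfg.n_volumes_task if is_task else cfg.n_volumes_rest
            jit = rng.normal(0.0, cfg.corr_jitter_sd, size=len(module_ids[cond]))
            deltas[cond][s] = jit
            lo = cfg.between_module_corr + 0.05
            within = {m: float(np.clip(cfg.within_module_corr + j, lo, 0.95))
                      for m, j in zip(module_ids[cond], jit)}
            R = block_correlation(part.labels, within, cfg.between_module_corr)
            L = np.linalg.cholesky(R)
            X = (L @ rng.standard_normal((cfg.n_nodes, n_vol))) * cfg.noise_sd
            conf, fd = _motion_confounds(rng, n_vol)
            loadings = rng.normal(0.0, cfg.confound_loading_sd,
                                  size=(cfg.n_nodes, conf.shape[0]))
            X = X + loadings @ conf
            events = None
            if is_task:
                events = schedule
                for etype in TASK_CONDITIONS:
                    ev = schedule[schedule["event_type"] == etype]
                    reg = hrf_regressor(ev, n_vol, cfg.repetition_time)
                    gains = rng.normal(1.0, 0.3, size=cfg.n_nodes)
                    X = X + cfg.coactivation_amplitude * np.outer(gains, reg)
            fd_records[sid][cond] = fd
            series.append(SubjectConditionSeries(sid, cond, X, conf,
                                                 cfg.repetition_time, events))

    phenotypes = _generate_phenotypes(cfg, ss_pheno, deltas, module_ids, fd_records)
    ground_truth = {
        "planted_partitions": {c: cfg.planted_partitions[c].labels.tolist()
                               for c in cfg.conditions},
        "module_ids": module_ids,
        "deltas": {c: deltas[c].tolist() for c in cfg.conditions},
        "phenotype_effects": dict(cfg.phenotype_effects),
        "seed": cfg.seed,
    }
    return series, phenotypes, ground_truth


def _generate_phenotypes(cfg: CohortConfig, ss, deltas, module_ids, fd_records):
    rng = np.random.default_rng(ss)
    n = cfg.n_subjects
    sids = [f"sub-{s + 1:03d}" for s in range(n)]
    cols: dict[str, np.ndarray] = {}
    for outcome in PRIMARY_OUTCOMES + NULL_OUTCOMES:
        noise = rng.standard_normal(n)
        effect = cfg.phenotype_effects.get(outcome)
        if effect is not None:
            module, cond, slope = effect
            j = module_ids[cond].index(module)
            z = deltas[cond][:, j] / cfg.corr_jitter_sd
            cols[outcome] = slope * z + noise
        else:
            cols[outcome] = noise
    cols["age"] = np.clip(rng.normal(14.0, 2.8, size=n), 9.0, 21.0)
    cols["sex"] = rng.integers(0, 2, size=n).astype(float)
    cols["medication_load"] = np.abs(rng.normal(0.0, 1.0, size=n))
    cols["scanner"] = rng.integers(0, 2, size=n).astype(float)
    df = pd.DataFrame(cols, index=pd.Index(sids, name="subject"))
    for cond in cfg.conditions:
        df[f"mean_fd_{cond}"] = [fd_records[sid][cond] for sid in sids]
    assert not df.isna().any().any()
    return df
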