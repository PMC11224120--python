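"""Reconfiguration statistics: Q contrasts, variation of information, inference.

Two complementary questions are answered for every pair of experimental
conditions (e.g. pre-task rest vs the anticipation phase after a frustrating
feedback):

* did overall segregation change? — paired t tests on the subjects' maximal
  modularity Q per density, with sign-flip permutation null and max-|t|
  familywise correction across the density ladder;
* did modular *composition* change? — normalized variation of information
  (VIn) between the two group consensus partitions, with a repeated-measures
  permutation null obtained by swapping each subject's pair of condition
  labels and rebuilding both consensus partitions.

Per-module VIn (on the sub-partition induced by a reference module's members)
localises which modules drive an overall reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modularity import Partition, canonical_labels, _consensus_labels

MODULE_MIN_SIZE = 4  # modules smaller than this are not reported per-module


# ---------------------------------------------------------------------------
# variation of information
# ---------------------------------------------------------------------------


def variation_of_information(p1, p2, normalized: bool = True) -> float:
    """Variation of information between two partitions of the same node set.

    ``VI = H(X|Y) + H(Y|X)`` with natural logarithms, computed from the joint
    contingency table; the normalized form divides by ``log(n)`` so the value
    lies in [0, 1], 0 iff the partitions agree up to relabeling and 1 for the
    one-module vs all-singletons extreme.
    """
    l1 = p1.labels if isinstance(p1, Partition) else canonical_labels(p1)
    l2 = p2.labels if isinstance(p2, Partition) else canonical_labels(p2)
    if l1.size != l2.size:
        raise ValueError("partitions must cover the same node set")
    n = l1.size
    if n < 2:
        raise ValueError("variation of information needs at least 2 nodes")
    k1, k2 = l1.max(), l2.max()
    joint = np.zeros((k1, k2))
    np.add.at(joint, (l1 - 1, l2 - 1), 1.0)
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    h_joint = -np.sum(pij[nz] * np.log(pij[nz]))
    h1 = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h2 = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    vi = max(0.0, 2.0 * h_joint - h1 - h2)
    if normalized:
        vi /= np.log(n)
    return float(vi)


def module_vin(reference: Partition, p1, p2, module_id: int) -> float:
    """Normalized VIn restricted to one reference module's members.

    The reference partition (conventionally the pre-task resting-state group
    consensus) defines the node subset; the induced sub-partitions of ``p1``
    and ``p2`` on that subset are compared, with normalization by the log of
    the subset size. Modules below ``MODULE_MIN_SIZE`` nodes are refused.
    """
    members = reference.members(module_id)
    if members.size < MODULE_MIN_SIZE:
        raise ValueError(
            f"module {module_id} has {members.size} nodes (< {MODULE_MIN_SIZE})")
    l1 = (p1.labels if isinstance(p1, Partition) else canonical_labels(p1))[members]
    l2 = (p2.labels if isinstance(p2, Partition) else canonical_labels(p2))[members]
    return variation_of_information(l1, l2, normalized=True)


# ---------------------------------------------------------------------------
# paired permutation machinery
# ---------------------------------------------------------------------------


def hedges_g_paired(diff: np.ndarray) -> float:
    """Paired-sample Hedges g: mean(diff)/sd(diff) with small-sample correction
    ``1 - 3/(4*df - 1)``, df = n - 1."""
    diff = np.asarray(diff, float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd <= 1e-12 * max(1.0, abs(diff.mean())):
        # zero-variance differences: g = 0 for an exact null, undefined otherwise
        return 0.0 if abs(diff.mean()) <= 1e-12 else np.nan
    df = n - 1
    return float(diff.mean() / sd * (1.0 - 3.0 / (4.0 * df - 1.0)))


def _paired_t(diff: np.ndarray, axis: int = -1) -> np.ndarray:
    n = diff.shape[axis]
    m = diff.mean(axis=axis)
    sd = diff.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (sd / np.sqrt(n))


@dataclass
class QContrast:
    """Per-density paired contrast of maximal modularity between conditions."""

    condition_a: str
    condition_b: str
    densities: np.ndarray
    t: np.ndarray
    p: np.ndarray            # per-density permutation p (two-sided)
    p_fwer: np.ndarray       # max-|t| corrected across densities
    hedges_g: np.ndarray
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition_a": self.condition_a, "condition_b": self.condition_b,
            "density": self.densities, "t": self.t, "p_perm": self.p,
            "p_fwer": self.p_fwer, "hedges_g": self.hedges_g,
            "n": self.n_subjects,
        })


def q_contrast(q_table: pd.DataFrame, cond_a: str, cond_b: str,
               n_perm: int = 5000, seed=0) -> QContrast:
    """Paired t tests on subjects' Q between two conditions, per density.

    ``q_table`` is tidy with columns ``subject``, ``condition``, ``density``,
    ``q``. The null is built by random sign flips of the paired differences
    (subjects exchangeable within pair); familywise correction across the
    density ladder uses the permutation distribution of the maximum |t|.
    The contrast direction is ``cond_a - cond_b``; Hedges g carries its sign.
    """
    wide = q_table.pivot_table(index="subject", columns=["condition", "density"],
                               values="q")
    densities = np.array(sorted({d for (_, d) in wide.columns}))
    qa = wide[cond_a].loc[:, densities].to_numpy()
    qb = wide[cond_b].loc[:, densities].to_numpy()
    if np.isnan(qa).any() or np.isnan(qb).any():
        raise ValueError("incomplete subject x condition x density table")
    diff = qa - qb  # subjects x densities
    n = diff.shape[0]
    t_obs = _paired_t(diff, axis=0)
    g = np.array([hedges_g_paired(diff[:, j]) for j in range(diff.shape[1])])

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # t for every permutation and density in one einsum pass
    perm_mean = signs @ diff / n                                  # perm x dens
    perm_sq = (signs ** 2) @ (diff ** 2) / n                      # constant, but explicit
    perm_sd = np.sqrt((perm_sq - perm_mean ** 2) * n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = perm_mean / (perm_sd / np.sqrt(n))
    t_perm = np.nan_to_num(t_perm)

    abs_obs = np.abs(t_obs)
    p = (1.0 + (np.abs(t_perm) >= abs_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0)
    max_perm = np.abs(t_perm).max(axis=1)
    p_fwer = (1.0 + (max_perm[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0)
    p_fwer = np.maximum(p, p_fwer)

    zero_var = diff.std(axis=0, ddof=1) == 0
    t_obs = np.where(zero_var & (diff.mean(axis=0) == 0), 0.0, t_obs)
    p[zero_var] = 1.0
    p_fwer[zero_var] = 1.0
    return QContrast(cond_a, cond_b, densities, t_obs, p, p_fwer, g, n)


# ---------------------------------------------------------------------------
# condition-level VIn test
# ---------------------------------------------------------------------------


@dataclass
class VInResult:
    condition_a: str
    condition_b: str
    density: float
    vin: float
    p: float
    n_perm: int
    n_subjects: int


def condition_vin_test(partitions_a, partitions_b, cond_a: str = "A",
                       cond_b: str = "B", density: float = np.nan,
                       n_perm: int = 5000, seed=0, tau: float = 0.4,
                       consensus_restarts: int = 20, max_iter: int = 20) -> VInResult:
    """Repeated-measures permutation test for a change in modular composition.

    The observed statistic is the VIn between the group consensus partitions
    of the two conditions. Under the null the two condition labels are
    exchangeable within each subject, so each permutation randomly swaps the
    subject's pair of partitions, rebuilds both group probability matrices
    and consensus partitions, and recomputes VIn;
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    parts_a = [p if isinstance(p, Partition) else Partition(p) for p in partitions_a]
    parts_b = [p if isinstance(p, Partition) else Partition(p) for p in partitions_b]
    if len(parts_a) != len(parts_b):
        raise ValueError("conditions must cover the same subjects")
    n_sub = len(parts_a)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_obs, ss_perm, ss_flip = ss.spawn(3)

    la = np.stack([p.labels for p in parts_a])  # subjects x nodes
    lb = np.stack([p.labels for p in parts_b])

    def _vin_between(mat_a, mat_b, child_ss):
        sa, sb = child_ss.spawn(2)
        ga = _group_prob(mat_a)
        gb = _group_prob(mat_b)
        la_, _, _ = _consensus_labels(ga, sa, tau, consensus_restarts, max_iter, 1.0)
        lb_, _, _ = _consensus_labels(gb, sb, tau, consensus_restarts, max_iter, 1.0)
        return variation_of_information(la_, lb_)

    obs = _vin_between(la, lb, ss_obs)
    rng = np.random.default_rng(ss_flip)
    perm_seeds = ss_perm.spawn(n_perm)
    count = 0
    for child in perm_seeds:
        swap = rng.random(n_sub) < 0.5
        pa = np.where(swap[:, None], lb, la)
        pb = np.where(swap[:, None], la, lb)
        if _vin_between(pa, pb, child) >= obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return VInResult(cond_a, cond_b, density, obs, p, n_perm, n_sub)


def _group_prob(label_matrix: np.ndarray) -> np.ndarray:
    """Co-assignment probability across subjects from a subjects x nodes label
    matrix (vectorised version of :func:`group_probability_matrix`)."""
    M = (label_matrix[:, :, None] == label_matrix[:, None, :]).mean(axis=0)
    np.fill_diagonal(M, 1.0)
    return M


# ---------------------------------------------------------------------------
# per-module VIn tests
# ---------------------------------------------------------------------------


@dataclass
class ModuleVInResult:
    """Per-module reconfiguration between one condition pair."""

    module_id: int
    condition_a: str
    condition_b: str
    values: np.ndarray          # per-subject module VIn
    mean_vin: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.mean_vin = float(self.values.mean())


def subject_module_vin(reference: Partition, parts_a, parts_b,
                       min_size: int = MODULE_MIN_SIZE) -> dict[int, np.ndarray]:
    """Per-subject module VIn for every eligible reference module."""
    out: dict[int, np.ndarray] = {}
    for m in sorted(reference.large_modules(min_size)):
        out[m] = np.array([module_vin(reference, a, b, m)
                           for a, b in zip(parts_a, parts_b)])
    return out


def module_vin_test(reference: Partition, parts_a, parts_b,
                    cond_a: str = "A", cond_b: str = "B",
                    n_perm: int = 5000, seed=0) -> tuple[list[ModuleVInResult], pd.DataFrame]:
    """Which reference modules drive a reconfiguration between two conditions.

    Per subject, each eligible module's VIn between the subject's partitions
    in the two conditions is computed; modules are then compared against each
    other with paired sign-flip t tests, familywise-corrected via the
    permutation distribution of the maximum |t| across module pairs. Returns
    the per-module results (sorted by mean VIn, highest = strongest driver)
    and the pairwise-test table.
    """
    per_module = subject_module_vin(reference, parts_a, parts_b)
    results = [ModuleVInResult(m, cond_a, cond_b, v) for m, v in per_module.items()]
    results.sort(key=lambda r: -r.mean_vin)
    mods = sorted(per_module)
    pairs = [(a, b) for i, a in enumerate(mods) for b in mods[i + 1:]]
    if not pairs:
        return results, pd.DataFrame(columns=["module_a", "module_b", "t", "p_perm", "p_fwer"])
    diffs = np.stack([per_module[a] - per_module[b] for a, b in pairs], axis=1)
    n = diffs.shape[0]
    t_obs = _paired_t(diffs, axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_mean = signs @ diffs / n
    perm_sd = np.sqrt(((signs ** 2) @ (diffs ** 2) / n - perm_mean ** 2) * n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.nan_to_num(perm_mean / (perm_sd / np.sqrt(n)))
    abs_obs = np.abs(np.nan_to_num(t_obs))
    p = (1.0 + (np.abs(t_perm) >= abs_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0)
    max_perm = np.abs(t_perm).max(axis=1)
    p_fwer = np.maximum(
        p, (1.0 + (max_perm[:, None] >= abs_obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1.0))
    table = pd.DataFrame({
        "module_a": [a for a, _ in pairs], "module_b": [b for _, b in pairs],
        "t": t_obs, "p_perm": p, "p_fwer": p_fwer,
    })
    return results, table
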