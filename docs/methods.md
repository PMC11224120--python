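# Methods

`frustnet` implements a graph-theoretic analysis of how brain functional
networks reorganise around an induced emotional state (frustration), together
with a synthetic-cohort generator that makes the whole chain testable without
any imaging data. This note records the models, the defaults and why they
were chosen, the numerical conventions, and what the validation studies do
and do not establish.

## Analysis model

For each subject and each of six experimental conditions (pre-task rest, the
four task events Reward / Reward+1 / FNR / FNR+1, post-task rest) the input
is a node x time residual series (116 nodes by default). The pipeline is:

1. **Confound regression.** Every node's series is OLS-residualised against
   an intercept, the confound matrix (motion-like regressors, drift) and —
   for task runs — one canonical-HRF-convolved regressor per task event
   type. The global mean signal is never regressed. Collinear design columns
   are dropped by rank-revealing QR with a warning.
2. **Event concatenation.** For a task event type, the residual volumes in
   `[onset + lag, onset + lag + duration)` are concatenated across trials
   (hemodynamic lag default 2 volumes; duplicated volumes are kept when
   shifted windows overlap).
3. **Connectivity.** Pearson correlation across time, Fisher z' transformed
   with `|r|` clipped to `1 - 1e-7`. Diagonal stored as 0 and ignored.
4. **Proportional thresholding.** The top `k = round(d * n(n-1)/2)` edges by
   signed z value are kept and binarised, for densities d in
   {5, 10, 15, 20, 25, 30}%. Ties at the cutoff are resolved in
   lexicographic node-pair order so runs are exactly reproducible. Strong
   negative correlations are thereby excluded; weighted graph metrics are
   deliberately unsupported.
5. **Modularity.** Newman modularity
   `Q = sum_m (e_mm/E - (d_m/2E)^2)` (resolution gamma = 1) is maximised by
   a seeded Louvain implementation (randomised sweep order, greedy local
   moving + aggregation; the Q trace across levels is non-decreasing by
   construction). With 1,000 restarts per graph (reduced in the demo
   profile) the best-Q partition is retained and a co-assignment agreement
   matrix is accumulated over all restarts.
6. **Consensus.** An agreement matrix (subject-level across restarts, or the
   group matrix of co-assignment probabilities across subjects' best
   partitions) is thresholded at tau = 0.4, re-clustered, and iterated until
   every restart returns the identical partition (Lancichinetti–Fortunato
   style). Modules with <= 3 nodes are kept but reported as "unassigned".
7. **Reconfiguration statistics.**
   - *Segregation*: paired t tests on subjects' maximal Q between
     conditions, per density; sign-flip permutation null; familywise
     correction across the density ladder by the permutation distribution of
     the maximum |t|; paired Hedges g
     (`mean(diff)/sd(diff) * (1 - 3/(4*df - 1))`, sign = condA − condB).
   - *Composition*: variation of information between the two group consensus
     partitions, `VI = H(X|Y) + H(Y|X)` from the contingency table with
     natural logs, normalised by `log(n)` to [0, 1]. The permutation null
     swaps each subject's pair of condition labels and rebuilds both group
     probability matrices and consensus partitions. p-values are
     `(1 + #{perm >= obs}) / (n_perm + 1)`.
   - *Module attribution*: for a reference partition (the pre-task rest
     group consensus), each module's VIn is computed on the induced
     sub-partitions of its members (normalised by the log of the member
     count; modules >= 4 nodes only), per subject, using the subject's
     consensus partitions; modules are compared against each other with
     sign-flip paired t tests and max-|t| familywise correction.
8. **Efficiency prediction.** Module global efficiency (mean inverse BFS
   shortest-path length over ordered pairs of the induced subgraph, with
   1/inf = 0) is computed per subject at 10% density for every module of
   each condition's group consensus. Predictors (module efficiencies, mean
   framewise displacement per condition, age, sex, medication load, scanner)
   enter a train/held-out framework: stratified split on outcome quartiles
   (48/18), standardisation with training statistics only, forward/backward
   stepwise selection scored by repeated k-fold cross-validated RMSE
   (10 folds x 20 repeats; the visited model with minimal CV RMSE wins),
   refit on the training set, held-out Pearson r / R² = r² / RMSE, one-sided
   permutation p on r > 0 by shuffling the held-out outcome, and
   Benjamini–Hochberg FDR across the five primary outcome models.
   Specificity (null) outcomes are reported uncorrected.

### Design choices made where the design was genuinely open

- The group probability matrix is built from subjects' best-Q partitions
  (averaging subject agreement matrices is exposed as an option, off by
  default); per-module paired tests use subject consensus partitions.
- Condition pairs are permuted pairwise; joint shuffling across all six
  conditions would be a natural extension but is not implemented.
- Per-module VIn uses the induced-subpartition definition above; a nodal
  entropy decomposition would be an alternative.
- The stratification variable for the train/held-out split is the outcome
  being predicted, one split per outcome, seeded.
- Medication load is a *candidate* predictor (selectable), not a forced
  covariate.
- The permutation target for prediction models is the held-out correlation;
  permuting training labels is available as an option.

## Synthetic cohort

The generator emulates the *statistical* situation of a frustration
paradigm, not fMRI physics. Per condition a planted partition defines a
block correlation matrix: compound symmetry within modules (within-module
correlation 0.6 by default), constant between-module correlation (0.05),
unit diagonal; positive definiteness is checked by the smallest eigenvalue
with automatic shrinkage toward the identity. Per (subject, module,
condition) the within-module correlation receives Gaussian jitter
(sd 0.08) — this latent jitter is the only subject-level signal, and it
drives module connectivity and hence module global efficiency monotonically.
Series are Gaussian draws from the Cholesky factor (`noise_sd` scales the
series without affecting correlations), with added motion-like AR(1)
confounds (6 regressors with occasional spikes, loadings N(0, 0.3) per
node), a linear drift, and — in task conditions — canonical-HRF-convolved
coactivation for every event type (amplitude 1.0, per-node gains
N(1, 0.3)). Mean framewise displacement is derived from the motion
regressors and stored per condition as a covariate.

Trial schedules follow the rigged paradigm: feedback is a loss ("FNR") with
probability 0.6 per trial (the rigged fraction), otherwise a win; the
anticipation phase of trial N+1 inherits FNR+1 / Reward+1 from trial N.
Phase durations (cue 0.5 s, target 0.5 s, anticipation 2 s, feedback 1 s,
ITI 4 s; 8 s per trial) and the repetition time (2 s) are declared defaults
— such timing is paradigm-specific and not derivable from summary
statistics. Resting scans default to 270 volumes (9 minutes). The two task
runs are collapsed into one long run of `n_trials * n_runs` trials.

Phenotypes are linear in the standardized latent jitter of one stated
(module, condition) block — `y = beta * z + N(0, 1)` — with default
standardized slopes in the 0.25–0.4 range typical of standardized regression
coefficients reported for post-task module efficiency; the three
specificity outcomes (anxiety-, inattention-, hyperactivity-like) are pure
noise from an independent stream. Because the link targets within-module
correlation rather than efficiency itself, efficiency-based prediction can
succeed only by actually running connectivity → thresholding → consensus →
efficiency.

What the generator does **not** emulate: voxel-level data, spatial node
geometry, condition series sharing one acquisition (each condition's series
is an independent draw), physiological noise, scanner differences beyond a
binary covariate, heterogeneous module sizes, or subject-specific module
*composition* (subjects share each condition's planted partition; their
individuality enters through correlation jitter and sampling noise).
Consequences of the last point are discussed below.

## Behaviour of the permutation tests on synthetic cohorts

Two findings from the calibration studies matter for interpreting results
on clean synthetic data; both are properties of the statistics, not bugs.

**The condition-VIn null has an atom at the observed statistic in
high-signal regimes.** The within-subject label swap makes the two permuted
groups complementary mixtures of the two condition's partitions. Whenever
the swap count deviates from n/2 by roughly sqrt(n) — an O(1)-probability
event at any n — the iterated consensus amplifies each group's majority
back to the *pure* planted configuration, and the permuted VIn ties exactly
with the observed VIn. On cohorts where subject-level partitions are nearly
noiseless, the permutation p is therefore bounded below by this snap
probability (measured ~0.3 at the default 116-node geometry, ~0.04 at a
60-node geometry whose thresholded graphs fragment subject partitions
more). Detection improves, paradoxically, with realistic subject-level
heterogeneity, because balanced mixtures then resolve to partitions that
resemble each other rather than the pure configurations. The test remains
exactly valid under the null in all regimes; what is limited is its power
resolution on sterile cohorts, so a floor-level p should not be expected
there.

**The VIn test is conservative on clean nulls.** When both conditions share
a planted partition and the signal is strong, both group consensus
partitions and all permuted rebuilds resolve to the same configuration:
observed and permuted statistics are all zero and p = 1. The test's
rejection rate under such nulls is therefore far below the nominal level —
exact validity with heavy discreteness. The paired-Q contrast, whose
statistic is continuous, calibrates at the nominal rate, and its max-|t|
familywise correction controls the familywise error across densities.

## Validation studies and simulation sizes

The studies in `frustnet.benchmarks` (run by both the test suite and
`scripts/acceptance.py`) use these problem sizes, chosen to give stable
estimates on a single CPU:

- *Metric oracles*: 200 random graphs/partitions of <= 20 nodes against
  brute-force edge-count Q, contingency-table VIn and Floyd–Warshall
  efficiency, plus closed forms (Q = 1 − 1/k for k equal cliques, VIn = 1
  for one-module vs singletons, E_glob = 1 for complete graphs, 5/6 for the
  3-node path); agreement to 1e-12.
- *Planted recovery*: 66 subjects, 116 nodes, 7 modules, T = 500 volumes,
  100 restarts, 500 permutations; group consensus recovers every planted
  partition with VIn < 0.05 and the unchanged condition pair stays null.
- *Type-I error*: 100–150 replicate two-condition null cohorts (12
  subjects, 40 nodes, T = 150, 12 restarts, 99 VIn permutations, 500 Q
  permutations), rates assessed against binomial tolerances computed from
  the replicate count used.
- *Prediction recovery*: 30–40 replicate cohorts (66 subjects split 48/18,
  60 nodes, 5 modules, T = 270) with a planted standardized slope of 0.6 on
  one post-task module; selection frequency of the matching efficiency
  column and median held-out r. The null calibration uses 25–30 zero-slope
  cohorts with BH correction across the five primary outcomes, plus a
  deliberately leaky negative control (selection and standardisation on the
  full sample) that demonstrates the optimism leakage produces.
- *Determinism*: the demo profile (12 subjects, 40 nodes, 6 conditions,
  50 restarts, 200–500 permutations) rerun with identical seeds must
  reproduce every output file byte for byte. The full-scale profile
  (1,000 restarts, 5,000 permutations) is the same code path with larger
  counts.

Passing these studies shows the machinery is correct and calibrated on the
generator's assumptions. It does not show that real fMRI cohorts satisfy
those assumptions — in particular, real between-subject variability in
module composition, non-Gaussian noise, and shared-acquisition dependence
between task conditions are outside the generative model.

## Numerical conventions

- All randomness descends from explicit integer seeds through
  `numpy.random.SeedSequence` trees; reruns are bit-identical.
- Louvain accepts a move only for a gain > 1e-12; ties keep the current
  community; the sweep order is a seeded permutation per level.
- Consensus convergence means all restarts return the identical partition;
  after 20 iterations without convergence the last partition is returned
  with a warning flag.
- Permutation p-values are floored at 1/(n_perm + 1); FWER-corrected p is
  never reported below the raw p.
- Zero-variance paired differences give p = 1 and g = 0 (exact null) or an
  undefined g (degenerate shift).
- Stepwise selection reuses one fold set for all candidate models (paired
  comparisons) and caps model size at n/3 predictors; an intercept-only
  winner is recorded as a failed prediction with p = 1.

## Known limitations

- Binary-graph metrics only; no weighted or signed modularity.
- Pairwise condition permutation; no joint multi-condition scheme.
- The generator's independence of condition series understates the
  dependence present in a single scanning session.
- Demo-profile permutation counts (200–500) resolve p only to ~2e-3;
  full-scale counts are needed for Table-1-style precision.
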