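# Methods

This note documents the models, algorithms, defaults and design choices
behind the package, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Preprocessing

ROI time series are averaged within their assigned large-scale networks
per time point. Each network signal is binarized per participant against
its own temporal mean: strictly above → +1 (active), at or below → −1.
The tie rule (exactly at the mean → inactive) is a deterministic choice;
ties are measure-zero for continuous signals. A constant network signal
binarizes to all −1 with a logged warning. Binarization happens per
participant before any concatenation; group-level fits concatenate the
per-participant binary series in roster order. The binary similarity
index between two series is the fraction of agreeing time points
(computed in 1/0 coding, equal to 1 − Hamming/N). The seed-based DMN
split correlates each DMN ROI with vmPFC and PCC seed series, Fisher
z-transforms the correlations (atanh with |r| clamped at 1 − 10⁻¹²),
averages z across participants, and assigns the ROI to the seed with the
larger average coupling.

## Pairwise maximum-entropy model

Energy convention: E(σ) = −Σ h_i σ_i − ½ Σ_{i≠j} J_ij σ_i σ_j with
P ∝ e^{−E}; the ½ merely rescales J and all probability-level outputs are
convention-invariant. Fitting is moment-matching gradient ascent from
zero initialization with effective step η/K (η default 0.2), stopping
when the maximum absolute moment discrepancy falls below 10⁻⁵ (default;
hard iteration cap 10⁶, non-convergence flagged, never silently
accepted). The log-likelihood is concave, so the optimum is unique and
the solver path-independent; a test verifies two different learning
rates land on the same parameters. All exhaustive operations enumerate
2^K patterns and refuse K > 20.

Goodness of fit follows the two standard summaries: the Pearson
correlation r between model and empirical pattern probabilities over the
2^K patterns, and the KL-divergence ratio (D1 − D2)/D1, where D2 is the
divergence of the empirical distribution from the pairwise model and D1
from the independent (first-order) model matching only the means. The
independent model is computed in closed form as a product of Bernoullis.
Empirical-zero cells contribute nothing to either divergence; D1 = 0
(already-independent data) makes the ratio undefined and is flagged
rather than returned as a number.

## Landscape

Two patterns are adjacent iff they differ in exactly one network. Local
minima require strictly lower energy than all K neighbours. Basins are
steepest-descent domains; the descent steps to the lowest-energy
neighbour, breaking exact ties toward the lowest pattern code, and a
descent that terminates on a non-minimum plateau raises an error naming
the pattern. The disconnectivity tree is built by inserting patterns in
increasing energy order into a union-find structure (Kruskal-style);
when two clusters containing labelled minima meet, the inserted
pattern's energy is the merge barrier. This is exactly equivalent to the
descending-threshold procedure (remove nodes with E ≥ E_th, sweep E_th
down the sorted distinct energies, record when minima pairs disconnect);
a test verifies the equivalence against a networkx-based threshold sweep
and a minimax-path (widest-path) oracle.

Brain states are labelled groupings of minima. The default is an
explicit grouping — the analysis design decides which minima form the
major and minor states, as done by inspecting the dendrogram in practice
— with two conveniences: grouping keys that are not minima of the given
landscape are ignored, and (optionally) unlisted minima inherit the
label of the labelled minimum they merge with at the lowest barrier.
The latter makes explicit groupings robust to the shallow spurious
minima that finite-sample fits occasionally add. An automatic mode cuts
the dendrogram below its highest merges into at most four groups and
ranks them by basin mass (two largest → major, rest → minor); it exists
for exploratory use, and the pipeline uses the explicit reference
grouping whenever one is available.

## Dynamics

The Metropolis kernel proposes one of the K neighbours uniformly and
accepts with min(1, e^{E_cur − E_prop}); rejections repeat the current
pattern, which is required for the Boltzmann law to be stationary
(verified analytically on the full 128-state kernel). Walks start at a
uniformly random pattern, discard a 100-step burn-in by default, and are
reproducible from their seed. Default walk length is 10⁵ steps; a
running coefficient-of-variation diagnostic re-estimates the indices
cumulatively at checkpoints and reports sd/mean over the trailing half
of the schedule, averaged over independent runs — its operationalization
(window, checkpoints, across-run averaging) is this package's own.

State sequences map each pattern to its basin's state label; simulated
walks and empirical binarized volumes share this code path. Transition
semantics (the strictest reading): a direct transition is a single-step
change between the two major states; an indirect transition is a
completed passage major_a → (≥1 consecutive intermediate steps) →
major_b with b ≠ a. Excursions into the intermediate state that return
to the same major state, and trajectories ending inside the intermediate
state, count as no transition. Transition frequencies are reported both
per retained step (as percentages; this is the scale used throughout)
and per label change, since either normalization is defensible.

## Coordination

Functional connectivity is the Pearson correlation between two networks'
continuous series; averaging always happens on the Fisher z scale. The
segregation strength of a two-module partition is the pooled mean z over
within-module pairs (both modules' internal pairs pooled, unweighted)
minus the mean z over across-module pairs. The two canonical partitions
are DMN/SMN/Auditory vs FPN/SAN/ATN/Visual (intermediate-state modules)
and DMN/Visual vs the rest (major-state modules).

## Group statistics

Two-sample comparisons use the pooled-variance t (df = n₁+n₂−2, matching
the reported degrees of freedom of this analysis family), a label-
shuffling permutation test with the two-sided add-one rule
p = (#{|t*| ≥ |t|}+1)/(n_perm+1) (default 10⁴ permutations, explicit
seed), and Cohen's d with the pooled sd. The chi-square test is Pearson's
with adjusted standardized residuals (O−E)/√(E(1−row share)(1−col
share)); Bonferroni factors are always supplied by the caller as the
family size. Partial correlation residualizes both variables on the
covariates (with intercept) and correlates the residuals, df = n−2−k.
The factorial ANOVA uses Type II sums of squares via statsmodels; the
intended designs are balanced, where Type I and Type II coincide.

## Diagnosis

The univariate rule is the midpoint cutoff ((min of the TD group)+(max
of the ASD group))/2; the side classified as ASD follows the training
group means rather than a hard-coded sign. The bivariate rule is a
linear soft-margin SVM on (intermediate-state frequency,
indirect-transition frequency) with C = 1 (configurable); no feature
scaling is applied. Evaluation reports sensitivity and specificity with
ASD as the positive class and refuses to score a cohort that overlaps
the training participants unless explicitly overridden. Test
participants are fitted at the individual level with the same defaults;
a warning is emitted when an individual fit's accuracy drops below 0.9,
which is common at ~240 volumes.

## Synthetic cohorts: what is planted and how

The generator ships two frozen K=7 parameter sets sharing six local
minima: majors {56, 62} and {65, 71} (funnels around the anticorrelated
DMN/VIS-vs-rest patterns) and minors 49 (DMN/SMN/AUD active) and 78 (its
complement). They were calibrated once, by a constructive procedure:

1. a multi-funnel target energy over the 128 patterns (linear funnels of
   unit slope around the six target minima; minor funnels shallower) is
   least-squares-projected onto the pairwise span {1, σ_i, σ_iσ_j};
2. a small linear program polishes each set — hard constraints keep all
   six minima strictly stable with prescribed margins, soft constraints
   shape the minor basins (kept at 12/128 patterns each in the TD-like
   set; evicted down to 3/128 in the ASD-like set via descent-witness
   constraints), and cutting planes remove any spurious minima the
   solution introduces;
3. global inverse-temperature factors (1.15 for TD-like, 1.45 for
   ASD-like) balance the two groups' direct-transition rates, since the
   group contrast of interest leaves direct transitions unchanged.

Long-walk indices of the frozen sets: TD-like — intermediate 18.2%,
indirect 2.6%/step, direct 5.9%/step, mean major duration 6.6 steps;
ASD-like — 3.6%, 0.9%, 5.3%, 13.6 steps; minor basins 9.4% vs 2.3% of
the landscape per state. A blind random search over module-block
couplings (the obvious simpler construction) was tried first and never
produced the six-minimum two-major/two-minor structure; the constructive
calibration is deterministic and auditable, and the accepted parameters
are frozen so every cohort draws from identical study conditions.

Cohort defaults mirror a single-site resting-state study: 26 TD-like and
24 ASD-like participants, 240 volumes each (~8 min at TR = 2 s).
Participants get small Gaussian parameter jitter (sd 0.04 on h, 0.02 on
J) for between-participant heterogeneity. Binary series are sampled by
default from the Metropolis chain ("markov"), not i.i.d.: with
independent volumes the empirical direct-transition count is set by the
product of major-state occupancies, which differs between the groups and
contradicts the planted "direct unchanged" contrast, whereas chain
sampling reproduces the barrier-limited mechanism and adds fMRI-like
autocorrelation. (`sample_mem_series` itself defaults to exact i.i.d.
categorical sampling, which unit tests prefer because it has no MCMC
error.) Continuous surrogates add Gaussian measurement noise, sd 0.1 by
default: at substantially larger noise the mean-threshold re-binarization
of slow, occupancy-unbalanced chains flips bits near basin boundaries and
selectively inflates the ASD-like direct count. Behavioural scores are
linear-plus-noise in the **true** (long reference walk, 10⁴ steps)
indices, with within-group correlations set by config (ADOS-like −0.47
with indirect frequency in the ASD-like group, FIQ-like +0.46 with
indirect frequency in TD-like and +0.55 with major duration in
ASD-like) and score scales matching typical demographics.

### What the synthetic tests do and do not show

They demonstrate that every algorithmic stage is correct (against
independent oracles and closed forms) and that the full pipeline
recovers planted group contrasts of realistic effect direction from
realistic amounts of surrogate data. They do not emulate hemodynamics,
scanner drift, motion artefacts, or anatomical ROI geometry, and two
quantitative behaviours deserve emphasis:

* **Attenuation.** Scores are planted against true indices; correlations
  with the estimated (240-volume) indices are attenuated by counting
  noise — roughly a factor of 2–3 for the indirect-transition frequency.
  A reported estimate-level correlation of ~−0.2 against a planted −0.47
  is expected behaviour, not a bug, and is itself measurable.
* **Transfer gap.** Diagnostic cutoffs are trained on group-level
  indices but applied to individual-level fits, which are far noisier at
  240 volumes; sensitivity/specificity on synthetic external cohorts is
  therefore substantially below what clean group-level separation would
  suggest.

## Problem sizes and checks

The acceptance checks run the landscape oracles on 100 random K=7
landscapes, verify detailed balance analytically on all 128·7 neighbour
pairs, compare a 10⁶-step walk to the exact Boltzmann law (total
variation < 0.01), fit 10⁵ exact samples (probability correlation
r > 0.99, accuracy > 0.9, recovery error monotone in T over 10³–10⁵),
and re-run the full pipeline on 20 master-seeded cohorts requiring every
planted contrast direction (the three planted effects at two-sided
α = 0.05; "direct transitions unchanged" as the equivalence-style bound
|Cohen's d| < 1, because absence of an effect cannot be certified by a
non-significant p, and the direct rate is exponentially sensitive to
fitted barrier heights) in at least 19 of 20 seeds. The statistics layer
is calibrated under a simulated null (type-I error 5% ± 2% over 10³
replicates) and checked against formula oracles.

## Known limitations

* Exhaustive enumeration limits K to ~20 in principle and 7–10 in
  practice; no approximate inference (pseudo-likelihood, mean-field) is
  provided.
* The automatic state grouping is a convenience, not a validated model
  selection rule; analyses should fix an explicit grouping.
* Individual-level fits at a few hundred volumes are noisy; their
  accuracy warning threshold (0.9) is a heuristic.
* The permutation test shuffles labels without stratification; exchange-
  ability is assumed.
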