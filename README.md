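# energylandscape

Energy-landscape analysis of brain-network dynamics: a tested, reusable
implementation of the pairwise maximum-entropy (Ising) pipeline used to
characterize resting-state fMRI dynamics as stays in, and transitions
between, a small set of dominant brain states — and to compare those
dynamics between groups (e.g. autistic and neurotypical cohorts).

## Who this is for

Researchers who have per-participant multivariate time series (time ×
brain networks, or time × ROIs plus an ROI→network table) and want to

* fit a pairwise maximum-entropy model to the binarized activity,
* enumerate the energy landscape over all 2^K activity patterns,
* find its local minima, attraction basins and disconnectivity tree,
* simulate Metropolis–Hastings dynamics on it and count direct/indirect
  transitions between major states and dwell times within them,
* relate those dynamics indices to behavioural scores, and
* train/evaluate simple diagnostic classifiers on independent cohorts.

Because the original fMRI data cannot be shipped, the package includes a
first-class synthetic-cohort generator with planted ground truth: two
parameter sets over K=7 canonical networks (DMN, FPN, SAN, ATN, SMN,
auditory, visual) that share the same six local minima — two major states
of two minima each, and two shallow minor states jointly forming the
intermediate state — but differ in minor-basin depth, plus behavioural
scores with planted correlations. Every pipeline stage is tested against
that ground truth.

## The model

Binary network activity σ ∈ {−1,+1}^K (σ_i = +1 when network *i* is above
its own temporal mean) is modelled by the least-structured distribution
matching the empirical first and second moments:

    P(σ) ∝ exp(−E(σ)),   E(σ) = −Σ_i h_i σ_i − ½ Σ_{i≠j} J_ij σ_i σ_j

with basal activities *h* and symmetric couplings *J* found by
moment-matching gradient ascent (the log-likelihood is concave). The
landscape is the hypercube graph of all 2^K patterns decorated with E;
local minima are patterns below all K neighbours, basins are
steepest-descent domains, and the disconnectivity tree records the
minimax barrier at which each pair of minima merges. A Metropolis walk
(uniform single-flip proposals, acceptance min(1, e^{−ΔE})) has P as its
stationary law and yields the three dynamics indices: intermediate-state
frequency, indirect-transition frequency (major → intermediate → other
major) and mean major-state duration.

## Worked example

```python
from energylandscape import (
    PlantedCohortConfig, build_cohort, analyze_cohort,
)

cohort = build_cohort(PlantedCohortConfig(master_seed=1))   # 26 TD, 24 ASD
analysis = analyze_cohort(cohort, seed=1)

td = analysis.groups["td"]
print(len(td.minima))                      # 7  (six planted minima + one shallow extra)
print(round(td.fit_report.r, 3))           # 0.99   model/empirical probability correlation
print(round(100 * td.fit_report.accuracy, 1))  # 96.8   (D1-D2)/D1 in percent

c = analysis.comparisons["indirect_freq"]
print(round(c.mean_a, 2), round(c.mean_b, 2))  # 3.14 0.92  % of volumes, TD vs ASD
print(round(c.cohens_d, 2))                    # 3.09
```

The fitted group model reproduces the empirical pattern probabilities
(r ≈ 0.99, accuracy ≈ 97%); the ASD-like group occupies the intermediate
state about five times less often (4.0% vs 21.3% of volumes), makes a
third as many indirect transitions, and dwells in the major states about
three times longer — while direct transitions stay comparable. These are
the planted contrasts, recovered end-to-end from the surrogate signals.

A command-line interface mirrors the library:

```bash
ela simulate-cohort --out cohort/ --seed 1
ela run-all --cohort cohort/ --out results/ --seed 1
ela diagnose --train cohort/ --test other_cohort/ --out report.json
```

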