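# Methods

This note records the model and protocol the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices that were genuinely open.

## The base learner

The neuro-fuzzy base learner (NEWFM) is a binary classifier over real
feature vectors. Per (feature, class) it keeps `m` triangular membership
functions (MFs); the class activation on a feature value is the bounded sum
`min(1, Σ_j w_j μ_j(x))` of the weighted memberships, so it always lies in
[0, 1].

Structure and update rule, fully pinned down:

* **Initialization.** MF centers are evenly spaced over the feature's
  training range; a zero-width range is widened by a machine-epsilon-scaled
  pad and flagged. All weights start at 0, so the initial activation is 0
  everywhere.
* **Supports.** An MF's support endpoints are the adjacent MF centers; the
  outermost supports extrapolate by one inter-center gap (for `m = 1`, by
  the feature-range width). Supports are therefore a pure function of the
  centers. An alternative would put support endpoints at midpoints between
  centers; the neighbor-center rule was chosen because it matches the
  even-spacing initialization (adjacent MFs overlap from the start) and
  keeps `left ≤ center ≤ right` automatic once centers stay ordered.
* **Update.** For each instance in data order, per feature: the
  most-activated MF of the true class (ties to the lowest index) moves its
  center toward the value by `α (x − c)` — clamped between its neighbors'
  centers so the bank stays ordered — and gains weight `min(1, w + δ)`; the
  most-activated MF of the opposite class loses `max(0, w − δ)`.
* **Stopping.** Training runs at most `max_epochs` sweeps and stops early
  once training accuracy has not improved for `patience` consecutive
  epochs.
* **Decision and score.** Classify by comparing the summed class
  activations over the selected features (tie → class 0). The defuzzified
  score is `(T + 1)/2` with `T = Σ(b₁ − b₀) / Σ(b₁ + b₀)`; an all-zero
  denominator maps to the indifferent score 0.5. The score agrees in sign
  with the classification whenever any membership is active.
* **Feature selection.** Features are ranked by the non-overlap area
  `∫ |b₁(x) − b₀(x)| dx` over the training range (trapezoid rule, 256
  points; ties to the lower index).

Defaults: `m = 3` MFs, learning rate `α = 0.1`, weight step `δ = 0.1`,
`max_epochs = 50`, `patience = 3`. All are ordinary hyperparameters; the
defaults are modest values that converge on separable data well inside the
epoch budget and are exposed on every constructor.

The per-instance update is sequential (each update changes what the next
instance sees), so the inner loop is compiled with numba; its semantics are
pinned bit-exactly against a pure-Python reference implementation of the
step rule in the test suite.

## Zoom-in units and the stacked network

A ZLU fits a standard NEWFM on its feature block, splits the training
instances into misclassified (MI) and correctly classified (CCI) groups by
that model's own decisions, and fits a *subpattern* NEWFM on the MIs and a
*refined* NEWFM on the CCIs. At test time only the subpattern and refined
models are evaluated; the unit's output is their score pair.

Degenerate groups: when MI or CCI has fewer than `min_count = 4` instances
or only one class, that component falls back to a value copy of the
standard model, keeping the unit's output contract total. Optional feature
selection happens during standard training and the selected subset is
shared by the subpattern and refined fits (independent selection is a
switch); in the reference protocol the 20-of-42 reduction happens per ROI
*before* the network, so unit-internal selection defaults off.

The network splits its input into contiguous equal blocks (first layer),
then repeatedly splits each layer's concatenated score pairs — ordered
(t_{1,M}, t_{1,C}, t_{2,M}, t_{2,C}, …) — into the next layer's inputs, and
trains a final NEWFM on the last layer's scores. Validity requires the
first-layer unit count to divide the input length and each subsequent count
to divide twice its predecessor. Scores are computed for *all* training
instances at every layer (not only the group a component trained on).

**Layerwise readout.** How intermediate layers should be scored is not part
of the model, so the package makes it explicit: layer ℓ's accuracy is the
mean over its units of an auxiliary NEWFM trained on each unit's own score
pair; the output-layer entry is the fitted output NEWFM itself. A readout
trained on the whole layer score vector was considered and rejected: it
already aggregates every unit at layer 1 and therefore measures the same
quantity at every depth, flattening the layer profile. The per-unit readout
measures what a single unit's representation supports, which is the
quantity that grows as zoom-in layers aggregate evidence (measured profile
on 20 default-condition cohorts: train 78 → 97 → 99%, test 67 → 76%).

## Experimental protocol

Three one-vs-rest tasks: AD vs NC+MCI (A-NM), NC vs AD+MCI (N-AM), MCI vs
AD+NC (M-AN). Per task:

1. **Hold-out split** — 23 training subjects per class, sampled uniformly
   per class with a seed; with cohort sizes 34/89/45 the test set is 11 AD,
   66 MCI, 22 NC.
2. **Per-ROI ranking** — on training subjects only, one NEWFM per ROI on
   its 42 features; the ROI's accuracy is a seeded stratified 5-fold
   cross-validation estimate (using test data here would leak), and a final
   fit on the whole training split selects the ROI's 20 features. Ranking
   is by accuracy, ties to the lower ROI index.
3. **Region selection** — the top 16 ROIs; their 20-feature blocks,
   concatenated in rank order, form the 320-dimensional network input.
4. **Network** — 16 first-layer units (one per selected ROI) and a 4-unit
   second layer (the second-layer width is not pinned by the protocol;
   4 is the package default and configurable), then the output NEWFM.
5. **Evaluation** — layerwise and final accuracies on train and test;
   accuracy is plain percent-correct (balanced variants are deliberately
   not the default).

Nothing downstream of the split reads a test label; the tests assert this
by corrupting test labels and requiring identical ROI selection and
training-side accuracies.

The package also ships the three published 16-region discriminative-ROI
rankings for the AAL-90 atlas; intersecting them yields the seven regions
implicated across all assessments (cingulum_mid_r, caudate_l,
parietal_sup_l, frontal_mid_r, frontal_mid_l, parietal_inf_l,
postcentral_r).

## Feature extraction

* **Wavelets.** Orthonormal Haar analysis (`a = (x₁+x₂)/√2`,
  `d = (x₁−x₂)/√2`, recursing on approximations) of the first 128 of 140
  timepoints — the only truncation to a power of two that yields exactly
  16 + 8 + 8 = 32 coefficients in the d3/d4/a4 bands at four levels. The
  orthonormal convention makes Parseval exact, which the tests exploit.
* **Connectivity.** Absolute Pearson correlation between ROI series (a
  numerically constant series is an error naming the ROI), proportional
  thresholding keeping the strongest `density` fraction of edges (default
  0.20; ties broken lexicographically so masks are reproducible).
* **Node measures** on the binary masked topology: degree, betweenness
  (unnormalized shortest-path counts, within components), k-core number,
  subgraph centrality (`Σ_j v_j(i)² e^{λ_j}`), eigenvector centrality
  (unit-norm non-negative principal eigenvector, computed by dense
  eigendecomposition; an edgeless graph is an error), PageRank (damping
  0.85, uniform teleport). Node strength and the diversity coefficient use
  the retained weights; diversity is the Shannon entropy, normalized by
  `log(#modules)`, of a node's strength across modules found by greedy
  modularity maximization on the weighted masked graph (deterministic
  tie-handling by node index; a single-module graph has diversity 0).
* **Graph measures**, replicated into every ROI's vector: degree
  assortativity (degree-regular graphs are reported as 0 with a flag) and
  small-worldness `σ = (C/C_rand)/(L/L_rand)` with `C` the mean clustering
  coefficient, `L` the characteristic path length of the largest component,
  and the null terms averaged over 20 seeded degree-preserving rewired
  graphs (10 swap attempts per edge; graphs with no feasible swap, e.g.
  complete graphs, rewire to themselves). A zero-clustering null yields a
  flagged `+inf` sentinel.

The graph-measure implementations are backed by networkx and are verified
against independently written brute-force oracles (BFS path enumeration,
iterative peeling, dense eigendecomposition, a PageRank linear solve) on
every connected graph with at most six nodes, up to isomorphism, with
node-relabeling equivariance tested separately.

## Synthetic cohorts

The generator emulates the *shape and statistical structure* the pipeline
assumes, not fMRI physics. Per subject: each ROI carries a standardized
AR(1) background (coefficient 0.3, scaled by `noise_sd`); subjects of class
index k (AD = 0, MCI = 1, NC = 2) add a sinusoid of period 32 timepoints
and amplitude `k × spectral_effect` to the informative ROIs (period 32
lands the energy in the d4/a4 bands of the 128-point analysis), and a
designated ROI block shares a latent AR(1) factor with loading
`√(k × connectivity_effect)` — a factor construction that is positive
semidefinite for any admissible effect, with the admissibility bound
(`2 × connectivity_effect < 1` for three classes) checked at spec
construction, naming the offending block. Labels for the three binary tasks
are derived views of the jointly generated cohort. All randomness flows
from one root seed through spawned per-subject streams; identical spec +
seed is bit-identical.

Defaults: 34/89/45 subjects, 90 ROIs, 140 timepoints, 8 informative ROIs,
`spectral_effect = 1.0`, `connectivity_effect = 0.15`, `noise_sd = 1.0`.
The effect defaults were chosen so that a single informative ROI supports
roughly 60–85% accuracy — the regime in which aggregating many weakly
informative regions (the point of the stacked architecture) is visible;
they are properties of the benchmark, not claims about ADNI data, whose
noise and effect sizes are not publicly characterized.

What the generator does **not** emulate: scanner artifacts, motion, spatial
voxel structure (the voxel model is signal + i.i.d. noise), site effects,
or realistic anatomical correlation topology. Passing tests therefore
demonstrate that the pipeline recovers the kinds of structure it targets —
low-frequency spectral contrasts and block-correlation contrasts — not that
it would achieve any particular accuracy on clinical data.

## Evaluation conditions and problem sizes

The statistical properties are measured as seeded Monte-Carlo experiments
at sizes chosen for a desk-scale benchmark: planted-ROI recovery on 20-ROI
cohorts with 5 informative ROIs and 15 subjects per class (20 seeds);
network-vs-single-learner ordering and the layerwise profile on 10-ROI
cohorts with 20 subjects per class (20 seeds, generator-default effects);
null calibration on zero-effect cohorts built so the relevant binary task
is balanced (chance = 50%). The acceptance script runs the full protocol at
the reference class sizes 34/89/45 on a 30-ROI atlas with the full 16-ROI ×
20-feature, [16, 4] architecture.

## Known limitations

* The base learner is strictly binary; multi-class assessment is handled
  only through the three one-vs-rest tasks.
* The update rule is a faithful minimal variant of the neuro-fuzzy family
  it belongs to, not a reproduction of any specific published
  implementation; its exact hyperbox bookkeeping differs from descriptions
  that were never published in full.
* Small-worldness depends on a finite rewired null ensemble, so it carries
  Monte-Carlo noise and is the one feature that is not exactly invariant
  under ROI relabeling (the ensemble is sampled on the labeled graph).
* Per-ROI cross-validated accuracies on small cohorts are coarse (fold
  granularity), so ROI rankings on weak effects are noisy; ties are broken
  deterministically but arbitrarily by ROI index.
* `run_assessment` extracts features for all subjects at once for
  convenience; this is safe (feature extraction never reads labels) but
  means feature extraction cost is not reduced by the split.
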