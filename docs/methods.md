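# Methods

## The problem

Small biomedical tables (tens of rows, dozens of variables) starve both
statistical tests and machine-learning models. Generative augmentation —
synthesizing extra rows that respect the structure of the originals —
can recover power, but it also amplifies whatever random variation the
original sample happens to contain. Left unchecked, that amplification
turns noise variables into "significant" findings: alpha-error
inflation. `esomaug` implements a structure-aware generator together
with a built-in inflation detector that tells the user how much
augmentation the dataset tolerates, including the answer "none".

## Structure learning and the critical radius

Variables are z-standardized (per-column mean 0, sd 1) before any
distance is computed; all radii and neighborhoods below live in this
standardized space, and generated rows are back-transformed for output.
Constant columns are given unit scale so they pass through unchanged.

An emergent self-organizing map (a large rectangular SOM lattice,
default 50 × 80 neurons, toroidal) is trained online:

    w_i <- w_i + eta(t) * h(BMU, i, t) * (x - w_i)

with the learning rate decayed linearly 0.5 → 0.1 and a Gaussian
lattice neighborhood whose radius decays linearly from half the smaller
lattice dimension to 1, over 24 epochs by default. Ties in the
best-matching-unit search break toward the lowest neuron index so runs
are reproducible bit for bit. Two emergent layers summarize the fit:
the U-matrix (per neuron, mean Euclidean distance to its 8-neighborhood
prototypes, wrapped on toroidal lattices) and the P-matrix (per neuron,
the number of data points within a given radius of its prototype,
inclusive boundary).

The generative radius r is estimated from the "abstract U-matrix"
heights: the Gabriel graph is built over the prototypes of occupied
BMUs (Gabriel edge: no third prototype inside or on the sphere whose
diameter is the connecting segment — the closed-ball convention, so a
square yields its four sides and no diagonal), and the edge lengths are
modeled as a two-component univariate Gaussian mixture fitted by EM
(k-means init, ≤100 iterations, tolerance 1e-8 on the mean
log-likelihood, fixed seed). EM runs on standardized heights so the
estimate is exactly equivariant under unit changes. r is the Bayes
decision boundary between the two components — the root of
π₁N(x|μ₁,σ₁) = π₂N(x|μ₂,σ₂) inside (μ₁, μ₂) — times a configurable
multiplier (default 1.0).

**Degeneracy.** The two-cluster reading of the heights fails when the
components collapse (a weight below 0.01 or means closer than a tenth
of the height sd) or when the fitted mixture has no density dip between
the component means (a unimodal fit: on [μ₁, μ₂] a unimodal density is
minimized at an endpoint, so we require an interior dip below 99% of
both endpoint densities). In either case — typical for datasets without
cluster structure, such as a single Gaussian cloud — the estimate falls
back to the median height and is flagged in the report rather than
silently substituted.

## Generation in the sigmoid neighborhood

The neighborhood of a point is graded by

    p(d) = 1 − 1/(1 + exp(−10 (d/c − 1)))

(p = 1/2 at d = c; implemented via `expit` because the literal form
cancels catastrophically for d ≫ c). For every original row, k
synthetic rows are produced by: (1) drawing a stratum — core
(p > 0.95), intermediate (0.10 < p < 0.95), or outer (p ≤ 0.10 with
d ≤ 2c) — with probabilities proportional to (0.85, 0.15, 0.05); since
those printed fractions sum to 1.05 they are renormalized to
(0.8095, 0.1429, 0.0476); (2) drawing a target probability uniformly
inside the stratum's band; (3) inverting the sigmoid for the distance
d\* = c(1 − logit(p\*)/10); (4) displacing the seed by d\* along a
direction drawn uniformly on the unit hypersphere of the standardized
feature space. Controlling the distance explicitly (rather than
jittering coordinates) avoids the concentration of high-dimensional
jitter on a hypersphere surface and caps every displacement at 2c.
Synthetic rows inherit their seed row's class label, so class
proportions are preserved exactly at every k. The scale c defaults to
the critical radius r.

Integer-coded columns are left real-valued by default; rounding is an
option (`GeneratorConfig.round_integers`).

## Engineered controls and the inflation signal

After structure learning — never before, so the controls cannot
contaminate the radius — every original variable X_j gains a permuted
counterpart X_j_perm (its values independently shuffled across rows).
Controls keep their parent's marginal distribution but are
class-irrelevant by construction. Originals and controls are then
augmented jointly, from the same seed rows and the same displacement
draws, so the controls experience identical generative dynamics: any
systematic advantage the originals develop over their own controls
beyond sampling noise is a read-out of error inflation.

Importance is measured by Boruta-style all-relevant selection: each
iteration appends a freshly permuted shadow copy of every feature,
fits a random forest (sqrt-features splits; 500 trees at full scale),
and scores features by out-of-bag permutation importance — the drop in
OOB accuracy when a feature's column is permuted, averaged over trees
(one shared permutation per feature per iteration, evaluated on each
tree's OOB rows). A feature scores a hit when it beats the iteration's
maximum shadow importance; a two-sided binomial test on hits at
alpha = 0.01 yields confirmed / rejected / tentative, with tentative
counted as not selected. Because single runs are noisy at n ≈ 20, the
error-control statistics use *selection counts* over R repeated runs
(R = 100 at full scale): count(X_j) = number of runs confirming X_j,
and the per-variable inflation signal is

    ΔI_j = count(X_j) − count(X_j_perm).

## Threshold and stopping criterion

The tolerance for ΔI is set once, on the unaugmented control-carrying
data: with a = per-control confirmed counts and b = per-original
confirmed counts, n_bootstrap = 100,000 paired resamples with
replacement give the difference distribution Δ = b_sample − a_sample,
and the cutoff is its empirical 95th percentile, L_Δ. (Re-running the
R selection runs inside every bootstrap draw would cost millions of
forest fits; resampling the count vectors reproduces the intended
sampling distribution of the count difference at the cost actually
reported for the procedure.)

The stopping search then tries augmentation levels k = 1, 2, …, each
generated fresh from the unaugmented data (not cumulatively),
recomputes selection counts, and stops at the first level where any
ΔI_j > L_Δ. The recommendation is that level minus one — the largest
level that did not surpass the threshold — so 0 is a valid outcome
meaning "do not augment". If no level up to `max_level` (default 10)
exceeds, the recommendation is `max_level` with a `capped` flag. The
threshold is computed once from the baseline rather than re-estimated
per level; re-estimation would let the cutoff drift upward with the
very inflation it is meant to detect.

The final augmentation is performed on the dataset *without* the
engineered columns: the controls are scaffolding for the decision, not
part of the delivered data.

All stage seeds derive deterministically from one master seed via
`numpy.random.SeedSequence`, so a single integer reproduces an entire
run.

## Evaluation

Per-variable significance uses Welch's two-sample t-test (two classes)
or one-way ANOVA (more), without multiplicity correction; variables
with zero variance in every class get p = 1 and a flag. The agreement
between significance and selection is Kendall's tau-b (tie-corrected —
selection counts tie heavily) between the p-values and the
counterpart-corrected frequencies count(X_j) − count(X_j_perm). A
strongly negative tau means significant variables are also the
frequently selected ones; the correlation is reported as absent when
either vector is constant.

## Synthetic benchmark data

Three generators provide ground-truth fixtures for every stage:

* **chainlink** — two classes of 500 points each, uniform over the
  volume of two orthogonally interlinked tori (minor radius 0.1, major
  radius 1.0; the second ring's center sits on the first ring's
  circle). Exercises structure learning with a geometry no plane can
  separate. Surface-uniform sampling is an option.
* **ascending** — 50 Gaussian variables (sd 1, n = 10 per class by
  default) whose class-1 and class-2 means ramp linearly from 1 to 50
  and from 1 to 40 respectively, so the class difference grows from 0
  to 10 sd across the variable index. Ground truth for ordering
  preservation.
* **no_effect** — 50 variables where both classes draw from the same
  N(μ_i, σ_i), μ_i integer-uniform on {10,…,30}, σ_i uniform on
  {1.00, 1.01, …, 3.00}; candidates are generated in batches of 4·n_v
  (at most 50 batches) and only those with a Welch t-test p ≥ 0.6 are
  retained, then n_v are subsampled. A stringent null for
  false-positive control.

What these fixtures do *not* emulate: real biomedical tables mix
scales and units, contain skewed and integer-coded variables,
correlated blocks, and missingness. Passing the suites shows the
machinery behaves correctly under known ground truth (no false alarms
on a true null, ordering preserved under a graded signal); it does not
certify any particular real dataset, where the stopping criterion must
be recomputed from that dataset's own controls.

## Problem sizes used by the test suite

The repeated-run suites run at a reduced scale chosen for the package's
test budget: selection runs use 12 Boruta iterations and 64 trees
(defaults: 100 and 500); the null-safety suite follows the reduced
conditions R = 20 runs and n_bootstrap = 10⁴ across 20 master seeds
with ESOM lattices of 20 × 30; the ordering suite uses R = 100 runs at
augmentation levels 1 and 5. At this scale a confirmation requires 11
hits in 12 iterations (binomial, alpha 0.01), which is conservative;
the qualitative behavior — no exceedances on null data at 1×, preserved
ordering with strongly negative tau on graded data — matches the
full-scale defaults.

## Known limitations

* The critical radius degrades to the median Gabriel height on
  cluster-free data; that fallback is flagged but still heuristic.
* OOB permutation importance uses one shared permutation per feature
  per iteration (evaluated per tree on OOB rows), a common
  approximation to per-tree permutation.
* The bootstrap threshold resamples selection counts rather than
  re-running selection per resample; with few variables the count
  vectors are short and L_Δ is coarse (it moves in steps of whole
  counts).
* Only numeric tabular data with a categorical target are supported;
  categorical feature synthesis, density-weighted (P-matrix-guided)
  per-region sampling rates, and train/validation splitting before
  augmentation are out of scope (the last is recommended practice left
  to the user).
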