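# Methods

This note records the statistical model behind `thresher`, the numerical
choices that are not forced by the model, and what the simulation-based
tests do and do not demonstrate.

## Data model and orientation

The unit of analysis is a real matrix with **variables in rows** and
**objects in columns**; the objects are what gets clustered.  All three
stages operate on the **objects' Pearson correlation matrix**, i.e. each
object column is centred and scaled across the variables before the SVD.
This makes the analysis invariant to per-object location and scale, which is
the right invariance when correlation is the similarity of interest, and it
removes any shared per-object mean offsets (a simulated mean vector, a batch
offset) that would otherwise masquerade as a rank-one component.  Notably,
the pipeline does *not* centre each variable across objects: when a single
correlated block spans most of the objects, the per-variable mean *is* the
shared signal, and subtracting it destroys exactly the structure the method
is looking for.  A row-wise `standardize` is still provided in
`thresher.data` as an ingestion utility for heterogeneous variables; it is
orthogonal to (and redundant with) what the PCA stages do internally.

## Stage 1 — number of significant components

For eigenvalues λ₁ ≥ … ≥ λ_K (K = min(n, P); numerically zero eigenvalues
are excluded as candidates since the residual model's tail mean would
vanish) the profile log-likelihood of "top d eigenvalues free, remaining
equal to their mean" is

    L(d) = −(n/2) [ Σ_{j≤d} ln λ_j + (K−d) ln( mean_{j>d} λ_j ) ].

With a prior penalty θ on dimension, the MAP dimension
d̂(θ) = argmax_d L(d) − θ·n·d is a nonincreasing step function of θ whose
breakpoints are slopes between vertices of the upper convex hull of
(d, L(d)/n); they are computed in closed form.  The **step length** of a
candidate dimension is the width of its θ-interval; dimensions that are
never MAP-optimal have length zero.

Dimension 0's interval is unbounded above and must be truncated to give it a
finite length.  We truncate at a **null-referenced width**: the largest
last-breakpoint observed among five white-noise matrices of the same shape
(a fixed-seed parametric bootstrap, cached per shape), scaled by
`NULL_WIDTH_FACTOR × K/2` with `NULL_WIDTH_FACTOR = 3.25`.  Under the
TwiceMean rule below, the effective cutoff then sits just above the largest
step that sampling noise alone can generate for that matrix shape, so
isotropic data reliably selects D = 0 while weak signals survive.  The
factor was calibrated once, against the published cutoff-selection table and
the noise/signal selection rates; the methods-level trade-off is explicit:
larger values are more conservative (noise → 0) and smaller values recover
weaker signals.

Two automated rules split the steps into "long" and "short":

* **TwiceMean** (default): a step is long when its length is at least twice
  the mean step length.  The mean runs over *all* candidate dimensions
  (zeros included), which keeps the cutoff stable when the MAP path happens
  to visit few dimensions.
* **CPT**: the step lengths are sorted and a single most-likely change in
  mean is sought (at-most-one-changepoint, squared-error cost); the change
  is accepted when the mean-shift statistic scaled by the null variance
  exceeds an MBIC-style penalty `3 ln m`.  Steps above the change are long.

D is the largest dimension with a long step, 0 if none qualifies.  Because
L(d)/n and the breakpoints do not depend on n beyond scale, D is identical
for a matrix and its transpose.

## Stage 2 — loading lengths and outliers

Objects are represented by the **weights they contribute to the
components**, not by their projected scores.  The loading vector of object j
on the first D components is the j-th row of V·diag(√λ) restricted to D
columns (V = eigenvectors of the objects' correlation matrix).  Entry (j, k)
is then the correlation between object j and the k-th component score, so
the squared length Δ² is the object's **communality** — the fraction of its
variance explained by the first D components — and Δ ∈ [0, 1] on every
dataset, which is what makes one fixed cutoff transferable.  Objects with
Δ < 0.3 (strict) are outliers; the default 0.3 reproduces the calibration
protocol's operating point (retain-TPR ≈ 0.995, retain-FPR ≈ 0.004).  Raw
(unit-norm) eigenvector entries are available via `scale="unit"`; with them
a fixed absolute cutoff is *not* meaningful across dataset sizes
(Σ_j Δ_j² = D forces typical entries toward 1/√P), so they are exposed for
diagnostics only.

## Stage 3 — clusters on the hypersphere

After filtering, D₀ is re-estimated on the retained objects and their
loading vectors are normalised to unit length.  Directions are modelled by a
mixture of von Mises–Fisher distributions with density
C_d(κ)·exp(κ⟨μ, x⟩), C_d(κ) = κ^{d/2−1} / ((2π)^{d/2} I_{d/2−1}(κ)),
evaluated with exponentially scaled Bessel functions for stability at large
κ.  EM details:

* initialization by spherical k-means++-style seeding; best of `n_starts`
  (default 10) random restarts;
* M-step: μ = normalised weighted resultant; κ starts from the Banerjee
  closed form (r̄d − r̄³)/(1 − r̄²) and is Newton-refined to the exact root
  of A_d(κ) = r̄ — the closed form alone is not an exact maximiser and can
  produce ~1e−6 likelihood dips, while the refined update keeps the
  log-likelihood monotone to machine precision;
* κ is capped at 1e5 (point-mass bundles) and floored at 0; convergence at
  relative log-likelihood change < 1e−8 or 200 iterations; a component whose
  responsibility mass collapses restarts the run.

The number of clusters N is searched over **N = D₀ … 2·D₀ + 1** (clipped to
[1, P₀]) and chosen by minimum BIC = −2·logL + (N·d + N − 1)·ln P₀, where d
is the embedding dimension and P₀ the number of retained objects; ties break
toward the smaller N.  The doubled upper range exists because anticorrelated
halves of one signal point in opposite directions and should be counted as
two clusters; the +1 absorbs the degenerate D₀ = 0 case, which
short-circuits to a single cluster without fitting.

One embedding subtlety: a vMF mixture needs at least a circle.  With
D₀ = 1 the normalised loadings degenerate to the two points {−1, +1}, where
a two-component mixture is likelihood-equivalent to one component with free
κ and can never win by BIC.  The pipeline therefore embeds in
max(D₀, 2) loading dimensions (capped at the matrix rank) while keeping the
search range tied to D₀.  The second coordinate is a within-block contrast
eigenvector, so for a signed one-dimensional signal the selected N is ≥ 2
essentially always, with exactly 2 modal and 3 a frequent alternative — the
antipodal halves are never merged, but their internal contrast is sometimes
resolved as a third direction.

## Synthetic data

`sample_mvn` draws each variable row i.i.d. from MVN(μ, Σ) with
Σ = σ²·corr (σ² = 1) and μ drawn once per dataset, standard normal per
object.  The correlation matrix is block structured: within a block
corr = s_j s_k ρ_b (s = ±1; a *signed* block negates its second half),
between blocks a constant, noise objects uncorrelated.  Implied matrices are
eigenvalue-checked for positive semidefiniteness before sampling.

The **cutoff-calibration protocol** draws, per dataset: number of variables
~ round N(300, 60) floored at 30; an even object count uniform on
{10, …, 20}; one correlation strength ~ N(0.5, 0.1) truncated to
(0.05, 0.95); one of five signal kinds (one or two independent signals, each
unsigned or signed — the five distinct combinations up to symmetry); and two
appended standard-normal noise objects (mean zero — they play the outlier
role).  "Roughly in half" splits are ⌈P/2⌉ vs ⌊P/2⌋.

Sixteen **preset block structures** cover noise-only, single and multiple
unsigned blocks at within-correlations 0.8/0.3 and between-correlations
0.3/0.1/0, noise-heavy variants, and signed/mixed variants at ±0.8/±0.3, at
24 or 96 objects.  Presets 1–3 are exact by construction; the block
partitions of presets 4–16 are this package's documented defaults
(equal-size blocks; `approximate=True` on the spec) because only their
qualitative layout is pinned down.

What the simulations do **not** emulate: non-Gaussian marginals, heavy
tails, variable-specific variances, correlated noise objects, missing data,
and any real measurement process.  Passing these tests shows the method
recovers planted block-correlation structure at realistic sizes; it does not
certify behaviour on real expression data, where the practitioner should
inspect the Δ distribution and the BIC-vs-N table in the result record.

## Problem sizes and determinism

The acceptance script uses 500 datasets per protocol kind (2 500 total,
matching the calibration's published scale), 500 replicates per noise-heavy
structure and 150 per cluster-count structure; the test suite uses 100–200
replicates per check.  All randomness flows through
`numpy.random.Generator` seeded from user input; the same data and seed give
bit-identical results.  The white-noise bootstrap inside the step-function
construction uses its own fixed generator keyed by matrix shape, so the
dimension estimate is a deterministic function of the data.

## Known limitations

* Independent noise objects are genuine one-dimensional structure in a
  correlation matrix; with many variables, a noise object's eigenvalue
  (≈ 1) can stand above a signal-shrunken residual bulk and be selected into
  D, giving that object Δ ≈ 1 and a false "retained" call (~0.5–1% of
  protocol noise objects; the published calibration shows the same flat
  false-positive tail at about half that rate).
* Two-object blocks are usually judged dimensionless against the noise
  null; the method is not designed to certify clusters of fewer than ~3
  objects.
* Near-duplicate objects create near-zero residual eigenvalues that inflate
  the profile likelihood of high dimensions; deduplicate before running.
* The CPT rule is a bespoke at-most-one-changepoint implementation; it is
  deliberately conservative on short step sequences.
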