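# Methods

## Model and assumptions

The classifier is a feed-forward network φ_W over embedded genotypes:
input dimension k (the embedding size), two relu hidden layers of 100 units,
and a softmax output over the c population classes.  The training objective
is the squared error of the softmax outputs against one-hot labels,
C_W(X′, Y) = ‖φ_W(X′) − Y‖²₂ (cross-entropy is available behind the
`loss="cross_entropy"` flag; it changes both training and the perturbation
gradients, so squared error is the default everywhere).

The method assumes the population signal is linear enough to survive a
truncated SVD of the *raw, uncentered* dosage matrix.  No centering or
scaling is applied before the SVD; an uncentered genotype matrix therefore
yields a dominant first component that is essentially the panel-wide allele
frequency profile (nearly constant across individuals) with the population
structure in later components.  This is deliberate fidelity to the method's
design rather than PCA convention; a column-centering option is available on
`fit_svd` callers by centering the matrix beforehand, but nothing in the
package does so by default.

## The three steps

1. *Weight learning.*  Adam on minibatches of 32, learning rate 1e−3,
   up to 200 epochs, early stopping when the epoch training loss fails to
   improve by 1e−8 for 20 consecutive epochs.  These optimizer settings are
   conventional defaults — the method itself does not prescribe them — and
   all are exposed in `TrainConfig`.
2. *Input perturbation.*  Targeted iterative FGSM toward each sample's true
   class with the trained weights frozen.  Defaults: M = 10 iterations, step
   ε = 0.01 × the per-column standard deviation of the embedded training
   matrix.  The per-column scaling is a deliberate choice: embedded features
   are not standardised and their scales differ by orders of magnitude
   across SVD components, so a single absolute ε would either do nothing to
   the first component or destroy the last.  An absolute scalar ε is
   supported for experiments.  sign(0) is defined as 0.  The optional
   `loss_plateau` stop rule accepts a step only if it improves the training
   loss by at least `plateau_tol`, so a rule that fires immediately leaves
   the inputs — and therefore every downstream artifact — exactly at the
   baseline.
3. *Projection recovery.*  min_V ‖X·V − X′*‖²_F solved by LAPACK's gelsd
   (SVD-based) driver, which returns the minimum-norm solution.  With
   m ≫ n the system is underdetermined and the solution interpolates:
   X·U* = X′* to machine precision, so the training-side accuracy through
   U* equals the accuracy on X′* exactly.  Minimum-norm is the natural
   selection rule here: it is unique, stable, and reproduces U^k exactly
   when X′* is the unperturbed embedding (U^k's columns lie in the row space
   of X).  Singular values below 1e−12·σ_max are truncated, with a warning
   on severely rank-deficient inputs.

Evaluation modes: **MLP** scores frozen W* on X_test·U^k; **MLP-IP** scores
frozen W* on X_test·U*; **MLP-IP-R** re-trains on X_train·U* before scoring
on X_test·U*.  Re-training warm-starts from W* by default
(`retrain_init="from_scratch"` re-initialises instead): the warm start
matches the idea of *re*-training an already-good classifier on its improved
embedding, and X·U* is the matrix that exists at test time.

## Numerical choices

* **Input standardisation inside the classifier.**  `MLPModel` carries an
  optional fixed (non-trainable) affine input transform (x − μ)/σ fitted on
  the embedded training matrix.  Without it, squared-error training fails
  outright: uncentered embeddings have coordinates with large nearly-constant
  offsets (~80 for the first SVD component of the desk-scale panel, ~10³ for
  every histogram column), the softmax saturates, and the MSE gradient
  underflows to exactly zero in float64.  The transform is part of the model,
  so input gradients (and hence IFGSM and the recovered U*) are still taken
  with respect to raw embedding coordinates via the chain rule.  It changes
  the optimisation geometry, not the function class.
* **SVD sign convention.**  Each basis column is flipped so its
  largest-magnitude entry is positive, removing the inherent sign ambiguity
  and making fits bit-reproducible.  For degenerate (tied) singular values
  any orthonormal basis of the invariant subspace is acceptable; tests
  compare subspace-level quantities there.
* **Argmax ties** resolve to the lowest class index (classes are ordered
  lexicographically by code, fixing confusion-matrix layout across runs).
* **Missing genotypes** are imputed at read time, per variant, with the mode
  of the observed calls (ties toward the lower dosage), or zeros via
  `impute="zero"`.  Imputation happens when a file is read — before any
  train/test split — which keeps readers self-contained; panels simulated
  in-package have no missing calls.
* **Stratified splitting** draws round(class_n × test_fraction) test samples
  per class (at least 1, at most class_n − 1) with a seeded generator;
  singleton classes are rejected with advice to merge or drop them.
* **Determinism.**  All randomness flows through named integer seeds (panel,
  split, init, train); with single-threaded BLAS two identical runs produce
  byte-identical metric files.  Multi-threaded BLAS may reorder reductions;
  agreement is then up to floating-point noise.

## The synthetic panel

`simulate_panel` draws Balding–Nichols genotypes: ancestral frequencies
uniform on [0.05, 0.95] (avoiding near-monomorphic, signal-free variants),
population frequencies Beta-distributed around them with variance F·p(1−p),
dosages Binomial(2, q).  Defaults — 6 populations × 100 samples, 5000
variants, F = 0.1 — are the desk-scale study condition used by the tests and
the acceptance script: large enough for the SVD to capture structure,
small enough that a full three-mode run takes ~2 s.

What the simulator does *not* emulate: linkage disequilibrium (variants are
independent), admixture, related individuals, demographic history, sex
chromosomes, genotyping error or missingness.  Passing tests therefore show
the method behaves as designed under clean allele-frequency differentiation;
they do not certify performance on real panels, where LD and admixture
blur class boundaries.  One consequence shows up directly in the test suite:
with 5000 independent SNPs even F = 0.01 separates six populations
perfectly (the between-population mean separation is ~9σ; the detectability
threshold scales as 1/√(nm)), so held-out accuracy saturates at 1.0 across
the F range the tests exercise, and accuracy-based difficulty comparisons
between F = 0.25 and F = 0.01 tie at the ceiling.  The
`expected_separability` statistic — which estimates F itself — is the
monotone difficulty measure the package exposes instead.

## Problem sizes

Unit tests run on panels of 90–600 samples and 300–5000 variants; the
acceptance script uses the standard fixture (600 × 5000) with five seeded
replicates per embedding kind, chosen so a full run completes in well under
a minute on one CPU.  The method itself scales to chip-sized inputs
(n ~ 3×10³, m ~ 3×10⁵): the SVD is economy-sized (O(n²m)), and the
least-squares recovery reuses the same factorisation cost.

## Known limitations

* The squared-error-on-softmax loss is flat wherever the softmax saturates;
  training escapes only because of the input standardisation above.  Very
  badly scaled custom embeddings could still stall it.
* The recovered U* is not orthonormal (it is not meant to be); downstream
  uses that assume an orthonormal projection should re-orthogonalise.
* IFGSM with a fixed iteration count does not guarantee a loss decrease for
  a given ε (the sign step can overshoot); the `loss_plateau` rule gives a
  monotone variant.
* `read_vcf_dosages` loads the full dosage matrix densely; for chip-scale
  VCFs memory is the binding constraint (~1 GB per 3×10⁸ genotypes at int16).
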