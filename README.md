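# snpclassify

Ancestry classification from SNP genotype matrices with a perturbed-projection
neural classifier.

## The problem

Genotype panels encode each individual as a vector of dosages over m biallelic
SNPs (homozygous reference = 0, heterozygous = 1, homozygous alternate = 2).
Panels such as the 1000 Genomes high-density chip release have m in the
hundreds of thousands but only a few thousand individuals, so a classifier
trained on raw genotypes overfits badly.  The standard remedy is to project
the data into a low-dimensional space first; this package implements a method
that goes one step further and *improves the projection itself* using the
trained classifier's gradients.

## The method

Given a training matrix X ∈ ℝ^{n×m} of dosages and one-hot population labels
Y over c classes:

1. **Embed.**  Take the top-k right singular vectors of X (equivalently the
   top-k left singular vectors of Xᵀ) as a projection basis U^k ∈ ℝ^{m×k} and
   form X′ = X·U^k.  Alternatively, use the per-class histogram basis: for
   each SNP and each class, the training proportions of dosage 0/1/2, an
   m×3c matrix (m×78 for 26 populations).
2. **Train.**  Fit a multilayer perceptron φ_W (two relu hidden layers of 100
   units, softmax output) by minimising the squared error
   C_W(X′, Y) = ‖φ_W(X′) − Y‖²₂, giving weights W*.
3. **Perturb the inputs.**  With W* frozen, move each embedded training row
   z_i toward its own (true) class by targeted iterative FGSM:
   z_i^{(m)} = z_i^{(m−1)} − ε·sign(∇_{z_i} C_{W*}(z_i^{(m−1)}, y_c)),
   for M iterations, producing X′*.  Every coordinate moves at most ε·M.
4. **Perturb the projection.**  Solve U* = argmin_V ‖X·V − X′*‖²₂.  With
   m ≫ n the system is underdetermined; the minimum-norm least-squares
   solution is used, which reproduces U^k exactly when X′* is unperturbed.

Held-out samples are then scored three ways: through U^k with W* (**MLP**),
through U* with frozen W* (**MLP-IP**), and through U* after re-training
from W* (**MLP-IP-R**).

Because no public genotype download is assumed, the package ships a
Balding–Nichols panel simulator: per-variant ancestral frequencies p are
drawn uniformly, population frequencies q_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
(so Var q_k = F·p(1−p)), and dosages are Binomial(2, q_k).  The divergence
parameter F is an Fst analogue and the single difficulty knob.

## Worked example

```python
from snpclassify import PopulationModel, RunConfig, run_pipeline, simulate_panel

# a deliberately hard panel: 5 populations, 40 samples each, 500 SNPs, F = 0.01
gm, labels = simulate_panel(
    PopulationModel(n_populations=5, samples_per_population=40,
                    n_variants=500, divergence=0.01, seed=9))
res = run_pipeline(RunConfig(k=15, split_seed=0, init_seed=0, train_seed=0),
                   gm, labels)
```

Running `python examples/04_perturb_projection.py` (the same computation)
prints:

```
training loss before perturbation: 0.0820
training loss after  perturbation: 0.0085
projection-recovery residual ||X U* - X'*||_F: 4.25e-13

MLP      (baseline, U^k): held-out accuracy 0.550
MLP-IP   (frozen W*, U*): held-out accuracy 0.625
MLP-IP-R (re-trained, U*): held-out accuracy 0.575
```

The targeted perturbation drives the training loss down by an order of
magnitude, the recovered projection interpolates the perturbed embedding
essentially exactly (residual ~1e−13, since m ≫ n), and scoring held-out
individuals through the perturbed projection raises accuracy over the
baseline.  On easier panels (the default F = 0.1 desk-scale fixture) all
three modes saturate at accuracy 1.0.

The other scripts in `examples/` walk through the simulator, the SVD
spectrum, plain training, and the per-class histogram embedding.  A thin CLI
wraps the same library calls:

```sh
snpclassify simulate --out-prefix panel -k 6 -n 100 -m 5000 -f 0.1 --seed 0
snpclassify run-all --matrix panel.genotypes.npz --labels panel.labels.tsv \
    -k 20 --out-dir run/
snpclassify sweep --matrix panel.genotypes.npz --labels panel.labels.tsv \
    --ks 10,20,50 --out-dir sweep/
```

Real data enters through `read_plink_raw` (PLINK additive-recode text) or
`read_vcf_dosages` (VCF GT fields), plus a two-column sample→population TSV.

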