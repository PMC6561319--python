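# stresstox

Analysis toolkit for bacterial chemical-stress proteomics: differential
protein abundance from label-free (LFQ) intensities, probabilistic
inference of transcription-factor (TF) activity changes through a binary
regulon-membership matrix, regulator-network export, and enzyme-kinetics
parameter estimation with jackknife error propagation. It was built
around the analysis of an *E. coli* vanillin-stress study (aldehyde
toxicity, oxidative stress response, and detoxification by the aldehyde
reductases YqhD/DkgA), but every stage is generic over a two-condition
LFQ design.

Because this kind of study's raw data is large and external, the package
ships a first-class synthetic-data module that generates inputs with the
same statistical structure (log-normal intensities, intensity-dependent
missingness, regulator-driven group effects, proportional-noise enzyme
rate curves), so every stage is testable against a known ground truth.

## The statistics at the core

**Differential abundance.** Proteins with fewer than 3 valid LFQ values
in both groups are removed; intensities are log2-transformed and
median-centred; missing values are drawn from a downshifted normal
(width 0.3, downshift 1.8, in per-sample SD units), modelling
left-censored dropout. Each protein is tested with the moderated
statistic

    d_i = (x̄_treated − x̄_control) / (se_i + s0),      s0 = 1

where `se_i` is the pooled two-sample standard error. The null comes
from group-label permutations (all 70 assignments are enumerated for a
4-vs-4 design, making the test deterministic); permuted |d*| are pooled
across proteins and the q-value of protein *i* is the mean permuted
count of |d*| ≥ |d_i| over the observed count of |d| ≥ |d_i|, clipped
to 1 and monotonized. Significance is called at permutation FDR 0.05.

**TF activity inference.** Observed fold changes y_g are modelled as

    y_g = Σ_t X_gt · b_gt · c_t + ε_g,   ε_g ~ N(0, τ⁻¹)

with X the binary connectivity, c_t the latent activity change of
regulator t (prior N(0,1)), b_gt the couplings (prior N(0,1)) and τ a
shared noise precision (Gamma prior). A fully factorized variational
approximation q(c)·q(b)·q(τ) is optimized by closed-form coordinate
ascent; the ELBO is tracked and must be non-decreasing. Regulators with
|posterior mean| ≥ 2 posterior SD are called altered.

**Enzyme kinetics.** Initial rates from absorbance slopes (with
co-chromophore correction where substrate and reporter absorb at the
same wavelength), unweighted least-squares Michaelis–Menten fits with
log-parameterized positivity, kcat = Vmax·MW·10⁻³, and leave-one-out
jackknife standard errors for kcat/Km, which respects the correlation
between kcat and Km estimated from the same curve.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_differential_abundance.py
python analysis/03_tf_activities.py
python analysis/04_regulator_network.py
python analysis/05_enzyme_kinetics.py
```

prints, among other lines:

```
1000 proteins x 8 samples, 14.6% missing cells, 8 altered regulators planted
892 proteins tested after filtering; 123 significant at FDR 0.05 (48 up, 75 down)
40 regulators x 774 observed targets (0 regulators dropped); converged=True in 74 sweeps
160 edges between 11 altered regulators and 123 significant proteins
  WT     kcat/Km =   1506 min^-1 mM^-1 (printed 1506)
simulated assay (5% noise): Km = 158 +/- 10 uM, Vmax = 4.88 +/- 0.09 umol/min/mg, kcat/Km = 1477 +/- 79 min^-1 mM^-1
```

That is: the simulator plants 8 altered regulators in a 1000-protein
4-vs-4 experiment; after filtering, 892 proteins are testable and 123
are flagged at FDR 0.05; the variational model converges and recovers
the planted regulators (the called set includes all 8 planted ones; the
extras reflect signal leaked through imputation and filtering, see
`docs/methods.md`); the kinetics module reproduces the printed
catalytic-efficiency table exactly and recovers Km = 154 µM / Vmax =
4.8 µmol·min⁻¹·mg⁻¹ to within noise from a simulated assay.

The same pipeline runs on real MaxQuant-style inputs through the CLI:

```bash
stresstox diff --in proteinGroups.tsv --design design.tsv --s0 1 --fdr 0.05 --seed 1
stresstox infer-tf --fold-changes fc.tsv --connectivity regulons.tsv --z 2 --seed 1
stresstox kinetics --in rates.tsv --mw 48000 --jackknife
stresstox run --config cfg.yaml --seed 1 --out results/
```

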