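# Methods

This note documents the models, the defaults and the numerical choices
behind `stresstox`, and what the simulation-based tests do and do not
establish about real data.

## Differential abundance (lfq_stats)

The workflow mirrors the conventional Perseus-style analysis of a
two-group label-free experiment.

**Filtering.** A protein is retained if it has at least `min_valid`
(default 3) observed intensities in *at least one* group. The one-sided
rule deliberately keeps presence/absence proteins: a protein observed in
all treated replicates and none of the controls is biologically the most
interesting case, and imputation supplies the censored group.

**Transform and normalization.** Intensities are log2-transformed
(zeros were already mapped to missing at read time; a non-positive
finite value at this point is a format error, not a quiet fix). Median
centring defaults to per-sample: each sample's median of observed
values is subtracted. A per-group mode (pooled group median) is
selectable; the two coincide when columns in a group share a median.
Per-sample is the default because it removes loading differences
between replicates, which pooled group medians cannot.

**Imputation.** Missing values in a sample are drawn from
N(m − 1.8·s, (0.3·s)²), where m and s are the mean and SD of that
sample's *observed* values. The downshift places imputed values in the
low-intensity tail, consistent with left-censored dropout; the narrow
width keeps imputed values from dominating group variances. Statistics
are computed per sample, not matrix-wide, so a sample with an intensity
offset imputes on its own scale. The seed is part of the configuration:
imputation is replayable bit for bit.

**Testing.** The moderated statistic is
d = (mean difference)/(pooled SE + s0) with s0 = 1 by default. The s0
offset damps proteins whose tiny pooled SE would otherwise make a
negligible difference look significant — at log2 scale, s0 = 1 means a
protein needs roughly a 2-fold difference to reach |d| near 1
regardless of how small its variance is. The null distribution
enumerates all distinct group-label assignments when there are at most
10,000 (a 4-vs-4 design gives C(8,4) = 70, so the test is fully
deterministic there) and falls back to seeded random assignments
otherwise. Permuted |d*| values are pooled across proteins (they share
a common null scale after the s0 moderation), and

    q(i) = [mean permuted #{|d*| ≥ |d_i|}] / #{observed |d| ≥ |d_i|}

clipped to 1 and monotonized from least to most significant. Ties in
|d| are broken by protein identifier so ranking is deterministic. Two
consequences worth knowing:

* q is invariant to the overall scale of d. In the s0 → ∞ limit the
  procedure becomes a plain mean-difference permutation test; it does
  not drive all q to 1.
* With 70 permutations and n proteins, the smallest attainable q is
  about 1/(70·n/n) per rank; on very small matrices (tens of proteins)
  the q granularity is coarse, which the tests account for.

A constant-everywhere matrix is rejected with an explicit error: the
statistic carries no information there and silently returning d = 0
would mask an upstream processing bug.

**Fold changes** are 2^(mean difference of imputed, normalized log2
values), reported as a fold increase when ≥ 1 and as the reciprocal
fold decrease otherwise — the presentation used in printed abundance
tables. Computing the ratio from log-averaged intensities (a geometric
mean on the linear scale) is fixed behavior and documented here because
arithmetic-mean ratios would differ.

## Synthetic data (synthetic_data)

The generator produces the structure the pipeline assumes, not a
facsimile of any particular instrument run:

* per-protein log2 baselines ~ N(25, 3²) — typical label-free
  magnitudes;
* a binary connectivity matrix with i.i.d. Bernoulli(density) entries
  (empty regulator columns resampled);
* regulator activities: `n_altered_tfs` of them ~ N(0, 1²) resampled
  until |value| ≥ 0.5 so planted effects are detectable, the rest
  exactly zero; couplings ~ N(1, 0.2²) on edges (activator-dominant);
* the treated group shifted by the exact connectivity-weighted effect;
  replicate noise N(0, 0.25²);
* dropout with probability logistic(−slope·(x − midpoint)), defaults
  midpoint 21 and slope 1 per log2 unit, i.e. ~50% dropout at 4 log2
  units below the mean baseline and ~14% of cells missing overall —
  the simplest monotone missing-not-at-random model consistent with
  left-censored imputation.

Defaults are 1000 proteins, 40 regulators, density 0.05, 8 altered
regulators, 4 replicates per group. A direct per-protein effect mode
(`direct_ground_truth`) bypasses the regulator structure for isolated
tests of the differential stage.

What the simulator does **not** emulate: peptide-level quantification
and roll-up, match-between-runs artefacts, correlated (batch)
missingness, heavy-tailed intensity noise, and regulon overlap
structure of a real transcriptional network (edges are independent).
Passing recovery tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not performance
guarantees on any real organism's data.

## TF activity inference (tf_inference)

Model: y_g = Σ_t X_gt b_gt c_t + ε_g with ε ~ N(0, τ⁻¹), priors
c_t ~ N(0,1), b_gt ~ N(0, coupling_prior_sd²) (default 1), and
τ ~ Gamma(10⁻³, 10⁻³) (a vague prior; the posterior is dominated by the
residuals). The unit prior scale on c pins down the multiplicative
b·c indeterminacy.

Inference is coordinate-ascent variational Bayes over the full
factorization q(c)·Π q(b_gt)·q(τ), all updates closed-form
Gaussian/Gamma. Update order per sweep: q(b) column by column (within a
column, targets are independent, so the column update is an exact
coordinate step), then q(c) regulator by regulator, then q(τ). The
fitted mean is maintained incrementally (Gauss–Seidel), which preserves
the CAVI guarantee that the ELBO never decreases; the ELBO trace is
stored and checked in tests at 1e−9 relative tolerance.

Numerical choices:

* initialization: E[c] from ridge regression of y on X with unit
  couplings, plus a seeded N(0, 10⁻⁴) jitter to break exact ties;
  couplings start at 1 (variance at prior variance);
* convergence: relative ELBO change below 1e−8 (default), cap 1000
  sweeps; non-convergence returns the state with a warning flag rather
  than raising, a NaN ELBO raises;
* sign indeterminacy: flipping (c_t, b_·t) jointly leaves the
  likelihood unchanged, so after convergence each regulator's sign is
  fixed to make Σ_g E[b_gt] ≥ 0 — an activator-dominant convention
  that matches the simulator's N(1, ·) couplings;
* single shared τ across proteins by default (the data rarely support
  per-protein precisions at these sample sizes);
* a regulator is "altered" when |posterior mean| ≥ z·SD with z = 2 —
  z is configurable because the cutoff is a reporting decision, not
  part of the model.

Two facts about the factorized approximation that the tests encode
explicitly: mean-field recovers the *means* of a Gaussian posterior
exactly (verified against the analytic conditional with couplings and
τ clamped), but the *marginal variances* are exact only when regulons
are disjoint; with shared targets the factorized variances
underestimate the true marginals. Posterior SDs for overlapping
regulons should therefore be read as lower bounds. Relatedly, the
clamped-coupling exactness test uses a disjoint-regulon design, where
the comparison is an honest equality.

When the model is run end-to-end on simulated LFQ data (rather than on
the direct fold-change output of the simulator), filtering removes some
regulon targets and imputation adds structured noise; the altered set
then typically contains all planted regulators plus a few extras with
small posterior means. The z-threshold trades these off; the recovery
criterion (median over 20 seeds: Pearson r ≥ 0.9, ≥ 7/8 true
positives, ≤ 2 false alarms) is evaluated on the direct path, which
isolates the inference from the quantification pipeline.

## Enzyme kinetics (enzyme_kinetics)

**Rates from slopes.** rate = |slope| / ((ε_reporter +
ε_cochromophore)·path), with ε converted to mM⁻¹cm⁻¹. Adding the
extinction coefficients implements the correction for a species
depleted 1:1 with the reporter (e.g. an aromatic aldehyde consumed
together with NADPH, both absorbing at 340 nm): the observed slope is
the sum of both absorbance losses, so the summed coefficient recovers
the single reaction rate.

**Fitting.** Unweighted least squares of v = Vmax·S/(Km + S),
parameterized as (log Km, log Vmax) so positivity is structural.
Initial values: Vmax₀ = max observed rate, Km₀ = the substrate level
where rates first cross Vmax₀/2. Standard errors come from the
Gauss–Newton curvature at the optimum with the usual residual-variance
estimate, mapped back from the log scale by the delta method.
Weighted fits are deliberately not the default: published initial-rate
curves of this kind are conventionally fit unweighted, and weights
would change the reported SEs without changing the point estimates
much.

**Derived quantities.** kcat = Vmax[µmol·min⁻¹·mg⁻¹]·MW[g/mol]·10⁻³
(dimensional identity; nmol units auto-convert). kcat/Km is reported
in min⁻¹·mM⁻¹ with two reporting styles: `table` truncates to an
integer — the convention that reproduces printed kinetics tables,
whose integers derive from full-precision kcat and Km — and `text`
rounds to 2 significant figures. Raw doubles are always retained. The
enzyme molar mass is an explicit argument everywhere (for the citrate
synthase worked example, a monomer mass of ≈48 kDa makes the
Vmax↔kcat relation consistent).

**Jackknife.** For kcat/Km, each observation is left out in turn, the
curve refit, and the efficiency recomputed; pseudo-values
θ*ᵢ = nθ − (n−1)θ₋ᵢ give the estimate (mean) and SE (SD/√n). This
propagates the strong negative correlation between fitted kcat and Km
automatically, which a naive independent-error formula would miss.
Leave-one-out fits that fail are excluded with a warning; more than 20%
failures aborts. Monte-Carlo checks show the jackknife SE tracks the
true sampling SD of the efficiency within a factor of ~2 at 5%
proportional noise on 9-point curves.

## Problem sizes and tolerances

The simulation studies run at sizes chosen to make their statistical
targets sharp while keeping the whole suite fast on one core: 200 null
experiments of 1000 proteins for the false-discovery calibration, 20
seeds of the (1000 proteins × 40 regulators, density 0.05) recovery
setting, 10⁴ imputed cells for the imputation calibration, 50 datasets
for the jackknife Monte-Carlo check. Exact comparisons (brute-force
permutation oracle, analytic Gaussian conditionals, noiseless round
trips) are made at 1e−12 to 1e−6 as appropriate to the arithmetic
involved.

## Known limitations

* The permutation test needs ≥3 replicates per group to be meaningful
  and is coarse below ~100 proteins (q granularity).
* The activity model is linear and single-contrast; time courses,
  per-condition activities and nonlinear regulation are out of scope.
* Posterior SDs under regulon overlap are mean-field lower bounds (see
  above).
* The connectivity matrix is treated as known and binary; edge
  uncertainty and signed regulation (repressors as negative prior
  couplings) are not modelled — repression is absorbed into negative
  posterior couplings.
* Imputation assumes each sample's observed distribution is roughly
  Gaussian in log2; heavily skewed samples will shift the imputed
  block.
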