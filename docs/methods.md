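# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want spelled
out. Every number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Study design being modelled

A two-genotype feeding study: flies from two *iPLA2-VIA* mutant lines
(one expression-reduced insertion allele, one null deletion) are raised
on control (DMSO) or decanoic-acid food, and metabolite panels are
measured in brain, gut, muscle and whole-fly samples at four ages with
three biological replicates — 2 × 2 × 4 × 4 × 3 = 192 study samples plus
extraction blanks. Lifespan arms hold 150 females each; qPCR runs in
biological triplicate.

## Feature quality control

A metabolite is retained when

1. its intensity is strictly positive in every sample of at least one
   design cell (tissue × genotype × treatment × age) — the finest design
   unit, the most conservative reading of "present in all samples of a
   group"; and
2. its mean intensity across all non-blank samples is ≥ `blank_fold`
   (default 5) times its mean across extraction blanks. A blank mean of
   zero makes the ratio +∞ and the feature passes.

Whether the blank comparison should use means, medians or maxima is a
genuinely open choice; the mean/mean ratio is the simplest symmetric
summary and is written per feature into the filter report so the decision
is auditable. Zeros encode missing measurements throughout. Before
multivariate modelling, intensities are log10-transformed — zeros first
imputed per feature to half that feature's minimum positive value, a
common practice that avoids −∞ while staying below the detection floor —
and then unit-variance scaled per feature (n−1 denominator). The
log-then-scale order is the standard chemometrics order; the two
operations are listed without order in many protocols.

## Per-metabolite inference

Each metabolite in each tissue × genotype is tested by a classical
balanced two-factor ANOVA (treatment × age, with interaction) of its
log10 abundance; significance means interaction *P* < α (default 0.05):
a treatment effect that changes with age. Main-effect p-values are
reported but do not drive the classification. No correction across
metabolites is applied; raw p-values are carried in the output so users
can post-correct.

Only balanced designs are accepted. For unbalanced data the
sum-of-squares decomposition is ambiguous (Type I/II/III), and a silent
choice is a classic source of irreproducibility; since the emulated
design is balanced by construction, unbalance is a hard error. The
decomposition is computed directly from cell and marginal means
(vectorised across metabolites); it agrees with `statsmodels.anova_lm`
to 1e-9 relative and satisfies SS_treatment + SS_age + SS_interaction +
SS_residual = SS_total to the same tolerance. Degenerate one-level
factors are permitted (their SS is zero), in which case the remaining
factor's F equals the squared pooled two-sample t statistic.

Tukey's HSD runs across all treatment × age cell means
(q = |mᵢ − mⱼ| / √(MS_resid/n)), with the within-age treatment contrasts
— the comparisons figure panels annotate — written to their own table.
The studentized-range survival function comes from
`scipy.stats.studentized_range`; for the large batches in the pipeline a
cached monotone (PCHIP) interpolant over an 801-point grid of the exact
values is used, accurate to ~1e-6, while direct calls (k = 2 reduction
tests and small batches) use exact quadrature.

The univariate route gates on Shapiro–Wilk at α per group: both normal →
unpaired two-tailed Welch t (the default of R's `t.test`, the environment
these tests are usually run in); otherwise the two-sided Mann–Whitney
test, exact enumeration for n ≤ 20 without ties and the tie-corrected
normal approximation above. All values tied in both groups returns p = 1
with a warning flag.

## PLS-DA and validation statistics

PLS-DA is NIPALS PLS2 on the preprocessed matrix against a one-hot,
column-centred class matrix, deflating X and Y per component
(convergence tolerance 1e-12, 500-iteration cap, non-convergence is an
error naming the component). NIPALS was chosen over SIMPLS/kernel
variants because its per-component deflation gives exactly the residual
sums of squares the cumulative Q² definition needs.

Cross-validation is K-fold (default sevenfold), random, stratified by
class, seed-controlled; each fold's model is centred on its own training
data. Per component a, PRESSₐ sums squared out-of-fold Y errors of the
a-component model, and

Q²(cum) = 1 − ∏ₐ PRESSₐ / SSₐ₋₁,

where SSₐ₋₁ is the residual Y sum of squares after a−1 components on the
full data — the product convention of SIMCA-lineage software. The simpler
global 1 − PRESS_A/SS₀ is available (`q2_rule="global"`). When the
component count is not specified it is chosen to maximise Q²(cum), capped
at 5.

CV-ANOVA tests the model: F = ((SSY − PRESS)/A) / (PRESS/(n − 1 − A)) on
(A, n − 1 − A) degrees of freedom, with p = 1 whenever PRESS ≥ SSY.
An important, measured property: because cross-validated prediction error
under the null typically *exceeds* the total Y variation, the permutation
null distribution of CV-ANOVA p-values carries a large atom at 1 (~86%
of permutations at A = 1, n = 40 in our simulations) — the test is
strongly conservative, not uniformly calibrated. Tests therefore verify
conservativeness (null rejection rate at 0.05 below nominal), high Q² and
tiny p on separated classes, and near-zero mean Q² under permutation.

## Cross-genotype overlap

With n_total metabolites tested in both genotypes, n_A and n_B
significant per genotype and k significant in both, the default
independence null gives p_single = (n_A/n_total)(n_B/n_total) and the
chance likelihood of the whole overlap is p_single^k (for example,
p_single = 0.1 and k = 10 gives 1e-10, i.e. 0.00000001%). A conditional
mode computes p(A)·p(B|A) when a conditional probability is supplied
externally; it is not the default because estimating p(B|A) from the same
data makes the chain rule an identity rather than a null. The product is
evaluated in log space and reported both linearly and as
`log10_chance_likelihood` (the linear value necessarily underflows once
below ~1e-308). Because p^k ignores the without-replacement structure of
drawing from a finite panel, two diagnostics are attached, never
substituted: a hypergeometric tail P(overlap ≥ k) and a permutation
estimate of the chance that the k observed metabolites would be jointly
significant under within-genotype label shuffles (which matches p^k in
order of magnitude for k ≪ n_A). Percentages are printed at two
significant figures.

## Pathway enrichment

enrichment = observed − expected significant metabolites per (tissue,
pathway), with two conventions for "expected":

- `literal` (default): (sig_in_pathway / total_sig) × measured_in_pathway
  — the size correction exactly as the source protocol words it. Its
  algebra is odd: the expectation depends on the observed count and the
  per-tissue expectations do not sum to total_sig (logged when they
  don't).
- `standard`: (total_sig / total_measured) × measured_in_pathway — the
  uniform-rate expectation, which conserves totals over disjoint covers.

Fidelity argues for defaulting to the literal formula; the flag exists so
users can avoid its artefacts. Pathway membership is intersected with the
measured panel; unmeasured pathways are omitted with a notice;
metabolites in several pathways count in each (KEGG-style double
counting); metabolites in no pathway enter totals but score nowhere. No
p-value is attached to the score — an optional hypergeometric column is
available as a diagnostic.

## Lifespan statistics

Kaplan–Meier product-limit estimation with deaths processed before
censorings at tied times (the standard convention; the underlying assay
does not dictate one). Median lifespan is the smallest event time with
S(t) ≤ 0.5, without interpolation between scoring days; maximum lifespan
is the median death time of the longest-lived ⌈0.1·n_deaths⌉ individuals,
censored flies excluded because their lifespans are unknown (ceiling
rounding keeps the definition deterministic and conservative). The
two-group comparison is the unweighted log-rank chi-squared on 1 df with
the hypergeometric variance at each death time; multi-arm studies run
pairwise against control with unadjusted p, as dose-response assays are
conventionally reported. One measured subtlety: appending an individual
censored after the last death does change the product-limit values (it
enlarges every earlier risk set); what is invariant is that late
censoring adds no drop and its exact time is irrelevant.

## qPCR

Classic ΔΔCt with amplification efficiency fixed at 2 and the arithmetic
mean calibrator ΔCt; per-replicate RQ values are retained so downstream
factorial tests and error bars operate on replicates, not summaries. The
reference gene is checked by a two-way ANOVA of its raw Ct on treatment ×
age; "stable" means no effect p ≤ α, and a perfectly constant reference
short-circuits to stable with p = 1. Note the stability declaration
involves three simultaneous tests, so its null "stable" rate is ≈
(1 − α)³ ≈ 86% at α = 0.05, not 95%.

## Synthetic-data generator

The generator is the package's test bed and defines the conditions under
which its guarantees are demonstrated.

- **Metabolomics.** Per-metabolite log10 baselines are uniform on (3, 6)
  (typical instrument dynamic range); residual noise is Normal(0, 0.1) on
  the log10 scale. A fraction (default 0.2) of metabolites per tissue ×
  genotype is "affected": treated samples gain effect_size (default 0.5,
  i.e. 5× the noise sd) times an age ramp rising linearly from 0 at the
  first age point to 1 at the last. The ramp makes the signal a genuine
  treatment × age interaction — the quantity the downstream test flags —
  rather than a main effect. Cross-genotype overlap of affected sets is
  controlled (default 0.5). Blanks sit at 1/20 of baseline; contaminant
  features sit at blank level in study samples too, giving the filter
  true positives and true negatives. A concentrate mode assigns affected
  metabolites round-robin across designated pathways (excluding members
  that also belong to outside pathways) for enrichment-recovery tests.
  Ages default to days 7, 14, 19, 24, mirroring a first collection at day
  7 with later points 5–10 days apart.
- **Lifespans.** Gompertz mortality h(t) = a·m·e^{bt} — the standard fly
  ageing hazard — with an analytic median log1p(b ln2/(am))/b for
  parameter-recovery tests; defaults a = 2.584e-4/d, b = 0.15/d give a
  40-day control median typical of a short-lived mutant line, n = 150 per
  arm. `multiplier_for_median_ratio` solves for the hazard multiplier
  producing a target median extension (e.g. 13%). Censoring draws a
  uniform time before the latent death.
- **qPCR.** Target Ct = realised reference Ct + calibrator ΔCt −
  log2(true RQ) + Normal(0, sd); the reference well carries its own
  technical noise, which cancels within a replicate's ΔCt, so ΔCt noise
  equals the stated well sd and the zero-noise table inverts exactly.

What the generator does **not** emulate: chromatographic drift, batch or
injection-order effects, missingness mechanisms other than hard zeros,
heteroscedastic (intensity-dependent) noise, correlated metabolite
modules, isotope/adduct redundancy, inter-vial frailty in lifespans, or
amplification-efficiency deviations in qPCR. Passing tests therefore
demonstrate correctness of the statistics under a clean factorial signal
model — not robustness to those real-data pathologies.

## Measured operating characteristics

At the default conditions (all computed in the suite or the acceptance
script): the blank filter removes all injected contaminants and retains
the full genuine panel; interaction detection has sensitivity ≈ 0.93–0.95
with false-positive rate ≈ 0.045–0.063; ANOVA interaction type-I error
0.045 over 1000 null simulations; designated pathways take the top-3
standard-convention enrichment in ≥ 99% of 200 simulated studies;
log-rank null rejection 0.038–0.052 over 1000 simulations at n = 150/arm
and power ≈ 1.0 for a 13% median extension; mean recovered RQ 2.02 for a
true value of 2 at Ct noise 0.2 over 200 studies.

## Determinism and problem sizes

Every generator and every cross-validation split is a pure function of
(config, seed); `run-all` output files are byte-identical across
invocations with equal config and seed (sets are sorted before writing,
floats written at full precision). Simulation sizes in the tests — 1000
null ANOVA/log-rank replicates, 200-seed recovery studies, 200-label
permutations — were chosen to keep the whole suite under a minute of
compute while leaving the binomial acceptance bands decisive.
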