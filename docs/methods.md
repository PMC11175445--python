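# Methods

## Setting

`mrmediate` analyses three GWAS summary-statistics tables — exposure,
mediator, outcome — each giving per-SNP marginal associations
(effect/other allele, effect-allele frequency, beta, SE, p, N) measured in
non-overlapping samples (the two-sample assumption: sampling noise is
independent across tables).  Traits are treated as standardized
(unit variance), so all effects are in SD units per effect allele.

## Instrument selection

Instruments are SNPs with association p below a threshold (default
5×10⁻⁸).  Independence filtering uses integer `ld_block` labels: one SNP —
the lowest-p, ties broken by smallest rsID — is kept per block.  This is a
deliberate stand-in for reference-panel clumping (r² = 0.001 within
10,000 kb): labels can come from any upstream clumping tool, and the
statistical consequence (independent instruments) is what the estimators
need.  A real reference panel is therefore not a dependency.  SNPs missing
from the outcome table may be replaced by LD proxies (three-column map
snp_id / proxy_id / r²); a proxy is admissible when r² > 0.8, and the
highest-r² admissible proxy wins.

Selection-stage p-values missing from the input are recomputed from
beta/SE under a two-sided normal, and p-values inconsistent with beta/SE
(beyond 2-significant-figure rounding) cause the row to be rejected at
read time, as do indels, multi-allelic records, non-positive SEs and
out-of-range frequencies.  Every rejection and drop is logged with a
per-row reason.

## Harmonization

For each SNP shared between two tables the second table is aligned to the
first table's effect allele: identical alleles are kept; swapped alleles
negate beta and complement EAF; strand complements (A/G vs T/C) are mapped
back before the same rule; irreconcilable allele sets are dropped.
Palindromic SNPs (A/T, C/G) cannot be resolved from labels: they are
dropped when the exposure EAF lies inside the ambiguity window (default
[0.42, 0.58], configurable) and otherwise oriented by frequency — if the
two studies' EAFs fall on opposite sides of 0.5 the outcome row is
flipped.  Multivariable harmonization aligns every exposure table and the
outcome to the first exposure's coding over a caller-supplied SNP union.

## Estimators

* **Wald ratio** θ̂_j = β̂_Yj/β̂_Xj with first-order delta SE se_Yj/|β̂_Xj|.
  The SE ignores exposure-side noise (NOME approximation); adequate at the
  instrument strengths the pipeline enforces, anticonservative below F ≈ 10.
* **IVW**: weighted mean of ratios with w_j = β̂²_Xj/se²_Yj, algebraically
  the WLS slope of β̂_Y on β̂_X through the origin with weights 1/se²_Yj.
  Fixed-effects SE (Σw)^{−1/2}; the random-effects variant (the headline
  method) multiplies by max(1, √(Q/(k−1))) — multiplicative
  over-dispersion, floored so homogeneous data fall back to fixed effects.
  Normal-quantile inference.
* **MR-Egger**: SNPs oriented to β̂_X > 0, WLS of β̂_Y on β̂_X with free
  intercept, weights 1/se²_Yj.  The residual scale is floored at 1, the
  same convention as IVW.  Inference uses t with k−2 df — honest at the
  small k common in applied MR; the choice of t over normal is a
  documented convention, not a claim about the reference used elsewhere.
* **Weighted median**: ratios sorted, IVW weights normalized to sum 1,
  cumulative midpoint positions p_j = Σ_{i<j}w_(i) + w_(j)/2, estimate by
  linear interpolation of θ over p at 0.5.  SE by parametric bootstrap:
  β̂_X and β̂_Y redrawn from normals at their reported SEs, default 1000
  replicates, explicit seed required (no hidden global RNG state).
* **MVMR**: WLS of β̂_Y on the (k×p) exposure matrix, no intercept,
  weights 1/se²_Yj; rank-deficient designs are rejected as collinear.
  Residual scale floored at 1 with df = k−p (k−p−1 with the Egger
  intercept, after orienting rows so the first exposure is positive).
  Per-exposure F uses the univariable R² formula summed over the shared
  set; conditional (Sanderson–Windmeijer) F is intentionally not
  implemented — a documented limitation, as the simple formula is what the
  report tables carry.

## Sensitivity diagnostics

Cochran's Q is computed on the ratio scale with the same first-order
weights as IVW — Q = Σ w_j(θ̂_j − θ̃_j)², with θ̃_j the IVW mean (df k−1) or
the Egger line mapped to ratio scale (df k−2) — so the random-effects
inflation and the reported Q are a single computation.  The Egger
intercept test reports the intercept, its SE and a t(k−2) p-value.
Leave-one-out refits random-effects IVW dropping each SNP; a row is
flagged as a driver when the reduced fit changes the sign conclusion of
the full fit (an artifact convention — the underlying study style reports
only the qualitative absence of drivers).  Funnel data pair each ratio
with its precision |β̂_X|/se_Y; rendering is left to the caller.

## Mediation

Two-step MR: β1 (exposure→mediator, on exposure instruments), β2
(mediator→outcome, on mediator instruments; optionally the MVMR-adjusted
mediator coefficient), β3 (total), β3′ (direct, from MVMR on the union of
both instrument sets harmonized across all three tables).  Indirect effect
β1·β2 with Sobel SE; mediator-existence conditions (β1, β3, β2 each
significant at 0.05) reported as flags.

The mediation ratio divides the indirect effect by the total effect, and
two totals are defensible: the directly estimated β3
(`estimated_total`, the default) or the reconstructed β3′ + β1·β2
(`reconstructed_total`).  Both are implemented and the output names the
convention, because the two differ in finite samples and the choice
materially changes the reported percentage.  The ratio's delta-method SE
treats the indirect effect and the total as independent; they share
exposure instruments, so this is an approximation — a seeded parametric
bootstrap is the honest alternative when the ratio is a primary endpoint.

## Synthetic-study generator

Two SNP blocks: an exposure block (effects γ_j on the exposure) and a
mediator block (effects δ_j directly on the mediator, none on the
exposure).  Structural equations per SNP: mediator effect θ_xm·γ_j + δ_j;
outcome effect θ_my·(θ_xm·γ_j + δ_j) + θ_xy·γ_j + α_j·1[j invalid].
Path-tracing gives β1 = θ_xm, β2 = θ_my, β3′ = θ_xy, β3 = θ_xm·θ_my + θ_xy.
The mediator block exists so that the mediator has its own instruments:
without it every mediator instrument would act through the exposure,
univariable mediator→outcome MR would estimate θ_my + θ_xy/θ_xm rather
than θ_my, and the exposure/mediator effect matrix would be exactly
collinear — no mediation analysis would be identifiable.

Effect magnitudes are half-normal, |N(0, sd²)| with sd = 0.1 by default:
the effect allele is by convention the trait-raising allele, which keeps
directional pleiotropy (α_j with nonzero mean on a chosen fraction of
exposure instruments, drawn independently of effect sizes — the InSIDE
regime) directional after Egger's orientation step.  Sampling SEs are the
analytic standardized-trait value 1/√(2N·p(1−p)) (MAF p ~ Uniform(0.05,
0.5)); observed betas add independent N(0, se²) noise per study, or none
in `noise_free` mode, where every estimator must return the path-traced
truth exactly.  Defaults — 50 + 50 SNPs, N = 100,000 per study, θ_xm =
−0.08, θ_my = −0.07, θ_xy = 0.045 — give mostly genome-wide-significant
instruments (F in the hundreds) and stage effects of the size seen in
anthropometric/lipid mediation studies.  Selection is applied by the
pipeline, not baked into generation; with a null true effect this sidesteps
winner's-curse modelling, which is out of scope.

What the generator does **not** emulate: LD between instruments (blocks
are singletons by construction), sample overlap between the three GWAS,
MAF-dependent effect-size architecture, non-collapsibility/binary traits,
and population stratification.  Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated model, not
robustness of MR to those real-data violations.

A companion `corrupt_alleles` operation re-codes a seeded random subset of
rows (allele swap with beta negation and EAF complement, strand
complement, or both) without changing their meaning, returning a
ground-truth log; harmonization must undo every alteration exactly, which
the test suite checks bit-for-bit on the betas.

## Numerical conventions and degenerate inputs

95% CIs throughout; significance at p < 0.05.  Exponentiated
(multiplicative-scale) CIs are exp of the beta-scale bounds; report tables
state their scale in a header comment.  p-values are floored at the
smallest positive double to keep them in (0,1] when z-scores underflow.
Weighted-median bootstrap draws that hit β̂_X = 0 are nudged to the
smallest positive double; IVW with k = 1 refuses and points to the Wald
ratio; Egger with constant exposure betas refuses (slope unidentifiable);
MVMR designs are rank-checked before inversion.  A total effect below
10⁻¹² in magnitude makes the mediation ratio undefined (reported as
missing with a warning) rather than dividing by ~0.  The scalar N in
F-statistics is the median per-SNP N of the exposure column.  All
stochastic steps take explicit seeds; pipeline outputs are
byte-deterministic given configuration and seed.

## Problem sizes used in validation

The test suite validates calibration and recovery at the generator's
default design (50-instrument studies, N = 100,000): 500 replicates for
null calibration (type-I error within [0.03, 0.08], mean Q/(k−1) within
5 % of 1), 200–300 replicates for parameter, MVMR and mediation recovery
(agreement within three Monte-Carlo standard errors of the replicate
mean), and exhaustive/closed-form checks (allele truth table, worked
estimator instances against independent normal-equations oracles) at
machine precision.  These sizes give Monte-Carlo standard errors an order
of magnitude below the effects being recovered while keeping the full
suite to a few minutes on one CPU.
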