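# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the places where the published analysis recipe is ambiguous and
the package had to commit to one reading.

## The pipeline

Per-sample deconvoluted peak lists (RT in minutes, fragment spectrum over
m/z 30–300, integrated area) are aligned into *retention-time ranges* —
clusters of peaks across samples presumed to be one substance — filtered,
normalised to relative areas, and analysed two ways: whole-profile ANOSIM
and a vectorised linear mixed model that screens individual substances.

### Retention-time alignment

* **Batch RT adjustment.** Chromatographic drift between sampling batches
  is corrected by a single per-batch shift: a first, unadjusted grouping
  pass (at a coarser gap tolerance, default 0.2 min, so that offsets up to
  that size still land in shared ranges) finds *anchor* ranges present in
  ≥80% of both the batch's and the reference batch's samples; the shift is
  the negated median anchor RT offset. This is a rigid translation, not a
  warping — adequate for slow drift, not for flow-rate changes mid-run.
* **Gap grouping.** Pooled peaks are sorted by RT and a new range starts
  whenever the gap to the previous peak exceeds `gap_tol` (default
  0.05 min). This is exactly single-linkage clustering cut at `gap_tol`
  (the test suite verifies the equivalence against
  `scipy.cluster.hierarchy`), chosen over fixed-width binning because it
  cannot split a tight peak cloud across a bin boundary. If one sample
  contributes several peaks to a range, the peak closest to the range's
  median RT is kept (ties → larger area) so each cell of the final matrix
  has at most one source peak.
* **Occurrence filter.** Ranges must occur in ≥14 samples (default,
  configurable) to be retained — rare peaks are indistinguishable from
  deconvolution artefacts.
* **Prominent masses and consistency.** Each range's quantification m/z are
  the top-5 fragments by total intensity over member peaks. Where the
  original workflow verified spectral consistency by manual inspection,
  this package uses an automated surrogate: the mean pairwise Jaccard
  similarity of the members' per-peak top-5 fragment sets must reach 0.5.
  Single-member ranges verify by convention. The threshold is exposed; the
  surrogate is deliberately crude and will not reproduce expert judgement
  on borderline co-elutions.
* **Quantification.** Cell value = member peak's summed intensity over the
  prominent m/z, falling back to total peak area when the spectrum has none
  of them. Absent peaks are 0, not missing, because the downstream relative
  area divides by the sum over all included ranges.

### Filters and transforms

Known contaminants (RT window + characteristic m/z, both must match) are
removed first; then a substance is excluded when its mean raw area over
blank samples equals or exceeds the mean over animal samples — ties go to
exclusion, and the aggregator (mean/median) is configurable since the
published rule names no statistic. Blanks leave the table at this point.
Relative areas are 100·area/Σarea per sample (rows sum to 100).

Three response transforms feed the models:

* `normalised` — per-substance z-score (sample SD, ddof = 1; the package's
  convention wherever an SD denominator is unstated). Constant columns map
  to zero with a warning. Because z-scoring removes per-substance location
  exactly, a pure per-substance shift is invisible to the downstream screen
  — a deliberate consistency property that the tests assert.
* `log1p` — ln(x+1), used for the Bray–Curtis input.
* `log_arcsine` — the recipe "log(x+0.001) and arcsine transformed" is not
  well defined as written, because ln of a relative area in (0, 100] is
  mostly negative and outside arcsine's domain. The package implements one
  documented reading: v = ln(x+0.001), linearly rescaled over the whole
  matrix to [−1, 1], then arcsin(v), mapping the matrix extremes to ±π/2.
  No claim is made that this reproduces any previously published numbers
  under that label.

### ANOSIM with restricted permutations

R ranks all off-diagonal dissimilarities (average ranks for ties) and
contrasts mean between-group vs within-group ranks, scaled by M/2 with
M = n(n−1)/2, so R ∈ [−1, 1] and is invariant to monotone transforms of the
dissimilarities. Because each female contributes many samples, unrestricted
permutation would badly inflate significance. Two schemes are provided:

* `within_individual` — group labels shuffle among each female's samples,
  independently per female. Valid only for factors that vary within a
  female (cycle state); the code refuses factors constant within every
  female.
* `individual_level` — each female's factor value is exchanged across
  females and propagated to her samples. This is the scheme used for age
  and parity: shuffling within a female is a no-op for a between-female
  factor, so the only exchangeable units are whole females. This is the
  largest inferential gap relative to the original description, which
  applied "permutation within an individual" to all three factors without
  saying how between-female factors were handled; results for age and
  parity under the individual-level scheme are this package's construction
  and are not claimed to match any previously published R/p values.

Monte-Carlo p-values use the add-one convention
p = (#{R* ≥ R} + 1)/(n_perm + 1) (default n_perm = 1000, one-sided upper
tail, resolution 1/(n_perm+1)); an exhaustive mode enumerates all distinct
restricted relabellings for small problems and the tests verify the two
agree. Age is treated as a categorical grouping with the observed discrete
year levels.

### The mixed model

The substance matrix is stacked sample-major into one response vector
(n_samples × n_substances rows) and fitted with independent variance
components: intercepts for sample, substance, female, room and sampling
batch; a random age slope within substance; and random interaction
intercepts of substance × {cycle, parity, side, ultrasound, assistants},
female × {cycle, ultrasound, assistants}, room × {cycle, ultrasound} and
batch × {cycle, ultrasound}. With the 9 fixed effects this enumerates 33
predictor variables; dropping the three test components (substance × cycle,
substance × parity, age slope within substance) gives the 30-term null.

Each interaction is parameterised as one independent `(grouping:factor)`
intercept component contributing exactly one variance parameter, so every
per-predictor likelihood-ratio test has df = 1. A correlated-slope
parameterisation would change the counts; with the independent
parameterisation the full–null comparison has df = 3 (the three test
components). LRT degrees of freedom are always reported as the actual
parameter-count difference.

**Solver.** The profiled (restricted) likelihood is maximised over the
variance ratios γ_k = σ²_k/σ²_e. Writing V₀ = I + Σ_k γ_k Z_k Z_kᵀ =
I + Z_s Z_sᵀ with Z_s the γ-scaled indicator blocks, every evaluation
reduces to one Cholesky factorisation of A = I + Z_sᵀZ_s (q × q, q = total
random-effect levels): log|V₀| = log|A|, and GLS quantities come from rank-q
Woodbury corrections of the precomputed cross-products, so cost scales with
the indicator nonzeros plus q², not with the row count. β and σ²_e are
profiled out in closed form. Optimisation uses L-BFGS-B with nonnegativity
bounds, an analytic gradient for ML (envelope theorem over β̂ and σ̂²), a
residual-variance-only start (all γ = 0), and tolerance ~1e-12 on the
deviance. ML is used for every fit feeding an LRT (REML likelihoods are not
comparable across fixed structures); REML is available for variance
reporting. Null-distribution caveat: the tested variance parameters sit on
the boundary of their space, so the nominal χ² reference is conservative —
the simulated type-I error at α = 0.05 runs well below 0.05, and the tests
only bound it above by 0.07.

**Screening rule.** The "slope estimates" of a test predictor are the
conditional modes (BLUP analogues) of its per-substance component: one
random slope per substance for age, and the level modes of the substance
interaction, centred within substance, for cycle and parity — i.e. one
estimate per substance *and level* for the categorical predictors. A
substance's score is its largest absolute estimate, and the flagging
threshold is mean + 2·SD over the population of *all* absolute estimates
for that predictor. Basing the threshold on the pooled per-level estimates
(rather than on the per-substance maxima) matters: a mean + 2·SD cut can,
by the one-sided Chebyshev inequality, exceed at most ~20% of whatever
population it is computed from, so thresholding the maxima themselves
degenerates exactly when a substantial fraction of substances is affected,
while the pooled population dilutes each substance's peak estimate with its
smaller co-levels and keeps the rule discriminating. The ≥ comparison keeps
the degenerate all-equal-scores case (SD = 0) flagging everything at the
mean. Directions report the sign of the age slope, the higher parity level,
and the cycle level with the highest mode. Conditional modes are shrunk
toward zero; the rule ranks substances, it does not estimate effect sizes.

Collinearity of the fixed effects is checked with per-column VIFs
(1/(1−R²) against the remaining columns) from the fixed design only.

### Bioassay statistics

The exact Wilcoxon signed-rank test drops zero differences, midranks ties,
takes V = sum of positive-difference ranks, and computes p by enumerating
the full 2ⁿ sign-flip null (via subset-sum counting over doubled ranks;
n ≤ 20). Two-sided p = 2·min(tails), capped at 1 — the sidedness convention
is the package's, as printed test statistics in this literature are often
ambiguous on that point. For n = 8 and all differences positive,
p = 1/256 ≈ 0.0039; the V = 34 configuration gives two-sided
p = 6/256 ≈ 0.0234.

Inter-observer reliability uses the two-way single-measure ICC from the
classical mean squares, defaulting to the absolute-agreement variant
(ICC(A,1); consistency ICC(C,1) optional), with the standard F-based 95%
confidence bounds (Satterthwaite df for agreement). Zero between-subject
variance yields ICC ≤ 0, not an error.

## The synthetic-data generator

The generator emulates the study design, not chromatographic physics.

* **Design.** 12 females (ages drawn 1–11 years; 5 parous, assigned
  independently of age so both are estimable), 27 (female, cycle) batches
  (three females × 1 cycle, three × 2, six × 3), cycle-state quotas
  56/104/52 met exactly with every batch non-empty, 9 handling + 22
  room-air blanks, three rooms, genital side random, ultrasound mostly
  after sampling (p = 0.8). The four assistant-presence flags are drawn
  independently (p = 0.3 each) — not one-hot — so the four fixed effects
  are jointly estimable alongside the intercept.
* **Intensities.** log-area = b_s + c_s[state] + a_s·z(age) + p_s·[parous]
  + nuisance + u_female + u_batch + ε, areas = exp(·). The log-normal form
  is an assumption chosen for coherence with the log-based transforms, not
  a claim about real chromatograms. Defaults: baselines N(11.5, 1) on the
  log scale, σ_ID = 0.5, σ_batch = 0.3, σ_e = 0.5, effect size 1.0 log
  unit; planted counts default to 6 cycle- / 11 age- / 7 parity-affected
  substances (mirroring the reported most-affected counts), age slopes
  mostly negative and parity shifts mostly favouring nulliparous females,
  matching the direction structure expected of real profiles.
* **Contaminants and blanks.** Contaminant substances are tube-derived:
  they carry no animal-linked terms and appear in blanks at an elevated
  level (+0.7 log units; the blank adsorbent has no competing animal
  signal), so the blank comparison removes them deterministically at
  fixture scale. Animal substances leak into blanks at a carryover fraction
  (default 0.01), giving the blank filter true negatives to act on.
* **Rendering.** Each positive-area substance becomes one peak at its true
  RT + N(0, jitter) (default 0.005 min) with a fixed fragment composition;
  peaks drop out independently at the configured rate. Optional per-batch
  RT offsets exercise the batch-adjustment step; substances can be flagged
  *inconsistent* to receive fresh fragment sets per peak and fail the
  Jaccard check. RTs are spread over 2.4–46.6 min with spacing far above
  the jitter, so the gap grouping recovers the planted substance count
  exactly — real co-elutions are harder than anything this generator
  produces.
* **Reproducibility.** One RNG stream per operation, seeded by
  (master seed, operation tag), so any stage regenerates independently;
  peak lists round-trip bit-identically through their TSV serialisation.

**What passing tests show — and don't.** The generator has well-separated
Gaussian-jittered peaks, log-normal noise, effects that match the fitted
model's functional form, and contaminants that behave. Recovery of planted
effects therefore validates the *statistical machinery* (alignment logic,
filter bookkeeping, likelihood maximisation, permutation schemes), not
performance on real chromatograms with co-elution, saturation, missing-ness
correlated with abundance, or model misspecification.

## Problem sizes

Tests and the acceptance script run the expensive pieces at reduced scale
chosen to exercise every code path: mixed-model recovery at 24 samples ×
40 substances (960 rows) over 10 seeds, null calibrations at 200
replicates, exhaustive permutation checks at ≤8 samples, and the full
212-sample design only for counting, alignment and ANOSIM (where it is
cheap). The 33-component model is fitted at fixture scale in seconds; a fit
at the full 33,920-row scale is supported by the same code path (cost is
driven by q ≈ 3600 random-effect levels, minutes on one CPU) but is not
part of any test.

## Known limitations

* Rigid per-batch RT shifts; no warping, no 2-D alignment.
* The Jaccard consistency check is a blunt stand-in for expert spectral
  inspection.
* Individual-level permutation for age/parity has only 12 exchangeable
  units at study scale — the p-value resolution for between-female factors
  is intrinsically coarse.
* Boundary-conservative LRT p-values; no chi-bar-square correction.
* Conditional-mode screening inherits shrinkage: scores are comparable
  within a fit, not across fits or response transforms.
* No substance identification: ranges are anonymous (RT + m/z) throughout.
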