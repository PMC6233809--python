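# Methods

This note documents the models, defaults, numerical choices, and limitations
of the `tastepe` pipeline, in the order the stages run.

## Conditioning task and prediction-error model

The task pairs three visual conditioned stimuli (CS) with three tastes
(1 M sucrose, no solution, artificial saliva). Sucrose- and no-solution-CS
trials are violated (the other taste delivered) on an *exact* fraction of
trials — `round(p_violation · n)` at uniformly random positions — rather than
per-trial Bernoulli draws. This guarantees the designed 20% split and, for
100 sucrose-CS trials, exactly 80 expected sucrose receipts, the trial set
the connectivity stage consumes. The saliva CS is never violated. Trial
duration is 6 s; inter-trial intervals are uniform 2–6 s jitter (standard
for event-related designs; the true schedule is not recoverable).

Prediction errors follow trial-level Rescorla–Wagner learning with one
expected value per CS type: δ = R − V at taste delivery, V ← V + αδ. Rewards
are coded sucrose = 1, no solution = saliva = 0. Defaults α = 0.7, V₀ = 0,
both config-exposed. A trial-level delta rule (rather than a time-resolved
temporal-difference model) suffices because only the trial-wise |δ| enters
the BOLD model; no behavioral responses exist to fit α against, so it is
fixed. Under these conventions V converges in expectation to each CS's
reinforcement probability, and violated trials carry the larger |δ| for any
α ∈ (0, 1) — both verified by simulation in the test suite.

## First-level GLM

The canonical HRF is the difference of two gamma densities (peak delay 6 s,
undershoot delay 16 s, unit dispersions, peak:undershoot 6:1), sampled at
0.1 s microtime, truncated at 32 s, peak-normalized; its argmax sits at
5.0 s. Condition boxcars and the |δ| parametric modulator (placed at the
trial, mean-centered so modulation is separated from the main condition
effect) are convolved at microtime and downsampled to the scan grid
(TR 2.1 s). Every task regressor carries a temporal derivative (one-step
finite difference of the kernel in time) and a dispersion derivative
(symmetric finite difference, ±5% in the dispersion parameter — platform
style without symbolic differentiation). Drift is absorbed by a
discrete-cosine basis with `floor(2·T/cutoff)` columns (9 at 300 scans,
TR 2.1 s, 128 s cutoff), so every basis period exceeds the cutoff.

A note on the drift basis: projecting out the DCT columns attenuates a
run-length drift to a few percent RMS but does *not* reduce every
sub-cutoff sinusoid below 1% — an off-bin or quarter-phase sinusoid leaks
3–12% because the basis holds cosines of specific phase only. This is the
standard behavior of this filter family; the tests assert the real property
(strong slow-drift attenuation, near-total retention of task-band signal).

Fitting is plain OLS per ROI (no AR(1) prewhitening — a deliberate,
documented divergence; the synthetic AR(1) noise is mild and OLS point
estimates stay unbiased, which the recovery benchmark confirms: mean PE-beta
bias ≈ 0.1% over 200 subjects). Rank-deficient designs fall back to the
pseudo-inverse with a logged warning. A constant modulator mean-centers to
zero and is dropped with a warning. The ROI panel takes the `pe_mod` beta
per subject × ROI, averaging across fits that share an ROI label (the
voxel-mean convention; ROI-level series pass through as identity).

## Synthetic cohort

The generator emulates the study conditions every downstream stage assumes:
56 AN and 52 control subjects; 18 reward-circuit ROIs (bilateral caudate
head, ventral striatum, nucleus accumbens, inferior/medial/middle OFC, gyrus
rectus, dorsal and ventral anterior insula); 300 scans at TR 2.1 s (enough
to hold 48 trials); 16 trials per CS type in the BOLD run.

Per subject, the ROI series is design · amplitude + AR(1) noise + slow
cosine drift. The true PE amplitude per (group, ROI) defaults to 0.5 in
controls and 0.6–1.0 in AN (largest in caudate and accumbens, intermediate
in ventral striatum and insula, smallest in OFC), mirroring the reference
cohort's effect-size ordering; between-subject amplitude SD is 0.45, split
between a shared "PE factor" and ROI-specific variation (weight 0.5 each).
Noise is AR(1) with φ = 0.3 and unit marginal SD. At these settings the
caudate group contrast lands near Cohen's d ≈ 1, consistent with the
reference F ≈ 23 at n = 108.

Trial-wise activation samples for the 80 expected sucrose receipts are drawn
*directly* from a two-variable linear structural model per hemisphere
(child = 0.8 · parent + unit-variance innovation; direction
ventral striatum → hypothalamus in AN, the reverse in controls), with the
remaining connectivity ROIs independent. The manifest labels this
`direct-sem`: the samples are not re-extracted from the BOLD series, because
no per-trial extraction convention is recoverable and the connectivity
stage's contract only requires trial samples. Innovations default to
uniform — the orientation stage requires non-gaussianity, and the bounded
uniform family is well behaved; gaussian innovations are allowed but raise
an unidentifiability warning.

Behavioral scales are drawn to the reference cohort's group means/SDs
(gaussian marginals). Harm avoidance is coupled to the subject's
gyrus-rectus amplitude deviation through a gaussian copula at rank
correlation 0.33 (the reported OFC–harm-avoidance association); the AN BMI
restoration rate is coupled to the shared PE factor at −0.35. Cortisol is
three samples (0, 60, 90 min: before breakfast, after breakfast, before
imaging — the schedule inferred from the stated collection protocol with
imaging 8:00–9:00 am) around a declining morning profile (0.35, 0.30, 0.25
µg/dL), subject-level SD 0.08, assay noise 0.05, and an AN shift of
+0.07 µg/dL, sized so the subset comparison (20 AN vs 25 controls) has the
reported medium-large effect.

What the generator does **not** emulate: voxel-level images, physiological
noise and motion, scanner differences, missing data, non-gaussian behavioral
marginals, learning-rate heterogeneity, and any coupling between the BOLD
amplitude and the trial-sample SEM. Passing tests therefore demonstrate that
the pipeline recovers the structures it models — not that those structures
hold in real data.

## Effective connectivity

Every subject contributes an 80 × ROI matrix; scoring uses the decomposable
pooled Gaussian BIC, `Σ_subjects [2·loglik(node | parents) −
penalty·(k+1)·log n]` (higher is better; penalty discount 1.0 by default).
The score is score-equivalent, so Markov-equivalent DAGs tie exactly, and it
sums over subjects rather than concatenating data — the independent
multisample design: one common structure, per-subject parameters.

The search is greedy equivalence search over CPDAGs with Chickering's
Insert/Delete operators (validity: clique and semi-directed-path conditions;
states are completed via Dor–Tarsi consistent extension and v-structure +
Meek-rule closure). Two refinement phases are added because plain two-phase
GES provably stalls on finite samples whose score argmax differs from the
generating class: a single-edge turning move (as in the GIES family) and an
exact reorientation sweep of the current skeleton (all acyclic orientations,
feasible below ~14 edges); for networks of ≤ 6 nodes a one-edge skeleton
perturbation (including edge swaps at ≤ 4 nodes) is also tried. All phases
alternate until no move improves the pooled score. On random 3-node
networks the result matches exhaustive enumeration in 1000/1000 datasets;
on dense random 4-node networks a ~0.1–0.2% residual mismatch rate remains —
genuine multi-edge local optima, not operator defects (the enumerated
optimum is itself a fixed point of the operators in those cases).

Orientation on the fixed skeleton: subjects are standardized and
concatenated, and each undirected edge is assigned the direction whose
regression residual is more non-gaussian relative to the regressor, using
the maximum-entropy approximation of differential entropy (log-cosh and
gaussian-moment terms) in a pairwise likelihood ratio; a skewness-based
third-moment rule is available as an alternative. Evidence below `10 / n`
(n = pooled sample size) leaves the edge undirected and flagged: under
gaussianity the evidence is O(1/n) while non-gaussian innovations give O(1),
so this scale separates the regimes without per-dataset calibration — at
56 × 80 samples gaussian edges are flagged essentially always and uniform
edges essentially never. Orientation cycles, should they arise, are broken
by reversing the weakest-evidence edge. Edge coefficients are per-subject
OLS of each child on all its parents.

The default search set is the 10-node subnetwork (bilateral ventral
striatum, hypothalamus, inferior and middle OFC, dorsal anterior insula).

## Group statistics

The normality gate applies the Shapiro–Wilk test to each pooled column and
replaces non-normal columns (p < .05) by mid-ranks over the pooled sample —
pooled rather than per group, matching the convention of reporting the panel
as collectively non-normal. Wilks λ is computed from |E| / |E + H| with
Rao's F approximation (validated against statsmodels to machine precision);
for two groups partial η² = 1 − λ. Covariates are residualized out of the
responses before the MANOVA (the MANCOVA convention here; with constant or
absent covariates this reduces exactly to the plain MANOVA). Univariate
follow-ups are pooled-variance one-way ANOVAs on the (possibly ranked)
columns with Bonferroni adjustment over the 18 ROIs.

Two summary-statistic conventions are embedded because they reproduce the
reference tables and the alternatives do not: demographic contrasts use
Welch t with the control − AN sign; ROI follow-ups use pooled-variance
rank-ANOVA F with η²ₚ = F / (F + n − 2). Bootstrap confidence intervals are
percentile (not BCa) with 1000 resamples and a seeded generator; degenerate
resamples (constant after resampling) are dropped. The slope comparison is
the Fisher z test on atanh-transformed correlations.

## Cortisol

AUC is computed with respect to ground (total output, the quantity a
between-group comparison of stress-axis activation needs) by the trapezoid
rule over the two intervals — exact for piecewise-linear profiles and
invariant to a common time shift. The group comparison is Welch t with
Satterthwaite df, contrast control − AN.

## Pipeline, seeding, problem sizes

`run_pipeline` executes simulate → fit → stats → connect → cortisol →
report. One run seed fans out to stage seeds via `SeedSequence` spawning,
recorded in the run manifest; identical (config, seed) runs produce
byte-identical CSV outputs. The CLI (`tastepe simulate|fit|connect|stats|
report|run-all`) is a thin wrapper; stage commands regenerate upstream
state deterministically from the seed.

Simulation sizes used by the validation benchmarks (and the acceptance
script): search/oracle agreement on 50 random 3–4-node datasets (8 subjects
× 100 trials each); orientation accuracy over 200 cohorts of 56 subjects ×
80 trials; end-to-end direction recovery over 50 full cohorts; GLM bias over
200 subjects; rank-MANOVA type-I error over 200 null cohorts. These sizes
keep each benchmark within a few minutes on one CPU while leaving
Monte-Carlo error well inside the asserted margins.

## Known limitations

- OLS without prewhitening mildly mis-states per-subject standard errors
  under AR(1) noise (only point estimates are consumed downstream).
- The greedy search is not exact on dense networks (see above); the
  exhaustive oracle is limited to ≤ 4 nodes.
- The entropy-based orientation rule assumes i.i.d. trials within subject;
  temporal autocorrelation in real trial estimates would dilute evidence.
- Printed-summary reproductions can only be as consistent as the summaries
  themselves; rows whose published statistics do not recompute from their
  own printed means/SDs are flagged in `tastepe.datasets` and excluded from
  reproduction checks.
- The cortisol sampling schedule is a fixed default; real inter-sample
  intervals vary by subject.
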