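# Methods

This note documents the models implemented in `kinovuln`, the
parameter choices behind them, what the synthetic-data generators do
and do not emulate, and the numerical decisions a maintainer would
want to audit.

## Differential expression

Input is a gene × sample matrix of log2 intensities (already
normalized; preprocessing of raw arrays is out of scope, though
`read_expression_study(..., linear_scale=True)` will log2-transform
linear input). For each gene the effect is
`log2FC = mean(tumor) − mean(normal)` and the p-value comes from a
two-sided two-sample test. Multiplicity is handled by
Benjamini–Hochberg over all genes; selection uses inclusive cutoffs
`|log2FC| ≥ 1` (two-fold or greater) and `q ≤ 0.1`.

**Choice of test.** The default is the pooled-variance Student's *t*.
With the emulated design — 16 tumors against only 3 normal cerebella —
a Welch test leaves ~2 degrees of freedom per gene, and per-gene
variance estimates from 3 samples are so unstable that planted
two-fold effects are missed ~20% of the time. Pooling borrows the
tumor-group variance and restores near-complete recovery
(sensitivity ≈ 0.99 at noise SD 0.2). Welch *t* and Mann–Whitney U
remain selectable per call and per pipeline config. A gene constant in
both groups is untestable and gets `p = 1` by convention.

**Funnel.** Annotation categories (e.g. cell-cycle genes, kinases)
are plain uppercase-normalized gene sets; the funnel is the
intersection of the selected set with every category, and is
order-independent by construction.

## Arrayed siRNA screen

Wells travel as a flat table (`plate_id, well, sirna_id, gene, role,
absorbance`). Scoring is a four-step chain:

1. **Background**: a single scalar optical density subtracted from
   every well, clipped at zero. (No per-plate blanks are modelled.)
2. **Plate normalization**: each well divided by the mean absorbance
   of that plate's non-silencing control wells, so controls average
   exactly 1.0 per plate and multiplicative plate effects cancel
   exactly. A plate without controls, or with non-positive control
   mean, is an error.
3. **Z score**: `(x − μ̂)/σ̂` with mean and SD estimated from the
   pooled **sample** wells of the whole screen (controls never enter
   the reference). A per-plate reference and a robust
   (median/1.4826·MAD) variant exist but are non-default: with ~80
   sample wells per plate and few expected true positives, the pooled
   plain Z is the conventional readout and matches an "average Z"
   analysis. Degenerate references (zero spread) are errors.
4. **Gene aggregation**: the per-gene score is the arithmetic mean of
   its siRNA well Zs (mean-of-Zs, not Z-of-mean); a gene with fewer
   wells simply has a smaller divisor. Hits are called at
   `mean Z < −2` and stringent hits at `mean Z < −3`, both strict
   inequalities, so a gene at exactly −2.0 is not a hit.

Under the null, the gene-level hit rate for 3 iid siRNAs would be
Φ(−2√3) ≈ 2.7 × 10⁻⁴; shared plate-normalization noise correlates
same-plate wells and pushes the realized rate upward, so calibration
is checked against the bracket [Φ(−2√3)/3, Φ(−2)] by Monte-Carlo.

## Candidate integration

Candidates are the intersection of the over-expressed set with the
screen hit set, annotated with `log2FC`, `q` and `mean Z`, ranked by
ascending mean Z (strongest proliferation phenotype first), ties by
descending fold change, then lexicographic gene id. Identifiers are
uppercased and stripped; an optional alias table maps naming variants
(e.g. "aurora kinase A" → AURKA). A candidate absent from either
annotation table is an error rather than a silent drop.

## Dose–response

Viability (percent of vehicle) follows the four-parameter logistic
`R(d) = bottom + (top − bottom)/(1 + (d/IC50)^h)`, `h > 0`. The
reported IC50 is the *relative* IC50 — the inflection dose — not the
absolute 50%-of-vehicle crossing. Fitting is nonlinear least squares
with IC50 and hill on log scale, five IC50 starts log-spaced across
the observed dose range, and `xtol = ftol = gtol = 1e-12`. Defaults
constrain `top = 100` (responses are percent-of-vehicle) and
`bottom ≥ 0`; both are releasable. Requirements and edge cases:

- ≥ 4 distinct doses; fewer is an error.
- All responses identical → a non-converged sentinel fit
  (`converged=False`, `IC50 = NaN`); downstream operations refuse
  non-converged fits.
- Hill slope is bounded to [1e-3, 50] to keep the model identifiable.

ICx doses invert the fitted curve analytically:
`d_x = IC50 · (x/(100−x))^{1/h}` for the normalized curve, with the
general closed form `((top−y)/(y−bottom))^{1/h}` behind it; `x` must
lie strictly in (0, 100). The combination-induced potency shift is
the plain ratio `IC50(combo)/IC50(single)`, flagged as sensitization
when below 1.

## Bliss synergy

Effects live on the fractional-inhibition scale
`f = clip(1 − treated/vehicle, 0, 1)`. Independence predicts
`f_bliss = f_a + f_b − f_a·f_b`; the per-cell excess is
`f_obs − f_bliss`. Single-agent fractions at arbitrary grid doses are
predicted from the two 4PL fits (not from raw single-agent wells), so
any dose grid is scorable. A combination is called synergistic when
at least one cell's excess exceeds `δ = 0.1`; the lowest qualifying
dose of each agent is reported. Because observed fractions are
clipped to [0, 1], a large planted excess is slightly underestimated
near saturation (planted 0.2 is recovered as ≈ 0.17 on the default
grid); this is a property of the effect scale, not an estimator bug.

## Efficacy statistics

Tumor volume is the caliper ellipsoid `V = (π/6)·L·W·H` (mm³). Arm
comparisons at a study day use per-animal volumes with a two-sided
Welch *t* by default (Mann–Whitney U available — at n = 10 per arm
neither normality nor pooling is safe to assume for tumor volumes)
and report mean ± SEM (`sd/√n`) per arm. Apoptosis is the percentage
of flow events in the two annexin-positive right quadrants. A cell is
DNA-damage positive when it has strictly more than 10 foci; fractions
can be normalized to a control condition. Relative colony number is
the ratio of treated to control mean counts.

## Synthetic data: what it emulates, and what it does not

Every generator is seeded (`numpy.random.default_rng`) and
byte-reproducible; truth labels are returned in sidecar tables, never
in the data the pipeline reads.

| Generator | Emulates | Defaults |
|---|---|---|
| expression | 16 tumor vs 3 normal log2 arrays | 1000 genes; baseline N(7, 1); noise SD 0.2 log2 units; planted effects N(1.5, 0.2) |
| screen | 710-gene × 3-siRNA viability screen | 80 sample + 3 control wells/plate; background 0.05 OD; signal 1.0 OD; lognormal plate effect σ = 0.15; well noise 0.05 OD |
| dose | single-agent MTS titrations | 8 doses 10–1200 nM ×3 reps; true IC50 150 nM, hill 1.2; noise 5% viability |
| combo | dose-pair inhibition grids | 6×6 grid; planted excess on top of the Bliss surface; noise 0.02 fractions |
| xeno | two-arm caliper series | 10/arm; V₀ ≈ 150 mm³ (CV 0.2); growth 0.06/day; measurement CV 0.15; days 0–63 weekly |

Noise models are the minimal conventional choices: Gaussian log2
expression noise, multiplicative lognormal plate effects with additive
Gaussian well noise, Gaussian viability noise, lognormal caliper
measurement error. Planted expression effects are drawn around
log2FC 1.5 (≈ 2.8-fold) with SD 0.2 — the planted genes emulate the
*selected* over-expressed set, which clears the two-fold criterion
with margin. In the joint (matched expression + screen) generator the
planted effects are additionally left-truncated at log2FC 1.2, so a
gene labelled over-expressed in the truth table always truly exceeds
the two-fold definition; without the truncation, exact-set recovery
would measure label inconsistency rather than pipeline error.
Xenograft calipers decompose the noisy volume into a mildly prolate
shape (aspect 1.0–1.4, fixed per animal); with measurement CV 0 the
implied volumes are exactly exponential.

Deliberately not emulated: raw CEL-file/probe-level structure,
probe→gene collapsing, spatial plate artifacts (edge effects, drift),
siRNA off-target effects and variable knockdown efficiency,
correlated gene expression, dropout or death of animals, and imaging
data (foci and quadrant counts enter as already-counted integers).
Passing tests therefore demonstrate correctness of the *statistical
machinery* under clean generative assumptions, not robustness to
every real-data pathology — the robust-Z option exists precisely
because real screens often violate them.

## Simulation sizes

The test suite and `scripts/acceptance.py` use: 100 simulated null
screens for Z calibration and the hit-rate bracket; 200 fully-null
expression studies (300 genes) for the false-discovery proportion; 20
planted expression studies (500 genes, 10% planted) for sensitivity;
10 screens × 20 planted essential genes (30% effect) for screen
sensitivity; 20 joint simulations for end-to-end exact recovery; 20
noisy titrations for IC50 error; 100 random parameter draws for the
ICx inversion oracle; 20 combination grids for the planted-excess
estimate. These sizes put Monte-Carlo error comfortably below each
check's margin while keeping the full run in seconds.

## Known limitations

- The pipeline operates at whatever identifier level its input tables
  use; it does not resolve probe sets to genes.
- The 4PL fitter assumes a monotone inhibitory response; biphasic
  curves will fit poorly (high RSS) rather than be flagged.
- Bliss excess is computed pointwise without a significance model; δ
  is a practical effect-size threshold, not a test.
- The screen's plain Z reference assumes few true positives among
  sample wells; screens with many strong hits should use the robust
  variant.
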