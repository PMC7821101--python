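# Methods

This note documents the models, parameter choices and known limitations
of the `optenrich` simulation and scoring stack.

## The screen being modeled

An optical-enrichment screen couples four stages: (1) a pooled CRISPRi
library is transduced at low multiplicity of infection so each cell
carries at most one sgRNA; (2) cells are imaged, nuclei segmented from
the H2B-GFP channel, and cells whose measured phenotype passes a gate
are photoactivated through a per-nucleus illumination mask; (3) the
photoactivated (mCherry-positive) cells are recovered by FACS; (4) sgRNA
read counts from the sorted populations are scored for enrichment.  The
package simulates stages 1–3 with exact ground truth and implements
stage 4 exactly as it would run on real count tables — the scoring
functions only see a count table and never touch the ground truth.

## Library and population model

* **Library**: genes with one or two transcription start sites (TSSs),
  a fixed number of sgRNAs per TSS (default 10) and nontargeting
  controls (default 22).  The default composition — 481 single-TSS
  genes, 63 two-TSS genes, 6,092 sgRNAs — reconciles a 544-gene,
  10-sgRNAs-per-TSS design with the 6,092-sgRNA total; the exact split
  of multi-TSS genes is one of several consistent reconstructions.
  sgRNA ids are opaque barcodes: no protospacer sequences, no off-target
  model.
* **Nucleus area**: lognormal, parameterized by arithmetic (mean, sd) =
  (450, 152) µm².  The pair is calibrated so the 99.5th percentile sits
  at 1,000 µm², making the "top 0.5% of controls" screening gate land on
  a round, interpretable threshold.  Cells expressing a hit phenotype
  draw their area from the same law scaled by `effect_size` (default
  2.0, i.e. one log2 unit).
* **Penetrance and efficacy**: a cell carrying a hit sgRNA expresses the
  phenotype with probability `penetrance × efficacy(sgRNA)`.  Efficacies
  are drawn per sgRNA from a two-component mixture — the first half of
  each TSS's sgRNAs ("Top5-like") from U(0.8, 1.0), the rest
  ("Supp5-like") from U(0.4, 0.7) — so that efficacy-subset analyses
  (rerunning the screen on only the strong half of the library) are
  exercisable.  Default penetrance 0.6 reflects a partially penetrant
  knockdown phenotype.
* **Infection reporter**: ln(mean BFP) ~ N(8.6, 0.5) for infected and
  N(6.6, 0.5) for uninfected cells, so the ln(BFP) = 7.6 infection gate
  separates them with ~2σ margin on each side.  Screen populations
  default to `infected_fraction = 0.95` (post-puromycin selection); the
  initial-transduction regime (10–15% BFP-positive) is simulated by
  setting the fraction accordingly.

## Imaging and measurement

Fields render nuclei as uniform-intensity filled ellipses (1-px Gaussian
edge blur, optional Gaussian read noise and Poisson shot noise) at
0.325 µm/px — a 20× objective on an sCMOS camera with 6.5 µm pixels; the
value is configurable and carried in field metadata so areas in µm² stay
self-consistent.  The ground-truth label mask is the exact, noise-free
ellipse raster.  Segmentation is deliberately classical: Gaussian smooth
(σ = 2 px) → global Otsu → fill holes → remove objects below the area
floor → distance-transform watershed (distance map smoothed with
σ = 4 px, marker spacing 12 px) to split touching nuclei.  On synthetic
fields with 2%-of-signal noise this recovers all non-overlapping nuclei
with centroid error < 2 px and area error < 5%.  Area is pixel count ×
pixel\_size²; the size threshold is the linearly-interpolated
(1 − 0.005) quantile of a control-area sample.  Border-touching nuclei
are excluded from both the positive and negative classes — they are
unanalyzed, not sorted negatives.

At screen scale (hundreds of thousands of cells) the pipeline does not
rasterize every field: measured area = true ellipse area × lognormal
measurement noise (CV 3%), which is the same quantity the segmentation
path produces, at simulation cost proportional to cells rather than
pixels.  The imaging and segmentation code paths are validated on
rendered fields by their own test suites and exposed through the
`render`/`segment` CLI stages.

## Photoactivation and FACS

PA-mCherry intensity follows saturating kinetics
I(t) = bg + (I<sub>max</sub> − bg)(1 − e^(−t/τ)) with defaults
bg = 100, I<sub>max</sub> = 30,000 camera units, τ = 1,000 ms, and
multiplicative lognormal noise with CV 0.10.  With these defaults the
four exposure classes 0 / 100 / 200 / 2,000 ms are separable with
pairwise Bayes error < 1% on log intensity.  The binding constraint is
the 100 vs 200 ms pair: any saturating response caps their log-intensity
gap below ln 2 ≈ 0.69, so at CV 0.15 the pairwise error floor is ~1%;
CV 0.10 keeps the populations cleanly distinguishable, matching the
qualitative "clearly separated FACS bands" behavior the model exists to
reproduce.  Activation masks are per-nucleus footprints eroded by 1 px
(spill-over guard) and never touch unselected nuclei.

FACS gates are data-driven, mimicking gate predefinition with
calibration samples: the mCherry-positive base gate sits at the 99.9th
percentile of an unactivated reference, and boundaries between exposure
classes at midpoints of expected log intensities.  Each gated cell is
recovered independently with probability 0.8 (FACS losses are real but
unquantified; the value is configurable).  Sequencing is a multinomial
draw over the sorted cells' sgRNA composition at fixed depth (default
10⁶ reads per sample).

**Detection errors.**  The mock screen's per-cell detection model uses
true-positive probability 0.9 and false-activation probability 0.005.
These two numbers were calibrated so the precision-versus-hit-fraction
curve spans the experimentally observed regime: ~80% precision at 2.3%
positives, ~98–99% at 30–44% positives.

## Scoring

* **ε**: log2 depth-normalized ratio with pseudocount 1, centered on the
  nontargeting median (the centering makes the control null exact and
  cancels the depth factor).  Per-run ε are averaged arithmetically
  across runs before testing.
* **Mann–Whitney**: two-sided.  Exact permutation enumeration (tie-aware,
  two-sided via |U − n₁n₂/2|) when C(n₁+n₂, n₁) ≤ 10⁵; otherwise the
  tie-corrected normal approximation with continuity correction, which
  matches `scipy.stats.mannwhitneyu(method="asymptotic")` to machine
  precision.  The batch path used for thousands of simulated negatives
  is a vectorized implementation of the same approximation.  Degenerate
  input (all values identical) returns p = 1.
* **η = |ε| · (−ln P)**: the two factors (phenotype severity,
  trustworthiness) are named by the method; the product is the minimal
  combination that is zero iff either factor is uninformative and
  monotone in both.  The sign of ε is kept alongside.  Multi-TSS genes
  collapse to the TSS with maximal η.
* **Simulated negatives**: random regrouping of *all* sgRNAs (hit,
  non-hit and nontargeting alike) into groups of 10, scored identically
  to genes.  One regrouping of a 6,092-sgRNA library yields 609
  negatives; the default draws 50 independent regroupings (~27–30k
  negatives).  The default is set by null resolution: to resolve an eFDR
  target of 0.1% the empirical null must be much larger than 1/target,
  and with ~30k negatives the chance that any truly null gene exceeds
  the null maximum is ~2%.  A single draw reproduces the
  one-regrouping design and remains available via `simneg_draws=1`.
  Note the contamination is intentional: regrouped nulls inherit the hit
  sgRNAs' ε tail, so the cutoff automatically hardens in screens with
  strong effects.
* **eFDR**: #{simneg η > c} / (#{gene η > c} + #{simneg η > c}), strict
  inequality, 0/0 := 0; the chosen cutoff is the smallest observed η
  with eFDR at or below target, and hits are genes strictly above it.
  The raw ratio is not monotone in c (both counts fall as c rises), so
  the curve is reported as defined rather than as a monotone envelope.
  With far fewer genes than 1/target, the cutoff in practice equals the
  maximum simulated-negative η.

## Pipeline scale choices

Desk-scale defaults replace the experiment's ~1.5 million cells per run
with 50,000 (size screen), 150,000 (mock screen) and 400,000 (FACS-only
screens), keeping the quantities that carry the statistics in a sane
regime:

* the photoactivated positive population stays in the few-hundred to
  few-thousand cell range, as in the real screens;
* reference samples (sorted true negatives, unanalyzed cells) default to
  caps of 50,000 cells — effectively "all available" — because reference
  material is not cell-limited and an under-sampled reference (fewer
  cells than sgRNAs) injects spike-slab noise into both sides of the ε
  ratio;
* FACS-only screens use 400,000 cells so the top-10% sorted sample keeps
  several cells per sgRNA; below that, count discreteness dominates and
  the screen loses power — consistent with FACS-only screens being the
  weakest of the three designs.

Everything is deterministic given (config, seed): seeds for every stage
are derived from the run seed through fixed-tag `SeedSequence`s, and
output TSVs carry the seed and a config hash in a header comment.

## What the generator does and does not emulate

The synthetic data reproduce the *structure* of a real screen — single
sgRNA per cell, partial penetrance, per-sgRNA efficacy spread, a
size-gated sparse positive population, FACS losses, finite sequencing
depth — but idealize much of its texture: nuclei are ellipses with
uniform intensity; segmentation errors at high confluence, debris,
doublets, cell-cycle area modulation and day-to-day batch effects are
absent; FACS gates have no spectral spillover or drift; the detection
error model is two fixed Bernoulli rates; read counts have multinomial
(not overdispersed) noise; and sgRNA efficacies are independent of
genomic context.  Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under the stated
generative model, not that a real screen with these settings would
achieve the same recovery.

## Degenerate inputs and numerical conventions

Blank or contrast-free images segment to zero nuclei (not an error);
precision with zero called positives raises an explicit error rather
than returning a number; p-values are floored at 1e-300 before taking
−ln; quantiles interpolate linearly between order statistics; grouping
drops leftover sgRNAs when the library size is not a multiple of the
group size; ties at the eFDR cutoff are non-hits (strict inequality).

## Known limitations

No 3-D or time-lapse imaging, no machine-learning segmentation, no
fixed-cell mode, no FCS binary format, no FASTQ processing (counts are
the entry point), no growth/fitness phenotype scoring, and no modeling
of hardware (DMD geometry, stage, cytometer fluidics).
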