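# Methods

## The measurement process being emulated

A microtrough chip holds ~18,000 sub-nanoliter wells. Cells settle into
wells at random; a glass slide carrying striped capture-antibody barcodes is
clamped on top, incubated for one 2-h window, then exchanged for a fresh
slide, so the *same* cells are profiled repeatedly: one basal window, then
three windows after LPS stimulation (T = 4, K = 10 proteins). Each exchange
rinses the chip, losing a fraction of cells; wells that contain no cell act
as in-situ background controls for their local antibody signals.

The raw observable per (well, window) is the mean photon count per protein
bar plus the bright-field cell count. Everything downstream — gating,
time-course assembly, dynamics classification, polyfunctionality, and
two-state clustering — consumes that table.

## Generator model (`chip_sim`)

* **Loading.** Well occupancies are iid Poisson(λ), λ = 0.5 by default so
  that the single-cell fraction λe^(−λ) ≈ 30.3% and one chip yields >5,000
  single cells. Loading is treated as purely Poisson (no settling
  exclusion); the occupancy histogram is a testable output, not an input.
* **Latent states.** Each cell is independently "high"-basal with
  probability `state_mix` = 0.35, else "low". The two states differ in their
  per-protein dynamic-mode probabilities; the high state is more active both
  before and after stimulation.
* **Dynamic modes.** Per cell and protein one of five modes is drawn:
  `ALL_ON`, `ON_OFF` (off-time uniform over windows 1..T−1), `OFF_ON`
  (onset uniform over 1..T−1), `OTHER_SILENT`, or `OTHER_OSC` (uniform over
  all length-T binary sequences with ≥ 2 transitions — 8 of them at T = 4;
  at T = 2 no such sequence exists, so two-window presets fold the
  oscillatory mass into silent). The default mode tables were chosen so that
  the 0.65/0.35 state mixture reproduces the published population pattern
  fractions for CCL2 (all-on 71.1%, on-off 7.9%), TNF (on-off 13.4%, off-on
  4.7%) and IL-6 (off-on 7.1%, on-off 0.6%); the seven proteins without
  published fractions carry a strong between-state contrast so that the two
  states form the clearly separated clusters the two-state analysis is
  designed to detect (hierarchical recovery ≳ 0.95 at 1,752 cells), while
  keeping mean basal polyfunctionality ≈ 2.5 proteins/cell.
* **Basal coupling.** A cell's basal active-protein count m₀ raises its
  chance of recruiting additional proteins after stimulation: each
  `OTHER_SILENT` protein converts to a late-onset off-on realization with
  probability `expit(β₀ + c·m₀)` (β₀ = −3.5, slope c = 0.5 per basal-active
  protein). `c = 0` disables the mechanism entirely, so realized modes equal
  drawn modes — the condition used for mode-fraction recovery. Note that
  even with c = 0, basal and stimulated activity remain correlated through
  shared modes (all-on proteins are active in both phases); a true null for
  the coupling slope therefore uses factorized mode probabilities
  P(mode) = P(basal on)·P(stimulated on) at T = 2.
* **Retention.** After each window a cell survives the slide exchange with
  probability `retention_p` = 0.56, independently per exchange. Lost cells
  vanish from later bright-field counts (their wells become zero-cell
  controls) and contribute background-only signal thereafter; carryover
  after the triple rinse is modeled as zero.
* **Fluorescence.** Intensity = background + secreted signal. Background is
  truncated-normal at 0 (mean 150, SD 15 photon counts per protein — the
  paper gives no noise model, so a right-bounded Gaussian read-noise model
  is used); the secretion signal of an actively secreting cell-window is
  lognormal (ln-mean 7.3 ≈ 1,480 counts, ln-SD 0.35), i.e. a right-skewed
  immunoassay signal sitting far above the μ₀ + 3σ₀ threshold (≈ 195), as
  in the validated assay. Multi-cell wells receive the summed signal of
  their occupants but are excluded from analysis by gating.
* **Determinism.** One `numpy` Generator drives the run; auxiliary draws
  are made for every (cell, protein) regardless of mode so the stream layout
  depends only on population size. Identical config ⇒ bit-identical output.

## Gating

Per protein and window, μ₀ and σ₀ are the sample mean and sample SD
(ddof = 1; the small-sample-unbiased choice) of zero-cell-well intensities,
pooled globally across the chip by default (`row_blocks` splits the chip
into row bands when local background matters). Threshold θ = μ₀ + 3σ₀;
values **strictly above** θ are secretion (ties count as background —
conservative calling), others are set to 0; log2(x + 1) is applied after
thresholding. Only 1-cell wells yield records. Under a normal background
the per-protein false-call rate is the 3σ tail, ≈ 0.135%.

## Tracking

Cells are adherent, so identity across windows is well coordinates alone.
A course is complete iff its well holds exactly one cell at every window; a
well that gains or loses a cell breaks completeness for that window (a
dislodged neighbour makes the well untrustworthy). Population analyses use
complete courses only; study-scale cohorts are 1,752 complete courses,
subsampled deterministically (row-major well order) from a full-retention
chip. Per-exchange retention is the fraction of cells present at window
t−1 that remain at t.

## Dynamics classification

Labels are decided by the transition count of the binary sequence: 0
transitions → all-on (if on) or other (if silent); exactly 1 transition →
on-off (starts on) or off-on (starts off); ≥ 2 transitions → other. "Active
early" is thus formalized as *on at the basal window* for on-off (and off at
the basal window for off-on); late transients such as 0110 are "other". The
basal window is part of the classified course. This is the only reading
that partitions all sequences without overlap; at T = 4 the classes contain
1 / 3 / 3 / 9 of the 16 sequences.

## Polyfunctionality

Function count m(t) = row sum of the call matrix at window t. For the PI,
cells are binned 0, 1, 2, 3, 4, ≥5 (six bins; the pooled top bin carries
weight i = 5) and PI = Σᵢ Fᵢ·(i/n)^q with n = 6, q = 1 and Fᵢ in percent.
With this binning the maximum attainable PI is 100·(n−1)/n; the published
worked example (bins 94/360/548/427/228/95 over 1,752 cells) gives
PI ≈ 39.23, which the implementation reproduces exactly. The alternative
algebraic reading Fᵢ·i/(n·q) — identical at q = 1 — is available behind the
`form` flag.

The basal-coupling fit bins cells by basal count (0..4, ≥5; the top bin's
regressor is its within-bin mean basal count), computes the mean stimulated
count per bin for each stimulated window, and fits ordinary least squares of
bin means on bin centers (matching a fit of *averaged* polyfunctionality;
total least squares would answer a different question). Between-neighbour
comparisons use Welch's two-sample t-test on the raw within-bin stimulated
counts (bins differ in size and variance). The fit requires ≥ 3 non-empty
basal bins.

## Two-state clustering

Features are the raw log2 signals, window-major, unscaled (all features
already share the log2 photon-count scale; z-scoring would up-weight
low-variance proteins). Route 1: Ward linkage on Euclidean distances, cut
at k = 2 — deterministic. Route 2: 2-D t-SNE (perplexity 30, capped at
(n−1)/3 for small inputs, PCA init, fixed seed) followed by k-means (k = 2,
10 restarts, best inertia, same seed). In both results cluster 1 is the one
with higher grand-mean signal ("more active"), which also makes the labels
invariant to row permutation. Overlap between partitions is the maximum
over the two label alignments of the agreement fraction (the published
"≈70% overlap" metric is not given a formula; global aligned agreement is
the simplest symmetric choice, and the 2×2 contingency table is reported
alongside).

## Problem sizes and what the tests show

Tests and the acceptance script run one 18,000-well chip per scenario and
1,752-cell cohorts — the scale of a single real experiment — which keeps
the whole suite at a few minutes on one core. Stochastic checks use 3σ
binomial/multinomial tolerances at these sizes.

The generator emulates occupancy statistics, retention, background/signal
separation, mode mixtures and basal coupling, but **not**: antibody
crosstalk, spatial background gradients (unless `row_blocks` > 1 scenarios
are constructed), cell motility or doublet dissociation, signal carryover
between windows, or concentration calibration. Passing recovery tests
therefore show the *analysis* is correct under the stated measurement
model, not that the model captures every artifact of real chips.

## Known limitations

* Identity-by-well cannot detect a cell swap within a well; real data would
  need image-based confirmation.
* The ≥5 PI bin follows the published six-bin layout; populations with many
  cells above 6 functions compress into one weight.
* t-SNE + k-means is a generic stand-in for embedding-based clustering;
  cluster shapes in the embedding depend on perplexity and seed, which the
  overlap report records.
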