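# seqsecrete

Analysis pipeline for **sequential single-cell protein-secretion assays**:
microtrough chips in which ~18,000 sub-nanoliter wells each capture 0–few
cells, and an antibody-barcode slide records a 10-plex secreted-protein
panel (CXCL8, IL-6, CCL2, TNF, IL-10, CCL4, MIF, CCL3, IL-1B, GM-CSF) from
the *same* cells over four sequential 2-hour windows — an unstimulated basal
window followed by three windows after LPS (TLR4) stimulation. Because no
raw chip data are publicly deposited for this assay class, the package
includes a first-class synthetic chip generator with known ground truth, so
every downstream stage is testable by parameter recovery.

It is written for quantitative immunologists and computational biologists
analysing microwell secretomics, and covers:

- **`chip_sim`** — Poisson well loading (λ = 0.5 cells/well → ~30% single-cell
  wells), two latent basal activation states, per-protein dynamic secretion
  modes, basal-coupled stimulated activation, lognormal secretion signal over
  truncated-normal background, and 56% per-slide-exchange cell retention.
- **`gating`** — on-chip background from zero-cell wells; the secretion
  threshold per protein and window is **μ₀ + 3σ₀**; sub-threshold values are
  zeroed and signals reported as log2(x + 1). Only 1-cell wells are analysed.
- **`tracking`** — same-cell time courses linked by well coordinates;
  completeness and per-exchange retention summaries.
- **`dynamics`** — each protein's binary call sequence is classified
  **all-on** (1…1), **on-off** (1…10…0), **off-on** (0…01…1) or **other**
  (silent or oscillatory, ≥2 transitions); the four classes partition all
  binary sequences.
- **`polyfunc`** — per-cell function counts m(t), the polyfunctionality
  index `PI = Σᵢ Fᵢ (i/n)^q` (bins 0,1,2,3,4,≥5; n = 6, q = 1; Fᵢ in %), and
  the binned OLS fit of mean stimulated polyfunctionality on basal
  polyfunctionality with Welch t-tests between neighbouring bins.
- **`states`** — 1752 × 40 matrices (10 proteins × 4 windows) clustered into
  two activation states by Ward hierarchical clustering and, independently,
  by t-SNE + k-means; agreement is the maximum aligned label overlap.

## Worked example

The numbered scripts under `analysis/` run the study-scale analyses and
write their tables under `results/`:

```bash
python analysis/01_simulate_chip.py --seed 0   # chip + ground truth
python analysis/02_gate_and_track.py           # gating + time courses
python analysis/03_secretion_dynamics.py --seed 0
python analysis/04_polyfunctionality.py --seed 0
python analysis/05_activation_states.py --seed 0
```

With seed 0 this prints, among other things:

```
18000 wells at lambda=0.5: 5583 single-cell wells (31.0%; Poisson predicts 30.3%)
...
per-exchange retention:
 exchange  n_before  n_after  fraction
        1      5583     3127  0.560093
...
  CCL2  ALL_ON  measured  71.1% (configured 71.1%)
  TNF   ON_OFF  measured  12.5% (configured 13.4%)
...
PI by window (basal = 0):
 window  n_cells  mean_functions    pi
      0     1752            2.67 42.20
      3     1752            4.48 57.33
...
hierarchical clusters: {1: 618, 2: 1134} (state recovery 97.4%)
embedding clusters:    {1: 770, 2: 982} (state recovery 90.9%)
between-method overlap: 90.5%
```

i.e. the chip yields >5000 single cells, the gating/tracking stages recover
the configured 56% retention, the dynamics classifier recovers the
configured pattern fractions within sampling error, polyfunctionality rises
monotonically after stimulation, and both clustering routes recover the two
latent activation states (the more active cluster is more active already in
the basal window).

The same stages are available as a CLI (`seqsecrete simulate|gate|track|
classify|polyfunc|states|run`), each stage consuming the previous stage's
CSV schema, with a JSON run manifest for reproducibility.

## Layout

```
src/seqsecrete/   library (generator, gating, tracking, dynamics,
                  polyfunc, states, pipeline, CLI)
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property and recovery tests)
docs/methods.md   model, parameters and design notes
```
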