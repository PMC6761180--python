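# Methods

This note documents the models behind `zspread`: what is simulated,
what is analysed, which parameters matter, and where the design was
genuinely open.

## Chip and acquisition model

One well carries a 6 × 7 grid of 100 µm disc electrodes at 300 µm
pitch, centred on the well (columns at x = ±150, ±450, ±750 µm; rows
at y = 0, ±300, ±600, ±900 µm), so the electrode-centre extent is
1.5 mm × 1.8 mm and a chip of nine wells carries 378 working
electrodes.  Indexing is (row, col), 0-based, row-major; units are µm
with the origin at the well centre.  Acquisition is magnitude-only
impedance spectroscopy: 41 log-spaced frequencies from 5 kHz to 5 MHz
per electrode per time point, with measurements at 0–144 h in 24 h
steps.  The counter electrode is not modelled separately; the
two-electrode read-out is folded into the equivalent circuit.

## Electrode impedance model

Each electrode follows a minimal ECIS-style equivalent circuit,

    Z(f, θ) = R_sol + 1/(Q·(i2πf)^n) + θ·R_cell/(1 + i2πf·R_cell·C_cell),

with a series solution resistance, a constant-phase element for the
gold/electrolyte double layer, and a cell layer as a parallel RC
branch scaled linearly by the covered-area fraction θ ∈ [0, 1].  θ = 0
is the cell-free baseline.  Defaults (version-pinned):

| parameter | default | meaning |
|---|---|---|
| R_sol | 2 kΩ | solution/spreading resistance |
| Q_cpe | 2 nS·s^n | CPE magnitude (≈ nF-scale double layer of a 100 µm disc) |
| n_cpe | 0.9 | CPE exponent |
| R_cell | 12 kΩ | cell-layer resistance at θ = 1 |
| C_cell | 55 pF | cell-layer capacitance |

These values place the relative-impedance peak of a fully covered
electrode at ≈ 190 kHz with an amplitude of ≈ 334 %, decreasing
linearly with θ to ≈ 17 % for a single adherent cell (θ ≈ 0.05).  The
mid-band peak location matches published spheroid/cell signals on
comparable gold microelectrodes (maxima reported between ~137 and
~275 kHz); the full-coverage amplitude is set in the hundreds of
percent so that well medians can span the observed 50–270 % range —
a device measuring whole spheroids in microcavities reports maxima in
the tens of percent, but monolayer-covered planar microelectrodes
show much larger relative signals, and the discrimination cut at
110 % median would otherwise be unreachable.  Absolute Ω scales are
unconstrained by any published baseline spectra and were chosen for
plausibility only; every analysis quantity is a ratio and invariant
to the overall scale.

## Egress simulator

Agents (cells) are emitted from the rim of a static spheroid disc of
radius 250 µm at the well centre:

* **Emission** — Poisson process at `egress_rate` cells/h, starting
  after an adhesion/outgrowth lag `egress_delay` and ending at
  `disassembly_time` (∞ = the spheroid persists).  Spheroid outgrowth
  assays commonly show a ~1-day lag before cells leave the body;
  covered-electrode counts correspondingly stay near the body
  footprint over the first day.
* **Motility** — persistent random walk: per step (dt = 0.5 h) an
  agent draws a speed from a normal truncated at zero and moves along
  its heading; the heading is relaxed toward a fresh random unit
  vector such that its autocorrelation over 1 h equals `persistence`
  (default 0.9).  Agents reaching the well wall (radius 3.2 mm,
  96-well scale) are absorbed there.
* **Proliferation** — each agent divides with probability
  1 − exp(−λ·dt) per step; the daughter is placed one cell diameter
  (10 µm) away in a random direction, so division raises local
  density without adding spread.  `mitomycin=True` forces the
  effective rate to zero, emulating the proliferation-suppressed
  reference populations.
* **Coverage** — θ(electrode, t) = min(1, footprint ×
  n agents on the disc / disc area) with a 400 µm² footprint per
  cell (≈ 5 % of a 100 µm disc, so one cell yields a ~17 % signal,
  comfortably above the 10 % detection cut and consistent with the
  smallest reported whole-spheroid signals of ~15 %).  Electrodes
  whose centre lies under the spheroid body are fully covered
  (θ = 1) while the body persists.
* **Noise** — measured spectra are multiplied by i.i.d. mean-one
  lognormal noise of relative sd 1 % (default); baselines are
  rendered noise-free so that the zero-coverage relative impedance is
  exactly zero (a flag enables noisy baselines).

### Phenotype presets

The presets are calibrated once, end-to-end through the render-and-
analyse pipeline averaged over ≥ 20 seeds, against the observed
spreading grades of the three emulated lines: the fast line covers
essentially all electrodes by 96 h and its spheroid fully disassembles
by 48 h; the intermediate line exceeds 60 % covered electrodes at
144 h; the slow line reaches ≈ 35 % at 144 h, with its
proliferation-suppressed variant at ~9–12 covered electrodes.
Division rates for the slow/intermediate lines (0.021/h) follow the
reported EdU-positive fractions of the emulated melanoma lines
(≈ 34 % labelled in 16 h); the fast line's 0.026/h corresponds to a
~27 h doubling time.

| preset | egress (cells/h) | lag (h) | speed (µm/h) | persistence | division (/h) | disassembly (h) |
|---|---|---|---|---|---|---|
| fast | 80 | 24 | 25 ± 8 | 0.9 | 0.026 | 48 |
| intermediate | 8 | 24 | 9.5 ± 4 | 0.9 | 0.021 | ∞ |
| slow | 5.5 | 28 | 4.7 ± 2.1 | 0.9 | 0.021 | ∞ |

`+mitomycin` variants differ only by a zero effective division rate.

### What the simulator does and does not emulate

It reproduces: per-electrode spectra with baseline, coverage growth
from a central source, the migration/proliferation contrast between
treated and untreated references, noise at the instrument's scale,
and full reproducibility from a seed.  It does **not** emulate:
electrode-to-electrode fabrication variability, baseline drift,
medium changes, cell death, mitomycin side effects beyond
proliferation arrest (the real drug also reduced early spreading),
3D-to-2D disassembly dynamics beyond a sharp stop of emission, or
spheroid size variability.  Passing tests therefore demonstrate that
the analysis chain recovers planted truth under idealised but
plausibly scaled conditions — not that it is robust to every artefact
of real recordings.

## Analysis chain

1. **Relative impedance** per electrode and time point against that
   electrode's own cell-free baseline; scale-invariant by
   construction.
2. **Spectrum maximum** — argmax on the sampled 41-point grid, no
   smoothing (41 log-spaced points are sparse and any smoothing
   dialect would be uncontrolled); ties break toward the lower
   frequency.
3. **Coverage call** — covered ⇔ maximum ≥ threshold, inclusive
   boundary.  The default 10 % sits well above the 1 % noise floor
   and below the single-cell signal (~17 %); it is exposed as a
   parameter everywhere because the original read-out's criterion is
   not documented.
4. **Well summary** — covered count, and the median maximum relative
   impedance over covered electrodes only (a median over all 42 would
   be dragged to ~0 by uncovered electrodes and could never reach the
   observed 100–270 % range).  No covered electrodes ⇒ the median is
   missing (NaN), never 0.
5. **Quadrants** — migration high ⇔ covered ≥ coverage_cut;
   proliferation high ⇔ median ≥ impedance_cut; (low,low) → Q1,
   (low,high) → Q2, (high,high) → Q3, (high,low) → Q4; boundaries
   inclusive on the high side; a missing median yields an explicit
   "undefined".  Cuts default to (20 electrodes, 110 %) and are
   calibrated, when labelled reference wells are given, as midpoints
   between the endpoint (144 h) group means — the endpoint because
   the quadrant scheme targets late time points, where disassembly
   artefacts have faded.
6. **Features and clustering** — 12 features per well (covered counts
   at 24, 48, …, 144 h, then medians at the same six times; missing
   medians imputed with 0, since a well with no covered electrode
   carries no cell signal, and flagged).  Features are z-scored
   (counts 0–42 and medians 0–330 % live on different scales),
   zero-variance features dropped with a warning, reduced to three
   principal components, and soft-clustered by fuzzy c-means with
   k = 4, fuzzifier m = 2, tolerance 1e−6 on the membership matrix,
   300 max iterations and the best of 20 seeded restarts.  New wells
   are standardised and projected with the frozen training
   parameters and assigned memberships against the fixed centres;
   the hard label is the argmax membership with ties to the lowest
   cluster index.

Fuzzy c-means is implemented in-package (`zspread.fcm`) with the
standard alternating updates; the objective is non-increasing per
iteration by construction and asserted in tests, and an exhaustive
hard-assignment search on 8-point instances serves as an independent
oracle.

## Numerical choices and degenerate inputs

* Electrode discs are disjoint (diameter < pitch), so an agent lies on
  at most one disc; assignment is by rounding to the nearest grid
  cell followed by an explicit distance check.
* Emission, movement and division draw from one seeded generator in a
  fixed order, so runs are bit-reproducible from (params, seed); the
  rendering noise stream is derived from the same seed.
* A sample exactly on a cluster centre receives membership 1 there;
  FCM initial centres are jittered data points to avoid coincident
  centres on duplicate-heavy inputs.
* Truncated-normal speeds use the exact truncated distribution, not
  clipping; a zero speed sd degenerates to a constant speed.
* The recording CSV stores doubles at 17 significant digits and is
  read back with exactly-rounded parsing, so round-trips are
  bit-lossless.

## Known limitations

* The absolute impedance scale and the circuit parameters are
  plausible but unconstrained by published baselines; only ratios are
  meaningful.
* The quadrant cuts and the 10 % coverage threshold are assay-specific
  conventions, not universal constants; the calibration helper exists
  precisely because they must be re-derived per cell system.
* With few covered electrodes (3–4) the covered-only median is an
  order statistic of a tiny sample and can jump between
  body-dominated and migrant-dominated values; per-well traces at
  early times are accordingly noisy, and the clustering features are
  anchored at 24 h steps where the presets' covered counts have
  stabilised on either side of that regime.
* Mitomycin is modelled purely as proliferation arrest; the real
  treatment also depressed early electrode coverage, which the
  presets do not reproduce.
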