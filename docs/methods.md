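# Methods

## Sample entropy on RF backscatter

For a series `X = {x_1 … x_N}`, templates of length `m` are
`X_m(i) = {x_i … x_{i+m-1}}`. Two templates match when their Chebyshev
distance is strictly below `r·σ`, where `σ` is the population standard
deviation of the analyzed series (the series is normalized internally, so
`r` is a dimensionless fraction). With `B` the number of unordered matching
template pairs at length `m` and `A` the number still matching at length
`m+1` (self-matches excluded),

    SampEn(m, r, N) = −ln(A / B).

Conventions fixed in this implementation:

* strict inequality `d < r·σ` defines a match;
* unordered pairs are counted once (`i < j`); the ratio `A/B` is identical
  under double counting;
* population (1/N) standard deviation;
* template start indices run over `0 … N−m−1`, so every counted template
  also has an `(m+1)`-point extension — this makes `A ≤ B` structural and
  `SampEn ≥ 0` whenever defined;
* `A = 0`, `B = 0`, or a zero-variance window yield NaN ("undefined"),
  never an exception; undefined windows are excluded from ROI statistics
  and logged with their window origins.

The histogram Shannon entropy baseline is `−Σ w log₂ w` over `n_bins`
equal-width bins spanning `[min, max]` of each analyzed window (200 bins by
default). Both entropies are computed on the raw RF samples, not the
envelope; an envelope-based series can be passed explicitly if wanted.

The vectorized estimator builds the pairwise distance matrix once per
window and extends it by a running maximum, so a full `(m, r)` calibration
grid costs little more than the largest `m` alone; a blocked path bounds
memory for long series (N = 10⁴ takes a few seconds). Both paths are tested
to machine precision against a naive double-loop oracle.

## Imaging pipeline

RF frames carry sampling rate `fs`, center frequency `fc`, measured pulse
length (PL, mm), sound speed `c` (default 1540 m/s) and lateral line pitch
(default 0.3 mm). Axial sample spacing is `c/(2 fs)` (pulse-echo two-way;
64.17 µm at 12 MHz). B-mode display is the magnitude of the per-line
analytic signal, log-compressed to a 40 dB dynamic range. Optional TGC
multiplies depth `z` (cm) by `10^(α · f_MHz · 2z / 20)` with
α = 0.3 dB/MHz-cm; it is off by default because the synthetic frames are
generated attenuation-free.

The analysis window is physically square: its side is
`WSL × PL` converted to axial samples and to scan lines through the line
pitch (36 samples × 8 lines at the defaults). The window slides at 50% of
its side per step; only fully contained windows are evaluated (no padding).
Window content is concatenated line by line into a 1-D series. Per-window
values sit at window centers and are bilinearly interpolated back to the
full RF grid, with nearest-center extension beyond the outermost centers
and nearest-valid substitution for undefined windows (a quality warning
fires above 20% undefined). ROI statistics are plain means over defined
pixels under the mask. Default overlay display ranges are 1.7–3.0 for
sample entropy and 3.8–4.2 for Shannon entropy.

Default computational setting: WSL = 1 PL, m = 4, r = 0.1, 50% overlap —
the recommended protocol for hepatic RF at 12 MHz sampling of a 3 MHz
carrier, where m = 4 equals the number of samples per carrier cycle.

## Synthetic phantom

Each scan line is an independent 1-D reflectivity train convolved with a
Gaussian-modulated 3 MHz pulse whose −6 dB envelope extent equals the
2.3 mm pulse length (evaluated analytically at continuous scatterer
depths, so echo phase is not quantized to the sample grid). Scatterers
arrive as a Poisson process at `scatterer_density` per resolution cell
(one PL), amplitudes standard normal.

* **Baseline density 3 per cell** places normal parenchyma in the
  pre-Rayleigh regime. A high-density phantom (≥ 20 per cell) reaches the
  Rayleigh limit (envelope mean/std within a few percent of
  √(π/(4−π)) ≈ 1.91), which the tests verify.
* **Steatosis** (`fat_level` ∈ [0, 1]): fat droplets are *added*
  scatterers with increased density and cross-section — extra density
  `3 × fat_level ×` baseline, amplitude gain 1.5. Mean envelope amplitude
  and sample entropy rise monotonically with fat level (the package's
  acceptance checks measure Spearman 1.0 over levels {0, 0.1, 0.25, 0.5}
  at 20 frames/level). A gain-only "replacement" mechanism was evaluated
  and produces a flat-to-negative entropy response (normalized SampEn is
  insensitive to pure amplitude scaling), which is why the added-scatterer
  mechanism is the one implemented.
* **Fibrosis** (`fibrosis_level` = σ of a lognormal amplitude multiplier on
  every scatterer): heterogeneous cross-sections make the normalized RF
  bursty, and sample entropy falls monotonically as σ grows at fixed high
  fat level.
* **Noise floor defaults to 0.** Additive electronic noise ties SampEn to
  SNR: as fat strengthens the signal over a fixed noise floor, entropy
  *falls*, reversing the steatosis direction. The generator therefore
  emulates noise-free beamformed RF; the parameter remains available.

The surrogate continuous reference ("HFF", percent) is the arbitrary
monotone map `2 + 60·fat_level`; ordinal steatosis grades (0–3) and
fibrosis scores (F0–F4) are construction bins of the generative levels.
Cohorts are written through the RF container I/O with a CSV manifest and
are bit-reproducible from a seed.

What the phantom does *not* emulate: lateral point-spread coupling between
lines (prototyped and rejected — with per-cell density fixed it saturates
the speckle and suppresses the steatosis response), attenuation,
scan-conversion geometry, coherent/structured scattering, and electronic
noise. Passing tests therefore demonstrate that the *pipeline* recovers the
directions the generator encodes, not that real livers behave this way.

## Calibration sweep

For every grid cell (WSL ∈ {1,2,3} PL, m ∈ 1…10, r ∈ 0.05…0.5) the
per-frame ROI-mean sample entropy is correlated (Pearson) with the
log-transformed continuous reference; the reference transform is a flag
(`log` default, `identity` available). Frames with undefined entropy at a
cell are dropped pairwise; a cell with more than half its frames undefined
is marked missing. `best_setting` takes the argmax with exact ties broken
toward smaller WSL (spatial resolution), then smaller m, then smaller r.
Within the sweep the ROI restriction keeps windows whose center falls in
the mask — equivalent to averaging the interpolated map over the ROI
without paying for per-cell interpolation.

A caveat this package's own simulations establish: on diffuse
convolutional speckle sampled at 4 samples per carrier cycle the
discrimination landscape is nearly flat in m (at fs = 4 fc, two
consecutive samples already span the in-phase/quadrature state of the
narrowband signal, so quarter-cycle templates carry essentially the same
scatterer-density information as full-cycle ones). The argmax therefore
wanders over m ∈ {1,2,3} from cohort to cohort, while the correlation at
the recommended setting (WSL = 1, m = 4, r = 0.1) remains strongly
positive (r_p ≈ 0.7–0.9). Pinning the optimum to the carrier-cycle length
appears to require signal structure beyond diffuse speckle.

## Diagnostics

AUROC is the Mann–Whitney concordance with ties counted ½; its standard
error and the paired two-marker test use DeLong structural components
(placement values per positive and per negative subject; the paired
variance uses the component differences, which carries the covariance).
The operating point maximizes Youden's J = sensitivity + specificity − 1
over cutoffs placed midway between adjacent unique scores; J-ties resolve
toward higher sensitivity. All Table-style metrics (accuracy, PPV, NPV,
LR±) are recomputed from the 2×2 confusion table at that cutoff, and a
test asserts that consistency. The score direction is an explicit flag
(`higher_is_positive` for steatosis, `lower_is_positive` for fibrosis
within steatosis); auto-flipping would silently inflate AUROC. Class sizes
are reported alongside every result because small control groups make
p-values fragile. Significance threshold is 0.05.

## Problem sizes used by tests and the acceptance script

Direction-recovery cohorts use 20 frames per level of 512 × 64 samples;
the calibration sweep uses 8 frames per fat level (32 frames) of 320 × 40
samples; the DeLong bootstrap uses n = 200 subjects and 5 000–10 000
replicates. These sizes give standard errors a factor ≳ 5 below the
effects being asserted while keeping the full pipeline runs to a few
minutes.

## Known limitations

* Sample entropy carries an N-dependent bias on correlated series
  (temporally adjacent template pairs inflate match rates in short
  windows), so ROI means shift upward by ~15–25% from WSL = 1 to 3 PL;
  comparisons should fix the window size, as the default protocol does.
* The surrogate reference mapping is arbitrary (only monotonicity is
  meaningful); absolute entropy values from the phantom are not calibrated
  to clinical values.
* No scan conversion: images are in sample/line coordinates.
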