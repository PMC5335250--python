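# Methods

`holophase` implements a label-free discrimination pipeline for
peripheral-blood immune cells measured with two simultaneous modalities:
off-axis digital holographic microscopy (DHM), which yields a
quantitative phase map of each cell, and single-point Raman
spectroscopy, which yields a molecular fingerprint. Cells are described
by per-cell feature vectors and discriminated with PCA followed by
leave-one-out cross-validated nearest-neighbour classification. A
synthetic cohort generator stands in for instrument data so every stage
is testable.

## Hologram reconstruction

An off-axis hologram records `I = |O + R|^2` with object wave `O` and a
tilted plane reference `R`; the tilt places the interference term on a
spatial carrier, so in the 2D Fourier domain the +1 diffraction order is
spatially separated from the zero-order and conjugate terms.
Reconstruction proceeds as:

1. **Carrier search.** The strongest spectral peak outside a DC
   exclusion disc (default radius: 2% of the smaller spectrum dimension,
   at least 4 bins) is taken as the carrier. If no peak rises at least
   5x above the median off-DC magnitude, a "no carrier" error is raised.
2. **Sideband isolation.** A circular window centred on the peak — flat
   over the inner 60% of its radius, raised-cosine tapered to zero at
   radius = half the DC-to-peak distance — isolates the +1 order. A pure
   full-disc cosine taper measurably attenuates the low-frequency cell
   dome, which is why the tapered-edge (Tukey) profile is used. The
   windowed sideband is rolled to the spectrum centre (carrier
   demodulation) and inverse-transformed; the argument of the result is
   the wrapped phase.
3. **Edge margin.** Unless the carrier is bin-aligned, the FFT's
   implicit periodicity corrupts the outermost rows and columns of the
   demodulated phase (ripple of order 0.1–0.6 rad). A margin of 5% of
   the smaller field dimension (at least 16 px) is discarded on every
   side before any fitting.
4. **Unwrapping.** 2D phase unwrapping uses the reliability-sorted
   (quality-guided) algorithm of `skimage.restoration.unwrap_phase`.
   Output is congruent to the input modulo 2π at every pixel; on fields
   whose true pixel-to-pixel steps stay below π it recovers the surface
   up to a global 2πk offset. Unwrapping precedes the background fit:
   fitting a smooth surface to an unwrapped field is numerically robust,
   whereas fitting wrapped data is not well defined.
5. **Curvature compensation.** A full 6-coefficient degree-2 polynomial
   (1, x, y, x², xy, y²) is least-squares fitted over background pixels
   and subtracted, removing reference wave-front curvature and the
   sub-bin carrier tilt. Because a cell occupies only a few percent of
   the field, a first fit over *all* pixels is background-dominated; its
   residual has exactly zero mean, so the phase sign is fixed by the
   residual's third moment (the cell forms a heavy one-sided tail).
   The fit is then refined twice on pixels below the 75th percentile of
   the current residual — i.e. excluding the top quartile that holds the
   cell and its halo. Fitting only the *lowest* quartile was tried and
   rejected: a quadratic fitted to the lower envelope of the residual
   drifts downward and leaves broad spurious plateaus.
6. **Flooring and cropping.** The noise floor defaults to 3x the robust
   standard deviation (1.4826 × MAD) of the background residual; pixels
   below it are set exactly to zero. Above-floor pixels that are not
   8-connected to the blob with the largest integrated phase are zeroed
   too (a 3σ floor leaves ~0.3% of background pixels above threshold by
   chance). The final 220 × 220 px region of interest is centred on the
   intensity-weighted centroid; if cell signal reaches the crop border
   the call fails rather than silently truncating. OPD conversion is
   `opd = phase · λ / 2π` with λ = 532 nm by default.

For a frame series, the frame with the greatest fringe modulation
(carrier-peak to DC magnitude ratio) is selected.

Measured on noiseless synthetic phantoms, the full round trip
(render → reconstruct) has interior RMS phase error ≈ 0.007 rad and
recovers the integrated phase to within 0.5%.

## Phase-map descriptors

* **Intensity histogram** (default 64 bins): bin 0 counts *exactly-zero*
  pixels, so cell area enters the descriptor directly (PC1 of the
  histogram family is dominated by this bin); bins 1–63 uniformly tile
  (0, range_max], right-closed, with values above range_max clipped into
  the last bin. range_max is shared across a cohort (99.9th percentile
  of all positive phase values) so vectors are comparable; per-cell
  ranges would destroy that comparability. Histograms are computed on
  phase in radians — equivalent to OPD up to the fixed λ/2π factor.
* **Co-occurrence texture**: the map is quantized to 8 equal-width grey
  levels over its own [min, max]; pair counting is non-symmetric at
  distance 1. Statistics: contrast Σ(i−j)²P, correlation
  Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ), energy ΣP² (the sum of squared matrix
  elements, *not* its square root), homogeneity ΣP/(1+|i−j|).
  Per-image quantization makes all four statistics invariant to
  multiplying the map by a positive constant. The 4-vector uses the 0°
  offset; the 16-vector covers 0°/45°/90°/135°, angle-major. A
  zero-variance marginal makes correlation undefined; it is encoded as
  1.0 (the constant-image limit) with a warning, keeping vectors finite.
* **Concatenations** (histogram+texture, Raman+histogram): blocks are
  rescaled to unit sum before joining, since raw pixel counts (~5·10⁴)
  would otherwise swamp unit-normalized spectra.

## Raman preprocessing

Spectra are restricted to the fingerprint region 900–1700 cm⁻¹ and
divided by their total retained intensity (unit sum), cancelling
excitation-power fluctuations. The shared analysis grid is 1 cm⁻¹
spacing (801 points). Per-wavenumber class comparisons use Welch's
unequal-variance t-test; no multiple-testing correction is applied
because the maps are used with extreme display thresholds (10⁻⁸–10⁻¹⁸)
as a qualitative band-finding device, not as inference. Zero-variance
columns get p = 0 when the means differ and p = 1 otherwise. No
baseline subtraction is performed in the main path (it was reported not
to change discrimination results in the source measurements); callers
can pre-apply their own baseline remover.

## Classification

PCA is implemented from scratch (mean-centred SVD; covariance
eigenvalues s²/(n−1); component signs fixed by making the
largest-magnitude loading positive). LOOCV refits the PCA for every
held-out cell and classifies it by the Euclidean nearest training
neighbour in PC-score space; scores are not eigenvalue-whitened, and
ties resolve to the smallest training-row index. Default PC counts:
10 for spectra, histograms and concatenations; 3 for the 4-value
texture vector (bounded by its dimension).

For a class pair (A, B):
`sensitivity(A vs B) = N(A→A) / (N(A→A) + N(B→A))` and
`specificity(A vs B) = N(B→B) / (N(B→B) + N(A→B))`, with N(X→Y) read
from the LOOCV confusion matrix. Percentages are rounded half-up to one
decimal at the reporting layer, and the "average" rows are the
unweighted means of the *rounded* pairwise values, again rounded
half-up — exact decimal arithmetic, chosen because it reproduces the
published reference tables digit for digit (raw-fraction averaging
differs in the last digit, e.g. 98.2 vs the printed 98.3).

## Synthetic cohorts

The generator emulates the three measured classes:

| parameter (mean ± sd)  | CD4-like    | B-cell-like | monocyte-like |
|------------------------|-------------|-------------|---------------|
| dome radius (px)       | 28 ± 1.5    | 30 ± 3.5    | 45 ± 3.5      |
| peak phase (rad)       | 2.2 ± 0.12  | 2.4 ± 0.30  | 3.2 ± 0.25    |
| texture amplitude (rad)| 0.05 ± 0.01 | 0.10 ± 0.03 | 0.30 ± 0.05   |
| texture corr. len. (px)| 6 ± 0.5     | 6 ± 0.5     | 10 ± 1        |

These values are the package's own choices (no quantitative per-class
morphology is published); they encode the documented qualitative
contrasts — monocytes clearly larger with larger total OPD and coarser
internal structure; B cells more variable than CD4 T cells — at
magnitudes plausible for lymphocytes (~8 µm) vs monocytes (~12–15 µm)
at ~0.35 µm/px sampling and a few radians of peak phase at 532 nm.

A cell is a truncated-paraboloid phase dome (closed-form volume
πR²h/2) plus a Gaussian random field smoothed to the class correlation
length, tapered by the dome profile so the texture vanishes at the rim;
phase is exactly zero outside the disc and the object is pure phase
(unit amplitude). Holograms are two-beam interference with carrier
(0.2, 0.2) cycles/px, additive Gaussian intensity noise (σ = 0.02 on a
[0, 4] intensity scale) and 8-bit quantization; shot noise and
diffraction blur are deliberately omitted. The default detector is
512 × 512 px (any shape ≥ the ROI works, including 1024 × 960); the
smaller default keeps a full 213-cell cohort within minutes on one CPU.

Raman spectra are sums of Gaussian bands at 938, 1129, 1259, 1304,
1421, 1455, 1585 and 1665 cm⁻¹ over a smooth quadratic baseline with
additive noise (σ = 0.03 against band heights of ~0.5–1.5). Band
heights differ between classes at the bands reported to discriminate
the corresponding real populations: CD4 vs B at 1455/1585/1665 cm⁻¹,
CD4 vs monocyte additionally at 938/1129/1421 cm⁻¹, B vs monocyte at
1259/1304 cm⁻¹.

All randomness derives from one cohort seed split into per-cell
(phantom, hologram, spectrum) streams via `numpy.random.SeedSequence`,
so every output is a pure function of seed and parameters.

**What passing synthetic tests do and do not show.** The generator
reproduces the *structure* of the measurement (carrier-encoded phase,
quantization, band-limited intracellular texture, class-distinct
spectral bands) but not donor variability, optical aberrations beyond
quadratic curvature, shot noise, focus drift, or biological outliers.
End-to-end results on synthetic cohorts therefore validate the
pipeline's correctness and its qualitative behaviour (monocytes easy,
CD4 vs B hard), not clinical performance on real cells. The published
per-class texture means and confusion matrices of the real measurements
are not reproducible from synthetic data; only metrics derivable from
the printed tables are checked exactly.

## Numerical choices and degenerate inputs

* Sideband choice: strongest off-DC peak; the conjugate ambiguity is
  resolved after reconstruction by the residual's third moment rather
  than by half-plane convention, which is robust to either carrier
  orientation.
* Constant (fringe-free) images raise "no carrier"; constant phase maps
  produce a flagged all-in-one-cell GLCM, not an error.
* A background mask covering < 10% of pixels, or one whose geometry is
  rank-deficient for the quadratic design, is rejected by name.
* An empty (all-zero-after-floor) field raises "no cell detected"; a
  cell reaching the ROI border raises "cell exceeds ROI". A zero-phase
  hologram under 8-bit quantization leaves a structured sub-floor
  ripple, so it terminates in one of these named errors or in an ROI of
  negligible mass — it never fabricates a believable cell.
* LOOCV requires ≥ 2 members per class and k ≤ min(n−2, d); explicit
  out-of-range k is an error, defaulted k is capped.

## Known limitations

* Phase and features are computed in pixel/radian units; no physical
  pixel-pitch scaling is applied (discrimination does not need it).
* Refractive index and thickness are not separable from a single
  wavelength; the phase map is their product.
* The nearest-neighbour rule uses a single neighbour; no alternative
  classifiers are provided.
* The reconstruction assumes a single cell per field of view.
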