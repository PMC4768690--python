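# Methods

## Pipeline model

The package treats species identification as closed-contour shape
classification. The otolith's outline is reduced to a one-dimensional polar
signature r(θ) — the distance from the segmented region's center of gravity
to each boundary pixel — and classified from a compact spectral summary of
that signature. The underlying assumptions are: one otolith per image, the
object darker/lighter separable from the background at a fixed intensity
threshold, and the centroid interior to the outline (true for the roughly
convex sagittae this pipeline targets; strongly non-star-convex outlines
make the angle ordering of the signature ambiguous, see below).

## Preprocessing

* **Threshold 0.1** on a [0, 1]-normalized grayscale image, foreground =
  intensity strictly greater than the threshold. Integer images are divided
  by their dtype maximum first. The low threshold accommodates otoliths
  over a wide range of transparency.
* **Mask cleanup order**: border-touching components removed first, then
  holes filled, then components under `min_area` = 50,000 px removed. The
  order matters: a hole must not disqualify an object from the area test.
  The area default presumes ~6.3× magnification imaging; the synthetic
  fixtures either render large shapes or lower `min_area` explicitly.
* **Connectivity**: 8-connectivity for foreground components and boundary
  tracing, the complementary 4-connectivity for background when filling
  holes. Boundary tracing is Moore-neighbour tracing started at the
  topmost-leftmost pixel; the traced cycle is re-oriented counterclockwise
  in a y-up frame (positive signed area) if needed.
* **Centroid** is the mean pixel coordinate of the filled component, not of
  its boundary — the center of gravity of the otolith silhouette.
* **Angle frame**: rows increase downward in images, so row offsets are
  negated; angle 0 at the positive x-axis, counterclockwise. The signature
  starts at the boundary point whose angle is circularly closest to 0.
* **Ordering**: `traversal` (default) keeps boundary-trace order, whose
  near-unit pixel spacing is what FFT resampling assumes; `angle_sorted`
  sorts by angle and matches a radius-vs-angle plot's x-axis. Synthetic
  shapes are star-convex, where the two nearly coincide.

## Feature extraction

* **Resampling**: the signature is treated as one period of a periodic
  signal (natural for a closed contour) and band-limited resampled to
  N = 1,000 samples via `scipy.signal.resample` (FFT truncation /
  zero-padding).
* **STFT**: consecutive segments of L = 100 samples with O = 40 overlap
  (hop 60), each multiplied by the window and transformed with an
  `nfft = max(256, 2^⌈log₂ L⌉)`-point DFT, keeping one-sided bins — the
  only nfft rule that yields 129 bins at L = 100. Trailing samples that do
  not fill a window are discarded, so S = ⌊(N−O)/(L−O)⌋ = 16. No
  detrending or mean removal is applied before windowing (an optional
  mean-removal switch exists for experimentation).
* **Windows**: 16 kinds via `scipy.signal.windows`, symmetric. Shape
  parameters are configurable with conventional defaults — Gaussian
  α = 2.5 in the reciprocal-sigma convention (σ = (L−1)/(2α)), Kaiser
  β = 0.5, Chebyshev 100 dB sidelobes, Tukey ratio 0.5.
* **Features**: per segment, |X_f| and the principal-value phases
  arg X_f ∈ (−π, π] (no unwrapping) are z-scored across the 129 bins with
  sample (n−1) standard deviation (`ddof` configurable) and the maxima
  retained. Z-scoring is within-segment across bins. The PSD display of a
  spectrogram is visualization only; features use the raw complex
  coefficients. Because z-scores are scale-free and phases ignore positive
  scaling, the features are invariant to multiplying the signal by any
  c > 0 — algebraically exact, and bit-exact in floating point for
  power-of-two factors (last-ulp differences otherwise).

## Classification

Linear discriminant analysis with pooled within-class covariance
(denominator n − K): with d = 32 features and a few dozen samples per
class, per-class covariances are not estimable, so the linear flavor is
the principled choice. Priors are uniform by default (the designs here are
balanced); empirical priors are available. Prediction ties break
deterministically by class order. If the covariance's condition number
exceeds 1e12 and a ridge is supplied, `ridge · trace(Σ)/d · I` is added
and recorded on the model; a singular covariance with ridge 0 raises an
error naming the remedy. Train/test splitting is the caller's
responsibility (a seeded fixed-count splitter is provided), matching the
fixed per-species train/test design.

## Synthetic data

Each species is r(θ) = R(1 + Σ aₖ cos(kθ + φₖ) + ε(θ)): base radius R
(default 150 px → ~70,000 px objects, above the default object filter), one
or more diagnostic harmonics of order ≥ 2, and smooth specimen noise ε — a
random combination of order 6–13 cosines with exactly the requested angular
standard deviation (default 0.01·R). Noise is smooth rather than per-pixel
to mimic biological outline variation, and amplitudes are budgeted
(Σ|aₖ| + 4·sd < 0.5) so every shape is star-convex with strictly positive
radius. Rendering marks a pixel foreground iff its center lies inside the
contour, at intensities 0.2/0.05 so the 0.1 threshold recovers the mask
exactly. Everything derives from `(seed, specimen_index)` through numpy's
seed-sequence spawning, so datasets are bit-reproducible.

The reference study conditions used by the end-to-end tests and the
acceptance script are three species with diagnostic harmonic orders 2, 3
and 5 at amplitude 0.15, noise sd 0.01, 18 training and 10 test specimens
per species on 512² canvases. What the generator does *not* emulate:
photographic texture, illumination gradients, the sulcus acusticus, shadow
or debris, and realistic within-species allometry. Passing end-to-end
tests therefore demonstrates the pipeline's correctness and its ability to
separate genuinely distinct outline families; it does not certify any
particular accuracy on real photographs.

## Numerical choices and problem sizes

* FFT resampling and the STFT use double precision throughout; the STFT is
  validated against a naive windowed-DFT oracle to 1e-9 relative.
* The discriminant stage solves with an explicit inverse of the (possibly
  ridged) pooled covariance; scores are validated against an
  elimination-based closed-form oracle to 1e-9 and predictions
  cross-checked against an independent LDA implementation.
* Unit and property tests run on reduced geometries (40–60 px shapes on
  128–256 px canvases with the object filter lowered to 500 px, 5-seed
  averages for the noise-monotonicity check) — small enough for quick
  iteration while exercising identical code paths; the end-to-end checks
  use the full-size study conditions above.
* Degenerate inputs fail loudly with typed errors: empty masks after
  cleanup, boundaries shorter than 4 pixels, zero radii (centroid on the
  boundary), zero-variance spectra (e.g. an all-zero signal), singular
  covariances, unseen test labels.

## Known limitations

* Accuracy figures on real photographs depend on imaging conditions; the
  published per-family tables can only be re-derived from their printed
  confusion matrices (which the acceptance script does) or by re-running
  the experiment on the original photographs via
  `scripts/replicate_real_data.py` — no accuracy gate is attached to the
  latter.
* No left/right mirroring, multi-otolith segmentation, illumination
  correction, wavelet or elliptic-Fourier feature extractors, quadratic
  DA, or alternative classifiers; cross-validation beyond the fixed split
  is out of scope.
* For non-star-convex outlines the radius signature is not a function of
  angle; `traversal` ordering remains well-defined but two shapes can in
  principle share a signature.
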