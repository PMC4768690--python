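"""STFT feature extraction from contour radius signals.

The radius signal is band-limited-resampled to a fixed length (1,000 samples
by default, treating the closed contour as one period of a periodic signal),
split into overlapping windowed segments (100-sample window, 40-sample
overlap -> 16 segments), and each segment is Fourier transformed. Per
segment, the one-sided spectrum's magnitudes and principal-value phase
angles are z-scored across the frequency bins and the two maxima retained:
MAX_ABS and MAX_ANG. With 16 segments this yields the 32-element feature
vector that feeds the discriminant classifier.

The default 256-point FFT gives 129 one-sided frequency bins per segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import resample as _fft_resample
from scipy.signal import windows as _w

from .contour import ContourSignal
from .errors import DegenerateSpectrumError, InvalidInputError, UnsupportedWindowError

__all__ = [
    "WINDOW_KINDS",
    "WindowSpec",
    "Spectrogram",
    "FeatureVector",
    "resample_fft",
    "make_window",
    "stft",
    "extract_features",
    "feature_names",
]

# window kind -> (scipy name, needs shape parameter, default shape parameter)
# Shape-parameter defaults follow the conventions of common signal-processing
# environments: gaussian alpha (reciprocal-sigma) 2.5, kaiser beta 0.5,
# chebyshev sidelobe attenuation 100 dB, tukey taper ratio 0.5.
_WINDOWS: dict[str, tuple[str, bool, float | None]] = {
    "bartlett_hann": ("barthann", False, None),
    "bartlett": ("bartlett", False, None),
    "blackman": ("blackman", False, None),
    "blackman_harris": ("blackmanharris", False, None),
    "bohman": ("bohman", False, None),
    "chebyshev": ("chebwin", True, 100.0),
    "flat_top": ("flattop", False, None),
    "gaussian": ("gaussian", True, 2.5),
    "hamming": ("hamming", False, None),
    "hann": ("hann", False, None),
    "kaiser": ("kaiser", True, 0.5),
    "nuttall": ("nuttall", False, None),
    "parzen": ("parzen", False, None),
    "rectangular": ("boxcar", False, None),
    "tukey": ("tukey", True, 0.5),
    "triangular": ("triang", False, None),
}

WINDOW_KINDS: tuple[str, ...] = tuple(_WINDOWS)


@dataclass(frozen=True)
class WindowSpec:
    """STFT windowing configuration.

    Attributes
    ----------
    kind
        One of the 16 supported window function names (:data:`WINDOW_KINDS`).
    length
        Window length L in samples (default 100).
    overlap
        Overlap O between consecutive segments, 0 <= O < L (default 40).
    shape_param
        Optional shape parameter: gaussian alpha (reciprocal sigma,
        default 2.5), kaiser beta (0.5), chebyshev sidelobe dB (100),
        tukey taper ratio (0.5). Ignored for parameter-free windows.
    """

    kind: str = "gaussian"
    length: int = 100
    overlap: int = 40
    shape_param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _WINDOWS:
            raise UnsupportedWindowError(
                f"unknown window kind {self.kind!r}; choose from {sorted(_WINDOWS)}"
            )
        if not (0 <= self.overlap < self.length):
            raise InvalidInputError(
                f"need 0 <= overlap < length, got overlap={self.overlap}, length={self.length}"
            )

    @property
    def hop(self) -> int:
        return self.length - self.overlap


@dataclass(frozen=True)
class Spectrogram:
    """Complex STFT coefficients, segments x one-sided frequency bins.

    ``fs`` is the (normalized) sampling frequency label used for axis
    annotation only; it never enters the feature computation.
    """

    coeffs: np.ndarray
    fs: float = 2.0 * np.pi
    nfft: int = 256

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[1]


@dataclass(frozen=True)
class FeatureVector:
    """Per-segment maxima of z-scored magnitudes (MAX_ABS) and phases (MAX_ANG)."""

    max_abs: np.ndarray
    max_ang: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.max_abs, self.max_ang])

    def __len__(self) -> int:
        return self.max_abs.size + self.max_ang.size


def feature_names(n_segments: int = 16, feature_set: str = "combined") -> list[str]:
    """Column names f01..f32 (f01..f16 = MAX_ABS by segment, rest MAX_ANG)."""
    abs_names = [f"f{i + 1:02d}" for i in range(n_segments)]
    ang_names = [f"f{i + 1 + n_segments:02d}" for i in range(n_segments)]
    if feature_set == "abs_only":
        return abs_names
    if feature_set == "ang_only":
        return ang_names
    if feature_set == "combined":
        return abs_names + ang_names
    raise InvalidInputError(f"unknown feature_set {feature_set!r}")


def resample_fft(signal: ContourSignal | np.ndarray, n: int = 1000) -> np.ndarray:
    """Band-limited (FFT) resampling of the radius sequence to `n` samples.

    The contour is closed, so the radius sequence is treated as one period of
    a periodic signal: forward FFT, symmetric truncation/zero-padding of the
    spectrum to `n` bins with amplitude rescaling, inverse FFT, real part.
    """
    x = signal.radii if isinstance(signal, ContourSignal) else np.asarray(signal, dtype=float)
    if n < 4:
        raise InvalidInputError(f"resample length must be >= 4, got {n}")
    if x.ndim != 1 or x.size < 4:
        raise InvalidInputError("signal must be 1D with at least 4 samples")
    if x.size == n:
        return x.astype(float, copy=True)
    return np.asarray(_fft_resample(x, n), dtype=float)


def make_window(spec: WindowSpec) -> np.ndarray:
    """Return the symmetric window of the requested kind and length."""
    name, takes_param, default = _WINDOWS[spec.kind]
    if takes_param:
        param = spec.shape_param if spec.shape_param is not None else default
        if spec.kind == "gaussian":
            # alpha is the reciprocal standard deviation: sigma = (L-1)/(2*alpha)
            param = (spec.length - 1) / (2.0 * param)
        return _w.get_window((name, param), spec.length, fftbins=False)
    return _w.get_window(name, spec.length, fftbins=False)


def default_nfft(length: int) -> int:
    """FFT length: max(256, next power of two >= window length)."""
    return max(256, 2 ** math.ceil(math.log2(length)))


def stft(x: np.ndarray, spec: WindowSpec | None = None, nfft: int | None = None) -> Spectrogram:
    """Short-time Fourier transform with consecutive overlapping segments.

    Segment s covers samples [s*hop, s*hop + L) with hop = L - O; each
    segment is multiplied by the window and transformed with a length-nfft
    DFT, keeping the one-sided bins 0..nfft/2. Trailing samples that do not
    fill a window are discarded, so S = floor((N - O) / hop).
    """
    if spec is None:
        spec = WindowSpec()
    x = np.asarray(x, dtype=float)
    n = x.size
    length, hop = spec.length, spec.hop
    if length > n:
        raise InvalidInputError(f"window length {length} exceeds signal length {n}")
    if nfft is None:
        nfft = default_nfft(length)
    if nfft < length:
        raise InvalidInputError(f"nfft ({nfft}) must be >= window length ({length})")
    n_seg = (n - spec.overlap) // hop
    win = make_window(spec)
    starts = np.arange(n_seg) * hop
    segments = x[starts[:, None] + np.arange(length)] * win
    coeffs = np.fft.rfft(segments, n=nfft, axis=1)
    return Spectrogram(coeffs=coeffs, fs=2.0 * np.pi, nfft=nfft)


def _zscore(a: np.ndarray, ddof: int) -> np.ndarray:
    mu = a.mean(axis=-1, keepdims=True)
    sd = a.std(axis=-1, ddof=ddof, keepdims=True)
    if np.any(sd == 0.0):
        raise DegenerateSpectrumError(
            "zero-variance segment spectrum; input signal is degenerate"
        )
    return (a - mu) / sd


def extract_features(spec: Spectrogram, ddof: int = 1) -> FeatureVector:
    """Per-segment MAX_ABS / MAX_ANG features from an STFT.

    For each segment the magnitudes |X_f| and principal-value phase angles
    arg(X_f) in (-pi, pi] are z-scored across the frequency bins (sample
    standard deviation, ``ddof=1`` by default) and the maximum of each
    z-scored vector is retained. Z-scoring removes any common scale factor,
    so features are invariant to multiplying the signal by c > 0.
    """
    if spec.n_bins < 2:
        raise InvalidInputError("need at least 2 frequency bins per segment")
    mags = np.abs(spec.coeffs)
    angs = np.angle(spec.coeffs)
    max_abs = _zscore(mags, ddof).max(axis=1)
    max_ang = _zscore(angs, ddof).max(axis=1)
    return FeatureVector(max_abs=max_abs, max_ang=max_ang)
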