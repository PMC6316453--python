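"""Spectra and MFCC featurization of 800-sample impulse responses.

The ring-down of a tap is short and the sample rate low, so spectra are
computed on a heavily zero-padded transform (8192 points) and reduced to
a 100-point grid over the analysis band.  For classification each
segment becomes a mel-frequency cepstrum: 0.03 s frames hopped by
0.01 s give 18 frames; 21 triangular mel filters, a floored log and an
orthonormal DCT-II give 21 coefficients per frame, flattened frame-major
into a 378-element vector.  Consistently low-valued coefficients can be
pruned before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import dct

from .extraction import IRSegment

N_COEFFS = 21
N_FRAMES = 18
N_FEATURES = N_COEFFS * N_FRAMES  # 378


def hz_to_mel(f):
    """m(f) = 2595·log10(1 + f/700), the common psychoacoustic pitch map."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass
class Spectrum:
    magnitudes: np.ndarray  # length n_points, >= 0
    freqs: np.ndarray  # Hz, uniform grid


@dataclass
class MelFilterbank:
    weights: np.ndarray  # (n_filters, n_bins)
    centers: np.ndarray  # Hz
    bin_freqs: np.ndarray  # Hz grid the weights live on


@dataclass
class MFCCConfig:
    rate: int = 4000
    window: float = 0.03  # s  -> 120 samples
    overlap: float = 0.02  # s  -> hop 0.01 s = 40 samples
    n_coeffs: int = N_COEFFS
    frame_nfft: int = 256
    fmin: float = 0.0
    fmax: float = 2000.0
    log_floor: float = 1e-10
    use_dct: bool = True  # False: raw log filterbank energies
    expected_frames: int | None = N_FRAMES  # None disables the frame-count check


@dataclass
class FeatureVector:
    mfcc: np.ndarray  # (n_coeffs, n_frames)
    patient_id: str = ""
    teacher: float | None = None  # 0 = OP, 1 = OK

    @property
    def vector(self) -> np.ndarray:
        """Frame-major flattening: frame 1's coefficients first."""
        return flatten_mfcc(self.mfcc)


def flatten_mfcc(mfcc: np.ndarray) -> np.ndarray:
    return np.asarray(mfcc).T.reshape(-1)


def unflatten_mfcc(vector: np.ndarray, n_coeffs: int = N_COEFFS) -> np.ndarray:
    v = np.asarray(vector)
    return v.reshape(-1, n_coeffs).T


def compute_spectrum(segment: IRSegment | np.ndarray, rate: float = 4000.0,
                     nfft: int = 8192, fmax: float = 500.0,
                     n_points: int = 100) -> Spectrum:
    """Zero-padded magnitude spectrum resampled to `n_points` over 0..fmax."""
    x = segment.samples if isinstance(segment, IRSegment) else np.asarray(segment, float)
    if nfft < len(x):
        raise ValueError("nfft must be at least the segment length")
    mag = np.abs(np.fft.rfft(x, nfft))
    bin_freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    grid = np.linspace(0.0, fmax, n_points)
    return Spectrum(magnitudes=np.interp(grid, bin_freqs, mag), freqs=grid)


def build_mel_filterbank(n: int = N_COEFFS, rate: float = 4000.0,
                         fmin: float = 0.0, fmax: float = 2000.0,
                         nfft: int = 256) -> MelFilterbank:
    """`n` triangular filters with vertices equally spaced on the mel scale."""
    if n < 1:
        raise ValueError("need at least one filter")
    if not (0 <= fmin < fmax <= rate / 2):
        raise ValueError("need 0 <= fmin < fmax <= Nyquist")
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    weights = np.zeros((n, len(bin_freqs)))
    for i in range(n):
        lo, c, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / (c - lo)
        down = (hi - bin_freqs) / (hi - c)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return MelFilterbank(weights=weights, centers=hz_pts[1:-1], bin_freqs=bin_freqs)


def frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    n_frames = 1 + (len(x) - win) // hop
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_mfcc(segment: IRSegment | np.ndarray, cfg: MFCCConfig | None = None,
                 patient_id: str | None = None, teacher: float | None = None,
                 filterbank: MelFilterbank | None = None) -> FeatureVector:
    """MFCC matrix (n_coeffs × n_frames) of one segment.

    Per frame: Hamming taper → zero-padded power spectrum → triangular
    mel filterbank energies → floored log → orthonormal DCT-II keeping
    all coefficients.  With the defaults an 800-sample segment at
    4 kHz yields 21 × 18 = 378 values.
    """
    cfg = cfg or MFCCConfig()
    x = segment.samples if isinstance(segment, IRSegment) else np.asarray(segment, float)
    if patient_id is None and isinstance(segment, IRSegment):
        patient_id = segment.patient_id
    win = int(round(cfg.window * cfg.rate))
    hop = int(round((cfg.window - cfg.overlap) * cfg.rate))
    if hop <= 0 or win > len(x):
        raise ValueError("invalid framing configuration for this segment")
    frames = frame_signal(x, win, hop)
    if cfg.expected_frames is not None and len(frames) != cfg.expected_frames:
        raise ValueError(
            f"framing yields {len(frames)} frames, expected {cfg.expected_frames}; "
            "set expected_frames=None to override")
    fb = filterbank or build_mel_filterbank(cfg.n_coeffs, cfg.rate, cfg.fmin,
                                            cfg.fmax, cfg.frame_nfft)
    tapered = frames * np.hamming(win)
    power = np.abs(np.fft.rfft(tapered, cfg.frame_nfft, axis=1)) ** 2
    energies = power @ fb.weights.T  # (n_frames, n_coeffs)
    log_e = np.log(np.maximum(energies, cfg.log_floor))
    if cfg.use_dct:
        coeffs = dct(log_e, type=2, norm="ortho", axis=1)
    else:
        coeffs = log_e
    return FeatureVector(mfcc=coeffs.T, patient_id=patient_id or "", teacher=teacher)


def prune_features(vectors, floor_threshold: float = 1e-6) -> np.ndarray:
    """Mask of coefficients worth keeping across a feature set.

    A coefficient index is dropped iff its maximum absolute value over
    every vector stays below the threshold — the 'consistently low'
    criterion.  The same mask must be applied to training and
    validation sets alike.
    """
    X = as_feature_matrix(vectors)
    if X.shape[0] < 1:
        raise ValueError("need at least one feature vector")
    return np.max(np.abs(X), axis=0) >= floor_threshold


def as_feature_matrix(vectors) -> np.ndarray:
    """Stack FeatureVectors (or raw rows) into an (n, n_features) array."""
    rows = [v.vector if isinstance(v, FeatureVector) else np.asarray(v, float)
            for v in vectors]
    return np.array(rows)


def find_spectral_peaks(spectra: list[Spectrum],
                        prominence_frac: float = 0.1) -> list[np.ndarray]:
    """Local maxima (Hz) above a relative prominence, per spectrum."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    out = []
    for s in spectra:
        peak = s.magnitudes.max()
        if peak == 0:
            out.append(np.array([]))
            continue
        idx, _ = sps.find_peaks(s.magnitudes, prominence=prominence_frac * peak)
        out.append(s.freqs[idx])
    return out
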