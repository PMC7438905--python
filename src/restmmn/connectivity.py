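"""Magnitude-squared coherence and band-averaged weighted networks.

Coherence between channels x and y,

    Coh_xy(f) = |S_xy(f)|^2 / (S_xx(f) S_yy(f)),

is estimated from Welch-averaged cross- and auto-spectra (Hann window, 2 s
segments, 50% overlap by default, giving 0.5 Hz resolution). The
band-averaged pairwise coherences form the symmetric weighted matrix w
(diagonal zero) that the graph stage binarizes.

The all-pairs estimator computes each channel's windowed segment spectra
once and forms every cross-spectrum from them, which is algebraically the
same per-pair estimate as ``scipy.signal.coherence`` with matching window
parameters (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.fft as sfft
from scipy import signal as sps

from .datatypes import BANDS, Band, Recording, ValidationError, get_band

__all__ = [
    "CoherenceSpectrum",
    "WeightedNetwork",
    "coherence_spectrum",
    "coherence_matrix",
    "band_average",
    "build_weighted_network",
    "build_weighted_networks",
]

DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class CoherenceSpectrum:
    """Pairwise magnitude-squared coherence on a frequency grid."""

    pair: tuple
    frequencies: np.ndarray
    coh: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.coh < -1e-9) or np.any(self.coh > 1 + 1e-9):
            raise ValidationError("coherence values must lie in [0, 1]")


@dataclass(frozen=True)
class WeightedNetwork:
    """Band-averaged coherence matrix: symmetric, zero diagonal, [0, 1]."""

    band: Band
    w: np.ndarray
    nodes: tuple

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("weight matrix shape does not match node list")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValidationError("weight matrix diagonal must be zero")
        if w.min() < -1e-9 or w.max() > 1 + 1e-9:
            raise ValidationError("weights must lie in [0, 1]")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "nodes", tuple(self.nodes))


def _segment_spectra(
    signals: np.ndarray, fs: float, window_s: float, overlap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed, mean-detrended segment spectra for each channel.

    Returns (frequencies, X) with X of shape (channels, segments, bins).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    nper = int(round(window_s * fs))
    if nper < 2:
        raise ValidationError("window too short")
    if not 0.0 <= overlap < 1.0:
        raise ValidationError("overlap must lie in [0, 1)")
    step = max(1, int(round(nper * (1.0 - overlap))))
    n = signals.shape[-1]
    n_seg = 1 + (n - nper) // step if n >= nper else 0
    if n_seg < 2:
        raise ValidationError(
            "need at least 2 Welch segments (single-segment coherence is "
            "identically 1); lengthen the signal or shorten the window"
        )
    idx = np.arange(nper)[None, :] + step * np.arange(n_seg)[:, None]
    # single precision keeps the 5-band, 19-channel analysis cheap; the
    # averaged coherence is accurate to ~1e-5, far below estimator noise
    segs = signals.astype(np.float32)[:, idx]  # (ch, seg, nper)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = sps.get_window("hann", nper).astype(np.float32)
    X = sfft.rfft(segs * win, axis=-1)
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, X


def coherence_matrix(
    signals: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    fmax: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs magnitude-squared coherence.

    Returns (frequencies, C) with C of shape (ch, ch, bins); ``fmax``
    truncates the frequency grid (the analysis bands stop at 60 Hz).
    """
    freqs, X = _segment_spectra(signals, fs, window_s, overlap)
    if fmax is not None:
        keep = freqs <= fmax
        freqs, X = freqs[keep], X[:, :, keep]
    S = (np.einsum("asf,bsf->abf", X, np.conj(X)) / X.shape[1]).astype(complex)
    auto = np.real(np.einsum("aaf->af", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.abs(S) ** 2 / denom
    C[~np.isfinite(C)] = 0.0
    return freqs, np.clip(C, 0.0, 1.0)


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    pair: tuple = ("x", "y"),
) -> CoherenceSpectrum:
    """Coherence spectrum of one channel pair (Welch-averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("signals must have equal length")
    freqs, C = coherence_matrix(np.vstack([x, y]), fs, window_s, overlap)
    return CoherenceSpectrum(pair=tuple(pair), frequencies=freqs, coh=C[0, 1])


def band_average(cs: CoherenceSpectrum, band: "Band | str") -> float:
    """Unweighted mean coherence over bins with low <= f < high."""
    band = get_band(band)
    mask = (cs.frequencies >= band.low) & (cs.frequencies < band.high)
    if not mask.any():
        raise ValidationError(
            f"no frequency bins inside band {band.name} "
            f"[{band.low}, {band.high}) Hz"
        )
    return float(cs.coh[mask].mean())


def build_weighted_networks(
    rec: Recording,
    bands: Optional[Sequence["Band | str"]] = None,
    nodes: Optional[Sequence[str]] = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> dict[str, WeightedNetwork]:
    """Band-averaged coherence networks for all requested bands at once.

    The spectra are estimated once per channel, so this is the economical
    entry point for the five-band analysis.
    """
    band_defs = [get_band(b) for b in (bands if bands is not None else BANDS)]
    node_list = list(nodes) if nodes is not None else list(rec.channel_labels)
    picked = rec.pick(node_list)  # raises naming any missing label
    fmax = max(b.high for b in band_defs)
    freqs, C = coherence_matrix(picked.signal, picked.fs, window_s, overlap, fmax=fmax)
    out = {}
    for band in band_defs:
        mask = (freqs >= band.low) & (freqs < band.high)
        if not mask.any():
            raise ValidationError(f"no frequency bins inside band {band.name}")
        w = C[:, :, mask].mean(axis=-1)
        w = 0.5 * (w + w.T)  # symmetric up to round-off by construction
        np.fill_diagonal(w, 0.0)
        out[band.name] = WeightedNetwork(band=band, w=w, nodes=tuple(node_list))
    return out


def build_weighted_network(
    rec: Recording,
    band: "Band | str",
    nodes: Optional[Sequence[str]] = None,
    window_s: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
) -> WeightedNetwork:
    """Weighted coherence network for a single band."""
    band = get_band(band)
    return build_weighted_networks(rec, [band], nodes, window_s, overlap)[band.name]
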