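"""Wavelet subband decomposition and overlapped windowing.

The detector front-end splits the raw lead into the five clinical EEG bands
with a Daubechies-3 discrete wavelet filter bank and cuts the signal into
fixed-length overlapped windows labelled from the arousal annotation.

At 200 Hz a ``level``-deep DWT yields detail components D1..Dlevel covering
dyadic ranges (D1 50-100 Hz, D2 25-50, ...) plus the final approximation.
Each component is reconstructed back to signal length and assigned to the
clinical band (delta < 4, theta 4-8, alpha 8-12, beta 12-30, gamma > 30 Hz)
whose range contains the component's nominal centre frequency.  The default
level of 5 is the shallowest that places the approximation fully inside the
delta band; level 3 is also accepted for fidelity with coarser setups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ._exceptions import ValidationError
from .signal_model import ArousalAnnotation, EEGRecord

__all__ = ["SubbandSet", "Window", "dwt_subbands", "window_signal"]

BAND_ORDER = ("delta", "theta", "alpha", "beta", "gamma")

#: Clinical assignment ranges (Hz); open-ended at the extremes.
_CLINICAL_RANGES = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, np.inf),
}


@dataclass(frozen=True)
class SubbandSet:
    """Per-band reconstructed signals, each the same length as the input."""

    bands: dict[str, np.ndarray]
    wavelet: str
    level: int
    #: nominal (lo_hz, hi_hz) covered by the DWT components mapped to each band
    nominal_ranges: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        lengths = {v.size for v in self.bands.values()}
        if len(lengths) > 1:
            raise ValidationError("subband signals differ in length")

    def sum(self) -> np.ndarray:
        return np.sum([self.bands[b] for b in BAND_ORDER], axis=0)


@dataclass(frozen=True)
class Window:
    """A fixed-length signal excerpt with its derived label."""

    samples: np.ndarray
    start_s: float
    label: int
    record_id: str
    band: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (1, 0, -1):
            raise ValidationError(f"window label must be in {{1,0,-1}}: {self.label}")


def _assign_band(lo: float, hi: float) -> str:
    center = (lo + hi) / 2.0
    for band, (blo, bhi) in _CLINICAL_RANGES.items():
        if blo <= center < bhi:
            return band
    return "gamma"


def dwt_subbands(record: EEGRecord, wavelet: str = "db3", level: int = 5) -> SubbandSet:
    """Decompose a record into the five clinical bands via a DWT filter bank.

    Each wavelet component (details D1..Dlevel and the approximation) is
    reconstructed to full signal length with all other coefficients zeroed;
    by linearity of the inverse transform the reconstructions sum back to
    the input to floating-point precision.
    """
    x = record.samples
    if level < 1:
        raise ValidationError("level must be >= 1")
    if x.size < 2**level:
        raise ValidationError(
            f"signal of {x.size} samples too short for level-{level} DWT"
        )
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValidationError(f"unknown discrete wavelet {wavelet!r}")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    bands = {b: np.zeros_like(x) for b in BAND_ORDER}
    nominal: dict[str, tuple[float, float]] = {}
    nyq = record.fs / 2.0
    # coeffs = [A_level, D_level, ..., D_1]
    for idx, _ in enumerate(coeffs):
        if idx == 0:
            lo, hi = 0.0, nyq / 2**level
        else:
            d = level - idx + 1  # detail order: idx=1 -> D_level, last -> D1
            lo, hi = nyq / 2**d, nyq / 2 ** (d - 1)
        zeroed = [np.zeros_like(c) if j != idx else c for j, c in enumerate(coeffs)]
        component = pywt.waverec(zeroed, wavelet)[: x.size]
        band = _assign_band(lo, hi)
        bands[band] = bands[band] + component
        blo, bhi = nominal.get(band, (lo, hi))
        nominal[band] = (min(blo, lo), max(bhi, hi))
    return SubbandSet(bands=bands, wavelet=wavelet, level=level, nominal_ranges=nominal)


def window_signal(
    record: EEGRecord,
    annotation: ArousalAnnotation,
    win_s: float = 1.0,
    overlap: float = 0.5,
    band: str | None = None,
    samples: np.ndarray | None = None,
) -> list[Window]:
    """Cut a record into overlapped fixed-length labelled windows.

    With ``W = round(win_s * fs)`` samples per window and hop
    ``H = round(win_s * (1 - overlap) * fs)``, the number of windows is
    ``floor((L - W) / H) + 1``.  A window is labelled ``1`` when at least
    half of its span lies inside label-1 intervals, ``-1`` when it touches
    any undefined (label ``-1``) region, and ``0`` otherwise.  Windows
    labelled ``-1`` are meant to be excluded downstream.

    ``samples`` allows windowing a derived signal (e.g. one subband) while
    keeping the record's timing and annotation; ``band`` tags the windows.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValidationError(f"overlap must be in [0, 1), got {overlap}")
    w = int(round(win_s * record.fs))
    if w < 2:
        raise ValidationError("window must span at least 2 samples")
    x = record.samples if samples is None else np.asarray(samples, dtype=np.float64)
    if x.size != record.n_samples:
        raise ValidationError("derived signal length differs from record length")
    if x.size < w:
        raise ValidationError(
            f"record of {x.size} samples shorter than one {w}-sample window"
        )
    hop = int(round(win_s * (1.0 - overlap) * record.fs))
    hop = max(1, hop)
    per_sample = annotation.label_samples(record.fs, record.n_samples)
    n_windows = (x.size - w) // hop + 1
    windows: list[Window] = []
    for k in range(n_windows):
        i0 = k * hop
        segment_labels = per_sample[i0 : i0 + w]
        if np.any(segment_labels == -1):
            label = -1
        elif np.count_nonzero(segment_labels == 1) * 2 >= w:
            label = 1
        else:
            label = 0
        windows.append(
            Window(
                samples=x[i0 : i0 + w].copy(),
                start_s=i0 / record.fs,
                label=label,
                record_id=record.record_id,
                band=band,
            )
        )
    return windows
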