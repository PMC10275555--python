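"""Short-time Fourier power spectrograms and fixed-size image rendering.

A rectangular (boxcar) analysis window slides over the signal; each segment
is discrete-Fourier transformed and squared to a one-sided power spectrum.
Interior frequency bins are doubled so that each frame satisfies Parseval's
identity exactly: ``sum_f power[t, f] / n_freq == sum_n segment[n]**2``.

Spectrograms are rendered to fixed-size grayscale images in [0, 1] — by
default 299x299, the input resolution of the downstream convolutional
feature extractor — after an optional decibel transform and min-max
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from ._exceptions import ValidationError
from .preprocess import Window

__all__ = ["STFTConfig", "Spectrogram", "SpectroImage", "stft_power", "render"]


@dataclass(frozen=True)
class STFTConfig:
    """Discretisation of the STFT: segment length, hop and DFT size, all in
    samples.  The analysis window shape is fixed to rectangular."""

    seg_len: int = 64
    hop: int = 8
    n_freq: int = 64

    def __post_init__(self) -> None:
        if not 1 <= self.hop <= self.seg_len <= self.n_freq:
            raise ValidationError(
                f"need 1 <= hop <= seg_len <= n_freq, got "
                f"hop={self.hop}, seg_len={self.seg_len}, n_freq={self.n_freq}"
            )


@dataclass(frozen=True)
class Spectrogram:
    """Non-negative time x frequency power grid."""

    power: np.ndarray  # (n_frames, n_bins)
    times_s: np.ndarray
    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        if self.power.ndim != 2 or self.power.size == 0:
            raise ValidationError("power must be a non-empty 2-D matrix")
        if np.any(self.power < 0):
            raise ValidationError("power entries must be non-negative")


@dataclass(frozen=True)
class SpectroImage:
    """Fixed-size grayscale image with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixels contain non-finite values")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def save_png(self, path: str) -> None:
        """Write as an 8-bit grayscale PNG (quantised to 256 levels)."""
        from PIL import Image

        Image.fromarray(
            np.round(self.pixels * 255.0).astype(np.uint8), mode="L"
        ).save(path, format="PNG")

    @classmethod
    def load_png(cls, path: str) -> "SpectroImage":
        from PIL import Image

        with Image.open(path) as img:
            pixels = np.asarray(img.convert("L"), dtype=np.float64) / 255.0
        return cls(pixels=pixels)


def stft_power(
    window: Window | np.ndarray, cfg: STFTConfig = STFTConfig(), fs: float = 200.0
) -> Spectrogram:
    """One-sided STFT power spectrogram of one signal window.

    ``power[t, f] = |DFT_f(segment_t)|**2`` under "ones" normalisation
    (rectangular window of unit height), with bins other than DC and
    Nyquist doubled to account for the conjugate-symmetric half.  The frame
    count is ``floor((N - seg_len) / hop) + 1``.
    """
    x = window.samples if isinstance(window, Window) else np.asarray(window, float)
    if x.size < cfg.seg_len:
        raise ValidationError(
            f"window of {x.size} samples shorter than seg_len={cfg.seg_len}"
        )
    n_frames = (x.size - cfg.seg_len) // cfg.hop + 1
    idx = np.arange(cfg.seg_len)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    segments = x[idx]
    spectrum = np.fft.rfft(segments, n=cfg.n_freq, axis=1)
    power = np.abs(spectrum) ** 2
    # fold the conjugate-symmetric half into the one-sided spectrum
    power[:, 1:] *= 2.0
    if cfg.n_freq % 2 == 0:
        power[:, -1] /= 2.0
    times = (cfg.hop * np.arange(n_frames) + cfg.seg_len / 2.0) / fs
    freqs = np.fft.rfftfreq(cfg.n_freq, d=1.0 / fs)
    return Spectrogram(power=power, times_s=times, freqs_hz=freqs)


def render(
    spec: Spectrogram, height: int = 299, width: int = 299, log_power: bool = True
) -> SpectroImage:
    """Render a spectrogram to a fixed-size normalised grayscale image.

    The optional decibel transform is ``10*log10(power + eps)`` with ``eps``
    taken relative to the spectrogram's peak power so that rendering is
    exactly invariant to overall power scaling; min-max normalisation then
    maps to [0, 1] (a constant spectrogram maps to all zeros), followed by
    bilinear resampling to ``height x width``.  Frequency runs along image
    rows (low at the top), time along columns.
    """
    if not np.all(np.isfinite(spec.power)):
        raise ValidationError("spectrogram contains non-finite power entries")
    grid = spec.power.T  # (freq, time)
    peak = grid.max()
    if log_power:
        eps = 1e-12 * peak if peak > 0 else 1e-12
        grid = 10.0 * np.log10(grid + eps)
    lo, hi = grid.min(), grid.max()
    if hi - lo <= 0:
        pixels = np.zeros((height, width))
    else:
        grid = (grid - lo) / (hi - lo)
        pixels = _resize(
            grid, (height, width), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        pixels = np.clip(pixels, 0.0, 1.0)
    return SpectroImage(pixels=pixels)
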