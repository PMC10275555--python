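"""EEG record and annotation types, synthetic generation, and container I/O.

The synthetic generator emulates the spectral picture that sleep scorers use
to mark cortical arousals on a single EEG lead: background sleep EEG is
dominated by slow (delta) activity, while an arousal is an abrupt, seconds-long
shift toward theta/alpha rhythms and activity above 16 Hz.  Records are built
as mixtures of band-limited Gaussian processes, one per clinical band
(delta < 4 Hz, theta 4-8, alpha 8-12, beta 12-30, gamma > 30), with arousal
intervals cross-faded in through a short raised-cosine ramp so the waveform
stays continuous at event boundaries.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ._exceptions import (
    ChannelNotFoundError,
    FormatError,
    PlacementError,
    ValidationError,
)

__all__ = [
    "BAND_RANGES_HZ",
    "EEGRecord",
    "ArousalAnnotation",
    "SynthConfig",
    "generate_record",
    "add_motion_noise",
    "write_record",
    "load_record",
]

#: Clinical EEG band edges in Hz.  For synthesis delta starts at 0.5 Hz
#: (DC-free) and gamma is capped below the default Nyquist of 100 Hz.
BAND_RANGES_HZ: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 48.0),
}

#: Relative band powers for background sleep EEG (delta-dominant) and for
#: arousal segments (elevated theta/alpha and > 16 Hz activity).
DEFAULT_BACKGROUND_WEIGHTS = {
    "delta": 1.0,
    "theta": 0.35,
    "alpha": 0.20,
    "beta": 0.10,
    "gamma": 0.04,
}
DEFAULT_AROUSAL_WEIGHTS = {
    "delta": 0.25,
    "theta": 0.80,
    "alpha": 1.00,
    "beta": 0.70,
    "gamma": 0.30,
}


@dataclass(frozen=True)
class EEGRecord:
    """One channel of EEG samples (microvolts) with its sampling rate."""

    samples: np.ndarray
    fs: float = 200.0
    channel: str = "O1-M2"
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class ArousalAnnotation:
    """Ordered, non-overlapping intervals ``(start_s, end_s, label)``.

    Labels follow the scoring convention: ``1`` arousal, ``0`` non-arousal,
    ``-1`` undefined (excluded from training and evaluation downstream).
    """

    intervals: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        ivs = tuple((float(s), float(e), int(l)) for s, e, l in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        prev_end = -math.inf
        for start, end, label in ivs:
            if not start < end:
                raise ValidationError(f"empty/inverted interval ({start}, {end})")
            if label not in (1, 0, -1):
                raise ValidationError(f"label must be in {{1, 0, -1}}, got {label}")
            if start < prev_end - 1e-9:
                raise ValidationError("intervals overlap or are unsorted")
            prev_end = end

    def normalized(self, duration_s: float, fill_label: int = 0) -> "ArousalAnnotation":
        """Return an annotation that exactly partitions ``[0, duration_s]``.

        Gaps are filled with ``fill_label``; abutting intervals with equal
        labels are merged.
        """
        events = [
            (max(0.0, s), min(duration_s, e), l)
            for s, e, l in self.intervals
            if e > 0 and s < duration_s
        ]
        out: list[list[float | int]] = []
        cursor = 0.0
        for start, end, label in events:
            if start > cursor + 1e-12:
                out.append([cursor, start, fill_label])
            out.append([start, end, label])
            cursor = end
        if cursor < duration_s - 1e-12:
            out.append([cursor, duration_s, fill_label])
        merged: list[list[float | int]] = []
        for iv in out:
            if merged and merged[-1][2] == iv[2] and abs(merged[-1][1] - iv[0]) < 1e-12:
                merged[-1][1] = iv[1]
            else:
                merged.append(list(iv))
        return ArousalAnnotation(tuple((s, e, l) for s, e, l in merged))

    def label_samples(self, fs: float, n_samples: int) -> np.ndarray:
        """Per-sample label array; samples outside any interval get 0."""
        labels = np.zeros(n_samples, dtype=np.int8)
        for start, end, label in self.intervals:
            i0 = max(0, int(round(start * fs)))
            i1 = min(n_samples, int(round(end * fs)))
            labels[i0:i1] = label
        return labels

    def intervals_with_label(self, label: int) -> list[tuple[float, float]]:
        return [(s, e) for s, e, l in self.intervals if l == label]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic single-lead EEG generator."""

    duration_s: float = 60.0
    fs: float = 200.0
    n_arousal_events: int = 2
    arousal_dur_range_s: tuple[float, float] = (5.0, 30.0)
    background_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_WEIGHTS)
    )
    arousal_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AROUSAL_WEIGHTS)
    )
    #: RMS amplitude of background EEG in microvolts.
    background_rms_uv: float = 20.0
    #: RMS amplitude of arousal-segment EEG in microvolts.
    arousal_rms_uv: float = 28.0
    #: Length of the raised-cosine cross-fade at event edges, seconds.
    ramp_s: float = 0.050
    #: Minimum gap between events and to the record edges, seconds.
    min_gap_s: float = 1.0
    noise_snr_db: float | None = None
    seed: int = 0
    channel: str = "O1-M2"
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        lo, hi = self.arousal_dur_range_s
        if lo <= 0 or hi < lo:
            raise ValidationError("arousal_dur_range_s must be positive and ordered")
        if self.n_arousal_events < 0:
            raise ValidationError("n_arousal_events must be >= 0")
        for name, weights in (
            ("background_weights", self.background_weights),
            ("arousal_weights", self.arousal_weights),
        ):
            vals = list(weights.values())
            if any(w < 0 for w in vals) or not any(w > 0 for w in vals):
                raise ValidationError(f"{name} must be non-negative, not all zero")


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (4th-order
    Butterworth, zero-phase)."""
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_mixture(
    rng: np.random.Generator,
    n: int,
    fs: float,
    weights: dict[str, float],
    rms_uv: float,
) -> np.ndarray:
    """Sum of band-limited processes with per-band power proportional to
    ``weights``, scaled to an overall RMS of ``rms_uv``."""
    total = np.zeros(n)
    for band, w in weights.items():
        if w <= 0:
            continue
        total += math.sqrt(w) * _band_limited_noise(rng, n, fs, BAND_RANGES_HZ[band])
    sd = total.std()
    if sd > 0:
        total *= rms_uv / sd
    return total


def _place_events(
    rng: np.random.Generator, cfg: SynthConfig
) -> list[tuple[float, float]]:
    """Draw non-overlapping (start, end) arousal intervals."""
    lo, hi = cfg.arousal_dur_range_s
    durations = rng.uniform(lo, hi, size=cfg.n_arousal_events)
    if durations.sum() + 2 * cfg.min_gap_s * cfg.n_arousal_events >= cfg.duration_s:
        raise PlacementError(
            f"cannot place {cfg.n_arousal_events} events totalling "
            f"{durations.sum():.1f}s in a {cfg.duration_s:.1f}s record"
        )
    placed: list[tuple[float, float]] = []
    for dur in durations:
        ok = False
        for _ in range(1000):
            start = rng.uniform(cfg.min_gap_s, cfg.duration_s - dur - cfg.min_gap_s)
            end = start + dur
            if all(
                end + cfg.min_gap_s <= s or start >= e + cfg.min_gap_s
                for s, e in placed
            ):
                placed.append((float(start), float(end)))
                ok = True
                break
        if not ok:
            raise PlacementError("event placement failed after 1000 attempts")
    return sorted(placed)


def generate_record(cfg: SynthConfig) -> tuple[EEGRecord, ArousalAnnotation]:
    """Generate a synthetic single-lead EEG record with arousal events.

    Returns a record of ``round(duration_s * fs)`` samples and an annotation
    that partitions ``[0, duration_s]`` into label-1 arousal intervals and
    label-0 background.  Arousal segments have, by construction, strictly
    more power above 8 Hz than background.  Identical configurations
    (including the seed) produce bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    background = _band_mixture(rng, n, cfg.fs, cfg.background_weights, cfg.background_rms_uv)
    events = _place_events(rng, cfg) if cfg.n_arousal_events else []
    if events:
        arousal = _band_mixture(rng, n, cfg.fs, cfg.arousal_weights, cfg.arousal_rms_uv)
        mask = np.zeros(n)
        ramp_n = max(1, int(round(cfg.ramp_s * cfg.fs)))
        ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, ramp_n)))
        for start, end in events:
            i0, i1 = int(round(start * cfg.fs)), int(round(end * cfg.fs))
            mask[i0:i1] = 1.0
            up_len = min(ramp_n, i1 - i0)
            mask[i0 : i0 + up_len] = ramp[:up_len]
            down_len = min(ramp_n, i1 - i0)
            mask[i1 - down_len : i1] = ramp[::-1][ramp_n - down_len :]
        samples = (1.0 - mask) * background + mask * arousal
    else:
        samples = background
    record = EEGRecord(samples, fs=cfg.fs, channel=cfg.channel, record_id=cfg.record_id)
    if cfg.noise_snr_db is not None and math.isfinite(cfg.noise_snr_db):
        record = add_motion_noise(record, cfg.noise_snr_db, seed=int(rng.integers(2**31)))
    annotation = ArousalAnnotation(
        tuple((s, e, 1) for s, e in events)
    ).normalized(cfg.duration_s, fill_label=0)
    return record, annotation


def add_motion_noise(
    record: EEGRecord, snr_db: float, seed: int = 0
) -> EEGRecord:
    """Add motion-artifact-like noise at a prescribed signal-to-noise ratio.

    Motion artifacts on scalp EEG are large, slow baseline excursions; they
    are emulated as Gaussian noise low-passed below 3 Hz and scaled so that
    ``10*log10(P_signal / P_noise) == snr_db`` exactly.  An infinite
    ``snr_db`` returns the record unchanged.
    """
    if record.n_samples == 0:
        raise ValidationError("record is empty")
    if snr_db is None or math.isinf(snr_db):
        return replace(record, samples=record.samples.copy())
    rng = np.random.default_rng(seed)
    sos = sps.butter(4, 3.0, btype="lowpass", fs=record.fs, output="sos")
    noise = sps.sosfiltfilt(sos, rng.standard_normal(record.n_samples))
    p_signal = float(np.mean(record.samples**2))
    p_target = p_signal / (10.0 ** (snr_db / 10.0))
    p_noise = float(np.mean(noise**2))
    if p_noise <= 0:
        raise ValidationError("degenerate noise realisation")
    noise *= math.sqrt(p_target / p_noise)
    return replace(record, samples=record.samples + noise)


# ---------------------------------------------------------------------------
# container I/O: flat little-endian float32 payload + text header + TSV sidecar
# ---------------------------------------------------------------------------

_HEADER_SUFFIX = ".hdr"
_DATA_SUFFIX = ".dat"
_SIDECAR_SUFFIX = ".tsv"


def _strip_suffix(path: str) -> str:
    for suffix in (_HEADER_SUFFIX, _DATA_SUFFIX, _SIDECAR_SUFFIX):
        if path.endswith(suffix):
            return path[: -len(suffix)]
    return path


def write_record(
    record: EEGRecord, annotation: ArousalAnnotation | None, path_prefix: str
) -> None:
    """Write ``<prefix>.hdr`` (text header), ``<prefix>.dat`` (float32 LE
    samples) and, when an annotation is given, ``<prefix>.tsv``."""
    prefix = _strip_suffix(path_prefix)
    with open(prefix + _HEADER_SUFFIX, "w") as fh:
        fh.write("format=sleeparousal-eeg-v1\n")
        fh.write(f"fs={record.fs!r}\n")
        fh.write(f"channel={record.channel}\n")
        fh.write(f"record_id={record.record_id}\n")
        fh.write(f"n_samples={record.n_samples}\n")
        fh.write("dtype=<f4\n")
    record.samples.astype("<f4").tofile(prefix + _DATA_SUFFIX)
    if annotation is not None:
        write_annotation(annotation, prefix + _SIDECAR_SUFFIX)


def write_annotation(annotation: ArousalAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tlabel\n")
        for start, end, label in annotation.intervals:
            fh.write(f"{start:.3f}\t{end:.3f}\t{label}\n")


def read_annotation(path: str) -> ArousalAnnotation:
    intervals = []
    with open(path) as fh:
        header = fh.readline()
        if header.split() != ["start_s", "end_s", "label"]:
            raise FormatError(f"{path}: bad sidecar header {header!r}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{line_no}: expected 3 columns")
            try:
                start, end, label = float(parts[0]), float(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{line_no}: {exc}") from exc
            intervals.append((start, end, label))
    return ArousalAnnotation(tuple(intervals))


def load_record(
    path: str, channel: str | None = None
) -> tuple[EEGRecord, ArousalAnnotation]:
    """Load a record (and its sidecar annotation, if present).

    ``path`` may be an internal-container prefix (or its .hdr/.dat file) or
    an EDF file (requires ``mne``; the channel is selected by label).  A
    missing sidecar yields a single label ``-1`` interval spanning the
    record, i.e. fully undefined.
    """
    if path.lower().endswith(".edf"):
        return _load_edf(path, channel)
    prefix = _strip_suffix(path)
    header_path = prefix + _HEADER_SUFFIX
    if not os.path.exists(header_path):
        raise FormatError(f"no container header found at {header_path}")
    header: dict[str, str] = {}
    with open(header_path) as fh:
        for line in fh:
            if "=" in line:
                key, _, value = line.partition("=")
                header[key.strip()] = value.strip()
    if header.get("format") != "sleeparousal-eeg-v1":
        raise FormatError(f"{header_path}: unknown container format")
    if channel is not None and channel != header["channel"]:
        raise ChannelNotFoundError(
            f"channel {channel!r} not in record (has {header['channel']!r})"
        )
    samples = np.fromfile(prefix + _DATA_SUFFIX, dtype=header.get("dtype", "<f4"))
    if samples.size != int(header["n_samples"]):
        raise FormatError(f"{prefix}{_DATA_SUFFIX}: truncated payload")
    record = EEGRecord(
        samples.astype(np.float64),
        fs=float(header["fs"]),
        channel=header["channel"],
        record_id=header.get("record_id", os.path.basename(prefix)),
    )
    sidecar = prefix + _SIDECAR_SUFFIX
    if os.path.exists(sidecar):
        annotation = read_annotation(sidecar)
    else:
        annotation = ArousalAnnotation(((0.0, record.duration_s, -1),))
    return record, annotation


def _load_edf(path: str, channel: str | None) -> tuple[EEGRecord, ArousalAnnotation]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional capability
        raise FormatError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel is None:
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise ChannelNotFoundError(f"channel {channel!r} not in {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    record = EEGRecord(
        data, fs=float(raw.info["sfreq"]), channel=channel,
        record_id=os.path.splitext(os.path.basename(path))[0],
    )
    sidecar = os.path.splitext(path)[0] + _SIDECAR_SUFFIX
    if os.path.exists(sidecar):
        annotation = read_annotation(sidecar)
    else:
        annotation = ArousalAnnotation(((0.0, record.duration_s, -1),))
    return record, annotation
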