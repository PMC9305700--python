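"""Continuous recordings → per-class averaged evoked responses.

Chain: zero-phase Butterworth bandpass, epoch extraction around stimulus
onsets, baseline correction on the pre-onset samples, absolute-amplitude
artifact rejection, epoch averaging with low-pass and baseline re-applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import CHANNELS, EPOCH_WINDOWS_MS, EventSchedule

log = logging.getLogger(__name__)

__all__ = [
    "EpochWindow",
    "SubjectErp",
    "bandpass_filter",
    "lowpass_filter",
    "rereference",
    "extract_epochs",
    "baseline_correct",
    "reject_artifacts",
    "average_epochs",
    "preprocess_recording",
    "preprocess_subject",
]


@dataclass(frozen=True)
class EpochWindow:
    """Epoch limits in ms around stimulus onset, on a given sample grid.

    Sample indices run inclusively from ``floor(t_min·fs/1000)`` to
    ``floor(t_max·fs/1000)`` relative to the onset sample; this is the only
    simple convention that yields both 257 samples for [-200, 800] ms and
    155 samples for [-100, 500] ms at 256 Hz.
    """

    t_min_ms: float
    t_max_ms: float
    fs_hz: float

    def __post_init__(self) -> None:
        # t_min < 0 is required for baseline correction but a degenerate
        # window starting at onset is a valid epoching request
        if not (self.t_min_ms <= 0 <= self.t_max_ms):
            raise ValueError("need t_min <= 0 <= t_max")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def first_index(self) -> int:
        return math.floor(self.t_min_ms * self.fs_hz / 1000.0)

    @property
    def last_index(self) -> int:
        return math.floor(self.t_max_ms * self.fs_hz / 1000.0)

    @property
    def n_samples(self) -> int:
        return self.last_index - self.first_index + 1

    @property
    def n_baseline(self) -> int:
        """Number of strictly pre-onset samples (relative index < 0)."""
        return -self.first_index

    def times_ms(self) -> np.ndarray:
        return (
            np.arange(self.first_index, self.last_index + 1) / self.fs_hz * 1000.0
        )


@dataclass
class SubjectErp:
    """Averaged evoked responses of one subject.

    ``waveforms`` maps ``(paradigm, stimulus_class, channel)`` to a 1-D array;
    all entries of one paradigm share that paradigm's epoch window.
    """

    subject_id: str
    group: str
    fs_hz: float
    windows: dict[str, EpochWindow]
    waveforms: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def get(self, paradigm: str, stimulus: str, channel: str) -> np.ndarray:
        key = (paradigm, stimulus, channel)
        if key not in self.waveforms:
            raise KeyError(
                f"subject {self.subject_id}: missing waveform for "
                f"paradigm={paradigm} stimulus={stimulus} channel={channel}"
            )
        return self.waveforms[key]


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def bandpass_filter(
    signal: np.ndarray,
    fs_hz: float,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass; output has the input's shape."""
    if not (0 < low_hz < high_hz < fs_hz / 2):
        raise ValueError("need 0 < low < high < fs/2")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=fs_hz)
    x = _as_2d(signal)
    out = sps.sosfiltfilt(sos, x, axis=0)
    return out[:, 0] if np.asarray(signal).ndim == 1 else out


def lowpass_filter(
    signal: np.ndarray, fs_hz: float, high_hz: float = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (used when re-filtering averages)."""
    if not (0 < high_hz < fs_hz / 2):
        raise ValueError("need 0 < high < fs/2")
    sos = sps.butter(order, high_hz, btype="lowpass", output="sos", fs=fs_hz)
    x = _as_2d(signal)
    out = sps.sosfiltfilt(sos, x, axis=0)
    return out[:, 0] if np.asarray(signal).ndim == 1 else out


def rereference(
    recording: np.ndarray,
    channel_names: list[str],
    reference_channels: tuple[str, str] | None = None,
) -> np.ndarray:
    """Subtract the mean of two designated reference channels.

    Synthetic 3-channel data has no ear channels, so the default (no
    reference channels) is a pass-through; multi-channel external data can
    name its linked-ear pair.
    """
    rec = _as_2d(recording)
    if reference_channels is None:
        return rec
    try:
        idx = [channel_names.index(c) for c in reference_channels]
    except ValueError as err:
        raise ValueError(f"reference channel missing: {err}") from err
    return rec - rec[:, idx].mean(axis=1, keepdims=True)


def extract_epochs(
    recording: np.ndarray,
    events: EventSchedule,
    window: EpochWindow,
) -> dict[str, np.ndarray]:
    """Cut per-class epoch stacks out of a continuous recording.

    Returns ``{class label: (n_epochs, n_samples, n_channels)}``. The onset
    sample is ``round(onset_s · fs)``; epochs whose window would leave the
    recording are dropped with a warning.
    """
    rec = _as_2d(recording)
    stacks: dict[str, list[np.ndarray]] = {}
    dropped = 0
    for onset_s, label in events.events:
        s = int(round(onset_s * window.fs_hz))
        lo = s + window.first_index
        hi = s + window.last_index + 1
        if lo < 0 or hi > rec.shape[0]:
            dropped += 1
            continue
        stacks.setdefault(label, []).append(rec[lo:hi])
    if dropped:
        log.warning("dropped %d epochs whose window left the recording", dropped)
    return {lab: np.stack(eps) for lab, eps in stacks.items()}


def baseline_correct(epoch: np.ndarray, window: EpochWindow) -> np.ndarray:
    """Subtract the mean of the pre-onset samples from the whole epoch.

    Works on a single epoch ``(n_samples[, n_channels])`` or a stack
    ``(n_epochs, n_samples, n_channels)``; the sample axis is inferred from
    the window length.
    """
    nb = window.n_baseline
    if nb < 1:
        raise ValueError("window has no pre-onset samples to use as baseline")
    x = np.asarray(epoch, dtype=float)
    axis = next(i for i, n in enumerate(x.shape) if n == window.n_samples)
    baseline = np.take(x, np.arange(nb), axis=axis).mean(axis=axis, keepdims=True)
    return x - baseline


def reject_artifacts(
    epochs: np.ndarray, threshold_uV: float = 100.0, class_label: str = ""
) -> tuple[np.ndarray, int]:
    """Drop epochs where any sample on any channel exceeds ±threshold."""
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(epochs, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    keep = np.max(np.abs(flat), axis=1) <= threshold_uV
    if not keep.any():
        raise ValueError(
            f"artifact rejection removed every epoch"
            + (f" of class {class_label!r}" if class_label else "")
        )
    return x[keep], int((~keep).sum())


def average_epochs(
    epochs: np.ndarray,
    window: EpochWindow,
    lowpass_hz: float = 30.0,
) -> np.ndarray:
    """Samplewise mean, then low-pass and baseline correction re-applied."""
    x = np.asarray(epochs, dtype=float)
    if x.ndim < 2 or x.shape[0] < 1:
        raise ValueError("need at least one epoch to average")
    avg = x.mean(axis=0)
    avg = lowpass_filter(avg, window.fs_hz, high_hz=lowpass_hz)
    return baseline_correct(avg, window)


def preprocess_recording(
    recording: np.ndarray,
    events: EventSchedule,
    window: EpochWindow,
    *,
    bandpass: tuple[float, float] = (0.1, 30.0),
    artifact_threshold_uV: float = 100.0,
) -> dict[str, np.ndarray]:
    """Full chain on one continuous recording → per-class averaged ERPs.

    Returns ``{class label: (n_samples, n_channels)}``.
    """
    filtered = bandpass_filter(recording, window.fs_hz, *bandpass)
    stacks = extract_epochs(filtered, events, window)
    out = {}
    for label, stack in stacks.items():
        stack = baseline_correct(stack, window)
        kept, n_rej = reject_artifacts(stack, artifact_threshold_uV, label)
        if n_rej:
            log.info("class %s: rejected %d/%d epochs", label, n_rej, stack.shape[0])
        out[label] = average_epochs(kept, window, lowpass_hz=bandpass[1])
    return out


def preprocess_subject(
    subject,
    *,
    windows_ms: dict[str, tuple[float, float]] | None = None,
    artifact_threshold_uV: float = 100.0,
) -> SubjectErp:
    """Preprocess every paradigm of a :class:`~erpmkl.synthetic.SubjectRecording`."""
    windows_ms = windows_ms or EPOCH_WINDOWS_MS
    erp = SubjectErp(
        subject_id=subject.subject_id,
        group=subject.group,
        fs_hz=subject.fs_hz,
        windows={},
    )
    for paradigm, (rec, schedule) in subject.recordings.items():
        window = EpochWindow(*windows_ms[paradigm], fs_hz=subject.fs_hz)
        erp.windows[paradigm] = window
        averages = preprocess_recording(
            rec, schedule, window, artifact_threshold_uV=artifact_threshold_uV
        )
        for label, avg in averages.items():
            for ci, ch in enumerate(CHANNELS):
                erp.waveforms[(paradigm, label, ch)] = avg[:, ci]
    return erp
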