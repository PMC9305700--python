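"""Averaged ERPs → named feature vectors.

Per (paradigm, rare stimulus class, channel) the feature block is:
7 features per peak, 3 per adjacent peak pair, and 10 whole-signal features,
giving 2·3·(7·4 + 3·3 + 10) = 282 columns per four-peak paradigm and
2·3·(7·2 + 3·1 + 10) = 162 for the two-peak paradigm — 726 in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocessing import EpochWindow, SubjectErp
from .synthetic import CHANNELS, RARE_CLASSES

log = logging.getLogger(__name__)

__all__ = [
    "PeakMeasurement",
    "PeakWindowTable",
    "recenter_windows",
    "FeatureSchema",
    "FeatureTable",
    "PEAK_FEATURES",
    "PEAK_TO_PEAK_FEATURES",
    "SIGNAL_FEATURES",
    "detect_peak",
    "peak_features",
    "peak_to_peak_features",
    "area_features",
    "zero_crossing_features",
    "spectral_features",
    "extract_subject_features",
    "build_feature_table",
    "feature_category",
]

PEAK_FEATURES = (
    "amplitude",
    "latency",
    "abs_amplitude",
    "ratio",
    "abs_ratio",
    "avg_abs_slope",
    "slope_sign_alternations",
)

PEAK_TO_PEAK_FEATURES = ("pp_abs_amplitude_diff", "pp_latency_diff", "pp_slope")

SIGNAL_FEATURES = (
    "positive_area",
    "negative_area",
    "total_area",
    "abs_total_area",
    "zero_crossing",
    "zero_cross_density",
    "mode_frequency",
    "median_frequency",
    "mean_frequency",
    "rms",
)

#: default peak search windows (ms); the two-peak paradigm's peaks are
#: addressed positionally since published labels for them disagree
DEFAULT_PEAK_WINDOWS: dict[tuple[str, str], tuple[float, float]] = {
    ("auditory_p300", "N100"): (70.0, 160.0),
    ("auditory_p300", "P200"): (150.0, 260.0),
    ("auditory_p300", "N200"): (200.0, 330.0),
    ("auditory_p300", "P300"): (280.0, 600.0),
    ("visual_p300", "N100"): (70.0, 160.0),
    ("visual_p300", "P200"): (150.0, 260.0),
    ("visual_p300", "N200"): (200.0, 330.0),
    ("visual_p300", "P300"): (280.0, 600.0),
    ("mmn", "mmn_peak1"): (100.0, 250.0),
    ("mmn", "mmn_peak2"): (250.0, 450.0),
}

DEFAULT_PEAKS: dict[str, tuple[str, ...]] = {
    "auditory_p300": ("N100", "P200", "N200", "P300"),
    "visual_p300": ("N100", "P200", "N200", "P300"),
    "mmn": ("mmn_peak1", "mmn_peak2"),
}


@dataclass(frozen=True)
class PeakMeasurement:
    """Signed amplitude and latency of the largest-|value| sample in a window."""

    amplitude_uV: float
    latency_ms: float
    index: int  # absolute sample index into the epoch


@dataclass(frozen=True)
class PeakWindowTable:
    """Map (paradigm, peak label) → [t_start_ms, t_end_ms] search interval."""

    windows: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PEAK_WINDOWS)
    )

    def get(self, paradigm: str, peak: str) -> tuple[float, float]:
        return self.windows[(paradigm, peak)]


def recenter_windows(
    table: PeakWindowTable,
    grand_average: np.ndarray,
    paradigm: str,
    peaks: tuple[str, ...],
    window: "EpochWindow",
) -> PeakWindowTable:
    """Optionally re-center search windows on a grand-average's peaks.

    Each peak's interval keeps its width but is shifted so its midpoint sits
    on the peak detected in the grand average (clipped to the epoch).
    """
    t = window.times_ms()
    new = dict(table.windows)
    prev_idx: int | None = None
    for pk in peaks:
        lo, hi = table.get(paradigm, pk)
        pm = detect_peak(grand_average, (lo, hi), window, min_index=prev_idx)
        prev_idx = pm.index + 1
        half = (hi - lo) / 2.0
        start = max(float(t[0]), pm.latency_ms - half)
        end = min(float(t[-1]), pm.latency_ms + half)
        new[(paradigm, pk)] = (start, end)
    return PeakWindowTable(windows=new)


@dataclass(frozen=True)
class FeatureSchema:
    """Deterministic enumeration of feature columns.

    Column names read ``paradigm.stimulus.channel.peak.feature``; the peak
    slot holds a peak label, an adjacent pair like ``N100-P200``, or
    ``signal`` for whole-signal features.
    """

    paradigms: tuple[str, ...] = ("auditory_p300", "visual_p300", "mmn")
    stimulus_classes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {p: RARE_CLASSES[p] for p in RARE_CLASSES}
    )
    channels: tuple[str, ...] = CHANNELS
    peaks: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PEAKS)
    )

    def block_columns(self, paradigm: str, stimulus: str, channel: str) -> list[str]:
        """Columns for one (paradigm, stimulus, channel) averaged signal."""
        prefix = f"{paradigm}.{stimulus}.{channel}"
        peaks = self.peaks[paradigm]
        cols = [f"{prefix}.{pk}.{f}" for pk in peaks for f in PEAK_FEATURES]
        cols += [
            f"{prefix}.{a}-{b}.{f}"
            for a, b in zip(peaks, peaks[1:])
            for f in PEAK_TO_PEAK_FEATURES
        ]
        cols += [f"{prefix}.signal.{f}" for f in SIGNAL_FEATURES]
        return cols

    def columns(self) -> list[str]:
        return [
            c
            for p in self.paradigms
            for s in self.stimulus_classes[p]
            for ch in self.channels
            for c in self.block_columns(p, s, ch)
        ]

    def n_columns(self, paradigm: str | None = None) -> int:
        paradigms = (paradigm,) if paradigm else self.paradigms
        return sum(
            len(self.stimulus_classes[p])
            * len(self.channels)
            * len(self.block_columns(p, self.stimulus_classes[p][0], self.channels[0]))
            for p in paradigms
        )

    def restrict(self, paradigms: tuple[str, ...]) -> "FeatureSchema":
        return FeatureSchema(
            paradigms=paradigms,
            stimulus_classes={p: self.stimulus_classes[p] for p in paradigms},
            channels=self.channels,
            peaks={p: self.peaks[p] for p in paradigms},
        )


@dataclass
class FeatureTable:
    """Subjects × features matrix plus group labels."""

    X: pd.DataFrame
    y: pd.Series
    schema: FeatureSchema | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def parse_column(name: str) -> tuple[str, str, str, str, str]:
    """Split ``paradigm.stimulus.channel.peak.feature``."""
    parts = name.split(".")
    if len(parts) != 5:
        raise ValueError(f"malformed feature name {name!r}")
    return tuple(parts)  # type: ignore[return-value]


def feature_category(name: str) -> str:
    """Bucket a column into latency_amplitude / morphological / frequency."""
    feat = parse_column(name)[4]
    if feat in ("amplitude", "latency", "abs_amplitude", "ratio", "abs_ratio"):
        return "latency_amplitude"
    if feat in ("mode_frequency", "median_frequency", "mean_frequency"):
        return "frequency"
    return "morphological"


# ---------------------------------------------------------------------------
# elementary feature operators
# ---------------------------------------------------------------------------


def _window_slice(
    search_ms: tuple[float, float], window: EpochWindow
) -> tuple[int, int]:
    """Absolute epoch-sample index range (inclusive) of a search interval."""
    t = window.times_ms()
    mask = (t >= search_ms[0]) & (t <= search_ms[1])
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"search window {search_ms} contains no samples")
    if search_ms[0] < t[0] or search_ms[1] > t[-1]:
        raise ValueError(f"search window {search_ms} exceeds the epoch {t[0], t[-1]}")
    return int(idx[0]), int(idx[-1])


def detect_peak(
    waveform: np.ndarray,
    search_ms: tuple[float, float],
    window: EpochWindow,
    min_index: int | None = None,
) -> PeakMeasurement:
    """Largest-absolute-value sample inside the interval; earliest wins ties.

    ``min_index`` optionally restricts the search to samples at or after an
    absolute epoch index — used to keep peaks detected in overlapping search
    windows in strictly increasing latency order.
    """
    lo, hi = _window_slice(search_ms, window)
    if min_index is not None and min_index > lo:
        if min_index > hi:
            raise ValueError("no samples left in window after ordering constraint")
        lo = min_index
    seg = np.asarray(waveform, dtype=float)[lo : hi + 1]
    k = int(np.argmax(np.abs(seg)))  # argmax returns the first maximal index
    idx = lo + k
    t = window.times_ms()[idx]
    return PeakMeasurement(amplitude_uV=float(seg[k]), latency_ms=float(t), index=idx)


def peak_features(
    pm: PeakMeasurement,
    waveform: np.ndarray,
    search_ms: tuple[float, float],
    window: EpochWindow,
) -> dict[str, float]:
    """The 7 per-peak features."""
    amp, lat = pm.amplitude_uV, pm.latency_ms
    if amp == 0.0:
        log.warning("zero peak amplitude at %.0f ms; ratio features set to 0", lat)
        ratio = abs_ratio = 0.0
    else:
        ratio = lat / amp
        abs_ratio = abs(ratio)
    lo, hi = _window_slice(search_ms, window)
    seg = np.asarray(waveform, dtype=float)[lo : hi + 1]
    dt_ms = 1000.0 / window.fs_hz
    diffs = np.diff(seg)
    avg_abs_slope = float(np.mean(np.abs(diffs)) / dt_ms) if diffs.size else 0.0
    signs = np.sign(diffs)
    signs = signs[signs != 0]
    alternations = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    return {
        "amplitude": amp,
        "latency": lat,
        "abs_amplitude": abs(amp),
        "ratio": ratio,
        "abs_ratio": abs_ratio,
        "avg_abs_slope": avg_abs_slope,
        "slope_sign_alternations": float(alternations),
    }


def peak_to_peak_features(
    pm_a: PeakMeasurement, pm_b: PeakMeasurement
) -> dict[str, float]:
    """Amplitude gap, latency gap, and slope between two adjacent peaks."""
    dl = pm_b.latency_ms - pm_a.latency_ms
    if dl == 0.0:
        raise ValueError("adjacent peaks share a latency; cannot form a slope")
    da = pm_b.amplitude_uV - pm_a.amplitude_uV
    return {
        "pp_abs_amplitude_diff": abs(da),
        "pp_latency_diff": dl,
        "pp_slope": da / dl,
    }


def area_features(waveform: np.ndarray, dt_s: float) -> dict[str, float]:
    """Signed and absolute rectangular areas under the signal."""
    v = np.asarray(waveform, dtype=float)
    pos = float(np.sum(np.maximum(v, 0.0)) * dt_s)
    neg = float(np.sum(np.minimum(v, 0.0)) * dt_s)
    return {
        "positive_area": pos,
        "negative_area": neg,
        "total_area": pos + neg,
        "abs_total_area": pos - neg,
    }


def zero_crossing_features(
    waveform: np.ndarray, first_peak_index: int, last_peak_index: int, dt_s: float
) -> dict[str, float]:
    """Zero crossings of the signal between its first and last peak."""
    if first_peak_index >= last_peak_index:
        raise ValueError("first peak index must precede last peak index")
    span = np.asarray(waveform, dtype=float)[first_peak_index : last_peak_index + 1]
    if span.size < 2:
        return {"zero_crossing": 0.0, "zero_cross_density": 0.0}
    crossings = int(np.sum(span[:-1] * span[1:] < 0))
    span_s = (last_peak_index - first_peak_index) * dt_s
    return {
        "zero_crossing": float(crossings),
        "zero_cross_density": crossings / span_s if span_s > 0 else 0.0,
    }


def spectral_features(
    waveform: np.ndarray, fs_hz: float, f_max_hz: float = 30.0
) -> dict[str, float]:
    """Mode, median, and mean frequency of the periodogram inside (0, f_max]."""
    v = np.asarray(waveform, dtype=float)
    if v.size < 8:
        raise ValueError("waveform too short for a spectral estimate")
    zero = {"mode_frequency": 0.0, "median_frequency": 0.0, "mean_frequency": 0.0}
    if not np.any(v):
        log.warning("all-zero waveform; spectral features set to 0")
        return zero
    f, psd = sps.periodogram(v - v.mean(), fs=fs_hz)
    band = (f > 0) & (f <= f_max_hz)
    f, psd = f[band], psd[band]
    total = float(psd.sum())
    if total <= 0:
        log.warning("no spectral power in band; spectral features set to 0")
        return zero
    mode = float(f[np.argmax(psd)])
    cum = np.cumsum(psd)
    median = float(f[np.searchsorted(cum, total / 2.0)])
    mean = float(np.sum(f * psd) / total)
    return {"mode_frequency": mode, "median_frequency": median, "mean_frequency": mean}


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


def _signal_block(
    waveform: np.ndarray,
    measurements: list[PeakMeasurement],
    window: EpochWindow,
) -> dict[str, float]:
    dt_s = 1.0 / window.fs_hz
    feats = area_features(waveform, dt_s)
    indices = [pm.index for pm in measurements]
    first, last = min(indices), max(indices)
    if first < last:
        feats.update(zero_crossing_features(waveform, first, last, dt_s))
    else:
        feats.update({"zero_crossing": 0.0, "zero_cross_density": 0.0})
    feats.update(spectral_features(waveform, window.fs_hz))
    v = np.asarray(waveform, dtype=float)
    feats["rms"] = float(np.sqrt(np.mean(v**2)))
    return feats


def extract_subject_features(
    erp: SubjectErp,
    schema: FeatureSchema,
    peak_windows: PeakWindowTable,
) -> dict[str, float]:
    """One subject's full feature vector keyed by column name."""
    out: dict[str, float] = {}
    for paradigm in schema.paradigms:
        window = erp.windows[paradigm]
        peaks = schema.peaks[paradigm]
        for stimulus in schema.stimulus_classes[paradigm]:
            for channel in schema.channels:
                wave = erp.get(paradigm, stimulus, channel)
                prefix = f"{paradigm}.{stimulus}.{channel}"
                pms = []
                for pk in peaks:
                    search = peak_windows.get(paradigm, pk)
                    # search windows may overlap; keep latencies strictly ordered
                    floor_idx = pms[-1].index + 1 if pms else None
                    pm = detect_peak(wave, search, window, min_index=floor_idx)
                    pms.append(pm)
                    for name, val in peak_features(pm, wave, search, window).items():
                        out[f"{prefix}.{pk}.{name}"] = val
                for (a, pa), (b, pb) in zip(zip(peaks, pms), zip(peaks[1:], pms[1:])):
                    for name, val in peak_to_peak_features(pa, pb).items():
                        out[f"{prefix}.{a}-{b}.{name}"] = val
                for name, val in _signal_block(wave, pms, window).items():
                    out[f"{prefix}.signal.{name}"] = val
    return out


def build_feature_table(
    cohort: list[SubjectErp],
    schema: FeatureSchema | None = None,
    peak_windows: PeakWindowTable | None = None,
) -> FeatureTable:
    """Extract the feature matrix for a cohort of averaged ERPs.

    Column order is deterministic (given by the schema enumeration) and
    independent of subject order.
    """
    schema = schema or FeatureSchema()
    peak_windows = peak_windows or PeakWindowTable()
    columns = schema.columns()
    rows, ids, groups = [], [], []
    for erp in cohort:
        vec = extract_subject_features(erp, schema, peak_windows)
        missing = [c for c in columns if c not in vec]
        if missing:
            raise ValueError(
                f"subject {erp.subject_id}: missing feature columns {missing[:3]}..."
            )
        rows.append([vec[c] for c in columns])
        ids.append(erp.subject_id)
        groups.append(erp.group)
    X = pd.DataFrame(rows, index=ids, columns=columns)
    y = pd.Series(groups, index=ids, name="group")
    if X.isna().any().any():
        raise ValueError("feature table contains missing values")
    return FeatureTable(X=X, y=y, schema=schema)
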