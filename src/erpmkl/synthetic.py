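"""Synthetic oddball-paradigm cohorts.

Generates event schedules, evoked-response templates, and two-group cohorts
of noisy continuous recordings so the downstream pipeline (preprocessing →
features → selection → classification) can be exercised without access to
clinical data.

Evoked components are modelled as Gaussian bumps: any smooth unimodal kernel
would do, the Gaussian is chosen because its peak amplitude and latency are
analytic, which makes peak-detection oracles exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

CHANNELS = ("Fz", "Cz", "Pz")

__all__ = [
    "CHANNELS",
    "StimulusClass",
    "ParadigmSpec",
    "ComponentSpec",
    "CohortConfig",
    "EventSchedule",
    "SubjectRecording",
    "AUDITORY_P300",
    "VISUAL_P300",
    "MMN",
    "DEFAULT_PARADIGMS",
    "RARE_CLASSES",
    "EPOCH_WINDOWS_MS",
    "simulate_schedule",
    "expected_session_duration",
    "erp_template",
    "template_time_grid",
    "simulate_cohort",
    "calibrate_noise_sd",
    "default_components",
]


@dataclass(frozen=True)
class StimulusClass:
    """One stimulus category of an oddball paradigm."""

    label: str
    proportion: float
    duration_ms: float


@dataclass(frozen=True)
class ParadigmSpec:
    """Schedule parameters of one oddball paradigm.

    ``isi_ms`` is an ``(lo, hi)`` interval for a uniform inter-stimulus
    interval draw; a fixed ISI is expressed as ``lo == hi``.
    """

    name: str
    stimulus_classes: tuple[StimulusClass, ...]
    isi_ms: tuple[float, float]
    n_stimuli: int

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.stimulus_classes)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"stimulus-class proportions must sum to 1, got {total!r}"
            )
        if any(c.duration_ms <= 0 for c in self.stimulus_classes):
            raise ValueError("stimulus durations must be positive")
        lo, hi = self.isi_ms
        if lo > hi or lo < 0:
            raise ValueError(f"invalid ISI interval {self.isi_ms!r}")
        if self.n_stimuli < 0:
            raise ValueError("n_stimuli must be non-negative")

    @property
    def mean_isi_ms(self) -> float:
        return 0.5 * (self.isi_ms[0] + self.isi_ms[1])

    def class_counts(self) -> dict[str, int]:
        """Exact per-class stimulus counts by largest-remainder allocation."""
        quotas = [c.proportion * self.n_stimuli for c in self.stimulus_classes]
        counts = [math.floor(q) for q in quotas]
        short = self.n_stimuli - sum(counts)
        # hand leftover stimuli to the largest fractional remainders,
        # ties broken by class order (stable sort)
        order = sorted(
            range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True
        )
        for i in order[:short]:
            counts[i] += 1
        return {c.label: n for c, n in zip(self.stimulus_classes, counts)}


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: a Gaussian bump with per-subject variability."""

    label: str
    polarity: int
    mean_latency_ms: float
    latency_sd_ms: float
    mean_amplitude_uV: float
    amplitude_sd_uV: float
    width_ms: float

    def __post_init__(self) -> None:
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if self.latency_sd_ms < 0 or self.amplitude_sd_uV < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class EventSchedule:
    """Stimulus onsets (seconds) with class labels, in presentation order."""

    events: tuple[tuple[float, str], ...]
    total_duration_s: float

    def onsets(self, label: str | None = None) -> np.ndarray:
        return np.array(
            [t for t, lab in self.events if label is None or lab == label]
        )

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, lab in self.events:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# published paradigm schedules
# ---------------------------------------------------------------------------

AUDITORY_P300 = ParadigmSpec(
    name="auditory_p300",
    stimulus_classes=(
        StimulusClass("target", 0.10, 100.0),
        StimulusClass("distractor", 0.10, 100.0),
        StimulusClass("standard", 0.80, 100.0),
    ),
    isi_ms=(1000.0, 1500.0),
    n_stimuli=400,
)

VISUAL_P300 = ParadigmSpec(
    name="visual_p300",
    stimulus_classes=(
        StimulusClass("target", 0.10, 100.0),
        StimulusClass("distractor", 0.10, 100.0),
        StimulusClass("standard", 0.80, 100.0),
    ),
    isi_ms=(1000.0, 1500.0),
    n_stimuli=400,
)

MMN = ParadigmSpec(
    name="mmn",
    stimulus_classes=(
        StimulusClass("duration_deviant", 0.05, 250.0),
        StimulusClass("frequency_deviant", 0.05, 100.0),
        StimulusClass("standard", 0.90, 100.0),
    ),
    isi_ms=(300.0, 300.0),
    n_stimuli=1800,
)

DEFAULT_PARADIGMS: tuple[ParadigmSpec, ...] = (AUDITORY_P300, VISUAL_P300, MMN)

#: the two rare stimulus classes whose averaged responses feed the features
RARE_CLASSES: dict[str, tuple[str, str]] = {
    "auditory_p300": ("target", "distractor"),
    "visual_p300": ("target", "distractor"),
    "mmn": ("duration_deviant", "frequency_deviant"),
}

#: epoch windows (ms) per paradigm
EPOCH_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "auditory_p300": (-200.0, 800.0),
    "visual_p300": (-200.0, 800.0),
    "mmn": (-100.0, 500.0),
}


def simulate_schedule(spec: ParadigmSpec, seed) -> EventSchedule:
    """Draw one stimulus presentation order with onset times.

    Class counts are exact (largest-remainder rounding of the proportions),
    the presentation order is a seeded uniform shuffle, and the gap between
    consecutive stimuli is the previous stimulus duration plus an ISI draw.
    """
    rng = np.random.default_rng(seed)
    counts = spec.class_counts()
    labels = [
        lab for c in spec.stimulus_classes for lab in [c.label] * counts[c.label]
    ]
    labels = [labels[i] for i in rng.permutation(len(labels))]
    durations = {c.label: c.duration_ms / 1000.0 for c in spec.stimulus_classes}
    lo, hi = spec.isi_ms[0] / 1000.0, spec.isi_ms[1] / 1000.0
    events = []
    t = 0.0
    for lab in labels:
        isi = rng.uniform(lo, hi) if hi > lo else lo
        onset = t + isi
        events.append((onset, lab))
        t = onset + durations[lab]
    return EventSchedule(events=tuple(events), total_duration_s=t)


def expected_session_duration(spec: ParadigmSpec) -> int:
    """Expected schedule duration in whole seconds (floored).

    The expectation is ``Σ_classes proportion·n·duration + n·mean(ISI)``;
    flooring to whole seconds reproduces the published session times.
    """
    dur = sum(
        c.proportion * spec.n_stimuli * c.duration_ms / 1000.0
        for c in spec.stimulus_classes
    )
    dur += spec.n_stimuli * spec.mean_isi_ms / 1000.0
    return math.floor(dur)


def template_time_grid(window_ms: tuple[float, float], fs_hz: float) -> np.ndarray:
    """Sample times (ms) of an epoch window, matching the epoching convention."""
    i0 = math.floor(window_ms[0] * fs_hz / 1000.0)
    i1 = math.floor(window_ms[1] * fs_hz / 1000.0)
    return np.arange(i0, i1 + 1) / fs_hz * 1000.0


def erp_template(
    components: list[ComponentSpec] | tuple[ComponentSpec, ...],
    window_ms: tuple[float, float],
    fs_hz: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evoked waveform on the epoch grid: a sum of Gaussian bumps.

    With ``rng`` given, per-subject amplitude and latency are drawn from each
    component's mean/sd (sd 0 keeps them fixed); without it the means are used.
    """
    t = template_time_grid(window_ms, fs_hz)
    wave = np.zeros_like(t)
    for comp in components:
        if not (window_ms[0] <= comp.mean_latency_ms <= window_ms[1]):
            raise ValueError(
                f"component {comp.label}: latency {comp.mean_latency_ms} ms "
                f"outside window {window_ms}"
            )
        amp, lat = comp.mean_amplitude_uV, comp.mean_latency_ms
        if rng is not None:
            if comp.amplitude_sd_uV > 0:
                amp = rng.normal(amp, comp.amplitude_sd_uV)
            if comp.latency_sd_ms > 0:
                lat = rng.normal(lat, comp.latency_sd_ms)
        wave += comp.polarity * amp * np.exp(-((t - lat) ** 2) / (2 * comp.width_ms**2))
    return wave


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

ComponentMap = dict[str, dict[str, dict[str, tuple[ComponentSpec, ...]]]]


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort: evoked components per group/paradigm/class + noise."""

    n_per_group: int
    components_by_group: ComponentMap
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"Fz": 0.7, "Cz": 1.0, "Pz": 0.9}
    )
    noise_sd_uV: float = 0.0
    n_trials_per_class: int | None = None
    fs_hz: float = 256.0
    seed: int = 0
    paradigms: tuple[ParadigmSpec, ...] = DEFAULT_PARADIGMS
    groups: tuple[str, str] = ("HC", "SZ")

    def __post_init__(self) -> None:
        for g in self.groups:
            if g not in self.components_by_group:
                raise ValueError(f"missing component map for group {g!r}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.n_trials_per_class is not None and self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1 when given")

    def schedule_spec(self, paradigm: ParadigmSpec) -> ParadigmSpec:
        """Paradigm spec, possibly rescaled so the rarest class gets
        ``n_trials_per_class`` stimuli (keeps tests cheap)."""
        if self.n_trials_per_class is None:
            return paradigm
        min_prop = min(c.proportion for c in paradigm.stimulus_classes)
        n = int(round(self.n_trials_per_class / min_prop))
        return ParadigmSpec(
            name=paradigm.name,
            stimulus_classes=paradigm.stimulus_classes,
            isi_ms=paradigm.isi_ms,
            n_stimuli=n,
        )


@dataclass
class SubjectRecording:
    """Continuous 3-channel recordings of one subject, one per paradigm."""

    subject_id: str
    group: str
    fs_hz: float
    #: paradigm name -> (samples × channels array, schedule)
    recordings: dict[str, tuple[np.ndarray, EventSchedule]]


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecording], list[str]]:
    """Synthesize noisy continuous recordings for a two-group cohort.

    For each subject and paradigm a schedule is drawn, subject-level component
    parameters are sampled, and the evoked template (channel-scaled) is added
    to white Gaussian noise at every matching stimulus onset. Fully
    reproducible from ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    subj_seeds = root.spawn(2 * config.n_per_group)
    lead_s = 1.0  # padding so every epoch window fits inside the recording
    tail_s = 1.5

    subjects: list[SubjectRecording] = []
    labels: list[str] = []
    idx = 0
    for group in config.groups:
        comp_map = config.components_by_group[group]
        for k in range(config.n_per_group):
            ss = subj_seeds[idx]
            sid = f"{group.lower()}{k:03d}"
            rng = np.random.default_rng(ss)
            recs: dict[str, tuple[np.ndarray, EventSchedule]] = {}
            for paradigm in config.paradigms:
                spec = config.schedule_spec(paradigm)
                schedule = simulate_schedule(spec, rng)
                window = EPOCH_WINDOWS_MS[paradigm.name]
                insert_window = (0.0, window[1])
                n_samples = (
                    int(round((schedule.total_duration_s + lead_s + tail_s) * config.fs_hz))
                )
                rec = rng.normal(
                    0.0, config.noise_sd_uV, size=(n_samples, len(CHANNELS))
                ) if config.noise_sd_uV > 0 else np.zeros((n_samples, len(CHANNELS)))
                # one template draw per (subject, class): subject-level
                # amplitude/latency variability, trial-level variability
                # comes from the additive noise
                for cls, comps in comp_map.get(paradigm.name, {}).items():
                    wave = erp_template(comps, insert_window, config.fs_hz, rng=rng)
                    for onset in schedule.onsets(cls):
                        s0 = int(round((onset + lead_s) * config.fs_hz))
                        s1 = s0 + wave.size
                        for ci, ch in enumerate(CHANNELS):
                            rec[s0:s1, ci] += config.channel_gains[ch] * wave
                shifted = EventSchedule(
                    events=tuple((t + lead_s, lab) for t, lab in schedule.events),
                    total_duration_s=schedule.total_duration_s + lead_s + tail_s,
                )
                recs[paradigm.name] = (rec, shifted)
            subjects.append(
                SubjectRecording(
                    subject_id=sid, group=group, fs_hz=config.fs_hz, recordings=recs
                )
            )
            labels.append(group)
            idx += 1
    return subjects, labels


def calibrate_noise_sd(
    component_amplitude_uV: float,
    target_snr: float,
    n_trials: int,
    fs_hz: float = 256.0,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    order: int = 4,
) -> float:
    """Raw white-noise sd giving the requested averaged-ERP component SNR.

    SNR is defined as component amplitude over the residual noise sd left in
    the per-subject average of ``n_trials`` epochs after zero-phase bandpass
    filtering; the filter's white-noise gain is integrated from its actual
    frequency response.
    """
    if target_snr <= 0 or n_trials < 1:
        raise ValueError("target_snr must be positive and n_trials >= 1")
    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", output="sos", fs=fs_hz
    )
    _, h = sps.sosfreqz(sos, worN=8192, fs=fs_hz)
    # forward-backward filtering squares the magnitude response
    gain = math.sqrt(float(np.mean(np.abs(h) ** 4)))
    residual_sd = component_amplitude_uV / target_snr
    return residual_sd * math.sqrt(n_trials) / gain


def default_components(
    p300_amplitude_uV: float = 10.0,
    p300_latency_ms: float = 350.0,
    amplitude_sd_uV: float = 1.0,
    latency_sd_ms: float = 10.0,
    p300_amplitude_scale: float = 1.0,
    p300_latency_shift_ms: float = 0.0,
) -> dict[str, dict[str, tuple[ComponentSpec, ...]]]:
    """Component map for one group, all paradigms.

    ``p300_amplitude_scale`` / ``p300_latency_shift_ms`` perturb the late
    positive component only, which is how a patient group is configured.
    """

    def c(label, pol, lat, amp, width, lat_sd=latency_sd_ms, amp_sd=amplitude_sd_uV):
        return ComponentSpec(
            label=label,
            polarity=pol,
            mean_latency_ms=lat,
            latency_sd_ms=lat_sd,
            mean_amplitude_uV=amp,
            amplitude_sd_uV=amp_sd,
            width_ms=width,
        )

    p300 = c(
        "P300",
        +1,
        p300_latency_ms + p300_latency_shift_ms,
        p300_amplitude_uV * p300_amplitude_scale,
        60.0,
    )
    rare_p300 = (
        c("N100", -1, 110.0, 5.0, 22.0),
        c("P200", +1, 200.0, 6.0, 25.0),
        c("N200", -1, 260.0, 4.0, 25.0),
        p300,
    )
    standard_p300 = (
        c("N100", -1, 110.0, 4.0, 22.0),
        c("P200", +1, 200.0, 5.0, 25.0),
    )
    mmn_rare = (
        c("MMN-early", -1, 160.0, 4.0, 30.0),
        c("MMN-late", +1, 320.0, 3.0, 40.0),
    )
    mmn_standard = (c("MMN-early", -1, 160.0, 1.5, 30.0),)
    return {
        "auditory_p300": {
            "target": rare_p300,
            "distractor": rare_p300,
            "standard": standard_p300,
        },
        "visual_p300": {
            "target": rare_p300,
            "distractor": rare_p300,
            "standard": standard_p300,
        },
        "mmn": {
            "duration_deviant": mmn_rare,
            "frequency_deviant": mmn_rare,
            "standard": mmn_standard,
        },
    }
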