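"""Synthetic chest-worn accelerometer study generator.

Emulates a lab protocol in which each participant wears a chest-strapped
triaxial accelerometer sampled at 50 Hz and performs, in one continuous
recording, six activities of daily living (jumping, lying down,
bending/picking up, sitting on a chair, standing up from a chair, walking)
followed by nine fall variants (a steep fall plus front/left/right/back
falls each in a soft and a hard version), resting 5-6 s between events.
All nine fall variants carry the single class label ``"Fall"``, giving the
7-class label set used downstream.

Conventions
-----------
* Units are g throughout; a resting upright wearer reads 1 g along the
  device's longitudinal (z) axis.
* Each event is an impulsive excursion of at most 2 s: a damped impact
  transient for falls, an oscillatory burst for walking/jumping, and a
  smooth ramp with a transient orientation excursion for postural events.
  The waveform is rescaled so that the maximal Euclidean magnitude within
  the event equals the template's peak amplitude exactly (before noise).
* One multiplicative amplitude factor per subject models between-subject
  variability, which is what makes leave-one-subject-out evaluation
  non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .segmentation import TriaxialRecording

__all__ = [
    "ADL_LABELS",
    "FALL_LABEL",
    "CLASS_LABELS",
    "ActivityTemplate",
    "SimulationConfig",
    "AnnotatedRecording",
    "ConfigurationError",
    "default_roster",
    "simulate_recording",
    "simulate_study",
]

ADL_LABELS = (
    "Jumping",
    "Lying down",
    "Bending and picking up",
    "Sitting on a chair",
    "Standing up from chair",
    "Walking",
)
FALL_LABEL = "Fall"
#: The 7 class labels of the study design, in roster order.
CLASS_LABELS = ADL_LABELS + (FALL_LABEL,)

_UPRIGHT = np.array([0.0, 0.0, 1.0])  # gravity direction on an upright wearer


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is invalid."""


@dataclass(frozen=True)
class ActivityTemplate:
    """Parametric waveform of one event class.

    Parameters
    ----------
    label :
        Class label attached to segments of this event (fall subtypes all
        use ``"Fall"``).
    duration :
        Length of the impulsive part in seconds; at most 2 s, matching the
        event-window design.
    peak_amplitude :
        Per-axis peak acceleration ``(ax, ay, az)`` in g.  Its Euclidean
        norm is the exact magnitude of the event's highest peak and must
        exceed the 1 g gravity baseline for the event to be detectable.
    frequency :
        Dominant oscillation frequency in Hz; 0 marks an aperiodic event.
    orientation :
        Gravity direction (unit 3-vector) at the height of the postural
        excursion; the wearer returns upright before the next event.
    kind :
        Waveform family: ``"impact"`` (damped transient), ``"burst"``
        (windowed oscillation) or ``"ramp"`` (smooth aperiodic bump).
    """

    label: str
    duration: float
    peak_amplitude: tuple[float, float, float]
    frequency: float = 0.0
    orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kind: str = "ramp"

    def __post_init__(self) -> None:
        if not 0 < self.duration <= 2.0:
            raise ConfigurationError("event duration must be in (0, 2] s")
        amp = np.asarray(self.peak_amplitude, dtype=float)
        if not np.all(np.isfinite(amp)) or np.any(amp < 0):
            raise ConfigurationError("peak amplitudes must be finite and >= 0")
        orient = np.asarray(self.orientation, dtype=float)
        if not np.isclose(np.linalg.norm(orient), 1.0, atol=1e-8):
            raise ConfigurationError("orientation must be a unit vector")
        if self.kind not in ("impact", "burst", "ramp"):
            raise ConfigurationError(f"unknown waveform kind {self.kind!r}")
        # normalise to plain-float tuples so configs serialise cleanly
        object.__setattr__(self, "peak_amplitude", tuple(float(v) for v in amp))
        object.__setattr__(self, "orientation", tuple(float(v) for v in orient))

    @property
    def peak_magnitude(self) -> float:
        """Euclidean norm of the per-axis peak amplitudes, in g."""
        return float(np.linalg.norm(self.peak_amplitude))


def _fall(magnitude: float, direction: np.ndarray) -> ActivityTemplate:
    direction = direction / np.linalg.norm(direction)
    return ActivityTemplate(
        label=FALL_LABEL,
        duration=1.2,
        peak_amplitude=tuple(magnitude * np.abs(direction)),
        frequency=7.0,
        orientation=tuple(direction),
        kind="impact",
    )


def default_roster() -> tuple[ActivityTemplate, ...]:
    """The default 15-event roster: 6 ADL templates then 9 fall variants.

    Amplitudes and frequencies are chosen to be physiologically plausible
    for a chest sensor: postural ADLs peak at 1.4-1.8 g, jumping at 3 g
    with a ~4 Hz hop rhythm, walking at 1.8 g with a ~2 Hz step rhythm,
    and fall impacts at 3.8-5.5 g with hard variants striking harder than
    soft ones.
    """
    lying = np.array([0.97, 0.05, 0.24])
    lying /= np.linalg.norm(lying)
    bend = np.array([0.71, 0.0, 0.71])
    bend /= np.linalg.norm(bend)
    adls = (
        ActivityTemplate("Jumping", 1.6, (0.3, 0.3, 2.97), 4.0, kind="burst"),
        ActivityTemplate("Lying down", 1.8, (1.35, 0.2, 0.8), orientation=tuple(lying)),
        ActivityTemplate(
            "Bending and picking up", 1.8, (1.0, 0.15, 1.1), orientation=tuple(bend)
        ),
        ActivityTemplate("Sitting on a chair", 1.4, (0.4, 0.25, 1.63)),
        ActivityTemplate("Standing up from chair", 1.4, (0.35, 0.2, 1.54)),
        ActivityTemplate("Walking", 2.0, (0.5, 0.4, 1.68), 2.0, kind="burst"),
    )
    falls = (
        _fall(5.5, np.array([0.2, 0.1, 0.97])),
        _fall(4.0, np.array([0.95, 0.1, 0.3])),
        _fall(5.0, np.array([0.95, 0.1, 0.3])),
        _fall(3.8, np.array([0.15, 0.95, 0.28])),
        _fall(4.8, np.array([0.15, 0.95, 0.28])),
        _fall(3.9, np.array([0.18, 0.94, 0.29])),
        _fall(4.9, np.array([0.18, 0.94, 0.29])),
        _fall(4.1, np.array([0.9, 0.05, 0.43])),
        _fall(5.1, np.array([0.9, 0.05, 0.43])),
    )
    return adls + falls


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated study.

    Defaults reproduce the study design: 35 subjects, each performing the
    15-event roster (6 ADL + 9 falls) at 50 Hz with 5-6 s rests.
    """

    n_subjects: int = 35
    events_per_subject: tuple[ActivityTemplate, ...] = field(default_factory=default_roster)
    rest_gap: tuple[float, float] = (5.0, 6.0)
    sampling_rate: float = 50.0
    noise_sd: float = 0.03
    subject_variability: float = 0.15
    seed: int = 0
    edge_pad_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        lo, hi = self.rest_gap
        if lo < 2.0 or hi < lo:
            raise ConfigurationError("rest gap must satisfy 2 <= lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.subject_variability < 1:
            raise ConfigurationError("subject_variability must be in [0, 1)")
        if not self.events_per_subject:
            raise ConfigurationError("events_per_subject must be non-empty")
        if self.edge_pad_s < 1.0:
            raise ConfigurationError("edge padding must be >= 1 s")


@dataclass(frozen=True)
class AnnotatedRecording:
    """A continuous recording together with its event ground truth.

    ``annotations`` is a list of ``(label, time_s)`` pairs marking the
    nominal (peak) time of each event, strictly increasing and at least
    1 s from both recording edges.
    """

    recording: TriaxialRecording
    annotations: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        times = [t for _, t in self.annotations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("annotation times must be strictly increasing")
        if times and (times[0] < 1.0 or times[-1] > self.recording.duration - 1.0):
            raise ValueError("annotations must lie at least 1 s from recording edges")


def _orientation_path(template: ActivityTemplate, t: np.ndarray) -> np.ndarray:
    """Gravity vector over the event: upright -> excursion target -> upright."""
    target = np.asarray(template.orientation, dtype=float)
    w = np.sin(np.pi * t / template.duration) ** 2
    path = (1 - w)[:, None] * _UPRIGHT + w[:, None] * target
    norms = np.linalg.norm(path, axis=1)
    norms[norms == 0] = 1.0
    return path / norms[:, None]


def _deviation_shape(template: ActivityTemplate, t: np.ndarray) -> np.ndarray:
    """Unit-scale deviation waveform (n, 3) before amplitude calibration."""
    d = template.duration
    centre = d / 2.0
    env = np.sin(np.pi * t / d) ** 2
    if template.kind == "impact":
        # sharp damped transient around the impact instant
        env = np.exp(-(((t - centre) / (d / 6.0)) ** 2))
        osc = np.cos(2 * np.pi * template.frequency * (t - centre))
        shape = env * osc
    elif template.kind == "burst":
        osc = np.cos(2 * np.pi * template.frequency * (t - centre))
        shape = env * osc
    else:  # smooth aperiodic ramp bump
        shape = env
    direction = np.asarray(template.peak_amplitude, dtype=float)
    n = np.linalg.norm(direction)
    direction = direction / n if n > 0 else _UPRIGHT
    return shape[:, None] * direction[None, :]


def _event_snippet(
    template: ActivityTemplate, fs: float, amplitude_factor: float
) -> tuple[np.ndarray, int]:
    """Noise-free event waveform and the index of its magnitude peak.

    The deviation is scaled (1-D root find on the peak magnitude, which is
    convex in the scale factor) so that the maximal Euclidean magnitude of
    gravity + deviation equals the jittered template peak exactly.
    """
    n = int(round(template.duration * fs)) + 1
    t = np.arange(n) / fs
    baseline = _orientation_path(template, t)
    dev = _deviation_shape(template, t)
    target = template.peak_magnitude * amplitude_factor
    base_max = float(np.linalg.norm(baseline, axis=1).max())
    if target <= base_max:
        raise ConfigurationError(
            f"template {template.label!r}: peak magnitude {target:.3f} g does not "
            "exceed the gravity baseline; the event would be undetectable"
        )

    def peak_excess(beta: float) -> float:
        return float(np.linalg.norm(baseline + beta * dev, axis=1).max()) - target

    hi = 1.0
    while peak_excess(hi) < 0:
        hi *= 2.0
    beta = brentq(peak_excess, 0.0, hi, xtol=1e-12)
    snippet = baseline + beta * dev
    peak_idx = int(np.argmax(np.linalg.norm(snippet, axis=1)))
    return snippet, peak_idx


def simulate_recording(config: SimulationConfig, subject_index: int) -> AnnotatedRecording:
    """Simulate one subject's continuous recording.

    The recording contains every event of ``config.events_per_subject`` in
    order, separated by rest gaps drawn uniformly from ``config.rest_gap``;
    during rests the signal is the 1 g upright gravity baseline plus white
    Gaussian noise.  Output is bit-identical for the same config and
    subject index.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError(
            f"subject_index {subject_index} outside [0, {config.n_subjects})"
        )
    rng = np.random.default_rng([config.seed, subject_index])
    v = config.subject_variability
    amp_factor = float(rng.uniform(1.0 - v, 1.0 + v))
    fs = config.sampling_rate

    pad = int(round(config.edge_pad_s * fs))
    pieces = [np.tile(_UPRIGHT, (pad, 1))]
    annotations: list[tuple[str, float]] = []
    pos = pad
    for i, template in enumerate(config.events_per_subject):
        snippet, peak_idx = _event_snippet(template, fs, amp_factor)
        annotations.append((template.label, (pos + peak_idx) / fs))
        pieces.append(snippet)
        pos += snippet.shape[0]
        if i < len(config.events_per_subject) - 1:
            gap_s = rng.uniform(*config.rest_gap)
            gap = int(round(gap_s * fs))
            pieces.append(np.tile(_UPRIGHT, (gap, 1)))
            pos += gap
    pieces.append(np.tile(_UPRIGHT, (pad, 1)))

    data = np.concatenate(pieces, axis=0)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    recording = TriaxialRecording(
        subject_id=f"S{subject_index:02d}", fs=fs, data=data
    )
    return AnnotatedRecording(recording=recording, annotations=tuple(annotations))


def simulate_study(config: SimulationConfig) -> list[AnnotatedRecording]:
    """Simulate the full study: one continuous recording per subject.

    With the default roster, segmenting all recordings yields
    ``n_subjects * 15`` events of which ``n_subjects * 9`` are falls
    (525 and 315 for the default 35 subjects).
    """
    return [simulate_recording(config, i) for i in range(config.n_subjects)]
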