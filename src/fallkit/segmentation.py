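"""Peak-centred event segmentation of continuous triaxial recordings.

A labelled event is represented by a 2 s window centred on the sample of
maximal Euclidean acceleration magnitude: at 50 Hz that is 101 samples per
axis (1 s before the peak, the peak itself, 1 s after).  Events whose peak
lies within 1 s of a recording edge cannot be windowed and are rejected
rather than padded, since padding would distort every downstream feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriaxialRecording",
    "EventSegment",
    "BoundaryError",
    "locate_event_peak",
    "extract_event_segment",
    "segment_recording",
]

logger = logging.getLogger(__name__)


class BoundaryError(ValueError):
    """Raised when an event peak is too close to a recording edge to window."""


@dataclass(frozen=True)
class TriaxialRecording:
    """Continuous 3-axis acceleration time series for one subject.

    Parameters
    ----------
    subject_id :
        Identifier of the wearer.
    fs :
        Sampling rate in Hz.
    data :
        Array of shape ``(n_samples, 3)`` holding the x, y, z acceleration
        channels in units of g (standard gravity).
    """

    subject_id: str
    fs: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError("recording data must have shape (n_samples, 3)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.data[:, 2]

    def magnitude(self) -> np.ndarray:
        """Per-sample Euclidean magnitude sqrt(Fx^2 + Fy^2 + Fz^2)."""
        return np.linalg.norm(self.data, axis=1)


@dataclass(frozen=True)
class EventSegment:
    """One labelled, peak-centred event window.

    The window holds ``2*fs + 1`` samples per axis (101 at 50 Hz) and the
    Euclidean-magnitude maximum sits exactly at the centre index.
    """

    subject_id: str
    label: str
    fs: float
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError("segment data must have shape (n, 3)")
        expected = 2 * int(round(self.fs)) + 1
        if data.shape[0] != expected:
            raise ValueError(
                f"segment must hold 2*fs+1 = {expected} samples, got {data.shape[0]}"
            )
        centre = data.shape[0] // 2
        mag = np.linalg.norm(data, axis=1)
        # the maximum must be attained at the centre (ties elsewhere are fine)
        if mag[centre] != mag.max():
            raise ValueError("magnitude maximum must be attained at the centre sample")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.data[:, 2]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.data, axis=1)


def locate_event_peak(
    recording: TriaxialRecording, window: tuple[float, float]
) -> int:
    """Find the sample of maximal acceleration magnitude inside a time window.

    Parameters
    ----------
    recording :
        The continuous recording to search.
    window :
        ``(start_s, end_s)`` in seconds; both endpoints are included.  The
        window must overlap the recording and contain at least one sample.

    Returns
    -------
    int
        Absolute sample index of the magnitude maximum; ties are broken by
        the earliest index.
    """
    start_s, end_s = window
    if end_s < start_s:
        raise ValueError("window end precedes window start")
    lo = max(0, int(np.ceil(start_s * recording.fs)))
    hi = min(recording.n_samples - 1, int(np.floor(end_s * recording.fs)))
    if hi < lo:
        raise ValueError("window contains no samples")
    mag = np.linalg.norm(recording.data[lo : hi + 1], axis=1)
    return lo + int(np.argmax(mag))  # argmax returns the first maximum


def extract_event_segment(
    recording: TriaxialRecording, peak_index: int, label: str
) -> EventSegment:
    """Slice the 2 s window centred on ``peak_index`` from all three axes.

    Raises
    ------
    BoundaryError
        If the peak lies within 1 s of either recording edge; such events
        are reported and discarded upstream, never padded.
    """
    half = int(round(recording.fs))
    if peak_index < half or peak_index > recording.n_samples - half - 1:
        raise BoundaryError(
            f"event peak at sample {peak_index} is within 1 s of a recording "
            f"edge (length {recording.n_samples}); segment discarded"
        )
    window = recording.data[peak_index - half : peak_index + half + 1]
    return EventSegment(
        subject_id=recording.subject_id, label=label, fs=recording.fs, data=window
    )


def segment_recording(annotated, search_halfwidth_s: float = 2.5) -> list[EventSegment]:
    """Extract one peak-centred segment per annotated event.

    For each annotation ``(label, t)`` the magnitude peak is located within
    ``[t - halfwidth, t + halfwidth]`` (clipped to the recording) and the
    2 s window around it is extracted.  Events whose peak falls within 1 s
    of a recording edge are dropped with a logged warning.

    Parameters
    ----------
    annotated :
        An :class:`~fallkit.simulate.AnnotatedRecording` (or any object with
        ``recording`` and ``annotations`` attributes).
    search_halfwidth_s :
        Half-width of the search window around each nominal event time.
        The default of 2.5 s is half the minimum inter-event rest gap, so
        under the simulator's design each window contains exactly one event.
    """
    recording: TriaxialRecording = annotated.recording
    annotations = list(annotated.annotations)
    times = [t for _, t in annotations]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("annotations must be strictly increasing in time")
    if any(t2 - t1 < 2 * search_halfwidth_s for t1, t2 in zip(times, times[1:])):
        raise ValueError("search windows overlap; reduce search_halfwidth_s")

    segments: list[EventSegment] = []
    for label, t in annotations:
        peak = locate_event_peak(
            recording,
            (max(0.0, t - search_halfwidth_s), t + search_halfwidth_s),
        )
        try:
            segments.append(extract_event_segment(recording, peak, label))
        except BoundaryError as exc:
            logger.warning(
                "subject %s: dropping %r event at %.2f s: %s",
                recording.subject_id,
                label,
                t,
                exc,
            )
    return segments
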