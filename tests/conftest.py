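import numpy as np
import pytest

import fallkit as fk


@pytest.fixture(scope="session")
def small_config() -> fk.SimulationConfig:
    return fk.SimulationConfig(n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return fk.simulate_study(small_config)


@pytest.fixture(scope="session")
def small_segments(small_study):
    segments = []
    for annotated in small_study:
        segments.extend(fk.segment_recording(annotated))
    return segments


@pytest.fixture(scope="session")
def small_dataset(small_segments) -> fk.FeatureDataset:
    return fk.FeatureDataset.from_feature_vectors(
        [fk.extract_event_features(s) for s in small_segments]
    )


@pytest.fixture
def make_segment():
    """Build an EventSegment from per-axis arrays (must peak at the centre)."""

    def _make(x, y, z, fs=50.0, label="Fall", subject_id="S00"):
        data = np.column_stack([x, y, z]).astype(float)
        return fk.EventSegment(subject_id=subject_id, label=label, fs=fs, data=data)

    return _make


def well_separated_config(n_subjects: int, seed: int) -> fk.SimulationConfig:
    """Study config whose fall impacts peak at >= 3x every ADL peak."""
    adls = tuple(
        t for t in fk.default_roster() if t.label != fk.FALL_LABEL
    )
    weak_adls = tuple(
        fk.ActivityTemplate(
            label=t.label,
            duration=t.duration,
            peak_amplitude=tuple(
                1.25 * np.asarray(t.peak_amplitude) / np.linalg.norm(t.peak_amplitude)
            ),
            frequency=t.frequency,
            orientation=t.orientation,
            kind=t.kind,
        )
        for t in adls
    )
    strong_falls = tuple(t for t in fk.default_roster() if t.label == fk.FALL_LABEL)
    return fk.SimulationConfig(
        n_subjects=n_subjects,
        events_per_subject=weak_adls + strong_falls,
        noise_sd=0.01,
        subject_variability=0.05,
        seed=seed,
    )
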