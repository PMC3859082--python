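"""Shared fixtures: canonical synthetic measurements and hand-built envelopes."""

import numpy as np
import pytest

from oscimap.envelope import (
    Envelope,
    EnvelopePoint,
    build_envelope,
    detect_pulse_peaks,
    extract_omw,
)
from oscimap.synth import SyntheticTruth, generate_recording


def envelope_from_points(points, n_dense=201):
    """Build an Envelope directly from (cuff_pressure, amplitude) pairs,
    linearly interpolated — for examples where the envelope shape is the
    known quantity, bypassing signal extraction."""
    points = list(points)
    times = np.arange(len(points), dtype=float)
    pressures = np.array([p for p, _ in points], dtype=float)
    amps = np.array([a for _, a in points], dtype=float)
    dense_t = np.linspace(times[0], times[-1], n_dense)
    dense_a = np.interp(dense_t, times, amps)
    dense_p = np.interp(dense_t, times, pressures)
    i_max = int(np.argmax(dense_a))
    return Envelope(
        points=[EnvelopePoint(float(t), float(p), float(a))
                for t, p, a in zip(times, pressures, amps)],
        dense_times=dense_t,
        dense_amplitude=dense_a,
        dense_pressure=dense_p,
        max_amplitude=float(dense_a[i_max]),
        pressure_at_max=float(dense_p[i_max]),
        index_of_max=i_max,
        degenerate=i_max in (0, n_dense - 1),
        smoothed=lambda t: np.interp(t, times, amps),
    )


def pipeline_envelope(rec):
    """Run extraction + peak detection + envelope building on a recording."""
    omw = extract_omw(rec)
    peaks = detect_pulse_peaks(omw)
    return build_envelope(omw, rec, peaks)


@pytest.fixture(scope="session")
def clean_truth():
    """A noiseless measurement with on-grid true ratios."""
    return SyntheticTruth(
        true_sbp=120.0,
        true_dbp=80.0,
        true_map=80.0 + 40.0 / 3.0,
        true_ratio_s=0.82,
        true_ratio_d=0.40,
        heart_rate=72.0,
        noise_sd=0.0,
        nurse_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_truth):
    rec, _ = generate_recording(clean_truth)
    return rec


@pytest.fixture(scope="session")
def clean_envelope(clean_recording):
    return pipeline_envelope(clean_recording)


@pytest.fixture
def three_point_envelope():
    """The canonical (120, 0.70), (93, 1.00), (65, 0.45) envelope."""
    return envelope_from_points([(120.0, 0.70), (93.0, 1.00), (65.0, 0.45)])
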