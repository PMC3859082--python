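"""Oscillometric waveform and envelope extraction.

A cuff-deflation recording is the superposition of a slowly decreasing
baseline (the deflating cuff) and small cardiac-synchronous oscillations.
This module separates the two, detects the pulse peaks, builds the
oscillation-amplitude envelope as a function of cuff pressure, smooths it
with a cubic spline, and provides the two inverse mappings every
ratio-based estimator needs:

* ``amplitude_to_pressure`` — the cuff pressure at which the envelope on a
  chosen branch (systolic = before the maximum, diastolic = after) falls to
  a target amplitude;
* ``amplitude_at_pressure`` — the envelope amplitude at a given cuff
  pressure on a chosen branch (used to derive reference ratios from
  auscultatory readings).

The cuff pressure at the envelope maximum approximates mean arterial
pressure; that maximum amplitude ``m`` is the normalizer for all
systolic/diastolic ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, savgol_filter

from .errors import EnvelopeError, SignalError

Side = Literal["systolic", "diastolic"]

#: largest tolerated local pressure inversion (sensor ripple), mmHg
MAX_PRESSURE_INVERSION = 2.0


@dataclass(frozen=True)
class CuffRecording:
    """One deflation-phase cuff-pressure recording.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject.
    measurement_index : int
        1-based index of the measurement within the subject's session.
    sample_times : ndarray
        Sample times in seconds, strictly increasing.
    cuff_pressure : ndarray
        Cuff pressure in mmHg, same length as ``sample_times``, finite
        and positive.
    sampling_rate : float
        Nominal sampling rate in Hz.
    """

    subject_id: str
    measurement_index: int
    sample_times: np.ndarray
    cuff_pressure: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        p = np.asarray(self.cuff_pressure, dtype=float)
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "cuff_pressure", p)
        if t.ndim != 1 or p.shape != t.shape:
            raise SignalError("sample_times and cuff_pressure must be 1-D and equal length")
        if t.size < 2:
            raise SignalError("insufficient signal: fewer than 2 samples")
        if not np.all(np.diff(t) > 0):
            raise SignalError("sample_times must be strictly increasing")
        if not np.all(np.isfinite(p)):
            raise SignalError("non-finite cuff pressure samples")
        if not np.all(p > 0):
            raise SignalError("cuff pressure must be positive")
        if self.sampling_rate <= 0:
            raise SignalError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return float(self.sample_times[-1] - self.sample_times[0])


@dataclass(frozen=True)
class OscillometricWaveform:
    """Detrended oscillation component of a cuff recording.

    ``omw`` is the cuff pressure minus a slow baseline (approximately
    zero-mean); ``pdw`` is the first difference of the cuff pressure per
    unit time, an auxiliary pulse-detection signal; ``baseline`` is the
    slow component itself, needed to map peak times back to deflation
    pressures.
    """

    sample_times: np.ndarray
    omw: np.ndarray
    pdw: np.ndarray
    baseline: np.ndarray
    sampling_rate: float


@dataclass(frozen=True)
class EnvelopePoint:
    """One raw envelope sample: a pulse peak's time, the deflation
    (baseline) pressure at that time, and the oscillation amplitude."""

    peak_time: float
    cuff_pressure_at_peak: float
    amplitude: float


@dataclass
class Envelope:
    """Smoothed oscillation-amplitude envelope.

    Attributes
    ----------
    points : list of EnvelopePoint
        Raw envelope samples ordered by peak time.
    dense_times, dense_amplitude, dense_pressure : ndarray
        The cubic-spline envelope evaluated on a uniform dense time grid,
        with the deflation pressure linearly interpolated onto the same
        grid.
    max_amplitude : float
        ``m``, the maximum of the smoothed envelope (mmHg).
    pressure_at_max : float
        Cuff pressure at the smoothed maximum — the mean-arterial-pressure
        estimate (mmHg).
    index_of_max : int
        Index of the maximum on the dense grid (first sample attaining it).
    degenerate : bool
        True when the maximum sits on the boundary of the dense grid, so
        one branch is empty and ratio-based estimation is unreliable.
    """

    points: list[EnvelopePoint]
    dense_times: np.ndarray
    dense_amplitude: np.ndarray
    dense_pressure: np.ndarray
    max_amplitude: float
    pressure_at_max: float
    index_of_max: int
    degenerate: bool
    smoothed: CubicSpline = field(repr=False)

    @property
    def m(self) -> float:
        """Alias for the maximum oscillometric amplitude."""
        return self.max_amplitude


def extract_omw(rec: CuffRecording, baseline_window: float = 3.0) -> OscillometricWaveform:
    """Split a recording into slow baseline and oscillometric waveform.

    The baseline is a twice-applied centered moving average of width
    ``baseline_window`` seconds (a polyorder-1 Savitzky–Golay filter with
    least-squares edge handling, so a linear deflation ramp is preserved
    exactly end to end; the second pass suppresses cardiac-frequency
    leakage into the baseline to below 1%). The OMW is the residual and
    the PDW is the first difference of the cuff pressure per sample
    interval.

    Raises
    ------
    SignalError
        If the recording is shorter than ``baseline_window`` or contains
        non-finite samples.
    """
    p = rec.cuff_pressure
    if rec.duration < baseline_window:
        raise SignalError("insufficient signal: recording shorter than baseline window")
    win = int(round(baseline_window * rec.sampling_rate))
    win = max(3, win | 1)  # odd, >= 3
    if win >= p.size:
        raise SignalError("insufficient signal: baseline window exceeds recording")
    baseline = savgol_filter(p, win, polyorder=1, mode="interp")
    baseline = savgol_filter(baseline, win, polyorder=1, mode="interp")
    omw = p - baseline
    dt = np.diff(rec.sample_times)
    pdw = np.empty_like(p)
    pdw[1:] = np.diff(p) / dt
    pdw[0] = pdw[1]
    return OscillometricWaveform(
        sample_times=rec.sample_times,
        omw=omw,
        pdw=pdw,
        baseline=baseline,
        sampling_rate=rec.sampling_rate,
    )


def _dominant_cardiac_frequency(
    omw: OscillometricWaveform, hr_range: tuple[float, float]
) -> float | None:
    """Dominant OMW frequency (Hz) inside the heart-rate band, or None
    when the band holds no usable spectral mass."""
    x = omw.omw
    n = x.size
    if n < 16:
        return None
    window = np.hanning(n)
    spectrum = np.abs(np.fft.rfft(x * window))
    freqs = np.fft.rfftfreq(n, d=1.0 / omw.sampling_rate)
    lo, hi = hr_range[0] / 60.0, hr_range[1] / 60.0
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any() or spectrum[band].max() <= 0:
        return None
    return float(freqs[band][int(np.argmax(spectrum[band]))])


def detect_pulse_peaks(
    omw: OscillometricWaveform,
    hr_range: tuple[float, float] = (40.0, 180.0),
    min_peaks: int = 5,
) -> np.ndarray:
    """Locate cardiac pulse peaks in the oscillometric waveform.

    The cardiac fundamental is first estimated as the dominant spectral
    peak of the OMW inside the plausible heart-rate band; peaks must then
    be separated by at least 0.6 of that cardiac period (never less than
    the ``60 / hr_max`` bound) and exceed a prominence of 5% of the
    median absolute oscillation. The period-based separation rejects
    noise maxima between beats that a fixed ``hr_max`` spacing would let
    through.

    Raises
    ------
    SignalError
        If fewer than ``min_peaks`` peaks are found ("too few pulses").
    """
    hr_min, hr_max = hr_range
    if not (0 < hr_min < hr_max):
        raise ValueError("hr_range must satisfy 0 < hr_min < hr_max")
    min_sep = 60.0 / hr_max
    f0 = _dominant_cardiac_frequency(omw, hr_range)
    if f0 is not None:
        min_sep = max(min_sep, 0.6 / f0)
    distance = max(1, int(round(min_sep * omw.sampling_rate)))
    scale = float(np.median(np.abs(omw.omw)))
    # floor far below any physiological oscillation, rejects numeric ripple
    prominence = max(0.05 * scale, 1e-3)
    idx, _ = find_peaks(omw.omw, distance=distance, prominence=prominence)
    if idx.size < min_peaks:
        raise SignalError(f"too few pulses: {idx.size} peaks detected (need {min_peaks})")
    return idx


def build_envelope(
    omw: OscillometricWaveform,
    rec: CuffRecording,
    peaks: Sequence[int],
    n_dense: int = 200,
) -> Envelope:
    """Build and spline-smooth the amplitude envelope from pulse peaks.

    One envelope point per peak: the amplitude is the OMW value at the
    peak, the pressure is the slow baseline at the peak time. A natural
    cubic spline through the points (amplitude as a function of peak time)
    is evaluated on ``n_dense`` uniform samples; the deflation pressure is
    carried onto that grid by linear interpolation of the baseline.

    Local pressure inversions up to 2 mmHg are tolerated with a warning
    (sensor ripple); larger ones raise. An envelope whose maximum falls on
    the first or last dense sample is flagged degenerate.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 5:
        raise SignalError("too few pulses: need at least 5 envelope points")
    amps = omw.omw[peaks]
    if np.any(amps <= 0):
        keep = amps > 0
        peaks, amps = peaks[keep], amps[keep]
        if peaks.size < 5:
            raise SignalError("too few pulses: fewer than 5 positive-amplitude peaks")
    times = omw.sample_times[peaks]
    pressures = omw.baseline[peaks]

    rises = np.diff(pressures)
    if np.any(rises > MAX_PRESSURE_INVERSION):
        raise SignalError(
            "non-monotone deflation: cuff pressure rises by more than "
            f"{MAX_PRESSURE_INVERSION} mmHg across pulse peaks"
        )
    if np.any(rises > 0):
        warnings.warn("small cuff-pressure inversions across peaks; continuing", stacklevel=2)

    points = [
        EnvelopePoint(float(t), float(p), float(a))
        for t, p, a in zip(times, pressures, amps)
    ]
    spline = CubicSpline(times, amps, bc_type="natural")
    dense_t = np.linspace(times[0], times[-1], n_dense)
    dense_a = spline(dense_t)
    dense_p = np.interp(dense_t, omw.sample_times, omw.baseline)

    i_max = int(np.argmax(dense_a))  # first sample attaining the max
    degenerate = i_max in (0, n_dense - 1)
    return Envelope(
        points=points,
        dense_times=dense_t,
        dense_amplitude=dense_a,
        dense_pressure=dense_p,
        max_amplitude=float(dense_a[i_max]),
        pressure_at_max=float(dense_p[i_max]),
        index_of_max=i_max,
        degenerate=degenerate,
        smoothed=spline,
    )


def _branch_slices(env: Envelope, side: Side) -> slice:
    if side == "systolic":
        return slice(0, env.index_of_max + 1)
    if side == "diastolic":
        return slice(env.index_of_max, len(env.dense_amplitude))
    raise ValueError(f"side must be 'systolic' or 'diastolic', got {side!r}")


def amplitude_to_pressure(env: Envelope, target_amplitude: float, side: Side) -> float:
    """Cuff pressure at which the chosen branch crosses a target amplitude.

    The systolic branch is the part of the dense envelope before the
    maximum (higher pressures during deflation), the diastolic branch the
    part after. When the branch crosses the target more than once the
    crossing farthest from the apex is taken — the outer intersection,
    which is the one of clinical interest.
    """
    m = env.max_amplitude
    if not 0 < target_amplitude <= m:
        if target_amplitude > m:
            raise EnvelopeError(
                f"amplitude exceeds maximum: {target_amplitude:.4g} > m = {m:.4g}"
            )
        raise EnvelopeError("target amplitude must be positive")
    if np.isclose(target_amplitude, m, rtol=0, atol=1e-12 * max(1.0, m)):
        return env.pressure_at_max

    sl = _branch_slices(env, side)
    a = env.dense_amplitude[sl]
    p = env.dense_pressure[sl]
    below = a < target_amplitude
    crossings = np.nonzero(below[:-1] != below[1:])[0]
    if crossings.size == 0:
        # the target may sit exactly on the branch's outer endpoint
        k = 0 if side == "systolic" else len(a) - 1
        if np.isclose(a[k], target_amplitude, rtol=1e-9, atol=1e-9 * max(1.0, m)):
            return float(p[k])
        raise EnvelopeError(
            f"branch does not reach amplitude: {side} branch never falls to "
            f"{target_amplitude:.4g}"
        )
    # farthest from the apex: apex is the branch end for systolic, start for diastolic
    k = int(crossings[0]) if side == "systolic" else int(crossings[-1])
    a0, a1 = a[k], a[k + 1]
    frac = 0.5 if a1 == a0 else (target_amplitude - a0) / (a1 - a0)
    return float(p[k] + frac * (p[k + 1] - p[k]))


def amplitude_at_pressure(env: Envelope, pressure: float, side: Side) -> float:
    """Smoothed envelope amplitude at a given cuff pressure on a branch.

    This is the inverse of :func:`amplitude_to_pressure` and is how
    auscultatory reference pressures are converted into reference ratios.
    Multiple crossings (ripple) resolve to the one farthest from the apex.
    """
    sl = _branch_slices(env, side)
    a = env.dense_amplitude[sl]
    p = env.dense_pressure[sl]
    lo, hi = float(np.min(p)), float(np.max(p))
    if not lo <= pressure <= hi:
        raise EnvelopeError(
            f"reference outside envelope support: {pressure:.4g} mmHg not in "
            f"[{lo:.4g}, {hi:.4g}] on the {side} branch"
        )
    above = p >= pressure
    crossings = np.nonzero(above[:-1] != above[1:])[0]
    if crossings.size == 0:
        # pressure equals a branch endpoint exactly
        k = int(np.argmin(np.abs(p - pressure)))
        return float(a[k])
    k = int(crossings[0]) if side == "systolic" else int(crossings[-1])
    p0, p1 = p[k], p[k + 1]
    frac = 0.5 if p1 == p0 else (pressure - p0) / (p1 - p0)
    return float(a[k] + frac * (a[k + 1] - a[k]))
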