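"""Synthetic cuff-deflation recordings with known ground truth.

Real oscillometric validation data (an 85-subject, five-measurement
auscultatory study) is proprietary, so this module generates recordings
with the same structure and fully known truth:

* a linear deflation ramp (2.5 mmHg/s by default) spanning from above the
  systolic to below the diastolic pressure;
* cardiac oscillations at a fixed heart rate whose amplitude follows a
  two-sided Gaussian bell in cuff pressure, centered at the true mean
  arterial pressure; the two branch widths are solved so that the
  envelope amplitude at the true SBP is exactly ``true_ratio_s`` times
  the peak and at the true DBP exactly ``true_ratio_d`` times the peak —
  the ratios are therefore exact construction constraints, not emergent
  properties;
* additive white sensor noise;
* two simulated nurse readings per measurement that differ by at most
  2 mmHg and average to the true pressure plus a reading error.

Cohorts draw subject-level ratios from truncated normals inside the
candidate-grid ranges (0.65–0.95 systolic, 0.30–0.60 diastolic) with
per-measurement jitter, and pressures from the study's observed ranges
(SBP 78–147, DBP 42–99 mmHg). All randomness flows through one seeded
generator; every measurement's truth is recorded in a manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .envelope import CuffRecording
from .errors import TruthError

DEFLATION_RATE = 2.5  # mmHg/s
DURATION_RANGE = (31.0, 95.0)  # s, observed study range


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic measurement."""

    true_sbp: float
    true_dbp: float
    true_map: float
    true_ratio_s: float
    true_ratio_d: float
    heart_rate: float = 72.0  # bpm
    oscillation_gain: float = 2.0  # peak envelope amplitude, mmHg
    noise_sd: float = 0.05  # sensor noise, mmHg
    nurse_noise_sd: float = 1.0  # reading error of the averaged nurses, mmHg
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_dbp < self.true_map < self.true_sbp:
            raise TruthError("inconsistent truth: need dbp < map < sbp")
        for r in (self.true_ratio_s, self.true_ratio_d):
            if not 0.0 < r < 1.0:
                raise TruthError("inconsistent truth: ratios must lie in (0, 1)")
        if self.oscillation_gain <= 0 or self.heart_rate <= 0:
            raise TruthError("inconsistent truth: gain and heart rate must be positive")

    @property
    def width_systolic(self) -> float:
        """Gaussian half-width of the envelope above the mean pressure,
        solved from the systolic ratio constraint."""
        return (self.true_sbp - self.true_map) / math.sqrt(-2.0 * math.log(self.true_ratio_s))

    @property
    def width_diastolic(self) -> float:
        return (self.true_map - self.true_dbp) / math.sqrt(-2.0 * math.log(self.true_ratio_d))


def envelope_amplitude(truth: SyntheticTruth, cuff_pressure) -> np.ndarray:
    """True envelope amplitude at given cuff pressures (the generator's
    oracle for envelope-recovery tests)."""
    cp = np.asarray(cuff_pressure, dtype=float)
    w = np.where(cp >= truth.true_map, truth.width_systolic, truth.width_diastolic)
    return truth.oscillation_gain * np.exp(-0.5 * ((cp - truth.true_map) / w) ** 2)


def _pressure_span(truth: SyntheticTruth) -> tuple[float, float]:
    # deflate from where the envelope has fallen to 0.60 of peak on the
    # systolic side (safely below the 0.65 grid floor) down to 0.25 on
    # the diastolic side (below the 0.30 floor), so every candidate
    # ratio and the classical (0.70, 0.45) pair have a crossing.
    start = max(
        truth.true_sbp + 30.0,
        truth.true_map + truth.width_systolic * math.sqrt(-2.0 * math.log(0.60)),
    )
    end = min(
        truth.true_dbp - 20.0,
        truth.true_map - truth.width_diastolic * math.sqrt(-2.0 * math.log(0.25)),
    )
    if end <= 5.0:
        raise TruthError("inconsistent truth: deflation would reach non-positive pressure")
    return start, end


def generate_recording(
    truth: SyntheticTruth,
    duration: float | None = None,
    sampling_rate: float = 100.0,
    subject_id: str = "synthetic",
    measurement_index: int = 1,
) -> tuple[CuffRecording, SyntheticTruth]:
    """Synthesize one cuff-deflation recording.

    The deflation duration follows from the pressure span at 2.5 mmHg/s,
    clipped into the 31–95 s range (the rate adapts if clipping binds);
    an explicit ``duration`` overrides it (20–120 s). Reproducible from
    ``truth.seed``.
    """
    if sampling_rate < 20:
        raise ValueError("sampling_rate must be >= 20 Hz")
    start, end = _pressure_span(truth)
    span = start - end
    if duration is None:
        duration = min(max(span / DEFLATION_RATE, DURATION_RANGE[0]), DURATION_RANGE[1])
    elif not 20.0 <= duration <= 120.0:
        raise ValueError("duration must lie in [20, 120] s")
    rate = span / duration

    rng = np.random.default_rng(truth.seed)
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    cp_base = start - rate * t
    amp = envelope_amplitude(truth, cp_base)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    osc = amp * np.sin(2.0 * np.pi * (truth.heart_rate / 60.0) * t + phase)
    noise = rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 else 0.0
    cp = cp_base + osc + noise
    rec = CuffRecording(
        subject_id=subject_id,
        measurement_index=measurement_index,
        sample_times=t,
        cuff_pressure=cp,
        sampling_rate=sampling_rate,
    )
    return rec, truth


def nurse_readings(truth: SyntheticTruth, rng: np.random.Generator) -> dict:
    """Two simulated auscultatory readings per pressure, at most 2 mmHg
    apart; their average is the true pressure plus a reading error with
    SD ``nurse_noise_sd``."""
    out = {}
    for key, true_val in (("sbp", truth.true_sbp), ("dbp", truth.true_dbp)):
        center = true_val + (
            rng.normal(0.0, truth.nurse_noise_sd) if truth.nurse_noise_sd > 0 else 0.0
        )
        half = rng.uniform(0.0, 1.0)  # two readings differ by 2*half <= 2 mmHg
        out[key] = (center - half, center + half)
    return out


@dataclass(frozen=True)
class CohortConfig:
    """Distributional assumptions for a synthetic cohort.

    Pressure ranges follow the study's observed spans; ratio means and
    spreads follow the reported per-measurement ratio averages (about
    0.80 (0.11) systolic, 0.42 (0.11) diastolic)."""

    sbp_mean: float = 110.0
    sbp_sd: float = 13.0
    sbp_range: tuple[float, float] = (78.0, 147.0)
    dbp_mean: float = 67.0
    dbp_sd: float = 10.0
    dbp_range: tuple[float, float] = (42.0, 99.0)
    min_pulse_pressure: float = 25.0
    ratio_s_mean: float = 0.80
    ratio_s_sd: float = 0.11
    ratio_s_range: tuple[float, float] = (0.65, 0.95)
    ratio_d_mean: float = 0.42
    ratio_d_sd: float = 0.11
    ratio_d_range: tuple[float, float] = (0.30, 0.60)
    ratio_jitter_sd: float = 0.03  # per-measurement within-subject jitter
    pressure_jitter_sd: float = 2.0  # per-measurement BP variation, mmHg
    hr_mean: float = 72.0
    hr_sd: float = 8.0
    hr_range: tuple[float, float] = (50.0, 100.0)
    oscillation_gain: float = 2.0
    noise_sd: float = 0.05
    nurse_noise_sd: float = 1.0
    sampling_rate: float = 100.0
    snap_ratios_to_grid: bool = False  # quantize true ratios to the 0.01 grid
    grid_step: float = 0.01


@dataclass(frozen=True)
class CohortMeasurement:
    subject_id: str
    measurement_index: int
    recording: CuffRecording
    nurse1_sbp: float
    nurse1_dbp: float
    nurse2_sbp: float
    nurse2_dbp: float
    truth: SyntheticTruth

    @property
    def ref_sbp(self) -> float:
        return 0.5 * (self.nurse1_sbp + self.nurse2_sbp)

    @property
    def ref_dbp(self) -> float:
        return 0.5 * (self.nurse1_dbp + self.nurse2_dbp)


@dataclass(frozen=True)
class Cohort:
    measurements: list[CohortMeasurement]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.measurements)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _snap(value: float, lo: float, hi: float, step: float) -> float:
    snapped = lo + round((value - lo) / step) * step
    return min(max(snapped, lo), hi)


def generate_cohort(
    n_subjects: int,
    n_measurements: int = 5,
    seed: int = 0,
    cfg: CohortConfig | None = None,
) -> Cohort:
    """Generate a full synthetic cohort with known per-measurement truth.

    Subject-level pressures, ratios and heart rate are drawn from the
    configured truncated normals; each measurement adds small jitter to
    ratios and pressures. One master seed drives everything; each
    recording gets its own child seed (recorded in its truth) so it can
    be regenerated in isolation.
    """
    if n_subjects < 1 or n_measurements < 1:
        raise ValueError("need at least one subject and one measurement")
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(seed)
    measurements: list[CohortMeasurement] = []
    for i in range(1, n_subjects + 1):
        sbp0 = _truncnorm(rng, cfg.sbp_mean, cfg.sbp_sd, *cfg.sbp_range)
        dbp_hi = min(cfg.dbp_range[1], sbp0 - cfg.min_pulse_pressure)
        dbp0 = _truncnorm(rng, cfg.dbp_mean, cfg.dbp_sd, cfg.dbp_range[0], dbp_hi)
        rs0 = _truncnorm(rng, cfg.ratio_s_mean, cfg.ratio_s_sd, *cfg.ratio_s_range)
        rd0 = _truncnorm(rng, cfg.ratio_d_mean, cfg.ratio_d_sd, *cfg.ratio_d_range)
        hr = _truncnorm(rng, cfg.hr_mean, cfg.hr_sd, *cfg.hr_range)
        for j in range(1, n_measurements + 1):
            jit = cfg.ratio_jitter_sd
            rs = float(np.clip(rs0 + (rng.normal(0, jit) if jit > 0 else 0.0), *cfg.ratio_s_range))
            rd = float(np.clip(rd0 + (rng.normal(0, jit) if jit > 0 else 0.0), *cfg.ratio_d_range))
            if cfg.snap_ratios_to_grid:
                rs = _snap(rs, *cfg.ratio_s_range, cfg.grid_step)
                rd = _snap(rd, *cfg.ratio_d_range, cfg.grid_step)
            pj = cfg.pressure_jitter_sd
            sbp = float(np.clip(sbp0 + (rng.normal(0, pj) if pj > 0 else 0.0), *cfg.sbp_range))
            dbp_cap = min(cfg.dbp_range[1], sbp - cfg.min_pulse_pressure)
            dbp = float(np.clip(dbp0 + (rng.normal(0, pj) if pj > 0 else 0.0),
                                cfg.dbp_range[0], dbp_cap))
            mean_p = dbp + (sbp - dbp) / 3.0
            child_seed = int(rng.integers(0, 2**31 - 1))
            truth = SyntheticTruth(
                true_sbp=sbp,
                true_dbp=dbp,
                true_map=mean_p,
                true_ratio_s=rs,
                true_ratio_d=rd,
                heart_rate=hr,
                oscillation_gain=cfg.oscillation_gain,
                noise_sd=cfg.noise_sd,
                nurse_noise_sd=cfg.nurse_noise_sd,
                seed=child_seed,
            )
            subject_id = f"subject{i:03d}"
            rec, _ = generate_recording(
                truth,
                sampling_rate=cfg.sampling_rate,
                subject_id=subject_id,
                measurement_index=j,
            )
            nr = nurse_readings(truth, rng)
            measurements.append(
                CohortMeasurement(
                    subject_id=subject_id,
                    measurement_index=j,
                    recording=rec,
                    nurse1_sbp=nr["sbp"][0],
                    nurse1_dbp=nr["dbp"][0],
                    nurse2_sbp=nr["sbp"][1],
                    nurse2_dbp=nr["dbp"][1],
                    truth=truth,
                )
            )
    return Cohort(measurements=measurements, config=cfg, seed=seed)
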