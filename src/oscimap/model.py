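"""Model/Results facade over the full estimation pipeline.

``OscillometricBPModel`` holds a set of cuff measurements with their
auscultatory references plus the estimation configuration (candidate
grids, likelihood, fixed ratios); ``fit()`` runs envelope extraction and
all requested estimators over every measurement and returns an
``OscillometricBPResults`` carrying the per-measurement estimates,
agreement statistics against the references, summary tables and
Bland–Altman plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import bayes as _bayes
from .agreement import AgreementStats, agreement, plot_bland_altman, summarize_by_measurement
from .envelope import CuffRecording, build_envelope, detect_pulse_peaks, extract_omw
from .errors import OscimapError
from .maa import FixedRatios, maa_estimate
from .synth import Cohort, SyntheticTruth

logger = logging.getLogger(__name__)

METHODS = ("MAA", "MAABG", "MAABL")


@dataclass(frozen=True)
class MeasurementData:
    """One measurement: a recording plus its (averaged) reference."""

    subject_id: str
    measurement_index: int
    recording: CuffRecording
    ref_sbp: float
    ref_dbp: float
    truth: SyntheticTruth | None = None


class OscillometricBPModel:
    """Oscillometric BP estimation over a set of measurements.

    Parameters
    ----------
    measurements : sequence of MeasurementData
    grid_s, grid_d : CandidateGrid, optional
        Candidate-ratio grids (defaults 0.65–0.95 / 0.30–0.60, step 0.01).
    sigma : float
        Likelihood standard deviation shared by both families.
    fixed_ratios : FixedRatios
        The classical fixed ratios for the conventional estimator.
    baseline_window : float
        Moving-average window (s) for baseline separation.
    hr_range : (float, float)
        Plausible heart-rate range (bpm) for pulse detection.
    """

    def __init__(
        self,
        measurements: Sequence[MeasurementData],
        grid_s: _bayes.CandidateGrid | None = None,
        grid_d: _bayes.CandidateGrid | None = None,
        sigma: float = _bayes.DEFAULT_SIGMA,
        fixed_ratios: FixedRatios | None = None,
        baseline_window: float = 3.0,
        hr_range: tuple[float, float] = (40.0, 180.0),
        n_dense: int = 200,
    ) -> None:
        if not measurements:
            raise OscimapError("no measurements found")
        self.measurements = list(measurements)
        self.grid_s = grid_s or _bayes.default_sbp_grid()
        self.grid_d = grid_d or _bayes.default_dbp_grid()
        self.sigma = sigma
        self.fixed_ratios = fixed_ratios or FixedRatios()
        self.baseline_window = baseline_window
        self.hr_range = hr_range
        self.n_dense = n_dense

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "OscillometricBPModel":
        data = [
            MeasurementData(
                subject_id=m.subject_id,
                measurement_index=m.measurement_index,
                recording=m.recording,
                ref_sbp=m.ref_sbp,
                ref_dbp=m.ref_dbp,
                truth=m.truth,
            )
            for m in cohort.measurements
        ]
        return cls(data, **kwargs)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "OscillometricBPModel":
        from .io import read_cohort

        return cls.from_cohort(read_cohort(path), **kwargs)

    def _process_one(self, meas: MeasurementData, methods: Sequence[str]) -> list[dict]:
        rec = meas.recording
        omw = extract_omw(rec, self.baseline_window)
        peaks = detect_pulse_peaks(omw, self.hr_range)
        env = build_envelope(omw, rec, peaks, self.n_dense)
        if env.degenerate:
            raise OscimapError("degenerate envelope (maximum on boundary)")
        rows = []
        base = {
            "subject": meas.subject_id,
            "measurement": meas.measurement_index,
            "ref_sbp": meas.ref_sbp,
            "ref_dbp": meas.ref_dbp,
            "map_pressure": env.pressure_at_max,
            "m": env.max_amplitude,
        }
        ref = None
        if any(m in methods for m in ("MAABG", "MAABL")):
            ref = _bayes.reference_ratio(env, meas.ref_sbp, meas.ref_dbp)
        for method in methods:
            if method == "MAA":
                est = maa_estimate(env, self.fixed_ratios)
                y_s = y_d = np.nan
            else:
                family = "gaussian" if method == "MAABG" else "laplacian"
                spec = _bayes.LikelihoodSpec(family=family, sigma=self.sigma)
                r_s = _bayes.map_ratio(ref.y_s, self.grid_s, spec=spec)
                r_d = _bayes.map_ratio(ref.y_d, self.grid_d, spec=spec)
                est = _bayes.estimate_bp_bayes(env, r_s, r_d)
                y_s, y_d = ref.y_s, ref.y_d
            rows.append(
                base
                | {
                    "method": method,
                    "sbp": est.sbp,
                    "dbp": est.dbp,
                    "ratio_s": est.ratios_used[0],
                    "ratio_d": est.ratios_used[1],
                    "y_s": y_s,
                    "y_d": y_d,
                }
            )
        return rows

    def fit(self, methods: Sequence[str] = METHODS) -> "OscillometricBPResults":
        """Run every requested estimator on every measurement.

        Measurements whose pipeline fails (too few pulses, degenerate
        envelope, unsupported ratio) are logged and skipped; the failure
        list and rate are carried on the results.
        """
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        rows: list[dict] = []
        failures: list[dict] = []
        for meas in self.measurements:
            try:
                rows.extend(self._process_one(meas, methods))
            except OscimapError as exc:
                logger.info(
                    "skipping %s/%s: %s", meas.subject_id, meas.measurement_index, exc
                )
                failures.append(
                    {
                        "subject": meas.subject_id,
                        "measurement": meas.measurement_index,
                        "error": str(exc),
                    }
                )
        frame = pd.DataFrame(rows)
        return OscillometricBPResults(
            model=self,
            estimates=frame,
            failures=failures,
            methods=tuple(methods),
        )


@dataclass
class OscillometricBPResults:
    """Per-measurement estimates and cohort-level agreement."""

    model: OscillometricBPModel
    estimates: pd.DataFrame
    failures: list[dict]
    methods: tuple[str, ...]

    @property
    def n_measurements(self) -> int:
        if self.estimates.empty:
            return 0
        return int(self.estimates.groupby(["subject", "measurement"]).ngroups)

    @property
    def failure_rate(self) -> float:
        total = self.n_measurements + len(self.failures)
        return len(self.failures) / total if total else 0.0

    def _pairs(self, method: str, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which not in ("sbp", "dbp"):
            raise ValueError("which must be 'sbp' or 'dbp'")
        sub = self.estimates[self.estimates["method"] == method]
        if sub.empty:
            raise OscimapError(f"no estimates for method {method!r}")
        return sub[which].to_numpy(), sub[f"ref_{which}"].to_numpy()

    def agreement(self, method: str, which: str) -> AgreementStats:
        """MD/SD/limits/AAMI flag of ``method`` against the references."""
        est, ref = self._pairs(method, which)
        return agreement(est, ref)

    def by_measurement(self, which: str) -> pd.DataFrame:
        """Per-measurement-index summary table (plus avg and pooled rows)."""
        long = self.estimates.rename(columns={which: "estimate", f"ref_{which}": "reference"})
        return summarize_by_measurement(
            long[["subject", "measurement", "method", "estimate", "reference"]]
        )

    def bland_altman_plot(self, method: str, which: str, ax=None):
        est, ref = self._pairs(method, which)
        return plot_bland_altman(est, ref, ax=ax, title=f"{method} {which.upper()}")

    def summary(self) -> str:
        """Validation-style text table: per measurement index and method,
        the MD (SD) of estimate minus reference, for SBP and DBP."""
        lines = [
            "Oscillometric BP estimation vs auscultatory reference",
            f"measurements: {self.n_measurements}   failed: {len(self.failures)}",
            "",
        ]
        for which in ("sbp", "dbp"):
            table = self.by_measurement(which)
            lines.append(f"{which.upper()} — MD (SD) in mmHg, estimate − reference")
            header = "meas".ljust(8) + "".join(m.ljust(16) for m in self.methods)
            lines.append(header)
            for idx, row in table.iterrows():
                cells = []
                for m in self.methods:
                    md, sd = row[("md", m)], row[("sd", m)]
                    cells.append(f"{md:6.2f} ({sd:5.2f})".ljust(16))
                lines.append(str(idx).ljust(8) + "".join(cells))
            for m in self.methods:
                stats = self.agreement(m, which)
                flag = "pass" if stats.aami_pass else "FAIL"
                lines.append(
                    f"  {m}: pooled MD {stats.md:.2f}, SD {stats.sd:.2f} mmHg "
                    f"(AAMI: {flag}, n={stats.n})"
                )
            lines.append("")
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-ready report: resolved config, agreement per method, and
        the per-measurement tables (both avg conventions)."""
        report: dict = {
            "config": {
                "grid_s": self.model.grid_s.values.tolist(),
                "grid_d": self.model.grid_d.values.tolist(),
                "sigma": self.model.sigma,
                "fixed_ratios": list(self.model.fixed_ratios.__dict__.values()),
                "baseline_window": self.model.baseline_window,
                "methods": list(self.methods),
            },
            "n_measurements": self.n_measurements,
            "failures": self.failures,
            "agreement": {},
            "by_measurement": {},
        }
        for which in ("sbp", "dbp"):
            report["agreement"][which] = {}
            for m in self.methods:
                s = self.agreement(m, which)
                report["agreement"][which][m] = {
                    "md": s.md,
                    "sd": s.sd,
                    "n": s.n,
                    "loa_low": s.loa_low,
                    "loa_high": s.loa_high,
                    "aami_pass": s.aami_pass,
                }
            table = self.by_measurement(which)
            report["by_measurement"][which] = {
                str(idx): {
                    m: {"md": row[("md", m)], "sd": row[("sd", m)]} for m in self.methods
                }
                for idx, row in table.iterrows()
            }
        return report
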