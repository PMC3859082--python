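"""Readers and writers for the on-disk formats.

Time series travel as two-column CSV (``time_s,cuff_pressure_mmhg``),
nurse references as JSON sidecars (single-reading or two-reading form,
two readings averaged downstream), cohorts as a directory tree
``cohort/subjectNNN/measM.csv`` + ``measM.nurse.json`` with a
``manifest.json`` recording the full generation truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .envelope import CuffRecording
from .errors import OscimapError
from .synth import Cohort, CohortConfig, CohortMeasurement, SyntheticTruth

RECORDING_HEADER = ["time_s", "cuff_pressure_mmhg"]


def read_recording(path, subject_id: str | None = None, measurement_index: int = 1) -> CuffRecording:
    """Read a cuff recording CSV, validating header and every row.

    Malformed rows are rejected with their 1-based line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != RECORDING_HEADER:
        raise OscimapError(
            f"{path}: expected header {','.join(RECORDING_HEADER)!r}, "
            f"got {','.join(map(str, df.columns))!r}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in numeric.index[bad][:10]]  # +2: header + 1-based
        raise OscimapError(f"{path}: non-numeric cells at lines {lines}")
    t = numeric["time_s"].to_numpy()
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        first = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 3
        raise OscimapError(f"{path}: time not strictly increasing at line {first}")
    fs = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 1.0
    return CuffRecording(
        subject_id=subject_id or path.stem,
        measurement_index=measurement_index,
        sample_times=t,
        cuff_pressure=numeric["cuff_pressure_mmhg"].to_numpy(),
        sampling_rate=fs,
    )


def write_recording(rec: CuffRecording, path) -> None:
    df = pd.DataFrame({"time_s": rec.sample_times, "cuff_pressure_mmhg": rec.cuff_pressure})
    df.to_csv(path, index=False, float_format="%.6f")


def read_nurse(path) -> dict:
    """Read a nurse-reference JSON sidecar.

    Accepts either ``{"sbp_mmhg": x, "dbp_mmhg": y}`` or the two-reading
    form ``{"nurse1": {...}, "nurse2": {...}}``; two readings are
    averaged into ``sbp_mmhg``/``dbp_mmhg``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "nurse1" in raw and "nurse2" in raw:
        sbp = 0.5 * (raw["nurse1"]["sbp_mmhg"] + raw["nurse2"]["sbp_mmhg"])
        dbp = 0.5 * (raw["nurse1"]["dbp_mmhg"] + raw["nurse2"]["dbp_mmhg"])
        return {"sbp_mmhg": sbp, "dbp_mmhg": dbp, "raw": raw}
    if "sbp_mmhg" in raw and "dbp_mmhg" in raw:
        return {"sbp_mmhg": float(raw["sbp_mmhg"]), "dbp_mmhg": float(raw["dbp_mmhg"]), "raw": raw}
    raise OscimapError(f"{path}: unrecognized nurse reference format")


def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to the on-disk layout with a truth manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cohort.seed,
        "config": dataclasses.asdict(cohort.config),
        "measurements": [],
    }
    for meas in cohort.measurements:
        subj_dir = root / meas.subject_id
        subj_dir.mkdir(exist_ok=True)
        rec_path = subj_dir / f"meas{meas.measurement_index}.csv"
        write_recording(meas.recording, rec_path)
        nurse_path = subj_dir / f"meas{meas.measurement_index}.nurse.json"
        with open(nurse_path, "w") as fh:
            json.dump(
                {
                    "nurse1": {"sbp_mmhg": meas.nurse1_sbp, "dbp_mmhg": meas.nurse1_dbp},
                    "nurse2": {"sbp_mmhg": meas.nurse2_sbp, "dbp_mmhg": meas.nurse2_dbp},
                },
                fh,
                indent=1,
            )
        manifest["measurements"].append(
            {
                "subject_id": meas.subject_id,
                "measurement_index": meas.measurement_index,
                "recording": rec_path.relative_to(root).as_posix(),
                "nurse": nurse_path.relative_to(root).as_posix(),
                "truth": dataclasses.asdict(meas.truth),
            }
        )
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return root


def read_cohort(path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise OscimapError(f"no measurements found: {manifest_path} missing")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if not manifest.get("measurements"):
        raise OscimapError(f"no measurements found in {root}")
    measurements = []
    for entry in manifest["measurements"]:
        rec = read_recording(
            root / entry["recording"],
            subject_id=entry["subject_id"],
            measurement_index=entry["measurement_index"],
        )
        with open(root / entry["nurse"]) as fh:
            nurse = json.load(fh)
        truth = SyntheticTruth(**entry["truth"])
        measurements.append(
            CohortMeasurement(
                subject_id=entry["subject_id"],
                measurement_index=entry["measurement_index"],
                recording=rec,
                nurse1_sbp=nurse["nurse1"]["sbp_mmhg"],
                nurse1_dbp=nurse["nurse1"]["dbp_mmhg"],
                nurse2_sbp=nurse["nurse2"]["sbp_mmhg"],
                nurse2_dbp=nurse["nurse2"]["dbp_mmhg"],
                truth=truth,
            )
        )
    cfg = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in manifest["config"].items()})
    return Cohort(measurements=measurements, config=cfg, seed=manifest["seed"])
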