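"""Agreement statistics between BP estimates and reference readings.

Implements the ANSI/AAMI SP10 accuracy metrics — the mean difference (MD)
and standard deviation (SD) of estimate-minus-reference differences, with
the pass rule |MD| <= 5 mmHg and SD <= 8 mmHg — plus Bland–Altman
quantities (per-pair mean/difference points and limits of agreement
MD ± 2 SD) and per-measurement summary tables across a cohort.

Differences are oriented estimate − reference throughout; the SD uses the
n − 1 denominator. The AAMI boundary is inclusive at exactly (5, 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AAMI_MD_LIMIT = 5.0
AAMI_SD_LIMIT = 8.0


@dataclass(frozen=True)
class AgreementStats:
    md: float
    sd: float
    n: int
    loa_low: float
    loa_high: float
    aami_pass: bool


def _diffs(estimates, references) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1-D sequences")
    if est.size == 0:
        raise ValueError("empty input")
    return est - ref


def agreement(estimates, references,
              md_limit: float = AAMI_MD_LIMIT, sd_limit: float = AAMI_SD_LIMIT) -> AgreementStats:
    """MD, SD, Bland–Altman limits and the AAMI pass flag for paired data."""
    d = _diffs(estimates, references)
    if d.size < 2:
        raise ValueError("need at least 2 pairs (SD undefined for n = 1)")
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(
        md=md,
        sd=sd,
        n=int(d.size),
        loa_low=md - 2 * sd,
        loa_high=md + 2 * sd,
        aami_pass=bool(abs(md) <= md_limit and sd <= sd_limit),
    )


def bland_altman_points(estimates, references) -> np.ndarray:
    """Per-pair (mean, difference) points for a Bland–Altman plot."""
    d = _diffs(estimates, references)
    mean = (np.asarray(estimates, float) + np.asarray(references, float)) / 2.0
    return np.column_stack([mean, d])


def plot_bland_altman(estimates, references, ax=None, title: str | None = None):
    """Draw a Bland–Altman plot with the MD line and MD ± 2 SD limits."""
    import matplotlib.pyplot as plt

    pts = bland_altman_points(estimates, references)
    stats = agreement(estimates, references)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7)
    ax.axhline(stats.md, color="k", lw=1.5)
    ax.axhline(stats.loa_low, color="k", lw=2.0, ls="--")
    ax.axhline(stats.loa_high, color="k", lw=2.0, ls="--")
    ax.set_xlabel("mean of estimate and reference (mmHg)")
    ax.set_ylabel("estimate − reference (mmHg)")
    if title:
        ax.set_title(title)
    return ax


def summarize_by_measurement(df: pd.DataFrame) -> pd.DataFrame:
    """Per-measurement-index, per-method summary of estimates and errors.

    Expects a long-format frame with columns ``subject``, ``measurement``,
    ``method``, ``estimate``, ``reference``. Returns one row per
    measurement index with, per method, the mean estimate (and SD across
    subjects) and the MD (and SD of differences), plus:

    * an ``avg`` row — the arithmetic mean of the per-measurement MDs and
      SDs, and
    * a ``pooled`` row — MD/SD over all differences pooled, for
      comparison.

    Missing cells stay missing (NaN); nothing is imputed.
    """
    required = {"subject", "measurement", "method", "estimate", "reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    work = df.copy()
    work["difference"] = work["estimate"] - work["reference"]

    g = work.groupby(["measurement", "method"])
    summary = g.agg(
        est_mean=("estimate", "mean"),
        est_sd=("estimate", lambda s: s.std(ddof=1)),
        md=("difference", "mean"),
        sd=("difference", lambda s: s.std(ddof=1)),
        n=("difference", "size"),
    ).unstack("method")

    per_meas = summary.copy()
    avg = per_meas.mean(axis=0)
    for method in per_meas["n"].columns:
        avg[("n", method)] = per_meas[("n", method)].sum()
    pooled_g = work.groupby("method")
    pooled = pd.Series(
        {
            (stat, method): val
            for method, sub in pooled_g
            for stat, val in (
                ("est_mean", sub["estimate"].mean()),
                ("est_sd", sub["estimate"].std(ddof=1)),
                ("md", sub["difference"].mean()),
                ("sd", sub["difference"].std(ddof=1)),
                ("n", float(len(sub))),
            )
        }
    )
    out = pd.concat([per_meas, pd.DataFrame([avg, pooled], index=["avg", "pooled"])])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stat", "method"])
    return out
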