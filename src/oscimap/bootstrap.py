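"""Nonparametric bootstrap of per-subject ratio samples.

With only a handful of measurements per subject (five in a typical
validation session), the sampling distribution of a subject's mean ratio
is approximated by resampling the observed ratios with replacement B
times and taking the mean of each resample. The resulting pseudo-ratio
distribution supports a normality check of the per-subject ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_B = 1000


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = DEFAULT_B
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    pseudo_means: np.ndarray
    original: np.ndarray
    normality_p: float | None = None
    normality_normal: bool | None = None
    degenerate: bool = field(default=False)


def npb(ratios, cfg: BootstrapConfig | None = None) -> BootstrapResult:
    """Bootstrap the mean of a small ratio sample.

    Draws ``cfg.B`` resamples of size ``m = len(ratios)`` with replacement
    using a generator seeded by ``cfg.seed`` and returns the resample
    means. Reproducible given the seed. When at least 20 pseudo means are
    available a normality check is attached to the result.
    """
    if cfg is None:
        cfg = BootstrapConfig()
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty ratio sample")
    if r.size < 2:
        raise ValueError("need at least 2 ratios to bootstrap")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite ratios")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, r.size, size=(cfg.B, r.size))
    pseudo = r[idx].mean(axis=1)
    p = normal = None
    degenerate = False
    if pseudo.size >= 20:
        check = normality_check(pseudo)
        p, normal, degenerate = check["p"], check["normal"], check["degenerate"]
    return BootstrapResult(
        pseudo_means=pseudo,
        original=r,
        normality_p=p,
        normality_normal=normal,
        degenerate=degenerate,
    )


def _anderson_darling_p(x: np.ndarray) -> float:
    """P-value for the Anderson–Darling normality statistic.

    Uses the small-sample adjustment ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)``
    and the standard piecewise-exponential approximation of the null
    distribution (Stephens / D'Agostino).
    """
    import warnings

    n = x.size
    with warnings.catch_warnings():
        # scipy >= 1.17 asks for a p-value method; only the statistic is used here
        warnings.simplefilter("ignore", FutureWarning)
        a2 = stats.anderson(x, dist="norm").statistic
    a2 *= 1.0 + 0.75 / n + 2.25 / n**2
    if a2 >= 0.6:
        return float(np.exp(1.2937 - 5.709 * a2 + 0.0186 * a2**2))
    if a2 >= 0.34:
        return float(np.exp(0.9177 - 4.279 * a2 - 1.38 * a2**2))
    if a2 >= 0.2:
        return float(1.0 - np.exp(-8.318 + 42.796 * a2 - 59.938 * a2**2))
    return float(1.0 - np.exp(-13.436 + 101.14 * a2 - 223.73 * a2**2))


def normality_check(values, alpha: float = 0.05, test: str = "anderson") -> dict:
    """Test a sample for normality at level ``alpha``.

    ``test`` selects the statistic: ``anderson`` (Anderson–Darling,
    default), ``shapiro`` (Shapiro–Wilk) or ``normaltest``
    (D'Agostino–Pearson). A constant sample is flagged degenerate and
    declared non-normal with p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 values for a normality check")
    if np.ptp(x) == 0:
        return {"normal": False, "p": 0.0, "degenerate": True}
    if test == "anderson":
        p = _anderson_darling_p(x)
    elif test == "shapiro":
        p = float(stats.shapiro(x).pvalue)
    elif test == "normaltest":
        p = float(stats.normaltest(x).pvalue)
    else:
        raise ValueError(f"unknown normality test {test!r}")
    p = min(max(p, 0.0), 1.0)
    return {"normal": p > alpha, "p": p, "degenerate": False}
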