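"""Bayesian MAP estimation of per-measurement systolic/diastolic ratios.

Instead of a single fixed amplitude ratio, the ratio is treated as a
random variable on a discrete candidate grid (default 0.65–0.95 for the
systolic ratio, 0.30–0.60 for the diastolic, step 0.01, K = 31
candidates). A uniform prior is combined with a likelihood centered on
the *reference ratio* — the envelope amplitude at the auscultatory
reference pressure divided by the maximum amplitude ``m`` — and the
candidate maximizing the posterior is taken as that measurement's ratio.

Two likelihood families are supported, both parameterized by a standard
deviation ``sigma``:

* Gaussian:  ``f(y | c) = (1 / (sqrt(2 pi) sigma)) exp(-(y - c)^2 / (2 sigma^2))``
* Laplacian: ``f(y | c) = (1 / (sqrt(2) sigma)) exp(-(sqrt(2) / sigma) |y - c|)``

With a uniform prior both densities are strictly decreasing in
``|y - c|``, so the MAP candidate is the grid point nearest the reference
ratio for either family and any ``sigma`` — which is why the Gaussian and
Laplacian variants (MAABG, MAABL) give identical estimates. Non-uniform
priors break this equivalence; the posterior machinery supports them.

Posteriors are computed in log space and normalized by log-sum-exp, so
small ``sigma`` never underflows to an all-zero posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import logsumexp

from .envelope import Envelope, amplitude_at_pressure
from .errors import GridError
from .maa import BPEstimate, FixedRatios, maa_estimate

Family = Literal["gaussian", "laplacian"]

#: default candidate-grid bounds and step
SBP_RATIO_BOUNDS = (0.65, 0.95)
DBP_RATIO_BOUNDS = (0.30, 0.60)
GRID_STEP = 0.01

#: validated range for the likelihood standard deviation
SIGMA_RANGE = (0.02, 0.20)
DEFAULT_SIGMA = 0.10

#: relative tolerance for posterior ties (ties resolve to the smaller ratio)
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class CandidateGrid:
    """Ordered, uniformly spaced candidate ratios."""

    values: np.ndarray
    step: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise GridError("grid must be a non-empty 1-D vector")
        if v.size > 1:
            d = np.diff(v)
            if np.any(d <= 0) or not np.allclose(d, self.step, rtol=0, atol=1e-9):
                raise GridError("grid values must be strictly increasing with uniform step")

    @property
    def K(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class Prior:
    """Prior probability vector over a candidate grid (sums to 1)."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0):
            raise GridError("prior probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise GridError("prior probabilities must sum to 1")


@dataclass(frozen=True)
class LikelihoodSpec:
    """Likelihood family and its standard deviation."""

    family: Family = "gaussian"
    sigma: float = DEFAULT_SIGMA
    validate_sigma: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "laplacian"):
            raise ValueError(f"unknown likelihood family {self.family!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        lo, hi = SIGMA_RANGE
        if self.validate_sigma and not lo <= self.sigma <= hi:
            raise ValueError(f"sigma {self.sigma} outside validated range {SIGMA_RANGE}")

    @property
    def method_tag(self) -> str:
        return "MAABG" if self.family == "gaussian" else "MAABL"


@dataclass(frozen=True)
class ReferenceRatio:
    """Reference ratios derived from auscultatory readings.

    ``y_s = a_s / m`` and ``y_d = a_d / m`` where ``a_s`` (``a_d``) is the
    envelope amplitude at the reference systolic (diastolic) pressure and
    ``m`` the maximum amplitude. ``ordering_violated`` flags the
    non-physiological case ``y_d >= y_s`` (not fatal).
    """

    y_s: float
    y_d: float
    a_s: float
    a_d: float
    m: float

    @property
    def ordering_violated(self) -> bool:
        return not self.y_d < self.y_s


@dataclass(frozen=True)
class Posterior:
    """Normalized posterior probabilities over a candidate grid."""

    probabilities: np.ndarray
    grid: CandidateGrid


@dataclass(frozen=True)
class RatioEstimate:
    """MAP ratio with its full posterior."""

    map_ratio: float
    posterior: Posterior
    family: Family


def make_grid(min_ratio: float, max_ratio: float, step: float = GRID_STEP) -> CandidateGrid:
    """Build a uniform candidate grid with exact endpoints.

    The span must be an integer multiple of the step (within 1e-9),
    otherwise a :class:`GridError` is raised.
    """
    if not (min_ratio < max_ratio and step > 0):
        raise GridError("need min_ratio < max_ratio and step > 0")
    span = (max_ratio - min_ratio) / step
    n = round(span)
    if abs(span - n) > 1e-9:
        raise GridError(
            f"grid bounds not commensurate with step: ({min_ratio}, {max_ratio}, {step})"
        )
    values = min_ratio + step * np.arange(n + 1)
    values[-1] = max_ratio  # exact endpoint
    return CandidateGrid(values=values, step=step)


def default_sbp_grid() -> CandidateGrid:
    return make_grid(*SBP_RATIO_BOUNDS, GRID_STEP)


def default_dbp_grid() -> CandidateGrid:
    return make_grid(*DBP_RATIO_BOUNDS, GRID_STEP)


def uniform_prior(grid: CandidateGrid) -> Prior:
    """Equal prior probability 1/K for every candidate."""
    return Prior(probabilities=np.full(grid.K, 1.0 / grid.K))


def reference_ratio(env: Envelope, nurse_sbp: float, nurse_dbp: float) -> ReferenceRatio:
    """Reference ratios from auscultatory SBP/DBP readings.

    Looks up the smoothed envelope amplitude at the reference systolic
    pressure on the systolic (higher-pressure) branch and at the reference
    diastolic pressure on the diastolic branch, then normalizes by ``m``.
    """
    a_s = amplitude_at_pressure(env, nurse_sbp, "systolic")
    a_d = amplitude_at_pressure(env, nurse_dbp, "diastolic")
    m = env.max_amplitude
    return ReferenceRatio(y_s=a_s / m, y_d=a_d / m, a_s=a_s, a_d=a_d, m=m)


def log_likelihood(y: float, candidates: np.ndarray, spec: LikelihoodSpec) -> np.ndarray:
    """Log density of the reference ratio ``y`` under each candidate."""
    dev = np.abs(y - np.asarray(candidates, dtype=float))
    s = spec.sigma
    if spec.family == "gaussian":
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (dev / s) ** 2
    return -0.5 * np.log(2.0) - np.log(s) - (np.sqrt(2.0) / s) * dev


def likelihood(y: float, candidate: float, spec: LikelihoodSpec) -> float:
    """Density of ``y`` under a single candidate ratio."""
    return float(np.exp(log_likelihood(y, np.asarray([candidate]), spec)[0]))


def posterior(y: float, grid: CandidateGrid, prior: Prior, spec: LikelihoodSpec) -> Posterior:
    """Posterior over the candidate grid given reference ratio ``y``.

    Element ``l`` is proportional to ``prior[l] * f(y | grid[l])``,
    normalized to sum to one. Computed in log space so the result is
    never all-zero even when every density underflows.
    """
    p = prior.probabilities
    if p.size != grid.K:
        raise GridError("prior length does not match grid")
    with np.errstate(divide="ignore"):
        log_post = np.log(p) + log_likelihood(y, grid.values, spec)
    log_post -= logsumexp(log_post)
    probs = np.exp(log_post)
    probs /= probs.sum()
    return Posterior(probabilities=probs, grid=grid)


def map_ratio(y: float, grid: CandidateGrid, prior: Prior | None = None,
              spec: LikelihoodSpec | None = None) -> RatioEstimate:
    """MAP candidate ratio for a reference ratio ``y``.

    Ties in the posterior (within relative tolerance 1e-9, e.g. ``y``
    exactly midway between adjacent candidates) resolve to the smaller
    candidate. A reference ratio outside the grid's range needs no
    special handling: the boundary candidate wins naturally.
    """
    if prior is None:
        prior = uniform_prior(grid)
    if spec is None:
        spec = LikelihoodSpec()
    post = posterior(y, grid, prior, spec)
    probs = post.probabilities
    p_max = probs.max()
    winners = np.nonzero(probs >= p_max * (1.0 - _TIE_RTOL))[0]
    idx = int(winners[0])  # smallest candidate among ties
    return RatioEstimate(map_ratio=float(grid.values[idx]), posterior=post, family=spec.family)


def estimate_bp_bayes(env: Envelope, ratio_s: RatioEstimate, ratio_d: RatioEstimate) -> BPEstimate:
    """SBP/DBP from MAP ratios, by the same amplitude back-mapping as the
    conventional MAA (the only mechanism that converts a ratio to mmHg).

    The method tag is MAABG for a Gaussian likelihood, MAABL for a
    Laplacian one (mixed families tag as MAAB).
    """
    if ratio_s.family == ratio_d.family:
        tag = "MAABG" if ratio_s.family == "gaussian" else "MAABL"
    else:
        tag = "MAAB"
    ratios = FixedRatios(r_s=ratio_s.map_ratio, r_d=ratio_d.map_ratio)
    return maa_estimate(env, ratios, method=tag)
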