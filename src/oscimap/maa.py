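"""Conventional maximum-amplitude algorithm (MAA).

The MAA takes the cuff pressure at the envelope's maximum oscillation as
the mean arterial pressure, multiplies the maximum amplitude ``m`` by
fixed systolic and diastolic ratios to get target amplitudes
``S_a = m * r_s`` and ``d_a = m * r_d``, and maps those amplitudes back to
the deflation curve: the systolic pressure is where the higher-pressure
branch of the envelope crosses ``S_a``, the diastolic where the
lower-pressure branch crosses ``d_a``. The classical fixed ratios are
0.70 (systolic) and 0.45 (diastolic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .envelope import Envelope, amplitude_to_pressure
from .errors import EnvelopeError

#: classical fixed systolic/diastolic amplitude ratios
DEFAULT_SYSTOLIC_RATIO = 0.70
DEFAULT_DIASTOLIC_RATIO = 0.45

#: validated production range for either ratio
RATIO_RANGE = (0.3, 0.99)


@dataclass(frozen=True)
class FixedRatios:
    """A (systolic, diastolic) ratio pair, ``0 < r_d <= r_s <= 1``.

    Ratios of exactly 1 collapse both targets onto the apex and are only
    meaningful for the degenerate identity ``sbp = dbp = map_pressure``;
    values outside [0.3, 0.99] trigger a warning.
    """

    r_s: float = DEFAULT_SYSTOLIC_RATIO
    r_d: float = DEFAULT_DIASTOLIC_RATIO

    def __post_init__(self) -> None:
        if not (0 < self.r_d <= self.r_s <= 1):
            raise ValueError(f"need 0 < r_d <= r_s <= 1, got ({self.r_s}, {self.r_d})")
        lo, hi = RATIO_RANGE
        if self.r_s != 1.0 and not (lo <= self.r_d and self.r_s <= hi):
            warnings.warn(
                f"ratios ({self.r_s}, {self.r_d}) outside validated range {RATIO_RANGE}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BPEstimate:
    """A systolic/diastolic/mean pressure triple with its provenance."""

    sbp: float
    dbp: float
    map_pressure: float
    method: str  # MAA | MAABG | MAABL
    ratios_used: tuple[float, float]
    systolic_amplitude: float
    diastolic_amplitude: float


def maa_estimate(env: Envelope, ratios: FixedRatios | None = None, method: str = "MAA") -> BPEstimate:
    """Estimate SBP/DBP from an envelope with fixed amplitude ratios.

    Raises
    ------
    EnvelopeError
        If the envelope is degenerate or a branch never reaches the
        ratio-scaled target amplitude.
    """
    if ratios is None:
        ratios = FixedRatios()
    if env.degenerate:
        raise EnvelopeError("envelope does not support ratio: degenerate envelope (maximum on boundary)")
    m = env.max_amplitude
    s_a = m * ratios.r_s
    d_a = m * ratios.r_d
    try:
        sbp = amplitude_to_pressure(env, s_a, "systolic")
        dbp = amplitude_to_pressure(env, d_a, "diastolic")
    except EnvelopeError as exc:
        raise EnvelopeError(f"envelope does not support ratio: {exc}") from exc
    return BPEstimate(
        sbp=sbp,
        dbp=dbp,
        map_pressure=env.pressure_at_max,
        method=method,
        ratios_used=(ratios.r_s, ratios.r_d),
        systolic_amplitude=s_a,
        diastolic_amplitude=d_a,
    )
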