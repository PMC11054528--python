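"""Retention-to-index arithmetic for fast-gradient biomimetic chromatography.

The Chromatographic Hydrophobicity Index (CHI) is obtained by linearly
calibrating gradient retention times against reference standards whose CHI
values are known; the same machinery serves the C18, IAM and HSA systems.
This module covers:

* calibration-line fitting and application (extrapolation beyond the
  nominal 0-100 CHI scale is allowed but flagged),
* the CHI -> CHI LogP conversion (0.054*CHI - 1.467, measured on the
  nonionized form, here the pH 10.6 run for organic bases),
* the %HSA <-> logK_HSA plasma-protein-binding transform
  logK = log10(pct / (101 - pct)), the 101-denominator form used in
  biomimetic HSA chromatography (verified to reproduce the bundled table
  to 2 decimals, where a 100-denominator variant misses high binders),
* acid/base character calls from the multi-pH CHI profile: ionization
  suppresses reversed-phase retention, so a base shows depressed CHI at
  acidic pH and an acid depressed CHI at basic pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from scipy import stats

from ._util import round_half_away
from .datasets import CHI_LOGP_INTERCEPT, CHI_LOGP_SLOPE

__all__ = [
    "CalibrationLine",
    "CalibratedIndex",
    "AcidBaseCall",
    "CalibrationError",
    "fit_calibration",
    "apply_calibration",
    "chi_to_chilogp",
    "pct_hsa_to_logk",
    "logk_to_pct_hsa",
    "format_pct_hsa",
    "classify_acid_base",
]

#: %HSA values above this bound are reported censored (">99.8").
PCT_HSA_CENSOR_BOUND = 99.8


class CalibrationError(ValueError):
    """Calibration standards are insufficient or degenerate."""


@dataclass(frozen=True)
class CalibrationLine:
    """Fitted linear map from gradient retention time (min) to an index."""

    slope: float  # index units per minute
    intercept: float  # index units
    r_squared: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise CalibrationError("a calibration line needs at least 2 standards")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationError(f"r_squared {self.r_squared} outside [0, 1]")


class CalibratedIndex(NamedTuple):
    value: float
    extrapolated: bool  # outside the nominal index scale


def fit_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationLine:
    """Ordinary least squares of literature index on retention time.

    ``standards`` is a sequence of ``(retention_time_min, literature_index)``
    pairs; at least two distinct retention times are required.
    """
    if len(standards) < 2:
        raise CalibrationError("need at least 2 calibration standards")
    t = [float(s[0]) for s in standards]
    y = [float(s[1]) for s in standards]
    if len(set(t)) == 1:
        raise CalibrationError("all retention times identical; slope undefined")
    res = stats.linregress(t, y)
    r2 = 1.0 if math.isnan(res.rvalue) else float(res.rvalue) ** 2
    return CalibrationLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_standards=len(standards),
    )


def apply_calibration(
    line: CalibrationLine,
    retention_time_min: float,
    scale_range: tuple[float, float] = (0.0, 100.0),
) -> CalibratedIndex:
    """Map a retention time through the calibration line.

    Extrapolation beyond ``scale_range`` is permitted (high-lipophilicity
    analytes routinely exceed CHI 100) but flagged in the result.
    """
    if retention_time_min < 0:
        raise ValueError(f"negative retention time: {retention_time_min}")
    value = line.slope * retention_time_min + line.intercept
    lo, hi = scale_range
    return CalibratedIndex(value=value, extrapolated=not (lo <= value <= hi))


def chi_to_chilogp(chi: float, rounded: bool = False) -> float:
    """Convert CHI (nonionized form) to the octanol/water CHI LogP scale.

    With ``rounded=True`` the result is rounded to 2 decimals (half away
    from zero) for table reproduction.
    """
    if not math.isfinite(chi):
        raise ValueError(f"CHI must be finite, got {chi}")
    value = CHI_LOGP_SLOPE * chi + CHI_LOGP_INTERCEPT
    return round_half_away(value, 2) if rounded else value


def pct_hsa_to_logk(pct_hsa: float, rounded: bool = False) -> float:
    """logK_HSA from percent HSA binding: log10(pct / (101 - pct))."""
    if not 0.0 < pct_hsa < 101.0:
        raise ValueError(f"%HSA must lie in (0, 101), got {pct_hsa}")
    value = math.log10(pct_hsa / (101.0 - pct_hsa))
    return round_half_away(value, 2) if rounded else value


def logk_to_pct_hsa(logk: float) -> float:
    """Percent HSA binding from logK_HSA: 101*10^logk / (1 + 10^logk).

    Exact inverse of :func:`pct_hsa_to_logk` on (0, 101); note the result
    can exceed 100 for strong binders — see :func:`format_pct_hsa`.
    """
    if not math.isfinite(logk):
        raise ValueError(f"logK must be finite, got {logk}")
    k = 10.0**logk
    return 101.0 * k / (1.0 + k)


def format_pct_hsa(pct: float, censor_bound: float = PCT_HSA_CENSOR_BOUND) -> str:
    """Report a %HSA value, censoring strong binders as ``>99.8``.

    Chromatographic %HSA above ~99.8 (and in particular above 100, which the
    101-denominator transform can produce) is not quantitatively meaningful
    and is reported as a bound, as published tables do.
    """
    if pct > censor_bound:
        return f">{censor_bound}"
    return f"{round_half_away(pct, 2):.2f}"


@dataclass(frozen=True)
class AcidBaseCall:
    """Acid/base character inferred from CHI at pH 2.6 / 7.4 / 10.6.

    ``delta_low``  = CHI(7.4) - CHI(2.6): positive when acidic-pH retention
    is suppressed (ionized base). ``delta_high`` = CHI(10.6) - CHI(7.4):
    negative when basic-pH retention is suppressed (ionized acid).
    ``ambiguous`` marks profiles suppressed at both ends (zwitterionic
    pattern), where the dominant suppression decides the call.
    """

    call: str  # "acidic" | "basic" | "neutral"
    delta_low: float
    delta_high: float
    ambiguous: bool = False


def classify_acid_base(
    chi_acid: float,
    chi_neutral: float,
    chi_basic: float,
    threshold: float = 10.0,
) -> AcidBaseCall:
    """Call acid/base character from the three-pH CHI profile.

    A compound is *basic* when its CHI at pH 2.6 is suppressed relative to
    pH 7.4 by more than ``threshold`` CHI units while pH 10.6 shows no such
    suppression (a further CHI rise from pH 7.4 to 10.6 — a strong base
    still partly ionized at 7.4 — also counts as basic). *Acidic* is the
    mirrored pattern; *neutral* when neither end is suppressed. If both
    ends are suppressed the dominant suppression decides and the call is
    flagged ambiguous. The default threshold of 10 CHI units is a
    configurable convention; the underlying protocol gives no number.
    """
    for name, v in [("chi_acid", chi_acid), ("chi_neutral", chi_neutral), ("chi_basic", chi_basic)]:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    suppression_acid_end = chi_neutral - chi_acid  # > 0: base-like
    suppression_basic_end = chi_neutral - chi_basic  # > 0: acid-like
    delta_low = suppression_acid_end
    delta_high = chi_basic - chi_neutral

    base_like = suppression_acid_end > threshold
    acid_like = suppression_basic_end > threshold
    if base_like and acid_like:
        call = "basic" if suppression_acid_end >= suppression_basic_end else "acidic"
        return AcidBaseCall(call, delta_low, delta_high, ambiguous=True)
    if base_like:
        return AcidBaseCall("basic", delta_low, delta_high)
    if acid_like:
        return AcidBaseCall("acidic", delta_low, delta_high)
    return AcidBaseCall("neutral", delta_low, delta_high)
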