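"""Decision-Factor / Global-Risk fusion of the two risk engines.

The Global Risk RG fuses the Technical Risk RT and Expert Risk RE via a
Decision Factor f(RT, RE) that weights the expert's judgment as a function
of the technical evidence:

    RG(RT, RE) = RT * f(RT, RE) / 10,  clamped at 100.

The Decision-Factor surface is piecewise in RT around a zone boundary
(default 50):

* exponential zone (RT <= 50):  f = f1(RT)^(RE - f2(RT)) + 10, so the factor
  stays near its floor until RE reaches a fast-growth region whose location
  and steepness depend on RT;
* logarithmic zone (RT > 50):   f = f3(RT)*ln(RE) + f4(RT), which rises
  quickly at low RE and then saturates — high Global Risk is reachable with
  low Expert Risk when the technical evidence dominates.

The shipped coefficient functions were fitted by generalized reduced
gradient and are used as-is:

    f1(RT) = -0.0015*RT + 1.1391
    f2(RT) = -0.0085*RT^2 + 0.5092*RT + 57.247
    f3(RT) = 215.3 * RT^-1.005
    f4(RT) = -0.0048*RT + 0.7849

Two first-level corrections let the expert reshape the Decision Factor on a
chosen interval (a chord interpolation in the exponential zone; a certainty
rescaling in the logarithmic zone), and a second-level sigmoidal correction
smooths the Global-Risk surface across the zone boundary.  All surfaces are
evaluated lazily from the closed forms, so corrections compose without
interpolation error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .engines import RiskScore

__all__ = [
    "DecisionFactorModel",
    "ExpCorrectionSpec",
    "LogCorrectionSpec",
    "SigmoidCorrectionSpec",
    "FusionResult",
    "decision_factor",
    "global_risk",
    "correct_exponential",
    "correct_logarithmic",
    "correct_sigmoidal",
    "fuse",
]

logger = logging.getLogger(__name__)


def _as_value(risk: "RiskScore | float") -> float:
    value = float(risk)
    if not 10.0 <= value <= 100.0:
        raise ValueError(f"risk value {value} outside [10, 100]")
    return value


@dataclass(frozen=True)
class DecisionFactorModel:
    """Coefficient functions and zone boundary of the Decision-Factor surface.

    ``exp_f1``/``exp_f2`` hold the polynomial coefficients (highest degree
    first) of the exponential-zone base and shift functions; ``log_f3`` is
    ``(amplitude, exponent)`` of the power-law gain and ``log_f4`` the linear
    offset of the logarithmic zone.  Values of RT at exactly the zone
    boundary use the exponential branch.
    """

    zone_boundary: float = 50.0
    exp_f1: tuple[float, float] = (-0.0015, 1.1391)
    exp_f2: tuple[float, float, float] = (-0.0085, 0.5092, 57.247)
    log_f3: tuple[float, float] = (215.3, -1.005)
    log_f4: tuple[float, float] = (-0.0048, 0.7849)
    df_floor: float = 10.0

    def f1(self, rt: float) -> float:
        return self.exp_f1[0] * rt + self.exp_f1[1]

    def f2(self, rt: float) -> float:
        return self.exp_f2[0] * rt**2 + self.exp_f2[1] * rt + self.exp_f2[2]

    def f3(self, rt: float) -> float:
        return self.log_f3[0] * rt ** self.log_f3[1]

    def f4(self, rt: float) -> float:
        return self.log_f4[0] * rt + self.log_f4[1]


@dataclass(frozen=True)
class ExpCorrectionSpec:
    """Chord-interpolation correction on an Expert-Risk interval (exp zone).

    The expert picks an RE interval [re_lo, re_hi] and two weights
    c1 + c2 = 1.  d1 is the gap from the Decision Factor up to the chord g
    through the interval endpoints (radical correction); d2 the gap down to
    the constant h = f at the lower endpoint (mild correction).
    """

    re_lo: float
    re_hi: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not 10.0 <= self.re_lo < self.re_hi <= 100.0:
            raise ValueError(
                f"correction interval must satisfy 10 <= re_lo < re_hi <= 100, "
                f"got [{self.re_lo}, {self.re_hi}]"
            )
        if self.c1 < 0 or self.c2 < 0 or not math.isclose(self.c1 + self.c2, 1.0):
            raise ValueError(f"weights must be nonnegative with c1 + c2 = 1, got {self.c1}, {self.c2}")


@dataclass(frozen=True)
class LogCorrectionSpec:
    """Certainty rescaling in the logarithmic zone.

    When the relative gap between RT and RG exceeds ``deviation_threshold``,
    the expert is asked for a certainty level (``security``, a percentage);
    the Decision Factor is scaled by 100/security, so full certainty leaves
    it unchanged and lower certainty inflates it, counteracting potential
    expert under-valuations.
    """

    deviation_threshold: float = 0.20
    security: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.security <= 100.0:
            raise ValueError(f"security must lie in (0, 100], got {self.security}")
        if self.deviation_threshold < 0:
            raise ValueError("deviation_threshold must be nonnegative")


@dataclass(frozen=True)
class SigmoidCorrectionSpec:
    """Sigmoidal blending of the Global-Risk surface across the zone boundary.

    The correction interval [rt1, rt2] must contain the zone boundary and is
    constrained to [25, 75] so the blended surface cannot drift away from the
    behavior established by the two zone models; ``b`` opens or closes the
    sigmoid along the Technical-Risk axis.
    """

    rt1: float
    rt2: float
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.rt1 < 25.0:
            raise ValueError(f"rt1 cannot be smaller than 25, got {self.rt1}")
        if self.rt2 > 75.0:
            raise ValueError(f"rt2 cannot be higher than 75, got {self.rt2}")
        if not self.rt1 < self.rt2:
            raise ValueError(f"need rt1 < rt2, got [{self.rt1}, {self.rt2}]")
        if self.b <= 0:
            raise ValueError(f"steepness b must be positive, got {self.b}")


def decision_factor(
    rt: "RiskScore | float",
    re: "RiskScore | float",
    model: DecisionFactorModel | None = None,
) -> float:
    """Decision Factor f(RT, RE): exponential branch for RT up to the zone
    boundary (inclusive), logarithmic branch above it."""
    model = model or DecisionFactorModel()
    rt, re = _as_value(rt), _as_value(re)
    if rt <= model.zone_boundary:
        return model.f1(rt) ** (re - model.f2(rt)) + model.df_floor
    return model.f3(rt) * math.log(re) + model.f4(rt)


def global_risk(rt: "RiskScore | float", df: float) -> RiskScore:
    """Global Risk RG = RT * DF / 10, clamped at 100."""
    rt = _as_value(rt)
    if df < 0:
        raise ValueError(f"Decision Factor must be nonnegative, got {df}")
    return RiskScore(value=min(rt * df / 10.0, 100.0), kind="global")


def correct_exponential(
    rt: "RiskScore | float",
    re: "RiskScore | float",
    model: DecisionFactorModel | None = None,
    spec: ExpCorrectionSpec | None = None,
) -> float:
    """First-level correction in the exponential zone.

    Returns the corrected Decision Factor; outside the correction interval
    the correction is not applied and the uncorrected value is returned.
    The corrected value is capped at the chord g(RE), the stated upper limit.
    """
    model = model or DecisionFactorModel()
    rt, re = _as_value(rt), _as_value(re)
    if rt > model.zone_boundary:
        raise ValueError(
            f"exponential-zone correction requires RT <= {model.zone_boundary}, got {rt}"
        )
    f = decision_factor(rt, re, model)
    if spec is None:
        return f
    if not spec.re_lo <= re <= spec.re_hi:
        logger.info(
            "RE=%.2f outside correction interval [%.2f, %.2f]; correction not applied",
            re, spec.re_lo, spec.re_hi,
        )
        return f
    f_lo = decision_factor(rt, spec.re_lo, model)
    f_hi = decision_factor(rt, spec.re_hi, model)
    g = f_lo + (f_hi - f_lo) * (re - spec.re_lo) / (spec.re_hi - spec.re_lo)
    h = f_lo
    d1 = g - f
    d2 = f - h
    corrected = f + spec.c1 * d1 + spec.c2 * d2
    return min(corrected, g)


def correct_logarithmic(
    rt: "RiskScore | float",
    rg: "RiskScore | float",
    df: float,
    spec: LogCorrectionSpec,
    zone_boundary: float = 50.0,
) -> float:
    """First-level correction in the logarithmic zone.

    If the relative deviation (RT - RG)/RT exceeds the threshold, the
    Decision Factor is rescaled by 100/security; the downstream RG clamp at
    100 still applies.  Otherwise the Decision Factor is returned unchanged.
    """
    rt = _as_value(rt)
    rg = float(rg)
    if rt <= zone_boundary:
        raise ValueError(
            f"logarithmic-zone correction requires RT > {zone_boundary}, got {rt}"
        )
    if (rt - rg) / rt > spec.deviation_threshold:
        return df * 100.0 / spec.security
    return df


def correct_sigmoidal(
    rg_surface,
    spec: SigmoidCorrectionSpec,
    rtj: float,
    rei: float,
    zone_boundary: float = 50.0,
) -> float:
    """Second-level correction: sigmoidal blend of RG between RT1 and RT2.

    ``rg_surface(rt, re)`` must return the (possibly first-level-corrected)
    Global Risk; the corrected value interpolates between the surface values
    at the interval endpoints along a logistic curve in RT.
    """
    if not spec.rt1 <= zone_boundary <= spec.rt2:
        raise ValueError(
            f"zone boundary {zone_boundary} must lie inside [{spec.rt1}, {spec.rt2}]"
        )
    if not spec.rt1 <= rtj <= spec.rt2:
        raise ValueError(f"RTj={rtj} outside correction interval [{spec.rt1}, {spec.rt2}]")
    rg1 = float(rg_surface(spec.rt1, rei))
    rg2 = float(rg_surface(spec.rt2, rei))
    mid = (spec.rt1 + spec.rt2) / 2.0
    return rg1 + (rg2 - rg1) / (1.0 + math.exp(-spec.b * (rtj - mid)))


@dataclass(frozen=True)
class FusionResult:
    """Outcome of fusing one (RT, RE) pair, with an audit of corrections."""

    rt: float
    re: float
    df: float
    df_corrected: float
    rg: float
    rg_corrected: float
    corrections_applied: tuple[str, ...] = field(default_factory=tuple)


def fuse(
    rt: "RiskScore | float",
    re: "RiskScore | float",
    model: DecisionFactorModel | None = None,
    exp_correction: ExpCorrectionSpec | None = None,
    log_correction: LogCorrectionSpec | None = None,
    sigmoid_correction: SigmoidCorrectionSpec | None = None,
) -> FusionResult:
    """Full fusion pipeline in application order.

    Decision Factor, then the zone-appropriate first-level correction, then
    Global Risk (clamped at 100), then the sigmoidal second-level correction
    when RT falls inside its interval.  Records which corrections changed
    the result.
    """
    model = model or DecisionFactorModel()
    rt, re = _as_value(rt), _as_value(re)
    applied: list[str] = []

    def corrected_df(rt_: float, re_: float) -> float:
        df_ = decision_factor(rt_, re_, model)
        if rt_ <= model.zone_boundary:
            if exp_correction is not None:
                df_ = correct_exponential(rt_, re_, model, exp_correction)
        elif log_correction is not None:
            rg_ = global_risk(rt_, df_).value
            df_ = correct_logarithmic(rt_, rg_, df_, log_correction, model.zone_boundary)
        return df_

    df = decision_factor(rt, re, model)
    df_corr = corrected_df(rt, re)
    if df_corr != df:
        applied.append("exponential" if rt <= model.zone_boundary else "logarithmic")
    rg = global_risk(rt, df_corr).value

    rg_corr = rg
    if sigmoid_correction is not None and sigmoid_correction.rt1 <= rt <= sigmoid_correction.rt2:
        surface = lambda t, e: global_risk(t, corrected_df(t, e)).value
        rg_corr = correct_sigmoidal(
            surface, sigmoid_correction, rt, re, model.zone_boundary
        )
        applied.append("sigmoidal")

    return FusionResult(
        rt=rt,
        re=re,
        df=df,
        df_corrected=df_corr,
        rg=rg,
        rg_corrected=rg_corr,
        corrections_applied=tuple(applied),
    )
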