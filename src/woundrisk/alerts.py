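"""Alert banding, manual override and whole-case orchestration.

The Global Risk is mapped onto three mutually exclusive recommendation
states with half-open bands (the last band closed at 100):

* ``continue``              — RG in [0, 60)
* ``evaluate_alternatives`` — RG in [60, 80)
* ``change_immediately``    — RG in [80, 100]

Thresholds are reconfigurable at any time; a generic band helper supports a
different number of intervals.  The healthcare team can always override the
computed alert, which is recorded in the report's audit trail.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

from . import fusion as _fusion
from . import imaging as _imaging
from .engines import (
    BradenAssessment,
    ExpertAssessment,
    RiskScore,
    compute_expert_risk,
    compute_technical_risk,
    load_default_config,
)
from .fuzzy import FuzzyEngineConfig

__all__ = [
    "CONTINUE",
    "EVALUATE_ALTERNATIVES",
    "CHANGE_IMMEDIATELY",
    "AlertThresholds",
    "CaseInputs",
    "CaseReport",
    "PipelineConfig",
    "classify_alert",
    "classify_bands",
    "override_alert",
    "run_case",
]

CONTINUE = "continue"
EVALUATE_ALTERNATIVES = "evaluate_alternatives"
CHANGE_IMMEDIATELY = "change_immediately"
ALERT_LEVELS = (CONTINUE, EVALUATE_ALTERNATIVES, CHANGE_IMMEDIATELY)


@dataclass(frozen=True)
class AlertThresholds:
    """Upper bounds of the first two bands; bands are left-closed/right-open,
    the final band closed at 100."""

    continue_upper: float = 60.0
    evaluate_upper: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 < self.continue_upper < self.evaluate_upper <= 100.0:
            raise ValueError(
                f"need 0 < continue_upper < evaluate_upper <= 100, got "
                f"({self.continue_upper}, {self.evaluate_upper})"
            )


def classify_bands(value: float, cuts: Sequence[float], labels: Sequence[str]) -> str:
    """Generic half-open band lookup over [0, 100].

    ``cuts`` are the interior band boundaries in increasing order and must
    have one element fewer than ``labels``.  Band i is [cut_{i-1}, cut_i),
    except the last, which is closed at 100.
    """
    if len(labels) != len(cuts) + 1:
        raise ValueError("need exactly one more label than interior cut")
    if list(cuts) != sorted(set(cuts)):
        raise ValueError("cuts must be strictly increasing")
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"value {value} outside [0, 100]")
    for cut, label in zip(cuts, labels):
        if value < cut:
            return label
    return labels[-1]


def classify_alert(rg: "RiskScore | float", thresholds: AlertThresholds | None = None) -> str:
    """Map a Global Risk value to exactly one alert level."""
    thresholds = thresholds or AlertThresholds()
    return classify_bands(
        float(rg),
        (thresholds.continue_upper, thresholds.evaluate_upper),
        ALERT_LEVELS,
    )


@dataclass
class CaseReport:
    """Fused risks, alert level and an append-only audit trail for one case."""

    patient_id: str
    date_ref: _dt.date | None
    date_now: _dt.date | None
    rt: float
    re: float
    df: float
    df_corrected: float
    rg: float
    rg_corrected: float
    alert: str
    overridden: bool = False
    corrections_applied: tuple[str, ...] = ()
    audit: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["date_ref"] = self.date_ref.isoformat() if self.date_ref else None
        d["date_now"] = self.date_now.isoformat() if self.date_now else None
        d["corrections_applied"] = list(self.corrections_applied)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def csv_row(self) -> str:
        return ",".join(
            str(v)
            for v in (
                self.patient_id,
                self.date_ref.isoformat() if self.date_ref else "",
                self.date_now.isoformat() if self.date_now else "",
                f"{self.rt:.2f}",
                f"{self.re:.2f}",
                f"{self.df:.2f}",
                f"{self.df_corrected:.2f}",
                f"{self.rg:.2f}",
                f"{self.rg_corrected:.2f}",
                self.alert,
                self.overridden,
            )
        )


def override_alert(report: CaseReport, level: str, reason: str) -> CaseReport:
    """Manually replace the alert level, recording the reason in the audit."""
    if level not in ALERT_LEVELS:
        raise ValueError(f"unknown alert level {level!r}; valid: {ALERT_LEVELS}")
    if not reason or not reason.strip():
        raise ValueError("an override requires a non-empty reason")
    report.audit.append(
        f"override: {report.alert} -> {level} (reason: {reason.strip()})"
    )
    report.alert = level
    report.overridden = True
    return report


@dataclass
class PipelineConfig:
    """Everything configurable about a case run: engines, fusion model,
    corrections and alert thresholds."""

    technical_config: FuzzyEngineConfig | None = None
    expert_config: FuzzyEngineConfig | None = None
    model: _fusion.DecisionFactorModel = field(default_factory=_fusion.DecisionFactorModel)
    exp_correction: _fusion.ExpCorrectionSpec | None = None
    log_correction: _fusion.LogCorrectionSpec | None = None
    sigmoid_correction: _fusion.SigmoidCorrectionSpec | None = None
    thresholds: AlertThresholds = field(default_factory=AlertThresholds)
    sensitivity: float = 0.15
    n_filters: int = 5

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        kwargs: dict = {}
        if "technical_config" in data:
            kwargs["technical_config"] = FuzzyEngineConfig.from_dict(data["technical_config"])
        if "expert_config" in data:
            kwargs["expert_config"] = FuzzyEngineConfig.from_dict(data["expert_config"])
        if "model" in data:
            m = data["model"]
            kwargs["model"] = _fusion.DecisionFactorModel(
                zone_boundary=float(m.get("zone_boundary", 50.0)),
                exp_f1=tuple(m.get("exp_f1", (-0.0015, 1.1391))),
                exp_f2=tuple(m.get("exp_f2", (-0.0085, 0.5092, 57.247))),
                log_f3=tuple(m.get("log_f3", (215.3, -1.005))),
                log_f4=tuple(m.get("log_f4", (-0.0048, 0.7849))),
                df_floor=float(m.get("df_floor", 10.0)),
            )
        if "exp_correction" in data:
            kwargs["exp_correction"] = _fusion.ExpCorrectionSpec(**data["exp_correction"])
        if "log_correction" in data:
            kwargs["log_correction"] = _fusion.LogCorrectionSpec(**data["log_correction"])
        if "sigmoid_correction" in data:
            kwargs["sigmoid_correction"] = _fusion.SigmoidCorrectionSpec(**data["sigmoid_correction"])
        if "thresholds" in data:
            kwargs["thresholds"] = AlertThresholds(**data["thresholds"])
        for key in ("sensitivity", "n_filters"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)


@dataclass
class CaseInputs:
    """Inputs for one case: clinical scores plus either two dated images or
    precomputed wound areas (cm^2) with their dates."""

    braden: BradenAssessment
    expert: ExpertAssessment
    patient_id: str = "anonymous"
    # precomputed route
    area_ref_cm2: float | None = None
    area_now_cm2: float | None = None
    date_ref: _dt.date | None = None
    date_now: _dt.date | None = None
    # image route
    image_ref: _imaging.WoundImage | None = None
    image_now: _imaging.WoundImage | None = None
    wound_seed_ref: tuple[int, int] | None = None
    wound_seed_now: tuple[int, int] | None = None
    marker_ref: _imaging.ReferenceMarker | None = None
    marker_now: _imaging.ReferenceMarker | None = None
    # direct risk injection (skips the engines)
    rt_override: float | None = None
    re_override: float | None = None


def _resolve_area_change(inputs: CaseInputs, config: PipelineConfig, audit: list[str]) -> _imaging.AreaChange:
    if inputs.image_ref is not None and inputs.image_now is not None:
        seg_ref = _imaging.measure_wound(
            inputs.image_ref, inputs.wound_seed_ref, inputs.marker_ref,
            sensitivity=config.sensitivity, n_filters=config.n_filters,
        )
        seg_now = _imaging.measure_wound(
            inputs.image_now, inputs.wound_seed_now, inputs.marker_now,
            sensitivity=config.sensitivity, n_filters=config.n_filters,
        )
        audit.append(
            f"imaging: areas {seg_ref.physical_area_cm2:.2f} -> "
            f"{seg_now.physical_area_cm2:.2f} cm2"
        )
        return _imaging.area_change_rate(
            seg_ref, inputs.image_ref.capture_date, seg_now, inputs.image_now.capture_date
        )
    if inputs.area_ref_cm2 is None or inputs.area_now_cm2 is None:
        raise ValueError("case needs either two images or two precomputed areas")
    if inputs.date_ref is None or inputs.date_now is None:
        raise ValueError("precomputed areas need their capture dates")
    days = (inputs.date_now - inputs.date_ref).days
    if days <= 0:
        raise ValueError("date_now must be strictly later than date_ref")
    audit.append(
        f"areas: precomputed {inputs.area_ref_cm2:.2f} -> {inputs.area_now_cm2:.2f} cm2"
    )
    return _imaging.AreaChange(
        area_ref_cm2=inputs.area_ref_cm2,
        area_now_cm2=inputs.area_now_cm2,
        days_elapsed=float(days),
    )


def run_case(config: PipelineConfig, inputs: CaseInputs) -> CaseReport:
    """Full pipeline: imaging -> risk engines -> fusion -> alert.

    Deterministic given fixed inputs and configuration.  ``rt_override`` /
    ``re_override`` bypass the corresponding engine (the audit records it).
    """
    audit: list[str] = []

    if inputs.rt_override is not None:
        rt = float(inputs.rt_override)
        audit.append(f"technical risk injected: {rt:.2f}")
        date_ref, date_now = inputs.date_ref, inputs.date_now
    else:
        try:
            change = _resolve_area_change(inputs, config, audit)
        except Exception as exc:
            raise RuntimeError(f"[imaging] {exc}") from exc
        date_ref = inputs.date_ref or (inputs.image_ref.capture_date if inputs.image_ref else None)
        date_now = inputs.date_now or (inputs.image_now.capture_date if inputs.image_now else None)
        try:
            rt = compute_technical_risk(
                inputs.braden.total,
                change.rate_pct,
                config.technical_config or load_default_config("technical"),
            ).value
        except Exception as exc:
            raise RuntimeError(f"[technical-engine] {exc}") from exc
        audit.append(
            f"technical risk {rt:.2f} (Braden {inputs.braden.total}, "
            f"rate {change.rate_pct:+.3f} %/day)"
        )

    if inputs.re_override is not None:
        re = float(inputs.re_override)
        audit.append(f"expert risk injected: {re:.2f}")
    else:
        try:
            re = compute_expert_risk(
                inputs.expert, config.expert_config or load_default_config("expert")
            ).value
        except Exception as exc:
            raise RuntimeError(f"[expert-engine] {exc}") from exc
        audit.append(f"expert risk {re:.2f}")

    try:
        result = _fusion.fuse(
            rt,
            re,
            model=config.model,
            exp_correction=config.exp_correction,
            log_correction=config.log_correction,
            sigmoid_correction=config.sigmoid_correction,
        )
    except Exception as exc:
        raise RuntimeError(f"[fusion] {exc}") from exc
    audit.append(
        f"fusion: df {result.df:.2f} -> {result.df_corrected:.2f}, "
        f"rg {result.rg:.2f} -> {result.rg_corrected:.2f} "
        f"(corrections: {', '.join(result.corrections_applied) or 'none'})"
    )

    try:
        alert = classify_alert(result.rg_corrected, config.thresholds)
    except Exception as exc:
        raise RuntimeError(f"[alerts] {exc}") from exc
    audit.append(f"alert: {alert}")

    return CaseReport(
        patient_id=inputs.patient_id,
        date_ref=date_ref,
        date_now=date_now,
        rt=rt,
        re=re,
        df=result.df,
        df_corrected=result.df_corrected,
        rg=result.rg,
        rg_corrected=result.rg_corrected,
        alert=alert,
        corrections_applied=result.corrections_applied,
        audit=audit,
    )
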