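"""Clinical risk engines: Technical Risk and Expert Risk.

Two Mamdani engines run concurrently.  The technical engine consumes
quantitative evidence — the Braden-scale total and the wound-area change
rate — and the expert engine consumes three qualitative 0-10 ratings from
the wound specialist.  Both produce a crisp risk score on [10, 100].

The default engine configurations live in ``woundrisk/configs/`` as YAML and
can be replaced wholesale; see :func:`load_default_config`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .fuzzy import FuzzyEngineConfig, infer

__all__ = [
    "BradenAssessment",
    "ExpertAssessment",
    "RiskScore",
    "braden_total",
    "load_default_config",
    "compute_technical_risk",
    "compute_expert_risk",
]

#: Canonical worked case shipped with the package: a high-age patient with
#: reduced mobility and treated diabetes, whose wound shrank from 10 cm^2 to
#: 7 cm^2 over 30 days (-1% of the reference area per day).  The default
#: engine configs are calibrated so this case yields Technical Risk 40 and
#: Expert Risk 70.
WORKED_CASE = {
    "braden": (2, 3, 1, 2, 4, 2),  # total 14
    "area_cm2": (10.0, 7.0),
    "days": 30,
    "expert": (3.0, 8.0, 4.0),
}

_BRADEN_RANGES = {
    "sensory_perception": (1, 4),
    "moisture": (1, 4),
    "activity": (1, 4),
    "mobility": (1, 4),
    "nutrition": (1, 4),
    "friction_shear": (1, 3),
}


@dataclass(frozen=True)
class BradenAssessment:
    """Braden pressure-ulcer risk scale: six subscales, total in [6, 23].

    Lower totals indicate higher risk of pressure-ulcer formation.
    """

    sensory_perception: int
    moisture: int
    activity: int
    mobility: int
    nutrition: int
    friction_shear: int

    def __post_init__(self) -> None:
        for field, (lo, hi) in _BRADEN_RANGES.items():
            value = getattr(self, field)
            if not isinstance(value, int) or not lo <= value <= hi:
                raise ValueError(
                    f"Braden subscale {field!r} must be an integer in "
                    f"[{lo}, {hi}], got {value!r}"
                )

    @property
    def total(self) -> int:
        return (
            self.sensory_perception
            + self.moisture
            + self.activity
            + self.mobility
            + self.nutrition
            + self.friction_shear
        )


@dataclass(frozen=True)
class ExpertAssessment:
    """The wound expert's three qualitative ratings, each on [0, 10]."""

    image_evaluation: float
    health_history: float
    other_risk_factors: float

    def __post_init__(self) -> None:
        for field in ("image_evaluation", "health_history", "other_risk_factors"):
            value = getattr(self, field)
            if not 0.0 <= value <= 10.0:
                raise ValueError(
                    f"expert rating {field!r} must lie in [0, 10], got {value!r}"
                )


@dataclass(frozen=True)
class RiskScore:
    """A crisp risk value on the [10, 100] scale.

    Engine outputs (technical, expert) are bounded below by 10; the fused
    global score is only required to lie in [0, 100] since the alert bands
    start at 0.
    """

    value: float
    kind: str  # technical | expert | global

    def __post_init__(self) -> None:
        if self.kind not in ("technical", "expert", "global"):
            raise ValueError(f"unknown risk kind {self.kind!r}")
        lo = 0.0 if self.kind == "global" else 10.0
        if not lo <= self.value <= 100.0:
            raise ValueError(f"risk value {self.value} outside [{lo:g}, 100]")

    def __float__(self) -> float:
        return self.value


def braden_total(assessment: BradenAssessment) -> int:
    """Arithmetic sum of the six Braden subscales, in [6, 23]."""
    return assessment.total


def load_default_config(which: str) -> FuzzyEngineConfig:
    """Load a shipped engine config: ``which`` is 'technical' or 'expert'."""
    if which not in ("technical", "expert"):
        raise ValueError(f"no default config named {which!r}")
    text = (resources.files("woundrisk") / "configs" / f"{which}.yaml").read_text()
    return FuzzyEngineConfig.from_yaml(text)


def compute_technical_risk(
    braden_total: int,
    area_rate_pct: float,
    config: FuzzyEngineConfig | None = None,
) -> RiskScore:
    """Technical Risk from the Braden total and the area change rate.

    ``area_rate_pct`` is the wound-area change rate normalized to percent of
    the reference area per day (negative = healing), which makes the engine
    scale-free.  Rates beyond the engine's input domain are clamped to its
    edges: growth or shrinkage faster than the domain limits is already
    maximally informative.
    """
    if not 6 <= braden_total <= 23:
        raise ValueError(f"Braden total must lie in [6, 23], got {braden_total}")
    config = config or load_default_config("technical")
    lo, hi = config.variable("area_rate_pct").domain
    rate = min(max(float(area_rate_pct), lo), hi)
    value = infer({"braden_total": float(braden_total), "area_rate_pct": rate}, config)
    return RiskScore(value=value, kind="technical")


def compute_expert_risk(
    assessment: ExpertAssessment,
    config: FuzzyEngineConfig | None = None,
) -> RiskScore:
    """Expert Risk from the three qualitative ratings."""
    config = config or load_default_config("expert")
    value = infer(
        {
            "image_evaluation": assessment.image_evaluation,
            "health_history": assessment.health_history,
            "other_risk_factors": assessment.other_risk_factors,
        },
        config,
    )
    return RiskScore(value=value, kind="expert")
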