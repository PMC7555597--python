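"""Generic Mamdani fuzzy inference with trapezoidal membership functions.

The engine follows the classical seven-step Mamdani scheme: fuzzification of
crisp inputs against trapezoidal sets, min/max rule evaluation (AND = minimum,
OR = maximum of antecedent degrees), min-implication (truncation of the
consequent set at the rule activation level), max-aggregation of all truncated
consequents, and centroid defuzzification on a uniform grid over the output
domain.

Engine configurations are plain data (dataclasses) and serialize to/from
YAML or JSON-compatible dictionaries, so rule bases can be shipped, inspected
and overridden as text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DomainError",
    "ConfigurationError",
    "NoRuleFiredError",
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "FuzzyEngineConfig",
    "fuzzify",
    "evaluate_rules",
    "aggregate_and_defuzzify",
    "infer",
]


class DomainError(ValueError):
    """An input value lies outside its linguistic variable's domain."""


class ConfigurationError(ValueError):
    """An engine configuration is internally inconsistent."""


class NoRuleFiredError(RuntimeError):
    """Every rule activation is zero: the aggregate is identically zero.

    Raised instead of returning a default so that callers cannot silently
    misreport a risk value; the caller decides any fallback.
    """


@dataclass(frozen=True)
class MembershipFunction:
    """Trapezoidal membership function with breakpoints a <= b <= c <= d.

    Membership is 0 outside [a, d], 1 on the plateau [b, c] and linear on
    the edges [a, b] and [c, d].  Degenerate trapezoids with b == c
    (triangles) are allowed; at an exact breakpoint shared by an edge and
    the plateau, membership takes the limiting plateau value (1).
    """

    label: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.a <= self.b <= self.c <= self.d):
            raise ConfigurationError(
                f"set {self.label!r}: breakpoints must satisfy a <= b <= c <= d, "
                f"got ({self.a}, {self.b}, {self.c}, {self.d})"
            )

    def __call__(self, x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.zeros(x.shape)
        if self.b > self.a:
            rising = (x > self.a) & (x < self.b)
            y = np.where(rising, (x - self.a) / (self.b - self.a), y)
        if self.d > self.c:
            falling = (x > self.c) & (x < self.d)
            y = np.where(falling, (self.d - x) / (self.d - self.c), y)
        # plateau last so exact breakpoints b, c take the limiting value 1
        y = np.where((x >= self.b) & (x <= self.c), 1.0, y)
        return y

    def to_dict(self) -> dict:
        return {"label": self.label, "points": [self.a, self.b, self.c, self.d]}

    @classmethod
    def from_dict(cls, data: Mapping) -> "MembershipFunction":
        a, b, c, d = (float(p) for p in data["points"])
        return cls(label=str(data["label"]), a=a, b=b, c=c, d=d)


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with a closed numeric domain and an ordered set family."""

    name: str
    domain: tuple[float, float]
    sets: tuple[MembershipFunction, ...]

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ConfigurationError(f"variable {self.name!r}: empty domain {self.domain}")
        labels = [s.label for s in self.sets]
        if len(labels) != len(set(labels)):
            raise ConfigurationError(f"variable {self.name!r}: duplicate set labels")
        for s in self.sets:
            if s.a < lo or s.d > hi:
                raise ConfigurationError(
                    f"variable {self.name!r}: set {s.label!r} support "
                    f"[{s.a}, {s.d}] exceeds domain [{lo}, {hi}]"
                )
        object.__setattr__(self, "sets", tuple(self.sets))

    def __getitem__(self, label: str) -> MembershipFunction:
        for s in self.sets:
            if s.label == label:
                return s
        raise KeyError(f"variable {self.name!r} has no set {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.sets)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": list(self.domain),
            "sets": [s.to_dict() for s in self.sets],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "LinguisticVariable":
        lo, hi = (float(v) for v in data["domain"])
        return cls(
            name=str(data["name"]),
            domain=(lo, hi),
            sets=tuple(MembershipFunction.from_dict(s) for s in data["sets"]),
        )


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedents joined by AND/OR> THEN <output set>, with optional weight."""

    antecedents: tuple[tuple[str, str], ...]  # (variable name, set label)
    consequent: str  # output set label
    connective: str = "and"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.connective not in ("and", "or"):
            raise ConfigurationError(f"connective must be 'and' or 'or', got {self.connective!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"rule weight must lie in [0, 1], got {self.weight}")
        if not self.antecedents:
            raise ConfigurationError("rule needs at least one antecedent")
        object.__setattr__(self, "antecedents", tuple(tuple(p) for p in self.antecedents))

    def to_dict(self) -> dict:
        d = {
            "if": {var: label for var, label in self.antecedents},
            "op": self.connective,
            "then": self.consequent,
        }
        if self.weight != 1.0:
            d["weight"] = self.weight
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "FuzzyRule":
        return cls(
            antecedents=tuple((str(v), str(l)) for v, l in data["if"].items()),
            consequent=str(data["then"]),
            connective=str(data.get("op", "and")),
            weight=float(data.get("weight", 1.0)),
        )


@dataclass(frozen=True)
class FuzzyEngineConfig:
    """Inputs, output and rule base for one Mamdani engine."""

    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]
    defuzz_grid: int = 1001

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigurationError("engine needs at least one rule")
        if self.defuzz_grid < 100:
            raise ConfigurationError(f"defuzz_grid must be >= 100, got {self.defuzz_grid}")
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        by_name = {v.name: v for v in self.inputs}
        if len(by_name) != len(self.inputs):
            raise ConfigurationError("duplicate input variable names")
        for rule in self.rules:
            for var, label in rule.antecedents:
                if var not in by_name:
                    raise ConfigurationError(f"rule references unknown variable {var!r}")
                if label not in by_name[var].labels:
                    raise ConfigurationError(
                        f"rule references unknown set {label!r} of variable {var!r}"
                    )
            if rule.consequent not in self.output.labels:
                raise ConfigurationError(
                    f"rule references unknown output set {rule.consequent!r}"
                )

    def variable(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "inputs": [v.to_dict() for v in self.inputs],
            "output": self.output.to_dict(),
            "rules": [r.to_dict() for r in self.rules],
            "defuzz_grid": self.defuzz_grid,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FuzzyEngineConfig":
        return cls(
            inputs=tuple(LinguisticVariable.from_dict(v) for v in data["inputs"]),
            output=LinguisticVariable.from_dict(data["output"]),
            rules=tuple(FuzzyRule.from_dict(r) for r in data["rules"]),
            defuzz_grid=int(data.get("defuzz_grid", 1001)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FuzzyEngineConfig":
        return cls.from_dict(yaml.safe_load(text))


def fuzzify(value: float, variable: LinguisticVariable) -> dict[str, float]:
    """Membership degree of ``value`` in every set of ``variable``.

    Raises :class:`DomainError` if the value lies outside the variable domain.
    """
    lo, hi = variable.domain
    if not np.isfinite(value) or value < lo or value > hi:
        raise DomainError(
            f"value {value} outside domain [{lo}, {hi}] of variable {variable.name!r}"
        )
    return {s.label: float(s(value)) for s in variable.sets}


def evaluate_rules(
    degrees: Mapping[str, Mapping[str, float]],
    rules: Iterable[FuzzyRule],
) -> list[tuple[str, float]]:
    """Activation level of each rule: AND -> min, OR -> max, scaled by weight."""
    activations: list[tuple[str, float]] = []
    for rule in rules:
        vals = []
        for var, label in rule.antecedents:
            try:
                vals.append(degrees[var][label])
            except KeyError as exc:
                raise ConfigurationError(
                    f"rule references {var!r}/{label!r} absent from fuzzified degrees"
                ) from exc
        level = min(vals) if rule.connective == "and" else max(vals)
        activations.append((rule.consequent, level * rule.weight))
    return activations


def aggregate_and_defuzzify(
    activations: Sequence[tuple[str, float]],
    output: LinguisticVariable,
    grid: int = 1001,
) -> float:
    """Max-aggregate min-truncated consequents and return the centroid.

    The aggregate is sampled on a uniform grid over the output domain,
    augmented with the trapezoid corners and the points where each edge
    crosses its truncation level, so the piecewise-linear aggregate is
    integrated exactly by the trapezoidal rule.  Raises
    :class:`NoRuleFiredError` when the aggregate is identically zero.
    """
    if grid < 100:
        raise ConfigurationError(f"defuzzification grid must be >= 100, got {grid}")
    lo, hi = output.domain
    knots: list[float] = []
    segments: list[tuple[float, float, float, float]] = []  # x0, x1, slope, intercept
    for label, level in activations:
        if level <= 0.0:
            continue
        mf = output[label]
        lvl = min(level, 1.0)
        knots.extend((mf.a, mf.b, mf.c, mf.d))
        x_rise_top = mf.a + lvl * (mf.b - mf.a) if mf.b > mf.a else mf.a
        x_fall_top = mf.d - lvl * (mf.d - mf.c) if mf.d > mf.c else mf.d
        knots.extend((x_rise_top, x_fall_top))
        if mf.b > mf.a:
            s = 1.0 / (mf.b - mf.a)
            segments.append((mf.a, x_rise_top, s, -s * mf.a))
        segments.append((x_rise_top, x_fall_top, 0.0, lvl))
        if mf.d > mf.c:
            s = -1.0 / (mf.d - mf.c)
            segments.append((x_fall_top, mf.d, s, -s * mf.d))
    # kinks of the pointwise max also occur where segments of different
    # sets intersect
    for i in range(len(segments)):
        x0a, x1a, sa, ia = segments[i]
        for x0b, x1b, sb, ib in segments[i + 1 :]:
            if sa == sb:
                continue
            xi = (ib - ia) / (sa - sb)
            if max(x0a, x0b) < xi < min(x1a, x1b):
                knots.append(xi)
    x = np.unique(np.concatenate([np.linspace(lo, hi, grid), np.asarray(knots)]))
    x = x[(x >= lo) & (x <= hi)]
    agg = np.zeros(x.size)
    for label, level in activations:
        if level <= 0.0:
            continue
        np.maximum(agg, np.minimum(output[label](x), level), out=agg)
    # the aggregate is piecewise linear with all kinks on the grid, so the
    # area is exact by the trapezoidal rule and the first moment (piecewise
    # quadratic) is exact by Simpson's rule per interval
    dx = np.diff(x)
    mu_a, mu_b = agg[:-1], agg[1:]
    area = float(np.sum(dx * (mu_a + mu_b) / 2.0))
    if area <= 0.0:
        raise NoRuleFiredError(
            "aggregate membership is identically zero (no rule fired)"
        )
    mid = (x[:-1] + x[1:]) / 2.0
    moment = float(
        np.sum(dx / 6.0 * (x[:-1] * mu_a + 2.0 * mid * (mu_a + mu_b) + x[1:] * mu_b))
    )
    return moment / area


def infer(values: Mapping[str, float], config: FuzzyEngineConfig) -> float:
    """Full Mamdani pipeline: fuzzify -> evaluate rules -> aggregate/defuzzify."""
    degrees = {v.name: fuzzify(values[v.name], v) for v in config.inputs}
    activations = evaluate_rules(degrees, config.rules)
    return aggregate_and_defuzzify(activations, config.output, config.defuzz_grid)
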