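"""Benchmark-anchored TOPSIS for a single city.

Classic TOPSIS ranks many alternatives against ideals derived from the
alternatives themselves, so it needs a field of competitors.  Here the
published health indicator standards play that role instead: each
indicator contributes a three-row column {city value, positive ideal PI,
negative ideal NI}.  The column is vector-normalized (Euclidean), scaled
by the indicator's AHP weight, and the orientation-aware best/worst of the
three weighted entries become the ideal A+ and anti-ideal A-.  Because the
extremum is taken over all three rows, a city that outperforms its
standard defines its own ideal.

Squared city-to-ideal deviations are pooled over an element's (or a
dimension's) member indicators; S+ and S- are the square roots of the
pooled sums and the relative closeness is

    c* = S- / (S+ + S-)   in [0, 1]

with 1 meaning the city sits on every positive ideal and 0 on every
negative one.  No element-level weights enter the pooling: a dimension
aggregates raw per-indicator deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .framework import CityObservation, Framework, IndicatorSpec

__all__ = [
    "BenchmarkPanel",
    "ClosenessResult",
    "EvaluationResult",
    "build_panel",
    "deviations",
    "aggregate_closeness",
    "rank_results",
    "evaluate_city",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkPanel:
    """One indicator's three-row decision column through the pipeline."""

    code: str
    orientation: str
    weight: float
    raw: tuple[float, float, float]          # (city, PI, NI), resolved
    norm: float                              # Euclidean norm of raw
    normalized: tuple[float, float, float]   # r = raw / norm
    weighted: tuple[float, float, float]     # v = w * r
    a_plus: float                            # best weighted entry
    a_minus: float                           # worst weighted entry
    dev_plus_sq: float                       # (v_city - A+)^2
    dev_minus_sq: float                      # (v_city - A-)^2

    @property
    def v_city(self) -> float:
        return self.weighted[0]


@dataclass
class ClosenessResult:
    """Pooled S+, S-, closeness and rank for one element or dimension."""

    scope: str
    level: str                       # "element" | "dimension"
    member_codes: tuple[str, ...]
    s_plus: float
    s_minus: float
    closeness: float
    rank: int | None = None


@dataclass(frozen=True)
class EvaluationResult:
    """Full result tree for one city against one framework."""

    city_id: str
    year: int | None
    panels: Mapping[str, BenchmarkPanel]             # by indicator code
    element_results: tuple[ClosenessResult, ...]     # ranked within dimension
    dimension_results: tuple[ClosenessResult, ...]   # ranked among themselves

    def element(self, code: str) -> ClosenessResult:
        for r in self.element_results:
            if r.scope == code:
                return r
        raise KeyError(code)

    def dimension(self, code: str) -> ClosenessResult:
        for r in self.dimension_results:
            if r.scope == code:
                return r
        raise KeyError(code)


def build_panel(spec: IndicatorSpec, city_value: float, weight: float, *,
                policy: str = "zero") -> BenchmarkPanel:
    """Run one indicator's {city, PI, NI} column through normalization,
    weighting, ideal selection and squared deviations."""
    if not (0.0 < weight <= 1.0):
        raise ValueError(f"indicator {spec.code}: weight {weight} not in (0, 1]")
    if not math.isfinite(city_value):
        raise ValueError(f"indicator {spec.code}: non-finite city value")
    pi, ni = spec.resolve_ideals(policy)
    x = np.array([city_value, pi, ni], dtype=float)
    norm = float(np.linalg.norm(x))
    if norm == 0.0:
        raise ValueError(
            f"indicator {spec.code}: all-zero column (city, PI, NI all 0); "
            f"cannot normalize"
        )
    r = x / norm
    v = weight * r
    if spec.orientation == "MAX":
        a_plus, a_minus = float(v.max()), float(v.min())
    else:
        a_plus, a_minus = float(v.min()), float(v.max())
    return BenchmarkPanel(
        code=spec.code,
        orientation=spec.orientation,
        weight=float(weight),
        raw=tuple(x),
        norm=norm,
        normalized=tuple(r),
        weighted=tuple(v),
        a_plus=a_plus,
        a_minus=a_minus,
        dev_plus_sq=float((v[0] - a_plus) ** 2),
        dev_minus_sq=float((v[0] - a_minus) ** 2),
    )


def deviations(panel: BenchmarkPanel) -> tuple[float, float]:
    """The city's squared deviation from A+ and from A- for one indicator."""
    return panel.dev_plus_sq, panel.dev_minus_sq


def aggregate_closeness(panels: Sequence[BenchmarkPanel], *,
                        scope: str = "group",
                        level: str = "element") -> ClosenessResult:
    """Pool squared deviations over a member set and form c* = S-/(S+ + S-).

    If both pooled distances are zero the city sits exactly on both ideals
    for every member; closeness is defined as 1 and a warning is logged.
    """
    panels = list(panels)
    if not panels:
        raise ValueError(f"{scope}: empty member set")
    s_plus = math.sqrt(sum(p.dev_plus_sq for p in panels))
    s_minus = math.sqrt(sum(p.dev_minus_sq for p in panels))
    denom = s_plus + s_minus
    if denom == 0.0:
        log.warning("%s: S+ + S- = 0 (city coincides with both ideals); "
                    "closeness defined as 1", scope)
        closeness = 1.0
    else:
        closeness = s_minus / denom
    return ClosenessResult(
        scope=scope, level=level,
        member_codes=tuple(p.code for p in panels),
        s_plus=s_plus, s_minus=s_minus, closeness=closeness,
    )


def rank_results(results: Iterable[ClosenessResult]) -> list[ClosenessResult]:
    """Assign ranks 1..k by descending closeness, ties broken by scope code.

    Results must share one peer group (the elements of one dimension, or
    the dimensions themselves).  Deterministic; returns the same objects
    with ``rank`` set, in rank order.
    """
    ordered = sorted(results, key=lambda r: (-r.closeness, r.scope))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def evaluate_city(framework: Framework, observation: CityObservation,
                  weights: Mapping[str, float], *,
                  policy: str | None = None) -> EvaluationResult:
    """Score a city per indicator, element and dimension.

    ``weights`` must cover every framework indicator; the observation must
    be complete.  ``policy`` overrides the framework's missing-ideal
    default.
    """
    observation.require_complete(framework)
    missing_w = [c for c in framework.indicator_codes if c not in weights]
    if missing_w:
        raise ValueError("no weight for indicator(s): " + ", ".join(missing_w))
    pol = framework.missing_ideal_default if policy is None else policy

    panels = {
        code: build_panel(framework.indicator_map[code],
                          observation.values[code], weights[code], policy=pol)
        for code in framework.indicator_codes
    }

    element_results: list[ClosenessResult] = []
    dimension_results: list[ClosenessResult] = []
    for dim in framework.dimensions:
        per_dim = [
            aggregate_closeness(
                [panels[c] for c in framework.element_map[ec].indicator_codes],
                scope=ec, level="element")
            for ec in dim.element_codes
        ]
        element_results.extend(rank_results(per_dim))
        dimension_results.append(aggregate_closeness(
            [panels[c] for c in framework.dimension_indicators(dim.code)],
            scope=dim.code, level="dimension"))
    dimension_results = rank_results(dimension_results)

    return EvaluationResult(
        city_id=observation.city_id,
        year=observation.year,
        panels=panels,
        element_results=tuple(element_results),
        dimension_results=tuple(dimension_results),
    )
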