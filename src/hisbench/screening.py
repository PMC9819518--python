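"""Indicator screening and improvement-strategy classification.

Two small expert-facing procedures sit around the scoring pipeline:

* IOC screening: each candidate indicator is rated by an odd expert panel
  with -1 (unsuitable), 0 (uncertain) or +1 (suitable); the index of
  item-objective congruence is the mean rating and the indicator is
  retained when the index reaches a threshold (0.5 by convention).

* Strategy levels: after scoring, each indicator is classified against its
  *published* standards only (substitutes never act as thresholds) into
  Level 1 (growth-maintaining: at or beyond the positive ideal), Level 2
  (monitoring: between the ideals) or Level 3 (improvement: beyond the
  negative ideal).  An explicit per-indicator override table can pin a
  level where policy aspiration, not the printed value, decides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .framework import IndicatorSpec

__all__ = [
    "IOCRecord",
    "StrategyAssignment",
    "LEVEL_NAMES",
    "ioc_index",
    "classify_strategy",
]

LEVEL_NAMES = {1: "growth-maintaining", 2: "monitoring", 3: "improvement"}


@dataclass(frozen=True)
class IOCRecord:
    code: str
    expert_scores: tuple[int, ...]
    index: float
    retained: bool


@dataclass(frozen=True)
class StrategyAssignment:
    code: str
    level: int                  # 1 | 2 | 3
    basis: str                  # "rule" | "override"

    @property
    def level_name(self) -> str:
        return LEVEL_NAMES[self.level]


def ioc_index(scores: Sequence[int], *, threshold: float = 0.5,
              code: str = "") -> IOCRecord:
    """Mean expert rating in {-1, 0, +1}; retained iff index >= threshold."""
    scores = tuple(int(s) for s in scores)
    if len(scores) < 3 or len(scores) % 2 == 0:
        raise ValueError(
            f"IOC needs an odd panel of at least 3 experts, got {len(scores)}"
        )
    bad = [s for s in scores if s not in (-1, 0, 1)]
    if bad:
        raise ValueError(f"scores must be in {{-1, 0, 1}}, got {bad}")
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    index = sum(scores) / len(scores)
    return IOCRecord(code=code, expert_scores=scores, index=index,
                     retained=index >= threshold)


def _rule_level(spec: IndicatorSpec, value: float) -> int:
    pi, ni = spec.positive_ideal, spec.negative_ideal
    if pi is None and ni is None:
        raise ValueError(
            f"indicator {spec.code}: no published ideal to classify against"
        )
    if spec.orientation == "MAX":
        if pi is not None and ni is not None:
            return 1 if value >= pi else (2 if value >= ni else 3)
        sole = pi if pi is not None else ni
        return 1 if value >= sole else 3
    else:  # MIN
        if pi is not None and ni is not None:
            return 1 if value <= pi else (2 if value <= ni else 3)
        sole = pi if pi is not None else ni
        return 1 if value <= sole else 3


def classify_strategy(spec: IndicatorSpec, city_value: float,
                      overrides: Mapping[str, int] | None = None
                      ) -> StrategyAssignment:
    """Three-level strategy for one indicator against its printed standards.

    The value-based rule is total and exhaustive for any indicator with at
    least one published ideal; a configured override wins and is marked as
    such.
    """
    if not math.isfinite(city_value):
        raise ValueError(f"indicator {spec.code}: non-finite city value")
    if overrides and spec.code in overrides:
        level = int(overrides[spec.code])
        if level not in LEVEL_NAMES:
            raise ValueError(f"override for {spec.code} must be 1, 2 or 3")
        return StrategyAssignment(code=spec.code, level=level, basis="override")
    return StrategyAssignment(code=spec.code, level=_rule_level(spec, city_value),
                              basis="rule")
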