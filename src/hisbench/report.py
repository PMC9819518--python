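"""Report assembly: one JSON payload, CSV tables as views of it.

All numbers are computed and stored in full precision; rounding (half away
from zero, matching how the benchmark tables are typeset) happens only when
rendering the CSV views.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import __version__
from .ahp import WeightSet
from .framework import CityObservation, Framework, serialize_framework
from .screening import StrategyAssignment, classify_strategy
from .topsis import EvaluationResult

__all__ = ["EvaluationReport", "build_report", "round_half_away"]


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6) at ``decimals``."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class EvaluationReport:
    """Canonical machine-readable result of one evaluation run."""

    metadata: dict
    weight_groups: dict[str, WeightSet]
    weights: dict[str, float]
    result: EvaluationResult
    strategies: tuple[StrategyAssignment, ...]
    framework: Framework

    # -- JSON -----------------------------------------------------------

    def to_payload(self) -> dict:
        panels = {
            code: {
                "orientation": p.orientation,
                "weight": p.weight,
                "raw": list(p.raw),
                "norm": p.norm,
                "normalized": list(p.normalized),
                "weighted": list(p.weighted),
                "a_plus": p.a_plus,
                "a_minus": p.a_minus,
                "dev_plus_sq": p.dev_plus_sq,
                "dev_minus_sq": p.dev_minus_sq,
            }
            for code, p in sorted(self.result.panels.items())
        }
        closeness = [
            {"scope": r.scope, "level": r.level,
             "members": list(r.member_codes), "s_plus": r.s_plus,
             "s_minus": r.s_minus, "closeness": r.closeness, "rank": r.rank}
            for r in (*self.result.element_results,
                      *self.result.dimension_results)
        ]
        consistency = {
            g: {"lambda_max": ws.lambda_max, "ci": ws.consistency_index,
                "ri": ws.random_index, "cr": ws.consistency_ratio,
                "acceptable": ws.acceptable}
            for g, ws in sorted(self.weight_groups.items())
        }
        return {
            "metadata": self.metadata,
            "weights": dict(sorted(self.weights.items())),
            "consistency": consistency,
            "panels": panels,
            "closeness": closeness,
            "strategies": [
                {"code": s.code, "level": s.level, "basis": s.basis}
                for s in self.strategies
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_payload(), indent=indent, sort_keys=False)

    # -- CSV views ------------------------------------------------------

    def weights_table(self) -> pd.DataFrame:
        rows = []
        for group, ws in self.weight_groups.items():
            for code, w in ws.as_mapping().items():
                rows.append({"code": code, "weight": self.weights[code],
                             "group": group, "lambda_max": ws.lambda_max,
                             "ci": ws.consistency_index,
                             "ri": ws.random_index,
                             "cr": ws.consistency_ratio})
        df = pd.DataFrame(rows).sort_values("code").reset_index(drop=True)
        return df

    def ideals_table(self, decimals: int = 2) -> pd.DataFrame:
        """Per-indicator ideal and anti-ideal (A+, A-) at table precision."""
        rows = [{"code": code,
                 "a_plus": round_half_away(p.a_plus, decimals),
                 "a_minus": round_half_away(p.a_minus, decimals)}
                for code, p in sorted(self.result.panels.items())]
        return pd.DataFrame(rows)

    def deviations_table(self, decimals: int = 3) -> pd.DataFrame:
        """Per-indicator squared deviations from A+ and A-."""
        rows = [{"code": code,
                 "dev_plus_sq": round_half_away(p.dev_plus_sq, decimals),
                 "dev_minus_sq": round_half_away(p.dev_minus_sq, decimals)}
                for code, p in sorted(self.result.panels.items())]
        return pd.DataFrame(rows)

    def closeness_table(self, decimals: int = 2) -> pd.DataFrame:
        """Element and dimension rows: scope, members, S+, S-, c*, rank."""
        rows = []
        for dim in self.framework.dimensions:
            for ec in dim.element_codes:
                r = self.result.element(ec)
                rows.append(self._closeness_row(dim.code, r, decimals))
            rows.append(self._closeness_row(
                dim.code, self.result.dimension(dim.code), decimals))
        return pd.DataFrame(rows)

    @staticmethod
    def _closeness_row(dimension: str, r, decimals: int) -> dict:
        members = r.member_codes
        span = (members[0] if len(members) == 1
                else f"{members[0]}-{members[-1]}")
        return {
            "dimension": dimension,
            "element": r.scope if r.level == "element" else "-",
            "codes": span,
            "s_plus": round_half_away(r.s_plus, decimals),
            "s_minus": round_half_away(r.s_minus, decimals),
            "closeness": round_half_away(r.closeness, decimals),
            "rank": r.rank,
        }

    def strategy_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"code": s.code, "level": s.level, "basis": s.basis}
             for s in self.strategies]
        )


def build_report(
    framework: Framework,
    observation: CityObservation,
    weight_groups: Mapping[str, WeightSet],
    weights: Mapping[str, float],
    result: EvaluationResult,
    strategy_overrides: Mapping[str, int] | None = None,
    *,
    policy: str | None = None,
) -> EvaluationReport:
    """Assemble the canonical report from pipeline outputs.

    The framework hash in the metadata fingerprints the validated framework
    serialization, so identical inputs produce identical payloads.
    """
    fw_hash = hashlib.sha256(
        serialize_framework(framework).encode()).hexdigest()[:16]
    strategies = tuple(
        classify_strategy(framework.indicator_map[c],
                          observation.values[c], strategy_overrides)
        for c in framework.indicator_codes
    )
    metadata = {
        "city_id": observation.city_id,
        "year": observation.year,
        "framework": framework.name,
        "framework_sha256_16": fw_hash,
        "missing_ideal_policy": policy or framework.missing_ideal_default,
        "tool_version": __version__,
    }
    return EvaluationReport(
        metadata=metadata,
        weight_groups=dict(weight_groups),
        weights=dict(weights),
        result=result,
        strategies=strategies,
        framework=framework,
    )
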