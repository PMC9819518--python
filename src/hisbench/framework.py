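"""Hierarchical indicator frameworks and city observations.

A framework is a three-level hierarchy: dimensions (health, environment,
social, economic) contain elements (e.g. "Health Status"), which contain
indicators (e.g. "VR01", life expectancy).  Each indicator carries an
orientation (MAX: higher is better; MIN: lower is better) and a pair of
benchmark ideals taken from published health indicator standards (HIS): the
positive ideal PI (the standard to reach) and the negative ideal NI (the
level to stay away from).  Standards bodies do not always publish both
sides, so an indicator may instead carry an explicit substitute value, or
fall back to a framework-level default policy.

Frameworks are read from a single YAML document which may also bundle the
expert pairwise-comparison matrices and strategy overrides; city
observations are read from two-column CSV files.
"""

from __future__ import annotations

import io
import csv
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "IndicatorSpec",
    "ElementSpec",
    "DimensionSpec",
    "Framework",
    "CityObservation",
    "FrameworkError",
    "MissingIndicatorError",
    "load_document",
    "load_framework",
    "load_city_observation",
    "framework_to_dict",
    "serialize_framework",
]

ORIENTATIONS = ("MAX", "MIN")
MISSING_IDEAL_POLICIES = ("zero", "one", "omit")


class FrameworkError(ValueError):
    """A framework document violates a structural invariant."""


class MissingIndicatorError(FrameworkError):
    """An observation does not cover every framework indicator."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(
            "observation is missing indicator(s): " + ", ".join(self.missing)
        )


@dataclass(frozen=True)
class IndicatorSpec:
    """One criterion with orientation, unit and its HIS benchmark ideals.

    ``positive_ideal``/``negative_ideal`` are the published standard values;
    ``substitute_pi``/``substitute_ni`` are explicit stand-ins used when the
    corresponding standard is unpublished.  Substitutes never overwrite
    published ideals.
    """

    code: str
    name: str = ""
    unit: str = ""
    orientation: str = "MAX"
    positive_ideal: float | None = None
    negative_ideal: float | None = None
    substitute_pi: float | None = None
    substitute_ni: float | None = None
    element_code: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise FrameworkError(
                f"indicator {self.code}: orientation must be MAX or MIN, "
                f"got {self.orientation!r}"
            )
        for attr in ("positive_ideal", "negative_ideal",
                     "substitute_pi", "substitute_ni"):
            v = getattr(self, attr)
            if v is not None and not math.isfinite(v):
                raise FrameworkError(f"indicator {self.code}: {attr} is not finite")
        pi, ni = self.positive_ideal, self.negative_ideal
        if pi is not None and ni is not None:
            if self.orientation == "MAX" and pi < ni:
                raise FrameworkError(
                    f"indicator {self.code}: MAX orientation requires PI >= NI "
                    f"(got PI={pi}, NI={ni})"
                )
            if self.orientation == "MIN" and pi > ni:
                raise FrameworkError(
                    f"indicator {self.code}: MIN orientation requires PI <= NI "
                    f"(got PI={pi}, NI={ni})"
                )

    def resolve_ideals(self, policy: str = "zero") -> tuple[float, float]:
        """Return the effective (PI, NI) pair.

        Published values win; otherwise the indicator's own substitute;
        otherwise the framework default policy (``zero`` -> 0.0, ``one`` ->
        1.0, ``omit`` -> raise).
        """
        if policy not in MISSING_IDEAL_POLICIES:
            raise ValueError(f"unknown missing-ideal policy {policy!r}")

        def _resolve(published: float | None, substitute: float | None,
                     side: str) -> float:
            if published is not None:
                return float(published)
            if substitute is not None:
                return float(substitute)
            if policy == "omit":
                raise FrameworkError(
                    f"indicator {self.code}: no {side} ideal and policy is 'omit'"
                )
            return 0.0 if policy == "zero" else 1.0

        return (_resolve(self.positive_ideal, self.substitute_pi, "positive"),
                _resolve(self.negative_ideal, self.substitute_ni, "negative"))


@dataclass(frozen=True)
class ElementSpec:
    code: str
    name: str = ""
    indicator_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.indicator_codes:
            raise FrameworkError(f"element {self.code}: no indicators")
        object.__setattr__(self, "indicator_codes", tuple(self.indicator_codes))


@dataclass(frozen=True)
class DimensionSpec:
    code: str
    name: str = ""
    element_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.element_codes:
            raise FrameworkError(f"dimension {self.code}: no elements")
        object.__setattr__(self, "element_codes", tuple(self.element_codes))


@dataclass(frozen=True)
class Framework:
    """A validated three-level indicator hierarchy."""

    dimensions: tuple[DimensionSpec, ...]
    elements: tuple[ElementSpec, ...]
    indicators: tuple[IndicatorSpec, ...]
    missing_ideal_default: str = "zero"
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "indicators", tuple(self.indicators))
        if self.missing_ideal_default not in MISSING_IDEAL_POLICIES:
            raise FrameworkError(
                f"missing_ideal_default must be one of {MISSING_IDEAL_POLICIES}"
            )
        self._validate()

    # -- lookup helpers -------------------------------------------------

    @property
    def indicator_map(self) -> dict[str, IndicatorSpec]:
        return {i.code: i for i in self.indicators}

    @property
    def element_map(self) -> dict[str, ElementSpec]:
        return {e.code: e for e in self.elements}

    @property
    def dimension_map(self) -> dict[str, DimensionSpec]:
        return {d.code: d for d in self.dimensions}

    @property
    def indicator_codes(self) -> tuple[str, ...]:
        return tuple(i.code for i in self.indicators)

    def element_of(self, indicator_code: str) -> ElementSpec:
        for e in self.elements:
            if indicator_code in e.indicator_codes:
                return e
        raise KeyError(indicator_code)

    def dimension_of(self, element_code: str) -> DimensionSpec:
        for d in self.dimensions:
            if element_code in d.element_codes:
                return d
        raise KeyError(element_code)

    def dimension_indicators(self, dimension_code: str) -> tuple[str, ...]:
        d = self.dimension_map[dimension_code]
        out: list[str] = []
        for ec in d.element_codes:
            out.extend(self.element_map[ec].indicator_codes)
        return tuple(out)

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        codes = [i.code for i in self.indicators]
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        if dupes:
            raise FrameworkError(f"duplicate indicator code(s): {', '.join(dupes)}")
        ecodes = [e.code for e in self.elements]
        if len(set(ecodes)) != len(ecodes):
            raise FrameworkError("duplicate element codes")
        dcodes = [d.code for d in self.dimensions]
        if len(set(dcodes)) != len(dcodes):
            raise FrameworkError("duplicate dimension codes")

        seen: dict[str, str] = {}
        for e in self.elements:
            for c in e.indicator_codes:
                if c not in set(codes):
                    raise FrameworkError(
                        f"element {e.code} references unknown indicator {c}"
                    )
                if c in seen:
                    raise FrameworkError(
                        f"indicator {c} belongs to both elements "
                        f"{seen[c]} and {e.code}"
                    )
                seen[c] = e.code
        orphans = sorted(set(codes) - set(seen))
        if orphans:
            raise FrameworkError(
                f"indicator(s) not referenced by any element: {', '.join(orphans)}"
            )

        seen_e: dict[str, str] = {}
        for d in self.dimensions:
            for ec in d.element_codes:
                if ec not in set(ecodes):
                    raise FrameworkError(
                        f"dimension {d.code} references unknown element {ec}"
                    )
                if ec in seen_e:
                    raise FrameworkError(
                        f"element {ec} belongs to both dimensions "
                        f"{seen_e[ec]} and {d.code}"
                    )
                seen_e[ec] = d.code
        orphan_e = sorted(set(ecodes) - set(seen_e))
        if orphan_e:
            raise FrameworkError(
                f"element(s) not referenced by any dimension: {', '.join(orphan_e)}"
            )

        for ind in self.indicators:
            if ind.element_code and seen[ind.code] != ind.element_code:
                raise FrameworkError(
                    f"indicator {ind.code}: element_code {ind.element_code} "
                    f"disagrees with membership in {seen[ind.code]}"
                )
            if self.missing_ideal_default == "omit":
                ind.resolve_ideals("omit")  # raises if unresolvable


@dataclass(frozen=True)
class CityObservation:
    """One city's indicator values (the x_ij column of the decision matrix)."""

    city_id: str
    year: int | None
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        bad = [c for c, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise FrameworkError(f"non-finite value(s) for: {', '.join(sorted(bad))}")

    def require_complete(self, framework: Framework) -> None:
        missing = [c for c in framework.indicator_codes if c not in self.values]
        if missing:
            raise MissingIndicatorError(missing)


# ----------------------------------------------------------------------
# Loading


def _parse_number(value: Any, context: str) -> float:
    """Accept YAML/CSV scalars including fraction strings like '1/3'."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(Fraction(value.strip()))
        except (ValueError, ZeroDivisionError) as exc:
            raise FrameworkError(f"{context}: cannot parse number {value!r}") from exc
    raise FrameworkError(f"{context}: cannot parse number {value!r}")


def _opt_number(mapping: Mapping[str, Any], key: str, context: str) -> float | None:
    v = mapping.get(key)
    if v is None or v == "-" or v == "":
        return None
    return _parse_number(v, f"{context}.{key}")


def load_document(source: str | Path | io.TextIOBase | Mapping[str, Any]):
    """Parse a framework YAML document.

    Returns ``(framework, pcm_blocks, strategy_overrides)`` where
    ``pcm_blocks`` maps group code to a raw ``{"labels": [...], "upper":
    [...]}`` mapping (turned into matrices by :mod:`hisbench.ahp`) and
    ``strategy_overrides`` maps indicator code to a level in {1, 2, 3}.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        elif isinstance(source, str):
            text = source
        else:
            text = source.read()
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FrameworkError("framework document is not a mapping")

    indicators = []
    for row in doc.get("indicators", []):
        ctx = f"indicator {row.get('code', '?')}"
        indicators.append(IndicatorSpec(
            code=str(row["code"]),
            name=str(row.get("name", "")),
            unit=str(row.get("unit", "")),
            orientation=str(row.get("orientation", "MAX")).upper(),
            positive_ideal=_opt_number(row, "positive_ideal", ctx),
            negative_ideal=_opt_number(row, "negative_ideal", ctx),
            substitute_pi=_opt_number(row, "substitute_pi", ctx),
            substitute_ni=_opt_number(row, "substitute_ni", ctx),
            element_code=str(row.get("element_code", "")),
        ))
    elements = [
        ElementSpec(code=str(r["code"]), name=str(r.get("name", "")),
                    indicator_codes=tuple(r["indicators"]))
        for r in doc.get("elements", [])
    ]
    dimensions = [
        DimensionSpec(code=str(r["code"]), name=str(r.get("name", "")),
                      element_codes=tuple(r["elements"]))
        for r in doc.get("dimensions", [])
    ]
    fw = Framework(
        dimensions=tuple(dimensions),
        elements=tuple(elements),
        indicators=tuple(indicators),
        missing_ideal_default=str(doc.get("missing_ideal_default", "zero")),
        name=str(doc.get("name", "")),
    )
    pcm_blocks = {str(k): v for k, v in (doc.get("pcm") or {}).items()}
    overrides = {str(k): int(v) for k, v in (doc.get("strategy_overrides") or {}).items()}
    return fw, pcm_blocks, overrides


def load_framework(source: str | Path | io.TextIOBase | Mapping[str, Any]) -> Framework:
    """Load and validate just the framework from a YAML document."""
    fw, _, _ = load_document(source)
    return fw


def framework_to_dict(fw: Framework) -> dict[str, Any]:
    """Plain-dict form of a framework (stable key order, round-trips)."""
    def _ind(i: IndicatorSpec) -> dict[str, Any]:
        d = {"code": i.code, "name": i.name, "unit": i.unit,
             "orientation": i.orientation}
        for k in ("positive_ideal", "negative_ideal", "substitute_pi",
                  "substitute_ni"):
            v = getattr(i, k)
            if v is not None:
                d[k] = v
        if i.element_code:
            d["element_code"] = i.element_code
        return d

    return {
        "name": fw.name,
        "missing_ideal_default": fw.missing_ideal_default,
        "dimensions": [{"code": d.code, "name": d.name,
                        "elements": list(d.element_codes)} for d in fw.dimensions],
        "elements": [{"code": e.code, "name": e.name,
                      "indicators": list(e.indicator_codes)} for e in fw.elements],
        "indicators": [_ind(i) for i in fw.indicators],
    }


def serialize_framework(fw: Framework) -> str:
    return yaml.safe_dump(framework_to_dict(fw), sort_keys=False,
                          allow_unicode=True)


def load_city_observation(source: str | Path | io.TextIOBase,
                          framework: Framework | None = None) -> CityObservation:
    """Read a ``code,value`` CSV, optionally validating coverage.

    Rows whose first field is ``city_id`` or ``year`` (before the header)
    carry metadata.  Codes not present in the framework are reported as
    warnings, not errors.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    city_id, year = "", None
    values: dict[str, float] = {}
    for lineno, row in enumerate(csv.reader(io.StringIO(text)), start=1):
        if not row or not row[0].strip() or row[0].lstrip().startswith("#"):
            continue
        key = row[0].strip()
        if key == "city_id":
            city_id = row[1].strip() if len(row) > 1 else ""
            continue
        if key == "year":
            year = int(row[1])
            continue
        if key.lower() == "code":
            continue  # header
        if len(row) < 2:
            raise FrameworkError(f"observation line {lineno}: no value for {key}")
        try:
            values[key] = float(row[1])
        except ValueError as exc:
            raise FrameworkError(
                f"observation line {lineno}: non-numeric value {row[1]!r} "
                f"for {key}"
            ) from exc

    obs = CityObservation(city_id=city_id, year=year, values=values)
    if framework is not None:
        obs.require_complete(framework)
        extra = sorted(set(values) - set(framework.indicator_codes))
        if extra:
            warnings.warn(
                f"observation has codes outside the framework: {', '.join(extra)}",
                stacklevel=2,
            )
    return obs
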