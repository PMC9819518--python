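"""Synthetic frameworks, judgment matrices and city observations.

Everything the scoring pipeline consumes can be generated from a seed:
random (but structurally valid) indicator hierarchies with controllable
missing-ideal rates, near-consistent Saaty matrices built by perturbing a
consistent ratio matrix and snapping back to legal scale values, and city
observations positioned linearly between the negative and positive ideals
(position 0 = on NI, 1 = on PI).  Independent child seeds drive the
framework, matrix and city streams, so regenerating one artifact never
shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ahp import PairwiseMatrix, validate_pcm
from .framework import (
    CityObservation,
    DimensionSpec,
    ElementSpec,
    Framework,
    IndicatorSpec,
)

__all__ = [
    "SynthConfig",
    "generate_framework",
    "generate_pcm",
    "generate_city",
    "generate_pcms_for_framework",
]

# admissible Saaty values: 1..9 and reciprocals
_SAATY = np.array(sorted({1.0 / k for k in range(1, 10)} | {float(k) for k in range(1, 10)}))


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_dimensions: int = 2
    elements_per_dimension: int = 2
    indicators_per_element: int = 3
    pcm_noise: float = 0.1          # log-scale perturbation before snapping
    city_position: float = 0.5      # 0 = at NI, 1 = at PI
    city_jitter: float = 0.0        # sd of position jitter
    missing_ideal_rate: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_dimensions, self.elements_per_dimension,
               self.indicators_per_element) < 1:
            raise ValueError("hierarchy sizes must be >= 1")
        if not 0.0 <= self.missing_ideal_rate <= 1.0:
            raise ValueError("missing_ideal_rate must be in [0, 1]")
        if self.pcm_noise < 0:
            raise ValueError("pcm_noise must be >= 0")


def _streams(seed: int, n: int = 3) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_framework(cfg: SynthConfig) -> Framework:
    """Random valid hierarchy with ~50/50 MAX/MIN orientations.

    MAX indicators draw PI > NI > 0; MIN indicators mirror that.  Missing
    ideals are injected at ``missing_ideal_rate`` with an explicit
    substitute consistent with the default zero policy.
    """
    rng = _streams(cfg.seed)[0]
    dims, elems, inds = [], [], []
    k = 0
    for d in range(cfg.n_dimensions):
        dcode = f"D{d + 1:02d}"
        ecodes = []
        for e in range(cfg.elements_per_dimension):
            ecode = f"{dcode}E{e + 1:02d}"
            icodes = []
            for _ in range(cfg.indicators_per_element):
                k += 1
                code = f"X{k:03d}"
                orientation = "MAX" if rng.random() < 0.5 else "MIN"
                lo = float(rng.uniform(0.5, 10.0))
                hi = lo * float(rng.uniform(1.5, 4.0))
                good, bad = (hi, lo) if orientation == "MAX" else (lo, hi)
                pi, ni, sub_pi, sub_ni = good, bad, None, None
                if rng.random() < cfg.missing_ideal_rate:
                    if rng.random() < 0.5:
                        pi, sub_pi = None, good
                    else:
                        ni, sub_ni = None, bad
                inds.append(IndicatorSpec(
                    code=code, name=f"synthetic indicator {k}", unit="index",
                    orientation=orientation, positive_ideal=pi,
                    negative_ideal=ni, substitute_pi=sub_pi,
                    substitute_ni=sub_ni, element_code=ecode,
                ))
                icodes.append(code)
            elems.append(ElementSpec(code=ecode, name=f"synthetic element {ecode}",
                                     indicator_codes=tuple(icodes)))
            ecodes.append(ecode)
        dims.append(DimensionSpec(code=dcode, name=f"synthetic dimension {dcode}",
                                  element_codes=tuple(ecodes)))
    return Framework(dimensions=tuple(dims), elements=tuple(elems),
                     indicators=tuple(inds), missing_ideal_default="zero",
                     name=f"synthetic-{cfg.seed}")


def _snap_saaty(x: float) -> float:
    # snap in log space so 1/3 and 3 are equally far from 1
    return float(_SAATY[np.argmin(np.abs(np.log(_SAATY) - np.log(x)))])


def generate_pcm(target_weights, noise: float, seed: int,
                 labels=None) -> PairwiseMatrix:
    """Saaty matrix whose priorities approximate ``target_weights``.

    Entries start from the consistent ratio matrix w_i / w_j, are perturbed
    multiplicatively by exp(noise * z) with standard normal z, and snapped
    to the nearest admissible Saaty value; reciprocity is enforced from the
    upper triangle, so the result is always a legal instrument (though
    large noise may legitimately fail the consistency gate).
    """
    w = np.asarray(target_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("target weights must be strictly positive")
    w = w / w.sum()
    n = len(w)
    if not 2 <= n <= 15:
        raise ValueError("matrix size must be in [2, 15]")
    rng = np.random.default_rng(seed)
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ratio = (w[i] / w[j]) * float(np.exp(noise * rng.standard_normal()))
            a[i, j] = _snap_saaty(ratio)
            a[j, i] = 1.0 / a[i, j]
    if labels is None:
        labels = [f"X{i + 1:03d}" for i in range(n)]
    return validate_pcm(a, labels)


def generate_pcms_for_framework(framework: Framework, cfg: SynthConfig
                                ) -> dict[str, PairwiseMatrix]:
    """One judgment matrix per element (elements of size 1 are grouped at
    dimension level, mirroring how single-indicator elements are weighted)."""
    rng = _streams(cfg.seed)[1]
    out: dict[str, PairwiseMatrix] = {}
    for dim in framework.dimensions:
        singletons = [ec for ec in dim.element_codes
                      if len(framework.element_map[ec].indicator_codes) == 1]
        if len(singletons) == len(dim.element_codes) and len(singletons) > 1:
            codes = framework.dimension_indicators(dim.code)
            w = rng.dirichlet(np.full(len(codes), 5.0))
            out[dim.code] = generate_pcm(w, cfg.pcm_noise,
                                         int(rng.integers(2**31)), labels=codes)
        else:
            for ec in dim.element_codes:
                codes = framework.element_map[ec].indicator_codes
                if len(codes) == 1:
                    raise ValueError(
                        f"element {ec}: cannot build a pairwise matrix for a "
                        f"single indicator in a mixed dimension"
                    )
                w = rng.dirichlet(np.full(len(codes), 5.0))
                out[ec] = generate_pcm(w, cfg.pcm_noise,
                                       int(rng.integers(2**31)), labels=codes)
    return out


def generate_city(framework: Framework, position: float, jitter: float = 0.0,
                  seed: int = 0, *, city_id: str = "synthetic-city",
                  year: int | None = None) -> CityObservation:
    """Observation at ``NI + position * (PI - NI)`` per indicator.

    Position 1 with zero jitter puts the city exactly on every positive
    ideal, position 0 on every negative ideal; jitter adds Gaussian noise
    on the position scale, independently per indicator.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must be in [0, 1]")
    rng = _streams(seed)[2]
    values = {}
    for ind in framework.indicators:
        pi, ni = ind.resolve_ideals(framework.missing_ideal_default)
        p = position + (jitter * float(rng.standard_normal()) if jitter else 0.0)
        values[ind.code] = ni + p * (pi - ni)
    return CityObservation(city_id=city_id, year=year, values=values)
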