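"""Analytic Hierarchy Process weighting with consistency control.

Expert judgments arrive as reciprocal pairwise comparison matrices (PCMs)
on Saaty's nine-point ratio scale.  Priorities are extracted by the
normalized-column / row-average method (column-normalize the PCM, then
average each row), which for a perfectly consistent matrix coincides with
the principal eigenvector.  Each matrix is gated by the consistency ratio

    lambda_max = mean_i (A w)_i / w_i
    C.I. = (lambda_max - n) / (n - 1)
    C.R. = C.I. / R.I.(n)        accepted iff C.R. < 0.1

where R.I. is a size-dependent random consistency index.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .framework import Framework

__all__ = [
    "PairwiseMatrix",
    "WeightSet",
    "PCMError",
    "ConsistencyError",
    "RANDOM_INDEX",
    "RANDOM_INDEX_SAATY_CLASSIC",
    "validate_pcm",
    "pcm_from_block",
    "priority_vector",
    "principal_eigenvector",
    "lambda_max",
    "consistency",
    "weights_for_framework",
]

CR_THRESHOLD = 0.1

# Random consistency index by matrix size.  The default table is the one
# this package standardises on; "saaty_classic" is the common alternative
# (they differ at n = 12).
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
    9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}
RANDOM_INDEX_SAATY_CLASSIC: dict[int, float] = {
    **RANDOM_INDEX, 12: 1.54, 13: 1.56, 14: 1.57, 15: 1.58,
}
_RI_TABLES = {"default": RANDOM_INDEX, "saaty_classic": RANDOM_INDEX_SAATY_CLASSIC}


class PCMError(ValueError):
    """A pairwise comparison matrix violates the Saaty-scale invariants."""


class ConsistencyError(ValueError):
    """A judgment matrix failed the C.R. < 0.1 gate."""

    def __init__(self, group: str, weightset: "WeightSet"):
        self.group = group
        self.weightset = weightset
        super().__init__(
            f"group {group}: C.R. = {weightset.consistency_ratio:.3f} >= "
            f"{CR_THRESHOLD} (lambda_max = {weightset.lambda_max:.4f}, "
            f"n = {len(weightset.labels)}); judgments must be revised"
        )


@dataclass(frozen=True)
class PairwiseMatrix:
    """A validated reciprocal Saaty-scale judgment matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def permuted(self, order: Sequence[int]) -> "PairwiseMatrix":
        idx = np.asarray(order)
        return PairwiseMatrix(
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[np.ix_(idx, idx)],
        )


def validate_pcm(matrix, labels: Sequence[str], *, tol: float = 1e-9) -> PairwiseMatrix:
    """Check and wrap a square reciprocal matrix of Saaty judgments.

    Requires a unit diagonal, pairwise reciprocity ``a_ji = 1/a_ij`` within
    ``tol``, and every entry in [1/9, 9].  Nothing is silently repaired.
    """
    a = np.asarray(matrix, dtype=float)
    labels = tuple(str(x) for x in labels)
    n = len(labels)
    if a.shape != (n, n):
        raise PCMError(f"matrix shape {a.shape} does not match {n} labels")
    if n < 2:
        raise PCMError("a pairwise comparison needs at least 2 items")
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise PCMError("entries must be finite and strictly positive")
    if np.any(np.abs(np.diag(a) - 1.0) > tol):
        i = int(np.argmax(np.abs(np.diag(a) - 1.0)))
        raise PCMError(f"diagonal entry for {labels[i]} is {a[i, i]}, expected 1")
    lo, hi = 1.0 / 9.0 - tol, 9.0 + tol
    if np.any((a < lo) | (a > hi)):
        i, j = np.unravel_index(int(np.argmax((a < lo) | (a > hi))), a.shape)
        raise PCMError(
            f"entry ({labels[i]}, {labels[j]}) = {a[i, j]} outside Saaty "
            f"scale [1/9, 9]"
        )
    recip = np.abs(a * a.T - 1.0)
    if np.any(recip > tol * np.maximum(a, a.T) * np.maximum(a, a.T)):
        # relative tolerance: a_ij * a_ji should equal 1
        mask = recip > tol * np.maximum(a, a.T) ** 2
        i, j = np.unravel_index(int(np.argmax(mask)), a.shape)
        raise PCMError(
            f"non-reciprocal pair ({labels[i]}, {labels[j]}): "
            f"a_ij = {a[i, j]}, a_ji = {a[j, i]} (a_ji != 1/a_ij)"
        )
    a = a.copy()
    a.flags.writeable = False
    return PairwiseMatrix(labels=labels, values=a)


def pcm_from_block(group: str, block: Mapping) -> PairwiseMatrix:
    """Build a PCM from a YAML block listing the upper triangle.

    ``block`` has ``labels: [c1, ..., cn]`` and ``upper: [[a_12 ... a_1n],
    [a_23 ... a_2n], ..., [a_{n-1,n}]]``; entries may be numbers or
    fraction strings such as ``"1/3"``.  Reciprocals and the unit diagonal
    are derived, so the stored instrument is exactly reciprocal.
    """
    labels = [str(x) for x in block["labels"]]
    n = len(labels)
    upper = block["upper"]
    if len(upper) != n - 1:
        raise PCMError(f"group {group}: expected {n - 1} upper-triangle rows")
    a = np.eye(n)
    for i, row in enumerate(upper):
        if len(row) != n - 1 - i:
            raise PCMError(f"group {group}: row {i} has wrong length")
        for k, cell in enumerate(row):
            j = i + 1 + k
            if isinstance(cell, str):
                v = float(Fraction(cell))
            else:
                v = float(cell)
            a[i, j] = v
            a[j, i] = 1.0 / v
    return validate_pcm(a, labels)


def priority_vector(pcm: PairwiseMatrix) -> np.ndarray:
    """Column-normalize the matrix and average across each row.

    Exact for consistent (rank-one) matrices; the standard approximation to
    the principal eigenvector otherwise.  Weights sum to 1.
    """
    a = pcm.values
    return (a / a.sum(axis=0)).mean(axis=1)


def principal_eigenvector(pcm: PairwiseMatrix, *, tol: float = 1e-14,
                          max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Power-iteration principal eigenvector, as an independent cross-check.

    Returns ``(weights, lambda_max)`` with weights normalized to sum 1.
    Not used by the default pipeline.
    """
    a = pcm.values
    w = np.full(pcm.n, 1.0 / pcm.n)
    lam = float(pcm.n)
    for _ in range(max_iter):
        aw = a @ w
        lam_new = float(aw.sum())  # since w sums to 1 after renorm below
        w_new = aw / aw.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            lam = float(np.mean((a @ w) / w))
            break
        w, lam = w_new, lam_new
    else:
        lam = float(np.mean((a @ w) / w))
    return w, lam


def lambda_max(pcm: PairwiseMatrix, weights: np.ndarray) -> float:
    """Mean of the component ratios (A w)_i / w_i; equals n when consistent."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return float(np.mean((pcm.values @ w) / w))


@dataclass(frozen=True)
class WeightSet:
    """A priority vector with its consistency report."""

    labels: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    random_index: float
    consistency_ratio: float
    acceptable: bool

    def as_mapping(self) -> dict[str, float]:
        return {c: float(w) for c, w in zip(self.labels, self.weights)}


def consistency(pcm: PairwiseMatrix, weights: np.ndarray | None = None, *,
                random_index: float | None = None,
                ri_table: str = "default") -> WeightSet:
    """Full consistency report for a PCM.

    For n <= 2 a reciprocal matrix is always consistent: C.I. and C.R. are
    defined as 0 and the matrix is acceptable.  For n > 15 an explicit
    ``random_index`` must be supplied (the lookup table stops there).
    """
    w = priority_vector(pcm) if weights is None else np.asarray(weights, float)
    n = pcm.n
    if n <= 2:
        lam, ci, ri, cr = float(n), 0.0, 0.0, 0.0
        return WeightSet(pcm.labels, w, lam, ci, ri, cr, acceptable=True)
    lam = lambda_max(pcm, w)
    ci = (lam - n) / (n - 1)
    if random_index is None:
        table = _RI_TABLES[ri_table]
        if n not in table:
            raise ValueError(
                f"no random index tabulated for n = {n}; pass random_index="
            )
        ri = table[n]
    else:
        ri = float(random_index)
    cr = ci / ri
    return WeightSet(pcm.labels, w, lam, ci, ri, cr,
                     acceptable=bool(cr < CR_THRESHOLD))


def weights_for_framework(
    framework: Framework,
    pcms: Mapping[str, PairwiseMatrix],
    *,
    ri_table: str = "default",
    decimals: int | None = None,
) -> dict[str, float]:
    """One weight per indicator from the per-group judgment matrices.

    Each group's labels must exactly cover one element's indicators, or a
    whole dimension's when that dimension's elements are single indicators.
    Any group with C.R. >= 0.1 aborts with :class:`ConsistencyError`.

    ``decimals`` optionally rounds each group's weights after extraction
    (half away from zero), for pipelines that carry printed two-decimal
    weights forward.
    """
    groups: dict[str, tuple[str, ...]] = {}
    for e in framework.elements:
        groups[e.code] = e.indicator_codes
    for d in framework.dimensions:
        groups[d.code] = framework.dimension_indicators(d.code)

    out: dict[str, float] = {}
    for gcode, pcm in pcms.items():
        if gcode not in groups:
            raise KeyError(f"PCM group {gcode} matches no element or dimension")
        expected = groups[gcode]
        if tuple(pcm.labels) != tuple(expected):
            raise PCMError(
                f"group {gcode}: PCM labels {pcm.labels} do not match "
                f"indicator set {expected}"
            )
        ws = consistency(pcm, ri_table=ri_table)
        if not ws.acceptable:
            raise ConsistencyError(gcode, ws)
        w = ws.weights
        if decimals is not None:
            w = _round_half_away(w, decimals)
        for code, wi in zip(pcm.labels, w):
            if code in out:
                raise PCMError(f"indicator {code} weighted by two groups")
            out[code] = float(wi)

    missing = [c for c in framework.indicator_codes if c not in out]
    if missing:
        raise PCMError("no PCM covers indicator(s): " + ", ".join(missing))
    return out


def _round_half_away(x: np.ndarray, decimals: int) -> np.ndarray:
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
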