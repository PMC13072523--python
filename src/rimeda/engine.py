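"""Core index computation over the weighted influence matrix.

Combining an assessment with the influence matrix produces the system
indices: per-entity active sums (influence exerted), passive sums
(influence received), Q-values (cross-linkage, signed by risk direction),
a factor category, and the total risk score.

All arithmetic is exact over integers; classification thresholds use exact
rationals. Display rounding happens only in the stratify module's charts.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Sequence

import numpy as np

from rimeda.model import (
    Assessment,
    InfluenceMatrix,
    ModelError,
    ModelSpec,
    validate_assessment,
)
from rimeda.stratify import stratify as _stratify

__all__ = [
    "EngineError",
    "WeightedMatrix",
    "EntityIndices",
    "RiskResult",
    "WEIGHTING_STRATEGIES",
    "Q_CONVENTIONS",
    "apply_weights",
    "active_sum",
    "passive_sum",
    "q_value",
    "total_risk_score",
    "classify_factor",
    "classify_all",
    "compute",
]


class EngineError(ValueError):
    """Unknown strategy/convention or inconsistent inputs."""


@dataclass(frozen=True)
class WeightedMatrix:
    """Influence matrix scaled by an assessment's weights.

    Under the ``row`` strategy ``cell(i, j) = w_i * delta_i * |m(i, j)|``
    where ``delta_i`` doubles the points of double-impact entities; under
    ``row_col`` the cell is additionally scaled by ``w_j * delta_j``. Signed
    weights (the -3 option of protective factors) carry their sign into the
    cells, which is how negative sums — and hence a risk-reducing reading —
    arise.
    """

    entity_order: tuple[str, ...]
    values: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        self.values.setflags(write=False)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.entity_order.index(entity_id)
        except ValueError:
            raise EngineError(f"unknown entity id {entity_id!r}") from None


def _row_strategy(absm: np.ndarray, scaled_w: np.ndarray) -> np.ndarray:
    return scaled_w[:, None] * absm


def _row_col_strategy(absm: np.ndarray, scaled_w: np.ndarray) -> np.ndarray:
    return scaled_w[:, None] * scaled_w[None, :] * absm


WEIGHTING_STRATEGIES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "row": _row_strategy,
    "row_col": _row_col_strategy,
}


def apply_weights(
    matrix: InfluenceMatrix,
    assessment: Assessment,
    model: ModelSpec,
    strategy: str | None = None,
) -> WeightedMatrix:
    """Scale the matrix's absolute cell values by the assessment's weights.

    The moduli of the matrix entries are taken first — the per-cell signs
    encode development direction and do not enter the scoring — and then
    multiplied by the signed, doubling-adjusted weights.
    """
    strategy = strategy or model.weighting_strategy
    if strategy not in WEIGHTING_STRATEGIES:
        raise EngineError(
            f"unknown weighting strategy {strategy!r}; "
            f"registered: {sorted(WEIGHTING_STRATEGIES)}"
        )
    validate_assessment(assessment, model).raise_if_invalid()
    order = matrix.entity_order
    w = np.array([assessment.weights[e] for e in order], dtype=np.int64)
    scaled = w * model.deltas
    values = WEIGHTING_STRATEGIES[strategy](np.abs(matrix.values), scaled)
    return WeightedMatrix(order, values, strategy)


def active_sum(weighted: WeightedMatrix, entity_id: str) -> int:
    """Row sum of the weighted matrix: influence the entity exerts."""
    return int(weighted.values[weighted.index_of(entity_id)].sum())


def passive_sum(weighted: WeightedMatrix, entity_id: str) -> int:
    """Column sum of the weighted matrix: influence the entity receives."""
    return int(weighted.values[:, weighted.index_of(entity_id)].sum())


def _q_product(a: int, p: int) -> int:
    return a * p


def _q_active_sign(a: int, p: int) -> int:
    if a == 0 or p == 0:
        return 0
    return abs(a * p) if a > 0 else -abs(a * p)


Q_CONVENTIONS: dict[str, Callable[[int, int], int]] = {
    "product": _q_product,
    "active_sign": _q_active_sign,
}


def q_value(active: int, passive: int, convention: str = "active_sign") -> int:
    """Cross-linkage index of a factor from its active and passive sums.

    ``|Q| = |AS| * |PS|`` under both conventions. ``product`` is the raw
    product; ``active_sign`` (default) gives |AS * PS| the sign of the
    active sum, so that a factor driving the system down always reads as
    risk-reducing even when both sums are negative.
    """
    if convention not in Q_CONVENTIONS:
        raise EngineError(
            f"unknown Q convention {convention!r}; registered: "
            f"{sorted(Q_CONVENTIONS)}"
        )
    return Q_CONVENTIONS[convention](int(active), int(passive))


def total_risk_score(weighted: WeightedMatrix) -> int:
    """Total of all active and passive sums — the overall risk measure.

    Every cell contributes once to a row sum and once to a column sum, so
    the score always equals twice the sum of all weighted cells; the
    identity is asserted.
    """
    cells = int(weighted.values.sum())
    by_sums = int(weighted.values.sum(axis=1).sum() + weighted.values.sum(axis=0).sum())
    assert by_sums == 2 * cells
    return by_sums


@dataclass(frozen=True)
class EntityIndices:
    """Active sum, passive sum, Q-value and factor category for one entity."""

    entity: str
    active_sum: int
    passive_sum: int
    q_value: int
    category: str


CATEGORIES = ("active", "reactive", "critical", "inert")


def classify_factor(
    active: int,
    passive: int,
    as_threshold: Fraction,
    ps_threshold: Fraction,
) -> str:
    """Place one factor into the four-quadrant category scheme.

    Compares |AS| and |PS| against the across-entity thresholds; ties
    resolve as ">=" (a factor exactly at the mean counts as pronounced).
    active: drives more than driven; reactive: driven more than driving;
    critical: both pronounced; inert: both low.
    """
    strong_a = abs(active) >= as_threshold
    strong_p = abs(passive) >= ps_threshold
    if strong_a and strong_p:
        return "critical"
    if strong_a:
        return "active"
    if strong_p:
        return "reactive"
    return "inert"


def _thresholds(
    sums: Sequence[tuple[int, int]], scheme: str, cutoffs: tuple[float, float] | None
) -> tuple[Fraction, Fraction]:
    n = len(sums)
    if scheme == "mean":
        a = Fraction(sum(abs(a) for a, _ in sums), n)
        p = Fraction(sum(abs(p) for _, p in sums), n)
    elif scheme == "median":
        def med(vals: list[int]) -> Fraction:
            vals = sorted(vals)
            m = len(vals) // 2
            if len(vals) % 2:
                return Fraction(vals[m])
            return Fraction(vals[m - 1] + vals[m], 2)

        a = med([abs(x) for x, _ in sums])
        p = med([abs(y) for _, y in sums])
    elif scheme == "fixed":
        if cutoffs is None:
            raise EngineError("fixed classification scheme needs explicit cutoffs")
        a, p = Fraction(cutoffs[0]).limit_denominator(10**6), Fraction(
            cutoffs[1]
        ).limit_denominator(10**6)
    else:
        raise EngineError(
            f"unknown classification scheme {scheme!r}; "
            "registered: ['mean', 'median', 'fixed']"
        )
    return a, p


def classify_all(
    sums: Mapping[str, tuple[int, int]],
    scheme: str = "mean",
    cutoffs: tuple[float, float] | None = None,
) -> dict[str, str]:
    """Classify every entity given its (active, passive) sums.

    The degenerate all-zero system has no interconnection at all, so every
    factor is inert regardless of thresholds.
    """
    if len(sums) < 2:
        raise EngineError("classification needs at least 2 entities")
    pairs = list(sums.values())
    if all(a == 0 and p == 0 for a, p in pairs):
        return {eid: "inert" for eid in sums}
    a_thr, p_thr = _thresholds(pairs, scheme, cutoffs)
    return {
        eid: classify_factor(a, p, a_thr, p_thr) for eid, (a, p) in sums.items()
    }


@dataclass(frozen=True)
class RiskResult:
    """All indices for one assessment of one model."""

    model_id: str
    assessment: Assessment
    indices: tuple[EntityIndices, ...]
    total_score: int
    score_bounds: tuple[int, int]
    band: str
    strategy: str
    q_convention: str

    def index_for(self, entity_id: str) -> EntityIndices:
        for idx in self.indices:
            if idx.entity == entity_id:
                return idx
        raise EngineError(f"unknown entity id {entity_id!r}")


def compute(
    model: ModelSpec,
    assessment: Assessment,
    classification_scheme: str = "mean",
) -> RiskResult:
    """Run the full assessment pipeline and return exact, unrounded indices.

    Orchestrates weighting, active/passive sums, Q-values, factor
    classification and band stratification. Deterministic; stored values are
    never display-rounded.
    """
    weighted = apply_weights(model.matrix, assessment, model)
    order = weighted.entity_order
    sums = {
        eid: (active_sum(weighted, eid), passive_sum(weighted, eid))
        for eid in order
    }
    categories = classify_all(sums, scheme=classification_scheme)
    indices = tuple(
        EntityIndices(
            entity=eid,
            active_sum=sums[eid][0],
            passive_sum=sums[eid][1],
            q_value=q_value(*sums[eid], convention=model.q_convention),
            category=categories[eid],
        )
        for eid in order
    )
    total = total_risk_score(weighted)
    assert total == sum(i.active_sum for i in indices) + sum(
        i.passive_sum for i in indices
    )
    band = _stratify(total, model.score_bounds, model.bands)
    return RiskResult(
        model_id=model.model_id,
        assessment=assessment,
        indices=indices,
        total_score=total,
        score_bounds=tuple(model.score_bounds),
        band=band,
        strategy=model.weighting_strategy,
        q_convention=model.q_convention,
    )
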