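"""Exploration of the admissible weight space.

Exact score bounds and per-index ranges, what-if deltas for single lever
moves, and exhaustive or Monte-Carlo sweeps over assessments. Under the
``row`` weighting strategy the total score is linear in each weight with
nonnegative coefficient ``2 * delta_i * R_i`` (``R_i`` the absolute row sum
of entity i), so its extremes sit at the per-entity domain extremes and the
bounds come out in closed form. Non-linear strategies fall back to
exhaustive corner enumeration, refused above a hard cap.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from rimeda import engine
from rimeda.model import Assessment, ModelSpec, validate_assessment

__all__ = [
    "SweepError",
    "SweepResult",
    "IndexRanges",
    "EXHAUSTIVE_CAP",
    "score_bounds",
    "index_ranges",
    "what_if",
    "sweep",
    "n_admissible",
    "per_entity_leverage",
]

#: largest weight box enumerated exhaustively
EXHAUSTIVE_CAP = 10**6


class SweepError(ValueError):
    """Raised when an exhaustive sweep would exceed the enumeration cap."""


def n_admissible(model: ModelSpec) -> int:
    """Number of admissible assessments (product of domain sizes)."""
    n = 1
    for e in model.entities:
        n *= len(e.weight_domain.admissible)
    return n


def _row_coefficients(model: ModelSpec) -> np.ndarray:
    """Score coefficients under ``row``: score = sum_i 2*delta_i*R_i*w_i."""
    row_abs = np.abs(model.matrix.values).sum(axis=1)
    return 2 * model.deltas * row_abs


def _score_of(model: ModelSpec, assessment: Assessment) -> int:
    weighted = engine.apply_weights(model.matrix, assessment, model)
    return engine.total_risk_score(weighted)


def _iter_assessments(model: ModelSpec) -> Iterator[Assessment]:
    ids = model.entity_ids
    domains = [model.entity(e).weight_domain.admissible for e in ids]
    for combo in itertools.product(*domains):
        yield Assessment(dict(zip(ids, combo)), label="sweep")


def score_bounds(
    model: ModelSpec,
) -> tuple[int, int, Assessment, Assessment]:
    """Exact (min, max) of the total score with achieving assessments.

    Linear strategies are solved per entity at the domain extremes; other
    strategies enumerate the full weight box (refused above the cap).
    """
    ids = model.entity_ids
    if model.weighting_strategy == "row":
        a_min = Assessment(
            {e.id: e.weight_domain.min for e in model.entities}, label="minimum"
        )
        a_max = Assessment(
            {e.id: e.weight_domain.max for e in model.entities}, label="maximum"
        )
        coeff = _row_coefficients(model)
        lo = int(sum(c * a_min.weights[e] for c, e in zip(coeff, ids)))
        hi = int(sum(c * a_max.weights[e] for c, e in zip(coeff, ids)))
        return lo, hi, a_min, a_max
    count = n_admissible(model)
    if count > EXHAUSTIVE_CAP:
        raise SweepError(
            f"strategy {model.weighting_strategy!r} needs exhaustive "
            f"enumeration, but {count} admissible assessments exceed the cap "
            f"of {EXHAUSTIVE_CAP}"
        )
    best_lo = best_hi = None
    a_lo = a_hi = None
    for a in _iter_assessments(model):
        s = _score_of(model, a)
        if best_lo is None or s < best_lo:
            best_lo, a_lo = s, a
        if best_hi is None or s > best_hi:
            best_hi, a_hi = s, a
    return best_lo, best_hi, a_lo, a_hi


@dataclass(frozen=True)
class IndexRanges:
    """Extremes of the per-entity indices over all admissible assessments."""

    active: dict[str, tuple[int, int]]
    passive: dict[str, tuple[int, int]]
    q: dict[str, tuple[int, int]]

    @property
    def active_overall(self) -> tuple[int, int]:
        return (min(lo for lo, _ in self.active.values()),
                max(hi for _, hi in self.active.values()))

    @property
    def passive_overall(self) -> tuple[int, int]:
        return (min(lo for lo, _ in self.passive.values()),
                max(hi for _, hi in self.passive.values()))

    @property
    def q_overall(self) -> tuple[int, int]:
        return (min(lo for lo, _ in self.q.values()),
                max(hi for _, hi in self.q.values()))


def _achievable_passive_values(model: ModelSpec, j: int) -> set[int]:
    """All reachable passive sums of column j under ``row`` (sumset DP)."""
    col = np.abs(model.matrix.values[:, j])
    deltas = model.deltas
    sums = {0}
    for i, e in enumerate(model.entities):
        c = int(deltas[i] * col[i])
        if c == 0:
            continue
        sums = {s + c * w for s in sums for w in e.weight_domain.admissible}
    return sums


def index_ranges(model: ModelSpec) -> IndexRanges:
    """Exact per-entity ranges of AS, PS and Q over admissible assessments.

    Under ``row``, AS(i) depends only on w_i while PS(i) is independent of
    w_i (zero diagonal), so Q extremes follow from the achievable AS values
    crossed with the achievable PS set of the column.
    """
    ids = model.entity_ids
    if model.weighting_strategy != "row":
        count = n_admissible(model)
        if count > EXHAUSTIVE_CAP:
            raise SweepError(
                f"index_ranges for strategy {model.weighting_strategy!r} "
                f"requires enumerating {count} assessments, above the cap of "
                f"{EXHAUSTIVE_CAP}"
            )
        active = {e: [None, None] for e in ids}
        passive = {e: [None, None] for e in ids}
        qrange = {e: [None, None] for e in ids}
        for a in _iter_assessments(model):
            w = engine.apply_weights(model.matrix, a, model)
            for eid in ids:
                asum = engine.active_sum(w, eid)
                psum = engine.passive_sum(w, eid)
                qv = engine.q_value(asum, psum, model.q_convention)
                for store, v in ((active, asum), (passive, psum), (qrange, qv)):
                    lo, hi = store[eid]
                    store[eid] = [v if lo is None else min(lo, v),
                                  v if hi is None else max(hi, v)]
        return IndexRanges(
            {e: tuple(v) for e, v in active.items()},
            {e: tuple(v) for e, v in passive.items()},
            {e: tuple(v) for e, v in qrange.items()},
        )

    row_abs = np.abs(model.matrix.values).sum(axis=1)
    active: dict[str, tuple[int, int]] = {}
    passive: dict[str, tuple[int, int]] = {}
    qrange: dict[str, tuple[int, int]] = {}
    for i, ent in enumerate(model.entities):
        coeff = int(model.deltas[i] * row_abs[i])
        as_values = {coeff * w for w in ent.weight_domain.admissible}
        ps_values = _achievable_passive_values(model, i)
        active[ent.id] = (min(as_values), max(as_values))
        passive[ent.id] = (min(ps_values), max(ps_values))
        qs = {
            engine.q_value(a, p, model.q_convention)
            for a in as_values
            for p in ps_values
        }
        qrange[ent.id] = (min(qs), max(qs))
    return IndexRanges(active, passive, qrange)


def per_entity_leverage(model: ModelSpec) -> dict[str, int]:
    """Max score change achievable by varying only one entity's weight.

    Under ``row`` this is exactly ``2 * delta_i * R_i * (max - min)`` of the
    entity's domain; for other strategies it is measured from the
    all-domain-minima reference assessment.
    """
    if model.weighting_strategy == "row":
        coeff = _row_coefficients(model)
        return {
            e.id: int(c * (e.weight_domain.max - e.weight_domain.min))
            for c, e in zip(coeff, model.entities)
        }
    base = Assessment(
        {e.id: e.weight_domain.min for e in model.entities}, label="reference"
    )
    out: dict[str, int] = {}
    for e in model.entities:
        scores = [
            _score_of(model, base.replaced({e.id: w}))
            for w in e.weight_domain.admissible
        ]
        out[e.id] = int(max(scores) - min(scores))
    return out


def what_if(
    model: ModelSpec, assessment: Assessment, changes: Mapping[str, int]
) -> tuple[engine.RiskResult, int]:
    """Recompute with substituted weights; returns (new result, score delta)."""
    validate_assessment(assessment, model).raise_if_invalid()
    changed = assessment.replaced(changes)
    validate_assessment(changed, model).raise_if_invalid()
    old = _score_of(model, assessment)
    new = engine.compute(model, changed)
    return new, int(new.total_score - old)


@dataclass(frozen=True)
class SweepResult:
    """Summary of a sweep over (a sample of) the admissible weight box."""

    mode: str
    n_evaluated: int
    seed: int | None
    score_min: int
    score_max: int
    min_assessment: dict[str, int]
    max_assessment: dict[str, int]
    histogram_edges: tuple[float, ...]
    histogram_counts: tuple[int, ...]
    per_entity_leverage: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_evaluated": self.n_evaluated,
            "seed": self.seed,
            "score_min": self.score_min,
            "score_max": self.score_max,
            "min_assessment": dict(self.min_assessment),
            "max_assessment": dict(self.max_assessment),
            "histogram": {
                "edges": list(self.histogram_edges),
                "counts": list(self.histogram_counts),
            },
            "per_entity_leverage": dict(self.per_entity_leverage),
        }


def sweep(
    model: ModelSpec,
    mode: str = "monte_carlo",
    n: int = 10_000,
    seed: int | None = 0,
    n_bins: int = 20,
) -> SweepResult:
    """Evaluate the score over the weight box, exhaustively or by sampling.

    Monte-Carlo draws each weight uniformly from its admissible set,
    independently across entities, driven by one integer seed; results are
    deterministic given (mode, n, seed). Exhaustive mode covers every
    admissible assessment and is refused above ``EXHAUSTIVE_CAP`` with
    guidance to sample instead.
    """
    scores: list[int] = []
    best: dict[str, tuple[int, Assessment]] = {}

    def consider(s: int, a: Assessment) -> None:
        scores.append(s)
        if "min" not in best or s < best["min"][0]:
            best["min"] = (s, a)
        if "max" not in best or s > best["max"][0]:
            best["max"] = (s, a)

    if mode == "exhaustive":
        count = n_admissible(model)
        if count > EXHAUSTIVE_CAP:
            raise SweepError(
                f"{count} admissible assessments exceed the exhaustive cap of "
                f"{EXHAUSTIVE_CAP}; use mode='monte_carlo' with a sample size"
            )
        for a in _iter_assessments(model):
            consider(_score_of(model, a), a)
        n_eval, used_seed = count, None
    elif mode == "monte_carlo":
        if n < 1:
            raise SweepError("monte_carlo sweep needs n >= 1")
        if seed is None:
            raise SweepError("monte_carlo sweep needs a seed for determinism")
        rng = np.random.default_rng(seed)
        ids = model.entity_ids
        domains = [model.entity(e).weight_domain.admissible for e in ids]
        for _ in range(n):
            a = Assessment(
                {
                    eid: int(dom[rng.integers(len(dom))])
                    for eid, dom in zip(ids, domains)
                },
                label="sample",
            )
            consider(_score_of(model, a), a)
        n_eval, used_seed = n, int(seed)
    else:
        raise SweepError(f"unknown sweep mode {mode!r}")

    lo, hi = best["min"][0], best["max"][0]
    span = (lo, hi if hi > lo else lo + 1)
    counts, edges = np.histogram(scores, bins=n_bins, range=span)
    return SweepResult(
        mode=mode,
        n_evaluated=n_eval,
        seed=used_seed,
        score_min=lo,
        score_max=hi,
        min_assessment=dict(best["min"][1].weights),
        max_assessment=dict(best["max"][1].weights),
        histogram_edges=tuple(float(e) for e in edges),
        histogram_counts=tuple(int(c) for c in counts),
        per_entity_leverage=per_entity_leverage(model),
    )
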