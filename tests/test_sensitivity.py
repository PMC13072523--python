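"""Score bounds, index ranges, what-if deltas and sweeps against brute force."""
import itertools

import pytest

from rimeda import Assessment, compute, fixtures, sensitivity
from rimeda.model import (
    EntityDef,
    InfluenceMatrix,
    ModelError,
    ModelSpec,
    Perspective,
    WeightDomain,
)
from rimeda.sensitivity import (
    EXHAUSTIVE_CAP,
    SweepError,
    index_ranges,
    n_admissible,
    per_entity_leverage,
    score_bounds,
    sweep,
    what_if,
)

from conftest import naive_sums


def brute_force_assessments(model):
    ids = model.entity_ids
    domains = [model.entity(e).weight_domain.admissible for e in ids]
    for combo in itertools.product(*domains):
        yield Assessment(dict(zip(ids, combo)))


def brute_force_score(model, assessment):
    active, passive = naive_sums(model, assessment)
    return sum(active.values()) + sum(passive.values())


class TestScoreBounds:
    def test_toy3_matches_exhaustive_enumeration(self, toy3):
        scores = [brute_force_score(toy3, a) for a in brute_force_assessments(toy3)]
        assert len(scores) == 48
        lo, hi, a_lo, a_hi = score_bounds(toy3)
        assert (lo, hi) == (min(scores), max(scores)) == (-8, 84)
        assert brute_force_score(toy3, a_lo) == lo
        assert brute_force_score(toy3, a_hi) == hi

    def test_random_models_analytic_equals_exhaustive(self):
        for seed in range(20):
            model = fixtures.random_model(
                fixtures.GeneratorConfig(n_entities=2 + seed % 4, seed=seed)
            )
            scores = [
                brute_force_score(model, a) for a in brute_force_assessments(model)
            ]
            lo, hi, _, _ = score_bounds(model)
            assert (lo, hi) == (min(scores), max(scores))

    def test_single_entity_zero_domain(self):
        model = ModelSpec(
            model_id="single",
            perspectives=(Perspective("P", "p"),),
            entities=(EntityDef("A", "a", "P", WeightDomain((0,))),),
            matrix=InfluenceMatrix(("A",), [[0]]),
        )
        lo, hi, _, _ = score_bounds(model)
        assert (lo, hi) == (0, 0)

    def test_row_col_strategy_uses_enumeration(self, toy3):
        model = ModelSpec(
            model_id="toy3-rc",
            perspectives=toy3.perspectives,
            entities=toy3.entities,
            matrix=toy3.matrix,
            weighting_strategy="row_col",
        )
        lo, hi, a_lo, a_hi = score_bounds(model)
        scores = {}
        for a in brute_force_assessments(model):
            active, passive = naive_sums(model, a, "row_col")
            scores[tuple(sorted(a.weights.items()))] = sum(active.values()) + sum(
                passive.values()
            )
        assert lo == min(scores.values())
        assert hi == max(scores.values())


class TestIndexRanges:
    def test_toy3_matches_exhaustive(self, toy3):
        seen_as = {e: set() for e in toy3.entity_ids}
        seen_ps = {e: set() for e in toy3.entity_ids}
        seen_q = {e: set() for e in toy3.entity_ids}
        from rimeda import q_value

        for a in brute_force_assessments(toy3):
            active, passive = naive_sums(toy3, a)
            for e in toy3.entity_ids:
                seen_as[e].add(active[e])
                seen_ps[e].add(passive[e])
                seen_q[e].add(q_value(active[e], passive[e], toy3.q_convention))
        ranges = index_ranges(toy3)
        for e in toy3.entity_ids:
            assert ranges.active[e] == (min(seen_as[e]), max(seen_as[e]))
            assert ranges.passive[e] == (min(seen_ps[e]), max(seen_ps[e]))
            assert ranges.q[e] == (min(seen_q[e]), max(seen_q[e]))

    def test_random_models_match_exhaustive(self):
        from rimeda import q_value

        for seed in range(10):
            model = fixtures.random_model(
                fixtures.GeneratorConfig(n_entities=2 + seed % 3, seed=seed)
            )
            ranges = index_ranges(model)
            lo_as = {e: None for e in model.entity_ids}
            for a in brute_force_assessments(model):
                active, passive = naive_sums(model, a)
                for e in model.entity_ids:
                    assert ranges.active[e][0] <= active[e] <= ranges.active[e][1]
                    assert ranges.passive[e][0] <= passive[e] <= ranges.passive[e][1]
                    q = q_value(active[e], passive[e], model.q_convention)
                    assert ranges.q[e][0] <= q <= ranges.q[e][1]

    def test_all_zero_matrix_gives_zero_ranges(self):
        model = ModelSpec(
            model_id="zero",
            perspectives=(Perspective("P", "p"),),
            entities=(
                EntityDef("A", "a", "P", WeightDomain((0, 1, 2, 3))),
                EntityDef("B", "b", "P", WeightDomain((1, 2, 3))),
            ),
            matrix=InfluenceMatrix(("A", "B"), [[0, 0], [0, 0]]),
        )
        ranges = index_ranges(model)
        assert ranges.active_overall == (0, 0)
        assert ranges.passive_overall == (0, 0)
        assert ranges.q_overall == (0, 0)


class TestWhatIf:
    def test_toy3_single_lever_delta(self, toy3, toy3_assessment):
        new, delta = what_if(toy3, toy3_assessment, {"X2": 3})
        assert delta == 20
        assert new.total_score == 36

    def test_identity_change(self, toy3, toy3_assessment):
        new, delta = what_if(toy3, toy3_assessment, {"X2": 1})
        assert delta == 0
        assert new.total_score == 16

    def test_protective_swing_is_negative(self, toy3):
        base = Assessment({"X1": 2, "X2": 1, "X3": 1})
        _, delta = what_if(toy3, base, {"X3": -3})
        assert delta == -24  # 2 * R(X3)=3 * (-3 - 1)

    def test_inadmissible_change_rejected(self, toy3, toy3_assessment):
        with pytest.raises(ModelError, match="X2"):
            what_if(toy3, toy3_assessment, {"X2": 0})

    def test_consistent_with_compute(self, toy3, toy3_assessment):
        new, _ = what_if(toy3, toy3_assessment, {"X1": 3, "X3": 2})
        direct = compute(toy3, toy3_assessment.replaced({"X1": 3, "X3": 2}))
        assert new == direct


class TestLeverage:
    def test_toy3_closed_form(self, toy3):
        assert per_entity_leverage(toy3) == {"X1": 36, "X2": 20, "X3": 36}

    def test_matches_observed_single_entity_swings(self):
        model = fixtures.random_model(fixtures.GeneratorConfig(n_entities=4, seed=9))
        lev = per_entity_leverage(model)
        base = Assessment({e.id: e.weight_domain.min for e in model.entities})
        for e in model.entities:
            swings = [
                brute_force_score(model, base.replaced({e.id: w}))
                for w in e.weight_domain.admissible
            ]
            assert lev[e.id] == max(swings) - min(swings)


class TestSweep:
    def test_exhaustive_toy3(self, toy3):
        result = sweep(toy3, mode="exhaustive")
        assert result.n_evaluated == 48
        assert sum(result.histogram_counts) == 48
        lo, hi, _, _ = score_bounds(toy3)
        assert (result.score_min, result.score_max) == (lo, hi)

    def test_monte_carlo_deterministic(self, toy3):
        a = sweep(toy3, mode="monte_carlo", n=200, seed=42)
        b = sweep(toy3, mode="monte_carlo", n=200, seed=42)
        assert a == b
        assert a.to_dict() == b.to_dict()

    def test_monte_carlo_bracketed_by_bounds(self, toy3):
        lo, hi, _, _ = score_bounds(toy3)
        result = sweep(toy3, mode="monte_carlo", n=500, seed=7)
        assert lo <= result.score_min <= result.score_max <= hi

    def test_histogram_mass_equals_n(self, toy3):
        result = sweep(toy3, mode="monte_carlo", n=333, seed=1)
        assert sum(result.histogram_counts) == 333

    def test_exhaustive_refused_over_cap(self, canonical):
        assert n_admissible(canonical) == 11_943_936 > EXHAUSTIVE_CAP
        with pytest.raises(SweepError, match="monte_carlo"):
            sweep(canonical, mode="exhaustive")

    def test_unknown_mode(self, toy3):
        with pytest.raises(SweepError, match="mode"):
            sweep(toy3, mode="walk")

    def test_monte_carlo_needs_seed_and_n(self, toy3):
        with pytest.raises(SweepError, match="seed"):
            sweep(toy3, mode="monte_carlo", n=10, seed=None)
        with pytest.raises(SweepError, match="n >= 1"):
            sweep(toy3, mode="monte_carlo", n=0, seed=1)

    def test_min_max_assessments_recorded_and_admissible(self, toy3):
        result = sweep(toy3, mode="exhaustive")
        from rimeda import validate_assessment

        for weights, score in (
            (result.min_assessment, result.score_min),
            (result.max_assessment, result.score_max),
        ):
            a = Assessment(weights)
            assert validate_assessment(a, toy3).ok
            assert brute_force_score(toy3, a) == score
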