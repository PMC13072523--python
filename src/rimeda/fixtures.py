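"""Deterministic generators of toy models and random admissible inputs.

Everything here is a pure function of its configuration and seed, and every
generated artefact passes the model module's full validation, so the rest of
the package is testable without any curated model file.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rimeda.model import (
    Assessment,
    EntityDef,
    InfluenceMatrix,
    ModelError,
    ModelSpec,
    Perspective,
    WeightDomain,
)

__all__ = ["GeneratorConfig", "toy3", "four_category_model", "random_model",
           "random_assessment"]

#: canonical weight domains to draw from when generating entities
DEFAULT_DOMAIN_PALETTE = (
    WeightDomain((0, 1, 2, 3)),
    WeightDomain((1, 2, 3)),
    WeightDomain((-3, 1, 2, 3)),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random model generator; all draws are seed-driven."""

    n_entities: int = 5
    cell_magnitude_probs: tuple[float, float, float, float] = (0.4, 0.25, 0.2, 0.15)
    negative_cell_prob: float = 0.2
    domain_palette: tuple[WeightDomain, ...] = DEFAULT_DOMAIN_PALETTE
    double_prob: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 2:
            raise ModelError("a model needs at least 2 entities")
        probs = tuple(float(p) for p in self.cell_magnitude_probs)
        if len(probs) != 4 or any(p < 0 for p in probs) or sum(probs) == 0:
            raise ModelError(
                "cell_magnitude_probs must be 4 nonnegative numbers over "
                "magnitudes {0,1,2,3}"
            )
        total = sum(probs)
        object.__setattr__(
            self, "cell_magnitude_probs", tuple(p / total for p in probs)
        )
        if not 0 <= self.negative_cell_prob <= 1:
            raise ModelError("negative_cell_prob must be in [0, 1]")
        if not 0 <= self.double_prob <= 1:
            raise ModelError("double_prob must be in [0, 1]")


def toy3() -> ModelSpec:
    """Fixed 3-entity toy model used throughout the test oracles.

    X1 has domain {0..3} and double impact, X2 {1..3}, X3 {-3, 1..3}
    (a protective, technical-style factor). Matrix rows:
    X1 [0, 2, -1], X2 [3, 0, 2], X3 [-2, 1, 0]; ``row`` weighting.
    """
    entities = (
        EntityDef("X1", "toy driver", "X", WeightDomain((0, 1, 2, 3)),
                  double=True, controllable=True,
                  countermeasures=("generalise the driver attribute",)),
        EntityDef("X2", "toy amplifier", "X", WeightDomain((1, 2, 3)),
                  controllable=False),
        EntityDef("X3", "toy safeguard", "X", WeightDomain((-3, 1, 2, 3)),
                  controllable=True,
                  countermeasures=("maintain the safeguard",)),
    )
    matrix = InfluenceMatrix(
        ("X1", "X2", "X3"),
        [[0, 2, -1], [3, 0, 2], [-2, 1, 0]],
    )
    return ModelSpec(
        model_id="TOY3",
        perspectives=(Perspective("X", "toy perspective"),),
        entities=entities,
        matrix=matrix,
        weighting_strategy="row",
        q_convention="active_sign",
    )


def four_category_model() -> tuple[ModelSpec, Assessment]:
    """4-entity fixture whose unit-weight indices hit all four categories.

    With all weights 1 the absolute row/column sums separate cleanly around
    their means, yielding one active, one reactive, one critical and one
    inert factor.
    """
    # rows chosen so |AS| = (6, 1, 6, 0) and |PS| = (1, 6, 4, 2):
    # both means 3.25 -> Y1 active, Y2 reactive, Y3 critical, Y4 inert
    matrix = InfluenceMatrix(
        ("Y1", "Y2", "Y3", "Y4"),
        [
            [0, 3, 3, 0],
            [0, 0, 1, 0],
            [1, 3, 0, 2],
            [0, 0, 0, 0],
        ],
    )
    entities = tuple(
        EntityDef(f"Y{i}", f"category probe {i}", "Y", WeightDomain((1,)))
        for i in range(1, 5)
    )
    spec = ModelSpec(
        model_id="FOURCAT",
        perspectives=(Perspective("Y", "category probe"),),
        entities=entities,
        matrix=matrix,
    )
    weights = Assessment({e.id: 1 for e in entities}, label="unit")
    return spec, weights


def random_model(cfg: GeneratorConfig) -> ModelSpec:
    """Generate a valid random model; identical config gives identical output."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_entities
    magnitudes = rng.choice(4, size=(n, n), p=cfg.cell_magnitude_probs)
    signs = np.where(rng.random((n, n)) < cfg.negative_cell_prob, -1, 1)
    values = magnitudes * signs
    np.fill_diagonal(values, 0)
    ids = tuple(f"G{i + 1}" for i in range(n))
    entities = tuple(
        EntityDef(
            id=eid,
            name=f"generated factor {eid}",
            perspective="G",
            weight_domain=cfg.domain_palette[
                int(rng.integers(len(cfg.domain_palette)))
            ],
            double=bool(rng.random() < cfg.double_prob),
            controllable=bool(rng.random() < 0.5),
        )
        for eid in ids
    )
    return ModelSpec(
        model_id=f"RANDOM-{cfg.seed}-{n}",
        perspectives=(Perspective("G", "generated"),),
        entities=entities,
        matrix=InfluenceMatrix(ids, values),
        weighting_strategy="row",
    )


def random_assessment(model: ModelSpec, seed: int) -> Assessment:
    """Draw each weight uniformly from its entity's admissible set."""
    rng = np.random.default_rng(seed)
    weights = {
        e.id: int(e.weight_domain.admissible[
            rng.integers(len(e.weight_domain.admissible))
        ])
        for e in model.entities
    }
    return Assessment(weights, label=f"random-{seed}")
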