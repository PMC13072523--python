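import pytest

from rimeda import Assessment, canonical_model, fixtures


@pytest.fixture(scope="session")
def toy3():
    return fixtures.toy3()


@pytest.fixture()
def toy3_assessment():
    return Assessment({"X1": 2, "X2": 1, "X3": -3}, label="hand oracle")


@pytest.fixture(scope="session")
def canonical():
    return canonical_model()


def naive_weighted_cells(model, assessment, strategy=None):
    """Independent scalar-loop recomputation of the weighted matrix.

    Deliberately avoids numpy and the engine's code path: plain dict/loop
    arithmetic over the matrix definition.
    """
    strategy = strategy or model.weighting_strategy
    ids = list(model.matrix.entity_order)
    deltas = {e.id: (2 if e.double else 1) for e in model.entities}
    cells = {}
    for i, ri in enumerate(ids):
        for j, rj in enumerate(ids):
            v = abs(int(model.matrix.values[i][j]))
            c = assessment.weights[ri] * deltas[ri] * v
            if strategy == "row_col":
                c *= assessment.weights[rj] * deltas[rj]
            cells[(ri, rj)] = c
    return cells


def naive_sums(model, assessment, strategy=None):
    """Active/passive sums from the scalar-loop weighted cells."""
    cells = naive_weighted_cells(model, assessment, strategy)
    ids = list(model.matrix.entity_order)
    active = {e: sum(cells[(e, j)] for j in ids) for e in ids}
    passive = {e: sum(cells[(i, e)] for i in ids) for e in ids}
    return active, passive
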