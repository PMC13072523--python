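"""Model loading, validation and serialisation round trips."""
import numpy as np
import pytest

from rimeda import (
    Assessment,
    InfluenceMatrix,
    ModelError,
    ModelSpec,
    Perspective,
    WeightDomain,
    fixtures,
    load_model,
    matrix_from_csv,
    matrix_to_csv,
    save_model,
    validate_assessment,
)
from rimeda.model import CANONICAL_ENTITY_IDS, EntityDef, load_assessment, save_assessment

CANONICAL_DOMAINS = {
    "D1": (0, 1, 2, 3), "D2": (0, 1, 2, 3), "D3": (0, 1, 2, 3),
    "W1": (1, 2, 3), "W2": (1, 2, 3), "W3": (0, 1, 2, 3), "W4": (1, 2, 3),
    "A1": (1, 2, 3), "A2": (1, 2, 3), "A3": (1, 2, 3),
    "TO1": (-3, 1, 2, 3), "TO2": (-3, 1, 2, 3), "TO3": (-3, 1, 2, 3),
}


class TestCanonicalModel:
    def test_structure(self, canonical):
        assert canonical.entity_ids == CANONICAL_ENTITY_IDS
        assert len(canonical.perspectives) == 4
        assert [p.id for p in canonical.perspectives] == ["D", "W", "A", "TO"]
        assert canonical.matrix.n == 13

    def test_weight_domains_match_factor_tables(self, canonical):
        for eid, dom in CANONICAL_DOMAINS.items():
            assert canonical.entity(eid).weight_domain.admissible == dom

    def test_doubling_flags(self, canonical):
        doubled = {e.id for e in canonical.entities if e.double}
        assert doubled == {"D1", "TO2"}

    def test_controllability_defaults(self, canonical):
        for e in canonical.entities:
            assert e.controllable == (e.perspective in ("D", "TO"))

    def test_matrix_cells_in_range_zero_diagonal(self, canonical):
        v = canonical.matrix.values
        assert v.min() >= -3 and v.max() <= 3
        assert not np.diag(v).any()


class TestWeightDomain:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("0-3", (0, 1, 2, 3)),
            ("1-3", (1, 2, 3)),
            ("-3; 1-3", (-3, 1, 2, 3)),
            ([3, 1, 2], (1, 2, 3)),
            ("2", (2,)),
        ],
    )
    def test_parse(self, text, expected):
        assert WeightDomain.parse(text).admissible == expected

    @pytest.mark.parametrize("bad", [[], [5], [-4], "junk", "3-1"])
    def test_rejects(self, bad):
        with pytest.raises(ModelError):
            WeightDomain.parse(bad)


class TestInfluenceMatrix:
    def test_rejects_cell_out_of_range(self):
        with pytest.raises(ModelError, match=r"out of \[-3, 3\]"):
            InfluenceMatrix(("A", "B"), [[0, 5], [1, 0]])

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(ModelError, match="diagonal"):
            InfluenceMatrix(("A", "B"), [[1, 2], [2, 0]])

    def test_rejects_non_square(self):
        with pytest.raises(ModelError, match="square"):
            InfluenceMatrix(("A", "B"), [[0, 1, 2], [1, 0, 2]])

    def test_rejects_order_mismatch(self):
        with pytest.raises(ModelError):
            InfluenceMatrix(("A", "B", "C"), [[0, 1], [1, 0]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ModelError, match="duplicate"):
            InfluenceMatrix(("A", "A"), [[0, 1], [1, 0]])

    def test_rejects_non_integer_cells(self):
        with pytest.raises(ModelError, match="non-integer"):
            InfluenceMatrix(("A", "B"), [[0, 1.5], [1, 0]])

    def test_row_column_strengths(self, toy3):
        assert [toy3.matrix.row_strength(e) for e in ("X1", "X2", "X3")] == [3, 5, 3]
        assert toy3.matrix.column_strength("X1") == 5


class TestMatrixCsv:
    def test_toy3_read(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",X1,X2,X3\nX1,0,2,-1\nX2,3,0,2\nX3,-2,1,0\n")
        m = matrix_from_csv(p)
        assert m.entity_order == ("X1", "X2", "X3")
        assert m.values.tolist() == [[0, 2, -1], [3, 0, 2], [-2, 1, 0]]

    def test_round_trip_bit_exact(self, tmp_path, canonical):
        p = tmp_path / "canon.csv"
        matrix_to_csv(canonical.matrix, p)
        assert matrix_from_csv(p) == canonical.matrix

    def test_rejects_diagonal_one(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",A,B\nA,1,2\nB,2,0\n")
        with pytest.raises(ModelError, match="diagonal"):
            matrix_from_csv(p)

    def test_rejects_non_integer_cell_with_coordinates(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",A,B\nA,0,x\nB,2,0\n")
        with pytest.raises(ModelError, match="'A'.*'B'"):
            matrix_from_csv(p)

    def test_rejects_header_mismatch(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",A,B\nA,0,1\nC,2,0\n")
        with pytest.raises(ModelError, match="do not match"):
            matrix_from_csv(p)


class TestModelRoundTrip:
    @pytest.mark.parametrize("make", [fixtures.toy3, lambda: fixtures.random_model(
        fixtures.GeneratorConfig(n_entities=6, seed=7))])
    def test_save_load_identity(self, tmp_path, make):
        model = make()
        p = tmp_path / "model.yaml"
        save_model(model, p)
        assert load_model(p) == model

    def test_canonical_round_trip(self, tmp_path, canonical):
        p = tmp_path / "model.yaml"
        save_model(canonical, p)
        assert load_model(p) == canonical

    def test_score_bounds_computed_on_load(self, tmp_path, toy3):
        p = tmp_path / "model.yaml"
        save_model(toy3, p)
        assert load_model(p).score_bounds == (-8, 84)

    def test_stated_bounds_must_match_computed(self, tmp_path, toy3):
        p = tmp_path / "model.yaml"
        save_model(toy3, p)
        text = p.read_text().replace("- -8\n- 84", "- 28\n- 1670")
        p.write_text(text)
        with pytest.raises(ModelError, match="score_bounds"):
            load_model(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ModelError, match="not found"):
            load_model(tmp_path / "nope.yaml")

    def test_matrix_entity_mismatch_names_ids(self, tmp_path, toy3):
        p = tmp_path / "model.yaml"
        save_model(toy3, p)
        p.write_text(p.read_text().replace("- X3\n", "- X9\n", 1))
        with pytest.raises(ModelError, match="X9"):
            load_model(p)

    def test_assessment_round_trip(self, tmp_path, toy3_assessment):
        p = tmp_path / "a.yaml"
        save_assessment(toy3_assessment, p)
        assert load_assessment(p) == toy3_assessment


class TestModelSpecInvariants:
    def test_rejects_unknown_perspective(self):
        with pytest.raises(ModelError, match="perspective"):
            ModelSpec(
                model_id="bad",
                perspectives=(Perspective("P", "p"),),
                entities=(
                    EntityDef("A", "a", "P", WeightDomain((1,))),
                    EntityDef("B", "b", "Q", WeightDomain((1,))),
                ),
                matrix=InfluenceMatrix(("A", "B"), [[0, 1], [1, 0]]),
            )

    def test_rejects_matrix_order_mismatch(self):
        with pytest.raises(ModelError, match="order"):
            ModelSpec(
                model_id="bad",
                perspectives=(Perspective("P", "p"),),
                entities=(
                    EntityDef("A", "a", "P", WeightDomain((1,))),
                    EntityDef("B", "b", "P", WeightDomain((1,))),
                ),
                matrix=InfluenceMatrix(("B", "A"), [[0, 1], [1, 0]]),
            )


class TestValidateAssessment:
    def test_valid_minimal(self, canonical):
        weights = {e.id: e.weight_domain.min for e in canonical.entities}
        weights["D1"] = 2
        assert validate_assessment(Assessment(weights), canonical).ok

    def test_inadmissible_weight_names_domain(self, canonical):
        weights = {e.id: e.weight_domain.min for e in canonical.entities}
        weights["W1"] = 0
        report = validate_assessment(Assessment(weights), canonical)
        assert not report.ok
        assert any("W1 admits 1..3" in f for f in report.findings)

    def test_uncovered_entity(self, canonical):
        weights = {e.id: e.weight_domain.min for e in canonical.entities}
        del weights["TO3"]
        report = validate_assessment(Assessment(weights), canonical)
        assert any("uncovered entity TO3" in f for f in report.findings)

    def test_unknown_entity(self, toy3):
        report = validate_assessment(
            Assessment({"X1": 1, "X2": 1, "X3": 1, "X9": 1}), toy3
        )
        assert any("unknown entity X9" in f for f in report.findings)
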