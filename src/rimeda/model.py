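"""Declarative domain model for influence-matrix risk assessment.

A model bundles the four risk perspectives (data, knowledge, attacker,
technical/organisational), the influencing factors ("entities") with their
admissible weight domains, and a signed integer influence matrix scoring the
directed effect of each factor on every other. An assessment is a data
controller's weight vector over the entities; combining the two is the
engine module's job.

All structures are validated strictly on construction and load: cells and
weights must be integers in [-3, 3], the matrix diagonal is zero
(self-influence is excluded), every weight must be admissible for its
entity, and matrix order must equal entity order.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rimeda.stratify import RiskBandScheme

__all__ = [
    "ModelError",
    "Perspective",
    "WeightDomain",
    "EntityDef",
    "InfluenceMatrix",
    "Assessment",
    "ModelSpec",
    "ValidationReport",
    "load_model",
    "save_model",
    "load_assessment",
    "save_assessment",
    "validate_assessment",
    "matrix_from_csv",
    "matrix_to_csv",
    "canonical_model",
    "CANONICAL_ENTITY_IDS",
]

CELL_MIN, CELL_MAX = -3, 3

#: entity ids of the 13-factor canonical model, in matrix order
CANONICAL_ENTITY_IDS = (
    "D1", "D2", "D3",
    "W1", "W2", "W3", "W4",
    "A1", "A2", "A3",
    "TO1", "TO2", "TO3",
)


class ModelError(ValueError):
    """Schema or structural violation in a model, matrix or assessment."""


@dataclass(frozen=True)
class Perspective:
    """One of the overarching viewpoints a factor belongs to (D/W/A/TO)."""

    id: str
    name: str
    description: str = ""


_RANGE_RE = re.compile(r"^(-?\d+)(?:\s*(?:\.\.|–|—|-)\s*(-?\d+))?$")


@dataclass(frozen=True)
class WeightDomain:
    """Finite set of integer weights an assessor may assign to an entity.

    Canonical domains are {0..3} (influence may be absent), {1..3}
    (influence always present) and {-3, 1..3} (protective factors may score
    a strong deduction).
    """

    admissible: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(sorted(set(int(v) for v in self.admissible)))
        if not vals:
            raise ModelError("weight domain is empty")
        for v in vals:
            if not CELL_MIN <= v <= CELL_MAX:
                raise ModelError(f"weight domain member {v} out of [-3, 3]")
        object.__setattr__(self, "admissible", vals)

    def __contains__(self, w: object) -> bool:
        return isinstance(w, int) and w in self.admissible

    @property
    def min(self) -> int:
        return self.admissible[0]

    @property
    def max(self) -> int:
        return self.admissible[-1]

    @classmethod
    def parse(cls, spec) -> "WeightDomain":
        """Build from a list of ints or a compact string like ``"-3; 1-3"``."""
        if isinstance(spec, WeightDomain):
            return spec
        if isinstance(spec, (list, tuple)):
            return cls(tuple(int(v) for v in spec))
        members: list[int] = []
        for token in re.split(r"[;,]", str(spec)):
            token = token.strip()
            if not token:
                continue
            m = _RANGE_RE.match(token)
            if not m:
                raise ModelError(f"cannot parse weight-domain token {token!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise ModelError(f"descending weight-domain range {token!r}")
            members.extend(range(lo, hi + 1))
        return cls(tuple(members))

    def to_text(self) -> str:
        runs: list[tuple[int, int]] = []
        for v in self.admissible:
            if runs and v == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], v)
            else:
                runs.append((v, v))
        return "; ".join(f"{a}" if a == b else f"{a}..{b}" for a, b in runs)


def _default_controllable(perspective: str) -> bool:
    # data and technical/organisational factors are under the controller's
    # influence; world knowledge and attackers are not
    return perspective in ("D", "TO")


@dataclass(frozen=True)
class EntityDef:
    """One influencing factor: id, perspective, weight domain, flags, guidance."""

    id: str
    name: str
    perspective: str
    weight_domain: WeightDomain
    double: bool = False
    controllable: bool | None = None
    rubric: tuple[str, ...] = field(default_factory=tuple)
    countermeasures: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.controllable is None:
            object.__setattr__(
                self, "controllable", _default_controllable(self.perspective)
            )
        object.__setattr__(self, "rubric", tuple(self.rubric))
        object.__setattr__(self, "countermeasures", tuple(self.countermeasures))

    @property
    def delta(self) -> int:
        """Point multiplier: 2 for double-impact entities, else 1."""
        return 2 if self.double else 1


class InfluenceMatrix:
    """Square signed integer table of pairwise effect strengths.

    ``values[i, j]`` scores how strongly entity ``entity_order[i]`` affects
    entity ``entity_order[j]``: 0 none, |1| weak, |2| medium, |3| strong; a
    negative sign marks opposing development. The diagonal is fixed at 0.
    """

    def __init__(self, entity_order: Sequence[str], values) -> None:
        order = tuple(str(e) for e in entity_order)
        if len(set(order)) != len(order):
            dupes = sorted({e for e in order if order.count(e) > 1})
            raise ModelError(f"duplicate entity ids in matrix order: {dupes}")
        arr = np.asarray(values)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ModelError(f"matrix must be square, got shape {arr.shape}")
        if arr.shape[0] != len(order):
            raise ModelError(
                f"matrix is {arr.shape[0]}x{arr.shape[1]} but "
                f"{len(order)} entities are listed"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                i, j = np.argwhere(arr != np.round(arr))[0]
                raise ModelError(
                    f"non-integer cell at ({order[i]}, {order[j]}): {arr[i, j]}"
                )
            arr = arr.astype(np.int64)
        bad = np.argwhere((arr < CELL_MIN) | (arr > CELL_MAX))
        if bad.size:
            i, j = bad[0]
            raise ModelError(
                f"cell out of [-3, 3] at ({order[i]}, {order[j]}): {arr[i, j]}"
            )
        diag = np.argwhere(np.diag(arr) != 0)
        if diag.size:
            i = int(diag[0][0])
            raise ModelError(
                f"nonzero diagonal at ({order[i]}, {order[i]}): {arr[i, i]} "
                "(self-influence is excluded)"
            )
        self.entity_order: tuple[str, ...] = order
        self.values: np.ndarray = arr.astype(np.int64)
        self.values.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.entity_order)

    def index_of(self, entity_id: str) -> int:
        try:
            return self.entity_order.index(entity_id)
        except ValueError:
            raise ModelError(f"unknown entity id {entity_id!r}") from None

    def row_strength(self, entity_id: str) -> int:
        """Sum of absolute values in the entity's row (unweighted active sum)."""
        return int(np.abs(self.values[self.index_of(entity_id)]).sum())

    def column_strength(self, entity_id: str) -> int:
        """Sum of absolute values in the entity's column (unweighted passive sum)."""
        return int(np.abs(self.values[:, self.index_of(entity_id)]).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.entity_order, columns=self.entity_order
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfluenceMatrix):
            return NotImplemented
        return self.entity_order == other.entity_order and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen-enough for use in sets/dicts
        return hash((self.entity_order, self.values.tobytes()))

    def __repr__(self) -> str:
        return f"InfluenceMatrix(n={self.n}, entities={list(self.entity_order)})"


def matrix_from_csv(path) -> InfluenceMatrix:
    """Read an influence matrix from CSV (header row/column of entity ids)."""
    try:
        frame = pd.read_csv(path, index_col=0, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise ModelError(f"cannot parse matrix CSV {path}: {exc}") from exc
    rows = [str(r).strip() for r in frame.index]
    cols = [str(c).strip() for c in frame.columns]
    if rows != cols:
        raise ModelError(
            f"matrix CSV row ids {rows} do not match column ids {cols}"
        )
    for j, col in enumerate(frame.columns):
        series = frame[col]
        if not np.issubdtype(series.dtype, np.number):
            i = int(np.argwhere(pd.to_numeric(series, errors="coerce").isna())[0][0])
            raise ModelError(
                f"non-integer cell at row {rows[i]!r}, column {cols[j]!r}: "
                f"{series.iloc[i]!r}"
            )
    return InfluenceMatrix(rows, frame.to_numpy())


def matrix_to_csv(matrix: InfluenceMatrix, path) -> None:
    """Write a matrix as UTF-8 CSV; round-trips bit-exactly via matrix_from_csv."""
    matrix.to_frame().to_csv(path, index_label="")


@dataclass(frozen=True)
class Assessment:
    """A data controller's weight vector over the model's entities."""

    weights: Mapping[str, int]
    label: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "weights", dict((str(k), int(v)) for k, v in self.weights.items())
        )

    def replaced(self, changes: Mapping[str, int], label: str | None = None) -> "Assessment":
        new = dict(self.weights)
        new.update({str(k): int(v) for k, v in changes.items()})
        return Assessment(new, label=label if label is not None else self.label,
                          notes=self.notes)


@dataclass(frozen=True)
class ValidationReport:
    """Findings from validating an assessment against a model; empty = valid."""

    findings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:
        return self.ok

    def raise_if_invalid(self) -> None:
        if self.findings:
            raise ModelError("invalid assessment: " + "; ".join(self.findings))


@dataclass(frozen=True)
class ModelSpec:
    """A complete, validated risk model ready for assessment."""

    model_id: str
    perspectives: tuple[Perspective, ...]
    entities: tuple[EntityDef, ...]
    matrix: InfluenceMatrix
    weighting_strategy: str = "row"
    q_convention: str = "active_sign"
    bands: RiskBandScheme = field(default_factory=RiskBandScheme)
    score_bounds: tuple[int, int] | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entities]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"duplicate entity ids: {dupes}")
        if tuple(ids) != self.matrix.entity_order:
            raise ModelError(
                f"matrix order {list(self.matrix.entity_order)} does not "
                f"match entity list {ids}"
            )
        known = {p.id for p in self.perspectives}
        for e in self.entities:
            if e.perspective not in known:
                raise ModelError(
                    f"entity {e.id} references unknown perspective "
                    f"{e.perspective!r}"
                )
        if self.score_bounds is None:
            from rimeda.sensitivity import score_bounds as _bounds

            lo, hi, _, _ = _bounds(self)
            object.__setattr__(self, "score_bounds", (lo, hi))

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.entities)

    def entity(self, entity_id: str) -> EntityDef:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise ModelError(f"unknown entity id {entity_id!r}")

    @property
    def deltas(self) -> np.ndarray:
        return np.array([e.delta for e in self.entities], dtype=np.int64)

    def domains(self) -> dict[str, WeightDomain]:
        return {e.id: e.weight_domain for e in self.entities}


def validate_assessment(assessment: Assessment, model: ModelSpec) -> ValidationReport:
    """Check coverage and admissibility; findings are human-readable lines."""
    findings: list[str] = []
    ids = set(model.entity_ids)
    for eid in model.entity_ids:
        if eid not in assessment.weights:
            findings.append(f"uncovered entity {eid}")
    for eid, w in sorted(assessment.weights.items()):
        if eid not in ids:
            findings.append(f"unknown entity {eid}")
            continue
        dom = model.entity(eid).weight_domain
        if w not in dom:
            findings.append(
                f"weight {w} not admissible for {eid} ({eid} admits {dom.to_text()})"
            )
    return ValidationReport(tuple(findings))


# ---------------------------------------------------------------------------
# serialisation

def _entity_to_dict(e: EntityDef) -> dict:
    return {
        "id": e.id,
        "name": e.name,
        "perspective": e.perspective,
        "weight_domain": list(e.weight_domain.admissible),
        "double": e.double,
        "controllable": e.controllable,
        "rubric": list(e.rubric),
        "countermeasures": list(e.countermeasures),
    }


def _bands_to_dict(b: RiskBandScheme) -> dict:
    d = {"mode": b.mode, "n_bands": b.n_bands, "labels": list(b.labels)}
    if b.mode == "custom":
        d["custom_edges"] = [float(e) for e in b.custom_edges]
    return d


def _bands_from_dict(d: Mapping) -> RiskBandScheme:
    labels = d.get("labels")
    n = int(d.get("n_bands", len(labels) if labels else 4))
    if labels is None:
        labels = (list(RiskBandScheme().labels) if n == 4
                  else [f"band{i + 1}" for i in range(n)])
    return RiskBandScheme(
        mode=str(d.get("mode", "equal_width")),
        n_bands=n,
        labels=tuple(str(s) for s in labels),
        custom_edges=tuple(float(e) for e in d.get("custom_edges", ())),
    )


def load_model(path) -> ModelSpec:
    """Load and fully validate a model file (YAML, matrix inline or via CSV).

    The matrix may be given inline as ``matrix: {entities: [...], values:
    [[...], ...]}`` or by reference as ``matrix: {csv: <path relative to the
    model file>}``. Score bounds, if present in the file, are checked against
    the bounds computed from the matrix and weight domains.
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ModelError(f"model file {path} is not a mapping")

    def need(key: str):
        if key not in raw:
            raise ModelError(f"model file {path} misses required key {key!r}")
        return raw[key]

    perspectives = tuple(
        Perspective(str(p["id"]), str(p.get("name", p["id"])),
                    str(p.get("description", "")))
        for p in need("perspectives")
    )
    entities = []
    for ent in need("entities"):
        try:
            entities.append(
                EntityDef(
                    id=str(ent["id"]),
                    name=str(ent.get("name", ent["id"])),
                    perspective=str(ent["perspective"]),
                    weight_domain=WeightDomain.parse(ent["weight_domain"]),
                    double=bool(ent.get("double", False)),
                    controllable=ent.get("controllable"),
                    rubric=tuple(str(s) for s in ent.get("rubric", ())),
                    countermeasures=tuple(
                        str(s) for s in ent.get("countermeasures", ())
                    ),
                )
            )
        except KeyError as exc:
            raise ModelError(
                f"entity entry {ent!r} misses required field {exc}"
            ) from None
    entity_ids = [e.id for e in entities]

    mraw = need("matrix")
    if isinstance(mraw, Mapping) and "csv" in mraw:
        matrix = matrix_from_csv(path.parent / str(mraw["csv"]))
    elif isinstance(mraw, Mapping) and "values" in mraw:
        order = [str(e) for e in mraw.get("entities", entity_ids)]
        matrix = InfluenceMatrix(order, mraw["values"])
    elif isinstance(mraw, list):
        matrix = InfluenceMatrix(entity_ids, mraw)
    else:
        raise ModelError(
            f"matrix must be inline values or a csv reference, got {type(mraw)}"
        )
    extra = set(matrix.entity_order) - set(entity_ids)
    missing = set(entity_ids) - set(matrix.entity_order)
    if extra or missing:
        raise ModelError(
            f"matrix/entity mismatch: matrix-only ids {sorted(extra)}, "
            f"entity-only ids {sorted(missing)}"
        )

    spec = ModelSpec(
        model_id=str(raw.get("model_id", path.stem)),
        perspectives=perspectives,
        entities=tuple(entities),
        matrix=matrix,
        weighting_strategy=str(raw.get("weighting_strategy", "row")),
        q_convention=str(raw.get("q_convention", "active_sign")),
        bands=_bands_from_dict(raw.get("bands", {})),
        notes=str(raw.get("notes", "")),
    )
    if "score_bounds" in raw:
        stated = tuple(int(v) for v in raw["score_bounds"])
        if stated != spec.score_bounds:
            raise ModelError(
                f"model file states score_bounds {stated} but the matrix and "
                f"weight domains give {spec.score_bounds}"
            )
    return spec


def save_model(model: ModelSpec, path) -> None:
    """Write a model as YAML with the matrix inline; load/save round-trips."""
    doc = {
        "model_id": model.model_id,
        "notes": model.notes,
        "perspectives": [
            {"id": p.id, "name": p.name, "description": p.description}
            for p in model.perspectives
        ],
        "entities": [_entity_to_dict(e) for e in model.entities],
        "matrix": {
            "entities": list(model.matrix.entity_order),
            "values": model.matrix.values.tolist(),
        },
        "weighting_strategy": model.weighting_strategy,
        "q_convention": model.q_convention,
        "bands": _bands_to_dict(model.bands),
        "score_bounds": list(model.score_bounds),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_assessment(path) -> Assessment:
    """Load an assessment YAML: ``weights: {id: w, ...}``, optional label/notes."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "weights" not in raw:
        raise ModelError(f"assessment file {path} must contain a 'weights' mapping")
    return Assessment(
        weights={str(k): int(v) for k, v in raw["weights"].items()},
        label=str(raw.get("label", "")),
        notes=str(raw.get("notes", "")),
    )


def save_assessment(assessment: Assessment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "label": assessment.label,
                "notes": assessment.notes,
                "weights": dict(assessment.weights),
            },
            fh,
            sort_keys=False,
        )


def canonical_model() -> ModelSpec:
    """Load the packaged 13-factor model of re-identification risk."""
    with resources.as_file(
        resources.files("rimeda.data") / "rimeda_model.yaml"
    ) as p:
        return load_model(p)
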