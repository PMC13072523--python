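"""Machine-readable assessment reports.

The JSON report echoes the inputs, carries the exact (never display-rounded)
indices, and round-trips losslessly. Human-readable renderings apply
ceiling-rounding; machine fields never do.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import rimeda
from rimeda.engine import RiskResult
from rimeda.model import ModelSpec
from rimeda.stratify import ceil_display, countermeasure_hints

__all__ = ["Report", "build_report", "file_digest"]


def file_digest(path) -> str:
    """SHA-256 hex digest of a file, for input provenance in reports."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class Report:
    """Serialisable record of one assessment run."""

    model_id: str
    strategy: str
    q_convention: str
    assessment: dict
    indices: tuple[dict, ...]
    total_score: int
    score_bounds: tuple[int, int]
    band: str
    levers: tuple[dict, ...]
    protective_levers: tuple[dict, ...]
    tool_version: str = rimeda.__version__
    input_digests: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tool": {"name": "rimeda", "version": self.tool_version},
            "model_id": self.model_id,
            "strategy": self.strategy,
            "q_convention": self.q_convention,
            "assessment": dict(self.assessment),
            "indices": [dict(i) for i in self.indices],
            "total_score": self.total_score,
            "score_bounds": list(self.score_bounds),
            "band": self.band,
            "levers": [dict(h) for h in self.levers],
            "protective_levers": [dict(h) for h in self.protective_levers],
            "input_digests": dict(self.input_digests),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_dict(cls, d: dict) -> "Report":
        return cls(
            model_id=d["model_id"],
            strategy=d["strategy"],
            q_convention=d["q_convention"],
            assessment=dict(d["assessment"]),
            indices=tuple(dict(i) for i in d["indices"]),
            total_score=int(d["total_score"]),
            score_bounds=tuple(int(v) for v in d["score_bounds"]),
            band=d["band"],
            levers=tuple(dict(h) for h in d["levers"]),
            protective_levers=tuple(dict(h) for h in d["protective_levers"]),
            tool_version=d["tool"]["version"],
            input_digests=dict(d.get("input_digests", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls.from_dict(json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def render_text(self) -> str:
        """Human-readable summary; the only place values are ceiling-rounded."""
        lines = [
            f"Model {self.model_id} — total risk score "
            f"{ceil_display(self.total_score)} "
            f"(achievable {self.score_bounds[0]}..{self.score_bounds[1]}), "
            f"band: {self.band}",
            "",
            f"{'entity':<6} {'AS':>6} {'PS':>6} {'Q':>8}  category",
        ]
        for i in self.indices:
            lines.append(
                f"{i['entity']:<6} {ceil_display(i['active_sum']):>6} "
                f"{ceil_display(i['passive_sum']):>6} "
                f"{ceil_display(i['q_value']):>8}  {i['category']}"
            )
        if self.levers:
            lines += ["", "Risk-increasing levers (address first):"]
            lines += [
                f"  {h['entity']} (Q={ceil_display(h['q_value'])}): "
                + ("; ".join(h["countermeasures"]) or h["name"])
                for h in self.levers
            ]
        if self.protective_levers:
            lines += ["", "Protective levers to maintain:"]
            lines += [
                f"  {h['entity']} (Q={ceil_display(h['q_value'])}): {h['name']}"
                for h in self.protective_levers
            ]
        return "\n".join(lines) + "\n"


def _hint_dict(h) -> dict:
    return {
        "entity": h.entity,
        "name": h.name,
        "q_value": int(h.q_value),
        "protective": h.protective,
        "countermeasures": list(h.countermeasures),
    }


def build_report(
    result: RiskResult, model: ModelSpec, input_digests: dict | None = None
) -> Report:
    """Assemble the full report from a computed result and its model."""
    levers, protective = countermeasure_hints(result, model)
    return Report(
        model_id=result.model_id,
        strategy=result.strategy,
        q_convention=result.q_convention,
        assessment={
            "label": result.assessment.label,
            "notes": result.assessment.notes,
            "weights": dict(sorted(result.assessment.weights.items())),
        },
        indices=tuple(
            {
                "entity": i.entity,
                "active_sum": i.active_sum,
                "passive_sum": i.passive_sum,
                "q_value": i.q_value,
                "category": i.category,
            }
            for i in result.indices
        ),
        total_score=result.total_score,
        score_bounds=tuple(result.score_bounds),
        band=result.band,
        levers=tuple(_hint_dict(h) for h in levers),
        protective_levers=tuple(_hint_dict(h) for h in protective),
        input_digests=dict(input_digests or {}),
    )
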