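"""Risk stratification and evaluation graphics.

Turns a computed :class:`~rimeda.engine.RiskResult` into the assessor-facing
outputs: a risk band, a score gauge, a signed Q-value chart, the
active/passive Cartesian system grid, and a ranked list of countermeasure
hints ("levers").

Charts are deterministic: rendering the same result twice yields
byte-identical SVG output (fixed hash salt, no timestamps). Values shown on
charts are ceiling-rounded for presentability; stored values are never
rounded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import TYPE_CHECKING, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from rimeda.engine import RiskResult
    from rimeda.model import ModelSpec

__all__ = [
    "RiskBandScheme",
    "CountermeasureHint",
    "stratify",
    "band_edges",
    "render_gauge",
    "render_q_chart",
    "render_system_grid",
    "countermeasure_hints",
    "ceil_display",
]

#: default band labels, lowest risk first
DEFAULT_LABELS = ("low", "moderate", "high", "critical")

# deterministic SVG ids; matplotlib otherwise salts them per process
matplotlib.rcParams["svg.hashsalt"] = "rimeda"


class StratifyError(ValueError):
    """Raised for out-of-range scores or malformed band schemes."""


@dataclass(frozen=True)
class RiskBandScheme:
    """Partition of the achievable score range into ordered risk classes.

    ``equal_width`` mode derives the edges from the model's score bounds at
    evaluation time; ``custom`` mode carries explicit ascending edges whose
    first/last entries must coincide with the bounds.
    """

    mode: str = "equal_width"
    n_bands: int = 4
    labels: tuple[str, ...] = DEFAULT_LABELS
    custom_edges: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("equal_width", "custom"):
            raise StratifyError(f"unknown band mode {self.mode!r}")
        if self.n_bands < 2:
            raise StratifyError("a band scheme needs at least 2 bands")
        if len(self.labels) != self.n_bands:
            raise StratifyError(
                f"{self.n_bands} bands but {len(self.labels)} labels"
            )
        if self.mode == "custom":
            edges = self.custom_edges
            if len(edges) != self.n_bands + 1:
                raise StratifyError(
                    f"custom mode needs {self.n_bands + 1} edges, got {len(edges)}"
                )
            if any(a >= b for a, b in zip(edges, edges[1:])):
                raise StratifyError("custom edges must be strictly ascending")


def band_edges(scheme: RiskBandScheme, bounds: tuple[float, float]) -> list[Fraction]:
    """Return the ``n_bands + 1`` ascending edges over the score bounds."""
    lo, hi = Fraction(bounds[0]), Fraction(bounds[1])
    if scheme.mode == "custom":
        edges = [Fraction(e) for e in scheme.custom_edges]
        if edges[0] != lo or edges[-1] != hi:
            raise StratifyError(
                f"custom edges [{edges[0]}, {edges[-1]}] do not span the "
                f"score bounds [{lo}, {hi}]"
            )
        return edges
    if hi <= lo:
        raise StratifyError("degenerate score bounds: min >= max")
    width = (hi - lo) / scheme.n_bands
    return [lo + k * width for k in range(scheme.n_bands + 1)]


def stratify(score, bounds: tuple[float, float], scheme: RiskBandScheme) -> str:
    """Map a total risk score to its band label.

    Bands are half-open ``[edge_k, edge_{k+1})``; the top band is closed so
    the maximum achievable score falls in the highest class. A score outside
    the bounds signals a model/assessment mismatch and raises.
    """
    s = Fraction(score)
    lo, hi = Fraction(bounds[0]), Fraction(bounds[1])
    if lo == hi:
        # degenerate model: only one achievable score, lowest class
        if s != lo:
            raise StratifyError(
                f"score {score} outside achievable bounds [{bounds[0]}, {bounds[1]}]"
            )
        return scheme.labels[0]
    edges = band_edges(scheme, bounds)
    if s < edges[0] or s > edges[-1]:
        raise StratifyError(
            f"score {score} outside achievable bounds [{bounds[0]}, {bounds[1]}]"
        )
    for k in range(scheme.n_bands - 1):
        if edges[k] <= s < edges[k + 1]:
            return scheme.labels[k]
    return scheme.labels[-1]


def ceil_display(value) -> int:
    """Ceiling-round a value for display on charts; storage stays exact."""
    return math.ceil(value)


def _finish(fig, path: str) -> None:
    # metadata Date=None strips the timestamp -> byte-identical re-renders
    fmt = str(path).rsplit(".", 1)[-1].lower()
    meta = {"Date": None} if fmt == "svg" else None
    fig.savefig(path, metadata=meta)
    plt.close(fig)


def render_gauge(result: "RiskResult", path: str, scheme: RiskBandScheme | None = None) -> None:
    """Draw a linear gauge of the total score between the achievable bounds.

    Band segments are shaded, edges ticked, and the achieved score marked;
    displayed numbers are ceiling-rounded.
    """
    scheme = scheme or RiskBandScheme()
    lo, hi = result.score_bounds
    edges = [float(e) for e in band_edges(scheme, (lo, hi))]
    score = float(result.total_score)

    fig, ax = plt.subplots(figsize=(8, 1.8))
    cmap = plt.get_cmap("RdYlGn_r")
    for k in range(len(edges) - 1):
        ax.axvspan(edges[k], edges[k + 1], color=cmap(k / max(len(edges) - 2, 1)),
                   alpha=0.6)
    ax.axvline(score, color="black", lw=2)
    ax.annotate(f"{ceil_display(result.total_score)}", (score, 0.5),
                xycoords=("data", "axes fraction"), ha="center", va="bottom",
                fontweight="bold")
    ax.set_xlim(edges[0], edges[-1])
    ax.set_yticks([])
    ax.set_xticks(edges)
    ax.set_xticklabels([f"{ceil_display(e)}" for e in edges])
    for k, lab in enumerate(scheme.labels):
        ax.text((edges[k] + edges[k + 1]) / 2, -0.35, lab, ha="center",
                va="top", transform=ax.get_xaxis_transform(), fontsize=8)
    ax.set_title(f"Re-identification risk score ({result.model_id})")
    fig.tight_layout()
    _finish(fig, path)


def render_q_chart(result: "RiskResult", path: str) -> None:
    """Signed bar chart of per-entity Q-values, ordered by |Q| descending.

    Positive (risk-increasing) and negative (risk-reducing) bars are
    coloured differently, mirroring the lever reading of the Q-value.
    """
    order = sorted(result.indices, key=lambda e: (-abs(e.q_value), e.entity))
    names = [e.entity for e in order]
    qs = [float(e.q_value) for e in order]
    colors = ["#c0392b" if q > 0 else "#27ae60" if q < 0 else "#7f8c8d" for q in qs]

    fig, ax = plt.subplots(figsize=(7, 0.45 * max(len(order), 4) + 1.2))
    ax.barh(range(len(order)), qs, color=colors)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(names)
    ax.invert_yaxis()
    ax.axvline(0, color="black", lw=0.8)
    for y, (e, q) in enumerate(zip(order, qs)):
        ax.annotate(f"{ceil_display(e.q_value)}", (q, y), ha="left" if q >= 0 else "right",
                    va="center", fontsize=8,
                    xytext=(3 if q >= 0 else -3, 0), textcoords="offset points")
    ax.set_xlabel("Q-value (positive = risk-increasing, negative = risk-reducing)")
    ax.set_title(f"Cross-linkage (Q) of influencing factors ({result.model_id})")
    fig.tight_layout()
    _finish(fig, path)


def render_system_grid(result: "RiskResult", path: str, n_subdivisions: int = 4) -> None:
    """Scatter each factor at (active sum, passive sum) on a Cartesian grid.

    The grid carries equal-size subdivisions representing increasingly strong
    expressions of the value pairs; axes always include the origin, and all
    four quadrants are shown whenever any sum is negative. Plotted
    coordinates are ceiling-rounded; stored indices are untouched.
    """
    xs = [ceil_display(e.active_sum) for e in result.indices]
    ys = [ceil_display(e.passive_sum) for e in result.indices]

    span = max([abs(v) for v in xs + ys] + [1])
    any_negative = any(v < 0 for v in xs + ys)
    lo = -span * 1.15 if any_negative else min(0, min(xs + ys)) - 0.05 * span
    hi = span * 1.15

    fig, ax = plt.subplots(figsize=(6.5, 6.5))
    step = (hi - lo) / n_subdivisions
    for k in range(1, n_subdivisions):
        ax.axvline(lo + k * step, color="0.85", lw=0.7, zorder=0)
        ax.axhline(lo + k * step, color="0.85", lw=0.7, zorder=0)
    ax.axhline(0, color="black", lw=0.8)
    ax.axvline(0, color="black", lw=0.8)

    palette = {"active": "#e67e22", "reactive": "#2980b9",
               "critical": "#c0392b", "inert": "#7f8c8d"}
    for e, x, y in zip(result.indices, xs, ys):
        ax.scatter([x], [y], color=palette[e.category], s=45, zorder=3)
        ax.annotate(f"{e.entity} ({e.category})", (x, y),
                    xytext=(4, 4), textcoords="offset points", fontsize=8)
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    ax.set_xlabel("active sum (influence exerted on the system)")
    ax.set_ylabel("passive sum (influence received from the system)")
    ax.set_title(f"System grid of influencing factors ({result.model_id})")
    fig.tight_layout()
    _finish(fig, path)


@dataclass(frozen=True)
class CountermeasureHint:
    """One controllable factor with its lever strength and guidance texts."""

    entity: str
    name: str
    q_value: Fraction
    protective: bool
    countermeasures: tuple[str, ...] = field(default_factory=tuple)


def countermeasure_hints(
    result: "RiskResult", model: "ModelSpec"
) -> tuple[list[CountermeasureHint], list[CountermeasureHint]]:
    """Rank controllable factors as levers for reducing the risk.

    Returns ``(levers, protective)``: risk-increasing controllable entities
    ranked by descending Q (strongest lever first), and risk-reducing
    controllable entities (negative Q) as protective levers to maintain,
    strongest reduction first. Entities with Q = 0 or not controllable are
    omitted; no entity ever appears in both lists.
    """
    by_id = {e.id: e for e in model.entities}
    levers: list[CountermeasureHint] = []
    protective: list[CountermeasureHint] = []
    for idx in result.indices:
        ent = by_id[idx.entity]
        if not ent.controllable or idx.q_value == 0:
            continue
        hint = CountermeasureHint(
            entity=ent.id,
            name=ent.name,
            q_value=idx.q_value,
            protective=idx.q_value < 0,
            countermeasures=tuple(ent.countermeasures),
        )
        (protective if hint.protective else levers).append(hint)
    levers.sort(key=lambda h: (-h.q_value, h.entity))
    protective.sort(key=lambda h: (h.q_value, h.entity))
    return levers, protective
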