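"""Render the three evaluation charts for a maximum-risk configuration.

Writes gauge.svg (score on the achievable scale), qchart.svg (signed
Q-values, lever reading) and grid.svg (active/passive Cartesian system
grid with factor categories) into ./charts.
"""
from pathlib import Path

from rimeda import canonical_model, compute
from rimeda.sensitivity import score_bounds
from rimeda.stratify import render_gauge, render_q_chart, render_system_grid

model = canonical_model()
_, _, _, a_max = score_bounds(model)
result = compute(model, a_max)

out = Path("charts")
out.mkdir(exist_ok=True)
render_gauge(result, str(out / "gauge.svg"), model.bands)
render_q_chart(result, str(out / "qchart.svg"))
render_system_grid(result, str(out / "grid.svg"))

print(f"score {result.total_score} (band '{result.band}') -> {out}/")
print(
    "gauge: where the release sits between the minimal and maximal"
    " achievable risk; qchart: which factors are the strongest levers;"
    " grid: active vs passive role of each factor in the system."
)
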