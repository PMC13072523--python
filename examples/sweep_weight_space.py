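"""Explore the admissible weight space of the 13-factor model.

Exact analytic score bounds, per-entity leverage, and a seeded Monte-Carlo
sweep over the ~1.2e7 admissible assessments (too many to enumerate, so the
sweep samples uniformly).
"""
from rimeda import canonical_model
from rimeda.sensitivity import per_entity_leverage, score_bounds, sweep

model = canonical_model()
lo, hi, a_min, a_max = score_bounds(model)
print(f"achievable total score: [{lo}, {hi}] (range {hi - lo})")

leverage = per_entity_leverage(model)
top = sorted(leverage.items(), key=lambda kv: -kv[1])[:5]
print("largest single-entity leverage:")
for eid, lev in top:
    print(f"  {eid}: up to {lev} score points")

result = sweep(model, mode="monte_carlo", n=5000, seed=42)
print(
    f"\nMonte-Carlo sweep (n={result.n_evaluated}, seed={result.seed}): "
    f"sampled scores in [{result.score_min}, {result.score_max}]"
)
print(
    "\nSampled extremes stay inside the analytic bounds; the leverage values"
    "\nsay how much of the score range each single factor controls."
)
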