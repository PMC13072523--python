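# rimeda

Quantify and stratify the **re-identification risk** of a medical dataset
before it is released for secondary use.

Classical privacy metrics (k-anonymity, uniqueness counts) score only the
data. In practice the risk of deanonymisation is a system: record
uniqueness interacts with the external data sources an adversary can link
against, with their motivation and skills, and with the organisational and
technical safeguards around the release. `rimeda` models this system as a
Vester-style cross-impact ("networked thinking") analysis: thirteen
influencing factors in four perspectives — **D**ata, **W** (knowledge),
**A**ttacker, **T**echnical/**O**rganisational — connected by a signed
integer influence matrix, weighted by a data controller's assessment, and
condensed into interpretable indices. The intended users are data
controllers, data-protection officers and privacy researchers deciding
whether and how a tabular medical dataset can be shared.

## Model

The influence matrix `M` holds integer cells `m_ij ∈ [-3, 3]`: the strength
(0 none, |1| weak, |2| medium, |3| strong) and direction (sign) of factor
*i*'s effect on factor *j*; the diagonal is zero. A data controller assigns
each factor a weight `w_i` from its admissible domain ({0..3}, {1..3}, or
{-3, 1..3} for protective technical/organisational factors, where -3
encodes a strong, risk-*reducing* implementation). Factors D1 (uniqueness)
and TO2 (anonymisation methods) carry double point values, `δ_i = 2`.

Under the default `row` weighting the scaled matrix is

```
c_ij = w_i · δ_i · |m_ij|
```

from which the indices follow:

- **active sum** `AS_i = Σ_j c_ij` — influence factor *i* exerts on the system;
- **passive sum** `PS_j = Σ_i c_ij` — influence the system exerts on factor *j*;
- **Q-value** `Q_i = sign(AS_i) · |AS_i · PS_i|` — cross-linkage; positive Q
  marks a risk-increasing factor, negative Q a risk-reducing one, and large
  |Q| marks a candidate *lever* for controlling the risk;
- **total risk score** `S = Σ_i AS_i + Σ_j PS_j = 2 Σ_ij c_ij`, stratified
  into equal-width risk bands (low/moderate/high/critical) over the exact
  achievable range;
- **factor categories** — active, reactive, critical or inert, by comparing
  |AS| and |PS| against their across-factor means.

All arithmetic is exact over integers; rounding (always upward) is applied
only when values are displayed or plotted.

The entity list, weight domains and doubling flags of the packaged
13-factor model follow the published factor tables for this procedure. The
influence-matrix cells themselves are a **synthetic reconstruction** encoded
from the published qualitative descriptions of the factor
interrelationships (the original prototype workbook is not available in
machine-readable form); see `docs/methods.md` for what does and does not
follow from that.

## Worked example

```python
from rimeda import Assessment, canonical_model, compute
from rimeda.report import build_report

model = canonical_model()
assessment = Assessment({
    "D1": 3, "D2": 1, "D3": 2,           # many unique, dissimilar records
    "W1": 2, "W2": 1, "W3": 3, "W4": 2,  # linkable sources, rich metadata
    "A1": 2, "A2": 2, "A3": 1,           # moderately capable adversary
    "TO1": 1, "TO2": -3, "TO3": -3,      # good methods and security
})
print(build_report(compute(model, assessment), model).render_text())
```

prints

```
Model rimeda-13 — total risk score 666 (achievable -154..1572), band: moderate

entity     AS     PS        Q  category
D1        168      7     1176  active
...
TO2      -108     40    -4320  critical
TO3       -27     29     -783  reactive

Risk-increasing levers (address first):
  D1 (Q=1176): Generalise quasi-identifier attributes (coarser categories, intervals). ...
```

The score 666 sits in the second of four equal-width bands over the exact
achievable range [-154, 1572]. Uniqueness (D1) is the strongest actionable
lever — generalise, suppress or randomise until records stop being unique —
while the strongly negative Q of TO2 shows the anonymisation methods
currently holding the risk down, a protective lever to maintain.

The same workflow is available from the shell:

```
rimeda demo --out demo            # emit a toy model + assessment
rimeda assess demo/toy3_model.yaml demo/toy3_assessment.yaml --out out
rimeda whatif model.yaml weights.yaml --set TO2=-3
rimeda sweep model.yaml --mode monte_carlo --n 10000 --seed 1
```

`examples/` contains runnable scripts for each capability: the hand-sized
toy walkthrough, a full assessment, what-if lever analysis, weight-space
sweeps, and chart rendering (score gauge, Q-value chart, active/passive
system grid).

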