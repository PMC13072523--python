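# Methods

## The risk model

`rimeda` treats the re-identification risk of a released tabular medical
dataset as a closed system of thirteen interacting factors grouped in four
perspectives:

- **Data (D)** — uniqueness (D1), similarity (D2), vulnerable
  quasi-identifiers (D3): properties measurable on the dataset itself.
- **Knowledge (W)** — external data sources (W1), background/contextual
  information (W2), metadata (W3), data inference (W4): what an adversary
  can bring to bear.
- **Attacker (A)** — motivation (A1), skills (A2), resources (A3).
- **Technical/organisational (TO)** — awareness (TO1), anonymisation
  methods (TO2), data security (TO3): the environment of the release.

The directed effect of factor *i* on factor *j* is an integer
`m_ij ∈ [-3, 3]` in the influence matrix; 0 means no effect, |1|–|3|
increasing strength, and a negative sign an opposing development. The
diagonal is fixed at zero: cross-impact analysis scores the interplay
*between* factors, and a self-influence term would inflate both sums of a
factor with the same information, so the loader rejects nonzero diagonals
outright.

An assessment assigns each factor a weight from its admissible domain.
Domains follow the factor tables: {0..3} where influence can be absent
(D1–D3, W3), {1..3} where some influence always exists (W1, W2, W4,
A1–A3), and {-3, 1, 2, 3} for the TO factors, where -3 encodes strong,
risk-*reducing* implementation (point deduction) and 1–3 increasingly poor
implementation. D1 and TO2 impact the system with double point values
(`δ = 2`).

## Index computation

Under the default `row` strategy the weighted cell is
`c_ij = w_i δ_i |m_ij|`: the moduli of the matrix entries carry the effect
strength, and the signed weight carries both the factor's expression and
its risk direction. Active sum, passive sum, total score and Q-value are
as in the README. Two properties are load-bearing and are asserted in
code and tests:

- `S = Σ AS + Σ PS = 2 Σ c_ij` — every cell counts once per axis;
- under `row`, `S` is linear in each `w_i` with nonnegative coefficient
  `2 δ_i R_i` (`R_i = Σ_j |m_ij|`), so exact score bounds and per-entity
  leverage come from the per-entity domain extremes in closed form, with
  no enumeration of the ~1.2×10⁷ admissible assessments.

A second strategy, `row_col` (`c_ij = w_i δ_i w_j δ_j |m_ij|`), is
registered for comparison; it is nonlinear, so its bounds are found by
exhaustive enumeration, refused above 10⁶ combinations with guidance to
use Monte-Carlo sampling.

**Q sign convention.** The Q-value is defined as the product of the sums,
but a raw product misreads the one situation the sign exists for: a factor
that drives the system down (AS < 0) while itself being suppressed
(PS < 0) would get a *positive* Q. The default `active_sign` convention
therefore takes `|AS·PS|` with the sign of AS, preserving the reading
"positive Q = risk-increasing, negative Q = risk-reducing" in every
quadrant; the raw `product` convention remains available for strict-formula
comparison. The convention in force is recorded in every report.

**Factor categories.** The four qualitative categories are made concrete
by comparing |AS| and |PS| to their across-factor means: active
(|AS| ≥ mean, |PS| < mean), reactive (converse), critical (both ≥), inert
(both <). Ties count as "pronounced" (≥). Medians or fixed cut-offs can be
substituted; the all-zero system classifies as all-inert by definition.
Exact `Fraction` arithmetic avoids any floating-point tie ambiguity.

**Risk bands.** No published cut-offs exist for risk classes, so the
default scheme divides the *exact achievable* score range into four
equal-width bands (low/moderate/high/critical), half-open with a closed
top band; custom edges can be supplied per model file. Band edges are
computed as exact rationals.

**Display rounding.** Values are ceiling-rounded for presentability in
charts and the text report only; stored and serialised indices are exact
integers.

## Provenance of the packaged 13-factor model

The entity list, perspectives, weight domains and the D1/TO2 doubling
flags follow the published factor tables of this assessment procedure.
The matrix cells are a different matter: the published figure is an image
and the prototype spreadsheet behind it is not available in
machine-readable form. The shipped
`data/influence_matrix_synthetic.csv` is therefore a **synthetic
reconstruction**: each row was encoded from the published qualitative
descriptions of the factor interrelationships (strong uniqueness →
quasi-identifier and linkage-attack channels; metadata as a strongly
cross-linked driver; TO factors acting on the system with negative,
risk-reducing cells), not transcribed from the original workbook.

Consequences, stated plainly:

- Structural and qualitative results on the canonical model are meaningful
  and tested: the exact bounds/linearity machinery, the dominance of
  uniqueness (D1) and metadata (W3) among the Q-values at maximum risk,
  and method quality (TO2) as the strongest inhibitor at minimum risk.
- The numeric aggregates of the reconstruction (score bounds [-154, 1572],
  active sums [-108, 168], passive sums [-19, 87]) are properties of this
  reconstruction only and are **not** the original instrument's printed
  aggregates. Reproducing those would additionally require the original
  workbook's exact cell-level weighting scheme, which the two strategies
  shipped here deliberately bracket rather than guess at.
- Every transcription-independent property (oracle equivalence, bounds vs
  exhaustive enumeration, score identity, monotonicity, annihilation,
  sign convention, determinism) is enforced by the acceptance suite on
  randomly generated models and the fixed TOY3 fixture, so replacing the
  matrix file with a true transcription requires no code change.

## Synthetic data and fixtures

`fixtures.random_model` draws cell magnitudes from a configurable
distribution over {0,1,2,3} (default 0.4/0.25/0.2/0.15, giving the sparse,
weak-tailed matrices typical of hand-curated cross-impact tables), flips
signs with probability 0.2, assigns domains from the canonical palette and
doubling flags with probability 0.15. Every generated artefact passes the
full model validation, and all generators are pure functions of their
seed. What the generator does *not* emulate: the block structure of a real
expert-curated matrix (perspective-internal cells tend to be denser) and
any correlation between an entity's domain and its connectivity — so
passing property tests demonstrate arithmetic correctness on the admissible
input space, not fidelity to any particular expert's matrix.

TOY3 (3 factors, all domain shapes, one double flag) is small enough that
every expected value in its tests was computed by hand; the exhaustive
weight box has 48 assessments.

## Numerical and design choices

- All index arithmetic is integer-exact; classification thresholds and
  band edges use `fractions.Fraction`. No tolerances exist outside
  rendering.
- Sweeps: exhaustive mode is capped at 10⁶ assessments (the canonical
  model's 11,943,936 admissible assessments exceed it); Monte-Carlo
  sampling is per-entity uniform and independent, driven by a single
  numpy `default_rng` seed, because no distribution over assessor
  behaviour is available.
- Controllability defaults: D and TO factors are controllable by the data
  controller, W and A factors are not; overridable per model file. Lever
  lists partition controllable factors by Q sign; zero-Q factors offer no
  leverage and are omitted.
- Determinism of outputs: reports serialise with sorted keys and no
  timestamps; SVG rendering pins matplotlib's `svg.hashsalt` and strips
  the date metadata, so re-rendering the same result is byte-identical.
- Problem sizes in the test and acceptance runs (random models with 2–7
  factors, 1000-model oracle batteries, 48-assessment exhaustive toy
  sweeps, 2¹³ corner enumeration on the canonical model, 20k-sample
  Monte-Carlo sweeps) keep every check exact or statistically stable while
  completing in seconds.

## Known limitations

- The canonical matrix is a reconstruction (above); institutions applying
  the procedure should review and, where needed, re-curate the cell values
  — the model file format makes that a data edit, not a code change.
- The procedure scores an assessor's structured judgement; it does not
  read datasets, compute uniqueness, or apply anonymisation operations.
  Hints are advisory text.
- Weight rubrics are guidance strings, not computable criteria;
  inter-rater variability is unaddressed by construction.
- Image and signal data are outside the model's scope.
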