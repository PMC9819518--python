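# Methods

## Model

`hisbench` evaluates one city against published health indicator standards
(HIS) through a two-stage pipeline: AHP weighting of indicators inside each
expert-judged group, then a single-alternative TOPSIS in which the
standards themselves supply the ideal rows.

### Indicator hierarchy

A framework is a strict partition: every indicator belongs to exactly one
element, every element to exactly one dimension. Each indicator carries an
orientation (`MAX` — higher is better, e.g. life expectancy; `MIN` — lower
is better, e.g. mortality per 100,000) and up to two published benchmark
values: a positive ideal `PI` (the level to reach) and a negative ideal
`NI` (the level to stay away from). Orientation decides which direction is
"good"; the structural invariant `PI ≥ NI` for MAX and `PI ≤ NI` for MIN is
enforced on published values at load time.

**Missing ideals.** Standards bodies frequently publish only one side
(e.g. a forest-cover target with no stated floor). The model needs both
rows, so an indicator may carry an explicit `substitute_pi` /
`substitute_ni`, and a framework-level default policy (`zero`, `one`, or
`omit` = refuse) covers the rest. Substitutes are stored separately and
never overwrite published values; the strategy classifier ignores them
entirely, because a bookkeeping stand-in is not a policy threshold. In the
bundled worked example the substitutes are 0 throughout except a floor of
1 for two per-capita mortality rates whose published tables only state a
ceiling (a literal zero mortality floor is not attainable and the worked
example's printed results imply the floor of 1).

### AHP stage

Per group, the priority vector is extracted by the normalized-column /
row-average method: divide each column of the judgment matrix by its sum,
then average across each row. For a perfectly consistent (rank-one) matrix
this is exact and equals the principal eigenvector; for real judgment
matrices it is the standard closed-form approximation, and we keep it as
the primary method because published weight tables in this field print it
cell by cell. A power-iteration principal eigenvector
(`ahp.principal_eigenvector`) is provided purely as a cross-check and is
validated in the tests against `scipy.linalg.eig`.

Consistency: `lambda_max` is the mean of the component ratios `(A·w)_i /
w_i`, `C.I. = (lambda_max − n)/(n − 1)`, and `C.R. = C.I. / R.I.(n)` with
the random-index lookup `{3: 0.58, 4: 0.90, 5: 1.12, …, 15: 1.59}`. The
default table uses 1.48 at n = 12; the common alternative (1.54) is
selectable as `ri_table="saaty_classic"`. For n ≤ 2 a reciprocal matrix
cannot be inconsistent, so `C.R.` is defined as 0. Any group with
`C.R. ≥ 0.1` aborts `weights_for_framework` — downstream scores from
incoherent judgments would be noise.

### TOPSIS stage

The decision matrix for each indicator has exactly three rows — city, PI,
NI — and the benchmark rows always participate in both the Euclidean
normalization and the ideal selection. Consequences worth knowing:

* the ideal `A+` is the orientation-aware extremum over all three rows, so
  a city outperforming its standard becomes its own ideal (its deviation
  from `A+` is then 0);
* per-indicator results are invariant to rescaling `(city, PI, NI)` by any
  k > 0 — units cancel in the normalization (property-tested to 1e-12);
* pooling to elements and dimensions sums raw squared deviations; no
  second-level weights are applied. An element's closeness is therefore
  driven by its own indicators' weighted shortfalls only.

Degenerate cases: a column of all zeros cannot be normalized and is an
error; if a pooled group has `S+ = S− = 0` (the city sits exactly on both
ideals for every member) the closeness is defined as 1 and a warning is
logged. Ranking is descending by closeness with deterministic ties broken
by ascending scope code.

**Weight precision.** All computation is double precision; rounding
happens only at the rendering layer (half away from zero, 2 decimals for
ideal/closeness tables, 3 for deviation tables). One deliberate exception:
`weights_for_framework(..., decimals=2)` rounds each group's weights
before scoring. Published weight tables carry two decimals, and the
worked example's printed ideal values are reproducible only when those
two-decimal weights are the ones carried forward; the default
(`decimals=None`) keeps full precision. Element- and dimension-level
closeness agrees to two decimals under either choice.

### Screening and strategy

The IOC screen is the exact rational mean of votes in {−1, 0, +1} from an
odd panel, retained at index ≥ 0.5 by default (configurable; 0.5 is the
conventional content-validity cut).

The strategy rule classifies each indicator against its *published* ideals
only: at/beyond PI → Level 1 (growth-maintaining), between the ideals →
Level 2 (monitoring), beyond NI → Level 3 (improvement); one-sided
indicators collapse to Level 1/Level 3 around their sole published value.
The rule is total and mutually exclusive for any indicator with at least
one published ideal. Published assessments sometimes place an indicator by
policy aspiration rather than by value (e.g. a staffing ratio judged
"must improve" although it lies between its standards); the fixture ships
those as explicit overrides (`strategy_overrides:` in the YAML), marked
`basis=override`, rather than bending the rule.

## Synthetic generator

The generator exists so every pipeline stage is testable without external
data. It emulates: (i) random strictly-valid hierarchies with ~50/50
MAX/MIN orientations, ideal pairs drawn with the good side 1.5–4× the bad
side, and missing ideals injected at a configurable rate with recorded
substitutes; (ii) judgment matrices built from a target weight vector as
`w_i/w_j`, multiplicatively perturbed by `exp(noise·z)` and snapped in log
space to the nearest legal Saaty value, reciprocity enforced from the
upper triangle — so synthetic instruments are always valid, though large
noise legitimately fails the C.R. gate; (iii) city observations placed at
`NI + position·(PI − NI)` per indicator with optional Gaussian jitter on
the position scale. Seeded child streams keep the three artifact kinds
independent.

What it does **not** emulate: correlated indicators, heavy-tailed or
censored real-world values, expert panels that disagree systematically, or
standards that change over time. Passing the anchor and invariance suites
therefore demonstrates the arithmetic and its boundary behaviour, not that
any particular real framework is well-specified.

## Worked-example fidelity and known errata

The bundled Khon Kaen 2019 fixture reproduces, at printed precision, the
nine group priority vectors, the consistency gate for all groups, 28 of 45
printed ideal rows, 17 of 45 printed deviation rows, and the element and
dimension closeness rows asserted in `tests/test_acceptance.py`. The
remaining printed cells are internally inconsistent with the sums printed
alongside them (several blocks appear shifted or transposed in the source
tables); they are excluded from the reproduction tests rather than fitted.
Two printed group C.R. cells and one printed S− cell fall in the same
category. The tests document exactly which cells are asserted.

## Numerical choices

* PCM validation tolerance: reciprocity within 1e-9 relative; no silent
  repair — a non-reciprocal instrument is an input error.
* Weight normalization asserted to 1e-9; consistent-matrix recovery holds
  to 1e-12 (tested).
* Rounding half away from zero, matching how the benchmark tables are
  typeset (`round_half_away`); Python's bankers' rounding would disagree
  on exact .5 cells.
* Test problem sizes: property suites run 100–1000 randomized panels and
  100 seeded synthetic frameworks; the whole suite completes in a few
  seconds on one CPU.

## Limitations

* Single-city scoring is the design point; multi-city input is possible by
  evaluating cities independently, but no cross-city normalization is
  offered (deliberately — the point of benchmark anchoring is to avoid
  league tables).
* One consensus judgment matrix per group; aggregation of multiple expert
  matrices (geometric-mean or otherwise) is out of scope.
* The closeness scale is comparable across elements only insofar as the
  underlying standards are equally ambitious; a lenient standard inflates
  c\*.
* R.I. values are tabulated to n = 15; larger groups need an explicit
  random index.
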