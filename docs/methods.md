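# Methods

## Data model

A screening collection is held as a ternary matrix: compounds (rows) ×
assays (columns), each cell *active*, *inactive* or *untested*. Activity is
binary by design — potency readouts (e.g. AC50) are assay-dependent and not
transferable across assay formats, so only explicit active/inactive calls
are modelled. Untested cells are stored by absence (scipy CSR of int8
codes), so memory scales with the number of observations; identifiers are
opaque strings.

Elementary quantities, all exact ratios of integer counts:

* matrix density = tested cells / (rows × cols);
* activity rate among tested = active cells / tested cells;
* active cell fraction = active cells / (rows × cols), identically the
  product of the former two (no rounding is involved: all three share the
  same counts);
* per-line density and hit rate, with hit rate of an untested line defined
  as 0 so that activity weighting can never favour retaining it.

Percentages for reports use decimal round-half-up (one decimal by default),
the convention of printed screening tables; Python's float `round` is
half-even and disagrees at exact `.x5` boundaries (41/400 → 10.3, not
10.2).

## Greedy dense-submatrix extraction

Score of a line: `w_axis · (density + w_act · hit_rate)`, with
`w_axis = compound_weight` for rows and `assay_weight` for columns. Each
iteration deletes the minimum-score line until overall density reaches the
target τ. The functional form was an open design choice; this one was
chosen because it reduces to the plain lowest-density rule at the defaults
(`w_a = w_c = 1`, `w_act = 0`) and both preferences — axis retention and
activity retention — are monotone in their knobs.

**Monotonicity.** With equal axis weights and no activity weighting, the
deleted line has minimal density; the mean of row densities (and of column
densities) equals the overall density, so the deleted line's density is at
or below the overall density, and deleting a line at or below the mean
cannot lower the mean. Density is therefore non-decreasing along the
default trajectory (asserted exactly, with rational arithmetic, in the
tests). With unequal weights or `w_act > 0` monotonicity can break, which
motivates the snapshot-selection rule below.

**Snapshot selection.** Both spec'd policies — "first snapshot reaching τ"
and "best feasible snapshot over the whole trajectory" — provably coincide:
every deletion strictly decreases `rows × cols` and weakly decreases the
tested-cell count, so no later feasible snapshot can exceed an earlier one
in cell count. The implementation stops at the first feasible snapshot for
either setting of `track_best`; the flag is retained for configuration
compatibility.

**Tie-breaking** (underdetermined by the method definition, fixed for
determinism): among minimum-score lines, delete from the axis with more
lines (shrinking the larger dimension preserves balance); if the axes tie,
delete a compound; within an axis, delete the lexicographically smallest
identifier. A pre-pass deletes lines with zero tested cells (columns then
rows, lexicographically) since they can never belong to a τ > 0 snapshot.

**Bookkeeping.** Line statistics are maintained incrementally with integer
counters (deleting a line decrements the opposite axis's tested/active
counts), which is exactly equivalent to full recomputation each iteration;
the tests assert this equivalence by replaying traces against independently
recomputed subsets. Infeasibility (matrix emptied before reaching τ) is a
flagged result carrying the full trace, not an exception, so weight-grid
experiments don't abort.

**Oracle.** `brute_force_max_complete_submatrix` enumerates all row subsets
(capped at 12×12; for a fixed row set the optimal column set is every
column fully tested on those rows) and serves as the independent optimum
in tests. The greedy heuristic is bounded by it on every instance of the
random battery; across 200 random matrices up to 10×10 it attains ~96% of
the optimal cell count on average (measured by the acceptance script, not
asserted as a constant).

## Assay selection

Real panels contain several assays per target; one is kept per
(assay type, target): the one screening the most compounds, ties broken by
smallest assay identifier. Confirmatory (dose–response) and primary
(single-dose) assays are resolved independently since matrices are built
per assay type.

## File formats

The deposition format is a wide CSV: header `CID,<assay ids...>`, one row
per compound, cells `1` / `0` / `NA`. The first header cell is not fixed by
convention anywhere authoritative; `CID` was chosen since rows are compound
identifiers. Output is unquoted with `\n` endings and therefore
byte-identical across platforms; identifiers may not contain commas or
newlines (an error, not an escape — screening identifiers are numeric
strings in practice). The reader additionally accepts `na` and the empty
string for untested cells, a dialect concession, and reports malformed
input with line numbers and cell coordinates. Row/column order is preserved
as-is; `sort=True` (CLI `--sort`) emits lexicographic order for canonical
diffs. The long-form ingest CSV (`compound_id, assay_id, outcome`) lists
tested pairs only; identical duplicate pairs are deduplicated with a
warning, conflicting ones are an error. Assay metadata tables go through
the stdlib csv module with minimal quoting because target names are free
text.

## Synthetic screening data

The generator emulates the structure of public screening sparsity, which is
*blocked*, not uniform: compounds belong to libraries, and each assay
screens some libraries. Pipeline: (1) assign each compound to one of
`n_libraries` (uniform or a given probability vector); (2) per assay, pick
covered libraries; (3) test each compound of a covered library with
probability `within_coverage_test_prob`; (4) mark each tested cell active
with the assay's hit rate. Expected density is
`coverage × within_coverage_test_prob`; the expected activity rate among
tested cells is the mean of the hit-rate law. Uniform-random sparsity is
recovered with one library and full coverage.

**Coverage mode.** By default each assay covers a fixed quota of
`round(coverage × n_libraries)` libraries drawn without replacement
(stochastic rounding when fractional). Screens are planned over whole
library plates, and the quota keeps the realized density's sampling
variance at the binomial scale of the per-cell test draws, making
calibration checks meaningful. An independent-Bernoulli mode per
(assay, library) pair is available; it adds block-sized variance (each
draw toggles ~compounds/libraries cells at once).

**Hit-rate law.** Per-assay hit rates are Beta-distributed with mean m and
dispersion d (variance `d·m(1−m)`; shapes `α = m(1/d−1)`, `β =
(1−m)(1/d−1)`); d = 0 degenerates to a constant. This guarantees assays
with above-average hit rates exist, giving the activity-weighting property
tests signal. A fixed per-assay profile may be supplied instead.

**Confirmatory preset** (`generate_paperlike_confirmatory`): 100 assays ×
20,000 compounds — a reduced scale that preserves the density and hit-rate
regime of public confirmatory collections while keeping the suite fast —
with 4 libraries, coverage 0.5 (quota 2), test probability 0.22 (expected
density 0.11), and a *fixed* heterogeneous hit-rate profile with mean
exactly 0.0115: gamma(shape 0.5) quantiles normalised to mean 1 and scaled.
The profile is deterministic rather than Beta-drawn because a random
per-assay rate adds `spread/√A` variance to the realized overall activity
rate, an order of magnitude above the binomial standard error at this cell
count; with a fixed profile the realized rate is conditionally binomial,
so the preset's calibration can be checked against binomial error bars.
The right-skewed profile also reproduces qualitative features of
confirmatory panels: most assays below 1% hit rate, a few hit-rich, some
with no realized hits at all.

What the generator does **not** emulate: chemical structure (scaffold
similarity, series correlations), assay-interference artifacts,
dose–response noise, or correlated activity across related targets.
Passing tests on synthetic data therefore validate the bookkeeping,
determinism and the direction of the weighting effects — not performance
on any particular real screening collection, whose block structure and
hit-rate profile will differ.

## Numerical and degenerate-input choices

* All counts are integers; densities are formed by a single float division,
  and tie comparisons in the greedy loop compare identically computed
  floats, so runs are bit-reproducible across platforms.
* Empty matrices (zero rows or columns) are explicit sentinels: `subset`
  may produce them and extraction may end on them, but density/profile
  operations reject them.
* A 1×1 untested matrix is infeasible at any τ (the pre-pass empties it).
* Extraction requires a non-degenerate input; τ ∈ (0, 1]; weights ≥ 0.

## Problem sizes in the test suite

The suite uses reduced scales chosen to exercise every regime: random
batteries up to 10×10 against the exponential-time oracle, 12×40 synthetic
matrices for weighting properties, the 100×20,000 preset (50 seeds) for
calibration, and a 60×3,000 preset instance for the extraction-feasibility
property (τ = 0.20, safely below the within-block density 0.22 whose
realized value fluctuates around its expectation).

## Known limitations

* The greedy deletion is a heuristic: it is bounded by, but does not always
  attain, the maximum complete submatrix (mean ~96% of optimal cells on
  the random battery).
* The exact weighting formula and tie-breaks used to derive the published
  deposited matrices are not public; this implementation's choices are
  documented above, so bit-exact reproduction of those depositions from
  raw screening data is not promised.
* Dense-matrix workflows that remove one matrix's compounds from another
  (non-overlapping designs) are supported as a post-filter via `subset`,
  not as a dedicated operation.
* The brute-force oracle is capped at 12 rows/columns by design.
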