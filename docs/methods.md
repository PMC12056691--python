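# Methods

## The empirical causal model

A long-format table is treated as an empirical causal model: each row is one
observed world; the categorical columns are the model's variables and their
*empirical domains* (the value sets realized in the table) stand in for the
model's value-assignment functions. The default schema has two context
variables (`Protein_ID`, `Concentration_of_Molecule`), one candidate
variable (`Small_Molecule`) and the real outcome `log2FC` — the log2 fold
change of a protein's corona abundance in treated relative to untreated
plasma. Any variable roles can be reassigned through `VariableSchema`
(e.g. promoting concentration to a candidate), and generic tables such as
the confounder toy use their own schemas.

This is token-level (actual) causality: verdicts are statements about the
observed dataset, not population-level claims, and they can change if the
dataset changes.

## The effect φ

φ is a dual-threshold rule on log2FC conditioned on protein class. The
class is defined solely by a set of accessions; the packaged default is the
25 most abundant plasma proteins (albumin first), user-overridable. In the
default `depletion_enrichment` orientation

φ(record) ⇔ (abundant ∧ log2FC ≤ θ_abundant) ∨ (¬abundant ∧ log2FC > θ_rest)

which encodes the desirable corona change: depletion of dominant proteins,
enrichment of the rest. A mirrored `enrichment_only` orientation
(abundant: ≥ θ_abundant; rest: ≤ θ_rest) is provided for screening
molecules that *raise* abundant-protein levels; the two rules are genuinely
different conventions in circulation for this analysis, so the orientation
is an explicit parameter rather than a hidden choice. Boundary conventions
(≤ on the abundant side, strict > on the rest side; ≥/≤ in the mirrored
mode) are fixed and tested — records exactly at a threshold are a defined
case, not an accident of floating point. Both thresholds default to 0.1
log2 units, the pivot separating the two sweep ranges.

Records with missing or non-finite outcome are rejected at read time and
counted per reason; imputation is out of scope.

## Cause identification

For a candidate assignment X ← x:

- **AC1** holds iff some record has X = x and φ.
- **Contingency matching**: the actual world is the set of X = x records.
  For every context (joint value of all other schema variables, outcome
  excluded) realized in the actual world, the matched counterfactual world
  is the set of X ≠ x records with exactly that context. Contexts observed
  only under X ≠ x are ignored (contexts are keyed by actual-world
  occurrence); contexts with no counterpart contribute to the actual-world
  probability but not the counterfactual one — a stated approximation.
- **PC2** holds iff P(φ | actual) > P(φ | counterfactual), strictly; ties
  are never causes. P(φ | actual) = k/n over all X = x records. Two
  aggregations of the counterfactual probability are implemented because the
  choice is genuinely open:
  - `pooled`: all matched counterfactual records form one pool.
  - `standardized` (default): the per-context counterfactual probabilities
    are averaged with weights proportional to the number of actual-world
    records in each usable context. This is the direct-standardization
    estimator; it is immune to Simpson-type reversal, and on the
    six-record confounder world it yields an exact tie (2/3 vs 2/3) where
    the pooled mode is fooled (2/3 vs 1/3). On a balanced design — every
    context observed exactly once per candidate value, as in the full
    factorial study layout — the two modes provably coincide (tested).
- **AC3** is automatic: only singleton causes are searched; multi-variable
  cause sets are out of scope.

All probabilities are exact `fractions.Fraction` ratios of record counts;
PC2 is decided by exact rational comparison. Identified causes are ranked
by the conditional probability P(φ | X = x) — identical to the actual-world
probability under the convention above, retained as a separate field — with
deterministic tie-breaking: larger support, then lexicographic variable and
value. `brute_force_causes` recomputes everything by literal nested-loop
set construction with no shared code path and is the oracle in tests.

## Threshold sweep

θ_abundant ranges over [min observed log2FC, 0.1] and θ_rest over
[0.1, max observed log2FC], linear spacing, endpoints included, default
20 × 21 = 420 cells (grid resolution is a free parameter; 420 cells keeps
percentages interpretable as integer cell counts). Each cell runs the full
search and stores the top-3 causes or a `None` marker. Cells are
independent, so the grid is a pure function of (table, axes, k, mode); the
contingency index is threshold-independent and is built once per table, not
per cell. The frequency summary reports raw cell counts alongside
percentages (denominator: all cells, `None` tracked as its own row) so
either denominator convention can be recovered.

## Synthetic data generator

The generator emulates the study layout: one record per
(protein × molecule × concentration), defaults 20 proteins (first 5
abundant, synthetic accessions `SYN0001…` kept disjoint from the real
fixture), the 10 study treatment labels (8 single molecules plus the
"Sauce 1"/"Sauce 2" mixtures), concentrations {10, 100, 1000}, and a
planted cause (PtdChos):

log2FC(p, m, c) = gain(c) · shift(m, class(p)) + ε,  ε ~ N(0, noise_sd)

The planted molecule's shift is −1.0 for abundant and +1.0 for non-abundant
proteins (clearly separated from, but on the scale of, real corona fold
changes). Null molecules get one molecule-specific draw from
N(0, null_shift_sd), identical across classes, so nuisance shifts can never
mimic the planted class-dependent signature. Both noise scales default to
0.2 log2 units — nuisance variation at one fifth of the planted effect,
chosen once as a realistically noisy but recoverable regime.
`concentration_gain` defaults to 1 for all levels, which makes cause
identification provably concentration-invariant and is the lever for
testing that property. Gaussian noise on log2FC is the simplest model
consistent with fold-change data; the generator reproduces the
combinatorial design, effect directions and nuisance variation, but none of
mass-spec intensity scaling, missingness mechanisms, or protein–protein
correlation — so passing synthetic tests demonstrates correctness of the
causal machinery, not biological validity on any particular real dataset.

A corner case worth knowing: with all noise at zero and thresholds at the
0.1/0.1 pivot, null molecules sit exactly at log2FC = 0, which satisfies
the abundant-side rule (0 ≤ 0.1). φ therefore fires on abundant-protein
records of *every* molecule; the planted molecule is still the unique
identified cause (probability 1 vs a strictly smaller counterfactual), and
grid cells where θ_rest reaches the maximum while θ_abundant ≥ 0 are
molecule-independent and correctly yield `None`.

`generate_confounded` emits the six-record season/ice-cream world in which
the outcome depends only on the season; it is the canonical test that the
standardized PC2 rejects confounded candidates that the pooled mode
accepts.

## Numerical and interface choices

- Probabilities: exact rationals internally; serialized at 12 significant
  digits; `NA` for undefined counterfactuals, the literal token `None` for
  cause-free sweep slots.
- Input: CSV/TSV auto-detected by header sniffing; a column-mapping option
  covers files whose headers differ from the canonical names; extra columns
  ignored, row order preserved.
- Determinism: identical inputs and configuration give byte-identical
  outputs; the generator is a pure function of its config (including seed);
  every CLI run echoes its resolved configuration next to its outputs.
- Degenerate inputs are defined, not errors: a candidate value with no
  counterfactual counterpart gets an undefined counterfactual probability
  and a False PC2; a table whose log2FC range does not straddle the 0.1
  pivot raises a degenerate-range error before sweeping.

## Problem sizes

Tests and the acceptance script run on desk-scale inputs chosen to keep the
suite fast while exercising every code path: 30-record random worlds for
oracle equivalence (100 replicates), 480–600-record synthetic tables for
recovery (50 replicates) and for the full 420-cell sweep. The search is
O(cells × candidates × contexts) with an index built once per table; the
default sweep on the default synthetic table completes in about a second.

## Known limitations

- Only singleton causes; no structural-equation inference, no type-level
  (do-calculus) or Granger causality.
- Contexts without counterfactual counterparts are asymmetrically used
  (actual side only), as stated above.
- Verdicts are dataset-relative; small strata make PC2 comparisons coarse
  (probabilities are ratios of small integers).
- The reader handles long-format tables only; wide matrices must be melted
  upstream. No mass-spec quantification, normalization or imputation.
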