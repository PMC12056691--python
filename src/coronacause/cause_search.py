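"""Singleton actual-cause identification by counterfactual contingency matching.

A candidate assignment X ← x is an actual cause of the effect φ when

* **AC1** — some observed record has X = x and φ;
* **PC2** — the probability of φ among the X = x records (the *actual
  world*) strictly exceeds its probability among contingency-matched
  records with X ≠ x (the *counterfactual worlds*: identical in every
  other variable, differing only in X); this is the probability-raising
  replacement for the deterministic counterfactual clause;
* **AC3** — minimality, automatic here because only singleton causes are
  searched.

Two PC2 aggregation modes are provided.  ``pooled`` lumps every matched
counterfactual record into one pool before taking the ratio; ``standardized``
(default) averages the per-context counterfactual probabilities weighted by
how often each context occurs in the actual world, which is immune to
Simpson-type reversal driven by a confounding context variable.  On a
balanced design (every context observed once per candidate value) the two
modes coincide.

All probabilities are exact ratios of record counts (`fractions.Fraction`);
no floating-point comparison ever decides PC2.  Identified causes are ranked
by the conditional probability of the effect given the cause,
count(X = x ∧ φ) / count(X = x) — a likelihood used to order causes, never
to establish them.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .causal_core import (
    Assignment,
    CausalTable,
    EffectPredicate,
    SchemaError,
    evaluate_effect,
)

MODES = ("pooled", "standardized")

#: φ may be an :class:`EffectPredicate` or any callable record → bool.
Predicate = Callable[[Mapping[str, Any]], bool]


class UndefinedProbabilityError(ValueError):
    """Requested a probability whose denominator is zero."""


@dataclass
class CauseResult:
    """Verdict and probabilities for one candidate assignment X ← x.

    ``p_counterfactual`` is ``None`` when no counterfactual world exists
    (every matched context is empty), in which case ``pc2`` is False.
    ``rank`` is set (1-based) for identified causes only.
    """

    assignment: Assignment
    ac1: bool
    pc2: bool
    ac3: bool
    p_actual: Fraction
    p_counterfactual: Fraction | None
    conditional_probability: Fraction
    n_actual: int
    n_counterfactual: int
    rank: int | None = None

    @property
    def is_cause(self) -> bool:
        return self.ac1 and self.pc2 and self.ac3


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def _context_columns(table: CausalTable, variable: str) -> list[str]:
    """Contingency context = every schema variable except X and the outcome."""
    schema = table.schema
    return [
        v
        for v in (*schema.context_vars, *schema.candidate_vars)
        if v != variable
    ]


def phi_mask(table: CausalTable, predicate: Predicate) -> np.ndarray:
    """Boolean φ over all records (vectorized for EffectPredicate)."""
    if isinstance(predicate, EffectPredicate):
        return predicate.mask(table)
    return np.fromiter(
        (bool(predicate(rec)) for rec in table.records()),
        dtype=bool,
        count=len(table),
    )


class ContingencyIndex:
    """Row-index structure for contingency matching of one candidate variable.

    For every observed value x of the variable, stores the rows of the actual
    world (X = x) and, per context realized in the actual world, the matched
    counterfactual rows (X ≠ x, same context).  The structure depends only on
    the categorical columns, so it can be built once and reused across many
    effect predicates (as the threshold sweep does).
    """

    def __init__(self, table: CausalTable, variable: str):
        if variable not in table.schema.candidate_vars:
            raise SchemaError(
                f"{variable!r} is not a candidate variable "
                f"(candidates: {table.schema.candidate_vars})"
            )
        self.variable = variable
        df = table.data
        x = df[variable].to_numpy()
        self.values: list[Any] = sorted(set(x.tolist()), key=str)
        self.actual: dict[Any, np.ndarray] = {
            v: np.flatnonzero(x == v) for v in self.values
        }
        ctx_cols = _context_columns(table, variable)
        # contexts[v] = list of (context key, actual rows, counterfactual rows)
        self.contexts: dict[Any, list[tuple[tuple, np.ndarray, np.ndarray]]] = {
            v: [] for v in self.values
        }
        if ctx_cols:
            groups = df.groupby(ctx_cols, sort=True).indices
        else:
            groups = {(): np.arange(len(df))}
        for key, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
            key = key if isinstance(key, tuple) else (key,)
            idx = np.asarray(idx)
            here = x[idx]
            for v in sorted(set(here.tolist()), key=str):
                is_v = here == v
                self.contexts[v].append((key, idx[is_v], idx[~is_v]))


def _evaluate_assignment(
    index: ContingencyIndex,
    value: Any,
    phi: np.ndarray,
    mode: str,
) -> CauseResult:
    act = index.actual[value]
    n_actual = int(act.size)
    k_actual = int(phi[act].sum())
    p_actual = Fraction(k_actual, n_actual)
    ac1 = k_actual > 0

    usable = [(a, c) for _, a, c in index.contexts[value] if c.size > 0]
    n_cf = sum(int(c.size) for _, c in usable)
    if n_cf == 0:
        p_cf: Fraction | None = None
        pc2 = False
    elif mode == "pooled":
        k_cf = sum(int(phi[c].sum()) for _, c in usable)
        p_cf = Fraction(k_cf, n_cf)
        pc2 = p_actual > p_cf
    else:  # standardized: actual-world-weighted mean of per-context p_cf
        n_act_usable = sum(int(a.size) for a, _ in usable)
        total = Fraction(0)
        for a, c in usable:
            total += Fraction(int(a.size) * int(phi[c].sum()), int(c.size))
        p_cf = total / n_act_usable
        pc2 = p_actual > p_cf

    return CauseResult(
        assignment=Assignment(index.variable, value),
        ac1=ac1,
        pc2=pc2,
        ac3=True,  # singleton causes are minimal by construction
        p_actual=p_actual,
        p_counterfactual=p_cf,
        conditional_probability=p_actual,
        n_actual=n_actual,
        n_counterfactual=n_cf,
    )


def _rank_key(r: CauseResult) -> tuple:
    # conditional probability desc, support desc, then lexicographic
    return (
        -r.conditional_probability,
        -r.n_actual,
        str(r.assignment.variable),
        str(r.assignment.value),
    )


def _order_and_rank(results: list[CauseResult], k: int) -> list[CauseResult]:
    causes = sorted((r for r in results if r.is_cause), key=_rank_key)
    others = sorted(
        (r for r in results if not r.is_cause),
        key=lambda r: (str(r.assignment.variable), str(r.assignment.value)),
    )
    for i, r in enumerate(causes):
        r.rank = i + 1 if i < k else None
    return causes + others


def candidate_assignments(table: CausalTable, variable: str) -> list[Assignment]:
    """One assignment per distinct observed value, in sorted order."""
    if variable not in table.schema.candidate_vars:
        raise SchemaError(
            f"{variable!r} is not a candidate variable "
            f"(candidates: {table.schema.candidate_vars})"
        )
    values = sorted(table.domains[variable], key=str)
    return [Assignment(variable, v) for v in values]


def ac1_holds(
    table: CausalTable, assignment: Assignment, predicate: Predicate
) -> bool:
    """AC1: the assignment and the effect occur together in some record."""
    assignment.validate(table)
    phi = phi_mask(table, predicate)
    where = (table.data[assignment.variable] == assignment.value).to_numpy()
    return bool((phi & where).any())


def contingency_split(
    table: CausalTable, assignment: Assignment
) -> tuple[pd.DataFrame, dict[tuple, pd.DataFrame]]:
    """Split the table into the actual world and matched counterfactual worlds.

    Returns the records with X = x, and a map from each context realized in
    the actual world (tuple of the remaining variables' values, in schema
    order) to the records with X ≠ x sharing that exact context — an empty
    frame when no counterpart exists.  Contexts seen only under X ≠ x do not
    appear.
    """
    assignment.validate(table)
    index = ContingencyIndex(table, assignment.variable)
    df = table.data
    actual = df.iloc[index.actual[assignment.value]]
    by_context = {
        key: df.iloc[cf] for key, _, cf in index.contexts[assignment.value]
    }
    return actual, by_context


def pc2_holds(
    table: CausalTable,
    assignment: Assignment,
    predicate: Predicate,
    mode: str = "standardized",
) -> tuple[bool, Fraction, Fraction | None]:
    """PC2: strict probability raising over contingency-matched worlds.

    Returns ``(verdict, p_actual, p_counterfactual)``; the counterfactual
    probability is ``None`` (and the verdict False) when the assignment has
    no counterfactual counterpart in any matched context.
    """
    _check_mode(mode)
    assignment.validate(table)
    index = ContingencyIndex(table, assignment.variable)
    phi = phi_mask(table, predicate)
    r = _evaluate_assignment(index, assignment.value, phi, mode)
    return r.pc2, r.p_actual, r.p_counterfactual


def conditional_probability(
    table: CausalTable, assignment: Assignment, predicate: Predicate
) -> Fraction:
    """count(X = x ∧ φ) / count(X = x), as an exact ratio."""
    assignment.validate(table)
    where = (table.data[assignment.variable] == assignment.value).to_numpy()
    n = int(where.sum())
    if n == 0:
        raise UndefinedProbabilityError(
            f"{assignment.variable} = {assignment.value!r} never occurs"
        )
    phi = phi_mask(table, predicate)
    return Fraction(int((phi & where).sum()), n)


def find_causes(
    table: CausalTable,
    predicate: Predicate,
    variables: Sequence[str] | None = None,
    k: int = 3,
    mode: str = "standardized",
) -> list[CauseResult]:
    """Evaluate every candidate assignment and rank the identified causes.

    Returns one :class:`CauseResult` per candidate assignment: causes first,
    ordered by conditional probability (ties: larger support, then
    lexicographic value) with the top ``k`` flagged by rank, followed by the
    non-causes in sorted order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_mode(mode)
    if variables is None:
        variables = table.schema.candidate_vars
    for v in variables:
        if v not in table.schema.candidate_vars:
            raise SchemaError(f"{v!r} is not a candidate variable")
    phi = phi_mask(table, predicate)
    indexes = {v: ContingencyIndex(table, v) for v in variables}
    return find_causes_from_mask(indexes, phi, k=k, mode=mode)


def find_causes_from_mask(
    indexes: Mapping[str, ContingencyIndex],
    phi: np.ndarray,
    k: int = 3,
    mode: str = "standardized",
) -> list[CauseResult]:
    """Core search given prebuilt contingency indexes and a φ mask.

    The threshold sweep calls this directly so the (threshold-independent)
    index structure is built once per table rather than once per grid cell.
    """
    results = [
        _evaluate_assignment(index, v, phi, mode)
        for index in indexes.values()
        for v in index.values
    ]
    return _order_and_rank(results, k)


def brute_force_causes(
    table: CausalTable,
    predicate: Predicate,
    variables: Sequence[str] | None = None,
    k: int = 3,
    mode: str = "standardized",
) -> list[CauseResult]:
    """Independent oracle: the same search by literal set construction.

    Pure-Python nested loops over plain dict records, no shared index or
    vectorized code path with :func:`find_causes`; intended for small tables
    (≲ 10⁴ records) and exact field-for-field comparison in tests.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_mode(mode)
    schema = table.schema
    if variables is None:
        variables = schema.candidate_vars
    records = table.records()
    if isinstance(predicate, EffectPredicate):
        phi = [
            evaluate_effect(r, predicate, outcome_var=schema.outcome_var)
            for r in records
        ]
    else:
        phi = [bool(predicate(r)) for r in records]

    results: list[CauseResult] = []
    for var in variables:
        if var not in schema.candidate_vars:
            raise SchemaError(f"{var!r} is not a candidate variable")
        ctx_cols = [
            c for c in (*schema.context_vars, *schema.candidate_vars) if c != var
        ]
        values = sorted({r[var] for r in records}, key=str)
        for x in values:
            actual = [i for i, r in enumerate(records) if r[var] == x]
            n_actual = len(actual)
            k_actual = sum(1 for i in actual if phi[i])
            p_actual = Fraction(k_actual, n_actual)

            contexts = sorted(
                {tuple(records[i][c] for c in ctx_cols) for i in actual}, key=str
            )
            usable: list[tuple[list[int], list[int]]] = []
            for ctx in contexts:
                act_here = [
                    i
                    for i in actual
                    if tuple(records[i][c] for c in ctx_cols) == ctx
                ]
                cf_here = [
                    i
                    for i, r in enumerate(records)
                    if r[var] != x
                    and tuple(r[c] for c in ctx_cols) == ctx
                ]
                if cf_here:
                    usable.append((act_here, cf_here))
            n_cf = sum(len(c) for _, c in usable)
            if n_cf == 0:
                p_cf: Fraction | None = None
                pc2 = False
            elif mode == "pooled":
                k_cf = sum(1 for _, c in usable for i in c if phi[i])
                p_cf = Fraction(k_cf, n_cf)
                pc2 = p_actual > p_cf
            else:
                n_act_usable = sum(len(a) for a, _ in usable)
                total = Fraction(0)
                for a, c in usable:
                    total += (
                        Fraction(len(a), n_act_usable)
                        * Fraction(sum(1 for i in c if phi[i]), len(c))
                    )
                p_cf = total
                pc2 = p_actual > p_cf

            results.append(
                CauseResult(
                    assignment=Assignment(var, x),
                    ac1=k_actual > 0,
                    pc2=pc2,
                    ac3=True,
                    p_actual=p_actual,
                    p_counterfactual=p_cf,
                    conditional_probability=p_actual,
                    n_actual=n_actual,
                    n_counterfactual=n_cf,
                )
            )
    return _order_and_rank(results, k)
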