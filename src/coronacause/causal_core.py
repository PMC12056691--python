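"""Domain types for the empirical causal model of protein-corona composition.

The analysis treats a long-format proteomics table as an empirical causal
model in the Halpern–Pearl sense: each row is one observed world, the
categorical columns (protein accession, spiked small molecule, concentration)
are the model's variables, and the real-valued outcome is the log2 fold
change (log2FC) of a protein's corona abundance in treated relative to
untreated plasma.  The variables' empirical domains — the value sets realized
in the table — stand in for the model's value-assignment functions.

The effect of interest, φ, is a dual-threshold rule over log2FC whose
direction depends on whether the protein belongs to the set of highly
abundant plasma proteins (packaged fixture of 25 accessions).  The desirable
corona change is *depletion* of highly abundant proteins together with
*enrichment* of everything else, so in the default orientation φ fires when
an abundant protein falls at or below its threshold, or a non-abundant
protein rises strictly above its threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Any, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

# Canonical column names of the long-format corona table.
PROTEIN = "Protein_ID"
MOLECULE = "Small_Molecule"
CONCENTRATION = "Concentration_of_Molecule"
LOG2FC = "log2FC"

#: log2FC value separating the depletion-side and enrichment-side threshold
#: ranges; also the default value of both thresholds.
THRESHOLD_PIVOT = 0.1

_FIXTURE_NAME = "highly_abundant_proteins.tsv"


class SchemaError(ValueError):
    """A table or schema violates the causal-model contract."""


class RecordError(ValueError):
    """A single record cannot be evaluated (e.g. missing/non-finite outcome)."""


@dataclass(frozen=True)
class VariableSchema:
    """Names and roles of the causal model's variables.

    Parameters
    ----------
    context_vars
        Categorical variables held fixed when constructing counterfactual
        worlds (default: protein accession and treatment concentration).
    candidate_vars
        Variables whose value assignments are eligible to be causes
        (default: the spiked small molecule).
    outcome_var
        The real-valued outcome column (default: log2FC).
    unit_note
        Free-text metadata carrying measurement units.
    """

    context_vars: tuple[str, ...] = (PROTEIN, CONCENTRATION)
    candidate_vars: tuple[str, ...] = (MOLECULE,)
    outcome_var: str = LOG2FC
    unit_note: str = "Concentration_of_Molecule in ug/mL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "context_vars", tuple(self.context_vars))
        object.__setattr__(self, "candidate_vars", tuple(self.candidate_vars))
        if not self.candidate_vars:
            raise SchemaError("candidate_vars must be nonempty")
        cats = (*self.context_vars, *self.candidate_vars)
        if len(set(cats)) != len(cats):
            raise SchemaError(f"duplicate variable names in schema: {cats}")
        if self.outcome_var in cats:
            raise SchemaError(
                f"outcome variable {self.outcome_var!r} cannot also be a "
                "context or candidate variable"
            )

    @property
    def all_vars(self) -> tuple[str, ...]:
        """All schema columns, outcome last."""
        return (*self.context_vars, *self.candidate_vars, self.outcome_var)


DEFAULT_SCHEMA = VariableSchema()


@dataclass(frozen=True)
class CausalTable:
    """A validated empirical causal model: schema + observed records.

    ``data`` holds one row per observed world; every schema column must be
    present and the outcome column must be finite real throughout.  Rows with
    missing outcomes are expected to have been filtered (and counted) by the
    reader before construction.
    """

    schema: VariableSchema
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in self.schema.all_vars if c not in self.data.columns]
        if missing:
            raise SchemaError(f"table is missing required column(s): {missing}")
        df = self.data[list(self.schema.all_vars)].reset_index(drop=True)
        y = pd.to_numeric(df[self.schema.outcome_var], errors="coerce")
        bad = ~np.isfinite(y.to_numpy(dtype=float))
        if bad.any():
            rows = list(np.flatnonzero(bad)[:5])
            raise RecordError(
                f"{int(bad.sum())} record(s) have missing/non-finite outcome "
                f"{self.schema.outcome_var!r} (first rows: {rows})"
            )
        df[self.schema.outcome_var] = y.astype(float)
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def domains(self) -> dict[str, set]:
        """Empirical domain (realized value set) of every schema variable."""
        return {v: set(self.data[v].tolist()) for v in self.schema.all_vars}

    def outcome(self) -> np.ndarray:
        return self.data[self.schema.outcome_var].to_numpy(dtype=float)

    def records(self) -> list[dict[str, Any]]:
        """Rows as plain dicts (order preserved)."""
        return self.data.to_dict(orient="records")

    def __iter__(self) -> Iterator[dict[str, Any]]:
        return iter(self.records())

    def restrict(self, variable: str, value: Any) -> "CausalTable":
        """Sub-table of records where ``variable == value`` (same schema)."""
        if variable not in self.schema.all_vars:
            raise SchemaError(f"unknown variable {variable!r}")
        sub = self.data[self.data[variable] == value]
        if sub.empty:
            raise SchemaError(f"no records with {variable} == {value!r}")
        return CausalTable(self.schema, sub)


class Assignment(NamedTuple):
    """A candidate cause X ← x: ``variable`` assigned categorical ``value``."""

    variable: str
    value: Any

    def validate(self, table: CausalTable) -> None:
        if self.variable not in table.schema.candidate_vars:
            raise SchemaError(
                f"{self.variable!r} is not a candidate variable "
                f"(candidates: {table.schema.candidate_vars})"
            )
        if self.value not in table.domains[self.variable]:
            raise SchemaError(
                f"value {self.value!r} never observed for {self.variable!r}"
            )


class Orientation(str, Enum):
    """Direction convention of the dual-threshold effect rule.

    ``DEPLETION_ENRICHMENT`` (default): φ fires on depletion of abundant
    proteins (log2FC ≤ θ_abundant) or enrichment of the rest
    (log2FC > θ_rest) — the desirable corona change.

    ``ENRICHMENT_ONLY``: the mirrored reading — φ fires on enrichment of
    abundant proteins (log2FC ≥ θ_abundant) or non-enrichment of the rest
    (log2FC ≤ θ_rest); useful for screening molecules *unsuitable* for
    deepening proteome coverage.
    """

    DEPLETION_ENRICHMENT = "depletion_enrichment"
    ENRICHMENT_ONLY = "enrichment_only"


@lru_cache(maxsize=1)
def _fixture_frame() -> pd.DataFrame:
    with resources.files("coronacause.data").joinpath(_FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return df


def abundant_protein_table() -> pd.DataFrame:
    """The packaged list of the 25 most abundant plasma proteins.

    Returns a two-column frame (``accession``, ``protein_name``) ordered by
    plasma abundance rank (albumin first).
    """
    return _fixture_frame().copy()


def load_abundant_fixture() -> frozenset[str]:
    """Accessions of the 25 highly abundant plasma proteins, as a set."""
    return frozenset(_fixture_frame()["accession"])


@dataclass(frozen=True)
class EffectPredicate:
    """The effect φ: a dual-threshold rule over log2FC by protein class.

    Parameters
    ----------
    theta_abundant
        Threshold applied to proteins in ``abundant_ids``.
    theta_rest
        Threshold applied to all other proteins.
    abundant_ids
        Accessions of the highly abundant proteins (default: packaged
        25-protein fixture).  May be empty, in which case every record is
        treated as non-abundant.
    orientation
        Boundary/direction convention; see :class:`Orientation`.
    protein_var
        Column holding the protein accession.
    """

    theta_abundant: float = THRESHOLD_PIVOT
    theta_rest: float = THRESHOLD_PIVOT
    abundant_ids: frozenset[str] = field(default_factory=load_abundant_fixture)
    orientation: Orientation = Orientation.DEPLETION_ENRICHMENT
    protein_var: str = PROTEIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundant_ids", frozenset(self.abundant_ids))
        object.__setattr__(self, "orientation", Orientation(self.orientation))

    def __call__(self, record: Mapping[str, Any], outcome_var: str = LOG2FC) -> bool:
        return evaluate_effect(record, self, outcome_var=outcome_var)

    def mask(self, table: CausalTable) -> np.ndarray:
        """Vectorized φ over a whole table (boolean array, row order)."""
        y = table.outcome()
        if self.protein_var in table.data.columns:
            abundant = table.data[self.protein_var].isin(self.abundant_ids).to_numpy()
        else:
            abundant = np.zeros(len(y), dtype=bool)
        if self.orientation is Orientation.DEPLETION_ENRICHMENT:
            return np.where(abundant, y <= self.theta_abundant, y > self.theta_rest)
        return np.where(abundant, y >= self.theta_abundant, y <= self.theta_rest)


def evaluate_effect(
    record: Mapping[str, Any],
    predicate: EffectPredicate,
    outcome_var: str = LOG2FC,
) -> bool:
    """Evaluate φ on one record.  Pure and total on valid records.

    Raises
    ------
    RecordError
        If the outcome value is missing or non-finite.
    """
    y = record.get(outcome_var)
    if y is None or not isinstance(y, (int, float, np.floating, np.integer)) \
            or not math.isfinite(float(y)):
        raise RecordError(
            f"record {dict(record)!r}: outcome {outcome_var!r} is missing or "
            f"non-finite ({y!r})"
        )
    y = float(y)
    abundant = record.get(predicate.protein_var) in predicate.abundant_ids
    if predicate.orientation is Orientation.DEPLETION_ENRICHMENT:
        return y <= predicate.theta_abundant if abundant else y > predicate.theta_rest
    return y >= predicate.theta_abundant if abundant else y <= predicate.theta_rest
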