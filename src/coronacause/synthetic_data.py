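"""Synthetic corona tables with known (planted) causal structure.

The generator emulates the study design behind the empirical causal model:
one log2 fold-change observation per (protein x small molecule x
concentration) cell.  A *planted* causal molecule shifts highly abundant
proteins toward depletion (negative log2FC) and the remaining proteins
toward enrichment (positive log2FC) — the signature of a molecule that
deepens plasma proteome coverage.  Every other ("null") molecule carries a
single molecule-specific nuisance shift drawn from N(0, null_shift_sd),
identical across protein classes so it can never mimic the planted
class-dependent signature, plus independent per-record Gaussian noise.

The generator is a test harness, not a biophysical model: it reproduces the
combinatorial layout, the direction and rough size of fold-change effects,
and between-molecule nuisance variation, but none of mass-spec intensity
scaling, missingness, or protein-protein correlation.

A second generator emits the classic confounding scenario (season drives
both ice-cream sales and shark attacks) as a tiny causal table on which
pooled PC2 is fooled by the confounder and context-standardized PC2 is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .causal_core import (
    CONCENTRATION,
    LOG2FC,
    MOLECULE,
    PROTEIN,
    CausalTable,
    VariableSchema,
)

#: Candidate treatment labels mirroring the study: eight single molecules
#: plus the two fixed four-molecule mixtures ("Sauce 1", "Sauce 2").
STUDY_MOLECULES = (
    "Diglycerol",
    "Glucose",
    "IMP",
    "PE",
    "PtdChos",
    "PtdIns",
    "Sauce 1",
    "Sauce 2",
    "Triglyceride",
    "Vitamin B-complex",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a corona-like table.

    Defaults follow the emulated study design: 20 proteins of which the
    first 5 are highly abundant, the 10 study treatment labels with PtdChos
    planted as the true cause, three concentrations, depletion/enrichment
    shifts of -1/+1 log2 units, and nuisance scales of 0.2.
    """

    n_proteins: int = 20
    n_abundant: int = 5
    molecules: tuple[str, ...] = STUDY_MOLECULES
    concentrations: tuple[Any, ...] = (10, 100, 1000)
    planted_cause: str | None = "PtdChos"
    depletion_shift: float = -1.0
    enrichment_shift: float = 1.0
    null_shift_sd: float = 0.2
    noise_sd: float = 0.2
    concentration_gain: Mapping[Any, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "molecules", tuple(self.molecules))
        object.__setattr__(self, "concentrations", tuple(self.concentrations))
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0 <= self.n_abundant <= self.n_proteins:
            raise ValueError("n_abundant must be in [0, n_proteins]")
        if not self.molecules:
            raise ValueError("molecules must be nonempty")
        if self.planted_cause is not None and self.planted_cause not in self.molecules:
            raise ValueError(
                f"planted_cause {self.planted_cause!r} not in molecules"
            )
        if self.null_shift_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.concentration_gain is not None:
            missing = set(self.concentrations) - set(self.concentration_gain)
            if missing:
                raise ValueError(f"concentration_gain missing levels: {missing}")

    def gain(self, concentration: Any) -> float:
        if self.concentration_gain is None:
            return 1.0
        return float(self.concentration_gain[concentration])


def protein_ids(n: int) -> list[str]:
    """Synthetic accessions SYN0001..SYN<n>, disjoint from real fixtures."""
    return [f"SYN{i:04d}" for i in range(1, n + 1)]


def generate(config: SyntheticConfig) -> tuple[CausalTable, frozenset[str]]:
    """Generate one table per the config; returns (table, abundant IDs).

    log2FC(p, m, c) = gain(c) * shift(m, class(p)) + N(0, noise_sd), where
    shift is the depletion/enrichment shift for the planted molecule by
    protein class and a molecule-specific N(0, null_shift_sd) draw otherwise.
    Deterministic given ``config.seed``; exactly one record per
    (protein x molecule x concentration).
    """
    rng = np.random.default_rng(config.seed)
    proteins = protein_ids(config.n_proteins)
    abundant = frozenset(proteins[: config.n_abundant])

    null_shift = {
        m: (0.0 if config.null_shift_sd == 0 else float(rng.normal(0.0, config.null_shift_sd)))
        for m in config.molecules
        if m != config.planted_cause
    }

    rows = []
    for p in proteins:
        is_abundant = p in abundant
        for m in config.molecules:
            if m == config.planted_cause:
                shift = config.depletion_shift if is_abundant else config.enrichment_shift
            else:
                shift = null_shift[m]
            for c in config.concentrations:
                rows.append((p, m, c, config.gain(c) * shift))
    df = pd.DataFrame(rows, columns=[PROTEIN, MOLECULE, CONCENTRATION, LOG2FC])
    if config.noise_sd > 0:
        df[LOG2FC] = df[LOG2FC].to_numpy() + rng.normal(0.0, config.noise_sd, len(df))
    return CausalTable(VariableSchema(), df), abundant


# The confounded scenario: Season drives both the candidate (IceCream) and
# the outcome; IceCream raises the effect probability only through Season.
CONFOUNDED_SCHEMA = VariableSchema(
    context_vars=(),
    candidate_vars=("Season", "IceCream"),
    outcome_var="Effect",
    unit_note="Effect is binary-coded (1.0 = event occurred)",
)

_CONFOUNDED_ROWS: Sequence[tuple[str, str, float]] = (
    ("summer", "hi", 1.0),
    ("summer", "hi", 1.0),
    ("summer", "lo", 1.0),
    ("winter", "hi", 0.0),
    ("winter", "lo", 0.0),
    ("winter", "lo", 0.0),
)


def confounded_effect(record: Mapping[str, Any]) -> bool:
    """φ for the confounded table: the binary-coded outcome occurred."""
    return float(record["Effect"]) > 0.5


def generate_confounded(seed: int = 0) -> CausalTable:
    """The shark-attack/ice-cream confound as a six-record causal table.

    The outcome depends only on Season, yet ice-cream sales are higher in
    summer, so the pooled counterfactual probability for IceCream <- hi is
    diluted by winter records (2/3 > 1/3: spuriously a cause) while the
    season-standardized comparison ties exactly (2/3 vs 2/3: rejected).
    Season <- summer raises the effect probability in both modes.  ``seed``
    only shuffles record order; the verdicts are order-invariant.
    """
    rows = list(_CONFOUNDED_ROWS)
    np.random.default_rng(seed).shuffle(rows)
    df = pd.DataFrame(rows, columns=["Season", "IceCream", "Effect"])
    return CausalTable(CONFOUNDED_SCHEMA, df)
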