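"""Shared fixtures: hand-checkable toy worlds and random-table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coronacause import CausalTable, VariableSchema
from coronacause.synthetic_data import generate_confounded

#: Schema of the 4-row toy world T1: one context variable C, one candidate
#: M, binary-coded outcome y (the effect is y > 0.5).
T1_SCHEMA = VariableSchema(
    context_vars=("C",), candidate_vars=("M",), outcome_var="y"
)


def t1_effect(record) -> bool:
    return record["y"] > 0.5


@pytest.fixture
def toy_t1() -> CausalTable:
    """Rows (M=a,C=1,phi), (a,2,phi), (b,1,no), (b,2,phi): M<-a is the
    unique cause (p_actual 1 vs counterfactual 1/2)."""
    df = pd.DataFrame(
        {"C": [1, 2, 1, 2], "M": ["a", "a", "b", "b"], "y": [1.0, 1.0, 0.0, 1.0]}
    )
    return CausalTable(T1_SCHEMA, df)


@pytest.fixture
def toy_t2() -> CausalTable:
    """The season/ice-cream confound (outcome depends only on Season)."""
    return generate_confounded(seed=0)


def random_binary_table(seed: int) -> CausalTable:
    """Small random world: 5 proteins x 3 molecules x 2 concentrations with
    a random binary-coded outcome; used for oracle-equivalence sweeps."""
    rng = np.random.default_rng(seed)
    proteins = [f"P{i}" for i in range(5)]
    molecules = ["m1", "m2", "m3"]
    concentrations = [10, 100]
    rows = [
        (p, m, c, float(rng.integers(0, 2)))
        for p in proteins
        for m in molecules
        for c in concentrations
    ]
    df = pd.DataFrame(
        rows, columns=["Protein_ID", "Small_Molecule",
                       "Concentration_of_Molecule", "log2FC"]
    )
    return CausalTable(VariableSchema(), df)


def binary_effect(record) -> bool:
    return record["log2FC"] > 0.5
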