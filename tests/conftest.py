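"""Shared fixtures: every dataset is generated programmatically."""

from __future__ import annotations

import pandas as pd
import pytest

from phenokit.phenlist import RawTable, build_phenlist
from phenokit.synthetic import SyntheticSpec, synthetic_phenlist


def make_raw(rows: list[dict]) -> RawTable:
    return RawTable(frame=pd.DataFrame(rows), source="memory")


def make_phenlist(rows: list[dict], test="mutant", ref="control", **kw):
    return build_phenlist(make_raw(rows), test_genotype=test, ref_genotype=ref, **kw)


@pytest.fixture(scope="session")
def mm_phenlist():
    """Default multi-batch screen: 70+70 controls / 20 batches, 7+7 mutants / 2."""
    pl, truth = synthetic_phenlist()
    return pl, truth


@pytest.fixture(scope="session")
def het_phenlist():
    """Screen with genotype-specific residual variance (5 vs 15)."""
    spec = SyntheticSpec(
        residual_sd={"control": 5.0, "mutant": 15.0},
        n_test={"male": 40, "female": 40},
        seed=7,
    )
    return synthetic_phenlist(spec)


@pytest.fixture(scope="session")
def categorical_phenlist():
    """Rare-event categorical screen: 2% abnormal controls, 40% mutants."""
    spec = SyntheticSpec(
        n_control={"male": 200, "female": 200},
        n_test={"male": 5, "female": 5},
        seed=11,
    )
    return synthetic_phenlist(spec, categorical=True)
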