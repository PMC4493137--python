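"""Fisher-exact framework for categorical phenotypes.

Categorical variables in phenotyping screens are mostly rare-event
classifications (e.g. skull shape normal/abnormal).  The framework
pools all control data to estimate the abnormality rate — batch is
ignored entirely — and compares category proportions between control
and mutant animals with an exact test, separately for each sex and for
both sexes combined.  The combined view is a toolkit addition for
low-n robustness and is flagged as such in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exact_tests import (
    ContingencyTable,
    SubsetEmptyError,
    build_count_table,
    fisher_exact,
    proportion_effect,
)
from .phenlist import PhenList

logger = logging.getLogger("phenokit")


class FEInfeasibleError(ValueError):
    """Variable unsuitable for the Fisher-exact framework."""


@dataclass
class FESubAnalysis:
    """Exact test of one subset (all / male / female)."""

    subset: str
    table: ContingencyTable
    p_value: float
    #: category → test-minus-control proportion difference
    effects: dict[str, float | None]
    reference_level: str


def _reference_level(table: ContingencyTable) -> str:
    """Modal control category: the assumed 'normal' level."""
    return table.col_labels[int(np.argmax(table.counts[0]))]


def _analyse_subset(pl: PhenList, dep_var: str, subset: str) -> FESubAnalysis:
    table = build_count_table(pl, dep_var, subset=subset)
    p = fisher_exact(table)
    ref_level = _reference_level(table)
    effects: dict[str, float | None] = {}
    for j, level in enumerate(table.col_labels):
        if level == ref_level:
            continue
        # collapse to (level vs rest) before taking the proportion difference
        two = np.column_stack(
            [table.counts[:, j], table.counts.sum(axis=1) - table.counts[:, j]]
        )
        effects[level] = proportion_effect(two, focal_col=0)
    return FESubAnalysis(
        subset=subset, table=table, p_value=p, effects=effects, reference_level=ref_level
    )


def fe_analyse(pl: PhenList, dep_var: str):
    """Exact tests for combined, male-only and female-only subsets.

    Batch plays no role.  A sex absent from the data leaves that
    sub-analysis marked "not performed"; a variable without at least
    two observed levels is refused with guidance.  Returns a
    :class:`phenokit.results_io.PhenTestResult`.
    """
    from .results_io import PhenTestResult

    observed = pl.frame[dep_var].dropna()
    if observed.astype(str).nunique() < 2:
        raise FEInfeasibleError(
            f"{dep_var!r} shows no variability (single observed level); "
            "an exact test of proportions is uninformative"
        )

    analyses: dict[str, FESubAnalysis] = {}
    skipped: dict[str, str] = {}
    for subset in ("all", "male", "female"):
        try:
            analyses[subset] = _analyse_subset(pl, dep_var, subset)
        except SubsetEmptyError as exc:
            skipped[subset] = str(exc)
            logger.info("FE subset %s not performed: %s", subset, exc)

    return PhenTestResult.from_fe(pl=pl, dep_var=dep_var, analyses=analyses, skipped=skipped)
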