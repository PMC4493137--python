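"""Time-as-fixed-effect framework for concurrent-control designs.

When mutant animals are phenotyped in a small number of batches, each
accompanied by controls measured the same day, batch can enter the
regression as a fixed effect — the model estimates each batch offset
explicitly to separate it from the genotype effect:

    y = Genotype + Sex + Genotype:Sex [+ Weight] + Batch + e

The framework first reduces the dataset to concurrent batches only
(batches holding at least one treated and one control measurement),
then runs the same top-down optimisation as the mixed-model framework
with the random-batch test replaced by an ML likelihood-ratio test of
the batch fixed effect.  The design is intended for up to five batches
of treated animals; beyond that the mixed-model framework applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .mixed_model import (
    estimate_effects,
    classify_effect,
    fit_model,
    genotype_test,
    optimise_model,
    start_spec,
)
from .phenlist import PhenList

logger = logging.getLogger("phenokit")

#: Maximum number of treated-animal batches the framework accepts.
MAX_TREATED_BATCHES = 5


class TFInfeasibleError(ValueError):
    """Dataset cannot support a time-as-fixed-effect analysis."""


@dataclass
class ReductionReport:
    """Outcome of the concurrent-control reduction."""

    n_rows_in: int
    n_rows_kept: int
    batches_in: int
    batches_kept: int
    removed_control_only: int
    removed_treated_only: int
    removed_missing: int

    @property
    def n_rows_removed(self) -> int:
        return self.n_rows_in - self.n_rows_kept

    def describe(self) -> str:
        return (
            f"concurrent reduction: kept {self.n_rows_kept}/{self.n_rows_in} rows in "
            f"{self.batches_kept}/{self.batches_in} batches "
            f"(removed {self.removed_control_only} control-only, "
            f"{self.removed_treated_only} treated-without-control, "
            f"{self.removed_missing} unusable rows)"
        )


def tf_dataset(pl: PhenList, dep_var: str) -> tuple[PhenList, ReductionReport]:
    """Reduce to batches with both genotypes measured (concurrent design).

    A batch qualifies when it contains at least one treated and one
    control animal with a non-missing value of ``dep_var``.  All other
    rows — control-only batches, treated animals without concurrent
    controls, and rows unusable for the analysis (missing batch or
    response) — are removed and counted.  Idempotent.
    """
    if not pl.has_batch:
        raise TFInfeasibleError("no Batch column: concurrent-control reduction impossible")
    df = pl.frame
    usable = df["Batch"].notna() & df[dep_var].notna()
    work = df[usable]
    batches_in = int(df["Batch"].dropna().nunique())

    treated = work[work["Genotype"] == pl.test_genotype]["Batch"]
    control = work[work["Genotype"] == pl.ref_genotype]["Batch"]
    concurrent = set(treated.unique()) & set(control.unique())

    keep_mask = usable & df["Batch"].isin(list(concurrent))
    removed_usable = usable & ~keep_mask
    control_only = int((df.loc[removed_usable, "Genotype"] == pl.ref_genotype).sum())
    treated_only = int((df.loc[removed_usable, "Genotype"] == pl.test_genotype).sum())
    missing = int((~usable).sum())

    report = ReductionReport(
        n_rows_in=len(df),
        n_rows_kept=int(keep_mask.sum()),
        batches_in=batches_in,
        batches_kept=len(concurrent),
        removed_control_only=control_only,
        removed_treated_only=treated_only,
        removed_missing=missing,
    )
    if not concurrent:
        raise TFInfeasibleError(
            "no batch contains both genotypes; the time-as-fixed-effect design "
            "requires concurrent controls — consider the mixed-model or "
            "reference-range framework"
        )
    reduced = PhenList(
        frame=df[keep_mask].reset_index(drop=True),
        test_genotype=pl.test_genotype,
        ref_genotype=pl.ref_genotype,
        variables=dict(pl.variables),
        cleaning_log=pl.cleaning_log + [report.describe()],
    )
    logger.info(report.describe())
    return reduced, report


def treated_batch_count(pl: PhenList, dep_var: str) -> int:
    """Distinct batches containing treated animals with a usable response."""
    df = pl.frame
    mask = (df["Genotype"] == pl.test_genotype) & df[dep_var].notna() & df["Batch"].notna()
    return int(df[mask]["Batch"].nunique())


def tf_analyse(pl: PhenList, dep_var: str, include_weight: bool = False):
    """Concurrent reduction, batch-as-fixed-effect fit, genotype test.

    Refuses designs with more than :data:`MAX_TREATED_BATCHES` treated
    batches (the mixed-model framework is the right tool there) or
    fewer than two.  Returns a
    :class:`phenokit.results_io.PhenTestResult`.
    """
    from .results_io import PhenTestResult

    reduced, report = tf_dataset(pl, dep_var)
    n_treated_batches = treated_batch_count(reduced, dep_var)
    if n_treated_batches > MAX_TREATED_BATCHES:
        raise TFInfeasibleError(
            f"{n_treated_batches} treated batches exceed the framework's limit of "
            f"{MAX_TREATED_BATCHES}; use the mixed-model framework"
        )
    if n_treated_batches < 2:
        raise TFInfeasibleError(
            "fewer than 2 treated batches after reduction; batch and genotype "
            "effects cannot be separated — consider the reference-range framework"
        )

    start = start_spec(dep_var, include_weight=include_weight, batch_role="fixed")
    final_spec, trace = optimise_model(reduced, start)
    p_geno = genotype_test(reduced, final_spec)
    fitted = fit_model(reduced, replace(final_spec, fit_objective="REML"))
    effects = estimate_effects(fitted)
    tag = classify_effect(p_geno, effects, trace.interaction_kept)
    return PhenTestResult.from_model(
        method="TF", pl=reduced, dep_var=dep_var, genotype_p=p_geno,
        effects=effects, classification_tag=tag, trace=trace,
        fitted=fitted, include_weight=include_weight, reduction=report,
    )
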