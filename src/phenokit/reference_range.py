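"""Reference-range framework for low-n or single-batch designs.

A simple, conservative method: the central part (default 95%) of the
control distribution defines a "normal" reference range; every animal
is classified Low / Normal / High against it, and each tail is tested
with a Fisher exact test of the 2×2 table (tail vs rest) × (control,
mutant).  The effect size is the change in penetrance: the difference
between the mutant and control proportions falling in the tail.  No
batch adjustment is attempted — the method exists precisely for
designs where a batch model cannot be fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exact_tests import ContingencyTable, fisher_exact, proportion_effect
from .phenlist import PhenList

logger = logging.getLogger("phenokit")

#: Default central fraction of the control distribution called Normal.
DEFAULT_RANGE_PROPORTION = 0.95

#: Minimum controls with a usable response required to estimate thresholds.
MIN_CONTROLS = 60

CATEGORIES = ("Low", "Normal", "High")


class RRInfeasibleError(ValueError):
    """Too few controls (or invalid options) for a reference range."""


@dataclass(frozen=True)
class RRThresholds:
    """Control-derived Low/High cut points for one analysis stratum."""

    low_threshold: float
    high_threshold: float
    range_proportion: float
    n_controls_used: int
    sex: str  # male | female | combined

    def __post_init__(self) -> None:
        if self.low_threshold > self.high_threshold:
            raise ValueError("low threshold exceeds high threshold")


def compute_thresholds(
    controls,
    range_proportion: float = DEFAULT_RANGE_PROPORTION,
    sex: str = "combined",
    min_controls: int = MIN_CONTROLS,
) -> RRThresholds:
    """Quantile cut points bracketing the central ``range_proportion``.

    Linear interpolation between order statistics (the numpy default
    quantile estimator).  With p = 0.95 the cut points are the 2.5th
    and 97.5th percentiles of the control values.
    """
    values = np.asarray([v for v in np.asarray(controls, dtype=float) if np.isfinite(v)])
    if not 0 < range_proportion < 1:
        raise RRInfeasibleError(
            f"range proportion must lie strictly inside (0, 1), got {range_proportion}"
        )
    if len(values) < min_controls:
        raise RRInfeasibleError(
            f"{len(values)} usable controls < required floor of {min_controls}; "
            "the reference range cannot be estimated reliably"
        )
    tail = (1.0 - range_proportion) / 2.0
    low, high = np.quantile(values, [tail, 1.0 - tail], method="linear")
    return RRThresholds(
        low_threshold=float(low),
        high_threshold=float(high),
        range_proportion=range_proportion,
        n_controls_used=len(values),
        sex=sex,
    )


def classify_values(values, thr: RRThresholds) -> tuple[list[str], tuple[int, int, int]]:
    """Label each value Low / Normal / High against the thresholds.

    Strict inequalities: a value equal to a cut point is Normal, so the
    control extreme fraction never exceeds 1 − range_proportion.
    Missing values are skipped; the count triple sums to the number of
    non-missing values.
    """
    labels: list[str] = []
    counts = [0, 0, 0]
    for v in np.asarray(values, dtype=float):
        if not np.isfinite(v):
            continue
        if v < thr.low_threshold:
            label = "Low"
        elif v > thr.high_threshold:
            label = "High"
        else:
            label = "Normal"
        labels.append(label)
        counts[CATEGORIES.index(label)] += 1
    return labels, tuple(counts)


@dataclass
class TailResult:
    """One tail's exact test and penetrance change."""

    tail: str  # Low | High
    table: ContingencyTable
    p_value: float
    penetrance_change: float | None  # test minus control tail proportion


def rr_test(
    control_counts: tuple[int, int, int],
    mutant_counts: tuple[int, int, int],
    row_labels: tuple[str, str] = ("control", "test"),
) -> dict[str, TailResult]:
    """Per-tail exact tests from (Low, Normal, High) count triples.

    Each tail is collapsed to a 2×2 table, tail vs the two remaining
    categories, rows (control, mutant).  A genotype with zero animals
    makes the comparison undefined and the tail is skipped.
    """
    results: dict[str, TailResult] = {}
    ctrl = np.asarray(control_counts, dtype=np.int64)
    mut = np.asarray(mutant_counts, dtype=np.int64)
    if ctrl.sum() == 0 or mut.sum() == 0:
        logger.warning("a genotype has no classified animals; tail tests skipped")
        return results
    for tail, idx in (("Low", 0), ("High", 2)):
        table = ContingencyTable(
            row_labels=row_labels,
            col_labels=(tail, "rest"),
            counts=np.array(
                [[ctrl[idx], ctrl.sum() - ctrl[idx]], [mut[idx], mut.sum() - mut[idx]]]
            ),
        )
        p = fisher_exact(table)
        effect = proportion_effect(table, focal_col=0)
        results[tail] = TailResult(tail=tail, table=table, p_value=p, penetrance_change=effect)
    return results


@dataclass
class RRStratum:
    """Full reference-range analysis of one sex stratum."""

    sex: str
    thresholds: RRThresholds
    control_counts: tuple[int, int, int]
    mutant_counts: tuple[int, int, int]
    tails: dict[str, TailResult]
    note: str | None = None


def rr_analyse(
    pl: PhenList,
    dep_var: str,
    range_proportion: float = DEFAULT_RANGE_PROPORTION,
    min_controls: int = MIN_CONTROLS,
):
    """Reference-range analysis per sex plus a combined-sex stratum.

    Thresholds come from each sex's own controls when both sexes reach
    the control floor; otherwise a combined-sex reference range is used
    for everything and flagged, since sex is a dominant source of
    variation and per-sex ranges are preferred whenever estimable.
    Returns a :class:`phenokit.results_io.PhenTestResult`.
    """
    from .results_io import PhenTestResult

    if pl.variables.get(dep_var) != "continuous":
        raise RRInfeasibleError(f"{dep_var!r} is not a continuous variable")

    def usable(genotype: str, sex: str | None) -> np.ndarray:
        df = pl.subset(sex=sex, genotype=genotype)
        return df[dep_var].dropna().to_numpy(dtype=float)

    sexes_present = [s for s in ("male", "female") if (pl.frame["Sex"] == s).any()]
    per_sex_ok = len(sexes_present) > 0 and all(
        len(usable(pl.ref_genotype, s)) >= min_controls for s in sexes_present
    )

    strata: list[RRStratum] = []
    skipped: dict[str, str] = {}

    def analyse_stratum(sex_label: str, sex_filter: str | None, thr: RRThresholds) -> None:
        ctrl_vals = usable(pl.ref_genotype, sex_filter)
        mut_vals = usable(pl.test_genotype, sex_filter)
        _, ctrl_counts = classify_values(ctrl_vals, thr)
        _, mut_counts = classify_values(mut_vals, thr)
        tails = rr_test(ctrl_counts, mut_counts, row_labels=pl.genotypes)
        note = None if thr.sex == sex_label else "combined-sex reference range used"
        strata.append(
            RRStratum(
                sex=sex_label, thresholds=thr,
                control_counts=ctrl_counts, mutant_counts=mut_counts,
                tails=tails, note=note,
            )
        )

    if per_sex_ok:
        for s in sexes_present:
            thr = compute_thresholds(
                usable(pl.ref_genotype, s), range_proportion, sex=s, min_controls=min_controls
            )
            analyse_stratum(s, s, thr)
    else:
        try:
            thr_combined = compute_thresholds(
                usable(pl.ref_genotype, None), range_proportion,
                sex="combined", min_controls=min_controls,
            )
        except RRInfeasibleError:
            raise
        for s in sexes_present:
            skipped[s] = (
                f"per-sex control floor ({min_controls}) unmet; "
                "combined-sex thresholds applied"
            )
            analyse_stratum(s, s, thr_combined)

    if len(sexes_present) > 1:
        thr_combined = compute_thresholds(
            usable(pl.ref_genotype, None), range_proportion,
            sex="combined", min_controls=min_controls,
        )
        analyse_stratum("combined", None, thr_combined)

    return PhenTestResult.from_rr(
        pl=pl, dep_var=dep_var, range_proportion=range_proportion,
        strata=strata, skipped=skipped,
    )
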