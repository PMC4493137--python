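"""Method-agnostic results: interactive summaries and fixed-schema vectors.

Every framework stores its outcome in a :class:`PhenTestResult`.  Two
output modes serve the two user groups: ``summary_output`` renders a
human-readable report for interactive analysis; ``vector_output``
produces a strictly defined, method-independent flat record (fields in
:data:`VECTOR_FIELDS`, inapplicable entries explicitly null) suitable
for loading into a database.  Both report identical numbers; only the
formatting differs.
"""

from __future__ import annotations

import csv
import json
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from .phenlist import PhenList

#: Version of the vector schema, stamped into every record.
VECTOR_SCHEMA_VERSION = 1

#: The fixed field set of the method-independent output vector.
VECTOR_FIELDS: tuple[str, ...] = (
    "method",
    "dep_var",
    "version",
    "schema_version",
    "n_ref_male",
    "n_ref_female",
    "n_test_male",
    "n_test_female",
    "n_used",
    "weight_included",
    "genotype_p",
    "sex_p",
    "interaction_p",
    "weight_p",
    "batch_significant",
    "batch_p",
    "variance_homogeneous",
    "variance_p",
    "effect_male",
    "effect_male_se",
    "effect_female",
    "effect_female_se",
    "effect_combined",
    "effect_combined_se",
    "classification_tag",
    "rr_range_proportion",
    "rr_male_low_threshold",
    "rr_male_high_threshold",
    "rr_female_low_threshold",
    "rr_female_high_threshold",
    "rr_combined_low_threshold",
    "rr_combined_high_threshold",
    "rr_male_low_p",
    "rr_male_low_effect",
    "rr_male_high_p",
    "rr_male_high_effect",
    "rr_female_low_p",
    "rr_female_low_effect",
    "rr_female_high_p",
    "rr_female_high_effect",
    "rr_combined_low_p",
    "rr_combined_low_effect",
    "rr_combined_high_p",
    "rr_combined_high_effect",
    "fe_all_p",
    "fe_all_effect",
    "fe_all_effect_category",
    "fe_male_p",
    "fe_male_effect",
    "fe_male_effect_category",
    "fe_female_p",
    "fe_female_effect",
    "fe_female_effect_category",
    "final_model",
    "cleaning_log",
)


@dataclass
class PhenTestResult:
    """Analysis outcome, identical in shape for every framework."""

    method: str
    dep_var: str
    test_genotype: str
    ref_genotype: str
    counts: dict[str, int]
    options: dict[str, Any] = field(default_factory=dict)
    genotype_p: float | None = None
    effects: Any = None              # mixed_model.SexEffects for MM/TF
    classification_tag: str | None = None
    trace: Any = None                # mixed_model.OptimisationTrace
    fitted: Any = None               # mixed_model.FittedModel
    rr_strata: list[Any] = field(default_factory=list)
    fe_analyses: dict[str, Any] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    reduction: Any = None            # time_fixed.ReductionReport
    cleaning_log: list[str] = field(default_factory=list)
    version: str = __version__

    # -- constructors ----------------------------------------------------
    @staticmethod
    def _counts(pl: PhenList, dep_var: str) -> dict[str, int]:
        df = pl.frame[pl.frame[dep_var].notna()]
        out = {}
        for role, genotype in (("ref", pl.ref_genotype), ("test", pl.test_genotype)):
            for sex in ("male", "female"):
                out[f"n_{role}_{sex}"] = int(
                    ((df["Genotype"] == genotype) & (df["Sex"] == sex)).sum()
                )
        return out

    @classmethod
    def from_model(cls, method, pl, dep_var, genotype_p, effects, classification_tag,
                   trace, fitted, include_weight, reduction=None) -> "PhenTestResult":
        res = cls(
            method=method, dep_var=dep_var,
            test_genotype=pl.test_genotype, ref_genotype=pl.ref_genotype,
            counts=cls._counts(pl, dep_var),
            options={"weight_included": include_weight},
            genotype_p=genotype_p, effects=effects,
            classification_tag=classification_tag,
            trace=trace, fitted=fitted, reduction=reduction,
            cleaning_log=list(pl.cleaning_log),
        )
        return res

    @classmethod
    def from_rr(cls, pl, dep_var, range_proportion, strata, skipped) -> "PhenTestResult":
        return cls(
            method="RR", dep_var=dep_var,
            test_genotype=pl.test_genotype, ref_genotype=pl.ref_genotype,
            counts=cls._counts(pl, dep_var),
            options={"range_proportion": range_proportion},
            rr_strata=strata, skipped=skipped,
            cleaning_log=list(pl.cleaning_log),
        )

    @classmethod
    def from_fe(cls, pl, dep_var, analyses, skipped) -> "PhenTestResult":
        return cls(
            method="FE", dep_var=dep_var,
            test_genotype=pl.test_genotype, ref_genotype=pl.ref_genotype,
            counts=cls._counts(pl, dep_var),
            fe_analyses=analyses, skipped=skipped,
            cleaning_log=list(pl.cleaning_log),
        )


# ---------------------------------------------------------------------------
# formatting helpers
# ---------------------------------------------------------------------------

def _fmt(x: Any, sig: int = 3) -> str:
    """3-significant-figure display; tiny p-values shown as '<1e-16'."""
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return "yes" if x else "no"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return "NA"
        if 0 < x < 1e-16:
            return "<1e-16"
        return f"{x:.{sig}g}"
    return str(x)


def _full(x: Any) -> Any:
    """Full-precision JSON-safe value for the vector output."""
    if x is None:
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        return float(x) if np.isfinite(x) else None
    return str(x)


# ---------------------------------------------------------------------------
# vector output
# ---------------------------------------------------------------------------

def _tail_entries(vec: dict, stratum) -> None:
    s = stratum.sex
    vec[f"rr_{s}_low_threshold"] = _full(stratum.thresholds.low_threshold)
    vec[f"rr_{s}_high_threshold"] = _full(stratum.thresholds.high_threshold)
    for tail in ("Low", "High"):
        key = tail.lower()
        res = stratum.tails.get(tail)
        if res is not None:
            vec[f"rr_{s}_{key}_p"] = _full(res.p_value)
            vec[f"rr_{s}_{key}_effect"] = _full(res.penetrance_change)


def _fe_entries(vec: dict, subset: str, analysis) -> None:
    vec[f"fe_{subset}_p"] = _full(analysis.p_value)
    defined = {k: v for k, v in analysis.effects.items() if v is not None}
    if defined:
        top = max(defined, key=lambda k: abs(defined[k]))
        vec[f"fe_{subset}_effect"] = _full(defined[top])
        vec[f"fe_{subset}_effect_category"] = top


def vector_output(r: PhenTestResult) -> "OrderedDict[str, Any]":
    """The strictly defined, method-independent output record.

    Every field of :data:`VECTOR_FIELDS` is present for every method;
    inapplicable entries are ``None``.  Values carry full precision.
    """
    vec: dict[str, Any] = {name: None for name in VECTOR_FIELDS}
    vec["method"] = r.method
    vec["dep_var"] = r.dep_var
    vec["version"] = r.version
    vec["schema_version"] = VECTOR_SCHEMA_VERSION
    vec.update({k: _full(v) for k, v in r.counts.items()})
    vec["weight_included"] = _full(r.options.get("weight_included"))
    vec["genotype_p"] = _full(r.genotype_p)
    vec["classification_tag"] = r.classification_tag
    vec["cleaning_log"] = " | ".join(r.cleaning_log) if r.cleaning_log else None

    if r.trace is not None:
        vec["interaction_p"] = _full(r.trace.interaction_p)
        vec["weight_p"] = _full(r.trace.weight_p)
        vec["batch_significant"] = _full(r.trace.batch_significant)
        vec["batch_p"] = _full(r.trace.batch_p)
        vec["variance_homogeneous"] = _full(r.trace.variance_homogeneous)
        vec["variance_p"] = _full(r.trace.variance_p)
    if r.effects is not None:
        for sex in ("male", "female", "combined"):
            pair = getattr(r.effects, sex)
            if pair is not None:
                vec[f"effect_{sex}"] = _full(pair[0])
                vec[f"effect_{sex}_se"] = _full(pair[1])
    if r.fitted is not None:
        vec["n_used"] = _full(r.fitted.n_used)
        spec = r.fitted.spec
        vec["final_model"] = (
            f"{spec.dep_var} ~ {' + '.join(spec.fixed_terms)}"
            + {"random": " + (1|Batch)", "fixed": " + Batch", "none": ""}[spec.batch_role]
            + f" [residual: {spec.residual_variance}]"
        )
    if r.method == "RR":
        vec["rr_range_proportion"] = _full(r.options.get("range_proportion"))
        for stratum in r.rr_strata:
            _tail_entries(vec, stratum)
    if r.method == "FE":
        for subset, analysis in r.fe_analyses.items():
            _fe_entries(vec, subset, analysis)
    return OrderedDict((name, vec[name]) for name in VECTOR_FIELDS)


def write_vector_json(r: PhenTestResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(vector_output(r), indent=2) + "\n")
    return path


def write_vector_csv(results: Sequence[PhenTestResult], path: str | Path) -> Path:
    """One CSV row per result, columns exactly :data:`VECTOR_FIELDS`."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(VECTOR_FIELDS))
        writer.writeheader()
        for r in results:
            row = {k: ("NA" if v is None else v) for k, v in vector_output(r).items()}
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# summary output
# ---------------------------------------------------------------------------

def summary_output(r: PhenTestResult) -> str:
    """Human-readable multi-section report of one analysis."""
    lines: list[str] = []
    add = lines.append
    add(f"phenokit v{r.version} — {r.method} analysis of {r.dep_var!r}")
    add(f"genotypes: {r.test_genotype} (test) vs {r.ref_genotype} (reference)")
    add("")
    add("Animals analysed (non-missing response):")
    add(f"  {r.ref_genotype}: {r.counts['n_ref_male']} male, {r.counts['n_ref_female']} female")
    add(f"  {r.test_genotype}: {r.counts['n_test_male']} male, {r.counts['n_test_female']} female")

    if r.cleaning_log:
        add("")
        add("Dataset cleaning:")
        for entry in r.cleaning_log:
            add(f"  - {entry}")

    if r.reduction is not None:
        add("")
        add("Concurrent-control reduction:")
        add(f"  {r.reduction.describe()}")

    if r.trace is not None:
        add("")
        add("Model optimisation:")
        if r.trace.batch_significant is not None:
            add(
                f"  batch effect: {'significant, kept' if r.trace.batch_significant else 'not significant, dropped'}"
                f" (p = {_fmt(r.trace.batch_p)})"
            )
        if r.trace.variance_homogeneous is not None:
            add(
                f"  residual variance: {'homogeneous' if r.trace.variance_homogeneous else 'heterogeneous across genotypes'}"
                f" (p = {_fmt(r.trace.variance_p)})"
            )
        if r.trace.interaction_p is not None:
            add(
                f"  genotype-by-sex interaction: {'kept' if r.trace.interaction_kept else 'dropped'}"
                f" (p = {_fmt(r.trace.interaction_p)})"
            )
        if r.trace.weight_p is not None:
            add(
                f"  weight covariate: {'kept' if r.trace.weight_kept else 'dropped'}"
                f" (p = {_fmt(r.trace.weight_p)})"
            )
        for note in r.trace.notes:
            add(f"  note: {note}")

    if r.genotype_p is not None:
        add("")
        add(f"Genotype test: p = {_fmt(r.genotype_p)}")
        if r.effects is not None:
            for sex in ("male", "female", "combined"):
                pair = getattr(r.effects, sex)
                if pair is not None:
                    add(f"  {sex} effect: {_fmt(pair[0])} ± {_fmt(pair[1])} (test − reference)")
        if r.classification_tag:
            add(f"  classification: {r.classification_tag}")

    if r.method == "RR":
        add("")
        add(f"Reference range (central {_fmt(100 * r.options['range_proportion'])}% of controls):")
        for stratum in r.rr_strata:
            add(f"  [{stratum.sex}] thresholds: low < {_fmt(stratum.thresholds.low_threshold)}, "
                f"high > {_fmt(stratum.thresholds.high_threshold)} "
                f"(from {stratum.thresholds.n_controls_used} controls)")
            add(f"    counts Low/Normal/High — {r.ref_genotype}: {stratum.control_counts}, "
                f"{r.test_genotype}: {stratum.mutant_counts}")
            for tail in ("Low", "High"):
                res = stratum.tails.get(tail)
                if res is None:
                    add(f"    {tail} tail: not tested")
                else:
                    pct = None if res.penetrance_change is None else 100 * res.penetrance_change
                    add(f"    {tail} tail: p = {_fmt(res.p_value)}, "
                        f"penetrance change = {_fmt(pct)}%")
            if stratum.note:
                add(f"    note: {stratum.note}")

    if r.method == "FE":
        add("")
        add("Fisher exact tests (batch ignored; combined view is a toolkit addition):")
        for subset in ("all", "male", "female"):
            analysis = r.fe_analyses.get(subset)
            if analysis is None:
                add(f"  [{subset}] not performed: {r.skipped.get(subset, 'no data')}")
                continue
            add(f"  [{subset}] p = {_fmt(analysis.p_value)} "
                f"(reference level {analysis.reference_level!r})")
            for level, eff in sorted(analysis.effects.items()):
                pct = None if eff is None else 100 * eff
                add(f"    {level}: proportion change = {_fmt(pct)}%")

    if r.skipped and r.method != "FE":
        add("")
        for key, why in sorted(r.skipped.items()):
            add(f"Skipped [{key}]: {why}")

    add("")
    return "\n".join(lines)
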