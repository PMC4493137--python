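"""Per-framework suitability checks and method recommendation.

Every framework has structural requirements (variable kind, batch
coverage, control pool size, concurrency).  ``check_method`` evaluates
them deterministically and reports each finding with an actionable
message; ``recommend_method`` returns the frameworks whose checks all
pass, in preference order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phenlist import PhenList
from .reference_range import MIN_CONTROLS
from .time_fixed import MAX_TREATED_BATCHES, TFInfeasibleError, tf_dataset, treated_batch_count

METHODS = ("MM", "TF", "RR", "FE")

#: Preference order among passing frameworks, by variable kind.
CONTINUOUS_ORDER = ("MM", "TF", "RR")
CATEGORICAL_ORDER = ("FE", "RR")


@dataclass
class Finding:
    check: str
    passed: bool
    message: str


@dataclass
class CheckReport:
    """Outcome of all mandatory checks for one framework."""

    method: str
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(f.passed for f in self.findings)

    def add(self, check: str, passed: bool, message: str) -> None:
        self.findings.append(Finding(check, passed, message))

    def failures(self) -> list[Finding]:
        return [f for f in self.findings if not f.passed]


def _base_checks(report: CheckReport, pl: PhenList, dep_var: str) -> None:
    if dep_var not in pl.variables:
        report.add("variable present", False, f"{dep_var!r} is not a declared variable")
        return
    report.add("variable present", True, f"{dep_var!r} declared")
    df = pl.frame
    for genotype in pl.genotypes:
        n = int(df[(df["Genotype"] == genotype) & df[dep_var].notna()].shape[0])
        report.add(
            f"data for {genotype}", n > 0,
            f"{n} non-missing {dep_var!r} values for genotype {genotype!r}"
            + ("" if n else " — no analysable data"),
        )
    n_sexes = df["Sex"].dropna().nunique()
    report.add("sex recorded", n_sexes >= 1, f"{n_sexes} sex(es) present")


def _continuous_variability(report: CheckReport, pl: PhenList, dep_var: str) -> None:
    if pl.variables.get(dep_var) != "continuous":
        report.add("continuous variable", False, f"{dep_var!r} is not continuous")
        return
    report.add("continuous variable", True, f"{dep_var!r} is continuous")
    df = pl.frame
    overall = df[dep_var].dropna().nunique()
    report.add(
        "variability", overall > 1,
        f"{overall} distinct values overall" + ("" if overall > 1 else " — constant variable"),
    )
    for genotype in pl.genotypes:
        k = df[df["Genotype"] == genotype][dep_var].dropna().nunique()
        report.add(
            f"variability within {genotype}", k > 1,
            f"{k} distinct values within {genotype!r}",
        )


def check_method(pl: PhenList, dep_var: str, method: str) -> CheckReport:
    """Deterministic suitability report for one framework.

    Failures are reported with guidance, never raised.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    report = CheckReport(method=method)
    _base_checks(report, pl, dep_var)
    if not report.passed:
        return report

    df = pl.frame
    if method in ("MM", "TF"):
        _continuous_variability(report, pl, dep_var)

    if method == "MM":
        if not pl.has_batch:
            report.add("batch column", False, "no Batch column: a batch model cannot be fitted")
        else:
            for genotype in pl.genotypes:
                sub = df[(df["Genotype"] == genotype) & df[dep_var].notna()]
                k = int(sub["Batch"].dropna().nunique())
                report.add(
                    f"batches for {genotype}", k >= 2,
                    f"genotype {genotype!r} spans {k} batch(es); the random-effect "
                    "model needs >= 2" if k < 2 else f"genotype {genotype!r} spans {k} batches",
                )

    elif method == "TF":
        if not pl.has_batch:
            report.add("batch column", False, "no Batch column: concurrency cannot be assessed")
        else:
            try:
                reduced, rep = tf_dataset(pl, dep_var)
            except TFInfeasibleError as exc:
                report.add("concurrent controls", False, str(exc))
            else:
                report.add("concurrent controls", True, rep.describe())
                k = treated_batch_count(reduced, dep_var)
                report.add(
                    "treated batch count", 2 <= k <= MAX_TREATED_BATCHES,
                    f"{k} treated batches after reduction (framework accepts 2–"
                    f"{MAX_TREATED_BATCHES})",
                )

    elif method == "RR":
        if pl.variables.get(dep_var) != "continuous":
            report.add("continuous variable", False, f"{dep_var!r} is not continuous")
        else:
            report.add("continuous variable", True, f"{dep_var!r} is continuous")
            n_ctrl = int(
                df[(df["Genotype"] == pl.ref_genotype) & df[dep_var].notna()].shape[0]
            )
            report.add(
                "control pool", n_ctrl >= MIN_CONTROLS,
                f"{n_ctrl} usable controls (floor {MIN_CONTROLS} for a stable "
                "reference range)",
            )

    elif method == "FE":
        if pl.variables.get(dep_var) != "categorical":
            report.add("categorical variable", False, f"{dep_var!r} is not categorical")
        else:
            report.add("categorical variable", True, f"{dep_var!r} is categorical")
            levels = df[dep_var].dropna().astype(str).nunique()
            report.add(
                "variability", levels >= 2,
                f"{levels} observed level(s)" + ("" if levels >= 2 else " — no variability"),
            )

    return report


def recommend_method(pl: PhenList, dep_var: str) -> list[str]:
    """Frameworks whose checks pass, in preference order.

    Continuous variables: MM, then TF, then RR.  Categorical: FE.
    An empty list means no framework suits this dataset/variable.
    """
    kind = pl.variables.get(dep_var)
    order = CONTINUOUS_ORDER if kind == "continuous" else CATEGORICAL_ORDER
    return [m for m in order if check_method(pl, dep_var, m).passed]
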