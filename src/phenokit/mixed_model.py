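"""Mixed-model framework for continuous phenotypes.

The model describes a measured variable as fixed effects of genotype,
sex, their interaction and optionally body weight, plus a random batch
(assay-day) intercept:

    y = Genotype + Sex + Genotype:Sex [+ Weight] + (1 | Batch) + e

Batch effects and residuals are normal; the residual variance may be
shared or genotype-specific.  The fitting engine profiles the fixed
effects out by generalised least squares and optimises the variance
parameters directly; per-batch covariance blocks are rank-one updates
of a diagonal, so Sherman–Morrison gives the inverse and determinant
in closed form.

An iterative top-down optimisation fixes the model structure before
the genotype test: (1) keep the random batch term only if a
boundary-corrected REML likelihood-ratio test retains it; (2) choose
homogeneous vs per-genotype residual variance by REML LRT; (3) drop a
non-significant Genotype:Sex interaction (ML LRT); (4) drop a
non-significant weight covariate (ML LRT).  Genotype is then tested by
an ML likelihood-ratio against the same model with all genotype terms
removed, per-sex effects are estimated from the final REML fit, and
the effect is classified for sexual dimorphism.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .phenlist import PhenList

logger = logging.getLogger("phenokit")

#: Significance level used at every decision point of the optimisation.
ALPHA = 0.05

#: Optimiser settings: relative tolerance and iteration cap.
OPT_TOL = 1e-8
OPT_MAXITER = 200

_TERMS = ("Genotype", "Sex", "Genotype:Sex", "Weight")


class FitError(RuntimeError):
    """Model fit failed (singular design or non-convergence)."""

    def __init__(self, message: str, spec: "ModelSpec | None" = None):
        super().__init__(message)
        self.spec = spec


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate model.

    ``fixed_terms`` is a subset of {Genotype, Sex, Genotype:Sex, Weight}
    obeying the hierarchy (an interaction requires both main effects);
    ``batch_role`` is "random" (batch intercept), "fixed" (batch dummy
    columns, used by the time-as-fixed-effect framework) or "none";
    ``residual_variance`` is "homogeneous" or "per_genotype";
    ``fit_objective`` is "REML" or "ML".
    """

    dep_var: str
    fixed_terms: tuple[str, ...] = ("Genotype", "Sex", "Genotype:Sex")
    batch_role: str = "random"
    residual_variance: str = "homogeneous"
    fit_objective: str = "REML"

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - set(_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        if "Genotype:Sex" in self.fixed_terms and not (
            "Genotype" in self.fixed_terms and "Sex" in self.fixed_terms
        ):
            raise ValueError("Genotype:Sex requires both Genotype and Sex (hierarchy)")
        if self.batch_role not in ("none", "random", "fixed"):
            raise ValueError(f"unknown batch_role {self.batch_role!r}")
        if self.residual_variance not in ("homogeneous", "per_genotype"):
            raise ValueError(f"unknown residual_variance {self.residual_variance!r}")
        if self.fit_objective not in ("ML", "REML"):
            raise ValueError(f"unknown fit_objective {self.fit_objective!r}")

    @property
    def include_weight(self) -> bool:
        return "Weight" in self.fixed_terms

    def without(self, *terms: str) -> "ModelSpec":
        keep = tuple(t for t in self.fixed_terms if t not in terms)
        return replace(self, fixed_terms=keep)


def start_spec(dep_var: str, include_weight: bool = False, batch_role: str = "random") -> ModelSpec:
    """The fullest plausible model the top-down optimisation starts from."""
    terms: tuple[str, ...] = ("Genotype", "Sex", "Genotype:Sex")
    if include_weight:
        terms = terms + ("Weight",)
    return ModelSpec(dep_var=dep_var, fixed_terms=terms, batch_role=batch_role)


@dataclass
class FittedModel:
    """A converged fit: coefficients, variance components, diagnostics."""

    spec: ModelSpec
    coefficients: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    batch_variance: float | None
    residual_variances: dict[str, float]
    loglik: float
    n_used: int
    fitted: np.ndarray
    residuals: np.ndarray
    genotype_per_row: np.ndarray = field(repr=False, default=None)
    dropped_rows: int = 0

    @property
    def objective(self) -> str:
        return self.spec.fit_objective


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _model_frame(pl: PhenList, spec: ModelSpec) -> pd.DataFrame:
    """Rows usable by this spec: non-missing response (+ weight, + batch)."""
    if spec.dep_var not in pl.variables:
        raise KeyError(f"unknown dependent variable {spec.dep_var!r}")
    if pl.variables[spec.dep_var] != "continuous":
        raise FitError(f"{spec.dep_var!r} is not a continuous variable", spec)
    df = pl.frame
    mask = df[spec.dep_var].notna()
    if spec.include_weight:
        if not pl.has_weight:
            raise FitError("weight covariate requested but no Weight column present", spec)
        mask &= df["Weight"].notna()
    if spec.batch_role != "none":
        if not pl.has_batch:
            raise FitError("batch term requested but no Batch column present", spec)
        mask &= df["Batch"].notna()
    return df[mask]


def _design(df: pd.DataFrame, pl: PhenList, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix.

    Baselines: reference genotype and female sex; batch dummies (fixed
    role) drop the first batch level.  Sex terms are only built when
    both sexes occur in the usable rows.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    geno = (df["Genotype"] == pl.test_genotype).to_numpy(dtype=float)
    sexes = sorted(df["Sex"].unique())
    two_sexes = len(sexes) > 1
    if "Genotype" in spec.fixed_terms:
        cols.append(geno)
        names.append("Genotype")
    if "Sex" in spec.fixed_terms and two_sexes:
        male = (df["Sex"] == "male").to_numpy(dtype=float)
        cols.append(male)
        names.append("Sex")
        if "Genotype:Sex" in spec.fixed_terms:
            cols.append(geno * male)
            names.append("Genotype:Sex")
    if "Weight" in spec.fixed_terms:
        cols.append(df["Weight"].to_numpy(dtype=float))
        names.append("Weight")
    if spec.batch_role == "fixed":
        levels = list(pd.unique(df["Batch"]))
        for lev in levels[1:]:
            cols.append((df["Batch"] == lev).to_numpy(dtype=float))
            names.append(f"Batch[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is singular (confounded terms)", spec)
    return X, names


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

class _LMMData:
    """Pre-grouped arrays for fast repeated likelihood evaluation."""

    def __init__(self, y, X, batch_codes, var_group):
        order = np.argsort(batch_codes, kind="stable") if batch_codes is not None else np.arange(len(y))
        self.y = y[order]
        self.X = X[order]
        self.var_group = var_group[order]
        self.order = order
        if batch_codes is not None:
            bc = batch_codes[order]
            _, starts = np.unique(bc, return_index=True)
            self.block_bounds = np.append(starts, len(y))
        else:
            self.block_bounds = None
        self.n, self.p = X.shape


def _gls_profile(data: _LMMData, batch_var: float, resid_vars: np.ndarray, objective: str):
    """Profiled log-likelihood at fixed variance parameters.

    Returns (loglik, beta, cov_beta).  Residual variance per row comes
    from ``resid_vars[var_group]``; the batch intercept contributes a
    rank-one term per block handled by Sherman–Morrison.
    """
    y, X = data.y, data.X
    n, p = data.n, data.p
    d = resid_vars[data.var_group]  # diagonal of D
    if np.any(d <= 0):
        return -np.inf, None, None
    dinv = 1.0 / d

    logdet = float(np.sum(np.log(d)))
    Xtd = X.T * dinv
    XtViX = Xtd @ X
    XtViy = Xtd @ y
    ytViy = float((y * dinv) @ y)
    if data.block_bounds is not None and batch_var > 0:
        # V_block = D + batch_var * 11'; Sherman–Morrison per block,
        # vectorised over blocks with reduceat on the batch-sorted rows
        starts = data.block_bounds[:-1]
        a = np.add.reduceat(dinv, starts)                    # 1' D^-1 1 per block
        U = np.add.reduceat(X * dinv[:, None], starts, axis=0)  # X' D^-1 1 per block
        v = np.add.reduceat(y * dinv, starts)                # y' D^-1 1 per block
        denom = 1.0 + batch_var * a
        logdet += float(np.sum(np.log(denom)))
        w = batch_var / denom
        XtViX -= (U.T * w) @ U
        XtViy -= U.T @ (w * v)
        ytViy -= float(np.sum(w * v * v))

    try:
        cov = np.linalg.inv(XtViX)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    beta = cov @ XtViy
    rss = ytViy - float(beta @ XtViy)  # r' V^-1 r
    if objective == "ML":
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + rss)
    else:
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, None, None
        ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdet_xvx + rss)
    return ll, beta, cov


def fit_model(pl: PhenList, spec: ModelSpec) -> FittedModel:
    """Fit one model specification by ML or REML.

    Rows missing the response (or weight / batch when those enter the
    model) are dropped and counted.  Non-convergence raises
    :class:`FitError` with the spec attached; it is never silently
    accepted.
    """
    df = _model_frame(pl, spec)
    dropped = len(pl.frame) - len(df)
    if dropped:
        logger.info("fit %s: dropped %d rows with missing required columns", spec.dep_var, dropped)
    if len(df) == 0:
        raise FitError("no usable rows for this model", spec)
    y = df[spec.dep_var].to_numpy(dtype=float)
    X, names = _design(df, pl, spec)
    n, p = X.shape
    if n <= p + 1:
        raise FitError(f"too few rows ({n}) for {p} fixed-effect columns", spec)

    geno_labels = df["Genotype"].to_numpy()
    if spec.residual_variance == "per_genotype":
        groups = list(pl.genotypes)
        var_group = np.array([groups.index(g) for g in geno_labels])
    else:
        groups = ["all"]
        var_group = np.zeros(n, dtype=int)

    batch_codes = None
    if spec.batch_role == "random":
        batch_codes = pd.factorize(df["Batch"])[0]

    data = _LMMData(y, X, batch_codes, var_group)

    # OLS anchor for starting values and scaling
    beta_ols, rss_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(rss_ols[0] / n) if np.size(rss_ols) else float(np.var(y - X @ beta_ols))
    s2 = max(s2, 1e-12 * max(1.0, float(np.var(y))), 1e-300)

    n_var = len(groups)
    use_random = spec.batch_role == "random"

    def unpack(theta: np.ndarray):
        if use_random:
            return s2 * theta[0], s2 * theta[1:]
        return 0.0, s2 * theta

    def nll(theta: np.ndarray) -> float:
        bv, rv = unpack(theta)
        ll, _, _ = _gls_profile(data, bv, rv, spec.fit_objective)
        return -ll if np.isfinite(ll) else 1e300

    if use_random or n_var > 1:
        x0 = np.concatenate(([0.25] if use_random else [], np.ones(n_var)))
        bounds = ([(0.0, 1e6)] if use_random else []) + [(1e-10, 1e6)] * n_var
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": OPT_MAXITER, "ftol": OPT_TOL, "gtol": 1e-10},
        )
        if not res.success:
            res2 = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": OPT_MAXITER * 10, "fatol": 1e-10, "xatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res = res2
            if not res.success and not np.isfinite(res.fun):
                raise FitError(f"variance optimisation did not converge: {res.message}", spec)
        theta = res.x
    else:
        # homogeneous residual, no random term: closed-form (OLS) solution
        dof = n if spec.fit_objective == "ML" else n - p
        theta = np.array([float(rss_ols[0]) / dof / s2]) if np.size(rss_ols) else np.array([1.0])

    batch_var, resid_vars = unpack(theta)
    ll, beta, cov = _gls_profile(data, batch_var, resid_vars, spec.fit_objective)
    if beta is None or not np.isfinite(ll):
        raise FitError("likelihood not finite at optimum", spec)

    coeffs = pd.Series(beta, index=names)
    bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=names)
    fitted_sorted = data.X @ beta
    resid_sorted = data.y - fitted_sorted
    fitted = np.empty(n)
    resid = np.empty(n)
    fitted[data.order] = fitted_sorted
    resid[data.order] = resid_sorted

    return FittedModel(
        spec=spec,
        coefficients=coeffs,
        bse=bse,
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        batch_variance=float(batch_var) if use_random else None,
        residual_variances={g: float(v) for g, v in zip(groups, resid_vars)},
        loglik=float(ll),
        n_used=n,
        fitted=fitted,
        residuals=resid,
        genotype_per_row=geno_labels,
        dropped_rows=dropped,
    )


def _assert_same_objective(a: ModelSpec, b: ModelSpec) -> None:
    if a.fit_objective != b.fit_objective:
        raise ValueError("likelihoods are only comparable within one objective (ML vs REML)")


def likelihood_ratio_test(pl: PhenList, full: ModelSpec, reduced: ModelSpec, df: int) -> tuple[float, float]:
    """Generic LRT between nested specs sharing one fit objective."""
    _assert_same_objective(full, reduced)
    f = fit_model(pl, full)
    r = fit_model(pl, reduced)
    lr = max(0.0, 2.0 * (f.loglik - r.loglik))
    return lr, float(stats.chi2.sf(lr, df))


# ---------------------------------------------------------------------------
# top-down optimisation steps
# ---------------------------------------------------------------------------

def test_batch_significance(pl: PhenList, spec: ModelSpec) -> tuple[bool, float]:
    """REML likelihood-ratio test for the random batch intercept.

    The null puts the batch variance on the boundary of its space, so
    the reference distribution is the equal mixture of a point mass at
    zero and chi-square(1): p = 0.5 * P(chi2_1 > LR).
    """
    if spec.batch_role != "random":
        raise ValueError("batch significance test requires batch_role='random'")
    full = replace(spec, fit_objective="REML")
    reduced = replace(full, batch_role="none")
    try:
        f = fit_model(pl, full)
        r = fit_model(pl, reduced)
    except FitError as exc:
        warnings.warn(f"batch test fit failed ({exc}); batch retained conservatively", stacklevel=2)
        return True, float("nan")
    lr = max(0.0, 2.0 * (f.loglik - r.loglik))
    p = 0.5 * float(stats.chi2.sf(lr, 1)) if lr > 0 else 1.0
    return p <= ALPHA, p


def test_variance_homogeneity(pl: PhenList, spec: ModelSpec) -> tuple[bool, float]:
    """REML LRT of shared vs per-genotype residual variance.

    Returns (homogeneous?, p): homogeneous when p > alpha.  A failed
    heterogeneous fit keeps the homogeneous structure with a warning.
    """
    hom = replace(spec, residual_variance="homogeneous", fit_objective="REML")
    het = replace(spec, residual_variance="per_genotype", fit_objective="REML")
    try:
        f_het = fit_model(pl, het)
        f_hom = fit_model(pl, hom)
    except FitError as exc:
        warnings.warn(f"variance homogeneity test fit failed ({exc}); homogeneous retained", stacklevel=2)
        return True, float("nan")
    lr = max(0.0, 2.0 * (f_het.loglik - f_hom.loglik))
    p = float(stats.chi2.sf(lr, 1))
    return p > ALPHA, p


@dataclass
class OptimisationTrace:
    """Decisions taken while reducing the start model."""

    batch_significant: bool | None = None
    batch_p: float | None = None
    variance_homogeneous: bool | None = None
    variance_p: float | None = None
    interaction_p: float | None = None
    interaction_kept: bool | None = None
    weight_p: float | None = None
    weight_kept: bool | None = None
    notes: list[str] = field(default_factory=list)


def optimise_model(pl: PhenList, start: ModelSpec) -> tuple[ModelSpec, OptimisationTrace]:
    """Top-down structure selection before the genotype test.

    Order: random-batch test, residual-variance structure, interaction,
    weight.  Sex stays whenever both sexes are present; Genotype always
    stays so the final test is defined.
    """
    trace = OptimisationTrace()
    spec = start

    if spec.batch_role == "random":
        significant, p = test_batch_significance(pl, spec)
        trace.batch_significant, trace.batch_p = significant, p
        if not significant:
            spec = replace(spec, batch_role="none")
            trace.notes.append("random batch term dropped (not significant); linear model fitted")
    elif spec.batch_role == "fixed":
        # fixed-effect batch (time-as-fixed-effect framework): ML LRT
        n_batches = pl.frame["Batch"].dropna().nunique()
        if n_batches < 2:
            spec = replace(spec, batch_role="none")
            trace.batch_significant = None
            trace.notes.append("single batch: fixed batch term unidentifiable, excluded")
        else:
            full = replace(spec, fit_objective="ML")
            reduced = replace(full, batch_role="none")
            lr, p = likelihood_ratio_test(pl, full, reduced, df=n_batches - 1)
            trace.batch_significant, trace.batch_p = p <= ALPHA, p
            if p > ALPHA:
                spec = replace(spec, batch_role="none")
                trace.notes.append("fixed batch term dropped (not significant)")

    homogeneous, p_var = test_variance_homogeneity(pl, spec)
    trace.variance_homogeneous, trace.variance_p = homogeneous, p_var
    spec = replace(spec, residual_variance="homogeneous" if homogeneous else "per_genotype")

    sexes = pl.frame["Sex"].dropna().unique()
    if len(sexes) < 2:
        drop = tuple(t for t in ("Genotype:Sex", "Sex") if t in spec.fixed_terms)
        if drop:
            spec = spec.without(*drop)
            trace.notes.append("single-sex data: sex terms excluded")
    elif "Genotype:Sex" in spec.fixed_terms:
        full = replace(spec, fit_objective="ML")
        reduced = full.without("Genotype:Sex")
        _, p_int = likelihood_ratio_test(pl, full, reduced, df=1)
        trace.interaction_p = p_int
        trace.interaction_kept = p_int <= ALPHA
        if p_int > ALPHA:
            spec = spec.without("Genotype:Sex")
            trace.notes.append("Genotype:Sex interaction dropped (not significant)")

    if "Weight" in spec.fixed_terms:
        full = replace(spec, fit_objective="ML")
        reduced = full.without("Weight")
        _, p_w = likelihood_ratio_test(pl, full, reduced, df=1)
        trace.weight_p = p_w
        trace.weight_kept = p_w <= ALPHA
        if p_w > ALPHA:
            spec = spec.without("Weight")
            trace.notes.append("weight covariate dropped (not significant)")

    return replace(spec, fit_objective="REML"), trace


def genotype_test(pl: PhenList, final_spec: ModelSpec) -> float:
    """ML likelihood-ratio test of all genotype terms in the final model."""
    geno_terms = tuple(t for t in final_spec.fixed_terms if t.startswith("Genotype"))
    if not geno_terms:
        raise ValueError("final model contains no genotype terms")
    full = replace(final_spec, fit_objective="ML")
    reduced = full.without(*geno_terms)
    _, p = likelihood_ratio_test(pl, full, reduced, df=len(geno_terms))
    return p


@dataclass
class SexEffects:
    """Per-sex genotype effects, test minus reference, response units."""

    male: tuple[float, float] | None = None     # (estimate, SE)
    female: tuple[float, float] | None = None
    combined: tuple[float, float] | None = None  # reported when no interaction


def estimate_effects(fitted: FittedModel) -> SexEffects:
    """Genotype effect per sex from treatment-coded coefficients.

    Female (baseline sex) effect is the Genotype coefficient; the male
    effect adds the interaction, with its SE from the coefficient
    covariance.  Without an interaction the single Genotype coefficient
    is the common (combined) effect.
    """
    c, cov = fitted.coefficients, fitted.cov_params
    if "Genotype" not in c.index:
        raise ValueError("fitted model has no genotype term")
    g, se_g = float(c["Genotype"]), float(np.sqrt(cov.loc["Genotype", "Genotype"]))
    if "Genotype:Sex" in c.index:
        i = float(c["Genotype:Sex"])
        var_m = (
            cov.loc["Genotype", "Genotype"]
            + cov.loc["Genotype:Sex", "Genotype:Sex"]
            + 2 * cov.loc["Genotype", "Genotype:Sex"]
        )
        return SexEffects(male=(g + i, float(np.sqrt(max(var_m, 0.0)))), female=(g, se_g))
    if "Sex" in c.index:
        return SexEffects(male=(g, se_g), female=(g, se_g), combined=(g, se_g))
    return SexEffects(combined=(g, se_g))


#: Closed set of genotype-effect classifications.
CLASSIFICATIONS = (
    "not significant",
    "both sexes equally",
    "different sizes — males greater",
    "different sizes — females greater",
    "male only",
    "female only",
    "different directions",
)


def classify_effect(genotype_p: float, effects: SexEffects, interaction_kept: bool | None) -> str:
    """Sexual-dimorphism classification of a tested genotype effect.

    No overall significance → "not significant"; interaction absent →
    "both sexes equally".  With an interaction, per-sex Wald tests at
    the decision alpha separate "male only"/"female only" (one sex
    shows an effect), "different directions" (opposite signs) and
    "different sizes" (same direction, magnitudes compared).
    """
    if not np.isfinite(genotype_p) or genotype_p > ALPHA:
        return "not significant"
    if not interaction_kept or effects.male is None or effects.female is None:
        return "both sexes equally"
    m, se_m = effects.male
    f, se_f = effects.female
    z = stats.norm.isf(ALPHA / 2)
    m_sig = se_m > 0 and abs(m) / se_m > z
    f_sig = se_f > 0 and abs(f) / se_f > z
    if m_sig and not f_sig:
        return "male only"
    if f_sig and not m_sig:
        return "female only"
    if np.sign(m) != np.sign(f) and m_sig and f_sig:
        return "different directions"
    return (
        "different sizes — males greater"
        if abs(m) >= abs(f)
        else "different sizes — females greater"
    )


def mm_analyse(pl: PhenList, dep_var: str, include_weight: bool = False):
    """Full mixed-model analysis: optimise, test, estimate, classify.

    Returns a :class:`phenokit.results_io.PhenTestResult`.
    """
    from .results_io import PhenTestResult

    start = start_spec(dep_var, include_weight=include_weight,
                       batch_role="random" if pl.has_batch else "none")
    final_spec, trace = optimise_model(pl, start)
    p_geno = genotype_test(pl, final_spec)
    fitted = fit_model(pl, replace(final_spec, fit_objective="REML"))
    effects = estimate_effects(fitted)
    tag = classify_effect(p_geno, effects, trace.interaction_kept)
    return PhenTestResult.from_model(
        method="MM", pl=pl, dep_var=dep_var, genotype_p=p_geno,
        effects=effects, classification_tag=tag, trace=trace,
        fitted=fitted, include_weight=include_weight,
    )
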