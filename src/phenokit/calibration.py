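"""Simulation studies validating the statistical frameworks.

Self-contained experiments a reviewer can rerun: exact-test agreement
with brute-force enumeration, type-I error of the mixed-model pipeline
under the global null, per-sex effect recovery, the degenerate-batch
equivalence with ordinary least squares, and structural checks of the
concurrent-control reduction and reference-range classification.  The
simulated designs echo a large multi-batch screen (a big control pool
spread over many assay days, a small mutant cohort concentrated in
two), scaled to run on a single CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import hypergeom

from .exact_tests import fisher_exact
from .mixed_model import (
    estimate_effects,
    fit_model,
    genotype_test,
    optimise_model,
    start_spec,
)
from .phenlist import build_phenlist
from .reference_range import classify_values, compute_thresholds, rr_analyse
from .synthetic import SyntheticSpec, generate_workflow, synthetic_phenlist
from .time_fixed import tf_dataset

#: Null-simulation design: a scaled version of a large multi-batch rat
#: screen (large male control pool over many batches, small female pool,
#: mutants concentrated in two batches per sex), modest batch variation.
NULL_DESIGN = dict(
    n_control={"male": 118, "female": 29},
    n_test={"male": 10, "female": 10},
    cell_batches={
        ("control", "male"): 43,
        ("control", "female"): 5,
        ("mutant", "male"): 2,
        ("mutant", "female"): 2,
    },
    batch_sd=2.0,
    residual_sd={"control": 8.5, "mutant": 8.5},
    genotype_effect={"male": 0.0, "female": 0.0},
)

#: Effect-recovery design: per-sex effects of -25 (male) and -15
#: (female) response units, batch SD 5, residual SD 8, n = 300.
RECOVERY_DESIGN = dict(
    n_control={"male": 75, "female": 75},
    n_test={"male": 75, "female": 75},
    n_batches=15,
    n_test_batches=15,
    design="concurrent_tf",
    n_control_only_batches=0,
    batch_sd=5.0,
    residual_sd={"control": 8.0, "mutant": 8.0},
    genotype_effect={"male": -25.0, "female": -15.0},
)


def fisher_vs_enumeration(max_margin: int = 12) -> dict:
    """Compare the 2×2 exact test against brute-force enumeration.

    Sweeps every 2×2 table whose four margins are all at most
    ``max_margin`` and returns the largest absolute p-value difference
    from an independent hypergeometric enumeration oracle.
    """
    worst = 0.0
    count = 0
    for a in range(max_margin + 1):
        for b in range(max_margin + 1 - a):
            for c in range(max_margin + 1):
                for d in range(max_margin + 1 - c):
                    if a + c > max_margin or b + d > max_margin:
                        continue
                    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                        continue
                    count += 1
                    p = fisher_exact(np.array([[a, b], [c, d]]))
                    r1, r2, c1 = a + b, c + d, a + c
                    n = r1 + r2
                    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
                    pmf = hypergeom.pmf(ks, n, r1, c1)
                    p_obs = hypergeom.pmf(a, n, r1, c1)
                    oracle = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
                    worst = max(worst, abs(p - oracle))
    return {"max_abs_diff": worst, "n_tables": count}


def mm_type1(n_rep: int = 2000, seed: int = 1) -> dict:
    """Type-I error of the mixed-model pipeline under the global null.

    Runs the full optimise → genotype-test pipeline on null data and,
    for contrast, the same genotype test on the interaction-free model
    (no dimorphism selection), whose rejection rate isolates the
    calibration of the test itself.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_rep)
    rej_pipeline = 0
    rej_unselected = 0
    for s in seeds:
        pl, _ = synthetic_phenlist(SyntheticSpec(seed=int(s), **NULL_DESIGN))
        final, trace = optimise_model(pl, start_spec("response"))
        rej_pipeline += genotype_test(pl, final) <= 0.05
        base = replace(
            final, fixed_terms=tuple(t for t in final.fixed_terms if t != "Genotype:Sex")
        )
        rej_unselected += genotype_test(pl, base) <= 0.05
    return {
        "rate": rej_pipeline / n_rep,
        "rate_unselected": rej_unselected / n_rep,
        "n_rep": n_rep,
    }


def mm_effect_recovery(n_rep: int = 500, seed: int = 2) -> dict:
    """Per-sex genotype-effect recovery across replicate screens.

    Fits the full interaction model on each replicate and reports the
    mean per-sex estimates, the truth, and the standard error of each
    mean, so calibration can be judged on the 3-SE scale.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_rep)
    males, females = [], []
    for s in seeds:
        pl, truth = synthetic_phenlist(SyntheticSpec(seed=int(s), **RECOVERY_DESIGN))
        eff = estimate_effects(fit_model(pl, start_spec("response")))
        males.append(eff.male[0])
        females.append(eff.female[0])
    males, females = np.asarray(males), np.asarray(females)
    return {
        "male_mean": float(males.mean()),
        "female_mean": float(females.mean()),
        "male_truth": RECOVERY_DESIGN["genotype_effect"]["male"],
        "female_truth": RECOVERY_DESIGN["genotype_effect"]["female"],
        "male_se": float(males.std(ddof=1) / np.sqrt(n_rep)),
        "female_se": float(females.std(ddof=1) / np.sqrt(n_rep)),
        "n_rep": n_rep,
    }


def mm_zero_batch_vs_ols(seed: int = 3, n_rep: int = 10) -> dict:
    """Degenerate-batch equivalence: boundary batch variance → OLS.

    On data generated without batch variation, the REML estimate of
    the batch variance lands on the zero boundary in a substantial
    fraction of replicates (on others it is a small positive value —
    a legitimate finite-sample estimate, at which generalised least
    squares deliberately differs from OLS).  For every boundary fit
    the mixed-model coefficients must equal an independent
    least-squares solution; returns the worst relative difference over
    those fits and the number of boundary fits found.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_rep)
    worst = 0.0
    boundary_fits = 0
    for s in seeds:
        pl, _ = synthetic_phenlist(SyntheticSpec(seed=int(s), batch_sd=0.0))
        fm = fit_model(pl, start_spec("response"))
        if fm.batch_variance > 1e-10 * fm.residual_variances["all"]:
            continue
        boundary_fits += 1
        df = pl.frame
        geno = (df["Genotype"] == "mutant").to_numpy(float)
        male = (df["Sex"] == "male").to_numpy(float)
        X = np.column_stack([np.ones(len(df)), geno, male, geno * male])
        beta, *_ = np.linalg.lstsq(X, df["response"].to_numpy(float), rcond=None)
        rel = np.abs(fm.coefficients.to_numpy() - beta) / np.maximum(np.abs(beta), 1e-12)
        worst = max(worst, float(rel.max()))
    return {"max_rel_diff": worst, "boundary_fits": boundary_fits, "n_rep": n_rep}


def tf_reduction_check(seed: int = 4) -> dict:
    """Concurrent reduction removes exactly the non-concurrent rows.

    Two constructed designs: control-only batches alongside concurrent
    ones, and an orphan treated batch.  Returns the number of
    misplaced rows (kept when they should go, or dropped when they
    should stay); zero means exact agreement with the design truth.
    """
    misplaced = 0

    raw, _ = generate_workflow(
        "concurrent_tf", seed=seed, n_test_batches=4, n_control_only_batches=6
    )
    pl = build_phenlist(raw, "mutant", "control")
    treated_batches = set(pl.frame.loc[pl.frame["Genotype"] == "mutant", "Batch"])
    reduced, report = tf_dataset(pl, "response")
    expected_keep = pl.frame["Batch"].isin(list(treated_batches)).sum()
    misplaced += abs(len(reduced) - int(expected_keep))
    misplaced += int(set(reduced.frame["Batch"]) != treated_batches)

    rows = pl.frame.copy()
    orphan = rows.iloc[:6].copy()
    orphan["Genotype"] = "mutant"
    orphan["Batch"] = "orphan"
    import pandas as pd

    pl2 = build_phenlist(
        type(raw)(frame=pd.concat([rows, orphan], ignore_index=True)), "mutant", "control"
    )
    reduced2, report2 = tf_dataset(pl2, "response")
    misplaced += int("orphan" in set(reduced2.frame["Batch"]))
    misplaced += abs(report2.removed_treated_only - len(orphan))

    return {"misplaced_rows": misplaced}


def rr_structure_check(n_rep: int = 50, seed: int = 5) -> dict:
    """Classification conservation and location equivariance.

    Over replicate control/mutant draws: counts must sum to n, and
    shifting every measurement by a constant must leave counts and
    tail p-values untouched.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    max_p_shift = 0.0
    for _ in range(n_rep):
        controls = rng.normal(50, 8, 120)
        mutants = rng.normal(45, 8, 8)
        thr = compute_thresholds(controls, 0.95)
        _, counts = classify_values(np.concatenate([controls, mutants]), thr)
        violations += int(sum(counts) != 128)

        shift = float(rng.uniform(-1e3, 1e3))
        thr_s = compute_thresholds(controls + shift, 0.95)
        _, c1 = classify_values(controls, thr)
        _, c1s = classify_values(controls + shift, thr_s)
        _, c2 = classify_values(mutants, thr)
        _, c2s = classify_values(mutants + shift, thr_s)
        violations += int(c1 != c1s) + int(c2 != c2s)
        from .reference_range import rr_test

        t = rr_test(c1, c2)
        ts = rr_test(c1s, c2s)
        for tail in t:
            max_p_shift = max(max_p_shift, abs(t[tail].p_value - ts[tail].p_value))
    return {"violations": violations, "max_p_shift": max_p_shift, "n_rep": n_rep}
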