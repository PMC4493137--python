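"""Synthetic phenotyping datasets with the structure the frameworks assume.

The generator emulates a high-throughput screen: animals of a control
and a mutant line measured across assay-day batches, with normally
distributed batch effects, a sex effect, per-sex genotype effects, a
body-weight covariate correlated with the response (males heavier),
optional genotype-specific residual variance, and rare-event
categorical phenotypes.  Three named designs mirror the workflows the
frameworks target:

* ``multi_batch_mm`` — controls spread over many batches, mutants
  concentrated in a few (no concurrency required): the mixed-model
  structure.
* ``concurrent_tf`` — a handful of mutant batches, each with
  concurrent controls, plus control-only batches: the
  time-as-fixed-effect structure.
* ``one_batch_rr`` — a single batch with a large control pool and few
  mutants: the reference-range structure.

Every draw is governed by one integer seed and the realised parameters
are returned in a truth record so that recovery tests never re-derive
truth from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .phenlist import PhenList, RawTable, build_phenlist

DESIGNS = ("multi_batch_mm", "concurrent_tf", "one_batch_rr")

#: Default genotype labels used in generated tables.
CONTROL_LABEL = "control"
MUTANT_LABEL = "mutant"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one simulated phenotyping workflow.

    Counts are per sex; effects are in response units (test minus
    control).  ``residual_sd`` maps genotype → residual SD, enabling
    heterogeneous-variance scenarios.  The defaults describe a typical
    screen: a large multi-batch control pool, a small mutant cohort,
    batch variation comparable to the residual scale, heavier males,
    and a weight-correlated response.
    """

    design: str = "multi_batch_mm"
    n_control: Mapping[str, int] = field(default_factory=lambda: {"male": 70, "female": 70})
    n_test: Mapping[str, int] = field(default_factory=lambda: {"male": 7, "female": 7})
    n_batches: int = 20
    n_test_batches: int = 2
    n_control_only_batches: int = 6
    batch_sd: float = 5.0
    residual_sd: Mapping[str, float] = field(
        default_factory=lambda: {CONTROL_LABEL: 8.0, MUTANT_LABEL: 8.0}
    )
    baseline: float = 50.0
    sex_effect: float = 10.0
    genotype_effect: Mapping[str, float] = field(
        default_factory=lambda: {"male": -25.0, "female": -15.0}
    )
    weight_mean: Mapping[str, float] = field(
        default_factory=lambda: {"male": 300.0, "female": 200.0}
    )
    weight_sd: Mapping[str, float] = field(default_factory=lambda: {"male": 30.0, "female": 20.0})
    weight_slope: float = 0.0
    categorical_rates: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {CONTROL_LABEL: (0.98, 0.02), MUTANT_LABEL: (0.60, 0.40)}
    )
    categorical_levels: tuple[str, ...] = ("normal", "abnormal")
    #: optional per-(genotype × sex) batch counts, e.g. to mimic a printed
    #: dataset-characteristics table exactly; falls back to the design rules.
    cell_batches: Mapping[tuple[str, str], int] | None = None
    seed: int = 20150706

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; choose from {DESIGNS}")
        if self.batch_sd < 0 or any(v < 0 for v in self.residual_sd.values()):
            raise ValueError("standard deviations must be non-negative")
        for rates in self.categorical_rates.values():
            if abs(sum(rates) - 1.0) > 1e-9 or any(r < 0 for r in rates):
                raise ValueError("categorical rates must be a probability vector")
            if len(rates) != len(self.categorical_levels):
                raise ValueError("rates and category levels differ in length")
        if self.n_batches < 1 and self.batch_sd > 0:
            raise ValueError("a positive batch SD needs at least one batch")


def _batch_assignment(spec: SyntheticSpec, rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
    """Batch label per animal for each genotype × sex cell, round-robin."""
    assignment: dict[tuple[str, str], np.ndarray] = {}

    def round_robin(labels: list[str], n: int) -> np.ndarray:
        return np.array([labels[i % len(labels)] for i in range(n)], dtype=object)

    all_batches = [f"b{i:03d}" for i in range(spec.n_batches)]
    if spec.design == "one_batch_rr":
        labels_ctrl = labels_test = ["b000"]
    elif spec.design == "concurrent_tf":
        shared = all_batches[: spec.n_test_batches]
        control_only = [
            f"c{i:03d}" for i in range(spec.n_control_only_batches)
        ]
        labels_test = shared
        labels_ctrl = shared + control_only
    else:  # multi_batch_mm: mutants in their own few batches, no concurrency
        labels_ctrl = all_batches
        labels_test = [f"t{i:03d}" for i in range(spec.n_test_batches)]

    for sex in ("male", "female"):
        for genotype, counts, labels in (
            (CONTROL_LABEL, spec.n_control, labels_ctrl),
            (MUTANT_LABEL, spec.n_test, labels_test),
        ):
            n = int(counts.get(sex, 0))
            cell_labels = labels
            if spec.cell_batches is not None:
                k = spec.cell_batches.get((genotype, sex))
                if k is not None:
                    # per-cell batch pool, disjoint across cells, exact count
                    cell_labels = [f"{genotype[:1]}{sex[:1]}{i:03d}" for i in range(k)]
            assignment[(genotype, sex)] = round_robin(cell_labels, n)
    return assignment


@dataclass
class TruthRecord:
    """Realised generative parameters, for recovery tests."""

    spec: SyntheticSpec
    batch_effects: dict[str, float]
    genotype_effect: dict[str, float]
    sex_effect: float
    weight_slope: float
    residual_sd: dict[str, float]
    n_rows: int


def generate_continuous(spec: SyntheticSpec, response_name: str = "response") -> tuple[RawTable, TruthRecord]:
    """Simulate a continuous phenotype under the additive batch model.

    response = baseline + sex effect (males) + per-sex genotype effect
    + weight slope × (weight − sex mean) + batch draw + residual, with
    the residual SD set by genotype.
    """
    rng = np.random.default_rng(spec.seed)
    assignment = _batch_assignment(spec, rng)
    all_labels = sorted({b for arr in assignment.values() for b in arr})
    batch_effects = {
        b: float(rng.normal(0.0, spec.batch_sd)) if spec.batch_sd > 0 else 0.0
        for b in all_labels
    }

    rows = []
    for (genotype, sex), batches in assignment.items():
        n = len(batches)
        if n == 0:
            continue
        weight = rng.normal(spec.weight_mean[sex], spec.weight_sd[sex], size=n)
        resid = rng.normal(0.0, spec.residual_sd[genotype], size=n)
        geno_shift = spec.genotype_effect[sex] if genotype == MUTANT_LABEL else 0.0
        sex_shift = spec.sex_effect if sex == "male" else 0.0
        y = (
            spec.baseline
            + sex_shift
            + geno_shift
            + spec.weight_slope * (weight - spec.weight_mean[sex])
            + np.array([batch_effects[b] for b in batches])
            + resid
        )
        for i in range(n):
            rows.append(
                {
                    "Genotype": genotype,
                    "Sex": sex,
                    "Batch": batches[i],
                    "Weight": round(float(weight[i]), 4),
                    response_name: round(float(y[i]), 6),
                }
            )
    frame = pd.DataFrame(rows)
    truth = TruthRecord(
        spec=spec,
        batch_effects=batch_effects,
        genotype_effect=dict(spec.genotype_effect),
        sex_effect=spec.sex_effect,
        weight_slope=spec.weight_slope,
        residual_sd=dict(spec.residual_sd),
        n_rows=len(frame),
    )
    return RawTable(frame=frame, source=f"synthetic:{spec.design}"), truth


def generate_categorical(spec: SyntheticSpec, response_name: str = "category") -> tuple[RawTable, TruthRecord]:
    """Simulate a categorical phenotype from per-genotype rate vectors."""
    rng = np.random.default_rng(spec.seed)
    assignment = _batch_assignment(spec, rng)
    rows = []
    for (genotype, sex), batches in assignment.items():
        n = len(batches)
        if n == 0:
            continue
        rates = np.asarray(spec.categorical_rates[genotype], dtype=float)
        draws = rng.choice(len(rates), size=n, p=rates)
        weight = rng.normal(spec.weight_mean[sex], spec.weight_sd[sex], size=n)
        for i in range(n):
            rows.append(
                {
                    "Genotype": genotype,
                    "Sex": sex,
                    "Batch": batches[i],
                    "Weight": round(float(weight[i]), 4),
                    response_name: spec.categorical_levels[int(draws[i])],
                }
            )
    frame = pd.DataFrame(rows)
    truth = TruthRecord(
        spec=spec, batch_effects={}, genotype_effect={}, sex_effect=0.0,
        weight_slope=0.0, residual_sd={}, n_rows=len(frame),
    )
    return RawTable(frame=frame, source=f"synthetic:{spec.design}:categorical"), truth


def generate_workflow(design: str, seed: int = 20150706, **overrides) -> tuple[RawTable, TruthRecord]:
    """A dataset with one of the three named workflow structures."""
    base = SyntheticSpec(design=design, seed=seed)
    if design == "one_batch_rr":
        base = replace(
            base,
            n_batches=1, n_test_batches=1,
            n_control={"male": 100, "female": 100},
            n_test={"male": 7, "female": 7},
            batch_sd=0.0,
        )
    elif design == "concurrent_tf":
        base = replace(base, n_test_batches=4, n_batches=4)
    if overrides:
        base = replace(base, **overrides)
    return generate_continuous(base)


def synthetic_phenlist(
    spec: SyntheticSpec | None = None,
    categorical: bool = False,
    response_name: str | None = None,
) -> tuple[PhenList, TruthRecord]:
    """Generate and immediately validate a dataset (test convenience)."""
    spec = spec or SyntheticSpec()
    name = response_name or ("category" if categorical else "response")
    gen = generate_categorical if categorical else generate_continuous
    raw, truth = gen(spec, response_name=name)
    pl = build_phenlist(raw, test_genotype=MUTANT_LABEL, ref_genotype=CONTROL_LABEL)
    return pl, truth
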