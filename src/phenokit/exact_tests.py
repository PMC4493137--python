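"""Contingency tables and exact tests shared by the FE and RR frameworks.

2×2 tables use the classical two-sided Fisher exact test
(probability-ordering rule).  Larger r×c tables use the Freeman–Halton
generalisation: full enumeration of all tables with the observed
margins when that is affordable, otherwise a seeded Monte Carlo
estimate drawn from the fixed-margin (multivariate hypergeometric)
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats

from .phenlist import PhenList

#: Relative slack when comparing table probabilities: any table whose
#: point probability is within this factor of the observed one counts
#: as "at least as extreme" (guards against floating-point ties).
_PROB_TIE_TOL = 1e-7

#: Switch from full Freeman–Halton enumeration to Monte Carlo when the
#: number of tables compatible with the margins exceeds this bound.
ENUMERATION_BOUND = 200_000

#: Monte Carlo defaults (draw count and seed) for large r×c tables.
MONTE_CARLO_DRAWS = 200_000
MONTE_CARLO_SEED = 20150706


@dataclass
class ContingencyTable:
    """Genotype × category count table.

    Rows are genotype groups with the reference genotype first; columns
    are the observed phenotype categories.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape[0] < 2 or self.counts.shape[1] < 2:
            raise ValueError("a contingency table needs >= 2 rows and >= 2 columns")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))


class SubsetEmptyError(ValueError):
    """Requested sex subset contains no analysable animals."""


def build_count_table(pl: PhenList, dep_var: str, subset: str = "all") -> ContingencyTable:
    """Tabulate animals by genotype × category for one sex subset.

    ``subset`` is "all", "male" or "female".  Animals with a missing
    value of ``dep_var`` are excluded.  Column order: observed category
    levels sorted lexically; row order: (reference, test) genotype.
    """
    if subset not in ("all", "male", "female"):
        raise ValueError(f"unknown subset {subset!r}")
    df = pl.frame if subset == "all" else pl.subset(sex=subset)
    df = df[df[dep_var].notna()]
    if len(df) == 0:
        raise SubsetEmptyError(f"no animals with non-missing {dep_var!r} in subset {subset!r}")
    levels = sorted(df[dep_var].astype(str).unique())
    counts = np.zeros((2, len(levels)), dtype=np.int64)
    for i, genotype in enumerate(pl.genotypes):
        sub = df[df["Genotype"] == genotype][dep_var].astype(str)
        vc = sub.value_counts()
        for j, level in enumerate(levels):
            counts[i, j] = int(vc.get(level, 0))
    return ContingencyTable(row_labels=pl.genotypes, col_labels=tuple(levels), counts=counts)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def _log_table_probability(counts: np.ndarray) -> float:
    """log P(table | margins) under the fixed-margin hypergeometric model."""
    n = counts.sum()
    lp = -lgamma(n + 1)
    lp += sum(lgamma(r + 1) for r in counts.sum(axis=1))
    lp += sum(lgamma(c + 1) for c in counts.sum(axis=0))
    lp -= sum(lgamma(v + 1) for v in counts.ravel())
    return lp


def _count_tables(row_margins: np.ndarray, col_margins: np.ndarray) -> int:
    """Exact count of tables sharing the given margins (memoised DP)."""
    rows = tuple(int(r) for r in row_margins)
    cache: dict[tuple[int, tuple[int, ...]], int] = {}

    def rec(i: int, remaining: tuple[int, ...]) -> int:
        if i == len(rows) - 1:
            return 1  # last row is forced: remaining sums to rows[-1]
        key = (i, remaining)
        if key in cache:
            return cache[key]

        def alloc(j: int, left: int, rem: tuple[int, ...]) -> int:
            if j == len(rem) - 1:
                if left <= rem[j]:
                    return rec(i + 1, rem[:j] + (rem[j] - left,))
                return 0
            return sum(
                alloc(j + 1, left - v, rem[:j] + (rem[j] - v,) + rem[j + 1:])
                for v in range(min(left, rem[j]) + 1)
            )

        out = alloc(0, rows[i], remaining)
        cache[key] = out
        return out

    return rec(0, tuple(int(c) for c in col_margins))


def _freeman_halton_enumerate(counts: np.ndarray) -> float:
    """Exact r×c p by full enumeration of the fixed-margin table space."""
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    lp_obs = _log_table_probability(counts)
    threshold = lp_obs + np.log1p(_PROB_TIE_TOL)

    rows = list(row_margins)
    ncol = len(col_margins)
    p_total = 0.0

    def rec(i: int, remaining: np.ndarray, partial: list[list[int]]) -> None:
        nonlocal p_total
        if i == len(rows) - 1:
            table = np.array(partial + [list(remaining)], dtype=np.int64)
            if _log_table_probability(table) <= threshold:
                p_total += np.exp(_log_table_probability(table))
            return

        def alloc(j: int, left: int, rem: np.ndarray, row: list[int]) -> None:
            if j == ncol - 1:
                if left <= rem[j]:
                    new_rem = rem.copy()
                    new_rem[j] -= left
                    rec(i + 1, new_rem, partial + [row + [left]])
                return
            hi = min(left, rem[j])
            for v in range(hi + 1):
                new_rem = rem.copy()
                new_rem[j] -= v
                alloc(j + 1, left - v, new_rem, row + [v])

        alloc(0, rows[i], remaining, [])

    rec(0, col_margins.astype(np.int64).copy(), [])
    return min(1.0, p_total)


def _freeman_halton_monte_carlo(counts: np.ndarray, draws: int, seed: int) -> float:
    """Seeded Monte Carlo estimate of the Freeman–Halton p-value.

    A table is as extreme as the observed one iff its point probability
    is no larger; with margins fixed that reduces to comparing the sum
    of log-factorials of the cells.
    """
    from scipy.special import gammaln

    rng = np.random.default_rng(seed)
    s_obs = float(gammaln(counts + 1.0).sum())
    sampler = stats.random_table(counts.sum(axis=1), counts.sum(axis=0))
    hits = 0
    block = 20_000
    done = 0
    while done < draws:
        k = min(block, draws - done)
        tables = sampler.rvs(size=k, random_state=rng).reshape(k, *counts.shape)
        s = gammaln(tables + 1.0).sum(axis=(1, 2))
        hits += int((s >= s_obs - np.log1p(_PROB_TIE_TOL)).sum())
        done += k
    return (hits + 1) / (draws + 1)


def fisher_exact(
    table: ContingencyTable | np.ndarray,
    monte_carlo_draws: int = MONTE_CARLO_DRAWS,
    seed: int = MONTE_CARLO_SEED,
) -> float:
    """Two-sided exact test of genotype × category independence.

    2×2 tables: classical Fisher test, summing the probabilities of all
    tables (margins fixed) whose point probability does not exceed the
    observed one.  r×c tables: Freeman–Halton by full enumeration, or a
    seeded Monte Carlo estimate when more than ``ENUMERATION_BOUND``
    tables share the margins.  A zero margin carries no information and
    yields p = 1 with a warning.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        warnings.warn("table has an empty row or column; p = 1 (no information)", stacklevel=2)
        return 1.0
    if counts.shape == (2, 2):
        return float(stats.fisher_exact(counts, alternative="two-sided")[1])
    n_tables = _count_tables(counts.sum(axis=1), counts.sum(axis=0))
    if n_tables <= ENUMERATION_BOUND:
        return float(_freeman_halton_enumerate(counts))
    return float(_freeman_halton_monte_carlo(counts, monte_carlo_draws, seed))


def proportion_effect(table: ContingencyTable | np.ndarray, focal_col: int = 0) -> float | None:
    """Signed difference in focal-column proportion, test minus reference.

    The penetrance-change effect size: with rows (reference, test), the
    value is ``test_count/test_total - ref_count/ref_total``, in [-1, 1].
    Returns None when a genotype has no animals (undefined).
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if counts.shape[0] != 2:
        raise ValueError("proportion effect is defined for two-genotype tables")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        return None
    ref_prop = counts[0, focal_col] / totals[0]
    test_prop = counts[1, focal_col] / totals[1]
    return float(test_prop - ref_prop)
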