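"""Exploratory and diagnostic figures for the genotype effect.

All functions write exactly one figure file at the requested path and
return that path.  Controls are drawn in black and the test genotype
in red by default (overridable), matching the convention of drawing
attention to the mutant line.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .mixed_model import FittedModel
from .phenlist import PhenList

#: Default genotype colours: (reference, test).
DEFAULT_COLOURS = ("black", "red")

#: Span of the locally weighted smooth in the weight scatter.
LOWESS_SPAN = 2.0 / 3.0


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def boxplot_sex_genotype(
    pl: PhenList, dep_var: str, label: str, path: str | Path,
    colours: tuple[str, str] = DEFAULT_COLOURS,
) -> Path:
    """Box per genotype × sex of a continuous variable."""
    fig, ax = plt.subplots(figsize=(7, 5))
    data, ticks, box_colours = [], [], []
    for sex in ("female", "male"):
        for genotype, colour in zip(pl.genotypes, colours):
            values = pl.subset(sex=sex, genotype=genotype)[dep_var].dropna().to_numpy(dtype=float)
            if len(values) == 0:
                continue
            data.append(values)
            ticks.append(f"{sex}\n{genotype}")
            box_colours.append(colour)
    if not data:
        ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction", ha="center")
    else:
        bp = ax.boxplot(data, tick_labels=ticks, patch_artist=True)
        for patch, colour in zip(bp["boxes"], box_colours):
            patch.set_facecolor("none")
            patch.set_edgecolor(colour)
        for median in bp["medians"]:
            median.set_color("grey")
    ax.set_ylabel(label)
    ax.set_title(f"{label} by genotype and sex")
    return _save(fig, path)


def scatterplot_genotype_sex_batch(
    pl: PhenList, dep_var: str, path: str | Path,
    colours: tuple[str, str] = DEFAULT_COLOURS,
) -> Path:
    """Per-sex panels of values grouped by batch, coloured by genotype.

    Batch identifiers are opaque assay-day labels; their order along
    the axis is arbitrary, not temporal.
    """
    sexes = [s for s in ("female", "male") if (pl.frame["Sex"] == s).any()]
    fig, axes = plt.subplots(1, max(1, len(sexes)), figsize=(6 * max(1, len(sexes)), 5), squeeze=False)
    batches = list(pl.frame["Batch"].dropna().unique())
    positions = {b: i for i, b in enumerate(batches)}
    for ax, sex in zip(axes[0], sexes or ["all"]):
        for genotype, colour in zip(pl.genotypes, colours):
            sub = pl.subset(sex=None if sex == "all" else sex, genotype=genotype)
            sub = sub[sub[dep_var].notna() & sub["Batch"].notna()]
            x = [positions[b] for b in sub["Batch"]]
            ax.scatter(x, sub[dep_var].astype(float), s=14, color=colour, label=genotype, alpha=0.7)
        ax.set_title(f"{sex} (batches unordered)")
        ax.set_xlabel("batch")
        ax.set_ylabel(dep_var)
        ax.legend(fontsize=8)
    return _save(fig, path)


def qqplot_genotype(fitted: FittedModel, path: str | Path,
                    colours: tuple[str, str] = DEFAULT_COLOURS) -> Path:
    """Normal quantile–quantile panel of residuals per genotype group."""
    groups = list(dict.fromkeys(fitted.genotype_per_row))
    fig, axes = plt.subplots(1, len(groups), figsize=(5.5 * len(groups), 5), squeeze=False)
    for ax, genotype, colour in zip(axes[0], groups, colours):
        resid = fitted.residuals[fitted.genotype_per_row == genotype]
        stats.probplot(resid, dist="norm", plot=ax)
        ax.get_lines()[0].set_color(colour)
        ax.get_lines()[0].set_markersize(4)
        ax.set_title(f"residuals: {genotype} (n={len(resid)})")
    return _save(fig, path)


def scatterplot_genotype_weight(
    pl: PhenList, dep_var: str, path: str | Path,
    colours: tuple[str, str] = DEFAULT_COLOURS,
) -> Path:
    """Response vs body weight per genotype with linear and lowess fits.

    The smooth is omitted for a genotype with fewer than 5 points; the
    straight line needs at least 2.  Rows with missing weight are
    excluded and the exclusion count annotated.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fig, ax = plt.subplots(figsize=(7, 5))
    n_excluded = 0
    for genotype, colour in zip(pl.genotypes, colours):
        sub = pl.subset(genotype=genotype)
        n_excluded += int((sub["Weight"].isna() | sub[dep_var].isna()).sum())
        sub = sub[sub["Weight"].notna() & sub[dep_var].notna()]
        w = sub["Weight"].to_numpy(dtype=float)
        y = sub[dep_var].to_numpy(dtype=float)
        ax.scatter(w, y, s=14, color=colour, alpha=0.6, label=genotype)
        if len(w) >= 2:
            slope, intercept = np.polyfit(w, y, 1)
            grid = np.linspace(w.min(), w.max(), 50)
            ax.plot(grid, intercept + slope * grid, color=colour, linewidth=1.5)
        if len(w) >= 5:
            smooth = lowess(y, w, frac=LOWESS_SPAN, return_sorted=True)
            ax.plot(smooth[:, 0], smooth[:, 1], color=colour, linewidth=1.2, linestyle="--")
    ax.set_xlabel("body weight")
    ax.set_ylabel(dep_var)
    if n_excluded:
        ax.annotate(f"{n_excluded} rows without weight excluded", (0.02, 0.02),
                    xycoords="axes fraction", fontsize=8)
    ax.legend(fontsize=8)
    return _save(fig, path)
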