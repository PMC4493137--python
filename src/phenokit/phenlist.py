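"""Dataset ingestion, terminology unification and cleaning.

High-throughput phenotyping centres describe the same experimental
metadata with different vocabularies ("Sex" vs "Gender", "Batch" vs
"Assay.Date") and mix control and mutant lines in one export.  This
module turns a raw delimited table into a validated two-genotype
dataset (:class:`PhenList`) that every downstream statistical
framework consumes, recording every cleaning action it takes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phenokit")

#: Missing-value spellings accepted in input files.
NA_VALUES = ["", "NA", "NaN"]

#: Canonical metadata column names every downstream module relies on.
CANONICAL_COLUMNS = ("Genotype", "Sex", "Batch", "Weight")

#: Fraction of non-missing values that must parse as numbers for a
#: column to be inferred as continuous.
CONTINUOUS_INFERENCE_FRACTION = 0.95


class FormatError(ValueError):
    """Input file malformed (no header, unparseable rows)."""


class AmbiguityError(ValueError):
    """Two source columns map to the same canonical column."""


class ConfigurationError(ValueError):
    """Requested genotypes or variables inconsistent with the data."""


@dataclass
class RawTable:
    """A parsed delimited table prior to validation.

    Thin wrapper around a :class:`pandas.DataFrame` keeping track of
    provenance and of renames performed by terminology unification.
    """

    frame: pd.DataFrame
    source: str = "memory"
    pending_log: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class TerminologyMap:
    """Observed → canonical name dictionary.

    ``synonyms`` maps observed column names to canonical ones
    (matched case-insensitively); ``value_synonyms`` normalises the
    Sex labels.  Values not covered by ``value_synonyms`` are treated
    as missing, because every analysis stratifies by a binary sex.
    """

    synonyms: dict[str, str] = field(default_factory=dict)
    value_synonyms: dict[str, str] = field(default_factory=dict)

    def merged_with_defaults(self) -> "TerminologyMap":
        syn = dict(DEFAULT_TERMINOLOGY.synonyms)
        syn.update(self.synonyms)
        val = dict(DEFAULT_TERMINOLOGY.value_synonyms)
        val.update(self.value_synonyms)
        return TerminologyMap(syn, val)


DEFAULT_TERMINOLOGY = TerminologyMap(
    synonyms={
        "gender": "Sex",
        "sex": "Sex",
        "genotype": "Genotype",
        "assay.date": "Batch",
        "assay_date": "Batch",
        "assay date": "Batch",
        "date": "Batch",
        "batch": "Batch",
        "body.weight": "Weight",
        "bodyweight": "Weight",
        "body_weight": "Weight",
        "body weight": "Weight",
        "weight": "Weight",
    },
    value_synonyms={
        "m": "male",
        "male": "male",
        "f": "female",
        "female": "female",
    },
)


@dataclass(frozen=True)
class PhenRecord:
    """One animal: metadata plus its measured values.

    Batch identifiers are opaque; they are compared only for equality
    (same assay day), never ordered — dates arrive in arbitrary formats.
    """

    genotype: str
    sex: str
    batch: str | None
    weight: float | None
    values: Mapping[str, object]


@dataclass
class PhenList:
    """Validated two-genotype dataset: the contract all frameworks use.

    ``frame`` holds canonical columns (Genotype, Sex, optional Batch
    and Weight) plus one column per measured variable.  ``variables``
    maps variable name → kind ("continuous" | "categorical").
    ``cleaning_log`` is the ordered human-readable record of every
    removal or rename performed while building the object.
    """

    frame: pd.DataFrame
    test_genotype: str
    ref_genotype: str
    variables: dict[str, str]
    cleaning_log: list[str] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------
    @property
    def genotypes(self) -> tuple[str, str]:
        return (self.ref_genotype, self.test_genotype)

    @property
    def has_batch(self) -> bool:
        return "Batch" in self.frame.columns

    @property
    def has_weight(self) -> bool:
        return "Weight" in self.frame.columns

    def records(self) -> Iterator[PhenRecord]:
        var_names = list(self.variables)
        for _, row in self.frame.iterrows():
            yield PhenRecord(
                genotype=row["Genotype"],
                sex=row["Sex"],
                batch=None if not self.has_batch or pd.isna(row.get("Batch")) else str(row["Batch"]),
                weight=None if not self.has_weight or pd.isna(row.get("Weight")) else float(row["Weight"]),
                values={v: row[v] for v in var_names},
            )

    def subset(self, sex: str | None = None, genotype: str | None = None) -> pd.DataFrame:
        df = self.frame
        if sex is not None:
            df = df[df["Sex"] == sex]
        if genotype is not None:
            df = df[df["Genotype"] == genotype]
        return df

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_table(path: str | Path, dialect: str = "comma") -> RawTable:
    """Read a delimited text file with a header row into a :class:`RawTable`.

    Missing cells (empty, "NA", "NaN") become NaN; everything else is
    kept as-is.  ``dialect`` is "comma" (CSV) or "tab" (TSV).
    """
    sep = {"comma": ",", "tab": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'")
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=sep, header=0, dtype=str,
            na_values=NA_VALUES, keep_default_na=False,
            skipinitialspace=True,
        )
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} has no header row") from exc
    if any(str(c).startswith("Unnamed:") for c in frame.columns) and len(frame.columns) > 1:
        # pandas names blank header fields "Unnamed: k"
        raise FormatError(f"{path} has blank fields in its header row")
    return RawTable(frame=frame, source=str(path))


def table_from_frame(frame: pd.DataFrame, source: str = "memory") -> RawTable:
    """Wrap an in-memory DataFrame as a :class:`RawTable`."""
    return RawTable(frame=frame.copy(), source=source)


# ---------------------------------------------------------------------------
# terminology unification
# ---------------------------------------------------------------------------

def unify_terminology(raw: RawTable, terminology: TerminologyMap | None = None) -> RawTable:
    """Rename synonym columns to canonical names and normalise Sex labels.

    Measured values are never altered — only column names and the Sex
    labels.  Raises :class:`AmbiguityError` if two source columns map
    to one canonical name.
    """
    tmap = (terminology or TerminologyMap()).merged_with_defaults()
    frame = raw.frame.copy()
    log: list[str] = list(raw.pending_log)

    renames: dict[str, str] = {}
    targets: dict[str, str] = {}
    for col in frame.columns:
        canonical = tmap.synonyms.get(str(col).strip().lower())
        if canonical is None:
            continue
        if canonical in targets and targets[canonical] != col:
            raise AmbiguityError(
                f"columns {targets[canonical]!r} and {col!r} both map to {canonical!r}"
            )
        targets[canonical] = col
        if col != canonical:
            renames[col] = canonical
    if renames:
        frame = frame.rename(columns=renames)
        for src, dst in renames.items():
            log.append(f"renamed column {src!r} to {dst!r}")

    if "Sex" in frame.columns:
        observed = frame["Sex"].astype("string").str.strip().str.lower()
        normalised = observed.map(tmap.value_synonyms)
        changed = (normalised != observed) & normalised.notna()
        if int(changed.sum()):
            log.append(f"normalised {int(changed.sum())} Sex labels to male/female")
        unknown = normalised.isna() & frame["Sex"].notna()
        if int(unknown.sum()):
            log.append(
                f"marked {int(unknown.sum())} unrecognised Sex labels as missing"
            )
        frame["Sex"] = normalised.astype(object).where(normalised.notna(), np.nan)

    return RawTable(frame=frame, source=raw.source, pending_log=log)


# ---------------------------------------------------------------------------
# building the PhenList
# ---------------------------------------------------------------------------

def _infer_kind(series: pd.Series) -> str:
    values = series.dropna()
    if len(values) == 0:
        return "categorical"
    numeric = pd.to_numeric(values, errors="coerce")
    frac = numeric.notna().mean()
    return "continuous" if frac >= CONTINUOUS_INFERENCE_FRACTION else "categorical"


def build_phenlist(
    raw: RawTable,
    test_genotype: str,
    ref_genotype: str,
    clean: bool = True,
    terminology: TerminologyMap | None = None,
    variable_kinds: Mapping[str, str] | None = None,
) -> PhenList:
    """Validate and clean a raw table into a two-genotype :class:`PhenList`.

    Keeps only rows of the two named genotypes with a known sex, infers
    each measured variable's kind (explicit ``variable_kinds`` overrides
    win), and records every removal in the cleaning log.  Missing weight
    does not drop a row here; weight-requiring model fits drop such rows
    at fit time.
    """
    unified = unify_terminology(raw, terminology) if clean else raw
    frame = unified.frame.copy()
    log = list(unified.pending_log)
    n_in = len(frame)

    for required in ("Genotype", "Sex"):
        if required not in frame.columns:
            raise ConfigurationError(f"required column {required!r} absent after unification")

    frame["Genotype"] = frame["Genotype"].astype("string").str.strip()
    observed_genotypes = set(frame["Genotype"].dropna().unique())
    if test_genotype not in observed_genotypes:
        raise ConfigurationError(
            f"test genotype {test_genotype!r} absent from data "
            f"(observed: {sorted(observed_genotypes)})"
        )
    if ref_genotype not in observed_genotypes:
        raise ConfigurationError(
            f"reference genotype {ref_genotype!r} absent from data "
            f"(observed: {sorted(observed_genotypes)})"
        )
    if test_genotype == ref_genotype:
        raise ConfigurationError("test and reference genotype must differ")

    missing_mask = frame["Genotype"].isna() | frame["Sex"].isna()
    if clean and int(missing_mask.sum()):
        log.append(f"dropped {int(missing_mask.sum())} rows with missing genotype or sex")
        frame = frame[~missing_mask]
    other_mask = ~frame["Genotype"].isin([test_genotype, ref_genotype])
    if clean and int(other_mask.sum()):
        log.append(
            f"dropped {int(other_mask.sum())} rows of genotypes other than "
            f"{test_genotype!r}/{ref_genotype!r}"
        )
        frame = frame[~other_mask]

    metadata = {"Genotype", "Sex", "Batch", "Weight"}
    variables: dict[str, str] = {}
    for col in frame.columns:
        if col in metadata:
            continue
        kind = None
        if variable_kinds and col in variable_kinds:
            kind = variable_kinds[col]
            if kind not in ("continuous", "categorical"):
                raise ConfigurationError(f"unknown variable kind {kind!r} for {col!r}")
        else:
            kind = _infer_kind(frame[col])
        variables[col] = kind
        if kind == "continuous":
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    if "Weight" in frame.columns:
        frame["Weight"] = pd.to_numeric(frame["Weight"], errors="coerce")
    if "Batch" in frame.columns:
        frame["Batch"] = frame["Batch"].astype("string")

    frame = frame.reset_index(drop=True)
    frame["Genotype"] = frame["Genotype"].astype(object)
    frame["Sex"] = frame["Sex"].astype(object)
    if len(set(frame["Genotype"].unique())) < 2:
        raise ConfigurationError("fewer than 2 genotypes remain after cleaning")

    for entry in log:
        logger.info("cleaning: %s", entry)
    logger.info("built PhenList: %d of %d rows retained", len(frame), n_in)
    return PhenList(
        frame=frame,
        test_genotype=test_genotype,
        ref_genotype=ref_genotype,
        variables=variables,
        cleaning_log=log,
    )


def dataset_summary(pl: PhenList, dep_var: str) -> pd.DataFrame:
    """Per genotype × sex counts of animals, batches and missing values.

    Mirrors the descriptive table reported for multi-batch screens:
    the batch count is the number of distinct batch identifiers among
    that cell's animals.
    """
    if dep_var not in pl.variables:
        raise KeyError(f"unknown dependent variable {dep_var!r}")
    rows = []
    for genotype in pl.genotypes:
        for sex in ("male", "female"):
            cell = pl.subset(sex=sex, genotype=genotype)
            if len(cell) == 0:
                continue
            n_batches = cell["Batch"].dropna().nunique() if pl.has_batch else 0
            rows.append(
                {
                    "Genotype": genotype,
                    "Sex": sex,
                    "n_animals": len(cell),
                    "n_batches": int(n_batches),
                    "n_missing": int(cell[dep_var].isna().sum()),
                }
            )
    return pd.DataFrame(rows).set_index(["Genotype", "Sex"])
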