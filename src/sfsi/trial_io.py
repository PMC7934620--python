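"""Plot-level trial data model, CSV reader/validator, and packaged reference tables.

The data model targets a two-treatment (low/high soil fertility) split-plot
field trial: each record is one plant observation inside a genotype subplot,
identified by genotype, year, treatment and replicate, carrying one or more
trait values in g plant^-1.

Two reference tables are packaged with the library: per-genotype mean tuber
yield and shoot dry weight under low (LF) and high (HF) fertility for a
published 21-entry white Guinea yam (*Dioscorea rotundata*) trial grown at
Ibadan, Nigeria (20 breeding lines plus the landrace check "Amula", listed as
"Local variety"). They drive the reproduction pipeline and serve as realistic
calibration input for the synthetic trial generator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, SchemaError

__all__ = [
    "ColumnSchema",
    "ValidationReport",
    "TrialDataset",
    "GenotypeMeansTable",
    "read_trial_csv",
    "write_trial_csv",
    "genotype_treatment_means",
    "load_reference_table",
    "load_reference_means",
    "REFERENCE_TRAITS",
    "REFERENCE_CHECK_ID",
]

#: Canonical internal column names, in output order.
CANONICAL_COLUMNS = ("genotype", "year", "treatment", "rep")

#: Traits available as packaged reference tables.
REFERENCE_TRAITS = ("tuber_yield", "shoot_dry_weight")

#: Check (landrace) entry name used in the reference tables.
REFERENCE_CHECK_ID = "Local variety"

#: Observations behind each reference genotype x treatment mean
#: (3 plants x 2 replicates x 2 years).
REFERENCE_N = 12


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from canonical design columns to the CSV's column names.

    Trait columns are passed separately because their names are the trait
    names themselves.
    """

    genotype: str = "genotype"
    year: str = "year"
    treatment: str = "treatment"
    replicate: str = "rep"

    def as_dict(self) -> dict[str, str]:
        return {
            "genotype": self.genotype,
            "year": self.year,
            "treatment": self.treatment,
            "rep": self.replicate,
        }


@dataclass
class ValidationReport:
    """Machine-readable list of warnings/exclusions raised while reading data."""

    warnings: list[dict] = field(default_factory=list)

    def add(self, kind: str, message: str, **detail) -> None:
        self.warnings.append({"kind": kind, "message": message, **detail})

    def __len__(self) -> int:
        return len(self.warnings)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"warnings": self.warnings}, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class TrialDataset:
    """Validated long-format plot-level trial data.

    Attributes
    ----------
    data
        One row per subplot/plant observation with canonical columns
        ``genotype, year, treatment, rep`` plus one float column per trait
        (NaN marks a missing value).
    traits
        Trait column names present in ``data``.
    treatment_labels
        ``(low, high)`` treatment level names; orientation is declared, never
        inferred from the data.
    check_id
        Name of the check/landrace entry, or None to disable check-relative
        operations.
    validation
        Warnings accumulated while building the dataset.
    """

    data: pd.DataFrame
    traits: tuple[str, ...]
    treatment_labels: tuple[str, str] = ("LF", "HF")
    check_id: str | None = None
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        self.traits = tuple(self.traits)
        self.treatment_labels = tuple(self.treatment_labels)  # type: ignore[assignment]
        if len(self.treatment_labels) != 2:
            raise DesignError("exactly two treatment levels must be declared")
        missing = [c for c in CANONICAL_COLUMNS + self.traits if c not in self.data.columns]
        if missing:
            raise SchemaError(f"dataset missing columns: {missing}")
        levels = set(self.data["treatment"].unique())
        extra = levels - set(self.treatment_labels)
        if extra:
            raise DesignError(
                f"treatment column has undeclared levels {sorted(extra)}; "
                f"declared: {self.treatment_labels}"
            )
        if (self.data["rep"] < 1).any():
            raise DesignError("replicate numbers must be >= 1")
        for t in self.traits:
            vals = self.data[t].to_numpy(dtype=float)
            bad = np.isfinite(vals) & (vals < 0)
            if bad.any():
                raise DesignError(f"trait {t!r} has {int(bad.sum())} negative values")
        if self.check_id is not None and self.check_id not in set(self.data["genotype"]):
            raise ConfigurationError(
                f"check entry {self.check_id!r} not among genotypes"
            )

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique())

    @property
    def low_label(self) -> str:
        return self.treatment_labels[0]

    @property
    def high_label(self) -> str:
        return self.treatment_labels[1]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GenotypeMeansTable:
    """Per-genotype mean trait values under the low and high treatment.

    ``data`` columns: ``genotype, x_lf, x_hf, n_lf, n_hf``. ``excluded``
    lists genotypes dropped for lacking observations in a treatment.
    """

    trait: str
    data: pd.DataFrame
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        need = {"genotype", "x_lf", "x_hf", "n_lf", "n_hf"}
        if not need.issubset(self.data.columns):
            raise SchemaError(f"means table needs columns {sorted(need)}")
        if ((self.data["n_lf"] < 1) | (self.data["n_hf"] < 1)).any():
            raise DesignError("every retained genotype needs n >= 1 per treatment")

    def __len__(self) -> int:
        return len(self.data)

    def row(self, genotype: str) -> pd.Series:
        sub = self.data[self.data["genotype"] == genotype]
        if sub.empty:
            raise KeyError(genotype)
        return sub.iloc[0]


def read_trial_csv(
    path: str | Path,
    traits: Iterable[str],
    schema: ColumnSchema | Mapping[str, str] | None = None,
    treatment_labels: tuple[str, str] = ("LF", "HF"),
    check_id: str | None = None,
) -> TrialDataset:
    """Read and validate a long-format plot-level trial CSV.

    Unparseable, negative or non-finite trait values become missing (NaN) and
    are listed in the returned dataset's validation report rather than being
    dropped silently.

    Raises
    ------
    SchemaError
        A mapped column is absent from the file.
    DesignError
        The treatment column does not have exactly the two declared levels.
    """
    path = Path(path)
    if schema is None:
        schema = ColumnSchema()
    elif isinstance(schema, Mapping):
        schema = ColumnSchema(
            genotype=schema.get("genotype", "genotype"),
            year=schema.get("year", "year"),
            treatment=schema.get("treatment", "treatment"),
            replicate=schema.get("rep", schema.get("replicate", "rep")),
        )
    raw = pd.read_csv(path, dtype=str)
    traits = list(traits)
    mapping = schema.as_dict()
    missing = [src for src in list(mapping.values()) + traits if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mapped columns {missing}")
    raw = raw.rename(columns={v: k for k, v in mapping.items()})
    levels = sorted(raw["treatment"].dropna().unique())
    if len(levels) != 2:
        raise DesignError(
            f"{path.name}: expected exactly 2 treatment levels, found {levels}"
        )
    report = ValidationReport()
    df = raw[list(CANONICAL_COLUMNS) + traits].copy()
    for col in ("year", "rep"):
        df[col] = pd.to_numeric(df[col], errors="raise", downcast=None).astype(int)
    for t in traits:
        parsed = pd.to_numeric(df[t], errors="coerce")
        bad = parsed.isna() & df[t].notna()
        invalid = parsed.notna() & (~np.isfinite(parsed) | (parsed < 0))
        for idx in df.index[bad | invalid]:
            report.add(
                "invalid_value",
                f"row {int(idx)}: trait {t!r} value {df.loc[idx, t]!r} recorded as missing",
                row=int(idx),
                trait=t,
            )
        parsed[invalid] = np.nan
        df[t] = parsed.astype(float)
    return TrialDataset(
        data=df.reset_index(drop=True),
        traits=tuple(traits),
        treatment_labels=treatment_labels,
        check_id=check_id,
        validation=report,
    )


def write_trial_csv(ds: TrialDataset, path: str | Path) -> Path:
    """Write a TrialDataset back to the canonical long-format CSV."""
    path = Path(path)
    cols = list(CANONICAL_COLUMNS) + list(ds.traits)
    ds.data[cols].to_csv(path, index=False)
    return path


def genotype_treatment_means(ds: TrialDataset, trait: str) -> GenotypeMeansTable:
    """Unweighted per-genotype mean trait value under each treatment.

    Means pool all non-missing observations across years, replicates and
    plants; with the balanced split-plot design this coincides with the mean
    of year means. Genotypes with zero observations under either treatment are
    excluded from the table and recorded in ``excluded`` (and in the dataset's
    validation report), never imputed.
    """
    if trait not in ds.traits:
        raise SchemaError(f"trait {trait!r} not declared in dataset ({ds.traits})")
    low, high = ds.treatment_labels
    g = ds.data.groupby(["genotype", "treatment"])[trait].agg(["mean", "count"])
    rows, excluded = [], []
    for geno in ds.genotypes:
        try:
            lo = g.loc[(geno, low)]
            hi = g.loc[(geno, high)]
        except KeyError:
            lo = hi = None
        if lo is None or lo["count"] < 1 or hi["count"] < 1:
            excluded.append(geno)
            ds.validation.add(
                "excluded_genotype",
                f"genotype {geno!r} has no usable {trait!r} observations in one treatment",
                genotype=geno,
                trait=trait,
            )
            continue
        rows.append(
            {
                "genotype": geno,
                "x_lf": float(lo["mean"]),
                "x_hf": float(hi["mean"]),
                "n_lf": int(lo["count"]),
                "n_hf": int(hi["count"]),
            }
        )
    return GenotypeMeansTable(
        trait=trait,
        data=pd.DataFrame(rows, columns=["genotype", "x_lf", "x_hf", "n_lf", "n_hf"]),
        excluded=tuple(excluded),
    )


def _data_path(name: str):
    return resources.files("sfsi.data").joinpath(name)


def load_reference_table(trait: str) -> pd.DataFrame:
    """Load a packaged reference table including its published PR/p/SFSI columns.

    Columns: ``genotype, x_lf, x_hf, pr_printed, p_value_printed,
    sfsi_printed`` in the source table's (SFSI-ascending) row order. The file
    checksum is verified on load.
    """
    if trait not in REFERENCE_TRAITS:
        raise KeyError(f"unknown reference trait {trait!r}; available: {REFERENCE_TRAITS}")
    name = f"{trait}.csv"
    blob = _data_path(name).read_bytes()
    sums = json.loads(_data_path("checksums.json").read_text())
    digest = hashlib.sha256(blob).hexdigest()
    if digest != sums[name]:
        raise IOError(f"reference table {name} is corrupted (checksum mismatch)")
    from io import BytesIO

    return pd.read_csv(BytesIO(blob))


def load_reference_means(trait: str) -> GenotypeMeansTable:
    """Packaged per-genotype LF/HF means for one reference trait (n = 12 each)."""
    df = load_reference_table(trait)
    data = df[["genotype", "x_lf", "x_hf"]].copy()
    data["n_lf"] = REFERENCE_N
    data["n_hf"] = REFERENCE_N
    return GenotypeMeansTable(trait=trait, data=data)
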