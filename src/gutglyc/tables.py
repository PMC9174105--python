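"""Data model and delimited-text I/O for the two core tables.

Two in-memory containers back the whole pipeline:

* :class:`GenusAbundanceTable` - participants x genera relative abundances
  (fractions). Count tables are accepted and converted to fractions row-wise
  at read time, since 16S genus tables circulate in both forms.
* the cohort table - a plain :class:`pandas.DataFrame` with one row per
  participant and a documented column contract (:data:`COHORT_COLUMNS`).
  Suffix ``_0`` marks the baseline survey, ``_1`` the follow-up survey.
  Missingness is explicit (NaN); imputation is a separate pipeline step.

Files are TSV or CSV (chosen by extension), decimal point only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Row-sum tolerance for relative-abundance validation.
ROW_SUM_TOL = 1e-6

#: Demographic / anthropometric / lifestyle covariates used for adjustment.
DEMO_COVARIATES = [
    "age", "sex", "income", "marital", "education", "residence",
    "urbanisation_index", "bmi", "energy", "alcohol", "smoking",
    "physical_activity",
]

#: Categorical covariates among :data:`DEMO_COVARIATES`.
CATEGORICAL_COVARIATES = ["sex", "marital", "education", "residence",
                          "alcohol", "smoking"]

#: The 12 food groups recorded as intake in kg/day.
FOOD_GROUPS = [
    "rice", "wheat", "fruit", "vegetable", "nuts", "pork", "poultry",
    "milk", "egg", "fish", "vegetable_oil", "animal_oil",
]

#: Required columns of the cohort table.
COHORT_COLUMNS = (
    ["participant_id", "province", "region"]
    + DEMO_COVARIATES
    + FOOD_GROUPS
    + ["fibre",
       "fasting_glucose_0", "fasting_insulin_0", "hba1c_0",
       "fasting_glucose_1", "fasting_insulin_1", "hba1c_1",
       "diabetes_medication_1", "followup_years"]
)

_NUMERIC_COHORT_COLUMNS = (
    ["age", "income", "urbanisation_index", "bmi", "energy",
     "physical_activity"]
    + FOOD_GROUPS
    + ["fibre",
       "fasting_glucose_0", "fasting_insulin_0", "hba1c_0",
       "fasting_glucose_1", "fasting_insulin_1", "hba1c_1",
       "followup_years"]
)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class GenusAbundanceTable:
    """Participants x genera relative abundances.

    ``data`` is indexed by participant id with one column per genus.
    Invariants (checked by :meth:`validate`): values >= 0, unique ids and
    genus names, row sums <= 1 + 1e-6.
    """

    data: pd.DataFrame

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def genus_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_genera(self) -> int:
        return self.data.shape[1]

    def validate(self) -> "GenusAbundanceTable":
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate participant id: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate genus name: {dup!r}")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValueError(
                f"missing abundance at participant {df.index[r]!r}, "
                f"genus {df.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative abundance at participant {df.index[r]!r}, "
                f"genus {df.columns[c]!r}: {vals[r, c]}"
            )
        sums = vals.sum(axis=1)
        if (sums > 1.0 + ROW_SUM_TOL).any():
            r = int(np.argmax(sums))
            raise ValueError(
                f"row sum {sums[r]:.6g} > 1 for participant {df.index[r]!r}"
            )
        return self

    def renormalized(self) -> "GenusAbundanceTable":
        """Return a copy with each row closed to sum exactly 1."""
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = sums.index[sums <= 0][0]
            raise ValueError(f"all-zero abundance row for participant {bad!r}")
        return GenusAbundanceTable(self.data.div(sums, axis=0))

    def prevalence(self) -> pd.Series:
        """Fraction of participants in which each genus is detected (> 0)."""
        return (self.data > 0).mean(axis=0)


def read_abundance_table(path: str | Path, renormalize: bool = False) -> GenusAbundanceTable:
    """Read a genus abundance table from delimited text.

    First column is the participant id; remaining columns are genus
    abundances. Integer count tables are detected (row sums far above 1)
    and converted to fractions row-wise. Negative or non-numeric cells are
    hard errors naming the offending row/column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric abundance at participant {row!r}, genus {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    table = GenusAbundanceTable(df.astype(float))
    # Count-table heuristic: any row summing clearly above 1 means counts.
    vals = table.data.to_numpy()
    if (vals < 0).any():
        table.validate()  # raises with cell location
    if vals.sum(axis=1).max() > 1.0 + ROW_SUM_TOL:
        table = table.renormalized()
    if renormalize:
        table = table.renormalized()
    return table.validate()


def write_abundance_table(table: GenusAbundanceTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path), index_label="participant_id",
                      float_format="%.17g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read the participant metadata table, preserving missingness.

    Raises if any required column (:data:`COHORT_COLUMNS`) is absent.
    Empty cells and ``NA`` are read as missing; nothing is imputed here.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""])
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    for col in _NUMERIC_COHORT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant id: {dup!r}")
    # region must be a deterministic function of province
    per_prov = df.dropna(subset=["region"]).groupby("province")["region"].nunique()
    if (per_prov > 1).any():
        bad = per_prov.index[per_prov > 1][0]
        raise ValueError(f"province {bad!r} maps to more than one region")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
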