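"""Shared domain types, tabular I/O, and the SUVr scaling primitive.

All regional uptake is handled as standardized uptake value ratios (SUVr):
the regional mean activity divided by the mean activity of a reference region
(here the cerebellum, so control-level values sit near 1.0).  Matrices are
subjects x regions; region columns are canonicalized to atlas order on read so
that every downstream stage can rely on a fixed column semantics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from tauperf.atlas import RegionAtlas

GROUPS = ("FOURRT", "OTHER_ND", "HC")

#: Valid closed ranges for clinical scores (checked when present).
SCORE_RANGES = {"pspr": (0.0, 100.0), "moca": (0.0, 30.0), "seadl": (0.0, 100.0)}

COHORT_COLUMNS = [
    "subject_id", "group", "subgroup", "age", "sex",
    "disease_duration_months", "pspr", "moca", "seadl", "site",
]


class Phase(str, enum.Enum):
    """Tracer acquisition window: EARLY = perfusion surrogate, LATE = tau."""

    EARLY = "EARLY"
    LATE = "LATE"


def compute_suvr(regional_mean_uptake: float, reference_mean_uptake: float) -> float:
    """Standardized uptake value ratio of a region against the reference.

    Parameters
    ----------
    regional_mean_uptake
        Mean activity concentration in the target region (> 0).
    reference_mean_uptake
        Mean activity concentration in the reference region (> 0).
    """
    if not regional_mean_uptake > 0:
        raise ValueError(
            f"regional_mean_uptake must be positive, got {regional_mean_uptake}"
        )
    if not reference_mean_uptake > 0:
        raise ValueError(
            f"reference_mean_uptake must be positive, got {reference_mean_uptake}"
        )
    return regional_mean_uptake / reference_mean_uptake


@dataclass(frozen=True)
class SuvrMatrix:
    """Subjects x regions table of reference-scaled uptake ratios.

    ``values`` is a DataFrame indexed by subject id with one column per atlas
    region, in atlas order.  All entries are strictly positive.
    """

    phase: Phase
    values: pd.DataFrame
    reference_label: str = "cerebellum"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("SUVr matrix contains non-finite values")
        if not np.all(arr > 0):
            raise ValueError("SUVr values must be strictly positive")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def subset(self, subject_ids) -> "SuvrMatrix":
        return replace(self, values=self.values.loc[list(subject_ids)])


@dataclass(frozen=True)
class CohortTable:
    """Per-subject diagnosis group, covariates and clinical scores.

    Missing clinical scores are NaN (explicit nulls), never sentinel numbers.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COHORT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        ids = self.table["subject_id"]
        if ids.duplicated().any():
            raise ValueError(
                f"duplicate subject ids: {ids[ids.duplicated()].unique().tolist()}"
            )
        bad_group = set(self.table["group"].unique()) - set(GROUPS)
        if bad_group:
            raise ValueError(f"unknown groups: {sorted(bad_group)}")
        bad_sex = set(self.table["sex"].unique()) - {"F", "M"}
        if bad_sex:
            raise ValueError(f"sex must be F or M, got: {sorted(bad_sex)}")
        for col, (lo, hi) in SCORE_RANGES.items():
            vals = self.table[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{col} values outside [{lo}, {hi}]")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    def subset(self, subject_ids) -> "CohortTable":
        wanted = list(subject_ids)
        sub = self.table.set_index("subject_id").loc[wanted].reset_index()
        return CohortTable(sub)

    def select(self, *, group=None, site=None) -> "CohortTable":
        t = self.table
        if group is not None:
            groups = (group,) if isinstance(group, str) else tuple(group)
            t = t[t["group"].isin(groups)]
        if site is not None:
            t = t[t["site"] == site]
        return CohortTable(t.reset_index(drop=True))


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip float parsing: written artifacts re-read bit-identically
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_suvr_matrix(path: str | Path, atlas: RegionAtlas, phase: Phase,
                     reference_label: str = "cerebellum") -> SuvrMatrix:
    """Read a SUVr CSV/TSV (first column subject id, one column per region).

    Columns are reordered to atlas order; unknown or missing region labels
    are rejected by name.
    """
    df = _read_table(path)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject id(s) in {path}: {dupes}")
    unknown = [c for c in df.columns if c not in set(atlas.labels)]
    if unknown:
        raise ValueError(f"column label(s) not in atlas: {unknown}")
    missing = [lab for lab in atlas.labels if lab not in set(df.columns)]
    if missing:
        raise ValueError(f"missing region column(s): {missing}")
    df = df[atlas.labels]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric SUVr cell in {path}: {exc}") from exc
    return SuvrMatrix(phase=phase, values=df, reference_label=reference_label)


def write_suvr_matrix(matrix: SuvrMatrix, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out = matrix.values.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep=sep)


def read_cohort(path: str | Path) -> CohortTable:
    df = _read_table(path)
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cohort.table.to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class AlignedData:
    """Row-aligned SUVr matrix and cohort restricted to common subjects."""

    matrix: SuvrMatrix
    cohort: CohortTable
    dropped_matrix_ids: tuple[str, ...]
    dropped_cohort_ids: tuple[str, ...]


def align_cohort(matrix: SuvrMatrix, cohort: CohortTable) -> AlignedData:
    """Pair matrix rows with cohort rows on subject id.

    Keeps the intersection in the matrix's original row order and reports
    the ids dropped from either side.  Raises if the id sets are disjoint.
    """
    matrix_ids = matrix.subject_ids
    cohort_ids = set(cohort.subject_ids)
    common = [sid for sid in matrix_ids if sid in cohort_ids]
    if not common:
        raise ValueError("subject id sets of matrix and cohort are disjoint")
    dropped_m = tuple(sid for sid in matrix_ids if sid not in cohort_ids)
    dropped_c = tuple(sid for sid in cohort.subject_ids if sid not in set(matrix_ids))
    return AlignedData(
        matrix=matrix.subset(common),
        cohort=cohort.subset(common),
        dropped_matrix_ids=dropped_m,
        dropped_cohort_ids=dropped_c,
    )
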