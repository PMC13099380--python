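"""Cohort volume tables: typed I/O and interquartile-range volume QC.

A cohort table is one row per subject: identifiers, group label, the four
model covariates (age, sex, education, total brain volume), and one column
of gray-matter volume (mm^3) per atlas region. QC flags per-group volume
outliers beyond ``k * IQR`` fences; flagged subjects are reported, never
dropped — the analysis keeps every subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas

COVARIATE_COLUMNS = ("age", "sex", "education", "total_brain_volume")
ID_COLUMNS = ("subject_id", "group")
DEFAULT_GROUPS = ("NEC", "TEC", "PTSD")

MIN_GROUP_SIZE_INFERENCE = 8


@dataclass
class CohortTable:
    """Subjects x (covariates + region volumes), with group labels.

    ``data`` column order is: subject_id, group, the four covariates, then
    the atlas regions in atlas order.
    """

    data: pd.DataFrame
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + COVARIATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        absent = [r for r in self.atlas.names if r not in self.data.columns]
        if absent:
            raise ValueError(f"cohort table missing region columns: {absent}")
        if self.data["subject_id"].duplicated().any():
            dup = self.data.loc[self.data["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {sorted(set(dup))}")
        for col in COVARIATE_COLUMNS:
            if self.data[col].isna().any():
                bad = self.data.loc[self.data[col].isna(), "subject_id"].tolist()
                raise ValueError(f"missing {col} for subjects {bad}")
        vols = self.data[self.atlas.names]
        if vols.isna().any().any() or (vols <= 0).any().any():
            mask = vols.isna() | (vols <= 0)
            sub, reg = np.argwhere(mask.to_numpy())[0]
            raise ValueError(
                "non-positive or missing volume for subject "
                f"{self.data['subject_id'].iloc[sub]!r}, region {self.atlas.names[reg]!r}"
            )
        # normalise column order to the canonical layout
        cols = list(ID_COLUMNS + COVARIATE_COLUMNS) + self.atlas.names
        self.data = self.data[cols].reset_index(drop=True)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.data["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def group_sizes(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()

    def n_subjects(self, group: str | None = None) -> int:
        if group is None:
            return len(self.data)
        return int((self.data["group"] == group).sum())

    def subset(self, group: str) -> pd.DataFrame:
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise ValueError(f"group {group!r} not present in cohort table")
        return sub

    def volumes(self, group: str | None = None) -> np.ndarray:
        """Subjects x regions volume matrix (atlas order), optionally per group."""
        frame = self.data if group is None else self.subset(group)
        return frame[self.atlas.names].to_numpy(dtype=float)

    def covariate_design(self, group: str | None = None) -> np.ndarray:
        """Design matrix [1, age, sex, education, TBV] for the regression adjustment."""
        frame = self.data if group is None else self.subset(group)
        X = frame[list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(frame)), X])

    def require_inferential_sizes(self, min_size: int = MIN_GROUP_SIZE_INFERENCE) -> None:
        small = {g: n for g, n in self.group_sizes.items() if n < min_size}
        if small:
            raise ValueError(
                f"groups too small for inference (need >= {min_size}): {small}"
            )


@dataclass
class OutlierReport:
    """Per-(subject, region) IQR flags and the derived participant outliers."""

    flags: pd.DataFrame  # boolean, index=subject_id, columns=regions
    participant_outliers: set[str]
    k_iqr: float
    min_regions: int
    skipped_regions: list[tuple[str, str]] = field(default_factory=list)  # (group, region)

    @property
    def n_flagged_per_subject(self) -> pd.Series:
        return self.flags.sum(axis=1)

    def group_counts(self, table: CohortTable) -> dict[str, int]:
        """Number of subjects per group with at least one flagged region."""
        any_flag = self.flags.any(axis=1)
        groups = table.data.set_index("subject_id")["group"]
        out: dict[str, int] = {}
        for g in table.groups:
            out[g] = int(any_flag[groups[groups == g].index].sum())
        return out


def _detect_sep(path: Path) -> str:
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path} contains no header row")


def load_cohort_table(path: str | Path, atlas: RegionAtlas) -> CohortTable:
    """Read a delimited cohort table (TSV default, comma accepted)."""
    path = Path(path)
    frame = pd.read_csv(
        path, sep=_detect_sep(path), comment="#", float_precision="round_trip"
    )
    frame["subject_id"] = frame["subject_id"].astype(str)
    return CohortTable(data=frame, atlas=atlas)


def write_cohort_table(
    table: CohortTable, path: str | Path, *, header_comment: str | None = None
) -> None:
    """Write a cohort table as TSV; round-trips bit-identically via repr precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # %.17g is lossless for float64, so write/read round-trips bit-identically
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def flag_volume_outliers(
    table: CohortTable, k_iqr: float = 3.0, min_regions: int = 4
) -> OutlierReport:
    """Flag per-group regional volumes outside ``[Q1 - k*IQR, Q3 + k*IQR]``.

    Quartiles use linear interpolation and are computed within each group,
    since group-level volume shifts would otherwise masquerade as outliers.
    Subjects flagged in at least ``min_regions`` regions are reported as
    participant outliers. The report is advisory: no rows are removed.
    """
    if k_iqr <= 0:
        raise ValueError("k_iqr must be positive")
    for g, n in table.group_sizes.items():
        if n < 5:
            raise ValueError(f"group {g!r} has {n} subjects; need >= 5 for quartiles")
    flags = pd.DataFrame(
        False, index=table.data["subject_id"], columns=table.atlas.names
    )
    skipped: list[tuple[str, str]] = []
    for g in table.groups:
        sub = table.subset(g)
        vols = sub[table.atlas.names].to_numpy(dtype=float)
        q1, q3 = np.percentile(vols, [25, 75], axis=0)  # linear interpolation
        iqr = q3 - q1
        degenerate = iqr == 0
        if degenerate.any():
            for j in np.flatnonzero(degenerate):
                skipped.append((g, table.atlas.names[j]))
            warnings.warn(
                f"group {g!r}: zero IQR for regions "
                f"{[table.atlas.names[j] for j in np.flatnonzero(degenerate)]}; skipped",
                stacklevel=2,
            )
        lo = q1 - k_iqr * iqr
        hi = q3 + k_iqr * iqr
        mask = (vols < lo) | (vols > hi)
        mask[:, degenerate] = False
        flags.loc[sub["subject_id"], :] = mask
    per_subject = flags.sum(axis=1)
    outliers = set(per_subject.index[per_subject >= min_regions])
    return OutlierReport(
        flags=flags,
        participant_outliers=outliers,
        k_iqr=k_iqr,
        min_regions=min_regions,
        skipped_regions=skipped,
    )
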