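"""Per-group covariate-adjusted partial-correlation association matrices.

Structural covariance is the inter-individual correlation of regional
gray-matter volumes within a group, after removing linear effects of age,
sex, education, and total brain volume.  Each group gets its own full
region x region association matrix (adjustment fitted per group, so no
group-mean structure leaks through the covariate fit), with a Fisher-z
twin for variance-stabilized comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cohort_io import COVARIATE_COLUMNS, CohortTable


@dataclass
class CovarianceNetwork:
    group: str
    r_matrix: np.ndarray
    n_subjects: int
    atlas: RegionAtlas
    covariates_used: tuple[str, ...] = COVARIATE_COLUMNS

    def __post_init__(self) -> None:
        R = np.asarray(self.r_matrix, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] != len(self.atlas):
            raise ValueError("r_matrix must be square and atlas-aligned")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("r_matrix must be symmetric")
        self.r_matrix = (R + R.T) / 2.0

    @property
    def z_matrix(self) -> np.ndarray:
        """Fisher transform of the off-diagonal; diagonal left at 0 (unused)."""
        off = ~np.eye(len(self.atlas), dtype=bool)
        z = np.zeros_like(self.r_matrix)
        z[off] = fisher_z(np.clip(self.r_matrix[off], -0.999999, 0.999999))
        return z

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(len(self.atlas), k=1)
        return self.r_matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_matrix, index=self.atlas.names, columns=self.atlas.names)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="region")
        meta = {
            "group": self.group,
            "n_subjects": self.n_subjects,
            "covariates": list(self.covariates_used),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of each column of ``values`` against ``design``.

    The design must contain an intercept column; residuals are orthogonal to
    every design column. Rank deficiency is a hard error naming the
    collinear columns.
    """
    values = np.asarray(values, dtype=float)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if values.shape[0] != n:
        raise ValueError("values and design have different numbers of rows")
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows for {p} design columns, got {n}")
    if not np.any(np.all(np.isclose(design, design[0:1, :]), axis=0)):
        raise ValueError("design must include an intercept (constant) column")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        # identify columns whose removal restores full column rank
        collinear = [
            j for j in range(p)
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def association_matrix(
    table: CohortTable,
    group: str,
    atlas: RegionAtlas | None = None,
    covariates: tuple[str, ...] = COVARIATE_COLUMNS,
) -> CovarianceNetwork:
    """Partial-correlation matrix for one group (full region x region).

    Pearson correlations of the residualized volume columns; the adjustment
    regression is fitted within the group.
    """
    atlas = atlas if atlas is not None else table.atlas
    sub = table.subset(group)
    n = len(sub)
    if n < len(covariates) + 3:
        raise ValueError(
            f"group {group!r} has {n} subjects; need >= {len(covariates) + 3}"
        )
    X = sub[atlas.names].to_numpy(dtype=float)
    D = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in covariates])
    resid = residualize(X, D)
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd < 1e-12)
    if dead.size:
        raise ValueError(
            f"zero-variance residuals for regions {[atlas.names[j] for j in dead]}"
        )
    R = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(R, 1.0)
    return CovarianceNetwork(
        group=group, r_matrix=R, n_subjects=n, atlas=atlas, covariates_used=covariates
    )


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1; clamp or exclude unit correlations")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def subnucleus_profile(
    network: CovarianceNetwork, subnucleus: str, atlas: RegionAtlas | None = None
) -> pd.DataFrame:
    """Covariance profile of one amygdala subnucleus with every non-subnucleus region.

    Returns a frame (partner, r, z) in atlas order; with the default
    105-region atlas this has exactly 87 rows.
    """
    atlas = atlas if atlas is not None else network.atlas
    sub_set = set(atlas.subnuclei)
    if subnucleus not in sub_set:
        raise ValueError(f"{subnucleus!r} is not an amygdala subnucleus in this atlas")
    i = atlas.index(subnucleus)
    rows = []
    for name in atlas.names:
        if name in sub_set:
            continue
        r = float(network.r_matrix[i, atlas.index(name)])
        rows.append((name, r, float(np.arctanh(np.clip(r, -0.999999, 0.999999)))))
    return pd.DataFrame(rows, columns=["partner", "r", "z"])
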