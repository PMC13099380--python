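"""Hirschberger-Qi-Steuer (HQS) random covariance null models.

HQS generates random positive-semidefinite covariance matrices whose
off-diagonal mean and variance match an observed matrix: C = B B^T with B
an (n_regions x m) matrix of i.i.d. normal(mu, sigma2) entries. The moment
identities

    m * mu^2                        = e_bar   (off-diagonal mean)
    m * (sigma2^2 + 2 mu^2 sigma2)  = v_bar   (off-diagonal variance)

fix mu and sigma2 once m is chosen.  Observed association matrices here
are correlation matrices (d_bar = 1), and null draws are normalized back
to correlation scale before thresholding so that null and observed graphs
are binarized under identical rules and edge counts.

The construction requires a positive off-diagonal mean; a negative mean
(rare for structural covariance, whose shared-growth factors push
correlations positive) is a hard error rather than a silent |r| fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import CovarianceNetwork
from .topology import (
    DensityGrid,
    adjacency_stack,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    nodal_degree,
)


@dataclass(frozen=True)
class HQSParams:
    e_bar: float
    v_bar: float
    d_bar: float
    m: int
    mu: float
    sigma2: float
    n_null: int = 20

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("factor count m must be >= 2")
        if self.e_bar <= 0:
            raise ValueError(
                "HQS requires a positive off-diagonal mean; "
                "use an |r| or shifted association mode upstream"
            )
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    def moment_residuals(self) -> tuple[float, float]:
        """How far the stored (mu, sigma2, m) are from the target moments."""
        r1 = self.m * self.mu**2 - self.e_bar
        r2 = self.m * (self.sigma2**2 + 2 * self.mu**2 * self.sigma2) - self.v_bar
        return r1, r2


def solve_hqs_moments(e_bar: float, v_bar: float, m: int) -> tuple[float, float]:
    """mu and sigma2 satisfying the HQS moment identities for a given m."""
    if e_bar <= 0:
        raise ValueError("e_bar must be positive")
    if v_bar <= 0:
        raise ValueError("v_bar must be positive")
    mu = np.sqrt(e_bar / m)
    sigma2 = -(mu**2) + np.sqrt(mu**4 + v_bar / m)
    return float(mu), float(sigma2)


def default_factor_count(e_bar: float, v_bar: float, d_bar: float, n_regions: int) -> int:
    """m matching the diagonal scale: round((d_bar^2 - e_bar^2)/v_bar), clipped."""
    m = int(round((d_bar**2 - e_bar**2) / v_bar))
    return int(np.clip(m, 2, max(2, n_regions)))


def fit_hqs_params(
    observed: CovarianceNetwork, m: int | None = None, n_null: int = 20
) -> HQSParams:
    """Match HQS parameters to an observed association (correlation) matrix."""
    off = observed.offdiagonal()
    e_bar = float(off.mean())
    v_bar = float(off.var())
    d_bar = float(np.diag(observed.r_matrix).mean())
    if e_bar <= 0:
        raise ValueError(
            f"off-diagonal mean {e_bar:.4f} <= 0; HQS moment construction "
            "assumes positive-mean covariance"
        )
    if m is None:
        m = default_factor_count(e_bar, v_bar, d_bar, len(observed.atlas))
    mu, sigma2 = solve_hqs_moments(e_bar, v_bar, m)
    return HQSParams(
        e_bar=e_bar, v_bar=v_bar, d_bar=d_bar, m=m, mu=mu, sigma2=sigma2, n_null=n_null
    )


def hqs_random_covariance(
    params: HQSParams, n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    """One random covariance draw C = B B^T (PSD by construction)."""
    B = rng.normal(params.mu, np.sqrt(params.sigma2), size=(n_regions, params.m))
    return B @ B.T


def to_correlation(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)


def null_topology_summary(
    params: HQSParams,
    n_regions: int,
    grid: DensityGrid,
    metrics: tuple[str, ...] = ("clustering", "path_length"),
    rng: np.random.Generator | None = None,
    n_null: int | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Null mean/SD of requested metrics per density over n_null HQS draws.

    Draws are normalized to correlation scale, thresholded with the same
    largest-k rule as observed networks (hence identical edge counts), and
    the metrics averaged. Disconnected nulls at low density contribute
    their connected-pair path length (per the observed-network convention).
    Returns {metric: {"mean": ..., "sd": ..., "n_null": ...}}.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n_null = n_null if n_null is not None else params.n_null
    acc: dict[str, list[np.ndarray]] = {m: [] for m in metrics}
    for _ in range(n_null):
        R = to_correlation(hqs_random_covariance(params, n_regions, rng))
        stack = adjacency_stack(R, grid)
        vals: dict[str, list[float]] = {m: [] for m in metrics}
        for A in stack.adjacency:
            for m in metrics:
                if m == "clustering":
                    vals[m].append(clustering_coefficient(A)[1])
                elif m == "path_length":
                    vals[m].append(characteristic_path_length(A)[0])
                elif m == "global_efficiency":
                    vals[m].append(global_efficiency(A))
                elif m == "degree":
                    vals[m].append(float(nodal_degree(A).mean()))
                else:
                    raise ValueError(f"unsupported null metric {m!r}")
        for m in metrics:
            acc[m].append(np.array(vals[m]))
    out: dict[str, dict[str, np.ndarray]] = {}
    for m in metrics:
        stackv = np.vstack(acc[m])
        out[m] = {
            "mean": np.nanmean(stackv, axis=0),
            "sd": np.nanstd(stackv, axis=0),
            "n_null": np.full(len(grid), n_null),
        }
    return out
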