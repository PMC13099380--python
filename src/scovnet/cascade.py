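"""Three-stage comparison of subnucleus covariance profiles between groups.

Stage 1 (omnibus gate): for each amygdala subnucleus, its Fisher-z
covariance profile (one z per non-subnucleus partner region; 87 with the
default atlas) is compared across groups with a Kruskal-Wallis rank test,
gated at p <= 0.02 (0.05 Bonferroni-split over the three group
comparisons).  Stage 2: Dunn's rank-based pairwise tests pick which group
pairs drive a gated subnucleus (unadjusted, gate role only, p <= 0.05).
Stage 3: for every surviving (subnucleus, group pair), each partner
region's correlations are compared as independent correlations — the
Fisher z statistic on atanh-transformed r with n-3 weights, plus Zou's
confidence interval for the correlation difference — and Benjamini-
Hochberg corrected within the family of partner regions.

The omnibus stage treats the profile values as exchangeable observations;
they are in fact mutually dependent (they share the subnucleus), so the
gate is a screening heuristic, not a calibrated test — the FDR-corrected
stage-3 comparisons carry the inferential weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas
from .cohort_io import CohortTable
from .networks import CovarianceNetwork, association_matrix, subnucleus_profile

R_CLAMP = 0.999999


def kruskal_wallis(samples: dict[str, np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in samples.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0  # all values identical: no rank information
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons following a Kruskal-Wallis test.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal
    p-values, unadjusted (the stage-2 gate).
    """
    names = list(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    rows = []
    for (i, gi), (j, gj) in combinations(enumerate(names), 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var) if var > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((gi, gj, float(z), float(p)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])


def _check_rn(r: float, n: int) -> float:
    if n <= 3:
        raise ValueError(f"need n > 3 per group for the Fisher comparison, got {n}")
    if abs(r) >= 1:
        warnings.warn(f"correlation {r} at unit bound; clamping to +/-{R_CLAMP}", stacklevel=3)
        r = float(np.sign(r)) * R_CLAMP
    return r


def fisher_compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Independent-correlation comparison: Fisher Z statistic and two-sided p.

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    r1 = _check_rn(r1, n1)
    r2 = _check_rn(r2, n2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def zou_interval(
    r1: float, n1: int, r2: float, n2: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Zou's confidence interval for the difference of two independent correlations.

    Each correlation gets its Fisher-transform CI, and the interval for
    r1 - r2 combines the per-group bounds:
      low  = r1 - r2 - sqrt((r1 - l1)^2 + (u2 - r2)^2)
      high = r1 - r2 + sqrt((u1 - r1)^2 + (r2 - l2)^2)
    """
    r1 = _check_rn(r1, n1)
    r2 = _check_rn(r2, n2)
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    l1, u1 = np.tanh(np.arctanh(r1) + np.array([-zc, zc]) / np.sqrt(n1 - 3))
    l2, u2 = np.tanh(np.arctanh(r2) + np.array([-zc, zc]) / np.sqrt(n2 - 3))
    diff = r1 - r2
    low = diff - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    high = diff + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return float(low), float(high)


@dataclass
class CascadeResult:
    """All three stages: omnibus tests, post-hoc gates, pairwise comparisons."""

    omnibus: pd.DataFrame  # subnucleus, kw_h, kw_p, passed
    posthoc: pd.DataFrame  # subnucleus, group_a, group_b, z, p, passed
    pairwise: pd.DataFrame  # subnucleus, group_a, group_b, partner, r1, r2, n1, n2,
    #                         fisher_Z, p, zou_low, zou_high, q_bh, significant
    gate_alpha: float | None = 0.02
    dunn_alpha: float | None = 0.05
    fdr_alpha: float = 0.05
    networks: dict[str, CovarianceNetwork] = field(default_factory=dict)

    def significant_pairs(self) -> pd.DataFrame:
        if self.pairwise.empty:
            return self.pairwise
        return self.pairwise[self.pairwise["significant"]].reset_index(drop=True)

    def table3_style(self) -> pd.DataFrame:
        """Omnibus + Dunn summary mirroring the per-subnucleus report layout."""
        rows = []
        for _, om in self.omnibus.iterrows():
            sub = self.posthoc[
                (self.posthoc["subnucleus"] == om["subnucleus"]) & self.posthoc["passed"]
            ]
            if sub.empty:
                rows.append((om["subnucleus"], om["kw_p"], "", np.nan, np.nan))
            for _, ph in sub.iterrows():
                rows.append(
                    (om["subnucleus"], om["kw_p"],
                     f"{ph['group_a']} - {ph['group_b']}", ph["z"], ph["p"])
                )
        return pd.DataFrame(
            rows, columns=["subnucleus", "kw_p", "comparison", "dunn_z", "dunn_p"]
        )

    def table4_style(self) -> pd.DataFrame:
        """Significant pairwise comparisons in the published-table layout."""
        sig = self.significant_pairs()
        cols = ["group_a", "group_b", "subnucleus", "partner", "r1", "r2",
                "fisher_Z", "zou_low", "zou_high", "q_bh"]
        return sig[cols] if not sig.empty else pd.DataFrame(columns=cols)


def run_cascade(
    table: CohortTable,
    atlas: RegionAtlas | None = None,
    gate_alpha: float | None = 0.02,
    dunn_alpha: float | None = 0.05,
    fdr_alpha: float = 0.05,
    networks: dict[str, CovarianceNetwork] | None = None,
) -> CascadeResult:
    """Run the full three-stage cascade on a cohort table.

    With exactly two groups the omnibus/post-hoc stages are skipped and
    stage 3 runs directly on the single pair; passing ``gate_alpha=None``
    (or ``dunn_alpha=None``) disables the corresponding gate explicitly.
    """
    atlas = atlas if atlas is not None else table.atlas
    subnuclei = atlas.subnuclei
    if not subnuclei:
        raise ValueError("atlas has no amygdala subnuclei")
    groups = table.groups
    table.require_inferential_sizes()
    if networks is None:
        networks = {g: association_matrix(table, g, atlas) for g in groups}
    n_by_group = {g: networks[g].n_subjects for g in groups}
    profiles = {
        (g, s): subnucleus_profile(networks[g], s, atlas)
        for g in groups
        for s in subnuclei
    }

    two_group_mode = len(groups) == 2
    omnibus_rows, posthoc_rows, pairwise_rows = [], [], []
    for s in subnuclei:
        samples = {g: profiles[(g, s)]["z"].to_numpy() for g in groups}
        if two_group_mode:
            gated_pairs = [tuple(groups)]
            omnibus_rows.append((s, np.nan, np.nan, True))
        else:
            h, p = kruskal_wallis(samples)
            passed = True if gate_alpha is None else p <= gate_alpha
            omnibus_rows.append((s, h, p, passed))
            gated_pairs = []
            if passed:
                dunn = dunn_posthoc(samples)
                for _, row in dunn.iterrows():
                    ok = True if dunn_alpha is None else row["p"] <= dunn_alpha
                    posthoc_rows.append(
                        (s, row["group_a"], row["group_b"], row["z"], row["p"], ok)
                    )
                    if ok:
                        gated_pairs.append((row["group_a"], row["group_b"]))
        for ga, gb in gated_pairs:
            prof_a, prof_b = profiles[(ga, s)], profiles[(gb, s)]
            n1, n2 = n_by_group[ga], n_by_group[gb]
            fam = []
            for (_, ra), (_, rb) in zip(prof_a.iterrows(), prof_b.iterrows()):
                z, p = fisher_compare_correlations(ra["r"], n1, rb["r"], n2)
                low, high = zou_interval(ra["r"], n1, rb["r"], n2)
                fam.append((ra["partner"], ra["r"], rb["r"], z, p, low, high))
            ps = np.array([f[4] for f in fam])
            qs = np.array([]) if ps.size == 0 else multipletests(ps, method="fdr_bh")[1]
            for (partner, r1, r2, z, p, low, high), q in zip(fam, qs):
                pairwise_rows.append(
                    (s, ga, gb, partner, r1, r2, n1, n2, z, p, low, high, q,
                     q <= fdr_alpha)
                )

    omnibus = pd.DataFrame(omnibus_rows, columns=["subnucleus", "kw_h", "kw_p", "passed"])
    posthoc = pd.DataFrame(
        posthoc_rows, columns=["subnucleus", "group_a", "group_b", "z", "p", "passed"]
    )
    pairwise = pd.DataFrame(
        pairwise_rows,
        columns=["subnucleus", "group_a", "group_b", "partner", "r1", "r2", "n1", "n2",
                 "fisher_Z", "p", "zou_low", "zou_high", "q_bh", "significant"],
    )
    return CascadeResult(
        omnibus=omnibus, posthoc=posthoc, pairwise=pairwise,
        gate_alpha=gate_alpha, dunn_alpha=dunn_alpha, fdr_alpha=fdr_alpha,
        networks=networks,
    )
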