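"""Synthetic cohorts with known covariance structure.

Regional volumes are generated from a latent-factor model so that the
covariate-adjusted inter-regional correlation matrix is known in closed
form: every region loads on a shared positive factor (producing the
positive-mean structural covariance the analysis assumes), optional
secondary factors add between-pair variability, and planted effects are
implemented as extra factor columns, never as post-hoc matrix surgery —
the implied covariance is positive semi-definite by construction.

For a planted pair (a, b) with target correlation ``rho`` in one group,
both regions drop their secondary loadings (so their rows are symmetric:
shared loading ``l``, unique noise variance ``s2n``) and gain a dedicated
factor with loading ``s`` on a and ``sign * s`` on b.  Writing
``T = l^2 + s2n`` (the variance without the pair factor), the pair
correlation is ``(l^2 + sign*s^2) / (T + s^2)``, which solves to

    s^2 = (rho*T - l^2) / (1 - rho)    if rho above the baseline l^2/T
    s^2 = (l^2 - rho*T) / (1 + rho)    otherwise (sign = -1)

so any target in (-1, 1) is feasible while unique variance stays positive.

A planted hub replaces one region's shared-factor loading in one group,
raising its correlation with every other region; the same mechanism
produces profile-wide group shifts for cascade-recovery scenarios.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, default_atlas, make_atlas
from .cohort_io import COVARIATE_COLUMNS, CohortTable, write_cohort_table

DEFAULT_GROUP_SIZES = {"NEC": 59, "TEC": 78, "PTSD": 73}

# Effect sizes in residual-SD units per covariate SD; recoverable by OLS.
DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.15,
    "sex": 0.10,
    "education": 0.05,
    "total_brain_volume": 0.40,
}

# Scales used to convert standardized effects into raw coefficients.
_COVARIATE_SCALES = {"age": 10.0, "sex": 0.5, "education": 1.2, "total_brain_volume": 1.8e5}

# Fraction of female participants when demographics are imbalanced (Table-1-like).
_IMBALANCED_FEMALE_FRAC = {"NEC": 0.51, "TEC": 0.65, "PTSD": 0.93}

_BASELINE_VOLUME = {"cortical": 8000.0, "subcortical": 4000.0, "amygdala_subnucleus": 300.0}


@dataclass(frozen=True)
class PlantedPair:
    """Pairwise correlation targets per group; groups not listed keep baseline."""

    region_a: str
    region_b: str
    targets: dict[str, float]


@dataclass(frozen=True)
class PlantedHub:
    """Replacement shared-factor loading for one region in one group."""

    region: str
    group: str
    loading: float


@dataclass(frozen=True)
class SyntheticSpec:
    """All knobs of the generator; defaults emulate the study cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    atlas: RegionAtlas | None = None
    latent_factors: int = 3
    loading_scale: float = 0.55
    secondary_loading_sd: float = 0.15
    noise_sd: float = 0.85
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_hubs: tuple[PlantedHub, ...] = ()
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    volume_cv: float = 0.08
    imbalanced_demographics: bool = False
    seed: int = 0

    def resolved_atlas(self) -> RegionAtlas:
        return self.atlas if self.atlas is not None else default_atlas()

    def validate(self) -> None:
        atlas = self.resolved_atlas()
        for g, n in self.group_sizes.items():
            if n < 8:
                raise ValueError(f"group {g!r} size {n} < 8")
        if self.latent_factors < 1:
            raise ValueError("need at least one latent factor")
        planted_regions: set[str] = set()
        for pp in self.planted_pairs:
            for r in (pp.region_a, pp.region_b):
                if r not in atlas:
                    raise ValueError(f"planted region {r!r} not in atlas")
                if r in planted_regions:
                    raise ValueError(f"region {r!r} appears in more than one planted pair")
                planted_regions.add(r)
            for g, rho in pp.targets.items():
                if g not in self.group_sizes:
                    raise ValueError(f"planted pair targets unknown group {g!r}")
                if not -1 < rho < 1:
                    raise ValueError(f"target correlation {rho} outside (-1, 1)")
        for hub in self.planted_hubs:
            if hub.region not in atlas:
                raise ValueError(f"planted hub region {hub.region!r} not in atlas")
            if hub.group not in self.group_sizes:
                raise ValueError(f"planted hub targets unknown group {hub.group!r}")


def _pair_factor_loading(
    rho: float, la: float, lb: float, noise_var: float
) -> tuple[float, float]:
    """Loading magnitude and sign of the dedicated pair factor.

    With shared-factor loadings (la, lb) and unique variance ``noise_var``,
    a pair factor with loadings (s, sign*s) gives

        corr(s) = (la*lb + sign*s^2) /
                  sqrt((la^2 + s^2 + noise_var) * (lb^2 + s^2 + noise_var))

    which runs from the baseline at s=0 toward ``sign`` as s grows, so any
    target in (-1, 1) brackets a root.  When la == lb the solution has the
    closed form s^2 = (rho*T - l^2)/(1 - rho) (above baseline, T = l^2 +
    noise_var) or (l^2 - rho*T)/(1 + rho) (below); the bracketed solve
    reproduces it and also covers hub-boosted asymmetric rows.
    """
    from scipy.optimize import brentq

    base = la * lb / np.sqrt((la**2 + noise_var) * (lb**2 + noise_var))
    if np.isclose(rho, base):
        return 0.0, 1.0
    sign = 1.0 if rho > base else -1.0

    def corr(s: float) -> float:
        return (la * lb + sign * s * s) / np.sqrt(
            (la**2 + s * s + noise_var) * (lb**2 + s * s + noise_var)
        )

    hi = 1.0
    while (corr(hi) - rho) * (corr(0.0) - rho) > 0:
        hi *= 2.0
        if hi > 1e8:
            raise ValueError(f"infeasible planted correlation {rho} (baseline {base:.3f})")
    return float(brentq(lambda s: corr(s) - rho, 0.0, hi, xtol=1e-12)), sign


def _group_loadings(
    spec: SyntheticSpec, group: str, secondary: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Loading matrix (regions x factors) and unique SDs for one group."""
    atlas = spec.resolved_atlas()
    n = len(atlas)
    n_pair_factors = len(spec.planted_pairs)
    lam = np.zeros((n, spec.latent_factors + n_pair_factors))
    lam[:, 0] = spec.loading_scale
    if spec.latent_factors > 1:
        lam[:, 1 : spec.latent_factors] = secondary
    for hub in spec.planted_hubs:
        if hub.group == group:
            i = atlas.index(hub.region)
            lam[i, 0] = hub.loading
            lam[i, 1 : spec.latent_factors] = 0.0
    noise_var = np.full(n, spec.noise_sd**2)
    for k, pp in enumerate(spec.planted_pairs):
        ia, ib = atlas.index(pp.region_a), atlas.index(pp.region_b)
        # symmetric rows required by the closed-form solve
        lam[[ia, ib], 1 : spec.latent_factors] = 0.0
        if group in pp.targets:
            s, sign = _pair_factor_loading(
                pp.targets[group], float(lam[ia, 0]), float(lam[ib, 0]), spec.noise_sd**2
            )
            lam[ia, spec.latent_factors + k] = s
            lam[ib, spec.latent_factors + k] = sign * s
    return lam, np.sqrt(noise_var)


def implied_correlations(spec: SyntheticSpec, group: str) -> np.ndarray:
    """Closed-form covariate-adjusted correlation matrix implied for a group."""
    spec.validate()
    secondary = _secondary_loadings(spec)
    lam, unique_sd = _group_loadings(spec, group, secondary)
    cov = lam @ lam.T + np.diag(unique_sd**2)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _secondary_loadings(spec: SyntheticSpec) -> np.ndarray:
    """Secondary-factor loadings, shared across groups, fixed by spec.seed."""
    n = len(spec.resolved_atlas())
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EC0]))
    if spec.latent_factors <= 1:
        return np.zeros((n, 0))
    return rng.normal(0.0, spec.secondary_loading_sd, size=(n, spec.latent_factors - 1))


def _covariates(rng: np.random.Generator, group: str, n: int, spec: SyntheticSpec) -> dict:
    if spec.imbalanced_demographics:
        female = _IMBALANCED_FEMALE_FRAC.get(group, 0.5)
        age_lo, age_hi = (18, 35) if group == "NEC" else (18, 55)
    else:
        female, (age_lo, age_hi) = 0.5, (18, 55)
    return {
        "age": rng.uniform(age_lo, age_hi, n),
        "sex": (rng.random(n) < female).astype(float),
        "education": rng.integers(0, 5, n).astype(float),
        "total_brain_volume": np.maximum(rng.normal(1.03e6, 1.8e5, n), 5e5),
    }


def generate_cohort(spec: SyntheticSpec, seed: int | None = None) -> CohortTable:
    """Sample a cohort table from the spec; deterministic under a fixed seed."""
    spec.validate()
    atlas = spec.resolved_atlas()
    n_regions = len(atlas)
    master = seed if seed is not None else spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([master, 0xC0F0]))
    design_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA5E]))

    classes = [r.region_class for r in atlas]
    baseline = np.array([_BASELINE_VOLUME[c] for c in classes])
    baseline = baseline * design_rng.uniform(0.7, 1.3, n_regions)  # per-region scale
    sd = spec.volume_cv * baseline

    secondary = _secondary_loadings(spec)
    rows = []
    for group, n_sub in spec.group_sizes.items():
        lam, unique_sd = _group_loadings(spec, group, secondary)
        total_sd = np.sqrt(np.einsum("ij,ij->i", lam, lam) + unique_sd**2)
        factors = rng.standard_normal((n_sub, lam.shape[1]))
        eps = rng.standard_normal((n_sub, n_regions))
        z = (factors @ lam.T + eps * unique_sd) / total_sd  # unit-variance latent
        cov = _covariates(rng, group, n_sub, spec)
        vols = baseline + sd * z
        for name, effect in spec.covariate_effects.items():
            centered = cov[name] - np.mean(
                [18.0, 55.0]
            ) if name == "age" else cov[name] - {"sex": 0.5, "education": 2.0,
                                                 "total_brain_volume": 1.03e6}[name]
            beta = effect * sd / _COVARIATE_SCALES[name]  # per-region coefficient
            vols = vols + np.outer(centered, beta)
        if (vols <= 0).any():
            warnings.warn("clipping non-positive synthetic volumes", stacklevel=2)
            vols = np.maximum(vols, 0.05 * baseline)
        frame = pd.DataFrame(vols, columns=atlas.names)
        frame.insert(0, "total_brain_volume", cov["total_brain_volume"])
        frame.insert(0, "education", cov["education"])
        frame.insert(0, "sex", cov["sex"])
        frame.insert(0, "age", cov["age"])
        frame.insert(0, "group", group)
        rows.append(frame)
    data = pd.concat(rows, ignore_index=True)
    data.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(len(data))])
    return CohortTable(data=data, atlas=atlas)


# ---------------------------------------------------------------------------
# fixtures and canned scenarios


def fixture_atlas() -> RegionAtlas:
    """8-region test atlas: 4 cortical, 2 subcortical, 2 amygdala subnuclei."""
    recs = [
        {"name": "ctx-lh-parahippocampal", "class": "cortical", "hemisphere": "left"},
        {"name": "ctx-rh-entorhinal", "class": "cortical", "hemisphere": "right"},
        {"name": "ctx-lh-precuneus", "class": "cortical", "hemisphere": "left"},
        {"name": "ctx-rh-insula", "class": "cortical", "hemisphere": "right"},
        {"name": "Left-Hippocampus", "class": "subcortical", "hemisphere": "left"},
        {"name": "Right-Amygdala", "class": "subcortical", "hemisphere": "right"},
        {"name": "Left-Lateral-nucleus", "class": "amygdala_subnucleus", "hemisphere": "left"},
        {"name": "Right-Lateral-nucleus", "class": "amygdala_subnucleus", "hemisphere": "right"},
    ]
    return make_atlas(recs)


FIXTURE_PAIR = ("Left-Lateral-nucleus", "ctx-lh-parahippocampal")


def make_fixture_spec() -> SyntheticSpec:
    # with 10 subjects per group the contrast must be strong for the
    # planted difference to be detectable (E[Fisher Z] ~ 4.7)
    return SyntheticSpec(
        group_sizes={"NEC": 10, "TEC": 10, "PTSD": 10},
        atlas=fixture_atlas(),
        planted_pairs=(
            PlantedPair(*FIXTURE_PAIR, targets={"NEC": 0.95, "PTSD": -0.6}),
        ),
        seed=2024,
    )


def make_fixture_small() -> CohortTable:
    """Deterministic 30-subject, 8-region cohort with one planted pair difference."""
    return generate_cohort(make_fixture_spec())


def fixture_checksum(table: CohortTable) -> str:
    """Stable checksum of the serialized fixture (round/format-normalized)."""
    payload = table.data.to_csv(sep="\t", index=False, float_format="%.6f")
    return hashlib.sha256(payload.encode()).hexdigest()


def make_recovery_spec(
    subnucleus: str = "Left-Central-nucleus",
    partner: str = "Left-Amygdala",
    r_nec: float = 0.9,
    r_other: float = 0.7,
    seed: int = 0,
) -> SyntheticSpec:
    """Cascade-recovery scenario at the study's group sizes.

    Plants one pairwise covariance difference (NEC vs the trauma groups) on a
    subnucleus whose shared-factor loading is also raised in NEC, so the
    subnucleus's whole covariance profile shifts between groups — the single
    pair alone cannot move an 87-value rank test, mirroring how profile-wide
    group differences are driven by specific pairs in real cohorts.
    """
    return SyntheticSpec(
        planted_pairs=(
            PlantedPair(
                subnucleus, partner,
                targets={"NEC": r_nec, "TEC": r_other, "PTSD": r_other},
            ),
        ),
        planted_hubs=(PlantedHub(subnucleus, "NEC", 0.80),),
        seed=seed,
    )


def make_hub_spec(
    region: str = "Right-Paralaminar-nucleus",
    group: str = "TEC",
    loading: float = 2.0,
    n_per_group: int = 60,
    other_group: str = "NEC",
    seed: int = 0,
) -> SyntheticSpec:
    """Two-group scenario with one planted high-connectivity (hub) subnucleus."""
    return SyntheticSpec(
        group_sizes={other_group: n_per_group, group: n_per_group},
        planted_hubs=(PlantedHub(region, group, loading),),
        seed=seed,
    )


def write_synthetic_cohort(spec: SyntheticSpec, path, seed: int | None = None) -> CohortTable:
    table = generate_cohort(spec, seed=seed)
    used = seed if seed is not None else spec.seed
    write_cohort_table(table, path, header_comment=f"synthetic cohort, seed={used}")
    return table
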