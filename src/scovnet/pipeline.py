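"""End-to-end pipeline: QC -> networks -> D_min -> topology -> nulls -> inference -> cascade.

The config carries every analysis constant (2% density steps, 1000
permutations, 20 null networks, the 0.02 omnibus gate) so a run is fully
described by one YAML file plus a master seed.  The master seed is
expanded into per-stage substreams, so stages rerun in isolation
reproduce the full run's numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, default_atlas, load_region_atlas
from .cascade import CascadeResult, run_cascade
from .cohort_io import CohortTable, flag_volume_outliers, load_cohort_table, write_cohort_table
from .inference import permutation_test_fda
from .networks import association_matrix
from .nulls import fit_hqs_params, null_topology_summary
from .synthetic import SyntheticSpec, generate_cohort, make_fixture_spec
from .topology import DensityGrid, find_dmin, metric_curves, small_worldness, binarize_at_density

log = logging.getLogger("scovnet")

_STAGE_SALT = {"nulls": 1, "inference": 2, "synthetic": 3}


@dataclass
class PipelineConfig:
    cohort_path: str | None = None
    atlas_path: str | None = None
    synthetic: dict | None = None  # SyntheticSpec overrides, or {"preset": "fixture"}
    step: float = 0.02
    d_max: float = 0.50
    b_perms: int = 1000
    n_null: int = 20
    gate_alpha: float = 0.02
    dunn_alpha: float = 0.05
    fdr_alpha: float = 0.05
    metrics: tuple[str, ...] = ("degree",)
    seed: int = 0
    outdir: str = "scovnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metrics" in payload:
            payload["metrics"] = tuple(payload["metrics"])
        return cls(**payload)

    def validate(self) -> None:
        for name in ("gate_alpha", "dunn_alpha", "fdr_alpha", "step", "d_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.cohort_path is None and self.synthetic is None:
            raise ValueError("config needs either a cohort path or a synthetic spec")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STAGE_SALT[stage]]))


def load_inputs(config: PipelineConfig) -> CohortTable:
    atlas = (
        load_region_atlas(config.atlas_path) if config.atlas_path else default_atlas()
    )
    if config.cohort_path:
        return load_cohort_table(config.cohort_path, atlas)
    overrides = dict(config.synthetic or {})
    if overrides.pop("preset", None) == "fixture":
        spec = make_fixture_spec()
    else:
        if config.atlas_path:
            overrides["atlas"] = atlas
        overrides.setdefault("seed", int(_stage_rng(config.seed, "synthetic").integers(2**31)))
        spec = SyntheticSpec(**overrides)
    return generate_cohort(spec)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns a summary dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    log.info("stage: inputs")
    table = load_inputs(config)
    atlas = table.atlas
    write_cohort_table(table, out / "cohort.tsv")
    summary["stages"]["inputs"] = {
        "n_subjects": table.n_subjects(),
        "groups": table.group_sizes,
        "n_regions": len(atlas),
        "class_counts": atlas.class_counts,
    }

    log.info("stage: qc")
    qc = flag_volume_outliers(table)
    qc_frame = pd.DataFrame(
        {
            "subject_id": qc.flags.index,
            "n_flagged_regions": qc.n_flagged_per_subject.to_numpy(),
            "participant_outlier": [s in qc.participant_outliers for s in qc.flags.index],
        }
    )
    _write_tsv(qc_frame, out / "qc_outliers.tsv")
    summary["stages"]["qc"] = {
        "flagged_subjects_per_group": qc.group_counts(table),
        "participant_outliers": sorted(qc.participant_outliers),
        "note": "report-only; no subjects removed",
    }

    log.info("stage: networks")
    networks = {g: association_matrix(table, g, atlas) for g in table.groups}
    for g, net in networks.items():
        net.write(out / f"association_{g}.tsv")

    log.info("stage: density grid")
    d_min = find_dmin([net.r_matrix for net in networks.values()], step=config.step)
    grid = DensityGrid(d_min=d_min, d_max=max(config.d_max, d_min), step=config.step)
    summary["stages"]["grid"] = {
        "d_min": d_min,
        "d_max": grid.d_max,
        "step": config.step,
        "n_densities": len(grid),
        "d_max_rule": "fixed upper bound from config",
    }

    log.info("stage: topology")
    tidy_rows = []
    for g, net in networks.items():
        curves = metric_curves(
            net.r_matrix, grid, metrics=config.metrics, node_names=atlas.names
        )
        for c in curves:
            for d, v in zip(c.densities, c.values):
                tidy_rows.append((g, c.metric, c.scope, d, v))
    _write_tsv(
        pd.DataFrame(tidy_rows, columns=["group", "metric", "scope", "density", "value"]),
        out / "metric_curves.tsv",
    )

    log.info("stage: null models")
    null_rng = _stage_rng(config.seed, "nulls")
    null_rows = []
    sw_rows = []
    for g, net in networks.items():
        params = fit_hqs_params(net, n_null=config.n_null)
        nulls = null_topology_summary(
            params, len(atlas), grid,
            metrics=("clustering", "path_length"), rng=null_rng,
        )
        for m, stats_ in nulls.items():
            for d, mean, sd in zip(grid.densities, stats_["mean"], stats_["sd"]):
                null_rows.append((g, m, d, mean, sd, config.n_null))
        for d, c_rand, l_rand in zip(
            grid.densities, nulls["clustering"]["mean"], nulls["path_length"]["mean"]
        ):
            A = binarize_at_density(net.r_matrix, d)
            sw_rows.append((g, d, small_worldness(A, c_rand, l_rand)))
    _write_tsv(
        pd.DataFrame(null_rows, columns=["group", "metric", "density", "null_mean", "null_sd", "n_null"]),
        out / "null_summaries.tsv",
    )
    _write_tsv(
        pd.DataFrame(sw_rows, columns=["group", "density", "small_worldness"]),
        out / "small_worldness.tsv",
    )

    log.info("stage: inference (degree FDA, %d permutations)", config.b_perms)
    inf_rng = _stage_rng(config.seed, "inference")
    inf_rows = []
    for ga, gb in combinations(table.groups, 2):
        results = permutation_test_fda(
            table, (ga, gb), metric="degree", scope=atlas.subnuclei or atlas.names,
            grid=grid, b_perms=config.b_perms, rng=inf_rng,
        )
        for r in results:
            inf_rows.append(
                (r.metric, r.scope, ga, gb, r.s_obs, r.p_perm, r.q_fdr, r.b_perms)
            )
    inference_frame = pd.DataFrame(
        inf_rows,
        columns=["metric", "scope", "group_a", "group_b", "s_obs", "p_perm", "q_fdr", "b_perms"],
    )
    _write_tsv(inference_frame, out / "fda_results.tsv")

    log.info("stage: cascade")
    if atlas.subnuclei:
        cascade = run_cascade(
            table, atlas, gate_alpha=config.gate_alpha,
            dunn_alpha=config.dunn_alpha, fdr_alpha=config.fdr_alpha,
            networks=networks,
        )
        _write_tsv(cascade.table3_style(), out / "cascade_omnibus.tsv")
        _write_tsv(cascade.table4_style(), out / "cascade_pairwise.tsv")
        summary["stages"]["cascade"] = {
            "gated_subnuclei": cascade.omnibus.loc[cascade.omnibus["passed"], "subnucleus"].tolist(),
            "n_significant_pairs": int(cascade.pairwise["significant"].sum())
            if not cascade.pairwise.empty else 0,
        }
    else:
        cascade = None

    _write_report(out, config, summary, inference_frame, cascade)
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary


def _write_report(
    out: Path,
    config: PipelineConfig,
    summary: dict,
    inference_frame: pd.DataFrame,
    cascade: CascadeResult | None,
) -> None:
    lines = ["# Structural covariance network report", ""]
    inp = summary["stages"]["inputs"]
    lines += [
        f"Seed: {config.seed}",
        f"Subjects: {inp['n_subjects']} in groups {inp['groups']}",
        f"Regions: {inp['n_regions']} ({inp['class_counts']})",
        "",
        "## Density grid",
        f"D_min = {summary['stages']['grid']['d_min']:.2f}, "
        f"D_max = {summary['stages']['grid']['d_max']:.2f}, "
        f"step = {config.step:.2f}",
        "",
        "## Nodal degree FDA (permutation) results",
        inference_frame.to_string(index=False),
        "",
    ]
    if cascade is not None:
        lines += [
            "## Covariance cascade: omnibus and post-hoc gates",
            cascade.table3_style().to_string(index=False),
            "",
            "## Covariance cascade: significant pairwise comparisons",
            cascade.table4_style().to_string(index=False)
            if not cascade.table4_style().empty
            else "(none at q <= %.2f)" % cascade.fdr_alpha,
            "",
        ]
    (out / "report.md").write_text("\n".join(lines), encoding="utf-8")
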