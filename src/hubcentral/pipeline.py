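"""End-to-end orchestration of the analysis stages.

``run_all`` ties simulate -> preprocess -> graphs -> centrality -> stats ->
seed connectivity into one reproducible run: a single master seed spawns
per-stage seeds, every stage writes plain-text outputs into the run
directory, and a manifest records the configuration hash and seeds so that
rerunning the same configuration reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import atlas, centrality, graphs, preprocess, seed_fc, stats, synthetic_cohort


@dataclass
class PipelineConfig:
    """Run configuration; defaults follow the reference acquisition and
    analysis parameters (185 volumes with 10 discarded, 0.01-0.08 Hz,
    densities 0.10-0.40 step 0.01, 100 modularity restarts, group networks
    at density 0.30)."""

    out_dir: str = "hubcentral_run"
    n_per_group: int = 20
    n_nodes: int = 92
    n_timepoints: int = 185
    n_discard: int = 10
    tr_seconds: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    density_start: float = 0.10
    density_stop: float = 0.40
    density_step: float = 0.01
    group_network_density: float = 0.30
    n_restarts: int = 100
    n_perm: int = 5000
    hub_boost: float = 0.25
    hypothesis_nodes: list[str] = field(
        default_factory=lambda: list(atlas.THALAMUS_NODES)
    )
    specificity_nodes: list[str] = field(
        default_factory=lambda: atlas.CEREBELLUM_NODES + atlas.MOTOR_CORTEX_NODES
    )
    seed_regions: dict[str, list[str]] = field(
        default_factory=lambda: {
            "putamen": list(atlas.PUTAMEN_NODES),
            "pallidum": list(atlas.PALLIDUM_NODES),
        }
    )
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_labels(self, labels: list[str]) -> None:
        wanted = (
            self.hypothesis_nodes
            + self.specificity_nodes
            + [n for ns in self.seed_regions.values() for n in ns]
        )
        atlas.label_indices(labels, wanted)

    def stage_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.master_seed)
        return {
            stage: int(rng.integers(0, 2**31 - 1))
            for stage in ("simulate", "centrality", "group_networks", "seed_fc")
        }


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage on a freshly simulated cohort; returns the manifest."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = config.stage_seeds()
    design = synthetic_cohort.CohortDesign(
        n_per_group=config.n_per_group,
        n_nodes=config.n_nodes,
        n_timepoints=config.n_timepoints,
        tr_seconds=config.tr_seconds,
        hub_boost=config.hub_boost,
        seed=seeds["simulate"],
    )
    config.validate_labels(design.node_labels)
    subjects = synthetic_cohort.build_cohort(design)
    raw_dir = os.path.join(config.out_dir, "raw")
    synthetic_cohort.write_cohort(subjects, raw_dir)
    cohort = stats.score_definitions(synthetic_cohort.cohort_table(subjects))
    cohort.to_csv(os.path.join(config.out_dir, "cohort_scored.csv"), index=False)

    grid = graphs.DensityGrid(
        config.density_start, config.density_stop, config.density_step
    )
    cleaned: list[tuple[preprocess.RoiTimeSeries, preprocess.NuisanceTable]] = []
    matrices: list[graphs.ConnectivityMatrix] = []
    profiles: list[centrality.CentralityProfile] = []
    qc_rows = []
    cent_rng = np.random.default_rng(seeds["centrality"])
    for s in subjects:
        clean = preprocess.clean_subject(
            s.timeseries, s.nuisance, config.n_discard,
            config.low_hz, config.high_hz,
        )
        nui = s.nuisance.drop_initial(config.n_discard)
        cleaned.append((clean, nui))
        qc = preprocess.motion_qc(s.nuisance.motion6, config.tr_seconds)
        qc_rows.append({"subject_id": s.subject_id, **asdict_qc(qc)})
        cm = graphs.correlation_matrix(clean)
        matrices.append(cm)
        stack = graphs.threshold_by_density(cm, grid)
        profiles.append(
            centrality.profile_subject(
                stack, config.n_restarts,
                int(cent_rng.integers(0, 2**31 - 1)),
            )
        )
    pd.DataFrame(qc_rows).to_csv(
        os.path.join(config.out_dir, "motion_qc.csv"), index=False
    )
    frame = stats.profiles_to_frame(profiles)
    frame.to_csv(
        os.path.join(config.out_dir, "centrality_long.tsv"), sep="\t",
        index=False,
    )

    nodes = config.hypothesis_nodes + config.specificity_nodes
    effects = stats.group_effects(frame, cohort, nodes)
    effects.to_csv(os.path.join(config.out_dir, "group_effects.csv"), index=False)
    # Resting tremor is constant zero in NTP by definition, so it is only
    # correlated within TP; the remaining scores are screened in both
    # patient groups.
    screen_tp = stats.specificity_screen(
        frame, cohort, config.hypothesis_nodes, centrality.METRICS,
        ["resting_tremor", "total_tremor", "bradykinesia", "rigidity"],
        groups=["TP"],
    )
    screen_ntp = stats.specificity_screen(
        frame, cohort, config.hypothesis_nodes, centrality.METRICS,
        ["total_tremor", "bradykinesia", "rigidity"], groups=["NTP"],
    )
    correlations = pd.concat(
        [screen_tp.correlations, screen_ntp.correlations], ignore_index=True
    )
    correlations.to_csv(
        os.path.join(config.out_dir, "clinical_correlations.csv"), index=False
    )

    by_group: dict[str, list[graphs.ConnectivityMatrix]] = {}
    for s, cm in zip(subjects, matrices):
        by_group.setdefault(s.group, []).append(cm)
    group_summaries = {}
    for grp, mats in by_group.items():
        summ = centrality.group_network_modules(
            mats, config.group_network_density, config.hypothesis_nodes,
            config.n_restarts, seeds["group_networks"],
        )
        group_summaries[grp] = {
            node: {
                "same_module": summ.neighbors[node]["same_module"],
                "other_module": summ.neighbors[node]["other_module"],
            }
            for node in config.hypothesis_nodes
        }

    fc_results = {}
    fc_rng = np.random.default_rng(seeds["seed_fc"])
    for seed_name, seed_nodes in config.seed_regions.items():
        betas = seed_fc.collect_betas(cleaned, seed_nodes)
        res = seed_fc.group_contrast_fwe(
            betas, cohort, config.hypothesis_nodes, "TP", "HC",
            n_perm=config.n_perm, seed=int(fc_rng.integers(0, 2**31 - 1)),
        )
        corr = seed_fc.beta_clinical_correlation(
            betas[res.peak_node], cohort,
            ["resting_tremor", "total_tremor"], "TP",
        )
        fc_results[seed_name] = {
            "peak_node": res.peak_node,
            "t": {n: float(v) for n, v in res.t.items()},
            "p_fwe": {n: float(v) for n, v in res.p_fwe.items()},
            "clinical": corr.to_dict(orient="records"),
        }

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "n_subjects": len(subjects),
        "group_networks": group_summaries,
        "seed_fc": fc_results,
        "outputs": sorted(set(os.listdir(config.out_dir)) | {"manifest.json"}),
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def asdict_qc(qc: preprocess.MotionQc) -> dict:
    return {
        "sum_translation_mm": qc.sum_translation_mm,
        "sum_rotation_deg": qc.sum_rotation_deg,
        "mean_fd_mm": qc.mean_fd_mm,
    }
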