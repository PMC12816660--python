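"""Stage orchestration and the convergence report.

The pipeline joins four independent lines of evidence about the
deficit-critical region — the CFWER-significant lesion-symptom cluster, the
consensus-hub connectome seeded from it, simulated-disconnection behaviour
correlations, and the stimulation-site probability-density map — and
quantifies their spatial convergence (Dice / directed overlap between the
SVR-LSM cluster, the PDE threshold mask, and the track-density core) in one
shared world frame.

``run_pipeline`` executes stages in dependency order from a single config
mapping and records a :class:`RunManifest`; ``verify_published_examples``
recomputes the worked-example statistics whose exact inputs are printed in
the published reference results (F ratios, paired t, Spearman rho) and reports
the deviation of each.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .behaviour import mixed_rm_anova, paired_effects, spearman_report
from .connectome import (build_fbc, composite_hubs, consensus_top_edges,
                         population_tdi, tdi)
from .disconnection import disconnection_table, edgewise_correlation
from .stats import bonferroni, cohens_dz_from_t, partial_eta_sq, spearman_p, spearman_t
from .stim import eloquence_rule, hemifield_error_summary, lateralisation, pde
from .streamlines import filter_by_roi
from .svrlsm import SvrLsmConfig, run_svrlsm
from .synthdata import (SyntheticSpec, make_connectome_cohort, make_lesion_cohort,
                        make_resection_scenarios, make_stim_sites)

__all__ = ["RunManifest", "run_pipeline", "verify_published_examples", "PipelineError"]

ALL_STAGES = ("synth", "behaviour", "svrlsm", "connectome", "disconnect", "stim", "report")


class PipelineError(RuntimeError):
    """A stage is missing its upstream input; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    timing_s: dict = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True, default=str))


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: Optional[dict] = None, out_dir="run",
                 stages: Sequence[str] = ALL_STAGES) -> RunManifest:
    """Execute the requested stages in dependency order on synthetic cohorts.

    ``config`` keys (all optional): ``seed``, ``synth`` (SyntheticSpec field
    overrides per sub-spec), ``svrlsm`` (SvrLsmConfig overrides),
    ``score`` (behavioural score column). Outputs land under ``out_dir``:
    NIfTI maps, CSV tables, and ``report.json`` with the convergence
    overlaps. Identical config and seed reproduce identical outputs.
    """
    from . import __version__

    config = dict(config or {})
    seed = int(config.get("seed", 7))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = _build_spec(seed, config.get("synth", {}))
    manifest = RunManifest(config=config, seed=seed, version=__version__)
    manifest.input_hashes["spec"] = spec.content_hash()
    stages = list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    state: dict = {}

    def _need(key: str, producer: str):
        if key not in state:
            raise PipelineError(
                f"stage needs '{key}' but stage '{producer}' has not run; "
                f"add '{producer}' to the stage list")
        return state[key]

    for stage in [s for s in ALL_STAGES if s in stages]:
        t0 = time.perf_counter()
        if stage == "synth":
            streams = spec.streams()
            cohort, lesion_truth = make_lesion_cohort(spec.lesion, streams["lesion"])
            sets, atlas, conn_truth = make_connectome_cohort(spec.connectome,
                                                             streams["connectome"])
            sites, stim_truth = make_stim_sites(spec.stim, streams["stim"])
            scenarios, res_atlas, res_truth = make_resection_scenarios(
                spec.resection, spec.connectome, streams["resection"])
            state.update(cohort=cohort, lesion_truth=lesion_truth, sets=sets,
                         atlas=atlas, conn_truth=conn_truth, sites=sites,
                         scenarios=scenarios, res_atlas=res_atlas, res_truth=res_truth)
            cio.save_lesion_cohort(cohort, out / "lesions")
            cio.save_atlas(atlas, out / "atlas.nii", out / "nodes.csv")
            cio.save_stim_csvs(sites, out / "sites.csv", out / "trials.csv")
            lesion_truth["region_mask"].save(out / "planted_region.nii")
            manifest.outputs["synth"] = str(out / "lesions")
        elif stage == "behaviour":
            cohort = _need("cohort", "synth")
            tbl = cohort.behaviour
            anova = mixed_rm_anova(tbl[["pre_total", "post_total"]]
                                   .rename(columns={"pre_total": "pre", "post_total": "post"}),
                                   tbl["hemisphere"]) if tbl["hemisphere"].nunique() > 1 else None
            paired = paired_effects(tbl["pre_asymmetry"], tbl["post_asymmetry"])
            rho = spearman_report(tbl["delta_total"], tbl["delta_asymmetry"])
            summary = {
                "paired_t": paired.t, "cohens_dz": paired.cohens_dz, "r_rb": paired.r_rb,
                "spearman_rho_total_vs_asym": rho.rho, "spearman_t": rho.t,
            }
            if anova:
                summary["anova_time_F"] = anova["time"].F
                summary["anova_time_eta_p_sq"] = anova["time"].partial_eta_sq
            _write_json(out / "behaviour_stats.json", summary)
            state["behaviour_summary"] = summary
            manifest.outputs["behaviour"] = str(out / "behaviour_stats.json")
        elif stage == "svrlsm":
            cohort = _need("cohort", "synth")
            cfg = _build_svr_config(seed, config.get("svrlsm", {}))
            result = run_svrlsm(cohort, cfg, score=config.get("score", "delta_asymmetry"))
            state["svrlsm"] = result
            result.beta_map.save(out / "beta_map.nii")
            result.p_map.save(out / "p_map.nii")
            result.significant_cluster_mask.save(out / "svr_cluster.nii")
            result.cluster_table.to_csv(out / "clusters.csv", index=False)
            _write_json(out / "svrlsm.json", {
                "hyperparameters": result.hyperparameters,
                "critical_p": result.critical_p,
                "prediction_accuracy": result.prediction_accuracy,
                "prediction_accuracy_sd": result.prediction_accuracy_sd,
                "reproducibility": result.reproducibility,
                "n_significant_voxels": int(result.significant_cluster_mask.data.sum()),
            })
            manifest.outputs["svrlsm"] = str(out / "svr_cluster.nii")
        elif stage == "connectome":
            sets = _need("sets", "synth")
            atlas = state["atlas"]
            roi = state["svrlsm"].significant_cluster_mask if "svrlsm" in state else None
            if roi is not None and roi.data.sum() > 0:
                filtered = [filter_by_roi(s, roi, segment_mode=True) for s in sets]
                filtered = [f if len(f) else s for f, s in zip(filtered, sets)]
            else:
                filtered = sets
            mats = [build_fbc(s, atlas) for s in filtered]
            hubs = composite_hubs(mats)
            edges = consensus_top_edges(mats, hubs.hubs or atlas.node_list[:1],
                                        classes=atlas.classes)
            grid = state["cohort"].grid if "cohort" in state else atlas.label_volume
            tdis = [tdi(s, grid) for s in filtered]
            pop = population_tdi([t.zmap for t in tdis])
            core = pop.with_data((pop.data > 2.0).astype(np.uint8))
            state.update(fbc=mats, hubs=hubs, edges=edges, tdi_core=core)
            hubs.consensus.to_csv(out / "hubs.csv", index=False)
            edges.to_csv(out / "consensus_edges.csv", index=False)
            pop.save(out / "tdi_population_z.nii")
            core.save(out / "tdi_core.nii")
            manifest.outputs["connectome"] = str(out / "hubs.csv")
        elif stage == "disconnect":
            scenarios = _need("scenarios", "synth")
            res_truth = state["res_truth"]
            edges = res_truth["top_edges"]
            table = disconnection_table(scenarios, state["res_atlas"], edges)
            corr = edgewise_correlation(table, m=len(edges))
            table.to_csv(out / "disconnection.csv", index=False)
            corr.to_csv(out / "disconnection_correlation.csv", index=False)
            state["disconnection_corr"] = corr
            manifest.outputs["disconnect"] = str(out / "disconnection_correlation.csv")
        elif stage == "stim":
            sites = _need("sites", "synth")
            grid = state["cohort"].grid if "cohort" in state else None
            if grid is None:
                raise PipelineError("stim stage needs the synth grid; run 'synth'")
            rows = []
            neglect_sites = []
            for s in sites:
                eloquent = eloquence_rule(s.trials)
                row = {"site_id": s.site_id, "gyrus_label": s.gyrus_label,
                       "eloquent": eloquent}
                if s.omitted_positions():
                    idx, neglect = lateralisation(s)
                    row.update(lateralisation_index=idx, neglect_like=neglect)
                    if eloquent and neglect:
                        neglect_sites.append(s)
                rows.append(row)
            site_table = pd.DataFrame(rows)
            summary = hemifield_error_summary(sites)
            coords = np.array([s.world_coordinate for s in
                               (neglect_sites if len(neglect_sites) >= 2 else sites)])
            pmap = pde(coords, grid, bandwidth_mm=config.get("pde_bandwidth_mm", 5.0))
            mask = pmap.threshold_mask(0.5)
            state.update(site_table=site_table, pde_mask=mask, pde_map=pmap)
            site_table.to_csv(out / "site_classification.csv", index=False)
            summary.to_csv(out / "hemifield_summary.csv", index=False)
            pmap.density.save(out / "pde.nii")
            mask.save(out / "pde_mask.nii")
            manifest.outputs["stim"] = str(out / "pde_mask.nii")
        elif stage == "report":
            report: dict = {"seed": seed, "spec_hash": spec.content_hash()}
            pairs = []
            if "svrlsm" in state and "pde_mask" in state:
                pairs.append(("svr_cluster_vs_pde",
                              state["svrlsm"].significant_cluster_mask, state["pde_mask"]))
            if "svrlsm" in state and "tdi_core" in state:
                pairs.append(("svr_cluster_vs_tdi_core",
                              state["svrlsm"].significant_cluster_mask, state["tdi_core"]))
            if "pde_mask" in state and "tdi_core" in state:
                pairs.append(("pde_vs_tdi_core", state["pde_mask"], state["tdi_core"]))
            from .stim import convergence_overlap
            for name, a, b in pairs:
                report[name] = convergence_overlap(a, b)
            if "hubs" in state:
                report["consensus_hubs"] = state["hubs"].hubs
                report["n_consensus_edges"] = int(len(state["edges"]))
            if "disconnection_corr" in state:
                top = state["disconnection_corr"].dropna(subset=["rho"]).head(3)
                report["top_disconnection_edges"] = top[
                    ["hub", "partner", "rho", "p_bonferroni"]].to_dict("records")
            _write_json(out / "report.json", report)
            state["report"] = report
            manifest.outputs["report"] = str(out / "report.json")
        manifest.stages.append(stage)
        manifest.timing_s[stage] = round(time.perf_counter() - t0, 3)
    manifest.save(out / "manifest.json")
    state["manifest"] = manifest
    run_pipeline.last_state = state  # inspection hook for drivers/tests
    return manifest


def _build_spec(seed: int, overrides: dict) -> SyntheticSpec:
    spec = SyntheticSpec(seed=seed)
    for section, values in overrides.items():
        sub = getattr(spec, section)
        for k, v in values.items():
            if not hasattr(sub, k):
                raise PipelineError(f"unknown synth option {section}.{k}")
            setattr(sub, k, type(getattr(sub, k))(v) if getattr(sub, k) is not None else v)
    return spec


def _build_svr_config(seed: int, overrides: dict) -> SvrLsmConfig:
    kwargs = {"seed": seed, "n_permutations": 500, "n_opt_iterations": 30}
    kwargs.update(overrides)
    return SvrLsmConfig(**kwargs)


def verify_published_examples() -> pd.DataFrame:
    """Recompute the worked-example statistics with printed exact inputs.

    Each row: the quantity, its recomputed value, the published value, the
    tolerance at which they are compared, and whether they agree.
    """
    rows = [
        ("eta_p_sq_time_total", partial_eta_sq(54.23, 1, 161), 0.252, 0.0005),
        ("eta_p_sq_interaction_asym", partial_eta_sq(24.92, 1, 161), 0.134, 0.0005),
        ("eta_p_sq_prospective_time", partial_eta_sq(0.10, 1, 45), 0.002, 0.0005),
        ("cohens_dz_right_asym", cohens_dz_from_t(-5.272, 82), -0.582, 0.001),
        ("spearman_t_total_vs_asym", spearman_t(0.770, 82), 10.79, 0.01),
        ("bonferroni_p_scef_thalamus", bonferroni(spearman_p(0.826, 15), 39),
         0.0057724, 0.02 * 0.0057724),
        ("bonferroni_p_scef_brainstem", bonferroni(spearman_p(0.8178, 15), 39),
         0.0076243, 0.02 * 0.0076243),
        ("bonferroni_p_sfl_scef", bonferroni(spearman_p(0.78911, 15), 39),
         0.018318, 0.02 * 0.018318),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "computed", "published", "tolerance"])
    df["ok"] = (df["computed"] - df["published"]).abs() <= df["tolerance"]
    return df
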