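"""Synthetic cohorts with the statistical structure each pipeline stage assumes.

Real resection cohorts, normative tractograms and intraoperative stimulation
logs are restricted data; these generators stand in for them with planted,
known ground truth so that every stage can be exercised and validated
end-to-end:

* **lesion cohorts** — ellipsoidal resection blobs on a shared grid with a
  planted deficit-critical region: the behavioural change score is
  effect * (overlap with the region) + covariate terms + Gaussian noise;
* **connectome cohorts** — weighted streamline bundles between lattice
  nodes over a near-regular base graph, with planted hub nodes (extra,
  heavier connections) and planted top edges (dominant bundles);
* **stimulation sites** — Gaussian clusters of coordinates whose omission
  positions carry a configurable left-hemifield bias;
* **resection scenarios** — cavities placed to sever planted consensus
  edges with graded overlap, and a deficit score that is a monotone
  function of planted-edge disconnection plus noise.

Everything is driven by one seed through named substreams: identical specs
give bit-identical outputs, and any field change alters the content hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .behaviour import BellsRecord
from .connectome import NodeAtlas
from .images import VoxelImage
from .streamlines import StreamlineSet
from .svrlsm import LesionCohort
from .disconnection import ResectionScenario
from .stim import StimSite, StimTrial

__all__ = [
    "LesionSpec", "ConnectomeSpec", "StimSpec", "ResectionSpec", "SyntheticSpec",
    "make_lesion_cohort", "make_connectome_cohort", "make_stim_sites",
    "make_resection_scenarios", "render_bells_sheet",
]


@dataclass
class LesionSpec:
    """Lesion cohort: 16^3 grid at 2 mm, 60 subjects, 3^3 planted region.

    Resections are focal ellipsoids that either *include* the planted
    critical region (a ``hit``: centre jittered around the region centre,
    probability ``hit_probability``, and the region removed en bloc with the
    blob) or *spare* it (centre uniform in the centre box at least
    ``miss_min_distance_vox`` from the region centre, blob clipped to
    respect the region) — the bimodal overlap distribution of real
    eloquence-guided resection cohorts, where critical tissue is removed or
    preserved as a unit. ``effect_size`` is in score points; at the default
    ``noise_sd`` of 1.0 it equals the effect in noise-SD units.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 2.0
    n_subjects: int = 60
    blob_radius_range_vox: tuple[float, float] = (2.0, 3.5)
    centre_box: tuple[tuple[int, int, int], tuple[int, int, int]] = ((4, 4, 4), (11, 11, 11))
    region_slices: tuple[tuple[int, int], ...] = ((6, 9), (6, 9), (6, 9))
    hit_probability: float = 0.5
    hit_jitter_vox: float = 0.8
    miss_min_distance_vox: float = 2.5
    effect_size: float = 1.5
    noise_sd: float = 1.0
    covariate_coefficients: tuple[float, float, float] = (0.02, -0.05, 0.2)  # age, education, grade
    bilateral_mean: float = 1.0
    bilateral_sd: float = 0.5


@dataclass
class ConnectomeSpec:
    """Connectome cohort: 20 subjects, 60 lattice nodes, 5 planted hubs.

    The base graph is 6-regular (so degree carries no hub signal under the
    null); planted hubs receive ``hub_extra_degree`` additional partners with
    ``hub_weight_multiplier``-fold heavier bundles, and each hub gets
    ``top_edges_per_hub`` planted dominant bundles at
    ``top_edge_multiplier`` times the hub edge weight. Weight noise is the
    fractional sd of the per-streamline weight jitter.
    """

    n_subjects: int = 20
    n_nodes: int = 60
    n_hubs: int = 5
    base_degree: int = 6
    hub_extra_degree: int = 22
    hub_weight_multiplier: float = 3.0
    top_edges_per_hub: int = 2
    top_edge_multiplier: float = 6.0
    weight_noise_fraction: float = 0.2
    streamlines_per_edge: int = 4
    mu_range: tuple[float, float] = (0.8, 1.2)
    world_size_mm: float = 32.0
    lattice_spacing_mm: float = 8.0
    bundle_spread_mm: float = 2.0
    base_edge_weight: float = 1.0


@dataclass
class StimSpec:
    """Stimulation sites: Gaussian clusters with position-coded omission bias.

    Defaults mirror a three-gyrus layout (superior/middle/inferior frontal)
    with decreasing left-hemifield bias; each cluster is a named group with
    its own centroid and bias. The first centroid sits at the world centre
    of the default planted lesion region so that stimulation evidence and
    lesion evidence converge in the shared synthetic frame.
    """

    cluster_names: tuple[str, ...] = ("SFG", "MFG", "IFG")
    cluster_centroids: tuple[tuple[float, float, float], ...] = (
        (14.0, 14.0, 14.0), (24.0, 20.0, 8.0), (6.0, 8.0, 24.0))
    cluster_left_bias: tuple[float, ...] = (0.93, 0.667, 0.533)
    sites_per_cluster: int = 20
    spread_mm: float = 4.0
    trials_per_site: int = 8
    stimulated_fraction: float = 0.75
    eloquent_fraction: float = 0.6
    p_omit_nontarget_trial: float = 0.1


@dataclass
class ResectionSpec:
    """Resection scenarios: graded cavities over planted consensus edges."""

    n_subjects: int = 15
    streamlines_per_edge: int = 10
    n_planted_edges: int = 3
    effect_scale: float = 2.0
    noise_sd: float = 0.2
    overlap_fractions: Optional[tuple[float, ...]] = None  # default: graded 0..1
    incidental_rate: float = 0.3  # chance a cavity also clips one non-planted edge


@dataclass
class SyntheticSpec:
    """Master spec: one seed, per-stage sub-specs, reproducible content hash."""

    seed: int = 7
    lesion: LesionSpec = field(default_factory=LesionSpec)
    connectome: ConnectomeSpec = field(default_factory=ConnectomeSpec)
    stim: StimSpec = field(default_factory=StimSpec)
    resection: ResectionSpec = field(default_factory=ResectionSpec)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("lesion", "connectome", "stim", "resection")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# lesion cohorts

def _ellipsoid_mask(shape, centre, semi_axes) -> np.ndarray:
    grids = np.indices(shape)
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi_axes))
    return d2 <= 1.0


def planted_region_mask(spec: LesionSpec) -> np.ndarray:
    mask = np.zeros(spec.grid_shape, dtype=bool)
    sl = tuple(slice(lo, hi) for lo, hi in spec.region_slices)
    mask[sl] = True
    return mask


def make_lesion_cohort(spec: LesionSpec, rng: np.random.Generator
                       ) -> tuple[LesionCohort, dict]:
    """Generate a lesion cohort with a planted deficit-critical region.

    Each subject gets one random ellipsoidal resection blob (centre uniform
    in the centre box, semi-axes uniform in the radius range). The latent
    behavioural change is

        delta_asym = effect_size * overlap + covariates + N(0, noise_sd)

    where overlap is the fraction of the planted region inside the blob.
    ``delta_asymmetry``/``delta_total`` columns carry the continuous latent
    scores used by the mapping; integer Bells records consistent with their
    rounded values populate the pre_/post_ columns.

    Returns (cohort, truth) with the planted mask and per-subject overlaps.
    """
    region = planted_region_mask(spec)
    if not region.any():
        raise ValueError("planted region is empty")
    if region.sum() and not region[tuple(slice(0, s) for s in spec.grid_shape)].sum() == region.sum():
        raise ValueError("planted region outside grid")
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    (lo, hi) = spec.centre_box
    subjects, masks = [], []
    overlaps = np.zeros(spec.n_subjects)
    records: list[BellsRecord] = []
    rows = []
    region_size = region.sum()
    region_centre = np.array([(a + b - 1) / 2.0 for a, b in spec.region_slices])
    for s in range(spec.n_subjects):
        sid = f"sub-{s:03d}"
        hit = rng.random() < spec.hit_probability
        if hit:
            centre = region_centre + rng.normal(0.0, spec.hit_jitter_vox, size=3)
        else:
            for _ in range(200):
                centre = rng.uniform(lo, hi)
                if np.linalg.norm(centre - region_centre) >= spec.miss_min_distance_vox:
                    break
        axes = rng.uniform(*spec.blob_radius_range_vox, size=3)
        blob = _ellipsoid_mask(spec.grid_shape, centre, axes)
        # eloquence-guided surgery treats the critical region as a unit
        blob = np.logical_or(blob, region) if hit else np.logical_and(blob, ~region)
        overlaps[s] = np.logical_and(blob, region).sum() / region_size
        subjects.append(sid)
        masks.append(VoxelImage(blob.astype(np.uint8), affine, "synthetic-2mm"))
        age = float(rng.uniform(20, 70))
        education = float(rng.uniform(8, 18))
        grade = int(rng.integers(1, 5))
        ca, ce, cg = spec.covariate_coefficients
        covar_part = ca * (age - 45.0) + ce * (education - 13.0) + cg * (grade - 2.5)
        delta_asym = (spec.effect_size * overlaps[s] + covar_part
                      + rng.normal(0.0, spec.noise_sd))
        bilateral = abs(rng.normal(spec.bilateral_mean, spec.bilateral_sd))
        delta_total = delta_asym + bilateral
        pre_l = min(int(rng.poisson(0.7)), 5)
        pre_r = min(int(rng.poisson(0.7)), 5)
        da = int(round(delta_asym))
        dr = max(0, int(round(bilateral / 2.0)))
        post_l = int(np.clip(pre_l + da + dr, 0, 18))
        post_r = int(np.clip(pre_r + dr, 0, 17))
        records.append(BellsRecord(sid, "pre", pre_l, pre_r))
        records.append(BellsRecord(sid, "post", post_l, post_r))
        rows.append({
            "subject_id": sid, "hemisphere": "right",
            "pre_total": pre_l + pre_r, "pre_asymmetry": pre_l - pre_r,
            "post_total": post_l + post_r, "post_asymmetry": post_l - post_r,
            "delta_total": delta_total, "delta_asymmetry": delta_asym,
            "age": age, "education": education, "grade": grade,
            "resection_volume_mm3": float(blob.sum()) * spec.voxel_size_mm ** 3,
        })
    behaviour = pd.DataFrame(rows).set_index("subject_id")
    cohort = LesionCohort(subjects, masks, behaviour)
    truth = {
        "region_mask": VoxelImage(region.astype(np.uint8), affine, "synthetic-2mm"),
        "overlaps": overlaps,
        "records": records,
    }
    return cohort, truth


def render_bells_sheet(record: BellsRecord, rng: np.random.Generator) -> pd.DataFrame:
    """Render one administration as a synthetic test sheet (one row per target).

    18 targets lie in the left half of the sheet, 17 in the right; the
    recorded omission counts select which targets went uncancelled.
    Recounting the sheet reproduces ``score_bells`` exactly.
    """
    n_left, n_right = 18, 17
    if record.omissions_left > n_left or record.omissions_right > n_right:
        raise ValueError("omissions exceed the per-half target counts of the layout")
    rows = []
    omit_l = set(rng.choice(n_left, size=record.omissions_left, replace=False).tolist())
    omit_r = set(rng.choice(n_right, size=record.omissions_right, replace=False).tolist())
    for i in range(n_left):
        rows.append({"target": i, "x": float(rng.uniform(0.0, 0.5)),
                     "y": float(rng.uniform(0, 1)), "side": "left", "omitted": i in omit_l})
    for i in range(n_right):
        rows.append({"target": n_left + i, "x": float(rng.uniform(0.5, 1.0)),
                     "y": float(rng.uniform(0, 1)), "side": "right", "omitted": i in omit_r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# connectome cohorts

def _node_positions(spec: ConnectomeSpec) -> np.ndarray:
    step = spec.lattice_spacing_mm
    per_axis = int(spec.world_size_mm // step)
    coords = [(i, j, k) for i in range(per_axis) for j in range(per_axis) for k in range(per_axis)]
    if len(coords) < spec.n_nodes:
        raise ValueError("lattice too small for requested node count")
    pos = np.asarray(coords[: spec.n_nodes], dtype=float) * step + step / 2.0
    return pos


def _base_topology(spec: ConnectomeSpec, rng: np.random.Generator) -> tuple[dict, list[int], dict]:
    """Shared edge-weight design: {(i, j): weight}, planted hub indices, top edges.

    The base graph is a circulant (each node linked to its base_degree/2
    nearest neighbours on a ring): vertex-transitive, so under the null no
    node is structurally more central than any other and hub signal can come
    only from the planted augmentation.
    """
    if spec.base_degree % 2:
        raise ValueError("base_degree must be even for the circulant base graph")
    g = nx.circulant_graph(spec.n_nodes, list(range(1, spec.base_degree // 2 + 1)))
    weights = {tuple(sorted(e)): spec.base_edge_weight for e in g.edges()}
    hubs = sorted(rng.choice(spec.n_nodes, size=spec.n_hubs, replace=False).tolist())
    top_edges: dict[tuple[int, int], float] = {}
    w_hub = spec.base_edge_weight * spec.hub_weight_multiplier
    for h in hubs:
        current = {j for (i, j) in weights if i == h} | {i for (i, j) in weights if j == h}
        # upgrade existing hub edges to hub weight
        for e in list(weights):
            if h in e:
                weights[e] = max(weights[e], w_hub)
        candidates = [j for j in range(spec.n_nodes)
                      if j != h and j not in current and j not in hubs]
        extra = rng.choice(candidates, size=min(spec.hub_extra_degree, len(candidates)),
                           replace=False)
        for j in extra:
            weights[tuple(sorted((h, int(j))))] = w_hub
        # dominant bundles live on the planted extra connections when present,
        # otherwise on existing neighbours (so a neutral multiplier is a true no-op)
        partners = [int(j) for j in extra] or sorted(current - set(hubs))
        chosen = rng.choice(np.asarray(partners, dtype=int),
                            size=min(spec.top_edges_per_hub, len(partners)), replace=False)
        for j in chosen:
            e = tuple(sorted((h, int(j))))
            weights[e] = weights[e] * spec.top_edge_multiplier
            if spec.top_edge_multiplier != 1.0:
                top_edges[e] = weights[e]
    return weights, hubs, top_edges


def make_connectome_cohort(spec: ConnectomeSpec, rng: np.random.Generator
                           ) -> tuple[list[StreamlineSet], NodeAtlas, dict]:
    """Streamline cohorts over a shared planted topology.

    Node centroids sit on a lattice; every edge is realised as a bundle of
    arced polylines (perpendicular offsets spread the bundle so a cavity can
    sever part of it). Per-subject randomness jitters streamline weights by
    the noise fraction and draws mu; the topology itself is shared, so with
    zero noise the FBC matrices are identical across subjects up to mu.

    Returns (streamline sets, atlas, truth) where truth holds planted hub
    *labels*, planted top-edge label pairs, and per-set streamline->edge
    assignments.
    """
    positions = _node_positions(spec)
    weights, hub_idx, top_edges = _base_topology(spec, rng)
    n_grid = int(spec.world_size_mm)
    labels = np.zeros((n_grid, n_grid, n_grid), dtype=np.int16)
    affine = np.eye(4)
    node_list = list(range(1, spec.n_nodes + 1))  # labels are 1-based
    for i, p in enumerate(positions):
        ijk = np.clip(np.floor(p).astype(int), 0, n_grid - 1)
        labels[tuple(ijk)] = i + 1
    atlas = NodeAtlas(VoxelImage(labels, affine, "synthetic-1mm"), node_list,
                      names={i + 1: f"node{i + 1:02d}" for i in range(spec.n_nodes)},
                      classes={i + 1: ("hub" if i in hub_idx else "cortical")
                               for i in range(spec.n_nodes)})
    edge_items = sorted(weights.items())
    sets: list[StreamlineSet] = []
    assignments: list[list[tuple[int, int]]] = []
    for s in range(spec.n_subjects):
        lines, wts, edge_of = [], [], []
        for (i, j), w in edge_items:
            a, b = positions[i], positions[j]
            direction = (b - a) / np.linalg.norm(b - a)
            # any perpendicular direction
            ref = np.array([0.0, 0.0, 1.0]) if abs(direction[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            perp = np.cross(direction, ref)
            perp /= np.linalg.norm(perp)
            k = spec.streamlines_per_edge
            for t in range(k):
                offset = (t - (k - 1) / 2.0) * spec.bundle_spread_mm
                jit_a = a + rng.normal(0, 0.25, size=3)
                jit_b = b + rng.normal(0, 0.25, size=3)
                mid = 0.5 * (jit_a + jit_b) + offset * perp
                q1 = 0.5 * (jit_a + mid)
                q3 = 0.5 * (mid + jit_b)
                lines.append(np.vstack([jit_a, q1, mid, q3, jit_b]))
                noise = rng.normal(0.0, spec.weight_noise_fraction)
                wts.append(max(w / k * (1.0 + noise), 1e-3))
                edge_of.append((i + 1, j + 1))
        mu = float(rng.uniform(*spec.mu_range))
        sets.append(StreamlineSet(lines, np.asarray(wts), mu, f"hcp-{s:03d}"))
        assignments.append(edge_of)
    truth = {
        "hubs": sorted(i + 1 for i in hub_idx),
        "top_edges": sorted((i + 1, j + 1) for (i, j) in top_edges),
        "edge_assignments": assignments,
        "positions": positions,
        "edge_weights": {(i + 1, j + 1): w for (i, j), w in weights.items()},
    }
    return sets, atlas, truth


# ---------------------------------------------------------------------------
# stimulation sites

def _make_trials(eloquent: bool, bias: float, spec: StimSpec,
                 rng: np.random.Generator) -> list[StimTrial]:
    n = spec.trials_per_site
    stimulated = np.zeros(n, dtype=bool)
    n_stim = max(3, int(round(spec.stimulated_fraction * n)))
    stimulated[rng.choice(n, size=min(n_stim, n), replace=False)] = True
    stim_order = np.flatnonzero(stimulated)
    if eloquent:
        # three error trials spaced >= 2 apart in the stimulated sequence
        picks = stim_order[[0, 2, 4]] if len(stim_order) >= 5 else stim_order[:3]
        error_trials = set(picks.tolist())
    else:
        k = int(rng.integers(0, 3))
        error_trials = set(stim_order[rng.choice(len(stim_order), size=min(k, len(stim_order)),
                                                 replace=False)].tolist())
    trials = []
    for t in range(n):
        left_t = int(rng.integers(1, 6))
        right_t = int(rng.integers(6, 11))
        omitted: set[int] = set()
        if t in error_trials:
            omitted = {left_t if rng.random() < bias else right_t}
        elif stimulated[t] and rng.random() < spec.p_omit_nontarget_trial:
            omitted = {left_t if rng.random() < bias else right_t}
        trials.append(StimTrial(t, (left_t, right_t), bool(stimulated[t]),
                                frozenset(omitted)))
    return trials


def make_stim_sites(spec: StimSpec, rng: np.random.Generator
                    ) -> tuple[list[StimSite], dict]:
    """Clustered stimulation sites with biased omission positions.

    Site coordinates follow a Gaussian mixture at the cluster centroids; each
    trial presents one left-half and one right-half target, and an omission
    falls on the left target with the cluster's bias probability. A
    controlled fraction of sites receives an eloquence-qualifying error
    pattern (three non-consecutive stimulated error trials).
    """
    sites: list[StimSite] = []
    truth_rows = []
    for name, centroid, bias in zip(spec.cluster_names, spec.cluster_centroids,
                                    spec.cluster_left_bias):
        for k in range(spec.sites_per_cluster):
            coord = rng.normal(centroid, spec.spread_mm)
            eloquent = bool(rng.random() < spec.eloquent_fraction)
            trials = _make_trials(eloquent, bias, spec, rng)
            site = StimSite(site_id=f"{name}-{k:03d}", world_coordinate=coord,
                            trials=trials, gyrus_label=name, hemisphere="right",
                            error_type="omission" if any(
                                t.has_omission for t in trials) else "none")
            sites.append(site)
            truth_rows.append({"site_id": site.site_id, "cluster": name,
                               "bias": bias, "eloquent_by_construction": eloquent,
                               "centroid": centroid})
    return sites, {"sites": pd.DataFrame(truth_rows),
                   "centroids": {n: np.asarray(c) for n, c in
                                 zip(spec.cluster_names, spec.cluster_centroids)}}


# ---------------------------------------------------------------------------
# resection scenarios

def make_resection_scenarios(spec: ResectionSpec, conn_spec: ConnectomeSpec,
                             rng: np.random.Generator
                             ) -> tuple[list[ResectionScenario], NodeAtlas, dict]:
    """Patients whose cavities sever planted consensus edges with graded overlap.

    A fresh streamline cohort of ``n_subjects`` patients is drawn on the
    shared planted topology (bundles of ``streamlines_per_edge`` lines so
    partial severance is expressible). Patient s's cavity marks the midpoint
    voxels of the first round(f_s * k) streamlines of each planted edge
    (f_s graded over [0, 1] unless overridden), occasionally clipping one
    non-planted edge as incidental damage. The deficit is

        delta_asym = effect_scale * mean planted-edge severed fraction + N(0, noise_sd).
    """
    conn = ConnectomeSpec(**{**asdict(conn_spec),
                             "n_subjects": spec.n_subjects,
                             "streamlines_per_edge": spec.streamlines_per_edge})
    sets, atlas, truth = make_connectome_cohort(conn, rng)
    top = truth["top_edges"]
    if len(top) < spec.n_planted_edges:
        raise ValueError("fewer planted top edges than requested planted resection edges")
    planted = top[: spec.n_planted_edges]
    fractions = (np.asarray(spec.overlap_fractions, dtype=float)
                 if spec.overlap_fractions is not None
                 else np.linspace(0.0, 1.0, spec.n_subjects))
    if len(fractions) != spec.n_subjects:
        raise ValueError("one overlap fraction per subject required")
    grid = atlas.label_volume
    scenarios = []
    all_edges = sorted(truth["edge_weights"])
    for s, (sset, f) in enumerate(zip(sets, fractions)):
        cavity = np.zeros(grid.shape, dtype=np.uint8)
        edge_of = truth["edge_assignments"][s]
        targets = {e: int(round(f * spec.streamlines_per_edge)) for e in planted}
        if rng.random() < spec.incidental_rate:
            extra = all_edges[int(rng.integers(len(all_edges)))]
            if extra not in targets:
                targets[extra] = int(rng.integers(0, spec.streamlines_per_edge // 2 + 1))
        severed_fraction = {}
        for e, n_cut in targets.items():
            idx = [i for i, ee in enumerate(edge_of) if tuple(sorted(ee)) == e]
            for i in idx[:n_cut]:
                mid = sset.streamlines[i][2]  # arc apex vertex
                ijk = np.clip(np.rint(grid.world_to_voxel(mid)[0]).astype(int),
                              0, np.asarray(grid.shape) - 1)
                cavity[tuple(ijk)] = 1
            if e in planted:
                severed_fraction[e] = n_cut / max(len(idx), 1)
        signal = float(np.mean([severed_fraction.get(e, 0.0) for e in planted]))
        delta = spec.effect_scale * signal + float(rng.normal(0.0, spec.noise_sd))
        scenarios.append(ResectionScenario(
            subject_id=f"pat-{s:02d}",
            preop_set=sset,
            cavity_mask=VoxelImage(cavity, grid.affine.copy(), grid.space_tag),
            behaviour_delta=delta,
        ))
    res_truth = {"planted_edges": planted, "top_edges": top,
                 "hubs": truth["hubs"], "fractions": fractions,
                 "edge_weights": truth["edge_weights"]}
    return scenarios, atlas, res_truth
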