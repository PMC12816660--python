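"""Fibre-bundle-capacity connectomes, consensus hubs, and track-density maps.

Edges are weighted by Fibre Bundle Capacity (FBC): mu times the summed
SIFT2 streamline weights joining two parcels, an estimate of the total
intra-axonal cross-sectional area (mm^2) of the connection. Graph analysis
runs on the unthresholded matrices.

Hub detection follows the composite z-score procedure: node strength,
degree and betweenness centrality are z-scored across nodes within each
subject, averaged into a composite score, and a node is a *consensus hub*
when its composite z exceeds 1.5 in at least half of the subjects. Each
hub's most important connections ("consensus top edges") are found the same
way by z-scoring the hub's nonzero FBC values within subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .images import VoxelImage
from .streamlines import StreamlineSet, traversed_voxels

log = logging.getLogger(__name__)

__all__ = [
    "NodeAtlas",
    "FbcMatrix",
    "HubReport",
    "TdiMap",
    "build_fbc",
    "node_metrics",
    "composite_hubs",
    "consensus_top_edges",
    "tdi",
]


@dataclass
class NodeAtlas:
    """Integer label volume with an ordered node list and display names."""

    label_volume: VoxelImage
    node_list: list[int]
    names: dict[int, str] = field(default_factory=dict)
    classes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_volume.data.astype(int))) - {0}
        unknown = present - set(self.node_list)
        if unknown:
            raise ValueError(f"labels in volume missing from node_list: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_list)

    def index_of(self) -> dict[int, int]:
        return {lab: i for i, lab in enumerate(self.node_list)}


@dataclass
class FbcMatrix:
    """Symmetric non-negative node-by-node FBC matrix (mm^2), zero diagonal."""

    values: np.ndarray
    node_list: list[int]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_list)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match node_list")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("FBC matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("FBC values must be non-negative")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal (self-loops) must be zero")

    def total(self) -> float:
        """Sum of FBC over unordered node pairs."""
        return float(self.values.sum() / 2.0)


@dataclass
class HubReport:
    metrics: pd.DataFrame          # long: subject, node, strength, degree, betweenness, z_*, composite_z
    consensus: pd.DataFrame        # node, consensus_fraction, median_composite_z, is_hub
    z_threshold: float
    consensus_threshold: float

    @property
    def hubs(self) -> list[int]:
        return self.consensus.loc[self.consensus["is_hub"], "node"].tolist()


@dataclass
class TdiMap:
    density: VoxelImage
    zmap: VoxelImage

    def core_mask(self, z_cut: float = 2.0) -> VoxelImage:
        return self.density.with_data((self.zmap.data > z_cut).astype(np.uint8))


def _nearest_label(point_mm: np.ndarray, atlas: NodeAtlas, radius_mm: float) -> int:
    """Label of the nearest labelled voxel within ``radius_mm`` of a point (0 = none)."""
    vol = atlas.label_volume
    data = vol.data.astype(int)
    centre = vol.world_to_voxel(point_mm)[0]
    ijk = np.rint(centre).astype(int)
    shape = np.asarray(vol.shape)
    if np.all((ijk >= 0) & (ijk < shape)) and data[tuple(ijk)] != 0:
        return int(data[tuple(ijk)])
    # search a small neighbourhood for the closest labelled voxel
    edge = np.linalg.norm(vol.affine[:3, :3], axis=0)
    r_vox = np.ceil(radius_mm / edge).astype(int)
    lo = np.maximum(ijk - r_vox, 0)
    hi = np.minimum(ijk + r_vox + 1, shape)
    if np.any(lo >= hi):
        return 0
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    cand = np.argwhere(sub != 0)
    if len(cand) == 0:
        return 0
    cand_world = vol.voxel_to_world(cand + lo)
    d = np.linalg.norm(cand_world - point_mm, axis=1)
    best = int(np.argmin(d))
    if d[best] > radius_mm:
        return 0
    return int(sub[tuple(cand[best])])


def build_fbc(sset: StreamlineSet, atlas: NodeAtlas, search_radius_mm: float = 2.0) -> FbcMatrix:
    """Assign streamline endpoints to nodes and sum mu-scaled weights per node pair.

    Each streamline contributes its weight to the unordered pair of nodes
    nearest its two endpoints (within ``search_radius_mm``); streamlines with
    an unassignable endpoint or with both endpoints in the same node are
    excluded and counted in the log.
    """
    n = atlas.n_nodes
    index = atlas.index_of()
    values = np.zeros((n, n))
    if len(sset) == 0:
        return FbcMatrix(values, list(atlas.node_list), sset.subject_id)
    unassigned = 0
    vol = atlas.label_volume
    data = vol.data.astype(int)
    shape = np.asarray(vol.shape)
    # vectorised fast path: the rounded endpoint voxel is itself labelled
    ends = np.vstack([[line[0], line[-1]] for line in sset.streamlines])
    vox = np.rint(vol.world_to_voxel(ends)).astype(int)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    labels = np.zeros(len(ends), dtype=int)
    vi = vox[inside]
    labels[inside] = data[vi[:, 0], vi[:, 1], vi[:, 2]]
    misses = np.flatnonzero(labels == 0)
    for k in misses:
        labels[k] = _nearest_label(ends[k], atlas, search_radius_mm)
    for s, w in enumerate(sset.weights):
        a, b = labels[2 * s], labels[2 * s + 1]
        if a == 0 or b == 0 or a == b:
            unassigned += 1
            continue
        i, j = index[a], index[b]
        values[i, j] += w
        values[j, i] += w
    if unassigned:
        log.info("build_fbc: %d/%d streamlines unassigned", unassigned, len(sset))
    return FbcMatrix(values * sset.mu, list(atlas.node_list), sset.subject_id)


def node_metrics(m: FbcMatrix) -> pd.DataFrame:
    """Strength, degree and normalized betweenness centrality per node.

    Strength is the row sum of FBC weights, degree the count of nonzero
    partners, and betweenness the fraction of all shortest paths through the
    node on the length graph with edge length = 1/weight (Brandes exact
    algorithm, normalization 2/((n-1)(n-2)) for undirected graphs). Paths
    are confined to connected components; disconnection is logged.
    """
    w = m.values
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)
    g = nx.Graph()
    g.add_nodes_from(range(len(m.node_list)))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)), weight="length")
    if nx.number_connected_components(g) > 1:
        log.info("node_metrics: graph has %d connected components",
                 nx.number_connected_components(g))
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return pd.DataFrame({
        "node": m.node_list,
        "strength": strength,
        "degree": degree.astype(float),
        "betweenness": [bc[i] for i in range(len(m.node_list))],
    })


def _zscore_across_nodes(x: np.ndarray) -> np.ndarray:
    """z-score with n-1 denominator; constant vectors map to zeros (flagged by caller)."""
    sd = np.std(x, ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def composite_hubs(cohort: Sequence[FbcMatrix], z_threshold: float = 1.5,
                   consensus: float = 0.5) -> HubReport:
    """Consensus hubs from the composite of z-scored strength/degree/betweenness.

    Within each subject the three metrics are z-scored across nodes (n-1
    denominator; a constant metric yields zeros with a warning) and averaged
    into a composite. A node is a consensus hub iff composite > z_threshold
    in at least ``consensus`` of the subjects (>= ceil(consensus * n_subjects)).
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    node_list = cohort[0].node_list
    for m in cohort[1:]:
        if m.node_list != node_list:
            raise ValueError("all subjects must share the node list")
    frames = []
    for m in cohort:
        met = node_metrics(m)
        for col in ("strength", "degree", "betweenness"):
            vals = met[col].to_numpy()
            if np.std(vals, ddof=1) == 0:
                log.warning("subject %s: %s constant across nodes; z set to 0",
                            m.subject_id, col)
            met[f"z_{col}"] = _zscore_across_nodes(vals)
        met["composite_z"] = met[["z_strength", "z_degree", "z_betweenness"]].mean(axis=1)
        met.insert(0, "subject", m.subject_id)
        frames.append(met)
    metrics = pd.concat(frames, ignore_index=True)
    n_subj = len(cohort)
    need = int(np.ceil(consensus * n_subj))
    grp = metrics.groupby("node", sort=False)
    consensus_df = pd.DataFrame({
        "node": node_list,
        "consensus_fraction": grp.apply(
            lambda d: float((d["composite_z"] > z_threshold).sum()) / n_subj,
            include_groups=False).reindex(node_list).to_numpy(),
        "median_composite_z": grp["composite_z"].median().reindex(node_list).to_numpy(),
    })
    consensus_df["is_hub"] = consensus_df["consensus_fraction"] * n_subj >= need
    return HubReport(metrics, consensus_df, z_threshold, consensus)


def consensus_top_edges(cohort: Sequence[FbcMatrix], hubs: Sequence[int],
                        z_threshold: float = 1.5, consensus: float = 0.5,
                        nonzero_only: bool = True,
                        classes: Optional[dict[int, str]] = None) -> pd.DataFrame:
    """Consensus top edges of each hub: z-scored FBC across the hub's connections.

    Per subject and hub, the hub's connection weights (nonzero by default,
    excluding the self-loop) are z-scored; an edge qualifies when z exceeds
    the threshold in at least ``consensus`` of the subjects. Hubs with fewer
    than 3 nonzero connections in a subject are skipped there with a warning.
    The table is deduplicated across hubs (an edge counted once, anchored at
    the hub that selected it first) and classified by the partner node class
    when a lookup is provided.
    """
    if len(hubs) == 0:
        raise ValueError("hubs must be nonempty")
    node_list = cohort[0].node_list
    index = {lab: i for i, lab in enumerate(node_list)}
    n_subj = len(cohort)
    need = int(np.ceil(consensus * n_subj))
    rows = []
    seen: set[frozenset] = set()
    for hub in hubs:
        hi = index[hub]
        exceed = np.zeros(len(node_list), dtype=int)
        counted = 0
        fbc_samples = {j: [] for j in range(len(node_list))}
        for m in cohort:
            w = m.values[hi].copy()
            w[hi] = 0.0
            sel = np.flatnonzero(w > 0) if nonzero_only else \
                np.array([j for j in range(len(w)) if j != hi])
            if len(sel) < 3:
                log.warning("hub %s in subject %s has <3 connections; skipped",
                            hub, m.subject_id)
                continue
            counted += 1
            z = _zscore_across_nodes(w[sel])
            for j, zj in zip(sel, z):
                if zj > z_threshold:
                    exceed[j] += 1
                fbc_samples[j].append(w[j])
        for j in np.flatnonzero(exceed >= need) if counted else []:
            key = frozenset((hub, node_list[j]))
            if key in seen:
                continue
            seen.add(key)
            partner = node_list[j]
            rows.append({
                "hub": hub, "partner": partner,
                "consensus_fraction": exceed[j] / n_subj,
                "median_fbc": float(np.median(fbc_samples[j])) if fbc_samples[j] else 0.0,
                "edge_class": (classes or {}).get(partner, ""),
            })
    return pd.DataFrame(rows, columns=["hub", "partner", "consensus_fraction",
                                       "median_fbc", "edge_class"])


def tdi(sset: StreamlineSet, grid: VoxelImage, mask: Optional[VoxelImage] = None,
        segment_mode: bool = True) -> TdiMap:
    """Track-density image: each streamline deposits weight*mu once per traversed voxel.

    The raw density is z-scored across in-mask voxels (the whole grid when no
    mask is given); population maps are voxelwise means of subject z-maps.
    Streamline portions outside the grid are clipped (logged by the traversal).
    """
    density = np.zeros(grid.shape)
    for line, w in zip(sset.streamlines, sset.weights):
        vox = traversed_voxels(line, grid, segment_mode=segment_mode)
        if len(vox):
            density[vox[:, 0], vox[:, 1], vox[:, 2]] += w * sset.mu
    sel = (mask.data > 0) if mask is not None else np.ones(grid.shape, dtype=bool)
    vals = density[sel]
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    z = np.zeros_like(density)
    if sd > 0:
        z[sel] = (vals - vals.mean()) / sd
    return TdiMap(grid.with_data(density), grid.with_data(z))


def population_tdi(zmaps: Sequence[VoxelImage]) -> VoxelImage:
    """Voxelwise mean of subject z-maps on a shared grid."""
    ref = zmaps[0]
    for m in zmaps[1:]:
        if not ref.same_grid(m):
            raise ValueError("z-maps must share the grid")
    return ref.with_data(np.mean([m.data for m in zmaps], axis=0))
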