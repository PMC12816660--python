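"""Weighted streamline sets: containers, TCK I/O, and voxel-traversal geometry.

A :class:`StreamlineSet` carries polylines in world (mm) coordinates with a
per-streamline non-negative weight (a SIFT2-style cross-sectional area
multiplier) and a subject-level proportionality coefficient ``mu`` that
converts summed weights into absolute mm^2 units.

Streamline files round-trip through the TCK format via
``nibabel.streamlines``; weights travel in a plain-text one-value-per-line
companion file and mu in a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile

from .images import VoxelImage

log = logging.getLogger(__name__)

__all__ = ["StreamlineSet", "filter_by_roi", "traversed_voxels", "streamline_voxel_hits"]


@dataclass
class StreamlineSet:
    """Polylines in world mm with per-streamline weights and subject mu."""

    streamlines: list[np.ndarray]
    weights: np.ndarray
    mu: float = 1.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.streamlines) != len(self.weights):
            raise ValueError("one weight per streamline required")
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError("each streamline must be an (npoints>=2, 3) array")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not self.mu > 0:
            raise ValueError("mu must be positive")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, keep: np.ndarray) -> "StreamlineSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return StreamlineSet([self.streamlines[i] for i in keep],
                             self.weights[keep], self.mu, self.subject_id)

    # -- I/O ---------------------------------------------------------------

    def save(self, tck_path) -> None:
        """Write TCK plus ``<stem>_weights.txt`` and ``<stem>_mu.json`` sidecars."""
        tck_path = Path(tck_path)
        tracto = Tractogram(self.streamlines, affine_to_rasmm=np.eye(4))
        TckFile(tracto).save(str(tck_path))
        stem = tck_path.with_suffix("")
        np.savetxt(f"{stem}_weights.txt", self.weights, fmt="%.10g")
        Path(f"{stem}_mu.json").write_text(
            json.dumps({"subject_id": self.subject_id, "mu": self.mu}))

    @classmethod
    def load(cls, tck_path) -> "StreamlineSet":
        tck_path = Path(tck_path)
        tck = nib.streamlines.load(str(tck_path))
        stem = tck_path.with_suffix("")
        weights = np.loadtxt(f"{stem}_weights.txt", ndmin=1)
        sidecar = json.loads(Path(f"{stem}_mu.json").read_text())
        return cls(list(tck.streamlines), weights, sidecar["mu"], sidecar.get("subject_id", ""))


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Densify a polyline so consecutive samples are at most ``step`` mm apart."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg))
        n = max(1, int(np.ceil(length / step)))
        ts = np.arange(1, n + 1) / n
        out.extend(a + t * seg for t in ts)
    return np.asarray(out)


def traversed_voxels(points: np.ndarray, image: VoxelImage, segment_mode: bool = True,
                     oversample: float = 4.0) -> np.ndarray:
    """Unique voxel indices (m, 3) visited by one streamline, in-grid only.

    With ``segment_mode`` each segment is densified to steps of
    (min voxel edge)/oversample before nearest-voxel assignment, so coarsely
    sampled polylines cannot skip voxels; otherwise only the stored vertices
    are tested (adequate for densely sampled tractograms).
    """
    if segment_mode:
        edge = np.abs(np.diag(image.affine)[:3])
        # handle rotated affines conservatively via column norms
        edge = np.linalg.norm(image.affine[:3, :3], axis=0)
        points = _resample_polyline(points, float(edge.min()) / oversample)
    vox = np.rint(image.world_to_voxel(points)).astype(int)
    shape = np.asarray(image.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    if not inside.all():
        log.debug("streamline clipped: %d/%d points outside grid", (~inside).sum(), len(vox))
    vox = vox[inside]
    if len(vox) == 0:
        return vox.reshape(0, 3)
    return np.unique(vox, axis=0)


def streamline_voxel_hits(sset: StreamlineSet, roi: VoxelImage,
                          segment_mode: bool = False) -> np.ndarray:
    """Boolean vector: does each streamline visit a nonzero voxel of ``roi``.

    The vertex test is fully vectorised over all streamlines; segment mode
    falls back to per-streamline densified traversal.
    """
    data = roi.data
    n = len(sset)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if segment_mode:
        hits = np.zeros(n, dtype=bool)
        for i, line in enumerate(sset.streamlines):
            vox = traversed_voxels(line, roi, segment_mode=True)
            if len(vox) and np.any(data[vox[:, 0], vox[:, 1], vox[:, 2]] > 0):
                hits[i] = True
        return hits
    lengths = np.array([len(s) for s in sset.streamlines])
    pts = np.vstack(sset.streamlines)
    vox = np.rint(roi.world_to_voxel(pts)).astype(int)
    shape = np.asarray(roi.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    in_roi = np.zeros(len(pts), dtype=bool)
    vi = vox[inside]
    in_roi[inside] = data[vi[:, 0], vi[:, 1], vi[:, 2]] > 0
    owner = np.repeat(np.arange(n), lengths)
    return np.bincount(owner, weights=in_roi, minlength=n) > 0


def filter_by_roi(sset: StreamlineSet, roi: VoxelImage, segment_mode: bool = False,
                  invert: bool = False) -> StreamlineSet:
    """Keep streamlines with at least one point inside the ROI (weights and mu preserved).

    Points are mapped through the inverse affine with nearest-voxel
    assignment; ``segment_mode`` additionally tests segment-voxel
    intersections for coarsely sampled polylines. ``invert`` keeps the
    complement instead (the exclusion-ROI use of resection cavities).
    """
    if not roi.is_binary():
        raise ValueError("ROI must be a binary mask")
    if roi.data.sum() == 0:
        warnings.warn("empty ROI: filter keeps nothing (or everything when inverted)",
                      stacklevel=2)
    hits = streamline_voxel_hits(sset, roi, segment_mode=segment_mode)
    return sset.subset(~hits if invert else hits)
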