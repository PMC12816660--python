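"""Intraoperative stimulation mapping: iVSAT scoring, site classification,
probability-density maps, and convergence overlaps.

The intraoperative visuospatial selective attention task (iVSAT) presents 10
consecutive letters containing exactly two 'H' targets; the patient reads
aloud the digit under each target. A missed target at position 1 is a
far-left error, at position 10 a far-right error, so the mean omitted
position is a lateralisation index. A stimulation site is *eloquent* when a
missed target occurred in at least three non-consecutive stimulated trials;
a site is *neglect-like* when all of its omissions fall in the left half of
the array (positions 1-5).

Site coordinates are summarised by an isotropic Gaussian kernel density
(PDE) evaluated on a voxel grid, normalised to its maximum and thresholded
at a configurable fraction to delineate the highest-probability region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .images import VoxelImage, overlap_fractions

__all__ = [
    "StimTrial",
    "StimSite",
    "PdeMap",
    "eloquence_rule",
    "lateralisation",
    "pde",
    "convergence_overlap",
    "hemifield_error_summary",
]

#: array positions 1-5 count as the left hemifield, 6-10 as the right
LEFT_POSITIONS = frozenset(range(1, 6))


@dataclass(frozen=True)
class StimTrial:
    """One iVSAT trial: 10 letters with exactly two 'H' targets."""

    trial_id: int
    target_positions: tuple[int, int]
    stimulated: bool
    omitted_positions: frozenset = frozenset()

    def __post_init__(self) -> None:
        targets = tuple(sorted(self.target_positions))
        object.__setattr__(self, "target_positions", targets)
        object.__setattr__(self, "omitted_positions", frozenset(self.omitted_positions))
        if len(set(targets)) != 2 or not all(1 <= t <= 10 for t in targets):
            raise ValueError("exactly 2 distinct target positions in 1..10 required")
        if not self.omitted_positions <= set(targets):
            raise ValueError("omitted positions must be a subset of target positions")

    @property
    def has_omission(self) -> bool:
        return len(self.omitted_positions) > 0


@dataclass
class StimSite:
    """A stimulation site with its trial log and derived classification."""

    site_id: str
    world_coordinate: np.ndarray
    trials: list[StimTrial] = field(default_factory=list)
    radius_mm: float = 5.0
    error_type: str = "none"       # {"omission", "eye_movement", "none"}
    hemisphere: str = ""
    gyrus_label: str = ""

    def __post_init__(self) -> None:
        self.world_coordinate = np.asarray(self.world_coordinate, dtype=float).reshape(3)

    def omitted_positions(self, stimulated_only: bool = True) -> list[int]:
        """All omission positions across trials, in trial order."""
        out: list[int] = []
        for t in self.trials:
            if stimulated_only and not t.stimulated:
                continue
            out.extend(sorted(t.omitted_positions))
        return out


def eloquence_rule(trials: Sequence[StimTrial], strict_nonconsecutive: bool = True) -> bool:
    """Positive interference: omissions in at least three non-consecutive stimulated trials.

    ``strict_nonconsecutive`` (default) requires that no two error trials be
    adjacent in the stimulated-trial sequence; the lenient alternative only
    rejects three-in-a-row runs. Fewer than 3 stimulated trials cannot
    qualify (warned).
    """
    stim_trials = [t for t in trials if t.stimulated]
    if len(stim_trials) < 3:
        warnings.warn("fewer than 3 stimulated trials: site cannot qualify", stacklevel=2)
        return False
    err_idx = [i for i, t in enumerate(stim_trials) if t.has_omission]
    if len(err_idx) < 3:
        return False
    gaps = np.diff(err_idx)
    if strict_nonconsecutive:
        return bool(np.all(gaps > 1))
    # lenient reading: not all qualifying errors in one consecutive run
    return not (len(err_idx) >= 3 and np.all(gaps == 1))


def lateralisation(site: StimSite, rule: str = "all") -> tuple[float, bool]:
    """(lateralisation index, neglect-like flag) for a site with >= 1 omission.

    The index is the mean omitted position across trials (1 = far left,
    10 = far right). ``rule="all"`` flags neglect-like only when every
    omission lies in positions 1-5; ``rule="majority"`` requires more than
    half.
    """
    positions = site.omitted_positions(stimulated_only=True)
    if not positions:
        raise ValueError(f"site {site.site_id} has no omissions: index undefined")
    index = float(np.mean(positions))
    left = sum(p in LEFT_POSITIONS for p in positions)
    if rule == "all":
        neglect_like = left == len(positions)
    elif rule == "majority":
        neglect_like = left > len(positions) / 2
    else:
        raise ValueError("rule must be 'all' or 'majority'")
    return index, neglect_like


@dataclass
class PdeMap:
    """Kernel density of site coordinates with a normalised + thresholded view."""

    density: VoxelImage                # integrates to ~1 over the grid
    bandwidth_mm: float
    n_sites: int

    @property
    def normalized(self) -> VoxelImage:
        peak = self.density.data.max()
        if peak <= 0:
            return self.density.with_data(np.zeros_like(self.density.data))
        return self.density.with_data(self.density.data / peak)

    def threshold_mask(self, fraction: float = 0.5) -> VoxelImage:
        """Voxels with normalised density strictly above ``fraction`` of the peak."""
        if not (0 <= fraction < 1):
            raise ValueError("fraction must be in [0, 1)")
        return self.density.with_data(
            (self.normalized.data > fraction).astype(np.uint8))


def pde(coordinates: np.ndarray, grid: VoxelImage, bandwidth_mm: float = 5.0) -> PdeMap:
    """Isotropic Gaussian kernel density of site coordinates on a voxel grid.

    density(x) = (1/n) * sum_i N(x; c_i, sigma^2 I) with sigma = bandwidth_mm,
    evaluated at voxel centres; the discrete sum times the voxel volume
    approximates 1 on a grid extending several bandwidths beyond the sites.
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 sites for a density estimate")
    if coords.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3) world mm")
    if not bandwidth_mm > 0:
        raise ValueError("bandwidth must be positive")
    shape = grid.shape
    ijk = np.indices(shape).reshape(3, -1).T
    centres = grid.voxel_to_world(ijk)
    norm = (2.0 * math.pi) ** 1.5 * bandwidth_mm ** 3
    inv_two_s2 = 1.0 / (2.0 * bandwidth_mm ** 2)
    dens = np.zeros(len(centres))
    for c in coords:                      # loop over sites: memory-light
        d2 = ((centres - c) ** 2).sum(axis=1)
        dens += np.exp(-d2 * inv_two_s2)
    dens /= len(coords) * norm
    return PdeMap(grid.with_data(dens.reshape(shape)), bandwidth_mm, len(coords))


def convergence_overlap(mask_a: VoxelImage, mask_b: VoxelImage) -> dict[str, float]:
    """Dice and directed overlap fractions between two masks on a shared grid."""
    if not mask_a.same_grid(mask_b):
        raise ValueError("masks are on different grids")
    if mask_a.data.sum() == 0 or mask_b.data.sum() == 0:
        warnings.warn("empty mask in overlap: Dice defined as 0", stacklevel=2)
    dice, fa, fb = overlap_fractions(mask_a.data, mask_b.data)
    return {"dice": dice, "fraction_a_in_b": fa, "fraction_b_in_a": fb}


def hemifield_error_summary(sites: Sequence[StimSite],
                            group_by: str = "gyrus_label") -> pd.DataFrame:
    """Left/right hemifield percentages of omissions per site group, plus a totals row.

    An omission is 'left' at positions 1-5 and 'right' at 6-10. Groups with
    no omissions are excluded.
    """
    counts: dict[str, list[int]] = {}
    for s in sites:
        key = getattr(s, group_by)
        left_right = counts.setdefault(key, [0, 0])
        for p in s.omitted_positions(stimulated_only=True):
            left_right[0 if p in LEFT_POSITIONS else 1] += 1
    rows = []
    tot_l = tot_r = 0
    for key, (l, r) in sorted(counts.items()):
        n = l + r
        if n == 0:
            continue
        tot_l += l
        tot_r += r
        rows.append({"group": key, "n_omissions": n,
                     "left_percent": 100.0 * l / n, "right_percent": 100.0 * r / n})
    if tot_l + tot_r:
        n = tot_l + tot_r
        rows.append({"group": "total", "n_omissions": n,
                     "left_percent": 100.0 * tot_l / n, "right_percent": 100.0 * tot_r / n})
    return pd.DataFrame(rows, columns=["group", "n_omissions", "left_percent", "right_percent"])
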