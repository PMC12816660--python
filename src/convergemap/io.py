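"""On-disk formats: NIfTI volumes, TCK streamline directories, CSV tables.

Conventions:

* masks and maps — NIfTI-1 (binary masks uint8, maps float32);
* behaviour tables — CSV with header (subject_id, hemisphere, pre_left,
  pre_right, post_left, post_right, age, education, grade,
  resection_volume_mm3), missing values as empty fields;
* streamlines — TCK plus ``<stem>_weights.txt`` / ``<stem>_mu.json``;
* atlas — NIfTI label volume plus node CSV (label, name, class);
* stimulation sites — sites CSV (site_id, x, y, z, hemisphere, gyrus_label,
  error_type) and long trials CSV (site_id, trial_idx, stimulated,
  target_positions, omitted_positions as semicolon lists).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import NodeAtlas
from .images import VoxelImage
from .stim import StimSite, StimTrial
from .streamlines import StreamlineSet
from .svrlsm import LesionCohort

__all__ = [
    "save_lesion_cohort", "load_lesion_cohort",
    "save_behaviour_csv", "load_behaviour_csv",
    "save_streamline_dir", "load_streamline_dir",
    "save_atlas", "load_atlas",
    "save_stim_csvs", "load_stim_csvs",
]

BEHAVIOUR_COLUMNS = ["subject_id", "hemisphere", "pre_left", "pre_right",
                     "post_left", "post_right", "age", "education", "grade",
                     "resection_volume_mm3"]


def save_behaviour_csv(table: pd.DataFrame, path) -> None:
    out = table.reset_index()
    cols = [c for c in BEHAVIOUR_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, index=False)


def load_behaviour_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path).set_index("subject_id")
    for a, b, out in (("post_left", "post_right", "post"), ("pre_left", "pre_right", "pre")):
        if a in table and b in table:
            table[f"{out}_total"] = table[a] + table[b]
            table[f"{out}_asymmetry"] = table[a] - table[b]
    if "delta_total" not in table and "pre_total" in table:
        table["delta_total"] = table["post_total"] - table["pre_total"]
        table["delta_asymmetry"] = table["post_asymmetry"] - table["pre_asymmetry"]
    return table


def save_lesion_cohort(cohort: LesionCohort, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, mask in zip(cohort.subjects, cohort.masks):
        mask.save(out_dir / f"{sid}_mask.nii")
    save_behaviour_csv(cohort.behaviour, out_dir / "behaviour.csv")


def load_lesion_cohort(lesions_dir, behaviour_csv=None) -> LesionCohort:
    lesions_dir = Path(lesions_dir)
    paths = sorted(lesions_dir.glob("*_mask.nii*"))
    if not paths:
        raise FileNotFoundError(f"no *_mask.nii files under {lesions_dir}")
    subjects = [p.name.split("_mask")[0] for p in paths]
    masks = [VoxelImage.load(p) for p in paths]
    behaviour = load_behaviour_csv(behaviour_csv or lesions_dir / "behaviour.csv")
    return LesionCohort(subjects, masks, behaviour)


def save_streamline_dir(sets: Sequence[StreamlineSet], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in sets:
        s.save(out_dir / f"{s.subject_id or 'subject'}.tck")


def load_streamline_dir(tracks_dir) -> list[StreamlineSet]:
    paths = sorted(Path(tracks_dir).glob("*.tck"))
    if not paths:
        raise FileNotFoundError(f"no .tck files under {tracks_dir}")
    return [StreamlineSet.load(p) for p in paths]


def save_atlas(atlas: NodeAtlas, nii_path, csv_path) -> None:
    atlas.label_volume.save(nii_path)
    pd.DataFrame({
        "label": atlas.node_list,
        "name": [atlas.names.get(l, str(l)) for l in atlas.node_list],
        "class": [atlas.classes.get(l, "") for l in atlas.node_list],
    }).to_csv(csv_path, index=False)


def load_atlas(nii_path, csv_path) -> NodeAtlas:
    vol = VoxelImage.load(nii_path)
    nodes = pd.read_csv(csv_path)
    return NodeAtlas(vol, nodes["label"].astype(int).tolist(),
                     names=dict(zip(nodes["label"], nodes["name"].astype(str))),
                     classes=dict(zip(nodes["label"], nodes["class"].astype(str))))


def save_stim_csvs(sites: Sequence[StimSite], sites_csv, trials_csv) -> None:
    srows, trows = [], []
    for s in sites:
        srows.append({"site_id": s.site_id, "x": s.world_coordinate[0],
                      "y": s.world_coordinate[1], "z": s.world_coordinate[2],
                      "hemisphere": s.hemisphere, "gyrus_label": s.gyrus_label,
                      "error_type": s.error_type})
        for t in s.trials:
            trows.append({"site_id": s.site_id, "trial_idx": t.trial_id,
                          "stimulated": int(t.stimulated),
                          "target_positions": ";".join(map(str, t.target_positions)),
                          "omitted_positions": ";".join(map(str, sorted(t.omitted_positions)))})
    pd.DataFrame(srows).to_csv(sites_csv, index=False)
    pd.DataFrame(trows).to_csv(trials_csv, index=False)


def load_stim_csvs(sites_csv, trials_csv) -> list[StimSite]:
    sites_df = pd.read_csv(sites_csv)
    trials_df = pd.read_csv(trials_csv, keep_default_na=False)
    trials_by_site: dict[str, list[StimTrial]] = {}
    for r in trials_df.itertuples():
        targets = tuple(int(x) for x in str(r.target_positions).split(";"))
        omitted = frozenset(int(x) for x in str(r.omitted_positions).split(";") if x)
        trials_by_site.setdefault(r.site_id, []).append(
            StimTrial(int(r.trial_idx), targets, bool(int(r.stimulated)), omitted))
    sites = []
    for r in sites_df.itertuples():
        sites.append(StimSite(site_id=r.site_id,
                              world_coordinate=np.array([r.x, r.y, r.z]),
                              trials=sorted(trials_by_site.get(r.site_id, []),
                                            key=lambda t: t.trial_id),
                              hemisphere=str(r.hemisphere),
                              gyrus_label=str(r.gyrus_label),
                              error_type=str(r.error_type)))
    return sites
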