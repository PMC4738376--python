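"""Atlas-based labelling of significant clusters.

Mirrors the usual VLSM reporting step: for each significant cluster, the
percentage of its voxels falling in each structure of one or more integer
label atlases (grey-matter parcellation, white-matter tract atlas) is
tabulated, alongside the cluster's overlap with the canonical tract.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tract import TractMap
from .volumes import VolumeGrid, read_volume


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume (0 = background) plus a label_id -> name table."""

    labels: VolumeGrid
    names: dict[int, str]
    atlas_name: str = "atlas"

    def __post_init__(self):
        present = set(np.unique(self.labels.data).tolist()) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"atlas labels without a name entry: {sorted(unnamed)}")


def read_atlas(volume_path: str | Path, names_path: str | Path,
               atlas_name: str = "atlas") -> LabelAtlas:
    """Load an integer atlas volume and its TSV name table (label_id, name)."""
    grid = read_volume(volume_path)
    grid = grid.with_data(np.rint(grid.data).astype(np.int32))
    tbl = pd.read_csv(names_path, sep="\t")
    names = {int(r["label_id"]): str(r["name"]) for _, r in tbl.iterrows()}
    return LabelAtlas(labels=grid, names=names, atlas_name=atlas_name)


def write_atlas(atlas: LabelAtlas, volume_path: str | Path, names_path: str | Path) -> None:
    from .volumes import write_volume
    write_volume(atlas.labels, volume_path, dtype=np.int16)
    pd.DataFrame(
        [{"label_id": k, "name": v} for k, v in sorted(atlas.names.items())]
    ).to_csv(names_path, sep="\t", index=False)


@dataclass
class OverlapReport:
    """Percent of a cluster's voxels per atlas structure.

    ``rows`` hold full-precision percents sorted descending; structures
    below the floor are dropped after the unlabelled remainder is computed,
    so the printed rows plus ``unlabelled_percent`` account for 100% of the
    cluster within rounding.
    """

    atlas_name: str
    rows: pd.DataFrame  # columns: structure, percent, voxels
    unlabelled_percent: float
    cluster_voxels: int

    def to_markdown(self) -> str:
        parts = [f"{r.structure} ({round(r.percent)})" for r in self.rows.itertuples()]
        return f"{self.atlas_name}: " + " ".join(parts) if parts else f"{self.atlas_name}: —"


def label_overlap(cluster_voxels: np.ndarray, atlas: LabelAtlas,
                  floor_percent: float = 1.0) -> OverlapReport:
    """Tabulate the cluster's percent overlap with each atlas structure.

    ``cluster_voxels`` is an (n, 3) integer array of voxel indices on the
    atlas grid.  Structures covering < ``floor_percent`` of the cluster are
    omitted from the rows (but still counted as labelled).
    """
    vox = np.atleast_2d(np.asarray(cluster_voxels, dtype=int))
    if vox.shape[0] == 0:
        raise ValueError("empty cluster")
    shape = atlas.labels.shape
    if (vox < 0).any() or (vox >= np.array(shape)).any():
        raise ValueError("cluster voxels fall outside the atlas grid")
    ids = atlas.labels.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    n = len(ids)
    uniq, counts = np.unique(ids, return_counts=True)
    rows = []
    unlabelled = 0.0
    for label_id, count in zip(uniq, counts):
        pct = 100.0 * count / n
        if label_id == 0:
            unlabelled = pct
            continue
        rows.append({"structure": atlas.names[int(label_id)],
                     "percent": pct, "voxels": int(count)})
    df = pd.DataFrame(rows, columns=["structure", "percent", "voxels"])
    df = df.sort_values("percent", ascending=False, kind="stable").reset_index(drop=True)
    df = df[df["percent"] >= floor_percent].reset_index(drop=True)
    return OverlapReport(
        atlas_name=atlas.atlas_name, rows=df,
        unlabelled_percent=unlabelled, cluster_voxels=n,
    )


def tract_intersection(cluster_voxels: np.ndarray, tract: TractMap) -> dict:
    """Cluster-tract overlap: voxel count and percent of the cluster.

    A zero count supports the kind of negative statement the method is
    often used for — that a significant cluster lies off the tract.
    """
    vox = np.atleast_2d(np.asarray(cluster_voxels, dtype=int))
    if vox.shape[0] == 0:
        raise ValueError("empty cluster")
    hits = tract.mask.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(bool)
    count = int(hits.sum())
    return {
        "voxels": count,
        "percent": 100.0 * count / len(vox),
        "overlaps_tract": count > 0,
    }
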