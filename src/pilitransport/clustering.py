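"""Clustering of candidate assembly models.

Three clustering views are used to pick the converged docking basin:
k-means and DBSCAN on the one-dimensional rotation angle, and greedy
energy-ordered leader clustering on structural similarity (RMSD, default
cutoff 1.75 Å). Angles are treated as plain scalars: the observed basins
(tens to ~163 degrees) never straddle the 0/360 wrap; a circular-metric
flag exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans

from .structure import kabsch_rmsd

__all__ = [
    "ModelRecord",
    "kmeans_angles",
    "dbscan_angles",
    "leader_cluster_rmsd",
    "read_model_table",
    "write_cluster_report",
    "DEFAULT_KMEANS_SEED",
]

#: Fixed default seed for k-means restarts (recorded in pipeline logs).
DEFAULT_KMEANS_SEED = 1234


@dataclass
class ModelRecord:
    """One docking decoy: id, rigid-body rotation angle, score, coordinates."""

    model_id: str
    rotation_angle: float  # degrees in [0, 360)
    energy_score: float = 0.0
    coords: np.ndarray | None = None  # (n_atoms, 3), for RMSD clustering

    def __post_init__(self) -> None:
        if not 0 <= self.rotation_angle < 360:
            raise ValueError(
                f"rotation_angle must lie in [0, 360), got {self.rotation_angle}"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)


def _to_column(angles: Sequence[float], circular: bool) -> np.ndarray:
    arr = np.asarray(angles, dtype=float)
    if arr.size == 0:
        raise ValueError("no angles supplied")
    if circular:
        rad = np.deg2rad(arr)
        return np.column_stack([np.cos(rad), np.sin(rad)])
    return arr.reshape(-1, 1)


def kmeans_angles(
    angles: Sequence[float],
    k: int,
    seed: int = DEFAULT_KMEANS_SEED,
    restarts: int = 10,
    circular: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means on 1-D rotation angles; best of ``restarts`` seeded runs.

    Returns ``(labels, centers)``; deterministic given ``seed``. Requires
    ``k`` not to exceed the number of distinct angle values.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    X = _to_column(angles, circular)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct angle value(s)")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    centers = km.cluster_centers_
    if circular:
        centers = np.rad2deg(np.arctan2(centers[:, 1], centers[:, 0])) % 360
    else:
        centers = centers.ravel()
    return labels, centers


def dbscan_angles(
    angles: Sequence[float],
    epsilon: float = 3.0,
    min_pts: int = 10,
    circular: bool = False,
) -> np.ndarray:
    """Density-based clustering of rotation angles; label -1 marks noise.

    A core point has at least ``min_pts`` neighbors within ``epsilon``
    (itself included), matching the classic DBSCAN definition.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if min_pts < 1:
        raise ValueError(f"min_pts must be >= 1, got {min_pts}")
    X = _to_column(angles, circular)
    return DBSCAN(eps=epsilon, min_samples=min_pts).fit_predict(X)


def leader_cluster_rmsd(
    models: Sequence[ModelRecord], cutoff: float = 1.75
) -> list[list[ModelRecord]]:
    """Greedy energy-ordered leader clustering on pairwise RMSD.

    Models are visited by ascending energy score; each joins the first
    existing cluster whose leader (founding model) lies within ``cutoff``
    RMSD after optimal superposition, otherwise it founds a new cluster.
    Clusters are returned sorted by member count, descending (ties by
    leader order). All models must share the same atom count.
    """
    if not models:
        return []
    counts = {m.coords.shape[0] if m.coords is not None else None for m in models}
    if None in counts:
        raise ValueError("all models need coordinates for RMSD clustering")
    if len(counts) != 1:
        raise ValueError(f"model atom counts differ: {sorted(counts)}")
    ordered = sorted(enumerate(models), key=lambda im: (im[1].energy_score, im[0]))
    clusters: list[list[ModelRecord]] = []
    for _, model in ordered:
        for cluster in clusters:
            rmsd, _, _ = kabsch_rmsd(cluster[0].coords, model.coords)
            if rmsd <= cutoff:
                cluster.append(model)
                break
        else:
            clusters.append([model])
    return sorted(clusters, key=len, reverse=True)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_model_table(path: str | Path) -> list[ModelRecord]:
    """Read a model table TSV with columns id, rotation_angle, energy_score[, pdb_path]."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "rotation_angle", "energy_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"model table missing column(s): {sorted(missing)}")
    return [
        ModelRecord(str(row["id"]), float(row["rotation_angle"]), float(row["energy_score"]))
        for _, row in df.iterrows()
    ]


def write_cluster_report(
    models: Sequence[ModelRecord], labels: Sequence[int], path: str | Path
) -> None:
    """Write per-model cluster assignments as TSV."""
    pd.DataFrame(
        {
            "id": [m.model_id for m in models],
            "rotation_angle": [m.rotation_angle for m in models],
            "energy_score": [m.energy_score for m in models],
            "cluster": list(labels),
        }
    ).to_csv(path, sep="\t", index=False)
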