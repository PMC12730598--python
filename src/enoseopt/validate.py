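"""Clustering-based validation of the optimized sensor array.

Second analysis path: the fitted per-sensor global variables
(a, b, c, d, e) are standardized and projected onto their top-2 principal
directions, clustered with K-means, checked for label consistency with a
leave-one-out nearest-neighbour rule, and condensed into sensor
equivalence groups — sets of sensors whose fitted response curves are so
alike that they are mutually replaceable.  This path never changes the
selected subset; it only annotates and confirms it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .panel import default_panel

__all__ = [
    "SensorEmbedding",
    "EquivalenceGroups",
    "embed_2d",
    "kmeans_cluster",
    "knn_consistency",
    "equivalence_groups",
]

_GV_COLUMNS = ("a", "b", "c", "d", "e")


@dataclass
class SensorEmbedding:
    """2-D principal-plane coordinates of sensors for one temperature."""

    temperature: float
    sensors: tuple
    coords: np.ndarray              # (n_sensors, 2)
    explained_variance_ratio: tuple
    rank_deficient: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sensor": self.sensors,
            "temperature_C": self.temperature,
            "dim1": self.coords[:, 0],
            "dim2": self.coords[:, 1],
        })


def embed_2d(gv_table: pd.DataFrame) -> dict[float, SensorEmbedding]:
    """Project standardized global-variable vectors onto their principal plane.

    One embedding per temperature condition: each sensor's (a, b, c, d, e)
    vector is standardized across sensors and projected onto the top-2
    variance directions.  Sign convention: within each component, the
    loading of largest magnitude is positive.  Rank-deficient input (all
    variance in one direction) zero-pads the second axis and is flagged.
    """
    out = {}
    for temp, grp in gv_table.groupby("temperature_C"):
        grp = grp.sort_values("sensor", key=lambda s: s.str[1:].astype(int))
        if len(grp) < 2:
            raise ValueError("embedding needs at least two sensors")
        V = StandardScaler().fit_transform(grp[list(_GV_COLUMNS)].to_numpy(float))
        n_comp = min(2, np.linalg.matrix_rank(V - V.mean(0)))
        n_comp = max(n_comp, 1)
        pca = PCA(n_components=n_comp)
        coords = pca.fit_transform(V)
        # deterministic sign: largest-magnitude loading positive
        for j in range(coords.shape[1]):
            load = pca.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                coords[:, j] *= -1
        rank_deficient = coords.shape[1] < 2
        if rank_deficient:
            coords = np.column_stack([coords, np.zeros(len(grp))])
        evr = tuple(float(v) for v in pca.explained_variance_ratio_)
        if len(evr) < 2:
            evr = (*evr, 0.0)
        out[float(temp)] = SensorEmbedding(
            temperature=float(temp),
            sensors=tuple(grp["sensor"]),
            coords=coords,
            explained_variance_ratio=evr,
            rank_deficient=rank_deficient,
        )
    return out


def kmeans_cluster(embedding: SensorEmbedding, k: int = 5, seed: int = 0) -> np.ndarray:
    """K-means (k-means++ seeding, 10 restarts, best inertia) on the plane."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(embedding.sensors):
        raise ValueError("k cannot exceed the number of sensors")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(embedding.coords)


def knn_consistency(coords: np.ndarray, labels, k_nn: int = 3) -> float:
    """Leave-one-out nearest-neighbour label agreement rate in [0, 1].

    Each point's label is compared with the majority label of its k_nn
    nearest other points (ties broken toward the smaller label).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two points")
    if not k_nn < n:
        raise ValueError("k_nn must be smaller than the number of points")
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    agree = 0
    for i in range(n):
        nbrs = np.argsort(d2[i], kind="stable")[:k_nn]
        vals, counts = np.unique(labels[nbrs], return_counts=True)
        majority = vals[np.argmax(counts)]
        agree += int(majority == labels[i])
    return agree / n


@dataclass
class EquivalenceGroups:
    """Disjoint groups of mutually replaceable sensors for one temperature."""

    temperature: float
    groups: list = field(default_factory=list)      # list of tuple of sensor ids
    cohesion: list = field(default_factory=list)    # per-group mean centroid distance
    shared_classes: list = field(default_factory=list)

    def group_of(self, sensor: str):
        for g in self.groups:
            if sensor in g:
                return g
        return None

    def to_dict(self) -> dict:
        return {
            "temperature_C": self.temperature,
            "groups": [list(g) for g in self.groups],
            "cohesion": [float(c) for c in self.cohesion],
            "shared_compound_classes": [sorted(s) for s in self.shared_classes],
        }


def equivalence_groups(
    embedding: SensorEmbedding,
    cluster_labels,
    cohesion_threshold: float = 0.3,
    panel=None,
) -> EquivalenceGroups:
    """Derive replaceable-sensor groups from a clustering.

    Sensors sharing a cluster whose intra-cluster dispersion (mean
    distance to the cluster centroid) is below the threshold form an
    equivalence group; everything else stays a singleton.  The groups
    partition the sensor set.  Each multi-sensor group is annotated with
    the compound classes all its members share.
    """
    labels = np.asarray(cluster_labels)
    panel = default_panel() if panel is None else panel
    classes = {p.sensor_id: set(p.target_classes) for p in panel}

    groups, cohesion, shared = [], [], []
    singles = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        members = tuple(embedding.sensors[i] for i in idx)
        pts = embedding.coords[idx]
        disp = float(np.mean(np.linalg.norm(pts - pts.mean(0), axis=1)))
        if len(members) > 1 and disp < cohesion_threshold:
            groups.append(members)
            cohesion.append(disp)
            common = set.intersection(*(classes.get(m, set()) for m in members))
            shared.append(common)
        else:
            singles.extend(members)
    for m in sorted(singles, key=lambda s: int(s[1:])):
        groups.append((m,))
        cohesion.append(0.0)
        shared.append(classes.get(m, set()))
    return EquivalenceGroups(
        temperature=embedding.temperature,
        groups=groups,
        cohesion=cohesion,
        shared_classes=shared,
    )
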