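"""Landscape typing: partition steady pixels into landscape types.

Within each ecological land-cover class, the steady pixels are split into
landscape types by a centroid-based cluster analysis (k-means) on
standardized vegetation features — multi-year mean NDVI and GPP by default.
The canonical configuration reproduces the four analysed landscapes: forest
(k=1), wetland (k=1) and grassland split into sparse vs. high-coverage
(k=2, ranked by NDVI).

Cluster ids are relabelled so that within a class the cluster mean of the
first feature (NDVI by convention) increases with the id, which makes the
type map invariant to the k-means initialization permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .persistence import NODATA, SteadyMask
from .raster import RasterGrid, RasterStack

__all__ = ["LandscapeTypeMap", "type_landscapes"]


@dataclass
class _ClassClustering:
    """Standardization + centroids for one land-cover class, kept so that
    unsteady pixels can later be assigned to their nearest landscape type."""

    class_code: int
    feature_mean: np.ndarray
    feature_std: np.ndarray
    centroids: np.ndarray  # (k, n_features), standardized space
    landscape_ids: np.ndarray  # (k,), global ids ordered like centroids

    def assign(self, features: np.ndarray) -> np.ndarray:
        """Nearest-centroid landscape id for raw feature rows (n, n_features)."""
        z = (features - self.feature_mean) / self.feature_std
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return self.landscape_ids[np.argmin(d2, axis=1)]


@dataclass
class LandscapeTypeMap:
    """Categorical map of landscape ids (contiguous, starting at 1)."""

    values: RasterGrid
    names: dict[int, str]
    features_used: list[str] = field(default_factory=list)
    class_of: dict[int, int] = field(default_factory=dict)  # landscape id -> land-cover code
    clusterings: dict[int, _ClassClustering] = field(default_factory=dict)

    def landscape_ids(self) -> list[int]:
        return sorted(self.names)


def _cluster_class(
    feats: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score features, run seeded k-means, return (labels, mean, std, centroids)."""
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    if np.any(std == 0):
        if k > 1:
            raise ValueError("all-constant feature with k > 1: clusters are undefined")
        std = np.where(std == 0, 1.0, std)
    std = np.where(std == 0, 1.0, std)
    z = (feats - mean) / std
    if k == 1:
        return np.zeros(len(feats), dtype=int), mean, std, z.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(z)
    return labels, mean, std, km.cluster_centers_


def type_landscapes(
    steady_masks: list[SteadyMask],
    veg_features: RasterStack,
    k_per_class: dict[int, int],
    seed: int,
    names: dict[int, list[str]] | None = None,
) -> LandscapeTypeMap:
    """Partition steady pixels of each class into landscape types.

    Parameters
    ----------
    steady_masks
        One persistence mask per ecological land-cover class; their label-1
        pixel sets must not overlap.
    veg_features
        Aligned stack of clustering features (first layer should be the
        multi-year mean NDVI; it drives the id ranking).
    k_per_class
        Number of landscape types per land-cover code (k >= 1).
    seed
        Seed for the k-means restarts; the output is deterministic in it.
    names
        Optional map class code -> list of k names, low-to-high NDVI rank.
        Defaults to the class code with a rank suffix when k > 1.
    """
    if not steady_masks:
        raise ValueError("no steady masks supplied")
    ref = steady_masks[0].values
    if not veg_features.layers or not veg_features.layers[0].is_aligned_with(ref):
        raise ValueError("veg_features must be aligned with the masks")

    claimed = np.zeros(ref.shape, dtype=bool)
    feat_cube = veg_features.as_array()  # (n_feat, rows, cols)

    out = np.full(ref.shape, NODATA, dtype=np.int16)
    name_map: dict[int, str] = {}
    class_of: dict[int, int] = {}
    clusterings: dict[int, _ClassClustering] = {}
    next_id = 1

    for mask in steady_masks:
        code = mask.landscape_code
        k = int(k_per_class.get(code, 1))
        if k < 1:
            raise ValueError(f"k must be >= 1 (class {code})")
        sel = mask.values.values == 1
        if (sel & claimed).any():
            raise ValueError("steady masks overlap in label-1 pixels")
        claimed |= sel
        n_pix = int(sel.sum())
        if n_pix == 0:
            continue
        if k > n_pix:
            raise ValueError(f"k={k} exceeds the {n_pix} steady pixels of class {code}")
        feats = feat_cube[:, sel].T  # (n_pix, n_feat)
        feats = np.nan_to_num(feats, nan=np.nanmean(feats))
        labels, mean, std, centroids = _cluster_class(feats, k, seed)

        # rank clusters by mean of the first feature (NDVI): low -> high id
        order = np.argsort([feats[labels == j, 0].mean() for j in range(k)], kind="stable")
        rank_of = np.empty(k, dtype=int)
        rank_of[order] = np.arange(k)

        ids = next_id + rank_of  # id for original cluster j is ids[j]
        out[sel] = ids[labels]
        class_names = (names or {}).get(code)
        for j in range(k):
            lid = int(next_id + j)  # j is the rank here
            if class_names is not None:
                name_map[lid] = class_names[j]
            else:
                name_map[lid] = f"class{code}" if k == 1 else f"class{code}_t{j + 1}"
            class_of[lid] = code
        clusterings[code] = _ClassClustering(
            class_code=code,
            feature_mean=mean,
            feature_std=std,
            centroids=centroids,
            landscape_ids=ids,
        )
        next_id += k

    grid = ref.with_values(out, nodata=NODATA)
    return LandscapeTypeMap(
        values=grid,
        names=name_map,
        features_used=list(veg_features.labels),
        class_of=class_of,
        clusterings=clusterings,
    )
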