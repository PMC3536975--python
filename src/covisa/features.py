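"""Voxel selection: top-k per t-map, union across maps, cluster-size filter.

The classifier's feature space is built by merging the voxels with the 500
highest values from each of the four contrast t-maps and then removing
connected components smaller than 5 voxels (face-adjacent 6-connectivity by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class FeatureMask:
    """The selected voxel set defining the classifier feature space.

    ``voxel_indices`` are unique sorted linear indices into the volume grid;
    ``cluster_labels`` gives each retained voxel's connected-component id.
    """

    shape: tuple[int, int, int]
    voxel_indices: np.ndarray
    cluster_labels: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_indices, dtype=np.intp)
        lab = np.asarray(self.cluster_labels, dtype=np.intp)
        if idx.ndim != 1 or lab.shape != idx.shape:
            raise ValueError("indices and labels must be matching 1-D arrays")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("voxel indices must be unique and sorted")
        n = int(np.prod(self.shape))
        if idx.size and (idx[0] < 0 or idx[-1] >= n):
            raise ValueError("voxel index outside the volume grid")
        object.__setattr__(self, "voxel_indices", idx)
        object.__setattr__(self, "cluster_labels", lab)

    @property
    def size(self) -> int:
        return int(self.voxel_indices.size)

    def to_volume(self) -> np.ndarray:
        """Binary 3-D mask volume."""
        v = np.zeros(int(np.prod(self.shape)), dtype=np.uint8)
        v[self.voxel_indices] = 1
        return v.reshape(self.shape)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Feature vector: ``volume`` values at the selected voxels."""
        return volume.ravel()[self.voxel_indices]


def top_k(t_map: np.ndarray, k: int = 500) -> np.ndarray:
    """Linear indices of the ``k`` voxels with the highest t values.

    Boundary ties are broken toward the lowest linear index so the
    selection is deterministic. If ``k`` exceeds the voxel count all
    voxels are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    flat = np.asarray(t_map, dtype=float).ravel()
    n = flat.size
    if k >= n:
        if k > n:
            warnings.warn(
                f"k={k} exceeds voxel count {n}; returning all voxels",
                stacklevel=2,
            )
        return np.arange(n, dtype=np.intp)
    # sort by (-t, index): stable deterministic tie-break at the boundary
    order = np.lexsort((np.arange(n), -flat))
    return np.sort(order[:k].astype(np.intp))


def merge_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Union of per-map selections (sorted unique linear indices)."""
    if not masks:
        return np.array([], dtype=np.intp)
    return np.unique(np.concatenate([np.asarray(m, dtype=np.intp) for m in masks]))


def remove_small_clusters(
    voxels: np.ndarray,
    shape: tuple[int, int, int],
    min_cluster: int = 5,
    connectivity: int = 6,
) -> FeatureMask:
    """Drop connected components smaller than ``min_cluster`` voxels.

    Components are computed under the given neighborhood (6 face-adjacent
    by default; 18 and 26 selectable). Idempotent.
    """
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    vol = np.zeros(int(np.prod(shape)), dtype=bool)
    vol[np.asarray(voxels, dtype=np.intp)] = True
    labeled, n_comp = ndimage.label(
        vol.reshape(shape), structure=CONNECTIVITY_STRUCTS[connectivity]
    )
    if n_comp:
        sizes = np.bincount(labeled.ravel())
        sizes[0] = 0
        keep = sizes >= min_cluster
        labeled[~keep[labeled]] = 0
    flat_labels = labeled.ravel()
    idx = np.flatnonzero(flat_labels)
    return FeatureMask(
        shape=tuple(shape),
        voxel_indices=idx.astype(np.intp),
        cluster_labels=flat_labels[idx].astype(np.intp),
    )


def select_features(
    t_maps: list[np.ndarray],
    k: int = 500,
    min_cluster: int = 5,
    connectivity: int = 6,
) -> FeatureMask:
    """Full selection: top-k per map, union, cluster-size filter."""
    merged = merge_masks([top_k(tm, k) for tm in t_maps])
    shape = tuple(np.asarray(t_maps[0]).shape)
    return remove_small_clusters(merged, shape, min_cluster, connectivity)
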