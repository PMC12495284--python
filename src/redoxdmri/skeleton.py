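"""White-matter skeleton containers.

The voxelwise analysis runs on a sparse set of voxels at tract centres
(a TBSS-style skeleton), represented here as explicit voxel coordinates
with a 26-connectivity adjacency graph, plus per-metric subjects x voxels
matrices.  A desk-scale synthetic template (a one-voxel-thick spherical
shell) mimics the sparsity and connectivity of a real skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SkeletonTemplate", "SkeletonDataset", "skeleton_template", "contiguous_cluster"]


@dataclass
class SkeletonTemplate:
    """Voxel set with 26-connectivity adjacency in CSR layout."""

    coords: np.ndarray  # (V, 3) int voxel coordinates
    shape: tuple[int, int, int]
    indptr: np.ndarray  # CSR adjacency over skeleton voxels
    indices: np.ndarray

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]


_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=np.int64,
)


def _adjacency_from_coords(coords: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    """26-connectivity CSR adjacency restricted to the given voxel set."""
    label = -np.ones(shape, dtype=np.int64)
    label[tuple(coords.T)] = np.arange(len(coords))
    neigh_lists = []
    for off in _OFFSETS:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        lab = -np.ones(len(coords), dtype=np.int64)
        lab[ok] = label[tuple(shifted[ok].T)]
        neigh_lists.append(lab)
    neigh = np.stack(neigh_lists, axis=1)  # (V, 26), -1 where absent
    counts = (neigh >= 0).sum(axis=1)
    indptr = np.zeros(len(coords) + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = neigh[neigh >= 0].astype(np.int64)
    return indptr, indices


def skeleton_template(radius: int = 34) -> SkeletonTemplate:
    """Spherical-shell skeleton of ~4*pi*radius^2 voxels, 26-connected.

    radius 34 gives ~15k voxels (full-scale default); radius 12 gives
    ~2k (reduced size used for permutation-calibration runs).
    """
    n = 2 * radius + 3
    c = radius + 1
    ax = np.arange(n) - c
    dist = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    mask = np.abs(dist - radius) < 0.5
    coords = np.argwhere(mask)
    indptr, indices = _adjacency_from_coords(coords, (n, n, n))
    return SkeletonTemplate(coords=coords, shape=(n, n, n), indptr=indptr, indices=indices)


def contiguous_cluster(template: SkeletonTemplate, size: int, start: int | None = None) -> np.ndarray:
    """Breadth-first growth of a connected voxel set of ``size`` voxels."""
    if size > template.n_voxels:
        raise ValueError("cluster larger than skeleton")
    if start is None:
        # deterministic start: voxel closest to the +x pole
        start = int(np.argmax(template.coords[:, 0]))
    seen = np.zeros(template.n_voxels, dtype=bool)
    order = []
    queue = [start]
    seen[start] = True
    while queue and len(order) < size:
        v = queue.pop(0)
        order.append(v)
        for w in template.neighbors(v):
            if not seen[w]:
                seen[w] = True
                queue.append(w)
    if len(order) < size:
        raise ValueError("skeleton component smaller than requested cluster")
    return np.array(sorted(order[:size]))


@dataclass
class SkeletonDataset:
    """Subjects x skeleton-voxel matrices per microstructure metric."""

    subjects: list[str]
    template: SkeletonTemplate
    metrics: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        v = self.template.n_voxels
        for name, mat in self.metrics.items():
            if mat.shape != (len(self.subjects), v):
                raise ValueError(
                    f"metric {name!r} shape {mat.shape} != ({len(self.subjects)}, {v})"
                )

    @property
    def n_voxels(self) -> int:
        return self.template.n_voxels

    def subset_subjects(self, keep) -> "SkeletonDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SkeletonDataset(
            subjects=[self.subjects[i] for i in keep],
            template=self.template,
            metrics={k: v[keep] for k, v in self.metrics.items()},
        )
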