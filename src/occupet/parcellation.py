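"""Functional brain parcellation by spatially constrained spectral
clustering of resting-state voxel correlation graphs.

The pipeline follows the normalized-cut recipe for rs-fMRI parcellation:
build a sparse graph over 26-connected in-mask voxel neighbours, weight
each edge by the Pearson correlation of the two voxels' time series
(edges below a threshold, default r = 0.5, are dropped), average edge
weights across subjects in Fisher-z space, then cluster the group graph
with the symmetric-normalized Laplacian's leading eigenvectors and
seeded k-means. Negative group weights are clipped to zero before the
Laplacian, which requires nonnegative affinities.

Spatial constraint and threshold defaults follow the Craddock-style
method; both are configurable and recorded in the parcellation's
provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_ATANH_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class VoxelTimeSeriesSet:
    """Preprocessed per-subject voxel x time matrices over a shared mask."""

    subjects: list  # list of (n_voxels, n_timepoints) arrays
    mask: np.ndarray  # 3D boolean
    coords: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if self.coords is None:
            object.__setattr__(self, "coords", np.argwhere(mask))
        n_vox = int(mask.sum())
        if not self.subjects:
            raise ValueError("at least one subject required")
        for i, ts in enumerate(self.subjects):
            ts = np.asarray(ts, dtype=float)
            if ts.shape[0] != n_vox:
                raise ValueError(
                    f"subject {i}: {ts.shape[0]} voxel rows but mask has {n_vox} voxels"
                )
            if ts.shape[1] < 2:
                raise ValueError(f"subject {i}: needs >= 2 timepoints")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Parcellation:
    """Integer label volume: 1..K over the mask, 0 outside."""

    labels: np.ndarray  # 3D int
    n_parcels: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        inside = labels[labels > 0]
        present = np.unique(inside)
        if len(present) and (present.min() < 1 or present.max() > self.n_parcels):
            raise ValueError("labels must lie in 1..K over the mask")

    def mask_labels(self, mask: np.ndarray) -> np.ndarray:
        return self.labels[np.asarray(mask, dtype=bool)]


def build_adjacency(mask: np.ndarray) -> np.ndarray:
    """26-connected neighbour pairs among in-mask voxels.

    Returns an (n_pairs, 2) array of voxel indices (into the mask's
    ``np.argwhere`` order), each unordered pair listed once, no
    self-pairs.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    index = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    index[mask] = np.arange(len(coords))
    pairs = []
    # enumerate 13 forward offsets; the reverse half is implied by symmetry
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ]
    shape = np.array(mask.shape)
    for off in offsets:
        nb = coords + np.array(off)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        src = index[tuple(coords[ok].T)]
        dst = index[tuple(nb[ok].T)]
        keep = dst >= 0
        pairs.append(np.column_stack([src[keep], dst[keep]]))
    out = np.vstack(pairs) if pairs else np.empty((0, 2), dtype=np.int64)
    return out


def correlation_graph(
    timeseries: np.ndarray, pairs: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Pearson r per neighbour pair; weights below threshold set to 0.

    Zero-variance voxel series yield weight 0 on all their edges (a
    warning is logged).
    """
    ts = np.asarray(timeseries, dtype=float)
    centered = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        logger.warning("%d zero-variance voxel series; their edges weighted 0", flat.sum())
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    i, j = pairs[:, 0], pairs[:, 1]
    r = np.einsum("ij,ij->i", unit[i], unit[j])
    r[flat[i] | flat[j]] = 0.0
    r[r < threshold] = 0.0
    return r


def fisher_average(graphs: list[np.ndarray]) -> np.ndarray:
    """Average edge weights across subjects in Fisher-z space.

    Each subject's r is clipped to +/-(1 - 1e-7) before atanh; the mean
    z is mapped back with tanh.
    """
    if not graphs:
        raise ValueError("no subject graphs to average")
    z = [np.arctanh(np.clip(g, -_ATANH_CLIP, _ATANH_CLIP)) for g in graphs]
    return np.tanh(np.mean(z, axis=0))


def _apportion(sizes: np.ndarray, k: int) -> np.ndarray:
    """Largest-remainder apportionment of k clusters over components,
    at least 1 and at most the component size each."""
    sizes = np.asarray(sizes, dtype=float)
    n_comp = len(sizes)
    if k < n_comp:
        raise ValueError(
            f"graph has {n_comp} connected components but only K={k} parcels requested"
        )
    quota = sizes / sizes.sum() * k
    alloc = np.maximum(1, np.floor(quota).astype(int))
    alloc = np.minimum(alloc, sizes.astype(int))
    while alloc.sum() < k:
        room = sizes - alloc
        frac = np.where(room > 0, quota - alloc, -np.inf)
        alloc[np.argmax(frac)] += 1
    while alloc.sum() > k:
        frac = np.where(alloc > 1, quota - alloc, np.inf)
        alloc[np.argmin(frac)] -= 1
    return alloc


def _spectral_labels(W: sp.csr_matrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """Ncut-style clustering of one connected component into k labels 0..k-1."""
    n = W.shape[0]
    if k == 1:
        return np.zeros(n, dtype=int)
    if k > n:
        raise ValueError(f"K={k} exceeds {n} voxels")
    deg = np.asarray(W.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0  # isolated voxels would be their own component
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    Wn = sp.diags(d_inv_sqrt) @ W @ sp.diags(d_inv_sqrt)
    # leading k eigenvectors of D^-1/2 W D^-1/2 == smallest of the
    # symmetric-normalized Laplacian
    if k >= n - 1:
        vals, vecs = np.linalg.eigh(Wn.toarray())
        vecs = vecs[:, np.argsort(vals)[::-1][:k]]
    else:
        _, vecs = eigsh(Wn.tocsc(), k=k, which="LA",
                        v0=rng.standard_normal(n))
    row_norm = np.linalg.norm(vecs, axis=1)
    row_norm[row_norm == 0] = 1.0
    emb = vecs / row_norm[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(emb)
    # repair empty clusters by splitting the largest along its embedding
    missing = set(range(k)) - set(np.unique(labels))
    for m in sorted(missing):
        counts = np.bincount(labels, minlength=k)
        big = int(np.argmax(counts))
        members = np.where(labels == big)[0]
        sub = KMeans(n_clusters=2, n_init=5,
                     random_state=int(rng.integers(2**31))).fit_predict(emb[members])
        labels[members[sub == 1]] = m
    return labels


def spectral_ncut(
    weights: np.ndarray,
    pairs: np.ndarray,
    mask: np.ndarray,
    k: int,
    seed: int = 0,
    threshold: float | None = None,
) -> Parcellation:
    """Cluster the group correlation graph into K parcels.

    Builds the sparse symmetric affinity from ``pairs``/``weights``
    (negative weights clipped to 0), normalizes, embeds with the leading
    K eigenvectors, row-normalizes and runs seeded k-means (10 restarts,
    lowest inertia wins). If thresholding disconnected the graph, each
    component is clustered separately with K apportioned by component
    size (a warning is issued). Deterministic given the seed.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError(f"K={k} exceeds number of mask voxels {n}")
    w = np.clip(np.asarray(weights, dtype=float), 0.0, None)
    keep = w > 0
    i, j = pairs[keep, 0], pairs[keep, 1]
    W = sp.coo_matrix((np.r_[w[keep], w[keep]], (np.r_[i, j], np.r_[j, i])),
                      shape=(n, n)).tocsr()
    n_comp, comp = connected_components(W, directed=False)
    rng = np.random.default_rng(seed)
    flat_labels = np.zeros(n, dtype=np.int32)
    if n_comp == 1:
        flat_labels = _spectral_labels(W, k, rng) + 1
    else:
        warnings.warn(
            f"correlation graph has {n_comp} connected components after "
            f"thresholding; apportioning K={k} by component size"
        )
        sizes = np.bincount(comp, minlength=n_comp)
        alloc = _apportion(sizes, k)
        next_label = 1
        for c in range(n_comp):
            idx = np.where(comp == c)[0]
            sub = W[idx][:, idx]
            sub_labels = _spectral_labels(sub.tocsr(), int(alloc[c]), rng)
            flat_labels[idx] = sub_labels + next_label
            next_label += int(alloc[c])
    vol = np.zeros(mask.shape, dtype=np.int32)
    vol[mask] = flat_labels
    return Parcellation(
        labels=vol,
        n_parcels=k,
        provenance={"k": k, "seed": seed, "threshold": threshold,
                    "eigen_dim": k, "n_components": n_comp},
    )


def parcellate(
    data: VoxelTimeSeriesSet, k: int, threshold: float = 0.5, seed: int = 0
) -> Parcellation:
    """Full parcellation pipeline: adjacency, per-subject thresholded
    correlation graphs, Fisher-z group average, normalized-cut clustering."""
    pairs = build_adjacency(data.mask)
    graphs = [correlation_graph(ts, pairs, threshold) for ts in data.subjects]
    group = fisher_average(graphs)
    parc = spectral_ncut(group, pairs, data.mask, k, seed=seed, threshold=threshold)
    return parc
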