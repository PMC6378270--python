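"""Emergent self-organizing map (ESOM) on a toroid grid with U-matrix
cluster extraction.

A large Kohonen neuron grid (default 50 x 80 = 4000 units, opposite edges
connected) is trained online on the rescaled concentration matrix. The
U-matrix overlays, on the 2-D grid, each neuron's mean high-dimensional
distance to its grid neighbours: low "valleys" mark clusters, high
"ridges" mark gaps in the data space. Cluster extraction thresholds the
U-heights and labels subjects by the basin of their best-matching unit
(BMU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EsomModel",
    "UMatrix",
    "train_esom",
    "compute_umatrix",
    "umatrix_clusters",
]


@dataclass
class EsomModel:
    weights: np.ndarray  # (rows, cols, d)
    toroid: bool
    epochs: int
    seed: int
    loss_history: list[float] | None = None  # mean subject-to-BMU distance per epoch

    @property
    def rows(self) -> int:
        return self.weights.shape[0]

    @property
    def cols(self) -> int:
        return self.weights.shape[1]

    def save(self, path) -> None:
        np.savez(path, weights=self.weights, toroid=self.toroid,
                 epochs=self.epochs, seed=self.seed)

    @classmethod
    def load(cls, path) -> "EsomModel":
        with np.load(path) as npz:
            return cls(npz["weights"], bool(npz["toroid"]),
                       int(npz["epochs"]), int(npz["seed"]))


@dataclass
class UMatrix:
    heights: np.ndarray  # (rows, cols)
    bmu: np.ndarray  # (n_subjects, 2) grid coordinates


def _wrapped_delta(idx: np.ndarray, center: int, size: int) -> np.ndarray:
    """Signed toroidal index distance magnitudes along one axis."""
    d = np.abs(idx - center)
    return np.minimum(d, size - d)


def _bmu_index(weights_flat: np.ndarray, x: np.ndarray) -> int:
    diff = weights_flat - x
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def train_esom(
    matrix,
    rows: int = 50,
    cols: int = 80,
    epochs: int = 30,
    seed: int = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.05,
) -> EsomModel:
    """Train a toroid Kohonen map by online learning.

    Weights are initialized by drawing each dimension independently from
    that feature's observed values. Per presentation the BMU is found by
    Euclidean distance, and all weights move toward the sample under a
    Gaussian neighbourhood on the toroidal grid whose radius decays from
    half the larger grid extent to 1; the learning rate decays linearly
    from ``lr_start`` to ``lr_end`` over all presentations.
    """
    X = np.asarray(matrix, dtype=float)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2 x 2")
    n, d = X.shape
    rng = np.random.default_rng(seed)

    W = np.empty((rows, cols, d))
    for j in range(d):
        W[:, :, j] = rng.choice(X[:, j], size=(rows, cols), replace=True)

    row_idx = np.arange(rows)
    col_idx = np.arange(cols)
    radius_start = max(rows, cols) / 2.0
    total_steps = epochs * n
    step = 0
    losses: list[float] = []
    for epoch in range(epochs):
        frac_epoch = epoch / max(1, epochs - 1) if epochs > 1 else 1.0
        sigma = radius_start * (1.0 - frac_epoch) + 1.0 * frac_epoch
        order = rng.permutation(n)
        for i in order:
            lr = lr_start + (lr_end - lr_start) * (step / max(1, total_steps - 1))
            step += 1
            x = X[i]
            flat = W.reshape(-1, d)
            b = _bmu_index(flat, x)
            br, bc = divmod(b, cols)
            dr = _wrapped_delta(row_idx, br, rows)
            dc = _wrapped_delta(col_idx, bc, cols)
            h = np.exp(-(dr[:, None] ** 2 + dc[None, :] ** 2) / (2.0 * sigma**2))
            W += (lr * h)[:, :, None] * (x[None, None, :] - W)
        flat = W.reshape(-1, d)
        loss = np.mean(
            [np.linalg.norm(flat[_bmu_index(flat, x)] - x) for x in X]
        )
        losses.append(float(loss))
    return EsomModel(W, toroid=True, epochs=epochs, seed=seed, loss_history=losses)


_NEIGH_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def compute_umatrix(model: EsomModel, matrix) -> UMatrix:
    """U-heights (mean distance to the 8 toroidal grid neighbours) and BMUs."""
    W = model.weights
    rows, cols, d = W.shape
    heights = np.zeros((rows, cols))
    for dr, dc in _NEIGH_OFFSETS:
        shifted = np.roll(np.roll(W, dr, axis=0), dc, axis=1)
        heights += np.linalg.norm(W - shifted, axis=2)
    heights /= len(_NEIGH_OFFSETS)

    X = np.asarray(matrix, dtype=float)
    flat = W.reshape(-1, d)
    bmu = np.empty((X.shape[0], 2), dtype=int)
    for i, x in enumerate(X):
        b = _bmu_index(flat, x)
        bmu[i] = divmod(b, cols)
    return UMatrix(heights, bmu)


def _toroid_components(low_mask: np.ndarray) -> np.ndarray:
    """Connected components (8-connectivity with wrap-around) of True cells.

    Returns an int grid: -1 outside, component id >= 0 inside.
    """
    rows, cols = low_mask.shape
    comp = -np.ones((rows, cols), dtype=int)
    cid = 0
    for r in range(rows):
        for c in range(cols):
            if not low_mask[r, c] or comp[r, c] >= 0:
                continue
            stack = [(r, c)]
            comp[r, c] = cid
            while stack:
                rr, cc = stack.pop()
                for dr, dc in _NEIGH_OFFSETS:
                    nr, nc = (rr + dr) % rows, (cc + dc) % cols
                    if low_mask[nr, nc] and comp[nr, nc] < 0:
                        comp[nr, nc] = cid
                        stack.append((nr, nc))
            cid += 1
    return comp


def umatrix_clusters(umatrix: UMatrix, height_quantile: float = 0.6) -> np.ndarray:
    """Extract cluster labels from U-matrix basins.

    Heights below the given quantile define "valley" cells; connected
    valley components on the toroid are basins. Each subject inherits the
    basin of its BMU; a BMU on a ridge is assigned to the basin of the
    nearest valley cell by toroidal grid distance. Basins are relabeled by
    decreasing subject count.
    """
    heights = umatrix.heights
    rows, cols = heights.shape
    thr = np.quantile(heights, height_quantile)
    low = heights <= thr
    comp = _toroid_components(low)

    low_cells = np.argwhere(low)
    labels = np.empty(len(umatrix.bmu), dtype=int)
    for i, (r, c) in enumerate(umatrix.bmu):
        if comp[r, c] >= 0:
            labels[i] = comp[r, c]
        else:
            dr = _wrapped_delta(low_cells[:, 0], r, rows)
            dc = _wrapped_delta(low_cells[:, 1], c, cols)
            nearest = low_cells[np.argmin(dr**2 + dc**2)]
            labels[i] = comp[nearest[0], nearest[1]]

    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) == 1:
        warnings.warn("all subjects fall into a single U-matrix basin")
    first = np.array([np.argmax(labels == u) for u in uniq])
    order = np.lexsort((first, -counts))
    mapping = {uniq[o]: i for i, o in enumerate(order)}
    return np.array([mapping[l] for l in labels])
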