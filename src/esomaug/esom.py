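"""Emergent self-organizing map: training and structure layers.

An ESOM is a large rectangular SOM lattice (thousands of neurons) whose
collective layout, rather than individual units, carries the structure
of the data.  Training follows the classical online update

    w_i <- w_i + eta(t) * h(BMU, i, t) * (x - w_i)

with a Gaussian neighborhood ``h`` on the (optionally toroidal) lattice
whose radius and the learning rate ``eta`` decay over epochs.  Two
emergent layers are derived from the trained lattice:

* the **U-matrix** — per neuron, the mean high-dimensional distance to
  its lattice neighbors; ridges mark cluster boundaries;
* the **P-matrix** — per neuron, the number of data points inside a
  hypersphere of a given radius around its prototype; a density layer.

Variables are z-standardized before training (the scaler is kept on the
grid so every downstream distance lives in the same space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Scaler, TabularDataset, ValidationError

#: default lattice follows the common ESOM convention of a few thousand
#: neurons on a toroidal 50 x 80 grid
DEFAULT_ROWS = 50
DEFAULT_COLS = 80
DEFAULT_EPOCHS = 24
DEFAULT_LEARNING_RATE = (0.5, 0.1)


@dataclass
class EsomGrid:
    """A trained neuron lattice.

    ``weights`` holds one prototype vector per neuron, in row-major
    neuron order (neuron ``i`` sits at lattice position
    ``(i // cols, i % cols)``).  ``bmu`` maps each training point to its
    best matching unit (ties broken toward the lowest neuron index).
    The fitted :class:`~esomaug.dataset.Scaler` records the
    standardization applied before training.
    """

    rows: int
    cols: int
    topology: str  # "planar" | "toroidal"
    weights: np.ndarray  # (m, J)
    scaler: Scaler
    bmu: np.ndarray | None = None  # (n,)
    epochs: int = 0
    learning_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    neighborhood_radii: np.ndarray = field(default_factory=lambda: np.array([]))
    umatrix_heights: np.ndarray | None = None
    pmatrix_density: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def lattice_coordinates(self) -> np.ndarray:
        rr, cc = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.column_stack([rr, cc])

    def neighbor_lists(self) -> list[np.ndarray]:
        """8-neighborhood per neuron (wrapped if toroidal, deduplicated)."""
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
        out: list[np.ndarray] = []
        for i in range(self.n_neurons):
            r, c = divmod(i, self.cols)
            seen = set()
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if self.topology == "toroidal":
                    nr %= self.rows
                    nc %= self.cols
                elif not (0 <= nr < self.rows and 0 <= nc < self.cols):
                    continue
                j = nr * self.cols + nc
                if j != i:
                    seen.add(j)
            out.append(np.array(sorted(seen), dtype=int))
        return out

    def grid_distance_sq(self, neuron: int) -> np.ndarray:
        """Squared lattice distance from ``neuron`` to every neuron."""
        coords = self.lattice_coordinates()
        r, c = divmod(neuron, self.cols)
        dr = np.abs(coords[:, 0] - r)
        dc = np.abs(coords[:, 1] - c)
        if self.topology == "toroidal":
            dr = np.minimum(dr, self.rows - dr)
            dc = np.minimum(dc, self.cols - dc)
        return (dr * dr + dc * dc).astype(float)

    def occupied_prototypes(self) -> np.ndarray:
        """Prototype vectors of neurons holding at least one data point."""
        if self.bmu is None:
            raise ValidationError("grid has no BMU assignment; train it first")
        occupied = np.unique(self.bmu)
        return self.weights[occupied]

    def export_frame(self):
        """One row per neuron: lattice row, column, weight components."""
        import pandas as pd

        coords = self.lattice_coordinates()
        frame = pd.DataFrame(coords, columns=["row", "col"])
        for j in range(self.weights.shape[1]):
            frame[f"w{j + 1}"] = self.weights[:, j]
        return frame


def _bmu_indices(weights: np.ndarray, x: np.ndarray) -> int:
    diff = weights - x
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def train_esom(
    data: TabularDataset,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    epochs: int = DEFAULT_EPOCHS,
    seed: int = 0,
    topology: str = "toroidal",
    learning_rate: tuple[float, float] = DEFAULT_LEARNING_RATE,
    standardize: bool = True,
) -> EsomGrid:
    """Train an ESOM on ``data`` and assign a BMU to every data point.

    The learning rate decays linearly between the two entries of
    ``learning_rate`` and the Gaussian neighborhood radius decays
    linearly from half the smaller lattice dimension to 1, both per
    epoch.  Training is deterministic for a fixed seed.
    """
    data.validate()
    if rows * cols < 4:
        raise ValueError("lattice needs at least 4 neurons")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if topology not in ("planar", "toroidal"):
        raise ValueError("topology must be 'planar' or 'toroidal'")

    scaler = Scaler.fit(data.values) if standardize else Scaler.identity(data.n_features)
    X = scaler.transform(data.values)
    n, J = X.shape
    m = rows * cols
    rng = np.random.default_rng(seed)

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    weights = lo + span * rng.uniform(size=(m, J))

    grid = EsomGrid(
        rows=rows, cols=cols, topology=topology, weights=weights, scaler=scaler, epochs=epochs
    )
    sigma0 = max(min(rows, cols) / 2.0, 1.0)
    sigmas = np.linspace(sigma0, 1.0, epochs)
    etas = np.linspace(learning_rate[0], learning_rate[1], epochs)
    grid.neighborhood_radii = sigmas
    grid.learning_rates = etas

    coords = grid.lattice_coordinates()
    rr = coords[:, 0]
    cc = coords[:, 1]
    for epoch in range(epochs):
        sigma, eta = sigmas[epoch], etas[epoch]
        two_sigma_sq = 2.0 * sigma * sigma
        order = rng.permutation(n)
        for idx in order:
            x = X[idx]
            b = _bmu_indices(weights, x)
            br, bc = divmod(b, cols)
            dr = np.abs(rr - br)
            dc = np.abs(cc - bc)
            if topology == "toroidal":
                dr = np.minimum(dr, rows - dr)
                dc = np.minimum(dc, cols - dc)
            d2 = (dr * dr + dc * dc).astype(float)
            h = np.exp(-d2 / two_sigma_sq)
            active = h > 1e-3  # negligible updates skipped
            weights[active] += (eta * h[active])[:, None] * (x - weights[active])

    # final BMU assignment, ties to the lowest neuron index via argmin
    w_sq = np.einsum("ij,ij->i", weights, weights)
    bmu = np.empty(n, dtype=int)
    block = max(1, int(2e6 // max(m, 1)))
    for start in range(0, n, block):
        chunk = X[start : start + block]
        d = w_sq[None, :] - 2.0 * chunk @ weights.T
        bmu[start : start + block] = np.argmin(d, axis=1)
    grid.weights = weights
    grid.bmu = bmu
    return grid


def compute_umatrix(grid: EsomGrid) -> np.ndarray:
    """Per-neuron mean Euclidean distance to lattice-neighbor prototypes."""
    if grid.weights is None or grid.weights.size == 0:
        raise ValidationError("grid has no weights; train it first")
    heights = np.empty(grid.n_neurons)
    for i, neighbors in enumerate(grid.neighbor_lists()):
        if neighbors.size == 0:
            heights[i] = 0.0
            continue
        diffs = grid.weights[neighbors] - grid.weights[i]
        heights[i] = float(np.sqrt(np.einsum("ij,ij->i", diffs, diffs)).mean())
    grid.umatrix_heights = heights
    return heights


def compute_pmatrix(grid: EsomGrid, data: TabularDataset, radius: float) -> np.ndarray:
    """Per-neuron count of data points within ``radius`` of its prototype.

    Distances are measured in the grid's standardized space; the count
    uses the inclusive boundary ``d <= radius``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if grid.weights is None or grid.weights.size == 0:
        raise ValidationError("grid has no weights; train it first")
    values = data.values if isinstance(data, TabularDataset) else np.asarray(data, dtype=float)
    values = values.reshape(-1, grid.weights.shape[1])
    X = grid.scaler.transform(values) if values.shape[0] else values
    if X.shape[0] == 0:
        density = np.zeros(grid.n_neurons, dtype=int)
    else:
        x_sq = np.einsum("ij,ij->i", X, X)
        density = np.empty(grid.n_neurons, dtype=int)
        block = max(1, int(2e6 // max(X.shape[0], 1)))
        r_sq = radius * radius
        w = grid.weights
        w_sq = np.einsum("ij,ij->i", w, w)
        for start in range(0, grid.n_neurons, block):
            d2 = (
                w_sq[start : start + block, None]
                - 2.0 * w[start : start + block] @ X.T
                + x_sq[None, :]
            )
            density[start : start + block] = (d2 <= r_sq + 1e-12).sum(axis=1)
    grid.pmatrix_density = density
    return density
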