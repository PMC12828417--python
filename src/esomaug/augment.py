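"""Engineered control features and neighborhood-based data generation.

Two ingredients of the augmentation stage live here.

**Engineered controls.**  For every original variable ``X_j`` a permuted
counterpart ``X_j_perm`` is appended — the same values, independently
shuffled across rows.  A control keeps the marginal distribution of its
parent but carries no class association, so its behavior under
augmentation is a pure read-out of error inflation.  Controls are
injected *after* structure learning (the pipeline orders this), so they
never contaminate the learned radius.

**Neighborhood generation.**  A synthetic point for seed ``x_i`` is
placed at a controlled distance ``d`` whose neighborhood probability

    p(d) = 1 - 1 / (1 + exp(-10 * (d / c - 1)))

falls into one of three strata: the core (p > 0.95, 85% of points),
intermediate distances (0.10 < p < 0.95, 15%), and an outer band
(p <= 0.10 with d <= 2c, 5%).  The stratum is drawn per point, a target
probability is drawn uniformly inside the stratum's band, the sigmoid
is inverted for the distance, and the displacement direction is uniform
on the unit hypersphere of the standardized feature space.  Explicit
distance control avoids the hypersphere-surface concentration that
plagues naive high-dimensional jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .dataset import (
    ENGINEERED,
    ORIGINAL,
    ROW_GENERATED,
    Scaler,
    TabularDataset,
)

#: default stratum target fractions (core, intermediate, outer)
DEFAULT_STRATA = (0.85, 0.15, 0.05)
#: steepness of the neighborhood sigmoid
_SIGMOID_GAIN = 10.0
#: stratum probability-band edges
CORE_P = 0.95
OUTER_P = 0.10
OUTER_D_FACTOR = 2.0


def neighborhood_probability(d, c: float):
    """Probability that a point at distance ``d`` lies in the
    neighborhood of scale ``c``: ``1 - 1/(1 + exp(-10 (d/c - 1)))``.

    Strictly decreasing in ``d`` with value 1/2 at ``d = c``.
    """
    if c <= 0:
        raise ValueError("scale c must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    # algebraically 1 - 1/(1 + exp(-10 (d/c - 1))); expit avoids the
    # catastrophic cancellation of the literal form for d >> c
    out = expit(-_SIGMOID_GAIN * (d / c - 1.0))
    return float(out) if out.ndim == 0 else out


def probability_to_distance(p, c: float):
    """Invert the neighborhood sigmoid: ``d = c (1 - logit(p)/10)``."""
    if c <= 0:
        raise ValueError("scale c must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    out = c * (1.0 - logit(p) / _SIGMOID_GAIN)
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneratorConfig:
    """Settings of the neighborhood generator.

    ``c`` is the neighborhood scaling constant (set to the critical
    radius by the pipeline), ``k`` the number of synthetic points per
    original row, ``strata`` the (core, intermediate, outer) target
    fractions (renormalized to sum to one).
    """

    c: float
    k: int
    strata: tuple[float, float, float] = DEFAULT_STRATA
    seed: int = 0
    round_integers: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("scale c must be positive")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError("k (points per original) must be an integer >= 1")
        self.k = int(self.k)
        strata = np.asarray(self.strata, dtype=float)
        if strata.shape != (3,) or np.any(strata <= 0):
            raise ValueError("strata must be three positive fractions")
        self.strata = tuple(strata / strata.sum())


def engineer_controls(data: TabularDataset, seed: int = 0) -> TabularDataset:
    """Append a permuted counterpart for every original column.

    Each ``X_j`` gains an ``X_j_perm`` column holding an independent
    random permutation of its rows; labels and row order are untouched.
    """
    data.validate()
    if data.engineered_feature_names():
        raise ValueError("dataset already carries engineered controls")
    rng = np.random.default_rng(seed)
    J = data.n_features
    permuted = np.empty_like(data.values)
    for j in range(J):
        permuted[:, j] = data.values[rng.permutation(data.n_rows), j]
    names = list(data.feature_names) + [f"{f}_perm" for f in data.feature_names]
    values = np.hstack([data.values, permuted])
    provenance = np.array([ORIGINAL] * J + [ENGINEERED] * J, dtype=object)
    counterpart_map = {f: f"{f}_perm" for f in data.feature_names}
    return TabularDataset(
        values=values,
        labels=data.labels.copy(),
        feature_names=names,
        provenance=provenance,
        counterpart_map=counterpart_map,
        row_origin=data.row_origin.copy(),
    )


def _draw_distances(rng: np.random.Generator, n: int, strata: tuple, c: float):
    """Per point: draw a stratum, a probability inside its band, and
    the corresponding distance.  Returns (distances, stratum ids)."""
    stratum = rng.choice(3, size=n, p=np.asarray(strata))
    p_star = np.empty(n)
    p_core_hi = neighborhood_probability(0.0, c)  # < 1: p at zero distance
    p_outer_lo = neighborhood_probability(OUTER_D_FACTOR * c, c)  # p at d = 2c
    core = stratum == 0
    mid = stratum == 1
    outer = stratum == 2
    p_star[core] = rng.uniform(CORE_P, p_core_hi, core.sum())
    p_star[mid] = rng.uniform(OUTER_P, CORE_P, mid.sum())
    p_star[outer] = rng.uniform(p_outer_lo, OUTER_P, outer.sum())
    return probability_to_distance(p_star, c), stratum


def generate_points(data: TabularDataset, config: GeneratorConfig) -> TabularDataset:
    """Generate ``k`` synthetic rows per original row of ``data``.

    Operates jointly on all present columns (original and engineered)
    in z-standardized space, so controls experience exactly the same
    augmentation dynamics as the true variables; outputs are
    back-transformed.  Every synthetic row inherits its seed row's
    class label.
    """
    data.validate()
    seeds = data.original_rows() if np.any(data.row_origin == ROW_GENERATED) else data
    n, J = seeds.n_rows, seeds.n_features
    total = n * config.k
    rng = np.random.default_rng(config.seed)
    scaler = Scaler.fit(seeds.values)
    Z = scaler.transform(seeds.values)

    distances, stratum = _draw_distances(rng, total, config.strata, config.c)
    directions = rng.standard_normal((total, J))
    norms = np.linalg.norm(directions, axis=1)
    # a zero draw is essentially impossible; re-point it at axis 0
    bad = norms == 0
    if np.any(bad):
        directions[bad, 0] = 1.0
        norms[bad] = 1.0
    directions /= norms[:, None]

    seed_idx = np.repeat(np.arange(n), config.k)
    synthetic_z = Z[seed_idx] + distances[:, None] * directions
    values = scaler.inverse(synthetic_z)
    if config.round_integers:
        integral = np.all(np.mod(seeds.values, 1.0) == 0.0, axis=0)
        values[:, integral] = np.round(values[:, integral])
    return TabularDataset(
        values=values,
        labels=seeds.labels[seed_idx],
        feature_names=list(seeds.feature_names),
        provenance=seeds.provenance.copy(),
        counterpart_map=dict(seeds.counterpart_map),
        row_origin=np.array([ROW_GENERATED] * total, dtype=object),
    )


def augment_dataset(data: TabularDataset, config: GeneratorConfig) -> TabularDataset:
    """Original rows followed by ``n * k`` generated rows.

    Row provenance is retained, so dropping the generated rows restores
    the input exactly.
    """
    synthetic = generate_points(data, config)
    return TabularDataset(
        values=np.vstack([data.values, synthetic.values]),
        labels=np.concatenate([data.labels, synthetic.labels]),
        feature_names=list(data.feature_names),
        provenance=data.provenance.copy(),
        counterpart_map=dict(data.counterpart_map),
        row_origin=np.concatenate([data.row_origin, synthetic.row_origin]),
    )
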