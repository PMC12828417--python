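"""Artificial benchmark datasets with known ground truth.

Three constructions exercise the pipeline end to end without any
external download:

``chainlink``
    Two interlinked rings in 3-D (two classes of points sampled
    uniformly from the volume of orthogonally intertwined tori) — a
    classic structure-discovery benchmark where no separating plane
    exists between the classes.
``ascending``
    Fifty Gaussian variables whose between-class mean difference grows
    linearly from zero to ten standard deviations, so the statistical
    significance of the class difference ascends systematically with
    the variable index.
``no_effect``
    Fifty Gaussian variables where both classes are drawn from the same
    distribution, post-filtered so every retained variable has a
    two-sample t-test p-value of at least 0.6 — a stringent null for
    false-positive control.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dataset import TabularDataset


def make_chainlink(
    n_per_class: int = 500,
    r_minor: float = 0.1,
    R_major: float = 1.0,
    seed: int = 0,
    surface: bool = False,
) -> TabularDataset:
    """Two interlinked tori in 3-D, ``n_per_class`` points per class.

    Ring 1 lies in the xy-plane centered at the origin; ring 2 lies in
    the xz-plane centered at ``(R_major, 0, 0)``, so the centerline
    circles are orthogonally interlinked.  Points are uniform over the
    solid torus volume by default (``surface=True`` samples the torus
    surface instead).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if r_minor >= R_major:
        raise ValueError("minor radius must be smaller than major radius (self-intersection)")
    rng = np.random.default_rng(seed)

    def torus_points(n: int) -> np.ndarray:
        # rejection-sample the volume element (R + rho cos v) drho dv du
        out = np.empty((0, 3))
        while out.shape[0] < n:
            m = 2 * (n - out.shape[0]) + 16
            u = rng.uniform(0, 2 * np.pi, m)
            v = rng.uniform(0, 2 * np.pi, m)
            if surface:
                rho = np.full(m, r_minor)
            else:
                rho = r_minor * np.sqrt(rng.uniform(size=m))
            accept = rng.uniform(size=m) < (R_major + rho * np.cos(v)) / (R_major + r_minor)
            u, v, rho = u[accept], v[accept], rho[accept]
            ring = np.column_stack(
                [
                    (R_major + rho * np.cos(v)) * np.cos(u),
                    (R_major + rho * np.cos(v)) * np.sin(u),
                    rho * np.sin(v),
                ]
            )
            out = np.vstack([out, ring])
        return out[:n]

    ring1 = torus_points(n_per_class)  # xy-plane, centered at origin
    ring2 = torus_points(n_per_class)  # xz-plane, centered at (R_major, 0, 0)
    ring2 = np.column_stack([ring2[:, 0] + R_major, ring2[:, 2], ring2[:, 1]])
    values = np.vstack([ring1, ring2])
    labels = np.concatenate([np.ones(n_per_class, dtype=int), np.full(n_per_class, 2, dtype=int)])
    return TabularDataset(values=values, labels=labels, feature_names=["X1", "X2", "X3"])


def make_ascending_significance(
    n_v: int = 50,
    n_per_class: int = 10,
    max1: float = 50.0,
    max2: float = 40.0,
    seed: int = 0,
) -> TabularDataset:
    """Two-class Gaussians with linearly ascending mean separation.

    Variable ``i`` (1-based) draws class 1 from ``N(mu1_i, 1)`` and
    class 2 from ``N(mu2_i, 1)`` with

        mu1_i = 1 + (i - 1) * (max1 - 1) / (n_v - 1)
        mu2_i = 1 + (i - 1) * (max2 - 1) / (n_v - 1)

    so the class difference is zero at ``i = 1`` and grows to
    ``max1 - max2`` at ``i = n_v``.
    """
    if n_v < 2:
        raise ValueError("n_v must be >= 2")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(1, n_v + 1)
    mu1 = 1.0 + (i - 1) * (max1 - 1.0) / (n_v - 1)
    mu2 = 1.0 + (i - 1) * (max2 - 1.0) / (n_v - 1)
    class1 = rng.normal(mu1, 1.0, size=(n_per_class, n_v))
    class2 = rng.normal(mu2, 1.0, size=(n_per_class, n_v))
    values = np.vstack([class1, class2])
    labels = np.concatenate([np.ones(n_per_class, dtype=int), np.full(n_per_class, 2, dtype=int)])
    names = [f"X{j}" for j in i]
    return TabularDataset(values=values, labels=labels, feature_names=names)


def make_no_effect(
    n_v: int = 50,
    n_per_class: int = 10,
    p_min: float = 0.6,
    seed: int = 0,
    batch_factor: int = 4,
    max_batches: int = 50,
) -> TabularDataset:
    """Two classes drawn from identical per-variable Gaussians.

    Candidate variables use ``mu ~ Uniform{10, ..., 30}`` (integer
    steps) and ``sigma ~ Uniform{1.00, 1.01, ..., 3.00}``; both classes
    draw ``n_per_class`` observations from the same ``N(mu, sigma)``.
    Candidates are generated in batches and only those whose two-sample
    t-test p-value is at least ``p_min`` are retained; ``n_v`` of the
    retained variables are then subsampled.
    """
    if n_v < 1:
        raise ValueError("n_v must be >= 1")
    if not 0 < p_min < 1:
        raise ValueError("p_min must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    kept_cols: list[np.ndarray] = []
    for _ in range(max_batches):
        m = batch_factor * n_v
        mu = rng.integers(10, 31, size=m).astype(float)
        sigma = rng.integers(100, 301, size=m) / 100.0
        class1 = rng.normal(mu, sigma, size=(n_per_class, m))
        class2 = rng.normal(mu, sigma, size=(n_per_class, m))
        pvals = stats.ttest_ind(class1, class2, equal_var=False).pvalue
        passing = np.flatnonzero(pvals >= p_min)
        for j in passing:
            kept_cols.append(np.concatenate([class1[:, j], class2[:, j]]))
        if len(kept_cols) >= n_v:
            break
    if len(kept_cols) < n_v:
        raise RuntimeError(
            f"could not retain {n_v} null variables with p >= {p_min} "
            f"after {max_batches} candidate batches"
        )
    pick = rng.choice(len(kept_cols), size=n_v, replace=False)
    values = np.column_stack([kept_cols[j] for j in pick])
    labels = np.concatenate(
        [np.ones(n_per_class, dtype=int), np.full(n_per_class, 2, dtype=int)]
    )
    names = [f"X{j + 1}" for j in range(n_v)]
    return TabularDataset(values=values, labels=labels, feature_names=names)
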