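"""Critical generative radius from the trained map's structure.

The radius that separates within-cluster from between-cluster distances
is estimated in three steps: (1) build the Gabriel graph over the
prototypes of occupied best-matching units and collect the edge lengths
("abstract U-matrix heights"); (2) fit a two-component univariate
Gaussian mixture to these heights by EM; (3) take the Bayes decision
boundary between the two components as the radius.  When the height
distribution is effectively unimodal the mixture view is meaningless,
so the estimate falls back to the median height and is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .esom import EsomGrid


class DegenerateFitError(ValueError):
    """Raised when a mixture fit cannot be formed at all."""


@dataclass
class GmmFit:
    """Two-component univariate Gaussian mixture, ordered by mean."""

    weights: np.ndarray  # (2,)
    means: np.ndarray  # (2,)
    sds: np.ndarray  # (2,)
    degenerate: bool = False
    log_likelihood: float = float("nan")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.weights[0] * stats.norm.pdf(x, self.means[0], self.sds[0]) + self.weights[
            1
        ] * stats.norm.pdf(x, self.means[1], self.sds[1])


@dataclass
class RadiusEstimate:
    """Gabriel-edge heights, mixture fit, Bayes boundary, and radius r."""

    au_heights: np.ndarray
    gmm: GmmFit | None
    t_au: float | None
    r: float
    degenerate: bool = False
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def to_dict(self) -> dict:
        return {
            "r": float(self.r),
            "t_au": None if self.t_au is None else float(self.t_au),
            "degenerate": bool(self.degenerate),
            "n_heights": int(len(self.au_heights)),
            "height_median": float(np.median(self.au_heights)) if len(self.au_heights) else None,
            "gmm": None
            if self.gmm is None
            else {
                "weights": self.gmm.weights.tolist(),
                "means": self.gmm.means.tolist(),
                "sds": self.gmm.sds.tolist(),
                "degenerate": bool(self.gmm.degenerate),
            },
        }


def gabriel_graph(points: np.ndarray) -> np.ndarray:
    """Edges ``(u, v)`` of the Gabriel graph over ``points``.

    An edge is present iff no third point lies inside (or on) the
    hypersphere having the segment uv as diameter; equivalently, iff
    ``d2(k,u) + d2(k,v) > d2(u,v)`` for every other point k, so that
    e.g. the corners of a square yield the four sides but no diagonal.
    Duplicate points are removed first.  Indices refer to the
    deduplicated point set (returned order = first occurrence).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    _, first = np.unique(points, axis=0, return_index=True)
    points = points[np.sort(first)]
    p = points.shape[0]
    if p < 2:
        raise ValueError("need at least 2 distinct points")
    sq = np.einsum("ij,ij->i", points, points)
    D = sq[:, None] - 2.0 * points @ points.T + sq[None, :]
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0)
    edges = []
    for i in range(p - 1):
        # min over k of D[k,i] + D[k,j], excluding k in {i, j}
        s = D[:, i][:, None] + D[:, i + 1 :]
        s[i] = np.inf
        rows = np.arange(i + 1, p)
        s[rows, rows - (i + 1)] = np.inf
        blocked = s.min(axis=0) <= D[i, i + 1 :] * (1.0 + 1e-12)
        for j in np.flatnonzero(~blocked):
            edges.append((i, i + 1 + j))
    return np.array(edges, dtype=int).reshape(-1, 2)


def fit_bimodal_gmm(heights: np.ndarray, seed: int = 0) -> GmmFit:
    """Fit a two-component univariate Gaussian mixture by EM.

    EM is initialized by k-means (k=2), runs at most 100 iterations to
    a log-likelihood tolerance of 1e-8, and is deterministic for a
    fixed seed.  The fit is flagged ``degenerate`` when the components
    collapse (a weight below 0.01, means closer than a tenth of the
    pooled standard deviation) or when the fitted mixture density is
    unimodal between the component means — either way the two-cluster
    reading of the height distribution is unsupported.
    """
    heights = np.asarray(heights, dtype=float).ravel()
    if len(heights) < 10:
        raise DegenerateFitError("need at least 10 heights for a mixture fit")
    scale = float(np.std(heights))
    if scale == 0:
        raise DegenerateFitError("heights have zero variance")
    # EM on standardized heights keeps tolerance and covariance floor
    # scale-free, so the estimate is exactly equivariant under unit
    # changes of the data
    center = float(np.mean(heights))
    z = (heights - center) / scale
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-8,
        max_iter=100,
        n_init=1,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-10,
    ).fit(z[:, None])
    order = np.argsort(gm.means_.ravel())
    weights = gm.weights_.ravel()[order]
    means = gm.means_.ravel()[order] * scale + center
    sds = np.sqrt(gm.covariances_.ravel()[order]) * scale
    fit = GmmFit(
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=float(
            (gm.score(z[:, None]) - np.log(scale)) * len(heights)
        ),
    )
    if weights.min() < 0.01 or abs(means[1] - means[0]) < 0.1 * scale:
        fit.degenerate = True
    elif not _is_bimodal(fit):
        fit.degenerate = True
    return fit


def _is_bimodal(fit: GmmFit, n_grid: int = 512) -> bool:
    """True iff the mixture density dips between the component means.

    On ``[mu1, mu2]`` a unimodal mixture attains its minimum at one of
    the endpoints; a genuine two-mode mixture dips strictly below both
    endpoint densities somewhere in the interior.
    """
    lo = fit.means[0]
    hi = fit.means[1]
    if hi <= lo:
        return False
    x = np.linspace(lo, hi, n_grid)
    d = fit.pdf(x)
    return bool(d[1:-1].min() < 0.99 * min(d[0], d[-1]))


def bayes_boundary(gmm: GmmFit) -> float:
    """Root of ``pi1 N(x|mu1,s1) = pi2 N(x|mu2,s2)`` inside (mu1, mu2).

    This is the Bayes decision boundary between the two mixture
    components; found by bracketing the log-density difference.
    """
    mu1, mu2 = float(gmm.means[0]), float(gmm.means[1])
    if not mu1 < mu2:
        raise ValueError("component means must satisfy mu1 < mu2")

    def logdiff(x: float) -> float:
        return (
            np.log(gmm.weights[0])
            + stats.norm.logpdf(x, mu1, gmm.sds[0])
            - np.log(gmm.weights[1])
            - stats.norm.logpdf(x, mu2, gmm.sds[1])
        )

    eps = 1e-9 * (mu2 - mu1)
    a, b = mu1 + eps, mu2 - eps
    fa, fb = logdiff(a), logdiff(b)
    if fa == 0.0:
        return float(a)
    if fb == 0.0:
        return float(b)
    if np.sign(fa) == np.sign(fb):
        raise ValueError("no Bayes boundary between the component means (pathological fit)")
    return float(optimize.brentq(logdiff, a, b, xtol=1e-12))


def critical_radius(grid: EsomGrid, seed: int = 0, multiplier: float = 1.0) -> RadiusEstimate:
    """Estimate the critical generative radius from a trained grid.

    Collects Gabriel-edge lengths between occupied-BMU prototypes, fits
    the bimodal mixture, and returns the Bayes boundary (scaled by
    ``multiplier``) as the radius.  On any degeneracy — too few
    heights, zero variance, component collapse, or no boundary — the
    radius falls back to the median height and the estimate is flagged.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    prototypes = grid.occupied_prototypes()
    prototypes = np.unique(prototypes, axis=0)
    if prototypes.shape[0] < 2:
        raise ValueError("need at least 2 distinct occupied BMU prototypes")
    edges = gabriel_graph(prototypes)
    diffs = prototypes[edges[:, 0]] - prototypes[edges[:, 1]]
    heights = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))

    gmm: GmmFit | None = None
    t_au: float | None = None
    degenerate = False
    try:
        gmm = fit_bimodal_gmm(heights, seed=seed)
        if gmm.degenerate:
            degenerate = True
        else:
            t_au = bayes_boundary(gmm)
    except (DegenerateFitError, ValueError):
        degenerate = True

    if degenerate or t_au is None:
        r = float(np.median(heights)) * multiplier
        degenerate = True
    else:
        r = float(t_au) * multiplier
    if r <= 0:
        # all-zero heights cannot happen after dedup, but guard anyway
        raise ValueError("estimated radius is not positive")
    return RadiusEstimate(
        au_heights=heights, gmm=gmm, t_au=t_au, r=r, degenerate=degenerate, edges=edges
    )
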