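"""Bootstrap overfitting threshold, stopping search, and the driver.

The error-control idea: permuted control variables are class-irrelevant
by construction, so any systematic advantage of original over permuted
selection counts beyond sampling noise signals inflation of random
effects.  The tolerance for that advantage is estimated once, on the
unaugmented control-carrying data, as the 95th percentile ``L_delta``
of the bootstrap distribution of paired count differences
``b_sample - a_sample`` (``b`` = original counts, ``a`` = permuted
counts).  Augmentation is then increased one level at a time — each
level generated fresh from the unaugmented data, never cumulatively —
until some variable's count difference over its own counterpart,
``delta_I_j``, exceeds ``L_delta``; the recommended level is the last
one that stayed below, with 0 meaning "do not augment".
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .augment import DEFAULT_STRATA, GeneratorConfig, augment_dataset, engineer_controls
from .dataset import RunReport, TabularDataset
from .esom import DEFAULT_COLS, DEFAULT_EPOCHS, DEFAULT_ROWS, train_esom
from .radius import critical_radius
from .selection import (
    DEFAULT_ALPHA,
    DEFAULT_MAX_ITER,
    DEFAULT_TREES,
    SelectionProfile,
    delta_importance,
    selection_frequencies,
)

logger = logging.getLogger("esomaug")

DEFAULT_N_BOOTSTRAP = 100_000
DEFAULT_QUANTILE = 0.95
DEFAULT_MAX_LEVEL = 10


@dataclass
class ErrorThreshold:
    """Bootstrap 95th-percentile threshold on count differences."""

    a: np.ndarray  # selection counts of permuted variables
    b: np.ndarray  # selection counts of original variables
    n_bootstrap: int
    q: float
    l_delta: float
    delta_summary: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "l_delta": float(self.l_delta),
            "q": float(self.q),
            "n_bootstrap": int(self.n_bootstrap),
            "a_counts": self.a.tolist(),
            "b_counts": self.b.tolist(),
            "delta_summary": self.delta_summary,
            "seed": int(self.seed),
        }


@dataclass
class StoppingResult:
    """Outcome of the stepwise augmentation search."""

    n_gen_per_data: int  # 0 = do not augment
    trace: list[dict]  # per level: {level, max_delta, argmax, exceeded}
    threshold: ErrorThreshold
    capped: bool = False

    def to_dict(self) -> dict:
        return {
            "n_gen_per_data": int(self.n_gen_per_data),
            "capped": bool(self.capped),
            "trace": self.trace,
            "threshold": self.threshold.to_dict(),
        }


def bootstrap_threshold(
    a: np.ndarray,
    b: np.ndarray,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    q: float = DEFAULT_QUANTILE,
    seed: int = 0,
) -> ErrorThreshold:
    """Empirical q-quantile of ``b_sample - a_sample`` over
    ``n_bootstrap`` paired resamples drawn with replacement."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("count vectors must be non-empty")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if n_bootstrap < 1000:
        raise ValueError("n_bootstrap must be >= 1000")
    rng = np.random.default_rng(seed)
    delta = b[rng.integers(0, b.size, n_bootstrap)] - a[rng.integers(0, a.size, n_bootstrap)]
    l_delta = float(np.quantile(delta, q))
    summary = {
        "mean": float(delta.mean()),
        "sd": float(delta.std(ddof=0)),
        "min": float(delta.min()),
        "max": float(delta.max()),
        "quantiles": {
            "0.05": float(np.quantile(delta, 0.05)),
            "0.50": float(np.quantile(delta, 0.50)),
            "0.95": float(np.quantile(delta, 0.95)),
        },
    }
    return ErrorThreshold(
        a=a, b=b, n_bootstrap=n_bootstrap, q=q, l_delta=l_delta, delta_summary=summary, seed=seed
    )


def find_stopping(
    data: TabularDataset,
    r: float,
    threshold: ErrorThreshold,
    runs: int = 100,
    max_level: int = DEFAULT_MAX_LEVEL,
    seed: int = 0,
    strata: tuple = DEFAULT_STRATA,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    n_trees: int = DEFAULT_TREES,
) -> StoppingResult:
    """Largest augmentation level whose count differences stay below
    the threshold.

    ``data`` must already carry engineered controls.  Each candidate
    level augments the *unaugmented* control-carrying table afresh,
    recomputes selection frequencies, and compares every original
    variable's ``delta_I_j`` (count minus counterpart count) against
    ``threshold.l_delta``.  The first exceeding level stops the search;
    the recommendation is that level minus one (0 = do not augment).
    If no level up to ``max_level`` exceeds, the recommendation is
    ``max_level`` with the ``capped`` flag set.
    """
    if not data.counterpart_map:
        raise ValueError("dataset must carry engineered controls")
    if r <= 0:
        raise ValueError("radius must be positive")
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    level_seeds = np.random.SeedSequence(seed).generate_state(2 * max_level) % (2**31)
    trace: list[dict] = []
    for level in range(1, max_level + 1):
        cfg = GeneratorConfig(c=r, k=level, strata=strata, seed=int(level_seeds[2 * level - 2]))
        augmented = augment_dataset(data, cfg)
        profile = selection_frequencies(
            augmented,
            runs=runs,
            seed=int(level_seeds[2 * level - 1]),
            max_iter=max_iter,
            alpha=alpha,
            n_trees=n_trees,
        )
        delta = delta_importance(profile, data.counterpart_map)
        argmax = max(delta, key=delta.get)
        max_delta = delta[argmax]
        exceeded = bool(max_delta > threshold.l_delta)
        trace.append(
            {
                "level": level,
                "max_delta": float(max_delta),
                "argmax": argmax,
                "exceeded": exceeded,
                "delta": {k: float(v) for k, v in delta.items()},
            }
        )
        logger.info(
            "stopping search: level %d, max delta_I = %.1f (%s), threshold %.2f%s",
            level,
            max_delta,
            argmax,
            threshold.l_delta,
            " -> exceeded" if exceeded else "",
        )
        if exceeded:
            return StoppingResult(
                n_gen_per_data=level - 1, trace=trace, threshold=threshold, capped=False
            )
    return StoppingResult(
        n_gen_per_data=max_level, trace=trace, threshold=threshold, capped=True
    )


@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs, with one master seed.

    All stage seeds are derived deterministically from ``seed``, so a
    single integer reproduces an entire run.
    """

    seed: int = 0
    # structure learning
    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    epochs: int = DEFAULT_EPOCHS
    topology: str = "toroidal"
    radius_multiplier: float = 1.0
    # selection
    runs: int = 100
    max_iter: int = DEFAULT_MAX_ITER
    alpha: float = DEFAULT_ALPHA
    n_trees: int = DEFAULT_TREES
    # error control
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP
    q: float = DEFAULT_QUANTILE
    max_level: int = DEFAULT_MAX_LEVEL
    strata: tuple = DEFAULT_STRATA

    def stage_seeds(self) -> dict[str, int]:
        names = ("esom", "controls", "baseline_selection", "bootstrap", "stopping", "generation")
        state = np.random.SeedSequence(self.seed).generate_state(len(names)) % (2**31)
        return {name: int(s) for name, s in zip(names, state)}


def safe_augment(
    data: TabularDataset, config: PipelineConfig | None = None
) -> tuple[TabularDataset, RunReport]:
    """End-to-end safe augmentation of a raw dataset.

    Order of stages: (1) ESOM structure learning on the original table
    and critical-radius estimation; (2) injection of engineered
    controls; (3) baseline selection frequencies and the bootstrap
    threshold; (4) stepwise stopping search; (5) final generation of
    the recommended number of points per original row on the table
    *without* engineered columns.  Returns the (possibly unchanged)
    dataset and a machine-readable report.
    """
    config = config or PipelineConfig()
    data.validate()
    data.require_classes(2)
    seeds = config.stage_seeds()
    report = RunReport({"config": {k: v for k, v in vars(config).items()}, "stage_seeds": seeds})
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    grid = train_esom(
        data,
        rows=config.rows,
        cols=config.cols,
        epochs=config.epochs,
        seed=seeds["esom"],
        topology=config.topology,
    )
    estimate = critical_radius(grid, seed=seeds["esom"], multiplier=config.radius_multiplier)
    timings["structure_learning"] = time.perf_counter() - t0
    report.update(radius=estimate.to_dict())
    logger.info("critical radius r = %.4f%s", estimate.r, " (degenerate fallback)" if estimate.degenerate else "")

    t0 = time.perf_counter()
    controlled = engineer_controls(data, seed=seeds["controls"])
    baseline = selection_frequencies(
        controlled,
        runs=config.runs,
        seed=seeds["baseline_selection"],
        max_iter=config.max_iter,
        alpha=config.alpha,
        n_trees=config.n_trees,
    )
    a = baseline.counts_for(controlled.engineered_feature_names())
    b = baseline.counts_for(controlled.original_feature_names())
    threshold = bootstrap_threshold(
        a, b, n_bootstrap=config.n_bootstrap, q=config.q, seed=seeds["bootstrap"]
    )
    timings["baseline_and_threshold"] = time.perf_counter() - t0
    logger.info("bootstrap threshold L_delta = %.2f", threshold.l_delta)

    t0 = time.perf_counter()
    stopping = find_stopping(
        controlled,
        r=estimate.r,
        threshold=threshold,
        runs=config.runs,
        max_level=config.max_level,
        seed=seeds["stopping"],
        strata=config.strata,
        max_iter=config.max_iter,
        alpha=config.alpha,
        n_trees=config.n_trees,
    )
    timings["stopping_search"] = time.perf_counter() - t0
    report.update(stopping=stopping.to_dict(), baseline_profile=baseline.to_frame().to_dict("list"))

    recommendation = stopping.n_gen_per_data
    t0 = time.perf_counter()
    if recommendation >= 1:
        cfg = GeneratorConfig(
            c=estimate.r, k=recommendation, strata=config.strata, seed=seeds["generation"]
        )
        augmented = augment_dataset(data, cfg)  # original columns only, no controls
        do_not_augment = False
    else:
        augmented = data.copy()
        do_not_augment = True
    timings["generation"] = time.perf_counter() - t0
    report.update(
        recommendation=recommendation,
        do_not_augment=do_not_augment,
        capped=stopping.capped,
        timings_s={k: round(v, 3) for k, v in timings.items()},
        n_rows_in=data.n_rows,
        n_rows_out=augmented.n_rows,
        # the recommendation counts levels below the first exceedance;
        # level 0 is a valid "do not augment" outcome
        semantics="largest n_gen_per_data not surpassing L_delta; 0 = do not augment",
        importance_scale="confirmed-selection counts over repeated runs",
    )
    logger.info(
        "recommendation: n_gen_per_data = %d%s",
        recommendation,
        " (do not augment)" if do_not_augment else "",
    )
    return augmented, report
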