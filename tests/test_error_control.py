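import itertools

import numpy as np
import pytest

from esomaug import (
    ErrorThreshold,
    PipelineConfig,
    TabularDataset,
    bootstrap_threshold,
    engineer_controls,
    find_stopping,
    safe_augment,
)

from conftest import FAST_SELECT


def exact_difference_quantile(a, b, q):
    """Inverse CDF of the fully enumerated difference distribution
    b_i - a_j (all pairs equally likely)."""
    diffs = np.sort([bi - ai for ai, bi in itertools.product(a, b)])
    cdf = np.arange(1, len(diffs) + 1) / len(diffs)
    return float(diffs[np.searchsorted(cdf, q)])


def _stub_threshold(l_delta: float) -> ErrorThreshold:
    return ErrorThreshold(
        a=np.zeros(3),
        b=np.zeros(3),
        n_bootstrap=1000,
        q=0.95,
        l_delta=l_delta,
        delta_summary={},
        seed=0,
    )


@pytest.fixture
def signal_dataset(labelcopy_dataset):
    return engineer_controls(labelcopy_dataset, seed=0)


class TestBootstrapThreshold:
    def test_constant_inputs_give_zero(self):
        thr = bootstrap_threshold(np.full(5, 4.0), np.full(5, 4.0), n_bootstrap=1000, seed=0)
        assert thr.l_delta == 0.0

    def test_degenerate_unit_difference(self):
        thr = bootstrap_threshold(np.zeros(4), np.ones(4), n_bootstrap=1000, seed=0)
        assert thr.l_delta == 1.0

    def test_matches_exact_enumeration(self):
        a, b = [0, 1, 2], [3, 4, 5]
        thr = bootstrap_threshold(np.array(a), np.array(b), n_bootstrap=100_000, seed=1)
        # exact 9-outcome distribution: Q0.95 sits firmly inside the
        # topmost atom, so Monte-Carlo agreement is exact
        assert thr.l_delta == pytest.approx(exact_difference_quantile(a, b, 0.95), abs=1e-9)

    def test_l_delta_within_range_bounds(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 50, size=12).astype(float)
        b = rng.integers(0, 50, size=12).astype(float)
        thr = bootstrap_threshold(a, b, n_bootstrap=10_000, seed=4)
        assert b.min() - a.max() <= thr.l_delta <= b.max() - a.min()

    def test_quantile_monotone_in_q(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 20, size=8).astype(float)
        b = rng.integers(0, 20, size=8).astype(float)
        levels = [bootstrap_threshold(a, b, n_bootstrap=10_000, q=q, seed=6).l_delta
                  for q in (0.5, 0.75, 0.9, 0.95, 0.99)]
        assert all(x <= y for x, y in zip(levels, levels[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_threshold(np.array([]), np.ones(3))
        with pytest.raises(ValueError):
            bootstrap_threshold(np.ones(3), np.ones(3), n_bootstrap=10)
        with pytest.raises(ValueError):
            bootstrap_threshold(np.ones(3), np.ones(3), q=1.5)


class TestFindStopping:
    def test_exceedance_at_level_one_means_do_not_augment(self, signal_dataset):
        # a negative threshold is exceeded by any delta, including 0
        result = find_stopping(
            signal_dataset,
            r=1.0,
            threshold=_stub_threshold(-1.0),
            runs=2,
            max_level=4,
            seed=0,
            **FAST_SELECT,
        )
        assert result.n_gen_per_data == 0
        assert not result.capped
        assert result.trace[0]["exceeded"]

    def test_threshold_never_reached_caps_at_max_level(self, signal_dataset):
        result = find_stopping(
            signal_dataset,
            r=1.0,
            threshold=_stub_threshold(1e9),
            runs=2,
            max_level=3,
            seed=0,
            **FAST_SELECT,
        )
        assert result.n_gen_per_data == 3
        assert result.capped
        assert [t["level"] for t in result.trace] == [1, 2, 3]

    def test_monotone_in_threshold(self, signal_dataset):
        kwargs = dict(runs=2, max_level=3, seed=1, max_iter=6, n_trees=32)
        levels = [
            find_stopping(signal_dataset, r=1.0, threshold=_stub_threshold(l), **kwargs).n_gen_per_data
            for l in (-1.0, 0.5, 1e9)
        ]
        assert levels[0] <= levels[1] <= levels[2]

    def test_requires_controls_and_valid_radius(self, labelcopy_dataset, signal_dataset):
        with pytest.raises(ValueError):
            find_stopping(labelcopy_dataset, r=1.0, threshold=_stub_threshold(0), runs=1)
        with pytest.raises(ValueError):
            find_stopping(signal_dataset, r=-1.0, threshold=_stub_threshold(0), runs=1)


class TestSafeAugment:
    @pytest.fixture
    def fast_config(self):
        return PipelineConfig(
            seed=3,
            rows=8,
            cols=12,
            epochs=6,
            runs=4,
            max_iter=8,
            n_trees=48,
            n_bootstrap=1000,
            max_level=2,
        )

    def test_output_carries_no_engineered_columns(self, labelcopy_dataset, fast_config):
        augmented, report = safe_augment(labelcopy_dataset, fast_config)
        assert augmented.engineered_feature_names() == []
        assert augmented.feature_names == labelcopy_dataset.feature_names
        assert "recommendation" in report

    def test_recommended_level_scales_rows_and_proportions(self, labelcopy_dataset, fast_config):
        augmented, report = safe_augment(labelcopy_dataset, fast_config)
        g = report["recommendation"]
        assert augmented.n_rows == labelcopy_dataset.n_rows * (1 + g)
        original_share = np.mean(labelcopy_dataset.labels == 1)
        assert np.mean(augmented.labels == 1) == pytest.approx(original_share)

    def test_zero_recommendation_returns_input_unchanged(
        self, labelcopy_dataset, fast_config, monkeypatch
    ):
        import esomaug.error_control as ec

        def forced_stop(data, r, threshold, **kwargs):
            return ec.StoppingResult(
                n_gen_per_data=0, trace=[], threshold=threshold, capped=False
            )

        monkeypatch.setattr(ec, "find_stopping", forced_stop)
        augmented, report = safe_augment(labelcopy_dataset, fast_config)
        assert report["do_not_augment"] is True
        np.testing.assert_array_equal(augmented.values, labelcopy_dataset.values)

    def test_single_class_rejected(self, fast_config):
        data = TabularDataset(
            values=np.random.default_rng(0).standard_normal((10, 3)),
            labels=np.ones(10, dtype=int),
            feature_names=["a", "b", "c"],
        )
        with pytest.raises(Exception):
            safe_augment(data, fast_config)
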