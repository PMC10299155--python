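"""Dwell extraction, censoring, exponential MLE/histogram fits."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smg4 import choose_components, extract_dwells, fit_exponential
from smg4.hmm import HmmModel, IdealizedTrajectory


def _model2() -> HmmModel:
    return HmmModel(
        n_states=2,
        means=np.array([0.0, 500.0]),
        sds=np.array([100.0, 100.0]),
        transition_matrix=np.array([[0.95, 0.05], [0.06, 0.94]]),
        initial_probs=np.array([0.5, 0.5]),
        log_likelihood=0.0,
        model_score=0.0,
        n_params=7,
        n_frames=0,
        converged=True,
    )


def _ideal(path, dt=0.1, mid="m0"):
    return IdealizedTrajectory(np.asarray(path), _model2(), mid, dt)


class TestExtractDwells:
    def test_hand_enumerated_example(self):
        table = extract_dwells([_ideal([0, 0, 1, 1, 1, 0, 0, 1])])
        interior = table.table[
            ~(table.table.censored_left | table.table.censored_right)
        ]
        assert len(interior) == 2
        bound = interior[interior.state == 1]
        unbound = interior[interior.state == 0]
        assert bound.duration_s.tolist() == [pytest.approx(0.3)]
        assert unbound.duration_s.tolist() == [pytest.approx(0.2)]
        ends = table.table[table.table.censored_left | table.table.censored_right]
        assert len(ends) == 2

    def test_constant_path_single_censored_dwell(self):
        table = extract_dwells([_ideal([1] * 50)])
        assert len(table.table) == 1
        row = table.table.iloc[0]
        assert row.censored_left and row.censored_right
        assert table.durations(1).size == 0  # nothing left for fitting

    def test_dwells_tile_segment_exactly(self):
        rng = np.random.default_rng(4)
        ideals = [
            _ideal(rng.integers(0, 2, 200), mid=f"m{i}") for i in range(10)
        ]
        table = extract_dwells(ideals)
        for mid, group in table.table.groupby("molecule_id"):
            assert group.duration_s.sum() == pytest.approx(200 * 0.1)

    def test_dwell_count_matches_truth_transitions(self, ensemble, analysis):
        # on high-SNR synthetic data the idealized dwell count tracks the
        # ground-truth frame-discretized transition count closely
        _, truths = ensemble
        true_transitions = sum(
            int(np.count_nonzero(np.diff(g.true_state_path[300:])))
            for g in truths
        )
        n_dwells = len(analysis.dwells.table)
        assert n_dwells == pytest.approx(true_transitions, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extract_dwells([])


class TestFitExponentialMle:
    def test_untruncated_mle_is_reciprocal_mean(self):
        fit = fit_exponential([1.0, 2.0, 3.0], 1, method="mle", t_min=0.0,
                              min_dwells=3)
        assert fit.rate == pytest.approx(0.5, rel=1e-12)

    def test_rate_recovery_with_se(self, rng):
        d = rng.exponential(1 / 0.67, 5000)
        fit = fit_exponential(d, 1, method="mle", t_min=0.0)
        assert abs(fit.rate - 0.67) < 3 * fit.se

    def test_truncation_removes_frame_bias(self, rng):
        # dwells below one frame are unobservable; pretending otherwise
        # biases the rate low, the truncated likelihood does not
        d = rng.exponential(1 / 5.0, 40000)
        d = d[d >= 0.1]
        biased = fit_exponential(d, 1, method="mle", t_min=0.0)
        unbiased = fit_exponential(d, 1, method="mle", t_min=0.1)
        assert biased.rate < 4.0  # strongly biased low
        assert unbiased.rate == pytest.approx(5.0, rel=0.05)

    def test_two_component_mixture_recovery(self, rng):
        d = np.concatenate(
            [rng.exponential(1 / 0.2, 2000), rng.exponential(1 / 5.0, 2000)]
        )
        fit = fit_exponential(d, 2, method="mle", t_min=0.0)
        assert fit.rates[0] == pytest.approx(0.2, rel=0.15)
        assert fit.rates[1] == pytest.approx(5.0, rel=0.15)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_exponential([1.0] * 5, 1)


class TestFitExponentialHistogram:
    def test_histogram_and_mle_agree(self, rng):
        d = rng.exponential(1 / 0.67, 5000)
        fm = fit_exponential(d, 1, method="mle", t_min=0.0)
        fh = fit_exponential(d, 1, method="histogram_lsq", bin_width=0.1)
        combined_se = np.hypot(fm.se, fh.se)
        assert abs(fm.rate - fh.rate) < 2 * combined_se

    def test_histogram_reports_rss_and_bins(self, rng):
        d = rng.exponential(1.0, 1000)
        fh = fit_exponential(d, 1, method="histogram_lsq", bin_width=0.2)
        assert fh.rss is not None and fh.rss >= 0
        assert fh.n_bins >= 4


class TestChooseComponents:
    @pytest.mark.parametrize("method", ["mle", "histogram_lsq"])
    def test_single_exponential_prefers_one_component(self, method):
        hits = 0
        for seed in range(10):
            d = np.random.default_rng(seed).exponential(1 / 0.67, 1000)
            kwargs = {"t_min": 0.0} if method == "mle" else {"bin_width": 0.1}
            fit = choose_components(d, alpha=0.05, method=method, **kwargs)
            hits += fit.n_components == 1
        assert hits >= 9

    def test_clear_mixture_prefers_two_components(self):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            d = np.concatenate(
                [r.exponential(1 / 0.2, 1000), r.exponential(1 / 5.0, 1000)]
            )
            fit = choose_components(d, alpha=0.05, method="mle", t_min=0.0)
            hits += fit.n_components == 2
        assert hits == 5

    def test_below_floor_errors(self):
        with pytest.raises(ValueError, match="at least"):
            choose_components([0.5] * 4)


@settings(max_examples=20, deadline=None)
@given(rate=st.floats(0.2, 5.0), n=st.integers(50, 300))
def test_mle_equals_reciprocal_mean_property(rate, n):
    """Without truncation the exponential MLE is exactly 1/mean."""
    d = np.random.default_rng(99).exponential(1 / rate, n)
    fit = fit_exponential(d, 1, method="mle", t_min=0.0)
    assert fit.rate == pytest.approx(1 / d.mean(), rel=1e-12)
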