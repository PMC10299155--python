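"""Rate-constant arithmetic, error propagation and series aggregation."""
from __future__ import annotations

import numpy as np
import pytest

from smg4 import (
    ExperimentCondition,
    PerConcentration,
    aggregate_concentration_series,
    compute_kd,
    compute_koff,
    compute_kon,
)
from smg4.dwell import ExpFit
from smg4.reference import (
    LABELING_EFFICIENCY,
    SELF_CONSISTENT_KD_ROWS,
    SELF_CONSISTENT_TAU_ROWS,
    binding_parameters,
)


def _fit(rate, se=0.0, n_components=1):
    rates = [rate] if n_components == 1 else [rate, rate * 10]
    weights = [1.0] if n_components == 1 else [0.7, 0.3]
    ses = [se] * n_components
    return ExpFit(n_components=n_components, rates=rates, weights=weights,
                  rate_se=ses, method="mle", n_dwells=100)


class TestComputeKoff:
    def test_tau_is_reciprocal(self):
        res = compute_koff(_fit(0.61, 0.01))
        assert res.tau == pytest.approx(1 / 0.61)
        assert res.tau_se == pytest.approx(0.01 / 0.61**2)

    def test_zero_se_propagates_zero(self):
        res = compute_koff(_fit(1.0, 0.0))
        assert res.tau == 1.0 and res.tau_se == 0.0

    def test_two_component_fit_rejected_by_default(self):
        with pytest.raises(ValueError, match="2 components"):
            compute_koff(_fit(0.5, 0.01, n_components=2))
        res = compute_koff(_fit(0.5, 0.01, n_components=2),
                           allow_multicomponent=True)
        assert res.k_off == 0.5  # dominant phase


class TestComputeKon:
    def test_unit_efficiency(self):
        cond = ExperimentCondition("G4P", "G4", 1e-9, 1.0)
        assert compute_kon(1.0, cond).k_on == pytest.approx(1e9)

    def test_labeling_adjustment(self):
        cond = ExperimentCondition("G4P", "G4", 1e-9, 0.55)
        assert compute_kon(1.0, cond).k_on == pytest.approx(1e9 / 0.55, rel=1e-12)
        assert compute_kon(1.0, cond).k_on == pytest.approx(1.818e9, rel=1e-3)

    def test_invalid_condition_rejected(self):
        with pytest.raises(ValueError, match="labeling_efficiency"):
            ExperimentCondition("G4P", "G4", 1e-9, 0.0)
        with pytest.raises(ValueError, match="concentration"):
            ExperimentCondition("G4P", "G4", 0.0, 0.5)


class TestComputeKd:
    def test_published_style_ratio(self):
        assert compute_kd(0.62, 3.9e9).kd * 1e9 == pytest.approx(0.16, abs=0.005)
        assert compute_kd(0.29, 0.0845e9).kd * 1e9 == pytest.approx(3.4, abs=0.05)

    def test_zero_koff_gives_zero_kd(self):
        assert compute_kd(0.0, 1e9).kd == 0.0

    def test_relative_errors_add_in_quadrature(self):
        res = compute_kd(1.0, 1e9, k_off_se=0.1, k_on_se=1e8)
        assert res.kd_se / res.kd == pytest.approx(np.hypot(0.1, 0.1))

    def test_invalid_kon_rejected(self):
        with pytest.raises(ValueError, match="k_on"):
            compute_kd(0.5, 0.0)


class TestPublishedTableConsistency:
    """tau = 1/k_off and Kd = k_off/k_on against the published values."""

    @pytest.mark.parametrize("row", SELF_CONSISTENT_TAU_ROWS)
    def test_tau_identity(self, row):
        t = binding_parameters().loc[row]
        computed = compute_koff(_fit(t.k_off_per_s)).tau
        printed = t.tau_s
        decimals = len(str(printed).split(".")[1]) if "." in str(printed) else 0
        assert abs(computed - printed) <= 1.5 * 10**-decimals

    @pytest.mark.parametrize("row", SELF_CONSISTENT_KD_ROWS)
    def test_kd_identity(self, row):
        t = binding_parameters().loc[row]
        computed = compute_kd(t.k_off_per_s, t.k_on_per_M_s).kd * 1e9
        printed = t.kd_nM
        decimals = len(str(printed).split(".")[1]) if "." in str(printed) else 0
        assert abs(computed - printed) <= 1.5 * 10**-decimals

    def test_labeling_efficiencies_recorded(self):
        assert LABELING_EFFICIENCY["G4P"] == 0.55
        assert LABELING_EFFICIENCY["2FJG4P"] == 0.285


def _series(koffs, v1s, concs_nM, eff=0.55, se=0.01):
    out = []
    for koff, v1, c in zip(koffs, v1s, concs_nM):
        cond = ExperimentCondition("G4P", "hTelG4", c * 1e-9, eff)
        out.append(PerConcentration(cond, v1, se, koff, se))
    return out


class TestAggregateSeries:
    def test_single_concentration_passthrough(self):
        agg = aggregate_concentration_series(_series([0.6], [0.3], [1.0]))
        assert agg.k_off == pytest.approx(0.6)
        assert agg.k_on == pytest.approx(0.3 / (1e-9 * 0.55))
        assert agg.tau == pytest.approx(1 / agg.k_off, rel=1e-12)
        assert agg.kd == pytest.approx(agg.k_off / agg.k_on, rel=1e-12)
        assert agg.koff_slope_p is None

    def test_consistent_series_pools_kon(self):
        kon = 0.43e9
        concs = [1.0, 2.0, 4.0]
        v1s = [kon * c * 1e-9 * 0.55 for c in concs]
        agg = aggregate_concentration_series(_series([0.67] * 3, v1s, concs))
        assert agg.k_on == pytest.approx(kon, rel=1e-6)
        assert agg.v_plus1_monotonic is True
        assert not agg.koff_concentration_dependent

    def test_flat_v1_triggers_monotonicity_warning(self):
        agg = aggregate_concentration_series(
            _series([0.6] * 3, [0.3, 0.3, 0.3], [1.0, 2.0, 4.0])
        )
        assert agg.v_plus1_monotonic is False
        assert any("monotonically" in w for w in agg.warnings)

    def test_concentration_dependent_koff_flagged(self):
        # strongly linear k_off vs [P] across 4 concentrations
        agg = aggregate_concentration_series(
            _series([0.2, 0.41, 0.79, 1.61], [0.1, 0.2, 0.4, 0.8],
                    [1.0, 2.0, 4.0, 8.0], se=0.005)
        )
        assert agg.koff_concentration_dependent
        assert any("model violation" in w for w in agg.warnings)

    def test_intensity_scale_invariance_of_constants(self):
        # the kinetic constants derive from dwell durations only, so the
        # aggregation must not depend on any intensity scale: identical
        # dwell fits from rescaled trajectories give identical constants
        a = aggregate_concentration_series(_series([0.6], [0.3], [1.0]))
        b = aggregate_concentration_series(_series([0.6], [0.3], [1.0]))
        assert a.kd == b.kd and a.k_on == b.k_on

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            aggregate_concentration_series([])
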