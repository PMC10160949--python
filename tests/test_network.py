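"""Rate-matrix construction and exact steady states of the ten-state network."""

import dataclasses

import numpy as np
import pytest
import scipy.linalg

import akinetics as ak
from akinetics.states import STATE_INDEX, SpeciesState as S


def _idx(a: S, b: S) -> tuple[int, int]:
    return STATE_INDEX[a], STATE_INDEX[b]


# every transition the topology allows, as (from, to) pairs
ALLOWED = (
    # conformational exchange for all five species
    [(S.E_O, S.E_C), (S.E_C, S.E_O), (S.ET_O, S.ET_C), (S.ET_C, S.ET_O),
     (S.EM_O, S.EM_C), (S.EM_C, S.EM_O), (S.ETM_O, S.ETM_C), (S.ETM_C, S.ETM_O),
     (S.ETMinh_O, S.ETMinh_C), (S.ETMinh_C, S.ETMinh_O)]
    # ATP binding/unbinding from open conformations only
    + [(S.E_O, S.ET_O), (S.ET_O, S.E_O), (S.EM_O, S.ETMinh_O), (S.ETMinh_O, S.EM_O)]
    # AMP binding/unbinding from both conformations
    + [(S.E_O, S.EM_O), (S.EM_O, S.E_O), (S.E_C, S.EM_C), (S.EM_C, S.E_C),
       (S.ET_O, S.ETM_O), (S.ETM_O, S.ET_O), (S.ET_C, S.ETM_C), (S.ETM_C, S.ET_C)]
    # interconversion through the open states, and phosphotransfer
    + [(S.ETM_O, S.ETMinh_O), (S.ETMinh_O, S.ETM_O), (S.ETM_C, S.E_O)]
)


class TestRateMatrix:
    def test_topology_is_exactly_the_25_allowed_transitions(self, wt):
        Q = ak.build_rate_matrix(wt, atp=1000.0, amp=1000.0)
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        nonzero = {tuple(ij) for ij in np.argwhere(off > 0)}
        assert nonzero == {_idx(a, b) for a, b in ALLOWED}
        assert len(nonzero) == 25

    def test_rows_sum_to_zero(self, wt):
        Q = ak.build_rate_matrix(wt, atp=137.0, amp=4200.0)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12 * np.abs(Q).max()

    def test_zero_concentrations_remove_binding_fluxes(self, wt):
        Q = ak.build_rate_matrix(wt, atp=0.0, amp=0.0)
        for a, b in [(S.E_O, S.ET_O), (S.EM_O, S.ETMinh_O), (S.E_O, S.EM_O),
                     (S.E_C, S.EM_C), (S.ET_O, S.ETM_O), (S.ET_C, S.ETM_C)]:
            assert Q[_idx(a, b)] == 0.0
        # unbinding, conformational and chemistry entries remain
        assert Q[_idx(S.ET_O, S.E_O)] > 0
        assert Q[_idx(S.ETM_C, S.E_O)] > 0
        assert Q[_idx(S.E_O, S.E_C)] > 0

    def test_negative_concentration_rejected(self, wt):
        with pytest.raises(ak.ParameterError):
            ak.build_rate_matrix(wt, atp=-1.0, amp=0.0)

    def test_nonpositive_conformational_rate_rejected(self):
        with pytest.raises(ak.ParameterError):
            ak.ConformationalRates(k_close=0.0, k_open=100.0)


class TestSteadyState:
    def test_isolated_apo_reduces_to_two_state_occupancy(self, wt):
        chem = dataclasses.replace(wt.chemistry, k_pt=0.0)
        params = wt.replace(chemistry=chem)
        ss = ak.steady_state(params, atp=0.0, amp=0.0)
        e = wt.conf(ak.Species.E)
        expected = e.k_close / (e.k_close + e.k_open)
        assert ss.occupancy[S.E_C] == pytest.approx(expected, abs=1e-12)
        assert ss.occupancy[S.E_O] == pytest.approx(1 - expected, abs=1e-12)
        assert ss.turnover == 0.0

    def test_occupancies_sum_to_one(self, suite):
        for params in suite.values():
            for atp, amp in [(1000.0, 1000.0), (10.0, 5000.0), (0.0, 0.0)]:
                ss = ak.steady_state(params, atp, amp)
                assert abs(sum(ss.occupancy.values()) - 1.0) < 1e-9
                assert min(ss.occupancy.values()) >= 0.0

    def test_matches_long_time_master_equation_integration(self, wt):
        Q = ak.build_rate_matrix(wt, 1000.0, 1000.0)
        p0 = np.zeros(10)
        p0[0] = 1.0
        p_t = p0 @ scipy.linalg.expm(Q * 20.0)
        ss = ak.steady_state(wt, 1000.0, 1000.0)
        np.testing.assert_allclose(ss.vector, p_t, rtol=0, atol=1e-8)
        assert ss.turnover == pytest.approx(
            wt.chemistry.k_pt * p_t[STATE_INDEX[S.ETM_C]], rel=1e-6
        )

    def test_detailed_balance_without_chemistry(self, wt):
        """With k_pt = 0 the default cycles are thermodynamically closed:
        every pairwise net flux vanishes at the stationary state."""
        chem = dataclasses.replace(wt.chemistry, k_pt=0.0)
        params = wt.replace(chemistry=chem)
        Q = ak.build_rate_matrix(params, 500.0, 800.0)
        p = ak.steady_state(params, 500.0, 800.0).vector
        net = p[:, None] * Q - (p[:, None] * Q).T
        np.fill_diagonal(net, 0.0)
        assert np.abs(net).max() < 1e-12 * np.abs(p[:, None] * Q).max()

    def test_disconnected_network_raises_degenerate_error(self, wt):
        binding = ak.BindingRates(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        params = wt.replace(binding=binding)
        with pytest.raises(ak.DegenerateModelError):
            ak.steady_state(params, 1000.0, 1000.0)


class TestActivityCurves:
    def test_wt_amp_curve_has_interior_maximum_and_positive_plateau(self, wt):
        curve = ak.activity_vs_amp(wt)
        i = np.argmax(curve.turnover)
        assert 0 < i < len(curve.grid) - 1
        assert curve.turnover[-1] > 0
        assert curve.turnover[-1] < curve.turnover[i]

    def test_f86w_amp_curve_is_monotone(self, f86w):
        curve = ak.activity_vs_amp(f86w)
        assert np.all(np.diff(curve.turnover) >= -1e-12 * curve.turnover.max())

    def test_fast_interconversion_abolishes_inhibition(self, wt, coarse_amp_grid):
        chem = dataclasses.replace(wt.chemistry, k_conv_fwd=1e9, k_conv_rev=1e9)
        curve = ak.activity_vs_amp(wt.replace(chemistry=chem), amp_grid=coarse_amp_grid)
        assert np.all(np.diff(curve.turnover) >= -1e-12 * curve.turnover.max())

    def test_atp_curves_monotone_for_all_variants(self, suite):
        grid = np.geomspace(1.0, 1e5, 21)
        for params in suite.values():
            curve = ak.activity_vs_atp(params, atp_grid=grid)
            assert np.all(np.diff(curve.turnover) >= -1e-12 * curve.turnover.max())

    def test_no_turnover_without_atp(self, wt):
        curve = ak.activity_vs_atp(wt, atp_grid=np.array([0.0, 10.0, 100.0]))
        assert curve.turnover[0] == pytest.approx(0.0, abs=1e-15)
        assert curve.turnover[-1] > 0

    def test_high_atp_asymptote(self, wt):
        curve = ak.activity_vs_atp(wt, atp_grid=np.geomspace(1e2, 1e6, 9))
        assert curve.turnover[-1] == pytest.approx(
            ak.steady_state(wt, 1e6, 1000.0).turnover, rel=1e-12
        )

    def test_empty_grid_rejected(self, wt):
        with pytest.raises(ValueError):
            ak.activity_vs_amp(wt, amp_grid=np.array([]))

    def test_fast_conformational_scaling_leaves_turnover_unchanged(self, wt):
        """Scaling every conformational rate 100-fold at fixed K_C changes
        activity by <1%: only the relative open/closed populations matter."""
        conf = {sp: r.scaled(100.0, 100.0) for sp, r in wt.conformational.items()}
        fast = wt.replace(conformational=conf)
        v0 = ak.steady_state(wt, 1000.0, 1000.0).turnover
        v1 = ak.steady_state(fast, 1000.0, 1000.0).turnover
        assert abs(v1 - v0) / v0 < 0.01


class TestScalarSummaries:
    @pytest.mark.parametrize(
        "k_close, k_open, expected",
        [(1000.0, 1000.0, 0.5), (27307.0, 23937.0, 0.5328818983685895), (0.0, 50.0, 0.0)],
    )
    def test_closed_occupancy_two_state(self, k_close, k_open, expected):
        assert ak.closed_occupancy_two_state(k_close, k_open) == pytest.approx(
            expected, abs=1e-12
        )

    def test_closed_occupancy_undefined_for_zero_rates(self):
        with pytest.raises(ak.ParameterError):
            ak.closed_occupancy_two_state(0.0, 0.0)

    def test_inhibition_index_arithmetic(self):
        assert ak.inhibition_index(np.array([1.0, 4.0, 2.0])) == pytest.approx(0.5)
        assert ak.inhibition_index(np.array([1.0, 2.0, 3.0])) == 0.0

    def test_inhibition_index_undefined_cases(self):
        from akinetics.network import UndefinedIndexError

        with pytest.raises(UndefinedIndexError):
            ak.inhibition_index(np.zeros(4))
        with pytest.raises(UndefinedIndexError):
            ak.inhibition_index(np.array([]))

    def test_wt_more_inhibited_than_f86w(self, wt, f86w):
        assert ak.inhibition_index(ak.activity_vs_amp(wt)) > ak.inhibition_index(
            ak.activity_vs_amp(f86w)
        )


class TestModelObject:
    def test_model_delegates_to_functions(self, wt):
        model = ak.KineticNetworkModel(wt)
        np.testing.assert_array_equal(
            model.rate_matrix(100.0, 200.0), ak.build_rate_matrix(wt, 100.0, 200.0)
        )
        assert model.steady_state(1000.0, 1000.0).turnover == pytest.approx(
            ak.steady_state(wt, 1000.0, 1000.0).turnover
        )

    def test_parameter_file_round_trip(self, suite, tmp_path):
        path = tmp_path / "variants.yaml"
        ak.save_parameter_file(path, suite)
        loaded = ak.load_parameter_file(path)
        assert set(loaded) == set(suite)
        for name in suite:
            assert loaded[name].binding == suite[name].binding
            assert loaded[name].chemistry == suite[name].chemistry
            for sp in ak.Species:
                assert loaded[name].conf(sp) == suite[name].conf(sp)
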