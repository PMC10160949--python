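"""Photon-by-photon HMM: likelihood, Viterbi, fitting, burst histograms.

The independent oracle enumerates all 2^N hidden-state paths, with
propagators from scipy's generic matrix exponential — sharing no code with
the closed-form forward/Viterbi implementation under test.
"""

import itertools

import numpy as np
import pytest
import scipy.linalg

import akinetics as ak
from akinetics.photons import IdentifiabilityWarning


def enumerate_paths(model, traj):
    """Brute-force path sum and argmax path for small trajectories."""
    n = traj.n_photons
    Q = np.array(
        [[-model.k_close, model.k_close], [model.k_open, -model.k_open]]
    )  # states: 0=open, 1=closed
    props = [scipy.linalg.expm(Q * dt) for dt in np.diff(traj.times)]
    pi = np.array([model.k_open, model.k_close]) / (model.k_open + model.k_close)
    eff = np.array([model.E_open, model.E_closed])

    def emit(state, channel):
        return eff[state] if channel == 1 else 1.0 - eff[state]

    total = 0.0
    best_p, best_path = -1.0, None
    for path in itertools.product((0, 1), repeat=n):
        p = pi[path[0]] * emit(path[0], traj.channels[0])
        for i in range(1, n):
            p *= props[i - 1][path[i - 1], path[i]] * emit(path[i], traj.channels[i])
        total += p
        if p > best_p:
            best_p, best_path = p, np.array(path)
    return np.log(total), best_path


def random_case(rng, n_photons):
    k_open = 10 ** rng.uniform(1, 4.5)
    k_close = 10 ** rng.uniform(1, 4.5)
    e_open = rng.uniform(0.05, 0.45)
    e_closed = rng.uniform(e_open + 0.1, 0.95)
    model = ak.TwoStateFretModel(k_open, k_close, e_open, e_closed)
    times = np.cumsum(rng.exponential(1.0 / 10 ** rng.uniform(3, 5), n_photons))
    channels = rng.integers(0, 2, n_photons).astype(np.int8)
    return model, ak.PhotonTrajectory(times=times, channels=channels)


class TestLogLikelihood:
    def test_frozen_single_state_reduces_to_bernoulli_counts(self):
        """With closing switched off the stream is i.i.d. Bernoulli in the
        open state: logL = n_A log E_open + n_D log(1 - E_open)."""
        model = ak.TwoStateFretModel(
            k_open=100.0, k_close=1e-12, E_open=0.4, E_closed=0.9
        )
        channels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        traj = ak.PhotonTrajectory(times=np.arange(1, 11) * 1e-4, channels=channels)
        expected = 4 * np.log(0.4) + 6 * np.log(0.6)
        assert ak.log_likelihood(model, traj) == pytest.approx(expected, rel=1e-9)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            model, traj = random_case(rng, int(rng.integers(2, 9)))
            expected, _ = enumerate_paths(model, traj)
            assert ak.log_likelihood(model, traj) == pytest.approx(expected, rel=1e-10)

    def test_long_gaps_decouple_photons(self):
        """When inter-photon gaps vastly exceed the relaxation time the
        propagator rows equal the stationary distribution, so photons
        become independent draws from the stationary color mixture."""
        model = ak.TwoStateFretModel(2000.0, 3000.0, 0.3, 0.8)
        n = 40
        times = np.arange(n) * 1.0  # 1 s gaps, relaxation time 0.2 ms
        rng = np.random.default_rng(0)
        channels = rng.integers(0, 2, n).astype(np.int8)
        traj = ak.PhotonTrajectory(times=times, channels=channels)
        p = model.closed_occupancy
        p_acc = p * model.E_closed + (1 - p) * model.E_open
        expected = sum(
            np.log(p_acc if c == 1 else 1 - p_acc) for c in channels
        )
        assert ak.log_likelihood(model, traj) == pytest.approx(expected, rel=1e-12)

    def test_contradictory_pinned_efficiency_returns_neg_inf(self):
        model = ak.TwoStateFretModel(100.0, 100.0, E_open=1.0, E_closed=1.0)
        traj = ak.PhotonTrajectory(
            times=np.array([0.0, 1e-3]), channels=np.array([1, 0], dtype=np.int8)
        )
        with pytest.warns(UserWarning, match="impossible"):
            assert ak.log_likelihood(model, traj) == -np.inf

    def test_nonincreasing_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ak.PhotonTrajectory(
                times=np.array([0.0, 2e-3, 1e-3]),
                channels=np.zeros(3, dtype=np.int8),
            )


class TestViterbi:
    def test_all_acceptor_photons_map_to_closed_path(self):
        model = ak.TwoStateFretModel(10.0, 10.0, 0.05, 0.95)
        traj = ak.PhotonTrajectory(
            times=np.arange(1, 6) * 1e-5, channels=np.ones(5, dtype=np.int8)
        )
        assert np.all(ak.viterbi_path(model, traj) == 1)

    def test_matches_enumeration_argmax(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            model, traj = random_case(rng, int(rng.integers(2, 10)))
            _, best = enumerate_paths(model, traj)
            np.testing.assert_array_equal(ak.viterbi_path(model, traj), best)

    def test_label_swap_symmetry(self):
        """A symmetric model with complementary channels flips the path."""
        model = ak.TwoStateFretModel(1500.0, 1500.0, 0.2, 0.8)
        rng = np.random.default_rng(5)
        times = np.cumsum(rng.exponential(2e-5, 50))
        channels = rng.integers(0, 2, 50).astype(np.int8)
        a = ak.viterbi_path(model, ak.PhotonTrajectory(times, channels))
        b = ak.viterbi_path(model, ak.PhotonTrajectory(times, 1 - channels))
        np.testing.assert_array_equal(a, 1 - b)


class TestFit:
    def test_recovers_rates_from_continuous_stream(self):
        truth = ak.TwoStateFretModel(2000.0, 3000.0, 0.37, 0.72)
        traj = ak.simulate_photon_trajectory(truth, 4.0, 50_000.0, seed=1)
        res = ak.fit_two_state(traj, n_restarts=3, seed=0)
        assert res.model.k_open == pytest.approx(truth.k_open, rel=0.15)
        assert res.model.k_close == pytest.approx(truth.k_close, rel=0.15)
        assert res.model.E_open == pytest.approx(0.37, abs=0.02)
        assert res.model.E_closed == pytest.approx(0.72, abs=0.02)
        assert res.closed_occupancy == pytest.approx(0.6, abs=0.03)
        assert "closed occupancy" in res.summary()

    def test_too_few_photons_rejected(self):
        traj = ak.simulate_photon_trajectory(
            ak.WT_FRET_MODEL, 0.01, 50_000.0, seed=2
        )
        with pytest.raises(ValueError, match="photons"):
            ak.fit_two_state(traj)

    def test_degenerate_emissions_raise_identifiability_warning(self):
        truth = ak.TwoStateFretModel(2000.0, 2000.0, 0.5, 0.5 + 1e-9)
        traj = ak.simulate_photon_trajectory(truth, 1.0, 30_000.0, seed=3)
        with pytest.warns(IdentifiabilityWarning):
            ak.fit_two_state(traj, n_restarts=1, seed=0, min_photons=1000)

    def test_occupancy_identity_on_result(self):
        traj = ak.simulate_photon_trajectory(
            ak.TwoStateFretModel(1000.0, 4000.0, 0.3, 0.8), 2.0, 50_000.0, seed=4
        )
        res = ak.fit_two_state(traj, n_restarts=2, seed=1)
        m = res.model
        assert res.closed_occupancy == pytest.approx(
            m.k_close / (m.k_close + m.k_open), abs=1e-12
        )


class TestBurstHistogram:
    def test_all_acceptor_bursts_give_unit_ratio(self):
        n = 120
        times = np.arange(n) * 1e-5
        traj = ak.PhotonTrajectory(
            times=times,
            channels=np.ones(n, dtype=np.int8),
            bursts=((0, 40), (40, 80), (80, 120)),
        )
        hist = ak.burst_histogram(traj)
        assert np.all(hist.values == 1.0)
        assert hist.counts.sum() == 3
        assert hist.counts[-1] == 3  # everything in the top bin

    def test_static_mixture_shows_two_modes(self):
        """Open-only and closed-only bursts (frozen conformations) produce
        separated modes near the two state efficiencies."""
        slow_open = ak.TwoStateFretModel(1e4, 1e-4, 0.37, 0.72)  # always open
        slow_closed = ak.TwoStateFretModel(1e-4, 1e4, 0.37, 0.72)  # always closed
        a = ak.generate_burst_set(slow_open, n_bursts=150, seed=10)
        b = ak.generate_burst_set(slow_closed, n_bursts=150, seed=11)
        ha = ak.burst_histogram(a)
        hb = ak.burst_histogram(b)
        assert abs(np.median(ha.values) - 0.37) < 0.05
        assert abs(np.median(hb.values) - 0.72) < 0.05

    def test_fast_exchange_collapses_to_occupancy_average(self):
        model = ak.TwoStateFretModel(40_000.0, 60_000.0, 0.37, 0.72)
        traj = ak.generate_burst_set(
            model, n_bursts=300, photon_rate=50_000.0, burst_duration_mean=5e-3, seed=12
        )
        hist = ak.burst_histogram(traj)
        p = model.closed_occupancy
        expected = p * 0.72 + (1 - p) * 0.37
        assert abs(np.mean(hist.values) - expected) < 0.025  # within bin width

    def test_min_photon_threshold_and_empty_error(self):
        from akinetics.photons import EmptyHistogramError

        times = np.arange(10) * 1e-4
        traj = ak.PhotonTrajectory(
            times=times, channels=np.zeros(10, dtype=np.int8), bursts=((0, 10),)
        )
        with pytest.raises(EmptyHistogramError):
            ak.burst_histogram(traj, min_photons=30)
        hist = ak.burst_histogram(traj, min_photons=5)
        assert hist.values.size == 1
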