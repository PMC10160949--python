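"""Photon-by-photon two-state hidden Markov analysis of smFRET data.

The LID domain switches between an open state (low FRET efficiency) and a
closed state (high FRET efficiency) much faster than typical binning times,
so the analysis conditions directly on individual photon arrival times: the
hidden state evolves as a continuous-time two-state Markov chain, the
propagator between consecutive photons is the closed-form 2×2 matrix
exponential, and each photon emits in the acceptor channel with probability
equal to the FRET efficiency of the state occupied at its arrival.

State-dependent brightness, background, spectral leakage and detection-factor
corrections are deliberately not modelled; the synthetic generator in
:mod:`akinetics.synthetic` matches this idealization.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.optimize
from numba import njit

__all__ = [
    "PhotonTrajectory",
    "TwoStateFretModel",
    "HmmFitResult",
    "BurstHistogram",
    "TwoStatePhotonHMM",
    "log_likelihood",
    "fit_two_state",
    "viterbi_path",
    "burst_histogram",
]

DONOR, ACCEPTOR = 0, 1

#: Default minimum total photon count required for rate fitting.
MIN_PHOTONS_FOR_FIT = 10_000

OPEN, CLOSED = 0, 1  # hidden-state order used throughout


class IdentifiabilityWarning(UserWarning):
    """The two states are not distinguishable from the photon stream."""


@dataclasses.dataclass(frozen=True)
class PhotonTrajectory:
    """Time-stamped two-channel photon stream, optionally split into bursts.

    ``times`` are strictly increasing arrival times in seconds; ``channels``
    holds 0 for donor and 1 for acceptor photons.  ``bursts`` is a list of
    half-open photon-index intervals ``(start, end)``.
    """

    times: np.ndarray
    channels: np.ndarray
    bursts: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        channels = np.asarray(self.channels, dtype=np.int8)
        if times.ndim != 1 or channels.shape != times.shape:
            raise ValueError("times and channels must be 1-d arrays of equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("photon arrival times must be strictly increasing")
        if not np.all((channels == DONOR) | (channels == ACCEPTOR)):
            raise ValueError("channels must be 0 (donor) or 1 (acceptor)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "channels", channels)
        if self.bursts is not None:
            bursts = tuple((int(a), int(b)) for a, b in self.bursts)
            prev_end = 0
            for a, b in bursts:
                if not (0 <= a < b <= times.size):
                    raise ValueError(f"burst interval ({a}, {b}) out of range")
                if a < prev_end:
                    raise ValueError("burst intervals must be non-overlapping and sorted")
                prev_end = b
            object.__setattr__(self, "bursts", bursts)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_photons(self) -> int:
        return self.times.size

    def burst_slices(self) -> list["PhotonTrajectory"]:
        if self.bursts is None:
            return [self]
        return [PhotonTrajectory(self.times[a:b], self.channels[a:b]) for a, b in self.bursts]

    def proximity_ratio(self) -> float:
        """Acceptor fraction n_A / (n_A + n_D) over the whole trajectory."""
        if self.n_photons == 0:
            raise ValueError("proximity ratio of an empty trajectory is undefined")
        return float(np.mean(self.channels == ACCEPTOR))


@dataclasses.dataclass(frozen=True)
class TwoStateFretModel:
    """Two-state conformational model observed through FRET photons.

    ``k_close`` is the open→closed rate, ``k_open`` the closed→open rate
    (both s⁻¹); ``E_open`` and ``E_closed`` are the state FRET efficiencies.
    The convention ``E_open < E_closed`` resolves the state-swap symmetry of
    the likelihood (the closed conformation brings the dyes closer).
    """

    k_open: float
    k_close: float
    E_open: float
    E_closed: float

    def __post_init__(self) -> None:
        if self.k_open <= 0 or self.k_close <= 0:
            raise ValueError("exchange rates must be strictly positive")
        if not (0.0 <= self.E_open <= 1.0 and 0.0 <= self.E_closed <= 1.0):
            raise ValueError("FRET efficiencies must lie in [0, 1]")
        if self.E_open > self.E_closed:
            raise ValueError(
                "labeling convention requires E_open <= E_closed; swap the states"
            )

    @property
    def closed_occupancy(self) -> float:
        return self.k_close / (self.k_close + self.k_open)

    @property
    def relaxation_rate(self) -> float:
        return self.k_open + self.k_close

    def canonical(self) -> "TwoStateFretModel":
        return self


@njit(cache=False, fastmath=True)
def _forward_loglik(dts, channels, k_open, k_close, e_open, e_closed):
    """Scaled forward recursion; returns the log-likelihood.

    The propagator over a gap dt is the analytic 2×2 matrix exponential
    P(dt) = Pi + exp(-lam*dt) (I - Pi) with lam = k_open + k_close and Pi the
    rank-one projector onto the stationary distribution.
    """
    lam = k_open + k_close
    p_open = k_open / lam
    p_closed = k_close / lam

    # emission probability per state for each channel
    if channels[0] == 1:
        a_o, a_c = e_open, e_closed
    else:
        a_o, a_c = 1.0 - e_open, 1.0 - e_closed
    f_o = p_open * a_o
    f_c = p_closed * a_c
    norm = f_o + f_c
    if norm <= 0.0:
        return -np.inf
    loglik = np.log(norm)
    f_o /= norm
    f_c /= norm

    for i in range(dts.shape[0]):
        g = np.exp(-lam * dts[i])
        # propagate: f @ P(dt)
        po = f_o * (p_open + g * p_closed) + f_c * (p_open - g * p_open)
        pc = f_o * (p_closed - g * p_closed) + f_c * (p_closed + g * p_open)
        if channels[i + 1] == 1:
            po *= e_open
            pc *= e_closed
        else:
            po *= 1.0 - e_open
            pc *= 1.0 - e_closed
        norm = po + pc
        if norm <= 0.0:
            return -np.inf
        loglik += np.log(norm)
        f_o = po / norm
        f_c = pc / norm
    return loglik


@njit(cache=False)
def _viterbi_kernel(dts, channels, k_open, k_close, e_open, e_closed):
    """Most probable hidden-state path at the photon instants (log-space)."""
    n = channels.shape[0]
    lam = k_open + k_close
    p_open = k_open / lam
    p_closed = k_close / lam

    path = np.empty(n, dtype=np.int8)
    back = np.empty((n, 2), dtype=np.int8)

    def _log(x):
        return np.log(x) if x > 0.0 else -np.inf

    if channels[0] == 1:
        d_o, d_c = _log(p_open * e_open), _log(p_closed * e_closed)
    else:
        d_o, d_c = _log(p_open * (1.0 - e_open)), _log(p_closed * (1.0 - e_closed))

    for i in range(1, n):
        g = np.exp(-lam * dts[i - 1])
        t_oo = _log(p_open + g * p_closed)
        t_oc = _log(p_closed - g * p_closed)
        t_co = _log(p_open - g * p_open)
        t_cc = _log(p_closed + g * p_open)
        # to open
        if d_o + t_oo >= d_c + t_co:
            n_o, back[i, 0] = d_o + t_oo, 0
        else:
            n_o, back[i, 0] = d_c + t_co, 1
        # to closed
        if d_o + t_oc >= d_c + t_cc:
            n_c, back[i, 1] = d_o + t_oc, 0
        else:
            n_c, back[i, 1] = d_c + t_cc, 1
        if channels[i] == 1:
            n_o += _log(e_open)
            n_c += _log(e_closed)
        else:
            n_o += _log(1.0 - e_open)
            n_c += _log(1.0 - e_closed)
        d_o, d_c = n_o, n_c

    path[n - 1] = 0 if d_o >= d_c else 1
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def _check_traj(traj: PhotonTrajectory) -> None:
    if traj.n_photons == 0:
        raise ValueError("photon trajectory is empty")


def log_likelihood(model: TwoStateFretModel, traj: PhotonTrajectory) -> float:
    """Exact log-likelihood of the channel sequence given the arrival times.

    Forward recursion over photons with inter-photon propagators
    ``exp(Q Δt)`` and per-photon emissions (acceptor with probability
    ``E_state``); the initial distribution is the stationary one.  The
    forward vector is renormalized at every photon and the log norms
    accumulated, so arbitrarily long streams do not underflow.  Returns
    ``-inf`` when an efficiency pinned at 0 or 1 contradicts an observed
    photon.
    """
    _check_traj(traj)
    ll = _forward_loglik(
        np.diff(traj.times),
        traj.channels,
        model.k_open,
        model.k_close,
        model.E_open,
        model.E_closed,
    )
    if not np.isfinite(ll):
        warnings.warn(
            "photon stream impossible under this model (efficiency at 0 or 1 "
            "contradicts an observed photon); log-likelihood is -inf",
            stacklevel=2,
        )
    return float(ll)


def viterbi_path(model: TwoStateFretModel, traj: PhotonTrajectory) -> np.ndarray:
    """Most probable joint state path at photon instants (0=open, 1=closed)."""
    _check_traj(traj)
    return np.asarray(
        _viterbi_kernel(
            np.diff(traj.times),
            traj.channels,
            model.k_open,
            model.k_close,
            model.E_open,
            model.E_closed,
        )
    )


# --------------------------------------------------------------------- fit


@dataclasses.dataclass(frozen=True)
class HmmFitResult:
    """Maximum-likelihood two-state model for a set of photon trajectories."""

    model: TwoStateFretModel
    log_likelihood: float
    converged: bool
    n_restarts_used: int
    n_photons: int

    @property
    def closed_occupancy(self) -> float:
        return self.model.closed_occupancy

    def summary(self) -> str:
        m = self.model
        lines = [
            "Two-state photon HMM fit",
            "========================",
            f"photons                 {self.n_photons}",
            f"log-likelihood          {self.log_likelihood:.2f}",
            f"converged               {self.converged}",
            f"restarts used           {self.n_restarts_used}",
            f"k_open   (closed→open)  {m.k_open:.1f} s^-1",
            f"k_close  (open→closed)  {m.k_close:.1f} s^-1",
            f"E_open                  {m.E_open:.3f}",
            f"E_closed                {m.E_closed:.3f}",
            f"closed occupancy        {self.closed_occupancy:.3f}",
        ]
        return "\n".join(lines)


def _pack(model: TwoStateFretModel) -> np.ndarray:
    def logit(p):
        p = min(max(p, 1e-6), 1 - 1e-6)
        return np.log(p / (1 - p))

    return np.array(
        [np.log(model.k_open), np.log(model.k_close), logit(model.E_open), logit(model.E_closed)]
    )


def _unpack(x: np.ndarray) -> tuple[float, float, float, float]:
    ko, kc = np.exp(x[0]), np.exp(x[1])
    eo = 1.0 / (1.0 + np.exp(-x[2]))
    ec = 1.0 / (1.0 + np.exp(-x[3]))
    if eo > ec:  # enforce the labeling convention by swapping states
        ko, kc = kc, ko
        eo, ec = ec, eo
    return ko, kc, eo, ec


class TwoStatePhotonHMM:
    """Maximum-likelihood two-state model estimation from photon streams.

    Model object in the spirit of a statsmodels estimator: constructed from
    one or more :class:`PhotonTrajectory`, :meth:`fit` maximizes the summed
    log-likelihood with a derivative-free simplex search in log-rate /
    logit-efficiency coordinates, using seeded multi-start jitter for
    robustness, and returns an :class:`HmmFitResult`.
    """

    def __init__(self, trajectories: PhotonTrajectory | Sequence[PhotonTrajectory]):
        if isinstance(trajectories, PhotonTrajectory):
            trajectories = [trajectories]
        self.trajectories = [t for t in trajectories if t.n_photons > 0]
        if not self.trajectories:
            raise ValueError("no non-empty trajectories supplied")
        self._dts = [np.diff(t.times) for t in self.trajectories]
        self._channels = [t.channels for t in self.trajectories]
        self.n_photons = sum(t.n_photons for t in self.trajectories)

    def _total_loglik(self, ko, kc, eo, ec) -> float:
        total = 0.0
        for dts, ch in zip(self._dts, self._channels):
            total += _forward_loglik(dts, ch, ko, kc, eo, ec)
            if not np.isfinite(total):
                return -np.inf
        return total

    def default_init(self) -> TwoStateFretModel:
        """Data-driven neutral starting point.

        Efficiencies straddle the pooled proximity ratio; both rates start at
        5% of the mean photon detection rate, the scale at which inter-photon
        gaps begin to carry kinetic information.
        """
        total_time = sum(t.times[-1] - t.times[0] for t in self.trajectories if len(t) > 1)
        rate = self.n_photons / max(total_time, 1e-12)
        pr = np.average(
            [t.proximity_ratio() for t in self.trajectories],
            weights=[t.n_photons for t in self.trajectories],
        )
        eo = float(np.clip(pr - 0.15, 0.02, 0.90))
        ec = float(np.clip(pr + 0.15, eo + 0.05, 0.98))
        k0 = max(0.05 * rate, 1.0)
        return TwoStateFretModel(k_open=k0, k_close=k0, E_open=eo, E_closed=ec)

    def fit(
        self,
        init: TwoStateFretModel | None = None,
        n_restarts: int = 5,
        seed: int = 0,
        min_photons: int = MIN_PHOTONS_FOR_FIT,
        maxfev: int = 600,
    ) -> HmmFitResult:
        """Maximize the photon likelihood over rates and efficiencies.

        ``n_restarts`` simplex searches are run from the initial point plus
        seeded log-space jitter; the best optimum is kept.  Non-convergence
        is flagged on the result rather than raised.  A fit whose optimum has
        ``E_open ≈ E_closed`` triggers an :class:`IdentifiabilityWarning`
        because the exchange rates are then unconstrained.
        """
        if self.n_photons < min_photons:
            raise ValueError(
                f"{self.n_photons} photons < required minimum {min_photons}; "
                "rate estimation needs more data (pass min_photons to override)"
            )
        if init is None:
            init = self.default_init()
        x0 = _pack(init)
        rng = np.random.default_rng(seed)

        def objective(x):
            return -self._total_loglik(*_unpack(x))

        best = None
        best_x = None
        converged = False
        used = 0
        for r in range(max(1, n_restarts)):
            x_start = x0 if r == 0 else x0 + rng.normal(0.0, [0.7, 0.7, 0.3, 0.3])
            res = scipy.optimize.minimize(
                objective,
                x_start,
                method="Nelder-Mead",
                options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-3},
            )
            used = r + 1
            if best is None or res.fun < best - 1e-9:
                best = res.fun
                best_x = res.x
                converged = bool(res.success)
        ko, kc, eo, ec = _unpack(best_x)
        # identifiability: the states separate only if both are visited and
        # their efficiencies differ; weight the separation by the occupancy
        # of the rarer state so a spurious, never-visited state also warns
        occ = kc / (ko + kc)
        if min(occ, 1.0 - occ) * (ec - eo) < 0.02:
            warnings.warn(
                "fitted states are effectively indistinguishable (nearly equal "
                "efficiencies or a vanishing occupancy); the exchange rates "
                "are unconstrained",
                IdentifiabilityWarning,
                stacklevel=2,
            )
        model = TwoStateFretModel(k_open=ko, k_close=kc, E_open=eo, E_closed=ec)
        return HmmFitResult(
            model=model,
            log_likelihood=-best,
            converged=converged,
            n_restarts_used=used,
            n_photons=self.n_photons,
        )


def fit_two_state(
    trajs: PhotonTrajectory | Sequence[PhotonTrajectory],
    init: TwoStateFretModel | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    **kwargs,
) -> HmmFitResult:
    """Functional wrapper around :class:`TwoStatePhotonHMM` . ``fit``."""
    return TwoStatePhotonHMM(trajs).fit(init=init, n_restarts=n_restarts, seed=seed, **kwargs)


# ------------------------------------------------------------- histograms


@dataclasses.dataclass(frozen=True)
class BurstHistogram:
    """Per-burst proximity-ratio values and their histogram over [0, 1]."""

    values: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        width = np.diff(self.bin_edges)
        ax.bar(self.bin_centers, self.counts, width=width, align="center", **kwargs)
        ax.set_xlabel("proximity ratio")
        ax.set_ylabel("bursts")
        return ax


class EmptyHistogramError(ValueError):
    """No burst passed the minimum-photon threshold."""


def burst_histogram(
    traj: PhotonTrajectory,
    min_photons: int = 30,
    bins: int = 41,
) -> BurstHistogram:
    """FRET-efficiency (proximity-ratio) histogram over qualifying bursts.

    Each burst with at least ``min_photons`` photons contributes one value
    n_A / (n_A + n_D); the histogram covers [0, 1] with ``bins`` bins.
    """
    if traj.bursts is None:
        raise ValueError("trajectory carries no burst boundaries")
    values = [
        b.proximity_ratio() for b in traj.burst_slices() if b.n_photons >= min_photons
    ]
    if not values:
        raise EmptyHistogramError(
            f"no burst has >= {min_photons} photons; histogram undefined"
        )
    values = np.array(values)
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return BurstHistogram(values=values, counts=counts, bin_edges=edges)
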