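"""The ten-state conformation-coupled reaction network and its steady states.

The network couples LID-domain conformational exchange (open ⇌ closed for
each of five ligation species) to nucleotide binding and chemistry.  Two
competing pathways lead to a doubly ligated complex: ATP-first produces the
productive ETM, AMP-first produces the unproductive ETMinh, and the two
interconvert only through their open conformations.  Phosphotransfer occurs
only from the productive closed complex ETM_C and is modelled as a single
irreversible transition back to the open apoenzyme (instantaneous product
release, no ADP rebinding), so the steady-state turnover is
``k_pt * p(ETM_C)``.

Free nucleotide concentrations are clamped (pseudo-first-order binding): the
enzyme does not deplete its substrates, matching bulk initial-velocity
conditions.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from .params import ParameterError, VariantParameterSet
from .states import N_STATES, STATE_INDEX, STATE_ORDER, Species, SpeciesState

__all__ = [
    "DegenerateModelError",
    "SteadyStateResult",
    "ActivityCurve",
    "KineticNetworkModel",
    "build_rate_matrix",
    "steady_state",
    "activity_vs_amp",
    "activity_vs_atp",
    "closed_occupancy_two_state",
    "inhibition_index",
    "DEFAULT_AMP_GRID",
    "DEFAULT_ATP_GRID",
]


class DegenerateModelError(RuntimeError):
    """The generator has a non-unique stationary distribution."""


class UndefinedIndexError(ValueError):
    """inhibition_index of an all-zero activity curve is undefined."""


#: Default AMP concentration grid (µM) for activity curves, spanning the
#: experimentally assayed range up to 10 mM.
DEFAULT_AMP_GRID = np.geomspace(1.0, 1.0e4, 61)

#: Default ATP concentration grid (µM).
DEFAULT_ATP_GRID = np.geomspace(1.0, 1.0e5, 61)

_S = {s: STATE_INDEX[s] for s in SpeciesState}
_CONF_PAIRS = [
    (Species.E, SpeciesState.E_O, SpeciesState.E_C),
    (Species.ET, SpeciesState.ET_O, SpeciesState.ET_C),
    (Species.EM, SpeciesState.EM_O, SpeciesState.EM_C),
    (Species.ETM, SpeciesState.ETM_O, SpeciesState.ETM_C),
    (Species.ETMinh, SpeciesState.ETMinh_O, SpeciesState.ETMinh_C),
]


def build_rate_matrix(
    params: VariantParameterSet,
    atp: float,
    amp: float,
    *,
    inhibited_closed_amp_release: bool = False,
) -> np.ndarray:
    """Generator matrix (rows sum to zero) over the ten species states.

    Parameters
    ----------
    params
        Rate constants of the variant.
    atp, amp
        Clamped free nucleotide concentrations in µM.
    inhibited_closed_amp_release
        Optional exploratory edge ETMinh_C → ET_C (AMP release from the
        inhibited closed complex); excluded from the default topology.

    Returns
    -------
    Q : (10, 10) ndarray ordered as :data:`akinetics.states.STATE_ORDER`;
        ``Q[i, j]`` is the i→j transition rate for i ≠ j.
    """
    if atp < 0 or amp < 0:
        raise ParameterError(f"concentrations must be nonnegative, got atp={atp}, amp={amp}")

    b = params.binding
    c = params.chemistry
    Q = np.zeros((N_STATES, N_STATES))

    # conformational exchange, one pair per ligation species (10 entries)
    for sp, so, sc in _CONF_PAIRS:
        r = params.conf(sp)
        Q[_S[so], _S[sc]] = r.k_close
        Q[_S[sc], _S[so]] = r.k_open

    # ATP binding/unbinding, open conformations only (4 entries)
    Q[_S[SpeciesState.E_O], _S[SpeciesState.ET_O]] = b.k_on_ATP * atp
    Q[_S[SpeciesState.ET_O], _S[SpeciesState.E_O]] = b.k_off_ATP
    Q[_S[SpeciesState.EM_O], _S[SpeciesState.ETMinh_O]] = b.k_on_ATP * atp
    Q[_S[SpeciesState.ETMinh_O], _S[SpeciesState.EM_O]] = b.k_off_ATP

    # AMP binding/unbinding, both conformations (8 entries)
    Q[_S[SpeciesState.E_O], _S[SpeciesState.EM_O]] = b.k_on_AMP_open * amp
    Q[_S[SpeciesState.EM_O], _S[SpeciesState.E_O]] = b.k_off_AMP_open
    Q[_S[SpeciesState.E_C], _S[SpeciesState.EM_C]] = b.k_on_AMP_closed * amp
    Q[_S[SpeciesState.EM_C], _S[SpeciesState.E_C]] = b.k_off_AMP_closed
    Q[_S[SpeciesState.ET_O], _S[SpeciesState.ETM_O]] = b.k_on_AMP_open * amp
    Q[_S[SpeciesState.ETM_O], _S[SpeciesState.ET_O]] = b.k_off_AMP_open
    Q[_S[SpeciesState.ET_C], _S[SpeciesState.ETM_C]] = b.k_on_AMP_closed * amp
    Q[_S[SpeciesState.ETM_C], _S[SpeciesState.ET_C]] = b.k_off_AMP_closed

    # productive/unproductive interconversion through the open states (2 entries)
    Q[_S[SpeciesState.ETM_O], _S[SpeciesState.ETMinh_O]] = c.k_conv_fwd
    Q[_S[SpeciesState.ETMinh_O], _S[SpeciesState.ETM_O]] = c.k_conv_rev

    # irreversible phosphotransfer from the productive closed complex (1 entry)
    Q[_S[SpeciesState.ETM_C], _S[SpeciesState.E_O]] += c.k_pt

    if inhibited_closed_amp_release:
        Q[_S[SpeciesState.ETMinh_C], _S[SpeciesState.ET_C]] = b.k_off_AMP_closed

    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclasses.dataclass(frozen=True)
class SteadyStateResult:
    """Stationary occupancies of the ten states plus the turnover flux."""

    occupancy: Mapping[SpeciesState, float]
    turnover: float

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.occupancy[s] for s in STATE_ORDER])

    def __getitem__(self, state: SpeciesState) -> float:
        return self.occupancy[state]


def _stationary_distribution(Q: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Normalized null vector of ``Q.T``; raises on a multi-dimensional null space."""
    null = scipy.linalg.null_space(Q.T, rcond=1e-12)
    if null.shape[1] != 1:
        raise DegenerateModelError(
            f"stationary distribution is not unique (null-space dimension "
            f"{null.shape[1]}); the network is disconnected for these parameters"
        )
    p = null[:, 0]
    p = p / p.sum()
    if p.min() < -rtol:
        raise DegenerateModelError("stationary solve produced negative occupancies")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def steady_state(params: VariantParameterSet, atp: float, amp: float, **kwargs) -> SteadyStateResult:
    """Exact stationary state of the network at clamped concentrations.

    The occupancy vector is the normalized null vector of the generator
    (linear solve, no time integration) and the turnover is the
    phosphotransfer flux ``k_pt * p(ETM_C)``.
    """
    Q = build_rate_matrix(params, atp, amp, **kwargs)
    p = _stationary_distribution(Q)
    occ = {s: float(p[i]) for i, s in enumerate(STATE_ORDER)}
    return SteadyStateResult(
        occupancy=occ,
        turnover=params.chemistry.k_pt * occ[SpeciesState.ETM_C],
    )


@dataclasses.dataclass(frozen=True)
class ActivityCurve:
    """Steady-state turnover along a concentration grid for one variant."""

    variant: str
    varied_ligand: str  # "ATP" or "AMP"
    fixed_ligand_conc: float
    grid: np.ndarray
    turnover: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        turn = np.asarray(self.turnover, dtype=float)
        if grid.size == 0:
            raise ValueError("activity-curve grid is empty")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("activity-curve grid must be strictly increasing")
        if grid.shape != turn.shape:
            raise ValueError("grid and turnover must have matching shapes")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "turnover", turn)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variant": self.variant,
                "varied_ligand": self.varied_ligand,
                "fixed_conc_uM": self.fixed_ligand_conc,
                "conc_uM": self.grid,
                "turnover_per_s": self.turnover,
            }
        )

    def plot(self, ax=None, **kwargs):
        """Plot turnover versus concentration on log-x axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.turnover, label=self.variant, **kwargs)
        ax.set_xscale("log")
        ax.set_xlabel(f"[{self.varied_ligand}] (µM)")
        ax.set_ylabel("turnover (s$^{-1}$)")
        return ax


def activity_vs_amp(
    params: VariantParameterSet,
    atp_fixed: float = 1000.0,
    amp_grid: Sequence[float] | None = None,
    **kwargs,
) -> ActivityCurve:
    """Activity curve versus AMP at fixed ATP (default 1,000 µM)."""
    grid = DEFAULT_AMP_GRID if amp_grid is None else np.asarray(amp_grid, dtype=float)
    turn = np.array([steady_state(params, atp_fixed, a, **kwargs).turnover for a in grid])
    return ActivityCurve(params.name, "AMP", atp_fixed, grid, turn)


def activity_vs_atp(
    params: VariantParameterSet,
    amp_fixed: float = 1000.0,
    atp_grid: Sequence[float] | None = None,
    **kwargs,
) -> ActivityCurve:
    """Activity curve versus ATP at fixed AMP (default 1,000 µM)."""
    grid = DEFAULT_ATP_GRID if atp_grid is None else np.asarray(atp_grid, dtype=float)
    turn = np.array([steady_state(params, a, amp_fixed, **kwargs).turnover for a in grid])
    return ActivityCurve(params.name, "ATP", amp_fixed, grid, turn)


def closed_occupancy_two_state(k_close: float, k_open: float) -> float:
    """Stationary closed-state occupancy ``k_close / (k_close + k_open)``."""
    if k_close < 0 or k_open < 0:
        raise ParameterError("rates must be nonnegative")
    if k_close + k_open == 0:
        raise ParameterError("occupancy undefined when both rates are zero")
    return k_close / (k_close + k_open)


def inhibition_index(curve: ActivityCurve | np.ndarray) -> float:
    """Scalar substrate-inhibition strength, ``1 - v(end) / max(v)``.

    Zero for monotone non-decreasing curves; ties in the maximum resolve to
    the first maximal grid point (immaterial to the value).
    """
    v = curve.turnover if isinstance(curve, ActivityCurve) else np.asarray(curve, dtype=float)
    if v.size == 0:
        raise UndefinedIndexError("inhibition index of an empty curve is undefined")
    vmax = v[np.argmax(v)]
    if vmax <= 0:
        raise UndefinedIndexError("inhibition index of an all-zero curve is undefined")
    return float(max(0.0, 1.0 - v[-1] / vmax))


class KineticNetworkModel:
    """Conformation-coupled kinetic model of one enzyme variant.

    A thin model object wrapping a :class:`VariantParameterSet`; its methods
    build the generator, solve for steady states and produce activity curves.
    Stochastic realizations hang off :meth:`simulate`.
    """

    def __init__(self, params: VariantParameterSet, **network_kwargs):
        self.params = params
        self.network_kwargs = network_kwargs

    @classmethod
    def from_parameter_file(cls, path, variant: str) -> "KineticNetworkModel":
        from .params import load_parameter_file

        return cls(load_parameter_file(path)[variant])

    def rate_matrix(self, atp: float, amp: float) -> np.ndarray:
        return build_rate_matrix(self.params, atp, amp, **self.network_kwargs)

    def steady_state(self, atp: float, amp: float) -> SteadyStateResult:
        return steady_state(self.params, atp, amp, **self.network_kwargs)

    def activity_vs_amp(self, atp_fixed: float = 1000.0, amp_grid=None) -> ActivityCurve:
        return activity_vs_amp(self.params, atp_fixed, amp_grid, **self.network_kwargs)

    def activity_vs_atp(self, amp_fixed: float = 1000.0, atp_grid=None) -> ActivityCurve:
        return activity_vs_atp(self.params, amp_fixed, atp_grid, **self.network_kwargs)

    def simulate(self, atp: float, amp: float, duration: float, seed: int):
        """Exact stochastic (Gillespie) realization; see :mod:`akinetics.gillespie`."""
        from .gillespie import gillespie

        return gillespie(self.params, atp, amp, duration, seed, **self.network_kwargs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"KineticNetworkModel({self.params.name!r})"
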