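"""Bulk-kinetics model fits: substrate inhibition and binding isotherms.

Two small nonlinear models cover the quantitative bulk analyses:

* the canonical uncompetitive substrate-inhibition rate law
  ``v = Vmax·S / (K_M + S·(1 + S/K_I))``, fitted to (concentration,
  initial-velocity) data to yield K_M and K_I, with K_I → ∞ recovering
  plain Michaelis–Menten behaviour; and
* the simple binding isotherm ``y = y0 + (ymax − y0)·S / (C50 + S)`` used
  for closed-state occupancies and closing rates versus ligand
  concentration, whose midpoint C50 quantifies the allosteric transition
  and whose plateau ``ymax`` supplies the closing rate of the inhibited
  ternary complex.

Fits follow a multiplicative error model (residuals relative to the model
value), as appropriate for initial-velocity assays whose errors scale with
signal, and K_I is parameterized through 1/K_I ≥ 0 so the no-inhibition
boundary is part of the parameter space.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import lmfit
import numpy as np

__all__ = [
    "ActivityDataset",
    "SIFitResult",
    "IsothermFitResult",
    "UncompetitiveInhibition",
    "BindingIsotherm",
    "si_velocity",
    "fit_uncompetitive_si",
    "screening_ratio",
    "fit_isotherm",
    "asymptotic_closing_rate",
]


@dataclasses.dataclass(frozen=True)
class ActivityDataset:
    """Initial-velocity measurements versus substrate concentration."""

    conc: np.ndarray
    velocity: np.ndarray
    fixed_cosubstrate_conc: float = np.nan
    variant: str = ""
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        if conc.ndim != 1 or conc.shape != vel.shape:
            raise ValueError("conc and velocity must be 1-d arrays of equal length")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "velocity", vel)
        if self.replicate is not None:
            rep = np.asarray(self.replicate)
            if rep.shape != conc.shape:
                raise ValueError("replicate ids must match data length")
            object.__setattr__(self, "replicate", rep)

    def __len__(self) -> int:
        return self.conc.size


def si_velocity(Vmax: float, K_M: float, K_I: float, S) -> float | np.ndarray:
    """Uncompetitive substrate-inhibition rate law.

    ``v = Vmax·S / (K_M + S·(1 + S/K_I))``; with ``K_I = inf`` this is the
    Michaelis–Menten law.  The velocity is maximal at ``S* = sqrt(K_M·K_I)``.
    """
    if Vmax <= 0 or K_M <= 0 or K_I <= 0:
        raise ValueError("Vmax, K_M and K_I must be positive (K_I may be inf)")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be nonnegative")
    inv_ki = 0.0 if np.isinf(K_I) else 1.0 / K_I
    v = Vmax * S / (K_M + S * (1.0 + S * inv_ki))
    return float(v) if v.ndim == 0 else v


def screening_ratio(Vmax: float, K_M: float, K_I: float) -> float:
    """Initial-velocity ratio v(100 µM) / v(500 µM).

    The lysate-screening statistic: values above 1 signal substrate
    inhibition between the two assay concentrations.
    """
    return float(si_velocity(Vmax, K_M, K_I, 100.0) / si_velocity(Vmax, K_M, K_I, 500.0))


@dataclasses.dataclass(frozen=True)
class SIFitResult:
    """Uncompetitive substrate-inhibition fit: Vmax, K_M, K_I and errors."""

    Vmax: float
    K_M: float
    K_I: float  # may be +inf (no inhibition)
    stderr: dict[str, float]
    rss: float
    converged: bool
    n_points: int

    @property
    def optimum_conc(self) -> float:
        """Concentration of maximal velocity, sqrt(K_M·K_I)."""
        return float(np.sqrt(self.K_M * self.K_I))

    def summary(self) -> str:
        ki = "inf (no inhibition)" if np.isinf(self.K_I) else f"{self.K_I:.4g} µM"
        lines = [
            "Uncompetitive substrate-inhibition fit",
            "======================================",
            f"n points      {self.n_points}",
            f"converged     {self.converged}",
            f"Vmax          {self.Vmax:.4g} ± {self.stderr.get('Vmax', float('nan')):.2g}",
            f"K_M           {self.K_M:.4g} ± {self.stderr.get('K_M', float('nan')):.2g} µM",
            f"K_I           {ki}",
            f"residual SS   {self.rss:.4g}",
        ]
        return "\n".join(lines)


class UncompetitiveInhibition:
    """Weighted least-squares estimator of (Vmax, K_M, K_I).

    Vmax and K_M are fitted in log space; inhibition enters through
    ``inv_KI = 1/K_I >= 0`` so that monotone (Michaelis–Menten) data sit on
    the boundary of the parameter space.  When the fitted ``inv_KI`` is
    within one standard error of zero, K_I is reported as infinity.
    ``with_residual`` adds an optional non-inhibited residual-activity
    component ``v_res·S/(K_M + S)`` for variants that keep turning over at
    saturating inhibitor concentrations (off by default).
    """

    def __init__(self, data: ActivityDataset, with_residual: bool = False):
        if len(data) < 5 or np.unique(data.conc[data.conc > 0]).size < 5:
            raise ValueError("need at least 5 distinct positive concentrations")
        self.data = data
        self.with_residual = with_residual

    def _model(self, params, S):
        vmax = np.exp(params["log_Vmax"].value)
        km = np.exp(params["log_KM"].value)
        inv_ki = params["inv_KI"].value
        v = vmax * S / (km + S * (1.0 + S * inv_ki))
        if self.with_residual:
            v = v + params["v_res"].value * S / (km + S)
        return v

    def fit(
        self,
        init: dict[str, float] | None = None,
    ) -> SIFitResult:
        data = self.data
        mask = data.conc > 0
        S, v = data.conc[mask], data.velocity[mask]

        guess = {
            "Vmax": float(np.max(v) * 1.5),
            "K_M": float(np.median(S)),
            "K_I": float(np.max(S)),
        }
        if init:
            guess.update(init)

        params = lmfit.Parameters()
        params.add("log_Vmax", value=np.log(max(guess["Vmax"], 1e-12)))
        params.add("log_KM", value=np.log(max(guess["K_M"], 1e-12)))
        ki0 = guess["K_I"]
        params.add("inv_KI", value=0.0 if np.isinf(ki0) else 1.0 / ki0, min=0.0)
        if self.with_residual:
            params.add("v_res", value=0.1 * guess["Vmax"], min=0.0)

        def residual(p):
            m = self._model(p, S)
            return (v - m) / np.maximum(m, 1e-30)

        out = lmfit.minimize(residual, params, method="leastsq")

        vmax = float(np.exp(out.params["log_Vmax"].value))
        km = float(np.exp(out.params["log_KM"].value))
        inv_ki = float(out.params["inv_KI"].value)
        inv_se = out.params["inv_KI"].stderr

        stderr: dict[str, float] = {}
        for name, target in [("log_Vmax", "Vmax"), ("log_KM", "K_M")]:
            se = out.params[name].stderr
            scale = vmax if target == "Vmax" else km
            stderr[target] = float(se * scale) if se is not None else float("nan")

        # K_I -> inf when 1/K_I is indistinguishable from 0: within one SE,
        # or (when the boundary optimum leaves no SE) when the inhibition
        # term S/K_I is negligible across the measured range
        negligible = inv_ki * float(np.max(S)) < 1e-6
        if inv_ki <= 0 or (inv_se is not None and inv_ki <= inv_se) or (
            inv_se is None and negligible
        ) or (inv_se is not None and np.isnan(inv_se) and negligible):
            ki = float("inf")
            stderr["K_I"] = float("nan")
        else:
            ki = 1.0 / inv_ki
            stderr["K_I"] = float(inv_se / inv_ki**2) if inv_se is not None else float("nan")

        resid = v - self._model(out.params, S)
        return SIFitResult(
            Vmax=vmax,
            K_M=km,
            K_I=ki,
            stderr=stderr,
            rss=float(np.sum(resid**2)),
            converged=bool(out.success),
            n_points=int(S.size),
        )


def fit_uncompetitive_si(
    data: ActivityDataset, init: dict[str, float] | None = None, **kwargs
) -> SIFitResult:
    """Functional wrapper around :class:`UncompetitiveInhibition` . ``fit``."""
    return UncompetitiveInhibition(data, **kwargs).fit(init=init)


# ----------------------------------------------------------------- isotherm


@dataclasses.dataclass(frozen=True)
class IsothermFitResult:
    """Binding-isotherm fit: baseline, plateau and midpoint C50."""

    y0: float
    ymax: float
    C50: float
    stderr: dict[str, float]
    converged: bool
    n_points: int

    def summary(self) -> str:
        lines = [
            "Binding-isotherm fit",
            "====================",
            f"n points   {self.n_points}",
            f"converged  {self.converged}",
            f"y0         {self.y0:.4g} ± {self.stderr.get('y0', float('nan')):.2g}",
            f"ymax       {self.ymax:.4g} ± {self.stderr.get('ymax', float('nan')):.2g}",
            f"C50        {self.C50:.4g} ± {self.stderr.get('C50', float('nan')):.2g} µM",
        ]
        return "\n".join(lines)


class BindingIsotherm:
    """Least-squares fit of ``y = y0 + (ymax − y0)·S/(C50 + S)``.

    The Hill exponent is fixed at 1 (a simple binding isotherm); pass
    ``free_hill=True`` to let a Hill coefficient float as an exploratory
    option.
    """

    def __init__(self, conc: Sequence[float], y: Sequence[float], free_hill: bool = False):
        conc = np.asarray(conc, dtype=float)
        y = np.asarray(y, dtype=float)
        if conc.ndim != 1 or conc.shape != y.shape:
            raise ValueError("conc and y must be 1-d arrays of equal length")
        if conc.size < 4:
            raise ValueError("need at least 4 points to fit an isotherm")
        if np.any(conc < 0):
            raise ValueError("concentrations must be nonnegative")
        self.conc = conc
        self.y = y
        self.free_hill = free_hill

    def fit(self, init: dict[str, float] | None = None) -> IsothermFitResult:
        conc, y = self.conc, self.y
        guess = {
            "y0": float(y[np.argmin(conc)]),
            "ymax": float(y[np.argmax(conc)]),
            "C50": float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0,
        }
        if init:
            guess.update(init)

        params = lmfit.Parameters()
        params.add("y0", value=guess["y0"])
        params.add("ymax", value=guess["ymax"])
        params.add("log_C50", value=np.log(max(guess["C50"], 1e-12)))
        if self.free_hill:
            params.add("hill", value=1.0, min=0.1, max=10.0)

        def model(p):
            c50 = np.exp(p["log_C50"].value)
            n = p["hill"].value if self.free_hill else 1.0
            s = np.power(conc, n)
            return p["y0"].value + (p["ymax"].value - p["y0"].value) * s / (c50**n + s)

        out = lmfit.minimize(lambda p: y - model(p), params, method="leastsq")

        c50 = float(np.exp(out.params["log_C50"].value))
        stderr: dict[str, float] = {}
        for name in ("y0", "ymax"):
            se = out.params[name].stderr
            stderr[name] = float(se) if se is not None else float("nan")
        se = out.params["log_C50"].stderr
        stderr["C50"] = float(se * c50) if se is not None else float("nan")

        return IsothermFitResult(
            y0=float(out.params["y0"].value),
            ymax=float(out.params["ymax"].value),
            C50=c50,
            stderr=stderr,
            converged=bool(out.success),
            n_points=int(conc.size),
        )


def fit_isotherm(conc, y, init: dict[str, float] | None = None, **kwargs) -> IsothermFitResult:
    """Functional wrapper around :class:`BindingIsotherm` . ``fit``."""
    return BindingIsotherm(conc, y, **kwargs).fit(init=init)


def asymptotic_closing_rate(fit: IsothermFitResult) -> float:
    """High-concentration plateau of a closing-rate isotherm.

    The plateau ``ymax`` is the closing rate of the fully formed inhibited
    ternary complex and feeds directly into a
    :class:`~akinetics.params.VariantParameterSet` as k_close(ETMinh).
    """
    if not fit.converged:
        raise ValueError("isotherm fit did not converge; plateau is unreliable")
    return float(fit.ymax)
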