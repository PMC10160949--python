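"""Parameter scans probing how LID-closure dynamics shape substrate inhibition.

Two scan families: (i) scaling the closing rate of either ternary complex
(productive ETM or unproductive ETMinh) while preserving either the
open/closed equilibrium ratio K_C (both rates scaled together) or the
opening rate (equilibrium shifted, as AMP does experimentally); and
(ii) varying the ETM_O ⇌ ETMinh_O interconversion rate.  Each scan point
recomputes the full AMP activity curve and its inhibition index.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np

from .network import ActivityCurve, activity_vs_amp, inhibition_index
from .params import VariantParameterSet
from .states import Species

__all__ = ["ScanResult", "scan_closing_rate", "scan_interconversion",
           "DEFAULT_FACTOR_GRID", "DEFAULT_KCONV_GRID"]

#: Default multiplicative factor grid for closing-rate scans.
DEFAULT_FACTOR_GRID = np.geomspace(0.1, 10.0, 13)

#: Default interconversion-rate grid (s⁻¹).
DEFAULT_KCONV_GRID = np.geomspace(1.0, 1.0e5, 10)


@dataclasses.dataclass(frozen=True)
class ScanResult:
    """One activity curve and inhibition index per scanned parameter value."""

    scanned_parameter: str
    values: np.ndarray
    curves: tuple[ActivityCurve, ...]
    indices: np.ndarray
    mode: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(values) <= 0):
            raise ValueError("scan values must be strictly increasing")
        if len(self.curves) != values.size or values.size != len(self.indices):
            raise ValueError("one curve and one index required per scan value")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=float))

    def to_frame(self):
        """Tidy long-format table: one row per (scan value, concentration)."""
        import pandas as pd

        frames = []
        for val, curve, idx in zip(self.values, self.curves, self.indices):
            f = curve.to_frame()
            f.insert(0, self.scanned_parameter, val)
            f["inhibition_index"] = idx
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def scan_closing_rate(
    params: VariantParameterSet,
    species: Literal["ETM", "ETMinh"] | Species,
    mode: Literal["preserve_Kc", "preserve_opening"],
    factors: Sequence[float] | None = None,
    atp_fixed: float = 1000.0,
    amp_grid: Sequence[float] | None = None,
) -> ScanResult:
    """Scale the closing rate of a ternary complex and recompute activity.

    For each factor f, ``k_close(species)`` is multiplied by f; in
    ``preserve_Kc`` mode ``k_open`` is scaled by f as well (equilibrium
    preserved, only the exchange speed changes), while ``preserve_opening``
    leaves ``k_open`` fixed so the closed state becomes more (f > 1) or less
    (f < 1) populated — the analogue of the experimentally observed
    AMP-induced closing acceleration.
    """
    species = Species(species)
    if species not in (Species.ETM, Species.ETMinh):
        raise ValueError("closing-rate scans address the ternary complexes ETM or ETMinh")
    if mode not in ("preserve_Kc", "preserve_opening"):
        raise ValueError(f"unknown scan mode {mode!r}")
    factors = DEFAULT_FACTOR_GRID if factors is None else np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("scan factors must be positive")

    base = params.conf(species)
    curves = []
    for f in factors:
        open_factor = f if mode == "preserve_Kc" else 1.0
        perturbed = params.with_conformational(species, base.scaled(f, open_factor))
        curves.append(activity_vs_amp(perturbed, atp_fixed, amp_grid))
    indices = np.array([inhibition_index(c) for c in curves])
    return ScanResult(
        scanned_parameter=f"k_close_{species.value}_factor",
        values=factors,
        curves=tuple(curves),
        indices=indices,
        mode=mode,
    )


def scan_interconversion(
    params: VariantParameterSet,
    k_conv_values: Sequence[float] | None = None,
    atp_fixed: float = 1000.0,
    amp_grid: Sequence[float] | None = None,
) -> ScanResult:
    """Vary the ETM_O ⇌ ETMinh_O interconversion rate (both directions equal).

    Fast interconversion lets the unproductive complex drain into the
    productive one before the next closure, abolishing substrate inhibition;
    slow interconversion deepens it.
    """
    values = DEFAULT_KCONV_GRID if k_conv_values is None else np.asarray(k_conv_values, float)
    if np.any(values <= 0):
        raise ValueError("interconversion rates must be positive")
    curves = []
    for k in values:
        chem = dataclasses.replace(params.chemistry, k_conv_fwd=float(k), k_conv_rev=float(k))
        curves.append(activity_vs_amp(params.replace(chemistry=chem), atp_fixed, amp_grid))
    indices = np.array([inhibition_index(c) for c in curves])
    return ScanResult(
        scanned_parameter="k_conv",
        values=values,
        curves=tuple(curves),
        indices=indices,
        mode=None,
    )
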