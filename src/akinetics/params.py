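"""Rate-constant containers defining one enzyme variant's reaction network.

Units are a single convention throughout the package: concentrations in µM,
times in seconds, first-order rates in s⁻¹ and association rates in µM⁻¹s⁻¹.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import yaml

from .states import Species


class ParameterError(ValueError):
    """Raised when a rate constant or concentration violates an invariant."""


@dataclasses.dataclass(frozen=True)
class ConformationalRates:
    """LID-domain closing/opening rate pair for one ligation species.

    ``K_C = k_close / k_open`` is the open↔closed equilibrium ratio; the
    stationary closed occupancy of the isolated two-state system is
    ``k_close / (k_close + k_open)``.
    """

    k_close: float
    k_open: float

    def __post_init__(self) -> None:
        if not (self.k_close > 0 and self.k_open > 0):
            raise ParameterError(
                f"conformational rates must be strictly positive, got "
                f"k_close={self.k_close}, k_open={self.k_open}"
            )

    @property
    def K_C(self) -> float:
        return self.k_close / self.k_open

    @property
    def closed_occupancy(self) -> float:
        return self.k_close / (self.k_close + self.k_open)

    def scaled(self, close_factor: float, open_factor: float) -> "ConformationalRates":
        return ConformationalRates(self.k_close * close_factor, self.k_open * open_factor)


@dataclasses.dataclass(frozen=True)
class BindingRates:
    """Nucleotide association/dissociation rates.

    ATP binds the LID site from open conformations only; AMP binds the NMP
    site from both conformations.  Association rates are in µM⁻¹s⁻¹,
    dissociation rates in s⁻¹.
    """

    k_on_ATP: float
    k_off_ATP: float
    k_on_AMP_open: float
    k_on_AMP_closed: float
    k_off_AMP_open: float
    k_off_AMP_closed: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"binding rate {f.name} must be nonnegative, got {v}")


@dataclasses.dataclass(frozen=True)
class ChemistryRates:
    """Chemical-step rates: phosphotransfer and ETM↔ETMinh interconversion.

    ``k_pt`` acts only from the productive closed complex ETM_C;
    ``k_conv_fwd`` is ETM_O → ETMinh_O and ``k_conv_rev`` the reverse.
    """

    k_pt: float = 500.0
    k_conv_fwd: float = 250.0
    k_conv_rev: float = 250.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"chemistry rate {f.name} must be nonnegative, got {v}")


@dataclasses.dataclass(frozen=True)
class VariantParameterSet:
    """All rate constants defining one enzyme variant's network."""

    name: str
    conformational: Mapping[Species, ConformationalRates]
    binding: BindingRates
    chemistry: ChemistryRates

    def __post_init__(self) -> None:
        missing = [s for s in Species if s not in self.conformational]
        if missing:
            raise ParameterError(
                f"variant {self.name!r} missing conformational rates for {missing}"
            )

    def conf(self, species: Species) -> ConformationalRates:
        return self.conformational[species]

    def replace(self, **kwargs) -> "VariantParameterSet":
        return dataclasses.replace(self, **kwargs)

    def with_conformational(
        self, species: Species, rates: ConformationalRates
    ) -> "VariantParameterSet":
        conf = dict(self.conformational)
        conf[species] = rates
        return dataclasses.replace(self, conformational=conf)

    # ------------------------------------------------------------------ IO

    def to_dict(self) -> dict:
        return {
            "conformational": {
                s.value: {"k_close": r.k_close, "k_open": r.k_open}
                for s, r in self.conformational.items()
            },
            "binding": dataclasses.asdict(self.binding),
            "chemistry": dataclasses.asdict(self.chemistry),
        }

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "VariantParameterSet":
        known = {"conformational", "binding", "chemistry"}
        unknown = set(d) - known
        if unknown:
            warnings.warn(
                f"variant {name!r}: ignoring unknown parameter keys {sorted(unknown)}",
                stacklevel=2,
            )
        conf = {}
        for key, rates in d["conformational"].items():
            extra = set(rates) - {"k_close", "k_open"}
            if extra:
                warnings.warn(
                    f"variant {name!r}/{key}: ignoring unknown keys {sorted(extra)}",
                    stacklevel=2,
                )
            conf[Species(key)] = ConformationalRates(
                float(rates["k_close"]), float(rates["k_open"])
            )
        bind = {k: float(v) for k, v in d["binding"].items()}
        extra = set(bind) - {f.name for f in dataclasses.fields(BindingRates)}
        for k in extra:
            warnings.warn(f"variant {name!r}: ignoring unknown binding key {k!r}", stacklevel=2)
            bind.pop(k)
        chem = {k: float(v) for k, v in d["chemistry"].items()}
        extra = set(chem) - {f.name for f in dataclasses.fields(ChemistryRates)}
        for k in extra:
            warnings.warn(f"variant {name!r}: ignoring unknown chemistry key {k!r}", stacklevel=2)
            chem.pop(k)
        return cls(
            name=name,
            conformational=conf,
            binding=BindingRates(**bind),
            chemistry=ChemistryRates(**chem),
        )


def save_parameter_file(path, variants: Mapping[str, VariantParameterSet]) -> None:
    """Write a YAML parameter file with one block per variant."""
    doc = {name: ps.to_dict() for name, ps in variants.items()}
    with open(path, "w") as fh:
        fh.write("# akinetics variant parameters; rates in s^-1, associations in uM^-1 s^-1\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameter_file(path) -> dict[str, VariantParameterSet]:
    """Load and validate a YAML parameter file (one block per variant)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise ParameterError(f"parameter file {path} contains no variant blocks")
    return {name: VariantParameterSet.from_dict(name, block) for name, block in doc.items()}
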