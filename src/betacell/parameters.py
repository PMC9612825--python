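"""Kinetic parameter containers.

A :class:`ParameterSet` maps parameter names to values together with
optional box bounds and a provenance tag.  Parameter names follow the
conventions of the model-definition document:

``Vf_<rxn>`` / ``Vr_<rxn>``
    forward / reverse maximal velocities (mM/min), class ``velocity``.
``Keq_<rxn>``
    lumped equilibrium constant of a reversible reaction, class
    ``equilibrium``.  After the identifiability reparameterization the
    reverse velocity of a constrained reaction is derived as
    ``Vr = Vf / Keq``.
``Km_<rxn>_<species>`` / ``Kp_<rxn>_<species>`` / ``Kx_<rxn>_...``
    Michaelis / product-binding / cross-binding constants (mM), class
    ``michaelis``.
``Ka_...`` / ``Ki_...`` / ``n_...``
    regulatory activation / inhibition constants and Hill coefficients,
    class ``regulatory``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

PARAMETER_CLASSES = ("velocity", "equilibrium", "michaelis", "regulatory")


@dataclass
class ParameterSet:
    """Named kinetic constants with optional bounds.

    Parameters
    ----------
    values : dict
        Parameter name -> value.  Velocities in mM/min, Michaelis-type
        constants in mM, equilibrium constants and regulatory factors
        dimensionless unless noted in the definition document.
    bounds : dict
        Parameter name -> (low, high).  Only parameters that are fitted
        need bounds.
    classes : dict
        Parameter name -> one of :data:`PARAMETER_CLASSES`.
    provenance : str
        ``"nominal"`` (definition document), ``"fitted"`` or ``"sampled"``.
    """

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)
    provenance: str = "nominal"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo <= self.values.get(name, lo) <= hi:
                raise ValueError(
                    f"parameter {name}={self.values.get(name)} outside bounds ({lo}, {hi})"
                )
        for name, cls in self.classes.items():
            if cls not in PARAMETER_CLASSES:
                raise ValueError(f"unknown parameter class {cls!r} for {name}")
        for name, value in self.values.items():
            if self.classes.get(name) == "velocity" and value < 0:
                raise ValueError(f"velocity parameter {name} must be >= 0, got {value}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def get(self, name: str, default: float | None = None) -> float | None:
        return self.values.get(name, default)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            dict(self.values), dict(self.bounds), dict(self.classes), self.provenance
        )

    def updated(self, new_values: Mapping[str, float], provenance: str | None = None) -> "ParameterSet":
        """Return a copy with ``new_values`` substituted."""
        unknown = set(new_values) - set(self.values)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        out = self.copy()
        out.values.update(new_values)
        if provenance is not None:
            out.provenance = provenance
        return out

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        """Return a copy with one parameter multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return self.updated({name: self.values[name] * factor})

    def as_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def names_of_class(self, cls: str) -> list[str]:
        return [n for n in self.values if self.classes.get(n) == cls]

    def multiplicative_bounds(self, names: Iterable[str], factor: float = 100.0) -> dict[str, tuple[float, float]]:
        """Box bounds ``factor`` times above and below the current value.

        This is the default search region used for fitting: every free
        velocity may vary two orders of magnitude around its nominal
        estimate.
        """
        if factor <= 1:
            raise ValueError("multiplicative bound factor must be > 1")
        out = {}
        for n in names:
            v = self.values[n]
            if v <= 0:
                raise ValueError(f"cannot place multiplicative bounds around {n}={v}")
            out[n] = (v / factor, v * factor)
        return out
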