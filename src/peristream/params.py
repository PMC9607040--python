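"""Dimensionless flow parameters for peristaltic transport of a compressible
Maxwell fluid in a two-dimensional flexible-wall channel.

The channel has half-width ``h`` and its walls carry a traveling sinusoidal
wave ``eta = eps * cos(alpha (x - t))`` (all lengths scaled by ``h``, speeds
by the wave speed ``c``).  Five dimensionless numbers fix the problem:

``alpha``
    wave number, ``2 pi h / lambda_wave``.
``reynolds``
    Reynolds number ``rho0 c h / mu``.
``chi``
    compressibility parameter of the exponential equation of state
    ``rho = exp(chi (p - p0))``; ``chi = 0`` is the incompressible limit.
``lambda1``
    stress relaxation time of the Maxwell element, scaled by ``h / c``.
``epsilon``
    amplitude ratio (wave amplitude over half-width), the perturbation
    parameter; must lie in (0, 1).

``variant`` selects the constitutive model: the linear Maxwell fluid
(partial time derivative in the stress relaxation equation) or the upper
convected Maxwell (UCM) fluid (frame-invariant convected derivative).  The
two coincide at first order in ``epsilon``; they differ only through the
quadratic convected terms entering the mean-flow forcing.  At
``lambda1 = 0`` both reduce to the compressible Newtonian fluid.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Any, Mapping


class Variant(str, enum.Enum):
    """Constitutive model variant."""

    LINEAR = "LINEAR"
    UCM = "UCM"

    @classmethod
    def coerce(cls, value: "Variant | str") -> "Variant":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class FlowParameters:
    """Validated bundle of the dimensionless numbers plus model variant."""

    alpha: float
    reynolds: float
    chi: float = 0.0
    lambda1: float = 0.0
    epsilon: float = 0.1
    variant: Variant = Variant.UCM

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant.coerce(self.variant))
        for name in ("alpha", "reynolds", "chi", "lambda1", "epsilon"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.reynolds <= 0:
            raise ValueError(f"reynolds must be > 0, got {self.reynolds}")
        if self.chi < 0:
            raise ValueError(f"chi must be >= 0, got {self.chi}")
        if self.lambda1 < 0:
            raise ValueError(f"lambda1 must be >= 0, got {self.lambda1}")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")

    @property
    def is_ucm(self) -> bool:
        return self.variant is Variant.UCM

    def with_(self, **changes: Any) -> "FlowParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "FlowParameters":
        """Build parameters from a flat config mapping.

        Recognized keys: alpha, reynolds, chi, lambda1, epsilon, variant.
        Unknown keys raise, to catch config typos early.
        """
        known = {"alpha", "reynolds", "chi", "lambda1", "epsilon", "variant"}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    def to_mapping(self) -> dict[str, Any]:
        return {
            "alpha": self.alpha,
            "reynolds": self.reynolds,
            "chi": self.chi,
            "lambda1": self.lambda1,
            "epsilon": self.epsilon,
            "variant": self.variant.value,
        }
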