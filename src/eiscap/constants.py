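"""Physical constants used throughout the capacitive model.

The default values are the rounded textbook values conventionally used in
semiconductor device calculations (q = 1.6e-19 C, k = 1.38e-23 J/K,
eps0 = 8.854e-12 F/m).  They are deliberately fixed rather than imported
from ``scipy.constants`` so that simulated curves are stable against
CODATA revisions; a config file may override them.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Elementary charge, Boltzmann constant and vacuum permittivity (SI)."""

    q: float = 1.6e-19  # C
    k: float = 1.38e-23  # J/K
    eps0: float = 8.854e-12  # F/m

    def __post_init__(self) -> None:
        if self.q <= 0 or self.k <= 0 or self.eps0 <= 0:
            raise ValueError("physical constants must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()
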