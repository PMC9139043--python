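"""Device parameters of an electrolyte-insulator-semiconductor capacitor.

An EISCAP is a field-effect sensor: a semiconductor substrate (here p-type
silicon), a thin gate insulator, an electrolyte gate contacted through a
reference electrode.  This module holds the physical parameters of one such
device and the scalar quantities derived from them that every other module
consumes:

* the insulator capacitance per unit area ``C_i0 = eps_i / d_i``,
* the maximum depletion-layer width ``w_m`` reached at strong inversion,
* the lumped, nanoparticle-independent interface voltage ``V_ip``
  (reference-electrode potential, solvent dipole potential, semiconductor
  work function and fixed oxide/interface charge, folded into one number).

Internally everything is SI (m, m^-3, F/m^2, V).  Conversions from the
bench units customary in the field (nm, cm^-3, cm^2, mV) happen only at the
I/O boundary, via the ``from_io_units`` constructors and ``to_io_dict``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "SemiconductorParams",
    "InsulatorParams",
    "InterfacePotentials",
    "DeviceParams",
    "insulator_capacitance_per_area",
    "max_depletion_width",
    "lumped_interface_voltage",
]

# I/O unit conversion factors (multiply on input, divide on output)
_NM = 1e-9
_PER_CM3 = 1e6
_CM2 = 1e-4
_MV = 1e-3


@dataclass(frozen=True)
class SemiconductorParams:
    """Uniformly doped p-type semiconductor substrate.

    Parameters
    ----------
    relative_permittivity
        Relative static permittivity ``eps_sr`` (11.7 for silicon).
    acceptor_density
        Ionized acceptor density ``N_a`` in m^-3.
    intrinsic_density
        Intrinsic carrier density ``n_i`` in m^-3 at the given temperature.
    temperature
        Absolute temperature in K.
    """

    relative_permittivity: float
    acceptor_density: float
    intrinsic_density: float
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.relative_permittivity > 1:
            raise ValueError("semiconductor relative permittivity must exceed 1")
        if not self.intrinsic_density > 0:
            raise ValueError("intrinsic density must be positive")
        if not self.acceptor_density > self.intrinsic_density:
            raise ValueError("acceptor density must exceed intrinsic density")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @classmethod
    def from_io_units(
        cls,
        eps_sr: float,
        N_a_per_cm3: float,
        n_i_per_cm3: float,
        T_K: float = 300.0,
    ) -> "SemiconductorParams":
        return cls(eps_sr, N_a_per_cm3 * _PER_CM3, n_i_per_cm3 * _PER_CM3, T_K)

    def to_io_dict(self) -> dict[str, float]:
        return {
            "eps_sr": self.relative_permittivity,
            "N_a_per_cm3": self.acceptor_density / _PER_CM3,
            "n_i_per_cm3": self.intrinsic_density / _PER_CM3,
            "T_K": self.temperature,
        }


@dataclass(frozen=True)
class InsulatorParams:
    """Gate insulator: relative permittivity and thickness (m)."""

    relative_permittivity: float
    thickness: float

    def __post_init__(self) -> None:
        if not self.relative_permittivity >= 1:
            raise ValueError("insulator relative permittivity must be >= 1")
        if not self.thickness > 0:
            raise ValueError("insulator thickness must be positive")

    @classmethod
    def from_io_units(cls, eps_ir: float, d_i_nm: float) -> "InsulatorParams":
        return cls(eps_ir, d_i_nm * _NM)

    def to_io_dict(self) -> dict[str, float]:
        return {"eps_ir": self.relative_permittivity, "d_i_nm": self.thickness / _NM}


#: keys of the optional V_ip decomposition, all in volts
_DECOMPOSITION_KEYS = ("E_ref", "chi_sol", "phi_s_over_q", "Q_over_Ci")


@dataclass(frozen=True)
class InterfacePotentials:
    """Interfacial potentials of the insulator/electrolyte boundary.

    ``v_ip`` lumps every potential contribution that does not depend on the
    nanoparticle decoration: the reference-electrode potential ``E_ref``,
    the solvent surface-dipole potential ``chi_sol``, minus the
    semiconductor work function expressed as a voltage, plus the fixed
    oxide and interface-state charge divided by the insulator capacitance.
    ``phi_0`` is the interfacial potential of the particle-free surface.

    The four-term decomposition is optional metadata; when supplied it must
    sum to ``v_ip`` (to 1e-12 V).
    """

    v_ip: float = 0.0
    phi_0: float = 0.0
    decomposition: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.decomposition is not None:
            extra = set(self.decomposition) - set(_DECOMPOSITION_KEYS)
            missing = set(_DECOMPOSITION_KEYS) - set(self.decomposition)
            if extra or missing:
                raise ValueError(
                    f"decomposition must have exactly the keys {_DECOMPOSITION_KEYS}; "
                    f"extra={sorted(extra)}, missing={sorted(missing)}"
                )
            total = lumped_interface_voltage(
                self.decomposition["E_ref"],
                self.decomposition["chi_sol"],
                self.decomposition["phi_s_over_q"],
                self.decomposition["Q_over_Ci"],
            )
            if abs(total - self.v_ip) > 1e-12:
                raise ValueError(
                    f"decomposition sums to {total} V but v_ip = {self.v_ip} V"
                )

    @classmethod
    def from_io_units(cls, V_ip_mV: float = 0.0, phi_0_mV: float = 0.0) -> "InterfacePotentials":
        return cls(V_ip_mV * _MV, phi_0_mV * _MV)

    def to_io_dict(self) -> dict[str, float]:
        return {"V_ip_mV": self.v_ip / _MV, "phi_0_mV": self.phi_0 / _MV}


@dataclass(frozen=True)
class DeviceParams:
    """Complete parameter set of one EISCAP.

    ``area`` is the electrolyte-contacted sensor area in m^2.
    """

    semiconductor: SemiconductorParams
    insulator: InsulatorParams
    area: float
    interface: InterfacePotentials = field(default_factory=InterfacePotentials)
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("device area must be positive")

    @classmethod
    def from_io_units(
        cls,
        eps_ir: float,
        d_i_nm: float,
        eps_sr: float,
        N_a_per_cm3: float,
        n_i_per_cm3: float,
        T_K: float,
        A_cm2: float,
        V_ip_mV: float = 0.0,
        phi_0_mV: float = 0.0,
        constants: PhysicalConstants = DEFAULT_CONSTANTS,
    ) -> "DeviceParams":
        return cls(
            semiconductor=SemiconductorParams.from_io_units(eps_sr, N_a_per_cm3, n_i_per_cm3, T_K),
            insulator=InsulatorParams.from_io_units(eps_ir, d_i_nm),
            area=A_cm2 * _CM2,
            interface=InterfacePotentials.from_io_units(V_ip_mV, phi_0_mV),
            constants=constants,
        )

    def to_io_dict(self) -> dict[str, float]:
        out = {}
        out.update(self.insulator.to_io_dict())
        out.update(self.semiconductor.to_io_dict())
        out["A_cm2"] = self.area / _CM2
        out.update(self.interface.to_io_dict())
        return out

    # -- derived scalars -------------------------------------------------

    @property
    def eps_i(self) -> float:
        """Absolute insulator permittivity (F/m)."""
        return self.constants.eps0 * self.insulator.relative_permittivity

    @property
    def eps_s(self) -> float:
        """Absolute semiconductor permittivity (F/m)."""
        return self.constants.eps0 * self.semiconductor.relative_permittivity

    @property
    def c_i0(self) -> float:
        """Insulator capacitance per unit area (F/m^2)."""
        return insulator_capacitance_per_area(self.insulator, self.constants)

    @property
    def w_max(self) -> float:
        """Maximum depletion width at strong inversion (m)."""
        return max_depletion_width(self.semiconductor, self.constants)


def insulator_capacitance_per_area(
    insulator: InsulatorParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Parallel-plate capacitance per unit area of the gate insulator.

    ``C_i0 = eps0 * eps_ir / d_i`` in F/m^2.
    """
    return constants.eps0 * insulator.relative_permittivity / insulator.thickness


def max_depletion_width(
    semiconductor: SemiconductorParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Maximum width of the space-charge region at strong inversion.

    ``w_m = sqrt(4 eps_s k T ln(N_a/n_i) / (q^2 N_a))``.  Under the
    high-frequency assumption the depletion layer never grows beyond this
    width; the inversion capacitance of the device follows from it.
    """
    s = semiconductor
    eps_s = constants.eps0 * s.relative_permittivity
    log_ratio = math.log(s.acceptor_density / s.intrinsic_density)
    # guaranteed positive by the N_a > n_i invariant
    return math.sqrt(
        4.0 * eps_s * constants.k * s.temperature * log_ratio
        / (constants.q**2 * s.acceptor_density)
    )


def lumped_interface_voltage(
    e_ref: float, chi_sol: float, phi_s_over_q: float, q_over_ci: float
) -> float:
    """Sum the nanoparticle-independent potential contributions (volts).

    ``V_ip = E_ref + chi_sol - phi_s/q + (Q_i + Q_ss)/C_i`` with every term
    already expressed in volts.
    """
    return e_ref + chi_sol - phi_s_over_q + q_over_ci
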