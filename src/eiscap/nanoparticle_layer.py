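"""Charged-nanoparticle decoration of the sensor surface.

Ligand-stabilized metal nanoparticles adsorbed on the gate insulator act as
local nano-gates: their effective charge changes the interfacial potential
of the covered surface fraction by ``delta_phi = N_NP * Q_NP / C_d``, where
``N_NP`` is the particle surface density, ``Q_NP`` the effective (screened)
charge per particle and ``C_d`` the double-layer capacitance per area in
the covered region.  Because adsorbed particles repel each other they never
tile the surface densely; the coverage ``n`` (projected hard-disk area
fraction) is the central knob of the two-region capacitive model.

The module also generates synthetic particle fields by random sequential
adsorption (RSA) of hard disks, emulating the particle arrangements seen in
electron micrographs of decorated chips, and converts between surface
density and coverage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RSA_JAMMING_LIMIT",
    "NanoparticleLayer",
    "ParticleField",
    "delta_phi_from_charge",
    "coverage_from_density",
    "density_from_coverage",
    "rsa_place_particles",
    "coverage_of_field",
]

#: saturation coverage of random sequential adsorption of equal hard disks
#: in 2-D; randomly adsorbed monolayers cannot exceed it.
RSA_JAMMING_LIMIT = 0.547

_NM = 1e-9
_PER_CM2 = 1e4
_MV = 1e-3


def delta_phi_from_charge(density: float, charge: float, c_d: float) -> float:
    """Interfacial potential change induced by the particle layer (V).

    ``delta_phi = N_NP * Q_NP / C_d``: the areal charge of the adsorbed
    particles divided by the double-layer capacitance per area.  ``charge``
    is the *effective* charge per particle after counterion screening, so
    the result already reflects the ionic strength of the electrolyte.
    """
    if c_d <= 0:
        raise ValueError("double-layer capacitance must be positive")
    if density < 0:
        raise ValueError("particle density cannot be negative")
    return density * charge / c_d


def coverage_from_density(density: float, diameter: float) -> float:
    """Projected hard-disk coverage ``n = N_NP * pi * d^2 / 4``.

    Emits a warning above the 2-D RSA jamming limit (0.547): such coverages
    cannot arise from random adsorption of equal disks, though the model
    equations remain evaluable.
    """
    if density < 0:
        raise ValueError("particle density cannot be negative")
    if diameter <= 0:
        raise ValueError("particle diameter must be positive")
    n = density * np.pi * diameter**2 / 4.0
    if n >= RSA_JAMMING_LIMIT:
        warnings.warn(
            f"coverage {n:.3f} exceeds the 2-D random-adsorption jamming "
            f"limit {RSA_JAMMING_LIMIT}; implausible for randomly adsorbed disks",
            stacklevel=2,
        )
    return n


def density_from_coverage(coverage: float, diameter: float) -> float:
    """Particle surface density giving a projected-disk coverage (m^-2)."""
    if not 0 <= coverage < 1:
        raise ValueError("coverage must lie in [0, 1)")
    if diameter <= 0:
        raise ValueError("particle diameter must be positive")
    return 4.0 * coverage / (np.pi * diameter**2)


@dataclass(frozen=True)
class NanoparticleLayer:
    """Description of the nanoparticle decoration of one device.

    Exactly one of two routes fixes the induced potential change:

    * ``delta_phi`` given directly (signed, volts), or
    * ``density``, ``per_particle_charge`` and ``double_layer_capacitance``
      given, from which ``delta_phi = N_NP * Q_NP / C_d`` is derived.

    ``charge_sign`` (+1/-1) may accompany a direct ``delta_phi`` to set its
    sign explicitly (the stored value becomes ``charge_sign * |delta_phi|``);
    when derived from charge the sign follows the particle charge.

    ``coverage`` is the projected-disk area fraction ``n`` in [0, 1); the
    two-region model degenerates at full coverage, so ``n = 1`` is accepted
    only for analytic limit checks.
    """

    coverage: float
    delta_phi: float | None = None
    charge_sign: int | None = None
    density: float | None = None
    core_diameter: float | None = None
    per_particle_charge: float | None = None
    double_layer_capacitance: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")
        from_charge = (
            self.density is not None
            and self.per_particle_charge is not None
            and self.double_layer_capacitance is not None
        )
        if (self.delta_phi is None) == (not from_charge):
            raise ValueError(
                "give exactly one of delta_phi or "
                "(density, per_particle_charge, double_layer_capacitance)"
            )
        if self.charge_sign is not None and self.charge_sign not in (-1, +1):
            raise ValueError("charge_sign must be +1 or -1")
        if from_charge:
            dphi = delta_phi_from_charge(
                self.density, self.per_particle_charge, self.double_layer_capacitance
            )
            sign = int(np.sign(self.per_particle_charge)) or +1
            if self.charge_sign is not None and self.charge_sign != sign and dphi != 0:
                raise ValueError("charge_sign contradicts the sign of per_particle_charge")
            object.__setattr__(self, "delta_phi", dphi)
            object.__setattr__(self, "charge_sign", sign)
        elif self.charge_sign is not None:
            object.__setattr__(self, "delta_phi", self.charge_sign * abs(self.delta_phi))
        else:
            object.__setattr__(
                self, "charge_sign", int(np.sign(self.delta_phi)) or +1
            )

    @classmethod
    def from_io_units(
        cls,
        n: float,
        delta_phi_mV: float | None = None,
        charge_sign: int | None = None,
        N_NP_per_cm2: float | None = None,
        core_diameter_nm: float | None = None,
        Q_NP_C: float | None = None,
        C_d_F_per_m2: float | None = None,
    ) -> "NanoparticleLayer":
        return cls(
            coverage=n,
            delta_phi=None if delta_phi_mV is None else delta_phi_mV * _MV,
            charge_sign=charge_sign,
            density=None if N_NP_per_cm2 is None else N_NP_per_cm2 * _PER_CM2,
            core_diameter=None if core_diameter_nm is None else core_diameter_nm * _NM,
            per_particle_charge=Q_NP_C,
            double_layer_capacitance=C_d_F_per_m2,
        )

    def to_io_dict(self) -> dict[str, float]:
        out: dict[str, float] = {
            "n": self.coverage,
            "delta_phi_mV": self.delta_phi / _MV,
            "charge_sign": self.charge_sign,
        }
        if self.density is not None:
            out["N_NP_per_cm2"] = self.density / _PER_CM2
        if self.core_diameter is not None:
            out["core_diameter_nm"] = self.core_diameter / _NM
        return out

    @classmethod
    def bare(cls) -> "NanoparticleLayer":
        """Particle-free surface (n = 0, delta_phi = 0)."""
        return cls(coverage=0.0, delta_phi=0.0)


@dataclass(frozen=True)
class ParticleField:
    """Hard-disk particle centers on a rectangular surface patch (SI m)."""

    patch_width: float
    patch_height: float
    centers: np.ndarray  # shape (N, 2)
    diameter: float
    seed: int | None = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centers", centers)
        if self.patch_width <= 0 or self.patch_height <= 0 or self.diameter <= 0:
            raise ValueError("patch dimensions and diameter must be positive")

    def __len__(self) -> int:
        return len(self.centers)

    def min_pair_distance(self) -> float:
        """Smallest center-to-center distance (inf for < 2 particles)."""
        if len(self) < 2:
            return np.inf
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def validate(self) -> None:
        """Check the hard-disk and in-patch invariants; raise on violation."""
        r = self.diameter / 2.0
        x, y = self.centers[:, 0], self.centers[:, 1]
        if len(self) and not (
            (x >= r).all()
            and (x <= self.patch_width - r).all()
            and (y >= r).all()
            and (y <= self.patch_height - r).all()
        ):
            raise ValueError("particle disks extend beyond the patch")
        if self.min_pair_distance() < self.diameter * (1 - 1e-12):
            raise ValueError("overlapping particles in field")

    # -- text I/O: CSV of centers plus a JSON sidecar with the geometry ----

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("x_nm,y_nm\n")
            for x, y in self.centers:
                fh.write(f"{x / _NM:.6f},{y / _NM:.6f}\n")
        sidecar = {
            "patch_width_nm": self.patch_width / _NM,
            "patch_height_nm": self.patch_height / _NM,
            "diameter_nm": self.diameter / _NM,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParticleField":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        centers = data * _NM if data.size else np.empty((0, 2))
        return cls(
            patch_width=meta["patch_width_nm"] * _NM,
            patch_height=meta["patch_height_nm"] * _NM,
            centers=centers,
            diameter=meta["diameter_nm"] * _NM,
            seed=meta["seed"],
        )


class PlacementError(RuntimeError):
    """Random sequential adsorption failed to reach the target coverage."""


def rsa_place_particles(
    patch_width: float,
    patch_height: float,
    target_coverage: float,
    diameter: float,
    seed: int,
    max_attempts_factor: int = 5000,
) -> ParticleField:
    """Place non-overlapping disks by random sequential adsorption.

    Uniform center proposals over the patch (kept a radius away from the
    edges so every disk lies wholly inside and the analytic coverage needs
    no edge correction); a proposal is accepted iff it keeps all
    center-to-center distances >= ``diameter``.  Placement stops at the
    particle count whose projected-disk coverage is closest to
    ``target_coverage``; a :class:`PlacementError` is raised if the attempt
    budget ``max_attempts_factor * target_count`` is exhausted first, which
    in practice only happens near the jamming limit.

    Deterministic for a fixed ``seed``.
    """
    if not 0 <= target_coverage < 0.5:
        raise ValueError("target coverage must lie in [0, 0.5) for hard-disk RSA")
    if diameter <= 0 or patch_width <= diameter or patch_height <= diameter:
        raise ValueError("patch must be larger than one particle diameter")
    disk_area = np.pi * diameter**2 / 4.0
    patch_area = patch_width * patch_height
    target_count = int(round(target_coverage * patch_area / disk_area))
    if target_count == 0:
        return ParticleField(patch_width, patch_height, np.empty((0, 2)), diameter, seed)

    rng = np.random.default_rng(seed)
    r = diameter / 2.0
    # cell list with cell size >= diameter: overlap candidates are confined
    # to the 3x3 cell neighborhood of a proposal
    nx = max(1, int(patch_width // diameter))
    ny = max(1, int(patch_height // diameter))
    cx, cy = patch_width / nx, patch_height / ny
    cells: dict[tuple[int, int], list[np.ndarray]] = {}

    centers: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_factor * target_count
    d2 = diameter * diameter
    while len(centers) < target_count:
        if attempts >= budget:
            raise PlacementError(
                f"placed {len(centers)}/{target_count} particles after "
                f"{attempts} attempts (target coverage {target_coverage})"
            )
        attempts += 1
        p = rng.uniform([r, r], [patch_width - r, patch_height - r])
        i, j = int(p[0] / cx), int(p[1] / cy)
        ok = True
        for ii in range(max(i - 1, 0), min(i + 2, nx)):
            for jj in range(max(j - 1, 0), min(j + 2, ny)):
                for q in cells.get((ii, jj), ()):
                    dx, dy = p[0] - q[0], p[1] - q[1]
                    if dx * dx + dy * dy < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers.append(p)
            cells.setdefault((i, j), []).append(p)

    return ParticleField(
        patch_width, patch_height, np.array(centers), diameter, seed
    )


def coverage_of_field(field: ParticleField) -> float:
    """Projected-disk coverage of a particle field.

    ``count * pi * d^2 / 4`` over the patch area; exact because generated
    disks lie wholly inside the patch.
    """
    disk_area = np.pi * field.diameter**2 / 4.0
    return len(field) * disk_area / (field.patch_width * field.patch_height)
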