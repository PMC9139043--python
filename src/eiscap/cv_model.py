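"""Two-region capacitance-voltage model of a nanoparticle-decorated EISCAP.

The decorated sensor is treated as two independent devices in parallel: a
particle-covered fraction ``n`` of the area whose interfacial potential is
shifted by ``delta_phi``, and a particle-free fraction ``1 - n``.  Each
fraction is a series chain of its gate-insulator capacitance and the
space-charge capacitance of the semiconductor beneath it (depletion
approximation, high-frequency inversion); the equivalent capacitance is the
sum of the two chains.  Discrete-particle electrostatics (fringing overlap
of neighboring depletion pockets) is deliberately not modeled: the model is
area-weighted and one-dimensional.

For a p-type substrate each sub-region passes, with rising gate voltage,
through

* accumulation (below its flat-band voltage): the chain reduces to the
  insulator capacitance, per area ``C_i0 = eps_i/d_i``;
* depletion: per-area chain capacitance ``1/S(V_eff)`` with
  ``S(V_eff) = sqrt(1/C_i0^2 + 2 V_eff/(q eps_s N_a))`` and
  ``V_eff = V_G - V_fb`` of that sub-region;
* strong inversion: the depletion layer saturates at ``w_m`` and the
  chain bottoms out at the high-frequency floor ``eps_s/w_m`` per area
  (insulator term dropped, as usual for ``C_i >> C_inv``).

Positively charged particles on a p-type device lower the flat-band voltage
of the covered fraction, so the curve shifts toward less positive gate
voltages and the capacitance at fixed depletion voltage drops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .device_model import DeviceParams
from .nanoparticle_layer import NanoparticleLayer

__all__ = [
    "CVCurve",
    "depletion_width",
    "flat_band_voltages",
    "ceq_accumulation",
    "ceq_inversion",
    "ceq_depletion",
    "ceq_depletion_series",
    "simulate_cv",
    "cv_shift_at_capacitance",
    "capacitance_change_at_voltage",
]

_MV = 1e-3
_NF = 1e-9

ACCUMULATION = "accumulation"
DEPLETION = "depletion"
INVERSION = "inversion"
MIXED = "mixed"


def _charge_factor(device: DeviceParams) -> float:
    """2/(q eps_s N_a), the voltage coefficient inside S(.)."""
    c = device.constants
    return 2.0 / (c.q * device.eps_s * device.semiconductor.acceptor_density)


def sqrt_term(v_eff, device: DeviceParams):
    """S(V_eff) = sqrt(1/C_i0^2 + 2 V_eff/(q eps_s N_a)) in m^2/F.

    The reciprocal is the per-area capacitance of one insulator +
    space-charge chain in depletion; S(0) = 1/C_i0.
    """
    return np.sqrt(1.0 / device.c_i0**2 + _charge_factor(device) * v_eff)


def min_effective_voltage(device: DeviceParams) -> float:
    """Most negative V_eff for which S(.) is real (domain edge)."""
    return -1.0 / (device.c_i0**2 * _charge_factor(device))


def depletion_width(v_eff, device: DeviceParams):
    """Space-charge width beneath one sub-region (m).

    ``w = sqrt(eps_s^2/C_i0^2 + 2 eps_s V_eff/(q N_a)) - eps_s/C_i0`` where
    ``V_eff`` is the gate voltage in excess of the sub-region's flat-band
    voltage.  Zero at flat band and monotone increasing; negative ``V_eff``
    (accumulation) is rejected — callers clamp it.
    """
    v_eff = np.asarray(v_eff, dtype=float)
    if np.any(v_eff < 0):
        raise ValueError("effective voltage must be non-negative in depletion")
    eps_s = device.eps_s
    w = eps_s * sqrt_term(v_eff, device) - eps_s / device.c_i0
    return w if w.ndim else float(w)


def flat_band_voltages(
    device: DeviceParams, layer: NanoparticleLayer
) -> tuple[float, float]:
    """Flat-band voltages (bare region, particle-covered region) in volts.

    ``V_fb = V_ip - phi_0`` and ``V_fbNP = V_ip - (phi_0 + delta_phi)``
    with ``delta_phi`` signed by the particle charge, so positively charged
    particles give ``V_fbNP < V_fb``.
    """
    v_ip = device.interface.v_ip
    phi_0 = device.interface.phi_0
    v_fb = v_ip - phi_0
    v_fb_np = v_ip - (phi_0 + layer.delta_phi)
    return v_fb, v_fb_np


def ceq_accumulation(device: DeviceParams) -> float:
    """Equivalent capacitance on the accumulation plateau (F).

    ``eps_i A / d_i`` — the space-charge capacitance is negligible there,
    so the result does not depend on the particle coverage.
    """
    return device.c_i0 * device.area


def ceq_inversion(device: DeviceParams) -> float:
    """Equivalent capacitance on the high-frequency inversion plateau (F).

    ``eps_s A / w_m``, coverage-independent; equals
    ``eps_s q A sqrt(N_a / (4 eps_s k T ln(N_a/n_i)))``.
    """
    return device.eps_s * device.area / device.w_max


def subregion_capacitance_per_area(v_eff, device: DeviceParams):
    """Per-area capacitance of one insulator + space-charge chain (F/m^2).

    Total in ``v_eff``: clamped at the insulator capacitance ``C_i0`` for
    ``v_eff <= 0`` (accumulation) and floored at the high-frequency
    inversion value ``eps_s/w_m`` once depletion saturates, which keeps the
    assembled curve continuous and non-increasing.
    """
    v_eff = np.asarray(v_eff, dtype=float)
    c_i0 = device.c_i0
    floor = device.eps_s / device.w_max
    c_dep = 1.0 / sqrt_term(np.maximum(v_eff, 0.0), device)
    c = np.where(v_eff <= 0, c_i0, np.maximum(c_dep, floor))
    return c if c.ndim else float(c)


def _effective_voltages(v_g, device: DeviceParams, layer: NanoparticleLayer):
    """(V_eff covered region, V_eff bare region) for gate voltage v_g."""
    v_ip = device.interface.v_ip
    phi_0 = device.interface.phi_0
    v_g = np.asarray(v_g, dtype=float)
    return v_g - v_ip + phi_0 + layer.delta_phi, v_g - v_ip + phi_0


def ceq_depletion(v_g, device: DeviceParams, layer: NanoparticleLayer):
    """Equivalent capacitance of the decorated device at gate voltage v_g (F).

    Closed form: ``A n / S(V_eff,NP) + A (1-n) / S(V_eff,0)`` with each
    sub-region term clamped to its accumulation value below its flat band
    and to its inversion floor beyond depletion saturation, making the
    expression total in ``v_g``.  Accepts scalars or arrays.
    """
    x_np, x_0 = _effective_voltages(v_g, device, layer)
    n = layer.coverage
    c = n * subregion_capacitance_per_area(x_np, device) + (
        1.0 - n
    ) * subregion_capacitance_per_area(x_0, device)
    c = device.area * np.asarray(c)
    return c if c.ndim else float(c)


def ceq_depletion_series(v_g, device: DeviceParams, layer: NanoparticleLayer):
    """Equivalent capacitance via the explicit equivalent-circuit chains (F).

    Builds the four branch capacitances C_iNP = eps_i A n/d_i,
    C_sNP = eps_s A n/w_NP, C_i = eps_i A (1-n)/d_i, C_s = eps_s A (1-n)/w_s
    and composes C_iNP*C_sNP/(C_iNP+C_sNP) + C_i*C_s/(C_i+C_s).  Defined
    for gate voltages where both sub-regions are depleted (no clamps); it
    must agree with :func:`ceq_depletion` there and exists as an
    independent cross-check of the closed form.
    """
    x_np, x_0 = _effective_voltages(v_g, device, layer)
    if np.any(np.asarray(x_np) < 0) or np.any(np.asarray(x_0) < 0):
        raise ValueError("series form requires both sub-regions in depletion")
    eps_s = device.eps_s
    n = layer.coverage
    c_i0 = device.c_i0

    def chain(fraction, v_eff):
        if fraction == 0:
            return np.zeros_like(np.asarray(v_eff, dtype=float))
        c_ins = fraction * device.area * c_i0
        w = eps_s * sqrt_term(v_eff, device) - eps_s / c_i0
        w = np.asarray(w, dtype=float)
        c_sc = np.where(w > 0, fraction * device.area * eps_s / np.where(w > 0, w, 1.0), np.inf)
        return np.where(np.isinf(c_sc), c_ins, c_ins * c_sc / (c_ins + c_sc))

    c = chain(n, x_np) + chain(1.0 - n, x_0)
    c = np.asarray(c)
    return c if c.ndim else float(c)


def _region_labels(v_eff, device: DeviceParams) -> np.ndarray:
    """Regime of one sub-region per grid point."""
    v_eff = np.asarray(v_eff, dtype=float)
    floor = device.eps_s / device.w_max
    c_dep = 1.0 / sqrt_term(np.maximum(v_eff, 0.0), device)
    labels = np.full(v_eff.shape, DEPLETION, dtype=object)
    labels[v_eff <= 0] = ACCUMULATION
    labels[(v_eff > 0) & (c_dep <= floor)] = INVERSION
    return labels


@dataclass(frozen=True)
class CVCurve:
    """Sampled capacitance-voltage characteristic of one device + layer."""

    gate_voltages: np.ndarray  # V, strictly increasing
    capacitances: np.ndarray  # F
    region_labels: np.ndarray  # {accumulation, depletion, inversion, mixed}
    device: DeviceParams
    layer: NanoparticleLayer

    def __post_init__(self) -> None:
        v = np.asarray(self.gate_voltages, dtype=float)
        c = np.asarray(self.capacitances, dtype=float)
        if v.shape != c.shape or v.shape != np.asarray(self.region_labels).shape:
            raise ValueError("gate_voltages, capacitances and labels must match")
        if np.any(np.diff(v) <= 0):
            raise ValueError("gate voltages must be strictly increasing")
        object.__setattr__(self, "gate_voltages", v)
        object.__setattr__(self, "capacitances", c)

    def to_csv(self, path: str | Path) -> None:
        """Write `V_G_mV, C_eq_nF, region` rows under a `#` parameter header."""
        path = Path(path)
        with path.open("w") as fh:
            for key, val in self.device.to_io_dict().items():
                fh.write(f"# {key} = {val!r}\n")
            for key, val in self.layer.to_io_dict().items():
                fh.write(f"# layer.{key} = {val!r}\n")
            fh.write("V_G_mV,C_eq_nF,region\n")
            for v, c, lab in zip(
                self.gate_voltages, self.capacitances, self.region_labels
            ):
                fh.write(f"{v / _MV:.3f},{c / _NF:.6f},{lab}\n")


def simulate_cv(
    v_min: float,
    v_max: float,
    n_points: int,
    device: DeviceParams,
    layer: NanoparticleLayer | None = None,
    smoothing_window: float | None = None,
) -> CVCurve:
    """Assemble a full C-V curve on a uniform gate-voltage grid.

    Each sub-region is evaluated independently in its own regime and the
    area-weighted sum taken; a grid point is labeled with the common regime
    of the two sub-regions, or ``mixed`` where they differ.  The result is
    continuous, non-increasing and bounded by the inversion and
    accumulation plateaus.

    ``smoothing_window`` (volts), if given, applies a cosine ramp across
    each sub-region's accumulation-to-depletion corner.  The hard-switch
    depletion approximation overestimates the sharpness of that corner;
    the ramp is cosmetic, for plotting only, and is never used in any
    quantitative readout.
    """
    if not v_min < v_max:
        raise ValueError("v_min must be below v_max")
    if n_points < 2:
        raise ValueError("need at least two grid points")
    layer = layer if layer is not None else NanoparticleLayer.bare()
    v = np.linspace(v_min, v_max, n_points)
    x_np, x_0 = _effective_voltages(v, device, layer)
    n = layer.coverage

    def per_area(x):
        c = subregion_capacitance_per_area(x, device)
        if smoothing_window:
            w = float(smoothing_window)
            t = np.clip((x + w) / (2.0 * w), 0.0, 1.0)
            s = 0.5 - 0.5 * np.cos(np.pi * t)
            c_dep = subregion_capacitance_per_area(np.maximum(x, 0.0), device)
            c = (1.0 - s) * device.c_i0 + s * c_dep
        return c

    cap = device.area * (n * per_area(x_np) + (1.0 - n) * per_area(x_0))

    lab_np = _region_labels(x_np, device)
    lab_0 = _region_labels(x_0, device)
    if n == 0:
        labels = lab_0
    elif n == 1:
        labels = lab_np
    else:
        labels = np.where(lab_np == lab_0, lab_0, MIXED)
    return CVCurve(v, cap, labels, device, layer)


def _voltage_at_capacitance(curve: CVCurve, c_ref: float) -> float:
    c = curve.capacitances
    v = curve.gate_voltages
    if not (c.min() < c_ref < c.max()):
        raise ValueError(
            f"reference capacitance {c_ref} F outside the curve's span "
            f"[{c.min()}, {c.max()}] F"
        )
    # capacitance is non-increasing in V; interpolate on the reversed arrays
    return float(np.interp(c_ref, c[::-1], v[::-1]))


def cv_shift_at_capacitance(curve_a: CVCurve, curve_b: CVCurve, c_ref: float) -> float:
    """Horizontal shift between two curves read at a fixed capacitance (V).

    Linearly interpolates each curve's crossing of ``c_ref`` (which must
    lie strictly inside both depletion spans) and returns
    ``V_b(c_ref) - V_a(c_ref)``; negative when curve_b sits at less
    positive voltages than curve_a.
    """
    return _voltage_at_capacitance(curve_b, c_ref) - _voltage_at_capacitance(
        curve_a, c_ref
    )


def capacitance_change_at_voltage(
    curve_a: CVCurve, curve_b: CVCurve, v_ref: float
) -> float:
    """Vertical capacitance difference at a fixed gate voltage (F)."""
    for curve in (curve_a, curve_b):
        v = curve.gate_voltages
        if not (v[0] <= v_ref <= v[-1]):
            raise ValueError(f"reference voltage {v_ref} V outside grid [{v[0]}, {v[-1]}]")
    ca = float(np.interp(v_ref, curve_a.gate_voltages, curve_a.capacitances))
    cb = float(np.interp(v_ref, curve_b.gate_voltages, curve_b.capacitances))
    return cb - ca
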