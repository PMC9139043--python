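"""Constant-capacitance (ConCap) readout of the decorated sensor.

In ConCap mode a feedback loop adjusts the gate voltage so that the device
capacitance stays pinned at a working value chosen in the depletion region
of the bare device's C-V curve.  When charged nanoparticles decorate a
fraction ``n`` of the surface, the loop must apply an additional voltage
``delta_V = V_G,NP - V_G`` to restore the working capacitance; this module
solves that balance

    n / S(V - V_ip + phi_0 + delta_phi) + (1 - n) / S(V - V_ip + phi_0)
        = C_work / A

for ``V`` by bracketed bisection (the left side is strictly monotone in
``V`` while both sub-regions stay depleted, so bisection is robust).  Only
at full coverage does the readout equal the interfacial potential change
(``delta_V = -delta_phi``); at partial coverage it is strictly smaller in
magnitude, which is the central quantitative point of the model.

Also provided: coverage sweeps, idealized step-protocol time traces
(instantaneous plateaus, no adsorption kinetics), and the inverse problem
of estimating ``delta_phi`` from an observed ConCap shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import bisect, brentq

from .cv_model import (
    ceq_accumulation,
    ceq_depletion,
    ceq_inversion,
    min_effective_voltage,
    sqrt_term,
)
from .device_model import DeviceParams
from .nanoparticle_layer import NanoparticleLayer

__all__ = [
    "ConCapResult",
    "StepProtocol",
    "ConCapTrace",
    "baseline_gate_voltage",
    "solve_concap_voltage",
    "concap_sweep",
    "simulate_concap_timeseries",
    "estimate_delta_phi",
]

_MV = 1e-3

#: bisection controls (absolute voltage tolerance, iteration cap, bracket
#: expansion attempts) — the nanovolt tolerance sits six orders of
#: magnitude below the millivolt scale of the signals and costs only ~30
#: bisection steps.
VOLTAGE_TOL = 1e-9
MAX_ITER = 200
MAX_EXPANSIONS = 5


class ConCapSolverError(RuntimeError):
    """The constant-capacitance condition could not be bracketed/solved."""


@dataclass(frozen=True)
class ConCapResult:
    """Solved ConCap operating point for one device + particle layer."""

    working_capacitance: float  # F
    v_g_baseline: float  # V, bare-device gate voltage at C_work
    v_g_np: float  # V, gate voltage restoring C_work with particles
    delta_v: float  # V, v_g_np - v_g_baseline (the ConCap signal change)
    solver_iterations: int
    residual: float  # F, capacitance mismatch at the returned voltage
    regime_clamped: bool = False  # True if a sub-region left depletion


def baseline_gate_voltage(c_work: float, device: DeviceParams) -> float:
    """Gate voltage of the bare device at a depletion working capacitance.

    Closed-form inversion of the bare depletion relation:
    ``V_G = V_ip - phi_0 + (q eps_s N_a / 2) ((A/C_work)^2 - 1/C_i0^2)``.
    ``c_work`` must lie strictly between the inversion and accumulation
    plateaus.
    """
    c_acc = ceq_accumulation(device)
    c_inv = ceq_inversion(device)
    if not (c_inv < c_work < c_acc):
        raise ValueError(
            f"working capacitance {c_work} F outside the depletion span "
            f"({c_inv}, {c_acc}) F"
        )
    consts = device.constants
    n_a = device.semiconductor.acceptor_density
    quad = (device.area / c_work) ** 2 - 1.0 / device.c_i0**2
    return (
        device.interface.v_ip
        - device.interface.phi_0
        + 0.5 * consts.q * device.eps_s * n_a * quad
    )


def _depletion_residual(v, c_work, device, layer):
    """Per-area constant-capacitance balance, pure depletion form (F/m^2).

    Zero-weight sub-region terms are skipped entirely so that at n = 0 or
    n = 1 the other region's square-root domain does not constrain v.
    """
    v_ip = device.interface.v_ip
    phi_0 = device.interface.phi_0
    n = layer.coverage
    out = -c_work / device.area
    if n > 0:
        out = out + n / sqrt_term(v - v_ip + phi_0 + layer.delta_phi, device)
    if n < 1:
        out = out + (1 - n) / sqrt_term(v - v_ip + phi_0, device)
    return out


def _domain_floor(device, layer) -> float:
    """Lowest gate voltage with real square roots for all weighted regions."""
    v_ip = device.interface.v_ip
    phi_0 = device.interface.phi_0
    x_min = min_effective_voltage(device)
    floors = []
    if layer.coverage > 0:
        floors.append(v_ip - phi_0 - layer.delta_phi + x_min)
    if layer.coverage < 1:
        floors.append(v_ip - phi_0 + x_min)
    return max(floors)


def _in_depletion(v, device, layer) -> bool:
    v_ip = device.interface.v_ip
    phi_0 = device.interface.phi_0
    floor = device.eps_s / device.w_max
    for x, frac in (
        (v - v_ip + phi_0 + layer.delta_phi, layer.coverage),
        (v - v_ip + phi_0, 1 - layer.coverage),
    ):
        if frac == 0:
            continue
        if x <= 0 or 1.0 / sqrt_term(x, device) < floor:
            return False
    return True


def solve_concap_voltage(
    c_work: float,
    device: DeviceParams,
    layer: NanoparticleLayer,
    voltage_tol: float = VOLTAGE_TOL,
) -> ConCapResult:
    """Solve the constant-capacitance condition for the gate voltage.

    Bisection over an initial bracket of ``v_baseline +/- (2 |delta_phi| +
    0.5 V)``, clamped to the domain of the square root and geometrically
    expanded (up to 5 doublings) if the residual does not change sign.  The
    residual diverges at the domain edge, so a bracket exists whenever the
    working capacitance lies in the bare depletion span.

    The balance as written assumes both sub-regions depleted.  If at the
    solution a weighted sub-region has left that regime (effective voltage
    <= 0, i.e. locally accumulated, or capacitance below the inversion
    floor), the result is flagged ``regime_clamped`` but the root of the
    written balance is still returned — it stays unique and strictly
    monotone in ``delta_phi``, which the clamped expression does not (its
    signal saturates once a region accumulates).  Only if the written
    balance cannot be bracketed at all is the clamped capacitance
    expression solved instead.
    """
    v_base = baseline_gate_voltage(c_work, device)
    v_domain = _domain_floor(device, layer)
    half = 2.0 * abs(layer.delta_phi) + 0.5
    eps = 1e-12

    f = lambda v: _depletion_residual(v, c_work, device, layer)
    lo = max(v_base - half, v_domain + eps)
    hi = v_base + half
    bracketed = False
    for _ in range(MAX_EXPANSIONS + 1):
        if f(lo) * f(hi) <= 0:
            bracketed = True
            break
        half *= 2.0
        lo = max(v_base - half, v_domain + eps)
        hi = v_base + half
    if bracketed:
        v_np, info = bisect(
            f, lo, hi, xtol=voltage_tol, maxiter=MAX_ITER, full_output=True
        )
        iterations = info.iterations
        regime_clamped = not _in_depletion(v_np, device, layer)
        residual = float(f(v_np) * device.area)
    else:
        # fall back to the clamped (total) capacitance expression, which is
        # defined for every gate voltage
        g = lambda v: ceq_depletion(v, device, layer) - c_work
        half_c = 2.0 * abs(layer.delta_phi) + 0.5
        lo_c, hi_c = v_base - half_c, v_base + half_c
        for _ in range(MAX_EXPANSIONS + 1):
            if g(lo_c) * g(hi_c) <= 0:
                break
            half_c *= 2.0
            lo_c, hi_c = v_base - half_c, v_base + half_c
        else:
            raise ConCapSolverError(
                f"could not bracket the working capacitance {c_work} F for "
                f"n={layer.coverage}, delta_phi={layer.delta_phi} V"
            )
        v_np, info = bisect(
            g, lo_c, hi_c, xtol=voltage_tol, maxiter=MAX_ITER, full_output=True
        )
        iterations = info.iterations
        regime_clamped = True
        residual = float(g(v_np))
    return ConCapResult(
        working_capacitance=c_work,
        v_g_baseline=v_base,
        v_g_np=float(v_np),
        delta_v=float(v_np) - v_base,
        solver_iterations=iterations,
        residual=residual,
        regime_clamped=regime_clamped,
    )


def concap_sweep(
    coverages: Sequence[float],
    c_work: float,
    device: DeviceParams,
    delta_phi: float,
) -> list[ConCapResult]:
    """ConCap operating points over a list of coverages at fixed delta_phi."""
    out = []
    for n in coverages:
        layer = NanoparticleLayer(coverage=n, delta_phi=delta_phi)
        try:
            out.append(solve_concap_voltage(c_work, device, layer))
        except (ValueError, ConCapSolverError) as exc:
            raise ConCapSolverError(f"at coverage n={n}: {exc}") from exc
    return out


@dataclass(frozen=True)
class StepProtocol:
    """Ordered decoration steps: (duration seconds, layer) per segment."""

    steps: Sequence[tuple[float, NanoparticleLayer]]
    sampling_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if any(duration <= 0 for duration, _ in self.steps):
            raise ValueError("segment durations must be positive")


@dataclass(frozen=True)
class ConCapTrace:
    """Idealized piecewise-constant ConCap signal trace."""

    times: np.ndarray  # s
    delta_v: np.ndarray  # V
    coverages: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("time_s,delta_V_mV,coverage\n")
            for t, dv, n in zip(self.times, self.delta_v, self.coverages):
                fh.write(f"{t:.6g},{dv / _MV:.3f},{n:g}\n")


def simulate_concap_timeseries(
    protocol: StepProtocol, c_work: float, device: DeviceParams
) -> ConCapTrace:
    """Piecewise-constant ConCap trace for a decoration step protocol.

    Each segment's level is the solved ConCap shift for its layer; levels
    switch instantaneously at segment boundaries (adsorption kinetics and
    feedback-loop dynamics are not modeled, matching a stabilized reading).
    """
    times, values, covs = [], [], []
    t0 = 0.0
    for duration, layer in protocol.steps:
        level = solve_concap_voltage(c_work, device, layer).delta_v
        t = np.arange(t0, t0 + duration, protocol.sampling_interval)
        times.append(t)
        values.append(np.full(t.shape, level))
        covs.append(np.full(t.shape, layer.coverage))
        t0 += duration
    return ConCapTrace(
        np.concatenate(times) if times else np.empty(0),
        np.concatenate(values) if values else np.empty(0),
        np.concatenate(covs) if covs else np.empty(0),
    )


def estimate_delta_phi(
    n: float,
    observed_delta_v: float,
    c_work: float,
    device: DeviceParams,
    search_max: float = 1.0,
) -> float:
    """Interfacial potential change explaining an observed ConCap shift (V).

    Inverts the forward ConCap model at known coverage ``n`` by root
    finding over ``delta_phi``: returns the value whose forward-simulated
    shift equals ``observed_delta_v``.  The recovered ``delta_phi`` has the
    opposite sign of the observed shift; because ``|delta_V| <= |delta_phi|``
    the magnitude search starts at ``|observed_delta_v|`` and expands until
    bracketed (up to ``search_max`` volts, beyond which the shift is deemed
    unattainable for this coverage).  The returned value is forward-checked
    to 0.01 mV.
    """
    if not 0 < n <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    if observed_delta_v == 0:
        return 0.0
    sign = -1.0 if observed_delta_v > 0 else 1.0  # sign of delta_phi
    target_mag = abs(observed_delta_v)

    def shift_mag(dphi_mag: float) -> float:
        """|delta_V| for |delta_phi| = dphi_mag; increasing in its argument."""
        layer = NanoparticleLayer(coverage=n, delta_phi=sign * dphi_mag)
        return abs(solve_concap_voltage(c_work, device, layer).delta_v)

    # |delta_V| <= |delta_phi| (equality only at n = 1), so the root sits at
    # or above target_mag; the small lower margin absorbs forward-solver
    # noise at the n = 1 boundary
    lo = max(target_mag - 1e-6, 0.0)
    hi = target_mag
    while shift_mag(hi) < target_mag:
        hi *= 2.0
        if hi > search_max:
            raise ValueError(
                f"|delta_V| = {target_mag} V unattainable at coverage {n} "
                f"within |delta_phi| <= {search_max} V"
            )
    mag = brentq(
        lambda m: shift_mag(m) - target_mag, lo, hi,
        xtol=VOLTAGE_TOL, maxiter=MAX_ITER,
    )
    dphi = sign * float(mag)
    check = sign * -1.0 * shift_mag(float(mag))
    if abs(check - observed_delta_v) > 1e-5:
        raise ConCapSolverError(
            f"forward check failed: recovered delta_phi={dphi} V reproduces "
            f"{check} V instead of {observed_delta_v} V"
        )
    return dphi
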