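# Methods

## Physical model and assumptions

The package models a p-type electrolyte-insulator-semiconductor capacitor
whose surface is partially covered by charged nanoparticles. The covered
fraction *n* and the bare fraction 1 − *n* are treated as two independent
one-dimensional MOS-like stacks in parallel; their capacitances add with
area weights. This two-region picture rests on the following assumptions:

* **No fringing overlap** between the depletion pockets under neighboring
  particles — valid when inter-particle spacing is large against the local
  depletion depth, which the electrostatic inter-particle repulsion that
  limits coverage also tends to ensure.
* **Depletion approximation** for the space charge: abrupt edge, fully
  ionized acceptors, no minority-carrier response (high-frequency
  small-signal measurement). The per-area capacitance of one stack in
  depletion is `1/S(V_eff)` with `S(V) = sqrt(1/C_i0² + 2V/(q ε_s N_a))`
  and `V_eff` the gate voltage in excess of that stack's flat-band
  voltage.
* **Series resistances and the electrolyte double layer are neglected** in
  the equivalent circuit (thin-oxide, sub-kHz, > 0.1 mM regime where the
  double-layer capacitance is much larger than the oxide capacitance).
* The particle layer enters **only** through a shift Δφ of the interfacial
  potential of the covered fraction: `V_fbNP = V_ip − (φ₀ + Δφ)`. Discrete
  particle electrostatics, ion sensitivity of the oxide (site binding) and
  Debye-screening physics are outside the model; screening is absorbed
  into the *effective* per-particle charge when Δφ is derived from
  `Δφ = N_NP·Q_NP/C_d`.

## Regime stitching of the C–V curve

Each sub-region switches regimes independently of the other:

* below its flat band the stack contributes its insulator capacitance
  `C_i0` per area (no accumulation-layer model);
* in depletion it contributes `1/S(V_eff)`;
* its contribution is floored at `ε_s/w_m` per area, the high-frequency
  strong-inversion value with the insulator series term dropped (the usual
  `C_i ≫ C_inv` simplification), where `w_m` is the maximum depletion
  width.

The floor is applied to the *capacitance*, not by clamping the width
inside the full series chain. Clamping the width would bottom the chain
out at `1/(d_i/ε_i + w_m/ε_s)` per area — for the canonical device 8.0 nF
against the 9.55 nF of the simplified inversion expression — and jumping
from there to the simplified plateau would make the curve non-monotone.
The capacitance floor keeps the assembled curve continuous, non-increasing
and bounded by the accumulation and inversion plateaus, at the price of
placing the depletion-to-inversion hand-off slightly before the width
formally reaches `w_m`. Consequently the model's inversion onset is
defined as "the stack capacitance falls to its inversion floor".

The hard accumulation switch overestimates the sharpness of the
accumulation-depletion corner of a real device. `simulate_cv` accepts an
optional cosine-ramp `smoothing_window` that rounds this corner **for
plotting only**; it is excluded from every quantitative readout and every
test.

## ConCap solver

The constant-capacitance balance

```
n/S(V − V_ip + φ₀ + Δφ) + (1−n)/S(V − V_ip + φ₀) = C_work/A
```

is solved for V by bisection. The left side is strictly decreasing in V
and diverges at the lower edge of the square root's domain, so a sign
change always exists inside the initial bracket
`V_baseline ± (2|Δφ| + 0.5 V)` (clamped to the domain, geometrically
doubled up to five times as a safety net). The absolute voltage tolerance
is 1 nV with a 200-iteration cap — about 30 bisection steps in practice.
The nanovolt tolerance is deliberately far below the millivolt scale of
the signals so that analytic identities (e.g. ΔV = −Δφ at n = 1, checked
to 10⁻⁴ mV) hold to well within their stated tolerance rather than at its
boundary.

Zero-weight terms are skipped when evaluating the balance, so at n = 0 or
n = 1 the other region's square-root domain does not artificially restrict
the bracket.

**Regime guard.** The balance as written assumes both sub-regions
depleted. When the solved voltage puts a weighted sub-region outside that
regime (locally accumulated, or below the inversion floor), the result is
flagged `regime_clamped=True` but the root of the written balance is still
returned. The alternative — re-solving with the regime-clamped capacitance
expression — was rejected because the clamped signal *saturates* once the
covered region accumulates: ΔV becomes independent of Δφ, which destroys
the uniqueness of the inverse problem (`estimate_delta_phi`) precisely in
the large-|Δφ|, small-n corner where it matters. The written balance keeps
ΔV strictly monotone in Δφ throughout. The clamped expression is used only
as a fallback if the written balance cannot be bracketed at all.

`estimate_delta_phi` inverts the forward solver by root finding over |Δφ|,
exploiting |ΔV| ≤ |Δφ| (equality only at n = 1) to start the bracket at
the observed magnitude; a 1 µV lower margin absorbs forward-solver noise
at the n = 1 boundary, and the search is capped (default 1 V) so an
unattainable observation fails loudly. Every estimate is forward-checked
to 0.01 mV.

## Nanoparticle layer and synthetic fields

Coverage is defined as projected hard-disk area fraction at the mean core
diameter, `n = N_NP·π·d²/4`. Real image-analysis pipelines measure
per-particle areas of a polydisperse ensemble, so density/coverage pairs
quoted from experiments are not exactly consistent with this mean-diameter
formula (the measured 6.17×10¹⁰ cm⁻² at d = 28 nm gives n = 0.38 by the
formula where image analysis reported 0.36); the formula is the package's
contract, and both routes of entry (density or coverage) are exact
inverses of each other.

Synthetic particle fields use random sequential adsorption (RSA) of hard
disks: uniform center proposals, rejection on any center distance below
one diameter, cell-list neighbor search. Centers are kept at least one
radius from the patch edge so every disk lies wholly inside and the
analytic coverage needs no edge-clipping correction. Placement stops at
the disk count closest to the target coverage, making the achieved
coverage exact to within one disk (≈ 6×10⁻⁴ for 28 nm disks on a 1 µm²
patch); an attempt budget of `max_attempts_factor × target count`
(default 5000×) turns jamming-limit pathologies into an explicit error.
Conversions warn above the 2-D RSA jamming limit (0.547), the highest
coverage reachable by random adsorption of equal disks. Generated fields
are deterministic per seed (`numpy.random.default_rng`).

What the generator does **not** emulate: polydisperse diameters,
electrostatic inter-particle correlations (RSA gives slightly different
pair statistics than interacting adsorption), particle clustering, and
image-analysis artifacts. Tests passing on RSA fields therefore validate
the geometry/coverage bookkeeping, not the statistics of real micrographs.

## Parameters, units, defaults

Internally everything is SI; bench units (nm, cm⁻³, cm², mV, nF) are
converted exactly once at the I/O boundary. Key parameters of the
canonical device used throughout the examples and tests:

| parameter | value | meaning |
|---|---|---|
| ε_ir, d_i | 3.9, 35 nm | SiO₂ gate oxide → C_i0 = 9.87×10⁻⁴ F/m² |
| ε_sr, N_a | 11.7, 2.76×10¹⁵ cm⁻³ | p-Si, ~5 Ω·cm wafer |
| n_i, T | 1.5×10¹⁰ cm⁻³, 300 K | → w_m = 542.5 nm |
| A | 0.5 cm² | electrolyte-contacted area |
| V_ip | 0 | lumped NP-independent potentials (default) |
| φ₀, φ_NP | −10 mV, +30 mV | interfacial potentials → Δφ = +40 mV |
| C_work | 30 nF | ConCap working point (baseline V_G ≈ 50 mV) |

Physical constants default to the rounded textbook values (q = 1.6×10⁻¹⁹ C,
k = 1.38×10⁻²³ J/K, ε₀ = 8.854×10⁻¹² F/m) and are overridable in the
config; pinning them keeps simulated curves stable against CODATA
revisions.

The C–V voltage grid defaults to 1 mV spacing; shift and capacitance-change
readouts interpolate linearly between grid points, keeping interpolation
error far below 1 mV. CSV outputs print voltages to 0.001 mV and
capacitances to 0.001 nF.

## Test-suite problem sizes

The suite favors closed-form and small-n brute-force oracles: the
depletion width is checked against a numeric inversion of the
insulator/space-charge voltage balance; the ConCap bisection against a
10⁵-point dense scan of the residual over the solver's own bracket for 50
random in-regime parameter sets; the closed-form depletion capacitance
against the explicit four-capacitor equivalent-circuit composition at 10³
random operating points (10⁻¹² relative); the inverse estimator against
forward-simulated shifts on a 9 × 8 coverage × Δφ grid. RSA fields are
tested on 1 µm² patches (≈ 200–600 particles), large enough for coverage
statistics yet exhaustively checkable for overlaps. The whole suite runs
in a few seconds.

## Known limitations

* p-type substrates only; the sign machinery generalizes but n-type is
  neither exposed nor tested.
* No accumulation-layer or low-frequency inversion capacitance; the
  accumulation-depletion transition is a hard switch (cosmetic smoothing
  aside).
* No interface-trap dispersion, no frequency dependence, no
  double-layer/series-resistance elements.
* ConCap traces are ideal plateaus: no adsorption kinetics, feedback
  dynamics, drift or noise.
* Wafer resistivity is not converted to doping (no mobility model);
  acceptor density is entered directly.
* `regime_clamped` results mean the written depletion balance was
  extrapolated outside its nominal regime; treat signals there as
  qualitative.
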