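# Methods

`mitoswell` simulates Ca²⁺-induced swelling of a single mitochondrion as a
two-compartment (matrix / cytosol) electro-diffusion problem coupled to a
quasi-static elastic membrane. This note records the model, its assumptions,
the unit normalization, the numerical choices, and the known limitations —
in particular where the package's behavior is a design decision rather than
a forced consequence of the underlying biophysics.

## State and compartments

The matrix of one prolate-spheroidal mitochondrion (semi-axes a = 0.5 µm,
c = 1 µm) exchanges Ca²⁺, K⁺, H⁺, a weak acid (A⁻/AH, a surrogate for the
second dissociation of phosphate, pKa 7.20) and a neutral "respiration
activator" with a cytosolic compartment of volume 2.86 × V_m(0). The state
vector is

    [ΔΨ (mV), Ca²⁺_in, K⁺_in, H⁺_in(free), A_in, acid_in, Ca²⁺_out, K⁺_out]

with concentrations in µM and time in minutes. Cytosolic pH (7.00) and the
cytosolic acid pool (50 µM) are clamped; cytosolic Ca²⁺ and K⁺ are conserved
pools, with cytosolic Ca²⁺ additionally floored at a buffered background of
0.5 µM. ΔΨ > 0 means matrix-negative (energized).

## Transport laws

* **Electrodiffusion.** Every ionic pathway uses the constant-field (GHK)
  flux. With u = −z·ΔΨ/V_T (V_T = k_BT/e ≈ 26.7 mV at 310 K), net influx is

      J = p · (a_out − a_in·e^u) · u / (e^u − 1)

  whose ΔΨ → 0 limit is Fick's law p(a_out − a_in). For |u| < 10⁻⁴ a
  second-order series replaces the removable 0/0. All fluxes are
  influx-positive throughout derivative assembly; the area factor
  S_m(t)/S_m(0) scales every membrane flux as the organelle swells.
* **Pathways.** Ca²⁺ enters through a uniporter; K⁺ and H⁺ move through a
  K⁺/H⁺ exchange pair whose permeabilities scale linearly with the
  counter-ion gradient (p_K,H ∝ |Δ[H⁺]| in µM, p_H,K ∝ |Δ[K⁺]| in mM); Ca²⁺,
  K⁺, H⁺ and A⁻ all permeate the open permeability transition pore (PTP),
  and the neutral activator leaks out of it one-sidedly. A zero-field
  ("depolarized") PTP diffusion term exists but is off by default. A
  Poiseuille term advects solutes through open pores under the membrane's
  restoring pressure (effective radius r₀·√P_PTP, r₀ = 1.5 nm); at the
  pressures this model reaches (tens of Pa) it is a minor correction.
* **Activities.** Concentrations are corrected to activities with the
  Debye–Hückel limiting law, ln γ = −z²e²κ_D/(8πεε₀k_BT) with κ_D the Debye
  wavenumber; at the µM–mM ionic strengths of these simulations γ ∈
  [0.93, 1].

## Gating and respiration

Pore opening is an instantaneous algebraic function of matrix pH:
P = αx^n/(1+αx^n) with x = max(pH − 7, 0), α = 1.2×10³, n = 4. P ≡ 0 at or
below neutral pH and reaches 75/76 ≈ 0.987 at pH 7.5 — the model's
"complete opening" regime. The package therefore defines complete opening as
P ≥ 75/76 (the gate's value at the stated complete-opening pH); a stricter
cutoff such as 0.999 would correspond to matrix pH ≈ 7.96, outside the
gate's physiological band, and is available as an explicit threshold
argument. A closed-form two-state open/close pore-count relaxation is
provided for reference but is not wired into the simulator.

Respiration is lumped into an activator A generated at
W_A = k_A·a_A0·(1 − e^(−ΔΨ/δ)) (δ = 43.42 mV, so W_A = 0.99·k_A·a_A0 at
200 mV; zero for a depolarized or reversed membrane) and consumed at
W_H = k_{A,H⁺}·a_A, each consumption event ejecting one H⁺ from the matrix.
This is the only primary proton pump: it alkalinizes the matrix and carries
positive charge outward (repolarizing). Matrix free H⁺ dynamics are divided
by a buffering factor B.

## Membrane mechanics

Osmotic pressure follows van 't Hoff, ΔP = RT·Σ(a_in − a_out), evaluated
**relative to the initial composition**: the model transports only five
species of an organelle whose full osmolyte budget is not modeled, so the
t = 0 state is taken as osmotically balanced (background osmolytes make up
the difference) and only deviations from it generate pressure. Evaluating
the sum literally over the modeled species would start every run with a
large negative pressure dominated by the cytosolic Ca²⁺ load, i.e. all runs
would begin by shrinking, contrary to the phenomenology the model exists to
produce.

The balance ΔP_os = ΔP_IMM is solved quasi-statically (osmotic water
transport is much faster than ion transport). The scalar balance cannot fix
two deformation degrees of freedom, so the default closure is affine,
shape-preserving scaling Δx/a = Δz/c = s. The restoring pressure is

    ΔP_IMM(s) = [2·g_xx(s·a)·s·a + g_zz(s·c)·s·c] / S_m(s)

with softening components g(δ) = g₀(1−βδ^n₁)/(1+βδ^n₁), floored at zero
(they vanish, they do not invert). The quoted softening constants
(β₀ = 10⁶ nm⁻⁴) would zero the rigidity at Δr ≈ 0.03 nm — five orders of
magnitude below the stated irreversibility criterion of +50 % volume
(strain 1.5^{1/3} − 1 ≈ 0.1447). By default the package re-anchors β so the
components vanish exactly at the critical strain; the literal constants
remain available (`recalibrate_beta = false`) and the config validator
warns about the inconsistency.

ΔP_IMM(s) rises, peaks near s ≈ 0.082, and falls to zero at the critical
strain. Pressures above the peak have no balancing root: the membrane
yields, the irreversibility flag latches for the rest of the run, the
restoring pressure is zero thereafter, and the deformation is held at the
critical strain (volume ceiling +50 %, the model's proxy for OMM-rupture
scale dysfunction). Negative osmotic imbalance is clamped at zero strain
(no shrinkage branch). A simplified spherical relaxation mode
(dΔV/dt = ηΔP_os − κ(ΔV)·ΔV with softening κ) is provided as an alternative
dynamic solver; its κ₀, γ, m have no published values and must be supplied.

## Charge balance and capacitance

The membrane potential integrates the net charge flux,
dΔΨ/dt = −k_V·[2J_Ca + J_K + J_H − J_A⁻ − W_H], with k_V = F·V_m/C and
C = ε_m·ε₀·S_m/h (ε_m = 2, a lipid-bilayer core; h = 10 nm). The literal
"C = S_m·h" relation of the source model has units of volume and cannot be
a capacitance, so the parallel-plate reading is used. Every pathway carries
its ionic charge — including the PTP fluxes — and respiration's H⁺ ejection
repolarizes. With these values, moving ≈19 µM of monovalent charge across
the membrane shifts ΔΨ by 200 mV; this number controls the depth of the
depolarization collapse (below).

## Unit normalization and calibration

The source parameterization quotes "reduced" permeabilities in
min⁻¹ mV⁻¹ (mg protein)⁻¹ (K·esu/erg), a mixed practical/CGS system with a
per-milligram-of-protein normalization that has no recoverable mapping onto
a single-organelle SI model (dimensionally these are not permeabilities).
The package therefore works in (min, mV, µM, Pa) and converts each
permeability class by one normalization constant, shipped as explicit
configuration:

| constant | applies to | default |
|---|---|---|
| `uniporter_scale` | Ca²⁺ uniporter | 2.35×10⁻¹⁰ |
| `exchanger_scale` | K⁺/H⁺ exchange pair | 0.145 |
| `ptp_scale` | PTP permeabilities of Ca²⁺, K⁺, H⁺ | 0.3 |
| `organic_ptp_scale` | PTP permeabilities of A⁻ and the activator | 2.6×10⁻⁴ |
| `buffering_b` | matrix H⁺ buffering divisor | 7 |
| `rigidity_pressure_scale` | rigidity-to-pascal factor | 1.68×10⁻⁵ |

These were calibrated once, jointly, against the model's stated operating
points — pore opening absent up to 75 µM cytosolic Ca²⁺ and complete from
200 µM up within a 600 s run, irreversible swelling appearing between 200
and 300 µM, matrix Ca²⁺ bounded near 100 µM even at 500 µM cytosolic load,
and shallow (≤7 %) membrane-potential modulation at low load — and then
frozen. (The source study states that its own rigidity constants were chosen
the same way, from the expected oscillation frequency.) The literal printed
buffering constant B = 3×10⁵ belongs to the unrecoverable unit system and is
retained as `buffering_b_literal` for reference.

## The emergent threshold mechanism

With the calibrated defaults the grid behavior follows a clean causal
chain, useful to know when reading trajectories:

1. With pores shut, charge balance slaves the membrane potential so that
   total cation influx matches respiration's H⁺ ejection. The matrix then
   alkalinizes at a rate proportional to the uniporter Ca²⁺ influx, so the
   time to reach the pH-7 gate scales roughly as 1/[Ca²⁺]_out: ~520 s at
   200 µM, ~390 s at 300 µM, beyond the 600 s window at ≤150 µM.
2. When pH crosses 7, the pore cracks open; the PTP's large Ca²⁺
   permeability discharges the membrane capacitance within a fraction of a
   second and drives ΔΨ slightly negative (reversed field, ≈ −30 to −40 mV).
3. Under a reversed field the PTP's own H⁺ pathway pumps protons *out* of
   the matrix (toward Nernst equilibrium), locking pH above 7.5 and the
   pore fully open — a self-sustaining Donnan-like state. Matrix Ca²⁺ is
   pinned near its Nernst value at the reversed potential (tens of µM, far
   below the cytosolic load).
4. The anion A⁻ then accumulates slowly through the pore, dragging
   co-cations with it; the osmotic load grows for minutes. Runs that open
   early (≥300 µM) exceed the rigidity ceiling and latch irreversible at
   +50 % volume; the 200 µM run opens too late to build that pressure and
   stays reversible.

## Absence of sustained oscillations

The source literature for this model family reports ~97 s oscillations of
matrix Ca²⁺/K⁺/H⁺ at the lowest load (1 µM Ca²⁺, 0.1 µM K⁺). The present
formulation does not produce them, and the reason is structural, not a
matter of calibration: below the gate the system has a unique fixed point
whose stability can be bounded — the respiration drive W_A(ΔΨ) has
logarithmic slope x·e⁻ˣ/(1−e⁻ˣ) ≤ 1 in ΔΨ while every GHK influx has
logarithmic slope ≥ 1, so the activator feedback loop gain is below unity
(no Hopf bifurcation), and the remaining couplings (K⁺ pinned near Nernst
equilibrium by the fast exchanger, H⁺ slaved through charge balance) are
overdamped. A gate-flicker relaxation oscillator at 1 µM would require the
matrix pH to reach 7.0 there, which — since the gate-crossing time scales
as 1/[Ca²⁺]_out — would force every higher-Ca²⁺ run to open orders of
magnitude earlier, destroying the published opening thresholds. The two
published behaviors (low-Ca oscillation and the 150→200 µM opening
threshold) are mutually inconsistent under any charge-conserving reading of
the printed equations; the package keeps the thresholds and reports the
low-Ca runs as non-oscillatory. The trace-analysis period estimator
therefore returns "absent" on the default low-Ca run; this is expected.

## Numerics

* Operator splitting: the ionic/electrical ODEs are integrated in 0.25 s
  chunks with LSODA (rtol 10⁻⁸, atol 10⁻¹² µM, 10⁻⁹ mV); between chunks the
  fast algebraic layer — activity coefficients, osmotic pressure,
  quasi-static mechanics, dilution rescale of matrix concentrations
  (amounts conserved), conserved-pool update — is re-solved. Gating and
  respiration are evaluated live inside the right-hand side.
* The pressure balance is solved by bracketed Brent root-finding on the
  ascending branch of ΔP_IMM(s); the peak is located once per
  parameterization on a 512-point grid.
* Matrix concentrations are clipped at zero when stiff pore-opening
  transients graze it by less than 10⁻⁶ µM; larger undershoots abort the
  run with a diagnostic.
* Everything is deterministic: no randomness, no seeds.
* Problem sizes: the standard analyses use 600 model-seconds per run
  (2 401 output samples) and the 10-condition low-K half of the grid; a
  single run integrates in a few seconds, the half-grid in about a minute.

## What the tests show, and what they do not

The test suite verifies the building blocks against independent oracles
(arbitrary-precision GHK evaluation, quadrature surface areas, bisection
mass-action roots, closed-form relaxations), conservation and determinism
of the assembled simulator, and the grid-level threshold phenomenology
under the calibrated defaults. Passing them shows the implementation is
internally consistent and reproduces the stated operating points of this
model family; it does not validate the model against experimental swelling
data, nor can it recover the source implementation's exact trajectories,
whose unit system is not reconstructible.

## Limitations

* Na⁺ transport, multi-protic acid ladders, mechanistic electron-transport
  stoichiometry and heterogeneous mitochondrial populations are out of
  scope.
* The cytosolic compartment keeps constant volume; the water entering the
  matrix (≤0.5 V_m(0)) is not debited from it.
* The weak-acid/H⁺ coupling uses a first-order association correction for
  incoming anions rather than a full two-sided equilibrium re-partition.
* The 10 µM K⁺ grid leg starts with a fast capacitive K⁺ rush that settles
  the membrane near +35 mV; its qualitative behavior (no pore opening at
  low Ca²⁺) matches the source narrative, but its potential trajectory is
  not comparable to the published plots.
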