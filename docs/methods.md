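# Methods

`axoplasmon` implements a wave-type model of saltatory conduction: the
nerve impulse in a periodically myelinated axon is carried not by diffusive
ionic current (cable theory) but by a plasmon-polariton — a wave of
synchronized dipole oscillations of the mobile ions in consecutive
myelinated segments, coupled through retarded dipole fields. The packet
travels at ~100 m/s and ignites the Hodgkin–Huxley (HH) cycle at each node
of Ranvier it passes; the HH machinery in turn replenishes the packet's
Ohmic losses, so propagation is effectively undamped over arbitrary
distances. This note records the model equations as implemented, the
parameter conventions, the numerical choices, and the limits of what the
tests demonstrate.

## Single-segment plasmons (`plasma`)

A segment is a finite electrolyte volume with ion charge q, mass m and
number density n in a host of relative permittivity ε. All public
interfaces are SI; the Gaussian-form literature expressions are converted
once, so the bulk plasma frequency is ω_p = √(q²n/(ε₀m)) and the dipole
(Mie) surface mode is ω₁ = ω_p/√(3ε), with multipoles
ω_l = ω_p √(l/(ε(2l+1))) saturating at ω_p/√(2ε).

Ohmic damping uses the classical Boltzmann mean ion speed 𝗏 = √(3k_BT/m):
1/τ₀ = 𝗏/(2λ_B) + C𝗏/(2a), a bulk mean-free-path term plus boundary
scattering with an order-unity constant C. Trans-membrane dissipation into
the surrounding electrolyte red-shifts the observable self-frequency to
ω₁′ = ω₁√(1 − 1/(τω₁)²). In the overdamped case τω₁ < 1 the function
returns 0 with a flag rather than a complex number; that branch is never
reached by the shipped presets.

Pinned constants (one table, `constants.py`): ε₀ = 8.8541878128e-12 F/m,
k_B = 1.380649e-23 J/K, m_e = 9.1e-31 kg, c = 3e8 m/s, q = 1.6e-19 C,
N_A = 6.02214076e23/mol. m_e and c are deliberately the rounded values
conventional in this modelling literature so that worked examples reproduce
the printed numbers.

A deliberate inconsistency is preserved rather than hidden: with the
standard worked-example electrolyte (q = 1.6e-19 C, m = 10⁴ m_e,
n = 2.1e16 m⁻³, ε = 80) the Mie formula gives ω₁ ≈ 5.3e6 rad/s, yet all
chain-level reproductions use ω₁ = 4e6 rad/s. The package treats 4e6 as an
*input* (the effective segment frequency after elongation and
myelin-thickness tuning, see below) and never forces the Mie formula to
print it.

## Chain dispersion (`dispersion`)

The chain (segment radius a, period d, host permittivity ε) is solved in
dimensionless variables: x = kd ∈ (0, 2π), u = ωd/v with v = c/√ε,
coupling g = (a/d)³ ≤ 1/8. Per polarization α the dispersion relation is

    ω² + i(2/τ₀)ω − ω₁²(1 − g F_α(x, u)) = 0,

with the retarded dipole lattice sums F_z (longitudinal) and F_x(y)
(transverse) given in the module docstring. Conventions: time factor
e^{−iωt}, so damping means Im ω ≤ 0; principal square root with Re ≥ 0.

**Closed-form evaluation.** Using product-to-sum identities every lattice
sum reduces to the six Fourier series Σ trig(my)/m^p, p = 1..3, at
y = x ± u. Four have elementary closed forms (Bernoulli polynomials, the
log-sine kernel, (π−y)/2); the Clausen function Cl₂(y) = Σ sin(my)/m² and
its cosine companion Σ cos(my)/m³ are evaluated by the zeta-coefficient
power series about y = 0 with reflection to (0, π] (`_clausen.py`, 44
terms, machine precision over the whole interval — verified against mpmath
and direct 2×10⁵-term summation in the tests). This makes the radiative
quenching identity Im F_α ≡ 0 in the subluminal triangle u < x < 2π − u an
*exact algebraic cancellation* of the Lorentz-friction u³ terms, reproduced
to ~1e-14 in floating point. Outside that triangle the wrapped Fourier
arguments break the cancellation and Im F ≠ 0 — the radiative zone.

**A sign correction.** The transverse sum as commonly printed carries
+u·cos(mx)cos(mu)/m² in its imaginary bracket; deriving F_x(y) directly
from the retarded dipole field gives −u·cos(mx)cos(mu)/m², and only the
derived sign produces the exact Im F_x(y) ≡ 0 cancellation. The package
implements the derived sign (the longitudinal sum needs no correction).
Likewise the transverse far-field denominator scales as 1/|l−m| between
segments l and m.

**Root finding.** Damped fixed-point iteration seeded at ω = ω₁,
ω_{j+1} = √(ω₁²(1 − gF(x, u_j)) − 2iω_j/τ₀), with u from Re ω (the
retarded series diverges for complex frequencies with Im ω < 0, so damping
is treated perturbatively inside the lattice sum — the standard approach
for these chains). Relative residual tolerance 1e-9, max 200 iterations, a
complex-Newton fallback with numerical derivative for stragglers;
non-converged points are flagged, never dropped. For the axon parameters
u ~ 1e-8, the lattice sum is essentially static in u and the iteration
converges in 2–3 steps.

**Grids and the light cone.** Default k grid: 2001 uniform points on
(δ, 2π/d − δ), δ = 1e-6·2π/d. The singular lines x = u and x = 2π − u are
excluded with half-width 1e-4 in x. For ω₁ = 4e6 rad/s and d ≈ 100 µm the
cone offsets are ω₁d/c ≈ 1.3e-6 (vacuum convention) or ω₁d/v ≈ 1.2e-5
(medium convention) — both are reported by `light_cone_offsets`, neither is
asserted, since the two conventions differ by √ε and the literature value
("order 10⁻⁶") matches only the vacuum one.

**Finite chains** are represented by the truncated lattice sum and the DFT
grid k_n = 2πn/((2N+1)d) rather than a separate eigen-solver: the m⁻² and
m⁻³ series converge so fast that ten segments reproduce the infinite chain
to < 5% (a property the tests assert), so a dedicated finite solver adds
nothing at these sizes.

**Group velocity** v_g = d(Re ω)/dk uses fourth-order central differences
in the interior (the Richardson refinement of the three-point stencil),
second-order near the ends, one-sided at the endpoints. The transverse
branch is solved but flagged `physically_suppressed`: transverse dipoles
cannot polarize the nodes of Ranvier, fall out of synchrony with the HH
cycle, and decay; only the longitudinal branch carries the trigger.

With the myelinated-axon preset (a = 50 µm, d/a = 2.01, ε = 80,
ω₁ = 4e6 rad/s, negligible Ohmic damping) the longitudinal branch spans
Re ω/ω₁ ∈ [0.64, 1.20] and max |v_g| ≈ 119 m/s — comfortably the ~100 m/s
scale of saltatory conduction.

## Cable baseline (`cable_model`)

The comparison model: per-length C = c_mπd, 1/G = ρ₁δ/(πd), R = 4ρ/(πd²),
velocity scale v_c = λ/τ = √G/(C√R) ∝ √d, and the discrete-diffusion
myelinated estimate v_m = √(l/d₀)·v_c. Of the two printed forms of C the
c_m (capacitance per area) form is primary, because the worked example is
stated in c_m; mixed practical units (µF/cm², Ω·cm², Ω·cm, µm) are
converted by `from_practical` (conversion table unit-tested). The textbook
constants give v_c = 5 cm/s exactly, and a 100-fold attenuation of C and G
gives the ×10 myelin speed-up — both orders of magnitude short of
observation, which is the motivation for the chain model. The composite
"~3 m/s for d ~ 1 µm" literature estimate mixes incommensurate factors and
is not asserted. No time-domain PDE integration is in scope: the model's
role here is the velocity scale only.

## Myelin-thickness control (`myelin_coupling`)

The dipole in a myelinated segment induces an opposite dipole in the
extracellular cave; coupled across the sheath of thickness ξ by the near
field −d/(εξ³), the pair has normal modes Ω₁,₂ = √(ω₀² ± κ), κ = μ/(εξ³),
and exciting one dipole alone produces beating at Ω₁ − Ω₂ ≈ κ/(ω₀) ∝ ξ⁻³.
Halving ξ multiplies the beat by 8; a 20% thinning by 1/0.8³ ≈ 1.95. This
is the knob that tunes the effective segment frequency onto the
microsecond Na⁺-gate activation time; thinning (demyelination) detunes it,
which is the model's reading of conduction slow-down in demyelinating
disease.

The absolute polarizability μ of a rod segment is not derivable here, so
the pair accepts either μ or the normalized ratio κ/ω₀², and thickness
curves can be anchored to a reference (ξ₀, beat₀) pair
(`anchored_beat_curve`) — reproducing the published ratios without
inventing an absolute μ. Retardation across ξ is neglected (ξ/v is
femtoseconds at these scales); the undamped pair uses the closed normal-
mode solution, the damped pair integrates the coupled ODEs with Radau at
rtol 1e-8. Mode selection (`select_synchronized_mode`) keeps the k-window
whose mode period is at least the gate activation time and picks the
maximal |v_g| inside it; with a 1 µs gate the whole longitudinal branch of
the myelinated preset is feasible and the selected packet does ≥ 100 m/s.

## Axon presets (`axon_presets`)

The fictitious sphere chain maps to the real cord (radius r, segment
length 2a) by conserving the oscillating ion count:
n′ = n(4/3 πa³)/(2aπr²) = (2/3)n(a/r)². The mapping is kept exact; with
the worked-example inputs it gives n′ ≈ 3.0e24 m⁻³, while the physiological
"~10 mM" rounds to 6e24 m⁻³ via the separate molar conversion
(c·N_A·10³) — a factor-2 discrepancy the package reports rather than
reconciles.

Presets are data (flat key-value config files shipped with the package),
not code constants. `myelinated_pns`: 2a = 100 µm Schwann segments, node
0.5 µm (d/a = 2.01; 5 and 10 µm nodes give 2.1 and 2.2), ε = 80,
ω₁ = 4e6 rad/s, undamped. `c_fibre`: unmyelinated, lipid-raft Na⁺ clusters
0.1 µm long every 5 µm; the trans-membrane damping strength is a free
parameter with default τω₁ = 1.5 — oscillatory but strongly red-shifted
(ω₁′ ≈ 0.75 ω₁), chosen as the qualitative regime the micro-saltatory
description requires; no measured τ exists to pin it.

`build_chain` hands the dispersion solver the *bare* stiffness frequency
ω₁ together with 1/τ₀, so the red-shifted observable ω₁′ = √(ω₁² − 1/τ₀²)
emerges from the solver's uncoupled pole; passing ω₁′ as the stiffness
would apply the red shift twice. ω₁′ itself is exposed as
`effective_self_frequency`.

## Firing simulator (`saltatory_sim`)

HH node dynamics are abstracted to a timed trigger/refractory state machine
(rest → triggered → firing → refractory), because the model explicitly
decouples packet propagation from the HH cycle: node j ignites at
t = |j − origin|·d/v, exactly (event-driven, no time-stepping error). A
spike marker lasts 1 ms by default; the refractory lockout defaults to 1 s
(gate restoration takes of order a second), which is what makes firing
unidirectional behind the front. Damaged nodes and cord breaks narrower
than a configurable maximum (default one period d) are traversed without
delay — a wave of synchronized oscillations needs no local continuity —
so downstream timing is invariant under interior damage, a property the
tests assert. Wider breaks stop the front on that side.

Counting convention: a 10 cm axon is 1000 segments of 100 µm; "nodes
ignited within t" includes the origin and uses a closed interval at t, so
a 100 m/s packet ignites exactly min(⌊vt/d⌋ + 1, 1000) = 1000 nodes in
1 ms on that axon. The simulator is fully deterministic; the only
randomness anywhere in the package is the ±10% jitter of the test-fixture
generator, under an explicit seed.

## What the tests do and do not show

All chain-level numbers are produced under the study conditions above
(a = 50 µm, d/a = 2.01, ε = 80, ω₁ = 4e6 rad/s, 2001-point grids) — these
are modelling conditions, not fits. The synthetic fixtures jitter nominal
parameters by ±10% to exercise invariants (homogeneity, parity,
antisymmetry, trace identities, residuals), which demonstrates internal
consistency of the implementation, not biological validity: the model
idealizes segments as identical spheres, ignores multipole corrections and
full electromagnetic Green functions, treats damping perturbatively inside
the retarded sums, and abstracts HH dynamics entirely. Known limitations
beyond scope: no RPA/quantum derivation of the ionic plasmon spectrum, no
FDTD electromagnetic modelling, no stochastic or thermodynamic HH
extensions, no derivation of the rod polarizability μ.
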