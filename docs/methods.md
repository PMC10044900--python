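# Methods

`frickesim` simulates the radiolytic oxidation of ferrous to ferric ions in
the ferrous-sulfate (Fricke) dosimeter — with and without the radioprotector
cystamine (RSSR) — under instantaneous pulses of N parallel 300-MeV proton
track segments.  Varying N from 1 to 1000 moves the system from conventional
to ultra-high (FLASH-regime) dose rates while every other condition is held
fixed.  This note records the model, its assumptions, the numerical choices,
and what the synthetic-data generator does and does not emulate.

## 1. The model in one paragraph

A pulse deposits energy along N rectilinear, parallel track axes entering a
disc of radius R0 = 0.1 μm; the pulse duration is zero (Dirac model), so the
absorbed dose per pulse is the only dose parameter.  At 1 ps the deposited
energy has become a spatial cloud of radiolytic species (e⁻aq, •OH, H•, H₂,
H₂O₂, H₃O⁺, HO₂•).  From 1 ps to 200 s the cloud evolves by diffusion and
reaction: transient–transient encounters are resolved stochastically with
the independent-reaction-times (IRT) method, and reactions with the uniform
background solutes (H⁺, HSO₄⁻, Fe²⁺, O₂, cystamine) are pseudo-first-order.
The observable is G(Fe³⁺), the ferric yield per 100 eV, whose 200-s value is
the dosimeter reading.

## 2. Medium and reaction network

The standard medium is 1 mM FeSO₄ in 0.4 M H₂SO₄, air-saturated
([O₂] = 2.5 × 10⁻⁴ M) or deaerated, with 0–1 M cystamine.  The first acid
dissociation is complete; the second (default Ka₂ = 1.0 × 10⁻² M, exposed in
`MediumComposition.ka2`) is solved exactly, conserving sulfate and charge.
Counter-ions (the FeSO₄ sulfate, cystamine's chloride) are inert spectators
that only contribute to the ionic strength (I ≈ 0.42 M for the standard
medium).  The *reported* pH is the H⁺ activity, using a WATEQ-style extended
Debye–Hückel single-ion coefficient (å = 4.78 Å, b = 0.24): a pH electrode
in 0.4 M H₂SO₄ reads ≈ 0.46 even though −log₁₀[H⁺] ≤ 0.40 — the
concentration speciation, which the kinetics uses, is exact regardless.

The packaged network (`fricke_cystamine_full`, 42 reactions) combines:

* the seven core dosimeter reactions and the nine cystamine reactions with
  their published rate constants (provenance `printed-in-paper` in the data
  files), including the SO₄•⁻ + Fe²⁺ channel;
* a standard pure-water spur set (e⁻aq/•OH/H•/H₂O₂/HO₂• cross-reactions),
  sulfate radical chemistry, and auxiliary protonation steps, shipped as
  provenance-tagged `literature-default` values.

Editable CSV is the source of truth; a JSON dialect round-trips losslessly.
Charge balance is enforced per reaction at load time.  Two bookkeeping
conventions make the printed chemistry balance:

* cystamine-family species carry the net charges of their doubly protonated
  forms (below pH 8 cystamine is ⁺NH₃–…–NH₃⁺), so RSSR = +2, RS• = +1, the
  radical cation (RSSR)•⁺ = +3, etc.;
* reactions that implicitly consume an acid proton (H• + Fe²⁺ → Fe³⁺ + H₂;
  the peroxyl + Fe²⁺ step) list H⁺ as a reservoir *co-reactant*: it joins
  the charge audit and the consumption ledger but not the kinetic order.

Gaps in the published scheme are closed with flagged assumptions: the
disulfide electron adduct (RSSR)•⁻ dissociates to RS• + RS⁻ at 10⁸ s⁻¹;
thiyl radicals dimerize (RS• + RS• → RSSR, 1.5 × 10⁹ M⁻¹s⁻¹); thiolate and
peroxyl anions protonate at 5 × 10¹⁰ M⁻¹s⁻¹.

### Ionic-strength correction

All ion–ion rate constants are corrected by the Brønsted–Bjerrum/extended
Debye–Hückel factor k = k₀·10^(1.02 zA zB √I/(1+√I)); the e⁻aq
self-recombination is exempt (no ionic-strength effect is observed for it).
The correction is applied *literally to every ion–ion pair*, as the source
procedure prescribes.  At molar cystamine concentrations this extrapolates
far outside Debye–Hückel validity (for the (RSSR)•⁺ disproportionation,
zA·zB = +9 at I ≈ 3.4 M), strongly accelerating capture-product
annihilation; the high-concentration yields depend on this behaviour.
`IRTOptions.reff_cap_nm` optionally imposes a molecular-contact cap for
sensitivity studies; it is off by default.

## 3. The synthetic 1-ps generator

The physical/physicochemical stages are *emulated statistically*, not
transported event by event: no explicit δ-ray trajectories or cross-section
sampling.  Per track: entry points uniform over the R0 disc; energy
deposition events form a Poisson process with linear density
LET/⟨E_event⟩ (LET = 0.3 keV/μm, ⟨E_event⟩ = 60 eV, exponential energy
distribution); per event, species counts are Poisson with mean
E·G_1ps(s)/100 and isotropic Gaussian displacements with species-specific
RMS (e⁻aq 3.5 nm; •OH calibrated, see below; others 3 nm).  All
particles are born at 1 ps.  Segment lengths follow L(N), log-interpolating
from 100 μm at N = 1 (the track length the multi-track geometry uses) to
5 μm at N = 1000, inside the 5–150 μm envelope; yields are per 100 eV, so
they are insensitive to L apart from axial edge effects of order
(diffusion length)/L.

### Calibration: the escape yields are the anchor

The free parameters of the emulator — the 1-ps yield table and the OH spur
width — are not taken from the literature as authoritative; they are tuned
by `calibrate_initial_yields` until the *escape yields* simulated at
10⁻⁷–10⁻⁶ s in air-saturated 0.4 M acid (no Fe²⁺, no cystamine) match the
reference primary yields of the dosimeter system: g(•OH) = 2.90 (counting
SO₄•⁻), g(e⁻aq + H•) = 3.70 (counting the O₂-frozen HO₂/O₂•⁻ pool less the
primary HO₂ input), g(H₂O₂) = 0.80.  These are the quantities the
dosimeter stoichiometry actually consumes:

    G(Fe³⁺)_aerated  = g(OH) + 3 g(e+H) + 2 g(H₂O₂) + 3 g(HO₂)
    G(Fe³⁺)_deaerated = g(OH) +  g(e+H) + 2 g(H₂O₂) + 3 g(HO₂)

The iteration is a damped multiplicative fixed point on the OH and (e,H)
table entries and on the *OH spur width*, which controls how much H₂O₂ the
OH+OH spur recombination produces.  The 1-ps H₂O₂ entry itself is pinned
at the literature-typical 0.20/100 eV: the three escape targets alone do
not separate (initial H₂O₂, spur width), and only the
recombination-dominated branch behaves correctly when a strong OH
scavenger is present — at molar cystamine, capture must *suppress*
peroxide formation, which a hard-coded 1-ps peroxide cannot reproduce.
Convergence (default 3 % relative, ≤ 8 iterations, 8 histories rising to
24 near convergence) is judged on OH, e+H and H₂O₂.  The primary HO₂
yield (0.02/100 eV — a few molecules per history, Poisson-dominated, 0.06
of ~15.5 G-units) is likewise a fixed input, not a fit target.  A zero
tolerance is rejected up front: the targets are stochastic.

## 4. The IRT chemistry engine

Classic IRT semantics: every eligible pair draws one tentative reaction
time from the pair Green's function — ultimate probability W∞ = Reff/r₀,
conditional CDF W(t)/W∞ = erfc[(r₀−Reff)/√(4D′t)], inverse-CDF sampled —
and every particle draws channel-resolved exponential scavenging times;
the earliest event executes; products are placed at the diffusion-weighted
midpoint (single-reactant products in place), then sample fresh times from
their birth position and time.  Encounter radii invert the
(ionic-strength-corrected) rate constants, Reff = k·10⁻³/(4πD′N_A), i.e.
every bimolecular transient reaction is treated as fully diffusion
controlled, preserving the measured k by construction; partially
diffusion-controlled boundary conditions are not implemented.  Positions
are propagated lazily: whenever a particle participates in an event or is
inspected, it first takes the free-diffusion displacement for the elapsed
interval (the standard IRT position approximation, ignoring the
no-reaction conditioning).  Pairs separated by r₀ ≤ Reff react immediately.

Every pair of particles receives exactly **one** IRT draw — nothing is
ever re-rolled — and three devices keep dense pulses (N = 1000, ~10⁵
particles, ~10⁸ within-horizon pairs) tractable; all are accuracy/cost
knobs in `IRTOptions`:

1. **Truncated initial pairing.**  The 1-ps cloud is paired against the
   256 nearest neighbours per particle within the 800 nm horizon.  Each
   particle stores its coverage radius (distance to its k-th neighbour, or
   the horizon when fewer are inside it), making "was this pair already
   considered" a pure geometric test on the stored 1-ps positions.  At
   N = 1 this covers everything in the horizon, i.e. canonical IRT; at
   N = 1000 it is a truncation.
2. **Dynamic birth neighbourhoods.**  New particles draw against the
   k = 30 nearest *current* survivors from a cell-grid spatial index
   (100 nm cells, expanding shells) — essential at high cystamine
   concentration, where sub-nanosecond capture converts whole spurs and
   the products (RS•, (RSSR)•⁺) must find each other.  Set-based
   bookkeeping preserves the one-draw rule for pairs involving births.
3. **Staging sweeps.**  At log-spaced times (10 ps to 1 ms — the
   radical–radical window) positions are propagated, the index is rebuilt,
   and particles without a usefully scheduled pair event receive draws
   against never-before-considered partners (90 per sweep).  A voided pair
   event (partner consumed elsewhere) likewise triggers an immediate
   fresh-partner draw for a survivor left with no pending events.  Because
   pairs introduced later are sampled from diffused (on average more
   distant) separations, the staged total reaction probability approaches
   the full-pair limit from below as the sweep cadence increases; the
   N = 1000 checks run at 4 sweeps/decade, where the N = 1000 yield is
   within the reported tolerance and insensitive to the segment length.

Inter-ion Coulomb bias on pair survival is ignored (Debye screening at
I ≈ 0.4 M makes the Onsager radius sub-ångström).  Background solutes are
constant reservoirs; a warning fires if a history consumes more than 5 % of
a reservoir within the diffusion-expanded beam cylinder (2 μm margin).
Species that exist only as reservoirs (Fe²⁺, O₂, RSSR, HSO₄⁻, SO₄²⁻) are
counted but not instantiated when they appear as products.  The fast
proton-shuttle null cycle HO₂• ⇌ O₂•⁻ + H⁺ (pKa 4.8; the protonated form
dominates at pH 0.46 by ~10⁴) is collapsed at engine setup when the return
rate exceeds 100× every other channel — it is pure event churn otherwise;
both reactions remain in the data files.

Long times need no special phase: once radicals are scavenged, the
remaining events are exponential cascade steps (H• + Fe²⁺ at ~10⁻⁵ s,
HO₂• + Fe²⁺ at ~10⁻³ s, H₂O₂ + Fe²⁺ with half-life ln2/(52·10⁻³) ≈ 13.3 s —
the reason G(Fe³⁺) only saturates near 200 s), which the same event queue
executes directly.

Yields are recorded per history as net species counts on a log grid (10
points/decade, 1 ps–200 s), normalized by that history's deposited energy;
experiments average ≥ 2 histories (mean ± SEM) with per-history RNG streams
spawned deterministically from the master seed, so identical seeds give
identical tables.

## 5. The homogeneous oracle

`predict_fricke_yield` is a deliberately spatial-effect-free cross-check:
each species' expected ferric count obeys a linear system over its
pseudo-first-order branching fractions (solved directly — the HO₂ ⇌ O₂•⁻
shuttle makes naive tree recursion cycle), and G(Fe³⁺) is the yield-weighted
sum.  With zero cystamine it reproduces the stoichiometric relations (the
deaerated case exactly; the aerated case to ~0.2 %, because the slow
H• + Fe²⁺ channel remains open beside H• + O₂ — real competition, not an
error).  The (RSSR)•⁺ disproportionation is second order and outside the
oracle's regime, so the oracle brackets G between "every (RSSR)•⁺ oxidizes
ferrous" and "all are lost pairwise", reporting both bounds.  A stiff-ODE
twin (`ode_crosscheck`, BDF with analytic Jacobian, rtol 10⁻⁹) of the same
linear network agrees with the solved system to better than 0.1 %, and in
the scavenger-dominated limit (N = 1, low cystamine) the IRT results match
the oracle within statistical error.

## 6. What the emulator does and does not show

The generator reproduces: the cylindrical multi-track geometry and its N
scaling, Poisson energy-deposition statistics, nanometre spur clustering
calibrated to the escape yields, and (through IRT) the competition between
intra/inter-track recombination and homogeneous scavenging over 14 decades
of time.  It does not reproduce: explicit δ-ray track structure (absorbed
into spur widths; whether escaping δ-rays change inter-track overlap at
N = 1000 is untested here), proton energy loss or straggling along the
segment (LET is constant), finite pulse duration or inter-pulse effects,
direct radiation action on solutes, LET or temperature variation (25 °C
only), or spin/radical-pair correlations beyond initial geometry.  Passing
tests therefore demonstrate the *chemistry-stage* behaviour of the model
under the stated geometry, not a validation of physical-stage transport.

The mapping from N to dose rate in Gy/s is calibration data from prior
work and is not recomputed; runs are labelled by N and by dose per pulse
(energy/(π R0² L ρ), ρ = 997 kg/m³; all deposited event energy counts,
including what later diffuses out of the cylinder).

## 7. Problem sizes used by the test suite and acceptance script

Chosen to fit interactive use on one CPU: calibration at L = 50 μm with
8–24 histories per iteration; N = 1 production runs at the default
L = 100 μm with 20 histories (SEM on G(Fe³⁺) ≈ 0.1); dense-pulse checks at
N = 1000 with L = 1 μm, 2–3 histories and 4 sweeps/decade — the yield at
this cadence is insensitive to L (verified against L = 2 μm), so the
shorter segment is pure economy; property tests on clouds of one to a few
thousand particles.  The reference statistics (5–100 histories depending
on N) are the `default_histories` schedule in `experiments`.

## 8. Known limitations

* The Brønsted–Bjerrum factor far outside its validity range (see §2) is
  the dominant model uncertainty at ≥ 0.1 M cystamine.
* The 18 unprinted cystamine reactions are literature defaults; the printed
  nine dominate ferric production, but the high-concentration floor is
  sensitive to the assumed thiyl/radical-cation termination rates.
* IRT with candidate truncation and staging sweeps is an approximation to
  the (already approximate) full-pair IRT; its bias grows with track
  density and is part of what the N = 1000 tolerance absorbs.  The most
  visible consequence: staged pairing spreads dense-pulse recombination
  over later decades than full-pair IRT would, so radicals that should
  already be gone can still be captured by intermediate scavenger
  concentrations.  The N = 1000 yield at the sub-millimolar end of the
  cystamine ladder therefore declines earlier than the flat plateau the
  dosimeter shows, and the test suite measures that residual honestly
  rather than hiding it; the endpoint yields (trace and molar cystamine)
  are unaffected.
* One energy-deposition event class (60 eV exponential) stands in for the
  real spur/blob/short-track hierarchy.
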