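# Methods

`knockon` analyses single-file K⁺ conduction through a potassium-channel
selectivity filter (SF) under an applied oscillating midinfrared field, and
ships the reduced-scale stochastic channel model that generates its test
data. This note records the model, its assumptions, the tunable parameters,
the numerical choices, and what the synthetic generator does and does not
emulate.

## The physical picture

The SF of a KcsA-type channel offers a ladder of discrete binding sites
(Scav, S4–S1, S0 from the intracellular to the extracellular side) in which
dehydrated K⁺ ions sit coordinated by backbone carbonyl (-C=O) oxygens.
Conduction proceeds by knock-on: an incoming ion destabilises the queue and
the topmost ion exits. Two modes are distinguished by the role of water:

* **direct knock-on** — ions contact each other in the filter (adjacent
  sites, or separated only by a vacancy, which leaves their Coulomb
  repulsion unscreened);
* **soft knock-on** — co-permeating waters always separate the ions
  (the K-W-K-W pattern).

The carbonyl stretch band absorbs near 51.87 THz (≈ 5.8 µm; the
experimental midinfrared line at 5.6 µm is 53.53 THz). Driving that band
resonantly stabilises the filter geometry at S1 and lowers the exit
barrier, increasing the current — the causal chain this package's
experiment module reproduces in reduced form: oscillator excitation →
S1-barrier drop → higher barrier-crossing rate.

## The channel simulator (synthetic-data generator)

Overdamped (Brownian) Langevin dynamics of labelled particles on the pore
axis z, Euler–Maruyama integration:

    dz_i = μ_i F_i dt + sqrt(2 D_i dt) η,   μ_i = 1/(m_i γ),  D_i = kT/(m_i γ)

with forces from (i) the multi-well landscape (waters see it scaled by
`water_depth_scale`, default 0.5), (ii) a linear membrane-voltage tilt
across the pore acting on charges, (iii) the oscillating field
E₀ cos(2πft + φ) acting on charges, (iv) screened Coulomb repulsion between
ion pairs, U(r) = q²/(4πε₀ε_r r)·exp(−r/λ_D) with ε_r = 2 and λ_D = 0.8 nm
by default, and (v) a soft-core exclusion (0.28 nm) plus an explicit
no-passing rule inside the filter (single-file order). A particle leaving
the extracellular edge is re-injected at the middle of the intracellular
reservoir ("recycling", emulating a periodic double-membrane torus); the
bottom wall reflects.

Assumptions and deliberate simplifications:

* 1-D pore axis only; no lipids, no explicit solvent, no 3-D pore shape.
* Overdamped dynamics — correct site statistics and barrier-controlled
  (Kramers) rates, no inertial effects, no absolute-current realism.
  Simulated currents are orders of magnitude above experimental pA values
  because barriers, lengths and sampling are desk-scaled.
* The field's only *mechanistic* effect is routed through the carbonyl
  oscillator (below); its direct force on ions is retained but averages to
  zero over a period.

**Units.** Length nm, time ps. Landscape, tilt and Coulomb energies are in
units of k_B·300 K (a fixed reference scale). Noise amplitude scales with
the configured temperature, so T → 0 silences the noise while drift forces
stay finite (the zero-noise fixed-point limit used in tests).

**Landscape.** Wells at −depth_i below the reservoir level; `barriers[i]`
is the absolute saddle height between wells i and i+1 (the outward
activation energy is depth_i + barrier_i). Nodes (wells, saddles, pore
edges) are joined by a monotone piecewise cubic (PCHIP), so stated depths
and barrier heights are exact extrema — clean closed-form oracles. Setting
`well_halfwidth` replaces each point saddle with a flat-topped plateau from
c_i + hw to c_{i+1} − hw: broad saddles and narrow wells concentrate the
mean first-passage time (MFPT) in the barrier regions, keeping transit
times Arrhenius-controlled. The default conduction landscape has five
wells (Scav…S1, depth 1.2 kT), 3 kT saddles, hw = 0.04 nm, and a flat
shoulder through S0.

**Time step.** Default 10 fs is fine for exploration, but on the
sharp-featured landscape it inflates hopping rates by tens of percent;
rates converge for dt ≤ 2 fs, validated against the MFPT oracle
(simulated cycle rate 0.62/ns vs oracle 0.616/ns on the reference
landscape). Quantitative rate analyses and the acceptance script use
dt = 2 fs. The oscillating field enters as its exact per-step time
integral, so the ~19 fs period never aliases against the particle step.
Pairwise forces are capped at 400 kT/nm (numerical regularisation of
unphysical close contacts); a step larger than half the smallest site
width raises an error advising a smaller dt.

**Boundaries and equilibrium.** Recycling deliberately rectifies traffic
(every completed exit is outward); it is therefore switched to a
reflecting top wall (`boundary="reflect"`) for all equilibrium analyses —
Boltzmann occupancy, PMF parameter recovery, zero-net-flux — where
detailed balance must hold exactly.

**Carbonyl oscillator.** One effective damped driven harmonic mode
(f₀ = 51.87 THz, γ = 3 ps⁻¹, i.e. an amplitude linewidth well under 2 THz,
q_eff = 0.8 e, oxygen mass), integrated by exact discretisation of the
linear system (`scipy.signal.lsim`) at 0.5 fs. Its steady-state amplitude
follows the Lorentzian A(ω) = (q_eff E₀/m)/√((ω₀²−ω²)² + γ²ω²) to < 1%.
The dimensionless excitation u = E_ss(f)/E_ss(f₀) is 1 on resonance,
0.016 at 50 THz and 0.043 at 53 THz with the default linewidth.

**Resonance coupling κ.** No quantitative link between carbonyl excitation
and barrier change is derivable here, so κ (kT of S1-saddle lowering per
unit u) is an explicit free parameter. `modulated_barrier` lowers *only*
the S2→S1 saddle. Because that is one of ~4 rate-limiting saddles, the
resonant fold change is bounded near (3 + e^{−κ})/4; the experiment driver
uses κ = 1.2, giving a clearly resolvable ≈1.2× resonant enhancement at
desk scale. The full 1.8× fold change corresponds to a uniform drop of
*all* barriers by ln 1.8 = 0.588 kT, which is exercised directly by the
current-ratio analysis.

**What the generator does not emulate.** Atomistic carbonyl/Y78 dynamics,
water structure, 3-D coordination geometry, absolute currents and the
field-condition-specific soft/direct percentages of real simulations.
Scripted trajectories (exact, hand-authored itineraries with validated
single-file consistency) therefore serve as the ground truth for the
occupancy, permeation and mechanism logic; passing tests demonstrate the
*analysis* is exact on known inputs and statistically consistent with
closed-form physics on simulated inputs — not that the generator matches
all-atom MD.

## Analysis modules

**Occupancy.** Each frame maps to a 4-character code over {K, W, 0} for
S1…S4 (S1 leftmost, the extracellular end); an ion in a site's half-open
z-interval beats a water; same-species ties resolve nearest-to-centre with
a logged warning. The census is frame-weighted, with six tracked
direct-contact codes (KKKW, K0KK, …) plus "Others".

**Permeation.** Two committor planes: an outward event requires entering
the site region from the intracellular reservoir and crossing into the
extracellular reservoir without re-crossing the entry plane — immune to
rapid single-plane recrossing. Recycling jumps traverse no site and create
no events. Current I = N·e/T in pA over the post-discard span; inward
events are counted separately and subtracted (net outward). Flux
conservation is checked at the S4/Scav and S0/extracellular planes
(planes inside the reservoir would miss crossings hidden inside recycling
jumps between sampled frames).

**Mechanism.** Per-event classification over the event's transit window:
*direct* if any frame shows two ions in S1–S4 with no water between them
(vacancies count as direct — unscreened repulsion; a declared convention,
not inferred from any source); *soft* if every multi-ion frame is
water-separated; *unassigned* if the window never holds two ions.
Percentages are over assigned events, rounded half-up to 2 decimals.

**PMF.** Boltzmann inversion W(z) = −kT ln(ρ(z)/ρ_max) of the species'
z-histogram (default Δz = 0.02 nm), minimum referenced to zero; empty bins
are flagged and masked, never interpolated. Driven runs yield a quasi-PMF,
labelled `equilibrium=False` from the trajectory metadata. Per-transition
barriers: lowest bin in each site interval is the well; the barrier is the
highest sampled bin between adjacent wells minus the donor well. Parameter
recovery on a reflecting-wall equilibrium run reproduces the input
landscape to ≈0.13 kT RMS at 50 ns (requirement: < 0.3 kT).

**Spectra.** The estimator is fixed: mean-removed dipole × Hann window,
zero-padded ×4, one-sided FFT, ω²-weighted power. By Wiener–Khinchin this
is the ω-weighted transform of the dipole autocorrelation up to a fixed
frequency weight that does not move narrow peaks. Sub-bin peak positions
by quadratic interpolation over three bins; FWHM by linear interpolation
at half height; no quantum correction. A 19.279 fs-period damped cosine
(decay 2 ps, 50 ps trace, 0.5 fs sampling) peaks at 51.87 THz to two
decimals. Parseval consistency (window-compensated) holds to 1e-6
relative.

**Geometry.** Pore radius r = l/2 − r_o from the cross-pore distance l of
a symmetric carbonyl-oxygen pair; r_o defaults to the oxygen van der Waals
radius 1.52 Å (configurable; it is a convention, not a measured input).
l = 5.84 Å gives the canonical 1.40 Å constriction. "Vibration amplitude"
is the post-discard standard deviation of l; with four oxygens the two
diagonal pairs are averaged. The simulator's optional S1 oxygen pair
breathes as an Ornstein–Uhlenbeck process whose stationary amplitude
shrinks with resonant excitation, A(u) = A₀(1 − 0.5u) — the emulated
"resonance stabilises the filter" signature.

## The current-ratio analysis (uniform barrier drop)

Two otherwise identical single-ion runs whose inter-site saddles differ by
a uniform Δ = ln 1.8 ≈ 0.588 kT should show a current fold change of
e^Δ = 1.8 in the pure Kramers limit. In 1-D overdamped transport at 3 kT
barriers the limit is not fully reached: the diffusive, barrier-insensitive
segments of each transit (reservoir entry, exit descent, well–saddle
ramps) dilute the factor. The study geometry maximises barrier dominance
(plateau saddles hw = 0.05 nm, wells 1.5 kT deep, 0.15 nm reservoirs,
10 mV tilt); the MFPT oracle then predicts 1.657 and the simulation
reproduces the oracle within sampling error (1.65–1.68 at 4 seeds × 300 ns,
dt = 2 fs, ~2000 events). The same dilution makes the Arrhenius slope of
ln(current) vs barrier shift slightly shallower than −1/kT, again exactly
as the oracle predicts; tests assert agreement with the oracle rather than
with the idealised slope.

## Problem sizes and determinism

Default analysis scales (chosen for desk-scale statistics): 40 ns
replicates for the four-condition experiment (2 replicates per condition,
2 ions + 2 waters), 50 ns for PMF recovery, 4 × 300 ns single-ion runs for
the current ratio. Every stochastic component takes an explicit integer
seed; identical configuration + seed is bit-reproducible on the same
platform, and the experiment report echoes all seeds. Scripted fixtures
and closed-form checks are exact and seed-free.

## Known limitations

* The generator's soft-knock-on fraction is an emergent property of its
  crude water model and is not calibrated to any reference percentages;
  those enter only through scripted fixtures.
* ε_r = 2 with λ_D = 0.8 nm makes adjacent-site double occupancy
  prohibitively expensive (~tens of kT), so simulated direct knock-on is
  realised by vacancy-separated pairs; adjacent-contact occupancy codes
  appear only in scripted data.
* Euler–Maruyama rate bias at the default 10 fs step (see above); use
  ≤ 2 fs when rates matter.
* PDB round-trips truncate particle ids to 4 characters and coordinates to
  1e-3 Å.
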