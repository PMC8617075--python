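# Methods

## Scope and structure

`ventplume` couples three sub-models: a 1-D buoyant-plume solver that sets
the physical and chemical state of the non-buoyant plume (NBP); a
thermodynamically explicit 18-guild community model that converts that
state into biomass production rates; and budget arithmetic that
extrapolates the rates to areal and global carbon fluxes. A synthetic-site
generator supplies study inputs so every stage runs without external data.

## Plume model

Assumptions: steady release, Boussinesq, quiescent unconfined ambient,
top-hat profiles, self-similar entrainment. State variables are the fluxes
Q = ur², M = u²r², B = g(ρ_a(z) − ρ)/ρ_ref·ur². The governing equations
(mass, momentum, density-deficit conservation) are integrated in B
directly, which makes the deficit flux exactly conserved in an
unstratified ambient; temperature and salinity ride along as conservative
tracers. The ambient is linearly stratified, interpolated from the density
at vent depth and a reference density `dz_ref` higher; the uniform case is
recovered as the densities coincide. Written for a uniform environment,
the same equations would never produce a finite rise height, so the
stratified ambient is the model's resolution of that tension.

Entrainment: α_e = α_j − (α_j − α_p)(Fr_p/Fr)², clamped to [α_j, α_p],
with defaults α_j = 0.08, α_p = 0.16 (midpoints of the literature ranges
0.05–0.10 and 0.15–0.20) and Fr_p = 1.6; all three configurable. When the
local reduced gravity is non-positive (the overshoot region) the
pure-plume value is used.

Integration: adaptive RK45 on (Q, M, B, QT, QS, rise-time integrand) with
rtol 1e-8, terminated when u falls to 1e-3 of the exit velocity; results
are interpolated onto a 300-cell uniform grid. The NBP is the first grid
level that is both denser than the ambient (B ≤ 0) and has u below 1% of
the profile maximum — i.e. the top of rise, matching the "maximum plume
height" convention. The dilution factor is the volume-flux ratio
Q(z_NBP)/Q(0); mapping grid-cell dilution to the chemistry this way is a
convention choice.

Seawater density uses the UNESCO EOS-80 one-atmosphere polynomial,
linearly extrapolated in temperature above 40 °C for hydrothermal
end-members. The linearisation understates the buoyancy of a ~360 °C
fluid; because the rise height depends on the source buoyancy flux only as
F₀^¼, this shifts predicted heights by tens of percent at most and mainly
affects the first metres of rise — a documented approximation. Pressure
corrections to density and to formation energies are no-ops by default
(the solver only uses density *differences* at one depth; an optional
constant-compressibility term exists).

Validation oracles (in the test suite): the far-field similarity solution
r(z) = (6α/5)z and u ∝ z^(−1/3) for a pure plume in a uniform ambient
(within 5%), and the classical maximum-rise formula
z_max = 3.76·F₀^¼·N^(−¾) in linear stratification (within 15%). The
classical coefficient is quoted for the *total* specific buoyancy flux
F₀ = g′·(πr₀²u₀) — the convention of the hydrothermal-plume literature,
where F₀ derives from total heat flux — and the tests use that convention.

## Thermodynamics

Formation energies at 25 °C/1 bar are embedded as a versioned CSV (a
standard compilation for aqueous species, minerals, water, and the
Heijnen-convention biomass species at −67 kJ/molC). In-situ temperature
correction is Gibbs–Helmholtz with ΔCp = 0:
ΔG_f(T) = ΔG_f(T₀)·T/T₀ + ΔH_f(T₀)(1 − T/T₀). Reaction energies are
ΔG = ΣνΔG_f(T) + RT ln Q with activities from molality (1 m³ ≈ 10³ kg
solvent), Davies coefficients by default (B-dot available, `unit` mode for
activity-independent tests), unit activity for solids and biomass, and
water activity a_w = 1 − 0.000537·S. The Mn-oxidation catabolic standard
energy (absent from thermodynamic databases) defaults to the value implied
by the embedded table and can be overridden in configuration.

The dissipation cost is the Heijnen correlation
ΔG_diss = 200 + 18(6−C)^1.8 + exp{[(3.8−γ)²]^0.16(3.6+0.4C)}, which gives
1477 kJ/molC for acetate (C = 2, γ = 8); following the empirical usage the
model instead assigns 539 kJ/molC to aerobic acetate respiration,
557 kJ/molC to acetate denitrification (the assignment of the printed pair
539–557 between the two heterotrophies is a configuration default — which
guild gets which is not constrained), and 3500 kJ/molC to all sixteen
chemolithoautotrophic pathways (the stated average for metabolisms with
reversed electron transport).

λ = −(ΔG_ana + ΔG_diss)/ΔG_cat, clamped at ≥ 0; a non-exergonic catabolism
(ΔG_cat ≥ 0 under in-situ activities) inactivates the guild. λ and all
activity corrections are recomputed at every solver step.

## Community model

State: 23 chemical species + 18 guild biomasses. The registry is a
reconstruction — source texts give both "21" and "27" species — and is
configurable; the default covers every species appearing in the 36
reactions plus the detrital pools.

Numerical choices:

* **Chemostatted H2O and H+.** Both are held fixed during integration and
  excluded from the growth-law product. Seawater is carbonate-buffered, so
  a fixed pH is the physically sensible closure; a freely evolving H+ pool
  at ~10⁻⁵ mol/m³ would be driven negative by anabolic consumption within
  days. Consequence: carbon is conserved exactly, while H/O/charge flow
  through the open reservoir.
* **Mortality closure.** The 40/10/50 carbon split into labile DOC
  (acetate equivalents), refractory DOC and POC is exact. Converting
  biomass (γ_C = 4.2) partly into acetate (γ_C = 4) is redox-inconsistent
  with pure-carbon or biomass-composition detrital pools, leaving a
  residual reductant; the pools are therefore assigned composition
  C₁H_{2/3}O_{1/6}, the unique choice for which the death reaction closes
  element and charge balance exactly with all biomass nitrogen released as
  ammonium and no residual species. The pools are inert, so only their
  carbon content has dynamical meaning.
* **Non-negativity.** Rates are evaluated on concentrations clipped at
  zero; the MTS exponential itself drives consumption to zero before a
  substrate is exhausted, so no repair ever injects mass. Growth exponents
  below the exp() underflow threshold are treated as zero.
* **Solver.** BDF with rtol 1e-8, atol 1e-15 mol/m³; log-spaced early
  samples capture the initial thermodynamic relaxation. Carbon is
  conserved to ~1e-15 relative over 30 days (structurally: every reaction
  column is element-balanced for any λ).
* **Initial biomass.** 10⁵ cells/ml × 20 fgC/cell (a standard deep-sea
  cell quota; the cell carbon content is a free parameter), spread
  uniformly over the 18 guilds — both configurable.

Reported rates: PHP is the time-averaged *gross* anabolic carbon flux into
the chemoorganotroph guilds, computed through the exact budget identity
∫μX dt = ΔX + α∫X dt (robust to fast transients between samples); the
gross convention is adopted because positive catabolic activities coexist
with zero net autotrophic production. Net autotrophic production is the
time-averaged change of summed autotroph biomass. Per-guild catabolic
activities (λμX) are reported in nmol m⁻³ d⁻¹.

## Synthetic sites and calibration

The generator emulates the structure of a measured site table: end-member
temperature, exit velocity, vent diameter, depth, and end-member
concentrations drawn uniformly (log-uniformly for fields spanning more
than a decade) from literature-plausible black-smoker ranges; a
hand-written TAG-like fixture provides a stable, human-readable
integration case. Ambient stratification uses N = 0.7×10⁻³ s⁻¹, a
realistic abyssal value that yields rise times just over an hour and NBP
heights of 150–550 m.

The deep-seawater background fixes labile DOC at 5×10⁻⁵ mol/m³ acetate
(50 nM — within the measured deep-sea acetate range). Through the MTS
exponential this reproduces the reported bathypelagic heterotrophic
production level (model 0.0071 vs. reported ~0.0067 and measured
0.0048 ± 0.001 µgC L⁻¹ d⁻¹); a 40 µM-C labile pool, by contrast, would
put the community in a substrate-replete regime three orders of magnitude
too productive. The end-member "labile DOC" range (0.05–0.5 mol/m³
acetate) deliberately lumps fluid volatile acids with diffuse-flow DOC
entrained during rise — the mechanisms invoked for plume DOC exceeding
conservative dilution.

What the generator does *not* emulate: measured covariances between
end-member species (each field is drawn independently), abiotic
scavenging/oxidation during rise, non-conservative DOC addition, and any
site-specific hydrography. Passing tests on synthetic sites therefore
demonstrate internal consistency and order-of-magnitude realism, not
agreement with any particular measured vent; the printed per-site rates
(e.g. TAG 0.0116 µgC L⁻¹ d⁻¹) are reproducible only with the measured
substrate table, which users can paste into the same CSV layout.

## Budget arithmetic

HP(Q) = aQ/(K+Q) with defaults a = 0.0123 µgC L⁻¹ d⁻¹, K = 5.987 MW. The
global mean rate uses the analytic primitive aQ − aK ln(Q+K) between
Q_sw = 0.001 (interpreted in MW; the result is insensitive to the unit
reading at this magnitude) and Q_vents = 10⁶ MW, giving 0.012 µgC L⁻¹ d⁻¹.
The published site-average 0.01235 ± 0.003 is not the arithmetic mean of
the printed site rates (0.00998); both the printed average (as the budget
default rate) and the integral mean are exposed, and the min/max global
budgets vary the vent count (713/1853) at fixed rate, with the rate
uncertainty propagated separately as an option. Areal production is
rate × height × 365 with unit conversion; global production multiplies by
the scenario plume area and vent count.

## Known limitations

* No crossflow, rotation, multi-source merging or particle dynamics in the
  plume; no reaction–transport within the rising plume (chemistry is pure
  conservative dilution, which may overestimate sulfide and H2).
* No speciation/complexation equilibria or pH dynamics; H+ enters only as
  an activity.
* ΔG_diss is fixed per metabolism; pathway switching (e.g. reductive
  acetyl-CoA in H2-rich settings) is outside scope.
* Formation energies use ΔCp = 0 and no pressure term; at 250–400 bar this
  is a few kJ/mol on typical reactions.
* The 5-day sensitivity horizon in `analysis/06` and the 30-day default
  elsewhere are the package's chosen problem sizes; longer (300-day) runs
  are available through `ModelParams.duration`.
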