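# Methods

## Scope

`lcdcc` simulates the simultaneous adsorption of humic acid (HA) and
fulvic acid (FA) to goethite in batch systems: single and binary
isotherms, the interfacial distribution of the adsorbed material over the
electrostatic planes, adsorptive molar-mass fractionation, exchange
ratios, and the comparison of a constant versus a variable (composition-
dependent) adsorption volume.  It couples four sub-models solved to joint
self-consistency at every batch point: CD-MUSIC surface speciation of the
oxide, bimodal NICA proton binding of the organic functional groups, an
ADAPT-style variable median affinity, and a competitive
Langmuir–Freundlich (LF) partition with mass balance.

## Surface electrostatics (CD-MUSIC)

The goethite surface carries two 1-pK site types (singly coordinated FeOH,
3.45 nm⁻², and triply coordinated Fe₃O, 2.7 nm⁻²) whose protonation
constants are set to the pristine point of zero charge (log K_H = 9.3), so
a symmetric 1:1 electrolyte yields PZC = 9.3 by construction.  NaCl forms
outer-sphere pairs (log K = −1) whose ion charge resides on the outermost
Stern plane.  The compact layer is a capacitor chain — extended Stern
(planes 0, 1, 2; C1 = 0.9, C2 = 0.74 F m⁻²) or basic Stern (planes 0, 1),
selectable in the configuration — followed by a d-plane and a
Gouy–Chapman diffuse layer.  C3 = 5 F m⁻² places the d-plane essentially
at the Stern/diffuse boundary.  Adsorbed organic charge can be imposed on
any plane; the electrolyte countercharge residing in the organic-occupied
region beyond the Stern layers (thickness `V − d_ST`) is assigned to the
d-plane.  The specific surface area is 96 m² g⁻¹; temperature 295.15 K
(22 °C); solution-species activities are taken equal to concentrations
(at 0.01 M ionic strength the activity corrections are small against the
other model uncertainties, and the PZC is unaffected).

The nonlinear system (mass action with Boltzmann factors, charge–
potential relations across the capacitors, diffuse-layer charge, global
electroneutrality) is solved for the plane potentials with a Powell
hybrid root solver; converged states satisfy electroneutrality to better
than 10⁻¹⁰ C m⁻².  When a large organic charge is imposed far from the
bare-surface solution, the solver falls back to a homotopy that ramps the
organic charge up from zero.  An independent nested-bisection solver of
the same equations serves as a test oracle.

## Organic components (NICA)

Each component carries a bimodal NICA proton-affinity distribution
(generic published humic/fulvic values: HA Q₁ = 3.15 mol kg⁻¹,
log K̃₁ = 2.93, m₁ = 0.50, Q₂ = 2.55, log K̃₂ = 8.00, m₂ = 0.26;
FA Q₁ = 5.88, log K̃₁ = 2.34, m₁ = 0.38, Q₂ = 1.86, log K̃₂ = 8.60,
m₂ = 0.53).  Groups at an interfacial plane titrate against the local
proton activity a_H·exp(−Fψ/RT).  Adsorbed material distributes its
groups over the first Stern pair (fraction f₀₊₁, charge split equally
between planes 0 and 1), the second pair (f₁₊₂, planes 1 and 2), and the
d-plane (f_d, the excess beyond the Stern capacity); the splits are
configurable.

## Interfacial structure

The Stern layers hold at most a volume θ_s·d_ST per unit area
(d_ST = 0.8 nm).  θ_s and the first-Stern share R respond to the
potential gradients of the compact layer through a pluggable regulator;
the default uses a logistic in (ψ₀−ψ₁) for R and a sech in (ψ₁−ψ₂) for
θ_s with a neutral point (θ_s = 1, R = ½) at a flat profile.  The
response coefficients are 0.2 and 0.05 per thermal volt: compact-layer
potential drops amount to tens of thermal volts, so order-one
coefficients would saturate the functionals and unphysically expel all
organic matter from the Stern region.

When both components are adsorbed they share the Stern capacity.  The
space is allocated by weighted proportional water-filling with weights
(d_ST/V_i)^p, p = 2 by default: smaller particles sit closer to the
surface and claim compact-layer space preferentially, pushing larger
humic particles toward the d-plane.  This is the package's realization of
competitive interfacial space limitation.

## Adsorption volume scenarios

Scenario 1 ("constant") fixes the adsorption volume, by default at the
single-HA value 3×10⁻⁹ m³ m⁻².  Scenario 2 ("variable") mixes the
component limiting volumes with the current adsorbed shares,
V = Σ ωᵢ Vᵢ, where ωᵢ is each component's share of the occupied layer
volume (Γᵢ/ρᵢ normalized; a mass-share alternative is a configuration
switch — the two coincide at equal densities).  Both components use the
mass density ρ_p = 1250 kg m⁻³ (midpoint of the hydrated–dry range
700–1700 kg m⁻³).

## Affinity (ADAPT-style bookkeeping)

The median LF affinity of a particle follows from

    ΔG_ads = M_w (e_elec + e_chem + e_rep) + offset,   ln K̃ = −ΔG_ads/RT

* `e_elec` — electrostatic work of moving the plane-assigned NICA charge
  from the bulk to the plane potentials, scaled by a per-component
  coupling (HA 0.05, FA 0.3).  The coupling represents screening of the
  particle charge by counterions within the adsorbed layer: most of a
  large humic coil is locally compensated, while small fulvic particles
  reside entirely within the compact layer and couple strongly.
* `e_chem` — ligand exchange of carboxylic groups held in the first
  Stern pair, E_le·Q₁·f₀₊₁ with E_le = −500 J per mol of groups.
* `e_rep` — lateral repulsion among adsorbed particles, proportional to
  the total surface loading (HA 500, FA 12 000 J kg⁻¹ per mg m⁻²; FA
  carries roughly twice the charge per unit mass, hence the much larger
  coefficient per kilogram).
* `M_w` — the mean molar mass of the adsorbing pool in kg mol⁻¹; for HA
  it varies with the adsorbed fraction through the fractionation relation
  below, for FA it is the constant 1.8 kDa.
* `offset` — a per-component constant calibrated against single-component
  behaviour (below).

This decomposition is the package's reference implementation of the
variable-affinity idea; it sits behind a stable interface
(`median_affinity`) so a different energy model can replace it without
touching the rest of the code.

### Calibration

`calibrate_plateau_offsets` pins each component's offset using one
single-component anchor state at pH 4, 0.01 M, with the solution
concentration held at 100 mg L⁻¹: FA at Γ = 0.95 mg m⁻² (its observed
~1 mg m⁻² maximum, just below complete filling of the 0.8 nm layer) and
HA at Γ = 2.0 mg m⁻² (half-filling of its 3.75 mg m⁻² layer capacity).
The HA anchor deliberately does *not* use the frequently quoted
~3 mg m⁻² maximum: with q = 0.1 the LF odds scale as C^0.1, so an
isotherm passing through the experimentally accessible loading range can
never reach 3 mg m⁻² at realistic concentrations — that number is a
geometric capacity, not an attainable plateau of this isotherm.  Anchoring
at 3 mg m⁻² locks the model into complete HA depletion at every design
point and suppresses all competitive displacement.  At the anchor state
the interfacial equations are solved self-consistently and the offset
follows in closed form from the LF equation.  A general least-squares
calibration against an arbitrary reference isotherm
(`calibrate_offset`) is also provided.

The remaining free internals of the energy bookkeeping (the two lateral-
repulsion coefficients, the two electrostatic couplings, E_le, and the
Stern-sharing preference exponent) were fixed once against the observed
class of competitive asymmetry — the mass exchange ratios of the two
standard batch designs at pH 4 — under hard qualitative constraints
checked independently: monotone isotherms in a component's own addition,
monotone displacement by the competitor, FA insensitivity to HA presence,
convergence at every design point at pH 4 and 6, and scenario-2 HA never
exceeding scenario-1 HA.  Parameter regions that matched the ratios only
through bistable branch switching were rejected.

## Competitive partition and the outer loop

At fixed affinities and volume, the binary LF system with the shared
unoccupied-space denominator plus the two mass balances is solved by
nested bracketed root finding: an outer scalar root on
t = −ln(1 − Σφ_ads) (robust arbitrarily close to a saturated layer) and
an inner monotone `brentq` per component.  The solution concentration is
always derived from the adsorbed amount, so mass balance holds to machine
precision; LF residuals are ≲10⁻¹² except at bound-limited points
(complete depletion, geometric limits), where the equation holds as an
inequality.

In the self-consistent loop the partition additionally uses a two-zone
picture: a component whose limiting volume fits inside the Stern
thickness (FA) equilibrates within the compact-layer zone with its own
saturation, while larger components (HA) share the full-layer
denominator.  Without this, a component confined to a thin layer would
gain spurious capacity from the larger mixed-layer volume.  The pure
shared-denominator form remains the default of `solve_binary_partition`.

The outer loop iterates surface electrostatics (organic charge regulating
inside the surface solve), joint interfacial distributions, molar masses,
affinities, the partition, and the volume rule, with damping 0.5,
oscillation-triggered step reduction, and a root-solve polish; it stops
when the relative loading change falls below 10⁻⁹.  Along an addition
series each point continues from the previous solution (warm start); the
converged state is independent of the start within tolerance.  The
conditional mode pins one component's adsorbed amount to a measured value
and equilibrates the other, mirroring how binary observations are
interpreted.

## Fractionation

The mean molar mass of the adsorbed HA pool follows
M_w = M_o + k(1 − ρ_ssr·C_HA/HA_tot), clamped to [M_o, M_o + k], with
M_o = 1.6 kDa and k = 15.4 kDa from the closure M_o + k = 17 kDa (the
original HA mean).  FA shows no measurable fractionation (k = 0;
M_w = 1.8 kDa).  Mixture means are mass-weighted,
M_w_mix = M_w_HA·φ_HA + M_w_FA·(1 − φ_HA), with an exact inversion for
deriving M_w_HA from a measured mixture mean.

## Experiment designs, synthetic data, parameter recovery

The two packaged designs reproduce the standard competitive layout:
goethite 1 g L⁻¹ in 0.01 M NaCl at pH 4 and 6; design I fixes FA at 0 or
100 mg L⁻¹ and varies HA over 20–240 mg L⁻¹ (8 additions); design II
fixes HA at 0 or 160 mg L⁻¹ and varies FA over 25–200 mg L⁻¹.  Exchange
ratios are ordinary least-squares slopes (free intercept by default;
through-origin optionally) of desorbed mass of the displaced component —
relative to the zero-competitor baseline at the same own-addition —
against the competitor's adsorbed mass.

The synthetic generator perturbs model-generated adsorbed amounts with
multiplicative Gaussian noise (relative SD as specified, truncated at
zero), seeded and byte-reproducible.  It emulates the relative scatter of
duplicate batch measurements; it does not emulate systematic errors of
the quantification chemistry, filtration losses, pH drift, or
inter-batch material variability, so recovery results bound only the
statistical component of parameter uncertainty.  The recovery harness
estimates up to three configuration parameters by bounded least squares
(a coarse grid scan plus scalar refinement for one parameter — the model
response is kinked where a limiting volume crosses the Stern thickness —
and trust-region least squares for several).  The packaged recovery
design extends the addition range (40–640 mg L⁻¹ for HA) beyond the
depletion-dominated regime so the heterogeneity exponent is identified by
the isotherm curvature.

## Numerical defaults and degenerate inputs

Charge residual tolerance 10⁻¹⁰ C m⁻²; outer-loop relative tolerance
10⁻⁹; LF root tolerances near machine precision; all solvers
deterministic given inputs.  Zero additions reduce exactly to the bare
oxide; zero-loading distributions are defined by the regulator's neutral
allocation; complete depletion and saturated layers are handled as
bound-limited equilibria.  Problem sizes are small by construction (a
design point solves in tens of milliseconds; a full two-pH design in
roughly a second), chosen to keep full test and reproduction runs quick.

## Known limitations

* The energy decomposition behind the variable affinity is a documented
  reference implementation of an approach whose original detailed form is
  not public; absolute affinities are therefore calibration-dependent,
  and only behaviour anchored by the calibration and the qualitative
  constraints should be interpreted quantitatively.
* Proton-only NICA: no metal-cation competition, no Donnan treatment of
  the dissolved organics.
* Two components maximum; no oxyanion ternary systems.
* The simulated pH-4 exchange ratios (1.69 and 0.23) carry the right
  asymmetry and magnitude class but are not exact reproductions of the
  measured 2.15 ± 0.05 and 0.31 ± 0.03; the pH-6 ratios (1.26, 0.35 vs
  measured 1.83, 0.44) likewise.  The model's pH trend in the ExpII ratio
  is weaker than measured.
* Crystal-face-resolved surface chemistry and kinetic rearrangement are
  out of scope.
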