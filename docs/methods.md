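# Methods

## Scope and model

`spinex` analyzes millisecond-timescale chemical exchange between a visible
protein ground state and sparsely populated ("invisible") excited states, as
probed by two NMR experiments: chemical exchange saturation transfer (CEST)
and Carr–Purcell–Meiboom–Gill (CPMG) relaxation dispersion. The underlying
dynamical model is the Bloch–McConnell extension of the Bloch equations: for
N exchanging states the magnetization evolves under a linear generator
combining per-state precession (chemical shift offsets), relaxation (R1 on z,
R2 on x/y), the radiofrequency field, and a first-order exchange generator K
whose columns sum to zero and whose off-diagonal entries obey detailed
balance with the state populations (`p_j K_ij = p_i K_ji`).

Supported kinetic topologies are two-state exchange (ground G / excited E,
parametrized by the excited population p_E and lifetime τ_E = 1/k_EG), linear
three-state chains N–I–H, I–N–H and N–H–I (parametrized by the two excited
populations and the summed rate k_ex of each edge, from which the pair rates
follow via the edge populations), and a pseudo-two-state reduction of
asymmetric dimerization. The latter covers a probe whose chemical environment
changes in only one of the two subunits of a dimer: with ω_D2 = ω_M and equal
intrinsic R2, the three-state transverse equations collapse exactly to a
two-state form with forward rate k_MD·[M] and reverse rate k_DM, so that
p_D = k_MD[M]/(k_MD[M] + k_DM).

### CEST simulation

For each irradiation offset the full 3N×3N generator (x, y, z per state) is
built and the thermal-equilibrium magnetization (population-weighted z) is
propagated for T_CEST by a matrix exponential; the reported ratio I/I0 is the
ground-state z component normalized by its value at t = 0, matching the
experimental definition (minor-state peaks are invisible in the readout).
Propagation uses a batched eigendecomposition over the offset stack (with a
scaling-and-squaring `expm` fallback for ill-conditioned members), which
makes a 40–90 offset profile a ~millisecond operation and keeps global CEST
fits tractable.

Two deliberate idealizations: B1 is a single nominal amplitude (no
inhomogeneity distribution), and relaxation drives magnetization to zero
rather than to thermal equilibrium (no constant term). The first means
simulated profiles retain weak Rabi oscillations around the main dip that
real probes wash out; the second reproduces the standard far-off-resonance
limit I/I0 = exp(−R1·T_CEST). Excited-state R1 values are exposed per state
but default equal to the ground-state value, since longitudinal relaxation of
a ~2% state is not determined by these data.

### CPMG simulation

Transverse magnetization (one complex component per state) is propagated
through the constant-time element as 2n repeats of (τ–180°–τ) with
τ = 1/(4ν_CPMG) and n = ν_CPMG·T_CPMG (validated integral), which fills
T_CPMG exactly. The 180° pulses are ideal and instantaneous (complex
conjugation); off-resonance and pulse-imperfection effects are out of scope,
matching the idealization used by the standard analysis programs for
backbone ¹⁵N data. R_2,eff = −(1/T_CPMG)·ln(|ΣM(T)|/|ΣM(0)|).

The operational exchange broadening R_ex = R_2,eff(ν_min) − R_2,eff(ν_max)
approximates the closed-form slow-exchange expression to better than 15%
when both k_ex ≲ 0.2·Δω *and* k_ex·T_CPMG ≳ 5; with slower exchange the
30 ms element contains too few exchange events for the asymptotic formula
and the endpoint measure overshoots it.

The simulator was validated against an exact closed-form solution of the
two-site echo train (the Carver–Richards treatment carried to exact finite
echo counts, implemented with scalar 2×2 algebra in the test suite):
agreement is at machine precision (~1e-12 s⁻¹) across p_E ≤ 5%,
k_ex ∈ [100, 5000] s⁻¹, |Δϖ| ≤ 10 ppm. Note that the familiar asymptotic
(single-eigenvalue) Carver–Richards formula deviates from any correct
finite-time propagation by up to ~2 s⁻¹ in slow exchange, so the exact form
is the only meaningful oracle at sub-0.1 s⁻¹ tolerances. A second
independent check integrates the CEST equations with an adaptive ODE solver.

### Conventions

Shift differences are Δϖ = ϖ(excited) − ϖ(ground) in ppm; "upfield" is
negative. Conversion to rad/s uses the observed nucleus's Larmor frequency
in MHz (2π·Δϖ·f). A table of ¹⁵N/¹³C-to-¹H frequency ratios is provided for
convenience but frequencies are always passed explicitly.

## Fitting

All fits minimize Σ((y_obs − y_model)/σ)² with scipy's trust-region
reflective least squares (finite-difference Jacobians; ftol 1e-10,
xtol 1e-8). Exchange rates and dissociation constants are searched in
log10; populations in (1e-4, 0.5); |Δϖ| ≤ 30 ppm; intrinsic rates in
(0.1, 100) s⁻¹ — bounds chosen as generous physical ranges, since the study
design itself states none. Each fit runs up to five perturbed restarts,
stopping early once χ²_red ≤ 1.3 (full multistart only engages when the
first solutions are poor — a pure robustness/runtime device that leaves
well-conditioned fits untouched). Parameter uncertainties are 1σ values
from the pseudo-inverse of JᵀJ at the solution (the covariance-matrix
method), transformed back from log coordinates where applicable;
χ²_red uses n_data − n_free_params. Fits with populations pinned at a bound
or without convergence are flagged, not silently accepted.

`TwoStateFitter` shares (p_E, k_ex) across all supplied profiles (or per
residue on request), with Δϖ per residue and intrinsic rates per profile.
`DimerLinkedFitter` ties the populations across sample concentrations
through mass action: its global parameters are K_diss and k_DM, and each
profile's (p_D, k_ex) follow from the solver below. Empirically, covariance
σ values calibrate to better than a factor 1.5 against the replicate scatter
of fitted populations, and correctly specified fits give χ²_red ≈ 1.

### Staged three-state protocol

Because four-parameter exchange surfaces (p_H, p_I, k_AB,ex, k_BC,ex) are
multimodal, three-state fitting is staged. Stage one grids the four
parameters — presets reproduce the study protocol: 11 log-spaced rate points
spanning 10–2016 s⁻¹ with 16 linear population points 0.5–23% for the
dimerization process, and 16 log rate points 10–11529 s⁻¹ with 10 linear
population points 0.5–14% for local folding — holding the CEST-derived
ground-to-excited shift Δϖ_NH fixed per residue and optimizing only the
hidden-state shift and intrinsic rates at each node (two inner starts:
hidden state near the ground or near the excited shift, the two ways an
intermediate escapes detection in a two-dip profile). Per-residue χ²_red
surfaces are summed, and the 10 lowest nodes (ties broken toward slower,
better-determined exchange: smaller k_AB,ex then k_BC,ex) seed stage two,
where every parameter is released. Grid-node failures record +inf and the
search continues. Node fits use relaxed tolerances (1e-6); they only rank
nodes.

### CEST dip extraction

Excited-state shifts are read from CEST profiles by fitting a constant
baseline minus a sum of Gaussians. Two implementation details matter in
practice. First, candidate dip centers are found by peak prominence on a
~1 ppm-smoothed depth profile, and dips beyond the first are placed
greedily by trying candidates from both the depth ranking and the residual
left after fitting the dips found so far — a minor dip sitting on the
shoulder of the saturation dip is often not a local extremum of the raw
profile but stands out in that residual. Second, one extra broad Gaussian
beyond the requested dip count absorbs the non-Gaussian wings of the main
saturation dip, which otherwise bias the minor-dip center toward the major
dip by several tenths of a ppm. Dip components are bounded near their
candidates; only the auxiliary component may be broad. Fitted dips closer
than one linewidth (FWHM) are merged, flagged, and the profile refitted
with fewer components.

A physical caveat documented here because it limits any extractor: the
apparent CEST dip of a state with a millisecond lifetime is displaced toward
the ground resonance by approximately k_EG²/Δω plus an overlap skew. At the
reference-condition dimerization kinetics (k_ex ≈ 344 s⁻¹, Δϖ = −8.3 ppm,
B1 = 31 Hz) the dip actually present in a noiseless profile sits ≈8.13 ppm
from the main dip, and the extractor reports 8.10 — accurate to ~0.03 ppm
for what is extractable, while slow-exchange profiles (k_ex ≲ 50 s⁻¹)
recover planted separations to ±0.05 ppm. Matching dip positions against
reference shift tables should therefore use a ~1 ppm window (the classifier
default below).

### Noise estimation

CEST noise is the standard deviation of baseline points (≥5, selected far
from all dips) after removing a linear trend; CPMG R_2,eff errors come from
the pooled standard deviation of duplicate intensity measurements,
propagated as σ_R = σ_I/(I·T_CPMG), with a configurable floor.

## Oligomerization thermodynamics

Fitted (p_D, k_ex) pairs are recast under mass action. Symmetric dimer
2M⇌D: k_ex = 2k_MD[M] + k_DM, p_D = 2[D]/(2[D]+[M]), giving
K_diss = 2C(1−p_D)²/p_D; the forward solution uses the numerically stable
root [M] = 2C/(1+√(1+8C/K_diss)) with [D] = [M]²/K_diss, so weak-association
limits (K_diss ≫ C) do not suffer cancellation. Asymmetric dimer (molecule
bookkeeping): k_ex = k_MD[M] + k_DM, p_D = [D]/([D]+[M]); the total-to-free
monomer mapping uses [M] = (1−p_D)·C, the small-p_D limit consistent with
that bookkeeping. Concentrations are mM throughout; K_MD in mM⁻¹, K_diss in
mM. Temperature series are fitted independently per temperature (Δϖ free at
each), then analyzed van't Hoff-style: weighted linear regression of ln K
(or ln k) on 1/T in kelvin, slope = −ΔH/R for an equilibrium constant.

## Process classification

Probes are assigned to the four exchange processes by a deterministic
cascade on R_ex = R_2,eff(ν_min) − R_2,eff(ν_max) measured across
conditions:

(a) concentration-independent probes with a large (≥3 ppm) CEST minor dip
within the folding-loop residue set → local folding (II);
(b) concentration-dependent probes whose dip matches the native-dimer shift
table *and* that carry the interface-burial annotation → native
dimerization (I);
(c) concentration-dependent, temperature-increasing probes with R_ex above
the process-I reference bound → non-native dimer III;
(d) concentration-dependent, temperature-decreasing → non-native dimer IV;
(e) otherwise unassigned, and conflicting evidence yields an explicit
unassignment with a recorded reason, never a silent choice.

Thresholds (configurable, defaults as used throughout): concentration ratio
R > 1.4 with R/σ_R ≥ 3 between the highest and lowest concentrations;
temperature difference D > 1 s⁻¹ with D/σ_D ≥ 3 between 35 °C and 25 °C;
R_ex > 5 s⁻¹ marks an exchange-active probe. The process-I bound is the
supremum of R_ex = p_G·p_E·k_ex·Δω²/(k_ex²+Δω²) over Δω at the reference
fit's parameters (analytically p_G·p_E·k_ex). The native-shift match window
is 1.0 ppm rather than a tighter value because of the dip-displacement
physics above: at the native-dimerization kinetics the apparent dip of a
correctly matching probe can sit up to ~0.7 ppm from the reference shift,
and a 0.5 ppm window rejects genuine matches while the competing processes
(shift differences ≤1.5 ppm, no burial annotation, unresolved dips) cannot
enter this criterion at all. Interface burial itself is a precomputed input
annotation (buried area > 2 Å² between monomer and dimer); no structural
computation is performed. Mutant datasets, when supplied with a list of the
processes each mutant eliminates, confirm assignments whose exchange
vanishes in the mutant and flag those where it persists.

## Synthetic data generator

The generator emulates a four-process study: ~80 ¹⁵N probes split among
native dimerization (I: 16 probes, upfield shifts 3.8–8.3 ppm, interface
burial annotations, K_diss = 85 mM, ~3%/3 ms at 1.3 mM and 25 °C), local
helix folding (II: 16 loop probes, shifts 3–10 ppm, 2.1%/13 ms,
concentration-independent), symmetric non-native dimerization (III: 20
probes, shifts 0.9–1.5 ppm, 3.3%/6.0 ms at 1.3 mM, R_ex increasing with
temperature), asymmetric non-native dimerization (IV: 16 probes, shifts
1.0–1.5 ppm via the reduced model, 2.1%/1.6 ms, R_ex decreasing with
temperature), plus 12 exchange-free null probes so classifier false-positive
rates are measurable. CPMG data (20-point ladders, T = 30 ms) are generated
at 600 and 800 MHz (¹H) over concentrations 0.7/2.0/3.5 mM and 25/35 °C;
CEST data (B1 = 31 and 59 Hz, T = 350 ms, 0.5 ppm steps) for the
large-shift probes at 0.7 and 1.3 mM. Populations of the intermolecular
processes rescale across concentration through the mass-action solvers;
temperature dependence is encoded as per-temperature (K_diss, k_DM) or
(p, τ) tables — not a thermodynamic model — because the analysis fits
temperatures independently. The 35 °C entries are chosen to give the
documented directions of temperature response with magnitudes typical of a
few-kcal/mol association enthalpy. Default noise: σ = 0.01 on CEST ratios,
σ = 0.2 s⁻¹ on R_2,eff — plausible bench values, overridable. All outputs
are bitwise-reproducible for a fixed seed.

One structural choice deserves emphasis. The dimer-interface probes of a
real aggregation-prone protein sense several concurrent processes, which
degrades their dispersion profiles: CPMG-visible exchange amplitudes at the
native-dimer interface are much smaller than the CEST-derived
thermodynamics imply. The generator reproduces this discordance by giving
process I two parameter channels — CEST observables from the
thermodynamic values above, CPMG observables from dispersion-consistent
parameters (~1% excited population with k_ex ≈ 280 s⁻¹ at 1.5 mM, giving a
reference bound of ≈2.8 s⁻¹). Without this split, the bound criterion (c)
could never separate processes I and III, because a 3%/3 ms dimerization
would cap its reporters at ~10 s⁻¹, above everything process III produces.
The mechanism of the attenuation (fluctuating local fields from proximal
processes) is *not* simulated; the split encodes only its observable
consequence.

What the generator does not emulate — and hence what passing tests do not
establish about real data: spectral lineshapes and peak overlap, B1
inhomogeneity, cross-contamination between processes at shared probes,
scalar couplings and anti-phase magnetization, temperature-dependent
viscosity beyond a simple R2 scaling, and any non-dimeric oligomer
stoichiometry.

## Problem sizes and numerical choices

The test suite and the acceptance script use 10 noise replicates for
recovery medians, 5-residue two-field dispersion sets, 4-residue
two-concentration CEST sets, 16–24-node grids for the staged-protocol
checks (the full presets are exercised for their axes, not searched
exhaustively), 100 fits for the recovery-rate ensemble and 200 replicates
for covariance calibration — sizes chosen so the whole pipeline, generation
through classification, reruns from scratch in minutes on one core while
every statistical claim retains adequate power. Degenerate inputs are
handled explicitly: non-positive errors, non-monotonic offset ladders,
non-integral CPMG cycle counts, populations outside the simplex, mass-action
conditions with p_D ≥ 0.5 and pathological (>1e8 s⁻¹) rates are all
rejected with diagnostics rather than propagated.

## Known limitations

* CPMG pulses are ideal; ¹³C methyl data with strong off-resonance effects
  would need a finite-pulse propagator.
* The asymmetric-dimer reduction assumes equal intrinsic R2 in monomer and
  dimer; a large R2 difference reintroduces three-state character.
* Dip extraction reports the dip actually present in a profile; at exchange
  rates above a few hundred s⁻¹ this is displaced from the true
  excited-state shift (see above) and no sum-of-Gaussians model can undo
  that displacement.
* The classifier's criteria are those of a specific experimental design
  (two concentrations, two temperatures, one mutant panel); other designs
  need threshold and condition-key changes in `ClassifierConfig`.
* Bayesian posteriors and bootstrap uncertainty distributions are out of
  scope; all uncertainties are covariance-based.
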