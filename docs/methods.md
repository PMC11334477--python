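# Methods

This note documents the models implemented in `eutflux`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate.

## Physiology: extracellular fluxes from batch time courses

Cells in balanced exponential growth are assumed to be at metabolic steady
state: the growth rate µ (h⁻¹) and every biomass-specific flux q
(mmol·gDW⁻¹·h⁻¹) are constant.  Concentrations then follow closed forms:

* biomass X(t) = X₀·e^{µt};
* substrate S(t) = S₀ − (q_S·X₀/µ)(e^{µt} − 1);
* product P(t) = P₀ + (q_P·X₀/µ)(e^{µt} − 1);
* volatile product (dP/dt = q_P X − k·P):
  P(t) = P₀e^{−kt} + q_P X₀ (e^{µt} − e^{−kt})/(µ + k).

The µ → 0 and µ → −k limits are implemented analytically to avoid 0/0.  The
ethanol evaporation constant defaults to the experimentally determined
0.0379 h⁻¹ and is fixed during fitting (it can be freed, but on a single
batch it is poorly identified jointly with q_EtOH).  The fitter minimizes
Σᵢ((xᵢ−yᵢ)/σᵢ)² jointly over all series with a bounded trust-region least
squares, 10 seeded multi-starts around data-driven initial guesses (µ from
log-linear regression of biomass, fluxes from secants).  σᵢ comes from the
table's `sd` column; uncertainty estimates use Monte-Carlo residual
resampling (off by default).  The model contains no lag, stationary phase
or Monod kinetics, so callers must truncate data to the exponential window.

## Compartmentalized FBA

The Eut BMC is inserted as a separate compartment whose NAD(H) and
CoA/acetyl-CoA pools have deliberately **no transport reactions** across the
shell.  At steady state those pools must close through EutE (NADH and
acetyl-CoA production), EutG (NADH consumption) and EutD (acetyl-CoA
consumption), which forces v_EutE = v_EutG = v_EutD for every feasible flux
vector — the structural signature of cofactor recycling inside the
compartment.  Ammonium released by the EutBC lyase goes to the cytosol, as
does the acetyl-phosphate exported by EutD (where acetate kinase, the
EutQ/P role, regenerates ATP in the cytosol).

The bundled core model lumps glycerol catabolism (glycerol → acetyl-P +
CO₂), the phosphotransacetylase/acetate-kinase node, the TCA cycle and
oxidative phosphorylation (P/O = 2) into single reactions, and uses a
biomass reaction draining 40.7 mmol carbon (as acetyl-CoA) and 10.18 mmol
nitrogen per gDW — an explicit 4:1 C:N molar composition.  Every internal
reaction balances C and N exactly (`audit_elemental_balance`); hydrogen and
oxygen bookkeeping is approximate in the lumped reactions, which is why the
audit is restricted to the elements the analysis tracks.  Because the core
model's biomass nitrogen demand is a coarse estimate, nitrogen-overflow
*percentages* are only qualitative at this scale; the carbon partition, by
contrast, is constraint-forced and exact (with EA uptake 7.8 and ethanol
excretion 2.6 mmol·gDW⁻¹·h⁻¹, the egress split 2.6/2.6/2.6 follows from the
sequestration constraint alone).  Exact genome-scale numbers (maximal
growth 0.72 h⁻¹, ammonium excretion 3.0 mmol·gDW⁻¹·h⁻¹) are only claimed
against a user-supplied iML1515 SBML file (`genome_scale_checks`).

LPs are solved by COBRApy/optlang (GLPK).  Alternate optima are not
tie-broken: partition reports are computed on the returned vertex, and FVA
(flux ranges at ≥ a fraction, default 99%, of the optimum) is the tool for
uniqueness claims.

## Dynamic ¹³C isotopic model

Three compartments: environment, cytoplasm, Eut BMC.  Processes: growth;
glycerol uptake with a coarse-grained glycolysis producing unlabeled
cytosolic acetyl-P (one CO₂ per glycerol); EA uptake and deamination in the
BMC (EutBC), acetaldehyde reduction to BMC acetyl-CoA (EutE) exported as
acetyl-P (EutD), acetaldehyde reduction to ethanol (EutG), direct
acetaldehyde release; cytosolic acetyl-P split between acetate excretion
and an anabolic acetyl-CoA sink (Pta); ammonium excretion plus an
assimilation sink; first-order ethanol evaporation (0.0379 h⁻¹).  Every
carbon-carrying reaction is duplicated for unlabeled/labeled twins, with
consumption split in proportion to the instantaneous label fraction of the
substrate pool (well-mixed pools; 0/0 guarded as all-unlabeled).  The
tracer is fully ¹³C₂-labeled EA (purity configurable, default 1.0).

Steady-state relations eliminate the dependent fluxes: v_EutE = v_EutG =
v_EutD (sequestration), v_AAL = v_EA − 2·v_EutG (BMC acetaldehyde balance),
v_Pta = v_glycolysis + v_EutD − v_AceX − v_cytEtOH (acetyl-P balance), and
N-assimilation = v_EA − v_NH4X.  Total glycerol uptake is a separate
parameter from the glycolytic acetyl-P flux; the difference is drained by
biomass synthesis and respiration, an unlabeled route that leaves the label
dynamics untouched — without it the model could not reproduce the measured
glycerol consumption (≈14.7) alongside the much smaller glycolytic acetyl-P
production (≈2.5 mmol·gDW⁻¹·h⁻¹).

Intracellular pools are kept small (default 0.01 mM in culture volume,
searched in log-space during fitting) so label fractions relax quickly and
trajectories are quasi-stationary, mirroring the metabolic-steady-state
assumption while keeping the ODEs well-posed.  Pool totals are constant by
construction (influx = outflux); treating them as culture-volume
concentrations rather than per-biomass quantities ignores growth dilution
of the pools, a negligible effect at these pool sizes.

Two simulation routes exist and are cross-checked in the tests:

* **reference** — stiff LSODA integration of the full 24-state
  labeled/unlabeled system (rtol 1e-8, atol 1e-9), including cumulative
  sink integrals used by the carbon/nitrogen conservation audits (< 1e-6
  relative drift required);
* **fast** — exact closed forms for all totals, exact label-fraction
  solutions of the linear cascade in the transformed time
  τ(t) = X₀(e^{µt} − 1)/µ, and 24-node Gauss–Legendre cumulative quadrature
  for the labeled environment pools.  Nearly degenerate cascade rates are
  separated by a 1e-7 relative perturbation (a measure-zero configuration;
  the error is far below fit tolerances).

The fast route evaluates in well under a millisecond and is used inside the
optimizer; the two routes agree to integrator tolerance (~1e-6 mM).

### Fitting

The objective is f(p) = Σᵢ((xᵢ−yᵢ(p))/σᵢ)², with replicates entering as
independent points against the shared trajectory and every point requiring
a σᵢ.  The free parameters (with v_cytEtOH enabled, 12; 11 by default) are
X₀, µ, glycerol₀, EA₀, v_glyc_uptake, v_glycolysis, v_EA, v_EutG, v_AceX,
v_NH4X, log₁₀ pool scale, and optionally v_cytEtOH; dependent fluxes are
derived, so every particle satisfies the steady-state relations by
construction, and derived-flux negativity is penalized smoothly.  The
optimizer is constriction-factor PSO (χ = 0.729, c₁ = c₂ = 1.49445),
global-best topology, reflecting bounds, default 2000 iterations × swarm
50, deterministic under a fixed seed.  An optional Nelder–Mead polish of
the swarm optimum is off by default.

The optional cytosolic ethanol route (v_cytEtOH, drawing on the cytosolic
acetyl-P pool) models the candidate origin of residual unlabeled ethanol; it
is disabled by default because it is structurally weak when near zero, and
fits report it with wide bounds rather than point claims.  Both split-label
and label-blind (total) observables are accepted for ethanol and acetate.

## Isotopologue correction

Low-resolution mode: the measured mass-shift distribution is
M @ true, where column j of M convolves (a) the natural-abundance shift
distribution of all non-carbon atoms, (b) the natural ¹³C binomial over the
n−j unlabeled carbons, and (c) the tracer-purity binomial over the j
labeled carbons, truncated at shift n.  Correction solves the inverse by
NNLS and renormalizes — robust to noise and truncation, and corrected
fractions are non-negative by contract.  Natural abundances default to
IUPAC representative values (¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364,
¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075, ³⁴S 0.0425, ³⁶S 0.0001), all
overridable.  No isotope-specific fine structure is modeled (matching
full-scan Orbitrap CID usage), and no spectral deconvolution from raw data.

## Per-BMC metrics

fmol·cell⁻¹·h⁻¹ = q · m_cell · 10¹²; per-BMC divides by the BMC count;
carbon weighting multiplies by carbon atoms.  Defaults: m_cell = 2.88e-13
gDW, cytosol 1.3 fL, BMC diameter 100 nm, 5.9 BMCs per cell (the microscopy
census).  These are configuration parameters echoed in every report, never
hard-coded in the operations — per-BMC numbers are only as good as the
census assumptions, so the inputs travel with the outputs.

## Synthetic data: what it does and does not emulate

The generators produce tidy replicated tables with multiplicative Gaussian
noise (CV default 2%, emulating ¹H-NMR quantification error) plus an
additive 0.02 mM floor; the applied SD is recorded per point and negative
noisy values are clipped at zero (logged).  Default sampling is hourly with
three biological replicates.  At the reference parameters (X₀ = 0.026
gDW/L, glycerol₀ = 30 mM, EA₀ = 20 mM) glycerol is exhausted at ≈8.0 h and
EA at ≈8.7 h, so generated/fitted windows are restricted to the exponential
phase (0–7 h; 8 hourly points for physiology, 12 points for tracer
experiments).  Acetaldehyde is generated as an optional trace series,
excluded from fitting by default.

Passing recovery tests on these data shows the estimators are consistent
and well-identified under the stated noise model; it does **not** validate
the noise model itself against real NMR replicates (per-point σᵢ of the
emulated experiments are not published), nor the network reconstruction
against the full deposited model — the network audit
(`IsotopicNetwork.audit`) exposes species/reaction/compartment counts so
divergence from other reconstructions is detectable rather than silent.

## Problem sizes and numerical defaults

Recovery property tests use desk-scale settings chosen as the package's own
test sizes: physiology, 20 seeded noisy datasets with 10-start fits;
isotopic, 8 seeded datasets fitted with 250 iterations × swarm 40 plus
polish (median flux error observed ≈1–2%, comfortably under the 10%
property bound).  The headline PSO fit uses the full 2000 × 50 settings.
LP tolerance is the GLPK default (~1e-9); ODE tolerances rtol 1e-8 / atol
1e-9; Gauss–Legendre order 24; NNLS is exact for these matrix sizes.

## Known limitations

* Constant-flux batch model only: no lag/stationary phase, no acetate
  re-consumption after substrate exhaustion, no Monod kinetics.
* The core FBA model is a desk-scale stand-in; genome-scale claims require
  the user-supplied iML1515 file.
* The isotopic model tracks unlabeled vs uniformly labeled species only
  (no positional isotopomers/EMU), appropriate for a ¹³C₂ tracer whose
  carbon skeleton stays intact through the Eut pathway.
* Per-BMC fluxes inherit the full uncertainty of the cell-mass and
  BMC-count assumptions.
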