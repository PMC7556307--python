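# Methods

## Model and assumptions

All analyses are flux balance analysis (FBA): a flux vector v over the
reaction set is constrained by steady-state mass balance S·v = 0 and bounds
lb ≤ v ≤ ub, and a single flux is optimized by linear programming.  Flux
units are mmol/gDCW/h throughout; growth rate is h⁻¹.  Yields (mg/gDCW) and
titers (mg/L) exist only at the measurement boundary and are converted once,
during contextualization.  No kinetics, no enzyme-capacity (V_max)
constraints, and no integer variables anywhere: every procedure is an LP.

Pigment accumulation is modeled as irreversible intracellular **sink**
drains, because carotenoids retained in biomass never re-enter metabolism
and the measurement (mg per gDCW) is a retained-content measurement, not a
secretion.  β-ionone, by contrast, is secreted and captured in the culture
medium/overlay, so it leaves through an **exchange** reaction.  All sinks
and the β-ionone exchange are created closed and opened only by the
contextualization step, so an extended-but-unconstrained model cannot leak
carbon.

### Heterologous pathway stoichiometry

Neutral-species formulas are used so every template reaction balances
exactly for C, H, O (and P for the prenyl steps):

| reaction | stoichiometry |
|---|---|
| CrtE | FPP (C15H28O7P2) + IPP (C5H12O7P2) → GGPP (C20H36O7P2) + PPi |
| CrtYB (synthase) | 2 GGPP → phytoene (C40H64) + 2 PPi |
| CrtI (lumped ×4) | phytoene + 4 FAD → lycopene (C40H56) + 4 FADH2 |
| CrtYB (cyclase) | lycopene → β-carotene (C40H56) |
| CCD1 double | β-carotene + 2 O2 → 2 β-ionone (C13H20O) + C14 dialdehyde (C14H16O2) |
| CCD1 single (optional) | β-carotene + O2 → β-ionone + C27 apocarotenal (C27H36O) |

C14H16O2 is the unique formula closing the double-cleavage balance; the C27
apocarotenal likewise closes the single-cleavage balance.  The four phytoene
desaturations are lumped with FAD/FADH2 as the electron pair — no mechanism
is established for the heterologous desaturase in yeast, and this choice is
elementally balanced and host-agnostic (FADH2 reoxidation is left to the
host).  Further cleavage of the C27 apocarotenal is *not* modeled: when the
single-cleavage route is enabled, the C27 product only accumulates in its
own sink.  Gene dosage, promoter strength and integration locus have no
stoichiometric representation; strains differing only in those enter the
analysis through the measurements they produce.

Molar masses use standard atomic weights (C 12.0107, H 1.00794, O 15.9994,
…): β-ionone 192.30 g/mol, β-carotene 536.87 g/mol.

## Contextualization

`apply_growth_context` encodes aerobic growth on glucose as sole carbon
source: every carbon-carrying exchange except glucose is closed to uptake
(exports stay open), O2 uptake and CO2 export are opened, and the
maintenance ATPase lower bound is set to NGAM (default 0.7 mmol
ATP/gDCW/h, the consensus value in curated yeast reconstructions).

`constrain_strain` turns one measurement row into interval constraints:

* growth flux = μ, CO2 exchange = q_CO2;
* each carotenoid sink = μ·Y_species/M_species (growth-coupled: a content of
  Y mg/gDCW in a population growing at μ accumulates at rate μ·Y/M);
* β-ionone exchange = titer/(X·t·M) (endpoint: the titer is the integral of
  secretion over the whole culture of biomass X for time t).  Both coupling
  modes are exposed; these defaults match the physical meaning of each
  measurement type.  With no titer the exchange is pinned to zero.
* the unmeasured cleavage co-product sinks (C14 dialdehyde, C27) are left
  free — their fate is unknown, and closing them would force infeasibility
  whenever cleavage is active.

Measured values become intervals of half-width `tol_frac` (default 5%)
around the measurement, **not equalities** — strict equalities on noisy
measurements routinely make the LP infeasible.  The tolerance also matters
scientifically: the counterfactual step explores flux states away from the
observed one, and needs the measured-CO2 interval to absorb the extra
pathway CO2 of the maximum-carotene scenario.  At `tol_frac = 0` the
counterfactual ceiling collapses onto the observed pathway flux and the
departure is 0 by construction; 5% is ample for the default toy scale, where
the extra CO2 of reaching the precursor ceiling is ≈3% of q_CO2.  Every
constraint carries a provenance note naming the measurement field it came
from, and constraint construction is a pure function (idempotent, original
model untouched).

When a table row lacks μ/q_CO2/glucose uptake (the published table prints
none of them), the pipeline either skips the rate-dependent stages with a
notice, or — on request (`use_rate_defaults`) — substitutes a packaged
literature table for aerobic batch growth of *S. cerevisiae* on glucose
(μ = 0.37 h⁻¹, q_CO2 = 22, q_glc = 15 mmol/gDCW/h), flagging every
substitution in the log.  The defaults are deliberately not baked into the
fixture rows: those rates were never printed, and inventing per-strain
values would contaminate the fixture.

## Interrogation procedures

1. **Minimal glucose uptake.**  Glucose uptake is the negative exchange
   flux, so the minimum uptake supporting the constraints is found by
   maximizing the exchange flux; the magnitude is reported.  This is the
   biomass-yield-on-glucose optimum.  Relative error = |pred − exp|/exp·100
   against the experimentally determined uptake.
2. **Carbon recovery.**  100·[μ·C_biomass + q_CO2 + Σ C_i·v_i(products)] /
   (6·q_glc,exp).  The biomass carbon content is derived from the biomass
   reaction composition (net carbon consumed per unit growth flux), with a
   configurable fallback of 40 mmol C/gDCW (≈0.48 g C/gDCW).  The
   denominator uses the *experimental* uptake by default: recovery against
   the model's own minimal uptake is ≈100% by construction and carries no
   information.
3. **Counterfactual maximum β-ionone.**  (i) Force β-ionone production to
   zero, keep all other strain constraints, and maximize the β-carotene
   sink → q_car,theo.  (ii) divertible carbon = 40·(q_car,theo − q_car,exp).
   (iii) Restore the observed β-carotene accumulation, cap total carbon into
   the cleavage reactions (40·Σv_CCD1 ≤ divertible carbon — the cap is on
   CCD1 substrate carbon, not on GGPP supply, the most literal reading of
   constraining the carbon flux toward β-carotene), and maximize the
   β-ionone exchange → q_ionone,max.  Departure = (1 −
   q_ionone,exp/q_ionone,max)·100.  A measurement above the model optimum
   (q_car,exp > q_car,theo) is reported as an error, not clipped;
   q_ionone,max = 0 leaves the departure undefined and says so.
4. **C14:ionone ratio.**  v_double/v_ionone on the step-3 optimum: each
   double-cleavage event makes one C14 and contributes two ionones, so pure
   double cleavage gives 0.5 and any single-site cleavage lowers it.

FBA optima are degenerate, and the published analysis does not say how its
flux ratios were made unique.  This package computes every flux-derived
statistic on the **parsimonious** optimum (minimum Σ|v| at the fixed
objective, reversible fluxes split into non-negative parts), and reports the
degeneracy breadth of the ratio besides (its min and max over the optimal
face, via two auxiliary LPs).  Reports carry a `parsimonious` provenance
flag.

## Numerical choices

* Solver: scipy's HiGHS interface; deterministic variable ordering
  (model insertion order), no randomized options.
* Tolerances: 1e-6 relative / 1e-9 absolute.  Solutions are post-checked
  against max|S·v| and the bounds and **rejected** on violation, never
  patched — a quietly violated constraint would corrupt the carbon
  accounting downstream.
* Infeasibility is reported as a status (with the forced-flux constraints
  echoed for diagnosis), distinct from numerical solver failure, which
  raises.
* The parsimony step pins the objective within its relative tolerance, so
  parsimonious objective values may sit at the lower edge of a ±1e-6 band.
* Degenerate inputs: zero yields give zero-flux constraints; zero titer
  converts to rate 0 without requiring the denominators; empty formulas,
  unknown elements and missing formulas raise immediately (a metabolite
  without a formula is never treated as carbon-free).

## Synthetic data

The toy host lumps central metabolism so every optimum has a closed form
(documented in the emitted model description): respiration yields
`atp_per_glucose` ATP per glucose (default 16, a lumped P/O-equivalent),
biomass costs `carbon_per_biomass`/6 glucose (default 40 mmol C/gDCW) plus
`gam_atp` ATP (default 60 mmol/gDCW), the optional fermentation branch
yields 2 ATP + 2 ethanol + 2 CO2 per glucose, and the lumped mevalonate
route pays 1.5 glucose + 6 ATP per IPP (C9 → C5 + 4 CO2; H/O bookkeeping of
this one lumped step is approximate — carbon and phosphorus balance
exactly, which is what the analyses consume).  FPP synthase carries the
`fpp_capacity` bound (default 0.02 mmol/gDCW/h), so the maximum β-carotene
flux after extension is exactly `fpp_capacity/2`; at μ = 0.3 h⁻¹ this
corresponds to ≈18 mg/gDCW maximal accumulation, i.e. the generator's
default scale mimics the single-to-few-copy strains, keeping the pathway
a few percent of total carbon flux.

The default simulated strain accumulates β-carotene at half the precursor
ceiling and cleaves 30% of the divertible carbon (double cleavage only) —
conditions under which the observed departures (~70%) and a specificity
diagnosis are reproduced.  Measurement noise is multiplicative log-normal
with unit mean at a stated CV (default 5%, the scale of triplicate
shake-flask scatter).  The three specific rates (μ, q_CO2, q_glc) share one
noise factor per strain: their dominant experimental error is the common
biomass denominator, and fully correlated rate errors keep the noisy
measurement stoichiometrically self-consistent, which is why constraint
construction at `tol_frac` ≥ the noise CV stays feasible.  Yields and the
titer receive independent factors; profile fractions are recomputed from
the noised per-species yields.

What the generator does **not** emulate: batch dynamics (the culture is
treated as pseudo-steady balanced growth; endpoint titers are averaged over
the culture time), dodecane-overlay partitioning (all β-ionone is assumed
captured in the measured titer), product toxicity, gene-dosage or locus
effects, and the full reaction repertoire of a genome-scale model.  Passing
tests on the toy therefore certify the *procedures* — constraint
construction, LP correctness, carbon accounting, recovery of a known
cleavage allocation — not the numerical values any particular genome-scale
reconstruction would produce.

## Published strain table

`published_strain_table()` packages the printed shake-flask results of the
strain series (total carotenoids 4/3.8/3.8/12/16/32 mg/gDCW for
β-Car1.1→β-Car5; β-ionone titers 1.8/18.2/26.3/33 mg/L for
β-iono2.1/5.1/5.2/5.3; residual carotenoids 14.2 and 26.7 mg/gDCW for
β-iono4.1 and β-iono5.1; 72-h cultures; 2.6–4.1 mg/gDCW across integration
loci).  Growth and CO₂ rates were not printed and the rows leave them
empty, so full-pipeline runs on this table degrade to unit-conversion and
fold-change checks by design.

## Problem sizes

The test suite and example runs use the toy host (≈25 metabolites, ≈30
reactions after extension), 110 random LP instances of ≤8 reactions for the
enumeration cross-check, 200 replicates for the noise calibration, and 20
seeds for the cleavage-fraction recovery; the whole suite completes in a few
seconds on one CPU.

## Known limitations

* A genome-scale reconstruction (e.g. iMM904 from the BiGG collection) can
  be loaded through the same interfaces (JSON/SBML, with a `host_map` from
  pathway roles to host metabolite ids), but no genome-scale fixture ships
  with the package, and full-scale quantities reported in the literature for
  these strain series (departures of 44–73.4%, C14:ionone ratios of
  0.15–0.32) depend on a bespoke genome-scale extension that is not publicly
  distributed and is not reproduced here.  Ratios below 0.5 require cleavage
  chemistry beyond β-carotene double cleavage (single-site cleavage and/or
  upstream substrates); the package models the single-cleavage route as an
  option but deliberately does not guess further apocarotenoid chemistry.
* SBML round trips preserve structure but reconstruct the reaction `kind`
  tag from id conventions (`SK_` prefix, "biomass" substring); the JSON
  dialect carries the tag losslessly and is the primary format.
* Proton/charge bookkeeping follows the host model's convention; the toy
  host's lumped MVA step balances C and P but not H/O.
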