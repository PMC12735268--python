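# Methods

## Model and analysis framework

All analyses operate on a constraint-based metabolic model: metabolites
with Hill-notation formulas (unknown tokens kept as opaque pseudo-elements)
and integer charges; reactions with signed rational stoichiometry, box flux
bounds in mmol·gDCW⁻¹·h⁻¹, optional boolean gene–protein–reaction rules,
and a `kind` flag (`internal`, `exchange`, `demand`, `sink`, `biomass`,
`maintenance`). The steady-state assumption S·v = 0 with bounds defines the
feasible flux space; three linear programs are the analysis primitives:

* **FBA** — maximize the objective flux.
* **pFBA** — fix the objective at its optimum (relative slack 1e-9), then
  minimize Σ|v| by splitting each flux into forward and reverse
  non-negative parts. Individual fluxes at degenerate alternate optima are
  solver-dependent; only objective values, flux totals and FVA envelopes
  are treated as well-defined, and tests assert nothing else.
* **FVA** — per reaction, minimize and maximize its flux subject to the
  objective ≥ fraction × optimum. The fraction defaults to 1.0 (ranges at
  the optimum) and is configurable.

The LP solver is HiGHS via `scipy.optimize.linprog`, behind a one-method
backend contract (`solve(c, A_eq, b_eq, bounds)`) so solvers are
swappable. Solver feasibility tolerances are HiGHS defaults (~1e-9);
assertions in tests use 1e-6 on objectives and 1e-5 on FVA endpoints;
fluxes below 1e-6 are reported as zero. All bounds are finite (the
"unbounded" magnitude is the COBRA-conventional 1000), so no LP is
unbounded by construction.

## Curation QC

* **Mass/charge balance** — Σ(coefficient × element count) and
  Σ(coefficient × charge) per reaction. Boundary, biomass, macromolecule
  synthesis and maintenance pseudo-reactions are exempt by kind; a missing
  formula makes a reaction *unauditable*, never silently balanced.
* **Duplicate metabolites** — same compartment, formula and charge, and
  names equal after normalization (case-fold, whitespace removal, and
  stripping of leading stereo-descriptor prefixes such as `S-`, `(S)-`,
  `S,S-`). The rule is deliberately explicit: it flags candidates for
  merging, it does not prove identity.
* **Duplicate reactions** — identical stoichiometry after rounding
  coefficients to 1e-9 (so float noise cannot defeat detection) and
  canonicalizing overall direction.
* **Dead ends** — metabolites only produced or only consumed, counting a
  reversible reaction as both producer and consumer and ignoring blocked
  reactions. Metabolites touching no active reaction are not flagged.
* **Loops** — all boundary reactions are closed to (0, 0), forced-positive
  internal lower bounds (e.g. the maintenance floor) are relaxed to
  include zero, and a pure-feasibility FVA is run; any internal reaction
  whose range escapes ±1e-6 participates in a thermodynamically infeasible
  internal cycle. The relaxation is required: a forced throughput would
  make the closed system infeasible and mask every loop. By construction
  the result is invariant to the medium.
* **Gene-set comparison** — region counts over the full inclusion/exclusion
  lattice of the models' GPR-derived gene sets, after an optional
  old-id → new-id mapping under which unmapped ids are dropped and counted.

Model editing is transactional: curation steps are `Edit` records
(set_bounds, add/remove/block reaction, merge metabolites, add
exchange/demand, set objective/biomass) in an ordered ledger, serialized as
a flat TSV with a free-text rationale and optional citation per record.
Replaying a ledger either applies every edit in order or leaves the input
model untouched, and reports before/after state per edit.

## The synthetic core network

`build_core_model` generates a ~68-reaction, fully mass- and
charge-balanced network that emulates an obligately heterofermentative
LAB: glucose uptake by both proton symport and PEP-dependent
phosphotransferase; the classical NADP-linked oxidative PPP and/or the
NAD-linked D-gluconate shunt into 6-phosphogluconate; NADP-linked
6-phosphogluconate dehydrogenase (CO₂ release); phosphoketolase; lower
glycolysis lumped into one reaction with exact net ATP/NADH stoichiometry
(the claims exercised here depend only on net carrier stoichiometry, not
per-step fidelity); lactate dehydrogenase; the acetate-kinase and
ethanol branches; the ADI arginine pathway with a strict 1:1
arginine/ornithine antiport; malolactic decarboxylation; the
acetolactate → acetoin → 2,3-butanediol branch; the Leloir pathway (with
lactose entering by extracellular hydrolysis into glucose + galactose, a
deliberate design choice over a PTS/phospho-β-galactosidase route); a
water-forming NAD(P)H oxidase; an optional diagnostic transhydrogenase
(NADTRHD); and ATP maintenance (NGAM) with configurable floor
(0 / 0.36 / 0.51 mmol·gDCW⁻¹·h⁻¹; default 0.51, a conventional
experimentally grounded LAB value).

Two stoichiometric policies are the scientific levers:

* **Ethanol-branch cofactor policy.** `mixed_NADH_NADPH` (default) makes
  the acetaldehyde → ethanol step NADPH-linked while acetyl-CoA →
  acetaldehyde stays NADH-linked; fermentation then demands exactly
  2 NADH + 1 NADPH per glucose, which the shunt supplies exactly and the
  classical route cannot. This one NADPH-accepting reduction is a declared
  modeling assumption: it is the stoichiometric mechanism implied by the
  flux behavior of heterofermenters, written out as chemistry.
  `strict_NADH` makes both reductions NADH-linked; the NADPH forced out of
  6-phosphogluconate dehydrogenase then has no catabolic sink at all, and
  glucose catabolism is throttled to the biosynthetic NADPH demand — the
  redox dead-lock regime in which the shunt (or a transhydrogenase) is
  decisive.
* **NAD(P)H oxidase promiscuity.** `include_nox` emits the NADH oxidase
  (nadh + ½ O₂ → nad + h₂o) together with an NADPH-accepting twin of the
  same enzyme. Without the NADPH activity, the NADPH forced out of the 6PG
  dehydrogenase would cap the aerobic ATP yield at the anaerobic value;
  with it, the full acetate switch reaches 2 ATP per glucose. Cofactor
  promiscuity of LAB Nox-type oxidases is the package's stated assumption
  here.

The biomass equation is grouped: an ATP-hydrolysis quartet (ATP + H₂O →
ADP + Pᵢ + H⁺, matched coefficients, default 18.5 mmol·gDCW⁻¹), wall
polymers (peptidoglycan 0.12, teichoic acid 0.08, both drawn from G6P),
and protein/DNA/RNA made by separate synthesis pseudo-reactions from
pyruvate, ammonium and NADPH (total biosynthetic NADPH ≈ 16
mmol·gDCW⁻¹, within the conventional bacterial range). ATP costs are
deliberately excluded from the synthesis reactions and consolidated in the
biomass equation. All coefficients are synthetic stand-ins calibrated to
generic LAB physiology, not measurements; a loader accepts user-supplied
specs. Swap variants A and B change only the ATP quartet, protein, DNA and
RNA coefficients and the three synthesis reactions, never the wall group.

The generator is fully deterministic; the only randomness is an optional
multiplicative jitter of the ±1000 default bounds behind a fixed seed
(default 42), used for robustness testing.

### What the generator does and does not emulate

It reproduces the *stoichiometric* logic of heterofermentative LAB — the
phosphoketolase split, the cofactor bookkeeping of the two glucose
oxidation routes, the ADI energetics, the aerobic acetate shift — on a
network small enough that every claim can be checked by hand. It does not
reproduce genome-scale detail: no amino-acid biosynthesis beyond lumped
precursor drains, no lipids, no vitamin/cofactor biosynthesis, no membrane
energetics (protons cross by a free leak reaction, so transport is not
energy-coupled), and biomass composition is not measured. Consequently the
absolute growth rates (≈1.8 h⁻¹ on glucose at uptake 25) and the
absolute cofactor turnover totals are not calibrated to any organism;
tests therefore assert mechanisms, ratios, orderings and exact
stoichiometric yields (1 ATP/glucose anaerobic, 2 aerobic, 1 ATP/arginine,
1:1:1 products), never absolute growth values. Headline numbers that
depend on a full genome-scale reconstruction (specific growth rates,
absolute shunt flux, genome-wide QC tallies) require such a model as an
external input and are out of scope for the built-in network.

A deliberately broken twin of the core (three mass-unbalanced reactions,
one charge-unbalanced, one duplicate-metabolite pair with its shadow
reaction, one literal duplicate reaction, one dead end, one reversible
3-cycle) ships together with the repair ledger that fixes all of it, and a
minimal loop fixture isolates the closed-boundary loop test.

## Protocols

* **Medium application** sets each listed exchange's lower bound to −cap
  and closes uptake on all others (secretion stays open); sweeps then move
  only the swept exchange's lower bound. The built-in CDM supplies the
  carbon source at 25 (glucose default), arginine at 0.2 — the amino acid
  the core models, standing in for the general amino-acid allowance —
  plus ammonium, phosphate, water and protons; oxygen only when requested.
* **Sweeps** record FBA growth, the pFBA point and the FVA envelope of the
  four fermentation products per grid point; infeasible points (e.g. zero
  carbon with a positive maintenance floor) are recorded as data. Default
  grids: substrate 0..25 step 1 (lactose 0..13), oxygen 0..10 at glucose
  10. An option opens a membrane ATPase toward ATP generation for models
  that have one; the core does not.
* **Cofactor turnover** sums the production-side flux of NADH and NADPH
  (coefficient × flux where positive under the actual direction). "Total
  cofactor flux" has no unique definition; this one is isolated in a
  single function so it can be swapped.
* **Shunt comparison** runs pFBA on four bound-toggled variants (baseline,
  +NADTRHD, +shunt, both) and reports growth, products, cofactor turnover
  and the shunt fraction flux(GDH)/glucose uptake.
* **Biomass sensitivity** scales each group's coefficients jointly by 0.5
  and 1.5 (the ATP quartet and the wall pair always as units, preserving
  their internal balance), re-runs FBA and reports percent change
  100 × (μ − μ₀)/μ₀; factor 1.0 short-circuits to the baseline so the
  identity row is exact; the input model is never mutated.
* **NGAM sensitivity** re-runs FBA at maintenance floors 0 / 0.36 / 0.51.
* **Biomass swap** replaces the energy and macromolecule terms and the
  three synthesis reactions with another spec's, leaving wall coefficients
  untouched; swapping back restores the original model exactly.

## Numerical choices and degenerate inputs

Stoichiometry comparisons round to 1e-9; balance audits ignore residuals
below 1e-8. pFBA falls back to the FBA solution if the second stage is
numerically infeasible inside the fixing window. Empty models produce
empty QC reports; empty ledgers are identities; merging a metabolite into
itself is a no-op; FVA rejects fractions outside (0, 1]. SBML output is
Level 3 Version 1 + fbc v2 with shared bound parameters and fully sorted
element order, so regeneration is byte-identical and diffs are meaningful;
Level 2 COBRA-notes dialects are auto-detected on read, with missing
bounds defaulted from the reversibility flag under a logged warning.

## Known limitations

No MILP (hence no loopless FVA), no flux sampling, no kinetic or dynamic
extensions, no quadratic objectives. The loop test is the closed-boundary
feasibility check only, not a full loop-analysis battery. QC covers the
audits listed above, not standardized model scoring or annotation-coverage
metrics. Gene-id mapping assumes a flat old→new table. The tabular format
is a fixture dialect, not an interchange standard.
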