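# heterogem

Constraint-based modeling toolkit for **obligately heterofermentative lactic
acid bacteria** (LAB): the solver primitives (FBA, parsimonious FBA, FVA),
genome-scale-model curation QC, a deterministic synthetic core network with
the NADH-regenerating **D-gluconate glucose shunt**, and the simulation
protocols built on top of them — exchange-profile sweeps, NADH/NADPH
turnover accounting, grouped biomass-equation sensitivity analysis, and
biomass-equation swapping.

It is aimed at systems biologists curating and interrogating LAB
genome-scale models who want the redox mechanics of heterofermentative
metabolism exercisable on a small, fully balanced network, with every
curation step recorded as a replayable edit ledger.

## The science in brief

A metabolic network with stoichiometric matrix **S** is analyzed at steady
state, **S·v = 0**, with box bounds *lb ≤ v ≤ ub* on every flux
(mmol·gDCW⁻¹·h⁻¹). FBA maximizes an objective flux (usually the biomass
pseudo-reaction, whose flux is the growth rate μ in h⁻¹); pFBA then
minimizes Σ|v| at the fixed optimum; FVA reports per-reaction flux ranges
at ≥ a fraction of the optimum.

Obligate heterofermenters lack phosphofructokinase and aldolase, so hexoses
are fermented through the **phosphoketolase pathway**: glucose 6-phosphate
is oxidized to ribulose 5-phosphate (releasing CO₂), and xylulose
5-phosphate is cleaved to glyceraldehyde 3-phosphate (→ lactate) and
acetyl-phosphate (→ ethanol or acetate). The two oxidations of the
classical route are NADP-linked, yielding **2 NADPH + 1 NADH** per glucose,
while anaerobic fermentation to lactate + ethanol demands **2 NADH +
1 NADPH** — a structural redox mismatch. The core network implements the
alternative first oxidation via the D-gluconate shunt,

```
glucose --(NAD+, glucose 1-dehydrogenase)--> D-glucono-1,5-lactone
        --(gluconolactonase, GL15LH)-------> D-gluconate
        --(gluconate kinase, ATP)----------> 6-phospho-D-gluconate
```

which swaps the first NADPH for NADH and closes the anaerobic redox balance
exactly, producing the canonical 1:1:1 lactate:ethanol:CO₂ profile with a
net yield of 1 ATP per glucose. The arginine deiminase (ADI) pathway
(arginine/ornithine antiport → deiminase → ornithine transcarbamylase →
carbamate kinase) contributes exactly 1 ATP per arginine. Under oxygen, the
water-forming NAD(P)H oxidase reroutes acetyl-phosphate from ethanol to the
ATP-yielding acetate kinase branch — the classic aerobic ethanol→acetate
shift.

## Worked example

```python
import heterogem as hg
from heterogem import CoreConfig

model = hg.build_core_model()
print(hg.model_stats(model))
cdm = hg.cdm_medium()           # glucose 25, arginine 0.2, anaerobic
m = hg.apply_medium(model, cdm)
sol = hg.pfba(m)
print(f"growth rate: {sol.objective_value:.3f} 1/h")
for exch in ("EX_glc__D_e", "EX_lac__L_e", "EX_etoh_e", "EX_ac_e", "EX_co2_e"):
    print(f"{exch:13s} {sol.fluxes[exch]:8.3f}")
```

prints

```
{'genes': 40, 'reactions': 68, 'reactions_without_gpr': 30, 'metabolites': 64}
growth rate: 1.792 1/h
EX_glc__D_e    -25.000
EX_lac__L_e     15.952
EX_etoh_e       14.608
EX_ac_e          9.747
EX_co2_e        24.555
```

i.e. on the chemically defined medium the core ferments all 25 units of
glucose with lactate produced in excess of ethanol. The decisive role of
the shunt shows up under the strict-NADH cofactor policy:

```python
cfg = CoreConfig(include_nadtrhd=True, ngam_lb=0.0, ethanol_branch="strict_NADH")
strict = hg.apply_medium(hg.build_core_model(cfg), cdm, inplace=True)
print(hg.shunt_comparison(strict)[["variant", "growth", "shunt_fraction"]])
```

```
 variant   growth  shunt_fraction
baseline 0.035492        0.000000
 nadtrhd 1.828737       -0.000000
   shunt 1.828737        0.808395
    both 1.828737        0.026334
```

With neither the shunt nor a transhydrogenase the redox balance cannot
close and growth collapses to the trickle supported by the ADI pathway;
opening the shunt (which then carries ~81% of the glucose) or the
diagnostic transhydrogenase restores it.

A CLI mirrors the library (`heterogem generate-core`, `qc`, `venn`, `fba`,
`pfba`, `fva`, `sweep`, `oxygen-sweep`, `sensitivity`, `ngam`, `shunt`,
`biomass-swap`, `apply-ledger`, `run`); `heterogem run --config run.yaml`
writes a manifest next to its outputs so runs are self-describing.

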