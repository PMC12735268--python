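"""Grouped biomass equations for the core network.

The biomass pseudo-reaction drains macromolecules (protein, DNA, RNA),
wall polymers (peptidoglycan, teichoic acid) and growth-associated ATP in
fixed stoichiometry per gram of cells; its flux is the growth rate μ (h⁻¹).
Components are organized in groups that scale jointly during sensitivity
analysis: the ATP-hydrolysis quartet (ATP + H₂O → ADP + Pᵢ + H⁺, with
matched coefficients so the group stays internally mass-balanced), the
wall group, and one group per macromolecule.

Macromolecule synthesis is decoupled from the biomass equation into
separate pseudo-reactions (protein/DNA/RNA built from central-carbon
precursors, ammonium and NADPH). ATP costs are deliberately *not* placed in
these synthesis reactions; all ATP demand is consolidated in the biomass
equation itself.

The default coefficient set is a synthetic stand-in calibrated to generic
LAB physiology (growth-associated ATP ≈ 18.5 mmol·gDCW⁻¹, biosynthetic
NADPH ≈ 16 mmol·gDCW⁻¹), not a measured composition; a loader exists for
user-supplied specs. Swap variants A and B emulate adopting a published
biomass equation from another LAB model: they differ from the default only
in the ATP-hydrolysis quartet, protein, DNA and RNA coefficients and in the
three macromolecule synthesis reactions, never in the wall group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["BiomassComponent", "BiomassSpec", "make_biomass_spec"]

BIOMASS_GROUPS = ("atp_hydrolysis", "wall", "protein", "dna", "rna", "water", "other")

#: The ATP-hydrolysis quartet-plus-proton: members and their sides.
ATP_GROUP_SIDES = {
    "atp_c": "consumed",
    "h2o_c": "consumed",
    "adp_c": "produced",
    "pi_c": "produced",
    "h_c": "produced",
}


@dataclass
class BiomassComponent:
    metabolite: str
    coefficient: float  # positive by convention; `side` carries the sign
    side: str  # consumed | produced
    group: str

    def __post_init__(self):
        if self.coefficient <= 0:
            raise ValueError(
                f"biomass coefficient for {self.metabolite} must be positive"
            )
        if self.side not in ("consumed", "produced"):
            raise ValueError(f"bad side {self.side!r}")
        if self.group not in BIOMASS_GROUPS:
            raise ValueError(f"bad group {self.group!r}")


@dataclass
class BiomassSpec:
    """A grouped biomass equation plus macromolecule synthesis definitions.

    ``synthesis`` maps macromolecule name (protein/dna/rna) to a signed
    stoichiometry map for its synthesis pseudo-reaction (the macromolecule
    itself appears with +1).
    """

    name: str
    components: list[BiomassComponent] = field(default_factory=list)
    synthesis: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        atp = {
            c.metabolite: c
            for c in self.components
            if c.group == "atp_hydrolysis"
        }
        if set(atp) != set(ATP_GROUP_SIDES):
            raise ValueError(
                "atp_hydrolysis group must contain exactly "
                f"{sorted(ATP_GROUP_SIDES)}, got {sorted(atp)}"
            )
        coeffs = {c.coefficient for c in atp.values()}
        if len(coeffs) != 1:
            raise ValueError("atp_hydrolysis coefficients must match")
        for met, comp in atp.items():
            if comp.side != ATP_GROUP_SIDES[met]:
                raise ValueError(f"{met} on wrong side of the ATP-hydrolysis group")
        seen = set()
        for c in self.components:
            if c.metabolite in seen:
                raise ValueError(f"{c.metabolite} appears twice in the biomass")
            seen.add(c.metabolite)

    def stoichiometry(self) -> dict[str, float]:
        """Signed biomass-reaction stoichiometry (consumed negative)."""
        return {
            c.metabolite: (-c.coefficient if c.side == "consumed" else c.coefficient)
            for c in self.components
        }

    def groups(self) -> dict[str, list[BiomassComponent]]:
        out: dict[str, list[BiomassComponent]] = {}
        for c in self.components:
            out.setdefault(c.group, []).append(c)
        return out

    def atp_coefficient(self) -> float:
        for c in self.components:
            if c.group == "atp_hydrolysis" and c.metabolite == "atp_c":
                return c.coefficient
        raise ValueError("no ATP-hydrolysis group")

    def copy(self) -> "BiomassSpec":
        return BiomassSpec(
            name=self.name,
            components=[BiomassComponent(**vars(c)) for c in self.components],
            synthesis={k: dict(v) for k, v in self.synthesis.items()},
        )


def _grouped(atp, protein, dna, rna, ptg=0.12, tca=0.08):
    comps = [
        BiomassComponent(m, atp, ATP_GROUP_SIDES[m], "atp_hydrolysis")
        for m in ATP_GROUP_SIDES
    ]
    comps += [
        BiomassComponent("protein_c", protein, "consumed", "protein"),
        BiomassComponent("dna_c", dna, "consumed", "dna"),
        BiomassComponent("rna_c", rna, "consumed", "rna"),
        BiomassComponent("ptg_c", ptg, "consumed", "wall"),
        BiomassComponent("tca_c", tca, "consumed", "wall"),
    ]
    return comps


def _synthesis(protein_pyr, protein_nadph, nuc_pyr, nuc_nadph):
    return {
        "protein": {
            "pyr_c": -protein_pyr,
            "nh4_c": -protein_pyr,
            "nadph_c": -protein_nadph,
            "nadp_c": protein_nadph,
            "protein_c": 1.0,
        },
        "dna": {
            "pyr_c": -nuc_pyr,
            "nh4_c": -1.0,
            "nadph_c": -nuc_nadph,
            "nadp_c": nuc_nadph,
            "dna_c": 1.0,
        },
        "rna": {
            "pyr_c": -nuc_pyr,
            "nh4_c": -1.0,
            "nadph_c": -nuc_nadph,
            "nadp_c": nuc_nadph,
            "rna_c": 1.0,
        },
    }


def make_biomass_spec(source: str = "default") -> BiomassSpec:
    """Built-in biomass coefficient sets.

    ``default`` is the core network's own equation; ``swap_variant_A`` and
    ``swap_variant_B`` differ only in the ATP-hydrolysis quartet, protein,
    DNA and RNA coefficients and the macromolecule synthesis reactions
    (wall stoichiometry is left unchanged), emulating the adoption of a
    published LAB biomass equation.
    """
    if source == "default":
        spec = BiomassSpec(
            name="default",
            components=_grouped(atp=18.5, protein=0.55, dna=0.025, rna=0.06),
            synthesis=_synthesis(8.0, 28.0, 2.0, 2.0),
        )
    elif source == "swap_variant_A":
        spec = BiomassSpec(
            name="swap_variant_A",
            components=_grouped(atp=22.0, protein=0.50, dna=0.03, rna=0.08),
            synthesis=_synthesis(8.2, 26.0, 2.1, 2.2),
        )
    elif source == "swap_variant_B":
        spec = BiomassSpec(
            name="swap_variant_B",
            components=_grouped(atp=15.0, protein=0.60, dna=0.02, rna=0.05),
            synthesis=_synthesis(7.5, 25.0, 1.9, 1.8),
        )
    else:
        raise ValueError(f"unknown biomass source {source!r}")
    spec.validate()
    return spec
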