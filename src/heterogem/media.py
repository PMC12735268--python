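"""Built-in medium definitions.

The chemically defined medium (CDM) used throughout supplies the carbon
source at 25 mmol·gDCW⁻¹·h⁻¹ (glucose by default) and amino acids at
0.2 mmol·gDCW⁻¹·h⁻¹ — arginine being the amino acid the core network
models — plus ammonium, phosphate, and freely exchanged water and protons.
Oxygen is excluded (anaerobic) unless an uptake cap is given.
"""

from __future__ import annotations

from .io import MediumSpec

__all__ = ["cdm_medium", "arginine_only_medium"]

_CARBON_EXCHANGE = {
    "glucose": "EX_glc__D_e",
    "galactose": "EX_gal_e",
    "lactose": "EX_lcts_e",
}

_BASE = {
    "EX_nh4_e": 10.0,
    "EX_pi_e": 10.0,
    "EX_h2o_e": 1000.0,
    "EX_h_e": 1000.0,
}


def cdm_medium(
    carbon: str = "glucose",
    carbon_uptake: float = 25.0,
    amino_acid_uptake: float = 0.2,
    oxygen_uptake: float = 0.0,
) -> MediumSpec:
    """The CDM with a configurable carbon source and oxygen cap."""
    uptake = dict(_BASE)
    uptake[_CARBON_EXCHANGE[carbon]] = carbon_uptake
    uptake["EX_arg__L_e"] = amino_acid_uptake
    if oxygen_uptake > 0:
        uptake["EX_o2_e"] = oxygen_uptake
    return MediumSpec(uptake=uptake)


def arginine_only_medium(arginine_uptake: float = 0.2) -> MediumSpec:
    """Arginine as the sole energy source (all carbon uptakes closed)."""
    uptake = dict(_BASE)
    uptake["EX_arg__L_e"] = arginine_uptake
    return MediumSpec(uptake=uptake)
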