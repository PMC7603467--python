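"""Tissue:plasma partition coefficients from composition, pH and binding.

The scheme is a simplified composition-based model in the spirit of the
standard mechanistic partition models: the affinity of a compound for a
compartment is additive in its water, lipid and protein-binding content,

    a = f_water / fn(pH) + 10**logP * f_lipid + B,

where ``fn`` is the Henderson–Hasselbalch neutral fraction (ionized drug
is confined to the aqueous phase, so a low neutral fraction inflates the
apparent aqueous affinity) and ``B`` is a protein-binding term.  The
plasma binding term is back-calibrated from the measured unbound plasma
fraction ``fu`` and propagated to tissues in proportion to their protein
content.  Partition coefficients are affinity ratios against plasma.
"""

from __future__ import annotations

from dataclasses import dataclass

from .compound import Compound, IonizationSpec, neutral_fraction
from .errors import InvalidPhysiologyError
from .physiology import Composition, SpeciesPhysiology

__all__ = ["compartment_affinity", "OrganPartition", "partition_coefficients"]


def compartment_affinity(
    comp: Composition, pH: float, compound: Compound, binding_term: float = 0.0
) -> float:
    """Relative affinity of ``compound`` for a compartment.

    ``binding_term`` is the compartment's protein-binding contribution
    (dimensionless, >= 0).  The result is strictly positive because the
    water fraction is strictly positive and ``fn`` is in (0, 1].
    """
    if binding_term < 0:
        raise InvalidPhysiologyError("binding_term must be non-negative")
    fn = neutral_fraction(compound.ionization, pH)
    a = comp.f_water / fn + 10.0**compound.logP * comp.f_lipid + binding_term
    if not a > 0:
        raise InvalidPhysiologyError("non-positive compartment affinity")
    return a


@dataclass(frozen=True)
class OrganPartition:
    """Partition coefficients of one organ against plasma."""

    Kp_total: float  # total tissue : plasma
    K_cell: float  # cellular sub-compartment : plasma
    K_int: float  # interstitial : plasma
    BP: float  # whole blood : plasma (shared by all organs)


def plasma_binding_term(species: SpeciesPhysiology, compound: Compound) -> float:
    """Plasma protein-binding term calibrated from the unbound fraction.

    Solves fu = (f_w/fn) / (f_w/fn + 10**logP * f_l + B_p) for B_p and
    clamps at zero (a very lipophilic, weakly bound compound can push the
    calibration negative; zero then means the lipid term alone already
    exceeds the binding implied by fu).
    """
    fu = compound.fraction_unbound_plasma
    pc = species.plasma_composition
    fn_p = neutral_fraction(compound.ionization, species.plasma_pH)
    aqueous = pc.f_water / fn_p
    b_p = aqueous * (1.0 / fu - 1.0) - 10.0**compound.logP * pc.f_lipid
    return max(b_p, 0.0)


def partition_coefficients(
    species: SpeciesPhysiology, compound: Compound
) -> dict[str, OrganPartition]:
    """Per-organ partition coefficients and the blood:plasma ratio."""
    pc = species.plasma_composition
    b_p = plasma_binding_term(species, compound)
    a_plasma = compartment_affinity(pc, species.plasma_pH, compound, b_p)

    def tissue_binding(comp: Composition) -> float:
        if pc.f_protein == 0:
            return 0.0
        return b_p * comp.f_protein / pc.f_protein

    a_int = compartment_affinity(
        species.interstitial_composition,
        species.plasma_pH,
        compound,
        tissue_binding(species.interstitial_composition),
    )
    a_rbc = compartment_affinity(
        species.rbc_composition,
        species.rbc_pH,
        compound,
        tissue_binding(species.rbc_composition),
    )
    k_int = a_int / a_plasma
    k_ery = a_rbc / a_plasma
    bp_ratio = (1.0 - species.haematocrit) + species.haematocrit * k_ery

    out: dict[str, OrganPartition] = {}
    for name, organ in species.organs.items():
        a_cell = compartment_affinity(
            organ.cellular_composition,
            organ.intracellular_pH,
            compound,
            tissue_binding(organ.cellular_composition),
        )
        k_cell = a_cell / a_plasma
        fv = organ.fraction_vascular
        fi = organ.fraction_interstitial
        kp = fv * bp_ratio + fi * k_int + (1.0 - fv - fi) * k_cell
        out[name] = OrganPartition(Kp_total=kp, K_cell=k_cell, K_int=k_int, BP=bp_ratio)
    return out
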