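"""Assembly of a whole-body PBTK model from species, compound and protocol.

The model couples a perfusion-limited organ network (lung in series
between the venous and arterial pools; spleen, stomach wall and the
intestinal walls draining through a portal node into the liver) with an
eight-segment gastrointestinal lumen chain for oral absorption and three
elimination sinks (metabolized, urine, faeces).  All derived quantities —
absolute dose, organ flows, cardiac output, partition coefficients,
luminal geometry and effective transit rates — are recomputed from
scratch whenever the model is rebuilt, so a parameter perturbation can
never see a stale cache.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .compound import Compound, neutral_fraction
from .errors import ModelConstructionError
from .partition import OrganPartition, partition_coefficients
from .physiology import (
    GIT_SEGMENT_ORDER,
    LARGE_INTESTINE_SEGMENTS,
    MANDATORY_ORGANS,
    PORTAL_DRAINING_ORGANS,
    SMALL_INTESTINE_SEGMENTS,
    AdministrationProtocol,
    SpeciesPhysiology,
    parameter_paths,
    perturb_parameter,
)

__all__ = ["PBTKModel", "build_model", "initialize_transit_rates", "DOSE_PARAMETER_PATH"]

#: Pseudo-path accepted by the sensitivity engine for the dose itself.
DOSE_PARAMETER_PATH = "Application|Dose"

_REGIONS: dict[str, tuple[tuple[str, ...], str]] = {
    "stomach": (("stomach",), "gastric_emptying_time"),
    "small": (SMALL_INTESTINE_SEGMENTS, "small_intestinal_transit_time"),
    "large": (LARGE_INTESTINE_SEGMENTS, "large_intestinal_transit_time"),
}


def _region_of(segment: str) -> str:
    for region, (members, _) in _REGIONS.items():
        if segment in members:
            return region
    raise ModelConstructionError(f"segment {segment!r} belongs to no region")


def initialize_transit_rates(species: SpeciesPhysiology) -> None:
    """Fill in unset (zero) per-segment transit rates from the regional
    transit times, splitting a region's residence time across its segments
    in proportion to segment length."""
    for region, (members, attr) in _REGIONS.items():
        present = [seg for seg in species.lumen if seg.name in members]
        if not present:
            continue
        region_time = getattr(species, attr)
        total_length = sum(seg.length for seg in present)
        for seg in present:
            if seg.transit_rate == 0.0:
                residence = region_time * seg.length / total_length
                seg.transit_rate = 1.0 / residence


@dataclass(frozen=True)
class LumenSegmentDerived:
    """Run-time quantities of one lumen segment."""

    name: str
    fluid_volume: float  # L
    surface_area: float  # cm^2 (SEF-enhanced)
    absorption_coefficient: float  # L/min, already includes the neutral fraction
    effective_transit_rate: float  # 1/min
    absorbs: bool


@dataclass
class PBTKModel:
    """An assembled whole-body PBTK model (species + compound + protocol)."""

    species: SpeciesPhysiology
    compound: Compound
    protocol: AdministrationProtocol
    model_id: str = ""

    # derived, populated by rebuild()
    dose_umol: float = field(init=False, default=0.0)
    fu: float = field(init=False, default=1.0)
    blood_plasma_ratio: float = field(init=False, default=1.0)
    partitions: dict[str, OrganPartition] = field(init=False, default_factory=dict)
    organ_flows: dict[str, float] = field(init=False, default_factory=dict)
    cardiac_output: float = field(init=False, default=0.0)
    portal_flow: float = field(init=False, default=0.0)
    lumen_derived: list[LumenSegmentDerived] = field(init=False, default_factory=list)
    parameter_paths: list[str] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self.model_id:
            self.model_id = (
                f"{self.species.name}:{self.compound.name}:{self.protocol.route}"
            )
        self.rebuild()

    # ------------------------------------------------------------------
    def rebuild(self) -> None:
        """Recompute every derived quantity from the current inputs."""
        sp, cmp_, proto = self.species, self.compound, self.protocol
        for organ in MANDATORY_ORGANS:
            if organ not in sp.organs:
                raise ModelConstructionError(f"species lacks mandatory organ {organ!r}")
        if proto.route == "oral" and not sp.lumen:
            raise ModelConstructionError("oral dosing requires a non-empty lumen")

        dose_mg = proto.dose_per_kg * sp.body_weight
        self.dose_umol = dose_mg / cmp_.molecular_weight * 1000.0

        self.partitions = partition_coefficients(sp, cmp_)
        self.blood_plasma_ratio = next(iter(self.partitions.values())).BP
        self.fu = cmp_.fraction_unbound_plasma

        self.organ_flows = {
            name: organ.specific_blood_flow * organ.volume
            for name, organ in sp.organs.items()
        }
        # lung sits in series and carries the full cardiac output
        self.cardiac_output = sum(
            q for name, q in self.organ_flows.items() if name != "lung"
        )
        if self.cardiac_output <= 0:
            raise ModelConstructionError("cardiac output must be positive")
        self.portal_flow = sum(
            self.organ_flows[name]
            for name in PORTAL_DRAINING_ORGANS
            if name in sp.organs
        )

        self.lumen_derived = self._derive_lumen()
        self.parameter_paths = parameter_paths(sp)

    def _derive_lumen(self) -> list[LumenSegmentDerived]:
        sp, cmp_ = self.species, self.compound
        # regional renormalization: the effective rate responds both to the
        # per-segment transit rate and to the regional transit time
        region_tau = {
            region: sum(
                1.0 / seg.transit_rate
                for seg in sp.lumen
                if seg.name in members and seg.transit_rate > 0
            )
            for region, (members, _) in _REGIONS.items()
        }
        out: list[LumenSegmentDerived] = []
        for seg in sp.lumen:
            region = _region_of(seg.name)
            region_time = getattr(sp, _REGIONS[region][1])
            if seg.transit_rate > 0 and region_tau[region] > 0:
                k_eff = seg.transit_rate * region_tau[region] / region_time
            else:
                k_eff = 0.0
            r = seg.mean_radius
            fluid_volume = math.pi * r * r * seg.length * seg.fill_fraction / 1000.0
            surface = 2.0 * math.pi * r * seg.length * seg.surface_enhancement_factor
            absorbs = seg.name != "stomach"
            if absorbs:
                fn = neutral_fraction(cmp_.ionization, seg.pH)
                # cm/min * cm^2 -> cm^3/min -> L/min
                ka = cmp_.effective_permeability * surface * fn / 1000.0
            else:
                ka = 0.0
            out.append(
                LumenSegmentDerived(
                    name=seg.name,
                    fluid_volume=fluid_volume,
                    surface_area=surface,
                    absorption_coefficient=ka,
                    effective_transit_rate=k_eff,
                    absorbs=absorbs,
                )
            )
        return out

    # ------------------------------------------------------------------
    def perturbed(self, path: str, factor: float) -> "PBTKModel":
        """A new model with one physiological leaf multiplied by ``factor``.

        Dependent parameters are deliberately not renormalized; every
        derived quantity is rebuilt from the perturbed physiology.
        """
        clone = perturb_parameter(self.species, path, factor)
        return PBTKModel(
            species=clone,
            compound=self.compound,
            protocol=self.protocol,
            model_id=self.model_id,
        )

    def with_dose_factor(self, factor: float) -> "PBTKModel":
        """A new model with the relative dose multiplied by ``factor``."""
        proto = AdministrationProtocol(
            route=self.protocol.route,
            dose_per_kg=self.protocol.dose_per_kg * factor,
            start_time=self.protocol.start_time,
        )
        return PBTKModel(
            species=self.species,
            compound=self.compound,
            protocol=proto,
            model_id=self.model_id,
        )

    @property
    def is_linear(self) -> bool:
        """True when the solubility cap can never engage, making the ODE
        system linear in dose.

        Intravenous dosing never populates the lumen; otherwise the cap is
        inactive whenever the whole dose dissolved in the smallest
        absorbing segment would still sit below the solubility limit.
        """
        if self.protocol.route == "iv_bolus":
            return True
        if math.isinf(self.compound.solubility):
            return True
        vols = [d.fluid_volume for d in self.lumen_derived if d.absorbs]
        if not vols:
            return True
        return self.dose_umol / min(vols) <= self.compound.solubility


def build_model(
    species: SpeciesPhysiology,
    compound: Compound,
    protocol: AdministrationProtocol,
    validate: bool = True,
) -> PBTKModel:
    """Assemble and validate a PBTK model.

    The species invariants (mandatory organs, volume closure within 2%)
    are checked unless ``validate`` is False; unset segment transit rates
    are initialized from the regional transit times.
    """
    if validate:
        species.validate()
    initialize_transit_rates(species)
    return PBTKModel(species=species, compound=compound, protocol=protocol)
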