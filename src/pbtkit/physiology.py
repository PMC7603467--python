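"""Species physiology: the substance-independent half of a PBTK model.

A :class:`SpeciesPhysiology` holds everything that characterises the
organism — organs with volumes, perfusion rates and tissue compositions,
the blood pools, the gastrointestinal lumen geometry and transit times,
and clearance physiology (specific GFR).  Every numeric leaf is
addressable through a pipe-delimited parameter path in the conventional
style, e.g. ``"Organism|Lumen|UpperIleum|pH"`` or
``"Organism|Kidney|GFR (specific)"``; the path registry built here is
what the sensitivity engine perturbs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Iterator

from .errors import InvalidPhysiologyError, ObservationError, SchemaError

__all__ = [
    "Composition",
    "OrganSpec",
    "GITSegmentSpec",
    "SpeciesPhysiology",
    "AdministrationProtocol",
    "ObservationSite",
    "MANDATORY_ORGANS",
    "GIT_SEGMENT_ORDER",
    "SMALL_INTESTINE_SEGMENTS",
    "LARGE_INTESTINE_SEGMENTS",
    "parameter_paths",
    "get_parameter",
    "set_parameter",
    "perturb_parameter",
]

MANDATORY_ORGANS = (
    "lung",
    "liver",
    "kidney",
    "muscle",
    "skin",
    "adipose",
    "brain",
    "heart",
    "gonads",
    "bone",
    "spleen",
    "stomach_wall",
    "small_intestine_wall",
    "large_intestine_wall",
    "rest",
)

#: Fixed anatomical order of the gut lumen segments.
GIT_SEGMENT_ORDER = (
    "stomach",
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
    "caecum",
    "colon",
)

SMALL_INTESTINE_SEGMENTS = (
    "duodenum",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
)
LARGE_INTESTINE_SEGMENTS = ("caecum", "colon")

#: Organs whose venous outflow drains into the portal vein.
PORTAL_DRAINING_ORGANS = (
    "spleen",
    "stomach_wall",
    "small_intestine_wall",
    "large_intestine_wall",
)

_ORGAN_PATH_NAMES = {
    "lung": "Lung",
    "liver": "Liver",
    "kidney": "Kidney",
    "muscle": "Muscle",
    "skin": "Skin",
    "adipose": "Adipose",
    "brain": "Brain",
    "heart": "Heart",
    "gonads": "Gonads",
    "bone": "Bone",
    "spleen": "Spleen",
    "stomach_wall": "Stomach",
    "small_intestine_wall": "SmallIntestine",
    "large_intestine_wall": "LargeIntestine",
    "rest": "Rest",
}

_SEGMENT_PATH_NAMES = {
    "stomach": "Stomach",
    "duodenum": "Duodenum",
    "upper_jejunum": "UpperJejunum",
    "lower_jejunum": "LowerJejunum",
    "upper_ileum": "UpperIleum",
    "lower_ileum": "LowerIleum",
    "caecum": "Caecum",
    "colon": "Colon",
}


@dataclass
class Composition:
    """Volume fractions of water, lipids and proteins in a compartment."""

    f_water: float
    f_lipid: float
    f_protein: float

    def __post_init__(self) -> None:
        for attr in ("f_water", "f_lipid", "f_protein"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{attr} {v} outside [0, 1]")
        if self.f_water <= 0:
            raise SchemaError("f_water must be positive")
        if self.f_water + self.f_lipid + self.f_protein > 1.0 + 1e-9:
            raise SchemaError("composition fractions sum above 1")


@dataclass
class OrganSpec:
    """One perfused organ.

    volume L; specific_blood_flow L blood/min per L organ;
    intracellular_pH of the cellular sub-compartment;
    fraction_vascular / fraction_interstitial partition the organ volume
    (the remainder is cellular); peripheral_blood_flow_fraction weights the
    organ's outflow in the peripheral venous plasma observation site;
    drains_to is ``"venous"`` or ``"portal"``.
    """

    name: str
    volume: float
    specific_blood_flow: float
    cellular_composition: Composition
    intracellular_pH: float = 7.0
    fraction_vascular: float = 0.05
    fraction_interstitial: float = 0.15
    peripheral_blood_flow_fraction: float = 0.0
    drains_to: str = "venous"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise SchemaError(f"organ {self.name}: volume must be positive")
        if self.specific_blood_flow < 0:
            raise SchemaError(f"organ {self.name}: negative specific blood flow")
        if self.fraction_vascular + self.fraction_interstitial >= 1.0:
            raise SchemaError(
                f"organ {self.name}: vascular+interstitial fractions must be < 1"
            )
        if not 0.0 <= self.peripheral_blood_flow_fraction <= 1.0:
            raise SchemaError(
                f"organ {self.name}: peripheral_blood_flow_fraction outside [0, 1]"
            )
        if self.drains_to not in ("venous", "portal"):
            raise SchemaError(f"organ {self.name}: drains_to {self.drains_to!r}")


@dataclass
class GITSegmentSpec:
    """One segment of the gut lumen.

    Geometry in cm; pH of the luminal fluid; surface_enhancement_factor
    multiplies the smooth-cylinder surface (villi/microvilli);
    fill_fraction is the fractional steady-state fill level of nutrients,
    which here scales the luminal fluid volume; transit_rate (1/min) is the
    segment's own transport rate, initialized from the regional transit
    time at model build.
    """

    name: str
    length: float
    proximal_radius: float
    distal_radius: float
    surface_enhancement_factor: float
    pH: float
    fill_fraction: float
    transit_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in GIT_SEGMENT_ORDER:
            raise SchemaError(f"unknown GI segment {self.name!r}")
        for attr in ("length", "proximal_radius", "distal_radius"):
            if getattr(self, attr) <= 0:
                raise SchemaError(f"segment {self.name}: {attr} must be positive")
        if self.surface_enhancement_factor < 1.0:
            raise SchemaError(f"segment {self.name}: surface enhancement < 1")
        if not 0.0 < self.fill_fraction <= 1.0:
            raise SchemaError(f"segment {self.name}: fill_fraction outside (0, 1]")
        if self.transit_rate < 0:
            raise SchemaError(f"segment {self.name}: negative transit_rate")

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.proximal_radius + self.distal_radius)


@dataclass
class AdministrationProtocol:
    """Route and body-weight relative dose (mg/kg)."""

    route: str
    dose_per_kg: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "oral"):
            raise SchemaError(f"unknown route {self.route!r}")
        if self.dose_per_kg <= 0:
            raise SchemaError("dose_per_kg must be positive")
        if self.start_time < 0:
            raise SchemaError("start_time must be non-negative")


@dataclass(frozen=True)
class ObservationSite:
    """Where a concentration profile is read out.

    ``venous_plasma`` (central venous pool), ``peripheral_venous_plasma``
    (flow-weighted outflow of the peripheral organs), or
    ``organ_intracellular`` (cellular sub-compartment of ``organ``).
    """

    site: str
    organ: str | None = None

    def __post_init__(self) -> None:
        if self.site not in (
            "venous_plasma",
            "peripheral_venous_plasma",
            "organ_intracellular",
        ):
            raise ObservationError(f"unknown site {self.site!r}")
        if self.site == "organ_intracellular" and not self.organ:
            raise ObservationError("organ required for organ_intracellular site")
        if self.site != "organ_intracellular" and self.organ is not None:
            raise ObservationError("organ only allowed for organ_intracellular site")

    def label(self) -> str:
        if self.site == "organ_intracellular":
            return f"{self.organ}_intracellular"
        return self.site


@dataclass
class SpeciesPhysiology:
    """Full substance-independent species parameterization.

    body_weight kg (density 1 kg/L ties it to the volume budget);
    organ and blood-pool volumes in L; times in minutes; specific_gfr in
    1/min per litre of kidney.
    """

    name: str
    body_weight: float
    haematocrit: float
    plasma_pH: float
    plasma_composition: Composition
    interstitial_composition: Composition
    rbc_composition: Composition
    rbc_pH: float
    organs: dict[str, OrganSpec]
    lumen: list[GITSegmentSpec]
    gastric_emptying_time: float
    small_intestinal_transit_time: float
    large_intestinal_transit_time: float
    specific_gfr: float
    venous_blood_volume: float
    arterial_blood_volume: float
    portal_vein_volume: float

    # -- validation ---------------------------------------------------

    def validate(self, check_volume_closure: bool = True) -> None:
        if self.body_weight <= 0:
            raise InvalidPhysiologyError("body_weight must be positive")
        if not 0.0 < self.haematocrit < 1.0:
            raise InvalidPhysiologyError("haematocrit outside (0, 1)")
        for organ in MANDATORY_ORGANS:
            if organ not in self.organs:
                raise SchemaError(f"missing mandatory organ {organ!r}")
        for name in self.organs:
            if name not in MANDATORY_ORGANS:
                raise SchemaError(f"unknown organ {name!r}")
        seen = [seg.name for seg in self.lumen]
        if seen != [s for s in GIT_SEGMENT_ORDER if s in seen]:
            raise SchemaError("GI segments out of anatomical order")
        if len(set(seen)) != len(seen):
            raise SchemaError("duplicate GI segment")
        for attr in (
            "gastric_emptying_time",
            "small_intestinal_transit_time",
            "large_intestinal_transit_time",
        ):
            if getattr(self, attr) <= 0:
                raise InvalidPhysiologyError(f"{attr} must be positive")
        if self.specific_gfr < 0:
            raise InvalidPhysiologyError("specific_gfr must be non-negative")
        for attr in (
            "venous_blood_volume",
            "arterial_blood_volume",
            "portal_vein_volume",
        ):
            if getattr(self, attr) <= 0:
                raise InvalidPhysiologyError(f"{attr} must be positive")
        if check_volume_closure:
            total = self.total_volume()
            target = self.body_weight  # density 1 kg/L
            if abs(total - target) / target > 0.02:
                raise InvalidPhysiologyError(
                    f"organ + blood volumes ({total:.4g} L) deviate from body "
                    f"weight ({target:.4g} kg) by more than 2%"
                )

    # -- geometry helpers ---------------------------------------------

    def total_volume(self) -> float:
        """Sum of organ and blood-pool volumes (L)."""
        return (
            sum(o.volume for o in self.organs.values())
            + self.venous_blood_volume
            + self.arterial_blood_volume
            + self.portal_vein_volume
        )

    def segment(self, name: str) -> GITSegmentSpec:
        for seg in self.lumen:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def total_lumen_volume(self) -> float:
        """Total luminal fluid volume, Σ π r̄² L · fill (cm³ → L)."""
        import math

        return sum(
            math.pi * seg.mean_radius**2 * seg.length * seg.fill_fraction
            for seg in self.lumen
        ) / 1000.0

    def total_lumen_surface(self) -> float:
        """Total effective absorptive surface, Σ 2π r̄ L · SEF (cm²)."""
        import math

        return sum(
            2.0 * math.pi * seg.mean_radius * seg.length * seg.surface_enhancement_factor
            for seg in self.lumen
        )


# ---------------------------------------------------------------------------
# Parameter path registry
# ---------------------------------------------------------------------------

_Accessor = tuple[Callable[[SpeciesPhysiology], float], Callable[[SpeciesPhysiology, float], None]]


def _comp_accessors(
    getcomp: Callable[[SpeciesPhysiology], Composition], attr: str
) -> _Accessor:
    return (
        lambda s: getattr(getcomp(s), attr),
        lambda s, v: setattr(getcomp(s), attr, v),
    )


def _attr_accessors(attr: str) -> _Accessor:
    return (lambda s: getattr(s, attr), lambda s, v: setattr(s, attr, v))


def _organ_accessors(organ: str, attr: str) -> _Accessor:
    return (
        lambda s: getattr(s.organs[organ], attr),
        lambda s, v: setattr(s.organs[organ], attr, v),
    )


def _segment_accessors(segment: str, attr: str) -> _Accessor:
    return (
        lambda s: getattr(s.segment(segment), attr),
        lambda s, v: setattr(s.segment(segment), attr, v),
    )


_COMP_LABELS = (("water", "f_water"), ("lipids", "f_lipid"), ("proteins", "f_protein"))

_SEGMENT_ATTRS = (
    ("pH", "pH"),
    ("Length", "length"),
    ("Proximal radius", "proximal_radius"),
    ("Distal radius", "distal_radius"),
    ("Effective surface area enhancement factor", "surface_enhancement_factor"),
    ("Fractional steady-state fill level", "fill_fraction"),
    ("Intestinal transit rate", "transit_rate"),
)

_ORGAN_ATTRS = (
    ("Volume", "volume"),
    ("Specific blood flow rate", "specific_blood_flow"),
    ("pH (intracellular)", "intracellular_pH"),
    ("Fraction vascular", "fraction_vascular"),
    ("Fraction interstitial", "fraction_interstitial"),
    ("Peripheral blood flow fraction", "peripheral_blood_flow_fraction"),
)


def _iter_registry(species: SpeciesPhysiology) -> Iterator[tuple[str, _Accessor]]:
    yield "Organism|Weight", _attr_accessors("body_weight")
    yield "Organism|Haematocrit", _attr_accessors("haematocrit")
    yield "Organism|pH (plasma)", _attr_accessors("plasma_pH")
    yield "Organism|pH (red blood cells)", _attr_accessors("rbc_pH")
    for pool, attr in (
        ("Plasma", "plasma_composition"),
        ("Interstitial", "interstitial_composition"),
        ("BloodCells", "rbc_composition"),
    ):
        for label, cattr in _COMP_LABELS:
            yield (
                f"Organism|{pool}|Vf ({label})",
                _comp_accessors(lambda s, a=attr: getattr(s, a), cattr),
            )
    yield "Organism|VenousBlood|Volume", _attr_accessors("venous_blood_volume")
    yield "Organism|ArterialBlood|Volume", _attr_accessors("arterial_blood_volume")
    yield "Organism|PortalVein|Volume", _attr_accessors("portal_vein_volume")
    yield (
        "Organism|Lumen|Stomach|Gastric emptying time",
        _attr_accessors("gastric_emptying_time"),
    )
    yield (
        "Organism|SmallIntestine|Small intestinal transit time",
        _attr_accessors("small_intestinal_transit_time"),
    )
    yield (
        "Organism|LargeIntestine|Large intestinal transit time",
        _attr_accessors("large_intestinal_transit_time"),
    )
    yield "Organism|Kidney|GFR (specific)", _attr_accessors("specific_gfr")
    for organ in MANDATORY_ORGANS:
        if organ not in species.organs:
            continue
        pname = _ORGAN_PATH_NAMES[organ]
        for label, attr in _ORGAN_ATTRS:
            yield f"Organism|{pname}|{label}", _organ_accessors(organ, attr)
        for label, cattr in _COMP_LABELS:
            yield (
                f"Organism|{pname}|Vf ({label})",
                _comp_accessors(lambda s, o=organ: s.organs[o].cellular_composition, cattr),
            )
    for seg in species.lumen:
        pname = _SEGMENT_PATH_NAMES[seg.name]
        for label, attr in _SEGMENT_ATTRS:
            yield f"Organism|Lumen|{pname}|{label}", _segment_accessors(seg.name, attr)


def parameter_paths(species: SpeciesPhysiology) -> list[str]:
    """Ordered list of every perturbable physiological leaf parameter."""
    return [path for path, _ in _iter_registry(species)]


def _find_accessor(species: SpeciesPhysiology, path: str) -> _Accessor:
    for p, acc in _iter_registry(species):
        if p == path:
            return acc
    raise KeyError(f"unknown parameter path {path!r}")


def get_parameter(species: SpeciesPhysiology, path: str) -> float:
    """Value of the physiological leaf addressed by ``path``."""
    return _find_accessor(species, path)[0](species)


def set_parameter(species: SpeciesPhysiology, path: str, value: float) -> None:
    """Set the physiological leaf addressed by ``path`` in place."""
    _find_accessor(species, path)[1](species, value)


def perturb_parameter(
    species: SpeciesPhysiology, path: str, factor: float
) -> SpeciesPhysiology:
    """Return a deep copy of ``species`` with one leaf multiplied by ``factor``.

    No dependent parameters are renormalized: perturbing e.g. the muscle
    volume does not rescale other organs.
    """
    clone = copy.deepcopy(species)
    acc = _find_accessor(clone, path)
    acc[1](clone, acc[0](clone) * factor)
    return clone


def organ_path_name(organ: str) -> str:
    return _ORGAN_PATH_NAMES[organ]


def segment_path_name(segment: str) -> str:
    return _SEGMENT_PATH_NAMES[segment]
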