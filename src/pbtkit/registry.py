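"""Species templates, species-file I/O, allometric scaling, extrapolation.

Seven mammalian template parameterizations (mouse, rat, rabbit, monkey,
beagle, minipig, human; body weights 0.02–73 kg) ship as YAML documents
under ``pbtkit/data/species``.  They are literature-plausible
approximations intended as scaffolds for new species models, not curated
reference databases.

Allometric scaling rescales a template to a target body weight: organ and
blood-pool volumes scale linearly (exponent 1 by default) and are
renormalized to close the volume–weight budget, while the gut lumen is
scaled so that its total volume follows BW^1.06 and its total surface
BW^0.76.  Both aggregate exponents are hit simultaneously by scaling
segment lengths with r^(2·0.76−1.06) = r^0.46 and radii with
r^(1.06−0.76) = r^0.30.  Intensive parameters (pH values, fractions,
compositions, specific rates, haematocrit, transit times) are untouched.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import SchemaError
from .model import PBTKModel, build_model
from .physiology import (
    Composition,
    GITSegmentSpec,
    OrganSpec,
    SpeciesPhysiology,
)

__all__ = [
    "ScalingSettings",
    "SpeciesTemplateSet",
    "TEMPLATE_NAMES",
    "load_template",
    "builtin_templates",
    "read_species_file",
    "write_species_file",
    "allometric_scale",
    "extrapolate",
]

TEMPLATE_NAMES = ("mouse", "rat", "rabbit", "monkey", "beagle", "minipig", "human")


@dataclass(frozen=True)
class ScalingSettings:
    """Allometric exponents: GIT volume BW^1.06, GIT surface BW^0.76,
    organ volumes linear."""

    git_volume_exponent: float = 1.06
    git_surface_exponent: float = 0.76
    organ_exponent: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise SchemaError(f"{f.name} must be positive")


@dataclass
class SpeciesTemplateSet:
    """The packaged seven-species template collection."""

    templates: dict[str, SpeciesPhysiology]

    def __getitem__(self, name: str) -> SpeciesPhysiology:
        return self.templates[name]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_COMP_KEYS = ("f_water", "f_lipid", "f_protein")
_ORGAN_KEYS = (
    "volume",
    "specific_blood_flow",
    "cellular_composition",
    "intracellular_pH",
    "fraction_vascular",
    "fraction_interstitial",
    "peripheral_blood_flow_fraction",
    "drains_to",
)
_SEGMENT_KEYS = (
    "name",
    "length",
    "proximal_radius",
    "distal_radius",
    "surface_enhancement_factor",
    "pH",
    "fill_fraction",
    "transit_rate",
)
_TOP_KEYS = (
    "name",
    "body_weight",
    "haematocrit",
    "plasma_pH",
    "rbc_pH",
    "plasma_composition",
    "interstitial_composition",
    "rbc_composition",
    "organs",
    "lumen",
    "gastric_emptying_time",
    "small_intestinal_transit_time",
    "large_intestinal_transit_time",
    "specific_gfr",
    "venous_blood_volume",
    "arterial_blood_volume",
    "portal_vein_volume",
)


def _comp_to_dict(c: Composition) -> dict:
    return {k: getattr(c, k) for k in _COMP_KEYS}


def species_to_dict(species: SpeciesPhysiology) -> dict:
    """Canonically ordered plain-dict form of a species."""
    d: dict = {}
    for key in _TOP_KEYS:
        if key == "organs":
            d["organs"] = {
                name: {
                    k: (_comp_to_dict(getattr(o, k)) if k == "cellular_composition" else getattr(o, k))
                    for k in _ORGAN_KEYS
                }
                for name, o in sorted(species.organs.items())
            }
        elif key == "lumen":
            d["lumen"] = [
                {k: getattr(seg, k) for k in _SEGMENT_KEYS} for seg in species.lumen
            ]
        elif key.endswith("_composition"):
            d[key] = _comp_to_dict(getattr(species, key))
        else:
            d[key] = getattr(species, key)
    return d


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing key {key!r} in {where}")
    return mapping[key]


def _check_unknown(mapping: dict, allowed: tuple, where: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise SchemaError(f"unknown keys {sorted(unknown)} in {where}")


def _comp_from_dict(d: dict, where: str) -> Composition:
    if not isinstance(d, dict):
        raise SchemaError(f"{where} must be a mapping")
    _check_unknown(d, _COMP_KEYS, where)
    return Composition(**{k: float(_require(d, k, where)) for k in _COMP_KEYS})


def species_from_dict(d: dict) -> SpeciesPhysiology:
    """Parse and fully validate a plain-dict species document."""
    if not isinstance(d, dict):
        raise SchemaError("species document must be a mapping")
    _check_unknown(d, _TOP_KEYS, "species")
    organs = {}
    for name, od in _require(d, "organs", "species").items():
        where = f"organs.{name}"
        _check_unknown(od, _ORGAN_KEYS, where)
        kwargs = {
            k: (
                _comp_from_dict(_require(od, k, where), f"{where}.{k}")
                if k == "cellular_composition"
                else _require(od, k, where)
            )
            for k in _ORGAN_KEYS
        }
        organs[name] = OrganSpec(name=name, **kwargs)
    lumen = []
    for i, sd in enumerate(_require(d, "lumen", "species")):
        where = f"lumen[{i}]"
        _check_unknown(sd, _SEGMENT_KEYS, where)
        lumen.append(
            GITSegmentSpec(**{k: _require(sd, k, where) for k in _SEGMENT_KEYS})
        )
    kwargs = {}
    for key in _TOP_KEYS:
        if key in ("organs", "lumen"):
            continue
        value = _require(d, key, "species")
        if key.endswith("_composition"):
            value = _comp_from_dict(value, f"species.{key}")
        kwargs[key] = value
    species = SpeciesPhysiology(organs=organs, lumen=lumen, **kwargs)
    species.validate()
    return species


def read_species_file(path: str | Path) -> SpeciesPhysiology:
    """Load a species from a JSON or YAML document (JSON is a YAML subset)."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed input
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    return species_from_dict(doc)


def write_species_file(species: SpeciesPhysiology, path: str | Path) -> Path:
    """Serialize a species to canonical, byte-deterministic YAML."""
    path = Path(path)
    doc = yaml.safe_dump(
        species_to_dict(species), sort_keys=False, default_flow_style=False
    )
    path.write_text(doc)
    return path


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def load_template(name: str) -> SpeciesPhysiology:
    """Load one packaged species template by name."""
    if name not in TEMPLATE_NAMES:
        raise SchemaError(f"unknown template {name!r}; choose from {TEMPLATE_NAMES}")
    ref = importlib.resources.files("pbtkit") / "data" / "species" / f"{name}.yaml"
    return species_from_dict(yaml.safe_load(ref.read_text()))


def builtin_templates() -> SpeciesTemplateSet:
    """All seven packaged templates."""
    return SpeciesTemplateSet({name: load_template(name) for name in TEMPLATE_NAMES})


# ---------------------------------------------------------------------------
# allometric scaling and extrapolation
# ---------------------------------------------------------------------------


def allometric_scale(
    template: SpeciesPhysiology,
    target_bw: float,
    settings: ScalingSettings | None = None,
) -> SpeciesPhysiology:
    """Rescale a species template to ``target_bw`` (kg)."""
    if settings is None:
        settings = ScalingSettings()
    if target_bw <= 0:
        raise SchemaError("target body weight must be positive")
    r = target_bw / template.body_weight
    out = copy.deepcopy(template)
    out.body_weight = target_bw

    vol_factor = r**settings.organ_exponent
    for organ in out.organs.values():
        organ.volume *= vol_factor
    out.venous_blood_volume *= vol_factor
    out.arterial_blood_volume *= vol_factor
    out.portal_vein_volume *= vol_factor
    # close the volume-weight budget exactly (density 1 kg/L); skip the
    # correction when it is already at rounding level so that re-scaling to
    # the same weight is an exact identity
    f = target_bw / out.total_volume()
    if abs(f - 1.0) > 1e-12:
        for organ in out.organs.values():
            organ.volume *= f
        out.venous_blood_volume *= f
        out.arterial_blood_volume *= f
        out.portal_vein_volume *= f

    length_exp = 2.0 * settings.git_surface_exponent - settings.git_volume_exponent
    radius_exp = settings.git_volume_exponent - settings.git_surface_exponent
    len_factor = r**length_exp
    rad_factor = r**radius_exp
    for seg in out.lumen:
        seg.length *= len_factor
        seg.proximal_radius *= rad_factor
        seg.distal_radius *= rad_factor
    return out


def extrapolate(model: PBTKModel, target: SpeciesPhysiology) -> PBTKModel:
    """Replace the physiology of a PBTK model with a new target species.

    The compound is untouched and the relative dose (mg/kg) is kept, so
    the absolute dose is recomputed from the target body weight.
    """
    return build_model(target, model.compound, model.protocol)
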