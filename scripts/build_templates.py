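"""Regenerate the packaged species template YAML files.

The templates are literature-plausible approximations of seven mammalian
species spanning 0.02–73 kg.  Organ volume fractions, perfusion rates and
tissue compositions follow typical textbook mammalian values; the gut
lumen geometry is a human-scale table scaled to each species with the
package's own joint length/radius allometric rule, so the shipped
templates respect the BW^1.06 (lumen volume) / BW^0.76 (lumen surface)
aggregate exponents by construction.

Usage: python scripts/build_templates.py
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pbtkit.model import initialize_transit_rates
from pbtkit.physiology import (
    Composition,
    GITSegmentSpec,
    OrganSpec,
    PORTAL_DRAINING_ORGANS,
    SpeciesPhysiology,
)
from pbtkit.registry import ScalingSettings, write_species_file

OUT_DIR = Path(__file__).resolve().parents[1] / "src" / "pbtkit" / "data" / "species"

BODY_WEIGHTS = {
    "mouse": 0.02,
    "rat": 0.25,
    "rabbit": 2.5,
    "monkey": 5.0,
    "beagle": 12.0,
    "minipig": 30.0,
    "human": 73.0,
}

HAEMATOCRIT = {
    "mouse": 0.45,
    "rat": 0.46,
    "rabbit": 0.40,
    "monkey": 0.42,
    "beagle": 0.45,
    "minipig": 0.42,
    "human": 0.44,
}

SPECIFIC_GFR = {  # 1/min per L kidney
    "mouse": 0.35,
    "rat": 0.30,
    "rabbit": 0.25,
    "monkey": 0.25,
    "beagle": 0.25,
    "minipig": 0.20,
    "human": 0.20,
}

# minutes
TRANSIT = {  # gastric emptying, small-intestinal, large-intestinal
    "mouse": (10.0, 90.0, 300.0),
    "rat": (15.0, 120.0, 500.0),
    "rabbit": (90.0, 200.0, 600.0),
    "monkey": (30.0, 180.0, 600.0),
    "beagle": (60.0, 120.0, 700.0),
    "minipig": (60.0, 240.0, 1200.0),
    "human": (15.0, 240.0, 1400.0),
}

STOMACH_PH = {
    "mouse": 3.0,
    "rat": 3.2,
    "rabbit": 1.9,
    "monkey": 2.2,
    "beagle": 1.5,
    "minipig": 2.5,
    "human": 2.0,
}

# base organ volume fractions of body weight; 'rest' absorbs the remainder
BASE_FRACTIONS = {
    "lung": 0.008,
    "liver": 0.035,
    "kidney": 0.008,
    "muscle": 0.40,
    "skin": 0.10,
    "adipose": 0.10,
    "brain": 0.012,
    "heart": 0.005,
    "gonads": 0.0015,
    "bone": 0.10,
    "spleen": 0.002,
    "stomach_wall": 0.005,
    "small_intestine_wall": 0.015,
    "large_intestine_wall": 0.008,
}
BLOOD_FRACTIONS = {"venous": 0.045, "arterial": 0.020, "portal": 0.005}

FRACTION_OVERRIDES = {
    "mouse": {"liver": 0.055, "brain": 0.016, "adipose": 0.07},
    "rat": {"liver": 0.040, "brain": 0.006},
    "monkey": {"brain": 0.015},
    "beagle": {"muscle": 0.44, "adipose": 0.08},
    "minipig": {"adipose": 0.20, "muscle": 0.35},
    "human": {"brain": 0.019, "adipose": 0.15, "liver": 0.025},
}

SPECIFIC_FLOWS = {  # L blood / min / L organ; lung carries cardiac output
    "lung": 0.0,
    "liver": 0.25,
    "kidney": 3.0,
    "muscle": 0.03,
    "skin": 0.08,
    "adipose": 0.03,
    "brain": 0.55,
    "heart": 0.80,
    "gonads": 0.10,
    "bone": 0.03,
    "spleen": 1.20,
    "stomach_wall": 0.60,
    "small_intestine_wall": 0.80,
    "large_intestine_wall": 0.60,
    "rest": 0.05,
}

CELL_COMPOSITIONS = {  # f_water, f_lipid, f_protein
    "lung": (0.78, 0.04, 0.15),
    "liver": (0.70, 0.06, 0.20),
    "kidney": (0.75, 0.04, 0.18),
    "muscle": (0.75, 0.022, 0.20),
    "skin": (0.65, 0.10, 0.25),
    "adipose": (0.15, 0.80, 0.03),
    "brain": (0.77, 0.11, 0.08),
    "heart": (0.73, 0.05, 0.18),
    "gonads": (0.80, 0.03, 0.15),
    "bone": (0.40, 0.25, 0.20),
    "spleen": (0.78, 0.03, 0.18),
    "stomach_wall": (0.75, 0.05, 0.17),
    "small_intestine_wall": (0.75, 0.06, 0.17),
    "large_intestine_wall": (0.75, 0.06, 0.17),
    "rest": (0.70, 0.10, 0.18),
}

FRACTION_VASCULAR = {
    "liver": 0.10,
    "spleen": 0.20,
    "kidney": 0.08,
    "lung": 0.15,
    "bone": 0.03,
    "muscle": 0.02,
}
FRACTION_INTERSTITIAL = {"skin": 0.35, "muscle": 0.12, "adipose": 0.10, "brain": 0.05}
PERIPHERAL_WEIGHT = {"muscle": 0.6, "skin": 0.4}

# human-scale lumen geometry (cm), scaled per species with the joint rule
HUMAN_LUMEN = [
    # name, length, r_prox, r_dist, SEF, pH, fill
    ("stomach", 25.0, 4.0, 3.0, 1.0, 2.0, 0.5),
    ("duodenum", 25.0, 1.6, 1.5, 300.0, 6.0, 0.4),
    ("upper_jejunum", 100.0, 1.45, 1.35, 250.0, 6.2, 0.4),
    ("lower_jejunum", 100.0, 1.30, 1.25, 200.0, 6.4, 0.4),
    ("upper_ileum", 75.0, 1.20, 1.15, 150.0, 6.8, 0.4),
    ("lower_ileum", 75.0, 1.10, 1.05, 100.0, 7.2, 0.4),
    ("caecum", 15.0, 3.5, 3.0, 8.0, 6.0, 0.6),
    ("colon", 120.0, 2.5, 2.5, 4.0, 6.5, 0.6),
]

PLASMA = Composition(f_water=0.93, f_lipid=0.005, f_protein=0.065)
INTERSTITIAL = Composition(f_water=0.92, f_lipid=0.005, f_protein=0.04)
RBC = Composition(f_water=0.65, f_lipid=0.003, f_protein=0.30)


def build_species(name: str) -> SpeciesPhysiology:
    bw = BODY_WEIGHTS[name]
    fractions = dict(BASE_FRACTIONS)
    fractions.update(FRACTION_OVERRIDES.get(name, {}))
    blood = {k: f * bw for k, f in BLOOD_FRACTIONS.items()}
    volumes = {organ: frac * bw for organ, frac in fractions.items()}
    # 'rest' absorbs the remainder so the volume budget closes exactly
    volumes["rest"] = bw - sum(volumes.values()) - sum(blood.values())
    assert volumes["rest"] > 0.01 * bw, f"{name}: no 'rest' volume left"

    organs = {}
    for organ, volume in volumes.items():
        w, l, p = CELL_COMPOSITIONS[organ]
        organs[organ] = OrganSpec(
            name=organ,
            volume=volume,
            specific_blood_flow=SPECIFIC_FLOWS[organ],
            cellular_composition=Composition(f_water=w, f_lipid=l, f_protein=p),
            intracellular_pH=7.0,
            fraction_vascular=FRACTION_VASCULAR.get(organ, 0.04),
            fraction_interstitial=FRACTION_INTERSTITIAL.get(organ, 0.15),
            peripheral_blood_flow_fraction=PERIPHERAL_WEIGHT.get(organ, 0.0),
            drains_to="portal" if organ in PORTAL_DRAINING_ORGANS else "venous",
        )

    scaling = ScalingSettings()
    r = bw / BODY_WEIGHTS["human"]
    len_factor = r ** (2.0 * scaling.git_surface_exponent - scaling.git_volume_exponent)
    rad_factor = r ** (scaling.git_volume_exponent - scaling.git_surface_exponent)
    lumen = []
    for seg_name, length, rp, rd, sef, ph, fill in HUMAN_LUMEN:
        ph_seg = STOMACH_PH[name] if seg_name == "stomach" else ph
        lumen.append(
            GITSegmentSpec(
                name=seg_name,
                length=length * len_factor,
                proximal_radius=rp * rad_factor,
                distal_radius=rd * rad_factor,
                surface_enhancement_factor=sef,
                pH=ph_seg,
                fill_fraction=fill,
            )
        )

    get, si, li = TRANSIT[name]
    species = SpeciesPhysiology(
        name=name,
        body_weight=bw,
        haematocrit=HAEMATOCRIT[name],
        plasma_pH=7.4,
        plasma_composition=PLASMA,
        interstitial_composition=INTERSTITIAL,
        rbc_composition=RBC,
        rbc_pH=7.2,
        organs=organs,
        lumen=lumen,
        gastric_emptying_time=get,
        small_intestinal_transit_time=si,
        large_intestinal_transit_time=li,
        specific_gfr=SPECIFIC_GFR[name],
        venous_blood_volume=blood["venous"],
        arterial_blood_volume=blood["arterial"],
        portal_vein_volume=blood["portal"],
    )
    initialize_transit_rates(species)
    species.validate()
    return species


def main() -> None:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for name in BODY_WEIGHTS:
        path = OUT_DIR / f"{name}.yaml"
        write_species_file(build_species(name), path)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
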