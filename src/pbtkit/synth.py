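"""Synthetic species, compounds, reference ensemble and pseudo-observations.

These generators stand in for curated physiology databases and validated
compound parameterizations.  Species are produced by allometric scaling
of a packaged template followed by mean-preserving lognormal jitter on
extensive and kinetic parameters; compounds are drawn from archetypes
(renal-only, hepatic-only, mixed hepatic + tubular) inside the property
window of typical small drug-like molecules (MW 151–361 g/mol,
logP −0.02 to 1.25).  The reference ensemble mirrors the classic
cross-species study design: eight (compound, protocol) pairs on the
rabbit template — acyclovir-like (i.v. and p.o.), caffeine-like (i.v.),
inulin-like (i.v.), ofloxacin-like (i.v.), paracetamol-like (p.o.) and
theophylline-like (i.v. and p.o.) — extrapolated to six further species,
giving 56 models in total.  All demo parameterizations are archetype
approximations labelled "-like"; the inulin stand-in is treated as a
purely glomerularly filtered compound because large-molecule pore
distribution is outside this package's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .compound import Compound, IonizationSpec
from .errors import SchemaError
from .model import PBTKModel, build_model
from .physiology import AdministrationProtocol, SpeciesPhysiology
from .registry import allometric_scale, builtin_templates, extrapolate
from .simulate import ConcentrationProfile, SimulationResult, observe, simulate
from .physiology import ObservationSite

__all__ = [
    "CompoundArchetype",
    "SyntheticConfig",
    "generate_compound",
    "generate_species",
    "make_reference_ensemble",
    "generate_observations",
    "DEMO_COMPOUNDS",
    "DEMO_PROTOCOLS",
]

ARCHETYPES = ("renal_only", "hepatic_only", "mixed_hepatic_tubular")

MW_RANGE = (151.0, 361.0)
LOGP_RANGE = (-0.02, 1.25)


@dataclass(frozen=True)
class CompoundArchetype:
    """Clearance archetype with the drug-like property window."""

    archetype: str
    mw_range: tuple[float, float] = MW_RANGE
    logp_range: tuple[float, float] = LOGP_RANGE

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise SchemaError(f"unknown archetype {self.archetype!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Seed and noise levels for every generator."""

    seed: int = 0
    jitter_cv: float = 0.2
    noise_cv: float = 0.15
    n_species_samples: int = 1
    n_compound_samples: int = 1

    def __post_init__(self) -> None:
        if self.jitter_cv < 0 or self.noise_cv < 0:
            raise SchemaError("coefficients of variation must be non-negative")


def generate_compound(archetype: CompoundArchetype, seed: int) -> Compound:
    """Draw a random compound of the given clearance archetype."""
    rng = np.random.default_rng(seed)
    mw = rng.uniform(*archetype.mw_range)
    logp = rng.uniform(*archetype.logp_range)
    kind = rng.choice(["neutral", "monoprotic_acid", "monoprotic_base"])
    ion = (
        IonizationSpec()
        if kind == "neutral"
        else IonizationSpec(kind=str(kind), pKa=float(rng.uniform(3.0, 10.0)))
    )
    fu = float(rng.uniform(0.05, 1.0))
    hepatic = tubular = 0.0
    gfr_fraction = 0.0
    if archetype.archetype == "renal_only":
        gfr_fraction = 1.0
    elif archetype.archetype == "hepatic_only":
        hepatic = float(rng.uniform(0.1, 1.0))
    else:
        hepatic = float(rng.uniform(0.1, 1.0))
        tubular = float(rng.uniform(0.05, 0.5))
    return Compound(
        name=f"{archetype.archetype}-{seed}",
        molecular_weight=float(mw),
        logP=float(logp),
        ionization=ion,
        fraction_unbound_plasma=fu,
        effective_permeability=float(rng.uniform(0.001, 0.02)),
        specific_hepatic_clearance=hepatic,
        specific_tubular_secretion=tubular,
        gfr_fraction=gfr_fraction,
    )


# mean-preserving lognormal: exp(sigma Z - sigma^2/2) with
# sigma^2 = ln(1 + cv^2) has expectation exactly 1 and the requested CV
def _jitter_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return np.exp(rng.normal(-0.5 * sigma2, sigma, size=n))


def generate_species(
    template: SpeciesPhysiology, target_bw: float, config: SyntheticConfig
) -> SpeciesPhysiology:
    """Allometric scaling plus mean-preserving lognormal jitter.

    Volumes, flows, lumen lengths and transit times are jittered
    (CV = ``jitter_cv``); pH values and fractions are not.  Volumes are
    renormalized afterwards so the volume–weight budget closes exactly.
    With ``jitter_cv = 0`` the output equals plain allometric scaling.
    """
    scaled = allometric_scale(template, target_bw)
    if config.jitter_cv == 0:
        return scaled
    rng = np.random.default_rng(config.seed)
    organs = list(scaled.organs.values())
    f = _jitter_factors(rng, config.jitter_cv, len(organs) + 3)
    for organ, factor in zip(organs, f[:-3]):
        organ.volume *= factor
    scaled.venous_blood_volume *= f[-3]
    scaled.arterial_blood_volume *= f[-2]
    scaled.portal_vein_volume *= f[-1]
    # close the volume budget again
    corr = target_bw / scaled.total_volume()
    for organ in organs:
        organ.volume *= corr
    scaled.venous_blood_volume *= corr
    scaled.arterial_blood_volume *= corr
    scaled.portal_vein_volume *= corr

    f = _jitter_factors(rng, config.jitter_cv, len(organs))
    for organ, factor in zip(organs, f):
        organ.specific_blood_flow *= factor
    f = _jitter_factors(rng, config.jitter_cv, len(scaled.lumen))
    for seg, factor in zip(scaled.lumen, f):
        seg.length *= factor
    for attr, factor in zip(
        (
            "gastric_emptying_time",
            "small_intestinal_transit_time",
            "large_intestinal_transit_time",
        ),
        _jitter_factors(rng, config.jitter_cv, 3),
    ):
        setattr(scaled, attr, getattr(scaled, attr) * factor)
    scaled.validate()
    return scaled


# -- demo compounds ---------------------------------------------------------
# archetype approximations of the classic reference set; property values
# are plausible for the named drug but deliberately not fitted to PK data.
DEMO_COMPOUNDS: dict[str, Compound] = {}


def _demo_compounds() -> dict[str, Compound]:
    return {
        "acyclovir-like": Compound(
            # low permeability + sparing solubility: oral absorption is
            # incomplete (F ~ 0.27 at 25 mg/kg in the rabbit reference
            # model) and saturable, falling with dose as for the real drug
            name="acyclovir-like",
            molecular_weight=225.2,
            logP=-0.02,
            ionization=IonizationSpec(),
            fraction_unbound_plasma=0.85,
            effective_permeability=1e-6,
            specific_tubular_secretion=0.10,
            gfr_fraction=1.0,
            solubility=5800.0,
        ),
        "caffeine-like": Compound(
            name="caffeine-like",
            molecular_weight=194.2,
            logP=-0.02,
            ionization=IonizationSpec(),
            fraction_unbound_plasma=0.65,
            effective_permeability=0.02,
            specific_hepatic_clearance=0.35,
        ),
        "inulin-like": Compound(
            # GFR-only small-molecule stand-in for the fructan tracer; the
            # pore-based large-molecule distribution model is out of scope
            name="inulin-like",
            molecular_weight=6179.0,
            logP=-10.0,
            ionization=IonizationSpec(),
            fraction_unbound_plasma=1.0,
            effective_permeability=0.0,
            gfr_fraction=1.0,
        ),
        "ofloxacin-like": Compound(
            # the real drug is a zwitterion that is net-neutral around
            # physiological pH; approximated here as a neutral species
            name="ofloxacin-like",
            molecular_weight=361.4,
            logP=0.35,
            ionization=IonizationSpec(),
            fraction_unbound_plasma=0.75,
            effective_permeability=0.001,
            specific_hepatic_clearance=0.05,
            specific_tubular_secretion=0.15,
            gfr_fraction=1.0,
        ),
        "paracetamol-like": Compound(
            name="paracetamol-like",
            molecular_weight=151.2,
            logP=0.46,
            ionization=IonizationSpec(kind="monoprotic_acid", pKa=9.38),
            fraction_unbound_plasma=0.80,
            effective_permeability=0.002,
            specific_hepatic_clearance=0.30,
            solubility=92000.0,
        ),
        "theophylline-like": Compound(
            name="theophylline-like",
            molecular_weight=180.2,
            logP=-0.02,
            ionization=IonizationSpec(kind="monoprotic_acid", pKa=8.81),
            fraction_unbound_plasma=0.60,
            effective_permeability=0.001,
            specific_hepatic_clearance=0.08,
            specific_tubular_secretion=0.10,
            solubility=41000.0,
        ),
    }


DEMO_COMPOUNDS = _demo_compounds()

#: (compound, route, dose mg/kg) of the eight reference protocols; doses
#: are realistic orders of magnitude but otherwise arbitrary defaults.
DEMO_PROTOCOLS: tuple[tuple[str, str, float], ...] = (
    ("acyclovir-like", "iv_bolus", 10.0),
    ("acyclovir-like", "oral", 25.0),
    ("caffeine-like", "iv_bolus", 5.0),
    ("inulin-like", "iv_bolus", 50.0),
    ("ofloxacin-like", "iv_bolus", 10.0),
    ("paracetamol-like", "oral", 15.0),
    ("theophylline-like", "iv_bolus", 5.0),
    ("theophylline-like", "oral", 10.0),
)

REFERENCE_SPECIES = "rabbit"
TARGET_SPECIES = ("mouse", "rat", "beagle", "minipig", "monkey", "human")


def make_reference_ensemble(config: SyntheticConfig | None = None) -> list[PBTKModel]:
    """The 8 × 7 reference ensemble: eight rabbit protocols extrapolated
    to six further species (56 models)."""
    config = config or SyntheticConfig()
    templates = builtin_templates()
    models: list[PBTKModel] = []
    for compound_name, route, dose in DEMO_PROTOCOLS:
        compound = DEMO_COMPOUNDS[compound_name]
        protocol = AdministrationProtocol(route=route, dose_per_kg=dose)
        reference = build_model(templates[REFERENCE_SPECIES], compound, protocol)
        models.append(reference)
        for species_name in TARGET_SPECIES:
            models.append(extrapolate(reference, templates[species_name]))
    return models


def generate_observations(
    model: PBTKModel,
    sample_times: list[float],
    config: SyntheticConfig,
    site: ObservationSite | None = None,
    result: SimulationResult | None = None,
) -> ConcentrationProfile:
    """Noisy pseudo-observations: the model prediction at ``sample_times``
    with multiplicative lognormal noise (CV = ``noise_cv``)."""
    if len(sample_times) == 0:
        raise SchemaError("empty sample times")
    site = site or ObservationSite("venous_plasma")
    if result is None:
        result = simulate(model)
    if max(sample_times) > result.times[-1] or min(sample_times) < result.times[0]:
        raise SchemaError("sample times outside the simulated span")
    profile = observe(result, site)
    pred = np.interp(sample_times, profile.times, profile.concentrations)
    rng = np.random.default_rng(config.seed)
    noisy = pred * _jitter_factors(rng, config.noise_cv, len(pred))
    out = ConcentrationProfile(
        site=site,
        times=np.asarray(sample_times, dtype=float),
        concentrations=np.maximum(noisy, np.finfo(float).tiny),
        role="observed",
    )
    return out
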