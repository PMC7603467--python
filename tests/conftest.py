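"""Shared fixtures: templates, demo compounds and degenerate configurations."""

from __future__ import annotations

import copy

import pytest
from hypothesis import HealthCheck, settings

from pbtkit import (
    AdministrationProtocol,
    Compound,
    SimulationSettings,
    build_model,
    load_template,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: Faster grid for tests that only need qualitative dynamics.
FAST = SimulationSettings(t_end=720.0, n_samples=60, rel_tol=1e-8, abs_tol=1e-10)


@pytest.fixture
def rabbit():
    return load_template("rabbit")


@pytest.fixture
def mouse():
    return load_template("mouse")


@pytest.fixture
def fast_settings():
    return FAST


@pytest.fixture
def caffeine_like():
    return Compound(
        name="caffeine-like",
        molecular_weight=194.2,
        logP=-0.02,
        fraction_unbound_plasma=0.65,
        effective_permeability=0.02,
        specific_hepatic_clearance=0.35,
    )


@pytest.fixture
def iv_model(rabbit, caffeine_like):
    return build_model(rabbit, caffeine_like, AdministrationProtocol("iv_bolus", 5.0))


@pytest.fixture
def oral_model(rabbit, caffeine_like):
    return build_model(rabbit, caffeine_like, AdministrationProtocol("oral", 10.0))


def make_one_compartment_species(template):
    """Degenerate physiology: uniform compositions/pH and near-infinite
    perfusion, so the whole body behaves as one well-mixed volume."""
    sp = copy.deepcopy(template)
    pc = sp.plasma_composition
    for organ in sp.organs.values():
        organ.cellular_composition = copy.deepcopy(pc)
        organ.intracellular_pH = sp.plasma_pH
        organ.specific_blood_flow = 1e4
    sp.interstitial_composition = copy.deepcopy(pc)
    sp.rbc_composition = copy.deepcopy(pc)
    sp.rbc_pH = sp.plasma_pH
    return sp


def make_gfr_tracer():
    """Freely filtered, unbound, neutral tracer (first-order renal
    elimination only)."""
    return Compound(
        name="gfr-tracer",
        molecular_weight=200.0,
        logP=0.0,
        fraction_unbound_plasma=1.0,
        gfr_fraction=1.0,
    )


@pytest.fixture
def one_compartment_model(rabbit):
    sp = make_one_compartment_species(rabbit)
    return build_model(sp, make_gfr_tracer(), AdministrationProtocol("iv_bolus", 5.0))
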