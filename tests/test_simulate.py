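"""Simulation: conservation, linearity, closed-form limit, observation."""

import copy
import dataclasses

import numpy as np
import pytest

from pbtkit import (
    AdministrationProtocol,
    Compound,
    ObservationError,
    ObservationSite,
    SimulationSettings,
    build_model,
    observe,
    simulate,
    summary_metrics,
)
from pbtkit.simulate import ConcentrationProfile

from conftest import FAST, make_gfr_tracer, make_one_compartment_species


@pytest.mark.parametrize("route, dose", [("iv_bolus", 5.0), ("oral", 10.0)])
def test_mass_balance(rabbit, caffeine_like, route, dose):
    """Total amount in compartments plus sinks equals the dose at every
    sample, for both routes."""
    model = build_model(rabbit, caffeine_like, AdministrationProtocol(route, dose))
    result = simulate(model)
    assert result.mass_balance_error() < 1e-6


def test_mass_balance_saturable_oral(rabbit):
    """Conservation also holds on the saturable (adaptive-solver) path."""
    compound = Compound(
        name="poor", molecular_weight=225.0, logP=0.0, fraction_unbound_plasma=0.85,
        effective_permeability=1e-6, gfr_fraction=1.0, solubility=5800.0,
    )
    model = build_model(rabbit, compound, AdministrationProtocol("oral", 25.0))
    assert not model.is_linear
    result = simulate(model, FAST)
    assert result.mass_balance_error() < 1e-6


def test_dose_linearity(rabbit, caffeine_like):
    """With unbounded solubility, doubling the dose doubles every
    concentration at every time."""
    m1 = build_model(rabbit, caffeine_like, AdministrationProtocol("oral", 10.0))
    m2 = build_model(copy.deepcopy(rabbit), caffeine_like,
                     AdministrationProtocol("oral", 20.0))
    r1 = simulate(m1, FAST)
    r2 = simulate(m2, FAST)
    mask = r1.amounts != 0
    assert np.allclose(r2.amounts[mask] / r1.amounts[mask], 2.0, rtol=1e-8)


def test_determinism_bit_identical(iv_model):
    a = simulate(iv_model, FAST)
    b = simulate(iv_model, FAST)
    assert np.array_equal(a.amounts, b.amounts)
    assert np.array_equal(a.times, b.times)


def test_iv_lumen_identically_zero(iv_model):
    result = simulate(iv_model, FAST)
    for i in result.index.lumen.values():
        assert np.all(result.amounts[i] == 0.0)


def test_one_compartment_closed_form(one_compartment_model):
    """The degenerate uniform-physiology model matches (D/V) e^{-kt}."""
    m = one_compartment_model
    sp = m.species
    result = simulate(m, SimulationSettings(t_end=1440.0))
    prof = observe(result, ObservationSite("venous_plasma"))
    V = sp.total_volume()
    k = sp.specific_gfr * sp.organs["kidney"].volume / V
    expected = m.dose_umol / V * np.exp(-k * prof.times)
    # t=0 is the bolus instant (all drug still in the venous pool)
    rel = np.abs(prof.concentrations[1:] - expected[1:]) / expected[1:]
    assert rel.max() < 1e-6


def test_uniform_equilibrium_without_elimination(rabbit):
    """With Kp = 1 everywhere and no elimination, every compartment relaxes
    to the same concentration (the whole-body mean)."""
    sp = make_one_compartment_species(rabbit)
    for organ in sp.organs.values():
        organ.specific_blood_flow = 1.0  # ordinary flows; just wait long enough
    compound = Compound(name="inert", molecular_weight=100.0, logP=0.0,
                        fraction_unbound_plasma=1.0)
    m = build_model(sp, compound, AdministrationProtocol("iv_bolus", 5.0))
    result = simulate(m, SimulationSettings(t_end=5000.0, n_samples=100))
    c_eq = m.dose_umol / sp.total_volume()
    final = result.amounts[:, -1]
    for name, i in result.index.organs.items():
        conc = final[i] / sp.organs[name].volume
        assert conc == pytest.approx(c_eq, rel=1e-4)
    assert final[result.index.venous] / sp.venous_blood_volume == pytest.approx(
        c_eq, rel=1e-4
    )


def test_observe_peripheral_single_organ(iv_model):
    """All peripheral weight on muscle reduces the site to the muscle
    outflow plasma concentration."""
    sp = iv_model.species
    for name, organ in sp.organs.items():
        organ.peripheral_blood_flow_fraction = 1.0 if name == "muscle" else 0.0
    model = build_model(sp, iv_model.compound, iv_model.protocol, validate=False)
    result = simulate(model, FAST)
    peripheral = observe(result, ObservationSite("peripheral_venous_plasma"))
    i = result.index.organs["muscle"]
    kp = model.partitions["muscle"].Kp_total
    expected = result.amounts[i] / sp.organs["muscle"].volume / kp
    assert np.allclose(peripheral.concentrations, np.maximum(expected, 0), rtol=1e-12)


def test_observe_intracellular_equals_total_when_cellular_only(rabbit, caffeine_like):
    sp = rabbit
    sp.organs["brain"].fraction_vascular = 0.0
    sp.organs["brain"].fraction_interstitial = 0.0
    model = build_model(sp, caffeine_like, AdministrationProtocol("iv_bolus", 5.0),
                        validate=False)
    result = simulate(model, FAST)
    intra = observe(result, ObservationSite("organ_intracellular", "brain"))
    i = result.index.organs["brain"]
    total = result.amounts[i] / sp.organs["brain"].volume
    assert np.allclose(intra.concentrations, np.maximum(total, 0), rtol=1e-12)


def test_observe_unknown_organ_errors(iv_model, fast_settings):
    result = simulate(iv_model, fast_settings)
    with pytest.raises(ObservationError):
        observe(result, ObservationSite("organ_intracellular", "gallbladder"))


def test_observe_peripheral_without_weights_errors(iv_model, fast_settings):
    sp = iv_model.species
    for organ in sp.organs.values():
        organ.peripheral_blood_flow_fraction = 0.0
    model = build_model(sp, iv_model.compound, iv_model.protocol, validate=False)
    result = simulate(model, fast_settings)
    with pytest.raises(ObservationError):
        observe(result, ObservationSite("peripheral_venous_plasma"))


def test_summary_metrics():
    site = ObservationSite("venous_plasma")
    prof = ConcentrationProfile(site, [0.0, 10.0, 20.0], [0.0, 3.0, 1.0])
    m = summary_metrics(prof)
    assert m["cmax"] == 3.0
    assert m["tmax"] == 10.0
    assert m["auc"] == pytest.approx(35.0)  # trapezoid by hand
    const = ConcentrationProfile(site, np.linspace(0, 100, 51), np.full(51, 2.0))
    assert summary_metrics(const)["auc"] == pytest.approx(200.0)


def test_summary_metrics_iv_tmax_at_origin(iv_model, fast_settings):
    prof = observe(simulate(iv_model, fast_settings), ObservationSite("venous_plasma"))
    assert summary_metrics(prof)["tmax"] == 0.0


def test_delayed_administration(rabbit, caffeine_like):
    proto = AdministrationProtocol("iv_bolus", 5.0, start_time=120.0)
    model = build_model(rabbit, caffeine_like, proto)
    result = simulate(model, FAST)
    before = result.times < 120.0
    assert np.all(result.amounts[:, before] == 0.0)
    assert result.amounts.sum(axis=0)[-1] == pytest.approx(model.dose_umol, rel=1e-9)


def test_settings_validation():
    with pytest.raises(Exception):
        SimulationSettings(t_end=-1.0)
    with pytest.raises(Exception):
        SimulationSettings(t_end=100.0, n_samples=10)
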