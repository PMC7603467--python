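"""Synthetic generators: compounds, jittered species, reference ensemble,
pseudo-observations and the recovery property of the validation step."""

import dataclasses

import numpy as np
import pytest

from pbtkit import (
    CompoundArchetype,
    ObservationSite,
    SyntheticConfig,
    build_model,
    generate_compound,
    generate_observations,
    generate_species,
    load_template,
    simulate,
    observe,
    validate_model,
)
from pbtkit.registry import allometric_scale, species_to_dict
from pbtkit.synth import DEMO_COMPOUNDS, DEMO_PROTOCOLS, make_reference_ensemble

from conftest import FAST


def test_compound_generation_deterministic():
    arch = CompoundArchetype("mixed_hepatic_tubular")
    assert generate_compound(arch, 7) == generate_compound(arch, 7)
    assert generate_compound(arch, 7) != generate_compound(arch, 8)


def test_archetype_constraints():
    renal = generate_compound(CompoundArchetype("renal_only"), 3)
    assert renal.specific_hepatic_clearance == 0.0
    assert renal.specific_tubular_secretion == 0.0
    assert renal.gfr_fraction == 1.0
    hepatic = generate_compound(CompoundArchetype("hepatic_only"), 3)
    assert hepatic.gfr_fraction == 0.0
    assert hepatic.specific_tubular_secretion == 0.0
    assert hepatic.specific_hepatic_clearance > 0


def test_property_windows():
    arch = CompoundArchetype("hepatic_only")
    for seed in range(200):
        c = generate_compound(arch, seed)
        assert 151.0 <= c.molecular_weight <= 361.0
        assert -0.02 <= c.logP <= 1.25
        assert 0.05 <= c.fraction_unbound_plasma <= 1.0


def test_species_jitter_zero_reduces_to_scaling(rabbit):
    config = SyntheticConfig(seed=5, jitter_cv=0.0)
    jittered = generate_species(rabbit, 4.0, config)
    scaled = allometric_scale(rabbit, 4.0)
    assert species_to_dict(jittered) == species_to_dict(scaled)


def test_species_jitter_preserves_volume_budget(rabbit):
    for seed in range(5):
        sp = generate_species(rabbit, 4.0, SyntheticConfig(seed=seed))
        assert sp.total_volume() == pytest.approx(4.0, rel=1e-9)
        assert sp.plasma_pH == rabbit.plasma_pH  # intensive values untouched


def test_species_jitter_is_mean_preserving(rabbit):
    """The lognormal jitter leaves the expected liver volume at the
    scaled template value (law of large numbers; CV 0.2)."""
    target = allometric_scale(rabbit, 4.0).organs["liver"].volume
    # volumes are renormalized, so test the raw multiplicative factors and
    # a moderate species-level sample
    draws = np.array(
        [
            generate_species(rabbit, 4.0, SyntheticConfig(seed=s)).organs["liver"].volume
            for s in range(600)
        ]
    )
    se = 0.2 / np.sqrt(draws.size)
    assert abs(draws.mean() / target - 1.0) < 5 * se


def test_reference_ensemble_shape():
    models = make_reference_ensemble()
    assert len(models) == 56  # 8 protocols x 7 species
    compounds = {m.compound.name for m in models}
    assert len(compounds) == 6
    protocols = {(m.compound.name, m.protocol.route) for m in models}
    assert len(protocols) == 8
    species = {m.species.name for m in models}
    assert species == {"mouse", "rat", "rabbit", "monkey", "beagle", "minipig", "human"}


def test_ensemble_doses_are_body_weight_relative():
    models = make_reference_ensemble()
    by_protocol = {}
    for m in models:
        key = (m.compound.name, m.protocol.route)
        by_protocol.setdefault(key, set()).add(m.protocol.dose_per_kg)
    for doses in by_protocol.values():
        assert len(doses) == 1  # same mg/kg in every species


def test_demo_compound_names_marked_approximate():
    assert set(DEMO_COMPOUNDS) == {c for c, _, _ in DEMO_PROTOCOLS}
    for name in DEMO_COMPOUNDS:
        assert name.endswith("-like")


def test_observations_noise_free_match_prediction(iv_model):
    result = simulate(iv_model, FAST)
    times = [60.0, 120.0, 240.0]
    obs = generate_observations(
        iv_model, times, SyntheticConfig(seed=1, noise_cv=0.0), result=result
    )
    prof = observe(result, ObservationSite("venous_plasma"))
    expected = np.interp(times, prof.times, prof.concentrations)
    assert np.allclose(obs.concentrations, expected, rtol=1e-12)


def test_observations_reproducible_and_positive(iv_model):
    result = simulate(iv_model, FAST)
    times = list(np.linspace(30, 600, 12))
    a = generate_observations(iv_model, times, SyntheticConfig(seed=9), result=result)
    b = generate_observations(iv_model, times, SyntheticConfig(seed=9), result=result)
    assert np.array_equal(a.concentrations, b.concentrations)
    assert np.all(a.concentrations > 0)


def test_observation_times_outside_span_error(iv_model):
    result = simulate(iv_model, FAST)
    with pytest.raises(Exception):
        generate_observations(iv_model, [1e6], SyntheticConfig(seed=1), result=result)


def test_validation_recovers_true_model(iv_model):
    """Observations drawn from the model itself pass the factor-of-2 check
    in at least 95% of seeds; observations from a model with 5x hepatic
    clearance fail in at least 95% of seeds."""
    result = simulate(iv_model, FAST)
    prof = observe(result, ObservationSite("venous_plasma"))
    times = list(np.linspace(30, 600, 10))

    wrong_compound = dataclasses.replace(
        iv_model.compound, specific_hepatic_clearance=5 * iv_model.compound.specific_hepatic_clearance
    )
    wrong = build_model(load_template("rabbit"), wrong_compound, iv_model.protocol)
    wrong_result = simulate(wrong, FAST)

    passes = fails = 0
    n = 200
    for seed in range(n):
        config = SyntheticConfig(seed=seed, noise_cv=0.3)
        obs_true = generate_observations(iv_model, times, config, result=result)
        if validate_model(prof, obs_true).passed:
            passes += 1
        obs_wrong = generate_observations(wrong, times, config, result=wrong_result)
        if not validate_model(prof, obs_wrong).passed:
            fails += 1
    assert passes >= 0.95 * n
    assert fails >= 0.95 * n
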