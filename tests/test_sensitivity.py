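"""Dose-normalized sensitivity: metric identities, oracle agreement,
classification, grouping, external-table loading."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pbtkit import (
    ClassificationThresholds,
    ObservationSite,
    SchemaError,
    SensitivitySettings,
    classify,
    ensemble_sensitivity,
    group_parameter,
    load_max_sensitivity_table,
    rmsd,
    sensitivity_for_parameter,
    summarize,
)
from pbtkit.model import DOSE_PARAMETER_PATH
from pbtkit.sensitivity import SensitivityRecord, SensitivityTable
from pbtkit.simulate import ConcentrationProfile, observe, simulate

from conftest import FAST

VEN = ObservationSite("venous_plasma")


def _profile(values, times=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values), dtype=float) if times is None else np.asarray(times)
    return ConcentrationProfile(VEN, t, values)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
        ([1.0, 1.0], [2.0, 2.0], 1.0),
        ([0.0, 0.0], [3.0, 4.0], math.sqrt(12.5)),
    ],
)
def test_rmsd_examples(a, b, expected):
    assert rmsd(_profile(a), _profile(b)) == pytest.approx(expected, rel=1e-12)


def test_rmsd_grid_mismatch_errors():
    with pytest.raises(SchemaError):
        rmsd(_profile([1.0, 2.0]), _profile([1.0, 2.0], times=[0.0, 2.0]))


def test_dose_parameter_sensitivity_is_exactly_one(iv_model, oral_model):
    for model in (iv_model, oral_model):
        for site in (VEN, ObservationSite("organ_intracellular", "brain")):
            rec = sensitivity_for_parameter(
                model, DOSE_PARAMETER_PATH, site, sim_settings=FAST
            )
            assert rec.sens_rmsd == 1.0
            assert rec.sens_cmax == 1.0


def test_lumen_parameters_inert_under_iv(iv_model):
    """Intravenous dosing never populates the lumen, so every lumen
    parameter is a structural zero."""
    for path in (
        "Organism|Lumen|UpperIleum|pH",
        "Organism|Lumen|LowerJejunum|Length",
        "Organism|Lumen|Stomach|Gastric emptying time",
        "Organism|SmallIntestine|Small intestinal transit time",
    ):
        rec = sensitivity_for_parameter(iv_model, path, VEN, sim_settings=FAST)
        assert rec.sens_rmsd < 1e-6


def test_whole_profile_scaling_parameter_gives_one(iv_model):
    """Body weight only rescales the absolute dose, so its perturbation
    scales the whole profile by 0.95 and the ratio is 1."""
    rec = sensitivity_for_parameter(iv_model, "Organism|Weight", VEN, sim_settings=FAST)
    assert rec.sens_rmsd == pytest.approx(1.0, abs=1e-10)


def test_sensitivity_matches_closed_form_oracle(one_compartment_model):
    """Independent brute-force evaluation of the ratio on the degenerate
    one-compartment model, using the analytic exponential solution."""
    m = one_compartment_model
    sp = m.species
    path = "Organism|Kidney|GFR (specific)"
    rec = sensitivity_for_parameter(m, path, VEN)

    # oracle: c(t) = (D/V) e^{-kt} with the t=0 sample being the bolus
    # value D/V_ven; GFR perturbation scales k by 0.95, dose scales D.
    from pbtkit.simulate import default_settings

    settings = default_settings(m)
    t = np.linspace(0.0, settings.t_end, settings.n_samples)
    V = sp.total_volume()
    D = m.dose_umol
    k = sp.specific_gfr * sp.organs["kidney"].volume / V

    def curve(dose, kk):
        c = dose / V * np.exp(-kk * t)
        c[0] = dose / sp.venous_blood_volume  # bolus instant
        return c

    c0 = curve(D, k)
    ci = curve(D, 0.95 * k)
    cdose = curve(0.95 * D, k)
    sens_expected = np.sqrt(np.mean((c0 - ci) ** 2)) / np.sqrt(
        np.mean((c0 - cdose) ** 2)
    )
    assert rec.sens_rmsd == pytest.approx(sens_expected, abs=1e-4)


def test_sensitivity_dose_invariant_under_linearity(iv_model):
    """For a linear model the normalized sensitivity does not depend on
    the dose level."""
    path = "Organism|Muscle|Volume"
    rec1 = sensitivity_for_parameter(iv_model, path, VEN, sim_settings=FAST)
    doubled = iv_model.with_dose_factor(2.0)
    rec2 = sensitivity_for_parameter(doubled, path, VEN, sim_settings=FAST)
    assert rec2.sens_rmsd == pytest.approx(rec1.sens_rmsd, rel=1e-8)


def test_ensemble_records_and_max(iv_model, oral_model):
    paths = ["Organism|Liver|Volume", "Organism|Haematocrit",
             "Organism|Lumen|UpperIleum|pH"]
    sites = (VEN, ObservationSite("organ_intracellular", "brain"))
    table = ensemble_sensitivity(
        [iv_model, oral_model],
        SensitivitySettings(sites=sites),
        sim_settings=FAST,
        parameter_paths=paths,
    )
    assert len(table.records) == 2 * 3 * 2  # models x params x sites
    for rec in table.records:
        assert table.max_by_parameter[rec.parameter_path] >= rec.sens_rmsd
    values = list(table.max_by_parameter.values())
    assert values == sorted(values, reverse=True)


def test_ensemble_skips_absent_parameters(iv_model):
    table = ensemble_sensitivity(
        [iv_model],
        SensitivitySettings(sites=(VEN,)),
        sim_settings=FAST,
        parameter_paths=["Organism|Liver|Volume", "Organism|Gallbladder|Volume"],
    )
    assert set(table.max_by_parameter) == {"Organism|Liver|Volume"}


def test_ensemble_empty_errors():
    with pytest.raises(SchemaError):
        ensemble_sensitivity([])


def test_max_aggregation_over_records():
    records = [
        SensitivityRecord("p", "m1", VEN, 0.1),
        SensitivityRecord("p", "m2", VEN, 0.5),
        SensitivityRecord("q", "m1", VEN, 0.2),
    ]
    table = SensitivityTable(records=records)
    assert table.max_by_parameter == {"p": 0.5, "q": 0.2}


@pytest.mark.parametrize(
    "value, label",
    [
        (0.005, "insensitive"),
        (0.05, "low"),
        (0.25, "moderate"),
        (0.4, "moderate"),  # boundary stays in the moderate class
        (0.401, "sensitive"),
        (2.0, "sensitive"),
    ],
)
def test_classify(value, label):
    assert classify(value) == label


def test_classify_negative_errors():
    with pytest.raises(SchemaError):
        classify(-0.1)


def test_thresholds_must_increase():
    with pytest.raises(SchemaError):
        ClassificationThresholds(insensitive_below=0.2, low_below=0.1)


@given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=200))
def test_classification_partitions(values):
    counts = {}
    for v in values:
        counts[classify(v)] = counts.get(classify(v), 0) + 1
    assert sum(counts.values()) == len(values)


@pytest.mark.parametrize(
    "path, tox, group",
    [
        ("Organism|Lumen|UpperIleum|pH", [], "git_pH"),
        ("Organism|Lumen|LowerJejunum|Length", [], "git_geometry"),
        ("Organism|Lumen|Caecum|Intestinal transit rate", [], "git_transit_times"),
        ("Organism|Lumen|Stomach|Gastric emptying time", [], "git_transit_times"),
        ("Organism|SmallIntestine|Small intestinal transit time", [], "git_transit_times"),
        ("Organism|Kidney|GFR (specific)", [], "volume_distribution_clearance"),
        ("Organism|Liver|Volume", [], "volume_distribution_clearance"),
        ("Organism|Muscle|Vf (lipids)", [], "volume_distribution_clearance"),
        ("Organism|Haematocrit", [], "plasma_parameters"),
        ("Organism|pH (plasma)", [], "plasma_parameters"),
        ("Organism|Brain|pH (intracellular)", ["brain"], "plasma_parameters"),
        ("Organism|Plasma|Vf (water)", [], "plasma_parameters"),
        ("Organism|Brain|Volume", ["brain"], "tox_organ"),
        ("Organism|Brain|Specific blood flow rate", ["brain"], "tox_organ"),
        ("Organism|Brain|Vf (lipids)", ["brain"], "tox_organ"),
        ("Organism|Brain|Volume", [], "other"),
        ("Organism|Skin|Fraction interstitial", [], "other"),
        ("Organism|SmallIntestine|Volume", [], "other"),
    ],
)
def test_group_parameter(path, tox, group):
    assert group_parameter(path, tox) == group


def test_group_parameter_malformed():
    with pytest.raises(SchemaError):
        group_parameter("no pipes here")


def test_load_table_long_csv(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("parameter_path,max_sensitivity\nOrganism|A|x,0.2\nOrganism|B|y,0.05\n")
    assert load_max_sensitivity_table(path) == {
        "Organism|A|x": 0.2,
        "Organism|B|y": 0.05,
    }


def test_load_table_wide_with_blanks(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        "parameter_path,model_a,model_b\nOrganism|A|x,0.2,0.5\nOrganism|B|y,,0.05\n"
    )
    assert load_max_sensitivity_table(path) == {
        "Organism|A|x": 0.5,
        "Organism|B|y": 0.05,
    }


def test_load_table_xlsx(tmp_path):
    path = tmp_path / "t.xlsx"
    pd.DataFrame(
        {"parameter_path": ["Organism|A|x"], "max_sensitivity": [0.7]}
    ).to_excel(path, index=False)
    assert load_max_sensitivity_table(path) == {"Organism|A|x": 0.7}


def test_load_table_duplicate_errors(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("parameter_path,max\nOrganism|A|x,0.2\nOrganism|A|x,0.3\n")
    with pytest.raises(SchemaError, match="duplicate"):
        load_max_sensitivity_table(path)


def test_load_table_non_numeric_errors(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("parameter_path,max\nOrganism|A|x,high\n")
    with pytest.raises(SchemaError, match="non-numeric"):
        load_max_sensitivity_table(path)


def test_summarize_counts_and_fractions():
    summary = summarize({"a": 0.005, "b": 0.05, "c": 0.2, "d": 0.5})
    assert summary["counts"] == {
        "insensitive": 1, "low": 1, "moderate": 1, "sensitive": 1,
    }
    assert summary["fractions"]["insensitive"] == pytest.approx(0.25)
    assert sum(summary["counts"].values()) == summary["total"] == 4
    assert sum(summary["histogram"]["counts"]) <= 4
    assert summary["top"][0]["parameter_path"] == "d"


def test_summarize_empty_errors():
    with pytest.raises(SchemaError):
        summarize({})
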