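"""Dose-normalized local parameter sensitivity analysis.

For each physiological parameter a one-at-a-time multiplicative
perturbation (×0.95 by default) is applied, the concentration–time curve
re-simulated, and the root-mean-square deviation from the baseline curve
computed.  The same is done for a 5% dose reduction, and the sensitivity
is the ratio

    sens_i = rmsd(c0, ci) / rmsd(c0, cdose).

The normalization makes the metric comparable across species, compounds,
administration routes and simulation lengths; a value of 1 means the
parameter matters as much as the dose itself, and values above 1 arise
when absorption is saturated so that the dose hardly moves the profile.
An ensemble run aggregates the maximum sensitivity per parameter over all
(model, site) pairs and ranks parameters by it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateNormalizationError, SchemaError
from .model import DOSE_PARAMETER_PATH, PBTKModel
from .physiology import ObservationSite, organ_path_name
from .simulate import (
    ConcentrationProfile,
    SimulationSettings,
    observe,
    simulate,
    summary_metrics,
)

__all__ = [
    "SensitivitySettings",
    "SensitivityRecord",
    "SensitivityTable",
    "ClassificationThresholds",
    "DEFAULT_SITES",
    "rmsd",
    "sensitivity_for_parameter",
    "ensemble_sensitivity",
    "classify",
    "group_parameter",
    "load_max_sensitivity_table",
    "summarize",
]

logger = logging.getLogger(__name__)

#: Venous blood plasma plus the intracellular space of the two tox organs.
DEFAULT_SITES = (
    ObservationSite("venous_plasma"),
    ObservationSite("organ_intracellular", "brain"),
    ObservationSite("organ_intracellular", "gonads"),
)


@dataclass(frozen=True)
class SensitivitySettings:
    """Perturbation factors and observation sites."""

    perturbation_factor: float = 0.95
    dose_factor: float = 0.95
    sites: tuple[ObservationSite, ...] = DEFAULT_SITES

    def __post_init__(self) -> None:
        for attr in ("perturbation_factor", "dose_factor"):
            v = getattr(self, attr)
            if v <= 0 or v == 1.0:
                raise SchemaError(f"{attr} must be positive and != 1")
        if not self.sites:
            raise SchemaError("at least one observation site required")


@dataclass(frozen=True)
class SensitivityRecord:
    parameter_path: str
    model_id: str
    site: ObservationSite
    sens_rmsd: float
    sens_cmax: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.sens_rmsd) or self.sens_rmsd < 0:
            raise SchemaError("sens_rmsd must be finite and non-negative")


def rmsd(a: ConcentrationProfile, b: ConcentrationProfile) -> float:
    """Root-mean-square deviation of two profiles on the same grid,
    on the linear concentration scale."""
    if a.times.shape != b.times.shape or not np.array_equal(a.times, b.times):
        raise SchemaError("profiles are on different time grids")
    if a.site != b.site:
        raise SchemaError("profiles are from different observation sites")
    d = a.concentrations - b.concentrations
    return float(np.sqrt(np.mean(d * d)))


class _BaselineCache:
    """Baseline and dose-perturbed observations of one model, shared
    across all parameter perturbations."""

    def __init__(
        self,
        model: PBTKModel,
        settings: SensitivitySettings,
        sim_settings: SimulationSettings | None,
    ) -> None:
        self.model = model
        self.settings = settings
        self.sim_settings = sim_settings
        base = simulate(model, sim_settings)
        dosed = simulate(model.with_dose_factor(settings.dose_factor), sim_settings)
        self.c0 = {s: observe(base, s) for s in settings.sites}
        self.cdose = {s: observe(dosed, s) for s in settings.sites}
        for p in self.c0.values():
            p.role = "baseline"
        for p in self.cdose.values():
            p.role = "dose_perturbed"
        self.denom_rmsd = {s: rmsd(self.c0[s], self.cdose[s]) for s in settings.sites}
        self.cmax0 = {s: summary_metrics(self.c0[s])["cmax"] for s in settings.sites}
        self.denom_cmax = {
            s: abs(summary_metrics(self.cdose[s])["cmax"] - self.cmax0[s])
            for s in settings.sites
        }

    def records_for(self, path: str) -> list[SensitivityRecord]:
        if path == DOSE_PARAMETER_PATH:
            # the perturbed curve is the dose curve itself: the ratio is 1
            return [
                SensitivityRecord(path, self.model.model_id, s, 1.0, 1.0)
                for s in self.settings.sites
            ]
        perturbed = self.model.perturbed(path, self.settings.perturbation_factor)
        result = simulate(perturbed, self.sim_settings)
        out = []
        for s in self.settings.sites:
            ci = observe(result, s)
            ci.role = "parameter_perturbed"
            denom = self.denom_rmsd[s]
            if denom == 0.0:
                raise DegenerateNormalizationError(
                    f"dose perturbation leaves site {s.label()} unchanged in "
                    f"model {self.model.model_id}"
                )
            s_rmsd = rmsd(self.c0[s], ci) / denom
            dc = self.denom_cmax[s]
            s_cmax = (
                abs(summary_metrics(ci)["cmax"] - self.cmax0[s]) / dc
                if dc > 0
                else None
            )
            out.append(
                SensitivityRecord(path, self.model.model_id, s, s_rmsd, s_cmax)
            )
        return out


def sensitivity_for_parameter(
    model: PBTKModel,
    path: str,
    site: ObservationSite,
    settings: SensitivitySettings | None = None,
    sim_settings: SimulationSettings | None = None,
) -> SensitivityRecord:
    """Dose-normalized sensitivity of one parameter at one site."""
    settings = settings or SensitivitySettings()
    if site not in settings.sites:
        settings = SensitivitySettings(
            perturbation_factor=settings.perturbation_factor,
            dose_factor=settings.dose_factor,
            sites=(site,),
        )
    if path != DOSE_PARAMETER_PATH and path not in model.parameter_paths:
        raise SchemaError(f"unknown parameter path {path!r}")
    cache = _BaselineCache(model, settings, sim_settings)
    for rec in cache.records_for(path):
        if rec.site == site:
            return rec
    raise AssertionError("site not produced")  # pragma: no cover


@dataclass
class SensitivityTable:
    """All records of an ensemble run plus the per-parameter maximum."""

    records: list[SensitivityRecord]
    max_by_parameter: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.max_by_parameter:
            agg: dict[str, float] = {}
            for rec in self.records:
                prev = agg.get(rec.parameter_path)
                if prev is None or rec.sens_rmsd > prev:
                    agg[rec.parameter_path] = rec.sens_rmsd
            # descending by max, ties by path
            self.max_by_parameter = dict(
                sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter_path": [r.parameter_path for r in self.records],
                "model_id": [r.model_id for r in self.records],
                "site": [r.site.label() for r in self.records],
                "sens_rmsd": [r.sens_rmsd for r in self.records],
                "sens_cmax": [r.sens_cmax for r in self.records],
            }
        )


def ensemble_sensitivity(
    models: list[PBTKModel],
    settings: SensitivitySettings | None = None,
    sim_settings: SimulationSettings | None = None,
    parameter_paths: list[str] | None = None,
    progress: bool = False,
) -> SensitivityTable:
    """Sensitivities for every (model, parameter, site) combination.

    Parameters absent from a model (or with a zero baseline value, which a
    multiplicative perturbation cannot move) contribute no record for that
    model.
    """
    if not models:
        raise SchemaError("empty model list")
    settings = settings or SensitivitySettings()
    records: list[SensitivityRecord] = []
    for n, model in enumerate(models):
        cache = _BaselineCache(model, settings, sim_settings)
        paths = parameter_paths if parameter_paths is not None else model.parameter_paths
        for path in paths:
            if path not in model.parameter_paths:
                continue
            from .physiology import get_parameter

            if get_parameter(model.species, path) == 0.0:
                logger.warning(
                    "skipping %s in %s: baseline value is 0", path, model.model_id
                )
                continue
            records.extend(cache.records_for(path))
        if progress:
            logger.info("model %d/%d (%s) done", n + 1, len(models), model.model_id)
    return SensitivityTable(records=records)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Class boundaries: insensitive < 0.01 <= low < 0.1 <= moderate <= 0.4
    < sensitive; above 1 additionally flags a stronger-than-dose effect."""

    insensitive_below: float = 0.01
    low_below: float = 0.1
    moderate_max: float = 0.4
    above_dose: float = 1.0

    def __post_init__(self) -> None:
        seq = (self.insensitive_below, self.low_below, self.moderate_max, self.above_dose)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise SchemaError("thresholds must be strictly increasing")


CLASS_LABELS = ("insensitive", "low", "moderate", "sensitive")


def classify(sens: float, thresholds: ClassificationThresholds | None = None) -> str:
    """Class label for a sensitivity value (the moderate class includes its
    upper boundary)."""
    thresholds = thresholds or ClassificationThresholds()
    if sens < 0:
        raise SchemaError("sensitivity must be non-negative")
    if sens < thresholds.insensitive_below:
        return "insensitive"
    if sens < thresholds.low_below:
        return "low"
    if sens <= thresholds.moderate_max:
        return "moderate"
    return "sensitive"


_GIT_TRANSIT_LEAVES = (
    "Intestinal transit rate",
    "Gastric emptying time",
    "Small intestinal transit time",
    "Large intestinal transit time",
)
_GIT_GEOMETRY_LEAVES = (
    "Length",
    "Proximal radius",
    "Distal radius",
    "Effective surface area enhancement factor",
    "Fractional steady-state fill level",
)
_PLASMA_LEAVES = ("Haematocrit", "pH (plasma)", "pH (red blood cells)")
_VDC_ORGANS = ("Liver", "Kidney", "Muscle")


def group_parameter(path: str, tox_organs: list[str] | None = None) -> str:
    """Functional group of a parameter path.

    Groups: git_transit_times, git_pH, git_geometry, plasma_parameters,
    volume_distribution_clearance, tox_organ, other.  A parameter of a
    declared tox organ (volume, specific blood flow, tissue composition)
    wins over the generic volume/clearance group.
    """
    if "|" not in path or not path.startswith(("Organism|", "Application|")):
        raise SchemaError(f"malformed parameter path {path!r}")
    parts = path.split("|")
    leaf = parts[-1]
    tox_path_names = {organ_path_name(o) for o in (tox_organs or [])}

    if len(parts) >= 3 and parts[1] in tox_path_names and (
        leaf in ("Volume", "Specific blood flow rate") or leaf.startswith("Vf (")
    ):
        return "tox_organ"
    if "Lumen" in parts:
        if leaf == "pH":
            return "git_pH"
        if leaf in _GIT_GEOMETRY_LEAVES:
            return "git_geometry"
        if leaf in _GIT_TRANSIT_LEAVES:
            return "git_transit_times"
    if leaf in _GIT_TRANSIT_LEAVES:
        return "git_transit_times"
    if leaf in _PLASMA_LEAVES or leaf == "pH (intracellular)":
        return "plasma_parameters"
    if parts[1] in ("Plasma", "Interstitial", "BloodCells") and leaf.startswith("Vf ("):
        return "plasma_parameters"
    if leaf == "GFR (specific)":
        return "volume_distribution_clearance"
    if len(parts) >= 3 and parts[1] in _VDC_ORGANS and (
        leaf in ("Volume", "Specific blood flow rate") or leaf.startswith("Vf (")
    ):
        return "volume_distribution_clearance"
    return "other"


def load_max_sensitivity_table(path: str) -> dict[str, float]:
    """Read an externally supplied per-parameter maximum-sensitivity table.

    Accepts CSV or XLSX in either a long layout (a parameter-path column
    plus a single max-sensitivity column) or a wide layout (a path column
    plus one numeric column per model; the row-wise maximum over non-blank
    cells is taken).  Duplicate paths and non-numeric cells are errors.
    """
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if df.empty:
        raise SchemaError("empty sensitivity table")

    path_col = None
    for col in df.columns:
        if "path" in str(col).lower() or "parameter" in str(col).lower():
            path_col = col
            break
    if path_col is None:
        path_col = df.columns[0]
    paths = df[path_col].astype(str)
    if paths.duplicated().any():
        dup = paths[paths.duplicated()].iloc[0]
        raise SchemaError(f"duplicate parameter path {dup!r}")

    value_cols = [c for c in df.columns if c != path_col]
    if not value_cols:
        raise SchemaError("no sensitivity columns found")
    values = df[value_cols].copy()
    for col in value_cols:
        try:
            values[col] = pd.to_numeric(values[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric sensitivity in column {col!r}") from exc
    row_max = values.max(axis=1, skipna=True)
    if row_max.isna().any():
        raise SchemaError("a parameter row has no sensitivity value")
    return dict(zip(paths, row_max.astype(float)))


def summarize(
    max_map: dict[str, float],
    thresholds: ClassificationThresholds | None = None,
    top_k: int = 20,
    histogram_edges: list[float] | None = None,
) -> dict:
    """Class counts/fractions, a log-binned histogram and the top-k list."""
    if not max_map:
        raise SchemaError("empty sensitivity map")
    thresholds = thresholds or ClassificationThresholds()
    counts = {label: 0 for label in CLASS_LABELS}
    n_above_dose = 0
    for v in max_map.values():
        counts[classify(v, thresholds)] += 1
        if v > thresholds.above_dose:
            n_above_dose += 1
    total = len(max_map)
    fractions = {k: v / total for k, v in counts.items()}
    if histogram_edges is None:
        histogram_edges = list(np.logspace(-4, 1, 11))
    values = np.array(list(max_map.values()))
    hist, _ = np.histogram(values, bins=histogram_edges)
    ranked = sorted(max_map.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        "total": total,
        "counts": counts,
        "fractions": fractions,
        "n_above_dose": n_above_dose,
        "max_sensitivity": float(values.max()),
        "histogram": {"edges": list(histogram_edges), "counts": hist.tolist()},
        "top": [
            {"parameter_path": p, "max_sensitivity": float(v)}
            for p, v in ranked[:top_k]
        ],
    }
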