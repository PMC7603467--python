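"""End-to-end pipeline: ensemble construction, sensitivity analysis,
classification, grouping and report assembly.

A :class:`PipelineConfig` names either explicit model input files
(species + compound + protocol documents) or a synthetic seed for the
packaged reference ensemble — exactly one of the two.  Running the
pipeline writes ``sens.csv`` (every sensitivity record), ``summary.json``
(class counts, fractions, histogram, top-k) and ``report.md``; the
report embeds provenance (config hash, seed, package version) and is
byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compound import Compound, IonizationSpec
from .errors import ConfigError, SchemaError
from .model import PBTKModel, build_model
from .physiology import AdministrationProtocol, ObservationSite
from .registry import read_species_file
from .sensitivity import (
    ClassificationThresholds,
    SensitivitySettings,
    SensitivityTable,
    classify,
    ensemble_sensitivity,
    group_parameter,
    summarize,
)
from .simulate import SimulationSettings
from .synth import SyntheticConfig, make_reference_ensemble

__all__ = ["PipelineConfig", "Report", "run_pipeline", "load_pipeline_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Pipeline inputs: either explicit model files or a synthetic seed."""

    model_files: list[dict] = field(default_factory=list)
    synthetic_seed: int | None = None
    max_models: int | None = None
    sites: list[str] = field(default_factory=lambda: ["venous_plasma", "brain", "gonads"])
    perturbation_factor: float = 0.95
    dose_factor: float = 0.95
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    tox_organs: list[str] = field(default_factory=lambda: ["brain", "gonads"])
    simulation: SimulationSettings | None = None
    top_k: int = 20
    histogram_edges: list[float] | None = None
    output_dir: Path = Path("pbtk_out")
    make_plot: bool = False

    def __post_init__(self) -> None:
        if bool(self.model_files) == (self.synthetic_seed is not None):
            raise ConfigError(
                "provide exactly one of model_files or synthetic_seed"
            )

    def observation_sites(self) -> tuple[ObservationSite, ...]:
        out = []
        for s in self.sites:
            if s in ("venous_plasma", "peripheral_venous_plasma"):
                out.append(ObservationSite(s))
            else:
                out.append(ObservationSite("organ_intracellular", s))
        return tuple(out)

    def canonical(self) -> dict:
        return {
            "model_files": self.model_files,
            "synthetic_seed": self.synthetic_seed,
            "max_models": self.max_models,
            "sites": self.sites,
            "perturbation_factor": self.perturbation_factor,
            "dose_factor": self.dose_factor,
            "thresholds": [
                self.thresholds.insensitive_below,
                self.thresholds.low_below,
                self.thresholds.moderate_max,
                self.thresholds.above_dose,
            ],
            "tox_organs": self.tox_organs,
            "simulation": (
                None
                if self.simulation is None
                else [
                    self.simulation.t_end,
                    self.simulation.n_samples,
                    self.simulation.rel_tol,
                    self.simulation.abs_tol,
                ]
            ),
            "top_k": self.top_k,
            "histogram_edges": self.histogram_edges,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("pipeline config must be a mapping")
    kwargs: dict = {}
    for key in (
        "model_files",
        "synthetic_seed",
        "max_models",
        "sites",
        "perturbation_factor",
        "dose_factor",
        "tox_organs",
        "top_k",
        "histogram_edges",
        "make_plot",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "thresholds" in doc:
        kwargs["thresholds"] = ClassificationThresholds(**doc["thresholds"])
    if "simulation" in doc:
        kwargs["simulation"] = SimulationSettings(**doc["simulation"])
    if "output_dir" in doc:
        kwargs["output_dir"] = Path(doc["output_dir"])
    unknown = set(doc) - set(kwargs) - {"thresholds", "simulation", "output_dir"}
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def _compound_from_dict(d: dict) -> Compound:
    d = dict(d)
    ion = d.pop("ionization", None)
    if ion is not None:
        d["ionization"] = IonizationSpec(**ion)
    return Compound(**d)


def load_models(entries: list[dict]) -> list[PBTKModel]:
    """Build models from config entries naming species/compound/protocol
    documents (YAML or JSON)."""
    models = []
    for entry in entries:
        species = read_species_file(entry["species"])
        cdoc = yaml.safe_load(Path(entry["compound"]).read_text())
        compound = _compound_from_dict(cdoc)
        pdoc = yaml.safe_load(Path(entry["protocol"]).read_text())
        protocol = AdministrationProtocol(**pdoc)
        models.append(build_model(species, compound, protocol))
    return models


@dataclass
class Report:
    """Assembled pipeline output."""

    summary: dict
    groups: dict[str, str]
    table: SensitivityTable
    provenance: dict

    def to_markdown(self) -> str:
        s = self.summary
        lines = [
            "# Parameter sensitivity report",
            "",
            f"Provenance: config {self.provenance['config_hash']}, "
            f"seed {self.provenance['seed']}, pbtkit {self.provenance['version']}",
            "",
            f"Parameters analysed: {s['total']}; records: "
            f"{len(self.table.records)}; maximum sensitivity "
            f"{s['max_sensitivity']:.4g}; {s['n_above_dose']} parameter(s) "
            "exceed the dose effect (sensitivity > 1).",
            "",
            "## Sensitivity classes",
            "",
            "| class | count | fraction |",
            "|---|---|---|",
        ]
        for label, count in s["counts"].items():
            lines.append(f"| {label} | {count} | {100*s['fractions'][label]:.1f}% |")
        lines += [
            "",
            "## Histogram of maximum sensitivities (log-spaced bins)",
            "",
            "| bin | count |",
            "|---|---|",
        ]
        edges = s["histogram"]["edges"]
        for (lo, hi), count in zip(zip(edges, edges[1:]), s["histogram"]["counts"]):
            lines.append(f"| {lo:.3g} – {hi:.3g} | {count} |")
        lines += ["", f"## Top {len(s['top'])} parameters", "",
                  "| rank | parameter | max sensitivity | group |", "|---|---|---|---|"]
        for rank, item in enumerate(s["top"], 1):
            p = item["parameter_path"]
            lines.append(
                f"| {rank} | {p} | {item['max_sensitivity']:.4g} | "
                f"{self.groups.get(p, 'other')} |"
            )
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> Report:
    """Build or load the model ensemble, run the sensitivity analysis,
    classify and group, and write the artifact files."""
    if config.synthetic_seed is not None:
        models = make_reference_ensemble(SyntheticConfig(seed=config.synthetic_seed))
        seed = config.synthetic_seed
    else:
        models = load_models(config.model_files)
        seed = None
    if config.max_models is not None:
        models = models[: config.max_models]
    logger.info("ensemble: %d models", len(models))

    settings = SensitivitySettings(
        perturbation_factor=config.perturbation_factor,
        dose_factor=config.dose_factor,
        sites=config.observation_sites(),
    )
    table = ensemble_sensitivity(
        models, settings, sim_settings=config.simulation, progress=True
    )
    summary = summarize(
        table.max_by_parameter,
        config.thresholds,
        top_k=config.top_k,
        histogram_edges=config.histogram_edges,
    )
    groups = {
        path: group_parameter(path, config.tox_organs)
        for path in table.max_by_parameter
    }
    summary["class_by_parameter"] = {
        p: classify(v, config.thresholds) for p, v in table.max_by_parameter.items()
    }
    report = Report(
        summary=summary,
        groups=groups,
        table=table,
        provenance={
            "config_hash": config.config_hash(),
            "seed": seed,
            "version": __version__,
        },
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.to_dataframe()
    df.to_csv(out / "sens.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps({"summary": summary, "groups": groups,
                    "provenance": report.provenance}, indent=2)
    )
    (out / "report.md").write_text(report.to_markdown())
    if config.make_plot:
        _write_histogram(summary, out / "histogram.png")
    logger.info("report written to %s", out)
    return report


def _write_histogram(summary: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = summary["histogram"]["edges"]
    counts = summary["histogram"]["counts"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(counts)), counts, width=0.9)
    ax.set_xticks(range(len(counts)))
    ax.set_xticklabels(
        [f"{lo:.2g}–{hi:.2g}" for lo, hi in zip(edges, edges[1:])],
        rotation=45,
        ha="right",
        fontsize=7,
    )
    ax.set_xlabel("maximum sensitivity")
    ax.set_ylabel("parameters")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
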