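"""Executable best-practice checklist for building a new species model,
plus the factor-of-2 validation comparator.

The checklist encodes the standard stepwise procedure: choose a template
species with similar physiology (and, for oral dosing, a similar food
spectrum), scale it allometrically, decide the administration route,
identify the gastrointestinal parameter groups only when oral absorption
matters, always identify the non-GIT groups (plasma parameters; volume of
distribution and clearance), parameterize any declared tox organs, and
finally validate simulations against observed concentrations with a
typical acceptance factor of 2 between model and mean observation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ObservationError, SchemaError
from .physiology import MANDATORY_ORGANS, organ_path_name
from .simulate import ConcentrationProfile

__all__ = ["WorkflowContext", "ChecklistStep", "Checklist", "ValidationResult",
           "build_checklist", "validate_model"]


@dataclass(frozen=True)
class WorkflowContext:
    """Inputs of the checklist generator.

    ``has_species_specific_data`` maps a parameter group name to whether
    measured values exist for the target species; groups with data are
    marked "use species-specific value", the rest fall back to
    literature review, interspecies scaling or targeted experiments.
    """

    target_species_name: str
    template_species: str
    target_bw: float
    routes: frozenset[str] = frozenset({"iv"})
    tox_organs: tuple[str, ...] = ()
    has_species_specific_data: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.routes:
            raise SchemaError("at least one administration route required")
        if not self.routes <= {"iv", "oral"}:
            raise SchemaError(f"unknown routes {self.routes - {'iv', 'oral'}}")
        for organ in self.tox_organs:
            if organ not in MANDATORY_ORGANS:
                raise SchemaError(f"unknown tox organ {organ!r}")


@dataclass
class ChecklistStep:
    step_id: str
    title: str
    required: bool
    parameter_groups: list[str]
    rationale: str
    status: str = "open"


@dataclass
class Checklist:
    """Ordered workflow steps for one target-species model build."""

    context: WorkflowContext
    steps: list[ChecklistStep]

    def to_markdown(self) -> str:
        lines = [
            f"# PBTK model build checklist: {self.context.target_species_name}",
            "",
            f"Template: {self.context.template_species}; "
            f"target body weight: {self.context.target_bw} kg; "
            f"routes: {', '.join(sorted(self.context.routes))}",
            "",
        ]
        for i, step in enumerate(self.steps, 1):
            marker = "required" if step.required else "optional"
            lines.append(f"{i}. **{step.title}** ({marker}; {step.status})")
            if step.parameter_groups:
                lines.append(f"   - groups: {', '.join(step.parameter_groups)}")
            lines.append(f"   - {step.rationale}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_species": self.context.target_species_name,
                "template_species": self.context.template_species,
                "target_bw": self.context.target_bw,
                "routes": sorted(self.context.routes),
                "tox_organs": list(self.context.tox_organs),
                "steps": [
                    {
                        "step_id": s.step_id,
                        "title": s.title,
                        "required": s.required,
                        "parameter_groups": s.parameter_groups,
                        "rationale": s.rationale,
                        "status": s.status,
                    }
                    for s in self.steps
                ],
            },
            indent=2,
        )


def _data_status(ctx: WorkflowContext, group: str) -> str:
    if ctx.has_species_specific_data.get(group, False):
        return "use species-specific value"
    return "literature / scaling / experiment"


def build_checklist(ctx: WorkflowContext) -> Checklist:
    """The fixed-order workflow checklist for ``ctx``.

    GIT steps are required only when the oral route is considered;
    the non-GIT steps are always required; one parameterization step is
    emitted per declared tox organ.
    """
    oral = "oral" in ctx.routes
    steps: list[ChecklistStep] = [
        ChecklistStep(
            "template",
            f"Choose template model ({ctx.template_species})",
            True,
            [],
            "Pick an established species model of similar physiology and "
            "weight; for oral dosing a similar food spectrum matters because "
            "it shapes the gastrointestinal tract (advisory).",
            status="chosen",
        ),
        ChecklistStep(
            "allometric_scaling",
            f"Allometric scaling to {ctx.target_bw} kg",
            True,
            [],
            "Scale organ weights linearly to the target body weight; scale "
            "gut lumen volume with BW^1.06 and surface with BW^0.76.",
        ),
        ChecklistStep(
            "route",
            f"Route decision: {', '.join(sorted(ctx.routes))}",
            True,
            [],
            "If oral absorption is not of interest the template's GIT can be "
            "kept without any parameter changes.",
            status="decided",
        ),
        ChecklistStep(
            "git_parameters",
            "Identify GIT parameters",
            oral,
            ["git_transit_times", "git_pH", "git_geometry"],
            "Intestinal transit times, pH and geometry drive oral "
            "bioavailability; "
            + (
                "; ".join(
                    f"{g}: {_data_status(ctx, g)}"
                    for g in ("git_transit_times", "git_pH", "git_geometry")
                )
                if oral
                else "not needed for purely intravenous use."
            ),
        ),
        ChecklistStep(
            "non_git_parameters",
            "Identify non-GIT parameters",
            True,
            ["plasma_parameters", "volume_distribution_clearance"],
            "Plasma parameters and the volume-of-distribution/clearance "
            "group matter for every route; "
            + "; ".join(
                f"{g}: {_data_status(ctx, g)}"
                for g in ("plasma_parameters", "volume_distribution_clearance")
            ),
        ),
        ChecklistStep(
            "tox_organ_decision",
            "Decide on additional tox organs",
            True,
            [],
            "Organ-specific exposure (e.g. brain for behavioural, gonads for "
            "reproductive effects) requires organ-specific parameterization.",
            status="decided",
        ),
    ]
    for organ in ctx.tox_organs:
        steps.append(
            ChecklistStep(
                f"tox_organ:{organ}",
                f"Parameterize tox organ {organ}",
                True,
                ["tox_organ"],
                f"Set volume, specific blood flow rate and tissue composition "
                f"of {organ} (paths under Organism|{organ_path_name(organ)}|...); "
                f"tox_organ: {_data_status(ctx, 'tox_organ')}.",
            )
        )
    steps.append(
        ChecklistStep(
            "validation",
            "Validate against observed concentration data",
            True,
            [],
            "Compare simulations with observations in the target species; "
            "differences beyond a factor of 2 between mean observation and "
            "model call for inspection.  Precedent: a rabbit reference model "
            "qualified with 6 compounds over 8 datasets (guidance only; the "
            "number of compounds is case specific).",
        )
    )
    return Checklist(context=ctx, steps=steps)


@dataclass
class ValidationResult:
    """Outcome of the factor-of-2 comparison for one profile."""

    fold_error: float
    threshold: float
    verdict: str
    notes: str = ""

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def validate_model(
    predicted: ConcentrationProfile,
    observed: ConcentrationProfile,
    threshold: float = 2.0,
) -> ValidationResult:
    """Geometric-mean fold error between prediction and observation.

    The prediction is linearly interpolated onto the observation times and
    the fold error is exp(|mean(log(pred/obs))|); the verdict is a pass
    when it does not exceed ``threshold`` (default 2, adjustable to the
    uncertainty and variability of the measurements).
    """
    if observed.times.size == 0:
        raise SchemaError("empty observation profile")
    if np.any(observed.concentrations <= 0):
        raise SchemaError("observations must be strictly positive")
    if (
        observed.times[0] < predicted.times[0]
        or observed.times[-1] > predicted.times[-1]
    ):
        raise ObservationError("observation times outside the predicted span")
    pred = np.interp(observed.times, predicted.times, predicted.concentrations)
    if np.any(pred <= 0):
        raise SchemaError("prediction is non-positive at an observation time")
    log_ratio = np.log(pred / observed.concentrations)
    fold = float(math.exp(abs(float(np.mean(log_ratio)))))
    verdict = "pass" if fold <= threshold else "fail"
    notes = f"geometric mean fold error over {observed.times.size} samples"
    return ValidationResult(
        fold_error=fold, threshold=threshold, verdict=verdict, notes=notes
    )
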