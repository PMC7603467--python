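"""Compound descriptions: physicochemistry, ionization and clearance routes.

A compound is the substance-specific half of a PBTK model, strictly
separated from the physiology of the organism.  Only passive processes are
described: lipophilicity (logP), a single optional ionizable group, plasma
protein binding via the unbound fraction ``fu``, intestinal permeability,
aqueous solubility, and three first-order clearance drivers (hepatic
metabolism, glomerular filtration, tubular secretion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import SchemaError

__all__ = ["IonizationSpec", "Compound", "neutral_fraction"]

_ION_KINDS = ("neutral", "monoprotic_acid", "monoprotic_base")


@dataclass
class IonizationSpec:
    """Ionization behaviour of a compound.

    kind
        ``neutral``, ``monoprotic_acid`` or ``monoprotic_base``.
    pKa
        Acid dissociation constant; required exactly when ``kind`` is not
        neutral, and must lie in the open interval (0, 14).
    """

    kind: str = "neutral"
    pKa: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _ION_KINDS:
            raise SchemaError(f"unknown ionization kind {self.kind!r}")
        if self.kind == "neutral":
            if self.pKa is not None:
                raise SchemaError("pKa must be absent for a neutral compound")
        else:
            if self.pKa is None:
                raise SchemaError(f"pKa required for kind {self.kind!r}")
            if not 0.0 < float(self.pKa) < 14.0:
                raise SchemaError(f"pKa {self.pKa} outside (0, 14)")


def neutral_fraction(ion: IonizationSpec, pH: float) -> float:
    """Henderson–Hasselbalch fraction of the neutral microspecies at ``pH``.

    Returns 1 for a neutral compound, ``1/(1+10**(pH-pKa))`` for a
    monoprotic acid and ``1/(1+10**(pKa-pH))`` for a monoprotic base.
    The result is always in (0, 1].
    """
    if ion.kind == "neutral":
        return 1.0
    if ion.kind == "monoprotic_acid":
        return 1.0 / (1.0 + 10.0 ** (pH - ion.pKa))
    return 1.0 / (1.0 + 10.0 ** (ion.pKa - pH))


@dataclass
class Compound:
    """A small-molecule compound parameterization.

    Units: molecular_weight g/mol; effective_permeability cm/min;
    specific clearances 1/min per litre of eliminating organ;
    solubility µmol/L (``math.inf`` for an effectively unbounded
    solubility, which makes the whole model linear in dose).
    ``gfr_fraction`` is the fraction of the glomerular filtration rate
    available to filter unbound drug (1 for a freely filtered compound).
    """

    name: str
    molecular_weight: float
    logP: float
    ionization: IonizationSpec = field(default_factory=IonizationSpec)
    fraction_unbound_plasma: float = 1.0
    effective_permeability: float = 0.0
    specific_hepatic_clearance: float = 0.0
    specific_tubular_secretion: float = 0.0
    gfr_fraction: float = 0.0
    solubility: float = math.inf

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise SchemaError("molecular_weight must be positive")
        fu = self.fraction_unbound_plasma
        if not 0.0 < fu <= 1.0:
            raise SchemaError(f"fraction_unbound_plasma {fu} outside (0, 1]")
        for attr in (
            "effective_permeability",
            "specific_hepatic_clearance",
            "specific_tubular_secretion",
        ):
            if getattr(self, attr) < 0:
                raise SchemaError(f"{attr} must be non-negative")
        if not 0.0 <= self.gfr_fraction <= 1.0:
            raise SchemaError("gfr_fraction outside [0, 1]")
        if not self.solubility > 0:
            raise SchemaError("solubility must be positive or unbounded")
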