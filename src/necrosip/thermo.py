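"""In-situ Gibbs energy of acetoclastic sulfate reduction.

For the reaction

    CH3COO- + SO4^2- -> 2 HCO3- + HS-

the actual energy yield under in-situ conditions is

    dG = dG0(T, p) + R T ln Q,      Q = a(HCO3-)^2 a(HS-) / (a(Ac-) a(SO4^2-))

with R the molar gas constant and all activities dimensionless (gamma * c /
1 mol/L when concentrations and activity coefficients are supplied).  The
standard-state dG0(T, p) is an *input* — it comes from thermodynamic property
tables (e.g. SUPCRT92-style computations) and is not recomputed here.  The
result is compared against the energetic limit of microbial sulfate
reduction, conventionally about -30 kJ/mol (more negative = still exergonic
enough to sustain the process).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .io import ValidationError

__all__ = [
    "R_GAS",
    "REACTION_SPECIES",
    "STOICHIOMETRY",
    "ReactionConditions",
    "EnergyResult",
    "reaction_quotient",
    "delta_g",
    "davies_log10_gamma",
]

R_GAS = 8.314462618  # J mol-1 K-1

# acetate- + sulfate -> 2 bicarbonate + bisulfide
STOICHIOMETRY: Mapping[str, int] = {
    "acetate": -1,
    "sulfate": -1,
    "bicarbonate": 2,
    "bisulfide": 1,
}
REACTION_SPECIES = tuple(STOICHIOMETRY)


@dataclass(frozen=True)
class ReactionConditions:
    """Temperature, standard-state energy and species activities.

    Either ``activities`` or both ``concentrations`` (mol/L) and
    ``activity_coefficients`` must be given; in the latter case
    activity = gamma * c / c0 with c0 = 1 mol/L.
    """

    temperature_K: float
    delta_g0_kJ_per_mol: float
    activities: Mapping[str, float] | None = None
    concentrations: Mapping[str, float] | None = None
    activity_coefficients: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValidationError("temperature must be positive (Kelvin)")
        if self.activities is None:
            if self.concentrations is None or self.activity_coefficients is None:
                raise ValidationError(
                    "provide activities, or concentrations plus activity_coefficients"
                )
        resolved = self.resolve_activities()
        missing = [s for s in REACTION_SPECIES if s not in resolved]
        if missing:
            raise ValidationError(f"missing species: {missing}")
        if any(a <= 0 for a in resolved.values()):
            raise ValidationError("all activities must be positive")

    def resolve_activities(self) -> dict[str, float]:
        if self.activities is not None:
            return {k: float(v) for k, v in self.activities.items()}
        assert self.concentrations is not None and self.activity_coefficients is not None
        out = {}
        for sp, c in self.concentrations.items():
            gamma = self.activity_coefficients.get(sp)
            if gamma is None:
                raise ValidationError(f"no activity coefficient for {sp!r}")
            out[sp] = float(gamma) * float(c)  # / c0 = 1 mol/L
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReactionConditions":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: not a mapping")
        return cls(
            temperature_K=float(data["temperature_K"]),
            delta_g0_kJ_per_mol=float(data["delta_g0_kJ_per_mol"]),
            activities=data.get("activities"),
            concentrations=data.get("concentrations"),
            activity_coefficients=data.get("activity_coefficients"),
        )


@dataclass(frozen=True)
class EnergyResult:
    delta_g_kJ_per_mol: float
    reaction_quotient: float
    limit_kJ_per_mol: float
    above_limit: bool  # True when more exergonic than the limit (dG < limit)

    def summary(self) -> str:
        verdict = (
            "more exergonic than the limit (process energetically feasible)"
            if self.above_limit
            else "less exergonic than the limit"
        )
        return (
            f"dG = {self.delta_g_kJ_per_mol:.1f} kJ/mol (Q = {self.reaction_quotient:.3e});"
            f" limit {self.limit_kJ_per_mol:.1f} kJ/mol -> {verdict}"
        )


def reaction_quotient(conditions: ReactionConditions) -> float:
    """Mass-action quotient Q = a(HCO3-)^2 a(HS-) / (a(Ac-) a(SO4^2-))."""
    a = conditions.resolve_activities()
    q = 1.0
    for species, nu in STOICHIOMETRY.items():
        q *= a[species] ** nu
    return q


def delta_g(
    conditions: ReactionConditions, limit_kJ_per_mol: float = -30.0
) -> EnergyResult:
    """Actual Gibbs energy of the reaction: dG = dG0(T,p) + R T ln Q, in kJ/mol.

    Negative dG = exergonic; ``above_limit`` is True when dG is below
    (more negative than) the energetic limit.
    """
    q = reaction_quotient(conditions)
    dg = conditions.delta_g0_kJ_per_mol + (
        R_GAS * conditions.temperature_K * math.log(q)
    ) / 1000.0
    return EnergyResult(
        delta_g_kJ_per_mol=dg,
        reaction_quotient=q,
        limit_kJ_per_mol=limit_kJ_per_mol,
        above_limit=dg < limit_kJ_per_mol,
    )


def davies_log10_gamma(charge: int, ionic_strength: float, a_dh: float = 0.5092) -> float:
    """Davies-equation activity-coefficient estimate (log10 gamma).

    log10 gamma = -A z^2 ( sqrt(I)/(1+sqrt(I)) - 0.3 I ), valid to I ~ 0.5 M.
    A helper for building condition files when only concentrations are known;
    the main computation accepts activities directly.
    """
    if ionic_strength < 0:
        raise ValidationError("ionic strength must be non-negative")
    s = math.sqrt(ionic_strength)
    return -a_dh * charge**2 * (s / (1.0 + s) - 0.3 * ionic_strength)
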