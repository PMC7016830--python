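"""Dose-volume constraint sets and per-patient DVH compliance evaluation.

Constraints are upper limits on D_v% or D_vcc in a stated RBE language;
evaluating a DVH against a set of the other language raises, since a
LEM-language curve compared against MKM-language limits (or vice versa)
is exactly the mistake the translation analysis exists to prevent.
Boundary equality counts as compliant, with a small reporting-rounding
tolerance (0.05 Gy(RBE)). ``hard`` vs ``soft`` priorities only label
severity; they never change pass/fail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .dvh import DVH, VolumeSpec, dose_at_volume

__all__ = [
    "Constraint",
    "ConstraintSet",
    "ComplianceRow",
    "evaluate",
    "cohort_compliance",
    "BUILTIN_CONSTRAINT_SETS",
    "get_constraint_set",
]

DOSE_TOLERANCE = 0.05  # Gy(RBE); allows for one-decimal reporting rounding

Priority = Literal["hard", "soft"]


@dataclass(frozen=True)
class Constraint:
    metric: VolumeSpec
    limit: float
    rbe_model: Literal["LEM", "MKM"]
    priority: Priority = "hard"

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValueError("dose limit must be positive")
        if self.priority not in ("hard", "soft"):
            raise ValueError("priority must be 'hard' or 'soft'")

    def label(self) -> str:
        return f"{self.metric.label()}<={self.limit:g}Gy(RBE)[{self.rbe_model}]"


@dataclass(frozen=True)
class ConstraintSet:
    name: str
    constraints: tuple[Constraint, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        constraints = tuple(self.constraints)
        specs = [(c.metric.kind, c.metric.amount) for c in constraints]
        if len(set(specs)) != len(specs):
            raise ValueError("duplicate metric specs within a constraint set")
        object.__setattr__(self, "constraints", constraints)


@dataclass(frozen=True)
class ComplianceRow:
    patient_id: str
    constraint: Constraint
    observed: float
    passed: bool
    margin: float  # limit - observed; negative when exceeded


# Built-in clinical sets. OLD_MKM are the NIRS-derived 16-fraction rectum
# limits (D20%/D10% may be compromised for target coverage); SACRUM_PRV is
# the stricter variant applied to a 5 mm-expanded rectum for sacral cases;
# TRANSLATED_LEM are the lower-95%-CI LEM-language translations of OLD_MKM;
# NEW_CC are the redefined absolute-volume limits.
BUILTIN_CONSTRAINT_SETS: dict[str, ConstraintSet] = {
    "OLD_MKM": ConstraintSet(
        name="OLD_MKM",
        constraints=(
            Constraint(VolumeSpec("percent", 20), 28.8, "MKM", "soft"),
            Constraint(VolumeSpec("percent", 10), 46.4, "MKM", "soft"),
            Constraint(VolumeSpec("percent", 5), 60.0, "MKM", "hard"),
            Constraint(VolumeSpec("percent", 1), 66.0, "MKM", "hard"),
        ),
        provenance="NIRS 16-fraction rectum D_MKM|v limits",
    ),
    "SACRUM_PRV": ConstraintSet(
        name="SACRUM_PRV",
        constraints=(
            Constraint(VolumeSpec("percent", 5), 56.0, "MKM", "hard"),
            Constraint(VolumeSpec("percent", 1), 61.0, "MKM", "hard"),
        ),
        provenance="rectum + 5 mm PRV limits for sacral chordoma plans (expansion applied upstream)",
    ),
    "TRANSLATED_LEM": ConstraintSet(
        name="TRANSLATED_LEM",
        constraints=(
            Constraint(VolumeSpec("percent", 20), 38.7, "LEM", "soft"),
            Constraint(VolumeSpec("percent", 10), 54.7, "LEM", "soft"),
            Constraint(VolumeSpec("percent", 5), 65.1, "LEM", "hard"),
            Constraint(VolumeSpec("percent", 1), 69.3, "LEM", "hard"),
        ),
        provenance="lower 95% CI bounds of the quadratic LEM translation of OLD_MKM",
    ),
    "NEW_CC": ConstraintSet(
        name="NEW_CC",
        constraints=(
            Constraint(VolumeSpec("cc", 1), 66.0, "LEM", "hard"),
            Constraint(VolumeSpec("cc", 5), 61.0, "LEM", "hard"),
            Constraint(VolumeSpec("cc", 10), 54.0, "LEM", "soft"),
        ),
        provenance="redefined absolute-volume rectum limits for 16-fraction pelvic plans",
    ),
}


def get_constraint_set(name: str) -> ConstraintSet:
    try:
        return BUILTIN_CONSTRAINT_SETS[name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_CONSTRAINT_SETS))
        raise KeyError(f"unknown constraint set {name!r}; built-ins: {known}") from None


def evaluate(
    dvh: DVH,
    cset: ConstraintSet,
    tolerance: float = DOSE_TOLERANCE,
) -> list[ComplianceRow]:
    """One compliance row per constraint for a single patient DVH."""
    rows = []
    for constraint in cset.constraints:
        if constraint.rbe_model != dvh.rbe_model:
            raise ValueError(
                "RBE-language mismatch: "
                f"DVH is {dvh.rbe_model}, constraint {constraint.label()} is "
                f"{constraint.rbe_model}"
            )
        observed = dose_at_volume(dvh, constraint.metric)
        rows.append(
            ComplianceRow(
                patient_id=dvh.patient_id or dvh.structure,
                constraint=constraint,
                observed=observed,
                passed=observed <= constraint.limit + tolerance,
                margin=constraint.limit - observed,
            )
        )
    return rows


def cohort_compliance(reports: Sequence[Sequence[ComplianceRow]]) -> pd.DataFrame:
    """Fraction of patients exceeding each constraint across a cohort."""
    if len(reports) == 0:
        raise ValueError("at least one patient report is required")
    records = []
    for rows in reports:
        for row in rows:
            records.append(
                {
                    "constraint": row.constraint.label(),
                    "priority": row.constraint.priority,
                    "failed": not row.passed,
                }
            )
    frame = pd.DataFrame(records)
    out = (
        frame.groupby(["constraint", "priority"], sort=False)["failed"]
        .agg(n_patients="count", n_failures="sum", exceedance_fraction="mean")
        .reset_index()
    )
    out["exceedance_percent"] = (out["exceedance_fraction"] * 100).round(1)
    return out


def compliance_frame(reports: Sequence[Sequence[ComplianceRow]]) -> pd.DataFrame:
    """Long-format per-patient x constraint table for CSV export."""
    records = []
    for rows in reports:
        for row in rows:
            records.append(
                {
                    "patient_id": row.patient_id,
                    "constraint": row.constraint.label(),
                    "metric": row.constraint.metric.label(),
                    "rbe_model": row.constraint.rbe_model,
                    "priority": row.constraint.priority,
                    "observed_gy_rbe": row.observed,
                    "limit_gy_rbe": row.constraint.limit,
                    "passed": row.passed,
                    "margin_gy_rbe": row.margin,
                }
            )
    return pd.DataFrame(records)
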