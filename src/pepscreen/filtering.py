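"""The candidate filter cascade: safety, stability, consensus, pose energy.

Screened peptides pass through a conjunction of independent gates applied
in a documented order (toxicity -> bitterness -> plasma stability ->
intestinal stability), then per-class confirmation by consensus across
prediction platforms, an optional score-threshold gate, and finally a
binding-energy triage over externally supplied docking/MD pose tables.

Default boundary semantics (all overridable through :class:`Thresholds`):

* toxicity: any peptide called toxic is excluded;
* bitterness: excluded when the score is strictly above 333;
* plasma half-life: retained when >= 800 s (inclusive);
* intestinal half-life: retained when strictly > 1.0 s;
* pose energy: retained when the mean is <= -30 kcal/mol (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError, SchemaError
from .predictors import BIOACTIVITY_CLASSES


@dataclass(frozen=True)
class Thresholds:
    """Filter-cascade cutoffs with the workflow's published defaults."""

    bitterness_max: float = 333.0       # dimensionless score; exclude strictly above
    plasma_min_s: float = 800.0         # seconds; retain at or above
    intestinal_min_s: float = 1.0       # seconds; retain strictly above
    energy_cutoff_kcal: float = -30.0   # kcal/mol; retain at or below


@dataclass(frozen=True)
class SafetyVerdict:
    """Externally predicted safety/stability properties of one peptide."""

    sequence: str
    toxic: bool
    bitterness_score: float
    plasma_half_life_s: float
    intestinal_half_life_s: float

    def __post_init__(self) -> None:
        if self.plasma_half_life_s < 0 or self.intestinal_half_life_s < 0:
            raise InputError(f"negative half-life for {self.sequence!r}")


@dataclass(frozen=True)
class FilterAudit:
    """Outcome of the cascade for one peptide.

    ``failed_at`` names the first failing gate in evaluation order
    (toxicity, bitterness, plasma, intestinal) or is None for survivors.
    """

    sequence: str
    retained: bool
    failed_at: str | None


def apply_safety_filters(
    peptides: Sequence[str],
    verdicts: Mapping[str, SafetyVerdict],
    thresholds: Thresholds = Thresholds(),
) -> tuple[list[str], list[FilterAudit]]:
    """Run the safety/stability cascade over ``peptides``.

    Retention is the conjunction of the four gates, so the outcome does not
    depend on gate order; only the audit trail's ``failed_at`` does.
    A peptide without a verdict raises :class:`InputError`.
    """
    survivors: list[str] = []
    audit: list[FilterAudit] = []
    for pep in peptides:
        verdict = verdicts.get(pep)
        if verdict is None:
            raise InputError(f"no safety verdict for peptide {pep!r}")
        failed = None
        if verdict.toxic:
            failed = "toxicity"
        elif verdict.bitterness_score > thresholds.bitterness_max:
            failed = "bitterness"
        elif verdict.plasma_half_life_s < thresholds.plasma_min_s:
            failed = "plasma"
        elif verdict.intestinal_half_life_s <= thresholds.intestinal_min_s:
            failed = "intestinal"
        retained = failed is None
        if retained:
            survivors.append(pep)
        audit.append(FilterAudit(sequence=pep, retained=retained, failed_at=failed))
    return survivors, audit


@dataclass(frozen=True)
class ConsensusPolicy:
    """How many platforms must agree before a class call is confirmed.

    The default ``m = None`` is the all-positive rule; an integer ``m``
    gives the m-of-n generalization.
    """

    class_label: str
    platforms: tuple[str, ...]
    m: int | None = None

    def __post_init__(self) -> None:
        if not self.platforms:
            raise InputError("consensus policy needs at least one platform")
        if self.m is not None and not 1 <= self.m <= len(self.platforms):
            raise InputError(
                f"m={self.m} outside 1..{len(self.platforms)} for {self.class_label}"
            )

    @property
    def required(self) -> int:
        return len(self.platforms) if self.m is None else self.m


def consensus_bioactivity(
    peptide: str,
    platform_calls: Mapping[str, bool],
    policy: ConsensusPolicy,
) -> bool:
    """True when enough of the policy's platforms call ``peptide`` positive."""
    unknown = set(platform_calls) - set(policy.platforms)
    if unknown:
        raise InputError(f"calls from unknown platforms {sorted(unknown)} for {peptide!r}")
    missing = set(policy.platforms) - set(platform_calls)
    if missing:
        raise InputError(f"missing platform calls {sorted(missing)} for {peptide!r}")
    positives = sum(bool(platform_calls[p]) for p in policy.platforms)
    return positives >= policy.required


def score_threshold_gate(
    peptide_scores: Mapping[str, float],
    class_label: str,
    threshold: float,
    direction: str = "greater",
) -> bool:
    """Gate one class score against a platform threshold.

    ``direction`` is ``"greater"`` (strictly above, the default reading of
    'exceeding'), ``"greater-or-equal"``, or ``"less"`` (strictly below).
    """
    if class_label not in peptide_scores:
        raise InputError(f"no score for class {class_label!r}")
    score = float(peptide_scores[class_label])
    if direction == "greater":
        return score > threshold
    if direction == "greater-or-equal":
        return score >= threshold
    if direction == "less":
        return score < threshold
    raise InputError(f"unknown gate direction {direction!r}")


@dataclass(frozen=True)
class PoseEnergy:
    """An externally computed end-state binding energy for one docked pose."""

    sequence: str
    target: str
    pose: int
    energy_mean: float  # kcal/mol
    energy_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.energy_sd < 0:
            raise InputError(f"negative energy sd for {self.sequence!r}")


def read_pose_table(path) -> list[PoseEnergy]:
    """Load a pose-energy TSV (sequence, target, pose, energy_mean, energy_sd)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "target", "pose", "energy_mean"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"pose table {path} lacks columns {sorted(missing)}")
    poses = []
    for row in df.itertuples(index=False):
        try:
            mean = float(row.energy_mean)
            sd = float(getattr(row, "energy_sd", 0.0) or 0.0)
        except (TypeError, ValueError):
            raise InputError(
                f"non-numeric energy for pose {row.sequence!r}/{row.target!r}"
            ) from None
        poses.append(
            PoseEnergy(
                sequence=str(row.sequence),
                target=str(row.target),
                pose=int(row.pose),
                energy_mean=mean,
                energy_sd=sd,
            )
        )
    return poses


def filter_poses_by_energy(
    poses: Iterable[PoseEnergy], cutoff: float = -30.0
) -> list[PoseEnergy]:
    """Keep poses with mean energy <= ``cutoff``, ranked most negative first.

    The sort is stable and ties on the mean break by (peptide sequence,
    pose index).
    """
    retained = [p for p in poses if p.energy_mean <= cutoff]
    retained.sort(key=lambda p: (p.energy_mean, p.sequence, p.pose))
    return retained
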