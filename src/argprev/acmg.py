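"""Combine ACMG/AMP evidence criteria into a five-tier classification.

Two rule systems are implemented.  The *classical* system applies the
original combining clauses over counts of criteria at each effective
strength tier; the *points* system maps each applied criterion to signed
integer points (supporting 1, moderate 2, strong 4, very strong 8; benign
criteria negative) and thresholds the sum.  The points system is the
default because it is the one consistent with a curation style in which a
lone predicted-loss-of-function criterion yields "likely pathogenic" rather
than "pathogenic".

PM2 (absence from population databases) and PP5 (reputable-source
assertion) are excluded from evidence sets by default: for a rare-disease
gene interrogated *through* a population database, PM2 is circular, and
PP5 is deprecated.

Criteria applied at non-default strengths count at their modified tier in
both systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .records import (
    DEFAULT_EXCLUDED_CODES,
    Classification,
    EvidenceSet,
    Strength,
    VariantRecord,
    is_benign_code,
)

__all__ = [
    "CombinerConfig",
    "ClassificationResult",
    "classify",
    "classify_classical",
    "classify_points",
    "ConcordanceReport",
    "concordance_report",
]

DEFAULT_STRENGTH_POINTS = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STAND_ALONE: 8,
}

# points thresholds: label <- first band containing the sum
DEFAULT_POINTS_THRESHOLDS = {
    Classification.P: 10,   # points >= 10
    Classification.LP: 6,   # 6..9
    Classification.VUS: 0,  # 0..5
    Classification.LB: -6,  # -6..-1
    Classification.B: -7,   # points <= -7
}


@dataclass(frozen=True)
class CombinerConfig:
    system: str = "points"  # "points" | "classical"
    excluded_codes: frozenset = DEFAULT_EXCLUDED_CODES
    strength_points: dict = field(default_factory=lambda: dict(DEFAULT_STRENGTH_POINTS))
    points_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_POINTS_THRESHOLDS))

    def __post_init__(self) -> None:
        if self.system not in ("points", "classical"):
            raise ValueError(f"unknown rule system {self.system!r}")
        pts = [self.strength_points[s] for s in
               (Strength.SUPPORTING, Strength.MODERATE, Strength.STRONG, Strength.VERY_STRONG)]
        if sorted(pts) != pts or len(set(pts)) != len(pts):
            raise ValueError("strength points must be strictly increasing")


@dataclass(frozen=True)
class ClassificationResult:
    label: Classification
    points: Optional[int] = None
    rule_fired: str = ""


def _tier_counts(evidence: EvidenceSet, benign: bool) -> dict:
    counts = {s: 0 for s in Strength}
    for code, strength in evidence.items:
        if is_benign_code(code) == benign:
            counts[strength] += 1
    return counts


def classify_classical(
    evidence: EvidenceSet, config: Optional[CombinerConfig] = None
) -> ClassificationResult:
    """Classify with the original combining clauses.

    Pathogenic and benign clause families are evaluated independently on
    effective-strength counts; if both fire, the result is VUS with
    ``rule_fired="conflicting"``; if neither, VUS ``"unmet"``.
    """
    config = config or CombinerConfig(system="classical")
    evidence = evidence.without(config.excluded_codes)

    path = _tier_counts(evidence, benign=False)
    ben = _tier_counts(evidence, benign=True)
    nvs, ns = path[Strength.VERY_STRONG], path[Strength.STRONG]
    nm, nsup = path[Strength.MODERATE], path[Strength.SUPPORTING]
    # benign moderate has no clause of its own; it counts as supporting
    b_sa = ben[Strength.STAND_ALONE]
    b_s = ben[Strength.STRONG]
    b_sup = ben[Strength.SUPPORTING] + ben[Strength.MODERATE]

    path_label, path_rule = None, ""
    if nvs >= 1 and (ns >= 1 or nm >= 2 or (nm >= 1 and nsup >= 1) or nsup >= 2):
        path_label, path_rule = Classification.P, "very_strong+corroboration"
    elif ns >= 2:
        path_label, path_rule = Classification.P, ">=2 strong"
    elif ns >= 1 and (nm >= 3 or (nm >= 2 and nsup >= 2) or (nm >= 1 and nsup >= 4)):
        path_label, path_rule = Classification.P, "strong+moderate/supporting"
    elif nvs >= 1 and nm >= 1:
        path_label, path_rule = Classification.LP, "very_strong+1 moderate"
    elif ns >= 1 and nm >= 1:
        path_label, path_rule = Classification.LP, "1 strong+1-2 moderate"
    elif ns >= 1 and nsup >= 2:
        path_label, path_rule = Classification.LP, "1 strong+>=2 supporting"
    elif nm >= 3:
        path_label, path_rule = Classification.LP, ">=3 moderate"
    elif nm >= 2 and nsup >= 2:
        path_label, path_rule = Classification.LP, "2 moderate+>=2 supporting"
    elif nm >= 1 and nsup >= 4:
        path_label, path_rule = Classification.LP, "1 moderate+>=4 supporting"

    ben_label, ben_rule = None, ""
    if b_sa >= 1:
        ben_label, ben_rule = Classification.B, "stand-alone benign"
    elif b_s >= 2:
        ben_label, ben_rule = Classification.B, ">=2 benign strong"
    elif b_s >= 1 and b_sup >= 1:
        ben_label, ben_rule = Classification.LB, "1 benign strong+1 supporting"
    elif b_sup >= 2:
        ben_label, ben_rule = Classification.LB, ">=2 benign supporting"

    if path_label and ben_label:
        return ClassificationResult(Classification.VUS, rule_fired="conflicting")
    if path_label:
        return ClassificationResult(path_label, rule_fired=path_rule)
    if ben_label:
        return ClassificationResult(ben_label, rule_fired=ben_rule)
    return ClassificationResult(Classification.VUS, rule_fired="unmet")


def classify_points(
    evidence: EvidenceSet, config: Optional[CombinerConfig] = None
) -> ClassificationResult:
    """Classify by summed signed evidence points."""
    config = config or CombinerConfig(system="points")
    evidence = evidence.without(config.excluded_codes)
    points = 0
    for code, strength in evidence.items:
        value = config.strength_points[strength]
        points += -value if is_benign_code(code) else value
    thr = config.points_thresholds
    if points >= thr[Classification.P]:
        label = Classification.P
    elif points >= thr[Classification.LP]:
        label = Classification.LP
    elif points >= thr[Classification.VUS]:
        label = Classification.VUS
    elif points >= thr[Classification.LB]:
        label = Classification.LB
    else:
        label = Classification.B
    return ClassificationResult(label, points=points, rule_fired=f"points={points}")


def classify(evidence: EvidenceSet, config: Optional[CombinerConfig] = None) -> ClassificationResult:
    config = config or CombinerConfig()
    if config.system == "classical":
        return classify_classical(evidence, config)
    return classify_points(evidence, config)


@dataclass
class ConcordanceReport:
    """Engine labels compared against externally assigned labels."""

    per_record: pd.DataFrame
    counts: pd.DataFrame       # agree/disagree tallies by assigned class
    discordant: pd.DataFrame   # the disagreeing rows, with rule_fired

    @property
    def n_agree(self) -> int:
        return int(self.per_record["agree"].sum())

    @property
    def n_total(self) -> int:
        return len(self.per_record)


def concordance_report(
    records: Iterable[VariantRecord],
    config: Optional[CombinerConfig] = None,
    label_source: str = "assigned_class",
) -> ConcordanceReport:
    """Compare engine output with assigned labels without mutating them.

    ``label_source`` may be ``assigned_class`` or ``clinvar_label``.
    Records lacking the chosen label are listed with ``agree=NA`` and are
    excluded from the tallies; if every record lacks it, this is an error.
    """
    config = config or CombinerConfig()
    rows = []
    any_label = False
    for rec in records:
        if label_source == "assigned_class":
            assigned = rec.assigned_class.value if rec.assigned_class else None
        else:
            assigned = rec.clinvar_label
        result = classify(rec.evidence, config)
        if assigned is not None:
            any_label = True
        rows.append(
            {
                "hgvs_c": rec.hgvs_c,
                "evidence": rec.evidence.to_text(),
                "assigned": assigned,
                "engine": result.label.value,
                "points": result.points,
                "rule_fired": result.rule_fired,
                "agree": (assigned == result.label.value) if assigned is not None else pd.NA,
            }
        )
    if not any_label:
        raise ValueError(f"no record carries a {label_source} label")
    per_record = pd.DataFrame(rows)
    labeled = per_record.dropna(subset=["agree"])
    counts = (
        labeled.groupby("assigned")["agree"]
        .agg(n="size", n_agree="sum")
        .assign(n_disagree=lambda d: d["n"] - d["n_agree"])
        .reset_index()
    )
    discordant = labeled[~labeled["agree"].astype(bool)].reset_index(drop=True)
    return ConcordanceReport(per_record=per_record, counts=counts, discordant=discordant)
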