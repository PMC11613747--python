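"""Inclusion models A-G, allele-frequency aggregation, and Hardy-Weinberg
conversion to carrier frequency and birth prevalence.

For an autosomal recessive disease the summed frequency q of all
disease-attributed alleles in the gene gives, under Hardy-Weinberg
equilibrium (p^2 + 2pq + q^2 = 1, p = 1 - q):

* birth prevalence  q^2          reported as "1 in round(1/q^2)"
* carrier frequency 2pq          reported as "1 in round(1/(2pq))"

q is the union over compound-heterozygous and homozygous configurations,
so no per-genotype enumeration is needed.  All aggregation is exact
rational arithmetic (:class:`fractions.Fraction`); rounding happens only
when a "1 in N" figure is reported, using round-half-away-from-zero.

The seven inclusion models differ in which variants contribute to q:

====== =============================================================
Model  Qualifying alleles
====== =============================================================
A      published variants only
B      published + unpublished called damaging by all 3 trio tools
C      published + unpublished called damaging by >=2 of 3 trio tools
D      classification P only (published and unpublished)
E      classification P or LP
F      classification P, LP or VUS
G      published + unpublished exceeding all 4 quartet score cut-offs
====== =============================================================

Models B, C and G additionally deem protein-length-altering variants
pathogenic and exclude UTR/intronic/noncoding/synonymous/upstream classes
from the in silico step; E and F exclude upstream/UTR/noncoding/synonymous
classes but retain splice variants classified P/LP.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .curation import consequence_filter
from .insilico import QuartetThresholds, deemed_pathogenic, quartet_call, trio_call
from .records import (
    Classification,
    QuartetScores,
    RegionFlag,
    Source,
    TrioCalls,
    VariantRecord,
    VariantType,
)

__all__ = [
    "AlleleFrequencyConvention",
    "ModelSpec",
    "MODELS",
    "HardyWeinbergResult",
    "SelectionReport",
    "ModelRun",
    "resolve_allele_frequency",
    "select_variants",
    "aggregate_q",
    "hardy_weinberg",
    "run_model",
    "round_half_away",
]


@dataclass(frozen=True)
class AlleleFrequencyConvention:
    """Missing-data conventions for allele-frequency resolution.

    ``absent_denominator`` is the total allele count of the reference
    exome+genome release (2 x (125,748 + 15,708) = 282,912): a published
    variant absent from the database and outside the coding sequence or
    the 10 bp junction window contributes 0/282,912.  Any other unlisted
    variant is assigned the upper-limit frequency 1/300,000.  Aggregates
    are reported per ``normalization_base`` alleles.
    """

    absent_denominator: int = 282_912
    unlisted_assumed_af: Fraction = Fraction(1, 300_000)
    normalization_base: int = 100_000

    def __post_init__(self) -> None:
        if self.normalization_base <= 0:
            raise ValueError("normalization_base must be positive")


DEFAULT_CONVENTION = AlleleFrequencyConvention()


def resolve_allele_frequency(
    record: VariantRecord, convention: AlleleFrequencyConvention = DEFAULT_CONVENTION
) -> Fraction:
    """Allele frequency of one record under the missing-data conventions.

    Present in the database -> AC/AN.  Absent and neither coding nor
    within 10 bp of an exon-intron junction -> 0 (over the reference
    denominator).  Absent otherwise -> the assumed upper limit.
    """
    if record.allele_count is not None and record.allele_number is not None:
        return Fraction(record.allele_count, record.allele_number)
    if record.region_flags is None:
        raise ValueError(
            f"{record.hgvs_c}: absent from database and region_flags unknown; "
            "cannot apply the missing-frequency convention"
        )
    near_coding = bool(
        record.region_flags
        & {RegionFlag.CODING, RegionFlag.WITHIN_10BP_OF_JUNCTION}
    )
    if not near_coding:
        return Fraction(0, convention.absent_denominator)
    return convention.unlisted_assumed_af


class UnpublishedRule(str, enum.Enum):
    NONE = "none"
    TRIO_STRICT = "trio_strict"
    TRIO_LENIENT = "trio_lenient"
    QUARTET = "quartet"
    ACMG_P = "acmg_P"
    ACMG_P_LP = "acmg_P_LP"
    ACMG_P_LP_VUS = "acmg_P_LP_VUS"


class PublishedRule(str, enum.Enum):
    ALL = "all"
    ACMG_P = "acmg_P"
    ACMG_P_LP = "acmg_P_LP"
    ACMG_P_LP_VUS = "acmg_P_LP_VUS"


_LABEL_SETS = {
    "acmg_P": {Classification.P},
    "acmg_P_LP": {Classification.P, Classification.LP},
    "acmg_P_LP_VUS": {Classification.P, Classification.LP, Classification.VUS},
}

# consequence classes outside the reach of the in silico panels / the
# classification-stratified frequency sums
NONCODING_EXCLUSIONS = frozenset(
    {
        VariantType.UTR5,
        VariantType.UTR3,
        VariantType.INTRONIC,
        VariantType.NONCODING,
        VariantType.SYNONYMOUS,
        VariantType.UPSTREAM,
    }
)
CLASSIFIED_EXCLUSIONS = frozenset(
    {
        VariantType.UPSTREAM,
        VariantType.UTR5,
        VariantType.NONCODING,
        VariantType.UTR3,
        VariantType.SYNONYMOUS,
    }
)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative inclusion rules for one birth-prevalence model."""

    model_id: str
    include_published: bool
    published_rule: PublishedRule
    unpublished_rule: UnpublishedRule
    consequence_exclusions: frozenset
    exclusions_apply_to: str  # "all" | "unpublished"
    include_deemed_pathogenic: bool
    description: str = ""


MODELS = {
    "A": ModelSpec(
        "A", True, PublishedRule.ALL, UnpublishedRule.NONE,
        frozenset(), "all", False,
        "published variants only",
    ),
    "B": ModelSpec(
        "B", True, PublishedRule.ALL, UnpublishedRule.TRIO_STRICT,
        NONCODING_EXCLUSIONS, "unpublished", True,
        "published + unpublished damaging by all 3 trio predictors",
    ),
    "C": ModelSpec(
        "C", True, PublishedRule.ALL, UnpublishedRule.TRIO_LENIENT,
        NONCODING_EXCLUSIONS, "unpublished", True,
        "published + unpublished damaging by >=2 of 3 trio predictors",
    ),
    "D": ModelSpec(
        "D", True, PublishedRule.ACMG_P, UnpublishedRule.ACMG_P,
        frozenset(), "all", False,
        "classification P only",
    ),
    "E": ModelSpec(
        "E", True, PublishedRule.ACMG_P_LP, UnpublishedRule.ACMG_P_LP,
        CLASSIFIED_EXCLUSIONS, "all", False,
        "classification P or LP",
    ),
    "F": ModelSpec(
        "F", True, PublishedRule.ACMG_P_LP_VUS, UnpublishedRule.ACMG_P_LP_VUS,
        CLASSIFIED_EXCLUSIONS, "all", False,
        "classification P, LP or VUS",
    ),
    "G": ModelSpec(
        "G", True, PublishedRule.ALL, UnpublishedRule.QUARTET,
        NONCODING_EXCLUSIONS, "unpublished", True,
        "published + unpublished exceeding all 4 quartet cut-offs",
    ),
}


def _label_of(record: VariantRecord, engine_labels: Optional[dict]) -> Optional[Classification]:
    if engine_labels is not None and record.dedup_key in engine_labels:
        return engine_labels[record.dedup_key]
    return record.assigned_class


def select_variants(
    records: Sequence[VariantRecord],
    spec: ModelSpec,
    engine_labels: Optional[dict] = None,
    quartet_thresholds: QuartetThresholds = QuartetThresholds(),
) -> list:
    """Records qualifying under one model's inclusion rules.

    ``engine_labels`` optionally overrides each record's assigned
    classification (keyed by ``dedup_key``), letting the rules engine
    rather than the curator drive label-based models.
    """
    label_map = (
        {rec.dedup_key: _label_of(rec, engine_labels) for rec in records}
        if spec.consequence_exclusions
        else None
    )

    selected = []
    for rec in records:
        if rec.source == Source.PUBLISHED:
            if not spec.include_published:
                continue
            if spec.published_rule == PublishedRule.ALL:
                selected.append(rec)
                continue
            label = _label_of(rec, engine_labels)
            if label is None:
                raise ValueError(
                    f"model {spec.model_id} requires a classification label; "
                    f"{rec.hgvs_c} has none"
                )
            if label in _LABEL_SETS[spec.published_rule.value]:
                selected.append(rec)
            continue

        rule = spec.unpublished_rule
        if rule == UnpublishedRule.NONE:
            continue
        if rule in (UnpublishedRule.ACMG_P, UnpublishedRule.ACMG_P_LP,
                    UnpublishedRule.ACMG_P_LP_VUS):
            label = _label_of(rec, engine_labels)
            if label is None:
                raise ValueError(
                    f"model {spec.model_id} requires a classification label; "
                    f"{rec.hgvs_c} has none"
                )
            if label in _LABEL_SETS[rule.value]:
                selected.append(rec)
            continue
        # predictor-driven rules: consequence exclusions apply before scoring
        if rec.variant_type in spec.consequence_exclusions:
            continue
        if spec.include_deemed_pathogenic and deemed_pathogenic(rec.variant_type):
            selected.append(rec)
            continue
        if rule in (UnpublishedRule.TRIO_STRICT, UnpublishedRule.TRIO_LENIENT):
            calls = rec.trio_calls
            if calls is None:
                raise ValueError(
                    f"model {spec.model_id} requires trio predictor calls; "
                    f"{rec.hgvs_c} has none (columns sift/polyphen2/mutationtaster2)"
                )
            mode = "strict_3of3" if rule == UnpublishedRule.TRIO_STRICT else "lenient_2of3"
            if trio_call(calls, mode):
                selected.append(rec)
            continue
        if rule == UnpublishedRule.QUARTET:
            scores = rec.quartet_scores
            if scores is None:
                raise ValueError(
                    f"model {spec.model_id} requires quartet scores; "
                    f"{rec.hgvs_c} has none (columns bayesdel/mutpred2/revel/vest4)"
                )
            if quartet_call(scores, quartet_thresholds):
                selected.append(rec)
            continue

    # label-based models: consequence exclusions after label selection
    if spec.consequence_exclusions and spec.exclusions_apply_to == "all":
        selected = consequence_filter(
            selected, spec.consequence_exclusions, labels=label_map
        )
    return selected


def aggregate_q(
    selected: Iterable[VariantRecord],
    convention: AlleleFrequencyConvention = DEFAULT_CONVENTION,
) -> Fraction:
    """Summed allele frequency of the selected records, exact, as a Fraction.

    Per-100,000 reporting is a display concern: multiply by
    ``convention.normalization_base``.
    """
    q = Fraction(0)
    n = 0
    for rec in selected:
        q += resolve_allele_frequency(rec, convention)
        n += 1
    if n == 0 or q == 0:
        warnings.warn("selection contributes zero allele frequency; "
                      "Hardy-Weinberg conversion will fail", stacklevel=2)
    return q


def round_half_away(x: Fraction) -> int:
    """Round to nearest integer, halves away from zero (exact on Fractions)."""
    x = Fraction(x)
    if x >= 0:
        return int((2 * x + 1) // 2)
    return -int((-2 * x + 1) // 2)


@dataclass(frozen=True)
class HardyWeinbergResult:
    """Hardy-Weinberg outputs for a summed pathogenic allele frequency q."""

    q: Fraction
    p: Fraction
    prevalence_one_in: int   # round(1 / q^2)
    carrier_one_in: int      # round(1 / (2 p q))
    carrier_rate_simple: Fraction  # variant alleles per individual, 2q

    @property
    def q_per_100k(self) -> Fraction:
        return self.q * 100_000


def hardy_weinberg(q) -> HardyWeinbergResult:
    """Convert a summed allele frequency into "1 in N" figures.

    ``q`` may be a Fraction, a float, or anything Fraction accepts;
    it must satisfy 0 < q < 1.
    """
    q = Fraction(q)
    if not (0 < q < 1):
        raise ValueError(f"q must lie strictly between 0 and 1, got {q}")
    p = 1 - q
    return HardyWeinbergResult(
        q=q,
        p=p,
        prevalence_one_in=round_half_away(1 / (q * q)),
        carrier_one_in=round_half_away(1 / (2 * p * q)),
        carrier_rate_simple=2 * q,
    )


@dataclass(frozen=True)
class SelectionReport:
    model_id: str
    n_input: int
    n_selected: int
    n_published_selected: int
    n_unpublished_selected: int
    selected_keys: tuple


@dataclass(frozen=True)
class ModelRun:
    """Result of running one inclusion model end to end."""

    q: Fraction
    hw: HardyWeinbergResult
    report: SelectionReport

    @property
    def q_per_100k(self) -> Fraction:
        return self.q * 100_000


def run_model(
    records: Sequence[VariantRecord],
    model_id: str,
    convention: AlleleFrequencyConvention = DEFAULT_CONVENTION,
    engine_labels: Optional[dict] = None,
) -> ModelRun:
    """select_variants -> aggregate_q -> hardy_weinberg for one model."""
    try:
        spec = MODELS[model_id.upper()]
    except KeyError:
        raise ValueError(f"unknown model {model_id!r}; expected one of A..G") from None
    selected = select_variants(records, spec, engine_labels=engine_labels)
    q = aggregate_q(selected, convention)
    if q == 0:
        raise ValueError(f"model {spec.model_id}: q = 0 (empty or zero-frequency selection)")
    hw = hardy_weinberg(q)
    report = SelectionReport(
        model_id=spec.model_id,
        n_input=len(records),
        n_selected=len(selected),
        n_published_selected=sum(1 for r in selected if r.source == Source.PUBLISHED),
        n_unpublished_selected=sum(1 for r in selected if r.source == Source.UNPUBLISHED),
        selected_keys=tuple(r.dedup_key for r in selected),
    )
    return ModelRun(q=q, hw=hw, report=report)
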