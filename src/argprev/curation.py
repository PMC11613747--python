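"""Curation filters: dedup against the published list, overlapping-gene
exclusion, and consequence-class exclusion.

The target gene's locus is overlapped by a second gene (MED23 overlaps
ARG1), so intronic database variants flagged as belonging to the
overlapping gene are removed before any downstream counting.  Published
and database lists are matched on a lexically normalized coding-HGVS key.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import Classification, RegionFlag, VariantRecord, VariantType

__all__ = [
    "CurationReport",
    "deduplicate",
    "exclude_overlap_gene",
    "consequence_filter",
    "curate",
]


@dataclass(frozen=True)
class CurationReport:
    n_input_db: int
    n_input_published: int
    n_duplicates_removed: int
    n_overlap_excluded: int
    n_remaining_unpublished: int

    def __post_init__(self) -> None:
        expected = self.n_input_db - self.n_duplicates_removed - self.n_overlap_excluded
        if self.n_remaining_unpublished != expected:
            raise ValueError(
                "curation counts inconsistent: "
                f"{self.n_input_db} - {self.n_duplicates_removed} - "
                f"{self.n_overlap_excluded} != {self.n_remaining_unpublished}"
            )


def deduplicate(
    db_records: Sequence[VariantRecord], published_records: Sequence[VariantRecord]
) -> tuple:
    """Drop database records whose coding-HGVS key matches a published record.

    The published list is never modified.  Returns the remaining database
    records and a :class:`CurationReport` with the overlap counter still
    zero (it is filled by :func:`curate` after the overlap stage).
    """
    published_keys = {rec.dedup_key for rec in published_records}
    remaining = [rec for rec in db_records if rec.dedup_key not in published_keys]
    report = CurationReport(
        n_input_db=len(db_records),
        n_input_published=len(published_records),
        n_duplicates_removed=len(db_records) - len(remaining),
        n_overlap_excluded=0,
        n_remaining_unpublished=len(remaining),
    )
    return remaining, report


def exclude_overlap_gene(records: Sequence[VariantRecord]) -> tuple:
    """Remove records that are intronic AND flagged as overlapping-gene.

    Only the combination triggers removal: a coding variant inside the
    overlapping gene's span is still a variant of the target gene.
    """
    kept, removed = [], 0
    for rec in records:
        if (
            rec.variant_type == VariantType.INTRONIC
            and RegionFlag.OVERLAPS_COMED_GENE in rec.region_flags
        ):
            removed += 1
        else:
            kept.append(rec)
    return kept, removed


_PLP = {Classification.P, Classification.LP}


def consequence_filter(
    records: Iterable[VariantRecord],
    excluded_types: Iterable[VariantType],
    labels: Optional[dict] = None,
    keep_plp_splice: bool = True,
) -> list:
    """Drop records whose consequence class is excluded.

    Splice-site (and intronic splice) records classified P or LP are
    retained even when their class is in the exclusion set, matching the
    convention that pathogenic splice alleles contribute to the summed
    frequency.  ``labels`` may override each record's assigned class,
    keyed by ``dedup_key``.
    """
    excluded = set(excluded_types)
    kept = []
    for rec in records:
        if rec.variant_type in excluded:
            label = (labels or {}).get(rec.dedup_key, rec.assigned_class)
            splice_like = rec.variant_type in (VariantType.SPLICE_SITE, VariantType.INTRONIC)
            if keep_plp_splice and splice_like and label in _PLP:
                kept.append(rec)
            continue
        else:
            kept.append(rec)
    return kept


def curate(
    db_records: Sequence[VariantRecord], published_records: Sequence[VariantRecord]
) -> tuple:
    """Dedup then overlapping-gene exclusion; returns (records, CurationReport)."""
    after_dedup, dd_report = deduplicate(db_records, published_records)
    after_overlap, n_overlap = exclude_overlap_gene(after_dedup)
    report = CurationReport(
        n_input_db=dd_report.n_input_db,
        n_input_published=dd_report.n_input_published,
        n_duplicates_removed=dd_report.n_duplicates_removed,
        n_overlap_excluded=n_overlap,
        n_remaining_unpublished=len(after_overlap),
    )
    return after_overlap, report
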