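"""Consensus rules over externally computed in silico pathogenicity predictors.

Two predictor panels are supported:

* the *trio* — SIFT, PolyPhen2, MutationTaster2 — combined either strictly
  (all three must call damaging, with PolyPhen2 at "probably damaging") or
  leniently (any 2 of 3 damaging votes, with PolyPhen2 "possibly" or
  "probably damaging" counting as a vote);
* the *quartet* — BayesDel, MutPred2, REVEL, VEST4 — where a variant is
  called pathogenic only when every score strictly exceeds its published
  calibration cut-off (BayesDel > 0.13, MutPred2 > 0.737, REVEL > 0.644,
  VEST4 > 0.764).

Protein-length-altering variants (frameshifts, nonsense, deletions, start
loss) cannot be scored by these tools and are deemed pathogenic outright.
Missing predictor values count as non-damaging votes by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import (
    MutationTasterCall,
    PolyPhenCall,
    QuartetScores,
    SiftCall,
    TrioCalls,
    VariantType,
)

__all__ = [
    "QuartetThresholds",
    "DEEMED_PATHOGENIC_TYPES",
    "deemed_pathogenic",
    "trio_call",
    "quartet_call",
]


@dataclass(frozen=True)
class QuartetThresholds:
    """Calibration cut-offs above which each score supports pathogenicity."""

    bayesdel: float = 0.13
    mutpred2: float = 0.737
    revel: float = 0.644
    vest4: float = 0.764


#: consequence classes that alter the protein coding sequence and cannot be
#: scored by the predictor panels
DEEMED_PATHOGENIC_TYPES = frozenset(
    {
        VariantType.FRAMESHIFT,
        VariantType.NONSENSE,
        VariantType.GROSS_DELETION,
        VariantType.EXON_DELETION,
        VariantType.INFRAME_DELETION,
        VariantType.START_LOSS,
    }
)


def deemed_pathogenic(variant_type: VariantType) -> bool:
    """True for protein-length-altering classes the predictors cannot score."""
    return variant_type in DEEMED_PATHOGENIC_TYPES


def trio_call(calls: TrioCalls, mode: str = "strict_3of3") -> bool:
    """Consensus pathogenicity call from the three-tool panel.

    ``strict_3of3`` requires all three calls present and damaging, with
    PolyPhen2 at probably-damaging.  ``lenient_2of3`` requires at least two
    damaging votes, PolyPhen2 possibly- or probably-damaging counting.
    A missing call is a non-damaging vote; all three missing is an error.
    """
    if calls.is_empty():
        raise ValueError("all three trio predictor calls are missing")
    if mode not in ("strict_3of3", "lenient_2of3"):
        raise ValueError(f"unknown trio mode {mode!r}")

    sift_vote = calls.sift == SiftCall.DELETERIOUS
    mt2_vote = calls.mutationtaster2 == MutationTasterCall.DISEASE_CAUSING
    if mode == "strict_3of3":
        pp2_vote = calls.polyphen2 == PolyPhenCall.PROBABLY_DAMAGING
        return sift_vote and mt2_vote and pp2_vote
    pp2_vote = calls.polyphen2 in (
        PolyPhenCall.POSSIBLY_DAMAGING,
        PolyPhenCall.PROBABLY_DAMAGING,
    )
    return (sift_vote + mt2_vote + pp2_vote) >= 2


def quartet_call(
    scores: QuartetScores, thresholds: QuartetThresholds = QuartetThresholds()
) -> bool:
    """True iff all four scores are present and strictly exceed their cut-offs."""
    if scores.is_empty():
        return False
    for name in ("bayesdel", "mutpred2", "revel", "vest4"):
        value = getattr(scores, name)
        if value is None or not value > getattr(thresholds, name):
            return False
    return True
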