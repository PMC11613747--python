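"""Generate gnomAD-like variant tables with known ground truth.

The generator emulates the shape of a rare-disease gene's variant list in a
population database: a few hundred variants over ~150,000-300,000 genotyped
alleles, mostly singletons, with a consequence-class mixture dominated by
intronic and missense changes, and with ACMG/AMP evidence tokens and in
silico predictor outputs drawn conditionally on a latent five-tier class.
Every draw is reproducible from the seed, and a :class:`GroundTruthLedger`
records the latent class and resolved allele frequency of every variant so
that aggregate quantities can be checked exactly (rational arithmetic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .records import (
    Classification,
    EvidenceSet,
    MutationTasterCall,
    PolyPhenCall,
    QuartetScores,
    RegionFlag,
    SiftCall,
    Source,
    TrioCalls,
    VariantRecord,
    VariantType,
    infer_region_flags,
    parse_evidence,
    read_variant_table,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruthLedger",
    "generate_table",
    "generate_curation_scenario",
    "make_fixtures",
]

# gnomAD-like marginal consequence mixture for a small gene's variant list
DEFAULT_CONSEQUENCE_MIX = {
    VariantType.INTRONIC: 0.40,
    VariantType.MISSENSE: 0.24,
    VariantType.SYNONYMOUS: 0.11,
    VariantType.UTR3: 0.07,
    VariantType.UTR5: 0.03,
    VariantType.UPSTREAM: 0.02,
    VariantType.NONCODING: 0.02,
    VariantType.FRAMESHIFT: 0.05,
    VariantType.NONSENSE: 0.02,
    VariantType.SPLICE_SITE: 0.03,
    VariantType.START_LOSS: 0.005,
    VariantType.INFRAME_DELETION: 0.005,
}

# class proportions observed in curated unpublished variants of a
# recessive-disease gene: VUS-dominated, few P
DEFAULT_CLASS_MIX = {
    Classification.P: 0.010,
    Classification.LP: 0.093,
    Classification.VUS: 0.758,
    Classification.LB: 0.116,
    Classification.B: 0.023,
}

# evidence profiles: per class, (token string, probability); designed so the
# points engine recovers the class with known probability
DEFAULT_EVIDENCE_PROFILES = {
    Classification.P: [("PVS1, PS1", 0.9), ("PVS1", 0.1)],
    Classification.LP: [("PVS1", 0.7), ("PM1, PM5, PP2, PP3", 0.3)],
    Classification.VUS: [("PP2, PP3", 0.7), ("PP3", 0.2), ("", 0.1)],
    Classification.LB: [("BS1, BP7", 1.0)],
    Classification.B: [("BS1, BS2", 0.5), ("BA1", 0.5)],
}

# probability that each predictor votes damaging, by latent class
DEFAULT_DAMAGING_PROPENSITY = {
    Classification.P: 0.95,
    Classification.LP: 0.90,
    Classification.VUS: 0.35,
    Classification.LB: 0.10,
    Classification.B: 0.05,
}

# consequence classes a pathogenic (P/LP) latent label may take: keeps
# generated P/LP variants out of the consequence-excluded classes so that
# ledger q for the P/LP rule matches label-rule model selection exactly
_PATHOGENIC_COMPATIBLE = frozenset(
    {
        VariantType.MISSENSE,
        VariantType.FRAMESHIFT,
        VariantType.NONSENSE,
        VariantType.SPLICE_SITE,
        VariantType.START_LOSS,
        VariantType.INFRAME_DELETION,
    }
)

_QUARTET_THRESH = {"bayesdel": 0.13, "mutpred2": 0.737, "revel": 0.644, "vest4": 0.764}
_QUARTET_MAX = {"bayesdel": 1.0, "mutpred2": 1.0, "revel": 1.0, "vest4": 1.0}
_SCORED_TYPES = frozenset({VariantType.MISSENSE, VariantType.SPLICE_SITE})


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic variant table."""

    seed: int = 0
    n_variants: int = 300
    total_alleles: int = 282_912
    singleton_fraction: float = 0.8
    consequence_mix: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX))
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    evidence_profiles: dict = field(default_factory=lambda: dict(DEFAULT_EVIDENCE_PROFILES))
    damaging_propensity: dict = field(default_factory=lambda: dict(DEFAULT_DAMAGING_PROPENSITY))
    target_q_per_100k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_alleles <= 0 or self.total_alleles % 2:
            raise ValueError("total_alleles must be a positive even integer")
        for name in ("consequence_mix", "class_mix"):
            total = sum(getattr(self, name).values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        if not (0.0 <= self.singleton_fraction <= 1.0):
            raise ValueError("singleton_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthLedger:
    """Per-variant latent truth plus exact aggregate bookkeeping."""

    classes: tuple
    allele_frequencies: tuple  # Fractions, index-aligned with the table
    consequence_counts: dict
    q_by_rule: dict  # label-rule name -> exact Fraction

    def q_per_100k(self, rule: str = "acmg_P_LP") -> Fraction:
        return self.q_by_rule[rule] * 100_000


def _choice(rng: np.random.Generator, options: Sequence, probs: Sequence[float]):
    return options[rng.choice(len(options), p=np.asarray(probs) / np.sum(probs))]


def _hgvs_name(index: int, vtype: VariantType) -> str:
    # positions start beyond any real coding coordinate of the gene so that
    # synthetic names never collide with curated fixture records
    pos = 2001 + 3 * index
    if vtype == VariantType.FRAMESHIFT:
        return f"c.{pos}del"
    if vtype == VariantType.INFRAME_DELETION:
        return f"c.{pos}_{pos + 2}del"
    if vtype == VariantType.SPLICE_SITE:
        return f"c.{pos}+1G>A"
    if vtype == VariantType.INTRONIC:
        return f"c.{pos}-50T>C"
    if vtype == VariantType.UPSTREAM:
        return f"c.-{200 + pos}G>A"
    if vtype == VariantType.UTR5:
        return f"c.-{pos}C>T"
    if vtype == VariantType.UTR3:
        return f"c.*{pos}A>G"
    if vtype == VariantType.START_LOSS:
        return f"c.2T>C_{index}"
    return f"c.{pos}G>A"


def _retarget_counts(
    counts: list, plp_idx: list, target_sum: int
) -> None:
    """Rescale allele counts at plp_idx so they sum exactly to target_sum.

    Largest-remainder apportionment; a count may be rescaled to zero, in
    which case that variant contributes no observed alleles.
    """
    n = len(plp_idx)
    if n == 0:
        raise ValueError("target_q set but no pathogenic/likely-pathogenic variants generated")
    if target_sum < 0:
        raise ValueError("target allele total must be non-negative")
    current = sum(counts[i] for i in plp_idx)
    ideal = [Fraction(counts[i] * target_sum, current) for i in plp_idx]
    base = [int(x) for x in ideal]
    diff = target_sum - sum(base)
    order = sorted(range(n), key=lambda j: (ideal[j] - int(ideal[j]), counts[plp_idx[j]]),
                   reverse=True)
    j = 0
    while diff != 0:
        k = order[j % n]
        if diff > 0:
            base[k] += 1
            diff -= 1
        elif base[k] > 0:
            base[k] -= 1
            diff += 1
        j += 1
        if j > 10 * n and diff != 0:
            raise ValueError("cannot apportion target allele total")
    for j, i in enumerate(plp_idx):
        counts[i] = base[j]


def _check_counts_feasible(counts: list, total_alleles: int) -> None:
    if any(c > total_alleles for c in counts):
        raise ValueError("target allele total infeasible: a variant would need "
                         "more copies than there are alleles")


def generate_table(config: SyntheticConfig) -> tuple:
    """Draw one synthetic table; returns ``(records, GroundTruthLedger)``.

    If ``target_q_per_100k`` is set, allele counts of the latent P/LP
    variants are re-apportioned so their summed frequency equals the target
    exactly; this requires ``target * total_alleles / 100000`` to be an
    integer (e.g. any ``total_alleles`` that is a multiple of 100,000).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_class, rng_cons, rng_ev, rng_count, rng_score = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    classes = list(config.class_mix)
    class_probs = [config.class_mix[c] for c in classes]
    cons = list(config.consequence_mix)
    cons_probs = [config.consequence_mix[c] for c in cons]
    path_cons = [c for c in cons if c in _PATHOGENIC_COMPATIBLE]
    path_probs = [config.consequence_mix[c] for c in path_cons]

    latent, vtypes, evidences, counts = [], [], [], []
    trio_list, quartet_list = [], []
    for i in range(config.n_variants):
        cls = _choice(rng_class, classes, class_probs)
        latent.append(cls)
        if cls in (Classification.P, Classification.LP) and path_cons:
            vtype = _choice(rng_cons, path_cons, path_probs)
        else:
            vtype = _choice(rng_cons, cons, cons_probs)
        vtypes.append(vtype)

        profile = config.evidence_profiles[cls]
        tokens = _choice(rng_ev, [t for t, _ in profile], [p for _, p in profile])
        evidences.append(parse_evidence(tokens))

        if rng_count.random() < config.singleton_fraction:
            ac = 1
        else:
            ac = 2 + int(rng_count.geometric(0.3))
        counts.append(ac)

        pi = config.damaging_propensity[cls]
        if vtype in _SCORED_TYPES:
            sift = SiftCall.DELETERIOUS if rng_score.random() < pi else SiftCall.TOLERATED
            pp2 = (
                PolyPhenCall.PROBABLY_DAMAGING
                if rng_score.random() < pi
                else PolyPhenCall.BENIGN
            )
            mt2 = (
                MutationTasterCall.DISEASE_CAUSING
                if rng_score.random() < pi
                else MutationTasterCall.POLYMORPHISM
            )
            trio_list.append(TrioCalls(sift=sift, polyphen2=pp2, mutationtaster2=mt2))
            score_vals = {}
            for name, thr in _QUARTET_THRESH.items():
                if rng_score.random() < pi:
                    score_vals[name] = round(thr + (1.0 - thr) * rng_score.random() * 0.99
                                             + (1.0 - thr) * 0.005, 4)
                else:
                    score_vals[name] = round(thr * rng_score.random() * 0.99, 4)
            quartet_list.append(QuartetScores(**score_vals))
        else:
            trio_list.append(None)
            quartet_list.append(None)

    if config.target_q_per_100k is not None:
        numer = config.target_q_per_100k * config.total_alleles
        if numer % 100_000:
            raise ValueError(
                "target_q_per_100k * total_alleles must be divisible by 100,000 "
                "for exact recovery; choose total_alleles as a multiple of 100,000"
            )
        plp_idx = [
            i for i, c in enumerate(latent) if c in (Classification.P, Classification.LP)
        ]
        _retarget_counts(counts, plp_idx, numer // 100_000)
        _check_counts_feasible(counts, config.total_alleles)

    records = []
    for i in range(config.n_variants):
        vtype = vtypes[i]
        records.append(
            VariantRecord(
                transcript="NM_000045.4",
                hgvs_c=_hgvs_name(i, vtype),
                hgvs_p="p.?",
                variant_type=vtype,
                source=Source.UNPUBLISHED,
                allele_count=counts[i],
                allele_number=config.total_alleles,
                region_flags=infer_region_flags(vtype),
                evidence=evidences[i],
                assigned_class=latent[i],
                trio_calls=trio_list[i],
                quartet_scores=quartet_list[i],
            )
        )

    afs = tuple(Fraction(counts[i], config.total_alleles) for i in range(config.n_variants))
    rule_sets = {
        "acmg_P": {Classification.P},
        "acmg_P_LP": {Classification.P, Classification.LP},
        "acmg_P_LP_VUS": {Classification.P, Classification.LP, Classification.VUS},
    }
    q_by_rule = {
        rule: sum((afs[i] for i, c in enumerate(latent) if c in allowed), Fraction(0))
        for rule, allowed in rule_sets.items()
    }
    ledger = GroundTruthLedger(
        classes=tuple(latent),
        allele_frequencies=afs,
        consequence_counts=dict(Counter(v.value for v in vtypes)),
        q_by_rule=q_by_rule,
    )
    return records, ledger


def generate_curation_scenario(
    seed: int,
    published: Sequence[VariantRecord],
    n_db: int = 457,
    n_duplicates: int = 26,
    n_overlap_intronic: int = 129,
) -> list:
    """A database-style table with planted duplicates and overlap-gene introns.

    Returns ``n_db`` records of which ``n_duplicates`` share a coding-HGVS
    key with the supplied published list and ``n_overlap_intronic`` are
    intronic records flagged as belonging to the overlapping gene, so the
    curation stage should retain ``n_db - n_duplicates - n_overlap_intronic``.
    """
    if n_duplicates > len(published):
        raise ValueError("cannot plant more duplicates than published records")
    n_fresh = n_db - n_duplicates - n_overlap_intronic
    if n_fresh < 0:
        raise ValueError("planted counts exceed n_db")

    config = SyntheticConfig(seed=seed, n_variants=n_fresh + n_overlap_intronic)
    base, _ = generate_table(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[-1])

    db: list = []
    for rec in base[:n_overlap_intronic]:
        db.append(
            rec.replace(
                variant_type=VariantType.INTRONIC,
                hgvs_c=f"{rec.hgvs_c}_ovl",
                region_flags=frozenset({RegionFlag.OVERLAPS_COMED_GENE}),
                evidence=EvidenceSet(),
                assigned_class=None,
                trio_calls=None,
                quartet_scores=None,
            )
        )
    db.extend(base[n_overlap_intronic:])
    dup_sources = rng.choice(len(published), size=n_duplicates, replace=False)
    for idx in dup_sources:
        src = published[int(idx)]
        db.append(
            VariantRecord(
                transcript=src.transcript,
                hgvs_c=src.hgvs_c,
                hgvs_p=src.hgvs_p,
                variant_type=src.variant_type,
                source=Source.UNPUBLISHED,
                allele_count=1,
                allele_number=config.total_alleles,
                region_flags=src.region_flags,
            )
        )
    order = rng.permutation(len(db))
    return [db[int(i)] for i in order]


def make_fixtures() -> tuple:
    """Load the packaged curated variant tables.

    Returns ``(published, unpublished)``: the 73 literature-reported
    variants with their ACMG/AMP evidence and classifications, and the 31
    database-only variants classified pathogenic or likely pathogenic.
    """
    data = resources.files("argprev.data")
    with resources.as_file(data / "published_variants.tsv") as p:
        published = read_variant_table(p)
    with resources.as_file(data / "unpublished_plp_variants.tsv") as p:
        unpublished = read_variant_table(p)
    return published, unpublished
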