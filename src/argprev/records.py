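"""Domain types and readers/writers for curated variant tables.

The central container is :class:`VariantRecord`: one curated gene variant
with its HGVS identity, molecular consequence, ACMG/AMP evidence tokens, an
assigned five-tier classification, gnomAD-style allele counts and any
externally computed in silico predictor outputs.  Tables of records move
through the pipeline as plain lists; :func:`read_variant_table` and
:func:`write_variant_table` give a lossless TSV round trip, and a
gnomAD-style VCF (AC/AN INFO keys) can be ingested through the same reader.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "VariantType",
    "Source",
    "Classification",
    "Strength",
    "RegionFlag",
    "EvidenceSet",
    "TrioCalls",
    "QuartetScores",
    "VariantRecord",
    "parse_evidence",
    "read_variant_table",
    "write_variant_table",
    "infer_region_flags",
]


class VariantType(str, enum.Enum):
    """Molecular consequence class of a variant."""

    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    START_LOSS = "start_loss"
    INFRAME_DELETION = "inframe_deletion"
    GROSS_DELETION = "gross_deletion"
    EXON_DELETION = "exon_deletion"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR5 = "utr5"
    UTR3 = "utr3"
    NONCODING = "noncoding"
    UPSTREAM = "upstream"


#: spellings accepted on input (lower-cased, spaces/hyphens collapsed)
_TYPE_ALIASES = {
    "missense": VariantType.MISSENSE,
    "frameshift": VariantType.FRAMESHIFT,
    "nonsense": VariantType.NONSENSE,
    "stop_gained": VariantType.NONSENSE,
    "splice_site": VariantType.SPLICE_SITE,
    "splice site": VariantType.SPLICE_SITE,
    "start_loss": VariantType.START_LOSS,
    "start loss": VariantType.START_LOSS,
    "inframe_deletion": VariantType.INFRAME_DELETION,
    "in-frame deletion": VariantType.INFRAME_DELETION,
    "in frame deletion": VariantType.INFRAME_DELETION,
    "gross_deletion": VariantType.GROSS_DELETION,
    "gross deletion": VariantType.GROSS_DELETION,
    "exon_deletion": VariantType.EXON_DELETION,
    "exon deletion": VariantType.EXON_DELETION,
    "synonymous": VariantType.SYNONYMOUS,
    "intronic": VariantType.INTRONIC,
    "intronic variant": VariantType.INTRONIC,
    "intron": VariantType.INTRONIC,
    "utr5": VariantType.UTR5,
    "5'utr": VariantType.UTR5,
    "5_prime_utr": VariantType.UTR5,
    "utr3": VariantType.UTR3,
    "3'utr": VariantType.UTR3,
    "3_prime_utr": VariantType.UTR3,
    "noncoding": VariantType.NONCODING,
    "non-coding": VariantType.NONCODING,
    "upstream": VariantType.UPSTREAM,
}


def parse_variant_type(token: str) -> VariantType:
    key = " ".join(token.strip().lower().split())
    try:
        return _TYPE_ALIASES[key]
    except KeyError:
        allowed = sorted({v.value for v in VariantType})
        raise ValueError(
            f"unknown variant type token {token!r}; allowed: {', '.join(allowed)}"
        ) from None


class Source(str, enum.Enum):
    PUBLISHED = "published"
    UNPUBLISHED = "unpublished"


class Classification(str, enum.Enum):
    """Five-tier ACMG/AMP classification label."""

    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


_CLASS_ALIASES = {
    "p": Classification.P,
    "pathogenic": Classification.P,
    "lp": Classification.LP,
    "likely pathogenic": Classification.LP,
    "likely_pathogenic": Classification.LP,
    "vus": Classification.VUS,
    "uncertain significance": Classification.VUS,
    "lb": Classification.LB,
    "likely benign": Classification.LB,
    "likely_benign": Classification.LB,
    "b": Classification.B,
    "benign": Classification.B,
}


def parse_classification(token: str) -> Classification:
    key = " ".join(token.strip().lower().split())
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown classification label {token!r}") from None


class Strength(str, enum.Enum):
    """Evidence strength tier of one applied criterion."""

    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE = "stand_alone"


class RegionFlag(str, enum.Enum):
    CODING = "coding"
    WITHIN_10BP_OF_JUNCTION = "within_10bp_of_junction"
    OVERLAPS_COMED_GENE = "overlaps_comed_gene"


# canonical criterion codes of the classification framework
PATHOGENIC_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
)
BENIGN_CODES = ["BA1"] + [f"BS{i}" for i in range(1, 5)] + [f"BP{i}" for i in range(1, 8)]
ALL_CODES = PATHOGENIC_CODES + BENIGN_CODES
_CODE_ORDER = {c: i for i, c in enumerate(ALL_CODES)}

#: criteria dropped from every evidence set before classification
DEFAULT_EXCLUDED_CODES = frozenset({"PM2", "PP5"})


def default_strength(code: str) -> Strength:
    """Strength tier implied by a criterion code's prefix."""
    if code == "PVS1":
        return Strength.VERY_STRONG
    if code == "BA1":
        return Strength.STAND_ALONE
    if code.startswith(("PS", "BS")):
        return Strength.STRONG
    if code.startswith("PM"):
        return Strength.MODERATE
    if code.startswith(("PP", "BP")):
        return Strength.SUPPORTING
    raise ValueError(f"unknown criterion code {code!r}")


def is_benign_code(code: str) -> bool:
    return code.startswith("B")


@dataclass(frozen=True)
class EvidenceSet:
    """A set of applied ACMG/AMP criteria with their effective strengths.

    Stored as a frozenset of ``(code, strength)`` pairs with at most one
    entry per code; a strength differing from the code prefix's default
    records a strength-modified application (e.g. PVS1 used at moderate).
    """

    items: frozenset = frozenset()

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.items]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate criterion codes in evidence set")
        for code, strength in self.items:
            if code not in _CODE_ORDER:
                raise ValueError(f"unknown criterion code {code!r}")
            if not isinstance(strength, Strength):
                raise TypeError(f"strength for {code} must be a Strength enum")

    @classmethod
    def of(cls, *tokens: str) -> "EvidenceSet":
        """Build from token strings, e.g. ``EvidenceSet.of("PVS1", "PS1_MODERATE")``."""
        return parse_evidence(", ".join(tokens))

    def codes(self) -> frozenset:
        return frozenset(c for c, _ in self.items)

    def strength_of(self, code: str) -> Optional[Strength]:
        for c, s in self.items:
            if c == code:
                return s
        return None

    def without(self, codes: Iterable[str]) -> "EvidenceSet":
        drop = set(codes)
        return EvidenceSet(frozenset((c, s) for c, s in self.items if c not in drop))

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(sorted(self.items, key=lambda cs: _CODE_ORDER[cs[0]]))

    def to_text(self) -> str:
        """Serialize in canonical code order; non-default strengths use ``CODE_STRENGTH``."""
        parts = []
        for code, strength in self:
            if strength == default_strength(code):
                parts.append(code)
            else:
                parts.append(f"{code}_{strength.value.upper()}")
        return ", ".join(parts)


_STRENGTH_SUFFIXES = {s.value.upper(): s for s in Strength}


def parse_evidence(
    text: str, excluded_codes: frozenset = DEFAULT_EXCLUDED_CODES
) -> EvidenceSet:
    """Parse a comma/semicolon-separated list of criterion tokens.

    Tokens are case- and whitespace-insensitive.  The suffix grammar
    ``CODE_STRENGTH`` (e.g. ``PVS1_MODERATE``) applies a criterion at a
    non-default strength.  Codes on the exclusion list (PM2 and PP5 by
    default) are dropped with a warning; a repeated code collapses to a
    single entry (last strength wins) with a warning.
    """
    if text is None:
        text = ""
    entries: dict = {}
    for raw in text.replace(";", ",").split(","):
        token = raw.strip().upper()
        if not token:
            continue
        code, strength = token, None
        if "_" in token:
            head, _, tail = token.partition("_")
            if tail in _STRENGTH_SUFFIXES:
                code, strength = head, _STRENGTH_SUFFIXES[tail]
        if code not in _CODE_ORDER:
            raise ValueError(f"unrecognized evidence token {raw.strip()!r}")
        if strength is None:
            strength = default_strength(code)
        if code in excluded_codes:
            warnings.warn(f"evidence code {code} is excluded and was dropped", stacklevel=2)
            continue
        if code in entries:
            warnings.warn(f"duplicate evidence code {code}; last strength wins", stacklevel=2)
        entries[code] = strength
    return EvidenceSet(frozenset(entries.items()))


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"


class PolyPhenCall(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"


class MutationTasterCall(str, enum.Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"


_SIFT_ALIASES = {"deleterious": SiftCall.DELETERIOUS, "damaging": SiftCall.DELETERIOUS,
                 "tolerated": SiftCall.TOLERATED}
_PP2_ALIASES = {
    "benign": PolyPhenCall.BENIGN,
    "possibly damaging": PolyPhenCall.POSSIBLY_DAMAGING,
    "possibly_damaging": PolyPhenCall.POSSIBLY_DAMAGING,
    "probably damaging": PolyPhenCall.PROBABLY_DAMAGING,
    "probably_damaging": PolyPhenCall.PROBABLY_DAMAGING,
}
# "deleterious" appears as a synonym for a disease-causing MutationTaster2 call
_MT2_ALIASES = {
    "disease causing": MutationTasterCall.DISEASE_CAUSING,
    "disease_causing": MutationTasterCall.DISEASE_CAUSING,
    "disease-causing": MutationTasterCall.DISEASE_CAUSING,
    "deleterious": MutationTasterCall.DISEASE_CAUSING,
    "polymorphism": MutationTasterCall.POLYMORPHISM,
}


@dataclass(frozen=True)
class TrioCalls:
    """Categorical calls from the SIFT / PolyPhen2 / MutationTaster2 trio."""

    sift: Optional[SiftCall] = None
    polyphen2: Optional[PolyPhenCall] = None
    mutationtaster2: Optional[MutationTasterCall] = None

    @classmethod
    def parse(cls, sift: str = "", polyphen2: str = "", mutationtaster2: str = "") -> "TrioCalls":
        def norm(text, aliases, tool):
            key = " ".join(text.strip().lower().split())
            if not key:
                return None
            try:
                return aliases[key]
            except KeyError:
                raise ValueError(f"unknown {tool} call {text!r}") from None

        return cls(
            sift=norm(sift, _SIFT_ALIASES, "SIFT"),
            polyphen2=norm(polyphen2, _PP2_ALIASES, "PolyPhen2"),
            mutationtaster2=norm(mutationtaster2, _MT2_ALIASES, "MutationTaster2"),
        )

    def is_empty(self) -> bool:
        return self.sift is None and self.polyphen2 is None and self.mutationtaster2 is None


@dataclass(frozen=True)
class QuartetScores:
    """Real-valued scores from the BayesDel / MutPred2 / REVEL / VEST4 quartet."""

    bayesdel: Optional[float] = None
    mutpred2: Optional[float] = None
    revel: Optional[float] = None
    vest4: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("mutpred2", "revel", "vest4"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} score {value} outside [0, 1]")

    def is_empty(self) -> bool:
        return all(
            getattr(self, n) is None for n in ("bayesdel", "mutpred2", "revel", "vest4")
        )


@dataclass(frozen=True)
class VariantRecord:
    """One curated variant: identity, consequence, evidence, frequency, scores."""

    transcript: str
    hgvs_c: str
    hgvs_p: str = "p.?"
    variant_type: VariantType = VariantType.MISSENSE
    source: Source = Source.UNPUBLISHED
    allele_count: Optional[int] = None
    allele_number: Optional[int] = None
    region_flags: frozenset = frozenset()
    evidence: EvidenceSet = field(default_factory=EvidenceSet)
    assigned_class: Optional[Classification] = None
    clinvar_label: Optional[str] = None
    trio_calls: Optional[TrioCalls] = None
    quartet_scores: Optional[QuartetScores] = None

    def __post_init__(self) -> None:
        if not self.hgvs_c:
            raise ValueError("hgvs_c must be non-empty")
        if self.allele_count is not None and self.allele_count < 0:
            raise ValueError("allele_count must be non-negative")
        if self.allele_number is not None and self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if (
            self.allele_count is not None
            and self.allele_number is not None
            and self.allele_count > self.allele_number
        ):
            raise ValueError(
                f"allele_count {self.allele_count} exceeds allele_number {self.allele_number}"
            )
        if self.region_flags is not None:
            for flag in self.region_flags:
                if not isinstance(flag, RegionFlag):
                    raise TypeError("region_flags must contain RegionFlag values")

    def replace(self, **kwargs) -> "VariantRecord":
        return replace(self, **kwargs)

    @property
    def dedup_key(self) -> str:
        """Lexically normalized coding-HGVS key used for duplicate matching."""
        return "".join(self.hgvs_c.split()).lower()


def infer_region_flags(variant_type: VariantType) -> frozenset:
    """Conservative region flags implied by consequence class alone."""
    coding = {
        VariantType.MISSENSE,
        VariantType.FRAMESHIFT,
        VariantType.NONSENSE,
        VariantType.START_LOSS,
        VariantType.INFRAME_DELETION,
        VariantType.GROSS_DELETION,
        VariantType.EXON_DELETION,
        VariantType.SYNONYMOUS,
    }
    if variant_type in coding:
        return frozenset({RegionFlag.CODING})
    if variant_type == VariantType.SPLICE_SITE:
        return frozenset({RegionFlag.WITHIN_10BP_OF_JUNCTION})
    return frozenset()


# ---------------------------------------------------------------------------
# Tabular IO

FIXTURE_COLUMNS = [
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "variant_type",
    "evidence",
    "assigned_class",
    "source",
    "allele_count",
    "allele_number",
    "clinvar_label",
    "sift",
    "polyphen2",
    "mutationtaster2",
    "bayesdel",
    "mutpred2",
    "revel",
    "vest4",
]
# optional trailing column carrying region flags (comma-separated tokens)
REGION_FLAGS_COLUMN = "region_flags"


def _record_from_row(row: dict, line_no: int) -> VariantRecord:
    def cell(name: str) -> str:
        value = row.get(name)
        return "" if value is None else str(value).strip()

    def opt_int(name: str) -> Optional[int]:
        text = cell(name)
        return int(text) if text else None

    def opt_float(name: str) -> Optional[float]:
        text = cell(name)
        return float(text) if text else None

    try:
        variant_type = parse_variant_type(cell("variant_type"))
        assigned = cell("assigned_class")
        flags_text = cell(REGION_FLAGS_COLUMN)
        if REGION_FLAGS_COLUMN in row:
            flags = frozenset(
                RegionFlag(tok.strip()) for tok in flags_text.split(",") if tok.strip()
            )
        else:
            flags = infer_region_flags(variant_type)
        trio = TrioCalls.parse(cell("sift"), cell("polyphen2"), cell("mutationtaster2"))
        quartet = QuartetScores(
            bayesdel=opt_float("bayesdel"),
            mutpred2=opt_float("mutpred2"),
            revel=opt_float("revel"),
            vest4=opt_float("vest4"),
        )
        return VariantRecord(
            transcript=cell("transcript"),
            hgvs_c=cell("hgvs_c"),
            hgvs_p=cell("hgvs_p") or "p.?",
            variant_type=variant_type,
            source=Source(cell("source") or "unpublished"),
            allele_count=opt_int("allele_count"),
            allele_number=opt_int("allele_number"),
            region_flags=flags,
            evidence=parse_evidence(cell("evidence")),
            assigned_class=parse_classification(assigned) if assigned else None,
            clinvar_label=cell("clinvar_label") or None,
            trio_calls=None if trio.is_empty() else trio,
            quartet_scores=None if quartet.is_empty() else quartet,
        )
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed variant row at line {line_no}: {exc}") from exc


def _read_fixture_tsv(path: Path) -> list:
    with open(path, newline="") as handle:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            return []
        header = header_line.split("\t")
        records = []
        for line_no, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"malformed variant row at line {line_no}: expected "
                    f"{len(header)} columns, found {len(cells)}"
                )
            records.append(_record_from_row(dict(zip(header, cells)), line_no))
    return records


# VEP-style consequence terms mapped onto the consequence enum
VCF_CONSEQUENCE_MAP = {
    "missense_variant": VariantType.MISSENSE,
    "frameshift_variant": VariantType.FRAMESHIFT,
    "stop_gained": VariantType.NONSENSE,
    "splice_acceptor_variant": VariantType.SPLICE_SITE,
    "splice_donor_variant": VariantType.SPLICE_SITE,
    "splice_region_variant": VariantType.SPLICE_SITE,
    "start_lost": VariantType.START_LOSS,
    "inframe_deletion": VariantType.INFRAME_DELETION,
    "transcript_ablation": VariantType.GROSS_DELETION,
    "synonymous_variant": VariantType.SYNONYMOUS,
    "intron_variant": VariantType.INTRONIC,
    "5_prime_UTR_variant": VariantType.UTR5,
    "3_prime_UTR_variant": VariantType.UTR3,
    "non_coding_transcript_variant": VariantType.NONCODING,
    "non_coding_transcript_exon_variant": VariantType.NONCODING,
    "upstream_gene_variant": VariantType.UPSTREAM,
}


def _read_gnomad_vcf(path: Path) -> list:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf.fetch() if vcf.index is not None else vcf:
            info = site.info
            ac = info.get("AC")
            if isinstance(ac, tuple):
                ac = ac[0]
            an = info.get("AN")
            csq = info.get("CSQ")
            if isinstance(csq, tuple):
                csq = csq[0]
            vtype = VCF_CONSEQUENCE_MAP.get(str(csq)) if csq else None
            if vtype is None:
                ref, alts = site.ref, site.alts or ("",)
                alt = alts[0]
                vtype = (
                    VariantType.MISSENSE
                    if len(ref) == len(alt) == 1
                    else VariantType.FRAMESHIFT
                    if abs(len(ref) - len(alt)) % 3
                    else VariantType.INFRAME_DELETION
                )
            records.append(
                VariantRecord(
                    transcript="",
                    hgvs_c=f"{site.chrom}:g.{site.pos}{site.ref}>{(site.alts or ('?',))[0]}",
                    variant_type=vtype,
                    source=Source.UNPUBLISHED,
                    allele_count=int(ac) if ac is not None else None,
                    allele_number=int(an) if an is not None else None,
                    region_flags=infer_region_flags(vtype),
                )
            )
    return records


def read_variant_table(path, dialect: str = "fixture_tsv") -> list:
    """Read a variant table.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {"fixture_tsv", "gnomad_vcf"}
        ``fixture_tsv`` is the package's canonical tab-separated layout;
        ``gnomad_vcf`` ingests a VCF with AC/AN INFO keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "fixture_tsv":
        return _read_fixture_tsv(path)
    if dialect == "gnomad_vcf":
        return _read_gnomad_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _row_from_record(rec: VariantRecord) -> list:
    trio = rec.trio_calls or TrioCalls()
    quartet = rec.quartet_scores or QuartetScores()

    def fmt(value) -> str:
        if value is None:
            return ""
        if isinstance(value, enum.Enum):
            return value.value
        return str(value)

    return [
        rec.transcript,
        rec.hgvs_c,
        rec.hgvs_p,
        rec.variant_type.value,
        rec.evidence.to_text(),
        fmt(rec.assigned_class),
        rec.source.value,
        fmt(rec.allele_count),
        fmt(rec.allele_number),
        fmt(rec.clinvar_label),
        fmt(trio.sift),
        fmt(trio.polyphen2),
        fmt(trio.mutationtaster2),
        fmt(quartet.bayesdel),
        fmt(quartet.mutpred2),
        fmt(quartet.revel),
        fmt(quartet.vest4),
        ",".join(sorted(f.value for f in rec.region_flags or ())),
    ]


def write_variant_table(records: Iterable[VariantRecord], path) -> None:
    """Write records as canonical TSV, re-readable with field equality."""
    path = Path(path)
    lines = ["\t".join(FIXTURE_COLUMNS + [REGION_FLAGS_COLUMN])]
    for rec in records:
        lines.append("\t".join(_row_from_record(rec)))
    path.write_text("\n".join(lines) + "\n")
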