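# Methods

## Model

For an autosomal recessive condition, let q be the summed population
frequency of all disease-attributed alleles in the gene and p = 1 − q.
Under Hardy–Weinberg equilibrium the genotype frequencies are p² (AA),
2pq (Aa, carriers) and q² (aa, affected), so birth prevalence is q² and
carrier frequency 2pq. Treating q as a *summed* frequency folds compound
heterozygotes and homozygotes together: the affected frequency is the
square of the union frequency, with no per-genotype enumeration and no
consanguinity correction (deliberately out of scope). Both figures are
reported in the conventional "1 in N" form with

- N_prevalence = round(1/q²)
- N_carrier  = round(1/(2pq))

using round-half-away-from-zero on exact rationals. The p factor in the
carrier denominator matters at the frequencies involved here: at
q = 124/100,000 the naive 1/(2q) rounds to 403 while 1/(2pq) rounds to
404; at q = 80/100,000 the two differ by one unit as well (625 vs 626).
Aggregation is carried in `fractions.Fraction` end to end; floats appear
only in display, so sums are permutation-invariant and drift-free.

## Inclusion models

Seven declarative model specifications (A–G) decide which variants
contribute to q. A counts published (literature-reported) variants only.
B and C add unpublished database variants called damaging by the
SIFT/PolyPhen2/MutationTaster2 trio (B: 3-of-3 with PolyPhen2 at
"probably damaging"; C: 2-of-3 with "possibly damaging" accepted); both
deem protein-length-altering classes (frameshift, nonsense, gross/exon
deletion, in-frame deletion, start loss) pathogenic without scoring and
drop UTR/intronic/noncoding/synonymous/upstream classes before the in
silico step. D, E and F select on the five-tier classification (P; P∪LP;
P∪LP∪VUS), excluding upstream/UTR/noncoding/synonymous classes but
retaining splice variants classified P/LP. G parallels B with the newer
quartet (BayesDel/MutPred2/REVEL/VEST4) at their published calibration
cut-offs, as strict inequalities. Because the label sets nest
(P ⊆ P∪LP ⊆ P∪LP∪VUS), q and hence prevalence are monotone across
D → E → F on any fixed table; the property suite asserts this.

Missing allele frequencies follow two conventions: a variant absent from
the database and located neither in the coding sequence nor within 10 bp
of an exon–intron junction contributes 0 (over the 282,912-allele
reference denominator, i.e. 2 × (125,748 exomes + 15,708 genomes)); any
other unlisted variant is assigned the upper-limit frequency 1/300,000.
"Within 10 bp of an intron" is read as within 10 bp of an exon–intron
junction and carried as an explicit region flag; when a table lacks the
flag column, flags are inferred conservatively from the consequence
class (coding classes → coding; splice-site → near-junction).

## Rules engine

Two evidence-combination systems share one configuration. The classical
system implements the original combining clauses over counts of criteria
at each effective strength tier; benign-moderate (only reachable through
strength-modified tokens) counts as benign-supporting, since the
classical benign clauses know no moderate tier. If a pathogenic and a
benign clause fire simultaneously the result is VUS ("conflicting");
if none fires, VUS ("unmet"). The points system sums signed strength
points (supporting 1, moderate 2, strong 4, very strong/stand-alone 8;
benign negative) and thresholds the total (P ≥ 10, LP 6–9, VUS 0–5,
LB −6…−1, B ≤ −7). Strength-modified criteria (underscore grammar,
e.g. `PVS1_MODERATE`) count at the modified tier in both systems.

PM2 and PP5 are stripped at parse time: PM2 (rarity) is circular when
the cohort *is* a population database, and PP5 is deprecated. The points
system is the default because it reproduces the dominant pattern in the
packaged tables — a lone PVS1 yields LP (8 points), PVS1+PS1 yields P
(12) — which the classical clauses cannot (classical PVS1 alone meets no
clause). Curated labels the engine cannot reach from the printed
evidence (e.g. LP on PM1+PP2+PP3 = 4 points, or P on PVS1 alone) are
*surfaced* through the concordance report rather than special-cased:
the original curation involved manual review whose extra evidence is not
recoverable, and silently reproducing its labels would misrepresent what
the evidence strings support. Both engines are verified exhaustively
against brute-force oracles over all 2¹⁰ subsets of the ten criterion
codes occurring in the packaged tables.

## Curation

Database records are deduplicated against the published list on a
lexically normalized coding-HGVS key (whitespace removed, case folded) —
list-level matching, not allele normalization, because the inputs are
curated tables rather than raw coordinates. Intronic records flagged as
belonging to the overlapping gene (MED23 overlaps ARG1) are then removed;
the flag combination is deliberate — a *coding* variant inside the
overlap span still belongs to the target gene. The curation report
guarantees by construction that every removed record lands in exactly
one counter. The analysis this package operationalizes reports 457
database variants − 26 duplicates − 129 overlap-intronic = 302 retained;
the pipeline reports its own arithmetic at each stage precisely because
such ledgers are where published counts tend to drift.

## Synthetic data

The generator emulates a small gene's variant list in a gnomAD-like
database: n variants over an even total allele number (default 282,912),
allele counts drawn as singletons with probability 0.8 (default) and a
geometric tail otherwise, a consequence mixture dominated by intronic
(0.40) and missense (0.24) classes, and a latent five-tier class drawn
from a VUS-dominated mix (P 0.010, LP 0.093, VUS 0.758, LB 0.116,
B 0.023 — the proportions observed in the curated unpublished set).
Evidence tokens are drawn per class from profiles mirroring the
combinations seen in the curated tables (P: {PVS1, PS1} with designed
0.9 engine-recovery probability; LP: {PVS1} or a moderate-heavy set;
VUS: supporting-only; LB/B: benign tokens), and predictor outputs are
drawn with a per-class damaging propensity for missense and splice-site
records. Latent P/LP variants are restricted to consequence classes
compatible with pathogenicity so that label-rule selection equals the
ledger's P/LP set exactly, making q-recovery an exact rational identity
rather than a statistical check.

When a target q (per 100,000) is requested, the P/LP allele counts are
re-apportioned by largest remainder to sum to target × total_alleles /
100,000, which must be an integer — use a total allele number that is a
multiple of 100,000 (tests use 300,000, itself one of the convention
denominators); counts may be rescaled to zero. All randomness flows from
one seed through per-field-family `numpy` substreams, so identical seeds
give byte-identical tables.

What the generator does not emulate: population substructure, linkage,
per-ancestry frequencies, genotype-level data, and realistic HGVS
coordinates (synthetic positions start beyond the real coding range to
avoid colliding with fixture keys). Passing tests therefore demonstrate
the pipeline's arithmetic and selection logic, not calibration against
real cohort composition.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: exhaustive
engine checks at 1,024 subsets, fixture tables at 73 + 31 records, the
planted curation scenario at 457 records, synthetic recovery at 10,000
variants — a few seconds in total on one CPU. Rounding is
half-away-from-zero everywhere a "1 in N" figure is produced; q = 0 or
q ≥ 1 raise rather than return infinities; empty selections warn at
aggregation and error at conversion.

## Known limitations

- Evidence *assignment* is out of scope: the engine combines given
  criterion tokens; it does not decide whether PVS1 applies to a variant.
- The packaged tables carry no per-variant AC/AN (the source tabulations
  do not print them), so fixture-driven prevalence runs resolve through
  the missing-data conventions and are upper-bound-flavoured; the
  tabulated per-model summed frequencies are used directly where the
  published "1 in N" figures are reproduced.
- No confidence intervals on q: inputs are point frequencies.
- VCF ingest reads AC/AN and a single consequence token per site; full
  VEP annotation parsing and multi-allelic decomposition are not
  attempted.
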