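"""Rules-engine behaviour against independent brute-force oracles."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from argprev.acmg import (
    CombinerConfig,
    classify_classical,
    classify_points,
    concordance_report,
)
from argprev.records import Classification, EvidenceSet, parse_evidence

# the criterion codes occurring in the curated fixture tables
FIXTURE_CODES = ["PVS1", "PS1", "PM1", "PM3", "PM4", "PM5", "PP2", "PP3", "BS1", "BP7"]

# --- independent oracles -----------------------------------------------------

_POINTS = {"PVS1": 8, "PS1": 4, "PM1": 2, "PM3": 2, "PM4": 2, "PM5": 2,
           "PP2": 1, "PP3": 1, "BS1": -4, "BP7": -1}


def points_oracle(codes):
    total = sum(_POINTS[c] for c in codes)
    if total >= 10:
        label = "P"
    elif total >= 6:
        label = "LP"
    elif total >= 0:
        label = "VUS"
    elif total >= -6:
        label = "LB"
    else:
        label = "B"
    return label, total


def classical_oracle(codes):
    vs = sum(1 for c in codes if c == "PVS1")
    s = sum(1 for c in codes if c == "PS1")
    m = sum(1 for c in codes if c in ("PM1", "PM3", "PM4", "PM5"))
    p = sum(1 for c in codes if c in ("PP2", "PP3"))
    bs = sum(1 for c in codes if c == "BS1")
    bp = sum(1 for c in codes if c == "BP7")

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_label = "P" if pathogenic else ("LP" if likely else None)
    ben_label = "B" if benign else ("LB" if likely_benign else None)
    if path_label and ben_label:
        return "VUS"
    return path_label or ben_label or "VUS"


def all_subsets(codes):
    for r in range(len(codes) + 1):
        yield from combinations(codes, r)


# --- exhaustive equivalence --------------------------------------------------

class TestOracleEquivalence:
    def test_points_engine_matches_summation_oracle_on_all_subsets(self):
        for subset in all_subsets(FIXTURE_CODES):
            ev = EvidenceSet.of(*subset) if subset else EvidenceSet()
            result = classify_points(ev)
            label, total = points_oracle(subset)
            assert (result.label.value, result.points) == (label, total), subset

    def test_classical_engine_matches_clause_oracle_on_all_subsets(self):
        for subset in all_subsets(FIXTURE_CODES):
            ev = EvidenceSet.of(*subset) if subset else EvidenceSet()
            assert classify_classical(ev).label.value == classical_oracle(subset), subset


# --- worked examples ---------------------------------------------------------

class TestClassicalExamples:
    @pytest.mark.parametrize(
        "tokens, label",
        [
            ("PS1, PVS1", "P"),
            ("PS1, PP3, PP2", "LP"),
            ("PP2, PP3", "VUS"),
            ("BS1, PP2", "VUS"),
            ("", "VUS"),
        ],
    )
    def test_fixture_evidence_combinations(self, tokens, label):
        assert classify_classical(parse_evidence(tokens)).label.value == label

    def test_conflicting_tiers_give_vus(self):
        ev = EvidenceSet.of("PVS1", "PS1", "BS1", "BS2")
        result = classify_classical(ev)
        assert result.label == Classification.VUS
        assert result.rule_fired == "conflicting"

    def test_stand_alone_benign(self):
        assert classify_classical(EvidenceSet.of("BA1")).label == Classification.B


class TestPointsExamples:
    @pytest.mark.parametrize(
        "tokens, points, label",
        [
            ("PVS1", 8, "LP"),
            ("PS1, PVS1", 12, "P"),
            ("PP3, PP2, PM1, PM5", 6, "LP"),
            ("", 0, "VUS"),
            ("BA1", -8, "B"),
            ("BS1, BP7", -5, "LB"),
        ],
    )
    def test_signed_point_sums(self, tokens, points, label):
        result = classify_points(parse_evidence(tokens))
        assert (result.points, result.label.value) == (points, label)

    def test_modified_strength_counts_at_modified_tier(self):
        # a very-strong criterion demoted to moderate contributes 2 points
        assert classify_points(parse_evidence("PVS1_MODERATE")).points == 2


# --- invariants --------------------------------------------------------------

_TIER_ORDER = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}
_path_codes = [c for c in FIXTURE_CODES if not c.startswith("B")]


@given(
    subset=st.sets(st.sampled_from(FIXTURE_CODES)),
    extra=st.sampled_from(_path_codes),
)
def test_points_adding_pathogenic_evidence_never_lowers_tier(subset, extra):
    before = classify_points(EvidenceSet.of(*subset) if subset else EvidenceSet())
    after = classify_points(EvidenceSet.of(*(subset | {extra})))
    assert _TIER_ORDER[after.label.value] >= _TIER_ORDER[before.label.value]


@given(
    subset=st.sets(st.sampled_from(FIXTURE_CODES)),
    extra=st.sampled_from(["BS1", "BP7"]),
)
def test_points_adding_benign_evidence_never_raises_tier(subset, extra):
    before = classify_points(EvidenceSet.of(*subset) if subset else EvidenceSet())
    after = classify_points(EvidenceSet.of(*(subset | {extra})))
    assert _TIER_ORDER[after.label.value] <= _TIER_ORDER[before.label.value]


@given(subset=st.sets(st.sampled_from(FIXTURE_CODES)))
def test_excluding_pm2_is_idempotent(subset):
    # PM2 never survives parsing, so including it changes nothing
    with_pm2 = EvidenceSet.of(*(subset | {"PM2"}))
    without = EvidenceSet.of(*subset) if subset else EvidenceSet()
    assert classify_points(with_pm2) == classify_points(without)
    assert classify_classical(with_pm2) == classify_classical(without)


# --- concordance reporting ---------------------------------------------------

class TestConcordance:
    def test_pvs1_only_rows_engine_labeled_lp_and_printed_p_flagged(self, unpublished):
        report = concordance_report(unpublished, CombinerConfig(system="points"))
        frame = report.per_record
        pvs1_only = frame[frame["evidence"] == "PVS1"]
        assert (pvs1_only["engine"] == "LP").all()
        # rows curated P on PVS1 alone are surfaced as discordant, not forced
        forced = frame[(frame["evidence"] == "PVS1") & (frame["assigned"] == "P")]
        assert len(forced) >= 1
        assert set(forced["hgvs_c"]).issubset(set(report.discordant["hgvs_c"]))

    def test_full_agreement_when_labels_come_from_engine(self, unpublished):
        config = CombinerConfig(system="points")
        from argprev.acmg import classify

        relabeled = [
            rec.replace(assigned_class=classify(rec.evidence, config).label)
            for rec in unpublished
        ]
        report = concordance_report(relabeled, config)
        assert report.n_agree == report.n_total == len(unpublished)

    def test_assigned_labels_never_mutated(self, published):
        before = [rec.assigned_class for rec in published]
        concordance_report(published, CombinerConfig(system="points"))
        assert [rec.assigned_class for rec in published] == before

    def test_all_labels_missing_is_an_error(self, published):
        stripped = [rec.replace(assigned_class=None) for rec in published]
        with pytest.raises(ValueError, match="label"):
            concordance_report(stripped, CombinerConfig())
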