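"""Allele-frequency resolution, exact aggregation, Hardy-Weinberg conversion
and the A-G inclusion models."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from argprev.prevalence import (
    DEFAULT_CONVENTION,
    MODELS,
    aggregate_q,
    hardy_weinberg,
    resolve_allele_frequency,
    round_half_away,
    run_model,
    select_variants,
)
from argprev.records import (
    Classification,
    RegionFlag,
    Source,
    VariantRecord,
    VariantType,
)
from argprev.simulate import SyntheticConfig, generate_table


def _rec(hgvs_c="c.1G>A", ac=None, an=None, vtype=VariantType.MISSENSE,
         flags=None, source=Source.PUBLISHED, assigned=None):
    if flags is None:
        flags = frozenset({RegionFlag.CODING}) if vtype == VariantType.MISSENSE else frozenset()
    return VariantRecord(
        transcript="NM_000045.4", hgvs_c=hgvs_c, variant_type=vtype,
        allele_count=ac, allele_number=an, region_flags=flags,
        source=source, assigned_class=assigned,
    )


class TestResolveAlleleFrequency:
    def test_present_in_database_gives_direct_ratio(self):
        rec = _rec(ac=3, an=282_912)
        assert resolve_allele_frequency(rec) == Fraction(3, 282_912)

    def test_absent_deep_intronic_counts_zero(self):
        rec = _rec(vtype=VariantType.INTRONIC, flags=frozenset())
        assert resolve_allele_frequency(rec) == 0

    def test_absent_coding_gets_assumed_upper_limit(self):
        rec = _rec(flags=frozenset({RegionFlag.CODING}))
        assert resolve_allele_frequency(rec) == Fraction(1, 300_000)

    def test_absent_near_junction_gets_assumed_upper_limit(self):
        rec = _rec(vtype=VariantType.SPLICE_SITE,
                   flags=frozenset({RegionFlag.WITHIN_10BP_OF_JUNCTION}))
        assert resolve_allele_frequency(rec) == Fraction(1, 300_000)

    def test_unknown_flags_demanded(self):
        rec = _rec(flags=None).replace(region_flags=None)
        with pytest.raises(ValueError, match="region_flags"):
            resolve_allele_frequency(rec)


class TestAggregateQ:
    def test_two_records_sum_exactly(self):
        records = [_rec("c.1G>A", 3, 300_000), _rec("c.4G>A", 3, 300_000)]
        q = aggregate_q(records)
        assert q * 100_000 == 2

    def test_500_singletons_over_250000(self):
        records = [_rec(f"c.{3 * i + 1}G>A", 1, 250_000) for i in range(500)]
        assert aggregate_q(records) * 100_000 == 200

    def test_permutation_invariant_and_exact(self):
        records, _ = generate_table(SyntheticConfig(seed=2, n_variants=200))
        q_fwd = aggregate_q(records)
        q_rev = aggregate_q(records[::-1])
        assert q_fwd == q_rev
        assert isinstance(q_fwd, Fraction)

    def test_empty_selection_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="zero"):
            assert aggregate_q([]) == 0


# printed allele frequencies (per 100,000) and the published "1 in N"
# figures they convert to
HW_TABLE = {
    "A": (61, 2_687_450, 820),
    "B": (124, 650_364, 404),
    "C": (225, 197_531, 223),
    "D": (17, 34_602_076, 2942),
    "E": (41, 5_948_840, 1220),
    "F": (266, 141_331, 188),
    "G": (80, 1_562_500, 626),
}


class TestHardyWeinberg:
    @pytest.mark.parametrize("model_id", sorted(HW_TABLE))
    def test_published_q_to_prevalence_and_carrier(self, model_id):
        q100k, prevalence, carrier = HW_TABLE[model_id]
        hw = hardy_weinberg(Fraction(q100k, 100_000))
        assert hw.prevalence_one_in == prevalence
        assert hw.carrier_one_in == carrier

    def test_closed_form_half(self):
        hw = hardy_weinberg(Fraction(1, 2))
        assert hw.prevalence_one_in == 4
        assert hw.carrier_one_in == 2
        assert hw.carrier_rate_simple == 1

    def test_carrier_needs_the_p_factor(self):
        # 1/(2q) alone would give 403 here; 2pq gives the published 404
        hw = hardy_weinberg(Fraction(124, 100_000))
        assert round_half_away(1 / (2 * hw.q)) == 403
        assert hw.carrier_one_in == 404

    @pytest.mark.parametrize("bad_q", [0, 1, -0.1, 1.5])
    def test_degenerate_q_rejected(self, bad_q):
        with pytest.raises(ValueError):
            hardy_weinberg(bad_q)

    @given(n=st.integers(10_000, 100_000_000))
    def test_round_trips_one_in_n_prevalence(self, n):
        # q derived from a "1 in n" prevalence is sqrt(1/n); converting back
        # must recover n (float sqrt error is far below the rounding step)
        import math

        q = Fraction(math.sqrt(1.0 / n))
        assert hardy_weinberg(q).prevalence_one_in == n

    def test_prevalence_never_below_carrier(self):
        for q100k, _, _ in HW_TABLE.values():
            hw = hardy_weinberg(Fraction(q100k, 100_000))
            assert hw.prevalence_one_in >= hw.carrier_one_in


class TestSelectVariants:
    def test_pathogenic_only_rule_on_published_table(self, published):
        selected = select_variants(published, MODELS["D"])
        assert len(selected) == 16

    def test_p_lp_rule_on_both_tables(self, all_records):
        selected = select_variants(all_records, MODELS["E"])
        assert len(selected) == 77
        n_pub = sum(1 for r in selected if r.source == Source.PUBLISHED)
        assert (n_pub, len(selected) - n_pub) == (46, 31)

    def test_empty_input_empty_output(self):
        assert select_variants([], MODELS["E"]) == []

    def test_label_rule_without_labels_errors(self):
        rec = _rec(assigned=None, source=Source.UNPUBLISHED)
        with pytest.raises(ValueError, match="label"):
            select_variants([rec], MODELS["D"])

    def test_frameshift_tally_among_published_p_lp(self, published):
        selected = select_variants(published, MODELS["E"])
        tally = sum(1 for r in selected if r.variant_type == VariantType.FRAMESHIFT)
        assert tally == 17


class TestRunModel:
    def test_model_d_on_printed_q(self):
        # the printed summed frequency for the P-only model, fed through the
        # same conversion the pipeline applies
        hw = hardy_weinberg(Fraction(17, 100_000))
        assert hw.prevalence_one_in == 34_602_076

    def test_nesting_d_e_f_on_fixtures(self, all_records):
        runs = {m: run_model(all_records, m) for m in "DEF"}
        assert runs["D"].q <= runs["E"].q <= runs["F"].q
        assert (runs["D"].hw.prevalence_one_in
                >= runs["E"].hw.prevalence_one_in
                >= runs["F"].hw.prevalence_one_in)

    def test_nesting_on_synthetic_table(self):
        records, _ = generate_table(SyntheticConfig(seed=9, n_variants=2000))
        runs = {m: run_model(records, m) for m in "DEF"}
        assert runs["D"].q <= runs["E"].q <= runs["F"].q

    def test_empty_selection_errors_q_zero(self):
        rec = _rec(assigned=Classification.B, source=Source.UNPUBLISHED,
                   ac=1, an=300_000)
        with pytest.raises(ValueError, match="q = 0"):
            run_model([rec], "D")

    def test_synthetic_ledger_q_recovered(self):
        config = SyntheticConfig(seed=4, n_variants=500)
        records, ledger = generate_table(config)
        run = run_model(records, "E")
        assert run.q == ledger.q_by_rule["acmg_P_LP"]

    def test_unknown_model_rejected(self, all_records):
        with pytest.raises(ValueError, match="A..G"):
            run_model(all_records, "Z")
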