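from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from myelomap.datamodel import CNVSegment, GenomicBreakpoint, SVCall
from myelomap.classify import (
    assign_size_bin,
    call_intrachromosomal_rearrangements,
    classify_clonality,
    detect_complex_rearrangements,
    flag_high_risk_loci,
    load_default_high_risk_loci,
)

from oracles import oracle_complex_components


class TestSizeBins:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (500, "small"),
            (50_000, "small"),
            (50_001, "medium"),
            (5_000_000, "medium"),
            (5_000_001, "large"),
            (14_502_000, "large"),  # the flagship EMM1 rearrangement
        ],
    )
    def test_declared_bin_edges(self, mk_call, size, expected):
        call = mk_call(pos_a=10**6, pos_b=10**6 + size, size_bp=size)
        assert assign_size_bin(call) == expected

    def test_sub_threshold_size_is_rejected_with_warning(self, mk_call):
        call = mk_call(pos_a=1000, pos_b=1499, size_bp=499)
        with pytest.warns(UserWarning, match="below"):
            assert assign_size_bin(call) is None

    def test_translocations_have_no_size_class(self, mk_call):
        call = mk_call(sv_type="translocation_inter", chrom_a="1", chrom_b="19", size_bp=None)
        assert assign_size_bin(call) == "not_applicable"


class TestClonality:
    @pytest.mark.parametrize(
        "vaf,expected",
        [(25.0, "subclonal"), (25.1, "clonal"), (49.0, "clonal"), (5.1, "subclonal")],
    )
    def test_cutoff_is_inclusive_subclonal(self, mk_call, vaf, expected):
        assert classify_clonality(mk_call(vaf_pct=vaf)) == expected

    def test_missing_vaf_is_an_error(self, mk_call):
        with pytest.raises(ValueError, match="VAF"):
            classify_clonality(mk_call(vaf_pct=None))

    def test_all_emm_fixture_intra_rearrangements_are_subclonal(self, fixture_cohort):
        calls, meta = fixture_cohort
        emm = {m.sample_id for m in meta if m.group == "EMM"}
        intra = [c for c in calls if c.sv_type == "intra_rearrangement" and c.sample_id in emm]
        assert intra and all(classify_clonality(c) == "subclonal" for c in intra)
        assert max(c.vaf_pct for c in intra) == 21


class TestIntraRearrangementCalling:
    def test_large_deletion_over_cn1_segment_is_retyped_with_loss_support(self, mk_call):
        call = mk_call(sv_type="deletion", pos_a=1_000_000, pos_b=15_560_000, sample_id="S1")
        cnv = [CNVSegment("S1", "1", 1_000_000, 15_560_000, 1)]
        (out,) = call_intrachromosomal_rearrangements([call], cnv)
        assert out.sv_type == "intra_rearrangement"
        assert out.cnv_support == "loss"
        assert out.original_type == "deletion"

    def test_inversion_over_uniform_cn2_is_copy_neutral(self, mk_call):
        call = mk_call(sv_type="inversion", pos_a=10**6, pos_b=7 * 10**6, sample_id="S1")
        cnv = [CNVSegment("S1", "2", 1, 10**7, 1)]  # other chromosome only
        (out,) = call_intrachromosomal_rearrangements([call], cnv)
        assert out.sv_type == "intra_rearrangement"
        assert out.cnv_support == "neutral"

    @pytest.mark.parametrize("span,retyped", [(4_999_999, False), (5_000_000, True)])
    def test_span_threshold_is_inclusive_at_5_mbp(self, mk_call, span, retyped):
        call = mk_call(sv_type="deletion", pos_a=10**6, pos_b=10**6 + span)
        (out,) = call_intrachromosomal_rearrangements([call], [])
        assert (out.sv_type == "intra_rearrangement") is retyped

    def test_sample_without_cnv_profile_is_unassessed(self, mk_call):
        call = mk_call(sv_type="deletion", pos_a=10**6, pos_b=8 * 10**6, sample_id="S9")
        (out,) = call_intrachromosomal_rearrangements(
            [call], [CNVSegment("other", "1", 1, 100, 1)]
        )
        assert out.cnv_support == "unassessed"

    def test_retyping_changes_nothing_but_type_and_support(self, genome, mk_call):
        rng = np.random.default_rng(8)
        calls = []
        for _ in range(30):
            pos_a = int(rng.integers(1, 10**8))
            span = int(rng.integers(10**6, 10**7))
            calls.append(
                mk_call(sv_type="deletion", pos_a=pos_a, pos_b=pos_a + span, sample_id="S1")
            )
        out = call_intrachromosomal_rearrangements(calls, [])
        for before, after in zip(calls, out):
            assert (before.bp_a, before.bp_b) == (after.bp_a, after.bp_b)
            assert before.vaf_pct == after.vaf_pct
            assert before.sample_id == after.sample_id
            assert before.size_bp == after.size_bp
            if after.sv_type == "intra_rearrangement":
                assert after.span_bp >= 5_000_000


class TestComplexRearrangements:
    def _trans(self, mk_call, chrom_a, pos_a, chrom_b, pos_b, sample_id="MM1"):
        return mk_call(
            sv_type="translocation_inter",
            chrom_a=chrom_a,
            pos_a=pos_a,
            chrom_b=chrom_b,
            pos_b=pos_b,
            size_bp=None,
            sample_id=sample_id,
        )

    def test_single_translocation_is_not_complex(self, mk_call):
        assert detect_complex_rearrangements([self._trans(mk_call, "1", 10**7, "19", 10**7)]) == []

    def test_chain_sharing_a_chromosome_within_window_is_one_event(self, mk_call):
        # a chr8-hub chain: t(6;8), t(8;17), t(8;22) with chr8 breakpoints within 1 Mbp
        calls = [
            self._trans(mk_call, "6", 50_000_000, "8", 127_000_000),
            self._trans(mk_call, "8", 127_400_000, "17", 30_000_000),
            self._trans(mk_call, "8", 127_900_000, "22", 20_000_000),
        ]
        (event,) = detect_complex_rearrangements(calls)
        assert event.chromosomes == frozenset({"6", "8", "17", "22"})
        assert len(event.member_call_ids) == 3

    def test_disjoint_translocations_are_not_complex(self, mk_call):
        calls = [
            self._trans(mk_call, "1", 10**7, "2", 10**7),
            self._trans(mk_call, "3", 10**7, "4", 10**7),
        ]
        assert detect_complex_rearrangements(calls) == []

    def test_matches_connected_components_oracle_on_random_sets(self, genome, mk_call, config):
        rng = np.random.default_rng(12)
        chroms = list(genome.chromosomes)[:10]
        for trial in range(20):
            calls = []
            for k in range(int(rng.integers(2, 50))):
                ca, cb = rng.choice(chroms, size=2, replace=False)
                calls.append(
                    self._trans(
                        mk_call,
                        str(ca),
                        int(rng.integers(1, 5 * 10**7)),
                        str(cb),
                        int(rng.integers(1, 5 * 10**7)),
                        sample_id=f"S{k % 3}",
                    )
                )
            got = {
                frozenset(e.member_call_ids)
                for e in detect_complex_rearrangements(calls, config)
            }
            assert got == oracle_complex_components(calls, config.complex_link_window_bp)


class TestHighRiskLoci:
    def test_default_loci_cover_the_published_panel(self):
        names = {l.name for l in load_default_high_risk_loci()}
        assert names == {
            "TP53_17p13",
            "RB1_13q14",
            "MYC_8q24",
            "GAIN_1q21",
            "DEL_1p32",
            "IGH_14q32",
            "IGK_2p11",
            "IGL_22q11",
        }

    def test_cn1_over_tp53_region_flags_cnv_loss(self):
        loci = load_default_high_risk_loci()
        cnv = [CNVSegment("EMM1", "17", 7_400_000, 7_800_000, 1)]
        matrix = flag_high_risk_loci([], cnv, loci)
        assert "cnv_loss" in matrix.flags("EMM1", "TP53_17p13")
        assert matrix.flags("EMM1", "MYC_8q24") == frozenset()

    def test_deletion_with_cn_loss_over_rb1_flags_sv_and_cnv_loss(self, mk_call):
        loci = load_default_high_risk_loci()
        call = mk_call(
            sv_type="deletion", chrom_a="13", pos_a=48_000_000, pos_b=49_100_000, sample_id="MM2"
        )
        cnv = [CNVSegment("MM2", "13", 47_900_000, 49_200_000, 1)]
        matrix = flag_high_risk_loci([call], cnv, loci)
        assert matrix.flags("MM2", "RB1_13q14") == frozenset({"sv", "cnv_loss"})

    def test_translocation_breakpoint_inside_igh_flags_translocation(self, mk_call):
        loci = load_default_high_risk_loci()
        call = mk_call(
            sv_type="translocation_inter",
            chrom_a="4",
            pos_a=1_900_000,
            chrom_b="14",
            pos_b=105_700_000,
            size_bp=None,
            sample_id="MM3",
        )
        matrix = flag_high_risk_loci([call], [], loci)
        assert "translocation" in matrix.flags("MM3", "IGH_14q32")

    def test_no_input_gives_all_none_matrix(self):
        loci = load_default_high_risk_loci()
        matrix = flag_high_risk_loci([], [], loci, samples=("A", "B"))
        assert all(
            matrix.flags(s, l.name) == frozenset() for s in ("A", "B") for l in loci
        )

    def test_flags_are_monotone_under_added_evidence(self, genome, mk_call):
        rng = np.random.default_rng(5)
        loci = load_default_high_risk_loci()
        from conftest import random_calls

        calls = random_calls(rng, 40, genome, sample_id="S1")
        cnv = [CNVSegment("S1", "17", 1_000_000, 9_000_000, 1)]
        base = flag_high_risk_loci(calls[:20], [], loci, samples=("S1",))
        more = flag_high_risk_loci(calls, cnv, loci, samples=("S1",))
        for locus in loci:
            assert base.flags("S1", locus.name) <= more.flags("S1", locus.name)
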