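"""SNV filter criteria and diagnostic-SNP identification."""

from __future__ import annotations

import pytest

from homeobias.io import DataError, LibraryMeta
from homeobias.snps import (
    SnvFilterCriteria,
    call_candidate_sites,
    identify_diagnostic_snps,
    partition_polymorphisms,
)

from conftest import GOLDEN_META, PARENTAL_META, make_record


def site(tid="t1", pos=100, qual=40, length=500, **per_lib_counts):
    per_lib = {lib: dict(zip("ACGT", cs)) for lib, cs in per_lib_counts.items()}
    return make_record(tid, pos, "C", per_lib, length=length, qual=qual)


def full_site(tid="t1", pos=100, qual=40, length=500):
    return make_record(
        tid,
        pos,
        "C",
        {
            "PP1": {"C": 30},
            "PP2": {"C": 30},
            "AA1": {"T": 30},
            "AA2": {"T": 30},
            "liv-PA": {"C": 15, "T": 15},
            "liv-PAA": {"C": 15, "T": 15},
        },
        length=length,
        qual=qual,
    )


class TestCandidateFilter:
    def test_quality_below_threshold_dropped(self):
        kept = call_candidate_sites([full_site(qual=19)])
        assert kept == []
        assert len(call_candidate_sites([full_site(qual=20)])) == 1

    def test_spacing_rule_is_greedy_left_to_right(self):
        recs = [full_site(pos=100), full_site(pos=103), full_site(pos=108)]
        kept = call_candidate_sites(recs)
        # 103 is 3 bp after 100 -> dropped; 108 is 8 bp after 100 -> kept
        assert [r.position for r in kept] == [100, 108]

    def test_border_rule_is_strict(self):
        # min(pos-1, length-pos) must exceed 5
        assert call_candidate_sites([full_site(pos=6, length=100)]) == []
        assert len(call_candidate_sites([full_site(pos=7, length=100)])) == 1
        assert call_candidate_sites([full_site(pos=95, length=100)]) == []
        assert len(call_candidate_sites([full_site(pos=94, length=100)])) == 1

    def test_shallow_covered_library_disqualifies_site(self):
        rec = make_record(
            "t1", 100, "C",
            {"PP1": {"C": 2}, "PP2": {"C": 30}, "AA1": {"T": 30},
             "AA2": {"T": 30}, "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )
        assert call_candidate_sites([rec]) == []

    def test_uncovered_library_does_not_disqualify(self):
        rec = make_record(
            "t1", 100, "C",
            {"PP2": {"C": 30}, "AA1": {"T": 30},
             "AA2": {"T": 30}, "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )  # PP1 has zero reads: uninformative, not disqualifying
        assert len(call_candidate_sites([rec])) == 1

    def test_unsorted_input_is_callers_error(self):
        recs = [full_site(pos=200), full_site(pos=100)]
        with pytest.raises(DataError, match="sorted"):
            call_candidate_sites(recs)

    def test_filter_is_idempotent(self):
        recs = [full_site(pos=p) for p in (100, 103, 150, 152, 200)]
        once = call_candidate_sites(recs)
        assert call_candidate_sites(once) == once


class TestPartition:
    def test_single_base_library_is_fixed(self):
        rec = site(PP1=(0, 0, 30, 0))
        fixed, het = partition_polymorphisms([rec], PARENTAL_META)
        assert fixed[("t1", 100)]["PP1"] == "G"
        assert het == []

    def test_two_base_library_is_heterozygous(self):
        # ref C; counts G:18, T:12 -> het, oriented major/minor (no ref base)
        rec = site(AA1=(0, 0, 18, 12))
        fixed, het = partition_polymorphisms([rec], PARENTAL_META)
        assert ("t1", 100) not in fixed or "AA1" not in fixed[("t1", 100)]
        (h,) = het
        assert {h.count_ref, h.count_alt} == {18, 12}

    def test_het_with_reference_base_is_ref_oriented(self):
        rec = site(AA1=(0, 12, 0, 30))  # ref C: C=12, T=30
        _, het = partition_polymorphisms([rec], PARENTAL_META)
        (h,) = het
        assert (h.count_ref, h.count_alt) == (12, 30)

    def test_singleton_minor_base_ignored(self):
        rec = site(PP1=(0, 0, 30, 1))
        fixed, het = partition_polymorphisms([rec], PARENTAL_META)
        assert fixed[("t1", 100)]["PP1"] == "G"
        assert het == []

    def test_zero_coverage_library_in_neither_bin(self):
        rec = site(PP1=(0, 0, 0, 0), PP2=(0, 0, 30, 0))
        fixed, het = partition_polymorphisms([rec], PARENTAL_META)
        assert "PP1" not in fixed.get(("t1", 100), {})
        assert all(h.library_id != "PP1" for h in het)


class TestDiagnostic:
    def test_fixed_different_bases_yield_snp(self):
        rec = full_site()  # PP fixed C (ref), AA fixed T
        fixed, _ = partition_polymorphisms([rec], PARENTAL_META)
        (snp,) = identify_diagnostic_snps([rec], fixed, GOLDEN_META)
        assert (snp.p_base, snp.a_base, snp.ref_matches) == ("C", "T", "P")

    def test_discordant_parental_group_not_diagnostic(self):
        rec = make_record(
            "t1", 100, "C",
            {"PP1": {"C": 30}, "PP2": {"C": 30},
             "AA1": {"T": 30}, "AA2": {"G": 30},
             "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )
        fixed, _ = partition_polymorphisms([rec], PARENTAL_META)
        assert identify_diagnostic_snps([rec], fixed, GOLDEN_META) == []

    def test_no_intergenomic_difference_not_diagnostic(self):
        rec = make_record(
            "t1", 100, "T",
            {"PP1": {"T": 30}, "PP2": {"T": 30},
             "AA1": {"T": 30}, "AA2": {"T": 30},
             "liv-PA": {"T": 30}, "liv-PAA": {"T": 30}},
        )
        fixed, _ = partition_polymorphisms([rec], PARENTAL_META)
        assert identify_diagnostic_snps([rec], fixed, GOLDEN_META) == []

    def test_heterozygous_parental_library_blocks_diagnosis(self):
        rec = make_record(
            "t1", 100, "C",
            {"PP1": {"C": 15, "G": 15}, "PP2": {"C": 30},
             "AA1": {"T": 30}, "AA2": {"T": 30},
             "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )
        fixed, het = partition_polymorphisms([rec], PARENTAL_META)
        assert len(het) == 1
        assert identify_diagnostic_snps([rec], fixed, GOLDEN_META) == []

    def test_reference_matching_neither_variant_excluded(self):
        rec = make_record(
            "t1", 100, "G",  # ref G but variants are C (P) and T (A)
            {"PP1": {"C": 30}, "PP2": {"C": 30},
             "AA1": {"T": 30}, "AA2": {"T": 30},
             "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )
        fixed, _ = partition_polymorphisms([rec], PARENTAL_META)
        assert identify_diagnostic_snps([rec], fixed, GOLDEN_META) == []

    def test_relaxed_library_requirement_tolerates_missingness(self):
        rec = make_record(
            "t1", 100, "C",
            {"PP1": {"C": 30}, "PP2": {"C": 30},
             "AA1": {"T": 30},  # AA2 uncovered
             "liv-PA": {"C": 30}, "liv-PAA": {"C": 30}},
        )
        fixed, _ = partition_polymorphisms([rec], PARENTAL_META)
        assert identify_diagnostic_snps([rec], fixed, GOLDEN_META) == []
        relaxed = identify_diagnostic_snps(
            [rec], fixed, GOLDEN_META, n_aa_required=1
        )
        assert len(relaxed) == 1


class TestSimulationRecovery:
    def test_truth_diagnostic_sites_recovered_at_depth(self, small_simulation):
        _, records, meta, truth = small_simulation
        records = sorted(records, key=lambda r: r.key)
        candidates = call_candidate_sites(records)
        fixed, het = partition_polymorphisms(candidates, meta)
        snps = identify_diagnostic_snps(candidates, fixed, meta)
        found = {s.key for s in snps}
        expected = truth.diagnostic_keys() & {r.key for r in candidates}
        # full recovery up to coverage dropouts (none expected at mean 150)
        assert found == expected
        missing = truth.diagnostic_keys() - found
        assert len(missing) / max(len(truth.diagnostic_keys()), 1) < 0.02
        # diagnostic sites and het-bearing sites are disjoint
        assert not (found & {(h.transcript_id, h.position) for h in het})
        # and P/A variant assignment matches truth everywhere
        for s in snps:
            t = truth.sites[s.key]
            assert (s.p_base, s.a_base, s.ref_matches) == (
                t.p_base,
                t.a_base,
                t.ref_matches,
            )
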