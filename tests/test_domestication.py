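import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promforge.domestication import (
    CLONING_LINKER,
    DEFAULT_CONFIG,
    DomesticatedPromoter,
    DomesticationConfig,
    DomesticationError,
    PartValidationError,
    SequenceEdit,
    add_flanks,
    append_cloning_linker,
    domesticate,
    edit_table,
    find_homopolymers,
    find_type_iis_sites,
    is_clean,
    validate_part,
)
from promforge.seq import AlphabetError
from promforge.synthetic_data import plant_violations

dna = st.text(alphabet="ACGTacgt", min_size=0, max_size=80)


from _oracles import brute_force_runs, brute_min_edits  # noqa: E402


class TestFindHomopolymers:
    def test_exact_threshold_run(self):
        assert find_homopolymers("A" * 10, 10) == [(0, 10, "A")]

    def test_below_threshold_ignored(self):
        assert find_homopolymers("A" * 9, 10) == []

    def test_case_insensitive_and_maximal(self):
        assert find_homopolymers("ccTTTtttTTTtcc", 10) == [(2, 10, "T")]

    def test_planted_run_matches_brute_force(self):
        seq, truth = plant_violations(1000, run_lengths=(13,), seed=42)
        got = find_homopolymers(seq, 10)
        assert got == brute_force_runs(seq, 10)
        (v,) = truth.planted_violations
        assert got == [(v["position"], 13, v["base"])]

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            find_homopolymers("ACGT", 1)

    def test_alphabet_error(self):
        with pytest.raises(AlphabetError):
            find_homopolymers("ACGTN", 10)

    @given(dna, st.integers(min_value=2, max_value=12))
    def test_agrees_with_brute_force(self, seq, min_len):
        assert find_homopolymers(seq, min_len) == brute_force_runs(seq, min_len)


class TestFindTypeIISSites:
    def test_plus_strand(self):
        assert find_type_iis_sites("ttGGTCTCtt") == [(2, "+")]

    def test_minus_strand(self):
        assert find_type_iis_sites("ttGAGACCtt") == [(2, "-")]

    def test_both_strands_and_overlap(self):
        # GGTCTC at 0 and GAGACC at 4 overlap; both reported
        seq = "GGTCGAGACC"
        assert find_type_iis_sites(seq) == [(4, "-")]
        seq = "GGTCTCGAGACC"
        assert find_type_iis_sites(seq) == [(0, "+"), (6, "-")]

    def test_palindrome_reported_once(self):
        assert find_type_iis_sites("ttGAATTCtt", "GAATTC") == [(2, "+")]

    def test_case_insensitive(self):
        assert find_type_iis_sites("ttggtctctt") == [(2, "+")]

    def test_short_recognition_rejected(self):
        with pytest.raises(ValueError):
            find_type_iis_sites("ACGT", "ACG")


class TestDomesticate:
    def test_no_violations_is_identity(self):
        seq = "gattacagattaca"
        res = domesticate(seq)
        assert res.edited == seq and res.edits == ()

    def test_single_run_needs_one_edit(self):
        seq, _ = plant_violations(60, run_lengths=(12,), seed=1)
        res = domesticate(seq)
        assert len(res.edits) == 1
        assert find_homopolymers(res.edited, 10) == []
        assert len(res.edits) == brute_min_edits(seq)

    def test_twenty_run_needs_two_edits(self):
        seq, truth = plant_violations(60, run_lengths=(20,), seed=2)
        res = domesticate(seq)
        assert len(res.edits) == 2  # floor(20 / 10)
        runs9 = find_homopolymers(res.edited, 2)
        assert max(length for _, length, _ in runs9) <= 9

    def test_site_needs_one_edit(self):
        seq, _ = plant_violations(60, n_sites=1, seed=3)
        res = domesticate(seq)
        assert len(res.edits) == 1
        assert res.edits[0].reason == "type_iis"
        assert find_type_iis_sites(res.edited) == []

    def test_site_edit_prefers_third_base(self):
        seq = "ttttcacaGGTCTCacacactg"
        res = domesticate(seq)
        assert len(res.edits) == 1
        assert res.edits[0].position == 10  # third base of the hexamer

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            domesticate("")

    def test_unsatisfiable_raises(self):
        # every single-base variant of the site is itself a recognition
        # sequence, so no substitution inside the hexamer can clear it
        site = "GGTCTC"
        variants = [
            site[:i] + b + site[i + 1 :]
            for i in range(6)
            for b in "ACGT"
            if b != site[i]
        ]
        config = DomesticationConfig(enzymes=tuple([site] + variants))
        with pytest.raises(DomesticationError):
            domesticate("tataGGTCTCatat", config)

    def test_edit_log_replays(self):
        seq, _ = plant_violations(120, run_lengths=(14,), n_sites=1, seed=4)
        res = domesticate(seq)
        replayed = list(res.original)
        for e in res.edits:
            assert replayed[e.position].upper() == e.ref_base.upper()
            replayed[e.position] = e.alt_base
        assert "".join(replayed).upper() == res.edited.upper()

    def test_case_preserved(self):
        seq = "cc" + "a" * 12 + "CC" + "A" * 12 + "gg"
        res = domesticate(seq)
        for e in res.edits:
            assert e.alt_base.islower() == e.ref_base.islower()
        assert res.edited.upper() != res.original.upper()
        assert res.edited.lower() == domesticate(seq.lower()).edited.lower()

    @given(st.integers(min_value=0, max_value=500))
    @settings(max_examples=40, deadline=None)
    def test_idempotent_and_length_preserving(self, seed):
        rng = np.random.default_rng(seed)
        # biased composition so runs actually occur
        probs = rng.dirichlet([0.6, 0.6, 0.6, 0.6])
        seq = "".join(rng.choice(list("ACGT"), size=70, p=probs))
        res = domesticate(seq)
        assert len(res.edited) == len(seq)
        assert is_clean(res.edited)
        again = domesticate(res.edited)
        assert again.edited == res.edited and again.edits == ()


class TestSequenceEdit:
    def test_rejects_identity_edit(self):
        with pytest.raises(ValueError):
            SequenceEdit(0, "A", "a", "homopolymer")

    def test_rejects_unknown_reason(self):
        with pytest.raises(ValueError):
            SequenceEdit(0, "A", "G", "gc_content")

    def test_promoter_invariants_enforced(self):
        with pytest.raises(ValueError):
            DomesticatedPromoter("ACGT", "ACG", ())
        with pytest.raises(ValueError):
            DomesticatedPromoter("ACGT", "AGGT", ())


class TestCloningLinker:
    def test_empty_input(self):
        assert append_cloning_linker("") == "aaaagcaggctaaaa"
        assert len(CLONING_LINKER) == 15

    @given(dna)
    def test_adds_exactly_15(self, seq):
        assert len(append_cloning_linker(seq)) == len(seq) + 15

    def test_reference_entry_reconstructed(self, reference_promoters):
        row = reference_promoters.set_index("gene").loc["his-64"]
        assert append_cloning_linker(row["endogenous_sequence"]) == row["sequence"]


class TestAddFlanksAndValidate:
    def test_round_trip_release(self):
        frag = add_flanks("cccc", "AATG", "GCTT")
        from promforge.assembly import BSAI, digest

        mid = [
            f
            for f in digest(frag, BSAI, "linear")
            if f.five_prime_overhang and f.three_prime_overhang
        ]
        assert len(mid) == 1
        assert mid[0].core == "cccc"
        assert mid[0].five_prime_overhang == "AATG"
        assert mid[0].three_prime_overhang == "GCTT"

    def test_identical_overhangs_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            add_flanks("cccc", "AATG", "aatg")

    def test_exactly_two_sites(self):
        frag = add_flanks("gattaca", "AATG", "GCTT")
        assert len(find_type_iis_sites(frag)) == 2

    def test_dirty_part_rejected(self):
        with pytest.raises(PartValidationError):
            add_flanks("ccGGTCTCcc", "AATG", "GCTT")
        with pytest.raises(PartValidationError):
            add_flanks("cc" + "A" * 10 + "cc", "AATG", "GCTT")

    def test_validate_clean_flanked_fragment(self):
        frag = add_flanks("gattaca", "AATG", "GCTT")
        rep = validate_part(frag)
        assert rep.flank_sites == 2
        assert rep.internal_sites == 0
        assert rep.internal_runs == 0
        assert rep.orientation_ok
        assert rep.ok

    def test_validate_planted_internal_site(self):
        rep = validate_part("ttttcacaGGTCTCacacactg")
        assert rep.internal_sites == 1
        assert not rep.ok

    def test_all_reference_entries_are_clean(self, reference_promoters):
        for _, row in reference_promoters.iterrows():
            rep = validate_part(row["endogenous_sequence"])
            assert rep.internal_sites == 0 and rep.internal_runs == 0, row["gene"]

    def test_flanked_reference_promoter(self, reference_promoters):
        seq = reference_promoters.set_index("gene").loc["his-64", "sequence"]
        rep = validate_part(add_flanks(seq, "GGAG", "AATG"))
        assert rep.flank_sites == 2 and rep.internal_sites == 0 and rep.internal_runs == 0


def test_edit_table_positions_are_one_based():
    seq, _ = plant_violations(60, run_lengths=(12,), seed=5)
    res = domesticate(seq)
    rows = edit_table([("p1", res)])
    assert rows[0]["seq_id"] == "p1"
    assert rows[0]["position"] == res.edits[0].position + 1
    assert rows[0]["reason"] == "homopolymer"
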