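"""Novel miRNA discovery: exclusion, windowing, candidate calling."""

import pytest

from mircms.io import SequenceRecord, reverse_complement
from mircms.novel import (CandidateNamer, PrecursorWindow, Rejection,
                          call_candidate, discover, evaluate_candidate,
                          exclude_annotated, fold_window, locate_windows)
from mircms.preprocess import SequenceTag
from mircms.simulate import make_genome

MATURE = "TGACAGAAGAAAGAGAGCACA"  # 21 nt


def perfect_hairpin_window(arm="5p", flank=15):
    """Window holding a perfect hairpin with the tag on the requested arm."""
    star = reverse_complement(MATURE)
    pad5 = "GATTACAGATTACAGATTAC"[:flank]
    pad3 = "CTGATCCTGATCCTGATCCT"[:flank]
    if arm == "5p":
        seq = pad5 + MATURE + "GTGAGTTG" + star + pad3
        offset = len(pad5)
    else:
        seq = pad5 + star + "GTGAGTTG" + MATURE + pad3
        offset = len(pad5) + len(MATURE) + 8
    return PrecursorWindow("chr1", 1, len(seq), "+", seq, offset)


class TestExcludeAnnotated:
    def test_tag_matching_rrna_excluded(self):
        rrna = [SequenceRecord("rRNA", "GGGG" + MATURE + "CCCC")]
        tags = [SequenceTag(MATURE, {"MF": 10})]
        assert exclude_annotated(tags, [rrna]) == []

    def test_reverse_complement_also_excluded(self):
        repeat = [SequenceRecord("rep", "TT" + reverse_complement(MATURE) + "AA")]
        tags = [SequenceTag(MATURE, {"MF": 10})]
        assert exclude_annotated(tags, [repeat]) == []

    def test_low_abundance_excluded_at_threshold(self):
        tags = [
            SequenceTag(MATURE, {"MF": 2, "CMS": 2}),       # total 4 < 5
            SequenceTag(MATURE[::-1], {"MF": 3, "CMS": 2}),  # total 5 kept
        ]
        kept = exclude_annotated(tags, [])
        assert [t.total_count for t in kept] == [5]

    def test_clean_abundant_tag_retained(self):
        tags = [SequenceTag(MATURE, {"MF": 10})]
        assert exclude_annotated(tags, [[SequenceRecord("x", "G" * 50)]]) == tags


class TestLocateWindows:
    def test_planted_tag_two_windows_containing_it(self):
        genome = [SequenceRecord("chr1", "A" * 499 + MATURE + "G" * 1480)]
        windows = locate_windows(MATURE, genome)
        assert len(windows) == 2
        assert all(MATURE in w.sequence for w in windows)
        assert {(w.start, w.end) for w in windows} == {(340, 540), (480, 680)}

    def test_minus_strand_window_reverse_complemented(self):
        insert = reverse_complement(MATURE)
        genome = [SequenceRecord("chr1", "C" * 300 + insert + "A" * 300)]
        windows = locate_windows(MATURE, genome)
        assert windows and all(w.strand == "-" for w in windows)
        for w in windows:
            assert w.sequence[w.tag_offset : w.tag_offset + len(MATURE)] == MATURE

    def test_two_occurrences_give_four_windows(self):
        genome = [
            SequenceRecord("chr1", "A" * 300 + MATURE + "G" * 600 + MATURE + "C" * 300)
        ]
        assert len(locate_windows(MATURE, genome)) == 4

    def test_absent_tag_gives_empty_result(self):
        assert locate_windows(MATURE, [SequenceRecord("chr1", "G" * 1000)]) == []

    def test_windows_clipped_to_sequence_bounds(self):
        genome = [SequenceRecord("chr1", MATURE + "A" * 50)]
        for w in locate_windows(MATURE, genome):
            assert w.start >= 1 and w.end <= len(genome[0].sequence)


class TestFoldWindow:
    def test_short_window_rejected(self):
        out = fold_window("ACGT" * 9)  # 36 < 40
        assert isinstance(out, Rejection) and "short" in out.reason

    def test_external_folder_hook(self):
        called = {}

        def fake_folder(seq):
            called["seq"] = seq
            return "." * len(seq)

        window = perfect_hairpin_window()
        assert fold_window(window, fake_folder) == "." * len(window.sequence)
        assert called["seq"] == window.sequence

    def test_bad_external_folder_detected(self):
        with pytest.raises(ValueError):
            fold_window(perfect_hairpin_window(), lambda s: "...")


class TestCallCandidate:
    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_planted_hairpin_accepted_on_correct_arm(self, arm):
        window = perfect_hairpin_window(arm)
        structure = fold_window(window)
        cand = call_candidate(MATURE, window, structure)
        assert not isinstance(cand, Rejection)
        assert cand.arm == arm
        assert cand.paired_mature_bases >= 14
        assert cand.candidate_id == f"PC-{arm}-1"

    def test_tag_on_loop_rejected(self):
        # place the "tag" across the terminal loop of the planted hairpin
        window = perfect_hairpin_window("5p", flank=15)
        structure = fold_window(window)
        loop_tag_offset = 15 + 10  # straddles mature/loop boundary
        loop_window = PrecursorWindow(
            "chr1", 1, window.end, "+", window.sequence, loop_tag_offset
        )
        tag = window.sequence[loop_tag_offset : loop_tag_offset + 21]
        out = evaluate_candidate(tag, loop_window, structure)
        assert isinstance(out, Rejection)

    def test_underpaired_tag_rejected(self):
        window = perfect_hairpin_window("5p")
        structure = fold_window(window)
        # keep only 10 of the tag's pairs: break the rest in the structure
        chars = list(structure)
        tag_positions = range(window.tag_offset, window.tag_offset + len(MATURE))
        from mircms.fold import pair_table

        pairs = pair_table(structure)
        broken = 0
        for i in tag_positions:
            if i in pairs and broken < 11:
                chars[i] = "."
                chars[pairs[i]] = "."
                broken += 1
        out = evaluate_candidate(MATURE, window, "".join(chars))
        assert isinstance(out, Rejection)

    def test_serials_increment_per_call(self):
        namer = CandidateNamer()
        window = perfect_hairpin_window("5p")
        structure = fold_window(window)
        c1 = call_candidate(MATURE, window, structure, namer)
        c2 = call_candidate(MATURE, window, structure, namer)
        assert (c1.candidate_id, c2.candidate_id) == ("PC-5p-1", "PC-5p-2")


class TestDiscover:
    def test_planted_hairpins_recovered_decoys_rejected(self):
        genome, truth = make_genome(11, n_hairpins=6, n_decoys=6, size=25_000)
        tags = [SequenceTag(p.mature, {"MF": 10}) for p in truth.precursors]
        decoys = [
            SequenceTag(genome.sequence[s - 1 + 12 : s - 1 + 33], {"MF": 10})
            for _, s, _ in truth.decoy_loci
        ]
        candidates = discover(tags + decoys, [genome])
        called = {c.tag_sequence for c in candidates}
        planted = {p.mature for p in truth.precursors}
        assert len(called & planted) >= 5  # sensitivity
        false_calls = [c for c in candidates if c.tag_sequence not in planted]
        assert len(false_calls) <= max(1, len(candidates) // 10)

    def test_ids_stable_across_reruns(self):
        genome, truth = make_genome(12, n_hairpins=3, n_decoys=0, size=12_000)
        tags = [SequenceTag(p.mature, {"MF": 10}) for p in truth.precursors]
        first = discover(tags, [genome])
        second = discover(tags, [genome])
        assert [(c.candidate_id, c.locus) for c in first] == [
            (c.candidate_id, c.locus) for c in second
        ]

    def test_exclusion_applies_before_folding(self):
        genome, truth = make_genome(13, n_hairpins=2, n_decoys=0, size=10_000)
        tags = [SequenceTag(p.mature, {"MF": 10}) for p in truth.precursors]
        exclusion = [[SequenceRecord("mRNA", truth.precursors[0].precursor)]]
        candidates = discover(tags, [genome], exclusion)
        assert truth.precursors[0].mature not in {c.tag_sequence for c in candidates}
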