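"""Folding, dinucleotide shuffling and the stem-loop criteria."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe.hairpin import (
    FoldResult,
    _mature_geometry,
    apply_criteria,
    dinucleotide_shuffle,
    extract_windows,
    fold_rna,
    screen_novel,
)
from srnapipe.seqio import ParseError, revcomp
from srnapipe.tags import Tag
from helpers import perfect_hairpin

_W = {"GC": 3, "CG": 3, "AT": 2, "TA": 2, "GT": 1, "TG": 1}


def enumeration_oracle(seq: str, min_loop: int = 3) -> int:
    """Best weighted pair sum by explicit enumeration of nested structures."""

    def structures(i, j):
        if j - i < 0:
            yield []
            return
        # position i unpaired
        yield from structures(i + 1, j)
        # or paired with some k, splitting the interval (nestedness)
        for k in range(i + min_loop + 1, j + 1):
            w = _W.get(seq[i] + seq[k], 0)
            if w:
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        yield [(i, k)] + inner + outer

    return max(
        sum(_W[seq[i] + seq[k]] for i, k in s) for s in structures(0, len(seq) - 1)
    )


class TestFold:
    def test_simple_hairpin(self):
        r = fold_rna("GGGAAAACCC")
        assert r.score == 9
        assert r.pair_count == 3
        assert r.structure == "(((....)))"
        assert r.pairs[0] == 9 and r.pairs[1] == 8 and r.pairs[2] == 7

    def test_homopolymer_has_no_pairs(self):
        r = fold_rna("A" * 10)
        assert r.pair_count == 0
        assert r.structure == "." * 10

    def test_perfect_inverted_repeat_fully_paired(self, rng):
        pre, mature = perfect_hairpin(rng, mature_len=21, ext=0, loop=6)
        r = fold_rna(pre)
        assert all(r.pairs[i] >= 0 for i in range(21))  # every arm base paired

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ParseError):
            fold_rna("ACGTNACGT")

    def test_structure_is_balanced_and_consistent(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 40))
            r = fold_rna(seq)
            assert r.structure.count("(") == r.structure.count(")") == r.pair_count
            for i, p in enumerate(r.pairs):
                if p >= 0:
                    assert r.pairs[p] == i
                    assert abs(p - i) > 3  # minimum loop length

    @given(st.text(alphabet="ACGT", min_size=4, max_size=12))
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_matches_enumeration_oracle(self, seq):
        assert fold_rna(seq).score == enumeration_oracle(seq)


class TestShuffle:
    @given(st.text(alphabet="ACGT", min_size=3, max_size=60))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_preserves_dinucleotide_counts_exactly(self, seq):
        rng = np.random.default_rng(5)
        shuffled = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestWindows:
    def test_window_lengths_internal_hit(self):
        genome = "A" * 1000
        wins = extract_windows(400, 421, genome, flank=150)
        assert sorted(len(w.seq) for w in wins) == [171, 171, 321]
        for w in wins:
            assert w.seq[w.mature_start : w.mature_end + 1] == genome[400:421]

    def test_hit_at_genome_start_clips_without_error(self):
        genome = "ACGT" * 50
        wins = extract_windows(0, 21, genome, flank=150)
        assert all(w.genome_start == 0 for w in wins)
        assert min(len(w.seq) for w in wins) == 21

    def test_minus_strand_window_contains_mature_in_sense(self, rng):
        pre, mature = perfect_hairpin(rng)
        genome = "ACGTACGTAC" + pre + "GGTTGGTTGG"
        # the mature's reverse complement lies on the 3' arm: a minus-strand hit
        rc = revcomp(mature)
        start = genome.find(rc)
        wins = extract_windows(start, start + len(rc), genome, flank=10, strand="-")
        for w in wins:
            assert w.seq[w.mature_start : w.mature_end + 1] == mature

    def test_planted_window_recovers_precursor(self, rng):
        pre, mature = perfect_hairpin(rng)  # mature at the 5' end of pre
        genome = "TTCATGGTCA" + pre + "CAGTTACGGA"
        start = genome.find(mature)
        flank = len(pre) - len(mature)
        wins = extract_windows(start, start + len(mature), genome, flank)
        assert any(w.seq == pre for w in wins)

    def test_absent_hit_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(10, 5, "A" * 100, 20)


class TestCriteria:
    def test_planted_hairpin_passes_all_flags(self, rng):
        pre, mature = perfect_hairpin(rng)
        cand = apply_criteria(pre, 0, len(mature) - 1)
        assert cand.passes
        assert cand.arm == "5p"
        assert cand.mature_in_one_arm and cand.duplex_pairing_ok
        assert cand.loop_ok and cand.stability_ok

    def test_mature_across_loop_fails_one_arm(self, rng):
        pre, _ = perfect_hairpin(rng, mature_len=21, ext=9, loop=8)
        arm = 30
        # mature centered on the loop pairs with itself across the loop
        m0, m1 = arm - 10, arm + 8 + 10
        cand = apply_criteria(pre, m0, m1)
        assert not cand.mature_in_one_arm
        assert not cand.passes

    def test_homopolymer_fails_duplex_pairing(self):
        pre = "A" * 68
        cand = apply_criteria(pre, 0, 20)
        assert not cand.duplex_pairing_ok
        assert not cand.passes

    def test_length_bounds_enforced(self, rng):
        pre, mature = perfect_hairpin(rng, mature_len=21, ext=3, loop=6)  # 54 nt
        cand = apply_criteria(pre, 0, 20)
        assert not cand.loop_ok
        long = apply_criteria(pre + "A" * 280, 0, 20, skip_stability=True)
        assert not long.loop_ok

    def test_mature_outside_precursor_rejected(self):
        with pytest.raises(ValueError):
            apply_criteria("ACGT" * 20, 70, 95)

    def test_removing_pairs_never_rescues_a_failure(self, rng):
        """Criteria are monotone in the pairing: unpairing mature bases can
        only degrade the geometric flags."""
        pre, mature = perfect_hairpin(rng)
        fold = fold_rna(pre)
        one_arm, duplex_ok, _ = _mature_geometry(fold, 0, len(mature) - 1)
        assert one_arm and duplex_ok
        pairs = fold.pairs.copy()
        # progressively unpair mature bases; a failed pairing criterion must
        # never recover as pairs are removed
        prev_duplex = duplex_ok
        for i in range(0, len(mature), 2):
            if pairs[i] >= 0:
                pairs[pairs[i]] = -1
                pairs[i] = -1
            weakened = FoldResult(fold.structure, pairs, int((pairs >= 0).sum()) // 2, 0)
            _, duplex_w, _ = _mature_geometry(weakened, 0, len(mature) - 1)
            if not prev_duplex:
                assert not duplex_w
            prev_duplex = duplex_w


class TestViennaBackend:
    def test_thermodynamic_backend_agrees_on_planted_hairpin(self, rng):
        """An MFE folder plugged into the criteria reaches the same verdict
        as the pair-maximization default on a clean planted hairpin."""
        from srnapipe.hairpin import vienna_fold_backend

        backend = vienna_fold_backend()
        pre, mature = perfect_hairpin(rng)
        cand = apply_criteria(pre, 0, len(mature) - 1, fold_backend=backend)
        assert cand.mature_in_one_arm and cand.duplex_pairing_ok
        assert cand.arm == "5p"
        default = apply_criteria(pre, 0, len(mature) - 1)
        assert default.passes == cand.passes


class TestScreen:
    def test_recovers_planted_loci_only(self, small_experiment):
        config, bundle, truth, libraries = small_experiment
        from srnapipe.annotate import annotate_waterfall
        from srnapipe.tags import collapse_reads

        tags, _, _ = collapse_reads(libraries.collapsed("FP"), libraries.collapsed("SP"))
        records = annotate_waterfall(tags, bundle.ncrna, bundle.mirna, bundle.genome)
        candidates = screen_novel(tags, bundle.genome, records)
        matures = {l.mature_seq for l in truth.novel_loci}
        found = {c.window.seq[c.mature_start : c.mature_end + 1] for c in candidates}
        assert found == matures

    def test_known_mirna_tags_never_screened(self, tiny_refs, rng):
        ncrna, mirna, _ = tiny_refs
        pre, mature = perfect_hairpin(rng)
        genome = [("chr1", "TGCATCGGTA" + pre + "CCATTGAGGT")]
        # the mature also happens to be a known miRNA: waterfall wins
        mirna = mirna + [RefRecord_for(mature)]
        from srnapipe.annotate import annotate_waterfall

        tags = [Tag(mature, 30, 30)]
        records = annotate_waterfall(tags, ncrna, mirna, genome)
        assert records[0].category == "known_miRNA"
        assert screen_novel(tags, genome, records) == []

    def test_low_abundance_flagging(self, rng):
        pre, mature = perfect_hairpin(rng)
        genome = [("chr1", "TGCATCGGTA" + pre + "CCATTGAGGT")]
        from srnapipe.annotate import AnnotationRecord

        records = [AnnotationRecord(mature, "genome_matched", "chr1")]
        (cand,) = screen_novel([Tag(mature, 7, 5)], genome, records)
        assert cand.low_abundance  # total 12 < 40
        (cand,) = screen_novel([Tag(mature, 30, 30)], genome, records)
        assert not cand.low_abundance


def RefRecord_for(seq):
    from srnapipe.seqio import RefRecord

    return RefRecord("rgl-miRz", "known_miRNA", "miRz", seq)
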