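"""Region model: CDS filtering, windows, branchpoints, SNV enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicemaps import regions
from splicemaps.regions import (
    Branchpoint,
    CdsExon,
    SplicePosition,
    annotate_near_splice,
    build_pwm,
    enumerate_snvs,
    filter_cds,
    positions_frame,
    resolve_conflicts,
    select_branchpoints,
)
from splicemaps.synthetic import features_from_lines


def gtf_line(chrom="chr1", ftype="CDS", start=101, end=150, strand="+",
             gene_type="protein_coding", transcript_type="protein_coding",
             level="2", tag='"CCDS"', tx="TX1"):
    attrs = (
        f'gene_id "G1"; transcript_id "{tx}"; gene_type "{gene_type}"; '
        f'transcript_type "{transcript_type}"; gene_name "GENE1"; '
        f"level {level}; tag {tag};"
    )
    return "\t".join([chrom, "test", ftype, str(start), str(end), ".", strand, "0", attrs])


class TestFilterCds:
    @pytest.mark.parametrize(
        "line,kept",
        [
            (gtf_line(), True),
            (gtf_line(level="3"), False),  # level-3 evidence excluded
            (gtf_line(tag='"basic"'), False),  # no accepted tag
            (gtf_line(tag='"appris_principal_1"'), True),
            (gtf_line(transcript_type="retained_intron"), False),
            (gtf_line(gene_type="lncRNA"), False),
            (gtf_line(ftype="exon"), False),
            (gtf_line(chrom="chrX"), False),  # autosome restriction on by default
        ],
    )
    def test_criteria(self, line, kept):
        out = filter_cds(features_from_lines([line]))
        assert bool(out) is kept

    def test_sex_chromosomes_kept_when_restriction_off(self):
        out = filter_cds(features_from_lines([gtf_line(chrom="chrX")]),
                         autosomes_only=False)
        assert len(out) == 1

    def test_unique_collapses_duplicate_coordinates(self):
        lines = [gtf_line(tx="TX1"), gtf_line(tx="TX2")]
        assert len(filter_cds(features_from_lines(lines))) == 2
        assert len(filter_cds(features_from_lines(lines), unique=True)) == 1

    def test_gtf_coordinates_become_half_open(self):
        exon = filter_cds(features_from_lines([gtf_line(start=101, end=150)]))[0]
        assert (exon.start, exon.end) == (100, 150)
        assert exon.to_gtf_coords() == (101, 150)

    def test_malformed_line_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "bad.gtf"
        path.write_text(gtf_line() + "\nchr1\tonly-two-fields\n")
        with caplog.at_level("WARNING"):
            out = list(regions.iter_gtf_features(path))
        assert len(out) == 1
        assert any("malformed" in r.message for r in caplog.records)

    def test_empty_result_is_empty_list(self):
        assert filter_cds(features_from_lines([gtf_line(level="3")])) == []


def three_exon_transcript(strand="+"):
    """Exons 0-based: [20,60), [100,150), [200,240); middle exon internal."""
    return [
        CdsExon("chr1", 20, 60, strand, "G1", "TX1"),
        CdsExon("chr1", 100, 150, strand, "G1", "TX1"),
        CdsExon("chr1", 200, 240, strand, "G1", "TX1"),
    ]


class TestNearSplice:
    def test_plus_strand_anchor_positions(self):
        positions = annotate_near_splice(three_exon_transcript("+"))
        mid = {(p.site, p.offset): p.pos for p in positions if 75 <= p.pos <= 175}
        # 1-based 101-150 exon: acceptor 0 at base 101 (0-based 100), donor 0 at 150
        assert mid[("acceptor", 0)] == 100
        assert mid[("acceptor", -1)] == 99
        assert mid[("donor", 0)] == 149
        assert mid[("donor", 1)] == 150

    def test_minus_strand_offsets_run_leftward(self):
        positions = annotate_near_splice(three_exon_transcript("-"))
        mid = {(p.site, p.offset): p.pos for p in positions if 75 <= p.pos <= 175}
        # transcript orientation flips: acceptor end is the high-coordinate end
        assert mid[("acceptor", 0)] == 149
        assert mid[("acceptor", -1)] == 150
        assert mid[("donor", 0)] == 100
        assert mid[("donor", 1)] == 99

    def test_terminal_cds_edges_get_no_windows(self):
        positions = annotate_near_splice(three_exon_transcript("+"))
        sites = {(p.site, p.offset, p.pos) for p in positions}
        # transcript start (exon1 acceptor side) and end (exon3 donor side) are
        # UTR-abutting: no acceptor window on exon1, no donor window on exon3
        assert not any(s == "acceptor" and 0 <= pos < 60 for s, o, pos in sites)
        assert not any(s == "donor" and pos >= 200 for s, o, pos in sites)

    def test_internal_exon_window_sizes(self):
        positions = annotate_near_splice(three_exon_transcript("+"))
        mid = [p for p in positions if p.site == "acceptor" and 75 <= p.pos <= 160]
        assert len(mid) == 36
        mid_d = [p for p in positions if p.site == "donor" and 135 <= p.pos <= 160]
        assert len(mid_d) == 21

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            CdsExon("chr1", 0, 10, ".", "G", "T")

    @given(length=st.integers(min_value=1, max_value=60))
    def test_per_exon_position_cap(self, length):
        """<= 57 conflict-free bases per internal exon; 57 iff length >= 21
        (shorter exons lose truncated or conflicting exonic labels)."""
        exons = [
            CdsExon("chr1", 1000, 1100, "+", "G", "T"),
            CdsExon("chr1", 2000, 2000 + length, "+", "G", "T"),
            CdsExon("chr1", 3000, 3100, "+", "G", "T"),
        ]
        raw = [p for p in annotate_near_splice(exons) if 1900 <= p.pos < 2300]
        mid = [p for p in resolve_conflicts(raw) if 1900 <= p.pos < 2300]
        assert len(raw) <= 57 and len(mid) <= 57
        # truncation: the full 36+21 labels are emitted once both exonic
        # windows fit (length >= 11); distinct conflict-free bases reach 57
        # only once the two exonic windows stop overlapping (length >= 22)
        assert (len(raw) == 57) == (length >= 11)
        assert (len(mid) == 57) == (length >= 22)

    def test_strand_symmetry_under_reverse_complement(self):
        """Mirroring the locus leaves the multiset of labels invariant."""
        L = 400
        fwd = annotate_near_splice(three_exon_transcript("+"))
        mirrored = [
            CdsExon("chr1", L - e.end, L - e.start, "-", e.gene_id, e.transcript_id)
            for e in three_exon_transcript("+")
        ]
        rev = annotate_near_splice(mirrored)
        assert sorted((p.site, p.offset) for p in fwd) == sorted(
            (p.site, p.offset) for p in rev
        )
        # and coordinates map through the mirror
        fwd_set = {(L - 1 - p.pos, p.site, p.offset) for p in fwd}
        rev_set = {(p.pos, p.site, p.offset) for p in rev}
        assert fwd_set == rev_set


class TestResolveConflicts:
    def test_identical_labels_deduplicate_to_smallest_transcript(self):
        a = SplicePosition("chr1", 50, "+", "donor", 5, "TXB")
        b = SplicePosition("chr1", 50, "+", "donor", 5, "TXA")
        out = resolve_conflicts([a, b])
        assert len(out) == 1 and out[0].transcript_id == "TXA"

    def test_conflicting_labels_remove_base(self):
        a = SplicePosition("chr1", 50, "+", "donor", -10, "TX1")
        b = SplicePosition("chr1", 50, "+", "acceptor", 3, "TX2")
        assert resolve_conflicts([a, b]) == []

    def test_empty_and_idempotent(self):
        assert resolve_conflicts([]) == []
        pos = [
            SplicePosition("chr1", 50, "+", "donor", 5, "TX1"),
            SplicePosition("chr1", 51, "+", "donor", 6, "TX1"),
            SplicePosition("chr1", 60, "+", "donor", -10, "TX1"),
            SplicePosition("chr1", 60, "+", "acceptor", 3, "TX2"),
        ]
        once = resolve_conflicts(pos)
        assert resolve_conflicts(once) == once


def bp_scores(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "intron_id", "score"])


class TestBranchpoints:
    def test_argmax_selected(self):
        scores = bp_scores(
            [("chr1", 976, "+", "i1", 0.93), ("chr1", 969, "+", "i1", 0.41)]
        )
        (bp,) = select_branchpoints(scores)
        assert bp.pos == 976 and bp.score == 0.93 and bp.high_confidence

    @pytest.mark.parametrize("strand,expect", [("+", 960), ("-", 1040)])
    def test_tie_broken_towards_five_prime(self, strand, expect):
        scores = bp_scores(
            [("chr1", 960, strand, "i1", 0.7), ("chr1", 1040, strand, "i1", 0.7)]
        )
        (bp,) = select_branchpoints(scores)
        assert bp.pos == expect
        assert not bp.high_confidence  # 0.7 <= 0.85

    def test_unscored_intron_skipped_with_warning(self, caplog):
        scores = bp_scores([("chr1", 960, "+", "i1", np.nan)])
        with caplog.at_level("WARNING"):
            assert select_branchpoints(scores) == []
        assert any("no scored positions" in r.message for r in caplog.records)

    def test_windows_follow_transcript_orientation(self):
        plus = Branchpoint("chr1", 100, "+", "i1", 0.9)
        minus = Branchpoint("chr1", 100, "-", "i2", 0.9)
        wplus = {p.offset: p.pos for p in regions.branchpoint_windows([plus])}
        wminus = {p.offset: p.pos for p in regions.branchpoint_windows([minus])}
        assert wplus[1] == 101 and wplus[-5] == 95
        assert wminus[1] == 99 and wminus[-5] == 105


class TestEnumerateSnvs:
    GENOME = {"chr1": "ACGTNACGTT"}

    def positions(self, *pos):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": list(pos), "strand": "+",
             "site": "donor", "offset": 1, "transcript_id": "T", "gene_name": "G"}
        )

    def test_three_alternates_with_context(self):
        out = enumerate_snvs(self.positions(2), self.GENOME)
        assert len(out) == 3
        assert set(out["alt"]) == {"A", "C", "T"}  # ref G excluded
        assert (out["context"] == "CGT").all()
        assert (out["context"].str[1] == out["ref"]).all()

    def test_ambiguous_reference_skipped_and_counted(self):
        out = enumerate_snvs(self.positions(2, 4, 6), self.GENOME)
        assert len(out) == 6  # position 4 is N
        assert out.attrs["n_skipped"] == 1

    def test_output_size_invariant(self, small_dataset):
        snvs = small_dataset.snvs
        assert len(snvs) == 3 * snvs[["chrom", "pos"]].drop_duplicates().shape[0]


class TestPwm:
    def test_hand_counted_frequencies(self):
        # four single-base "sequences" at one offset: A,A,C,G
        genome = {"chr1": "AACG"}
        pos = pd.DataFrame(
            {"chrom": "chr1", "pos": [0, 1, 2, 3], "strand": "+",
             "site": "donor", "offset": 1}
        )
        pwm = build_pwm(pos, genome)
        row = pwm.loc[("donor", 1)]
        assert row["A"] == pytest.approx(0.5)
        assert row["C"] == pytest.approx(0.25)
        assert row["G"] == pytest.approx(0.25)
        assert row["T"] == 0.0
        assert row.sum() == pytest.approx(1.0)

    def test_single_sequence_is_one_hot(self):
        pwm = build_pwm(
            pd.DataFrame({"chrom": "chr1", "pos": [0], "strand": "+",
                          "site": "donor", "offset": 2}),
            {"chr1": "T"},
        )
        assert pwm.loc[("donor", 2)].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_minus_strand_bases_complemented(self):
        pwm = build_pwm(
            pd.DataFrame({"chrom": "chr1", "pos": [0], "strand": "-",
                          "site": "donor", "offset": 1}),
            {"chr1": "C"},
        )
        assert pwm.loc[("donor", 1), "G"] == 1.0

    def test_donor_dinucleotide_dominates_in_synthetic_genome(self, small_dataset):
        pwm = build_pwm(small_dataset.ns_positions, small_dataset.annotation.genome)
        assert pwm.loc[("donor", 1), "G"] == 1.0  # canonical GT planted
        assert pwm.loc[("donor", 2), "T"] == 1.0
        assert pwm.loc[("acceptor", -2), "A"] == 1.0
        assert pwm.loc[("acceptor", -1), "G"] == 1.0
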