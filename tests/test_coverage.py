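"""Read filtering, strand attribution, per-exon base counting, normalization."""

import numpy as np
import pytest

from covasym import (
    AssayConfig, Orientation, ReadFilterParams, count_exon_bases, library_qc,
    library_size, normalize_profile, read_passes_filters, tk_depth,
    transcript_orientation,
)
from covasym.coverage import aligned_ref_blocks, aligned_ref_length

from conftest import oracle_exon_counts, sam_record, sam_text

PARAMS = ReadFilterParams()


class TestReadFilters:
    @pytest.mark.parametrize(
        "mapq,aln_len,dup,sec,unmapped,expected",
        [
            (255, 50, False, False, False, True),   # STAR unique mapper
            (101, 10, False, False, False, True),   # both thresholds inclusive
            (100, 50, False, False, False, False),  # MQ > 100 is strict
            (255, 9, False, False, False, False),   # < 10 bp aligned
            (255, 50, True, False, False, False),   # duplicate flag honored
            (255, 50, False, True, False, False),   # secondary/supplementary
            (255, 50, False, False, True, False),   # unmapped
        ],
    )
    def test_predicate(self, mapq, aln_len, dup, sec, unmapped, expected):
        assert read_passes_filters(
            mapq, aln_len, dup, sec, unmapped, PARAMS) is expected

    def test_duplicates_kept_when_not_excluded(self):
        keep_dups = ReadFilterParams(exclude_duplicates=False)
        assert read_passes_filters(255, 50, True, False, False, keep_dups)

    @pytest.mark.parametrize(
        "cigar,blocks,length",
        [
            ("50M", [(0, 50)], 50),
            ("10M5N10M", [(0, 10), (15, 25)], 20),   # splice gap splits
            ("10M2D10M", [(0, 10), (12, 22)], 20),   # deletion uncovered
            ("5S20M3I10M", [(0, 30)], 30),           # clips/inserts: no ref
            ("4M", [(0, 4)], 4),
        ],
    )
    def test_cigar_block_semantics(self, cigar, blocks, length):
        import re

        tuples = [
            ("MIDNSHP=X".index(op), int(n))
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
        ]
        assert aligned_ref_blocks(tuples) == blocks
        assert aligned_ref_length(tuples) == length


class TestOrientationTruthTable:
    @pytest.mark.parametrize(
        "library,read_forward,gene_strand,expected",
        [
            ("reverse", True, "-", Orientation.SENSE),
            ("reverse", False, "-", Orientation.ANTISENSE),
            ("reverse", True, "+", Orientation.ANTISENSE),
            ("reverse", False, "+", Orientation.SENSE),
            ("forward", True, "+", Orientation.SENSE),
            ("forward", False, "+", Orientation.ANTISENSE),
            ("forward", True, "-", Orientation.ANTISENSE),
            ("forward", False, "-", Orientation.SENSE),
            ("unstranded", True, "+", Orientation.BOTH),
            ("unstranded", False, "-", Orientation.BOTH),
        ],
    )
    def test_table(self, library, read_forward, gene_strand, expected):
        assert transcript_orientation(read_forward, gene_strand, library) is expected


class TestCountExonBases:
    # three_exon_model: '+' gene, exons (100,200), (300,400), (500,550);
    # reverse library => '-' reads are SENSE

    def test_read_fully_inside_exon(self, write_sam, three_exon_model):
        sam = write_sam([sam_record("r1", "2", 121, "50M", flag=16)])
        prof = count_exon_bases(sam, three_exon_model)
        assert prof.data.loc[1, "sense_bases"] == 50
        assert prof.data["sense_bases"].sum() == 50
        assert prof.data["antisense_bases"].sum() == 0

    def test_boundary_overlap_counts_partial(self, write_sam, three_exon_model):
        # 1-based start 91 -> 0-based 90..140; exon1 is 100..200 => 40 in
        sam = write_sam([sam_record("r1", "2", 91, "50M", flag=16)])
        prof = count_exon_bases(sam, three_exon_model)
        assert prof.data.loc[1, "sense_bases"] == 40

    def test_splice_gap_spanning_exon_contributes_zero(
        self, write_sam, three_exon_model
    ):
        # blocks: 150..200 and 500..550 (N spans exon 2 entirely)
        sam = write_sam([sam_record("r1", "2", 151, "50M300N50M", flag=16)])
        prof = count_exon_bases(sam, three_exon_model)
        assert prof.data.loc[1, "sense_bases"] == 50
        assert prof.data.loc[2, "sense_bases"] == 0
        assert prof.data.loc[3, "sense_bases"] == 50

    def test_filtered_reads_do_not_count(self, write_sam, three_exon_model):
        sam = write_sam([
            sam_record("dup", "2", 121, "50M", flag=16 | 0x400),
            sam_record("lowmq", "2", 121, "50M", flag=16, mapq=100),
            sam_record("short", "2", 121, "9M", flag=16),
            sam_record("secondary", "2", 121, "50M", flag=16 | 0x100),
        ])
        prof = count_exon_bases(sam, three_exon_model)
        assert prof.data[["sense_bases", "antisense_bases"]].to_numpy().sum() == 0

    def test_read2_is_flipped_to_fragment_strand(self, write_sam, three_exon_model):
        # paired read-2 on '+': fragment strand '-', i.e. SENSE (reverse lib)
        sam = write_sam([sam_record("r1", "2", 121, "50M", flag=0x1 | 0x80)])
        prof = count_exon_bases(sam, three_exon_model)
        assert prof.data.loc[1, "sense_bases"] == 50
        assert prof.data.loc[1, "antisense_bases"] == 0

    def test_unstranded_counts_everything_as_sense(
        self, write_sam, three_exon_model
    ):
        sam = write_sam([
            sam_record("f", "2", 121, "50M", flag=0),
            sam_record("r", "2", 121, "50M", flag=16),
        ])
        prof = count_exon_bases(sam, three_exon_model, library="unstranded")
        assert prof.data.loc[1, "sense_bases"] == 100
        assert prof.data.loc[1, "antisense_bases"] == 0

    def test_contig_mismatch_raises_with_hint(self, tmp_path, three_exon_model):
        from dataclasses import replace

        chr_model = replace(three_exon_model, chrom="chr2")
        sam = tmp_path / "x.sam"
        sam.write_text(sam_text([sam_record("r1", "2", 121, "50M")]))
        with pytest.raises(ValueError, match="contig not found.*chr-prefix"):
            count_exon_bases(sam, chr_model)


class TestOracleEquivalence:
    """Per-exon counts equal per-position brute force on random small SAMs."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("library", ["reverse", "forward"])
    def test_random_fixture_matches_oracle(
        self, seed, library, write_sam, three_exon_model
    ):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(40):
            pos1 = int(rng.integers(1, 700))
            kind = rng.integers(0, 5)
            cigar = {
                0: "50M", 1: "20M", 2: "30M100N20M", 3: "15M5D15M", 4: "5S30M",
            }[int(kind)]
            flag = 0
            if rng.random() < 0.5:
                flag |= 0x10
            if rng.random() < 0.15:
                flag |= 0x400
            if rng.random() < 0.1:
                flag |= 0x100
            mapq = int(rng.choice([255, 100, 3]))
            records.append(sam_record(f"r{i}", "2", pos1, cigar, flag, mapq))
        body = sam_text(records)
        sam = write_sam(records, name=f"rand{seed}_{library}.sam")
        prof = count_exon_bases(sam, three_exon_model, library=library)
        expected = oracle_exon_counts(body, three_exon_model, library=library)
        for n in three_exon_model.exon_numbers:
            assert prof.data.loc[n, "sense_bases"] == expected[n]["sense"]
            assert prof.data.loc[n, "antisense_bases"] == expected[n]["antisense"]

    def test_conservation_bound(self, write_sam, three_exon_model):
        # total attributed bases never exceed total aligned length
        records = [
            sam_record("a", "2", 101, "100M", flag=16),   # exactly exon 1
            sam_record("b", "2", 251, "100M", flag=16),   # half in exon 2
            sam_record("c", "2", 1001, "50M", flag=16),   # outside all exons
        ]
        prof = count_exon_bases(write_sam(records), three_exon_model)
        attributed = prof.data[["sense_bases", "antisense_bases"]].to_numpy().sum()
        assert attributed == 100 + 50
        assert attributed <= 250


class TestLibrarySize:
    def test_duplicates_excluded(self, write_sam):
        records = [sam_record(f"r{i}", "2", 1000 + i, "50M") for i in range(8)]
        records += [
            sam_record("d1", "2", 2000, "50M", flag=0x400),
            sam_record("d2", "2", 2100, "50M", flag=0x400),
        ]
        assert library_size(write_sam(records)) == 8

    def test_only_unmapped_reads_is_zero_with_warning(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(sam_text(["u1\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*"]))
        with pytest.warns(UserWarning, match="no usable reads"):
            assert library_size(sam) == 0

    def test_no_mapq_filter_at_library_level(self, write_sam):
        records = [sam_record("r1", "2", 1000, "50M", mapq=0)]
        assert library_size(write_sam(records)) == 1


class TestNormalization:
    def _counts_profile(self, write_sam, model, n_reads=20):
        records = [
            sam_record(f"r{i}", "2", 121, "50M", flag=16) for i in range(n_reads)
        ]
        return count_exon_bases(write_sam(records), model)

    def test_direct_formula(self, write_sam, three_exon_model):
        # 1000 bases on the 100 bp exon 1, library 10_000_000
        prof = self._counts_profile(write_sam, three_exon_model)
        prof = normalize_profile(prof, 10_000_000)
        # 20 reads x 50 bases = 1000; (1000/100)/1e7*1e6 = 1.0
        assert prof.data.loc[1, "norm_sense"] == pytest.approx(1.0)
        assert prof.data.loc[2, "norm_sense"] == 0.0

    def test_homogeneity_library_scaling(self, write_sam, three_exon_model):
        p1 = normalize_profile(
            self._counts_profile(write_sam, three_exon_model), 1_000_000)
        p2 = normalize_profile(
            self._counts_profile(write_sam, three_exon_model), 2_000_000)
        assert np.allclose(p1.data["norm_sense"], 2 * p2.data["norm_sense"])

    def test_zero_library_raises(self, write_sam, three_exon_model):
        prof = self._counts_profile(write_sam, three_exon_model)
        with pytest.raises(ValueError, match="empty library"):
            normalize_profile(prof, 0)


class TestTkDepth:
    def test_bases_over_combined_length(self, write_sam, three_exon_model):
        # exon 2+3 combined length 150; 3 reads x 50 bases inside exon 2
        records = [
            sam_record(f"r{i}", "2", 301 + i, "50M", flag=16) for i in range(3)
        ]
        prof = count_exon_bases(write_sam(records), three_exon_model)
        assert tk_depth(prof, {2, 3}) == pytest.approx(150 / 150)

    def test_zero_coverage_zero_depth(self, write_sam, three_exon_model):
        prof = count_exon_bases(write_sam([]), three_exon_model)
        assert tk_depth(prof, {2, 3}) == 0.0

    def test_both_strands_flag(self, write_sam, three_exon_model):
        records = [
            sam_record("s", "2", 301, "50M", flag=16),  # sense (reverse lib)
            sam_record("a", "2", 301, "50M", flag=0),   # antisense
        ]
        prof = count_exon_bases(write_sam(records), three_exon_model)
        assert tk_depth(prof, {2}) == pytest.approx(0.5)
        assert tk_depth(prof, {2}, both_strands=True) == pytest.approx(1.0)


class TestLibraryQC:
    @pytest.mark.parametrize(
        "n,expected", [(2_500_000, True), (2_499_999, False), (0, False)])
    def test_unique_read_floor(self, n, expected):
        assert library_qc(n, AssayConfig()) is expected
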