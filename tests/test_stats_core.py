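import numpy as np
import pytest

from bamdigest import errors
from bamdigest.bam_io import (
    MappingTable,
    ReadSample,
    SampledRead,
    sample_full_records,
    scan_mapping_locations,
)
from bamdigest.genome_meta import GenomeMeta
from bamdigest.stats_core import (
    base_composition,
    cigar_stats,
    compute_depth,
    depth_threshold_table,
    duplication_histogram,
    expected_base_freq,
    feature_mean_depth,
    flag_summary,
    insert_size_summary,
    mapq_summary,
    mismatch_summary,
    positional_quality,
    quality_summary,
)

import oracles


def _read(seq=None, qual=None, cigar="*", flag=0, pos=1, mapq=60, tlen=0,
          chrom="chr1", qname="r"):
    return SampledRead(
        qname=qname, flag=flag, chrom=chrom, pos=pos, mapq=mapq,
        cigar=cigar, tlen=tlen, seq=seq, qual=qual,
    )


def _sample(records):
    return ReadSample(records=records, requested_n=len(records),
                      total_seen=len(records), seed=0)


def _table(chroms, poss, strands, mapqs=None, spans=None,
           names=("chr1",), lengths=(10_000,)):
    n = len(poss)
    return MappingTable(
        reference_names=list(names),
        reference_lengths=list(lengths),
        chrom=np.asarray(chroms, dtype=np.int32),
        pos=np.asarray(poss, dtype=np.int64),
        strand=np.asarray(strands, dtype=bool),
        mapq=np.asarray(mapqs if mapqs is not None else [60] * n, dtype=np.int16),
        ref_span=np.asarray(spans if spans is not None else [75] * n, dtype=np.int64),
    )


def _flat_meta(length=10_000, name="chr1"):
    return GenomeMeta(
        chrom_lengths={name: length},
        chrom_base_freq={name: {b: 0.25 for b in "ACGT"}},
        chrom_ambiguous={name: 0},
        genome_base_freq={b: 0.25 for b in "ACGT"},
        genome_ambiguous=0,
        features={},
    )


class TestCigarStats:
    def test_75m_gapless(self):
        cs = cigar_stats("75M")
        assert cs.bases_by_op["M"] == 75
        assert cs.read_len == 75
        assert cs.ref_span == 75

    def test_single_deletion(self):
        cs = cigar_stats("20M1D55M")
        assert cs.bases_by_op["M"] == 75
        assert cs.bases_by_op["D"] == 1
        assert cs.read_len == 75
        assert cs.ref_span == 76

    def test_soft_clip(self):
        cs = cigar_stats("10S65M")
        assert cs.bases_by_op["S"] == 10
        assert cs.bases_by_op["M"] == 65
        assert cs.read_len == 75
        assert cs.ref_span == 65

    def test_star_is_all_zero(self):
        cs = cigar_stats("*")
        assert cs.read_len == 0 and cs.ref_span == 0
        assert all(v == 0 for v in cs.bases_by_op.values())

    def test_skip_and_hard_clip(self):
        cs = cigar_stats("5H10M100N10M")
        assert cs.read_len == 20
        assert cs.ref_span == 120
        assert cs.bases_by_op["H"] == 5

    @pytest.mark.parametrize("bad", ["", "M75", "75", "12Q", "1M2", "75m"])
    def test_malformed(self, bad):
        with pytest.raises(errors.MalformedCigar):
            cigar_stats(bad)


class TestComputeDepth:
    def test_single_read_interval(self):
        table = _table([0], [100], [False], spans=[75])
        profile = compute_depth(table, _flat_meta())
        d = profile.depth["chr1"]
        assert (d[99:174] == 1).all()  # 1-based [100, 174]
        assert d[98] == 0 and d[174] == 0
        assert int(d.sum()) == 75

    def test_empty_table_all_zero(self):
        table = _table([], [], [])
        profile = compute_depth(table, _flat_meta())
        assert profile.total == 0
        assert (profile.depth["chr1"] == 0).all()

    def test_matches_naive_oracle(self, single_end_bam, toy_genome):
        meta = toy_genome["meta"]
        table = scan_mapping_locations(single_end_bam["path"])
        profile = compute_depth(table, meta)
        naive = oracles.naive_pileup(single_end_bam["path"], meta.chrom_lengths)
        for chrom in meta.chrom_lengths:
            assert profile.depth[chrom].tolist() == naive[chrom]

    def test_pileup_conservation(self, single_end_bam, toy_genome):
        table = scan_mapping_locations(single_end_bam["path"])
        profile = compute_depth(table, toy_genome["meta"])
        assert profile.total == int(table.ref_span.sum())

    def test_position_beyond_chromosome(self):
        table = _table([0], [9_990], [False], spans=[75])
        with pytest.raises(errors.PositionBeyondChromosome):
            compute_depth(table, _flat_meta())

    def test_binned_landscape_mean(self):
        # uniform depth 2 -> every bin mean is 2
        table = _table([0, 0], [1, 1], [False, False], spans=[10_000, 10_000])
        profile = compute_depth(table, _flat_meta())
        assert np.allclose(profile.binned["chr1"], 2.0)
        assert profile.bin_width["chr1"] == 1000


class TestDepthThresholdTable:
    def test_all_zero_profile(self):
        table = _table([], [], [])
        profile = compute_depth(table, _flat_meta())
        rows = depth_threshold_table(profile, [1, 5, 10])
        assert [r["bases"] for r in rows] == [0, 0, 0]

    def test_threshold_zero_fraction_one(self):
        table = _table([0], [1], [False], spans=[10])
        profile = compute_depth(table, _flat_meta())
        rows = depth_threshold_table(profile, [0])
        assert rows[0]["fraction"] == 1.0

    def test_known_toy_depths(self):
        # depths {0, 1, 1, 3} over a 4-base genome; thresholds 1,2,3 -> 3,1,1
        meta = _flat_meta(length=4)
        table = _table(
            [0, 0, 0, 0, 0],
            [2, 3, 4, 4, 4],
            [False] * 5,
            spans=[1, 1, 1, 1, 1],
            lengths=(4,),
        )
        profile = compute_depth(table, meta)
        assert profile.depth["chr1"].tolist() == [0, 1, 1, 3]
        rows = depth_threshold_table(profile, [1, 2, 3])
        assert [r["bases"] for r in rows] == [3, 1, 1]

    def test_non_increasing_fractions(self, single_end_bam, toy_genome):
        table = scan_mapping_locations(single_end_bam["path"])
        profile = compute_depth(table, toy_genome["meta"])
        rows = depth_threshold_table(profile)
        fr = [r["fraction"] for r in rows]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_rejects_non_increasing_thresholds(self):
        table = _table([], [], [])
        profile = compute_depth(table, _flat_meta())
        with pytest.raises(ValueError):
            depth_threshold_table(profile, [5, 5])


class TestFeatureMeanDepth:
    def test_uniform_blocks(self):
        meta = _flat_meta(length=1000)
        meta.features = {
            "exon": [("chr1", 101, 200)],
            "intergenic": [("chr1", 1, 100), ("chr1", 201, 1000)],
        }
        # depth 10 exactly on the exon
        table = _table([0] * 10, [101] * 10, [False] * 10, spans=[100] * 10,
                       lengths=(1000,))
        profile = compute_depth(table, meta)
        means = feature_mean_depth(profile, meta)
        assert means["exon"] == pytest.approx(10.0)
        assert means["intergenic"] == pytest.approx(0.0)

    def test_whole_genome_class_equals_global_mean(self):
        meta = _flat_meta(length=1000)
        meta.features = {"all": [("chr1", 1, 1000)]}
        table = _table([0, 0], [1, 501], [False, False], spans=[500, 100],
                       lengths=(1000,))
        profile = compute_depth(table, meta)
        means = feature_mean_depth(profile, meta)
        assert means["all"] == pytest.approx(profile.mean_depth())

    def test_exome_like_enrichment(self, toy_genome, tmp_path):
        from bamdigest.synthetic_bam import SimSpec, generate_synthetic_bam

        meta = toy_genome["meta"]
        spec = SimSpec(
            fasta=toy_genome["fasta"],
            read_count=4000,
            read_length=75,
            on_target_fraction=0.8,
            target_intervals=list(meta.features["exon"]),
            seed=77,
        )
        path = str(tmp_path / "exome.bam")
        generate_synthetic_bam(spec, path)
        table = scan_mapping_locations(path)
        profile = compute_depth(table, meta)
        means = feature_mean_depth(profile, meta)
        assert means["exon"] > means["intron"] > 0


class TestQualitySummary:
    def test_all_q30(self):
        qual = chr(30 + 33) * 10
        sample = _sample([_read(qual=qual), _read(qual=qual)])
        prof = quality_summary(sample, cutoffs=[30, 31])
        assert prof.threshold_table[0]["fraction"] == 1.0
        assert prof.threshold_table[1]["fraction"] == 0.0
        assert prof.threshold_table[0]["error_prob"] == pytest.approx(0.001)

    def test_known_multiset(self):
        sample = _sample([
            _read(qual=chr(20 + 33) * 10),
            _read(qual=chr(30 + 33) * 10),
        ])
        prof = quality_summary(sample, cutoffs=[30])
        assert prof.threshold_table[0]["fraction"] == pytest.approx(0.5)
        assert prof.mean == pytest.approx(25.0)

    def test_histogram_total(self, single_end_bam):
        sample = sample_full_records(single_end_bam["path"], n=500, seed=1)
        prof = quality_summary(sample)
        total_bases = sum(len(r.qual) for r in sample.records)
        assert sum(prof.histogram.values()) == total_bases

    def test_missing_quality(self):
        sample = _sample([_read(qual=None), _read(qual="*")])
        with pytest.raises(errors.MissingQuality):
            quality_summary(sample)

    def test_non_increasing_fractions(self, single_end_bam):
        sample = sample_full_records(single_end_bam["path"], n=500, seed=1)
        prof = quality_summary(sample)
        fr = [r["fraction"] for r in prof.threshold_table]
        assert all(a >= b for a, b in zip(fr, fr[1:]))


class TestPositionalQuality:
    def test_constant_input(self):
        scores = [30, 35, 20, 25]
        qual = "".join(chr(s + 33) for s in scores)
        sample = _sample([_read(qual=qual) for _ in range(5)])
        pos = positional_quality(sample)
        assert pos["mean"] == pytest.approx(scores)
        assert pos["median"] == scores

    def test_mixed_lengths_denominator(self):
        q50 = chr(63) * 50  # Q30
        q75 = chr(73) * 75  # Q40
        sample = _sample([_read(qual=q50), _read(qual=q75)])
        pos = positional_quality(sample)
        assert pos["n_reads"][:50] == [2] * 50
        assert pos["n_reads"][50:] == [1] * 25
        assert pos["mean"][60] == pytest.approx(40.0)
        assert pos["mean"][10] == pytest.approx(35.0)

    def test_reverse_reads_flipped_to_sequencing_orientation(self):
        # forward read scores rise; reverse read stores them reversed.
        scores = list(range(10, 20))
        fwd = "".join(chr(s + 33) for s in scores)
        rev = fwd[::-1]
        sample = _sample([_read(qual=fwd), _read(qual=rev, flag=0x10)])
        pos = positional_quality(sample)
        assert pos["mean"] == pytest.approx([float(s) for s in scores])

    def test_decay_recovery(self, single_end_bam):
        # generator decays mean quality linearly; recovered slope is negative
        sample = sample_full_records(single_end_bam["path"], n=1000, seed=4)
        pos = positional_quality(sample)
        means = np.asarray(pos["mean"])
        x = np.arange(means.shape[0])
        slope = np.polyfit(x, means, 1)[0]
        expected = -single_end_bam["spec"].quality_decay
        assert slope == pytest.approx(expected, abs=0.03)


class TestFlagSummary:
    def test_proper_pairs(self):
        counts = flag_summary([99, 147, 83, 163])
        assert counts["paired"] == 4
        assert counts["properly_paired"] == 4
        assert counts["unmapped"] == 0
        assert counts["mapped"] == 4

    def test_unmapped_bit(self):
        counts = flag_summary([4])
        assert counts["unmapped"] == 1
        assert counts["mapped"] == 0

    def test_random_mixture_against_bit_oracle(self):
        rng = np.random.default_rng(5)
        flags = [int(f) for f in rng.integers(0, 4096, size=500)]
        counts = flag_summary(flags)
        for name, bit, wanted in [
            ("paired", 0x1, True), ("properly_paired", 0x2, True),
            ("unmapped", 0x4, True), ("mate_unmapped", 0x8, True),
            ("reverse_strand", 0x10, True), ("secondary", 0x100, True),
            ("duplicate", 0x400, True), ("supplementary", 0x800, True),
        ]:
            brute = sum(1 for f in flags if bool(f & bit) == wanted)
            assert counts[name] == brute

    def test_path_input_counts_all_records(self, paired_bam):
        counts = flag_summary(paired_bam["path"])
        truth = paired_bam["truth"]
        assert counts["total"] == truth.total_reads
        assert counts["properly_paired"] == truth.total_reads


class TestMapqSummary:
    def test_constant(self):
        table = _table([0], [1], [False], mapqs=[70])
        out = mapq_summary(table, cutoffs=[70])
        assert out["threshold_table"][0]["fraction"] == 1.0

    def test_direct_count(self):
        table = _table([0] * 3, [1, 2, 3], [False] * 3, mapqs=[0, 30, 70])
        out = mapq_summary(table, cutoffs=[30])
        assert out["threshold_table"][0]["fraction"] == pytest.approx(2 / 3)

    def test_histogram_matches_truth(self, single_end_bam):
        table = scan_mapping_locations(single_end_bam["path"])
        out = mapq_summary(table)
        assert out["histogram"] == single_end_bam["truth"].mapq_histogram


class TestMismatchSummary:
    def test_all_perfect(self):
        sample = _sample([_read(cigar="75M", seq="A" * 75) for _ in range(4)])
        out = mismatch_summary(sample)
        assert out["fractions"]["M"] == 1.0
        assert out["reads_with_indel_or_clip"] == 0.0

    def test_deletion_reads(self):
        sample = _sample([_read(cigar="20M1D55M") for _ in range(3)])
        out = mismatch_summary(sample)
        assert out["bases_by_op"]["D"] == 3
        assert out["reads_with_indel_or_clip"] == 1.0
        # D normalized by reference span
        assert out["fractions"]["D"] == pytest.approx(3 / (76 * 3))

    def test_soft_clip_fraction(self):
        records = [_read(cigar="10S65M")] + [_read(cigar="75M")] * 9
        out = mismatch_summary(_sample(records))
        assert out["fractions"]["S"] == pytest.approx(10 / 750)

    def test_against_naive_oracle(self, single_end_bam):
        sample = sample_full_records(single_end_bam["path"], n=10_000, seed=2)
        out = mismatch_summary(sample)
        naive = oracles.naive_mismatch_fractions(r.cigar for r in sample.records)
        assert out["fractions"]["M"] == pytest.approx(naive["M"])
        assert out["fractions"]["I"] == pytest.approx(naive["I"])
        assert out["fractions"]["S"] == pytest.approx(naive["S"])
        assert out["fractions"]["D"] == pytest.approx(naive["D"])
        assert out["reads_with_indel_or_clip"] == pytest.approx(
            naive["reads_with_event"]
        )


class TestDuplicationHistogram:
    def test_direct_count(self):
        table = _table(
            [0, 0, 0, 0], [100, 100, 100, 200], [False] * 4
        )
        assert duplication_histogram(table) == {3: 1, 1: 1}

    def test_all_distinct(self):
        table = _table([0] * 5, [10, 20, 30, 40, 50], [False] * 5)
        assert duplication_histogram(table) == {1: 5}

    def test_strand_distinguishes_locations(self):
        table = _table([0, 0], [100, 100], [False, True])
        assert duplication_histogram(table) == {1: 2}

    def test_empty(self):
        assert duplication_histogram(_table([], [], [])) == {}

    def test_matches_generator_truth(self, single_end_bam):
        table = scan_mapping_locations(single_end_bam["path"])
        hist = duplication_histogram(table)
        assert hist == single_end_bam["truth"].location_multiplicity

    def test_matches_naive_oracle(self, paired_bam):
        table = scan_mapping_locations(paired_bam["path"])
        assert duplication_histogram(table) == oracles.naive_duplication_histogram(
            paired_bam["path"]
        )

    def test_sigma_k_times_count_equals_rows(self, single_end_bam):
        table = scan_mapping_locations(single_end_bam["path"])
        hist = duplication_histogram(table)
        assert sum(k * n for k, n in hist.items()) == table.n_rows


class TestInsertSizeSummary:
    def test_two_proper_pairs(self):
        records = [
            _read(flag=99, tlen=200), _read(flag=147, tlen=-200),
            _read(flag=99, tlen=300), _read(flag=147, tlen=-300),
        ]
        out = insert_size_summary(_sample(records))
        assert out["n"] == 2  # first-in-pair only
        assert out["mean"] == pytest.approx(250.0)

    def test_single_end_absent(self):
        out = insert_size_summary(_sample([_read(flag=0, tlen=0)] * 5))
        assert out is None

    def test_cap_excludes_artifacts(self):
        records = [
            _read(flag=99, tlen=200),
            _read(flag=99, tlen=50_000),
        ]
        out = insert_size_summary(_sample(records), max_abs=10_000)
        assert out["n"] == 1
        assert out["excluded_over_max"] == 1

    def test_recovery_within_3se(self, paired_bam):
        sample = sample_full_records(paired_bam["path"], n=10_000, seed=6)
        out = insert_size_summary(sample)
        truth = paired_bam["truth"]
        se = truth.insert_sizes_sd / np.sqrt(out["n"])
        assert abs(out["mean"] - truth.insert_sizes_mean) < 3 * se + 1e-9


class TestBaseComposition:
    def test_arithmetic_example(self):
        meta = _flat_meta()
        sample = _sample([
            _read(seq="AACG", qual="IIII"),
            _read(seq="TTNN", qual="IIII"),
        ])
        out = base_composition(sample, meta, k=2, end_window=2)
        assert out.n_base_fraction == pytest.approx(0.25)
        assert out.fraction_reads_with_n == pytest.approx(0.5)
        gc_a = out.gc_histogram
        assert gc_a["mean"] == pytest.approx((0.5 + 0.0) / 2)

    def test_forced_start_composition(self):
        meta = _flat_meta()
        sample = _sample([_read(seq="GATC") for _ in range(4)])
        out = base_composition(sample, meta, k=2, end_window=2)
        assert out.positional_start[0]["freq"]["G"] == 1.0

    def test_reverse_strand_flipped_back(self):
        meta = _flat_meta()
        # stored (reference-oriented) seq GATC on reverse strand reads GATC
        # in sequencing orientation as revcomp = GATC -> ... check position 1
        sample = _sample([_read(seq="AAAC", flag=0x10)])
        out = base_composition(sample, meta, k=2, end_window=2)
        # sequencing orientation = revcomp("AAAC") = "GTTT"
        assert out.positional_start[0]["freq"]["G"] == 1.0

    def test_positional_rows_sum_to_one(self, single_end_bam, toy_genome):
        sample = sample_full_records(single_end_bam["path"], n=1000, seed=8)
        out = base_composition(sample, toy_genome["meta"])
        for row in out.positional_start + out.positional_end:
            if row["n_called"]:
                assert sum(row["freq"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_observed_close_to_expected_for_uniform_sampling(
        self, single_end_bam, toy_genome
    ):
        sample = sample_full_records(single_end_bam["path"], n=10_000, seed=8)
        out = base_composition(sample, toy_genome["meta"])
        for b in "ACGT":
            assert out.observed_freq[b] / out.expected_freq[b] == pytest.approx(
                1.0, abs=0.02
            )

    def test_expected_is_strand_symmetrized(self):
        meta = _flat_meta()
        meta.genome_base_freq = {"A": 0.4, "C": 0.1, "G": 0.2, "T": 0.3}
        exp = expected_base_freq(meta)
        assert exp["A"] == exp["T"] == pytest.approx(0.35)
        assert exp["C"] == exp["G"] == pytest.approx(0.15)

    def test_kmer_tables(self):
        meta = _flat_meta()
        sample = _sample([_read(seq="ACGTACGT")] * 3 + [_read(seq="TTTTACGT")])
        out = base_composition(sample, meta, k=4)
        top_start = out.kmer_start["top"]
        assert top_start[0]["kmer"] == "ACGT"
        assert top_start[0]["count"] == 3
        top_end = out.kmer_end["top"]
        assert top_end[0]["kmer"] == "ACGT"
        assert top_end[0]["count"] == 4

    def test_missing_sequence(self):
        with pytest.raises(errors.MissingSequence):
            base_composition(_sample([_read(seq=None)]), _flat_meta())

    def test_n_rate_recovery(self, single_end_bam, toy_genome):
        sample = sample_full_records(single_end_bam["path"], n=10_000, seed=8)
        out = base_composition(sample, toy_genome["meta"])
        truth = single_end_bam["truth"]
        assert out.n_base_fraction == pytest.approx(
            truth.n_bases / truth.total_bases
        )
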