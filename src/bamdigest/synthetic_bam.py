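"""Synthetic sorted/indexed BAM fixtures with fully specified ground truth.

Every statistic the digest computes is testable against the TruthRecord
emitted next to the BAM. Reads are error-free copies of the reference
except for explicit N substitution and declared indel/soft-clip events, so
CIGAR classes fully determine mismatch statistics.

SEQ/QUAL are stored reference-oriented as SAM requires: for reverse-strand
reads the stored sequence equals the forward reference segment and the
stored qualities are the sequencing-orientation qualities reversed.

Pairs are emitted FR-oriented with the leftmost mate carrying positive
TLEN. For paired specs each pair contributes one forward and one reverse
read, so strand_forward_fraction applies to single-end specs only.
"""

from __future__ import annotations

import json
import os
from array import array
from collections import Counter
from dataclasses import asdict, dataclass, field

import numpy as np
import pysam

from .errors import SpecInfeasible
from .genome_meta import compile_genome_meta

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass
class SimSpec:
    """Parameters of one synthetic BAM; every knob is recoverable truth."""

    fasta: str
    read_count: int = 1000
    read_length: int = 75
    paired: bool = False
    insert_mean: float = 262.6
    insert_sd: float = 60.0
    quality_start_mean: float = 35.0
    quality_decay: float = 0.1  # mean score lost per read position
    quality_noise_sd: float = 2.0
    n_rate: float = 0.0  # per-base probability of an N call
    strand_forward_fraction: float = 0.5
    duplicate_rate: float = 0.0  # per-read probability of re-using a location
    softclip_rate: float = 0.0
    softclip_len: int = 10
    insertion_rate: float = 0.0
    insertion_len: int = 2
    deletion_rate: float = 0.0
    deletion_len: int = 1
    mapq_dist: dict[int, float] = field(default_factory=lambda: {60: 1.0})
    on_target_fraction: float = 0.0  # reads forced to start inside target intervals
    target_intervals: list = field(default_factory=list)  # (chrom, start, end)
    seed: int = 0

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        for name, p in [
            ("n_rate", self.n_rate),
            ("duplicate_rate", self.duplicate_rate),
            ("softclip_rate", self.softclip_rate),
            ("insertion_rate", self.insertion_rate),
            ("deletion_rate", self.deletion_rate),
            ("strand_forward_fraction", self.strand_forward_fraction),
            ("on_target_fraction", self.on_target_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise SpecInfeasible(f"{name}={p} outside [0, 1]")
        if self.softclip_rate + self.deletion_rate + self.insertion_rate > 1.0:
            raise SpecInfeasible("event rates sum to more than 1")
        if self.paired and self.insert_mean <= 0:
            raise SpecInfeasible("insert_mean must be positive for paired specs")
        max_span = self.read_length + self.deletion_len
        if all(l < max_span for l in chrom_lengths.values()):
            raise SpecInfeasible(
                f"read length {self.read_length} exceeds every chromosome"
            )
        if abs(sum(self.mapq_dist.values()) - 1.0) > 1e-9:
            raise SpecInfeasible("mapq_dist probabilities must sum to 1")


@dataclass
class TruthRecord:
    """Exact realized values of every simulated quantity."""

    total_reads: int = 0
    total_bases: int = 0
    n_bases: int = 0
    reads_with_n: int = 0
    base_counts: dict[str, int] = field(default_factory=dict)
    forward_reads: int = 0
    reverse_reads: int = 0
    duplicate_events: int = 0
    location_multiplicity: dict[int, int] = field(default_factory=dict)
    mapq_histogram: dict[int, int] = field(default_factory=dict)
    flag_counts: dict[int, int] = field(default_factory=dict)
    insert_sizes_mean: float | None = None
    insert_sizes_sd: float = 0.0
    insert_sizes_n: int = 0
    per_position_mean_quality: list[float] = field(default_factory=list)
    reads_with_softclip: int = 0
    reads_with_insertion: int = 0
    reads_with_deletion: int = 0
    softclip_bases: int = 0
    insertion_bases: int = 0
    deletion_bases: int = 0
    aligned_ref_span_total: int = 0
    gc_fraction: float = 0.0
    spec: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def generate_toy_genome(
    out_dir: str,
    n_chroms: int = 2,
    lengths: tuple[int, ...] = (100_000, 50_000),
    base_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    n_genes_per_chrom: int = 5,
    gene_length: int = 3000,
    exons_per_gene: int = 3,
    exon_length: int = 200,
    seed: int = 0,
    build_label: str = "toy",
):
    """Write a random FASTA plus a consistent GFF3 and compile its metadata.

    Genes are evenly spaced along each chromosome; each holds evenly spaced
    fixed-length exons. Returns (fasta_path, gff_path, GenomeMeta).
    """
    if any(l < 1000 for l in lengths[:n_chroms]):
        raise ValueError("chromosome lengths must be >= 1000")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "toy.fa")
    gff_path = os.path.join(out_dir, "toy.gff3")
    w = np.asarray(base_weights, dtype=float)
    w = w / w.sum()
    with open(fasta_path, "w") as fh:
        for i in range(n_chroms):
            name = f"chr{i + 1}"
            seq = rng.choice(_BASES, size=lengths[i], p=w)
            fh.write(f">{name}\n")
            raw = seq.tobytes().decode()
            for j in range(0, len(raw), 80):
                fh.write(raw[j : j + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(n_chroms):
            name = f"chr{i + 1}"
            length = lengths[i]
            gap = length // (n_genes_per_chrom + 1)
            for g in range(n_genes_per_chrom):
                gstart = gap * (g + 1)
                gend = min(gstart + gene_length - 1, length)
                fh.write(
                    f"{name}\ttoy\tgene\t{gstart}\t{gend}\t.\t+\t.\t"
                    f"ID=gene{i}_{g}\n"
                )
                estep = max(exon_length, (gend - gstart + 1) // exons_per_gene)
                for x in range(exons_per_gene):
                    es = gstart + x * estep
                    ee = min(es + exon_length - 1, gend)
                    if es > gend:
                        break
                    fh.write(
                        f"{name}\ttoy\texon\t{es}\t{ee}\t.\t+\t.\t"
                        f"Parent=gene{i}_{g}\n"
                    )
    meta = compile_genome_meta(fasta_path, gff_path, build_label=build_label)
    return fasta_path, gff_path, meta


def _load_chrom_seqs(fasta: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(fasta) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts).upper()
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts).upper()
    return seqs


def generate_synthetic_bam(spec: SimSpec, out_path: str) -> TruthRecord:
    """Emit a coordinate-sorted, indexed BAM conforming to `spec`.

    The TruthRecord is saved next to the BAM (`<out>.truth.json`) and
    returned. For paired specs `read_count` counts individual reads and is
    rounded down to a whole number of pairs.
    """
    seqs = _load_chrom_seqs(spec.fasta)
    if not seqs:
        raise SpecInfeasible(f"no sequences in {spec.fasta}")
    chrom_lengths = {c: len(s) for c, s in seqs.items()}
    spec.validate(chrom_lengths)
    rng = np.random.default_rng(spec.seed)

    names = list(chrom_lengths)
    L = spec.read_length
    max_span = L + spec.deletion_len
    if spec.paired:
        frag_hi = int(max(spec.insert_mean + 6 * spec.insert_sd, max_span))
        span_need = frag_hi + spec.deletion_len
    else:
        frag_hi = 0
        span_need = max_span
    usable = np.asarray(
        [max(0, chrom_lengths[c] - span_need + 1) for c in names], dtype=np.float64
    )
    if usable.sum() == 0:
        raise SpecInfeasible("no chromosome can hold a full read/fragment")
    chrom_probs = usable / usable.sum()

    mapq_vals = np.asarray(list(spec.mapq_dist), dtype=np.int64)
    mapq_probs = np.asarray([spec.mapq_dist[int(v)] for v in mapq_vals])

    targets = [
        (c, s, e)
        for c, s, e in spec.target_intervals
        if e - s + 1 >= span_need and c in chrom_lengths
    ]

    truth = TruthRecord(spec={**asdict(spec), "fasta": os.path.basename(spec.fasta)})
    base_counter: Counter = Counter()
    qual_sum = np.zeros(L, dtype=np.float64)
    qual_n = 0
    location_counter: Counter = Counter()
    flag_counter: Counter = Counter()
    mapq_counter: Counter = Counter()
    inserts: list[int] = []

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in names],
        }
    )
    tid = {c: i for i, c in enumerate(names)}

    def draw_position():
        if targets and rng.random() < spec.on_target_fraction:
            c, s, e = targets[rng.integers(len(targets))]
            return c, int(rng.integers(s, e - span_need + 2))
        ci = rng.choice(len(names), p=chrom_probs)
        c = names[ci]
        return c, int(rng.integers(1, chrom_lengths[c] - span_need + 2))

    def make_qualities() -> np.ndarray:
        base = spec.quality_start_mean - spec.quality_decay * np.arange(L)
        noisy = base + rng.normal(0.0, spec.quality_noise_sd, size=L)
        return np.clip(np.rint(noisy), 2, 40).astype(np.int64)

    def build_read(chrom: str, pos: int):
        """One read anchored at 1-based pos on the forward reference.

        Returns (cigar, seq, event) with seq in reference orientation;
        at most one declared event (softclip / deletion / insertion).
        """
        ref = seqs[chrom]
        u = rng.random()
        if u < spec.softclip_rate:
            sl = min(spec.softclip_len, L - 1)
            body = ref[pos - 1 : pos - 1 + (L - sl)]
            clip = "".join(rng.choice(_BASES, size=sl).astype("U1"))
            return f"{sl}S{L - sl}M", clip + body, "S"
        u -= spec.softclip_rate
        if u < spec.deletion_rate:
            dl = spec.deletion_len
            m1 = L // 2
            m2 = L - m1
            s = (
                ref[pos - 1 : pos - 1 + m1]
                + ref[pos - 1 + m1 + dl : pos - 1 + m1 + dl + m2]
            )
            return f"{m1}M{dl}D{m2}M", s, "D"
        u -= spec.deletion_rate
        if u < spec.insertion_rate:
            il = min(spec.insertion_len, L - 2)
            m1 = (L - il) // 2
            m2 = L - il - m1
            ins = "".join(rng.choice(_BASES, size=il).astype("U1"))
            s = ref[pos - 1 : pos - 1 + m1] + ins + ref[pos - 1 + m1 : pos - 1 + m1 + m2]
            return f"{m1}M{il}I{m2}M", s, "I"
        return f"{L}M", ref[pos - 1 : pos - 1 + L], None

    def apply_n(seq: str) -> str:
        if spec.n_rate <= 0:
            return seq
        mask = rng.random(len(seq)) < spec.n_rate
        if not mask.any():
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        arr[mask] = b"N"
        return arr.tobytes().decode()

    def account(seq_store, q_seqorient, chrom, pos, reverse, flag, cigar, event):
        truth.total_reads += 1
        truth.total_bases += len(seq_store)
        oriented = _revcomp(seq_store) if reverse else seq_store
        nn = oriented.count("N")
        truth.n_bases += nn
        if nn:
            truth.reads_with_n += 1
        for b in "ACGTN":
            base_counter[b] += oriented.count(b)
        nonlocal qual_n
        qual_sum[: q_seqorient.shape[0]] += q_seqorient
        qual_n += 1
        location_counter[(tid[chrom], pos, reverse)] += 1
        flag_counter[flag] += 1
        if reverse:
            truth.reverse_reads += 1
        else:
            truth.forward_reads += 1
        if event == "S":
            truth.reads_with_softclip += 1
            truth.softclip_bases += min(spec.softclip_len, L - 1)
        elif event == "I":
            truth.reads_with_insertion += 1
            truth.insertion_bases += min(spec.insertion_len, L - 2)
        elif event == "D":
            truth.reads_with_deletion += 1
            truth.deletion_bases += spec.deletion_len
        span = 0
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                if ch in "MDN=X":
                    span += int(num)
                num = ""
        truth.aligned_ref_span_total += span

    records = []
    n_units = spec.read_count // 2 if spec.paired else spec.read_count
    prev_location = None

    for i in range(n_units):
        is_dup = prev_location is not None and rng.random() < spec.duplicate_rate
        if is_dup:
            chrom, pos = prev_location
            truth.duplicate_events += 1
        else:
            chrom, pos = draw_position()
            prev_location = (chrom, pos)
        mapq = int(rng.choice(mapq_vals, p=mapq_probs))

        if spec.paired:
            frag = int(np.rint(rng.normal(spec.insert_mean, spec.insert_sd)))
            frag = min(max(frag, max_span), frag_hi)
            pos2 = pos + frag - L
            cig1, s1, ev1 = build_read(chrom, pos)
            cig2, s2, ev2 = build_read(chrom, pos2)
            inserts.append(frag)
            mapq_counter[mapq] += 2
            for (p, cig, s, ev, flag, mate_p, t) in (
                (pos, cig1, s1, ev1, 99, pos2, frag),
                (pos2, cig2, s2, ev2, 147, pos, -frag),
            ):
                reverse = bool(flag & 0x10)
                s = apply_n(s)
                q = make_qualities()
                qual_store = q[::-1] if reverse else q
                records.append(
                    (tid[chrom], p - 1, f"read{i}", flag, mapq, cig,
                     s, qual_store, t, tid[chrom], mate_p - 1)
                )
                account(s, q, chrom, p, reverse, flag, cig, ev)
        else:
            reverse = bool(rng.random() >= spec.strand_forward_fraction)
            cig, s, ev = build_read(chrom, pos)
            s = apply_n(s)
            q = make_qualities()
            qual_store = q[::-1] if reverse else q
            flag = 0x10 if reverse else 0
            mapq_counter[mapq] += 1
            records.append(
                (tid[chrom], pos - 1, f"read{i}", flag, mapq, cig,
                 s, qual_store, 0, -1, -1)
            )
            account(s, q, chrom, pos, reverse, flag, cig, ev)

    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
        for (t, p0, name, flag, mapq, cig, seq, qual, tlen, mtid, mpos0) in records:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.flag = flag
            a.reference_id = t
            a.reference_start = p0
            a.mapping_quality = mapq
            a.cigarstring = cig
            a.query_sequence = seq
            a.query_qualities = array("B", qual.tolist())
            a.template_length = tlen
            a.next_reference_id = mtid
            a.next_reference_start = mpos0
            bam.write(a)
    pysam.index(out_path)

    truth.base_counts = {b: int(base_counter[b]) for b in "ACGTN"}
    truth.location_multiplicity = {
        int(k): int(v) for k, v in sorted(Counter(location_counter.values()).items())
    }
    truth.mapq_histogram = {int(k): int(v) for k, v in sorted(mapq_counter.items())}
    truth.flag_counts = {int(k): int(v) for k, v in sorted(flag_counter.items())}
    if inserts:
        arr = np.asarray(inserts, dtype=np.float64)
        truth.insert_sizes_mean = float(arr.mean())
        truth.insert_sizes_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        truth.insert_sizes_n = int(arr.size)
    if qual_n:
        truth.per_position_mean_quality = (qual_sum / qual_n).tolist()
    called = sum(truth.base_counts[b] for b in "ACGT")
    gc = truth.base_counts["C"] + truth.base_counts["G"]
    truth.gc_fraction = gc / called if called else 0.0
    truth.save(out_path + ".truth.json")
    return truth
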