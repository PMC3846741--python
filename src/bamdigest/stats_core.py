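"""All report statistics: depth, quality, mapping and base composition.

Inputs are the three ingestion products — the full-pass MappingTable, the
ReadSample of complete records, and the GenomeMeta store. Per-base
statistics (quality, composition, CIGAR classes, insert sizes) come from
the subsample; location statistics (depth, duplication, mapq, strand) from
the full pass.

Positional statistics are computed in sequencing orientation: records
aligned to the reverse strand are flipped back (sequence
reverse-complemented, qualities reversed) before per-position accounting,
so read-start artifacts such as primer contamination stay detectable.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .bam_io import (
    FLAG_DUPLICATE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    MappingTable,
    ReadSample,
)
from .errors import (
    MalformedCigar,
    MissingQuality,
    MissingSequence,
    PositionBeyondChromosome,
)
from .genome_meta import GenomeMeta

DEFAULT_DEPTH_THRESHOLDS = (1, 5, 10, 20, 30, 50, 100)
DEFAULT_QUALITY_CUTOFFS = (10, 20, 30, 40)
DEFAULT_MAPQ_CUTOFFS = (1, 10, 20, 30, 60)
DEFAULT_MAX_INSERT = 10_000
DEFAULT_KMER_K = 5
DEFAULT_END_WINDOW = 10
MAX_QUALITY_SCORE = 93  # phred+33 printable range

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")
_READ_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


# --- CIGAR ----------------------------------------------------------------

@dataclass
class CigarSummary:
    """Per-operation base totals plus derived read length and reference span.

    read_len sums the read-consuming operations (M, I, S, =, X); ref_span
    sums the reference-consuming ones (M, D, N, =, X).
    """

    bases_by_op: dict[str, int]
    read_len: int
    ref_span: int


def cigar_stats(cigar: str) -> CigarSummary:
    """Parse a CIGAR string into per-operation base counts.

    "75M" is 75 read bases aligned without gap (read_len = ref_span = 75);
    "20M1D55M" has a one-base deletion, so 75 read bases span 76 reference
    bases. "*" (no alignment shape) yields an all-zero summary.
    """
    ops = {op: 0 for op in "MIDNSHP=X"}
    if cigar == "*":
        return CigarSummary(bases_by_op=ops, read_len=0, ref_span=0)
    if not _CIGAR_FULL_RE.match(cigar):
        raise MalformedCigar(f"invalid CIGAR string: {cigar!r}")
    for count, op in _CIGAR_RE.findall(cigar):
        ops[op] += int(count)
    read_len = sum(ops[o] for o in _READ_OPS)
    ref_span = sum(ops[o] for o in _REF_OPS)
    return CigarSummary(bases_by_op=ops, read_len=read_len, ref_span=ref_span)


# --- sequencing depth -----------------------------------------------------

@dataclass
class DepthProfile:
    """Exact per-base pileup plus a low-resolution binned landscape."""

    depth: dict[str, np.ndarray]
    bin_width: dict[str, int]
    binned: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(d.shape[0] for d in self.depth.values()))

    def mean_depth(self) -> float:
        glen = self.genome_length
        return self.total / glen if glen else 0.0

    def per_chromosome_mean(self) -> dict[str, float]:
        return {
            c: (float(d.mean()) if d.shape[0] else 0.0)
            for c, d in self.depth.items()
        }


def landscape_bin_width(chrom_length: int) -> int:
    """~500 bins per chromosome, floored to 1-kb multiples, minimum 1 kb."""
    return max(1000, (chrom_length // 500) // 1000 * 1000)


def compute_depth(table: MappingTable, meta: GenomeMeta) -> DepthProfile:
    """Exact pileup via difference-array accumulation over (pos, ref_span)."""
    if table.ref_span is None:
        raise ValueError("depth requires ref_span; table was built in minimal mode")
    depth: dict[str, np.ndarray] = {}
    for name in meta.chrom_lengths:
        depth[name] = np.zeros(meta.chrom_lengths[name], dtype=np.int64)

    for ci, name in enumerate(table.reference_names):
        mask = table.chrom == ci
        if not mask.any():
            continue
        if name not in meta.chrom_lengths:
            raise PositionBeyondChromosome(
                f"BAM reference {name!r} absent from genome metadata"
            )
        length = meta.chrom_lengths[name]
        pos = table.pos[mask]
        span = table.ref_span[mask]
        ends = pos + span - 1
        if (ends > length).any() or (pos < 1).any():
            bad = int(pos[ends > length][0]) if (ends > length).any() else int(pos[0])
            raise PositionBeyondChromosome(
                f"alignment at {name}:{bad} extends past chromosome end "
                f"({length} bp): BAM/metadata mismatch"
            )
        diff = np.zeros(length + 1, dtype=np.int64)
        np.add.at(diff, pos - 1, 1)
        np.add.at(diff, ends, -1)
        depth[name] = np.cumsum(diff[:-1])

    bin_width: dict[str, int] = {}
    binned: dict[str, np.ndarray] = {}
    for name, d in depth.items():
        w = landscape_bin_width(d.shape[0])
        bin_width[name] = w
        nbins = (d.shape[0] + w - 1) // w
        padded = np.zeros(nbins * w, dtype=np.float64)
        padded[: d.shape[0]] = d
        sums = padded.reshape(nbins, w).sum(axis=1)
        sizes = np.full(nbins, w, dtype=np.float64)
        if d.shape[0] % w:
            sizes[-1] = d.shape[0] % w
        binned[name] = sums / sizes
    return DepthProfile(depth=depth, bin_width=bin_width, binned=binned)


def depth_threshold_table(
    profile: DepthProfile, thresholds=DEFAULT_DEPTH_THRESHOLDS
) -> list[dict]:
    """Genome-wide base counts and fractions at depth >= each threshold."""
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    glen = profile.genome_length
    rows = []
    for t in thresholds:
        count = int(sum(int((d >= t).sum()) for d in profile.depth.values()))
        rows.append(
            {
                "threshold": int(t),
                "bases": count,
                "fraction": count / glen if glen else 0.0,
            }
        )
    return rows


def feature_mean_depth(profile: DepthProfile, meta: GenomeMeta) -> dict[str, float]:
    """Mean depth over the positions of each feature class."""
    out: dict[str, float] = {}
    for cls in meta.feature_classes():
        total = 0
        length = 0
        for chrom, s, e in meta.features.get(cls, []):
            d = profile.depth.get(chrom)
            if d is None:
                continue
            total += int(d[s - 1 : e].sum())
            length += e - s + 1
        out[cls] = total / length if length else 0.0
    return out


# --- sequencing quality ---------------------------------------------------

def _qual_array(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


@dataclass
class QualityProfile:
    histogram: dict[int, int]
    threshold_table: list[dict]
    mean: float
    median: float
    positional: dict = field(default_factory=dict)


def quality_summary(
    sample: ReadSample, cutoffs=DEFAULT_QUALITY_CUTOFFS
) -> QualityProfile:
    """Global single-base score histogram and threshold fractions.

    Each score (and cutoff) is annotated with its Phred error probability
    p = 10^(-Q/10); Q30 corresponds to p = 0.001.
    """
    counts = np.zeros(MAX_QUALITY_SCORE + 1, dtype=np.int64)
    for rec in sample.records:
        if rec.qual is None or rec.qual == "*":
            continue
        q = _qual_array(rec.qual)
        counts += np.bincount(q, minlength=MAX_QUALITY_SCORE + 1)[
            : MAX_QUALITY_SCORE + 1
        ]
    total = int(counts.sum())
    if total == 0:
        raise MissingQuality("no sampled record carries base qualities")
    scores = np.arange(MAX_QUALITY_SCORE + 1)
    mean = float((scores * counts).sum() / total)
    cum = np.cumsum(counts)
    median = float(int(np.searchsorted(cum, (total + 1) // 2)))
    table = []
    for c in cutoffs:
        ge = int(counts[c:].sum())
        table.append(
            {
                "cutoff": int(c),
                "bases": ge,
                "fraction": ge / total,
                "error_prob": 10 ** (-c / 10),
            }
        )
    histogram = {int(s): int(n) for s, n in enumerate(counts) if n > 0}
    return QualityProfile(
        histogram=histogram, threshold_table=table, mean=mean, median=median
    )


def positional_quality(sample: ReadSample) -> dict:
    """Score histogram, median and mean per read position (1-based).

    Positions are in sequencing orientation; each position's denominator is
    the number of reads long enough to reach it.
    """
    max_len = 0
    quals = []
    for rec in sample.records:
        if rec.qual is None or rec.qual == "*":
            continue
        q = _qual_array(rec.qual)
        if rec.is_reverse:
            q = q[::-1]
        quals.append(q)
        max_len = max(max_len, q.shape[0])
    if not quals:
        raise MissingQuality("no sampled record carries base qualities")
    hist = np.zeros((max_len, MAX_QUALITY_SCORE + 1), dtype=np.int64)
    for q in quals:
        hist[np.arange(q.shape[0]), q] += 1
    n_reads = hist.sum(axis=1)
    scores = np.arange(MAX_QUALITY_SCORE + 1)
    means = (hist * scores).sum(axis=1) / np.maximum(n_reads, 1)
    cum = np.cumsum(hist, axis=1)
    half = (n_reads.reshape(-1, 1) + 1) // 2
    medians = (cum < half).sum(axis=1)
    return {
        "max_length": int(max_len),
        "n_reads": n_reads.astype(int).tolist(),
        "mean": means.astype(float).tolist(),
        "median": medians.astype(int).tolist(),
        "histogram": hist,
    }


# --- mapping --------------------------------------------------------------

_FLAG_CATEGORIES = (
    ("paired", FLAG_PAIRED, True),
    ("properly_paired", FLAG_PROPER_PAIR, True),
    ("unmapped", FLAG_UNMAPPED, True),
    ("mapped", FLAG_UNMAPPED, False),
    ("mate_unmapped", FLAG_MATE_UNMAPPED, True),
    ("reverse_strand", FLAG_REVERSE, True),
    ("secondary", FLAG_SECONDARY, True),
    ("duplicate", FLAG_DUPLICATE, True),
    ("supplementary", FLAG_SUPPLEMENTARY, True),
)


def flag_summary(flags) -> dict[str, int]:
    """Tabulate FLAG-derived categories; categories are not exclusive.

    Accepts an iterable of integer flags, a ReadSample, or a BAM path (in
    which case every record in the file is counted, unfiltered).
    """
    if isinstance(flags, ReadSample):
        flags = [r.flag for r in flags.records]
    elif isinstance(flags, str):
        import pysam

        with pysam.AlignmentFile(flags, "rb") as bam:
            flags = [rec.flag for rec in bam.fetch(until_eof=True)]
    counts = {name: 0 for name, _, _ in _FLAG_CATEGORIES}
    counts["total"] = 0
    for f in flags:
        counts["total"] += 1
        for name, bit, wanted in _FLAG_CATEGORIES:
            if bool(f & bit) == wanted:
                counts[name] += 1
    return counts


def mapq_summary(table: MappingTable, cutoffs=DEFAULT_MAPQ_CUTOFFS) -> dict:
    """Mapping-quality histogram and >=cutoff fractions over the full pass."""
    if table.mapq is None:
        raise ValueError("mapq unavailable; table was built in minimal mode")
    n = table.n_rows
    hist = Counter(int(v) for v in table.mapq)
    rows = []
    for c in cutoffs:
        ge = int((table.mapq >= c).sum())
        rows.append(
            {"cutoff": int(c), "reads": ge, "fraction": ge / n if n else 0.0}
        )
    return {
        "histogram": dict(sorted(hist.items())),
        "threshold_table": rows,
        "mean": float(table.mapq.mean()) if n else 0.0,
    }


def mismatch_summary(sample: ReadSample) -> dict:
    """Base fractions per CIGAR class and reads containing any I/D/S.

    M, I and S are normalized by total read bases; D consumes no read bases
    so it is normalized by total aligned reference span.
    """
    totals = {op: 0 for op in "MIDNSHP=X"}
    read_bases = 0
    ref_bases = 0
    n_reads = 0
    n_with_event = 0
    for rec in sample.records:
        cs = cigar_stats(rec.cigar)
        n_reads += 1
        read_bases += cs.read_len
        ref_bases += cs.ref_span
        for op, v in cs.bases_by_op.items():
            totals[op] += v
        if cs.bases_by_op["I"] or cs.bases_by_op["D"] or cs.bases_by_op["S"]:
            n_with_event += 1
    def frac(x, d):
        return x / d if d else 0.0
    return {
        "bases_by_op": totals,
        "total_read_bases": read_bases,
        "total_ref_span": ref_bases,
        "fractions": {
            "M": frac(totals["M"] + totals["="] + totals["X"], read_bases),
            "I": frac(totals["I"], read_bases),
            "S": frac(totals["S"], read_bases),
            "D": frac(totals["D"], ref_bases),
        },
        "reads_with_indel_or_clip": frac(n_with_event, n_reads),
        "n_reads": n_reads,
    }


def duplication_histogram(table: MappingTable) -> dict[int, int]:
    """Histogram of reads-per-location, locations keyed (chrom, pos, strand)."""
    if table.n_rows == 0:
        return {}
    key = (
        table.chrom.astype(np.int64) << 40
    ) | (table.pos << 1) | table.strand.astype(np.int64)
    _, mult = np.unique(key, return_counts=True)
    ks, ns = np.unique(mult, return_counts=True)
    return {int(k): int(n) for k, n in zip(ks, ns)}


def insert_size_summary(sample: ReadSample, max_abs: int = DEFAULT_MAX_INSERT):
    """Template-length distribution of properly paired reads.

    Uses |TLEN| of properly-paired first-in-pair records with
    0 < |TLEN| <= max_abs; returns None (section absent) when no such
    records exist, e.g. single-end data.
    """
    values = []
    excluded = 0
    for rec in sample.records:
        f = rec.flag
        if not (f & FLAG_PROPER_PAIR and f & FLAG_READ1):
            continue
        t = abs(rec.tlen)
        if t == 0:
            continue
        if t > max_abs:
            excluded += 1
            continue
        values.append(t)
    if not values:
        return None
    arr = np.asarray(values, dtype=np.int64)
    hist = Counter(int(v) for v in arr)
    return {
        "n": int(arr.shape[0]),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sd": float(arr.std(ddof=1)) if arr.shape[0] > 1 else 0.0,
        "histogram": dict(sorted(hist.items())),
        "excluded_over_max": excluded,
        "max_abs": max_abs,
    }


# --- base composition -----------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _oriented_seq(rec) -> str:
    seq = rec.seq.upper()
    return reverse_complement(seq) if rec.is_reverse else seq


def _positional_base_freq(seqs: list[str], window: int, from_end: bool):
    """Per-position called-base frequencies over the first/last `window` positions."""
    counts = np.zeros((window, 4), dtype=np.int64)
    n_count = np.zeros(window, dtype=np.int64)
    idx = {b: i for i, b in enumerate("ACGT")}
    for s in seqs:
        w = min(window, len(s))
        part = s[-w:] if from_end else s[:w]
        if from_end:
            offset = window - w
        else:
            offset = 0
        for i, b in enumerate(part):
            j = idx.get(b)
            if j is None:
                n_count[offset + i] += 1
            else:
                counts[offset + i, j] += 1
    rows = []
    for i in range(window):
        called = counts[i].sum()
        pos = i + 1 if not from_end else -(window - i)
        freq = (
            {b: counts[i, j] / called for b, j in idx.items()}
            if called
            else {b: 0.0 for b in "ACGT"}
        )
        rows.append(
            {"position": pos, "freq": freq, "n_called": int(called),
             "n_ambiguous": int(n_count[i])}
        )
    return rows


def _end_kmer_table(seqs: list[str], k: int, from_end: bool, top: int):
    counter: Counter = Counter()
    for s in seqs:
        if len(s) < k:
            continue
        kmer = s[-k:] if from_end else s[:k]
        if "N" not in kmer:
            counter[kmer] += 1
    total = sum(counter.values())
    table = [
        {"kmer": km, "count": c, "fraction": c / total}
        for km, c in counter.most_common(top)
    ]
    return {"total": total, "top": table}


@dataclass
class BaseCompositionProfile:
    n_base_fraction: float
    fraction_reads_with_n: float
    observed_freq: dict[str, float]
    expected_freq: dict[str, float]
    gc_histogram: dict
    positional_start: list[dict]
    positional_end: list[dict]
    dibase_start: dict[str, float]
    dibase_end: dict[str, float]
    kmer_start: dict
    kmer_end: dict
    total_bases: int
    k: int


def expected_base_freq(meta: GenomeMeta) -> dict[str, float]:
    """Strand-symmetrized genome frequencies: reads sample both strands."""
    f = meta.genome_base_freq
    at = (f["A"] + f["T"]) / 2
    cg = (f["C"] + f["G"]) / 2
    return {"A": at, "C": cg, "G": cg, "T": at}


def base_composition(
    sample: ReadSample,
    meta: GenomeMeta,
    k: int = DEFAULT_KMER_K,
    end_window: int = DEFAULT_END_WINDOW,
    gc_bins: int = 20,
    top_kmers: int = 20,
) -> BaseCompositionProfile:
    """N rate, observed-vs-expected nucleotide frequencies, per-read GC and
    positional/k-mer composition at both read ends."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = []
    for rec in sample.records:
        if rec.seq:
            seqs.append(_oriented_seq(rec))
    if not seqs:
        raise MissingSequence("no sampled record carries a base string")

    total_bases = 0
    n_bases = 0
    reads_with_n = 0
    base_counts = Counter()
    gc_fracs = []
    for s in seqs:
        total_bases += len(s)
        counts = {b: s.count(b) for b in "ACGT"}
        called = sum(counts.values())
        nn = len(s) - called
        n_bases += nn
        if nn:
            reads_with_n += 1
        for b, c in counts.items():
            base_counts[b] += c
        if called:
            gc_fracs.append((counts["G"] + counts["C"]) / called)

    called_total = sum(base_counts.values())
    observed = {
        b: (base_counts[b] / called_total if called_total else 0.0) for b in "ACGT"
    }

    gc_arr = np.asarray(gc_fracs)
    edges = np.linspace(0.0, 1.0, gc_bins + 1)
    gc_hist, _ = np.histogram(gc_arr, bins=edges)
    gc_histogram = {
        "bin_edges": edges.tolist(),
        "counts": gc_hist.astype(int).tolist(),
        "mean": float(gc_arr.mean()) if gc_arr.size else 0.0,
    }

    def dibase(from_end: bool) -> dict[str, float]:
        c: Counter = Counter()
        for s in seqs:
            if len(s) < 2:
                continue
            d = s[-2:] if from_end else s[:2]
            if "N" not in d:
                c[d] += 1
        tot = sum(c.values())
        return {d: n / tot for d, n in sorted(c.items())} if tot else {}

    return BaseCompositionProfile(
        n_base_fraction=n_bases / total_bases if total_bases else 0.0,
        fraction_reads_with_n=reads_with_n / len(seqs),
        observed_freq=observed,
        expected_freq=expected_base_freq(meta),
        gc_histogram=gc_histogram,
        positional_start=_positional_base_freq(seqs, end_window, from_end=False),
        positional_end=_positional_base_freq(seqs, end_window, from_end=True),
        dibase_start=dibase(False),
        dibase_end=dibase(True),
        kmer_start=_end_kmer_table(seqs, k, False, top_kmers),
        kmer_end=_end_kmer_table(seqs, k, True, top_kmers),
        total_bases=total_bases,
        k=k,
    )
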