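"""Naive read-by-read re-implementations, kept independent of the package.

These iterate records with their own minimal CIGAR tokenizer and plain
Python counting, so agreement with the vectorized implementations is a
meaningful check rather than a tautology.
"""

from collections import Counter

import pysam


def tokenize_cigar(cigar):
    """Minimal CIGAR tokenizer: list of (count, op)."""
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((int(num), ch))
            num = ""
    return out


def ref_span_of(cigar):
    if cigar == "*":
        return 0
    return sum(n for n, op in tokenize_cigar(cigar) if op in "MDN=X")


def read_len_of(cigar):
    if cigar == "*":
        return 0
    return sum(n for n, op in tokenize_cigar(cigar) if op in "MIS=X")


def passes_default(flag):
    return not (flag & 0x4 or flag & 0x100 or flag & 0x800)


def naive_pileup(path, chrom_lengths):
    """Increment every covered base, read by read."""
    depth = {c: [0] * l for c, l in chrom_lengths.items()}
    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if not passes_default(rec.flag):
                continue
            chrom = bam.get_reference_name(rec.reference_id)
            pos = rec.reference_start  # 0-based
            for i in range(ref_span_of(rec.cigarstring or "*")):
                depth[chrom][pos + i] += 1
    return depth


def naive_duplication_histogram(path):
    locs = Counter()
    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if not passes_default(rec.flag):
                continue
            locs[(rec.reference_id, rec.reference_start, rec.is_reverse)] += 1
    return dict(Counter(locs.values()))


def naive_flag_summary(path):
    bits = {
        "paired": (0x1, True),
        "properly_paired": (0x2, True),
        "unmapped": (0x4, True),
        "mapped": (0x4, False),
        "mate_unmapped": (0x8, True),
        "reverse_strand": (0x10, True),
        "secondary": (0x100, True),
        "duplicate": (0x400, True),
        "supplementary": (0x800, True),
    }
    counts = {k: 0 for k in bits}
    counts["total"] = 0
    with pysam.AlignmentFile(path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            counts["total"] += 1
            for name, (bit, wanted) in bits.items():
                if bool(rec.flag & bit) == wanted:
                    counts[name] += 1
    return counts


def naive_mismatch_fractions(records):
    """records: iterable of CIGAR strings for the sampled reads."""
    per_op = Counter()
    read_bases = 0
    ref_bases = 0
    n_reads = 0
    n_event = 0
    for cigar in records:
        n_reads += 1
        toks = [] if cigar == "*" else tokenize_cigar(cigar)
        for n, op in toks:
            per_op[op] += n
        read_bases += read_len_of(cigar)
        ref_bases += ref_span_of(cigar)
        if any(op in "IDS" for _, op in toks):
            n_event += 1
    return {
        "M": (per_op["M"] + per_op["="] + per_op["X"]) / read_bases if read_bases else 0.0,
        "I": per_op["I"] / read_bases if read_bases else 0.0,
        "S": per_op["S"] / read_bases if read_bases else 0.0,
        "D": per_op["D"] / ref_bases if ref_bases else 0.0,
        "reads_with_event": n_event / n_reads if n_reads else 0.0,
    }
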