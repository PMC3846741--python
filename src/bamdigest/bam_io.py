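"""BAM ingestion: validation, full-pass mapping locations, seeded subsampling.

Two-track ingestion keeps memory bounded: the full pass retains only
lightweight per-alignment columns (chromosome, position, strand, mapq,
reference span), while per-base statistics are computed from a uniform
random subsample of complete records drawn by single-pass reservoir
selection.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import (
    MissingFile,
    MissingIndex,
    NoReadsPass,
    NotCoordinateSorted,
    TruncatedFile,
)

DEFAULT_SAMPLE_SIZE = 100_000
DEFAULT_SEED = 17

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class ReadFilter:
    """Inclusion filter applied to the full pass and the subsample.

    Defaults exclude unmapped, secondary and supplementary alignments;
    duplicates are kept because duplication is reported, not removed.
    """

    exclude_unmapped: bool = True
    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = False

    def passes(self, flag: int) -> bool:
        if self.exclude_unmapped and flag & FLAG_UNMAPPED:
            return False
        if self.exclude_secondary and flag & FLAG_SECONDARY:
            return False
        if self.exclude_supplementary and flag & FLAG_SUPPLEMENTARY:
            return False
        if self.exclude_duplicates and flag & FLAG_DUPLICATE:
            return False
        return True


DEFAULT_FILTER = ReadFilter()


@dataclass
class BamHeaderInfo:
    path: str
    sort_order: str  # "coordinate" or "other"
    has_index: bool
    references: list[tuple[str, int]]


@dataclass
class MappingTable:
    """Columnar record of every filter-passing alignment.

    ``chrom`` holds reference indices into ``reference_names``; ``pos`` is
    the 1-based leftmost mapped position; ``strand`` is True for reverse.
    ``mapq`` and ``ref_span`` are dropped in minimal mode.
    """

    reference_names: list[str]
    reference_lengths: list[int]
    chrom: np.ndarray
    pos: np.ndarray
    strand: np.ndarray
    mapq: np.ndarray | None
    ref_span: np.ndarray | None
    n_filtered_out: int = 0

    @property
    def n_rows(self) -> int:
        return int(self.chrom.shape[0])

    def strand_fractions(self) -> dict[str, float]:
        n = self.n_rows
        if n == 0:
            return {"forward": 0.0, "reverse": 0.0}
        rev = int(self.strand.sum())
        return {"forward": (n - rev) / n, "reverse": rev / n}


@dataclass
class SampledRead:
    """All SAM fields of one sampled alignment needed downstream."""

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: str
    tlen: int
    seq: str | None
    qual: str | None  # phred+33 encoded

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)


@dataclass
class ReadSample:
    records: list[SampledRead]
    requested_n: int
    total_seen: int
    seed: int
    filter: ReadFilter = field(default_factory=ReadFilter)


def _open_bam(path: str) -> pysam.AlignmentFile:
    if not os.path.exists(path):
        raise MissingFile(f"BAM file not found: {path}")
    try:
        return pysam.AlignmentFile(path, "rb")
    except (OSError, ValueError) as exc:
        raise MissingFile(f"cannot open BAM file {path}: {exc}") from exc


def validate_bam(path: str) -> BamHeaderInfo:
    """Check the two hard input requirements: coordinate sort and an index.

    Raises :class:`NotCoordinateSorted` or :class:`MissingIndex` naming the
    violated requirement; returns header info on success.
    """
    with _open_bam(path) as bam:
        header = bam.header.to_dict()
        sort_order = header.get("HD", {}).get("SO", "unknown")
        if sort_order != "coordinate":
            raise NotCoordinateSorted(
                f"{path}: header declares sort order {sort_order!r}; "
                "a coordinate-sorted BAM is required"
            )
        try:
            has_index = bam.check_index()
        except (ValueError, AttributeError):
            has_index = False
        if not has_index:
            raise MissingIndex(
                f"{path}: no BAI/CSI index found; index the BAM first "
                "(e.g. samtools index)"
            )
        references = list(zip(bam.references, bam.lengths))
    return BamHeaderInfo(
        path=path,
        sort_order="coordinate",
        has_index=True,
        references=references,
    )


def _iter_records(bam: pysam.AlignmentFile):
    try:
        yield from bam.fetch(until_eof=True)
    except OSError as exc:  # htslib reports truncation as an OSError
        raise TruncatedFile(f"{bam.filename.decode()}: {exc}") from exc


def scan_mapping_locations(
    path: str,
    filter: ReadFilter = DEFAULT_FILTER,
    minimal: bool = False,
) -> MappingTable:
    """Full pass: one row per filter-passing alignment.

    ``ref_span`` is the number of reference bases consumed by the CIGAR
    (M/D/N/=/X); with it the pileup is exact rather than approximated by a
    constant read length. ``minimal=True`` drops mapq and ref_span.
    """
    chroms: list[int] = []
    poss: list[int] = []
    strands: list[bool] = []
    mapqs: list[int] = []
    spans: list[int] = []
    n_filtered = 0
    with _open_bam(path) as bam:
        names = list(bam.references)
        lengths = list(bam.lengths)
        for rec in _iter_records(bam):
            if not filter.passes(rec.flag):
                n_filtered += 1
                continue
            chroms.append(rec.reference_id)
            poss.append(rec.reference_start + 1)  # SAM 1-based
            strands.append(rec.is_reverse)
            if not minimal:
                mapqs.append(rec.mapping_quality)
                spans.append(rec.reference_length or 0)
    return MappingTable(
        reference_names=names,
        reference_lengths=lengths,
        chrom=np.asarray(chroms, dtype=np.int32),
        pos=np.asarray(poss, dtype=np.int64),
        strand=np.asarray(strands, dtype=bool),
        mapq=None if minimal else np.asarray(mapqs, dtype=np.int16),
        ref_span=None if minimal else np.asarray(spans, dtype=np.int64),
        n_filtered_out=n_filtered,
    )


def _to_sampled(rec: pysam.AlignedSegment, names: list[str]) -> SampledRead:
    rid = rec.reference_id
    return SampledRead(
        qname=rec.query_name or "",
        flag=rec.flag,
        chrom=names[rid] if rid >= 0 else "*",
        pos=rec.reference_start + 1,
        mapq=rec.mapping_quality,
        cigar=rec.cigarstring or "*",
        tlen=rec.template_length,
        seq=rec.query_sequence,
        qual=rec.qual,
    )


def sample_full_records(
    path: str,
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: int = DEFAULT_SEED,
    filter: ReadFilter = DEFAULT_FILTER,
) -> ReadSample:
    """Uniform sample without replacement of all filter-passing alignments.

    Single-pass reservoir selection (algorithm R): every passing read has
    inclusion probability min(1, n/total_seen), reproducibly for a fixed
    seed regardless of file size.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = random.Random(seed)
    reservoir: list[SampledRead] = []
    total_seen = 0
    with _open_bam(path) as bam:
        names = list(bam.references)
        for rec in _iter_records(bam):
            if not filter.passes(rec.flag):
                continue
            total_seen += 1
            if len(reservoir) < n:
                reservoir.append(_to_sampled(rec, names))
            else:
                j = rng.randrange(total_seen)
                if j < n:
                    reservoir[j] = _to_sampled(rec, names)
    if total_seen == 0:
        raise NoReadsPass(f"{path}: no alignments pass the inclusion filter")
    return ReadSample(
        records=reservoir,
        requested_n=n,
        total_seen=total_seen,
        seed=seed,
        filter=filter,
    )
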