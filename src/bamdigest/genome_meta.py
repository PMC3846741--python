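"""Reference-genome metadata: chromosome lengths, base frequencies, features.

The metadata store is the second required input of a digest run. It is
compiled once from a FASTA (plus optional GFF3/GTF or BED annotation) and
persisted as versioned JSON so it is human-inspectable and diff-able.

Coordinates are 1-based inclusive throughout; BED input is converted on
read. Feature classes are normalized to disjoint sorted interval sets.
Priority when classes overlap: exon > intron > everything else > intergenic.
"""

from __future__ import annotations

import gzip
import json
import os
from bisect import bisect_right
from dataclasses import dataclass, field

from pyfaidx import Fasta

from .errors import (
    AnnotationChromMismatch,
    CorruptStore,
    EmptyFasta,
    UnknownChromosome,
    VersionMismatch,
)

SCHEMA_VERSION = 1
_CALLED = "ACGT"
_PRIORITY = ("exon", "intron")  # remaining classes follow alphabetically

Interval = tuple[str, int, int]  # chrom, start, end (1-based inclusive)


@dataclass
class GenomeMeta:
    chrom_lengths: dict[str, int]
    chrom_base_freq: dict[str, dict[str, float]]
    chrom_ambiguous: dict[str, int]
    genome_base_freq: dict[str, float]
    genome_ambiguous: int
    features: dict[str, list[Interval]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    version: int = SCHEMA_VERSION

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def feature_classes(self) -> list[str]:
        """Feature class names in priority order (intergenic last)."""
        known = [c for c in _PRIORITY if c in self.features]
        extra = sorted(
            c for c in self.features if c not in _PRIORITY and c != "intergenic"
        )
        tail = ["intergenic"] if "intergenic" in self.features else []
        return known + extra + tail


# --- interval primitives --------------------------------------------------

def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """a minus b; both merged and sorted."""
    out = []
    bi = 0
    for s, e in a:
        cur = s
        while bi < len(b) and b[bi][1] < cur:
            bi += 1
        j = bi
        while j < len(b) and b[j][0] <= e:
            bs, be = b[j]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            j += 1
        if cur <= e:
            out.append((cur, e))
    return out


def complement_intervals(
    ivs: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    return subtract_intervals([(1, length)], ivs)


# --- compilation ----------------------------------------------------------

def _base_counts(seq: str) -> dict[str, int]:
    up = seq.upper()
    counts = {b: up.count(b) for b in _CALLED}
    counts["ambiguous"] = len(up) - sum(counts.values())
    return counts


def _freq(counts: dict[str, int]) -> dict[str, float]:
    called = sum(counts[b] for b in _CALLED)
    if called == 0:
        return {b: 0.0 for b in _CALLED}
    return {b: counts[b] / called for b in _CALLED}


def _parse_bed(path, chrom_lengths) -> dict[str, dict[str, list]]:
    """BED: 0-based half-open; name column (4th) selects the feature class."""
    per_class: dict[str, dict[str, list]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]) + 1, int(parts[2])
            if chrom not in chrom_lengths:
                raise AnnotationChromMismatch(
                    f"annotation names {chrom!r}, absent from FASTA"
                )
            cls = parts[3] if len(parts) > 3 and parts[3] else "feature"
            per_class.setdefault(cls, {}).setdefault(chrom, []).append((start, end))
    return per_class


def _parse_gff(path, chrom_lengths) -> dict[str, dict[str, list]]:
    """GFF3/GTF: feature-type column selects exon/gene; 1-based inclusive."""
    per_class: dict[str, dict[str, list]] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, ftype = parts[0], parts[2].lower()
            if chrom not in chrom_lengths:
                raise AnnotationChromMismatch(
                    f"annotation names {chrom!r}, absent from FASTA"
                )
            if ftype in ("exon", "gene"):
                start, end = int(parts[3]), int(parts[4])
                per_class.setdefault(ftype, {}).setdefault(chrom, []).append(
                    (start, end)
                )
    return per_class


def _flatten(per_chrom: dict[str, list]) -> list[Interval]:
    out: list[Interval] = []
    for chrom in sorted(per_chrom):
        for s, e in merge_intervals(per_chrom[chrom]):
            out.append((chrom, s, e))
    return out


def compile_genome_meta(
    fasta: str,
    annotation: str | None = None,
    build_label: str = "",
) -> GenomeMeta:
    """Compile the metadata store from a FASTA and optional annotation.

    Base frequencies are case-insensitive over called bases (A/C/G/T); N and
    other IUPAC ambiguity codes are pooled in a separate count. With a
    GFF3/GTF annotation, exons are merged, introns derived as gene span
    minus exons, and intergenic as the complement of gene spans. With BED,
    named classes pass through and intergenic is the complement of their
    union.
    """
    if not os.path.exists(fasta):
        raise EmptyFasta(f"FASTA not found: {fasta}")
    try:
        fa = Fasta(fasta, rebuild=True, build_index=True)
    except Exception as exc:
        raise EmptyFasta(f"cannot read FASTA {fasta}: {exc}") from exc
    names = list(fa.keys())
    if not names:
        raise EmptyFasta(f"{fasta}: no sequences")

    chrom_lengths: dict[str, int] = {}
    chrom_base_freq: dict[str, dict[str, float]] = {}
    chrom_ambiguous: dict[str, int] = {}
    totals = {b: 0 for b in _CALLED}
    totals["ambiguous"] = 0
    for name in names:
        seq = str(fa[name])
        counts = _base_counts(seq)
        chrom_lengths[name] = len(seq)
        chrom_base_freq[name] = _freq(counts)
        chrom_ambiguous[name] = counts["ambiguous"]
        for k in totals:
            totals[k] += counts[k]
    if sum(chrom_lengths.values()) == 0:
        raise EmptyFasta(f"{fasta}: sequences are all empty")

    features: dict[str, list[Interval]] = {}
    if annotation is not None:
        lower = str(annotation).lower()
        if lower.endswith((".bed", ".bed.gz")):
            per_class = _parse_bed(annotation, chrom_lengths)
            features = {cls: _flatten(d) for cls, d in per_class.items()}
            union: dict[str, list] = {}
            for d in per_class.values():
                for chrom, ivs in d.items():
                    union.setdefault(chrom, []).extend(ivs)
            features["intergenic"] = _flatten(
                {
                    c: complement_intervals(
                        merge_intervals(union.get(c, [])), chrom_lengths[c]
                    )
                    for c in chrom_lengths
                }
            )
        else:
            per_class = _parse_gff(annotation, chrom_lengths)
            exons = {c: merge_intervals(v) for c, v in per_class.get("exon", {}).items()}
            genes = {c: merge_intervals(v) for c, v in per_class.get("gene", {}).items()}
            features["exon"] = _flatten(exons)
            if genes:
                introns = {
                    c: subtract_intervals(genes[c], exons.get(c, []))
                    for c in genes
                }
                features["intron"] = _flatten(introns)
                features["intergenic"] = _flatten(
                    {
                        c: complement_intervals(genes.get(c, []), chrom_lengths[c])
                        for c in chrom_lengths
                    }
                )
            else:
                features["intergenic"] = _flatten(
                    {
                        c: complement_intervals(exons.get(c, []), chrom_lengths[c])
                        for c in chrom_lengths
                    }
                )

    return GenomeMeta(
        chrom_lengths=chrom_lengths,
        chrom_base_freq=chrom_base_freq,
        chrom_ambiguous=chrom_ambiguous,
        genome_base_freq=_freq(totals),
        genome_ambiguous=totals["ambiguous"],
        features=features,
        provenance={
            "fasta": os.path.basename(fasta),
            "annotation": os.path.basename(annotation) if annotation else None,
            "build": build_label,
        },
    )


# --- persistence ----------------------------------------------------------

def save_genome_meta(meta: GenomeMeta, path: str) -> None:
    doc = {
        "format": "bamdigest-genome-meta",
        "version": meta.version,
        "chrom_lengths": meta.chrom_lengths,
        "chrom_base_freq": meta.chrom_base_freq,
        "chrom_ambiguous": meta.chrom_ambiguous,
        "genome_base_freq": meta.genome_base_freq,
        "genome_ambiguous": meta.genome_ambiguous,
        "features": {
            cls: [[c, s, e] for c, s, e in ivs] for cls, ivs in meta.features.items()
        },
        "provenance": meta.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_genome_meta(path: str) -> GenomeMeta:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise CorruptStore(f"cannot read genome metadata {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "bamdigest-genome-meta":
        raise CorruptStore(f"{path}: not a genome metadata store")
    if doc.get("version", 0) > SCHEMA_VERSION:
        raise VersionMismatch(
            f"{path}: store version {doc['version']} is newer than "
            f"supported version {SCHEMA_VERSION}"
        )
    try:
        return GenomeMeta(
            chrom_lengths=doc["chrom_lengths"],
            chrom_base_freq=doc["chrom_base_freq"],
            chrom_ambiguous=doc["chrom_ambiguous"],
            genome_base_freq=doc["genome_base_freq"],
            genome_ambiguous=doc["genome_ambiguous"],
            features={
                cls: [(c, int(s), int(e)) for c, s, e in ivs]
                for cls, ivs in doc["features"].items()
            },
            provenance=doc.get("provenance", {}),
            version=doc["version"],
        )
    except KeyError as exc:
        raise CorruptStore(f"{path}: missing field {exc}") from exc


# --- queries --------------------------------------------------------------

def _chrom_starts_ends(meta: GenomeMeta, cls: str, chrom: str):
    ivs = [(s, e) for c, s, e in meta.features.get(cls, []) if c == chrom]
    return [s for s, _ in ivs], [e for _, e in ivs]


def feature_of(meta: GenomeMeta, chrom: str, pos: int) -> str:
    """Highest-priority feature class containing pos; 'intergenic' if none."""
    if chrom not in meta.chrom_lengths:
        raise UnknownChromosome(chrom)
    for cls in meta.feature_classes():
        if cls == "intergenic":
            continue
        starts, ends = _chrom_starts_ends(meta, cls, chrom)
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos <= ends[i]:
            return cls
    return "intergenic"
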