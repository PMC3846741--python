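"""Assemble the results bundle and serialize it.

The bundle is the single point of contact between the statistics layer and
the report template: it is plain JSON-native data, losslessly serializable,
and the renderer never touches the BAM. Identical inputs, config and seed
produce byte-identical serialized bundles (the provenance timestamp is the
BAM file's mtime, not wall-clock time).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone

from . import __version__
from .alerts import DEFAULT_RULES, evaluate_alerts
from .bam_io import (
    DEFAULT_FILTER,
    DEFAULT_SAMPLE_SIZE,
    DEFAULT_SEED,
    ReadFilter,
    sample_full_records,
    scan_mapping_locations,
    validate_bam,
)
from .errors import CorruptResults
from .genome_meta import GenomeMeta
from . import stats_core as sc

SECTION_ORDER = (
    "depth_landscape",
    "summary",
    "coverage",
    "quality",
    "mapping",
    "composition",
    "alerts",
)


@dataclass
class QCConfig:
    sample_size: int = DEFAULT_SAMPLE_SIZE
    seed: int = DEFAULT_SEED
    depth_thresholds: tuple = sc.DEFAULT_DEPTH_THRESHOLDS
    quality_cutoffs: tuple = sc.DEFAULT_QUALITY_CUTOFFS
    mapq_cutoffs: tuple = sc.DEFAULT_MAPQ_CUTOFFS
    max_insert: int = sc.DEFAULT_MAX_INSERT
    kmer_k: int = sc.DEFAULT_KMER_K
    end_window: int = sc.DEFAULT_END_WINDOW
    filter: ReadFilter = field(default_factory=ReadFilter)
    rules: tuple = DEFAULT_RULES


@dataclass
class ResultsBundle:
    """Structured container of every computed statistic, JSON-native."""

    sections: dict

    def __getitem__(self, key):
        return self.sections[key]

    def to_dict(self) -> dict:
        return {"format": "bamdigest-results", "version": 1, **self.sections}

    @classmethod
    def from_dict(cls, doc: dict) -> "ResultsBundle":
        if not isinstance(doc, dict) or doc.get("format") != "bamdigest-results":
            raise CorruptResults("not a bamdigest results document")
        sections = {k: v for k, v in doc.items() if k not in ("format", "version")}
        return cls(sections=sections)


def _jsonify(obj):
    """Coerce dataclasses / numpy scalars / arrays to JSON-native values."""
    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def build_results(
    bam_path: str, meta: GenomeMeta, config: QCConfig | None = None
) -> ResultsBundle:
    """Orchestrate ingestion -> statistics -> alerts into one bundle."""
    config = config or QCConfig()
    info = validate_bam(bam_path)
    table = scan_mapping_locations(bam_path, filter=config.filter)
    flag_counts = sc.flag_summary(bam_path)

    profile = sc.compute_depth(table, meta)
    depth_table = sc.depth_threshold_table(profile, config.depth_thresholds)
    feature_means = sc.feature_mean_depth(profile, meta)
    chrom_means = profile.per_chromosome_mean()

    if table.n_rows > 0:
        sample = sample_full_records(
            bam_path, n=config.sample_size, seed=config.seed, filter=config.filter
        )
        quality = sc.quality_summary(sample, config.quality_cutoffs)
        positional = sc.positional_quality(sample)
        mismatch = sc.mismatch_summary(sample)
        insert = sc.insert_size_summary(sample, config.max_insert)
        composition = sc.base_composition(
            sample, meta, k=config.kmer_k, end_window=config.end_window
        )
        mean_read_length = (
            mismatch["total_read_bases"] / mismatch["n_reads"]
            if mismatch["n_reads"]
            else 0.0
        )
        sample_meta = {
            "requested_n": sample.requested_n,
            "actual_n": len(sample.records),
            "total_seen": sample.total_seen,
            "seed": sample.seed,
        }
    else:
        sample = None
        quality = positional = mismatch = insert = composition = None
        mean_read_length = 0.0
        sample_meta = {"requested_n": config.sample_size, "actual_n": 0,
                       "total_seen": 0, "seed": config.seed}

    mapq = sc.mapq_summary(table, config.mapq_cutoffs) if table.n_rows else None
    dup_hist = sc.duplication_histogram(table)
    strand = table.strand_fractions()
    max_strand = max(strand.values()) if table.n_rows else 0.0

    mtime = os.path.getmtime(bam_path)
    sections = {
        "provenance": {
            "bam": os.path.abspath(bam_path),
            "bam_mtime": datetime.fromtimestamp(mtime, tz=timezone.utc).isoformat(),
            "build": meta.provenance.get("build", ""),
            "tool_version": __version__,
            "seed": config.seed,
            "sample_size": config.sample_size,
            "references": [[n, l] for n, l in info.references],
        },
        "summary": {
            "total_reads": table.n_rows,
            "filtered_out": table.n_filtered_out,
            "estimated_total_bases": int(round(mean_read_length * table.n_rows)),
            "mean_read_length": mean_read_length,
            "mean_quality": quality.mean if quality else None,
            "mean_depth": profile.mean_depth(),
            "genome_length": profile.genome_length,
        },
        "depth_landscape": {
            "bin_width": profile.bin_width,
            "binned_mean_depth": {c: b.tolist() for c, b in profile.binned.items()},
        },
        "coverage": {
            "threshold_table": depth_table,
            "feature_mean_depth": feature_means,
            "chromosome_mean_depth": chrom_means,
            "total_aligned_bases": profile.total,
        },
        "quality": {
            "global": None if quality is None else {
                "histogram": {str(k): v for k, v in quality.histogram.items()},
                "threshold_table": quality.threshold_table,
                "mean": quality.mean,
                "median": quality.median,
            },
            "positional": None if positional is None else {
                "max_length": positional["max_length"],
                "n_reads": positional["n_reads"],
                "mean": positional["mean"],
                "median": positional["median"],
                "histogram": positional["histogram"].tolist(),
            },
        },
        "mapping": {
            "flag_counts": flag_counts,
            "mapq": mapq,
            "mismatch": mismatch,
            "duplication_histogram": {str(k): v for k, v in dup_hist.items()},
            "insert_size": insert,  # None marks the section absent (single-end)
            "strand_fractions": strand,
            "max_strand_fraction": max_strand,
            "sample": sample_meta,
        },
        "composition": None if composition is None else {
            "n_base_fraction": composition.n_base_fraction,
            "fraction_reads_with_n": composition.fraction_reads_with_n,
            "observed_freq": composition.observed_freq,
            "expected_freq": composition.expected_freq,
            "gc_histogram": composition.gc_histogram,
            "positional_start": composition.positional_start,
            "positional_end": composition.positional_end,
            "dibase_start": composition.dibase_start,
            "dibase_end": composition.dibase_end,
            "kmer_start": composition.kmer_start,
            "kmer_end": composition.kmer_end,
            "total_bases": composition.total_bases,
            "k": composition.k,
        },
    }
    sections = _jsonify(sections)
    bundle = ResultsBundle(sections=sections)
    if sections["composition"] is None:
        bundle.sections["alerts"] = []
    else:
        found = evaluate_alerts(bundle, config.rules)
        bundle.sections["alerts"] = [_jsonify(a) for a in found]
    return bundle


def serialize_results(results: ResultsBundle, path: str) -> None:
    with open(path, "w") as fh:
        # insertion order is deterministic; keep it so a loaded bundle
        # renders byte-identically to a fresh one
        json.dump(results.to_dict(), fh, indent=1)


def load_results(path: str) -> ResultsBundle:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise CorruptResults(f"cannot read results {path}: {exc}") from exc
    return ResultsBundle.from_dict(doc)
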