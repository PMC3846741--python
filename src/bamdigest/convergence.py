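"""Resampling experiment: how well does a read subsample estimate globals?

One full pass collects the per-read ingredients of each summary statistic;
subsamples are then index sets drawn without replacement, which is
distribution-identical to re-sampling records and keeps repeated resampling
cheap. Rep r uses the derived seed (master seed + r), so runs are fully
deterministic and sizes within one rep share a generator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .bam_io import (
    DEFAULT_FILTER,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    ReadFilter,
    _iter_records,
    _open_bam,
)
from .errors import NoReadsPass, SizeExceedsPopulation
from .stats_core import DEFAULT_MAX_INSERT, _qual_array

DEFAULT_SIZES = (100, 1_000, 10_000, 100_000)
DEFAULT_REPS = 100
DEFAULT_STATISTICS = (
    "mean_insert_size",
    "mean_base_quality",
    "mean_mapq",
    "n_fraction",
    "gc_fraction",
    "mean_read_length",
)


@dataclass
class ConvergenceResult:
    statistics: list[str]
    sizes: list[int]
    reps: int
    seed: int
    total_reads: int
    # estimates[stat][size_index] -> list of `reps` values (NaN if undefined)
    estimates: dict[str, list[list[float]]]
    global_values: dict[str, float]
    summary: dict[str, list[dict]] = field(default_factory=dict)

    def to_rows(self):
        for stat in self.statistics:
            for si, size in enumerate(self.sizes):
                for rep, v in enumerate(self.estimates[stat][si]):
                    yield {
                        "statistic": stat,
                        "size": size,
                        "rep": rep,
                        "estimate": v,
                    }

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["statistic", "size", "rep", "estimate"])
            w.writeheader()
            for row in self.to_rows():
                w.writerow(row)


@dataclass
class _PerRead:
    """Per-read ingredient arrays for all supported statistics."""

    read_len: np.ndarray
    qual_sum: np.ndarray
    qual_n: np.ndarray
    mapq: np.ndarray
    n_count: np.ndarray
    gc_count: np.ndarray
    called_count: np.ndarray
    insert: np.ndarray  # |TLEN| for eligible records, NaN otherwise

    @property
    def n(self) -> int:
        return int(self.read_len.shape[0])


def _collect(path: str, filt: ReadFilter, max_insert: int) -> _PerRead:
    read_len, qual_sum, qual_n = [], [], []
    mapq, n_count, gc_count, called, insert = [], [], [], [], []
    with _open_bam(path) as bam:
        for rec in _iter_records(bam):
            if not filt.passes(rec.flag):
                continue
            seq = (rec.query_sequence or "").upper()
            read_len.append(len(seq))
            nn = seq.count("N")
            n_count.append(nn)
            gc = seq.count("G") + seq.count("C")
            gc_count.append(gc)
            called.append(len(seq) - nn)
            q = rec.qual
            if q and q != "*":
                arr = _qual_array(q)
                qual_sum.append(int(arr.sum()))
                qual_n.append(arr.shape[0])
            else:
                qual_sum.append(0)
                qual_n.append(0)
            mapq.append(rec.mapping_quality)
            t = abs(rec.template_length)
            ok = (
                rec.flag & FLAG_PROPER_PAIR
                and rec.flag & FLAG_READ1
                and 0 < t <= max_insert
            )
            insert.append(float(t) if ok else np.nan)
    if not read_len:
        raise NoReadsPass(f"{path}: no alignments pass the inclusion filter")
    return _PerRead(
        read_len=np.asarray(read_len, dtype=np.float64),
        qual_sum=np.asarray(qual_sum, dtype=np.float64),
        qual_n=np.asarray(qual_n, dtype=np.float64),
        mapq=np.asarray(mapq, dtype=np.float64),
        n_count=np.asarray(n_count, dtype=np.float64),
        gc_count=np.asarray(gc_count, dtype=np.float64),
        called_count=np.asarray(called, dtype=np.float64),
        insert=np.asarray(insert, dtype=np.float64),
    )


def _evaluate(per: _PerRead, idx) -> dict[str, float]:
    rl = per.read_len[idx]
    qs, qn = per.qual_sum[idx], per.qual_n[idx]
    ins = per.insert[idx]
    ins = ins[~np.isnan(ins)]
    called = per.called_count[idx].sum()
    total = rl.sum()
    return {
        "mean_insert_size": float(ins.mean()) if ins.size else float("nan"),
        "mean_base_quality": float(qs.sum() / qn.sum()) if qn.sum() else float("nan"),
        "mean_mapq": float(per.mapq[idx].mean()),
        "n_fraction": float(per.n_count[idx].sum() / total) if total else float("nan"),
        "gc_fraction": float(per.gc_count[idx].sum() / called) if called else float("nan"),
        "mean_read_length": float(rl.mean()),
    }


def run_convergence(
    path: str,
    sizes=DEFAULT_SIZES,
    reps: int = DEFAULT_REPS,
    statistics=DEFAULT_STATISTICS,
    seed: int = 17,
    filter: ReadFilter = DEFAULT_FILTER,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> ConvergenceResult:
    """Repeatedly estimate each statistic from subsamples of each size.

    A subsample of the full population reproduces every global value
    exactly (sampling without replacement). Raises SizeExceedsPopulation
    when a requested size is larger than the passing-read count.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    sizes = sorted(int(s) for s in sizes)
    per = _collect(path, filter, max_insert)
    n = per.n
    for s in sizes:
        if s > n:
            raise SizeExceedsPopulation(
                f"requested subsample of {s} reads but only {n} pass the filter"
            )
    global_values = _evaluate(per, np.arange(n))
    stats = list(statistics)
    estimates = {st: [[] for _ in sizes] for st in stats}
    for r in range(reps):
        rng = np.random.default_rng(seed + r)
        for si, size in enumerate(sizes):
            idx = rng.choice(n, size=size, replace=False)
            vals = _evaluate(per, idx)
            for st in stats:
                estimates[st][si].append(vals[st])
    summary = {}
    for st in stats:
        rows = []
        for si, size in enumerate(sizes):
            arr = np.asarray(estimates[st][si])
            finite = arr[~np.isnan(arr)]
            if finite.size:
                q1, q3 = np.percentile(finite, [25, 75])
                rows.append(
                    {
                        "size": size,
                        "min": float(finite.min()),
                        "max": float(finite.max()),
                        "iqr": float(q3 - q1),
                        "mean": float(finite.mean()),
                    }
                )
            else:
                rows.append(
                    {"size": size, "min": float("nan"), "max": float("nan"),
                     "iqr": float("nan"), "mean": float("nan")}
                )
        summary[st] = rows
    return ConvergenceResult(
        statistics=stats,
        sizes=sizes,
        reps=reps,
        seed=seed,
        total_reads=n,
        estimates=estimates,
        global_values={st: global_values[st] for st in stats},
        summary=summary,
    )
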