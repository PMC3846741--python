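"""Render a results bundle into a standalone HTML (optionally PDF) report.

A pure function of the bundle: no BAM or genome access, and byte-identical
output for identical bundles (figures are PNG-encoded without timestamps;
the report date comes from bundle provenance). Seven sections in fixed
order, linked from a table of contents.
"""

from __future__ import annotations

import base64
import html
import io

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .errors import RendererUnavailable
from .reporting import ResultsBundle

_SECTION_TITLES = (
    ("depth_landscape", "Sequencing depth landscape"),
    ("summary", "Summary statistics"),
    ("coverage", "Read count and sequencing coverage"),
    ("quality", "Sequencing quality"),
    ("mapping", "Reference genome mapping"),
    ("composition", "Base frequency"),
    ("alerts", "Alerts"),
)

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 60em; color: #222; }
h1 { border-bottom: 2px solid #345; }
h2 { border-bottom: 1px solid #abc; margin-top: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #ccc; padding: 0.3em 0.8em; text-align: right; }
th { background: #eef; }
td.l, th.l { text-align: left; }
.alert { background: #fee; border: 1px solid #c66; padding: 0.6em 1em; margin: 0.5em 0; }
.ok { background: #efe; border: 1px solid #6a6; padding: 0.6em 1em; }
img { max-width: 100%; }
.absent { color: #777; font-style: italic; }
"""


def _fig_to_img(fig) -> str:
    buf = io.BytesIO()
    # metadata Date=None keeps the PNG byte-stable across renders
    fig.savefig(buf, format="png", dpi=90, metadata={"Date": None})
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img src="data:image/png;base64,{data}"/>'


def _table(headers, rows, left_cols=1) -> str:
    head = "".join(
        f'<th class="l">{h}</th>' if i < left_cols else f"<th>{h}</th>"
        for i, h in enumerate(headers)
    )
    body = []
    for row in rows:
        cells = "".join(
            f'<td class="l">{html.escape(str(c))}</td>'
            if i < left_cols
            else f"<td>{html.escape(str(c))}</td>"
            for i, c in enumerate(row)
        )
        body.append(f"<tr>{cells}</tr>")
    return f"<table><tr>{head}</tr>{''.join(body)}</table>"


def _fmt(x, digits=3):
    if x is None:
        return "—"
    if isinstance(x, float):
        return f"{x:.{digits}f}"
    return str(x)


def _pct(x, digits=2):
    return "—" if x is None else f"{100 * x:.{digits}f}%"


# --- figures --------------------------------------------------------------

def _fig_landscape(section) -> str:
    chroms = list(section["binned_mean_depth"])
    if not chroms:
        return '<p class="absent">No chromosomes.</p>'
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.2 * len(chroms) + 0.8), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        d = np.asarray(section["binned_mean_depth"][chrom])
        w = section["bin_width"][chrom]
        x = (np.arange(d.shape[0]) + 0.5) * w / 1e3
        ax.fill_between(x, d, color="#69c", step="mid")
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
        ax.tick_params(labelsize=7)
    axes[-1, 0].set_xlabel("position (kb)")
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_bar(labels, values, ylabel, color="#69c") -> str:
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(range(len(values)), values, color=color)
    ax.set_xticks(range(len(labels)))
    ax.set_xticklabels([str(l) for l in labels], fontsize=8)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_quality_hist(qual) -> str:
    scores = sorted(int(s) for s in qual["histogram"])
    counts = [qual["histogram"][str(s)] for s in scores]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(scores, counts, color="#485")
    ax.set_xlabel("Phred quality score")
    ax.set_ylabel("base count")
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_positional_quality(pos) -> str:
    hist = np.asarray(pos["histogram"], dtype=float)  # positions x scores
    if hist.size == 0:
        return ""
    col_tot = hist.sum(axis=1, keepdims=True)
    frac = hist / np.maximum(col_tot, 1)
    qmax = max(int(np.nonzero(hist.sum(axis=0))[0].max()) + 2, 42)
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.imshow(
        frac[:, :qmax].T, origin="lower", aspect="auto", cmap="viridis",
        extent=(0.5, hist.shape[0] + 0.5, -0.5, qmax - 0.5),
    )
    x = np.arange(1, hist.shape[0] + 1)
    ax.plot(x, pos["median"], color="#48f", lw=1.5, label="median")
    ax.plot(x, pos["mean"], color="black", ls="--", lw=1.2, label="mean")
    ax.set_xlabel("read position")
    ax.set_ylabel("quality score")
    ax.legend(fontsize=8, loc="lower left")
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_histogram_dict(hist: dict, xlabel, ylabel, log=False, color="#69c") -> str:
    ks = sorted(int(k) for k in hist)
    vs = [hist[str(k)] for k in ks]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(ks, vs, color=color, width=max(1, (max(ks) - min(ks)) // 200 or 1))
    if log:
        ax.set_yscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_obs_exp(comp) -> str:
    bases = ["A", "C", "G", "T"]
    obs = [comp["observed_freq"][b] for b in bases]
    exp = [comp["expected_freq"][b] for b in bases]
    x = np.arange(4)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(x - 0.2, exp, width=0.4, label="expected", color="#abc")
    ax.bar(x + 0.2, obs, width=0.4, label="observed", color="#345")
    ax.set_xticks(x)
    ax.set_xticklabels(bases)
    ax.set_ylabel("frequency")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_gc(comp) -> str:
    gch = comp["gc_histogram"]
    edges = np.asarray(gch["bin_edges"])
    mids = 100 * (edges[:-1] + edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(mids, gch["counts"], width=100 * (edges[1] - edges[0]) * 0.9, color="#586")
    ax.set_xlabel("per-read GC (%)")
    ax.set_ylabel("read count")
    fig.tight_layout()
    return _fig_to_img(fig)


def _fig_positional_composition(rows, title) -> str:
    fig, ax = plt.subplots(figsize=(6, 3))
    xs = [r["position"] for r in rows]
    for b, color in zip("ACGT", ("#2a2", "#26c", "#c80", "#c22")):
        ax.plot(xs, [r["freq"][b] for r in rows], marker="o", ms=3, label=b, color=color)
    ax.set_xlabel("read position")
    ax.set_ylabel("frequency")
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=8, ncol=4)
    fig.tight_layout()
    return _fig_to_img(fig)


# --- sections -------------------------------------------------------------

def _sec_depth_landscape(b) -> str:
    return _fig_landscape(b["depth_landscape"])


def _sec_summary(b) -> str:
    s = b["summary"]
    rows = [
        ("Total counted reads", f"{s['total_reads']:,}"),
        ("Alignments excluded by filter", f"{s['filtered_out']:,}"),
        ("Mean read length", _fmt(s["mean_read_length"], 2)),
        ("Estimated total bases", f"{s['estimated_total_bases']:,}"),
        ("Mean base quality (sampled)", _fmt(s["mean_quality"], 2)),
        ("Mean sequencing depth", _fmt(s["mean_depth"], 3)),
        ("Genome length", f"{s['genome_length']:,}"),
    ]
    return _table(["Statistic", "Value"], rows)


def _sec_coverage(b) -> str:
    c = b["coverage"]
    parts = []
    parts.append("<h3>Depth thresholds</h3>")
    parts.append(
        _table(
            ["Depth ≥", "Bases", "Fraction of genome"],
            [
                (r["threshold"], f"{r['bases']:,}", _pct(r["fraction"]))
                for r in c["threshold_table"]
            ],
        )
    )
    parts.append(
        _fig_bar(
            [r["threshold"] for r in c["threshold_table"]],
            [100 * r["fraction"] for r in c["threshold_table"]],
            "% of genome at ≥ depth",
        )
    )
    if c["feature_mean_depth"]:
        parts.append("<h3>Mean depth by genomic feature</h3>")
        parts.append(
            _table(
                ["Feature", "Mean depth"],
                [(k, _fmt(v)) for k, v in c["feature_mean_depth"].items()],
            )
        )
    parts.append("<h3>Mean depth by chromosome</h3>")
    parts.append(
        _table(
            ["Chromosome", "Mean depth"],
            [(k, _fmt(v)) for k, v in c["chromosome_mean_depth"].items()],
        )
    )
    return "".join(parts)


def _sec_quality(b) -> str:
    q = b["quality"]
    if q["global"] is None:
        return '<p class="absent">No base qualities available.</p>'
    g = q["global"]
    parts = ["<h3>Global score distribution</h3>"]
    parts.append(
        _table(
            ["Quality ≥", "Bases", "Fraction", "Error probability"],
            [
                (r["cutoff"], f"{r['bases']:,}", _pct(r["fraction"]),
                 f"{r['error_prob']:.4g}")
                for r in g["threshold_table"]
            ],
        )
    )
    parts.append(_fig_quality_hist(g))
    if q["positional"] is not None:
        parts.append("<h3>Quality by read position</h3>")
        parts.append(_fig_positional_quality(q["positional"]))
    return "".join(parts)


def _sec_mapping(b) -> str:
    m = b["mapping"]
    parts = ["<h3>FLAG categories</h3>"]
    fc = m["flag_counts"]
    parts.append(
        _table(["Category", "Reads"], [(k, f"{v:,}") for k, v in fc.items()])
    )
    if m["mapq"] is not None:
        parts.append("<h3>Mapping quality</h3>")
        parts.append(
            _table(
                ["MAPQ ≥", "Reads", "Fraction"],
                [
                    (r["cutoff"], f"{r['reads']:,}", _pct(r["fraction"]))
                    for r in m["mapq"]["threshold_table"]
                ],
            )
        )
    if m["mismatch"] is not None:
        mm = m["mismatch"]
        parts.append("<h3>Base-level alignment classes (sampled)</h3>")
        parts.append(
            _table(
                ["Class", "Fraction"],
                [
                    ("M (aligned)", _pct(mm["fractions"]["M"], 3)),
                    ("I (inserted, of read bases)", _pct(mm["fractions"]["I"], 3)),
                    ("S (soft-clipped, of read bases)", _pct(mm["fractions"]["S"], 3)),
                    ("D (deleted, of reference span)", _pct(mm["fractions"]["D"], 3)),
                    ("Reads with any I/D/S", _pct(mm["reads_with_indel_or_clip"], 2)),
                ],
            )
        )
    parts.append("<h3>Duplicated mapping locations</h3>")
    if m["duplication_histogram"]:
        parts.append(
            _fig_histogram_dict(
                m["duplication_histogram"],
                "reads sharing one location", "locations", log=True, color="#965",
            )
        )
    parts.append("<h3>Insert size</h3>")
    if m["insert_size"] is None:
        parts.append(
            '<p class="absent">Not applicable: no properly paired reads '
            "(single-end data).</p>"
        )
    else:
        ins = m["insert_size"]
        parts.append(
            _table(
                ["n", "Mean", "Median", "SD", "Excluded > max"],
                [
                    (f"{ins['n']:,}", _fmt(ins["mean"], 1), _fmt(ins["median"], 1),
                     _fmt(ins["sd"], 1), ins["excluded_over_max"])
                ],
            )
        )
        parts.append(
            _fig_histogram_dict(
                ins["histogram"], "insert size (bp)", "pairs", color="#579"
            )
        )
    parts.append("<h3>Strand</h3>")
    sf = m["strand_fractions"]
    parts.append(
        _table(
            ["Strand", "Fraction"],
            [("forward", _pct(sf["forward"])), ("reverse", _pct(sf["reverse"]))],
        )
    )
    return "".join(parts)


def _sec_composition(b) -> str:
    comp = b["composition"]
    if comp is None:
        return '<p class="absent">No sequences available.</p>'
    parts = []
    parts.append(
        _table(
            ["Statistic", "Value"],
            [
                ("N base fraction", _pct(comp["n_base_fraction"], 3)),
                ("Reads containing any N", _pct(comp["fraction_reads_with_n"], 2)),
                ("Mean per-read GC", _pct(comp["gc_histogram"]["mean"], 2)),
            ],
        )
    )
    parts.append("<h3>Observed vs expected base frequency</h3>")
    parts.append(_fig_obs_exp(comp))
    parts.append("<h3>Per-read GC</h3>")
    parts.append(_fig_gc(comp))
    parts.append("<h3>Positional composition</h3>")
    parts.append(_fig_positional_composition(comp["positional_start"], "read start"))
    parts.append(_fig_positional_composition(comp["positional_end"], "read end"))
    for key, title in (("kmer_start", "read start"), ("kmer_end", "read end")):
        top = comp[key]["top"]
        if top:
            parts.append(f"<h3>Most frequent {comp['k']}-mers at {title}</h3>")
            parts.append(
                _table(
                    ["k-mer", "Count", "Fraction"],
                    [(r["kmer"], f"{r['count']:,}", _pct(r["fraction"])) for r in top],
                )
            )
    return "".join(parts)


def _sec_alerts(b) -> str:
    alerts = b["alerts"]
    if not alerts:
        return '<p class="ok">No alerts: no configured rule fired.</p>'
    return "".join(
        f'<div class="alert"><strong>{html.escape(a["rule_id"])}</strong>: '
        f'{html.escape(a["message"])}</div>'
        for a in alerts
    )


_RENDERERS = {
    "depth_landscape": _sec_depth_landscape,
    "summary": _sec_summary,
    "coverage": _sec_coverage,
    "quality": _sec_quality,
    "mapping": _sec_mapping,
    "composition": _sec_composition,
    "alerts": _sec_alerts,
}


def render_html(results: ResultsBundle) -> str:
    prov = results["provenance"]
    toc = "".join(
        f'<li><a href="#{key}">{title}</a></li>' for key, title in _SECTION_TITLES
    )
    body = []
    for key, title in _SECTION_TITLES:
        body.append(f'<h2 id="{key}">{title}</h2>')
        body.append(_RENDERERS[key](results))
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"/>
<title>bamdigest report</title>
<style>{_CSS}</style></head>
<body>
<h1>bamdigest report</h1>
<p>BAM: <code>{html.escape(prov["bam"])}</code><br/>
Genome build: {html.escape(str(prov.get("build", "")))} ·
tool v{html.escape(str(prov.get("tool_version", "")))} ·
seed {prov.get("seed")} · sample size {prov.get("sample_size"):,}<br/>
BAM file date: {html.escape(str(prov.get("bam_mtime", "")))}</p>
<h2>Contents</h2>
<ol>{toc}</ol>
{"".join(body)}
</body></html>
"""


def render_report(results: ResultsBundle, out_path: str, format: str = "html") -> str:
    """Write the report; returns the output path.

    HTML is always available. PDF needs the optional weasyprint backend and
    raises RendererUnavailable with a fallback instruction when missing.
    """
    doc = render_html(results)
    if format == "html":
        with open(out_path, "w") as fh:
            fh.write(doc)
        return out_path
    if format == "pdf":
        try:
            from weasyprint import HTML  # optional dependency
        except ImportError as exc:
            raise RendererUnavailable(
                "PDF export needs the 'weasyprint' package; install it or "
                "render HTML instead (--format html)"
            ) from exc
        HTML(string=doc).write_pdf(out_path)
        return out_path
    raise ValueError(f"unknown format {format!r}")
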