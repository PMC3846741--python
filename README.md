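# bamdigest

One-command QC digest of a coordinate-sorted, indexed BAM file. `bamdigest`
computes coverage, quality, mapping and base-composition statistics, applies
rule-based alerts, and renders everything into a standalone HTML report plus
a machine-readable JSON results bundle. It makes no assumption about how the
BAM was produced (platform, aligner or protocol).

Two ingestion tracks keep large files tractable:

* a **full pass** stores only lightweight per-alignment columns
  (chromosome, position, strand, mapq, reference span) and drives the exact
  pileup, duplication, mapq and strand statistics;
* a seeded **reservoir subsample** of complete records (default 100,000
  reads — a size at which subsample estimates closely track global values,
  verifiable with the built-in `converge` command) drives all per-base
  statistics: quality profiles, CIGAR class fractions, insert sizes and
  base composition.

The package ships a synthetic-BAM generator with exact ground truth, so the
entire statistics layer is testable offline with no external data.

## CLI

Compile genome metadata once per reference (FASTA plus optional GFF3/GTF or
BED annotation):

```sh
bamdigest compile-genome --fasta ref.fa --features ann.gff3 --build toy1 \
    -o toy1.gmeta.json
```

Digest a BAM:

```sh
bamdigest run --bam sample.bam --genome toy1.gmeta.json \
    --out report.html --json results.json \
    --sample-size 100000 --seed 17 [--pdf] [--fail-on-alert] [--rules qc.yaml]
```

The report contains seven sections in fixed order: depth landscape, summary
statistics, read count & coverage, sequencing quality, reference genome
mapping, base frequency, and alerts. PDF export needs the optional
`weasyprint` package; HTML is always available. Rendering is a pure
function of the results bundle — `results.json` can be re-rendered later
without the BAM.

Resampling experiment (how estimates tighten with subsample size):

```sh
bamdigest converge --bam sample.bam --sizes 100,1000,10000,100000 \
    --reps 100 --seed 17 --out convergence.csv --plot violins.png
```

Synthetic fixtures:

```sh
bamdigest simulate --spec spec.yaml --seed 7 -o toy.bam
```

writes a sorted, indexed BAM plus `toy.bam.truth.json` with the realized
value of every simulation parameter.

## Alerts

Default rules: uncalled-base frequency **higher than 0.5%**, and **more
than 55%** of reads mapped to one strand (strict comparisons — boundary
values do not fire). Extend or replace them with `--rules rules.yaml`,
a YAML list with `id`, `metric` (dotted path into the results bundle),
`comparator` (`gt`/`lt`), `threshold` and `message`.

## Layout

| module | role |
| --- | --- |
| `bamdigest.bam_io` | BAM validation, full-pass mapping table, reservoir subsample |
| `bamdigest.genome_meta` | compile/persist/query reference metadata (lengths, base frequencies, exon/intron/intergenic intervals) |
| `bamdigest.stats_core` | all report statistics (CIGAR, pileup, quality, mapping, composition) |
| `bamdigest.convergence` | subsample-vs-global resampling experiment |
| `bamdigest.alerts` | rule evaluation over the results bundle |
| `bamdigest.reporting` / `bamdigest.render` | bundle assembly, JSON persistence, HTML/PDF report |
| `bamdigest.synthetic_bam` | toy genomes and truth-tracked synthetic BAMs |
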