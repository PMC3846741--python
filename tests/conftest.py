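"""Shared fixtures: all BAM/FASTA inputs are generated at test time."""

import os

import pytest

from bamdigest.genome_meta import compile_genome_meta
from bamdigest.synthetic_bam import SimSpec, generate_synthetic_bam, generate_toy_genome


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Two-chromosome 150-kb toy genome with genes/exons and compiled meta."""
    d = tmp_path_factory.mktemp("genome")
    fasta, gff, meta = generate_toy_genome(str(d), seed=11)
    return {"dir": str(d), "fasta": fasta, "gff": gff, "meta": meta}


@pytest.fixture(scope="session")
def single_end_bam(tmp_path_factory, toy_genome):
    """1,000 single-end reads with N calls, duplicates and CIGAR events."""
    d = tmp_path_factory.mktemp("bam_se")
    path = os.path.join(d, "se.bam")
    spec = SimSpec(
        fasta=toy_genome["fasta"],
        read_count=1000,
        read_length=75,
        n_rate=0.003,
        strand_forward_fraction=0.5,
        duplicate_rate=0.10,
        softclip_rate=0.05,
        insertion_rate=0.02,
        deletion_rate=0.03,
        mapq_dist={60: 0.8, 30: 0.15, 0: 0.05},
        seed=101,
    )
    truth = generate_synthetic_bam(spec, path)
    return {"path": path, "truth": truth, "spec": spec}


@pytest.fixture(scope="session")
def paired_bam(tmp_path_factory, toy_genome):
    """2,000 paired reads (1,000 FR pairs) with a known insert distribution."""
    d = tmp_path_factory.mktemp("bam_pe")
    path = os.path.join(d, "pe.bam")
    spec = SimSpec(
        fasta=toy_genome["fasta"],
        read_count=2000,
        read_length=75,
        paired=True,
        insert_mean=262.6,
        insert_sd=60.0,
        n_rate=0.002,
        duplicate_rate=0.05,
        mapq_dist={60: 1.0},
        seed=202,
    )
    truth = generate_synthetic_bam(spec, path)
    return {"path": path, "truth": truth, "spec": spec}


@pytest.fixture(scope="session")
def plain_meta(tmp_path_factory):
    """Single-chromosome meta without annotation, for depth unit tests."""
    d = tmp_path_factory.mktemp("plainref")
    fasta, gff, _ = generate_toy_genome(
        str(d), n_chroms=1, lengths=(100_000,), seed=3
    )
    return compile_genome_meta(fasta, build_label="plain")
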