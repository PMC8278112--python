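"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from txatlas.annotation import (
    AnnotationSet,
    GeneRecord,
    TranscriptRecord,
    build_annotation,
    tss_of,
)
from txatlas.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at generator defaults (seed 7)."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast small dataset for plumbing-level tests."""
    cfg = GeneratorConfig(
        seed=11,
        n_genes=120,
        n_antisense_pairs=4,
        n_h2h_pairs=3,
        n_specific_per_tissue=1,
        n_specific_isoforms=2,
    )
    return generate(cfg)


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str,
    biotype: str = "protein_coding",
    chrom: str = "chr1",
) -> tuple[GeneRecord, TranscriptRecord]:
    """A single-transcript gene for hand-built geometry fixtures."""
    tx_id = f"{gene_id}.1"
    tx = TranscriptRecord(tx_id, gene_id, chrom, start, end, strand, biotype)
    gene = GeneRecord(gene_id, chrom, start, end, strand, biotype, frozenset({tx_id}))
    return gene, tx


def make_annotation(*specs) -> AnnotationSet:
    """Build an AnnotationSet from (gene_id, start, end, strand[, biotype[, chrom]])."""
    genes, txs = [], []
    for spec in specs:
        g, t = make_gene(*spec)
        genes.append(g)
        txs.append(t)
    return build_annotation(genes, txs)


def random_annotation(rng: np.random.Generator, n_genes: int) -> AnnotationSet:
    """Random single-transcript genes with arbitrary overlaps, for oracle tests."""
    genes, txs = [], []
    chroms = ["chrA", "chrB"]
    for i in range(n_genes):
        start = int(rng.integers(1, 60_000))
        length = int(rng.integers(100, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        g, t = make_gene(f"R{i:04d}", start, start + length - 1, strand, chrom=chrom)
        genes.append(g)
        txs.append(t)
    return build_annotation(genes, txs)


# ------------------------------------------------------- brute-force oracles
def brute_force_antisense(ann: AnnotationSet) -> dict[tuple[str, str], int]:
    """All-pairs scan: opposite-strand span overlaps >= 1 bp, with lengths."""
    out = {}
    for a, b in itertools.combinations(sorted(ann.genes.values(), key=lambda g: g.gene_id), 2):
        if a.chrom != b.chrom or a.strand == b.strand:
            continue
        ov = min(a.end, b.end) - max(a.start, b.start) + 1
        if ov >= 1:
            out[tuple(sorted((a.gene_id, b.gene_id)))] = ov
    return out


def brute_force_h2h(ann: AnnotationSet, max_distance: int = 1000) -> dict[tuple[str, str], int]:
    """All-pairs scan: opposite-strand TSS distances <= max_distance."""
    out = {}
    for a, b in itertools.combinations(sorted(ann.genes.values(), key=lambda g: g.gene_id), 2):
        if a.chrom != b.chrom or a.strand == b.strand:
            continue
        d = abs(tss_of(a) - tss_of(b))
        if d <= max_distance:
            out[tuple(sorted((a.gene_id, b.gene_id)))] = d
    return out
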