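"""Expressed-isoform counts per gene per tissue and summary statistics.

For each (gene, tissue) the count is the number of that gene's transcripts
passing the expression call. Per-tissue means are taken over genes with at
least one expressed isoform (a gene silent in a tissue does not dilute the
average), and histograms bucket counts as 1, 2, 3 and 4+.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import AnnotationSet
from .expression import ExpressionCallSet

HISTOGRAM_BUCKETS = ["1", "2", "3", "4+"]


@dataclass
class IsoformCountTable:
    """Per-gene-per-tissue expressed-isoform counts with summaries."""

    counts: pd.DataFrame  # gene × tissue, integer expressed-isoform counts
    mean_per_tissue: pd.Series  # over genes with >= 1 expressed isoform
    histograms: pd.DataFrame  # bucket × tissue gene counts

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)


def isoform_counts(tx_calls: ExpressionCallSet, ann: AnnotationSet) -> IsoformCountTable:
    """Count expressed isoforms per gene in each tissue.

    Raises if a called transcript has no annotation record. Genes with zero
    expressed isoforms in a tissue hold count 0 there and are excluded from
    that tissue's mean and histogram.
    """
    tissues = tx_calls.tissues
    genes = sorted(ann.genes)
    counts = pd.DataFrame(0, index=genes, columns=tissues, dtype=int)
    for tissue in tissues:
        for tx in tx_calls.expressed[tissue]:
            if tx not in ann.transcripts:
                raise ValueError(f"called transcript {tx} has no parent gene")
            counts.loc[ann.transcripts[tx].gene_id, tissue] += 1

    means = {}
    hist = pd.DataFrame(0, index=HISTOGRAM_BUCKETS, columns=tissues, dtype=int)
    for tissue in tissues:
        expressed = counts[tissue][counts[tissue] >= 1]
        means[tissue] = float(expressed.mean()) if len(expressed) else float("nan")
        for c in expressed:
            bucket = str(c) if c < 4 else "4+"
            hist.loc[bucket, tissue] += 1
    return IsoformCountTable(
        counts=counts,
        mean_per_tissue=pd.Series(means, name="mean_isoforms_per_gene"),
        histograms=hist,
    )


def high_isoform_genes(
    table: IsoformCountTable, k: int = 4
) -> tuple[list[str], pd.DataFrame]:
    """Genes with >= k expressed isoforms in *every* tissue, plus per-tissue
    maxima.

    Returns the sorted intersection and a deterministic (count desc, gene id
    asc) per-tissue table of each tissue's maximum-isoform gene count.
    """
    everywhere = table.counts[(table.counts >= k).all(axis=1)]
    rows = []
    for tissue in table.tissues:
        col = table.counts[tissue]
        ordered = col.sort_index().sort_values(ascending=False, kind="mergesort")
        if len(ordered):
            rows.append(
                {"tissue": tissue, "gene_id": ordered.index[0], "max_isoforms": int(ordered.iloc[0])}
            )
    maxima = pd.DataFrame.from_records(rows, columns=["tissue", "gene_id", "max_isoforms"])
    return sorted(everywhere.index), maxima
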