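"""Opposite-strand gene-pair geometry and per-tissue expression status.

Two relations are detected on gene spans (1-based inclusive coordinates):

* **antisense overlap** — same chromosome, opposite strands, spans overlap
  by at least one base pair;
* **head-to-head (H2H)** — same chromosome, opposite strands, transcription
  start sites within 1 kb of each other (inclusive bound).

A pair is classified by its member biotypes (PC–PC, PC–lncRNA,
lncRNA–lncRNA, other) and, given an expression call set, each (pair, tissue)
is exactly one of co-expressed (both members), mono-expressed (exactly one)
or silent (neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import BIOTYPES, AnnotationSet, GeneRecord, tss_of
from .expression import ExpressionCallSet

ANTISENSE_OVERLAP = "antisense_overlap"
HEAD_TO_HEAD = "head_to_head"

PC_PC = "PC-PC"
PC_LNC = "PC-lncRNA"
LNC_LNC = "lncRNA-lncRNA"
OTHER = "other"

CO = "co_expressed"
MONO = "mono_expressed"
SILENT = "silent"


@dataclass(frozen=True, order=True)
class GenePair:
    """An unordered opposite-strand gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    relation: str
    overlap_bp: int | None = None
    tss_distance_bp: int | None = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair members must be stored with gene_a < gene_b")
        if self.relation == ANTISENSE_OVERLAP and (
            self.overlap_bp is None or self.overlap_bp < 1
        ):
            raise ValueError("antisense pair requires overlap_bp >= 1")
        if self.relation == HEAD_TO_HEAD and (
            self.tss_distance_bp is None or self.tss_distance_bp < 0
        ):
            raise ValueError("head-to-head pair requires tss_distance_bp >= 0")

    @property
    def members(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _make_pair(a: GeneRecord, b: GeneRecord, relation: str, value: int) -> GenePair:
    ga, gb = sorted((a.gene_id, b.gene_id))
    if relation == ANTISENSE_OVERLAP:
        return GenePair(ga, gb, relation, overlap_bp=value)
    return GenePair(ga, gb, relation, tss_distance_bp=value)


def overlap_bp(a: GeneRecord, b: GeneRecord) -> int:
    """Overlap length of two spans in 1-based inclusive coordinates (may be <= 0)."""
    return min(a.end, b.end) - max(a.start, b.start) + 1


def find_antisense_pairs(ann: AnnotationSet) -> list[GenePair]:
    """All same-chromosome opposite-strand gene pairs overlapping >= 1 bp.

    Uses an interval index over plus-strand genes per chromosome and queries
    each minus-strand gene against it; a gene overlapping several
    opposite-strand partners contributes one pair per partner. The result is
    sorted and deterministic.
    """
    by_chrom: dict[str, tuple[list[GeneRecord], list[GeneRecord]]] = {}
    for g in ann.genes.values():
        plus, minus = by_chrom.setdefault(g.chrom, ([], []))
        (plus if g.strand == "+" else minus).append(g)

    pairs: list[GenePair] = []
    for plus, minus in by_chrom.values():
        if not plus or not minus:
            continue
        tree = IntervalTree()
        for g in plus:
            tree.addi(g.start, g.end + 1, g)  # half-open internally
        for m in minus:
            for hit in tree.overlap(m.start, m.end + 1):
                p = hit.data
                ov = overlap_bp(p, m)
                if ov >= 1:
                    pairs.append(_make_pair(p, m, ANTISENSE_OVERLAP, ov))
    return sorted(set(pairs))


def find_h2h_pairs(ann: AnnotationSet, max_distance: int = 1000) -> list[GenePair]:
    """Opposite-strand pairs whose TSSs are within ``max_distance`` bp
    (inclusive), regardless of span overlap.

    Implemented as a sorted-TSS window search per chromosome; exact
    equivalence with the all-pairs scan is the contract.
    """
    by_chrom: dict[str, tuple[list[GeneRecord], list[GeneRecord]]] = {}
    for g in ann.genes.values():
        plus, minus = by_chrom.setdefault(g.chrom, ([], []))
        (plus if g.strand == "+" else minus).append(g)

    pairs: list[GenePair] = []
    for plus, minus in by_chrom.values():
        if not plus or not minus:
            continue
        minus_sorted = sorted(minus, key=tss_of)
        minus_tss = np.array([tss_of(g) for g in minus_sorted])
        for p in plus:
            t = tss_of(p)
            lo = int(np.searchsorted(minus_tss, t - max_distance, side="left"))
            hi = int(np.searchsorted(minus_tss, t + max_distance, side="right"))
            for m in minus_sorted[lo:hi]:
                pairs.append(_make_pair(p, m, HEAD_TO_HEAD, abs(t - tss_of(m))))
    return sorted(set(pairs))


def classify_pair_biotype(pair: GenePair, ann: AnnotationSet) -> str:
    """Biotype category of a pair: PC–PC, PC–lncRNA, lncRNA–lncRNA or other.

    Any member outside {protein_coding, lncRNA} makes the pair "other",
    matching the census convention of three named categories plus remainder.
    Unknown biotype strings are rejected (strict 15-term vocabulary).
    """
    biotypes = []
    for gid in pair.members:
        b = ann.genes[gid].biotype
        if b not in BIOTYPES:
            raise ValueError(f"gene {gid}: unknown biotype {b!r}")
        biotypes.append(b)
    named = {"protein_coding", "lncRNA"}
    if not set(biotypes) <= named:
        return OTHER
    if biotypes[0] == biotypes[1]:
        return PC_PC if biotypes[0] == "protein_coding" else LNC_LNC
    return PC_LNC


@dataclass
class PairStatusResult:
    """Per-(pair, tissue) statuses with stratified tallies and unique sets."""

    statuses: pd.DataFrame  # columns: gene_a, gene_b, relation, category, tissue, status
    counts: pd.DataFrame  # (relation, category, tissue) -> co/mono/silent counts
    unique_co: dict[str, frozenset[tuple[str, str]]]
    unique_mono: dict[str, frozenset[tuple[str, str]]]


def pair_expression_status(
    pairs: Iterable[GenePair],
    calls: ExpressionCallSet,
    ann: AnnotationSet,
) -> PairStatusResult:
    """Score every pair in every tissue as co-/mono-expressed or silent.

    A gene absent from the call set simply counts as not expressed. A pair
    is *unique to tissue t* for a status iff it holds that status in exactly
    one tissue, namely t.
    """
    pairs = sorted(set(pairs))
    tissues = calls.tissues
    records = []
    status_by_pair: dict[GenePair, dict[str, str]] = {}
    for pair in pairs:
        category = classify_pair_biotype(pair, ann)
        per_tissue: dict[str, str] = {}
        for tissue in tissues:
            a_on = pair.gene_a in calls.expressed[tissue]
            b_on = pair.gene_b in calls.expressed[tissue]
            status = CO if (a_on and b_on) else (MONO if (a_on or b_on) else SILENT)
            per_tissue[tissue] = status
            records.append(
                {
                    "gene_a": pair.gene_a,
                    "gene_b": pair.gene_b,
                    "relation": pair.relation,
                    "category": category,
                    "tissue": tissue,
                    "status": status,
                }
            )
        status_by_pair[pair] = per_tissue

    statuses = pd.DataFrame.from_records(
        records, columns=["gene_a", "gene_b", "relation", "category", "tissue", "status"]
    )
    if len(statuses):
        counts = (
            statuses.groupby(["relation", "category", "tissue"])["status"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=[CO, MONO, SILENT], fill_value=0)
        )
    else:
        counts = pd.DataFrame(columns=[CO, MONO, SILENT])

    unique_co: dict[str, set[tuple[str, str]]] = {t: set() for t in tissues}
    unique_mono: dict[str, set[tuple[str, str]]] = {t: set() for t in tissues}
    for pair, per_tissue in status_by_pair.items():
        for status, sink in ((CO, unique_co), (MONO, unique_mono)):
            holding = [t for t, s in per_tissue.items() if s == status]
            if len(holding) == 1:
                sink[holding[0]].add(pair.members)
    return PairStatusResult(
        statuses=statuses,
        counts=counts,
        unique_co={t: frozenset(s) for t, s in unique_co.items()},
        unique_mono={t: frozenset(s) for t, s in unique_mono.items()},
    )


def pairs_to_bed(pairs: Iterable[GenePair], ann: AnnotationSet) -> pd.DataFrame:
    """BED-like 6-column table (0-based half-open on output only)."""
    rows = []
    for p in sorted(set(pairs)):
        a, b = ann.genes[p.gene_a], ann.genes[p.gene_b]
        start = min(a.start, b.start) - 1
        end = max(a.end, b.end)
        value = p.overlap_bp if p.relation == ANTISENSE_OVERLAP else p.tss_distance_bp
        rows.append(
            {
                "chrom": a.chrom,
                "start": start,
                "end": end,
                "name": f"{p.gene_a}|{p.gene_b}|{p.relation}",
                "score": value,
                "strand": ".",
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
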