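"""Strand-aware gene/transcript annotation model built from GTF.

The annotation is the geometric substrate for everything downstream:
biotype census totals, transcript→gene resolution for isoform counting,
and gene spans + transcription start sites (TSSs) for opposite-strand
pair detection.

Coordinates follow the GTF convention throughout: 1-based, inclusive on
both ends. Overlap length between two spans is ``min(end) - max(start) + 1``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

#: The transcript biotype vocabulary of the Ensembl chicken (GRCg6a) annotation.
BIOTYPES = frozenset(
    {
        "protein_coding",
        "lncRNA",
        "miRNA",
        "pseudogene",
        "misc_RNA",
        "snoRNA",
        "snRNA",
        "scaRNA",
        "rRNA",
        "processed_pseudogene",
        "IG_V_gene",
        "Mt_rRNA",
        "Mt_tRNA",
        "ribozyme",
        "sRNA",
    }
)


class GtfParseError(ValueError):
    """Raised when a GTF line violates the format contract."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript (isoform)."""

    transcript_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}"
            )
        if not self.biotype:
            raise ValueError(f"transcript {self.transcript_id}: empty biotype")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    """A gene: the span covering all of its transcripts on one strand.

    The span is the overlap substrate for antisense pair detection and the
    source of the TSS (strand-dependent 5' end).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    transcript_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.transcript_ids:
            raise ValueError(f"gene {self.gene_id}: no member transcripts")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def tss_of(gene: GeneRecord) -> int:
    """Transcription start site of a gene: the strand-dependent 5' end.

    For a "+" gene this is the span start; for a "-" gene the span end.
    """
    return gene.start if gene.strand == "+" else gene.end


class AnnotationSet:
    """Validated container of genes and transcripts from one annotation.

    Enforces referential integrity (every transcript's gene resolves), span
    covering (each gene's span contains all member transcripts), strand/chrom
    consistency within a gene, and a biotype vocabulary partition.
    """

    def __init__(
        self,
        genes: Mapping[str, GeneRecord],
        transcripts: Mapping[str, TranscriptRecord],
    ) -> None:
        self.genes: dict[str, GeneRecord] = dict(genes)
        self.transcripts: dict[str, TranscriptRecord] = dict(transcripts)
        self._validate()
        self._tx_by_gene: dict[str, frozenset[str]] = {
            g.gene_id: g.transcript_ids for g in self.genes.values()
        }

    def _validate(self) -> None:
        for tx in self.transcripts.values():
            gene = self.genes.get(tx.gene_id)
            if gene is None:
                raise ValueError(
                    f"transcript {tx.transcript_id}: unresolvable gene_id {tx.gene_id}"
                )
            if gene.chrom != tx.chrom:
                raise ValueError(
                    f"transcript {tx.transcript_id}: chrom {tx.chrom} differs from "
                    f"gene {gene.gene_id} chrom {gene.chrom}"
                )
            if gene.strand != tx.strand:
                raise ValueError(
                    f"transcript {tx.transcript_id}: strand {tx.strand} conflicts with "
                    f"gene {gene.gene_id} strand {gene.strand}"
                )
            if not (gene.start <= tx.start and tx.end <= gene.end):
                raise ValueError(
                    f"gene {gene.gene_id} span [{gene.start},{gene.end}] does not cover "
                    f"transcript {tx.transcript_id} [{tx.start},{tx.end}]"
                )
        for gene in self.genes.values():
            for tx_id in gene.transcript_ids:
                if tx_id not in self.transcripts:
                    raise ValueError(
                        f"gene {gene.gene_id} lists unknown transcript {tx_id}"
                    )

    # ------------------------------------------------------------------ views
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def biotype_counts(self) -> Counter:
        """Transcript-level biotype totals; values sum to ``n_transcripts``."""
        return Counter(tx.biotype for tx in self.transcripts.values())

    def transcripts_of(self, gene_id: str) -> frozenset[str]:
        return self._tx_by_gene[gene_id]

    def gene_of(self, transcript_id: str) -> str:
        return self.transcripts[transcript_id].gene_id

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AnnotationSet({self.n_genes} genes, {self.n_transcripts} transcripts)"


_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def _parse_attributes(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_gtf(path: str | Path) -> AnnotationSet:
    """Parse a GTF file into an :class:`AnnotationSet`.

    Only ``gene`` and ``transcript`` feature lines are consumed; all other
    feature types (exon, CDS, UTR, ...) are skipped. Transcript biotype is
    read from the ``transcript_biotype`` attribute, falling back to
    ``gene_biotype`` (both Ensembl dialects occur in the wild). Gene spans
    come from an explicit ``gene`` line when present, otherwise the union
    (min start, max end) of the gene's transcripts.

    Raises
    ------
    GtfParseError
        On malformed lines, missing required attributes, invalid strand or
        start > end — always naming the offending line number.
    """
    path = Path(path)
    gene_lines: dict[str, GeneRecord] = {}
    # transcript_id -> raw tuple; assembled at the end
    tx_raw: dict[str, tuple[str, str, int, int, str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path.name}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "transcript"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            if start > end:
                raise GtfParseError(f"{path.name}:{lineno}: start {start} > end {end}")
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path.name}:{lineno}: unknown strand character {strand!r}"
                )
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GtfParseError(f"{path.name}:{lineno}: missing gene_id attribute")

            if feature == "gene":
                biotype = attrs.get("gene_biotype", "")
                gene_lines[gene_id] = GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotype,
                    transcript_ids=frozenset({"__placeholder__"}),
                )
            else:
                tx_id = attrs.get("transcript_id")
                if not tx_id:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: missing transcript_id attribute"
                    )
                biotype = attrs.get("transcript_biotype") or attrs.get("gene_biotype")
                if not biotype:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: transcript {tx_id} carries neither "
                        "transcript_biotype nor gene_biotype"
                    )
                if tx_id in tx_raw:
                    raise GtfParseError(
                        f"{path.name}:{lineno}: duplicate transcript_id {tx_id}"
                    )
                tx_raw[tx_id] = (gene_id, chrom, start, end, strand, biotype)

    transcripts = {
        tx_id: TranscriptRecord(tx_id, g, c, s, e, st, b)
        for tx_id, (g, c, s, e, st, b) in tx_raw.items()
    }
    return _assemble(gene_lines, transcripts, str(path.name))


def _assemble(
    gene_lines: Mapping[str, GeneRecord],
    transcripts: Mapping[str, TranscriptRecord],
    source: str,
) -> AnnotationSet:
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for tx in transcripts.values():
        by_gene.setdefault(tx.gene_id, []).append(tx)

    genes: dict[str, GeneRecord] = {}
    for gene_id, txs in by_gene.items():
        strands = {t.strand for t in txs}
        chroms = {t.chrom for t in txs}
        if len(strands) > 1:
            raise GtfParseError(
                f"{source}: gene {gene_id} has transcripts on conflicting strands"
            )
        if len(chroms) > 1:
            raise GtfParseError(
                f"{source}: gene {gene_id} has transcripts on multiple chromosomes"
            )
        tx_ids = frozenset(t.transcript_id for t in txs)
        explicit = gene_lines.get(gene_id)
        if explicit is not None:
            if explicit.strand != txs[0].strand or explicit.chrom != txs[0].chrom:
                raise GtfParseError(
                    f"{source}: gene line for {gene_id} conflicts with its transcripts"
                )
            start, end = explicit.start, explicit.end
            biotype = explicit.biotype or txs[0].biotype
        else:
            start = min(t.start for t in txs)
            end = max(t.end for t in txs)
            biotype = txs[0].biotype
        genes[gene_id] = GeneRecord(
            gene_id=gene_id,
            chrom=txs[0].chrom,
            start=start,
            end=end,
            strand=txs[0].strand,
            biotype=biotype,
            transcript_ids=tx_ids,
        )

    orphans = set(gene_lines) - set(genes)
    if orphans:
        raise GtfParseError(
            f"{source}: gene(s) without any transcript: {', '.join(sorted(orphans))}"
        )
    return AnnotationSet(genes, transcripts)


def build_annotation(
    genes: Iterable[GeneRecord], transcripts: Iterable[TranscriptRecord]
) -> AnnotationSet:
    """Construct an AnnotationSet from in-memory records (generator path)."""
    return AnnotationSet(
        {g.gene_id: g for g in genes}, {t.transcript_id: t for t in transcripts}
    )
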