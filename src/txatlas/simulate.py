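"""Synthetic annotation + expression generator with planted ground truth.

Emulates the study design the pipeline targets: ~10 tissue groups sequenced
in duplicate, a mixed-biotype annotation on both strands, and expression
with negative-binomial noise. Four kinds of structure are planted and
recorded in a :class:`SyntheticTruth` so every downstream stage can be
tested by parameter recovery:

* **antisense pairs** — convergent opposite-strand gene pairs overlapping by
  a drawn 1–500 bp (member spans >= 1500 bp, so their TSSs are always
  > 1 kb apart and the pair can never double as head-to-head);
* **head-to-head pairs** — opposite-strand genes with a drawn TSS gap of
  1–1000 bp and zero span overlap;
* **tissue-specific genes** — background mean multiplied by the fold
  enrichment in one target tissue and suppressed to a near-zero mean
  elsewhere;
* **tissue-specific isoforms** — two-isoform genes expressed everywhere
  whose second isoform is used only in one target tissue;
* **high-isoform genes** — genes drawing >= 4 isoforms get balanced isoform
  usage and background-level expression, so all isoforms pass the call in
  every tissue.

All other inter-gene gaps exceed 1 kb, and a brute-force no-leakage scan at
generation time asserts that no accidental overlap or TSS adjacency exists.
Everything is drawn from a single seeded generator; the same seed gives a
byte-identical GTF and identical matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    BIOTYPES,
    AnnotationSet,
    GeneRecord,
    TranscriptRecord,
    build_annotation,
    tss_of,
)
from .expression import DEFAULT_TPM_THRESHOLD, ExpressionMatrix

CHROM = "chrS"


def _default_biotype_proportions() -> dict[str, float]:
    # Echoes the annotation's transcript shares: ~69% protein-coding,
    # ~23% lncRNA, ~3% miRNA, remainder spread over the low-abundance types.
    other = sorted(BIOTYPES - {"protein_coding", "lncRNA", "miRNA"})
    props = {"protein_coding": 0.69, "lncRNA": 0.23, "miRNA": 0.029}
    share = (1.0 - sum(props.values())) / len(other)
    for b in other:
        props[b] = share
    return props


def _default_isoform_probs() -> dict[int, float]:
    return {1: 0.80, 2: 0.15, 3: 0.04, 4: 0.01}  # 4 means "4 or more"


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic dataset."""

    n_tissues: int = 10
    replicates_per_tissue: int = 2  # assays "in at least duplicates"
    n_genes: int = 1000
    biotype_proportions: dict[str, float] = field(
        default_factory=_default_biotype_proportions
    )
    isoform_probs: dict[int, float] = field(default_factory=_default_isoform_probs)
    n_antisense_pairs: int = 10
    antisense_overlap_range: tuple[int, int] = (1, 500)
    n_h2h_pairs: int = 10
    h2h_gap_range: tuple[int, int] = (1, 1000)
    n_specific_per_tissue: int = 3
    fold_enrichment: float = 100.0
    suppressed_mean: float = 0.001  # off-target mean count: effectively silent
    n_specific_isoforms: int = 5
    mean_count: float = 500.0
    nb_dispersion: float = 0.05  # var = mu + a*mu^2
    library_size_cv: float = 0.2
    gene_length_range: tuple[int, int] = (1500, 3000)
    max_isoforms: int = 6
    seed: int = 0

    def validate(self) -> None:
        props = sum(self.biotype_proportions.values())
        if abs(props - 1.0) > 1e-9:
            raise ValueError(f"biotype proportions sum to {props}, not 1")
        if abs(sum(self.isoform_probs.values()) - 1.0) > 1e-9:
            raise ValueError("isoform-count probabilities must sum to 1")
        pair_genes = 2 * (self.n_antisense_pairs + self.n_h2h_pairs)
        planted_singles = (
            self.n_tissues * self.n_specific_per_tissue + self.n_specific_isoforms
        )
        if pair_genes + planted_singles > self.n_genes:
            raise ValueError(
                f"infeasible packing: {pair_genes} pair genes + {planted_singles} "
                f"planted singles exceed n_genes={self.n_genes}"
            )
        if self.h2h_gap_range[1] > 1000:
            raise ValueError("h2h gaps above 1000 bp would not be head-to-head")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for parameter-recovery tests."""

    antisense_pairs: list[tuple[str, str]]
    antisense_overlaps: dict[tuple[str, str], int]
    h2h_pairs: list[tuple[str, str]]
    h2h_gaps: dict[tuple[str, str], int]
    specific_genes: dict[str, list[str]]  # tissue -> gene ids
    specific_isoforms: list[tuple[str, str]]  # (transcript_id, target tissue)
    high_isoform_genes: list[str]
    expected_gene_mean_counts: pd.DataFrame | None = None  # gene × tissue
    expected_mean_tpm: pd.DataFrame | None = None  # transcript × tissue

    def to_json_dict(self) -> dict:
        return {
            "antisense_pairs": [list(p) for p in self.antisense_pairs],
            "antisense_overlaps": {
                f"{a}|{b}": v for (a, b), v in self.antisense_overlaps.items()
            },
            "h2h_pairs": [list(p) for p in self.h2h_pairs],
            "h2h_gaps": {f"{a}|{b}": v for (a, b), v in self.h2h_gaps.items()},
            "specific_genes": self.specific_genes,
            "specific_isoforms": [list(p) for p in self.specific_isoforms],
            "high_isoform_genes": self.high_isoform_genes,
        }


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth."""

    config: GeneratorConfig
    annotation: AnnotationSet
    tpm: ExpressionMatrix  # transcript-level
    gene_counts: ExpressionMatrix  # gene-level integer counts
    grouping: dict[str, str]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "annotation.gtf").write_text(write_gtf(self.annotation))
        self.tpm.values.to_csv(outdir / "tx_tpm.tsv", sep="\t", index_label="transcript_id")
        self.gene_counts.values.to_csv(
            outdir / "gene_counts.tsv", sep="\t", index_label="gene_id"
        )
        pd.DataFrame(
            {"sample": list(self.grouping), "tissue": list(self.grouping.values())}
        ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth.to_json_dict(), indent=2, sort_keys=True)
        )


def write_gtf(ann: AnnotationSet) -> str:
    """Serialize an AnnotationSet as GTF text (deterministic line order)."""
    lines = []
    for gid in sorted(ann.genes, key=lambda g: (ann.genes[g].start, g)):
        g = ann.genes[gid]
        lines.append(
            f"{g.chrom}\ttxatlas_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        )
        for tx_id in sorted(g.transcript_ids):
            t = ann.transcripts[tx_id]
            lines.append(
                f"{t.chrom}\ttxatlas_sim\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}"; gene_biotype "{g.biotype}";'
            )
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------- annotation
def generate_annotation(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationSet, SyntheticTruth, dict]:
    """Lay out genes on one synthetic chromosome and plant pair structure.

    Returns the annotation, a partial truth (pairs only; expression truth is
    filled by :func:`generate_expression`) and the internal role assignment.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    lo_len, hi_len = cfg.gene_length_range
    units: list[str] = (
        ["antisense"] * cfg.n_antisense_pairs
        + ["h2h"] * cfg.n_h2h_pairs
        + ["single"] * (cfg.n_genes - 2 * (cfg.n_antisense_pairs + cfg.n_h2h_pairs))
    )
    rng.shuffle(units)

    genes: list[GeneRecord] = []
    antisense: list[tuple[str, str]] = []
    overlaps: dict[tuple[str, str], int] = {}
    h2h: list[tuple[str, str]] = []
    gaps: dict[tuple[str, str], int] = {}
    singles: list[str] = []

    cursor = 1001
    serial = 0

    def _next_id() -> str:
        nonlocal serial
        serial += 1
        return f"G{serial:05d}"

    def _gap() -> int:
        return 1001 + int(rng.integers(0, 2000))

    for unit in units:
        if unit == "single":
            gid = _next_id()
            length = int(rng.integers(lo_len, hi_len + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(gid, CHROM, cursor, cursor + length - 1, strand, "", frozenset({"x"}))
            )
            singles.append(gid)
            cursor += length + _gap()
        elif unit == "antisense":
            # convergent (tail-to-tail) overlap; long spans keep TSSs > 1 kb apart
            ga, gb = _next_id(), _next_id()
            len_a = int(rng.integers(lo_len, hi_len + 1))
            len_b = int(rng.integers(lo_len, hi_len + 1))
            ov = int(rng.integers(cfg.antisense_overlap_range[0], cfg.antisense_overlap_range[1] + 1))
            # convergent only: a divergent overlap would place both TSSs
            # inside the overlap region and make the pair head-to-head too
            a_start, a_end = cursor, cursor + len_a - 1
            b_start = a_end - ov + 1
            b_end = b_start + len_b - 1
            genes.append(GeneRecord(ga, CHROM, a_start, a_end, "+", "", frozenset({"x"})))
            genes.append(GeneRecord(gb, CHROM, b_start, b_end, "-", "", frozenset({"x"})))
            key = tuple(sorted((ga, gb)))
            antisense.append(key)
            overlaps[key] = ov
            cursor = max(a_end, b_end) + 1 + _gap()
        else:  # h2h: divergent TSSs, zero span overlap
            ga, gb = _next_id(), _next_id()
            len_a = int(rng.integers(lo_len, hi_len + 1))
            len_b = int(rng.integers(lo_len, hi_len + 1))
            gap = int(rng.integers(cfg.h2h_gap_range[0], cfg.h2h_gap_range[1] + 1))
            a_start, a_end = cursor, cursor + len_a - 1  # "-" gene, TSS = a_end
            b_start = a_end + gap  # "+" gene, TSS = b_start
            b_end = b_start + len_b - 1
            genes.append(GeneRecord(ga, CHROM, a_start, a_end, "-", "", frozenset({"x"})))
            genes.append(GeneRecord(gb, CHROM, b_start, b_end, "+", "", frozenset({"x"})))
            key = tuple(sorted((ga, gb)))
            h2h.append(key)
            gaps[key] = gap
            cursor = b_end + 1 + _gap()

    # ---- roles on single genes: tissue-specific, isoform-specific
    tissues = [f"t{i:02d}" for i in range(1, cfg.n_tissues + 1)]
    n_specific = cfg.n_tissues * cfg.n_specific_per_tissue
    chosen = rng.choice(
        np.array(singles), size=n_specific + cfg.n_specific_isoforms, replace=False
    )
    specific_flat = [str(g) for g in chosen[:n_specific]]
    iso_specific = [str(g) for g in chosen[n_specific:]]
    specific_genes = {
        t: sorted(specific_flat[i * cfg.n_specific_per_tissue : (i + 1) * cfg.n_specific_per_tissue])
        for i, t in enumerate(tissues)
    }
    iso_targets = {g: tissues[int(rng.integers(0, cfg.n_tissues))] for g in iso_specific}

    # ---- biotypes and isoform counts
    biotype_names = sorted(cfg.biotype_proportions)
    biotype_p = np.array([cfg.biotype_proportions[b] for b in biotype_names])
    iso_ks = sorted(cfg.isoform_probs)
    iso_p = np.array([cfg.isoform_probs[k] for k in iso_ks])
    specific_set = set(specific_flat)
    iso_specific_set = set(iso_specific)

    high_isoform: list[str] = []
    final_genes: list[GeneRecord] = []
    transcripts: list[TranscriptRecord] = []
    for g in genes:
        biotype = str(rng.choice(biotype_names, p=biotype_p))
        if g.gene_id in specific_set:
            k = 1
        elif g.gene_id in iso_specific_set:
            k = 2
        else:
            k = int(rng.choice(iso_ks, p=iso_p))
            if k >= 4:
                k = int(rng.integers(4, cfg.max_isoforms + 1))
                high_isoform.append(g.gene_id)
        tx_ids = []
        for i in range(1, k + 1):
            tx_id = f"{g.gene_id}.{i}"
            if i == 1:
                s, e = g.start, g.end  # first isoform covers the span
            else:
                margin = g.length // 4
                a = int(rng.integers(0, margin + 1))
                b = int(rng.integers(0, margin + 1))
                s, e = g.start + a, g.end - b
            transcripts.append(
                TranscriptRecord(tx_id, g.gene_id, g.chrom, s, e, g.strand, biotype)
            )
            tx_ids.append(tx_id)
        final_genes.append(
            GeneRecord(g.gene_id, g.chrom, g.start, g.end, g.strand, biotype, frozenset(tx_ids))
        )

    ann = build_annotation(final_genes, transcripts)
    _assert_no_leakage(ann, set(antisense), set(h2h), cfg.h2h_gap_range[1])

    truth = SyntheticTruth(
        antisense_pairs=sorted(antisense),
        antisense_overlaps=overlaps,
        h2h_pairs=sorted(h2h),
        h2h_gaps=gaps,
        specific_genes=specific_genes,
        specific_isoforms=sorted((f"{g}.2", t) for g, t in iso_targets.items()),
        high_isoform_genes=sorted(high_isoform),
    )
    roles = {
        "tissues": tissues,
        "specific_target": {
            g: t for t, gs in specific_genes.items() for g in gs
        },
        "iso_targets": iso_targets,
        "high_isoform": set(high_isoform),
    }
    return ann, truth, roles


def _assert_no_leakage(
    ann: AnnotationSet,
    planted_as: set[tuple[str, str]],
    planted_h2h: set[tuple[str, str]],
    max_distance: int,
) -> None:
    """Brute-force check: no accidental antisense overlap or TSS adjacency."""
    gs = sorted(ann.genes.values(), key=lambda g: g.gene_id)
    start = np.array([g.start for g in gs])
    end = np.array([g.end for g in gs])
    plus = np.array([g.strand == "+" for g in gs])
    tss = np.array([tss_of(g) for g in gs])
    ids = [g.gene_id for g in gs]

    opposite = plus[:, None] != plus[None, :]
    ov = np.minimum(end[:, None], end[None, :]) - np.maximum(start[:, None], start[None, :]) + 1
    as_hits = np.triu(opposite & (ov >= 1), k=1)
    found_as = {tuple(sorted((ids[i], ids[j]))) for i, j in zip(*np.nonzero(as_hits))}
    if found_as != planted_as:
        raise AssertionError(
            f"antisense leakage: found {found_as ^ planted_as} beyond/missing planted"
        )
    dist = np.abs(tss[:, None] - tss[None, :])
    h2h_hits = np.triu(opposite & (dist <= max_distance), k=1)
    found_h2h = {tuple(sorted((ids[i], ids[j]))) for i, j in zip(*np.nonzero(h2h_hits))}
    if found_h2h != planted_h2h:
        raise AssertionError(
            f"h2h leakage: found {found_h2h ^ planted_h2h} beyond/missing planted"
        )


# ----------------------------------------------------------------- expression
def generate_expression(
    ann: AnnotationSet,
    truth: SyntheticTruth,
    roles: dict,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict[str, str], SyntheticTruth]:
    """Draw gene counts (negative binomial) and derive transcript TPMs.

    Gene counts are Gamma–Poisson draws around per-tissue means; transcript
    values split each gene's count over its isoforms by a usage simplex
    (Dirichlet, shared across tissues, except for planted structure) and are
    normalized per sample to one million (equal transcript lengths — length
    bias is not modeled). Replicates are independent draws.
    """
    tissues: list[str] = roles["tissues"]
    gene_ids = sorted(ann.genes)
    n_g = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # expected per-tissue mean counts (gene × tissue)
    mean = np.full((n_g, len(tissues)), cfg.mean_count)
    for g, target in roles["specific_target"].items():
        i = gene_index[g]
        mean[i, :] = cfg.suppressed_mean
        mean[i, tissues.index(target)] = cfg.fold_enrichment * cfg.mean_count

    # isoform usage per gene: array over that gene's sorted transcripts
    usage: dict[str, np.ndarray] = {}
    for g in gene_ids:
        k = len(ann.genes[g].transcript_ids)
        if g in roles["high_isoform"]:
            usage[g] = np.full(k, 1.0 / k)
        elif g in roles["iso_targets"]:
            usage[g] = np.array([1.0, 0.0])  # off-target; target tissue overridden
        elif k == 1:
            usage[g] = np.array([1.0])
        else:
            usage[g] = rng.dirichlet(np.full(k, 5.0))

    def _usage_in(g: str, tissue: str) -> np.ndarray:
        if g in roles["iso_targets"] and roles["iso_targets"][g] == tissue:
            return np.array([0.5, 0.5])
        return usage[g]

    tx_ids = sorted(ann.transcripts)
    tx_rows = {t: i for i, t in enumerate(tx_ids)}

    samples: list[str] = []
    grouping: dict[str, str] = {}
    count_cols: list[np.ndarray] = []
    tpm_cols: list[np.ndarray] = []
    shape = 1.0 / cfg.nb_dispersion
    for t_idx, tissue in enumerate(tissues):
        for r in range(1, cfg.replicates_per_tissue + 1):
            s = f"{tissue}_r{r}"
            samples.append(s)
            grouping[s] = tissue
            lib = rng.lognormal(mean=0.0, sigma=cfg.library_size_cv)
            mu = mean[:, t_idx] * lib
            lam = rng.gamma(shape, mu * cfg.nb_dispersion)
            counts = rng.poisson(lam).astype(float)
            count_cols.append(counts)
            tx_vals = np.zeros(len(tx_ids))
            for g, c in zip(gene_ids, counts):
                if c == 0:
                    continue
                u = _usage_in(g, tissue)
                for tx, frac in zip(sorted(ann.genes[g].transcript_ids), u):
                    tx_vals[tx_rows[tx]] = c * frac
            total = tx_vals.sum()
            tpm_cols.append(tx_vals / total * 1e6 if total > 0 else tx_vals)

    counts_df = pd.DataFrame(
        np.column_stack(count_cols), index=gene_ids, columns=samples
    ).astype(int)
    tpm_df = pd.DataFrame(np.column_stack(tpm_cols), index=tx_ids, columns=samples)

    # ---- expected (noise-free) means for the truth record
    exp_gene = pd.DataFrame(mean, index=gene_ids, columns=tissues)
    exp_tx = np.zeros((len(tx_ids), len(tissues)))
    for t_idx, tissue in enumerate(tissues):
        for g in gene_ids:
            u = _usage_in(g, tissue)
            for tx, frac in zip(sorted(ann.genes[g].transcript_ids), u):
                exp_tx[tx_rows[tx], t_idx] = mean[gene_index[g], t_idx] * frac
        col_total = exp_tx[:, t_idx].sum()
        exp_tx[:, t_idx] = exp_tx[:, t_idx] / col_total * 1e6
    exp_tpm = pd.DataFrame(exp_tx, index=tx_ids, columns=tissues)

    _verify_expression_truth(truth, roles, exp_tpm, tissues)
    truth.expected_gene_mean_counts = exp_gene
    truth.expected_mean_tpm = exp_tpm

    tpm = ExpressionMatrix(values=tpm_df, units="TPM", grouping=grouping)
    counts_m = ExpressionMatrix(values=counts_df, units="counts", grouping=grouping)
    return tpm, counts_m, grouping, truth


def _verify_expression_truth(
    truth: SyntheticTruth,
    roles: dict,
    exp_tpm: pd.DataFrame,
    tissues: list[str],
) -> None:
    """Consistency check: planted structure holds in the expected TPMs."""
    thr = DEFAULT_TPM_THRESHOLD
    for tissue, gs in truth.specific_genes.items():
        for g in gs:
            row = exp_tpm.loc[f"{g}.1"]
            if not (row[tissue] > thr and (row.drop(tissue) <= thr).all()):
                raise AssertionError(f"specific gene {g} truth violated")
    for tx, tissue in truth.specific_isoforms:
        row = exp_tpm.loc[tx]
        if not (row[tissue] > thr and (row.drop(tissue) <= thr).all()):
            raise AssertionError(f"specific isoform {tx} truth violated")
    for g in truth.high_isoform_genes:
        for tx in (t for t in exp_tpm.index if t.startswith(f"{g}.")):
            if not (exp_tpm.loc[tx] > thr).all():
                raise AssertionError(f"high-isoform gene {g} truth violated at {tx}")


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full dataset (annotation, matrices, grouping, truth)."""
    rng = np.random.default_rng(cfg.seed)
    ann, truth, roles = generate_annotation(cfg, rng)
    tpm, counts, grouping, truth = generate_expression(ann, truth, roles, cfg, rng)
    return SyntheticDataset(
        config=cfg,
        annotation=ann,
        tpm=tpm,
        gene_counts=counts,
        grouping=grouping,
        truth=truth,
    )
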