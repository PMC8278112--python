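"""Expression matrices, replicate averaging, expression calling and census.

The detection pipeline follows the atlas convention: a feature (gene or
transcript) counts as *expressed* in a tissue when its replicate-averaged
TPM is strictly greater than 0.5. Counts are made cross-sample comparable
with the median-of-ratios size-factor procedure before any cross-tissue
comparison. Printed percentages are always one-decimal, rounded
half-away-from-zero, and re-derivable from their stored integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .annotation import AnnotationSet

DEFAULT_TPM_THRESHOLD = 0.5


def percent(numerator: int | float, denominator: int | float, ndigits: int = 1) -> float:
    """Percentage with half-away-from-zero rounding (the pinned convention).

    ``percent(17872, 24356)`` → 73.4. Python's built-in ``round`` is
    banker's rounding and would drift on .5 boundaries, so Decimal
    quantization is used instead.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class ExpressionMatrix:
    """Feature × sample expression table with a sample→tissue grouping.

    ``values`` rows are features (genes or transcripts), columns samples.
    ``units`` is ``"TPM"`` or ``"counts"`` and gates which operations apply.
    """

    values: pd.DataFrame
    units: str
    grouping: dict[str, str]

    def __post_init__(self) -> None:
        if self.units not in ("TPM", "counts"):
            raise ValueError(f"units must be 'TPM' or 'counts', got {self.units!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.grouping]
        if missing:
            raise ValueError(f"samples missing from grouping: {missing}")
        neg = np.argwhere(self.values.to_numpy() < 0)
        if len(neg):
            i, j = neg[0]
            raise ValueError(
                f"negative value at ({self.values.index[i]}, {self.values.columns[j]})"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.grouping[s], None)
        return list(seen)


def read_grouping(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→tissue TSV (header ``sample<TAB>tissue``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("grouping table needs two columns: sample, tissue")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_matrix(
    path: str | Path,
    grouping: Mapping[str, str] | str | Path,
    units: str,
) -> ExpressionMatrix:
    """Load a TSV expression matrix (first column feature ids, header samples)."""
    if not isinstance(grouping, Mapping):
        grouping = read_grouping(grouping)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, units=units, grouping=dict(grouping))


@dataclass
class TissueProfile:
    """Replicate-averaged expression, feature × tissue."""

    values: pd.DataFrame
    units: str

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def average_replicates(m: ExpressionMatrix) -> TissueProfile:
    """Arithmetic mean of each tissue's replicate columns.

    A single-replicate tissue passes through unchanged. Raises if a tissue
    label in the grouping has no sample column.
    """
    cols_by_tissue: dict[str, list[str]] = {}
    for s in m.values.columns:
        cols_by_tissue.setdefault(m.grouping[s], []).append(s)
    for tissue in set(m.grouping.values()):
        if not cols_by_tissue.get(tissue):
            raise ValueError(f"tissue group {tissue!r} has no samples in the matrix")
    averaged = pd.DataFrame(
        {t: m.values[cols].mean(axis=1) for t, cols in cols_by_tissue.items()},
        index=m.values.index,
    )
    return TissueProfile(values=averaged, units=m.units)


@dataclass
class ExpressionCallSet:
    """Per-tissue sets of expressed feature ids at a fixed TPM threshold."""

    expressed: dict[str, frozenset[str]]
    threshold: float
    level: str = "transcript"  # or "gene"

    @property
    def tissues(self) -> list[str]:
        return list(self.expressed)

    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.expressed.values():
            out |= s
        return frozenset(out)

    def n_tissues_expressed(self, feature_id: str) -> int:
        return sum(feature_id in s for s in self.expressed.values())

    def is_expressed(self, feature_id: str, tissue: str) -> bool:
        return feature_id in self.expressed[tissue]


def call_expressed(
    profile: TissueProfile,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    level: str = "transcript",
) -> ExpressionCallSet:
    """Call a feature expressed in a tissue iff averaged value > threshold.

    The inequality is strict: a feature averaging exactly the threshold is
    *not* expressed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = profile.values > threshold
    expressed = {
        t: frozenset(profile.values.index[mask[t]]) for t in profile.values.columns
    }
    return ExpressionCallSet(expressed=expressed, threshold=threshold, level=level)


def gene_calls_from_transcripts(
    tx_calls: ExpressionCallSet, ann: AnnotationSet
) -> ExpressionCallSet:
    """Lift transcript-level calls to genes: a gene is detected in a tissue
    iff at least one of its transcripts is."""
    expressed: dict[str, frozenset[str]] = {}
    for tissue, txs in tx_calls.expressed.items():
        genes = set()
        for tx in txs:
            if tx not in ann.transcripts:
                raise ValueError(f"called transcript {tx} absent from annotation")
            genes.add(ann.transcripts[tx].gene_id)
        expressed[tissue] = frozenset(genes)
    return ExpressionCallSet(
        expressed=expressed, threshold=tx_calls.threshold, level="gene"
    )


# --------------------------------------------------------------- normalization
def size_factors_median_of_ratios(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization formula).

    For every feature with strictly positive counts in *all* samples, compute
    its geometric mean across samples; each sample's factor is the median of
    that sample's count/geometric-mean ratios. Features containing a zero are
    excluded because their geometric mean vanishes. Factors are centered to
    geometric mean 1 — a global-scale convention that leaves relative
    normalization untouched and makes the procedure exactly idempotent
    (re-estimating on a normalized matrix returns all-1 factors).
    """
    if counts.units != "counts":
        raise ValueError("size factors are defined on count matrices")
    x = counts.values.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "pseudo-reference fallbacks are out of scope"
        )
    ref = x[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric-mean-1 centering
    return pd.Series(
        np.exp(log_factors), index=counts.values.columns, name="size_factor"
    )


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    factors = size_factors_median_of_ratios(counts)
    normalized = counts.values.div(factors, axis=1)
    return ExpressionMatrix(values=normalized, units="counts", grouping=counts.grouping)


# --------------------------------------------------------------------- census
@dataclass
class BiotypeCensus:
    """Per-tissue biotype breakdown of detected transcripts."""

    counts: pd.DataFrame  # tissue × biotype, integers
    percentages: pd.DataFrame  # tissue × biotype, one decimal
    low_abundance: pd.DataFrame  # counts restricted to non-PC/non-lncRNA biotypes


def biotype_census(calls: ExpressionCallSet, ann: AnnotationSet) -> BiotypeCensus:
    """Count detected transcripts per biotype per tissue.

    Percentages are over each tissue's detected total; the low-abundance
    report drops protein_coding and lncRNA (everything below a few percent).
    """
    biotypes = sorted(ann.biotype_counts)
    rows = {}
    for tissue, txs in calls.expressed.items():
        unknown = [t for t in txs if t not in ann.transcripts]
        if unknown:
            raise ValueError(f"called ids absent from annotation: {sorted(unknown)}")
        tally = {b: 0 for b in biotypes}
        for tx in txs:
            tally[ann.transcripts[tx].biotype] += 1
        rows[tissue] = tally
    counts = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=biotypes)
    counts = counts.fillna(0).astype(int)
    totals = counts.sum(axis=1)
    percentages = counts.copy().astype(float)
    for tissue in counts.index:
        tot = int(totals[tissue])
        for b in biotypes:
            percentages.loc[tissue, b] = (
                percent(int(counts.loc[tissue, b]), tot) if tot else 0.0
            )
    low = counts.drop(columns=[c for c in ("protein_coding", "lncRNA") if c in counts])
    return BiotypeCensus(counts=counts, percentages=percentages, low_abundance=low)


def unique_expression(
    calls: ExpressionCallSet,
    ann: AnnotationSet | None = None,
    biotype_filter: str | None = None,
) -> dict[str, frozenset[str]]:
    """Features expressed in exactly one tissue, keyed by that tissue.

    With ``biotype_filter`` the result is restricted to one biotype (feature
    biotype is the transcript's, or the gene's for gene-level call sets).
    """
    if len(calls.expressed) < 2:
        raise ValueError("unique expression needs at least two tissues")

    def _biotype(fid: str) -> str:
        assert ann is not None
        if calls.level == "gene":
            return ann.genes[fid].biotype
        return ann.transcripts[fid].biotype

    out: dict[str, frozenset[str]] = {}
    tissues = list(calls.expressed)
    for t in tissues:
        others: set[str] = set()
        for u in tissues:
            if u != t:
                others |= calls.expressed[u]
        unique = set(calls.expressed[t]) - others
        if biotype_filter is not None:
            if ann is None:
                raise ValueError("biotype_filter requires an annotation")
            unique = {f for f in unique if _biotype(f) == biotype_filter}
        out[t] = frozenset(unique)
    return out


@dataclass
class DetectionSummary:
    """Detected-vs-annotated totals and the per-tissue Table-1-shaped counts."""

    detected_genes: int
    annotated_genes: int
    detected_transcripts: int
    annotated_transcripts: int
    gene_pct: float
    transcript_pct: float
    per_tissue: pd.DataFrame  # tissue × (transcripts, genes, lncRNA)

    def to_frame(self) -> pd.DataFrame:
        overall = pd.DataFrame(
            {
                "transcripts": [self.detected_transcripts],
                "genes": [self.detected_genes],
                "lncRNA": [pd.NA],
            },
            index=["all"],
        )
        return pd.concat([self.per_tissue, overall])


def detection_summary(
    gene_calls: ExpressionCallSet,
    tx_calls: ExpressionCallSet,
    ann: AnnotationSet,
) -> DetectionSummary:
    """Overall and per-tissue detection counts with pinned percentages.

    Overall detection is the union across tissues; percentages are
    100 × detected / annotated at one decimal, half-away-from-zero.
    Per-tissue rows report gene, transcript and lncRNA-transcript counts.
    """
    detected_genes = len(gene_calls.union())
    detected_tx = len(tx_calls.union())
    rows = {}
    for tissue in tx_calls.tissues:
        txs = tx_calls.expressed[tissue]
        lnc = sum(1 for t in txs if ann.transcripts[t].biotype == "lncRNA")
        rows[tissue] = {
            "transcripts": len(txs),
            "genes": len(gene_calls.expressed[tissue]),
            "lncRNA": lnc,
        }
    per_tissue = pd.DataFrame.from_dict(rows, orient="index")
    return DetectionSummary(
        detected_genes=detected_genes,
        annotated_genes=ann.n_genes,
        detected_transcripts=detected_tx,
        annotated_transcripts=ann.n_transcripts,
        gene_pct=percent(detected_genes, ann.n_genes),
        transcript_pct=percent(detected_tx, ann.n_transcripts),
        per_tissue=per_tissue,
    )


# ----------------------------------------------------------------- similarity
def sample_similarity(m: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample × sample Euclidean distance and Pearson correlation matrices.

    Count matrices are size-factor normalized first so library depth does not
    dominate the distances. A constant sample has no defined Pearson
    correlation; its row/column is NaN rather than a silent 0.
    """
    if m.values.shape[1] < 2:
        raise ValueError("similarity needs at least two samples")
    values = normalize_counts(m).values if m.units == "counts" else m.values
    x = values.to_numpy(dtype=float).T  # samples × features
    dist = squareform(pdist(x, metric="euclidean"))
    dist_df = pd.DataFrame(dist, index=values.columns, columns=values.columns)
    corr_df = values.corr(method="pearson")  # constant columns -> NaN
    return dist_df, corr_df
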