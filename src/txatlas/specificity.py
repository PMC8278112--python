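"""Tissue-specificity scoring by Shannon entropy.

A gene whose expression concentrates in few tissues has low entropy across
the tissue profile; specificity is reported as ``log2(T) - H`` (bits), so a
single-tissue gene scores ``log2(T)`` and a perfectly uniform gene scores 0.
Rankings are identical whichever of the two quantities is sorted, and both
orderings are exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .expression import (
    DEFAULT_TPM_THRESHOLD,
    ExpressionCallSet,
    TissueProfile,
    call_expressed,
)

logger = logging.getLogger(__name__)


def shannon_entropy(x) -> float:
    """Shannon entropy (bits) of a non-negative vector after normalization.

    ``p_i = x_i / sum(x)``; ``H = -sum p_i log2 p_i`` with ``0 log 0 = 0``.
    Raises on an all-zero vector — callers must pre-filter silent features.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("entropy requires non-negative input")
    total = x.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero vector is undefined")
    p = x / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0)  # + 0.0 avoids IEEE -0.0


@dataclass
class SpecificityTable:
    """Ranked per-feature entropy/specificity scores over T tissues."""

    table: pd.DataFrame  # columns: entropy, score; index: feature_id; sorted by rank
    n_tissues: int

    @property
    def max_score(self) -> float:
        return float(np.log2(self.n_tissues))


def _score_features(profile: TissueProfile) -> pd.DataFrame:
    values = profile.values
    totals = values.sum(axis=1)
    kept = values.loc[totals > 0]
    n_t = values.shape[1]
    ent = kept.apply(lambda row: shannon_entropy(row.to_numpy()), axis=1)
    score = np.log2(n_t) - ent
    return pd.DataFrame({"entropy": ent, "score": score})


def rank_gene_specificity(
    profile: TissueProfile,
    top_n: int = 2000,
    most_specific: bool = True,
) -> tuple[SpecificityTable, pd.DataFrame]:
    """Rank features by specificity and return the top-``top_n`` expression
    matrix for heatmap export.

    Features with zero total expression are excluded before ranking. Rank 1
    is the most specific feature (highest ``log2(T) - H``) by default; with
    ``most_specific=False`` the ordering is reversed (least-specific tail).
    Ties break lexicographically by feature id so output is deterministic.
    """
    if profile.values.shape[1] < 2:
        raise ValueError("specificity needs at least two tissues")
    scored = _score_features(profile)
    ascending = not most_specific
    scored = scored.sort_values(
        by=["score"], ascending=ascending, kind="mergesort"
    )
    # mergesort is stable; pre-sort the index for the lexicographic tie rule
    scored = (
        scored.sort_index(kind="mergesort")
        .sort_values(by=["score"], ascending=ascending, kind="mergesort")
    )
    scored["rank"] = np.arange(1, len(scored) + 1)
    if top_n > len(scored):
        logger.warning(
            "requested top %d features but only %d available; returning all",
            top_n,
            len(scored),
        )
        top_n = len(scored)
    top_ids = scored.index[:top_n]
    heatmap = profile.values.loc[top_ids]
    return SpecificityTable(table=scored, n_tissues=profile.values.shape[1]), heatmap


def rank_isoform_specificity(
    tx_profile: TissueProfile,
    gene_calls: ExpressionCallSet,
    ann: AnnotationSet,
    top_n: int = 500,
    threshold: float = DEFAULT_TPM_THRESHOLD,
    most_specific: bool = True,
) -> tuple[SpecificityTable, pd.DataFrame]:
    """Isoform-level specificity with the multi-tissue parent-gene filter.

    An isoform enters the ranking only if (a) its parent gene is expressed in
    at least two tissues and (b) the isoform itself passes the expression
    call (averaged TPM > threshold) in at least one tissue.
    """
    if gene_calls.level != "gene":
        raise ValueError("gene_calls must be a gene-level call set")
    keep = []
    for tx_id in tx_profile.values.index:
        if tx_id not in ann.transcripts:
            raise ValueError(f"transcript {tx_id} has no annotation record")
        gene_id = ann.transcripts[tx_id].gene_id
        if gene_calls.n_tissues_expressed(gene_id) < 2:
            continue
        keep.append(tx_id)
    filtered = TissueProfile(values=tx_profile.values.loc[keep], units=tx_profile.units)
    tx_calls = call_expressed(filtered, threshold=threshold)
    called_somewhere = tx_calls.union()
    filtered = TissueProfile(
        values=filtered.values.loc[[t for t in keep if t in called_somewhere]],
        units=tx_profile.units,
    )
    return rank_gene_specificity(filtered, top_n=top_n, most_specific=most_specific)
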