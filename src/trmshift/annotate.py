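"""Rank-based gene-signature (AUC) scoring and cell labelling.

Each cell's genes are ranked by expression (rank 1 = highest count, ties
broken deterministically by ascending gene index), and each signature is
scored by the area under its recovery curve over the top fraction of the
ranking, normalised by the maximum achievable area.  Because only ranks are
used, scores are invariant under any strictly monotone transform of a
cell's counts, so no prior normalisation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ValidationError
from .simulate import UNASSIGNED, CountMatrix


@dataclass(frozen=True)
class Signature:
    """A named gene set used to score cells."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")


def rank_genes(counts_for_cell: np.ndarray) -> np.ndarray:
    """Ordinal ranking of one cell's genes, rank 1 = highest count.

    Ties are broken by ascending gene index, so an all-zero vector ranks
    genes 1..n in index order and the ranking is always a permutation.
    """
    counts_for_cell = np.asarray(counts_for_cell)
    order = np.argsort(-counts_for_cell, kind="stable")
    ranks = np.empty(counts_for_cell.shape[0], dtype=np.int64)
    ranks[order] = np.arange(1, counts_for_cell.shape[0] + 1)
    return ranks


def auc_score(
    ranks: np.ndarray,
    signature: Signature,
    top_fraction: float = 0.05,
    *,
    genes: Sequence[str],
) -> float:
    """Normalised recovery-curve AUC of ``signature`` in one cell's ranking.

    The recovery curve counts signature genes found within the top ``x``
    ranks for ``x = 1 .. ceil(top_fraction * n_genes)``; its area is
    normalised by the maximum achievable (all signature genes at the very
    top), so a perfect-recovery cell scores exactly 1 regardless of
    signature size and a cell with no signature gene in the window scores 0.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    n_genes = len(genes)
    gene_set = set(signature.genes)
    positions = [i for i, g in enumerate(genes) if g in gene_set]
    if not positions:
        raise ValidationError(
            f"signature {signature.name!r} shares no genes with the universe"
        )
    return _auc_from_sig_ranks(
        np.asarray(ranks)[positions], ceil(top_fraction * n_genes)
    )


def _auc_from_sig_ranks(sig_ranks: np.ndarray, window: int) -> float:
    # area = sum over x=1..window of (#signature genes with rank <= x)
    area = int(np.maximum(0, window - sig_ranks + 1).sum())
    m = sig_ranks.size
    max_area = sum(min(x, m) for x in range(1, window + 1))
    return area / max_area


def score_cells(
    counts: CountMatrix,
    signatures: Sequence[Signature],
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Score every signature in every cell; signatures x cells DataFrame.

    Signatures with no gene in the matrix's universe are skipped with a
    warning.  The ranking window is recorded in ``df.attrs["top_fraction"]``.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError(f"top_fraction must be in (0, 1], got {top_fraction}")
    gene_index = {g: i for i, g in enumerate(counts.genes)}
    kept: list[tuple[str, np.ndarray]] = []
    for sig in signatures:
        idx = np.array([gene_index[g] for g in sig.genes if g in gene_index], int)
        if idx.size == 0:
            warnings.warn(
                f"signature {sig.name!r} shares no genes with the matrix; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        kept.append((sig.name, idx))
    if not kept:
        raise ValidationError("no signature overlaps the gene universe")

    n_genes = len(counts.genes)
    window = ceil(top_fraction * n_genes)
    dense = np.asarray(
        counts.matrix.toarray()
        if sparse.issparse(counts.matrix)
        else counts.matrix
    )
    scores = np.empty((len(kept), dense.shape[1]))
    for j in range(dense.shape[1]):
        ranks = rank_genes(dense[:, j])
        for i, (_, idx) in enumerate(kept):
            scores[i, j] = _auc_from_sig_ranks(ranks[idx], window)
    out = pd.DataFrame(
        scores, index=[name for name, _ in kept], columns=counts.barcodes
    )
    out.attrs["top_fraction"] = top_fraction
    return out


def assign_labels(scores: pd.DataFrame, min_score: float = 0.1) -> pd.Series:
    """Label each cell by its best-scoring signature.

    The label is the argmax signature when the maximum score reaches
    ``min_score`` and is unique; a sub-threshold maximum or an exact tie
    yields ``"unassigned"``.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValidationError(f"min_score must be in [0, 1], got {min_score}")
    vals = scores.to_numpy()
    best = vals.max(axis=0)
    ties = (vals == best[None, :]).sum(axis=0) > 1
    labels = scores.index.to_numpy()[vals.argmax(axis=0)].astype(object)
    labels[(best < min_score) | ties] = UNASSIGNED
    return pd.Series(labels, index=scores.columns, name="subset")
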