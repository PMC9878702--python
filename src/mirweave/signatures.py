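"""Summed z-score signature scoring over a reference corpus.

A gene set's score in a corpus sample is the sum of its member genes'
z-scores, where each gene's expression (log2CPM) is standardized across
corpus samples. Scores of two sets are then compared by Pearson
correlation across the corpus — the standard way to ask whether two
transcriptional programs co-vary in a reference population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection
from .de import compute_log2cpm
from .stats import pearson_with_p, zscore_rows

logger = logging.getLogger(__name__)


@dataclass
class SignatureScoreMatrix:
    """Per-set, per-sample summed z-scores over one corpus."""

    scores: pd.DataFrame  # sets x corpus samples
    flagged: tuple[str, ...] = ()  # sets scored on < 2 genes
    collection_name: str = ""
    corpus_id: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def score_signatures(
    corpus_expr,
    sets: GeneSetCollection,
    collection_name: str = "",
    corpus_id: str = "",
    already_normalized: bool = False,
) -> SignatureScoreMatrix:
    """Summed z-score signatures of each set over the corpus.

    ``corpus_expr`` is a :class:`CountMatrix` (log2CPM is computed
    internally) or, with ``already_normalized=True``, a DataFrame of
    pre-normalised expression. Genes constant across the corpus carry
    no information and are dropped before scoring; sets with no
    scorable gene are skipped with a log entry, sets with exactly one
    are scored but flagged.
    """
    if isinstance(corpus_expr, CountMatrix):
        expr = compute_log2cpm(corpus_expr)
    elif already_normalized:
        expr = pd.DataFrame(corpus_expr)
    else:
        raise TypeError("pass a CountMatrix, or a DataFrame with already_normalized=True")
    if expr.shape[1] < 3:
        raise ValueError("corpus needs at least 3 samples")

    z, kept = zscore_rows(expr.to_numpy(dtype=float))
    zframe = pd.DataFrame(z, index=expr.index[kept], columns=expr.columns)
    scorable = set(zframe.index)

    rows, flagged = {}, []
    for name in sets:
        members = [g for g in sets[name] if g in scorable]
        if not members:
            logger.info("set %s has no scorable genes in the corpus; skipped", name)
            continue
        if len(members) < 2:
            flagged.append(name)
        rows[name] = zframe.loc[members].to_numpy().sum(axis=0)
    scores = pd.DataFrame(rows, index=expr.columns).T
    return SignatureScoreMatrix(
        scores=scores,
        flagged=tuple(flagged),
        collection_name=collection_name,
        corpus_id=corpus_id,
    )


def correlate_scores(
    scores_a: SignatureScoreMatrix,
    scores_b: SignatureScoreMatrix,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """All pairwise Pearson correlations between two score matrices.

    Both matrices must be over the same corpus samples in the same
    order. Returns long-format columns
    ``set_a, set_b, r, pvalue, significant``.
    """
    if scores_a.sample_ids != scores_b.sample_ids:
        raise ValueError("score matrices must share the same corpus samples in the same order")
    rows = []
    for na in scores_a.scores.index:
        x = scores_a.scores.loc[na].to_numpy(dtype=float)
        for nb in scores_b.scores.index:
            y = scores_b.scores.loc[nb].to_numpy(dtype=float)
            r, p = pearson_with_p(x, y)
            rows.append(dict(set_a=na, set_b=nb, r=r, pvalue=p, significant=p < p_threshold))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "r", "pvalue", "significant"])


def correlation_matrix(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format correlation table to a set_a x set_b matrix
    (for heatmap rendering or export)."""
    return long_table.pivot(index="set_a", columns="set_b", values="r")
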