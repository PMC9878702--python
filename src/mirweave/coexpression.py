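"""Correlation-network modules, cell-type deconvolution, trait association.

The module core is the weighted-correlation-network recipe: an
unsigned adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the soft power
``beta`` chosen by the scale-free topology criterion, smoothed into the
topological overlap measure (TOM), clustered by average-linkage
hierarchical clustering on ``1 - TOM`` with a static height cut, and
clusters below the minimum module size assigned to ``grey``. Modules
are named by decreasing size from the conventional colour palette
(turquoise, blue, brown, ...). A static cut replaces the dynamic
hybrid tree cut: it is fully specifiable, deterministic and easy to
test, at the cost of less adaptive branch splitting.

Module summaries are eigengenes (first principal component of the
standardized member expression, sign-oriented, unit variance), which
are then correlated against sample traits — here the deconvolved
cell-type fractions plus binary case status.

Cell-type fractions come from per-sample non-negative least squares on
marker-gene expression against a cell-type signature matrix, with
fractions renormalised to sum to one. This is a constrained-regression
stand-in for kernel-regression deconvolution methods; on noiseless
mixtures it is exact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .stats import pearson_with_p

logger = logging.getLogger(__name__)

MODULE_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)
GREY = "grey"

DEFAULT_POWERS = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)
DEFAULT_CUT_HEIGHT = 0.995
DEFAULT_MIN_MODULE_SIZE = 5


def _check_expression(expr: pd.DataFrame) -> None:
    sd = expr.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"constant genes must be removed first: {bad[:5]}")


def compute_adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^power, zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    _check_expression(expr)
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    adj = np.abs(np.clip(cor, -1.0, 1.0)) ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k regression over connectivity bins."""
    k = adjacency.to_numpy().sum(axis=1)
    k = k[k > 0]
    if k.size < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    centers, freqs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (k >= lo) & (k < hi)
        if mask.sum() > 0:
            centers.append(k[mask].mean())
            freqs.append(mask.mean())
    if len(centers) < 3:
        return 0.0
    x = np.log10(np.asarray(centers))
    y = np.log10(np.asarray(freqs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    expr: pd.DataFrame, candidate_powers=DEFAULT_POWERS, r2_target: float = 0.8
) -> int:
    """Smallest candidate power reaching scale-free fit R^2 >= 0.8,
    falling back to the power with the best fit."""
    powers = list(candidate_powers)
    if not powers:
        raise ValueError("candidate_powers must be non-empty")
    best_power, best_r2 = powers[0], -1.0
    for p in powers:
        r2 = scale_free_fit(compute_adjacency(expr, p))
        if r2 >= r2_target:
            return p
        if r2 > best_r2:
            best_power, best_r2 = p, r2
    return best_power


def compute_tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over ``u != i, j`` and row connectivity
    ``k_i``; the diagonal is 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a  # (A^2)_ij sums over all u; diagonal of a is 0 so only u=i,j terms vanish anyway
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(np.clip(tom, 0.0, 1.0), index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` go to ``grey``; surviving
    modules are labelled by decreasing size from the colour palette.
    Returns a gene -> label Series.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = list(tom.index)
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    # deterministic ordering: by size desc, then smallest member index
    first_member = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_member[c]))
    palette = list(MODULE_PALETTE) + [f"module{i}" for i in range(len(MODULE_PALETTE), len(keep))]
    mapping = {c: palette[i] for i, c in enumerate(keep)}
    labels = [mapping.get(c, GREY) for c in raw]
    return pd.Series(labels, index=genes, name="module")


def compute_eigengenes(
    expr: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Module eigengenes: PC1 of row-standardized member expression.

    Each eigengene is scaled to unit variance and sign-oriented so its
    mean correlation with member genes is non-negative. Returns
    ``(eigengenes modules x samples, variance_explained per module)``.
    The grey pseudo-module is excluded.
    """
    _check_expression(expr)
    modules = [m for m in assignment.unique() if m != GREY]
    rows, varex = {}, {}
    for m in sorted(modules):
        members = assignment.index[assignment == m]
        sub = expr.loc[members].to_numpy(dtype=float)
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        mean_cor = np.mean([np.corrcoef(pc1, row)[0, 1] for row in z])
        if mean_cor < 0:
            pc1 = -pc1
        pc1 = pc1 / pc1.std(ddof=1)
        rows[m] = pc1
        varex[m] = float(s[0] ** 2 / np.sum(s**2))
    eig = pd.DataFrame(rows, index=expr.columns).T
    if eig.empty:
        eig = pd.DataFrame(columns=expr.columns, dtype=float)
    return eig, pd.Series(varex, name="variance_explained", dtype=float)


def deconvolve_fractions(bulk_expr: pd.DataFrame, signature: pd.DataFrame) -> pd.DataFrame:
    """Cell-type fractions by per-sample non-negative least squares.

    ``bulk_expr`` and ``signature`` are on linear (not log) scale;
    rows of the signature are marker genes, columns cell types. Only
    marker genes present in the bulk matrix are used; fractions are
    normalised to sum to 1 per sample.
    """
    markers = [g for g in signature.index if g in set(bulk_expr.index)]
    if len(markers) < signature.shape[1]:
        raise ValueError("need at least as many shared marker genes as cell types")
    S = signature.loc[markers].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("signature matrix is rank-deficient")
    B = bulk_expr.loc[markers].to_numpy(dtype=float)
    out = np.zeros((bulk_expr.shape[1], signature.shape[1]))
    for j in range(B.shape[1]):
        coef, _ = nnls(S, B[:, j])
        total = coef.sum()
        out[j] = coef / total if total > 0 else np.full(len(coef), 1.0 / len(coef))
    return pd.DataFrame(out, index=bulk_expr.columns, columns=signature.columns)


def module_trait_association(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait.

    Traits must be numeric (binary status coded 0/1); constant traits
    are skipped with a log entry. Returns columns
    ``module, trait, r, pvalue, significant``.
    """
    samples = list(eigengenes.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    traits = traits.loc[samples]
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            logger.info("trait %s is constant; skipped", trait)
            continue
        for m in eigengenes.index:
            r, p = pearson_with_p(eigengenes.loc[m].to_numpy(dtype=float), t)
            rows.append(dict(module=m, trait=trait, r=r, pvalue=p, significant=p < p_threshold))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "pvalue", "significant"])


def build_signature_matrix(truth, base_expression_scale: float = 1.0) -> pd.DataFrame:
    """Reference signature (markers x cell types) matching the synthetic
    generative model: a marker of cell type t has pure-type expression
    ``2^base / mean_fraction_t`` in its own column and 0 elsewhere."""
    mean_frac = truth.cell_fractions.mean(axis=0)
    rows, index = [], []
    types = list(truth.marker_genes)
    for ctype in types:
        for g in truth.marker_genes[ctype]:
            base = float(2.0 ** truth.base_log2_gene[g]) * base_expression_scale
            row = [base / mean_frac[t] if t == ctype else 0.0 for t in types]
            rows.append(row)
            index.append(g)
    return pd.DataFrame(rows, index=index, columns=types)
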