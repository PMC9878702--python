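"""miRNA-target enrichment and network assembly (SigTerms-style core).

For each screened miRNA candidate the question is whether its predicted
targets are over-represented among differentially expressed genes of a
given direction. With universe N (genes measured *and* present in the
compendium), K predicted targets of the miRNA in that universe, n DE
genes of the direction in the universe and k their overlap, the
statistic is the hypergeometric upper tail P(X >= k), adjusted by
Benjamini-Hochberg across the miRNAs tested within a mode. Significant
regulators (q < 0.05) contribute bipartite edges to their DE targets.

Four direction modes are assembled: the two canonical pairings
(up-miRNA/down-gene, down-miRNA/up-gene — direct suppression) and the
two non-canonical same-direction pairings (possible through indirect
regulation, e.g. intermediary non-coding RNAs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .containers import TargetCompendium
from .stats import HypergeomQuery, bh_adjust, hypergeometric_tail, pearson_with_p

logger = logging.getLogger(__name__)

#: mode name -> (miRNA direction, gene direction)
MODES = {
    "canonical_up_down": ("up", "down"),
    "canonical_down_up": ("down", "up"),
    "noncanonical_down_down": ("down", "down"),
    "noncanonical_up_up": ("up", "up"),
}

REGULATOR_COLUMNS = ("mirna_id", "k", "K", "n", "N", "pvalue", "qvalue")


@dataclass
class MirnaMrnaNetwork:
    """One direction-mode network: regulator table plus bipartite edges."""

    mode: str
    regulators: pd.DataFrame  # all tested miRNAs with k, K, n, N, p, q
    edges: set[tuple[str, str]] = field(default_factory=set)
    q_threshold: float = 0.05

    @property
    def significant_regulators(self) -> list[str]:
        sig = self.regulators[self.regulators["qvalue"] < self.q_threshold]
        return list(sig["mirna_id"])

    @property
    def target_genes(self) -> frozenset[str]:
        """Genes targeted by at least one significant regulator."""
        return frozenset(g for _, g in self.edges)

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(self.edges)
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).assign(mode=self.mode)


@dataclass
class OverlapResult:
    """Hypergeometric overlap of two fixed gene (or pathway) lists."""

    size_a: int
    size_b: int
    overlap: int
    universe_size: int
    expected_overlap: float
    pvalue: float


def enrich_mirna_targets(
    mirna_candidates: pd.DataFrame,
    gene_de: pd.DataFrame,
    compendium: TargetCompendium,
    mode: str,
    q_threshold: float = 0.05,
) -> MirnaMrnaNetwork:
    """Direction-stratified target enrichment for one mode.

    ``mirna_candidates`` and ``gene_de`` are DE tables with a
    ``direction`` column (from ``screen_de_mirnas`` /
    ``classify_de_genes``). The universe is genes measured in the DE
    analysis intersected with the compendium universe; miRNAs with no
    predicted target in the universe are skipped.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(MODES)}")
    mirna_dir, gene_dir = MODES[mode]

    measured = set(gene_de["feature_id"])
    universe = measured & set(compendium.universe)
    if not universe:
        raise ValueError("empty enrichment universe (no measured gene is in the compendium)")
    N = len(universe)

    de_genes = set(gene_de.loc[gene_de["direction"] == gene_dir, "feature_id"]) & universe
    n = len(de_genes)

    candidates = mirna_candidates.loc[mirna_candidates["direction"] == mirna_dir, "feature_id"]
    rows = []
    edge_targets: dict[str, set[str]] = {}
    for mid in candidates:
        targets = compendium.targets.get(mid, frozenset()) & universe
        K = len(targets)
        if K == 0:
            logger.info("miRNA %s has no predicted targets in the universe; skipped", mid)
            continue
        overlap = targets & de_genes
        k = len(overlap)
        p = hypergeometric_tail(HypergeomQuery(N=N, K=K, n=n, k=k))
        rows.append(dict(mirna_id=mid, k=k, K=K, n=n, N=N, pvalue=p))
        edge_targets[mid] = overlap

    reg = pd.DataFrame(rows, columns=list(REGULATOR_COLUMNS[:-1]))
    if len(reg):
        reg["qvalue"] = bh_adjust(reg["pvalue"].to_numpy())
    else:
        reg["qvalue"] = pd.Series(dtype=float)

    edges: set[tuple[str, str]] = set()
    for _, row in reg[reg["qvalue"] < q_threshold].iterrows():
        for g in edge_targets[row["mirna_id"]]:
            edges.add((row["mirna_id"], g))
    return MirnaMrnaNetwork(mode=mode, regulators=reg, edges=edges, q_threshold=q_threshold)


def run_all_modes(
    mirna_candidates: pd.DataFrame,
    gene_de: pd.DataFrame,
    compendium: TargetCompendium,
    q_threshold: float = 0.05,
) -> dict[str, MirnaMrnaNetwork]:
    """All four direction modes, each FDR-adjusted independently."""
    return {
        mode: enrich_mirna_targets(mirna_candidates, gene_de, compendium, mode, q_threshold)
        for mode in MODES
    }


def list_overlap(list_a, list_b, universe) -> OverlapResult:
    """Hypergeometric overlap significance of two fixed lists.

    A fixed-list test: with N = |universe|, K = |A|, n = |B| the
    observed overlap k is scored by P(X >= k).
    """
    uni = set(universe)
    a = set(list_a) & uni
    b = set(list_b) & uni
    if len(a) != len(set(list_a)) or len(b) != len(set(list_b)):
        raise ValueError("both lists must be contained in the universe")
    k = len(a & b)
    N, K, n = len(uni), len(a), len(b)
    p = hypergeometric_tail(HypergeomQuery(N=N, K=K, n=n, k=k))
    expected = K * n / N if N else 0.0
    return OverlapResult(
        size_a=K, size_b=n, overlap=k, universe_size=N, expected_overlap=expected, pvalue=p
    )


def cross_tissue_target_overlap(
    net_a: MirnaMrnaNetwork, net_b: MirnaMrnaNetwork, universe
) -> OverlapResult:
    """Overlap of the gene sets targeted by two tissues' networks."""
    return list_overlap(net_a.target_genes, net_b.target_genes, universe)


def cross_tissue_mirna_correlation(
    log2cpm_a: pd.DataFrame,
    log2cpm_b: pd.DataFrame,
    shared_samples=None,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-miRNA Pearson correlation between two tissues' log2CPM.

    Correlates each miRNA detected in both matrices across the shared
    donors; miRNAs constant in either tissue are skipped with a log
    entry. Returns columns ``mirna_id, r, pvalue, significant``.
    """
    if shared_samples is None:
        shared_samples = [s for s in log2cpm_a.columns if s in set(log2cpm_b.columns)]
    shared_samples = list(shared_samples)
    if len(shared_samples) < 3:
        raise ValueError("need at least 3 shared donors")
    shared_mirnas = [m for m in log2cpm_a.index if m in set(log2cpm_b.index)]
    rows = []
    for mid in shared_mirnas:
        x = log2cpm_a.loc[mid, shared_samples].to_numpy(dtype=float)
        y = log2cpm_b.loc[mid, shared_samples].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            logger.info("miRNA %s constant in one tissue; skipped", mid)
            continue
        r, p = pearson_with_p(x, y)
        rows.append(dict(mirna_id=mid, r=r, pvalue=p, significant=p < p_threshold))
    return pd.DataFrame(rows, columns=["mirna_id", "r", "pvalue", "significant"])
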