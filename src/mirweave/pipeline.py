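"""End-to-end pipeline driver.

Runs the full analysis over one study's inputs — simulated by default,
or read from a directory of standard-format files — and writes every
result table, a machine-readable manifest (thresholds, seed, stage
status) and a log into a run directory:

    simulate -> differential expression -> target-enrichment networks
    (all four direction modes, brain and blood candidates) -> pathway
    enrichment -> GO-term meta-enrichment -> coexpression modules ->
    cell-type deconvolution + module-trait association -> signature
    scoring over the reference corpus -> cross-tissue overlap
    statistics.

A stage failure aborts the run with the stage name; tables written by
earlier stages are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .containers import CountMatrix
from .coexpression import (
    DEFAULT_CUT_HEIGHT,
    DEFAULT_MIN_MODULE_SIZE,
    DEFAULT_POWERS,
    build_signature_matrix,
    compute_adjacency,
    compute_eigengenes,
    compute_tom,
    deconvolve_fractions,
    detect_modules,
    module_trait_association,
    pick_soft_threshold,
)
from .containers import GeneSetCollection
from .de import (
    classify_de_genes,
    compute_log2cpm,
    demographics_compare,
    fit_de,
    screen_de_mirnas,
)
from .enrich import go_term_meta_enrichment, pathway_enrichment, pathway_list_overlap
from .integrate import (
    cross_tissue_mirna_correlation,
    cross_tissue_target_overlap,
    run_all_modes,
)
from .signatures import correlate_scores, correlation_matrix, score_signatures
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "differential_expression",
    "network_integration",
    "pathway_enrichment",
    "term_meta_enrichment",
    "coexpression_modules",
    "deconvolution_traits",
    "signature_scores",
    "overlap_statistics",
)


@dataclass
class PipelineConfig:
    """Thresholds and knobs for one pipeline run.

    Thresholds default to the study criteria: gene calls at FDR 0.05
    and fold change 1.5, miRNA screen at raw p 0.05, enrichment at FDR
    0.05 with >= 2 overlapping genes, trait association at p 0.05,
    minimum module size 5.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gene_fdr: float = 0.05
    gene_fc: float = 1.5
    mirna_p: float = 0.05
    enrich_fdr: float = 0.05
    min_overlap_genes: int = 2
    trait_p: float = 0.05
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE
    cut_height: float = DEFAULT_CUT_HEIGHT
    powers: tuple[int, ...] = DEFAULT_POWERS
    covariates: tuple[str, ...] = ("Sex", "Age", "PMI", "pH", "RIN")
    min_module_genes_for_wgcna: int = 15

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def manifest_dict(self) -> dict:
        return {
            "seed": self.seed,
            "thresholds": {
                "gene_fdr": self.gene_fdr,
                "gene_fc": self.gene_fc,
                "mirna_p": self.mirna_p,
                "enrich_fdr": self.enrich_fdr,
                "min_overlap_genes": self.min_overlap_genes,
                "trait_p": self.trait_p,
                "min_module_size": self.min_module_size,
                "cut_height": self.cut_height,
            },
            "covariates": list(self.covariates),
        }


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns in-memory results keyed by stage."""
    out = Path(outdir)
    tables = out / "tables"
    inputs = out / "inputs"
    tables.mkdir(parents=True, exist_ok=True)
    inputs.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mirweave")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest = config.manifest_dict()
    manifest["stages"] = {}
    results: dict = {}

    def finish(stage: str) -> None:
        manifest["stages"][stage] = "complete"
        mio.write_manifest(manifest, out / "manifest.json")
        logger.info("stage %s complete", stage)

    try:
        # -- 1. simulate ------------------------------------------------
        stage = "simulate"
        study = simulate_study(config.simulation)
        corpus = study.reference_corpus()
        mio.write_counts(study.gene_counts, inputs / "gene_counts.tsv")
        mio.write_counts(study.mirna_counts, inputs / "mirna_counts_brain.tsv")
        mio.write_counts(study.blood_mirna_counts, inputs / "mirna_counts_blood.tsv")
        mio.write_metadata(study.metadata, inputs / "metadata.csv")
        mio.write_compendium(study.compendium, inputs / "target_compendium.tsv")
        mio.write_gmt(study.gobp, inputs / "gobp_like.gmt")
        mio.write_gmt(study.hallmark, inputs / "hallmark_like.gmt")
        mio.write_term_annotation(study.term_annotation, inputs / "term_annotation.tsv")
        results[stage] = study
        finish(stage)

        # -- 2. differential expression ---------------------------------
        stage = "differential_expression"
        gene_de = classify_de_genes(
            fit_de(study.gene_counts, study.metadata, config.covariates),
            fc_threshold=config.gene_fc,
            q_threshold=config.gene_fdr,
        )
        brain_mirna = screen_de_mirnas(
            fit_de(study.mirna_counts, study.metadata, config.covariates),
            p_threshold=config.mirna_p,
        )
        blood_meta = study.metadata.loc[study.blood_mirna_counts.sample_ids]
        blood_mirna = screen_de_mirnas(
            fit_de(study.blood_mirna_counts, blood_meta, config.covariates),
            p_threshold=config.mirna_p,
        )
        demo = demographics_compare(study.metadata)
        mio.write_table(gene_de, tables / "de_genes.tsv")
        mio.write_table(brain_mirna, tables / "de_mirnas_brain.tsv")
        mio.write_table(blood_mirna, tables / "de_mirnas_blood.tsv")
        mio.write_table(
            pd.DataFrame(
                [{k: v for k, v in demo.items() if k != "sex_table"}]
            ),
            tables / "demographics.tsv",
        )
        results[stage] = dict(
            gene_de=gene_de, brain_mirna=brain_mirna, blood_mirna=blood_mirna, demographics=demo
        )
        finish(stage)

        # -- 3. network integration -------------------------------------
        stage = "network_integration"
        networks = {
            "brain": run_all_modes(brain_mirna, gene_de, study.compendium, config.enrich_fdr),
            "blood": run_all_modes(blood_mirna, gene_de, study.compendium, config.enrich_fdr),
        }
        for tissue, nets in networks.items():
            for mode, net in nets.items():
                mio.write_table(net.regulators, tables / f"regulators_{tissue}_{mode}.tsv")
                mio.write_table(net.edge_frame(), tables / f"edges_{tissue}_{mode}.tsv")
                mio.write_network_sif(net.edges, tables / f"network_{tissue}_{mode}.sif")
        results[stage] = networks
        finish(stage)

        brain_net = networks["brain"]["canonical_up_down"]
        blood_net = networks["blood"]["canonical_up_down"]
        gene_universe = set(gene_de["feature_id"]) & set(study.compendium.universe)

        # -- 4. pathway enrichment --------------------------------------
        stage = "pathway_enrichment"
        measured = set(gene_de["feature_id"])
        pathway_tables = {}
        for tissue, net in (("brain", brain_net), ("blood", blood_net)):
            targets = sorted(net.target_genes & measured)
            if targets:
                tab = pathway_enrichment(
                    targets, study.gobp, measured, config.enrich_fdr, config.min_overlap_genes
                )
            else:
                tab = pd.DataFrame(
                    columns=["pathway", "overlap_k", "set_size", "pvalue", "qvalue",
                             "significant", "member_genes"]
                )
            pathway_tables[tissue] = tab
            mio.write_table(tab, tables / f"pathways_{tissue}.tsv")
        results[stage] = pathway_tables
        finish(stage)

        # -- 5. GO-term meta-enrichment ---------------------------------
        stage = "term_meta_enrichment"
        term_tables = {}
        all_pathways = list(study.gobp.sets)
        for tissue, tab in pathway_tables.items():
            sig = list(tab.loc[tab["significant"], "pathway"])
            meta_tab = go_term_meta_enrichment(
                sig, all_pathways, study.term_annotation, config.enrich_fdr
            )
            term_tables[tissue] = meta_tab
            mio.write_table(meta_tab, tables / f"go_terms_{tissue}.tsv")
        results[stage] = term_tables
        finish(stage)

        # -- 6. coexpression modules ------------------------------------
        stage = "coexpression_modules"
        log2cpm = compute_log2cpm(study.gene_counts)
        module_genes = sorted(brain_net.target_genes)
        if len(module_genes) < config.min_module_genes_for_wgcna:
            # too few network targets to cluster; fall back to DE genes
            module_genes = sorted(gene_de.loc[gene_de["direction"] != "ns", "feature_id"])
        expr = log2cpm.loc[module_genes]
        expr = expr[expr.std(axis=1, ddof=1) > 0]
        power = pick_soft_threshold(expr, config.powers)
        tom = compute_tom(compute_adjacency(expr, power))
        assignment = detect_modules(tom, config.min_module_size, config.cut_height)
        eigengenes, varex = compute_eigengenes(expr, assignment)
        mio.write_table(
            assignment.rename_axis("gene_id").reset_index(), tables / "module_assignment.tsv"
        )
        mio.write_table(eigengenes, tables / "module_eigengenes.tsv", index=True, index_label="module")
        results[stage] = dict(
            assignment=assignment, eigengenes=eigengenes, variance_explained=varex, power=power
        )
        finish(stage)

        # -- 7. deconvolution + trait association -----------------------
        stage = "deconvolution_traits"
        signature = build_signature_matrix(study.truth)
        cpm_linear = pd.DataFrame(
            study.gene_counts.counts.to_numpy(dtype=float)
            / study.gene_counts.lib_sizes.to_numpy(dtype=float)[None, :]
            * 1e6,
            index=study.gene_counts.feature_ids,
            columns=study.gene_counts.sample_ids,
        )
        fractions = deconvolve_fractions(cpm_linear, signature)
        traits = fractions.copy()
        traits["case_status"] = (study.metadata["group"] == "case").astype(float)
        assoc = module_trait_association(eigengenes, traits, config.trait_p)
        mio.write_table(fractions, tables / "cell_fractions.tsv", index=True, index_label="sample_id")
        mio.write_table(assoc, tables / "module_trait_association.tsv")
        results[stage] = dict(fractions=fractions, traits=traits, association=assoc)
        finish(stage)

        # -- 8. signature scores ----------------------------------------
        stage = "signature_scores"
        module_sets = {
            f"module_{m}": frozenset(assignment.index[assignment == m])
            for m in eigengenes.index
        }
        target_sets = {}
        if brain_net.target_genes:
            target_sets["brain_mirna_targets"] = brain_net.target_genes
        if blood_net.target_genes:
            target_sets["blood_mirna_targets"] = blood_net.target_genes
        query = GeneSetCollection({**module_sets, **target_sets})
        hallmark_scores = score_signatures(corpus, study.hallmark, "hallmark_like", "corpus")
        query_scores = score_signatures(corpus, query, "network_sets", "corpus")
        cor_long = correlate_scores(query_scores, hallmark_scores, config.trait_p)
        mio.write_table(cor_long, tables / "signature_correlations.tsv")
        mio.write_table(
            correlation_matrix(cor_long), tables / "signature_correlation_matrix.tsv",
            index=True, index_label="set_a",
        )
        results[stage] = dict(
            hallmark_scores=hallmark_scores, query_scores=query_scores, correlations=cor_long
        )
        finish(stage)

        # -- 9. overlap statistics --------------------------------------
        stage = "overlap_statistics"
        target_overlap = cross_tissue_target_overlap(brain_net, blood_net, gene_universe)
        pw_overlap = pathway_list_overlap(
            list(pathway_tables["brain"].loc[pathway_tables["brain"]["significant"], "pathway"]),
            list(pathway_tables["blood"].loc[pathway_tables["blood"]["significant"], "pathway"]),
            all_pathways,
        )
        brain_cpm = compute_log2cpm(study.mirna_counts)
        blood_cpm = compute_log2cpm(study.blood_mirna_counts)
        xcor = cross_tissue_mirna_correlation(brain_cpm, blood_cpm)
        overlap_rows = pd.DataFrame(
            [
                dict(comparison="target_genes", **vars(target_overlap)),
                dict(comparison="pathways", **vars(pw_overlap)),
            ]
        )
        mio.write_table(overlap_rows, tables / "overlap_statistics.tsv")
        mio.write_table(xcor, tables / "cross_tissue_mirna_correlation.tsv")
        results[stage] = dict(
            target_overlap=target_overlap, pathway_overlap=pw_overlap, mirna_correlation=xcor
        )
        finish(stage)
    except Exception as exc:  # noqa: BLE001 - stage name context matters more
        mio.write_manifest(manifest, out / "manifest.json")
        raise StageFailure(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    return results
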