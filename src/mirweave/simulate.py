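"""Synthetic cohort generator for the miRNA-mRNA network pipeline.

Generates every input the pipeline consumes — gene and miRNA count
matrices for a case/control brain cohort, a matched blood miRNA matrix
for a donor subset, a miRDB-like target compendium, GOBP-like and
Hallmark-like gene-set collections with GO-style term annotations, and
a large reference corpus of control transcriptomes — together with the
ground truth needed to score recovery.

Generative model
----------------
Counts are negative binomial with mean ``mu`` and dispersion ``alpha``
(variance ``mu + alpha mu^2``; ``alpha = 0`` is the Poisson limit),
the standard bulk RNA-seq assumption. Per-sample library sizes are
log-normal with configured mean and coefficient of variation. Effects
are additive on the log2 mean:

* planted regulators: true-regulator miRNAs shift up in cases by
  ``mirna_induction_log2fc``; their (disjoint) target genes shift by
  ``suppression_log2fc`` — the canonical up-miRNA / down-gene
  structure;
* covariate confounding: per-gene Gaussian coefficients on
  standardized Sex/Age/PMI/pH/RIN, with the demographic imbalance
  between arms (sex ratio, age gap) mirroring the study cohort;
* coexpression: each planted module (one per regulator) shares a
  per-sample latent factor, giving the within-module correlation that
  module detection feeds on;
* cell types: marker genes scale with Dirichlet-distributed per-sample
  cell fractions, giving deconvolution a recoverable signal;
* cross-tissue coupling: each miRNA carries a per-donor latent value
  expressed in both brain and blood (blood with configurable loading
  and extra noise), so blood-brain expression correlation of a miRNA
  is a planted, tunable quantity.

Relative abundances are *not* renormalized after planting effects, so
case libraries are slightly lighter than the nominal mean — the usual
compositional footprint of suppressing a slice of the transcriptome.

All randomness flows from ``config.seed`` through fixed per-component
substreams, so each generator is deterministic given the config and
independent of the order generators are called in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, TargetCompendium

# substream indices keyed off config.seed
_STREAM_TRUTH = 0
_STREAM_COMPENDIUM = 1
_STREAM_COUNTS = 2
_STREAM_BLOOD = 3
_STREAM_CORPUS = 4

#: Default per-covariate effect scales (log2 units per covariate SD).
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "Sex": 0.1,
    "Age": 0.1,
    "PMI": 0.05,
    "pH": 0.05,
    "RIN": 0.1,
}

CELL_TYPE_NAMES = ("astrocytes", "neurons", "endothelial", "microglia", "oligodendrocytes")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 15 control vs 27 case brain samples, 2000
    genes, 20 miRNAs of which 5 are planted up-regulated regulators each
    suppressing 40 disjoint target genes by one log2 unit, NB dispersion
    0.1, a 425-sample reference corpus and 50 Hallmark-like sets."""

    n_control: int = 15
    n_case: int = 27
    n_genes: int = 2000
    n_mirnas: int = 20
    n_true_regulators: int = 5
    targets_per_mirna: int = 40
    suppression_log2fc: float = -1.0
    mirna_induction_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    lib_size_mean: int = 2_000_000
    lib_size_cv: float = 0.2
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    n_cell_types: int = 4
    n_marker_genes_per_type: int = 20
    corpus_size: int = 425
    n_pathways: int = 200
    pathway_size_range: tuple[int, int] = (10, 60)
    n_hallmark_sets: int = 50
    n_go_terms: int = 40
    n_target_enriched_pathways: int = 20
    target_pathway_fraction: float = 0.5
    module_factor_sd: float = 0.3
    donor_latent_sd: float = 0.2
    cross_tissue_loading: float = 1.0
    cross_tissue_noise_sd: float = 0.2
    corpus_factor_loading: float = 1.0
    corpus_noise_sd: float = 0.1
    n_blood_control: int = 8
    n_blood_case: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_control": self.n_control,
            "n_case": self.n_case,
            "n_genes": self.n_genes,
            "n_mirnas": self.n_mirnas,
            "targets_per_mirna": self.targets_per_mirna,
            "lib_size_mean": self.lib_size_mean,
            "corpus_size": self.corpus_size,
            "n_pathways": self.n_pathways,
            "n_cell_types": self.n_cell_types,
            "n_marker_genes_per_type": self.n_marker_genes_per_type,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_true_regulators < 0 or self.n_true_regulators > self.n_mirnas:
            raise ValueError("n_true_regulators must be in [0, n_mirnas]")
        if self.targets_per_mirna > self.n_genes:
            raise ValueError("targets_per_mirna cannot exceed n_genes")
        if self.targets_per_mirna * self.n_true_regulators > self.n_genes:
            raise ValueError("planted target sets exceed the gene universe")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0 (0 = Poisson)")
        if self.lib_size_cv < 0:
            raise ValueError("lib_size_cv must be >= 0")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ValueError("pathway_size_range must satisfy 2 <= min <= max")
        if self.corpus_size < 3:
            raise ValueError("corpus_size must be >= 3")
        if self.n_blood_control > self.n_control or self.n_blood_case > self.n_case:
            raise ValueError("blood subset cannot exceed the cohort")

    @classmethod
    def null(cls, **overrides) -> "SimulationConfig":
        """A configuration with every planted effect switched off.

        Used for type-I-error calibration: no regulator effects, no
        covariate effects, no module factors, no cross-tissue latent.
        """
        base = dict(
            suppression_log2fc=0.0,
            mirna_induction_log2fc=0.0,
            covariate_effects={},
            module_factor_sd=0.0,
            donor_latent_sd=0.0,
            corpus_factor_loading=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]
    true_regulators: tuple[str, ...]
    true_targets: dict[str, frozenset[str]]
    true_de_genes: dict[str, float]
    mirna_effects: dict[str, float]
    planted_module_labels: dict[str, str]
    marker_genes: dict[str, tuple[str, ...]]
    cell_fractions: pd.DataFrame
    pathway_membership: dict[str, frozenset[str]]
    hallmark_names: tuple[str, ...]
    gobp_names: tuple[str, ...]
    term_annotation: dict[str, frozenset[str]]
    base_log2_gene: pd.Series
    base_log2_mirna: pd.Series
    donor_latent: pd.DataFrame  # miRNAs x samples

    @property
    def all_target_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.true_targets.values():
            out |= genes
        return frozenset(out)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def make_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted structure shared by every generator below."""
    rng = _rng(config, _STREAM_TRUTH)
    genes = tuple(f"G{i:05d}" for i in range(config.n_genes))
    mirnas = tuple(f"miR-{i + 1:03d}-5p" for i in range(config.n_mirnas))
    samples = tuple(
        [f"CTRL{i + 1:02d}" for i in range(config.n_control)]
        + [f"CASE{i + 1:02d}" for i in range(config.n_case)]
    )
    groups = tuple(["control"] * config.n_control + ["case"] * config.n_case)

    regulators = tuple(
        sorted(rng.choice(config.n_mirnas, size=config.n_true_regulators, replace=False))
    )
    regulator_ids = tuple(mirnas[i] for i in regulators)

    perm = rng.permutation(config.n_genes)
    true_targets: dict[str, frozenset[str]] = {}
    planted_module_labels: dict[str, str] = {}
    cursor = 0
    for j, mid in enumerate(regulator_ids):
        block = perm[cursor : cursor + config.targets_per_mirna]
        cursor += config.targets_per_mirna
        members = frozenset(genes[i] for i in block)
        true_targets[mid] = members
        for g in members:
            planted_module_labels[g] = f"module{j + 1}"
    target_genes = frozenset(planted_module_labels)

    true_de = {g: config.suppression_log2fc for g in target_genes}
    mirna_effects = {m: config.mirna_induction_log2fc for m in regulator_ids}

    # cell-type markers drawn outside the planted target genes
    cell_types = tuple(CELL_TYPE_NAMES[i] for i in range(min(config.n_cell_types, len(CELL_TYPE_NAMES))))
    if config.n_cell_types > len(CELL_TYPE_NAMES):
        cell_types = cell_types + tuple(
            f"celltype{i + 1}" for i in range(len(CELL_TYPE_NAMES), config.n_cell_types)
        )
    marker_genes: dict[str, tuple[str, ...]] = {}
    for t, ctype in enumerate(cell_types):
        block = perm[cursor : cursor + config.n_marker_genes_per_type]
        cursor += config.n_marker_genes_per_type
        if len(block) < config.n_marker_genes_per_type:
            raise ValueError("not enough genes for cell-type markers after planting targets")
        marker_genes[ctype] = tuple(genes[i] for i in block)

    alpha = np.linspace(8.0, 2.0, num=len(cell_types))
    fractions = rng.dirichlet(alpha, size=len(samples))
    cell_fractions = pd.DataFrame(fractions, index=list(samples), columns=list(cell_types))

    base_gene = pd.Series(rng.normal(0.0, 1.5, size=config.n_genes), index=list(genes))
    base_mirna = pd.Series(rng.normal(0.0, 1.0, size=config.n_mirnas), index=list(mirnas))

    donor_latent = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(config.n_mirnas, len(samples))),
        index=list(mirnas),
        columns=list(samples),
    )

    # gene-set memberships: GOBP-like (with a target-enriched slice) and
    # Hallmark-like (drawn outside the planted targets)
    lo, hi = config.pathway_size_range
    non_target = np.array([g for g in genes if g not in target_genes])
    target_arr = np.array(sorted(target_genes))
    membership: dict[str, frozenset[str]] = {}
    gobp_names = []
    n_enriched = min(config.n_target_enriched_pathways, config.n_pathways)
    for i in range(config.n_pathways):
        name = f"GOBP_PATHWAY_{i + 1:04d}"
        gobp_names.append(name)
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched and len(target_arr) > 0:
            k_t = min(len(target_arr), max(2, int(round(size * config.target_pathway_fraction))))
            pick_t = rng.choice(target_arr, size=k_t, replace=False)
            pick_r = rng.choice(non_target, size=size - k_t, replace=False)
            members = frozenset(pick_t) | frozenset(pick_r)
        else:
            members = frozenset(rng.choice(genes, size=size, replace=False))
        membership[name] = members
    hallmark_names = []
    for i in range(config.n_hallmark_sets):
        name = f"HALLMARK_SET_{i + 1:02d}"
        hallmark_names.append(name)
        size = int(rng.integers(lo, hi + 1))
        size = min(size, len(non_target))
        membership[name] = frozenset(rng.choice(non_target, size=size, replace=False))

    # GO-style term annotation: target-enriched pathways preferentially
    # carry the first few terms so term meta-enrichment has planted signal
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    n_sig_terms = min(5, config.n_go_terms)
    annotation: dict[str, frozenset[str]] = {}
    for i, name in enumerate(gobp_names):
        picked: set[str] = set()
        n_terms = int(rng.integers(1, 4))
        if i < n_enriched and n_sig_terms:
            picked.add(terms[int(rng.integers(0, n_sig_terms))])
        while len(picked) < n_terms:
            picked.add(terms[int(rng.integers(0, config.n_go_terms))])
        annotation[name] = frozenset(picked)

    return GroundTruth(
        gene_ids=genes,
        mirna_ids=mirnas,
        sample_ids=samples,
        groups=groups,
        true_regulators=regulator_ids,
        true_targets=true_targets,
        true_de_genes=true_de,
        mirna_effects=mirna_effects,
        planted_module_labels=planted_module_labels,
        marker_genes=marker_genes,
        cell_fractions=cell_fractions,
        pathway_membership=membership,
        hallmark_names=tuple(hallmark_names),
        gobp_names=tuple(gobp_names),
        term_annotation=annotation,
        base_log2_gene=base_gene,
        base_log2_mirna=base_mirna,
        donor_latent=donor_latent,
    )


def generate_target_compendium(config: SimulationConfig, truth: GroundTruth) -> TargetCompendium:
    """miRDB-like predicted-target map.

    True regulators keep their planted target set plus an equal number
    of uniformly drawn decoy targets; non-regulator miRNAs get purely
    random target sets of the same total size, which makes them an
    exact null for enrichment calibration.
    """
    rng = _rng(config, _STREAM_COMPENDIUM)
    genes = np.array(truth.gene_ids)
    per_mirna = min(2 * config.targets_per_mirna, config.n_genes)
    targets: dict[str, frozenset[str]] = {}
    for mid in truth.mirna_ids:
        if mid in truth.true_targets:
            planted = truth.true_targets[mid]
            pool = np.array([g for g in genes if g not in planted])
            n_decoy = min(per_mirna - len(planted), len(pool))
            decoys = rng.choice(pool, size=n_decoy, replace=False)
            targets[mid] = planted | frozenset(decoys)
        else:
            targets[mid] = frozenset(rng.choice(genes, size=per_mirna, replace=False))
    return TargetCompendium(targets)


def _lognormal_lib_sizes(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2; alpha=0 is Poisson."""
    mu = np.clip(mu, 1e-12, None)
    if alpha <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def simulate_metadata(config: SimulationConfig, truth: GroundTruth,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Demographics with study-like confounding: controls skew male
    (87% vs 56%) and older (55 +/- 14 vs 39 +/- 13 years)."""
    rows = []
    for sid, grp in zip(truth.sample_ids, truth.groups):
        if grp == "control":
            sex = "M" if rng.random() < 0.87 else "F"
            age = rng.normal(55.0, 14.0)
            pmi = rng.normal(29.0, 7.0)
        else:
            sex = "M" if rng.random() < 0.56 else "F"
            age = rng.normal(39.0, 13.0)
            pmi = rng.normal(26.0, 9.0)
        rows.append(
            dict(
                sample_id=sid,
                group=grp,
                Sex=sex,
                Age=float(np.clip(age, 18.0, 90.0)),
                PMI=float(np.clip(pmi, 2.0, 60.0)),
                pH=float(rng.normal(6.5, 0.25)),
                RIN=float(np.clip(rng.normal(7.5, 0.8), 4.0, 10.0)),
            )
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _covariate_design(meta: pd.DataFrame, covariates) -> pd.DataFrame:
    """Standardized numeric covariate columns (Sex coded M=1/F=0)."""
    cols = {}
    for c in covariates:
        v = meta[c]
        if c == "Sex":
            v = (v == "M").astype(float)
        v = v.astype(float)
        sd = v.std(ddof=0)
        cols[c] = (v - v.mean()) / sd if sd > 0 else v * 0.0
    return pd.DataFrame(cols, index=meta.index)


def simulate_paired_counts(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Brain gene and miRNA count matrices plus sample metadata."""
    if len(truth.gene_ids) != config.n_genes or len(truth.mirna_ids) != config.n_mirnas:
        raise ValueError("ground truth dimensions do not match the config")
    rng = _rng(config, _STREAM_COUNTS)
    meta = simulate_metadata(config, truth, rng)
    n_samples = len(truth.sample_ids)
    is_case = np.array([g == "case" for g in truth.groups], dtype=float)

    design = _covariate_design(meta, list(config.covariate_effects))
    log2mu = np.tile(truth.base_log2_gene.to_numpy()[:, None], (1, n_samples))

    for c, scale in config.covariate_effects.items():
        betas = rng.normal(0.0, scale, size=config.n_genes)
        log2mu += betas[:, None] * design[c].to_numpy()[None, :]

    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    for g, lfc in truth.true_de_genes.items():
        log2mu[gene_index[g]] += lfc * is_case

    if config.module_factor_sd > 0 and truth.planted_module_labels:
        # within-group centering keeps module coexpression orthogonal to
        # the planted group effect, so realized fold changes stay honest
        grp_masks = [is_case == 1.0, is_case == 0.0]
        labels = sorted(set(truth.planted_module_labels.values()))
        for lab in labels:
            f = rng.normal(0.0, config.module_factor_sd, size=n_samples)
            for mask in grp_masks:
                f[mask] -= f[mask].mean()
            for g, gl in truth.planted_module_labels.items():
                if gl == lab:
                    log2mu[gene_index[g]] += f

    mean_frac = truth.cell_fractions.mean(axis=0)
    for ctype, markers in truth.marker_genes.items():
        frac = truth.cell_fractions.loc[list(truth.sample_ids), ctype].to_numpy()
        shift = np.log2(np.clip(frac, 1e-6, None) / mean_frac[ctype])
        for g in markers:
            log2mu[gene_index[g]] += shift

    rel = np.exp2(log2mu)
    base_total = float(np.exp2(truth.base_log2_gene.to_numpy()).sum())
    libs = _lognormal_lib_sizes(rng, n_samples, config.lib_size_mean, config.lib_size_cv)
    mu = rel / base_total * libs[None, :]
    gene_counts = _nb_draw(rng, mu, config.nb_dispersion)
    gene_cm = CountMatrix(
        pd.DataFrame(gene_counts, index=list(truth.gene_ids), columns=list(truth.sample_ids))
    )

    # miRNA matrix: baseline + induction in cases + per-donor latent
    log2m = np.tile(truth.base_log2_mirna.to_numpy()[:, None], (1, n_samples))
    mirna_index = {m: i for i, m in enumerate(truth.mirna_ids)}
    for m, lfc in truth.mirna_effects.items():
        log2m[mirna_index[m]] += lfc * is_case
    if config.donor_latent_sd > 0:
        log2m += config.donor_latent_sd * truth.donor_latent.to_numpy()
    relm = np.exp2(log2m)
    basem_total = float(np.exp2(truth.base_log2_mirna.to_numpy()).sum())
    libs_m = _lognormal_lib_sizes(rng, n_samples, config.lib_size_mean, config.lib_size_cv)
    mum = relm / basem_total * libs_m[None, :]
    mirna_counts = _nb_draw(rng, mum, config.nb_dispersion)
    mirna_cm = CountMatrix(
        pd.DataFrame(mirna_counts, index=list(truth.mirna_ids), columns=list(truth.sample_ids))
    )
    return gene_cm, mirna_cm, meta


def simulate_blood_mirnas(config: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """Blood miRNA counts for the donor subset with blood available.

    Shares the per-donor latent with the brain matrix (scaled by
    ``cross_tissue_loading`` plus noise ``cross_tissue_noise_sd``), so a
    miRNA's blood-brain correlation across shared donors is planted.
    Regulator induction is systemic: the same miRNAs shift up in blood.
    """
    rng = _rng(config, _STREAM_BLOOD)
    controls = [s for s, g in zip(truth.sample_ids, truth.groups) if g == "control"]
    cases = [s for s, g in zip(truth.sample_ids, truth.groups) if g == "case"]
    samples = controls[: config.n_blood_control] + cases[: config.n_blood_case]
    is_case = np.array([s in cases for s in samples], dtype=float)

    tissue_shift = rng.normal(0.0, 0.5, size=config.n_mirnas)
    log2m = np.tile(
        (truth.base_log2_mirna.to_numpy() + tissue_shift)[:, None], (1, len(samples))
    )
    mirna_index = {m: i for i, m in enumerate(truth.mirna_ids)}
    for m, lfc in truth.mirna_effects.items():
        log2m[mirna_index[m]] += lfc * is_case
    latent = truth.donor_latent.loc[:, samples].to_numpy()
    log2m = log2m + config.donor_latent_sd * config.cross_tissue_loading * latent
    if config.cross_tissue_noise_sd > 0:
        log2m = log2m + rng.normal(0.0, config.cross_tissue_noise_sd, size=log2m.shape)

    relm = np.exp2(log2m)
    base_total = float(np.exp2(truth.base_log2_mirna.to_numpy() + tissue_shift).sum())
    libs = _lognormal_lib_sizes(rng, len(samples), config.lib_size_mean, config.lib_size_cv)
    mum = relm / base_total * libs[None, :]
    counts = _nb_draw(rng, mum, config.nb_dispersion)
    return CountMatrix(pd.DataFrame(counts, index=list(truth.mirna_ids), columns=samples))


def simulate_reference_corpus(config: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """Control-like reference corpus (GTEx-style) for signature scoring.

    Each Hallmark-like set k loads on latent factor k with loading
    ``corpus_factor_loading``; planted module m shares the factor of
    Hallmark set m, so module/pathway signature-score correlation over
    the corpus is a planted, recoverable quantity.
    """
    rng = _rng(config, _STREAM_CORPUS)
    n = config.corpus_size
    n_factors = max(1, config.n_hallmark_sets)
    factors = rng.normal(0.0, 1.0, size=(n_factors, n))

    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    loadings = np.zeros((config.n_genes, n_factors))
    if config.corpus_factor_loading != 0:
        for k, name in enumerate(truth.hallmark_names):
            for g in truth.pathway_membership[name]:
                loadings[gene_index[g], k % n_factors] = config.corpus_factor_loading
        module_names = sorted(set(truth.planted_module_labels.values()))
        for m, lab in enumerate(module_names):
            for g, gl in truth.planted_module_labels.items():
                if gl == lab:
                    loadings[gene_index[g], m % n_factors] = config.corpus_factor_loading

    log2mu = truth.base_log2_gene.to_numpy()[:, None] + loadings @ factors
    if config.corpus_noise_sd > 0:
        log2mu = log2mu + rng.normal(0.0, config.corpus_noise_sd, size=log2mu.shape)
    rel = np.exp2(log2mu)
    base_total = float(np.exp2(truth.base_log2_gene.to_numpy()).sum())
    libs = _lognormal_lib_sizes(rng, n, config.lib_size_mean, config.lib_size_cv)
    mu = rel / base_total * libs[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    samples = [f"REF{i + 1:04d}" for i in range(n)]
    return CountMatrix(pd.DataFrame(counts, index=list(truth.gene_ids), columns=samples))


def generate_geneset_collections(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[GeneSetCollection, GeneSetCollection, dict[str, frozenset[str]]]:
    """Package the planted memberships as GMT-writable collections.

    Returns ``(gobp_like, hallmark_like, term_annotation)``; every
    GOBP-like pathway carries at least one GO-style term id.
    """
    gobp = GeneSetCollection(
        {n: truth.pathway_membership[n] for n in truth.gobp_names},
        {n: "synthetic GOBP-like pathway" for n in truth.gobp_names},
    )
    hallmark = GeneSetCollection(
        {n: truth.pathway_membership[n] for n in truth.hallmark_names},
        {n: "synthetic Hallmark-like pathway" for n in truth.hallmark_names},
    )
    return gobp, hallmark, dict(truth.term_annotation)


def simulate_coexpression_blocks(
    block_sizes,
    n_samples: int,
    within_cor: float = 0.8,
    n_noise: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Block-structured expression for module-detection benchmarks.

    Genes in block b are ``sqrt(rho) f_b + sqrt(1-rho) eps`` with a
    shared standard-normal factor per block, so the within-block
    correlation is ``rho = within_cor``; noise genes are independent.

    Returns the expression frame (genes x samples) and the true label
    map (noise genes labelled ``"grey"``).
    """
    if not 0 <= within_cor < 1:
        raise ValueError("within_cor must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    ids = []
    for b, size in enumerate(block_sizes):
        f = rng.normal(size=n_samples)
        for j in range(size):
            gid = f"B{b + 1:02d}_{j + 1:03d}"
            rows.append(np.sqrt(within_cor) * f + np.sqrt(1 - within_cor) * rng.normal(size=n_samples))
            labels[gid] = f"block{b + 1}"
            ids.append(gid)
    for j in range(n_noise):
        gid = f"NOISE_{j + 1:03d}"
        rows.append(rng.normal(size=n_samples))
        labels[gid] = "grey"
        ids.append(gid)
    return pd.DataFrame(np.array(rows), index=ids, columns=[f"S{i + 1:03d}" for i in range(n_samples)]), labels


@dataclass
class StudyData:
    """One fully simulated study: all pipeline inputs plus ground truth."""

    config: SimulationConfig
    truth: GroundTruth
    compendium: TargetCompendium
    gene_counts: CountMatrix
    mirna_counts: CountMatrix
    blood_mirna_counts: CountMatrix
    metadata: pd.DataFrame
    gobp: GeneSetCollection
    hallmark: GeneSetCollection
    term_annotation: dict[str, frozenset[str]]

    def reference_corpus(self) -> CountMatrix:
        """Corpus generation is deferred — it is the largest matrix."""
        return simulate_reference_corpus(self.config, self.truth)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate every pipeline input for one configuration."""
    truth = make_ground_truth(config)
    compendium = generate_target_compendium(config, truth)
    gene_cm, mirna_cm, meta = simulate_paired_counts(config, truth)
    blood_cm = simulate_blood_mirnas(config, truth)
    gobp, hallmark, annotation = generate_geneset_collections(config, truth)
    return StudyData(
        config=config,
        truth=truth,
        compendium=compendium,
        gene_counts=gene_cm,
        mirna_counts=mirna_cm,
        blood_mirna_counts=blood_cm,
        metadata=meta,
        gobp=gobp,
        hallmark=hallmark,
        term_annotation=annotation,
    )
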