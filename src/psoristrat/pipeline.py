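"""End-to-end orchestration of the stratification pipeline.

simulate (or load) -> pairwise DE + core set -> two-class PN/PP forest ->
unsupervised RF subgrouping of PP -> four-class re-classification ->
clinical association -> per-subgroup networks + MCL + enrichment.

Stage functions live in their own modules; this wires them together the
way the command-line ``report`` subcommand and the acceptance script run
them.
"""

from __future__ import annotations

import numpy as np

from . import de, network, stratify
from .forest import GiniForestClassifier
from .io import PipelineConfig
from .simulate import CohortDesign, generate_cohort, truth_report


def run_de_stage(matrix, classes, config):
    """Three pairwise comparisons plus the core intersection."""
    tables, selected = {}, {}
    for a, b in (("NN", "PN"), ("PN", "PP"), ("NN", "PP")):
        key = f"{a}_vs_{b}"
        tables[key], selected[key] = de.run_pairwise_de(
            matrix, classes, a, b, alpha=config.de_alpha, fdr=config.de_fdr,
            top_k=config.de_top_k)
    core = de.intersect_core(
        [selected["NN_vs_PN"], selected["PN_vs_PP"], selected["NN_vs_PP"]],
        tables["NN_vs_PP"])
    return tables, selected, core


def run_pipeline(config: PipelineConfig = None, design: CohortDesign = None,
                 seed=None, skip_permutation_null=True):
    """Run the full pipeline on a synthetic cohort; returns a result dict.

    The lesional signature (the NN-vs-PP selected set) is the feature
    space for subgrouping: it contains every gene with lesional-specific
    behaviour, including genes that vary between lesional subgroups and
    therefore cannot reach the three-way core.
    """
    config = config or PipelineConfig()
    if seed is not None:
        config = PipelineConfig(**{**config.to_dict(), "rng_seed": seed})
    design = design or CohortDesign(seed=config.rng_seed)
    matrix, annotations, truth = generate_cohort(design)
    classes = np.array([a.tissue_class for a in annotations])
    sample_ids = np.array(matrix.sample_ids)

    tables, selected, core = run_de_stage(matrix, classes, config)
    lesional_signature = selected["NN_vs_PP"]

    # two-class PN vs PP forest on the lesional signature
    pnpp_mask = np.isin(classes, ["PN", "PP"])
    sig_matrix = matrix.subset(feature_ids=lesional_signature)
    two_class = GiniForestClassifier(
        n_trees=config.n_trees, mtry=config.mtry,
        random_state=config.rng_seed).fit(
            sig_matrix.values[:, pnpp_mask].T, classes[pnpp_mask])

    # unsupervised subgrouping of PP samples on the lesional signature
    pp_mask = classes == "PP"
    partition, dissim, embedding = stratify.stratify_samples(
        sig_matrix.values[:, pp_mask].T, sample_ids=list(sample_ids[pp_mask]),
        k=config.k_subgroups, n_trees=config.n_trees,
        reference_mode=config.reference_mode,
        transform=config.dissimilarity_transform, seed=config.rng_seed)

    # four-class re-classification on the full matrix
    four_labels = classes.copy().astype(object)
    for sid, lab in partition.labels.items():
        four_labels[sample_ids == sid] = lab
    four_model, importance, top_genes = stratify.classify_four_groups(
        matrix.values.T, four_labels, n_trees=config.n_trees, mtry=config.mtry,
        seed=config.rng_seed, feature_ids=matrix.feature_ids)

    assoc = stratify.clinical_association(
        partition.labels, annotations,
        ["PASI", "BMI", "age_of_onset", "age", "BSA"])

    # per-subgroup co-expression networks over the lesional signature
    networks, cluster_sets = {}, {}
    for grp in sorted(set(partition.labels.values())):
        grp_samples = [s for s, l in partition.labels.items() if l == grp]
        block = sig_matrix.subset(sample_ids=grp_samples)
        corr = network.pearson_matrix(block.values, gene_ids=block.feature_ids)
        G = network.build_coexpression_network(
            corr, threshold=config.corr_threshold, subgroup=grp)
        networks[grp] = G
        cluster_sets[grp] = network.mcl_cluster(
            G, inflation=config.mcl_inflation, expansion=config.mcl_expansion)

    report = truth_report(truth, recovered_genes=lesional_signature,
                          recovered_partition=partition.labels)
    return {
        "config": config, "design": design, "matrix": matrix,
        "annotations": annotations, "truth": truth, "classes": classes,
        "de_tables": tables, "de_selected": selected, "core": core,
        "lesional_signature": lesional_signature, "two_class_model": two_class,
        "partition": partition, "dissimilarity": dissim,
        "embedding": embedding, "four_class_model": four_model,
        "importance": importance, "top_genes": top_genes,
        "clinical": assoc, "networks": networks, "mcl_clusters": cluster_sets,
        "truth_report": report,
    }
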