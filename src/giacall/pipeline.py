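"""Orchestration of the full ancestry-inference workflow for one query.

The workflow runs one query at a time: panel preparation (sample exclusion
and relatedness pruning) is done once, then each query is merged with the
panel, the merged matrix is MAF/HWE-filtered and LD-pruned, principal
components are computed jointly for references plus the query, and the
three classifiers feed the consensus rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .admixture import AdmixtureModel, em_fractions, fit_model
from .classify import correlation_classify, knn_classify
from .config import WorkflowConfig
from .consensus import ConsensusResult, consensus_call
from .genotype_io import GenotypeMatrix, ReferencePanel
from .ld import ld_prune
from .pca import PCScores, compute_pcs
from .qc import apply_variant_filters, exclude_samples, prune_related


@dataclass
class InferenceReport:
    """Everything the workflow produces for one query sample."""

    sample_id: str
    result: ConsensusResult
    pc_scores: PCScores
    model: AdmixtureModel
    stage_counts: dict[str, int] = field(default_factory=dict)


def prepare_panel(panel: ReferencePanel,
                  cfg: WorkflowConfig) -> ReferencePanel:
    """Sample-level panel QC: exclusion list, then relatedness pruning."""
    if cfg.excluded_samples:
        panel = exclude_samples(panel, set(cfg.excluded_samples))
    return prune_related(panel, cfg)


def infer_ancestry(query: GenotypeMatrix, panel: ReferencePanel,
                   cfg: WorkflowConfig,
                   panel_prepared: bool = False) -> InferenceReport:
    """Run merge -> filters -> LD prune -> joint PCA -> three classifiers
    -> consensus for a single query sample."""
    from .genotype_io import merge_query_with_panel

    if not panel_prepared:
        panel = prepare_panel(panel, cfg)
    query_id = query.samples[0]
    counts = {"panel_samples": panel.genotypes.n_samples,
              "panel_variants": panel.genotypes.n_variants,
              "query_variants": query.n_variants}

    merged = merge_query_with_panel(query, panel)
    counts["merged_variants"] = merged.n_variants
    filtered = apply_variant_filters(merged, cfg)
    counts["after_maf_hwe"] = filtered.n_variants
    prune = ld_prune(filtered, cfg)
    pruned = filtered.subset_variants(prune.kept)
    counts["after_ld_prune"] = pruned.n_variants

    pcs = compute_pcs(pruned, cfg)
    ref_ids = list(panel.genotypes.samples)
    ref_scores = pcs.subset(ref_ids)
    query_score = pcs.row(query_id)

    knn = knn_classify(ref_scores, panel.labels, query_score, cfg)
    corr = correlation_classify(ref_scores, panel.labels, query_score, cfg)

    ref_pruned = ReferencePanel(genotypes=pruned.subset_samples(ref_ids),
                                labels=dict(panel.labels))
    model = fit_model(ref_pruned, cfg)
    qrow = pruned.dosages[pruned.samples.index(query_id)]
    fractions = em_fractions(qrow, model, cfg)

    result = consensus_call(knn, corr, fractions, model, cfg)
    return InferenceReport(sample_id=query_id, result=result, pc_scores=pcs,
                           model=model, stage_counts=counts)
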