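"""Shared fixtures: hand-built toy datasets and seeded simulation scenarios.

The heavier simulation chains (signaling recovery, DE calibration) are
session-scoped so that unit, property, and acceptance tests share one run.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spotlink.config import PipelineConfig
from spotlink.dataset import SpotDataset
from spotlink.diffexp import nb_wald_test, pseudobulk
from spotlink.preprocess import (attach_clusters, filter_low_quality_spots,
                                 filter_rare_genes, normalize_logcpm)
from spotlink.regulon import aucell_scores, build_modules, \
    coexpression_importance
from spotlink.signaling import run_interaction_analysis, \
    score_network_recovery
from spotlink.synthetic import (SimulationParams, generate_tissue,
                                lr_reference_from_truth, null_cohort_params,
                                truth_to_annotations)


def make_dataset(counts, gene_ids=None, rows=None, cols=None,
                 sample_id="s1", group="A", cluster=None):
    """Small hand-built SpotDataset with valid hex coordinates."""
    counts = np.asarray(counts)
    n_genes, n_spots = counts.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    if rows is None:
        rows = [0] * n_spots
        cols = [2 * j for j in range(n_spots)]
    obs = pd.DataFrame({
        "array_row": rows, "array_col": cols,
        "sample_id": sample_id, "group": group,
        "cluster": cluster if cluster is not None else pd.NA,
        "compartment": pd.NA,
    }, index=pd.Index([f"{sample_id}_sp{j}" for j in range(n_spots)],
                      name="barcode"))
    return SpotDataset(counts, np.array(gene_ids, dtype=object), obs)


@pytest.fixture
def toy_dataset():
    counts = np.array([[5, 0, 3, 1],
                       [0, 0, 0, 0],
                       [2, 8, 1, 9]])
    return make_dataset(counts)


@pytest.fixture(scope="session")
def signaling_scenario():
    """Default two-sample simulation carried through the full chain."""
    params = SimulationParams(n_samples_per_group=(1, 1))
    ds, truth = generate_tissue(params, seed=1)
    ds = filter_low_quality_spots(ds, 250)
    ds = attach_clusters(ds, truth_to_annotations(truth).loc[ds.obs.index])
    norm = normalize_logcpm(ds)
    imp = coexpression_importance(norm, ds.gene_ids, truth.tf_list, seed=7)
    prior = {r.tf: r.targets for r in truth.planted_regulons}
    config = PipelineConfig()
    regs = build_modules(imp, config.importance_percentile,
                         config.min_module_genes, prior=prior)
    act = aucell_scores(norm, ds.gene_ids, regs, list(ds.obs.index),
                        config.aucell_top_fraction, seed=3)
    lr = lr_reference_from_truth(truth)
    nets = run_interaction_analysis(ds, act, regs, lr, config)
    precision, recall = score_network_recovery(nets, truth)
    return {"ds": ds, "truth": truth, "norm": norm, "regulons": regs,
            "activity": act, "lr": lr, "networks": nets,
            "precision": precision, "recall": recall, "config": config}


@pytest.fixture(scope="session")
def null_de_result():
    """Pseudo-bulk DE on a cohort with nothing planted (6 vs 6, 2000 genes)."""
    ds, truth = generate_tissue(null_cohort_params(), seed=11)
    ds = filter_low_quality_spots(ds, 250)
    ds = attach_clusters(ds, truth_to_annotations(truth).loc[ds.obs.index])
    ds = filter_rare_genes(ds, 0.025)
    return nb_wald_test(pseudobulk(ds, "tumor"))


@pytest.fixture(scope="session")
def planted_de_scenario():
    """Cohort with 60 genes planted at log2FC = ±2 between groups."""
    params = SimulationParams(
        n_samples_per_group=(6, 6), grid_rows=16, grid_cols=24,
        n_genes=2000, n_regulons=0, n_decoy_tfs=0, n_decoy_receptors=0,
        n_de_genes=60, n_signature_genes=0, n_markers_per_domain=0)
    ds, truth = generate_tissue(params, seed=5)
    ds = filter_low_quality_spots(ds, 250)
    ds = attach_clusters(ds, truth_to_annotations(truth).loc[ds.obs.index])
    ds = filter_rare_genes(ds, 0.025)
    res = nb_wald_test(pseudobulk(ds, "tumor"))
    return {"result": res, "truth": truth}
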