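"""Ligand→receptor→TF-module signaling networks between adjacent clusters.

For each sample and each spatially adjacent (sender, receiver) cluster
pair, the chain is: subset the region to the two clusters, drop genes below
the detection floor within the region, correlate each TF module's per-spot
activity with z-scaled receptor expression over the region spots, zero out
receptors targeted by the module's own TF, keep links whose Pearson r
strictly exceeds the threshold, and finally require a cognate ligand
detected in the sender cluster. Every surviving (ligand, receptor, module)
triple becomes one directed edge.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .dataset import LRReference, SpotDataset
from .errors import SpotlinkError, ValidationError
from .preprocess import (adjacent_cluster_pairs, build_neighbor_graph,
                         filter_rare_genes, normalize_logcpm, subset_region)
from .regulon import ActivityMatrix, Regulon
from .synthetic import SyntheticTruth

log = logging.getLogger(__name__)

MIN_REGION_SPOTS = 10


@dataclass(frozen=True)
class SignalingEdge:
    sender_cluster: str
    receiver_cluster: str
    ligand: str
    receptor: str
    tf_module: str
    pearson_r: float


@dataclass
class SignalingNetwork:
    """Edges plus the analyzed region and the config snapshot."""

    edges: list[SignalingEdge]
    region: set[str]
    config_snapshot: dict = field(default_factory=dict)
    receptor_zscore_mean: dict[str, float] = field(default_factory=dict)
    exclusions: list[dict] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        """Distinct (receptor, tf_module) links."""
        return {(e.receptor, e.tf_module) for e in self.edges}

    def validate_rules(self, regulons: Sequence[Regulon],
                       corr_threshold: float) -> None:
        targets = {r.tf: set(r.targets) for r in regulons}
        for e in self.edges:
            if not e.pearson_r > corr_threshold:
                raise ValidationError(
                    f"edge {e} violates r > {corr_threshold}")
            if e.receptor in targets.get(e.tf_module, set()):
                raise ValidationError(
                    f"edge {e} has a receptor targeted by its TF")


# ---------------------------------------------------------------------------
# stage operations

def receptor_module_correlation(activity: ActivityMatrix,
                                norm_matrix: np.ndarray,
                                gene_ids: Sequence[str],
                                receptors: Sequence[str],
                                region_spot_idx: np.ndarray,
                                spot_ids: Sequence[str]
                                ) -> tuple[pd.DataFrame, list[str]]:
    """Pearson r between module activity and z-scaled receptor expression.

    Both sides are evaluated over the region spots only; receptor
    expression is z-scaled within the region, module activity enters as raw
    AUC scores. Zero-variance receptors or modules yield r = 0 and are
    flagged. Returns (receptors × modules matrix, flagged receptor list).
    """
    region_spot_idx = np.asarray(region_spot_idx, dtype=int)
    if len(region_spot_idx) < MIN_REGION_SPOTS:
        raise SpotlinkError(
            f"region has {len(region_spot_idx)} spots "
            f"(< {MIN_REGION_SPOTS}); correlation is meaningless")
    gi = {g: i for i, g in enumerate(gene_ids)}
    missing = [r for r in receptors if r not in gi]
    if missing:
        raise ValidationError(f"receptors not in matrix: {missing[:5]}")
    region_cols = [spot_ids[i] for i in region_spot_idx]
    act = activity.scores[region_cols].to_numpy(dtype=float)
    expr = np.asarray(norm_matrix, dtype=float)[
        [gi[r] for r in receptors]][:, region_spot_idx]

    # constant vectors (including numerically-constant ones) are flagged
    # and forced to r = 0 exactly rather than leaking rounding noise
    const_r = (expr == expr[:, :1]).all(axis=1)
    flagged = [r for r, c in zip(receptors, const_r) if c]
    mu, sd = expr.mean(axis=1, keepdims=True), expr.std(axis=1, keepdims=True)
    sd[const_r, :] = 0.0
    z = np.where(sd > 0, (expr - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    const_a = (act == act[:, :1]).all(axis=1)
    a_mu = act.mean(axis=1, keepdims=True)
    a_sd = act.std(axis=1, keepdims=True)
    a_sd[const_a, :] = 0.0
    az = np.where(a_sd > 0, (act - a_mu) / np.where(a_sd > 0, a_sd, 1.0), 0.0)
    n = len(region_spot_idx)
    corr = (z @ az.T) / n
    corr[const_r, :] = 0.0
    corr[:, const_a] = 0.0
    out = pd.DataFrame(corr, index=list(receptors),
                       columns=list(activity.scores.index))
    return out, flagged


def prune_targeted_receptors(corr_matrix: pd.DataFrame,
                             regulons: Sequence[Regulon]) -> pd.DataFrame:
    """Set r to exactly 0 wherever the receptor is a target of the TF."""
    out = corr_matrix.copy()
    targets = {r.tf: set(r.targets) for r in regulons}
    for tf in out.columns:
        tset = targets.get(tf, set())
        hit = [rec for rec in out.index if rec in tset]
        if hit:
            out.loc[hit, tf] = 0.0
    return out


def link_receptors(corr_matrix: pd.DataFrame,
                   corr_threshold: float = 0.3) -> list[tuple[str, str, float]]:
    """(receptor, module, r) candidates with r strictly above the threshold."""
    links = []
    vals = corr_matrix.to_numpy()
    for i, rec in enumerate(corr_matrix.index):
        for j, tf in enumerate(corr_matrix.columns):
            if vals[i, j] > corr_threshold:
                links.append((rec, tf, float(vals[i, j])))
    return links


def detected_fraction(norm_matrix: np.ndarray, gene_ids: Sequence[str],
                      gene: str, spot_idx: np.ndarray) -> float:
    gi = {g: i for i, g in enumerate(gene_ids)}
    if gene not in gi:
        return 0.0
    vals = np.asarray(norm_matrix)[gi[gene]][np.asarray(spot_idx, dtype=int)]
    return float((vals > 0).mean()) if len(vals) else 0.0


def require_cognate_ligands(links: Sequence[tuple[str, str, float]],
                            lr: LRReference,
                            norm_matrix: np.ndarray,
                            gene_ids: Sequence[str],
                            sender_spot_idx: np.ndarray,
                            ligand_expr_fraction: float = 0.05,
                            sender_cluster: str = "",
                            receiver_cluster: str = ""
                            ) -> tuple[list[SignalingEdge], list[dict]]:
    """Keep links whose receptor has a cognate ligand detected in the sender.

    A ligand qualifies when every subunit is detected in at least
    `ligand_expr_fraction` of sender spots; multi-subunit receptors
    likewise require every subunit present in the gene universe. One edge
    is emitted per qualifying (ligand, receptor, module) triple; dropped
    links are returned in an exclusion report.
    """
    genes = set(gene_ids)
    edges, exclusions = [], []
    for receptor, tf, r in links:
        pairs = [p for p in lr.pairs if receptor in p.receptor]
        pairs = [p for p in pairs if set(p.receptor) <= genes]
        if not pairs:
            exclusions.append({"receptor": receptor, "tf_module": tf,
                               "reason": "receptor absent from LR reference"})
            continue
        emitted = False
        for p in pairs:
            fracs = [detected_fraction(norm_matrix, gene_ids, lg,
                                       sender_spot_idx) for lg in p.ligand]
            if all(f >= ligand_expr_fraction for f in fracs):
                edges.append(SignalingEdge(
                    sender_cluster, receiver_cluster,
                    "_".join(p.ligand), receptor, tf, r))
                emitted = True
        if not emitted:
            exclusions.append({"receptor": receptor, "tf_module": tf,
                               "reason": "no cognate ligand detected "
                                         "in sender"})
    return edges, exclusions


# ---------------------------------------------------------------------------
# orchestrated per-sample analysis

def run_interaction_analysis(ds: SpotDataset, activity: ActivityMatrix,
                             regulons: Sequence[Regulon], lr: LRReference,
                             config: PipelineConfig | None = None
                             ) -> dict[tuple[str, str, str], SignalingNetwork]:
    """Full chain per sample and per adjacent directed cluster pair.

    Returns {(sample, sender_cluster, receiver_cluster): network}. Both
    orientations of every adjacent pair are analyzed: modules and receptors
    on the receiver side, ligands on the sender side. A sample with no
    adjacent pairs contributes nothing (not an error).
    """
    config = config or PipelineConfig()
    config.validate()
    if ds.obs["cluster"].isna().any():
        raise ValidationError("clusters must be assigned before signaling")
    results: dict[tuple[str, str, str], SignalingNetwork] = {}
    all_receptors = sorted(lr.receptors())
    for sample in ds.samples:
        sds = ds.subset_spots(
            np.flatnonzero((ds.obs["sample_id"] == sample).to_numpy()))
        graph = build_neighbor_graph(sds)
        pairs = adjacent_cluster_pairs(graph, sds.obs["cluster"],
                                       config.min_contact_edges)
        for a, b in sorted(pairs):
            for sender, receiver in ((a, b), (b, a)):
                net = _analyze_pair(sds, activity, regulons, lr,
                                    all_receptors, sender, receiver, config)
                if net is not None:
                    results[(sample, sender, receiver)] = net
    return results


def _analyze_pair(sds: SpotDataset, activity: ActivityMatrix,
                  regulons: Sequence[Regulon], lr: LRReference,
                  all_receptors: list[str], sender: str, receiver: str,
                  config: PipelineConfig) -> SignalingNetwork | None:
    region_clusters = ({sender, receiver} if config.region_mode == "union"
                       else {receiver})
    region = subset_region(sds, region_clusters)
    if region.n_spots < MIN_REGION_SPOTS:
        return None
    try:
        region = filter_rare_genes(region, config.min_spot_fraction)
    except SpotlinkError:
        return None
    norm = normalize_logcpm(region)
    gene_ids = region.gene_ids
    receptors = [r for r in all_receptors if r in set(gene_ids)]
    if not receptors or not len(activity.scores):
        return None
    spot_ids = list(region.obs.index)
    idx = np.arange(region.n_spots)
    corr, flagged = receptor_module_correlation(
        activity, norm, gene_ids, receptors, idx, spot_ids)
    corr = prune_targeted_receptors(corr, regulons)
    links = link_receptors(corr, config.corr_threshold)
    sender_idx = np.flatnonzero(
        (region.obs["cluster"] == sender).to_numpy())
    edges, exclusions = require_cognate_ligands(
        links, lr, norm, gene_ids, sender_idx,
        config.ligand_expr_fraction, str(sender), str(receiver))
    net = SignalingNetwork(
        edges=edges, region=set(map(str, region_clusters)),
        config_snapshot=config.to_dict(),
        receptor_zscore_mean={r: 0.0 for r in flagged},
        exclusions=exclusions)
    net.validate_rules(regulons, config.corr_threshold)
    return net


def score_network_recovery(networks, truth: SyntheticTruth
                           ) -> tuple[float, float]:
    """Precision and recall of recovered (receptor, tf_module) links.

    `networks` may be one network or the dict from
    :func:`run_interaction_analysis`; recovered links are pooled. With an
    empty recovery set, precision is NaN and recall 0.
    """
    if isinstance(networks, SignalingNetwork):
        networks = {"_": networks}
    recovered: set[tuple[str, str]] = set()
    for net in networks.values():
        recovered |= net.edge_set()
    planted = {(l.receptor, l.tf) for l in truth.planted_links}
    if not recovered:
        return (float("nan"), 0.0 if planted else float("nan"))
    tp = len(recovered & planted)
    precision = tp / len(recovered)
    recall = tp / len(planted) if planted else float("nan")
    return precision, recall
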