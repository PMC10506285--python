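"""Filtering, normalization, compartment merging, and hex-grid geometry.

The spatial dialect: spots live on a hexagonal array where valid positions
satisfy (array_row + array_col) even, and two spots are neighbors iff their
coordinate offset is (0, ±2) or (±1, ±1) within the same sample. Cluster
adjacency ("clusters in direct contact") is a floor on the number of
boundary edges between spots of two clusters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import SpotDataset
from .errors import SpotlinkError, ValidationError

log = logging.getLogger(__name__)

#: Hexagonal neighbor offsets (Δrow, Δcol), both directions.
HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


# ---------------------------------------------------------------------------
# filtering and normalization

def filter_low_quality_spots(ds: SpotDataset, min_counts: int = 250,
                             exclude_spot_ids: Iterable[str] = ()
                             ) -> SpotDataset:
    """Drop spots with total counts below `min_counts` or explicitly listed.

    The explicit list stands in for histology-driven exclusion (necrosis,
    tissue folds). Raises if nothing survives.
    """
    if min_counts < 0:
        raise ValidationError("min_counts must be >= 0")
    totals = ds.counts.sum(axis=0)
    excl = set(exclude_spot_ids)
    low = totals < min_counts
    listed = np.array([s in excl for s in ds.obs.index])
    keep = ~(low | listed)
    n_low, n_listed = int(low.sum()), int((listed & ~low).sum())
    if n_low or n_listed:
        log.info("removing %d low-count and %d listed spots", n_low, n_listed)
    if not keep.any():
        raise SpotlinkError("spot filtering removed every spot")
    return ds.subset_spots(np.flatnonzero(keep))


def filter_rare_genes(ds: SpotDataset, min_spot_fraction: float = 0.025
                      ) -> SpotDataset:
    """Keep genes detected (count > 0) in >= `min_spot_fraction` of spots.

    The boundary is inclusive: a gene detected in exactly the threshold
    fraction of spots is retained.
    """
    if not 0.0 < min_spot_fraction < 1.0:
        raise ValidationError("min_spot_fraction must lie in (0, 1)")
    detected = (ds.counts > 0).sum(axis=1)
    frac = detected / ds.n_spots
    keep = frac >= min_spot_fraction
    if not keep.any():
        raise SpotlinkError("gene filtering removed every gene")
    return ds.subset_genes(np.flatnonzero(keep))


def normalize_logcpm(ds: SpotDataset, scale: float = 1e4) -> np.ndarray:
    """log2(1 + scale * count / spot_total), genes × spots.

    Depth-normalizes each spot to `scale` counts then log-transforms; a
    monotone variance-stabilizing scale sufficient for the rank- and
    correlation-based statistics downstream.
    """
    totals = ds.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise SpotlinkError("zero-total spot reached normalization; "
                            "filter spots first")
    return np.log2(1.0 + scale * ds.counts / totals[None, :])


# ---------------------------------------------------------------------------
# annotation

def attach_clusters(ds: SpotDataset, annotations: pd.DataFrame) -> SpotDataset:
    """Attach cluster (and optionally compartment) labels by barcode."""
    missing = [b for b in ds.obs.index if b not in annotations.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} spots lack annotation (first: {missing[:5]})")
    obs = ds.obs.copy()
    obs["cluster"] = annotations.loc[ds.obs.index, "cluster"].to_numpy()
    if "compartment" in annotations.columns:
        obs["compartment"] = annotations.loc[ds.obs.index,
                                             "compartment"].to_numpy()
    return ds.with_obs(obs)


def merge_compartments(ds: SpotDataset,
                       cluster_map: Mapping[str, str]) -> SpotDataset:
    """Populate the compartment field by merging clusters.

    Every cluster present must be mapped (e.g. {T1: tumor, T2: tumor,
    I1: immune}); cluster labels themselves are untouched.
    """
    clusters = ds.obs["cluster"]
    if clusters.isna().any():
        raise ValidationError("spots without cluster labels cannot be merged")
    unmapped = sorted(set(clusters.unique()) - set(cluster_map))
    if unmapped:
        raise ValidationError(f"clusters without compartment map: {unmapped}")
    obs = ds.obs.copy()
    obs["compartment"] = clusters.map(dict(cluster_map)).to_numpy()
    return ds.with_obs(obs)


def compartment_proportions(ds: SpotDataset) -> pd.DataFrame:
    """Per-sample compartment fractions (rows sum to 1)."""
    if ds.obs["compartment"].isna().any():
        raise ValidationError("compartments not assigned")
    tab = pd.crosstab(ds.obs["sample_id"], ds.obs["compartment"])
    return tab.div(tab.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# geometry

@dataclass
class NeighborGraph:
    """Undirected spot-level hex adjacency within samples.

    ``edges`` holds index pairs (u < v) into the originating dataset's spot
    order; no self-edges, max degree 6, never across samples.
    """

    n_spots: int
    edges: np.ndarray               # shape (n_edges, 2), u < v
    spot_ids: np.ndarray

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_spots, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def cluster_contact_counts(self, clusters: Sequence) -> dict:
        """(cluster_a, cluster_b) -> number of boundary edges, symmetric keys
        stored once with a sorted tuple."""
        clusters = np.asarray(clusters, dtype=object)
        counts: dict[tuple, int] = {}
        for u, v in self.edges:
            a, b = clusters[u], clusters[v]
            if a == b or pd.isna(a) or pd.isna(b):
                continue
            key = tuple(sorted((a, b)))
            counts[key] = counts.get(key, 0) + 1
        return counts


def build_neighbor_graph(ds: SpotDataset) -> NeighborGraph:
    """Hex adjacency: (|Δrow|, |Δcol|) ∈ {(0,2), (1,1)} within one sample."""
    rows = ds.obs["array_row"].to_numpy(dtype=int)
    cols = ds.obs["array_col"].to_numpy(dtype=int)
    parity = (rows + cols) % 2
    if len(set(parity.tolist())) > 1:
        raise ValidationError(
            "inconsistent (array_row + array_col) parity across spots")
    samples = ds.obs["sample_id"].to_numpy()
    lut = {(s, r, c): i
           for i, (s, r, c) in enumerate(zip(samples, rows, cols))}
    edges = []
    for i in range(ds.n_spots):
        for dr, dc in HEX_OFFSETS:
            j = lut.get((samples[i], rows[i] + dr, cols[i] + dc))
            if j is not None and j > i:
                edges.append((i, j))
    edges_arr = (np.array(edges, dtype=int) if edges
                 else np.zeros((0, 2), dtype=int))
    return NeighborGraph(ds.n_spots, edges_arr, ds.spot_ids.copy())


def adjacent_cluster_pairs(graph: NeighborGraph, clusters: Sequence,
                           min_contact_edges: int = 10) -> set[tuple]:
    """Unordered cluster pairs with >= `min_contact_edges` boundary edges."""
    contacts = graph.cluster_contact_counts(clusters)
    return {pair for pair, n in contacts.items() if n >= min_contact_edges}


def subset_region(ds: SpotDataset, clusters: Iterable) -> SpotDataset:
    """Spots of exactly the given clusters; gene universe unchanged."""
    wanted = set(clusters)
    if not wanted:
        raise ValidationError("empty cluster subset")
    present = set(ds.obs["cluster"].dropna().unique())
    unknown = sorted(wanted - present)
    if unknown:
        raise ValidationError(f"unknown clusters: {unknown}")
    keep = ds.obs["cluster"].isin(wanted).to_numpy()
    return ds.subset_spots(np.flatnonzero(keep))


def morans_i(values: np.ndarray, edges: np.ndarray) -> float:
    """Moran's I spatial autocorrelation over an undirected edge list."""
    x = np.asarray(values, dtype=float)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0 or len(edges) == 0:
        return 0.0
    num = sum(z[u] * z[v] for u, v in edges) * 2.0  # both directions
    w_sum = 2.0 * len(edges)
    return (len(x) / w_sum) * (num / denom)


def kmeans_fallback_clusters(norm_matrix: np.ndarray, n_clusters: int,
                             seed: int = 0) -> np.ndarray:
    """Label-free smoke-test clustering: PCA then k-means on spots.

    Not part of the analysis contract — cluster labels are pipeline inputs —
    but convenient when none are available.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    x = np.asarray(norm_matrix, dtype=float).T  # spots × genes
    n_comp = int(min(20, x.shape[0] - 1, x.shape[1] - 1))
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(
        x - x.mean(axis=0))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(pcs).astype(str)
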