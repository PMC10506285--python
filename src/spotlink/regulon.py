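"""TF regulatory modules and per-spot activity scoring.

A module is a transcription factor plus the co-expressed genes whose
importance exceeds the TF's 95th-percentile cutoff, optionally pruned by a
user-supplied TF→candidate-target prior (standing in for motif-based
pruning); modules with fewer than 20 genes are discarded. Per-spot activity
is the area under the module's gene-recovery curve within the top-ranked
fraction of that spot's expression profile, normalized to [0, 1].
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class Regulon:
    """A TF with its retained targets and their importances."""

    tf: str
    targets: list[str]
    importances: dict[str, float]
    provenance: str = "coexpression"   # or "prior-pruned"

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValidationError(f"regulon {self.tf}: TF inside own targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError(f"regulon {self.tf}: duplicate targets")


@dataclass
class ActivityMatrix:
    """Regulons × spots activity scores in [0, 1]."""

    scores: pd.DataFrame   # index: tf names, columns: spot ids

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (not np.all(np.isfinite(vals))
                          or vals.min() < 0 or vals.max() > 1):
            raise ValidationError("activity scores must be finite in [0, 1]")


# ---------------------------------------------------------------------------
# co-expression importance

def coexpression_importance(norm_matrix: np.ndarray, gene_ids: Sequence[str],
                            tf_list: Sequence[str], seed: int = 0,
                            method: str = "spearman"
                            ) -> dict[str, pd.Series]:
    """Importance of every expressed gene for each TF.

    Default importance is the absolute Spearman correlation between the
    TF's expression and each candidate gene across spots — a monotone
    co-expression measure whose job is to rank candidate targets.
    ``method="spearman+forest"`` augments it with a normalized
    extremely-randomized-trees importance (slower; seeded).
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    x = np.asarray(norm_matrix, dtype=float)
    if x.shape[0] != len(gene_ids):
        raise ValidationError("norm_matrix rows must match gene_ids")
    present = [tf for tf in tf_list if tf in set(gene_ids)]
    for tf in tf_list:
        if tf not in set(gene_ids):
            log.warning("TF %s absent from the matrix; skipped", tf)
    ranks = rankdata(x, axis=1)
    rz = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((rz**2).sum(axis=1))
    norms[norms == 0] = np.inf   # constant genes correlate 0 with everything
    gi = {g: i for i, g in enumerate(gene_ids)}
    out: dict[str, pd.Series] = {}
    for tf in present:
        i = gi[tf]
        rho = (rz @ rz[i]) / (norms * norms[i])
        imp = np.abs(rho)
        imp[i] = 0.0
        series = pd.Series(imp, index=gene_ids).drop(tf)
        if method == "spearman+forest":
            series = series + 0.5 * _forest_importance(x, gi, tf, gene_ids,
                                                       seed)
        out[tf] = series
    return out


def _forest_importance(x, gi, tf, gene_ids, seed) -> pd.Series:
    from sklearn.ensemble import ExtraTreesRegressor
    others = [g for g in gene_ids if g != tf]
    idx = [gi[g] for g in others]
    model = ExtraTreesRegressor(n_estimators=50, max_depth=5,
                                random_state=seed, n_jobs=1)
    model.fit(x[idx].T, x[gi[tf]])
    imp = model.feature_importances_
    peak = imp.max() if imp.max() > 0 else 1.0
    return pd.Series(imp / peak, index=others)


def build_modules(importances: Mapping[str, pd.Series],
                  importance_percentile: float = 95.0,
                  min_module_genes: int = 20,
                  prior: Mapping[str, Sequence[str]] | None = None,
                  percentile_scope: str = "per_tf") -> list[Regulon]:
    """Threshold importances into modules and apply the size floor.

    Targets strictly above the TF's `importance_percentile` cutoff are
    retained (``percentile_scope="global"`` pools all TF importances for one
    cutoff). A prior maps each TF to its allowed targets; targets outside
    it are removed before the size rule. Modules smaller than
    `min_module_genes` are discarded.
    """
    if percentile_scope not in ("per_tf", "global"):
        raise ValidationError("percentile_scope must be per_tf or global")
    global_cut = None
    if percentile_scope == "global" and importances:
        pooled = np.concatenate([s.to_numpy() for s in importances.values()])
        global_cut = np.percentile(pooled, importance_percentile)
    regulons = []
    for tf, series in importances.items():
        cut = (global_cut if global_cut is not None
               else np.percentile(series.to_numpy(), importance_percentile))
        kept = series[series > cut]
        provenance = "coexpression"
        if prior is not None:
            allowed = set(prior.get(tf, ()))
            kept = kept[kept.index.isin(allowed)]
            provenance = "prior-pruned"
        if len(kept) < min_module_genes:
            log.info("module %s discarded: %d genes < %d",
                     tf, len(kept), min_module_genes)
            continue
        kept = kept.sort_values(ascending=False)
        regulons.append(Regulon(tf, list(kept.index),
                                kept.to_dict(), provenance))
    return regulons


# ---------------------------------------------------------------------------
# AUC activity scoring

def _rank_orders(norm_matrix: np.ndarray, rng: np.random.Generator
                 ) -> np.ndarray:
    """Per-spot gene ranking, descending expression, seeded random tie-break.

    Returns ``rank_of_gene``: entry (g, j) is the 0-based rank of gene g in
    spot j. One random gene permutation per run breaks all ties, so equal
    values are ordered reproducibly but without systematic index bias.
    """
    n_genes, n_spots = norm_matrix.shape
    perm = rng.permutation(n_genes)
    shuffled = norm_matrix[perm, :]
    order = np.argsort(-shuffled, axis=0, kind="stable")
    gene_order = perm[order]                     # ranking position -> gene
    rank_of_gene = np.empty((n_genes, n_spots), dtype=np.int32)
    rows = np.arange(n_genes)[:, None]
    np.put_along_axis(rank_of_gene, gene_order, rows.astype(np.int32), axis=0)
    return rank_of_gene


def aucell_scores(norm_matrix: np.ndarray, gene_ids: Sequence[str],
                  regulons: Sequence[Regulon], spot_ids: Sequence[str],
                  aucell_top_fraction: float = 0.05,
                  seed: int = 0) -> ActivityMatrix:
    """Per-spot module activity: normalized AUC of the gene-recovery curve.

    For each spot, genes are ranked by descending normalized expression;
    the recovery curve counts module genes found within the top k ranks,
    k = ceil(top_fraction · N). The score is the area under this step curve
    divided by the maximal achievable area (all module genes at the very
    top), hence in [0, 1].
    """
    if not regulons:
        raise ValidationError("no regulons to score")
    if not 0.0 < aucell_top_fraction <= 0.5:
        raise ValidationError("aucell_top_fraction must lie in (0, 0.5]")
    gene_ids = np.asarray(gene_ids, dtype=object)
    x = np.asarray(norm_matrix, dtype=float)
    n_genes = x.shape[0]
    k = math.ceil(aucell_top_fraction * n_genes)
    rng = np.random.default_rng(seed)
    rank_of_gene = _rank_orders(x, rng)
    gi = {g: i for i, g in enumerate(gene_ids)}
    rows = {}
    for reg in regulons:
        present = [g for g in reg.targets if g in gi]
        if len(present) < len(reg.targets):
            log.warning("module %s: %d/%d genes absent from matrix",
                        reg.tf, len(reg.targets) - len(present),
                        len(reg.targets))
        if not present:
            rows[reg.tf] = np.zeros(x.shape[1])
            continue
        r = rank_of_gene[[gi[g] for g in present], :]
        area = np.clip(k - r, 0, None).sum(axis=0)
        m = len(present)
        max_area = sum(k - j for j in range(min(m, k)))
        rows[reg.tf] = area / max_area
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores.columns = list(spot_ids)
    return ActivityMatrix(scores)


def recovery_auc_bruteforce(ranking: Sequence[int], module_positions,
                            k: int) -> float:
    """Independent step-curve integrator for the AUC activity score.

    ``ranking`` is the gene order (position -> gene index); the curve value
    at step i is the number of module genes among the first i positions;
    the score is the summed curve over steps 1..k divided by its maximum.
    Exists as a readable oracle; the production scorer is vectorized.
    """
    module = set(module_positions)
    hits = 0
    area = 0
    for i in range(k):
        if ranking[i] in module:
            hits += 1
        area += hits
    m = len(module)
    max_area = sum(min(i + 1, m) for i in range(k))
    return area / max_area
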