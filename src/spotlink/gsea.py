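"""Preranked gene-set enrichment by the weighted running-sum statistic.

Genes are sorted by a ranking score (log2 fold change by default); walking
down the list, the running sum gains |score|^1 / (sum of |score| in the set)
on set members and loses 1/(N - m) on non-members. The enrichment score is
the extremum of the walk by absolute value; significance comes from
gene-label permutations, with normalization and FDR computed within
sign-matched null pools.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import GeneSetCollection
from .errors import ValidationError

log = logging.getLogger(__name__)

MIN_SET_SIZE = 5


@dataclass
class EnrichmentResult:
    """Per-set enrichment statistics plus the skipped-set record."""

    table: pd.DataFrame          # es, nes, pvalue, fdr, size
    leading_edge: dict[str, list[str]]
    skipped: list[str] = field(default_factory=list)


def _sorted_ranking(ranking: pd.Series) -> pd.Series:
    if ranking.isna().any():
        raise ValidationError("ranking contains NaN scores")
    if ranking.index.has_duplicates:
        raise ValidationError("ranking has duplicate gene ids")
    # descending score, ties broken by gene id for determinism
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    return ranking.loc[order]


def _es_from_positions(positions: np.ndarray, absw: np.ndarray,
                       n_genes: int) -> tuple[float, int]:
    """Enrichment score given sorted 0-based hit positions.

    The running sum attains candidate extrema immediately after each hit and
    immediately before each hit; returns (es, index of the extremal hit).
    """
    m = len(positions)
    w = absw[positions]
    nr = w.sum()
    n_miss = n_genes - m
    k = np.arange(1, m + 1)
    if nr == 0:
        # all-zero scores inside the set: hits contribute equal weight
        cum = k / m
    else:
        cum = np.cumsum(w) / nr
    if n_miss == 0:
        after = cum
        before = cum - (0 if nr else 0)
        dev = after
        i = int(np.argmax(np.abs(dev)))
        return float(dev[i]), i
    after = cum - (positions + 1 - k) / n_miss
    before = np.concatenate([[0.0], cum[:-1]]) - (positions - k + 1) / n_miss
    cand = np.concatenate([after, before])
    i = int(np.argmax(np.abs(cand)))
    return float(cand[i]), i % m


def _null_es(n_genes: int, set_size: int, absw: np.ndarray, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES from gene-label permutation: random hit positions."""
    u = rng.random((n_perm, n_genes))
    pos = np.argpartition(u, set_size, axis=1)[:, :set_size]
    pos.sort(axis=1)
    w = absw[pos]
    nr = w.sum(axis=1, keepdims=True)
    k = np.arange(1, set_size + 1)[None, :]
    n_miss = n_genes - set_size
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.where(nr > 0, np.cumsum(w, axis=1) / np.where(nr > 0, nr, 1),
                       k / set_size)
    after = cum - (pos + 1 - k) / n_miss
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (pos - k + 1) / n_miss
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def preranked_gsea(ranking: pd.Series, sets: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0,
                   weight: float = 1.0) -> EnrichmentResult:
    """Weighted-KS preranked enrichment with a gene-label permutation null.

    Parameters
    ----------
    ranking
        gene -> score (e.g. DE log2 fold change); no NaN allowed.
    sets
        Gene sets; sets with fewer than 5 genes present in the ranking are
        skipped with a warning, zero-overlap sets are recorded as skipped.
    weight
        Exponent on |score| in the hit increment (1 = classic weighted
        statistic, 0 = unweighted Kolmogorov–Smirnov).
    """
    ranking = _sorted_ranking(pd.Series(ranking, dtype=float))
    genes = np.array(ranking.index, dtype=object)
    absw = np.abs(ranking.to_numpy()) ** weight
    n_genes = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, leading, skipped = {}, {}, []
    null_pools: dict[str, np.ndarray] = {}
    for name, members in sets:
        positions = np.array(sorted(pos_of[g] for g in members
                                    if g in pos_of), dtype=int)
        if len(positions) == 0:
            skipped.append(name)
            log.warning("set %s has zero overlap with the ranking; skipped",
                        name)
            continue
        if len(positions) < MIN_SET_SIZE:
            skipped.append(name)
            log.warning("set %s has %d genes in the ranking (<%d); skipped",
                        name, len(positions), MIN_SET_SIZE)
            continue
        es, ext = _es_from_positions(positions, absw, n_genes)
        null = _null_es(n_genes, len(positions), absw, n_perm, rng)
        null_pools[name] = null
        same = null[null > 0] if es >= 0 else null[null < 0]
        if len(same):
            exceed = int((same >= es).sum()) if es >= 0 else \
                int((same <= es).sum())
            pvalue = (1 + exceed) / (1 + len(same))
            nes = es / np.mean(np.abs(same))
        else:
            pvalue = 1.0 / (1 + n_perm)
            nes = np.nan
            log.warning("set %s: empty %s-sign null pool; nes is NaN",
                        name, "positive" if es >= 0 else "negative")
        if es >= 0:
            led = [g for g in genes[:positions[ext] + 1] if g in set(members)]
        else:
            led = [g for g in genes[positions[ext]:] if g in set(members)]
        rows[name] = {"es": es, "nes": nes, "pvalue": pvalue,
                      "size": len(positions)}
        leading[name] = led

    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table.index.name = "set"
        table["fdr"] = _permutation_fdr(table, null_pools)
        table = table[["es", "nes", "pvalue", "fdr", "size"]]
    return EnrichmentResult(table, leading, skipped)


def _permutation_fdr(table: pd.DataFrame, null_pools: dict) -> np.ndarray:
    """Sign-pooled permutation FDR on normalized enrichment scores."""
    null_nes = []
    for name, null in null_pools.items():
        pos, neg = null[null > 0], null[null < 0]
        if len(pos):
            null_nes.append(pos / np.abs(pos).mean())
        if len(neg):
            null_nes.append(neg / np.abs(neg).mean())
    null_nes = np.concatenate(null_nes) if null_nes else np.zeros(0)
    obs = table["nes"].to_numpy()
    fdr = np.full(len(obs), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            n_null, d_null = (null_nes >= nes).sum(), (null_nes >= 0).sum()
            n_obs = np.sum(obs[np.isfinite(obs)] >= nes)
            d_obs = np.sum(obs[np.isfinite(obs)] >= 0)
        else:
            n_null, d_null = (null_nes <= nes).sum(), (null_nes < 0).sum()
            n_obs = np.sum(obs[np.isfinite(obs)] <= nes)
            d_obs = np.sum(obs[np.isfinite(obs)] < 0)
        null_rate = n_null / d_null if d_null else np.nan
        obs_rate = n_obs / d_obs if d_obs else np.nan
        fdr[i] = min(1.0, null_rate / obs_rate) if obs_rate else np.nan
    return fdr


def hallmark_summary(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    """Stack per-contrast enrichment tables ranked by NES (sign = group)."""
    frames = []
    for contrast, res in results.items():
        t = res.table.copy()
        t.index.name = "set"
        t["contrast"] = contrast
        frames.append(t.reset_index())
    if not frames:
        return pd.DataFrame(
            columns=["set", "es", "nes", "pvalue", "fdr", "size", "contrast"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["nes", "set"], ascending=[False, True],
                           na_position="last").reset_index(drop=True)
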