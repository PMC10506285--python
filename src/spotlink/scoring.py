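"""Gene-signature module scores, region contrasts, and proportion correlation.

A signature's module score in a spot is the mean normalized expression of
its genes present in the data (optionally background-corrected against
expression-matched control genes). Region contrasts use the two-sided
Wilcoxon rank-sum test with BH adjustment across signatures; association
between signature-gene expression and deconvolved cell-type proportions
uses Spearman correlation with average-rank tie handling.
"""
from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import GeneSetCollection
from .diffexp import benjamini_hochberg
from .errors import SpotlinkError, ValidationError

log = logging.getLogger(__name__)

#: Printed stemness marker list; two entries are not resolvable gene symbols
#: and are excluded from scoring unless explicitly requested.
AMBIGUOUS_CSC_SYMBOLS = ("SP", "YY1A1")


def module_score(norm_matrix: np.ndarray, gene_ids, sets: GeneSetCollection,
                 spot_ids, background_correct: bool = False,
                 n_bins: int = 24, seed: int = 0) -> pd.DataFrame:
    """Per-spot signature scores: mean normalized expression of set genes.

    Returns spots × signatures. Sets with no gene present are skipped with
    a warning. With ``background_correct=True`` the mean expression of an
    expression-bin-matched control set (same size, drawn per gene from the
    same average-expression bin, seeded) is subtracted.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    x = np.asarray(norm_matrix, dtype=float)
    gi = {g: i for i, g in enumerate(gene_ids)}
    rng = np.random.default_rng(seed)
    bins = None
    if background_correct:
        avg = x.mean(axis=1)
        qs = np.quantile(avg, np.linspace(0, 1, n_bins + 1))
        bin_of = np.clip(np.searchsorted(qs, avg, side="right") - 1,
                         0, n_bins - 1)
        bins = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
        gene_bin = bin_of
    cols = {}
    for name, genes in sets:
        idx = [gi[g] for g in genes if g in gi]
        if not idx:
            log.warning("signature %s: no genes present; skipped", name)
            continue
        score = x[idx].mean(axis=0)
        if background_correct:
            ctrl_idx = [int(rng.choice(bins[gene_bin[i]])) for i in idx]
            score = score - x[ctrl_idx].mean(axis=0)
        cols[name] = score
    return pd.DataFrame(cols, index=pd.Index(list(spot_ids), name="spot"))


def compare_regions(scores: pd.DataFrame, region_a_spots, region_b_spots
                    ) -> pd.DataFrame:
    """Per-signature region contrast: median difference and rank-sum p.

    Two-sided Wilcoxon rank-sum (Mann–Whitney) per signature between
    disjoint spot sets (each with at least 10 spots), BH across signatures.
    """
    a = list(region_a_spots)
    b = list(region_b_spots)
    if set(a) & set(b):
        raise ValidationError("regions overlap")
    if len(a) < 10 or len(b) < 10:
        raise SpotlinkError("each region needs >= 10 spots")
    rows = {}
    for sig in scores.columns:
        xa = scores.loc[a, sig].to_numpy(dtype=float)
        xb = scores.loc[b, sig].to_numpy(dtype=float)
        # exact tail when enumerable and tie-free; normal approx otherwise
        no_ties = len(np.unique(np.concatenate([xa, xb]))) == len(xa) + \
            len(xb)
        method = "exact" if (max(len(xa), len(xb)) <= 10
                             and no_ties) else "asymptotic"
        stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method=method)
        rows[sig] = {"median_diff": float(np.median(xa) - np.median(xb)),
                     "statistic": float(stat), "pvalue": float(p)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "signature"
    out["padj"] = benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def signature_proportion_correlation(expr: pd.DataFrame,
                                     proportions: pd.DataFrame,
                                     signature_genes) -> tuple[pd.DataFrame,
                                                               pd.DataFrame]:
    """Spearman rho of each signature gene against each cell-type proportion.

    Both inputs are samples × columns tables; the correlation runs over
    their common samples (at least 5 required). Returns (rho, pvalue)
    gene × cell-type matrices; p-values via the t approximation.
    """
    common = sorted(set(expr.index) & set(proportions.index))
    if len(common) < 5:
        raise SpotlinkError(
            f"only {len(common)} common samples (< 5); cannot correlate")
    genes = [g for g in signature_genes if g in expr.columns]
    absent = sorted(set(signature_genes) - set(genes))
    if absent:
        log.warning("signature genes absent from expression table: %s",
                    absent[:10])
    if not genes:
        raise ValidationError("no signature gene present in the table")
    e = expr.loc[common, genes]
    p = proportions.loc[common]
    rho = pd.DataFrame(index=genes, columns=p.columns, dtype=float)
    pval = pd.DataFrame(index=genes, columns=p.columns, dtype=float)
    for ct in p.columns:
        for g in genes:
            r, pv = stats.spearmanr(e[g], p[ct])
            rho.loc[g, ct] = r
            pval.loc[g, ct] = pv
    return rho, pval


def load_csc_signature(include_ambiguous: bool = False) -> GeneSetCollection:
    """The packaged cancer-stem-cell marker signature.

    Two printed entries (``SP``, ``YY1A1``) are not standard HGNC symbols;
    they are excluded by default with a loud warning rather than silently
    remapped. Pass ``include_ambiguous=True`` to keep them.
    """
    from .io import read_gmt
    ref = resources.files("spotlink.data") / "csc_signature.gmt"
    with resources.as_file(ref) as path:
        coll = read_gmt(path)
    if not include_ambiguous:
        for name in list(coll.sets):
            kept = [g for g in coll.sets[name]
                    if g not in AMBIGUOUS_CSC_SYMBOLS]
            dropped = [g for g in coll.sets[name]
                       if g in AMBIGUOUS_CSC_SYMBOLS]
            if dropped:
                log.warning(
                    "CSC signature: excluding ambiguous symbols %s "
                    "(not standard gene symbols); pass "
                    "include_ambiguous=True to keep them", dropped)
            coll.sets[name] = kept
    return coll
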