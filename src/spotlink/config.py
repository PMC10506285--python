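"""Pipeline configuration.

Every numeric rule the analysis applies lives here so that a run is fully
described by one object: the gene-detection floor, the differential-expression
significance thresholds, the regulon-construction percentile and size floor,
the receptor-module correlation threshold, the AUC top fraction, and the
spatial-contact floor defining cluster adjacency.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Thresholds and switches for every analysis stage.

    Parameters
    ----------
    min_spot_fraction
        A gene must be detected (count > 0) in at least this fraction of
        spots to be analyzed. Default 0.025 (2.5% of spots).
    lfc_threshold
        Minimum |log2 fold change| for a gene to be called differentially
        expressed. Default 2.0.
    padj_threshold
        Maximum BH-adjusted p-value for a DE call. Default 0.01.
    importance_percentile
        Per-TF percentile of co-expression importances above which a
        candidate target enters the TF's module. Default 95.
    min_module_genes
        Modules with fewer targets than this are discarded. Default 20.
    corr_threshold
        A receptor signals a TF module only when the Pearson correlation
        between module activity and z-scaled receptor expression strictly
        exceeds this value. Default 0.3.
    aucell_top_fraction
        Fraction of the gene ranking that defines the recovery window of
        the per-spot AUC activity score. Default 0.05.
    gsea_permutations
        Gene-label permutations for the enrichment null. Default 1000.
    min_contact_edges
        Minimum number of neighboring-spot contacts for two clusters to
        count as spatially adjacent. Default 10.
    ligand_expr_fraction
        A cognate ligand must be detected in at least this fraction of
        sender-cluster spots for its receptor's edge to survive.
        Default 0.05.
    min_counts
        Spot-level QC floor on total counts. Not a published value; see
        the methods note.
    rng_seed
        Root seed; all stage-level randomness derives from it.
    """

    min_spot_fraction: float = 0.025
    lfc_threshold: float = 2.0
    padj_threshold: float = 0.01
    importance_percentile: float = 95.0
    min_module_genes: int = 20
    corr_threshold: float = 0.3
    aucell_top_fraction: float = 0.05
    gsea_permutations: int = 1000
    min_contact_edges: int = 10
    ligand_expr_fraction: float = 0.05
    min_counts: int = 250
    rng_seed: int = 0

    # switches for points the upstream protocol leaves open
    percentile_scope: str = "per_tf"        # or "global"
    region_mode: str = "union"              # or "receiver"
    gene_filter_scope: str = "region"       # or "global"
    importance_method: str = "spearman"     # or "spearman+forest"
    gsea_rank_metric: str = "log2fc"        # or "signed_logp"

    def validate(self) -> None:
        """Raise :class:`ParameterError` on any out-of-range field."""
        for name in ("min_spot_fraction", "aucell_top_fraction",
                     "ligand_expr_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name}={v} must lie in (0, 1)")
        if self.aucell_top_fraction > 0.5:
            raise ParameterError("aucell_top_fraction must be <= 0.5")
        if not (0.0 < self.importance_percentile < 100.0):
            raise ParameterError("importance_percentile must lie in (0, 100)")
        if not (-1.0 <= self.corr_threshold <= 1.0):
            raise ParameterError(
                f"corr_threshold={self.corr_threshold} is not a correlation")
        if not (0.0 < self.padj_threshold <= 1.0):
            raise ParameterError("padj_threshold must lie in (0, 1]")
        for name in ("lfc_threshold",):
            if not (getattr(self, name) >= 0):
                raise ParameterError(f"{name} must be non-negative")
        for name in ("min_module_genes", "gsea_permutations",
                     "min_contact_edges", "min_counts"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.percentile_scope not in ("per_tf", "global"):
            raise ParameterError("percentile_scope must be per_tf or global")
        if self.region_mode not in ("union", "receiver"):
            raise ParameterError("region_mode must be union or receiver")
        if self.gene_filter_scope not in ("region", "global"):
            raise ParameterError("gene_filter_scope must be region or global")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def stage_seed(root_seed: int, label: str) -> int:
    """Derive a deterministic per-stage seed from the root seed.

    Uses a fixed string hash so the same (root, label) always maps to the
    same 31-bit seed, independent of process hash randomization.
    """
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return (int(root_seed) * 1000003 + h) % (2**31 - 1)
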