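"""Core in-memory containers for spot-level spatial expression data.

The central object is :class:`SpotDataset`: a genes × spots count matrix with
per-spot array coordinates (Visium hexagonal convention), sample and response
group labels, and optional cluster / compartment annotation. Gene sets and
ligand–receptor references are thin typed wrappers around the corresponding
text formats.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Columns required in the per-spot annotation table.
OBS_COLUMNS = ("array_row", "array_col", "sample_id", "group",
               "cluster", "compartment")

#: Valid compartment labels after cluster merging.
COMPARTMENTS = ("tumor", "immune", "CAF", "other")

#: Visium array extent (rows × columns) under the hex dialect used throughout.
ARRAY_ROW_MAX = 77
ARRAY_COL_MAX = 127


@dataclass
class SpotDataset:
    """Genes × spots counts with spatial coordinates and annotations.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_spots)``.
    gene_ids
        Unique gene symbols, length ``n_genes``.
    obs
        Per-spot table indexed by unique spot barcodes with columns
        ``array_row``, ``array_col``, ``sample_id``, ``group``,
        ``cluster``, ``compartment`` (the last two may be all-NA until
        annotation is attached).
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    obs: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes × spots matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValidationError("counts has negative entries")
        n_genes, n_spots = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene_ids length {len(self.gene_ids)} != {n_genes} rows")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids contain duplicates")
        if len(self.obs) != n_spots:
            raise ValidationError(
                f"obs has {len(self.obs)} rows for {n_spots} spots")
        if self.obs.index.has_duplicates:
            dups = self.obs.index[self.obs.index.duplicated()].tolist()
            raise ValidationError(f"duplicate spot barcodes: {dups[:5]}")
        missing = [c for c in OBS_COLUMNS if c not in self.obs.columns]
        if missing:
            raise ValidationError(f"obs missing columns: {missing}")
        coords = self.obs[["array_row", "array_col"]]
        if coords.isna().any().any():
            raise ValidationError("every spot needs array coordinates")
        # one group label per sample
        per_sample = self.obs.groupby("sample_id", observed=True)["group"].nunique(
            dropna=False)
        bad = per_sample[per_sample > 1]
        if len(bad):
            raise ValidationError(
                f"samples with >1 group label: {bad.index.tolist()}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_spots(self) -> int:
        return self.counts.shape[1]

    @property
    def spot_ids(self) -> np.ndarray:
        return self.obs.index.to_numpy()

    @property
    def samples(self) -> list[str]:
        return sorted(self.obs["sample_id"].unique())

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Indices of `genes` in the gene universe; missing genes raise."""
        lut = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lut[g] for g in genes], dtype=int)
        except KeyError as e:
            raise ValidationError(f"gene {e.args[0]!r} not in dataset") from e

    def subset_genes(self, mask_or_idx) -> "SpotDataset":
        idx = np.asarray(mask_or_idx)
        return SpotDataset(self.counts[idx], self.gene_ids[idx],
                           self.obs.copy())

    def subset_spots(self, mask_or_idx) -> "SpotDataset":
        idx = np.asarray(mask_or_idx)
        return SpotDataset(self.counts[:, idx], self.gene_ids.copy(),
                           self.obs.iloc[idx].copy()
                           if idx.dtype != bool else self.obs.loc[idx].copy())

    def with_obs(self, obs: pd.DataFrame) -> "SpotDataset":
        return SpotDataset(self.counts, self.gene_ids, obs)

    def to_anndata(self):
        """Spots × genes AnnData view (transposed), for interoperability."""
        import anndata
        return anndata.AnnData(
            X=self.counts.T.copy(), obs=self.obs.copy(),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Hallmark pathways), order-preserving."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(
                    f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def restrict(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Drop genes absent from `universe`; empty sets are removed."""
        uni = set(universe)
        kept = {n: [g for g in gs if g in uni] for n, gs in self.sets.items()}
        kept = {n: gs for n, gs in kept.items() if gs}
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "")
                                        for n in kept})


@dataclass(frozen=True)
class LRPair:
    """One ligand–receptor record; either side may be a multi-subunit complex."""

    pair_id: str
    ligand: tuple[str, ...]
    receptor: tuple[str, ...]


@dataclass
class LRReference:
    """A ligand–receptor pair table (CellphoneDB-style)."""

    pairs: list[LRPair]

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate pair_ids in LR reference")
        for p in self.pairs:
            if not p.ligand or not p.receptor:
                raise ValidationError(
                    f"pair {p.pair_id!r} lacks a ligand or receptor gene")

    def __len__(self) -> int:
        return len(self.pairs)

    def receptors(self) -> set[str]:
        return {g for p in self.pairs for g in p.receptor}

    def pairs_for_receptor(self, receptor_genes: Sequence[str]) -> list[LRPair]:
        """Pairs whose receptor complex is exactly covered by `receptor_genes`.

        For single-gene receptors this is membership; for complexes every
        subunit must be present in the queried gene list.
        """
        gs = set(receptor_genes)
        return [p for p in self.pairs if set(p.receptor) <= gs]
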