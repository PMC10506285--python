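"""Readers and writers for the text formats the pipeline touches.

Count matrices arrive in the 10x triplet layout (MatrixMarket ``.mtx`` plus
gene and barcode lists) with a Visium-style spot-positions table. Gene sets
use GMT; ligand–receptor references, annotations and proportion tables are
TSV; run metadata is JSON.
"""
from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .dataset import (OBS_COLUMNS, GeneSetCollection, LRPair, LRReference,
                      SpotDataset)
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

POSITIONS_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pxl_row", "pxl_col"]

#: Separator for subunits of a ligand/receptor complex in TSV references.
COMPLEX_SEP = "_"


def _read_list(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh
                if line.strip()]


def read_10x_triplet(matrix_path, genes_path, barcodes_path,
                     positions_path, samples_path=None) -> SpotDataset:
    """Load a genes × spots dataset from the 10x triplet layout.

    ``positions_path`` is a CSV with columns
    ``barcode,in_tissue,array_row,array_col,pxl_row,pxl_col``; barcodes in
    the matrix but absent from the positions table are rejected. An
    optional ``samples_path`` TSV (barcode, sample_id[, group]) attaches
    multi-sample identity; otherwise all spots belong to one sample.
    """
    genes = _read_list(genes_path)
    barcodes = _read_list(barcodes_path)
    if len(set(barcodes)) != len(barcodes):
        dups = pd.Series(barcodes)
        dups = dups[dups.duplicated()].tolist()
        raise ValidationError(
            f"duplicate barcodes in {barcodes_path}: {dups[:5]}")
    if len(set(genes)) != len(genes):
        raise ValidationError(f"duplicate gene ids in {genes_path}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as e:
        raise FormatError(f"cannot parse MatrixMarket file "
                          f"{matrix_path}: {e}") from e
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{matrix_path}: matrix shape {mat.shape} does not match "
            f"{len(genes)} genes × {len(barcodes)} barcodes")
    counts = np.asarray(mat.todense()).astype(np.int64)

    try:
        pos = pd.read_csv(positions_path)
    except Exception as e:
        raise FormatError(f"cannot parse positions file "
                          f"{positions_path}: {e}") from e
    missing_cols = [c for c in POSITIONS_COLUMNS if c not in pos.columns]
    if missing_cols:
        raise FormatError(
            f"{positions_path}: missing columns {missing_cols}")
    pos = pos.set_index("barcode")
    absent = [b for b in barcodes if b not in pos.index]
    if absent:
        raise FormatError(
            f"{positions_path}: {len(absent)} barcodes have no position "
            f"(first: {absent[:5]})")
    pos = pos.loc[barcodes]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs["array_row"] = pos["array_row"].astype(int).to_numpy()
    obs["array_col"] = pos["array_col"].astype(int).to_numpy()
    obs["sample_id"] = "sample0"
    obs["group"] = pd.NA
    if samples_path is not None:
        try:
            smp = pd.read_csv(samples_path, sep="\t", dtype=str)
        except Exception as e:
            raise FormatError(f"cannot parse samples file "
                              f"{samples_path}: {e}") from e
        if "barcode" not in smp.columns or "sample_id" not in smp.columns:
            raise FormatError(
                f"{samples_path}: needs columns barcode, sample_id")
        smp = smp.set_index("barcode")
        absent = [b for b in barcodes if b not in smp.index]
        if absent:
            raise FormatError(
                f"{samples_path}: {len(absent)} barcodes missing "
                f"(first: {absent[:5]})")
        obs["sample_id"] = smp.loc[barcodes, "sample_id"].to_numpy()
        if "group" in smp.columns:
            obs["group"] = smp.loc[barcodes, "group"].to_numpy()
    obs["cluster"] = pd.NA
    obs["compartment"] = pd.NA
    return SpotDataset(counts, np.array(genes, dtype=object), obs)


def write_10x_triplet(ds: SpotDataset, out_dir) -> None:
    """Write the triplet layout (matrix.mtx, genes.tsv, barcodes.tsv,
    positions.csv) for one dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"),
                     scipy.sparse.coo_matrix(ds.counts))
    (out / "genes.tsv").write_text(
        "".join(f"{g}\n" for g in ds.gene_ids))
    (out / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in ds.obs.index))
    pos = pd.DataFrame({
        "barcode": ds.obs.index,
        "in_tissue": 1,
        "array_row": ds.obs["array_row"].to_numpy(),
        "array_col": ds.obs["array_col"].to_numpy(),
        "pxl_row": ds.obs["array_row"].to_numpy() * 100,
        "pxl_col": ds.obs["array_col"].to_numpy() * 100,
    })
    pos.to_csv(out / "positions.csv", index=False)
    smp = pd.DataFrame({"barcode": ds.obs.index,
                        "sample_id": ds.obs["sample_id"].to_numpy(),
                        "group": ds.obs["group"].to_numpy()})
    smp.to_csv(out / "samples.tsv", sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields name, description, genes."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                log.warning("%s:%d: set %s has duplicate genes; collapsed",
                            path, lineno, name)
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_lr_reference(path) -> LRReference:
    """Load a ligand–receptor TSV with columns pair_id, ligand, receptor.

    Complex subunits are joined with ``_`` (e.g. ``ITGA1_ITGB1``).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as e:
        raise FormatError(f"cannot parse LR reference {path}: {e}") from e
    for col in ("pair_id", "ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pairs = [LRPair(row.pair_id,
                    tuple(row.ligand.split(COMPLEX_SEP)),
                    tuple(row.receptor.split(COMPLEX_SEP)))
             for row in df.itertuples()]
    return LRReference(pairs)


def write_lr_reference(lr: LRReference, path) -> None:
    df = pd.DataFrame({
        "pair_id": [p.pair_id for p in lr.pairs],
        "ligand": [COMPLEX_SEP.join(p.ligand) for p in lr.pairs],
        "receptor": [COMPLEX_SEP.join(p.receptor) for p in lr.pairs],
    })
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Spot annotation TSV with columns barcode, cluster[, compartment]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "barcode" not in df.columns or "cluster" not in df.columns:
        raise FormatError(f"{path}: needs columns barcode, cluster")
    return df.set_index("barcode")


NETWORK_COLUMNS = ["sender_cluster", "receiver_cluster", "ligand",
                   "receptor", "tf_module", "correlation"]


def write_network(network, path) -> None:
    """Serialize a SignalingNetwork as a TSV edge list.

    Run metadata (config snapshot, region, seed) is embedded in ``#``-prefixed
    header lines as JSON so a read-back reproduces the object exactly.
    """
    meta = {"region": sorted(network.region),
            "config": network.config_snapshot}
    with open(path, "w") as fh:
        fh.write("# spotlink-network\t" + json.dumps(meta, sort_keys=True)
                 + "\n")
        fh.write("\t".join(NETWORK_COLUMNS) + "\n")
        for e in network.edges:
            fh.write("\t".join([e.sender_cluster, e.receiver_cluster,
                                e.ligand, e.receptor, e.tf_module,
                                format(e.pearson_r, ".10g")]) + "\n")


def read_network(path):
    """Read back a network TSV written by :func:`write_network`."""
    from .signaling import SignalingEdge, SignalingNetwork
    meta = {}
    rows = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            if line.startswith("#"):
                try:
                    meta = json.loads(line.split("\t", 1)[1])
                except (IndexError, json.JSONDecodeError) as e:
                    raise FormatError(f"{path}: bad metadata line: {e}")
                continue
            fields = line.rstrip("\n").split("\t")
            if not header_seen:
                if fields != NETWORK_COLUMNS:
                    raise FormatError(f"{path}: unexpected header {fields}")
                header_seen = True
                continue
            if len(fields) != len(NETWORK_COLUMNS):
                raise FormatError(f"{path}: ragged row {fields}")
            rows.append(SignalingEdge(*fields[:5], float(fields[5])))
    return SignalingNetwork(edges=rows, region=set(meta.get("region", [])),
                            config_snapshot=meta.get("config", {}))


def write_run_metadata(path, config, seed, extra: Mapping | None = None):
    """JSON run-metadata block: config snapshot, seed, package version."""
    from . import __version__
    payload = {"config": config.to_dict() if hasattr(config, "to_dict")
               else dict(config),
               "seed": int(seed), "spotlink_version": __version__}
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
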