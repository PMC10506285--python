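"""Synthetic Visium-like tissue generator with planted ground truth.

Emulates the statistical structure a spatial signaling analysis must be able
to resolve: a multi-sample cohort split into two response groups; spatially
contiguous tumor / immune / CAF domains on a hexagonal spot array;
negative-binomial UMI counts with log-normal per-spot depth; planted TF
regulons whose targets and receptor share a smooth latent activity field in a
receiver domain; cognate ligands elevated only in an adjacent sender domain;
group-level fold changes on planted genes; and pathway / stemness signatures
localized to sub-regions. Everything planted is returned as an explicit
:class:`SyntheticTruth` so downstream stages can be scored against it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import LRPair, LRReference, SpotDataset
from .errors import ParameterError, ValidationError

DOMAINS = ("tumor_A", "tumor_B", "immune", "CAF", "other")

#: Merge rule from synthetic domains to analysis compartments.
DOMAIN_TO_COMPARTMENT = {"tumor_A": "tumor", "tumor_B": "tumor",
                         "immune": "immune", "CAF": "CAF", "other": "other"}

# fractional (row, col) seed positions for region growth, per domain
_DOMAIN_SEEDS = {"tumor_A": (0.50, 0.50), "immune": (0.45, 0.15),
                 "CAF": (0.55, 0.85), "tumor_B": (0.90, 0.45),
                 "other": (0.08, 0.55)}

_DOMAIN_QUOTAS = {"tumor_A": 0.34, "tumor_B": 0.18, "immune": 0.20,
                  "CAF": 0.16, "other": 0.12}

#: (sender_domain, receiver_domain) for each planted link, cycled.
_LINK_TOPOLOGY = [("tumor_A", "immune"), ("tumor_A", "CAF"),
                  ("immune", "tumor_A"), ("CAF", "tumor_A")]


@dataclass
class SimulationParams:
    """Generator parameters; defaults define the reference study conditions.

    The cohort mirrors a small two-arm surgical series (4 responder vs 3
    non-responder samples); each sample carries a full hexagonal patch of
    2000 spots. Loadings are on the natural-log scale of the NB mean.
    """

    n_samples_per_group: tuple[int, int] = (4, 3)
    grid_rows: int = 50
    grid_cols: int = 80
    n_genes: int = 1500
    n_regulons: int = 8
    targets_per_regulon: int = 30
    n_decoy_tfs: int = 12
    n_decoy_receptors: int = 40
    n_de_genes: int = 60            # half up in group A, half in group B
    group_log2fc: float = 2.0
    n_signature_genes: int = 30     # per planted signature
    n_markers_per_domain: int = 15
    target_loading: float = 1.5     # ln-scale loading of targets & TF
    receptor_loading: float = 2.4   # ln-scale loading of the receptor
    target_correlation: float = 0.6  # design value recorded in the truth
    ligand_loading: float = 1.5     # ln-scale sender-domain ligand boost
    marker_loading: float = 1.5
    signature_loading: float = 1.2
    mean_depth: float = 8000.0      # expected UMI per spot before variation
    depth_cv: float = 0.3           # log-normal per-spot depth CV
    dispersion_meanlog: float = np.log(0.15)
    dispersion_sdlog: float = 0.5
    smoothing_sweeps: int = 3

    def validate(self) -> None:
        if min(self.n_samples_per_group) < 0:
            raise ParameterError("sample counts must be non-negative")
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ParameterError("grid must be at least 4 x 4")
        n_spots = sum((r + c) % 2 == 0 for r in range(self.grid_rows)
                      for c in range(self.grid_cols))
        if n_spots < len(DOMAINS):
            raise ParameterError(
                f"grid with {n_spots} spots cannot hold {len(DOMAINS)} domains")
        reserved = (self.n_regulons * (self.targets_per_regulon + 3)
                    + self.n_decoy_tfs + 2 * self.n_decoy_receptors
                    + self.n_de_genes + 2 * self.n_signature_genes
                    + len(DOMAINS) * self.n_markers_per_domain)
        if reserved > self.n_genes:
            raise ParameterError(
                f"n_genes={self.n_genes} too small for {reserved} planted genes")
        if not 0 < self.mean_depth:
            raise ParameterError("mean_depth must be positive")


@dataclass
class PlantedRegulon:
    tf: str
    targets: list[str]
    latent_activity: np.ndarray  # per spot of the emitted dataset, 0 outside
    receiver_domain: str


@dataclass
class PlantedLink:
    ligand: str
    receptor: str
    tf: str
    sender_domain: str
    receiver_domain: str
    target_correlation: float


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, for scoring downstream stages."""

    domain_map: pd.Series                # spot -> domain label
    planted_regulons: list[PlantedRegulon]
    planted_links: list[PlantedLink]
    planted_de: dict[str, float]         # gene -> true log2 FC (A over B)
    planted_signatures: dict[str, tuple[list[str], str]]
    tf_list: list[str]                   # planted + decoy TFs
    decoy_receptors: list[str]
    decoy_ligands: list[str]
    generator_params: dict

    def __post_init__(self) -> None:
        for link in self.planted_links:
            if not -1.0 <= link.target_correlation <= 1.0:
                raise ValidationError("planted |target_correlation| > 1")
        for reg in self.planted_regulons:
            if not np.all(np.isfinite(reg.latent_activity)):
                raise ValidationError("latent activity not finite")
        targets_by_tf = {r.tf: set(r.targets) for r in self.planted_regulons}
        for link in self.planted_links:
            if link.receptor in targets_by_tf.get(link.tf, set()):
                raise ValidationError(
                    f"receptor {link.receptor} is a target of its own TF")


# ---------------------------------------------------------------------------
# geometry helpers

def hex_grid(n_rows: int, n_cols: int) -> np.ndarray:
    """All (row, col) with row+col even — the hex dialect used throughout."""
    coords = [(r, c) for r in range(n_rows) for c in range(n_cols)
              if (r + c) % 2 == 0]
    return np.array(coords, dtype=int)


def _hex_edges(coords: np.ndarray) -> list[tuple[int, int]]:
    lut = {(int(r), int(c)): i for i, (r, c) in enumerate(coords)}
    offsets = [(0, 2), (1, 1), (1, -1)]  # half of the 6; undirected edges
    edges = []
    for i, (r, c) in enumerate(coords):
        for dr, dc in offsets:
            j = lut.get((int(r) + dr, int(c) + dc))
            if j is not None:
                edges.append((i, j))
    return edges


def _grow_domains(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Contiguous domains via quota-limited multi-source breadth-first growth."""
    n = len(coords)
    edges = _hex_edges(coords)
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    rmax, cmax = coords[:, 0].max(), coords[:, 1].max()
    assignment = np.full(n, -1, dtype=int)
    targets = {}
    frontiers: dict[str, deque[int]] = {}
    order = list(DOMAINS)
    for d in order:
        fr, fc = _DOMAIN_SEEDS[d]
        want = (fr * rmax, fc * cmax)
        dist = np.abs(coords[:, 0] - want[0]) + np.abs(coords[:, 1] - want[1])
        dist = dist + (assignment != -1) * 10**9
        seed = int(np.argmin(dist))
        assignment[seed] = order.index(d)
        frontiers[d] = deque([seed])
        targets[d] = max(1, int(round(_DOMAIN_QUOTAS[d] * n)))
    counts = {d: 1 for d in order}
    active = set(order)
    while active:
        for d in list(order):
            if d not in active:
                continue
            if counts[d] >= targets[d]:
                active.discard(d)
                continue
            claimed = False
            while frontiers[d]:
                u = frontiers[d][0]
                nxt = [v for v in adj[u] if assignment[v] == -1]
                if not nxt:
                    frontiers[d].popleft()
                    continue
                v = nxt[int(rng.integers(len(nxt)))]
                assignment[v] = order.index(d)
                frontiers[d].append(v)
                counts[d] += 1
                claimed = True
                break
            if not claimed:
                active.discard(d)
    # attach any leftover spots to an assigned neighbor (keeps contiguity)
    left = np.flatnonzero(assignment == -1)
    while len(left):
        progressed = False
        for u in left:
            lab = next((assignment[v] for v in adj[u] if assignment[v] != -1),
                       -1)
            if lab != -1:
                assignment[u] = lab
                progressed = True
        left = np.flatnonzero(assignment == -1)
        if not progressed and len(left):
            assignment[left] = order.index("other")  # disconnected corner
            break
    return assignment


def _smooth_field(values: np.ndarray, adj: list[list[int]],
                  sweeps: int) -> np.ndarray:
    """Neighbor-averaging smoother; yields positive spatial autocorrelation."""
    out = values.astype(float).copy()
    for _ in range(sweeps):
        nxt = out.copy()
        for i, nbrs in enumerate(adj):
            if nbrs:
                nxt[i] = 0.5 * out[i] + 0.5 * np.mean([out[j] for j in nbrs])
        out = nxt
    return out


# ---------------------------------------------------------------------------
# main generator

def generate_tissue(params: SimulationParams | None = None,
                    seed: int = 0) -> tuple[SpotDataset, SyntheticTruth]:
    """Generate a multi-sample hex-grid cohort with planted structure.

    Returns the dataset (all samples concatenated along the spot axis, with
    cluster/compartment left unassigned) and the ground truth. The same
    ``(params, seed)`` reproduces counts bit for bit.
    """
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(seed)

    gene_ids, roles = _gene_universe(params)
    n_genes = params.n_genes

    # gene-level baseline relative abundance; planted genes get a moderate
    # floor so they clear detection filters at default depth
    w = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    planted_mask = np.array([r != "background" for r in roles])
    w[planted_mask] = rng.lognormal(mean=0.6, sigma=0.4,
                                    size=planted_mask.sum())
    rel_abund = w / w.sum()
    dispersion = rng.lognormal(params.dispersion_meanlog,
                               params.dispersion_sdlog, size=n_genes)

    gi = {g: i for i, g in enumerate(gene_ids)}
    tf_names = [g for g, r in zip(gene_ids, roles) if r == "tf"]
    decoy_tfs = [g for g, r in zip(gene_ids, roles) if r == "decoy_tf"]
    receptors = [g for g, r in zip(gene_ids, roles) if r == "receptor"]
    ligands = [g for g, r in zip(gene_ids, roles) if r == "ligand"]
    decoy_receptors = [g for g, r in zip(gene_ids, roles)
                       if r == "decoy_receptor"]
    decoy_ligands = [g for g, r in zip(gene_ids, roles) if r == "decoy_ligand"]
    de_genes = [g for g, r in zip(gene_ids, roles) if r == "de"]
    sig_genes = {"CSC_LIKE": [g for g, r in zip(gene_ids, roles)
                              if r == "sig_csc"],
                 "IMMUNE_ACTIVATION": [g for g, r in zip(gene_ids, roles)
                                       if r == "sig_immune"]}
    markers = {d: [g for g, r in zip(gene_ids, roles) if r == f"marker_{d}"]
               for d in DOMAINS}
    targets = {tf: [g for g, r in zip(gene_ids, roles)
                    if r == f"targets_{tf}"] for tf in tf_names}

    link_defs = [(ligands[k], receptors[k], tf_names[k],
                  *_LINK_TOPOLOGY[k % len(_LINK_TOPOLOGY)])
                 for k in range(params.n_regulons)]

    # planted group effects: first half up in group A, second half in B
    planted_de = {}
    half = len(de_genes) // 2
    for j, g in enumerate(de_genes):
        planted_de[g] = params.group_log2fc if j < half else -params.group_log2fc

    coords = hex_grid(params.grid_rows, params.grid_cols)
    edges = _hex_edges(coords)
    adj: list[list[int]] = [[] for _ in range(len(coords))]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    sample_names, sample_groups = [], []
    for gidx, gname in enumerate(("A", "B")):
        for k in range(params.n_samples_per_group[gidx]):
            sample_names.append(f"{gname}{k + 1}")
            sample_groups.append(gname)

    all_counts, all_obs, all_domains = [], [], []
    latent_per_regulon = [[] for _ in range(params.n_regulons)]

    for sname, sgroup in zip(sample_names, sample_groups):
        dom_idx = _grow_domains(coords, rng)
        domains = np.array([DOMAINS[i] for i in dom_idx], dtype=object)
        _check_link_adjacency(link_defs, domains, adj)

        n_spots = len(coords)
        depth = params.mean_depth * rng.lognormal(
            mean=-0.5 * np.log(1 + params.depth_cv**2)**1,
            sigma=np.sqrt(np.log(1 + params.depth_cv**2)), size=n_spots)

        log_effect = np.zeros((n_genes, n_spots))
        for d in DOMAINS:
            in_d = domains == d
            if markers[d]:
                log_effect[np.ix_([gi[g] for g in markers[d]], in_d)] \
                    += params.marker_loading
        for name, genes in sig_genes.items():
            dom = "tumor_B" if name == "CSC_LIKE" else "immune"
            log_effect[np.ix_([gi[g] for g in genes], domains == dom)] \
                += params.signature_loading
        if sgroup == "A":
            for g, lfc in planted_de.items():
                if lfc > 0:
                    log_effect[gi[g], :] += lfc * np.log(2)
        else:
            for g, lfc in planted_de.items():
                if lfc < 0:
                    log_effect[gi[g], :] += -lfc * np.log(2)

        # planted regulons: smooth latent field in the receiver domain.
        # Fields of regulons sharing a receiver domain are orthogonalized so
        # that each receptor tracks its own module and not its neighbors'.
        by_receiver: dict[str, list[int]] = {}
        for k, (_, _, _, _, receiver) in enumerate(link_defs):
            by_receiver.setdefault(receiver, []).append(k)
        fields = {}
        for receiver, ks in by_receiver.items():
            idx_recv = np.flatnonzero(domains == receiver)
            sub_adj = _restrict_adj(adj, idx_recv)
            cols = []
            for _ in ks:
                z = rng.standard_normal(len(idx_recv))
                z = _smooth_field(z, sub_adj, params.smoothing_sweeps)
                cols.append(z)
            zmat = np.column_stack(cols)
            zmat = zmat - zmat.mean(axis=0)
            q, _ = np.linalg.qr(zmat)
            for col, k in enumerate(ks):
                z = q[:, col]
                z = (z - z.mean()) / (z.std() + 1e-12)
                fields[k] = (idx_recv, np.clip(z, -3.0, 3.0))
        for k, (lig, rec, tf, sender, receiver) in enumerate(link_defs):
            idx_recv, z = fields[k]
            act = np.zeros(n_spots)
            act[idx_recv] = 0.5 * z      # centered smooth activity field
            latent_per_regulon[k].append(act)

            module_rows = [gi[g] for g in targets[tf]] + [gi[tf]]
            log_effect[module_rows, :] += params.target_loading * act
            log_effect[gi[rec], :] += params.receptor_loading * act
            in_sender = domains == sender
            log_effect[gi[lig], in_sender] += params.ligand_loading

        mu = rel_abund[:, None] * depth[None, :] * np.exp(log_effect)
        r = 1.0 / dispersion
        p = r[:, None] / (r[:, None] + mu)
        counts = rng.negative_binomial(r[:, None], p)

        obs = pd.DataFrame({
            "array_row": coords[:, 0], "array_col": coords[:, 1],
            "sample_id": sname, "group": sgroup,
            "cluster": pd.NA, "compartment": pd.NA,
        }, index=pd.Index([f"{sname}_{r0:03d}_{c0:03d}"
                           for r0, c0 in coords], name="barcode"))
        all_counts.append(counts)
        all_obs.append(obs)
        all_domains.append(pd.Series(domains, index=obs.index))

    counts = np.concatenate(all_counts, axis=1) if all_counts else \
        np.zeros((n_genes, 0), dtype=np.int64)
    obs = pd.concat(all_obs) if all_obs else _empty_obs()
    domain_map = pd.concat(all_domains) if all_domains else pd.Series(dtype=object)
    ds = SpotDataset(counts, np.array(gene_ids, dtype=object), obs)

    regs = []
    for k, (lig, rec, tf, sender, receiver) in enumerate(link_defs):
        latent = (np.concatenate(latent_per_regulon[k])
                  if latent_per_regulon[k] else np.zeros(0))
        regs.append(PlantedRegulon(tf, targets[tf], latent, receiver))
    links = [PlantedLink(lig, rec, tf, sender, receiver,
                         params.target_correlation)
             for (lig, rec, tf, sender, receiver) in link_defs]
    truth = SyntheticTruth(
        domain_map=domain_map, planted_regulons=regs, planted_links=links,
        planted_de=planted_de,
        planted_signatures={n: (g, "tumor_B" if n == "CSC_LIKE" else "immune")
                            for n, g in sig_genes.items()},
        tf_list=tf_names + decoy_tfs,
        decoy_receptors=decoy_receptors, decoy_ligands=decoy_ligands,
        generator_params={**asdict(params), "seed": int(seed)})
    return ds, truth


def _gene_universe(params: SimulationParams):
    """Deterministic gene naming by role; background genes fill the rest."""
    gene_ids: list[str] = []
    roles: list[str] = []

    def add(names, role):
        gene_ids.extend(names)
        roles.extend([role] * len(names))

    tfs = [f"TF{k + 1:02d}" for k in range(params.n_regulons)]
    add(tfs, "tf")
    for tf in tfs:
        add([f"TG_{tf}_{j + 1:02d}" for j in range(params.targets_per_regulon)],
            f"targets_{tf}")
    add([f"REC{k + 1:02d}" for k in range(params.n_regulons)], "receptor")
    add([f"LIG{k + 1:02d}" for k in range(params.n_regulons)], "ligand")
    add([f"DTF{k + 1:02d}" for k in range(params.n_decoy_tfs)], "decoy_tf")
    add([f"DREC{k + 1:02d}" for k in range(params.n_decoy_receptors)],
        "decoy_receptor")
    add([f"DLIG{k + 1:02d}" for k in range(params.n_decoy_receptors)],
        "decoy_ligand")
    add([f"DE{j + 1:03d}" for j in range(params.n_de_genes)], "de")
    add([f"CSC{j + 1:02d}" for j in range(params.n_signature_genes)],
        "sig_csc")
    add([f"IMM{j + 1:02d}" for j in range(params.n_signature_genes)],
        "sig_immune")
    for d in DOMAINS:
        add([f"MK_{d}_{j + 1:02d}" for j in range(params.n_markers_per_domain)],
            f"marker_{d}")
    n_bg = params.n_genes - len(gene_ids)
    add([f"BG{j + 1:04d}" for j in range(n_bg)], "background")
    return gene_ids, roles


def _restrict_adj(adj: list[list[int]], idx: np.ndarray) -> list[list[int]]:
    pos = {int(v): i for i, v in enumerate(idx)}
    return [[pos[v] for v in adj[int(u)] if v in pos] for u in idx]


def _check_link_adjacency(link_defs, domains, adj) -> None:
    needed = {(s, r) for (_, _, _, s, r) in link_defs}
    for s, r in needed:
        touching = any(
            {domains[u], domains[v]} == {s, r}
            for u, nbrs in enumerate(adj) for v in nbrs if v > u)
        if not touching:
            raise ParameterError(
                f"grown domains leave planted pair ({s}, {r}) non-adjacent; "
                f"enlarge the grid")


def _empty_obs() -> pd.DataFrame:
    return pd.DataFrame(columns=["array_row", "array_col", "sample_id",
                                 "group", "cluster", "compartment"],
                        index=pd.Index([], name="barcode"))


def truth_to_annotations(truth: SyntheticTruth) -> pd.DataFrame:
    """Cluster/compartment annotation from the planted domain map.

    Domains become cluster labels; tumor_A and tumor_B merge into the tumor
    compartment, immune and CAF map to themselves, anything else to other.
    """
    if len(truth.domain_map) == 0:
        raise ValidationError("truth has an empty domain map")
    unknown = set(truth.domain_map.unique()) - set(DOMAINS)
    if unknown:
        raise ValidationError(f"unknown domain labels: {sorted(unknown)}")
    return pd.DataFrame({
        "cluster": truth.domain_map.astype(object),
        "compartment": truth.domain_map.map(DOMAIN_TO_COMPARTMENT),
    })


def lr_reference_from_truth(truth: SyntheticTruth) -> LRReference:
    """Ligand–receptor table covering planted links plus decoy pairs.

    Decoy receptors get decoy ligand partners so that only the correlation
    rules — not mere absence from the reference — can exclude them.
    """
    pairs = [LRPair(f"planted_{k + 1:02d}", (l.ligand,), (l.receptor,))
             for k, l in enumerate(truth.planted_links)]
    for j, (lig, rec) in enumerate(zip(truth.decoy_ligands,
                                       truth.decoy_receptors)):
        pairs.append(LRPair(f"decoy_{j + 1:02d}", (lig,), (rec,)))
    return LRReference(pairs)


def null_cohort_params(n_per_group: tuple[int, int] = (6, 6),
                       n_genes: int = 2000,
                       grid_rows: int = 16, grid_cols: int = 24,
                       ) -> SimulationParams:
    """A cohort with no planted effects: no regulons, zero group fold change.

    Counts are exchangeable across groups by construction, so two-group
    differential expression should be calibrated at its nominal level.
    """
    return SimulationParams(
        n_samples_per_group=n_per_group, grid_rows=grid_rows,
        grid_cols=grid_cols, n_genes=n_genes, n_regulons=0,
        n_decoy_tfs=0, n_decoy_receptors=0, n_de_genes=0,
        n_signature_genes=0, n_markers_per_domain=0, group_log2fc=0.0)
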