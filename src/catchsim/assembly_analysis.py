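"""Trajectory analysis: hydrogen bonds, association graphs, cluster
classification and assembly kinetics.

A pair of peptides is *joined* when either (1) a majority of the
backbone hydrogen-bonding sites between them are occupied, or (2) they
share at least one hydrophobic sidechain contact.  Connected components
of joined pairs are classified by size: 1 = free peptide, 2-5 =
oligomer, >5 = fibril.  Strand-order statistics (alternating versus
like-charge neighbours within a beta-sheet) use the stricter
hydrogen-bond-majority notion of neighbourhood, since strand order is a
backbone-registry concept; hydrophobic-only (bilayer) contacts are
reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .forcefield import KIND_CO, KIND_NH, KIND_R, InteractionTable, SystemTopology

__all__ = [
    "detect_hbonds",
    "hydrophobic_contacts",
    "build_association_graph",
    "classify_clusters",
    "kinetics_series",
    "strand_order_stats",
    "AssemblyKinetics",
    "StrandOrderStats",
    "default_hb_majority_threshold",
]


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def default_hb_majority_threshold(topology: SystemTopology) -> int:
    """Majority of backbone H-bond sites: ceil((L+1)/2) for L residues."""
    L = max(len(c) for c in topology.chains)
    return (L + 2) // 2


def detect_hbonds(
    positions: np.ndarray,
    topology: SystemTopology,
    box_side: float,
    table: InteractionTable | None = None,
) -> list[tuple[int, int]]:
    """Geometric hydrogen-bond detection on a snapshot.

    Returns (NH bead, CO bead) pairs that lie within the hydrogen-bond
    well and satisfy the auxiliary directionality constraints, excluding
    pairs within the same or adjacent residues of one chain.  Each NH
    and each CO participates in at most one bond; when several
    candidates compete the closest pair wins.
    """
    table = table or topology.table
    hbd = table.hb_distance
    aux_min = table.hb_aux_min
    kind = topology.bead_kind
    nh_idx = np.where(kind == KIND_NH)[0]
    co_idx = np.where(kind == KIND_CO)[0]
    if nh_idx.size == 0 or co_idx.size == 0:
        return []

    d = _min_image(
        positions[nh_idx][:, None, :] - positions[co_idx][None, :, :], box_side
    )
    dist = np.sqrt((d**2).sum(axis=2))

    same_chain = (
        topology.chain_id[nh_idx][:, None] == topology.chain_id[co_idx][None, :]
    )
    close_res = (
        np.abs(
            topology.residue_index[nh_idx][:, None]
            - topology.residue_index[co_idx][None, :]
        )
        <= 1
    )
    candidate = (dist < hbd) & ~(same_chain & close_res)

    # auxiliary directionality constraints on the flanking beads
    def flanks(bead: int) -> list[int]:
        k = kind[bead]
        r = topology.residue_index[bead]
        out = [bead + 1 if k == KIND_NH else bead - 1]  # CA of same residue
        if k == KIND_NH and r > 0:
            out.append(bead - 2)  # CO of previous residue
        if k == KIND_CO and bead + 2 < len(kind) and topology.chain_id[
            bead + 2
        ] == topology.chain_id[bead]:
            out.append(bead + 2)  # NH of next residue
        return out

    pairs = []
    for a, b in zip(*np.where(candidate)):
        nh, co = int(nh_idx[a]), int(co_idx[b])
        ok = True
        for f in flanks(nh):
            df = _min_image(positions[f] - positions[co], box_side)
            if np.sqrt(df @ df) < aux_min:
                ok = False
                break
        if ok:
            for f in flanks(co):
                df = _min_image(positions[f] - positions[nh], box_side)
                if np.sqrt(df @ df) < aux_min:
                    ok = False
                    break
        if ok:
            pairs.append((dist[a, b], nh, co))

    # closest-pair-wins unique matching
    pairs.sort()
    used_nh: set[int] = set()
    used_co: set[int] = set()
    out = []
    for _, nh, co in pairs:
        if nh in used_nh or co in used_co:
            continue
        used_nh.add(nh)
        used_co.add(co)
        out.append((nh, co))
    return out


def hydrophobic_contacts(
    positions: np.ndarray,
    topology: SystemTopology,
    box_side: float,
) -> list[tuple[int, int]]:
    """Inter-chain hydrophobic sidechain pairs inside their attractive well."""
    hyd = np.array(
        [
            topology.bead_kind[i] == KIND_R
            and topology.chains[topology.chain_id[i]]
            .residues[topology.residue_index[i]]
            .hydrophobic
            for i in range(topology.n_beads)
        ]
    )
    idx = np.where(hyd)[0]
    if idx.size < 2:
        return []
    d = _min_image(positions[idx][:, None, :] - positions[idx][None, :, :], box_side)
    dist = np.sqrt((d**2).sum(axis=2))
    edge = topology.well_edge[topology.itype[idx][:, None], topology.itype[idx][None, :]]
    depth = topology.well_depth[
        topology.itype[idx][:, None], topology.itype[idx][None, :]
    ]
    diff_chain = (
        topology.chain_id[idx][:, None] != topology.chain_id[idx][None, :]
    )
    inside = (edge > 0) & (depth < 0) & (dist < edge) & diff_chain
    out = []
    for a, b in zip(*np.where(np.triu(inside, k=1))):
        out.append((int(idx[a]), int(idx[b])))
    return out


def build_association_graph(
    positions: np.ndarray,
    topology: SystemTopology,
    box_side: float,
    hb_majority_threshold: int | None = None,
    table: InteractionTable | None = None,
) -> nx.Graph:
    """Peptide-association graph for one snapshot.

    Nodes are chain indices (attribute ``species``, ``charge``); every
    chain pair with any hydrogen bond or hydrophobic contact gets an
    edge with counts ``n_hbonds`` and ``n_hydrophobic_contacts`` and the
    boolean ``joined`` per the two-condition rule.
    """
    if hb_majority_threshold is None:
        hb_majority_threshold = default_hb_majority_threshold(topology)
    g = nx.Graph()
    for c, pep in enumerate(topology.chains):
        g.add_node(c, species=pep.id, charge=pep.net_charge)

    counts: dict[tuple[int, int], list[int]] = {}
    for nh, co in detect_hbonds(positions, topology, box_side, table):
        ci, cj = int(topology.chain_id[nh]), int(topology.chain_id[co])
        if ci == cj:
            continue
        key = (min(ci, cj), max(ci, cj))
        counts.setdefault(key, [0, 0])[0] += 1
    for a, b in hydrophobic_contacts(positions, topology, box_side):
        ci, cj = int(topology.chain_id[a]), int(topology.chain_id[b])
        key = (min(ci, cj), max(ci, cj))
        counts.setdefault(key, [0, 0])[1] += 1

    for (ci, cj), (nhb, nphob) in counts.items():
        g.add_edge(
            ci,
            cj,
            n_hbonds=nhb,
            n_hydrophobic_contacts=nphob,
            joined=(nhb >= hb_majority_threshold) or (nphob >= 1),
        )
    return g


def classify_clusters(
    g: nx.Graph,
) -> tuple[set[int], list[set[int]], list[set[int]]]:
    """Partition peptides into free / oligomers (2-5) / fibrils (>5).

    Connected components of joined edges; singletons are free peptides.
    """
    joined = nx.Graph()
    joined.add_nodes_from(g.nodes)
    joined.add_edges_from(
        (u, v) for u, v, d in g.edges(data=True) if d.get("joined")
    )
    free: set[int] = set()
    oligomers: list[set[int]] = []
    fibrils: list[set[int]] = []
    for comp in nx.connected_components(joined):
        if len(comp) == 1:
            free |= comp
        elif len(comp) <= 5:
            oligomers.append(set(comp))
        else:
            fibrils.append(set(comp))
    return free, oligomers, fibrils


@dataclass
class AssemblyKinetics:
    """Assembly time series on the snapshot grid."""

    times: np.ndarray
    n_free: np.ndarray
    n_in_oligomers: np.ndarray
    n_in_fibrils: np.ndarray
    n_hbonds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_free": self.n_free,
                "n_oligomer_peptides": self.n_in_oligomers,
                "n_fibril_peptides": self.n_in_fibrils,
                "n_hbonds": self.n_hbonds,
            }
        )

    def time_to_depletion(self, fraction: float = 0.5) -> float:
        """First snapshot time at which the free-peptide count has
        dropped to ``fraction`` of the total, or +inf if never."""
        total = self.n_free[0] + self.n_in_oligomers[0] + self.n_in_fibrils[0]
        hit = np.where(self.n_free <= fraction * total)[0]
        return float(self.times[hit[0]]) if hit.size else math.inf


def kinetics_series(
    traj,
    hb_majority_threshold: int | None = None,
) -> AssemblyKinetics:
    """Per-snapshot H-bond count and free/oligomer/fibril peptide counts.

    The peptide-count conservation invariant
    ``n_free + n_in_oligomers + n_in_fibrils == n_chains`` holds at
    every snapshot by construction.
    """
    topo = traj.topology
    S = traj.n_snapshots
    n_free = np.zeros(S, dtype=int)
    n_olig = np.zeros(S, dtype=int)
    n_fib = np.zeros(S, dtype=int)
    n_hb = np.zeros(S, dtype=int)
    for s in range(S):
        pos = traj.positions[s]
        n_hb[s] = len(detect_hbonds(pos, topo, traj.box_side))
        g = build_association_graph(
            pos, topo, traj.box_side, hb_majority_threshold
        )
        free, oligomers, fibrils = classify_clusters(g)
        n_free[s] = len(free)
        n_olig[s] = sum(len(c) for c in oligomers)
        n_fib[s] = sum(len(c) for c in fibrils)
    return AssemblyKinetics(
        times=traj.times.copy(),
        n_free=n_free,
        n_in_oligomers=n_olig,
        n_in_fibrils=n_fib,
        n_hbonds=n_hb,
    )


@dataclass(frozen=True)
class StrandOrderStats:
    """Charge ordering of neighbouring strands within one cluster."""

    n_alternating_neighbors: int
    n_like_charge_neighbors: int
    cation_fraction: float


def strand_order_stats(
    cluster: Iterable[int],
    g: nx.Graph,
    hb_majority_threshold: int | None = None,
) -> StrandOrderStats:
    """Alternating vs like-charge neighbour counts within a cluster.

    Within-sheet neighbours are chain pairs whose hydrogen-bond count
    meets the majority threshold (backbone registry); the cation
    fraction is the fraction of peptides in the cluster with positive
    net charge, the model-side comparator for the experimentally
    estimated cationic-to-anionic content ratio.
    """
    members = set(cluster)
    if hb_majority_threshold is None:
        # infer from any edge data? fall back to 6, the 11-mer majority
        hb_majority_threshold = 6
    n_alt = 0
    n_like = 0
    for u, v, d in g.edges(data=True):
        if u in members and v in members:
            if d.get("n_hbonds", 0) >= hb_majority_threshold:
                qu = g.nodes[u]["charge"]
                qv = g.nodes[v]["charge"]
                if qu * qv < 0:
                    n_alt += 1
                else:
                    n_like += 1
    n_cat = sum(1 for c in members if g.nodes[c]["charge"] > 0)
    return StrandOrderStats(
        n_alternating_neighbors=n_alt,
        n_like_charge_neighbors=n_like,
        cation_fraction=n_cat / len(members) if members else float("nan"),
    )
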