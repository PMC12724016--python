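"""Dynamic network analysis: contact-filtered correlation graphs and optimal
allosteric pathways.

Residues are nodes (anchored at the Cα).  An edge joins residues i and j when
their minimum heavy-atom distance is below the contact cutoff in at least the
occupancy-threshold fraction of frames, excluding trivial sequence neighbors.
Retained edges carry the weight

    W_ij = -log |C_ij|,

so the minimum total-weight path between a source and a sink maximizes the
product of correlation magnitudes along the route — the optimal pathway for
allosteric signal transduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .essential import CorrelationMatrix
from .exceptions import ConfigError, InputError
from .trajio import Topology, Trajectory

__all__ = [
    "DynamicNetwork",
    "Path",
    "contact_occupancy",
    "build_network",
    "build_network_from_matrices",
    "optimal_path",
    "path_report",
]

logger = logging.getLogger(__name__)


@dataclass
class DynamicNetwork:
    """Residue graph with occupancy-filtered, correlation-weighted edges.

    Nodes are 1-based author resids; edge attributes are ``occupancy``,
    ``cij`` and ``weight``.
    """

    graph: nx.Graph
    contact_cutoff: float
    occupancy_threshold: float
    neighbor_exclusion: int
    dropped_zero_correlation: int = 0

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Path:
    """An optimal source-to-sink route through the network."""

    nodes: tuple[int, ...]
    total_weight: float
    edges: list[dict] = field(default_factory=list)


def contact_occupancy(
    traj: Trajectory, residue_ordinals: np.ndarray, cutoff: float = 4.5
) -> np.ndarray:
    """Fraction of frames in which each residue pair is in contact.

    Contact = minimum heavy-atom/heavy-atom distance < cutoff.  Returns a
    symmetric ``n x n`` matrix over ``residue_ordinals`` with unit diagonal.
    """
    top = traj.topology
    heavy = top.heavy_atom_mask()
    groups = []
    for ordinal in residue_ordinals:
        atoms = top.atoms_of_residue(int(ordinal))
        atoms = atoms[heavy[atoms]]
        if atoms.size == 0:
            raise InputError(f"residue {top.residue_label(int(ordinal))} has no heavy atoms")
        groups.append(atoms)
    all_atoms = np.concatenate(groups)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    n = len(groups)
    counts = np.zeros((n, n))
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f, all_atoms], traj.coords[f, all_atoms])
        for a in range(n):
            sa = slice(offsets[a], offsets[a + 1])
            for b in range(a + 1, n):
                sb = slice(offsets[b], offsets[b + 1])
                if d[sa, sb].min() < cutoff:
                    counts[a, b] += 1
    occ = (counts + counts.T) / traj.n_frames
    np.fill_diagonal(occ, 1.0)
    return occ


def build_network_from_matrices(
    occupancy: np.ndarray,
    dccm: CorrelationMatrix,
    *,
    contact_cutoff: float = 4.5,
    occupancy_threshold: float = 0.75,
    neighbor_exclusion: int = 1,
    chains: np.ndarray | None = None,
) -> DynamicNetwork:
    """Assemble the network from a precomputed occupancy matrix and a DCCM."""
    if not 0 < occupancy_threshold <= 1:
        raise ConfigError(f"occupancy_threshold {occupancy_threshold} outside (0, 1]")
    if contact_cutoff <= 0:
        raise ConfigError("contact_cutoff must be positive")
    n = dccm.n_residues
    if occupancy.shape != (n, n):
        raise InputError("occupancy matrix does not match the DCCM residues")
    resids = dccm.residue_resids
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in resids)
    dropped = 0
    for a in range(n):
        for b in range(a + 1, n):
            if occupancy[a, b] < occupancy_threshold:
                continue
            same_chain = chains is None or chains[a] == chains[b]
            if same_chain and abs(int(resids[a]) - int(resids[b])) <= neighbor_exclusion:
                continue
            c = dccm.matrix[a, b]
            if abs(c) < 1e-6:
                dropped += 1
                continue
            w = -np.log(min(abs(c), 1.0))
            g.add_edge(int(resids[a]), int(resids[b]),
                       occupancy=float(occupancy[a, b]), cij=float(c), weight=float(w))
    if dropped:
        logger.info("dropped %d zero-correlation edges", dropped)
    if g.number_of_edges() == 0:
        logger.warning("dynamic network has no edges")
    return DynamicNetwork(g, contact_cutoff, occupancy_threshold, neighbor_exclusion, dropped)


def build_network(
    traj: Trajectory,
    dccm: CorrelationMatrix,
    *,
    contact_cutoff: float = 4.5,
    occupancy_threshold: float = 0.75,
    neighbor_exclusion: int = 1,
) -> DynamicNetwork:
    """Build the dynamic network from a trajectory and its DCCM."""
    if not 0 < occupancy_threshold <= 1:
        raise ConfigError(f"occupancy_threshold {occupancy_threshold} outside (0, 1]")
    occ = contact_occupancy(traj, dccm.residue_indices, contact_cutoff)
    chains = traj.topology.residue_chains[dccm.residue_indices]
    return build_network_from_matrices(
        occ,
        dccm,
        contact_cutoff=contact_cutoff,
        occupancy_threshold=occupancy_threshold,
        neighbor_exclusion=neighbor_exclusion,
        chains=chains,
    )


def optimal_path(network: DynamicNetwork, source: int, sink: int) -> Path | None:
    """Minimum total-weight path (Dijkstra; weights are non-negative).

    Ties are broken toward the lexicographically smallest residue-index
    sequence.  Returns ``None`` when source and sink are disconnected.
    """
    g = network.graph
    for node in (source, sink):
        if node not in g:
            raise InputError(f"residue {node} is not a network node")
    if source == sink:
        return Path((source,), 0.0)
    dist = nx.single_source_dijkstra_path_length(g, sink, weight="weight")
    if source not in dist:
        return None
    # Greedy reconstruction source -> sink over shortest-path-DAG edges,
    # choosing the smallest next residue index: yields the lexicographically
    # smallest minimum-weight node sequence.
    tol = 1e-10
    nodes = [source]
    total = 0.0
    current = source
    visited = {source}
    while current != sink:
        best = None
        for nbr in g.neighbors(current):
            if nbr in visited or nbr not in dist:
                continue
            w = g.edges[current, nbr]["weight"]
            if abs(w + dist[nbr] - dist[current]) <= tol * max(1.0, dist[current]):
                if best is None or nbr < best:
                    best = nbr
        if best is None:  # numerical fallback: retighten via fresh Dijkstra
            rest = nx.dijkstra_path(g, current, sink, weight="weight")
            for nbr in rest[1:]:
                total += g.edges[nodes[-1], nbr]["weight"]
                nodes.append(nbr)
            current = sink
            break
        total += g.edges[current, best]["weight"]
        nodes.append(best)
        visited.add(best)
        current = best
    edges = [
        {
            "res_i": i,
            "res_j": j,
            "cij": g.edges[i, j]["cij"],
            "occupancy": g.edges[i, j]["occupancy"],
            "weight": g.edges[i, j]["weight"],
        }
        for i, j in zip(nodes, nodes[1:])
    ]
    return Path(tuple(nodes), float(total), edges)


def path_report(paths: list[Path | None], topology: Topology | None = None) -> pd.DataFrame:
    """Tabulate paths edge-by-edge (one row per edge, stable column order)."""
    label = {}
    if topology is not None:
        for ordinal in range(topology.n_residues):
            label[int(topology.residue_resids[ordinal])] = topology.residue_label(ordinal)
    rows = []
    for p, path in enumerate(paths):
        if path is None:
            continue
        for step, e in enumerate(path.edges):
            rows.append(
                {
                    "path": p,
                    "step": step,
                    "res_i": e["res_i"],
                    "res_j": e["res_j"],
                    "label_i": label.get(e["res_i"], str(e["res_i"])),
                    "label_j": label.get(e["res_j"], str(e["res_j"])),
                    "cij": e["cij"],
                    "occupancy": e["occupancy"],
                    "weight": e["weight"],
                    "total_weight": path.total_weight,
                }
            )
    columns = ["path", "step", "res_i", "res_j", "label_i", "label_j",
               "cij", "occupancy", "weight", "total_weight"]
    return pd.DataFrame(rows, columns=columns)


def export_edges(network: DynamicNetwork) -> pd.DataFrame:
    """Edge list as a DataFrame (res_i, res_j, occupancy, cij, weight)."""
    rows = [
        {"res_i": i, "res_j": j, "occupancy": d["occupancy"],
         "cij": d["cij"], "weight": d["weight"]}
        for i, j, d in sorted(network.graph.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "occupancy", "cij", "weight"])
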