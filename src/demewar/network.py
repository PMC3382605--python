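"""Migration networks on demes and the per-individual migration step.

The demes sit on the nodes of an undirected simple graph.  Three
generators are provided at matched mean connectivity z:

* Erdos-Renyi G(D, p) with p = z/(D-1) — Poisson degree distribution
  in the large-D limit, finite degree variance;
* the island model — the complete graph K_D, zero degree variance
  (every deme neighbours every other);
* scale-free (Barabasi-Albert preferential attachment with attachment
  count round(z/2)) — heavy-tailed, the most heterogeneous comparator.

Each generation every individual migrates independently with
probability m to a uniformly chosen neighbour deme; fitness and
strategy travel unchanged, empty demes are legal destinations
(recolonisation), and individuals in isolated demes stay put.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model import ModelParams, PopulationState, TopologyKind, TopologySpec

__all__ = [
    "MigrationNetwork",
    "generate_er",
    "generate_island",
    "generate_scale_free",
    "build_network",
    "migrate",
    "load_network",
    "export_network",
]


@dataclass
class MigrationNetwork:
    """Undirected simple graph on deme ids 0..D-1.

    ``neighbors[d]`` is a sorted int array of the demes adjacent to d;
    the sort order is part of the randomness contract (a migrant's
    destination is ``neighbors[d][rng.integers(k)]``).
    """

    n_nodes: int
    neighbors: list[np.ndarray] = field(repr=False)

    @classmethod
    def from_graph(cls, g: nx.Graph, n_nodes: int) -> "MigrationNetwork":
        nbrs = [
            np.array(sorted(g.neighbors(d)), dtype=np.intp) if d in g else np.empty(0, np.intp)
            for d in range(n_nodes)
        ]
        return cls(n_nodes=n_nodes, neighbors=nbrs)

    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def edge_set(self) -> set[tuple[int, int]]:
        edges = set()
        for u, nb in enumerate(self.neighbors):
            for v in nb:
                edges.add((min(u, int(v)), max(u, int(v))))
        return edges


def _maybe_resample(make, rng: np.random.Generator, resample_isolated: bool,
                    max_tries: int = 1000) -> nx.Graph:
    g = make(rng)
    if not resample_isolated:
        return g
    for _ in range(max_tries):
        if min((d for _, d in g.degree()), default=0) >= 1:
            return g
        g = make(rng)
    raise RuntimeError("could not sample a network with min degree >= 1")


def generate_er(D: int, z: float, rng: np.random.Generator,
                resample_isolated: bool = False) -> MigrationNetwork:
    """Erdos-Renyi G(D, p) with p = z/(D-1); isolated nodes permitted."""
    if not (0 < z < D):
        raise ValueError(f"ER mean degree z must satisfy 0 < z < D, got z={z}, D={D}")
    p = z / (D - 1) if D > 1 else 0.0
    g = _maybe_resample(
        lambda r: nx.gnp_random_graph(D, p, seed=r), rng, resample_isolated
    )
    return MigrationNetwork.from_graph(g, D)


def generate_island(D: int) -> MigrationNetwork:
    """Island model: the complete graph K_D (degree D-1 everywhere)."""
    if D < 2:
        raise ValueError(f"island model needs D >= 2, got {D}")
    return MigrationNetwork.from_graph(nx.complete_graph(D), D)


def generate_scale_free(D: int, z: float, rng: np.random.Generator) -> MigrationNetwork:
    """Barabasi-Albert graph with attachment count round(z/2) (mean degree ~ z)."""
    m_attach = int(round(z / 2))
    if m_attach < 1:
        raise ValueError(f"attachment count round(z/2) must be >= 1, got z={z}")
    if D <= m_attach:
        raise ValueError(f"BA graph needs D > round(z/2), got D={D}, z={z}")
    g = nx.barabasi_albert_graph(D, m_attach, seed=rng)
    return MigrationNetwork.from_graph(g, D)


def build_network(spec: TopologySpec, D: int, rng: np.random.Generator,
                  resample_isolated: bool = False) -> MigrationNetwork:
    """Build the network a replicate will use (quenched for the whole run)."""
    if spec.kind is TopologyKind.ERDOS_RENYI:
        return generate_er(D, spec.mean_degree, rng, resample_isolated)
    if spec.kind is TopologyKind.ISLAND:
        return generate_island(D)
    if spec.kind is TopologyKind.SCALE_FREE:
        return generate_scale_free(D, spec.mean_degree, rng)
    if spec.kind is TopologyKind.USER:
        return load_network(spec.edge_list_path, D)
    raise ValueError(f"unknown topology kind {spec.kind!r}")


def migrate(
    state: PopulationState,
    net: MigrationNetwork,
    m: float,
    rng: np.random.Generator,
) -> PopulationState:
    """One migration step; conserves the multiset of individuals exactly.

    Demes are processed in id order on their pre-migration rosters.  Per
    non-empty deme one ``rng.random(n)`` call decides who moves; if any
    do and the deme has k >= 1 neighbours, one ``rng.integers(0, k,
    size=n_movers)`` call picks destinations.  Would-be migrants from an
    isolated deme stay.  Stayers keep their order; arrivals append in
    processing order.  Deme sizes may leave N0 freely here.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"migration rate m must be in [0, 1], got {m}")
    if net.n_nodes != state.n_demes:
        raise ValueError("network size does not match number of demes")
    D = state.n_demes
    stay_s: list[np.ndarray] = []
    stay_f: list[np.ndarray] = []
    mov_s: list[np.ndarray] = []
    mov_f: list[np.ndarray] = []
    mov_dest: list[np.ndarray] = []
    for d in range(D):
        s, f = state.strategies[d], state.fitness[d]
        n = len(s)
        if n == 0:
            stay_s.append(s)
            stay_f.append(f)
            continue
        u = rng.random(n)
        moving = u < m
        nbrs = net.neighbors[d]
        k = len(nbrs)
        n_mov = int(moving.sum())
        if n_mov == 0 or k == 0:
            stay_s.append(s)
            stay_f.append(f)
            continue
        mov_dest.append(nbrs[rng.integers(0, k, size=n_mov)])
        stay_s.append(s[~moving])
        stay_f.append(f[~moving])
        mov_s.append(s[moving])
        mov_f.append(f[moving])
    if not mov_dest:
        state.strategies = stay_s
        state.fitness = stay_f
        return state
    # stable sort by destination keeps arrivals in processing order
    all_dest = np.concatenate(mov_dest)
    order = np.argsort(all_dest, kind="stable")
    arr_s = np.concatenate(mov_s)[order]
    arr_f = np.concatenate(mov_f)[order]
    bounds = np.searchsorted(all_dest[order], np.arange(D + 1))
    for d in range(D):
        lo, hi = bounds[d], bounds[d + 1]
        if hi > lo:
            state.strategies[d] = np.concatenate([stay_s[d], arr_s[lo:hi]])
            state.fitness[d] = np.concatenate([stay_f[d], arr_f[lo:hi]])
        else:
            state.strategies[d] = stay_s[d]
            state.fitness[d] = stay_f[d]
    return state


def load_network(path, D: int | None = None) -> MigrationNetwork:
    """Read a whitespace-delimited edge list ("u v" per line, 0-based ids)."""
    edges: list[tuple[int, int]] = []
    max_node = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'u v', got {line!r}")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop {u}-{v} not allowed")
            if u < 0 or v < 0:
                raise ValueError(f"{path}:{lineno}: negative node id")
            edges.append((u, v))
            max_node = max(max_node, u, v)
    n = D if D is not None else max_node + 1
    if max_node >= n:
        raise ValueError(f"node id {max_node} out of range for D={n}")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return MigrationNetwork.from_graph(g, n)


def export_network(net: MigrationNetwork, path) -> None:
    """Write the sorted edge list; load o export is the identity."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edge_set()):
            fh.write(f"{u} {v}\n")
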