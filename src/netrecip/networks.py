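"""Network structures and initial strategy placement.

Generators for the contact structures the model is studied on: ring and
planar lattices (periodic boundaries, so every node has degree exactly 4 or
8), single-scale networks (Watts-Strogatz with full rewiring, narrow degree
distribution), scale-free networks (Barabasi-Albert, hub-dominated), the
Holme-Kim scale-free variant with tunable transitivity, and the star and
complete graphs used as analytic reference cases.  All generators return
connected graphs; random models are resampled with an incremented seed when
a draw comes out disconnected.

Graph construction is delegated to :mod:`networkx`; the :class:`Network`
container keeps the edge list as a plain integer array, which is what the
game dynamics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "StrategyAssignment",
    "build_lattice",
    "build_random_network",
    "assign_initial_strategies",
    "read_edge_list",
    "write_edge_list",
]

logger = logging.getLogger(__name__)

LATTICE_KINDS = ("ring4", "square4", "moore8")
RANDOM_MODELS = ("single_scale", "scale_free", "holme_kim", "complete", "star")


@dataclass(frozen=True)
class Network:
    """Static undirected connected graph, stored as a sorted edge array.

    ``edges`` has shape (E, 2) with ``edges[:, 0] < edges[:, 1]``, 0-based
    node indices, no self-loops, no multi-edges.
    """

    n_nodes: int
    edges: np.ndarray
    name: str = "network"
    _adjacency: tuple = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64)
        if edges.ndim != 2 or edges.shape[1] != 2:
            raise ValueError("edges must be an (E, 2) array")
        if np.any(edges[:, 0] == edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if np.any((edges < 0) | (edges >= self.n_nodes)):
            raise ValueError("edge endpoint out of range")
        lo = np.minimum(edges[:, 0], edges[:, 1])
        hi = np.maximum(edges[:, 0], edges[:, 1])
        edges = np.stack([lo, hi], axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
        if len(edges) and np.any(np.all(edges[1:] == edges[:-1], axis=1)):
            raise ValueError("multi-edges are not allowed")
        object.__setattr__(self, "edges", edges)
        if not self.is_connected():
            raise ValueError("network must be connected")

    # -- derived structure -------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        return np.bincount(self.edges.ravel(), minlength=self.n_nodes)

    @property
    def k_max(self) -> int:
        return int(self.degrees.max())

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, name: str = "network") -> "Network":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = np.array(
            [[mapping[u], mapping[v]] for u, v in g.edges()], dtype=np.int64
        ).reshape(-1, 2)
        return cls(n_nodes=g.number_of_nodes(), edges=edges, name=name)

    def incidence(self):
        """Per-node incident edges: (edge indices, side) arrays, cached.

        ``side`` is 0 when the node is ``edges[:, 0]`` of the edge, 1
        otherwise; the game dynamics store one abstention counter per
        directed edge side.
        """
        if self._adjacency is None:
            by_node = [([], []) for _ in range(self.n_nodes)]
            for e, (u, v) in enumerate(self.edges):
                by_node[u][0].append(e)
                by_node[u][1].append(0)
                by_node[v][0].append(e)
                by_node[v][1].append(1)
            cached = tuple(
                (np.array(eidx, dtype=np.int64), np.array(side, dtype=np.int64))
                for eidx, side in by_node
            )
            object.__setattr__(self, "_adjacency", cached)
        return self._adjacency

    def neighbors(self, node: int) -> np.ndarray:
        eidx, side = self.incidence()[node]
        return self.edges[eidx, 1 - side]


@dataclass(frozen=True)
class StrategyAssignment:
    """Initial per-node strategy labels plus placement bookkeeping.

    ``is_c`` is a boolean array over nodes (True = cooperator);
    ``isolated_fraction`` is the share of initial C's with no C-neighbor.
    """

    is_c: np.ndarray
    scheme: str
    seed: int | None
    isolated_fraction: float

    @property
    def count_c(self) -> int:
        return int(self.is_c.sum())


def _torus_edges(side: int, moore: bool) -> np.ndarray:
    """Edges of a side x side torus; von Neumann (4) or Moore (8) stencil."""
    idx = np.arange(side * side).reshape(side, side)
    offsets = [(0, 1), (1, 0)]
    if moore:
        offsets += [(1, 1), (1, -1)]
    edges = []
    for di, dj in offsets:
        shifted = np.roll(np.roll(idx, -di, axis=0), -dj, axis=1)
        edges.append(np.stack([idx.ravel(), shifted.ravel()], axis=1))
    return np.concatenate(edges)


def build_lattice(kind: str, n: int) -> Network:
    """Build a regular lattice: ``ring4``, ``square4`` or ``moore8``.

    ``ring4`` is a ring of nodes each connected to its 4 nearest loop
    neighbors (circulant graph with offsets {1, 2}).  ``square4`` and
    ``moore8`` are planar lattices with wrap-around (torus) boundaries, so
    every node has degree exactly 4 / 8; for these, ``n`` must be a perfect
    square (grid side sqrt(n)).
    """
    if kind not in LATTICE_KINDS:
        raise ValueError(f"unknown lattice kind {kind!r}; choose from {LATTICE_KINDS}")
    if n < 5:
        raise ValueError(f"lattice needs at least 5 nodes, got {n}")
    if kind == "ring4":
        g = nx.circulant_graph(n, [1, 2])
        return Network.from_networkx(g, name=f"ring4(N={n})")
    side = round(n**0.5)
    if side * side != n:
        raise ValueError(
            f"{kind} lattice requires a perfect-square node count, got N={n} "
            f"(nearest squares: {side**2}, {(side + 1) ** 2})"
        )
    if side < 3:
        raise ValueError(f"{kind} torus needs side >= 3, got side {side}")
    edges = _torus_edges(side, moore=(kind == "moore8"))
    # 3x3 Moore torus duplicates diagonal wrap pairs; Network dedups sorted
    # pairs, so normalize and unique here.
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return Network(n_nodes=n, edges=edges, name=f"{kind}(N={n})")


def build_random_network(
    model: str,
    n: int,
    mean_degree: int | None = None,
    seed: int | None = None,
    transitivity: float | None = None,
    max_retries: int = 100,
) -> Network:
    """Build a random (or reference) network of ``n`` nodes.

    ``single_scale`` is a Watts-Strogatz ring with rewiring probability 1
    (full rewiring: narrow, single-scale degree distribution);
    ``scale_free`` is Barabasi-Albert with ``m = mean_degree / 2``;
    ``holme_kim`` adds triad formation with probability ``transitivity``.
    ``complete`` and ``star`` ignore ``mean_degree``.  Disconnected draws
    are resampled with an incremented seed (logged).
    """
    if model not in RANDOM_MODELS:
        raise ValueError(f"unknown network model {model!r}; choose from {RANDOM_MODELS}")
    if model == "complete":
        return Network.from_networkx(nx.complete_graph(n), name=f"complete(N={n})")
    if model == "star":
        return Network.from_networkx(nx.star_graph(n - 1), name=f"star(N={n})")
    if mean_degree is None:
        raise ValueError(f"{model} requires mean_degree")
    if mean_degree % 2 != 0 or mean_degree <= 0:
        raise ValueError(f"{model} requires a positive even mean_degree, got {mean_degree}")
    if n <= mean_degree:
        raise ValueError(f"need n > mean_degree, got n={n}, mean_degree={mean_degree}")
    if model == "holme_kim" and transitivity is None:
        raise ValueError("holme_kim requires the triad-formation probability 'transitivity'")

    attempt_seed = seed
    for _ in range(max_retries):
        rng_seed = attempt_seed if attempt_seed is not None else None
        if model == "single_scale":
            g = nx.watts_strogatz_graph(n, mean_degree, p=1.0, seed=rng_seed)
        elif model == "scale_free":
            g = nx.barabasi_albert_graph(n, mean_degree // 2, seed=rng_seed)
        else:  # holme_kim
            g = nx.powerlaw_cluster_graph(n, mean_degree // 2, transitivity, seed=rng_seed)
        if nx.is_connected(g):
            return Network.from_networkx(g, name=f"{model}(N={n},<k>={mean_degree})")
        logger.info("%s draw with seed %s disconnected; retrying", model, attempt_seed)
        attempt_seed = 0 if attempt_seed is None else attempt_seed + 1
    raise RuntimeError(f"could not draw a connected {model} network in {max_retries} tries")


def assign_initial_strategies(
    network: Network,
    scheme: str,
    count_c: int,
    seed: int | None = None,
    node: int | None = None,
) -> StrategyAssignment:
    """Place ``count_c`` initial cooperators on the network.

    Schemes: ``random`` (uniform without replacement), ``degree_rank`` (the
    ``count_c`` highest-degree nodes, ties broken by ascending node index),
    ``connected_pairs`` (``count_c / 2`` disjoint edges whose endpoints
    become C), ``single`` (one node, given via ``node`` or drawn at
    random).  Also reports the fraction of initial C's with no C-neighbor.
    """
    n = network.n_nodes
    if not 0 <= count_c <= n:
        raise ValueError(f"count_c={count_c} outside [0, {n}]")
    rng = np.random.default_rng(seed)
    is_c = np.zeros(n, dtype=bool)

    if scheme == "random":
        is_c[rng.choice(n, size=count_c, replace=False)] = True
    elif scheme == "degree_rank":
        # stable sort on (-degree, index): ties go to the lower node index
        order = np.lexsort((np.arange(n), -network.degrees))
        is_c[order[:count_c]] = True
    elif scheme == "connected_pairs":
        if count_c % 2 != 0:
            raise ValueError("connected_pairs requires an even count_c")
        chosen: list[int] = []
        used = np.zeros(n, dtype=bool)
        for e in rng.permutation(network.n_edges):
            u, v = network.edges[e]
            if not used[u] and not used[v]:
                chosen.append(e)
                used[u] = used[v] = True
                if len(chosen) == count_c // 2:
                    break
        if len(chosen) < count_c // 2:
            raise ValueError("not enough disjoint edges for connected_pairs placement")
        is_c[network.edges[chosen].ravel()] = True
    elif scheme == "single":
        if count_c != 1:
            raise ValueError("scheme 'single' requires count_c = 1")
        is_c[node if node is not None else int(rng.integers(n))] = True
    else:
        raise ValueError(f"unknown placement scheme {scheme!r}")

    c_nodes = np.flatnonzero(is_c)
    if c_nodes.size:
        isolated = sum(1 for u in c_nodes if not is_c[network.neighbors(u)].any())
        isolated_fraction = isolated / c_nodes.size
    else:
        isolated_fraction = 0.0
    return StrategyAssignment(
        is_c=is_c, scheme=scheme, seed=seed, isolated_fraction=isolated_fraction
    )


def write_edge_list(network: Network, path: str | Path) -> None:
    """Write the edge list as one ``i j`` pair per line (0-based indices)."""
    with open(path, "w") as fh:
        fh.write(f"# N={network.n_nodes}\n")
        for u, v in network.edges:
            fh.write(f"{u} {v}\n")


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> Network:
    """Read a whitespace-separated 0-based edge list.

    A leading ``# N=<count>`` comment (as written by
    :func:`write_edge_list`) fixes the node count; otherwise it is taken as
    ``max index + 1`` or from ``n_nodes``.
    """
    edges = []
    header_n = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "N=" in line:
                    header_n = int(line.split("N=")[1])
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    if n_nodes is None:
        n_nodes = header_n if header_n is not None else int(edges.max()) + 1
    return Network(n_nodes=n_nodes, edges=edges, name=str(path))
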