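"""Binary graph construction and topology metrics.

A group correlation matrix is thresholded at a fixed *sparsity* S — the edge
count K divided by the maximum possible N(N-1)/2 — so every group network has
the same number of nodes and edges before topology is compared. On the
resulting undirected simple graph this module computes:

* the mean clustering coefficient Cp (local cliquishness),
* the characteristic path length Lp (mean over nodes of the average
  breadth-first distance to all other nodes, in edge-count units),
* small-world indices gamma = Cp / Cp_rand and lambda = Lp / Lp_rand against
  degree-matched rewired surrogates (gamma > 1 with lambda ~ 1 is the
  small-world signature),
* Freeman/Brandes betweenness centrality with fractional credit over tied
  shortest paths, its network-mean normalization b_i = B_i / <B>, and the
  hub rule b_i > 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .atlas import RegionAtlas
from .exceptions import ContractError, DisconnectedNetworkError
from .network import CorrelationMatrix

logger = logging.getLogger(__name__)

#: Default hub criterion: normalized betweenness above this value.
HUB_THRESHOLD = 2.0


@dataclass
class BinaryNetwork:
    """An undirected simple graph, usually on the atlas regions.

    ``atlas`` may be omitted for generic graphs (toy examples, surrogate
    studies); node labels then fall back to ``n1..nN``.
    """

    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    atlas: RegionAtlas | None = None
    group_label: str = ""
    n_swaps_accepted: int | None = None  # set on rewired surrogates

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractError(f"adjacency must be square, got shape {a.shape}")
        if self.atlas is not None and a.shape[0] != self.atlas.n_regions:
            raise ContractError(
                f"adjacency shape {a.shape} does not match atlas size {self.atlas.n_regions}"
            )
        if np.any(a != a.T):
            raise ContractError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ContractError("adjacency must have a zero diagonal")
        self.adjacency = a

    @property
    def labels(self) -> list[str]:
        if self.atlas is not None:
            return self.atlas.abbreviations
        return [f"n{i + 1}" for i in range(self.n_nodes)]

    @property
    def region_ids(self) -> list[int]:
        if self.atlas is not None:
            return [r.region_id for r in self.atlas]
        return list(range(1, self.n_nodes + 1))

    @property
    def names(self) -> list[str]:
        return self.atlas.names if self.atlas is not None else self.labels

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    # K in the field's notation
    K = n_edges

    @property
    def sparsity(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> list[tuple[int, int]]:
        """Edges as 0-based (i, j) pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def is_connected(self) -> bool:
        return component_sizes(self.adjacency) == (self.n_nodes,)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges())
        return g


def component_sizes(adjacency: np.ndarray) -> tuple[int, ...]:
    """Sizes of the connected components, largest first."""
    n_comp, labels = connected_components(csr_matrix(adjacency), directed=False)
    return tuple(sorted(np.bincount(labels).tolist(), reverse=True))


def _require_connected(net: BinaryNetwork, what: str) -> None:
    sizes = component_sizes(net.adjacency)
    if len(sizes) > 1:
        raise DisconnectedNetworkError(
            f"{what} requires a connected network; component sizes {sizes}",
            component_sizes=sizes,
        )


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def edge_count_for_sparsity(sparsity: float, n_possible: int) -> int:
    """K = round(S * n_possible), rounding halves up."""
    return int(np.floor(sparsity * n_possible + 0.5))


def top_k_adjacency(r: np.ndarray, k: int, rank: str = "absolute") -> np.ndarray:
    """Boolean adjacency of the ``k`` strongest off-diagonal pairs.

    Ranking is by |r| (``rank="absolute"``) or signed r (``rank="positive"``);
    ties at the cutoff are broken deterministically by (i, j) lexicographic
    order, which makes the edge set at a smaller k a subset of the edge set
    at any larger k.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    scores = np.abs(r[iu, ju]) if rank == "absolute" else r[iu, ju]
    # primary: score descending; then i, then j ascending
    order = np.lexsort((ju, iu, -scores))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    return adj | adj.T


def threshold_by_sparsity(corr: CorrelationMatrix, sparsity: float,
                          rank: str = "absolute") -> BinaryNetwork:
    """Binarize a correlation matrix at the given sparsity.

    The K = round(S * N(N-1)/2) pairs with the strongest correlations become
    the edges of an undirected simple graph.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ContractError(f"sparsity must be in (0, 1], got {sparsity}")
    if rank not in ("absolute", "positive"):
        raise ContractError(f"rank must be 'absolute' or 'positive', got {rank!r}")
    k = edge_count_for_sparsity(sparsity, corr.n_pairs)
    if k == 0:
        warnings.warn(f"sparsity {sparsity} rounds to zero edges; returning an empty network")
    adj = top_k_adjacency(corr.r, k, rank=rank)
    return BinaryNetwork(adjacency=adj, atlas=corr.atlas, group_label=corr.group_label)


# ---------------------------------------------------------------------------
# clustering and path length
# ---------------------------------------------------------------------------

def clustering_coefficients(net: BinaryNetwork) -> np.ndarray:
    """Per-node clustering C_i = 2 e_i / (k_i (k_i - 1)).

    ``e_i`` counts edges among node i's neighbors. Nodes of degree < 2 get
    C_i = 0 and are included in the Cp mean.
    """
    a = net.adjacency.astype(float)
    deg = a.sum(axis=1)
    closed_triples = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * e_i per node
    denom = deg * (deg - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, closed_triples / denom, 0.0)
    return c


def average_clustering(net: BinaryNetwork) -> float:
    """Cp: mean clustering coefficient over all nodes."""
    return float(np.mean(clustering_coefficients(net)))


def distance_matrix(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted (breadth-first) shortest-path distances."""
    _require_connected(net, "shortest-path computation")
    d = shortest_path(csr_matrix(net.adjacency), method="D", unweighted=True, directed=False)
    return d


def mean_path_length(net: BinaryNetwork) -> float:
    """Lp: mean over nodes of the average distance to every other node."""
    d = distance_matrix(net)
    n = net.n_nodes
    per_node = d.sum(axis=1) / (n - 1)
    return float(per_node.mean())


def _cp_lp(adjacency: np.ndarray) -> tuple[float, float]:
    """Fast internal Cp/Lp on a raw adjacency; raises if disconnected."""
    a = adjacency.astype(float)
    deg = a.sum(axis=1)
    closed = np.einsum("ij,jk,ki->i", a, a, a)
    denom = deg * (deg - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cp = float(np.where(denom > 0, closed / denom, 0.0).mean())
    d = shortest_path(csr_matrix(adjacency), method="D", unweighted=True, directed=False)
    if np.isinf(d).any():
        sizes = component_sizes(adjacency)
        raise DisconnectedNetworkError(
            f"network is disconnected; component sizes {sizes}", component_sizes=sizes
        )
    n = adjacency.shape[0]
    lp = float((d.sum() / (n - 1)) / n)
    return cp, lp


# ---------------------------------------------------------------------------
# betweenness and hubs
# ---------------------------------------------------------------------------

def nodal_metrics(net: BinaryNetwork) -> pd.DataFrame:
    """Per-node table: degree, clustering, betweenness, normalized betweenness, hub.

    Betweenness B_i sums, over all unordered pairs (s, t) of *other* nodes,
    the fraction of shortest s-t paths that pass through i; the normalized
    value b_i = B_i / <B> divides by the network mean, and nodes with
    b_i > 2 are flagged as hubs.
    """
    _require_connected(net, "betweenness centrality")
    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    b = np.array([bc[i] for i in range(net.n_nodes)], dtype=float)
    mean_b = b.mean()
    if mean_b > 0:
        b_norm = b / mean_b
    else:
        logger.warning("all betweenness values are zero; normalized betweenness set to 0")
        b_norm = np.zeros_like(b)
    df = pd.DataFrame(
        {
            "region_id": net.region_ids,
            "region": net.labels,
            "name": net.names,
            "degree": net.degrees(),
            "clustering": clustering_coefficients(net),
            "betweenness": b,
            "normalized_betweenness": b_norm,
        }
    )
    df["hub"] = df["normalized_betweenness"] > HUB_THRESHOLD
    return df


def detect_hubs(metrics: pd.DataFrame, threshold: float = HUB_THRESHOLD) -> list[int]:
    """Region ids whose normalized betweenness exceeds ``threshold``."""
    mask = metrics["normalized_betweenness"] > threshold
    return metrics.loc[mask, "region_id"].tolist()


# ---------------------------------------------------------------------------
# degree-preserving rewiring and small-world indices
# ---------------------------------------------------------------------------

def rewire_preserving_degrees(net: BinaryNetwork, n_swaps: int, seed=None,
                              max_tries: int | None = None) -> BinaryNetwork:
    """Randomize topology by double-edge swaps, preserving every degree.

    Repeatedly picks two edges (a,b), (c,d) and replaces them with (a,d),
    (c,b), rejecting proposals that would create self-loops or duplicate
    edges. Connectivity is preserved lazily: swaps are accepted in windows
    and a window is rolled back (and shrunk) whenever a connectivity check
    fails, as in the standard connected double-edge-swap algorithm. If the
    retry budget runs out before ``n_swaps`` swaps are accepted, the current
    network is returned with a warning; ``n_swaps_accepted`` records the
    count actually achieved.
    """
    _require_connected(net, "degree-preserving rewiring")
    if net.n_edges < 2:
        raise ContractError("rewiring requires at least 2 edges")
    if n_swaps < 0:
        raise ContractError("n_swaps must be >= 0")
    rng = np.random.default_rng(seed)
    adj = net.adjacency.copy()
    edges = net.edges()
    n_edges = len(edges)
    if max_tries is None:
        max_tries = 100 * max(n_swaps, 1) + 1000

    accepted = 0
    tries = 0
    window = 16
    undo: list[tuple[int, int, tuple[int, int], tuple[int, int]]] = []

    def _apply(e1: int, e2: int, new1: tuple[int, int], new2: tuple[int, int]) -> None:
        (a, b), (c, d) = edges[e1], edges[e2]
        adj[a, b] = adj[b, a] = False
        adj[c, d] = adj[d, c] = False
        adj[new1[0], new1[1]] = adj[new1[1], new1[0]] = True
        adj[new2[0], new2[1]] = adj[new2[1], new2[0]] = True
        edges[e1], edges[e2] = new1, new2

    def _rollback() -> None:
        for e1, e2, old1, old2 in reversed(undo):
            _apply(e1, e2, old1, old2)
        undo.clear()

    # draw candidate randomness in chunks to amortize generator overhead
    chunk = 4096
    buf_idx = rng.integers(0, n_edges, size=(chunk, 2))
    buf_flip = rng.random(chunk)
    pos = 0

    while accepted < n_swaps and tries < max_tries:
        if pos >= chunk:
            buf_idx = rng.integers(0, n_edges, size=(chunk, 2))
            buf_flip = rng.random(chunk)
            pos = 0
        e1, e2 = int(buf_idx[pos, 0]), int(buf_idx[pos, 1])
        flip = buf_flip[pos] < 0.5
        pos += 1
        tries += 1
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4 or adj[a, d] or adj[c, b]:
            continue
        old1, old2 = edges[e1], edges[e2]
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        _apply(e1, e2, new1, new2)
        undo.append((e1, e2, old1, old2))
        accepted += 1
        if len(undo) >= window or accepted >= n_swaps:
            if len(component_sizes(adj)) == 1:
                undo.clear()
                window = min(window * 2, 512)
            else:
                accepted -= len(undo)
                _rollback()
                window = max(window // 2, 1)

    if undo:  # final window not yet validated
        if len(component_sizes(adj)) != 1:
            accepted -= len(undo)
            _rollback()
        else:
            undo.clear()

    if accepted < n_swaps:
        warnings.warn(
            f"rewiring accepted only {accepted} of {n_swaps} requested swaps "
            "before exhausting the retry budget"
        )
    out = BinaryNetwork(adjacency=adj, atlas=net.atlas, group_label=net.group_label)
    out.n_swaps_accepted = accepted
    return out


@dataclass
class GlobalMetrics:
    """Whole-network small-world summary."""

    Cp: float
    Lp: float
    gamma: float  # Cp / Cp_rand
    lam: float  # Lp / Lp_rand
    Cp_rand: float
    Lp_rand: float
    n_random: int
    connected: bool = True

    def as_dict(self) -> dict:
        return {
            "Cp": self.Cp, "Lp": self.Lp, "gamma": self.gamma, "lambda": self.lam,
            "Cp_rand": self.Cp_rand, "Lp_rand": self.Lp_rand, "n_random": self.n_random,
        }


#: Accepted double-edge swaps per surrogate, as a multiple of the edge count.
SWAPS_PER_EDGE = 10


def small_world_indices(net: BinaryNetwork, n_random: int = 100, seed=None,
                        swaps_per_edge: int = SWAPS_PER_EDGE) -> GlobalMetrics:
    """Cp, Lp and their ratios to degree-matched rewired surrogates.

    Each of the ``n_random`` surrogates is produced by ``10 K`` accepted
    double-edge swaps of the real network (K = edge count), so it shares the
    exact degree sequence and stays connected. gamma = Cp / mean(Cp_rand),
    lambda = Lp / mean(Lp_rand). Deterministic for a fixed (seed, n_random).
    """
    if n_random < 1:
        raise ContractError("n_random must be >= 1")
    cp, lp = _cp_lp(net.adjacency)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_random)
    cps = np.empty(n_random)
    lps = np.empty(n_random)
    n_swaps = swaps_per_edge * net.n_edges
    for k, child in enumerate(children):
        surrogate = rewire_preserving_degrees(net, n_swaps=n_swaps, seed=child)
        cps[k], lps[k] = _cp_lp(surrogate.adjacency)
    cp_rand = float(cps.mean())
    lp_rand = float(lps.mean())
    return GlobalMetrics(
        Cp=cp, Lp=lp,
        gamma=cp / cp_rand if cp_rand > 0 else float("inf"),
        lam=lp / lp_rand,
        Cp_rand=cp_rand, Lp_rand=lp_rand, n_random=n_random,
    )
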