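"""Latent transition graphs and random-walk stimulus sequences.

The task exposes learners to a sequence of stimuli generated by a uniform
random walk on a 10-node, degree-4 graph.  Two topologies are used: a
*modular* graph (two five-node modules, each a near-clique, joined by two
boundary edges) and a *ring lattice* (each node connected to its nearest and
next-nearest neighbours around a ring).  Because both graphs are 4-regular,
all local transition statistics are identical and the graphs differ only in
higher-order structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GraphSpec",
    "build_modular_graph",
    "build_lattice_graph",
    "transition_matrix",
    "random_walk",
]

N_NODES = 10


@dataclass(frozen=True)
class GraphSpec:
    """A latent graph: symmetric binary adjacency plus optional module labels.

    Parameters
    ----------
    adjacency : (n, n) int array
        Symmetric, zero-diagonal, binary.
    kind : {"modular", "lattice"}
    module_labels : (n,) int array or None
        Two groups of five for the modular graph; None for the lattice.
    """

    adjacency: np.ndarray
    kind: str
    module_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", adj)
        if self.module_labels is not None:
            object.__setattr__(
                self, "module_labels", np.asarray(self.module_labels, dtype=int)
            )

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "n_nodes": int(self.n_nodes),
            "edges": [[int(a), int(b)] for a, b in self.edges()],
        }
        if self.module_labels is not None:
            payload["module_labels"] = self.module_labels.tolist()
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GraphSpec":
        payload = json.loads(text)
        n = payload["n_nodes"]
        adj = np.zeros((n, n), dtype=int)
        for a, b in payload["edges"]:
            adj[a, b] = adj[b, a] = 1
        labels = payload.get("module_labels")
        return cls(
            adjacency=adj,
            kind=payload["kind"],
            module_labels=None if labels is None else np.asarray(labels),
        )


def build_modular_graph() -> GraphSpec:
    """Two five-node modules ({0..4} and {5..9}), every node degree 4.

    Within each module all pairs are connected except the pair of boundary
    nodes ((0, 4) and (5, 9)); the modules are joined by the two cross edges
    (4, 5) and (9, 0).  This is the minimal-cross-edge topology compatible
    with two modules of five and 4-regularity.
    """
    adj = np.zeros((N_NODES, N_NODES), dtype=int)
    for offset in (0, 5):
        nodes = range(offset, offset + 5)
        for a in nodes:
            for b in nodes:
                if a < b:
                    adj[a, b] = adj[b, a] = 1
        # boundary nodes of each module are not connected to each other
        adj[offset, offset + 4] = adj[offset + 4, offset] = 0
    adj[4, 5] = adj[5, 4] = 1
    adj[9, 0] = adj[0, 9] = 1
    labels = np.array([0] * 5 + [1] * 5)
    return GraphSpec(adjacency=adj, kind="modular", module_labels=labels)


def build_lattice_graph() -> GraphSpec:
    """Ring lattice: node i connected to i±1 and i±2 (mod 10)."""
    adj = np.zeros((N_NODES, N_NODES), dtype=int)
    for i in range(N_NODES):
        for off in (1, 2):
            j = (i + off) % N_NODES
            adj[i, j] = adj[j, i] = 1
    return GraphSpec(adjacency=adj, kind="lattice")


def transition_matrix(g: GraphSpec) -> np.ndarray:
    """Row-stochastic uniform random-walk transition matrix of a graph.

    Row i is adjacency row i divided by the degree of node i; for the
    degree-4 graphs used here every nonzero entry equals 1/4.
    """
    deg = g.degrees()
    if np.any(deg == 0):
        raise ValueError("graph has an isolated node; cannot normalise")
    return g.adjacency / deg[:, None]


def random_walk(A: np.ndarray, n_steps: int, seed: int | np.random.Generator) -> np.ndarray:
    """Sample a random-walk node sequence from a transition matrix.

    The first node is uniform over all nodes; each subsequent node is drawn
    from the row of ``A`` indexed by the current node.

    Parameters
    ----------
    A : (n, n) row-stochastic array
    n_steps : total sequence length (>= 1)
    seed : int seed or an existing Generator

    Returns
    -------
    (n_steps,) int array of 0-based node indices.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cum = np.cumsum(A, axis=1)
    if not np.allclose(cum[:, -1], 1.0):
        raise ValueError("rows of A must sum to 1")
    u = rng.random(n_steps)
    x = np.empty(n_steps, dtype=int)
    x[0] = rng.integers(n)
    for t in range(1, n_steps):
        x[t] = min(np.searchsorted(cum[x[t - 1]], u[t], side="right"), n - 1)
    return x
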