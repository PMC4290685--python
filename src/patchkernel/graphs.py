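"""Labeled residue-contact graphs and their shortest-path transform.

A patch becomes an undirected labeled graph: one node per residue carrying
its normalized attribute vector, one edge per contacting residue pair (closest
heavy-atom distance below the sum of van der Waals radii plus 0.5 Å).  The
graph is induced on the patch — contacts to residues outside the patch are
ignored.

The shortest-path transform (Floyd–Warshall over unit edge weights) produces a
graph on the same nodes with one edge per connected node pair, weighted by the
hop-count distance in the contact graph.  Node pairs in different components
get no edge, which keeps the downstream Brownian-bridge edge kernel finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .errors import StateError
from .features import Protein, ResidueRecord, ResKey, key_to_str
from .geometry import DEFAULT_CONTACT_PAD, residue_pair_gap
from .patches import Patch


@dataclass(frozen=True)
class LabeledGraph:
    """Undirected graph with attribute-vector node labels and unweighted edges.

    Nodes are kept sorted by residue key, so construction is invariant to the
    order residues are supplied in.  ``edges`` holds index pairs (i, j), i < j.
    """

    keys: tuple[ResKey, ...]
    labels: np.ndarray  # (n_nodes, n_features)
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.keys)
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if not (0 <= i < j < n):
                raise ValueError(f"edge ({i}, {j}) references missing nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.keys)


@dataclass(frozen=True)
class ShortestPathGraph:
    """Same nodes as the contact graph; one edge per connected pair, weighted
    by hop count (integer ≥ 1)."""

    keys: tuple[ResKey, ...]
    labels: np.ndarray  # (n_nodes, n_features)
    edges: np.ndarray  # (n_edges, 2) int, i < j
    weights: np.ndarray  # (n_edges,) int ≥ 1

    @property
    def n_nodes(self) -> int:
        return len(self.keys)

    @property
    def n_edges(self) -> int:
        return len(self.weights)


def residues_in_contact(r1: ResidueRecord, r2: ResidueRecord, *,
                        pad: float = DEFAULT_CONTACT_PAD) -> bool:
    """True iff some heavy-atom pair is closer than r_a + r_b + pad (strict)."""
    return residue_pair_gap(r1, r2) < pad


def build_patch_graph(patch: Patch, protein: Protein, *,
                      features: Sequence[int] | None = None,
                      pad: float = DEFAULT_CONTACT_PAD) -> LabeledGraph:
    """Induced contact graph on the patch residues, labeled with normalized
    attributes (optionally restricted to the attribute indices ``features``)."""
    keys = tuple(sorted(patch.residue_keys))
    residues = [protein.residue(k) for k in keys]
    for res in residues:
        if res.attributes is None:
            raise StateError(f"residue {res.key} has no attributes")
    cols = (np.asarray(features, dtype=int) if features is not None
            else np.arange(residues[0].attributes.shape[0]))
    labels = []
    for res in residues:
        vec = res.attributes[cols]
        if np.any(vec < 0) or np.any(vec > 1):
            raise StateError(
                f"residue {res.key}: attributes outside [0, 1]; "
                "apply a fitted normalizer first"
            )
        labels.append(vec)
    edges = frozenset(
        (i, j)
        for i in range(len(residues))
        for j in range(i + 1, len(residues))
        if residue_pair_gap(residues[i], residues[j]) < pad
    )
    return LabeledGraph(keys=keys, labels=np.array(labels, dtype=float),
                        edges=edges)


def shortest_path_transform(g: LabeledGraph) -> ShortestPathGraph:
    """All-pairs shortest hop counts via Floyd–Warshall; disconnected pairs
    produce no edge."""
    n = g.n_nodes
    adj = np.zeros((n, n))
    for i, j in g.edges:
        adj[i, j] = adj[j, i] = 1
    if n:
        dist = floyd_warshall(adj, directed=False, unweighted=True)
    else:
        dist = np.zeros((0, 0))
    iu, ju = np.triu_indices(n, k=1)
    finite = np.isfinite(dist[iu, ju])
    edges = np.stack([iu[finite], ju[finite]], axis=1).astype(int)
    weights = dist[iu, ju][finite].astype(int)
    return ShortestPathGraph(keys=g.keys, labels=g.labels, edges=edges,
                             weights=weights)


# ---------------------------------------------------------------------------
# Serialization (debug dump + CLI interchange)


def dump_edge_list(g: ShortestPathGraph) -> str:
    """Plain-text edge list: node key, node key, weight (tab separated)."""
    lines = [
        f"{key_to_str(g.keys[i])}\t{key_to_str(g.keys[j])}\t{w}"
        for (i, j), w in zip(g.edges.tolist(), g.weights.tolist())
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def graph_to_json(g: ShortestPathGraph, path: str | Path | None = None) -> str:
    """JSON form of a shortest-path graph (keys, labels, weighted edges)."""
    obj = {
        "keys": [list(k) for k in g.keys],
        "labels": g.labels.tolist(),
        "edges": g.edges.tolist(),
        "weights": g.weights.tolist(),
    }
    text = json.dumps(obj, separators=(",", ":"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def graph_from_json(source: str | Path) -> ShortestPathGraph:
    """Inverse of :func:`graph_to_json`; ``source`` is a path or a JSON string."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    obj = json.loads(text)
    keys = tuple((c, int(r), ic) for c, r, ic in obj["keys"])
    labels = np.asarray(obj["labels"], dtype=float)
    edges = np.asarray(obj["edges"], dtype=int).reshape(-1, 2)
    weights = np.asarray(obj["weights"], dtype=int)
    return ShortestPathGraph(keys=keys, labels=labels, edges=edges, weights=weights)
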