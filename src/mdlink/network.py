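"""Heterogeneous molecular association network (MAN).

The MAN is an undirected binary graph over five molecule types — miRNA,
lncRNA, protein, disease and drug — connected by nine association types
(miRNA-disease, miRNA-protein, miRNA-lncRNA, lncRNA-disease, lncRNA-protein,
protein-protein, protein-disease, drug-protein, drug-disease).  Its adjacency
matrix is the input to the structural deep network embedding, and its
miRNA-disease edges are the positive labels of the link-prediction task.

Node identity is the pair ``(node_type, node_id)`` so identifiers may be
reused across molecule types without collision.  Node order is always sorted
by that pair, which makes adjacency layout — and hence every downstream
embedding — reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_TYPES = ("disease", "drug", "lncRNA", "miRNA", "protein")

#: The nine association types and their (source, target) endpoint node types.
ASSOC_TYPES: dict[str, tuple[str, str]] = {
    "miRNA-disease": ("miRNA", "disease"),
    "miRNA-protein": ("miRNA", "protein"),
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "lncRNA-disease": ("lncRNA", "disease"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "protein-protein": ("protein", "protein"),
    "protein-disease": ("protein", "disease"),
    "drug-protein": ("drug", "protein"),
    "drug-disease": ("drug", "disease"),
}


class NodeRef(NamedTuple):
    """A typed node reference; ``(node_type, node_id)`` is the identity key."""

    node_type: str
    node_id: str


class EdgeRecord(NamedTuple):
    source: NodeRef
    target: NodeRef
    assoc_type: str


class NetworkError(ValueError):
    """Raised for malformed edge input or inconsistent network queries."""


def _check_node(node: NodeRef) -> None:
    if node.node_type not in NODE_TYPES:
        raise NetworkError(f"unknown node type {node.node_type!r}")
    if not node.node_id:
        raise NetworkError("empty node_id")


def _canonical_edge(a: NodeRef, b: NodeRef, assoc_type: str) -> EdgeRecord:
    """Orient an undirected edge deterministically (sorted endpoint key)."""
    if a == b:
        raise NetworkError(f"self-loop on {a}")
    if a > b:
        a, b = b, a
    return EdgeRecord(a, b, assoc_type)


def load_edge_list(path: str | Path, assoc_type: str) -> list[EdgeRecord]:
    """Read a two-column TSV of ids into undirected, deduplicated edges.

    Lines starting with ``#`` are treated as comments/headers.  The first
    column holds ids of the association's source type, the second the target
    type (for same-type associations such as protein-protein both columns are
    that type).  Both orientations of a pair collapse to one edge.
    """
    if assoc_type not in ASSOC_TYPES:
        raise NetworkError(f"unknown association type {assoc_type!r}")
    type_a, type_b = ASSOC_TYPES[assoc_type]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    edges: set[EdgeRecord] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise NetworkError(
                    f"{path}:{lineno}: expected >=2 tab-separated fields, "
                    f"got {line!r}"
                )
            src = NodeRef(type_a, fields[0].strip())
            tgt = NodeRef(type_b, fields[1].strip())
            _check_node(src)
            _check_node(tgt)
            edges.add(_canonical_edge(src, tgt, assoc_type))
    return sorted(edges)


@dataclass(frozen=True)
class HeteroNetwork:
    """Typed node list plus symmetric binary adjacency.

    ``adjacency[i, j] = 1`` iff nodes ``i`` and ``j`` are associated; the
    diagonal is zero and the matrix equals its transpose.  Row ``i`` is the
    neighbourhood indicator vector fed to the network embedding.
    """

    nodes: tuple[NodeRef, ...]
    adjacency: np.ndarray
    _index: dict[NodeRef, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        if not self._index:
            object.__setattr__(
                self, "_index", {n: i for i, n in enumerate(self.nodes)}
            )
        self.validate()

    def validate(self) -> None:
        s = self.adjacency
        n = len(self.nodes)
        if s.shape != (n, n):
            raise NetworkError("adjacency shape does not match node count")
        if not np.array_equal(s, s.T):
            raise NetworkError("adjacency is not symmetric")
        if np.any(np.diag(s) != 0):
            raise NetworkError("adjacency has nonzero diagonal")
        if not np.isin(s, (0, 1)).all():
            raise NetworkError("adjacency entries must be binary")

    # -- queries ----------------------------------------------------------

    def index_of(self, node: NodeRef) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise NetworkError(f"node {node} not in network") from None

    def __contains__(self, node: NodeRef) -> bool:
        return node in self._index

    def nodes_of_type(self, node_type: str) -> list[NodeRef]:
        return [n for n in self.nodes if n.node_type == node_type]

    def degree(self, node: NodeRef) -> int:
        return int(self.adjacency[self.index_of(node)].sum())

    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    # -- persistence ------------------------------------------------------

    def to_files(self, node_path: str | Path, edge_path: str | Path) -> None:
        """Write a node-list TSV and a sparse edge TSV."""
        pd.DataFrame(self.nodes, columns=["node_type", "node_id"]).to_csv(
            node_path, sep="\t", index=False
        )
        ii, jj = np.nonzero(np.triu(self.adjacency))
        rows = [
            (self.nodes[i].node_type, self.nodes[i].node_id,
             self.nodes[j].node_type, self.nodes[j].node_id)
            for i, j in zip(ii, jj)
        ]
        pd.DataFrame(
            rows, columns=["source_type", "source_id", "target_type", "target_id"]
        ).to_csv(edge_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, node_path: str | Path, edge_path: str | Path) -> "HeteroNetwork":
        nodes_df = pd.read_csv(node_path, sep="\t", dtype=str)
        nodes = tuple(
            sorted(NodeRef(t, i) for t, i in zip(nodes_df.node_type, nodes_df.node_id))
        )
        idx = {n: k for k, n in enumerate(nodes)}
        s = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
        edges_df = pd.read_csv(edge_path, sep="\t", dtype=str)
        for st, si, tt, ti in zip(
            edges_df.source_type, edges_df.source_id,
            edges_df.target_type, edges_df.target_id,
        ):
            i, j = idx[NodeRef(st, si)], idx[NodeRef(tt, ti)]
            s[i, j] = s[j, i] = 1
        return cls(nodes=nodes, adjacency=s)


def assemble_network(edges: Sequence[EdgeRecord]) -> HeteroNetwork:
    """Build a :class:`HeteroNetwork` from edge records.

    The node set is the union of edge endpoints, sorted by
    ``(node_type, node_id)``; each undirected edge sets both ``s[i, j]`` and
    ``s[j, i]``, so the total degree equals twice the unique-edge count.
    """
    if not edges:
        raise NetworkError("cannot assemble a network from an empty edge list")
    nodes = tuple(sorted({n for e in edges for n in (e.source, e.target)}))
    idx = {n: i for i, n in enumerate(nodes)}
    s = np.zeros((len(nodes), len(nodes)), dtype=np.uint8)
    for e in edges:
        i, j = idx[e.source], idx[e.target]
        s[i, j] = s[j, i] = 1
    return HeteroNetwork(nodes=nodes, adjacency=s)


def remove_md_edges(
    net: HeteroNetwork, held_out: Iterable[tuple[str, str]]
) -> HeteroNetwork:
    """Return a copy of ``net`` with the given miRNA-disease edges zeroed.

    ``held_out`` is an iterable of ``(mirna_id, disease_id)`` pairs (plain id
    strings).  This is the leakage control of cross validation: test-fold
    associations are masked before embeddings are computed so that evaluation
    never sees test labels through the graph.  Pairs that are not edges are
    tolerated and logged; nodes losing all edges are kept with zero rows so
    indices stay stable across folds.
    """
    s = net.adjacency.copy()
    for mi_id, di_id in held_out:
        mi = NodeRef("miRNA", mi_id)
        di = NodeRef("disease", di_id)
        if mi not in net or di not in net:
            logger.warning("held-out pair (%s, %s) has unknown node", mi_id, di_id)
            continue
        i, j = net.index_of(mi), net.index_of(di)
        if s[i, j] == 0:
            logger.warning("held-out pair (%s, %s) is not an edge", mi_id, di_id)
        s[i, j] = s[j, i] = 0
    return HeteroNetwork(nodes=net.nodes, adjacency=s)


def adjacency_row(net: HeteroNetwork, node: NodeRef) -> np.ndarray:
    """Binary neighbourhood indicator of ``node`` (embedding input x_i)."""
    return net.adjacency[net.index_of(node)].astype(np.float64)


@dataclass(frozen=True)
class LabeledPairSet:
    """miRNA-disease pairs with binary association labels."""

    pairs: tuple[tuple[str, str, int], ...]

    def __post_init__(self):
        keys = [(m, d) for m, d, _ in self.pairs]
        if len(keys) != len(set(keys)):
            raise NetworkError("duplicate (miRNA, disease) pair in labeled set")
        if any(lab not in (0, 1) for _, _, lab in self.pairs):
            raise NetworkError("labels must be 0 or 1")

    def positives(self) -> list[tuple[str, str]]:
        return [(m, d) for m, d, lab in self.pairs if lab == 1]

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_file(cls, path: str | Path) -> "LabeledPairSet":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["mirna_id", "disease_id", "label"],
            dtype={"mirna_id": str, "disease_id": str, "label": int},
        )
        return cls(tuple(df.itertuples(index=False, name=None)))

    def to_file(self, path: str | Path) -> None:
        pd.DataFrame(list(self.pairs)).to_csv(
            path, sep="\t", index=False, header=False
        )
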