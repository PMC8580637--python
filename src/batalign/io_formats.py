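"""Plain tab-separated I/O for networks, similarity scores, GO annotations and alignments.

Every on-disk format is TSV with ``#`` comment lines and blank lines ignored,
and node labels treated as case-sensitive byte strings:

* edge list — two columns, one undirected interaction per line;
* similarity — three columns ``label1  label2  score`` (non-negative, e.g.
  BLAST bit-scores);
* annotations — two columns ``label  GO-term-id``, a deliberately minimal
  GAF-like subset;
* alignment — two columns ``source-label  target-label``.

Node order is first appearance in the edge-list file; that order fixes the
row/column indexing of every matrix built on top of a :class:`Network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("batalign")

__all__ = [
    "Network",
    "GOAnnotation",
    "ParseError",
    "read_edgelist",
    "write_edgelist",
    "read_similarity",
    "write_similarity",
    "read_annotations",
    "write_annotations",
    "read_alignment",
    "write_alignment",
    "average_degree",
    "mean_degree",
]


class ParseError(ValueError):
    """A malformed line in one of the TSV formats."""


class Network:
    """Simple undirected graph with a stable label ↔ integer-index bijection.

    Parameters
    ----------
    labels : sequence of str
        Unique node labels; their order defines the integer indexing.
    edges : iterable of (int, int)
        Undirected edges as index pairs. Duplicates are collapsed;
        self-loops are rejected (drop them before construction).

    Attributes
    ----------
    n, m : int
        Node and edge counts.
    edge_array : ndarray of shape (m, 2)
        Each row ``(u, v)`` with ``u < v``, rows sorted — a canonical,
        deterministic edge listing.
    """

    __slots__ = ("labels", "index", "edge_array", "n", "m",
                 "_adj", "_packed", "_neighbors", "_degrees")

    def __init__(self, labels, edges):
        self.labels = [str(x) for x in labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate node labels")
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.n = len(self.labels)
        pairs = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on index {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge endpoint out of range: ({u}, {v})")
            pairs.add((u, v) if u < v else (v, u))
        if pairs:
            self.edge_array = np.array(sorted(pairs), dtype=np.int64)
        else:
            self.edge_array = np.empty((0, 2), dtype=np.int64)
        self.m = len(pairs)
        self._adj = None
        self._packed = None
        self._neighbors = None
        self._degrees = None

    # -- derived views, cached lazily ------------------------------------

    @property
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix (float64, n×n)."""
        if self._adj is None:
            a = np.zeros((self.n, self.n))
            if self.m:
                u, v = self.edge_array[:, 0], self.edge_array[:, 1]
                a[u, v] = 1.0
                a[v, u] = 1.0
            self._adj = a
        return self._adj

    @property
    def packed_edges(self) -> np.ndarray:
        """Sorted int64 keys ``u * n + v`` (u < v); supports fast membership."""
        if self._packed is None:
            keys = self.edge_array[:, 0] * self.n + self.edge_array[:, 1]
            self._packed = np.sort(keys)
        return self._packed

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            d = np.zeros(self.n, dtype=np.int64)
            if self.m:
                np.add.at(d, self.edge_array[:, 0], 1)
                np.add.at(d, self.edge_array[:, 1], 1)
            self._degrees = d
        return self._degrees

    def neighbors(self, i: int) -> list[int]:
        if self._neighbors is None:
            nb: list[list[int]] = [[] for _ in range(self.n)]
            for u, v in self.edge_array:
                nb[u].append(int(v))
                nb[v].append(int(u))
            self._neighbors = nb
        return self._neighbors[i]

    def has_edge(self, u: int, v: int) -> bool:
        if u == v:
            return False
        lo, hi = (u, v) if u < v else (v, u)
        key = lo * self.n + hi
        pos = np.searchsorted(self.packed_edges, key)
        return pos < self.m and self.packed_edges[pos] == key

    def edge_label_pairs(self):
        """Edges as (label, label) tuples, in canonical order."""
        return [(self.labels[u], self.labels[v]) for u, v in self.edge_array]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edge_label_pairs())
        return g

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Network(n={self.n}, m={self.m})"


@dataclass
class GOAnnotation:
    """Map from node label to its set of GO term identifiers.

    Lookup of an unannotated label returns the empty set.
    """

    terms: dict[str, set[str]] = field(default_factory=dict)

    def __getitem__(self, label: str) -> set[str]:
        return self.terms.get(label, set())

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path):
    """Yield (lineno, stripped line) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edgelist(path) -> Network:
    """Read an undirected network from a two-column TSV edge list.

    Duplicate edges are collapsed and self-loops silently dropped (counts
    logged). Node order is first appearance, which fixes all downstream
    matrix indexings. An edge list with no data lines is an error.
    """
    labels: list[str] = []
    index: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_loops = 0
    n_dups = 0
    n_lines = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated "
                             f"fields, got {len(fields)}")
        n_lines += 1
        a, b = fields[0], fields[1]
        for lab in (a, b):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
        u, v = index[a], index[b]
        if u == v:
            n_loops += 1
            continue
        key = (u, v) if u < v else (v, u)
        if key in pairs:
            n_dups += 1
        pairs.add(key)
    if n_lines == 0:
        raise ParseError(f"{path}: no edges found")
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dups)
    return Network(labels, pairs)


def write_edgelist(net: Network, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in net.edge_label_pairs():
            fh.write(f"{a}\t{b}\n")


def read_similarity(path, net1: Network, net2: Network) -> np.ndarray:
    """Read cross-network similarity scores into a dense (n₁ × n₂) matrix.

    Rows follow ``net1`` indexing, columns ``net2``. Absent pairs are 0;
    pairs naming labels outside either network are skipped (count logged);
    duplicate pairs keep the maximum score. Negative or non-numeric scores
    are errors.
    """
    B = np.zeros((net1.n, net2.n))
    n_skipped = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated "
                             f"fields, got {len(fields)}")
        a, b, raw = fields[0], fields[1], fields[2]
        try:
            score = float(raw)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score {raw!r}")
        if not np.isfinite(score) or score < 0:
            raise ParseError(f"{path}:{lineno}: score must be a finite "
                             f"non-negative number, got {raw!r}")
        i = net1.index.get(a)
        j = net2.index.get(b)
        if i is None or j is None:
            n_skipped += 1
            continue
        if score > B[i, j]:
            B[i, j] = score
    if n_skipped:
        logger.info("%s: skipped %d line(s) with unknown labels",
                    path, n_skipped)
    return B


def write_similarity(B: np.ndarray, net1: Network, net2: Network,
                     path) -> None:
    """Write the nonzero entries of a similarity matrix as 3-column TSV."""
    rows, cols = np.nonzero(B)
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{net1.labels[i]}\t{net2.labels[j]}\t{B[i, j]:.17g}\n")


def read_annotations(path) -> GOAnnotation:
    """Read two-column ``label  GO-term`` lines into per-label term sets."""
    terms: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated "
                             f"fields, got {len(fields)}")
        terms.setdefault(fields[0], set()).add(fields[1])
    return GOAnnotation(terms)


def write_annotations(annot: GOAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label in annot.terms:
            for term in sorted(annot.terms[label]):
                fh.write(f"{label}\t{term}\n")


def read_alignment(path, net1: Network, net2: Network) -> np.ndarray:
    """Read a two-column alignment file into a target-index vector.

    Returns ``target_of`` of length ``net1.n`` where entry *i* is the
    ``net2`` index aligned to source index *i*. Both columns must be
    injective and every source node must be covered.
    """
    target_of = np.full(net1.n, -1, dtype=np.int64)
    seen_targets: set[int] = set()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated "
                             f"fields, got {len(fields)}")
        a, b = fields[0], fields[1]
        i = net1.index.get(a)
        j = net2.index.get(b)
        if i is None:
            raise ParseError(f"{path}:{lineno}: unknown source label {a!r}")
        if j is None:
            raise ParseError(f"{path}:{lineno}: unknown target label {b!r}")
        if target_of[i] != -1:
            raise ParseError(f"{path}:{lineno}: source {a!r} aligned twice")
        if j in seen_targets:
            raise ParseError(f"{path}:{lineno}: target {b!r} aligned twice")
        target_of[i] = j
        seen_targets.add(j)
    if (target_of == -1).any():
        missing = net1.labels[int(np.argmax(target_of == -1))]
        raise ParseError(f"{path}: source node {missing!r} not aligned")
    return target_of


def write_alignment(target_of: np.ndarray, net1: Network, net2: Network,
                    path) -> None:
    """Write one ``source<TAB>target`` line per source node, in index order."""
    if len(target_of) != net1.n:
        raise ValueError("alignment length does not match net1")
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in enumerate(target_of):
            fh.write(f"{net1.labels[i]}\t{net2.labels[int(j)]}\n")


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

def mean_degree(n_nodes: int, n_edges: int) -> float:
    """Average degree 2m/n of an undirected graph given its node/edge counts."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return 2.0 * n_edges / n_nodes


def average_degree(net: Network) -> float:
    """Average degree 2m/n of a network."""
    return mean_degree(net.n, net.m)
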