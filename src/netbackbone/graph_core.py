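"""Graph containers, file I/O, type detection, and model suggestion.

Two in-memory containers are used throughout the package:

* :class:`WeightedGraph` — an undirected, node-labelled weighted graph,
  stored as a dense symmetric adjacency matrix with a zero diagonal.
  Unweighted unipartite networks are the special case of 0/1 weights.
* :class:`BipartiteGraph` — an agents × artifacts binary incidence
  matrix.  The weighted one-mode projection P = B·Bᵀ counts artifacts
  shared by each pair of agents.

Supported interchange formats: edgelist CSV/TSV, dense labelled CSV,
Matrix Market coordinate, and GraphML.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class GraphValidationError(ValueError):
    """Raised when a graph violates a structural invariant."""


class GraphParseError(ValueError):
    """Raised when an input file cannot be parsed; carries a line number
    when one is known."""


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        raise GraphValidationError(f"duplicate {what} labels")
    return labels


@dataclass
class WeightedGraph:
    """Undirected weighted graph with ordered string node labels.

    Parameters
    ----------
    nodes
        Node labels in input order; all package outputs refer to nodes by
        label, never by index.
    matrix
        Symmetric nonnegative adjacency matrix with a zero diagonal.
        Entry ``matrix[i, j]`` is the weight of the edge between
        ``nodes[i]`` and ``nodes[j]``; zero means no edge.
    """

    nodes: list[str]
    matrix: np.ndarray
    directed: bool = False

    def __post_init__(self) -> None:
        self.nodes = _check_labels(self.nodes, "node")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise GraphValidationError("adjacency matrix must be square")
        if m.shape[0] != len(self.nodes):
            raise GraphValidationError("node labels do not match matrix size")
        if not np.all(np.isfinite(m)):
            raise GraphValidationError("weights must be finite (no NaN/Inf)")
        if np.any(m < 0):
            raise GraphValidationError("negative edge weights are not allowed")
        if not self.directed and not np.allclose(m, m.T):
            raise GraphValidationError("undirected graph requires a symmetric matrix")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """Number of undirected positive-weight edges."""
        return int(np.count_nonzero(np.triu(self.matrix, 1)))

    def degrees(self) -> np.ndarray:
        """Unweighted degree k_i = #{j : w_ij > 0}."""
        return (self.matrix > 0).sum(axis=1)

    def strengths(self) -> np.ndarray:
        """Node strength s_i = Σ_j w_ij."""
        return self.matrix.sum(axis=1)

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once, endpoint labels in sorted order."""
        iu, ju = np.nonzero(np.triu(self.matrix, 1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            u, v = sorted((self.nodes[i], self.nodes[j]))
            yield u, v, float(self.matrix[i, j])

    def is_binary(self) -> bool:
        vals = np.unique(self.matrix)
        return bool(np.isin(vals, (0.0, 1.0)).all())

    # -- conversions -----------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges():
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedGraph":
        nodes = [str(v) for v in g.nodes()]
        idx = {v: i for i, v in enumerate(nodes)}
        m = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            i, j = idx[str(u)], idx[str(v)]
            m[i, j] = m[j, i] = w
        return cls(nodes, m)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, nodes: Sequence[str] | None = None) -> "WeightedGraph":
        matrix = np.asarray(matrix, dtype=float)
        if nodes is None:
            nodes = [f"n{i + 1}" for i in range(matrix.shape[0])]
        return cls(list(nodes), matrix)


@dataclass
class BipartiteGraph:
    """Binary agents × artifacts incidence structure.

    ``incidence[i, k] == 1`` means agent i (row) is linked to artifact k
    (column): an author on a paper, a legislator on a bill, a species at
    a site.  Row sums d_i are agent degrees; column sums f_k are
    artifact degrees.
    """

    agents: list[str]
    artifacts: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.agents = _check_labels(self.agents, "agent")
        self.artifacts = _check_labels(self.artifacts, "artifact")
        b = np.asarray(self.incidence)
        if b.ndim != 2:
            raise GraphValidationError("incidence must be a 2-D matrix")
        if b.shape != (len(self.agents), len(self.artifacts)):
            raise GraphValidationError("labels do not match incidence shape")
        if not np.isin(b, (0, 1)).all():
            raise GraphValidationError("incidence entries must be 0 or 1")
        self.incidence = b.astype(np.int8)

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    @property
    def n_artifacts(self) -> int:
        return len(self.artifacts)

    def agent_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(int)

    def artifact_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0).astype(int)


Graph = Union[WeightedGraph, BipartiteGraph]


@dataclass
class SuggestReport:
    """Outcome of input-type detection and model suggestion."""

    detected_type: str  # bipartite | weighted_unipartite | unweighted_unipartite
    suggested_model: str
    projection_warning: bool = False


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(B: BipartiteGraph) -> WeightedGraph:
    """One-mode (agent × agent) projection P = B·Bᵀ with zero diagonal.

    P_ij counts the artifacts shared by agents i and j.
    """
    P = (B.incidence.astype(np.int64) @ B.incidence.T.astype(np.int64)).astype(float)
    np.fill_diagonal(P, 0.0)
    return WeightedGraph(list(B.agents), P)


# ---------------------------------------------------------------------------
# model suggestion
# ---------------------------------------------------------------------------

def _coerce_matrix(G) -> np.ndarray:
    if isinstance(G, WeightedGraph):
        return G.matrix
    if isinstance(G, BipartiteGraph):
        return G.incidence.astype(float)
    m = np.asarray(G, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise GraphValidationError("input must be a non-empty 2-D matrix")
    return m


def suggest_model(G) -> SuggestReport:
    """Detect the network type of an input and suggest a backbone model.

    Heuristic: a binary matrix that is rectangular, or square but not
    symmetric, is read as a bipartite incidence (suggest SDSM); any
    non-binary matrix is read as a weighted unipartite network (suggest
    the disparity filter); a binary symmetric square matrix is an
    unweighted unipartite network (suggest L-Spar sparsification).

    A warning flag is raised when a weighted matrix looks like it could
    be a bipartite projection: square, symmetric, all entries
    nonnegative integers, with at least one off-diagonal count above 1.
    """
    if isinstance(G, BipartiteGraph):
        m = G.incidence.astype(float)
    else:
        m = _coerce_matrix(G)
    if m.size == 0:
        raise GraphValidationError("empty matrix")

    square = m.shape[0] == m.shape[1]
    binary = np.isin(m, (0.0, 1.0)).all()
    symmetric = square and np.allclose(m, m.T)

    off = m[~np.eye(m.shape[0], m.shape[1], dtype=bool)] if square else None
    integral = np.all(m >= 0) and np.allclose(m, np.round(m))
    warning = bool(square and symmetric and integral and np.any(off > 1))

    if binary and (not square or not symmetric):
        return SuggestReport("bipartite", "sdsm", False)
    if not binary:
        return SuggestReport("weighted_unipartite", "disparity", warning)
    return SuggestReport("unweighted_unipartite", "sparsify.lspar", False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("edgelist", "dense", "mtx", "graphml")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    return {
        ".csv": "edgelist",
        ".tsv": "edgelist",
        ".mtx": "mtx",
        ".graphml": "graphml",
    }.get(ext, "edgelist")


def _fmt_weight(w: float) -> str:
    if float(w).is_integer():
        return str(int(w))
    return repr(float(w))


def read_graph(path: str, format: str | None = None) -> Graph:
    """Read a graph from ``path``.

    ``format`` is one of ``edgelist`` (CSV/TSV with header
    ``source,target[,weight]``), ``dense`` (labelled dense CSV), ``mtx``
    (Matrix Market coordinate), or ``graphml``; inferred from the file
    extension when omitted.  A dense or Matrix Market input that is
    binary and rectangular (or square with distinct row/column labels)
    is returned as a :class:`BipartiteGraph`.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GraphParseError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt == "dense":
        return _read_dense(path)
    if fmt == "mtx":
        return _read_mtx(path)
    return _read_graphml(path)


def write_graph(G: Graph, path: str, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise GraphParseError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist":
        _write_edgelist(G, path)
    elif fmt == "dense":
        _write_dense(G, path)
    elif fmt == "mtx":
        _write_mtx(G, path)
    else:
        _write_graphml(G, path)


def _sep_for(path: str) -> str:
    return "\t" if path.lower().endswith(".tsv") else ","


def _read_edgelist(path: str) -> WeightedGraph:
    sep = _sep_for(path)
    nodes: list[str] = []
    index: dict[str, int] = {}
    rows: list[tuple[int, int, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
        cols = [c.strip().lower() for c in header.rstrip("\n").split(sep)]
        if cols[:2] != ["source", "target"]:
            raise GraphParseError(f"{path}:1: expected header 'source{sep}target[{sep}weight]'")
        has_weight = len(cols) >= 3 and cols[2] == "weight"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) < 2 + has_weight:
                raise GraphParseError(f"{path}:{lineno}: expected {2 + has_weight} fields, got {len(parts)}")
            u, v = parts[0].strip(), parts[1].strip()
            if has_weight:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphParseError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
            else:
                w = 1.0
            if not np.isfinite(w):
                raise GraphValidationError(f"{path}:{lineno}: weight must be finite")
            if w < 0:
                raise GraphValidationError(f"{path}:{lineno}: negative weight {w}")
            for lab in (u, v):
                if lab not in index:
                    index[lab] = len(nodes)
                    nodes.append(lab)
            rows.append((index[u], index[v], w))
    m = np.zeros((len(nodes), len(nodes)))
    for i, j, w in rows:
        m[i, j] = m[j, i] = w
    return WeightedGraph(nodes, m)


def _write_edgelist(G: Graph, path: str) -> None:
    if isinstance(G, BipartiteGraph):
        G = project(G)
    sep = _sep_for(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(sep.join(("source", "target", "weight")) + "\n")
        for u, v, w in sorted(G.edges()):
            fh.write(sep.join((u, v, _fmt_weight(w))) + "\n")


def _read_dense(path: str):
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas reports details
        raise GraphParseError(f"{path}: {exc}") from exc
    m = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        raise GraphValidationError(f"{path}: weights must be finite")
    if np.any(m < 0):
        raise GraphValidationError(f"{path}: negative weights not allowed")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    binary = np.isin(m, (0.0, 1.0)).all()
    square = m.shape[0] == m.shape[1]
    if binary and (not square or rows != cols):
        return BipartiteGraph(rows, cols, m.astype(np.int8))
    if not square:
        raise GraphParseError(f"{path}: non-square dense matrix must be a binary incidence")
    return WeightedGraph(rows, m)


def _write_dense(G: Graph, path: str) -> None:
    if isinstance(G, BipartiteGraph):
        df = pd.DataFrame(G.incidence, index=G.agents, columns=G.artifacts)
    else:
        df = pd.DataFrame(G.matrix, index=G.nodes, columns=G.nodes)
    df.to_csv(path)


def _read_mtx(path: str):
    try:
        m = scipy.io.mmread(path)
    except Exception as exc:
        raise GraphParseError(f"{path}: {exc}") from exc
    m = np.asarray(scipy.sparse.coo_matrix(m).todense(), dtype=float)
    binary = np.isin(m, (0.0, 1.0)).all()
    square = m.shape[0] == m.shape[1]
    symmetric = square and np.allclose(m, m.T)
    if binary and (not square or not symmetric):
        agents = [f"r{i + 1}" for i in range(m.shape[0])]
        artifacts = [f"c{k + 1}" for k in range(m.shape[1])]
        return BipartiteGraph(agents, artifacts, m.astype(np.int8))
    if not square:
        raise GraphParseError(f"{path}: non-square weighted Matrix Market input")
    return WeightedGraph.from_matrix(m)


def _write_mtx(G: Graph, path: str) -> None:
    m = G.incidence if isinstance(G, BipartiteGraph) else G.matrix
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m))
    # mmwrite may append .mtx itself; normalise to the requested path
    if not os.path.exists(path) and os.path.exists(path + ".mtx"):
        os.replace(path + ".mtx", path)


def _read_graphml(path: str) -> WeightedGraph:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:
        raise GraphParseError(f"{path}: {exc}") from exc
    return WeightedGraph.from_networkx(nx.Graph(g))


def _write_graphml(G: Graph, path: str) -> None:
    if isinstance(G, BipartiteGraph):
        G = project(G)
    nx.write_graphml(G.to_networkx(), path)
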