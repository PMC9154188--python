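"""Statistical inference on edgewise p-values.

Statistical backbone models score each dyad with an upper-tail p-value
(probability of an edge weight at least as large under the null) and a
lower-tail p-value (at least as small).  This module turns those scores
into a backbone: multiple-test correction, one- or two-tailed
extraction at a significance level alpha, and a narrative report of the
reduction achieved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from statsmodels.stats.multitest import multipletests

from .graph_core import GraphValidationError, WeightedGraph

if TYPE_CHECKING:  # pragma: no cover
    from .weighted_models import BackboneResult

_MTC_METHODS = {
    "none": None,
    "bonferroni": "bonferroni",
    "holm": "holm",
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "by": "fdr_by",
    "fdr_by": "fdr_by",
}

# citation strings attached to narrative output, keyed by model name
_CITATIONS = {
    "disparity": (
        "Serrano, M. A., Boguna, M., & Vespignani, A. (2009). Extracting the "
        "multiscale backbone of complex weighted networks. PNAS, 106(16), 6483-6488."
    ),
    "sdsm": (
        "Neal, Z. P. (2014). The backbone of bipartite projections. "
        "Social Networks, 39, 84-97."
    ),
    "fdsm": (
        "Zweig, K. A., & Kaufmann, M. (2011). A systematic approach to the "
        "one-mode projection of bipartite graphs. "
        "Social Network Analysis and Mining, 1(3), 187-218."
    ),
    "fixedrow": (
        "Tumminello, M., et al. (2011). Statistically validated networks in "
        "bipartite complex systems. PLOS ONE, 6(3), e17994."
    ),
    "fixedcol": (
        "Tumminello, M., et al. (2011). Statistically validated networks in "
        "bipartite complex systems. PLOS ONE, 6(3), e17994."
    ),
    "fixedfill": (
        "Zweig, K. A., & Kaufmann, M. (2011). A systematic approach to the "
        "one-mode projection of bipartite graphs. "
        "Social Network Analysis and Mining, 1(3), 187-218."
    ),
    "lspar": (
        "Satuluri, V., Parthasarathy, S., & Ruan, Y. (2011). Local graph "
        "sparsification for scalable clustering. SIGMOD 2011, 721-732."
    ),
    "localdegree": (
        "Hamann, M., Lindner, G., Meyerhenke, H., Staudt, C. L., & Wagner, D. "
        "(2016). Structure-preserving sparsification methods for social "
        "networks. Social Network Analysis and Mining, 6(1), 22."
    ),
}


@dataclass
class Backbone:
    """An extracted backbone: unweighted, optionally signed.

    ``signs`` is a symmetric integer matrix over the original node set
    with +1 for retained (significantly strong) edges, -1 for
    significantly weak edges in a signed backbone, and 0 otherwise.
    ``provenance`` records the model, alpha, correction, signed flag,
    and the reduction statistics relative to the original network.
    """

    nodes: list[str]
    signs: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.signs, dtype=np.int8)
        if s.shape != (len(self.nodes), len(self.nodes)):
            raise GraphValidationError("sign matrix does not match node set")
        if not np.isin(s, (-1, 0, 1)).all():
            raise GraphValidationError("signs must be -1, 0, or +1")
        if not np.array_equal(s, s.T):
            raise GraphValidationError("sign matrix must be symmetric")
        np.fill_diagonal(s, 0)
        self.signs = s

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.signs, 1)))

    @property
    def n_positive(self) -> int:
        return int(np.count_nonzero(np.triu(self.signs, 1) == 1))

    @property
    def n_negative(self) -> int:
        return int(np.count_nonzero(np.triu(self.signs, 1) == -1))

    def edges(self):
        """Yield (u, v, sign) for each backbone edge, labels sorted."""
        iu, ju = np.nonzero(np.triu(self.signs, 1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            u, v = sorted((self.nodes[i], self.nodes[j]))
            yield u, v, int(self.signs[i, j])

    def edge_set(self) -> frozenset:
        return frozenset((u, v) for u, v, _ in self.edges())

    def to_weighted_graph(self) -> WeightedGraph:
        """Unsigned view: every retained edge gets weight 1."""
        return WeightedGraph(list(self.nodes), (self.signs != 0).astype(float))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, sign in self.edges():
            g.add_edge(u, v, sign=sign)
        return g


def adjust_pvalues(p, method: str = "none") -> np.ndarray:
    """Adjust a family of p-values for multiple testing.

    ``method`` is one of none, bonferroni, holm, BH (Benjamini-
    Hochberg), BY (Benjamini-Yekutieli).  Output order matches input;
    adjusted values are capped at 1.
    """
    key = str(method).lower()
    if key not in _MTC_METHODS:
        raise GraphValidationError(
            f"unknown correction {method!r}; expected one of "
            "none, bonferroni, holm, BH, BY"
        )
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise GraphValidationError("p-values must lie in [0, 1]")
    sm_method = _MTC_METHODS[key]
    if sm_method is None:
        return p.copy()
    return multipletests(p.ravel(), method=sm_method)[1].reshape(p.shape)


def familywise_rate(m: int, alpha: float) -> float:
    """Probability of at least one false positive over m independent
    tests at level alpha: 1 - (1 - alpha)^m."""
    if m < 1:
        raise GraphValidationError("m must be at least 1")
    if not 0 < alpha < 1:
        raise GraphValidationError("alpha must be in (0, 1)")
    return 1.0 - (1.0 - alpha) ** m


def _reduction_stats(original: WeightedGraph, signs: np.ndarray) -> dict:
    e0 = original.n_edges
    n0 = int(np.count_nonzero(original.degrees() > 0))
    eb = int(np.count_nonzero(np.triu(signs, 1)))
    nb = int(np.count_nonzero((signs != 0).sum(axis=1) > 0))
    return {
        "original_edges": e0,
        "backbone_edges": eb,
        "original_connected_nodes": n0,
        "backbone_connected_nodes": nb,
        "edge_reduction_pct": 100.0 * (1.0 - eb / e0) if e0 else 0.0,
        "node_reduction_pct": 100.0 * (1.0 - nb / n0) if n0 else 0.0,
    }


def extract_backbone(
    R: "BackboneResult",
    alpha: float,
    signed: bool = False,
    mtc: str = "none",
) -> Backbone:
    """Extract a backbone from a p-value object at significance alpha.

    Unsigned: an edge is retained iff its (corrected) upper-tail
    p-value is strictly below alpha.  Signed: the test is two-tailed at
    alpha/2 per tail — significantly strong dyads become +1 edges and
    significantly weak dyads become -1 edges; the two tails are
    corrected separately over the same family of m tested dyads.
    """
    if not 0 < alpha < 1:
        raise GraphValidationError("alpha must be in (0, 1)")
    if signed and R.p_lower is None:
        raise GraphValidationError("signed extraction requires lower-tail p-values")

    n = len(R.nodes)
    tested = np.triu(R.tested, 1)
    ti, tj = np.nonzero(tested)
    signs = np.zeros((n, n), dtype=np.int8)
    level = alpha / 2 if signed else alpha
    if ti.size:
        up = adjust_pvalues(R.p_upper[ti, tj], mtc)
        keep = up < level
        signs[ti[keep], tj[keep]] = 1
        if signed:
            low = adjust_pvalues(R.p_lower[ti, tj], mtc)
            neg = low < level
            signs[ti[neg], tj[neg]] = -1
    signs = np.maximum(signs, signs.T) + np.minimum(signs, signs.T)  # symmetrize

    original = WeightedGraph(list(R.nodes), R.weights)
    provenance = {
        "model": R.model,
        "alpha": alpha,
        "mtc": str(mtc).lower(),
        "signed": signed,
        "m_tested": int(ti.size),
        **getattr(R, "params", {}),
        **_reduction_stats(original, signs),
    }
    return Backbone(list(R.nodes), signs, provenance)


def _fmt_pct(x: float) -> str:
    """Round to one decimal and trim a trailing '.0': 40.0% -> '40%'."""
    s = f"{round(x, 1):.1f}"
    if s.endswith(".0"):
        s = s[:-2]
    return s


def narrative_text(original: WeightedGraph, backbone: Backbone) -> tuple[str, dict]:
    """Plain-language description of an extraction plus its statistics.

    Edge reduction is the percentage decrease in undirected
    positive-weight edges; connected-node reduction is the percentage
    decrease in nodes of degree >= 1.
    """
    if original.n_edges == 0:
        raise GraphValidationError("original graph has no edges")
    stats = _reduction_stats(original, backbone.signs)
    prov = backbone.provenance
    model = prov.get("model", "unknown")

    bits = [
        f"We used the netbackbone package to extract the unweighted backbone "
        f"of a network containing {original.n_nodes} nodes."
    ]
    if prov.get("alpha") is not None:
        tail = "two-tailed, signed" if prov.get("signed") else "one-tailed"
        bits.append(
            f"An edge was retained if its weight was statistically significant "
            f"(alpha = {prov['alpha']}, {tail}"
            + (f", {prov['mtc']} correction" if prov.get("mtc", "none") != "none" else "")
            + f") under the {model} model."
        )
    elif "s" in prov:
        bits.append(
            f"Edges were retained using the {model} sparsification model "
            f"with sparsification parameter s = {prov['s']}."
        )
    elif "threshold" in prov:
        bits.append(
            f"An edge was retained if its weight exceeded the global "
            f"threshold {prov['threshold']:g}."
        )
    bits.append(
        f"This reduced the number of edges by "
        f"{_fmt_pct(stats['edge_reduction_pct'])}%, and reduced the number of "
        f"connected nodes by {_fmt_pct(stats['node_reduction_pct'])}%."
    )
    citation = _CITATIONS.get(model)
    if citation:
        bits.append(citation)
    return "\n".join(bits), stats
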