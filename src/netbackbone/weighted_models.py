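"""Backbone models for weighted unipartite networks.

Two models are provided.  The *global threshold* keeps every edge whose
weight exceeds a single cutoff — simple, but blind to multi-scale
structure where different regions of the network have different
characteristic weights.  The *disparity filter* instead tests each edge
locally: under its null model a node's total strength s_i is split
uniformly at random among its k_i edges, so the normalized weight
w_ij / s_i of a genuine edge should be larger than the null predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np

from .graph_core import GraphValidationError, WeightedGraph
from .inference import Backbone, extract_backbone, _reduction_stats

Threshold = Union[float, int, str, tuple, Callable[[np.ndarray], float]]


@dataclass
class BackboneResult:
    """Edgewise p-values plus the original weights (the alpha = NULL object).

    ``p_upper[i, j]`` is the probability under the model's null of an
    edge weight at least as large as the observed w_ij; ``p_lower`` of
    one at least as small.  Both are defined exactly on the dyads
    flagged in ``tested`` (NaN elsewhere).  A backbone at any alpha can
    be extracted later without recomputing the p-values.
    """

    nodes: list[str]
    weights: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    model: str
    params: dict = field(default_factory=dict)
    tested: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tested is None:
            # default family: dyads carrying a positive weight
            self.tested = np.triu(self.weights, 1) > 0
            self.tested |= self.tested.T
        finite_up = self.p_upper[self.tested]
        finite_lo = self.p_lower[self.tested]
        for vals, name in ((finite_up, "p_upper"), (finite_lo, "p_lower")):
            if np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
                raise GraphValidationError(f"{name} outside [0, 1]")

    def extract(self, alpha: float, signed: bool = False, mtc: str = "none") -> Backbone:
        return extract_backbone(self, alpha, signed=signed, mtc=mtc)


def _resolve_threshold(matrix: np.ndarray, upper: Threshold) -> float:
    """Evaluate a threshold specification over ALL cells of the full
    adjacency matrix — zeros and the diagonal included.  This matches
    applying a summary statistic to the matrix object itself and it
    changes results: the mean over all 100 cells of a 10x10 matrix is
    much smaller than the mean over its nonzero edges."""
    if isinstance(upper, (int, float)) and not isinstance(upper, bool):
        return float(upper)
    if callable(upper):
        return float(upper(matrix))
    if isinstance(upper, str):
        key = upper.lower()
        if key == "mean":
            return float(matrix.mean())
        if key == "median":
            return float(np.median(matrix))
        raise GraphValidationError(f"unknown threshold statistic {upper!r}")
    if isinstance(upper, tuple) and len(upper) == 2 and upper[0] == "quantile":
        return float(np.quantile(matrix, float(upper[1])))
    raise GraphValidationError(f"cannot interpret threshold {upper!r}")


def global_threshold(G: WeightedGraph, upper: Threshold) -> Backbone:
    """Global threshold backbone: keep edges with w_ij strictly above
    the cutoff.

    ``upper`` may be a number, the name of a statistic ("mean",
    "median"), a ("quantile", q) pair, or a callable applied to the
    full adjacency matrix.
    """
    t = _resolve_threshold(G.matrix, upper)
    signs = (G.matrix > t).astype(np.int8)
    provenance = {
        "model": "global",
        "alpha": None,
        "mtc": "none",
        "signed": False,
        "threshold": t,
        **_reduction_stats(G, signs),
    }
    return Backbone(list(G.nodes), signs, provenance)


def disparity_pvalues(G: WeightedGraph) -> BackboneResult:
    """Disparity-filter p-values for every positive-weight edge.

    For endpoint i with degree k_i and strength s_i the upper-tail
    value of edge (i, j) is a_i = (1 - w_ij / s_i)^(k_i - 1); a
    degree-1 endpoint contributes a_i = 1 (such an edge can still be
    kept through its other endpoint).  The edge-level upper-tail
    p-value is min(a_i, a_j) — an edge is significant if it is
    significant from either side — and since the null is continuous the
    lower tail is the complement, p_lower = 1 - p_upper.
    """
    m = G.matrix
    n = G.n_nodes
    k = G.degrees().astype(float)
    s = G.strengths()

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s[:, None] > 0, m / np.where(s[:, None] > 0, s[:, None], 1.0), 0.0)
    # endpoint-wise upper-tail value from the row node's perspective
    a = np.ones_like(m)
    active = (m > 0) & (k[:, None] > 1)
    a[active] = (1.0 - frac[active]) ** (k[:, None] - 1.0).repeat(n, axis=1)[active]

    p_upper = np.minimum(a, a.T)
    p_upper[m <= 0] = np.nan
    p_lower = 1.0 - p_upper
    tested = m > 0
    return BackboneResult(
        nodes=list(G.nodes),
        weights=m.copy(),
        p_upper=p_upper,
        p_lower=p_lower,
        model="disparity",
        params={},
        tested=tested,
    )


def disparity(
    G: WeightedGraph,
    alpha: float | None = 0.05,
    mtc: str = "none",
    signed: bool = False,
) -> Backbone | BackboneResult:
    """Disparity-filter backbone at significance level ``alpha``.

    With ``alpha=None`` the p-value object itself is returned so that
    backbones at several levels can be extracted without recomputation.
    """
    R = disparity_pvalues(G)
    if alpha is None:
        return R
    return extract_backbone(R, alpha, signed=signed, mtc=mtc)
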