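"""Null models for weighted bipartite projections.

The edge weight P_ij of a bipartite projection counts artifacts shared
by agents i and j, so its significance must be judged against random
bipartite networks — not against the projection alone.  The models here
differ in what they hold fixed:

* ``sdsm``      — stochastic degree sequence model: row and column sums
  are matched *on average* via the maximum-entropy bipartite
  configuration model; the null weight is Poisson-binomial.  Exact and
  deterministic.
* ``fdsm``      — fixed degree sequence model: row and column sums are
  matched *exactly*; p-values are estimated by Monte-Carlo sampling of
  the margin class with the curveball algorithm.
* ``fixedrow``  — only row sums fixed; the null weight is
  hypergeometric.
* ``fixedcol``  — only column sums fixed; Poisson-binomial over
  artifacts.
* ``fixedfill`` — only the total number of ones fixed; binomial.

All models return a :class:`~netbackbone.weighted_models.BackboneResult`
holding upper- and lower-tail p-values for every dyad, from which a
backbone (signed or unsigned) is extracted at any alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph_core import BipartiteGraph, GraphValidationError, project
from .weighted_models import BackboneResult

# Above this many Bernoulli components the exact dynamic-programming
# Poisson-binomial tail switches to a skewness-corrected (refined)
# normal approximation.
EXACT_PB_LIMIT = 1024


@dataclass
class ProbabilityMatrix:
    """Cellwise link probabilities Q_ik under a stochastic null.

    Expected margins sum(Q, axis=1) and sum(Q, axis=0) reproduce the
    observed agent and artifact degrees within the solver tolerance.
    """

    Q: np.ndarray
    method: str
    iterations: int
    max_residual: float


@dataclass
class NullWeightDistribution:
    """Distribution of a dyad's null edge weight W on support {0..c}.

    ``kind`` is binomial, hypergeometric, poisson_binomial, or
    empirical; ``params`` holds the kind-specific parameters.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def tails(self, w: int) -> tuple[float, float]:
        """Return (P(W >= w), P(W <= w))."""
        w = int(w)
        if self.kind == "binomial":
            n, p = self.params["n"], self.params["p"]
            if not 0 <= w <= n:
                raise GraphValidationError(f"observed weight {w} outside support [0, {n}]")
            d = stats.binom(n, p)
            return float(d.sf(w - 1)), float(d.cdf(w))
        if self.kind == "hypergeometric":
            c, di, dj = self.params["c"], self.params["d_i"], self.params["d_j"]
            d = stats.hypergeom(M=c, n=di, N=dj)
            return float(d.sf(w - 1)), float(d.cdf(w))
        if self.kind == "poisson_binomial":
            return poisson_binomial_tail(self.params["probs"], w)
        if self.kind == "empirical":
            samples = np.asarray(self.params["samples"])
            t = samples.size
            # add-one estimator: never exactly 0, usable by MTC
            pu = (1 + int(np.count_nonzero(samples >= w))) / (t + 1)
            pl = (1 + int(np.count_nonzero(samples <= w))) / (t + 1)
            return min(pu, 1.0), min(pl, 1.0)
        raise GraphValidationError(f"unknown null kind {self.kind!r}")

    def pmf(self) -> np.ndarray:
        """Exact probability mass on {0..n}; defined for exact kinds."""
        if self.kind == "binomial":
            n, p = self.params["n"], self.params["p"]
            return stats.binom(n, p).pmf(np.arange(n + 1))
        if self.kind == "hypergeometric":
            c, di, dj = self.params["c"], self.params["d_i"], self.params["d_j"]
            return stats.hypergeom(M=c, n=di, N=dj).pmf(np.arange(min(di, dj) + 1))
        if self.kind == "poisson_binomial":
            return _pb_pmf(np.asarray(self.params["probs"], dtype=float))
        raise GraphValidationError(f"no exact pmf for kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Poisson-binomial kernel
# ---------------------------------------------------------------------------

def _pb_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact PMF of a sum of independent Bernoulli(p_k) by sequential
    convolution (dynamic programming), O(n^2)."""
    pmf = np.zeros(probs.size + 1)
    pmf[0] = 1.0
    for m, p in enumerate(probs):
        if p == 0.0:
            continue
        pmf[1 : m + 2] = pmf[1 : m + 2] * (1.0 - p) + pmf[: m + 1] * p
        pmf[0] *= 1.0 - p
    return pmf


def _pb_tail_rna(probs: np.ndarray, w: int) -> tuple[float, float]:
    """Refined (second-order, skewness-corrected) normal approximation
    to the Poisson-binomial tails, used beyond the exact-DP crossover."""
    mu = probs.sum()
    var = (probs * (1.0 - probs)).sum()
    if var <= 0:
        # degenerate: W is a point mass at mu
        pu = 1.0 if w <= mu else 0.0
        pl = 1.0 if w >= mu else 0.0
        return pu, pl
    sigma = np.sqrt(var)
    gamma = (probs * (1.0 - probs) * (1.0 - 2.0 * probs)).sum() / sigma**3

    def cdf(x: float) -> float:
        z = (x + 0.5 - mu) / sigma
        val = stats.norm.cdf(z) + gamma * (1.0 - z * z) * stats.norm.pdf(z) / 6.0
        return float(np.clip(val, 0.0, 1.0))

    p_lower = cdf(w)
    p_upper = 1.0 - cdf(w - 1)
    return p_upper, p_lower


def poisson_binomial_tail(probs, w: int, exact_limit: int = EXACT_PB_LIMIT) -> tuple[float, float]:
    """Tail probabilities of W = Σ Bernoulli(p_k).

    Returns ``(P(W >= w), P(W <= w))``.  The PMF is computed by exact
    dynamic programming up to ``exact_limit`` components and by a
    refined normal approximation beyond.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1:
        raise GraphValidationError("probs must be a 1-D sequence")
    if np.any((probs < 0) | (probs > 1)):
        raise GraphValidationError("probabilities must lie in [0, 1]")
    w = int(w)
    if not 0 <= w <= probs.size:
        raise GraphValidationError(f"observed weight {w} outside support [0, {probs.size}]")
    if probs.size > exact_limit:
        return _pb_tail_rna(probs, w)
    pmf = _pb_pmf(probs)
    # the boundary tails are exactly 1; don't let float drift spoil that
    p_upper = 1.0 if w == 0 else float(pmf[w:].sum())
    p_lower = 1.0 if w == probs.size else float(pmf[: w + 1].sum())
    return min(p_upper, 1.0), min(p_lower, 1.0)


# ---------------------------------------------------------------------------
# bipartite configuration model (maximum entropy)
# ---------------------------------------------------------------------------

def bicm_fit(B: BipartiteGraph, tol: float = 1e-8, max_iter: int = 10_000) -> ProbabilityMatrix:
    """Fit the maximum-entropy bipartite configuration model.

    Solves for fitness parameters x_i (agents) and y_k (artifacts) such
    that Q_ik = x_i y_k / (1 + x_i y_k) reproduces the observed row and
    column sums in expectation, by damped fixed-point iteration.
    Degenerate margins (empty or saturated rows/columns) are peeled off
    and assigned Q = 0 or Q = 1 before solving.
    """
    B_mat = B.incidence.astype(float)
    r, c = B_mat.shape
    d = B_mat.sum(axis=1)
    f = B_mat.sum(axis=0)
    Q = np.full((r, c), np.nan)

    row_active = np.ones(r, dtype=bool)
    col_active = np.ones(c, dtype=bool)
    d_rem = d.copy()
    f_rem = f.copy()

    # peel empty/saturated margins until none remain
    changed = True
    while changed:
        changed = False
        n_cols = int(col_active.sum())
        for i in np.nonzero(row_active)[0]:
            if d_rem[i] == 0:
                Q[i, col_active] = 0.0
                row_active[i] = False
                changed = True
            elif d_rem[i] == n_cols and n_cols > 0:
                Q[i, col_active] = 1.0
                f_rem[col_active] -= 1
                row_active[i] = False
                changed = True
        n_rows = int(row_active.sum())
        for k in np.nonzero(col_active)[0]:
            if not col_active[k]:
                continue
            if f_rem[k] == 0:
                Q[row_active, k] = 0.0
                col_active[k] = False
                changed = True
            elif f_rem[k] == n_rows and n_rows > 0:
                Q[row_active, k] = 1.0
                d_rem[row_active] -= 1
                col_active[k] = False
                changed = True

    ri = np.nonzero(row_active)[0]
    ci = np.nonzero(col_active)[0]
    iterations = 0
    max_resid = 0.0
    if ri.size and ci.size:
        dd = d_rem[ri]
        ff = f_rem[ci]
        total = dd.sum()
        x = dd / np.sqrt(total)
        y = ff / np.sqrt(total)
        damp = 0.5
        for iterations in range(1, max_iter + 1):
            xy = np.outer(x, y)
            x_new = dd / (y / (1.0 + xy)).sum(axis=1)
            x = damp * x_new + (1.0 - damp) * x
            xy = np.outer(x, y)
            y_new = ff / (x[:, None] / (1.0 + xy)).sum(axis=0)
            y = damp * y_new + (1.0 - damp) * y
            xy = np.outer(x, y)
            Q_sub = xy / (1.0 + xy)
            resid_r = np.abs(Q_sub.sum(axis=1) - dd)
            resid_c = np.abs(Q_sub.sum(axis=0) - ff)
            max_resid = float(max(resid_r.max(), resid_c.max()))
            if max_resid < tol:
                break
        else:
            worst = max(
                (resid_r.max(), f"agent {B.agents[ri[int(resid_r.argmax())]]}"),
                (resid_c.max(), f"artifact {B.artifacts[ci[int(resid_c.argmax())]]}"),
            )
            raise GraphValidationError(
                f"bicm_fit did not converge in {max_iter} iterations; "
                f"worst margin residual {worst[0]:.3g} at {worst[1]}"
            )
        Q[np.ix_(ri, ci)] = Q_sub

    assert not np.isnan(Q).any()
    return ProbabilityMatrix(Q=Q, method="bicm", iterations=iterations, max_residual=max_resid)


# ---------------------------------------------------------------------------
# deterministic models
# ---------------------------------------------------------------------------

def _result_from_nulls(B: BipartiteGraph, null_for_pair, model: str, params: dict) -> BackboneResult:
    """Assemble a BackboneResult by evaluating a per-pair null at the
    observed projection weights.  All dyads are tested so that signed
    extraction (significantly weak zero-weight pairs) is possible."""
    P = project(B)
    r = B.n_agents
    p_upper = np.full((r, r), np.nan)
    p_lower = np.full((r, r), np.nan)
    for i in range(r):
        p_upper[i, i] = p_lower[i, i] = np.nan
        for j in range(i + 1, r):
            dist = null_for_pair(i, j)
            pu, pl = dist.tails(int(P.matrix[i, j]))
            p_upper[i, j] = p_upper[j, i] = pu
            p_lower[i, j] = p_lower[j, i] = pl
    tested = ~np.eye(r, dtype=bool)
    return BackboneResult(
        nodes=list(B.agents),
        weights=P.matrix,
        p_upper=p_upper,
        p_lower=p_lower,
        model=model,
        params=params,
        tested=tested,
    )


def sdsm(B: BipartiteGraph, tol: float = 1e-8, max_iter: int = 10_000) -> BackboneResult:
    """Stochastic degree sequence model.

    Cell probabilities Q come from the maximum-entropy bipartite
    configuration model; the null weight of dyad (i, j) is then
    Poisson-binomial with parameters {Q_ik * Q_jk over artifacts k}.
    Fully deterministic.
    """
    pm = bicm_fit(B, tol=tol, max_iter=max_iter)
    Q = pm.Q

    def null(i: int, j: int) -> NullWeightDistribution:
        return NullWeightDistribution("poisson_binomial", {"probs": Q[i] * Q[j]})

    return _result_from_nulls(
        B, null, "sdsm",
        {"probability_model": "bicm", "bicm_iterations": pm.iterations},
    )


def fixedrow(B: BipartiteGraph) -> BackboneResult:
    """Fixed row sums: W_ij ~ Hypergeometric(c, d_i, d_j) — agent j's
    d_j artifacts drawn uniformly among the c, overlapping agent i's
    d_i."""
    d = B.agent_degrees()
    c = B.n_artifacts

    def null(i: int, j: int) -> NullWeightDistribution:
        return NullWeightDistribution(
            "hypergeometric", {"c": c, "d_i": int(d[i]), "d_j": int(d[j])}
        )

    return _result_from_nulls(B, null, "fixedrow", {})


def fixedcol(B: BipartiteGraph) -> BackboneResult:
    """Fixed column sums: each artifact k independently joins a random
    pair of agents with probability pi_k = (f_k/r)((f_k-1)/(r-1)); the
    dyad weight is Poisson-binomial over artifacts (identical for all
    dyads)."""
    r = B.n_agents
    if r < 2:
        raise GraphValidationError("fixedcol requires at least 2 agents")
    f = B.artifact_degrees().astype(float)
    pi = (f / r) * (np.maximum(f - 1.0, 0.0) / (r - 1))
    dist = NullWeightDistribution("poisson_binomial", {"probs": pi})

    # one distribution for every dyad: precompute its CDF once
    pmf = dist.pmf()
    cdf = np.cumsum(pmf)

    class _Shared:
        def tails(self, w: int) -> tuple[float, float]:
            pl = float(min(cdf[w], 1.0))
            pu = float(min(1.0 - (cdf[w - 1] if w > 0 else 0.0), 1.0)) if w > 0 else 1.0
            return pu, pl

    shared = _Shared()
    return _result_from_nulls(B, lambda i, j: shared, "fixedcol", {})


def fixedfill(B: BipartiteGraph) -> BackboneResult:
    """Fixed fill: only the density q = (number of ones)/(r*c) is
    constrained, so each artifact joins a given pair with probability
    q^2 and W ~ Binomial(c, q^2)."""
    r, c = B.n_agents, B.n_artifacts
    if r * c == 0:
        raise GraphValidationError("empty incidence matrix")
    q = float(B.incidence.sum()) / (r * c)
    dist = NullWeightDistribution("binomial", {"n": c, "p": q * q})
    return _result_from_nulls(B, lambda i, j: dist, "fixedfill", {"q": q})


# ---------------------------------------------------------------------------
# fixed degree sequence model (Monte Carlo)
# ---------------------------------------------------------------------------

def _curveball_trades(row_sets: list[set], steps: int, rng: np.random.Generator) -> None:
    """Perform ``steps`` curveball trades in place: two random rows swap
    a random number of their non-shared artifacts, preserving both row
    and column sums."""
    r = len(row_sets)
    for _ in range(steps):
        i, j = rng.choice(r, size=2, replace=False)
        a_only = list(row_sets[i] - row_sets[j])
        b_only = list(row_sets[j] - row_sets[i])
        if not a_only and not b_only:
            continue
        pool = a_only + b_only
        perm = rng.permutation(len(pool))
        new_a = {pool[t] for t in perm[: len(a_only)]}
        new_b = {pool[t] for t in perm[len(a_only) :]}
        shared = row_sets[i] & row_sets[j]
        row_sets[i] = shared | new_a
        row_sets[j] = shared | new_b

def _sets_to_incidence(row_sets: list[set], c: int) -> np.ndarray:
    m = np.zeros((len(row_sets), c), dtype=np.int8)
    for i, s in enumerate(row_sets):
        m[i, list(s)] = 1
    return m


def curveball_sample(B: BipartiteGraph, steps: int = None, seed: int | np.random.Generator = 0) -> BipartiteGraph:
    """Draw one random bipartite network with exactly the row and
    column sums of ``B`` via ``steps`` curveball trades (default 5r).

    Deterministic given ``seed``.
    """
    if steps is None:
        steps = 5 * B.n_agents
    if steps < 1:
        raise GraphValidationError("steps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row_sets = [set(np.nonzero(B.incidence[i])[0].tolist()) for i in range(B.n_agents)]
    _curveball_trades(row_sets, steps, rng)
    return BipartiteGraph(
        list(B.agents), list(B.artifacts), _sets_to_incidence(row_sets, B.n_artifacts)
    )


def auto_trials(alpha: float, z: float = 1.96) -> int:
    """Smallest Monte-Carlo sample size at which the 95% binomial
    confidence interval for a p-value near ``alpha`` has half-width at
    most alpha/10."""
    if not 0 < alpha < 1:
        raise GraphValidationError("alpha must be in (0, 1)")
    return int(np.ceil(z * z * (1.0 - alpha) * 100.0 / alpha))


def fdsm(
    B: BipartiteGraph,
    trials: int | str | None = None,
    alpha: float | None = None,
    seed: int = 0,
) -> BackboneResult:
    """Fixed degree sequence model with Monte-Carlo p-values.

    Samples the class of bipartite networks with exactly the observed
    margins by a sequential curveball chain (5r trades between retained
    samples).  Empirical p-values use the add-one estimator
    (1 + hits)/(trials + 1), so they are never exactly zero.  With
    ``trials`` omitted, the sample size is chosen from ``alpha`` so the
    p-value is estimated precisely enough to compare against it.
    """
    if trials in (None, "auto"):
        if alpha is None:
            raise GraphValidationError("automatic trials selection requires alpha")
        trials = auto_trials(alpha)
    trials = int(trials)
    if trials < 1:
        raise GraphValidationError("trials must be >= 1")

    P_obs = project(B).matrix.astype(int)
    r, c = B.n_agents, B.n_artifacts
    rng = np.random.default_rng(seed)
    row_sets = [set(np.nonzero(B.incidence[i])[0].tolist()) for i in range(r)]
    step = 5 * r

    count_ge = np.zeros((r, r), dtype=np.int64)
    count_le = np.zeros((r, r), dtype=np.int64)
    for _ in range(trials):
        _curveball_trades(row_sets, step, rng)
        m = _sets_to_incidence(row_sets, c).astype(np.int64)
        P_star = m @ m.T
        count_ge += P_star >= P_obs
        count_le += P_star <= P_obs

    p_upper = (1.0 + count_ge) / (trials + 1.0)
    p_lower = (1.0 + count_le) / (trials + 1.0)
    np.clip(p_upper, 0.0, 1.0, out=p_upper)
    np.clip(p_lower, 0.0, 1.0, out=p_lower)
    np.fill_diagonal(p_upper, np.nan)
    np.fill_diagonal(p_lower, np.nan)
    tested = ~np.eye(r, dtype=bool)
    return BackboneResult(
        nodes=list(B.agents),
        weights=P_obs.astype(float),
        p_upper=p_upper,
        p_lower=p_lower,
        model="fdsm",
        params={"trials": trials, "seed": seed, "trades_per_sample": step},
        tested=tested,
    )
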