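"""Hybrid Bayesian-network structure learning with MDL scoring.

Constraint phase: a G-test on every variable pair prunes the search space
to a candidate skeleton.  Score phase: greedy hill climbing over the
operators add / delete / reverse, restricted to skeleton pairs and the DAG
constraint, minimizing a decomposable two-part MDL code length (bits):

    score(node | parents) = sum_{j,k} -N_jk log2(N_jk / N_j.)
                            + (log2 N)/2 * q * (r - 1)

where r is the node arity and q the product of parent arities.  Multiple
restarts from the empty graph, each with an independently shuffled
operator-evaluation order, guard against local optima; the best-scoring
network across restarts is returned, bit-identically reproducible given
the seed.  Edge strength ("explanatory weight") is the MDL improvement a
single edge contributes given the child's other parents.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import inf, log2

import numpy as np
from scipy.stats import chi2

from .discretize import DiscretizedDataset
from .mmi import crosstab, plugin_mi

_LN2 = float(np.log(2.0))
_EPS = 1e-9  # strict-improvement threshold for hill-climbing moves


@dataclass
class BayesianNetwork:
    """Learned DAG with per-edge strengths and per-node local MDL scores."""

    nodes: list[str]
    arities: dict[str, int]
    edges: set[tuple[str, str]]
    edge_strengths: dict[tuple[str, str], float]
    node_scores: dict[str, float]
    total_score: float
    learn_meta: dict = field(default_factory=dict)

    def parents(self, node: str) -> set[str]:
        return {u for (u, v) in self.edges if v == node}

    def children(self, node: str) -> set[str]:
        return {v for (u, v) in self.edges if u == node}

    def neighbors(self, node: str) -> set[str]:
        return self.parents(node) | self.children(node)


@dataclass
class MarkovView:
    """Markov neighborhood and blanket of a target node.

    The neighborhood (MN) holds the immediately adjacent variables with the
    strength of the adjoining edge; the blanket (MB) adds co-parents
    (other parents of the target's children) and carries the edges induced
    among blanket members.
    """

    target: str
    neighborhood: dict[str, float]
    blanket: set[str]
    induced_edges: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# MDL scoring
# ---------------------------------------------------------------------------

def local_mdl_score(node: str, parents, dds: DiscretizedDataset) -> float:
    """Two-part MDL code length (bits) of ``node`` given ``parents``.

    Lower is better.  The penalty counts the full parent-configuration
    space (product of arities), observed or not.
    """
    parents = sorted(parents)
    if node in parents:
        raise ValueError(f"node {node!r} cannot be its own parent")
    x = dds.column(node)
    r = dds.arity(node)
    n = dds.n_samples
    if parents:
        q = 1
        cfg = np.zeros(n, dtype=np.int64)
        for p in parents:
            cfg = cfg * dds.arity(p) + dds.column(p)
            q *= dds.arity(p)
        counts = np.bincount(cfg * r + x, minlength=q * r).reshape(q, r).astype(float)
    else:
        q = 1
        counts = np.bincount(x, minlength=r).astype(float).reshape(1, r)
    row_tot = counts.sum(axis=1, keepdims=True)
    mask = counts > 0
    loglik = -(counts[mask] * np.log2(counts[mask] / np.broadcast_to(row_tot, counts.shape)[mask])).sum()
    penalty = 0.5 * log2(n) * q * (r - 1)
    return float(loglik + penalty)


def candidate_skeleton(dds: DiscretizedDataset, alpha: float = 0.01) -> set[frozenset]:
    """Unordered variable pairs surviving a pairwise G-test of independence.

    A pair is kept iff G = 2 N ln2 * MI(x, y) exceeds the chi-square
    critical value with (r_x - 1)(r_y - 1) degrees of freedom at ``alpha``.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    names = dds.var_names
    n = dds.n_samples
    cols = {v: dds.column(v) for v in names}
    ars = {v: dds.arity(v) for v in names}
    kept: set[frozenset] = set()
    crit_cache: dict[int, float] = {}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            mi = plugin_mi(crosstab(cols[x], cols[y], ars[x], ars[y]))
            g = 2.0 * n * _LN2 * mi
            df = (ars[x] - 1) * (ars[y] - 1)
            if df not in crit_cache:
                crit_cache[df] = float(chi2.isf(alpha, df)) if alpha < 1 else 0.0
            if g > crit_cache[df]:
                kept.add(frozenset((x, y)))
    return kept


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

class _Searcher:
    """One hill-climbing run over a fixed candidate pair order."""

    def __init__(self, dds: DiscretizedDataset, pairs: list[tuple[str, str]],
                 cache: dict, flips: list[bool] | None = None):
        self.dds = dds
        self.pairs = pairs
        # per-pair direction evaluation order: score-equivalent orientations
        # tie-break differently across restarts, letting some restart seed
        # the orientation a collider needs
        self.flips = flips or [False] * len(pairs)
        self.cache = cache
        self.parents: dict[str, set[str]] = {v: set() for v in dds.var_names}
        self.children: dict[str, set[str]] = {v: set() for v in dds.var_names}
        self.scores = {v: self.local(v, frozenset()) for v in dds.var_names}

    def local(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key not in self.cache:
            self.cache[key] = local_mdl_score(node, parents, self.dds)
        return self.cache[key]

    def creates_cycle(self, u: str, v: str) -> bool:
        """Would adding u -> v close a directed cycle (path v ~> u)?"""
        stack, seen = [v], {v}
        while stack:
            w = stack.pop()
            if w == u:
                return True
            for c in self.children[w]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return False

    def apply(self, move) -> None:
        op, u, v = move
        if op == "add":
            self.parents[v].add(u)
            self.children[u].add(v)
            self.scores[v] = self.local(v, frozenset(self.parents[v]))
        elif op == "del":
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.scores[v] = self.local(v, frozenset(self.parents[v]))
        else:  # reverse u -> v into v -> u
            self.apply(("del", u, v))
            self.apply(("add", v, u))

    def pair_move(self, x: str, y: str, flip: bool = False):
        """Best strictly-improving move touching the pair {x, y}, or None."""
        best_delta, best = -_EPS, None
        fwd = x in self.parents[y]
        rev = y in self.parents[x]
        if not fwd and not rev:
            directions = ((y, x), (x, y)) if flip else ((x, y), (y, x))
            for u, v in directions:
                if self.creates_cycle(u, v):
                    continue
                new = self.local(v, frozenset(self.parents[v] | {u}))
                delta = new - self.scores[v]
                if delta < best_delta:
                    best_delta, best = delta, ("add", u, v)
        else:
            u, v = (x, y) if fwd else (y, x)
            new = self.local(v, frozenset(self.parents[v] - {u}))
            delta = new - self.scores[v]
            if delta < best_delta:
                best_delta, best = delta, ("del", u, v)
            # reverse: delete u->v then add v->u
            self.children[u].discard(v)  # transient: cycle check without the edge
            cyc = self.creates_cycle(v, u)
            self.children[u].add(v)
            if not cyc:
                d_child = new - self.scores[v]
                d_parent = (self.local(u, frozenset(self.parents[u] | {v}))
                            - self.scores[u])
                delta = d_child + d_parent
                if delta < best_delta:
                    best_delta, best = delta, ("rev", u, v)
        return best

    def climb(self) -> float:
        """First-improvement hill climbing over the (shuffled) pair order.

        Repeated passes apply the best improving move per pair as soon as it
        is found; terminates at a local optimum (a full pass with no move).
        Different pair orders thus explore genuinely different trajectories,
        which is what makes the restarts informative.
        """
        improved = True
        while improved:
            improved = False
            for (x, y), flip in zip(self.pairs, self.flips):
                move = self.pair_move(x, y, flip)
                if move is not None:
                    self.apply(move)
                    improved = True
        return sum(self.scores.values())

    def prune_zero_strength(self) -> None:
        """Drop edges whose removal does not worsen the score (strength <= 0)."""
        changed = True
        while changed:
            changed = False
            for v in sorted(self.parents):
                for u in sorted(self.parents[v]):
                    without = self.local(v, frozenset(self.parents[v] - {u}))
                    if without - self.scores[v] <= _EPS:
                        self.apply(("del", u, v))
                        changed = True


def learn_structure(dds: DiscretizedDataset, restarts: int = 20,
                    seed: int = 0, alpha: float = 0.01,
                    skeleton: set | None = None) -> BayesianNetwork:
    """Learn a DAG minimizing total MDL via restarted greedy hill climbing.

    Each restart begins from the empty graph with an independently
    shuffled operator-evaluation order; the best-scoring restart wins
    (earliest restart on ties).  Fully reproducible given ``seed``.
    """
    if restarts <= 0:
        raise ValueError("restarts must be positive")
    names = dds.var_names
    if len(names) < 2 or dds.n_samples < 1:
        raise ValueError("need at least 2 variables and 1 sample")
    if skeleton is None:
        skeleton = candidate_skeleton(dds, alpha=alpha)
    base_pairs = sorted(tuple(sorted(p)) for p in skeleton)
    rng = np.random.default_rng(seed)
    cache: dict = {}

    best_score, best_state = inf, None
    for _ in range(restarts):
        if base_pairs:
            order = rng.permutation(len(base_pairs))
            pairs = [base_pairs[i] for i in order]
            flips = list(rng.random(len(pairs)) < 0.5)
        else:
            pairs, flips = [], []
        s = _Searcher(dds, pairs, cache, flips)
        total = s.climb()
        s.prune_zero_strength()
        total = sum(s.scores.values())
        if total < best_score - _EPS:
            best_score = total
            best_state = {v: frozenset(ps) for v, ps in s.parents.items()}

    edges = {(u, v) for v, ps in best_state.items() for u in ps}
    node_scores = {
        v: local_mdl_score(v, best_state[v], dds) for v in names
    }
    bn = BayesianNetwork(
        nodes=list(names),
        arities={v: dds.arity(v) for v in names},
        edges=edges,
        edge_strengths={},
        node_scores=node_scores,
        total_score=float(sum(node_scores.values())),
        learn_meta={"restarts": restarts, "seed": seed, "alpha": alpha,
                    "n_samples": dds.n_samples},
    )
    bn.edge_strengths = {e: edge_strength(bn, e, dds) for e in edges}
    return bn


def edge_strength(bn: BayesianNetwork, edge: tuple[str, str],
                  dds: DiscretizedDataset) -> float:
    """MDL improvement (bits) attributable to ``edge`` given the other parents.

    strength = score(child | parents - {parent}) - score(child | parents);
    positive for every retained edge.
    """
    if edge not in bn.edges:
        raise KeyError(f"edge {edge} not in network")
    parent, child = edge
    parents = bn.parents(child)
    return (local_mdl_score(child, parents - {parent}, dds)
            - local_mdl_score(child, parents, dds))


def markov_view(bn: BayesianNetwork, target: str) -> MarkovView:
    """Markov neighborhood and blanket of ``target`` in ``bn``."""
    if target not in bn.nodes:
        raise KeyError(f"unknown target {target!r}")
    parents = bn.parents(target)
    children = bn.children(target)
    neighborhood = {}
    for p in parents:
        neighborhood[p] = bn.edge_strengths.get((p, target), 0.0)
    for c in children:
        neighborhood[c] = bn.edge_strengths.get((target, c), 0.0)
    coparents = set()
    for c in children:
        coparents |= bn.parents(c)
    blanket = (parents | children | coparents) - {target}
    induced = {(u, v) for (u, v) in bn.edges if u in blanket and v in blanket}
    return MarkovView(target=target, neighborhood=neighborhood,
                      blanket=blanket, induced_edges=induced)


def dependency_path(bn: BayesianNetwork, a: str, b: str):
    """Shortest undirected path from ``a`` to ``b``; None if disconnected.

    Among equal-length paths the lexicographically smallest node sequence
    is returned.
    """
    for node in (a, b):
        if node not in bn.nodes:
            raise KeyError(f"unknown node {node!r}")
    if a == b:
        return [a]
    adj: dict[str, list[str]] = {v: [] for v in bn.nodes}
    for (u, v) in bn.edges:
        adj[u].append(v)
        adj[v].append(u)
    adj = {v: sorted(set(ns)) for v, ns in adj.items()}
    # BFS distances from b, then greedy lexicographic descent from a
    dist = {b: 0}
    frontier = [b]
    while frontier:
        nxt = []
        for w in frontier:
            for u in adj[w]:
                if u not in dist:
                    dist[u] = dist[w] + 1
                    nxt.append(u)
        frontier = nxt
    if a not in dist:
        return None
    path = [a]
    cur = a
    while cur != b:
        cur = min(u for u in adj[cur] if dist.get(cur, 0) - 1 == dist.get(u, -2))
        path.append(cur)
    return path
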