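"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the package's own code paths: MI by a
literal double loop over cells, max-entropy partitioning by recursive
enumeration, and structure scores by exhaustive enumeration of all DAGs on
three variables.
"""
from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import settings

import expressbn as xbn

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def mi_bruteforce(table) -> float:
    """Plug-in MI by an explicit double loop (bits)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * math.log2(nij * n / (rows[i] * cols[j]))
    return mi


def entropy_bits(sizes) -> float:
    n = sum(sizes)
    return -sum((s / n) * math.log2(s / n) for s in sizes if s > 0)


def all_tie_respecting_partitions(group_counts, k):
    """Yield every contiguous k-partition of tie groups as a size tuple."""
    m = len(group_counts)

    def rec(start, bins_left):
        if bins_left == 1:
            yield (sum(group_counts[start:]),)
            return
        # leave at least bins_left-1 groups for the remaining bins
        for end in range(start + 1, m - bins_left + 2):
            head = sum(group_counts[start:end])
            for rest in rec(end, bins_left - 1):
                yield (head,) + rest

    yield from rec(0, k)


def max_partition_entropy(values, k) -> float:
    """Best achievable occupancy entropy by exhaustive enumeration."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return max(entropy_bits(s) for s in all_tie_respecting_partitions(counts, k))


def all_dags(nodes):
    """Every DAG over the given nodes as a frozenset of directed edges."""
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    dags = []
    # each unordered pair is absent, forward, or backward
    for choice in product((0, 1, 2), repeat=len(pairs)):
        edges = set()
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.add((a, b))
            elif c == 2:
                edges.add((b, a))
        if _is_acyclic(nodes, edges):
            dags.append(frozenset(edges))
    return dags


def _is_acyclic(nodes, edges) -> bool:
    children = {v: [] for v in nodes}
    for u, v in edges:
        children[u].append(v)
    seen, done = set(), set()

    def visit(v):
        if v in done:
            return True
        if v in seen:
            return False
        seen.add(v)
        ok = all(visit(c) for c in children[v])
        done.add(v)
        return ok

    return all(visit(v) for v in nodes)


def exhaustive_best_score(dds, nodes) -> float:
    """Minimum total MDL over every DAG on ``nodes`` (exhaustive search)."""
    best = math.inf
    for dag in all_dags(list(nodes)):
        total = 0.0
        for v in nodes:
            parents = {u for (u, w) in dag if w == v}
            total += xbn.local_mdl_score(v, parents, dds)
        best = min(best, total)
    return best


def dds_from_codes(columns: dict[str, np.ndarray], arities: dict[str, int]):
    """Build a DiscretizedDataset directly from integer-coded columns."""
    from expressbn.discretize import DiscretizedDataset
    from expressbn.io import VariableSpec

    names = list(columns)
    n = len(next(iter(columns.values())))
    return DiscretizedDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        variable_specs=[VariableSpec(v, "discrete", arities[v]) for v in names],
        codes=np.column_stack([columns[v] for v in names]),
    )


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared across tests (50 transcripts)."""
    cfg = xbn.kronos_like(seed=11, n_transcripts=50)
    ds, truth = xbn.generate(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def small_dds(small_cohort):
    ds, _ = small_cohort
    return xbn.discretize_dataset(ds, k=3)
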