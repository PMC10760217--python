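"""Maximum-entropy discretization of continuous variables.

Each continuous variable is cut into ``k`` ordered bins (default 3:
low / medium / high) by the tie-respecting contiguous partition of its
sorted values that maximizes the Shannon entropy of bin occupancy — the
multinomial representation consumed by the mutual-information ranking and
the Bayesian-network learner.  Equal frequency is the entropy optimum, so
for tie-free data this is equal-frequency binning; ties are never split
across a bin boundary, which keeps the code a function of the raw value.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .io import ExpressionDataset, VariableSpec

log = logging.getLogger(__name__)

#: largest number of candidate partitions enumerated exhaustively
_ENUM_CAP = 4_000_000


class DegenerateVariableError(ValueError):
    """Variable has fewer distinct values than requested bins."""


@dataclass
class BinAssignment:
    """Cut points and integer codes for one discretized variable."""

    variable: str
    edges: list[float]        # k-1 sorted cut points (midpoints between values)
    codes: np.ndarray         # per-sample bin index, 0 = low
    bin_counts: np.ndarray    # occupancy per bin, all >= 1

    @property
    def k(self) -> int:
        return len(self.bin_counts)

    def code_value(self, x: float) -> int:
        """Bin index for a (possibly out-of-sample) raw value."""
        return int(np.digitize([x], self.edges)[0])


@dataclass
class DiscretizedDataset:
    """Integer-coded samples x variables matrix with per-variable metadata."""

    sample_ids: list[str]
    variable_specs: list[VariableSpec]
    codes: np.ndarray
    assignments: dict[str, BinAssignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self._index = {s.name: i for i, s in enumerate(self.variable_specs)}
        if self.codes.shape != (len(self.sample_ids), len(self.variable_specs)):
            raise ValueError("codes shape does not match ids/specs")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def var_names(self) -> list[str]:
        return [s.name for s in self.variable_specs]

    def arity(self, name: str) -> int:
        return self.variable_specs[self._index[name]].arity

    def column(self, name: str) -> np.ndarray:
        if name not in self._index:
            raise KeyError(f"unknown variable {name!r}")
        return self.codes[:, self._index[name]]

    def subset(self, names: list[str]) -> "DiscretizedDataset":
        idx = [self._index[n] for n in names]
        return DiscretizedDataset(
            sample_ids=list(self.sample_ids),
            variable_specs=[self.variable_specs[i] for i in idx],
            codes=self.codes[:, idx],
            assignments={n: self.assignments[n] for n in names
                         if n in self.assignments},
        )


def occupancy_entropy(assignment: BinAssignment) -> float:
    """Shannon entropy (bits) of the bin-occupancy distribution."""
    return _entropy_bits(np.asarray(assignment.bin_counts, dtype=float))


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _best_partition_enumerate(group_counts: np.ndarray, k: int):
    """Exhaustively score every tie-respecting contiguous k-partition.

    Returns (cut group-indices, bin sizes).  Ties on entropy are broken by
    the lexicographically most balanced size multiset (sorted descending),
    then by the smallest cut-index vector — fully deterministic.
    """
    m = len(group_counts)
    pref = np.concatenate(([0], np.cumsum(group_counts)))
    total = pref[-1]
    cuts = np.array(list(combinations(range(1, m), k - 1)), dtype=np.int64)
    boundary = pref[cuts]  # (R, k-1) cumulative counts at each cut
    rows = len(cuts)
    sizes = np.diff(
        np.hstack([np.zeros((rows, 1)), boundary, np.full((rows, 1), total)]),
        axis=1,
    )
    p = sizes / total
    entropy = -(p * np.log2(p)).sum(axis=1)
    best = entropy.max()
    tied = np.flatnonzero(entropy >= best - 1e-12)
    key = min(
        tied,
        key=lambda r: (
            tuple(sorted(sizes[r], reverse=True)),
            tuple(cuts[r]),
        ),
    )
    return list(cuts[key]), sizes[key].astype(int)


def _best_partition_dp(group_counts: np.ndarray, k: int):
    """Entropy-maximizing partition by dynamic programming.

    Exact on the entropy objective (it is additive over bins); the global
    balancedness tie-break is applied only locally, preferring smaller cut
    indices.  Used when exhaustive enumeration would be too large.
    """
    m = len(group_counts)
    pref = np.concatenate(([0.0], np.cumsum(group_counts)))
    total = pref[-1]

    def seg(i: int, j: int) -> float:  # -p log2 p for groups [i, j)
        p = (pref[j] - pref[i]) / total
        return -p * np.log2(p)

    NEG = -np.inf
    score = np.full((m + 1, k + 1), NEG)
    back = np.zeros((m + 1, k + 1), dtype=np.int64)
    score[0, 0] = 0.0
    for j in range(1, m + 1):
        bmax = min(k, j)
        for b in range(1, bmax + 1):
            for i in range(b - 1, j):
                if score[i, b - 1] == NEG:
                    continue
                cand = score[i, b - 1] + seg(i, j)
                if cand > score[j, b] + 1e-15:
                    score[j, b] = cand
                    back[j, b] = i
    cuts = []
    j, b = m, k
    while b > 1:
        j = back[j, b]
        cuts.append(j)
        b -= 1
    cuts = sorted(cuts)
    bounds = [0] + cuts + [m]
    sizes = np.array([pref[bounds[i + 1]] - pref[bounds[i]]
                      for i in range(k)], dtype=int)
    return cuts, sizes


def max_entropy_bins(values, k: int = 3, variable: str = "x") -> BinAssignment:
    """Discretize ``values`` into ``k`` bins maximizing occupancy entropy.

    Considers every contiguous partition of the sorted values that keeps
    tied values together; requires at least ``k`` distinct values.  Cut
    points are stored as midpoints between the adjacent distinct values
    across each boundary, so out-of-sample values code stably.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    uniq, counts = np.unique(values, return_counts=True)
    if len(uniq) < k:
        raise DegenerateVariableError(
            f"variable {variable!r} has {len(uniq)} distinct values; needs >= {k}"
        )
    if len(uniq) == len(values):
        # tie-free fast path: entropy is strictly concave in the size vector,
        # so the optimum is the balanced split; the tie-break (most balanced,
        # then smallest first cut) puts the remainder in the last bins
        n, rem = divmod(len(values), k)
        sizes = np.array([n] * (k - rem) + [n + 1] * rem)
        cut_idx = list(np.cumsum(sizes)[:-1])
    elif comb(len(uniq) - 1, k - 1) <= _ENUM_CAP:
        cut_idx, sizes = _best_partition_enumerate(counts, k)
    else:
        cut_idx, sizes = _best_partition_dp(counts, k)
    edges = [float((uniq[j - 1] + uniq[j]) / 2.0) for j in cut_idx]
    codes = np.digitize(values, edges)
    bin_counts = np.bincount(codes, minlength=k)
    assert (bin_counts == sizes).all()
    return BinAssignment(variable=variable, edges=edges,
                         codes=codes.astype(np.int64), bin_counts=bin_counts)


def discretize_dataset(
    ds: ExpressionDataset,
    k: int = 3,
    degenerate_policy: str = "drop",
) -> DiscretizedDataset:
    """Discretize every transcript of ``ds``; pass phenotypes through.

    Transcripts with fewer than ``k`` distinct values are dropped with a
    warning (``degenerate_policy="drop"``) or raise
    (``degenerate_policy="error"``).  Phenotype columns keep their integer
    codes, with arity recorded as ``max+1`` (binary for DX / APOE_Genetic).
    """
    if degenerate_policy not in ("drop", "error"):
        raise ValueError(f"unknown degenerate policy {degenerate_policy!r}")

    specs: list[VariableSpec] = []
    cols: list[np.ndarray] = []
    assignments: dict[str, BinAssignment] = {}
    for j, name in enumerate(ds.transcript_ids):
        try:
            a = max_entropy_bins(ds.values[:, j], k=k, variable=name)
        except DegenerateVariableError:
            if degenerate_policy == "error":
                raise
            log.warning("dropping degenerate transcript %r", name)
            continue
        specs.append(VariableSpec(name=name, kind="discrete", arity=k))
        cols.append(a.codes)
        assignments[name] = a

    for name, vec in ds.phenotypes.items():
        vec = np.asarray(vec, dtype=np.int64)
        if vec.min() < 0:
            raise ValueError(f"phenotype {name!r} has negative codes")
        arity = max(int(vec.max()) + 1, 2)
        specs.append(VariableSpec(name=name, kind="discrete", arity=arity))
        cols.append(vec)

    if not cols:
        raise DegenerateVariableError("all variables degenerate; nothing to discretize")
    return DiscretizedDataset(
        sample_ids=list(ds.sample_ids),
        variable_specs=specs,
        codes=np.column_stack(cols),
        assignments=assignments,
    )


def export_bin_edges(dds: DiscretizedDataset, path) -> None:
    """TSV of per-variable cut points (variable, edge_1, ..., edge_{k-1})."""
    with open(path, "w") as fh:
        for name in dds.var_names:
            a = dds.assignments.get(name)
            if a is None:
                continue
            fh.write(name + "\t" + "\t".join(f"{e:.6f}" for e in a.edges) + "\n")
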