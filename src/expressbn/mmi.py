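"""Mixed mutual information ranking against the diagnosis node.

Mutual information between each (discretized) variable and a discrete
target such as LOAD status, computed with the plug-in estimator on the
shared multinomial coding.  Produces the descending MMI ranking used for
top-k transcript pre-selection and the empirical MMI CDF used to place
named hits by explanatory weight.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discretize import DiscretizedDataset


def plugin_mi(counts) -> float:
    """Plug-in mutual information (bits) of a 2-way contingency table.

    ``I = sum p(x,y) log2[ p(x,y) / (p(x) p(y)) ]`` with 0 log 0 = 0.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table < 0).any():
        raise ValueError("negative cell in contingency table")
    n = table.sum()
    if n < 1:
        raise ValueError("table total must be >= 1")
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    mi = (pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])).sum()
    return max(float(mi), 0.0)  # clamp float round-off on independent tables


def crosstab(x: np.ndarray, y: np.ndarray, rx: int, ry: int) -> np.ndarray:
    """Joint count table of two integer-coded vectors."""
    return np.bincount(x * ry + y, minlength=rx * ry).reshape(rx, ry)


def mmi_pair(x: str, y: str, dds: DiscretizedDataset) -> float:
    """Mutual information (bits) between two coded variables of ``dds``."""
    cx, cy = dds.column(x), dds.column(y)
    return plugin_mi(crosstab(cx, cy, dds.arity(x), dds.arity(y)))


@dataclass
class MMIRanking:
    """Descending MMI-with-target ranking of a dataset's variables."""

    dataset_label: str
    target: str
    entries: list[tuple[str, float]]  # (variable, mmi bits), descending
    n_samples: int

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.entries])

    def mmi_of(self, variable: str) -> float:
        for name, v in self.entries:
            if name == variable:
                return v
        raise KeyError(f"variable {variable!r} not in ranking")

    def restrict(self, universe: set[str]) -> "MMIRanking":
        return MMIRanking(
            dataset_label=self.dataset_label,
            target=self.target,
            entries=[(n, v) for n, v in self.entries if n in universe],
            n_samples=self.n_samples,
        )


def rank_by_mmi(dds: DiscretizedDataset, target: str = "DX",
                dataset_label: str = "") -> MMIRanking:
    """Rank every non-target variable by MMI with ``target``, descending.

    Ties are broken lexicographically by variable name, so the ranking is
    deterministic.
    """
    if target not in dds.var_names:
        raise KeyError(f"target {target!r} not in dataset")
    tcol = dds.column(target)
    tar = dds.arity(target)
    entries = []
    for name in dds.var_names:
        if name == target:
            continue
        mi = plugin_mi(crosstab(dds.column(name), tcol, dds.arity(name), tar))
        entries.append((name, mi))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return MMIRanking(dataset_label=dataset_label, target=target,
                      entries=entries, n_samples=dds.n_samples)


def select_top_k(ranking: MMIRanking, k: int) -> list[str]:
    """First ``k`` variable names of the ranking."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranking.entries):
        raise ValueError(f"k={k} exceeds ranking size {len(ranking.entries)}")
    return ranking.names[:k]


@dataclass
class MMICdf:
    """Right-continuous empirical CDF over a ranking's MMI values."""

    points: list[tuple[float, float]]  # (mmi value, CDF height), ascending
    positions: dict[str, float]        # variable -> CDF height at its value

    def lookup(self, variable: str) -> float:
        if variable not in self.positions:
            raise KeyError(f"variable {variable!r} not in ranking")
        return self.positions[variable]


def mmi_cdf(ranking: MMIRanking) -> MMICdf:
    """Empirical CDF of the MMI values with per-variable position lookup."""
    if not ranking.entries:
        raise ValueError("empty ranking")
    vals = np.sort(ranking.values)
    n = len(vals)
    uniq, idx = np.unique(vals, return_index=True)
    # CDF at v = fraction of entries <= v (right-continuous)
    counts_le = np.searchsorted(vals, uniq, side="right")
    points = [(float(v), float(c / n)) for v, c in zip(uniq, counts_le)]
    heights = dict(points)
    positions = {name: heights[float(v)] for name, v in ranking.entries}
    return MMICdf(points=points, positions=positions)


def export_ranking(ranking: MMIRanking, path) -> None:
    """TSV export: rank, variable, mmi_bits, cdf_position."""
    cdf = mmi_cdf(ranking)
    with open(path, "w") as fh:
        fh.write("rank\tvariable\tmmi_bits\tcdf_position\n")
        for i, (name, v) in enumerate(ranking.entries, start=1):
            fh.write(f"{i}\t{name}\t{v:.6f}\t{cdf.lookup(name):.6f}\n")
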