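"""Cross-dataset similarity of MMI rankings.

Two cohorts' MMI-with-diagnosis rankings are compared over their shared
transcript universe G: at each percentile cutoff p the sets
``{g : MMI(g) > x_p}`` (strict inequality, x_p the p-th percentile of each
cohort's MMI distribution) are intersected, their Jaccard index computed,
and the overlap's significance assessed with the hypergeometric upper
tail — with set sizes fixed, "Jaccard at least as large as observed" is
equivalent to "overlap at least t_obs".
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import hypergeom

from .mmi import MMIRanking


def threshold_set(ranking: MMIRanking, p: float) -> set[str]:
    """Variables whose MMI strictly exceeds the p-th percentile value.

    Percentiles use the linear-interpolation convention; p in [0, 100).
    """
    if not ranking.entries:
        raise ValueError("empty ranking")
    if not (0 <= p < 100):
        raise ValueError("percentile must be in [0, 100)")
    x_p = float(np.percentile(ranking.values, p))
    return {name for name, v in ranking.entries if v > x_p}


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; defined as 0.0 when both sets are empty."""
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_pvalue(universe: int, m: int, n: int, t_obs: int,
                   log10: bool = False) -> float:
    """P(overlap >= t_obs) for two random subsets of sizes m, n drawn from G.

    Upper tail of Hypergeometric(universe, m, n).  With ``log10=True`` the
    base-10 log p-value is returned (computed in log space, safe for
    extreme tails).
    """
    if min(universe, m, n, t_obs) < 0 or m > universe or n > universe:
        raise ValueError("infeasible (universe, m, n, t_obs)")
    if t_obs > min(m, n):
        raise ValueError("t_obs cannot exceed min(m, n)")
    rv = hypergeom(universe, m, n)
    if log10:
        if t_obs == 0:
            return 0.0
        return float(rv.logsf(t_obs - 1) / np.log(10))
    if t_obs == 0:
        return 1.0
    return float(min(1.0, rv.sf(t_obs - 1)))


@dataclass
class SimilarityPoint:
    percentile: float
    threshold_a: float
    threshold_b: float
    size_a: int
    size_b: int
    overlap: int
    jaccard: float
    p_value: float
    log10_p: float


@dataclass
class SimilarityCurve:
    """Jaccard overlap and hypergeometric significance vs percentile cutoff."""

    label_a: str
    label_b: str
    universe_size: int
    points: list[SimilarityPoint]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("p\tx_a\tx_b\tsize_a\tsize_b\toverlap\tjaccard"
                     "\tp_value\tlog10_p\n")
            for pt in self.points:
                fh.write(
                    f"{pt.percentile:g}\t{pt.threshold_a:.6f}\t{pt.threshold_b:.6f}"
                    f"\t{pt.size_a}\t{pt.size_b}\t{pt.overlap}"
                    f"\t{pt.jaccard:.6f}\t{pt.p_value:.6g}\t{pt.log10_p:.4f}\n"
                )

    def to_json(self) -> str:
        return json.dumps({
            "label_a": self.label_a,
            "label_b": self.label_b,
            "universe_size": self.universe_size,
            "points": [asdict(p) for p in self.points],
        }, indent=2)


DEFAULT_GRID = tuple(range(0, 100, 5))


def similarity_curve(rank_a: MMIRanking, rank_b: MMIRanking,
                     percentiles=DEFAULT_GRID) -> SimilarityCurve:
    """Similarity curve of two rankings over their shared transcript universe."""
    universe = set(rank_a.names) & set(rank_b.names)
    if not universe:
        raise ValueError("empty shared universe")
    dropped = (len(rank_a.names) - len(universe), len(rank_b.names) - len(universe))
    if any(dropped):
        import logging
        logging.getLogger(__name__).warning(
            "restricting to shared universe of %d labels (dropped %d / %d)",
            len(universe), *dropped)
    ra = rank_a.restrict(universe)
    rb = rank_b.restrict(universe)
    points = []
    for p in percentiles:
        xa = float(np.percentile(ra.values, p))
        xb = float(np.percentile(rb.values, p))
        sa = threshold_set(ra, p)
        sb = threshold_set(rb, p)
        t = len(sa & sb)
        ji = jaccard(sa, sb)
        if sa or sb:
            pv = overlap_pvalue(len(universe), len(sa), len(sb), t)
            lp = overlap_pvalue(len(universe), len(sa), len(sb), t, log10=True)
        else:
            pv, lp = 1.0, 0.0
        points.append(SimilarityPoint(
            percentile=float(p), threshold_a=xa, threshold_b=xb,
            size_a=len(sa), size_b=len(sb), overlap=t,
            jaccard=ji, p_value=pv, log10_p=lp,
        ))
    return SimilarityCurve(label_a=rank_a.dataset_label or "A",
                           label_b=rank_b.dataset_label or "B",
                           universe_size=len(universe), points=points)
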