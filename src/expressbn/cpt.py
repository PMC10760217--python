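"""Conditional-probability trees of diagnosis risk and 2x2 odds-ratio stats.

A two-level CPT stratifies P(DX=1) first by carrier status (APOE_Genetic)
and then by a transcript's expression bin, exposing the raw counts at every
node.  Risk contrasts between two leaves are summarized as a 2x2 odds
ratio with a Wald 95% confidence interval on the log scale and a two-sided
normal p-value.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .discretize import DiscretizedDataset

Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class OddsRatioResult:
    """Wald odds ratio for a 2x2 table [[a, b], [c, d]].

    Rows are exposure (exposed / unexposed), columns outcome (case /
    control): or = (a d)/(b c).  The 95% CI is log-symmetric about the OR.
    """

    table: list[list[int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "wald"
    haldane: bool = False  # True when the 0.5 zero-cell correction was applied


def odds_ratio(table) -> OddsRatioResult:
    """Odds ratio with Wald 95% CI and two-sided p from a 2x2 count table.

    A single zero cell triggers the Haldane–Anscombe correction (0.5 added
    to every cell, flagged in the result); two zero cells in the same row
    or column leave the OR undefined and raise.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be nonnegative")
    a, b = t[0]
    c, d = t[1]
    if (a == 0 and b == 0) or (c == 0 and d == 0) or \
       (a == 0 and c == 0) or (b == 0 and d == 0):
        raise ValueError("odds ratio undefined: a full row or column is zero")
    haldane = bool((t == 0).any())
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - Z95 * se)
    ci_high = math.exp(log_or + Z95 * se)
    p = float(min(1.0, 2.0 * norm.sf(abs(log_or) / se)))
    return OddsRatioResult(
        table=[[int(v) for v in row] for row in np.asarray(table)],
        odds_ratio=float(or_), ci_low=float(ci_low), ci_high=float(ci_high),
        p_value=p, haldane=haldane,
    )


@dataclass
class CPTLeaf:
    layer1_value: int
    bin: int
    n: int
    n_case: int
    p: float | None  # None for empty strata (honest: no 0-imputation)


@dataclass
class CPTStratum:
    layer1_value: int
    n: int
    n_case: int
    p: float | None
    leaves: list[CPTLeaf]


@dataclass
class ConditionalProbabilityTree:
    """Two-level tree of P(target=1) by layer1 value then layer2 bin."""

    target: str
    layer1: str
    layer2: str
    n: int
    n_case: int
    p_marginal: float
    strata: list[CPTStratum]
    leaf_order: list[tuple[int, int]] = field(default_factory=list)

    def leaf(self, layer1_value: int, bin: int) -> CPTLeaf:
        for s in self.strata:
            if s.layer1_value == layer1_value:
                for lf in s.leaves:
                    if lf.bin == bin:
                        return lf
        raise KeyError(f"no leaf ({layer1_value}, {bin})")

    def to_json(self, contrasts: list | None = None) -> str:
        doc = {
            "target": self.target,
            "layer1": self.layer1,
            "layer2": self.layer2,
            "root": {"n": self.n, "n_case": self.n_case, "p": self.p_marginal},
            "strata": [
                {
                    "layer1_value": s.layer1_value,
                    "n": s.n, "n_case": s.n_case, "p": s.p,
                    "leaves": [
                        {"bin": lf.bin, "n": lf.n, "n_case": lf.n_case, "p": lf.p}
                        for lf in s.leaves
                    ],
                }
                for s in self.strata
            ],
            "leaf_order": [list(t) for t in self.leaf_order],
            "contrasts": [asdict(c) if hasattr(c, "__dataclass_fields__") else c
                          for c in (contrasts or [])],
        }
        return json.dumps(doc, indent=2)


def build_cpt(dds: DiscretizedDataset, target: str = "DX",
              layer1: str = "APOE_Genetic", layer2: str = "") -> ConditionalProbabilityTree:
    """Cross-tabulate a two-level CPT of ``target`` risk.

    Counts are exact integer arithmetic so the tree satisfies count
    consistency and the law of total probability identically.  Empty
    strata keep count 0 with probability None.
    """
    y = dds.column(target)
    if dds.arity(target) != 2 or not np.isin(y, (0, 1)).all():
        raise ValueError(f"target {target!r} must be binary")
    l1 = dds.column(layer1)
    l2 = dds.column(layer2)
    r1, r2 = dds.arity(layer1), dds.arity(layer2)

    n = len(y)
    n_case = int(y.sum())
    strata = []
    order: list[tuple[float, int, int]] = []
    for a in range(r1):
        in_a = l1 == a
        na, ca = int(in_a.sum()), int(y[in_a].sum())
        leaves = []
        for bv in range(r2):
            in_leaf = in_a & (l2 == bv)
            nl, cl = int(in_leaf.sum()), int(y[in_leaf].sum())
            p = cl / nl if nl else None
            leaves.append(CPTLeaf(layer1_value=a, bin=bv, n=nl, n_case=cl, p=p))
            if p is not None:
                order.append((p, a, bv))
        strata.append(CPTStratum(layer1_value=a, n=na, n_case=ca,
                                 p=(ca / na if na else None), leaves=leaves))
    order.sort()
    return ConditionalProbabilityTree(
        target=target, layer1=layer1, layer2=layer2,
        n=n, n_case=n_case, p_marginal=n_case / n,
        strata=strata,
        leaf_order=[(a, bv) for _, a, bv in order],
    )


@dataclass
class RiskContrast:
    """Odds ratio between two CPT leaves plus the relative risk difference."""

    stratum_a: tuple[int, int]
    stratum_b: tuple[int, int]
    result: OddsRatioResult
    p_a: float
    p_b: float
    relative_difference: float  # (p_a - p_b) / p_b


def risk_contrast(cpt: ConditionalProbabilityTree,
                  stratum_a: tuple[int, int],
                  stratum_b: tuple[int, int]) -> RiskContrast:
    """2x2 contrast of case odds between two (layer1 value, bin) leaves."""
    la = cpt.leaf(*stratum_a)
    lb = cpt.leaf(*stratum_b)
    if la.n == 0 or lb.n == 0:
        raise ValueError("cannot contrast an empty stratum")
    table = [[la.n_case, la.n - la.n_case],
             [lb.n_case, lb.n - lb.n_case]]
    res = odds_ratio(table)
    return RiskContrast(
        stratum_a=stratum_a, stratum_b=stratum_b, result=res,
        p_a=la.p, p_b=lb.p,
        relative_difference=(la.p - lb.p) / lb.p if lb.p else float("inf"),
    )
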