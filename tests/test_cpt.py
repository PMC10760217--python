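"""CPT construction, odds ratios and risk contrasts."""
import json

import numpy as np
import pytest

import expressbn as xbn

from conftest import dds_from_codes


def _cpt_dds(n=240, seed=0):
    """Construct codes with exact, hand-countable strata."""
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 2, n)
    bins = rng.integers(0, 3, n)
    dx = rng.integers(0, 2, n)
    return dds_from_codes({"DX": dx, "APOE_Genetic": geno, "g": bins},
                          {"DX": 2, "APOE_Genetic": 2, "g": 3})


def test_cpt_counts_and_total_probability():
    dds = _cpt_dds()
    cpt = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    assert cpt.n == dds.n_samples
    assert cpt.p_marginal == pytest.approx(cpt.n_case / cpt.n)
    for s in cpt.strata:
        assert s.n == sum(leaf.n for leaf in s.leaves)
        assert s.n_case == sum(leaf.n_case for leaf in s.leaves)
        if s.n:
            # law of total probability holds exactly in count arithmetic
            mix = sum(leaf.n * (leaf.p or 0.0) for leaf in s.leaves) / s.n
            assert mix == pytest.approx(s.p, abs=1e-12)
    assert sum(s.n for s in cpt.strata) == cpt.n


def test_cpt_independent_target_leaves_match_marginal():
    # construct exact independence: every (geno, bin) cell holds 5 cases, 5 controls
    rows = []
    for geno in (0, 1):
        for b in (0, 1, 2):
            for dx in (0, 1):
                rows += [(dx, geno, b)] * 5
    dx, geno, bins = (np.array(v) for v in zip(*rows))
    dds = dds_from_codes({"DX": dx, "APOE_Genetic": geno, "g": bins},
                         {"DX": 2, "APOE_Genetic": 2, "g": 3})
    cpt = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    for s in cpt.strata:
        for leaf in s.leaves:
            assert leaf.p == pytest.approx(cpt.p_marginal)


def test_cpt_stratum_probability_by_hand():
    # layer1=0 stratum: 8 samples with 2 cases -> P(DX=1|layer1=0) = 0.25
    dx = np.array([1, 1, 0, 0, 0, 0, 0, 0] + [1] * 6 + [0] * 6)
    geno = np.array([0] * 8 + [1] * 12)
    bins = np.tile([0, 1, 2, 0], 5)
    dds = dds_from_codes({"DX": dx, "APOE_Genetic": geno, "g": bins},
                         {"DX": 2, "APOE_Genetic": 2, "g": 3})
    cpt = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    assert cpt.strata[0].n == 8
    assert cpt.strata[0].p == pytest.approx(0.25)


def test_cpt_leaf_order_ascending_and_json_nulls():
    dds = _cpt_dds(seed=3)
    cpt = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    probs = [cpt.leaf(a, b).p for a, b in cpt.leaf_order]
    assert probs == sorted(probs)
    doc = json.loads(cpt.to_json())
    assert doc["root"]["n"] == cpt.n
    # empty strata serialize probability as null, never 0
    empty = dds_from_codes(
        {"DX": np.array([0, 1, 0, 1]), "APOE_Genetic": np.array([0, 0, 0, 0]),
         "g": np.array([0, 0, 1, 2])},
        {"DX": 2, "APOE_Genetic": 2, "g": 3})
    doc = json.loads(xbn.build_cpt(empty, "DX", "APOE_Genetic", "g").to_json())
    carrier = [s for s in doc["strata"] if s["layer1_value"] == 1][0]
    assert carrier["n"] == 0 and carrier["p"] is None


def test_cpt_requires_binary_target():
    dds = _cpt_dds()
    with pytest.raises(ValueError):
        xbn.build_cpt(dds, "g", "APOE_Genetic", "DX")


def test_cpt_invariant_to_sample_permutation():
    dds = _cpt_dds(seed=7)
    perm = np.random.default_rng(1).permutation(dds.n_samples)
    shuffled = dds_from_codes(
        {v: dds.column(v)[perm] for v in dds.var_names},
        {v: dds.arity(v) for v in dds.var_names})
    a = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    b = xbn.build_cpt(shuffled, "DX", "APOE_Genetic", "g")
    assert a.to_json() == b.to_json()


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def test_odds_ratio_symmetric_table():
    r = xbn.odds_ratio([[10, 10], [10, 10]])
    assert r.odds_ratio == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high
    assert r.p_value == pytest.approx(1.0)


def test_odds_ratio_hand_computation():
    r = xbn.odds_ratio([[10, 20], [5, 40]])
    assert r.odds_ratio == pytest.approx(4.0)
    assert r.ci_low == pytest.approx(1.2036, abs=2e-3)
    assert r.ci_high == pytest.approx(13.29, abs=0.02)
    assert r.p_value == pytest.approx(0.0236, abs=5e-4)
    assert not r.haldane


def test_odds_ratio_log_symmetry_invariant():
    rng = np.random.default_rng(10)
    for _ in range(50):
        t = rng.integers(1, 60, size=(2, 2))
        r = xbn.odds_ratio(t)
        assert np.log(r.odds_ratio) - np.log(r.ci_low) == pytest.approx(
            np.log(r.ci_high) - np.log(r.odds_ratio), abs=1e-9)
        assert r.ci_low <= r.odds_ratio <= r.ci_high


def test_odds_ratio_zero_cell_haldane_and_errors():
    r = xbn.odds_ratio([[0, 10], [5, 5]])
    assert r.haldane and r.odds_ratio > 0
    with pytest.raises(ValueError):
        xbn.odds_ratio([[0, 0], [5, 5]])
    with pytest.raises(ValueError):
        xbn.odds_ratio([[0, 10], [0, 5]])


def test_printed_interval_is_wald_log_symmetric():
    """The published OR triple satisfies the log-midpoint identity to 4 dp,
    which is what justifies the Wald method choice."""
    or_, lo, hi = 2.2810, 1.2217, 4.2588
    midpoint = 0.5 * (np.log(lo) + np.log(hi))
    assert midpoint == pytest.approx(np.log(or_), abs=5e-5)


def test_risk_contrast_count_arithmetic_and_antisymmetry():
    # stratum probabilities 0.5 (20/40) and 0.25 (10/40)
    dx = np.array([1] * 20 + [0] * 20 + [1] * 10 + [0] * 30)
    geno = np.ones(80, dtype=int)
    bins = np.array([2] * 40 + [0] * 40)
    dds = dds_from_codes({"DX": dx, "APOE_Genetic": geno, "g": bins},
                         {"DX": 2, "APOE_Genetic": 2, "g": 3})
    cpt = xbn.build_cpt(dds, "DX", "APOE_Genetic", "g")
    rc = xbn.risk_contrast(cpt, (1, 2), (1, 0))
    assert rc.result.odds_ratio == pytest.approx(3.0)
    assert rc.p_a == pytest.approx(0.5) and rc.p_b == pytest.approx(0.25)
    swapped = xbn.risk_contrast(cpt, (1, 0), (1, 2))
    assert swapped.result.odds_ratio == pytest.approx(1 / 3.0)
    assert swapped.result.ci_low == pytest.approx(1 / rc.result.ci_high)
    identical = xbn.risk_contrast(cpt, (1, 2), (1, 2))
    assert identical.result.odds_ratio == pytest.approx(1.0)
    with pytest.raises(ValueError):
        xbn.risk_contrast(cpt, (0, 0), (1, 0))  # empty stratum
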