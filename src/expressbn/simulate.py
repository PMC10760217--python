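"""Synthetic case/control expression cohorts with planted network structure.

Generates datasets emulating the statistical shape of the two brain-bank
cohorts the pipeline is designed for: a few hundred samples, a binary risk
genotype with configurable carrier frequency linked to diagnosis through a
logistic model, a handful of signal transcripts whose means shift with
diagnosis and/or genotype (Gaussian class-shift, effect sizes in
within-group sigma units), transcript-to-transcript chains that create
transitive dependencies, and thousands of null transcripts.  The true
generating DAG and the implied Markov blanket of DX are returned as ground
truth for recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .io import ExpressionDataset, write_expression_table, write_phenotype_table

ROLES = ("dx_signal", "genotype_signal", "joint_signal", "chain_child", "null")

GENOTYPE = "APOE_Genetic"
TARGET = "DX"


@dataclass(frozen=True)
class SignalSpec:
    """One planted transcript: its role, effect size (sigma units), parent."""

    name: str
    role: str
    effect_size: float = 0.0
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "chain_child" and not self.parent:
            raise ValueError("chain_child needs a parent transcript")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 475
    n_transcripts: int = 200
    case_fraction: float = 218 / 475
    genotype_freq: float = 206 / 475
    genotype_or: float = 7.917          # odds ratio genotype -> DX
    signal_spec: list[SignalSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    chain_corr: float = 0.8             # target parent-child correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.case_fraction < 1 and 0 < self.genotype_freq < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.genotype_or <= 0:
            raise ValueError("genotype_or must be positive")
        names = [s.name for s in self.signal_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate signal transcript names")
        by_name = {s.name: s for s in self.signal_spec}
        for s in self.signal_spec:
            if s.role == "chain_child":
                p = by_name.get(s.parent)
                if p is None or p.role in ("null",):
                    raise ValueError(
                        f"chain_child {s.name!r} must hang off a non-null transcript")
        if len(self.signal_spec) > self.n_transcripts:
            raise ValueError("more signals than transcripts")


@dataclass
class GroundTruth:
    """True generating DAG and the Markov blanket of DX it implies."""

    dag: list[tuple[str, str]]
    expected_mb_of_dx: list[str]
    config: GeneratorConfig

    def to_json(self) -> str:
        doc = {
            "dag": [list(e) for e in self.dag],
            "expected_mb_of_dx": self.expected_mb_of_dx,
            "config": {**asdict(self.config),
                       "signal_spec": [asdict(s) for s in self.config.signal_spec]},
        }
        return json.dumps(doc, indent=2)


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def _solve_base_logit(cfg: GeneratorConfig) -> float:
    """Intercept of the genotype->DX logistic link hitting the case fraction.

    Solves (1-f) sigma(b) + f sigma(b + ln OR) = case_fraction by bisection.
    """
    f = cfg.genotype_freq
    lor = np.log(cfg.genotype_or)

    def marginal(b: float) -> float:
        return (1 - f) * _sigmoid(b) + f * _sigmoid(b + lor) - cfg.case_fraction

    lo, hi = -40.0, 40.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ValueError("infeasible (case_fraction, genotype_or, genotype_freq)")
    return float(brentq(marginal, lo, hi, xtol=1e-12))


def true_dag(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = [(GENOTYPE, TARGET)]
    for s in cfg.signal_spec:
        if s.role == "dx_signal":
            edges.append((TARGET, s.name))
        elif s.role == "genotype_signal":
            edges.append((GENOTYPE, s.name))
        elif s.role == "joint_signal":
            edges.append((TARGET, s.name))
            edges.append((GENOTYPE, s.name))
        elif s.role == "chain_child":
            edges.append((s.parent, s.name))
    return edges


def expected_mb(cfg: GeneratorConfig) -> set[str]:
    """Markov blanket of DX in the true DAG: parent genotype, signal
    children, and co-parents of joint signals (the genotype again)."""
    mb = {GENOTYPE} if cfg.genotype_or != 1.0 else set()
    for s in cfg.signal_spec:
        if s.role in ("dx_signal", "joint_signal") and s.effect_size != 0.0:
            mb.add(s.name)
            if s.role == "joint_signal":
                mb.add(GENOTYPE)
    return mb


def _null_names(cfg: GeneratorConfig) -> list[str]:
    n_null = cfg.n_transcripts - len(cfg.signal_spec)
    width = max(4, len(str(cfg.n_transcripts)))
    return [f"T{i:0{width}d}" for i in range(1, n_null + 1)]


def generate(cfg: GeneratorConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one synthetic cohort; bit-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sigma = cfg.noise_sd

    genotype = (rng.random(n) < cfg.genotype_freq).astype(int)
    base = _solve_base_logit(cfg)
    p_dx = 1.0 / (1.0 + np.exp(-(base + np.log(cfg.genotype_or) * genotype)))
    dx = (rng.random(n) < p_dx).astype(int)

    columns: dict[str, np.ndarray] = {}
    # signals first (chain parents before children by ordering the spec),
    # then nulls; noise drawn in fixed declaration order for reproducibility
    pending = list(cfg.signal_spec)
    done: set[str] = set()
    while pending:
        progressed = False
        for s in list(pending):
            if s.role == "chain_child" and s.parent not in done:
                continue
            noise = rng.normal(0.0, sigma, n)
            if s.role == "dx_signal":
                col = s.effect_size * sigma * dx + noise
            elif s.role == "genotype_signal":
                col = s.effect_size * sigma * genotype + noise
            elif s.role == "joint_signal":
                col = s.effect_size * sigma * (dx + genotype) + noise
            elif s.role == "chain_child":
                parent = columns[s.parent]
                rho = cfg.chain_corr
                beta = rho * sigma / (parent.std() * np.sqrt(1 - rho ** 2))
                col = beta * parent + noise
            else:  # explicit null in the spec
                col = noise
            columns[s.name] = col
            done.add(s.name)
            pending.remove(s)
            progressed = True
        if not progressed:
            raise ValueError("unresolvable chain_child parent ordering")
    null_names = _null_names(cfg)
    for name in null_names:
        columns[name] = rng.normal(0.0, sigma, n)

    transcript_ids = [s.name for s in cfg.signal_spec] + null_names
    values = np.column_stack([columns[t] for t in transcript_ids])
    ds = ExpressionDataset(
        sample_ids=[f"S{i:05d}" for i in range(1, n + 1)],
        transcript_ids=transcript_ids,
        values=values,
        phenotypes={TARGET: dx, GENOTYPE: genotype},
    )
    truth = GroundTruth(dag=true_dag(cfg),
                        expected_mb_of_dx=sorted(expected_mb(cfg)),
                        config=cfg)
    return ds, truth


# ---------------------------------------------------------------------------
# presets emulating the two cohorts' shapes
# ---------------------------------------------------------------------------

def default_signals(effect_size: float = 1.5) -> list[SignalSpec]:
    """Three diagnosis-shifted hits, one genotype-shifted transcript, and a
    chain child.

    The hits emulate the blanket composition the pipeline is meant to
    recover: transcripts whose expression shifts with diagnosis, alongside
    the genotype node itself.  The genotype-shifted transcript and the
    chain child (hanging off the first hit) plant transitive dependencies
    the learner should route through their parents rather than wire to DX
    directly.  A joint diagnosis+genotype child is deliberately not
    planted here: an additive joint child induces explaining-away
    cancellation of the direct genotype-diagnosis dependence (see the
    methods note); the ``joint_signal`` role stays available for
    sensitivity experiments.
    """
    return [
        SignalSpec("SIG_DX1", "dx_signal", effect_size),
        SignalSpec("SIG_DX2", "dx_signal", effect_size),
        SignalSpec("SIG_DX3", "dx_signal", effect_size),
        SignalSpec("SIG_APOE", "genotype_signal", effect_size),
        SignalSpec("SIG_CHAIN", "chain_child", parent="SIG_DX1"),
    ]


def kronos_like(seed: int = 0, n_transcripts: int = 200,
                effect_size: float = 1.5) -> GeneratorConfig:
    """475 samples, 218 cases, ~43% carriers, genotype OR from the printed
    carrier-by-diagnosis counts (150*201)/(56*68)."""
    return GeneratorConfig(
        n_samples=475, n_transcripts=n_transcripts,
        case_fraction=218 / 475, genotype_freq=206 / 475,
        genotype_or=(150 * 201) / (56 * 68),
        signal_spec=default_signals(effect_size), seed=seed,
    )


def rush_like(seed: int = 0, n_transcripts: int = 200,
              effect_size: float = 1.5) -> GeneratorConfig:
    """306 samples, 144 cases, ~26% carriers, genotype OR (57*140)/(22*87)."""
    return GeneratorConfig(
        n_samples=306, n_transcripts=n_transcripts,
        case_fraction=144 / 306, genotype_freq=79 / 306,
        genotype_or=(57 * 140) / (22 * 87),
        signal_spec=default_signals(effect_size), seed=seed,
    )


def null_config(seed: int = 0, n_samples: int = 475, n_transcripts: int = 200,
                genotype_or: float = 1.0) -> GeneratorConfig:
    """All-null cohort (no signal transcripts); genotype optionally unlinked."""
    return GeneratorConfig(
        n_samples=n_samples, n_transcripts=n_transcripts,
        case_fraction=218 / 475, genotype_freq=206 / 475,
        genotype_or=genotype_or, signal_spec=[], seed=seed,
    )


PRESETS = {"kronos-like": kronos_like, "rush-like": rush_like}


def write_run(ds: ExpressionDataset, truth: GroundTruth, out_dir) -> None:
    """Write expression.tsv, phenotypes.tsv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(ds, out / "expression.tsv")
    write_phenotype_table(ds, out / "phenotypes.tsv")
    (out / "ground_truth.json").write_text(truth.to_json())
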