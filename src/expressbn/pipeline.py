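"""End-to-end pipeline orchestration.

Runs the full analysis on one cohort — discretize, MMI-rank, pre-select
top-k transcripts (always keeping the phenotype nodes), learn the network,
extract the Markov view of DX, and build CPTs for the neighborhood hits —
writing every artifact plus a manifest of hyper-parameters and seeds into
a run directory.  Also provides the genotype-split validation runs and the
cross-cohort similarity comparison.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .io import (ExpressionDataset, attach_phenotypes, load_expression_table,
                 write_network, REQUIRED_PHENOTYPES)
from .discretize import discretize_dataset, export_bin_edges
from .mmi import rank_by_mmi, mmi_cdf, export_ranking, MMIRanking
from .bayesnet import BayesianNetwork, learn_structure, markov_view, dependency_path
from .cpt import build_cpt, risk_contrast
from .similarity import similarity_curve, DEFAULT_GRID

log = logging.getLogger(__name__)

TARGET = "DX"
GENOTYPE = "APOE_Genetic"
MIN_GROUP_SIZE = 30


@dataclass
class PipelineConfig:
    """Hyper-parameters of one pipeline run; defaults are the study settings
    (2000 transcripts pre-selected, 3 bins, 20 restarts)."""

    expression_path: str | None = None
    phenotype_path: str | None = None
    label: str = "dataset"
    k_top: int = 2000
    n_bins: int = 3
    restarts: int = 20
    alpha: float = 0.01
    seed: int = 0
    split_by_genotype: bool = False
    percentile_grid: list = field(default_factory=lambda: list(DEFAULT_GRID))

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    ranking: MMIRanking
    network: BayesianNetwork
    view: "object"
    cpt_transcripts: list[str]


def _load(cfg: PipelineConfig) -> ExpressionDataset:
    if cfg.expression_path is None or cfg.phenotype_path is None:
        raise ValueError("config lacks input paths and no dataset was supplied")
    ds = load_expression_table(cfg.expression_path)
    return attach_phenotypes(ds, cfg.phenotype_path)


def _analyze(ds: ExpressionDataset, cfg: PipelineConfig):
    """Shared core: discretize -> rank -> select -> learn -> markov view."""
    dds = discretize_dataset(ds, k=cfg.n_bins)
    ranking = rank_by_mmi(dds, TARGET, dataset_label=cfg.label)
    transcripts = set(ds.transcript_ids)
    top = [n for n in ranking.names if n in transcripts][:cfg.k_top]
    phenos = [c for c in dds.var_names if c not in transcripts and c != TARGET]
    selected = top + phenos + [TARGET]
    bn = learn_structure(dds.subset(selected), restarts=cfg.restarts,
                         seed=cfg.seed, alpha=cfg.alpha)
    view = markov_view(bn, TARGET)
    return dds, ranking, bn, view


def _write_markov_json(view, bn, dds, path: Path) -> None:
    paths = {}
    for member in sorted(view.blanket):
        p = dependency_path(bn, TARGET, member)
        if p is not None:
            paths[member] = p
    doc = {
        "target": view.target,
        "neighborhood": {k: round(v, 6)
                         for k, v in sorted(view.neighborhood.items())},
        "blanket": sorted(view.blanket),
        "induced_edges": [list(e) for e in sorted(view.induced_edges)],
        "dependency_paths": paths,
    }
    path.write_text(json.dumps(doc, indent=2))


def run_pipeline(cfg: PipelineConfig, out_dir,
                 dataset: ExpressionDataset | None = None) -> PipelineResult:
    """Execute the full single-cohort pipeline into ``out_dir``.

    Any stage failure leaves partial outputs plus a FAILED marker naming
    the stage.  Outputs are byte-identical across reruns with the same
    config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        ds = dataset if dataset is not None else _load(cfg)
        if TARGET not in ds.phenotypes:
            raise ValueError(f"phenotype column {TARGET!r} missing")
        ds.validate()

        stage = "discretize+rank+learn"
        dds, ranking, bn, view = _analyze(ds, cfg)

        stage = "write"
        export_ranking(ranking, out / "ranking.tsv")
        export_bin_edges(dds, out / "bin_edges.tsv")
        write_network(bn, out / "network.graphml", format="graphml")
        write_network(bn, out / "network_edges.tsv", format="edge_tsv")
        _write_markov_json(view, bn, dds, out / "markov_blanket.json")

        stage = "cpt"
        cpt_transcripts: list[str] = []
        if GENOTYPE in dds.var_names:
            hits = sorted(
                (n for n in view.neighborhood if n in set(ds.transcript_ids)),
                key=lambda n: (-view.neighborhood[n], n))
            for name in hits:
                cpt = build_cpt(dds, TARGET, GENOTYPE, name)
                contrasts = []
                hi, lo = cfg.n_bins - 1, 0  # drop the medium bin
                for a in range(dds.arity(GENOTYPE)):
                    try:
                        rc = risk_contrast(cpt, (a, hi), (a, lo))
                    except ValueError:
                        continue
                    contrasts.append({
                        "layer1_value": a, "high_bin": hi, "low_bin": lo,
                        "odds_ratio": rc.result.odds_ratio,
                        "ci_low": rc.result.ci_low,
                        "ci_high": rc.result.ci_high,
                        "p_value": rc.result.p_value,
                        "haldane": rc.result.haldane,
                        "p_high": rc.p_a, "p_low": rc.p_b,
                        "relative_difference": rc.relative_difference,
                    })
                (out / f"cpt_{name}.json").write_text(cpt.to_json(contrasts))
                cpt_transcripts.append(name)
        else:
            log.info("no %s column; skipping CPT stage", GENOTYPE)

        stage = "manifest"
        manifest = {
            "package": "expressbn",
            "version": __version__,
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "n_samples": ds.n_samples,
            "n_transcripts": ds.n_transcripts,
            "n_selected": len(bn.nodes),
            "total_score_bits": round(bn.total_score, 6),
            "markov_blanket": sorted(view.blanket),
            "cpt_transcripts": cpt_transcripts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}\n{err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return PipelineResult(out_dir=out, ranking=ranking, network=bn,
                          view=view, cpt_transcripts=cpt_transcripts)


def run_split(cfg: PipelineConfig, out_dir,
              dataset: ExpressionDataset | None = None) -> dict[int, PipelineResult]:
    """Run the pipeline separately in carriers and non-carriers.

    The genotype column is excluded within each group (it is constant
    there); rankings and structures are re-learned from scratch per group.
    """
    out = Path(out_dir)
    ds = dataset if dataset is not None else _load(cfg)
    ds.validate(require_phenotypes=True)
    geno = ds.phenotypes[GENOTYPE]
    results: dict[int, PipelineResult] = {}
    for value, tag in ((0, "apoe_neg"), (1, "apoe_pos")):
        mask = geno == value
        if mask.sum() < MIN_GROUP_SIZE:
            raise ValueError(
                f"group {tag} has {int(mask.sum())} samples "
                f"(< {MIN_GROUP_SIZE}); cannot run split analysis")
        sub = ds.subset_samples(mask)
        sub.phenotypes = {c: v for c, v in sub.phenotypes.items() if c != GENOTYPE}
        sub_cfg = PipelineConfig(**{**asdict(cfg), "label": f"{cfg.label}_{tag}"})
        results[value] = run_pipeline(sub_cfg, out / tag, dataset=sub)
    return results


def genotype_tabulation(ds: ExpressionDataset) -> dict:
    """Carrier-by-diagnosis counts (the descriptive frequency comparison)."""
    dx = ds.phenotypes[TARGET]
    g = ds.phenotypes[GENOTYPE]
    return {
        "n": ds.n_samples,
        "carrier_freq": float(g.mean()),
        "counts": {
            "carrier_cases": int(((g == 1) & (dx == 1)).sum()),
            "carrier_controls": int(((g == 1) & (dx == 0)).sum()),
            "noncarrier_cases": int(((g == 0) & (dx == 1)).sum()),
            "noncarrier_controls": int(((g == 0) & (dx == 0)).sum()),
        },
    }


def run_compare(cfg_a: PipelineConfig, cfg_b: PipelineConfig, out_dir,
                dataset_a: ExpressionDataset | None = None,
                dataset_b: ExpressionDataset | None = None):
    """Cross-cohort similarity report.

    Emits the similarity curve (TSV + JSON), a rank-concordance table of
    the two Markov blankets, and the genotype-frequency tabulation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds_a = dataset_a if dataset_a is not None else _load(cfg_a)
    ds_b = dataset_b if dataset_b is not None else _load(cfg_b)
    _, rank_a, bn_a, view_a = _analyze(ds_a, cfg_a)
    _, rank_b, bn_b, view_b = _analyze(ds_b, cfg_b)

    ta = rank_a.restrict(set(ds_a.transcript_ids))
    tb = rank_b.restrict(set(ds_b.transcript_ids))
    curve = similarity_curve(ta, tb, percentiles=cfg_a.percentile_grid)
    curve.to_tsv(out / "similarity.tsv")
    (out / "similarity.json").write_text(curve.to_json())

    cdf_a, cdf_b = mmi_cdf(rank_a), mmi_cdf(rank_b)
    members = sorted(view_a.blanket | view_b.blanket)
    with open(out / "mb_concordance.tsv", "w") as fh:
        fh.write("variable\tin_mb_a\tin_mb_b\tcdf_a\tcdf_b\n")
        for m in members:
            ca = f"{cdf_a.lookup(m):.4f}" if m in cdf_a.positions else "NA"
            cb = f"{cdf_b.lookup(m):.4f}" if m in cdf_b.positions else "NA"
            fh.write(f"{m}\t{int(m in view_a.blanket)}\t{int(m in view_b.blanket)}"
                     f"\t{ca}\t{cb}\n")

    tab = {cfg_a.label: genotype_tabulation(ds_a),
           cfg_b.label: genotype_tabulation(ds_b)}
    (out / "genotype_frequencies.json").write_text(json.dumps(tab, indent=2))
    return curve
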