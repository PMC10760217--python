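"""Data model and file I/O.

In-memory containers for covariate-adjusted expression matrices with binary
phenotype columns (diagnosis ``DX`` and carrier status ``APOE_Genetic``),
plus readers/writers for delimited expression/phenotype tables and learned
networks (GraphML, DOT, edge TSV).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: tokens treated as missing values in expression tables (case-insensitive)
MISSING_TOKENS = {"", "na", "nan", "null", "n/a"}

REQUIRED_PHENOTYPES = ("DX", "APOE_Genetic")


class DataValidationError(ValueError):
    """Raised when an input table violates the data-model contract."""


@dataclass(frozen=True)
class VariableSpec:
    """Name, kind and (for discrete variables) arity of one variable."""

    name: str
    kind: str  # "continuous" or "discrete"
    arity: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "discrete":
            if self.arity is None or self.arity < 2:
                raise ValueError(
                    f"discrete variable {self.name!r} needs arity >= 2, got {self.arity}"
                )
        elif self.arity is not None:
            raise ValueError("continuous variables carry no arity")


@dataclass
class ExpressionDataset:
    """Samples x transcripts expression matrix plus discrete phenotype columns.

    ``values[i, j]`` is the (covariate-adjusted) expression of transcript
    ``transcript_ids[j]`` in sample ``sample_ids[i]``.  Phenotypes are
    integer-coded per-sample vectors; ``DX`` and ``APOE_Genetic`` must be
    binary when present.
    """

    sample_ids: list[str]
    transcript_ids: list[str]
    values: np.ndarray
    phenotypes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self, require_phenotypes: bool = False) -> None:
        n, m = self.values.shape
        if n != len(self.sample_ids):
            raise DataValidationError(
                f"values has {n} rows but {len(self.sample_ids)} sample ids"
            )
        if m != len(self.transcript_ids):
            raise DataValidationError(
                f"values has {m} columns but {len(self.transcript_ids)} transcript ids"
            )
        if len(set(self.sample_ids)) != n:
            raise DataValidationError("duplicate sample ids")
        if len(set(self.transcript_ids)) != m:
            raise DataValidationError("duplicate transcript ids")
        if np.isnan(self.values).any():
            raise DataValidationError("missing expression values after load")
        if require_phenotypes:
            for col in REQUIRED_PHENOTYPES:
                if col not in self.phenotypes:
                    raise DataValidationError(f"phenotype column {col!r} missing")
        for col, vec in self.phenotypes.items():
            if len(vec) != n:
                raise DataValidationError(f"phenotype {col!r} has wrong length")
            if col in REQUIRED_PHENOTYPES and not np.isin(vec, (0, 1)).all():
                raise DataValidationError(f"{col} must contain only 0/1 values")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def subset_samples(self, mask: np.ndarray) -> "ExpressionDataset":
        """New dataset keeping samples where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return ExpressionDataset(
            sample_ids=[s for s, keep in zip(self.sample_ids, mask) if keep],
            transcript_ids=list(self.transcript_ids),
            values=self.values[mask],
            phenotypes={c: v[mask].copy() for c, v in self.phenotypes.items()},
        )

    def equals(self, other: "ExpressionDataset", rtol: float = 1e-9) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.transcript_ids == other.transcript_ids
            and np.allclose(self.values, other.values, rtol=rtol)
            and set(self.phenotypes) == set(other.phenotypes)
            and all(
                np.array_equal(self.phenotypes[c], other.phenotypes[c])
                for c in self.phenotypes
            )
        )


# ---------------------------------------------------------------------------
# expression / phenotype tables
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def load_expression_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    missing_policy: str = "drop_sample",
) -> ExpressionDataset:
    """Read a delimited expression table into canonical orientation.

    The file must have one header row and a leading ID column; the body is
    numeric.  ``orientation`` states what the file's rows are; the returned
    dataset is always samples x transcripts.  Cells holding a recognised
    missing token are handled by ``missing_policy`` ("drop_sample" or
    "drop_transcript"); any other non-numeric cell is a parse error.
    """
    if orientation not in ("samples_as_rows", "transcripts_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if missing_policy not in ("drop_sample", "drop_transcript"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")

    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise DataValidationError(f"empty table: {path}")

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        tokens = raw[col].astype(str).str.strip()
        is_missing = tokens.str.lower().isin(MISSING_TOKENS)
        parsed = pd.to_numeric(tokens.mask(is_missing), errors="coerce")
        bad = parsed.isna() & ~is_missing
        if bad.any():
            row = raw.index[np.argmax(bad.to_numpy())]
            raise DataValidationError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{tokens[bad].iloc[0]!r}"
            )
        values[:, j] = parsed.to_numpy()

    row_ids = [str(i) for i in raw.index]
    col_ids = [str(c) for c in raw.columns]
    if orientation == "transcripts_as_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids

    if len(set(row_ids)) != len(row_ids):
        raise DataValidationError("duplicate sample ids in table")
    if len(set(col_ids)) != len(col_ids):
        raise DataValidationError("duplicate transcript ids in table")

    nan_mask = np.isnan(values)
    if nan_mask.any():
        if missing_policy == "drop_sample":
            keep = ~nan_mask.any(axis=1)
            dropped = [s for s, k in zip(row_ids, keep) if not k]
            log.warning("dropping %d sample(s) with missing values: %s",
                        len(dropped), ", ".join(dropped))
            values = values[keep]
            row_ids = [s for s, k in zip(row_ids, keep) if k]
        else:
            keep = ~nan_mask.any(axis=0)
            dropped = [t for t, k in zip(col_ids, keep) if not k]
            log.warning("dropping %d transcript(s) with missing values: %s",
                        len(dropped), ", ".join(dropped))
            values = values[:, keep]
            col_ids = [t for t, k in zip(col_ids, keep) if k]
        if values.size == 0:
            raise DataValidationError("no data left after missing-value filtering")

    return ExpressionDataset(sample_ids=row_ids, transcript_ids=col_ids,
                             values=values)


def attach_phenotypes(ds: ExpressionDataset, path: str | Path) -> ExpressionDataset:
    """Inner-join a phenotype table (sample_id, DX, APOE_Genetic, ...) onto ``ds``.

    Samples missing from the phenotype table are dropped with a warning.
    Extra integer-coded columns are preserved as additional discrete
    phenotypes; non-integer extras are dropped with a warning.
    """
    tab = pd.read_csv(path, sep=_sep_for(path))
    id_col = "sample_id" if "sample_id" in tab.columns else tab.columns[0]
    tab = tab.set_index(tab[id_col].astype(str)).drop(columns=[id_col])
    for col in REQUIRED_PHENOTYPES:
        if col not in tab.columns:
            raise DataValidationError(f"phenotype table lacks column {col!r}")

    keep_cols: dict[str, np.ndarray] = {}
    for col in tab.columns:
        parsed = pd.to_numeric(tab[col], errors="coerce")
        if parsed.isna().any() or not np.allclose(parsed, parsed.round()):
            if col in REQUIRED_PHENOTYPES:
                raise DataValidationError(f"{col} is not integer-coded")
            log.warning("dropping non-integer phenotype column %r", col)
            continue
        keep_cols[col] = parsed.round().astype(int).to_numpy()
    pheno = pd.DataFrame(keep_cols, index=tab.index)

    overlap = [s for s in ds.sample_ids if s in pheno.index]
    if not overlap:
        raise DataValidationError("no overlapping samples between expression and phenotypes")
    if len(overlap) < ds.n_samples:
        log.warning("dropping %d sample(s) absent from phenotype table",
                    ds.n_samples - len(overlap))
    mask = np.array([s in pheno.index for s in ds.sample_ids])
    out = ds.subset_samples(mask)
    pheno = pheno.loc[out.sample_ids]
    for col in REQUIRED_PHENOTYPES:
        if not pheno[col].isin((0, 1)).all():
            bad = pheno.loc[~pheno[col].isin((0, 1)), col].iloc[0]
            raise DataValidationError(f"{col} contains value {bad} outside {{0,1}}")
    out.phenotypes = {c: pheno[c].to_numpy() for c in pheno.columns}
    out.validate(require_phenotypes=True)
    return out


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.transcript_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.6f")


def write_phenotype_table(ds: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.phenotypes, index=ds.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

def _as_digraph(bn) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in bn.nodes:
        g.add_node(node, arity=int(bn.arities.get(node, 0)))
    for (u, v) in sorted(bn.edges):
        g.add_edge(u, v, strength=float(bn.edge_strengths.get((u, v), 0.0)))
    meta = getattr(bn, "learn_meta", None) or {}
    for key, val in meta.items():
        g.graph[f"learn_{key}"] = val
    if getattr(bn, "total_score", None) is not None:
        g.graph["total_score_bits"] = float(bn.total_score)
    return g


def write_network(bn, path: str | Path, format: str = "graphml") -> None:
    """Serialize a directed network with per-edge ``strength`` attributes.

    Formats: ``graphml`` (lossless round trip), ``edge_tsv`` (source, target,
    strength at 6 decimals) and ``dot`` (write-only, for rendering).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_as_digraph(bn), path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tstrength\n")
            for (u, v) in sorted(bn.edges):
                s = float(bn.edge_strengths.get((u, v), 0.0))
                fh.write(f"{u}\t{v}\t{s:.6f}\n")
            # isolated nodes appear as node-only rows so the node set survives
            linked = {x for e in bn.edges for x in e}
            for node in bn.nodes:
                if node not in linked:
                    fh.write(f"{node}\t\t\n")
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph bn {\n")
            for node in bn.nodes:
                fh.write(f'  "{node}";\n')
            for (u, v) in sorted(bn.edges):
                s = float(bn.edge_strengths.get((u, v), 0.0))
                fh.write(f'  "{u}" -> "{v}" [label="{s:.2f}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml"):
    """Read a network written by :func:`write_network` (graphml or edge_tsv)."""
    from .bayesnet import BayesianNetwork  # local import to avoid a cycle

    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes)
        arities = {n: int(g.nodes[n].get("arity", 0)) for n in nodes}
        edges = {(u, v) for u, v in g.edges}
        strengths = {(u, v): float(g.edges[u, v].get("strength", 0.0))
                     for u, v in g.edges}
    elif format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        nodes_set: set[str] = set()
        edges = set()
        strengths = {}
        for _, row in df.iterrows():
            nodes_set.add(row["source"])
            if row["target"]:
                nodes_set.add(row["target"])
                edges.add((row["source"], row["target"]))
                strengths[(row["source"], row["target"])] = float(row["strength"])
        nodes = sorted(nodes_set)
        arities = {n: 0 for n in nodes}
    else:
        raise ValueError(f"unknown network format {format!r}")
    return BayesianNetwork(nodes=nodes, arities=arities, edges=edges,
                           edge_strengths=strengths, node_scores={},
                           total_score=0.0, learn_meta={})
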