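"""Readers and writers for the on-disk artifacts of a GRN reconstruction run.

Formats are deliberately plain: tab-separated edge lists (TF, target,
regulatory mode), FASTA promoter sequences, delimited expression matrices
(samples x genes), a knockout manifest pointing at paired control /
post-knockout expression files, and a YAML run configuration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_MODES = ("activation", "repression", "unknown")
PROMOTER_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class EdgeRecord:
    """A single TF -> target regulatory interaction.

    After mode collapsing every surviving record carries the mode
    "interactive": duplicate (tf, target) pairs, including pairs annotated
    both as activation and repression, are reduced to one link.
    """

    tf_id: str
    target_id: str
    mode: str = "unknown"

    def __post_init__(self):
        if not self.tf_id or not self.target_id:
            raise ValueError("edge endpoints must be non-empty identifiers")
        if self.mode not in VALID_MODES + ("interactive",):
            raise ValueError(f"unknown regulatory mode {self.mode!r}")


@dataclass
class GeneGraph:
    """Undirected simple graph over the gene universe (TFs and targets).

    `adjacency` is a symmetric {0,1} matrix with zero diagonal, rows/columns
    ordered by `node_ids` (lexicographic by construction in build_graph).
    `tf_flags[i]` marks nodes that appear as the TF of at least one edge.
    """

    node_ids: list[str]
    adjacency: np.ndarray
    tf_flags: np.ndarray

    def __post_init__(self):
        a = self.adjacency
        if a.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("adjacency shape does not match node set")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_ids)}

    def edge_array(self) -> np.ndarray:
        """Upper-triangle edges as an (m, 2) int array of node indices."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])


@dataclass
class ExpressionMatrix:
    """Real-valued expression, samples in rows, genes in columns."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError("expression shape does not match labels")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")


@dataclass
class KnockoutExperiment:
    """Paired control / post-knockout expression over the same gene order."""

    pre: np.ndarray
    target_gene: str
    post: np.ndarray
    gene_ids: list[str]

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1:
            raise ValueError("pre and post vectors must be 1-D with equal length")
        if len(self.gene_ids) != self.pre.size:
            raise ValueError("gene_ids length must match expression vectors")
        if self.target_gene not in self.gene_ids:
            raise ValueError(f"knockout target {self.target_gene!r} not in gene set")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [tok.strip() for tok in line.rstrip("\n").split(sep)]


def read_edge_list(path, collapse_modes: bool = True) -> list[EdgeRecord]:
    """Parse a TF–target edge list; de-duplicate (tf, target) pairs.

    When ``collapse_modes`` is set, activation / repression / unknown are
    collapsed into the single mode "interactive", so a pair annotated with
    several modes is kept as one link.
    """
    records: dict[tuple[str, str], EdgeRecord] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            toks = _split_line(raw)
            if len(toks) < 2 or not toks[0] or not toks[1]:
                raise ValueError(f"{path}: malformed edge on line {lineno}: {raw!r}")
            mode = toks[2] if len(toks) > 2 and toks[2] else "unknown"
            if mode not in VALID_MODES + ("interactive",):
                raise ValueError(
                    f"{path}: line {lineno}: mode {mode!r} not in {VALID_MODES}")
            key = (toks[0], toks[1])
            rec = EdgeRecord(toks[0], toks[1], "interactive" if collapse_modes else mode)
            records.setdefault(key, rec)
    if not records:
        raise ValueError(f"{path}: edge list is empty")
    return list(records.values())


def write_edge_list(records: list[EdgeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# tf\ttarget\tmode\n")
        for r in records:
            fh.write(f"{r.tf_id}\t{r.target_id}\t{r.mode}\n")


def build_graph(edges: list[EdgeRecord], node_universe: list[str] | None = None) -> GeneGraph:
    """Build the undirected adjacency over the union of endpoints.

    Node order is lexicographic over gene ids so downstream seeding is
    independent of input edge order.  Self-regulation edges are dropped with
    a warning (the simple-graph formulation has a zero diagonal).
    """
    if not edges and node_universe is None:
        raise ValueError("no edges and no node universe given")
    kept = []
    for e in edges:
        if e.tf_id == e.target_id:
            warnings.warn(f"dropping self-regulation edge {e.tf_id}->{e.target_id}")
            continue
        kept.append(e)
    ids = set(node_universe or [])
    for e in kept:
        ids.update((e.tf_id, e.target_id))
    node_ids = sorted(ids)
    idx = {g: i for i, g in enumerate(node_ids)}
    n = len(node_ids)
    a = np.zeros((n, n), dtype=np.int8)
    tf_flags = np.zeros(n, dtype=bool)
    for e in kept:
        i, j = idx[e.tf_id], idx[e.target_id]
        a[i, j] = a[j, i] = 1
        tf_flags[i] = True
    return GeneGraph(node_ids, a, tf_flags)


# ---------------------------------------------------------------------------
# promoters / attributes / expression
# ---------------------------------------------------------------------------

def read_fasta_promoters(path) -> dict[str, str]:
    """Load promoter sequences keyed by the first header token.

    Sequences are upper-cased; only A/C/G/T/N are accepted.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate promoter record {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - PROMOTER_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta_promoters(promoters: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for gid, seq in promoters.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_attributes(path) -> pd.DataFrame:
    """Categorical gene attribute table: rows = genes, columns = features."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids in attribute table")
    return df


def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


def read_expression(path) -> ExpressionMatrix:
    """Load a samples x genes matrix (first row gene ids, first column sample ids)."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(values, [str(s) for s in df.index], [str(g) for g in df.columns])


def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(expr.values, index=expr.sample_ids, columns=expr.gene_ids).to_csv(path)


def read_knockouts(manifest_path) -> list[KnockoutExperiment]:
    """Load knockout experiments from a TSV manifest of
    ``pre_file <TAB> target_gene <TAB> post_file`` triples (paths relative to
    the manifest)."""
    base = Path(manifest_path).parent
    out: list[KnockoutExperiment] = []
    with open(manifest_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            toks = _split_line(raw)
            if len(toks) != 3:
                raise ValueError(f"{manifest_path}: line {lineno}: expected 3 fields")
            pre_file, target, post_file = toks
            pre = read_expression(base / pre_file)
            post = read_expression(base / post_file)
            if pre.gene_ids != post.gene_ids:
                raise ValueError(
                    f"{manifest_path}: line {lineno}: pre/post gene order differs")
            if target not in pre.gene_ids:
                raise ValueError(
                    f"{manifest_path}: line {lineno}: target {target!r} missing from genes")
            out.append(KnockoutExperiment(pre.values[0], target, post.values[0],
                                          pre.gene_ids))
    if not out:
        raise ValueError(f"{manifest_path}: manifest lists no experiments")
    return out


def write_knockouts(experiments: list[KnockoutExperiment], out_dir) -> Path:
    """Write each experiment as a pre/post CSV pair plus a manifest; returns
    the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "knockouts.tsv"
    with open(manifest, "w") as fh:
        fh.write("# pre_file\ttarget_gene\tpost_file\n")
        for i, ko in enumerate(experiments):
            pre_name, post_name = f"ko{i}_pre.csv", f"ko{i}_post.csv"
            write_expression(ExpressionMatrix(ko.pre[None, :], ["control"], ko.gene_ids),
                             out_dir / pre_name)
            write_expression(ExpressionMatrix(ko.post[None, :], ["knockout"], ko.gene_ids),
                             out_dir / post_name)
            fh.write(f"{pre_name}\t{ko.target_gene}\t{post_name}\n")
    return manifest


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path):
    """Load a YAML run configuration; unknown keys are rejected."""
    from .training import RunConfig  # local import to avoid a cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {unknown}; valid keys: {sorted(valid)}")
    return RunConfig(**raw)


def write_config(config, path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
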