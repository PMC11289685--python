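"""Self-consistent synthetic inputs with planted latent structure.

A world is built from a latent gene matrix U (n genes x d_latent):

* the regulatory graph is sampled Bernoulli(sigmoid(u_i . u_j + b)) with the
  bias b calibrated so the expected edge density matches the request;
* expression is a low-rank factor model, sample loadings times U^T plus
  Gaussian noise;
* promoters are random DNA in which every planted edge's two genes share an
  inserted common motif, giving k-mer features genuine signal;
* categorical attributes summarize the latent coordinates (sign pattern,
  quartile, hub status), so attribute features are informative about U;
* knockouts follow a first-order linear propagation rule: the target is
  zeroed and each neighbor j loses w * A_tj * pre_j before noise.

Same seed, same world, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_formats import (EdgeRecord, ExpressionMatrix, GeneGraph,
                         KnockoutExperiment, write_edge_list, write_expression,
                         write_fasta_promoters, write_knockouts)
from .seeding import named_rng

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticWorld:
    latent: np.ndarray
    graph: GeneGraph
    expression: ExpressionMatrix
    promoters: dict[str, str]
    attributes: pd.DataFrame
    knockouts: list[KnockoutExperiment]
    seed: int
    params: dict = field(default_factory=dict)


def _calibrate_bias(logits_upper: np.ndarray, density: float) -> float:
    """Solve mean(sigmoid(logits + b)) = density for b by bracketed root find."""
    def f(b):
        return expit(logits_upper + b).mean() - density

    lo, hi = -80.0, 80.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"cannot calibrate bias for edge density {density}")
    return float(brentq(f, lo, hi, xtol=1e-10))


def make_world(n_genes: int = 100, n_samples: int = 50, d_latent: int = 8,
               edge_density: float = 0.05, noise_sd: float = 0.1,
               motif_len: int = 8, n_knockouts: int = 40, seed: int = 0,
               promoter_len: int = 2500, latent_scale: float = 1.5,
               knockout_strength: float = 0.5) -> SyntheticWorld:
    """Generate a fully self-consistent synthetic input bundle."""
    if min(n_genes, n_samples, d_latent, motif_len, n_knockouts) < 1:
        raise ValueError("all counts must be >= 1")
    if not 0 < edge_density < 0.5:
        raise ValueError("edge_density must lie in (0, 0.5)")

    width = max(3, len(str(n_genes - 1)))
    node_ids = [f"g{i:0{width}d}" for i in range(n_genes)]  # lexicographic

    # latent coordinates and graph
    rng = named_rng(seed, "latent")
    U = latent_scale * rng.standard_normal((n_genes, d_latent))
    logits = U @ U.T
    iu, ju = np.triu_indices(n_genes, 1)
    bias = _calibrate_bias(logits[iu, ju], edge_density)
    grng = named_rng(seed, "graph")
    probs = expit(logits[iu, ju] + bias)
    draw = grng.random(iu.size) < probs
    A = np.zeros((n_genes, n_genes), dtype=np.int8)
    A[iu[draw], ju[draw]] = 1
    A = A + A.T
    degree = A.sum(axis=1)
    graph = GeneGraph(node_ids, A, degree > np.median(degree))

    # expression: low-rank factor model
    erng = named_rng(seed, "expression")
    loadings = erng.standard_normal((n_samples, d_latent))
    X = loadings @ U.T + noise_sd * erng.standard_normal((n_samples, n_genes))
    expression = ExpressionMatrix(
        X, [f"s{i:03d}" for i in range(n_samples)], node_ids)

    # promoters: one motif per (latent dimension, sign); copy number tracks
    # |u_it|, so k-mer composition is a noisy linear readout of the latent
    # coordinates and edge-sharing genes share motifs
    prng = named_rng(seed, "promoters")
    seqs = prng.choice(_BASES, size=(n_genes, promoter_len))
    motifs = {(t, s): prng.choice(_BASES, size=motif_len)
              for t in range(d_latent) for s in (1, -1)}

    def insert(g: int, motif: np.ndarray) -> None:
        pos = prng.integers(0, promoter_len - motif_len + 1)
        seqs[g, pos:pos + motif_len] = motif

    copies = np.minimum(4, np.rint(np.abs(U) / latent_scale)).astype(int)
    signs = np.where(U > 0, 1, -1)
    for g in range(n_genes):
        for t in range(d_latent):
            for _ in range(copies[g, t]):
                insert(g, motifs[(t, signs[g, t])])
    # guarantee every planted edge's pair shares at least one common motif
    for a, b in zip(iu[draw], ju[draw]):
        agree = signs[a] == signs[b]
        if not (agree & (copies[a] > 0) & (copies[b] > 0)).any():
            prod = np.where(agree, U[a] * U[b], -np.inf)
            t = int(np.argmax(prod))
            m = motifs[(t, signs[a, t])]
            insert(a, m)
            insert(b, m)
    promoters = {node_ids[i]: "".join(seqs[i]) for i in range(n_genes)}

    # categorical attributes correlated with the latent structure
    sign_pat = np.where(U[:, 0] > 0, "p", "n")
    if d_latent > 1:
        sign_pat = np.char.add(sign_pat, np.where(U[:, 1] > 0, "p", "n"))
    quart = pd.qcut(U[:, 0], q=min(4, n_genes), labels=False, duplicates="drop")
    attributes = pd.DataFrame(
        {
            "latent_sign": sign_pat,
            "level_quartile": [f"q{int(q)+1}" for q in quart],
            "hub_status": np.where(graph.tf_flags, "TF", "non-TF"),
        },
        index=node_ids,
    )

    # knockouts via first-order propagation
    krng = named_rng(seed, "knockouts")
    candidates = np.flatnonzero(degree > 0)
    if candidates.size == 0:
        candidates = np.arange(n_genes)
    targets = krng.choice(candidates, size=n_knockouts,
                          replace=n_knockouts > candidates.size)
    knockouts = []
    for t in targets:
        pre = krng.standard_normal(d_latent) @ U.T
        if noise_sd > 0:
            pre = pre + noise_sd * krng.standard_normal(n_genes)
        post = pre - knockout_strength * A[t] * pre
        post[t] = 0.0
        if noise_sd > 0:
            post = post + noise_sd * krng.standard_normal(n_genes)
        knockouts.append(KnockoutExperiment(pre, node_ids[t], post, node_ids))

    params = dict(n_genes=n_genes, n_samples=n_samples, d_latent=d_latent,
                  edge_density=edge_density, noise_sd=noise_sd,
                  motif_len=motif_len, n_knockouts=n_knockouts,
                  promoter_len=promoter_len, latent_scale=latent_scale,
                  knockout_strength=knockout_strength)
    return SyntheticWorld(U, graph, expression, promoters, attributes,
                          knockouts, seed, params)


def write_world(world: SyntheticWorld, out_dir) -> None:
    """Serialize a world in the package's on-disk formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = [EdgeRecord(world.graph.node_ids[i], world.graph.node_ids[j], "unknown")
             for i, j in world.graph.edge_array()]
    write_edge_list(edges, out / "edges.tsv")
    write_fasta_promoters(world.promoters, out / "promoters.fasta")
    world.attributes.to_csv(out / "attributes.tsv", sep="\t", index_label="gene")
    write_expression(world.expression, out / "expression.csv")
    write_knockouts(world.knockouts, out / "knockouts")


# ---------------------------------------------------------------------------
# edge splitting and masking
# ---------------------------------------------------------------------------

@dataclass
class EdgeSplit:
    """Disjoint positive partitions plus matched sampled negatives, all as
    (m, 2) arrays of node indices with i < j."""

    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    train_neg: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray


def split_edges(graph: GeneGraph, frac_train: float = 0.8, frac_val: float = 0.1,
                frac_test: float = 0.1, seed: int = 0,
                negative_ratio: int = 1) -> EdgeSplit:
    """Partition positives into train/val/test and sample matched negatives.

    Negatives are drawn uniformly without replacement from non-edge,
    non-self pairs, `negative_ratio` per positive, disjoint across splits.
    """
    fracs = (frac_train, frac_val, frac_test)
    if min(fracs) < 0 or max(fracs) <= 0 or abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError("split fractions must be non-negative and sum to 1")
    pos = graph.edge_array()
    m = len(pos)
    rng = named_rng(seed, "split")
    pos = pos[rng.permutation(m)]
    n_val = int(round(frac_val * m))
    n_test = int(round(frac_test * m))
    n_train = m - n_val - n_test
    train_pos, val_pos, test_pos = np.split(pos, [n_train, n_train + n_val])

    iu, ju = np.triu_indices(graph.n_nodes, 1)
    non_edge = graph.adjacency[iu, ju] == 0
    cand = np.column_stack([iu[non_edge], ju[non_edge]])
    need = negative_ratio * m
    if need > len(cand):
        raise ValueError(
            f"graph too dense: need {need} negatives, only {len(cand)} non-edges")
    neg = cand[named_rng(seed, "negatives").choice(len(cand), size=need, replace=False)]
    train_neg, val_neg, test_neg = np.split(
        neg, [negative_ratio * n_train, negative_ratio * (n_train + n_val)])
    return EdgeSplit(train_pos, val_pos, test_pos, train_neg, val_neg, test_neg)


@dataclass
class PerturbedTrain:
    """Training positives after masking: masked positives are relabeled as
    (forced) negatives during training."""

    positives: np.ndarray
    forced_negatives: np.ndarray


def mask_positives(train_edges: np.ndarray, fraction: float,
                   seed: int = 0) -> tuple[PerturbedTrain, np.ndarray]:
    """Relabel floor(fraction * |train|) random positives as negatives.

    The selection is the prefix of one seeded permutation, so for a fixed
    seed larger fractions mask supersets of smaller ones (nested masks).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    train_edges = np.asarray(train_edges)
    k = int(np.floor(fraction * len(train_edges)))
    perm = named_rng(seed, "mask").permutation(len(train_edges))
    masked = train_edges[perm[:k]]
    kept = train_edges[np.sort(perm[k:])]
    return PerturbedTrain(kept, masked), masked
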