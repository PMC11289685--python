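"""Task heads on top of the gene embeddings Z.

* Edge decoder: A_hat_ij = logistic(z_i . z_j), trained with binary
  cross-entropy over sampled positive and negative pairs.
* Knockout head: an MLP encoder compresses the control expression vector,
  the code is concatenated with a reduced one-hot embedding of the knocked-
  out gene, and an MLP decoder emits the post-knockout expression; MSE loss.
* Expression reconstruction: sample embeddings times Z^T approximate the
  expression matrix; MSE loss over all cells.

The logistic squashing in the edge decoder makes the dot-product score a
probability, which the cross-entropy loss requires; scores are clamped to
[1e-12, 1 - 1e-12] before the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .autodiff import Tensor, concat

_EPS = 1e-12


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# edge decoder
# ---------------------------------------------------------------------------

@dataclass
class EdgeScores:
    """Symmetric matrix of predicted interaction probabilities in (0, 1).

    The diagonal is reported for completeness but excluded from losses and
    metrics."""

    A_hat: np.ndarray

    def __post_init__(self):
        if not ((self.A_hat > 0) & (self.A_hat < 1)).all():
            raise ValueError("edge scores must lie strictly inside (0, 1)")


def decode_edges_t(Z: Tensor) -> Tensor:
    return (Z @ Z.T).sigmoid()


def decode_edges(Z) -> EdgeScores:
    """A_hat = logistic(Z Z^T), nudged off the numerically saturated
    endpoints so scores stay strictly inside (0, 1)."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("embeddings must be finite")
    return EdgeScores(np.clip(decode_edges_t(Tensor(Z)).data, _EPS, 1.0 - _EPS))


def pair_logits_t(Z: Tensor, pairs: np.ndarray) -> Tensor:
    """Dot products z_i . z_j for an (m, 2) array of node-index pairs."""
    pairs = np.asarray(pairs)
    zi = Z[pairs[:, 0]]
    zj = Z[pairs[:, 1]]
    return (zi * zj).sum(axis=1)


def pair_scores_t(Z: Tensor, pairs: np.ndarray) -> Tensor:
    """Logistic dot-product scores for an (m, 2) array of node-index pairs."""
    return pair_logits_t(Z, pairs).sigmoid()


def loss_grn_t(Z: Tensor, positive_pairs: np.ndarray,
               negative_pairs: np.ndarray) -> Tensor:
    """Summed BCE over the sampled positive and negative pairs.

    Evaluated from the dot-product logits via softplus for numerical
    stability: -y log s - (1-y) log(1-s) = softplus(x) - y x at s = logistic(x).
    """
    pos = np.asarray(positive_pairs).reshape(-1, 2)
    neg = np.asarray(negative_pairs).reshape(-1, 2)
    overlap = set(map(tuple, pos)) & set(map(tuple, neg))
    if overlap:
        raise ValueError(f"positive and negative pair sets overlap: {sorted(overlap)[:3]}")
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    x = pair_logits_t(Z, pairs)
    return (x.softplus() - labels * x).sum()


def loss_grn(A_hat, positive_pairs, negative_pairs) -> float:
    """BCE evaluated on a precomputed score matrix (reporting convenience)."""
    A = A_hat.A_hat if isinstance(A_hat, EdgeScores) else np.asarray(A_hat, dtype=float)
    pos = np.asarray(positive_pairs).reshape(-1, 2)
    neg = np.asarray(negative_pairs).reshape(-1, 2)
    overlap = set(map(tuple, pos)) & set(map(tuple, neg))
    if overlap:
        raise ValueError("positive and negative pair sets overlap")
    p = np.clip(np.concatenate([A[pos[:, 0], pos[:, 1]], A[neg[:, 0], neg[:, 1]]]),
                _EPS, 1.0 - _EPS)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


# ---------------------------------------------------------------------------
# knockout head
# ---------------------------------------------------------------------------

class TargetEmbedder:
    """Reduced one-hot embedding E_tg of the knocked-out gene: the identity
    block over the gene universe projected to d_t PCA components."""

    def __init__(self, gene_ids: list[str], d_t: int = 32):
        n = len(gene_ids)
        d_t = min(d_t, n)
        self.gene_ids = list(gene_ids)
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        pca = PCA(n_components=d_t, svd_solver="full")
        self.table = pca.fit_transform(np.eye(n))
        self.d_t = d_t

    def embed(self, genes) -> np.ndarray:
        if isinstance(genes, str):
            genes = [genes]
        rows = []
        for g in genes:
            if g not in self._index:
                raise KeyError(f"unknown knockout target {g!r}")
            rows.append(self.table[self._index[g]])
        return np.vstack(rows)


@dataclass
class KnockoutHeadParams:
    """Encoder/decoder affine maps (row-vector convention) plus the fixed
    target embedder; decoder input width = code width + d_t."""

    W_enc: Tensor  # M x d_s
    b_enc: Tensor  # d_s
    W_dec: Tensor  # (d_s + d_t) x M
    b_dec: Tensor  # M
    target_embedder: TargetEmbedder

    def __post_init__(self):
        d_s = self.W_enc.shape[1]
        if self.W_dec.shape[0] != d_s + self.target_embedder.d_t:
            raise ValueError("decoder input width must equal code width + d_t")

    def parameters(self) -> list[Tensor]:
        return [self.W_enc, self.b_enc, self.W_dec, self.b_dec]


def init_knockout_head(n_genes: int, d_s: int, target_embedder: TargetEmbedder,
                       rng: np.random.Generator) -> KnockoutHeadParams:
    lim1 = np.sqrt(6.0 / (n_genes + d_s))
    d_in = d_s + target_embedder.d_t
    lim2 = np.sqrt(6.0 / (d_in + n_genes))
    return KnockoutHeadParams(
        Tensor(rng.uniform(-lim1, lim1, (n_genes, d_s)), requires_grad=True),
        Tensor(np.zeros(d_s), requires_grad=True),
        Tensor(rng.uniform(-lim2, lim2, (d_in, n_genes)), requires_grad=True),
        Tensor(np.zeros(n_genes), requires_grad=True),
        target_embedder,
    )


def encode_samples_t(head: KnockoutHeadParams, X) -> Tensor:
    """E = relu(X W_enc + b_enc) for a batch of expression row-vectors.

    The same encoder embeds knockout controls and ordinary
    samples for the expression-reconstruction head.
    """
    X = _lift(x=X)
    if X.data.ndim == 1:
        X = X.reshape(1, -1)
    return (X @ head.W_enc + head.b_enc).relu()


def predict_knockout_t(head: KnockoutHeadParams, pre, targets) -> Tensor:
    E_gp = encode_samples_t(head, pre)
    E_tg = Tensor(head.target_embedder.embed(targets))
    E_con = concat([E_gp, E_tg], axis=1)
    return E_con @ head.W_dec + head.b_dec


def predict_knockout(head: KnockoutHeadParams, pre_expression, target_gene) -> np.ndarray:
    """Predicted post-knockout expression vector(s) of length M."""
    out = predict_knockout_t(head, np.asarray(pre_expression, dtype=float),
                             target_gene).data
    return out[0] if np.asarray(pre_expression).ndim == 1 else out


def loss_perturb_t(pred: Tensor, true: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(true, dtype=float))
    return (diff * diff).mean()


def loss_perturb(pred, true) -> float:
    """Mean squared error over genes (and experiments, if batched)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("predicted and true expression have different shapes")
    return float(np.mean((pred - true) ** 2))


# ---------------------------------------------------------------------------
# expression reconstruction
# ---------------------------------------------------------------------------

@dataclass
class SampleEmbeddings:
    """Per-sample codes E_gp (N x d); d must match the gene-embedding width."""

    E_gp: np.ndarray


def reconstruct_expression_t(E_gp: Tensor, Z: Tensor) -> Tensor:
    if E_gp.shape[1] != Z.shape[1]:
        raise ValueError("sample and gene embedding widths differ")
    return E_gp @ Z.T


def reconstruct_expression(E_gp, Z) -> np.ndarray:
    """X_exp = E_gp Z^T (N samples x M genes)."""
    E = E_gp.E_gp if isinstance(E_gp, SampleEmbeddings) else np.asarray(E_gp, dtype=float)
    return reconstruct_expression_t(Tensor(E), Tensor(np.asarray(Z, dtype=float))).data


def loss_exp_t(X: np.ndarray, X_exp: Tensor, per_sample: bool = False) -> Tensor:
    diff = X_exp - Tensor(np.asarray(X, dtype=float))
    sq = diff * diff
    if per_sample:  # literal 1/N normalization (sum over cells / n_samples)
        return sq.sum() / X.shape[0]
    return sq.mean()


def loss_exp(X, X_exp, per_sample: bool = False) -> float:
    """Reconstruction MSE; by default the mean over all N*M cells."""
    X = np.asarray(X, dtype=float)
    X_exp = np.asarray(X_exp, dtype=float)
    if X.shape != X_exp.shape:
        raise ValueError("expression and reconstruction have different shapes")
    sq = (X - X_exp) ** 2
    return float(sq.sum() / X.shape[0]) if per_sample else float(sq.mean())
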