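"""Joint optimization of the encoder and the three task heads.

The combined objective is

    L_joint = lambda1 * L_GRN + lambda2 * L_perturb
              + (1 - lambda1 - lambda2) * L_exp

minimized full-batch with Adam.  Only training-split edges enter the
attention mask (held-out edges must not leak through message passing);
negatives are resampled each epoch from unlabeled pairs unless a fixed set
is requested.  Early stopping tracks validation link AUROC and the best
parameters are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoders, features as feat, gat_encoder, io_formats
from .autodiff import Adam, Tensor
from .io_formats import GeneGraph
from .seeding import named_rng
from .synthetic_data import EdgeSplit, PerturbedTrain, split_edges

FEATURE_STRATEGIES = ("random", "promoter", "attributes", "concat")
TASK_VARIANTS = ("grnr_only", "no_gemr", "no_gkp", "full")


@dataclass
class RunConfig:
    """All knobs of a training run; loss weights must satisfy
    lambda1 + lambda2 <= 1 with each in [0, 1]."""

    lambda1: float = 0.01
    lambda2: float = 0.3
    epochs: int = 600
    learning_rate: float = 0.01
    seed: int = 0
    frac_train: float = 0.8
    frac_val: float = 0.1
    frac_test: float = 0.1
    negative_ratio: int = 1
    n_heads: int = 4
    d_head: int = 64
    d_z: int = 64
    d_t: int = 32
    kmer_k: int = 3
    kmer_normalize: bool = False
    d_promoter: int = 32
    d_attr: int = 32
    early_stop_patience: int = 150
    feature_strategy: str = "concat"
    expression_normalize: str = "zscore"
    resample_negatives: bool = True
    share_sample_encoder: bool = True

    def __post_init__(self):
        if not (0 <= self.lambda1 <= 1 and 0 <= self.lambda2 <= 1):
            raise ValueError("lambda weights must lie in [0, 1]")
        if self.lambda1 + self.lambda2 > 1 + 1e-12:
            raise ValueError("lambda1 + lambda2 must not exceed 1")
        for name in ("n_heads", "d_head", "d_z", "d_t", "kmer_k",
                     "d_promoter", "d_attr", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.feature_strategy not in FEATURE_STRATEGIES:
            raise ValueError(f"feature_strategy must be one of {FEATURE_STRATEGIES}")
        if self.expression_normalize not in ("none", "zscore", "log1p_zscore"):
            raise ValueError("expression_normalize must be none|zscore|log1p_zscore")


def joint_loss(L_GRN: float, L_perturb: float, L_exp: float,
               lambda1: float, lambda2: float) -> float:
    """The lambda-weighted combination of the three task losses."""
    if lambda1 + lambda2 > 1 + 1e-12 or min(lambda1, lambda2) < 0:
        raise ValueError("invalid lambda weights")
    return lambda1 * L_GRN + lambda2 * L_perturb + (1 - lambda1 - lambda2) * L_exp


# ---------------------------------------------------------------------------
# input bundle and feature building
# ---------------------------------------------------------------------------

@dataclass
class InputBundle:
    """Aligned in-memory inputs (what a SyntheticWorld also provides)."""

    graph: GeneGraph
    promoters: dict[str, str]
    attributes: pd.DataFrame
    expression: io_formats.ExpressionMatrix
    knockouts: list[io_formats.KnockoutExperiment]


def load_bundle(data_dir) -> InputBundle:
    """Read a full input bundle from the on-disk formats under `data_dir`."""
    d = Path(data_dir)
    edges = io_formats.read_edge_list(d / "edges.tsv")
    attributes = io_formats.read_attributes(d / "attributes.tsv")
    # the attribute table defines the gene universe, so isolated genes survive
    graph = io_formats.build_graph(edges, node_universe=[str(g) for g in attributes.index])
    promoters = io_formats.read_fasta_promoters(d / "promoters.fasta")
    expression = io_formats.read_expression(d / "expression.csv")
    ko_manifest = d / "knockouts" / "knockouts.tsv"
    knockouts = io_formats.read_knockouts(ko_manifest) if ko_manifest.exists() else []
    return InputBundle(graph, promoters, attributes, expression, knockouts)


def _center_and_scale(values: np.ndarray) -> np.ndarray:
    """Center columns and divide by the matrix root-mean-square.

    Keeps the PCA variance ordering intact (unlike per-column
    standardization, which inflates noise components to signal scale) while
    bringing raw k-mer-count coordinates to O(1) so attention scores and
    dot-product logits do not saturate."""
    v = values - values.mean(axis=0)
    rms = float(np.sqrt((v ** 2).mean()))
    return v / rms if rms > 0 else v


def build_features(bundle, config: RunConfig,
                   strategy: str | None = None) -> feat.FeatureMatrix:
    """Node features per strategy, rows in graph node order.

    Requested PCA widths are clamped to what each block can support
    (n genes, block columns), so small worlds remain valid.  Each returned matrix is
    centered and RMS-scaled after reduction.
    """
    strategy = strategy or config.feature_strategy
    node_ids = bundle.graph.node_ids
    n = len(node_ids)
    if strategy == "random":
        return feat.make_random_features(
            n, config.d_promoter + config.d_attr,
            named_rng(config.seed, "random-features").integers(2 ** 31))
    P = feat.kmer_matrix(bundle.promoters, node_ids, config.kmer_k,
                         normalize=config.kmer_normalize)
    B, _ = feat.onehot_encode(bundle.attributes.loc[node_ids])
    dp = min(config.d_promoter, min(P.shape))
    da = min(config.d_attr, min(B.shape))
    fm = feat.reduce_and_concat(P, B, dp, da, fit=True)
    if strategy == "concat":
        return feat.FeatureMatrix(_center_and_scale(fm.values), fm.block_spec,
                                  fm.fitted_reducers)
    if strategy == "promoter":
        return feat.FeatureMatrix(_center_and_scale(fm.values[:, :dp]),
                                  [("promoter-reduced", dp)],
                                  {"promoter": fm.fitted_reducers["promoter"]})
    if strategy == "attributes":
        return feat.FeatureMatrix(_center_and_scale(fm.values[:, dp:]),
                                  [("attribute-reduced", da)],
                                  {"attribute": fm.fitted_reducers["attribute"]})
    raise ValueError(f"unknown feature strategy {strategy!r}")


@dataclass
class ExpressionNormalizer:
    """Per-gene transform shared by the expression matrix and knockout
    vectors; 'zscore' centers/scales per gene, 'log1p_zscore' applies log1p
    first (nonnegative data only)."""

    mode: str
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ExpressionNormalizer":
        X = self._pre(X)
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        return self

    def _pre(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "log1p_zscore":
            if (X < 0).any():
                raise ValueError("log1p normalization requires nonnegative data")
            return np.log1p(X)
        return np.asarray(X, dtype=float)

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(X, dtype=float)
        return (self._pre(X) - self.mean) / self.sd

    def inverse(self, X: np.ndarray) -> np.ndarray:
        if self.mode == "none":
            return np.asarray(X, dtype=float)
        raw = X * self.sd + self.mean
        return np.expm1(raw) if self.mode == "log1p_zscore" else raw


# ---------------------------------------------------------------------------
# checkpoint
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Trained parameters plus everything needed to score new pairs and
    predict knockouts: node order, node features, the expression normalizer
    and the final gene embeddings."""

    config: RunConfig
    node_ids: list[str]
    encoder: gat_encoder.GatEncoderParams
    knockout_head: decoders.KnockoutHeadParams
    feature_matrix: np.ndarray
    train_mask_adjacency: np.ndarray
    normalizer: ExpressionNormalizer
    Z: np.ndarray
    train_pos: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_ids)}

    def pair_scores(self, pairs: np.ndarray) -> np.ndarray:
        return decoders.pair_scores_t(Tensor(self.Z), np.asarray(pairs)).data

    def predict_knockout(self, pre_raw: np.ndarray, target_gene: str) -> np.ndarray:
        """Raw-scale post-knockout prediction for a raw-scale control vector."""
        pre = self.normalizer.transform(np.asarray(pre_raw, dtype=float)[None, :])
        pred = decoders.predict_knockout_t(self.knockout_head, pre, target_gene).data
        return self.normalizer.inverse(pred)[0]


def save_checkpoint(ckpt: Checkpoint, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "feature_matrix": ckpt.feature_matrix,
        "train_mask_adjacency": ckpt.train_mask_adjacency,
        "Z": ckpt.Z,
        "train_pos": ckpt.train_pos,
        "ko_W_enc": ckpt.knockout_head.W_enc.data,
        "ko_b_enc": ckpt.knockout_head.b_enc.data,
        "ko_W_dec": ckpt.knockout_head.W_dec.data,
        "ko_b_dec": ckpt.knockout_head.b_dec.data,
        "ko_table": ckpt.knockout_head.target_embedder.table,
        "norm_mean": np.zeros(0) if ckpt.normalizer.mean is None else ckpt.normalizer.mean,
        "norm_sd": np.zeros(0) if ckpt.normalizer.sd is None else ckpt.normalizer.sd,
    }
    for li, layer in enumerate((ckpt.encoder.layer1, ckpt.encoder.layer2), 1):
        for hi in range(layer.n_heads):
            arrays[f"l{li}_W{hi}"] = layer.Ws[hi].data
            arrays[f"l{li}_asrc{hi}"] = layer.a_src[hi].data
            arrays[f"l{li}_adst{hi}"] = layer.a_dst[hi].data
    np.savez(path / "params.npz", **arrays)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": asdict(ckpt.config), "node_ids": ckpt.node_ids,
                        "normalize_mode": ckpt.normalizer.mode}, fh)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    with open(path / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    config = RunConfig(**meta["config"])
    node_ids = list(meta["node_ids"])
    z = np.load(path / "params.npz")

    def layer(li: int, mode: str) -> gat_encoder.GatLayerParams:
        heads = sorted(int(k[len(f"l{li}_W"):]) for k in z.files
                       if k.startswith(f"l{li}_W"))
        return gat_encoder.GatLayerParams(
            [Tensor(z[f"l{li}_W{h}"], requires_grad=True) for h in heads],
            [Tensor(z[f"l{li}_asrc{h}"], requires_grad=True) for h in heads],
            [Tensor(z[f"l{li}_adst{h}"], requires_grad=True) for h in heads],
            mode)

    embedder = decoders.TargetEmbedder.__new__(decoders.TargetEmbedder)
    embedder.gene_ids = node_ids
    embedder._index = {g: i for i, g in enumerate(node_ids)}
    embedder.table = z["ko_table"]
    embedder.d_t = embedder.table.shape[1]
    head = decoders.KnockoutHeadParams(
        Tensor(z["ko_W_enc"], requires_grad=True),
        Tensor(z["ko_b_enc"], requires_grad=True),
        Tensor(z["ko_W_dec"], requires_grad=True),
        Tensor(z["ko_b_dec"], requires_grad=True),
        embedder)
    norm = ExpressionNormalizer(meta["normalize_mode"])
    if z["norm_mean"].size:
        norm.mean, norm.sd = z["norm_mean"], z["norm_sd"]
    return Checkpoint(config, node_ids,
                      gat_encoder.GatEncoderParams(layer(1, "concat"), layer(2, "average")),
                      head, z["feature_matrix"], z["train_mask_adjacency"],
                      norm, z["Z"], z["train_pos"])


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _align_expression(expr: io_formats.ExpressionMatrix,
                      node_ids: list[str]) -> np.ndarray:
    missing = [g for g in node_ids if g not in expr.gene_ids]
    if missing:
        raise ValueError(f"expression matrix lacks genes {missing[:5]}...")
    df = pd.DataFrame(expr.values, columns=expr.gene_ids)
    return df[node_ids].to_numpy(dtype=float)


def _align_knockouts(knockouts, node_ids: list[str]):
    pres, posts, targets = [], [], []
    for ko in knockouts:
        order = pd.Series(np.arange(len(ko.gene_ids)), index=ko.gene_ids)
        idx = order[node_ids].to_numpy()
        pres.append(ko.pre[idx])
        posts.append(ko.post[idx])
        targets.append(ko.target_gene)
    return (np.vstack(pres) if pres else np.zeros((0, len(node_ids)))),\
        (np.vstack(posts) if posts else np.zeros((0, len(node_ids)))), targets


def _val_auroc(Z: np.ndarray, split: EdgeSplit) -> float:
    from sklearn.metrics import roc_auc_score

    if len(split.val_pos) == 0 or len(split.val_neg) == 0:
        return float("nan")
    pairs = np.vstack([split.val_pos, split.val_neg])
    labels = np.concatenate([np.ones(len(split.val_pos)), np.zeros(len(split.val_neg))])
    scores = decoders.pair_scores_t(Tensor(Z), pairs).data
    return float(roc_auc_score(labels, scores))


def train(bundle, config: RunConfig, split: EdgeSplit | None = None,
          perturbed: PerturbedTrain | None = None,
          feature_matrix: feat.FeatureMatrix | None = None
          ) -> tuple[Checkpoint, pd.DataFrame]:
    """Jointly train encoder and heads; returns the best-validation-AUROC
    checkpoint and the per-epoch history (losses and validation AUROC)."""
    graph = bundle.graph
    node_ids = graph.node_ids
    n = graph.n_nodes

    if split is None:
        split = split_edges(graph, config.frac_train, config.frac_val,
                            config.frac_test, config.seed, config.negative_ratio)
    train_pos = split.train_pos if perturbed is None else perturbed.positives
    forced_neg = (np.zeros((0, 2), dtype=int) if perturbed is None
                  else perturbed.forced_negatives)

    fm = feature_matrix if feature_matrix is not None else build_features(bundle, config)
    X = Tensor(fm.values)

    # attention mask: training positives only (+ self-loops added downstream)
    A_train = np.zeros((n, n), dtype=np.int8)
    if len(train_pos):
        A_train[train_pos[:, 0], train_pos[:, 1]] = 1
        A_train[train_pos[:, 1], train_pos[:, 0]] = 1

    # negative-sampling candidates: anything not a known positive, not self
    known = np.zeros((n, n), dtype=bool)
    for arr in (train_pos, split.val_pos, split.test_pos, forced_neg):
        if len(arr):
            known[arr[:, 0], arr[:, 1]] = True
    iu, ju = np.triu_indices(n, 1)
    free = ~known[iu, ju]
    candidates = np.column_stack([iu[free], ju[free]])

    norm = ExpressionNormalizer(config.expression_normalize)
    X_expr_raw = _align_expression(bundle.expression, node_ids)
    norm.fit(X_expr_raw)
    X_expr = norm.transform(X_expr_raw)
    ko_pre_raw, ko_post_raw, ko_targets = _align_knockouts(bundle.knockouts, node_ids)
    ko_pre = norm.transform(ko_pre_raw) if len(ko_pre_raw) else ko_pre_raw
    ko_post = norm.transform(ko_post_raw) if len(ko_post_raw) else ko_post_raw
    has_ko = len(ko_targets) > 0

    init_rng = named_rng(config.seed, "init")
    encoder = gat_encoder.init_encoder(fm.values.shape[1], config.d_head,
                                       config.n_heads, config.d_z, init_rng)
    embedder = decoders.TargetEmbedder(node_ids, config.d_t)
    head = decoders.init_knockout_head(n, config.d_z, embedder, init_rng)
    params = encoder.parameters() + head.parameters()
    opt = Adam(params, lr=config.learning_rate)

    lam1, lam2 = config.lambda1, config.lambda2
    lam3 = 1.0 - lam1 - lam2
    neg_rng = named_rng(config.seed, "epoch-negatives")
    # count negatives against the full (pre-masking) positive total so the
    # sampled negative set is identical across masked and unmasked runs
    n_neg = config.negative_ratio * max(len(train_pos) + len(forced_neg), 1)
    fixed_neg = None
    if not config.resample_negatives:
        fixed_neg = candidates[neg_rng.choice(len(candidates),
                                              size=min(n_neg, len(candidates)),
                                              replace=False)]

    rows = []
    best = {"auroc": -np.inf, "epoch": -1, "snapshot": None}
    for epoch in range(1, config.epochs + 1):
        if fixed_neg is not None:
            neg = fixed_neg
        else:
            neg = candidates[neg_rng.choice(len(candidates),
                                            size=min(n_neg, len(candidates)),
                                            replace=False)]
        if len(forced_neg):
            neg = np.vstack([neg, forced_neg])

        Z = gat_encoder.encode_t(encoder, X, A_train)
        L_GRN = decoders.loss_grn_t(Z, train_pos, neg)
        if has_ko:
            pred = decoders.predict_knockout_t(head, ko_pre, ko_targets)
            L_perturb = decoders.loss_perturb_t(pred, ko_post)
        else:
            L_perturb = Tensor(0.0)
        E_gp = decoders.encode_samples_t(head, X_expr)
        L_exp = decoders.loss_exp_t(X_expr, decoders.reconstruct_expression_t(E_gp, Z))
        total = lam1 * L_GRN + lam2 * L_perturb + lam3 * L_exp

        for name, t in (("L_GRN", L_GRN), ("L_perturb", L_perturb),
                        ("L_exp", L_exp), ("L_joint", total)):
            if not np.isfinite(t.data).all():
                raise FloatingPointError(f"non-finite {name} at epoch {epoch}")

        opt.zero_grad()
        total.backward()
        opt.step()

        val_auroc = _val_auroc(Z.data, split)
        rows.append({"epoch": epoch, "L_GRN": float(L_GRN.data),
                     "L_perturb": float(L_perturb.data), "L_exp": float(L_exp.data),
                     "L_joint": float(total.data), "val_auroc": val_auroc})
        if np.isfinite(val_auroc) and val_auroc > best["auroc"]:
            # the snapshot covers the link-prediction path (encoder) only;
            # the knockout head has its own objective and keeps its final
            # parameters, since validation link AUROC says nothing about it
            best.update(auroc=val_auroc, epoch=epoch,
                        snapshot=[p.data.copy() for p in encoder.parameters()])
        if (np.isfinite(val_auroc) and best["epoch"] > 0
                and epoch - best["epoch"] >= config.early_stop_patience):
            break

    if best["snapshot"] is not None:
        for p, snap in zip(encoder.parameters(), best["snapshot"]):
            p.data = snap
    Z_final = gat_encoder.encode_t(encoder, X, A_train).data.copy()
    ckpt = Checkpoint(config, node_ids, encoder, head, fm.values.copy(),
                      A_train, norm, Z_final, np.asarray(train_pos))
    return ckpt, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

def task_lambdas(variant: str, config: RunConfig) -> tuple[float, float]:
    """Loss-weight mapping of the task-ablation variants."""
    if variant == "grnr_only":
        return 1.0, 0.0
    if variant == "no_gemr":   # drop expression reconstruction
        return config.lambda1, 1.0 - config.lambda1
    if variant == "no_gkp":    # drop knockout prediction
        return config.lambda1, 0.0
    if variant == "full":
        return config.lambda1, config.lambda2
    raise ValueError(f"unknown task variant {variant!r}")


def run_ablation(bundle, config: RunConfig,
                 feature_variants: tuple[str, ...] = FEATURE_STRATEGIES,
                 task_variants: tuple[str, ...] = TASK_VARIANTS) -> pd.DataFrame:
    """Train one model per (feature strategy x task variant) cell on shared
    splits and report test-set link metrics per cell."""
    from .evaluation import link_metrics

    split = split_edges(bundle.graph, config.frac_train, config.frac_val,
                        config.frac_test, config.seed, config.negative_ratio)
    rows = []
    for fstrat in feature_variants:
        fm = build_features(bundle, config, strategy=fstrat)
        for tvar in task_variants:
            lam1, lam2 = task_lambdas(tvar, config)
            cfg = RunConfig(**{**asdict(config), "lambda1": lam1,
                               "lambda2": lam2, "feature_strategy": fstrat})
            ckpt, _ = train(bundle, cfg, split=split, feature_matrix=fm)
            pairs = np.vstack([split.test_pos, split.test_neg])
            labels = np.concatenate([np.ones(len(split.test_pos)),
                                     np.zeros(len(split.test_neg))])
            rep = link_metrics(ckpt.pair_scores(pairs), labels)
            rows.append({"features": fstrat, "tasks": tvar,
                         "accuracy": rep.accuracy, "auroc": rep.auroc,
                         "precision": rep.precision, "recall": rep.recall,
                         "f1": rep.f1})
    return pd.DataFrame(rows)
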