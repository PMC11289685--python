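"""Metrics and study protocols.

Link prediction is scored with accuracy / precision / recall / F1 at a
probability threshold plus rank-based AUROC; multiple runs can be combined
by consensus binarization (keep a link only if predicted in at least
`min_votes` of the runs).  Knockout prediction is scored with Pearson
correlation of expression (corr), correlation of expression *changes*
(corr_delta), MSE and direction-of-change agreement, on all genes or on the
top-20 differentially expressed subset.  Robustness to false-negative labels
is quantified by the Jaccard index between test-set edge predictions before
and after masking a fraction of training positives as negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import roc_auc_score

from .io_formats import GeneGraph
from .seeding import substream_seed
from .synthetic_data import mask_positives


@dataclass
class MetricsReport:
    accuracy: float
    auroc: float
    precision: float
    recall: float
    f1: float
    n_runs: int = 1
    per_run: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def link_metrics(scores: np.ndarray, labels: np.ndarray,
                 threshold: float = 0.5) -> MetricsReport:
    """Score binary-labeled pairs: AUROC from the score ranking (midrank
    ties), the other metrics from predictions at `threshold` (predict
    positive at score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: test set contains a single class")
    auroc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = float((pred == labels).mean())
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return MetricsReport(acc, auroc, prec, rec, f1)


def aggregate_runs(reports: list[MetricsReport]) -> MetricsReport:
    """Mean over runs, with the per-run values retained."""
    if not reports:
        raise ValueError("no reports to aggregate")
    names = ("accuracy", "auroc", "precision", "recall", "f1")
    per_run = {m: [getattr(r, m) for r in reports] for m in names}
    means = {m: float(np.mean(v)) for m, v in per_run.items()}
    return MetricsReport(**means, n_runs=len(reports), per_run=per_run)


def consensus_binarize(run_matrices: list[np.ndarray], min_votes: int = 3) -> np.ndarray:
    """Element-wise vote: 1 iff at least `min_votes` runs predicted 1."""
    if len(run_matrices) < min_votes:
        raise ValueError(f"need at least {min_votes} run matrices")
    stack = np.stack([np.asarray(m) for m in run_matrices])
    if not np.isin(stack, (0, 1)).all():
        raise ValueError("run matrices must be binary")
    return (stack.sum(axis=0) >= min_votes).astype(np.int8)


# ---------------------------------------------------------------------------
# knockout metrics
# ---------------------------------------------------------------------------

@dataclass
class KnockoutReport:
    corr: float
    corr_delta: float
    mse: float
    direction_accuracy: float
    subset: str  # "ALL" | "DE"


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("correlation undefined (zero variance); reporting NaN")
        return float("nan")
    return float(pearsonr(a, b)[0])


def knockout_metrics(predicted_post: np.ndarray, true_post: np.ndarray,
                     control_pre: np.ndarray, subset: str = "ALL",
                     n_de: int = 20) -> KnockoutReport:
    """Compare a predicted post-knockout expression vector to the truth.

    corr correlates expression levels, corr_delta correlates changes from
    control; direction accuracy is agreement of sign(pred - pre) with
    sign(true - pre) over genes with nonzero true change.  The DE subset is
    the `n_de` genes with the largest |true - pre|.
    """
    pred = np.asarray(predicted_post, dtype=float)
    true = np.asarray(true_post, dtype=float)
    pre = np.asarray(control_pre, dtype=float)
    if not pred.shape == true.shape == pre.shape:
        raise ValueError("vectors must share one gene ordering")
    if subset not in ("ALL", "DE"):
        raise ValueError("subset must be 'ALL' or 'DE'")
    idx = np.arange(pred.size)
    if subset == "DE":
        idx = np.argsort(-np.abs(true - pre), kind="stable")[:n_de]
    p, t, c = pred[idx], true[idx], pre[idx]
    true_delta, pred_delta = t - c, p - c
    nonzero = true_delta != 0
    direction = (float(np.mean(np.sign(pred_delta[nonzero]) == np.sign(true_delta[nonzero])))
                 if nonzero.any() else float("nan"))
    return KnockoutReport(
        corr=_safe_pearson(p, t),
        corr_delta=_safe_pearson(pred_delta, true_delta),
        mse=float(np.mean((p - t) ** 2)),
        direction_accuracy=direction,
        subset=subset,
    )


# ---------------------------------------------------------------------------
# masked-positive robustness
# ---------------------------------------------------------------------------

@dataclass
class JaccardCurve:
    mask_fractions: list[float]
    jaccard_test: list[float]       # mean over repeats per fraction
    jaccard_train: list[float]
    accuracy_per_fraction: list[float]
    per_repeat: dict = field(default_factory=dict)


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _predicted_sets(ckpt, pairs: np.ndarray, threshold: float = 0.5) -> set:
    scores = ckpt.pair_scores(pairs)
    return {tuple(p) for p, s in zip(pairs.tolist(), scores) if s >= threshold}


def jaccard_robustness(bundle, config, fractions=(0.02, 0.05, 0.08, 0.10, 0.12, 0.15),
                       repeats: int = 10, threshold: float = 0.5) -> JaccardCurve:
    """Mask a fraction of training positives as negatives, retrain with the
    identical split, and compare edge predictions with the unmasked model.

    Masks are nested per repeat (one permutation per repeat, the fraction
    takes its prefix) so degradation is comparable across fractions.
    Fraction 0 reproduces the baseline run and gives Jaccard exactly 1.
    """
    from dataclasses import asdict as _asdict

    from .training import train
    from .synthetic_data import split_edges

    # fixed-negative mode: the sampled negatives are identical across the
    # baseline and every masked run (the candidate pool is unchanged by
    # masking), so prediction differences reflect the masked labels alone
    config = type(config)(**{**_asdict(config), "resample_negatives": False})
    split = split_edges(bundle.graph, config.frac_train, config.frac_val,
                        config.frac_test, config.seed, config.negative_ratio)
    base_ckpt, _ = train(bundle, config, split=split)
    test_pairs = np.vstack([split.test_pos, split.test_neg])
    test_labels = np.concatenate([np.ones(len(split.test_pos)),
                                  np.zeros(len(split.test_neg))])
    trval_pairs = np.vstack([split.train_pos, split.val_pos,
                             split.train_neg, split.val_neg])
    base_test = _predicted_sets(base_ckpt, test_pairs, threshold)
    base_trval = _predicted_sets(base_ckpt, trval_pairs, threshold)

    j_test, j_train, acc, per_repeat = [], [], [], {}
    for frac in fractions:
        jt_r, jr_r, acc_r = [], [], []
        for rep in range(repeats):
            perturbed, _ = mask_positives(
                split.train_pos, frac,
                seed=substream_seed(config.seed, f"mask-rep{rep}"))
            ckpt, _ = train(bundle, config, split=split, perturbed=perturbed)
            pred_test = _predicted_sets(ckpt, test_pairs, threshold)
            jt_r.append(jaccard(pred_test, base_test))
            jr_r.append(jaccard(_predicted_sets(ckpt, trval_pairs, threshold),
                                base_trval))
            pred = (ckpt.pair_scores(test_pairs) >= threshold).astype(int)
            acc_r.append(float((pred == test_labels).mean()))
        per_repeat[frac] = {"jaccard_test": jt_r, "jaccard_train": jr_r,
                            "accuracy": acc_r}
        j_test.append(float(np.mean(jt_r)))
        j_train.append(float(np.mean(jr_r)))
        acc.append(float(np.mean(acc_r)))
    return JaccardCurve(list(fractions), j_test, j_train, acc, per_repeat)


# ---------------------------------------------------------------------------
# centrality and top predictions
# ---------------------------------------------------------------------------

def centrality_rank(graph: GeneGraph) -> pd.DataFrame:
    """Degree, betweenness and eigenvector centrality per gene, plus a
    composite mean-of-ranks ordering (ties broken by gene id).

    Eigenvector centrality is computed on the largest connected component
    (0 elsewhere) and rescaled to max 1; degree and betweenness use their
    standard normalizations.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    G = nx.from_numpy_array(graph.adjacency)
    G = nx.relabel_nodes(G, dict(enumerate(graph.node_ids)))
    deg = nx.degree_centrality(G)
    bet = nx.betweenness_centrality(G, normalized=True)
    eig = {g: 0.0 for g in graph.node_ids}
    comps = sorted(nx.connected_components(G), key=len, reverse=True)
    if comps and len(comps[0]) > 1:
        sub = G.subgraph(comps[0])
        ev = nx.eigenvector_centrality_numpy(sub)
        peak = max(ev.values())
        for g, v in ev.items():
            eig[g] = abs(v) / abs(peak) if peak else 0.0
    df = pd.DataFrame({
        "gene": graph.node_ids,
        "degree": [deg[g] for g in graph.node_ids],
        "betweenness": [bet[g] for g in graph.node_ids],
        "eigenvector": [eig[g] for g in graph.node_ids],
    })
    for col in ("degree", "betweenness", "eigenvector"):
        df[f"{col}_rank"] = df[col].rank(ascending=False, method="min")
    df["composite_rank"] = df[[c for c in df.columns if c.endswith("_rank")]].mean(axis=1)
    df = df.sort_values(["composite_rank", "gene"], kind="stable").reset_index(drop=True)
    return df.drop(columns=[c for c in df.columns if c.endswith("_rank")])


def top_predictions(ckpt, tf_id: str, exclude_known: bool = True,
                    top_n: int = 25) -> pd.DataFrame:
    """Genes ranked by decoded edge score against `tf_id`; optionally drop
    the TF's known training partners."""
    idx = ckpt.index
    if tf_id not in idx:
        raise KeyError(f"unknown TF {tf_id!r}")
    t = idx[tf_id]
    others = np.array([i for i in range(len(ckpt.node_ids)) if i != t])
    pairs = np.column_stack([np.full(len(others), t), others])
    scores = ckpt.pair_scores(pairs)
    known = set()
    if exclude_known and len(ckpt.train_pos):
        for i, j in ckpt.train_pos:
            if i == t:
                known.add(j)
            elif j == t:
                known.add(i)
    keep = [k for k, o in enumerate(others) if o not in known]
    order = sorted(keep, key=lambda k: (-scores[k], ckpt.node_ids[others[k]]))[:top_n]
    return pd.DataFrame({
        "gene": [ckpt.node_ids[others[k]] for k in order],
        "score": [float(scores[k]) for k in order],
    })
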