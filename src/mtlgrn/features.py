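"""Node feature construction: promoter k-mer counts, one-hot biological
attributes, per-block PCA reduction and concatenation.

Each gene's feature vector is ``X = D(P) (+) D(B)`` where P is its k-mer
count vector over the 4^k lexicographic k-mer alphabet, B the concatenated
one-hot encoding of its categorical attributes, and D a PCA fitted
independently per block (centering only, no unit scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_alphabet(k: int) -> list[str]:
    """All k-mers over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class KmerVector:
    """Counts of overlapping k-mers; windows containing 'N' are skipped."""

    counts: np.ndarray
    k: int

    def __post_init__(self):
        if self.counts.shape != (4 ** self.k,):
            raise ValueError("k-mer vector has wrong length")
        if (self.counts < 0).any():
            raise ValueError("k-mer counts must be non-negative")


def kmer_encode(sequence: str, k: int) -> KmerVector:
    """Tally all overlapping length-k windows of `sequence`.

    Vectorized: bases are mapped to 2-bit codes and window indices built by a
    rolling polynomial; any window touching an 'N' is excluded from the tally.
    """
    seq = sequence.upper()
    if k < 1 or k > len(seq):
        raise ValueError(f"k={k} out of range for sequence of length {len(seq)}")
    codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    n_win = len(seq) - k + 1
    # window index = sum codes[i+t] * 4^(k-1-t)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    idx = (windows[valid] * weights).sum(axis=1)
    counts = np.bincount(idx, minlength=4 ** k).astype(np.int64)
    assert counts.sum() == valid.sum() == n_win - (~valid).sum()
    return KmerVector(counts, k)


def kmer_matrix(promoters: dict[str, str], gene_order: list[str], k: int,
                normalize: bool = False) -> np.ndarray:
    """Stack per-gene k-mer vectors in `gene_order`; optionally as frequencies."""
    rows = []
    for g in gene_order:
        if g not in promoters:
            raise KeyError(f"no promoter sequence for gene {g!r}")
        v = kmer_encode(promoters[g], k).counts.astype(float)
        if normalize:
            total = v.sum()
            v = v / total if total > 0 else v
        rows.append(v)
    return np.vstack(rows)


@dataclass
class OneHotBlock:
    """Indicator bits over the (lexicographically ordered) categories of one
    attribute; missing values encode as all zeros, multi-label values
    ('|'-separated) may set several bits."""

    feature: str
    categories: list[str]


class AttributeEncoder:
    """Fit/transform one-hot encoder for a categorical gene attribute table.

    Category order within each block is lexicographic; block order follows
    `feature_order`.  Unseen categories at transform time raise.
    """

    MISSING = {"", "na", "nan", "none"}

    def __init__(self, feature_order: list[str] | None = None):
        self.feature_order = feature_order
        self.blocks: list[OneHotBlock] | None = None

    @staticmethod
    def _labels(cell) -> list[str]:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return []
        s = str(cell).strip()
        if s.lower() in AttributeEncoder.MISSING:
            return []
        return [t.strip() for t in s.split("|") if t.strip()]

    def fit(self, table: pd.DataFrame) -> "AttributeEncoder":
        order = self.feature_order or list(table.columns)
        missing_cols = [c for c in order if c not in table.columns]
        if missing_cols:
            raise KeyError(f"attribute table lacks features {missing_cols}")
        self.feature_order = order
        self.blocks = []
        for feat in order:
            cats: set[str] = set()
            for cell in table[feat]:
                cats.update(self._labels(cell))
            if not cats:
                raise ValueError(f"attribute {feat!r} has no observed categories")
            self.blocks.append(OneHotBlock(feat, sorted(cats)))
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if self.blocks is None:
            raise RuntimeError("encoder is not fitted")
        n = len(table)
        cols = []
        for block in self.blocks:
            sub = np.zeros((n, len(block.categories)))
            cat_idx = {c: j for j, c in enumerate(block.categories)}
            for i, cell in enumerate(table[block.feature]):
                for lab in self._labels(cell):
                    if lab not in cat_idx:
                        raise ValueError(
                            f"unseen category {lab!r} for attribute {block.feature!r}")
                    sub[i, cat_idx[lab]] = 1.0
            cols.append(sub)
        return np.hstack(cols)


def onehot_encode(table: pd.DataFrame, feature_order: list[str] | None = None,
                  encoder: AttributeEncoder | None = None
                  ) -> tuple[np.ndarray, AttributeEncoder]:
    """One-hot encode an attribute table; returns (matrix B, fitted encoder).

    Pass a fitted `encoder` to transform new genes with the training-time
    category sets.
    """
    if encoder is None:
        encoder = AttributeEncoder(feature_order).fit(table)
    return encoder.transform(table), encoder


@dataclass
class FeatureMatrix:
    """Concatenated reduced node features, rows aligned to the graph node order.

    `block_spec` records the provenance and width of each column block;
    `fitted_reducers` stores the PCA bases so held-out genes can be projected
    with the training-time transform.
    """

    values: np.ndarray
    block_spec: list[tuple[str, int]]
    fitted_reducers: dict = field(default_factory=dict)

    def __post_init__(self):
        if sum(w for _, w in self.block_spec) != self.values.shape[1]:
            raise ValueError("block widths do not sum to feature width")


def _reduce(block: np.ndarray, d: int, fit: bool, store: dict, name: str) -> np.ndarray:
    cap = min(block.shape)
    if d > cap:
        raise ValueError(
            f"{name}: requested {d} components but input supports at most {cap}")
    if fit:
        pca = PCA(n_components=d, svd_solver="full")
        out = pca.fit_transform(block)
        store[name] = pca
    else:
        if name not in store:
            raise RuntimeError(f"{name}: no fitted reducer available in transform mode")
        out = store[name].transform(block)
    return out


def reduce_and_concat(promoter_vectors: np.ndarray, attribute_vectors: np.ndarray,
                      d_promoter: int = 32, d_attr: int = 32, fit: bool = True,
                      reducers: dict | None = None) -> FeatureMatrix:
    """PCA-reduce the two blocks independently and concatenate columns."""
    P = np.asarray(promoter_vectors, dtype=float)
    B = np.asarray(attribute_vectors, dtype=float)
    if P.shape[0] != B.shape[0]:
        raise ValueError("promoter and attribute blocks are not row-aligned")
    reducers = {} if (fit or reducers is None) else dict(reducers)
    store: dict = reducers if not fit else {}
    xp = _reduce(P, d_promoter, fit, store, "promoter")
    xb = _reduce(B, d_attr, fit, store, "attribute")
    return FeatureMatrix(
        np.hstack([xp, xb]),
        [("promoter-reduced", d_promoter), ("attribute-reduced", d_attr)],
        store,
    )


def make_random_features(n: int, d: int, seed: int) -> FeatureMatrix:
    """i.i.d. standard-normal node features (ablation baseline)."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    rng = np.random.default_rng(seed)
    return FeatureMatrix(rng.standard_normal((n, d)), [("random", d)])
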