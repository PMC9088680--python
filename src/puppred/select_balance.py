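"""Chi-square feature selection and class balancing (RUS / SMOTE).

Fused feature vectors are high-dimensional and partly redundant; the
chi-square selector scores each non-negative feature by how unevenly its
mass splits across the two classes and keeps the top K (default 600).
Class imbalance is handled by random under-sampling of the majority class
(RUS) and/or Chawla-style SMOTE over-sampling of the minority class.

Columns that can be negative (property scales, embeddings) are shifted to
[0, 1] per column by a fitted min-max transform before scoring; the fitted
shift is part of the model bundle and is re-applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_selection import chi2 as _sk_chi2
from sklearn.neighbors import NearestNeighbors

from .encoders import FeatureMatrix


@dataclass
class SelectionResult:
    """Per-feature chi-square scores and the induced ranking."""

    scores: np.ndarray
    ranking: np.ndarray  # feature indices by descending score, ties by column order
    selected_k: int
    selected_names: list[str]


@dataclass
class BalanceConfig:
    """How to balance a labeled sample.

    ``target_ratio`` is the desired positives:negatives ratio (1.0 = equal).
    ``rus_ratio`` is the intermediate ratio after the RUS step of the
    combined ``rus_then_smote`` strategy (default 0.5, i.e. negatives
    under-sampled to 2:1 before SMOTE brings positives to target).
    """

    strategy: str = "rus_then_smote"
    target_ratio: float = 1.0
    rus_ratio: float = 0.5
    smote_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in {"rus", "smote", "rus_then_smote", "none"}:
            raise ValueError(f"unknown balancing strategy {self.strategy!r}")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be > 0")
        if self.smote_neighbors < 1:
            raise ValueError("smote_neighbors must be >= 1")


# ---------------------------------------------------------------------------
# Chi-square selection
# ---------------------------------------------------------------------------

class NonnegativeShifter:
    """Per-column min-max shift to [0, 1] for columns containing negatives.

    Columns already non-negative are passed through unchanged so that
    frequency-style features keep their scale.  Constant negative columns
    map to 0.  Values outside the fitted range (possible at prediction
    time) are clipped to [0, 1].
    """

    def __init__(self) -> None:
        self.cols_: np.ndarray | None = None
        self.lo_: np.ndarray | None = None
        self.span_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "NonnegativeShifter":
        X = np.asarray(X, dtype=np.float64)
        self.cols_ = np.where((X < 0).any(axis=0))[0]
        sub = X[:, self.cols_]
        self.lo_ = sub.min(axis=0)
        span = sub.max(axis=0) - self.lo_
        span[span == 0] = 1.0
        self.span_ = span
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.cols_ is None:
            raise RuntimeError("NonnegativeShifter not fitted")
        X = np.asarray(X, dtype=np.float64).copy()
        if len(self.cols_):
            X[:, self.cols_] = np.clip((X[:, self.cols_] - self.lo_) / self.span_, 0.0, 1.0)
        return X

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_dict(self) -> dict:
        return {
            "cols": self.cols_.tolist(),
            "lo": self.lo_.tolist(),
            "span": self.span_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NonnegativeShifter":
        obj = cls()
        obj.cols_ = np.asarray(d["cols"], dtype=np.int64)
        obj.lo_ = np.asarray(d["lo"], dtype=np.float64)
        obj.span_ = np.asarray(d["span"], dtype=np.float64)
        return obj


def chi2_scores(features: FeatureMatrix, labels) -> SelectionResult:
    """Chi-square statistic of observed vs expected class-conditional feature mass.

    The standard non-negative-feature selector: for each feature, the
    observed per-class sums of the feature are compared against the sums
    expected from the class priors.  Higher scores mean a stronger
    class/feature association; a constant (or all-zero) column scores 0.
    Ranking ties are broken by original column order.
    """
    y = np.asarray(labels, dtype=np.int64)
    if set(np.unique(y)) - {0, 1} or len(np.unique(y)) < 2:
        raise ValueError("labels must be binary with both classes present")
    X = features.values
    if (X < 0).any():
        bad = [features.feature_names[i] for i in np.where((X < 0).any(axis=0))[0][:10]]
        raise ValueError(
            f"chi2_scores requires non-negative features; offending columns include {bad}; "
            "apply NonnegativeShifter first"
        )
    scores, _ = _sk_chi2(X, y)
    scores = np.nan_to_num(np.asarray(scores, dtype=np.float64), nan=0.0)
    # stable sort on negated scores keeps original column order on ties
    ranking = np.argsort(-scores, kind="stable")
    return SelectionResult(
        scores=scores,
        ranking=ranking,
        selected_k=len(ranking),
        selected_names=[features.feature_names[i] for i in ranking],
    )


def select_top_k(result: SelectionResult, features: FeatureMatrix, k: int) -> FeatureMatrix:
    """Restrict the matrix to the k top-ranked columns, in ranking order."""
    if not 1 <= k <= features.n_features:
        raise ValueError(f"k={k} out of range 1..{features.n_features}")
    return features.subset_columns(result.ranking[:k])


def selection_report_tsv(result: SelectionResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_name\tscore\trank\n")
        for rank, idx in enumerate(result.ranking, 1):
            fh.write(f"{result.selected_names[rank - 1]}\t{result.scores[idx]!r}\t{rank}\n")


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def _counts(y: np.ndarray) -> tuple[int, int]:
    return int((y == 1).sum()), int((y == 0).sum())


def random_undersample(
    features: FeatureMatrix, labels, cfg: BalanceConfig
) -> tuple[FeatureMatrix, np.ndarray]:
    """Delete majority-class rows uniformly at random until the ratio holds.

    The minority class is untouched; row order of kept samples is preserved.
    Already-satisfied input is returned unchanged.
    """
    y = np.asarray(labels, dtype=np.int64)
    n_pos, n_neg = _counts(y)
    r = cfg.target_ratio  # desired pos:neg
    if n_neg > 0 and n_pos / n_neg < r:
        # negatives are in excess: keep round(n_pos / r) of them
        keep_neg = int(round(n_pos / r))
        if keep_neg > n_neg:
            raise ValueError("random_undersample: ratio unreachable by deletion")
        if keep_neg == 0:
            raise ValueError("random_undersample: ratio would delete all negatives")
        maj_idx, maj_keep = np.where(y == 0)[0], keep_neg
    elif n_pos > 0 and (n_neg == 0 or n_pos / n_neg > r):
        keep_pos = int(round(r * n_neg))
        if keep_pos > n_pos:
            raise ValueError("random_undersample: ratio unreachable by deletion")
        if keep_pos == 0:
            raise ValueError("random_undersample: ratio would delete all positives")
        maj_idx, maj_keep = np.where(y == 1)[0], keep_pos
    else:
        return features, y
    rng = np.random.default_rng(cfg.seed)
    kept_maj = rng.choice(maj_idx, size=maj_keep, replace=False)
    keep = np.zeros(len(y), dtype=bool)
    keep[kept_maj] = True
    keep[np.setdiff1d(np.arange(len(y)), maj_idx)] = True
    idx = np.where(keep)[0]
    return features.subset_rows(idx), y[idx]


def smote_oversample(
    features: FeatureMatrix, labels, cfg: BalanceConfig
) -> tuple[FeatureMatrix, np.ndarray]:
    """Chawla-style SMOTE: synthesize minority rows along neighbor segments.

    Each synthetic point is x + u * (x_nn - x) with u ~ U[0, 1] and x_nn one
    of the ``smote_neighbors`` nearest minority neighbors of a minority
    parent x.  Synthetic rows get sample ids prefixed ``synth:``.
    """
    y = np.asarray(labels, dtype=np.int64)
    n_pos, n_neg = _counts(y)
    r = cfg.target_ratio
    # the minority class is whichever is short of the target ratio
    if n_neg > 0 and n_pos / n_neg < r:
        minority, need = 1, int(round(r * n_neg)) - n_pos
    elif n_pos > 0 and (n_neg == 0 or n_pos / n_neg > r):
        minority, need = 0, int(round(n_pos / r)) - n_neg
    else:
        return features, y
    if need <= 0:
        return features, y
    min_idx = np.where(y == minority)[0]
    if len(min_idx) < 2:
        raise ValueError("smote_oversample: minority class must have >= 2 samples")
    Xmin = features.values[min_idx]
    k = min(cfg.smote_neighbors, len(min_idx) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    neigh = nn.kneighbors(Xmin, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(cfg.seed)
    parents = rng.integers(0, len(min_idx), size=need)
    picks = rng.integers(0, k, size=need)
    u = rng.random(size=need)
    x = Xmin[parents]
    x_nn = Xmin[neigh[parents, picks]]
    synth = x + u[:, None] * (x_nn - x)

    new_ids = list(features.sample_ids) + [
        f"synth:{features.sample_ids[min_idx[p]]}:{i}" for i, p in enumerate(parents)
    ]
    out = FeatureMatrix(
        feature_names=list(features.feature_names),
        values=np.vstack([features.values, synth]),
        sample_ids=new_ids,
    )
    return out, np.concatenate([y, np.full(need, minority, dtype=np.int64)])


def balance(
    features: FeatureMatrix, labels, cfg: BalanceConfig
) -> tuple[FeatureMatrix, np.ndarray]:
    """Apply the configured balancing strategy.

    ``rus_then_smote`` first under-samples the majority to ``rus_ratio``,
    then SMOTEs the minority up to ``target_ratio``.
    """
    y = np.asarray(labels, dtype=np.int64)
    if cfg.strategy == "none":
        return features, y
    if cfg.strategy == "rus":
        return random_undersample(features, y, cfg)
    if cfg.strategy == "smote":
        return smote_oversample(features, y, cfg)
    # RUS step only applies when negatives exceed the intermediate ratio;
    # on already-balanced input it is a no-op and SMOTE finishes the job.
    n_pos, n_neg = _counts(y)
    if n_neg > 0 and n_pos / n_neg < cfg.rus_ratio:
        step1 = BalanceConfig(
            strategy="rus",
            target_ratio=cfg.rus_ratio,
            smote_neighbors=cfg.smote_neighbors,
            seed=cfg.seed,
        )
        X1, y1 = random_undersample(features, y, step1)
    else:
        X1, y1 = features, y
    step2 = BalanceConfig(
        strategy="smote",
        target_ratio=cfg.target_ratio,
        smote_neighbors=cfg.smote_neighbors,
        seed=cfg.seed + 1,
    )
    return smote_oversample(X1, y1, step2)
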