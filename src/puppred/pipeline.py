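"""The two prediction pipelines and their persisted model bundles.

Protein-level: GO-KNN neighbor fractions (10) fused with the three-model
k-mer CBOW embedding (896) into a 906-dimensional vector, balanced with
RUS + SMOTE, classified with gradient boosting by default.

Site-level: the five window encoders (TPC, AAI, One-Hot, PseAAC, CKSAAP)
fused with the window-peptide embedding, chi-square top-K selection
(default K=600) fitted inside each fold, stacking ensemble by default.

During cross-validation everything fitted on data — embeddings, GO-KNN
neighbor labels, the non-negative shift, chi-square ranking, balancing — is
fold-local; the final bundle fits them once on the full training set.
"""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from itertools import count
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .classify import (
    ClassifierSpec,
    MetricsReport,
    cross_validate_indexed,
    make_classifier,
)
from .encoders import FeatureMatrix, encode_windows, fuse_features
from .embedding import (
    EmbeddingModel,
    embed_matrix,
    embedding_feature_names,
    train_fused_models,
)
from .goknn import GoKnnConfig, goknn_feature_names, goknn_matrix
from .select_balance import (
    BalanceConfig,
    NonnegativeShifter,
    balance as apply_balance,
    chi2_scores,
    select_top_k,
)
from .windows import (
    DEFAULT_DELTA,
    ProteinRecord,
    SiteWindow,
    extract_windows,
)

logger = logging.getLogger(__name__)

SITE_ENCODERS_DEFAULT = ("tpc", "aai", "onehot", "pseaac", "cksaap")
DEFAULT_SELECTION_K = 600


def _fold_seed(base: int, fold: int) -> int:
    return (base * 1009 + fold) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Protein-level pipeline
# ---------------------------------------------------------------------------

def protein_features(
    query_ids: list[str],
    sequences: list[str],
    train_ids: list[str],
    train_labels,
    annotations: dict[str, set[str]],
    models: list[EmbeddingModel],
    go_cfg: GoKnnConfig | None = None,
) -> FeatureMatrix:
    """GO-KNN fractions fused with the 896-D embedding (906 columns)."""
    go_cfg = go_cfg or GoKnnConfig()
    go_part = FeatureMatrix(
        feature_names=goknn_feature_names(go_cfg),
        values=goknn_matrix(query_ids, train_ids, train_labels, annotations, go_cfg),
        sample_ids=list(query_ids),
    )
    emb_part = FeatureMatrix(
        feature_names=embedding_feature_names(models),
        values=embed_matrix(sequences, models),
        sample_ids=list(query_ids),
    )
    return fuse_features([go_part, emb_part], prefixes=["goknn", "emb"])


def protein_cv(
    proteins: list[ProteinRecord],
    labels,
    annotations: dict[str, set[str]],
    *,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    balance_cfg: BalanceConfig | None = None,
    go_cfg: GoKnnConfig | None = None,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> tuple[MetricsReport, np.ndarray]:
    """Stratified CV of the protein pipeline with fold-local featurization."""
    spec = spec or ClassifierSpec(name="xgb", seed=seed)
    balance_cfg = balance_cfg if balance_cfg is not None else BalanceConfig(seed=seed)
    embed_kwargs = embed_kwargs or {}
    y = np.asarray(labels, dtype=np.int64)
    ids = [p.id for p in proteins]
    seqs = [p.sequence for p in proteins]
    fold_counter = count()

    def featurizer(tr, va):
        fold = next(fold_counter)
        models = train_fused_models(
            [seqs[i] for i in tr], seed=_fold_seed(seed, fold), **embed_kwargs
        )
        tr_ids = [ids[i] for i in tr]
        Xtr = protein_features(
            tr_ids, [seqs[i] for i in tr], tr_ids, y[tr], annotations, models, go_cfg
        )
        Xva = protein_features(
            [ids[i] for i in va], [seqs[i] for i in va], tr_ids, y[tr], annotations, models, go_cfg
        )
        return Xtr, Xva

    return cross_validate_indexed(
        spec, y, featurizer, folds=folds, balance_cfg=balance_cfg, seed=seed
    )


# ---------------------------------------------------------------------------
# Site-level pipeline
# ---------------------------------------------------------------------------

def site_static_features(windows: list[SiteWindow], encoders=SITE_ENCODERS_DEFAULT) -> FeatureMatrix:
    """The stateless window encoders, fused (no embedding block)."""
    delta = windows[0].delta
    ids = [f"{w.protein_id}:{w.center_pos}" for w in windows]
    return encode_windows([w.peptide for w in windows], ids, delta, list(encoders))


def site_cv(
    windows: list[SiteWindow],
    *,
    spec: ClassifierSpec | None = None,
    folds: int = 10,
    selection_k: Optional[int] = DEFAULT_SELECTION_K,
    balance_cfg: BalanceConfig | None = None,
    encoders=SITE_ENCODERS_DEFAULT,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> tuple[MetricsReport, np.ndarray]:
    """Stratified CV of the site pipeline.

    The five window encoders are stateless and computed once; the embedding
    block, the shift, the chi-square ranking and any balancing are fitted
    per training fold.
    """
    spec = spec or ClassifierSpec(name="stacking", seed=seed)
    embed_kwargs = embed_kwargs or {}
    y = np.asarray([w.label for w in windows], dtype=np.int64)
    peptides = [w.peptide for w in windows]
    static = site_static_features(windows, encoders)
    if selection_k is not None:
        selection_k = min(selection_k, static.n_features + 896)
    fold_counter = count()

    def featurizer(tr, va):
        fold = next(fold_counter)
        models = train_fused_models(
            [peptides[i] for i in tr], seed=_fold_seed(seed, fold), **embed_kwargs
        )
        emb_names = embedding_feature_names(models)

        def block(idx):
            emb = FeatureMatrix(
                feature_names=emb_names,
                values=embed_matrix([peptides[i] for i in idx], models),
                sample_ids=[static.sample_ids[i] for i in idx],
            )
            return fuse_features([static.subset_rows(idx), emb], prefixes=["win", "emb"])

        return block(tr), block(va)

    return cross_validate_indexed(
        spec,
        y,
        featurizer,
        folds=folds,
        balance_cfg=balance_cfg,
        selection_k=selection_k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fitted pipeline persisted as a directory.

    Contents: the fitted classifier (pickle), the embedding models
    (TSV + JSON pairs), the fitted non-negative shift, the selected feature
    indices (site task), the training GO table and labels (protein task),
    and a metadata manifest with task, delta, seeds and package version.
    """

    meta: dict
    classifier: object
    models: list[EmbeddingModel]
    shifter: NonnegativeShifter
    selected_idx: Optional[np.ndarray] = None
    train_ids: Optional[list[str]] = None
    train_labels: Optional[np.ndarray] = None
    annotations: Optional[dict[str, set[str]]] = None

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=1, sort_keys=True)
        with open(outdir / "classifier.pkl", "wb") as fh:
            pickle.dump(self.classifier, fh)
        for m in self.models:
            m.save(outdir / f"embedding_k{m.kmer_length}")
        with open(outdir / "shifter.json", "w") as fh:
            json.dump(self.shifter.to_dict(), fh)
        if self.selected_idx is not None:
            with open(outdir / "selection.json", "w") as fh:
                json.dump(self.selected_idx.tolist(), fh)
        if self.train_ids is not None:
            with open(outdir / "train_labels.tsv", "w") as fh:
                fh.write("protein_id\tlabel\n")
                for pid, lab in zip(self.train_ids, self.train_labels):
                    fh.write(f"{pid}\t{int(lab)}\n")
            from .goknn import write_go_table

            write_go_table(self.annotations, outdir / "go.tsv")
        return outdir

    @classmethod
    def load(cls, indir: str | Path) -> "ModelBundle":
        indir = Path(indir)
        with open(indir / "meta.json") as fh:
            meta = json.load(fh)
        with open(indir / "classifier.pkl", "rb") as fh:
            clf = pickle.load(fh)
        models = [
            EmbeddingModel.load(indir / f"embedding_k{k}")
            for k in meta["kmer_lengths"]
        ]
        with open(indir / "shifter.json") as fh:
            shifter = NonnegativeShifter.from_dict(json.load(fh))
        selected = None
        if (indir / "selection.json").exists():
            with open(indir / "selection.json") as fh:
                selected = np.asarray(json.load(fh), dtype=np.int64)
        train_ids = train_labels = annotations = None
        if (indir / "train_labels.tsv").exists():
            from .windows import read_protein_labels
            from .goknn import read_go_table

            lab = read_protein_labels(indir / "train_labels.tsv")
            train_ids = list(lab)
            train_labels = np.asarray([lab[i] for i in train_ids], dtype=np.int64)
            annotations = read_go_table(indir / "go.tsv")
        return cls(
            meta=meta,
            classifier=clf,
            models=models,
            shifter=shifter,
            selected_idx=selected,
            train_ids=train_ids,
            train_labels=train_labels,
            annotations=annotations,
        )


def fit_protein_bundle(
    proteins: list[ProteinRecord],
    labels,
    annotations: dict[str, set[str]],
    *,
    spec: ClassifierSpec | None = None,
    balance_cfg: BalanceConfig | None = None,
    go_cfg: GoKnnConfig | None = None,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> ModelBundle:
    """Fit the protein pipeline on the full training set."""
    spec = spec or ClassifierSpec(name="xgb", seed=seed)
    balance_cfg = balance_cfg if balance_cfg is not None else BalanceConfig(seed=seed)
    y = np.asarray(labels, dtype=np.int64)
    ids = [p.id for p in proteins]
    seqs = [p.sequence for p in proteins]
    models = train_fused_models(seqs, seed=seed, **(embed_kwargs or {}))
    X = protein_features(ids, seqs, ids, y, annotations, models, go_cfg)
    shifter = NonnegativeShifter().fit(X.values)
    X = FeatureMatrix(X.feature_names, shifter.transform(X.values), X.sample_ids)
    Xb, yb = apply_balance(X, y, balance_cfg)
    clf = make_classifier(spec)
    clf.fit(Xb.values, yb)
    meta = {
        "task": "protein",
        "classifier": spec.name,
        "seed": seed,
        "kmer_lengths": sorted(m.kmer_length for m in models),
        "threshold": 0.5,
        "version": __version__,
        "n_train": len(y),
    }
    return ModelBundle(
        meta=meta,
        classifier=clf,
        models=models,
        shifter=shifter,
        train_ids=ids,
        train_labels=y,
        annotations=annotations,
    )


def fit_site_bundle(
    windows: list[SiteWindow],
    *,
    spec: ClassifierSpec | None = None,
    selection_k: Optional[int] = DEFAULT_SELECTION_K,
    balance_cfg: BalanceConfig | None = None,
    encoders=SITE_ENCODERS_DEFAULT,
    seed: int = 0,
    embed_kwargs: dict | None = None,
) -> ModelBundle:
    """Fit the site pipeline on the full training set."""
    spec = spec or ClassifierSpec(name="stacking", seed=seed)
    y = np.asarray([w.label for w in windows], dtype=np.int64)
    peptides = [w.peptide for w in windows]
    models = train_fused_models(peptides, seed=seed, **(embed_kwargs or {}))
    static = site_static_features(windows, encoders)
    emb = FeatureMatrix(
        feature_names=embedding_feature_names(models),
        values=embed_matrix(peptides, models),
        sample_ids=static.sample_ids,
    )
    X = fuse_features([static, emb], prefixes=["win", "emb"])
    shifter = NonnegativeShifter().fit(X.values)
    X = FeatureMatrix(X.feature_names, shifter.transform(X.values), X.sample_ids)
    selected = None
    if selection_k is not None:
        selection_k = min(selection_k, X.n_features)
        sel = chi2_scores(X, y)
        selected = sel.ranking[:selection_k]
        X = X.subset_columns(selected)
    if balance_cfg is not None and balance_cfg.strategy != "none":
        X, y = apply_balance(X, y, balance_cfg)
    clf = make_classifier(spec)
    clf.fit(X.values, y)
    meta = {
        "task": "site",
        "classifier": spec.name,
        "seed": seed,
        "delta": windows[0].delta,
        "encoders": list(encoders),
        "kmer_lengths": sorted(m.kmer_length for m in models),
        "threshold": 0.5,
        "version": __version__,
        "n_train": len(windows),
    }
    return ModelBundle(meta=meta, classifier=clf, models=models, shifter=shifter, selected_idx=selected)


def run_protein_pipeline(
    config,
    proteins: list[ProteinRecord],
    labels,
    annotations: dict[str, set[str]],
) -> tuple[MetricsReport, ModelBundle]:
    """Cross-validate and fit the protein pipeline from a RunConfig."""
    from .goknn import GoKnnConfig

    spec = ClassifierSpec(name=config.default_classifier_name(), seed=config.seed)
    bal = BalanceConfig(seed=config.seed)
    if config.balance is not None:
        bal = BalanceConfig(
            strategy=config.balance.strategy,
            target_ratio=config.balance.target_ratio,
            rus_ratio=config.balance.rus_ratio,
            smote_neighbors=config.balance.smote_neighbors,
            seed=config.seed,
        )
    go_cfg = GoKnnConfig(neighbor_counts=tuple(config.go_knn.neighbor_counts))
    common = dict(
        spec=spec,
        balance_cfg=bal,
        go_cfg=go_cfg,
        seed=config.seed,
        embed_kwargs=config.embedding.kwargs(),
    )
    report, _ = protein_cv(proteins, labels, annotations, folds=config.folds, **common)
    bundle = fit_protein_bundle(proteins, labels, annotations, **common)
    return report, bundle


def run_site_pipeline(config, windows: list[SiteWindow]) -> tuple[MetricsReport, ModelBundle]:
    """Cross-validate and fit the site pipeline from a RunConfig."""
    spec = ClassifierSpec(name=config.default_classifier_name(), seed=config.seed)
    bal = None
    if config.balance is not None:
        bal = BalanceConfig(
            strategy=config.balance.strategy,
            target_ratio=config.balance.target_ratio,
            rus_ratio=config.balance.rus_ratio,
            smote_neighbors=config.balance.smote_neighbors,
            seed=config.seed,
        )
    common = dict(
        spec=spec,
        selection_k=config.selection_k,
        balance_cfg=bal,
        encoders=tuple(config.encoders),
        seed=config.seed,
        embed_kwargs=config.embedding.kwargs(),
    )
    report, _ = site_cv(windows, folds=config.folds, **common)
    bundle = fit_site_bundle(windows, **common)
    return report, bundle


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(
    bundle: ModelBundle,
    proteins: list[ProteinRecord],
    annotations: dict[str, set[str]] | None = None,
) -> list[dict]:
    """Score new proteins (protein task) or every K site (site task).

    Returns one row per protein or per candidate lysine, with the score and
    the binary call at the bundle's threshold.  Proteins without a K yield
    no site rows (their K count is simply 0).
    """
    thr = bundle.meta.get("threshold", 0.5)
    if bundle.meta["task"] == "protein":
        if annotations is None:
            raise ValueError("protein-task prediction requires a GO annotation table")
        ids = [p.id for p in proteins]
        X = protein_features(
            ids,
            [p.sequence for p in proteins],
            bundle.train_ids,
            bundle.train_labels,
            {**bundle.annotations, **annotations},
        )
        scores = bundle.classifier.predict_proba(bundle.shifter.transform(X.values))[:, 1]
        return [
            {"protein_id": pid, "score": float(s), "call": int(s >= thr)}
            for pid, s in zip(ids, scores)
        ]

    delta = bundle.meta["delta"]
    windows = []
    for prot in proteins:
        windows.extend(extract_windows(prot, delta))
    if not windows:
        return []
    static = site_static_features(windows, bundle.meta["encoders"])
    emb = FeatureMatrix(
        feature_names=embedding_feature_names(bundle.models),
        values=embed_matrix([w.peptide for w in windows], bundle.models),
        sample_ids=static.sample_ids,
    )
    X = fuse_features([static, emb], prefixes=["win", "emb"])
    vals = bundle.shifter.transform(X.values)
    if bundle.selected_idx is not None:
        vals = vals[:, bundle.selected_idx]
    scores = bundle.classifier.predict_proba(vals)[:, 1]
    return [
        {
            "protein_id": w.protein_id,
            "position": w.center_pos,
            "score": float(s),
            "call": int(s >= thr),
        }
        for w, s in zip(windows, scores)
    ]
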