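"""k-mer word embeddings for protein sequences.

Sequences are split into overlapping k-mers (stride 1) and treated as
sentences.  A continuous-bag-of-words (CBOW) model with negative sampling
is trained per fragment length; three models — fragment lengths 2, 3, 4
paired with vector dimensions 128, 256, 512 — are concatenated into one
896-dimensional per-sequence vector.

The trainer is a compact numpy implementation: per sentence, the context
means of all center positions are formed at once and the input/output
matrices are updated with scatter-adds.  With a fixed seed the result is
bit-reproducible (single-threaded numpy, one RNG stream).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Default (fragment length -> embedding dimension) pairing, ascending in both.
DEFAULT_KMER_DIMS: dict[int, int] = {2: 128, 3: 256, 4: 512}
FUSED_DIM = sum(DEFAULT_KMER_DIMS.values())  # 896


def tokenize(sequence: str, k: int) -> list[str]:
    """Overlapping k-mers with stride 1; exactly L-k+1 tokens."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclass
class EmbeddingModel:
    """A trained k-mer -> dense-vector map of a fixed dimension."""

    kmer_length: int
    dim: int
    vocabulary: dict[str, np.ndarray]
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tok, vec in self.vocabulary.items():
            if len(tok) != self.kmer_length:
                raise ValueError(f"token {tok!r} has length != {self.kmer_length}")
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {tok!r} has shape {vec.shape}, want ({self.dim},)")

    def save(self, prefix: str | Path) -> None:
        """Persist as vocabulary TSV (token + floats) plus JSON metadata."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            for tok in sorted(self.vocabulary):
                vec = self.vocabulary[tok]
                fh.write(tok + "\t" + "\t".join(repr(float(v)) for v in vec) + "\n")
        meta = {"kmer_length": self.kmer_length, "dim": self.dim, **self.training_meta}
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingModel":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        vocab = {}
        with open(prefix.with_suffix(".tsv")) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vocab[parts[0]] = np.asarray([float(x) for x in parts[1:]])
        return cls(
            kmer_length=meta.pop("kmer_length"),
            dim=meta.pop("dim"),
            vocabulary=vocab,
            training_meta=meta,
        )


def train_cbow(
    corpus: list[list[str]],
    dim: int,
    seed: int,
    *,
    window: int = 5,
    epochs: int = 10,
    negatives: int = 5,
    min_count: int = 1,
    learning_rate: float = 0.025,
    batch_positions: int = 256,
) -> EmbeddingModel:
    """Train a CBOW model with negative sampling on tokenized sentences.

    The context of each center token is the surrounding ``window`` tokens on
    each side; the hidden layer is their mean.  For every center position,
    one positive target and ``negatives`` noise tokens (drawn from the
    unigram distribution raised to 3/4) receive sigmoid-gradient updates.
    One SGD step processes a small group of sentences (about
    ``batch_positions`` center positions); context windows never cross
    sentence boundaries.  The learning rate decays linearly over epochs.
    Weights are float32, as is usual for word-embedding training, and all
    updates are deterministic segment-sum scatters.
    """
    if not corpus or all(len(s) == 0 for s in corpus):
        raise ValueError("train_cbow: empty corpus")
    if dim < 1:
        raise ValueError("dim must be >= 1")

    counts: dict[str, int] = {}
    for sent in corpus:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError(f"train_cbow: no token reaches min_count={min_count}")
    tok2id = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    kmer_length = len(vocab[0])

    rng = np.random.default_rng(seed)
    W_in = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float32)
    W_out = np.zeros((V, dim), dtype=np.float32)

    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_p = freq / freq.sum()

    sents = [
        np.fromiter((tok2id[t] for t in sent if t in tok2id), dtype=np.int64)
        for sent in corpus
    ]
    sents = [s for s in sents if len(s) >= 2]
    if not sents:
        # degenerate corpus (single-token sentences): vectors stay at init
        logger.warning("train_cbow: no sentence has >= 2 in-vocabulary tokens")

    def scatter_add(W: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
        # W[idx[m]] += grads[m] with duplicates summed.  Fancy-index += drops
        # duplicate rows, so apply one occurrence per index per pass; indices
        # here are mostly unique, so this usually finishes in 1-2 passes and
        # is far faster than buffered np.add.at.
        while True:
            uniq, first = np.unique(idx, return_index=True)
            W[uniq] += grads[first]
            if len(uniq) == len(idx):
                return
            mask = np.ones(len(idx), dtype=bool)
            mask[first] = False
            idx = idx[mask]
            grads = grads[mask]

    # group sentences into batches and precompute their context geometry;
    # lo/hi index into the concatenated batch but stay inside each sentence
    prepared = []
    group: list[np.ndarray] = []
    group_n = 0
    for s in sents + [None]:
        if s is not None:
            group.append(s)
            group_n += len(s)
        if group and (s is None or group_n >= batch_positions):
            ids = np.concatenate(group)
            lo_parts, hi_parts = [], []
            off = 0
            for g_s in group:
                T = len(g_s)
                pos = np.arange(T)
                lo_parts.append(np.maximum(pos - window, 0) + off)
                hi_parts.append(np.minimum(pos + window + 1, T) + off)
                off += T
            lo = np.concatenate(lo_parts)
            hi = np.concatenate(hi_parts)
            n_ctx = (hi - lo - 1).astype(np.float32)[:, None]  # excludes center
            prepared.append((ids, lo, hi, n_ctx))
            group, group_n = [], 0

    one = np.zeros((1, dim), dtype=np.float32)
    for epoch in range(epochs):
        lr = np.float32(learning_rate * (1.0 - epoch / epochs))
        for ids, lo, hi, n_ctx in prepared:
            E = W_in[ids]
            csum = np.concatenate([one, np.cumsum(E, axis=0)])
            h = (csum[hi] - csum[lo] - E) / n_ctx  # context mean per center

            T = len(ids)
            neg = rng.choice(V, size=(T, negatives), p=noise_p)
            targets = np.concatenate([ids[:, None], neg], axis=1)  # T x (1+neg)
            label = np.zeros((T, 1 + negatives), dtype=np.float32)
            label[:, 0] = 1.0

            tvecs = W_out[targets]  # pre-update output vectors
            score = np.einsum("td,tnd->tn", h, tvecs)
            g = (label - 1.0 / (1.0 + np.exp(-score))) * lr  # T x (1+neg)

            # gradient w.r.t. the hidden layer (from pre-update output vectors)
            eh = np.einsum("tn,tnd->td", g, tvecs) / n_ctx
            # gradient w.r.t. output vectors, scattered by target id
            scatter_add(W_out, targets.ravel(), (g[:, :, None] * h[:, None, :]).reshape(-1, dim))
            # spread the hidden gradient back over each center's context range
            # [lo, hi) via a difference array; subtracting eh removes the
            # center itself from its own range
            diff = np.zeros((T + 1, dim), dtype=np.float32)
            scatter_add(diff, lo, eh)
            scatter_add(diff, hi, -eh)
            upd = np.cumsum(diff[:-1], axis=0) - eh
            scatter_add(W_in, ids, upd)

    vocabulary = {t: W_in[i].astype(np.float64) for t, i in tok2id.items()}
    meta = {
        "epochs": epochs,
        "negatives": negatives,
        "window": window,
        "min_count": min_count,
        "seed": seed,
        "learning_rate": learning_rate,
    }
    return EmbeddingModel(kmer_length=kmer_length, dim=dim, vocabulary=vocabulary, training_meta=meta)


def embed_sequence(sequence: str, model: EmbeddingModel) -> np.ndarray:
    """Mean of the vectors of all in-vocabulary k-mers of the sequence.

    Out-of-vocabulary tokens are skipped; a sequence with no known token
    maps to the zero vector (logged).
    """
    tokens = tokenize(sequence, model.kmer_length)
    vecs = [model.vocabulary[t] for t in tokens if t in model.vocabulary]
    if not vecs:
        logger.warning("embed_sequence: all %d tokens out of vocabulary", len(tokens))
        return np.zeros(model.dim)
    return np.mean(vecs, axis=0)


def embed_fused(sequence: str, models: list[EmbeddingModel]) -> np.ndarray:
    """Concatenate per-model sequence vectors in ascending dimension order.

    With the default three models (dims 128, 256, 512) the output length is
    896 regardless of vocabulary coverage.
    """
    dims = sorted(m.dim for m in models)
    if dims != sorted(DEFAULT_KMER_DIMS.values()):
        raise ValueError(f"embed_fused expects model dims {sorted(DEFAULT_KMER_DIMS.values())}, got {dims}")
    ordered = sorted(models, key=lambda m: m.dim)
    return np.concatenate([embed_sequence(sequence, m) for m in ordered])


def train_fused_models(
    sequences: list[str],
    seed: int,
    *,
    kmer_dims: dict[int, int] | None = None,
    **train_kwargs,
) -> list[EmbeddingModel]:
    """Train one CBOW model per (fragment length, dimension) pair.

    Sequences shorter than a fragment length are skipped for that model.
    Each model gets a distinct sub-seed derived from ``seed``.
    """
    if kmer_dims is None:
        kmer_dims = DEFAULT_KMER_DIMS
    models = []
    for i, (k, dim) in enumerate(sorted(kmer_dims.items())):
        corpus = [tokenize(s, k) for s in sequences if len(s) >= k]
        models.append(train_cbow(corpus, dim=dim, seed=(seed * 97 + i) % (2**31 - 1), **train_kwargs))
    return models


def embed_matrix(sequences: list[str], models: list[EmbeddingModel]) -> np.ndarray:
    """Stack fused embeddings for a list of sequences (n x 896)."""
    return np.vstack([embed_fused(s, models) for s in sequences])


def embedding_feature_names(models: list[EmbeddingModel]) -> list[str]:
    names = []
    for m in sorted(models, key=lambda m: m.dim):
        names.extend(f"k{m.kmer_length}_d{m.dim}_{i}" for i in range(m.dim))
    return names
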