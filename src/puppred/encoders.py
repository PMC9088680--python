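"""Deterministic sequence-to-vector encoders.

Five window/sequence encoders used for site prediction:

* TPC — tripeptide composition over the 21-letter alphabet (9,261 dims).
* One-Hot — 20 bits per window position, X as the all-zero block.
* AAI — 15 amino-acid property scales per position (855 dims at window 57).
* PseAAC — Chou's pseudo-amino-acid composition, 20 + lambda dims.
* CKSAAP — composition of k-spaced amino-acid pairs, 441*(k_max+1) dims.

All encoders are pure functions of their input: identical input gives
bit-identical output.  Residues are ordered ACDEFGHIKLMNPQRSTVWY with the
pseudo-residue X last wherever a 21-letter ordering is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .windows import ALPHABET21, CANONICAL_AA, PAD

_IDX21 = {ch: i for i, ch in enumerate(ALPHABET21)}
_IDX20 = {ch: i for i, ch in enumerate(CANONICAL_AA)}

TPC_DIM = 21 ** 3  # 9,261
CKSAAP_PAIRS = 21 ** 2  # 441


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Samples x named-features numeric matrix.

    The interchange object between encoders, selection/balancing, and the
    classifiers.  Values must be finite; feature names unique.
    """

    feature_names: list[str]
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, d = self.values.shape
        if d != len(self.feature_names):
            raise ValueError(f"{d} columns but {len(self.feature_names)} feature names")
        if n != len(self.sample_ids):
            raise ValueError(f"{n} rows but {len(self.sample_ids)} sample ids")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_columns(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            feature_names=[self.feature_names[i] for i in idx],
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_rows(self, idx: Sequence[int], sample_ids: list[str] | None = None) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            feature_names=list(self.feature_names),
            values=self.values[idx, :],
            sample_ids=sample_ids if sample_ids is not None else [self.sample_ids[i] for i in idx],
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(self.feature_names) + "\n")
            for sid, row in zip(self.sample_ids, self.values):
                fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "sample_id":
                raise ValueError(f"{path}: first column must be sample_id")
            names = header[1:]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(feature_names=names, values=np.asarray(rows, dtype=np.float64), sample_ids=ids)

    def to_npz(self, path: str | Path) -> None:
        """Binary cache: a single .npz with names, ids and the value block."""
        np.savez(
            path,
            feature_names=np.asarray(self.feature_names),
            sample_ids=np.asarray(self.sample_ids),
            values=self.values,
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                feature_names=[str(x) for x in z["feature_names"]],
                values=z["values"],
                sample_ids=[str(x) for x in z["sample_ids"]],
            )


def fuse_features(parts: list[FeatureMatrix], prefixes: list[str] | None = None) -> FeatureMatrix:
    """Column-wise fusion of feature blocks sharing the same sample order.

    Feature names are prefixed per part (``<prefix>:<name>``) so fused
    matrices stay self-describing; a single part is returned unchanged.
    """
    if not parts:
        raise ValueError("no parts to fuse")
    if len(parts) == 1 and prefixes is None:
        return parts[0]
    base = parts[0].sample_ids
    for p in parts[1:]:
        if p.sample_ids != base:
            raise ValueError("sample_ids differ between fused parts")
    if prefixes is None:
        prefixes = [f"part{i}" for i in range(len(parts))]
    if len(prefixes) != len(parts):
        raise ValueError("one prefix per part required")
    names: list[str] = []
    for pre, p in zip(prefixes, parts):
        names.extend(f"{pre}:{n}" for n in p.feature_names)
    return FeatureMatrix(
        feature_names=names,
        values=np.concatenate([p.values for p in parts], axis=1),
        sample_ids=list(base),
    )


# ---------------------------------------------------------------------------
# Property tables
# ---------------------------------------------------------------------------

def _read_property_tsv(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[1:]
        if cols != list(CANONICAL_AA):
            raise ValueError(f"{path}: residue columns must be {CANONICAL_AA}")
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ids, np.asarray(rows, dtype=np.float64)


def _bundled(name: str):
    return resources.files("puppred.data").joinpath(name)


@dataclass
class AAIndexTable:
    """15 amino-acid property scales (rows) x 20 canonical residues (columns).

    ``x_policy`` controls the vector emitted for the pseudo-residue X:
    ``"zeros"`` (default) or ``"mean"`` (per-scale mean over the 20 residues).
    """

    index_ids: list[str]
    values: np.ndarray
    x_policy: str = "zeros"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.index_ids), 20):
            raise ValueError("AAIndexTable must be n_indices x 20")
        if self.x_policy not in {"zeros", "mean"}:
            raise ValueError(f"unknown x_policy {self.x_policy!r}")

    @classmethod
    def from_tsv(cls, path, x_policy: str = "zeros") -> "AAIndexTable":
        ids, vals = _read_property_tsv(path)
        return cls(index_ids=ids, values=vals, x_policy=x_policy)

    @classmethod
    def default(cls, x_policy: str = "zeros") -> "AAIndexTable":
        return cls.from_tsv(_bundled("aaindex15.tsv"), x_policy=x_policy)

    def column(self, residue: str) -> np.ndarray:
        if residue == PAD:
            if self.x_policy == "zeros":
                return np.zeros(len(self.index_ids))
            return self.values.mean(axis=1)
        if residue not in _IDX20:
            raise ValueError(f"residue {residue!r} missing from AAIndexTable")
        return self.values[:, _IDX20[residue]]


@dataclass
class PseAACPropertyTable:
    """Six physicochemical scales used by the PseAAC correlation factors.

    Hydrophobicity, hydrophilicity, side-chain mass, pK1 (alpha-COOH),
    pK2 (alpha-NH3+), and isoelectric point pI.  Rows are standardized to
    zero mean and unit (population) variance over the 20 residues, the usual
    convention before computing sequence-order correlations.
    """

    property_names: list[str]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.property_names), 20):
            raise ValueError("PseAACPropertyTable must be n_properties x 20")

    @classmethod
    def from_tsv(cls, path) -> "PseAACPropertyTable":
        ids, vals = _read_property_tsv(path)
        return cls(property_names=ids, values=vals)

    @classmethod
    def default(cls) -> "PseAACPropertyTable":
        return cls.from_tsv(_bundled("pseaac6.tsv")).standardize()

    def standardize(self) -> "PseAACPropertyTable":
        if self.standardized:
            return self
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)  # population std over 20 residues
        return PseAACPropertyTable(
            property_names=list(self.property_names),
            values=(self.values - mu) / sd,
            standardized=True,
        )


@dataclass
class CksaapConfig:
    k_max: int = 5

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")

    @property
    def dim(self) -> int:
        return CKSAAP_PAIRS * (self.k_max + 1)


@dataclass
class PseAACConfig:
    omega: float = 0.05
    lam: int = 5

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.lam < 1:
            raise ValueError("lam must be >= 1")

    @property
    def dim(self) -> int:
        return 20 + self.lam


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def _check_alphabet21(peptide: str, op: str) -> None:
    bad = set(peptide) - set(ALPHABET21)
    if bad:
        raise ValueError(f"{op}: letters {sorted(bad)} outside the 21-letter alphabet")


def encode_tpc(peptide: str) -> np.ndarray:
    """Tripeptide composition: normalized counts of all length-3 substrings.

    The 9,261 components index tripeptides lexicographically over the
    21-letter alphabet (A..Y, then X); they sum to 1.
    """
    if len(peptide) < 3:
        raise ValueError(f"encode_tpc: peptide length {len(peptide)} < 3")
    _check_alphabet21(peptide, "encode_tpc")
    idx = np.fromiter((_IDX21[c] for c in peptide), dtype=np.int64, count=len(peptide))
    tri = idx[:-2] * 441 + idx[1:-1] * 21 + idx[2:]
    vec = np.bincount(tri, minlength=TPC_DIM).astype(np.float64)
    return vec / vec.sum()


def encode_onehot(peptide: str, delta: int) -> np.ndarray:
    """Per-position 20-bit one-hot blocks; X encodes as all zeros."""
    if len(peptide) != 2 * delta + 1:
        raise ValueError(
            f"encode_onehot: peptide length {len(peptide)} != 2*{delta}+1"
        )
    _check_alphabet21(peptide, "encode_onehot")
    out = np.zeros((len(peptide), 20))
    for i, ch in enumerate(peptide):
        if ch != PAD:
            out[i, _IDX20[ch]] = 1.0
    return out.ravel()


def encode_aai(peptide: str, table: AAIndexTable | None = None) -> np.ndarray:
    """Concatenate, position-major, the property values of each residue."""
    if len(peptide) < 1:
        raise ValueError("encode_aai: empty peptide")
    _check_alphabet21(peptide, "encode_aai")
    if table is None:
        table = AAIndexTable.default()
    return np.concatenate([table.column(ch) for ch in peptide])


def encode_pseaac(
    sequence: str,
    props: PseAACPropertyTable | None = None,
    cfg: PseAACConfig | None = None,
) -> np.ndarray:
    """Chou's pseudo-amino-acid composition (type 1), 20 + lambda components.

    The first 20 components are the residue frequencies f_i down-weighted by
    the sequence-order term; the last lambda components are omega-weighted
    correlation factors theta_j, where

        theta_j = (1/(L-j)) * sum_i Theta(R_i, R_{i+j})
        Theta(a, b) = mean over the 6 standardized properties of (H(b)-H(a))^2

    X residues carry no physicochemical values and are stripped before
    encoding.  All 20 + lambda components sum to 1.
    """
    if cfg is None:
        cfg = PseAACConfig()
    if props is None:
        props = PseAACPropertyTable.default()
    props = props.standardize()
    seq = sequence.replace(PAD, "")
    bad = set(seq) - _IDX20.keys()
    if bad:
        raise ValueError(f"encode_pseaac: unknown residues {sorted(bad)}")
    L = len(seq)
    if L <= cfg.lam:
        raise ValueError(
            f"encode_pseaac: sequence length {L} (after X-stripping) must exceed lambda={cfg.lam}"
        )
    idx = np.fromiter((_IDX20[c] for c in seq), dtype=np.int64, count=L)
    # f_i: normalized residue frequencies
    f = np.bincount(idx, minlength=20).astype(np.float64) / L
    # per-position property profile, L x 6
    H = props.values[:, idx].T
    theta = np.empty(cfg.lam)
    for j in range(1, cfg.lam + 1):
        d = H[j:] - H[:-j]
        theta[j - 1] = np.mean(d * d)  # mean over positions and properties
    denom = f.sum() + cfg.omega * theta.sum()
    return np.concatenate([f / denom, cfg.omega * theta / denom])


def encode_cksaap(peptide: str, cfg: CksaapConfig | None = None) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs for k = 0..k_max.

    For each k, the 441 pair counts over the 21-letter alphabet are divided
    by F_N = L - k - 1 (the number of k-spaced pairs), so each 441-block
    sums to 1.  Blocks are concatenated in ascending k.
    """
    if cfg is None:
        cfg = CksaapConfig()
    L = len(peptide)
    if L <= cfg.k_max + 1:
        raise ValueError(
            f"encode_cksaap: peptide length {L} must exceed k_max+1 = {cfg.k_max + 1}"
        )
    _check_alphabet21(peptide, "encode_cksaap")
    idx = np.fromiter((_IDX21[c] for c in peptide), dtype=np.int64, count=L)
    blocks = []
    for k in range(cfg.k_max + 1):
        pair = idx[: L - k - 1] * 21 + idx[k + 1 :]
        counts = np.bincount(pair, minlength=CKSAAP_PAIRS).astype(np.float64)
        blocks.append(counts / (L - k - 1))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Feature names and registry
# ---------------------------------------------------------------------------

def tpc_feature_names() -> list[str]:
    return ["".join(t) for t in itertools.product(ALPHABET21, repeat=3)]


def onehot_feature_names(delta: int) -> list[str]:
    return [f"pos{p - delta}_{aa}" for p in range(2 * delta + 1) for aa in CANONICAL_AA]


def aai_feature_names(length: int, table: AAIndexTable) -> list[str]:
    return [f"pos{i}_{idx}" for i in range(length) for idx in table.index_ids]


def pseaac_feature_names(cfg: PseAACConfig) -> list[str]:
    return [f"f_{aa}" for aa in CANONICAL_AA] + [f"theta_{j}" for j in range(1, cfg.lam + 1)]


def cksaap_feature_names(cfg: CksaapConfig) -> list[str]:
    return [
        f"k{k}_{a}{b}"
        for k in range(cfg.k_max + 1)
        for a in ALPHABET21
        for b in ALPHABET21
    ]


#: Registry of window encoders selectable by name (used by the pipelines/CLI).
#: Each entry maps a name to (encode_fn(peptide, delta) -> vector, names_fn(delta)).
WINDOW_ENCODERS: dict[str, tuple[Callable, Callable]] = {
    "tpc": (lambda pep, delta: encode_tpc(pep), lambda delta: tpc_feature_names()),
    "onehot": (encode_onehot, onehot_feature_names),
    "aai": (
        lambda pep, delta: encode_aai(pep),
        lambda delta: aai_feature_names(2 * delta + 1, AAIndexTable.default()),
    ),
    "pseaac": (
        lambda pep, delta: encode_pseaac(pep),
        lambda delta: pseaac_feature_names(PseAACConfig()),
    ),
    "cksaap": (
        lambda pep, delta: encode_cksaap(pep),
        lambda delta: cksaap_feature_names(CksaapConfig()),
    ),
}


def encode_windows(
    peptides: list[str],
    sample_ids: list[str],
    delta: int,
    encoder_names: list[str],
) -> FeatureMatrix:
    """Run a subset of the registered window encoders and fuse the blocks."""
    parts = []
    for name in encoder_names:
        if name not in WINDOW_ENCODERS:
            raise KeyError(f"unknown encoder {name!r}; known: {sorted(WINDOW_ENCODERS)}")
        enc, names_fn = WINDOW_ENCODERS[name]
        vals = np.vstack([enc(p, delta) for p in peptides])
        parts.append(
            FeatureMatrix(feature_names=names_fn(delta), values=vals, sample_ids=list(sample_ids))
        )
    return fuse_features(parts, prefixes=list(encoder_names))
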