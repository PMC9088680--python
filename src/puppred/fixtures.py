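"""Synthetic corpora for exercising the full prediction stack.

Real pupylation data needs curated databases and GO annotation services;
the generator below emulates the shapes of that data so every stage runs
offline.  Positive lysine sites carry an implanted upstream motif (a stand-in
for real sequence preference around modified lysines), negative sites are
guaranteed motif-free, and GO term sets are class-correlated: positive
proteins draw each term from an enriched vocabulary half with probability
``class_term_bias`` while negatives draw from it with probability
``1 - class_term_bias``.  At bias 0.5 the two classes are therefore
indistinguishable (a true null), and at bias 1.0 they use disjoint halves.

Everything is a pure function of the config seed: the same config generates
byte-identical FASTA/TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .windows import (
    CANONICAL_AA,
    ProteinRecord,
    SiteWindow,
    extract_windows,
    label_windows,
    write_fasta,
    write_site_table,
)
from .goknn import write_go_table


@dataclass
class FixtureConfig:
    n_proteins: int = 200
    length_range: tuple[int, int] = (60, 120)
    pos_fraction: float = 0.5
    motif: str = "GGQ"
    motif_offset: int = -3  # motif start relative to the central K (upstream)
    motif_prob: float = 1.0
    sites_per_positive: tuple[int, int] = (1, 3)
    go_vocab_size: int = 160
    go_enriched_size: int = 80
    go_terms_per_protein: tuple[int, int] = (3, 10)
    class_term_bias: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.go_vocab_size < 2:
            raise ValueError("counts must be positive")
        if not 0 <= self.motif_prob <= 1 or not 0 <= self.class_term_bias <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.pos_fraction <= 1:
            raise ValueError("pos_fraction must be in [0, 1]")
        if not 0 < self.go_enriched_size < self.go_vocab_size:
            raise ValueError("go_enriched_size must be within the vocabulary")
        lo = self.motif_offset
        hi = self.motif_offset + len(self.motif) - 1
        if lo <= 0 <= hi:
            raise ValueError("motif region must not cover the central K")
        if "K" in self.motif:
            raise ValueError("motif must not contain K (it would create new sites)")


def _go_vocab(cfg: FixtureConfig) -> tuple[list[str], list[str]]:
    terms = [f"GO:{n:07d}" for n in range(1, cfg.go_vocab_size + 1)]
    return terms[: cfg.go_enriched_size], terms[cfg.go_enriched_size :]


def generate_proteins(
    cfg: FixtureConfig,
) -> tuple[list[ProteinRecord], set[tuple[str, int]], dict[str, set[str]]]:
    """Generate labeled proteins, a positive-site table, and a GO table.

    Proteins are uniform-random over the 20 canonical residues.  A
    ``pos_fraction`` of proteins is positive; each positive protein gets
    1..n positive K sites carrying the motif with probability
    ``motif_prob``.  Every remaining K site is negative and scrubbed of
    chance motif occurrences at the configured offset, so negative windows
    never carry the signal.
    """
    rng = np.random.default_rng(cfg.seed)
    aas = np.asarray(list(CANONICAL_AA))
    n_pos = int(round(cfg.n_proteins * cfg.pos_fraction))
    motif = list(cfg.motif)
    off = cfg.motif_offset
    mlen = len(motif)
    enriched, plain = _go_vocab(cfg)

    proteins: list[ProteinRecord] = []
    site_table: set[tuple[str, int]] = set()
    go_table: dict[str, set[str]] = {}

    for p in range(cfg.n_proteins):
        pid = f"prot{p:04d}"
        is_pos = p < n_pos
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        seq = list(aas[rng.integers(0, 20, size=L)])

        locked: set[int] = set()
        pos_centers: list[int] = []
        if is_pos:
            lo_s, hi_s = cfg.sites_per_positive
            want = int(rng.integers(lo_s, hi_s + 1))
            # candidate centers must fit the motif region inside the sequence
            cand = [
                i
                for i in range(L)
                if 0 <= i + off and i + off + mlen <= L
            ]
            rng.shuffle(cand)
            for i in cand:
                if len(pos_centers) == want:
                    break
                region = set(range(i + off, i + off + mlen))
                if region & locked or i in locked or any(c in region for c in pos_centers):
                    continue
                seq[i] = "K"
                if rng.random() < cfg.motif_prob:
                    for j, ch in zip(range(i + off, i + off + mlen), motif):
                        seq[j] = ch
                pos_centers.append(i)
                locked |= region | {i}
            for i in pos_centers:
                site_table.add((pid, i + 1))

        # scrub chance motif occurrences upstream of negative K sites
        for i in range(L):
            if seq[i] != "K" or i in pos_centers:
                continue
            lo, hi = i + off, i + off + mlen
            if lo < 0 or hi > L:
                continue
            if seq[lo:hi] == motif:
                free = [j for j in range(lo, hi) if j not in locked and j != i]
                # replacement letters outside the motif alphabet (and not K)
                # can only destroy motif matches, never create one elsewhere
                choices = [c for c in CANONICAL_AA if c not in cfg.motif and c != "K"]
                if free:
                    seq[free[0]] = choices[int(rng.integers(0, len(choices)))]
                else:
                    seq[i] = choices[0]  # motif region locked: retire this candidate K

        proteins.append(ProteinRecord(id=pid, sequence="".join(seq), label=int(is_pos)))

        # class-correlated GO terms (symmetric bias; 0.5 is exactly null)
        n_terms = int(rng.integers(cfg.go_terms_per_protein[0], cfg.go_terms_per_protein[1] + 1))
        p_enriched = cfg.class_term_bias if is_pos else 1.0 - cfg.class_term_bias
        terms: set[str] = set()
        while len(terms) < n_terms:
            pool = enriched if rng.random() < p_enriched else plain
            terms.add(pool[int(rng.integers(0, len(pool)))])
        go_table[pid] = terms

    return proteins, site_table, go_table


def negatives_for_ratio(n_pos: int, ratio: float | str) -> int:
    """Number of negatives matching a positives:negatives ratio.

    ``ratio`` may be a float (positives per negative) or a string like
    ``"1:5.6"``; e.g. 201 positives at 1:5.6 require 1126 negatives.
    """
    if isinstance(ratio, str):
        a, b = ratio.split(":")
        ratio = float(a) / float(b)
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return int(round(n_pos / ratio))


def generate_ratio_dataset(
    cfg: FixtureConfig,
    ratio: float | str = 1.0,
    delta: int = 28,
) -> tuple[list[SiteWindow], list[ProteinRecord], dict[str, set[str]]]:
    """Labeled site windows at an exact positives:negatives ratio.

    All positive windows are kept; negatives are sub-sampled (seeded) down
    to the requested count.  An unreachable ratio (more negatives requested
    than exist) is a contract error.
    """
    proteins, site_table, go_table = generate_proteins(cfg)
    windows: list[SiteWindow] = []
    for prot in proteins:
        windows.extend(label_windows(extract_windows(prot, delta), site_table))
    pos = [w for w in windows if w.label == 1]
    neg = [w for w in windows if w.label == 0]
    if not pos:
        raise ValueError("generate_ratio_dataset: no positive windows generated")
    n_neg = negatives_for_ratio(len(pos), ratio)
    if n_neg > len(neg):
        raise ValueError(
            f"generate_ratio_dataset: ratio needs {n_neg} negatives, only {len(neg)} exist"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    keep = rng.choice(len(neg), size=n_neg, replace=False)
    sampled = [neg[i] for i in sorted(keep)]
    return pos + sampled, proteins, go_table


def write_fixture_dir(cfg: FixtureConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize a fixture corpus as FASTA + TSV files.

    Emits ``proteins.fasta``, ``sites.tsv`` (positive K positions),
    ``protein_labels.tsv`` and ``go.tsv``; all parse losslessly through the
    package readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, site_table, go_table = generate_proteins(cfg)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "sites": outdir / "sites.tsv",
        "labels": outdir / "protein_labels.tsv",
        "go": outdir / "go.tsv",
    }
    write_fasta(proteins, paths["fasta"])
    write_site_table(sorted(site_table), paths["sites"])
    with open(paths["labels"], "w") as fh:
        fh.write("protein_id\tlabel\n")
        for prot in proteins:
            fh.write(f"{prot.id}\t{prot.label}\n")
    write_go_table(go_table, paths["go"])
    return paths
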