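"""Lysine-centered sequence windows.

Site-level prediction operates on fixed-length peptides theta_delta(K): a
window of 2*delta+1 residues centered on a candidate lysine, padded with the
pseudo-residue ``X`` wherever the protein ends before the window does. The
default half-width is delta=28 (window length 57), the size at which window
scans of pupylation substrates predict best.

Coordinates are 1-based and inclusive throughout (R_1 ... R_L).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical residues in alphabetical one-letter order (A first, Y last).
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: The padding / pseudo-residue letter.
PAD = "X"
#: 21-letter alphabet used by window-level encoders: canonical residues then X.
ALPHABET21 = CANONICAL_AA + PAD

DEFAULT_DELTA = 28

_CANONICAL_SET = frozenset(CANONICAL_AA)
_ALPHABET21_SET = frozenset(ALPHABET21)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty sequence, no header)."""


class SiteTableError(ValueError):
    """Raised when a site-label table row contradicts the sequences."""


@dataclass
class ProteinRecord:
    """A protein sequence P = R_1 R_2 ... R_L with an optional binary label.

    After sanitization the sequence is over the 21-letter alphabet: the 20
    canonical residues, plus X standing for any ambiguity/unknown code.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET21_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-canonical letters {sorted(bad)}; "
                "sanitize with sanitize_sequence() first"
            )


@dataclass
class SiteWindow:
    """A candidate-site peptide of length 2*delta+1 centered on a lysine.

    ``center_pos`` is the 1-based index of the central K in the parent
    protein.  Non-central letters come from the 21-letter alphabet (the 20
    canonical residues plus the padding letter X).
    """

    protein_id: str
    center_pos: int
    peptide: str
    delta: int
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.peptide) != 2 * self.delta + 1:
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: peptide length "
                f"{len(self.peptide)} != 2*{self.delta}+1"
            )
        if self.peptide[self.delta] != "K":
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: center residue "
                f"{self.peptide[self.delta]!r} is not K"
            )
        bad = set(self.peptide) - _ALPHABET21_SET
        if bad:
            raise ValueError(
                f"window {self.protein_id}:{self.center_pos}: letters {sorted(bad)} "
                "outside the 21-letter alphabet"
            )


def sanitize_sequence(raw: str, *, protein_id: str = "?") -> str:
    """Uppercase and map non-canonical letters (B, J, O, U, Z, X, '*', gaps) to X.

    The pipeline's 21-letter alphabet already contains the padding letter X,
    so ambiguous or unknown residues are absorbed rather than rejected.  A
    warning is logged once per offending protein.
    """
    seq = raw.upper().replace("-", "").replace(".", "")
    out = []
    replaced = set()
    for ch in seq:
        if ch in _CANONICAL_SET:
            out.append(ch)
        else:
            replaced.add(ch)
            out.append(PAD)
    if replaced:
        logger.warning(
            "protein %s: mapped non-canonical letters %s to X",
            protein_id,
            sorted(replaced),
        )
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into sanitized ProteinRecords.

    Sequences are uppercased; letters outside the 20-residue alphabet are
    mapped to X by :func:`sanitize_sequence` and survive into windows, where
    they are legal.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = sanitize_sequence(str(entry.seq), protein_id=entry.id)
        if not seq:
            raise FastaParseError(f"entry {entry.id!r} in {path} has an empty sequence")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract_windows(protein: ProteinRecord, delta: int = DEFAULT_DELTA) -> list[SiteWindow]:
    """Extract one window per K residue, X-padded at the protein ends.

    Windows are returned in ascending ``center_pos`` order.  A protein with
    no lysine yields an empty list.
    """
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    seq = protein.sequence
    L = len(seq)
    windows = []
    for i, ch in enumerate(seq):  # i is 0-based; center_pos is i+1
        if ch != "K":
            continue
        lo, hi = i - delta, i + delta + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - L)
        peptide = PAD * left_pad + seq[max(lo, 0) : min(hi, L)] + PAD * right_pad
        windows.append(
            SiteWindow(
                protein_id=protein.id,
                center_pos=i + 1,
                peptide=peptide,
                delta=delta,
            )
        )
    return windows


def read_site_table(path: str | Path) -> set[tuple[str, int]]:
    """Read a site-label TSV (protein_id<TAB>position, 1-based) into a set."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SiteTableError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pid, pos = parts[0], parts[1]
            if pid == "protein_id":  # optional header
                continue
            try:
                sites.add((pid, int(pos)))
            except ValueError as exc:
                raise SiteTableError(f"{path}:{lineno}: non-integer position {pos!r}") from exc
    return sites


def write_site_table(sites: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\n")
        for pid, pos in sites:
            fh.write(f"{pid}\t{pos}\n")


def label_windows(
    windows: list[SiteWindow], site_table: set[tuple[str, int]]
) -> list[SiteWindow]:
    """Assign label 1 to windows listed in the site table, 0 otherwise.

    Every table row must name an existing (protein_id, center_pos) window,
    i.e. a position that actually holds a K; otherwise a SiteTableError is
    raised listing the offending rows.
    """
    keys = {(w.protein_id, w.center_pos) for w in windows}
    referenced_proteins = {w.protein_id for w in windows}
    bad = [
        row
        for row in site_table
        if row not in keys and row[0] in referenced_proteins
    ]
    if bad:
        raise SiteTableError(
            "site table rows do not match a K residue: "
            + ", ".join(f"({p},{q})" for p, q in sorted(bad))
        )
    out = []
    for w in windows:
        out.append(
            SiteWindow(
                protein_id=w.protein_id,
                center_pos=w.center_pos,
                peptide=w.peptide,
                delta=w.delta,
                label=1 if (w.protein_id, w.center_pos) in site_table else 0,
            )
        )
    return out


def windows_to_tsv(windows: Iterable[SiteWindow], path: str | Path) -> None:
    """Export windows as TSV (protein_id, center_pos, peptide, label)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter_pos\tpeptide\tlabel\n")
        for w in windows:
            lab = "" if w.label is None else str(w.label)
            fh.write(f"{w.protein_id}\t{w.center_pos}\t{w.peptide}\t{lab}\n")


def read_protein_labels(path: str | Path) -> dict[str, int]:
    """Read a per-protein label TSV (protein_id<TAB>label in {0,1})."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":
                continue
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise SiteTableError(f"{path}:{lineno}: expected 'id<TAB>0|1'")
            labels[parts[0]] = int(parts[1])
    return labels
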