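"""GO-annotation nearest-neighbor features for protein-level prediction.

Each protein is described by its set of Gene Ontology term identifiers.
The distance between two proteins is the Jaccard distance of their term
sets; a query protein's feature vector is the fraction of positive-labeled
training proteins among its Y nearest neighbors, for a doubling ladder of
Y values.  Ten neighbor counts give a 10-dimensional feature.

Proteins without GO annotation must be resolved upstream (e.g. by
substituting the terms of a close homolog); the table reader accepts only
fully annotated input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Doubling ladder of neighbor counts.  The tenth value (512) completes the
#: 2..1024 doubling sequence; drop it to reproduce a nine-value variant.
DEFAULT_NEIGHBOR_COUNTS = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)

_GO_RE = re.compile(r"^GO:\d{7}$")


class GOTableError(ValueError):
    """Raised for malformed GO annotation tables or unannotated queries."""


@dataclass
class GoKnnConfig:
    neighbor_counts: tuple[int, ...] = DEFAULT_NEIGHBOR_COUNTS

    def __post_init__(self) -> None:
        ys = tuple(self.neighbor_counts)
        if not ys or any(y <= 0 for y in ys) or any(a >= b for a, b in zip(ys, ys[1:])):
            raise ValueError("neighbor_counts must be strictly increasing positive integers")
        self.neighbor_counts = ys

    @property
    def dim(self) -> int:
        return len(self.neighbor_counts)


def read_go_table(path: str | Path) -> dict[str, set[str]]:
    """Read a GO annotation TSV: protein_id<TAB>GO:...;GO:...

    Duplicate protein rows are merged by set union.  A row with an empty
    term list is a validation error (annotation must be resolved upstream).
    """
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":
                continue
            if len(parts) != 2:
                raise GOTableError(f"{path}:{lineno}: expected 2 columns")
            pid, terms_s = parts
            terms = {t for t in terms_s.split(";") if t}
            if not terms:
                raise GOTableError(
                    f"{path}:{lineno}: protein {pid!r} has no GO terms; substitute "
                    "the terms of a homologous protein before featurization"
                )
            bad = [t for t in terms if not _GO_RE.match(t)]
            if bad:
                raise GOTableError(f"{path}:{lineno}: malformed GO terms {sorted(bad)}")
            table.setdefault(pid, set()).update(terms)
    return table


def write_go_table(table: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgo_terms\n")
        for pid in table:
            fh.write(pid + "\t" + ";".join(sorted(table[pid])) + "\n")


def go_distance(a: set[str], b: set[str]) -> float:
    """Jaccard distance 1 - |a & b| / |a | b| between two GO term sets."""
    if not a or not b:
        raise ValueError("go_distance: GO term sets must be non-empty")
    return 1.0 - len(a & b) / len(a | b)


def knn_positive_fractions(
    query: str,
    train_ids: list[str],
    train_labels: list[int] | np.ndarray,
    annotations: dict[str, set[str]],
    cfg: GoKnnConfig | None = None,
) -> np.ndarray:
    """Positive fraction among the Y nearest training proteins, per Y.

    Distances from the query to every training protein are sorted ascending
    (ties broken by ascending protein id, for determinism); component j is
    the fraction of label-1 proteins among the first Y_j.  If the query
    itself occurs in ``train_ids`` it is excluded (leave-self-out).

    A Y value of at least the training-set size is truncated to the set
    size: the neighborhood is then the whole set, so the component is the
    set's positive fraction — computed over the full training list (self
    included) so that it is the same constant for every query.  Under
    leave-self-out it would instead differ by exactly the query's own
    label, a leakage that classifiers exploit on small training sets.
    """
    if cfg is None:
        cfg = GoKnnConfig()
    if query not in annotations:
        raise GOTableError(
            f"protein {query!r} has no GO annotation; substitute the terms of a "
            "homologous protein and re-run"
        )
    qset = annotations[query]
    order_ids, order_d, order_lab = [], [], []
    for pid, lab in zip(train_ids, train_labels):
        if pid == query:
            continue
        if pid not in annotations:
            raise GOTableError(f"training protein {pid!r} has no GO annotation")
        order_ids.append(pid)
        order_d.append(go_distance(qset, annotations[pid]))
        order_lab.append(int(lab))
    if not order_ids:
        raise ValueError("knn_positive_fractions: empty training set after leave-self-out")
    order = sorted(range(len(order_ids)), key=lambda i: (order_d[i], order_ids[i]))
    labs = np.asarray([order_lab[i] for i in order], dtype=np.float64)
    cum = np.cumsum(labs)
    n_avail = len(labs)
    n_set = len(train_ids)
    prior = float(np.mean([int(l) for l in train_labels]))
    out = np.empty(cfg.dim)
    for j, y in enumerate(cfg.neighbor_counts):
        if y >= n_set:
            out[j] = prior  # neighborhood is the entire set
        else:
            y = min(y, n_avail)
            out[j] = cum[y - 1] / y
    return out


def goknn_matrix(
    query_ids: list[str],
    train_ids: list[str],
    train_labels: list[int] | np.ndarray,
    annotations: dict[str, set[str]],
    cfg: GoKnnConfig | None = None,
) -> np.ndarray:
    """Stack :func:`knn_positive_fractions` rows for many queries.

    Training proteins appearing among the queries are automatically handled
    by leave-self-out inside :func:`knn_positive_fractions`.
    """
    if cfg is None:
        cfg = GoKnnConfig()
    return np.vstack(
        [knn_positive_fractions(q, train_ids, train_labels, annotations, cfg) for q in query_ids]
    )


def goknn_feature_names(cfg: GoKnnConfig | None = None) -> list[str]:
    if cfg is None:
        cfg = GoKnnConfig()
    return [f"posfrac_Y{y}" for y in cfg.neighbor_counts]
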