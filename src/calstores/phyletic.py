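"""Paralog-count matrices and clade annotations.

The central object of the pipeline is the paralog-count matrix
``c(o, p)``: for each organism ``o`` in an organism set ``O`` and each
protein family ``p`` in a family set ``P``, the number of paralogs of
that family encoded in that organism's genome.  Rows of the matrix are
*organism complement vectors* (the protein complement of one organism),
columns are *family distribution vectors* (the distribution of one
family across organisms).  Everything downstream — distances,
clustering, ordination, the polydomain score, and ancestral
reconstruction — consumes this object.

Matrices travel as plain TSV: a header row of family names, a first
column of organism identifiers, integer cells.  Lines starting with
``#`` are treated as comments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("calstores")

UNANNOTATED = "unannotated"


class MatrixValidationError(ValueError):
    """Raised when a paralog-count matrix violates its invariants."""


@dataclass(frozen=True)
class ParalogCountMatrix:
    """Organisms × families matrix of non-negative integer paralog counts.

    Parameters
    ----------
    organisms
        Ordered organism identifiers (the set ``O``); unique.
    families
        Ordered protein-family identifiers (the set ``P``); unique.
    counts
        Integer array of shape ``(len(organisms), len(families))`` with
        ``counts[i, j]`` the number of paralogs of family ``j`` in
        organism ``i``.
    """

    organisms: tuple[str, ...]
    families: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "organisms", tuple(self.organisms))
        object.__setattr__(self, "families", tuple(self.families))
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.organisms), len(self.families)):
            raise MatrixValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.organisms)} organisms x {len(self.families)} families"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise MatrixValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.unravel_index(int(np.argmin(counts)), counts.shape)
            raise MatrixValidationError(
                f"negative count at organism {self.organisms[i]!r}, "
                f"family {self.families[j]!r}"
            )
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        _check_unique(self.organisms, "organism")
        _check_unique(self.families, "family")

    @property
    def n_organisms(self) -> int:
        return len(self.organisms)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def organism_vectors(self) -> list[np.ndarray]:
        """Rows: one complement vector of length ``|P|`` per organism."""
        return [self.counts[i, :].copy() for i in range(self.n_organisms)]

    def family_vectors(self) -> list[np.ndarray]:
        """Columns: one distribution vector of length ``|O|`` per family."""
        return [self.counts[:, j].copy() for j in range(self.n_families)]

    def transpose(self) -> "ParalogCountMatrix":
        return ParalogCountMatrix(self.families, self.organisms, self.counts.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.organisms), columns=list(self.families)
        )

    def subset_organisms(self, keep: Iterable[str]) -> "ParalogCountMatrix":
        keep = list(keep)
        idx = {o: i for i, o in enumerate(self.organisms)}
        missing = [o for o in keep if o not in idx]
        if missing:
            raise KeyError(f"organisms not in matrix: {missing}")
        rows = [idx[o] for o in keep]
        return ParalogCountMatrix(keep, self.families, self.counts[rows, :])


def _check_unique(items: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            raise MatrixValidationError(f"duplicate {what} identifier {it!r}")
        seen.add(it)


@dataclass(frozen=True)
class CladeAnnotation:
    """Mapping of organism → clade label, plus LDA prior-group representatives.

    Organisms absent from the mapping are treated as ``"unannotated"``:
    they are classified downstream but never used as training priors.
    """

    clades: Mapping[str, str]
    representatives: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "clades", dict(self.clades))
        object.__setattr__(self, "representatives", frozenset(self.representatives))
        unknown = self.representatives - set(self.clades)
        if unknown:
            raise ValueError(f"representatives without clade annotation: {sorted(unknown)}")

    def clade_of(self, organism: str) -> str:
        return self.clades.get(organism, UNANNOTATED)

    def labels_for(self, organisms: Sequence[str]) -> list[str]:
        return [self.clade_of(o) for o in organisms]

    def members(self, clade: str) -> list[str]:
        return [o for o, c in self.clades.items() if c == clade]

    @property
    def clade_names(self) -> list[str]:
        return sorted(set(self.clades.values()))


# ---------------------------------------------------------------------------
# TSV / JSON I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> ParalogCountMatrix:
    """Read a paralog-count matrix from TSV.

    Header row: family names.  First column: organism identifiers.
    Cells must be non-negative integers; ``#`` lines are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise MatrixValidationError(f"{path}: duplicate organism or family identifiers")
    organisms = [str(o) for o in df.index]
    families = [str(f) for f in df.columns]
    counts = np.empty(df.shape, dtype=np.int64)
    for j, fam in enumerate(df.columns):
        col = df[fam]
        for i, (org, cell) in enumerate(col.items()):
            try:
                val = int(str(cell).strip())
            except (TypeError, ValueError):
                raise MatrixValidationError(
                    f"{path}: non-integer cell {cell!r} at organism {org!r}, family {fam!r}"
                ) from None
            if val < 0:
                raise MatrixValidationError(
                    f"{path}: negative count {val} at organism {org!r}, family {fam!r}"
                )
            counts[i, j] = val
    m = ParalogCountMatrix(organisms, families, counts)
    logger.info("read matrix %s: %d organisms x %d families", path, m.n_organisms, m.n_families)
    return m


def write_matrix(m: ParalogCountMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; round-trips exactly through :func:`read_matrix`."""
    m.to_frame().to_csv(path, sep="\t", index_label="organism")


def read_clades(path: str | Path) -> CladeAnnotation:
    """Read a clade table: columns ``organism``, ``clade``, optional
    ``is_representative`` (truthy values: 1/true/yes)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "organism" not in cols or "clade" not in cols:
        raise ValueError(f"{path}: clade table needs 'organism' and 'clade' columns")
    orgs = df[cols["organism"]].astype(str)
    if orgs.duplicated().any():
        dup = orgs[orgs.duplicated()].iloc[0]
        raise ValueError(f"{path}: organism {dup!r} annotated more than once")
    clades = dict(zip(orgs, df[cols["clade"]].astype(str)))
    reps: set[str] = set()
    if "is_representative" in cols:
        flag = df[cols["is_representative"]].astype(str).str.strip().str.lower()
        reps = set(orgs[flag.isin({"1", "true", "yes"})])
    return CladeAnnotation(clades, frozenset(reps))


def write_clades(ca: CladeAnnotation, path: str | Path) -> None:
    rows = [
        {
            "organism": o,
            "clade": c,
            "is_representative": int(o in ca.representatives),
        }
        for o, c in ca.clades.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    """Serialize a result summary as deterministic, sorted-key JSON."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
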