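"""Genotype data model and delimited-table I/O for SSR fingerprinting.

An SSR call for one sample at one marker is a small set of amplicon sizes
(base pairs), e.g. ``177/181``.  Sizes are qualitative identities: they are
stored as exact integers and never binned.  A dash (``-``), an empty cell or
``NA`` denotes a missing call.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AlleleSet",
    "GenotypeTable",
    "GenotypeParseError",
    "MISSING_TOKEN",
    "parse_genotype_string",
    "read_genotype_table",
    "write_genotype_table",
]

#: Canonical serialization of a missing call.
MISSING_TOKEN = "-"

#: Input tokens accepted as "missing" (case-insensitive for the NA variants).
_MISSING_INPUT = {"-", "", "na", "nan"}


class GenotypeParseError(ValueError):
    """Raised when a genotype cell or table cannot be parsed."""


@dataclass(frozen=True)
class AlleleSet:
    """The set of amplicon sizes observed for one sample at one marker.

    ``alleles`` is a frozenset of positive integers; an empty set means the
    call is missing.  Duplicate sizes collapse under set semantics.
    """

    alleles: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        alleles = frozenset(int(a) for a in self.alleles)
        for a in alleles:
            if a <= 0:
                raise GenotypeParseError(f"allele sizes must be positive, got {a}")
        object.__setattr__(self, "alleles", alleles)

    @property
    def missing(self) -> bool:
        return not self.alleles

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(sorted(self.alleles))

    def to_string(self) -> str:
        """Canonical cell text: ascending sizes joined by ``/``; ``-`` if missing."""
        if self.missing:
            return MISSING_TOKEN
        return "/".join(str(a) for a in sorted(self.alleles))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


#: Shared missing-call singleton (AlleleSet is immutable).
MISSING_CALL = AlleleSet()


def parse_genotype_string(text: str, context: str | None = None) -> AlleleSet:
    """Parse one genotype cell such as ``"177/181"`` into an :class:`AlleleSet`.

    ``-``, the empty string and ``NA`` (any case) parse to a missing call.
    Tokens must be positive integers separated by single slashes.

    Parameters
    ----------
    text:
        Raw cell content.  Surrounding whitespace is ignored.
    context:
        Optional "row x column" description used in error messages.
    """
    where = f" at {context}" if context else ""
    stripped = text.strip()
    if stripped.lower() in _MISSING_INPUT:
        return MISSING_CALL
    tokens = stripped.split("/")
    alleles = []
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            raise GenotypeParseError(
                f"malformed genotype {text!r}{where}: empty allele token"
            )
        try:
            value = int(tok)
        except ValueError:
            raise GenotypeParseError(
                f"malformed genotype {text!r}{where}: non-integer token {tok!r}"
            ) from None
        if value <= 0:
            raise GenotypeParseError(
                f"malformed genotype {text!r}{where}: non-positive allele {value}"
            )
        alleles.append(value)
    return AlleleSet(frozenset(alleles))


@dataclass
class GenotypeTable:
    """A rectangular samples x markers grid of :class:`AlleleSet` calls.

    ``cells`` is an object ndarray of shape ``(n_samples, n_markers)``.
    ``labels``, when present, assigns one class label per sample (aligned
    with ``sample_ids``).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    cells: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.cells = np.asarray(self.cells, dtype=object)
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeParseError("duplicate sample identifiers")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeParseError("duplicate marker identifiers")
        if self.cells.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise GenotypeParseError(
                f"grid shape {self.cells.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        for cell in self.cells.flat:
            if not isinstance(cell, AlleleSet):
                raise GenotypeParseError(f"cell {cell!r} is not an AlleleSet")
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise GenotypeParseError("labels do not align with sample_ids")

    # -- basic accessors --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def sample_genotype(self, sample_id: str) -> dict[str, AlleleSet]:
        """Per-marker allele sets for one sample, keyed by marker id."""
        i = self.sample_index(sample_id)
        return dict(zip(self.marker_ids, self.cells[i, :]))

    def marker_column(self, marker_id: str) -> list[AlleleSet]:
        return list(self.cells[:, self.marker_index(marker_id)])

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table carries no class labels")
        return np.asarray(self.labels, dtype=object)

    # -- subsetting -------------------------------------------------------
    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.marker_index(m) for m in marker_ids]
        return GenotypeTable(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[i] for i in idx],
            cells=self.cells[:, idx].copy(),
            labels=None if self.labels is None else list(self.labels),
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeTable":
        indices = list(indices)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in indices],
            marker_ids=list(self.marker_ids),
            cells=self.cells[indices, :].copy(),
            labels=None
            if self.labels is None
            else [self.labels[i] for i in indices],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.marker_ids == other.marker_ids
            and self.labels == other.labels
            and self.cells.shape == other.cells.shape
            and all(
                a == b for a, b in zip(self.cells.flat, other.cells.flat)
            )
        )


def _sniff_delimiter(header_line: str) -> str:
    # Tab-separated is the native dialect; fall back to comma.
    return "\t" if "\t" in header_line else ","


def read_genotype_table(
    path: str | Path,
    label_column: str | None = None,
    delimiter: str | None = None,
) -> GenotypeTable:
    """Read a delimited genotype table.

    Layout: header row with marker names (first column = sample id, optional
    label column named by ``label_column``), one row per sample, cells like
    ``177/181`` with ``-`` for missing.  Tab-separated by default, comma
    auto-detected.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise GenotypeParseError(f"{path}: empty file")
        delim = delimiter or _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        rows = list(reader)

    header = [h.strip() for h in header]
    if len(header) < 2:
        raise GenotypeParseError(f"{path}: header has no marker columns")
    columns = header[1:]
    if label_column is not None:
        if label_column not in columns:
            raise GenotypeParseError(
                f"{path}: label column {label_column!r} not found"
            )
        label_pos = columns.index(label_column) + 1
        marker_ids = [c for c in columns if c != label_column]
    else:
        label_pos = None
        marker_ids = columns

    if not rows:
        raise GenotypeParseError(f"{path}: no sample rows")
    if len(set(marker_ids)) != len(marker_ids):
        raise GenotypeParseError(f"{path}: duplicate marker names in header")

    sample_ids: list[str] = []
    labels: list[str] | None = [] if label_pos is not None else None
    cells: list[list[AlleleSet]] = []
    for lineno, row in enumerate(rows, start=2):
        if not any(f.strip() for f in row):
            continue  # blank line
        if len(row) != len(header):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        sample_id = row[0].strip()
        sample_ids.append(sample_id)
        parsed: list[AlleleSet] = []
        for col_pos, raw in enumerate(row[1:], start=1):
            if col_pos == label_pos:
                labels.append(raw.strip())  # type: ignore[union-attr]
                continue
            marker = header[col_pos]
            parsed.append(
                parse_genotype_string(
                    raw, context=f"{path}:{lineno} (sample {sample_id!r}, marker {marker!r})"
                )
            )
        cells.append(parsed)

    if len(set(sample_ids)) != len(sample_ids):
        raise GenotypeParseError(f"{path}: duplicate sample identifiers")
    return GenotypeTable(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        cells=np.array(cells, dtype=object),
        labels=labels,
    )


def write_genotype_table(
    table: GenotypeTable,
    path: str | Path,
    label_column: str = "group",
    delimiter: str = "\t",
) -> None:
    """Write a table in the dialect :func:`read_genotype_table` accepts.

    Missing cells are written as ``-``; allele sizes ascending.  The label
    column is emitted only when the table carries labels.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        header = ["sample"]
        if table.labels is not None:
            header.append(label_column)
        header.extend(table.marker_ids)
        writer.writerow(header)
        for i, sample_id in enumerate(table.sample_ids):
            row = [sample_id]
            if table.labels is not None:
                row.append(table.labels[i])
            row.extend(cell.to_string() for cell in table.cells[i, :])
            writer.writerow(row)
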