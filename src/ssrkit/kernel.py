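"""Nei-Li genetic distance and the induced positive-definite similarity kernel.

For two samples typed at markers ``k = 1..m`` with allele sets ``A_k`` and
``B_k``, the distance pools symmetric differences over markers::

    d(a, b) = sum_k |A_k ^ B_k| / sum_k (|A_k| + |B_k|)

and the similarity ``1 - d`` is the Dice/Sorensen coefficient
``2 sum_k |A_k & B_k| / sum_k (|A_k| + |B_k|)`` on marker-tagged alleles.
The similarity is a positive-definite kernel, so its Gram matrices are PSD
(up to eigensolver noise) and support kernel discriminant methods.

Missing calls enter the pooled sums as empty allele sets: they contribute
nothing to intersections or set sizes, so a marker missing in both samples
of a pair drops out entirely, while missing-versus-observed counts the
observed alleles as unmatched.  This keeps the similarity an exact Dice
coefficient on pooled marker-tagged allele sets, so Gram matrices stay
positive semi-definite even with missing data (pair-dependent marker
exclusion does not: it measurably breaks PSD at a few percent missingness).
A pair with no observed allele at all over the subset has no defined
distance and raises :class:`DistanceUndefinedError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import AlleleSet, GenotypeTable

__all__ = [
    "DistanceUndefinedError",
    "GramMatrix",
    "MarkerPairComponents",
    "nei_li_distance",
    "nei_li_similarity",
    "gram_matrix",
    "cross_gram",
    "write_distance_matrix",
]

#: Relative eigenvalue tolerance for the PSD check.
PSD_RTOL = 1e-8


class DistanceUndefinedError(ValueError):
    """A sample pair has no observed allele over the requested marker subset."""


@dataclass
class GramMatrix:
    """Square symmetric Nei-Li similarity matrix with provenance."""

    values: np.ndarray
    sample_ids: list[str]
    marker_subset: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("Gram matrix shape does not match sample_ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def is_psd(self, rtol: float = PSD_RTOL) -> bool:
        eigvals = np.linalg.eigvalsh((self.values + self.values.T) / 2.0)
        largest = max(eigvals[-1], 0.0)
        return bool(eigvals[0] >= -rtol * max(largest, 1.0))


def _pair_terms(
    genotype_a: Mapping[str, AlleleSet],
    genotype_b: Mapping[str, AlleleSet],
    marker_subset: Sequence[str],
) -> tuple[int, int]:
    """Pooled (symmetric-difference, size-sum) totals over usable markers."""
    if not marker_subset:
        raise ValueError("marker_subset must be non-empty")
    num = 0
    den = 0
    for marker in marker_subset:
        a = genotype_a[marker].alleles
        b = genotype_b[marker].alleles
        num += len(a ^ b)
        den += len(a) + len(b)
    return num, den


def nei_li_distance(
    genotype_a: Mapping[str, AlleleSet],
    genotype_b: Mapping[str, AlleleSet],
    marker_subset: Sequence[str],
) -> float:
    """Pooled Nei-Li distance between two per-marker genotype mappings."""
    num, den = _pair_terms(genotype_a, genotype_b, marker_subset)
    if den == 0:
        raise DistanceUndefinedError(
            "no observed allele at any marker of the subset for this pair"
        )
    return num / den


def nei_li_similarity(
    genotype_a: Mapping[str, AlleleSet],
    genotype_b: Mapping[str, AlleleSet],
    marker_subset: Sequence[str],
) -> float:
    """Dice similarity ``1 - nei_li_distance`` on the same marker subset.

    Computed as the exact integer ratio ``(den - num) / den`` so it equals
    ``2 sum|A & B| / sum(|A| + |B|)`` bit-for-bit.
    """
    num, den = _pair_terms(genotype_a, genotype_b, marker_subset)
    if den == 0:
        raise DistanceUndefinedError(
            "no observed allele at any marker of the subset for this pair"
        )
    return (den - num) / den


def _membership_matrix(
    column: Sequence[AlleleSet], universe: dict[int, int]
) -> np.ndarray:
    """0/1 allele-membership rows; a missing call is an all-zero row."""
    member = np.zeros((len(column), len(universe)), dtype=np.float64)
    for i, cell in enumerate(column):
        for a in cell.alleles:
            member[i, universe[a]] = 1.0
    return member


def _marker_pair_arrays(
    col_a: Sequence[AlleleSet], col_b: Sequence[AlleleSet] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair ``|A ^ B|`` and ``|A| + |B|`` for one marker.

    With one column: all within-column pairs (square).  With two: rows of
    ``col_a`` against columns of ``col_b`` (rectangular).  Missing calls are
    empty sets, so a marker missing in both members of a pair contributes
    (0, 0) and drops out of the pooled sums.
    """
    cols = list(col_a) + (list(col_b) if col_b is not None else [])
    alleles = sorted({a for cell in cols for a in cell.alleles})
    universe = {a: j for j, a in enumerate(alleles)}

    mem_a = _membership_matrix(col_a, universe)
    mem_b = mem_a if col_b is None else _membership_matrix(col_b, universe)

    inter = mem_a @ mem_b.T
    size_a = mem_a.sum(axis=1)
    size_b = mem_b.sum(axis=1)
    den = size_a[:, None] + size_b[None, :]
    num = den - 2.0 * inter
    return num, den


@dataclass
class MarkerPairComponents:
    """Per-marker pooled-sum components for all sample pairs of a table.

    ``numer[k]`` and ``denom[k]`` hold ``|A ^ B|`` and ``|A| + |B|`` for
    marker ``k`` over all sample pairs; summing any subset of markers and
    taking ``1 - num/den`` yields that subset's Gram matrix in O(n^2).
    Used to make exhaustive subset searches affordable.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    numer: np.ndarray  # (m, n, n)
    denom: np.ndarray  # (m, n, n)

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "MarkerPairComponents":
        n = table.n_samples
        m = table.n_markers
        numer = np.empty((m, n, n), dtype=np.float32)
        denom = np.empty((m, n, n), dtype=np.float32)
        for k, marker in enumerate(table.marker_ids):
            num, den = _marker_pair_arrays(table.marker_column(marker))
            numer[k] = num
            denom[k] = den
        return cls(
            marker_ids=list(table.marker_ids),
            sample_ids=list(table.sample_ids),
            numer=numer,
            denom=denom,
        )

    def gram_values(self, marker_indices: Sequence[int]) -> np.ndarray:
        """Similarity matrix over the marker index subset (raises if any
        sample pair has no usable marker)."""
        idx = list(marker_indices)
        num = self.numer[idx].sum(axis=0, dtype=np.float64)
        den = self.denom[idx].sum(axis=0, dtype=np.float64)
        if np.any(den == 0):
            i, j = np.argwhere(den == 0)[0]
            raise DistanceUndefinedError(
                f"samples {self.sample_ids[i]!r} and {self.sample_ids[j]!r} "
                "have no observed allele over the subset"
            )
        return (den - num) / den


def _resolve_subset(
    table: GenotypeTable, marker_subset: Sequence[str] | None
) -> list[str]:
    if marker_subset is None:
        return list(table.marker_ids)
    subset = list(marker_subset)
    if not subset:
        raise ValueError("marker_subset must be non-empty")
    unknown = [m for m in subset if m not in table.marker_ids]
    if unknown:
        raise KeyError(f"markers not in table: {unknown}")
    return subset


def gram_matrix(
    table: GenotypeTable, marker_subset: Sequence[str] | None = None
) -> GramMatrix:
    """Pairwise Nei-Li similarity Gram matrix over a marker subset."""
    if table.n_samples == 0:
        raise ValueError("table has no samples")
    subset = _resolve_subset(table, marker_subset)
    n = table.n_samples
    num = np.zeros((n, n), dtype=np.float64)
    den = np.zeros((n, n), dtype=np.float64)
    for marker in subset:
        dn, dd = _marker_pair_arrays(table.marker_column(marker))
        num += dn
        den += dd
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise DistanceUndefinedError(
            f"samples {table.sample_ids[i]!r} and {table.sample_ids[j]!r} "
            "have no observed allele over the subset"
        )
    values = (den - num) / den
    # exact-arithmetic symmetry can drift by 1 ulp in the blas product
    values = (values + values.T) / 2.0
    return GramMatrix(values=values, sample_ids=list(table.sample_ids), marker_subset=subset)


def cross_gram(
    train: GenotypeTable,
    test: GenotypeTable,
    marker_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """Test x train Nei-Li similarities.

    Alleles seen only in test samples enter the symmetric differences
    directly — no retraining or re-coding of the kernel is needed.
    """
    if train.marker_ids != test.marker_ids:
        raise ValueError("train and test tables must share identical marker ids")
    subset = _resolve_subset(train, marker_subset)
    n_test, n_train = test.n_samples, train.n_samples
    num = np.zeros((n_test, n_train), dtype=np.float64)
    den = np.zeros((n_test, n_train), dtype=np.float64)
    for marker in subset:
        dn, dd = _marker_pair_arrays(
            test.marker_column(marker), train.marker_column(marker)
        )
        num += dn
        den += dd
    if np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise DistanceUndefinedError(
            f"test sample {test.sample_ids[i]!r} and training sample "
            f"{train.sample_ids[j]!r} have no observed allele over the subset"
        )
    return (den - num) / den


def write_distance_matrix(
    gram: GramMatrix, path: str | Path, fmt: str = "square"
) -> None:
    """Export ``1 - similarity`` as square PHYLIP-style text or long TSV."""
    path = Path(path)
    dist = 1.0 - gram.values
    if fmt == "square":
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{gram.n}\n")
            for i, sid in enumerate(gram.sample_ids):
                row = " ".join(f"{d:.6f}" for d in dist[i])
                fh.write(f"{sid}\t{row}\n")
    elif fmt == "long":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("sample_a\tsample_b\tdistance\n")
            for i, a in enumerate(gram.sample_ids):
                for j in range(i + 1, gram.n):
                    fh.write(f"{a}\t{gram.sample_ids[j]}\t{dist[i, j]:.6f}\n")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'square' or 'long')")
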