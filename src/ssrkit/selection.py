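"""Marker kit selection from information-theoretic filter scores.

Each marker's observed genotype (the full multi-allele call) is treated as
one categorical value.  A marker's discrimination power is the asymmetric
uncertainty coefficient ``U(Group | Marker)`` — the fraction of group
entropy explained by the marker — and the redundancy between two markers is
the symmetric uncertainty coefficient of their genotype categories.  Both
come with large-sample (delta-method) variances, giving Z-scores that weigh
statistical evidence rather than raw coefficients.

The greedy selector visits markers by decreasing power and keeps marker
``i`` only when the evidence for its power beats ``alpha`` times the
strongest evidence of redundancy with the markers already kept::

    Z_power(i) >= alpha * max_j Z_redundancy(i, j)      (j already selected)

``alpha = 0`` disables skipping (plain top-N by power).  MIFS and mRMR
baselines operate on the same genotype categories with plug-in mutual
information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genotype_io import GenotypeTable

__all__ = [
    "MarkerScore",
    "RedundancyScore",
    "SelectionConfig",
    "SelectionResult",
    "empirical_entropy",
    "asymmetric_uncertainty",
    "symmetric_uncertainty",
    "mutual_information",
    "marker_scores",
    "greedy_select",
    "mifs_select",
    "mrmr_select",
]

_ZERO_TOL = 1e-12


def empirical_entropy(counts: Sequence[float] | np.ndarray) -> float:
    """Plug-in entropy (natural log) of the empirical distribution.

    Zero-count categories contribute nothing; an all-zero vector is an error.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must not be all zero")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def _contingency(x: Sequence, y: Sequence) -> np.ndarray:
    """Joint count table of two equal-length categorical vectors."""
    x = np.asarray(list(x), dtype=object)
    y = np.asarray(list(y), dtype=object)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired observations")
    _, xi = np.unique(x.astype(str), return_inverse=True)
    _, yi = np.unique(y.astype(str), return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def _entropies(table: np.ndarray) -> tuple[float, float, float, float]:
    n = table.sum()
    h_row = empirical_entropy(table.sum(axis=1))
    h_col = empirical_entropy(table.sum(axis=0))
    h_joint = empirical_entropy(table)
    return float(n), h_row, h_col, h_joint


def _zscore(value: float, variance: float) -> float:
    if variance > _ZERO_TOL:
        return value / np.sqrt(variance)
    return np.inf if value > _ZERO_TOL else 0.0


@dataclass
class MarkerScore:
    """Discrimination power of one marker with its evidence Z-score."""

    marker_id: str
    power: float
    power_variance: float
    power_z: float = field(init=False)

    def __post_init__(self) -> None:
        self.power_z = _zscore(self.power, self.power_variance)


@dataclass
class RedundancyScore:
    """Symmetric uncertainty between two markers' genotype categories."""

    marker_pair: tuple[str, str]
    value: float
    variance: float
    z: float = field(init=False)

    def __post_init__(self) -> None:
        self.z = _zscore(self.value, self.variance)


def asymmetric_uncertainty(
    group: Sequence, marker_genotypes: Sequence, marker_id: str = ""
) -> MarkerScore:
    """``U(Group | Marker)`` with its asymptotic (delta-method) variance.

    ``U = [H(G) + H(S) - H(G, S)] / H(G)`` lies in [0, 1]: 1 when the
    marker's categories determine the group, 0 under exact empirical
    independence.  The variance is the standard large-sample expression for
    the uncertainty coefficient of a two-way contingency table::

        var = sum_ij n_ij [ H_G ln(n_ij / n_i.) + (H_S - H_GS) ln(n_.j / n) ]^2
              / (n^2 H_G^4)

    with ``i`` indexing marker categories and ``j`` group categories.
    """
    table = _contingency(marker_genotypes, group)  # rows: marker, cols: group
    n, h_s, h_g, h_gs = _entropies(table)
    if h_g <= _ZERO_TOL:
        raise ValueError("group variable is constant (zero entropy)")
    u = (h_s + h_g - h_gs) / h_g
    u = float(min(max(u, 0.0), 1.0))

    row_tot = table.sum(axis=1, keepdims=True).astype(float)
    col_tot = table.sum(axis=0, keepdims=True).astype(float)
    nz = table > 0
    term = np.zeros_like(table, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(nz, np.log(np.where(nz, table / row_tot, 1.0)), 0.0)
        colp = np.log(np.broadcast_to(col_tot / n, table.shape))
    term[nz] = h_g * cond[nz] + (h_s - h_gs) * colp[nz]
    variance = float((table * term**2).sum() / (n**2 * h_g**4))
    variance = max(variance, 0.0)
    return MarkerScore(marker_id=marker_id, power=u, power_variance=variance)


def symmetric_uncertainty(
    marker_i: Sequence, marker_j: Sequence, pair: tuple[str, str] = ("", "")
) -> RedundancyScore:
    """Symmetric uncertainty ``2 [H(X)+H(Y)-H(X,Y)] / [H(X)+H(Y)]`` with its
    asymptotic variance::

        var = 4 sum_ij n_ij [ H_XY ln(n_i. n_.j / n^2)
                              - (H_X + H_Y) ln(n_ij / n) ]^2
              / (n^2 (H_X + H_Y)^4)
    """
    table = _contingency(marker_i, marker_j)
    n, h_x, h_y, h_xy = _entropies(table)
    denom = h_x + h_y
    if denom <= _ZERO_TOL:
        raise ValueError("both variables are constant (zero entropy)")
    u = 2.0 * (h_x + h_y - h_xy) / denom
    u = float(min(max(u, 0.0), 1.0))

    row_tot = table.sum(axis=1, keepdims=True).astype(float)
    col_tot = table.sum(axis=0, keepdims=True).astype(float)
    nz = table > 0
    term = np.zeros_like(table, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        marg = np.log((row_tot @ col_tot) / n**2)
        joint = np.where(nz, np.log(np.where(nz, table / n, 1.0)), 0.0)
    term[nz] = h_xy * marg[nz] - denom * joint[nz]
    variance = float(4.0 * (table * term**2).sum() / (n**2 * denom**4))
    variance = max(variance, 0.0)
    return RedundancyScore(marker_pair=pair, value=u, variance=variance)


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information (nats) of two categorical vectors."""
    table = _contingency(x, y)
    _, h_x, h_y, h_xy = _entropies(table)
    return max(h_x + h_y - h_xy, 0.0)


# ---------------------------------------------------------------------------
# genotype-category extraction with pairwise deletion of missing calls
# ---------------------------------------------------------------------------


def _marker_categories(table: GenotypeTable, marker_id: str) -> np.ndarray:
    """Canonical category string per sample; empty string marks missing."""
    return np.asarray(
        ["" if c.missing else c.to_string() for c in table.marker_column(marker_id)],
        dtype=object,
    )


def _labels_of(table: GenotypeTable, labels: Sequence | None) -> np.ndarray:
    if labels is None:
        return table.label_array()
    y = np.asarray(list(labels), dtype=object)
    if len(y) != table.n_samples:
        raise ValueError("labels must align with table samples")
    return y


def marker_scores(
    table: GenotypeTable, labels: Sequence | None = None
) -> list[MarkerScore]:
    """Discrimination power for every marker (missing calls dropped per
    marker; a marker constant after deletion scores 0 and ranks last)."""
    y = _labels_of(table, labels)
    scores = []
    for marker in table.marker_ids:
        cats = _marker_categories(table, marker)
        keep = cats != ""
        if keep.sum() < 2 or len(set(cats[keep])) < 2:
            scores.append(MarkerScore(marker_id=marker, power=0.0, power_variance=0.0))
            continue
        if len(set(y[keep])) < 2:
            scores.append(MarkerScore(marker_id=marker, power=0.0, power_variance=0.0))
            continue
        scores.append(asymmetric_uncertainty(y[keep], cats[keep], marker_id=marker))
    return scores


def _redundancy(
    table: GenotypeTable, marker_a: str, marker_b: str
) -> RedundancyScore:
    ca = _marker_categories(table, marker_a)
    cb = _marker_categories(table, marker_b)
    keep = (ca != "") & (cb != "")
    if keep.sum() < 2:
        return RedundancyScore(marker_pair=(marker_a, marker_b), value=0.0, variance=0.0)
    if len(set(ca[keep])) < 2 and len(set(cb[keep])) < 2:
        return RedundancyScore(marker_pair=(marker_a, marker_b), value=0.0, variance=0.0)
    return symmetric_uncertainty(ca[keep], cb[keep], pair=(marker_a, marker_b))


# ---------------------------------------------------------------------------
# selection algorithms
# ---------------------------------------------------------------------------


@dataclass
class SelectionConfig:
    """Kit-selection settings.

    ``alpha`` trades power evidence against redundancy evidence in the
    greedy method (default 1); ``beta`` is the MIFS penalty weight.
    ``redundancy_aggregation`` chooses how redundancy Z-scores against the
    already-selected kit are combined ("max" or "sum").
    """

    kit_size: int
    alpha: float = 1.0
    method: str = "FS"
    beta: float = 0.0
    redundancy_aggregation: str = "max"

    def __post_init__(self) -> None:
        if self.kit_size < 1:
            raise ValueError("kit_size must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.method not in {"FS", "MIFS", "mRMR"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.redundancy_aggregation not in {"max", "sum"}:
            raise ValueError("redundancy_aggregation must be 'max' or 'sum'")


@dataclass
class SkippedMarker:
    score: MarkerScore
    blocking_redundancy: RedundancyScore
    blocking_marker: str


@dataclass
class SelectionResult:
    """Ordered selected kit plus the evidence that excluded skipped markers."""

    selected: list[MarkerScore]
    skipped: list[SkippedMarker]
    config: SelectionConfig

    @property
    def selected_markers(self) -> list[str]:
        return [s.marker_id for s in self.selected]


def _cap_kit_size(config: SelectionConfig, n_markers: int) -> int:
    if config.kit_size > n_markers:
        warnings.warn(
            f"kit size {config.kit_size} exceeds the {n_markers} available "
            "markers; selecting from all markers",
            RuntimeWarning,
            stacklevel=3,
        )
        return n_markers
    return config.kit_size


def greedy_select(
    table: GenotypeTable,
    labels: Sequence | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Greedy power-ordered selection with redundancy-evidence skipping.

    Markers are visited by decreasing power (stable tie-break on input
    order).  Marker ``i`` joins the kit while it is not full and
    ``Z_power(i) >= alpha * agg_j Z_redundancy(i, j)`` over already-selected
    ``j``; otherwise it is skipped and the blocking marker recorded.  With
    ``alpha = 0`` nothing is ever skipped (top-N by power).
    """
    if config is None:
        raise ValueError("a SelectionConfig is required")
    if table.n_markers < 1:
        raise ValueError("table has no markers")
    n_kit = _cap_kit_size(config, table.n_markers)
    scores = marker_scores(table, labels)
    order = sorted(range(len(scores)), key=lambda i: -scores[i].power)

    agg: Callable[[list[float]], float] = max if config.redundancy_aggregation == "max" else sum
    selected: list[MarkerScore] = []
    skipped: list[SkippedMarker] = []
    for rank, i in enumerate(order):
        if len(selected) >= n_kit:
            break
        score = scores[i]
        if rank == 0 or config.alpha == 0 or not selected:
            selected.append(score)
            continue
        redundancies = [
            _redundancy(table, score.marker_id, s.marker_id) for s in selected
        ]
        zs = [r.z for r in redundancies]
        threshold = config.alpha * agg(zs)
        if score.power_z >= threshold:
            selected.append(score)
        else:
            blocker = redundancies[int(np.argmax(zs))]
            skipped.append(
                SkippedMarker(
                    score=score,
                    blocking_redundancy=blocker,
                    blocking_marker=blocker.marker_pair[1],
                )
            )
    return SelectionResult(selected=selected, skipped=skipped, config=config)


def _mi_greedy(
    table: GenotypeTable,
    labels: Sequence | None,
    config: SelectionConfig,
    penalty: Callable[[list[float]], float],
) -> SelectionResult:
    y = _labels_of(table, labels)
    n_kit = _cap_kit_size(config, table.n_markers)
    markers = list(table.marker_ids)
    cats = {m: _marker_categories(table, m) for m in markers}

    def relevance(m: str) -> float:
        keep = cats[m] != ""
        if keep.sum() < 2:
            return 0.0
        return mutual_information(y[keep], cats[m][keep])

    def pair_mi(a: str, b: str) -> float:
        keep = (cats[a] != "") & (cats[b] != "")
        if keep.sum() < 2:
            return 0.0
        return mutual_information(cats[a][keep], cats[b][keep])

    rel = {m: relevance(m) for m in markers}
    remaining = list(markers)
    selected_ids: list[str] = []
    while remaining and len(selected_ids) < n_kit:
        best, best_val = None, -np.inf
        for m in remaining:
            if selected_ids:
                val = rel[m] - penalty([pair_mi(m, s) for s in selected_ids])
            else:
                val = rel[m]
            if val > best_val + _ZERO_TOL:
                best, best_val = m, val
        selected_ids.append(best)
        remaining.remove(best)

    score_by_id = {s.marker_id: s for s in marker_scores(table, labels)}
    return SelectionResult(
        selected=[score_by_id[m] for m in selected_ids],
        skipped=[],
        config=config,
    )


def mifs_select(
    table: GenotypeTable,
    labels: Sequence | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """MIFS: greedily maximize ``I(G; S_i) - beta * sum_j I(S_i; S_j)``."""
    if config is None or config.method != "MIFS":
        raise ValueError("config with method='MIFS' is required")
    beta = config.beta
    return _mi_greedy(table, labels, config, lambda mis: beta * sum(mis))


def mrmr_select(
    table: GenotypeTable,
    labels: Sequence | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """mRMR (MID form): maximize ``I(G; S_i) - mean_j I(S_i; S_j)``."""
    if config is None or config.method != "mRMR":
        raise ValueError("config with method='mRMR' is required")
    return _mi_greedy(
        table, labels, config, lambda mis: float(np.mean(mis)) if mis else 0.0
    )


def select(
    table: GenotypeTable,
    labels: Sequence | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Dispatch to the configured selection method."""
    if config is None:
        raise ValueError("a SelectionConfig is required")
    if config.method == "FS":
        return greedy_select(table, labels, config)
    if config.method == "MIFS":
        return mifs_select(table, labels, config)
    return mrmr_select(table, labels, config)
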