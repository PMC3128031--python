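"""Cross-validated benchmarking of selector x classifier x kit size.

Feature selection runs inside every fold's training split (the "leaky"
variant, selecting once on the full data, exists only to demonstrate
selection bias).  Folds are stratified and fully determined by the seed, so
a whole pipeline run is bit-reproducible.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifiers import KernelClassifierModel, fit_klda, fit_kpclda, predict
from .genotype_io import GenotypeTable
from .kernel import DistanceUndefinedError, MarkerPairComponents, cross_gram, gram_matrix
from .selection import SelectionConfig, select

__all__ = [
    "CVReport",
    "stratified_kfold",
    "cross_validate",
    "grid_search",
    "exhaustive_subset_search",
    "rank_selected_kit",
]

#: Quantile levels (percent) reported by the exhaustive subset search.
SUBSET_QUANTILES = (0.0, 0.5, 1.0, 5.0, 25.0, 50.0, 75.0, 100.0)


@dataclass
class CVReport:
    """Per-fold cross-validation errors for one configuration."""

    selector: str
    classifier: str
    kit_size: int | None
    parameter_name: str | None
    parameter_value: float | None
    fold_errors: list[float]
    fold_sizes: list[int]
    fold_kits: list[list[str]]
    seed: int
    k: int
    failed_folds: list[int] = field(default_factory=list)

    @property
    def mean_error(self) -> float:
        """Sample-weighted mean error over valid folds."""
        errs = np.asarray(self.fold_errors, dtype=float)
        sizes = np.asarray(self.fold_sizes, dtype=float)
        ok = ~np.isnan(errs)
        if not ok.any():
            return float("nan")
        return float((errs[ok] * sizes[ok]).sum() / sizes[ok].sum())

    @property
    def std_error(self) -> float:
        """Standard error of the per-fold error rates."""
        errs = np.asarray(self.fold_errors, dtype=float)
        errs = errs[~np.isnan(errs)]
        if len(errs) < 2:
            return float("nan")
        return float(errs.std(ddof=1) / math.sqrt(len(errs)))

    @property
    def partial(self) -> bool:
        return bool(self.failed_folds)

    def to_dict(self) -> dict:
        return {
            "selector": self.selector,
            "classifier": self.classifier,
            "kit_size": self.kit_size,
            "parameter_name": self.parameter_name,
            "parameter_value": self.parameter_value,
            "fold_errors": self.fold_errors,
            "fold_sizes": self.fold_sizes,
            "fold_kits": self.fold_kits,
            "failed_folds": self.failed_folds,
            "mean_error": self.mean_error,
            "std_error": self.std_error,
            "seed": self.seed,
            "k": self.k,
        }


def stratified_kfold(
    labels: Sequence, k: int, seed: int = 0
) -> tuple[np.ndarray, int]:
    """Deterministic stratified fold assignment.

    Returns ``(assignment, k_eff)`` where ``assignment[i]`` is the fold of
    sample ``i`` (``-1`` for members of singleton classes, which stay in
    every training split).  ``k`` is downgraded with a warning when some
    class with >= 2 members has fewer members than ``k``.
    """
    y = np.asarray(list(labels), dtype=object)
    if k < 2:
        raise ValueError("k must be >= 2 (k=1 leaves no held-out data)")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    multi = counts[counts >= 2]
    if len(multi) == 0:
        raise ValueError("every class is a singleton; cross-validation impossible")
    k_eff = int(min(k, multi.min()))
    if k_eff < k:
        warnings.warn(
            f"downgrading k from {k} to {k_eff}: smallest usable class has "
            f"{k_eff} members",
            RuntimeWarning,
            stacklevel=2,
        )
    singletons = classes[counts == 1]
    if len(singletons):
        warnings.warn(
            f"classes {list(singletons)} have a single member; kept in "
            "training splits only",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    assignment = np.full(len(y), -1, dtype=int)
    offset = 0
    for c in classes:
        members = np.flatnonzero(y.astype(str) == c)
        if len(members) < 2:
            continue
        members = rng.permutation(members)
        for pos, idx in enumerate(members):
            assignment[idx] = (pos + offset) % k_eff
        offset += len(members)  # rotate so small classes spread over folds
    return assignment, k_eff


def _fit(classifier: str, gram, labels, classifier_params: dict | None):
    params = dict(classifier_params or {})
    if classifier.upper() == "KLDA":
        return fit_klda(gram, labels, **params)
    if classifier.upper() == "KPCLDA":
        return fit_kpclda(gram, labels, **params)
    raise ValueError(f"unknown classifier {classifier!r}")


def cross_validate(
    table: GenotypeTable,
    labels: Sequence | None = None,
    selector_config: SelectionConfig | None = None,
    classifier: str = "KLDA",
    classifier_params: dict | None = None,
    k: int = 10,
    seed: int = 0,
    leaky: bool = False,
) -> CVReport:
    """Stratified k-fold CV with feature selection inside the loop.

    ``selector_config=None`` uses the full marker set.  ``leaky=True``
    deliberately performs the selection once on all samples before the loop
    (the biased protocol) and exists for demonstrating that bias in tests.
    """
    y = np.asarray(
        list(labels) if labels is not None else table.label_array(), dtype=object
    )
    assignment, k_eff = stratified_kfold(y, k, seed)

    leaky_kit: list[str] | None = None
    if leaky and selector_config is not None:
        leaky_kit = select(table, y, selector_config).selected_markers

    fold_errors: list[float] = []
    fold_sizes: list[int] = []
    fold_kits: list[list[str]] = []
    failed: list[int] = []
    for fold in range(k_eff):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        train = table.subset_samples(train_idx)
        test = table.subset_samples(test_idx)
        y_train, y_test = y[train_idx], y[test_idx]

        if selector_config is None:
            kit = list(table.marker_ids)
        elif leaky_kit is not None:
            kit = leaky_kit
        else:
            kit = select(train, y_train, selector_config).selected_markers
        fold_kits.append(kit)

        try:
            gram = gram_matrix(train, kit)
            model = _fit(classifier, gram, y_train, classifier_params)
            cross = cross_gram(train, test, kit)
            pred = predict(model, cross)
            err = float(np.mean(pred.astype(str) != y_test.astype(str)))
        except Exception as exc:  # noqa: BLE001 - fold-level containment
            warnings.warn(
                f"fold {fold} failed ({exc}); report marked partial",
                RuntimeWarning,
                stacklevel=2,
            )
            failed.append(fold)
            err = float("nan")
        fold_errors.append(err)
        fold_sizes.append(len(test_idx))

    return CVReport(
        selector="none" if selector_config is None else selector_config.method,
        classifier=classifier.upper(),
        kit_size=None if selector_config is None else selector_config.kit_size,
        parameter_name=None,
        parameter_value=None,
        fold_errors=fold_errors,
        fold_sizes=fold_sizes,
        fold_kits=fold_kits,
        seed=seed,
        k=k_eff,
        failed_folds=failed,
    )


def grid_search(
    table: GenotypeTable,
    labels: Sequence | None = None,
    selector: str = "FS",
    classifier: str = "KLDA",
    kit_size: int = 5,
    grid: Sequence[float] = (0.0, 0.75, 1.0, 1.25),
    classifier_params: dict | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[CVReport, list[CVReport]]:
    """CV over a parameter grid (alpha for FS, beta for MIFS).

    Returns ``(best, all_reports)`` where best has minimal mean error, ties
    resolved toward the smaller parameter value.  mRMR has no parameter; the
    grid collapses to a single run.
    """
    if not len(list(grid)):
        raise ValueError("grid must be non-empty")
    param_name = {"FS": "alpha", "MIFS": "beta", "mRMR": None}[selector]
    values = sorted(set(float(g) for g in grid)) if param_name else [None]

    reports: list[CVReport] = []
    for value in values:
        kwargs = {"kit_size": kit_size, "method": selector}
        if param_name == "alpha":
            kwargs["alpha"] = value
        elif param_name == "beta":
            kwargs["beta"] = value
        config = SelectionConfig(**kwargs)
        report = cross_validate(
            table,
            labels,
            selector_config=config,
            classifier=classifier,
            classifier_params=classifier_params,
            k=k,
            seed=seed,
        )
        report.parameter_name = param_name
        report.parameter_value = value
        reports.append(report)

    best = reports[0]
    for report in reports[1:]:
        if report.mean_error < best.mean_error - 1e-15:
            best = report
    return best, reports


def _subset_cv_error(
    K: np.ndarray,
    y: np.ndarray,
    assignment: np.ndarray,
    k_eff: int,
    classifier: str,
    classifier_params: dict | None,
) -> float:
    total_err = 0
    total_n = 0
    for fold in range(k_eff):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        K_train = K[np.ix_(train_idx, train_idx)]
        K_cross = K[np.ix_(test_idx, train_idx)]
        model = _fit(classifier, K_train, y[train_idx], classifier_params)
        pred = predict(model, K_cross)
        total_err += int((pred.astype(str) != y[test_idx].astype(str)).sum())
        total_n += len(test_idx)
    return total_err / total_n


def exhaustive_subset_search(
    table: GenotypeTable,
    labels: Sequence | None = None,
    subset_size: int = 5,
    classifier: str = "KPCLDA",
    classifier_params: dict | None = None,
    k: int = 10,
    seed: int = 0,
    cap: int = 1_000_000,
    count_only: bool = False,
) -> dict:
    """10-fold CV error for every marker subset of the given size.

    Per-marker pair components are precomputed once so each subset's Gram
    matrix is a cheap re-sum.  ``count_only=True`` just enumerates (for
    combinatorial sanity checks).  Returns a dict with the subset list,
    error array, quantile summary and the enumeration count.
    """
    m = table.n_markers
    if not 1 <= subset_size <= m:
        raise ValueError("subset_size must be between 1 and the marker count")
    n_subsets = math.comb(m, subset_size)
    if n_subsets > cap:
        raise ValueError(
            f"{n_subsets} subsets exceed the cap of {cap}; use a random-sample "
            "strategy or raise the cap"
        )
    subsets = list(itertools.combinations(range(m), subset_size))
    assert len(subsets) == n_subsets
    if count_only:
        return {"n_subsets": n_subsets, "subset_size": subset_size}

    y = np.asarray(
        list(labels) if labels is not None else table.label_array(), dtype=object
    )
    assignment, k_eff = stratified_kfold(y, k, seed)
    components = MarkerPairComponents.from_table(table)

    errors = np.empty(n_subsets, dtype=float)
    n_undefined = 0
    for s, subset in enumerate(subsets):
        try:
            K = components.gram_values(subset)
        except DistanceUndefinedError:
            # some sample has no observed allele on this subset; the subset
            # cannot embed it, so it is excluded from the distribution
            errors[s] = np.nan
            n_undefined += 1
            continue
        errors[s] = _subset_cv_error(
            K, y, assignment, k_eff, classifier, classifier_params
        )

    finite = errors[~np.isnan(errors)]
    if finite.size == 0:
        raise DistanceUndefinedError("no subset yields a defined Gram matrix")
    quantiles = {
        q: float(np.percentile(finite, q)) for q in SUBSET_QUANTILES
    }
    marker_subsets = [
        tuple(table.marker_ids[i] for i in subset) for subset in subsets
    ]
    return {
        "n_subsets": n_subsets,
        "subset_size": subset_size,
        "subsets": marker_subsets,
        "errors": errors,
        "n_undefined": n_undefined,
        "quantiles": quantiles,
        "classifier": classifier.upper(),
        "k": k_eff,
        "seed": seed,
    }


def rank_selected_kit(
    selected_kit_error: float, error_distribution: Sequence[float]
) -> float:
    """Fraction of subsets with error strictly below the kit's error."""
    errors = np.asarray(list(error_distribution), dtype=float)
    if errors.size == 0:
        raise ValueError("error distribution is empty")
    return float(np.mean(errors < selected_kit_error))
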