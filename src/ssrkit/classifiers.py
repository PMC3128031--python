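"""Kernel discriminant classifiers on precomputed Nei-Li Gram matrices.

Two methods are provided:

* ``KLDA`` — Fisher's between/within criterion solved in the kernel feature
  space through dual coefficients (regularized generalized eigenproblem).
* ``KPCLDA`` — kernel PCA (double-centered Gram, leading components) followed
  by ordinary multi-class LDA on the component scores.

Both reduce prediction to an affine map of a test sample's similarity vector
followed by nearest-class-centroid assignment in discriminant space, so a
fitted model only needs its training sample ids, one coefficient matrix, one
offset vector and the class centroids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .kernel import GramMatrix

__all__ = [
    "KernelClassifierModel",
    "SingularWithinScatterError",
    "fit_klda",
    "fit_kpclda",
    "predict",
]


class SingularWithinScatterError(np.linalg.LinAlgError):
    """Within-class scatter is singular and no regularization was requested."""


@dataclass
class KernelClassifierModel:
    """A fitted kernel discriminant model.

    Test projection: ``Z = cross @ dual_coefficients - intercept`` where
    ``cross`` is the test x train similarity matrix; labels are assigned by
    the nearest class centroid (Euclidean) in that discriminant space.
    """

    method: str
    training_sample_ids: list[str]
    class_labels: list[str]
    dual_coefficients: np.ndarray  # (n_train, n_discriminants)
    intercept: np.ndarray  # (n_discriminants,)
    class_centroids: np.ndarray  # (n_classes, n_discriminants)
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dual_coefficients = np.asarray(self.dual_coefficients, dtype=float)
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.class_centroids = np.asarray(self.class_centroids, dtype=float)
        n_train = len(self.training_sample_ids)
        if self.dual_coefficients.shape[0] != n_train:
            raise ValueError("dual coefficient rows must match training samples")
        d = self.dual_coefficients.shape[1]
        if self.intercept.shape != (d,):
            raise ValueError("intercept length must match discriminant count")
        if self.class_centroids.shape != (len(self.class_labels), d):
            raise ValueError("centroid shape must be (n_classes, n_discriminants)")

    @property
    def n_discriminants(self) -> int:
        return self.dual_coefficients.shape[1]

    def project(self, cross: np.ndarray) -> np.ndarray:
        cross = np.asarray(cross, dtype=float)
        if cross.ndim != 2 or cross.shape[1] != len(self.training_sample_ids):
            raise ValueError(
                f"similarity matrix has {cross.shape} shape; columns must align "
                f"with the {len(self.training_sample_ids)} training samples"
            )
        return cross @ self.dual_coefficients - self.intercept

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "training_sample_ids": self.training_sample_ids,
            "class_labels": self.class_labels,
            "dual_coefficients": self.dual_coefficients.tolist(),
            "intercept": self.intercept.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "hyperparameters": self.hyperparameters,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "KernelClassifierModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            method=payload["method"],
            training_sample_ids=list(payload["training_sample_ids"]),
            class_labels=list(payload["class_labels"]),
            dual_coefficients=np.asarray(payload["dual_coefficients"]),
            intercept=np.asarray(payload["intercept"]),
            class_centroids=np.asarray(payload["class_centroids"]),
            hyperparameters=payload.get("hyperparameters", {}),
        )


def _check_labels(labels: Sequence, n: int) -> tuple[np.ndarray, list]:
    y = np.asarray(list(labels), dtype=object)
    if len(y) != n:
        raise ValueError("labels must align with Gram matrix samples")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("at least two classes are required")
    return y, classes


def _as_values(gram: GramMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(gram, GramMatrix):
        return gram.values, list(gram.sample_ids)
    K = np.asarray(gram, dtype=float)
    return K, [str(i) for i in range(K.shape[0])]


def _finalize(
    method: str,
    sample_ids: list[str],
    classes: list,
    y: np.ndarray,
    K: np.ndarray,
    coef: np.ndarray,
    intercept: np.ndarray,
    hyperparameters: dict,
) -> KernelClassifierModel:
    scores = K @ coef - intercept
    centroids = np.vstack([scores[y == c].mean(axis=0) for c in classes])
    return KernelClassifierModel(
        method=method,
        training_sample_ids=sample_ids,
        class_labels=[str(c) for c in classes],
        dual_coefficients=coef,
        intercept=intercept,
        class_centroids=centroids,
        hyperparameters=hyperparameters,
    )


def fit_klda(
    gram: GramMatrix | np.ndarray,
    labels: Sequence,
    regularization: float = 1e-3,
) -> KernelClassifierModel:
    """Kernel Fisher discriminant via a regularized generalized eigenproblem.

    The between-class scatter ``K (P - J/n) K`` is maximized against the
    within-class scatter ``K (I - P) K`` in the dual, where ``P`` averages
    within classes and ``J/n`` averages globally.  ``regularization`` adds a
    trace-scaled ridge to the within scatter (required whenever it is
    rank-deficient, which is the norm for kernel matrices).
    """
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    K, sample_ids = _as_values(gram)
    n = K.shape[0]
    y, classes = _check_labels(labels, n)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")

    P = np.zeros((n, n))
    for c in classes:
        members = np.flatnonzero(y == c)
        P[np.ix_(members, members)] = 1.0 / len(members)
    J = np.full((n, n), 1.0 / n)

    between = K @ (P - J) @ K
    within = K @ (np.eye(n) - P) @ K
    between = (between + between.T) / 2.0
    within = (within + within.T) / 2.0

    if regularization > 0:
        scale = np.trace(within) / n
        if scale <= 0:
            scale = max(np.trace(K) / n, 1.0)
        within = within + regularization * scale * np.eye(n)

    try:
        eigvals, eigvecs = scipy.linalg.eigh(between, within)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise SingularWithinScatterError(
            "within-class scatter is singular; pass regularization > 0"
        ) from exc

    d = len(classes) - 1
    order = np.argsort(eigvals)[::-1][:d]
    coef = eigvecs[:, order]
    # scale-normalize each direction; classification is invariant to this
    norms = np.linalg.norm(coef, axis=0)
    norms[norms == 0] = 1.0
    coef = coef / norms

    return _finalize(
        "KLDA",
        sample_ids,
        classes,
        y,
        K,
        coef,
        np.zeros(d),
        {"regularization": regularization},
    )


def _lda_directions(
    X: np.ndarray, y: np.ndarray, classes: list, ridge: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary multi-class LDA directions on feature scores.

    Solves the between/within generalized eigenproblem with a tiny
    trace-scaled ridge so perfectly separated data (zero within-class
    scatter) still yields directions.  Returns ``(W, xbar)`` with one column
    per discriminant (at most n_classes - 1).
    """
    n, d = X.shape
    xbar = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        diff = Xc - mu
        Sw += diff.T @ diff
        Sb += len(Xc) * np.outer(mu - xbar, mu - xbar)
    scale = np.trace(Sw) / d
    if scale <= 0:
        scale = max(np.trace(Sb) / d, 1.0)
    Sw = Sw + ridge * scale * np.eye(d)
    eigvals, eigvecs = scipy.linalg.eigh((Sb + Sb.T) / 2.0, (Sw + Sw.T) / 2.0)
    order = np.argsort(eigvals)[::-1][: len(classes) - 1]
    return eigvecs[:, order], xbar


def _center_train(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Double-center a training Gram matrix; return (Kc, row_means, grand)."""
    row_means = K.mean(axis=0)
    grand = K.mean()
    Kc = K - row_means[None, :] - row_means[:, None] + grand
    return Kc, row_means, grand


def fit_kpclda(
    gram: GramMatrix | np.ndarray,
    labels: Sequence,
    eig_rtol: float = 1e-9,
    max_components: int | None = None,
) -> KernelClassifierModel:
    """Kernel PCA (double-centered Gram) followed by LDA on the scores.

    Components with eigenvalue above ``eig_rtol`` times the largest are
    retained, capped at ``n_train - n_classes`` (or ``max_components``) to
    keep LDA well-posed.  If fewer than ``n_classes - 1`` components survive,
    a warning is issued and all positive-eigenvalue components are used.
    """
    K, sample_ids = _as_values(gram)
    n = K.shape[0]
    y, classes = _check_labels(labels, n)
    n_classes = len(classes)

    Kc, row_means, grand = _center_train(K)
    eigvals, eigvecs = scipy.linalg.eigh((Kc + Kc.T) / 2.0)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    largest = eigvals[0] if eigvals.size else 0.0
    if largest <= 0:
        raise ValueError("degenerate kernel: all samples are identical after centering")

    keep = eigvals > eig_rtol * largest
    cap = n - n_classes if max_components is None else max_components
    cap = max(cap, 1)
    idx = np.flatnonzero(keep)[:cap]
    if len(idx) < n_classes - 1:
        warnings.warn(
            f"only {len(idx)} kernel components retained for {n_classes} classes; "
            "falling back to all positive-eigenvalue components",
            RuntimeWarning,
            stacklevel=2,
        )
        idx = np.flatnonzero(eigvals > 0)
    lam = eigvals[idx]
    V = eigvecs[:, idx]
    # score of training sample i on component j is sqrt(lam_j) * V[i, j];
    # equivalently Kc @ A with A = V / sqrt(lam)
    A = V / np.sqrt(lam)[None, :]

    scores = Kc @ A
    W, xbar = _lda_directions(scores, y, classes)

    # fold KPCA centering + projection + LDA transform into one affine map:
    # disc(k) = (center(k) @ A - xbar) @ W
    #         = k @ B - (row_means @ B_raw ... )  with centering expanded
    # center(k) = (k - row_means) - mean(k - row_means) * 1
    #           = (k - row_means) @ (I - J/n)  applied on the train axis
    C = (np.eye(n) - np.full((n, n), 1.0 / n)) @ A @ W
    coef = C
    intercept = row_means @ C + xbar @ W

    return _finalize(
        "KPCLDA",
        sample_ids,
        classes,
        y,
        K,
        coef,
        intercept,
        {
            "eig_rtol": eig_rtol,
            "n_components": int(len(idx)),
        },
    )


def predict(model: KernelClassifierModel, cross: np.ndarray) -> np.ndarray:
    """Assign each test sample the label of its nearest class centroid.

    ``cross`` is the test x train similarity matrix with columns aligned to
    ``model.training_sample_ids``.
    """
    scores = model.project(cross)
    dist2 = (
        (scores**2).sum(axis=1)[:, None]
        - 2.0 * scores @ model.class_centroids.T
        + (model.class_centroids**2).sum(axis=1)[None, :]
    )
    winners = np.argmin(dist2, axis=1)
    return np.asarray([model.class_labels[w] for w in winners], dtype=object)
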