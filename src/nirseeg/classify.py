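"""Two-class Fisher linear discriminant, written from scratch.

The decoder reduces each control decision to binary problems (each movement
command against Stop, plus left-vs-right and arithmetic-vs-counting inside
the fusion stage). The discriminant is the classical pooled-covariance LDA:

    w = S_pooled^-1 (mu_1 - mu_0)
    b = -w . (mu_0 + mu_1) / 2 + ln(pi_1 / pi_0)

with a small ridge added to the covariance diagonal when it is singular.
The decision is ``sign(w . x + b)``; exact ties break to class 0, which by
convention is the rest/Stop class (no movement on ambiguity).

Evaluation uses seed-controlled stratified k-fold cross-validation,
implemented here directly so the classifier stack has no external
dependencies beyond numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateModelError, InvalidArgumentError


@dataclass
class LDAModel:
    """Fitted two-class linear discriminant."""

    w: np.ndarray  # weight vector, shape [p]
    b: float
    means: np.ndarray  # class means, shape [2 x p] (class 0 first)
    pooled_cov: np.ndarray  # [p x p]
    classes: tuple  # (class0, class1); class 0 wins ties
    priors: tuple[float, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "w": self.w.tolist(),
                "b": self.b,
                "means": self.means.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "classes": list(self.classes),
                "priors": list(self.priors),
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "LDAModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            means=np.asarray(d["means"], dtype=float),
            pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
            classes=tuple(d["classes"]),
            priors=tuple(d["priors"]),
        )


def fit_lda(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    classes: tuple | None = None,
    ridge: float | None = None,
) -> LDAModel:
    """Fit the pooled-covariance discriminant.

    ``classes`` fixes the (class0, class1) order; by default labels are
    sorted, with 'rest'/'Stop'-like labels forced into the class-0 slot when
    present so that ties decode conservatively to no movement.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise InvalidArgumentError(
            f"features [n x p] and labels [n] must align, got {x.shape} vs {y.shape}"
        )
    uniq = sorted(np.unique(y).tolist())
    if classes is None:
        rest_like = [c for c in uniq if str(c).lower() in ("rest", "stop")]
        classes = tuple(rest_like + [c for c in uniq if c not in rest_like])
    if len(classes) != 2 or set(classes) != set(uniq):
        raise InvalidArgumentError(f"need exactly two classes, got {uniq}")
    n0, n1 = (int(np.sum(y == c)) for c in classes)
    if min(n0, n1) < 2:
        raise InvalidArgumentError(
            f"each class needs >= 2 samples, got {n0} and {n1} for {classes}"
        )
    if np.allclose(x, x[0], atol=0.0):
        raise DegenerateModelError("all feature vectors are identical")

    x0, x1 = x[y == classes[0]], x[y == classes[1]]
    mu0, mu1 = x0.mean(axis=0), x1.mean(axis=0)
    scatter = (x0 - mu0).T @ (x0 - mu0) + (x1 - mu1).T @ (x1 - mu1)
    cov = scatter / max(1, n0 + n1 - 2)
    p = x.shape[1]
    if ridge is None:
        # regularize only when the pooled covariance is (near-)singular
        if np.linalg.matrix_rank(cov, tol=1e-10 * max(1.0, np.trace(cov))) < p:
            ridge = max(1e-6 * np.trace(cov) / p, 1e-12)
        else:
            ridge = 0.0
    cov_r = cov + ridge * np.eye(p)
    try:
        w = np.linalg.solve(cov_r, mu1 - mu0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - ridge should prevent this
        raise DegenerateModelError(f"pooled covariance not solvable: {exc}") from exc
    priors = (n0 / (n0 + n1), n1 / (n0 + n1))
    b = float(-w @ (mu0 + mu1) / 2.0 + np.log(priors[1] / priors[0]))
    return LDAModel(
        w=w,
        b=b,
        means=np.stack([mu0, mu1]),
        pooled_cov=cov,
        classes=tuple(classes),
        priors=priors,
    )


def decision_scores(model: LDAModel, features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.w.shape[0]:
        raise InvalidArgumentError(
            f"feature dimension {x.shape[1]} does not match model dimension {model.w.shape[0]}"
        )
    scores = x @ model.w + model.b
    return scores[0] if squeeze else scores


def predict(model: LDAModel, features: np.ndarray):
    """Predicted label(s) plus discriminant score(s); ties -> class 0."""
    scores = decision_scores(model, features)
    if np.ndim(scores) == 0:
        return (model.classes[1] if scores > 0 else model.classes[0]), float(scores)
    labels = np.where(scores > 0, model.classes[1], model.classes[0])
    return labels, scores


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified k-fold assignment (round-robin within each class)."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


@dataclass
class CrossValidationResult:
    accuracy: float  # percent
    fold_accuracies: list[float]
    n: int
    classes: tuple

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CrossValidationResult(accuracy={self.accuracy:.1f}%, k={len(self.fold_accuracies)})"


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    *,
    classes: tuple | None = None,
) -> CrossValidationResult:
    """Stratified k-fold accuracy (percent), deterministic given the seed."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = y.shape[0]
    if k < 2:
        raise InvalidArgumentError(f"k must be >= 2, got {k}")
    if k > n:
        raise InvalidArgumentError(f"k = {k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    correct = 0
    fold_acc = []
    fitted_classes: tuple | None = None
    for fold in folds:
        if fold.size == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = fit_lda(x[mask], y[mask], classes=classes)
        fitted_classes = model.classes
        pred, _ = predict(model, x[fold])
        hits = int(np.sum(pred == y[fold]))
        correct += hits
        fold_acc.append(100.0 * hits / fold.size)
    return CrossValidationResult(
        accuracy=100.0 * correct / n,
        fold_accuracies=fold_acc,
        n=n,
        classes=fitted_classes or tuple(np.unique(y)),
    )
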