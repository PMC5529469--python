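"""Multi-kernel SVM classification under nested leave-one-out CV.

Each network type (low, high, associated) contributes its own feature
matrix; after per-fold PCA+LASSO selection the subject vectors are
scaled to unit Euclidean norm and turned into a linear Gram matrix.
The composite kernel is a convex combination
``K = τ₁·K_low + τ₂·K_high + τ₃·K_assoc`` with the weights on the
probability simplex, and a soft-margin SVM (C = 1) classifies on it.

The outer leave-one-out loop holds out one subject at a time; an inner
leave-one-out loop on the remaining ``N − 1`` picks the LASSO penalty of
each network type (by single-kernel inner accuracy) and then the kernel
weights (over a simplex grid), after which the winning configuration is
refit on all ``N − 1`` subjects to predict the held-out one.  Ties in
inner accuracy break deterministically: for penalties, toward the
smallest λ; for weights, toward larger weight on the low-order kernel,
then on the high-order kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidConfigError,
    InvalidWeightError,
    ShapeError,
)
from .evaluation import MetricReport, eq1_metrics
from .selection import (
    fit_pca,
    lambda_grid,
    pick_nonempty_lambda,
    selection_path,
)
from .svm import svm_fit_predict

__all__ = [
    "KernelBundle",
    "FoldRecord",
    "CVResult",
    "ClassifierConfig",
    "normalize_rows",
    "linear_gram",
    "cross_gram",
    "composite_kernel",
    "weight_grid",
    "nested_loocv",
]

_SIMPLEX_TOL = 1e-9

# weight ordering convention: τ₁ low, τ₂ high, τ₃ associated
_TYPE_ORDER = {"low": 0, "high": 1, "associated": 2}


def canonical_type_order(keys) -> list[str]:
    """Network types in the fixed fusion order low → high → associated
    (unrecognized names follow alphabetically)."""
    return sorted(keys, key=lambda t: (_TYPE_ORDER.get(t, len(_TYPE_ORDER)), t))


@dataclass
class ClassifierConfig:
    """Hyperparameter search space and SVM settings.

    ``tau_step`` controls the simplex grid of kernel weights; the λ grid
    has ``n_lambdas`` log-spaced penalties down to ``lambda_min_ratio``
    of each fold's λ_max.
    """

    tau_step: float = 0.1
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    svm_c: float = 1.0
    standardize_features: bool = True
    normalize: str = "unit"  # unit-norm per subject; "none" to disable

    def __post_init__(self) -> None:
        if not 0 < self.tau_step <= 0.5 and self.tau_step != 1.0:
            raise InvalidConfigError(f"tau_step must be in (0, 0.5] or 1, got {self.tau_step}")
        if self.n_lambdas < 1:
            raise InvalidConfigError("n_lambdas must be >= 1")
        if self.normalize not in ("unit", "none"):
            raise InvalidConfigError(f"unknown normalization {self.normalize!r}")


@dataclass
class KernelBundle:
    """Per-type Gram matrices, simplex weights, and their combination."""

    grams: dict[str, np.ndarray]
    weights: tuple[float, ...]
    composite: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.composite = composite_kernel(
            [self.grams[t] for t in canonical_type_order(self.grams)], self.weights
        )


@dataclass
class FoldRecord:
    """Audit trail of one outer fold's inner-CV choices."""

    test_index: int
    lambdas: dict[str, float]
    weights: tuple[float, ...]
    inner_accuracy: float
    n_selected: dict[str, int]


@dataclass
class CVResult:
    """One held-out prediction per subject plus aggregate metrics."""

    y_true: np.ndarray
    y_pred: np.ndarray
    decision_values: np.ndarray
    folds: list[FoldRecord]
    metrics: MetricReport


def normalize_rows(features: np.ndarray) -> np.ndarray:
    """Scale each subject's vector to unit Euclidean norm (zero rows kept
    at zero).  Uses no cross-subject statistics, hence leakage-safe."""
    x = np.asarray(features, dtype=float)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)


def linear_gram(features: np.ndarray, *, normalize: bool = True) -> np.ndarray:
    """Linear kernel ``K[a, b] = f_aᵀ f_b`` across subjects."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ShapeError(f"features must be 2-D, got {x.shape}")
    if x.shape[1] == 0:
        raise ShapeError("empty feature vectors (0 features)")
    if normalize:
        x = normalize_rows(x)
    g = x @ x.T
    return (g + g.T) / 2.0


def cross_gram(
    test_features: np.ndarray, train_features: np.ndarray, *, normalize: bool = True
) -> np.ndarray:
    """Kernel values between test rows and training rows."""
    a = np.asarray(test_features, dtype=float)
    b = np.asarray(train_features, dtype=float)
    if a.shape[1] != b.shape[1]:
        raise ShapeError(f"feature dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    if normalize:
        a = normalize_rows(a)
        b = normalize_rows(b)
    return a @ b.T


def composite_kernel(
    grams: list[np.ndarray] | tuple[np.ndarray, ...], weights: tuple[float, ...]
) -> np.ndarray:
    """Convex combination of Gram matrices with weights on the simplex."""
    weights = tuple(float(w) for w in weights)
    if len(grams) != len(weights):
        raise ShapeError(f"{len(grams)} kernels but {len(weights)} weights")
    if min(weights) < -_SIMPLEX_TOL or abs(sum(weights) - 1.0) > _SIMPLEX_TOL:
        raise InvalidWeightError(
            f"kernel weights must be nonnegative and sum to 1, got {weights}"
        )
    shapes = {np.asarray(g).shape for g in grams}
    if len(shapes) != 1:
        raise ShapeError(f"Gram matrices not conformable: {sorted(shapes)}")
    out = np.zeros(shapes.pop())
    for w, g in zip(weights, grams):
        out += w * np.asarray(g, dtype=float)
    return out


def weight_grid(step: float = 0.1, n_kernels: int = 3) -> list[tuple[float, ...]]:
    """All weight tuples on the simplex lattice with the given step.

    For three kernels these are the ``(τ₁, τ₂, τ₃ = 1 − τ₁ − τ₂)`` with
    ``τ₁, τ₂ ∈ {0, step, 2·step, ..., 1}`` and ``τ₁ + τ₂ ≤ 1``.
    """
    if not 0 < step <= 1:
        raise InvalidConfigError(f"weight step must be in (0, 1], got {step}")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise InvalidConfigError(f"weight step {step} does not divide 1 evenly")
    if n_kernels == 1:
        return [(1.0,)]

    grid: list[tuple[float, ...]] = []

    def extend(prefix: list[int], remaining: int, slots: int) -> None:
        if slots == 1:
            grid.append(tuple(p / n_steps for p in prefix + [remaining]))
            return
        for units in range(remaining + 1):
            extend(prefix + [units], remaining - units, slots - 1)

    extend([], n_steps, n_kernels)
    return grid


def _loo_folds(n: int) -> list[tuple[np.ndarray, int]]:
    idx = np.arange(n)
    return [(np.delete(idx, i), i) for i in range(n)]


class _TypePipeline:
    """Per-fold cache of the selection path for one network type.

    For a given training subset, fits standardize+PCA once and the full
    LASSO coefficient path once; selected features for any penalty index
    are then a cheap column slice.
    """

    def __init__(
        self,
        features: np.ndarray,
        labels_pm1: np.ndarray,
        train_idx: np.ndarray,
        lambdas: np.ndarray,
        standardize: bool,
    ) -> None:
        self.lambdas = lambdas
        self.model = fit_pca(features[train_idx], standardize=standardize)
        self.train_pcs = self.model.transform_pca(features[train_idx])
        self.coef_path = selection_path(self.train_pcs, labels_pm1[train_idx], lambdas)

    def selected(self, lam_index: int) -> np.ndarray:
        """Column indices selected at the (fallback-adjusted) penalty."""
        eff = pick_nonempty_lambda(self.coef_path, self.lambdas, lam_index)
        return np.flatnonzero(self.coef_path[eff] != 0.0)

    def train_features(self, lam_index: int) -> np.ndarray:
        return self.train_pcs[:, self.selected(lam_index)]

    def test_features(self, x_raw: np.ndarray, lam_index: int) -> np.ndarray:
        return self.model.transform_pca(np.atleast_2d(x_raw))[:, self.selected(lam_index)]


def _tie_key(weights: tuple[float, ...]) -> tuple[float, ...]:
    # sort candidates so that, at equal accuracy, larger weight on the
    # first (low-order) kernel wins, then on the second, etc.
    return tuple(-w for w in weights)


def nested_loocv(
    features_by_type: dict[str, np.ndarray],
    labels: np.ndarray,
    config: ClassifierConfig | None = None,
    *,
    taus: list[tuple[float, ...]] | None = None,
) -> CVResult:
    """Nested leave-one-out evaluation of the multi-kernel pipeline.

    ``features_by_type`` maps each network type to its raw ``N × D``
    WLCC feature matrix (a single-type dict runs the corresponding
    single-network pipeline).  Labels are binary; the larger value is
    the positive class.  Deterministic given the inputs.  ``taus``
    overrides the kernel-weight grid (e.g. a single simplex vertex pins
    the fusion to one network type).
    """
    config = config or ClassifierConfig()
    types = canonical_type_order(features_by_type)
    if not types:
        raise InvalidConfigError("no feature sets given")
    y = np.asarray(labels, dtype=float).ravel()
    n = y.size
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need two classes, got {classes.tolist()}")
    if n < 6 or min(np.sum(y == c) for c in classes) < 3:
        raise InsufficientDataError("nested LOOCV needs N >= 6 with >= 3 per class")
    y_pm1 = np.where(y == classes.max(), 1.0, -1.0)
    mats = {t: np.asarray(features_by_type[t], dtype=float) for t in types}
    for t in types:
        if mats[t].shape[0] != n:
            raise ShapeError(f"type {t!r} has {mats[t].shape[0]} rows for {n} labels")

    if taus is None:
        taus = weight_grid(config.tau_step, n_kernels=len(types))
    if not taus:
        raise InvalidConfigError("empty kernel-weight grid")
    if any(len(t) != len(types) for t in taus):
        raise InvalidConfigError("weight tuples must have one entry per network type")
    taus = sorted(taus, key=_tie_key)
    norm = config.normalize == "unit"

    decision_values = np.zeros(n)
    y_pred = np.zeros(n)
    folds: list[FoldRecord] = []

    for train_idx, test_i in _loo_folds(n):
        y_tr = y_pm1[train_idx]
        # λ grid per type from the full outer-training set
        grids: dict[str, np.ndarray] = {}
        for t in types:
            outer_model = fit_pca(mats[t][train_idx], standardize=config.standardize_features)
            pcs = outer_model.transform_pca(mats[t][train_idx])
            grids[t] = lambda_grid(
                pcs, y_tr, n_lambdas=config.n_lambdas, min_ratio=config.lambda_min_ratio
            )

        inner = _loo_folds(train_idx.size)
        # one selection-path fit per (inner fold, type)
        pipes: list[dict[str, _TypePipeline]] = []
        for in_tr, _ in inner:
            pipes.append(
                {
                    t: _TypePipeline(
                        mats[t][train_idx],
                        y_tr,
                        in_tr,
                        grids[t],
                        config.standardize_features,
                    )
                    for t in types
                }
            )

        # stage 1: λ per type by single-kernel inner-LOOCV accuracy;
        # ties break toward the smallest λ (grids are descending)
        chosen_lam: dict[str, int] = {}
        for t in types:
            best_acc, best_l = -1.0, 0
            for l in range(config.n_lambdas):
                hits = 0
                for (in_tr, in_te), pipe in zip(inner, pipes):
                    f_tr = pipe[t].train_features(l)
                    f_te = pipe[t].test_features(mats[t][train_idx][in_te], l)
                    gram = linear_gram(f_tr, normalize=norm)
                    cg = cross_gram(f_te, f_tr, normalize=norm)
                    _, pred = svm_fit_predict(gram, y_tr[in_tr], cg, c=config.svm_c)
                    hits += pred[0] == y_tr[in_te]
                acc = hits / len(inner)
                if acc >= best_acc:  # >= walks toward smaller λ on ties
                    best_acc, best_l = acc, l
            chosen_lam[t] = best_l

        # stage 2: kernel weights by inner-LOOCV accuracy at the chosen λs
        inner_grams = []
        for (in_tr, in_te), pipe in zip(inner, pipes):
            per_type = {}
            for t in types:
                f_tr = pipe[t].train_features(chosen_lam[t])
                f_te = pipe[t].test_features(mats[t][train_idx][in_te], chosen_lam[t])
                per_type[t] = (
                    linear_gram(f_tr, normalize=norm),
                    cross_gram(f_te, f_tr, normalize=norm),
                )
            inner_grams.append(per_type)

        best_acc, best_tau = -1.0, taus[0]
        for tau in taus:
            hits = 0
            for (in_tr, in_te), per_type in zip(inner, inner_grams):
                gram = composite_kernel([per_type[t][0] for t in types], tau)
                cg = composite_kernel([per_type[t][1] for t in types], tau)
                _, pred = svm_fit_predict(gram, y_tr[in_tr], cg, c=config.svm_c)
                hits += pred[0] == y_tr[in_te]
            acc = hits / len(inner)
            if acc > best_acc:  # taus pre-sorted by the tie-break order
                best_acc, best_tau = acc, tau

        # refit the winning configuration on all N−1 and predict held out
        full = {
            t: _TypePipeline(
                mats[t][train_idx],
                y_tr,
                np.arange(train_idx.size),
                grids[t],
                config.standardize_features,
            )
            for t in types
        }
        train_grams = []
        cross_grams = []
        lam_values: dict[str, float] = {}
        n_selected: dict[str, int] = {}
        for t in types:
            l = chosen_lam[t]
            f_tr = full[t].train_features(l)
            f_te = full[t].test_features(mats[t][test_i], l)
            train_grams.append(linear_gram(f_tr, normalize=norm))
            cross_grams.append(cross_gram(f_te, f_tr, normalize=norm))
            eff = pick_nonempty_lambda(full[t].coef_path, grids[t], l, loud=True)
            lam_values[t] = float(grids[t][eff])
            n_selected[t] = int(full[t].selected(l).size)
        gram = composite_kernel(train_grams, best_tau)
        cg = composite_kernel(cross_grams, best_tau)
        dec, pred = svm_fit_predict(gram, y_pm1[train_idx], cg, c=config.svm_c)
        decision_values[test_i] = dec[0]
        y_pred[test_i] = classes.max() if pred[0] > 0 else classes.min()
        folds.append(
            FoldRecord(
                test_index=test_i,
                lambdas=lam_values,
                weights=best_tau,
                inner_accuracy=best_acc,
                n_selected=n_selected,
            )
        )

    metrics = eq1_metrics(y, y_pred, decision_values)
    return CVResult(
        y_true=y,
        y_pred=y_pred,
        decision_values=decision_values,
        folds=folds,
        metrics=metrics,
    )
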