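"""Dimension reduction and supervised feature selection.

Per network type, the cohort's WLCC feature matrix (``N × Q·R``) is
first standardized (train mean/std per column), then projected onto its
principal components — at most ``N_train − 1`` of them carry nonzero
variance — and finally screened with the classical LASSO: an
L1-penalized least-squares regression of the ±1 class labels on the
components; components with nonzero coefficients are retained.

Every statistic (scaling, PCA mean/loadings, LASSO coefficients) is
estimated on training subjects only and applied frozen to test
subjects, which is what makes the nested cross-validation leakage-free.

The LASSO objective follows scikit-learn's convention,
``(1/2n)·||y − Xw||² + λ·||w||₁``, so the smallest penalty that zeroes
every coefficient is ``λ_max = max_j |x_jᵀ(y − ȳ)| / n``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso, lasso_path

from .errors import DegenerateLabelsError, InsufficientDataError, ShapeError

__all__ = [
    "FeatureMatrix",
    "SelectionModel",
    "fit_pca",
    "fit_lasso",
    "apply_selection",
    "fit_selection_model",
    "lambda_grid",
    "selection_path",
    "pick_nonempty_lambda",
]

logger = logging.getLogger(__name__)

_LASSO_TOL = 1e-7
#: Eigenvalues below this fraction of the largest count as zero.
_EIG_RTOL = 1e-10


@dataclass
class FeatureMatrix:
    """``N × D`` feature table with a processing-stage tag."""

    values: np.ndarray
    stage: str = "raw"  # raw | pca | selected
    column_meta: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"feature matrix must be 2-D, got {self.values.shape}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SelectionModel:
    """Frozen train-set statistics for standardize → PCA → LASSO-select."""

    scale_mean: np.ndarray
    scale_std: np.ndarray
    pca_mean: np.ndarray
    components: np.ndarray  # (n_components, D0) orthonormal rows
    eigenvalues: np.ndarray
    lasso_lambda: float | None = None
    coefficients: np.ndarray | None = None
    selected_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_input_features(self) -> int:
        return self.components.shape[1]

    def save(self, path) -> None:
        """Serialize the fitted statistics to one ``.npz`` archive."""
        if self.coefficients is None:
            raise ValueError("cannot serialize a partially fitted model")
        np.savez(
            path,
            scale_mean=self.scale_mean,
            scale_std=self.scale_std,
            pca_mean=self.pca_mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
            lasso_lambda=np.array(self.lasso_lambda),
            coefficients=self.coefficients,
            selected_indices=self.selected_indices,
        )

    @classmethod
    def load(cls, path) -> "SelectionModel":
        with np.load(path) as data:
            return cls(
                scale_mean=data["scale_mean"],
                scale_std=data["scale_std"],
                pca_mean=data["pca_mean"],
                components=data["components"],
                eigenvalues=data["eigenvalues"],
                lasso_lambda=float(data["lasso_lambda"]),
                coefficients=data["coefficients"],
                selected_indices=data["selected_indices"],
            )

    def transform_pca(self, x: np.ndarray) -> np.ndarray:
        """Standardize with stored scale, centre, project on components."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_input_features:
            raise ShapeError(
                f"expected (n, {self.n_input_features}) features, got {x.shape}"
            )
        z = (x - self.scale_mean) / self.scale_std
        return (z - self.pca_mean) @ self.components.T


def _signs(labels: np.ndarray) -> np.ndarray:
    """Map binary {0,1} or ±1 labels to ±1; reject single-class input."""
    y = np.asarray(labels, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(
            f"need exactly two classes, got labels {classes.tolist()}"
        )
    return np.where(y == classes.max(), 1.0, -1.0)


def fit_pca(
    train: FeatureMatrix | np.ndarray, *, standardize: bool = True
) -> SelectionModel:
    """Fit the unsupervised half of the selection model on training rows.

    Retains the principal components with nonzero eigenvalues — at most
    ``N_train − 1`` for centred data.
    """
    x = train.values if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"PCA needs at least 3 training subjects, got {n}")
    mean = x.mean(axis=0)
    if standardize:
        std = x.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros_like(mean)
        std = np.ones_like(mean)
    z = (x - mean) / std
    pca = PCA(n_components=min(n - 1, x.shape[1]), svd_solver="full")
    pca.fit(z)
    ev = pca.explained_variance_
    keep = ev > _EIG_RTOL * max(ev[0], np.finfo(float).tiny)
    return SelectionModel(
        scale_mean=mean,
        scale_std=std,
        pca_mean=pca.mean_,
        components=pca.components_[keep],
        eigenvalues=ev[keep],
    )


def lambda_grid(
    train_pca: np.ndarray,
    labels: np.ndarray,
    *,
    n_lambdas: int = 20,
    min_ratio: float = 1e-3,
) -> np.ndarray:
    """Descending log-spaced LASSO penalties spanning
    ``[min_ratio·λ_max, λ_max]`` for the given training components."""
    x = np.asarray(train_pca, dtype=float)
    y = _signs(labels)
    n = x.shape[0]
    lam_max = float(np.max(np.abs(x.T @ (y - y.mean())))) / n
    if lam_max <= 0:  # pathological: components carry no label signal
        lam_max = 1e-6
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambdas)


def fit_lasso(
    train_pca: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    lasso_lambda: float,
    *,
    model: SelectionModel | None = None,
) -> SelectionModel:
    """L1-penalized regression of ±1 labels on principal components.

    Completes ``model`` (or a bare one) with the penalty, coefficients
    and the indices of nonzero-coefficient components.
    """
    x = train_pca.values if isinstance(train_pca, FeatureMatrix) else np.asarray(train_pca, float)
    y = _signs(labels)
    lasso = Lasso(alpha=lasso_lambda, fit_intercept=True, tol=_LASSO_TOL, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter on tiny folds
        lasso.fit(x, y)
    coef = lasso.coef_
    selected = np.flatnonzero(coef != 0.0)
    if model is None:
        d = x.shape[1]
        model = SelectionModel(
            scale_mean=np.zeros(d),
            scale_std=np.ones(d),
            pca_mean=np.zeros(d),
            components=np.eye(d),
            eigenvalues=np.ones(d),
        )
    model.lasso_lambda = float(lasso_lambda)
    model.coefficients = coef
    model.selected_indices = selected
    return model


def selection_path(
    train_pca: np.ndarray, labels: np.ndarray, lambdas: np.ndarray
) -> np.ndarray:
    """Coefficients along a descending λ path, shape ``(n_lambdas, D)``.

    One coordinate-descent sweep over the whole path; columns of the
    result with nonzero entries are the selected components at that λ.
    """
    x = np.asarray(train_pca, dtype=float)
    y = _signs(labels)
    lambdas = np.asarray(lambdas, dtype=float)
    order = np.argsort(lambdas)[::-1]  # lasso_path wants descending
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = lasso_path(x, y, alphas=lambdas[order], tol=_LASSO_TOL)
    out = np.empty((lambdas.size, x.shape[1]))
    out[order] = coefs.T
    return out


def pick_nonempty_lambda(
    coef_path: np.ndarray, lambdas: np.ndarray, chosen_index: int, *, loud: bool = False
) -> int:
    """Index of the penalty to actually use: ``chosen_index`` unless it
    selects nothing, in which case fall back to the smallest λ selecting at
    least one component; the last grid point if all empty.

    The fallback is logged as a warning when ``loud`` (final refits) and
    at debug level otherwise (routine during grid search, where the
    largest penalties select nothing by construction).
    """
    if np.any(coef_path[chosen_index] != 0.0):
        return chosen_index
    log = logger.warning if loud else logger.debug
    nonzero = np.flatnonzero(np.any(coef_path != 0.0, axis=1))
    if nonzero.size == 0:
        log("LASSO selected zero features at every penalty; using the smallest")
        return len(lambdas) - 1
    # lambdas are descending, so the last nonempty index is the smallest such λ
    fallback = int(nonzero[-1])
    log(
        "LASSO selected zero features at lambda=%.3g; falling back to lambda=%.3g",
        lambdas[chosen_index],
        lambdas[fallback],
    )
    return fallback


def apply_selection(model: SelectionModel, subjects: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project raw features through the frozen model and keep the
    LASSO-selected components.  Never refits on the given rows."""
    if model.coefficients is None:
        raise ValueError("selection model is not fully fitted (no LASSO stage)")
    x = subjects.values if isinstance(subjects, FeatureMatrix) else np.asarray(subjects, float)
    return model.transform_pca(x)[:, model.selected_indices]


def fit_selection_model(
    train: np.ndarray,
    labels: np.ndarray,
    lasso_lambda: float,
    *,
    standardize: bool = True,
) -> SelectionModel:
    """Convenience: fit standardize → PCA → LASSO in one call."""
    model = fit_pca(FeatureMatrix(np.asarray(train, float)), standardize=standardize)
    pcs = model.transform_pca(np.asarray(train, float))
    return fit_lasso(pcs, labels, lasso_lambda, model=model)
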