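"""Soft-margin SVM with a precomputed kernel.

Nested leave-one-out model selection fits on the order of 10^5 SVMs per
cohort, each on a handful of subjects, so the dual problem is solved by
a compact SMO (sequential minimal optimization) routine compiled with
numba rather than by going through a full estimator API per fit.  The
solver is the standard C-SVC dual

    min_α  ½ αᵀQα − eᵀα   s.t.  0 ≤ α_i ≤ C,  yᵀα = 0,

with ``Q_ij = y_i y_j K_ij``, maximal-violating-pair working-set
selection and the usual KKT stopping rule; the intercept is the midpoint
of the final violation bounds, exactly as in LIBSVM.  Agreement with
scikit-learn's ``SVC(kernel="precomputed")`` is checked in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import DegenerateLabelsError, ShapeError

__all__ = ["svm_fit", "svm_fit_predict", "SVM_TOL"]

#: KKT violation tolerance of the dual solver.
SVM_TOL = 1e-6


@njit(cache=True)
def _smo(kernel, y, c, tol, max_iter):  # pragma: no cover - exercised via svm_fit
    n = kernel.shape[0]
    alpha = np.zeros(n)
    grad = -np.ones(n)  # grad_i = (Qα)_i − 1
    for _ in range(max_iter):
        # maximal violating pair: i maximizes −y_i·grad_i over I_up,
        # j minimizes it over I_low
        g_max = -1e300
        g_min = 1e300
        i_sel = -1
        j_sel = -1
        for t in range(n):
            v = -y[t] * grad[t]
            if (y[t] > 0 and alpha[t] < c) or (y[t] < 0 and alpha[t] > 0):
                if v > g_max:
                    g_max = v
                    i_sel = t
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < c):
                if v < g_min:
                    g_min = v
                    j_sel = t
        if g_max - g_min < tol or i_sel < 0 or j_sel < 0:
            break
        i = i_sel
        j = j_sel
        quad = kernel[i, i] + kernel[j, j] - 2.0 * kernel[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        step = (g_max - g_min) / quad
        # box constraints along the feasible direction α_i += y_i t, α_j −= y_j t
        if y[i] > 0:
            step = min(step, c - alpha[i])
        else:
            step = min(step, alpha[i])
        if y[j] > 0:
            step = min(step, alpha[j])
        else:
            step = min(step, c - alpha[j])
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        for t in range(n):
            grad[t] += y[t] * step * (kernel[t, i] - kernel[t, j])
    # intercept: −y·grad equals b for free SVs; midpoint of the bounds otherwise
    g_max = -1e300
    g_min = 1e300
    for t in range(n):
        v = -y[t] * grad[t]
        if (y[t] > 0 and alpha[t] < c) or (y[t] < 0 and alpha[t] > 0):
            if v > g_max:
                g_max = v
        if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < c):
            if v < g_min:
                g_min = v
    b = 0.5 * (g_max + g_min)
    return alpha, b


def svm_fit(
    train_gram: np.ndarray,
    train_labels: np.ndarray,
    *,
    c: float = 1.0,
    tol: float = SVM_TOL,
) -> tuple[np.ndarray, float]:
    """Solve the C-SVC dual on a precomputed Gram matrix.

    Returns ``(dual_coef, intercept)`` where ``dual_coef = α ⊙ y``, so a
    decision value is ``K_test_train @ dual_coef + intercept``.
    """
    gram = np.ascontiguousarray(train_gram, dtype=np.float64)
    if gram.ndim != 2 or gram.shape[0] != gram.shape[1]:
        raise ShapeError(f"training Gram matrix must be square, got {gram.shape}")
    y = np.asarray(train_labels, dtype=np.float64).ravel()
    if y.size != gram.shape[0]:
        raise ShapeError("label count does not match Gram size")
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(
            f"training fold must contain both classes, got {classes.tolist()}"
        )
    signs = np.where(y == classes.max(), 1.0, -1.0)
    max_iter = max(10_000, 200 * y.size * y.size)
    alpha, b = _smo(gram, signs, float(c), float(tol), max_iter)
    return alpha * signs, float(b)


def svm_fit_predict(
    train_gram: np.ndarray,
    train_labels: np.ndarray,
    cross_gram: np.ndarray,
    *,
    c: float = 1.0,
    tol: float = SVM_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training Gram and score test rows.

    ``cross_gram`` holds kernel values between test rows and training
    rows, shape ``(n_test, n_train)``.  Returns ``(decision_values,
    predicted_signs)``; the decision sign gives the predicted class
    (+1 for the larger label value), with ties going to +1.
    """
    dual_coef, intercept = svm_fit(train_gram, train_labels, c=c, tol=tol)
    cross = np.asarray(cross_gram, dtype=np.float64)
    if cross.ndim == 1:
        cross = cross[None, :]
    if cross.shape[1] != dual_coef.size:
        raise ShapeError(
            f"cross Gram has {cross.shape[1]} training columns, expected {dual_coef.size}"
        )
    decision = cross @ dual_coef + intercept
    return decision, np.where(decision >= 0, 1.0, -1.0)
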