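"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use explicit loops and textbook
formulas (two-vector Pearson, naive DFT sums, set-based clustering
coefficients, all-pairs AUC) so they stay independent of the vectorized
implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hyfcnet import CohortSpec, SubjectTimeSeries, generate_cohort


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def pearson_loop(a, b) -> float:
    """Pearson correlation by the explicit covariance/deviation formula."""
    n = len(a)
    mean_a = sum(a) / n
    mean_b = sum(b) / n
    cov = sxx = syy = 0.0
    for i in range(n):
        da = a[i] - mean_a
        db = b[i] - mean_b
        cov += da * db
        sxx += da * da
        syy += db * db
    return cov / math.sqrt(sxx * syy)


def pearson_matrix_loop(m: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of the columns of ``m``, by loops."""
    r = m.shape[1]
    out = np.empty((r, r))
    for i in range(r):
        for j in range(r):
            out[i, j] = pearson_loop(m[:, i], m[:, j])
    return out


def dft_power_loop(series) -> list[float]:
    """One-sided |DFT|² by the quadratic-time direct sum."""
    k = len(series)
    out = []
    for q in range(k // 2 + 1):
        re = im = 0.0
        for t in range(k):
            ang = -2.0 * math.pi * q * t / k
            re += series[t] * math.cos(ang)
            im += series[t] * math.sin(ang)
        out.append(re * re + im * im)
    return out


def wlcc_loop(z: np.ndarray, i: int) -> float:
    """WLCC by explicit neighbourhood-set construction and cube-root sum."""
    r = z.shape[0]
    omega = [j for j in range(r) if j != i and z[i, j] > 0]
    v = len(omega)
    if v <= 1:
        return 0.0
    total = 0.0
    for j in omega:
        total += z[i, j] ** (1.0 / 3.0)
    return 2.0 * total / (v * (v - 1))


def auc_pairs_loop(y_true, scores) -> float:
    """AUC by exhaustive positive/negative pair counting, ties count ½."""
    pos = [s for s, y in zip(scores, y_true) if y == max(y_true)]
    neg = [s for s, y in zip(scores, y_true) if y != max(y_true)]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort() -> tuple[list[SubjectTimeSeries], np.ndarray]:
    """A fast strong-effect cohort for pipeline-level tests."""
    spec = CohortSpec(
        n_per_group=5,
        n_rois=10,
        n_timepoints=40,
        n_modules=2,
        modulation_amplitude=(0.0, 0.5),
        modulation_frequency_hz=(0.01, 0.01),
        seed=7,
    )
    return generate_cohort(spec)


def random_time_series(
    rng: np.random.Generator, p: int = 30, r: int = 6, subject_id: str = "rand"
) -> SubjectTimeSeries:
    return SubjectTimeSeries(
        rng.standard_normal((p, r)),
        [f"R{i}" for i in range(r)],
        subject_id=subject_id,
        tr_seconds=3.0,
    )
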