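"""Weighted local clustering coefficient (WLCC) features.

For a nonnegative symmetric weight matrix ``Z`` the WLCC of node *i* is

    f_i = 2 · Σ_{j ∈ Ω_i} Z_ij^{1/3} / (v_i (v_i − 1)),

where ``Ω_i = {j ≠ i : Z_ij > 0}`` is the neighbourhood of *i* and
``v_i = |Ω_i|``.  Nodes with fewer than two neighbours have no
"cliqueness" and score 0.  An alternative triangle-based variant
(geometric mean of the three max-normalized edge weights around each
triangle, after Onnela) is available via ``variant="onnela"``.

A subject's feature vector concatenates the per-node WLCC of every
spectral network, frequency-major:
``f = [f_1^1..f_R^1, f_1^2..f_R^2, ..., f_1^Q..f_R^Q]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AsymmetryError, InvalidWeightError, ShapeError
from .networks import ConnectivityMatrix
from .spectral import SpectralNetworkStack

__all__ = [
    "NodeFeatureVector",
    "wlcc",
    "wlcc_all",
    "feature_vector",
    "static_feature_vector",
]

_SYMMETRY_TOL = 1e-9


@dataclass
class NodeFeatureVector:
    """Length ``Q×R`` WLCC feature vector for one subject and network type."""

    values: np.ndarray
    n_rois: int
    n_bins: int
    network_type: str
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.n_rois * self.n_bins:
            raise ShapeError(
                f"feature vector length {self.values.size} != Q*R = {self.n_bins * self.n_rois}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


def _check_weights(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ShapeError(f"weight matrix must be square, got {z.shape}")
    if np.min(z) < 0:
        i, j = np.unravel_index(np.argmin(z), z.shape)
        raise InvalidWeightError(f"negative weight {z[i, j]:g} at edge ({i}, {j})")
    if np.max(np.abs(z - z.T)) > _SYMMETRY_TOL:
        raise AsymmetryError("weight matrix is asymmetric beyond tolerance")
    return z


def wlcc_all(z: np.ndarray, *, variant: str = "as_printed") -> np.ndarray:
    """WLCC of every node of a nonnegative symmetric weight matrix."""
    z = _check_weights(z)
    r = z.shape[0]
    off = z.copy()
    np.fill_diagonal(off, 0.0)
    adj = off > 0
    v = adj.sum(axis=1).astype(float)
    denom = v * (v - 1.0)
    if variant == "as_printed":
        sums = np.cbrt(off).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, 2.0 * sums / denom, 0.0)
        return f
    if variant == "onnela":
        wmax = off.max()
        if wmax == 0:
            return np.zeros(r)
        w = np.cbrt(off / wmax)
        tri = np.einsum("ij,jk,ki->i", w, w, w)  # 2 × Σ_{j<k} ŵ_ij ŵ_jk ŵ_ki
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(denom > 0, tri / denom, 0.0)
        return f
    raise ValueError(f"unknown WLCC variant {variant!r}")


def wlcc(z: np.ndarray, i: int, *, variant: str = "as_printed") -> float:
    """WLCC of node ``i`` (0-based) of weight matrix ``Z``."""
    z = np.asarray(z, dtype=float)
    if not 0 <= i < z.shape[0]:
        raise IndexError(f"node {i} out of range for R={z.shape[0]}")
    return float(wlcc_all(z, variant=variant)[i])


def feature_vector(
    stack: SpectralNetworkStack, *, variant: str = "as_printed"
) -> NodeFeatureVector:
    """Frequency-major concatenation of per-node WLCC over all spectral
    networks: element ``(q−1)·R + i`` is the WLCC of node *i* in ``Z^q``."""
    values = np.concatenate(
        [wlcc_all(stack.spectra[q], variant=variant) for q in range(stack.n_bins)]
    )
    return NodeFeatureVector(
        values,
        n_rois=stack.n_rois,
        n_bins=stack.n_bins,
        network_type=stack.network_type,
        subject_id=stack.subject_id,
    )


def static_feature_vector(
    matrix: ConnectivityMatrix,
    *,
    variant: str = "as_printed",
    edge_transform: str = "abs",
) -> NodeFeatureVector:
    """WLCC features of a static connectivity matrix (length ``R``).

    Correlation networks carry negative edges, which the WLCC cannot
    weight; ``edge_transform="abs"`` (default) uses absolute correlation,
    ``"positive"`` clips negatives to zero.
    """
    if edge_transform == "abs":
        z = np.abs(matrix.values)
    elif edge_transform == "positive":
        z = np.clip(matrix.values, 0.0, None)
    else:
        raise ValueError(f"unknown edge transform {edge_transform!r}")
    z = (z + z.T) / 2.0  # symmetrize round-off
    return NodeFeatureVector(
        wlcc_all(z, variant=variant),
        n_rois=matrix.n_rois,
        n_bins=1,
        network_type=matrix.network_type,
    )
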