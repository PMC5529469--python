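"""Construction of low-order, high-order and associated high-order
functional connectivity (FC) networks from ROI time series.

The low-order network of a window is the Pearson correlation matrix of
the windowed ROI signals, ``C = X'ᵀX'`` where ``X'`` is the window with
each column centred and scaled to unit Euclidean norm.  The high-order
network correlates pairs of low-order connectivity profiles (columns of
``C``): ``H = C'ᵀC'`` with ``C'`` the column-standardized ``C`` — a
"correlation of correlations".  The associated high-order network
correlates each low-order profile with each high-order profile,
``A = C'ᵀH'``; it is asymmetric by construction and is symmetrized as
``(A + Aᵀ)/2`` by default.

Dynamic variants slide a window of ``L`` volumes with step ``S`` over
the ``P``-volume series, yielding ``K = floor((P − L)/S) + 1`` windows;
the static network is the limiting case ``L = P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import (
    DegenerateProfileError,
    DegenerateSignalError,
    InvalidWindowError,
    ShapeError,
)

__all__ = [
    "SubjectTimeSeries",
    "WindowSpec",
    "ConnectivityMatrix",
    "DynamicNetworkSet",
    "NETWORK_TYPES",
    "STATIC",
    "segment_sliding_windows",
    "standardize_columns",
    "low_order_network",
    "high_order_network",
    "associated_high_order_network",
    "build_dynamic_networks",
    "build_static_networks",
]

NETWORK_TYPES = ("low", "high", "associated")

#: Sentinel window index marking a static (whole-series) network.
STATIC = "static"

# Euclidean norm below which a centred column counts as constant.
_DEGENERATE_NORM = 1e-12


@dataclass
class SubjectTimeSeries:
    """One subject's ROI-averaged time series.

    Parameters
    ----------
    data:
        ``(P, R)`` array, rows are time points, columns are ROIs.
    roi_labels:
        ``R`` unique region names.
    subject_id:
        Identifier used in filenames and reports.
    tr_seconds:
        Repetition time (sampling interval of the rows) in seconds.
    """

    data: np.ndarray
    roi_labels: Sequence[str]
    subject_id: str = "subject"
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = list(self.roi_labels)
        if self.data.ndim != 2:
            raise ShapeError(
                f"time series must be 2-D (time x ROI), got shape {self.data.shape}"
            )
        p, r = self.data.shape
        if p < 2 or r < 2:
            raise ShapeError(f"need P >= 2 and R >= 2, got P={p}, R={r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")
        if len(self.roi_labels) != r:
            raise ShapeError(
                f"subject {self.subject_id!r}: {len(self.roi_labels)} ROI labels for {r} columns"
            )
        if len(set(self.roi_labels)) != r:
            raise ValueError(f"subject {self.subject_id!r}: ROI labels are not unique")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length ``L`` and step ``S`` in volumes."""

    length: int
    step: int = 1

    def __post_init__(self) -> None:
        if self.length < 2:
            raise InvalidWindowError(f"window length must be >= 2, got L={self.length}")
        if self.step < 1:
            raise InvalidWindowError(f"window step must be >= 1, got S={self.step}")

    def n_windows(self, n_timepoints: int) -> int:
        """Number of windows ``K = floor((P − L)/S) + 1`` for a P-point series."""
        if self.length > n_timepoints:
            raise InvalidWindowError(
                f"window length L={self.length} exceeds series length P={n_timepoints}"
            )
        return (n_timepoints - self.length) // self.step + 1

    def duration_seconds(self, tr_seconds: float) -> float:
        """Temporal extent of one window, ``L × TR``, in seconds."""
        return self.length * tr_seconds


@dataclass
class ConnectivityMatrix:
    """A single ``R×R`` FC network of one type for one window."""

    values: np.ndarray
    network_type: str
    window_index: Union[int, str] = STATIC

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError(f"connectivity matrix must be square, got {self.values.shape}")
        if self.network_type not in NETWORK_TYPES:
            raise ValueError(f"unknown network type {self.network_type!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix contains non-finite entries")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class DynamicNetworkSet:
    """Ordered windows ``1..K`` of connectivity matrices of one type."""

    matrices: list[ConnectivityMatrix]
    window_spec: WindowSpec
    subject_id: str = "subject"
    tr_seconds: float = 3.0
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ShapeError("DynamicNetworkSet needs at least one matrix")
        types = {m.network_type for m in self.matrices}
        if len(types) != 1:
            raise ValueError(f"mixed network types in one set: {sorted(types)}")
        sizes = {m.n_rois for m in self.matrices}
        if len(sizes) != 1:
            raise ShapeError(f"mixed ROI counts in one set: {sorted(sizes)}")

    @property
    def network_type(self) -> str:
        return self.matrices[0].network_type

    @property
    def n_windows(self) -> int:
        return len(self.matrices)

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois

    @property
    def sampling_interval_seconds(self) -> float:
        """Time between consecutive windows: ``S × TR``."""
        return self.window_spec.step * self.tr_seconds

    def as_array(self) -> np.ndarray:
        """Stack windows into a ``(K, R, R)`` array."""
        return np.stack([m.values for m in self.matrices])


def segment_sliding_windows(
    ts: SubjectTimeSeries, spec: WindowSpec
) -> list[np.ndarray]:
    """Cut a ``(P, R)`` series into ``K`` overlapping ``(L, R)`` sub-series.

    Window ``k`` (0-based) covers rows ``k·S .. k·S + L − 1``.
    """
    k = spec.n_windows(ts.n_timepoints)  # validates L <= P
    return [
        ts.data[start : start + spec.length].copy()
        for start in range(0, k * spec.step, spec.step)
    ]


def standardize_columns(
    matrix: np.ndarray,
    *,
    labels: Sequence[str] | None = None,
    context: str = "",
) -> np.ndarray:
    """Centre each column and scale it to unit Euclidean norm.

    After this transform ``MᵀM`` is exactly the matrix of pairwise Pearson
    correlations of the original columns.  A constant column has no
    direction and raises :class:`DegenerateSignalError`.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ShapeError(f"expected a 2-D matrix, got shape {matrix.shape}")
    centred = matrix - matrix.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centred, axis=0)
    bad = np.flatnonzero(norms <= _DEGENERATE_NORM)
    if bad.size:
        names = (
            ", ".join(str(labels[i]) for i in bad[:5])
            if labels is not None
            else ", ".join(str(i) for i in bad[:5])
        )
        where = f" ({context})" if context else ""
        raise DegenerateSignalError(
            f"constant column(s) with zero variance{where}: {names}"
        )
    return centred / norms


def _correlation_product(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """``leftᵀ·right`` for two column-standardized matrices, clipped to
    the exact Pearson range [−1, 1] against round-off."""
    return np.clip(left.T @ right, -1.0, 1.0)


def low_order_network(
    sub_series: np.ndarray,
    *,
    window_index: Union[int, str] = STATIC,
    roi_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Pearson correlation network ``C = X'ᵀX'`` of a windowed series."""
    ctx = f"window {window_index}" if window_index != STATIC else "static window"
    x = standardize_columns(np.asarray(sub_series, dtype=float), labels=roi_labels, context=ctx)
    c = _correlation_product(x, x)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(c, "low", window_index)


def high_order_network(c: ConnectivityMatrix) -> ConnectivityMatrix:
    """Correlation of low-order connectivity profiles, ``H = C'ᵀC'``.

    Entry ``H[i, j]`` is the Pearson correlation between columns ``i`` and
    ``j`` of ``C`` (full columns, including the unit self-correlation).
    """
    if c.network_type != "low":
        raise ValueError(f"high-order network requires a low-order input, got {c.network_type!r}")
    try:
        cs = standardize_columns(c.values, context=f"low-order profiles, window {c.window_index}")
    except DegenerateSignalError as err:
        raise DegenerateProfileError(str(err)) from err
    h = _correlation_product(cs, cs)
    h = (h + h.T) / 2.0
    np.fill_diagonal(h, 1.0)
    return ConnectivityMatrix(h, "high", c.window_index)


def associated_high_order_network(
    c: ConnectivityMatrix,
    h: ConnectivityMatrix,
    *,
    symmetrize: bool = True,
) -> ConnectivityMatrix:
    """Inter-level network ``A = C'ᵀH'`` of low- vs high-order profiles.

    ``A[i, j]`` is the Pearson correlation between the *i*-th low-order
    profile (column of ``C``) and the *j*-th high-order profile (column of
    ``H``).  The raw product is generally asymmetric; with
    ``symmetrize=True`` (default) ``(A + Aᵀ)/2`` is returned.
    """
    if c.n_rois != h.n_rois:
        raise ShapeError(f"C has R={c.n_rois} but H has R={h.n_rois}")
    if c.network_type != "low" or h.network_type != "high":
        raise ValueError(
            f"expected (low, high) inputs, got ({c.network_type!r}, {h.network_type!r})"
        )
    try:
        cs = standardize_columns(c.values, context=f"low-order profiles, window {c.window_index}")
        hs = standardize_columns(h.values, context=f"high-order profiles, window {h.window_index}")
    except DegenerateSignalError as err:
        raise DegenerateProfileError(str(err)) from err
    a = _correlation_product(cs, hs)
    if symmetrize:
        a = (a + a.T) / 2.0
    return ConnectivityMatrix(a, "associated", c.window_index)


def _networks_for_window(
    sub_series: np.ndarray,
    types: frozenset[str],
    window_index: Union[int, str],
    roi_labels: Sequence[str] | None,
    symmetrize: bool,
) -> dict[str, ConnectivityMatrix]:
    """Compute the requested network types for one window, respecting the
    low → high → associated dependency chain."""
    out: dict[str, ConnectivityMatrix] = {}
    c = low_order_network(sub_series, window_index=window_index, roi_labels=roi_labels)
    if "low" in types:
        out["low"] = c
    if types & {"high", "associated"}:
        h = high_order_network(c)
        if "high" in types:
            out["high"] = h
        if "associated" in types:
            out["associated"] = associated_high_order_network(c, h, symmetrize=symmetrize)
    return out


def build_dynamic_networks(
    ts: SubjectTimeSeries,
    spec: WindowSpec,
    types: Iterable[str] = NETWORK_TYPES,
    *,
    symmetrize: bool = True,
) -> dict[str, DynamicNetworkSet]:
    """Sliding-window network sets of the requested types for one subject.

    Requesting ``associated`` implicitly computes the low- and high-order
    networks of each window (only the requested types are returned).
    Window indices are 1-based, matching ``k = 1..K`` reporting.
    """
    wanted = frozenset(types)
    unknown = wanted - set(NETWORK_TYPES)
    if unknown:
        raise ValueError(f"unknown network type(s): {sorted(unknown)}")
    if not wanted:
        raise ValueError("no network types requested")
    windows = segment_sliding_windows(ts, spec)
    per_type: dict[str, list[ConnectivityMatrix]] = {t: [] for t in wanted}
    for k, sub in enumerate(windows, start=1):
        idx: Union[int, str] = STATIC if spec.length == ts.n_timepoints and len(windows) == 1 else k
        built = _networks_for_window(sub, wanted, idx, ts.roi_labels, symmetrize)
        for t in wanted:
            per_type[t].append(built[t])
    return {
        t: DynamicNetworkSet(
            per_type[t],
            window_spec=spec,
            subject_id=ts.subject_id,
            tr_seconds=ts.tr_seconds,
            roi_labels=list(ts.roi_labels),
        )
        for t in sorted(wanted)
    }


def build_static_networks(
    ts: SubjectTimeSeries,
    types: Iterable[str] = NETWORK_TYPES,
    *,
    symmetrize: bool = True,
) -> dict[str, ConnectivityMatrix]:
    """Whole-series networks: the ``L = P`` limiting case of the dynamic ones."""
    spec = WindowSpec(length=ts.n_timepoints, step=1)
    sets = build_dynamic_networks(ts, spec, types, symmetrize=symmetrize)
    return {t: s.matrices[0] for t, s in sets.items()}
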