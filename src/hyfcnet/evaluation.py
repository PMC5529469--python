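"""Classification metrics and group-separability maps.

Metrics follow the usual confusion-count identities — SEN = TP/(TP+FN),
SPE = TN/(TN+FP), ACC = (TP+TN)/N — with AUC computed from decision
values by the rank (Mann–Whitney) statistic, ties counting one half.

Separability between two groups of a continuous quantity is the squared
point-biserial correlation r²: the squared Pearson correlation between
the per-subject values and the 0/1 group label (population-variance
convention, so the identity is exact).  Applied per edge it gives an
R×R separability map; applied per frequency bin of one edge's dynamic
FC spectrum it gives a separability curve over frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import (
    DegenerateLabelsError,
    MissingScoresError,
    ShapeError,
    UndefinedSeparabilityError,
)
from .networks import SubjectTimeSeries, WindowSpec, build_dynamic_networks
from .spectral import edge_series, power_spectrum

__all__ = [
    "MetricReport",
    "SeparabilityMap",
    "eq1_metrics",
    "rank_auc",
    "pointwise_r2",
    "edge_separability",
    "spectrum_separability",
]


@dataclass
class MetricReport:
    """Confusion counts and the derived ACC/AUC/SEN/SPE."""

    tp: int
    fn: int
    tn: int
    fp: int
    auc: float | None = None

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "acc": self.acc,
            "auc": self.auc,
            "sen": self.sen,
            "spe": self.spe,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


@dataclass
class SeparabilityMap:
    """Symmetric R×R map of per-edge r² values (NaN where undefined)."""

    r2: np.ndarray
    roi_labels: list[str] | None = None


def _binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateLabelsError(f"need exactly two classes, got {classes.tolist()}")
    return (y == classes.max()).astype(float)


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUC: probability a random positive outscores a random
    negative, with score ties contributing ½."""
    pos = _binary(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != pos.size:
        raise ShapeError("scores and labels differ in length")
    ranks = rankdata(scores)  # average ranks on ties
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def eq1_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    decision_values: np.ndarray | None = None,
    *,
    want_auc: bool = True,
) -> MetricReport:
    """Confusion-count metrics; the larger label value is positive."""
    y = np.asarray(y_true).ravel()
    p = np.asarray(y_pred).ravel()
    if y.size != p.size:
        raise ShapeError("true and predicted labels differ in length")
    pos_val = np.unique(y).max()
    truth = y == pos_val
    call = p == pos_val
    tp = int(np.sum(truth & call))
    fn = int(np.sum(truth & ~call))
    tn = int(np.sum(~truth & ~call))
    fp = int(np.sum(~truth & call))
    auc = None
    if want_auc:
        if decision_values is None:
            raise MissingScoresError("AUC requested but no decision values supplied")
        auc = rank_auc(y, decision_values)
    return MetricReport(tp=tp, fn=fn, tn=tn, fp=fp, auc=auc)


def pointwise_r2(values: np.ndarray, labels: np.ndarray) -> float:
    """Squared point-biserial correlation of values against group labels.

    Equals the squared Pearson correlation with the 0/1 label
    (population standard deviations), so it lies in [0, 1].
    """
    x = np.asarray(values, dtype=float).ravel()
    y = _binary(labels)
    if x.size != y.size:
        raise ShapeError("values and labels differ in length")
    sd = x.std()
    if sd <= 0:
        raise UndefinedSeparabilityError("values have zero variance; separability undefined")
    n = x.size
    n1 = y.sum()
    n0 = n - n1
    r = (x[y == 1].mean() - x[y == 0].mean()) / sd * np.sqrt(n1 * n0 / n**2)
    return float(r * r)


def edge_separability(
    matrices: Sequence[np.ndarray] | np.ndarray,
    labels: np.ndarray,
    *,
    roi_labels: list[str] | None = None,
) -> SeparabilityMap:
    """Per-edge r² map over a cohort of same-size connectivity matrices.

    Edges whose value is constant across subjects have undefined
    separability and are reported as NaN rather than zero.
    """
    arr = np.stack([np.asarray(m, dtype=float) for m in matrices])  # (N, R, R)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ShapeError(f"expected a stack of square matrices, got {arr.shape}")
    y = _binary(labels)
    if arr.shape[0] != y.size:
        raise ShapeError("subject count does not match labels")
    n = y.size
    n1 = y.sum()
    n0 = n - n1
    mean1 = arr[y == 1].mean(axis=0)
    mean0 = arr[y == 0].mean(axis=0)
    sd = arr.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mean1 - mean0) / sd * np.sqrt(n1 * n0 / n**2)
        r2 = np.where(sd > 0, r * r, np.nan)
    r2 = (r2 + r2.T) / 2.0  # exact for symmetric inputs; averages round-off otherwise
    return SeparabilityMap(r2, roi_labels=roi_labels)


def spectrum_separability(
    cohort: Sequence[SubjectTimeSeries],
    edge: tuple[int, int],
    labels: np.ndarray,
    window_lengths: Sequence[int],
    *,
    step: int = 1,
    network_type: str = "low",
    demean: bool = False,
    kind: str = "power",
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-frequency r² curves for one edge at several window lengths.

    For each window length L, rebuilds each subject's dynamic networks,
    takes the edge's power spectrum, and correlates each frequency bin
    with the group label.  Returns ``{L: (frequencies_hz, r2_curve)}``.
    """
    i, j = edge
    y = _binary(labels)
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for length in window_lengths:
        spec = WindowSpec(length=int(length), step=step)
        spectra = []
        for ts in cohort:
            dns = build_dynamic_networks(ts, spec, types={network_type})[network_type]
            spectra.append(power_spectrum(edge_series(dns, i, j), demean=demean, kind=kind))
        arr = np.stack(spectra)  # (N, Q)
        k = spec.n_windows(cohort[0].n_timepoints)
        dt = step * cohort[0].tr_seconds
        freqs = np.arange(arr.shape[1]) / (k * dt)
        curve = np.array(
            [
                pointwise_r2(arr[:, q], y) if arr[:, q].std() > 0 else np.nan
                for q in range(arr.shape[1])
            ]
        )
        out[int(length)] = (freqs, curve)
    return out
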