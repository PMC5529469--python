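"""Frequency-power spectral networks of dynamic FC edge series.

The value of one edge ``(i, j)`` across the ``K`` sliding windows forms a
length-``K`` series ``g_ij`` describing how that connection fluctuates
over time.  Because window ``k`` has no temporal correspondence across
subjects, the series is moved to the frequency domain: the squared
magnitude of its DFT over the one-sided bins ``q = 0..floor(K/2)`` gives
``Q = floor(K/2) + 1`` power values per edge, and collecting bin ``q``
over all edges yields a time-invariant spectral network ``Z^q``.

The windowed series is sampled every ``S × TR`` seconds, so bin ``q``
sits at frequency ``q / (K · S · TR)`` Hz and the axis tops out at the
Nyquist frequency ``1 / (2 · S · TR)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, StaticInputError
from .networks import DynamicNetworkSet

__all__ = [
    "EdgeDynamicsSeries",
    "SpectralNetworkStack",
    "edge_series",
    "power_spectrum",
    "spectral_stack",
    "n_frequency_bins",
]


def n_frequency_bins(n_windows: int) -> int:
    """One-sided DFT bin count ``Q = floor(K/2) + 1`` (DC bin included)."""
    return n_windows // 2 + 1


def wavelength_seconds(frequency_hz: float) -> float:
    """Period of an oscillation at the given frequency.

    The slowest component passed by a high-pass filter at ``f`` Hz has
    period ``1/f`` — the usual lower bound argued for the sliding-window
    length, so that every retained BOLD wavelength fits in one window.
    """
    if frequency_hz <= 0:
        raise ValueError(f"frequency must be positive, got {frequency_hz}")
    return 1.0 / frequency_hz


@dataclass
class EdgeDynamicsSeries:
    """Dynamic FC series of one edge: ``g_ij = [C_ij^1, ..., C_ij^K]``."""

    values: np.ndarray
    edge: tuple[int, int]
    sampling_interval_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n_windows(self) -> int:
        return self.values.size


@dataclass
class SpectralNetworkStack:
    """``Q`` frequency-power networks ``Z^1..Z^Q`` for one subject/type."""

    spectra: np.ndarray  # (Q, R, R), nonnegative
    frequencies_hz: np.ndarray  # (Q,)
    network_type: str
    subject_id: str = "subject"
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        if self.spectra.ndim != 3 or self.spectra.shape[1] != self.spectra.shape[2]:
            raise ShapeError(f"spectra must be (Q, R, R), got {self.spectra.shape}")
        if self.frequencies_hz.shape != (self.spectra.shape[0],):
            raise ShapeError("frequency axis length must equal the number of spectra")

    @property
    def n_bins(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_rois(self) -> int:
        return self.spectra.shape[1]


def edge_series(dns: DynamicNetworkSet, i: int, j: int) -> EdgeDynamicsSeries:
    """Extract the length-``K`` dynamic series of edge ``(i, j)``
    (0-based ROI indices)."""
    r = dns.n_rois
    if not (0 <= i < r and 0 <= j < r):
        raise IndexError(f"edge ({i}, {j}) out of range for R={r} ROIs")
    values = np.array([m.values[i, j] for m in dns.matrices])
    return EdgeDynamicsSeries(values, (i, j), dns.sampling_interval_seconds)


def power_spectrum(
    series: EdgeDynamicsSeries | np.ndarray,
    *,
    demean: bool = False,
    kind: str = "power",
) -> np.ndarray:
    """One-sided DFT spectrum of a dynamic FC series.

    ``kind="power"`` (default) returns ``|DFT|²`` per bin, ``"amplitude"``
    returns ``|DFT|``.  No taper or normalization is applied; with
    ``demean=True`` the series mean is removed first, which zeroes the DC
    bin.
    """
    values = series.values if isinstance(series, EdgeDynamicsSeries) else np.asarray(series, float)
    if values.ndim != 1:
        raise ShapeError(f"series must be 1-D, got shape {values.shape}")
    if values.size < 2:
        raise StaticInputError(f"need at least 2 windows for a spectrum, got K={values.size}")
    if kind not in ("power", "amplitude"):
        raise ValueError(f"kind must be 'power' or 'amplitude', got {kind!r}")
    if demean:
        values = values - values.mean()
    mag = np.abs(np.fft.rfft(values))
    return mag**2 if kind == "power" else mag


def spectral_stack(
    dns: DynamicNetworkSet,
    *,
    demean: bool = False,
    kind: str = "power",
) -> SpectralNetworkStack:
    """Build the ``Q`` spectral networks of a dynamic network set.

    ``Z^q[i, j]`` is the power of edge ``(i, j)``'s dynamic series in bin
    ``q``; a static set (K = 1) has no dynamics and is rejected.
    """
    k = dns.n_windows
    if k < 2:
        raise StaticInputError(
            "spectral networks are undefined for a static network set (K = 1)"
        )
    arr = dns.as_array()  # (K, R, R)
    if demean:
        arr = arr - arr.mean(axis=0, keepdims=True)
    mag = np.abs(np.fft.rfft(arr, axis=0))
    spectra = mag**2 if kind == "power" else mag
    dt = dns.sampling_interval_seconds
    freqs = np.arange(n_frequency_bins(k)) / (k * dt)
    return SpectralNetworkStack(
        spectra,
        freqs,
        network_type=dns.network_type,
        subject_id=dns.subject_id,
        roi_labels=list(dns.roi_labels) if dns.roi_labels else None,
    )
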