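"""Synthetic two-group ROI time-series cohorts with planted dynamic
connectivity differences.

Each subject is drawn from a modular latent-factor model: the ``R``
ROIs are split into ``n_modules`` contiguous modules, each driven by
its own standard-normal latent factor.  At time ``t`` an ROI in module
``m`` observes

    x_i(t) = sqrt(c(t)) · u_m(t) + sqrt(1 − c(t)) · ε_i(t) + σ · η_i(t),

so the instantaneous within-module correlation (before measurement
noise ``η``) equals the coupling

    c(t) = base_coupling + a_g · sin(2π f_g t + φ_subject),

where amplitude ``a_g`` and frequency ``f_g`` are group-specific and
the phase ``φ`` is uniform per subject.  Groups that share all
parameters are statistically exchangeable (the null cohort); a
between-group amplitude gap plants a purely *dynamic* FC difference —
the time-averaged coupling, the signal variance and the between-module
structure are identical across groups, so only the fluctuation of
connectivity (and its spectrum) separates them.

Default scales mirror a small rs-fMRI study: 15 subjects per group,
130 volumes at TR = 3 s, 30 ROIs in 3 modules, and a slow coupling
modulation (0.003 Hz ≈ 5.6-minute period) that survives the heavy
low-pass smoothing of a 70-volume sliding window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidConfigError
from .networks import SubjectTimeSeries

__all__ = ["CohortSpec", "generate_cohort", "generate_fixture_matrices"]


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for a two-group cohort.

    ``modulation_amplitude`` and ``modulation_frequency_hz`` are
    ``(group0, group1)`` pairs; group 0 is labelled 0 (controls) and
    group 1 is labelled 1 (patients).
    """

    n_per_group: int = 15
    n_rois: int = 30
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    n_modules: int = 3
    base_coupling: float = 0.30
    modulation_amplitude: tuple[float, float] = (0.0, 0.4)
    modulation_frequency_hz: tuple[float, float] = (0.003, 0.003)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise InvalidConfigError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if self.n_rois < 2:
            raise InvalidConfigError(f"n_rois must be >= 2, got {self.n_rois}")
        if self.n_timepoints < 2:
            raise InvalidConfigError(f"n_timepoints must be >= 2, got {self.n_timepoints}")
        if self.tr_seconds <= 0:
            raise InvalidConfigError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not 1 <= self.n_modules <= self.n_rois:
            raise InvalidConfigError(
                f"n_modules must be in [1, n_rois], got {self.n_modules}"
            )
        if not 0 < self.base_coupling < 1:
            raise InvalidConfigError(
                f"base_coupling must be in (0, 1), got {self.base_coupling}"
            )
        if min(self.modulation_amplitude) < 0:
            raise InvalidConfigError(
                f"modulation_amplitude must be >= 0, got {self.modulation_amplitude}"
            )
        if min(self.modulation_frequency_hz) < 0:
            raise InvalidConfigError(
                f"modulation_frequency_hz must be >= 0, got {self.modulation_frequency_hz}"
            )
        if self.noise_sd <= 0:
            raise InvalidConfigError(f"noise_sd must be > 0, got {self.noise_sd}")

    # --- presets ----------------------------------------------------------
    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """No planted group difference: both groups unmodulated."""
        return cls(modulation_amplitude=(0.0, 0.0), seed=seed, **overrides)

    @classmethod
    def strong_effect(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """The default amplitude gap (0 vs 0.4) — the 'strong' preset."""
        return cls(seed=seed, **overrides)

    def with_amplitude_gap(self, gap: float) -> "CohortSpec":
        """Same cohort with group 1's modulation amplitude set to ``gap``."""
        return replace(self, modulation_amplitude=(self.modulation_amplitude[0], gap))


def _module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal module membership for each ROI."""
    return np.repeat(np.arange(n_modules), -(-n_rois // n_modules))[:n_rois]


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectTimeSeries], np.ndarray]:
    """Draw a balanced two-group cohort; deterministic given the spec.

    Returns the subjects (group 0 first) and their 0/1 labels.
    """
    rng = np.random.default_rng(spec.seed)
    modules = _module_assignment(spec.n_rois, spec.n_modules)
    t = np.arange(spec.n_timepoints) * spec.tr_seconds
    roi_labels = [f"ROI{i + 1:03d}" for i in range(spec.n_rois)]
    subjects: list[SubjectTimeSeries] = []
    labels = []
    for group in (0, 1):
        amp = spec.modulation_amplitude[group]
        freq = spec.modulation_frequency_hz[group]
        for s in range(spec.n_per_group):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            coupling = np.clip(
                spec.base_coupling + amp * np.sin(2.0 * np.pi * freq * t + phase),
                0.0,
                0.99,
            )
            factors = rng.standard_normal((spec.n_timepoints, spec.n_modules))
            idio = rng.standard_normal((spec.n_timepoints, spec.n_rois))
            noise = rng.standard_normal((spec.n_timepoints, spec.n_rois))
            sq = np.sqrt(coupling)[:, None]
            sq1 = np.sqrt(1.0 - coupling)[:, None]
            data = sq * factors[:, modules] + sq1 * idio + spec.noise_sd * noise
            if np.any(data.std(axis=0) == 0):  # essentially impossible for noise_sd > 0
                raise RuntimeError("generated a constant ROI column; reseed")
            subjects.append(
                SubjectTimeSeries(
                    data,
                    roi_labels,
                    subject_id=f"sub-g{group}-{s:03d}",
                    tr_seconds=spec.tr_seconds,
                )
            )
            labels.append(group)
    return subjects, np.array(labels, dtype=int)


def generate_fixture_matrices(seed: int = 0) -> dict[str, np.ndarray]:
    """Small, byte-stable matrices for hand-checkable unit tests.

    - ``windowing``: a 10×3 ramp matrix for the P=10, L=4, S=3 window case.
    - ``ordering_stack``: a (2, 3, 3) spectral stack for the Q=2, R=3
      feature-ordering case.
    - ``random_series``: a reproducible 30×6 Gaussian series for
      correlation oracles.
    """
    base = np.arange(30, dtype=float).reshape(10, 3)
    windowing = base + np.array([0.0, 100.0, 200.0])
    ordering_stack = np.zeros((2, 3, 3))
    ordering_stack[0] = [[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]]
    ordering_stack[1] = [[0.0, 0.5, 0.0], [0.5, 0.0, 0.25], [0.0, 0.25, 0.0]]
    rng = np.random.default_rng(seed)
    random_series = rng.standard_normal((30, 6))
    return {
        "windowing": windowing,
        "ordering_stack": ordering_stack,
        "random_series": random_series,
    }
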