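"""End-to-end pipeline: time series → networks → spectra → WLCC
features → PCA+LASSO+multi-kernel SVM under nested LOOCV."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import __version__
from .classification import CVResult, nested_loocv
from .config import RunConfig
from .graph_features import feature_vector, static_feature_vector
from .networks import (
    SubjectTimeSeries,
    WindowSpec,
    build_dynamic_networks,
    build_static_networks,
)
from .spectral import spectral_stack

__all__ = ["subject_features", "cohort_feature_matrices", "run_pipeline"]


def subject_features(ts: SubjectTimeSeries, config: RunConfig) -> dict[str, np.ndarray]:
    """WLCC feature vector per requested network type for one subject.

    Dynamic mode: per type, the Q spectral networks of the window-sliding
    edge series give a length Q·R vector.  Static mode: the WLCC of the
    whole-series network (absolute correlations) gives a length-R vector.
    """
    types = set(config.types)
    if config.static:
        nets = build_static_networks(ts, types, symmetrize=config.symmetrize_associated)
        return {
            t: static_feature_vector(
                nets[t],
                variant=config.wlcc_variant,
                edge_transform=config.static_edge_transform,
            ).values
            for t in sorted(types)
        }
    spec = WindowSpec(length=config.window_length, step=config.window_step)
    sets = build_dynamic_networks(ts, spec, types, symmetrize=config.symmetrize_associated)
    out = {}
    for t in sorted(types):
        stack = spectral_stack(
            sets[t], demean=config.demean_edge_series, kind=config.spectrum_kind
        )
        out[t] = feature_vector(stack, variant=config.wlcc_variant).values
    return out


def cohort_feature_matrices(
    cohort: Sequence[SubjectTimeSeries], config: RunConfig
) -> dict[str, np.ndarray]:
    """Stack per-subject feature vectors into ``N × D`` matrices per type."""
    rows = [subject_features(ts, config) for ts in cohort]
    return {t: np.stack([r[t] for r in rows]) for t in sorted(set(config.types))}


def run_pipeline(
    cohort: Sequence[SubjectTimeSeries],
    labels: np.ndarray,
    config: RunConfig | None = None,
) -> tuple[dict, CVResult]:
    """Run the full pipeline on a cohort and return (report, CV result).

    The report is JSON-serializable: resolved config, package version,
    aggregate metrics and the per-fold hyperparameter audit trail.
    """
    config = config or RunConfig()
    features = cohort_feature_matrices(cohort, config)
    result = nested_loocv(features, labels, config.classifier())
    report = {
        "package": {"name": "hyfcnet", "version": __version__},
        "config": config.to_dict(),
        "n_subjects": int(len(cohort)),
        "n_features_per_type": {t: int(m.shape[1]) for t, m in features.items()},
        "metrics": result.metrics.as_dict(),
        "folds": [
            {
                "test_index": f.test_index,
                "test_subject": cohort[f.test_index].subject_id,
                "lambdas": f.lambdas,
                "weights": list(f.weights),
                "inner_accuracy": f.inner_accuracy,
                "n_selected": f.n_selected,
            }
            for f in result.folds
        ],
        "predictions": [
            {
                "subject_id": cohort[i].subject_id,
                "true_label": int(result.y_true[i]),
                "predicted_label": int(result.y_pred[i]),
                "decision_value": float(result.decision_values[i]),
            }
            for i in range(len(cohort))
        ],
    }
    return report, result
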