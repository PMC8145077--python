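"""Dementia prevalence estimation from consensus diagnoses and model
predictions.

The cohort splits into a consensus-diagnosed subsample and a remainder
classified by the model; the unweighted prevalence pools the two positive
counts over the full sample, and the survey-weighted estimate is the
weight-share of positive cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PrevalenceEstimate:
    n_total: int
    n_diagnosed_pos: int
    n_predicted_pos: int
    unweighted_pct: float
    weighted_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_diagnosed_pos": self.n_diagnosed_pos,
            "n_predicted_pos": self.n_predicted_pos,
            "unweighted_pct": self.unweighted_pct,
            "weighted_pct": self.weighted_pct,
        }


def unweighted_prevalence(n_diag_pos: int, n_pred_pos: int, n_total: int) -> float:
    """Pooled unweighted prevalence, as a percentage of the full sample."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_diag_pos < 0 or n_pred_pos < 0:
        raise ValueError("counts must be nonnegative")
    if n_diag_pos + n_pred_pos > n_total:
        raise ValueError("positive counts exceed n_total")
    return 100.0 * (n_diag_pos + n_pred_pos) / n_total


def weighted_prevalence(labels, weights) -> float:
    """Survey-weighted prevalence: 100 * sum(w*y) / sum(w)."""
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise ValueError("labels and weights must be aligned")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float(100.0 * (w * y).sum() / w.sum())


def estimate_prevalence(diagnosed_labels, predicted_labels,
                        weights=None) -> PrevalenceEstimate:
    """Combine consensus-diagnosed and model-classified subsamples.

    ``diagnosed_labels`` are consensus dementia calls for the diagnosed
    subsample; ``predicted_labels`` the model's calls for the remainder.
    When per-person weights are given (concatenated in the same order:
    diagnosed then predicted), a weighted estimate is added.
    """
    diag = np.asarray(diagnosed_labels, dtype=int)
    pred = np.asarray(predicted_labels, dtype=int)
    n_total = diag.size + pred.size
    est_w = None
    if weights is not None:
        est_w = weighted_prevalence(np.concatenate([diag, pred]), weights)
    return PrevalenceEstimate(
        n_total=n_total,
        n_diagnosed_pos=int(diag.sum()),
        n_predicted_pos=int(pred.sum()),
        unweighted_pct=unweighted_prevalence(int(diag.sum()), int(pred.sum()), n_total),
        weighted_pct=est_w,
    )
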