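"""Cohort preparation: diagnosis labels, train/test split, clinical group
flags and class-imbalance weights.

The dementia label follows the consensus-diagnosis rule: positive iff the
global Clinical Dementia Rating is at least 1 (so CDR 0.5, "very mild", is a
negative). The four group-membership flags used by the voting ensemble are
depression score in the training top quartile, anxiety score in the training
top quartile, and self-reported vision / hearing impairment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

DEMENTIA_CDR_THRESHOLD = 1.0

FLAG_COLUMNS = ["dep_top_quartile", "anx_top_quartile", "vision_impaired",
                "hearing_impaired"]


class StructuralError(ValueError):
    pass


def label_dementia(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to rows with a consensus global CDR and attach the binary
    dementia label (1 iff global_cdr >= 1)."""
    if "global_cdr" not in records.columns:
        raise StructuralError("records need a 'global_cdr' column")
    labeled = records[records["global_cdr"].notna()].copy()
    labeled["dementia"] = (
        labeled["global_cdr"] >= DEMENTIA_CDR_THRESHOLD
    ).astype(int)
    return labeled


@dataclass(frozen=True)
class SplitResult:
    train_ids: np.ndarray
    test_ids: np.ndarray
    seed: int


def split_70_30(cohort: pd.DataFrame, seed: int, train_frac: float = 0.7) -> SplitResult:
    """Simple random 70/30 split by id; |train| = round-half-up(0.7 n)."""
    n = len(cohort)
    if n < 2:
        raise ValueError(f"need at least 2 rows to split, got {n}")
    n_train = int(np.floor(train_frac * n + 0.5))
    rng = np.random.default_rng(seed)
    ids = cohort["id"].to_numpy()
    perm = rng.permutation(n)
    return SplitResult(
        train_ids=np.sort(ids[perm[:n_train]]),
        test_ids=np.sort(ids[perm[n_train:]]),
        seed=seed,
    )


def fit_quartile_thresholds(train: pd.DataFrame) -> dict[str, float]:
    """Training-set 75th percentiles (linear-interpolation quantile) of the
    depression and anxiety scores; frozen for reuse on test data."""
    if len(train) == 0:
        raise ValueError("cannot fit quartile thresholds on an empty set")
    return {
        "depression_q3": float(np.quantile(train["cesd"].to_numpy(float), 0.75)),
        "anxiety_q3": float(np.quantile(train["anxiety"].to_numpy(float), 0.75)),
    }


def compute_group_flags(records: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Four boolean group memberships per row.

    Top-quartile flags are strict (score > training Q3, so scores tied with
    the threshold are non-members); sensory flags copy the self-reported
    diagnosis columns.
    """
    needed = ["cesd", "anxiety", "dx_vision", "dx_hearing"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise StructuralError(f"records missing columns: {missing}")
    return pd.DataFrame(
        {
            "dep_top_quartile": records["cesd"].to_numpy(float) > thresholds["depression_q3"],
            "anx_top_quartile": records["anxiety"].to_numpy(float) > thresholds["anxiety_q3"],
            "vision_impaired": records["dx_vision"].to_numpy() > 0,
            "hearing_impaired": records["dx_hearing"].to_numpy() > 0,
        },
        index=records.index,
    )


class TopQuartileFlagger(BaseEstimator, TransformerMixin):
    """Transformer producing the four ensemble group flags.

    Fits the depression/anxiety 75th percentiles on the training frame and
    applies them (strictly-greater rule) to any frame with ``cesd``,
    ``anxiety``, ``dx_vision`` and ``dx_hearing`` columns.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.thresholds_ = fit_quartile_thresholds(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "thresholds_")
        return compute_group_flags(X, self.thresholds_)


def compute_class_weights(labels) -> np.ndarray:
    """Per-observation weights inversely proportional to class size.

    Normalized so the weights sum to n with equal total mass (n/2) on each
    class: positives get n/(2 n_pos), negatives n/(2 n_neg).
    """
    y = np.asarray(labels)
    n = y.size
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    return w
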