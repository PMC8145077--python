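"""Step 2 of the two-step procedure: the group-conditional majority-vote
classifier.

Each individual belongs (or not) to four clinically motivated strata —
depression score in the training top quartile, anxiety score in the top
quartile, vision impairment, hearing impairment — conditions that can mimic
dementia on cognitive tests and daily-function reports. For every
(dimension, membership) cell an F1-maximizing risk-score cutoff is fitted
on the training rows in that cell; an individual then receives four weak
binary classifications by comparing their risk score to the cutoff of their
own cell on each dimension, and is called positive when at least three of
the four weak votes are positive.

Cutoff search convention: candidates are the unique observed scores, the
prediction rule is positive iff score >= cutoff, F1 with zero true
positives counts as 0 (keeping the argmax total), and equal-F1 ties break
toward the smallest cutoff (maximizing sensitivity at no F1 cost). A cell
whose training subset has no positive cases falls back to the cutoff fitted
on the full training set; the +inf sentinel (no positives anywhere) yields
an always-negative vote.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .prep import FLAG_COLUMNS, TopQuartileFlagger
from .risk import CVSpec, DementiaRiskScorer

DIMENSIONS = ["depression", "anxiety", "vision", "hearing"]

#: dimension -> group-flag column
DIMENSION_FLAGS = dict(zip(DIMENSIONS, FLAG_COLUMNS))


def f1_at_cutoff(scores, labels, cutoff) -> float:
    """F1 of the rule (score >= cutoff), with F1 := 0 when tp = 0."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= cutoff
    tp = int((pred & (y == 1)).sum())
    if tp == 0:
        return 0.0
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    return 2.0 * tp / (2.0 * tp + fp + fn)


def select_f1_cutoff(scores, labels) -> float:
    """F1-optimal cutoff over the unique observed scores.

    Returns +inf when the labels contain no positive case (always-negative
    sentinel). Ties in F1 break toward the smallest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    n_pos = int(y.sum())
    if n_pos == 0:
        return math.inf

    order = np.argsort(-s, kind="stable")
    s_desc, y_desc = s[order], y[order]
    cum_tp = np.cumsum(y_desc)
    # last occurrence of each distinct value in descending order gives the
    # confusion counts of the rule (score >= value)
    is_last = np.r_[s_desc[1:] != s_desc[:-1], True]
    idx = np.flatnonzero(is_last)
    tp = cum_tp[idx]
    pred_pos = idx + 1.0
    f1 = np.where(tp > 0, 2.0 * tp / (pred_pos + n_pos), 0.0)
    # candidates are descending here; argmax of reversed array -> smallest
    # cutoff among F1 ties
    best_rev = int(np.argmax(f1[::-1]))
    return float(s_desc[idx[::-1][best_rev]])


@dataclass
class CutoffTable:
    """Eight fitted cutoffs: one per (dimension, membership) cell.

    ``provenance`` records per cell the training subset size, its positive
    count, and whether the global fallback fired (empty cell or a cell with
    no positives).
    """

    cutoffs: dict = field(default_factory=dict)   # (dim, is_member) -> float
    provenance: dict = field(default_factory=dict)
    global_fallback: float = math.inf
    min_votes: int = 3

    def cell(self, dimension: str, is_member: bool) -> float:
        return self.cutoffs[(dimension, bool(is_member))]

    def to_dict(self) -> dict:
        return {
            "cells": {
                f"{d}:{'member' if m else 'non-member'}": (
                    None if math.isinf(c) else c
                )
                for (d, m), c in self.cutoffs.items()
            },
            "provenance": {
                f"{d}:{'member' if m else 'non-member'}": p
                for (d, m), p in self.provenance.items()
            },
            "global_fallback": (
                None if math.isinf(self.global_fallback) else self.global_fallback
            ),
            "min_votes": self.min_votes,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffTable":
        cutoffs, prov = {}, {}
        for key, c in d["cells"].items():
            dim, mem = key.split(":")
            cutoffs[(dim, mem == "member")] = math.inf if c is None else float(c)
        for key, p in d.get("provenance", {}).items():
            dim, mem = key.split(":")
            prov[(dim, mem == "member")] = p
        gf = d.get("global_fallback")
        return cls(cutoffs=cutoffs, provenance=prov,
                   global_fallback=math.inf if gf is None else float(gf),
                   min_votes=int(d.get("min_votes", 3)))

    @classmethod
    def from_json(cls, path) -> "CutoffTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_cutoff_table(train_scores, labels, flags_table: pd.DataFrame,
                     min_votes: int = 3, mode: str = "per_cell") -> CutoffTable:
    """Fit the eight group-conditional cutoffs on the training set.

    ``mode="per_cell"`` (default) fits every (dimension, membership) cell on
    its own subset; ``mode="member_only"`` fits member cells per-subset and
    gives every non-member cell the full-sample cutoff.
    """
    s = np.asarray(train_scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(flags_table) != s.size:
        raise ValueError("flags_table must align with train_scores")
    if mode not in ("per_cell", "member_only"):
        raise ValueError(f"unknown mode {mode!r}")

    global_cutoff = select_f1_cutoff(s, y)
    table = CutoffTable(global_fallback=global_cutoff, min_votes=min_votes)
    for dim in DIMENSIONS:
        member = flags_table[DIMENSION_FLAGS[dim]].to_numpy(bool)
        for is_member in (True, False):
            mask = member if is_member else ~member
            n_cell, n_pos = int(mask.sum()), int(y[mask].sum())
            if mode == "member_only" and not is_member:
                cutoff, fallback = global_cutoff, False
            elif n_cell == 0 or n_pos == 0:
                cutoff, fallback = global_cutoff, True
            else:
                cutoff, fallback = select_f1_cutoff(s[mask], y[mask]), False
            table.cutoffs[(dim, is_member)] = cutoff
            table.provenance[(dim, is_member)] = {
                "n": n_cell, "n_pos": n_pos, "fallback": fallback,
            }
    return table


@dataclass(frozen=True)
class VoteResult:
    weak_votes: tuple
    final: bool


def classify(score: float, flags, table: CutoffTable) -> VoteResult:
    """Vote one individual: per dimension, compare the risk score to the
    cutoff of their own (dimension, membership) cell; final call is positive
    when at least ``table.min_votes`` weak votes are positive."""
    if isinstance(flags, pd.Series):
        flags = {d: bool(flags[DIMENSION_FLAGS[d]]) for d in DIMENSIONS}
    elif not isinstance(flags, dict):
        flags = dict(zip(DIMENSIONS, flags))
    votes = tuple(
        bool(score >= table.cell(d, flags[d])) for d in DIMENSIONS
    )
    return VoteResult(weak_votes=votes, final=sum(votes) >= table.min_votes)


def predict_cohort(scores, flags_table: pd.DataFrame, table: CutoffTable) -> pd.DataFrame:
    """Vectorized voting over a cohort; returns a vote audit table with one
    column per dimension's applicable cutoff and vote, plus ``final``."""
    s = np.asarray(scores, dtype=float)
    if len(flags_table) != s.size:
        raise ValueError("scores and flags_table must be row-aligned")
    out = {}
    n_votes = np.zeros(s.size, dtype=int)
    for dim in DIMENSIONS:
        member = flags_table[DIMENSION_FLAGS[dim]].to_numpy(bool)
        cut = np.where(member, table.cell(dim, True), table.cell(dim, False))
        vote = s >= cut
        out[f"cutoff_{dim}"] = cut
        out[f"vote_{dim}"] = vote
        n_votes += vote
    out["n_votes"] = n_votes
    out["final"] = n_votes >= table.min_votes
    return pd.DataFrame(out, index=flags_table.index)


class MajorityVoteClassifier(BaseEstimator, ClassifierMixin):
    """Group-conditional F1-cutoff majority voter over precomputed risk
    scores.

    ``X`` is a DataFrame with a ``risk_score`` column and the four group
    flag columns (``dep_top_quartile``, ``anx_top_quartile``,
    ``vision_impaired``, ``hearing_impaired``).
    """

    def __init__(self, min_votes: int = 3, mode: str = "per_cell"):
        self.min_votes = min_votes
        self.mode = mode

    @staticmethod
    def _split(X: pd.DataFrame):
        missing = [c for c in ["risk_score", *FLAG_COLUMNS] if c not in X.columns]
        if missing:
            raise ValueError(f"X missing columns: {missing}")
        return X["risk_score"].to_numpy(float), X[FLAG_COLUMNS]

    def fit(self, X: pd.DataFrame, y):
        scores, flags = self._split(X)
        self.cutoff_table_ = fit_cutoff_table(
            scores, y, flags, min_votes=self.min_votes, mode=self.mode,
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "cutoff_table_")
        scores, flags = self._split(X)
        return predict_cohort(scores, flags, self.cutoff_table_)["final"].to_numpy(int)

    def vote_audit(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "cutoff_table_")
        scores, flags = self._split(X)
        return predict_cohort(scores, flags, self.cutoff_table_)


class TwoStepDementiaClassifier(BaseEstimator, ClassifierMixin):
    """The full two-step procedure as one estimator.

    Step 1 tunes a probabilistic learner by repeated cross-validation and
    converts predicted probabilities to 0-100 risk scores; step 2 fits the
    group-conditional F1-optimal cutoffs and votes. ``X`` is a cohort
    DataFrame carrying the predictor columns plus ``cesd``, ``anxiety``,
    ``dx_vision`` and ``dx_hearing`` (used for group membership).

    Fitted attributes: ``scorer_`` (the tuned risk model), ``flagger_``
    (frozen top-quartile thresholds), ``voter_`` (the cutoff table), and
    ``single_cutoff_`` — the one-threshold F1-optimal baseline fitted on
    the same training scores, kept for step-2 ablation.
    """

    def __init__(self, learner: str = "svm_rbf", grid: dict | None = None,
                 cv_folds: int = 10, cv_repeats: int = 10, min_votes: int = 3,
                 mode: str = "per_cell", class_weighting: bool = True,
                 random_state: int = 0):
        self.learner = learner
        self.grid = grid
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.min_votes = min_votes
        self.mode = mode
        self.class_weighting = class_weighting
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        y = np.asarray(y).astype(int)
        self.scorer_ = DementiaRiskScorer(
            learner=self.learner, grid=self.grid, cv_folds=self.cv_folds,
            cv_repeats=self.cv_repeats, class_weighting=self.class_weighting,
            random_state=self.random_state,
        ).fit(X, y, sample_weight=sample_weight)
        self.flagger_ = TopQuartileFlagger().fit(X)
        # cutoffs are fitted on the cross-validated (out-of-fold) training
        # scores from step 1, not on in-sample predictions
        scores = self.scorer_.oof_scores_
        flags = self.flagger_.transform(X)
        self.voter_ = MajorityVoteClassifier(
            min_votes=self.min_votes, mode=self.mode,
        ).fit(flags.assign(risk_score=scores), y)
        self.single_cutoff_ = select_f1_cutoff(scores, y)
        self.classes_ = np.array([0, 1])
        return self

    def risk_score(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "scorer_")
        return self.scorer_.risk_score(X)

    def _voting_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.flagger_.transform(X).assign(risk_score=self.risk_score(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "voter_")
        return self.voter_.predict(self._voting_frame(X))

    def vote_audit(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "voter_")
        return self.voter_.vote_audit(self._voting_frame(X))

    def predict_single_threshold(self, X: pd.DataFrame) -> np.ndarray:
        """Step-1-only baseline: positive iff risk score >= the single
        F1-optimal training cutoff."""
        check_is_fitted(self, "single_cutoff_")
        return (self.risk_score(X) >= self.single_cutoff_).astype(int)
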