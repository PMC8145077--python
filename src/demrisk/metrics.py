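"""Evaluation metrics and the model-versus-clinician agreement comparison.

All metrics are computed from first principles off the 2x2 confusion table:
accuracy, sensitivity (recall), specificity, precision, F1, and Cohen's
kappa (chance-corrected agreement, (p_o - p_e) / (1 - p_e) with the expected
agreement p_e from the marginal products). AUROC is the Mann-Whitney rank
statistic — the probability that a random positive outscores a random
negative, ties counting one half — which equals the trapezoidal area under
the empirical ROC curve.

Ratios with empty denominators (e.g. precision with no predicted positives)
are reported as NaN and flagged in ``MetricSet.undefined`` rather than
silently zeroed; the F1 := 0 convention for zero-true-positive cutoffs lives
in the cutoff search, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    kappa: float
    auroc: float = math.nan
    undefined: frozenset = field(default_factory=frozenset)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Report-table presentation: half-up rounding to ``ndigits``."""
        out = {}
        for name in ("auroc", "accuracy", "sensitivity", "specificity",
                     "precision", "f1", "kappa"):
            v = getattr(self, name)
            out[name] = v if math.isnan(v) else round_half_up(v, ndigits)
        return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if not np.isin(arr, (0, 1, True, False)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr.astype(int)


def confusion(pred, truth) -> ConfusionCounts:
    """Standard 2x2 counts from aligned binary vectors."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
    )


def kappa_from_counts(c: ConfusionCounts) -> float:
    """Cohen's kappa; 1.0 on perfect agreement even when marginals are
    degenerate, NaN when chance agreement is 1 without perfect agreement."""
    n = c.n
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.fp + c.tn) * (c.fn + c.tn)) / (n * n)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1.0 - p_e)


def metric_set(counts: ConfusionCounts, scores=None, truth=None) -> MetricSet:
    """All threshold metrics from a confusion table; AUROC when ``scores``
    and ``truth`` are supplied."""
    n = counts.n
    if n == 0:
        raise ValueError("metric_set needs at least one observation")
    undefined = set()

    def ratio(num, den, name):
        if den == 0:
            undefined.add(name)
            return math.nan
        return num / den

    acc = (counts.tp + counts.tn) / n
    sens = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    spec = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    prec = ratio(counts.tp, counts.tp + counts.fp, "precision")
    if math.isnan(sens) or math.isnan(prec) or (sens + prec) == 0:
        undefined.add("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    kap = kappa_from_counts(counts)
    if math.isnan(kap):
        undefined.add("kappa")
    auc = math.nan
    if scores is not None and truth is not None:
        auc = auroc(scores, truth)
    else:
        undefined.add("auroc")
    return MetricSet(accuracy=acc, sensitivity=sens, specificity=spec,
                     precision=prec, f1=f1, kappa=kap, auroc=auc,
                     undefined=frozenset(undefined))


def auroc(scores, truth) -> float:
    """Rank-statistic AUROC with ties counted 0.5.

    Equals the probability that a uniformly drawn positive case receives a
    strictly higher score than a uniformly drawn negative case, plus half
    the probability of a tie.
    """
    s = np.asarray(scores, dtype=float)
    t = _as_binary(truth, "truth")
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(pred, truth, scores=None) -> MetricSet:
    """Confusion + metric_set in one call."""
    return metric_set(confusion(pred, truth),
                      scores=scores, truth=truth if scores is not None else None)


@dataclass
class RaterComparison:
    """Per-rater agreement with the consensus, summarized against the model.

    ``accuracy_p`` / ``kappa_p`` are two-sided one-sample t-test p-values of
    the rater values against the model's point value; ``degenerate`` flags
    zero cross-rater variance (p-values undefined).
    """

    per_rater: list
    rater_accuracy_mean: float
    rater_accuracy_ci: tuple[float, float]
    rater_kappa_mean: float
    rater_kappa_ci: tuple[float, float]
    model_accuracy: float
    model_kappa: float
    accuracy_p: float
    kappa_p: float
    degenerate: bool


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    k = values.size
    m = values.mean()
    if k < 2:
        return (m, m)
    half = stats.t.ppf(0.5 + level / 2.0, k - 1) * values.std(ddof=1) / math.sqrt(k)
    return (m - half, m + half)


def _t_p(values: np.ndarray, popmean: float) -> float:
    if values.std(ddof=1) == 0.0:
        return math.nan
    return float(stats.ttest_1samp(values, popmean).pvalue)


def compare_to_raters(per_rater_predictions, consensus, model_predictions) -> RaterComparison:
    """Compare individual raters' agreement with the consensus to the
    model's.

    ``per_rater_predictions`` is a (n_raters, n_cases) array of binary
    dementia calls; ``consensus`` and ``model_predictions`` are aligned
    binary vectors. Accuracy and kappa are computed per rater against the
    consensus; their mean and t-based 95% CI are reported along with
    two-sided one-sample t-tests against the model's values.
    """
    preds = np.atleast_2d(np.asarray(per_rater_predictions))
    if preds.shape[0] < 2:
        raise ValueError("need at least 2 raters")
    per_rater = [evaluate_predictions(row, consensus) for row in preds]
    acc = np.array([m.accuracy for m in per_rater])
    kap = np.array([m.kappa for m in per_rater])
    model = evaluate_predictions(model_predictions, consensus)
    degenerate = (acc.std(ddof=1) == 0.0) or (kap.std(ddof=1) == 0.0)
    return RaterComparison(
        per_rater=per_rater,
        rater_accuracy_mean=float(acc.mean()),
        rater_accuracy_ci=_t_ci(acc),
        rater_kappa_mean=float(kap.mean()),
        rater_kappa_ci=_t_ci(kap),
        model_accuracy=model.accuracy,
        model_kappa=model.kappa,
        accuracy_p=_t_p(acc, model.accuracy),
        kappa_p=_t_p(kap, model.kappa),
        degenerate=degenerate,
    )
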