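"""Instrument summary scoring from item-level responses.

Three scoring families cover the battery:

* count-correct — cognitive screens and functional-difficulty checklists
  (HMSE, TICS, CSID, judgment, numeracy, ADL, IADL, mobility): the summary
  is the number of items answered correctly / with difficulty (binary item
  codes).
* sum-coded — symptom scales (10-item CES-D depression, items 0-3; 5-item
  anxiety, items 0-3): the summary is the item-code sum.
* mean-coded — informant scales (16-item IQCODE, items 1-5; 3-item Blessed
  habits, items 1-4): the summary is the item-code mean.

The Blessed performance scale has its own rule: each of 8 items records a
loss level (none/some/severe) and, when lost, an attribution (physical /
mental / both); an item scores 0 for no loss or purely physical loss, 0.5
for some loss attributed to mental causes or both, and 1 for severe loss
attributed to mental causes or both, and the summary is the item sum
(0-8 in 0.5 steps). Severe loss attributed only to physical causes scores
0, extending the physical-exemption principle to the severe level.

A summary score is missing (NaN) whenever any item response is missing;
no prorating is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


class StructuralError(ValueError):
    """Item responses do not match the instrument's structure."""


@dataclass(frozen=True)
class InstrumentDef:
    name: str
    n_items: int
    item_min: int
    item_max: int
    family: str  # count | sum | mean


# Numeracy item count follows the printed 0-9 score range (config-driven via
# make_instrument for variants administered with fewer items).
COUNT_INSTRUMENTS = {
    "hmse": InstrumentDef("hmse", 30, 0, 1, "count"),
    "tics": InstrumentDef("tics", 3, 0, 1, "count"),
    "csid": InstrumentDef("csid", 4, 0, 1, "count"),
    "judgment": InstrumentDef("judgment", 5, 0, 1, "count"),
    "numeracy": InstrumentDef("numeracy", 9, 0, 1, "count"),
    "adl": InstrumentDef("adl", 6, 0, 1, "count"),
    "iadl": InstrumentDef("iadl", 7, 0, 1, "count"),
    "mobility": InstrumentDef("mobility", 9, 0, 1, "count"),
}

SUM_INSTRUMENTS = {
    "cesd": InstrumentDef("cesd", 10, 0, 3, "sum"),
    "anxiety": InstrumentDef("anxiety", 5, 0, 3, "sum"),
}

MEAN_INSTRUMENTS = {
    "iqcode": InstrumentDef("iqcode", 16, 1, 5, "mean"),
    "blessed_habits": InstrumentDef("blessed_habits", 3, 1, 4, "mean"),
}

INSTRUMENTS = {**COUNT_INSTRUMENTS, **SUM_INSTRUMENTS, **MEAN_INSTRUMENTS}

BLESSED_N_ITEMS = 8
LOSS_LEVELS = ("none", "some", "severe")
ATTRIBUTIONS = ("physical", "mental", "both", "n/a")


def make_instrument(name: str, n_items: int, item_min: int, item_max: int,
                    family: str) -> InstrumentDef:
    """Define an instrument variant (e.g. a shorter numeracy module)."""
    if family not in ("count", "sum", "mean"):
        raise ValueError(f"unknown scoring family {family!r}")
    return InstrumentDef(name, n_items, item_min, item_max, family)


def _check_items(values: Sequence, inst: InstrumentDef) -> np.ndarray | None:
    """Validate item codes; returns the array, or None if any item is missing."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != inst.n_items:
        raise StructuralError(
            f"{inst.name}: expected {inst.n_items} items, got {arr.size}"
        )
    if np.isnan(arr).any():
        return None
    for i, v in enumerate(arr):
        if not (inst.item_min <= v <= inst.item_max) or v != int(v):
            raise ValueError(
                f"{inst.name}: item {i} code {v!r} outside "
                f"{{{inst.item_min}..{inst.item_max}}}"
            )
    return arr


def score_count_correct(responses: Sequence, instrument: str) -> float:
    """Number of correct / endorsed items for a count-scored instrument."""
    inst = COUNT_INSTRUMENTS.get(instrument)
    if inst is None:
        raise StructuralError(f"{instrument!r} is not a count-scored instrument")
    arr = _check_items(responses, inst)
    return math.nan if arr is None else float(arr.sum())


def score_sum_coded(responses: Sequence, instrument: str) -> float:
    """Item-code sum for a symptom scale (CES-D 0-30, anxiety 0-15)."""
    inst = SUM_INSTRUMENTS.get(instrument)
    if inst is None:
        raise StructuralError(f"{instrument!r} is not a sum-scored instrument")
    arr = _check_items(responses, inst)
    return math.nan if arr is None else float(arr.sum())


def score_mean_coded(responses: Sequence, instrument: str) -> float:
    """Item-code mean for an informant scale (IQCODE 1-5, habits 1-4)."""
    inst = MEAN_INSTRUMENTS.get(instrument)
    if inst is None:
        raise StructuralError(f"{instrument!r} is not a mean-scored instrument")
    arr = _check_items(responses, inst)
    return math.nan if arr is None else float(arr.mean())


def score_blessed_item(loss: str, attribution: str | None) -> float:
    """Score one Blessed performance item by the 0 / 0.5 / 1 rule."""
    if loss not in LOSS_LEVELS:
        raise ValueError(f"unknown loss level {loss!r}")
    if loss == "none":
        return 0.0  # attribution, if recorded, is ignored
    if attribution is None or attribution == "n/a":
        raise ValueError(f"loss {loss!r} requires an attribution")
    if attribution not in ATTRIBUTIONS:
        raise ValueError(f"unknown attribution {attribution!r}")
    if attribution == "physical":
        return 0.0
    return 0.5 if loss == "some" else 1.0


def score_blessed_performance(responses: Sequence[tuple]) -> float:
    """Blessed performance summary: sum of 8 item scores, 0-8 in 0.5 steps.

    Each response is a ``(loss, attribution)`` pair; attribution may be None
    or "n/a" when there is no loss. A missing response (None) makes the
    summary missing.
    """
    responses = list(responses)
    if len(responses) != BLESSED_N_ITEMS:
        raise StructuralError(
            f"blessed_performance: expected {BLESSED_N_ITEMS} items, "
            f"got {len(responses)}"
        )
    total = 0.0
    for item in responses:
        if item is None:
            return math.nan
        loss, attribution = item
        total += score_blessed_item(loss, attribution)
    return total


def score_items_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Score an item-level table into summary scores.

    Columns follow the ``<instrument>_<k>`` naming scheme (1-based item
    index); Blessed performance items use ``blessed_performance_<k>_loss``
    and ``blessed_performance_<k>_attr``. Instruments whose columns are
    absent are skipped; an ``id`` column, when present, is carried through.
    """
    out: dict[str, list] = {}
    if "id" in items.columns:
        out["id"] = items["id"].tolist()

    for name, inst in INSTRUMENTS.items():
        cols = [f"{name}_{k}" for k in range(1, inst.n_items + 1)]
        if not all(c in items.columns for c in cols):
            continue
        scorer = {
            "count": score_count_correct,
            "sum": score_sum_coded,
            "mean": score_mean_coded,
        }[inst.family]
        out[name] = [scorer(row, name) for row in items[cols].to_numpy()]

    loss_cols = [f"blessed_performance_{k}_loss" for k in range(1, BLESSED_N_ITEMS + 1)]
    attr_cols = [f"blessed_performance_{k}_attr" for k in range(1, BLESSED_N_ITEMS + 1)]
    if all(c in items.columns for c in loss_cols + attr_cols):
        scores = []
        for _, row in items.iterrows():
            pairs = []
            for lc, ac in zip(loss_cols, attr_cols):
                loss = row[lc]
                attr = row[ac]
                if pd.isna(loss):
                    pairs.append(None)
                else:
                    pairs.append((loss, None if pd.isna(attr) else attr))
            scores.append(score_blessed_performance(pairs))
        out["blessed_performance"] = scores
    return pd.DataFrame(out)
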