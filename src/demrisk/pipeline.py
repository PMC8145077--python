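"""End-to-end orchestration: simulate -> label -> split -> train -> vote ->
evaluate -> select -> predict-unlabeled -> prevalence.

Every stage writes its artifact (CSV/JSON) into a run directory together
with a JSON-lines log of seeds and stage outcomes, so a run is auditable
and reproducible from its persisted config.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import prep, synthetic
from .ensemble import TwoStepDementiaClassifier
from .metrics import evaluate_predictions
from .prevalence import estimate_prevalence

METRIC_ORDER = ["auroc", "accuracy", "sensitivity", "specificity",
                "precision", "f1", "kappa"]

DEFAULT_LEARNERS = ["gradient_boosting", "random_forest", "svm_rbf",
                    "elastic_net", "regression_splines", "mlp"]


@dataclass
class PipelineConfig:
    """Run recipe; either a cohort CSV path or a synthetic-cohort block.

    ``unlabeled_frac`` withholds the consensus rating for a random fraction
    of a synthetic cohort, emulating participants who never progressed
    through the diagnostic process; the selected model predicts their
    status for the prevalence stage.
    """

    cohort_csv: str | None = None
    n_total: int = 2528
    unlabeled_frac: float = 0.0
    weight_dispersion: float = 0.5
    learners: list = field(default_factory=lambda: list(DEFAULT_LEARNERS))
    learner_grids: dict | None = None   # learner -> grid; None = registry default
    cv_folds: int = 10
    cv_repeats: int = 10
    min_votes: int = 3
    vote_mode: str = "per_cell"
    seed: int = 0
    outdir: str = "runs/latest"

    def validate(self) -> None:
        if self.cohort_csv is None and self.n_total < 2:
            raise ValueError("need a cohort_csv or a synthetic n_total >= 2")
        if not 0.0 <= self.unlabeled_frac < 1.0:
            raise ValueError("unlabeled_frac must be in [0, 1)")
        if not self.learners:
            raise ValueError("at least one learner is required")
        if not 1 <= self.min_votes <= 4:
            raise ValueError("min_votes must be in 1..4")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def select_best(report: pd.DataFrame) -> str:
    """Pick the learner with the highest kappa; ties break by higher F1,
    then higher sensitivity, then learner name for full determinism."""
    ranked = report.sort_values(
        by=["kappa", "f1", "sensitivity", "learner"],
        ascending=[False, False, False, True],
        kind="stable",
    )
    return str(ranked.iloc[0]["learner"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary report dict (also
    persisted as ``report.json`` in the run directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "log.jsonl"

    def log(stage: str, **info):
        with open(log_path, "a") as fh:
            fh.write(json.dumps({"stage": stage, "time": time.time(), **info}) + "\n")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)

    rng = np.random.default_rng(config.seed)

    # --- cohort -----------------------------------------------------------
    if config.cohort_csv is not None:
        cohort = synthetic.read_cohort_csv(config.cohort_csv)
        log("load", path=config.cohort_csv, n=len(cohort))
    else:
        spec = synthetic.CohortSpec(
            n_total=config.n_total,
            weight_dispersion=config.weight_dispersion,
            seed=int(rng.integers(2**31 - 1)),
        )
        cohort = synthetic.generate_cohort(spec)
        if config.unlabeled_frac > 0:
            n_hide = int(round(config.unlabeled_frac * len(cohort)))
            hide = rng.choice(len(cohort), size=n_hide, replace=False)
            cohort.loc[cohort.index[hide], "global_cdr"] = np.nan
        synthetic.write_cohort_csv(cohort, outdir / "cohort.csv")
        log("simulate", n=len(cohort), n_unlabeled=int(cohort["global_cdr"].isna().sum()))

    # --- label + split ----------------------------------------------------
    labeled = prep.label_dementia(cohort)
    unlabeled = cohort[cohort["global_cdr"].isna()]
    split_seed = int(rng.integers(2**31 - 1))
    split = prep.split_70_30(labeled, seed=split_seed)
    train = labeled[labeled["id"].isin(split.train_ids)]
    test = labeled[labeled["id"].isin(split.test_ids)]
    pd.concat([
        pd.DataFrame({"id": split.train_ids, "partition": "train"}),
        pd.DataFrame({"id": split.test_ids, "partition": "test"}),
    ]).to_csv(outdir / "split.csv", index=False)
    log("split", seed=split_seed, n_train=len(train), n_test=len(test),
        pos_train=int(train["dementia"].sum()), pos_test=int(test["dementia"].sum()))

    # --- train all learners ----------------------------------------------
    fit_seed = int(rng.integers(2**31 - 1))
    models: dict[str, TwoStepDementiaClassifier] = {}
    rows = []
    for learner in config.learners:
        grid = (config.learner_grids or {}).get(learner)
        clf = TwoStepDementiaClassifier(
            learner=learner, grid=grid, cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats, min_votes=config.min_votes,
            mode=config.vote_mode, random_state=fit_seed,
        ).fit(train, train["dementia"])
        models[learner] = clf
        m = evaluate_predictions(
            clf.predict(test), test["dementia"], scores=clf.risk_score(test),
        )
        rows.append({"learner": learner, **m.rounded(),
                     "cv_auroc": clf.scorer_.cv_auroc_,
                     **{f"raw_{k}": getattr(m, k) for k in METRIC_ORDER}})
        clf.voter_.cutoff_table_.to_json(outdir / f"cutoffs_{learner}.json")
        log("train", learner=learner, cv_auroc=clf.scorer_.cv_auroc_,
            best_params=clf.scorer_.best_params_)
    report = pd.DataFrame(rows)
    report[["learner", *METRIC_ORDER]].to_csv(outdir / "report.csv", index=False)

    # --- select + predict unlabeled + prevalence --------------------------
    best = select_best(report.assign(
        kappa=report["raw_kappa"], f1=report["raw_f1"],
        sensitivity=report["raw_sensitivity"],
    ))
    best_model = models[best]
    log("select", learner=best)

    summary = {
        "report": report[["learner", *METRIC_ORDER]].to_dict(orient="records"),
        "selected": best,
        "split": {"n_train": len(train), "n_test": len(test),
                  "pos_train": int(train["dementia"].sum()),
                  "pos_test": int(test["dementia"].sum())},
    }

    if len(unlabeled):
        pred_unlabeled = best_model.predict(unlabeled)
        pd.DataFrame({"id": unlabeled["id"], "predicted": pred_unlabeled}).to_csv(
            outdir / "predictions_unlabeled.csv", index=False,
        )
        weights = None
        if "weight" in cohort.columns:
            weights = np.concatenate([
                labeled["weight"].to_numpy(float),
                unlabeled["weight"].to_numpy(float),
            ])
        est = estimate_prevalence(labeled["dementia"], pred_unlabeled, weights)
        summary["prevalence"] = est.to_dict()
        log("prevalence", **est.to_dict())

    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log("done")
    summary["models"] = models
    summary["test"] = test
    summary["train"] = train
    return summary
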