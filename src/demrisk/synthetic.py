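"""Synthetic cohort generation and clinician-panel consensus simulation.

The real study cohort (a nationally representative Indian aging survey with a
clinical consensus diagnosis subsample) is access restricted, so this module
generates cohorts with the same statistical skeleton the downstream analysis
assumes: published marginal means/SDs and prevalences for every instrument
score and health-history flag, a global Clinical Dementia Rating (CDR) on the
ordinal scale {0, 0.5, 1, 2, 3} with a realistic class distribution, positive
mean-1 sampling weights, and a single latent severity factor that links every
instrument to the diagnosis.

The generative model is deliberately the simplest structure that induces the
assumed signal: one standard-normal latent severity ``z`` per participant;
the global CDR is obtained by cutting ``z`` at thresholds calibrated to a
target class distribution; each continuous score is drawn from its marginal
normal and shifted by ``loading * z`` before clipping and rounding to the
instrument's admissible range and granularity; each binary flag is Bernoulli
with probability shifted on the logit scale by ``loading * z``.

A panel of noisy raters is simulated on the same latent scale: each rater
thresholds ``z`` plus personal noise (round 1); dissenters may move toward
the round-1 majority and re-rate (round 2); unresolved cases go to a
consensus meeting that returns the true CDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

CDR_VALUES = np.array([0.0, 0.5, 1.0, 2.0, 3.0])

#: Global CDR class counts for {0, 0.5, 1, 2, 3} in the published consensus
#: sample (n=2528); fractions of these counts are the default target
#: distribution and sum to 1 exactly.
CDR_CLASS_COUNTS = np.array([768, 1568, 162, 25, 5])

DIST_TOL = 1e-3


class SpecificationError(ValueError):
    """A cohort or rater specification violates its invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """Marginal description of one generated variable.

    Parameters
    ----------
    kind : {"continuous", "binary"}
        Continuous variables are normal with ``mean``/``sd``, clipped to
        ``[lo, hi]`` and rounded to multiples of ``step`` (no rounding when
        ``step`` is None). Binary variables are Bernoulli(``prevalence``).
    loading : float
        Signed effect of one SD of latent severity: additive on the score
        scale for continuous variables, additive on the logit scale for
        binary ones. Positive loadings make the variable a deficit marker.
    """

    kind: str
    mean: float = 0.0
    sd: float = 1.0
    lo: float = -np.inf
    hi: float = np.inf
    step: float | None = None
    prevalence: float = 0.0
    loading: float = 0.0

    def validate(self, name: str) -> None:
        if self.kind not in ("continuous", "binary"):
            raise SpecificationError(f"{name}: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            if self.sd < 0:
                raise SpecificationError(f"{name}: sd must be >= 0, got {self.sd}")
            if not self.lo <= self.hi:
                raise SpecificationError(f"{name}: empty range [{self.lo}, {self.hi}]")
            if self.step is not None and self.step <= 0:
                raise SpecificationError(f"{name}: step must be positive")
        else:
            if not 0.0 <= self.prevalence <= 1.0:
                raise SpecificationError(
                    f"{name}: prevalence must be in [0, 1], got {self.prevalence}"
                )


def _cont(mean, sd, lo, hi, loading=0.0, step=1.0):
    return VariableSpec("continuous", mean=mean, sd=sd, lo=lo, hi=hi,
                        step=step, loading=loading)


def _flag(prevalence, loading=0.0):
    return VariableSpec("binary", prevalence=prevalence, loading=loading)


def default_variable_specs() -> dict[str, VariableSpec]:
    """Marginals matching the published descriptive table (unweighted column).

    Loadings are chosen so that cognitive/functional deficits rise and
    abilities fall with severity at roughly the strength seen in real
    dementia cohorts (score-scale shift per SD of severity, about 0.2-0.6
    of each instrument's SD); blood pressure and sex carry no signal.
    """
    return {
        "age": _cont(68.69, 7.50, 60, 103, loading=2.0),
        "married": _flag(0.6614, loading=-0.3),
        "female": _flag(0.4763),
        "education": _cont(3.64, 4.60, 0, 20, loading=-1.5),
        "sbp": _cont(138.38, 23.35, 76.5, 225.0, step=0.5),
        "dbp": _cont(82.73, 12.46, 47.5, 137.0, step=0.5),
        "dx_stroke": _flag(0.0324, loading=0.3),
        "dx_heart": _flag(0.0613),
        "dx_diabetes": _flag(0.1487),
        "dx_hypertension": _flag(0.3813),
        "dx_depression": _flag(0.0083, loading=0.3),
        "dx_dementia": _flag(0.0103, loading=1.5),
        "dx_psychiatric": _flag(0.0067, loading=0.3),
        "dx_neurologic": _flag(0.0229, loading=0.5),
        "dx_vision": _flag(0.4403, loading=0.3),
        "dx_hearing": _flag(0.2816, loading=0.3),
        "hmse": _cont(22.11, 5.87, 0, 30, loading=-3.5),
        "tics": _cont(2.01, 0.92, 0, 3, loading=-0.45),
        "csid": _cont(3.31, 0.94, 0, 4, loading=-0.5),
        "judgment": _cont(2.21, 1.51, 0, 5, loading=-0.75),
        "numeracy": _cont(3.85, 2.64, 0, 9, loading=-1.2),
        "adl": _cont(1.34, 1.76, 0, 6, loading=1.0),
        "iadl": _cont(2.27, 2.24, 0, 7, loading=1.3),
        "mobility": _cont(3.72, 2.92, 0, 9, loading=1.2),
        "cesd": _cont(9.92, 5.25, 0, 30, loading=1.5),
        "anxiety": _cont(2.94, 3.30, 0, 15, loading=0.8),
        "iqcode": _cont(3.51, 0.56, 1, 5, loading=0.35, step=None),
        "blessed_habits": _cont(1.09, 0.32, 1, 4, loading=0.15, step=None),
        "blessed_performance": _cont(1.26, 1.71, 0, 8, loading=1.0, step=0.5),
    }


DX_FLAG_COLUMNS = [
    "dx_stroke", "dx_heart", "dx_diabetes", "dx_hypertension", "dx_depression",
    "dx_dementia", "dx_psychiatric", "dx_neurologic", "dx_vision", "dx_hearing",
]


def default_condition_effects() -> dict[str, dict[str, float]]:
    """Label-independent deficit noise tied to the four voting conditions.

    Depression, anxiety and sensory impairment depress test performance and
    inflate informant-reported difficulty without any change in true
    dementia status — the clinical confound the group-conditional voting
    step exists to absorb. ``depression``/``anxiety`` effects are per SD of
    an independent standard-normal symptom factor (which also drives the
    CES-D / anxiety scores themselves); ``vision``/``hearing`` effects
    apply to the mean-centered impairment flag, so marginal score means are
    preserved.
    """
    return {
        "depression": {
            "cesd": 3.0, "hmse": -1.2, "tics": -0.12, "csid": -0.12,
            "judgment": -0.3, "numeracy": -0.4, "adl": 0.4, "iadl": 0.5,
            "mobility": 0.5, "iqcode": 0.08, "blessed_performance": 0.3,
        },
        "anxiety": {
            "anxiety": 2.0, "hmse": -0.8, "tics": -0.1, "csid": -0.1,
            "judgment": -0.2, "numeracy": -0.3, "iadl": 0.3,
            "mobility": 0.3, "blessed_performance": 0.2,
        },
        "vision": {
            "hmse": -1.5, "numeracy": -0.6, "judgment": -0.3, "csid": -0.3,
            "adl": 0.4, "iadl": 0.5, "mobility": 0.5,
        },
        "hearing": {
            "hmse": -1.2, "tics": -0.3, "csid": -0.3, "judgment": -0.3,
            "iadl": 0.3, "iqcode": 0.06,
        },
    }


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort.

    ``cdr_target_dist`` gives target probabilities for global CDR classes
    {0, 0.5, 1, 2, 3}; defaults are the exact published class fractions.
    ``weight_dispersion`` is the log-scale SD of the lognormal sampling
    weights (weights are normalized to mean 1 per cohort).
    """

    n_total: int = 2528
    cdr_target_dist: tuple[float, ...] = tuple(CDR_CLASS_COUNTS / CDR_CLASS_COUNTS.sum())
    variable_specs: dict[str, VariableSpec] = field(default_factory=default_variable_specs)
    condition_effects: dict[str, dict[str, float]] = field(
        default_factory=default_condition_effects)
    condition_strength: float = 1.0
    weight_dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_total < 0:
            raise SpecificationError(f"n_total must be >= 0, got {self.n_total}")
        dist = np.asarray(self.cdr_target_dist, dtype=float)
        if dist.shape != (5,):
            raise SpecificationError("cdr_target_dist must have 5 entries")
        if (dist < 0).any():
            raise SpecificationError("cdr_target_dist entries must be >= 0")
        if abs(dist.sum() - 1.0) > DIST_TOL:
            raise SpecificationError(
                f"cdr_target_dist must sum to 1 (got {dist.sum():.6f})"
            )
        if self.weight_dispersion < 0:
            raise SpecificationError("weight_dispersion must be >= 0")
        for name, vs in self.variable_specs.items():
            vs.validate(name)

    def with_loadings_scaled(self, factor: float) -> "CohortSpec":
        """Return a copy with every severity loading multiplied by ``factor``."""
        scaled = {
            name: replace(vs, loading=vs.loading * factor)
            for name, vs in self.variable_specs.items()
        }
        return replace(self, variable_specs=scaled)


@dataclass(frozen=True)
class RaterSpec:
    """Noisy-rater panel: ``n_raters`` independent reviewers, each rating the
    participant by thresholding latent severity plus personal N(0, noise_sd)
    error; in round 2 dissenters move ``round2_shrinkage`` of the way toward
    the round-1 majority's interval midpoint."""

    n_raters: int = 3
    noise_sd: float = 0.3
    round2_shrinkage: float = 0.8

    def validate(self) -> None:
        if self.n_raters < 3:
            raise SpecificationError(f"n_raters must be >= 3, got {self.n_raters}")
        if self.noise_sd < 0:
            raise SpecificationError("noise_sd must be >= 0")
        if not 0.0 <= self.round2_shrinkage <= 1.0:
            raise SpecificationError("round2_shrinkage must be in [0, 1]")


def _clipped_normal_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Mean of clip(N(mu, sd), lo, hi) in closed form."""
    if sd == 0:
        return float(np.clip(mu, lo, hi))
    a, b = (lo - mu) / sd, (hi - mu) / sd
    mean = mu + sd * (norm.pdf(a) - norm.pdf(b))
    if np.isfinite(lo):
        mean += (lo - mu) * norm.cdf(a)
    if np.isfinite(hi):
        mean += (hi - mu) * (1.0 - norm.cdf(b))
    return float(mean)


def _location_for_target_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Pre-clip location whose clipped-normal mean equals ``target``.

    Score floors/ceilings bias the clipped mean toward the interior (e.g. a
    symptom scale floored at 0); solving for the location keeps the
    generated marginal mean on its published value.
    """
    if sd == 0 or (not np.isfinite(lo) and not np.isfinite(hi)):
        return target
    from scipy.optimize import brentq
    f = lambda mu: _clipped_normal_mean(mu, sd, lo, hi) - target
    span = 8.0 * sd + 1.0
    return float(brentq(f, target - span, target + span, xtol=1e-10))


def calibrate_severity_thresholds(cdr_target_dist) -> np.ndarray:
    """Cut points on the latent standard-normal severity scale.

    Returns 4 increasing thresholds such that a N(0,1) draw lands in CDR
    class k with probability ``cdr_target_dist[k]``: the thresholds are
    standard-normal quantiles of the cumulative class probabilities. A
    zero-probability interior class collapses two adjacent thresholds onto
    one cut point (with a warning); classes whose cumulative probability
    reaches 1 get +inf thresholds.
    """
    dist = np.asarray(cdr_target_dist, dtype=float)
    if dist.ndim != 1 or dist.size != 5:
        raise SpecificationError("cdr_target_dist must have 5 entries")
    if (dist < 0).any():
        raise SpecificationError("cdr_target_dist entries must be >= 0")
    if abs(dist.sum() - 1.0) > DIST_TOL:
        raise SpecificationError(
            f"cdr_target_dist must sum to 1 (got {dist.sum():.6f})"
        )
    if (dist[1:-1] == 0).any():
        warnings.warn(
            "zero-probability interior CDR class: adjacent severity "
            "thresholds collapse", UserWarning, stacklevel=2,
        )
    cum = np.minimum(np.cumsum(dist)[:4], 1.0)
    with np.errstate(divide="ignore"):
        thresholds = norm.ppf(cum)
    return thresholds


def assign_cdr(severity, thresholds) -> np.ndarray:
    """Map latent severity draws to global CDR values via the cut points.

    Class k covers the half-open interval [t_{k-1}, t_k); +inf thresholds
    make the upper classes unreachable.
    """
    idx = np.searchsorted(np.asarray(thresholds), np.asarray(severity), side="right")
    return CDR_VALUES[idx]


def _interval_midpoints(thresholds: np.ndarray) -> np.ndarray:
    """Representative severity per CDR class: the interval midpoint, with
    unbounded extreme intervals represented by the finite bound -/+ 0.5."""
    bounds = np.concatenate([[-np.inf], thresholds, [np.inf]])
    mids = np.empty(5)
    for k in range(5):
        lo, hi = bounds[k], bounds[k + 1]
        if np.isinf(lo) and np.isinf(hi):
            mids[k] = 0.0
        elif np.isinf(lo):
            mids[k] = hi - 0.5
        elif np.isinf(hi):
            mids[k] = lo + 0.5
        else:
            mids[k] = 0.5 * (lo + hi)
    return mids


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one cohort.

    Returns a DataFrame with one row per participant: ``id``, every variable
    in ``spec.variable_specs``, the latent ``severity`` draw, ``global_cdr``
    and a positive ``weight`` normalized to mean 1. Fully reproducible from
    ``seed`` (defaults to ``spec.seed``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_total
    thresholds = calibrate_severity_thresholds(spec.cdr_target_dist)

    z = rng.standard_normal(n)
    # independent symptom factors for the depression/anxiety confounds
    factors = {
        "depression": rng.standard_normal(n),
        "anxiety": rng.standard_normal(n),
    }

    data: dict[str, np.ndarray] = {"id": np.arange(n)}
    raw_cont: dict[str, np.ndarray] = {}
    for name, vs in spec.variable_specs.items():
        if vs.kind == "continuous":
            mu = _location_for_target_mean(vs.mean, vs.sd, vs.lo, vs.hi)
            raw_cont[name] = rng.normal(mu, vs.sd, size=n) + vs.loading * z
        else:
            if vs.loading == 0.0 or vs.prevalence in (0.0, 1.0):
                p = np.full(n, vs.prevalence)
            else:
                logit = np.log(vs.prevalence / (1.0 - vs.prevalence))
                p = 1.0 / (1.0 + np.exp(-(logit + vs.loading * z)))
            data[name] = (rng.random(n) < p).astype(int)

    # label-independent condition noise: sensory drivers are the
    # mean-centered impairment flags, so marginal means are preserved
    if spec.condition_strength != 0.0:
        for cond, effects in spec.condition_effects.items():
            if cond in factors:
                driver = factors[cond]
            else:
                flag = f"dx_{cond}"
                if flag not in data:
                    continue
                vs_flag = spec.variable_specs[flag]
                driver = data[flag] - vs_flag.prevalence
            for var, eff in effects.items():
                if var in raw_cont:
                    raw_cont[var] = raw_cont[var] + spec.condition_strength * eff * driver

    for name, vs in spec.variable_specs.items():
        if vs.kind != "continuous":
            continue
        raw = np.clip(raw_cont[name], vs.lo, vs.hi)
        if vs.step is not None:
            raw = vs.lo + np.round((raw - vs.lo) / vs.step) * vs.step
            raw = np.clip(raw, vs.lo, vs.hi)
        data[name] = raw

    data["severity"] = z
    data["global_cdr"] = assign_cdr(z, thresholds)
    if n > 0:
        w = rng.lognormal(mean=0.0, sigma=spec.weight_dispersion, size=n)
        data["weight"] = w / w.mean()
    else:
        data["weight"] = np.empty(0)
    columns = ["id", *spec.variable_specs, "severity", "global_cdr", "weight"]
    return pd.DataFrame(data)[columns]


def simulate_raters(
    cohort: pd.DataFrame, rater_spec: RaterSpec, seed: int = 0,
    cdr_target_dist=None,
) -> pd.DataFrame:
    """Simulate the multi-round consensus rating process for each participant.

    Round 1: every rater thresholds ``severity`` plus personal noise. If the
    panel is unanimous the case resolves at ``round1``. Otherwise each
    dissenting rater (one not at the round-1 modal rating; modal ties break
    toward the lower rating) moves ``round2_shrinkage`` of the way from their
    perturbed severity toward the modal class's interval midpoint and
    re-rates. Unanimity now resolves at ``round2``; otherwise the case goes
    to ``meeting`` and the final rating is the participant's true global CDR.

    Returns a wide DataFrame: ``id``, ``round1_r<j>``/``round2_r<j>`` per
    rater, ``final_cdr``, ``resolution_stage``.
    """
    rater_spec.validate()
    if "severity" not in cohort.columns:
        raise SpecificationError(
            "cohort must carry the generator's latent 'severity' column"
        )
    dist = (tuple(CDR_CLASS_COUNTS / CDR_CLASS_COUNTS.sum())
            if cdr_target_dist is None else cdr_target_dist)
    thresholds = calibrate_severity_thresholds(dist)
    mids = _interval_midpoints(thresholds)
    rng = np.random.default_rng(seed)

    z = cohort["severity"].to_numpy(float)
    true_cdr = cohort["global_cdr"].to_numpy(float)
    n, k = len(z), rater_spec.n_raters

    perturbed = z[:, None] + rng.normal(0.0, rater_spec.noise_sd, size=(n, k))
    round1 = assign_cdr(perturbed.ravel(), thresholds).reshape(n, k)

    # modal round-1 rating per case; ties toward the lower rating
    class_idx = np.searchsorted(CDR_VALUES, round1.ravel()).reshape(n, k)
    counts = (class_idx[:, :, None] == np.arange(5)).sum(axis=1)
    modal_idx = counts.argmax(axis=1)
    modal_cdr = CDR_VALUES[modal_idx]

    unanimous1 = (round1 == round1[:, [0]]).all(axis=1)

    shrink = rater_spec.round2_shrinkage
    target = mids[modal_idx][:, None]
    dissent = round1 != modal_cdr[:, None]
    moved = np.where(dissent, perturbed + shrink * (target - perturbed), perturbed)
    round2 = assign_cdr(moved.ravel(), thresholds).reshape(n, k)
    round2[unanimous1] = round1[unanimous1]
    unanimous2 = (round2 == round2[:, [0]]).all(axis=1)

    stage = np.where(unanimous1, "round1", np.where(unanimous2, "round2", "meeting"))
    final = np.where(unanimous1, round1[:, 0],
                     np.where(unanimous2, round2[:, 0], true_cdr))

    out = {"id": cohort["id"].to_numpy()}
    for j in range(k):
        out[f"round1_r{j + 1}"] = round1[:, j]
    for j in range(k):
        out[f"round2_r{j + 1}"] = round2[:, j]
    out["final_cdr"] = final
    out["resolution_stage"] = stage
    return pd.DataFrame(out)


def consensus_to_long(consensus: pd.DataFrame) -> pd.DataFrame:
    """Reshape a consensus table to long format: one row per rater x round,
    plus one ``final`` row per participant (rater 0)."""
    rater_cols = [c for c in consensus.columns if c.startswith("round")]
    rows = []
    for _, rec in consensus.iterrows():
        for c in rater_cols:
            rnd, rater = c.split("_r")
            rows.append((rec["id"], rnd, int(rater), rec[c], ""))
        rows.append((rec["id"], "final", 0, rec["final_cdr"], rec["resolution_stage"]))
    return pd.DataFrame(
        rows, columns=["id", "round", "rater", "rating", "resolution_stage"]
    )


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; missing global CDR serializes as an empty field."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
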