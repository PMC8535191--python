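"""Predictor screening, AICc model tuning and cross-validated evaluation.

Tuning follows the ENMeval-style protocol: a fixed grid of candidate settings
(13 feature-class combinations x a regularization-multiplier lattice, by
default 1.0–5.0 in steps of 0.2, i.e. 21 values and 273 candidates).  Each
candidate is fit on all presences and scored by AICc computed from the raw
Gibbs scores standardized over every study-area cell, with K = the number of
nonzero coefficients.  The winner is the smallest valid AICc; discrimination
metrics (AUC, TSS at the 10-percentile training presence threshold) come from
a seeded random k-fold cross-validation of the selected settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import maxent
from .config import FEATURE_COMBOS
from .grids import ScenarioStack
from .metrics import auc, ten_percentile_threshold, tss

__all__ = [
    "CandidateSpec",
    "TuneResult",
    "EvalResult",
    "candidate_grid",
    "pearson_screen",
    "aicc",
    "kfold_evaluate",
    "tune",
    "select_best",
]


@dataclass(frozen=True)
class CandidateSpec:
    """One tuning candidate: a feature-class combo and a regularization multiplier."""

    combo: str
    rm: float

    def __post_init__(self) -> None:
        if self.combo not in FEATURE_COMBOS:
            raise ValueError(f"combo {self.combo!r} not in the admissible list")
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be > 0")


@dataclass
class TuneResult:
    spec: CandidateSpec
    k_nonzero: int
    log_likelihood: float
    aicc: float
    valid: bool
    model: "maxent.MaxentModel | None" = field(default=None, repr=False)


@dataclass
class EvalResult:
    spec: CandidateSpec
    mean_auc: float
    mean_tss: float
    fold_auc: list[float]
    fold_tss: list[float]
    fold_threshold: list[float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")
        if not (-1.0 <= self.mean_tss <= 1.0):
            raise ValueError("TSS out of [-1, 1]")


def candidate_grid(
    combos: tuple[str, ...] = FEATURE_COMBOS,
    rm_values: list[float] | None = None,
) -> list[CandidateSpec]:
    """Deterministic candidate list; defaults give 13 x 21 = 273 specs."""
    if rm_values is None:
        rm_values = [round(1.0 + 0.2 * i, 10) for i in range(21)]
    return [CandidateSpec(c, rm) for c in combos for rm in rm_values]


def pearson_screen(
    stack: ScenarioStack,
    ranking: list[str],
    r_max: float = 0.75,
) -> tuple[list[str], pd.DataFrame]:
    """Best-first collinearity screen over valid cells.

    Traverses ``ranking`` (best candidate first) and keeps a variable iff its
    absolute Pearson correlation with every already-kept variable is below
    ``r_max``.  Returns the kept list and the full correlation matrix.
    """
    missing = [v for v in stack.variables if v not in ranking]
    if missing:
        raise ValueError(f"ranking does not cover variables: {missing}")
    mask = stack.valid_mask()
    data = {v: stack.grids[v].values[mask] for v in ranking if v in stack.grids}
    df = pd.DataFrame(data)
    corr = df.corr(method="pearson")
    kept: list[str] = []
    for v in ranking:
        if v not in df.columns:
            continue
        if df[v].std(ddof=0) == 0:
            warnings.warn(f"variable {v!r} is constant; correlation undefined, dropped",
                          stacklevel=2)
            continue
        if all(abs(corr.loc[v, u]) < r_max for u in kept):
            kept.append(v)
    return kept, corr


def aicc_formula(k: int, ll: float, n: int) -> float:
    """Small-sample AIC: 2K − 2ll + 2K(K+1)/(n − K − 1); inf when undefined."""
    if n - k - 1 <= 0:
        return float("inf")
    return 2 * k - 2 * ll + (2 * k * (k + 1)) / (n - k - 1)


def aicc(
    model: "maxent.MaxentModel",
    presence_raw: np.ndarray,
    region_raw: np.ndarray,
) -> TuneResult:
    """AICc of a fitted model from region-standardized raw scores.

    Raw scores are renormalized to sum to 1 over *all* study-area cells
    (``region_raw``), the log-likelihood is the sum of log standardized
    scores at the occurrences, and K counts nonzero coefficients.  Flagged
    invalid when n − K − 1 <= 0.
    """
    n = len(presence_raw)
    eta_region = model.eta(region_raw)
    mx = eta_region.max()
    log_z_region = mx + np.log(np.exp(eta_region - mx).sum())
    ll = float((model.eta(presence_raw) - log_z_region).sum())
    k = model.k_nonzero
    spec = (CandidateSpec(model.classes, model.rm)
            if model.classes in FEATURE_COMBOS else CandidateSpec("L", model.rm))
    value = aicc_formula(k, ll, n)
    return TuneResult(spec, k, ll, value, bool(np.isfinite(value)), model)


def kfold_evaluate(
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    variables: list[str],
    spec: CandidateSpec,
    k: int = 10,
    seed: int = 0,
    threshold_percentile: float = 10.0,
    **fit_kwargs,
) -> EvalResult:
    """Random k-fold cross-validation of one candidate.

    Presences are partitioned into k seeded folds; the background is never
    partitioned — every fold's AUC and specificity use the full background as
    pseudo-absences.  The TSS threshold is the 10-percentile (by default)
    training presence cloglog score of that fold's training split.
    """
    m = len(presence_raw)
    if m < k:
        raise ValueError(f"need at least k={k} presences, got {m}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    if any(len(f) == 0 for f in folds):  # cannot happen for m >= k
        order = rng.permutation(m)
        folds = np.array_split(order, k)
        if any(len(f) == 0 for f in folds):
            raise RuntimeError("empty cross-validation fold")

    fold_auc, fold_tss, fold_tau = [], [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        model = maxent.fit(presence_raw[train_idx], background_raw, variables,
                           classes=spec.combo, rm=spec.rm, **fit_kwargs)
        s_train = model.cloglog(presence_raw[train_idx])
        s_test = model.cloglog(presence_raw[test_idx])
        s_bg = model.cloglog(background_raw)
        fold_auc.append(auc(s_test, s_bg))
        tau = ten_percentile_threshold(s_train, threshold_percentile)
        sens = float(np.mean(s_test >= tau))
        spec_ = float(np.mean(s_bg < tau))
        fold_tss.append(tss(sens, spec_))
        fold_tau.append(tau)
    return EvalResult(spec, float(np.mean(fold_auc)), float(np.mean(fold_tss)),
                      fold_auc, fold_tss, fold_tau)


def tune(
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    region_raw: np.ndarray,
    variables: list[str],
    candidates: list[CandidateSpec] | None = None,
    **fit_kwargs,
) -> list[TuneResult]:
    """Fit every candidate on all presences and score it by AICc."""
    if candidates is None:
        candidates = candidate_grid()
    results = []
    for cand in candidates:
        model = maxent.fit(presence_raw, background_raw, variables,
                           classes=cand.combo, rm=cand.rm, **fit_kwargs)
        res = aicc(model, presence_raw, region_raw)
        res.spec = cand
        results.append(res)
    return results


def select_best(results: list[TuneResult]) -> TuneResult:
    """Smallest valid AICc; ties broken by smaller K, then RM, then combo order."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid candidate (all AICc flagged invalid)")
    return min(valid, key=lambda r: (r.aicc, r.k_nonzero, r.spec.rm,
                                     FEATURE_COMBOS.index(r.spec.combo)))


def tuning_table(results: list[TuneResult],
                 evals: dict[CandidateSpec, EvalResult] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"combo": r.spec.combo, "rm": r.spec.rm, "K": r.k_nonzero,
               "log_likelihood": r.log_likelihood, "AICc": r.aicc, "valid": r.valid}
        if evals and r.spec in evals:
            row["mean_auc"] = evals[r.spec].mean_auc
            row["mean_tss"] = evals[r.spec].mean_tss
        rows.append(row)
    return pd.DataFrame(rows)
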