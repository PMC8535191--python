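"""Presence-background maximum-entropy (Maxent-style) niche model.

The model is an L1-penalized Gibbs distribution over background cells:
``p(x) ∝ exp(βᵀ f(x))`` where ``f`` expands the raw predictors into feature
classes — Linear, Quadratic, pairwise Product, and Hinge bases — each rescaled
to [0, 1] by background min/max.  Fitting maximizes the mean presence
log-likelihood under the background-normalized distribution minus per-feature
L1 penalties::

    max_β  (1/m) Σ_i βᵀf(x_i) − log Σ_j exp(βᵀf(x_j)) − Σ_k λ_k |β_k|

with ``λ_k = RM · β_class(m) · max(sd_k(presences), floor) / √m`` following
the published Maxent default regularization tables per feature class.  The
optimizer is a monotone proximal-gradient method (ISTA with backtracking):
the penalized objective never decreases across iterations, and convergence is
declared when its relative change falls below the tolerance.

Suitability output uses the cloglog transform of Maxent v3.4:
``cloglog(x) = 1 − exp(−e^H · raw(x))`` where ``H`` is the entropy of the raw
distribution over the training background, and ``raw`` is the
background-normalized Gibbs probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .config import BETA_TABLES
from .grids import Grid, ScenarioStack

__all__ = [
    "FeatureSpec",
    "MaxentModel",
    "build_feature_specs",
    "expand_features",
    "fit",
    "predict",
    "response_curve",
    "permutation_importance",
    "percent_contribution",
    "sample_background",
    "presence_values",
    "beta_class_default",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: its class, source variable(s), and hinge parameters.

    ``knot`` lives on the [0, 1] background-scaled axis of the variable;
    ``orientation`` is 'forward' (ramp up after the knot) or 'reverse'.
    """

    feature_class: str                   # 'L' | 'Q' | 'P' | 'H'
    variables: tuple[str, ...]
    knot: float | None = None
    orientation: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in ("L", "Q", "P", "H"):
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        n_expected = 2 if self.feature_class == "P" else 1
        if len(self.variables) != n_expected:
            raise ValueError(f"{self.feature_class} feature needs {n_expected} variable(s)")
        if self.feature_class == "P" and self.variables[0] == self.variables[1]:
            raise ValueError("product feature needs two distinct variables")
        if self.feature_class == "H":
            if self.knot is None or not (0.0 < self.knot < 1.0):
                raise ValueError("hinge knot must lie strictly inside the background range")
            if self.orientation not in ("forward", "reverse"):
                raise ValueError("hinge orientation must be 'forward' or 'reverse'")

    @property
    def label(self) -> str:
        if self.feature_class == "P":
            return f"P({self.variables[0]}*{self.variables[1]})"
        if self.feature_class == "H":
            return f"H({self.variables[0]},{self.orientation},{self.knot:.4g})"
        return f"{self.feature_class}({self.variables[0]})"


def beta_class_default(feature_class: str, m: int) -> float:
    """Default per-class regularization beta, interpolated over presence count."""
    xs, ys = BETA_TABLES[feature_class]
    return float(np.interp(m, xs, ys))


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

def build_feature_specs(
    variables: list[str],
    classes: str,
    bg_scaled: np.ndarray,
    n_hinge_knots: int = 50,
) -> list[FeatureSpec]:
    """Feature specs for the requested classes over the given variables.

    ``bg_scaled`` is the (N, p) background matrix already scaled to [0, 1];
    hinge knots are placed at evenly spaced background quantiles, forward and
    reverse orientations each getting ``n_hinge_knots`` knots per variable.
    Variables constant over the background keep their (flagged) L feature but
    contribute no Q/P/H features.
    """
    classes = classes.upper()
    bad = set(classes) - set("LQPH")
    if bad:
        raise ValueError(f"unknown feature classes: {sorted(bad)}")
    constant = [bool(np.all(bg_scaled[:, i] == bg_scaled[0, i]))
                for i in range(len(variables))]
    if any(constant):
        warnings.warn(
            f"variables constant over background: "
            f"{[v for v, c in zip(variables, constant) if c]}; "
            "their Q/P/H features are dropped", stacklevel=2)
    specs: list[FeatureSpec] = []
    if "L" in classes:
        specs += [FeatureSpec("L", (v,)) for v in variables]
    if "Q" in classes:
        specs += [FeatureSpec("Q", (v,)) for v, c in zip(variables, constant) if not c]
    if "P" in classes:
        for (i, a), (j, b) in combinations(enumerate(variables), 2):
            if not (constant[i] or constant[j]):
                specs.append(FeatureSpec("P", (a, b)))
    if "H" in classes:
        qs = (np.arange(n_hinge_knots) + 1) / (n_hinge_knots + 1)
        for i, v in enumerate(variables):
            if constant[i]:
                continue
            knots = np.quantile(bg_scaled[:, i], qs)
            knots = np.clip(knots, 1e-9, 1 - 1e-9)
            for orient in ("forward", "reverse"):
                seen: set[float] = set()
                for t in knots:
                    t = float(t)
                    if t in seen:
                        continue  # duplicate quantiles collapse to one basis
                    seen.add(t)
                    specs.append(FeatureSpec("H", (v,), knot=t, orientation=orient))
    return specs


def _scale(raw: np.ndarray, vmin: np.ndarray, vmax: np.ndarray) -> np.ndarray:
    rng = np.where(vmax > vmin, vmax - vmin, 1.0)
    return (raw - vmin) / rng


def expand_features(
    raw: np.ndarray,
    variables: list[str],
    specs: list[FeatureSpec],
    vmin: np.ndarray,
    vmax: np.ndarray,
) -> np.ndarray:
    """(n, n_features) design matrix; identical expansion for any cell."""
    z = _scale(np.asarray(raw, dtype=float), vmin, vmax)
    idx = {v: i for i, v in enumerate(variables)}
    cols = []
    for s in specs:
        if s.feature_class == "L":
            cols.append(z[:, idx[s.variables[0]]])
        elif s.feature_class == "Q":
            cols.append(z[:, idx[s.variables[0]]] ** 2)
        elif s.feature_class == "P":
            cols.append(z[:, idx[s.variables[0]]] * z[:, idx[s.variables[1]]])
        else:  # hinge, rescaled back to [0, 1]
            zi = z[:, idx[s.variables[0]]]
            t = s.knot
            if s.orientation == "forward":
                cols.append(np.maximum(0.0, zi - t) / (1.0 - t))
            else:
                cols.append(np.maximum(0.0, t - zi) / t)
    return np.column_stack(cols) if cols else np.empty((len(z), 0))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    variables: list[str]
    specs: list[FeatureSpec]
    beta: np.ndarray
    lambdas: np.ndarray
    vmin: np.ndarray                      # background minima per variable
    vmax: np.ndarray                      # background maxima per variable
    rm: float
    log_z: float                          # log partition over training background
    entropy: float                        # H of raw distribution over background
    feature_sd_bg: np.ndarray             # per-feature sd over training background
    m_presences: int
    n_background: int
    iterations: int
    converged: bool
    classes: str = ""
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def k_nonzero(self) -> int:
        return int(np.sum(self.beta != 0))

    def features(self, raw: np.ndarray) -> np.ndarray:
        return expand_features(raw, self.variables, self.specs, self.vmin, self.vmax)

    def eta(self, raw: np.ndarray) -> np.ndarray:
        """Linear predictor βᵀf(x) for raw-variable rows."""
        return self.features(raw) @ self.beta

    def raw_score(self, raw: np.ndarray) -> np.ndarray:
        """Background-normalized Gibbs probability exp(η − log Z)."""
        # cap the exponent: projection cells far outside the training envelope
        # saturate instead of overflowing
        return np.exp(np.minimum(self.eta(raw) - self.log_z, 700.0))

    def cloglog(self, raw: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.entropy) * self.raw_score(raw))

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        payload = {
            "variables": self.variables,
            "specs": [{"feature_class": s.feature_class, "variables": list(s.variables),
                       "knot": s.knot, "orientation": s.orientation} for s in self.specs],
            "beta": self.beta.tolist(),
            "lambdas": self.lambdas.tolist(),
            "vmin": self.vmin.tolist(),
            "vmax": self.vmax.tolist(),
            "rm": self.rm,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "feature_sd_bg": self.feature_sd_bg.tolist(),
            "m_presences": self.m_presences,
            "n_background": self.n_background,
            "iterations": self.iterations,
            "converged": self.converged,
            "classes": self.classes,
        }
        path = Path(path)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        return cls(
            variables=d["variables"],
            specs=[FeatureSpec(s["feature_class"], tuple(s["variables"]),
                               s["knot"], s["orientation"]) for s in d["specs"]],
            beta=np.array(d["beta"]), lambdas=np.array(d["lambdas"]),
            vmin=np.array(d["vmin"]), vmax=np.array(d["vmax"]), rm=d["rm"],
            log_z=d["log_z"], entropy=d["entropy"],
            feature_sd_bg=np.array(d["feature_sd_bg"]),
            m_presences=d["m_presences"], n_background=d["n_background"],
            iterations=d["iterations"], converged=d["converged"],
            classes=d.get("classes", ""),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _log_sum_exp(v: np.ndarray) -> float:
    mx = v.max()
    return float(mx + np.log(np.exp(v - mx).sum()))


def fit(
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    variables: list[str],
    classes: str = "LQ",
    rm: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-7,
    n_hinge_knots: int = 50,
    penalty_sd_floor: float = 0.05,
) -> MaxentModel:
    """Fit the penalized Gibbs model; see the module docstring for the objective.

    ``presence_raw`` (m, p) and ``background_raw`` (N, p) hold the raw
    predictor values at presence and background cells, column order matching
    ``variables``.
    """
    P = np.asarray(presence_raw, dtype=float)
    B = np.asarray(background_raw, dtype=float)
    m, p = P.shape
    if m < 2:
        raise ValueError("need at least 2 presences")
    if B.shape[0] < m:
        raise ValueError("need at least as many background cells as presences")
    if B.shape[1] != p or p != len(variables):
        raise ValueError("presence/background/variable dimensions disagree")

    vmin = B.min(axis=0)
    vmax = B.max(axis=0)
    bg_scaled = _scale(B, vmin, vmax)
    specs = build_feature_specs(variables, classes, bg_scaled, n_hinge_knots)
    Fp = expand_features(P, variables, specs, vmin, vmax)
    Fb = expand_features(B, variables, specs, vmin, vmax)
    n_feat = Fb.shape[1]
    if n_feat == 0 or np.all(Fb == Fb[0:1, :]):
        raise ValueError("no variation in any feature over the background")

    # per-feature penalties from the presence-sample spread
    sd_pres = Fp.std(axis=0, ddof=0)
    betas_fc = np.array([beta_class_default(s.feature_class, m) for s in specs])
    lam = rm * betas_fc * np.maximum(sd_pres, penalty_sd_floor) / np.sqrt(m)

    mean_pres = Fp.mean(axis=0)

    def smooth(beta: np.ndarray) -> tuple[float, np.ndarray, float]:
        eta_b = Fb @ beta
        lz = _log_sum_exp(eta_b)
        q = np.exp(eta_b - lz)
        val = -float(mean_pres @ beta) + lz
        grad = -mean_pres + Fb.T @ q
        return val, grad, lz

    beta = np.zeros(n_feat)
    f_val, grad, log_z = smooth(beta)
    obj = f_val + float(lam @ np.abs(beta))
    trace = [obj]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # proximal gradient step with backtracking: guarantees monotone descent
        while True:
            cand = beta - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * lam, 0.0)
            delta = cand - beta
            f_cand, grad_cand, lz_cand = smooth(cand)
            quad = f_val + float(grad @ delta) + float(delta @ delta) / (2 * step)
            if f_cand <= quad + 1e-12 * abs(quad):
                break
            step *= 0.5
            if step < 1e-12:
                cand, f_cand, grad_cand, lz_cand = beta, f_val, grad, log_z
                break
        new_obj = f_cand + float(lam @ np.abs(cand))
        trace.append(min(new_obj, obj))
        rel = abs(obj - new_obj) / max(abs(obj), 1.0)
        beta, f_val, grad, log_z = cand, f_cand, grad_cand, lz_cand
        obj = min(new_obj, obj)
        if rel < tol:
            converged = True
            break
        step *= 1.25  # optimistic step growth; backtracking restores safety

    eta_b = Fb @ beta
    log_z = _log_sum_exp(eta_b)
    q = np.exp(eta_b - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(
        variables=list(variables), specs=specs, beta=beta, lambdas=lam,
        vmin=vmin, vmax=vmax, rm=rm, log_z=log_z, entropy=entropy,
        feature_sd_bg=Fb.std(axis=0, ddof=0),
        m_presences=m, n_background=B.shape[0], iterations=it,
        converged=converged, classes=classes.upper(),
        objective_trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# Prediction over grids
# ---------------------------------------------------------------------------

def predict(model: MaxentModel, stack: ScenarioStack, output: str = "cloglog") -> Grid:
    """Suitability grid over all valid cells of the stack (raw or cloglog)."""
    missing = [v for v in model.variables if v not in stack.grids]
    if missing:
        raise ValueError(f"stack lacks model variable(s): {missing}")
    if output not in ("raw", "cloglog"):
        raise ValueError("output must be 'raw' or 'cloglog'")
    template = stack.grids[model.variables[0]]
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    raw_vals = np.column_stack([stack.grids[v].values[rows, cols]
                                for v in model.variables])
    scores = model.raw_score(raw_vals)
    if output == "cloglog":
        scores = 1.0 - np.exp(-np.exp(model.entropy) * scores)
    out = np.full(template.shape, template.nodata, dtype=float)
    out[rows, cols] = scores
    return Grid(values=out, x_origin=template.x_origin, y_origin=template.y_origin,
                cell_size=template.cell_size, nodata=template.nodata,
                name=f"suitability_{output}")


def response_curve(
    variable: str,
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    variables: list[str],
    classes: str = "LQ",
    rm: float = 1.0,
    n_points: int = 100,
    **fit_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate response: cloglog of a model fit on this variable alone."""
    j = variables.index(variable)
    uni = fit(presence_raw[:, [j]], background_raw[:, [j]], [variable],
              classes=classes, rm=rm, **fit_kwargs)
    lo, hi = background_raw[:, j].min(), background_raw[:, j].max()
    xs = np.linspace(lo, hi, n_points)
    return xs, uni.cloglog(xs[:, None])


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    from .metrics import auc
    return auc(pos, neg)


def permutation_importance(
    model: MaxentModel,
    presence_raw: np.ndarray,
    background_raw: np.ndarray,
    seed: int = 0,
    n_perm: int = 10,
) -> dict[str, float]:
    """Drop in training AUC when one variable is permuted, normalized to 100.

    The variable's values are permuted jointly across presences and
    background; importance per variable is max(0, AUC_orig − AUC_perm)
    averaged over permutations, then normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    m = len(presence_raw)
    stacked = np.vstack([presence_raw, background_raw]).astype(float)
    auc0 = _rank_auc(model.eta(presence_raw), model.eta(background_raw))
    drops = {}
    for j, v in enumerate(model.variables):
        d = 0.0
        for _ in range(n_perm):
            perm = stacked.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            scores = model.eta(perm)
            d += max(0.0, auc0 - _rank_auc(scores[:m], scores[m:]))
        drops[v] = d / n_perm
    total = sum(drops.values())
    if total == 0:
        warnings.warn("no permutation produced an AUC drop; uniform importances",
                      stacklevel=2)
        return {v: 100.0 / len(drops) for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Per-variable share of Σ|β|·sd_bg(feature), normalized to 100.

    A magnitude-based surrogate for Maxent's path-dependent contribution
    bookkeeping (which cannot be reproduced outside its training trajectory);
    product features split evenly between their two variables.
    """
    weight = {v: 0.0 for v in model.variables}
    for s, b, sd in zip(model.specs, model.beta, model.feature_sd_bg):
        w = abs(b) * sd
        if s.feature_class == "P":
            weight[s.variables[0]] += w / 2
            weight[s.variables[1]] += w / 2
        else:
            weight[s.variables[0]] += w
    total = sum(weight.values())
    if total == 0:
        warnings.warn("all-zero model; uniform contribution split", stacklevel=2)
        return {v: 100.0 / len(weight) for v in weight}
    return {v: 100.0 * w / total for v, w in weight.items()}


# ---------------------------------------------------------------------------
# Cell extraction helpers
# ---------------------------------------------------------------------------

def sample_background(stack: ScenarioStack, n: int, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample n valid cells WITHOUT replacement: (rows, cols, raw matrix)."""
    mask = stack.valid_mask()
    rows, cols = np.nonzero(mask)
    if n > len(rows):
        raise ValueError(f"requested {n} background cells, only {len(rows)} valid")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    r, c = rows[pick], cols[pick]
    return r, c, stack.values_at_cells(r, c)


def presence_values(stack: ScenarioStack, coords: np.ndarray) -> np.ndarray:
    """Raw predictor values at the cells containing each presence point."""
    template = stack.template
    out = np.empty((len(coords), len(stack.variables)))
    for i, (x, y) in enumerate(np.asarray(coords, dtype=float)):
        r, c = template.cell_index(x, y)
        out[i] = [stack.grids[v].values[r, c] for v in stack.variables]
    return out
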