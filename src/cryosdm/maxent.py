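"""Presence-background maximum-entropy (MaxEnt) niche model, from scratch.

The model estimates a Gibbs distribution over the background sample of the
landscape: P(x) = exp(lambda . f(x)) / Z, where f(x) are bounded features
built from the environmental covariates (linear, quadratic, pairwise
product, and hinge classes on min-max-scaled covariates) and Z normalises
over the training background.  The weights minimise the regularised
log-loss

    L(lambda) = -(1/m) sum_presence lambda.f(x)
                + log sum_background exp(lambda.f(x))
                + sum_j beta_j |lambda_j|,

which is the relative entropy between the presence density and the model,
plus an L1 penalty.  Per-feature penalties follow the MaxEnt convention
beta_j = beta * s_j / sqrt(m) with s_j the feature's standard deviation
over the presence sample (floored so features constant on presences stay
bounded), making shrinkage scale-aware and stronger for small samples.

The L1 problem is solved exactly as a bound-constrained smooth problem by
splitting lambda into positive and negative parts (L-BFGS-B); convergence
is verified against the subgradient optimality conditions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .covariates import CovariateMatrix
from .errors import ConvergenceError, FoldError, SchemaError
from .evaluation import auc, random_folds

log = logging.getLogger(__name__)

_FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand, and how.

    ``hinge_knots`` interior knots per covariate generate that many forward
    and reverse hinges each; ``clamp`` truncates prediction-time inputs to
    the training range before expansion (avoids feature extrapolation).
    """

    classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge")
    hinge_knots: int = 8
    clamp: bool = True

    def __post_init__(self):
        if not self.classes:
            raise SchemaError("FeatureSpec.classes must be non-empty")
        bad = set(self.classes) - set(_FEATURE_CLASSES)
        if bad:
            raise SchemaError(f"unknown feature classes {sorted(bad)}")
        if "hinge" in self.classes and self.hinge_knots < 2:
            raise SchemaError("hinge_knots must be >= 2 when hinge features are active")

    def label(self) -> str:
        return "+".join(c for c in _FEATURE_CLASSES if c in self.classes)


def expand_features(
    values: np.ndarray,
    cov_names: list[str],
    spec: FeatureSpec,
    ranges: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str], tuple[np.ndarray, np.ndarray]]:
    """Expand raw covariates into the bounded MaxEnt feature matrix.

    Covariates are min-max scaled to [0, 1] using ``ranges`` (training
    mins/maxs); when ``ranges`` is None they are derived from ``values``
    (training time).  Covariates with zero training range are dropped with
    a warning.  Returns (features, feature_names, ranges).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(cov_names):
        raise SchemaError("values must be (n, n_covariates) matching cov_names")
    if ranges is None:
        ranges = (x.min(axis=0), x.max(axis=0))
    mins, maxs = ranges
    span = maxs - mins
    keep = span > 0
    if not keep.all():
        dropped = [n for n, k in zip(cov_names, keep) if not k]
        log.warning("dropping zero-variance covariates: %s", dropped)
    names = [n for n, k in zip(cov_names, keep) if k]
    z = (x[:, keep] - mins[keep]) / span[keep]
    if spec.clamp:
        z = np.clip(z, 0.0, 1.0)
    cols: list[np.ndarray] = []
    fnames: list[str] = []
    if "linear" in spec.classes:
        for j, n in enumerate(names):
            cols.append(z[:, j])
            fnames.append(f"lin({n})")
    if "quadratic" in spec.classes:
        for j, n in enumerate(names):
            cols.append(z[:, j] ** 2)
            fnames.append(f"quad({n})")
    if "product" in spec.classes:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                cols.append(z[:, i] * z[:, j])
                fnames.append(f"prod({names[i]},{names[j]})")
    if "hinge" in spec.classes:
        knots = np.linspace(0.0, 1.0, spec.hinge_knots + 2)[1:-1]
        for j, n in enumerate(names):
            for t in knots:
                cols.append(np.maximum(0.0, (z[:, j] - t) / (1.0 - t)))
                fnames.append(f"hinge+({n}@{t:.4f})")
            for t in knots:
                cols.append(np.maximum(0.0, (t - z[:, j]) / t))
                fnames.append(f"hinge-({n}@{t:.4f})")
    feats = np.column_stack(cols) if cols else np.empty((x.shape[0], 0))
    return feats, fnames, (mins, maxs)


@dataclass
class MaxEntModel:
    """Fitted model: weights, normaliser, and everything needed to replay
    predictions exactly (training covariate ranges, feature spec, penalty)."""

    cov_names: list[str]
    cov_mins: np.ndarray
    cov_maxs: np.ndarray
    feature_names: list[str]
    weights: np.ndarray
    log_normaliser: float  # log Z over the training background
    n_background: int
    entropy: float  # entropy of the raw distribution over training background
    reg_multiplier: float
    spec: FeatureSpec
    kkt_residual: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "cov_names": self.cov_names,
                "cov_mins": self.cov_mins.tolist(),
                "cov_maxs": self.cov_maxs.tolist(),
                "feature_names": self.feature_names,
                "weights": self.weights.tolist(),
                "log_normaliser": self.log_normaliser,
                "n_background": self.n_background,
                "entropy": self.entropy,
                "reg_multiplier": self.reg_multiplier,
                "spec": {
                    "classes": list(self.spec.classes),
                    "hinge_knots": self.spec.hinge_knots,
                    "clamp": self.spec.clamp,
                },
                "kkt_residual": self.kkt_residual,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        return cls(
            cov_names=d["cov_names"],
            cov_mins=np.array(d["cov_mins"]),
            cov_maxs=np.array(d["cov_maxs"]),
            feature_names=d["feature_names"],
            weights=np.array(d["weights"]),
            log_normaliser=d["log_normaliser"],
            n_background=d["n_background"],
            entropy=d["entropy"],
            reg_multiplier=d["reg_multiplier"],
            spec=FeatureSpec(
                classes=tuple(d["spec"]["classes"]),
                hinge_knots=d["spec"]["hinge_knots"],
                clamp=d["spec"]["clamp"],
            ),
            kkt_residual=d.get("kkt_residual", 0.0),
        )


# floor on the per-feature presence standard deviation entering the penalty.
# Features nearly constant across presences (e.g. a covariate that simply
# brackets the range boundary) would otherwise be almost penalty-free, letting
# the optimiser substitute them for the covariates that actually structure
# the niche; the floor keeps every feature's shrinkage within a factor ~3 of
# a typical [0,1] feature's (sd ~0.29) and keeps weights finite
_PENALTY_STD_FLOOR = 0.1


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta: float = 1.0,
    feature_betas: np.ndarray | None = None,
    max_iter: int = 20000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, float]:
    """Fit weights on pre-expanded feature matrices.

    Returns (weights, log_normaliser, kkt_residual).  ``feature_betas``
    overrides the default per-feature penalties beta * s_j / sqrt(m).
    Raises :class:`ConvergenceError` if the subgradient optimality residual
    exceeds ``tol`` after the iteration budget (residual also above a 1e-4
    hard ceiling; small L-BFGS-B slack below that is logged, not fatal).
    """
    fp = np.asarray(presence_features, dtype=float)
    fb = np.asarray(background_features, dtype=float)
    m, p = fp.shape
    n = fb.shape[0]
    if m < 5:
        log.warning("only %d presences; MaxEnt fits are unreliable below 5", m)
    if n < m:
        log.warning("background (%d) smaller than presence sample (%d)", n, m)
    if feature_betas is None:
        s = np.maximum(fp.std(axis=0), _PENALTY_STD_FLOOR)
        feature_betas = beta * s / np.sqrt(m)
    feature_betas = np.asarray(feature_betas, dtype=float)
    mean_fp = fp.mean(axis=0)

    def smooth_value_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        scores = fb @ lam
        val = float(-mean_fp @ lam + logsumexp(scores))
        grad = -mean_fp + softmax(scores) @ fb
        return val, grad

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = w[:p], w[p:]
        lam = u - v
        val, grad = smooth_value_grad(lam)
        val += float(feature_betas @ (u + v))
        return val, np.concatenate([grad + feature_betas, -grad + feature_betas])

    def kkt_residual(lam: np.ndarray) -> float:
        # subgradient optimality: |g_j| <= beta_j where lambda_j = 0,
        # g_j = -beta_j (resp. +beta_j) where lambda_j > 0 (resp. < 0)
        _, grad = smooth_value_grad(lam)
        active = np.abs(lam) > 1e-12
        ra = np.abs(grad[active] + np.sign(lam[active]) * feature_betas[active])
        rz = np.maximum(np.abs(grad[~active]) - feature_betas[~active], 0.0)
        return float(max(ra.max(initial=0.0), rz.max(initial=0.0)))

    w = np.zeros(2 * p)
    kkt = np.inf
    for attempt in range(4):  # warm restarts refresh the Hessian approximation
        res = minimize(
            fun,
            w,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * p),
            options={"maxiter": max_iter, "maxfun": max_iter,
                     "ftol": 1e-14, "gtol": 1e-10},
        )
        w = res.x
        kkt = kkt_residual(w[:p] - w[p:])
        if kkt <= tol:
            break
    lam = w[:p] - w[p:]
    if kkt > tol:
        if kkt > 1e-3:
            raise ConvergenceError(
                f"MaxEnt fit did not converge: KKT residual {kkt:.2e}", grad_norm=kkt
            )
        log.info("MaxEnt fit stopped with KKT residual %.2e (tol %.0e)", kkt, tol)
    log_z = float(logsumexp(fb @ lam))
    return lam, log_z, kkt


def train_maxent(
    presence: CovariateMatrix,
    background: CovariateMatrix,
    spec: FeatureSpec = FeatureSpec(),
    beta: float = 1.0,
) -> MaxEntModel:
    """Expand features and fit a model from presence/background covariates.

    Training min-max ranges are taken over the pooled presence + background
    sample, so every training feature lies in [0, 1].
    """
    if presence.names != background.names:
        raise SchemaError(
            f"presence covariates {presence.names} != background {background.names}"
        )
    pooled = np.vstack([presence.values, background.values])
    mins, maxs = pooled.min(axis=0), pooled.max(axis=0)
    fp, fnames, _ = expand_features(presence.values, presence.names, spec, (mins, maxs))
    fb, _, _ = expand_features(background.values, background.names, spec, (mins, maxs))
    lam, log_z, kkt = fit_maxent(fp, fb, beta=beta)
    raw_bg = softmax(fb @ lam)
    entropy = float(-(raw_bg * np.log(raw_bg)).sum())
    return MaxEntModel(
        cov_names=list(presence.names),
        cov_mins=mins,
        cov_maxs=maxs,
        feature_names=fnames,
        weights=lam,
        log_normaliser=log_z,
        n_background=background.n,
        entropy=entropy,
        reg_multiplier=beta,
        spec=spec,
        kkt_residual=kkt,
    )


def predict(model: MaxEntModel, m: CovariateMatrix, output: str = "raw") -> np.ndarray:
    """Per-cell suitability under a fitted model.

    ``raw`` is the Gibbs density exp(lambda.f(x))/Z (sums to 1 over the
    training background); ``logistic`` maps raw r to tau*r*n/(1 + tau*r*n)
    with tau = 0.5 and n the background size; ``cloglog`` is
    1 - exp(-exp(H)*r) with H the training entropy.  Both transforms are
    strictly increasing in raw, so rankings (and AUC) are unchanged.
    """
    if set(m.names) != set(model.cov_names):
        raise SchemaError(
            f"covariate names {m.names} do not match training {model.cov_names}"
        )
    order = [m.names.index(n) for n in model.cov_names]
    vals = m.values[:, order]
    feats, _, _ = expand_features(
        vals, model.cov_names, model.spec, (model.cov_mins, model.cov_maxs)
    )
    raw = np.exp(feats @ model.weights - model.log_normaliser)
    if output == "raw":
        return raw
    if output == "logistic":
        tau = 0.5
        q = tau * raw * model.n_background
        return q / (1.0 + q)
    if output == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise SchemaError(f"unknown output transform {output!r}")


@dataclass
class TuningResult:
    grid: list[tuple[float, FeatureSpec]]
    cv_scores: list[float]
    best: tuple[float, FeatureSpec]
    model: MaxEntModel  # best candidate refit on all presences

    def summary(self) -> list[dict]:
        return [
            {"beta": b, "features": s.label(), "cv_auc": score}
            for (b, s), score in zip(self.grid, self.cv_scores)
        ]


DEFAULT_SPEC_GRID = (
    FeatureSpec(classes=("linear", "quadratic")),
    FeatureSpec(classes=("linear", "quadratic", "product")),
    FeatureSpec(classes=("hinge",)),
    FeatureSpec(classes=("linear", "quadratic", "product", "hinge")),
)
DEFAULT_BETA_GRID = (0.5, 1.0, 2.0, 4.0)


def tune(
    presence: CovariateMatrix,
    background: CovariateMatrix,
    spec_grid=DEFAULT_SPEC_GRID,
    beta_grid=DEFAULT_BETA_GRID,
    k: int = 5,
    seed: int = 0,
) -> TuningResult:
    """Cross-validated selection of the penalty and feature classes.

    Presences are split into k seeded folds; each (beta, spec) candidate is
    scored by the mean held-out AUC of fold-left-out fits against the full
    background.  Ties go to the first candidate in grid order; the winner
    is refit on all presences.
    """
    if presence.n < k:
        raise FoldError(f"{presence.n} presences cannot fill {k} folds")
    folds = random_folds(presence.cells, k=k, seed=seed)
    candidates = [(b, s) for s in spec_grid for b in beta_grid]
    scores = []
    for b, s in candidates:
        fold_scores = []
        for i in range(1, k + 1):
            tr = folds.fold != i
            te = ~tr
            if not te.any():
                raise FoldError(f"fold {i} has no presences")
            pm = CovariateMatrix(presence.cells[tr], presence.names, presence.values[tr])
            model = train_maxent(pm, background, spec=s, beta=b)
            held = CovariateMatrix(presence.cells[te], presence.names, presence.values[te])
            fold_scores.append(
                auc(predict(model, held), predict(model, background))
            )
        scores.append(float(np.mean(fold_scores)))
    best_i = int(np.argmax(scores))  # first max: tie rule
    b, s = candidates[best_i]
    final = train_maxent(presence, background, spec=s, beta=b)
    return TuningResult(grid=candidates, cv_scores=scores, best=(b, s), model=final)


def variable_contribution(
    model: MaxEntModel,
    presence: CovariateMatrix,
    background: CovariateMatrix,
    seed: int = 0,
    n_repeats: int = 3,
) -> dict[str, float]:
    """Permutation importance as percentages summing to 100.

    Each covariate column is shuffled jointly across the pooled presence +
    background rows; the drop in training-data AUC (averaged over
    ``n_repeats`` shuffles, floored at zero) is normalised across
    covariates.  If no covariate matters, attribution is uniform (with a
    warning).
    """
    rng = np.random.default_rng(seed)
    base = auc(predict(model, presence), predict(model, background))
    pooled = np.vstack([presence.values[:, [presence.names.index(n) for n in model.cov_names]],
                        background.values[:, [background.names.index(n) for n in model.cov_names]]])
    m = presence.n
    drops = np.zeros(len(model.cov_names))
    for j in range(len(model.cov_names)):
        for _ in range(n_repeats):
            perm = pooled.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            pm = CovariateMatrix(presence.cells, model.cov_names, perm[:m])
            bm = CovariateMatrix(background.cells, model.cov_names, perm[m:])
            drops[j] += base - auc(predict(model, pm), predict(model, bm))
        drops[j] /= n_repeats
    drops = np.maximum(drops, 0.0)
    total = drops.sum()
    if total == 0:
        log.warning("no covariate permutation changed AUC; uniform attribution")
        pct = np.full(len(model.cov_names), 100.0 / len(model.cov_names))
    else:
        pct = 100.0 * drops / total
    return {n: float(v) for n, v in zip(model.cov_names, pct)}
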