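"""Penalized maximum-entropy presence-background model.

The model is the Gibbs distribution over the background sample that
maximizes entropy subject to (L1-regularized) feature-mean constraints.
Equivalently, the coefficient vector lambda minimizes the convex objective

    J(lambda) = -(1/m) * sum_presences lambda . f(x_i)
                + log Z(lambda) + sum_j beta_j * |lambda_j|,

with Z(lambda) = sum_background exp(lambda . f(x)). "Raw" output is the
fitted Gibbs probability p(x) = exp(lambda . f(x)) / Z over the background
reference (sums to 1); "cloglog" output maps raw values to a [0, 1]
suitability index via 1 - exp(-e^H * p) with H the entropy of the fitted
raw distribution.

Features are restricted to linear and quadratic transforms of min-max
scaled covariates plus one-hot categorical indicators — feature classes
"L", "Q", and "LQ". Per-feature penalties beta_j default to the classic
sample-size-dependent rule (a tuning constant tau interpolated log-linearly
in the presence count, times sqrt(var_j / m)), all scaled by a single
regularization multiplier (RM).

The solver is FISTA (accelerated proximal gradient with backtracking and
adaptive restart); convergence is declared when the maximum KKT violation
of the L1-stationarity conditions drops below ``tol``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax

FEATURE_CLASSES = ("L", "Q", "LQ")

#: tau interpolation tables: (presence count, tau). Log-linear in m,
#: clamped at the endpoints. Continuous features share one table;
#: categorical indicators another.
TAU_CONTINUOUS = ((10.0, 1.0), (30.0, 0.2), (100.0, 0.05))
TAU_CATEGORICAL = ((10.0, 0.25), (17.0, 0.05))

VARIANCE_FLOOR = 1e-4


def _interp_tau(m: float, table) -> float:
    ms = np.log(np.array([row[0] for row in table]))
    taus = np.array([row[1] for row in table])
    return float(np.interp(np.log(max(m, 1.0)), ms, taus))


@dataclass(frozen=True)
class FeatureExpansion:
    """Deterministic covariates -> feature-vector mapping.

    Continuous variables are scaled to [0, 1] using the background min/max
    (prediction-time values are clamped into the range; novel conditions
    are handled separately by the similarity mask). Class "L" emits the
    scaled value, "Q" its square, "LQ" both. Categorical variables emit
    one indicator per declared level; an unseen level at prediction time
    yields all-zero indicators with a warning.
    """

    feature_class: str
    continuous: tuple = ()  # ((name, lo, hi), ...)
    categorical: tuple = ()  # ((name, (levels...)), ...)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        for name, lo, hi in self.continuous:
            if not hi > lo:
                raise ValueError(f"variable {name!r}: max must exceed min")

    @classmethod
    def from_background(
        cls, background_values: dict, feature_class: str, categorical: dict | None = None
    ) -> "FeatureExpansion":
        """Build an expansion from background variable values; categorical
        maps variable name -> level tuple."""
        categorical = categorical or {}
        cont = []
        for name, vals in background_values.items():
            if name in categorical:
                continue
            vals = np.asarray(vals, dtype=float)
            ok = np.isfinite(vals)
            lo, hi = float(vals[ok].min()), float(vals[ok].max())
            if hi == lo:
                hi = lo + 1e-9  # degenerate variable contributes a constant
            cont.append((name, lo, hi))
        cat = tuple(
            (name, tuple(float(v) for v in levels))
            for name, levels in categorical.items()
        )
        return cls(feature_class=feature_class, continuous=tuple(cont), categorical=cat)

    @property
    def feature_names(self) -> list[str]:
        names = []
        for name, _, _ in self.continuous:
            if self.feature_class in ("L", "LQ"):
                names.append(name)
            if self.feature_class in ("Q", "LQ"):
                names.append(f"{name}^2")
        for name, levels in self.categorical:
            names.extend(f"{name}=={lvl:g}" for lvl in levels)
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def is_categorical_feature(self) -> np.ndarray:
        per_cont = {"L": 1, "Q": 1, "LQ": 2}[self.feature_class]
        flags = [False] * (per_cont * len(self.continuous))
        for _, levels in self.categorical:
            flags.extend([True] * len(levels))
        return np.array(flags, dtype=bool)

    def transform(self, values: dict) -> np.ndarray:
        """Map per-variable value arrays to the (n, d) feature matrix."""
        cols = []
        n = None
        for name, lo, hi in self.continuous:
            v = np.asarray(values[name], dtype=float)
            n = len(v)
            s = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
            if self.feature_class in ("L", "LQ"):
                cols.append(s)
            if self.feature_class in ("Q", "LQ"):
                cols.append(s**2)
        for name, levels in self.categorical:
            v = np.asarray(values[name], dtype=float)
            n = len(v)
            seen = np.isin(v[np.isfinite(v)], levels)
            if not seen.all():
                warnings.warn(
                    f"variable {name!r}: levels unseen at training time; "
                    "their indicators are all-zero",
                    stacklevel=2,
                )
            for lvl in levels:
                cols.append((v == lvl).astype(float))
        if not cols:
            return np.zeros((n if n is not None else 0, 0))
        return np.column_stack(cols)


def default_beta(
    expansion: FeatureExpansion,
    n_presence: int,
    rm: float,
    presence_features: np.ndarray,
) -> np.ndarray:
    """Per-feature L1 penalties: beta_j = rm * tau(class, m) * sqrt(v_j/m),
    with v_j the feature variance over presences floored at 1e-4."""
    if n_presence < 1 or rm <= 0:
        raise ValueError("need n_presence >= 1 and rm > 0")
    m = float(n_presence)
    is_cat = expansion.is_categorical_feature()
    tau_cont = _interp_tau(m, TAU_CONTINUOUS)
    tau_cat = _interp_tau(m, TAU_CATEGORICAL)
    tau = np.where(is_cat, tau_cat, tau_cont)
    if presence_features.shape[1] != expansion.n_features:
        raise ValueError("presence feature matrix does not match expansion")
    var = presence_features.var(axis=0) if len(presence_features) else np.zeros(
        expansion.n_features
    )
    var = np.maximum(var, VARIANCE_FLOOR)
    return rm * tau * np.sqrt(var / m)


@dataclass
class MaxEntModel:
    """A fitted model: coefficients, penalties, expansion, and the entropy
    and normalizer of the raw distribution over the training background."""

    expansion: FeatureExpansion
    lam: np.ndarray
    beta: np.ndarray
    rm: float
    n_presence: int
    entropy: float
    log_z: float
    converged: bool = True
    n_iter: int = 0

    @property
    def feature_class(self) -> str:
        return self.expansion.feature_class

    def to_json(self) -> str:
        doc = {
            "feature_class": self.expansion.feature_class,
            "continuous": [list(c) for c in self.expansion.continuous],
            "categorical": [[n, list(l)] for n, l in self.expansion.categorical],
            "lambda": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "rm": self.rm,
            "n_presence": self.n_presence,
            "entropy": self.entropy,
            "log_z": self.log_z,
            "converged": self.converged,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        doc = json.loads(text)
        expansion = FeatureExpansion(
            feature_class=doc["feature_class"],
            continuous=tuple((n, lo, hi) for n, lo, hi in doc["continuous"]),
            categorical=tuple((n, tuple(l)) for n, l in doc["categorical"]),
        )
        return cls(
            expansion=expansion,
            lam=np.array(doc["lambda"]),
            beta=np.array(doc["beta"]),
            rm=doc["rm"],
            n_presence=doc["n_presence"],
            entropy=doc["entropy"],
            log_z=doc["log_z"],
            converged=doc["converged"],
        )


def objective(
    lam: np.ndarray,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    beta: np.ndarray,
) -> float:
    """The penalized negative log-likelihood J(lambda)."""
    emp = presence_features.mean(axis=0) if len(presence_features) else lam * 0
    return float(
        -emp @ lam
        + logsumexp(background_features @ lam)
        + np.abs(lam) @ beta
    )


def kkt_violation(
    lam: np.ndarray, grad: np.ndarray, beta: np.ndarray
) -> float:
    """Max violation of the L1 stationarity conditions at lambda."""
    if lam.size == 0:
        return 0.0
    at_zero = lam == 0
    viol = np.abs(grad + np.sign(lam) * beta)
    viol[at_zero] = np.maximum(np.abs(grad[at_zero]) - beta[at_zero], 0.0)
    return float(viol.max())


def _soft_threshold(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    expansion: FeatureExpansion,
    rm: float = 1.0,
    beta: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 20_000,
) -> MaxEntModel:
    """Fit the L1-penalized maxent model by FISTA.

    ``beta`` overrides the default penalty vector (useful for closed-form
    checks); otherwise penalties come from :func:`default_beta` with the
    given regularization multiplier. Non-convergence at ``max_iter``
    returns the best iterate flagged ``converged=False``.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    if len(P) < 1 or len(B) < 2:
        raise ValueError("need >= 1 presence and >= 2 background rows")
    d = expansion.n_features
    if P.shape[1] != d or B.shape[1] != d:
        raise ValueError("feature matrices do not match the expansion")
    if beta is None:
        beta = default_beta(expansion, len(P), rm, P)
    beta = np.asarray(beta, dtype=float)

    if d == 0:
        # no constraints: the maximum-entropy solution is uniform
        n = len(B)
        return MaxEntModel(
            expansion=expansion,
            lam=np.zeros(0),
            beta=beta,
            rm=rm,
            n_presence=len(P),
            entropy=float(np.log(n)),
            log_z=float(np.log(n)),
            converged=True,
            n_iter=0,
        )

    emp = P.mean(axis=0)

    def smooth_val_grad(lam):
        eta = B @ lam
        lse = logsumexp(eta)
        p = np.exp(eta - lse)
        return float(-emp @ lam + lse), p @ B - emp

    lam = np.zeros(d)
    y = lam.copy()
    t_k = 1.0
    L = 1.0
    best_lam, best_obj = lam.copy(), objective(lam, P, B, beta)
    converged = False
    n_iter = 0
    fy, gy = smooth_val_grad(y)

    for n_iter in range(1, max_iter + 1):
        # backtracking proximal step from the momentum point y
        while True:
            cand = _soft_threshold(y - gy / L, beta / L)
            diff = cand - y
            f_cand, g_cand = smooth_val_grad(cand)
            if f_cand <= fy + gy @ diff + 0.5 * L * (diff @ diff) + 1e-14:
                break
            L *= 2.0
        obj = f_cand + np.abs(cand) @ beta
        if obj < best_obj:
            best_obj, best_lam = obj, cand.copy()

        if kkt_violation(cand, g_cand, beta) < tol:
            lam = cand
            converged = True
            break

        # momentum with gradient-based adaptive restart
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k * t_k))
        momentum = (t_k - 1.0) / t_next
        if (y - cand) @ (cand - lam) > 0:
            t_next, momentum = 1.0, 0.0  # restart
        y = cand + momentum * (cand - lam)
        lam, t_k = cand, t_next
        fy, gy = smooth_val_grad(y)
        L *= 0.95  # allow the step size to grow again

    if not converged:
        lam = best_lam
        warnings.warn(
            f"maxent fit did not reach tol={tol} in {max_iter} iterations",
            stacklevel=2,
        )

    eta = B @ lam
    log_z = float(logsumexp(eta))
    p = np.exp(eta - log_z)
    entropy = float(-(p * np.log(np.clip(p, 1e-300, None))).sum())
    return MaxEntModel(
        expansion=expansion,
        lam=lam,
        beta=beta,
        rm=rm,
        n_presence=len(P),
        entropy=entropy,
        log_z=log_z,
        converged=converged,
        n_iter=n_iter,
    )


def fit_maxent_values(
    presence_values: dict,
    background_values: dict,
    feature_class: str = "LQ",
    categorical: dict | None = None,
    rm: float = 1.0,
    **kw,
) -> MaxEntModel:
    """Convenience wrapper: build the expansion from background values,
    expand both samples identically, and fit."""
    expansion = FeatureExpansion.from_background(
        background_values, feature_class, categorical
    )
    P = expansion.transform(presence_values)
    B = expansion.transform(background_values)
    return fit_maxent(P, B, expansion, rm=rm, **kw)


def predict_raw(model: MaxEntModel, features: np.ndarray) -> np.ndarray:
    """Gibbs probabilities relative to the model's background normalizer;
    over the training background rows these sum to 1."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.expansion.n_features:
        raise ValueError("feature matrix does not match the model expansion")
    if model.expansion.n_features == 0:
        return np.full(len(features), np.exp(-model.log_z))
    return np.exp(features @ model.lam - model.log_z)


def predict_raw_values(model: MaxEntModel, values: dict) -> np.ndarray:
    return predict_raw(model, model.expansion.transform(values))


def predict_cloglog(model: MaxEntModel, features: np.ndarray) -> np.ndarray:
    """Complementary log-log suitability 1 - exp(-e^H * p_raw) in [0, 1];
    strictly increasing in the raw output."""
    p = predict_raw(model, features)
    return 1.0 - np.exp(-np.exp(model.entropy) * p)


def predict_cloglog_values(model: MaxEntModel, values: dict) -> np.ndarray:
    return predict_cloglog(model, model.expansion.transform(values))
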