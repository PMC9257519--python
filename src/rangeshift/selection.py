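"""Cross-validated tuning over the RM × feature-class grid.

Candidate models span regularization multipliers 0.5–5.0 in steps of 0.5
and feature classes L, Q, LQ (30 candidates). Each candidate is scored by
k-fold cross-validation on the presences (background shared across folds):
test AUC against the background sample measures discrimination, and the
10% training omission rate (OR10) measures overfitting — the fraction of
test presences scoring strictly below the threshold that omits the
lowest-scoring 10% of training presences. Selection is two-step: keep
candidates with mean OR10 < 0.10, then pick the highest mean AUC among
them (ties broken toward lower RM, then the simpler feature class); if no
candidate passes the omission filter, fall back to the minimum-OR10
candidate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .maxent import (
    FeatureExpansion,
    MaxEntModel,
    fit_maxent,
)

logger = logging.getLogger(__name__)

DEFAULT_RM_GRID = tuple(0.5 * i for i in range(1, 11))
DEFAULT_FEATURE_CLASSES = ("L", "Q", "LQ")
_CLASS_SIMPLICITY = {"L": 0, "Q": 1, "LQ": 2}


@dataclass(frozen=True)
class CandidateConfig:
    rm: float
    feature_class: str


def default_grid(
    rms=DEFAULT_RM_GRID, feature_classes=DEFAULT_FEATURE_CLASSES
) -> list[CandidateConfig]:
    """The full tuning grid (30 candidates at the defaults)."""
    return [
        CandidateConfig(rm=float(rm), feature_class=fc)
        for rm, fc in itertools.product(rms, feature_classes)
    ]


@dataclass
class CandidateScore:
    config: CandidateConfig
    fold_auc: list = field(default_factory=list)
    fold_or10: list = field(default_factory=list)
    any_nonconverged: bool = False

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_or10(self) -> float:
        return float(np.mean(self.fold_or10))


@dataclass
class TuningResult:
    scores: list
    selected: CandidateConfig
    model: MaxEntModel
    fallback_used: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rm": s.config.rm,
                "feature_class": s.config.feature_class,
                "mean_auc": s.mean_auc,
                "mean_or10": s.mean_or10,
                "selected": s.config == self.selected,
            }
            for s in self.scores
        ]
        return pd.DataFrame(rows)


def make_folds(n_presences: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of presences into k near-equal folds (fold id per
    presence); deterministic given the seed."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n_presences < k:
        raise ValueError("fewer presences than folds")
    rng = np.random.default_rng(seed)
    folds = np.arange(n_presences) % k
    rng.shuffle(folds)
    return folds


def auc_rank(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos == neg)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def p10_threshold(train_scores) -> float:
    """The (floor(0.1*m) + 1)-th smallest training score — the threshold
    that omits the lowest-scoring 10% of training presences."""
    train = np.sort(np.asarray(train_scores, dtype=float))
    m = len(train)
    if m == 0:
        raise ValueError("empty training scores")
    return float(train[int(np.floor(0.1 * m))])


def omission_rate_10(train_pos_scores, test_pos_scores) -> float:
    """OR10: fraction of test presences scoring strictly below the 10%
    training-omission threshold."""
    test = np.asarray(test_pos_scores, dtype=float)
    if len(test) == 0:
        raise ValueError("empty test scores")
    m = len(np.asarray(train_pos_scores))
    if m < 10:
        logger.warning("OR10 with fewer than 10 training scores (m=%d)", m)
    t = p10_threshold(train_pos_scores)
    return float(np.mean(test < t))


def evaluate_candidate(
    config: CandidateConfig,
    presence_values: dict,
    background_values: dict,
    folds: np.ndarray,
    categorical: dict | None = None,
    tol: float = 1e-6,
    max_iter: int = 20_000,
) -> CandidateScore:
    """Score one (RM, feature class) candidate by cross-validation.

    Per fold: fit on the training presences plus the full background,
    score with raw predictions, and record AUC (test presences vs
    background) and OR10 (train vs test presences). Raw and cloglog give
    identical AUC (monotone transform); raw is used so OR10 thresholds
    are reproducible.
    """
    expansion = FeatureExpansion.from_background(
        background_values, config.feature_class, categorical
    )
    P = expansion.transform(presence_values)
    B = expansion.transform(background_values)
    score = CandidateScore(config=config)
    for fold in np.unique(folds):
        train, test = P[folds != fold], P[folds == fold]
        model = fit_maxent(
            train, B, expansion, rm=config.rm, tol=tol, max_iter=max_iter
        )
        if not model.converged:
            score.any_nonconverged = True
        # raw scores: exp(lambda . f) up to the shared normalizer
        s_train = train @ model.lam
        s_test = test @ model.lam
        s_bg = B @ model.lam
        score.fold_auc.append(auc_rank(np.exp(s_test), np.exp(s_bg)))
        score.fold_or10.append(omission_rate_10(np.exp(s_train), np.exp(s_test)))
    return score


def select_best(scores) -> tuple[CandidateScore, bool]:
    """The two-step selection rule.

    Candidates with mean OR10 < 0.10 are eligible; among them the highest
    mean AUC wins, ties broken toward lower RM, then the simpler feature
    class (L < Q < LQ). With no eligible candidate the minimum-OR10
    candidate is selected instead (returned flag True)."""
    scores = list(scores)
    if not scores:
        raise ValueError("no candidate scores")

    def tie_key(s: CandidateScore):
        return (-s.mean_auc, s.config.rm, _CLASS_SIMPLICITY[s.config.feature_class])

    eligible = [s for s in scores if s.mean_or10 < 0.10]
    if eligible:
        return min(eligible, key=tie_key), False
    logger.warning("no candidate with OR10 < 0.10; falling back to min OR10")
    return min(scores, key=lambda s: (s.mean_or10, tie_key(s))), True


def tune_and_select(
    presence_values: dict,
    background_values: dict,
    grid=None,
    categorical: dict | None = None,
    k: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 20_000,
) -> TuningResult:
    """Evaluate the whole grid, apply the two-step OR10/AUC rule, and
    refit the selected configuration on all presences."""
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty tuning grid")
    n = len(next(iter(presence_values.values())))
    folds = make_folds(n, k=k, seed=seed)
    scores = [
        evaluate_candidate(
            cfg, presence_values, background_values, folds,
            categorical=categorical, tol=tol, max_iter=max_iter,
        )
        for cfg in grid
    ]
    best, fallback = select_best(scores)


    expansion = FeatureExpansion.from_background(
        background_values, best.config.feature_class, categorical
    )
    model = fit_maxent(
        expansion.transform(presence_values),
        expansion.transform(background_values),
        expansion,
        rm=best.config.rm,
        tol=tol,
        max_iter=max_iter,
    )
    return TuningResult(
        scores=scores, selected=best.config, model=model, fallback_used=fallback
    )
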