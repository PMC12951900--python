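"""Protein-panel selection: gradient-boosting importance ranking followed by
sequential forward selection with a DeLong/epsilon plateau stopping rule.

A preliminary boosted-tree classifier is trained once on all Bonferroni-
significant candidates (protein features only) and its total split-gain
importances order the candidates.  Proteins are then added one at a time to
an empty classifier in importance order; after each addition the cumulative
AUC is computed (out-of-fold within the derivation set by default, because
in-sample AUC of a boosted tree is near 1 and would defeat the rule).  A step
counts as an improvement only when its gain over the best-so-far AUC is both
material (>= ``auc_epsilon``) and DeLong-significant; selection stops after
``plateau_length`` consecutive non-improvements and the panel is the
best-so-far prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lightgbm as lgb
import numpy as np
from sklearn.model_selection import StratifiedKFold

from .metrics import auc, delong_compare


@dataclass
class GBMParams:
    """Boosted-tree hyperparameters (conservative, stability-oriented).

    ``min_child_samples`` is deliberately large: with only a handful of
    features a lightly-constrained booster memorizes feature quantiles,
    which depresses out-of-fold AUC at small panel sizes and destabilizes
    the forward-selection trace.
    """

    n_estimators: int = 200
    num_leaves: int = 8
    max_depth: int = 3
    learning_rate: float = 0.05
    min_child_samples: int = 200
    seed: int = 0

    def lgb_params(self) -> dict:
        return {
            "objective": "binary",
            "n_estimators": self.n_estimators,
            "num_leaves": self.num_leaves,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "min_child_samples": self.min_child_samples,
            "random_state": self.seed,
            "deterministic": True,
            "force_row_wise": True,
            "n_jobs": 1,
            "verbosity": -1,
        }


@dataclass
class SelectionConfig:
    auc_epsilon: float = 0.003
    plateau_length: int = 4
    delong_alpha: float = 0.05
    gbm_params: GBMParams = field(default_factory=GBMParams)
    eval_scheme: str = "derivation_cv"  # or "in_sample"
    cv_folds: int = 5
    #: compare each step against the best-so-far panel (default) or the
    #: immediately preceding step
    baseline: str = "best_so_far"  # or "previous"

    def __post_init__(self) -> None:
        if self.auc_epsilon <= 0:
            raise ValueError("auc_epsilon must be > 0")
        if self.plateau_length < 1:
            raise ValueError("plateau_length must be >= 1")
        if self.eval_scheme not in ("derivation_cv", "in_sample"):
            raise ValueError(f"unknown eval_scheme {self.eval_scheme!r}")
        if self.baseline not in ("best_so_far", "previous"):
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if isinstance(self.gbm_params, dict):
            self.gbm_params = GBMParams(**self.gbm_params)


@dataclass
class PanelResult:
    """Outcome of importance ranking plus forward selection."""

    candidates: list[str]
    importance_scores: list[float]
    cumulative_auc: list[float]
    stop_index: int
    selected_panel: list[str]
    subgroup: Optional[str] = None
    plateau_reached: bool = True

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "importance_scores": self.importance_scores,
            "cumulative_auc": self.cumulative_auc,
            "stop_index": self.stop_index,
            "selected_panel": self.selected_panel,
            "subgroup": self.subgroup,
            "plateau_reached": self.plateau_reached,
        }


def train_classifier(X: np.ndarray, y: np.ndarray, params: GBMParams
                     ) -> lgb.LGBMClassifier:
    """One deterministic boosted-tree classifier; missing values handled
    natively by the trees."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")
    lgb_params = params.lgb_params()
    # keep the leaf-size floor proportionate on small training sets, else
    # the trees cannot split at all and predictions collapse to a constant
    lgb_params["min_child_samples"] = min(params.min_child_samples,
                                          max(20, len(y) // 20))
    clf = lgb.LGBMClassifier(**lgb_params)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def predict_risk(clf: lgb.LGBMClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted event probability.

    Goes through the underlying booster: lightgbm invents "Column_i" feature
    names even for array input, which would otherwise trip scikit-learn's
    feature-name validation on every predict.
    """
    return np.asarray(clf.booster_.predict(np.asarray(X, dtype=float)))


def rank_importance(X: np.ndarray, y: np.ndarray,
                    candidates: Sequence[str],
                    params: Optional[GBMParams] = None
                    ) -> tuple[list[str], list[float]]:
    """Order candidate proteins by total split-gain importance (descending).

    One classifier is trained on all candidates together; ties in gain are
    broken by candidate position for determinism.
    """
    params = params or GBMParams()
    candidates = list(candidates)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(candidates):
        raise ValueError("X columns must match candidates")
    if len(candidates) == 0:
        raise ValueError("need at least one candidate")
    if len(candidates) == 1:
        return candidates, [1.0]
    clf = train_classifier(X, y, params)
    gain = clf.booster_.feature_importance(importance_type="gain")
    order = np.lexsort((np.arange(len(candidates)), -gain))
    return [candidates[i] for i in order], [float(gain[i]) for i in order]


def _cv_scores(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig
               ) -> np.ndarray:
    """Out-of-fold predicted probabilities (stratified K-fold)."""
    oof = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.gbm_params.seed)
    for tr, te in skf.split(X, y):
        clf = train_classifier(X[tr], y[tr], cfg.gbm_params)
        oof[te] = predict_risk(clf, X[te])
    return oof


def forward_select(X: np.ndarray, y: np.ndarray,
                   ordered_candidates: Sequence[str],
                   config: Optional[SelectionConfig] = None,
                   subgroup: Optional[str] = None,
                   importance_scores: Optional[Sequence[float]] = None
                   ) -> PanelResult:
    """Sequential forward selection over importance-ordered candidates.

    ``X`` columns must be aligned with ``ordered_candidates``.  Step ``k``
    evaluates the top-``k`` prefix; an improvement requires a gain over the
    baseline AUC of at least ``auc_epsilon`` that is also DeLong-significant
    at ``delong_alpha``.
    If the candidate list is exhausted before the plateau triggers, all
    candidates are returned with ``plateau_reached=False``.
    """
    cfg = config or SelectionConfig()
    ordered_candidates = list(ordered_candidates)
    if not ordered_candidates:
        raise ValueError("ordered_candidates is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)

    def eval_prefix(k: int) -> np.ndarray:
        Xk = X[:, :k]
        if cfg.eval_scheme == "derivation_cv":
            return _cv_scores(Xk, y, cfg)
        clf = train_classifier(Xk, y, cfg.gbm_params)
        return predict_risk(clf, Xk)

    trace: list[float] = []
    best_auc = -np.inf
    best_scores: Optional[np.ndarray] = None
    base_auc = -np.inf
    base_scores: Optional[np.ndarray] = None
    best_k = 1
    run = 0
    plateau = False
    for k in range(1, len(ordered_candidates) + 1):
        scores = eval_prefix(k)
        a = auc(scores, y)
        trace.append(a)
        if k == 1:
            best_auc, best_scores, best_k = a, scores, 1
            base_auc, base_scores = a, scores
        else:
            gain = a - base_auc
            cmp = delong_compare(base_scores, scores, y)
            # an improvement must be both material (>= epsilon) and
            # DeLong-significant; anything else counts toward the plateau
            improved = gain >= cfg.auc_epsilon and cmp.p < cfg.delong_alpha
            if improved:
                run = 0
                best_auc, best_scores, best_k = a, scores, k
            else:
                run += 1
            if cfg.baseline == "previous":
                base_auc, base_scores = a, scores
            else:
                base_auc, base_scores = best_auc, best_scores
            if run >= cfg.plateau_length:
                plateau = True
                break
    if not plateau:
        warnings.warn("candidates exhausted before the plateau rule "
                      "triggered; returning all candidates", stacklevel=2)
        return PanelResult(
            candidates=ordered_candidates,
            importance_scores=list(importance_scores or []),
            cumulative_auc=trace, stop_index=len(ordered_candidates),
            selected_panel=ordered_candidates, subgroup=subgroup,
            plateau_reached=False,
        )
    return PanelResult(
        candidates=ordered_candidates,
        importance_scores=list(importance_scores or []),
        cumulative_auc=trace, stop_index=best_k,
        selected_panel=ordered_candidates[:best_k], subgroup=subgroup,
        plateau_reached=True,
    )


def select_panel(X: np.ndarray, y: np.ndarray, candidates: Sequence[str],
                 config: Optional[SelectionConfig] = None,
                 subgroup: Optional[str] = None) -> PanelResult:
    """rank_importance followed by forward_select on the ranked order."""
    cfg = config or SelectionConfig()
    ranked, scores = rank_importance(X, y, candidates, cfg.gbm_params)
    cols = [list(candidates).index(c) for c in ranked]
    return forward_select(np.asarray(X, dtype=float)[:, cols], y, ranked,
                          cfg, subgroup=subgroup, importance_scores=scores)
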