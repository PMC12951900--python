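"""Evaluation statistics: ROC/AUC, the DeLong test for paired AUCs,
time-horizon dynamic AUC, categorical net reclassification improvement with
bootstrap inference, Harrell bootstrap optimism correction, leave-one-region-
out cross-validation, and pairwise Z-tests on log hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.min() < 0 or labels.max() > 1:
        raise ValueError("labels must be 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC estimate; ties count 1/2."""
    labels = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    r = rankdata(scores)
    m = int(labels.sum())
    n = len(labels) - m
    return float((r[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


@dataclass
class RocComparison:
    """DeLong comparison of two correlated AUCs on the same labels."""

    auc_a: float
    auc_b: float
    delta: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    degenerate: bool = False


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the structural components V10 (cases) and V01 (controls)."""
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    m, n = len(cases), len(ctrls)
    all_r = rankdata(np.concatenate([cases, ctrls]))
    case_r = rankdata(cases)
    ctrl_r = rankdata(ctrls)
    v10 = (all_r[:m] - case_r) / n
    v01 = 1.0 - (all_r[m:] - ctrl_r) / m
    a = float((all_r[:m].sum() - m * (m + 1) / 2) / (m * n))
    return a, v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, variance of the AUC) by the DeLong structural-component method."""
    labels = _check_labels(np.asarray(labels))
    a, v10, v01 = _delong_components(np.asarray(scores, dtype=float), labels)
    m, n = len(v10), len(v01)
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return a, var


def delong_compare(scores_a, scores_b, labels) -> RocComparison:
    """Two-sided DeLong test of AUC(b) - AUC(a) on paired scores."""
    labels = _check_labels(np.asarray(labels))
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != labels.shape[0]:
        raise ValueError("paired scores must align with labels")
    aa, va10, va01 = _delong_components(sa, labels)
    ab, vb10, vb01 = _delong_components(sb, labels)
    m, n = len(va10), len(va01)
    var_a = float(np.var(va10, ddof=1) / m + np.var(va01, ddof=1) / n)
    var_b = float(np.var(vb10, ddof=1) / m + np.var(vb01, ddof=1) / n)
    cov = float(np.cov(va10, vb10, ddof=1)[0, 1] / m
                + np.cov(va01, vb01, ddof=1)[0, 1] / n)
    delta = ab - aa
    var_delta = var_a + var_b - 2.0 * cov
    if var_delta <= 1e-16:
        return RocComparison(aa, ab, delta, var_a, var_b, cov,
                             z=0.0, p=1.0, degenerate=True)
    z = delta / np.sqrt(var_delta)
    return RocComparison(aa, ab, float(delta), var_a, var_b, cov,
                         z=float(z), p=float(2 * norm.sf(abs(z))))


def dynamic_auc(scores, time, event, horizons: Sequence[float]
                ) -> pd.DataFrame:
    """AUC per prediction horizon.

    At horizon ``t``: cases are subjects with an event by ``t``; controls are
    subjects still under observation at ``t`` without an event (follow-up
    >= t); subjects censored before ``t`` without an event are excluded.
    Horizons with a missing class yield NaN.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    rows = []
    for t in horizons:
        case = (event == 1) & (time <= t)
        ctrl = (time >= t) & ~((event == 1) & (time <= t))
        use = case | ctrl
        n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
        if n_case == 0 or n_ctrl == 0:
            rows.append((t, np.nan, n_case, n_ctrl))
            continue
        rows.append((t, auc(scores[use], case[use].astype(int)),
                     n_case, n_ctrl))
    return pd.DataFrame(rows, columns=["horizon", "auc", "n_cases",
                                       "n_controls"])


@dataclass
class ReclassResult:
    """Categorical NRI of a new risk model against an old one."""

    threshold: float
    counts: dict
    nri_overall: float
    nri_event: float
    nri_nonevent: float
    ci95: dict
    p: dict
    n_boot: int
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "counts": self.counts,
            "nri_overall": self.nri_overall, "nri_event": self.nri_event,
            "nri_nonevent": self.nri_nonevent,
            "ci95": self.ci95, "p": self.p, "n_boot": self.n_boot,
            "n_events": self.n_events, "n_nonevents": self.n_nonevents,
        }


def _movement_counts(old_cat, new_cat, labels) -> dict:
    out = {}
    for cls, mask in (("event", labels == 1), ("nonevent", labels == 0)):
        tab = np.zeros((2, 2), dtype=int)
        for o in (0, 1):
            for nw in (0, 1):
                tab[o, nw] = int(np.sum(mask & (old_cat == o) & (new_cat == nw)))
        out[cls] = tab.tolist()
    return out


def categorical_nri(risk_old, risk_new, labels, threshold: float,
                    n_boot: int = 1000, seed: int = 0) -> ReclassResult:
    """Two-category NRI at a single risk threshold.

    nri_event = (ups - downs) / n_events among events;
    nri_nonevent = (downs - ups) / n_nonevents among non-events;
    nri_overall = nri_event + nri_nonevent (an identity on the same sample).
    95% CIs are percentile bootstrap over participants; p-values use the
    normal approximation with the bootstrap SE.
    """
    risk_old = np.asarray(risk_old, dtype=float)
    risk_new = np.asarray(risk_new, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if np.nanmin(risk_old) < 0 or np.nanmax(risk_old) > 1 \
            or np.nanmin(risk_new) < 0 or np.nanmax(risk_new) > 1:
        raise ValueError("risks must lie in [0, 1]")
    old_cat = (risk_old >= threshold).astype(int)
    new_cat = (risk_new >= threshold).astype(int)
    move = new_cat - old_cat  # +1 up, -1 down, 0 unchanged
    ev = labels == 1
    n_e = int(ev.sum())
    n_ne = len(labels) - n_e
    nri_e = float(move[ev].sum() / n_e)
    nri_ne = float(-move[~ev].sum() / n_ne)
    nri = nri_e + nri_ne

    rng = np.random.default_rng(seed)
    n = len(labels)
    boot_e = np.empty(n_boot)
    boot_ne = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(5e6 / max(n, 1)) or 1))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(k, n))
        L = labels[idx]
        M = move[idx]
        se_ = L.sum(axis=1)
        sne = n - se_
        with np.errstate(invalid="ignore", divide="ignore"):
            be = np.where(se_ > 0, (M * L).sum(axis=1) / se_, np.nan)
            bne = np.where(sne > 0, -(M * (1 - L)).sum(axis=1) / sne, np.nan)
        boot_e[done:done + k] = be
        boot_ne[done:done + k] = bne
        done += k
    ok = ~(np.isnan(boot_e) | np.isnan(boot_ne))
    if not ok.all():
        warnings.warn(f"dropped {int((~ok).sum())} degenerate bootstrap "
                      "resamples (single class)", stacklevel=2)
    boot_e, boot_ne = boot_e[ok], boot_ne[ok]
    boot_all = boot_e + boot_ne

    def _ci_p(stat: float, boot: np.ndarray) -> tuple[list[float], float]:
        if len(boot) < 2:
            return [float("nan"), float("nan")], float("nan")
        lo, hi = np.percentile(boot, [2.5, 97.5])
        se_b = boot.std(ddof=1)
        if se_b == 0:
            return [float(lo), float(hi)], 1.0 if stat == 0 else 0.0
        z = stat / se_b
        return [float(lo), float(hi)], float(2 * norm.sf(abs(z)))

    ci, pv = {}, {}
    for key, stat, boot in (("overall", nri, boot_all),
                            ("event", nri_e, boot_e),
                            ("nonevent", nri_ne, boot_ne)):
        ci[key], pv[key] = _ci_p(stat, boot)

    return ReclassResult(
        threshold=float(threshold),
        counts=_movement_counts(old_cat, new_cat, labels),
        nri_overall=nri, nri_event=nri_e, nri_nonevent=nri_ne,
        ci95=ci, p=pv, n_boot=int(ok.sum()),
        n_events=n_e, n_nonevents=n_ne,
    )


def calibrate_risks(risk_fit, labels_fit, risk_apply) -> np.ndarray:
    """Logistic recalibration: intercept + slope on the logit of predicted risk.

    The recalibration map is fitted on (``risk_fit``, ``labels_fit``) —
    normally derivation-set predictions — and applied to ``risk_apply``.
    """
    from sklearn.linear_model import LogisticRegression

    def _logit(r):
        r = np.clip(np.asarray(r, dtype=float), 1e-12, 1 - 1e-12)
        return np.log(r / (1 - r))

    lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    lr.fit(_logit(risk_fit)[:, None], np.asarray(labels_fit).astype(int))
    return lr.predict_proba(_logit(risk_apply)[:, None])[:, 1]


FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
"""Modeling recipe: (X_train, y_train, X_eval) -> scores for X_eval."""


def optimism_corrected_auc(X, y, fit_predict: FitPredict,
                           n_boot: int = 500, seed: int = 0) -> dict:
    """Harrell bootstrap optimism correction of the apparent AUC.

    For each resample: refit, measure AUC on the resample (boot-apparent) and
    on the original sample (boot-original); optimism is their difference and
    the corrected AUC is apparent minus mean optimism.  Single-class
    resamples are redrawn (logged).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(np.asarray(y))
    if n_boot < 2:
        warnings.warn("n_boot < 2: optimism estimate is unstable",
                      stacklevel=2)
    apparent = auc(fit_predict(X, y, X), y)
    rng = np.random.default_rng(seed)
    n = len(y)
    optimism = []
    redraws = 0
    while len(optimism) < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.sum() in (0, n):
            redraws += 1
            continue
        Xb = X[idx]
        sb = fit_predict(Xb, yb, Xb)
        so = fit_predict(Xb, yb, X)
        optimism.append(auc(sb, yb) - auc(so, y))
    if redraws:
        warnings.warn(f"redrew {redraws} single-class bootstrap resamples",
                      stacklevel=2)
    optimism = np.asarray(optimism)
    return {
        "apparent_auc": float(apparent),
        "mean_optimism": float(optimism.mean()),
        "corrected_auc": float(apparent - optimism.mean()),
        "optimism_per_resample": optimism.tolist(),
        "n_boot": int(n_boot),
    }


def region_cv(X, y, regions, fit_predict: FitPredict) -> dict:
    """Leave-one-region-out cross-validation.

    Trains on all-but-one region, evaluates AUC on the held-out region;
    regions whose test fold has a single class are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    regions = np.asarray(regions)
    uniq = np.unique(regions)
    if len(uniq) < 2:
        raise ValueError("need at least 2 regions")
    fold_auc = {}
    for r in uniq:
        test = regions == r
        y_te = y[test]
        y_tr = y[~test]
        if y_te.sum() in (0, len(y_te)):
            warnings.warn(f"region {r!r} skipped: single-class test fold",
                          stacklevel=2)
            continue
        if y_tr.sum() in (0, len(y_tr)):
            warnings.warn(f"region {r!r} skipped: single-class training set",
                          stacklevel=2)
            continue
        scores = fit_predict(X[~test], y[~test], X[test])
        fold_auc[str(r)] = auc(scores, y_te)
    vals = np.array(list(fold_auc.values()))
    return {
        "fold_auc": fold_auc,
        "mean_auc": float(vals.mean()) if len(vals) else float("nan"),
        "sd_auc": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        "n_folds": len(fold_auc),
    }


def hr_heterogeneity_z(log_hr_1: float, se_1: float,
                       log_hr_2: float, se_2: float) -> tuple[float, float]:
    """Pairwise Z-test for a difference between two log hazard ratios."""
    if se_1 <= 0 or se_2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (log_hr_1 - log_hr_2) / np.hypot(se_1, se_2)
    return float(z), float(2 * norm.sf(abs(z)))
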