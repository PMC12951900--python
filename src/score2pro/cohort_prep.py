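"""Cohort preparation: protein missingness filter, clinical imputation,
derived variables, protein standardization, and the derivation/validation
split.

The canonical order is ``filter -> impute -> split -> derive``: the
derivation/validation labels must exist before protein standardization so the
scaling parameters can be frozen on derivation rows only (leakage-safe).
Proteins are never imputed: the tree learners downstream handle missing
protein values natively and the Cox screen drops missing rows per protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .synthetic_cohort import Cohort, MASKABLE_CLINICAL


@dataclass
class PrepConfig:
    protein_missing_threshold: float = 0.25
    derivation_fraction: float = 0.70
    split_seed: int = 0
    imputation_method: str = "iterative_forest"  # or "median"
    scale_proteins: bool = True
    # iterative-forest knobs (kept small: a handful of chained rounds suffices
    # for MCAR clinical missingness at the rates simulated here)
    forest_trees: int = 25
    forest_max_iter: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.protein_missing_threshold < 1.0:
            raise ValueError("protein_missing_threshold must be in (0, 1)")
        if not 0.0 < self.derivation_fraction < 1.0:
            raise ValueError("derivation_fraction must be in (0, 1)")
        if self.imputation_method not in ("iterative_forest", "median"):
            raise ValueError(f"unknown imputation method {self.imputation_method!r}")


def filter_proteins(cohort: Cohort, threshold: float = 0.25
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Drop proteins whose missing fraction (over all rows) exceeds ``threshold``.

    Returns the filtered cohort and a report table with one row per dropped
    protein (name, missing fraction).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    frac = cohort.proteins().isna().mean(axis=0)
    dropped = frac[frac > threshold]
    keep = [c for c in cohort.protein_cols if c not in dropped.index]
    if not keep:
        raise ValueError("all proteins exceed the missingness threshold")
    report = pd.DataFrame({
        "protein": dropped.index,
        "missing_fraction": dropped.to_numpy(),
    }).reset_index(drop=True)
    data = cohort.data.drop(columns=list(dropped.index))
    return Cohort(data, keep, cohort.proteins_standardized), report


def impute_clinical(cohort: Cohort, method: str = "iterative_forest",
                    seed: int = 0, config: Optional[PrepConfig] = None
                    ) -> Cohort:
    """Fill missing clinical values; observed values are left untouched.

    ``median`` fills each column with its observed median.  ``iterative_forest``
    runs chained imputation with extra-trees regressors over the continuous
    clinical columns, exploiting their correlation structure (e.g. DBP
    predicts SBP, LDL/HDL/TG predict total cholesterol).  Deterministic given
    ``seed``.
    """
    out = cohort.copy()
    cols = [c for c in MASKABLE_CLINICAL if c in out.data.columns]
    block = out.data[cols]
    if block.isna().all(axis=0).any():
        empty = block.columns[block.isna().all(axis=0)].tolist()
        raise ValueError(f"clinical columns entirely missing: {empty}")
    if not block.isna().any().any():
        return out
    if method == "median":
        filled = block.fillna(block.median())
    elif method == "iterative_forest":
        from sklearn.ensemble import ExtraTreesRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        cfg = config or PrepConfig()
        est = ExtraTreesRegressor(
            n_estimators=cfg.forest_trees, max_depth=8,
            random_state=seed, n_jobs=1,
        )
        imp = IterativeImputer(
            estimator=est, max_iter=cfg.forest_max_iter,
            random_state=seed, sample_posterior=False,
            initial_strategy="median", tol=1e-3,
        )
        filled = pd.DataFrame(imp.fit_transform(block), columns=cols,
                              index=block.index)
        # chained imputation must never move an observed value
        filled = filled.where(block.isna(), block)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    out.data[cols] = filled
    if {"total_chol", "hdl"} <= set(out.data.columns):
        out.data["non_hdl"] = out.data["total_chol"] - out.data["hdl"]
    return out


def derive_variables(cohort: Cohort, scale_proteins: bool = True) -> Cohort:
    """Recompute non-HDL cholesterol and standardize protein columns.

    non_hdl = total_chol - hdl.  When ``scale_proteins`` is on, each protein
    is centred and scaled to SD 1 using parameters computed on derivation rows
    only (all rows if the split is unassigned) and applied to every row;
    missing protein entries stay missing.
    """
    out = cohort.copy()
    bad = (out.data["hdl"] > out.data["total_chol"]).mean()
    if bad > 0.01:
        raise ValueError(
            f"hdl exceeds total cholesterol in {bad:.1%} of rows; "
            "malformed input")
    out.data["non_hdl"] = out.data["total_chol"] - out.data["hdl"]
    if scale_proteins and out.protein_cols:
        deriv = out.derivation_mask()
        if not deriv.any():
            deriv = np.ones(len(out.data), dtype=bool)
        block = out.data[out.protein_cols].to_numpy(dtype=float)
        ref = block[deriv]
        mu = np.nanmean(ref, axis=0)
        sd = np.nanstd(ref, axis=0, ddof=0)
        if (sd == 0).any():
            const = [out.protein_cols[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant protein columns cannot be scaled: {const[:5]}")
        out.data[out.protein_cols] = (block - mu) / sd
        out.proteins_standardized = True
    return out


def split_cohort(cohort: Cohort, fraction: float = 0.70, seed: int = 0
                 ) -> Cohort:
    """Simple random derivation/validation split, reproducible by seed.

    Derivation count = round(fraction * n).  Existing labels are overwritten.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(cohort)
    n_deriv = int(np.rint(fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.full(n, "validation", dtype=object)
    labels[order[:n_deriv]] = "derivation"
    out = cohort.copy()
    out.data["split"] = labels
    return out


def split_report(cohort: Cohort) -> dict:
    """Split sizes and per-split event rates, with a 2-SE comparability check."""
    rep: dict = {}
    rates = []
    for name in ("derivation", "validation"):
        m = cohort.data["split"] == name
        k = int(m.sum())
        r = float(cohort.data.loc[m, "event"].mean()) if k else float("nan")
        rep[name] = {"n": k, "event_rate": r}
        rates.append((r, k))
    (r1, n1), (r2, n2) = rates
    if n1 and n2:
        pooled = (r1 * n1 + r2 * n2) / (n1 + n2)
        se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        rep["event_rate_diff"] = float(r1 - r2)
        rep["event_rate_diff_2se"] = float(2 * se)
        rep["event_rates_comparable"] = bool(abs(r1 - r2) <= 2 * se)
    return rep


def prepare(cohort: Cohort, config: PrepConfig, out_report: str | Path | None = None
            ) -> tuple[Cohort, dict]:
    """filter -> impute -> split -> derive; returns cohort + prep report.

    Rows with an assigned split keep their labels only if the full cohort is
    re-split with the same seed (the operation is deterministic, so running
    ``prepare`` twice with one config is idempotent).
    """
    filtered, dropped = filter_proteins(cohort, config.protein_missing_threshold)
    imputed = impute_clinical(filtered, config.imputation_method,
                              seed=config.split_seed, config=config)
    split = split_cohort(imputed, config.derivation_fraction, config.split_seed)
    derived = derive_variables(split, config.scale_proteins)
    report = {
        "n_proteins_in": len(cohort.protein_cols),
        "n_proteins_retained": len(derived.protein_cols),
        "dropped_proteins": dropped.to_dict(orient="records"),
        "splits": split_report(derived),
    }
    if out_report is not None:
        Path(out_report).write_text(json.dumps(report, indent=1))
    return derived, report
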