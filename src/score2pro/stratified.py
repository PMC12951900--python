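"""Subgroup-stratified model building and evaluation.

For each of the ten clinical subgroups this module runs, on the subgroup's
derivation rows: the Bonferroni-corrected Cox screen, gradient-boosting
importance ranking and forward selection; it then trains a subgroup-specific
protein classifier and compares it — on the identical subgroup validation
rows — against a clinical comparator trained on the SCORE2 covariate set
(age, sex, smoking, SBP, total and HDL cholesterol; the published SCORE2
coefficients are deliberately not used).  The module also evaluates the
high-risk composite subgroup, sweeps all 32 composite cells, and tabulates
protein-set intersections across subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cox_assoc import screen_proteins, screen_table
from .metrics import (auc, calibrate_risks, categorical_nri, delong_compare)
from .panel_select import (GBMParams, PanelResult, SelectionConfig,
                           predict_risk, select_panel, train_classifier)
from .subgroups import (HIGH_RISK_COMPOSITE, STANDARD_SUBGROUPS,
                        STRAT_VARIABLES, CompositeSubgroup, SubgroupSpec,
                        assign_subgroups, composite_cells, get_subgroup)
from .synthetic_cohort import Cohort

SCORE2_COVARIATES = ["age", "sex", "smoking", "sbp", "total_chol", "hdl"]


@dataclass
class EvalConfig:
    min_derivation_events: int = 30
    nri_threshold: float = 0.05
    nri_n_boot: int = 1000
    calibrate_nri: bool = False
    screen_alpha: float = 0.05
    include_diabetes_in_high_risk: bool = False
    seed: int = 0


@dataclass
class ModelCard:
    """Evaluation record of one model within one subgroup."""

    model_kind: str  # clinical | general_protein | specific_protein | clinical_plus_protein
    features: list[str]
    subgroup: str
    n_train: int
    n_eval: int
    auc: float
    delta_auc_vs_clinical: Optional[float] = None
    delong_p_vs_clinical: Optional[float] = None
    nri_vs_clinical: Optional[dict] = None

    def to_row(self) -> dict:
        nri = self.nri_vs_clinical or {}
        ci = nri.get("ci95", {}).get("overall", [None, None])
        return {
            "subgroup": self.subgroup, "model": self.model_kind,
            "n_proteins": sum(f.startswith("prot_") for f in self.features),
            "auc": self.auc,
            "delta_auc": self.delta_auc_vs_clinical,
            "delong_p": self.delong_p_vs_clinical,
            "nri": nri.get("nri_overall"),
            "nri_ci_lo": ci[0], "nri_ci_hi": ci[1],
            "nri_p": nri.get("p", {}).get("overall"),
            "n_train": self.n_train, "n_eval": self.n_eval,
        }


def clinical_feature_frame(df: pd.DataFrame,
                           drop_constant: bool = True) -> pd.DataFrame:
    """SCORE2 covariates as a numeric frame; constant columns are dropped
    (e.g. sex inside a sex subgroup) unless ``drop_constant`` is off."""
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"].astype(float)
    out["sex_male"] = (df["sex"] == "male").astype(float)
    out["smoking_previous"] = (df["smoking"] == "previous").astype(float)
    out["smoking_current"] = (df["smoking"] == "current").astype(float)
    out["sbp"] = df["sbp"].astype(float)
    out["total_chol"] = df["total_chol"].astype(float)
    out["hdl"] = df["hdl"].astype(float)
    if drop_constant:
        keep = [c for c in out.columns if out[c].nunique(dropna=True) > 1]
        out = out[keep]
    return out


def _feature_block(df: pd.DataFrame, feature_frames: Sequence[str],
                   panel: Sequence[str],
                   clinical_cols: Optional[Sequence[str]] = None
                   ) -> tuple[np.ndarray, list[str]]:
    blocks, names = [], []
    if "clinical" in feature_frames:
        cf = clinical_feature_frame(df, drop_constant=clinical_cols is None)
        if clinical_cols is not None:
            cf = cf[list(clinical_cols)]
        blocks.append(cf.to_numpy())
        names.extend(cf.columns)
    if panel:
        blocks.append(df[list(panel)].to_numpy(dtype=float))
        names.extend(panel)
    return np.hstack(blocks), names


def _fit_eval(train_df: pd.DataFrame, eval_df: pd.DataFrame, y_train,
              feature_frames: Sequence[str], panel: Sequence[str],
              gbm: GBMParams, return_clf: bool = False):
    """Train a boosted classifier on the given feature blocks; return
    predicted event probabilities on the evaluation rows and feature names."""
    Xtr, names = _feature_block(train_df, feature_frames, panel)
    Xev, _ = _feature_block(eval_df, feature_frames, panel,
                            clinical_cols=[n for n in names
                                           if not n.startswith("prot_")]
                            if "clinical" in feature_frames else None)
    clf = train_classifier(Xtr, y_train, gbm)
    scores = predict_risk(clf, Xev)
    if return_clf:
        return scores, names, clf
    return scores, names


@dataclass
class SubgroupOutcome:
    subgroup: str
    skipped: bool
    reason: Optional[str] = None
    screen: Optional[pd.DataFrame] = None
    panel: Optional[PanelResult] = None
    cards: dict = field(default_factory=dict)
    eval_row_ids: Optional[list] = None
    risk_scores: dict = field(default_factory=dict)
    eval_labels: Optional[np.ndarray] = None


def _maybe_calibrate(scores_eval, scores_train, y_train, enabled: bool):
    if not enabled:
        return np.clip(scores_eval, 0.0, 1.0)
    return calibrate_risks(scores_train, y_train, scores_eval)


def run_subgroup_pipeline(cohort: Cohort, subgroup: SubgroupSpec | str,
                          selection: Optional[SelectionConfig] = None,
                          eval_config: Optional[EvalConfig] = None,
                          general_model: Optional[dict] = None
                          ) -> SubgroupOutcome:
    """Screen -> rank -> forward-select -> train -> validate, in one subgroup.

    The derivation/validation split is inherited from the full cohort, never
    re-drawn.  ``general_model`` (as returned by :func:`build_general_model`)
    supplies the unstratified comparator: its classifier — trained on the
    full derivation set — is evaluated on this subgroup's validation rows.
    Returns all model cards, the raw risk scores on the subgroup's
    validation rows (audit: the identical rows for every model), and the
    screen table.  Subgroups whose derivation rows hold fewer than
    ``min_derivation_events`` events are skipped with an explicit reason.
    """
    if isinstance(subgroup, str):
        subgroup = get_subgroup(subgroup)
    sel = selection or SelectionConfig()
    ev = eval_config or EvalConfig()

    mask = subgroup.mask(cohort.data)
    sub = cohort.rows(mask)
    sub.data.reset_index(drop=True, inplace=True)
    deriv = sub.derivation_mask()
    val = sub.validation_mask()
    n_events_deriv = int(sub.data.loc[deriv, "event"].sum())
    if n_events_deriv < ev.min_derivation_events:
        return SubgroupOutcome(subgroup.name, skipped=True,
                               reason=f"only {n_events_deriv} derivation "
                                      f"events (< {ev.min_derivation_events})")
    if int(sub.data.loc[val, "event"].sum()) < 2 or val.sum() < 10:
        return SubgroupOutcome(subgroup.name, skipped=True,
                               reason="validation rows insufficient")

    results = screen_proteins(sub, model="model2", alpha=ev.screen_alpha,
                              subgroup=subgroup.name, rows=deriv)
    stable = screen_table(results)
    candidates = [r.protein for r in results
                  if r.significant_bonferroni and r.converged]
    out = SubgroupOutcome(subgroup.name, skipped=False, screen=stable)
    deriv_df = sub.data.loc[deriv]
    val_df = sub.data.loc[val]
    y_tr = deriv_df["event"].to_numpy(dtype=int)
    y_ev = val_df["event"].to_numpy(dtype=int)
    out.eval_row_ids = val_df["id"].tolist()
    out.eval_labels = y_ev

    if candidates:
        panel = select_panel(deriv_df[candidates].to_numpy(dtype=float),
                             y_tr, candidates, sel, subgroup=subgroup.name)
    else:
        warnings.warn(f"{subgroup.name}: no Bonferroni-significant proteins; "
                      "no specific panel built", stacklevel=2)
        panel = PanelResult([], [], [], 0, [], subgroup=subgroup.name,
                            plateau_reached=False)
    out.panel = panel

    # --- models evaluated on the identical validation rows -----------------
    gbm = sel.gbm_params
    scores: dict[str, np.ndarray] = {}
    train_scores: dict[str, np.ndarray] = {}

    def build(kind: str, frames: Sequence[str], prot: Sequence[str]):
        s_ev, names = _fit_eval(deriv_df, val_df, y_tr, frames, prot, gbm)
        s_tr, _ = _fit_eval(deriv_df, deriv_df, y_tr, frames, prot, gbm)
        scores[kind] = s_ev
        train_scores[kind] = s_tr
        return names

    clin_names = build("clinical", ["clinical"], [])
    cards: dict[str, ModelCard] = {}
    clin_auc = auc(scores["clinical"], y_ev)
    cards["clinical"] = ModelCard("clinical", clin_names, subgroup.name,
                                  len(deriv_df), len(val_df), clin_auc)

    def card_vs_clinical(kind: str, names: list[str]) -> ModelCard:
        cmp = delong_compare(scores["clinical"], scores[kind], y_ev)
        r_old = _maybe_calibrate(scores["clinical"], train_scores["clinical"],
                                 y_tr, ev.calibrate_nri)
        r_new = _maybe_calibrate(scores[kind], train_scores[kind],
                                 y_tr, ev.calibrate_nri)
        nri = categorical_nri(r_old, r_new, y_ev, ev.nri_threshold,
                              n_boot=ev.nri_n_boot, seed=ev.seed)
        return ModelCard(kind, names, subgroup.name, len(deriv_df),
                         len(val_df), auc(scores[kind], y_ev),
                         delta_auc_vs_clinical=float(cmp.delta),
                         delong_p_vs_clinical=float(cmp.p),
                         nri_vs_clinical=nri.to_dict())

    if panel.selected_panel:
        names = build("specific_protein", [], panel.selected_panel)
        cards["specific_protein"] = card_vs_clinical("specific_protein", names)
        names = build("clinical_plus_protein", ["clinical"],
                      panel.selected_panel)
        cards["clinical_plus_protein"] = card_vs_clinical(
            "clinical_plus_protein", names)
    if general_model and general_model.get("panel"):
        # the unstratified comparator: trained on the FULL derivation set,
        # evaluated on this subgroup's validation rows
        g_panel = list(general_model["panel"])
        g_clf = general_model["clf"]
        scores["general_protein"] = predict_risk(
            g_clf, val_df[g_panel].to_numpy(dtype=float))
        train_scores["general_protein"] = predict_risk(
            g_clf, deriv_df[g_panel].to_numpy(dtype=float))
        cards["general_protein"] = card_vs_clinical("general_protein",
                                                    g_panel)

    out.cards = cards
    out.risk_scores = scores
    return out


def build_general_model(cohort: Cohort,
                        selection: Optional[SelectionConfig] = None,
                        eval_config: Optional[EvalConfig] = None) -> dict:
    """The unstratified pipeline: screen, select and evaluate on the full
    cohort.  Returns the screen table, the general PanelResult and model
    cards (clinical / protein panel / combined) on the full validation set."""
    sel = selection or SelectionConfig()
    ev = eval_config or EvalConfig()
    deriv = cohort.derivation_mask()
    val = cohort.validation_mask()
    results = screen_proteins(cohort, model="model2", alpha=ev.screen_alpha,
                              rows=deriv)
    stable = screen_table(results)
    candidates = [r.protein for r in results
                  if r.significant_bonferroni and r.converged]
    deriv_df = cohort.data.loc[deriv]
    val_df = cohort.data.loc[val]
    y_tr = deriv_df["event"].to_numpy(dtype=int)
    y_ev = val_df["event"].to_numpy(dtype=int)
    if candidates:
        panel = select_panel(deriv_df[candidates].to_numpy(dtype=float),
                             y_tr, candidates, sel, subgroup="general")
    else:
        warnings.warn("general screen found no significant proteins",
                      stacklevel=2)
        panel = PanelResult([], [], [], 0, [], subgroup="general",
                            plateau_reached=False)
    gbm = sel.gbm_params
    scores = {}
    s, clin_names = _fit_eval(deriv_df, val_df, y_tr, ["clinical"], [], gbm)
    scores["clinical"] = s
    cards = {"clinical": ModelCard("clinical", clin_names, "general",
                                   len(deriv_df), len(val_df),
                                   auc(s, y_ev))}
    protein_clf = None
    if panel.selected_panel:
        for kind, frames in (("general_protein", []),
                             ("clinical_plus_protein", ["clinical"])):
            s, names, clf = _fit_eval(deriv_df, val_df, y_tr, frames,
                                      panel.selected_panel, gbm,
                                      return_clf=True)
            if kind == "general_protein":
                protein_clf = clf
            scores[kind] = s
            cmp = delong_compare(scores["clinical"], s, y_ev)
            nri = categorical_nri(np.clip(scores["clinical"], 0, 1),
                                  np.clip(s, 0, 1), y_ev, ev.nri_threshold,
                                  n_boot=ev.nri_n_boot, seed=ev.seed)
            cards[kind] = ModelCard(
                kind, names, "general", len(deriv_df), len(val_df),
                auc(s, y_ev), delta_auc_vs_clinical=float(cmp.delta),
                delong_p_vs_clinical=float(cmp.p),
                nri_vs_clinical=nri.to_dict())
    return {"screen": stable, "panel": panel.selected_panel, "clf": protein_clf,
            "panel_result": panel, "cards": cards,
            "scores": scores, "eval_labels": y_ev}


def compare_specific_vs_general(outcome: SubgroupOutcome,
                                eval_config: Optional[EvalConfig] = None
                                ) -> Optional[dict]:
    """Specific vs general protein model on the identical subgroup
    validation rows (both must already be evaluated in ``outcome``)."""
    ev = eval_config or EvalConfig()
    if "specific_protein" not in outcome.cards \
            or "general_protein" not in outcome.cards:
        return None
    y = outcome.eval_labels
    s_gen = outcome.risk_scores["general_protein"]
    s_spec = outcome.risk_scores["specific_protein"]
    cmp = delong_compare(s_gen, s_spec, y)
    nri = categorical_nri(np.clip(s_gen, 0, 1), np.clip(s_spec, 0, 1), y,
                          ev.nri_threshold, n_boot=ev.nri_n_boot, seed=ev.seed)
    return {
        "subgroup": outcome.subgroup,
        "auc_general": float(cmp.auc_a),
        "auc_specific": float(cmp.auc_b),
        "delta_auc": float(cmp.delta),
        "delong_p": float(cmp.p),
        "nri_specific_vs_general": nri.to_dict(),
        "panel_size_specific": len(outcome.cards["specific_protein"].features),
        "panel_size_general": len(outcome.cards["general_protein"].features),
    }


def _panel_union_for(members: Sequence[SubgroupSpec],
                     outcomes: dict[str, SubgroupOutcome]) -> list[str]:
    union: list[str] = []
    for spec in members:
        oc = outcomes.get(spec.name)
        if oc is None or oc.skipped or oc.panel is None:
            continue
        for p in oc.panel.selected_panel:
            if p not in union:
                union.append(p)
    return union


def evaluate_high_risk(cohort: Cohort, outcomes: dict[str, SubgroupOutcome],
                       general_panel: Sequence[str],
                       composite: Optional[CompositeSubgroup] = None,
                       selection: Optional[SelectionConfig] = None,
                       eval_config: Optional[EvalConfig] = None,
                       threshold: Optional[float] = None) -> dict:
    """Reclassification analysis in a high-risk composite subgroup.

    The specific proteomic model combines the proteins of the one-variable
    panels matching the composite's sides.  Four analyses against the
    clinical comparator are reported: specific alone, specific + clinical,
    general alone, general + clinical.  The risk threshold defaults to the
    observed event incidence in the composite subgroup, rounded to the
    nearest percent.
    """
    sel = selection or SelectionConfig()
    ev = eval_config or EvalConfig()
    comp = composite or HIGH_RISK_COMPOSITE
    mask = comp.mask(cohort.data)
    if ev.include_diabetes_in_high_risk and comp is HIGH_RISK_COMPOSITE:
        mask = mask | ((cohort.data["diabetes"] == 1).to_numpy()
                       & get_subgroup("male").mask(cohort.data))
    if not mask.any():
        raise ValueError(
            f"composite subgroup {comp.name!r} "
            f"({' & '.join(m.name for m in comp.members)}) is empty")
    sub = cohort.rows(mask)
    sub.data.reset_index(drop=True, inplace=True)
    deriv = sub.derivation_mask()
    val = sub.validation_mask()
    n_ev_deriv = int(sub.data.loc[deriv, "event"].sum())
    if n_ev_deriv < ev.min_derivation_events:
        raise ValueError(f"composite {comp.name!r}: only {n_ev_deriv} "
                         "derivation events")
    incidence = float(sub.data["event"].mean())
    thr = threshold if threshold is not None else round(incidence, 2)

    union = _panel_union_for(comp.members, outcomes)
    if not union:
        raise ValueError("no subgroup panels available for the composite")
    deriv_df, val_df = sub.data.loc[deriv], sub.data.loc[val]
    y_tr = deriv_df["event"].to_numpy(dtype=int)
    y_ev = val_df["event"].to_numpy(dtype=int)
    gbm = sel.gbm_params

    def scores_for(frames, prot):
        s, _ = _fit_eval(deriv_df, val_df, y_tr, frames, prot, gbm)
        return np.clip(s, 0, 1)

    s_clin = scores_for(["clinical"], [])
    bundles = {
        "specific_alone": scores_for([], union),
        "specific_plus_clinical": scores_for(["clinical"], union),
        "general_alone": scores_for([], list(general_panel)),
        "general_plus_clinical": scores_for(["clinical"], list(general_panel)),
    }
    analyses = {}
    for name, s in bundles.items():
        analyses[name] = categorical_nri(
            s_clin, s, y_ev, thr, n_boot=ev.nri_n_boot, seed=ev.seed
        ).to_dict()
    return {
        "composite": comp.name,
        "members": [m.name for m in comp.members],
        "n": int(mask.sum()),
        "observed_incidence": incidence,
        "threshold": float(thr),
        "protein_union": union,
        "n_derivation_events": n_ev_deriv,
        "analyses": analyses,
    }


def sweep_composite_cells(cohort: Cohort,
                          outcomes: dict[str, SubgroupOutcome],
                          selection: Optional[SelectionConfig] = None,
                          eval_config: Optional[EvalConfig] = None
                          ) -> pd.DataFrame:
    """Reclassification across all 32 composite cells.

    Each cell's protein set is the union of the panels of the five
    one-variable subgroups matching the cell's sides; its risk threshold is
    the cell's own observed event incidence.  Cells below the derivation
    event floor are reported as skipped.
    """
    sel = selection or SelectionConfig()
    ev = eval_config or EvalConfig()
    rows = []
    for cell in composite_cells():
        mask = cell.mask(cohort.data)
        base = {"cell": cell.name, "n": int(mask.sum())}
        if not mask.any():
            rows.append({**base, "skipped": True, "reason": "empty"})
            continue
        sub = cohort.rows(mask)
        sub.data.reset_index(drop=True, inplace=True)
        deriv, val = sub.derivation_mask(), sub.validation_mask()
        n_ev_deriv = int(sub.data.loc[deriv, "event"].sum())
        n_ev_val = int(sub.data.loc[val, "event"].sum())
        if n_ev_deriv < ev.min_derivation_events or n_ev_val < 2 \
                or (val.sum() - n_ev_val) < 2:
            rows.append({**base, "skipped": True,
                         "reason": f"{n_ev_deriv} derivation / {n_ev_val} "
                                   "validation events below floor"})
            continue
        union = _panel_union_for(cell.members, outcomes)
        if not union:
            rows.append({**base, "skipped": True, "reason": "no panels"})
            continue
        incidence = float(sub.data["event"].mean())
        thr = round(incidence, 2) if incidence >= 0.005 else incidence
        deriv_df, val_df = sub.data.loc[deriv], sub.data.loc[val]
        y_tr = deriv_df["event"].to_numpy(dtype=int)
        y_ev = val_df["event"].to_numpy(dtype=int)
        s_clin, _ = _fit_eval(deriv_df, val_df, y_tr, ["clinical"], [],
                              sel.gbm_params)
        s_prot, _ = _fit_eval(deriv_df, val_df, y_tr, [], union,
                              sel.gbm_params)
        nri = categorical_nri(np.clip(s_clin, 0, 1), np.clip(s_prot, 0, 1),
                              y_ev, thr, n_boot=ev.nri_n_boot, seed=ev.seed)
        rows.append({
            **base, "skipped": False, "reason": None,
            "observed_incidence": incidence, "threshold": float(thr),
            "n_proteins": len(union),
            "nri_overall": nri.nri_overall, "nri_event": nri.nri_event,
            "nri_nonevent": nri.nri_nonevent,
            "nri_p": nri.p.get("overall"),
            "nri_ci_lo": nri.ci95.get("overall", [None, None])[0],
            "nri_ci_hi": nri.ci95.get("overall", [None, None])[1],
        })
    return pd.DataFrame(rows)


def panel_intersections(panels: dict[str, Sequence[str]]) -> dict:
    """Set-membership table across subgroup panels.

    Returns the protein x subgroup incidence matrix, per-protein subgroup
    counts, and exact intersection-pattern counts (UpSet-style cells).
    """
    if not panels:
        raise ValueError("need at least one panel")
    union = sorted({p for ps in panels.values() for p in ps})
    names = list(panels)
    mat = pd.DataFrame(False, index=union, columns=names)
    for g, ps in panels.items():
        mat.loc[list(ps), g] = True
    counts = mat.sum(axis=1).rename("n_subgroups")
    patterns: dict[str, list[str]] = {}
    for prot in union:
        key = "&".join(g for g in names if mat.loc[prot, g]) or "(none)"
        patterns.setdefault(key, []).append(prot)
    cells = (pd.DataFrame(
        [{"pattern": k, "n_proteins": len(v), "proteins": sorted(v)}
         for k, v in patterns.items()])
        .sort_values("n_proteins", ascending=False).reset_index(drop=True))
    return {"membership": mat, "protein_counts": counts,
            "intersection_cells": cells,
            "union_size": len(union),
            "panel_sizes": {g: int(mat[g].sum()) for g in names}}


def table2_summary(outcomes: dict[str, SubgroupOutcome]) -> pd.DataFrame:
    """Subgroup x model grid of AUC / dAUC / DeLong p / NRI with CIs."""
    rows = []
    for name, oc in outcomes.items():
        if oc.skipped:
            rows.append({"subgroup": name, "model": None, "skipped": True,
                         "reason": oc.reason})
            continue
        for card in oc.cards.values():
            rows.append({**card.to_row(), "skipped": False, "reason": None})
    return pd.DataFrame(rows)
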