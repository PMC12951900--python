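"""Binary clinical stratifications used throughout the pipeline.

The stratification scheme follows the SCORE2 risk-chart axes: sex, age band
(middle-aged < 60 y vs elderly >= 60 y), smoking (never vs ever), systolic
blood pressure (< 140 vs >= 140 mmHg, the European hypertension boundary) and
non-HDL cholesterol (< 4 vs >= 4 mmol/L).  Each variable splits the cohort
into exactly two sides; the cross of all five gives 32 composite cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

AGE_CUT_YEARS = 60.0
SBP_CUT_MMHG = 140.0
NON_HDL_CUT_MMOL = 4.0

#: the five stratification variables, in canonical order
STRAT_VARIABLES = ("sex", "age", "smoking", "sbp", "non_hdl")


@dataclass(frozen=True)
class SubgroupSpec:
    """One side of a binary clinical stratification.

    Parameters
    ----------
    name
        Human-readable label, e.g. ``"female"`` or ``"sbp_high"``.
    variable
        One of :data:`STRAT_VARIABLES`.
    rule
        Vectorised predicate mapping a cohort DataFrame to a boolean mask of
        membership.
    """

    name: str
    variable: str
    rule: Callable[[pd.DataFrame], np.ndarray]

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        out = np.asarray(self.rule(df), dtype=bool)
        if out.shape != (len(df),):
            raise ValueError(f"subgroup rule for {self.name!r} returned wrong shape")
        return out


def _ever_smoker(df: pd.DataFrame) -> np.ndarray:
    return df["smoking"].isin(["previous", "current"]).to_numpy()


#: the ten standard subgroups (two sides per stratification variable)
STANDARD_SUBGROUPS: tuple[SubgroupSpec, ...] = (
    SubgroupSpec("female", "sex", lambda d: (d["sex"] == "female").to_numpy()),
    SubgroupSpec("male", "sex", lambda d: (d["sex"] == "male").to_numpy()),
    SubgroupSpec("middle_aged", "age", lambda d: (d["age"] < AGE_CUT_YEARS).to_numpy()),
    SubgroupSpec("elderly", "age", lambda d: (d["age"] >= AGE_CUT_YEARS).to_numpy()),
    SubgroupSpec("non_smoking", "smoking", lambda d: (d["smoking"] == "never").to_numpy()),
    SubgroupSpec("smoking", "smoking", _ever_smoker),
    SubgroupSpec("sbp_low", "sbp", lambda d: (d["sbp"] < SBP_CUT_MMHG).to_numpy()),
    SubgroupSpec("sbp_high", "sbp", lambda d: (d["sbp"] >= SBP_CUT_MMHG).to_numpy()),
    SubgroupSpec("non_hdl_low", "non_hdl", lambda d: (d["non_hdl"] < NON_HDL_CUT_MMOL).to_numpy()),
    SubgroupSpec("non_hdl_high", "non_hdl", lambda d: (d["non_hdl"] >= NON_HDL_CUT_MMOL).to_numpy()),
)

SUBGROUPS_BY_NAME = {s.name: s for s in STANDARD_SUBGROUPS}


def get_subgroup(name: str) -> SubgroupSpec:
    try:
        return SUBGROUPS_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown subgroup {name!r}; known: {sorted(SUBGROUPS_BY_NAME)}"
        ) from None


@dataclass(frozen=True)
class CompositeSubgroup:
    """Conjunction of one side per (subset of) stratification variable."""

    name: str
    members: tuple[SubgroupSpec, ...]

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(df), dtype=bool)
        for spec in self.members:
            out &= spec.mask(df)
        return out


#: the high-risk composite of the reclassification analysis: male ever-smokers
#: with SBP >= 140 mmHg and non-HDL cholesterol >= 4 mmol/L
HIGH_RISK_COMPOSITE = CompositeSubgroup(
    "high_risk",
    (
        SUBGROUPS_BY_NAME["male"],
        SUBGROUPS_BY_NAME["smoking"],
        SUBGROUPS_BY_NAME["sbp_high"],
        SUBGROUPS_BY_NAME["non_hdl_high"],
    ),
)


def composite_cells() -> list[CompositeSubgroup]:
    """All 2^5 = 32 composite cells, in a canonical order.

    Cell names join one side-name per variable with ``"&"``, e.g.
    ``"male&elderly&smoking&sbp_high&non_hdl_high"``.
    """
    sides_per_var = [
        [s for s in STANDARD_SUBGROUPS if s.variable == v] for v in STRAT_VARIABLES
    ]
    cells: list[CompositeSubgroup] = []
    idx = np.zeros(5, dtype=int)
    for code in range(32):
        for j in range(5):
            idx[j] = (code >> (4 - j)) & 1
        members = tuple(sides_per_var[j][idx[j]] for j in range(5))
        cells.append(CompositeSubgroup("&".join(m.name for m in members), members))
    return cells


def assign_subgroups(df: pd.DataFrame) -> pd.DataFrame:
    """Membership flags for the 10 standard subgroups plus the 32-cell label.

    Returns a DataFrame aligned with ``df`` holding one boolean column per
    subgroup name and a ``cell`` column with the composite-cell label.  Each
    row belongs to exactly one side of each variable and exactly one cell.
    """
    needed = {"sex", "age", "smoking", "sbp", "non_hdl"}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise ValueError(f"cohort lacks stratification columns: {sorted(missing_cols)}")
    for col in needed:
        if df[col].isna().any():
            raise ValueError(
                f"stratification variable {col!r} has missing values; impute first"
            )
    out = pd.DataFrame(index=df.index)
    for spec in STANDARD_SUBGROUPS:
        out[spec.name] = spec.mask(df)
    for var in STRAT_VARIABLES:
        sides = [s.name for s in STANDARD_SUBGROUPS if s.variable == var]
        both = out[sides[0]] == out[sides[1]]
        if both.any():
            raise ValueError(f"sides of {var!r} do not partition the cohort")
    labels = []
    for spec in STANDARD_SUBGROUPS:
        labels.append(np.where(out[spec.name], spec.name, ""))
    cell = [
        "&".join(x for x in row if x)
        for row in zip(*[np.asarray(c) for c in labels])
    ]
    out["cell"] = cell
    return out
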