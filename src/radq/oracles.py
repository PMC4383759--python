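"""Independent reference solvers for validating the estimation pipeline.

These deliberately avoid the regression machinery: the dynamic-programming
solver works on empirical cell means over fully discrete histories, and
the stratified value estimator averages within design strata.  On suitable
inputs (saturated models, populated cells) the Q-learning fit and the IPW
estimator must agree with them.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    BUP, PAR, PBO, BUP_HIGH, PAR_HIGH, Cohort, add_derived,
)


def dp_solve_discrete(cohort, stage2_vars: Sequence[str],
                      stage1_vars: Sequence[str]):
    """Brute-force backward induction on discrete history cells.

    Stage 2: empirical mean outcome per (stage2_vars, Trt2) cell among
    placebo non-responders; the cell rule is the argmin over the two arms
    (ties to high-dose Paroxetine).  Stage 1: pseudo-outcomes substitute
    the cell minimum for placebo non-responders, then empirical means per
    (stage1_vars, Trt1) cell give the stage-1 rule (ties to placebo, then
    Bupropion).  Every cell must be populated.

    Returns ``(rule2, rule1, q2_cells, q1_cells)`` where the rules map a
    tuple of variable values to a treatment.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    df = add_derived(df)
    s2 = df[(df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)]
    q2 = s2.groupby([*stage2_vars, "Trt2"], observed=True)["SUMD2"].mean()

    rule2 = {}
    q2_cells = {}
    cells2 = s2.groupby(list(stage2_vars), observed=True).groups.keys()
    for cell in cells2:
        cell = cell if isinstance(cell, tuple) else (cell,)
        vals = {}
        for a2 in (BUP_HIGH, PAR_HIGH):
            key = (*cell, a2)
            if key not in q2.index:
                raise ValueError(f"unpopulated stage-2 cell {key}")
            vals[a2] = float(q2.loc[key])
        q2_cells[cell] = vals
        rule2[cell] = BUP_HIGH if vals[BUP_HIGH] < vals[PAR_HIGH] \
            else PAR_HIGH

    yhat = df["SUMD2"].to_numpy(dtype=float).copy()
    mask = ((df["Trt1"] == PBO) & (df["RESPONSE1"] == 0)).to_numpy()
    sub = df[mask]
    mins = np.array([min(q2_cells[tuple(row)].values())
                     for row in sub[list(stage2_vars)].to_numpy()])
    yhat[mask] = mins

    work = df[list(stage1_vars) + ["Trt1"]].copy()
    work["_yhat"] = yhat
    q1 = work.groupby([*stage1_vars, "Trt1"], observed=True)["_yhat"].mean()

    rule1 = {}
    q1_cells = {}
    cells1 = work.groupby(list(stage1_vars), observed=True).groups.keys()
    for cell in cells1:
        cell = cell if isinstance(cell, tuple) else (cell,)
        vals = {}
        for a1 in (PBO, BUP, PAR):
            key = (*cell, a1)
            if key not in q1.index:
                raise ValueError(f"unpopulated stage-1 cell {key}")
            vals[a1] = float(q1.loc[key])
        q1_cells[cell] = vals
        best = min(vals.values())
        for a1 in (PBO, BUP, PAR):          # tie-break order
            if vals[a1] == best:
                rule1[cell] = a1
                break
    return rule2, rule1, q2_cells, q1_cells


def stratified_static_value(cohort, pi1: str, pi2: str = None) -> float:
    """Direct stratification estimate of a static regime's value.

    Mean outcome of subjects on the regime's stage-1 arm, combining the
    responder stratum and the non-responder stratum (restricted, on the
    placebo arm, to the recommended second-line drug), weighted by the
    empirical responder rate of that arm.  With empirical propensities
    this equals the normalized IPW estimate.
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    arm = df[df["Trt1"] == pi1]
    if len(arm) == 0:
        raise ValueError(f"no subjects on arm {pi1}")
    resp = arm[arm["RESPONSE1"] == 1]
    nonresp = arm[arm["RESPONSE1"] == 0]
    if pi1 == PBO:
        nonresp = nonresp[nonresp["Trt2"] == pi2]
    p_resp = len(resp) / len(arm)
    mean_r = resp["SUMD2"].mean() if len(resp) else 0.0
    mean_nr = nonresp["SUMD2"].mean() if len(nonresp) else 0.0
    return float(p_resp * mean_r + (1 - p_resp) * mean_nr)
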