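"""Core data types for two-stage SMART trajectories.

The trial design mirrored here is the acute-depression randomized (RAD)
pathway of STEP-BD: at stage 1 every subject is randomized to adjunctive
Bupropion, Paroxetine, or placebo on top of a mood stabilizer.  After six
weeks, responders (at least 50% improvement in the depression subscale SUMD
and no emergent (hypo)mania) continue without re-randomization; placebo
non-responders are re-randomized 1:1 to high-dose Bupropion or high-dose
Paroxetine; drug non-responders escalate the dose of their current drug
deterministically.  The distal outcome is SUMD at week 12, lower is better.

A cohort is stored as one row per subject in a pandas DataFrame whose
columns follow the candidate-predictor table abbreviations.  Missing values
are NaN in memory and empty cells on disk.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Treatments
BUP = "BUP"
PAR = "PAR"
PBO = "PBO"
BUP_HIGH = "BUP_HIGH"
PAR_HIGH = "PAR_HIGH"

STAGE1_TREATMENTS = (BUP, PAR, PBO)
STAGE2_TREATMENTS = (BUP_HIGH, PAR_HIGH)
ESCALATION = {BUP: BUP_HIGH, PAR: PAR_HIGH}

# Instrument ranges
SUMD_RANGE = (0.0, 22.0)
SUMM_RANGE = (0.0, 16.0)
MIN_AGE = 18.0

# Categorical levels; the first two levels of each trinary map onto the
# dummies <NAME>1 / <NAME>2, the last level is the reference.
GENDER_LEVELS = ("female", "transgender", "male")
MARSTAT_LEVELS = ("married", "separated", "never_married")
PRONSET_LEVELS = ("remission", "manic", "mixed")

CATEGORICAL_LEVELS = {
    "GENDER": GENDER_LEVELS,
    "MARSTAT": MARSTAT_LEVELS,
    "PRONSET": PRONSET_LEVELS,
    "Trt1": STAGE1_TREATMENTS,
}

SIDE_COLUMNS = tuple(f"SIDE{i}" for i in range(1, 10))
BINARY_COLUMNS = ("RACE", "HINCOME", "EMPLOY", "EDUCATE", "MEDINS",
                  "BITYPE") + SIDE_COLUMNS
NUMERIC_BASELINE = ("AGE", "SUMD0", "SUMM0")

BASELINE_COLUMNS = (
    "AGE", "RACE", "GENDER", "MARSTAT", "HINCOME", "EMPLOY", "EDUCATE",
    "MEDINS", "BITYPE", "PRONSET", "SUMD0", "SUMM0",
) + SIDE_COLUMNS

#: Canonical on-disk column order (one row per subject, empty cell = missing).
COLUMNS = BASELINE_COLUMNS + ("Trt1", "SUMD1", "SUMM1", "RESPONSE1",
                              "Trt2", "SUMD2")

STRING_COLUMNS = ("GENDER", "MARSTAT", "PRONSET", "Trt1", "Trt2")


def classify_response(sumd0, sumd1, mania_flag):
    """Responder rule: at least 50% improvement in SUMD and no (hypo)mania.

    The 50% boundary is inclusive ("at least"): ``sumd1 == 0.5 * sumd0``
    counts as a response.  Accepts scalars or arrays; returns 0/1 ints.

    Raises
    ------
    ValueError
        If any ``sumd0`` is zero (the relative improvement is undefined)
        or a score lies outside the instrument range.
    """
    sumd0 = np.asarray(sumd0, dtype=float)
    sumd1 = np.asarray(sumd1, dtype=float)
    mania = np.asarray(mania_flag)
    if np.any(sumd0 == 0):
        raise ValueError("classify_response: SUMD0 = 0 makes percent "
                         "improvement undefined")
    for name, x, (lo, hi) in (("SUMD0", sumd0, SUMD_RANGE),
                              ("SUMD1", sumd1, SUMD_RANGE)):
        if np.any((x < lo) | (x > hi)):
            raise ValueError(f"classify_response: {name} outside [{lo}, {hi}]")
    resp = (sumd1 <= 0.5 * sumd0) & (mania == 0)
    out = resp.astype(int)
    return out if out.ndim else int(out)


def feasible_treatments(stage: int, history: Mapping) -> frozenset:
    """Feasible treatment set for a history prefix at the given stage.

    Stage 1 is unrestricted.  At stage 2 responders are never re-randomized
    (empty set); placebo non-responders may receive either high-dose drug;
    drug non-responders escalate their stage-1 drug.
    """
    if stage == 1:
        return frozenset(STAGE1_TREATMENTS)
    if stage != 2:
        raise ValueError(f"unknown stage {stage!r}")
    try:
        a1 = history["Trt1"] if isinstance(history, Mapping) else history.Trt1
        r = history["RESPONSE1"] if isinstance(history, Mapping) \
            else history.RESPONSE1
    except (KeyError, AttributeError) as exc:
        raise ValueError("stage-2 history must include Trt1 and RESPONSE1") \
            from exc
    if a1 not in STAGE1_TREATMENTS:
        raise ValueError(f"unknown stage-1 treatment {a1!r}")
    if pd.isna(r):
        raise ValueError("responder status is missing")
    if int(r) == 1:
        return frozenset()
    if a1 == PBO:
        return frozenset(STAGE2_TREATMENTS)
    return frozenset({ESCALATION[a1]})


def add_derived(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with dummy codings appended.

    PRONSET1 = remission, PRONSET2 = (hypo)manic, mixed as reference;
    GENDER1/GENDER2 and MARSTAT1/MARSTAT2 analogously from the level
    tables; A11/A12 code Bupropion/Paroxetine against placebo; A2 codes
    high-dose Bupropion against high-dose Paroxetine.  Dummies inherit
    NaN where the source value is missing.
    """
    out = df.copy()
    for name in ("GENDER", "MARSTAT", "PRONSET"):
        if name in out.columns:
            levels = CATEGORICAL_LEVELS[name]
            col = out[name]
            for k in (0, 1):
                dummy = (col == levels[k]).astype(float)
                dummy[col.isna()] = np.nan
                out[f"{name}{k + 1}"] = dummy
    if "Trt1" in out.columns:
        a1 = out["Trt1"]
        for dummy, trt in (("A11", BUP), ("A12", PAR)):
            d = (a1 == trt).astype(float)
            d[a1.isna()] = np.nan
            out[dummy] = d
    if "Trt2" in out.columns:
        a2 = out["Trt2"]
        d = (a2 == BUP_HIGH).astype(float)
        d[a2.isna()] = np.nan
        out["A2"] = d
    return out


def _check_range(df, col, lo, hi, errors):
    x = pd.to_numeric(df[col], errors="coerce")
    bad = x.notna() & ((x < lo) | (x > hi))
    if bad.any():
        errors.append(f"{col}: {int(bad.sum())} value(s) outside [{lo}, {hi}]")


class Cohort:
    """A collection of subject trajectories with missingness marks.

    Thin wrapper around a DataFrame in the canonical column schema.  NaN
    marks a missing (masked) cell.  ``validate`` enforces instrument
    ranges and the design's feasibility constraints; loading from CSV
    validates by default.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        for col in STRING_COLUMNS:
            c = self.df[col]
            if c.dtype == object and c.isna().any():
                self.df[col] = c.where(c.notna(), np.nan)  # None -> NaN
        if validate:
            self.validate()

    @property
    def n(self) -> int:
        return len(self.df)

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy(), validate=False)

    def is_complete(self) -> bool:
        """True if no cell is missing.  A responder's absent Trt2 is
        structural (never assigned), not missing."""
        cols = [c for c in COLUMNS if c != "Trt2"]
        if self.df[cols].isna().any().any():
            return False
        need_trt2 = self.df["RESPONSE1"] == 0
        return not self.df.loc[need_trt2, "Trt2"].isna().any()

    def mask_counts(self) -> pd.Series:
        counts = self.df[list(COLUMNS)].isna().sum()
        counts["Trt2"] = int((self.df["Trt2"].isna()
                              & (self.df["RESPONSE1"] == 0)).sum())
        return counts

    def validate(self) -> None:
        df = self.df
        errors: list[str] = []
        _check_range(df, "AGE", MIN_AGE, 120, errors)
        for col in ("SUMD0", "SUMD1", "SUMD2"):
            _check_range(df, col, *SUMD_RANGE, errors)
        for col in ("SUMM0", "SUMM1"):
            _check_range(df, col, *SUMM_RANGE, errors)
        for col in BINARY_COLUMNS + ("RESPONSE1",):
            x = df[col]
            bad = x.notna() & ~x.isin([0, 1, 0.0, 1.0])
            if bad.any():
                errors.append(f"{col}: non-binary values")
        for col, levels in CATEGORICAL_LEVELS.items():
            bad = df[col].notna() & ~df[col].isin(levels)
            if bad.any():
                errors.append(f"{col}: values outside {levels}")
        bad = df["Trt2"].notna() & ~df["Trt2"].isin(STAGE2_TREATMENTS)
        if bad.any():
            errors.append(f"Trt2: values outside {STAGE2_TREATMENTS}")

        # Feasibility of the observed second-stage assignment, where the
        # responder status and stage-1 arm are known.
        known = df["RESPONSE1"].notna() & df["Trt1"].notna()
        resp = known & (df["RESPONSE1"] == 1)
        if (resp & df["Trt2"].notna()).any():
            errors.append("responders with a second-stage treatment")
        nonresp = known & (df["RESPONSE1"] == 0)
        for a1, a2 in ESCALATION.items():
            bad = nonresp & (df["Trt1"] == a1) & df["Trt2"].notna() \
                & (df["Trt2"] != a2)
            if bad.any():
                errors.append(f"{a1} non-responders assigned a treatment "
                              f"other than {a2}")
        if errors:
            raise ValueError("cohort validation failed: " + "; ".join(errors))

    # ---- I/O ------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df[list(COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "Cohort":
        df = pd.read_csv(path, dtype={c: object for c in STRING_COLUMNS})
        for col in df.columns:
            if col not in STRING_COLUMNS:
                df[col] = pd.to_numeric(df[col], errors="raise")
        return cls(df, validate=validate)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "Cohort":
        return cls(df.copy(), validate=validate)


def linear_predictor(df: pd.DataFrame, coeffs: Mapping[str, float]) -> np.ndarray:
    """Evaluate sum_k coef_k * term_k row-wise on a derived frame.

    Term names are ``"const"``, a column name, or a ``":"``-joined product
    of column names (e.g. ``"A2:SUMM1"``).
    """
    out = np.zeros(len(df))
    for term, coef in coeffs.items():
        if coef == 0:
            continue
        if term == "const":
            out += coef
            continue
        val = np.ones(len(df))
        for part in term.split(":"):
            if part not in df.columns:
                raise KeyError(f"term {term!r}: column {part!r} not found")
            val = val * df[part].to_numpy(dtype=float)
        out += coef * val
    return out
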