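"""Self-controlled case series construction over longitudinal EHR tables.

Each patient serves as their own control: for a given drug, the change in an
outpatient laboratory value (HbA1c % or glucose mg/dL) is measured between a
baseline window before first exposure (t0) and a follow-up window after it.

Two site "dialects" reflect how continued exposure is ascertained in EHRs
with and without complete pharmacy data:

* ``fills``    -- at least one refill within 180 days of t0 and >= 90 days of
  cumulative days-supply dispensed inside that window;
* ``mentions`` -- at least two medication mentions (the initial one counts)
  within 180 days of t0.

All times are integer day offsets from an arbitrary study origin; "six
months" is fixed at 180 days and "nine months" at 270 days throughout.
Window boundary conventions (declared, since natural language does not fix
them): baseline ``[t0-180, t0)``; HbA1c follow-up ``(t0+30, t0+180]``
(earliest measure, the 30-day blank avoids values reflecting pre-treatment
physiology); glucose follow-up ``(t0, t0+180]`` (mean of all measures).
Two measures on the same qualifying day are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

DAYS_6M = 180
DAYS_9M = 270
FOLLOWUP_BLANK_DAYS = 30

#: Physiologic plausibility bounds (inclusive); exclusion is strict.
LAB_BOUNDS = {"hba1c": (3.0, 18.0), "glucose": (5.0, 2750.0)}

DIALECTS = ("fills", "mentions")


@dataclass
class SeriesResult:
    """One drug x analyte x site case series plus its attrition audit."""

    drug_id: str
    analyte: str
    dialect: str
    cases: pd.DataFrame  # columns: patient_id, drug_id, t0, analyte, baseline, followup, delta
    attrition: dict = field(default_factory=dict)
    suppressed: bool = False

    @property
    def n(self) -> int:
        return len(self.cases)

    @property
    def deltas(self) -> np.ndarray:
        return self.cases["delta"].to_numpy()


def first_exposure_index(events: pd.DataFrame, drug_id: str) -> pd.Series:
    """Earliest event day (t0) per patient for ``drug_id``.

    Patients with no event for the drug are absent from the result.
    """
    sub = events[events["drug_id"] == drug_id]
    return sub.groupby("patient_id")["day"].min()


def exclusion_screen(
    events: pd.DataFrame,
    t0_map: pd.Series,
    own_group: str,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Flag patients exposed to another medication group around t0.

    A patient is ineligible when any drug from one of the *other* two groups
    has an event ever before or on t0, or inside the six-month follow-up
    ``(t0, t0+180]``.  Same-group co-prescriptions never exclude.

    Returns a frame indexed like ``t0_map`` with ``eligible`` and ``reason``
    (``eligible``, ``other_group_on_or_before_t0``,
    ``other_group_in_followup``).
    """
    missing = set(events["drug_id"]) - set(groups)
    if missing:
        raise KeyError(f"drugs missing from medication catalog: {sorted(missing)!r}")

    ev = events[events["patient_id"].isin(t0_map.index)].copy()
    ev["group"] = ev["drug_id"].map(groups)
    other = ev[ev["group"] != own_group]
    t0 = other["patient_id"].map(t0_map)

    before = other.loc[other["day"] <= t0, "patient_id"].unique()
    during = other.loc[
        (other["day"] > t0) & (other["day"] <= t0 + DAYS_6M), "patient_id"
    ].unique()

    out = pd.DataFrame(index=t0_map.index)
    out["eligible"] = True
    out["reason"] = "eligible"
    # follow-up first so the stronger "ever before / at t0" reason wins
    out.loc[out.index.isin(during), ["eligible", "reason"]] = [
        False,
        "other_group_in_followup",
    ]
    out.loc[out.index.isin(before), ["eligible", "reason"]] = [
        False,
        "other_group_on_or_before_t0",
    ]
    return out


def persistence_check(
    events: pd.DataFrame, t0_map: pd.Series, dialect: str
) -> pd.Series:
    """Continued-exposure flag per patient under the site dialect.

    ``events`` must already be restricted to the series drug.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    ev = events[events["patient_id"].isin(t0_map.index)].copy()
    t0 = ev["patient_id"].map(t0_map)

    if dialect == "fills":
        fills = ev[ev["event_type"] == "fill"]
        t0f = fills["patient_id"].map(t0_map)
        refill = (
            fills[(fills["day"] > t0f) & (fills["day"] <= t0f + DAYS_6M)]
            .groupby("patient_id")
            .size()
            >= 1
        )
        window = fills[(fills["day"] >= t0f) & (fills["day"] <= t0f + DAYS_6M)]
        supply = window.groupby("patient_id")["days_supply"].sum() >= 90
        ok = refill.reindex(t0_map.index, fill_value=False) & supply.reindex(
            t0_map.index, fill_value=False
        )
    else:
        mention_n = (
            ev[(ev["day"] >= t0) & (ev["day"] <= t0 + DAYS_6M)]
            .groupby("patient_id")
            .size()
        )
        ok = (mention_n >= 2).reindex(t0_map.index, fill_value=False)
    ok.name = "persistent"
    return ok


def lab_qc(
    labs: pd.DataFrame,
    pregnancy: pd.DataFrame | None = None,
    apply_pregnancy: bool = False,
    pregnancy_window: int = DAYS_9M,
) -> pd.DataFrame:
    """Quality-control filter on laboratory rows.

    Keeps outpatient measures within physiologic bounds (HbA1c in [3, 18] %,
    glucose in [5, 2750] mg/dL -- bounds inclusive, the exclusions are strict
    inequalities).  With ``apply_pregnancy``, drops any lab within
    ``pregnancy_window`` days (either direction) of a pregnancy event for the
    same patient.
    """
    unknown = set(labs["analyte"]) - set(LAB_BOUNDS)
    if unknown:
        raise ValueError(f"unknown analyte(s): {sorted(unknown)!r}")

    out = labs[labs["setting"] == "outpatient"].copy()
    lo = out["analyte"].map(lambda a: LAB_BOUNDS[a][0])
    hi = out["analyte"].map(lambda a: LAB_BOUNDS[a][1])
    out = out[(out["value"] >= lo) & (out["value"] <= hi)]

    if apply_pregnancy and pregnancy is not None and not pregnancy.empty:
        merged = out.reset_index().merge(
            pregnancy.rename(columns={"day": "preg_day"}), on="patient_id", how="left"
        )
        near = (merged["day"] - merged["preg_day"]).abs() <= pregnancy_window
        drop_idx = merged.loc[near.fillna(False), "index"].unique()
        out = out.drop(index=drop_idx)
    return out


def _window_mean(labs: pd.DataFrame, day: int) -> float:
    """Mean value on one calendar day (duplicate same-day draws average)."""
    return float(labs.loc[labs["day"] == day, "value"].mean())


def outcome_delta_hba1c(labs: pd.DataFrame, t0: int) -> tuple[float, float] | None:
    """(baseline, follow-up) HbA1c for one patient, or ``None``.

    Baseline: most recent measure in ``[t0-180, t0)``.  Follow-up: first
    measure in ``(t0+30, t0+180]``.
    """
    pre = labs[(labs["day"] >= t0 - DAYS_6M) & (labs["day"] < t0)]
    post = labs[
        (labs["day"] > t0 + FOLLOWUP_BLANK_DAYS) & (labs["day"] <= t0 + DAYS_6M)
    ]
    if pre.empty or post.empty:
        return None
    return _window_mean(pre, pre["day"].max()), _window_mean(post, post["day"].min())


def outcome_delta_glucose(labs: pd.DataFrame, t0: int) -> tuple[float, float] | None:
    """(baseline, follow-up) glucose for one patient, or ``None``.

    Baseline: mean of all measures in ``[t0-180, t0)``; follow-up: mean of
    all measures in ``(t0, t0+180]``.
    """
    pre = labs[(labs["day"] >= t0 - DAYS_6M) & (labs["day"] < t0)]
    post = labs[(labs["day"] > t0) & (labs["day"] <= t0 + DAYS_6M)]
    if pre.empty or post.empty:
        return None
    return float(pre["value"].mean()), float(post["value"].mean())


_OUTCOME = {"hba1c": outcome_delta_hba1c, "glucose": outcome_delta_glucose}


def build_drug_series(
    prescriptions: pd.DataFrame,
    labs: pd.DataFrame,
    drug_id: str,
    analyte: str,
    dialect: str,
    groups: Mapping[str, str],
    pregnancy: pd.DataFrame | None = None,
    apply_pregnancy: bool | None = None,
    pregnancy_window: int = DAYS_9M,
    min_n: int = 30,
) -> SeriesResult:
    """Assemble the case series for one drug, analyte and site dialect.

    Patients pass, in order: first-exposure indexing, the other-group
    exclusion screen, the persistence check, and outcome extraction from
    QC'd outpatient labs.  The series is *suppressed* (cases emptied, flag
    set) when fewer than ``min_n`` patients remain.

    ``apply_pregnancy`` defaults to True for the ``mentions`` dialect only,
    mirroring a discovery population that is overwhelmingly male versus a
    general-population replication site.
    """
    if analyte not in _OUTCOME:
        raise ValueError(f"analyte must be one of {sorted(_OUTCOME)}")
    if apply_pregnancy is None:
        apply_pregnancy = dialect == "mentions"

    t0_map = first_exposure_index(prescriptions, drug_id)
    attrition = {"indexed": int(len(t0_map))}

    own_group = groups.get(drug_id)
    if own_group is None:
        raise KeyError(f"drug {drug_id!r} missing from medication catalog")
    screen = exclusion_screen(prescriptions, t0_map, own_group, groups)
    t0_map = t0_map[screen["eligible"]]
    attrition["after_exclusion_screen"] = int(len(t0_map))

    drug_events = prescriptions[prescriptions["drug_id"] == drug_id]
    persistent = persistence_check(drug_events, t0_map, dialect)
    t0_map = t0_map[persistent]
    attrition["after_persistence"] = int(len(t0_map))

    clean = lab_qc(
        labs,
        pregnancy=pregnancy,
        apply_pregnancy=apply_pregnancy,
        pregnancy_window=pregnancy_window,
    )
    clean = clean[(clean["analyte"] == analyte) & clean["patient_id"].isin(t0_map.index)]
    outcome = _OUTCOME[analyte]

    rows = []
    for pid, labs_p in clean.groupby("patient_id"):
        t0 = int(t0_map.loc[pid])
        pair = outcome(labs_p, t0)
        if pair is None:
            continue
        baseline, followup = pair
        rows.append(
            {
                "patient_id": pid,
                "drug_id": drug_id,
                "t0": t0,
                "analyte": analyte,
                "baseline": baseline,
                "followup": followup,
                "delta": followup - baseline,
            }
        )
    cases = pd.DataFrame(
        rows,
        columns=["patient_id", "drug_id", "t0", "analyte", "baseline", "followup", "delta"],
    ).sort_values("patient_id").reset_index(drop=True)
    attrition["with_outcome"] = int(len(cases))

    suppressed = len(cases) < min_n
    if suppressed:
        cases = cases.iloc[0:0]
    return SeriesResult(
        drug_id=drug_id,
        analyte=analyte,
        dialect=dialect,
        cases=cases,
        attrition=attrition,
        suppressed=suppressed,
    )
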