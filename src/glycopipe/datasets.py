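"""Packaged reference tables.

``table1_hba1c`` and ``table2_glucose`` are the published two-site paired
t-test summaries (one row per drug: n, mean change, 95% CI and p at a
discovery and a replication site) for HbA1c (%) and glucose (mg/dL).
``medication_groups`` assigns every drug appearing in those tables to one of
the three series groups (experimental / glucose_decreasing /
glucose_increasing) and to a pharmacological class used by the class-level
meta-analysis.

p-values printed as censored bounds (``<0.0001``) are parsed into a numeric
column ``p_*`` (the bound itself) plus a boolean ``p_*_censored`` flag; every
downstream comparison is one-sided against 0.05, so the bound is sufficient.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

_SITES = ("discovery", "replication")


def _data_path(name: str):
    return importlib.resources.files("glycopipe.data") / name


def _parse_p(col: pd.Series) -> tuple[pd.Series, pd.Series]:
    s = col.astype(str)
    censored = s.str.startswith("<")
    numeric = pd.to_numeric(s.str.lstrip("<"), errors="raise")
    return numeric, censored


def load_site_table(analyte: str) -> pd.DataFrame:
    """Load the published two-site summary table for ``hba1c`` or ``glucose``."""
    fname = {"hba1c": "table1_hba1c.csv", "glucose": "table2_glucose.csv"}
    try:
        path = _data_path(fname[analyte])
    except KeyError:
        raise ValueError(f"unknown analyte {analyte!r}") from None
    df = pd.read_csv(path)
    for site in _SITES:
        p, cens = _parse_p(df[f"p_{site}"])
        df[f"p_{site}"] = p
        df[f"p_{site}_censored"] = cens
    return df


def load_medication_groups() -> pd.DataFrame:
    """Drug -> series group and pharmacological class."""
    return pd.read_csv(_data_path("medication_groups.csv"))


def load_action_synonyms() -> dict[str, str]:
    """Editable synonym map normalizing mechanism-of-action labels."""
    df = pd.read_csv(_data_path("action_synonyms.csv"))
    return dict(zip(df["synonym"], df["action"]))
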