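"""Patient cohort table and summary statistics.

The packaged fixture transcribes the 59-patient clinical table of the
study: 40 multiple sclerosis cases (cases 1-40, split into the working
forms G+/M-, G+/M+, spinal and primary progressive), 9 neuromyelitis
optica cases (41-49) and 10 non-inflammatory neurological controls
(50-59).  Three grouping schemes are supported:

* ``coarse``    — Control / MS / NMO (all 59 records);
* ``classical`` — RMS / SPMS / PPMS over the 40 MS cases, assigned by
  each case's clinical course (CIS is counted within RMS; spinal cases
  are assigned by their RRMS/SPMS course);
* ``working``   — G+/M- / G+/M+ / Spinal / PPMS over the 40 MS cases.

Group means and SDs (n-1 denominator) exclude missing values pairwise;
``N.A.`` and ``U.`` are explicit missing markers, never zeros.  The
severity score (MSSS) is carried as printed where present and never
recomputed, since it requires an external population reference table.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_table1_fixture",
    "load_table1_raw",
    "write_table1_raw",
    "assign_groups",
    "summarize",
    "group_tests",
    "GROUPINGS",
]

MISSING_MARKERS = ("N.A.", "U.")

_WORKING_FORM_MAP = {
    "RMS (G+/M−)": "RMS_GMminus",  # unicode minus, as printed
    "RMS (G+/M-)": "RMS_GMminus",
    "RMS (G+/M+)": "RMS_GMplus",
    "Spinal MS": "SPINAL",
    "PPMS": "PPMS",
    "NMO": "NMO",
    "CONTROL": "CONTROL",
}

GROUPINGS = ("coarse", "classical", "working")


def _fixture_path() -> Path:
    return Path(str(resources.files("metaboflux").joinpath("data/table1_cohort.csv")))


def load_table1_raw(path: str | Path | None = None) -> pd.DataFrame:
    """The fixture verbatim: every cell a string, headers as printed."""
    src = Path(path) if path is not None else _fixture_path()
    if not src.exists():
        raise FileNotFoundError(f"cohort fixture not found: {src}")
    return pd.read_csv(src, dtype=str)


def write_table1_raw(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, lineterminator="\n")


def load_table1_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Parsed cohort table (one row per patient, typed columns).

    Columns: case_id, gender, age, working_form (canonical label),
    clinical_form (as printed), progression_time, edss, ocgb, ocmb,
    aqp4, treatment.  Raises if the fixture is absent or violates the
    structural invariants (59 records, valid EDSS steps, controls with
    no disability scores).
    """
    raw = load_table1_raw(path)
    expected_cols = [
        "Case", "G", "Age", "Working Clinical Form", "Clinical Form",
        "P.T.", "Actual EDSS", "OCGB IgG", "OCMB IgM", "Ac-AQ4", "T",
    ]
    if list(raw.columns) != expected_cols:
        raise ValueError(f"cohort fixture corrupted: columns {list(raw.columns)}")

    def clean(col: pd.Series) -> pd.Series:
        return col.where(~col.isin(MISSING_MARKERS))

    table = pd.DataFrame(
        {
            "case_id": raw["Case"].astype(int),
            "gender": raw["G"],
            "age": raw["Age"].astype(float),
            "working_form": raw["Working Clinical Form"].map(_WORKING_FORM_MAP),
            "clinical_form": raw["Clinical Form"],
            "progression_time": pd.to_numeric(clean(raw["P.T."])),
            "edss": pd.to_numeric(clean(raw["Actual EDSS"])),
            "ocgb": clean(raw["OCGB IgG"]),
            "ocmb": clean(raw["OCMB IgM"]),
            "aqp4": clean(raw["Ac-AQ4"]),
            "treatment": raw["T"],
        }
    )
    if len(table) != 59:
        raise ValueError(f"cohort fixture corrupted: {len(table)} records, expected 59")
    if table["working_form"].isna().any():
        bad = raw.loc[table["working_form"].isna(), "Working Clinical Form"].tolist()
        raise ValueError(f"unrecognised working forms: {bad}")
    if (table["age"] <= 0).any():
        raise ValueError("non-positive patient age")
    edss = table["edss"].dropna()
    if ((edss * 2) % 1 != 0).any() or (edss < 0).any() or (edss > 10).any():
        raise ValueError("EDSS values must lie on the 0-10 half-point scale")
    controls = table["working_form"] == "CONTROL"
    if not (
        table.loc[controls, "edss"].isna().all()
        and table.loc[controls, "progression_time"].isna().all()
    ):
        raise ValueError("control records must have no EDSS or progression time")
    return table


def assign_groups(table: pd.DataFrame, grouping: str) -> pd.Series:
    """Group label per record under a scheme; NaN for records outside it."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {GROUPINGS}")
    wf = table["working_form"]
    if grouping == "coarse":
        return pd.Series(
            np.where(wf == "CONTROL", "Control", np.where(wf == "NMO", "NMO", "MS")),
            index=table.index,
        )
    ms = ~wf.isin(["CONTROL", "NMO"])
    if grouping == "classical":
        # CIS counted within RMS; spinal cases assigned by clinical course
        mapping = {"RRMS": "RMS", "CIS": "RMS", "SPMS": "SPMS", "PPMS": "PPMS"}
        labels = table["clinical_form"].map(mapping)
        return labels.where(ms)
    labels = wf.map(
        {"RMS_GMminus": "G+/M-", "RMS_GMplus": "G+/M+", "SPINAL": "Spinal", "PPMS": "PPMS"}
    )
    return labels.where(ms)


_GROUP_ORDERS = {
    "coarse": ["Control", "MS", "NMO"],
    "classical": ["RMS", "SPMS", "PPMS"],
    "working": ["G+/M-", "G+/M+", "Spinal", "PPMS"],
}

_SUMMARY_VARS = ("age", "edss", "progression_time")


def summarize(table: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-group n, female share, and mean/SD of age, EDSS and
    progression time (full precision; round for display)."""
    labels = assign_groups(table, grouping)
    rows = []
    for group in _GROUP_ORDERS[grouping]:
        sub = table[labels == group]
        row: dict[str, object] = {
            "group": group,
            "n": len(sub),
            "female_count": int((sub["gender"] == "F").sum()),
        }
        row["percent_female"] = (
            100.0 * row["female_count"] / row["n"] if row["n"] else np.nan
        )
        for var in _SUMMARY_VARS:
            vals = sub[var].dropna()
            row[f"{var}_n"] = len(vals)
            row[f"{var}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def render_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """One-decimal rendering of a summary frame (display convention)."""
    out = summary.copy()
    out["percent_female"] = out["percent_female"].round(1)
    for var in _SUMMARY_VARS:
        out[f"{var}_mean"] = out[f"{var}_mean"].round(1)
        out[f"{var}_sd"] = out[f"{var}_sd"].round(1)
    return out


def group_tests(
    table: pd.DataFrame, grouping: str, welch: bool = False
) -> dict[str, float]:
    """Between-group tests mirroring the cohort tables.

    Gender: chi-square on the gender-by-group contingency table, no
    continuity correction.  Continuous variables: one-way ANOVA when at
    least three groups have data, a two-sample t-test (pooled variance
    unless ``welch``) when exactly two do; omitted with a warning
    otherwise.  Keys are ``gender_chi2`` and ``<var>_<test>``.
    """
    labels = assign_groups(table, grouping)
    present = labels.dropna()
    sub = table.loc[present.index]
    results: dict[str, float] = {}

    contingency = pd.crosstab(sub["gender"], present)
    chi2 = stats.chi2_contingency(contingency.to_numpy(), correction=False)
    results["gender_chi2"] = float(chi2.pvalue)

    for var in _SUMMARY_VARS:
        samples = [
            sub.loc[present == g, var].dropna().to_numpy()
            for g in _GROUP_ORDERS[grouping]
        ]
        samples = [s for s in samples if len(s) >= 2]
        if len(samples) >= 3:
            results[f"{var}_anova"] = float(stats.f_oneway(*samples).pvalue)
        elif len(samples) == 2:
            t = stats.ttest_ind(samples[0], samples[1], equal_var=not welch)
            results[f"{var}_ttest"] = float(t.pvalue)
        else:
            warnings.warn(
                f"{var}: fewer than 2 groups with data under {grouping!r}; "
                "statistic omitted",
                stacklevel=2,
            )
    return results
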