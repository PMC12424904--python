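"""Plain-text interchange formats and input validation.

Cohorts travel as tab-separated text with a header row (missing values as
empty fields, occupation histories serialized as ``year:class;year:class``);
rate tables as comma-separated text; every result table is delimiter-
separated text with ``#``-prefixed header comments carrying the config hash
and seed for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .harmonize import format_occupation_history, parse_occupation_history
from .synthetic_cohort import COHORT_COLUMNS

__all__ = [
    "write_table",
    "read_table",
    "write_cohort",
    "read_cohort",
    "write_rates",
    "read_rates",
    "validate_inputs",
]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sep: str = "\t",
    header_comments: Optional[dict] = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (header_comments or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep=sep, index=False, lineterminator="\n")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_cohort(
    cohort: pd.DataFrame, path: str | Path, header_comments: Optional[dict] = None
) -> None:
    out = cohort.copy()
    out["occupation_history"] = [
        format_occupation_history(h) for h in out["occupation_history"]
    ]
    write_table(out, path, sep="\t", header_comments=header_comments)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"occupation_history": "string"},
    )
    df["occupation_history"] = [
        parse_occupation_history(x) if pd.notna(x) and x != "" else None
        for x in df["occupation_history"]
    ]
    return df


def write_rates(
    rates: pd.DataFrame, path: str | Path, header_comments: Optional[dict] = None
) -> None:
    write_table(rates, path, sep=",", header_comments=header_comments)


def read_rates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def validate_inputs(cohort_path: str | Path, rates_path: str | Path) -> list[str]:
    """Structural and invariant checks on the input files.

    Returns a list of human-readable violation strings (empty when clean):
    missing columns, negative rates, cause-specific mortality exceeding
    all-cause, non-contiguous age bins, per-study PGS not standardized,
    event ages outside [0, 80], inconsistent event typing.
    """
    violations: list[str] = []
    cohort = read_cohort(cohort_path)
    rates = read_rates(rates_path)

    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        violations.append(f"cohort: missing columns {missing}")
    rate_cols = [
        "age_lo", "age_hi", "sex", "incidence", "prevalence", "mort_all", "mort_cause",
    ]
    missing_r = [c for c in rate_cols if c not in rates.columns]
    if missing_r:
        violations.append(f"rates: missing columns {missing_r}")
    if missing or missing_r:
        return violations

    for col in ("incidence", "prevalence", "mort_all", "mort_cause"):
        bad = rates.index[rates[col] < 0]
        for row in bad:
            violations.append(f"rates row {row}: negative {col}")
    bad = rates.index[rates["mort_cause"] > rates["mort_all"]]
    for row in bad:
        violations.append(f"rates row {row}: mort_cause exceeds mort_all")
    for sex, sub in rates.groupby("sex"):
        sub = sub.sort_values("age_lo")
        if not np.allclose(
            sub["age_lo"].to_numpy()[1:], sub["age_hi"].to_numpy()[:-1]
        ):
            violations.append(f"rates ({sex}): age bins not contiguous")

    for study, sub in cohort.groupby("study_id"):
        x = sub["pgs"].to_numpy(dtype=float)
        if x.size >= 2:
            if abs(x.mean()) > 1e-6 or abs(x.std(ddof=1) - 1.0) > 0.01:
                violations.append(
                    f"cohort study {study}: PGS not standardized "
                    f"(mean={x.mean():.4f}, sd={x.std(ddof=1):.4f})"
                )
    bad_age = cohort.index[(cohort["event_age"] < 0) | (cohort["event_age"] > 80)]
    for row in bad_age:
        violations.append(f"cohort row {row}: event_age outside [0, 80]")
    bad_type = cohort.index[~cohort["event_type"].isin([0, 1, 2])]
    for row in bad_type:
        violations.append(f"cohort row {row}: unknown event_type")
    return violations
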