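"""Harmonization rules applied before any model fitting.

Three pieces: ISCED education dichotomization (low <= 4, high >= 5), the
iterative census-occupation resolution algorithm, and endpoint-level
inclusion filters (entry-age window, sex-restricted endpoints, whole-study
exclusions for discovery-GWAS overlap, follow-up truncation).
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import EndpointSpec

__all__ = [
    "HarmonizationError",
    "dichotomize_education",
    "resolve_occupation",
    "apply_endpoint_filters",
    "parse_occupation_history",
    "format_occupation_history",
    "INFORMATIVE_CLASSES",
]


class HarmonizationError(ValueError):
    pass


#: Occupation class codes: 1 self-employed, 2 upper-level, 3 lower-level
#: clerical, 4 manual, 5 students, 6 pensioners, 7 other, 8 unknown, 9 missing.
INFORMATIVE_CLASSES = frozenset({1, 2, 3, 4})

_CLASS_TO_LEVEL = {
    1: "self_employed",
    2: "upper_level",
    3: "lower_level",   # lower-level clerical and manual workers are combined
    4: "lower_level",
}


def dichotomize_education(isced: int) -> str:
    """Map an ISCED 1997 level (0-8) to the low/high dichotomy.

    Low is ISCED <= 4, high is ISCED >= 5.  Missing or out-of-range values
    raise :class:`HarmonizationError` so the caller can flag the record.
    """
    if isced is None or (isinstance(isced, float) and np.isnan(isced)):
        raise HarmonizationError("missing ISCED level")
    level = int(isced)
    if level != isced or not 0 <= level <= 8:
        raise HarmonizationError(f"ISCED level out of range: {isced!r}")
    return "low" if level <= 4 else "high"


def resolve_occupation(
    history: Mapping[int, int], reference_year: int
) -> Optional[str]:
    """Resolve a census occupation history to an analysis class.

    Selects the census year closest to ``reference_year`` (the event year
    for cases, end of follow-up for controls); ties go to the earlier
    census.  If the selected class is uninformative (students, pensioners,
    other, unknown, missing), earlier censuses are tried iteratively until
    an informative class (self-employed, upper-level, lower-level clerical,
    manual) is found.  Returns ``upper_level``, ``lower_level`` (clerical
    and manual combined), ``self_employed``, or None when no informative
    class exists at or before the selected census (the record is excluded).
    """
    if not history:
        raise HarmonizationError("empty occupation history")
    years = sorted(history)
    # closest year; ties (equidistant) resolved to the earlier census
    closest = min(years, key=lambda y: (abs(y - reference_year), y))
    idx = years.index(closest)
    for y in reversed(years[: idx + 1]):
        cls = history[y]
        if cls in INFORMATIVE_CLASSES:
            return _CLASS_TO_LEVEL[cls]
    return None


def parse_occupation_history(text: str) -> dict[int, int]:
    """Parse the serialized ``year:class;year:class`` occupation column."""
    if text is None or text == "" or (isinstance(text, float) and np.isnan(text)):
        return {}
    out: dict[int, int] = {}
    for item in str(text).split(";"):
        year, cls = item.split(":")
        out[int(year)] = int(cls)
    return out


def format_occupation_history(history: Mapping[int, int] | None) -> str:
    if not history:
        return ""
    return ";".join(f"{y}:{c}" for y, c in sorted(history.items()))


def apply_endpoint_filters(
    cohort: pd.DataFrame,
    spec: EndpointSpec,
    entry_age_range: tuple[float, float] = (35.0, 80.0),
) -> pd.DataFrame:
    """Apply endpoint-level inclusion rules and follow-up truncation.

    Drops records with study-entry age outside ``entry_age_range``, the
    disallowed sex for sex-restricted endpoints, and whole studies named in
    ``spec.excluded_studies``.  Events after ``spec.analysis_max_age``
    become censored at that age.  No other field is altered; row count is
    non-increasing.
    """
    lo, hi = entry_age_range
    out = cohort[(cohort["entry_age"] >= lo) & (cohort["entry_age"] <= hi)]
    if spec.sex_restriction == "female_only":
        out = out[out["sex"] == "female"]
    elif spec.sex_restriction == "male_only":
        out = out[out["sex"] == "male"]
    if spec.excluded_studies:
        out = out[~out["study_id"].isin(spec.excluded_studies)]
    out = out.copy()
    late = out["event_age"] > spec.analysis_max_age
    out.loc[late, "event_age"] = spec.analysis_max_age
    out.loc[late, "event_type"] = 0
    return out.reset_index(drop=True)
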