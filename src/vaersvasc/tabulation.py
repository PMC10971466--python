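"""Frequency, onset-day and age-of-onset tables.

The central statistic is the normalized frequency: adverse-event cases per
100,000 reports-with-symptoms in a stratum (a vaccine code, or a single year
of age). Two integer conventions occur in published tabulations and both are
explicit parameters here: round-half-away-from-zero (the per-vaccine table)
and truncation (the per-age table). A stratum with zero cases is reported as
an upper bound "<X" with X = floor(100000 / denominator), i.e. the frequency
that a single case would not have exceeded.

One published quirk is reproduced deliberately: the per-vaccine table's
denominator counts reports in a young-child age window (default ages 0–5)
while its numerator counts flagged reports at any age. The two age windows
are therefore independent parameters of :func:`vaccine_frequency_table`; see
``docs/methods.md`` for discussion.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROUND_NEAREST = "round_nearest"
TRUNCATE = "truncate"

BLANK = "Blank"  # onset-day label for missing NUMDAYS
NA_AGE = "N.A."  # age label for missing AGE_YRS


def _convert(value: float, convention: str) -> int:
    if convention == ROUND_NEAREST:
        # half away from zero; value is non-negative here
        return math.floor(value + 0.5)
    if convention == TRUNCATE:
        return math.trunc(value)
    raise ValueError(f"unknown rounding convention {convention!r}")


def zero_count_bound(denominator: int) -> str:
    """Upper-bound marker for a zero-case stratum: ``"<" + floor(1e5/den)``."""
    return f"<{100000 // denominator}"


def normalized_frequency(
    case_count: int, denominator: int, convention: str = ROUND_NEAREST
) -> int | str:
    """Cases per 100,000 reports-with-symptoms, as a printed integer.

    Returns the integer under the given convention when ``case_count > 0``
    and the ``"<X"`` upper-bound marker when ``case_count == 0``.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if case_count < 0:
        raise ValueError(f"case_count must be non-negative, got {case_count}")
    if case_count == 0:
        return zero_count_bound(denominator)
    return _convert(100000 * case_count / denominator, convention)


def _floor_age(age: float | None) -> int | None:
    return None if age is None else math.floor(age)


def _in_window(age: float | None, window: tuple[int, int] | None) -> bool:
    if window is None:
        return True
    if age is None:
        return False
    return window[0] <= math.floor(age) <= window[1]


def vaccine_frequency_table(
    reports,
    cases: pd.DataFrame,
    category: str,
    min_cases: int = 5,
    denominator_age_window: tuple[int, int] | None = (0, 5),
    numerator_age_window: tuple[int, int] | None = None,
    convention: str = ROUND_NEAREST,
) -> pd.DataFrame:
    """Per-vaccine case counts, denominators and normalized frequencies.

    denominator
        distinct reports listing the vaccine code, having at least one
        symptom term, with floor(age) inside ``denominator_age_window``
        (``None`` = no age restriction; missing ages fail any window).
    case count
        flagged reports listing the code, restricted only by
        ``numerator_age_window`` (default unrestricted).

    A report listing k vaccine codes contributes to all k rows (no fractional
    attribution). Rows with fewer than ``min_cases`` cases are dropped, as
    are rows whose denominator is zero (logged).
    """
    if min_cases < 0:
        raise ValueError("min_cases must be >= 0")
    flag = cases[category]
    counts: dict[str, int] = {}
    denoms: dict[str, int] = {}
    for report in reports:
        if not report.symptom_terms:
            continue
        is_case = bool(flag.get(report.vaers_id, False))
        for code in report.vaccine_codes:
            if _in_window(report.age_years, denominator_age_window):
                denoms[code] = denoms.get(code, 0) + 1
            if is_case and _in_window(report.age_years, numerator_age_window):
                counts[code] = counts.get(code, 0) + 1

    rows = []
    for code in sorted(set(counts) | set(denoms)):
        case_count = counts.get(code, 0)
        denominator = denoms.get(code, 0)
        if case_count < min_cases:
            continue
        if denominator == 0:
            logger.warning(
                "vaccine %s: %d case(s) but empty denominator window; dropped",
                code,
                case_count,
            )
            continue
        rows.append(
            {
                "vaccine_code": code,
                "case_count": case_count,
                "denominator": denominator,
                "frequency_per_100k": normalized_frequency(
                    case_count, denominator, convention
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["vaccine_code", "case_count", "denominator", "frequency_per_100k"]
    )


def onset_table(
    reports,
    cases: pd.DataFrame,
    category: str,
    vaccine_codes: Sequence[str],
    max_day: int = 30,
) -> pd.DataFrame:
    """Onset-day distribution of flagged reports, per vaccine code.

    Rows are the ``Blank`` marker (missing onset interval) followed by days
    0..``max_day``; flagged reports with onset beyond ``max_day`` are excluded
    from the printed rows with a logged count. A report listing several of
    the requested codes contributes to each matching column.
    """
    if max_day < 0:
        raise ValueError("max_day must be >= 0")
    flag = cases[category]
    index = [BLANK] + list(range(max_day + 1))
    table = pd.DataFrame(0, index=pd.Index(index, name="onset_day"), columns=list(vaccine_codes))
    overflow = 0
    for report in reports:
        if not bool(flag.get(report.vaers_id, False)):
            continue
        day = report.onset_interval_days
        if day is not None and day > max_day:
            overflow += 1
            continue
        row = BLANK if day is None else day
        for code in report.vaccine_codes:
            if code in table.columns:
                table.loc[row, code] += 1
    if overflow:
        logger.info("onset_table: %d flagged report(s) beyond day %d excluded", overflow, max_day)
    return table


def age_table(
    reports,
    cases: pd.DataFrame,
    categories: Sequence[str],
    max_age: int = 20,
) -> pd.DataFrame:
    """Age-of-onset counts per category, ages binned as floor(AGE_YRS).

    Rows are the ``N.A.`` marker (missing age) followed by ages
    0..``max_age``; flagged reports older than ``max_age`` are excluded from
    the printed rows with a logged count.
    """
    if max_age < 0:
        raise ValueError("max_age must be >= 0")
    index = [NA_AGE] + list(range(max_age + 1))
    table = pd.DataFrame(0, index=pd.Index(index, name="age"), columns=list(categories))
    overflow = 0
    for report in reports:
        age_bin = _floor_age(report.age_years)
        if age_bin is not None and age_bin > max_age:
            if any(bool(cases[c].get(report.vaers_id, False)) for c in categories):
                overflow += 1
            continue
        row = NA_AGE if age_bin is None else age_bin
        for category in categories:
            if bool(cases[category].get(report.vaers_id, False)):
                table.loc[row, category] += 1
    if overflow:
        logger.info("age_table: %d flagged report(s) older than %d excluded", overflow, max_age)
    return table


def age_frequency_table(
    reports,
    cases: pd.DataFrame,
    category: str,
    vaccine_code: str,
    convention: str = TRUNCATE,
    age_range: tuple[int, int] = (1, 30),
) -> pd.DataFrame:
    """Per-single-year-age frequencies for one vaccine code.

    Numerator and denominator are both restricted to reports listing
    ``vaccine_code`` with at least one symptom term and floor(age) equal to
    the row's age. Zero-case ages get ``"<X"`` bound markers; ages with an
    empty denominator get a missing frequency.
    """
    flag = cases[category]
    lo, hi = age_range
    counts = {age: 0 for age in range(lo, hi + 1)}
    denoms = {age: 0 for age in range(lo, hi + 1)}
    for report in reports:
        if vaccine_code not in report.vaccine_codes or not report.symptom_terms:
            continue
        age_bin = _floor_age(report.age_years)
        if age_bin is None or not (lo <= age_bin <= hi):
            continue
        denoms[age_bin] += 1
        if bool(flag.get(report.vaers_id, False)):
            counts[age_bin] += 1
    rows = []
    for age in range(lo, hi + 1):
        denominator = denoms[age]
        frequency: int | str | None
        if denominator == 0:
            frequency = None
        else:
            frequency = normalized_frequency(counts[age], denominator, convention)
        rows.append(
            {
                "age": age,
                "case_count": counts[age],
                "denominator": denominator,
                "frequency_per_100k": frequency,
            }
        )
    return pd.DataFrame(rows, columns=["age", "case_count", "denominator", "frequency_per_100k"])


def write_table_csv(table: pd.DataFrame, path) -> None:
    """Write a table as CSV, keeping Blank/N.A. labels and ``<X`` markers verbatim."""
    index = table.index.name is not None
    table.to_csv(path, index=index)


def write_table_text(table: pd.DataFrame, path) -> None:
    """Write a table as aligned plain text mirroring the published layout."""
    frame = table.reset_index() if table.index.name is not None else table
    widths = [
        max(len(str(col)), *(len(str(v)) for v in frame[col])) if len(frame) else len(str(col))
        for col in frame.columns
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "  ".join(str(c).ljust(w) for c, w in zip(frame.columns, widths)).rstrip() + "\n"
        )
        for _, row in frame.iterrows():
            cells = ["" if v is None or v is pd.NA else str(v) for v in row]
            fh.write("  ".join(c.ljust(w) for c, w in zip(cells, widths)).rstrip() + "\n")
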