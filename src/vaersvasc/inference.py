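"""Statistical layer: chi-squared tests against a background rate, Bonferroni
correction, and age-band summary statistics.

Each vaccine stratum's case count is compared against a population background
incidence (Kawasaki disease: 9–20 per 100,000 per year in the literature; 20
is the default) with a two-cell goodness-of-fit chi-squared test: observed
(cases, non-cases) versus expected (n·p0, n·(1−p0)) with p0 the background
rate per report. The background is quoted per year while the frequencies are
per report; the default comparison treats the rate as per-report (the only
dimensionally direct reading), with an optional multiplicative
``year_scale`` for sensitivity analyses. Family-wise error over the set of
vaccine strata is controlled by Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class BackgroundRate:
    """Background incidence per 100,000, with a free-text period note."""

    rate_per_100k: float = 20.0
    period_note: str = "per year; compared per report by default"

    def __post_init__(self) -> None:
        if not (0 < self.rate_per_100k < 100000):
            raise ValueError(
                f"rate_per_100k must be in (0, 100000), got {self.rate_per_100k}"
            )

    @property
    def proportion(self) -> float:
        return self.rate_per_100k / 100000.0


@dataclass
class TestResult:
    """Outcome of one chi-squared test."""

    stratum: str
    statistic: float
    df: int
    p_value: float
    alpha_corrected: float | None = None
    significant: bool | None = None
    low_expected: bool = False  # an expected cell < 1: approximation caveat

    def apply_alpha(self, alpha_corrected: float) -> "TestResult":
        self.alpha_corrected = alpha_corrected
        self.significant = self.p_value < alpha_corrected
        return self


@dataclass
class GroupSummary:
    """Mean and sample SD (n−1 denominator) of a group of frequencies."""

    label: str
    values: list[float] = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")


def chi_squared_vs_background(
    case_count: int,
    denominator: int,
    background: BackgroundRate,
    stratum: str = "",
    continuity_correction: bool = False,
    method: str = "chisq",
    year_scale: float = 1.0,
    alpha: float | None = None,
) -> TestResult:
    """Two-cell goodness-of-fit of one stratum's count against the background.

    ``method="chisq"`` is the Pearson statistic Σ(O−E)²/E with df = 1 and an
    upper-tail p-value; ``method="binom"`` is an exact two-sided binomial
    test, preferable when the expected case cell is small. No continuity
    correction is applied unless requested. ``year_scale`` multiplies the
    background proportion (1.0 compares the quoted rate per report).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= case_count <= denominator:
        raise ValueError("case_count must be in [0, denominator]")
    p0 = background.proportion * year_scale
    if not 0 < p0 < 1:
        raise ValueError(f"scaled background proportion {p0} outside (0, 1)")
    expected = np.array([denominator * p0, denominator * (1 - p0)])
    observed = np.array([case_count, denominator - case_count], dtype=float)
    low_expected = bool(expected.min() < 1.0)
    if method == "binom":
        p_value = stats.binomtest(case_count, denominator, p0).pvalue
        # report the Pearson statistic alongside the exact p for context
        statistic = float((((np.abs(observed - expected)) ** 2) / expected).sum())
    elif method == "chisq":
        diff = np.abs(observed - expected)
        if continuity_correction:
            diff = np.maximum(diff - 0.5, 0.0)
        statistic = float((diff**2 / expected).sum())
        p_value = float(stats.chi2.sf(statistic, df=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    result = TestResult(
        stratum=stratum,
        statistic=statistic,
        df=1,
        p_value=float(p_value),
        low_expected=low_expected,
    )
    if alpha is not None:
        result.apply_alpha(alpha)
    return result


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def evaluate_all_vaccines(
    freq_table: pd.DataFrame,
    background: BackgroundRate,
    alpha: float = 0.05,
    exclude_codes: tuple[str, ...] = (),
    **test_kwargs,
) -> tuple[list[TestResult], dict]:
    """Test every vaccine row of a frequency table against the background.

    Rows whose code is in ``exclude_codes`` are dropped before testing, so
    the Bonferroni denominator m is the number of retained rows; by default
    every row is tested, which on the published 30-row per-vaccine table
    gives the 30-test family with corrected threshold 0.05/30. Pass
    ``exclude_codes=("UNK",)`` to drop the unknown-vaccine stratum as a
    sensitivity analysis. Returns the per-row results and a summary with the
    number significant and the minimum frequency among significant rows.
    """
    if freq_table.empty:
        raise ValueError("freq_table must be nonempty")
    stratum_col = "vaccine_code" if "vaccine_code" in freq_table.columns else "stratum"
    retained = freq_table[~freq_table[stratum_col].isin(exclude_codes)]
    m = len(retained)
    threshold = bonferroni_threshold(alpha, m)
    results = []
    for _, row in retained.iterrows():
        result = chi_squared_vs_background(
            int(row["case_count"]),
            int(row["denominator"]),
            background,
            stratum=str(row[stratum_col]),
            **test_kwargs,
        ).apply_alpha(threshold)
        results.append(result)
    significant = [r for r in results if r.significant]
    sig_freqs = [
        row["frequency_per_100k"]
        for (_, row), r in zip(retained.iterrows(), results)
        if r.significant and isinstance(row["frequency_per_100k"], (int, np.integer))
    ]
    summary = {
        "n_tests": m,
        "alpha": alpha,
        "alpha_corrected": threshold,
        "n_significant": len(significant),
        "min_significant_frequency": min(sig_freqs) if sig_freqs else None,
    }
    return results, summary


def results_to_frame(results: list[TestResult], freq_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate test results, optionally merged with the source frequency rows."""
    frame = pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "alpha_corrected": [r.alpha_corrected for r in results],
            "significant": [r.significant for r in results],
            "low_expected": [r.low_expected for r in results],
        }
    )
    if freq_table is not None:
        stratum_col = "vaccine_code" if "vaccine_code" in freq_table.columns else "stratum"
        merged = freq_table.rename(columns={stratum_col: "stratum"})
        frame = merged.merge(frame, on="stratum", how="right")
    return frame


def _bound_value(marker: str) -> float:
    """Integer from a ``"<X"`` upper-bound marker."""
    return float(marker.lstrip("<"))


def group_summary(
    freq_rows: pd.DataFrame,
    age_lo: int,
    age_hi: int,
    zero_count_policy: str = "exclude",
    label: str | None = None,
) -> GroupSummary:
    """Mean and sample SD of per-age frequencies over an age band.

    ``zero_count_policy`` decides what a zero-case age contributes:
    ``"exclude"`` drops it, ``"use_bound"`` substitutes the integer from its
    ``"<X"`` marker (i.e. treats the bound as the value).
    """
    if zero_count_policy not in ("exclude", "use_bound"):
        raise ValueError(f"unknown zero_count_policy {zero_count_policy!r}")
    band = freq_rows[(freq_rows["age"] >= age_lo) & (freq_rows["age"] <= age_hi)]
    values: list[float] = []
    for freq in band["frequency_per_100k"]:
        if freq is None or (isinstance(freq, float) and np.isnan(freq)):
            continue
        if isinstance(freq, str):
            if zero_count_policy == "use_bound":
                values.append(_bound_value(freq))
            continue
        values.append(float(freq))
    if len(values) < 2:
        raise ValueError(
            f"need at least 2 frequency values in ages {age_lo}-{age_hi}, got {len(values)}"
        )
    arr = np.asarray(values, dtype=float)
    return GroupSummary(
        label=label or f"ages {age_lo}-{age_hi}",
        values=values,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
    )
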