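"""Expected adverse-event counts under background-only and vaccine-augmented
reporting, a stochastic simulator, and a cross-vaccine homogeneity test.

The model: for a population vector P_age (ages 0..100), an adverse event
occurring on day d after vaccination is reported with probability diminished
by a reporting-bias multiplier r_day (declining in d), and individuals of age
a experience the background event with per-day probability b_age[a]. The
expected number of reported background events over an n-day collection
horizon is the double sum

    E_background = Σ_age P_age · Σ_day r_day · b_age .

A vaccine adds an age-indexed attributable excess v_age:

    E_vaccine = Σ_age P_age · Σ_day r_day · (v_age + b_age) ,

which reduces to the background expression when v_age is zero (the
no-association hypothesis). The model specifies expectations only; the
simulator draws per-(age, day) cell counts as Poisson with the cell mean
P·r·(v+b) — the standard rare-event approximation — with an exact
Bernoulli-per-person mode for small populations.

The homogeneity test operationalizes the competing hypotheses: if vaccines
only reflect background incidence, per-vaccine case rates are exchangeable,
and a chi-squared test of independence on the K×2 cases/non-cases table
(df = K−1) should not reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .inference import TestResult

N_AGES = 101  # ages 0..100 inclusive


@dataclass
class BackgroundModelParams:
    """Parameters of the reporting model.

    P_age : population size per single year of age 0..100 (length 101)
    r_day : reporting-bias multiplier per day 0..n_days, each in [0, 1]
    b_age : background per-person per-day event probability by age
    v_age : vaccine-attributable additive excess by age (zero vector under
            the no-association hypothesis)
    """

    P_age: np.ndarray
    r_day: np.ndarray
    b_age: np.ndarray
    v_age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P_age = np.asarray(self.P_age, dtype=float)
        self.r_day = np.asarray(self.r_day, dtype=float)
        self.b_age = np.asarray(self.b_age, dtype=float)
        if self.v_age is None:
            self.v_age = np.zeros_like(self.b_age)
        self.v_age = np.asarray(self.v_age, dtype=float)
        for name in ("P_age", "b_age", "v_age"):
            vec = getattr(self, name)
            if vec.shape != (N_AGES,):
                raise ValueError(f"{name} must have length {N_AGES}, got {vec.shape}")
            if (vec < 0).any():
                raise ValueError(f"{name} must be non-negative")
        if self.r_day.ndim != 1 or self.r_day.size < 1:
            raise ValueError("r_day must be a non-empty vector")
        if ((self.r_day < 0) | (self.r_day > 1)).any():
            raise ValueError("r_day entries must lie in [0, 1]")
        if ((self.b_age + self.v_age) > 1).any():
            raise ValueError("b_age + v_age must be <= 1 elementwise")

    @property
    def n_days(self) -> int:
        return self.r_day.size - 1

    def with_v_scale(self, scale: float) -> "BackgroundModelParams":
        return replace(self, v_age=self.v_age * scale)


@dataclass
class SimulatedCounts:
    """Simulated reported-event counts per (age, day) cell."""

    counts: np.ndarray  # shape (101, n_days + 1), non-negative integers
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = int(self.counts.sum())


def expected_events_background(params: BackgroundModelParams) -> float:
    """Expected reported background events: Σ_age P_age Σ_day r_day b_age."""
    return float(params.r_day.sum() * (params.P_age * params.b_age).sum())


def expected_events_vaccine(params: BackgroundModelParams) -> float:
    """Expected reported events with the vaccine-attributable excess added."""
    return float(
        params.r_day.sum() * (params.P_age * (params.b_age + params.v_age)).sum()
    )


def cell_means(params: BackgroundModelParams) -> np.ndarray:
    """Per-(age, day) expected counts P_age · r_day · (v_age + b_age)."""
    rate = params.b_age + params.v_age
    return params.P_age[:, None] * rate[:, None] * params.r_day[None, :]


def simulate_counts(
    params: BackgroundModelParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
    method: str = "poisson",
) -> SimulatedCounts:
    """Draw one realization of the (age, day) count matrix.

    ``method="poisson"`` draws each cell as Poisson with its mean (rare-event
    approximation); ``method="bernoulli"`` draws Binomial(P_age, r·(v+b))
    per cell, exact for integer populations. Identical seeds give identical
    output.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if method == "poisson":
        counts = rng.poisson(cell_means(params))
    elif method == "bernoulli":
        trials = np.rint(params.P_age).astype(np.int64)
        prob = np.clip(
            (params.b_age + params.v_age)[:, None] * params.r_day[None, :], 0.0, 1.0
        )
        counts = rng.binomial(trials[:, None], prob)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SimulatedCounts(counts=counts)


def homogeneity_test(per_vaccine: list[tuple[int, int]]) -> TestResult:
    """Chi-squared test of independence on the K×2 cases/non-cases table.

    Rejection indicates per-vaccine case rates are not exchangeable — the
    observed frequencies cannot all reflect one shared background rate.
    Degenerate tables (all-zero or all-full case column) return statistic 0,
    p = 1.
    """
    if len(per_vaccine) < 2:
        raise ValueError("need at least 2 strata")
    table = []
    for case_count, denominator in per_vaccine:
        if denominator <= 0:
            raise ValueError("denominators must be positive")
        if not 0 <= case_count <= denominator:
            raise ValueError("case_count must be in [0, denominator]")
        table.append([case_count, denominator - case_count])
    arr = np.asarray(table, dtype=float)
    df = arr.shape[0] - 1
    if (arr.sum(axis=0) == 0).any():
        return TestResult(stratum="homogeneity", statistic=0.0, df=df, p_value=1.0)
    statistic, p_value, _, expected = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        stratum="homogeneity",
        statistic=float(statistic),
        df=df,
        p_value=float(p_value),
        low_expected=bool(expected.min() < 1.0),
    )


def hypothesis_power_curve(
    base_params: BackgroundModelParams,
    v_grid: list[float],
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
    n_strata: int = 10,
) -> list[tuple[float, float]]:
    """Rejection rate of the homogeneity test versus excess-rate scale.

    For each scale in ``v_grid``, ``n_reps`` replicate cohorts of
    ``n_strata`` vaccine strata are simulated: every stratum draws its case
    count from the background model; one stratum additionally receives the
    excess ``scale · v_age``. The homogeneity test is run per replicate and
    the rejection fraction at ``alpha`` reported. The entry at scale 0
    estimates the type-I error.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable rate estimate")
    if n_strata < 2:
        raise ValueError("n_strata must be >= 2")
    denominator = int(round(base_params.P_age.sum()))
    background_mean = expected_events_background(base_params)
    root = np.random.SeedSequence(seed)
    curve = []
    for scale, seq in zip(v_grid, root.spawn(len(v_grid))):
        rng = np.random.default_rng(seq)
        excess_mean = expected_events_vaccine(base_params.with_v_scale(scale))
        rejections = 0
        for _ in range(n_reps):
            counts = rng.poisson(background_mean, size=n_strata)
            counts[0] = rng.poisson(excess_mean)
            counts = np.minimum(counts, denominator)
            result = homogeneity_test(
                [(int(c), denominator) for c in counts]
            )
            if result.p_value < alpha:
                rejections += 1
        curve.append((float(scale), rejections / n_reps))
    return curve


def make_stratum_params(
    n_reports: int = 5000,
    background_rate_per_100k: float = 20.0,
    rho: float = 0.9,
    n_days: int = 30,
) -> BackgroundModelParams:
    """Parameters for one vaccine stratum of ``n_reports`` reports.

    The population is spread uniformly over ages 0..100 and the per-cell
    background probability is chosen so the expected case total equals
    ``n_reports · background_rate_per_100k / 100000`` under the geometric
    reporting decay r_day = rho**day. ``v_age`` is set equal to ``b_age`` so
    that scaling it by s (``with_v_scale``) yields a total rate of
    (1 + s) × background.
    """
    P_age = np.full(N_AGES, n_reports / N_AGES)
    r_day = rho ** np.arange(n_days + 1)
    b = (background_rate_per_100k / 100000.0) / r_day.sum()
    b_age = np.full(N_AGES, b)
    return BackgroundModelParams(P_age=P_age, r_day=r_day, b_age=b_age, v_age=b_age.copy())


def params_from_dict(doc: dict) -> BackgroundModelParams:
    """Build params from a plain mapping (e.g. parsed YAML).

    Vectors may be given in full, or compactly: ``P_age``/``b_age``/``v_age``
    as scalars (broadcast over all 101 ages) and ``r_day`` as
    ``{"rho": g, "n_days": n}`` for geometric decay r_day = rho**day.
    """
    def age_vec(value) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        return np.full(N_AGES, float(arr)) if arr.ndim == 0 else arr

    r_spec = doc["r_day"]
    if isinstance(r_spec, dict):
        rho, n_days = float(r_spec["rho"]), int(r_spec["n_days"])
        r_day = rho ** np.arange(n_days + 1)
    else:
        r_day = np.asarray(r_spec, dtype=float)
    return BackgroundModelParams(
        P_age=age_vec(doc["P_age"]),
        r_day=r_day,
        b_age=age_vec(doc["b_age"]),
        v_age=age_vec(doc.get("v_age", 0.0)),
    )
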