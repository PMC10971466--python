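"""Synthetic VAERS-format data with sidecar ground truth.

Emits file triplets in the exact dialect read by :mod:`vaersvasc.vaers_io`
(``<YEAR>VAERSDATA.csv`` / ``VAERSSYMPTOMS`` / ``VAERSVAX``) generated under
the vaccine-augmented reporting model: each configured vaccine stratum draws
cases at background + excess rate per 100,000 reports, onset days follow a
geometric reporting decay P(day = d) ∝ rho**d, and the messy features of real
exports are emulated — multi-vaccine reports, continuation symptom rows for
reports with more than five terms, missing ages and onset days, decoy
preferred terms including superstrings of the searched terms (e.g.
"Cutaneous vasculitis" versus "Vasculitis").

The ground truth (per-report flags, per-vaccine counts and denominators, and
the generating parameters) is written as a JSON sidecar, never embedded in
the VAERS files themselves, so the pipeline under test cannot read it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .case_extraction import HS, KD, MIS_C, VASCULITIS

DEFAULT_DECOY_TERMS = [
    "Pyrexia",
    "Rash",
    "Urticaria",
    "Headache",
    "Vomiting",
    "Diarrhoea",
    "Fatigue",
    "Injection site erythema",
    "Cutaneous vasculitis",  # superstring decoy for the "Vasculitis" term
    "Retinal vasculitis",    # ditto
]

#: preferred term planted for each supported case category
CATEGORY_TERMS = {
    KD: "Kawasaki's disease",
    HS: "Henoch-Schonlein purpura",
    MIS_C: "Multisystem inflammatory syndrome in children",
    VASCULITIS: "Vasculitis",
}

_STATES = ["CA", "TX", "NY", "FL", "WA", "OH", ""]

DATA_HEADER = ["VAERS_ID", "RECVDATE", "STATE", "AGE_YRS", "SEX", "NUMDAYS"]
SYMPTOMS_HEADER = ["VAERS_ID"] + [
    col for i in range(1, 6) for col in (f"SYMPTOM{i}", f"SYMPTOMVERSION{i}")
]
VAX_HEADER = ["VAERS_ID", "VAX_TYPE", "VAX_MANU", "VAX_DOSE_SERIES"]

TRUTH_FILENAME = "ground_truth.json"


@dataclass
class VaccineSpec:
    """One synthetic vaccine stratum.

    Rates are per 100,000 reports: ``background_rate_per_100k`` is what every
    stratum shares under the no-association hypothesis; a nonzero
    ``excess_rate_per_100k`` adds a vaccine-attributable excess. The default
    background of 20/100k matches the literature Kawasaki-disease rate used
    throughout the package.
    """

    code: str
    n_reports: int
    age_dist: tuple = ("uniform", 0.0, 5.0)
    background_rate_per_100k: float = 20.0
    excess_rate_per_100k: float = 0.0

    @property
    def case_probability(self) -> float:
        return (self.background_rate_per_100k + self.excess_rate_per_100k) / 100000.0


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the study conditions."""

    vaccine_specs: list[VaccineSpec]
    case_category: str = KD
    onset_decay: float = 0.9          # geometric rho for the reporting decay
    max_onset_day: int = 30
    p_missing_age: float = 0.10
    p_missing_onset: float = 0.25
    p_coadmin: float = 0.30
    p_no_symptoms: float = 0.02
    decoy_terms: list[str] = field(default_factory=lambda: list(DEFAULT_DECOY_TERMS))
    symptoms_per_report: tuple = ("poisson", 2.0)  # 1 + Poisson(mean) terms
    seed: int = 0
    year: int = 2020

    def __post_init__(self) -> None:
        for name in ("p_missing_age", "p_missing_onset", "p_coadmin", "p_no_symptoms"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0 < self.onset_decay <= 1:
            raise ValueError("onset_decay must be in (0, 1]")
        if self.case_category not in CATEGORY_TERMS:
            raise ValueError(f"unsupported case_category {self.case_category!r}")
        for spec in self.vaccine_specs:
            if spec.n_reports < 0:
                raise ValueError("n_reports must be >= 0")
            if spec.background_rate_per_100k < 0 or spec.excess_rate_per_100k < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """Sidecar truth for one generated triplet."""

    case_category: str
    reports: dict[str, dict] = field(default_factory=dict)
    per_vaccine: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(**doc)


def _per_vaccine_truth(reports: dict[str, dict], category: str) -> dict[str, dict]:
    """Per-vaccine case counts and reports-with-symptoms denominators."""
    out: dict[str, dict] = {}
    for info in reports.values():
        if not info["symptom_terms"]:
            continue
        is_case = info["categories"].get(category, False)
        for code in info["vaccine_codes"]:
            entry = out.setdefault(code, {"cases": 0, "denominator": 0})
            entry["denominator"] += 1
            if is_case:
                entry["cases"] += 1
    return dict(sorted(out.items()))


def _draw_age(rng: np.random.Generator, dist: tuple) -> float:
    kind = dist[0]
    if kind == "uniform":
        return float(round(rng.uniform(dist[1], dist[2]), 1))
    if kind == "normal":
        return float(round(min(max(rng.normal(dist[1], dist[2]), 0.0), 119.0), 1))
    if kind == "fixed":
        return float(dist[1])
    raise ValueError(f"unknown age distribution {kind!r}")


def _draw_n_symptoms(rng: np.random.Generator, dist: tuple) -> int:
    kind = dist[0]
    if kind == "poisson":
        return 1 + int(rng.poisson(dist[1]))
    if kind == "uniform_int":
        return int(rng.integers(dist[1], dist[2] + 1))
    if kind == "fixed":
        return int(dist[1])
    raise ValueError(f"unknown symptom-count distribution {kind!r}")


def _draw_onset(rng: np.random.Generator, rho: float, max_day: int) -> int:
    weights = rho ** np.arange(max_day + 1)
    return int(rng.choice(max_day + 1, p=weights / weights.sum()))


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def _flags(planted_terms: list[str]) -> dict[str, bool]:
    term_set = set(planted_terms)
    return {cat: (term in term_set) for cat, term in CATEGORY_TERMS.items()}


def generate(config: SimConfig, out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Emit a VAERS triplet plus sidecar truth; deterministic under the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    case_term = CATEGORY_TERMS[config.case_category]
    codes = [spec.code for spec in config.vaccine_specs]

    data_rows: list[list[str]] = []
    symptom_rows: list[list[str]] = []
    vax_rows: list[list[str]] = []
    reports: dict[str, dict] = {}

    seq = 0
    for spec in config.vaccine_specs:
        for _ in range(spec.n_reports):
            seq += 1
            vaers_id = f"{config.year}{seq:06d}"
            age: float | None = _draw_age(rng, spec.age_dist)
            if rng.random() < config.p_missing_age:
                age = None
            onset: int | None = _draw_onset(rng, config.onset_decay, config.max_onset_day)
            if rng.random() < config.p_missing_onset:
                onset = None
            is_case = rng.random() < spec.case_probability

            vaccine_codes = [spec.code]
            if rng.random() < config.p_coadmin:
                others = [c for c in codes if c != spec.code]
                if others:
                    vaccine_codes.append(str(rng.choice(others)))

            terms: list[str] = []
            if is_case:
                terms.append(case_term)
            if not (not is_case and rng.random() < config.p_no_symptoms):
                n_decoys = _draw_n_symptoms(rng, config.symptoms_per_report)
                if is_case:
                    n_decoys = max(n_decoys - 1, 0)
                picked = rng.choice(
                    len(config.decoy_terms),
                    size=min(n_decoys, len(config.decoy_terms)),
                    replace=False,
                )
                terms.extend(config.decoy_terms[i] for i in sorted(picked))

            data_rows.append(
                [
                    vaers_id,
                    f"01/15/{config.year}",
                    str(rng.choice(_STATES)),
                    "" if age is None else f"{age:g}",
                    str(rng.choice(["F", "M", "U"])),
                    "" if onset is None else str(onset),
                ]
            )
            for start in range(0, len(terms), 5):
                chunk = terms[start : start + 5]
                row = [vaers_id]
                for i in range(5):
                    if i < len(chunk):
                        row.extend([chunk[i], "25.1"])
                    else:
                        row.extend(["", ""])
                symptom_rows.append(row)
            for dose, code in enumerate(vaccine_codes, start=1):
                vax_rows.append([vaers_id, code, "SYNTHETIC", str(dose)])

            reports[vaers_id] = {
                "age": age,
                "onset_day": onset,
                "vaccine_codes": sorted(set(vaccine_codes)),
                "symptom_terms": sorted(set(terms)),
                "categories": _flags(terms),
            }

    paths = {
        "data": out / f"{config.year}VAERSDATA.csv",
        "symptoms": out / f"{config.year}VAERSSYMPTOMS.csv",
        "vax": out / f"{config.year}VAERSVAX.csv",
        "truth": out / TRUTH_FILENAME,
    }
    _write_csv(paths["data"], DATA_HEADER, data_rows)
    _write_csv(paths["symptoms"], SYMPTOMS_HEADER, symptom_rows)
    _write_csv(paths["vax"], VAX_HEADER, vax_rows)

    truth = GroundTruth(
        case_category=config.case_category,
        reports=reports,
        per_vaccine=_per_vaccine_truth(reports, config.case_category),
        params={
            "seed": config.seed,
            "year": config.year,
            "onset_decay": config.onset_decay,
            "vaccine_specs": [asdict(s) for s in config.vaccine_specs],
            "p_missing_age": config.p_missing_age,
            "p_missing_onset": config.p_missing_onset,
            "p_coadmin": config.p_coadmin,
            "p_no_symptoms": config.p_no_symptoms,
        },
    )
    truth.save(paths["truth"])
    return paths, truth


# --- hand-written 12-report fixture -------------------------------------
# Covers: multi-vaccine report, continuation symptom rows (7 terms), missing
# age, missing onset, superstring decoy, the UNK vaccine code, a report with
# zero symptom rows, and planted cases: 3 KD, 3 exact vasculitis (+1
# substring-only decoy), 1 HS, 1 MIS-C.
_FIXTURE_YEAR = 2019
_FIXTURE_ROWS = [
    # (seq, age, onset, vaccine codes, terms)
    (1, "0.5", "2", ["MENB"], ["Kawasaki's disease", "Pyrexia"]),
    (2, "1", "0", ["MENB", "HIBV"], ["Kawasaki's disease"]),
    (3, "3", "", ["PNC13"], ["Kawasaki's disease", "Rash"]),
    (4, "", "5", ["UNK"], ["Vasculitis"]),
    (5, "17", "1", ["COVID19"], ["Vasculitis"]),
    (6, "42", "10", ["FLU3"], ["Vasculitis", "Headache"]),
    (7, "6", "3", ["MMR"], ["Cutaneous vasculitis"]),
    (8, "2", "0", ["HIBV"],
     ["Pyrexia", "Rash", "Urticaria", "Headache", "Vomiting", "Diarrhoea", "Fatigue"]),
    (9, "0.2", "4", ["RV5"], ["Pyrexia"]),
    (10, "30", "", ["COVID19"], []),
    (11, "5", "7", ["MENB"], ["Henoch-Schonlein purpura"]),
    (12, "8", "12", ["COVID19"], ["Multisystem inflammatory syndrome in children"]),
]


def fixture_small(out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Write the hand-crafted 12-report fixture triplet plus sidecar truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_rows, symptom_rows, vax_rows = [], [], []
    reports: dict[str, dict] = {}
    for seq, age, onset, vax_codes, terms in _FIXTURE_ROWS:
        vaers_id = f"{_FIXTURE_YEAR}{seq:06d}"
        data_rows.append([vaers_id, f"06/01/{_FIXTURE_YEAR}", "CA", age, "U", onset])
        for start in range(0, len(terms), 5):
            chunk = terms[start : start + 5]
            row = [vaers_id]
            for i in range(5):
                row.extend([chunk[i], "25.1"] if i < len(chunk) else ["", ""])
            symptom_rows.append(row)
        for dose, code in enumerate(vax_codes, start=1):
            vax_rows.append([vaers_id, code, "FIXTURE", str(dose)])
        reports[vaers_id] = {
            "age": float(age) if age else None,
            "onset_day": int(onset) if onset else None,
            "vaccine_codes": sorted(set(vax_codes)),
            "symptom_terms": sorted(set(terms)),
            "categories": _flags(terms),
        }

    paths = {
        "data": out / f"{_FIXTURE_YEAR}VAERSDATA.csv",
        "symptoms": out / f"{_FIXTURE_YEAR}VAERSSYMPTOMS.csv",
        "vax": out / f"{_FIXTURE_YEAR}VAERSVAX.csv",
        "truth": out / TRUTH_FILENAME,
    }
    _write_csv(paths["data"], DATA_HEADER, data_rows)
    _write_csv(paths["symptoms"], SYMPTOMS_HEADER, symptom_rows)
    _write_csv(paths["vax"], VAX_HEADER, vax_rows)
    truth = GroundTruth(
        case_category=KD,
        reports=reports,
        per_vaccine=_per_vaccine_truth(reports, KD),
        params={"fixture": "small", "year": _FIXTURE_YEAR},
    )
    truth.save(paths["truth"])
    return paths, truth
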