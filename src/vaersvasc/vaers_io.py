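"""Readers for the VAERS three-file CSV distribution.

VAERS ships each year as three comma-separated files joined on ``VAERS_ID``:

* ``<YEAR>VAERSDATA.csv`` — one row per report (demographics, dates, onset
  interval in the ``NUMDAYS`` column);
* ``<YEAR>VAERSSYMPTOMS.csv`` — up to five MedDRA preferred terms per physical
  row (``SYMPTOM1``..``SYMPTOM5``), with continuation rows when a report lists
  more than five terms;
* ``<YEAR>VAERSVAX.csv`` — one row per vaccine administered
  (``VAX_TYPE`` code, manufacturer, dose).

A ``NonDomestic`` triple uses the same dialect with the year replaced by the
literal prefix ``NonDomestic``. Real exports are Windows-1252 encoded, so
files are decoded as cp1252 first with a UTF-8 fallback.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

NONDOMESTIC_PREFIX = "NonDomestic"

#: maximum plausible age in years; values outside [0, MAX_AGE_YEARS] are
#: treated as data-entry errors and recorded as missing.
MAX_AGE_YEARS = 120.0


class VaersFormatError(ValueError):
    """A required column is absent from a VAERS file header."""


@dataclass
class DataRecord:
    """One row of a VAERSDATA file."""

    vaers_id: str
    received_date: str | None = None
    age_years: float | None = None
    onset_interval_days: int | None = None
    state: str | None = None
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class SymptomRecord:
    """One physical row of a VAERSSYMPTOMS file (1–5 non-empty terms)."""

    vaers_id: str
    terms: list[str]
    term_versions: list[str] = field(default_factory=list)


@dataclass
class VaxRecord:
    """One row of a VAERSVAX file; ``vax_type`` is uppercased on ingest."""

    vaers_id: str
    vax_type: str
    vax_manu: str | None = None
    vax_dose: str | None = None
    raw: dict[str, str] = field(default_factory=dict)


@dataclass
class JoinedReport:
    """One VAERS report after joining the three files on ``VAERS_ID``.

    ``symptom_terms`` pools every term over all symptom rows of the report,
    de-duplicated; ``vaccine_codes`` likewise. A report with no symptom rows
    is retained with an empty term set (downstream denominators of
    "reports with symptoms" exclude it).
    """

    vaers_id: str
    age_years: float | None = None
    onset_interval_days: int | None = None
    received_date: str | None = None
    vaccine_codes: set[str] = field(default_factory=set)
    symptom_terms: set[str] = field(default_factory=set)
    nondomestic: bool = False

    @property
    def has_symptoms(self) -> bool:
        return len(self.symptom_terms) > 0


def _read_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a VAERS CSV into (uppercased header, row dicts).

    cp1252 first — real VAERS exports are not UTF-8 — falling back to UTF-8.
    """
    path = Path(path)
    for encoding in ("cp1252", "utf-8"):
        try:
            with open(path, newline="", encoding=encoding) as fh:
                reader = csv.reader(fh)
                try:
                    header = next(reader)
                except StopIteration:
                    return [], []
                header = [h.strip().upper() for h in header]
                rows = []
                for cells in reader:
                    if not any(c.strip() for c in cells):
                        continue
                    row = {
                        name: (cells[i] if i < len(cells) else "")
                        for i, name in enumerate(header)
                    }
                    rows.append(row)
                return header, rows
        except UnicodeDecodeError:
            continue
    raise VaersFormatError(f"{path}: undecodable as cp1252 or UTF-8")


def _require_columns(header: list[str], required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise VaersFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )


def _parse_age(cell: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        value = float(cell)
    except ValueError:
        return None
    if value < 0 or value > MAX_AGE_YEARS:
        logger.warning("implausible AGE_YRS %r treated as missing", cell)
        return None
    return value


def _parse_numdays(cell: str) -> int | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        value = int(float(cell))
    except ValueError:
        return None
    if value < 0:
        logger.warning("negative NUMDAYS %r treated as missing", cell)
        return None
    return value


def read_data_file(path: str | Path) -> list[DataRecord]:
    """Read a VAERSDATA file into :class:`DataRecord` rows, order preserved.

    Unparseable numeric cells become missing, never zero. A ``VAERS_ID``
    duplicated within the file keeps its first row (warning logged).
    """
    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["VAERS_ID", "AGE_YRS", "NUMDAYS"], path)
    records: list[DataRecord] = []
    seen: set[str] = set()
    for row in rows:
        vaers_id = row["VAERS_ID"].strip()
        if not vaers_id:
            continue
        if vaers_id in seen:
            logger.warning("%s: duplicate VAERS_ID %s, keeping first", path, vaers_id)
            continue
        seen.add(vaers_id)
        records.append(
            DataRecord(
                vaers_id=vaers_id,
                received_date=row.get("RECVDATE", "").strip() or None,
                age_years=_parse_age(row["AGE_YRS"]),
                onset_interval_days=_parse_numdays(row["NUMDAYS"]),
                state=row.get("STATE", "").strip() or None,
                raw=row,
            )
        )
    return records


_SYMPTOM_COLS = [f"SYMPTOM{i}" for i in range(1, 6)]
_VERSION_COLS = [f"SYMPTOMVERSION{i}" for i in range(1, 6)]


def read_symptoms_file(path: str | Path) -> list[SymptomRecord]:
    """Read a VAERSSYMPTOMS file; one record per physical row.

    Empty term cells are dropped rather than kept as empty strings; rows
    whose five term cells are all empty are skipped. Multiple rows per
    ``VAERS_ID`` are continuation rows for reports with more than five terms.
    """
    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["VAERS_ID"] + _SYMPTOM_COLS, path)
    records: list[SymptomRecord] = []
    for row in rows:
        vaers_id = row["VAERS_ID"].strip()
        if not vaers_id:
            continue
        terms, versions = [], []
        for term_col, ver_col in zip(_SYMPTOM_COLS, _VERSION_COLS):
            term = row.get(term_col, "").strip()
            if term:
                terms.append(term)
                versions.append(row.get(ver_col, "").strip())
        if terms:
            records.append(SymptomRecord(vaers_id, terms, versions))
    return records


def read_vax_file(path: str | Path) -> list[VaxRecord]:
    """Read a VAERSVAX file; ``VAX_TYPE`` is stripped and uppercased."""
    path = Path(path)
    header, rows = _read_rows(path)
    _require_columns(header, ["VAERS_ID", "VAX_TYPE"], path)
    records: list[VaxRecord] = []
    for row in rows:
        vaers_id = row["VAERS_ID"].strip()
        vax_type = row["VAX_TYPE"].strip().upper()
        if not vaers_id or not vax_type:
            continue
        records.append(
            VaxRecord(
                vaers_id=vaers_id,
                vax_type=vax_type,
                vax_manu=row.get("VAX_MANU", "").strip() or None,
                vax_dose=row.get("VAX_DOSE_SERIES", "").strip() or None,
                raw=row,
            )
        )
    return records


def join_reports(
    data: list[DataRecord],
    symptoms: list[SymptomRecord],
    vax: list[VaxRecord],
    nondomestic: bool = False,
) -> list[JoinedReport]:
    """Left join anchored on the data records.

    Symptom terms and vaccine codes are pooled and de-duplicated per report.
    Symptom/vax rows whose ``VAERS_ID`` has no data record are orphans: they
    are counted and logged, never silently dropped into the output.
    """
    by_id: dict[str, JoinedReport] = {}
    for rec in data:
        by_id[rec.vaers_id] = JoinedReport(
            vaers_id=rec.vaers_id,
            age_years=rec.age_years,
            onset_interval_days=rec.onset_interval_days,
            received_date=rec.received_date,
            nondomestic=nondomestic,
        )
    orphan_symptoms = orphan_vax = 0
    for srec in symptoms:
        report = by_id.get(srec.vaers_id)
        if report is None:
            orphan_symptoms += 1
            continue
        report.symptom_terms.update(srec.terms)
    for vrec in vax:
        report = by_id.get(vrec.vaers_id)
        if report is None:
            orphan_vax += 1
            continue
        report.vaccine_codes.add(vrec.vax_type)
    if orphan_symptoms or orphan_vax:
        logger.warning(
            "join: %d orphan symptom row(s) and %d orphan vax row(s) "
            "had no matching data record",
            orphan_symptoms,
            orphan_vax,
        )
    return [by_id[rec.vaers_id] for rec in data]


def _triple_paths(root: Path, prefix: str) -> dict[str, Path]:
    return {
        "data": root / f"{prefix}VAERSDATA.csv",
        "symptoms": root / f"{prefix}VAERSSYMPTOMS.csv",
        "vax": root / f"{prefix}VAERSVAX.csv",
    }


def load_triple(root_dir: str | Path, prefix: str, nondomestic: bool = False) -> list[JoinedReport]:
    """Load and join one ``<prefix>VAERS{DATA,SYMPTOMS,VAX}.csv`` triple."""
    paths = _triple_paths(Path(root_dir), prefix)
    return join_reports(
        read_data_file(paths["data"]),
        read_symptoms_file(paths["symptoms"]),
        read_vax_file(paths["vax"]),
        nondomestic=nondomestic,
    )


def load_year_range(
    root_dir: str | Path,
    year_start: int,
    year_end: int,
    include_nondomestic: bool = False,
    on_missing: str = "skip",
) -> list[JoinedReport]:
    """Concatenate per-year joins over ``year_start..year_end`` inclusive.

    A report id appearing in two year files is kept once, first year wins,
    with a logged count. ``on_missing`` is ``"skip"`` (warn and continue)
    or ``"fatal"`` (raise :class:`FileNotFoundError` on an incomplete triple).
    """
    if on_missing not in ("skip", "fatal"):
        raise ValueError(f"on_missing must be 'skip' or 'fatal', got {on_missing!r}")
    root = Path(root_dir)
    prefixes: list[tuple[str, bool]] = [
        (str(year), False) for year in range(year_start, year_end + 1)
    ]
    if include_nondomestic:
        prefixes.append((NONDOMESTIC_PREFIX, True))

    reports: list[JoinedReport] = []
    seen_ids: set[str] = set()
    cross_year_dupes = 0
    for prefix, nondom in prefixes:
        paths = _triple_paths(root, prefix)
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            if on_missing == "fatal":
                raise FileNotFoundError(
                    f"incomplete VAERS triple for {prefix}: missing {missing}"
                )
            logger.warning("skipping %s: missing %s", prefix, missing)
            continue
        for report in load_triple(root, prefix, nondomestic=nondom):
            if report.vaers_id in seen_ids:
                cross_year_dupes += 1
                continue
            seen_ids.add(report.vaers_id)
            reports.append(report)
    if cross_year_dupes:
        logger.warning(
            "dropped %d report id(s) duplicated across year files (first year kept)",
            cross_year_dupes,
        )
    return reports
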