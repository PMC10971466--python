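"""Published VAERS summary integers used as program inputs.

Two reference tabulations from the published retrospective VAERS analysis of
Kawasaki-disease and MIS adverse events (reports received 1990 – 27 October
2023) are embedded here as plain integers:

* the per-vaccine Kawasaki-disease table — for each vaccine code with five or
  more KD reports: the number of reports-with-symptoms at ages 0–5
  ("vaccinations"), the all-ages KD case count, and the printed normalized
  frequency per 100,000 (round-half-away convention);
* the per-age COVID-19 table for the composite "KD, MIS, MIS-A, or MIS-C" —
  case count, reports-with-symptoms denominator, and printed frequency per
  100,000 (truncation convention; zero-count ages printed as "<X" bounds).

They serve as inputs for the arithmetic-convention audits, the Bonferroni /
chi-squared re-analysis, and the age-band summary statistics; the raw
underlying VAERS pull is not redistributed here.
"""

from __future__ import annotations

import pandas as pd

# vaccine_code, reports-with-symptoms ages 0-5, KD cases (all ages), printed freq/100k
_KD_VACCINE_ROWS = [
    ("6VAX-F", 4092, 68, 1662),
    ("BCG", 241, 5, 2075),
    ("COVID19", 7267, 54, 743),
    ("DTAP", 55155, 57, 103),
    ("DTAPHEPBIP", 11606, 41, 353),
    ("DTAPIPV", 10939, 15, 137),
    ("DTAPIPVHIB", 10861, 55, 506),
    ("DTP", 21679, 11, 51),
    ("DTPIPV", 504, 10, 1984),
    ("FLU3", 9145, 7, 77),
    ("FLU4", 5270, 14, 266),
    ("FLUX", 2181, 18, 825),
    ("HBHEPB", 5236, 8, 153),
    ("HEP", 20648, 58, 281),
    ("HEPA", 18061, 30, 166),
    ("HIBV", 52928, 126, 238),
    ("IPV", 36648, 44, 120),
    ("MEN", 1239, 16, 1291),
    ("MENB", 2790, 91, 3262),
    ("MMR", 59053, 64, 108),
    ("MMRV", 11873, 11, 93),
    ("PNC", 26198, 107, 408),
    ("PNC13", 23510, 160, 681),
    ("PPV", 4573, 16, 350),
    ("RV1", 7858, 79, 1005),
    ("RV5", 16921, 104, 615),
    ("RVX", 1398, 6, 429),
    ("TYP", 233, 6, 2575),
    ("UNK", 2840, 24, 845),
    ("VARCEL", 43062, 31, 72),
]

# age, composite KD/MIS cases, reports-with-symptoms denominator, printed freq
# (int, or "<X" bound for zero-count ages)
_COVID_AGE_ROWS = [
    (1, 3, 851, 352),
    (2, 2, 826, 242),
    (3, 2, 865, 231),
    (4, 1, 1071, 93),
    (5, 11, 2751, 399),
    (6, 6, 1921, 312),
    (7, 19, 2117, 897),
    (8, 10, 2194, 455),
    (9, 16, 2417, 661),
    (10, 13, 2687, 483),
    (11, 11, 3950, 278),
    (12, 22, 6136, 358),
    (13, 16, 4862, 329),
    (14, 7, 5306, 131),
    (15, 11, 6410, 171),
    (16, 11, 8329, 132),
    (17, 14, 10274, 136),
    (18, 3, 7237, 41),
    (19, 3, 7497, 40),
    (20, 4, 8321, 48),
    (21, 2, 8716, 22),
    (22, 3, 9445, 31),
    (23, 1, 10291, 9),
    (24, 2, 10985, 18),
    (25, 1, 11912, 8),
    (26, 0, 12456, "<8"),
    (27, 1, 13197, 7),
    (28, 2, 13813, 14),
    (29, 1, 14700, 7),
    (30, 0, 16084, "<6"),
]


def kd_vaccine_frequency_table() -> pd.DataFrame:
    """Published per-vaccine KD frequency table (31 vaccine codes)."""
    return pd.DataFrame(
        _KD_VACCINE_ROWS,
        columns=["vaccine_code", "denominator", "case_count", "frequency_per_100k"],
    )[["vaccine_code", "case_count", "denominator", "frequency_per_100k"]]


def covid_age_frequency_table() -> pd.DataFrame:
    """Published per-age COVID-19 composite KD/MIS frequency table (ages 1–30)."""
    return pd.DataFrame(
        _COVID_AGE_ROWS,
        columns=["age", "case_count", "denominator", "frequency_per_100k"],
    )
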