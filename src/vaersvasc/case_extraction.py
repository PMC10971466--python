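"""Flag reports whose symptom terms match the studied adverse-event categories.

The studied categories are the vasculitis adverse events searchable in VAERS
by MedDRA preferred term: Kawasaki disease, the Multisystem Inflammatory
Syndrome family, Henoch–Schönlein purpura, and vasculitis, plus the composite
"KD, MIS, MIS-A, or MIS-C" (union of its members). Matching is by default
exact on the preferred term, case-insensitive: a substring policy would sweep
distinct preferred terms such as "Cutaneous vasculitis" into the "Vasculitis"
category and inflate counts, so substring mode is retained only as an explicit
sensitivity switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

#: category labels used throughout the package
KD = "KD"
MIS = "MIS"
MIS_A = "MIS-A"
MIS_C = "MIS-C"
HS = "HS"
VASCULITIS = "vasculitis"
KD_MIS_COMPOSITE = "KD, MIS, MIS-A, or MIS-C"


class CategoryConfigError(ValueError):
    """A category definition is inconsistent (unknown member, cycle, ...)."""


@dataclass(frozen=True)
class TermPolicy:
    """How a report's symptom term is compared against a category term.

    ``match_mode`` is ``"exact"`` (normalized equality) or ``"substring"``
    (normalized containment). Normalization case-folds unless
    ``case_sensitive``, trims, and collapses internal whitespace.
    """

    match_mode: str = "exact"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.match_mode not in ("exact", "substring"):
            raise ValueError(
                f"match_mode must be 'exact' or 'substring', got {self.match_mode!r}"
            )


@dataclass
class CategoryDefinition:
    """An adverse-event category: a term list, or a composite of categories."""

    name: str
    terms: list[str] = field(default_factory=list)
    composite_of: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.terms and not self.composite_of:
            raise CategoryConfigError(
                f"category {self.name!r} needs terms or composite_of"
            )


def default_categories() -> list[CategoryDefinition]:
    """The six searched preferred-term categories plus the KD/MIS composite.

    The VAERS spelling "Kawasaki's disease" (with apostrophe) is the
    canonical preferred term.
    """
    return [
        CategoryDefinition(HS, ["Henoch-Schonlein purpura"]),
        CategoryDefinition(KD, ["Kawasaki's disease"]),
        CategoryDefinition(MIS, ["Multisystem inflammatory syndrome"]),
        CategoryDefinition(MIS_A, ["Multisystem inflammatory syndrome in adults"]),
        CategoryDefinition(MIS_C, ["Multisystem inflammatory syndrome in children"]),
        CategoryDefinition(VASCULITIS, ["Vasculitis"]),
        CategoryDefinition(
            KD_MIS_COMPOSITE, composite_of=[KD, MIS, MIS_A, MIS_C]
        ),
    ]


def _normalize(text: str, case_sensitive: bool) -> str:
    collapsed = " ".join(text.split())
    return collapsed if case_sensitive else collapsed.casefold()


def match_term(symptom: str, term: str, policy: TermPolicy = TermPolicy()) -> bool:
    """True iff ``symptom`` matches ``term`` under the policy."""
    s = _normalize(symptom, policy.case_sensitive)
    t = _normalize(term, policy.case_sensitive)
    if policy.match_mode == "exact":
        return s == t
    return t in s


def _resolve_order(categories: list[CategoryDefinition]) -> list[CategoryDefinition]:
    """Topologically order categories so members precede composites."""
    by_name = {c.name: c for c in categories}
    ordered: list[CategoryDefinition] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(name: str, chain: tuple[str, ...]) -> None:
        if name not in by_name:
            raise CategoryConfigError(
                f"composite references unknown category {name!r}"
            )
        if state.get(name) == 1:
            return
        if state.get(name) == 0:
            raise CategoryConfigError(
                f"composite cycle: {' -> '.join(chain + (name,))}"
            )
        state[name] = 0
        cat = by_name[name]
        for member in cat.composite_of or []:
            visit(member, chain + (name,))
        state[name] = 1
        ordered.append(cat)

    for cat in categories:
        visit(cat.name, ())
    return ordered


def extract_cases(
    reports,
    categories: list[CategoryDefinition] | None = None,
    policy: TermPolicy = TermPolicy(),
) -> pd.DataFrame:
    """Build the case table: one boolean row per report, one column per category.

    A report is one case per category regardless of how many of its terms
    match; composite flags are the union of their members, computed after the
    atomic flags. Reports with no symptom terms get all-false rows.
    """
    if categories is None:
        categories = default_categories()
    ordered = _resolve_order(categories)
    names = [c.name for c in ordered]

    index = [r.vaers_id for r in reports]
    table = pd.DataFrame(False, index=pd.Index(index, name="vaers_id"), columns=names)

    for cat in ordered:
        if cat.composite_of:
            flags = table[cat.composite_of].any(axis=1)
        else:
            flags = pd.Series(
                [
                    any(
                        match_term(symptom, term, policy)
                        for symptom in report.symptom_terms
                        for term in cat.terms
                    )
                    for report in reports
                ],
                index=table.index,
                dtype=bool,
            )
        table[cat.name] = flags
    # restore the caller's column order
    table = table[[c.name for c in categories]]
    return table


def categories_from_config(entries: list[dict]) -> list[CategoryDefinition]:
    """Build categories from config mappings with keys name/terms/composite_of."""
    cats = [
        CategoryDefinition(
            name=entry["name"],
            terms=list(entry.get("terms", [])),
            composite_of=list(entry["composite_of"]) if "composite_of" in entry else None,
        )
        for entry in entries
    ]
    _resolve_order(cats)  # validate references and acyclicity up front
    return cats


def load_categories_yaml(path) -> list[CategoryDefinition]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("categories", [])
    return categories_from_config(doc)
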