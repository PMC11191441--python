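"""Common data model (CDM) container and I/O.

A CDM harmonizes heterogeneous cohort-study variables against a canonical
set of *reference terms*. Each reference term carries a human-readable name
(often including the field's customary abbreviation, e.g. "Mini-Mental State
Examination (MMSE)"), an optional description taken from a mapped ontology
term, an optional compact ontology identifier (CURIE), and a modality label
grouping variables by measurement type (MRI, Clinical, Demographics, ...).

Cohort variables are the raw names found in source data dictionaries
("PTAGE", "cdr_sb", "Lhippo_FS_adj"); each maps to exactly one reference
term. The set of variables mapped onto a term is that term's *alias set* —
the "prior known mappings" used to enrich candidate retrieval at inference
time.

Two serialization formats are supported: a long-format CSV (one row per
variable, term columns repeated; matches the data-dictionary world cohort
curators live in) and a JSON format with separate term/variable/edge arrays,
which is the lossless master format. Text is stored verbatim: no case
folding happens at the data layer.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "ReferenceTerm",
    "CohortVariable",
    "CDM",
    "CDMFormatError",
    "CDMIntegrityError",
    "load_cdm",
    "save_cdm",
    "aliases_of",
    "reference_of",
    "load_data_dictionary",
]

#: CSV column order for the long-format CDM table.
CDM_CSV_COLUMNS = [
    "term_id",
    "term_name",
    "term_description",
    "ontology_id",
    "modality",
    "variable_name",
    "variable_description",
    "source_id",
]

# Fig-1-style placeholder for "no description" in curated tables.
_MISSING_DESCRIPTION_TOKENS = {"–", "-", "—"}


class CDMFormatError(ValueError):
    """Raised when a CDM file is malformed (e.g. a required column is missing)."""


class CDMIntegrityError(ValueError):
    """Raised when CDM content violates a structural invariant."""


def _clean_description(text: str) -> str:
    text = (text or "").strip()
    return "" if text in _MISSING_DESCRIPTION_TOKENS else text


@dataclass(frozen=True)
class ReferenceTerm:
    """A canonical mapping target in the common data model."""

    term_id: str
    name: str
    description: str = ""
    ontology_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CDMIntegrityError(f"reference term {self.term_id!r} has an empty name")
        if not self.term_id:
            raise CDMIntegrityError("reference term has an empty term_id")


@dataclass(frozen=True)
class CohortVariable:
    """A variable name as it appears in one source data dictionary."""

    name: str
    description: str = ""
    source_id: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CDMIntegrityError(f"cohort variable from {self.source_id!r} has an empty name")


@dataclass
class CDM:
    """Reference terms, cohort variables, and many-to-one mapping edges.

    ``mappings`` maps the key ``(variable_name, source_id)`` to a
    ``term_id``. Every variable maps to exactly one term; a term may have
    arbitrarily many variables (its aliases).
    """

    terms: dict[str, ReferenceTerm] = field(default_factory=dict)
    variables: dict[tuple[str, str], CohortVariable] = field(default_factory=dict)
    mappings: dict[tuple[str, str], str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    def add_term(self, term: ReferenceTerm) -> None:
        if term.term_id in self.terms:
            raise CDMIntegrityError(f"duplicate term_id {term.term_id!r}")
        self.terms[term.term_id] = term

    def add_variable(self, variable: CohortVariable, term_id: str) -> None:
        key = (variable.name, variable.source_id)
        if key in self.variables:
            raise CDMIntegrityError(
                f"duplicate variable {variable.name!r} for source {variable.source_id!r}"
            )
        if term_id not in self.terms:
            raise CDMIntegrityError(
                f"variable {variable.name!r} mapped to unknown term_id {term_id!r}"
            )
        self.variables[key] = variable
        self.mappings[key] = term_id

    # -- queries ----------------------------------------------------------

    @property
    def modalities(self) -> set[str]:
        return {t.modality for t in self.terms.values()}

    def aliases_of(self, term_id: str) -> list[CohortVariable]:
        """All cohort variables mapped onto ``term_id`` (the prior known
        mappings), sorted by (source_id, name) for determinism."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term_id {term_id!r}")
        hits = [self.variables[k] for k, t in self.mappings.items() if t == term_id]
        return sorted(hits, key=lambda v: (v.source_id, v.name))

    def reference_of(self, variable_name: str, source_id: str) -> ReferenceTerm:
        """Reverse a known mapping: the unique term a variable maps to."""
        key = (variable_name, source_id)
        if key not in self.mappings:
            raise KeyError(f"unknown variable {variable_name!r} for source {source_id!r}")
        return self.terms[self.mappings[key]]

    def validate(self) -> None:
        """Raise :class:`CDMIntegrityError` on any structural violation."""
        for key, term_id in self.mappings.items():
            if key not in self.variables:
                raise CDMIntegrityError(f"mapping edge for unregistered variable {key!r}")
            if term_id not in self.terms:
                raise CDMIntegrityError(f"dangling edge {key!r} -> {term_id!r}")
        for key in self.variables:
            if key not in self.mappings:
                raise CDMIntegrityError(f"variable {key!r} has no mapping edge")
        declared = self.modalities
        for key, var in self.variables.items():
            term = self.terms[self.mappings[key]]
            if var.modality != term.modality:
                raise CDMIntegrityError(
                    f"variable {var.name!r} has modality {var.modality!r} but its "
                    f"reference term {term.term_id!r} has {term.modality!r}"
                )
            if var.modality not in declared:
                raise CDMIntegrityError(f"variable {var.name!r} modality not declared")

    def __len__(self) -> int:
        return len(self.terms)


# -- module-level operation wrappers --------------------------------------


def aliases_of(cdm: CDM, term_id: str) -> list[CohortVariable]:
    return cdm.aliases_of(term_id)


def reference_of(cdm: CDM, variable_name: str, source_id: str) -> ReferenceTerm:
    return cdm.reference_of(variable_name, source_id)


# -- I/O -------------------------------------------------------------------


def _cdm_from_records(
    term_records: Iterable[dict], variable_records: Iterable[dict]
) -> CDM:
    cdm = CDM()
    for rec in term_records:
        cdm.add_term(
            ReferenceTerm(
                term_id=rec["term_id"],
                name=rec["name"],
                description=_clean_description(rec.get("description", "")),
                ontology_id=rec.get("ontology_id", "") or "",
                modality=rec.get("modality", "") or "",
            )
        )
    for rec in variable_records:
        term_id = rec["term_id"]
        if term_id not in cdm.terms:
            raise CDMIntegrityError(
                f"variable {rec['name']!r} references unknown term_id {term_id!r}"
            )
        cdm.add_variable(
            CohortVariable(
                name=rec["name"],
                description=_clean_description(rec.get("description", "")),
                source_id=rec.get("source_id", "") or "",
                modality=cdm.terms[term_id].modality,
            ),
            term_id,
        )
    cdm.validate()
    return cdm


def load_cdm(path: str | Path, format: Literal["csv", "json"] | None = None) -> CDM:
    """Load a CDM from a long-format CSV or the JSON master format.

    ``format`` defaults to the file extension. Raises
    :class:`CDMFormatError` for missing columns and
    :class:`CDMIntegrityError` for structural violations (duplicate
    variables, dangling edges).
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        for section in ("terms", "variables"):
            if section not in payload:
                raise CDMFormatError(f"JSON CDM missing {section!r} section")
        return _cdm_from_records(payload["terms"], payload["variables"])
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in CDM_CSV_COLUMNS if c not in header]
            if missing:
                raise CDMFormatError(f"CDM CSV missing column(s): {', '.join(missing)}")
            rows = list(reader)
        term_records: dict[str, dict] = {}
        variable_records: list[dict] = []
        for row in rows:
            tid = row["term_id"]
            rec = {
                "term_id": tid,
                "name": row["term_name"],
                "description": row["term_description"],
                "ontology_id": row["ontology_id"],
                "modality": row["modality"],
            }
            prior = term_records.setdefault(tid, rec)
            if prior["name"] != rec["name"]:
                raise CDMIntegrityError(f"term_id {tid!r} repeated with different names")
            if row["variable_name"]:  # term-only rows declare terms without aliases
                variable_records.append(
                    {
                        "term_id": tid,
                        "name": row["variable_name"],
                        "description": row["variable_description"],
                        "source_id": row["source_id"],
                    }
                )
        return _cdm_from_records(term_records.values(), variable_records)
    raise CDMFormatError(f"unknown CDM format {fmt!r}")


def save_cdm(cdm: CDM, path: str | Path, format: Literal["csv", "json"] | None = None) -> None:
    """Write a CDM; JSON round-trips bit-identically through :func:`load_cdm`."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    term_ids = sorted(cdm.terms)
    if fmt == "json":
        payload = {
            "terms": [
                {
                    "term_id": t.term_id,
                    "name": t.name,
                    "description": t.description,
                    "ontology_id": t.ontology_id,
                    "modality": t.modality,
                }
                for t in (cdm.terms[tid] for tid in term_ids)
            ],
            "variables": [
                {
                    "term_id": cdm.mappings[key],
                    "name": v.name,
                    "description": v.description,
                    "source_id": v.source_id,
                }
                for key, v in sorted(cdm.variables.items(), key=lambda kv: (cdm.mappings[kv[0]], kv[0]))
            ],
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        return
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CDM_CSV_COLUMNS)
            for tid in term_ids:
                term = cdm.terms[tid]
                aliases = cdm.aliases_of(tid)
                if not aliases:
                    writer.writerow(
                        [tid, term.name, term.description, term.ontology_id, term.modality, "", "", ""]
                    )
                for v in aliases:
                    writer.writerow(
                        [
                            tid,
                            term.name,
                            term.description,
                            term.ontology_id,
                            term.modality,
                            v.name,
                            v.description,
                            v.source_id,
                        ]
                    )
        return
    raise CDMFormatError(f"unknown CDM format {fmt!r}")


def load_data_dictionary(path: str | Path) -> list[tuple[str, str]]:
    """Read a cohort data dictionary CSV: a ``variable`` column plus an
    optional ``description`` column. Returns (name, description) rows in
    file order."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if "variable" not in header:
            raise CDMFormatError("data dictionary CSV missing 'variable' column")
        has_desc = "description" in header
        return [
            (row["variable"], _clean_description(row["description"]) if has_desc else "")
            for row in reader
        ]
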