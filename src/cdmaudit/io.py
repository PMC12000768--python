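"""Delimited-text readers/writers for CDM tables, terminology fixtures and
concept libraries.

Column names follow PCORnet-style defaults (RAW_LAB_NAME / LAB_LOINC,
RAW_RX_MED_NAME / RXNORM_CUI, DX / DX_ORIGIN, ...) but every semantic field
can be remapped through a :class:`Dialect`, since the audits target any CDM
that carries the needed fields.  All outputs are UTF-8; dates serialize as
ISO-8601; the delimiter is auto-detected on read unless given explicitly.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import (
    Category,
    CdmDataset,
    CodedEventRecord,
    ConceptLibrary,
    EventDomain,
    LabRecord,
    MedAdminRecord,
    MedOrderRecord,
    MethodFlag,
    TableKind,
    TermGranularity,
    TerminologyConcept,
    TerminologyReference,
    TermSystem,
    coerce_encounter_type,
    coerce_provenance,
)

__all__ = [
    "Dialect",
    "DEFAULT_DIALECTS",
    "DEFAULT_SENTINELS",
    "TableReadResult",
    "ConfigurationError",
    "read_cdm_table",
    "write_cdm_table",
    "read_dataset",
    "write_dataset",
    "load_terminology",
    "write_terminology",
    "load_concept_library",
    "write_concept_library",
]

#: "No information" sentinel values that normalize to null/unknown.
DEFAULT_SENTINELS: frozenset[str] = frozenset({"NI", "UN", "OT", ""})


class ConfigurationError(ValueError):
    """A dialect/column configuration problem (names the offending column)."""


@dataclass(frozen=True)
class Dialect:
    """Mapping from semantic field names to source column headers."""

    columns: Mapping[str, str]

    def column(self, semantic: str) -> str:
        try:
            return self.columns[semantic]
        except KeyError:
            raise ConfigurationError(
                f"dialect defines no column for semantic field {semantic!r}"
            ) from None

    def optional(self, semantic: str) -> str | None:
        return self.columns.get(semantic)


DEFAULT_DIALECTS: dict[TableKind, Dialect] = {
    TableKind.LAB: Dialect(
        {
            "patient_id": "PATIENT_ID",
            "record_id": "LAB_RESULT_CM_ID",
            "date": "RESULT_DATE",
            "raw_name": "RAW_LAB_NAME",
            "code": "LAB_LOINC",
            "numeric_result": "RESULT_NUM",
            "result_unit": "RESULT_UNIT",
        }
    ),
    TableKind.ORDER: Dialect(
        {
            "patient_id": "PATIENT_ID",
            "record_id": "PRESCRIBINGID",
            "date": "RX_ORDER_DATE",
            "raw_name": "RAW_RX_MED_NAME",
            "code": "RXNORM_CUI",
        }
    ),
    TableKind.ADMINISTRATION: Dialect(
        {
            "patient_id": "PATIENT_ID",
            "record_id": "MEDADMINID",
            "date": "MEDADMIN_START_DATE",
            "raw_name": "RAW_MEDADMIN_MED_NAME",
            "code": "MEDADMIN_CODE",
        }
    ),
    TableKind.DIAGNOSIS: Dialect(
        {
            "patient_id": "PATIENT_ID",
            "record_id": "DIAGNOSISID",
            "date": "DX_DATE",
            "code": "DX",
            "code_system": "DX_TYPE",
            "provenance": "DX_ORIGIN",
            "encounter_type": "ENC_TYPE",
        }
    ),
    TableKind.PROCEDURE: Dialect(
        {
            "patient_id": "PATIENT_ID",
            "record_id": "PROCEDURESID",
            "date": "PX_DATE",
            "code": "PX",
            "code_system": "PX_TYPE",
            "provenance": "PX_SOURCE",
            "encounter_type": "ENC_TYPE",
        }
    ),
}

_MANDATORY: dict[TableKind, tuple[str, ...]] = {
    TableKind.LAB: ("patient_id", "record_id", "date", "raw_name", "code"),
    TableKind.ORDER: ("patient_id", "record_id", "date", "raw_name", "code"),
    TableKind.ADMINISTRATION: ("patient_id", "record_id", "date", "raw_name", "code"),
    TableKind.DIAGNOSIS: ("patient_id", "record_id", "date", "code"),
    TableKind.PROCEDURE: ("patient_id", "record_id", "date", "code"),
}


@dataclass
class TableReadResult:
    records: list
    n_dropped_dates: int
    kind: TableKind


def _clean(value: object, sentinels: frozenset[str]) -> str | None:
    """Sentinel normalization (idempotent): missing/sentinel -> None."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text.upper() in sentinels or text == "":
        return None
    return text


def _parse_date(value: object) -> _dt.date | None:
    if value is None:
        return None
    text = str(value).strip()
    if not text:
        return None
    try:
        return _dt.date.fromisoformat(text[:10])
    except ValueError:
        ts = pd.to_datetime(text, errors="coerce")
        if pd.isna(ts):
            return None
        return ts.date()


def _read_frame(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read {path}: file does not exist")
    if sep is None:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            sample = fh.read(64 * 1024)
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",\t;|").delimiter
        except csv.Error:
            sep = ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def read_cdm_table(
    path: str | Path,
    kind: TableKind,
    dialect: Dialect | None = None,
    sep: str | None = None,
    sentinels: Iterable[str] = DEFAULT_SENTINELS,
) -> TableReadResult:
    """Read one CDM table into typed records.

    Rows whose date fails to parse are dropped and counted in
    ``n_dropped_dates``.  Empty-string and sentinel codes become None; for
    diagnoses/procedures sentinel provenance/encounter values coerce to the
    ``unknown`` enum member.
    """
    kind = TableKind(kind)
    dialect = dialect or DEFAULT_DIALECTS[kind]
    sentinels = frozenset(s.upper() for s in sentinels)
    frame = _read_frame(path, sep)

    for semantic in _MANDATORY[kind]:
        col = dialect.column(semantic)
        if col not in frame.columns:
            raise ConfigurationError(
                f"{path}: missing mandatory column {col!r} "
                f"(semantic field {semantic!r})"
            )

    def col(semantic: str) -> str | None:
        name = dialect.optional(semantic)
        return name if name in frame.columns else None

    records: list = []
    n_dropped = 0
    date_col = dialect.column("date")
    columns = list(frame.columns)
    for values in frame.itertuples(index=False, name=None):
        row_d = dict(zip(columns, values))
        date = _parse_date(row_d.get(date_col))
        if date is None:
            n_dropped += 1
            continue
        patient_id = str(row_d[dialect.column("patient_id")]).strip()
        record_id = str(row_d[dialect.column("record_id")]).strip()
        code = _clean(row_d.get(dialect.column("code")), sentinels)
        if kind is TableKind.LAB:
            num_col, unit_col = col("numeric_result"), col("result_unit")
            num_raw = _clean(row_d.get(num_col), sentinels) if num_col else None
            try:
                numeric = float(num_raw) if num_raw is not None else None
            except ValueError:
                numeric = None
            records.append(
                LabRecord(
                    patient_id=patient_id,
                    record_id=record_id,
                    result_date=date,
                    raw_name=_clean(row_d.get(dialect.column("raw_name")), sentinels) or "",
                    code=code,
                    numeric_result=numeric,
                    result_unit=_clean(row_d.get(unit_col), sentinels) if unit_col else None,
                )
            )
        elif kind is TableKind.ORDER:
            records.append(
                MedOrderRecord(
                    patient_id=patient_id,
                    record_id=record_id,
                    order_date=date,
                    raw_name=_clean(row_d.get(dialect.column("raw_name")), sentinels) or "",
                    code=code,
                )
            )
        elif kind is TableKind.ADMINISTRATION:
            records.append(
                MedAdminRecord(
                    patient_id=patient_id,
                    record_id=record_id,
                    admin_date=date,
                    raw_name=_clean(row_d.get(dialect.column("raw_name")), sentinels) or "",
                    code=code,
                )
            )
        else:
            domain = (
                EventDomain.DIAGNOSIS if kind is TableKind.DIAGNOSIS else EventDomain.PROCEDURE
            )
            sys_col, prov_col, enc_col = col("code_system"), col("provenance"), col("encounter_type")
            records.append(
                CodedEventRecord(
                    patient_id=patient_id,
                    record_id=record_id,
                    event_date=date,
                    domain=domain,
                    code=code or "",
                    code_system=(_clean(row_d.get(sys_col), sentinels) or "") if sys_col else "",
                    # Provenance/encounter values skip sentinel cleaning: "OT"
                    # is a meaningful encounter type (other), and the coercers
                    # already send unrecognized values to the unknown member.
                    provenance=coerce_provenance(row_d.get(prov_col) if prov_col else None),
                    encounter_type=coerce_encounter_type(row_d.get(enc_col) if enc_col else None),
                )
            )
    return TableReadResult(records=records, n_dropped_dates=n_dropped, kind=kind)


_PROV_OUT = {"ordered": "OD", "billing": "BI", "claim": "CL", "derived": "DR", "unknown": "NI"}
_ENC_OUT = {"outpatient": "AV", "inpatient": "IP", "emergency": "ED", "other": "OT", "unknown": "NI"}


def write_cdm_table(
    records: Sequence,
    path: str | Path,
    kind: TableKind,
    dialect: Dialect | None = None,
    sep: str = ",",
) -> None:
    """Write records back to a delimited file using the dialect's headers."""
    kind = TableKind(kind)
    dialect = dialect or DEFAULT_DIALECTS[kind]
    rows: list[dict[str, object]] = []
    for r in records:
        row: dict[str, object] = {
            dialect.column("patient_id"): r.patient_id,
            dialect.column("record_id"): r.record_id,
            dialect.column("date"): r.date.isoformat(),
        }
        if kind in (TableKind.LAB, TableKind.ORDER, TableKind.ADMINISTRATION):
            row[dialect.column("raw_name")] = r.raw_name
            row[dialect.column("code")] = r.code if r.code is not None else ""
            if kind is TableKind.LAB:
                row[dialect.column("numeric_result")] = (
                    "" if r.numeric_result is None else repr(float(r.numeric_result))
                )
                row[dialect.column("result_unit")] = r.result_unit or ""
        else:
            row[dialect.column("code")] = r.code
            row[dialect.column("code_system")] = r.code_system
            row[dialect.column("provenance")] = _PROV_OUT[r.provenance.value]
            row[dialect.column("encounter_type")] = _ENC_OUT[r.encounter_type.value]
        rows.append(row)
    header = list(rows[0]) if rows else [dialect.column(s) for s in _MANDATORY[kind]]
    pd.DataFrame(rows, columns=header).to_csv(path, sep=sep, index=False, encoding="utf-8")


_TABLE_FILES: dict[str, TableKind] = {
    "labs.csv": TableKind.LAB,
    "orders.csv": TableKind.ORDER,
    "administrations.csv": TableKind.ADMINISTRATION,
    "diagnoses.csv": TableKind.DIAGNOSIS,
    "procedures.csv": TableKind.PROCEDURE,
}


def write_dataset(dataset: CdmDataset, outdir: str | Path, sep: str = ",") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cdm_table(dataset.labs, outdir / "labs.csv", TableKind.LAB, sep=sep)
    write_cdm_table(dataset.orders, outdir / "orders.csv", TableKind.ORDER, sep=sep)
    write_cdm_table(
        dataset.administrations, outdir / "administrations.csv", TableKind.ADMINISTRATION, sep=sep
    )
    write_cdm_table(dataset.diagnoses, outdir / "diagnoses.csv", TableKind.DIAGNOSIS, sep=sep)
    write_cdm_table(dataset.procedures, outdir / "procedures.csv", TableKind.PROCEDURE, sep=sep)


def read_dataset(indir: str | Path, partner_label: str = "", sep: str | None = None) -> CdmDataset:
    """Read a directory of CDM tables written by :func:`write_dataset`."""
    indir = Path(indir)
    dataset = CdmDataset(partner_label=partner_label)
    for filename, kind in _TABLE_FILES.items():
        path = indir / filename
        if not path.exists():
            continue
        result = read_cdm_table(path, kind, sep=sep)
        if kind is TableKind.LAB:
            dataset.labs = result.records
        elif kind is TableKind.ORDER:
            dataset.orders = result.records
        elif kind is TableKind.ADMINISTRATION:
            dataset.administrations = result.records
        else:
            dataset.events.extend(result.records)
    return dataset


# ---------------------------------------------------------------------------
# Terminology fixtures
# ---------------------------------------------------------------------------

def load_terminology(
    lab_path: str | Path | None, drug_path: str | Path | None, sep: str | None = None
) -> TerminologyReference:
    """Load lab/drug terminology fixture files into a reference lookup.

    Lab fixture columns: CODE, DESCRIPTION, COMPONENT, SPECIMEN, METHOD.
    Drug fixture columns: CODE, DESCRIPTION, INGREDIENTS (semicolon-joined),
    GRANULARITY, BRAND.  Either path may be None (degenerate, single-system
    reference).
    """
    concepts: list[TerminologyConcept] = []
    if lab_path is not None:
        frame = _read_frame(lab_path, sep)
        for row in frame.to_dict("records"):
            concepts.append(
                TerminologyConcept(
                    code=str(row["CODE"]).strip(),
                    system=TermSystem.LAB,
                    description=str(row.get("DESCRIPTION", "")).strip(),
                    component=(str(row["COMPONENT"]).strip() or None)
                    if "COMPONENT" in row
                    else None,
                    specimen=(str(row["SPECIMEN"]).strip() or None)
                    if "SPECIMEN" in row
                    else None,
                    method_flag=MethodFlag(str(row.get("METHOD", "unspecified")).strip() or "unspecified"),
                )
            )
    if drug_path is not None:
        frame = _read_frame(drug_path, sep)
        for row in frame.to_dict("records"):
            ingredients = tuple(
                t.strip() for t in str(row.get("INGREDIENTS", "")).split(";") if t.strip()
            )
            brand = str(row.get("BRAND", "")).strip() or None
            concepts.append(
                TerminologyConcept(
                    code=str(row["CODE"]).strip(),
                    system=TermSystem.DRUG,
                    description=str(row.get("DESCRIPTION", "")).strip(),
                    ingredients=ingredients,
                    term_granularity=TermGranularity(
                        str(row.get("GRANULARITY", "other")).strip() or "other"
                    ),
                    brand=brand,
                )
            )
    return TerminologyReference(concepts)


def write_terminology(ref: TerminologyReference, outdir: str | Path, sep: str = ",") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lab_rows = [
        {
            "CODE": c.code,
            "DESCRIPTION": c.description,
            "COMPONENT": c.component or "",
            "SPECIMEN": c.specimen or "",
            "METHOD": c.method_flag.value,
        }
        for c in ref.lab_concepts()
    ]
    drug_rows = [
        {
            "CODE": c.code,
            "DESCRIPTION": c.description,
            "INGREDIENTS": ";".join(c.ingredients),
            "GRANULARITY": c.term_granularity.value if c.term_granularity else "other",
            "BRAND": c.brand or "",
        }
        for c in ref.drug_concepts()
    ]
    pd.DataFrame(lab_rows, columns=["CODE", "DESCRIPTION", "COMPONENT", "SPECIMEN", "METHOD"]).to_csv(
        outdir / "terminology_labs.csv", sep=sep, index=False, encoding="utf-8"
    )
    pd.DataFrame(
        drug_rows, columns=["CODE", "DESCRIPTION", "INGREDIENTS", "GRANULARITY", "BRAND"]
    ).to_csv(outdir / "terminology_drugs.csv", sep=sep, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Concept library (declarative YAML)
# ---------------------------------------------------------------------------

def load_concept_library(path: str | Path) -> ConceptLibrary:
    """Load a condition/category/concept/code library from YAML.

    Layout::

        conditions:
          chronic_kidney_disease:
            cohort_entry:
              - {system: ICD10, code: "N18.3"}
            diagnoses:
              anemia:
                - {system: ICD10, code: "D64.9"}
            medications: {...}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    conditions = doc.get("conditions", {})
    entries: dict[str, dict[Category, dict[str, list[tuple[str, str]]]]] = {}
    cohort_entry: dict[str, list[tuple[str, str]]] = {}
    allowed = {c.value for c in Category}
    for condition, body in conditions.items():
        body = body or {}
        cohort = [
            (str(e.get("system", "")), str(e["code"])) for e in body.get("cohort_entry", []) or []
        ]
        cohort_entry[condition] = cohort
        cat_map: dict[Category, dict[str, list[tuple[str, str]]]] = {}
        for key, concepts in body.items():
            if key == "cohort_entry":
                continue
            if key not in allowed:
                raise ValueError(
                    f"condition {condition!r}: unknown category {key!r}; "
                    f"allowed categories: {sorted(allowed)}"
                )
            cat_map[Category(key)] = {
                concept: [(str(e.get("system", "")), str(e["code"])) for e in codes or []]
                for concept, codes in (concepts or {}).items()
            }
        entries[condition] = cat_map
    return ConceptLibrary(entries=entries, cohort_entry=cohort_entry)


def write_concept_library(library: ConceptLibrary, path: str | Path) -> None:
    doc: dict[str, dict] = {"conditions": {}}
    for condition, categories in library.entries.items():
        body: dict[str, object] = {
            "cohort_entry": [
                {"system": s, "code": c} for s, c in library.cohort_entry[condition]
            ]
        }
        for category, concepts in categories.items():
            body[category.value] = {
                concept: [{"system": s, "code": c} for s, c in codes]
                for concept, codes in concepts.items()
            }
        doc["conditions"][condition] = body
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
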