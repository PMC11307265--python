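"""Reading, normalizing and writing ICSR line listings.

The expected input is a delimited text export with one row per case report
and a single packed column carrying the reaction list. The packing
convention, column names and separators vary between exports, so they are
all carried by a :class:`Dialect`.

Rows with unparseable mandatory fields are collected into an error report,
never silently dropped; unknown enum tokens degrade to ``unspecified`` with
a logged warning.
"""
from __future__ import annotations

import csv
import gzip
import io
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .model import (
    AgeGroup,
    CaseReport,
    ChemicalSubgroup,
    DrugExposure,
    Era,
    NOT_SPECIFIED_SOC,
    Outcome,
    ReactionRecord,
    Region,
    Reporter,
    Seriousness,
    Sex,
)
from .reference import ATCCatalogue, MedDRAMap

log = logging.getLogger(__name__)

DEFAULT_COLUMNS = (
    "report_id",
    "receipt_date",
    "sex",
    "age_group",
    "reporter_qualification",
    "region",
    "suspect_drugs",
    "reaction_list",
)


class ConfigurationError(ValueError):
    """Raised when the input does not match the configured dialect."""


@dataclass
class Dialect:
    """Format configuration for one line-listing export flavour."""

    delimiter: str = ","
    columns: tuple = DEFAULT_COLUMNS
    drug_separator: str = ";"
    entry_separator: str = ",\n"       # between reactions inside the packed field
    subfield_separator: str = "–"  # en dash between duration/outcome/seriousness
    seriousness_separator: str = ";"   # between criteria of one reaction
    encoding: str = "utf-8"


@dataclass
class IngestResult:
    reports: list
    errors: list = field(default_factory=list)  # (row_number, reason, raw row)

    @property
    def n_ingested(self) -> int:
        return len(self.reports)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


# ---------------------------------------------------------------------------
# Token tables (display label in exports <-> internal enum)
# ---------------------------------------------------------------------------

_SEX_TOKENS = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
}
_AGE_TOKENS = {
    "0-2": AgeGroup.A0_2,
    "0-2 years": AgeGroup.A0_2,
    "2 years or under": AgeGroup.A0_2,
    "3-17": AgeGroup.A3_17,
    "3-17 years": AgeGroup.A3_17,
    "18-64": AgeGroup.A18_64,
    "18-64 years": AgeGroup.A18_64,
    ">64": AgeGroup.A65_PLUS,
    "65plus": AgeGroup.A65_PLUS,
    "65 years or older": AgeGroup.A65_PLUS,
}
_REPORTER_TOKENS = {
    "healthcare professional": Reporter.HEALTHCARE_PROFESSIONAL,
    "healthcare_professional": Reporter.HEALTHCARE_PROFESSIONAL,
    "non healthcare professional": Reporter.NON_HEALTHCARE_PROFESSIONAL,
    "non-healthcare professional": Reporter.NON_HEALTHCARE_PROFESSIONAL,
    "non_healthcare_professional": Reporter.NON_HEALTHCARE_PROFESSIONAL,
}
_REGION_TOKENS = {
    "eea": Region.EEA,
    "european economic area": Region.EEA,
    "non eea": Region.NON_EEA,
    "non-eea": Region.NON_EEA,
    "non_eea": Region.NON_EEA,
}
_OUTCOME_TOKENS = {
    "fatal": Outcome.FATAL,
    "not recovered/not resolved": Outcome.NOT_RECOVERED,
    "not recovered": Outcome.NOT_RECOVERED,
    "not_recovered": Outcome.NOT_RECOVERED,
    "recovered/resolved": Outcome.RECOVERED,
    "recovered": Outcome.RECOVERED,
    "recovered/resolved with sequelae": Outcome.RECOVERED_WITH_SEQUELAE,
    "recovered_with_sequelae": Outcome.RECOVERED_WITH_SEQUELAE,
    "recovering/resolving": Outcome.RECOVERING,
    "recovering": Outcome.RECOVERING,
}
_SERIOUSNESS_TOKENS = {
    "other medically important condition": Seriousness.OTHER_MEDICALLY_IMPORTANT,
    "other_medically_important": Seriousness.OTHER_MEDICALLY_IMPORTANT,
    "caused/prolonged hospitalisation": Seriousness.HOSPITALISATION,
    "caused/prolonged hospitalization": Seriousness.HOSPITALISATION,
    "hospitalisation": Seriousness.HOSPITALISATION,
    "congenital anomaly": Seriousness.CONGENITAL_ANOMALY,
    "congenital_anomaly": Seriousness.CONGENITAL_ANOMALY,
    "disabling": Seriousness.DISABLING,
    "life threatening": Seriousness.LIFE_THREATENING,
    "life_threatening": Seriousness.LIFE_THREATENING,
    "results in death": Seriousness.DEATH,
    "death": Seriousness.DEATH,
}
_UNSPECIFIED_TOKENS = {"", "n/a", "na", "unknown", "unspecified", "not specified",
                       "not specified/unknown"}

# Display labels used when writing listings back out.
OUTCOME_LABELS = {
    Outcome.FATAL: "Fatal",
    Outcome.NOT_RECOVERED: "Not Recovered/Not Resolved",
    Outcome.RECOVERED: "Recovered/Resolved",
    Outcome.RECOVERED_WITH_SEQUELAE: "Recovered/Resolved with Sequelae",
    Outcome.RECOVERING: "Recovering/Resolving",
    Outcome.UNSPECIFIED: "Unknown",
}
SERIOUSNESS_LABELS = {
    Seriousness.OTHER_MEDICALLY_IMPORTANT: "Other Medically Important Condition",
    Seriousness.HOSPITALISATION: "Caused/Prolonged Hospitalisation",
    Seriousness.CONGENITAL_ANOMALY: "Congenital Anomaly",
    Seriousness.DISABLING: "Disabling",
    Seriousness.LIFE_THREATENING: "Life Threatening",
    Seriousness.DEATH: "Results in Death",
    Seriousness.UNSPECIFIED: "Not Specified/Unknown",
}
AGE_LABELS = {
    AgeGroup.A0_2: "0-2 years",
    AgeGroup.A3_17: "3-17 years",
    AgeGroup.A18_64: "18-64 years",
    AgeGroup.A65_PLUS: "65 years or older",
    AgeGroup.UNSPECIFIED: "Not Specified",
}


def _norm_token(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip()).casefold()


def _parse_enum(text: str, tokens: dict, default, what: str):
    key = _norm_token(text)
    if key in _UNSPECIFIED_TOKENS:
        return default
    value = tokens.get(key)
    if value is None:
        log.warning("unknown %s token %r mapped to unspecified", what, text)
        return default
    return value


# ---------------------------------------------------------------------------
# Packed reaction list
# ---------------------------------------------------------------------------

def parse_reaction_list(packed: str, dialect: Optional[Dialect] = None) -> list:
    """Unpack one reaction-list field into :class:`ReactionRecord` objects.

    Entry pattern: ``PT (duration - outcome - seriousness1; seriousness2)``
    with the dialect's separators. Missing sub-fields map to unspecified.
    A malformed entry (unbalanced parenthesis) yields a record flagged
    ``malformed`` with the raw text preserved.
    """
    dialect = dialect or Dialect()
    records = []
    for entry in packed.split(dialect.entry_separator):
        entry = entry.strip()
        if not entry:
            continue
        records.append(_parse_reaction_entry(entry, dialect))
    return records


def _parse_reaction_entry(entry: str, dialect: Dialect) -> ReactionRecord:
    m = re.match(r"^(?P<pt>[^()]*?)\s*\((?P<body>.*)\)\s*$", entry, flags=re.DOTALL)
    if m is None:
        if "(" in entry or ")" in entry or not entry.strip():
            return ReactionRecord(pt=entry.strip(), malformed=True, raw=entry)
        return ReactionRecord(pt=entry.strip())  # PT only, rest unspecified
    pt = m.group("pt").strip()
    if not pt:
        return ReactionRecord(pt="", malformed=True, raw=entry)
    parts = [p.strip() for p in m.group("body").split(dialect.subfield_separator)]
    parts += [""] * (3 - len(parts))
    duration_text, outcome_text, seriousness_text = parts[0], parts[1], parts[2]

    duration = None if _norm_token(duration_text) in _UNSPECIFIED_TOKENS else duration_text
    outcome = _parse_enum(outcome_text, _OUTCOME_TOKENS, Outcome.UNSPECIFIED, "outcome")
    criteria = set()
    for token in seriousness_text.split(dialect.seriousness_separator):
        if _norm_token(token) in _UNSPECIFIED_TOKENS:
            continue
        criteria.add(
            _parse_enum(token, _SERIOUSNESS_TOKENS, Seriousness.UNSPECIFIED, "seriousness")
        )
    criteria.discard(Seriousness.UNSPECIFIED)
    seriousness = frozenset(criteria) if criteria else frozenset({Seriousness.UNSPECIFIED})
    return ReactionRecord(
        pt=pt, seriousness=seriousness, outcome=outcome, duration=duration
    )


def format_reaction_list(records: Iterable[ReactionRecord],
                         dialect: Optional[Dialect] = None) -> str:
    dialect = dialect or Dialect()
    sep = f" {dialect.subfield_separator} "
    entries = []
    for rec in records:
        duration = rec.duration if rec.duration else "n/a"
        outcome = OUTCOME_LABELS[rec.outcome]
        labels = sorted(SERIOUSNESS_LABELS[s] for s in rec.seriousness)
        seriousness = f"{dialect.seriousness_separator} ".join(labels)
        entries.append(f"{rec.pt} ({duration}{sep}{outcome}{sep}{seriousness})")
    return dialect.entry_separator.join(entries)


# ---------------------------------------------------------------------------
# Line listing reader / writer
# ---------------------------------------------------------------------------

def _open_text(path, encoding: str, mode: str = "rt"):
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode, encoding=encoding, newline="")
        return open(path, mode.replace("t", ""), encoding=encoding, newline="")
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding=encoding, newline="")
    return open(path, mode.replace("t", ""), encoding=encoding, newline="")


def _parse_year(text: str) -> Optional[int]:
    m = re.match(r"^\s*(\d{4})", text or "")
    return int(m.group(1)) if m else None


def parse_line_listing(path, dialect: Optional[Dialect] = None) -> IngestResult:
    """Read a line-listing export into case reports.

    Mandatory columns missing from the header raise
    :class:`ConfigurationError` naming the column. Rows whose mandatory
    fields cannot be parsed are collected into ``result.errors``.
    """
    dialect = dialect or Dialect()
    with _open_text(path, dialect.encoding) as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames
        if header is None:
            log.warning("empty line listing %s", path)
            return IngestResult(reports=[])
        for column in dialect.columns:
            if column not in header:
                raise ConfigurationError(f"missing mandatory column: {column!r}")
        reports: list = []
        errors: list = []
        seen_ids: set = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                report = _parse_row(row, dialect)
            except ValueError as exc:
                errors.append((i, str(exc), dict(row)))
                continue
            if report.report_id in seen_ids:
                errors.append((i, f"duplicate report_id {report.report_id!r}", dict(row)))
                continue
            seen_ids.add(report.report_id)
            reports.append(report)
    log.info("ingested %d reports, rejected %d rows from %s",
             len(reports), len(errors), path)
    return IngestResult(reports=reports, errors=errors)


def _parse_row(row: dict, dialect: Dialect) -> CaseReport:
    # dialect.columns holds the actual header names, in canonical role order
    c = dict(zip(DEFAULT_COLUMNS, dialect.columns))
    report_id = (row.get(c["report_id"]) or "").strip()
    if not report_id:
        raise ValueError("missing report_id")
    year = _parse_year(row.get(c["receipt_date"]) or "")
    if year is None:
        raise ValueError("unparseable receipt_date")
    drugs = [
        DrugExposure(substance=s.strip())
        for s in (row.get(c["suspect_drugs"]) or "").split(dialect.drug_separator)
        if s.strip()
    ]
    if not drugs:
        raise ValueError("no suspect drugs")
    reactions = parse_reaction_list(row.get(c["reaction_list"]) or "", dialect)
    if not reactions:
        raise ValueError("no reactions")
    return CaseReport(
        report_id=report_id,
        receipt_year=year,
        sex=_parse_enum(row.get(c["sex"]) or "", _SEX_TOKENS, Sex.UNSPECIFIED, "sex"),
        age_group=_parse_enum(row.get(c["age_group"]) or "", _AGE_TOKENS,
                              AgeGroup.UNSPECIFIED, "age_group"),
        reporter=_parse_enum(row.get(c["reporter_qualification"]) or "", _REPORTER_TOKENS,
                             Reporter.UNSPECIFIED, "reporter"),
        region=_parse_enum(row.get(c["region"]) or "", _REGION_TOKENS,
                           Region.UNSPECIFIED, "region"),
        drugs=drugs,
        reactions=reactions,
    )


def write_line_listing(reports: Iterable[CaseReport], path,
                       dialect: Optional[Dialect] = None) -> None:
    """Write reports in the normalized listing format (round-trips with
    :func:`parse_line_listing`)."""
    dialect = dialect or Dialect()
    sex_labels = {Sex.MALE: "Male", Sex.FEMALE: "Female", Sex.UNSPECIFIED: "Not Specified"}
    reporter_labels = {
        Reporter.HEALTHCARE_PROFESSIONAL: "Healthcare Professional",
        Reporter.NON_HEALTHCARE_PROFESSIONAL: "Non Healthcare Professional",
        Reporter.UNSPECIFIED: "Not Specified",
    }
    region_labels = {Region.EEA: "EEA", Region.NON_EEA: "Non EEA",
                     Region.UNSPECIFIED: "Not Specified"}
    with _open_text(path, dialect.encoding, mode="wt") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(dialect.columns)
        for rep in reports:
            writer.writerow([
                rep.report_id,
                str(rep.receipt_year),
                sex_labels[rep.sex],
                AGE_LABELS[rep.age_group],
                reporter_labels[rep.reporter],
                region_labels[rep.region],
                f"{dialect.drug_separator} ".join(d.substance for d in rep.drugs),
                format_reaction_list(rep.reactions, dialect),
            ])


# ---------------------------------------------------------------------------
# Normalization passes
# ---------------------------------------------------------------------------

def assign_soc(records: list, meddra: MedDRAMap) -> list:
    """Populate every record's SOC from the map (total, idempotent)."""
    for rec in records:
        rec.soc = meddra.get(rec.pt)
    return records


def assign_soc_reports(reports: list, meddra: MedDRAMap) -> list:
    for rep in reports:
        assign_soc(rep.reactions, meddra)
    return reports


def classify_drugs(reports: list, catalogue: ATCCatalogue) -> list:
    """Resolve every exposure's subgroup and era via the catalogue.

    Unknown substances keep era ``unclassified`` (warning logged), never
    dropped.
    """
    unknown: set = set()
    for rep in reports:
        for i, drug in enumerate(rep.drugs):
            resolved = catalogue.lookup(drug.substance)
            if resolved.era is Era.UNCLASSIFIED and resolved.subgroup is None:
                unknown.add(drug.substance)
            rep.drugs[i] = resolved
    if unknown:
        log.warning("unclassified substances: %s", ", ".join(sorted(unknown)))
    return reports


def filter_window(reports: list, start: int = 2012, end: int = 2021) -> list:
    """Inclusive receipt-year window filter."""
    return [r for r in reports if start <= r.receipt_year <= end]


# ---------------------------------------------------------------------------
# Overview table
# ---------------------------------------------------------------------------

def summarize_reports(reports: list) -> pd.DataFrame:
    """Report-level overview: counts and percent of total by stratum.

    Percentages are of the report total, two decimals, round-half-up.
    """
    from .stats import round_half_up

    total = len(reports)

    def pct(n: int) -> float:
        return round_half_up(100.0 * n / total, 2) if total else 0.0

    rows = [("total", "All reports", total, pct(total))]

    def count_section(section: str, keyfn, levels):
        counts: dict = {lv: 0 for lv in levels}
        for rep in reports:
            counts[keyfn(rep)] = counts.get(keyfn(rep), 0) + 1
        for lv in counts:
            rows.append((section, getattr(lv, "value", str(lv)), counts[lv], pct(counts[lv])))

    count_section("age_group", lambda r: r.age_group, list(AgeGroup))
    count_section("sex", lambda r: r.sex, list(Sex))
    count_section("reporter", lambda r: r.reporter, list(Reporter))
    count_section("region", lambda r: r.region, list(Region))

    # drug sections count reports mentioning the substance/subgroup at least once
    sub_counts: dict = {}
    grp_counts: dict = {sg: 0 for sg in ChemicalSubgroup}
    for rep in reports:
        names = {d.substance for d in rep.drugs}
        for name in sorted(names):
            sub_counts[name] = sub_counts.get(name, 0) + 1
        groups = {d.subgroup for d in rep.drugs if d.subgroup is not None}
        for g in groups:
            grp_counts[g] += 1
    for g in ChemicalSubgroup:
        rows.append(("subgroup", g.value, grp_counts[g], pct(grp_counts[g])))
    for name in sorted(sub_counts):
        rows.append(("substance", name, sub_counts[name], pct(sub_counts[name])))

    return pd.DataFrame(rows, columns=["section", "label", "count", "percent"])
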