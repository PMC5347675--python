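"""Reading spontaneous adverse-event reports and building case cohorts.

Input records follow a subset of the openFDA drug-event schema, either as
JSON-lines (one report per line) or as a flat CSV with one row per
report x drug x reaction. Cohort construction mirrors a sex-stratified
indication-restricted FAERS query: a report joins a drug's cohort only when
the patient's sex is recorded, the receipt date falls inside the study
window, and the drug of interest carries a qualifying indication on its own
drug entry (not on a co-medication).
"""

from __future__ import annotations

import csv as _csv
import io
import json
import logging
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import IO, Iterable, Iterator, Mapping

logger = logging.getLogger("prrnet.ingest")

__all__ = [
    "Sex",
    "DrugEntry",
    "AdverseEventReport",
    "CaseCohort",
    "RecordError",
    "normalize_term",
    "default_alopecia_terms",
    "parse_reports",
    "build_cohort",
    "DEFAULT_DATE_WINDOW",
]


class Sex(str, Enum):
    """Patient sex as recorded on the report."""

    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


#: openFDA ``patientsex`` codes; anything else (including 0) maps to unknown.
SEX_CODES: Mapping[str, Sex] = {"1": Sex.MALE, "2": Sex.FEMALE}

#: MedDRA preferred terms used to restrict drug entries to alopecia treatment.
_ALOPECIA_TERMS = frozenset(
    {
        "ALOPECIA",
        "ALOPECIA AREATA",
        "ALOPECIA EFFLUVIUM",
        "ALOPECIA SCARRING",
        "ALOPECIA TOTALIS",
        "ALOPECIA UNIVERSALIS",
        "ANDROGENETIC ALOPECIA",
        "DIFFUSE ALOPECIA",
    }
)

#: Half-open receipt-date window covering January 2004 through June 2014.
DEFAULT_DATE_WINDOW: tuple[date, date] = (date(2004, 1, 1), date(2014, 7, 1))


def normalize_term(raw: str) -> str:
    """Normalize a free-text term: uppercase, trim, collapse inner whitespace.

    Idempotent; MedDRA preferred terms, drug names and indications are all
    matched through this normal form.
    """
    return " ".join(str(raw).split()).upper()


def default_alopecia_terms() -> frozenset[str]:
    """The eight MedDRA alopecia indication terms used by the default query."""
    return _ALOPECIA_TERMS


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug on a report, with the indication recorded for that drug."""

    generic_name: str
    indication_term: str | None = None


@dataclass(frozen=True, slots=True)
class AdverseEventReport:
    """A single spontaneous report.

    ``reactions`` is a set of normalized MedDRA preferred terms and is
    non-empty by construction (records without parseable reactions are
    dropped at parse time).
    """

    report_id: str
    receipt_date: date
    sex: Sex
    drug_entries: tuple[DrugEntry, ...]
    reactions: frozenset[str]


@dataclass(frozen=True, slots=True)
class RecordError:
    """A record-level parse failure (collected, not fatal)."""

    line: int
    message: str


@dataclass(frozen=True)
class CaseCohort:
    """Reports of one sex exposed to one drug for a qualifying indication."""

    drug: str
    sex: Sex
    indication_terms: frozenset[str]
    date_window: tuple[date, date]
    reports: Mapping[str, AdverseEventReport]

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports.values())


# ---------------------------------------------------------------------------
# parsing


class _Malformed(ValueError):
    pass


def _parse_date(raw: object) -> date:
    s = str(raw or "").strip()
    if len(s) == 8 and s.isdigit():  # openFDA CCYYMMDD
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    try:
        return date.fromisoformat(s)
    except ValueError:
        raise _Malformed(f"unparseable receipt date {raw!r}") from None


def _sex_from_code(raw: object) -> Sex:
    return SEX_CODES.get(str(raw).strip() if raw is not None else "", Sex.UNKNOWN)


def _report_from_json(rec: Mapping, line: int) -> AdverseEventReport | None:
    if not isinstance(rec, Mapping):
        raise _Malformed("record is not a JSON object")
    rid = str(rec.get("safetyreportid") or "").strip()
    if not rid:
        raise _Malformed("missing safetyreportid")
    receipt = _parse_date(rec.get("receiptdate"))
    patient = rec.get("patient") or {}
    sex = _sex_from_code(patient.get("patientsex"))
    entries = []
    for d in patient.get("drug") or []:
        name = normalize_term(d.get("medicinalproduct") or "")
        if not name:
            continue
        ind_raw = d.get("drugindication")
        ind = normalize_term(ind_raw) if ind_raw and normalize_term(ind_raw) else None
        entries.append(DrugEntry(name, ind))
    reactions = frozenset(
        t
        for r in patient.get("reaction") or []
        if (t := normalize_term(r.get("reactionmeddrapt") or ""))
    )
    if not reactions:
        logger.warning("report %s (line %d) has no parseable reactions; dropped", rid, line)
        return None
    return AdverseEventReport(rid, receipt, sex, tuple(entries), reactions)


def _iter_jsonl(stream: IO[str]) -> Iterator[tuple[int, AdverseEventReport | None, RecordError | None]]:
    for lineno, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            yield lineno, _report_from_json(rec, lineno), None
        except (_Malformed, json.JSONDecodeError, TypeError) as exc:
            yield lineno, None, RecordError(lineno, str(exc))


_CSV_COLUMNS = ("report_id", "receipt_date", "sex", "drug", "indication", "reaction")


def _parse_csv(stream: IO[str], errors: list[RecordError]) -> list[AdverseEventReport]:
    reader = _csv.DictReader(stream)
    if reader.fieldnames is None or not set(_CSV_COLUMNS) <= set(reader.fieldnames):
        raise ValueError(
            f"CSV input must have columns {_CSV_COLUMNS}, got {reader.fieldnames}"
        )
    # one row per report x drug x reaction, reassembled by report_id
    order: list[str] = []
    dates: dict[str, date] = {}
    sexes: dict[str, Sex] = {}
    drugs: dict[str, dict[DrugEntry, None]] = {}
    reactions: dict[str, set[str]] = {}
    bad: set[str] = set()
    for lineno, row in enumerate(reader, start=2):
        rid = (row.get("report_id") or "").strip()
        if not rid:
            errors.append(RecordError(lineno, "missing report_id"))
            continue
        if rid not in dates and rid not in bad:
            try:
                dates[rid] = _parse_date(row.get("receipt_date"))
            except _Malformed as exc:
                errors.append(RecordError(lineno, str(exc)))
                bad.add(rid)
                continue
            sexes[rid] = _sex_from_code(row.get("sex"))
            order.append(rid)
            drugs[rid] = {}
            reactions[rid] = set()
        if rid in bad:
            continue
        name = normalize_term(row.get("drug") or "")
        if name:
            ind = normalize_term(row.get("indication") or "") or None
            drugs[rid][DrugEntry(name, ind)] = None
        rx = normalize_term(row.get("reaction") or "")
        if rx:
            reactions[rid].add(rx)
    out = []
    for rid in order:
        if not reactions[rid]:
            logger.warning("report %s has no parseable reactions; dropped", rid)
            continue
        out.append(
            AdverseEventReport(
                rid, dates[rid], sexes[rid], tuple(drugs[rid]), frozenset(reactions[rid])
            )
        )
    return out


def parse_reports(
    source: str | bytes | IO[str],
    format: str = "jsonl",
    errors: list[RecordError] | None = None,
) -> list[AdverseEventReport]:
    """Parse adverse-event reports from a stream, path-less string, or file.

    Parameters
    ----------
    source
        An open text stream, or the raw text/bytes content itself.
    format
        ``"jsonl"`` (openFDA-dialect JSON lines) or ``"csv"`` (flat rows
        keyed by report_id).
    errors
        Optional list collecting :class:`RecordError` for malformed records;
        such records are skipped, never fatal. Parse failures are also logged.

    Returns
    -------
    list of AdverseEventReport
        Reports in input order; records with no parseable reactions are
        dropped with a warning.
    """
    if isinstance(source, bytes):
        try:
            source = source.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise ValueError(f"input stream does not decode as UTF-8: {exc}") from exc
    stream: IO[str] = io.StringIO(source) if isinstance(source, str) else source
    sink = errors if errors is not None else []
    if format == "jsonl":
        out = []
        for _, report, err in _iter_jsonl(stream):
            if err is not None:
                logger.warning("line %d: %s", err.line, err.message)
                sink.append(err)
            elif report is not None:
                out.append(report)
        return out
    if format == "csv":
        return _parse_csv(stream, sink)
    raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


# ---------------------------------------------------------------------------
# cohort construction


def _matches(
    report: AdverseEventReport,
    names: frozenset[str],
    terms: frozenset[str],
) -> bool:
    """Drug + per-drug indication match (indication on the matching entry)."""
    return any(
        e.generic_name in names and e.indication_term in terms
        for e in report.drug_entries
    )


def build_cohort(
    reports: Iterable[AdverseEventReport],
    drug: str,
    sex: Sex,
    indication_terms: Iterable[str] | None = None,
    date_window: tuple[date, date] = DEFAULT_DATE_WINDOW,
    exclude_drugs: Iterable[str] = (),
    synonyms: Iterable[str] | None = None,
) -> CaseCohort:
    """Select the reports forming one drug's case cohort for one sex.

    A report is retained when all of the following hold:

    * its sex equals ``sex`` (reports with unknown sex never qualify);
    * its receipt date lies in the half-open window ``[start, end)``;
    * at least one drug entry matches ``drug`` (or a synonym,
      case-insensitively) *and* that same entry's indication is in
      ``indication_terms``;
    * no drug entry matches any name in ``exclude_drugs`` (used to drop
      combination-exposure reports and keep comparison arms disjoint).

    An empty result is a valid empty cohort.
    """
    if sex not in (Sex.MALE, Sex.FEMALE):
        raise ValueError("cohort sex must be male or female")
    terms = frozenset(
        normalize_term(t) for t in (indication_terms if indication_terms is not None else _ALOPECIA_TERMS)
    )
    if not terms:
        raise ValueError("indication_terms must be non-empty")
    start, end = date_window
    if not start < end:
        raise ValueError(f"date window is not well-ordered: {start} .. {end}")
    names = frozenset(normalize_term(s) for s in (synonyms if synonyms else [drug]))
    excluded = frozenset(normalize_term(x) for x in exclude_drugs)
    members: dict[str, AdverseEventReport] = {}
    for r in reports:
        if r.sex is not sex or not (start <= r.receipt_date < end):
            continue
        if excluded and any(e.generic_name in excluded for e in r.drug_entries):
            continue
        if _matches(r, names, terms) and r.report_id not in members:
            members[r.report_id] = r
    return CaseCohort(
        drug=normalize_term(drug),
        sex=sex,
        indication_terms=terms,
        date_window=date_window,
        reports=members,
    )
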