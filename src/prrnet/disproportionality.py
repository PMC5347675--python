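"""Disproportionality statistics for drug-vs-drug adverse-event comparison.

Implements case-level event counting, the proportional reporting ratio
(PRR) with its delta-method 95% confidence interval, a two-tailed Fisher
exact test, male/female gender-composition odds ratios against a reference
population, and assembly of ranked comparison tables.

The PRR for event X compares reporting proportions between an exposed drug
and a comparator::

    PRR_X = (A1/A0) / (B1/B0)

with A1 affected cases among A0 total cases on the exposed drug, and B1/B0
the same for the comparator. The 95% CI is::

    exp( ln PRR  -/+  1.96 * sqrt(1/A1 + 1/B1 - 1/A0 - 1/B0) )

The Fisher exact test enters the four counts (A1, A0, B1, B0) directly as
the cells of the 2x2 table, i.e. each drug's row is (affected, total); this
reporting-rate construction is the one the comparison tables are built on,
and the gender-composition test uses the standard (male, female) cells.

Degenerate rows keep the conventions of spontaneous-report tables: a PRR
with no comparator cases reporting the event (B1 = 0) is undefined and
rendered "N/A"; a PRR with no exposed cases reporting it (A1 = 0, B1 > 0)
is zero and rendered "0.00"; the CI is suppressed in both situations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .ingest import CaseCohort

__all__ = [
    "ContingencyTable",
    "PrrRow",
    "GenderCompositionRow",
    "count_affected",
    "top_events",
    "prr",
    "prr_ci",
    "fisher_exact_two_tailed",
    "fisher_two_tailed_cells",
    "gender_composition",
    "compare_drugs",
    "stars_for",
    "round_half_up",
    "format_prr",
    "format_ci",
    "format_p",
    "render_comparison",
    "comparison_frame",
]

#: Relative tolerance for probability ties in the two-tailed Fisher sum.
FISHER_TIE_RTOL = 1e-7

#: Smallest p-value kept internally (display floor renders below this as "0").
P_DISPLAY_FLOOR = 1e-300


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Counts behind one PRR: (affected, total) for exposed and comparator."""

    a1: int
    a0: int
    b1: int
    b0: int

    def __post_init__(self) -> None:
        if not (0 <= self.a1 <= self.a0 and 0 <= self.b1 <= self.b0):
            raise ValueError(f"inconsistent counts {self}")
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("cohort totals must be positive")


@dataclass(frozen=True, slots=True)
class PrrRow:
    """One event row of a drug-vs-drug comparison table.

    ``prr`` is a positive float, ``0.0`` (no exposed cases affected), or
    ``None`` when undefined (no comparator cases affected). ``ci_lower`` /
    ``ci_upper`` are ``None`` whenever either affected count is zero.
    """

    event_term: str
    table: ContingencyTable
    prop_a: float
    prop_b: float
    prr: float | None
    ci_lower: float | None
    ci_upper: float | None
    p_value: float
    stars: str


@dataclass(frozen=True, slots=True)
class GenderCompositionRow:
    """Male/female composition of a cohort against a reference population."""

    male: int
    female: int
    pct_male: float
    or_mf: float | None
    p_value: float


# ---------------------------------------------------------------------------
# counting


def count_affected(cohort: CaseCohort, event_term: str) -> int:
    """Number of distinct reports in the cohort mentioning the event term.

    Case-level counting: a report counts once however many times the term
    appears on it (reaction sets already deduplicate).
    """
    return sum(1 for r in cohort if event_term in r.reactions)


def top_events(cohort: CaseCohort, n: int) -> list[tuple[str, int]]:
    """The ``n`` most commonly reported event terms with their counts.

    Descending by affected-case count, ties broken lexicographically.
    Returns fewer than ``n`` pairs if the cohort has fewer distinct terms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts: dict[str, int] = {}
    for r in cohort:
        for t in r.reactions:
            counts[t] = counts.get(t, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


# ---------------------------------------------------------------------------
# PRR and the Fisher test


def prr(table: ContingencyTable) -> float | None:
    """The proportional reporting ratio, or a degenerate sentinel.

    Returns ``None`` (undefined) when the comparator count b1 is zero —
    including the doubly-empty a1 = b1 = 0 row — and ``0.0`` when only the
    exposed count a1 is zero.
    """
    if table.b1 == 0:
        return None
    return (table.a1 / table.a0) / (table.b1 / table.b0)


def prr_ci(table: ContingencyTable) -> tuple[float, float] | None:
    """Delta-method 95% confidence interval for the PRR on the log scale.

    Undefined (``None``) unless both affected counts are positive.
    """
    if table.a1 == 0 or table.b1 == 0:
        return None
    point = prr(table)
    assert point is not None and point > 0
    radicand = 1 / table.a1 + 1 / table.b1 - 1 / table.a0 - 1 / table.b0
    if radicand < 0:  # impossible while a1 <= a0 and b1 <= b0
        raise ArithmeticError(f"negative CI radicand for {table}")
    half = 1.96 * math.sqrt(radicand)
    return math.exp(math.log(point) - half), math.exp(math.log(point) + half)


def fisher_two_tailed_cells(x11: int, x12: int, x21: int, x22: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 with the given cells.

    Sums hypergeometric probabilities, over all tables with the observed
    margins, that do not exceed the observed table's probability within
    relative tolerance ``FISHER_TIE_RTOL``. Computed in log space; the
    result is clipped to [floor, 1] where the floor keeps astronomically
    small values nonzero.
    """
    if min(x11, x12, x21, x22) < 0:
        raise ValueError("cells must be nonnegative")
    n_total = x11 + x12 + x21 + x22
    k_col = x11 + x21  # first-column margin
    n_row = x11 + x12  # first-row margin
    lo = max(0, k_col - (x21 + x22))
    hi = min(k_col, n_row)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n_total, k_col, n_row)
    observed = logpmf[x11 - lo]
    selected = logpmf[logpmf <= observed + math.log1p(FISHER_TIE_RTOL)]
    p = float(np.exp(logsumexp(selected)))
    return min(max(p, P_DISPLAY_FLOOR * 1e-20), 1.0)


def fisher_exact_two_tailed(table: ContingencyTable) -> float:
    """Two-tailed Fisher exact p for a comparison row.

    The affected and total counts enter as the four cells — each drug's row
    of the 2x2 is (affected, total) — matching the construction behind the
    comparison tables' printed p-values.
    """
    return fisher_two_tailed_cells(table.a1, table.a0, table.b1, table.b0)


def stars_for(p_value: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# gender composition


def gender_composition(
    male: int, female: int, ref_male: int, ref_female: int
) -> GenderCompositionRow:
    """Male percentage and male-to-female odds ratio versus a reference.

    ``or_mf`` (the male/female odds ratio relative to the reference
    population, > 1 when the cohort skews male compared with the reference)
    is ``None`` when the cohort has no female cases. The p-value is a
    two-tailed Fisher exact test on the (male, female) 2x2.
    """
    if male < 0 or female < 0 or male + female == 0:
        raise ValueError("cohort counts must be nonnegative and not both zero")
    if ref_male <= 0 or ref_female <= 0:
        raise ValueError("reference cells must be positive")
    pct_male = 100.0 * male / (male + female)
    or_mf = None if female == 0 else (male / female) / (ref_male / ref_female)
    p = fisher_two_tailed_cells(male, female, ref_male, ref_female)
    return GenderCompositionRow(male, female, pct_male, or_mf, p)


# ---------------------------------------------------------------------------
# comparison tables


def compare_drugs(
    cohort_a: CaseCohort,
    cohort_b: CaseCohort,
    events: Sequence[str] | None = None,
    top_n: int = 10,
) -> list[PrrRow]:
    """One PrrRow per event for an exposed-vs-comparator cohort pair.

    ``events`` defaults to the union of both cohorts' top-``top_n`` terms,
    the row set of a published-style comparison table. Rows are returned in
    alphabetical event order.
    """
    if cohort_a.sex is not cohort_b.sex:
        raise ValueError("cohorts must share the sex stratum")
    if events is None:
        terms = {t for t, _ in top_events(cohort_a, top_n)} if len(cohort_a) else set()
        terms |= {t for t, _ in top_events(cohort_b, top_n)} if len(cohort_b) else set()
        events = sorted(terms)
    if not events:
        return []
    rows = []
    a0, b0 = len(cohort_a), len(cohort_b)
    for term in events:
        table = ContingencyTable(
            count_affected(cohort_a, term), a0, count_affected(cohort_b, term), b0
        )
        point = prr(table)
        ci = prr_ci(table)
        p = fisher_exact_two_tailed(table)
        rows.append(
            PrrRow(
                event_term=term,
                table=table,
                prop_a=table.a1 / a0,
                prop_b=table.b1 / b0,
                prr=point,
                ci_lower=ci[0] if ci else None,
                ci_upper=ci[1] if ci else None,
                p_value=p,
                stars=stars_for(p),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# rendering


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table rendering)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_prr(value: float | None) -> str:
    if value is None:
        return "N/A"
    return f"{round_half_up(value, 2):.2f}"


def format_ci(lower: float | None, upper: float | None) -> str:
    if lower is None or upper is None:
        return ""
    return f"({round_half_up(lower, 2):.2f} - {round_half_up(upper, 2):.2f})"


def format_p(p_value: float, stars: str = "") -> str:
    if p_value < P_DISPLAY_FLOOR:
        return "0" + stars
    return f"{p_value:.3g}{stars}"


def _pct(x: float, ndigits: int = 2) -> str:
    return f"{round_half_up(100.0 * x, ndigits):.{ndigits}f}%"


def render_comparison(rows: Iterable[PrrRow], drug_a: str, drug_b: str) -> str:
    """Human-readable text table: two lines per event, as printed tables do."""
    header = (
        "Adverse Effect\tDrug\tAffected Cases\tTotal Cases\tProportion\t"
        "PRR (95% CI)\tP-value"
    )
    lines = [header]
    for r in rows:
        ci = format_ci(r.ci_lower, r.ci_upper)
        prr_cell = format_prr(r.prr) + (f" {ci}" if ci else "")
        lines.append(
            f"{r.event_term.title()}\t{drug_a.title()}\t{r.table.a1}\t{r.table.a0}\t"
            f"{_pct(r.prop_a)}\t{prr_cell}\t{format_p(r.p_value, r.stars)}"
        )
        lines.append(
            f"\t{drug_b.title()}\t{r.table.b1}\t{r.table.b0}\t{_pct(r.prop_b)}\t\t"
        )
    return "\n".join(lines) + "\n"


def comparison_frame(rows: Iterable[PrrRow], drug_a: str, drug_b: str):
    """The comparison table as a tidy DataFrame (two rows per event).

    PRR, CI, p-value and stars are carried on the exposed drug's row; full
    precision is kept (rounding happens only in the text rendering).
    """
    import pandas as pd

    records = []
    for r in rows:
        records.append(
            {
                "event": r.event_term,
                "drug": drug_a,
                "affected": r.table.a1,
                "total": r.table.a0,
                "proportion": r.prop_a,
                "prr": "N/A" if r.prr is None else r.prr,
                "ci_lower": "" if r.ci_lower is None else r.ci_lower,
                "ci_upper": "" if r.ci_upper is None else r.ci_upper,
                "p_value": r.p_value,
                "stars": r.stars,
            }
        )
        records.append(
            {
                "event": r.event_term,
                "drug": drug_b,
                "affected": r.table.b1,
                "total": r.table.b0,
                "proportion": r.prop_b,
                "prr": "",
                "ci_lower": "",
                "ci_upper": "",
                "p_value": "",
                "stars": "",
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "event",
            "drug",
            "affected",
            "total",
            "proportion",
            "prr",
            "ci_lower",
            "ci_upper",
            "p_value",
            "stars",
        ],
    )
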