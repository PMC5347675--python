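"""Seeded synthetic adverse-event report generation with known ground truth.

Two uses:

* :func:`generate_reports` draws report collections from a
  :class:`SyntheticCohortSpec` whose per-event, per-sex reporting
  probabilities are known, so the true reporting-probability ratio between
  two drugs — what the PRR estimates — is available analytically via
  :func:`expected_prr`. This drives CI-coverage (recovery) tests.

* :func:`fixture_from_counts` deterministically reconstructs a report
  collection whose case-level marginal counts reproduce a printed
  comparison table exactly, for desk-checking published statistics.

Both emit :class:`~prrnet.ingest.AdverseEventReport` objects and a JSON-lines
serialization in the same openFDA dialect the ingest module consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .ingest import (
    DEFAULT_DATE_WINDOW,
    AdverseEventReport,
    DrugEntry,
    Sex,
    default_alopecia_terms,
    normalize_term,
)

__all__ = [
    "ArmSpec",
    "SyntheticCohortSpec",
    "generate_reports",
    "expected_prr",
    "fixture_from_counts",
    "recovery_spec",
    "reports_to_jsonl",
]

_ALOPECIA_TERMS_ORDERED = tuple(sorted(default_alopecia_terms()))

_DEFAULT_INDICATION_POOL = (
    "BENIGN PROSTATIC HYPERPLASIA",
    "HYPERTENSION",
    "HIRSUTISM",
)
_DEFAULT_BACKGROUND_POOL = (
    "HEADACHE",
    "NAUSEA",
    "RASH",
    "DRUG INEFFECTIVE",
)


@dataclass(frozen=True)
class ArmSpec:
    """Generation parameters for one drug's reports.

    ``event_probs`` maps an event term to its per-report inclusion
    probability as ``(p_male, p_female)``; events are drawn independently.
    ``p_sex_missing`` masks the drawn sex to unknown (the sex still drives
    event draws, as it would for a real patient whose report omits it).
    With probability ``p_offlabel_indication`` the drug entry carries a
    non-alopecia indication drawn from ``indication_pool``.
    """

    drug: str
    n_reports: int
    p_male: float = 0.5
    p_sex_missing: float = 0.05
    event_probs: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    p_offlabel_indication: float = 0.05
    indication_pool: tuple[str, ...] = _DEFAULT_INDICATION_POOL
    background_event_pool: tuple[str, ...] = _DEFAULT_BACKGROUND_POOL


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """A seeded multi-arm generation recipe (one ArmSpec per drug)."""

    arms: tuple[ArmSpec, ...]
    seed: int
    date_window: tuple[date, date] = DEFAULT_DATE_WINDOW


def _validate(spec: SyntheticCohortSpec) -> None:
    if not spec.arms:
        raise ValueError("spec must declare at least one arm")
    for arm in spec.arms:
        if arm.n_reports < 1:
            raise ValueError(f"arm {arm.drug!r}: n_reports must be >= 1")
        if not arm.event_probs:
            raise ValueError(f"arm {arm.drug!r}: event_probs must be non-empty")
        probs = [arm.p_male, arm.p_sex_missing, arm.p_offlabel_indication]
        probs += [p for pair in arm.event_probs.values() for p in pair]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"arm {arm.drug!r}: probabilities must lie in [0, 1]")
        if not arm.background_event_pool:
            raise ValueError(f"arm {arm.drug!r}: background_event_pool is empty")
        if arm.p_offlabel_indication > 0 and not arm.indication_pool:
            raise ValueError(f"arm {arm.drug!r}: indication_pool is empty")
    start, end = spec.date_window
    if not start < end:
        raise ValueError("date window is not well-ordered")


def generate_reports(spec: SyntheticCohortSpec) -> list[AdverseEventReport]:
    """Draw a deterministic report collection from the spec.

    Identical specs (including the seed) produce identical reports. Each
    report carries exactly one drug entry; a report whose event draws all
    miss receives one uniformly drawn background reaction, so reaction sets
    are always non-empty as in real spontaneous reports.
    """
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    start, end = spec.date_window
    n_days = (end - start).days
    reports: list[AdverseEventReport] = []
    for arm in spec.arms:
        n = arm.n_reports
        drug = normalize_term(arm.drug)
        is_male = rng.random(n) < arm.p_male
        masked = rng.random(n) < arm.p_sex_missing
        day_offset = rng.integers(0, n_days, n)
        terms = list(arm.event_probs)
        hit = np.empty((n, len(terms)), dtype=bool)
        draws = rng.random((n, len(terms)))
        for j, t in enumerate(terms):
            p_m, p_f = arm.event_probs[t]
            hit[:, j] = draws[:, j] < np.where(is_male, p_m, p_f)
        offlabel = rng.random(n) < arm.p_offlabel_indication
        pool_idx = rng.integers(0, len(arm.indication_pool), n)
        alo_idx = rng.integers(0, len(_ALOPECIA_TERMS_ORDERED), n)
        bg_idx = rng.integers(0, len(arm.background_event_pool), n)

        reactions: list[set[str]] = [set() for _ in range(n)]
        norm_terms = [normalize_term(t) for t in terms]
        for j, col in enumerate(hit.T):
            t = norm_terms[j]
            for i in np.nonzero(col)[0]:
                reactions[i].add(t)
        for i in range(n):
            rx = reactions[i]
            if not rx:
                rx.add(normalize_term(arm.background_event_pool[bg_idx[i]]))
            sex = (
                Sex.UNKNOWN
                if masked[i]
                else (Sex.MALE if is_male[i] else Sex.FEMALE)
            )
            indication = (
                normalize_term(arm.indication_pool[pool_idx[i]])
                if offlabel[i]
                else _ALOPECIA_TERMS_ORDERED[alo_idx[i]]
            )
            reports.append(
                AdverseEventReport(
                    report_id=f"{drug}-{i:07d}",
                    receipt_date=start + timedelta(days=int(day_offset[i])),
                    sex=sex,
                    drug_entries=(DrugEntry(drug, indication),),
                    reactions=frozenset(rx),
                )
            )
    return reports


def expected_prr(
    spec: SyntheticCohortSpec, event: str, sex: Sex
) -> float | None:
    """Analytic truth the PRR estimates: the ratio of the first two arms'
    sex-specific reporting probabilities for ``event``.

    ``None`` (undefined) when the comparator arm's probability is zero.
    """
    if len(spec.arms) < 2:
        raise ValueError("expected_prr needs an exposed and a comparator arm")
    idx = 0 if sex is Sex.MALE else 1
    key = normalize_term(event)
    probs = []
    for arm in spec.arms[:2]:
        lookup = {normalize_term(t): p for t, p in arm.event_probs.items()}
        if key not in lookup:
            raise KeyError(f"event {event!r} not in arm {arm.drug!r} event_probs")
        probs.append(lookup[key][idx])
    if probs[1] == 0:
        return None
    return probs[0] / probs[1]


def recovery_spec(
    seed: int,
    n_per_arm: int = 2000,
    p_exposed: float = 0.40,
    p_comparator: float = 0.05,
    event: str = "LIBIDO DECREASED",
) -> SyntheticCohortSpec:
    """The calibration configuration for CI-coverage (recovery) runs.

    All-male arms of exactly ``n_per_arm`` reports with no missing sex and
    no off-label indications, so the male cohort equals the generated arm
    and the true reporting-probability ratio is ``p_exposed/p_comparator``
    (8.0 at the defaults) with nothing but binomial sampling noise.
    """
    def arm(drug: str, p: float) -> ArmSpec:
        return ArmSpec(
            drug=drug,
            n_reports=n_per_arm,
            p_male=1.0,
            p_sex_missing=0.0,
            event_probs={event: (p, p)},
            p_offlabel_indication=0.0,
        )

    return SyntheticCohortSpec(
        arms=(arm("FINASTERIDE", p_exposed), arm("MINOXIDIL", p_comparator)),
        seed=seed,
    )


def fixture_from_counts(
    counts: Sequence[tuple[str, int, int]],
    a0: int,
    b0: int,
    drug_a: str,
    drug_b: str,
    sex: Sex,
    receipt_date: date = date(2010, 1, 1),
    indication: str = "ALOPECIA",
) -> list[AdverseEventReport]:
    """Deterministic reports whose marginal counts equal a printed table.

    For each arm, event terms are co-assigned to the earliest report ids:
    an event with affected count k lands on reports 0..k-1, so every
    per-event count and both cohort totals round-trip exactly. Reports left
    with no events receive a per-report filler reaction (distinct per
    report, so fillers never enter event rankings).
    """
    if a0 < 1 or b0 < 1:
        raise ValueError("cohort totals must be >= 1")
    for term, ka, kb in counts:
        if not (0 <= ka <= a0 and 0 <= kb <= b0):
            raise ValueError(
                f"infeasible counts for {term!r}: ({ka}/{a0}, {kb}/{b0})"
            )
    ind = normalize_term(indication)
    reports: list[AdverseEventReport] = []
    for drug, total, col in ((drug_a, a0, 1), (drug_b, b0, 2)):
        name = normalize_term(drug)
        sets: list[set[str]] = [set() for _ in range(total)]
        for row in counts:
            term, k = normalize_term(row[0]), row[col]
            for i in range(k):
                sets[i].add(term)
        for i, rx in enumerate(sets):
            if not rx:
                rx.add(f"UNSPECIFIED REACTION {i:06d}")
            reports.append(
                AdverseEventReport(
                    report_id=f"{name}-{i:06d}",
                    receipt_date=receipt_date,
                    sex=sex,
                    drug_entries=(DrugEntry(name, ind),),
                    reactions=frozenset(rx),
                )
            )
    return reports


# ---------------------------------------------------------------------------
# serialization

_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def reports_to_jsonl(reports: Sequence[AdverseEventReport]) -> str:
    """Serialize reports to the openFDA-dialect JSON-lines the ingester reads."""
    lines = []
    for r in reports:
        rec = {
            "safetyreportid": r.report_id,
            "receiptdate": r.receipt_date.strftime("%Y%m%d"),
            "patient": {
                "patientsex": _SEX_TO_CODE[r.sex],
                "drug": [
                    {
                        "medicinalproduct": e.generic_name,
                        **(
                            {"drugindication": e.indication_term}
                            if e.indication_term
                            else {}
                        ),
                    }
                    for e in r.drug_entries
                ],
                "reaction": [
                    {"reactionmeddrapt": t} for t in sorted(r.reactions)
                ],
            },
        }
        lines.append(json.dumps(rec, sort_keys=True))
    return "\n".join(lines) + "\n"
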