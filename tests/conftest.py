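import pytest

from prrnet import Sex, build_cohort, fixture_from_counts
from prrnet import fixtures


def _cohort_pair(event_counts, totals, sex):
    rows = [(e, a, b) for e, (a, b) in event_counts.items()]
    reports = fixture_from_counts(
        rows, totals[0], totals[1], "FINASTERIDE", "MINOXIDIL", sex
    )
    exposed = build_cohort(reports, "FINASTERIDE", sex)
    comparator = build_cohort(reports, "MINOXIDIL", sex)
    return exposed, comparator


@pytest.fixture(scope="session")
def male_cohorts():
    """Cohorts whose marginal counts equal the published male comparison table."""
    return _cohort_pair(fixtures.MALE_EVENT_COUNTS, fixtures.MALE_TOTALS, Sex.MALE)


@pytest.fixture(scope="session")
def female_cohorts():
    """Cohorts whose marginal counts equal the published female comparison table."""
    return _cohort_pair(fixtures.FEMALE_EVENT_COUNTS, fixtures.FEMALE_TOTALS, Sex.FEMALE)
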