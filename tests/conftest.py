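"""Shared fixtures: the deterministic reference study and analysed cohorts."""

from __future__ import annotations

import pytest

from pvsignal import (
    apply_cohort_criteria,
    drop_duplicates,
    find_duplicates,
    normalize_reactions,
    reference_criteria,
)
from pvsignal.synthetic import ReferenceStudy, reference_study


@pytest.fixture(scope="session")
def study() -> ReferenceStudy:
    return reference_study()


@pytest.fixture(scope="session")
def cohorts(study):
    """Filtered, deduplicated, synonym-normalized cohort per drug."""
    out = {}
    for drug, raw in study.raw_records.items():
        filtered = apply_cohort_criteria(raw, reference_criteria(drug))
        deduped = drop_duplicates(filtered, find_duplicates(filtered))
        out[drug] = normalize_reactions(deduped, study.meddra)
    return out


@pytest.fixture(scope="session")
def esketamine(cohorts):
    return cohorts["esketamine"]
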