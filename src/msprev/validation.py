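"""Validation of the case-finding algorithm against a gold-standard cohort.

The gold standard is a cohort of clinically confirmed MS patients from
specialist treatment centers.  Cohort records are linked to the ascertained
prevalent cases by exact person-ID match; records lacking a usable ID cannot
be linked but stay in the accounting.  Because the cohort contains only true
cases, sensitivity is the only estimable accuracy measure.  Two variants are
reported: the headline *overall* sensitivity keeps missing-ID records in the
denominator (matched/total); the *linkable* sensitivity (matched/with_id) is
the measure a linkage-quality audit needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("msprev")


@dataclass(frozen=True)
class ValidationResult:
    """Linkage accounting of a gold-standard cohort against ascertained cases."""

    total: int
    missing_id: int
    with_id: int
    matched: int
    unmatched_with_id: int
    sensitivity_overall: float
    sensitivity_linkable: float

    def __post_init__(self) -> None:
        assert self.total == self.missing_id + self.with_id
        assert self.with_id == self.matched + self.unmatched_with_id

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "missing_id": self.missing_id,
            "with_id": self.with_id,
            "matched": self.matched,
            "unmatched_with_id": self.unmatched_with_id,
            "sensitivity_overall": self.sensitivity_overall,
            "sensitivity_linkable": self.sensitivity_linkable,
            "sensitivity_overall_pct": round(100 * self.sensitivity_overall),
        }


def validate(cohort: pd.DataFrame, cases: pd.DataFrame) -> ValidationResult:
    """Sensitivity of ascertainment, taking the clinic cohort as gold standard.

    ``cohort`` needs a ``person_id`` column where missing IDs are empty
    strings or NA; ``cases`` is the ascertained prevalent-case table.
    Duplicate cohort IDs are deduplicated with a logged count; missing-ID
    records are counted, never dropped.
    """
    ids = cohort["person_id"]
    usable = ids.notna() & (ids.astype(str).str.strip() != "")
    missing_id = int((~usable).sum())
    with_ids = ids[usable].astype(str)
    dups = int(with_ids.duplicated().sum())
    if dups:
        logger.warning("cohort contains %d duplicate person IDs; deduplicated", dups)
        with_ids = with_ids.drop_duplicates()
    with_id = int(len(with_ids))
    case_ids = set(cases["person_id"].astype(str))
    matched = int(with_ids.isin(case_ids).sum())
    total = missing_id + with_id
    return ValidationResult(
        total=total,
        missing_id=missing_id,
        with_id=with_id,
        matched=matched,
        unmatched_with_id=with_id - matched,
        sensitivity_overall=matched / total if total else 0.0,
        sensitivity_linkable=matched / with_id if with_id else 0.0,
    )
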