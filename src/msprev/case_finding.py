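"""Multi-source case ascertainment by deterministic record linkage.

A prevalent case is any person with at least one qualifying claim in the study
window in any of three sources — an MS hospital discharge (HDR), an MS
disease-modifying-drug claim (PHARMED), or an MS ticket exemption (TER) —
linked across sources by exact person-ID match, minus persons who died on or
before the prevalence day and persons not registered with the regional health
service on that day.  Each case carries the date of the first qualifying
claim over all sources and the set of sources that contributed it.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd

from .registry_model import (
    DEFAULT_BANDING,
    HDR_DX_COLUMNS,
    SOURCES,
    AgeBanding,
    RegistryBundle,
    age_on,
    is_ms_diagnosis_code,
    is_ms_dmd,
    is_ms_exemption,
)

logger = logging.getLogger("msprev")

#: The 7 non-empty source combinations, canonical order.
VENN_KEYS = (
    "HDR",
    "PHARMED",
    "TER",
    "HDR|PHARMED",
    "HDR|TER",
    "PHARMED|TER",
    "HDR|PHARMED|TER",
)


@dataclass
class CaseSelectionReport:
    """Counts documenting each stage of the selection flow."""

    candidates_per_source: dict[str, int] = field(default_factory=dict)
    union_count: int = 0
    excluded_deceased: int = 0
    excluded_nonresident: int = 0
    prevalent_count: int = 0
    venn: dict[str, int] = field(default_factory=dict)
    venn_shares: dict[str, float] = field(default_factory=dict)
    repeat_claim_counts: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "candidates_per_source": self.candidates_per_source,
            "union_count": self.union_count,
            "excluded_deceased": self.excluded_deceased,
            "excluded_nonresident": self.excluded_nonresident,
            "prevalent_count": self.prevalent_count,
            "venn": self.venn,
            "venn_shares": self.venn_shares,
            "repeat_claim_counts": self.repeat_claim_counts,
        }


def share_pct(count: int, total: int) -> float:
    """A count's share of a total, as a percentage rounded to 1 decimal."""
    return round(100.0 * count / total, 1) if total else 0.0


def select_candidates(
    bundle: RegistryBundle, window: tuple[dt.date, dt.date]
) -> dict[str, pd.DataFrame]:
    """Per-source candidates: persons with >=1 qualifying claim in the window.

    Returns one long DataFrame per source with columns ``person_id`` and
    ``claim_date`` — every qualifying claim, not only the first, so repeat
    claims remain countable downstream.
    """
    start, end = window
    if start > end:
        raise ValueError(f"empty ascertainment window {start}..{end}")

    hdr = bundle.hdr
    ms_dx = hdr[HDR_DX_COLUMNS].map(
        lambda c: is_ms_diagnosis_code(c) if isinstance(c, str) and c else False
    )
    hdr_hits = hdr.loc[ms_dx.any(axis=1), ["person_id", "discharge_date"]].rename(
        columns={"discharge_date": "claim_date"}
    )

    ph = bundle.pharmed
    ph_hits = ph.loc[ph["drug"].map(is_ms_dmd), ["person_id", "dispense_date"]].rename(
        columns={"dispense_date": "claim_date"}
    )

    ter = bundle.ter
    ter_hits = ter.loc[
        ter["exemption_code"].map(is_ms_exemption), ["person_id", "start_date"]
    ].rename(columns={"start_date": "claim_date"})

    out: dict[str, pd.DataFrame] = {}
    for source, hits in zip(SOURCES, (hdr_hits, ph_hits, ter_hits)):
        in_window = hits[(hits["claim_date"] >= start) & (hits["claim_date"] <= end)]
        out[source] = in_window.reset_index(drop=True)
        logger.info(
            "%s: %d qualifying claims, %d candidates",
            source,
            len(in_window),
            in_window["person_id"].nunique(),
        )
    return out


def link_and_deduplicate(candidates: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union candidates across sources by exact person-ID equality.

    One row per person with ``first_claim_date`` (minimum qualifying date over
    all contributing sources) and ``sources`` (pipe-joined, canonical order).
    """
    frames = []
    for source in SOURCES:
        df = candidates.get(source)
        if df is None or df.empty:
            continue
        frames.append(df.assign(source=source))
    if not frames:
        return pd.DataFrame(columns=["person_id", "first_claim_date", "sources"])
    long = pd.concat(frames, ignore_index=True)
    first = long.groupby("person_id", sort=True)["claim_date"].min()
    srcs = long.groupby("person_id", sort=True)["source"].agg(
        lambda s: "|".join(src for src in SOURCES if src in set(s))
    )
    return pd.DataFrame(
        {
            "person_id": first.index,
            "first_claim_date": first.values,
            "sources": srcs.values,
        }
    ).reset_index(drop=True)


def apply_exclusions(
    linked: pd.DataFrame,
    bundle: RegistryBundle,
    prevalence_day: dt.date,
    banding: AgeBanding = DEFAULT_BANDING,
) -> tuple[pd.DataFrame, int, int]:
    """Drop deceased then non-resident candidates; attach demographics.

    Deceased: a mortality-registry record dated on or before the prevalence
    day (a death after that day leaves the person prevalent).  Non-resident:
    no assistance record, or one flagged unregistered on the prevalence day.
    Demographics and area always come from the assistance file so numerators
    share the denominators' frame.  Returns (cases, n_deceased, n_nonresident).
    """
    deaths = bundle.rencam
    dead_ids = set(
        deaths.loc[deaths["death_date"] <= prevalence_day, "person_id"]
    )
    is_dead = linked["person_id"].isin(dead_ids)
    n_deceased = int(is_dead.sum())
    alive = linked[~is_dead]

    assist = bundle.assistance.drop_duplicates(subset="person_id", keep="first")
    merged = alive.merge(
        assist[
            ["person_id", "birth_date", "gender", "district_id", "lhu_id", "registered"]
        ],
        on="person_id",
        how="left",
    )
    resident = merged["registered"].astype("boolean").fillna(False).astype(bool)
    n_nonresident = int((~resident).sum())
    cases = merged[resident].copy()

    cases["age_band"] = cases["birth_date"].map(
        lambda b: banding.label_of(age_on(b, prevalence_day))
    )
    cases = cases[
        [
            "person_id",
            "first_claim_date",
            "sources",
            "gender",
            "age_band",
            "district_id",
            "lhu_id",
        ]
    ].reset_index(drop=True)
    logger.info(
        "exclusions: %d deceased, %d non-resident; %d prevalent cases",
        n_deceased,
        n_nonresident,
        len(cases),
    )
    return cases, n_deceased, n_nonresident


def source_overlap(cases: pd.DataFrame) -> tuple[dict[str, int], dict[str, float]]:
    """Venn decomposition of the prevalent set over the 7 source combinations."""
    counts = {k: 0 for k in VENN_KEYS}
    for combo, n in cases["sources"].value_counts().items():
        counts[combo] += int(n)
    total = len(cases)
    shares = {k: share_pct(v, total) for k, v in counts.items()}
    return counts, shares


def repeat_claim_stats(
    cases: pd.DataFrame, candidates: dict[str, pd.DataFrame]
) -> dict[str, dict[str, float]]:
    """Among exclusive-source cases, how many had more than one qualifying claim.

    For each source, restrict to cases found in that source only, count those
    with >=2 qualifying claims there within the window, and report the count,
    the exclusive-case denominator, and the share as a percentage.
    """
    out: dict[str, dict[str, float]] = {}
    for source in SOURCES:
        exclusive = cases.loc[cases["sources"] == source, "person_id"]
        claims = candidates[source]
        per_person = claims.groupby("person_id").size()
        multi = int((per_person.reindex(exclusive).fillna(0) >= 2).sum())
        out[source] = {
            "exclusive_cases": int(len(exclusive)),
            "multi_claim_cases": multi,
            "multi_claim_pct": share_pct(multi, len(exclusive)),
        }
    return out


def find_cases(
    bundle: RegistryBundle,
    window: tuple[dt.date, dt.date],
    prevalence_day: dt.date,
    banding: AgeBanding = DEFAULT_BANDING,
) -> tuple[pd.DataFrame, CaseSelectionReport]:
    """Run the full ascertainment algorithm; return (cases, selection report)."""
    candidates = select_candidates(bundle, window)
    linked = link_and_deduplicate(candidates)
    cases, n_dead, n_nonres = apply_exclusions(linked, bundle, prevalence_day, banding)
    venn, shares = source_overlap(cases)
    report = CaseSelectionReport(
        candidates_per_source={
            s: int(df["person_id"].nunique()) for s, df in candidates.items()
        },
        union_count=len(linked),
        excluded_deceased=n_dead,
        excluded_nonresident=n_nonres,
        prevalent_count=len(cases),
        venn=venn,
        venn_shares=shares,
        repeat_claim_counts=repeat_claim_stats(cases, candidates),
    )
    return cases, report
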