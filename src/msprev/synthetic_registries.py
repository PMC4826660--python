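"""Synthetic registry bundles with known ground truth.

Emulates the structure of a regional health-information ecosystem: a
population stratified by district x age band x gender carries a configurable
true MS prevalence; each true case is captured independently by each of the
three ascertainment sources (hospital discharges, DMD claims, ticket
exemptions) with per-source probabilities; captured cases accrue repeat
claims; some cases die within the study window or are unregistered on the
prevalence day; false positives and non-MS distractor records can be
injected.  A truth table links every emitted qualifying record to a person
with known status, so every downstream stage is testable without real data.

The default configuration mirrors the Lazio study's published structure:
the regional age x gender distribution and stratum rates from the published
age/gender table, 12 Local Health Units with their published populations and
prevalence ratios, 56 districts nested within them, and source-capture
probabilities solved from the published exclusive/triple overlap shares under
the module's independence assumption.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .registry_model import (
    DEFAULT_BANDING,
    DEFAULT_PREVALENCE_DAY,
    DEFAULT_STUDY_WINDOW,
    AgeBand,
    AgeBanding,
    RegistryBundle,
)

#: Capture probabilities consistent (under independence) with the published
#: exclusive-source and all-three overlap shares.
DEFAULT_CAPTURE_PROBS = {"HDR": 0.63, "PHARMED": 0.53, "TER": 0.60}

#: Expected extra claims per captured case (Poisson); chosen so the share of
#: multi-claim cases 1-exp(-lambda) matches the published shares (28.6 % of
#: exclusive hospital cases, 78.2 % of exclusive pharmacy cases).
DEFAULT_REPEAT_CLAIM_MEAN = {"HDR": 0.337, "PHARMED": 1.524, "TER": 0.0}

_DMD_TOKENS = ("IFNB1A", "IFNB1B", "GLATIRAMER", "NATALIZUMAB")
_NON_MS_DX = ("331.0", "345.9", "250.00", "401.9")
_NON_MS_DRUGS = ("METFORMIN", "RAMIPRIL", "ATORVASTATIN")
_NON_MS_EXEMPTIONS = ("013.250", "002.009")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic registry generator.

    ``strata`` has one row per (district_id, lhu_id, age_band, gender) with
    columns ``population`` and ``prevalence_per_100k``.
    """

    seed: int
    strata: pd.DataFrame
    prevalence_day: dt.date = DEFAULT_PREVALENCE_DAY
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW
    capture_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAPTURE_PROBS)
    )
    repeat_claim_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPEAT_CLAIM_MEAN)
    )
    death_prob: float = 0.06
    emigration_prob: float = 0.02
    false_positive_rate: dict[str, float] = field(
        default_factory=lambda: {"HDR": 0.0, "TER": 0.0}
    )
    distractor_rate: float = 0.0
    clinic_fraction: float = 0.5
    clinic_missing_id_prob: float = 171 / 3881
    banding: AgeBanding = DEFAULT_BANDING

    def __post_init__(self) -> None:
        probs = [
            *self.capture_probs.values(),
            self.death_prob,
            self.emigration_prob,
            *self.false_positive_rate.values(),
            self.distractor_rate,
            self.clinic_fraction,
            self.clinic_missing_id_prob,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if (self.strata["population"] <= 0).any():
            raise ValueError("stratum populations must be positive")
        if (self.strata["prevalence_per_100k"] > 100_000).any():
            raise ValueError("prevalence cannot exceed 100,000 per 100,000")


def _districts_per_lhu(n_lhu: int, n_districts: int) -> list[int]:
    base, extra = divmod(n_districts, n_lhu)
    return [base + (1 if i < extra else 0) for i in range(n_lhu)]


def default_strata(n_districts: int = 56) -> pd.DataFrame:
    """Stratum grid mirroring the published regional structure.

    Age x gender rates and the regional population distribution come from the
    published age/gender table; each of the 12 LHUs gets its published
    population (reconstructed as cases / crude rate) and its published
    prevalence ratio as a multiplier on the stratum rates; districts split
    each LHU's population evenly.
    """
    ag = datasets.load_age_gender_counts()
    ag["rate"] = 1e5 * ag["cases"] / ag["population"]
    ag["share"] = ag["population"] / ag["population"].sum()
    lhu = datasets.load_lhu_table()
    lhu["lhu_pop"] = lhu["cases"] / lhu["crude_rate"] * 1e5
    nd = _districts_per_lhu(len(lhu), n_districts)
    rows = []
    d = 0
    for (_, l), n_dist in zip(lhu.iterrows(), nd):
        for _ in range(n_dist):
            d += 1
            for _, cell in ag.iterrows():
                rows.append(
                    {
                        "district_id": f"D{d:02d}",
                        "lhu_id": l["lhu_id"],
                        "age_band": cell["age_band"],
                        "gender": cell["gender"],
                        "population": int(round(l["lhu_pop"] * cell["share"] / n_dist)),
                        "prevalence_per_100k": cell["rate"] * l["pr"],
                    }
                )
    return pd.DataFrame(rows)


def default_config(seed: int, **overrides) -> SimulationConfig:
    """The study-shaped default configuration with a given seed.

    Overrides accept any config field; ``strata`` may be given as a list of
    row dicts (as from a YAML file) as well as a DataFrame, and date fields
    as ISO strings.
    """
    if isinstance(overrides.get("strata"), list):
        overrides["strata"] = pd.DataFrame(overrides["strata"])
    if isinstance(overrides.get("prevalence_day"), str):
        overrides["prevalence_day"] = dt.date.fromisoformat(overrides["prevalence_day"])
    if "study_window" in overrides:
        overrides["study_window"] = tuple(
            dt.date.fromisoformat(d) if isinstance(d, str) else d
            for d in overrides["study_window"]
        )
    cfg = SimulationConfig(seed=seed, strata=default_strata())
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _random_birth_date(
    rng: np.random.Generator, age: int, reference: dt.date
) -> dt.date:
    """A birth date giving exactly ``age`` completed years at ``reference``."""
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    year = reference.year - age - (1 if (month, day) > (reference.month, reference.day) else 0)
    return dt.date(year, month, day)


def _random_dates(
    rng: np.random.Generator, n: int, window: tuple[dt.date, dt.date]
) -> list[dt.date]:
    span = (window[1] - window[0]).days
    return [window[0] + dt.timedelta(days=int(o)) for o in rng.integers(0, span + 1, n)]


def _age_in_band(rng: np.random.Generator, band: AgeBand) -> int:
    upper = band.upper if band.upper is not None else band.lower + 25
    return int(rng.integers(band.lower, upper + 1))


class _Tables:
    def __init__(self) -> None:
        self.hdr: list[dict] = []
        self.pharmed: list[dict] = []
        self.ter: list[dict] = []
        self.rencam: list[dict] = []
        self.assistance: list[dict] = []
        self.truth: list[dict] = []


def _emit_person(
    t: _Tables,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    pid: str,
    stratum: pd.Series,
    *,
    true_ms: bool,
    captured: dict[str, bool],
) -> None:
    band = AgeBand.parse(stratum["age_band"])
    age = _age_in_band(rng, band)
    birth = _random_birth_date(rng, age, cfg.prevalence_day)
    died = true_ms and rng.random() < cfg.death_prob
    emigrated = (not died) and true_ms and rng.random() < cfg.emigration_prob
    registered = not (died or emigrated)

    window = cfg.study_window
    if captured.get("HDR"):
        n = 1 + int(rng.poisson(cfg.repeat_claim_mean.get("HDR", 0.0)))
        for date in _random_dates(rng, n, window):
            primary = rng.random() < 0.5
            t.hdr.append(
                {
                    "person_id": pid,
                    "discharge_date": date,
                    "dx1": "340.0" if primary else str(rng.choice(_NON_MS_DX)),
                    "dx2": "" if primary else "340.0",
                    "dx3": "", "dx4": "", "dx5": "", "dx6": "",
                }
            )
    if captured.get("PHARMED"):
        n = 1 + int(rng.poisson(cfg.repeat_claim_mean.get("PHARMED", 0.0)))
        for date in _random_dates(rng, n, window):
            t.pharmed.append(
                {
                    "person_id": pid,
                    "dispense_date": date,
                    "drug": str(rng.choice(_DMD_TOKENS)),
                }
            )
    if captured.get("TER"):
        n = 1 + int(rng.poisson(cfg.repeat_claim_mean.get("TER", 0.0)))
        for date in _random_dates(rng, n, window):
            t.ter.append(
                {"person_id": pid, "exemption_code": "046.340", "start_date": date}
            )
    if died:
        span = (cfg.prevalence_day - window[0]).days
        t.rencam.append(
            {
                "person_id": pid,
                "death_date": window[0] + dt.timedelta(days=int(rng.integers(0, span))),
            }
        )
    t.assistance.append(
        {
            "person_id": pid,
            "birth_date": birth,
            "gender": stratum["gender"],
            "district_id": stratum["district_id"],
            "lhu_id": stratum["lhu_id"],
            "registered": registered,
        }
    )
    t.truth.append(
        {
            "person_id": pid,
            "true_ms": true_ms,
            "district_id": stratum["district_id"],
            "lhu_id": stratum["lhu_id"],
            "age_band": stratum["age_band"],
            "gender": stratum["gender"],
            "captured_hdr": bool(captured.get("HDR")),
            "captured_pharmed": bool(captured.get("PHARMED")),
            "captured_ter": bool(captured.get("TER")),
            "died": died,
            "registered": registered,
        }
    )


def simulate_bundle(cfg: SimulationConfig) -> tuple[RegistryBundle, pd.DataFrame]:
    """Draw a registry bundle and its truth table from the configuration.

    Case counts per stratum are Binomial(population, prevalence); captures are
    independent Bernoulli per source; claim dates are uniform over the study
    window.  Output is bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    t = _Tables()
    counter = 0
    for _, stratum in cfg.strata.iterrows():
        pop = int(stratum["population"])
        prev = float(stratum["prevalence_per_100k"]) / 1e5
        n_cases = int(rng.binomial(pop, prev))
        for _ in range(n_cases):
            counter += 1
            captured = {s: rng.random() < p for s, p in cfg.capture_probs.items()}
            _emit_person(
                t, rng, cfg, f"P{counter:07d}", stratum, true_ms=True, captured=captured
            )
        for source, rate in cfg.false_positive_rate.items():
            if rate <= 0:
                continue
            n_fp = int(rng.binomial(max(pop - n_cases, 0), rate))
            for _ in range(n_fp):
                counter += 1
                _emit_person(
                    t, rng, cfg, f"P{counter:07d}", stratum,
                    true_ms=False, captured={source: True},
                )
        if cfg.distractor_rate > 0:
            n_noise = int(rng.binomial(max(pop - n_cases, 0), cfg.distractor_rate))
            for _ in range(n_noise):
                counter += 1
                pid = f"P{counter:07d}"
                _emit_person(t, rng, cfg, pid, stratum, true_ms=False, captured={})
                for date in _random_dates(rng, 1, cfg.study_window):
                    which = rng.random()
                    if which < 1 / 3:
                        t.hdr.append(
                            {
                                "person_id": pid, "discharge_date": date,
                                "dx1": str(rng.choice(_NON_MS_DX)),
                                "dx2": "", "dx3": "", "dx4": "", "dx5": "", "dx6": "",
                            }
                        )
                    elif which < 2 / 3:
                        t.pharmed.append(
                            {
                                "person_id": pid, "dispense_date": date,
                                "drug": str(rng.choice(_NON_MS_DRUGS)),
                            }
                        )
                    else:
                        t.ter.append(
                            {
                                "person_id": pid,
                                "exemption_code": str(rng.choice(_NON_MS_EXEMPTIONS)),
                                "start_date": date,
                            }
                        )

    pop_rows = []
    strata = cfg.strata
    for (dist, band, gender), grp in strata.groupby(
        ["district_id", "age_band", "gender"], sort=True
    ):
        pop_rows.append(
            {
                "area_id": dist, "area_level": "district", "age_band": band,
                "gender": gender, "population": int(grp["population"].sum()),
            }
        )
    for (lhu, band, gender), grp in strata.groupby(
        ["lhu_id", "age_band", "gender"], sort=True
    ):
        pop_rows.append(
            {
                "area_id": lhu, "area_level": "lhu", "age_band": band,
                "gender": gender, "population": int(grp["population"].sum()),
            }
        )
    for (band, gender), grp in strata.groupby(["age_band", "gender"], sort=True):
        pop_rows.append(
            {
                "area_id": "region", "area_level": "region", "age_band": band,
                "gender": gender, "population": int(grp["population"].sum()),
            }
        )

    areas = (
        strata[["district_id", "lhu_id"]]
        .drop_duplicates()
        .sort_values("district_id")
        .reset_index(drop=True)
    )
    schemas = {
        "hdr": ["person_id", "discharge_date", "dx1", "dx2", "dx3", "dx4", "dx5", "dx6"],
        "pharmed": ["person_id", "dispense_date", "drug"],
        "ter": ["person_id", "exemption_code", "start_date"],
        "rencam": ["person_id", "death_date"],
        "assistance": ["person_id", "birth_date", "gender", "district_id", "lhu_id", "registered"],
    }
    frames = {
        name: pd.DataFrame(getattr(t, name), columns=cols)
        for name, cols in schemas.items()
    }
    bundle = RegistryBundle(
        **frames, population=pd.DataFrame(pop_rows), areas=areas
    )
    truth = pd.DataFrame(
        t.truth,
        columns=[
            "person_id", "true_ms", "district_id", "lhu_id", "age_band", "gender",
            "captured_hdr", "captured_pharmed", "captured_ter", "died", "registered",
        ],
    )
    return bundle, truth


def simulate_clinic_cohort(
    truth: pd.DataFrame, cfg: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """A gold-standard clinic cohort subsampled from the true cases.

    Each sampled record's person ID is blanked independently with
    ``clinic_missing_id_prob`` (an unusable identifier, not an absent
    patient).  Columns: person_id ('' when missing), enrollment_date, center.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    cases = truth[truth["true_ms"]].reset_index(drop=True)
    take = rng.random(len(cases)) < cfg.clinic_fraction
    sampled = cases[take].reset_index(drop=True)
    blank = rng.random(len(sampled)) < cfg.clinic_missing_id_prob
    ids = sampled["person_id"].where(~blank, "")
    return pd.DataFrame(
        {
            "person_id": ids,
            "enrollment_date": _random_dates(rng, len(sampled), cfg.study_window),
            "center": [f"C{int(c)}" for c in rng.integers(1, 6, len(sampled))],
        }
    )
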