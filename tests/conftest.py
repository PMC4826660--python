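import datetime as dt

import pandas as pd
import pytest

import msprev


def make_strata(
    areas: dict[str, float],
    population: int = 20_000,
    prevalence: float = 150.0,
    bands: tuple[str, ...] = ("0-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65+"),
) -> pd.DataFrame:
    """Uniform stratum grid: per-area rate multiplier x base prevalence.

    ``areas`` maps district IDs to rate multipliers; districts are wrapped
    one-per-LHU unless the ID contains '/', in which case 'LHU/district'.
    """
    rows = []
    for area, mult in areas.items():
        lhu, _, district = area.partition("/")
        district = district or area
        for band in bands:
            for gender in ("female", "male"):
                rows.append(
                    {
                        "district_id": district,
                        "lhu_id": lhu,
                        "age_band": band,
                        "gender": gender,
                        "population": population,
                        "prevalence_per_100k": prevalence * mult,
                    }
                )
    return pd.DataFrame(rows)


def small_config(seed: int = 7, **overrides) -> msprev.SimulationConfig:
    defaults = dict(
        strata=make_strata({"A": 1.0, "B": 1.0, "C": 1.0}, population=5_000),
        death_prob=0.0,
        emigration_prob=0.0,
    )
    defaults.update(overrides)
    return msprev.default_config(seed, **defaults)


@pytest.fixture
def small_bundle():
    cfg = small_config()
    bundle, truth = msprev.simulate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture
def window() -> tuple[dt.date, dt.date]:
    return msprev.DEFAULT_STUDY_WINDOW


@pytest.fixture
def prevalence_day() -> dt.date:
    return msprev.DEFAULT_PREVALENCE_DAY
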