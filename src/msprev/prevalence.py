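"""Crude, stratum-specific and directly standardized prevalence with 95 % CIs.

Rates are expressed per 100,000 residents alive on the prevalence day.  The
default confidence interval is the normal approximation on the rate scale,
``rate * (1 +/- 1.96/sqrt(d))`` for ``d`` cases, which is the interval the
study tables use; an exact Poisson (Garwood) interval is available behind a
switch.  Direct standardization uses a fixed standard population's age-band
weights; the bundled standard is the 1976 European Standard Population (ESP),
shipped as 5-year weights and aggregated at run time to the working banding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .registry_model import DEFAULT_BANDING, GENDERS, AgeBand, AgeBanding

PER = 100_000.0
Z975 = 1.959963984540054  # Phi^{-1}(0.975)
#: Exact one-sided Poisson upper bound on the mean for zero observed events.
ZERO_EVENT_UPPER = 3.689


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A prevalence rate per 100,000 with its case count, denominator and CI."""

    cases: int
    population: float
    rate: float
    ci_low: float
    ci_high: float
    area: str = "region"
    age_band: str = "all"
    gender: str = "all"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate + 1e-9 and self.rate <= self.ci_high + 1e-9):
            raise ValueError("CI must bracket the rate")


def crude_rate(
    d: int, n: float, *, ci_method: str = "normal", labels: dict | None = None
) -> PrevalenceEstimate:
    """Prevalence per 100,000 from ``d`` cases and denominator ``n``.

    ``ci_method`` is ``"normal"`` (rate * (1 +/- 1.96/sqrt(d))) or ``"exact"``
    (Garwood gamma interval on the Poisson count).  With zero cases the normal
    interval degenerates; the exact upper bound 3.69/n is reported instead.
    """
    if n <= 0:
        raise ValueError(f"population must be positive, got {n}")
    if d < 0 or d > n:
        raise ValueError(f"case count {d} outside [0, {n}]")
    rate = PER * d / n
    if d == 0:
        lo, hi = 0.0, PER * ZERO_EVENT_UPPER / n
    elif ci_method == "normal":
        half = Z975 / np.sqrt(d)
        lo, hi = rate * (1 - half), rate * (1 + half)
    elif ci_method == "exact":
        lo = PER * stats.chi2.ppf(0.025, 2 * d) / 2 / n
        hi = PER * stats.chi2.ppf(0.975, 2 * d + 2) / 2 / n
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    labels = labels or {}
    return PrevalenceEstimate(d, n, rate, max(lo, 0.0), hi, **labels)


def stratified_rates(
    cases: pd.DataFrame,
    population: pd.DataFrame,
    banding: AgeBanding = DEFAULT_BANDING,
    *,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Rate table by age band x gender with gender margins and grand total.

    ``cases`` needs columns ``age_band`` and ``gender`` (one row per prevalent
    case) or precomputed counts (columns ``age_band, gender, cases``);
    ``population`` needs ``age_band, gender, population`` covering every
    stratum that contains a case.  Returns one row per cell plus ``gender
    margins`` (age_band == "all") and the grand total, with columns
    cases, population, rate, ci_low, ci_high.
    """
    if "cases" in cases.columns:
        counts = cases.groupby(["age_band", "gender"], as_index=False)["cases"].sum()
    else:
        counts = (
            cases.groupby(["age_band", "gender"], as_index=False)
            .size()
            .rename(columns={"size": "cases"})
        )
    pop = population.groupby(["age_band", "gender"], as_index=False)["population"].sum()
    merged = pop.merge(counts, on=["age_band", "gender"], how="outer")
    merged["cases"] = merged["cases"].fillna(0).astype(int)
    orphan = merged["population"].isna() & (merged["cases"] > 0)
    if orphan.any():
        bad = merged.loc[orphan, ["age_band", "gender"]].to_records(index=False)
        raise ValueError(f"cases in strata missing from the population table: {list(bad)}")
    merged = merged.dropna(subset=["population"])
    merged["population"] = merged["population"].astype(int)

    rows = []
    band_order = {lab: i for i, lab in enumerate(banding.labels)}

    def emit(d: int, n: int, band: str, gender: str) -> None:
        est = crude_rate(int(d), int(n), ci_method=ci_method)
        rows.append(
            {
                "age_band": band,
                "gender": gender,
                "cases": est.cases,
                "population": est.population,
                "rate": est.rate,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )

    for band in banding.labels:
        sub = merged[merged["age_band"] == band]
        for gender in GENDERS:
            cell = sub[sub["gender"] == gender]
            if len(cell):
                emit(cell["cases"].sum(), cell["population"].sum(), band, gender)
        if len(sub):
            emit(sub["cases"].sum(), sub["population"].sum(), band, "all")
    for gender in GENDERS:
        sub = merged[merged["gender"] == gender]
        if len(sub):
            emit(sub["cases"].sum(), sub["population"].sum(), "all", gender)
    emit(merged["cases"].sum(), merged["population"].sum(), "all", "all")

    out = pd.DataFrame(rows)
    out["__o"] = out["age_band"].map(lambda b: band_order.get(b, len(band_order)))
    return out.sort_values(["__o", "gender"]).drop(columns="__o").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Direct standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights of a fixed reference population, summing to one."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


def load_esp1976(banding: AgeBanding = DEFAULT_BANDING) -> StandardPopulation:
    """The 1976 European Standard Population aggregated to ``banding``.

    The shipped file carries per-100,000 weights on 5-year bands (85+ open);
    each 5-year band is assigned to the analysis band containing its lower
    bound, and weights are summed and renormalized to 1.
    """
    with resources.files("msprev.data").joinpath("esp1976.csv").open() as fh:
        esp = pd.read_csv(fh)
    agg: dict[str, float] = {lab: 0.0 for lab in banding.labels}
    for _, row in esp.iterrows():
        lower = AgeBand.parse(row["age_band_5yr"]).lower
        agg[banding.label_of(lower)] += float(row["weight"])
    total = sum(agg.values())
    return StandardPopulation({k: v / total for k, v in agg.items()})


def direct_standardize(
    band_rates: pd.DataFrame, std: StandardPopulation
) -> PrevalenceEstimate:
    """Directly standardized rate ``sum_b w_b * rate_b`` with a 95 % CI.

    ``band_rates`` needs one row per age band with columns ``age_band`` and
    ``rate``; when ``cases`` and ``population`` are present the CI uses the
    Poisson variance ``sum_b w_b^2 * 1e5^2 * d_b / n_b^2``, otherwise only the
    point estimate is meaningful (CI collapses to the rate).
    """
    have = set(band_rates["age_band"])
    want = set(std.weights)
    if have != want:
        raise ValueError(
            f"band mismatch: rates have {sorted(have - want)} extra, "
            f"missing {sorted(want - have)}"
        )
    rate = 0.0
    var = 0.0
    d_tot = 0
    n_tot = 0.0
    has_counts = {"cases", "population"} <= set(band_rates.columns)
    for _, row in band_rates.iterrows():
        w = std.weights[row["age_band"]]
        rate += w * float(row["rate"])
        if has_counts:
            d, n = float(row["cases"]), float(row["population"])
            var += w * w * PER * PER * d / (n * n)
            d_tot += int(d)
            n_tot += n
    half = Z975 * np.sqrt(var)
    return PrevalenceEstimate(
        d_tot, n_tot if n_tot else 1.0, rate, rate - half, rate + half
    )


def gender_rate_ratio(female: PrevalenceEstimate, male: PrevalenceEstimate) -> float:
    """Female-to-male rate ratio (the study's 1:x comparison)."""
    if male.rate <= 0:
        raise ValueError("male rate must be positive")
    return female.rate / male.rate
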