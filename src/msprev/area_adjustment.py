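"""Age- and gender-adjusted small-area prevalence via Poisson regression.

The model compares areas (Local Health Units or districts) net of their age
and gender structure.  Aggregated case counts per area x age band x gender
stratum are modelled as Poisson with a log link and log-population offset.
The design has **no intercept**: one indicator per area, plus age-band and
gender indicators **centered** on their population-weighted regional means,
so that ``exp(area coefficient)`` is the area's rate at the regional
age/gender mix.  Per-area expected rates p_j are obtained by averaging the
model's cell predictions over the regional age x gender distribution, then
rescaled by the multiplicative correction factor

    K = actual number of events / sum_j p_j * n_j

(n_j the area's population, m areas), which restores exact calibration of
total expected to total observed events — the log link makes plain averaging
of cell rates miss that identity.  Prevalence ratios PR_j = K*p_j / regional
crude rate quantify each area's excess prevalence; p-values are two-sided
Wald tests of the area coefficient against the population-weighted mean area
effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .registry_model import GENDERS

logger = logging.getLogger("msprev")

PER = 100_000.0
Z975 = 1.959963984540054

MAX_ITER = 100
REL_TOL = 1e-10
#: Working floor on the linear predictor, guards zero-event degeneracy.
ETA_FLOOR = -30.0


def aggregate_strata(
    cases: pd.DataFrame, population: pd.DataFrame, area_level: str
) -> pd.DataFrame:
    """Zero-filled complete crossing of area x age band x gender with counts.

    ``cases`` carries one row per prevalent case with ``lhu_id``/``district_id``,
    ``age_band`` and ``gender``; ``population`` is the denominator table with
    an ``area_level`` column.  Totals are conserved: the events column sums to
    the prevalent case count.
    """
    if area_level not in ("lhu", "district"):
        raise ValueError(f"area_level must be 'lhu' or 'district', got {area_level!r}")
    area_col = f"{area_level}_id"
    pop = population[population["area_level"] == area_level]
    if pop.empty:
        raise ValueError(f"population table has no rows at level {area_level!r}")
    pop = pop.rename(columns={"area_id": area_col})[
        [area_col, "age_band", "gender", "population"]
    ]
    counts = (
        cases.groupby([area_col, "age_band", "gender"], as_index=False)
        .size()
        .rename(columns={"size": "events"})
    )
    unknown = set(counts[area_col]) - set(pop[area_col])
    if unknown:
        raise ValueError(f"case areas missing from population table: {sorted(unknown)}")
    full = pop.merge(counts, on=[area_col, "age_band", "gender"], how="left")
    full["events"] = full["events"].fillna(0).astype(int)
    orphans = counts.merge(pop, on=[area_col, "age_band", "gender"], how="left")
    if orphans["population"].isna().any():
        bad = orphans.loc[orphans["population"].isna(), [area_col, "age_band", "gender"]]
        raise ValueError(f"case strata missing from population table:\n{bad}")
    return full.rename(columns={area_col: "area_id"}).reset_index(drop=True)


@dataclass
class AreaAdjustmentFit:
    """Fitted no-intercept centered-covariate Poisson model for area rates."""

    areas: list[str]
    coefficients: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_iter: int
    actual_events: int
    group_sizes: pd.Series  # n_j: per-area population
    covariate_means: pd.Series  # population-weighted regional means used to center
    cell_design: pd.DataFrame  # centered covariate rows per age x gender cell
    cell_shares: pd.Series  # regional population share per cell
    zero_event_areas: list[str] = field(default_factory=list)
    expected: pd.Series | None = None  # p_j per 100,000
    K: float | None = None

    @property
    def m(self) -> int:
        return len(self.areas)


def _build_design(
    strata: pd.DataFrame,
) -> tuple[np.ndarray, list[str], pd.Series, pd.DataFrame, pd.Series]:
    """Design matrix with area indicators and centered age/gender covariates."""
    areas = sorted(strata["area_id"].unique())
    bands = list(pd.unique(strata["age_band"]))
    genders = list(pd.unique(strata["gender"]))
    # Reference levels (first band, female) are absorbed by the area
    # indicators; single-level covariates are dropped entirely.
    covar_names = [f"age[{b}]" for b in bands[1:]]
    covar_cols = [(strata["age_band"] == b).to_numpy(float) for b in bands[1:]]
    if len(genders) > 1:
        covar_names.append("gender[male]")
        covar_cols.append((strata["gender"] == "male").to_numpy(float))

    X_area = np.column_stack(
        [(strata["area_id"] == a).to_numpy(float) for a in areas]
    )
    w = strata["population"].to_numpy(float)
    if covar_cols:
        covars = np.column_stack(covar_cols)
        means = covars.T @ w / w.sum()
        X = np.hstack([X_area, covars - means])
    else:
        means = np.zeros(0)
        X = X_area

    cells = (
        strata.groupby(["age_band", "gender"], sort=False)["population"]
        .sum()
        .reset_index()
    )
    cell_cols = [(cells["age_band"] == b).to_numpy(float) for b in bands[1:]]
    if len(genders) > 1:
        cell_cols.append((cells["gender"] == "male").to_numpy(float))
    cell_cov = (
        np.column_stack(cell_cols) if cell_cols else np.zeros((len(cells), 0))
    )
    cell_design = pd.DataFrame(
        cell_cov - means,
        columns=covar_names,
        index=pd.MultiIndex.from_frame(cells[["age_band", "gender"]]),
    )
    cell_shares = pd.Series(
        (cells["population"] / cells["population"].sum()).to_numpy(),
        index=cell_design.index,
    )
    means_s = pd.Series(means, index=covar_names)
    return X, areas, means_s, cell_design, cell_shares


def poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood sum(y log mu - mu - log y!)."""
    mu = np.clip(mu, 1e-300, None)
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def fit_area_model(strata: pd.DataFrame) -> AreaAdjustmentFit:
    """Maximize the Poisson likelihood by iteratively reweighted least squares.

    Strata with zero population are dropped (no exposure); convergence is a
    relative log-likelihood change below 1e-10 within 100 iterations.  Areas
    with zero events are flagged — their coefficient sits at the working
    floor and only a one-sided interval is meaningful.
    """
    strata = strata[strata["population"] > 0].reset_index(drop=True)
    if strata["area_id"].nunique() < 2:
        raise ValueError("need at least 2 areas to compare")
    X, areas, means, cell_design, cell_shares = _build_design(strata)
    y = strata["events"].to_numpy(float)
    offset = np.log(strata["population"].to_numpy(float))
    names = areas + list(means.index)

    p = X.shape[1]
    beta = np.zeros(p)
    beta[: len(areas)] = np.log(max(y.sum(), 0.5) / strata["population"].sum())
    ll_old = -np.inf
    trace: list[float] = []
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(X @ beta + offset, ETA_FLOOR, None)
        mu = np.exp(eta)
        ll = poisson_loglik(y, mu)
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= REL_TOL * (abs(ll_old) + 1e-12):
            break
        ll_old = ll
        z = (eta - offset) + (y - mu) / mu
        XtW = X.T * mu
        beta = np.linalg.solve(XtW @ X, XtW @ z)
    else:
        raise RuntimeError(
            f"IRLS did not converge in {MAX_ITER} iterations; trace tail "
            f"{trace[-5:]}"
        )
    eta = np.clip(X @ beta + offset, ETA_FLOOR, None)
    mu = np.exp(eta)
    cov = np.linalg.inv((X.T * mu) @ X)

    events_by_area = strata.groupby("area_id")["events"].sum()
    zero_areas = [a for a in areas if events_by_area.get(a, 0) == 0]
    if zero_areas:
        logger.warning("areas with zero events (one-sided CIs only): %s", zero_areas)

    return AreaAdjustmentFit(
        areas=areas,
        coefficients=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglik=poisson_loglik(y, mu),
        n_iter=it,
        actual_events=int(y.sum()),
        group_sizes=strata.groupby("area_id")["population"].sum(),
        covariate_means=means,
        cell_design=cell_design,
        cell_shares=cell_shares,
        zero_event_areas=zero_areas,
    )


def expected_rates(fit: AreaAdjustmentFit) -> pd.Series:
    """Per-area expected rates p_j per 100,000 at the regional age/gender mix.

    p_j averages the model's predicted stratum rates for area j over the
    regional population shares of the age x gender cells.
    """
    if abs(fit.cell_shares.sum() - 1.0) > 1e-9:
        raise ValueError("regional cell shares do not sum to 1")
    covar_names = list(fit.covariate_means.index)
    beta_cov = fit.coefficients[covar_names].to_numpy()
    cell_eta = fit.cell_design.to_numpy() @ beta_cov
    shares = fit.cell_shares.to_numpy()
    rates = {}
    for area in fit.areas:
        alpha = fit.coefficients[area]
        rates[area] = PER * float(np.sum(shares * np.exp(alpha + cell_eta)))
    fit.expected = pd.Series(rates)
    return fit.expected


def correction_factor(
    p: pd.Series, n: pd.Series, actual_events: int
) -> float:
    """K = actual events / sum_j (p_j / 100,000) * n_j."""
    if (n <= 0).any():
        raise ValueError("all group sizes must be positive")
    denom = float((p / PER * n.reindex(p.index)).sum())
    if denom <= 0:
        raise ValueError("expected events sum to zero")
    return actual_events / denom


def _adjusted_rate_ci(fit: AreaAdjustmentFit, area: str, K: float) -> tuple[float, float]:
    """Delta-method CI for K * p_j, propagated through the linear predictor."""
    covar_names = list(fit.covariate_means.index)
    names = list(fit.coefficients.index)
    beta_cov = fit.coefficients[covar_names].to_numpy()
    cell_eta = fit.cell_design.to_numpy() @ beta_cov
    shares = fit.cell_shares.to_numpy()
    alpha = fit.coefficients[area]
    cell_pred = shares * np.exp(alpha + cell_eta)  # per-cell contribution to p_j/1e5
    p_j = cell_pred.sum()
    grad = np.zeros(len(names))
    grad[names.index(area)] = p_j
    D = fit.cell_design.to_numpy()
    for k, name in enumerate(covar_names):
        grad[names.index(name)] = float(np.sum(cell_pred * D[:, k]))
    var = float(grad @ fit.cov.to_numpy() @ grad)
    se_log = np.sqrt(var) / p_j  # SE of log p_j by the delta method
    rate = K * PER * p_j
    return rate * np.exp(-Z975 * se_log), rate * np.exp(Z975 * se_log)


def prevalence_ratios(
    adjusted: pd.Series, regional_crude_rate: float, fit: AreaAdjustmentFit
) -> pd.DataFrame:
    """PR_j = adjusted rate / regional crude rate, with Wald p-values.

    The p-value tests the area coefficient's departure from the
    population-weighted mean area effect (contrast Wald z, two-sided).
    """
    if regional_crude_rate <= 0:
        raise ValueError("regional crude rate must be positive")
    names = list(fit.coefficients.index)
    w = fit.group_sizes.reindex(fit.areas).to_numpy(float)
    w = w / w.sum()
    cov = fit.cov.to_numpy()
    beta = fit.coefficients.to_numpy()
    rows = []
    for j, area in enumerate(fit.areas):
        c = np.zeros(len(names))
        for l, a in enumerate(fit.areas):
            c[names.index(a)] = (1.0 if a == area else 0.0) - w[l]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.nan
        pval = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "area_id": area,
                "pr": adjusted[area] / regional_crude_rate,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def adjust_areas(
    cases: pd.DataFrame, population: pd.DataFrame, area_level: str
) -> tuple[pd.DataFrame, AreaAdjustmentFit]:
    """Full small-area adjustment: aggregate, fit, calibrate, compare.

    Returns the per-area results table (area_id, cases, crude_rate,
    adjusted_rate, ci_low, ci_high, pr, p_value) and the underlying fit
    (which records K and the expected rates).
    """
    strata = aggregate_strata(cases, population, area_level)
    fit = fit_area_model(strata)
    p = expected_rates(fit)
    K = correction_factor(p, fit.group_sizes, fit.actual_events)
    fit.K = K
    logger.info("correction factor K = %.6f at level %s", K, area_level)

    events = strata.groupby("area_id")["events"].sum()
    pops = fit.group_sizes
    regional_crude = PER * fit.actual_events / pops.sum()
    adjusted = K * p
    prs = prevalence_ratios(adjusted, regional_crude, fit).set_index("area_id")

    rows = []
    for area in fit.areas:
        lo, hi = _adjusted_rate_ci(fit, area, K)
        rows.append(
            {
                "area_id": area,
                "cases": int(events[area]),
                "crude_rate": PER * events[area] / pops[area],
                "adjusted_rate": adjusted[area],
                "ci_low": lo,
                "ci_high": hi,
                "pr": prs.loc[area, "pr"],
                "p_value": prs.loc[area, "p_value"],
            }
        )
    return pd.DataFrame(rows), fit
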