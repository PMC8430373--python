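"""Design-based estimation for stratified multistage cluster samples.

Point estimates of population proportions use probability weights; variances
use Taylor linearisation of the ratio estimator, with primary sampling units
(PSUs) as the clustering level and PSU totals compared within strata. This is
the standard design-based approach used for household surveys such as the DHS,
where each record carries a stratum identifier, a PSU identifier and a
sampling weight.

Multi-country pooling follows the DHS convention: per-country normalized
weights (mean ~1) are first denormalised by external population totals so that
each country contributes in proportion to its population, then the datasets
are concatenated with country-namespaced design identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyDesign",
    "WeightedEstimate",
    "weighted_proportion",
    "weighted_mean",
    "denormalize_weights",
    "pool_datasets",
]


@dataclass(frozen=True)
class SurveyDesign:
    """Column roles describing a complex sampling design.

    Parameters
    ----------
    strata : name of the stratum-identifier column.
    psu : name of the primary-sampling-unit column. PSUs are assumed nested
        within strata; the pair (stratum, psu) identifies a cluster.
    weight : name of the sampling-weight column (positive reals).
    single_psu : policy for strata containing a single PSU, which contribute
        no within-stratum contrast. ``"centre"`` scores the lone PSU against
        the grand mean of all PSU totals (Stata's ``singleunit(centered)``);
        ``"error"`` raises.
    use_t : if True, confidence intervals use Student's t with
        ``n_psu - n_strata`` degrees of freedom instead of the normal score.
    """

    strata: str = "stratum_id"
    psu: str = "psu_id"
    weight: str = "weight"
    single_psu: Literal["centre", "error"] = "centre"
    use_t: bool = False

    def validate(self, data: pd.DataFrame) -> None:
        for col in (self.strata, self.psu, self.weight):
            if col not in data.columns:
                raise KeyError(f"design column {col!r} not in data")
        w = data[self.weight].to_numpy(dtype=float)
        if not np.all(w > 0):
            raise ValueError("all sampling weights must be positive")


@dataclass
class WeightedEstimate:
    """A design-based point estimate with its linearised uncertainty."""

    point: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    n_psu: int
    n_strata: int
    n_weighted: float = field(default=float("nan"))

    def __iter__(self):  # allow tuple-unpacking (point, se, lo, hi)
        return iter((self.point, self.se, self.ci_low, self.ci_high))


def _taylor_se(
    z: np.ndarray,
    strata: np.ndarray,
    psu: np.ndarray,
    single_psu: str,
) -> tuple[float, int, int]:
    """Standard error from linearised scores ``z`` via PSU totals in strata.

    Var = sum_h n_h/(n_h-1) * sum_c (Z_hc - Zbar_h)^2 over PSUs c in stratum h.
    """
    df = pd.DataFrame({"z": z, "_s": strata, "_p": psu})
    totals = df.groupby(["_s", "_p"], sort=False)["z"].sum()
    n_psu = len(totals)
    per_stratum = totals.groupby(level="_s", sort=False)
    n_strata = per_stratum.ngroups
    grand_mean = totals.to_numpy().mean()

    var = 0.0
    for _, t in per_stratum:
        vals = t.to_numpy()
        nh = len(vals)
        if nh == 1:
            if single_psu == "error":
                raise ValueError("stratum with a single PSU (policy: error)")
            logger.warning("single-PSU stratum: centring at grand mean")
            var += (vals[0] - grand_mean) ** 2
        else:
            var += nh / (nh - 1) * np.sum((vals - vals.mean()) ** 2)
    return float(np.sqrt(var)), n_psu, n_strata


def weighted_mean(
    values: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    *,
    alpha: float = 0.05,
    proportion: bool = False,
) -> WeightedEstimate:
    """Survey-weighted mean of ``values`` with a Taylor-linearised CI.

    Missing values are dropped together with their design rows. With
    ``proportion=True`` the CI is truncated to [0, 1].
    """
    design.validate(data)
    y = np.asarray(pd.Series(values, index=data.index), dtype=float)
    keep = ~np.isnan(y)
    if not keep.any():
        raise ValueError("indicator is entirely missing")
    y = y[keep]
    sub = data.loc[keep]
    w = sub[design.weight].to_numpy(dtype=float)
    W = w.sum()
    if W <= 0:
        raise ValueError("total weight is zero")
    point = float(np.sum(w * y) / W)

    # Linearised score of the ratio estimator Y/W
    z = w * (y - point) / W
    se, n_psu, n_strata = _taylor_se(
        z,
        sub[design.strata].to_numpy(),
        sub[design.psu].to_numpy(),
        design.single_psu,
    )
    if design.use_t and n_psu > n_strata:
        q = float(stats.t.ppf(1 - alpha / 2, df=n_psu - n_strata))
    else:
        q = float(stats.norm.ppf(1 - alpha / 2))
    lo, hi = point - q * se, point + q * se
    if proportion:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return WeightedEstimate(
        point=point,
        se=se,
        ci_low=lo,
        ci_high=hi,
        n_unweighted=int(len(y)),
        n_psu=n_psu,
        n_strata=n_strata,
        n_weighted=float(W),
    )


def weighted_proportion(
    indicator: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    *,
    alpha: float = 0.05,
) -> WeightedEstimate:
    """Design-based estimate of a population proportion.

    ``indicator`` is a 0/1 (or boolean) series aligned with ``data``; missing
    entries are excluded. The point estimate is the Hajek ratio
    ``sum(w*x)/sum(w)``; the SE comes from Taylor linearisation over PSU
    totals within strata; the 95% CI is normal-based and truncated to [0, 1].
    """
    ind = pd.Series(indicator, index=data.index).astype(float)
    vals = ind.dropna().unique()
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("indicator must be binary (0/1) or missing")
    return weighted_mean(ind, data, design, alpha=alpha, proportion=True)


def denormalize_weights(
    weights: pd.Series | np.ndarray, population_total: float
) -> np.ndarray:
    """Rescale weights so they sum exactly to an external population total.

    DHS analytic weights are normalized to mean ~1 within a country; pooled
    multi-country analyses rescale them by the country's population so that
    countries contribute proportionally to population size.
    """
    if population_total <= 0:
        raise ValueError("population_total must be positive")
    w = np.asarray(weights, dtype=float)
    if not np.all(w > 0):
        raise ValueError("weights must be positive")
    return w * (population_total / w.sum())


def pool_datasets(
    datasets: Sequence[pd.DataFrame],
    population_totals: Sequence[float],
    *,
    country_col: str = "country_id",
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Concatenate per-country datasets after weight denormalisation.

    Stratum and PSU identifiers are namespaced by country so clusters never
    merge across countries. Countries must have identical schemas and
    distinct ``country_col`` values.
    """
    if len(datasets) != len(population_totals):
        raise ValueError("one population total per dataset required")
    if not datasets:
        raise ValueError("no datasets to pool")
    design = design or SurveyDesign()
    cols = list(datasets[0].columns)
    seen: set = set()
    out = []
    for df, pop in zip(datasets, population_totals):
        if list(df.columns) != cols:
            raise ValueError("pooled datasets must share an identical schema")
        ids = set(df[country_col].unique())
        if ids & seen:
            raise ValueError(f"duplicate country id(s): {sorted(ids & seen)}")
        seen |= ids
        df = df.copy()
        df[design.weight] = denormalize_weights(df[design.weight], pop)
        for col in (design.strata, design.psu):
            df[col] = (
                df[country_col].astype(str) + "::" + df[col].astype(str)
            )
        out.append(df)
    return pd.concat(out, ignore_index=True)
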