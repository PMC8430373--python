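"""Socioeconomic inequality measures for binary coverage indicators.

Simple measures compare the extreme socioeconomic groups directly
(difference and ratio of coverages). Complex measures use the whole
socioeconomic distribution via the ridit score — the midpoint of each
ordered group's cumulative population-share interval, scaled to (0, 1) with
weighted mean 0.5:

* **RII** (relative index of inequality): exp of the ridit coefficient from
  a survey-weighted Poisson regression with log link; the risk ratio between
  the top and bottom of the socioeconomic distribution. RII > 1 means the
  advantaged are more likely to be covered.
* **SII** (slope index of inequality): the ridit coefficient from an
  identity-link fit; the absolute coverage gap across the full distribution.
* **Erreygers' normalised concentration index**: for a binary outcome,
  E = 8 x weighted covariance of the outcome with the fractional
  socioeconomic rank; bounded in [-1, 1], positive when coverage
  concentrates among the better-off.

Poisson (not binomial) estimating equations with robust, PSU-clustered
variance are used for RII/SII — the standard log-binomial-free way to
estimate risk ratios for common outcomes. Identity-link Poisson fits on
binary data often fail to converge; the documented fallback is a
survey-weighted linear probability fit, flagged in the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .survey_design import SurveyDesign, WeightedEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "RiditScores",
    "InequalityResult",
    "ridit_scores",
    "simple_measures",
    "weighted_fractional_rank",
    "estimate_rii",
    "estimate_sii",
    "erreygers_ci",
    "vif",
]

Z975 = 1.959963984540054


@dataclass(frozen=True)
class RiditScores:
    """Midpoint ridit scores of ordered socioeconomic groups."""

    categories: tuple[str, ...]  # lowest -> highest socioeconomic position
    proportions: tuple[float, ...]  # weighted group shares, sum to 1
    scores: tuple[float, ...]  # strictly increasing, in (0, 1)

    def to_records(self, labels: pd.Series) -> pd.Series:
        """Broadcast group scores to a per-record series (NaN if unknown)."""
        mapping = dict(zip(self.categories, self.scores))
        return labels.map(mapping).astype(float)


@dataclass
class InequalityResult:
    """One inequality estimate with its design-based uncertainty."""

    measure: str  # difference | ratio | rii | sii | erreygers_ci
    point: float
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    stratifier: str | None = None
    covariates: tuple[str, ...] = ()
    n: int = 0
    converged: bool = True
    link: str | None = None
    undefined: bool = False


def ridit_scores(
    labels: pd.Series,
    weights: pd.Series | np.ndarray,
    order: Sequence[str] | None = None,
) -> RiditScores:
    """Weighted midpoint ridit scores for an ordered categorical series.

    ``r_g = (cumulative weighted share below g) + p_g / 2``. Groups are taken
    in ``order`` (lowest to highest socioeconomic position); by default the
    sorted unique labels. Empty groups are dropped with a warning. The
    weighted mean of the assigned scores is exactly 0.5.
    """
    labels = pd.Series(labels).reset_index(drop=True)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(labels):
        raise ValueError("labels and weights must be aligned")
    if order is None:
        order = sorted(labels.dropna().unique())
    totals = []
    kept = []
    for g in order:
        tw = float(w[(labels == g).to_numpy()].sum())
        if tw <= 0:
            logger.warning("ridit: dropping empty group %r", g)
            continue
        kept.append(g)
        totals.append(tw)
    if len(kept) < 2:
        raise ValueError("ridit scores require at least 2 nonempty groups")
    p = np.array(totals) / np.sum(totals)
    cum = np.concatenate([[0.0], np.cumsum(p)[:-1]])
    r = cum + p / 2.0
    return RiditScores(tuple(kept), tuple(p), tuple(r))


def weighted_fractional_rank(
    labels: pd.Series,
    weights: pd.Series | np.ndarray,
    order: Sequence[str] | None = None,
) -> pd.Series:
    """Per-record fractional rank in (0, 1): each member of an ordered group
    receives the group's midpoint cumulative-weight rank. Identical values to
    :func:`ridit_scores` broadcast to records."""
    labels = pd.Series(labels)
    w = np.asarray(weights, dtype=float)
    if not np.all(w > 0):
        raise ValueError("weights must be positive")
    if order is None:
        order = sorted(labels.dropna().unique())
    if len(order) == 1:
        return pd.Series(0.5, index=labels.index)
    return ridit_scores(labels, w, order).to_records(labels)


def simple_measures(
    coverage_by_group: Mapping[str, WeightedEstimate | float],
    most_advantaged: str,
    least_advantaged: str,
) -> tuple[InequalityResult, InequalityResult]:
    """Pairwise difference and ratio between the extreme groups.

    difference = p_adv - p_dis; ratio = p_adv / p_dis (flagged undefined when
    the disadvantaged coverage is zero, in which case the difference is still
    returned).
    """
    def _point(v):
        return v.point if isinstance(v, WeightedEstimate) else float(v)

    try:
        p_adv = _point(coverage_by_group[most_advantaged])
        p_dis = _point(coverage_by_group[least_advantaged])
    except KeyError as e:
        raise KeyError(f"group {e.args[0]!r} missing from coverage table") from None

    diff = InequalityResult(measure="difference", point=p_adv - p_dis)
    if p_dis == 0:
        ratio = InequalityResult(
            measure="ratio", point=float("nan"), undefined=True
        )
    else:
        ratio = InequalityResult(measure="ratio", point=p_adv / p_dis)
    return diff, ratio


# ---------------------------------------------------------------------------
# regression-based indices

def _model_matrix(
    data: pd.DataFrame, covariates: Sequence[str], ridit: np.ndarray
) -> pd.DataFrame:
    X = pd.DataFrame({"ridit": ridit}, index=data.index)
    if covariates:
        dummies = pd.get_dummies(
            data[list(covariates)].astype("category"),
            drop_first=True,
            dtype=float,
        )
        X = pd.concat([X, dummies], axis=1)
    return sm.add_constant(X, has_constant="add")


def _cluster_groups(data: pd.DataFrame, design: SurveyDesign) -> np.ndarray:
    key = (
        data[design.strata].astype(str) + "::" + data[design.psu].astype(str)
    )
    return pd.factorize(key)[0]


def _glm_fit(
    y: np.ndarray,
    X: pd.DataFrame,
    w: np.ndarray,
    groups: np.ndarray,
    link,
    start_params=None,
):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(
            y, X.to_numpy(dtype=float),
            family=sm.families.Poisson(link=link),
            var_weights=w,
        )
        res = model.fit(
            cov_type="cluster",
            cov_kwds={"groups": groups},
            start_params=start_params,
            maxiter=200,
        )
    return res


def _prepare(
    outcome: pd.Series | np.ndarray,
    ridit: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    covariates: Sequence[str],
):
    design.validate(data)
    y = np.asarray(pd.Series(outcome, index=data.index), dtype=float)
    r = np.asarray(pd.Series(ridit, index=data.index), dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(r)
    for c in covariates:
        keep &= data[c].notna().to_numpy()
    sub = data.loc[keep]
    y, r = y[keep], r[keep]
    if len(y) == 0:
        raise ValueError("no usable records")
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; index undefined")
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("ridit scores must lie strictly in (0, 1)")
    X = _model_matrix(sub, covariates, r)
    w = sub[design.weight].to_numpy(dtype=float)
    groups = _cluster_groups(sub, design)
    return y, X, w, groups, sub


def estimate_rii(
    outcome: pd.Series | np.ndarray,
    ridit: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    covariates: Sequence[str] = (),
    stratifier: str | None = None,
) -> InequalityResult:
    """Relative index of inequality from a log-link Poisson fit.

    The binary outcome is regressed on the ridit score (plus covariates)
    with sampling weights as estimating-equation weights; the variance is a
    robust sandwich clustered at the PSU. RII = exp(ridit coefficient): the
    modelled risk ratio between the extremes of the socioeconomic
    distribution (ridit 1 vs 0).
    """
    y, X, w, groups, _ = _prepare(outcome, ridit, data, design, covariates)
    try:
        res = _glm_fit(y, X, w, groups, sm.families.links.Log())
        converged = bool(res.converged)
    except Exception as exc:  # separation, singular fits
        logger.warning("RII fit failed: %s", exc)
        return InequalityResult(
            measure="rii", point=float("nan"), stratifier=stratifier,
            covariates=tuple(covariates), n=len(y), converged=False,
            link="log",
        )
    i = list(X.columns).index("ridit")
    b, se = float(res.params[i]), float(res.bse[i])
    return InequalityResult(
        measure="rii",
        point=float(np.exp(b)),
        se=float(np.exp(b) * se),  # delta method, reported on the RII scale
        ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)),
        stratifier=stratifier,
        covariates=tuple(covariates),
        n=len(y),
        converged=converged,
        link="log",
    )


def estimate_sii(
    outcome: pd.Series | np.ndarray,
    ridit: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    covariates: Sequence[str] = (),
    stratifier: str | None = None,
) -> InequalityResult:
    """Slope index of inequality from an identity-link Poisson fit.

    SII is the ridit coefficient: the absolute coverage difference across
    the full socioeconomic range. Identity-link Poisson on binary data can
    fail to keep the mean positive; on failure the documented fallback is a
    survey-weighted linear probability (WLS) fit with the same clustered
    variance, flagged via ``link="linear_probability"``.
    """
    y, X, w, groups, _ = _prepare(outcome, ridit, data, design, covariates)
    i = list(X.columns).index("ridit")

    # WLS both as fallback and as starting values for the Poisson iterations
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wls = sm.WLS(y, X.to_numpy(dtype=float), weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
    try:
        res = _glm_fit(
            y, X, w, groups, sm.families.links.Identity(),
            start_params=wls.params,
        )
        mu = res.predict()
        if not res.converged or np.any(mu <= 0) or np.any(~np.isfinite(mu)):
            raise ValueError("identity-link fit left the parameter space")
        b, se, link, converged = (
            float(res.params[i]), float(res.bse[i]), "identity", True
        )
    except Exception as exc:
        logger.warning("identity-link SII failed (%s); linear-probability "
                       "fallback used", exc)
        b, se, link, converged = (
            float(wls.params[i]), float(wls.bse[i]),
            "linear_probability", True,
        )
    return InequalityResult(
        measure="sii",
        point=b,
        se=se,
        ci_low=b - Z975 * se,
        ci_high=b + Z975 * se,
        stratifier=stratifier,
        covariates=tuple(covariates),
        n=len(y),
        converged=converged,
        link=link,
    )


# ---------------------------------------------------------------------------
# concentration index

def _weighted_cov(y: np.ndarray, r: np.ndarray, w: np.ndarray) -> float:
    W = w.sum()
    my = np.sum(w * y) / W
    mr = np.sum(w * r) / W
    return float(np.sum(w * (y - my) * (r - mr)) / W)


def erreygers_ci(
    outcome: pd.Series | np.ndarray,
    ranks: pd.Series | np.ndarray,
    data: pd.DataFrame,
    design: SurveyDesign,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    stratifier: str | None = None,
) -> InequalityResult:
    """Erreygers' normalised concentration index for a binary outcome.

    ``E = 8 * weighted cov(outcome, fractional rank)``, the normalisation of
    the relative concentration index ``C = 2 cov / mu`` that restores the
    [-1, 1] range for bounded outcomes (E = 4 mu C for binary outcomes).
    The standard error comes from a seeded clustered bootstrap: PSUs are
    resampled with replacement within strata.
    """
    design.validate(data)
    y = np.asarray(pd.Series(outcome, index=data.index), dtype=float)
    r = np.asarray(pd.Series(ranks, index=data.index), dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(r)
    y, r = y[keep], r[keep]
    sub = data.loc[keep]
    if len(y) == 0:
        raise ValueError("empty input")
    if np.all(r == r[0]):
        raise ValueError("ranks are constant; concentration index undefined")
    w = sub[design.weight].to_numpy(dtype=float)
    point = 8.0 * _weighted_cov(y, r, w)

    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        strata = sub[design.strata].to_numpy()
        psu = sub[design.psu].to_numpy()
        # index PSU membership once
        key = pd.factorize(
            pd.Series(strata).astype(str) + "::" + pd.Series(psu).astype(str)
        )[0]
        psu_rows: dict[int, np.ndarray] = {
            k: np.flatnonzero(key == k) for k in np.unique(key)
        }
        psu_stratum = {k: strata[rows[0]] for k, rows in psu_rows.items()}
        by_stratum: dict = {}
        for k, s in psu_stratum.items():
            by_stratum.setdefault(s, []).append(k)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            rows = []
            for s, psus in by_stratum.items():
                picks = rng.choice(len(psus), size=len(psus), replace=True)
                rows.extend(psu_rows[psus[p]] for p in picks)
            idx = np.concatenate(rows)
            rb = r[idx]
            if np.all(rb == rb[0]):
                draws[b] = np.nan
                continue
            draws[b] = 8.0 * _weighted_cov(y[idx], rb, w[idx])
        se = float(np.nanstd(draws, ddof=1))
    return InequalityResult(
        measure="erreygers_ci",
        point=point,
        se=se,
        ci_low=point - Z975 * se,
        ci_high=point + Z975 * se,
        stratifier=stratifier,
        n=len(y),
        link=None,
    )


def vif(design_matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j) from regressing
    column j on the remaining columns (with intercept). Perfectly collinear
    columns report ``inf``."""
    X = design_matrix.astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 covariate columns")
    if (X.nunique() <= 1).any():
        raise ValueError("constant column in covariate matrix")
    out = {}
    for col in X.columns:
        yj = X[col].to_numpy()
        others = sm.add_constant(X.drop(columns=[col]).to_numpy())
        res = sm.OLS(yj, others).fit()
        r2 = res.rsquared
        out[col] = float("inf") if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
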