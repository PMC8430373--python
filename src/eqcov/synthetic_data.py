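"""Seeded generator of DHS-like multi-country survey microdata.

The generator emulates the design features of Demographic and Health
Surveys that matter for design-based inference — stratified two-stage
cluster sampling, normalized sampling weights, within-country wealth
quintiles derived from a latent socioeconomic score with cluster-level
correlation — and attaches per-service effective-coverage cascades whose
stage-wise conditional success probabilities follow a log-link model in the
wealth ridit score:

    P(stage k | stage k-1, r, z) = exp(alpha_k + beta_k * r + gamma_k' z)

where ``r`` is the individual's wealth-quintile midpoint ridit and ``z``
one-hot covariate indicators. Because the generative link equals the
estimating link of the relative index of inequality (RII), ``exp(beta_k)``
is *exactly* the conditional RII truth and ``exp(sum_{j<=k} beta_j)`` the
marginal truth at stage k — parameter-recovery tests are sharp, not
approximate. Probabilities are never clipped: a truth whose probabilities
would exceed 1 is rejected at validation, since clipping would silently
bias the known truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cascade import SERVICE_REGISTRY, STAGE_ORDER

__all__ = [
    "SimulationConfig",
    "StageTruth",
    "SimulationTruth",
    "default_config",
    "default_truth",
    "generate_survey",
    "true_stage_coverage",
    "true_marginal_rii",
    "inject_missingness",
    "write_records",
    "read_records",
    "write_truth_sidecar",
    "read_truth_sidecar",
]

#: Midpoint ridits of five equal-share wealth quintiles.
QUINTILE_RIDITS = np.array([0.1, 0.3, 0.5, 0.7, 0.9])

WEALTH_LABELS = ["Q1", "Q2", "Q3", "Q4", "Q5"]
INCOME_GROUPS = ["low", "lower-middle", "upper-middle"]

DEFAULT_COVARIATE_PREVALENCES: dict[str, dict[str, float]] = {
    "age_group": {"<20": 0.15, "20-35": 0.65, "35-49": 0.20},
    "parity_group": {"<=2": 0.55, ">2": 0.45},
    "education": {"primary_or_lower": 0.45, "secondary": 0.40, "tertiary": 0.15},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Design parameters of one simulated multi-country survey.

    Defaults give a desk-scale version of a multi-country DHS round:
    3 countries x 10 strata x 5 clusters x 25 individuals = 1250 records
    per country, a latent SES with moderate cluster-level correlation
    (ICC = 0.5^2/(0.5^2+1) ~ 0.2), and 40% urban clusters.
    """

    n_countries: int = 3
    n_strata: int = 10
    clusters_per_stratum: int = 5
    individuals_per_cluster: int = 25
    ses_cluster_sd: float = 0.5
    ses_individual_sd: float = 1.0
    urban_fraction: float = 0.4
    covariate_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_PREVALENCES
    )
    eligibility_fraction: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.6 for s in SERVICE_REGISTRY}
    )
    eligibility_ses_slope: float = 0.0  # logit slope of eligibility in SES
    missingness_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_countries", "n_strata", "clusters_per_stratum",
                     "individuals_per_cluster"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.ses_cluster_sd < 0 or self.ses_individual_sd < 0:
            raise ValueError("SES standard deviations must be non-negative")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction must be in [0, 1]")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        for svc, frac in self.eligibility_fraction.items():
            if not 0 < frac <= 1:
                raise ValueError(f"eligibility_fraction[{svc!r}] not in (0,1]")
        for cov, probs in self.covariate_prevalences.items():
            p = np.array(list(probs.values()), dtype=float)
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"prevalences for {cov!r} must sum to 1")

    @property
    def n_per_country(self) -> int:
        return (self.n_strata * self.clusters_per_stratum
                * self.individuals_per_cluster)


@dataclass(frozen=True)
class StageTruth:
    """Log-linear truth for one conditional cascade stage.

    alpha : log conditional baseline coverage at ridit 0.
    beta : log conditional RII across the full ridit range (0 -> 1).
    gamma : covariate -> {category: log risk ratio vs the reference}.
    """

    alpha: float
    beta: float = 0.0
    gamma: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def log_prob_bound(self) -> float:
        """Supremum of log conditional probability over ridit and covariates."""
        bound = self.alpha + max(0.0, self.beta)
        for effects in self.gamma.values():
            bound += max(0.0, max(effects.values(), default=0.0))
        return bound


@dataclass(frozen=True)
class SimulationTruth:
    """Per-service, per-stage generative parameters (the recovery estimand)."""

    services: Mapping[str, tuple[StageTruth, ...]]

    def __post_init__(self):
        for svc, stages in self.services.items():
            if svc not in SERVICE_REGISTRY:
                raise KeyError(f"unknown service {svc!r}")
            expected = len(SERVICE_REGISTRY[svc].stage_names)
            if len(stages) != expected:
                raise ValueError(
                    f"{svc}: expected {expected} stage truths, got {len(stages)}"
                )

    def validate(self) -> None:
        """Reject any stage whose probability could exceed 1 (no clipping)."""
        for svc, stages in self.services.items():
            for k, st in enumerate(stages):
                if st.log_prob_bound() > 1e-12:
                    raise ValueError(
                        f"{svc} stage {STAGE_ORDER[k]}: conditional "
                        "probability can exceed 1; clipping is not applied"
                    )

    def stage_names(self, service: str) -> tuple[str, ...]:
        return SERVICE_REGISTRY[service].stage_names


def default_truth() -> SimulationTruth:
    """Plausible truth: moderate baselines, pro-rich gradients that steepen
    along the cascade, and modest covariate effects."""
    gamma = {
        "age_group": {"<20": -0.10, "35-49": -0.05},
        "residence": {"rural": -0.15},
        "parity_group": {">2": -0.10},
    }

    def stages(alphas, betas):
        return tuple(
            StageTruth(alpha=a, beta=b, gamma=gamma) for a, b in zip(alphas, betas)
        )

    ln = np.log
    services = {
        "family_planning": stages([ln(0.55), ln(0.75), ln(0.60)],
                                  [0.10, 0.20, 0.25]),
        "anc": stages([ln(0.70), ln(0.60), ln(0.65), ln(0.70)],
                      [0.15, 0.25, 0.30, 0.30]),
        "delivery": stages([ln(0.65), ln(0.80)], [0.25, 0.15]),
        "pnc": stages([ln(0.65), ln(0.55), ln(0.50)], [0.20, 0.25, 0.35]),
        "immunisation": stages([ln(0.80), ln(0.75), ln(0.80), ln(0.55)],
                               [0.10, 0.15, 0.10, 0.25]),
        "diarrhoea": stages([ln(0.60), ln(0.65), ln(0.60), ln(0.60)],
                            [0.08, 0.12, 0.10, 0.12]),
        "itn": stages([ln(0.70), ln(0.75)], [0.05, 0.00]),
    }
    truth = SimulationTruth(services=services)
    truth.validate()
    return truth


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# generation

def _weighted_quintiles(ses: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted within-country quintile assignment (1..5) of a latent score.

    Records are ranked by (score, original order) — stable sort breaks ties
    by record order — and cut at weighted cumulative shares of 0.2.
    """
    order = np.argsort(ses, kind="stable")
    cum = np.cumsum(weights[order])
    mid = (cum - weights[order] / 2.0) / weights.sum()
    q_sorted = np.minimum((mid * 5).astype(int), 4) + 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _draw_categorical(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    cats = np.array(list(probs.keys()))
    p = np.array(list(probs.values()), dtype=float)
    return cats[rng.choice(len(cats), size=n, p=p / p.sum())]


def _covariate_log_effect(
    gamma: Mapping[str, Mapping[str, float]], frame: pd.DataFrame
) -> np.ndarray:
    eff = np.zeros(len(frame))
    for cov, effects in gamma.items():
        col = frame[cov].to_numpy()
        for cat, val in effects.items():
            eff += np.where(col == cat, val, 0.0)
    return eff


def generate_survey(
    config: SimulationConfig, truth: SimulationTruth
) -> pd.DataFrame:
    """Generate one deterministic multi-country survey dataset.

    Latent SES is a cluster-level Normal intercept plus individual Normal
    noise; wealth quintiles are weighted within-country quintile cuts of the
    latent score; sampling weights are Gamma(10) draws rescaled to mean 1 per
    country; residence is assigned at cluster level (clusters are wholly
    urban or rural, as in DHS sampling frames). For each service, eligibility
    is Bernoulli and stage indicators are drawn sequentially: a record that
    fails stage k-1 fails all deeper stages, so nesting holds by construction.

    The output is sorted by (country, stratum, psu, household, person) and is
    byte-identical for identical (config, truth).
    """
    truth.validate()
    rng = np.random.default_rng(config.seed)
    frames = []
    for ci in range(config.n_countries):
        n = config.n_per_country
        n_clusters = config.n_strata * config.clusters_per_stratum
        stratum = np.repeat(
            np.arange(config.n_strata),
            config.clusters_per_stratum * config.individuals_per_cluster,
        )
        cluster = np.repeat(np.arange(n_clusters), config.individuals_per_cluster)

        cluster_eff = rng.normal(0.0, config.ses_cluster_sd, n_clusters)
        ses = cluster_eff[cluster] + rng.normal(
            0.0, config.ses_individual_sd, n
        )
        weights = rng.gamma(shape=10.0, scale=0.1, size=n)
        weights *= n / weights.sum()  # mean exactly 1 within country

        urban_cluster = rng.random(n_clusters) < config.urban_fraction
        frame = pd.DataFrame(
            {
                "country_id": f"C{ci + 1:02d}",
                "income_group_label": INCOME_GROUPS[ci % len(INCOME_GROUPS)],
                "stratum_id": stratum + 1,
                "psu_id": cluster + 1,
                "household_id": np.arange(n) + 1,
                "person_id": 1,
                "weight": weights,
                "residence": np.where(urban_cluster[cluster], "urban", "rural"),
            }
        )
        quintile = _weighted_quintiles(ses, weights)
        frame["wealth_quintile"] = np.array(WEALTH_LABELS)[quintile - 1]
        ridit = QUINTILE_RIDITS[quintile - 1]

        for cov, probs in config.covariate_prevalences.items():
            frame[cov] = _draw_categorical(rng, probs, n)

        for svc, stages in truth.services.items():
            p_elig = config.eligibility_fraction.get(svc, 1.0)
            if config.eligibility_ses_slope != 0.0:
                logit = np.log(p_elig / (1 - p_elig)) if p_elig < 1 else np.inf
                logit = logit + config.eligibility_ses_slope * ses
                p = 1.0 / (1.0 + np.exp(-logit))
            else:
                p = np.full(n, p_elig)
            eligible = rng.random(n) < p
            frame[f"eligible_{svc}"] = eligible.astype(int)

            alive = eligible.astype(float)  # 1 while still in the cascade
            stage_names = SERVICE_REGISTRY[svc].stage_names
            for st, stage in zip(stages, stage_names):
                lp = st.alpha + st.beta * ridit + _covariate_log_effect(
                    st.gamma, frame
                )
                prob = np.exp(lp)
                if np.any(prob > 1 + 1e-12):
                    raise ValueError(
                        f"{svc}/{stage}: generated probability exceeds 1"
                    )
                success = (rng.random(n) < prob) & (alive == 1)
                col = np.where(eligible, success.astype(float), np.nan)
                frame[f"{svc}_{stage}"] = col
                alive = np.where(eligible, success.astype(float), 0.0)

        frames.append(frame)

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["country_id", "stratum_id", "psu_id", "household_id", "person_id"],
        kind="stable",
    ).reset_index(drop=True)
    if config.missingness_rate > 0:
        out = inject_missingness(
            out, config.missingness_rate, seed=config.seed + 1
        )
    return out


def inject_missingness(
    records: pd.DataFrame,
    rate: float,
    seed: int,
    covariates: Sequence[str] = ("age_group", "parity_group", "education",
                                 "residence"),
) -> pd.DataFrame:
    """Mark covariates missing completely at random at the given per-field
    rate. Stage indicators and design variables are untouched, so indicator
    nesting is preserved."""
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must be in [0, 1)")
    out = records.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    for cov in covariates:
        if cov not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        out[cov] = out[cov].astype(object)
        out.loc[mask, cov] = np.nan
    return out


# ---------------------------------------------------------------------------
# analytic oracles

def _covariate_patterns(
    config: SimulationConfig,
) -> list[tuple[dict[str, str], float]]:
    """Enumerate (covariate pattern, probability) over the generator's
    discrete covariate distribution, including cluster-level residence."""
    names, cat_lists, prob_lists = [], [], []
    for cov, probs in config.covariate_prevalences.items():
        names.append(cov)
        cat_lists.append(list(probs.keys()))
        prob_lists.append(list(probs.values()))
    names.append("residence")
    cat_lists.append(["urban", "rural"])
    prob_lists.append([config.urban_fraction, 1 - config.urban_fraction])

    patterns = []
    for combo in itertools.product(*(range(len(c)) for c in cat_lists)):
        patt = {n: cat_lists[i][j] for i, (n, j) in enumerate(zip(names, combo))}
        p = float(np.prod([prob_lists[i][j] for i, j in enumerate(combo)]))
        if p > 0:
            patterns.append((patt, p))
    return patterns


def _pattern_log_effect(
    gamma: Mapping[str, Mapping[str, float]], pattern: Mapping[str, str]
) -> float:
    eff = 0.0
    for cov, effects in gamma.items():
        eff += effects.get(pattern.get(cov, ""), 0.0)
    return eff


def true_stage_coverage(
    truth: SimulationTruth,
    config: SimulationConfig,
    service: str,
    stage: str,
) -> float:
    """Exact expected marginal coverage at a cascade stage.

    Sums the product of conditional stage probabilities over the discrete
    joint distribution of (quintile ridit, covariate pattern) — quintiles
    carry weight 0.2 each by construction of the weighted quintile cut.
    """
    if service not in truth.services:
        raise KeyError(f"unknown service {service!r}")
    stage_names = SERVICE_REGISTRY[service].stage_names
    if stage not in stage_names:
        raise KeyError(f"service {service!r} has no stage {stage!r}")
    k = stage_names.index(stage)
    stages = truth.services[service][: k + 1]

    total = 0.0
    for pattern, p_z in _covariate_patterns(config):
        for r in QUINTILE_RIDITS:
            lp = sum(
                st.alpha + st.beta * r + _pattern_log_effect(st.gamma, pattern)
                for st in stages
            )
            total += p_z * 0.2 * np.exp(lp)
    return float(total)


def true_marginal_rii(truth: SimulationTruth, service: str, stage: str) -> float:
    """exp(sum of beta up to the stage): the marginal log-link RII truth."""
    stage_names = SERVICE_REGISTRY[service].stage_names
    k = stage_names.index(stage)
    return float(np.exp(sum(st.beta for st in truth.services[service][: k + 1])))


# ---------------------------------------------------------------------------
# canonical CSV and truth sidecar

def write_records(records: pd.DataFrame, path) -> None:
    """Write the canonical record CSV: booleans as 0/1, missing as empty."""
    out = records.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format="%.10g")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_sidecar(
    truth: SimulationTruth, config: SimulationConfig, path
) -> None:
    doc = {
        "config": {
            **{k: v for k, v in asdict(config).items()
               if k not in ("covariate_prevalences", "eligibility_fraction")},
            "covariate_prevalences": {
                k: dict(v) for k, v in config.covariate_prevalences.items()
            },
            "eligibility_fraction": dict(config.eligibility_fraction),
        },
        "truth": {
            svc: [
                {"stage": stage, "alpha": float(st.alpha),
                 "beta": float(st.beta),
                 "gamma": {k: {c: float(x) for c, x in v.items()}
                           for k, v in st.gamma.items()}}
                for st, stage in zip(stages, SERVICE_REGISTRY[svc].stage_names)
            ]
            for svc, stages in truth.services.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_truth_sidecar(path) -> tuple[SimulationTruth, SimulationConfig]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    config = SimulationConfig(**doc["config"])
    services = {
        svc: tuple(
            StageTruth(alpha=d["alpha"], beta=d["beta"], gamma=d.get("gamma", {}))
            for d in stages
        )
        for svc, stages in doc["truth"].items()
    }
    return SimulationTruth(services=services), config
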