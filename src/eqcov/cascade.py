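"""Effective-coverage cascades for RMNCH services.

An effective-coverage cascade decomposes service coverage into ordered,
conditional stages: *service contact* (the target population reached a
provider), *crude coverage* (the intervention was received), *quality-adjusted
coverage* (received according to recommended standards), and
*user-adherence-adjusted coverage* (received to standard and the user adhered
to the guideline). Each stage is conditional on the previous one, so stage
coverages are non-increasing and the drop between adjacent stages localises
where potential health gain is lost: a contact→crude gap is an access/uptake
problem, a crude→quality gap a quality-of-care problem.

The built-in registry encodes seven RMNCH services with the stage depth each
supports in standard household-survey data: delivery care and insecticide-
treated nets (ITN) stop at crude coverage; family planning and postnatal care
stop at quality; antenatal care, immunisation and diarrhoea treatment run the
full four stages.

Records are expected in the canonical CSV schema: one row per individual with
``eligible_<service>`` (0/1) and per-stage raw indicators
``<service>_contact``, ``<service>_crude``, ``<service>_quality``,
``<service>_adherence`` (0/1, empty where undefined). Raw indicators may
violate nesting (real surveys contain skip-pattern inconsistencies); nesting
is enforced at estimation time by conjunction and violations are counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_design import SurveyDesign, WeightedEstimate, weighted_proportion

logger = logging.getLogger(__name__)

__all__ = [
    "STAGE_ORDER",
    "STAGE_LABELS",
    "StageDefinition",
    "CascadeDefinition",
    "CascadeResult",
    "SERVICE_REGISTRY",
    "get_cascade",
    "select_target_population",
    "nested_indicators",
    "estimate_cascade",
    "average_stage_loss",
    "retention",
]

#: Fixed four-level stage ordering (column suffix -> presentation label).
STAGE_ORDER: tuple[str, ...] = ("contact", "crude", "quality", "adherence")
STAGE_LABELS: dict[str, str] = {
    "contact": "service_contact",
    "crude": "crude",
    "quality": "quality_adjusted",
    "adherence": "user_adherence",
}

#: Default covariates excluded listwise when missing (complete-case rule).
DEFAULT_COVARIATES: tuple[str, ...] = ("age_group", "residence", "parity_group")


@dataclass(frozen=True)
class StageDefinition:
    """One cascade stage: its canonical name and required boolean fields."""

    stage_name: str
    required_fields: tuple[str, ...]

    def __post_init__(self):
        if self.stage_name not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage_name!r}")


@dataclass(frozen=True)
class CascadeDefinition:
    """A service's eligibility rule and ordered stage definitions."""

    service: str
    eligibility_field: str
    stages: tuple[StageDefinition, ...]

    def __post_init__(self):
        names = [s.stage_name for s in self.stages]
        order = [s for s in STAGE_ORDER if s in names]
        if names != order or not 2 <= len(names) <= 4:
            raise ValueError(
                f"stages must be 2-4 names in cascade order, got {names}"
            )

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(s.stage_name for s in self.stages)

    def indicator_column(self, stage: str) -> str:
        return f"{self.service}_{stage}"


def _simple_cascade(service: str, depth: int) -> CascadeDefinition:
    stages = tuple(
        StageDefinition(stage, (f"{service}_{stage}",))
        for stage in STAGE_ORDER[:depth]
    )
    return CascadeDefinition(service, f"eligible_{service}", stages)


#: The built-in seven-service registry. Depth reflects what household surveys
#: measure consistently: delivery and ITN use stop at crude coverage; family
#: planning and PNC at quality-adjusted; ANC, immunisation and diarrhoea
#: treatment support the full cascade.
SERVICE_REGISTRY: dict[str, CascadeDefinition] = {
    "family_planning": _simple_cascade("family_planning", 3),
    "anc": _simple_cascade("anc", 4),
    "delivery": _simple_cascade("delivery", 2),
    "pnc": _simple_cascade("pnc", 3),
    "immunisation": _simple_cascade("immunisation", 4),
    "diarrhoea": _simple_cascade("diarrhoea", 4),
    "itn": _simple_cascade("itn", 2),
}


def get_cascade(service: str) -> CascadeDefinition:
    try:
        return SERVICE_REGISTRY[service]
    except KeyError:
        raise KeyError(
            f"unknown service {service!r}; known: {sorted(SERVICE_REGISTRY)}"
        ) from None


@dataclass
class CascadeResult:
    """Stage-wise coverage with losses (pp) and conditional retentions (%)."""

    service: str
    estimates: dict[str, WeightedEstimate]
    losses_pp: dict[str, float]
    retentions_pct: dict[str, float | None]
    n_target_unweighted: int
    n_target_weighted: float
    n_excluded_missing: int
    nesting_violations: int

    def coverage(self, stage: str) -> float:
        return self.estimates[stage].point


def select_target_population(
    records: pd.DataFrame,
    cascade: CascadeDefinition,
    *,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, int]:
    """Restrict to the service's eligible, complete-case records.

    Returns ``(subset, n_excluded_missing)``. Records missing any of the
    listed covariates are excluded (complete-case rule) and counted.
    """
    if cascade.eligibility_field not in records.columns:
        raise KeyError(
            f"eligibility field {cascade.eligibility_field!r} missing"
        )
    eligible = records[records[cascade.eligibility_field].astype(float) == 1]
    present = [c for c in covariates if c in eligible.columns]
    complete = eligible.dropna(subset=present) if present else eligible
    n_excl = len(eligible) - len(complete)
    if n_excl:
        logger.info(
            "%s: excluded %d/%d eligible records with missing covariates",
            cascade.service, n_excl, len(eligible),
        )
    if complete.empty:
        raise ValueError(f"no eligible records for {cascade.service!r}")
    return complete, n_excl


def nested_indicators(
    records: pd.DataFrame, cascade: CascadeDefinition
) -> tuple[pd.DataFrame, int]:
    """Monotone stage indicators by cumulative conjunction of raw indicators.

    The cascade is conditional by definition: stage k requires stages 1..k.
    Raw survey indicators can violate that (skip-pattern errors); the
    conjunction repairs nesting, and each record-stage where a raw positive
    was downgraded is counted as a violation. A missing raw indicator at any
    required stage yields a missing nested value at that and deeper stages.
    """
    nested = pd.DataFrame(index=records.index)
    violations = 0
    running = pd.Series(1.0, index=records.index)
    for stage_def in cascade.stages:
        raw = pd.Series(1.0, index=records.index)
        for f in stage_def.required_fields:
            if f not in records.columns:
                raise KeyError(f"indicator field {f!r} missing from records")
            raw = raw * records[f].astype(float)
        value = running * raw
        violations += int(((raw == 1) & (running == 0)).sum())
        nested[stage_def.stage_name] = value
        running = value
    return nested, violations


def retention(upstream: float, downstream: float) -> float | None:
    """Conditional retention in percent; None when upstream coverage is 0."""
    if upstream <= 0:
        return None
    return 100.0 * downstream / upstream


def estimate_cascade(
    records: pd.DataFrame,
    cascade: CascadeDefinition | str,
    design: SurveyDesign,
    *,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CascadeResult:
    """Design-based stage coverages for one service's cascade.

    Coverage at each stage is the weighted proportion of the target
    population with the nested indicator; losses between adjacent stages are
    in percentage points and retentions are conditional percentages. Values
    are carried at full precision; rounding is presentation-only.
    """
    if isinstance(cascade, str):
        cascade = get_cascade(cascade)
    target, n_excl = select_target_population(
        records, cascade, covariates=covariates
    )
    nested, violations = nested_indicators(target, cascade)
    if violations:
        logger.warning(
            "%s: repaired %d nesting violations", cascade.service, violations
        )
    estimates: dict[str, WeightedEstimate] = {}
    for stage in cascade.stage_names:
        estimates[stage] = weighted_proportion(nested[stage], target, design)

    losses: dict[str, float] = {}
    retentions: dict[str, float | None] = {}
    names = cascade.stage_names
    for a, b in zip(names, names[1:]):
        key = f"{a}->{b}"
        losses[key] = 100.0 * (estimates[a].point - estimates[b].point)
        retentions[key] = retention(estimates[a].point, estimates[b].point)

    w = target[design.weight].to_numpy(dtype=float)
    return CascadeResult(
        service=cascade.service,
        estimates=estimates,
        losses_pp=losses,
        retentions_pct=retentions,
        n_target_unweighted=len(target),
        n_target_weighted=float(w.sum()),
        n_excluded_missing=n_excl,
        nesting_violations=violations,
    )


def average_stage_loss(
    losses_pp: Sequence[float] | Sequence[CascadeResult],
    stage_pair: str | None = None,
) -> float:
    """Unweighted mean of per-service stage losses in percentage points.

    Accepts either raw pp values or CascadeResults plus a stage pair key
    such as ``"contact->crude"``. For the loss from the target population to
    service contact, pass ``100 - coverage`` values directly.
    """
    vals: list[float] = []
    for item in losses_pp:
        if isinstance(item, CascadeResult):
            if stage_pair is None or stage_pair not in item.losses_pp:
                raise KeyError(f"stage pair {stage_pair!r} not in {item.service}")
            vals.append(item.losses_pp[stage_pair])
        else:
            vals.append(float(item))
    if not vals:
        raise ValueError("no losses supplied")
    return float(np.mean(vals))
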