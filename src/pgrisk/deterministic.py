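"""Point-estimate dietary exposure screen: chronic %ADI and acute %ARfD.

The chronic hazard quotient compares the estimated daily intake of a
residue with its acceptable daily intake:

    %ADI = C * F / (bw * ADI) * 100

with C the residue level (mg/kg), F the mean daily mushroom consumption
(converted internally from g/day to kg/day), bw the body weight (kg) and
ADI in mg/kg bw/day. The acute quotient uses a single large portion LP
(97.5th percentile of eaters, g -> kg) and the highest residue HR observed
in the survey:

    %ARfD = LP * HR / (bw * ARfD) * 100

A quotient below 100 is an acceptable risk; exactly 100 or above is not.
Non-detects enter the chronic screen at zero (best-case lower bound).
Analytes without the needed reference value cannot be assessed and are
reported as skipped rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .survey import (
    CensoringState,
    PGRDefinition,
    SubstitutionPolicy,
    SurveyDataset,
    substitute_nondetects,
)

__all__ = [
    "ConsumptionProfile",
    "RiskResult",
    "chronic_risk",
    "acute_risk",
    "highest_residue",
    "risk_screen",
    "illustrative_profiles",
    "GENERAL_LARGE_PORTION_G",
    "CHILD_LARGE_PORTION_G",
]

#: large portion sizes (97.5th percentile of eaters), Australian survey data
GENERAL_LARGE_PORTION_G = 46.3
CHILD_LARGE_PORTION_G = 12.7

RESIDUE_STATISTICS = ("mean", "p95", "p99", "max")


@dataclass(frozen=True)
class ConsumptionProfile:
    """Subpopulation consumption parameters.

    Attributes
    ----------
    label
        Subpopulation name (general, children, male, female, urban, rural,
        an age band, ...).
    f_mean
        Mean daily mushroom consumption, g/day.
    bw
        Mean body weight, kg.
    lp
        Large portion, g: the 97.5th percentile of single-occasion
        consumption among eaters, used in the acute assessment.
    """

    label: str
    f_mean: float
    bw: float
    lp: float = 0.0

    def __post_init__(self) -> None:
        if self.f_mean < 0:
            raise ValueError(f"{self.label}: f_mean must be >= 0")
        if not self.bw > 0:
            raise ValueError(f"{self.label}: body weight must be > 0")
        if self.lp < 0:
            raise ValueError(f"{self.label}: large portion must be >= 0")


@dataclass(frozen=True)
class RiskResult:
    """One hazard quotient with its full scenario metadata."""

    analyte: str
    subpopulation: str
    metric: str  # chronic_pct_adi | acute_pct_arfd
    value: float
    scenario: str  # substitution policy and residue statistic used

    @property
    def acceptable(self) -> bool:
        return self.value < 100.0


def chronic_risk(c: float, f: float, bw: float, adi: float | None) -> float:
    """Chronic hazard quotient %ADI.

    Parameters: residue level ``c`` (mg/kg), mean daily consumption ``f``
    (g/day), body weight ``bw`` (kg), ``adi`` (mg/kg bw/day).

    Raises
    ------
    ValueError
        When ``adi`` is absent (chronic risk cannot be assessed) or inputs
        are out of range.
    """
    if adi is None:
        raise ValueError("chronic risk needs an ADI; none is established")
    if c < 0 or f < 0 or not bw > 0 or not adi > 0:
        raise ValueError("chronic_risk inputs out of range")
    return c * (f / 1000.0) / (bw * adi) * 100.0


def acute_risk(lp: float, hr: float, bw: float, arfd: float | None) -> float:
    """Acute hazard quotient %ARfD.

    Parameters: large portion ``lp`` (g), highest residue ``hr`` (mg/kg),
    body weight ``bw`` (kg), ``arfd`` (mg/kg bw).

    Raises
    ------
    ValueError
        When ``arfd`` is absent — the analyte is excluded from acute
        assessment (as for thidiazuron and sodium nitrophenolate).
    """
    if arfd is None:
        raise ValueError("acute risk needs an ARfD; none is established")
    if lp < 0 or hr < 0 or not bw > 0 or not arfd > 0:
        raise ValueError("acute_risk inputs out of range")
    return (lp / 1000.0) * hr / (bw * arfd) * 100.0


def highest_residue(dataset: SurveyDataset, analyte: str) -> float:
    """Maximum quantified concentration of ``analyte`` across the survey
    (mg/kg); 0.0 when nothing was quantified."""
    frame = dataset.subset(analyte=analyte)
    quantified = frame[frame["state"] == CensoringState.QUANTIFIED.value]
    if quantified.empty:
        return 0.0
    return float(quantified["concentration_mg_kg"].max())


def _residue_statistic(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(values.mean()) if len(values) else 0.0
    if statistic == "p95":
        return float(np.percentile(values, 95)) if len(values) else 0.0
    if statistic == "p99":
        return float(np.percentile(values, 99)) if len(values) else 0.0
    if statistic == "max":
        return float(values.max()) if len(values) else 0.0
    raise ValueError(
        f"unknown residue statistic {statistic!r}; expected one of {RESIDUE_STATISTICS}"
    )


def risk_screen(
    dataset: SurveyDataset,
    profiles: Sequence[ConsumptionProfile],
    panel: Iterable[PGRDefinition],
    residue_statistic: str = "mean",
    policy: SubstitutionPolicy | str = SubstitutionPolicy.ZERO,
) -> tuple[list[RiskResult], list[str]]:
    """Deterministic chronic + acute screen over a survey.

    For every (analyte with ADI, profile) pair a chronic quotient is
    computed from the chosen residue statistic on policy-substituted data
    (default zero substitution, the lower-bound scenario); for every
    (analyte with ARfD, profile) pair an acute quotient from the highest
    residue. Analytes lacking the needed reference value are returned in
    the skipped list.

    Returns
    -------
    results : list of RiskResult
        Deterministically ordered (analyte, profile, metric).
    skipped : list of str
        Human-readable notes for analyte/metric pairs that could not be
        assessed.
    """
    panel = sorted(panel, key=lambda p: p.name)
    if not profiles:
        raise ValueError("risk_screen needs at least one consumption profile")
    if not panel:
        raise ValueError("risk_screen needs a non-empty analyte panel")
    _residue_statistic(np.zeros(1), residue_statistic)  # validate label early
    vectors = substitute_nondetects(dataset, policy)
    measured = set(dataset.analytes)
    results: list[RiskResult] = []
    skipped: list[str] = []
    policy_label = SubstitutionPolicy(policy).value
    for pgr in panel:
        if pgr.name not in measured:
            continue
        values = vectors[pgr.name]
        c = _residue_statistic(values, residue_statistic)
        hr = highest_residue(dataset, pgr.name)
        for profile in profiles:
            if pgr.adi is not None:
                results.append(
                    RiskResult(
                        analyte=pgr.name,
                        subpopulation=profile.label,
                        metric="chronic_pct_adi",
                        value=chronic_risk(c, profile.f_mean, profile.bw, pgr.adi),
                        scenario=f"policy={policy_label},statistic={residue_statistic}",
                    )
                )
            if pgr.arfd is not None and profile.lp > 0:
                results.append(
                    RiskResult(
                        analyte=pgr.name,
                        subpopulation=profile.label,
                        metric="acute_pct_arfd",
                        value=acute_risk(profile.lp, hr, profile.bw, pgr.arfd),
                        scenario=f"policy={policy_label},statistic=highest_residue",
                    )
                )
        if pgr.adi is None:
            skipped.append(f"{pgr.name}: no ADI established; chronic risk not assessed")
        if pgr.arfd is None:
            skipped.append(f"{pgr.name}: no ARfD established; acute risk not assessed")
    return results, skipped


def risk_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Risk results as a DataFrame with scenario metadata columns."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "subpopulation": r.subpopulation,
                "metric": r.metric,
                "value_pct": r.value,
                "scenario": r.scenario,
                "acceptable": r.acceptable,
            }
            for r in results
        ]
    )


def load_profiles(path) -> list[ConsumptionProfile]:
    """Read consumption profiles from CSV (label, f_mean_g_day, bw_kg, lp_g)."""
    frame = pd.read_csv(path)
    required = {"label", "f_mean_g_day", "bw_kg", "lp_g"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: profiles CSV missing column(s) {sorted(missing)}")
    return [
        ConsumptionProfile(
            label=str(row.label),
            f_mean=float(row.f_mean_g_day),
            bw=float(row.bw_kg),
            lp=float(row.lp_g),
        )
        for row in frame.itertuples(index=False)
    ]


def illustrative_profiles() -> list[ConsumptionProfile]:
    """Synthetic consumption profiles for demonstrations and tests.

    These are illustrative values in the range typical of East-Asian food
    consumption surveys, NOT the (unpublished) survey behind any particular
    study; real assessments must supply their own profiles.
    """
    return [
        ConsumptionProfile("general", f_mean=8.0, bw=60.0, lp=GENERAL_LARGE_PORTION_G),
        ConsumptionProfile("children", f_mean=4.0, bw=16.0, lp=CHILD_LARGE_PORTION_G),
        ConsumptionProfile("male", f_mean=8.5, bw=66.0, lp=GENERAL_LARGE_PORTION_G),
        ConsumptionProfile("female", f_mean=7.5, bw=56.0, lp=GENERAL_LARGE_PORTION_G),
        ConsumptionProfile("urban", f_mean=7.8, bw=61.0, lp=GENERAL_LARGE_PORTION_G),
        ConsumptionProfile("rural", f_mean=8.8, bw=59.0, lp=GENERAL_LARGE_PORTION_G),
    ]
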