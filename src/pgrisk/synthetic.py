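"""Synthetic residue surveys and consumption populations.

The analysis stages assume a particular statistical structure: a survey of
several mushroom varieties with fixed per-variety sample counts, where each
(sample, analyte) measurement is detected (quantified, >= LOQ) with some
probability and, when detected, carries a lognormal concentration; and
consumption subpopulations described by intake and body-weight
distributions. This module generates data with exactly that structure so
every pipeline stage is testable end-to-end without external data, and can
calibrate a generator design to a published per-variety summary table so
that detection counts are reproduced exactly and means approximately.

All randomness flows from the mandatory design seed through a single
:class:`numpy.random.Generator`; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deterministic import ConsumptionProfile
from .montecarlo import SamplingModel
from .survey import (
    CensoringState,
    ResidueMeasurement,
    SurveyDataset,
)

__all__ = [
    "AnalyteSpec",
    "SurveyDesign",
    "PopulationSample",
    "generate_survey",
    "calibrate_to_summary",
    "generate_population",
    "DEFAULT_LOD",
    "DEFAULT_LOQ",
]

# default reporting limits for generated analytes, mg/kg; chosen inside the
# 0.0001-0.005 (LOD) and 0.0004-0.0165 (LOQ) ranges typical of multi-residue
# LC-MS/MS methods and below every quantified value in the packaged summary
DEFAULT_LOD = 0.001
DEFAULT_LOQ = 0.002


def _per_variety(value, variety: str, default: float) -> float:
    if isinstance(value, Mapping):
        return float(value.get(variety, default))
    return float(value)


@dataclass(frozen=True)
class AnalyteSpec:
    """Generating model for one analyte.

    ``detection_probability``, ``mu`` and ``sigma`` may each be a scalar
    (shared across varieties) or a mapping variety -> value; varieties
    absent from the mapping default to probability 0 (never detected).
    Quantified concentrations are lognormal(mu, sigma) truncated below at
    the LOQ by rejection, keeping generated data consistent with the
    detection rule.
    """

    analyte: str
    detection_probability: float | Mapping[str, float] = 0.0
    mu: float | Mapping[str, float] = 0.0
    sigma: float | Mapping[str, float] = 1.0
    lod: float = DEFAULT_LOD
    loq: float = DEFAULT_LOQ
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lod <= self.loq:
            raise ValueError(f"{self.analyte}: need 0 < lod <= loq")
        probs = (
            self.detection_probability.values()
            if isinstance(self.detection_probability, Mapping)
            else [self.detection_probability]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError(f"{self.analyte}: detection probability outside [0, 1]")
        sigmas = (
            self.sigma.values() if isinstance(self.sigma, Mapping) else [self.sigma]
        )
        if any(s < 0 for s in sigmas):
            raise ValueError(f"{self.analyte}: sigma must be >= 0")


@dataclass(frozen=True)
class SurveyDesign:
    """A survey layout: per-variety sample counts plus analyte specs.

    The default layout mirrors the reference survey: 7 varieties x 15
    samples = 105. Seeds are mandatory so every generated survey is
    reproducible from its design alone.
    """

    varieties: Mapping[str, int]
    analytes: Sequence[AnalyteSpec]
    seed: int

    def __post_init__(self) -> None:
        if not self.varieties:
            raise ValueError("design needs at least one variety")
        if any(n < 1 for n in self.varieties.values()):
            raise ValueError("per-variety sample counts must be >= 1")
        names = [a.analyte for a in self.analytes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte spec")

    @property
    def total_samples(self) -> int:
        return sum(self.varieties.values())


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, loq: float, size: int
) -> np.ndarray:
    """Lognormal draws conditioned on >= loq (rejection; degenerate sigma=0
    collapses to max(exp(mu), loq))."""
    if sigma == 0.0:
        return np.full(size, max(np.exp(mu), loq))
    out = rng.lognormal(mu, sigma, size=size)
    for _ in range(1000):
        below = out < loq
        if not below.any():
            return out
        out[below] = rng.lognormal(mu, sigma, size=int(below.sum()))
    # pathological spec (mass almost entirely below LOQ): clamp remainder
    out[out < loq] = loq
    return out


def generate_survey(design: SurveyDesign) -> SurveyDataset:
    """Draw one survey from a design.

    For each (sample, analyte): with the analyte's per-variety detection
    probability, the measurement is quantified with a truncated-lognormal
    concentration; otherwise it is a non-detect. With
    ``spec.exact_counts`` the number of detected samples per variety is
    fixed at ``round(p * n)``, the detected slots chosen by sampling
    without replacement. Deterministic given the design seed.
    """
    rng = np.random.default_rng(design.seed)
    measurements: list[ResidueMeasurement] = []
    for variety, n in design.varieties.items():
        slug = variety.replace(" ", "_").replace(".", "")
        sample_ids = [f"{slug}-{i + 1:04d}" for i in range(n)]
        for spec in design.analytes:
            p = _per_variety(spec.detection_probability, variety, 0.0)
            mu = _per_variety(spec.mu, variety, 0.0)
            sigma = _per_variety(spec.sigma, variety, 0.0)
            if spec.exact_counts:
                n_det = int(round(p * n))
                detected = np.zeros(n, dtype=bool)
                if n_det > 0:
                    detected[rng.choice(n, size=n_det, replace=False)] = True
            else:
                detected = rng.random(n) < p
            n_det = int(detected.sum())
            concs = _truncated_lognormal(rng, mu, sigma, spec.loq, n_det)
            it = iter(concs)
            for sid, is_det in zip(sample_ids, detected):
                measurements.append(
                    ResidueMeasurement(
                        sample_id=sid,
                        variety=variety,
                        analyte=spec.analyte,
                        concentration=float(next(it)) if is_det else 0.0,
                        state=(
                            CensoringState.QUANTIFIED
                            if is_det
                            else CensoringState.NONDETECT
                        ),
                        lod=spec.lod,
                        loq=spec.loq,
                    )
                )
    return SurveyDataset(measurements, provenance=f"synthetic(seed={design.seed})")


def calibrate_to_summary(
    target: pd.DataFrame,
    seed: int,
    lod: float = DEFAULT_LOD,
    loq: float = DEFAULT_LOQ,
) -> SurveyDesign:
    """Build a design whose surveys reproduce a per-variety summary table.

    ``target`` uses the packaged occurrence-summary columns (variety,
    analyte, n_samples, n_detected, max_mg_kg, mean_mg_kg, ...), with equal
    ``n_samples`` per variety and means computed under zero substitution.

    Detection probabilities are set to the target detection frequencies and
    realized exactly (``exact_counts``), so summarizing a generated survey
    reproduces every detection count. The lognormal (mu, sigma) of each
    cell are moment-matched on the detected fraction: the detected-values
    mean ``m_d = mean * n / n_detected`` pins ``mu + sigma^2/2``, and the
    observed maximum, treated as the (n_d - 0.5)/n_d quantile of the
    detected distribution, pins ``mu + z * sigma``. Generated means are
    therefore approximate; detection counts are exact by construction.

    Raises
    ------
    ValueError
        For an infeasible target (cell mean exceeding its maximum, or
        unequal per-variety sample counts).
    """
    required = {"variety", "analyte", "n_samples", "n_detected", "max_mg_kg", "mean_mg_kg"}
    missing = required - set(target.columns)
    if missing:
        raise ValueError(f"target summary missing column(s) {sorted(missing)}")
    counts = target.groupby("variety")["n_samples"].first()
    if target.groupby("variety")["n_samples"].nunique().gt(1).any():
        raise ValueError("inconsistent n_samples within a variety")
    if counts.nunique() != 1:
        raise ValueError("calibration requires equal per-variety sample counts")
    bad = target[target["mean_mg_kg"] > target["max_mg_kg"] + 1e-12]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValueError(
            f"infeasible target: {row['variety']}/{row['analyte']} mean "
            f"{row['mean_mg_kg']} exceeds max {row['max_mg_kg']}"
        )

    varieties = {v: int(n) for v, n in counts.items()}
    specs: list[AnalyteSpec] = []
    for analyte, rows in target.groupby("analyte", sort=True):
        probs: dict[str, float] = {}
        mus: dict[str, float] = {}
        sigmas: dict[str, float] = {}
        for row in rows.itertuples(index=False):
            n = int(row.n_samples)
            n_det = int(row.n_detected)
            probs[row.variety] = n_det / n
            if n_det == 0:
                continue
            m_d = min(float(row.mean_mg_kg) * n / n_det, float(row.max_mg_kg))
            m_d = max(m_d, loq)
            z = stats.norm.ppf((n_det - 0.5) / n_det) if n_det >= 2 else 0.0
            d = max(np.log(float(row.max_mg_kg) / m_d), 0.0) if row.max_mg_kg > 0 else 0.0
            if z <= 0 or d == 0:
                sigma = 0.0
            elif z * z >= 2 * d:
                sigma = z - np.sqrt(z * z - 2 * d)
            else:
                sigma = z
            mus[row.variety] = float(np.log(m_d) - sigma**2 / 2.0)
            sigmas[row.variety] = float(sigma)
        specs.append(
            AnalyteSpec(
                analyte=analyte,
                detection_probability=probs,
                mu=mus,
                sigma=sigmas,
                lod=lod,
                loq=loq,
                exact_counts=True,
            )
        )
    return SurveyDesign(varieties=varieties, analytes=specs, seed=seed)


@dataclass
class PopulationSample:
    """Simulated consumption survey for one subpopulation."""

    label: str
    intake_g_day: np.ndarray
    bw_kg: np.ndarray

    @property
    def profile(self) -> ConsumptionProfile:
        """Summary profile: mean intake, mean body weight, and the empirical
        97.5th-percentile intake as the large portion."""
        return ConsumptionProfile(
            label=self.label,
            f_mean=float(self.intake_g_day.mean()),
            bw=float(self.bw_kg.mean()),
            lp=float(np.percentile(self.intake_g_day, 97.5, method="linear")),
        )


def generate_population(
    spec: Mapping[str, Mapping[str, SamplingModel]],
    n: int,
    seed: int,
) -> dict[str, PopulationSample]:
    """Simulate consumption/body-weight surveys for subpopulations.

    ``spec`` maps subpopulation label -> {"intake": SamplingModel,
    "bw": SamplingModel} (intake in g/day, bw in kg). Per label the intake
    vector is drawn first, then body weight, from one seeded generator;
    labels are processed in sorted order for reproducibility.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, PopulationSample] = {}
    for label in sorted(spec):
        models = spec[label]
        intake = models["intake"].sample(n, rng)
        bw = models["bw"].sample(n, rng)
        if (intake < 0).any() or (bw <= 0).any():
            raise ValueError(f"{label}: invalid intake/body-weight draws")
        out[label] = PopulationSample(label=label, intake_g_day=intake, bw_kg=bw)
    return out
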