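"""Probabilistic (Monte Carlo) dietary exposure assessment.

Residue concentrations are modelled as lognormal, fitted by maximum
likelihood to LOD-substituted survey values (the pessimistic censoring
convention for the probabilistic tier). Each simulation iteration draws a
residue value — and, if so configured, a consumption and body-weight value
— and propagates them through the chronic (%ADI) or acute (%ARfD) hazard
quotient. The result is a full distribution of the quotient from which
upper percentiles (default 95th and 99th) are read off, with a
block-resampling Monte Carlo standard error as convergence diagnostic.

Draws are consumed in a fixed, documented order (residue vector, then
consumption, then body weight) from a single seeded generator, so a run is
bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .deterministic import ConsumptionProfile
from .survey import SubstitutionPolicy

__all__ = [
    "SamplingModel",
    "MonteCarloConfig",
    "ExposureDistribution",
    "fit_residue_distribution",
    "simulate_exposure",
    "percentile",
    "mc_standard_error",
]


@dataclass(frozen=True)
class SamplingModel:
    """How one scalar input (consumption or body weight) is sampled.

    kind:
        ``fixed``     — every draw equals ``value``.
        ``normal``    — Normal(mean, sd), truncated below at 0 by rejection.
        ``lognormal`` — exp(Normal(mu, sigma)).
        ``empirical`` — resample ``values`` with replacement.
    """

    kind: str = "fixed"
    value: float | None = None
    mean: float | None = None
    sd: float | None = None
    mu: float | None = None
    sigma: float | None = None
    values: tuple[float, ...] | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            if self.value is None:
                raise ValueError("fixed sampling model needs `value`")
            return np.full(n, float(self.value))
        if self.kind == "normal":
            if self.mean is None or self.sd is None:
                raise ValueError("normal sampling model needs `mean` and `sd`")
            draws = rng.normal(self.mean, self.sd, size=n)
            while True:  # redraw the (rare) negative tail
                bad = draws <= 0
                if not bad.any():
                    return draws
                draws[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
        if self.kind == "lognormal":
            if self.mu is None or self.sigma is None:
                raise ValueError("lognormal sampling model needs `mu` and `sigma`")
            return rng.lognormal(self.mu, self.sigma, size=n)
        if self.kind == "empirical":
            if not self.values:
                raise ValueError("empirical sampling model needs `values`")
            pool = np.asarray(self.values, dtype=float)
            return rng.choice(pool, size=n, replace=True)
        raise ValueError(f"unknown sampling model kind {self.kind!r}")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Configuration of one exposure simulation."""

    iterations: int = 10_000
    seed: int = 0
    residue_distribution: str = "lognormal_mle"  # or empirical_bootstrap
    consumption_model: SamplingModel = field(
        default_factory=lambda: SamplingModel("fixed", value=0.0)
    )
    bw_model: SamplingModel = field(
        default_factory=lambda: SamplingModel("fixed", value=60.0)
    )
    percentiles: tuple[float, ...] = (95.0, 99.0)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        ps = list(self.percentiles)
        if any(not 0 < p < 100 for p in ps) or ps != sorted(set(ps)):
            raise ValueError("percentiles must be strictly increasing, in (0, 100)")
        if self.residue_distribution not in ("lognormal_mle", "empirical_bootstrap"):
            raise ValueError(
                f"unknown residue distribution {self.residue_distribution!r}"
            )


@dataclass
class ExposureDistribution:
    """Monte Carlo draws of a hazard quotient, with summary accessors."""

    draws: np.ndarray
    metric: str  # chronic_pct_adi | acute_pct_arfd
    config: MonteCarloConfig

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if (self.draws < 0).any():
            raise ValueError("hazard-quotient draws must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def percentile(self, q: float) -> float:
        return percentile(self, q)

    def standard_error(self, q: float, blocks: int = 10) -> float:
        return mc_standard_error(self, q, blocks)


def fit_residue_distribution(
    values: Sequence[float] | np.ndarray,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.LOD,
) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit to a substituted residue vector.

    Returns ``(mu, sigma)``: the mean and standard deviation (denominator
    ``n``) of the log concentrations. The vector must already have censored
    values substituted by a strictly positive policy — LOD by convention —
    since a lognormal cannot carry zeros; the zero policy is rejected
    outright.
    """
    policy = SubstitutionPolicy(policy)
    if policy is SubstitutionPolicy.ZERO:
        raise ValueError(
            "policy 'zero' leaves zero concentrations; a lognormal fit needs "
            "a positive substitution (use 'lod')"
        )
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to fit a lognormal")
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError(
            f"non-positive value in input under policy {policy.value!r}; "
            "substitute censored measurements by a positive value first"
        )
    logs = np.log(x)
    return float(logs.mean()), float(logs.std(ddof=0))


def simulate_exposure(
    config: MonteCarloConfig,
    residue: tuple[float, float] | Sequence[float],
    profile: ConsumptionProfile,
    reference: float,
    metric: str = "chronic_pct_adi",
) -> ExposureDistribution:
    """Monte Carlo propagation of residues through a hazard quotient.

    Parameters
    ----------
    config
        Iteration count, seed, sampling models.
    residue
        ``(mu, sigma)`` lognormal parameters when
        ``config.residue_distribution == "lognormal_mle"``; a vector of
        observed (substituted) concentrations for ``empirical_bootstrap``.
    profile
        Supplies the fixed consumption/body-weight fallbacks: if a sampling
        model is fixed with ``value=0``/unset, the profile's ``f_mean``
        (chronic), ``lp`` (acute) and ``bw`` are used.
    reference
        ADI (mg/kg bw/day, chronic) or ARfD (mg/kg bw, acute).
    metric
        ``chronic_pct_adi`` or ``acute_pct_arfd``.

    Per iteration the drawn residue plays the role of C (chronic) or HR
    (acute); intake is F (chronic) or LP (acute), g/day or g respectively.
    """
    if metric not in ("chronic_pct_adi", "acute_pct_arfd"):
        raise ValueError(f"unknown metric {metric!r}")
    if reference is None or not reference > 0:
        raise ValueError(f"{metric} needs a positive reference value")
    rng = np.random.default_rng(config.seed)
    n = config.iterations

    # draw order: residue, consumption, body weight
    if config.residue_distribution == "lognormal_mle":
        mu, sigma = residue  # type: ignore[misc]
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        c = np.exp(mu + sigma * rng.standard_normal(n)) if sigma > 0 else np.full(
            n, np.exp(mu)
        )
    else:
        pool = np.asarray(residue, dtype=float)
        if pool.size == 0:
            raise ValueError("empirical_bootstrap needs a non-empty residue vector")
        c = rng.choice(pool, size=n, replace=True)

    cons_model = config.consumption_model
    if cons_model.kind == "fixed" and not cons_model.value:
        fallback = profile.f_mean if metric == "chronic_pct_adi" else profile.lp
        cons_model = replace(cons_model, value=fallback)
    intake_g = cons_model.sample(n, rng)

    bw_model = config.bw_model
    if bw_model.kind == "fixed" and not bw_model.value:
        bw_model = replace(bw_model, value=profile.bw)
    bw = bw_model.sample(n, rng)

    draws = c * (intake_g / 1000.0) / (bw * reference) * 100.0
    return ExposureDistribution(draws=draws, metric=metric, config=config)


def percentile(dist: ExposureDistribution | np.ndarray, q: float) -> float:
    """Empirical q-th percentile (linear interpolation between closest order
    statistics, the spreadsheet convention)."""
    if not 0 < q < 100:
        raise ValueError(f"percentile q must be in (0, 100), got {q}")
    draws = dist.draws if isinstance(dist, ExposureDistribution) else np.asarray(dist)
    return float(np.percentile(draws, q, method="linear"))


def mc_standard_error(
    dist: ExposureDistribution | np.ndarray,
    q: float,
    blocks: int = 10,
) -> float:
    """Monte Carlo standard error of the q-th percentile by block splitting.

    The draw vector is cut into ``blocks`` equal consecutive blocks; the
    percentile is computed per block and the standard error of their mean
    (sd / sqrt(blocks)) is returned. Shrinks roughly as 1/sqrt(iterations).
    """
    draws = dist.draws if isinstance(dist, ExposureDistribution) else np.asarray(dist)
    if blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(draws) % blocks != 0:
        raise ValueError(
            f"iterations ({len(draws)}) must divide evenly into {blocks} blocks"
        )
    per_block = np.array(
        [percentile(chunk, q) for chunk in draws.reshape(blocks, -1)]
    )
    return float(per_block.std(ddof=1) / np.sqrt(blocks))
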