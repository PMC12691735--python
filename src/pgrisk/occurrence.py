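"""Occurrence statistics for residue surveys.

Detection frequencies, per-cell (variety x analyte) summaries under a
censoring-substitution policy, cross-variety aggregation to survey-wide
means, multi-residue co-occurrence profiles, and one-way ANOVA across
varieties with optional Tukey HSD grouping letters.

Detection throughout means a quantified measurement (>= LOQ). Detection
frequency therefore depends only on censoring states, never on the
substitution policy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import (
    CensoringState,
    SubstitutionPolicy,
    SummaryRow,
    SurveyDataset,
    substituted_frame,
)

__all__ = [
    "CooccurrenceProfile",
    "AnovaResult",
    "detection_frequency",
    "summarize",
    "summary_frame",
    "aggregate_overall_mean",
    "cooccurrence_profile",
    "one_way_anova",
    "tukey_letters",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching reported-percentage style."""
    scale = 10.0 ** ndigits
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x))


@dataclass
class CooccurrenceProfile:
    """Distribution of the number of distinct analytes detected per sample."""

    counts_by_k: dict[int, int]
    total_samples: int

    @property
    def multi_residue_rate(self) -> float:
        """Fraction of samples with two or more detected analytes."""
        if self.total_samples == 0:
            return 0.0
        multi = sum(c for k, c in self.counts_by_k.items() if k >= 2)
        return multi / self.total_samples

    @property
    def max_k(self) -> int:
        detected = [k for k, c in self.counts_by_k.items() if c > 0]
        return max(detected) if detected else 0


@dataclass
class AnovaResult:
    """Classical one-way ANOVA of residue levels across varieties."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        """Significance at the conventional p < 0.05 level."""
        return self.p_value < 0.05


def detection_frequency(
    dataset: SurveyDataset,
    analyte: str,
    variety: str | None = None,
) -> float:
    """Fraction of samples in scope with a quantified residue of ``analyte``.

    With ``variety=None`` the denominator is the full survey: samples of
    varieties never measured for the analyte count in the denominator with
    zero detections, so an analyte absent from some varieties is diluted
    accordingly.
    """
    frame = dataset.to_frame()
    if variety is not None:
        if variety not in set(frame["variety"]):
            raise KeyError(f"unknown variety {variety!r}")
        frame = frame[frame["variety"] == variety]
    n_samples = frame["sample_id"].nunique()
    if n_samples == 0:
        return 0.0
    rows = frame[frame["analyte"] == analyte]
    n_detected = int((rows["state"] == CensoringState.QUANTIFIED.value).sum())
    return n_detected / n_samples


def summarize(
    dataset: SurveyDataset,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.ZERO,
) -> list[SummaryRow]:
    """Per-(variety, analyte) occurrence summary rows.

    min/max/mean/median are computed on policy-substituted vectors, so
    censored measurements contribute their substitute value (medians of
    0.000 arise naturally in low-detection cells under the zero policy).
    """
    frame = substituted_frame(dataset, policy)
    rows: list[SummaryRow] = []
    for (variety, analyte), group in frame.groupby(["variety", "analyte"], sort=True):
        values = group["value"].to_numpy(dtype=float)
        n_detected = int((group["state"] == CensoringState.QUANTIFIED.value).sum())
        rows.append(
            SummaryRow(
                variety=variety,
                analyte=analyte,
                n_samples=len(group),
                n_detected=n_detected,
                min=float(values.min()),
                max=float(values.max()),
                mean=float(values.mean()),
                median=float(np.median(values)),
            )
        )
    return rows


def summary_frame(
    dataset: SurveyDataset,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.ZERO,
) -> pd.DataFrame:
    """:func:`summarize` as a DataFrame ready for CSV export."""
    rows = summarize(dataset, policy)
    return pd.DataFrame(
        [
            {
                "variety": r.variety,
                "analyte": r.analyte,
                "n_samples": r.n_samples,
                "n_detected": r.n_detected,
                "detection_frequency": r.detection_frequency,
                "min_mg_kg": r.min,
                "max_mg_kg": r.max,
                "mean_mg_kg": r.mean,
                "median_mg_kg": r.median,
            }
            for r in rows
        ]
    )


def aggregate_overall_mean(
    summary: pd.DataFrame | list[SummaryRow],
    analyte: str,
    n_varieties: int,
) -> float:
    """Survey-wide mean residue level from per-variety summary means.

    With equal per-variety sample counts the grand mean over the whole
    survey equals the sum of per-variety means divided by the number of
    varieties, where variety x analyte pairs with no measurements (i.e. all
    below LOD, not reported) contribute a mean of zero. This is how a
    survey-wide average is assembled from a per-variety summary table when
    sample-level data are unavailable.

    Raises
    ------
    ValueError
        If per-variety sample counts are unequal (the identity breaks; the
        mean must then be computed at sample level).
    """
    if not isinstance(summary, pd.DataFrame):
        summary = pd.DataFrame(
            [
                {"variety": r.variety, "analyte": r.analyte,
                 "n_samples": r.n_samples, "mean_mg_kg": r.mean}
                for r in summary
            ]
        )
    mean_col = "mean_mg_kg" if "mean_mg_kg" in summary.columns else "mean"
    rows = summary[summary["analyte"] == analyte]
    if rows.empty:
        return 0.0
    counts = summary["n_samples"].unique()
    if len(counts) != 1:
        raise ValueError(
            "per-variety sample counts are unequal; compute the grand mean "
            "from sample-level data instead"
        )
    if rows["variety"].nunique() > n_varieties:
        raise ValueError(
            f"{analyte}: summary covers more varieties than n_varieties={n_varieties}"
        )
    return float(rows[mean_col].sum()) / n_varieties


def cooccurrence_profile(dataset: SurveyDataset) -> CooccurrenceProfile:
    """Per-sample counts of distinct detected analytes and the multi-residue
    rate (fraction of samples with >= 2 detections)."""
    frame = dataset.to_frame()
    detected = frame[frame["state"] == CensoringState.QUANTIFIED.value]
    per_sample = detected.groupby("sample_id")["analyte"].nunique()
    all_samples = frame["sample_id"].unique()
    counts: dict[int, int] = {}
    for sid in all_samples:
        k = int(per_sample.get(sid, 0))
        counts[k] = counts.get(k, 0) + 1
    return CooccurrenceProfile(
        counts_by_k=dict(sorted(counts.items())),
        total_samples=len(all_samples),
    )


def _groups(
    dataset: SurveyDataset, analyte: str, policy: SubstitutionPolicy | str
) -> dict[str, np.ndarray]:
    frame = substituted_frame(dataset, policy)
    frame = frame[frame["analyte"] == analyte]
    return {
        variety: group["value"].to_numpy(dtype=float)
        for variety, group in frame.groupby("variety", sort=True)
    }


def one_way_anova(
    dataset: SurveyDataset,
    analyte: str,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.ZERO,
) -> AnovaResult:
    """One-way ANOVA of residue levels across varieties.

    Runs on policy-substituted concentrations (default zero substitution,
    consistent with the lower-bound deterministic scenario) grouped by
    variety.

    Raises
    ------
    ValueError
        With fewer than 2 varieties measured for the analyte, or zero
        within-group degrees of freedom.
    """
    groups = _groups(dataset, analyte, policy)
    if len(groups) < 2:
        raise ValueError(
            f"{analyte}: one-way ANOVA needs >= 2 varieties, got {len(groups)}"
        )
    sizes = [len(v) for v in groups.values()]
    n_total = sum(sizes)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if df_within <= 0:
        raise ValueError(f"{analyte}: zero within-group degrees of freedom")
    f_stat, p_value = stats.f_oneway(*groups.values())
    if not np.isfinite(f_stat):  # all groups constant and equal
        f_stat, p_value = 0.0, 1.0
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p_value),
        group_means={k: float(v.mean()) for k, v in groups.items()},
    )


def tukey_letters(
    dataset: SurveyDataset,
    analyte: str,
    policy: SubstitutionPolicy | str = SubstitutionPolicy.ZERO,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display from Tukey HSD pairwise comparisons.

    Varieties sharing a letter are not significantly different at ``alpha``.
    Letters are assigned greedily to varieties ordered by descending mean;
    a reporting convenience layered on the pairwise test, not an inference
    surface of its own.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = _groups(dataset, analyte, policy)
    if len(groups) < 2:
        raise ValueError("Tukey letters need >= 2 varieties")
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    names = list(res.groupsunique)
    differ = {
        frozenset((names[i], names[j])): bool(reject)
        for (i, j), reject in zip(
            itertools.combinations(range(len(names)), 2), res.reject
        )
    }
    ordered = sorted(groups, key=lambda g: -groups[g].mean())
    letters: dict[str, str] = {g: "" for g in ordered}
    letter_members: list[set[str]] = []
    for g in ordered:
        placed = False
        for members in letter_members:
            if all(not differ[frozenset((g, m))] for m in members):
                members.add(g)
                placed = True
        if not placed:
            letter_members.append({g})
    for idx, members in enumerate(letter_members):
        char = chr(ord("a") + idx)
        for g in members:
            letters[g] += char
    return letters
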