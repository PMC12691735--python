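"""Data model and I/O for plant-growth-regulator residue surveys.

A residue survey is a set of mushroom samples, each measured for a panel of
analytes by LC-MS/MS. Every measurement carries a censoring state relative
to the analytical limits: below the limit of detection (``nondetect``),
between LOD and LOQ (``trace``), or quantified at or above the LOQ. The
downstream occurrence and risk stages treat "detected" as quantified
(>= LOQ); trace values are substituted like non-detects.

Surveys travel as plain CSV (UTF-8, comma-separated, header row) with the
schema::

    sample_id, variety, analyte, concentration_mg_kg,
    state {nondetect|trace|quantified}, lod_mg_kg, loq_mg_kg

The module also ships machine-readable reference tables: toxicological
reference values (ADI, ARfD) for the 11-analyte PGR panel compiled from
JMPR / EU / GB2763 evaluations, and the per-variety occurrence summary of a
published 105-sample survey of seven cultivated mushroom varieties (15
samples each) that serves as the calibration target for synthetic data.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CensoringState",
    "SubstitutionPolicy",
    "PGRDefinition",
    "ResidueMeasurement",
    "SurveyDataset",
    "SummaryRow",
    "SurveyValidationError",
    "SurveySchemaError",
    "SURVEY_COLUMNS",
    "CANONICAL_VARIETIES",
    "NITROPHENOLATE_CONGENERS",
    "load_survey",
    "write_survey",
    "substitute_nondetects",
    "substituted_frame",
    "builtin_reference_tables",
]

#: canonical survey CSV column order
SURVEY_COLUMNS = (
    "sample_id",
    "variety",
    "analyte",
    "concentration_mg_kg",
    "state",
    "lod_mg_kg",
    "loq_mg_kg",
)

#: the seven mushroom varieties of the reference survey
CANONICAL_VARIETIES = (
    "A. aegerita",
    "A. auricula",
    "L. edodes",
    "P. eryngii",
    "P. ostreatus",
    "T. fuciformis",
    "H. erinaceus",
)

#: congeners reported jointly as "sodium nitrophenolate" (their per-sample
#: concentrations are summed before analysis)
NITROPHENOLATE_CONGENERS = {
    "sodium 2-nitrophenoxide": "sodium nitrophenolate",
    "sodium 4-nitrophenoxide": "sodium nitrophenolate",
    "sodium 5-nitroguaiacolate": "sodium nitrophenolate",
}


class SurveyValidationError(ValueError):
    """A survey row or record violates the data-model invariants."""


class SurveySchemaError(ValueError):
    """A survey file is missing required columns."""


class CensoringState(str, enum.Enum):
    """Censoring status of one measurement relative to LOD/LOQ."""

    NONDETECT = "nondetect"  # below LOD
    TRACE = "trace"          # >= LOD but < LOQ
    QUANTIFIED = "quantified"  # >= LOQ


class SubstitutionPolicy(str, enum.Enum):
    """How censored (nondetect/trace) values enter numeric computations.

    Ordered from optimistic to pessimistic: ``zero`` (lower bound) <
    ``half_lod`` < ``lod`` < ``loq``. The deterministic screen uses ``zero``;
    the probabilistic assessment uses ``lod``.
    """

    ZERO = "zero"
    HALF_LOD = "half_lod"
    LOD = "lod"
    LOQ = "loq"


@dataclass(frozen=True)
class PGRDefinition:
    """Toxicological reference data for one plant growth regulator.

    Parameters
    ----------
    name
        Analyte identifier.
    adi
        Acceptable daily intake, mg per kg body weight per day; ``None``
        when no chronic reference value is established.
    arfd
        Acute reference dose, mg per kg body weight; ``None`` when not
        established (such analytes are excluded from the acute assessment).
    moa
        Mode of action, free text.
    registered_cotton, registered_wheat, registered_corn
        Whether the compound is registered for use on the crop whose
        residues (seed hulls, bran) end up in mushroom cultivation
        substrates.
    source
        Citation tag of the evaluation the reference values come from.
    """

    name: str
    adi: float | None = None
    arfd: float | None = None
    moa: str = ""
    registered_cotton: bool = False
    registered_wheat: bool = False
    registered_corn: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.adi is not None and not self.adi > 0:
            raise SurveyValidationError(
                f"{self.name}: ADI must be positive when present, got {self.adi}"
            )
        if self.arfd is not None and not self.arfd > 0:
            raise SurveyValidationError(
                f"{self.name}: ARfD must be positive when present, got {self.arfd}"
            )


@dataclass(frozen=True)
class ResidueMeasurement:
    """One analyte concentration in one sample, with censoring metadata.

    ``concentration`` is mg/kg fresh weight and is meaningful only when
    ``state`` is quantified; for nondetect/trace records it is stored as 0
    and replaced at analysis time by the active substitution policy.
    """

    sample_id: str
    variety: str
    analyte: str
    concentration: float
    state: CensoringState
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise SurveyValidationError(
                f"sample {self.sample_id}/{self.analyte}: LOD must be > 0, got {self.lod}"
            )
        if self.loq < self.lod:
            raise SurveyValidationError(
                f"sample {self.sample_id}/{self.analyte}: LOQ {self.loq} < LOD {self.lod}"
            )
        if self.concentration < 0 or not math.isfinite(self.concentration):
            raise SurveyValidationError(
                f"sample {self.sample_id}/{self.analyte}: negative or non-finite "
                f"concentration {self.concentration}"
            )
        if self.state is CensoringState.QUANTIFIED and self.concentration < self.loq:
            raise SurveyValidationError(
                f"sample {self.sample_id}/{self.analyte}: quantified concentration "
                f"{self.concentration} below LOQ {self.loq}"
            )


@dataclass
class SummaryRow:
    """Occurrence summary for one (variety, analyte) cell.

    ``min``/``max``/``mean``/``median`` are computed on the vector obtained
    under the active substitution policy, so non-detects participate (as 0,
    LOD/2, LOD or LOQ). Detection means quantified, i.e. >= LOQ.
    """

    variety: str
    analyte: str
    n_samples: int
    n_detected: int
    min: float
    max: float
    mean: float
    median: float

    @property
    def detection_frequency(self) -> float:
        return self.n_detected / self.n_samples if self.n_samples else 0.0


class SurveyDataset:
    """A collection of samples x analytes residue measurements.

    Invariants enforced at construction: unique (sample, analyte) pairs, a
    single variety per sample, and per-measurement censoring consistency.
    The measurements are held as a :class:`pandas.DataFrame` in canonical
    column order, sorted by (sample_id, analyte) so that all derived outputs
    are deterministic.
    """

    def __init__(
        self,
        measurements: Iterable[ResidueMeasurement],
        provenance: str = "",
    ) -> None:
        records = list(measurements)
        self.provenance = provenance
        seen: dict[tuple[str, str], None] = {}
        variety_of: dict[str, str] = {}
        for m in records:
            key = (m.sample_id, m.analyte)
            if key in seen:
                raise SurveyValidationError(
                    f"duplicate measurement for sample {m.sample_id!r}, "
                    f"analyte {m.analyte!r}"
                )
            seen[key] = None
            prev = variety_of.setdefault(m.sample_id, m.variety)
            if prev != m.variety:
                raise SurveyValidationError(
                    f"sample {m.sample_id!r} appears with varieties "
                    f"{prev!r} and {m.variety!r}"
                )
        frame = pd.DataFrame(
            [
                (m.sample_id, m.variety, m.analyte, m.concentration,
                 m.state.value, m.lod, m.loq)
                for m in records
            ],
            columns=list(SURVEY_COLUMNS),
        )
        self._frame = frame.sort_values(
            ["sample_id", "analyte"], kind="mergesort"
        ).reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Measurements as a DataFrame in canonical column order (a copy)."""
        return self._frame.copy()

    @property
    def n_samples(self) -> int:
        return self._frame["sample_id"].nunique()

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self._frame["sample_id"].unique())

    @property
    def varieties(self) -> list[str]:
        return sorted(self._frame["variety"].unique())

    @property
    def analytes(self) -> list[str]:
        return sorted(self._frame["analyte"].unique())

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return self._frame.equals(other._frame)

    def measurements(self) -> list[ResidueMeasurement]:
        return [
            ResidueMeasurement(
                sample_id=row.sample_id,
                variety=row.variety,
                analyte=row.analyte,
                concentration=float(row.concentration_mg_kg),
                state=CensoringState(row.state),
                lod=float(row.lod_mg_kg),
                loq=float(row.loq_mg_kg),
            )
            for row in self._frame.itertuples(index=False)
        ]

    def subset(self, variety: str | None = None, analyte: str | None = None) -> pd.DataFrame:
        """Measurement rows restricted to a variety and/or analyte."""
        frame = self._frame
        if variety is not None:
            frame = frame[frame["variety"] == variety]
        if analyte is not None:
            frame = frame[frame["analyte"] == analyte]
        return frame.copy()


# -- substitution -----------------------------------------------------------

def _policy_values(frame: pd.DataFrame, policy: SubstitutionPolicy) -> np.ndarray:
    """Substituted concentration vector for the rows of ``frame``."""
    conc = frame["concentration_mg_kg"].to_numpy(dtype=float)
    censored = frame["state"].to_numpy() != CensoringState.QUANTIFIED.value
    if policy is SubstitutionPolicy.ZERO:
        fill = np.zeros(len(frame))
    elif policy is SubstitutionPolicy.HALF_LOD:
        fill = frame["lod_mg_kg"].to_numpy(dtype=float) / 2.0
    elif policy is SubstitutionPolicy.LOD:
        fill = frame["lod_mg_kg"].to_numpy(dtype=float)
    elif policy is SubstitutionPolicy.LOQ:
        fill = frame["loq_mg_kg"].to_numpy(dtype=float)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown substitution policy {policy!r}")
    return np.where(censored, fill, conc)


def substitute_nondetects(
    dataset: SurveyDataset,
    policy: SubstitutionPolicy | str,
) -> dict[str, np.ndarray]:
    """Per-analyte numeric concentration vectors under a substitution policy.

    Every nondetect and trace measurement is replaced by the policy value
    (0, LOD/2, LOD, or LOQ); quantified values pass through unchanged. Each
    vector is ordered by sample_id, with length equal to the number of
    samples measured for that analyte.

    Raises
    ------
    ValueError
        For an unknown policy label.
    """
    policy = SubstitutionPolicy(policy)
    frame = dataset.to_frame()
    return {
        analyte: _policy_values(group, policy)
        for analyte, group in frame.groupby("analyte", sort=True)
    }


def substituted_frame(
    dataset: SurveyDataset, policy: SubstitutionPolicy | str
) -> pd.DataFrame:
    """Measurement frame with an extra ``value`` column under ``policy``."""
    policy = SubstitutionPolicy(policy)
    frame = dataset.to_frame()
    frame["value"] = _policy_values(frame, policy)
    return frame


# -- CSV I/O -----------------------------------------------------------------

def _parse_row(
    row: Mapping[str, object], rownum: int, schema: Mapping[str, str]
) -> ResidueMeasurement:
    def col(name: str) -> object:
        return row[schema.get(name, name)]

    try:
        state = CensoringState(str(col("state")).strip().lower())
    except ValueError as exc:
        raise SurveyValidationError(
            f"row {rownum}: unknown censoring state {col('state')!r}"
        ) from exc
    try:
        conc = float(col("concentration_mg_kg"))
        lod = float(col("lod_mg_kg"))
        loq = float(col("loq_mg_kg"))
    except (TypeError, ValueError) as exc:
        raise SurveyValidationError(
            f"row {rownum}: non-numeric concentration/LOD/LOQ"
        ) from exc
    try:
        return ResidueMeasurement(
            sample_id=str(col("sample_id")),
            variety=str(col("variety")),
            analyte=str(col("analyte")).strip().lower(),
            concentration=conc,
            state=state,
            lod=lod,
            loq=loq,
        )
    except SurveyValidationError as exc:
        raise SurveyValidationError(f"row {rownum}: {exc}") from exc


def _merge_congeners(
    records: list[ResidueMeasurement],
) -> list[ResidueMeasurement]:
    """Sum congener-level rows into their joint analyte, per sample.

    The summed record is quantified if any congener is, with concentration
    the sum of quantified congener concentrations, and LOD/LOQ the maximum
    across congeners (the most conservative reporting limit).
    """
    plain = [r for r in records if r.analyte not in NITROPHENOLATE_CONGENERS]
    groups: dict[tuple[str, str], list[ResidueMeasurement]] = {}
    for r in records:
        if r.analyte in NITROPHENOLATE_CONGENERS:
            joint = NITROPHENOLATE_CONGENERS[r.analyte]
            groups.setdefault((r.sample_id, joint), []).append(r)
    for (sample_id, joint), members in groups.items():
        states = [m.state for m in members]
        if CensoringState.QUANTIFIED in states:
            state = CensoringState.QUANTIFIED
        elif CensoringState.TRACE in states:
            state = CensoringState.TRACE
        else:
            state = CensoringState.NONDETECT
        conc = sum(
            m.concentration for m in members if m.state is CensoringState.QUANTIFIED
        )
        lod = max(m.lod for m in members)
        loq = max(m.loq for m in members)
        if state is CensoringState.QUANTIFIED:
            # the summed total can sit below the (max) LOQ; keep it valid
            loq = min(loq, conc) if conc > 0 else loq
            lod = min(lod, loq)
        plain.append(
            ResidueMeasurement(
                sample_id=sample_id,
                variety=members[0].variety,
                analyte=joint,
                concentration=conc if state is CensoringState.QUANTIFIED else 0.0,
                state=state,
                lod=lod,
                loq=loq,
            )
        )
    return plain


def load_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> SurveyDataset:
    """Read a residue survey from delimited text.

    Parameters
    ----------
    path
        CSV file with the canonical survey columns (header required).
    schema
        Optional mapping from canonical column names to the names used in
        the file, for ingesting foreign layouts.
    provenance
        Free-text origin note; defaults to the file name.

    Raises
    ------
    SurveySchemaError
        If a required column is missing.
    SurveyValidationError
        If any row violates the measurement invariants; the message names
        the 1-based data row.
    """
    schema = dict(schema or {})
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [
        canonical
        for canonical in SURVEY_COLUMNS
        if schema.get(canonical, canonical) not in frame.columns
    ]
    if missing:
        raise SurveySchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    records = [
        _parse_row(row, rownum, schema)
        for rownum, row in enumerate(frame.to_dict("records"), start=1)
    ]
    records = _merge_congeners(records)
    return SurveyDataset(
        records, provenance=provenance if provenance is not None else str(path)
    )


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a survey to CSV in canonical column order, one row per
    measurement, censoring state spelled out. Lossless inverse of
    :func:`load_survey` (and idempotent: write -> read -> write is
    byte-identical)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")


# -- packaged reference tables ----------------------------------------------

def _data_path(name: str):
    return resources.files("pgrisk.data").joinpath(name)


def builtin_reference_tables() -> tuple[list[PGRDefinition], pd.DataFrame]:
    """Packaged machine-readable reference data.

    Returns
    -------
    panel : list of PGRDefinition
        The 11-analyte PGR panel with ADI/ARfD values from JMPR / EU /
        GB2763 evaluations.
    occurrence : pandas.DataFrame
        Per-variety occurrence summary of the reference 105-sample survey
        (7 varieties x 15 samples): detection counts ("N > LOQ"), maxima,
        means and medians under lower-bound (zero) substitution. Columns:
        variety, analyte, n_samples, n_detected, min_detected_mg_kg,
        max_mg_kg, mean_mg_kg, median_mg_kg.
    """
    with _data_path("pgr_reference_values.csv").open() as fh:
        ref = pd.read_csv(fh)
    panel = [
        PGRDefinition(
            name=row.name,
            adi=None if pd.isna(row.adi_mg_kg_bw_day) else float(row.adi_mg_kg_bw_day),
            arfd=None if pd.isna(row.arfd_mg_kg_bw) else float(row.arfd_mg_kg_bw),
            moa=row.moa,
            registered_cotton=row.registered_cotton == "Y",
            registered_wheat=row.registered_wheat == "Y",
            registered_corn=row.registered_corn == "Y",
            source=row.source,
        )
        for row in ref.itertuples(index=False)
    ]
    with _data_path("mushroom_occurrence_summary.csv").open() as fh:
        occurrence = pd.read_csv(fh)
    return panel, occurrence


def panel_by_name() -> dict[str, PGRDefinition]:
    """The packaged PGR panel keyed by analyte name."""
    panel, _ = builtin_reference_tables()
    return {p.name: p for p in panel}
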