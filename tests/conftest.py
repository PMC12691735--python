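import numpy as np
import pytest

from pgrisk.survey import (
    CensoringState,
    ResidueMeasurement,
    SurveyDataset,
    builtin_reference_tables,
)


@pytest.fixture(scope="session")
def reference_tables():
    return builtin_reference_tables()


@pytest.fixture(scope="session")
def panel_by_name(reference_tables):
    panel, _ = reference_tables
    return {p.name: p for p in panel}


def make_measurement(
    sample_id="s1",
    variety="A. aegerita",
    analyte="chlormequat",
    concentration=0.0,
    state=CensoringState.NONDETECT,
    lod=0.001,
    loq=0.002,
):
    return ResidueMeasurement(
        sample_id=sample_id,
        variety=variety,
        analyte=analyte,
        concentration=concentration,
        state=state,
        lod=lod,
        loq=loq,
    )


def dataset_from_values(values_by_analyte, variety="A. aegerita", lod=0.001, loq=0.002):
    """Dataset from {analyte: [conc or None]} where None means nondetect.

    All analytes must supply equally long vectors; sample i gets one
    measurement per analyte.
    """
    measurements = []
    n = len(next(iter(values_by_analyte.values())))
    for analyte, values in values_by_analyte.items():
        assert len(values) == n
        for i, v in enumerate(values):
            measurements.append(
                make_measurement(
                    sample_id=f"s{i + 1:03d}",
                    variety=variety,
                    analyte=analyte,
                    concentration=0.0 if v is None else float(v),
                    state=(
                        CensoringState.NONDETECT
                        if v is None
                        else CensoringState.QUANTIFIED
                    ),
                    lod=lod,
                    loq=loq,
                )
            )
    return SurveyDataset(measurements)


def random_grouped_dataset(rng, n_groups=3, n_per_group=5, analyte="chlormequat"):
    """Random multi-variety dataset with a mix of quantified and censored
    measurements, for oracle-equivalence checks."""
    measurements = []
    loq = 0.002
    for g in range(n_groups):
        variety = f"variety-{g}"
        for i in range(n_per_group):
            detected = rng.random() < 0.7
            conc = float(loq + rng.lognormal(0.0, 1.0)) if detected else 0.0
            measurements.append(
                make_measurement(
                    sample_id=f"g{g}s{i}",
                    variety=variety,
                    analyte=analyte,
                    concentration=conc,
                    state=(
                        CensoringState.QUANTIFIED
                        if detected
                        else CensoringState.NONDETECT
                    ),
                    loq=loq,
                )
            )
    return SurveyDataset(measurements)
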