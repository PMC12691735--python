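"""Detection frequencies, summaries, aggregation, co-occurrence and ANOVA."""

import numpy as np
import pytest
from scipy import stats

from pgrisk.occurrence import (
    aggregate_overall_mean,
    cooccurrence_profile,
    detection_frequency,
    one_way_anova,
    round_half_up,
    summarize,
    summary_frame,
    tukey_letters,
)
from pgrisk.survey import CensoringState, SubstitutionPolicy, SurveyDataset

from conftest import dataset_from_values, make_measurement, random_grouped_dataset


def grouped_dataset(groups, analyte="chlormequat"):
    """Dataset with one variety per group of quantified values."""
    measurements = []
    for g, values in enumerate(groups):
        for i, v in enumerate(values):
            measurements.append(
                make_measurement(
                    sample_id=f"g{g}s{i}",
                    variety=f"variety-{g}",
                    analyte=analyte,
                    concentration=float(v),
                    state=CensoringState.QUANTIFIED,
                    loq=1e-6,
                    lod=1e-6,
                )
            )
    return SurveyDataset(measurements)


class TestDetectionFrequency:
    def test_full_detection_within_variety(self):
        ds = dataset_from_values({"chlormequat": [0.1] * 15}, variety="T. fuciformis")
        assert detection_frequency(ds, "chlormequat", "T. fuciformis") == 1.0

    def test_overall_denominator_includes_unmeasured_varieties(self):
        # analyte measured only in one of two varieties: the other variety's
        # samples still count in the overall denominator
        a = dataset_from_values({"chlormequat": [0.1, None]}, variety="A. aegerita")
        merged = SurveyDataset(
            a.measurements()
            + [
                make_measurement(
                    sample_id=f"x{i}", variety="L. edodes", analyte="diuron",
                    concentration=c, state=CensoringState.QUANTIFIED,
                )
                for i, c in enumerate([0.2, 0.3])
            ]
        )
        assert detection_frequency(merged, "chlormequat") == pytest.approx(1 / 4)

    def test_never_measured_analyte_is_zero(self):
        ds = dataset_from_values({"chlormequat": [0.1]})
        assert detection_frequency(ds, "diuron") == 0.0

    def test_unknown_variety_raises(self):
        ds = dataset_from_values({"chlormequat": [0.1]})
        with pytest.raises(KeyError):
            detection_frequency(ds, "chlormequat", "P. eryngii")

    def test_invariant_under_substitution_policy(self):
        # frequency depends only on censoring states
        ds = dataset_from_values({"chlormequat": [0.1, None, None, 0.3]})
        base = detection_frequency(ds, "chlormequat")
        assert base == 0.5  # policies play no role in the computation


class TestSummarize:
    def test_all_nondetect_zero_policy(self):
        ds = dataset_from_values({"chlormequat": [None] * 15})
        (row,) = summarize(ds, "zero")
        assert (row.mean, row.median, row.max, row.n_detected) == (0.0, 0.0, 0.0, 0)
        assert row.n_samples == 15

    def test_mean_matches_hand_arithmetic(self):
        # 12 quantified values summing to 16.95 plus 3 nondetects, zero policy
        quantified = [3.259, 2.0, 1.5, 1.2, 1.0, 0.9, 0.9, 1.3, 1.4, 1.5, 1.0, 0.991]
        assert sum(quantified) == pytest.approx(16.95)
        ds = dataset_from_values(
            {"chlormequat": quantified + [None] * 3}, variety="H. erinaceus"
        )
        (row,) = summarize(ds, "zero")
        assert row.mean == pytest.approx(16.95 / 15)
        assert round_half_up(row.mean, 3) == 1.130

    def test_median_monotone_between_policies(self):
        ds = dataset_from_values(
            {"chlormequat": [None, None, 0.5, 0.7, None]}, lod=0.01, loq=0.02
        )
        med_zero = summarize(ds, "zero")[0].median
        med_lod = summarize(ds, "lod")[0].median
        assert med_zero <= med_lod

    def test_summary_row_internal_consistency(self):
        rng = np.random.default_rng(7)
        ds = random_grouped_dataset(rng, n_groups=4, n_per_group=8)
        for row in summarize(ds, "half_lod"):
            assert 0 <= row.n_detected <= row.n_samples
            assert row.min <= row.median <= row.max
            assert row.min <= row.mean <= row.max


class TestAggregateOverallMean:
    def test_survey_wide_mean_from_reference_summary(self, reference_tables):
        _, occ = reference_tables
        assert round_half_up(aggregate_overall_mean(occ, "chlormequat", 7), 3) == 0.352
        assert round_half_up(aggregate_overall_mean(occ, "thidiazuron", 7), 3) == 0.006

    def test_absent_analyte_contributes_zero(self, reference_tables):
        _, occ = reference_tables
        assert aggregate_overall_mean(occ, "paclobutrazol", 7) == 0.0

    def test_unequal_group_sizes_refused(self, reference_tables):
        _, occ = reference_tables
        bad = occ.copy()
        bad.loc[bad.index[0], "n_samples"] = 14
        with pytest.raises(ValueError, match="unequal"):
            aggregate_overall_mean(bad, "chlormequat", 7)

    def test_equals_sample_level_grand_mean_for_equal_groups(self):
        rng = np.random.default_rng(11)
        ds = random_grouped_dataset(rng, n_groups=5, n_per_group=6)
        sf = summary_frame(ds, "zero")
        agg = aggregate_overall_mean(sf, "chlormequat", 5)
        from pgrisk.survey import substitute_nondetects

        sample_level = substitute_nondetects(ds, "zero")["chlormequat"].mean()
        assert agg == pytest.approx(sample_level)


class TestCooccurrence:
    def test_single_analyte_panel_has_no_multi_residues(self):
        ds = dataset_from_values({"chlormequat": [0.1, None, 0.2]})
        assert cooccurrence_profile(ds).multi_residue_rate == 0.0

    def test_toy_counts(self):
        # five samples with 0, 1, 2, 2 and 4 detected analytes
        analytes = ["a1", "a2", "a3", "a4"]
        per_sample = [0, 1, 2, 2, 4]
        measurements = []
        for i, k in enumerate(per_sample):
            for j, analyte in enumerate(analytes):
                detected = j < k
                measurements.append(
                    make_measurement(
                        sample_id=f"s{i}", analyte=analyte,
                        concentration=0.5 if detected else 0.0,
                        state=(
                            CensoringState.QUANTIFIED
                            if detected
                            else CensoringState.NONDETECT
                        ),
                    )
                )
        profile = cooccurrence_profile(SurveyDataset(measurements))
        assert profile.multi_residue_rate == pytest.approx(0.6)
        assert profile.max_k == 4
        assert sum(profile.counts_by_k.values()) == profile.total_samples == 5
        assert profile.counts_by_k == {0: 1, 1: 1, 2: 2, 4: 1}

    def test_invariant_under_sample_order(self):
        ds = dataset_from_values({"a1": [0.1, None], "a2": [0.2, 0.3]})
        reordered = SurveyDataset(list(reversed(ds.measurements())))
        assert (
            cooccurrence_profile(ds).counts_by_k
            == cooccurrence_profile(reordered).counts_by_k
        )


def brute_force_anova(groups):
    """Independent sums-of-squares one-way ANOVA."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, stats.f.sf(f, dfb, dfw)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        ds = grouped_dataset([[1, 2, 3], [1, 2, 3]])
        res = one_way_anova(ds, "chlormequat")
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_shifted_groups_hand_computed(self):
        ds = grouped_dataset([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        res = one_way_anova(ds, "chlormequat")
        assert res.f_statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p_value == pytest.approx(stats.f.sf(3.0, 2, 6))
        assert res.group_means["variety-0"] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            ds = random_grouped_dataset(
                rng,
                n_groups=int(rng.integers(2, 5)),
                n_per_group=int(rng.integers(3, 8)),
            )
            res = one_way_anova(ds, "chlormequat", "half_lod")
            from pgrisk.survey import substituted_frame

            frame = substituted_frame(ds, "half_lod")
            groups = [
                g["value"].to_numpy()
                for _, g in frame.groupby("variety", sort=True)
            ]
            f_ref, p_ref = brute_force_anova(groups)
            assert res.f_statistic == pytest.approx(f_ref, rel=1e-9)
            assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_p_value_roughly_uniform_under_null(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            groups = [rng.normal(1.0, 0.3, 8) for _ in range(3)]
            ds = grouped_dataset([np.abs(g) + 0.1 for g in groups])
            pvals.append(one_way_anova(ds, "chlormequat").p_value)
        pvals = np.array(pvals)
        assert 0.40 < pvals.mean() < 0.60
        assert 0.005 <= (pvals < 0.05).mean() <= 0.125

    def test_too_few_groups_refused(self):
        ds = grouped_dataset([[1, 2, 3]])
        with pytest.raises(ValueError, match=">= 2 varieties"):
            one_way_anova(ds, "chlormequat")

    def test_zero_within_degrees_of_freedom_refused(self):
        ds = grouped_dataset([[1], [2]])
        with pytest.raises(ValueError, match="degrees of freedom"):
            one_way_anova(ds, "chlormequat")

    def test_tukey_letters_separate_distant_groups(self):
        rng = np.random.default_rng(3)
        ds = grouped_dataset(
            [rng.normal(1.0, 0.05, 10), rng.normal(5.0, 0.05, 10)]
        )
        letters = tukey_letters(ds, "chlormequat")
        assert letters["variety-0"] != letters["variety-1"]
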