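"""PBIF averaging, two-sample scaling and sample-pair selection."""

import numpy as np
import pytest

import pbifpet as p
from pbifpet.pbif_builder import _pearson


def variants(template, scales):
    return [
        type(template)(
            t_peak=template.t_peak, peak_value=template.peak_value * s,
            rise_times=template.rise_times, rise_values=template.rise_values * s,
            tail_amplitudes=template.tail_amplitudes * s,
            tail_rates=template.tail_rates, subject_id=f"s{i}")
        for i, s in enumerate(scales)
    ]


class TestBuildPbif:
    def test_identical_curves_mean_is_curve_sd_zero(self, healthy_template):
        curves = variants(healthy_template, [1.0, 1.0, 1.0])
        grid = p.default_grid()
        pbif = p.build_pbif(curves, grid)
        np.testing.assert_allclose(pbif.mean, healthy_template.value(grid.times))
        np.testing.assert_allclose(pbif.sd, 0.0, atol=1e-12)
        assert pbif.n == 3

    def test_two_curves_pointwise_average(self, healthy_template):
        curves = variants(healthy_template, [0.8, 1.3])
        grid = p.default_grid()
        pbif = p.build_pbif(curves, grid)
        for t in (0.5, 1.0, 5.0, 15.0, 60.0):
            expected = 0.5 * (curves[0].value(t) + curves[1].value(t))
            assert pbif.value_at(t) == pytest.approx(expected, rel=1e-12)

    def test_leave_one_out_equals_build_on_rest(self, healthy_template):
        curves = variants(healthy_template, [0.8, 1.0, 1.3])
        grid = p.default_grid()
        loo = p.build_pbif(curves, grid, leave_out="s1")
        rest = p.build_pbif([curves[0], curves[2]], grid)
        np.testing.assert_array_equal(loo.mean, rest.mean)
        assert loo.excluded_subject == "s1"

    def test_permutation_invariance(self, healthy_template):
        curves = variants(healthy_template, [0.7, 1.0, 1.4, 0.9])
        grid = p.default_grid()
        a = p.build_pbif(curves, grid)
        b = p.build_pbif(curves[::-1], grid)
        np.testing.assert_allclose(a.mean, b.mean)
        np.testing.assert_allclose(a.sd, b.sd)

    def test_missing_leave_out_id_rejected(self, healthy_template):
        curves = variants(healthy_template, [1.0, 1.1, 0.9])
        with pytest.raises(ValueError, match="not in cohort"):
            p.build_pbif(curves, p.default_grid(), leave_out="nobody")

    def test_duplicate_ids_rejected(self, healthy_template):
        curves = variants(healthy_template, [1.0, 1.1])
        curves = [curves[0], curves[0]]
        with pytest.raises(ValueError, match="unique"):
            p.build_pbif(curves, p.default_grid())


def synthetic_pbif():
    """PBIF with known values 0.75 SUV at 15 min and 0.15 SUV at 60 min."""
    grid = p.default_grid()
    mean = np.interp(grid.times, [0, 1, 15, 60, 120], [0.2, 3.0, 0.75, 0.15, 0.05])
    return p.PBIF(grid=grid, mean=mean, sd=np.zeros_like(mean), n=10)


class TestScalePbif:
    def test_exact_multiple_recovers_scale(self, healthy_template):
        grid = p.default_grid()
        pbif = p.build_pbif(variants(healthy_template, [1.0, 1.0]), grid)
        c = 1.37
        samples = [(15.0, c * pbif.value_at(15.0)), (60.0, c * pbif.value_at(60.0))]
        sif = p.scale_pbif(pbif, samples)
        assert sif.scale == pytest.approx(c, rel=1e-14)

    def test_linearity_in_samples(self):
        pbif = synthetic_pbif()
        base = [(15.0, 0.70), (60.0, 0.16)]
        inflated = [(t, 1.1 * v) for t, v in base]
        s0 = p.scale_pbif(pbif, base).scale
        s1 = p.scale_pbif(pbif, inflated).scale
        assert s1 == pytest.approx(1.1 * s0, rel=1e-12)

    def test_least_squares_formula_on_reported_values(self):
        # group-typical samples 0.79/0.15 SUV against population values
        # 0.75/0.15: s = (0.79*0.75 + 0.15*0.15) / (0.75^2 + 0.15^2)
        pbif = synthetic_pbif()
        sif = p.scale_pbif(pbif, [(15.0, 0.79), (60.0, 0.15)])
        expected = (0.79 * 0.75 + 0.15 * 0.15) / (0.75 ** 2 + 0.15 ** 2)
        assert sif.scale == pytest.approx(expected, rel=1e-12)
        assert sif.scale == pytest.approx(1.0513, abs=1e-4)

    def test_mean_ratio_method(self):
        pbif = synthetic_pbif()
        sif = p.scale_pbif(pbif, [(15.0, 0.79), (60.0, 0.15)],
                           method="mean_ratio")
        assert sif.scale == pytest.approx(0.5 * (0.79 / 0.75 + 1.0), rel=1e-12)

    def test_nonpositive_sample_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            p.scale_pbif(synthetic_pbif(), [(15.0, 0.0), (60.0, 0.15)])

    def test_scale_equivariance(self):
        pbif = synthetic_pbif()
        samples = [(15.0, 0.8), (60.0, 0.14)]
        for c in (0.5, 2.0, 7.3):
            scaled = [(t, c * v) for t, v in samples]
            assert p.scale_pbif(pbif, scaled).scale == pytest.approx(
                c * p.scale_pbif(pbif, samples).scale, rel=1e-12)


class TestSelectSamplePair:
    def test_proportional_cohort_all_r_one_earliest_pair_wins(self, healthy_template):
        curves = variants(healthy_template, [0.6, 0.9, 1.2, 1.5])
        (ta, tb), table = p.select_sample_pair(curves,
                                               candidate_times=[15, 30, 60])
        assert all(r == pytest.approx(1.0, abs=1e-12) for r in table.values())
        assert (ta, tb) == (15.0, 30.0)

    def test_pearson_matches_textbook_formula(self, small_healthy_fits):
        curves = small_healthy_fits[:4]
        _, table = p.select_sample_pair(curves, candidate_times=[15, 60])
        x = np.array([c.value(15.0) + c.value(60.0) for c in curves])
        y = np.array([c.auc(0, 120) for c in curves])
        # brute-force Pearson
        xc, yc = x - x.mean(), y - y.mean()
        r = float(np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))
        assert table[(15.0, 60.0)] == pytest.approx(r, abs=1e-12)

    def test_constant_time_reduces_to_single_time_correlation(self, healthy_template):
        # all subjects share the same tail value at a "constant" time if the
        # predictor difference comes only from the varying time
        rng = np.random.default_rng(3)
        scales = 1.0 + 0.3 * rng.standard_normal(5)
        curves = variants(healthy_template, np.abs(scales) + 0.2)
        y = np.array([c.auc(0, 120) for c in curves])
        v15 = np.array([c.value(15.0) for c in curves])
        const = np.full_like(v15, 0.5)
        xc = (v15 + const) - (v15 + const).mean()
        yc = y - y.mean()
        r_expected = float(np.sum(xc * yc)
                           / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2)))
        r_single = _pearson(v15, y)
        assert r_expected == pytest.approx(r_single, abs=1e-12)

    def test_scaled_pbif_auc_predictor_perfect_on_proportional_cohort(
            self, healthy_template):
        # exact scalar multiples: the leave-one-out PBIF rescaled by any pair
        # reproduces each subject's AUC up to a common factor, so r = 1
        curves = variants(healthy_template, [0.7, 1.0, 1.4])
        (ta, tb), table = p.select_sample_pair(
            curves, candidate_times=[15, 60], predictor="auc_of_scaled_pbif")
        assert table[(15.0, 60.0)] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_subjects_rejected(self, healthy_template):
        with pytest.raises(ValueError):
            p.select_sample_pair(variants(healthy_template, [1.0, 1.1]))


class TestPopulationProperties:
    def test_leave_one_out_scaling_is_unbiased(self, healthy_template):
        """Homogeneous cohort (template x lognormal scalar): the mean ratio of
        scaled-PBIF peak to true peak is ~1, the population-unbiasedness
        property of two-sample rescaling."""
        rng = np.random.default_rng(42)
        scales = np.exp(0.2 * rng.standard_normal(24) - 0.5 * 0.04)
        curves = variants(healthy_template, scales)
        grid = p.default_grid()
        ratios = []
        for c in curves:
            loo = p.build_pbif(curves, grid, leave_out=c.subject_id)
            sif = p.scale_pbif(loo, [(15.0, c.value(15.0)),
                                     (60.0, c.value(60.0))])
            est_peak = np.max(sif.values)
            ratios.append(est_peak / c.peak_value)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.03)

    def test_blunted_peak_subject_gets_overestimated_auc(self, healthy_template):
        """A subject with a blunted peak but population-matching tail receives
        a scaled PBIF whose total AUC exceeds their true AUC -- the sign that
        drives selective V_T underestimation."""
        grid = p.default_grid()
        pbif = p.build_pbif(variants(healthy_template, [1.0, 1.0]), grid)
        blunted = p.make_template_if(p.group_profile("cannabis"))
        sif = p.scale_pbif(pbif, [(15.0, blunted.value(15.0)),
                                  (60.0, blunted.value(60.0))])
        auc_scaled = p.auc_sampled(sif.times, sif.values, 0, 120)
        assert auc_scaled > blunted.auc(0, 120)

    def test_matching_shape_subject_has_zero_auc_error(self, healthy_template):
        grid = p.default_grid()
        pbif = p.build_pbif(variants(healthy_template, [1.0, 1.0]), grid)
        subject = healthy_template.scaled(0.85)
        sif = p.scale_pbif(pbif, [(15.0, subject.value(15.0)),
                                  (60.0, subject.value(60.0))])
        auc_scaled = p.auc_sampled(sif.times, sif.values, 0, 120)
        assert auc_scaled == pytest.approx(subject.auc(0, 120), rel=2e-3)
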