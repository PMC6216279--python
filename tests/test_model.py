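"""Incorporation model: closed form, simulator, inversion, normalisation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitofidelity as mf
from mitofidelity.reporter import DEFINED

MTCO1 = mf.ReporterStats("MT-CO1", ("C", "M"), 1, 96, 32, 48, 64.0, DEFINED)
MTCO2 = mf.ReporterStats("MT-CO2", ("C", "M"), 3, 29, 10, 26, 3.717948717948718, DEFINED)

counts = st.integers(1, 150)


class TestClosedForm:
    def test_unity_at_zero_epsilon(self):
        assert mf.expected_ratio_fold_change(MTCO1, 0.0).ratio_fold_change == 1.0

    def test_mtco1_at_one_percent(self):
        # (1 + 0.96)/(32 + 0.48) normalised by 1/32
        res = mf.expected_ratio_fold_change(MTCO1, 0.01)
        assert res.ratio_fold_change == pytest.approx(1.9310, abs=5e-4)

    def test_initial_slope_is_count_ratio_difference(self):
        for stats in (MTCO1, MTCO2):
            h = 1e-7
            numeric = (
                mf.expected_ratio_fold_change(stats, h).ratio_fold_change - 1.0
            ) / h
            assert numeric == pytest.approx(mf.ratio_slope_at_zero(stats), rel=1e-4)
        assert mf.ratio_slope_at_zero(MTCO1) == pytest.approx(94.5)
        assert mf.ratio_slope_at_zero(MTCO2) == pytest.approx(29 / 3 - 2.6)

    def test_undefined_for_zero_cognates(self):
        stats = mf.ReporterStats("g", ("C", "M"), 0, 5, 3, 4, None, "undefined")
        assert mf.expected_ratio_fold_change(stats, 0.01).flag == "undefined"

    @given(counts, counts, counts, counts)
    def test_monotone_iff_positive_slope(self, c_a, nc_a, c_b, nc_b):
        ratio, flag = mf.reporter_ratio(c_a, nc_a, c_b, nc_b)
        stats = mf.ReporterStats("g", ("A", "B"), c_a, nc_a, c_b, nc_b, ratio, flag)
        f1 = mf.expected_ratio_fold_change(stats, 0.3).ratio_fold_change
        f2 = mf.expected_ratio_fold_change(stats, 0.7).ratio_fold_change
        slope = mf.ratio_slope_at_zero(stats)
        if slope > 0:
            assert f2 > f1
        elif slope < 0:
            assert f2 < f1
        else:
            assert f2 == pytest.approx(f1)

    def test_sensitivity_ordering_of_the_two_reporters(self):
        # at any fixed misreading level the high-R CDS responds more
        for eps in (1e-3, 1e-2, 5e-2):
            f1 = mf.expected_ratio_fold_change(MTCO1, eps).ratio_fold_change
            f2 = mf.expected_ratio_fold_change(MTCO2, eps).ratio_fold_change
            assert f1 > f2 > 1.0


def _planted_cds():
    spec = mf.SyntheticGenomeSpec(
        n_genes=1,
        length_range=(160, 160),
        seed=77,
        planted=(mf.PlantedComposition(0, ("C", "M"), 1, 96, 32, 48),),
    )
    return mf.gen_cds(spec, 0)


@pytest.fixture(scope="module")
def cds():
    return _planted_cds()


class TestSimulator:

    def test_zero_epsilon_exact(self, cds, cys_hood, met_hood):
        params = mf.MisreadingModelParams(epsilon=0.0, n_molecules=500, seed=1)
        res = mf.simulate_incorporation(cds, cys_hood, met_hood, params)
        assert res.ratio_fold_change == 1.0
        assert res.mc_stderr == 0.0

    def test_same_seed_bit_identical(self, cds, cys_hood, met_hood):
        params = mf.MisreadingModelParams(epsilon=0.02, n_molecules=2000, seed=42)
        a = mf.simulate_incorporation(cds, cys_hood, met_hood, params)
        b = mf.simulate_incorporation(cds, cys_hood, met_hood, params)
        assert a == b

    def test_different_seeds_differ(self, cds, cys_hood, met_hood):
        p1 = mf.MisreadingModelParams(epsilon=0.02, n_molecules=2000, seed=1)
        p2 = mf.MisreadingModelParams(epsilon=0.02, n_molecules=2000, seed=2)
        a = mf.simulate_incorporation(cds, cys_hood, met_hood, p1)
        b = mf.simulate_incorporation(cds, cys_hood, met_hood, p2)
        assert a.ratio_fold_change != b.ratio_fold_change

    @pytest.mark.parametrize("eps", [1e-3, 1e-2, 5e-2])
    def test_agrees_with_closed_form_within_three_stderr(
        self, cds, cys_hood, met_hood, eps
    ):
        params = mf.MisreadingModelParams(epsilon=eps, n_molecules=100_000, seed=7)
        sim = mf.simulate_incorporation(cds, cys_hood, met_hood, params)
        c_a, nc_a = mf.count_codons(cds, cys_hood)
        c_b, nc_b = mf.count_codons(cds, met_hood)
        assert (c_a, nc_a, c_b, nc_b) == (1, 96, 32, 48)
        closed = mf.expected_ratio_fold_change(MTCO1, eps).ratio_fold_change
        assert sim.mc_stderr > 0
        assert abs(sim.ratio_fold_change - closed) < 3 * sim.mc_stderr

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mf.MisreadingModelParams(epsilon=1.5)
        with pytest.raises(ValueError):
            mf.MisreadingModelParams(epsilon=0.1, n_molecules=0)


class TestFitEpsilon:
    def test_unity_maps_to_zero(self):
        assert mf.fit_epsilon(1.0, MTCO1) == 0.0

    def test_inverse_of_printed_example(self):
        observed = mf.expected_ratio_fold_change(MTCO1, 0.01).ratio_fold_change
        assert observed == pytest.approx(1.931, abs=5e-4)
        assert mf.fit_epsilon(observed, MTCO1) == pytest.approx(0.01, abs=1e-10)

    def test_round_trip_sweep(self):
        for eps in np.geomspace(1e-4, 5e-2, 12):
            f = mf.expected_ratio_fold_change(MTCO1, eps).ratio_fold_change
            assert abs(mf.fit_epsilon(f, MTCO1) - eps) < 1e-8

    def test_out_of_range_rejected(self):
        f_max = mf.expected_ratio_fold_change(MTCO1, 1.0).ratio_fold_change
        with pytest.raises(ValueError, match="outside model range"):
            mf.fit_epsilon(0.5, MTCO1)
        with pytest.raises(ValueError, match="outside model range"):
            mf.fit_epsilon(f_max * 1.01, MTCO1)

    def test_insensitive_reporter_rejected(self):
        flat = mf.ReporterStats("g", ("A", "B"), 10, 5, 10, 5, 1.0, DEFINED)
        with pytest.raises(ValueError, match="not identifiable"):
            mf.fit_epsilon(1.2, flat)


class TestNormalization:
    def test_identical_groups_give_unity(self):
        group = [mf.DualReporterMeasurement(3.0, 2.0) for _ in range(4)]
        res = mf.normalize_dual_reporter(group, group)
        assert res.fold_change == 1.0
        assert res.reference.mean == 1.0

    def test_exact_doubling(self):
        test = [mf.DualReporterMeasurement(2.0, 1.0) for _ in range(3)]
        ref = [mf.DualReporterMeasurement(1.0, 1.0) for _ in range(3)]
        res = mf.normalize_dual_reporter(test, ref)
        assert res.fold_change == 2.0
        assert res.test.sem == 0.0
        assert res.reference.sem == 0.0

    def test_reference_mean_is_one_by_construction(self):
        rng = np.random.default_rng(3)
        test = [
            mf.DualReporterMeasurement(float(x), 1.0) for x in rng.lognormal(0.5, 0.2, 8)
        ]
        ref = [
            mf.DualReporterMeasurement(float(x), 1.0) for x in rng.lognormal(0.0, 0.2, 8)
        ]
        res = mf.normalize_dual_reporter(test, ref)
        assert res.reference.mean == pytest.approx(1.0, abs=1e-12)
        assert res.reference.n == res.test.n == 8

    def test_noisy_replicates_recover_generative_fold_change(self):
        test, ref = mf.gen_assay(1.5, n_replicates=1000, noise_cv=0.2, seed=11)
        res = mf.normalize_dual_reporter(test, ref)
        # within 3 SEM of truth at this replicate count
        pooled_sem = np.hypot(res.test.sem, 1.5 * res.reference.sem)
        assert abs(res.fold_change - 1.5) < 3 * pooled_sem

    def test_non_positive_signal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mf.DualReporterMeasurement(0.0, 1.0)

    def test_empty_group_rejected(self):
        ref = [mf.DualReporterMeasurement(1.0, 1.0)]
        with pytest.raises(ValueError, match="at least one replicate"):
            mf.normalize_dual_reporter([], ref)


def test_group_difference_test_detects_shift():
    test, ref = mf.gen_assay(1.5, n_replicates=12, noise_cv=0.05, seed=2)
    t, p = mf.group_difference_test(test, ref)
    assert t > 0 and p < 0.01
    same_a, same_b = mf.gen_assay(1.0, n_replicates=12, noise_cv=0.05, seed=3)
    _, p_null = mf.group_difference_test(same_a, same_b)
    assert p_null > 0.01
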