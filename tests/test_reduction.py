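"""Unit and property tests for the BRET reduction chain."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grkbret.reduction import (
    baseline_bars,
    bret_ratio,
    mock_correct,
    net_fold_change,
    percent_change,
    reduce_plate,
    window_means,
)
from grkbret.synth import AssayDesign, ConditionTruth, generate_bret_dataset
from grkbret.types import (
    ConfigurationError,
    CorrectedMeasurement,
    DataError,
    DegenerateWellError,
    WellMeta,
    WellTrace,
)


def _well(donor, acceptor, time=None, **meta_kw):
    time = np.arange(len(donor)) * 10.0 if time is None else np.asarray(time)
    kw = dict(
        well_id="w1", condition="c", role="sample", concentration_M=1e-7,
        replicate=1, stimulation_time_s=float(time[len(time) // 2]),
    )
    kw.update(meta_kw)
    return WellTrace(time=time, donor=np.asarray(donor, float),
                     acceptor=np.asarray(acceptor, float), meta=WellMeta(**kw))


class TestBretRatio:
    def test_constant_channels(self):
        w = _well([1000.0] * 6, [500.0] * 6)
        assert np.allclose(bret_ratio(w), 0.5)

    def test_zero_acceptor(self):
        w = _well([1000.0] * 6, [0.0] * 6)
        assert np.all(bret_ratio(w) == 0.0)

    def test_scale_invariance(self):
        w1 = _well([800.0, 900.0, 1000.0, 1100.0], [400.0, 450.0, 500.0, 550.0])
        w2 = _well([2.5 * d for d in [800, 900, 1000, 1100]],
                   [2.5 * a for a in [400, 450, 500, 550]])
        assert np.allclose(bret_ratio(w1), bret_ratio(w2))

    def test_nonpositive_donor_names_well(self):
        w = _well([1000.0, 0.0, 1000.0, 1000.0], [1.0] * 4, well_id="bad-well")
        with pytest.raises(DataError, match="bad-well"):
            bret_ratio(w)


class TestMockCorrect:
    def test_subtracts_mean_of_mocks(self):
        sample = np.full(5, 0.60)
        mocks = [np.full(5, 0.08), np.full(5, 0.12)]
        assert np.allclose(mock_correct(sample, mocks), 0.50)

    def test_sample_equals_mock_mean(self):
        sample = np.full(5, 0.10)
        assert np.allclose(mock_correct(sample, [np.full(5, 0.10)]), 0.0)

    def test_empty_mock_set(self):
        with pytest.raises(ConfigurationError):
            mock_correct(np.ones(5), [])

    def test_time_base_mismatch(self):
        with pytest.raises(DataError):
            mock_correct(np.ones(5), [np.ones(4)])

    def test_scalar_mode(self):
        sample = np.full(4, 0.6)
        mocks = [np.array([0.0, 0.1, 0.2, 0.1])]
        out = mock_correct(sample, mocks, mode="scalar")
        assert np.allclose(out, 0.6 - 0.1)


class TestWindowMeans:
    time = np.arange(0.0, 490.0, 10.0)

    def test_constant_series_fold_one(self):
        cm = window_means(self.time, np.full(49, 0.5), 180.0, 180.0, 300.0)
        assert cm.fold_change == pytest.approx(1.0)

    def test_step_series(self):
        y = np.where(self.time <= 180.0, 0.50, 0.55)
        cm = window_means(self.time, y, 180.0, 180.0, 300.0)
        assert cm.fold_change == pytest.approx(1.1)

    def test_stimulation_timepoint_excluded_from_both_windows(self):
        # a spike exactly at the stimulation time must not affect either mean
        y = np.full(49, 0.5)
        y[self.time == 180.0] = 99.0
        cm = window_means(self.time, y, 180.0, 180.0, 300.0)
        assert cm.baseline_mean == pytest.approx(0.5)
        assert cm.stimulated_mean == pytest.approx(0.5)

    def test_degenerate_baseline(self):
        with pytest.raises(DegenerateWellError):
            window_means(self.time, np.zeros(49), 180.0, 180.0, 300.0)

    def test_empty_window(self):
        with pytest.raises(DataError):
            window_means(np.array([0.0, 500.0, 600.0]), np.ones(3), 180.0, 180.0, 300.0)


class TestNetFoldChange:
    def test_vehicle_division(self):
        cm = CorrectedMeasurement(baseline_mean=1.0, stimulated_mean=1.10)
        assert net_fold_change(cm, [1.0]).value == pytest.approx(1.10)

    def test_vehicle_against_itself_is_one(self):
        cm = CorrectedMeasurement(baseline_mean=0.5, stimulated_mean=0.55)
        assert net_fold_change(cm, [cm.fold_change]).value == 1.0

    def test_empty_vehicle_set(self):
        cm = CorrectedMeasurement(baseline_mean=1.0, stimulated_mean=1.1)
        with pytest.raises(ConfigurationError):
            net_fold_change(cm, [])


@pytest.mark.parametrize("value,expected", [(1.0, 0.0), (1.25, 25.0), (0.9, -10.0)])
def test_percent_change(value, expected):
    assert percent_change(value) == pytest.approx(expected)


class TestRoundTrip:
    def test_zero_noise_recovers_top_fold(self, zero_noise_plate):
        wells, design, truth = zero_noise_plate
        reduced = reduce_plate(wells)
        top = reduced[(reduced["role"] == "sample")
                      & (reduced["concentration_M"] == 0.1)]
        assert np.allclose(top["net_fold_change"], truth.top_fold, atol=1e-9)

    def test_vehicle_net_fold_is_exactly_one(self, zero_noise_plate):
        wells, _, _ = zero_noise_plate
        reduced = reduce_plate(wells)
        veh = reduced[reduced["role"] == "vehicle"]["net_fold_change"]
        assert (veh == 1.0).all()

    def test_mock_idempotence_with_matched_donors(self):
        # equal donors: adding a constant to sample AND mock acceptors cancels
        time = np.arange(0.0, 490.0, 10.0)
        donor = np.full(49, 1.0e5)
        base = 0.1 + np.where(time <= 180.0, 0.5, 0.6)
        sample = _well(donor, donor * base, time=time, stimulation_time_s=180.0)
        mock = _well(donor, donor * 0.1, time=time, role="mock",
                     concentration_M=0.0, well_id="m1", stimulation_time_s=180.0)
        shift = 0.07 * donor
        sample2 = _well(donor, sample.acceptor + shift, time=time,
                        stimulation_time_s=180.0)
        mock2 = _well(donor, mock.acceptor + shift, time=time, role="mock",
                      concentration_M=0.0, well_id="m1", stimulation_time_s=180.0)
        c1 = mock_correct(bret_ratio(sample), [bret_ratio(mock)])
        c2 = mock_correct(bret_ratio(sample2), [bret_ratio(mock2)])
        assert np.allclose(c1, c2, atol=1e-12)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_channel_scale_invariance(self, scale):
        design = AssayDesign(conditions=("c",), concentrations=(0.0, 1e-8, 1e-7),
                             n_replicates=2)
        truth = ConditionTruth(noise_cv=0.02)
        wells = generate_bret_dataset(design, {"c": truth}, seed=11)
        reduced1 = reduce_plate(wells)
        for w in wells:
            w.donor = w.donor * scale
            w.acceptor = w.acceptor * scale
        reduced2 = reduce_plate(wells)
        np.testing.assert_allclose(
            reduced1["net_fold_change"], reduced2["net_fold_change"], rtol=1e-12
        )


class TestBaselineBars:
    def _reduced(self):
        design = AssayDesign(conditions=("ref", "pre"), concentrations=(0.0, 1e-6),
                             n_replicates=3)
        truths = {
            "ref": ConditionTruth(noise_cv=0.0, response_tau_s=0.0),
            "pre": ConditionTruth(noise_cv=0.0, response_tau_s=0.0,
                                  precoupling_factor=1.5),
        }
        return reduce_plate(generate_bret_dataset(design, truths, seed=3))

    def test_reference_maps_to_one(self):
        bars = baseline_bars(self._reduced(), "ref")
        ref_row = bars[bars["condition"] == "ref"].iloc[0]
        assert ref_row["baseline_norm_mean"] == pytest.approx(1.0)

    def test_planted_precoupling_recovered(self):
        bars = baseline_bars(self._reduced(), "ref")
        pre_row = bars[bars["condition"] == "pre"].iloc[0]
        assert pre_row["baseline_norm_mean"] == pytest.approx(1.5, abs=1e-9)

    def test_missing_reference(self):
        with pytest.raises(ConfigurationError):
            baseline_bars(self._reduced(), "nonexistent")

    def test_ordering_preserved(self):
        bars = baseline_bars(self._reduced(), "ref")
        # division by a common positive constant preserves stim > baseline
        for _, row in bars.iterrows():
            assert row["stimulated_norm_mean"] >= row["baseline_norm_mean"] - 1e-12
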