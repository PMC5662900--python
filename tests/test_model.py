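"""Forward-model unit and property tests: CM clipping, the unit
potential, the cycle histogram, and the circularly convolved ANN."""

import numpy as np
import pytest
from scipy import stats

from ecochg import (
    ANNParams,
    CMParams,
    ParameterError,
    ResolutionError,
    TimeGrid,
    ann_waveform,
    cm_waveform,
    cycle_histogram,
    ecochg_model,
    unit_potential,
)
from ecochg.model import _circular_convolve

from conftest import make_params


def brute_force_circular_convolve(signal, kernel):
    """O(N²) double-loop circular convolution, kernel wrapped onto the period."""
    n = len(signal)
    padded = [0.0] * n
    for i, v in enumerate(kernel):
        padded[i % n] += v
    out = [0.0] * n
    for k in range(n):
        for j in range(n):
            out[k] += signal[j] * padded[(k - j) % n]
    return np.array(out)


class TestTimeGrid:
    def test_standard_grid(self, grid):
        assert grid.n_samples == 32
        assert grid.times[0] == 0.0
        assert np.allclose(np.diff(grid.times), 1.0 / 16000.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            TimeGrid(stimulus_frequency=500.0, sampling_rate=3000.0)


class TestCMWaveform:
    def test_zero_amplitude_gives_zero_series(self, grid):
        cm = CMParams(a_cm=0.0, phi_cm=0.3, upper_cutoff=10.0, lower_cutoff=-10.0)
        assert np.all(cm_waveform(cm, grid) == 0.0)

    def test_quarter_period_sample_hits_peak(self, grid):
        # 500 Hz: t = 0.5 ms is a quarter period, sin(π/2) = 1
        cm = CMParams(a_cm=1.0, phi_cm=0.0, upper_cutoff=10.0, lower_cutoff=-10.0)
        y = cm_waveform(cm, grid)
        i = int(round(0.0005 * grid.sampling_rate))
        assert y[i] == pytest.approx(1.0)

    def test_asymmetric_clipping(self, grid):
        cm = CMParams(a_cm=1.0, phi_cm=0.0, upper_cutoff=0.5, lower_cutoff=-10.0)
        y = cm_waveform(cm, grid)
        assert y.max() == pytest.approx(0.5)
        assert y.min() == pytest.approx(-1.0)

    def test_clipping_idempotent(self, grid):
        cm = CMParams(a_cm=2.0, phi_cm=0.17, upper_cutoff=1.1, lower_cutoff=-0.6)
        once = cm_waveform(cm, grid)
        twice = np.clip(once, cm.lower_cutoff, cm.upper_cutoff)
        np.testing.assert_array_equal(once, twice)

    def test_unclipped_scaling_linearity(self, grid):
        for k in (0.0, 0.4, 2.5):
            base = CMParams(a_cm=1.0, phi_cm=0.2, upper_cutoff=100.0, lower_cutoff=-100.0)
            scaled = CMParams(a_cm=k, phi_cm=0.2, upper_cutoff=100.0, lower_cutoff=-100.0)
            np.testing.assert_allclose(
                cm_waveform(scaled, grid), k * cm_waveform(base, grid), atol=1e-14
            )

    def test_bad_cutoff_ordering_rejected(self):
        with pytest.raises(ParameterError):
            CMParams(a_cm=1.0, phi_cm=0.0, upper_cutoff=-0.5, lower_cutoff=0.5)


class TestUnitPotential:
    def test_kernel_length(self):
        assert unit_potential(1100.0, 48000.0).size == 44

    def test_full_cycle_integrates_to_zero(self):
        kernel = unit_potential(1100.0, 16000.0)
        assert abs(kernel.sum()) < 1e-12

    def test_unit_peak(self):
        assert np.max(np.abs(unit_potential(1100.0, 16000.0))) == pytest.approx(1.0)

    def test_starts_positive(self):
        # positive-first convention: equal phases align the components
        kernel = unit_potential(1100.0, 48000.0)
        assert kernel[1] > 0

    def test_undersampled_rejected(self):
        with pytest.raises(ResolutionError):
            unit_potential(1100.0, 3000.0)


class TestCycleHistogram:
    @pytest.mark.parametrize("soe", [0.35, 0.5, 0.65])
    def test_nonnegative_unit_peak(self, grid, soe):
        ch = cycle_histogram(ANNParams(a_ann=1.0, phi_ann=0.0, soe=soe), grid)
        assert ch.min() >= 0.0
        assert ch.max() == pytest.approx(1.0)

    def test_width_grows_with_soe(self, grid):
        def fwhm(soe):
            dense = TimeGrid(stimulus_frequency=500.0, sampling_rate=512000.0)
            ch = cycle_histogram(ANNParams(a_ann=1.0, phi_ann=0.0, soe=soe), dense)
            above = np.flatnonzero(ch >= 0.5)
            return (above[-1] - above[0]) / dense.n_samples

        assert fwhm(0.65) > fwhm(0.35)

    def test_mode_matches_dense_grid_argmax(self):
        # oracle: maximize the lognormal density itself on a 1e5-point grid
        soe = 0.5
        t_up = 1.0 / 1100.0
        t_dense = np.linspace(1e-9, 1 / 500.0, 100_000)
        oracle = t_dense[np.argmax(stats.lognorm.pdf(t_dense / t_up, s=soe))]
        dense = TimeGrid(stimulus_frequency=500.0, sampling_rate=5e7)
        ch = cycle_histogram(ANNParams(a_ann=1.0, phi_ann=0.0, soe=soe), dense)
        mode = dense.times[np.argmax(ch)]
        assert mode == pytest.approx(oracle, abs=2e-7)
        # and both sit at the analytic lognormal mode e^(μ−σ²)·T_UP
        assert mode == pytest.approx(np.exp(-(soe**2)) * t_up, rel=1e-3)

    def test_soe_bounds_enforced(self):
        with pytest.raises(ParameterError):
            ANNParams(a_ann=1.0, phi_ann=0.0, soe=0.7)
        with pytest.raises(ParameterError):
            ANNParams(a_ann=1.0, phi_ann=0.0, soe=0.2)

    def test_up_frequency_must_exceed_stimulus(self, grid):
        with pytest.raises(ParameterError):
            cycle_histogram(
                ANNParams(a_ann=1.0, phi_ann=0.0, soe=0.5, up_frequency=400.0), grid
            )


class TestANNWaveform:
    def test_zero_amplitude(self, grid):
        ann = ANNParams(a_ann=0.0, phi_ann=0.3, soe=0.5)
        assert np.all(ann_waveform(ann, grid) == 0.0)

    def test_full_cycle_shift_is_identity(self, grid):
        a = ann_waveform(ANNParams(a_ann=1.0, phi_ann=0.0, soe=0.5), grid)
        b = ann_waveform(ANNParams(a_ann=1.0, phi_ann=1.0, soe=0.5), grid)
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_unit_peak_before_scaling(self, grid):
        y = ann_waveform(ANNParams(a_ann=2.5, phi_ann=0.0, soe=0.5), grid)
        assert np.max(np.abs(y)) == pytest.approx(2.5)

    def test_scaling_linearity(self, grid):
        base = ann_waveform(ANNParams(a_ann=1.0, phi_ann=0.2, soe=0.5), grid)
        for k in (0.0, 0.7, 3.0):
            scaled = ann_waveform(ANNParams(a_ann=k, phi_ann=0.2, soe=0.5), grid)
            np.testing.assert_allclose(scaled, k * base, atol=1e-14)

    def test_shift_group_property(self, grid):
        n = grid.n_samples
        y0 = ann_waveform(ANNParams(a_ann=1.0, phi_ann=0.0, soe=0.5), grid)
        for a_shift, b_shift in [(3, 5), (10, 30), (17, 17)]:
            ya = ann_waveform(
                ANNParams(a_ann=1.0, phi_ann=(a_shift + b_shift) / n, soe=0.5), grid
            )
            yb = np.roll(y0, (a_shift + b_shift) % n)
            np.testing.assert_allclose(ya, yb, atol=1e-14)

    @pytest.mark.parametrize("n", [8, 16, 32, 33, 47, 64, 128, 256])
    def test_circular_convolution_matches_brute_force(self, n, rng):
        signal = rng.normal(size=n)
        kernel = rng.normal(size=min(n, 11))
        fast = _circular_convolve(signal, kernel)
        slow = brute_force_circular_convolve(signal, kernel)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)

    def test_pipeline_matches_brute_force_oracle(self, grid):
        # full ANN construction vs an independently coded convolution
        ann = ANNParams(a_ann=0.7, phi_ann=0.25, soe=0.45)
        ch = cycle_histogram(ann, grid)
        up = unit_potential(ann.up_frequency, grid.sampling_rate)
        kernel = brute_force_circular_convolve(ch, up)
        kernel = kernel / np.max(np.abs(kernel))
        expected = 0.7 * np.roll(kernel, round(0.25 * grid.n_samples))
        np.testing.assert_allclose(ann_waveform(ann, grid), expected, rtol=1e-10)


class TestCombinedModel:
    def test_zero_ann_reduces_to_cm(self, grid):
        p = make_params(a_ann=0.0)
        np.testing.assert_array_equal(
            ecochg_model(p, grid), cm_waveform(p.cm, grid)
        )

    def test_additivity(self, grid):
        p = make_params(a_ann=0.5, phi_ann=0.3)
        total = ecochg_model(p, grid)
        np.testing.assert_allclose(
            total - ann_waveform(p.ann, grid), cm_waveform(p.cm, grid), atol=1e-14
        )

    def test_in_phase_exceeds_anti_phase_peak_to_peak(self, grid):
        # constructive vs destructive interference of the two components
        in_phase = ecochg_model(make_params(a_ann=1.0, phi_ann=0.0), grid)
        anti_phase = ecochg_model(make_params(a_ann=1.0, phi_ann=0.5), grid)
        assert np.ptp(in_phase) > np.ptp(anti_phase)
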