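"""ANN/CM comparison metrics: ratio, index, dB, and the 5% cutoff rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecochg import (
    DecompositionMetrics,
    amplitude_to_db,
    ann_cm_index,
    apply_small_ratio_cutoff,
    component_magnitudes,
    decomposition_metrics,
    fit_decomposition,
    generate_simulated_cycle,
)
from ecochg.errors import ParameterError
from ecochg.simulate import DEFAULT_GRID

from conftest import make_params

positive = st.floats(min_value=1e-6, max_value=1e6)


class TestIndex:
    def test_all_cm_endpoint(self):
        assert ann_cm_index(0.0, 1.0) == -1.0

    def test_equal_components_zero(self):
        assert ann_cm_index(0.7, 0.7) == 0.0

    def test_all_ann_endpoint(self):
        assert ann_cm_index(1.0, 0.0) == 1.0

    def test_population_mean_index_inverts_to_ratio(self):
        # an index of −0.56 corresponds to a CM about 3.5× the ANN
        index = -0.56
        cm_over_ann = (1 - index) / (1 + index)
        assert cm_over_ann == pytest.approx(3.5, rel=0.02)

    def test_both_zero_undefined(self):
        with pytest.raises(ParameterError):
            ann_cm_index(0.0, 0.0)

    @given(a=positive, c=positive)
    def test_antisymmetric(self, a, c):
        assert ann_cm_index(a, c) == pytest.approx(-ann_cm_index(c, a))

    @given(a=positive, c=positive, k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariant(self, a, c, k):
        assert ann_cm_index(k * a, k * c) == pytest.approx(
            ann_cm_index(a, c), abs=1e-9
        )

    @given(a=positive, c=positive)
    def test_consistent_with_ratio(self, a, c):
        ratio = a / c
        assert ann_cm_index(a, c) == pytest.approx((ratio - 1) / (ratio + 1))


class TestDecibels:
    def test_noise_floor_example(self):
        # a 20 nV signal sits ~34 dB below 1 μV
        assert amplitude_to_db(0.02, 1.0) == pytest.approx(-33.98, abs=0.01)

    def test_unity_is_zero(self):
        assert amplitude_to_db(1.0, 1.0) == 0.0

    def test_factor_two(self):
        assert amplitude_to_db(2.0, 1.0) == pytest.approx(6.02, abs=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            amplitude_to_db(0.0, 1.0)


class TestSmallRatioCutoff:
    def _metrics(self, ratio):
        return DecompositionMetrics(
            cm_magnitude=1.0,
            ann_magnitude=ratio,
            ann_cm_ratio=ratio,
            ann_cm_index=(ratio - 1) / (ratio + 1),
            ann_re_cm_db=0.0,
        )

    def test_below_threshold_zeroes_ann(self):
        m = apply_small_ratio_cutoff(self._metrics(0.04))
        assert m.cutoff_applied
        assert m.ann_magnitude == 0.0
        # ratio and index keep their pre-cutoff values
        assert m.ann_cm_ratio == 0.04
        assert m.ann_cm_index == pytest.approx((0.04 - 1) / (0.04 + 1))

    def test_threshold_is_strict(self):
        m = apply_small_ratio_cutoff(self._metrics(0.05))
        assert not m.cutoff_applied
        assert m.ann_magnitude == 0.05

    def test_above_threshold_unchanged(self):
        m = self._metrics(0.50)
        assert apply_small_ratio_cutoff(m) == m


class TestComponentMagnitudes:
    def test_zero_ann_in_both_bases(self):
        cycle = generate_simulated_cycle(make_params(a_ann=0.0), DEFAULT_GRID)
        fit = fit_decomposition(cycle)
        for basis in ("parameter", "first_harmonic"):
            _, ann = component_magnitudes(fit, basis)
            assert ann == pytest.approx(0.0, abs=5e-3)

    def test_unclipped_cm_equal_in_both_bases(self):
        cycle = generate_simulated_cycle(make_params(a_ann=0.3), DEFAULT_GRID)
        fit = fit_decomposition(cycle)
        cm_param, _ = component_magnitudes(fit, "parameter")
        cm_h1, _ = component_magnitudes(fit, "first_harmonic")
        assert cm_h1 == pytest.approx(cm_param, rel=1e-3)

    def test_clipped_cm_first_harmonic_below_parameter(self):
        # symmetric 50% clipping strips fundamental energy
        cycle = generate_simulated_cycle(
            make_params(peak_saturation=0.5, trough_saturation=0.5, a_ann=0.0),
            DEFAULT_GRID,
        )
        fit = fit_decomposition(cycle)
        cm_param, _ = component_magnitudes(fit, "parameter")
        cm_h1, _ = component_magnitudes(fit, "first_harmonic")
        assert cm_h1 < cm_param

    def test_full_metrics_record(self):
        cycle = generate_simulated_cycle(make_params(a_ann=0.3), DEFAULT_GRID)
        fit = fit_decomposition(cycle)
        m = decomposition_metrics(fit)
        assert -1.0 <= m.ann_cm_index <= 1.0
        assert m.ann_cm_ratio == pytest.approx(
            m.ann_magnitude / m.cm_magnitude if not m.cutoff_applied else m.ann_cm_ratio
        )
        assert m.ann_re_cm_db == pytest.approx(
            amplitude_to_db(m.ann_cm_ratio, 1.0), abs=1e-9
        )
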