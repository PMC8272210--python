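"""Multiexponential relaxation-curve fitting and phase assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emulrelax import (
    CPMGModel,
    InversionRecoveryModel,
    RelaxationComponent,
    SignalTrace,
    assign_phases,
    fit_cpmg,
    fit_inversion_recovery,
    observed_rate,
    select_n_components,
)
from emulrelax.relaxation import (
    ComponentCollapseWarning,
    NonDecayingTraceError,
    PhaseAssignmentError,
)
from conftest import make_cpmg, make_ir


class TestSignalTrace:
    def test_too_few_points_rejected(self):
        times = np.linspace(0.01, 1, 6)
        with pytest.raises(ValueError, match="at least 8"):
            SignalTrace(times, np.exp(-times), "cpmg")

    def test_non_increasing_times_rejected(self):
        times = np.array([0.01, 0.02, 0.02, 0.04, 0.05, 0.06, 0.07, 0.08])
        with pytest.raises(ValueError, match="increasing"):
            SignalTrace(times, np.ones(8), "cpmg")

    def test_csv_round_trip(self, tmp_path):
        trace = make_cpmg()
        trace.to_csv(tmp_path / "t.csv")
        back = SignalTrace.from_csv(tmp_path / "t.csv", "cpmg")
        np.testing.assert_allclose(back.times, trace.times)
        np.testing.assert_allclose(back.amplitudes, trace.amplitudes)


class TestInversionRecovery:
    def test_noiseless_monoexponential(self):
        times = np.geomspace(0.01, 3.0, 20)
        trace = SignalTrace(times, 1 - 2 * np.exp(-times / 0.5), "inversion_recovery")
        res = fit_inversion_recovery(trace, n_components=1)
        assert res.converged
        assert res.time_constants[0] == pytest.approx(0.5, rel=1e-6)

    def test_noiseless_biexponential(self):
        res = fit_inversion_recovery(make_ir(0.06, 0.6, 0.2), n_components=2)
        np.testing.assert_allclose(res.time_constants, [0.06, 0.6], rtol=1e-4)
        np.testing.assert_allclose(res.fractions, [0.2, 0.8], atol=1e-4)

    def test_insufficient_points_for_two_components(self):
        times = np.geomspace(0.01, 1.0, 6)
        with pytest.raises(ValueError):
            trace = SignalTrace(times, 1 - 2 * np.exp(-times / 0.3), "inversion_recovery")
            fit_inversion_recovery(trace, n_components=2)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError, match="inversion_recovery"):
            InversionRecoveryModel(make_cpmg())


class TestCPMG:
    def test_noiseless_biexponential_200_echoes(self):
        res = fit_cpmg(make_cpmg(0.03, 0.3, 0.2, n=200), n_components=2)
        np.testing.assert_allclose(res.time_constants, [0.03, 0.3], rtol=1e-4)
        np.testing.assert_allclose(res.fractions, [0.2, 0.8], atol=1e-4)

    def test_noisy_recovery_snr_200(self):
        res = fit_cpmg(make_cpmg(0.03, 0.3, 0.2, n=200, noise=1 / 200, seed=3), 2)
        np.testing.assert_allclose(res.time_constants, [0.03, 0.3], rtol=0.05)
        np.testing.assert_allclose(res.fractions, [0.2, 0.8], atol=0.05)

    def test_constant_amplitudes_rejected(self):
        times = np.linspace(0.01, 1.0, 50)
        with pytest.raises(NonDecayingTraceError):
            CPMGModel(SignalTrace(times, np.ones(50), "cpmg"))

    def test_fractions_sum_to_one(self):
        res = fit_cpmg(make_cpmg(noise=1 / 100), 2)
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_components_sorted_ascending(self):
        res = fit_cpmg(make_cpmg(0.02, 0.4, 0.35), 2)
        assert res.time_constants[0] < res.time_constants[1]

    def test_collapse_warning_for_close_time_constants(self):
        with pytest.warns(ComponentCollapseWarning):
            fit_cpmg(make_cpmg(0.1, 0.105, 0.5), 2)

    def test_summary_mentions_components(self):
        res = fit_cpmg(make_cpmg(), 2)
        text = res.summary()
        assert "CPMG" in text and "T2" in text


class TestRoundTripProperty:
    @given(
        t_short=st.floats(min_value=0.01, max_value=0.3),
        ratio=st.floats(min_value=3.0, max_value=20.0),
        p=st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_noiseless_generate_fit_recovers(self, t_short, ratio, p):
        t_long = min(t_short * ratio, 2.0)
        if t_long / t_short < 3.0:
            return
        res = fit_cpmg(make_cpmg(t_short, t_long, p, n=120), 2)
        np.testing.assert_allclose(res.time_constants, [t_short, t_long], rtol=1e-3)
        np.testing.assert_allclose(res.fractions, [p, 1 - p], atol=1e-3)


class TestModelSelection:
    def test_clean_monoexponential_selects_one(self):
        times = np.geomspace(0.01, 3.0, 40)
        trace = SignalTrace(times, 1 - 2 * np.exp(-times / 0.5), "inversion_recovery")
        assert select_n_components(trace, 2) == 1

    def test_clean_biexponential_selects_two(self):
        assert select_n_components(make_cpmg(0.05, 0.5, 0.3, n=100), 2) == 2

    def test_unresolvable_ratio_collapses_to_one(self):
        assert select_n_components(make_cpmg(0.1, 0.105, 0.5, n=100), 2) == 1

    def test_invalid_max_components(self):
        with pytest.raises(ValueError):
            select_n_components(make_cpmg(), 4)


class TestObservedRate:
    def test_single_pool(self):
        comps = [RelaxationComponent(2.0, 1.0, "T1")]
        assert observed_rate(comps) == pytest.approx(0.5)

    def test_identical_pools(self):
        comps = [RelaxationComponent(1.0, 0.5, "T2"), RelaxationComponent(1.0, 0.5, "T2")]
        assert observed_rate(comps) == pytest.approx(1.0)

    def test_weighted_average(self):
        comps = [RelaxationComponent(0.1, 0.25, "T1"), RelaxationComponent(1.0, 0.75, "T1")]
        assert observed_rate(comps) == pytest.approx(3.25)

    def test_mixed_kinds_rejected(self):
        comps = [RelaxationComponent(0.1, 0.5, "T1"), RelaxationComponent(1.0, 0.5, "T2")]
        with pytest.raises(TypeError):
            observed_rate(comps)

    def test_unnormalized_fractions_rejected(self):
        comps = [RelaxationComponent(0.1, 0.3, "T1"), RelaxationComponent(1.0, 0.3, "T1")]
        with pytest.raises(ValueError, match="sum"):
            observed_rate(comps)


class TestAssignPhases:
    def test_short_is_oil_long_is_water(self):
        fit_t1 = fit_inversion_recovery(make_ir(0.06, 0.6, 0.2), 2)
        fit_t2 = fit_cpmg(make_cpmg(0.03, 0.3, 0.2), 2)
        oil, water = assign_phases(fit_t1, fit_t2)
        assert [c.phase for c in oil + water] == ["oil", "oil", "water", "water"]
        assert oil[0].time_constant == pytest.approx(0.06, rel=1e-3)
        assert oil[1].time_constant == pytest.approx(0.03, rel=1e-3)
        assert water[0].time_constant == pytest.approx(0.6, rel=1e-3)
        assert water[1].time_constant == pytest.approx(0.3, rel=1e-3)

    def test_single_component_fit_rejected(self):
        mono = fit_cpmg(make_cpmg(0.05, 0.5, 0.3), n_components=1)
        bi = fit_cpmg(make_cpmg(0.03, 0.3, 0.2), 2)
        with pytest.raises(PhaseAssignmentError, match="explicit"):
            assign_phases(bi, mono)

    def test_tied_time_constants_rejected(self):
        bi = fit_cpmg(make_cpmg(0.03, 0.3, 0.2), 2)
        tied = fit_cpmg(make_cpmg(0.03, 0.3, 0.2), 2)
        object.__setattr__(tied.components[0], "time_constant", 0.1)
        object.__setattr__(tied.components[1], "time_constant", 0.1)
        with pytest.raises(PhaseAssignmentError, match="tie"):
            assign_phases(bi, tied)
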