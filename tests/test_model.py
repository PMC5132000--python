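import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import exosurv as es
from exosurv.model import SegmentClass, ValidationWarning


class TestSegmentation:
    @pytest.mark.parametrize("t,expected", [
        (0.5, SegmentClass.FIRST_PULSE),
        (10.0, SegmentClass.LATER_PULSE),
        (11.0, SegmentClass.BETWEEN),
        (5.0, SegmentClass.BETWEEN),
        (0.0, SegmentClass.FIRST_PULSE),
        (1.0, SegmentClass.BETWEEN),   # half-open pulse intervals
        (90.5, SegmentClass.LATER_PULSE),
        (99.9, SegmentClass.BETWEEN),
    ])
    def test_segment_of(self, protocol, t, expected):
        assert es.segment_of(t, protocol) == expected

    @pytest.mark.parametrize("t", [-0.1, 100.0, 150.0])
    def test_segment_of_domain_error(self, protocol, t):
        with pytest.raises(ValueError):
            es.segment_of(t, protocol)

    def test_partition_measure(self, protocol):
        # total pulse time 10 s, rest 90 s under the default protocol
        expo = protocol.class_exposures(100.0)
        assert expo[0] == 1.0
        assert expo[1] == 9.0
        assert expo[2] == 90.0

    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            es.StimulusProtocol((0.0, 0.5), 1.0, 100.0)  # overlapping pulses
        with pytest.raises(ValueError):
            es.StimulusProtocol((0.0, 10.0), 1.0, 10.5)  # pulse beyond end


class TestHazard:
    def test_hazard_identity(self, protocol):
        p = es.FrailtyParams(alpha1=math.log(0.001), alpha2=math.log(1e-4),
                             beta2=1.43, eta=500.0, pi0=0.02, pi1=0.01)
        assert es.hazard_at(10.5, p, X=0, z=1.0) == pytest.approx(0.001)
        assert es.hazard_at(10.5, p, X=0, z=500.0) == pytest.approx(0.5)
        assert es.hazard_at(5.0, p, X=1, z=1.0) == pytest.approx(1e-4 * math.exp(1.43))

    def test_negative_time_rejected(self):
        p = es.PoissonParams(alpha=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            es.hazard_at(-1.0, p)

    def test_cumulative_hazard_closed_form(self, protocol):
        p = es.PoissonParams(alpha=(math.log(0.1), math.log(0.1), math.log(0.01)))
        assert es.cumulative_baseline_hazard(0.5, p) == pytest.approx(0.05)
        assert es.cumulative_baseline_hazard(10.0, p) == pytest.approx(0.19)
        assert es.cumulative_baseline_hazard(100.0, p) == pytest.approx(1.9)

    def test_cumulative_hazard_matches_quadrature(self, protocol):
        p = es.PoissonParams(alpha=(math.log(0.05), math.log(0.02), math.log(0.003)),
                             beta=(0.2, -0.1, 0.5))
        breaks = sorted({s for s in protocol.pulse_starts}
                        | {s + 1 for s in protocol.pulse_starts} | {0.0, 73.0})
        for X in (0, 1):
            val, err = quad(lambda u: es.hazard_at(u, p, X, 1.0, protocol),
                            0, 73.0, points=[b for b in breaks if b <= 73],
                            limit=200)
            assert es.cumulative_baseline_hazard(73.0, p, X) == pytest.approx(
                val, abs=1e-10)

    def test_cumulative_hazard_continuity_and_linearity(self, protocol):
        p = es.PoissonParams(alpha=(math.log(0.3), math.log(0.1), math.log(0.02)))
        eps = 1e-9
        for b in [1.0, 10.0, 11.0, 50.0, 91.0]:
            left = es.cumulative_baseline_hazard(b - eps, p)
            right = es.cumulative_baseline_hazard(b + eps, p)
            assert abs(right - left) < 1e-7  # continuous across boundaries
        # exactly linear inside a segment: midpoint identity
        a, b = 12.0, 18.0
        mid = es.cumulative_baseline_hazard(15.0, p)
        assert mid == pytest.approx(
            0.5 * (es.cumulative_baseline_hazard(a, p)
                   + es.cumulative_baseline_hazard(b, p)), abs=1e-12)

    def test_domain_error_beyond_end(self, protocol):
        p = es.PoissonParams(alpha=(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            es.cumulative_baseline_hazard(101.0, p)


class TestMarginalSurvival:
    def test_at_zero(self, table2_truth):
        assert es.marginal_survival(0.0, 0, table2_truth) == 1.0
        assert es.marginal_survival(0.0, 1, table2_truth) == 1.0

    def test_mixture_value(self):
        # pi=0.5, eta=2 and M0(t)=1: S = 0.5 e^-2 + 0.5 e^-1
        p = es.FrailtyParams(alpha1=math.log(0.1), alpha2=math.log(0.1),
                             beta2=0.0, eta=2.0, pi0=0.5, pi1=0.5)
        # with equal rates M0(10) = 0.1 * 10 = 1
        assert es.marginal_survival(10.0, 0, p) == pytest.approx(
            0.5 * math.exp(-2) + 0.5 * math.exp(-1), abs=1e-12)

    def test_degenerate_mixture(self, protocol):
        p = es.FrailtyParams(alpha1=math.log(0.01), alpha2=math.log(0.001),
                             beta2=0.5, eta=50.0, pi0=0.0, pi1=0.0)
        t = np.linspace(0, 100, 11)
        m0 = es.cumulative_baseline_hazard(t, p, 1)
        np.testing.assert_allclose(es.marginal_survival(t, 1, p),
                                   np.exp(-m0), atol=1e-14)

    def test_monotone_and_bracketed(self, table2_truth):
        t = np.linspace(0, 100, 400)
        s = es.marginal_survival(t, 0, table2_truth)
        assert np.all(np.diff(s) <= 1e-15)
        m0 = es.cumulative_baseline_hazard(t, table2_truth, 0)
        assert np.all(s <= np.exp(-m0) + 1e-15)
        assert np.all(s >= np.exp(-table2_truth.eta * m0) - 1e-15)

    def test_neg_log_survival_derivative_is_marginal_hazard(self, table2_truth):
        # d/dt[-log S] equals the marginal hazard, checked against the
        # finite-difference (S(t) - S(t+delta)) / (delta S(t))
        p, X, delta = table2_truth, 0, 1e-6
        for t in [0.5, 5.0, 10.5, 47.0]:
            s0 = es.marginal_survival(t, X, p)
            s1 = es.marginal_survival(t + delta, X, p)
            fd = (s0 - s1) / (delta * s0)
            m0 = es.cumulative_baseline_hazard(t, p, X)
            mu0 = es.hazard_at(t, p, X, 1.0)
            pi = p.pi(X)
            marginal_hazard = mu0 * (
                pi * p.eta * np.exp(-p.eta * m0) + (1 - pi) * np.exp(-m0)) / s0
            assert fd == pytest.approx(marginal_hazard, rel=1e-4)


class TestIncidenceComponents:
    def test_components_sum_to_marginal(self, table2_truth):
        grid = np.linspace(0, 100, 301)
        for X in (0, 1):
            comp = es.incidence_components(grid, X, table2_truth)
            np.testing.assert_allclose(
                comp["irp"].values + comp["non_irp"].values,
                comp["marginal"].values, atol=1e-12)

    def test_pi_one_degenerates_to_irp(self):
        p = es.FrailtyParams(alpha1=math.log(0.01), alpha2=math.log(0.001),
                             beta2=0.0, eta=10.0, pi0=1.0, pi1=1.0)
        comp = es.incidence_components(np.linspace(0, 100, 50), 0, p)
        np.testing.assert_allclose(comp["irp"].values, comp["marginal"].values,
                                   atol=1e-14)

    def test_irp_plateau_after_first_pulse(self):
        # strong pulse hazard + large eta empties the IRP within the first
        # pulse; its component should sit within 1% of pi by t=9
        p = es.FrailtyParams(alpha1=math.log(0.05), alpha2=math.log(1e-5),
                             beta2=0.0, eta=500.0, pi0=0.03, pi1=0.03)
        comp = es.incidence_components(np.array([9.0]), 0, p)
        assert comp["irp"].values[0] == pytest.approx(0.03, rel=0.01)


class TestEventDataset:
    def _frame(self, **overrides):
        import pandas as pd
        base = dict(cell_id=["c1", "c1"], granule_id=["g1", "g2"],
                    time=[50.0, 100.0], event=[1, 0], diabetic=[0, 0])
        base.update(overrides)
        return pd.DataFrame(base)

    def test_valid(self, protocol):
        ds = es.EventDataset(self._frame(), protocol)
        assert ds.n_clusters == 1 and ds.n_events == 1

    def test_covariate_must_be_cell_constant(self, protocol):
        with pytest.raises(ValueError, match="varies within"):
            es.EventDataset(self._frame(diabetic=[0, 1]), protocol)

    def test_time_domain(self, protocol):
        with pytest.raises(ValueError):
            es.EventDataset(self._frame(time=[0.0, 100.0]), protocol)
        with pytest.raises(ValueError):
            es.EventDataset(self._frame(time=[50.0, 101.0]), protocol)

    def test_event_at_end_accepted_censored_early_warns(self, protocol):
        es.EventDataset(self._frame(time=[100.0, 100.0], event=[1, 0]), protocol)
        with pytest.warns(ValidationWarning):
            es.EventDataset(self._frame(time=[50.0, 99.0]), protocol)


@settings(max_examples=50, deadline=None)
@given(t=st.floats(min_value=0.0, max_value=100.0, exclude_max=True))
def test_segment_partition_is_exhaustive(t):
    protocol = es.StimulusProtocol.default()
    assert es.segment_of(t, protocol) in (0, 1, 2)
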