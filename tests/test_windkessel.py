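"""3-element Windkessel: response, impedance, and parameter recovery."""

import numpy as np
import pytest

from graftflow.errors import ValidationError
from graftflow.waveforms import FlowWaveform
from graftflow.windkessel import (
    BranchSurrogate,
    RCRParameters,
    TuningTarget,
    rcr_impedance,
    rcr_pressure,
    split_inlet_flow,
    tune_rcr,
)

T = 1.0
TGRID = np.arange(256) / 256


def _flow(values):
    return FlowWaveform(t=TGRID, Q=values, T=T)


class TestPressureResponse:
    def test_steady_limit(self):
        p = RCRParameters(Rp=1.44e8, C=1e-9, Rd=1.456e9, P_ref=0.0)
        q = _flow(np.full(256, 5e-6))
        P = rcr_pressure(q, p)
        np.testing.assert_allclose(P, 5e-6 * 1.6e9, rtol=1e-8)

    def test_zero_flow_gives_reference_pressure(self):
        p = RCRParameters(Rp=1e8, C=1e-9, Rd=1e9, P_ref=9000.0)
        P = rcr_pressure(_flow(np.zeros(256)), p)
        np.testing.assert_allclose(P, 9000.0, atol=1e-6)

    def test_sinusoid_matches_phasor_solution(self):
        p = RCRParameters(Rp=1e8, C=2e-10, Rd=1.2e9, P_ref=0.0)
        omega = 2 * np.pi / T
        q1 = 3e-6
        q = _flow(q1 * np.cos(omega * TGRID))
        P = rcr_pressure(q, p, periodicity_tol=1e-10)
        Z = rcr_impedance(omega, p)
        # trapezoidal integration of the ODE has its own O(dt^2) error;
        # compare against the phasor solution of the *discrete* scheme by
        # using a fine grid and a modest tolerance on the analytic one
        want = (q1 / 2 * Z * np.exp(1j * omega * TGRID)).real * 2
        assert np.max(np.abs(P - want)) / np.max(np.abs(want)) < 1e-3

    def test_phasor_accuracy_refines_with_sampling(self):
        p = RCRParameters(Rp=1e8, C=2e-10, Rd=1.2e9, P_ref=0.0)
        omega = 2 * np.pi / T
        errs = []
        for n in (128, 512):
            t = np.arange(n) / n
            q = FlowWaveform(t=t, Q=3e-6 * np.cos(omega * t), T=T)
            P = rcr_pressure(q, p, periodicity_tol=1e-12)
            Z = rcr_impedance(omega, p)
            want = (3e-6 * Z * np.exp(1j * omega * t)).real
            errs.append(np.max(np.abs(P - want)) / np.max(np.abs(want)))
        assert errs[1] < errs[0] / 8  # second-order in the sample step

    def test_mean_pressure_identity(self):
        p = RCRParameters(Rp=2e7, C=5e-9, Rd=4e7, P_ref=1200.0)
        rng = np.random.default_rng(3)
        base = rng.normal(2e-4, 5e-5, size=8)
        q = np.interp(
            TGRID, np.linspace(0, T, 9), np.concatenate([base, base[:1]])
        )
        P = rcr_pressure(_flow(q), p, periodicity_tol=1e-11)
        assert np.mean(P) - p.P_ref == pytest.approx(
            np.mean(q) * p.total_resistance, rel=1e-6
        )

    def test_linearity_in_flow(self):
        p = RCRParameters(Rp=1e8, C=3e-10, Rd=9e8, P_ref=0.0)
        q = np.abs(np.sin(2 * np.pi * TGRID)) * 4e-6
        P1 = rcr_pressure(_flow(q), p, periodicity_tol=1e-11)
        P2 = rcr_pressure(_flow(2 * q), p, periodicity_tol=1e-11)
        np.testing.assert_allclose(P2, 2 * P1, rtol=1e-6, atol=1e-6)

    def test_resistive_power_floor(self):
        p = RCRParameters(Rp=1e8, C=3e-10, Rd=9e8, P_ref=0.0)
        q = 2e-6 + 1.5e-6 * np.cos(2 * np.pi * TGRID)
        P = rcr_pressure(_flow(q), p, periodicity_tol=1e-11)
        assert np.mean(q * P) >= np.mean(q) ** 2 * p.Rp


class TestImpedance:
    P = RCRParameters(Rp=1e8, C=2e-10, Rd=1.2e9)

    def test_dc_and_high_frequency_limits(self):
        assert rcr_impedance(0.0, self.P) == self.P.Rp + self.P.Rd
        whigh = 1e6 / (self.P.Rd * self.P.C)
        assert abs(rcr_impedance(whigh, self.P) - self.P.Rp) < 1e-6 * (
            self.P.Rp + self.P.Rd
        )

    def test_corner_frequency_value(self):
        w = 1.0 / (self.P.Rd * self.P.C)
        want = self.P.Rp + self.P.Rd * (1 - 1j) / 2
        assert rcr_impedance(w, self.P) == pytest.approx(want, rel=1e-12)

    def test_magnitude_monotone_decreasing(self):
        w = np.linspace(0, 1e3, 200)
        mag = np.abs(rcr_impedance(w, self.P))
        assert np.all(np.diff(mag) <= 1e-9 * mag[0])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            RCRParameters(Rp=-1.0, C=1e-9, Rd=1e9)


class TestTuning:
    def _setup(self, rcr_true=None):
        branches = [
            BranchSurrogate(outlet="SFA", resistance=2e5, inertance=3e4),
            BranchSurrogate(outlet="DFA", resistance=3e5, inertance=2e4),
        ]
        rcr_true = rcr_true or {
            "SFA": RCRParameters(Rp=4.5e6, C=6e-9, Rd=4.6e7),
            "DFA": RCRParameters(Rp=5.5e6, C=4e-9, Rd=5.6e7),
        }
        qin = _flow(
            4e-4 * (1.0 + 0.8 * np.cos(2 * np.pi * TGRID)
                    + 0.3 * np.sin(4 * np.pi * TGRID))
        )
        flows = split_inlet_flow(qin, branches, rcr_true, N=8)
        return branches, rcr_true, qin, flows

    def test_parameter_recovery_from_synthetic_flows(self):
        branches, rcr_true, qin, flows = self._setup()
        targets = [
            TuningTarget(outlet=k, Q_target=flows[k],
                         mean_pressure_target=flows[k].mean()
                         * (rcr_true[k].total_resistance + b.resistance))
            for k, b in (("SFA", branches[0]), ("DFA", branches[1]))
        ]
        tuned = tune_rcr(targets, qin, branches, N=8)
        split_true = flows["SFA"].mean() / qin.mean()
        tuned_flows = split_inlet_flow(qin, branches, tuned, N=8)
        split_tuned = tuned_flows["SFA"].mean() / qin.mean()
        assert split_tuned == pytest.approx(split_true, abs=0.01)
        for k in ("SFA", "DFA"):
            assert tuned[k].total_resistance == pytest.approx(
                rcr_true[k].total_resistance, rel=0.05
            )

    def test_symmetric_targets_give_symmetric_parameters(self):
        branches = [
            BranchSurrogate(outlet="A", resistance=2e5, inertance=3e4),
            BranchSurrogate(outlet="B", resistance=2e5, inertance=3e4),
        ]
        rcr = {
            "A": RCRParameters(Rp=5e6, C=5e-9, Rd=5e7),
            "B": RCRParameters(Rp=5e6, C=5e-9, Rd=5e7),
        }
        qin = _flow(4e-4 * (1.0 + 0.6 * np.cos(2 * np.pi * TGRID)))
        flows = split_inlet_flow(qin, branches, rcr, N=6)
        p_t = qin.mean() / 2 * (5.5e7 + 2e5)
        targets = [
            TuningTarget(outlet=k, Q_target=flows[k], mean_pressure_target=p_t)
            for k in ("A", "B")
        ]
        tuned = tune_rcr(targets, qin, branches, N=6)
        assert tuned["A"].total_resistance == pytest.approx(
            tuned["B"].total_resistance, rel=0.02
        )

    def test_overcommitted_targets_rejected(self):
        branches, _, qin, flows = self._setup()
        targets = [
            TuningTarget(outlet=k, Q_target=flows[k].scaled(3.0),
                         mean_pressure_target=1e4)
            for k in ("SFA", "DFA")
        ]
        with pytest.raises(ValidationError, match="exceed"):
            tune_rcr(targets, qin, branches)


def test_split_conserves_mass():
    branches = [
        BranchSurrogate(outlet="A", resistance=1e5, inertance=1e4),
        BranchSurrogate(outlet="B", resistance=4e5, inertance=3e4),
    ]
    rcr = {
        "A": RCRParameters(Rp=4e6, C=8e-9, Rd=3e7),
        "B": RCRParameters(Rp=9e6, C=2e-9, Rd=9e7),
    }
    qin = _flow(3e-4 * (1 + 0.9 * np.cos(2 * np.pi * TGRID)))
    flows = split_inlet_flow(qin, branches, rcr, N=10)
    total = flows["A"].Q + flows["B"].Q
    # band-limited comparison: reconstruct qin at the same truncation
    from graftflow.waveforms import fourier_decompose

    qin_bl = fourier_decompose(qin, N=10)(TGRID)
    np.testing.assert_allclose(total, qin_bl, rtol=1e-9, atol=1e-12)
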