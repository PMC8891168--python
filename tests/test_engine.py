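import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synenergy.core import EnergyState, PlasticityParams, Sample
from synenergy.engine import run, step, supply_closed_form
from synenergy.fixtures import Segment, closed_form_unconstrained, piecewise_trace


class TestSupplyClosedForm:
    def test_onset_value_is_minimum_supply(self, params):
        assert supply_closed_form(0.0, params) == params.S0 == 25.0

    def test_zero_rate_collapses_to_constant(self):
        p = PlasticityParams(R=0.0)
        assert supply_closed_form(0.0, p) == supply_closed_form(7.3, p) == p.S0

    def test_value_at_tau(self, params):
        # R·τ·e⁻¹ + S0 with the fitted parameters
        assert supply_closed_form(2.0, params) == pytest.approx(350.0 / np.e + 25.0)

    def test_maximum_at_tau_and_decay_to_minimum(self, params):
        t = np.linspace(0.0, 60.0, 6001)
        s = supply_closed_form(t, params)
        assert t[np.argmax(s)] == pytest.approx(params.tau, abs=0.02)
        assert s[-1] == pytest.approx(params.S0, rel=1e-3)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            supply_closed_form(-0.1, params)


class TestStep:
    def test_subthreshold_depolarizing_step(self):
        # one coarse unconstrained step: ΔP = V·I·dt, P_bas = A_r·ΔP
        p = PlasticityParams(dt=0.1)
        st1 = step(EnergyState(), Sample(0.0, -65.0, 2.0), p)
        assert st1.P == pytest.approx(-13.0)
        assert st1.P_bas == pytest.approx(-2.6)
        assert st1.P_sup == 0.0
        assert st1.W - 0.5 == pytest.approx(-0.052)

    def test_suprathreshold_repolarizing_step(self):
        p = PlasticityParams(dt=0.05)
        st1 = step(EnergyState(), Sample(0.0, 20.0, -3.0), p)
        assert st1.P_sup == pytest.approx(-3.0)
        assert st1.P_bas == 0.0
        assert st1.W - 0.5 == pytest.approx(+0.06)

    def test_silent_sample_leaves_energy_but_advances_supply(self, params):
        st1 = step(EnergyState(), Sample(0.0, 0.0, 0.0), params)
        assert st1.P == 0.0 and st1.W == 0.5
        assert st1.S_damp < 1.0 and st1.S_lin > 0.0

    def test_sign_zero_freezes_energy_state(self):
        # R=0 keeps S at S0 exactly, so |P| = S0 gives sign(0) = 0
        p = PlasticityParams(R=0.0, dt=1e-3)
        st0 = EnergyState(P=-25.0, P_bas=-5.0, W=0.4)
        st1 = step(st0, Sample(0.0, -65.0, 5.0), p)
        assert st1.P == st0.P and st1.P_bas == st0.P_bas and st1.W == st0.W
        assert st1.P_u != st0.P_u  # the unconstrained shadow keeps integrating

    def test_non_finite_sample_rejected(self, params):
        with pytest.raises(ValueError):
            step(EnergyState(), Sample(0.0, float("nan"), 1.0), params)


class TestRun:
    def test_zero_trace_leaves_initial_state(self, params):
        tr = piecewise_trace([Segment(0.05, 0.0, 0.0)], 1e-4)
        out = run(tr, params)
        fs = out.final["fix0"]
        assert fs.W == 0.5 and fs.P == 0.0 and fs.P_u == 0.0

    @pytest.mark.parametrize(
        "segments",
        [
            [Segment(0.1, -65.0, 2.0)],
            [Segment(0.05, 20.0, -3.0)],
            [Segment(0.04, -65.0, 2.0), Segment(0.03, -50.0, 1.5),
             Segment(0.02, 10.0, -2.0)],
        ],
    )
    def test_unconstrained_matches_closed_form(self, params, segments):
        """On piecewise-constant traces below the supply bound the engine
        must reproduce the segment sums to machine precision."""
        P, P_bas, P_sup, dW = closed_form_unconstrained(segments, params)
        tr = piecewise_trace(segments, 1e-4)
        fs = run(tr, params).final["fix0"]
        assert fs.P_u == pytest.approx(P, rel=1e-10, abs=1e-10)
        assert fs.P_bas_u == pytest.approx(P_bas, rel=1e-10, abs=1e-10)
        assert fs.P_sup_u == pytest.approx(P_sup, rel=1e-10, abs=1e-10)
        assert fs.W_u - 0.5 == pytest.approx(dW, rel=1e-9, abs=1e-12)
        # below the bound the constrained trajectory is the same numbers
        assert fs.P == fs.P_u and fs.W == fs.W_u

    def test_inactive_constraint_is_bitwise_identical(self, params):
        tr = piecewise_trace([Segment(0.1, -65.0, 0.5)], 1e-4)  # |P| max 3.25
        out = run(tr, params, record=1)
        np.testing.assert_array_equal(out.P, out.P_u)
        np.testing.assert_array_equal(out.W, out.W_u)

    def test_shadows_ignore_supply_parameters(self):
        segs = [Segment(0.1, -65.0, 11.0)]
        tr = piecewise_trace(segs, 1e-4)
        a = run(tr, PlasticityParams()).final["fix0"]
        b = run(tr, PlasticityParams(R=20.0, S0=5.0, tau=0.5)).final["fix0"]
        assert a.W_u == b.W_u and a.P_u == b.P_u
        assert a.W != b.W  # while the constrained path does respond

    def test_weaker_supply_never_strengthens_plasticity(self, params):
        """A lower supply rate or floor can only shrink |ΔW| when the trace
        accumulates energy in a single threshold class (when both classes
        contribute, ΔW is a difference and clamping can shift its balance)."""
        from synenergy.fixtures import constrained_battery

        for name, segs in constrained_battery():
            classes = {s.V_m >= params.V_th for s in segs}
            if len(classes) > 1:
                continue
            tr = piecewise_trace(segs, 1e-4)
            base = abs(run(tr, params).final["fix0"].W - 0.5)
            for weaker in (PlasticityParams(R=50.0), PlasticityParams(S0=10.0)):
                low = abs(run(tr, weaker).final["fix0"].W - 0.5)
                assert low <= base + 1e-12

    def test_multiple_synapses_per_compartment_share_trace(self, params):
        tr = piecewise_trace([Segment(0.05, -65.0, 2.0)], 1e-4)
        out = run(tr, params, synapse_map={"fix0": ["s_a", "s_b"]})
        assert out.final["s_a"].W == out.final["s_b"].W

    def test_unknown_compartment_rejected(self, params):
        tr = piecewise_trace([Segment(0.01, 0.0, 0.0)], 1e-4)
        with pytest.raises(ValueError, match="unknown compartment"):
            run(tr, params, synapse_map={"nope": "s"})

    def test_step_and_run_agree(self, params):
        segs = [Segment(0.01, -65.0, 11.0), Segment(0.01, -30.0, 5.0)]
        tr = piecewise_trace(segs, 1e-3)
        st = EnergyState()
        for k in range(tr.n_samples):
            st = step(st, Sample(tr.t[k], tr.V_m[0, k], tr.I_m[0, k]),
                      PlasticityParams(dt=1e-3))
        fs = run(tr, PlasticityParams(dt=1e-3)).final["fix0"]
        assert fs.P == pytest.approx(st.P, rel=1e-12)
        assert fs.W == pytest.approx(st.W, rel=1e-12)
        assert fs.S_damp == pytest.approx(st.S_damp, rel=1e-12)


@st.composite
def random_segments(draw):
    n = draw(st.integers(1, 4))
    return [
        Segment(
            duration=draw(st.sampled_from([0.01, 0.02, 0.05])),
            V_m=draw(st.floats(-90.0, 20.0)),
            I_m=draw(st.floats(-30.0, 30.0)),
        )
        for _ in range(n)
    ]


class TestInvariants:
    @given(segments=random_segments())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_decomposition_and_weight_identity_every_step(self, segments):
        """P = P_bas/A_r + P_sup and W_u − 0.5 = A(P_bas_u − P_sup_u) must
        hold at every step, for the constrained path and the shadows."""
        params = PlasticityParams(dt=1e-3)
        tr = piecewise_trace(segments, 1e-3)
        out = run(tr, params, record=1)
        np.testing.assert_allclose(
            out.P, out.P_bas / params.A_r + out.P_sup, rtol=1e-10, atol=1e-9)
        np.testing.assert_allclose(
            out.P_u, out.P_bas_u / params.A_r + out.P_sup_u, rtol=1e-10, atol=1e-9)
        np.testing.assert_allclose(
            out.W_u - 0.5, params.A * (out.P_bas_u - out.P_sup_u),
            rtol=1e-9, atol=1e-12)

    @given(segments=random_segments(), outward=st.booleans())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_supply_bound_with_one_euler_increment_slack(self, segments, outward):
        """While the power V·I pushes |P| outward with a consistent sign, the
        sign-factor chatter holds |P| within one Euler increment of S."""
        sign = 1.0 if outward else -1.0
        segments = [
            Segment(s.duration, -abs(s.V_m) - 1.0, sign * abs(s.I_m))
            for s in segments
        ]
        params = PlasticityParams(dt=1e-3)
        tr = piecewise_trace(segments, 1e-3)
        out = run(tr, params, record=1)
        slack = params.A_scale * np.max(np.abs(tr.V_m * tr.I_m)) * 1e-3
        assert np.all(np.abs(out.P[0]) <= out.S + slack + 1e-12)

    def test_halving_dt_converges_on_constrained_fixture(self):
        """End-of-trace W error shrinks as the step is refined."""
        from synenergy.fixtures import reference_integrator

        segs = [Segment(0.1, -65.0, 11.0)]
        errs = []
        for dt in (4e-4, 2e-4, 1e-4):
            tr = piecewise_trace(segs, dt)
            w = run(tr, PlasticityParams(dt=dt)).final["fix0"].W
            ref = reference_integrator(tr, PlasticityParams(dt=dt), refine=20)
            errs.append(abs(w - ref["fix0"].W))
        assert errs[2] < errs[0]
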