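import math

import numpy as np
import pytest

from synenergy.core import PlasticityParams
from synenergy.engine import run, supply_closed_form
from synenergy.fixtures import (
    Segment,
    closed_form_unconstrained,
    constrained_battery,
    piecewise_trace,
    reference_integrator,
)


class TestPiecewiseTrace:
    def test_sample_count(self):
        tr = piecewise_trace([Segment(0.1, -65.0, 2.0)], 1e-4)
        assert tr.n_samples == 1000
        assert tr.dt == pytest.approx(1e-4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            piecewise_trace([], 1e-4)

    def test_off_grid_duration_rejected(self):
        with pytest.raises(ValueError, match="multiple of dt"):
            piecewise_trace([Segment(0.00015, 0.0, 0.0)], 1e-4)

    def test_boundary_sample_belongs_to_second_segment(self):
        tr = piecewise_trace([Segment(0.001, -65.0, 1.0), Segment(0.001, -50.0, 2.0)],
                             1e-3)
        # half-open convention: sample at t=0.001 carries the second segment
        assert tr.V_m[0, 0] == -65.0
        assert tr.V_m[0, 1] == -50.0


class TestClosedForm:
    @pytest.mark.parametrize(
        "segments, expected",
        [
            ([Segment(0.1, -65.0, 2.0)], (-13.0, -2.6, 0.0, -0.052)),
            ([Segment(0.05, 20.0, -3.0)], (-3.0, 0.0, -3.0, +0.06)),
            ([Segment(0.2, -80.0, 0.0)], (0.0, 0.0, 0.0, 0.0)),
        ],
    )
    def test_segment_arithmetic(self, params, segments, expected):
        P, P_bas, P_sup, dW = closed_form_unconstrained(segments, params)
        assert (P, P_bas, P_sup) == pytest.approx(expected[:3])
        assert dW == pytest.approx(expected[3])

    def test_baseline_to_subthreshold_ratio_is_A_r(self, params):
        segs = [Segment(0.05, -65.0, 2.0), Segment(0.02, -70.0, -1.0)]
        P, P_bas, P_sup, _ = closed_form_unconstrained(segs, params)
        assert P_sup == 0.0
        assert P_bas / P == pytest.approx(params.A_r)


class TestReferenceIntegrator:
    def test_refine_below_two_rejected(self, params):
        tr = piecewise_trace([Segment(0.001, 0.0, 0.0)], 1e-3)
        with pytest.raises(ValueError):
            reference_integrator(tr, params, refine=1)

    def test_matches_closed_form_when_unconstrained(self, params):
        segs = [Segment(0.02, -65.0, 2.0), Segment(0.01, 10.0, -3.0)]
        tr = piecewise_trace(segs, 1e-3)
        P, P_bas, P_sup, dW = closed_form_unconstrained(segs, params)
        ref = reference_integrator(tr, params, refine=4)["fix0"]
        assert ref.P == pytest.approx(P, rel=1e-9)
        assert ref.P_bas == pytest.approx(P_bas, rel=1e-9)
        assert ref.P_sup == pytest.approx(P_sup, rel=1e-9, abs=1e-12)
        assert ref.W - 0.5 == pytest.approx(dW, rel=1e-9)

    def test_engine_agrees_with_oracle_on_constrained_battery(self, params):
        """Independent naive re-integration at dt/10 reproduces the engine's
        end state within the chattering bound (energies) and 1 % (weights)."""
        for name, segs in constrained_battery():
            tr = piecewise_trace(segs, 1e-4)
            eng = run(tr, params).final["fix0"]
            ref = reference_integrator(tr, params, refine=10)["fix0"]
            bound = 2 * max(abs(s.V_m * s.I_m) for s in segs) * 1e-4
            assert abs(eng.P - ref.P) <= bound, name
            # weight agreement within 1 % of the accumulated plasticity flux
            # (ΔW itself can be a near-cancelling difference of the classes)
            scale = params.A * (abs(ref.P_bas) + abs(ref.P_sup))
            assert abs(eng.W - ref.W) <= 0.01 * scale + 1e-12, name

    def test_refined_trajectory_tracks_supply_boundary(self, params):
        segs = [Segment(0.1, -65.0, 11.0)]
        tr = piecewise_trace(segs, 1e-4)
        ref = reference_integrator(tr, params, refine=10)["fix0"]
        s_end = supply_closed_form(0.1, params)
        fine_inc = abs(-65.0 * 11.0) * 1e-5
        assert abs(abs(ref.P) - s_end) <= fine_inc

    def test_subthreshold_ratio_exact_on_engine_output(self, params):
        """P_bas is one fifth of the subthreshold energy (A_r = 0.2), exactly,
        constrained and unconstrained."""
        for name, segs in constrained_battery():
            tr = piecewise_trace(segs, 1e-4)
            fs = run(tr, params).final["fix0"]
            p_sub_u = fs.P_u - fs.P_sup_u
            if p_sub_u != 0.0:
                assert fs.P_bas_u / p_sub_u == pytest.approx(params.A_r, rel=1e-12), name
            p_sub = fs.P - fs.P_sup
            if p_sub != 0.0:
                assert fs.P_bas / p_sub == pytest.approx(params.A_r, rel=1e-9), name
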