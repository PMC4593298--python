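"""Model registry, conductance-block application and the demo model's RHS."""

import numpy as np
import pytest

from apblock.biomarkers import compute_biomarkers
from apblock.cellmodels import (
    BlockWarning,
    SIXCURRENT_PARAMS,
    apply_block,
    available_models,
    evaluate_rhs,
    get_model,
)
from apblock.doseresponse import BlockFactors, ChannelId
from apblock.engine import PacingProtocol, pace_to_steady


class TestRegistry:
    def test_demo_model_maps_all_six_channels(self):
        model = get_model("sixcurrent_demo")
        assert set(model.conductance_keys) == set(ChannelId)
        assert not model.ito_is_total

    def test_totalito_variant(self):
        model = get_model("sixcurrent_demo_totalito")
        assert model.ito_is_total

    def test_unknown_model_lists_choices(self):
        with pytest.raises(KeyError, match="sixcurrent_demo"):
            get_model("no_such_model")

    def test_no_state_leakage_between_calls(self):
        m1 = get_model("sixcurrent_demo")
        m1.default_parameters["g_Kr"] = 0.0
        m1.default_initial_state[0] = 0.0
        m2 = get_model("sixcurrent_demo")
        assert m2.default_parameters["g_Kr"] == SIXCURRENT_PARAMS["g_Kr"]
        assert m2.default_initial_state[0] != 0.0

    def test_available_models(self):
        assert "sixcurrent_demo" in available_models()


class TestApplyBlock:
    def test_identity_factors_leave_parameters_unchanged(self, demo_model):
        params = demo_model.default_parameters
        out = apply_block(demo_model, params, BlockFactors())
        assert dict(out) == dict(params)

    def test_half_ikr_block_scales_only_gkr(self, demo_model):
        params = demo_model.default_parameters
        out = apply_block(demo_model, params,
                          BlockFactors({ChannelId.IKr: 0.5}))
        assert out["g_Kr"] == pytest.approx(0.5 * params["g_Kr"])
        for k in params:
            if k != "g_Kr":
                assert out[k] == params[k]
        # original untouched
        assert params["g_Kr"] == SIXCURRENT_PARAMS["g_Kr"]

    def test_total_ito_aliasing(self):
        model = get_model("sixcurrent_demo_totalito")
        out = apply_block(model, model.default_parameters,
                          BlockFactors({ChannelId.Ito: 0.25}))
        assert out["g_to"] == pytest.approx(
            0.25 * model.default_parameters["g_to"])

    def test_unmapped_channel_warns(self, demo_model):
        import copy

        model = copy.deepcopy(demo_model)
        del model.conductance_keys[ChannelId.IKs]
        with pytest.warns(BlockWarning, match="IKs"):
            apply_block(model, model.default_parameters,
                        BlockFactors({ChannelId.IKs: 0.5}))

    def test_composition_equals_product_of_factors(self, demo_model):
        params = demo_model.default_parameters
        f1 = BlockFactors({ChannelId.IKr: 0.5, ChannelId.INa: 0.8})
        f2 = BlockFactors({ChannelId.IKr: 0.4, ChannelId.ICaL: 0.9})
        seq = apply_block(demo_model, apply_block(demo_model, params, f1), f2)
        prod = BlockFactors({c: f1[c] * f2[c] for c in ChannelId})
        once = apply_block(demo_model, params, prod)
        assert dict(seq) == pytest.approx(dict(once))


class TestEvaluateRhs:
    def test_equilibrium_derivatives_vanish(self, demo_model,
                                            equilibrium_state):
        dy = evaluate_rhs(demo_model, 0.0, equilibrium_state,
                          demo_model.default_parameters, stim=0.0)
        assert np.abs(dy).max() < 1e-8

    def test_depolarizing_stimulus_raises_voltage(self, demo_model,
                                                  equilibrium_state):
        dy = evaluate_rhs(demo_model, 0.0, equilibrium_state,
                          demo_model.default_parameters, stim=30.0)
        assert dy[0] > 0

    def test_rhs_linearity_in_maximal_conductance(self, demo_model):
        # at a plateau-like state the IKr contribution doubles with g_Kr
        state = demo_model.default_initial_state.copy()
        state[0] = 10.0  # depolarized
        state[5] = 0.5  # xr open
        params = demo_model.default_parameters
        base = evaluate_rhs(demo_model, 0.0, state, params)[0]
        p0 = params.copy()
        p0["g_Kr"] = 0.0
        off = evaluate_rhs(demo_model, 0.0, state, p0)[0]
        p2 = params.copy()
        p2["g_Kr"] = 2.0 * params["g_Kr"]
        double = evaluate_rhs(demo_model, 0.0, state, p2)[0]
        ikr_term = base - off
        assert double - off == pytest.approx(2.0 * ikr_term, rel=1e-12)

    def test_nan_state_identified_by_index(self, demo_model):
        state = demo_model.default_initial_state.copy()
        state[4] = np.nan
        with pytest.raises(ValueError, match=r"\[4\]"):
            evaluate_rhs(demo_model, 0.0, state,
                         demo_model.default_parameters)

    def test_determinism(self, demo_model):
        state = demo_model.default_initial_state
        params = demo_model.default_parameters
        a = evaluate_rhs(demo_model, 0.0, state, params, 5.0)
        b = evaluate_rhs(demo_model, 0.0, state, params, 5.0)
        assert np.array_equal(a, b)


class TestDemoModelMorphology:
    """Regression freeze of the tuned demonstration model at 1 Hz."""

    def test_action_potential_shape(self, control_steady):
        marks = compute_biomarkers(control_steady.final_trace)
        assert -90.0 <= marks.rest_v <= -75.0
        assert 10.0 <= marks.peak_v <= 50.0
        assert 200.0 <= marks.apd90 <= 350.0
        assert control_steady.paces_run <= 1000

    def test_frozen_baseline_values(self, control_steady):
        # tuned constants are frozen: a parameter change must show up here
        marks = compute_biomarkers(control_steady.final_trace)
        assert marks.apd90 == pytest.approx(242.29, abs=0.1)
        assert marks.apd50 == pytest.approx(217.35, abs=0.1)
        assert marks.rest_v == pytest.approx(-88.0, abs=0.05)
        assert marks.peak_v == pytest.approx(30.55, abs=0.1)
        assert marks.dvdt_max == pytest.approx(163.0, abs=1.0)

    @pytest.mark.parametrize(
        "gkey, check",
        [
            ("g_Kr", "apd90_up"),
            ("g_CaL", "apd90_down"),
            ("g_Na", "dvdt_down"),
        ],
    )
    def test_pharmacology_directions(self, demo_model, protocol,
                                     control_steady, gkey, check):
        """50% single-channel block moves the biomarkers the way cardiac
        electrophysiology says it must."""
        control = compute_biomarkers(control_steady.final_trace)
        params = demo_model.default_parameters.copy()
        params[gkey] = 0.5 * params[gkey]
        ss = pace_to_steady(demo_model, params, protocol,
                            control_steady.end_state)
        marks = compute_biomarkers(ss.final_trace)
        if check == "apd90_up":
            assert marks.apd90 > control.apd90
        elif check == "apd90_down":
            assert marks.apd90 < control.apd90
        else:
            assert marks.dvdt_max < control.dvdt_max
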