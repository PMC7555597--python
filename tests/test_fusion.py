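"""Decision-Factor curves, Global Risk, and both correction levels."""

import math

import numpy as np
import pytest

from woundrisk.fusion import (
    DecisionFactorModel,
    ExpCorrectionSpec,
    LogCorrectionSpec,
    SigmoidCorrectionSpec,
    correct_exponential,
    correct_logarithmic,
    correct_sigmoidal,
    decision_factor,
    fuse,
    global_risk,
)


class TestDecisionFactor:
    def test_worked_example(self, model):
        assert decision_factor(40.0, 70.0, model) == pytest.approx(11.58, abs=5e-3)

    def test_logarithmic_zone_value(self, model):
        # independently recomputed: f3(60)*ln(50) + f4(60)
        assert decision_factor(60.0, 50.0, model) == pytest.approx(14.25, abs=5e-3)

    @pytest.mark.parametrize("rt", [10.0, 20.0, 30.0, 40.0, 50.0])
    def test_zero_exponent_gives_floor_plus_one(self, rt, model):
        # RE equal to the shift f2(rt) makes the exponent vanish: DF = 10 + 1
        assert decision_factor(rt, model.f2(rt), model) == pytest.approx(11.0)

    def test_boundary_uses_exponential_branch(self, model):
        expo = model.f1(50.0) ** (70.0 - model.f2(50.0)) + model.df_floor
        assert decision_factor(50.0, 70.0, model) == pytest.approx(expo)

    def test_out_of_range_risk_rejected(self, model):
        with pytest.raises(ValueError):
            decision_factor(5.0, 70.0, model)
        with pytest.raises(ValueError):
            decision_factor(40.0, 101.0, model)

    @pytest.mark.parametrize("rt", [10.0, 25.0, 40.0, 50.0, 50.5, 60.0, 80.0, 100.0])
    def test_strictly_increasing_in_expert_risk(self, rt, model):
        values = [decision_factor(rt, re, model) for re in np.arange(10.0, 101.0, 1.0)]
        assert (np.diff(values) > 0).all()


class TestGlobalRisk:
    def test_worked_example(self, model):
        df = decision_factor(40.0, 70.0, model)
        rg = global_risk(40.0, df)
        assert rg.kind == "global"
        assert rg.value == pytest.approx(46.31, abs=5e-3)

    def test_minimum_technical_risk_reduces_to_decision_factor(self, model, rng):
        for re in rng.uniform(10.0, 100.0, 20):
            df = decision_factor(10.0, float(re), model)
            assert global_risk(10.0, df).value == pytest.approx(df)

    def test_clamped_at_100(self):
        assert global_risk(100.0, 50.0).value == 100.0

    def test_negative_decision_factor_rejected(self):
        with pytest.raises(ValueError):
            global_risk(40.0, -1.0)

    def test_bounded_on_full_grid(self, model):
        for rt in np.linspace(10, 100, 31):
            for re in np.linspace(10, 100, 31):
                value = global_risk(rt, decision_factor(rt, re, model)).value
                assert 10.0 <= value <= 100.0


class TestExponentialCorrection:
    spec_interval = (64.0, 80.0)

    def test_full_weight_on_d1_lands_on_chord(self, model):
        lo, hi = self.spec_interval
        spec = ExpCorrectionSpec(re_lo=lo, re_hi=hi, c1=1.0, c2=0.0)
        re = 70.0
        f_lo = decision_factor(40.0, lo, model)
        f_hi = decision_factor(40.0, hi, model)
        chord = f_lo + (f_hi - f_lo) * (re - lo) / (hi - lo)
        assert correct_exponential(40.0, re, model, spec) == pytest.approx(chord)

    def test_outside_interval_is_identity(self, model, caplog):
        spec = ExpCorrectionSpec(re_lo=64.0, re_hi=80.0, c1=0.5, c2=0.5)
        with caplog.at_level("INFO", logger="woundrisk.fusion"):
            value = correct_exponential(40.0, 30.0, model, spec)
        assert value == pytest.approx(decision_factor(40.0, 30.0, model))
        assert any("not applied" in r.message for r in caplog.records)

    def test_flat_function_with_d2_only_is_identity(self):
        # a model whose exponential branch is constant in RE: f1 = 1
        flat = DecisionFactorModel(exp_f1=(0.0, 1.0))
        spec = ExpCorrectionSpec(re_lo=20.0, re_hi=40.0, c1=0.0, c2=1.0)
        f = decision_factor(30.0, 30.0, flat)
        assert correct_exponential(30.0, 30.0, flat, spec) == pytest.approx(f)

    def test_even_weights_lie_between_f_and_chord(self, model):
        """Pointwise on a 100-point grid the correction sits in [f, g]."""
        lo, hi = self.spec_interval
        spec = ExpCorrectionSpec(re_lo=lo, re_hi=hi, c1=0.5, c2=0.5)
        f_lo = decision_factor(40.0, lo, model)
        f_hi = decision_factor(40.0, hi, model)
        for re in np.linspace(lo, hi, 100):
            f = decision_factor(40.0, float(re), model)
            g = f_lo + (f_hi - f_lo) * (re - lo) / (hi - lo)
            corrected = correct_exponential(40.0, float(re), model, spec)
            assert f - 1e-9 <= corrected <= g + 1e-9

    def test_logarithmic_zone_input_rejected(self, model):
        spec = ExpCorrectionSpec(re_lo=64.0, re_hi=80.0, c1=0.5, c2=0.5)
        with pytest.raises(ValueError):
            correct_exponential(60.0, 70.0, model, spec)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ExpCorrectionSpec(re_lo=64.0, re_hi=80.0, c1=0.7, c2=0.7)


class TestLogarithmicCorrection:
    def test_below_threshold_unchanged(self):
        # rt=60, rg=55: deviation 8.3% < 20%
        spec = LogCorrectionSpec(deviation_threshold=0.20, security=50.0)
        assert correct_logarithmic(60.0, 55.0, 14.0, spec) == 14.0

    def test_full_certainty_is_identity(self):
        spec = LogCorrectionSpec(security=100.0)
        assert correct_logarithmic(60.0, 30.0, 14.0, spec) == pytest.approx(14.0)

    def test_half_certainty_doubles_decision_factor(self):
        spec = LogCorrectionSpec(security=50.0)
        assert correct_logarithmic(60.0, 30.0, 14.0, spec) == pytest.approx(28.0)

    def test_zero_security_rejected(self):
        with pytest.raises(ValueError):
            LogCorrectionSpec(security=0.0)

    def test_exponential_zone_input_rejected(self):
        spec = LogCorrectionSpec(security=50.0)
        with pytest.raises(ValueError):
            correct_logarithmic(40.0, 20.0, 14.0, spec)


class TestSigmoidalCorrection:
    def _surface(self, model):
        return lambda rt, re: global_risk(rt, decision_factor(rt, re, model)).value

    def test_midpoint_is_average_of_endpoints(self, model, rng):
        surface = self._surface(model)
        for _ in range(10):
            rt1 = float(rng.uniform(25.0, 49.0))
            rt2 = float(rng.uniform(51.0, 75.0))
            re = float(rng.uniform(10.0, 100.0))
            spec = SigmoidCorrectionSpec(rt1=rt1, rt2=rt2, b=float(rng.uniform(0.1, 5.0)))
            mid = (rt1 + rt2) / 2.0
            expected = (surface(rt1, re) + surface(rt2, re)) / 2.0
            assert correct_sigmoidal(surface, spec, mid, re) == pytest.approx(expected)

    def test_steep_sigmoid_approaches_endpoint(self, model):
        surface = self._surface(model)
        spec = SigmoidCorrectionSpec(rt1=30.0, rt2=70.0, b=50.0)
        value = correct_sigmoidal(surface, spec, 70.0, 50.0)
        assert value == pytest.approx(surface(70.0, 50.0), abs=1e-6)

    def test_bounded_by_endpoint_values(self, model, rng):
        surface = self._surface(model)
        spec = SigmoidCorrectionSpec(rt1=25.0, rt2=75.0, b=0.8)
        for _ in range(20):
            rtj = float(rng.uniform(25.0, 75.0))
            re = float(rng.uniform(10.0, 100.0))
            lo, hi = sorted((surface(25.0, re), surface(75.0, re)))
            assert lo - 1e-9 <= correct_sigmoidal(surface, spec, rtj, re) <= hi + 1e-9

    def test_interval_limits_enforced(self):
        with pytest.raises(ValueError):
            SigmoidCorrectionSpec(rt1=20.0, rt2=70.0)
        with pytest.raises(ValueError):
            SigmoidCorrectionSpec(rt1=30.0, rt2=80.0)
        with pytest.raises(ValueError):
            SigmoidCorrectionSpec(rt1=30.0, rt2=70.0, b=0.0)

    def test_boundary_must_lie_inside_interval(self, model):
        surface = self._surface(model)
        spec = SigmoidCorrectionSpec(rt1=55.0, rt2=75.0)
        with pytest.raises(ValueError, match="boundary"):
            correct_sigmoidal(surface, spec, 60.0, 50.0)


class TestFuse:
    def test_worked_example_without_corrections(self, model):
        result = fuse(40.0, 70.0, model)
        assert result.df == pytest.approx(11.58, abs=5e-3)
        assert result.df_corrected == pytest.approx(result.df)
        assert result.rg == pytest.approx(46.31, abs=5e-3)
        assert result.rg_corrected == pytest.approx(result.rg)
        assert result.corrections_applied == ()

    def test_minimum_technical_risk_yields_rg_equal_df(self, model, rng):
        for re in rng.uniform(10.0, 100.0, 10):
            result = fuse(10.0, float(re), model)
            assert result.rg == pytest.approx(result.df_corrected)

    def test_disabled_corrections_match_bare_pipeline_on_grid(self, model):
        for rt in np.linspace(10, 100, 20):
            for re in np.linspace(10, 100, 20):
                result = fuse(float(rt), float(re), model)
                df = decision_factor(float(rt), float(re), model)
                assert result.df == pytest.approx(df)
                assert result.rg == pytest.approx(global_risk(float(rt), df).value)

    def test_applied_corrections_are_recorded(self, model):
        result = fuse(
            40.0,
            70.0,
            model,
            exp_correction=ExpCorrectionSpec(re_lo=64.0, re_hi=80.0, c1=1.0, c2=0.0),
            sigmoid_correction=SigmoidCorrectionSpec(rt1=30.0, rt2=70.0, b=1.0),
        )
        assert result.corrections_applied == ("exponential", "sigmoidal")
        assert result.df_corrected > result.df

    def test_security_correction_fires_only_beyond_threshold(self, model):
        spec = LogCorrectionSpec(deviation_threshold=0.20, security=50.0)
        # rt=95, re=15: rg well below rt -> correction fires and doubles DF
        fired = fuse(95.0, 15.0, model, log_correction=spec)
        assert "logarithmic" in fired.corrections_applied
        bare = fuse(95.0, 15.0, model)
        assert fired.df_corrected == pytest.approx(2.0 * bare.df_corrected)
        # rt=60, re=90: deviation small -> unchanged
        quiet = fuse(60.0, 90.0, model, log_correction=spec)
        assert quiet.corrections_applied == ()

    def test_rg_clamp_holds_with_security_correction(self, model):
        spec = LogCorrectionSpec(deviation_threshold=0.20, security=25.0)
        for rt in np.linspace(10, 100, 91):
            for re in np.linspace(10, 100, 16):
                result = fuse(float(rt), float(re), model, log_correction=spec)
                assert result.rg <= 100.0 + 1e-12
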