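import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnaip import (
    ModificationPenalty,
    RateScheme,
    RegulatoryGeometry,
    Step,
    apply_penalties,
    regulatory_positions,
    simulate_progress,
    step_processivity,
    total_amplitude,
)
from trnaip.kinetics import DegenerateStepError, identity_step_map, PARENT_ANALOG

from ._oracles import brute_force_amplitude, stochastic_unwinding_curve


class TestStepProcessivity:
    @pytest.mark.parametrize(
        "kU, kD, expected",
        [(10.0, 0.0, 1.0), (1.0, 1.0, 0.5), (3.0, 1.0, 0.75)],
    )
    def test_examples(self, kU, kD, expected):
        assert step_processivity(kU, kD) == pytest.approx(expected)

    def test_both_zero_raises(self):
        with pytest.raises(DegenerateStepError):
            step_processivity(0.0, 0.0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            step_processivity(-1.0, 1.0)


class TestTotalAmplitude:
    def test_two_step_product(self):
        # processivities 0.9 and 0.8
        scheme = RateScheme(k_act=1.0, steps=(Step(9.0, 1.0), Step(8.0, 2.0)))
        assert total_amplitude(scheme) == pytest.approx(0.72)

    def test_lossless_returns_baseline(self):
        scheme = RateScheme.uniform(10, 3.0, 0.0, k_act=0.5, baseline_amplitude=0.63)
        assert total_amplitude(scheme) == pytest.approx(0.63)

    def test_94_step_chain_against_brute_force(self):
        scheme = RateScheme.uniform(94, 50.0, 0.5, k_act=0.01)
        expected = brute_force_amplitude(scheme)
        assert expected == pytest.approx(0.3924559017904847, rel=1e-12)  # frozen oracle value
        assert total_amplitude(scheme) == pytest.approx(expected, rel=1e-12)

    def test_matches_progress_curve_asymptote(self, small_scheme):
        t_end = 50.0 / small_scheme.k_act
        curve = simulate_progress(small_scheme, [t_end])
        assert curve.fraction_unwound[-1] == pytest.approx(
            total_amplitude(small_scheme), abs=1e-6
        )


class TestSimulateProgress:
    def test_zero_time_is_zero(self, small_scheme):
        curve = simulate_progress(small_scheme, [0.0, 1.0])
        assert curve.fraction_unwound[0] == 0.0

    def test_negative_time_raises(self, small_scheme):
        with pytest.raises(ValueError):
            simulate_progress(small_scheme, [-1.0])

    def test_single_exponential_limit(self):
        # steps are fast and lossless, activation (0.01/s) is rate-limiting:
        # F(t) tracks 1 - exp(-0.01 t) within 1%
        scheme = RateScheme.uniform(10, 1000.0, 0.0, k_act=0.01)
        times = np.array([1.0, 10.0, 50.0, 100.0, 300.0, 700.0])
        curve = simulate_progress(scheme, times)
        analytic = 1.0 - np.exp(-0.01 * times)
        assert np.all(np.abs(curve.fraction_unwound - analytic) <= 0.01 * np.maximum(analytic, 1e-3))

    def test_single_branch_symmetry(self):
        # one step with kU = kD, everything else lossless: asymptote 0.5 x baseline
        steps = tuple(Step(5.0, 5.0) if i == 3 else Step(5.0, 0.0) for i in range(8))
        scheme = RateScheme(k_act=0.1, steps=steps, baseline_amplitude=0.8)
        curve = simulate_progress(scheme, [2000.0])
        assert curve.fraction_unwound[-1] == pytest.approx(0.4, abs=1e-6)

    def test_monotone_nondecreasing(self, small_scheme):
        curve = simulate_progress(small_scheme, np.linspace(0, 400, 40))
        assert np.all(np.diff(curve.fraction_unwound) >= -1e-12)

    def test_agrees_with_stochastic_oracle(self, rng):
        scheme = RateScheme.uniform(12, 2.0, 0.3, k_act=0.05, baseline_amplitude=0.8)
        times = [1.0, 5.0, 10.0, 30.0, 60.0, 120.0]
        frac, se = stochastic_unwinding_curve(scheme, times, 100_000, rng)
        curve = simulate_progress(scheme, times)
        assert np.all(np.abs(curve.fraction_unwound - frac) <= 3.0 * se)


class TestApplyPenalties:
    def test_empty_is_identity(self, small_scheme):
        assert apply_penalties(small_scheme, []) == small_scheme

    def test_parent_analog_is_identity(self, small_scheme):
        pen = ModificationPenalty(position=2, analog=PARENT_ANALOG)
        assert apply_penalties(small_scheme, [pen]) == small_scheme

    def test_parent_analog_rejects_factors(self):
        with pytest.raises(ValueError):
            ModificationPenalty(position=1, analog=PARENT_ANALOG, kD_factor=2.0)

    def test_kd_factor_on_high_processivity_step(self):
        # step with processivity 0.99 (kU=99, kD=1); 10x kD gives 99/109 by hand
        scheme = RateScheme(k_act=1.0, steps=(Step(99.0, 1.0),))
        out = apply_penalties(
            scheme, [ModificationPenalty(position=1, analog="2'-deoxy", kD_factor=10.0)]
        )
        assert step_processivity(out.steps[0].k_U, out.steps[0].k_D) == pytest.approx(
            99.0 / 109.0
        )
        assert total_amplitude(out) == pytest.approx(0.9082568807339449, rel=1e-12)

    def test_value_semantics(self, small_scheme):
        before = small_scheme.steps
        apply_penalties(
            small_scheme,
            [ModificationPenalty(position=1, analog="x", kU_factor=0.1)],
        )
        assert small_scheme.steps == before

    def test_penalties_combine_multiplicatively(self, small_scheme):
        pens = [
            ModificationPenalty(position=2, analog="a", kD_factor=2.0),
            ModificationPenalty(position=2, analog="b", kD_factor=3.0),
        ]
        out = apply_penalties(small_scheme, pens)
        assert out.steps[1].k_D == pytest.approx(small_scheme.steps[1].k_D * 6.0)

    def test_unmapped_position_raises_with_position(self, small_scheme):
        with pytest.raises(KeyError, match="99"):
            apply_penalties(
                small_scheme, [ModificationPenalty(position=99, analog="x", kD_factor=2.0)]
            )

    def test_shifted_origin_mapping(self, small_scheme):
        mapping = identity_step_map(small_scheme.n_steps, origin=25)
        pen = ModificationPenalty(position=26, analog="x", kD_factor=4.0)
        out = apply_penalties(small_scheme, [pen], position_to_step=mapping)
        assert out.steps[1].k_D == pytest.approx(small_scheme.steps[1].k_D * 4.0)


class TestRegulatoryGeometry:
    def test_arithmetic_progression(self):
        geo = RegulatoryGeometry(period=7, offset=4)
        assert regulatory_positions(geo, 25) == [4, 11, 18, 25]

    def test_period_one_hits_everything(self):
        geo = RegulatoryGeometry(period=1, offset=1)
        assert regulatory_positions(geo, 3) == [1, 2, 3]

    def test_default_spacing_is_seven(self):
        positions = regulatory_positions(RegulatoryGeometry(), 100)
        assert np.all(np.diff(positions) == 7)

    def test_offset_bounds(self):
        with pytest.raises(ValueError):
            RegulatoryGeometry(period=7, offset=8)


class TestSerialization:
    def test_scheme_round_trip(self, small_scheme):
        assert RateScheme.from_dict(small_scheme.to_dict()) == small_scheme

    def test_uniform_shorthand(self):
        scheme = RateScheme.from_dict(
            {"k_act": 0.02, "n_steps": 3, "kU": 5.0, "kD": 0.1}
        )
        assert scheme.n_steps == 3 and scheme.steps[0] == Step(5.0, 0.1)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            RateScheme.from_dict({"k_act": 1.0, "n_steps": 1, "kU": 1, "kD": 0, "bogus": 2})

    def test_geometry_round_trip(self):
        geo = RegulatoryGeometry(n_subunits=6, period=7, offset=3)
        assert RegulatoryGeometry.from_dict(geo.to_dict()) == geo


# ---------------------------------------------------------------------------
# property tests

_rates = st.floats(min_value=0.05, max_value=20.0, allow_nan=False)
_kds = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)


@st.composite
def schemes(draw, max_steps=6):
    n = draw(st.integers(min_value=1, max_value=max_steps))
    steps = tuple(Step(draw(_rates), draw(_kds)) for _ in range(n))
    return RateScheme(
        k_act=draw(st.floats(min_value=0.01, max_value=2.0)),
        steps=steps,
        baseline_amplitude=draw(st.floats(min_value=0.1, max_value=1.0)),
    )


@settings(max_examples=25, deadline=None)
@given(schemes())
def test_property_asymptote_matches_product(scheme):
    rates = [scheme.k_act] + [s.k_U + s.k_D for s in scheme.steps]
    t_end = 50.0 / min(rates)
    curve = simulate_progress(scheme, [t_end])
    assert abs(curve.fraction_unwound[-1] - total_amplitude(scheme)) < 1e-6


@settings(max_examples=25, deadline=None)
@given(schemes(), st.floats(min_value=1.0, max_value=50.0), st.data())
def test_property_kd_increase_never_raises_amplitude(scheme, factor, data):
    pos = data.draw(st.integers(min_value=1, max_value=scheme.n_steps))
    worse = apply_penalties(
        scheme, [ModificationPenalty(position=pos, analog="x", kD_factor=factor)]
    )
    assert total_amplitude(worse) <= total_amplitude(scheme) + 1e-12


@settings(max_examples=25, deadline=None)
@given(schemes(), st.floats(min_value=1.0, max_value=50.0), st.data())
def test_property_ku_increase_never_lowers_amplitude(scheme, factor, data):
    pos = data.draw(st.integers(min_value=1, max_value=scheme.n_steps))
    better = apply_penalties(
        scheme, [ModificationPenalty(position=pos, analog="x", kU_factor=factor)]
    )
    assert total_amplitude(better) >= total_amplitude(scheme) - 1e-12
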