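"""Positional labeling model: entry patterns, turn transition, secreted sums."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citrace.errors import CitraceError, UndefinedRatioError
from citrace.model import (
    TURN_TRANSITION,
    CitrateLabelState,
    ModelParams,
    TracerSpec,
    expected_turns,
    initial_label_pattern,
    r1_vs_d_curve,
    ratio_R1,
    ratio_R2,
    secreted_distribution,
    turn_transition,
)

from conftest import closed_form_secreted


class TestTracerSpec:
    def test_glucose_entry_positions(self):
        t = TracerSpec.glucose_1_6()
        assert t.pdc_entry_positions == {2}
        assert t.pc_entry_positions == {3, 4}

    def test_pyruvate_entry_positions(self):
        t = TracerSpec.pyruvate_2()
        assert t.pdc_entry_positions == {1}
        assert t.pc_entry_positions == {3, 4}

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_enrichment_bounds(self, bad):
        with pytest.raises(ValueError):
            TracerSpec.glucose_1_6(f_p=bad)

    def test_entry_positions_must_be_citrate_carbons(self):
        with pytest.raises(ValueError):
            TracerSpec("glucose_1_6", frozenset({7}), frozenset({3, 4}), 0.8, 0.56)


class TestModelParams:
    def test_d_zero_rejected_with_named_error(self):
        with pytest.raises(CitraceError, match="no secretion"):
            ModelParams(d=0.0, p=0.1)

    @pytest.mark.parametrize("d,p", [(1.2, 0.1), (0.5, 1.0), (0.5, -0.1)])
    def test_out_of_range_parameters(self, d, p):
        with pytest.raises(ValueError):
            ModelParams(d=d, p=p)


class TestInitialLabelPattern:
    def test_pdc_only_full_enrichment_pyruvate(self):
        """PDC-only [2-13C]pyruvate puts all label on citrate C1."""
        t = TracerSpec.pyruvate_2(f_p=1.0, f_a=1.0)
        c = initial_label_pattern(t, ModelParams(d=0.5, p=0.0))
        assert np.allclose(c.c, [1, 0, 0, 0, 0, 0])

    def test_glucose_mixed_entry_weights(self):
        """Placement arithmetic: (1-p)·f_a on C2, p·f_p/2 on C3 and C4."""
        t = TracerSpec.glucose_1_6(f_p=0.80, f_a=0.56)
        c = initial_label_pattern(t, ModelParams(d=0.5, p=0.21))
        assert c[2] == pytest.approx(0.79 * 0.56)   # 0.4424
        assert c[3] == pytest.approx(0.21 * 0.80 / 2)  # 0.084
        assert c[4] == pytest.approx(0.084)
        assert c[1] == c[5] == c[6] == 0.0

    def test_pc_only_scrambles_equally(self):
        t = TracerSpec.pyruvate_2(f_p=1.0, f_a=1.0)
        c = initial_label_pattern(t, ModelParams(d=0.5, p=0.999999))
        # p -> 1 limit: half on C3, half on C4
        assert c[3] == pytest.approx(0.5, abs=1e-5)
        assert c[4] == pytest.approx(0.5, abs=1e-5)

    def test_glutamine_rejected_by_engine(self):
        with pytest.raises(CitraceError, match="glucose_1_6, pyruvate_2"):
            initial_label_pattern(TracerSpec.glutamine_5(), ModelParams(d=0.5, p=0.0))


class TestTurnTransition:
    @pytest.mark.parametrize(
        "start,expected",
        [
            ((1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0.5, 0.5)),   # C1 -> C5/C6
            ((0, 0, 1, 0, 0, 0), (0, 0, 0.5, 0.5, 0, 0)),   # C3 re-scrambles
            ((0, 1, 0, 0, 0, 0), (0, 0, 0.5, 0.5, 0, 0)),   # C2 -> C3/C4
            ((0, 0, 0, 1, 0, 0), (0, 0, 0, 0, 0.5, 0.5)),   # C4 -> C5/C6
            ((0, 0, 0, 0, 1, 1), (0, 0, 0, 0, 0, 0)),       # C5/C6 lost as CO2
        ],
    )
    def test_carbon_fates(self, start, expected):
        out = turn_transition(CitrateLabelState(np.array(start, dtype=float)))
        assert np.allclose(out.c, expected)

    def test_columns_substochastic(self):
        """C1..C4 redistribute with weight exactly 1; C5/C6 map to zero."""
        sums = TURN_TRANSITION.sum(axis=0)
        assert np.allclose(sums[:4], 1.0)
        assert np.allclose(sums[4:], 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        u, v = rng.uniform(0, 0.5, 6), rng.uniform(0, 0.5, 6)
        left = turn_transition(CitrateLabelState(u + v)).c
        right = turn_transition(CitrateLabelState(u)).c + turn_transition(CitrateLabelState(v)).c
        assert np.allclose(left, right)


class TestSecretedDistribution:
    def test_everything_secreted_at_generation_zero(self):
        t = TracerSpec.pyruvate_2(f_p=1.0, f_a=1.0)
        s = secreted_distribution(t, ModelParams(d=1.0, p=0.0))
        assert np.allclose(s.s, [1, 0, 0, 0, 0, 0])

    def test_glucose_closed_form_values(self, glucose_tracer):
        """Frozen values from the independent geometric closed form."""
        s = secreted_distribution(glucose_tracer, ModelParams(d=0.79, p=0.21))
        assert s[2] == pytest.approx(0.3495, abs=2e-4)
        assert s[3] == pytest.approx(0.1151, abs=2e-4)
        assert s[4] == pytest.approx(0.1151, abs=2e-4)

    def test_zero_initial_label_gives_zero(self):
        t = TracerSpec.glucose_1_6(f_p=0.0, f_a=0.0)
        s = secreted_distribution(t, ModelParams(d=0.5, p=0.3))
        assert np.allclose(s.s, 0.0)

    @pytest.mark.parametrize("d", [0.05, 0.2, 0.5, 0.79, 1.0])
    @pytest.mark.parametrize("p", [0.0, 0.21, 0.5, 0.9])
    @pytest.mark.parametrize("tracer_name", ["glucose_1_6", "pyruvate_2"])
    def test_iterative_equals_closed_form(self, d, p, tracer_name):
        """Matrix iteration agrees with the hand-derived geometric sums."""
        tracer = (TracerSpec.glucose_1_6() if tracer_name == "glucose_1_6"
                  else TracerSpec.pyruvate_2())
        s = secreted_distribution(tracer, ModelParams(d=d, p=p))
        expected = closed_form_secreted(tracer, d, p)
        assert np.allclose(s.s, expected, atol=1e-10)

    def test_secretion_weights_normalize_and_truncation_is_tight(self):
        """The geometric secretion weights sum to 1, and truncating when the
        label increment drops below tol leaves a negligible tail."""
        for d in (0.05, 0.3, 0.79):
            # infinite geometric sum of the weights themselves
            assert d * sum((1 - d) ** k for k in range(5000)) == pytest.approx(1.0)
            tracer = TracerSpec.glucose_1_6(f_p=1.0, f_a=1.0)
            s = secreted_distribution(tracer, ModelParams(d=d, p=0.0))
            assert s.converged
            exhaustive = secreted_distribution(
                tracer, ModelParams(d=d, p=0.0, max_turns=2000, tol=1e-16)
            )
            assert np.allclose(s.s, exhaustive.s, atol=1e-10)

    @given(
        d=st.floats(0.05, 1.0),
        p=st.floats(0.0, 0.9),
        fp=st.floats(0.1, 1.0),
        fa=st.floats(0.1, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_scrambling_symmetry(self, d, p, fp, fa):
        """Complete OAA scrambling forces s3 = s4 and s5 = s6 exactly."""
        for tracer in (TracerSpec.glucose_1_6(f_p=fp, f_a=fa),
                       TracerSpec.pyruvate_2(f_p=fp, f_a=fa)):
            s = secreted_distribution(tracer, ModelParams(d=d, p=p))
            assert s[3] == s[4]
            assert s[5] == s[6]


class TestRatios:
    def test_r1_direct_arithmetic(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.array([0, 2, 1, 1, 0, 0.0]), 1, True)
        assert ratio_R1(dist) == pytest.approx(2 / 3)

    def test_r1_equal_labeling_is_half(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.array([0, 1, 1, 1, 0, 0.0]), 1, True)
        assert ratio_R1(dist) == pytest.approx(0.5)

    def test_r1_c2_only_is_one(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.array([0, 1, 0, 0, 0, 0.0]), 1, True)
        assert ratio_R1(dist) == 1.0

    def test_r1_undefined_when_c24_zero(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.zeros(6), 1, True)
        with pytest.raises(UndefinedRatioError):
            ratio_R1(dist)

    def test_r2_direct_arithmetic(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.array([5, 0, 1, 1, 0.2, 0.2]), 1, True)
        assert ratio_R2(dist) == pytest.approx(5.2)

    def test_r2_undefined_when_c3_zero(self):
        from citrace.model import SecretedDistribution
        dist = SecretedDistribution(np.array([1, 0, 0, 0, 0, 0.0]), 1, True)
        with pytest.raises(UndefinedRatioError, match="p = 0"):
            ratio_R2(dist)

    def test_forward_r2_near_published_value(self, pyruvate_tracer):
        """Forward model at the fitted LNCaP pair lands near R2 ~ 5.2-5.3."""
        s = secreted_distribution(pyruvate_tracer, ModelParams(d=0.79, p=0.21))
        assert 5.2 <= ratio_R2(s) <= 5.35


class TestExpectedTurns:
    @pytest.mark.parametrize("d,expected", [(1.0, 0.0), (0.5, 1.0), (0.79, 0.2658)])
    def test_geometric_mean(self, d, expected):
        assert expected_turns(d) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("d", [0.0, -0.5, 1.5])
    def test_domain(self, d):
        with pytest.raises(CitraceError):
            expected_turns(d)


class TestR1Curve:
    def test_pdc_only_limits(self, glucose_tracer):
        """With p=0, R1 climbs from 0.5 (d->0) to exactly 1 at d=1."""
        curve = dict(r1_vs_d_curve(0.0, glucose_tracer, np.array([1e-3, 1.0])))
        assert curve[1e-3] == pytest.approx(0.5, abs=0.005)
        assert curve[1.0] == 1.0

    def test_monotone_nondecreasing_for_pdc_only(self, glucose_tracer):
        grid = np.linspace(0.01, 1.0, 100)
        r1 = np.array([r for _, r in r1_vs_d_curve(0.0, glucose_tracer, grid)])
        assert (np.diff(r1) >= -1e-12).all()

    def test_pc_offset_at_small_d(self, glucose_tracer):
        """PC feeding C3 directly pushes small-d R1 below the 0.5 limit."""
        (_, r1_p), = r1_vs_d_curve(0.3, glucose_tracer, np.array([1e-3]))
        assert r1_p < 0.5

    def test_single_point_matches_generation_zero(self, glucose_tracer):
        (_, r1), = r1_vs_d_curve(0.21, glucose_tracer, np.array([1.0]))
        s0 = secreted_distribution(glucose_tracer, ModelParams(d=1.0, p=0.21))
        assert r1 == pytest.approx(ratio_R1(s0))

    def test_empty_grid_rejected(self, glucose_tracer):
        with pytest.raises(CitraceError, match="empty"):
            r1_vs_d_curve(0.0, glucose_tracer, np.array([]))
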