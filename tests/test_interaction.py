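"""Overlap, mortality, rejection and the combined emergence expectation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import igparasitoid as ig
from igparasitoid import (
    ExposureProtocol,
    InteractionParams,
    ModelSpec,
    available_hosts,
    expected_attacked,
    expected_emergence,
    host_mortality,
    overlap,
    scenario_projection,
)
from igparasitoid.interaction import combine_emergence
from igparasitoid.reference import POSTERIOR_MEANS, SELECTED_SPEC


class TestAvailableHosts:
    @pytest.mark.parametrize(
        "p,s,flag,expected",
        [(100, 0.15, True, 85.0), (77, 0.0, True, 77.0), (0, 0.3, True, 0.0), (100, 0.15, False, 100.0)],
    )
    def test_values(self, p, s, flag, expected):
        assert available_hosts(p, s, flag) == pytest.approx(expected)

    def test_rejects_bad_proportion(self):
        with pytest.raises(ValueError):
            available_hosts(10, 1.5, True)


class TestOverlap:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.5, 2.0), (1.0, 8.0), (0.75, 5.0), (0.0, 0.0), (0.25, 1.0)],
    )
    def test_interpolation_through_random_point(self, theta, expected):
        assert overlap(10.0, 8.0, 40.0, theta) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        p=st.floats(1.0, 200.0),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
        theta=st.floats(0.0, 1.0),
    )
    def test_always_within_frechet_bounds(self, p, f1, f2, theta):
        R1, R2 = f1 * p, f2 * p
        r12 = overlap(R1, R2, p, theta)
        assert max(0.0, R1 + R2 - p) - 1e-9 <= r12 <= min(R1, R2) + 1e-9

    def test_empty_pool_with_attacks_is_inconsistent(self):
        with pytest.raises(ValueError):
            overlap(1.0, 0.0, 0.0, 0.5)
        assert overlap(0.0, 0.0, 0.0, 0.5) == 0.0


class TestHostMortality:
    @pytest.mark.parametrize("m,n,expected", [(0.14, 1, 0.14), (0.14, 2, 0.2604), (0.0, 7, 0.0), (1.0, 1, 1.0)])
    def test_compounding(self, m, n, expected):
        assert host_mortality(m, n) == pytest.approx(expected)


class TestExpectedEmergence:
    def test_contested_hosts_split_by_win_probability(self):
        # 8 exclusive + 2 contested at even odds -> 9 expected for the first species
        e_first, e_second = combine_emergence(10.0, 5.0, 2.0, 0.5, 1.0, 1.0)
        assert e_first == pytest.approx(9.0)
        assert e_second == pytest.approx(4.0)

    def test_zero_density(self):
        fr, comp, inter = ig.build_params(SELECTED_SPEC, POSTERIOR_MEANS)
        assert expected_emergence(SELECTED_SPEC, fr, comp, inter, ExposureProtocol(1, 2, 0.0)) == (0.0, 0.0)

    def test_null_competition_reduces_to_random_even_split(self):
        spec = ModelSpec.from_string("FRII:NHD:M0:R0:Cabs")
        values = {"b_1": 0.3, "b_2": 0.2, "H_1": 0.02, "H_2": 0.05}
        fr, comp, inter = ig.build_params(spec, values)
        p = 60.0
        e1, e2 = expected_emergence(spec, fr, comp, inter, ExposureProtocol(1, 2, p))
        R1 = expected_attacked(fr[1], spec.fr_family, False, p)
        R2 = expected_attacked(fr[2], spec.fr_family, False, p)
        R12 = R1 * R2 / p
        assert e1 == pytest.approx(R1 - R12 + 0.5 * R12)
        assert e2 == pytest.approx(R2 - R12 + 0.5 * R12)

    def test_all_mechanisms_off_reduces_to_bare_responses(self):
        spec = ModelSpec.from_string("FRII:NHD:M0:R0:Cabs")
        values = {"b_1": 0.3, "b_2": 0.2, "H_1": 0.02, "H_2": 0.05}
        fr, comp, inter = ig.build_params(spec, values)
        for sp in (1, 2):
            e1, e2 = expected_emergence(spec, fr, comp, inter, ExposureProtocol(sp, None, 50.0))
            bare = expected_attacked(fr[sp], spec.fr_family, False, 50.0)
            assert (e1, e2)[sp - 1] == pytest.approx(bare)
            assert (e1, e2)[2 - sp] == 0.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.0, 150.0),
        b1=st.floats(0.01, 1.0),
        b2=st.floats(0.01, 1.0),
        theta=st.floats(0.0, 1.0),
        s=st.floats(0.0, 0.9),
        m=st.floats(0.0, 1.0),
        first=st.sampled_from([1, 2]),
    )
    def test_conservation_of_hosts(self, p, b1, b2, theta, s, m, first):
        """Emergences plus dead/empty hosts account for every host offered."""
        values = dict(POSTERIOR_MEANS)
        values.update({"b_1": b1, "b_2": b2, "theta_1": theta, "theta_2": theta, "s": s, "m": m})
        fr, comp, inter = ig.build_params(SELECTED_SPEC, values)
        e1, e2 = expected_emergence(SELECTED_SPEC, fr, comp, inter, ExposureProtocol(first, 3 - first, p))
        assert e1 >= -1e-9 and e2 >= -1e-9
        assert e1 + e2 <= p + 1e-9

    def test_emergence_never_exceeds_offered(self):
        fr, comp, inter = ig.build_params(SELECTED_SPEC, POSTERIOR_MEANS)
        for p in (0.0, 5.0, 50.0, 110.0):
            e1, e2 = expected_emergence(SELECTED_SPEC, fr, comp, inter, ExposureProtocol(1, 2, p))
            assert 0.0 <= e1 + e2 <= p + 1e-9


@pytest.fixture(scope="module")
def projection():
    fr, comp, inter = ig.build_params(SELECTED_SPEC, POSTERIOR_MEANS)
    return scenario_projection(SELECTED_SPEC, fr, comp, inter, range(10, 111, 10))


class TestScenarioProjection:

    def test_preference_lowers_total_below_random_reference(self, projection):
        """θ₂ = 0.8 > 0.5: releasing species 1 first, extra overlap cuts total emergence."""
        sub = projection[projection["order"] == "1->2"]
        totals = sub.groupby("density")[["expected", "reference"]].sum()
        assert (totals["expected"] <= totals["reference"] + 1e-9).all()

    def test_avoidance_raises_total_above_random_reference(self, projection):
        """θ₁ = 0.3 < 0.5: releasing species 2 first, avoidance spreads attacks."""
        sub = projection[projection["order"] == "2->1"]
        totals = sub.groupby("density")[["expected", "reference"]].sum()
        assert (totals["expected"] >= totals["reference"] - 1e-9).all()

    def test_random_indices_equal_reference_exactly(self):
        values = dict(POSTERIOR_MEANS, theta_1=0.5, theta_2=0.5)
        fr, comp, inter = ig.build_params(SELECTED_SPEC, values)
        table = scenario_projection(SELECTED_SPEC, fr, comp, inter, range(10, 111, 20))
        assert np.allclose(table["expected"], table["reference"])


class TestValidation:
    def test_interaction_params_bounds(self):
        with pytest.raises(ValueError):
            InteractionParams(theta1=1.2)
        with pytest.raises(ValueError):
            InteractionParams(m=-0.1)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ExposureProtocol(1, 1, 10)
        with pytest.raises(ValueError):
            ExposureProtocol(1, 2, -5)
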