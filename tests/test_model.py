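import numpy as np
import pytest

from herbcomp import (
    ModelParams,
    PopulationState,
    ResetEvent,
    ResetSchedule,
    classify_outcome,
    collapse_search,
    herbivory_benefit,
    invasion_analysis,
    isocline_species1,
    isocline_species2,
    logistic_solution,
    rhs,
    simulate,
)


def closed_logistic(n0, r, K, t):
    """Textbook logistic solution, independent oracle for the simulator."""
    return K / (1.0 + (K / n0 - 1.0) * np.exp(-r * t))


class TestRhs:
    def test_extinction_absorbing(self):
        p = ModelParams(r1=0.5, r2=0.5, a11=0.01, a22=0.01, a12=1, a21=1, beta1=1, beta2=1, Nh=3)
        assert rhs(PopulationState(0, 0, 0), p) == (0.0, 0.0)

    def test_carrying_capacity(self):
        p = ModelParams(r1=0.3, r2=1, a11=0.001, a22=1)
        d1, _ = rhs(PopulationState(0, 1000.0, 0.0), p)
        assert d1 == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # 0.2 * 100 * (1 - 0.1 - 0.1 - 0.1) = 14
        p = ModelParams(r1=0.2, r2=1, a11=0.001, a22=1, a12=0.0005, beta1=0.1, Nh=1)
        d1, _ = rhs(PopulationState(0, 100.0, 200.0), p)
        assert d1 == pytest.approx(14.0, abs=1e-12)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            PopulationState(0.0, np.inf, 1.0)


class TestLogisticSolution:
    def test_exponential_when_c_zero(self):
        assert logistic_solution(5.0, 0.3, 0.0, 7.0) == pytest.approx(5 * np.exp(2.1), rel=1e-12)

    def test_b_zero(self):
        # dN/dt = -c N^2 -> N = n0/(1 + c n0 t)
        assert logistic_solution(10.0, 0.0, 0.1, 3.0) == pytest.approx(10 / 4, rel=1e-12)

    def test_matches_textbook_logistic(self):
        r, a, n0, t = 0.4, 0.002, 30.0, 9.0
        assert logistic_solution(n0, r, r * a, t) == pytest.approx(
            closed_logistic(n0, r, 1 / a, t), rel=1e-12
        )

    def test_decay_large_time_safe(self):
        val = logistic_solution(100.0, -0.5, 0.001, 500.0)
        assert 0.0 <= val < 1e-50

    def test_growth_large_time_safe(self):
        assert logistic_solution(1.0, 1.0, 0.001, 1000.0) == pytest.approx(1000.0, rel=1e-9)

    def test_zero_initial(self):
        assert logistic_solution(0.0, 0.5, 0.001, 10.0) == 0.0

    def test_vectorized(self):
        out = logistic_solution(np.array([5.0, 50.0]), 0.3, 0.3 * 0.001, 7.0)
        assert out.shape == (2,)
        assert np.all(out > 0)


class TestSimulate:
    def test_logistic_limit(self):
        p = ModelParams(r1=0.4, r2=1, a11=0.002, a22=1, a12=0.5)
        traj = simulate(p, PopulationState(0, 50.0, 0.0), 200.0)
        assert traj.final.N1 == pytest.approx(1 / p.a11, rel=1e-6)
        assert np.all(traj.N2 == 0.0)

    def test_closed_form_logistic_oracle(self):
        p = ModelParams(r1=1, r2=0.6, a11=1, a22=0.004, a21=0.0)
        n0 = 0.5 / p.a22
        traj = simulate(p, PopulationState(0, 0.0, n0), 10.0)
        expected = closed_logistic(n0, p.r2, 1 / p.a22, traj.t)
        assert np.allclose(traj.N2, expected, rtol=1e-6)

    def test_overgrazed_species_decays(self):
        p = ModelParams(r1=0.5, r2=1, a11=0.001, a22=1, beta1=1.3, Nh=1)
        traj = simulate(p, PopulationState(0, 500.0, 0.0), 80.0)
        assert traj.final.N1 < 1e-4 * 500

    def test_nonnegative(self):
        p = ModelParams(r1=0.9, r2=0.8, a11=0.01, a22=0.02, a12=0.05, a21=0.03,
                        beta1=0.4, beta2=0.9, Nh=2)
        traj = simulate(p, PopulationState(0, 10.0, 10.0), 120.0)
        assert np.all(traj.N1 >= 0) and np.all(traj.N2 >= 0)

    def test_resets_applied(self):
        p = ModelParams(r1=0.3, r2=0.9, a11=0.001, a22=0.1, a12=0.07)
        sched = ResetSchedule.daily(2, 1.33, t_end=6.0)
        traj = simulate(p, PopulationState(0, 100.0, 1.33), 7.0,
                        schedule=sched, t_eval=np.arange(0, 7.5, 0.5))
        flagged = traj.t[traj.event_flag == 1]
        assert list(flagged) == [1, 2, 3, 4, 5, 6]
        assert np.allclose(traj.N2[traj.event_flag == 1], 1.33)
        assert len(traj.applied_events) == 6

    def test_reset_outside_span_rejected(self):
        p = ModelParams(r1=0.3, r2=0.9, a11=0.001, a22=0.1)
        with pytest.raises(ValueError, match="outside"):
            simulate(p, PopulationState(0, 10, 1), 5.0,
                     schedule=[ResetEvent(9.0, 2, 1.0)])

    def test_t_end_must_exceed_start(self):
        p = ModelParams(r1=0.3, r2=0.9, a11=0.001, a22=0.1)
        with pytest.raises(ValueError):
            simulate(p, PopulationState(2.0, 10, 1), 2.0)

    def test_species_at_zero_stays_zero(self):
        p = ModelParams(r1=0.3, r2=0.9, a11=0.001, a22=0.1)
        traj = simulate(p, PopulationState(0, 0.0, 5.0), 30.0)
        assert np.all(traj.N1 == 0.0)
        assert traj.final.N2 == pytest.approx(10.0, rel=1e-6)


class TestIsoclines:
    def test_axis_intercept(self):
        p = ModelParams(r1=1, r2=1, a11=0.004, a22=1)
        assert isocline_species1(p, [0.0])[0] == pytest.approx(250.0)

    def test_hand_value(self):
        p = ModelParams(r1=1, r2=1, a11=0.1, a22=1, a12=0.5)
        assert isocline_species1(p, [2.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_growth_on_isocline(self, rng):
        for _ in range(100):
            p = ModelParams(
                r1=rng.uniform(0.1, 1), r2=rng.uniform(0.1, 1),
                a11=10 ** rng.uniform(-3, 0), a22=10 ** rng.uniform(-3, 0),
                a12=10 ** rng.uniform(-4, -1), a21=10 ** rng.uniform(-4, -1),
                beta1=rng.uniform(0, 0.3), beta2=rng.uniform(0, 0.3),
                Nh=float(rng.integers(0, 3)),
            )
            n2 = rng.uniform(0, 1 / p.a22, 10)
            n1 = isocline_species1(p, n2)
            for x2, x1 in zip(n2, n1):
                if x1 > 0:
                    d1, _ = rhs(PopulationState(0, x1, x2), p)
                    assert abs(d1) < 1e-9 * p.r1 * x1
            n1g = rng.uniform(0, 1 / p.a11, 10)
            n2i = isocline_species2(p, n1g)
            for x1, x2 in zip(n1g, n2i):
                if x2 > 0:
                    _, d2 = rhs(PopulationState(0, x1, x2), p)
                    assert abs(d2) < 1e-9 * p.r2 * x2

    def test_symmetric_operation(self):
        p = ModelParams(r1=1, r2=1, a11=1, a22=0.2, a21=0.05, beta2=0.1, Nh=1)
        assert isocline_species2(p, [4.0])[0] == pytest.approx((1 - 0.2 - 0.1) / 0.2)


class TestInvasionAnalysis:
    def test_no_herbivore_neutral(self):
        p = ModelParams(r1=1, r2=1, a11=1, a22=0.5, a12=0.1, beta1=0.2, beta2=0.3, Nh=0)
        rep = invasion_analysis(p)
        assert rep.N2w == rep.N2wo == pytest.approx(2.0)
        assert rep.benefit == "neutral"
        assert rep.IGRw == rep.IGRwo

    def test_benefit_example(self):
        p = ModelParams(r1=0.5, r2=0.5, a11=0.001, a22=0.002, a12=0.004,
                        beta1=0.02, beta2=0.2, Nh=1)
        rep = invasion_analysis(p)
        assert rep.benefit == "benefit"
        assert rep.margin == pytest.approx(0.004 / 0.002 - 0.02 / 0.2)

    def test_boundary_neutral(self):
        # beta1/beta2 == a12/a22 exactly (power-of-two values) -> IGRw == IGRwo
        p = ModelParams(r1=0.5, r2=0.5, a11=0.001, a22=0.25, a12=0.5,
                        beta1=0.5, beta2=0.25, Nh=1)
        rep = invasion_analysis(p)
        assert rep.IGRw == pytest.approx(rep.IGRwo, abs=1e-14)
        assert rep.benefit == "neutral"

    def test_resident_collapse_flagged(self):
        p = ModelParams(r1=0.5, r2=0.5, a11=0.001, a22=0.01, a12=0.002,
                        beta1=0.1, beta2=0.8, Nh=2)
        rep = invasion_analysis(p)
        assert rep.resident_collapsed
        assert rep.N2w == 0.0
        assert rep.N2wo == pytest.approx(100.0)

    def test_beta2_zero_margin_undefined(self):
        p = ModelParams(r1=0.5, r2=0.5, a11=0.001, a22=0.01, a12=0.002,
                        beta1=0.1, beta2=0.0, Nh=1)
        rep = invasion_analysis(p)
        assert rep.margin is None and rep.margin_undefined
        assert rep.benefit == "harm"  # herbivore eats only the focal species


class TestHerbivoryBenefit:
    def test_focal_not_eaten(self):
        p = ModelParams(r1=1, r2=1, a11=1, a22=1, a12=0.5, beta1=0.0, beta2=0.4)
        assert herbivory_benefit(p).verdict == "benefit"

    def test_no_competition_to_relieve(self):
        p = ModelParams(r1=1, r2=1, a11=1, a22=1, a12=0.0, beta1=0.2, beta2=0.4)
        assert herbivory_benefit(p).verdict == "harm"

    def test_beta2_zero_flag(self):
        p = ModelParams(r1=1, r2=1, a11=1, a22=1, a12=0.5, beta1=0.2, beta2=0.0)
        v = herbivory_benefit(p)
        assert v.margin_undefined and v.margin is None
        assert v.verdict == "harm"

    def test_agrees_with_invasion_analysis(self, rng):
        # exhaustive equivalence in the regime where the resident persists
        for _ in range(1000):
            beta2 = rng.uniform(0.01, 0.9)
            nh = float(rng.integers(1, int(1 / beta2) + 1))
            p = ModelParams(
                r1=rng.uniform(0.1, 1), r2=rng.uniform(0.1, 1),
                a11=10 ** rng.uniform(-3, 0), a22=10 ** rng.uniform(-3, 0),
                a12=10 ** rng.uniform(-4, 0), beta1=rng.uniform(0, 1),
                beta2=beta2, Nh=nh,
            )
            assert herbivory_benefit(p).verdict == invasion_analysis(p).benefit

    def test_density_independent_of_unit_rescaling(self):
        # changing species-2 units rescales N2, a12 and a22 together
        p = ModelParams(r1=0.3, r2=0.9, a11=0.001, a22=0.1, a12=0.07,
                        beta1=0.6, beta2=1.1, Nh=1)
        for s in (0.01, 1.0, 250.0):
            q = p.replace(a12=p.a12 / s, a22=p.a22 / s)
            assert herbivory_benefit(q).verdict == herbivory_benefit(p).verdict
            assert herbivory_benefit(q).margin == pytest.approx(
                herbivory_benefit(p).margin
            )


class TestClassifyOutcome:
    def test_classic_coexistence(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, a12=0.01, a21=0.005, Nh=0)
        oc = classify_outcome(p)
        assert oc.label == "coexistence"
        assert oc.igr1 > 0 and oc.igr2 > 0

    def test_both_collapse(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, beta1=0.6, beta2=0.7, Nh=2)
        assert classify_outcome(p).label == "both_collapse"

    def test_species1_excludes(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, a12=0.01, a21=0.03, Nh=0)
        assert classify_outcome(p).label == "species1_excludes"

    def test_species2_excludes(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, a12=0.05, a21=0.005, Nh=0)
        assert classify_outcome(p).label == "species2_excludes"

    def test_founder_control(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, a12=0.05, a21=0.03, Nh=0)
        assert classify_outcome(p).label == "founder_control"

    def test_one_sided_collapse_not_both(self):
        # species 1 is overgrazed, species 2 persists
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, beta1=1.5, beta2=0.1, Nh=1)
        assert classify_outcome(p).label == "species2_excludes"


class TestCollapseSearch:
    def test_minimal_two(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, beta1=0.6, beta2=0.7)
        scan = collapse_search(p, 5)
        assert scan.minimal_nh == 2
        assert scan.outcomes[1].label != "both_collapse"
        assert scan.outcomes[2].label == "both_collapse"

    def test_none_found_when_inedible(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, beta1=0.0, beta2=0.0)
        scan = collapse_search(p, 10)
        assert scan.minimal_nh is None and not scan.found
        assert len(scan.outcomes) == 10

    def test_minimal_one(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02, beta1=1.1, beta2=1.2)
        assert collapse_search(p, 3).minimal_nh == 1

    def test_requires_positive_range(self):
        p = ModelParams(r1=1, r2=1, a11=0.01, a22=0.02)
        with pytest.raises(ValueError):
            collapse_search(p, 0)
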