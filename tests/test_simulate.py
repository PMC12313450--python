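import numpy as np
import pytest

from neopkpd import (
    DoseEvent,
    DoseSchedule,
    IndividualParameters,
    default_time_grid,
    ode_profile,
    simulate_profile,
)

from conftest import random_params, random_schedule


def single_dose(amount=50.0, duration=0.001):
    return DoseSchedule("s", [DoseEvent(0.0, amount, duration)])


class TestClosedForm:
    def test_near_bolus_matches_monoexponential_decay(self):
        """A 50 mg dose over 0.001 h into V=1 L with CL=0.2 L/h decays as
        50 exp(-0.2 t): C(10 h) = 6.77 mg/L."""
        p = IndividualParameters("s", cl=0.2, v=1.0)
        prof = simulate_profile(p, single_dose(), np.array([10.0]))
        assert prof.total[0] == pytest.approx(50 * np.exp(-2.0), rel=1e-3)
        assert prof.total[0] == pytest.approx(6.77, abs=0.01)

    def test_constant_infusion_reaches_rate_over_clearance(self):
        """C_ss = R0 / CL = 10 / 2 = 5 mg/L."""
        p = IndividualParameters("s", cl=2.0, v=1.0)
        sched = DoseSchedule("s", [DoseEvent(0.0, 10.0 * 2000, 2000.0)])
        prof = simulate_profile(p, sched, np.array([1500.0]))
        assert prof.total[0] == pytest.approx(5.0, rel=1e-9)

    def test_dose_linearity_to_machine_precision(self):
        rng = np.random.default_rng(4)
        p = random_params(rng, two_cpt=True)
        sched = random_schedule(rng)
        grid = default_time_grid()
        base = simulate_profile(p, sched, grid).total
        tripled = simulate_profile(p, sched.scaled(3.0), grid).total
        np.testing.assert_allclose(tripled, 3.0 * base, rtol=1e-12)

    def test_overlapping_infusions_add(self):
        p = IndividualParameters("s", cl=1.0, v=1.0)
        one = DoseSchedule("s", [DoseEvent(0.0, 24.0, 24.0)])
        two = DoseSchedule("s", [DoseEvent(0.0, 24.0, 24.0), DoseEvent(0.0, 24.0, 24.0)])
        grid = np.linspace(0, 24, 50)
        np.testing.assert_allclose(
            simulate_profile(p, two, grid).total, 2 * simulate_profile(p, one, grid).total
        )

    def test_two_compartment_collapses_to_one_as_q_vanishes(self):
        """With Q = 1e-6 L/h the peripheral compartment is unreachable: the
        biexponential solution matches the 1-compartment one within 0.5%."""
        grid = default_time_grid(24.0)
        sched = DoseSchedule("s", [DoseEvent(0.0, 50.0, 0.5), DoseEvent(12.0, 50.0, 0.5)])
        p1 = IndividualParameters("s", cl=0.3, v=1.2)
        p2 = IndividualParameters("s", cl=0.3, v=1.2, q=1e-6, v2=0.8)
        c1 = simulate_profile(p1, sched, grid).total
        c2 = simulate_profile(p2, sched, grid).total
        assert np.max(np.abs(c1 - c2)) / np.max(c1) < 0.005

    def test_negative_time_rejected(self):
        p = IndividualParameters("s", cl=0.2, v=1.0)
        with pytest.raises(ValueError, match="non-negative"):
            simulate_profile(p, single_dose(), np.array([-1.0, 5.0]))


class TestOdeOracleAgreement:
    @pytest.mark.parametrize("two_cpt", [False, True])
    def test_randomized_instances_agree_within_tenth_percent(self, two_cpt):
        rng = np.random.default_rng(11 if two_cpt else 10)
        grid = default_time_grid(48.0, 0.25)
        for _ in range(10):
            p = random_params(rng, two_cpt=two_cpt)
            sched = random_schedule(rng)
            a = simulate_profile(p, sched, grid).total
            o = ode_profile(p, sched, grid).total
            assert np.max(np.abs(a - o)) / np.max(o) < 1e-3

    def test_zero_doses_give_zero_profile(self):
        p = IndividualParameters("s", cl=0.2, v=1.0)
        prof = ode_profile(p, DoseSchedule("s", []), np.linspace(0, 48, 20))
        np.testing.assert_array_equal(prof.total, 0.0)


class TestBatchProfile:
    def test_matches_scalar_path_row_by_row(self):
        from neopkpd.simulate import batch_profile

        rng = np.random.default_rng(3)
        sched = random_schedule(rng)
        times = np.sort(rng.uniform(0, 48, 25))
        params = [random_params(rng, two_cpt=True) for _ in range(8)]
        batch = batch_profile(
            np.array([p.cl for p in params]),
            np.array([p.v for p in params]),
            sched,
            times,
            q=np.array([p.q for p in params]),
            v2=np.array([p.v2 for p in params]),
        )
        for i, p in enumerate(params):
            np.testing.assert_allclose(batch[i], simulate_profile(p, sched, times).total, rtol=1e-12)
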