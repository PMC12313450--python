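import numpy as np
import pytest

from neopkpd import (
    ConcentrationProfile,
    PkPdTarget,
    VirtualSubject,
    apply_protein_binding,
    binding_sensitivity,
    fraction_time_above,
    pta,
    pta_grid,
    toxicity_summary,
)
from neopkpd.exposure import ga_category

from conftest import random_params, random_schedule


def flat_profile(value, t_end=48.0, n=100):
    t = np.linspace(0, t_end, n)
    return apply_protein_binding(ConcentrationProfile("s", t, np.full(n, float(value))), 0.0)


def monoexp_profile(c0=50.0, k=0.2, t_end=48.0, step=0.05):
    t = np.arange(0, t_end + step / 2, step)
    return apply_protein_binding(ConcentrationProfile("s", t, c0 * np.exp(-k * t)), 0.0)


class TestProteinBinding:
    @pytest.mark.parametrize("bound,unbound", [(11.7, 88.3), (49.2, 50.8), (0.0, 100.0)])
    def test_unbound_fraction(self, bound, unbound):
        prof = apply_protein_binding(ConcentrationProfile("s", [0.0], [100.0]), bound)
        assert prof.unbound[0] == pytest.approx(unbound)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_protein_binding(ConcentrationProfile("s", [0.0], [1.0]), 100.0)


class TestFractionTimeAbove:
    def test_always_above_is_hundred(self):
        assert fraction_time_above(flat_profile(10), 1.0) == pytest.approx(100.0)

    def test_touching_threshold_counts_as_below(self):
        """Strict inequality: a profile sitting exactly at the threshold
        spends 0% of the window above it."""
        assert fraction_time_above(flat_profile(10), 10.0) == 0.0

    def test_monoexponential_crossing(self):
        """C(t) = 50 exp(-0.2 t) crosses 1 mg/L at ln(50)/0.2 = 19.56 h:
        81.5% of a 24-h window."""
        frac = fraction_time_above(monoexp_profile(), 1.0, window=(0.0, 24.0))
        assert frac == pytest.approx(100 * np.log(50) / 0.2 / 24, abs=0.05)
        assert frac == pytest.approx(81.5, abs=0.1)

    def test_agrees_with_dense_midpoint_oracle(self, demo_spec):
        """Crossing refinement on the production 0.05-h grid matches a 0.001-h
        midpoint-sampling oracle within 0.1 percentage points."""
        from neopkpd import simulate_profile

        rng = np.random.default_rng(12)
        coarse = np.arange(0, 48.0001, 0.05)
        dense = np.arange(0, 48.0005, 0.001)
        mid = 0.5 * (dense[:-1] + dense[1:])
        for _ in range(100):
            p = random_params(rng, two_cpt=bool(rng.integers(2)))
            sched = random_schedule(rng)
            prof = apply_protein_binding(simulate_profile(p, sched, coarse), 30.0)
            thr = float(rng.uniform(0.5, 30.0))
            got = fraction_time_above(prof, thr)
            dense_c = simulate_profile(p, sched, mid).total * 0.7
            want = 100.0 * np.mean(dense_c > thr)
            assert got == pytest.approx(want, abs=0.1)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fraction_time_above(flat_profile(10), 1.0, window=(5.0, 5.0))


class TestPta:
    def test_counting(self):
        profiles = [flat_profile(10)] * 9 + [flat_profile(0.1)]
        res = pta(profiles, PkPdTarget(mic=1.0, required_fraction=50.0), bound_pct=0.0)
        assert res.pta == pytest.approx(90.0)
        assert res.n_subjects == 10

    def test_permanently_above_four_mic_attains_everything(self):
        profiles = [flat_profile(100)] * 5
        for frac in (40.0, 70.0, 100.0):
            res = pta(profiles, PkPdTarget(mic=1.0, required_fraction=frac, mic_multiplier=4.0), 0.0)
            assert res.pta == 100.0

    def test_stricter_fraction_never_increases_pta(self, demo_spec):
        from neopkpd import simulate_profile

        rng = np.random.default_rng(21)
        grid = np.arange(0, 48.0001, 0.05)
        profiles = [
            simulate_profile(random_params(rng), random_schedule(rng), grid) for _ in range(30)
        ]
        loose = pta(profiles, PkPdTarget(mic=1.0, required_fraction=40.0), 20.0)
        strict = pta(profiles, PkPdTarget(mic=1.0, required_fraction=100.0), 20.0)
        assert strict.pta <= loose.pta


@pytest.fixture(scope="module")
def profiles():
    from neopkpd import simulate_profile

    rng = np.random.default_rng(31)
    grid = np.arange(0, 48.0001, 0.05)
    return [
        simulate_profile(random_params(rng), random_schedule(rng), grid) for _ in range(40)
    ]


class TestPtaGrid:
    def test_single_cell_reduces_to_pta(self, profiles):
        g = pta_grid(profiles, [0.5], [60.0], [1.0], bound_pct=15.0)
        single = pta(profiles, PkPdTarget(mic=0.5, required_fraction=60.0), 15.0)
        assert len(g) == 1
        assert g["pta"].iloc[0] == pytest.approx(single.pta)

    def test_monotone_in_mic_fraction_and_multiplier(self, profiles):
        g = pta_grid(profiles, [0.125, 0.25, 1.0], [40.0, 70.0, 100.0], [1.0, 4.0], 20.0)
        for (mult, frac), sub in g.groupby(["multiplier", "required_fraction"]):
            assert (np.diff(sub.sort_values("mic")["pta"]) <= 0).all()
        for (mic, mult), sub in g.groupby(["mic", "multiplier"]):
            assert (np.diff(sub.sort_values("required_fraction")["pta"]) <= 0).all()
        for (mic, frac), sub in g.groupby(["mic", "required_fraction"]):
            assert (np.diff(sub.sort_values("multiplier")["pta"]) <= 0).all()

    def test_monotone_in_bound_fraction(self, profiles):
        """More binding -> less unbound drug -> PTA cannot increase."""
        sweep = binding_sensitivity(profiles, [10.0, 30.0, 60.0], 30.0, [0.5], [60.0], [1.0])
        ptas = sweep.sort_values("bound_pct")["pta"].to_numpy()
        assert (np.diff(ptas) <= 0).all()

    def test_empty_grid_rejected(self, profiles):
        with pytest.raises(ValueError):
            pta_grid(profiles, [], [40.0], [1.0], 0.0)


class TestToxicity:
    def subjects(self):
        gas = [25.0, 30.0, 34.0, 40.0]
        return [VirtualSubject(f"s{i}", ga_weeks=ga, birth_weight=1.0) for i, ga in enumerate(gas)]

    def test_all_below_threshold_gives_zero_medians(self):
        profiles = [flat_profile(5)] * 4
        res = toxicity_summary(profiles, 110.0, self.subjects())
        assert set(res) == {
            "extremely_preterm", "very_preterm", "moderate_late_preterm", "full_term"
        }
        assert all(r.median == 0.0 for r in res.values())

    def test_median_of_mixed_exposures(self):
        t = np.linspace(0, 48, 1000)
        profiles = [
            ConcentrationProfile("a", t, np.where(t < 48 * f, 20.0, 1.0))
            for f in (0.0, 0.1, 0.2)
        ]
        subs = [VirtualSubject(s, ga_weeks=25.0, birth_weight=1.0) for s in "abc"]
        res = toxicity_summary(profiles, 10.0, subs)
        assert res["extremely_preterm"].median == pytest.approx(10.0, abs=0.1)

    def test_monotone_in_threshold(self):
        t = np.linspace(0, 48, 2000)
        profiles = [ConcentrationProfile("a", t, 100 * np.exp(-0.1 * t))]
        subs = [VirtualSubject("a", ga_weeks=40.0, birth_weight=3.0)]
        pct = [
            toxicity_summary(profiles, thr, subs)["full_term"].median for thr in (10, 50, 75)
        ]
        assert pct[0] >= pct[1] >= pct[2]


@pytest.mark.parametrize(
    "ga,label",
    [(24.0, "extremely_preterm"), (28.0, "very_preterm"), (36.9, "moderate_late_preterm"),
     (37.0, "full_term"), (42.0, "full_term")],
)
def test_prematurity_category_boundaries(ga, label):
    assert ga_category(ga) == label
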