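import copy
import math

import numpy as np
import pytest

from evbkit import (FreeEnergyProfile, HarmonicSurrogate, Schedule,
                    WindowSample, extract_barriers, ground_state_energy,
                    profile_pipeline, surrogate_window_samples, us_assemble,
                    zwanzig_increments)
from evbkit.constants import R_KCAL
from evbkit.errors import CoverageError, NoBarrierError, ValidationError

T = 298.15
BETA = 1.0 / (R_KCAL * T)


def make_window(lam, eps1, eps2, replica=0):
    return WindowSample(lam=lam, eps1=np.asarray(eps1, float),
                        eps2=np.asarray(eps2, float), n_equil=0,
                        temperature=T, dt=0.0, seed=0, replica=replica)


class TestZwanzig:
    def test_identical_states_give_zero(self):
        ws = [make_window(l, [5.0] * 10, [5.0] * 10)
              for l in (1.0, 0.5, 0.0)]
        m = zwanzig_increments(ws, T)
        assert np.allclose(m.dg, 0.0, atol=1e-14)
        assert np.allclose(m.dg_forward, m.dg_reverse, atol=1e-14)

    def test_constant_gap_gives_exact_linear_ramp(self):
        # e_{m+1} - e_m = dlam * X with X constant => increment exactly
        gap = 7.0
        lams = [1.0, 0.75, 0.5, 0.25, 0.0]
        ws = [make_window(l, [gap] * 8, [0.0] * 8) for l in lams]
        m = zwanzig_increments(ws, T)
        expected = [(l - 1.0) * gap for l in lams]
        assert np.allclose(m.dg, expected, atol=1e-12)
        assert m.hysteresis == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_increment_closed_form(self):
        # linear-response: dG = dlam*mean(X) - beta*dlam^2*var(X)/2
        rng = np.random.default_rng(14)
        mu, sigma, dlam = 12.0, 4.0, -0.02
        n = 40_000
        x1 = rng.normal(mu, sigma, n)
        x2 = rng.normal(mu, sigma, n)
        ws = [make_window(1.0, x1, np.zeros(n)),
              make_window(0.98, x2, np.zeros(n))]
        m = zwanzig_increments(ws, T)
        expected_fwd = dlam * mu - BETA * dlam**2 * sigma**2 / 2.0
        expected_rev = dlam * mu + BETA * dlam**2 * sigma**2 / 2.0
        se = abs(dlam) * sigma / math.sqrt(n)
        assert abs(m.dg_forward[-1] - expected_fwd) < 3 * se
        assert abs(m.dg_reverse[-1] - expected_rev) < 3 * se

    def test_exact_surrogate_mapping_free_energy(self, surrogate40,
                                                 surrogate_samples,
                                                 surrogate_mapping):
        # closed form: dG(lam) = L*lam*(1-lam) + (1-lam)*dG0
        for lam in (0.8, 0.5, 0.2, 0.0):
            exact = surrogate40.exact_mapping_free_energy(lam)
            assert surrogate_mapping.lookup(lam) == pytest.approx(
                exact, abs=0.05)

    def test_requires_two_windows(self):
        with pytest.raises(ValidationError):
            zwanzig_increments([make_window(1.0, [1.0], [0.0])], T)


class TestUsAssemble:
    def test_marcus_barrier_via_full_estimator(self, surrogate_samples,
                                               surrogate_mapping):
        prof = us_assemble(surrogate_samples, surrogate_mapping, 0.0, T,
                           bin_width=0.25)
        summ = extract_barriers(prof)
        tol = 3 * summ.se_activation
        assert abs(summ.dg_activation - 10.0) < tol
        assert abs(summ.x_ts) <= 0.25
        assert abs(summ.dg_reaction) < 3 * summ.se_reaction + 0.05

    def test_constant_coupling_lowers_crossing(self, surrogate40,
                                               surrogate_samples,
                                               surrogate_mapping):
        # exact adiabatic barrier from a 1-D scan of the ground state
        h = 4.0
        x = np.linspace(-2.0, surrogate40.d + 2.0, 20_001)
        e1, e2 = surrogate40.diabats(x)
        eg = ground_state_energy(e1, e2, h)
        mid = np.argmin(np.abs(x - surrogate40.crossing_x()))
        exact = (eg[mid - 2000:mid + 2000].max()
                 - eg[:mid].min())
        assert exact == pytest.approx(10.0 - h + h * h / 40.0, abs=0.05)
        prof = us_assemble(surrogate_samples, surrogate_mapping, h, T,
                           bin_width=0.5)
        summ = extract_barriers(prof)
        # within 3 SE of the exact value, and within the documented
        # O(h^2/L) band of the naive Marcus-minus-h estimate
        assert abs(summ.dg_activation - exact) < \
            3 * summ.se_activation + 0.1
        assert abs(summ.dg_activation - (10.0 - h)) < \
            3 * summ.se_activation + 2.0 * h * h / 40.0

    def test_coupling_monotonically_lowers_barrier(self, toy_samples,
                                                   toy_mapping):
        barriers = []
        for h in (0.0, 10.0, 20.0, 40.0):
            prof = us_assemble(toy_samples, toy_mapping, h, 300.0)
            barriers.append(extract_barriers(prof).dg_activation)
        assert all(a > b for a, b in zip(barriers, barriers[1:]))

    def test_bin_width_robustness(self, toy_samples, toy_mapping):
        b2 = extract_barriers(
            us_assemble(toy_samples, toy_mapping, 20.0, 300.0,
                        bin_width=2.0)).dg_activation
        b4 = extract_barriers(
            us_assemble(toy_samples, toy_mapping, 20.0, 300.0,
                        bin_width=4.0)).dg_activation
        assert abs(b2 - b4) < 0.2

    def test_min_count_filters_bins(self, surrogate_samples,
                                    surrogate_mapping):
        lo = us_assemble(surrogate_samples, surrogate_mapping, 0.0, T,
                         min_count=1)
        hi = us_assemble(surrogate_samples, surrogate_mapping, 0.0, T,
                         min_count=500)
        assert len(hi.x_centers) < len(lo.x_centers)
        assert hi.counts.min() >= 500

    def test_reactant_minimum_gauged_to_zero(self, surrogate_samples,
                                             surrogate_mapping):
        prof = us_assemble(surrogate_samples, surrogate_mapping, 0.0, T)
        summ = extract_barriers(prof)
        react = prof.x_centers < summ.x_ts
        assert prof.dg[react].min() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_windows_raise_coverage_error(self):
        ws = [make_window(1.0, np.full(30, -60.0), np.zeros(30)),
              make_window(0.0, np.full(30, +60.0), np.zeros(30))]
        m = zwanzig_increments(ws, T)
        with pytest.raises(CoverageError):
            us_assemble(ws, m, 0.0, T)


class TestExtractBarriers:
    def test_reference_row_as_synthetic_profile(self):
        prof = FreeEnergyProfile(
            x_centers=np.array([-50.0, 0.0, 50.0]),
            dg=np.array([0.0, 30.60, 19.18]),
            counts=np.array([100, 100, 100]),
            se=np.array([0.1, 0.1, 0.1]))
        s = extract_barriers(prof)
        assert s.dg_activation == pytest.approx(30.60)
        assert s.dg_reaction == pytest.approx(19.18)
        assert (s.x_reactant, s.x_ts, s.x_product) == (-50.0, 0.0, 50.0)

    def test_symmetric_double_well(self):
        x = np.linspace(-10, 10, 21)
        dg = 5.0 - 0.05 * x**2 + 0.0005 * x**4  # two wells, max at 0
        prof = FreeEnergyProfile(x_centers=x, dg=dg - dg.min(),
                                 counts=np.full(21, 100),
                                 se=np.full(21, 0.1))
        s = extract_barriers(prof)
        assert s.dg_reaction == pytest.approx(0.0, abs=1e-12)
        assert s.x_ts == 0.0

    def test_monotone_profile_raises(self):
        prof = FreeEnergyProfile(
            x_centers=np.arange(5.0), dg=np.arange(5.0) * 2.0,
            counts=np.full(5, 50), se=np.full(5, 0.1))
        with pytest.raises(NoBarrierError):
            extract_barriers(prof)


class TestPipeline:
    def test_deterministic_summary(self, toy_system):
        sched = Schedule(lambdas=np.linspace(0, 1, 11), replicas=2,
                         n_steps=2500, n_equil_init=2500, friction=5e-3)
        _, a = profile_pipeline(toy_system, sched, seed=4,
                                bin_width=4.0, min_count=10)
        _, b = profile_pipeline(toy_system, sched, seed=4,
                                bin_width=4.0, min_count=10)
        assert a == b

    def test_gauge_invariance_of_barriers(self, toy_system, small_schedule):
        # shifting both diabats by a constant leaves the profile unchanged
        shifted = copy.deepcopy(toy_system)
        shifted.state1.shift += 7.3
        shifted.state2.shift += 7.3
        p1, s1 = profile_pipeline(toy_system, small_schedule, seed=31)
        p2, s2 = profile_pipeline(shifted, small_schedule, seed=31)
        assert s1.dg_activation == pytest.approx(s2.dg_activation,
                                                 abs=1e-9)
        assert s1.dg_reaction == pytest.approx(s2.dg_reaction, abs=1e-9)
        assert np.allclose(p1.dg, p2.dg, atol=1e-9)

    def test_schedule_density_robustness(self, toy_system, small_schedule):
        p21, s21 = profile_pipeline(toy_system, small_schedule, seed=99)
        sparse = Schedule(lambdas=np.linspace(0, 1, 11), replicas=3,
                          n_steps=4000, friction=5e-3)
        _, s11 = profile_pipeline(toy_system, sparse, seed=99)
        pooled = math.hypot(s21.se_activation, s11.se_activation)
        assert abs(s21.dg_activation - s11.dg_activation) < 3 * pooled + 0.3

    def test_direction_robustness(self, toy_system, small_schedule):
        # monotone chains start cold at the product endpoint, so they get
        # longer windows and a larger equilibration discard
        bi = Schedule(lambdas=small_schedule.lambdas, replicas=3,
                      n_steps=10_000, friction=5e-3)
        mono = Schedule(lambdas=small_schedule.lambdas, direction="monotone",
                        replicas=3, n_steps=10_000, friction=5e-3,
                        equil_fraction=0.5)
        _, s_bi = profile_pipeline(toy_system, bi, seed=99)
        _, s_mono = profile_pipeline(toy_system, mono, seed=99)
        pooled = math.hypot(s_bi.se_activation, s_mono.se_activation)
        assert abs(s_bi.dg_activation - s_mono.dg_activation) < \
            3 * pooled + 0.3

    def test_surrogate_end_to_end_marcus(self, surrogate_samples,
                                         surrogate_mapping):
        # composition contract exercised via the surrogate's stages
        prof = us_assemble(surrogate_samples, surrogate_mapping, 0.0, T,
                           bin_width=0.25)
        summ = extract_barriers(prof)
        assert summ.dg_activation == pytest.approx(10.0, abs=0.15)

    def test_profile_tsv_round_trip(self, toy_samples, toy_mapping,
                                    tmp_path):
        prof = us_assemble(toy_samples, toy_mapping, 20.0, 300.0)
        path = tmp_path / "profile.tsv"
        prof.to_tsv(path)
        back = FreeEnergyProfile.from_tsv(path)
        assert np.allclose(back.x_centers, prof.x_centers)
        assert np.allclose(back.dg, prof.dg, atol=1e-7)
        assert back.metadata["h_ij_kcal"] == 20.0
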