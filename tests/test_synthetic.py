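import hashlib
import math

import numpy as np
import pytest
from scipy import stats

from evbkit import (HarmonicSurrogate, ToySpec, build_toy_system,
                    surrogate_window_samples, write_fixture)
from evbkit.constants import R_KCAL
from evbkit.errors import IOFailure, ValidationError
from evbkit.synthetic import (FIXTURE_SEED, read_window_tsv, read_windows,
                              realized_reorganization, write_window_tsv)


class TestToySpec:
    @pytest.mark.parametrize("lam_target,n_b,k_b",
                             [(40.0, 10, 2.0), (12.5, 3, 0.7),
                              (95.0, 25, 4.0)])
    def test_reorganization_realized_exactly(self, lam_target, n_b, k_b):
        spec = ToySpec(reorganization=lam_target, n_bath=n_b, k_bath=k_b)
        # generator's own bookkeeping: sum of 1/2 k d_i^2 over oscillators
        disp = spec.bath_displacements()
        assert disp.shape == (n_b, 3)
        realized = 0.5 * k_b * float(np.sum(disp * disp))
        assert realized == pytest.approx(lam_target, rel=1e-9)
        assert realized_reorganization(spec) == pytest.approx(
            lam_target, rel=1e-6)

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            ToySpec(reorganization=-1.0)
        with pytest.raises(ValidationError):
            ToySpec(n_bath=0)
        with pytest.raises(ValidationError):
            ToySpec(k_bath=0.0)


class TestBuildToySystem:
    def test_bond_topology(self, toy_system):
        iC = toy_system.role_index("donor-C")
        iH = toy_system.role_index("hydride-H")
        iN = toy_system.role_index("acceptor-N")
        s1_pairs = {tuple(sorted(t[:2])) for t in
                    toy_system.state1.morse_terms}
        s2_pairs = {tuple(sorted(t[:2])) for t in
                    toy_system.state2.morse_terms}
        assert s1_pairs == {tuple(sorted((iC, iH)))}
        assert s2_pairs == {tuple(sorted((iH, iN)))}

    def test_installed_parameters(self):
        spec = ToySpec(alpha=22.5, h_ij=17.0)
        sys = build_toy_system(spec)
        assert sys.h_ij == 17.0
        assert sys.state2.shift == 22.5
        assert sys.state1.shift == 0.0

    def test_deterministic_for_fixed_spec(self):
        a = build_toy_system(ToySpec())
        b = build_toy_system(ToySpec())
        assert a.to_dict() == b.to_dict()

    def test_bath_count(self):
        sys = build_toy_system(ToySpec(n_bath=7))
        assert sys.n_particles == 10
        assert sum(p.role == "bath" for p in sys.particles) == 7


class TestHarmonicSurrogate:
    def test_marcus_crossing_closed_form(self):
        # with h_ij = 0 the diabatic crossing height is (L+dG0)^2/(4L)
        for lam, dg0 in [(40.0, 0.0), (40.0, 10.0), (25.0, -5.0)]:
            s = HarmonicSurrogate.from_reorganization(lam, dg0=dg0)
            xc = s.crossing_x()
            e1, e2 = s.diabats(xc)
            assert e1 == pytest.approx(e2, abs=1e-9)
            assert e1 == pytest.approx((lam + dg0) ** 2 / (4 * lam),
                                       rel=1e-12)

    def test_implied_reorganization(self):
        s = HarmonicSurrogate(k=2.0, d=math.sqrt(40.0))
        assert s.reorganization == pytest.approx(40.0, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValidationError):
            HarmonicSurrogate(k=-1.0)
        with pytest.raises(ValidationError):
            HarmonicSurrogate.from_reorganization(0.0)


class TestSurrogateSampling:
    def test_zero_temperature_limit(self, surrogate40):
        ws = surrogate_window_samples(surrogate40, [0.0, 0.3, 1.0], 50,
                                      1e-6, seed=4)
        for w in ws:
            x_mean = surrogate40.window_mean(w.lam)
            e1, e2 = surrogate40.diabats(x_mean)
            assert np.allclose(w.eps1, e1, atol=1e-3)
            assert np.allclose(w.eps2, e2, atol=1e-3)

    def test_gap_variance_closed_form(self, surrogate40):
        T = 298.15
        n = 6000
        (w,) = surrogate_window_samples(surrogate40, [0.5], n, T, seed=8)
        var = np.var(w.gap, ddof=1)
        expected = surrogate40.window_gap_variance(T)
        assert expected == pytest.approx(2 * 40.0 * R_KCAL * T, rel=1e-12)
        se = expected * math.sqrt(2.0 / (n - 1))
        assert abs(var - expected) < 3 * se

    def test_determinism(self, surrogate40):
        a = surrogate_window_samples(surrogate40, [0.2, 0.8], 100, 300.0,
                                     seed=5)
        b = surrogate_window_samples(surrogate40, [0.2, 0.8], 100, 300.0,
                                     seed=5)
        c = surrogate_window_samples(surrogate40, [0.2, 0.8], 100, 300.0,
                                     seed=6)
        for x, y in zip(a, b):
            assert np.array_equal(x.eps1, y.eps1)
            assert np.array_equal(x.eps2, y.eps2)
        assert not np.array_equal(a[0].eps1, c[0].eps1)

    def test_adding_windows_keeps_existing_draws(self, surrogate40):
        a = surrogate_window_samples(surrogate40, [0.25, 0.75], 64, 300.0,
                                     seed=9)
        b = surrogate_window_samples(surrogate40, [0.25, 0.5, 0.75], 64,
                                     300.0, seed=9)
        assert np.array_equal(a[0].eps1, b[0].eps1)
        assert np.array_equal(a[1].eps1, b[2].eps1)

    def test_window_normality(self, surrogate40):
        # linear response: the sampled gap is Gaussian within each window;
        # documented check: D'Agostino-Pearson at alpha = 1e-3, n >= 1e3
        (w,) = surrogate_window_samples(surrogate40, [0.4], 2000, 298.15,
                                        seed=12)
        _, p = stats.normaltest(w.gap)
        assert p > 1e-3


class TestToyGapStatistics:
    def test_gap_near_gaussian_in_windows(self, toy_samples):
        # excess kurtosis bounded at default parameters
        mids = [s for s in toy_samples
                if 0.2 <= s.lam <= 0.8 and s.replica == 0]
        pooled_kurt = [stats.kurtosis(s.gap) for s in mids]
        assert np.median(np.abs(pooled_kurt)) < 0.5


class TestWindowIO:
    def test_round_trip(self, surrogate40, tmp_path):
        (w,) = surrogate_window_samples(surrogate40, [0.62], 40, 310.0,
                                        seed=2, replicas=1)
        path = tmp_path / "win.tsv"
        write_window_tsv(w, path)
        r = read_window_tsv(path)
        assert r.lam == w.lam
        assert r.temperature == 310.0
        assert np.allclose(r.eps1, w.eps1, atol=1e-9)
        assert np.allclose(r.eps2, w.eps2, atol=1e-9)

    def test_fixture_directory_layout(self, surrogate40, tmp_path):
        ws = surrogate_window_samples(surrogate40, [0.0, 0.5, 1.0], 10,
                                      300.0, seed=3, replicas=2)
        files = write_fixture(ws, tmp_path / "fx")
        names = sorted(f.name for f in files)
        assert names == ["win_000_rep0.tsv", "win_000_rep1.tsv",
                         "win_001_rep0.tsv", "win_001_rep1.tsv",
                         "win_002_rep0.tsv", "win_002_rep1.tsv"]
        back = read_windows(tmp_path / "fx")
        assert len(back) == 6

    def test_empty_fixture_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_fixture([], tmp_path / "empty")
        assert not (tmp_path / "empty").exists()

    def test_regeneration_digest(self, surrogate40, tmp_path):
        def digest(d):
            ws = surrogate_window_samples(surrogate40, [0.0, 1.0], 25,
                                          300.0, seed=FIXTURE_SEED)
            (f1, f2) = write_fixture(ws, d)
            h = hashlib.sha256()
            h.update(f1.read_bytes())
            h.update(f2.read_bytes())
            return h.hexdigest()

        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_malformed_row_has_context(self, tmp_path):
        p = tmp_path / "win_000_rep0.tsv"
        p.write_text("frame\tlambda\teps1_kcal\teps2_kcal\n0\t0.5\t1.0\n")
        with pytest.raises(IOFailure, match=r"win_000_rep0\.tsv:2"):
            read_window_tsv(p)

    def test_missing_directory_and_empty_dir(self, tmp_path):
        with pytest.raises(IOFailure):
            read_windows(tmp_path / "nope")
        (tmp_path / "empty").mkdir()
        with pytest.raises(IOFailure):
            read_windows(tmp_path / "empty")
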