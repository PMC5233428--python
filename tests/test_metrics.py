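"""fODF reconstruction, peak matching, and the scalar indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import irlfod as F
from irlfod.metrics import MATCH_ANGLE_CAP
from irlfod.phantom import crossing_directions


def delta_coeffs(basis, *atoms, iso=0.0):
    c = np.zeros(basis.n_atoms + 1)
    for a in atoms:
        c[a] = 1.0
    c[-1] = iso
    return c


class TestReconstructFodf:
    def test_pure_iso_coefficient(self, basis, render):
        c = delta_coeffs(basis, iso=1.0)
        f = F.reconstruct_fodf(c, basis, render)
        assert np.allclose(f.values, 0.0)
        assert f.f_iso == pytest.approx(basis.iso_scale)

    def test_single_atom_argmax(self, basis, render):
        atom = 42
        f = F.reconstruct_fodf(delta_coeffs(basis, atom), basis, render)
        best = render.vertices[np.argmax(f.values)]
        ang = F.angle_between_lines(best, basis.atom_directions[atom])
        assert ang <= 4.0   # within one render vertex spacing

    def test_zero_coefficients(self, basis, render):
        f = F.reconstruct_fodf(np.zeros(basis.n_atoms + 1), basis, render)
        assert np.all(f.values == 0.0)
        assert f.f_iso == 0.0

    def test_wrong_length_rejected(self, basis, render):
        with pytest.raises(ValueError):
            F.reconstruct_fodf(np.zeros(5), basis, render)


class TestExtractPeaks:
    def test_single_atom_single_peak(self, basis, render):
        f = F.reconstruct_fodf(delta_coeffs(basis, 42), basis, render)
        pk = F.extract_peaks(f, render)
        assert pk.n_peaks == 1
        assert F.angle_between_lines(pk.directions[0],
                                     basis.atom_directions[42]) <= 4.0

    def test_two_orthogonal_atoms_two_peaks(self, basis, render):
        pair = np.argwhere(np.abs(
            basis.atom_directions @ basis.atom_directions.T) < 1e-3)[0]
        f = F.reconstruct_fodf(delta_coeffs(basis, *pair), basis, render)
        pk = F.extract_peaks(f, render)
        assert pk.n_peaks == 2
        assert list(pk.amplitudes) == sorted(pk.amplitudes, reverse=True)

    def test_constant_fodf_no_peaks(self, render):
        f = F.FODF(values=np.ones(len(render)), f_iso=0.0)
        assert F.extract_peaks(f, render).n_peaks == 0

    def test_min_separation_suppression(self, basis, render):
        # two atoms ~8 deg apart merge under the 25 deg suppression radius
        nbr = basis.phi[:, 42]
        second = int(np.argsort(-nbr)[1])
        f = F.reconstruct_fodf(delta_coeffs(basis, 42, second), basis, render)
        assert F.extract_peaks(f, render).n_peaks == 1


class TestMatchPeaks:
    truth70 = crossing_directions(70.0)

    def test_exact_match(self):
        est = F.PeakSet(self.truth70.copy(), np.array([1.0, 0.9]))
        pairs, m_plus, m_minus = F.match_peaks(est, self.truth70, 70.0)
        assert len(pairs) == 2 and m_plus == 0 and m_minus == 0
        assert all(p[2] == pytest.approx(0.0, abs=1e-9) for p in pairs)

    def test_cap_at_35_degrees(self):
        # 36 deg away exceeds the cap even when crossing_angle/2 = 45
        truth = np.array([[1.0, 0.0, 0.0]])
        th = np.radians(36.0)
        est = F.PeakSet(np.array([[np.cos(th), np.sin(th), 0.0]]),
                        np.array([1.0]))
        pairs, m_plus, m_minus = F.match_peaks(est, truth, 90.0)
        assert pairs == [] and m_plus == 1 and m_minus == 1

    def test_half_crossing_angle_limit(self):
        # at a 40 deg crossing the limit is 20 deg, so a 25 deg error fails
        truth = np.array([[1.0, 0.0, 0.0]])
        th = np.radians(25.0)
        est = F.PeakSet(np.array([[np.cos(th), np.sin(th), 0.0]]),
                        np.array([1.0]))
        pairs, _, _ = F.match_peaks(est, truth, 40.0)
        assert pairs == []
        pairs, _, _ = F.match_peaks(est, truth, 60.0)
        assert len(pairs) == 1

    def test_extra_peak_counting(self):
        est_dirs = np.vstack([self.truth70,
                              crossing_directions(50.0)[:1]])
        est = F.PeakSet(est_dirs, np.array([1.0, 0.9, 0.2]))
        pairs, m_plus, m_minus = F.match_peaks(est, self.truth70, 70.0)
        assert len(pairs) == 2 and m_plus == 1 and m_minus == 0


class TestAae:
    def test_exact_is_zero(self):
        assert F.aae([[(0, 0, 0.0)], [(0, 0, 0.0)]]) == 0.0

    def test_single_pair(self):
        assert F.aae([[(0, 0, 10.0)]]) == pytest.approx(10.0)

    def test_per_voxel_then_region_mean(self):
        voxel_a = [(0, 0, 4.0), (1, 1, 6.0)]    # per-voxel mean 5
        voxel_b = [(0, 0, 15.0)]                # per-voxel mean 15
        assert F.aae([voxel_a, voxel_b]) == pytest.approx(10.0)

    def test_no_matches_is_nan(self):
        assert np.isnan(F.aae([[], []]))

    def test_sign_flip_invariance(self, rng):
        a = rng.standard_normal(3)
        b = rng.standard_normal(3)
        est = F.PeakSet(np.array([a / np.linalg.norm(a)]), np.array([1.0]))
        p1, _, _ = F.match_peaks(est, b[None, :], 90.0)
        est2 = F.PeakSet(-est.directions, est.amplitudes)
        p2, _, _ = F.match_peaks(est2, -b[None, :], 90.0)
        assert [round(p[2], 9) for p in p1] == [round(p[2], 9) for p in p2]


class TestFalsePeakRates:
    def test_perfect_detection(self):
        assert F.false_peak_rates([0, 0], [0, 0]) == (0.0, 0.0)

    def test_one_extra(self):
        r_plus, r_minus = F.false_peak_rates([1], [0])
        assert r_plus == 100.0 and r_minus == 0.0

    def test_one_missed(self):
        r_plus, r_minus = F.false_peak_rates([0], [1])
        assert r_plus == 0.0 and r_minus == 100.0

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            F.false_peak_rates([], [])


class TestScalarIndices:
    @pytest.mark.parametrize("evals,expected", [
        ((1.0, 1.0, 1.0), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
        ((1.7e-3, 0.2e-3, 0.2e-3), 0.8704),
    ])
    def test_fa(self, evals, expected):
        assert F.fa(evals) == pytest.approx(expected, abs=1e-4)

    def test_fa_degenerate(self):
        assert np.isnan(F.fa((0.0, 0.0, 0.0)))

    def test_fa_scale_invariant(self, rng):
        lam = rng.uniform(0.1, 1.0, 3)
        assert F.fa(lam) == pytest.approx(F.fa(10.0 * lam))

    def test_gfa_constant(self):
        assert F.gfa(np.full(100, 0.7)) == pytest.approx(0.0)

    def test_gfa_one_hot(self):
        f = np.zeros(50)
        f[7] = 3.1
        assert F.gfa(f) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_gfa_bounded(self, seed):
        f = np.random.default_rng(seed).uniform(0, 1, 30)
        if f.any():
            assert 0.0 <= F.gfa(f) <= 1.0 + 1e-12

    def test_gra_constant(self):
        assert F.gra(np.full(10, 2.0)) == pytest.approx(0.0)

    def test_gra_two_point(self):
        assert F.gra(np.array([2.0, 0.0])) == pytest.approx(1.0)

    def test_gra_scale_invariant(self, rng):
        f = rng.uniform(0.1, 1.0, 40)
        assert F.gra(f) == pytest.approx(F.gra(7.3 * f))

    @pytest.mark.parametrize("c,expected", [
        (np.array([0.0, 0.0, 1.0]), 1.0),
        (np.array([0.4, 0.6, 0.0]), 0.0),
        (np.array([0.3, 0.7, 1.0]), 0.5),
    ])
    def test_p_iso(self, c, expected):
        assert F.p_iso(c) == pytest.approx(expected)

    def test_p_iso_zero_coeffs(self):
        assert np.isnan(F.p_iso(np.zeros(5)))


class TestSweepEvaluation:
    def test_sweep_rows_and_determinism(self, gtab, operator, basis, render,
                                        tmp_path):
        angles = [60.0, 90.0]
        series = F.make_angle_series(angles, iso_fraction=0.3, snr=1e12,
                                     n_reps=4, seed=5, gtab=gtab)
        cfg = F.SolverConfig(max_iter=100)
        fits = [F.fit_field(vol, gtab, operator, cfg) for _, vol, _ in series]
        t1 = F.evaluate_sweep(series, fits, basis, render,
                              csv_path=tmp_path / "a.csv")
        t2 = F.evaluate_sweep(series, fits, basis, render,
                              csv_path=tmp_path / "b.csv")
        assert len(t1) == 2
        assert list(t1.columns) == ["sweep_value", "aae_deg", "r_plus_pct",
                                    "r_minus_pct", "correct_peaks_mean"]
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        # noise-free easy sweep: AAE below one render-vertex spacing
        assert t1["aae_deg"].max() < 4.0

    def test_grid_piso_monotone_in_iso_fraction(self, gtab, operator):
        vol, truth, _ = F.make_pve_snr_grid(90.0, seed=17, gtab=gtab)
        cf = F.fit_field(vol, gtab, operator, F.SolverConfig())
        profile = np.nanmean(F.p_iso_map(cf)[:, :, 0], axis=1)
        from scipy.stats import spearmanr
        rho = spearmanr(np.arange(len(profile)), profile).statistic
        assert rho >= 0.9
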