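import numpy as np
import pytest

from refltriage import intensity_stats as istats
from refltriage import simulate as sim
from refltriage import symmetry as symm
from refltriage import tncs as tm
from refltriage.reflection_data import ReflectionDataset, UnitCell
from refltriage.simulate import unique_reflections


def _flat_dataset(cell=None, laue="1", d_min=3.0):
    """z identically 1: featureless Patterson."""
    cell = cell or UnitCell(30, 30, 40)
    pg = symm.point_group(laue)
    hkl = unique_reflections(cell, pg, d_min)
    eps = symm.epsilon_factors(hkl, pg).astype(float)
    return ReflectionDataset(hkl=hkl, I=100.0 * eps, sigI=np.ones(len(hkl)),
                             cell=cell, laue_symbol=laue,
                             _skip_canonicalization=True)


def _tncs_draws(model, cell=None, laue="1", d_min=2.2, seed=0, alpha=0.0):
    """Wilson draws with a TNCS expected-intensity modulation imposed."""
    cell = cell or UnitCell(30, 30, 40)
    pg = symm.point_group(laue)
    hkl = unique_reflections(cell, pg, d_min)
    rng = np.random.default_rng(seed)
    eps_t = tm.tncs_epsilon(hkl, model, cell=cell)
    e1 = rng.exponential(size=len(hkl))
    e2 = rng.exponential(size=len(hkl))
    z = (1 - alpha) * e1 + alpha * e2
    I = 100.0 * eps_t * z
    return ReflectionDataset(hkl=hkl, I=I, sigI=0.02 * I + 0.5, cell=cell,
                             laue_symbol=laue, _skip_canonicalization=True)


class TestInterferenceG:
    def test_limit_at_zero(self):
        assert tm.interference_G(0.0) == pytest.approx(1.0)

    def test_at_pi(self):
        x = np.pi
        oracle = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        assert tm.interference_G(x) == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(3 / np.pi**2)

    def test_decay_beyond_50(self):
        xs = np.linspace(50, 500, 2000)
        assert np.max(np.abs(tm.interference_G(xs))) < 0.01

    def test_series_matches_closed_form_at_crossover(self):
        x = 0.0999  # series branch; compare with the closed form directly
        closed = 3 * (np.sin(x) - x * np.cos(x)) / x**3
        assert tm.interference_G(x) == pytest.approx(closed, abs=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tm.interference_G(-1.0)


class TestTncsEpsilon:
    def test_uncorrelated_copies_flat(self):
        cell = UnitCell(30, 30, 40)
        model = tm.TncsModel(m=3, t=np.array([0, 0, 1 / 3]), f0=0.0)
        hkl = unique_reflections(cell, symm.point_group("1"), 3.0)
        raw = tm.tncs_epsilon(hkl, model, cell=cell, normalized=False)
        np.testing.assert_allclose(raw, 3.0)
        norm = tm.tncs_epsilon(hkl, model, cell=cell)
        np.testing.assert_allclose(norm, 1.0)

    def test_order2_interference_limits(self):
        cell = UnitCell(30, 30, 40)
        model = tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=1.0)
        # h.t = 0.5 -> destructive; h.t = 0 -> constructive
        raw = tm.tncs_epsilon(np.array([[1, 0, 0], [2, 0, 0]]), model,
                              cell=cell, normalized=False)
        assert raw[0] == pytest.approx(0.0, abs=1e-5)
        assert raw[1] == pytest.approx(4.0, rel=1e-6)

    def test_shell_normalized_unit_mean(self):
        cell = UnitCell(30, 30, 40)
        model = tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.8,
                             sigma_rmsd=0.5, beta=5.0)
        hkl = unique_reflections(cell, symm.point_group("1"), 2.2)
        binning = istats.make_binning(
            np.einsum("ni,ni->n", hkl @ cell.M.T, hkl @ cell.M.T))
        eps = tm.tncs_epsilon(hkl, model, cell=cell, binning=binning)
        for b in range(binning.nbins):
            assert np.mean(eps[binning.assignments == b]) == pytest.approx(1.0, abs=1e-3)

    def test_trivial_model_identity(self):
        cell = UnitCell(30, 30, 40)
        hkl = unique_reflections(cell, symm.point_group("1"), 3.0)
        np.testing.assert_allclose(
            tm.tncs_epsilon(hkl, tm.TncsModel(m=1), cell=cell), 1.0)


class TestPattersonMap:
    def test_featureless_map_near_zero(self):
        ds = _flat_dataset()
        pmap = tm.patterson_map(ds)
        off = pmap.values.copy()
        off[0, 0, 0] = 0.0
        assert np.max(np.abs(off)) < 0.05 * pmap.origin_value

    def test_inversion_symmetry(self):
        ds = _tncs_draws(tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.8), seed=1)
        pmap = tm.patterson_map(ds)
        v = pmap.values
        flipped = v[
            (-np.arange(v.shape[0])) % v.shape[0]][:,
            (-np.arange(v.shape[1])) % v.shape[1]][:, :,
            (-np.arange(v.shape[2])) % v.shape[2]]
        np.testing.assert_allclose(v, flipped, atol=1e-9)

    def test_order2_peak_location(self):
        ds = _tncs_draws(tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.8), seed=2)
        pmap = tm.patterson_map(ds)
        peaks = tm.find_tncs_vectors(pmap)
        assert peaks
        u = np.array(peaks[0].u)
        step = 1.0 / pmap.grid[0]
        assert min(abs(u[0] - 0.5), abs(u[0] + 0.5 - 1)) <= step + 1e-9

    def test_empty_window_fatal(self):
        ds = _flat_dataset(d_min=3.0)
        with pytest.raises(ValueError):
            tm.patterson_map(ds, d_max=30.0, d_min=25.0)


class TestFindVectors:
    def test_featureless_empty(self):
        pmap = tm.patterson_map(_flat_dataset())
        assert tm.find_tncs_vectors(pmap) == []

    def test_threshold_above_origin_empty(self):
        ds = _tncs_draws(tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.9), seed=3)
        pmap = tm.patterson_map(ds)
        assert tm.find_tncs_vectors(pmap, threshold_rel=1.01) == []

    def test_order7_colinear_family(self):
        truth = sim.SimulationTruth(seed=4, cell=(30, 30, 70, 90, 90, 90),
                                    laue="1", n_atoms=30, tncs_m=7,
                                    tncs_t=(0, 0, 1 / 7), tncs_f0=0.95,
                                    tncs_sigma_rmsd=0.2, d_min=2.5)
        ds = sim.simulate_dataset(truth)["dataset"]
        pmap = tm.patterson_map(ds)
        peaks = tm.find_tncs_vectors(pmap)
        assert len(peaks) >= 3
        for p in peaks[:3]:
            u = np.array(p.u)
            assert abs(u[0]) < 0.1 or abs(u[0] - 1) < 0.1
            k7 = u[2] * 7
            assert abs(k7 - round(k7)) < 7 * (1.0 / pmap.grid[2])


class TestInferOrders:
    def test_empty_gives_no_tncs_only(self):
        out = tm.infer_tncs_orders([])
        assert [h["m"] for h in out] == [1]

    def test_single_half_cell_peak(self):
        peaks = [tm.TncsPeak(u=(0.5, 0.0, 0.0), height_rel=0.6)]
        out = tm.infer_tncs_orders(peaks)
        assert out[0]["m"] == 2
        assert out[0]["t"] == pytest.approx((0.5, 0, 0), abs=1e-9)
        assert out[-1]["m"] == 1

    def test_order7_family_top(self):
        peaks = [tm.TncsPeak(u=(0.0, 0.0, k / 7), height_rel=0.8 - 0.05 * k)
                 for k in range(1, 4)]
        # inversion mates cover k = 4..6
        out = tm.infer_tncs_orders(peaks, grid_tol=0.02)
        nontrivial = [h for h in out if h["m"] > 1]
        assert nontrivial[0]["m"] == 7
        np.testing.assert_allclose(np.abs(nontrivial[0]["t"]), (0, 0, 1 / 7), atol=0.02)


class TestRefineTncs:
    def test_trivial_candidate(self, small_dataset):
        model = tm.refine_tncs(small_dataset, {"m": 1})
        assert model.is_trivial()
        np.testing.assert_allclose(
            tm.tncs_epsilon(small_dataset, model), 1.0)

    def test_parameter_recovery_order2(self):
        truth_model = tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.8,
                                   sigma_rmsd=0.5)
        ds = _tncs_draws(truth_model, d_min=1.9, seed=5)
        assert ds.n > 8000
        model = tm.refine_tncs(ds, {"m": 2, "t": (0.5, 0, 0)})
        assert model.warning is None
        assert model.f0 == pytest.approx(0.8, abs=0.1)
        assert np.max(np.abs(model.t - truth_model.t)) < 0.05

    def test_no_tncs_flagged(self):
        ds = _tncs_draws(tm.TncsModel(m=1), seed=6, d_min=2.4)
        model = tm.refine_tncs(ds, {"m": 2, "t": (0.5, 0, 0)})
        assert model.warning == "tncs_not_supported"

    def test_second_moment_restored(self):
        truth_model = tm.TncsModel(m=2, t=np.array([0.5, 0, 0]), f0=0.9,
                                   sigma_rmsd=0.3)
        ds = _tncs_draws(truth_model, d_min=2.0, seed=7)
        binning = istats.make_binning(ds.s_squared())
        before = istats.second_moments(
            istats.estimate_sigma_curve(ds, binning))["acentric"]
        assert before["m2"] > 2.2
        model = tm.refine_tncs(ds, {"m": 2, "t": (0.5, 0, 0)}, binning=binning)
        eps_t = tm.tncs_epsilon(ds, model, binning=binning)
        after = istats.second_moments(
            istats.estimate_sigma_curve(ds, binning, eps_tncs=eps_t))["acentric"]
        assert after["m2"] == pytest.approx(2.0, abs=3 * after["se"])


class TestPeakHeightMonotonicInF0:
    def test_sweep(self):
        heights = []
        for f0 in (0.2, 0.5, 0.8):
            truth = sim.SimulationTruth(seed=8, cell=(28, 28, 36, 90, 90, 90),
                                        laue="1", n_atoms=40, tncs_m=2,
                                        tncs_t=(0.5, 0, 0), tncs_f0=f0,
                                        d_min=2.5, noise_frac=0.01)
            ds = sim.simulate_dataset(truth)["dataset"]
            pmap = tm.patterson_map(ds)
            peaks = tm.find_tncs_vectors(pmap, threshold_rel=0.05)
            on_x = [p for p in peaks
                    if min(abs(p.u[0] - 0.5), abs(p.u[0] - 0.5)) < 0.1]
            heights.append(max(p.height_rel for p in on_x) if on_x else 0.0)
        assert heights[0] < heights[1] < heights[2]
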