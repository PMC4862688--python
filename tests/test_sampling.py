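"""Langevin integrator, classification, umbrella sampling, WHAM, profiles."""

import numpy as np
import pandas as pd
import pytest

from swapfold._kernels import KB
from swapfold.go_model import Topology, native_tandem_coords_from_domain
from swapfold.permutants import tandem_contact_sets
from swapfold.sampling import (
    FreeEnergyProfile,
    LangevinParams,
    UmbrellaWindow,
    barrier_from_profile,
    classify_state,
    first_passage_campaign,
    langevin_run,
    nucleus_location_distribution,
    select_temperature,
    stability_from_profile,
    umbrella_sampling,
    wham,
)
from swapfold.structures import fully_extended_coords


def single_bead_topology():
    e_i, e_f = np.empty(0, int), np.empty(0)
    return Topology(
        n=1, bond_i=e_i, bond_j=e_i, bond_r0=e_f, bond_k=e_f,
        ang_i=e_i, ang_j=e_i, ang_k=e_i, ang_theta0=e_f, ang_kth=e_f,
        dih_i=e_i, dih_j=e_i, dih_k=e_i, dih_l=e_i,
        dih_phi0=e_f, dih_k1=e_f, dih_k3=e_f,
        con_i=e_i, con_j=e_i, con_eps=e_f, con_r0=e_f,
        sigma=np.array([0.4]),
    )


class TestIntegrator:
    def test_equipartition_in_harmonic_well(self):
        k = 50.0
        topo = single_bead_topology()
        p = LangevinParams(temperature=300.0, seed=3, n_steps=400_000)
        traj = langevin_run(
            topo, p, np.zeros((1, 3)), save_stride=100,
            tether=(np.array([k]), np.zeros((1, 3))),
        )
        var = traj.frames[100:, 0, :].var()
        assert var == pytest.approx(KB * 300.0 / k, rel=0.05)

    def test_same_seed_bitwise_identical(self, hairpin_domain, hairpin):
        p = LangevinParams(temperature=320.0, seed=5, n_steps=4000)
        a = langevin_run(hairpin_domain, p, hairpin.coords.copy(), save_stride=500)
        b = langevin_run(hairpin_domain, p, hairpin.coords.copy(), save_stride=500)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_low_temperature_quench_dissipates(self, hairpin_domain, hairpin):
        from swapfold.go_model import potential_energy

        local_rng = np.random.default_rng(42)
        start = hairpin.coords + local_rng.normal(scale=0.05,
                                                  size=hairpin.coords.shape)
        e_start, _ = potential_energy(hairpin_domain, start)
        # strong friction: the T -> 0 limit relaxes into a local minimum
        # (a small numerical jitter band remains from the bounded angle
        # force near collinear geometries)
        p = LangevinParams(temperature=1e-3, friction=20.0, seed=2,
                           n_steps=20_000)
        traj = langevin_run(hairpin_domain, p, start, save_stride=1000)
        assert traj.energies[-1] < e_start - 1.0
        assert np.max(traj.energies) < e_start
        assert np.ptp(traj.energies[len(traj.energies) // 2:]) < 0.6

    def test_nan_initial_raises(self, hairpin_domain):
        bad = np.full((hairpin_domain.n_residues, 3), np.nan)
        with pytest.raises(ValueError):
            langevin_run(hairpin_domain, LangevinParams(n_steps=10), bad)


def swapped_frame(tandem, K, separation=6.0):
    """Frame with the K-permutant's central and terminal domains both at
    native-like geometry, far apart."""
    L = tandem.L
    ref = native_tandem_coords_from_domain(
        tandem.domain_model.structure.coords, L
    )
    frame = np.zeros((2 * L, 3))
    for m in range(1, 2 * L + 1):
        if K + 1 <= m <= K + L:  # central domain
            role = m if m <= L else m - L
            frame[m - 1] = ref[role - 1]
        else:  # terminal domain
            role = m if m <= K else m - L
            frame[m - 1] = ref[role - 1] + [0.0, separation, 0.0]
    return frame


class TestClassification:
    def test_native_frame(self, hairpin_tandem):
        sets = tandem_contact_sets(hairpin_tandem)
        ref = native_tandem_coords_from_domain(
            hairpin_tandem.domain_model.structure.coords, hairpin_tandem.L
        )
        assert classify_state(ref, sets) == 0

    def test_extended_frame_incomplete(self, hairpin_tandem):
        sets = tandem_contact_sets(hairpin_tandem)
        ext = fully_extended_coords(hairpin_tandem.n_residues)
        assert classify_state(ext, sets) == "incomplete"

    def test_constructed_swap_frame_labels_K(self, hairpin_tandem):
        sets = tandem_contact_sets(hairpin_tandem)
        K = next(s.K for s in sets if s.K > 0)
        frame = swapped_frame(hairpin_tandem, K)
        assert classify_state(frame, sets) == K

    def test_threshold_domain(self, hairpin_tandem):
        sets = tandem_contact_sets(hairpin_tandem)
        with pytest.raises(ValueError):
            classify_state(np.zeros((hairpin_tandem.n_residues, 3)), sets, 0.4)


class TestCampaign:
    def test_fractions_sum_to_one_and_se(self, hairpin_tandem):
        sets = tandem_contact_sets(hairpin_tandem)
        params = LangevinParams(temperature=300.0, seed=9)
        outcomes, summary = first_passage_campaign(
            hairpin_tandem, sets, n_traj=8, t_max_steps=120_000, params=params,
        )
        assert len(outcomes) == 8
        assert summary["fraction"].sum() == pytest.approx(1.0)
        for _, row in summary.iterrows():
            p = row["fraction"]
            assert row["stderr"] == pytest.approx(np.sqrt(p * (1 - p) / 8))
        # one label per trajectory, native reachable at this temperature
        assert (summary["count"].sum()) == 8


class TestUmbrellaSampling:
    def test_window_overlap_and_spread_halving(self, hairpin_domain, hairpin):
        cm = hairpin_domain.contact_map
        arrays = (cm.i, cm.j, cm.r0)
        p = LangevinParams(temperature=360.0, seed=6)
        wins = umbrella_sampling(
            hairpin_domain, arrays, p, centers=np.linspace(0.1, 0.9, 8),
            kappa=40.0, n_steps=12_000, n_equil=4_000,
            initial=hairpin.coords.copy(),
        )
        assert len(wins) == 8
        # neighbouring windows overlap (no exception) and spread shrinks with k
        wins_stiff = umbrella_sampling(
            hairpin_domain, arrays, p, centers=np.array([0.5]),
            kappa=160.0, n_steps=12_000, n_equil=4_000,
            initial=hairpin.coords.copy(),
        )
        soft = next(w for w in wins if np.isclose(w.center, 0.5, atol=0.06))
        ratio = wins_stiff[0].samples.var() / soft.samples.var()
        assert ratio < 0.8

    def test_bias_energy_zero_at_center(self, hairpin_domain, hairpin):
        from swapfold import _kernels
        from swapfold.sampling import _kernel_args, _q_of_arrays

        cm = hairpin_domain.contact_map
        q_now = _q_of_arrays(hairpin.coords, cm.i, cm.j, cm.r0)
        args_unbiased = _kernel_args(hairpin_domain.topology)
        args_biased = _kernel_args(
            hairpin_domain.topology,
            bias=(cm.i - 1, cm.j - 1, cm.r0, 100.0, q_now, 50.0, 1.2),
        )
        f = np.zeros_like(hairpin.coords)
        e0 = _kernels.compute_forces(hairpin.coords.copy(), *args_unbiased, f)
        e1 = _kernels.compute_forces(hairpin.coords.copy(), *args_biased, f)
        assert e1 - e0 == pytest.approx(0.0, abs=1e-10)


def synthetic_double_well(grid=None):
    grid = np.arange(0.005, 1.0, 0.01) if grid is None else grid
    F = 30 * (grid - 0.15) ** 2 * (grid - 0.85) ** 2 / 0.1225
    return grid, F - F.min()


def draw_biased_windows(grid, F, T, centers, kappa, n, seed):
    kbt = KB * T
    rng = np.random.default_rng(seed)
    wins = []
    for c in centers:
        w = np.exp(-(F + 0.5 * kappa * (grid - c) ** 2) / kbt)
        w /= w.sum()
        samples = rng.choice(grid, size=n, p=w) + rng.uniform(-0.005, 0.005, n)
        wins.append(UmbrellaWindow(center=c, kappa=kappa, samples=samples))
    return wins


class TestWham:
    def test_recovers_analytic_double_well(self):
        grid, F = synthetic_double_well()
        wins = draw_biased_windows(
            grid, F, 350.0, np.linspace(0.0, 1.0, 21), 60.0, 4000, seed=3
        )
        prof = wham(wins, 350.0)
        interp = np.interp(grid, prof.grid, prof.F)
        mask = F < 8
        resid = interp[mask] - F[mask]
        rms = np.sqrt(np.mean((resid - resid.mean()) ** 2))
        assert rms < 0.1

    def test_single_unbiased_window_is_log_histogram(self, rng):
        grid, F = synthetic_double_well()
        kbt = KB * 300.0
        w = np.exp(-F / kbt)
        w /= w.sum()
        samples = rng.choice(grid, size=30_000, p=w)
        prof = wham([UmbrellaWindow(center=0.0, kappa=0.0, samples=samples)],
                    300.0)
        hist, edges = np.histogram(
            samples, bins=np.arange(-0.05, 1.06, 0.01)
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        direct = -kbt * np.log(hist[keep])
        direct -= direct.min()
        np.testing.assert_allclose(prof.F, direct, atol=1e-8)
        np.testing.assert_allclose(prof.grid, centers[keep])

    def test_window_order_irrelevant(self):
        grid, F = synthetic_double_well()
        wins = draw_biased_windows(
            grid, F, 350.0, np.linspace(0.0, 1.0, 11), 60.0, 2000, seed=5
        )
        a = wham(wins, 350.0)
        b = wham(wins[::-1], 350.0)
        np.testing.assert_allclose(a.F, b.F, atol=1e-6)

    def test_disjoint_windows_raise(self):
        wins = [
            UmbrellaWindow(center=0.1, kappa=50.0,
                           samples=np.random.default_rng(0).uniform(0.05, 0.15, 100)),
            UmbrellaWindow(center=0.9, kappa=50.0,
                           samples=np.random.default_rng(1).uniform(0.85, 0.95, 100)),
        ]
        with pytest.raises(RuntimeError, match="overlap"):
            umbrella_check = __import__(
                "swapfold.sampling", fromlist=["_check_overlap"]
            )._check_overlap(wins)


class TestProfileAnalysis:
    def test_symmetric_double_well_is_neutral(self):
        grid, F = synthetic_double_well()
        prof = FreeEnergyProfile(grid=grid, F=F, temperature=350.0)
        dgs, q_dagger, q_u = stability_from_profile(prof)
        assert dgs == pytest.approx(0.0, abs=0.02)
        assert q_dagger == pytest.approx(0.5, abs=0.02)
        assert q_u == pytest.approx(0.15, abs=0.03)

    def test_imposed_two_kcal_recovered(self):
        grid = np.arange(0.005, 1.0, 0.01)
        kbt = KB * 350.0
        p = (0.5 * np.exp(-0.5 * ((grid - 0.2) / 0.06) ** 2)
             + 0.5 * np.exp(2.0 / kbt) * np.exp(-0.5 * ((grid - 0.8) / 0.06) ** 2))
        prof = FreeEnergyProfile(grid=grid, F=-kbt * np.log(p), temperature=350.0)
        dgs, _, _ = stability_from_profile(prof)
        assert dgs == pytest.approx(2.0, abs=0.05)

    def test_constant_shift_invariance(self):
        grid, F = synthetic_double_well()
        a = stability_from_profile(FreeEnergyProfile(grid=grid, F=F, temperature=350.0))[0]
        b = stability_from_profile(FreeEnergyProfile(grid=grid, F=F + 7.3, temperature=350.0))[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_barrier_height_of_symmetric_well(self):
        grid, F = synthetic_double_well()
        prof = FreeEnergyProfile(grid=grid, F=F, temperature=350.0)
        dgf, q_dagger = barrier_from_profile(prof)
        k = np.argmin(np.abs(grid - 0.5))
        assert dgf == pytest.approx(F[k], abs=0.05)

    def test_monotone_profile_raises(self):
        grid = np.linspace(0.0, 1.0, 50)
        prof = FreeEnergyProfile(grid=grid, F=5 * (1 - grid), temperature=300.0)
        with pytest.raises(ValueError, match="two-state"):
            stability_from_profile(prof)

    def test_explicit_dividing_point(self):
        grid = np.linspace(0.0, 1.0, 101)
        prof = FreeEnergyProfile(grid=grid, F=3 * (1 - grid), temperature=300.0)
        dgs, q_dagger, _ = stability_from_profile(prof, q_dagger=0.5)
        assert q_dagger == 0.5
        assert dgs > 0  # downhill profile: folded side carries more weight


def analytic_profiler(T):
    """Synthetic two-basin family with controlled thermodynamics:
    unfolded well at Q = 0.15, folded well at Q = 0.85 sitting
    s(T) = (380 − T)/20 kcal/mol below it (melting near 380 K), and a
    barrier built so ΔG_f/k_BT ≈ 1.5 + (T − 250)/100 (crosses 2.5 near
    350 K)."""
    grid = np.arange(0.005, 1.0, 0.01)
    kbt = KB * T
    s = (380.0 - T) / 20.0
    b = kbt * (1.5 + (T - 250.0) / 100.0)
    base = ((grid - 0.15) ** 2) * ((grid - 0.85) ** 2) / (0.35 ** 4)
    well = -s * np.exp(-0.5 * ((grid - 0.85) / 0.05) ** 2)
    return FreeEnergyProfile(grid=grid, F=b * base + well, temperature=T)


class TestSelectTemperature:
    def test_bisection_meets_barrier_criterion(self):
        t_sel, info = select_temperature(
            profiler=analytic_profiler, t_range=(250.0, 420.0), max_bisect=30,
        )
        prof = analytic_profiler(t_sel)
        dgf, _ = barrier_from_profile(prof)
        assert abs(dgf / (KB * t_sel) - 2.5) < 0.1
        # Tm bracket: stability changes sign near 380 K
        assert info["tm"] == pytest.approx(380.0, abs=20.0)

    def test_stability_decreases_with_temperature(self):
        dgs = [stability_from_profile(analytic_profiler(T))[0]
               for T in (300.0, 350.0, 390.0)]
        assert dgs[0] > dgs[1] > dgs[2]

    def test_no_qualifying_temperature_reports_scan(self, hairpin_domain):
        """Toy folds are downhill: no temperature gives a 2.5 kT barrier,
        and the error carries the scan table."""
        with pytest.raises(RuntimeError, match="scan"):
            select_temperature(
                hairpin_domain, t_range=(300.0, 420.0),
                n_windows=8, n_steps=8_000, n_equil=3_000, seed=2,
            )


class TestNucleusLocation:
    def test_one_domain_band_and_shift(self, hairpin_tandem):
        L = hairpin_tandem.L
        ref = native_tandem_coords_from_domain(
            hairpin_tandem.domain_model.structure.coords, L
        )
        ext = fully_extended_coords(2 * L) * 3.0
        frame_dom1 = np.vstack([ref[:L], ext[L:] + [0.0, 8.0, 0.0]])
        frame_dom2 = np.vstack([ext[:L] + [0.0, 8.0, 0.0], ref[L:]])
        hist, edges, vals1 = nucleus_location_distribution(
            np.array([frame_dom1]), hairpin_tandem, q_value=0.5, q_tol=0.1,
        )
        assert hist.sum() == pytest.approx(1.0)
        _, _, vals2 = nucleus_location_distribution(
            np.array([frame_dom2]), hairpin_tandem, q_value=0.5, q_tol=0.1,
        )
        assert vals2.mean() - vals1.mean() == pytest.approx(L, abs=1e-6)

    def test_empty_band_raises(self, hairpin_tandem):
        ext = fully_extended_coords(hairpin_tandem.n_residues)
        with pytest.raises(ValueError, match="band"):
            nucleus_location_distribution(
                np.array([ext]), hairpin_tandem, q_value=0.5, q_tol=0.01,
            )
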