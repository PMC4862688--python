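"""Alchemical ΔΔG predictor: entropy bookkeeping, windows, feasibility."""

import numpy as np
import pytest

from swapfold.alchemy import (
    AlchemicalParams,
    cut_free_energy,
    ddg_total,
    entropy_per_residue,
    join_free_energy,
    termini_offset,
)
from swapfold.go_model import ContactMap, build_go_model
from swapfold.structures import CalphaStructure, ToySpec, make_toy_structure


def make_map(n, pairs, eps):
    i, j = np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])
    return ContactMap(i=i, j=j, eps=np.array(eps, float),
                      r0=np.full(len(pairs), 0.5), n_residues=n)


class TestEntropyPerResidue:
    def test_arithmetic(self):
        cm = make_map(70, [(1, 10), (2, 20)], [-30.0, -40.0])
        ds = entropy_per_residue(cm, T=350.0, N=70)
        assert ds == pytest.approx(-70.0 / (350.0 * 70.0))

    def test_doubling_epsilon_doubles_ds(self):
        cm1 = make_map(50, [(1, 10)], [-5.0])
        cm2 = make_map(50, [(1, 10)], [-10.0])
        assert entropy_per_residue(cm2, 300.0) == \
            pytest.approx(2 * entropy_per_residue(cm1, 300.0))

    def test_cancellation_identity(self):
        cm = make_map(40, [(1, 10), (5, 30)], [-12.0, -8.0])
        ds = entropy_per_residue(cm, T=310.0)
        assert ds * 310.0 * 40 == pytest.approx(cm.total_energy)

    def test_empty_map_raises(self):
        cm = make_map(10, [(1, 5)], [-1.0])
        cm.i = cm.j = cm.eps = cm.r0 = np.empty(0)
        with pytest.raises(ValueError):
            entropy_per_residue(cm, 300.0)


class TestTerminiOffset:
    def test_antiparallel_meander_gets_six(self):
        s = make_toy_structure(ToySpec(4, 6, 3, 1.4, seed=1))  # even strands
        assert termini_offset(s) == 6

    def test_parallel_termini_get_zero(self):
        s = make_toy_structure(ToySpec(3, 6, 3, 2.1, seed=1))  # odd strands
        assert termini_offset(s) == 0

    def test_too_short_chain_raises(self):
        s = CalphaStructure(sequence="AA", coords=np.array([[0, 0, 0], [0.38, 0, 0]]))
        with pytest.raises(ValueError):
            termini_offset(s)


def hand_join_system():
    """12 beads engineered so the only cost-2.0 feasible join peels
    residue 1 and residue 12 (both contact-bearing): broken contacts
    (1,6) + (7,12) cost 3.0, entropy gain 2 x T|ds| = 1.0."""
    coords = np.array([
        [0.0, -1.5, 0.0],   # R1: far from everything at the C end
        [0.0, 0.0, 0.0],    # R2: 0.9 from R11 -> (1,11) feasible
        [0.3, -0.5, 0.0],   # R3: > 1.05 from R12 -> (2,12) infeasible
        [0.1, -1.0, 0.0],
        [0.4, -1.1, 0.0],
        [0.7, -1.0, 0.0],
        [1.0, -1.1, 0.0],
        [0.6, 1.4, 0.0],    # R8..R10: far from R1 (small-peel windows fail)
        [1.2, 1.0, 0.0],
        [1.2, 0.4, 0.0],
        [0.9, 0.0, 0.0],    # R11
        [0.9, 1.5, 0.0],    # R12
    ])
    s = CalphaStructure(sequence="A" * 12, coords=coords)
    pairs = [(1, 6), (7, 12), (2, 8), (3, 9), (4, 10), (5, 11)]
    eps = [-2.0, -1.0, -1.0, -1.0, -1.0, -1.0]
    return s, make_map(12, pairs, eps)


class TestJoinFreeEnergy:
    def test_zero_cost_when_termini_touch(self):
        # ring: first and last bead adjacent
        n = 10
        ang = np.linspace(0, 2 * np.pi * (n - 1) / n, n)
        coords = 0.55 * np.stack([np.cos(ang), np.sin(ang), 0 * ang], axis=1)
        s = CalphaStructure(sequence="A" * n, coords=coords)
        cm = make_map(n, [(1, 5), (2, 8)], [-1.0, -1.0])
        dg, (i, j), kappa = join_free_energy(
            s, cm, ds=-0.001, params=AlchemicalParams(M=0, T=300.0)
        )
        assert dg == 0.0
        assert (i, j) == (0, n)
        assert kappa == 0

    def test_hand_built_two_residue_peel(self):
        s, cm = hand_join_system()
        dg, (i, j), kappa = join_free_energy(
            s, cm, ds=-0.5 / 300.0, params=AlchemicalParams(M=0, T=300.0)
        )
        assert (i, j) == (1, 11)
        assert kappa == 0
        assert dg == pytest.approx(3.0 - 1.0)

    def test_contactless_tail_never_increases_cost(self):
        s, cm = hand_join_system()
        base, _, _ = join_free_energy(
            s, cm, ds=-0.5 / 300.0, params=AlchemicalParams(M=0, T=300.0)
        )
        # prepend two contact-free beads (tail extends outward)
        ext = np.vstack([
            s.coords[0] + [0.76, 0.0, 0.0],
            s.coords[0] + [0.38, 0.0, 0.0],
            s.coords,
        ])
        s2 = CalphaStructure(sequence="GG" + s.sequence, coords=ext)
        cm2 = make_map(len(s2), list(zip(cm.i + 2, cm.j + 2)), cm.eps)
        with_tail, _, _ = join_free_energy(
            s2, cm2, ds=-0.5 / 300.0, params=AlchemicalParams(M=0, T=300.0)
        )
        assert with_tail <= base + 1e-9

    def test_infeasible_join_raises(self):
        # long straight rod: termini can never be joined within the windows
        n = 60
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 0.38
        s = CalphaStructure(sequence="A" * n, coords=coords)
        cm = make_map(n, [(k, k + 4) for k in range(1, 55)], [-1.0] * 54)
        with pytest.raises(RuntimeError, match="joined"):
            join_free_energy(s, cm, ds=-0.001,
                             params=AlchemicalParams(M=0, T=300.0))


class TestCutFreeEnergy:
    def test_clean_loop_costs_nothing(self):
        # contacts far from the cut; window residues are contact-free
        cm = make_map(30, [(1, 6), (24, 30)], [-1.0, -1.0])
        dg, (ip, jp) = cut_free_energy(
            cm, K=15, ds=-0.01, params=AlchemicalParams(M=0, T=300.0)
        )
        assert dg == 0.0

    def test_hand_enumeration_oracle(self):
        """Brute-force the 4x4 window search independently and compare."""
        K, L = 15, 30
        t_ds = 2.0  # strong entropy gain per contact-bearing residue
        cm = make_map(L, [(K - 1, K + 6), (2, 8)], [-1.5, -1.0])
        params = AlchemicalParams(M=0, T=400.0)
        ds = -t_ds / params.T
        bearing = {K - 1, K + 6, 2, 8}
        best = None
        for ip in range(K - 3, K + 1):
            for jp in range(K + 1, K + 5):
                unfolded = set(range(ip + 1, K + 1)) | set(range(K + 1, jp))
                e = 1.5 if (K - 1) in unfolded else 0.0
                s_gain = t_ds * len(unfolded & bearing)
                cost = e - s_gain
                n_unf = len(unfolded)
                if best is None or cost < best[0] - 1e-12 or (
                    abs(cost - best[0]) <= 1e-12 and n_unf < best[2]
                ):
                    best = (cost, (ip, jp), n_unf)
        dg, arg = cut_free_energy(cm, K, ds, params)
        assert dg == pytest.approx(best[0])
        assert arg == best[1]
        # the entropy term makes breaking the contact worthwhile here
        assert dg == pytest.approx(1.5 - t_ds)

    def test_frame_shift_invariance(self):
        L = 20
        pairs = [(3, 9), (8, 14)]
        cm1 = make_map(L, pairs, [-1.0, -2.0])
        cm2 = make_map(2 * L, [(i + L, j + L) for i, j in pairs], [-1.0, -2.0])
        p = AlchemicalParams(M=0, T=300.0)
        a = cut_free_energy(cm1, K=10, ds=-0.002, params=p)
        b = cut_free_energy(cm2, K=10 + L, ds=-0.002, params=p)
        assert a[0] == pytest.approx(b[0])

    def test_cut_near_chain_end_raises(self):
        cm = make_map(20, [(1, 10)], [-1.0])
        with pytest.raises(ValueError, match="end"):
            cut_free_energy(cm, K=2, ds=-0.01,
                            params=AlchemicalParams(M=0, T=300.0))


class TestDdgTotal:
    def test_sum_of_parts_and_join_shared_across_cuts(self, meander, meander_domain):
        from swapfold.permutants import enumerate_cut_sites

        sites = enumerate_cut_sites(meander_domain)
        assert len(sites) >= 2
        results = [
            ddg_total(meander, meander_domain.contact_map, s.K, T=360.0)
            for s in sites
        ]
        for r in results:
            assert r.ddG_tot == pytest.approx(r.dG_J + r.dG_C)
        # the cyclization step is identical for every cut position
        assert len({round(r.dG_J, 9) for r in results}) == 1

    def test_wider_termini_gap_never_helps(self):
        """A structure with farther-apart termini is at least as hard to
        cyclize, for every cut position."""
        K = 23
        near = make_toy_structure(ToySpec(4, 6, 7, 1.0, seed=1))
        far = make_toy_structure(ToySpec(4, 6, 7, 1.44, seed=1))
        dom_near = build_go_model(near, energy_unit=1.0)
        dom_far = build_go_model(far, energy_unit=1.0)
        a = ddg_total(near, dom_near.contact_map, K, T=360.0)
        b = ddg_total(far, dom_far.contact_map, K, T=360.0)
        assert b.ddG_tot >= a.ddG_tot - 1e-9
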