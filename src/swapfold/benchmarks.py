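"""Desk-scale benchmark systems and end-to-end study procedures.

These are the package's reference computations on synthetic toys: the
misfolding first-passage campaign, the WSME oracle comparison, the WHAM
recovery check and the alchemy-vs-simulation ranking.  Tests and the
acceptance script both call these, so the measured quantities come from a
single definition of each study.

Scales are deliberately desk-sized (tens to a few hundred trajectories,
toy folds of 15-90 residues); the corresponding full-scale campaigns
(1024 x 12 us on experimentally derived domain models) use the same code
paths through the public API but need cluster resources.
"""

from __future__ import annotations

import numpy as np

from ._kernels import KB
from .go_model import (
    build_circular_permutant_model,
    build_go_model,
    build_tandem_model,
)
from .alchemy import ddg_total
from .sampling import (
    LangevinParams,
    UmbrellaWindow,
    first_passage_campaign,
    stability_from_profile,
    umbrella_sampling,
    wham,
)
from .permutants import tandem_contact_sets
from .structures import ToySpec, make_toy_structure
from .stats_report import spearman
from .wsme import (
    WsmeConfig,
    exact_partition,
    mc_sample,
    theta_occupancy_mc,
    total_variation,
)

#: energy unit used by all toy benchmarks (mean |eps| per contact, kcal/mol)
TOY_ENERGY_UNIT = 1.0
#: stabilizing working temperature of the toy campaigns, K
CAMPAIGN_T = 300.0

#: the misfolding-competent toy: hairpin tandem with matched loop/linker
VIABLE_TOY = ToySpec(n_strands=2, strand_length=6, loop_length=3,
                     termini_gap=0.48, seed=1)
VIABLE_LINKER = "GSG"

#: the permutant-hostile toy: no cuttable loops, termini maximally apart
HOSTILE_TOY = ToySpec(n_strands=4, strand_length=6, loop_length=3,
                      termini_gap=1.44, seed=1)
HOSTILE_LINKER = "GSG"

#: alchemy-ranking family: one four-strand architecture with the
#: circular-permutant destabilization graded by the native termini gap
#: (name, termini gap nm, junction length). Members are spaced so their
#: simulated stability differences are several times the sampling noise.
FAMILY = [
    ("gap1.0", 1.0, 1),
    ("gap1.25", 1.25, 1),
    ("gap1.44", 1.44, 1),
]
FAMILY_K = 23
FAMILY_T = 400.0


def family_member_spec(gap: float) -> ToySpec:
    return ToySpec(n_strands=4, strand_length=6, loop_length=7,
                   termini_gap=gap, seed=1)


def build_viable_tandem():
    domain = build_go_model(make_toy_structure(VIABLE_TOY),
                            energy_unit=TOY_ENERGY_UNIT)
    return build_tandem_model(domain, VIABLE_LINKER)


def build_hostile_tandem():
    domain = build_go_model(make_toy_structure(HOSTILE_TOY),
                            energy_unit=TOY_ENERGY_UNIT)
    return build_tandem_model(domain, HOSTILE_LINKER)


def misfolding_campaign(n_traj: int = 256, t_max_steps: int = 400_000,
                        seed: int = 11, hostile: bool = False):
    """First-passage campaign on the viable (or hostile) toy tandem.

    Returns (outcomes, summary); labels are 'native', 'incomplete' or a
    cut position K.
    """
    tandem = build_hostile_tandem() if hostile else build_viable_tandem()
    sets = tandem_contact_sets(tandem)
    params = LangevinParams(temperature=CAMPAIGN_T, seed=seed)
    return first_passage_campaign(
        tandem, sets, n_traj, t_max_steps, params, record_final_q=False,
    )


def wsme_benchmark(n_steps: int = 1_000_000, seed: int = 7,
                   ep_values=(0.0, 2.0, 4.0, 6.0)):
    """WSME oracle comparison on the viable toy tandem's duplicated map.

    Returns a dict with the MC-vs-enumeration total-variation distance,
    the midpoint-crossing occupancy along the E_p sweep (exact and MC),
    and the spread of full-length segment free energies at E_p = 0.
    """
    tandem = build_viable_tandem()
    cfg0 = WsmeConfig(contact_map=tandem.duplicated_contacts,
                      L=tandem.L, Ep=0.0)
    ens0 = exact_partition(cfg0)
    counts, _, _ = mc_sample(cfg0, n_steps, seed=seed)
    tv = total_variation(ens0, counts)
    occ_exact, occ_mc = [], []
    for ep in ep_values:
        cfg = WsmeConfig(contact_map=tandem.duplicated_contacts,
                         L=tandem.L, Ep=ep)
        occ_exact.append(exact_partition(cfg).theta_occupancy())
        cc, _, _ = mc_sample(cfg, max(n_steps // 2, 1), seed=seed + 1)
        occ_mc.append(theta_occupancy_mc(cfg, cc))
    full = ens0.lengths == cfg0.L
    spread = float(ens0.G[full].max() - ens0.G[full].min())
    return {
        "tv": float(tv),
        "ep_values": list(ep_values),
        "theta_exact": occ_exact,
        "theta_mc": occ_mc,
        "full_length_G_spread": spread,
    }


def synthetic_double_well(grid=None):
    """Analytic symmetric quartic double well on [0, 1]."""
    grid = np.arange(0.005, 1.0, 0.01) if grid is None else grid
    F = 30 * (grid - 0.15) ** 2 * (grid - 0.85) ** 2 / 0.1225
    return grid, F - F.min()


def wham_recovery_benchmark(T: float = 350.0, seed: int = 3,
                            n_per_window: int = 4000):
    """RMS error of WHAM against the analytic double well, from samples
    drawn directly under each harmonic bias (no dynamics involved)."""
    grid, F = synthetic_double_well()
    kbt = KB * T
    rng = np.random.default_rng(seed)
    windows = []
    for c in np.linspace(0.0, 1.0, 21):
        kappa = 60.0
        w = np.exp(-(F + 0.5 * kappa * (grid - c) ** 2) / kbt)
        w /= w.sum()
        samples = rng.choice(grid, size=n_per_window, p=w)
        samples = samples + rng.uniform(-0.005, 0.005, n_per_window)
        windows.append(UmbrellaWindow(center=c, kappa=kappa, samples=samples))
    prof = wham(windows, T)
    interp = np.interp(grid, prof.grid, prof.F)
    mask = F < 8.0
    resid = interp[mask] - F[mask]
    return float(np.sqrt(np.mean((resid - resid.mean()) ** 2)))


def family_stability(gap: float, ll: int, seed: int,
                     n_steps: int = 30_000, n_equil: int = 10_000):
    """Umbrella-sampled stability of one family member's circular
    permutant: bidirectional windows (down from folded, up from extended)
    to cancel walking hysteresis, Eq-2 quadrature with a fixed dividing
    surface at Q = 0.5 (appropriate for these weakly cooperative toys)."""
    structure = make_toy_structure(family_member_spec(gap))
    domain = build_go_model(structure, energy_unit=TOY_ENERGY_UNIT)
    cp = build_circular_permutant_model(domain, FAMILY_K, "G" * ll)
    cm = cp.contact_map
    params = LangevinParams(temperature=FAMILY_T, seed=seed)
    windows = umbrella_sampling(
        cp, (cm.i, cm.j, cm.r0), params, np.linspace(0.02, 0.98, 14),
        kappa=60.0, n_steps=n_steps, n_equil=n_equil,
        initial=cp.structure.coords.copy(), bidirectional=True,
    )
    profile = wham(windows, FAMILY_T, bin_width=0.025)
    dgs, _, _ = stability_from_profile(profile, q_dagger=0.5)
    return dgs


def alchemy_ranking_benchmark(seed: int = 5, n_replicates: int = 3):
    """Predicted ΔΔG_tot vs simulated permutant stability over the family.

    Returns (table rows, Spearman rho of −ΔΔG_tot against ΔG_s).
    """
    rows = []
    for name, gap, ll in FAMILY:
        structure = make_toy_structure(family_member_spec(gap))
        domain = build_go_model(structure, energy_unit=TOY_ENERGY_UNIT)
        res = ddg_total(structure, domain.contact_map, FAMILY_K,
                        T=FAMILY_T, linker_extra=ll)
        reps = [
            family_stability(gap, ll, seed=seed + 100 * r)
            for r in range(n_replicates)
        ]
        rows.append({
            "member": name, "K": FAMILY_K, "ddG_tot": res.ddG_tot,
            "dG_J": res.dG_J, "dG_C": res.dG_C,
            "dG_s": float(np.mean(reps)), "dG_s_replicates": reps,
        })
    rho = spearman([-r["ddG_tot"] for r in rows], [r["dG_s"] for r in rows])
    return rows, rho
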