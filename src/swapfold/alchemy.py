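"""Alchemical prediction of circular-permutant destabilization.

The conversion native → circular permutant is decomposed into two steps:
joining the N- and C-termini into a cyclic intermediate (ΔG_J, the same
for every cut position K) and cutting a loop at K (ΔG_C), so that

    ΔΔG_tot = ΔG_CP − ΔG_WT = ΔG_J + ΔG_C.

Joining may require peeling terminal residues off the native structure:
peeling residues 1..i and j+1..L is geometrically feasible when the native
Cα distance between residues i+1 and j is shorter than the effective
length of the joint loop, (i + 1 + L − j − M)·r0 with r0 = 3.5 Å per
residue and M a turn offset (6 when the termini point in opposite
directions, 0 when they are parallel).  The free-energy cost of a peel or
cut is the contact energy lost (each broken contact counted once) minus
the entropy gained by the unfolded residues, T·δs per residue, where
δs = Σ ε_ij / (T·N) at the folding temperature.  Residues whose only
interactions are with sequence neighbours gain no entropy (the κ rule).

A large ΔΔG_tot marks a fold whose circular permutants — the central
domains of domain-swapped misfolds — are too unstable to form, so the
prediction rank-orders misfolding propensity without any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .go_model import ContactMap
from .permutants import CutSite
from .structures import CalphaStructure

#: average length contribution of one peeled residue, nm (3.5 Å)
R0_PEEL = 0.35
#: half-width of the join windows (i in 0..9, j in L-9..L)
JOIN_WINDOW = 9
#: cut windows: i' in K-3..K, j' in K+1..K+4
CUT_WINDOW = 3


@dataclass
class AlchemicalParams:
    r0_peel: float = R0_PEEL  # nm per peeled residue
    M: int = 0                # turn offset, 0 or 6
    T: float = 350.0          # K, folding temperature
    linker_extra: int = 0     # structureless linker residues aiding the join
    join_window: int = JOIN_WINDOW
    cut_window: int = CUT_WINDOW

    def __post_init__(self):
        if self.r0_peel <= 0:
            raise ValueError("r0_peel must be positive")
        if self.M not in (0, 6):
            raise ValueError("M must be 0 or 6")
        if self.linker_extra < 0:
            raise ValueError("linker_extra must be >= 0")


@dataclass
class AlchemicalResult:
    K: int
    dG_J: float
    dG_C: float
    ddG_tot: float
    argmin_join: tuple  # (i, j)
    argmin_cut: tuple   # (i', j')
    kappa: int          # contact-free peeled residues in the join step
    ds_per_residue: float


def entropy_per_residue(contact_map: ContactMap, T: float, N: int | None = None) -> float:
    """δs = Σ ε_ij / (T·N), kcal/mol/K (negative with ε < 0).

    At the folding temperature this makes T·ΔS for fully unfolding the
    chain cancel the total contact energy: δs·T·N = Σ ε.
    """
    if contact_map.n_contacts == 0:
        raise ValueError("empty contact map")
    if N is None:
        N = contact_map.n_residues
    if N <= 0 or T <= 0:
        raise ValueError("N and T must be positive")
    return contact_map.total_energy / (T * N)


def termini_offset(structure: CalphaStructure, threshold: float = 0.0) -> int:
    """Turn offset M: 6 if the chain directions at the termini oppose each
    other (dot < threshold), else 0."""
    v_n, v_c = structure.termini_vectors
    return 6 if float(np.dot(v_n, v_c)) < threshold else 0


def _contact_bearing(contact_map: ContactMap, local_sep: int = 2) -> np.ndarray:
    """Boolean per residue (1-based): has a contact beyond sequence
    neighbours (|i−j| > local_sep)."""
    has = np.zeros(contact_map.n_residues + 1, dtype=bool)
    mask = (contact_map.j - contact_map.i) > local_sep
    for a, b in zip(contact_map.i[mask], contact_map.j[mask]):
        has[a] = True
        has[b] = True
    return has


def _broken_energy(contact_map: ContactMap, unfolded: np.ndarray) -> float:
    """|ε| lost by unfolding a residue set: contacts with at least one
    endpoint in the set, each counted once."""
    m = unfolded[contact_map.i] | unfolded[contact_map.j]
    return float(-contact_map.eps[m].sum())


def join_free_energy(
    structure: CalphaStructure,
    contact_map: ContactMap,
    ds: float,
    params: AlchemicalParams,
):
    """Minimal free-energy cost ΔG_J of cyclizing the native state.

    Searches peel counts i ∈ {0..9} (N side) and j ∈ {L−9..L} (C side);
    a combination is feasible when d(R_{i+1}, R_j) < (i + 1 + L − j + ll − M)·r0,
    where ll = ``params.linker_extra`` counts structureless linker residues
    that lengthen the joint loop without costing contacts (longer
    interdomain linkers make circular permutants easier to form).
    Returns (ΔG_J, (i, j), κ).
    """
    L = len(structure)
    coords = structure.coords
    bearing = _contact_bearing(contact_map)
    t_ds = params.T * abs(ds)
    best = None
    for i in range(0, min(params.join_window, L - 2) + 1):
        for j in range(max(L - params.join_window, i + 2), L + 1):
            # peeled residues + linker residues + 1 junction segment
            n_loop = i + 1 + L - j + params.linker_extra
            d = float(np.linalg.norm(coords[j - 1] - coords[i]))  # R_{i+1}, R_j
            if d >= (n_loop - params.M) * params.r0_peel:
                continue
            unfolded = np.zeros(L + 1, dtype=bool)
            unfolded[1:i + 1] = True
            unfolded[j + 1:L + 1] = True
            e_cost = _broken_energy(contact_map, unfolded)
            peeled = np.nonzero(unfolded)[0]
            kappa = int(np.sum(~bearing[peeled])) if len(peeled) else 0
            s_gain = t_ds * (len(peeled) - kappa)
            dg = e_cost - s_gain
            # ties resolve toward the smallest perturbation
            if best is None or dg < best[0] - 1e-12 or (
                abs(dg - best[0]) <= 1e-12 and len(peeled) < best[3]
            ):
                best = (dg, (i, j), kappa, len(peeled))
    if best is None:
        raise RuntimeError(
            "termini cannot be joined within the peel budget: no feasible "
            f"(i, j) in the {params.join_window}-residue windows"
        )
    return best[:3]


def cut_free_energy(
    contact_map: ContactMap,
    K: int,
    ds: float,
    params: AlchemicalParams,
):
    """Minimal free-energy cost ΔG_C of cutting the cyclic state at K.

    Window search i′ ∈ {K−3..K}, j′ ∈ {K+1..K+4}; residues i′+1..K and
    K+1..j′−1 unfold.  Entropy is gained only by contact-bearing residues
    (κ rule), so cutting a contact-free loop costs exactly zero.
    Returns (ΔG_C, (i′, j′)).
    """
    L = contact_map.n_residues
    if K < params.cut_window + 1 or K > L - params.cut_window - 1:
        raise ValueError(
            f"cut position K={K} too close to a chain end for the "
            f"±{params.cut_window} window"
        )
    bearing = _contact_bearing(contact_map)
    t_ds = params.T * abs(ds)
    best = None
    for ip in range(K - params.cut_window, K + 1):
        for jp in range(K + 1, K + params.cut_window + 2):
            unfolded = np.zeros(L + 1, dtype=bool)
            unfolded[ip + 1:K + 1] = True
            unfolded[K + 1:jp] = True
            e_cost = _broken_energy(contact_map, unfolded)
            idx = np.nonzero(unfolded)[0]
            n_eff = int(np.sum(bearing[idx])) if len(idx) else 0
            dg = e_cost - t_ds * n_eff
            if best is None or dg < best[0] - 1e-12 or (
                abs(dg - best[0]) <= 1e-12 and len(idx) < best[2]
            ):
                best = (dg, (ip, jp), len(idx))
    return best[:2]


def ddg_total(
    structure: CalphaStructure,
    contact_map: ContactMap,
    K: int,
    T: float,
    M: int | None = None,
    ds: float | None = None,
    linker_extra: int = 0,
) -> AlchemicalResult:
    """ΔΔG_tot = ΔG_J + ΔG_C for one circular permutant.

    The correlation of −ΔΔG_tot with the permutant stability ΔG_s measured
    by umbrella sampling is the predictor's full-scale validation property;
    it is exercised on toy families in the test suite.
    """
    if ds is None:
        ds = entropy_per_residue(contact_map, T)
    if M is None:
        M = termini_offset(structure)
    params = AlchemicalParams(M=M, T=T, linker_extra=linker_extra)
    dg_j, arg_j, kappa = join_free_energy(structure, contact_map, ds, params)
    dg_c, arg_c = cut_free_energy(contact_map, K, ds, params)
    return AlchemicalResult(
        K=K, dG_J=dg_j, dG_C=dg_c, ddG_tot=dg_j + dg_c,
        argmin_join=arg_j, argmin_cut=arg_c,
        kappa=kappa, ds_per_residue=ds,
    )


def score_all_permutants(
    structure: CalphaStructure,
    contact_map: ContactMap,
    cut_sites: list[CutSite],
    T: float,
    M: int | None = None,
) -> pd.DataFrame:
    """Batch ΔΔG_tot for every candidate cut site, ranked most-stable first."""
    rows = []
    for site in cut_sites:
        if site.K == 0:
            continue
        res = ddg_total(structure, contact_map, site.K, T, M=M)
        rows.append({
            "K": res.K, "dG_J": res.dG_J, "dG_C": res.dG_C,
            "ddG_tot": res.ddG_tot,
            "join_i": res.argmin_join[0], "join_j": res.argmin_join[1],
            "cut_i": res.argmin_cut[0], "cut_j": res.argmin_cut[1],
            "kappa": res.kappa,
        })
    df = pd.DataFrame(rows).sort_values("ddG_tot").reset_index(drop=True)
    return df
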