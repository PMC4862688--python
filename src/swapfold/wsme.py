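"""Single-sequence Wako-Saitô-Muñoz-Eaton model of first-domain formation.

Residues are binary (folded/unfolded) and native structure grows in one
contiguous segment (single-sequence approximation).  A segment state χ has
free energy

    G(χ) = n(χ)·ϵ − N_f(χ)·T·Δs + E_p·θ(χ)

with n(χ) the native contacts fully inside the segment, N_f the segment
length, ϵ < 0 the favourable contact energy, Δs < 0 the per-residue
entropy penalty of folding, and θ(χ) = 1 when the segment crosses the
midpoint of the tandem sequence (contains the bond between residues L and
L+1) — the strain penalty E_p that mimics the destabilization of circular
permutant misfolds.  Segments longer than one repeat (L) are disallowed,
so only the *first* domain (native or permutant) forms.

Both exact enumeration (the oracle) and a Metropolis Monte Carlo chain
over the same state space are provided, plus the F(Q_res, ij̄) surfaces
used to visualize how the penalty suppresses midpoint-crossing minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._kernels import KB
from .go_model import ContactMap

#: temperature of the reference surface plots, K
DEFAULT_T = 525.0
#: default uniform contact energy, kcal/mol
DEFAULT_EPS = -0.5
#: default per-residue folding entropy change, kcal/mol/K
DEFAULT_DS = -0.0017


@dataclass
class WsmeConfig:
    """Parameterization of the tandem WSME model."""

    contact_map: ContactMap  # duplicated tandem map over 2L residues
    L: int
    eps: float | None = DEFAULT_EPS  # None -> use per-contact map energies
    ds: float = DEFAULT_DS
    Ep: float = 0.0
    T: float = DEFAULT_T

    def __post_init__(self):
        if self.Ep < 0:
            raise ValueError("Ep must be >= 0")
        if self.L > self.contact_map.n_residues // 2:
            raise ValueError("L must be at most half the sequence length")

    @property
    def seq_length(self) -> int:
        return self.contact_map.n_residues

    @property
    def kbt(self) -> float:
        return KB * self.T

    def contact_weights(self) -> np.ndarray:
        if self.eps is None:
            return self.contact_map.eps.copy()
        return np.full(self.contact_map.n_contacts, self.eps)


@dataclass(frozen=True)
class WsmeState:
    """Contiguous native segment: start = 0 encodes the fully unfolded state."""

    start: int
    length: int

    def __post_init__(self):
        if self.start == 0 and self.length != 0:
            raise ValueError("empty state must have length 0")
        if self.start > 0 and self.length < 1:
            raise ValueError("non-empty state needs length >= 1")

    @property
    def empty(self) -> bool:
        return self.start == 0

    @property
    def last(self) -> int:
        return self.start + self.length - 1


def _segment_contacts(config: WsmeConfig, start: int, length: int):
    """(weighted contact energy, contact count, midpoint sum) of a segment."""
    cm = config.contact_map
    w = config.contact_weights()
    last = start + length - 1
    inside = (cm.i >= start) & (cm.j <= last)
    return (
        float(w[inside].sum()),
        int(inside.sum()),
        float(((cm.i[inside] + cm.j[inside]) / 2.0).sum()),
    )


def theta_midpoint(config: WsmeConfig, start: int, length: int) -> int:
    """1 iff the segment contains both residue L and residue L+1."""
    if start == 0:
        return 0
    return int(start <= config.L and start + length - 1 >= config.L + 1)


def state_energy(state: WsmeState, config: WsmeConfig) -> float:
    """G(χ) = n(χ)·ϵ − N_f(χ)·T·Δs + E_p·θ(χ), kcal/mol."""
    if state.empty:
        return 0.0
    if state.length > config.L:
        raise ValueError("segment longer than one repeat")
    if state.start < 1 or state.last > config.seq_length:
        raise ValueError("segment outside the chain")
    e_con, _, _ = _segment_contacts(config, state.start, state.length)
    return (
        e_con
        - state.length * config.T * config.ds
        + config.Ep * theta_midpoint(config, state.start, state.length)
    )


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

@dataclass
class WsmeEnsemble:
    """Exhaustively enumerated state space with Boltzmann probabilities."""

    starts: np.ndarray     # start == 0 encodes the empty state
    lengths: np.ndarray
    G: np.ndarray
    p: np.ndarray
    q_res: np.ndarray
    ij_bar: np.ndarray     # NaN when no contact is formed
    theta: np.ndarray
    config: WsmeConfig

    @property
    def Z(self) -> float:
        return float(np.sum(np.exp(-(self.G - self.G.min()) / self.config.kbt)))

    def theta_occupancy(self) -> float:
        return float(np.sum(self.p[self.theta == 1]))


def exact_partition(config: WsmeConfig, max_states: int = 2_000_000) -> WsmeEnsemble:
    """Enumerate the empty state and every (start, length <= L) segment.

    Contact counts are built incrementally while extending each segment,
    so the cost is O(states × mean contact degree).
    """
    n = config.seq_length
    L = config.L
    n_states = 1 + sum(min(L, n - s + 1) for s in range(1, n + 1))
    if n_states > max_states:
        raise ValueError(
            f"state space too large ({n_states} states): use mc_sample"
        )
    cm = config.contact_map
    w = config.contact_weights()
    # adjacency: partners and weights per residue
    partners = [[] for _ in range(n + 1)]
    for k in range(cm.n_contacts):
        partners[cm.i[k]].append((cm.j[k], w[k]))
        partners[cm.j[k]].append((cm.i[k], w[k]))

    starts, lengths, G, qres, ijb, theta = [0], [0], [0.0], [0.0], [np.nan], [0]
    for s in range(1, n + 1):
        e_con = 0.0
        n_con = 0
        mid_sum = 0.0
        for length in range(1, min(L, n - s + 1) + 1):
            r = s + length - 1  # residue being added
            for q, wt in partners[r]:
                if s <= q < r:
                    e_con += wt
                    n_con += 1
                    mid_sum += (q + r) / 2.0
            th = theta_midpoint(config, s, length)
            g = e_con - length * config.T * config.ds + config.Ep * th
            starts.append(s)
            lengths.append(length)
            G.append(g)
            qres.append(length / L)
            ijb.append(mid_sum / n_con if n_con else np.nan)
            theta.append(th)
    G = np.array(G)
    boltz = np.exp(-(G - G.min()) / config.kbt)
    p = boltz / boltz.sum()
    return WsmeEnsemble(
        starts=np.array(starts), lengths=np.array(lengths), G=G, p=p,
        q_res=np.array(qres), ij_bar=np.array(ijb),
        theta=np.array(theta), config=config,
    )


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_loop(
    n, L, kbt, t_ds, ep, nbr_ptr, nbr_idx, nbr_w,
    first0, last0, n_steps, rand_moves, rand_accept, rand_sites,
    counts, stride, rec_first, rec_last,
):
    # first == 0 encodes the empty (fully unfolded) state
    first, last = first0, last0
    accepted = 0
    rejected_constraint = 0
    rec_k = 0
    for step in range(n_steps):
        if first == 0:
            # nucleation: pick a site uniformly; the reverse (vanishing)
            # move is proposed with probability 1/2, hence the Hastings
            # factor L = (1/2)/(1/(2L))
            s = rand_sites[step]
            de = -t_ds  # single residue: no contacts, theta = 0
            a = L * np.exp(-de / kbt)
            if rand_accept[step] < a:
                first = s
                last = s
                accepted += 1
            counts[first, last - first + 1 if first > 0 else 0] += 1
            if stride > 0 and step % stride == 0:
                rec_first[rec_k] = first
                rec_last[rec_k] = last
                rec_k += 1
            continue
        c = rand_moves[step]
        if first == last and (c == 1 or c == 2):
            # vanishing move (both shrink proposals empty the segment):
            # Hastings factor 1/L, inverse of nucleation
            de = t_ds
            a = np.exp(-de / kbt) / L
            if rand_accept[step] < a:
                first = 0
                last = -1
                accepted += 1
            counts[first, last - first + 1 if first > 0 else 0] += 1
            if stride > 0 and step % stride == 0:
                rec_first[rec_k] = first
                rec_last[rec_k] = last
                rec_k += 1
            continue
        nf, nl = first, last
        grow_res = -1
        shrink_res = -1
        if c == 0:
            nf = first - 1
            grow_res = nf
        elif c == 1:
            nf = first + 1
            shrink_res = first
        elif c == 2:
            nl = last - 1
            shrink_res = last
        else:
            nl = last + 1
            grow_res = nl
        ok = True
        if nf < 1 or nl > n or nl < nf:  # off-chain
            ok = False
        elif nl - nf + 1 > L:  # segment longer than one repeat
            ok = False
        if not ok:
            rejected_constraint += 1
        else:
            de = 0.0
            if grow_res >= 0:
                lo = min(first, nf)
                hi = max(last, nl)
                for k in range(nbr_ptr[grow_res], nbr_ptr[grow_res + 1]):
                    q = nbr_idx[k]
                    if lo <= q <= hi and q != grow_res:
                        de += nbr_w[k]
                de -= t_ds
            else:
                for k in range(nbr_ptr[shrink_res], nbr_ptr[shrink_res + 1]):
                    q = nbr_idx[k]
                    if nf <= q <= nl:
                        de -= nbr_w[k]
                de += t_ds
            th_old = 1 if (first <= L and last >= L + 1) else 0
            th_new = 1 if (nf <= L and nl >= L + 1) else 0
            de += ep * (th_new - th_old)
            if de <= 0.0 or rand_accept[step] < np.exp(-de / kbt):
                first, last = nf, nl
                accepted += 1
        counts[first, last - first + 1] += 1
        if stride > 0 and step % stride == 0:
            rec_first[rec_k] = first
            rec_last[rec_k] = last
            rec_k += 1
    return accepted, rejected_constraint, rec_k


def mc_sample(
    config: WsmeConfig,
    n_steps: int,
    seed: int = 0,
    initial: WsmeState | None = None,
    record_stride: int = 0,
):
    """Metropolis chain over segment states.

    One randomly chosen residue among {first−1, first, last, last+1} is
    flipped; proposals that break contiguity, leave the chain, or exceed
    length L are rejected and counted.  Acceptance for these moves is
    min[1, exp(−ΔE/k_BT)].  The fully unfolded state is reachable through
    vanishing/nucleation moves, which carry the Metropolis–Hastings
    proposal-ratio factor (a nucleation site is drawn uniformly from the
    chain, while vanishing is proposed with probability 1/2) so that the
    chain targets exactly the enumerated ensemble.  Returns (occupancy
    counts over (start, length), stats dict, optional recorded state
    trajectory).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = config.seq_length
    cm = config.contact_map
    w = config.contact_weights()
    deg = np.zeros(n + 2, dtype=np.int64)
    for k in range(cm.n_contacts):
        deg[cm.i[k]] += 1
        deg[cm.j[k]] += 1
    nbr_ptr = np.zeros(n + 2, dtype=np.int64)
    nbr_ptr[1:] = np.cumsum(deg[:-1])
    fill = nbr_ptr.copy()
    nbr_idx = np.zeros(2 * cm.n_contacts, dtype=np.int64)
    nbr_w = np.zeros(2 * cm.n_contacts)
    for k in range(cm.n_contacts):
        a, b = cm.i[k], cm.j[k]
        nbr_idx[fill[a]] = b
        nbr_w[fill[a]] = w[k]
        fill[a] += 1
        nbr_idx[fill[b]] = a
        nbr_w[fill[b]] = w[k]
        fill[b] += 1

    rng = np.random.default_rng(seed)
    if initial is None:
        initial = WsmeState(start=int(rng.integers(1, n + 1)), length=1)
    rand_moves = rng.integers(0, 4, size=n_steps).astype(np.int64)
    rand_accept = rng.random(size=n_steps)
    rand_sites = rng.integers(1, n + 1, size=n_steps).astype(np.int64)
    counts = np.zeros((n + 2, config.L + 2), dtype=np.int64)
    n_rec = n_steps // record_stride + 1 if record_stride else 1
    rec_first = np.zeros(n_rec, dtype=np.int64)
    rec_last = np.zeros(n_rec, dtype=np.int64)
    accepted, rejected, rec_k = _mc_loop(
        n, config.L, config.kbt, config.T * config.ds, config.Ep,
        nbr_ptr, nbr_idx, nbr_w,
        initial.start, initial.start + initial.length - 1 if initial.start else -1,
        n_steps,
        rand_moves, rand_accept, rand_sites, counts,
        record_stride, rec_first, rec_last,
    )
    stats = {
        "accepted": int(accepted),
        "rejected_constraint": int(rejected),
        "acceptance_rate": accepted / n_steps,
    }
    record = None
    if record_stride:
        record = np.stack(
            [rec_first[:rec_k], rec_last[:rec_k] - rec_first[:rec_k] + 1], axis=1
        )
    return counts, stats, record


def mc_probabilities(counts: np.ndarray) -> dict:
    """Normalized empirical state probabilities {(start, length): p}."""
    total = counts.sum()
    out = {}
    nz = np.nonzero(counts)
    for s, ln in zip(*nz):
        out[(int(s), int(ln))] = counts[s, ln] / total
    return out


def total_variation(ensemble: WsmeEnsemble, counts: np.ndarray) -> float:
    """TV distance between exact state probabilities and MC occupancy."""
    emp = mc_probabilities(counts)
    tv = 0.0
    seen = set()
    for s, ln, p in zip(ensemble.starts, ensemble.lengths, ensemble.p):
        key = (int(s), int(ln))
        tv += abs(p - emp.get(key, 0.0))
        seen.add(key)
    for key, p in emp.items():
        if key not in seen:
            tv += p
    return 0.5 * tv


def theta_occupancy_mc(config: WsmeConfig, counts: np.ndarray) -> float:
    occ = 0.0
    total = counts.sum()
    nz = np.nonzero(counts)
    for s, ln in zip(*nz):
        if s >= 1 and theta_midpoint(config, int(s), int(ln)):
            occ += counts[s, ln]
    return occ / total


# ---------------------------------------------------------------------------
# F(Q_res, ij_bar) surfaces
# ---------------------------------------------------------------------------

def wsme_surface(
    ensemble: WsmeEnsemble | None = None,
    config: WsmeConfig | None = None,
    counts: np.ndarray | None = None,
    ij_bin: float = 1.0,
):
    """2D free-energy table F(Q_res, ij̄) from exact probabilities or MC counts.

    Segments with no formed contact are placed at their sequence midpoint.
    Unreachable cells hold NaN (flagged, never 0); F is min-shifted to 0.
    Returns (q_grid, ij_grid, F).
    """
    if ensemble is not None:
        config = ensemble.config
        starts, lengths, p = ensemble.starts, ensemble.lengths, ensemble.p
        ij = ensemble.ij_bar.copy()
        qres = ensemble.q_res
    elif counts is not None and config is not None:
        probs = mc_probabilities(counts)
        starts = np.array([k[0] for k in probs])
        lengths = np.array([k[1] for k in probs])
        p = np.array(list(probs.values()))
        qres = np.where(starts > 0, lengths / config.L, 0.0)
        ij = np.full(len(starts), np.nan)
        for k, (s, ln) in enumerate(zip(starts, lengths)):
            if s > 0:
                _, ncon, midsum = _segment_contacts(config, int(s), int(ln))
                ij[k] = midsum / ncon if ncon else np.nan
    else:
        raise ValueError("provide an ensemble or (config, counts)")
    # contact-free (but nonempty) segments sit at their sequence midpoint
    seg_mid = np.where(starts > 0, starts + (lengths - 1) / 2.0, np.nan)
    ij = np.where(np.isnan(ij) & (starts > 0), seg_mid, ij)

    n = config.seq_length
    q_grid = np.arange(0, config.L + 1) / config.L
    ij_edges = np.arange(0.5, n + 1.5 + ij_bin, ij_bin)
    ij_grid = 0.5 * (ij_edges[:-1] + ij_edges[1:])
    P = np.zeros((len(q_grid), len(ij_grid)))
    for s, ln, pij, pk in zip(starts, lengths, ij, p):
        qi = int(ln) if s > 0 else 0
        if np.isnan(pij):
            ji = 0
        else:
            ji = int(np.clip(np.searchsorted(ij_edges, pij) - 1, 0, len(ij_grid) - 1))
        P[qi, ji] += pk
    F = np.full_like(P, np.nan)
    mask = P > 0
    F[mask] = -config.kbt * np.log(P[mask])
    F -= np.nanmin(F)
    return q_grid, ij_grid, F
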