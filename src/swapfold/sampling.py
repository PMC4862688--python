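"""Langevin dynamics, first-passage misfolding campaigns, umbrella sampling
and WHAM free-energy analysis.

The integrator is BAOAB underdamped Langevin with friction 0.1 ps⁻¹ and a
10 fs time step by default, uniform residue mass, seeded and
bit-reproducible.  First-passage campaigns start every trajectory from a
fully extended chain and classify the final frame against the contact sets
of the native fold (K = 0) and each circular-permutant misfold.  Umbrella
sampling applies a harmonic bias on the logistic contact coordinate Q and
the profiles F(Q) are recovered by self-consistent WHAM; ΔG_s and ΔG_f are
read off the profile with the stable-fold-positive sign convention.

Desk-scale defaults (tens to a few hundred trajectories on toy models) are
used throughout; campaigns of 1024 × 12 μs on real protein models are
configuration-exposed but are cluster-scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import KB, RESIDUE_MASS
from .go_model import TandemModel, Topology
from .permutants import PermutantContactSets, QParams, q_k
from .structures import fully_extended_coords

#: full-scale campaign settings (cluster-scale; desk defaults are far smaller)
FULL_SCALE_N_TRAJ = 1024
FULL_SCALE_T_MAX_PS = 12_000_000.0  # 12 us


@dataclass
class LangevinParams:
    """Integrator parameters: friction ps⁻¹, dt ps, temperature K."""

    temperature: float = 300.0
    friction: float = 0.1
    dt: float = 0.01  # 10 fs
    seed: int = 0
    n_steps: int = 10000

    def __post_init__(self):
        if self.dt <= 0 or self.friction <= 0:
            raise ValueError("dt and friction must be positive")


@dataclass
class Trajectory:
    frames: np.ndarray          # (n_saved, n, 3)
    energies: np.ndarray        # (n_saved,)
    params: LangevinParams
    final_coords: np.ndarray = None

    def __post_init__(self):
        if self.final_coords is None:
            self.final_coords = self.frames[-1]


class EnergyBlowupError(RuntimeError):
    pass


def _kernel_args(topo: Topology, tether=None, bias=None):
    n = topo.n
    if tether is None:
        teth_k = np.zeros(n)
        teth_center = np.zeros((n, 3))
    else:
        teth_k, teth_center = tether
        teth_k = np.asarray(teth_k, float)
        teth_center = np.asarray(teth_center, float)
    if bias is None:
        bias_i = np.empty(0, np.int64)
        bias_j = np.empty(0, np.int64)
        bias_r0 = np.empty(0)
        bias_kappa, bias_q0, bias_beta, bias_lam = 0.0, 0.0, 50.0, 1.2
    else:
        bias_i, bias_j, bias_r0, bias_kappa, bias_q0, bias_beta, bias_lam = bias
    return (
        topo.bond_i.astype(np.int64), topo.bond_j.astype(np.int64),
        topo.bond_r0, topo.bond_k,
        topo.ang_i.astype(np.int64), topo.ang_j.astype(np.int64),
        topo.ang_k.astype(np.int64), topo.ang_theta0, topo.ang_kth,
        topo.dih_i.astype(np.int64), topo.dih_j.astype(np.int64),
        topo.dih_k.astype(np.int64), topo.dih_l.astype(np.int64),
        topo.dih_phi0, topo.dih_k1, topo.dih_k3,
        topo.con_i.astype(np.int64), topo.con_j.astype(np.int64),
        topo.con_eps, topo.con_r0,
        topo.sigma, topo.native_pair_mask(), topo.min_seq_sep,
        teth_k, teth_center,
        bias_i.astype(np.int64), bias_j.astype(np.int64), bias_r0,
        float(bias_kappa), float(bias_q0), float(bias_beta), float(bias_lam),
    )


def langevin_run(
    model,
    params: LangevinParams,
    initial: np.ndarray,
    save_stride: int = 1000,
    tether=None,
    bias=None,
    chunk: int = 1000,
    stop_condition=None,
) -> Trajectory:
    """Run seeded BAOAB Langevin dynamics.

    ``model`` is anything with a ``.topology``; ``bias`` an optional
    umbrella restraint tuple; ``stop_condition(coords) -> bool`` is checked
    between chunks for early termination (first-passage runs).  Raises
    :class:`EnergyBlowupError` on numerical explosion.
    """
    topo: Topology = model.topology if hasattr(model, "topology") else model
    coords = np.array(initial, dtype=float)
    if coords.shape != (topo.n, 3):
        raise ValueError("initial coordinates do not match the model")
    if np.any(~np.isfinite(coords)):
        raise ValueError("initial coordinates contain NaN")
    rng = np.random.default_rng(params.seed)
    kbt = KB * params.temperature
    vel = rng.normal(scale=np.sqrt(kbt / RESIDUE_MASS), size=(topo.n, 3))
    forces = np.zeros((topo.n, 3))
    args = _kernel_args(topo, tether=tether, bias=bias)

    frames, energies = [], []
    done = 0
    e_scale = max(abs(topo.con_eps.sum()), 1.0)
    while done < params.n_steps:
        this = min(chunk, params.n_steps - done)
        noise = rng.normal(size=(this, topo.n, 3))
        energy = _kernels.baoab_chunk(
            coords, vel, noise, params.dt, params.friction, kbt,
            RESIDUE_MASS, *args, forces,
        )
        done += this
        if not np.isfinite(energy) or energy > 1e4 * e_scale:
            raise EnergyBlowupError(
                f"energy blow-up at step {done}: E = {energy:.3g} kcal/mol"
            )
        if done % save_stride == 0 or done == params.n_steps:
            frames.append(coords.copy())
            energies.append(energy)
        if stop_condition is not None and stop_condition(coords):
            break
    return Trajectory(
        frames=np.array(frames), energies=np.array(energies),
        params=params, final_coords=coords.copy(),
    )


# ---------------------------------------------------------------------------
# State classification and first-passage campaigns
# ---------------------------------------------------------------------------

def classify_state(
    coords: np.ndarray,
    all_sets: list[PermutantContactSets],
    threshold: float = 0.8,
    qparams: QParams = QParams(),
):
    """Label a frame: K if Q_in,K and Q_out,K both exceed the threshold,
    else "incomplete".  Ties break toward the highest min(Q_in, Q_out)."""
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must be in (0.5, 1)")
    best, best_score = "incomplete", -1.0
    for sets in all_sets:
        qi = q_k(coords, sets, "in", qparams)
        qo = q_k(coords, sets, "out", qparams)
        score = min(qi, qo)
        if qi >= threshold and qo >= threshold and score > best_score:
            best, best_score = sets.K, score
    return best


def first_passage_campaign(
    model: TandemModel,
    all_sets: list[PermutantContactSets],
    n_traj: int,
    t_max_steps: int,
    params: LangevinParams,
    threshold: float = 0.8,
    check_every: int = 4000,
    record_final_q: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Independent folding runs from fully extended chains.

    Each trajectory gets its own seed derived from ``params.seed``; runs
    terminate at first passage into a labelled state or at ``t_max_steps``.
    Returns the per-trajectory outcome table and a population summary with
    binomial standard errors.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rows = []
    for t in range(n_traj):
        seed = (params.seed * 100003 + t) % (2**31 - 1)
        rng0 = np.random.default_rng(seed + 7)
        start = fully_extended_coords(model.topology.n, rng=rng0)
        p = LangevinParams(
            temperature=params.temperature, friction=params.friction,
            dt=params.dt, seed=seed, n_steps=t_max_steps,
        )
        label_holder = {}

        def stop(coords):
            lab = classify_state(coords, all_sets, threshold)
            if lab != "incomplete":
                label_holder["label"] = lab
                return True
            return False

        traj = langevin_run(
            model, p, start, save_stride=t_max_steps,
            chunk=check_every, stop_condition=stop,
        )
        label = label_holder.get(
            "label", classify_state(traj.final_coords, all_sets, threshold)
        )
        row = {"trajectory_id": t, "seed": seed, "final_label": label}
        if record_final_q:
            for sets in all_sets:
                row[f"q_in_{sets.K}"] = q_k(traj.final_coords, sets, "in")
                row[f"q_out_{sets.K}"] = q_k(traj.final_coords, sets, "out")
        rows.append(row)
    outcomes = pd.DataFrame(rows)
    labels = ["native" if s.K == 0 else s.K for s in all_sets] + ["incomplete"]
    outcomes["final_label"] = outcomes["final_label"].map(
        lambda x: "native" if x == 0 else x
    )
    counts = {lab: int((outcomes["final_label"] == lab).sum()) for lab in labels}
    summary = pd.DataFrame(
        {
            "label": list(counts),
            "count": list(counts.values()),
        }
    )
    summary["fraction"] = summary["count"] / n_traj
    summary["stderr"] = np.sqrt(
        summary["fraction"] * (1 - summary["fraction"]) / n_traj
    )
    return outcomes, summary


# ---------------------------------------------------------------------------
# Umbrella sampling + WHAM
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    center: float
    kappa: float          # kcal/mol per unit Q^2
    samples: np.ndarray   # Q values
    seed: int = 0


@dataclass
class FreeEnergyProfile:
    """F(Q) on a grid at temperature T, shifted so min F = 0."""

    grid: np.ndarray
    F: np.ndarray
    temperature: float
    coordinate_id: object = 0

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        self.F = self.F - np.nanmin(self.F)


def umbrella_sampling(
    model,
    contact_arrays,
    params: LangevinParams,
    centers: np.ndarray,
    kappa: float = 50.0,
    n_steps: int = 60000,
    n_equil: int = 10000,
    sample_stride: int = 50,
    initial: np.ndarray | None = None,
    qparams: QParams = QParams(),
    bidirectional: bool = False,
) -> list[UmbrellaWindow]:
    """Harmonic-bias windows along the logistic contact coordinate.

    ``contact_arrays`` is (i, j, r0) with 1-based indices selecting the
    contacts that define Q.  Windows are visited from high to low center,
    each starting from the previous window's final frame (the first from
    ``initial``); with ``bidirectional`` a second sweep climbs up from a
    fully extended chain and the two passes are pooled per window, which
    cancels most walking-direction hysteresis.  Neighbouring windows
    whose sample histograms do not overlap raise an error naming the gap.
    """
    ii, jj, r0 = contact_arrays
    topo = model.topology if hasattr(model, "topology") else model
    if initial is None:
        raise ValueError("initial coordinates required")
    rng = np.random.default_rng(params.seed)

    def sweep(start_coords, order):
        coords = np.array(start_coords, float)
        out = {}
        for w in order:
            qc = float(centers[w])
            seed = int(rng.integers(2**31 - 1))
            bias = (ii - 1, jj - 1, r0, kappa, qc, qparams.beta, qparams.lam)
            p = LangevinParams(
                temperature=params.temperature, friction=params.friction,
                dt=params.dt, seed=seed, n_steps=n_equil,
            )
            traj = langevin_run(model, p, coords, save_stride=n_equil, bias=bias)
            coords = traj.final_coords
            # production: sample Q every stride
            p2 = LangevinParams(
                temperature=params.temperature, friction=params.friction,
                dt=params.dt, seed=seed + 1, n_steps=n_steps,
            )
            traj = langevin_run(
                model, p2, coords, save_stride=sample_stride, bias=bias,
                chunk=sample_stride,
            )
            samples = [_q_of_arrays(f, ii, jj, r0, qparams) for f in traj.frames]
            coords = traj.final_coords
            out[w] = (qc, np.array(samples), seed)
        return out

    down = sweep(initial, np.argsort(centers)[::-1])  # folded, walking down
    passes = [down]
    if bidirectional:
        up = sweep(fully_extended_coords(topo.n), np.argsort(centers))
        passes.append(up)
    windows = []
    for w in range(len(centers)):
        qc = float(centers[w])
        samples = np.concatenate([p[w][1] for p in passes])
        windows.append(UmbrellaWindow(center=qc, kappa=kappa,
                                      samples=samples, seed=passes[0][w][2]))
    windows.sort(key=lambda w: w.center)
    _check_overlap(windows)
    return windows


def _q_of_arrays(coords, ii, jj, r0, qparams=QParams()):
    r = np.linalg.norm(coords[jj - 1] - coords[ii - 1], axis=1)
    x = np.clip(qparams.beta * (r - qparams.lam * r0), -500, 500)
    return float(np.mean(1.0 / (1.0 + np.exp(x))))


def _check_overlap(windows: list[UmbrellaWindow]):
    for a, b in zip(windows[:-1], windows[1:]):
        lo_a, hi_a = a.samples.min(), a.samples.max()
        lo_b, hi_b = b.samples.min(), b.samples.max()
        if hi_a < lo_b or hi_b < lo_a:
            raise RuntimeError(
                f"umbrella windows at Q={a.center:.2f} and Q={b.center:.2f} "
                f"do not overlap (ranges [{lo_a:.2f},{hi_a:.2f}] vs "
                f"[{lo_b:.2f},{hi_b:.2f}])"
            )


def wham(
    windows: list[UmbrellaWindow],
    temperature: float,
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 50000,
    grid_range: tuple = (-0.05, 1.05),
) -> FreeEnergyProfile:
    """Self-consistent WHAM unbiasing of harmonic umbrella windows."""
    kbt = KB * temperature
    edges = np.arange(grid_range[0], grid_range[1] + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win = len(windows)
    hist = np.zeros((n_win, len(centers)))
    n_samples = np.zeros(n_win)
    for w, win in enumerate(windows):
        hist[w], _ = np.histogram(win.samples, bins=edges)
        n_samples[w] = len(win.samples)
    bias = np.array(
        [0.5 * win.kappa * (centers - win.center) ** 2 for win in windows]
    )
    boltz = np.exp(-bias / kbt)
    f = np.zeros(n_win)
    total = hist.sum(axis=0)
    for it in range(max_iter):
        denom = (n_samples[:, None] * np.exp(f[:, None] / kbt) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        z = (boltz * p[None, :]).sum(axis=1)
        f_new = -kbt * np.log(np.where(z > 0, z, 1e-300))
        f_new -= f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            break
    else:
        raise RuntimeError(f"WHAM did not converge: residual {delta:.3g}")
    mask = p > 0
    F = np.full_like(p, np.nan)
    F[mask] = -kbt * np.log(p[mask])
    keep = ~np.isnan(F)
    return FreeEnergyProfile(
        grid=centers[keep], F=F[keep], temperature=temperature,
    )


def profile_from_unbiased(samples, temperature, bin_width=0.01):
    """Degenerate single-window case: F = −kT log histogram."""
    win = UmbrellaWindow(center=0.0, kappa=0.0, samples=np.asarray(samples))
    return wham([win], temperature, bin_width=bin_width)


# ---------------------------------------------------------------------------
# Profile analysis
# ---------------------------------------------------------------------------

def _two_state_split(profile: FreeEnergyProfile):
    """Positions of the two lowest minima and the top of the barrier
    between them.  Raises on profiles without two-state structure."""
    F, grid = profile.F, profile.grid
    mins = [
        k for k in range(1, len(F) - 1)
        if F[k] <= F[k - 1] and F[k] <= F[k + 1]
    ]
    if len(F) >= 2 and F[0] < F[1]:
        mins.insert(0, 0)
    if len(F) >= 2 and F[-1] < F[-2]:
        mins.append(len(F) - 1)
    # deduplicate plateaus: keep local minima separated by a rise
    if len(mins) < 2:
        raise ValueError("no two-state structure: profile has fewer than two minima")
    best = None
    for a in range(len(mins)):
        for b in range(a + 1, len(mins)):
            ka, kb = mins[a], mins[b]
            kbar = ka + int(np.argmax(F[ka:kb + 1]))
            barrier = F[kbar] - max(F[ka], F[kb])
            if barrier <= 0.0:
                continue
            depth = -(F[ka] + F[kb])
            if best is None or depth > best[0]:
                best = (depth, ka, kb, kbar)
    if best is None:
        raise ValueError("no two-state structure: no interior barrier found")
    _, ka, kb, kbar = best
    return ka, kb, kbar


def stability_from_profile(profile: FreeEnergyProfile, q_dagger: float | None = None):
    """ΔG_s with the stable-fold-positive convention, plus Q_‡ and Q_u.

    ΔG_s = k_BT ln [∫_{Q_‡}^{1} e^{−F/kT} dQ / ∫_0^{Q_‡} e^{−F/kT} dQ]:
    positive when the folded (high-Q) basin carries more weight.  Q_‡ is
    located automatically as the top of the highest interior barrier; for
    weakly cooperative profiles without a barrier an explicit dividing
    point ``q_dagger`` may be supplied instead (the quadrature is
    well-defined for any split).
    """
    kbt = KB * profile.temperature
    if q_dagger is None:
        ka, kb, kbar = _two_state_split(profile)
        q_dagger = float(profile.grid[kbar])
        q_u = float(profile.grid[min(ka, kb)])
    else:
        lo_mask = profile.grid <= q_dagger
        if not lo_mask.any() or lo_mask.all():
            raise ValueError("q_dagger outside the profile grid")
        q_u = float(profile.grid[lo_mask][np.argmin(profile.F[lo_mask])])
    w = np.exp(-(profile.F - profile.F.min()) / kbt)
    lo = profile.grid <= q_dagger
    hi = profile.grid >= q_dagger
    z_u = np.trapezoid(w[lo], profile.grid[lo])
    z_f = np.trapezoid(w[hi], profile.grid[hi])
    dg_s = kbt * np.log(z_f / z_u)
    return float(dg_s), q_dagger, q_u


def barrier_from_profile(profile: FreeEnergyProfile):
    """ΔG_f = F(Q_‡) − F(Q_u), the folding barrier seen from the unfolded
    (low-Q) minimum."""
    ka, kb, kbar = _two_state_split(profile)
    k_u = min(ka, kb)
    return float(profile.F[kbar] - profile.F[k_u]), float(profile.grid[kbar])


# ---------------------------------------------------------------------------
# Temperature selection
# ---------------------------------------------------------------------------

def _domain_profile(model, params, n_steps, n_equil, centers, kappa):
    cm = model.contact_map
    arrays = (cm.i, cm.j, cm.r0)
    windows = umbrella_sampling(
        model, arrays, params, centers, kappa=kappa,
        n_steps=n_steps, n_equil=n_equil,
        initial=model.structure.coords.copy(),
    )
    return wham(windows, params.temperature)


def select_temperature(
    model=None,
    t_range: tuple = (250.0, 500.0),
    target_barrier_kbt: float = 2.5,
    tol_kbt: float = 0.1,
    seed: int = 0,
    n_windows: int = 14,
    kappa: float = 40.0,
    n_steps: int = 40000,
    n_equil: int = 8000,
    max_bisect: int = 12,
    report_tm: bool = True,
    profiler=None,
    q_dagger: float | None = None,
):
    """Pick the working temperature where ΔG_f ≈ 2.5 k_BT (bisection),
    optionally also bracketing the melting temperature (ΔG_s = 0).

    ``profiler(T) -> FreeEnergyProfile`` defaults to umbrella sampling +
    WHAM on the model's native-contact coordinate.  Returns
    (temperature, {scan table, tm}).  The scan table records every
    (T, ΔG_f/k_BT, ΔG_s) probed, and is included in the error message
    when no temperature in range meets the barrier criterion.
    """
    if profiler is None:
        if model is None:
            raise ValueError("provide a model or a profiler")
        centers = np.linspace(0.02, 0.98, n_windows)

        def profiler(T):
            p = LangevinParams(temperature=T, seed=seed, n_steps=0)
            return _domain_profile(model, p, n_steps, n_equil, centers, kappa)

    scan = []

    def probe(T):
        prof = profiler(T)
        try:
            dgf, _ = barrier_from_profile(prof)
            dgs, _, _ = stability_from_profile(prof, q_dagger=q_dagger)
        except ValueError:
            try:
                dgs, _, _ = stability_from_profile(prof, q_dagger=q_dagger or 0.5)
            except ValueError:
                dgs = np.nan
            scan.append((T, np.nan, dgs))
            return None
        scan.append((T, dgf / (KB * T), dgs))
        return dgf / (KB * T), dgs

    lo, hi = t_range
    r_lo, r_hi = probe(lo), probe(hi)

    def excess(res):
        return None if res is None else res[0] - target_barrier_kbt

    e_lo, e_hi = excess(r_lo), excess(r_hi)
    if e_lo is None or e_hi is None or e_lo * e_hi > 0:
        table = pd.DataFrame(scan, columns=["T", "dGf_kbt", "dGs"])
        raise RuntimeError(
            "no temperature in range satisfies the barrier criterion; "
            f"scan:\n{table}"
        )
    t_sel = 0.5 * (lo + hi)
    for _ in range(max_bisect):
        t_sel = 0.5 * (lo + hi)
        res = probe(t_sel)
        e = excess(res)
        if e is None:
            break
        if abs(e) < tol_kbt:
            break
        if e * e_lo > 0:
            lo, e_lo = t_sel, e
        else:
            hi = t_sel
    tm = None
    if report_tm:
        s = [(T, dgs) for T, _, dgs in scan if np.isfinite(dgs)]
        s.sort()
        for (t1, g1), (t2, g2) in zip(s[:-1], s[1:]):
            if g1 > 0 >= g2:
                tm = t1 + (t2 - t1) * g1 / (g1 - g2)
                break
    table = pd.DataFrame(scan, columns=["T", "dGf_kbt", "dGs"])
    return t_sel, {"scan": table, "tm": tm}


# ---------------------------------------------------------------------------
# Nucleus location distribution p(ij_bar | Q)
# ---------------------------------------------------------------------------

def nucleus_location_distribution(
    frames: np.ndarray,
    tandem: TandemModel,
    q_value: float,
    q_tol: float = 0.02,
    bins: np.ndarray | None = None,
    lam: float = 1.2,
):
    """Histogram of the contact-midpoint order parameter ij̄ over frames in
    a global-Q band.

    Global Q counts formed contacts among *all* native and native-like
    (swap-copy) pairs, divided by the number of contacts in the native
    dimer state (2 × per-domain contacts), so Q ≈ 0.5 is one folded domain.
    """
    dup = tandem.duplicated_contacts
    n_native_dimer = dup.n_contacts // 2
    vals = []
    for frame in frames:
        r = np.linalg.norm(frame[dup.j - 1] - frame[dup.i - 1], axis=1)
        formed = r < lam * dup.r0
        qg = formed.sum() / n_native_dimer
        if abs(qg - q_value) <= q_tol:
            if formed.any():
                vals.append(float(np.mean((dup.i[formed] + dup.j[formed]) / 2.0)))
    if not vals:
        raise ValueError(f"no frames in the Q band {q_value} ± {q_tol}")
    if bins is None:
        bins = np.linspace(1, tandem.n_residues, 41)
    hist, edges = np.histogram(vals, bins=bins)
    hist = hist / hist.sum()
    return hist, edges, np.array(vals)
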