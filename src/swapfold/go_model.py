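"""Structure-based (Gō-type) energy models for single domains and tandem dimers.

One bead per residue.  Native contacts (Cα pairs within a cutoff, separated
by more than two residues in sequence) are attractive 12-10 wells whose
relative depths follow the Miyazawa-Jernigan contact potential; all other
non-bonded pairs are purely repulsive.  Bonded terms are harmonic bonds and
angles at their native values plus a two-term cosine dihedral.  This is a
documented simplified variant of the classic one-bead structure-based
force field; the analyses built on it are property- and statistics-based
rather than force-field-exact.

The tandem dimer duplicates every native contact across the two repeats
with equal strength:  E(i,j) = E(i+L,j) = E(i,j+L) = E(i+L,j+L), where L is
the repeat length (domain plus interdomain linker).  This is what permits
domain-swapped misfolds built from native-like interactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mj import mj_energy
from .structures import CA_BOND, CalphaStructure

#: default Cα-Cα contact cutoff, nm
DEFAULT_CUTOFF = 0.8
#: default minimum sequence separation for a contact (j - i >= 3)
DEFAULT_MIN_SEQ_SEP = 3
#: default mean |ε| of native wells, kcal/mol
DEFAULT_ENERGY_UNIT = 0.7

K_BOND = 2000.0   # kcal/mol/nm^2
K_ANGLE = 40.0    # kcal/mol/rad^2
K_ANGLE_LINKER = 10.0
THETA0_LINKER = np.deg2rad(130.0)
K_DIH_1 = 1.0     # kcal/mol
K_DIH_3 = 0.5     # kcal/mol
EPS_REP = 0.2     # kcal/mol, repulsive prefactor

#: per-residue excluded-volume radii, nm (small for Gly/Ser linkers)
SIGMA = {"G": 0.33, "S": 0.36, "A": 0.37}
SIGMA_DEFAULT = 0.40


def _sigma_for(seq: str) -> np.ndarray:
    return np.array([SIGMA.get(aa, SIGMA_DEFAULT) for aa in seq])


@dataclass
class ContactMap:
    """Weighted native contact set.  Indices are 1-based, stored min-first."""

    i: np.ndarray
    j: np.ndarray
    eps: np.ndarray  # kcal/mol, negative = favourable
    r0: np.ndarray   # nm
    n_residues: int
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.eps = np.asarray(self.eps, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        swap = self.i > self.j
        if np.any(swap):
            self.i[swap], self.j[swap] = self.j[swap].copy(), self.i[swap].copy()
        if np.any(self.j - self.i <= 2):
            raise ValueError("contacts must be separated by more than two residues")
        if len(self.eps) and np.any(self.eps >= 0):
            raise ValueError("contact energies must be negative (favourable)")
        if len(self.r0) and np.any(self.r0 <= 0):
            raise ValueError("native distances must be positive")
        if len({(a, b) for a, b in zip(self.i, self.j)}) != len(self.i):
            raise ValueError("duplicate contact pair")

    @property
    def n_contacts(self) -> int:
        return len(self.i)

    @property
    def total_energy(self) -> float:
        return float(self.eps.sum())

    def pairs(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in zip(self.i, self.j)}

    def contacts_of(self, residue: int) -> np.ndarray:
        """Indices into the contact arrays of contacts involving ``residue``."""
        return np.nonzero((self.i == residue) | (self.j == residue))[0]


def build_contact_map(
    structure: CalphaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    energy_unit: float = DEFAULT_ENERGY_UNIT,
) -> ContactMap:
    """Native contacts from Cα geometry.

    A pair (i, j) is a contact iff the native Cα-Cα distance is below
    ``cutoff`` and j - i >= ``min_seq_sep``.  Well depths are the MJ
    energies for the residue pair, rescaled so the mean |ε| equals
    ``energy_unit`` (only relative MJ energies are meaningful).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_seq_sep < 3:
        raise ValueError("min_seq_sep must be >= 3")
    n = len(structure)
    warnings = []
    if n < min_seq_sep + 1:
        warnings.append("structure shorter than min_seq_sep + 1: empty contact map")
        return ContactMap(
            i=np.empty(0, int), j=np.empty(0, int),
            eps=np.empty(0), r0=np.empty(0),
            n_residues=n, warnings=warnings,
        )
    coords = structure.coords
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.nonzero((dist < cutoff) & (np.subtract.outer(np.arange(n), np.arange(n)) <= -min_seq_sep))
    raw = np.array([mj_energy(structure.sequence[a], structure.sequence[b]) for a, b in zip(ii, jj)])
    if len(raw):
        raw = raw * (energy_unit / np.mean(np.abs(raw)))
    return ContactMap(
        i=ii + 1, j=jj + 1, eps=raw, r0=dist[ii, jj],
        n_residues=n, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Topology: the flat parameter arrays consumed by the integrator
# ---------------------------------------------------------------------------

@dataclass
class Topology:
    """Flat bonded/non-bonded parameter tables for one chain."""

    n: int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_theta0: np.ndarray
    ang_kth: np.ndarray
    dih_i: np.ndarray
    dih_j: np.ndarray
    dih_k: np.ndarray
    dih_l: np.ndarray
    dih_phi0: np.ndarray
    dih_k1: np.ndarray
    dih_k3: np.ndarray
    con_i: np.ndarray  # 0-based
    con_j: np.ndarray
    con_eps: np.ndarray  # negative
    con_r0: np.ndarray
    sigma: np.ndarray  # per bead, nm
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP

    def native_pair_mask(self) -> np.ndarray:
        m = np.zeros((self.n, self.n), dtype=bool)
        m[self.con_i, self.con_j] = True
        m[self.con_j, self.con_i] = True
        return m


def _dihedral_angles(coords: np.ndarray) -> np.ndarray:
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def _bend_angles(coords: np.ndarray) -> np.ndarray:
    v1 = coords[:-2] - coords[1:-1]
    v2 = coords[2:] - coords[1:-1]
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _build_topology(
    coords: np.ndarray,
    sequence: str,
    contact_map: ContactMap,
    native_mask_beads: np.ndarray,
) -> Topology:
    """Bonded terms from native geometry.  Beads where ``native_mask_beads``
    is False (linkers) get generic bonds/angles and no dihedral bias."""
    n = len(coords)
    idx = np.arange(n)
    bond_i, bond_j = idx[:-1], idx[1:]
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    bond_r0 = np.where(
        native_mask_beads[:-1] & native_mask_beads[1:], d, CA_BOND
    )
    bond_k = np.full(n - 1, K_BOND)

    ang_i, ang_j, ang_k = idx[:-2], idx[1:-1], idx[2:]
    native_ang = (
        native_mask_beads[:-2] & native_mask_beads[1:-1] & native_mask_beads[2:]
    )
    theta_native = _bend_angles(coords)
    ang_theta0 = np.where(native_ang, theta_native, THETA0_LINKER)
    ang_kth = np.where(native_ang, K_ANGLE, K_ANGLE_LINKER)

    dih_i, dih_j, dih_k, dih_l = idx[:-3], idx[1:-2], idx[2:-1], idx[3:]
    native_dih = (
        native_mask_beads[:-3] & native_mask_beads[1:-2]
        & native_mask_beads[2:-1] & native_mask_beads[3:]
    )
    phi_native = _dihedral_angles(coords)
    dih_phi0 = np.where(native_dih, phi_native, 0.0)
    dih_k1 = np.where(native_dih, K_DIH_1, 0.0)
    dih_k3 = np.where(native_dih, K_DIH_3, 0.0)

    return Topology(
        n=n,
        bond_i=bond_i, bond_j=bond_j, bond_r0=bond_r0, bond_k=bond_k,
        ang_i=ang_i, ang_j=ang_j, ang_k=ang_k,
        ang_theta0=ang_theta0, ang_kth=ang_kth,
        dih_i=dih_i, dih_j=dih_j, dih_k=dih_k, dih_l=dih_l,
        dih_phi0=dih_phi0, dih_k1=dih_k1, dih_k3=dih_k3,
        con_i=contact_map.i - 1, con_j=contact_map.j - 1,
        con_eps=contact_map.eps, con_r0=contact_map.r0,
        sigma=_sigma_for(sequence),
    )


@dataclass
class GoModel:
    """Single-domain structure-based model."""

    structure: CalphaStructure
    contact_map: ContactMap
    topology: Topology

    @property
    def n_residues(self) -> int:
        return len(self.structure)

    @property
    def total_contact_energy(self) -> float:
        return self.contact_map.total_energy


def build_go_model(
    structure: CalphaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
    energy_unit: float = DEFAULT_ENERGY_UNIT,
    contact_map: ContactMap | None = None,
) -> GoModel:
    if contact_map is None:
        contact_map = build_contact_map(structure, cutoff, min_seq_sep, energy_unit)
    topo = _build_topology(
        structure.coords, structure.sequence, contact_map,
        np.ones(len(structure), dtype=bool),
    )
    return GoModel(structure=structure, contact_map=contact_map, topology=topo)


@dataclass
class TandemModel:
    """Two identical repeats joined by structureless linkers.

    The chain is [domain][linker][domain][linker]; the repeat length
    L = len(domain) + len(linker) so residue i of repeat 1 corresponds to
    residue i + L of repeat 2.  Every native contact appears in four copies
    (intra-repeat twice, swap copies twice) with identical parameters.
    """

    domain_model: GoModel
    linker_sequence: str
    duplicated_contacts: ContactMap
    topology: Topology
    sequence: str

    @property
    def L(self) -> int:
        return self.domain_model.n_residues + len(self.linker_sequence)

    @property
    def midpoint(self) -> int:
        return self.L

    @property
    def n_residues(self) -> int:
        return 2 * self.L


def gs_pad(ll: int, pattern: str = "GS") -> str:
    """Gly-Ser-repeat linker of length ll: full pattern copies padded with
    the pattern's final residue (ll = 5 with GS gives GSGSS)."""
    if ll < 0:
        raise ValueError("linker length must be >= 0")
    reps = ll // len(pattern)
    rem = ll - reps * len(pattern)
    return pattern * reps + pattern[-1] * rem


def build_tandem_model(domain: GoModel, linker_sequence: str = "") -> TandemModel:
    """Duplicate a single-domain model into a tandem dimer.

    Linker beads carry bonded and excluded-volume terms only (no native
    contacts, no dihedral bias).
    """
    n_dom = domain.n_residues
    L = n_dom + len(linker_sequence)
    cm = domain.contact_map
    reps = []
    for di in (0, L):
        for dj in (0, L):
            reps.append((cm.i + di, cm.j + dj))
    ii = np.concatenate([r[0] for r in reps]) if cm.n_contacts else np.empty(0, int)
    jj = np.concatenate([r[1] for r in reps]) if cm.n_contacts else np.empty(0, int)
    eps = np.tile(cm.eps, 4)
    r0 = np.tile(cm.r0, 4)
    dup = ContactMap(i=ii, j=jj, eps=eps, r0=r0, n_residues=2 * L)

    seq = (domain.structure.sequence + linker_sequence) * 2
    native_beads = np.zeros(2 * L, dtype=bool)
    native_beads[:n_dom] = True
    native_beads[L:L + n_dom] = True
    coords = native_tandem_coords_from_domain(domain.structure.coords, L)
    topo = _build_topology(coords, seq, dup, native_beads)
    return TandemModel(
        domain_model=domain,
        linker_sequence=linker_sequence,
        duplicated_contacts=dup,
        topology=topo,
        sequence=seq,
    )


def native_tandem_coords_from_domain(domain_coords: np.ndarray, L: int) -> np.ndarray:
    """Reference tandem frame: repeat 2 displaced along the domain's
    N-to-C axis, linker beads interpolated between junctions.

    This is a *contact-reference* frame (all intradomain contacts at native
    distances); linker bonds may be stretched and it is not an equilibrium
    conformation.
    """
    n_dom = len(domain_coords)
    n_link = L - n_dom
    e = domain_coords[-1] - domain_coords[0]
    norm_e = np.linalg.norm(e)
    u = e / norm_e if norm_e > 1e-9 else np.array([1.0, 0.0, 0.0])
    # displacement: far enough to avoid inter-repeat clash
    extent = np.ptp(domain_coords @ u)
    t = (norm_e + max((n_link + 1) * CA_BOND, extent * 0.5 + 0.8)) * u
    coords = np.zeros((2 * L, 3))
    coords[:n_dom] = domain_coords
    coords[L:L + n_dom] = domain_coords + t
    for rep, (a, b) in enumerate(
        [(domain_coords[-1], domain_coords[0] + t),
         (domain_coords[-1] + t, domain_coords[0] + 2 * t)]
    ):
        for k in range(n_link):
            frac = (k + 1) / (n_link + 1)
            coords[rep * L + n_dom + k] = a + frac * (b - a)
    return coords


def build_circular_permutant_model(
    domain: GoModel,
    K: int,
    junction_sequence: str = "G",
) -> GoModel:
    """Isolated circular permutant: cut after residue K, join the old
    termini through ``junction_sequence`` beads.

    The new chain runs old-(K+1)..old-n, junction, old-1..old-K; contacts
    are the native pairs relabelled.  Junction bonds rest at the generic
    Cα spacing, so a domain whose native termini are far apart carries
    real elastic strain in the permutant's folded state — the physical
    origin of circular-permutant destabilization.
    """
    n = domain.n_residues
    if not 1 <= K < n:
        raise ValueError(f"K={K} outside 1..{n - 1}")
    if len(junction_sequence) < 1:
        raise ValueError("the junction needs at least one residue")
    nj = len(junction_sequence)
    old = domain.structure
    # new position (1-based) of old residue r
    new_pos = np.empty(n + 1, dtype=int)
    for r in range(K + 1, n + 1):
        new_pos[r] = r - K
    for r in range(1, K + 1):
        new_pos[r] = (n - K) + nj + r
    seq = old.sequence[K:] + junction_sequence + old.sequence[:K]
    coords = np.empty((n + nj, 3))
    coords[: n - K] = old.coords[K:]
    coords[n - K + nj:] = old.coords[:K]
    a, b = old.coords[-1], old.coords[0]
    centroid = old.coords.mean(axis=0)
    mid = 0.5 * (a + b)
    outward = mid - centroid
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    # bow the junction outward until its beads clear the folded core
    for bow in (0.0, 0.15, 0.3, 0.45, 0.6):
        for k in range(nj):
            frac = (k + 1) / (nj + 1)
            arc = np.sin(np.pi * frac) * bow
            coords[n - K + k] = a + frac * (b - a) + arc * outward
        d = np.linalg.norm(
            coords[n - K: n - K + nj, None, :] - old.coords[None, :, :],
            axis=-1,
        )
        if d.min() > 0.3:
            break
    cm = domain.contact_map
    ni, nj_arr = new_pos[cm.i], new_pos[cm.j]
    # contacts between the old termini become sequence-local across the new
    # junction; they are absorbed into the junction's bonded terms
    keep = np.abs(nj_arr - ni) > 2
    new_cm = ContactMap(
        i=ni[keep], j=nj_arr[keep], eps=cm.eps[keep], r0=cm.r0[keep],
        n_residues=n + nj,
    )
    native_beads = np.ones(n + nj, dtype=bool)
    native_beads[n - K: n - K + nj] = False
    topo = _build_topology(coords, seq, new_cm, native_beads)
    structure = CalphaStructure(sequence=seq, coords=coords)
    return GoModel(structure=structure, contact_map=new_cm, topology=topo)


def apply_linker_extension(model: TandemModel, ll: int, pattern: str = "GS") -> TandemModel:
    """Extend the interdomain linker by ll Gly-Ser-pattern residues."""
    if ll == 0:
        return model
    return build_tandem_model(
        model.domain_model, model.linker_sequence + gs_pad(ll, pattern)
    )


# ---------------------------------------------------------------------------
# Potential energy (reference numpy implementation)
# ---------------------------------------------------------------------------

def potential_energy(model, coords: np.ndarray) -> tuple[float, dict]:
    """Total potential energy in kcal/mol with a per-term breakdown.

    Terms: bonds, angles, dihedrals, native contact wells
    (ε[5(r0/r)¹² − 6(r0/r)¹⁰], depth |ε| at r0) and purely repulsive
    excluded volume for non-native pairs with j − i >= 3.
    """
    topo: Topology = model.topology
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topo.n, 3):
        raise ValueError(f"coords shape {coords.shape} != ({topo.n}, 3)")
    if np.any(~np.isfinite(coords)):
        raise ValueError("coordinates contain NaN/inf")

    d = np.linalg.norm(coords[topo.bond_j] - coords[topo.bond_i], axis=1)
    e_bond = float(np.sum(0.5 * topo.bond_k * (d - topo.bond_r0) ** 2))

    theta = _bend_angles(coords)
    e_angle = float(np.sum(0.5 * topo.ang_kth * (theta - topo.ang_theta0) ** 2))

    if topo.n >= 4:
        phi = _dihedral_angles(coords)
        e_dih = float(np.sum(
            topo.dih_k1 * (1.0 - np.cos(phi - topo.dih_phi0))
            + topo.dih_k3 * (1.0 - np.cos(3.0 * (phi - topo.dih_phi0)))
        ))
    else:
        e_dih = 0.0

    r = np.linalg.norm(coords[topo.con_j] - coords[topo.con_i], axis=1)
    ratio = topo.con_r0 / r
    e_native = float(np.sum(-topo.con_eps * (5.0 * ratio ** 12 - 6.0 * ratio ** 10)))

    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    sep = np.subtract.outer(np.arange(topo.n), np.arange(topo.n))
    nonnative = (sep <= -topo.min_seq_sep) & ~topo.native_pair_mask()
    iu = np.nonzero(nonnative)
    sig = 0.5 * (topo.sigma[iu[0]] + topo.sigma[iu[1]])
    r_nn = np.maximum(dist[iu], 0.3 * sig)
    close = r_nn < 2.0 * sig  # truncated at 2 sigma, as in the dynamics kernel
    e_rep = float(np.sum(EPS_REP * (sig[close] / r_nn[close]) ** 12))

    breakdown = {
        "bonds": e_bond, "angles": e_angle, "dihedrals": e_dih,
        "contacts": e_native, "repulsion": e_rep,
    }
    return sum(breakdown.values()), breakdown


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _cm_to_dict(cm: ContactMap) -> dict:
    return {
        "i": cm.i.tolist(), "j": cm.j.tolist(),
        "eps": cm.eps.tolist(), "r0": cm.r0.tolist(),
        "n_residues": cm.n_residues,
    }


def _cm_from_dict(d: dict) -> ContactMap:
    return ContactMap(
        i=np.array(d["i"], int), j=np.array(d["j"], int),
        eps=np.array(d["eps"]), r0=np.array(d["r0"]),
        n_residues=d["n_residues"],
    )


def model_to_json(model) -> str:
    """Serialize a GoModel or TandemModel to a JSON document."""
    if isinstance(model, TandemModel):
        return json.dumps({
            "kind": "tandem",
            "linker_sequence": model.linker_sequence,
            "domain": json.loads(model_to_json(model.domain_model)),
        })
    return json.dumps({
        "kind": "domain",
        "sequence": model.structure.sequence,
        "coords": model.structure.coords.tolist(),
        "contact_map": _cm_to_dict(model.contact_map),
    })


def model_from_json(text: str):
    d = json.loads(text)
    if d["kind"] == "tandem":
        domain = model_from_json(json.dumps(d["domain"]))
        return build_tandem_model(domain, d["linker_sequence"])
    structure = CalphaStructure(sequence=d["sequence"], coords=np.array(d["coords"]))
    return build_go_model(structure, contact_map=_cm_from_dict(d["contact_map"]))
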