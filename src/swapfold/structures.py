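"""One-bead-per-residue protein structures and synthetic toy folds.

Everything downstream (contact maps, Gō models, reaction coordinates,
alchemy) operates on a :class:`CalphaStructure`: an ordered chain of Cα
positions in nm plus a one-letter sequence.  Structures come either from
experimental PDB files (``read_structure``) or from the deterministic toy
generator (``make_toy_structure``), which builds an antiparallel
β-meander-like trace with controllable loop geometry and N-to-C terminus
separation so that every module is testable without downloading anything.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

#: virtual Cα-Cα bond length, nm
CA_BOND = 0.38
#: inter-strand spacing of the toy meander, nm
STRAND_SPACING = 0.48
#: physical range for consecutive Cα distances, nm
BOND_RANGE = (0.25, 0.45)


@dataclass
class CalphaStructure:
    """A single-chain Cα trace.

    Coordinates are stored in nm (PDB I/O converts from/to Å) so that the
    contact switching parameter β = 50 nm⁻¹ applies without conversion.
    ``residue_ids`` are contiguous 1-based indices after any dropping of
    residues with missing Cα records.
    """

    sequence: str
    coords: np.ndarray  # (n, 3), nm
    residue_ids: np.ndarray = None
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if len(self.sequence) != len(self.coords):
            raise ValueError(
                f"sequence length {len(self.sequence)} != number of beads "
                f"{len(self.coords)}"
            )
        if self.residue_ids is None:
            self.residue_ids = np.arange(1, len(self.coords) + 1)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.residue_ids) and (
            self.residue_ids[0] != 1
            or np.any(np.diff(self.residue_ids) <= 0)
        ):
            raise ValueError("residue_ids must be strictly increasing from 1")

    def __len__(self):
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    @property
    def termini_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit chain-direction vectors at the N and C terminus.

        Computed from the first/last three Cα positions; used to decide the
        turn offset M of the alchemical join step (antiparallel termini need
        ~6 residues to form the joining turn).
        """
        if len(self) < 3:
            raise ValueError("need at least 3 residues to define termini vectors")
        v_n = self.coords[2] - self.coords[0]
        v_c = self.coords[-1] - self.coords[-3]
        return v_n / np.linalg.norm(v_n), v_c / np.linalg.norm(v_c)

    def termini_distance(self) -> float:
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))


@dataclass
class ToySpec:
    """Parameters of the synthetic β-meander generator."""

    n_strands: int = 4
    strand_length: int = 6
    loop_length: int = 3
    termini_gap: float = 0.5  # nm
    seed: int = 0

    def __post_init__(self):
        if self.n_strands < 2:
            raise ValueError("n_strands must be >= 2")
        if self.strand_length < 2 or self.loop_length < 2:
            raise ValueError("strand_length and loop_length must be >= 2")
        if self.termini_gap <= 0:
            raise ValueError("termini_gap must be positive")


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_structure(pdb_text: str, chain: str = "A") -> CalphaStructure:
    """Extract a Cα chain from PDB-format text.

    Heteroatoms, waters and alternate locations are dropped; each residue
    contributes exactly one bead.  Coordinates are converted from Å to nm.
    Chain breaks (consecutive Cα further apart than 0.45 nm) are recorded
    as warnings on the returned structure, not raised.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb_file.get_structure(model=1, altloc="first")
    mask = (
        (atoms.chain_id == chain)
        & (atoms.atom_name == "CA")
        & (atoms.element != "CA")  # exclude calcium ions named CA
        & ~atoms.hetero
    )
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError(f"no Calpha records found for chain {chain!r}")
    # one bead per residue: keep first CA per residue id
    _, first = np.unique(ca.res_id, return_index=True)
    ca = ca[np.sort(first)]
    seq = "".join(_THREE_TO_ONE.get(r, "X") for r in ca.res_name)
    coords = np.asarray(ca.coord, dtype=float) / 10.0  # Angstrom -> nm
    warnings = []
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    for k in np.nonzero(d > BOND_RANGE[1])[0]:
        warnings.append(
            f"chain break between residues {k + 1} and {k + 2} "
            f"(Calpha distance {d[k]:.3f} nm)"
        )
    return CalphaStructure(sequence=seq, coords=coords, warnings=warnings)


def write_structure(structure: CalphaStructure, chain: str = "A") -> str:
    """Serialize a Cα-only PDB text (coordinates back in Å)."""
    lines = []
    for k, (aa, xyz) in enumerate(zip(structure.sequence, structure.coords)):
        res = _ONE_TO_THREE.get(aa, "UNK")
        x, y, z = xyz * 10.0
        lines.append(
            f"ATOM  {k + 1:5d}  CA  {res:3s} {chain}{structure.residue_ids[k]:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_xyz_trajectory(frames: np.ndarray, handle) -> None:
    """Write frames in the package's plain-text XYZ dialect (nm units).

    Format: a header line ``frames: <n_frames> beads: <n_beads>`` followed,
    for each frame, by a ``frame <index>`` line and one ``x y z`` line per
    bead.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    handle.write(f"frames: {frames.shape[0]} beads: {frames.shape[1]}\n")
    for f, frame in enumerate(frames):
        handle.write(f"frame {f}\n")
        for x, y, z in frame:
            handle.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(handle) -> np.ndarray:
    header = handle.readline().split()
    n_frames, n_beads = int(header[1]), int(header[3])
    frames = np.empty((n_frames, n_beads, 3))
    for f in range(n_frames):
        handle.readline()  # frame marker
        for b in range(n_beads):
            frames[f, b] = [float(v) for v in handle.readline().split()]
    return frames


# ---------------------------------------------------------------------------
# Toy structure generator
# ---------------------------------------------------------------------------

def _loop_points(a: np.ndarray, b: np.ndarray, bulge: np.ndarray,
                 n_points: int) -> np.ndarray:
    """Interior points of a loop from a to b bulging along ``bulge``.

    The path is a semi-ellipse in the (chord, bulge) plane whose height is
    solved so the total path length matches ``n_points + 1`` Cα-bond-sized
    segments; points are placed at equal arc length, which keeps every
    consecutive spacing physical and pushes the loop interior well clear of
    the sheet.
    """
    chord = float(np.linalg.norm(b - a))
    u = (b - a) / chord
    w = bulge - np.dot(bulge, u) * u
    w = w / np.linalg.norm(w)
    n_seg = n_points + 1
    target_len = max(n_seg * 0.36, chord * 1.05)

    # staple path: straight legs out along w, semicircular cap of radius
    # chord/2 (the gentlest turn the chord permits)
    radius = 0.5 * chord
    cap_len = np.pi * radius
    leg = max(0.5 * (target_len - cap_len), 0.02)
    t_leg = np.linspace(0.0, 1.0, 128)[:, None]
    p1 = a[None, :] + t_leg * leg * w[None, :]
    ang = np.linspace(np.pi, 0.0, 256)[:, None]
    center = 0.5 * (a + b) + leg * w
    p2 = center[None, :] + radius * (
        np.cos(ang) * -u[None, :] * -1.0 + np.sin(ang) * w[None, :]
    )
    p3 = b[None, :] + (1.0 - t_leg) * leg * w[None, :]
    pts = np.vstack([p1, p2[1:], p3[1:]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = arc[-1] * np.arange(1, n_seg) / n_seg
    out = np.empty((n_points, 3))
    for k, t in enumerate(targets):
        idx = int(np.searchsorted(arc, t))
        idx = min(max(idx, 1), len(arc) - 1)
        frac = (t - arc[idx - 1]) / (arc[idx] - arc[idx - 1])
        out[k] = pts[idx - 1] + frac * (pts[idx] - pts[idx - 1])
    return out


def _build_meander(spec: ToySpec, bend: float) -> np.ndarray:
    """Meander coordinates with bend angle ``bend`` at each strand junction.

    Strand centre-lines sit on a circular arc in the xz-plane (radius set by
    the bend), which preserves adjacent-strand spacing exactly while moving
    the chain termini closer together as the sheet curls.
    """
    n, m, p = spec.n_strands, spec.strand_length, spec.loop_length
    d = STRAND_SPACING
    if bend < 1e-9:
        origins = np.array([[s * d, 0.0, 0.0] for s in range(n)])
    else:
        r = d / (2.0 * np.sin(bend / 2.0))
        origins = np.array(
            [[r * np.sin(s * bend), 0.0, r * (1.0 - np.cos(s * bend))]
             for s in range(n)]
        )
    y_top = (m - 1) * CA_BOND
    beads = []
    for s in range(n):
        ys = np.arange(m) * CA_BOND if s % 2 == 0 else y_top - np.arange(m) * CA_BOND
        strand = origins[s][None, :] + np.outer(ys, [0.0, 1.0, 0.0])
        beads.append(strand)
        if s < n - 1:
            a = strand[-1]
            ys_next = 0.0 if (s + 1) % 2 == 0 else y_top
            b = origins[s + 1] + np.array([0.0, ys_next, 0.0])
            y_sign = 1.0 if s % 2 == 0 else -1.0
            # outward sheet normal at this junction (rotates with the curl)
            ang = (s + 0.5) * bend
            normal = np.array([np.sin(ang), 0.0, -np.cos(ang)])
            # alternate the out-of-plane tilt so same-side loops separate;
            # fade the tilt as the sheet curls (curl itself separates them)
            z_sign = 1.0 if s % 4 in (0, 1) else -1.0
            tilt = 0.9 * max(0.0, 1.0 - bend / 0.7)
            bulge = np.array([0.0, y_sign, 0.0]) + tilt * z_sign * normal
            bulge /= np.linalg.norm(bulge)
            beads.append(_loop_points(a, b, bulge, p))
    return np.vstack(beads)


def _toy_sequence(spec: ToySpec) -> str:
    strand_cycle = "ILVT"
    loop_cycle = "GSG"
    seq = []
    for s in range(spec.n_strands):
        seq.extend(strand_cycle[k % len(strand_cycle)] for k in range(spec.strand_length))
        if s < spec.n_strands - 1:
            seq.extend(loop_cycle[k % len(loop_cycle)] for k in range(spec.loop_length))
    return "".join(seq)


def make_toy_structure(spec: ToySpec) -> CalphaStructure:
    """Build a deterministic antiparallel β-meander-like Cα trace.

    The N-to-C distance is tuned to ``spec.termini_gap`` (within 10%) by
    curling the sheet: every strand-to-strand junction is bent by the same
    angle, chosen by bisection.  A small seed-dependent jitter perturbs the
    coordinates without changing the contact topology.
    """
    flat_gap = float(
        np.linalg.norm(_build_meander(spec, 0.0)[-1] - _build_meander(spec, 0.0)[0])
    )
    if spec.termini_gap > 1.10 * flat_gap:
        raise ValueError(
            f"termini_gap {spec.termini_gap} nm infeasible: flat meander with "
            f"{spec.n_strands} strands reaches at most {flat_gap:.2f} nm"
        )

    def gap(bend):
        c = _build_meander(spec, bend)
        return float(np.linalg.norm(c[-1] - c[0]))

    max_bend = 2.0 * np.pi / max(spec.n_strands - 1, 1) * 0.98
    if spec.termini_gap >= flat_gap:
        bend = 0.0
    else:
        lo, hi = 0.0, max_bend
        if gap(hi) > spec.termini_gap:
            raise ValueError(
                f"termini_gap {spec.termini_gap} nm infeasible: curling "
                f"bottoms out at {gap(hi):.2f} nm for this geometry"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if gap(mid) > spec.termini_gap:
                lo = mid
            else:
                hi = mid
        bend = 0.5 * (lo + hi)
    coords = _build_meander(spec, bend)

    # clash check: curling must not push non-bonded beads inside hard core
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(len(coords), k=2)
    if dist[iu].min() < 0.28:
        raise ValueError(
            f"termini_gap {spec.termini_gap} nm infeasible: required curl "
            f"brings non-bonded beads to {dist[iu].min():.2f} nm"
        )

    # seed-dependent jitter, shrunk if it would flip any near-cutoff pair
    # of the default contact rule (topology must be seed-independent)
    def _default_contacts(c):
        dd = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        sep = np.subtract.outer(np.arange(len(c)), np.arange(len(c)))
        return frozenset(zip(*np.nonzero((dd < 0.8) & (sep <= -3))))

    clean = _default_contacts(coords)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(size=coords.shape)
    scale = 0.008
    for _ in range(6):
        if _default_contacts(coords + scale * noise) == clean:
            break
        scale *= 0.5
    coords = coords + scale * noise
    structure = CalphaStructure(sequence=_toy_sequence(spec), coords=coords)
    achieved = structure.termini_distance()
    if abs(achieved - spec.termini_gap) > 0.10 * spec.termini_gap + 0.03:
        raise ValueError(
            f"could not hit termini_gap {spec.termini_gap} nm "
            f"(achieved {achieved:.3f} nm)"
        )
    return structure


def fully_extended_coords(n_residues: int, rng=None) -> np.ndarray:
    """Fully extended starting chain: beads along x at the Cα bond length,
    with a tiny transverse perturbation to break collinearity."""
    coords = np.zeros((n_residues, 3))
    coords[:, 0] = np.arange(n_residues) * CA_BOND
    if rng is not None:
        coords[:, 1:] += rng.normal(scale=0.01, size=(n_residues, 2))
    else:
        coords[:, 1] = 0.01 * np.cos(np.arange(n_residues))
    return coords
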