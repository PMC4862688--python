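"""Circular-permutant contact algebra and reaction coordinates.

A domain-swapped misfold of a tandem dimer is characterized by the loop
position K after which its "central domain" begins (K = 0 is the native
fold).  Given the native contact set of one repeat, the native-like
contacts of the central domain (S_in,K) and terminal domain (S_out,K) are
obtained by a Heaviside frame shift:

    C_in(K)  = (i + Θ(K−i)·L,  j + Θ(K−j)·L)
    C_out(K) = (i + Θ(i−K)·L,  j + Θ(j−K)·L)

with Θ(0) = 1, so residue K itself belongs to the terminal (pre-cut) side
and the central domain spans K+1 .. K+L.  The fraction-of-contacts
coordinate Q_K uses a logistic switching function with β = 50 nm⁻¹ and
λ = 1.2 to absorb native-distance fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .go_model import ContactMap, GoModel


@dataclass(frozen=True)
class QParams:
    """Switching-function parameters of the contact coordinate."""

    beta: float = 50.0  # nm^-1
    lam: float = 1.2

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")


@dataclass(frozen=True)
class CutSite:
    """Cut position K (0 = native) inside a loop span (1-based, inclusive)."""

    K: int
    loop_span: tuple = ()

    def __post_init__(self):
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.K == 0 and self.loop_span:
            raise ValueError("K = 0 has an empty loop span")
        if self.K > 0:
            if not self.loop_span:
                raise ValueError("K > 0 requires a loop span")
            a, b = self.loop_span
            if not (a <= self.K <= b):
                raise ValueError(f"K={self.K} outside loop span {self.loop_span}")

    @classmethod
    def native(cls) -> "CutSite":
        return cls(K=0)


@dataclass
class PermutantContactSets:
    """Frame-shifted contact sets of one permutant over the 2L tandem chain."""

    cut: CutSite
    L: int
    in_i: np.ndarray
    in_j: np.ndarray
    out_i: np.ndarray
    out_j: np.ndarray
    r0: np.ndarray  # shared: native-like distance per contact
    eps: np.ndarray = None

    @property
    def K(self) -> int:
        return self.cut.K

    @property
    def n_contacts(self) -> int:
        return len(self.in_i)

    def set_arrays(self, which: str):
        if which == "in":
            return self.in_i, self.in_j, self.r0
        if which == "out":
            return self.out_i, self.out_j, self.r0
        if which == "both":
            return (
                np.concatenate([self.in_i, self.out_i]),
                np.concatenate([self.in_j, self.out_j]),
                np.concatenate([self.r0, self.r0]),
            )
        raise ValueError("which must be 'in', 'out' or 'both'")


def _theta(x: np.ndarray) -> np.ndarray:
    """Heaviside step with Θ(0) = 1."""
    return (x >= 0).astype(int)


def permuted_contact_sets(native: ContactMap, cut: CutSite, L: int) -> PermutantContactSets:
    """Frame-shift the native contact set for cut position K.

    Output pairs are stored min-index-first; indices land in [1, 2L].
    """
    K = cut.K
    if K >= L:
        raise ValueError(f"K={K} must be smaller than the repeat length L={L}")
    i, j = native.i, native.j
    if len(i) and (i.min() < 1 or j.max() > L):
        raise ValueError("native contacts must lie within a single repeat [1, L]")
    in_i = i + _theta(K - i) * L
    in_j = j + _theta(K - j) * L
    out_i = i + _theta(i - K) * L
    out_j = j + _theta(j - K) * L
    in_i, in_j = np.minimum(in_i, in_j), np.maximum(in_i, in_j)
    out_i, out_j = np.minimum(out_i, out_j), np.maximum(out_i, out_j)
    return PermutantContactSets(
        cut=cut, L=L, in_i=in_i, in_j=in_j, out_i=out_i, out_j=out_j,
        r0=native.r0.copy(), eps=native.eps.copy(),
    )


def q_k(
    coords: np.ndarray,
    sets: PermutantContactSets,
    which: str = "in",
    params: QParams = QParams(),
) -> float:
    """Fraction of native-like contacts formed, Q_K ∈ [0, 1].

    Mean logistic indicator 1/(1+exp(β(r_ij − λ·r0_ij))) over the selected
    contact set; the normalization N is the size of that set.
    """
    ii, jj, r0 = sets.set_arrays(which)
    if len(ii) == 0:
        raise ValueError("empty contact set")
    coords = np.asarray(coords)
    if coords.shape[0] < 2 * sets.L:
        raise ValueError("coords must cover the 2L tandem chain")
    r = np.linalg.norm(coords[jj - 1] - coords[ii - 1], axis=1)
    x = np.clip(params.beta * (r - params.lam * r0), -500, 500)
    return float(np.mean(1.0 / (1.0 + np.exp(x))))


def formed_contacts(
    coords: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    r0: np.ndarray,
    lam: float = 1.2,
) -> np.ndarray:
    """Sharp formed-contact criterion r < λ·r0; returns a boolean mask."""
    r = np.linalg.norm(np.asarray(coords)[jj - 1] - np.asarray(coords)[ii - 1], axis=1)
    return r < lam * r0


def ij_bar(ii: np.ndarray, jj: np.ndarray) -> float:
    """Mean sequence position (i+j)/2 of a set of formed contacts.

    Returns NaN (never 0) when no contacts are formed.
    """
    if len(ii) == 0:
        return float("nan")
    return float(np.mean((np.asarray(ii) + np.asarray(jj)) / 2.0))


def rco(ii: np.ndarray, jj: np.ndarray, L: int) -> float:
    """Relative contact order: mean |i−j| over the set, divided by L."""
    if len(ii) == 0:
        raise ValueError("empty contact set")
    return float(np.sum(np.abs(np.asarray(jj) - np.asarray(ii))) / (L * len(ii)))


def detect_loops(
    contact_map: ContactMap,
    min_run: int = 3,
    local_sep: int = 4,
) -> list[tuple[int, int]]:
    """Loops: maximal runs of >= min_run consecutive residues participating
    in no contact with |i−j| > local_sep.  Returns 1-based inclusive spans."""
    n = contact_map.n_residues
    has_long = np.zeros(n + 1, dtype=bool)
    long_mask = (contact_map.j - contact_map.i) > local_sep
    for a, b in zip(contact_map.i[long_mask], contact_map.j[long_mask]):
        has_long[a] = True
        has_long[b] = True
    spans = []
    r = 1
    while r <= n:
        if not has_long[r]:
            start = r
            while r <= n and not has_long[r]:
                r += 1
            if r - start >= min_run:
                spans.append((start, r - 1))
        else:
            r += 1
    return spans


def enumerate_cut_sites(
    model: GoModel,
    explicit: list[int] | None = None,
    min_run: int = 3,
) -> list[CutSite]:
    """Candidate circular-permutant cut positions.

    Auto-detection returns the central residue of each contact-free loop.
    An explicit K list (e.g. from a printed table) is validated against the
    detected loops and returned verbatim; a K inside a contact-dense region
    raises, naming the offending position.  Terminal loops (runs touching
    the chain ends) are excluded: cutting there does not produce a swap.
    """
    spans = detect_loops(model.contact_map, min_run=min_run)
    n = model.contact_map.n_residues
    interior = [s for s in spans if s[0] > 1 and s[1] < n]
    if explicit is not None:
        sites = []
        for K in explicit:
            span = next((s for s in spans if s[0] <= K <= s[1]), None)
            if span is None:
                raise ValueError(
                    f"explicit cut position K={K} lies in a contact-dense region"
                )
            sites.append(CutSite(K=K, loop_span=span))
        return sites
    return [CutSite(K=(a + b) // 2, loop_span=(a, b)) for a, b in interior]


def tandem_contact_sets(
    tandem,
    cut_sites: list[CutSite] | None = None,
    explicit: list[int] | None = None,
) -> list[PermutantContactSets]:
    """S_in/S_out for K = 0 plus every candidate cut site of a tandem model."""
    if cut_sites is None:
        cut_sites = enumerate_cut_sites(tandem.domain_model, explicit=explicit)
    all_sites = [CutSite.native()] + [c for c in cut_sites if c.K > 0]
    return [
        permuted_contact_sets(tandem.domain_model.contact_map, c, tandem.L)
        for c in all_sites
    ]
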