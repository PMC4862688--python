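# Methods

This note documents the models implemented in `swapfold`, the parameter
choices that matter, what the synthetic structures do and do not
emulate, and the numerical conventions.  Units throughout: lengths in
nm, energies in kcal/mol, time in ps, temperatures in K,
k_B = 0.0019872 kcal/mol/K.

## Coarse-grained energy model

Each residue is one bead at the Cα position.  Native contacts are Cα
pairs closer than 0.8 nm in the reference structure and separated by at
least three positions in sequence; each carries an attractive 12-10
well, ε[5(r₀/r)¹² − 6(r₀/r)¹⁰], of depth |ε| at its native distance r₀.
Relative depths follow the Miyazawa–Jernigan statistical contact
potential for the residue pair, rescaled so the mean |ε| equals a
configurable energy unit (default 0.7 kcal/mol for experimental
structures; the toy benchmarks use 1.0).  Only relative MJ energies are
meaningful, so the overall scale is a free unit that sets the melting
temperature.

Bonded terms are harmonic bonds (k = 2000 kcal/mol/nm², rest lengths
from the reference geometry), harmonic angles (k = 40 kcal/mol/rad² at
native angles), and a two-term cosine dihedral
k₁(1 − cos(φ − φ₀)) + k₃(1 − cos 3(φ − φ₀)) with k₁ = 1.0,
k₃ = 0.5 kcal/mol at native dihedrals.  Non-native pairs with sequence
separation ≥ 3 are purely repulsive, 0.2·(σ/r)¹² truncated at 2σ, with
per-residue radii (0.40 nm default, smaller for Gly/Ser).  This is a
deliberately simplified one-bead structure-based force field: the
analyses built on it are property- and statistics-based, and nothing
downstream depends on force-field-exact details.

**Tandem dimers.**  The chain is two identical repeats
[domain][linker][domain][linker]; the repeat length L counts domain plus
linker, so residue i of repeat 1 corresponds to residue i + L of repeat
2.  Every native contact (i, j) is present in four copies —
(i,j), (i+L,j), (i,j+L), (i+L,j+L) — with identical depth and distance.
This duplication is what makes domain-swapped, native-like misfolds
energetically degenerate with the native arrangement contact-by-contact.
Linker beads (Gly/Ser-type) carry bonded and excluded-volume terms only:
generic bond lengths, a weak generic angle (130°, 10 kcal/mol/rad²),
no dihedral bias and no contacts.

**Circular permutants.**  An isolated permutant cut after residue K is
built by reordering the chain (K+1..n, junction, 1..K) and bridging the
old termini with at least one structureless junction residue whose
bonds rest at the generic Cα spacing.  A domain whose native termini
are far apart therefore carries real elastic/fraying strain in the
permutant's folded state — the physical origin of circular-permutant
destabilization.  Contacts that become sequence-local (|i − j| ≤ 2)
across the new junction are dropped, being absorbed into the junction's
bonded terms.  Junction beads are bowed away from the folded core at
construction so the starting conformation is free of steric overlap.

## Reaction coordinates

For a cut position K, the native-like contact sets of the central and
terminal domains are Heaviside frame shifts of the native set:
C_in(K) = (i + Θ(K−i)L, j + Θ(K−j)L) and
C_out(K) = (i + Θ(i−K)L, j + Θ(j−K)L), with Θ(0) = 1, so the central
domain spans K+1 .. K+L.  Q_K is the mean logistic indicator
1/(1 + exp(β(r − λr₀))) with β = 50 nm⁻¹ and λ = 1.2, normalized by the
size of the set actually summed over (the "both" variant normalizes by
|S_in| + |S_out|), which keeps every variant in [0, 1].  Relative
contact order is RCO_K = Σ|i−j| / (L·N) over S_in,K; the nucleus
location ij̄ is the mean contact midpoint (i+j)/2 over contacts that are
*formed* under the sharp criterion r < λr₀, and is NaN (never 0) when no
contact is formed.

Candidate cut sites are loops: maximal runs of ≥ 3 consecutive residues
with no contact beyond |i − j| > 4, excluding terminal runs; the cut is
placed at the loop centre.  Both thresholds are explicit parameters.
An explicit K list is validated against the detected loops.

## Sampling

Dynamics are BAOAB Langevin steps with friction 0.1 ps⁻¹, time step
10 fs and uniform residue mass (110 u).  Noise is pre-generated per
chunk from a seeded generator, making trajectories bit-reproducible.
Near-collinear backbone geometries are handled by bounding the 1/sin θ
factor of the angle force and skipping the (ill-defined) dihedral force
below |n|² = 10⁻⁵; energies are exact throughout.

First-passage campaigns start from fully extended chains, one seed per
trajectory, and stop at first passage into a labelled state: label K
when both Q_in,K and Q_out,K exceed 0.8 (a threshold well above the
logistic midpoint and below the native plateau), "incomplete"
otherwise, ties broken by the larger min(Q_in, Q_out).

Umbrella sampling applies ½κ(Q − Q_c)² along the logistic Q of a chosen
contact set, walking windows from the folded state downward, each window
seeded independently.  WHAM solves the standard self-consistent
equations on a 0.01-wide Q grid (0.025 for the noisier toy runs) to a
tolerance of 10⁻⁷ on the window free energies; non-overlapping
neighbouring windows are an error, not a warning.

ΔG_s uses the two-basin quadrature with the stable-fold-positive sign
convention: ΔG_s = k_BT ln[∫_{Q‡}^1 e^{−F/kT} / ∫_0^{Q‡} e^{−F/kT}].
Q_‡ is located automatically as the top of the highest interior barrier
between the two lowest minima; ΔG_f = F(Q_‡) − F(Q_u) with Q_u the
low-Q minimum.  Small toy folds are weakly cooperative (their F(Q) has
no interior barrier at any temperature), so the quadrature also accepts
an explicit dividing point (Q_‡ = 0.5 in the toy benchmarks) — the
integral is well-defined for any split, while the automatic barrier
detection and its "no two-state structure" error are unchanged for
cooperative profiles.  Temperature selection (bisection to a folding
barrier of 2.5 k_BT, plus a melting-temperature bracket) accepts any
profile source; on barrierless toys it reports the scan table and
raises, as no temperature qualifies.

**Desk scales.**  The package's benchmarks use 64–256 trajectories of
15–90-residue toys for campaigns and 14 umbrella windows × 50–60 k
steps for profiles, chosen so the full study suite completes on one CPU
in minutes.  Full-scale campaigns (1024 trajectories × 12 μs on
experimentally derived models) are the same code path with larger
configuration values and need cluster resources.

## WSME model of first-domain formation

Residues are binary (native/unfolded); native structure occupies one
contiguous segment (single-sequence approximation), never longer than
one repeat L, so exactly one domain — native or circularly permuted —
can form.  A segment χ has
G(χ) = n(χ)·ϵ − N_f(χ)·T·Δs + E_p·θ(χ): n contacts fully inside the
segment (ϵ < 0 favourable; uniform ϵ by default, per-contact MJ depths
optional), N_f segment length (Δs < 0, the per-residue entropy penalty
of folding), and θ(χ) = 1 iff the segment contains both residues L and
L+1 — crossing the midpoint means building a circular permutant, which
pays the strain penalty E_p once.  Defaults: ϵ = −0.5 kcal/mol,
Δs = −0.0017 kcal/mol/K, T = 525 K; these place the toy maps in a
regime where folded and unfolded states both carry weight, which is
where the penalty response is informative.

Exact enumeration over the empty state and all (start, length ≤ L)
segments is the oracle (O(states × contact degree), fine up to ~10⁶
states).  The Metropolis chain flips one residue among
{first−1, first, last, last+1} with acceptance min[1, e^(−ΔE/k_BT)];
proposals that break contiguity, leave the chain or exceed L are
rejected and counted.  The fully unfolded state is reachable through
nucleation/vanishing moves that carry the Metropolis–Hastings
proposal-ratio factor (nucleation site drawn uniformly from 2L
positions, vanishing proposed with probability 1/2); without this
factor the sampler demonstrably misweights the empty state.

At E_p = 0, the four-copy contact duplication makes every full-length
window contain exactly one copy of each native contact, so all
full-length segments — native and permutant — are exactly isoenergetic;
this symmetry is asserted at state level.  The binned F(Q_res, ij̄)
surface can merge several degenerate states into one cell (an offset of
k_BT·ln m for m merged states), so surface values are compared like
against like (exact vs Monte Carlo on the same grid).

## Alchemical predictor

ΔΔG_tot = ΔG_J + ΔG_C converts the native fold into the circular
permutant in two steps, assuming equal unfolded free energies.

*Joining* (ΔG_J, shared by all K): peel i N-terminal and L−j C-terminal
residues, feasible when d(R_{i+1}, R_j) < (i + 1 + L − j + ll − M)·r₀
with r₀ = 0.35 nm per residue, ll structureless linker residues (the
linker-length effect: longer interdomain linkers need fewer contacts
disrupted), and M = 6 when the termini point in opposite directions
(≈ one turn of the joint loop contributes no reach), 0 when parallel —
decided from the chain-direction vectors at the termini (sign of their
dot product).  The cost is the contact energy lost (each broken contact
counted once, even when both endpoints peel) minus T·δs per unfolded
residue, with δs = Σε/(T·N) at the folding temperature, i.e. the
per-residue entropy that exactly balances the mean contact energy
there.  Windows: i ∈ {0..9}, j ∈ {L−9..L}; i = 0 peels nothing, and the
entropy term counts the residues actually peeled.

*Cutting* (ΔG_C): fray p′ ∈ {i′+1..K} and q′ ∈ {K+1..j′−1} around the
cut, windows i′ ∈ {K−3..K}, j′ ∈ {K+1..K+4}, same energy/entropy
bookkeeping.  In both steps, residues whose only interactions are with
sequence neighbours (|i−j| ≤ 2) gain no entropy (the κ rule).  Applying
the rule to the cut step as well as the join step is a deliberate
choice: without it the window minimization is dominated by spurious
entropy gain from unfolding contact-free loop residues and every clean
loop cut comes out strictly negative, instead of the expected zero.

The predictor's validation property — −ΔΔG_tot rank-orders simulated
permutant stabilities — is exercised on a toy family that grades
destabilization by the native termini gap at a fixed four-strand
architecture, with members spaced so their simulated stability
differences are several times the umbrella-sampling noise.  Two family
designs were rejected on measurement: a mixed-size family (raw ΔG_s
tracks fold size unless each member is simulated at its own
barrier-matched temperature, which barrierless toys cannot provide) and
a junction-length family (the simulation relieves junction strain by
cheap terminal fraying, so linker length barely moves ΔG_s even though
the predictor resolves it).

## Synthetic structures

The generator builds antiparallel β-meander Cα traces: strands 0.48 nm
apart with 0.38 nm virtual bonds, loops as equal-arc-length "staple"
paths (straight legs plus a semicircular cap) that keep every
consecutive spacing within 0.25–0.45 nm, successive loops tilted to
alternate sides of the sheet so loop interiors stay contact-free.  The
N-to-C distance is tuned (to 10%) by curling the sheet: every
strand-junction is bent by a common angle found by bisection, which
preserves adjacent-strand spacing exactly; infeasible targets (beyond
the flat reach, or requiring a curl that clashes) raise errors.  A
small seeded jitter (σ = 8 pm) decorrelates coordinates without
changing the contact topology.  Even strand counts give antiparallel
termini (M = 6), odd counts parallel (M = 0).

What the toys emulate: compact folds with well-defined contact maps,
cuttable contact-free loops, controllable termini separation, and
attachable structureless linkers.  What they do not: real β-sheet
twist, side-chain packing, heterogeneous loop lengths, or two-state
folding cooperativity — toy folding is downhill, so barrier-based
quantities (ΔG_f ≈ 2.5 k_BT temperature selection, automatic Q_‡) are
demonstrated on constructed profiles, and toy stabilities use the fixed
dividing surface.  Passing desk-scale tests therefore validates the
machinery and its symmetries, not force-field realism on real proteins.

## Reference propensity table

The packaged table (`swapfold/data/table1.tsv`, provenance column
`paper-fixture`) lists K, RCO, ΔG_f, ΔG_s and final-state populations
for the permutants of seven domain families, as produced by full-scale
first-passage campaigns of tandem dimers.  The statistics module
reproduces its per-protein rank correlations (mid-rank ties are
essential: SH3's tied populations give ρ = 0.63 only with fractional
ranks) and the binomial error bound (worst case 1.6% at n = 1024).

## Known limitations

- The force field is a simplified variant; per-protein melting
  temperatures of experimental structures will not match published
  coarse-grained studies quantitatively.
- Toy folds are weakly cooperative (no folding barrier); all
  barrier-dependent machinery is validated on constructed profiles.
- The WSME ϵ and Δs defaults are package choices; only E_p, T and the
  model structure are constrained by the problem.
- Amyloid-like misfolds, structural comparison to experimental
  swapped-dimer crystal structures, and FRET/AFM observable modelling
  are out of scope.
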