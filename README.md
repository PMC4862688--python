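# swapfold

Coarse-grained simulation and theory of **domain-swapped misfolding in
tandem multidomain proteins**.

Proteins built from tandem repeats of the same domain (titin's Ig
domains, polyubiquitin, fibronectin-III arrays, ...) can misfold into
long-lived *domain-swapped* states: two native-like folds assembled from
exchanged halves of adjacent repeats.  Each such misfold is
characterized by the loop position `K` after which its "central domain"
begins; that central domain is a **circular permutant** of the native
fold (K = 0 is the native arrangement).  `swapfold` provides the
complete computational apparatus for studying which folds are prone to
this misfolding and why:

- **one-bead structure-based (Gō) models** of single domains and tandem
  dimers, with every native contact duplicated across repeats at equal
  strength — `E(i,j) = E(i+L,j) = E(i,j+L) = E(i+L,j+L)`, where `L` is
  the repeat length — so that swapped, native-like folds are energetically
  accessible;
- **circular-permutant contact algebra**: frame-shifted contact sets
  `S_in,K` / `S_out,K` via a Heaviside index shift, the logistic contact
  coordinate `Q_K` (β = 50 nm⁻¹, λ = 1.2), relative contact order
  `RCO_K`, and the nucleus-location order parameter `ij̄`;
- **sampling machinery**: seeded BAOAB Langevin dynamics (friction
  0.1 ps⁻¹, 10 fs steps), first-passage folding campaigns from extended
  chains, umbrella sampling along Q with WHAM unbiasing, and the
  stability / barrier readouts ΔG_s and ΔG_f from F(Q);
- a **Wako–Saitô–Muñoz–Eaton (WSME) Ising model** of first-domain
  formation under the single-sequence approximation, with a strain
  penalty `E_p` whenever the native segment crosses the inter-repeat
  midpoint — both exact enumeration and Metropolis Monte Carlo;
- an **alchemical predictor** of circular-permutant destabilization,
  `ΔΔG_tot = ΔG_J + ΔG_C` (termini joining + loop cutting), with the
  geometric feasibility condition `d(R_i, R_j) < (i + L − j − M)·r₀`,
  r₀ = 3.5 Å per peeled residue and turn offset M ∈ {0, 6};
- **rank-correlation analysis** connecting permutant properties (RCO,
  ΔG_f, ΔG_s) to misfolded-state populations, with binomial standard
  errors, and a packaged reference propensity table for seven domain
  families (SH3, SH2, PDZ, TNfn3, Titin I27, ubiquitin, protein G).

A deterministic synthetic-structure generator (antiparallel β-meander
toys with controllable loops and termini separation) makes every
analysis runnable and testable without downloading any structure.

## Worked example

Build a toy fold, its tandem dimer, enumerate the possible swaps, run a
small folding campaign, and score the permutants alchemically:

```python
import numpy as np
from swapfold.structures import ToySpec, make_toy_structure
from swapfold.go_model import build_go_model, build_tandem_model
from swapfold.permutants import tandem_contact_sets
from swapfold.sampling import LangevinParams, first_passage_campaign
from swapfold.alchemy import ddg_total

structure = make_toy_structure(ToySpec(n_strands=2, strand_length=6,
                                       loop_length=3, termini_gap=0.48,
                                       seed=1))
domain = build_go_model(structure, energy_unit=1.0)
tandem = build_tandem_model(domain, "GSG")      # repeat length L = 18
sets = tandem_contact_sets(tandem)              # K = 0 plus one loop cut
print([s.K for s in sets])

outcomes, summary = first_passage_campaign(
    tandem, sets, n_traj=64, t_max_steps=400_000,
    params=LangevinParams(temperature=300.0, seed=21),
)
print(summary[["label", "count", "fraction", "stderr"]])
```

Output (seed 21):

```
[0, 8]
        label  count  fraction    stderr
0      native     62   0.96875  0.021749
1           8      2   0.03125  0.021749
2  incomplete      0   0.00000  0.000000
```

62 of 64 chains fold into the native tandem; two reach the K = 8
domain-swapped state, in which the central domain is the circular
permutant cut in the hairpin loop — a misfolded fraction of ~3%,
comparable to what single-molecule experiments report for
misfolding-prone tandem repeats.  The binomial standard error for each
population is reported alongside (for the full-scale 1024-trajectory
campaigns the worst case is 1.6%).

Scoring the permutant's stability without any simulation:

```python
res = ddg_total(structure, domain.contact_map, K=8, T=360.0)
print(round(res.ddG_tot, 2), round(res.dG_J, 2), round(res.dG_C, 2))
# 0.95 1.92 -0.97   (kcal/mol; a mildly destabilized, viable permutant)
```

The same tools run on experimental structures through
`swapfold.structures.read_structure` (Cα extraction from PDB text) or the
CLI:

```bash
swapfold build-model --structure 1shg.pdb --chain A --linker DETG --out sh3.json
swapfold enumerate-cp --model sh3.json --k-list 18,37,46
swapfold simulate --model sh3.json --mode first-passage --n 256 --seed 7
swapfold ising --model sh3.json --ep 4.0 --temp 525 --steps 1e6 --seed 3
swapfold alchemy --model sh3.json --temp 350
swapfold report
```

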