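# methylwalk

Structure-based assignment of methyl-TROSY NMR spectra for large proteins,
combining NOE networks from multiple ligand-induced protein states,
paramagnetic restraints (pseudocontact shifts and relaxation enhancements)
and a quantitative metal/ligand binding model for paramagnetic sample design.

## Who this is for

Biomolecular NMR groups assigning [¹³C,¹H₃]-methyl resonances of proteins too
large for backbone-based strategies (tens of kDa and up).  The input is what
such a project produces anyway: crystal structures of two or more protein
states, 2D ¹H,¹³C HMQC peak lists, 4D HMQC-NOESY-HMQC cross-peak lists,
ligand titrations, and (optionally) PCS/PRE tables from lanthanide- or
Mn²⁺-loaded samples.

## What it computes

**Monte-Carlo NOE assignment.**  Typed HMQC peaks are mapped onto the methyl
probes of a crystal structure by Metropolis Monte Carlo annealing over
type-respecting permutations.  The energy of a mapping counts NOE edges whose
assigned methyl pair is farther apart than a cut-off *d*:

    E = w_noe · Σ_edges w_e · 1[r(probe_i, probe_j) > d]  +  w_pcs · Σ |δ_obs − δ_calc|

with mutual NOEs weighted 1 and one-sided NOEs ½.  Confidence comes from
consensus over independent trials (a peak counts as assigned only when every
trial agrees), the cut-off is scanned to maximize the consistent count, and
assignments found in only one protein state are transferred through a
titration peak map and fixed in a re-run of the other state — the
ligand-induced conformational change is what makes the two NOE sets
complementary.

**Paramagnetic restraints.**  Pseudocontact shifts follow the five-parameter
traceless Δχ-tensor form

    δ_pcs = (1/4πr⁵) · [x²−z², y²−z², 2xy, 2xz, 2yz] · (Δχxx, Δχyy, Δχxy, Δχxz, Δχyz)ᵀ

fitted by linear solve + nonlinear metal-position refinement over a structural
ensemble, with bootstrap errors, unique-tensor-representation (UTR)
decomposition, and ensemble Q factors.  PREs follow the Solomon–Bloembergen–
Morgan equation for Γ₂ = R₂,para − R₂,dia; the metal is localized by BFGS
minimization of the S_Γ₂-weighted ensemble cost.  PCS-restrained MMC re-runs
expand the NOE assignment, accepting a new assignment only when two Δχ tensors
of opposite field orientation agree on it; PREs validate assignments in the
10–30 Å shell and can propose unique-distance matches.

**Four-state binding model.**  Paramagnetic observables come only from the
ternary UTP:metal:protein (UMP) complex, while free metal above ~80 µM causes
unspecific broadening.  The coupled equilibria

    U + M ⇌ UM (K_D1),  U + P ⇌ UP (K_D2),  UM + P ⇌ UMP (K_D3),  UP + M ⇌ UMP (K_D4)

obey the cycle K_D1·K_D3 = K_D2·K_D4 and are solved by damped Newton on the
log free concentrations, giving occupancy and free-metal curves that tell you
how much metal to add.  Dissociation constants for the UDP-glucose
pyrophosphorylase (LmUGP) / UTP / lanthanide system ship with the package,
and two-state K_D values can be fitted globally from CSP titrations.

A ground-truthed synthetic generator (two-state toy structures, NOE lists
with dropout, PCS/PRE tables, isotherm titrations) closes the loop: every
analysis stage is tested by recovery against known truth.

## Worked example

Simulate a 50-probe two-state toy, build the NOE network and assign it:

```
$ methylwalk simulate --preset toy50 --seed 3 --outdir demo
synthetic toy50 written to demo
$ methylwalk build-network --hmqc demo/peaks_a.tsv --noes demo/noes_a.tsv \
      --tol-h 0.004 --tol-c 0.04 --out demo/net_a.tsv
95 edges (0 problem cross-peaks) -> demo/net_a.tsv
$ methylwalk assign --network demo/net_a.tsv --peaks demo/peaks_a.tsv \
      --pdb demo/state_a.pdb --cutoff-scan 6:8:1 --trials 10 --steps 8000 \
      --seed 7 --out demo/assign_a.csv
cutoff 7.0 A: 50/50 consistent -> demo/assign_a.csv
```

The scan picks the 7 Å cut-off (the contact radius the NOEs actually encode)
and all 50 peaks are consistently assigned across the 10 trials; the CSV
lists each peak's residue, consistency count and status, and the JSON report
next to it records the per-cut-off scan and seeds.

Planning a paramagnetic sample answers "how much EuCl₃ can I add before free
metal broadens everything?":

```
$ methylwalk plan-metal --metal Eu --protein 100 --utp 3500 \
      --metal-grid 0:3000:50 --ceiling 80 --out demo/plan_eu.tsv
Eu: M_t = 2650 uM -> occupancy 64.7%, free metal 78.3 uM
```

i.e. at 100 µM protein and 3.5 mM UTP you can push total Eu to 2.65 mM
(65% metal-site occupancy) before free Eu³⁺ crosses the 80 µM ceiling.

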