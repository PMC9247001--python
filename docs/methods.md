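# Methods

This note records the models implemented in `methylwalk`, the defaults and
units that matter, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Peak matching and residue typing

All peak matching operates in a scaled shift space (δH, δC/α) with α = 5, the
typical ratio of ¹³C to ¹H shift dispersion in the methyl region; default
tolerances are 0.02 ppm (¹H) and 0.2 ppm (¹³C) and are exposed on every
command.  Residue types come from selectively labeled samples: single-type
samples type peaks directly, and the Leu/Val pair is split by leucine
selective unlabeling (present in the combined Leu+Val list and in the
Val-only list → Val; combined only → Leu).  A reference peak matching
selective peaks of two different types is flagged ambiguous and left untyped
rather than guessed.  Cross-peaks of a 4D HMQC-NOESY-HMQC list are matched at
both ends; only uniquely matched, non-diagonal cross-peaks become graph
edges, and a cross-peak with two or more candidate HMQC peaks at either end
goes to a report with all candidates — overlap is surfaced, not resolved
silently.

## The MMC assignment engine

The assignment energy is a re-implementation designed around cut-off
semantics, not a port of any published program (the reference programs'
energy functions are not public).  Per mapping it counts NOE edges whose
assigned probe pair exceeds the cut-off distance; mutual edges (observed in
both NOE directions) weigh 1, one-sided edges ½.  An edge incident on an
unmapped peak always counts as violated, so letting a surplus peak float
never buys energy.  Optional restraint terms add weighted absolute
deviations: PCS with weight 10 (matching the relative scale of PRE-type
restraints in this kind of calculation; configurable) and chemical shifts
with weight 1e-12, which keeps the term visible in the data model while
excluding it from the optimization in practice.

Annealing uses a geometric schedule over 50 temperature levels (default
T: 3 → 0.02 in edge-count units, 20 000 steps per trial); moves are
within-type swaps and relocations to free probes, never touching fixed
peaks.  Inter-methyl distance is carbon–carbon between the labeled methyl
carbons — a single well-defined atom per probe; a pseudo-proton option
exists but is off by default.  Consensus over 20 independent trials requires
unanimity ("consistent"); a relaxed quorum is available but off by default.
Cut-off scanning re-runs the full consensus per cut-off and picks the one
with the most consistent peaks, ties going to the smallest cut-off.  The
two-state protocol transfers single-state assignments through the titration
peak map as fixed constraints and iterates until the consistent sets stop
growing (typically one round); cross-state disagreements and transferred
fixes that violate the receiving state's NOEs are reported, never silently
overwritten.  Untyped peaks are excluded from the search and reported;
when peaks outnumber probes of a type the surplus floats.

## PCS and Δχ tensors

The pseudocontact shift is evaluated in the five-component form (components
Δχxx, Δχyy, Δχxy, Δχxz, Δχyz; Δχzz implied by tracelessness), which is linear
in the components.  Fitting therefore does a linear least-squares solve at
any metal position and, when the metal is released, wraps that inner solve
in a Levenberg–Marquardt refinement of the three coordinates.  Calculated
values are averaged over the models of a structural ensemble; the ensemble
Q factor sums the model-summed residual per atom over the model-summed
observed values, reducing to the standard Q for a single model.  Working
units are 10⁻³² m³ for tensor components, Å for coordinates, ppm internally
for shifts (Hz at I/O given the ¹H spectrometer frequency).  Only ¹H shifts
enter fits; ¹³C values may be stored but are never fitted (they carry larger
residual-anisotropy errors).  Residual anisotropic shift corrections
(RACS/RADS) are not applied — a known simplification that matters at the
few-Hz level for ¹³C but little for the ¹H-only fits done here.

Bootstrap errors refit on 80% subsets without replacement (1000 iterations
by default, seed-reproducible); underdetermined draws are skipped and
counted.  The UTR decomposition orders principal values by magnitude
(|χzz| ≥ |χyy| ≥ |χxx|), defines Δχax = χzz − (χxx+χyy)/2 and
Δχrh = χxx − χyy, and reports ZYZ Euler angles of the eigenframe;
near-degenerate eigenvalues flag the angles as undefined.  Two tensors are
"opposite" when their predicted fields over the probes anticorrelate
(Pearson r < 0) — an operational definition chosen because opposite-sign
anisotropies are exactly what makes two lanthanides cross-validate an
assignment.  PCS-based expansion accepts a new assignment only when at
least two pairwise-opposite tensors agree on it, and reports prior
assignments that a PCS run contradicts.

## PREs and metal localization

Γ₂ = R₂,para − R₂,dia with quadrature error propagation.  R₂ comes from
single-exponential fits of interleaved decays on the 0–100 ms delay grid;
peaks below 3σ of the spectral noise floor at the 6 ms delay are excluded
with a reason, and uncertainties are one standard deviation over Monte-Carlo
refits with noise at the floor.  The dipolar SBM expression uses
τc⁻¹ = τr⁻¹ + τs⁻¹ (τs = 9.6 ns for Mn²⁺ at 600 MHz; τr is an input, e.g.
from TRACT) and is evaluated at the methyl carbon, treating the three
equivalent protons as one probe at the carbon; calculated rates are scaled
by the bound fraction of the paramagnetic ternary complex (0.0241 for the
Mn²⁺ sample composition, computed by the binding module).  The metal is
localized by BFGS minimization of the uncertainty-weighted ensemble cost
with the model residuals summed per atom exactly as defined (a mean-mode
switch exists); five random restarts around the initial position guard
against local minima, and the position SD is one standard deviation over
Monte-Carlo refits with Γ₂ noise at the reported uncertainties.

The Curie-spin contribution is computed from the standard thermally-averaged
moment expression with τr as the correlation time, and is used only for
negligibility checks, never in fitting.  For the Mn²⁺ conditions modelled
here it stays below 10% of the total — small enough that neglecting it in
the dipolar fits is safe, though the exact ratio depends on τr and on
convention details that differ between treatments in the literature.

## Binding model

The four-state solver treats the free concentrations (P, U, M) as unknowns
of the three mass balances, with complexes given by mass action
(UP = PU/K_D2, UM = UM/K_D1, UMP = PUM/(K_D2·K_D4)).  It runs damped Newton
on the logs of the free concentrations (positivity by construction, analytic
Jacobian) starting from a nested-bisection profile, and demands residuals
below 1e-9 relative.  Missing constants are filled through the thermodynamic
cycle K_D1·K_D3 = K_D2·K_D4; when all four are given and the cycle does not
close (the Mn²⁺ row, whose K_D3 is borrowed from Mg²⁺), the given K_D4
governs ternary-complex formation and the deviation is reported via
provenance flags.  The Tb³⁺/Tm³⁺ metal–UTP constants are unmeasurable under
strong PREs and use the mean of the measured lanthanide values.  Occupancy
is defined as UMP/P_t (total protein in the denominator); with UTP in large
excess the alternative denominator (UTP-bound protein) gives nearly the same
number for the compositions of interest.  CSPs are Euclidean combinations
in Hz; the two-state isotherm is the closed-form quadratic root, and global
K_D fits share one K_D across the curves selected by the mean + 2 SD rule at
the highest ligand point, with Monte-Carlo errors.

## Synthetic data: what it emulates, and what it does not

The generator packs methyl probes on a jittered grid (minimum distance
> 4 Å, nearest neighbours typically 5–8 Å), draws residue types in the
proportions of the 199-methyl LmUGP constellation (43 Ala / 16 Ile / 50 Leu /
19 Met / 30 Thr / 41 Val; a 199-probe preset uses the exact counts), and
creates a second state by rigidly rotating the probes on one side of a random
plane — a hinge motion of configurable fraction and angle (defaults 30%,
17°).  Chemical shifts occupy literature-like per-type regions (the region
table in `synthetic.py` is this package's own choice), so peak-overlap
statistics are realistic.  NOE lists contain both directions of every pair
within the cut-off with independent per-direction dropout, optional false
peaks between beyond-cut-off pairs, and optional overlap merging.  PCS/PRE
tables are exact field evaluations plus Gaussian noise; PRE tables drop
probes whose true Γ₂ exceeds a detectability ceiling (default 300 s⁻¹),
because real spectra never contain those bleached signals.  Titrations obey
the closed-form isotherm with straight-line peak motion.

What passing these tests shows: the algorithms recover ground truth under
controlled imperfections (dropout, noise, overlap) at the study's scale and
geometry.  What they do not show: robustness to spectral artefacts the
generator does not model — relaxation-dependent NOE intensities, chemical
exchange broadening, peak-picking errors, incorrect structures, or
deviations of solution conformations from the crystal.

## Numerical choices and problem sizes

Tolerances: equilibrium solves to 1e-9 relative; tensor fits solved by
`lstsq`/Levenberg–Marquardt with machine-precision linear algebra; MMC
reproducibility guaranteed by spawned per-trial seeds.  Tie-breaks: cut-off
scan ties go to the smallest cut-off; contested titration links go to the
closer predecessor, the loser flagged.  Degenerate inputs: all-zero observed
vectors make Q undefined (error), constant PCS fields make the orientation
test undefined (error), flat PRE cost landscapes are rejected.

The test suite runs desk-scale problems: 10–50-probe toys (the 199-probe
preset is exercised for generation only), 6–20 MMC trials with 2 000–10 000
steps, and 20–1000-draw Monte-Carlo/bootstrap loops, chosen so the full
recovery loops (including the five-seed end-to-end pipeline) complete in
about a minute of CPU while leaving comfortable statistical margins.

## Known limitations

- The MMC energy is a faithful re-design around cut-off counting, not a
  reproduction of any specific published program; absolute energies are not
  comparable across programs, only the resulting assignments.
- RACS/RADS corrections and ¹³C PCS fitting are out of scope.
- Curie-spin relaxation is diagnostic only; cross-correlation effects are
  not modelled.
- The experimental Q factors for the deposited LmUGP data (0.172 for the
  Mn²⁺ PREs, 0.133 for the Tb³⁺ PCS on the three-structure ensemble) can
  only be recomputed with the deposited observation tables and the public
  crystal structures; the corresponding test states exactly which files it
  needs under `data/external/` and fails otherwise.
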