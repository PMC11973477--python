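# Methods

`macropka` implements the desk-side half of a physics-based pKa-prediction
workflow for flexible polybasic molecules such as tetra-aza macrocycles:
everything from "per-microstate Gibbs free energies" to "pKa ladder,
protomer assignment, and speciation diagram". The expensive upstream half —
metadynamics conformer sampling (CREST/GFN2-xTB class tools) and DFT
refinement in continuum solvent — is deliberately external; it communicates
with this package through a plain free-energy table.

## Model

### Microstates

A molecule with N exchangeable protons defines 2^N protonation microstates,
encoded as occupancy bitstrings in the user's site order ("1011" = sites
1, 3, 4 protonated). The net charge of a state is
`reference_charge − (N − popcount)`, where the reference is the fully
protonated input species. Single-deprotonation transitions form the
N-dimensional hypercube (N·2^(N−1) edges). Spatial symmetry is *not* used to
deduplicate: symmetry-equivalent protomers are physically distinct
microstates and carry the statistical factors of the macroscopic ladder; the
API only allows annotating them for reporting. (Published descriptions of
this enumeration occasionally quote 14 rather than 16 states for a 4-site
molecule; the binomial breakdown 1 + 4 + 6 + 4 + 1 = 2^4 is what is
implemented.)

### Thermodynamic cycle

The microscopic pKa of a deprotonation HA^n → H⁺ + A^(n−1) is

    pKa = [G(A, aq) + G(H⁺, aq) − G(HA, aq)] / (RT ln 10)

with solute free energies from the upstream stage and the aqueous proton
free energy assembled from experimentally anchored pieces:

| quantity | default | units | note |
|---|---|---|---|
| T | 298.15 | K | |
| R | 1.98720×10⁻³ | kcal/(mol·K) | fixes RT·ln 10 = 1.3642 kcal/mol |
| G⁰_g(H⁺) = (5/2)RT − T·S⁰ | −6.286 | kcal/mol | S⁰ = 26.05 cal/(mol·K), Sackur–Tetrode at 1 bar |
| ΔG(1 atm → 1 M) = RT ln 24.46 | +1.894 | kcal/mol | standard-state change |
| ΔG_solv(H⁺) | −265.9 | kcal/mol | Tissandier-derived, 1 M → 1 M convention |
| G(H⁺, aq) total | −270.29 | kcal/mol | sum of the above |

Internal unit is kcal/mol; Hartree inputs are converted on ingest with
627.5095 kcal/mol per Hartree. A water-referenced alternative cycle
(HA + H₂O → H₃O⁺ + A) is provided for runs that use only computed solvation
free energies; its hydronium/water references are user-supplied and a
constant `offset` hook (default 0) accommodates post-hoc corrections such as
a water standard-state term, whose treatment upstream conventions leave
open.

Per protonation state, the default free energy is the **minimum** over its
conformers (lowest-energy conformation of each protonation state); a
Boltzmann ensemble average −RT ln Σ exp(−G_i/RT) is available behind an
explicit flag.

Note on invariants: the microscopic pKa is invariant under a global energy
shift and its *state-function part* is antisymmetric under donor/acceptor
exchange — the constant proton-reference term does not flip sign, so
pka(d,a) + pka(a,d) = 2·pka(0,0), which is what the property tests assert.

### Macroscopic ladder and speciation

Experiment measures stepwise pKa between adjacent total-charge states. Two
aggregation modes:

- `min_state` (default): each charge level represented by its lowest-G
  protomer.
- `boltzmann`: each level represented by −RT ln Σ exp(−G/RT) over its
  protomers — the binding-polynomial result, including statistical factors
  (for N identical independent sites, step k = p + log10((N−k+1)/k)).

The modes agree within log10(m) per level (m = protomers in the level), and
exactly when every level has one state. Step numbering follows the
experimental convention: **step 1 is the most basic transition** (lowest
adjacent charge pair), so a normal ladder is printed in descending pKa
order.

Speciation weights microstate s at a given pH by
exp(−[G(s) − n_s·μ_H]/RT) with μ_H = G(H⁺, aq) − RT ln 10 · pH, normalized
over states. All population arithmetic is in log space (log-sum-exp):
free energies of multiply charged species are hundreds of kcal/mol and
would overflow naive exponentials. The default pH grid is 0–14 in steps of
0.05. Titration midpoints are located by linear interpolation of
charge-fraction crossings; at the crossing of per-charge Boltzmann weights
the pH equals the boltzmann-mode ladder step, which the tests exploit as a
cross-check.

Degenerate protomer energies break ties to the lexicographically smallest
bitstring (deterministic, and stable for the symmetry-redundant states the
enumeration deliberately keeps), with a warning carrying the gap.

### Linear empirical correction

Continuum solvation under-screens highly charged species, inflating the
computed pKa spread (the packaged benchmark's molecule 2: 16 log units
computed vs 9.9 measured between first and fourth step). An affine map
`pKa_corr = a·pKa_comp + b`, fitted by **unweighted OLS of experimental on
computed** (scipy.stats.linregress), absorbs most of this systematic error.
On the packaged 32-pair benchmark: a = 0.505 (prints 0.50), b = 4.217
(prints 4.22), RMSD 3.87 → 1.21 log units. Pairing convention: the k-th
experimental pKa (descending) pairs with the k-th ladder step (descending).
The identity map lies in the fit family, so in-sample the corrected RMSD
can never exceed the uncorrected one — a property tested on random data.
Leave-one-molecule-out refitting ships as a transferability diagnostic
beyond the single benchmark fit.

Reported fit parameters keep full precision; comparisons to two-decimal
published values round at the comparison, not in the model. (Published
summaries of the same benchmark round the corrected RMSD to both 1.21 and
1.20; the value recomputed from the packaged columns, 1.208, is primary.)

## Surrogate generator

The surrogate replaces the external quantum-chemistry stages with a
site-interaction model whose answers are known exactly: site i has intrinsic
pKa p_i and pair (i, j) a symmetric penalty ε_ij (log units) for
simultaneous protonation. State energies are built so that

    pKa(s → s − e_i) = p_i − Σ_{j≠i} s_j ε_ij   (exactly)

with the fully deprotonated state pinned at G = 0 kcal/mol (arbitrary;
every output is shift-invariant). Energies are state functions by
construction, so thermodynamic-cycle closure holds to round-off even with
noise. Options: extra conformers shifted by U(0, spread) and Gaussian
per-conformer noise N(0, σ) — per conformer, not per state, mimicking
conformational-sampling error, the dominant stochastic stage of the real
workflow. All randomness flows from one integer seed; a fixed model emits a
byte-identical table.

What the surrogate does *not* emulate: physically realistic conformational
energetics, solvent-model systematic error, or tautomerization involving
non-listed sites. Passing surrogate tests therefore demonstrates the
correctness of the enumeration/thermodynamics/aggregation machinery, not
the accuracy of any quantum-chemistry protocol on real molecules — that is
what the packaged experimental benchmark is for.

## Packaged reference data

- `table1` — 32 measured stepwise pKa over ten synthesized tetra-aza
  macrocycles, paired with thermodynamic-cycle predictions
  (M06-2X/def2-TZVP/SMD, proton cycle, lowest conformer per state), with
  per-row literature source tags. This is the LEC training and validation
  set.
- `table2` — corrected predictions for four not-yet-synthesized macrocycles.
  Display/regression only: recomputing them requires the external
  CREST/DFT stages, as do protomer identities from real energies and
  model-chemistry comparisons, none of which are recomputable here.

Both files are TSV with SHA-256 checksums verified on load.

## Numerical choices and problem sizes

- Enumeration is capped at N = 20 sites (2^20 states) with a clear error.
- Missing microstate energies (real DFT runs do fail on some states) are
  skipped with a warning by default; `strict=True` raises; a whole empty
  charge level is always fatal for ladder construction.
- The brute-force binding-polynomial ladder used as a test oracle evaluates
  plain shifted exponential sums, independent of the pipeline's log-sum-exp
  path; round-trip agreement is asserted at 1e−9 for N ≤ 4.
- Monte-Carlo noise checks use 100 fixed seeds at 2 sites, 0.5 kcal/mol
  noise; property sweeps use 1000 random regression datasets — sizes chosen
  to keep the full suite in a few seconds while leaving the statistical
  assertions comfortably powered.

## Known limitations

- The package never relaxes stripped-proton geometries; lone-pair
  reorientation is left to the external sampling stage.
- SDF output places the whole net charge on the first atom (the in-memory
  structure tracks net, not per-atom, charge); net charge round-trips
  exactly, per-atom placement does not.
- The water-referenced cycle ships without a recommended hydronium free
  energy; users of that route must supply their own references.
- The LEC is a benchmark-specific correction: applying the packaged fit to
  chemistry far from polybasic aza-macrocycles extrapolates beyond its
  training support (the leave-one-molecule-out diagnostic quantifies this
  within the benchmark family only).
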