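# Methods

`ensemble-mimic` analyses conformational ensembles of a protein and of an
N-terminal fragment of it, with one goal: find the shortest contiguous
stretch of the fragment whose backbone dynamics reproduce those of the
full-length protein, and turn that stretch into a deliverable peptide
(cell-penetrating Tat fusion plus a scrambled control).  The motivating
system is the tumor suppressor Fhit, whose N-terminal 38 residues bind
annexin A4; the package ships the Fhit 1-38 sequence
(`FHIT_NTERM_SEQ`, UniProt P49789) as its default fragment.

## The analysis chain

1. **Ensembles.**  An `Ensemble` is a list of topology-identical
   `Conformer` frames, read from multi-model PDB or produced by the
   synthetic samplers.  Hydrogens and waters are dropped at parse time:
   every "all-atom" quantity in this package means all *heavy* atoms.
   This is a deliberate contract — crystal structures are routinely
   deposited without hydrogens and the synthetic samplers never place
   them, so heavy-atom-only keeps real and synthetic inputs commensurate.

2. **Superposition and RMSD.**  Rigid-body fits use the Kabsch algorithm
   (SVD of the 3x3 covariance, reflection corrected by a sign flip of the
   smallest singular direction).  Fit and measure selections are
   independent: conformer clustering fits and measures on backbone
   (N, CA, C, O); the fragment-vs-protein cross matrix fits on the mapped
   backbone and measures over all mapped heavy atoms.  The second
   convention is a documented choice: superposing on backbone and
   measuring everything is the standard way to compare a peptide's
   overall pose without letting sidechain noise steer the fit.  No mass
   weighting anywhere.  All-against-all matrices evaluate the Kabsch
   rotation for every frame pair via a batched 3x3 SVD and the closed
   form |A|^2 + |B|^2 - 2 tr(R H); the closed form cancels at the squared
   scale, so self-comparisons bottom out near 1e-7 A rather than 0.

3. **Residue fluctuation analysis (RFA).**  The ensemble is aligned to a
   converged mean (backbone fit, iterate superpose-onto-mean /
   recompute-mean until the mean shifts < 1e-6 A, max 10 iterations);
   RMSF_r is the root mean squared displacement of residue r's basis
   atoms (default: CA; a residue-heavy option exists) about their mean.
   Alignment removes 6 rigid-body degrees of freedom from 3N, so measured
   RMSF sits ~6/(2*3N) below the unaligned expectation — about 1% for the
   147-residue chain, which is why analytic-recovery checks use long
   chains or unaligned displacements.

4. **Clustering.**  Average-linkage agglomeration on the backbone RMSD
   matrix, merging while the smallest inter-cluster average distance is
   <= the cutoff (default 2.0 A), ties broken by the smallest index pair.
   The "cutoff among members of the same cluster" is read as this merge
   threshold; complete linkage would be a stricter alternative reading.
   Each cluster is represented by its medoid (smallest mean RMSD to the
   other members; ties to the lowest frame index).  The implementation is
   a direct Lance-Williams update and is tested against both an
   exhaustive re-averaging oracle and scipy's hierarchy module.

5. **Lysine reactivity.**  Amine-reactive cross-linkers (NHS esters such
   as DSP) mark lysines that are exposed and nucleophilic.  Exposure is
   ASASA: the trajectory mean of a lysine's sidechain solvent-accessible
   surface area, computed with Shrake-Rupley (probe 1.4 A, 960
   golden-spiral points per atom, Bondi radii: C 1.70, N 1.55, O 1.52,
   S 1.80 A).  Coordinates are rotated to a principal-axes frame before
   point placement so the discretised area is exactly invariant under
   rigid motion of the input.  ASASA averages over *all* frames, not just
   cluster representatives.  Nucleophilicity comes from an external
   per-lysine partial-charge table (TSV); more negative charge is read as
   a more electron-rich amine.  Both descriptors are min-max normalised
   over the lysine set and combined as a weighted mean (default weight
   0.5; exposure alone when no charges are supplied).  The combination
   rule is this package's choice — the descriptors are standard, a single
   published weighting is not.

6. **Mimetic window.**  Fragment and protein RFA profiles are compared
   over a positional identity mapping (the fragment is N-terminal; no
   sequence alignment).  The per-residue |dRMSF| profile is scanned
   exhaustively with a fixed-length window (default 5); the window with
   the smallest mean |dRMSF| wins, ties to the smallest start.  The core
   is then extended by up to `max_extension` (default 1) flanking
   residues per side whose Kyte-Doolittle hydropathy is negative —
   a solubility heuristic that admits Gln (-3.5) and Ser (-0.8) but not
   Val/Ile.  Finally the extended peptide is fused downstream of the
   HIV-1 Tat 47-58 sequence (YGRKKRRQRRR) with a Gly linker, and a seeded
   Fisher-Yates scramble (re-drawn until it differs from the input)
   provides the composition-matched control.

## Synthetic ensembles

Desk-scale surrogates stand in for explicit-solvent MD; both samplers
are fully seeded (`numpy.random.default_rng`), and identical spec + seed
reproduces coordinates bitwise.

**Reference geometry.**  `build_reference_chain` places CA atoms on a
regular coil with 3.6 residues/turn and 1.5 A rise, radius chosen so the
CA-CA spacing is exactly 3.8 A.  N/C/O are placed off the local tangent
and normal; a single CB pseudo-sidechain sits 1.5 A along the outward
radial, perpendicular to the chain direction (glycine gets none — the
spirit is a minimal united-sidechain model in which relative, not
absolute, sidechain exposure is meaningful).  When a flexible loop is
requested, the loop residues are built with the per-residue rise
stretched to 3.7 A (turn angle re-solved to keep CA-CA at 3.8 A): the
loop physically strings out along the coil axis, keeping only |i-j| <= 2
contacts at a 10 A cutoff (~4.5 springs/residue vs ~12 in the core).

**Gaussian sampler.**  Frame coordinates are the reference plus a rigid
per-residue displacement drawn i.i.d. per residue, frame and axis with
per-axis SD a_r; the expected unaligned CA RMSF is a_r * sqrt(3).  The
default amplitude is 0.3 A/axis (CA RMSF ~ 0.52 A — a typical folded
core), tripled inside the flexible loop.  Rigid-residue displacement
keeps intra-residue geometry fixed, so sidechain exposure varies only
through packing, and every statistical property is analytically
checkable.

**ENM sampler.**  Overdamped Langevin (Euler-Maruyama) dynamics on CA
beads connected by harmonic springs (k = 10 energy/A^2) between all
reference pairs within 10 A, at kT = 0.6, dt = 0.005, friction 1
(mobility dt/gamma = 0.005; stable well below the ~2/k_max limit), 2000
equilibration steps, one frame every 20 steps; backbone/CB atoms ride
rigidly on their CA.  The low-contact loop fluctuates more than the core
because fewer springs restrain it — the mechanism, not the magnitude, of
the real protein's flexible loop.  Any coordinate exceeding 1e3 A aborts
with a stability error suggesting a smaller dt.

**Planted mimicry.**  `sample_fragment_pair` truncates the protein
sequence to the fragment range and transfers the protein's gaussian
amplitude profile, multiplied by `outside_scale` (default 2.0)
everywhere except inside the planted window.  Downstream window
selection should therefore recover the planted window; with 150 frames
the per-residue |dRMSF| noise (~0.03 A) is an order of magnitude below
the planted contrast (~0.5 A), and recovery is near-certain.  Planting
is defined for the gaussian sampler only: the amplitude-transfer rule
has no elastic-network analogue.

**What the surrogates do and do not show.**  They reproduce the
*statistical shape* of trajectory analyses — frame counts, matrix
cardinalities, fluctuation contrasts, window recovery — under known
ground truth.  They have no force field, solvent, or thermodynamics, and
their absolute RMSD/SASA magnitudes are not those of real MD: with the
default 0.3 A amplitudes the cross-ensemble RMSD values sit below 2 A,
so the fraction-in-[2,4] A statistic is near zero on synthetic defaults
even though the machinery computing it is fully exercised.  Passing
tests validate the pipeline's correctness, not any claim about real
Fhit dynamics.  Likewise positions 39-147 of the default chain are a
fixed synthetic tail (only residues 1-38 are the real Fhit sequence),
so lysine rankings beyond the fragment are exercise data.

## Numerical choices

- Kabsch requires >= 3 non-collinear points (second singular value
  > 1e-8); degenerate input raises rather than returning an arbitrary
  rotation.
- Ensemble alignment: convergence at max mean shift < 1e-6 A or 10
  iterations, mean initialised to frame 1.
- SASA quadrature: 960 points keeps the isolated-sphere error under 1%;
  doubling the count moves it by < 0.5%.  Neighbour search uses a k-d
  tree with radius 2 * max expanded radius.
- fraction_in_range uses a closed interval [lo, hi] (boundary values
  count); a per-row variant (row means classified instead of entries) is
  exposed for the alternative "fraction of structures" reading.
- Tie-breaks are everywhere lowest-index/lowest-residue, making every
  stage deterministic; pipeline outputs are written with fixed float
  formats so reruns are byte-identical.
- Unknown elements get the default 1.70 A radius with a warning; unknown
  residue names map to 'X' with a warning; multi-chain files use the
  first chain with a warning.

## Problem sizes

Default study conditions: 150 frames per ensemble, 147-residue protein
with loop 108-127, fragment 1-38, planted window 8-12, cluster cutoff
2.0 A, probe 1.4 A, 960 sphere points, RMSD band 2-4 A, window length 5.
Statistical guarantees (loop flexibility, window recovery) are assessed
over 100 seeds at these sizes; analytic RMSF recovery uses 1000 frames.
The end-to-end determinism check runs a 24-frame, 120-point
configuration — determinism is size-independent, so the smallest
faithful run is used.

## Known limitations

- No mmCIF input; no loop rebuilding (missing residues are detected and
  reported, never modelled); first-chain-only for multi-chain files.
- The window scan is fixed-length and exhaustive; it will happily select
  a window in noise if no true mimicry exists (the score magnitude, also
  reported, is the guard).
- QM charges are consumed from a TSV, never computed; the ranking
  without charges is exposure-only.
- The scrambled control is random among non-identity permutations; it is
  not guaranteed to avoid partial motifs of the original peptide.
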