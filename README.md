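# ensemble-mimic

Conformational-ensemble analysis for designing a minimal peptide mimetic
of a protein's dynamics.

## The problem

The tumor suppressor Fhit binds annexin A4 (ANXA4) through its
N-terminal 38 residues; the interaction is captured experimentally with
the amine-reactive cross-linker DSP, whose NHS-ester groups react with
lysine sidechains.  Designing a short, soluble, cell-penetrating peptide
that recapitulates this binding requires answering, from structural
ensembles alone:

1. **Which lysines react?**  Rank every Lys by exposure (trajectory-mean
   sidechain SASA, "ASASA") and, when quantum-chemistry partial charges
   are supplied, by amine nucleophilicity.
2. **Where is the protein flexible?**  Residue fluctuation analysis
   (per-residue RMSF of the aligned ensemble) flags mobile loops.
3. **Does the free fragment still move like the protein?**  An
   all-against-all cross-RMSD matrix (every fragment frame vs every
   protein frame, backbone fit, all-heavy-atom measure) plus the
   fraction of values in a 2-4 A band.
4. **What is the minimal mimetic window?**  The contiguous stretch
   minimising the mean per-residue |dRMSF| between fragment and protein,
   extended by hydrophilic flanks (Kyte-Doolittle < 0) for solubility,
   then fused to the HIV-1 Tat 47-58 carrier (YGRKKRRQRRR-G-…) with a
   seeded scrambled control.

The package implements this whole chain as a library plus a CLI, with
seeded synthetic ensemble generators (an analytic gaussian sampler and a
coarse-grained elastic-network Langevin sampler) standing in for
molecular-dynamics trajectories, so every statistical claim is testable
against planted ground truth.  See `docs/methods.md` for the model
details and assumptions.

At its core are three standard quantities, for frames x, y with atom
selections F (fit) and M (measure):

- RMSd(x, y) = min over rigid T of sqrt( mean_{i in M} |T x_i - y_i|^2 ),
  with T fitted on F by the Kabsch algorithm;
- RMSF_r = sqrt( mean over frames and basis atoms of residue r of the
  squared displacement from the mean structure ), after alignment to a
  converged mean;
- SASA by Shrake-Rupley with a 1.4 A probe and 960 deterministic
  golden-spiral points per atom.

Clustering is agglomerative average linkage with a 2.0 A backbone-RMSd
merge cutoff; each cluster is summarised by its medoid.

## Worked example

Run the full pipeline on the default synthetic system — a 147-residue
chain whose first 38 residues are the human Fhit N-terminus, a flexible
loop at 108-127, a 1-38 fragment with a planted mimetic window at 8-12 —
with 150 frames per ensemble:

```
$ ensemble-mimic run --seed 1 --outdir out
cross matrix entries: 22500
fraction of RMSD in [2.0, 4.0] A: 0.0000
clusters: 1
core window: 8-12 (mean |dRMSF| 0.0273 A)
extended window: 7-13 -> QHLIKPS
Tat construct: YGRKKRRQRRRGQHLIKPS
```

Reading the output: the two 150-frame ensembles give a 150 x 150 = 22500
cross-RMSd matrix; the synthetic amplitudes (0.3 A per axis) keep those
values below 2 A, so the 2-4 A fraction is zero and the whole protein
ensemble collapses into one cluster at the 2.0 A cutoff.  Window
selection recovers the planted 8-12 core — its mean |dRMSF| of 0.027 A
is pure sampling noise, an order of magnitude below the ~0.5 A contrast
planted outside the window — and the hydrophilic extension picks up
Gln7 and Ser13 (Kyte-Doolittle -3.5 and -0.8) but stops before Gly6/
Val14, yielding the QHLIKPS heptapeptide and its Tat fusion.  `out/`
additionally contains the RFA profiles, cluster and medoid tables, the
lysine ASASA/reactivity ranking, the full cross-RMSd matrix, the
peptides as FASTA (including the scrambled control) and a provenance
block (`report.json`); rerunning with the same seed reproduces every
file byte-for-byte.

Individual stages are available as subcommands (`generate`, `analyze`,
`sasa`, `rank-lysines`, `compare`, `map-peptide`) and as library
functions, e.g.:

```python
import ensemble_mimic as em

ens = em.read_pdb_models("ensemble.pdb")          # multi-model PDB
profile = em.residue_fluctuation(ens)             # RFA
asasa = em.lysine_asasa(ens)                      # Lys exposure
table = em.rank_lysines(asasa, em.load_charge_table("charges.tsv"))
```

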