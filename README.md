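# somtool

Analysis toolkit for molecular-dynamics studies of **proteins embedded in
condensed soil-organic-matter (SOM) models** — humic-substance matrices,
simple organic co-solvent systems (calcium acetate/benzoate, calcium
chloride) and explicit water.  It is aimed at computational biophysicists
and soil scientists who run such simulations and need the bespoke
post-processing those systems require, plus a synthetic-data layer that
makes every stage of the pipeline testable without an MD engine.

## What it computes

* **Insertion protocol** (`somtool.insertion`): embed a protein into a dense
  organic matrix InflateGro-style — inflate the box by +1 nm per dimension
  (matrix molecules moved rigidly, fractional centres preserved), place the
  protein at the box centre with overlap removal and ion rebalancing, then
  deflate in 10 × 0.1 nm steps, each followed by a relaxation
  (built-in soft-sphere steepest descent, or any user-supplied minimizer)
  with the protein positionally restrained at k = 10⁵ kJ mol⁻¹ nm⁻².
* **Minimum-distance function** (`somtool.contacts`): per frame, the
  distance between the closest atoms of a functional-group/ion instance and
  the protein; instances of one label are concatenated into a 200-bin
  histogram normalized by the number of instances.
* **Hydrogen bonds** (`somtool.hbonds`): geometric criterion
  (donor–acceptor ≤ 0.35 nm, H–D–A ≤ 30°), per-frame counts classified by
  the protein's partner species (protein/SOM/water/ion).
* **Cluster analysis** (`somtool.clustering`): molecules joined into one
  cluster when ≥ 1 hydrogen bond connects them; only SOM and protein
  molecules are nodes; clusters are connected components, reported as a
  time series with a 1-ns running average.
* **Kirkwood–Buff preferential solvation** (`somtool.solvation`):
  centre-of-mass RDFs, running integrals
  G_ij(R) = 4π ∫₀ᴿ [g_ij(r) − 1] r² dr averaged over R ∈ [1.0, 1.6] nm, and
  δ_s,ij = x_i x_j (G_si − G_sj); δ ≈ 0 signals homogeneous mixing.
* **Nonbonded energy decomposition** (`somtool.energetics`): pairwise
  Coulomb with reaction-field correction
  (E_C = f q_i q_j (1/r + k_rf r² − c_rf), ε_rf = 61, cutoff 1.4 nm, so
  E_C(r_cut) = 0 exactly) plus Lennard-Jones, summed per partner species.
* **Stability and ensemble similarity** (`somtool.ensemble`): Kabsch
  superposition, backbone RMSD, per-atom RMSF about the average structure,
  and the harmonic ensemble similarity
  D_HES = ½[KL(N_a‖N_b) + KL(N_b‖N_a)] between multivariate-Gaussian fits
  to two conformational ensembles.
* **Replicate statistics** (`somtool.stats`): pooled two-sample t-tests
  (n = 3 replicates), Bonferroni correction per metric family, significance
  stars (* ≤ .05, ** ≤ .01, *** ≤ .001 on the adjusted p).
* **Synthetic data** (`somtool.synthetic`): systems and trajectories with
  *planted* ground truth — contact shells at a known distance, exact
  hydrogen-bond graphs, ideal-gas frames, Gaussian ensembles — used
  throughout the test suite.

## Worked example

Plant a carboxyl contact shell at 0.19 nm around a 6-bead model protein
and recover it with the MDF pipeline, then check the composition
bookkeeping on a single acetate:

```python
from somtool import (SyntheticSpec, make_trajectory, make_system,
                     carbon_fractions, average_molecular_weight)
from somtool.contacts import mdf_traces, mdf_histogram, mdf_peak

spec = SyntheticSpec(seed=1, box=6.0, n_protein_beads=6,
                     cosolvent_counts={"acetate": 15}, n_frames=60,
                     planted_shell=("carboxyl", 0.19, 0.01))
traj = make_trajectory(spec)
hist = mdf_histogram(mdf_traces(traj, "carboxyl"))
peak, height = mdf_peak(hist)
print(f"carboxyl MDF peak: {peak:.4f} nm (height {height:.1f})")

top, _ = make_system(SyntheticSpec(seed=1, box=4.0,
                                   cosolvent_counts={"acetate": 1}))
print("carbon fractions:",
      {g.value: round(f, 2) for g, f in carbon_fractions(top).items()})
print(f"average MW: {average_molecular_weight(top):.1f} g/mol")
```

Output:

```
carboxyl MDF peak: 0.1925 nm (height 12.5)
carbon fractions: {'carboxyl': 0.5, 'aliphatic': 0.5}
average MW: 59.0 g/mol
```

The recovered peak sits within one 5-pm histogram bin of the planted
0.19 nm shell; the acetate template splits its two carbons evenly between
the carboxyl and aliphatic classes and weighs 59 g/mol.

A `somtool` command-line entry point exposes the same pipeline
(`simulate`, `insert`, `mdf`, `hbonds`, `clusters`, `energy`, `kb`,
`stability`, `dhes`, `stats`); run `somtool --help`.

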