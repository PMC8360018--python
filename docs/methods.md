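# Methods

This note documents the models, conventions and numerical choices behind
`somtool`, and what its synthetic-data tests do and do not demonstrate
about real simulation data.

## Scope and units

The package post-processes topologies and trajectories of proteins in
condensed organic-matter (humic-substance) models and their simple
co-solvent analogues.  It does not run dynamics: molecular-dynamics
engines, force-field assignment, thermostats/barostats and constraint
algorithms are out of scope, and secondary-structure assignment is left to
an external DSSP-style tool.  Internally all lengths are nm, times ps,
energies kJ/mol, masses amu, charges in units of e; Angstrom-based
formats (PDB) are converted at the I/O boundary only.  Boxes are
orthorhombic; triclinic input raises an explicit error.  Atom indices are
0-based internally, with native 1-based serials preserved in file formats.

## Insertion protocol

A protein is embedded into a pre-equilibrated dense matrix in three
stages.  *Inflate*: each box edge grows by `inflate_amount` (default
1.0 nm) and every non-protein molecule is translated rigidly so its
centre keeps the same fractional box position — molecules are
repositioned, never stretched.  *Place*: the protein's centre of geometry
is moved to the box centre; any matrix molecule with a heavy atom within
the removal radius (default 0.3 nm, roughly van der Waals contact) of a
protein heavy atom is deleted, and ions are removed and/or re-added so
the total charge is exactly zero (the smallest such change is chosen by
exhaustive search; re-added ions are placed at random positions at least
0.25 nm from all atoms).  *Deflate*: the box shrinks in `n_steps` equal
steps (default 10 x 0.1 nm; the product must equal the inflation, so the
final box is the original to machine precision), each step followed by a
relaxation with the protein positionally restrained at its placed
coordinates (default k = 1e5 kJ mol^-1 nm^-2).

Relaxation is a pluggable interface.  The bundled minimizer performs
steepest descent on a purely repulsive soft-sphere potential
U = sum eps (sigma/r)^12 over intermolecular pairs (eps = 1 kJ/mol,
sigma = 0.3 nm, minimum image, cutoff 1.4 nm) plus the harmonic
restraints.  This is a deliberate design decision, not an approximation
of any published force field: the protocol's contribution is the
inflate/restrain/deflate bookkeeping, and the only job of its relaxation
stage is to remove steric overlaps created by compression.  Users with an
MD engine can substitute full force-field minimization through the same
interface.  Steepest descent uses a displacement-bound step (initial
0.01 nm) doubled after an energy-lowering move and halved otherwise, so
the energy is non-increasing over accepted steps; it terminates when the
maximum atomic force falls below `sd_force_tol` (default
10 kJ mol^-1 nm^-1 — the per-step tolerance is configurable because no
authoritative default exists for the in-step criterion) or when
iterations are exhausted.  Coincident atoms (NaN forces) are resolved by
a seeded 1e-3 nm jitter; recurrence raises an error.  Neighbour search
uses a periodic k-d tree; an O(N^2) loop is kept in the tests as the
oracle.

## Contact analysis (minimum-distance function)

The MDF of a group instance is, per frame, the minimum over all
cross-pairs of minimum-image distances between the instance's atoms and
all protein atoms (hydrogens included by default; configurable).  A
"functional-group instance" is a contiguous run of atoms with one label
inside one molecule; an ion instance is the ion itself.  Same-label
traces are concatenated into a 200-bin histogram over [0, 1.0] nm (the
range is configurable; the default covers the contact shells of interest)
and counts are divided by the number of instances, making the frequency a
per-group quantity: replicating a trace leaves the histogram unchanged,
and total mass x n_groups equals the number of concatenated samples
exactly.  The peak is the centre of the maximal bin, ties broken toward
smaller distance.

## Hydrogen bonds and cluster analysis

A hydrogen bond D-H...A is declared when the donor-heavy-to-acceptor
distance is <= 0.35 nm (minimum image) and the H-D-A angle is <= 30
degrees — the conventional geometric defaults of MD analysis suites; both
cutoffs are configurable.  The angle convention is H-D-A (not deviation
from D-H...A linearity); this is an interpretation choice and is flagged
here because the two conventions differ for borderline geometries.  One
donor hydrogen may bond several acceptors; no exclusivity is imposed.
Partner accounting classifies every bond touching the protein by the
partner molecule's species without distinguishing donation from
acceptance; protein-internal bonds count as protein-protein.

For aggregation, molecules are nodes of a per-frame graph with an edge
wherever at least one intermolecular hydrogen bond exists; only
organic-matter and protein molecules are nodes, so water/ion bridges
never merge clusters.  Cluster counts are connected components (isolated
molecules are size-1 clusters), computed with networkx's BFS-based
routine and checked in the tests against an independent union-find and,
exhaustively, against all 1024 graphs on five nodes.  The time series is
smoothed with a centred moving average over a 1-ns window, shrinking
symmetrically at the edges (the smoothing literature-standard; whether
published running averages are centred or trailing is usually unstated,
and centred was chosen as the common plotting default).  Replicates are
summarized as mean +- standard error of the window means.

## Nonbonded energies

Pair electrostatics follow the truncated-Coulomb-plus-reaction-field
convention: E_C = f q_i q_j (1/r + k_rf r^2 - c_rf) inside the cutoff and
0 beyond, with k_rf = (eps_rf - eps1)/((2 eps_rf + eps1) R_c^3) and
c_rf = 1/R_c + k_rf R_c^2, so E_C is exactly zero and continuous at the
cutoff.  Defaults: R_c = 1.4 nm, eps_rf = 61, eps1 = 1, ionic screening
kappa = 0, f = 138.935458 kJ mol^-1 nm e^-2.  Lennard-Jones is the
unshifted C12/r^12 - C6/r^6 with geometric combination of per-atom
coefficients.  The decomposition is strictly intermolecular (protein vs
every other molecule, binned by partner species, class vocabulary driven
by the topology); intramolecular protein energetics, exclusions and 1-4
scaling are out of scope because the grouped protein-environment report
never needs them.  Forces, virials and mesh electrostatics are not
computed.

## Kirkwood-Buff solvation

RDFs are computed between molecular centres of mass (the species-level
preferential-solvation question is molecule-level; atom-level RDFs can be
had by passing positions directly), normalized by spherical-shell volume
and ideal-gas pair density, with self-pairs excluded and N(N-1)
normalization for the i = j case.  The running Kirkwood-Buff integral
G(R) = 4 pi int_0^R [g(r) - 1] r^2 dr is evaluated by treating the binned
g as piecewise-constant and integrating r^2 exactly per bin
(Sum 4 pi/3 (g_k - 1)(r_hi^3 - r_lo^3)).  This is the faithful quadrature
for histogram data: it is exact for g identically 1 and for bin-aligned
step functions such as a hard core (G = -(4 pi/3) sigma^3), and behaves
as a midpoint rule (O(h^2)) on smooth g.  A trapezoidal option exists for
comparison.  Because simulation boxes are finite, G(R) is averaged over
R in [1.0, 1.6] nm rather than extrapolated to infinity, and no
finite-size or closed-system corrections are applied — the window average
of the running integral is the reported quantity by design.

Preferential solvation of a solute s in a binary i/j solvent defaults to
the limiting linear (Ben-Naim) form delta = x_i x_j (G_si - G_sj); the
raw difference G_si - G_sj is exposed as an alternative convention since
published analyses often interpret only sign and magnitude.  delta near 0
indicates homogeneous mixing; in the tests, uncorrelated ideal-gas
species give delta within statistical error of zero while a deliberately
demixed two-block system gives a large positive self-association delta.

## Stability and ensemble similarity

Superposition is least-squares rigid-body (Kabsch) via quaternion-free
SVD alignment with the determinant constraint, so reflections are never
returned; collinear configurations raise an error.  RMSD is reported
after superposition per frame against a fixed reference structure.  RMSF
superposes each frame onto the iteratively refined trajectory-average
structure (not the external reference) — the standard fluctuation
convention, noted here as an assumption — and reports
sqrt(<|x_i - <x_i>|^2>) per atom.

The harmonic ensemble similarity D_HES models each conformational
ensemble as a multivariate normal over the flattened coordinates of a
selection (C-alpha-like beads by default) and returns the symmetrized
Kullback-Leibler divergence ½[KL(a||b) + KL(b||a)] in closed form.
Covariances receive a diagonal regularization of 1e-6 nm^2 so they are
invertible even when the sample count is below 3M; the value is small
against physical positional variances (>= 1e-4 nm^2 in practice) and is
configurable.  Ensemble pre-processing mirrors common practice:
subsample to one snapshot per 40 ps, concatenate replicates, and
superpose both ensembles onto the mean structure of their union so
rigid-body variance is removed symmetrically.  Only the harmonic variant
is implemented; clustering- and embedding-based ensemble comparisons are
out of scope.  Note that D_HES between two *independent finite samples*
of the same distribution is positive with bias of order d^2/n; the
identity D_HES = 0 holds for identical ensembles and in the large-n
limit, which is what the tests assert.

## Replicate statistics

Conditions are compared to the water reference with a two-sided
pooled-variance Student's t-test on n = 3 replicate means (Welch
available behind a flag); zero-pooled-variance degeneracies return p = 1
for equal means and p = 0 with a warning otherwise.  P-values are
Bonferroni-corrected with the family defined per metric as all
non-reference conditions carrying that metric (an inference from how
per-figure significance marks are usually grouped; a global family is a
one-line change).  Stars are assigned on the adjusted p at .05/.01/.001.

## Synthetic data: what it emulates and what it does not

The generator builds the study-like compositions from templates: 4-site
acetate and 9-site benzoate anions (united-atom carbon masses so their
molecular weights are the real 59 and 121 g/mol and their carbon
fractions are 0.50/0.50 and 0.14/0.86), SPC-like water, Ca2+/Cl-, a
4-site humic fragment with one donor arm and one acceptor, and an N-bead
protein chain (0.38 nm spacing, alternating donor/acceptor beads).
Packing places molecules at random poses with a 0.2 nm minimum spacing —
moderate density, chosen so the insertion stress test is well-posed
without making the toy relaxation stage the bottleneck.

Planted structure is exact by construction. Contact shells: each
labelled group is placed at a Normal(target, width) distance from a
randomly chosen protein bead along a direction perpendicular to the
chain (and away from the bead hydrogens), which provably makes that bead
the nearest protein atom, so the per-frame minimum distance *is* the
sampled draw.  Hydrogen-bond graphs: molecules sit on a 1.5 nm lattice;
each planted component is traversed breadth-first and the child's donor
arm is relocated collinear with the parent's acceptor at 0.25 nm
heavy-atom separation, comfortably inside the criterion, while the
lattice spacing keeps all non-edges far outside it; each donor arm is
used at most once, and graphs that need more than six neighbours of one
node, more molecules than lattice cells, or chemically impossible
donor/acceptor pairings raise an "unsatisfiable" error.  For cyclic
graphs only a spanning forest is realized geometrically — the connected
components, which the cluster analysis consumes, are identical.  Ideal
gas: every molecule is placed rigidly at an independent uniform position
with random orientation each frame, so pair correlations vanish in
expectation.  Gaussian ensembles are drawn from a specified multivariate
normal (symmetry and positive semi-definiteness checked).

These constructions validate the *analysis* chain: that the MDF recovers
a planted shell, clustering a planted component count, RMSF planted
variances, D_HES planted divergences, and that KB integrals vanish for
uncorrelated placement.  They do not validate anything about real MD
data — no excluded volume, no energetic correlations, no realistic
hydrogen-bond geometry distributions, no time correlation between frames
— so passing tests certify correct bookkeeping and estimators, not
force-field realism.

## Problem sizes and determinism

Default test and acceptance workloads are desk-scale by design: planted
shells use ~15 molecules x 60 frames, cluster schedules 50 molecules x 60
frames, RMSF recovery 1e4 frames of a 6-bead chain, oracle-equivalence
suites 100 random instances per primitive, and the insertion stress test
a ~500-molecule matrix (~1500 atoms) — sizes at which every brute-force
oracle is affordable while the statistical tolerances (5% on RMSF, one
bin on MDF peaks, +-1 cluster) are comfortably met.  All stochastic
stages take explicit seeds and use a single NumPy generator per call; no
global random state is touched, and identical seeds give byte-identical
systems.

## Known limitations

Orthorhombic boxes only; minimum-image distances beyond half the box
edge are reported with a warning rather than an error.  The soft-sphere
relaxation cannot reproduce force-field-specific packing (hydrogen-bond
networks, salt bridges) after insertion — it guarantees the protocol's
geometric contracts (box restoration, overlap removal, restraint
efficacy) only.  The trajectory format is plain-text concatenated GRO
blocks; engine-native compressed trajectories should be converted or
adapted through the frame-iterator interface.  The Bonferroni family and
the delta convention are documented choices where published practice is
ambiguous; both are configurable rather than hard-wired.
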