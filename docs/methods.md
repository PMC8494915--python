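# Methods

## The detection problem

Ligand binding to a G protein-coupled receptor such as CXCR4 transmits a
signal from the extracellular (EC) face to the intracellular (IC) face
without necessarily producing a large conformational change — much of the
transmission is carried by altered *fluctuation patterns*, mainly of side
chains ("dynamic allostery").  `dioscope` detects the residues carrying
such changes by comparing a ligand-free (apo) and a ligand-bound (holo)
MD trajectory of the same receptor.

The unit of analysis is the residue pair.  For every unordered pair
(i, j) the distance between the side-chain heavy-atom centers of mass is
sampled on a regular time grid, giving one distance vector per pair
(n residues → n(n−1)/2 vectors; for the full-scale CXCR4 system, 281
receptor residues → 39,340 vectors on a 1900-step grid from 50.5 to
1000 ns at 0.5 ns).  Side-chain rather than backbone distances are used
because the signal of interest is sub-conformational; glycine, which has
no heavy side-chain atom, is represented by its Cα (a standard
convention; a flag can exclude glycine pairs instead).

## Autoencoder and DIO vectors

A pyramidal autoencoder — fully connected layers whose widths descend
from the input dimension d in fixed steps to a floor, pass a narrow
coding layer, and mirror back up (d=1900, step 300, floor 400, code 100
gives 13 layers) — is trained on the apo pair vectors only, minimising
the mean squared reconstruction error (MSE) with minibatch Adam
(learning rate 1e-5, batch 100, up to 100,000 epochs at full scale).
80% of the rows train the network, 20% are held out; training stops when
the validation MSE has not improved for a `patience` number of epochs and
the best-validation weights are restored.  The stopping rule, hidden
activations (ReLU), output activation (linear) and input scaling (raw Å)
are deliberate choices where the procedure leaves them open; they are
all exposed in `AEConfig`, and the scaling choice is the reason DIO
values below retain a physical Å scale.

Inspecting a vector means a single forward pass.  Apo-like vectors
reconstruct accurately; vectors containing fluctuation structure absent
from the apo training distribution are pulled toward apo-like shapes.
The **DIO vector** of a pair is the per-time-step residual

    DIO = input − output

(the sign convention is recorded in output metadata; the analysis is
sign-sensitive downstream).  Apo pairs have small DIO; holo pairs whose
dynamics changed carry structured DIO.

The network is implemented directly on numpy: a dense ReLU stack with
hand-written backpropagation and Adam.  At the matrix sizes involved the
cost is dominated by BLAS matmuls, and a self-contained implementation
keeps training bit-reproducible under a single integer seed.

## Clustering and role extraction

For one apo–holo combination, the apo and holo DIO rows are stacked and
clustered jointly: cosine dissimilarity d(u,v) = 1 − u·v/(‖u‖‖v‖)
(range [0, 2]), agglomerated under the Ward.D2 criterion, i.e. the
Lance–Williams update

    d(i∪j, k) = sqrt( ((n_i+n_k) d_ik² + (n_j+n_k) d_jk² − n_k d_ij²) / (n_i+n_j+n_k) )

on the raw dissimilarities — the behaviour of R `hclust(method="ward.D2")`,
here provided by `scipy.cluster.hierarchy.linkage(method="ward")` on the
condensed matrix and verified in the test suite against an independent
O(n³) greedy oracle.  Rows with exactly zero norm have no direction; they
are placed at distance 0 from one another and 2 from every nonzero row
(logged).  The tree is cut at k = 2..9 clusters.

Within a cluster, the *partner fraction* of residue r is the number of
distinct residues it is paired with in that cluster divided by
(universe − 1), where the universe is all residues of the clustered
system (receptor plus ligand when present; a switch restricts it to the
receptor).  Fraction ≥ 0.8 makes r a **Lead** residue, 0.6 ≤ fraction
< 0.8 an **Accm** (accompanying) residue; both boundaries are inclusive
at the lower end.  At each cut the cluster holding the most pairs — in
practice the near-zero apo background — is treated as the remainder and
excluded from role extraction.  The scan stops at the smallest k whose
successor contributes no receptor Lead/Accm residue beyond those already
seen; if the range is exhausted the result is flagged.  Roles are
reported at the chosen k.  Four combinations (two apo replicates × two
holo replicates, each apo training its own network) are aggregated by
union with per-residue provenance, and each residue is annotated with
its helix region.

## Region annotation

A helix-boundary table (shipped for CXCR4: TM1 9–41, TM2 50–77, TM3
83–118, TM4 124–152, TM5 172–206, TM6 214–244, TM7 252–279 on chain
1–281, N-terminus facing EC) is expanded into a total partition of the
chain into `TM{h}_{EC|TM|IC}` labels.  The TM stretch of a helix [s, e]
is [s+f−1, e−f+1] with flank width f (default 8, counting the helix ends
as the first flank residue); flanks join the compartment that helix end
faces, alternating EC/IC with helix parity; each inter-helix turn is
split at its midpoint, the extra residue of an odd-length turn staying
with the N-side half (the only split consistent with the documented
CXCR4 instance TM1_IC 35–45 / TM2_IC 46–56); the termini join the
outward regions of the first and last helices.  The odd-turn rule is
constrained only by the CXCR4 instances; other choices would relabel at
most one residue per odd turn.

## Evaluation and baselines

A detected residue set is scored against an externally supplied
reference list by recall (overlap/reference) and precision
(overlap/detected; undefined and flagged when nothing is detected).  A
two-column mapping table can renumber a homolog's reference residues —
e.g. experimentally derived CXCR2 signaling residues transferred to
CXCR4 numbering — and must be injective; building such mappings
(alignments) is out of scope.  With the documented full-scale counts
(25 reference, 102 detected, 14 shared) this gives recall 0.56 and
precision 14/102 ≈ 0.137.

Conventional comparison analyses are provided: the dynamic
cross-correlation matrix C_ij = ⟨Δr_i·Δr_j⟩/√(⟨Δr_i²⟩⟨Δr_j²⟩) of Cα
displacements after superposition; a residue ranking by unweighted
shortest-path betweenness centrality on the graph with edges |C_ij| ≥
threshold (default 0.5 — the construction details behind published
network baselines are not fixed, so the threshold is a flag and the
baseline carries no expected values); and the per-pair mean/variance
summary of the distance series.  Contact statistics (any-atom distance
strictly below 4 Å, sequence neighbours excluded) are aggregated by
region pair in two counting modes, `pair_frames` (pair × frame events)
and `unique_pairs`, because published contact totals do not determine
the counting semantics; neither mode is asserted to reproduce them.
The differential-contact filter selects region pairs abundant (> 100)
in both replicates of one form with all four cross-form count ratios
(min/max) below 0.1.

## Synthetic study conditions

The generator emulates only what the pipeline consumes: stationary
per-atom fluctuation with residue-localised perturbations.  Residues sit
on a ring with 3.8 Å Cα spacing (an ideal helix is available), each with
a CA backbone proxy and two side-chain atoms at 1.5 Å steps outward.
Every atom coordinate follows an independent Ornstein–Uhlenbeck process
(stationary sd 0.5 Å, relaxation 0.05 ns), chosen for its closed-form
stationary statistics, which the tests check directly.  In the holo
form, the side-chain atoms of the designated signaling residues acquire,
after a 2 ns onset, a 3 Å mean shift plus a 1 Å sinusoid of 2 ns period,
both along the residue's outward direction.  The outward (radial)
direction is a deliberate geometric choice: the Lead definition requires
one cluster to contain most of a residue's partners, which presupposes a
sign-coherent distance response; an isotropically random displacement
direction splits a residue's partners into two anti-correlated DIO
groups under the sign-sensitive cosine metric, each below the 60% bar,
and the concept being tested would be unreachable by construction.

Desk scale is 30 residues × 3 atoms × 2000 frames at 5 ps, features
sampled every 10th frame (200 steps), and a reduced pyramid (floor 100,
step 50, code 20, learning rate 1e-3, ≤ 400 epochs, patience 50,
`AEConfig.desk_scale`).  One run takes a few seconds on one CPU; the
multi-seed recovery suite runs in minutes.  These sizes were fixed as
the package's standard desk conditions and are not tuned per test.

What passing synthetic tests show — and what they do not: the pipeline
recovers residues whose side-chain fluctuation statistics change
coherently and localises them through the partner-fraction logic, and it
does not flag the designated set when no effect is planted (overlap at
chance level).  The generator's noise is temporally almost white and
independent across atoms, unlike real MD, where collective correlated
motions make apo vectors far more compressible; consequently apo DIO
rows here are not near-zero as they are in real data, the background
clusters are noisier, and precision on synthetic runs understates what
structured trajectories allow.  Recall of planted residues is the
meaningful synthetic quantity; membrane physics, anisotropic side-chain
rotamer dynamics and receptor–ligand pair types are not emulated.

## Numerical notes and limitations

- Time-grid points map to the nearest frame; exact matches are expected
  when the stride is a multiple of the save interval.  Windows outside
  the trajectory span are errors, not clamped.
- Distances are kept in Å end to end (nm-based formats are converted on
  load); DIO magnitudes therefore have physical units unless the
  optional min-max input scaling is enabled, which is recorded in
  metadata because it rescales DIO.
- RMSF/RMSD use a single Kabsch superposition pass against the
  time-average structure; reflections are excluded via the determinant
  sign.  The fitting protocol behind published RMSF curves is not
  specified anywhere, so this is a package convention.
- Determinism: all stochastic stages (weight init, batch order, splits,
  synthetic noise) derive from explicit integer seeds through
  `numpy.random.Generator`; reruns with the same config are
  reproducible, including written TSVs.
- The exact-distance contact matrix is O(n²) memory; above a
  configurable cap the CLI refuses rather than approximating.
- Degenerate inputs: empty reconstruction input returns an empty output;
  an empty DCCM network yields an all-zero flagged ranking; a detected
  set of size zero yields flagged undefined precision.
- The partner-fraction universe and the per-cluster-vs-global
  denominator question are genuinely open in the underlying procedure;
  both are configuration, with the defaults stated above.
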