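# dioscope

Detecting residues essential for receptor signaling by comparing apo and
holo molecular-dynamics trajectories with an autoencoder.

Ligand binding to a G protein-coupled receptor (the package ships
defaults for CXCR4) transmits a signal from the extracellular to the
intracellular face largely through changed *side-chain fluctuation
patterns* rather than large conformational motion.  `dioscope` finds the
residues carrying those changes:

1. **Features** — for every residue pair (i, j), the distance between
   side-chain heavy-atom centers of mass is sampled on a regular time
   grid, one vector x_ij per pair (n residues → n(n−1)/2 vectors; the
   full-scale CXCR4 window 50.5–1000 ns at 0.5 ns gives 1900-dimensional
   vectors, 39,340 of them for 281 residues).
2. **Autoencoder** — a pyramidal fully connected network (e.g.
   1900→1600→…→400→100→400→…→1900, 13 layers) is trained by Adam on the
   *apo* vectors only (80/20 train/validation, early stopping on the
   validation MSE).
3. **DIO** — each apo and holo vector is inspected by the apo-trained
   network; the residual DIO = x − x̂ is near zero for apo-like dynamics
   and structured for holo-specific fluctuation patterns.
4. **Clustering** — apo+holo DIO rows are clustered jointly (cosine
   dissimilarity, Ward.D2 linkage), cutting the tree at k = 2..9.
5. **Roles** — within each cluster (the bulk "remainder" cluster
   excluded), a residue pairing with ≥ 80% of the other residues is a
   **Lead** residue, with ≥ 60% and < 80% an **Accm** residue; a
   stopping rule picks the cut depth after which deeper cuts add no new
   receptor residues.  Results from several apo×holo combinations are
   aggregated, annotated with EC/TM/IC helix regions, and optionally
   scored (recall/precision) against a reference residue list.

DCCM + betweenness-centrality ranking and mean/variance summaries are
included as conventional baselines, and a synthetic trajectory generator
with planted signaling residues makes the whole pipeline testable
without any MD engine or download.

## Worked example

Generate a 30-residue synthetic system (2000 frames, 5 ps spacing,
0.5 Å baseline fluctuation) in which residues 5, 12 and 21 change their
side-chain dynamics after ligand binding, and run one apo–holo
combination end to end:

```python
from dioscope import SynthConfig, run_synthetic
from dioscope.roles_eval import evaluate_against_reference

result, truth = run_synthetic(SynthConfig(seed=1))
table = result.role_table
print("chosen k:", result.chosen_k)
print("planted:", sorted(truth))
print("Lead:", sorted(int(r) for r in table[table.role == "Lead"].residue.unique()))
print("Accm:", sorted(int(r) for r in table[table.role == "Accm"].residue.unique()))
ev = evaluate_against_reference(set(table.residue), truth)
print(f"recall of planted residues: {ev.recall:.2f}")
```

prints

```
chosen k: 5
planted: [5, 12, 21]
Lead: [5, 12, 21, 24]
Accm: [2, 4, 6, 9, 10, 18, 19, 25, 28]
recall of planted residues: 1.00
```

The tree was cut at k = 5 (deeper cuts added no new receptor residues);
all three planted residues emerge as Lead residues — each pairs with
nearly every other residue inside a holo-specific DIO cluster — along
with background residues picked up from noise clusters, which is why
recall rather than precision is the meaningful quantity at this scale.

The same stages are exposed on the command line:

```sh
dioscope simulate --n-residues 30 --signaling 5,12,21 --seed 1 \
    --out-apo apo.pdb --out-holo holo.pdb --truth truth.json
dioscope extract --topology apo.pdb --dt-ns 0.005 \
    --t-start 0 --t-end 9.95 --stride 0.05 --out apo.npz
dioscope train --features apo.npz --min-width 100 --width-step 50 \
    --coding-dim 20 --learning-rate 1e-3 --max-epochs 400 --patience 50 \
    --seed 1 --out model.npz
dioscope inspect --model model.npz --features holo.npz --out holo_dio.npz
```

Real trajectories are read from multi-model PDB, GRO/PDB + XTC/TRR/DCD
(`dioscope run --config run.json` drives the full multi-combination
pipeline; ligand chains are tagged via `--ligand-chains`).  The CXCR4
helix-boundary table used for EC/TM/IC annotation ships with the package
(`dioscope.regions.default_cxcr4_table()`).

## Layout

- `dioscope.regions` — EC/TM/IC partition of a receptor chain from a
  helix-boundary table.
- `dioscope.md_features` — trajectory loading, side-chain pair distance
  matrices, RMSF/RMSD, 4 Å contact statistics.
- `dioscope.autoencoder` — pyramidal autoencoder (numpy, Adam, early
  stopping), checkpoints.
- `dioscope.dio_cluster` — DIO residuals, cosine/Ward.D2 clustering,
  tree cuts.
- `dioscope.roles_eval` — Lead/Accm extraction, stopping rule,
  aggregation, reference evaluation.
- `dioscope.baselines` — DCCM, betweenness ranking, mean/variance.
- `dioscope.synthetic_data` — OU-process fixture generator with planted
  effects.
- `dioscope.pipeline` / `dioscope.cli` — orchestration and the
  `dioscope` command.

See `docs/methods.md` for the model, parameter defaults and the design
rationale.
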