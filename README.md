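# conforma

Analysis toolkit for ligand-bound protein conformational ensembles:

- **structure_io** — multi-model PDB reading/writing, receptor/ligand/cofactor
  role assignment, and scoring atom-type assignment (`element` or
  `element_context` schemes).
- **potential** — a distance-binned knowledge-based pair potential with a
  *mean reference state*: per-type-pair probability tables over half-open
  distance bins, pseudocount-smoothed, scored as `s = −ln(P_pair/P_ref)`
  (negative = favorable, exactly 0 outside the binning range). Whole-complex
  scores decompose exactly into per-pair and per-residue contributions.
- **trajectory** — Kabsch superposition (reflections excluded), RMSD time
  series over main-chain C/O/N or Cα selections, stable-window frame
  extraction (e.g. the last 4 ns at 10 ps intervals → 400 frames), Cα
  covariance PCA, and porcupine-arrow construction for mode visualization.
- **pipeline** — per-variant orchestration: binding-pocket selection by
  distance cutoff, frame-by-frame scoring, lowest-total-score representative
  selection, reactive-pair distance with a ≥ 2.9 Å feasibility annotation,
  SRS-classified per-residue tables, geometric hydrogen-bond detection, and
  cross-variant comparison ranked by reactive-pair score.
- **synthetic** — seeded generators for every input: contact databases with
  truncated-normal distance laws, pose ensembles with a labeled near-native
  subset (labels kept in a sidecar file, never in the PDB), and trajectories
  with planted orthonormal collective modes plus isotropic noise.

## CLI

```bash
# 1. synthesize a contact database (or bring your own TSV: type_a, type_b, distance)
conforma simulate --kind contacts --spec db_spec.json --out contacts.tsv

# 2. train the potential
conforma build-potential --contacts contacts.tsv --out potential.json

# 3. score an ensemble (multi-model PDB) and pick the representative frame
conforma score --ensemble poses.pdb --potential potential.json \
    --config config.json --out report.tsv --summary summary.json

# 4. trajectory diagnostics
conforma rmsd --ensemble traj.pdb --selection mainchain_CON --out rmsd.tsv
conforma pca  --ensemble traj.pdb --out-modes modes.json --out-arrows arrows.csv

# 5. compare variants (summaries from step 3)
conforma compare wt.json mut1.json mut2.json --out comparison.tsv
```

`config.json` (all keys optional; defaults shown in `conforma.cli.DEFAULT_CONFIG`):

```json
{
  "ligand_resnames": ["LIG"],
  "cofactor_resnames": ["HEM"],
  "typing_scheme": "element",
  "pocket_cutoff": 5.0,
  "binning": {"d_min": 0.0, "d_max": 6.0, "width": 0.2},
  "pseudocount": 1.0,
  "reactive": {"probe": {"residue_name": "HEM", "atom_name": "O1"},
               "target": {"residue_name": "LIG", "atom_name": "C7"}},
  "min_allowed_reactive_distance": 2.9,
  "dt_ps": 10.0
}
```

## Notes

- All distances are Å; PDB coordinates round-trip at the fixed-width
  `%8.3f` precision (1e-3 Å).
- Every generator and pipeline stage is deterministic given its seed/config;
  reruns produce byte-identical reports.
- The statistical potential here is trained on synthetic or user-supplied
  contact data; no licensed structural-database tables ship with the package.
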