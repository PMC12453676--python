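# trajembed

Contact-graph embeddings and conformational-state classification for protein
MD trajectories.

`trajembed` turns each frame of a molecular-dynamics trajectory into a
distance-weighted Cα contact graph (edge iff d < cutoff, weight
`1 - d/cutoff`, default cutoff 10 Å), learns per-frame node embeddings —
node2vec biased random walks with a NumPy skip-gram, or GCN / GAT /
GraphSAGE encoders trained by unsupervised link prediction — flattens the
`|V| × d` matrices into a per-frame feature table, derives conformational
state labels with a superpose → PCA → 2D kernel density → threshold-region
procedure (states `A`/`B`/`I`, non-state `N`), and trains/evaluates
supervised classifiers of the per-frame state (logistic regression, random
forest, two gradient-boosting variants, MLP, 1-D CNN, SVM).

A synthetic module generates multi-state hinge ensembles with ground-truth
labels, so the entire pipeline is testable without any external dataset.

## CLI

Full pipeline from a YAML config:

```bash
trajembed run --config config.yaml --out rundir/
```

Example config:

```yaml
seed: 11
synthetic: {n_residues: 40, n_frames: 2000, noise_sigma: 0.5}
cutoff: 10.0
embedding: {method: graphsage, dimension: 16, hidden_dim: 32, gnn_epochs: 15}
labeling: {state_names: [A, B], threshold_fraction: 0.3}
models: [logistic_regression]
```

For real data replace `synthetic:` with
`input: {topology: top.pdb, trajectory: traj.xtc, selection: "protein and name CA"}`
(PDB/GRO topologies; DCD/XTC/multi-model-PDB coordinates).

Composable per-stage subcommands (each stage's text output feeds the next):

```bash
trajembed simulate      --n-residues 40 --n-frames 500 --seed 4 --out work/
trajembed build-graphs  --ensemble work/ensemble.tsv --out work/graphs.tsv
trajembed embed         --graphs work/graphs.tsv --method graphsage --out work/emb
trajembed label         --ensemble work/ensemble.tsv --out work/lab
trajembed features      --embeddings work/emb --labels work/labels.tsv --out work/features.tsv
trajembed train         --features work/features.tsv --model logistic_regression --out work/model.joblib
trajembed evaluate      --model work/model.joblib --out work/report.json
trajembed benchmark     --features work/features.tsv --models logistic_regression,random_forest --out work/bench.tsv
```

Each run directory contains a `manifest.json` recording parameters,
per-stage derived seeds, and sha256 checksums of every artifact; reruns
with the same config and seed are checksum-identical.

## Layout

| module | contents |
| --- | --- |
| `trajembed.trajectory_io` | MDAnalysis-backed trajectory reading, striding, internal delimited ensemble format |
| `trajembed.graph_builder` | distance matrices, cutoff-filtered weighted contact graphs, edge-list I/O |
| `trajembed.embeddings` | node2vec (walks + skip-gram) and GCN/GAT/GraphSAGE link-prediction encoders |
| `trajembed.labeling` | Kabsch superposition, coordinate PCA, grid KDE, region extraction, label assignment |
| `trajembed.features_ml` | feature tables, stratified splits, seven classifier families, evaluation reports, benchmarking |
| `trajembed.synthetic` | hinge-chain reference conformations and multi-state ensemble generation |
| `trajembed.cli` | config-driven orchestration and per-stage subcommands |
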