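# eqppis

Per-residue prediction of protein–protein interaction sites (PPIS) with a
dual-scale, E(3)-equivariant graph neural network.

Interface residues — the residues of one protein that physically contact a
partner — are central to understanding binding mechanisms and to drug and
antibody design, but mapping them experimentally is slow and expensive.
`eqppis` treats a protein chain as a residue graph and predicts, for every
residue, the probability that it belongs to an interface. It is a library
first (importable API plus `examples/`), with a thin `eqppis` command-line
pipeline on top.

## The model

A chain of L residues becomes an undirected graph: node *i* sits at the
residue's side-chain centroid **x**ᵢ ∈ ℝ³, and an edge joins residues whose
centroids are closer than 14 Å. Each node carries a 62-dimensional feature
vector

X = [X_PSSM, X_HMM, X_DSSP, X_AF, X_PEF]  (20 + 20 + 14 + 7 + 1 columns)

combining evolutionary profiles (PSI-BLAST PSSM, HHblits HMM), secondary
structure / solvent accessibility / backbone torsions (DSSP), averaged
atomic characteristics, and a positional scalar. Readers for the standard
PSSM / HHM / DSSP file dialects are included; running those tools is not.

Features are updated by a stack of six **equivariant graph convolutional
layers** (EGCL). For adjacent residues i, j:

- mᵢⱼ = φₑ(hᵢ, hⱼ, ‖xᵢ − xⱼ‖²)
- xᵢ ← xᵢ + C · Σⱼ (xᵢ − xⱼ) · φₓ(mᵢⱼ),  C = 1/(M−1)
- hᵢ ← φₕ(hᵢ, Σⱼ mᵢⱼ),  wrapped in a residual: hˡ⁺¹ = relu(hˡ + EGCL(hˡ))

Coordinates enter only through squared distances, so the feature stream is
invariant — and the coordinate stream equivariant — under every rotation,
reflection and translation of the input structure.

The network runs twice with **shared weights**: once on the original graph,
and once on a subgraph selected by learnable top-k pooling (scores
ỹ = σ(Xp/‖p‖), keep the top 60 %, gate kept rows by their scores, connect
them through the boolean square A² of the adjacency). The subgraph output
is scattered back to size L, the two channels are fused by an elementwise
maximum, and a three-layer head (62 → 20 → 10 → 2, softmax) emits interface
probabilities. Training minimises the unweighted cross-entropy with Adam
(lr 10⁻³, 50 epochs, reduce-on-plateau).

There is no PyTorch dependency: the network runs on a small reverse-mode
autodiff engine over NumPy arrays that ships with the package and is
verified against finite differences in the test suite.

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

trains the default model for 12 epochs on 8 synthetic chains whose
interface labels were planted by a geometric rule, and prints:

```
dataset: 8 training / 2 held-out chains, positive fraction 0.26
cross-entropy: epoch 0 5.426 -> epoch 11 0.328
held-out: ACC 0.761  Precision 1.000  Recall 0.160  F1 0.276
          MCC 0.346  AUROC 0.860  AUPRC 0.690
```

The falling cross-entropy shows the optimisation working; a held-out AUROC
of 0.86 after only 12 epochs shows the network recovering the planted
interface signal on chains it never saw (the packaged default trains for 50
epochs and scores higher — see the reproduction section below). The other
examples demonstrate graph construction from files (`01`), pooling (`02`),
the equivariance property (`03`), and the ablation switches (`05`).

The same pipeline is scriptable from a shell:

```bash
eqppis make-fixtures --out data --n-chains 20 --seed 0
eqppis train    --graphs data/train --out model.json --seed 0
eqppis predict  --ckpt model.json --graphs data/test --out pred.tsv
eqppis evaluate --pred pred.tsv --labels labels.tsv --report report.json
```

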