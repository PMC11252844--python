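# Methods

## Problem setting

Given the 3D structure of a single protein chain plus per-residue sequence
profiles, predict for each residue whether it belongs to a protein–protein
interface. Labels are binary and heavily imbalanced (interfaces are
typically 15–25 % of residues), so threshold-free metrics (AUROC, AUPRC)
and the Matthews correlation are reported alongside accuracy, precision,
recall and F1.

## Graph representation

A residue's position is the unweighted mean of its side-chain heavy atoms
(the side-chain centroid); glycine, which has none, falls back to CA — the
standard surrogate. Two residues are connected when their centroids lie
strictly below 14 Å apart (an edge at exactly 14.000 Å is *not* created);
the adjacency is binary, symmetric, with a zero diagonal.

Node features (62 columns, fixed order):

| block | width | content |
|---|---|---|
| PSSM | 20 | PSI-BLAST log-odds scores, used as read (a sigmoid rescaling flag exists but defaults to off) |
| HMM | 20 | HHblits match-emission probabilities, decoded as 2^(−s/1000) from the integer file scores |
| DSSP | 14 | one-hot secondary structure over H B E G I T S P and coil (9), relative solvent accessibility (ASA / max-ASA of Tien et al. 2013, clipped to 1), sin/cos of φ and ψ |
| AF | 7 | per-residue means over heavy atoms of: atomic mass, B-factor, side-chain flag, electron count, bonded-H count, ring flag, van der Waals radius |
| PEF | 1 | distance of the residue's centroid to the chain centroid after centring — a translation- and rotation-invariant positional scalar |

The 20/20/14/7/1 split is the only standard-width decomposition reaching
the 62-column total; the per-atom constants ship in `eqppis.elements` with
sources in its docstring. Residues are indexed 0..L−1 in file order;
non-canonical residues fall back to documented defaults (max-ASA 200 Ų,
zero H-count/ring membership).

## Network

**EGCL.** Messages mᵢⱼ = φₑ(hᵢ, hⱼ, ‖xᵢ−xⱼ‖²) are computed for *graph
neighbours only* — the contact graph is the locality structure of the
problem, and summing over all pairs would ignore it. Coordinates update as
xᵢ ← xᵢ + C Σⱼ (xᵢ−xⱼ) φₓ(mᵢⱼ) with C = 1/(M−1), M the node count of the
graph being processed (the pooled subgraph uses its own k). Features update
as hᵢ ← φₕ(hᵢ, Σⱼ mᵢⱼ). φₑ, φₓ, φₕ are two-layer perceptrons with SiLU
nonlinearities; φₓ ends in a single linear unit without bias and a narrow
(16-unit) inner layer, since it only emits one scalar gate per edge. Edges
carry no attributes by default (spatial relationships already enter through
the squared distance); the squared distance can be divided by a
configurable scale constant, default 1 (the equations taken literally).

**Initialisation.** Weights are Gaussian with std 1/√fan-in. Two output
layers are additionally damped: φₑ's by 0.1 (messages are *summed* over
neighbours, and residue graphs at a 14 Å cutoff have mean degree ≈ 14, so
unit-scale messages make a six-layer residual stack grow exponentially at
initialisation) and φₓ's by 0.001 (coordinate updates feed the next
layer's distances, so unbounded gates destabilise the geometry). Both are
pure initialisation choices — the architecture and its gradients are
untouched.

**Dual channels.** Hidden width equals the input width (62), so no input
projection is needed by default; feature-group ablations that shrink the
input insert a linear projection to 62. Pooling happens once, before the
layer stack, on the (projected) input features: scores ỹ = σ(Xp/‖p‖), the
top k = max(1, ⌈0.6·L⌉) nodes are kept (ties broken toward lower index;
indices re-sorted ascending), kept feature rows are gated by their scores —
this is what makes the selection trainable — and the subgraph adjacency is
the boolean square of the original adjacency restricted to the kept nodes,
with the diagonal zeroed. Kept *coordinates* are carried ungated: the
scores scale abstract features, but scaling physical coordinates would
corrupt the geometry the equivariant layers consume. After the shared
stack, subgraph features are scattered back into a zero L×62 matrix at the
remembered indices and fused with the original channel by elementwise
maximum. Coordinates updated inside the stack are discarded afterwards;
only the invariant feature stream reaches the head, which is why final
probabilities are exactly invariant under rigid motions.

**Head and calls.** Three linear layers 62 → 20 → 10 → 2 with ReLU between
and softmax output. Binary calls threshold the positive-class probability
at 0.5 (configurable; published PPIS thresholds are rarely stated).

## Training and evaluation

One protein graph per Adam step (lr 10⁻³, 50 epochs). The scheduler is
reduce-on-plateau on the epoch-mean training loss (factor 0.5, patience 5,
min-lr 10⁻⁶). A seeded 10 % chain-level validation split selects the
retained checkpoint; with fewer than ten chains the split may be empty, in
which case training loss is monitored. The loss is the unweighted
cross-entropy, with log-probabilities clipped at log(10⁻¹²).

Evaluation pools residues from all chains into one confusion table
(macro per-chain averaging is available via a flag), computes accuracy,
precision, recall, F1 and MCC from the counts (undefined ratios report 0),
and computes AUROC / average precision from the raw positive-class scores
via scikit-learn. A single-class label set makes the two areas undefined;
they are reported as such rather than silently defaulted.

## Synthetic data

The generator emulates the *shape* of the real problem, not its biology:

- **Geometry** — a seeded self-avoiding random walk with exact 3.8 Å steps
  (consecutive-CA spacing) and a 3.4 Å exclusion radius between
  non-consecutive residues, giving 14 Å-cutoff degree distributions in the
  low teens, comparable to folded chains.
- **Labels** — residues within 10 Å of a probe point (the position of one
  randomly chosen residue, standing in for a partner's contact point) are
  positive; optional independent label flips add noise. Across 40–80
  residue chains this yields an 18–21 % positive fraction, matching the
  imbalance of real interface benchmarks.
- **Features** — PSSM values live on the integer grid of PSI-BLAST output,
  HMM probabilities on the 2^(−s/1000) grid of HHM files, DSSP rows on the
  file's 0.1-degree / integer-ASA grid, so written fixture files re-read
  *bit-exactly*. Class signal is a mean shift (default 2.0) on a
  per-dataset random subset of 12 of the 40 PSSM+HMM columns, so no single
  block is trivially sufficient; DSSP/AF/PEF carry no planted signal.
  Atomic features are computed from generated atom records through the same
  code path used for real structures.

What passing tests on this generator do **not** show: real evolutionary
covariance in profiles, real secondary-structure geometry, bound/unbound
conformational differences, or transferability across protein families.
They show that the architecture, optimisation and evaluation machinery
recover a planted, geometrically coherent signal and that all structural
invariants hold.

## Numerical choices

- float64 throughout; equivariance holds to ~10⁻¹⁵ in practice, asserted
  at 10⁻⁵.
- Stable sigmoid (`scipy.special.expit`) and max-shifted log-softmax.
- Ties in pooling scores break toward the lower node index; `argsort` with
  a stable kind makes this reproducible.
- k = max(1, ⌈ratio·L⌉) guarantees a non-empty subgraph on tiny chains.
- Single-node graphs pass through an EGCL unchanged (no pairs exist).
- The PDB writer carries 0.001 Å precision, so structure round-trips agree
  to ~10⁻³ Å; feature-file round-trips are exact by construction.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds reproduce training histories
  bit-for-bit.

## Problem sizes

The packaged runs are desk-scale by design: the acceptance recovery run
trains on 15 chains of 30–55 residues (5 held out) for 50 epochs, the
equivariance suite uses 50 graphs of 5–50 nodes, and the pooling oracle 100
graphs of 3–40 nodes. Larger chains and datasets run unchanged, linearly in
the edge count.

## Known limitations

- The reverse-mode engine is minimal: no broadcasting beyond NumPy rules,
  no in-place ops, one backward pass per graph build.
- Single-chain graphs only; multi-chain complex assembly is out of scope.
- One pooling level (no hierarchies) and top-k selection only.
- Readers target the classic dialects of PSSM/HHM/DSSP output; exotic
  variants may need adjustment.
- The published benchmark numbers for this model family depend on external
  datasets and profile databases and are not reproducible from this
  repository; the synthetic recovery run is the supported end-to-end check.
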