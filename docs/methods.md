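# Methods

## Problem and model

Given a receptor structure and a candidate placement (pose) of a small
molecule in its binding pocket, the package predicts two quantities at
once from the complex geometry:

* **RMSD_pred** — the pose's heavy-atom root-mean-square deviation from
  the (unknown at inference time) native conformation, in Angstrom, a
  direct answer to *how* the molecule binds;
* **pKd_pred** — the binding strength (−log10 of Kd/Ki/IC50), an answer
  to *how strongly* it binds.

The two outputs are coupled through a learned, per-complex **decay
factor** `W ∈ (0, 1)`: during training the affinity target of a docking
decoy is constructed as

```
pKd_label = pKd_nat − W · RMSD_real
```

so the native pose (RMSD ≈ 0) is anchored at the measured affinity
pKd_nat and increasingly misdocked poses are discounted at a rate the
network itself infers.  `W` is produced by a sigmoid head, guaranteeing
the open interval; by default it is treated as a constant inside the
label (`detach_W_in_label = true`) so the optimizer cannot lower the
loss by manipulating its own regression target.  The flag is
configurable for studying the alternative.

### Input representation

Two graphs encode a pose (all cutoffs strict `<`, all coordinates in A):

* **Pocket graph** (residue level): nodes are residues with any heavy
  atom within 8 A of the reference ligand; edges join residue pairs with
  minimum heavy-atom distance below 10 A.  Node features: residue-type
  one-hot (20 standard + OTHER), the internal distances CA–N, CA–C,
  CA–O, CA–side-chain-centroid, N–centroid, C–centroid (zero-filled with
  a presence flag when side chain or atom is absent), and the CA
  distance to the pocket center (geometric center of all pocket-residue
  heavy atoms; the notion of "pocket center" is otherwise undefined and
  this is our fixed choice).  Edge features: the four main-chain
  distances CA–CA, N–N, C–C, O–O.  These descriptor sets are package
  defaults, chosen to capture residue identity, internal geometry and
  placement; they are config-extensible.

* **Interaction graph** (atom level, heterogeneous): protein nodes V_R
  are heavy atoms within 8 A of the reference ligand; ligand nodes V_L
  are the pose's heavy atoms.  Channels: intra-protein edges below 5 A
  (feature: distance), intra-ligand covalent bonds (bond-order one-hot,
  ring and conjugation flags, bond length), and protein–ligand cross
  edges below 8 A in both directions.  Protein node features are a
  RES-{MC|SC}-{ELEM} class one-hot (20 residues × main/side chain ×
  {C,N,O,S}, plus OTHER), an aromatic-ring flag (His/Phe/Tyr/Trp ring
  atoms), a template formal charge (Lys NZ +1, Arg NH1/NH2 +1, Asp/Glu
  carboxylate oxygens −1, flagged on each member atom of the charged
  group; protonation fixed at physiological pH, no partial charges) and
  the distance to the residue's CA.  Ligand node features: a 7-way
  element class (C, N, O, P, S, Hal = F/Cl/Br/I, DU = anything else),
  aromaticity, formal charge.

  Each cross edge between protein atom R (residue alpha carbon Cα) and
  ligand atom L (ligand geometric center P) carries the orientation
  features `[sin(φ/2), cos(θ1/2), cos(θ2/2), d(R,L)]`, where θ1 is the
  angle at R between Cα–R and L–R, θ2 the angle at L between P–L and
  R–L, and φ the signed torsion Cα–R–L–P.  The identical 4-vector sits
  on both edge directions.  The torsion uses the standard IUPAC sign
  convention (positive clockwise looking down the R→L axis); since
  sin(φ/2) is sign-sensitive the convention is fixed here and verified
  against an independent cross-product construction in the tests.

  Degenerate frames occur legitimately: the protein atom may *be* the
  CA, a single-heavy-atom ligand makes L = P, and collinear frames void
  the torsion.  Affected trigonometric entries take the fill value 0 —
  the midpoint of their ranges — while the distance stays exact.

The reference that defines V_R and the pocket is the co-crystal ligand
in `native_ref` mode (also used for decoys) and the scored pose itself
in `self_ref` mode, the variant usable when no crystal ligand exists.

Hydrogens are parsed but excluded from every graph and every RMSD;
docking engines differ in hydrogen placement, and the symmetry-corrected
RMSD convention used for labels is heavy-atom.  Receptor hetero groups
(metals, cofactors, waters) are excluded from V_R by default.

### Symmetry-corrected RMSD

Pose RMSD is computed without superposition (poses share the receptor
frame) and minimized over all graph automorphisms of the ligand
topology — the element- and bond-preserving permutations of heavy atoms
— so that, e.g., a flipped benzene ring scores 0 rather than one bond
length.  Automorphisms are found by VF2 backtracking search with strict
preservation of the (order, ring, conjugation) bond key; the search is
capped at 10,000 permutations, beyond which the identity-only fallback
is used with a warning.  Exhaustive permutation filtering serves as the
test oracle for small molecules.

### Network

Both graphs are encoded with **edge-featured multi-head graph
attention** (EGAT) layers.  Per directed edge (j→i) with edge feature
f_ij, each head computes `f′_ij = A h_j + B f_ij + C h_i`, attends with
`α_ij = softmax_i(a · LeakyReLU(f′_ij))` over the incoming edges of i,
and aggregates `h′_i = Σ_j α_ij W h_j`; heads are concatenated and f′ is
the updated edge feature.  Destination nodes with no incoming edges
receive an affine self-update — isolated nodes are routine in the
bipartite cross channels.

The pocket branch stacks two EGAT layers, applies mean readout and an
affine map to a 1024-dim pocket embedding.  One interaction round runs
four EGAT layers — intra-protein, ligand→protein, intra-ligand,
protein→ligand — and fuses each node set's two updates through
batch-normalized residual addition (`h_rec ← BN(h_intra) +
BN(Linear(h_cross))`, likewise for the ligand), followed by an ELU.  Two
rounds with separate parameters are applied (the rounds are assumed
unshared; nothing suggests weight tying), then mean readout and affine
maps give 1024-dim protein and ligand embeddings.  Mean pooling keeps
the readout permutation-invariant; sum pooling is available in config.

The 3072-dim concatenated latent is decoded by two parallel modules,
each a gMLP block followed by two linear layers, into V_RMSD and V_pkd
(128 each).  The gMLP needs a token axis: the latent is treated as 3
tokens of 1024 (pocket / protein / ligand — its natural block
structure), with the spatial gating unit's token-mixing weights
initialized near zero and its bias at one so the block starts near
identity gating.  V_RMSD is mapped by a linear layer into the pKd space
as V′_pkd; the fused vector V′_pkd + V_pkd yields
`W = σ(Linear(·))` and `pKd_pred = Linear(·)`, while
`RMSD_pred = softplus(Linear(V_RMSD))`.  The softplus/affine output
heads are our choice (non-negative RMSD, unconstrained pKd); pKd is
decoded from the fused vector, consistent with W's definition.

Interpretability: the cross-channel attention of the final round is
retained; a protein atom's importance is its head-averaged attention
summed over all its cross edges in both directions, aggregated by
protein atom class.  Importance mass equals total cross-edge attention
mass by construction.

### Loss and training

For a mini-batch of N samples:

```
L = α·mse(RMSD_real, RMSD_pred) + β·mse(pKd_label, pKd_pred) + γ·(1/N)Σ pKd_pred
```

with defaults (α, β, γ) = (1, 0.5, 0.05).  The third term presses
predicted pKd downward overall, promoting the designed negative
correlation between predicted affinity and pose RMSD; it is taken as
the signed mean of the batch.  Samples without a measured pKd_nat
contribute only the RMSD term.  Native poses carry RMSD_real = 0
exactly (not their self-RMSD).  Optimization is Adam with default
learning rate 1e-4 and batch size 32, all configurable; runs are seeded
and reproducible to identical loss curves on one device.  Batch
normalization uses batch statistics during training and running
averages in evaluation, so all determinism and invariance contracts are
stated for evaluation mode.

### Numerical engine

The network runs on a small in-package reverse-mode automatic
differentiation engine over NumPy (float64), with sparse-matrix-backed
row gather / segment-sum primitives for message passing.  Graphs are
mini-batched as disjoint unions with per-graph readout segments;
batching is exactly equivalent to single-graph evaluation (tested to
1e-5).  The attention layers are verified against a dense loop-based
reference implementation, and every elementwise/matrix gradient against
central finite differences.

## Synthetic study conditions

The fixture generator emulates the ingredients of a docking-based
training corpus at desk scale:

* **Receptors**: residues on an ideal helical curve (rise 1.5 A, 100°
  twist, CA radius 2.3 A → consecutive CA–CA ≈ 3.8 A) with backbone
  N/CA/C/O and outward-pointing template side chains drawn from
  {GLY, ALA, SER, THR, LEU, ASP, LYS, PHE} — enough diversity to
  exercise residue classes, charges and aromatic flags.
* **Ligands**: template topologies (3-atom hetero chain, branched
  5-atom, benzene ring, ring + 2-atom tail); the ring's 12-fold graph
  symmetry exercises the symmetry-corrected RMSD.  The ligand is placed
  against the helix so every heavy atom is within contact range.
* **Decoys**: a bounded random rigid motion (rotation about the ligand
  center, translation capped at 3 A so contact is never lost) plus
  center-preserving per-atom jitter, scaled by bisection until the
  symmetry-corrected RMSD from the native pose hits a target within
  0.05 A.  The default target grid {0, 0.5, 1, 2, 4, 8} A spans
  near-native to clearly misdocked.  Because decoys differ from the
  native pose geometrically, the generated data intrinsically carries a
  recoverable monotone signal from coordinates to RMSD — no separate
  "learnable mode" is needed.
* **Labels**: pKd_nat ~ U[2, 11] per complex (millimolar to ~10 pM);
  rmsd_real recorded as the achieved symmetry-corrected value.

What this generator does *not* emulate: real side-chain rotamers and
packing, physically relaxed ligand conformers, solvation, or the pose
distributions of a particular docking engine.  Green tests therefore
demonstrate that the implementation is correct and that the
architecture can extract geometric signal — not that the model attains
benchmark accuracy on real complexes, which requires a full docking
corpus and full-width training.

## Learning-sanity experiment

`scripts/acceptance.py` (and the corresponding test) fits the model on
20 synthetic complexes × 10 poses (targets 0–8 A) for 200 epochs and
reports: the final/initial training-loss ratio, the Spearman correlation
of predicted vs. true RMSD on the training poses, and the Spearman
correlation of predicted pKd vs. true RMSD (expected negative — the
coupling the label construction and the γ term are designed to induce).
A fresh 8-complex decoy set is then scored by predicted RMSD and
summarized as top-1 docking success at 2 A.  The run uses a narrow
instance of the architecture (node width 32, edge width 16, 2 heads,
full 1024/128 embedding and decoder dims) — problem sizes chosen so the
whole protocol is comfortable on a single CPU; width does not change
any architectural contract being exercised.

## Known limitations

* No pretrained weights are shipped; the package is the framework, the
  featurization and the training machinery, validated on synthetic
  conditions.
* mmCIF receptors, protonation/tautomer assignment, structure repair
  and explicit water/cofactor modeling are out of scope.
* The automorphism search treats bond typing strictly; resonance-
  equivalent terminal groups (e.g. carboxylate oxygens written with
  localized single/double bonds) are not interchanged unless the input
  encodes them equivalently (aromatic/conjugated flags usually do).
* The exact supplementary feature inventories of the original
  formulation are not public; the node/edge descriptor sets above are
  explicit, documented stand-ins and are config-extensible.
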