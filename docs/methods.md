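# Methods

## The design problem

A functional motif is given as one or more backbone segments (chain id
plus 1-based inclusive residue ranges) extracted from a source
structure, together with their native amino acids. A *contig string*
fixes the segment order and the scaffold gap lengths between and around
them; gaps may be ranges, sampled uniformly over the closed integer
interval, so repeated placements explore scaffolds of different
lengths. Design means choosing the non-motif letters of the resulting
length-L sequence so that a structure predictor is confident about the
fold and reproduces the motif's internal geometry.

## Losses

All losses are deterministic, pure functions of a prediction (and
static context), and all are minimized, so optimizer code is uniform.
Predictions carry coordinates, binned pairwise geometry (distograms
over four channels), per-residue confidence (pLDDT, 0–100) and pairwise
aligned error (PAE, Å).

- **Motif distogram cross-entropy.** Mean over ordered motif–motif
  pairs (i≠j) and channels of −log(predicted mass on the native bin +
  ε), ε = 1e-8. The ε floors the log under an adversarial one-hot
  mismatch; the probed mass is additionally clipped at 1 so the loss is
  exactly non-negative. The pair set includes only pairs with *both*
  endpoints in the motif (intra- and inter-segment): the site's
  internal geometry is the specification, scaffold context is free.
  This is toggleable.
- **Motif coordinate RMSD.** Kabsch-superposed backbone RMSD over motif
  positions, atoms N/CA/C by default (CA-only available). Defined for
  motifs of ≥ 3 residues.
- **Certainty.** Mean Shannon entropy of selected pair distributions
  (entropy mode), or negative mean KL from a background (kl_background
  mode; uniform background by default — a learned background network
  is intentionally not shipped, and the slot is pluggable). Pair
  selection: all pairs, off-diagonal, inter-chain (the inter-chain
  entropy loss used for binder design), or an explicit mask.
- **Repulsion.** For two-chain predictions, the mean distance-channel
  mass below the contact cutoff (8 Å Cβ–Cβ, the conventional contact
  definition; configurable) over cross-chain ordered pairs not in an
  allowed set. Bounded in [0, 1].
- **Radius of gyration.** max(0, Rg − rg_max)² on CA atoms; a
  compactness regularizer of the task-specific family.
- **Mean PAE.** Mean predicted aligned error over all or inter-chain
  pairs.

Channel aggregation is an unweighted mean over the four channels unless
per-channel weights are given. The composite loss is Σ weightᵢ·termᵢ
with a per-term breakdown (unweighted and weighted) reported at every
step.

## Pairwise geometry discretization

Per ordered pair: Cβ–Cβ distance, omega dihedral (CAᵢ–CBᵢ–CBⱼ–CAⱼ),
theta dihedral (Nᵢ–CAᵢ–CBᵢ–CBⱼ), planar phi (CAᵢ–CBᵢ–CBⱼ). Bins follow
the published trRosetta conventions: distance 36 × 0.5 Å over 2–20 Å
plus a no-contact state (37 states); omega/theta 24 × 15° plus
no-contact; phi 12 × 15° plus no-contact. Pairs beyond 20 Å — and the
diagonal — occupy the no-contact state in all channels; sub-2 Å
distances clip into the first bin. The whole scheme is configurable
(`BinScheme`) because feature definitions differ between predictor
generations. Cβ is always the virtual Cβ rebuilt from N/CA/C with the
standard ideal-geometry coefficients (|CB−CA| = 1.5268 Å on the fixture
backbone, frozen as a regression value), so glycine and mutated
positions are handled uniformly.

Kabsch superposition is the closed-form SVD solution; improper optima
are corrected by sign-flipping the smallest singular direction, so
rotations are proper unless reflection is explicitly allowed.
Near-collinear point sets are *flagged* degenerate rather than raised,
because sampled gap geometries can be nearly collinear; the returned
transform is still the closed-form optimum.

## The planted-landscape toy predictor

The package verifies its design machinery against a synthetic predictor
rather than a trained network. A landscape plants a hidden structure X*
(an idealized fixture backbone, or a fixture with a real motif rigidly
embedded) and sequence s*. For an input distribution P: the per-position
match m is P's mass on s*, the agreement a is m averaged over a ±w
window clipped at chain boundaries (w = 2 by default), pair confidence
is c = a·aᵀ, and the predicted distogram is the mixture
c·onehot(features(X*)) + (1−c)·uniform, with pLDDT = 100·a and
PAE = max_pae·(1−c). max_pae defaults to 30 Å, the order of magnitude
of real predictors' error cap; pLDDT is on the 0–100 scale so the usual
filter thresholds (e.g. > 80) apply unchanged.

Because the distogram entropy strictly decreases in c, certainty-type
losses are minimized (over hard sequences) exactly at s*: planted
recovery is a sharp, exactly-analyzable test of the optimizers. All
outputs are closed-form in P, so the composite loss has an analytic
gradient: each term contributes its sensitivity to the confidence
fields (c, a), and the chain rule through c = a·aᵀ, a = W·m,
m_k = P[k, s*_k] collapses to an L×20 matrix supported on the s*
column. Terms that depend only on coordinates (motif coordinate RMSD,
radius of gyration) are constant in P on the toy landscape and
contribute zero gradient; KL-to-background gradients are implemented
for the uniform background only, and other backgrounds raise an
explicit not-differentiable error. Gradients are validated elementwise
against central finite differences.

What the toy world does **not** emulate: sequence–structure coupling
beyond local identity (no epistasis between positions except through
window overlap), physical realism of coordinates (planted scaffolds
with embedded motifs are discontinuous at the seams), uncertainty that
is not monotone in sequence correctness, and any notion of
designability. Passing the planted-recovery tests therefore shows the
*optimization and loss machinery* is correct, not that designs against
a real network will fold.

## Optimizers

**Simulated annealing.** Proposals mutate one uniformly chosen
non-motif position to a uniformly chosen different letter; acceptance
is Metropolis. Motif positions hold the native motif letters and are
never proposed. The mutation alphabet excludes cysteine by default
(common de novo design practice, avoiding spurious disulfides);
fixture/planted sequences are drawn cysteine-free so recovery is
attainable under that default. Cooling is geometric over the step
budget with Tf = T0/100. The temperature scale is calibrated against
the scale of loss *changes*, not the absolute loss: composite losses
carry large state-independent offsets (the entropy of a near-uniform
distogram), and a temperature proportional to the absolute loss would
accept essentially every uphill move for the entire schedule. By
default T0 = 0.1 × the mean |Δloss| of a short seeded probe of random
single mutations from the initial state (24 proposals); explicit
schedules override this, and the realized schedule is recorded in the
trajectory's provenance. The current state's prediction is cached, so
each proposal costs one predictor call.

**Gradient descent.** The variable is an L×20 logit matrix; the
predictor sees its row-wise softmax (softmax temperature 1;
straight-through argmax is deliberately not the default). Motif rows
are clamped to one-hot native letters and receive no updates. Steepest
descent with a constant (or scheduled) learning rate; the reported
design is the per-position argmax of the best-scoring logits.

**Staged protocols** chain heterogeneous stages, initializing each from
the previous best design; a hard sequence entering a gradient stage is
lifted to one-hot logits scaled by 3.0 (softmax ≈ 0.87 on the letter —
confident but still movable). Stage k uses seed + k so stages are
decorrelated but reproducible. Provenance records every stage's
optimizer, steps and loss configuration.

All stochastic operations take explicit seeds; there is no global RNG
state. Identical seeds and configurations give bit-identical
trajectories, best-so-far loss is non-increasing by construction, and
motif letters are preserved end to end — all three are asserted
throughout the test suite.

## Inpainting benchmark

For each input protein, n_masks contiguous windows of mask_length are
drawn with starts uniform over the valid range (with replacement —
duplicates are legitimate draws); the default protocol is 20 masks of
length 30. Masked records carry only sentinels ('X' letters, NaN
coordinates), so completers cannot see native content. Scoring:
sequence recovery inside the window, Kabsch-superposed backbone RMSD of
the unmasked region, and mean completer-reported confidence inside the
window when available. The module ships the completer *contract* plus
an oracle completer (returns the native; scores must be exactly
recovery 1.0 / RMSD 0 — the harness fixed point) and a naive
poly-alanine/ideal-helix baseline; a trained inpainting network is one
possible completer but is deliberately out of scope. Channel modes
(sequence-only, structure-only, both) cover the wider task taxonomy of
missing-information-recovery problems.

## Evaluation and filters

Metrics: region-mean pLDDT; motif RMSD (shared implementation with the
coordinate loss; atom set N/CA/C by default — the printed filter sets
do not state the atom set, so CA-only is an option); inter-chain PAE
aggregated by mean over both off-diagonal blocks (median via config —
mean vs median is likewise not stated); target-aligned binder RMSD
(superpose on the target chain only, then measure the binder without
re-superposition, so rigid displacement of the binder is fully
visible). Filters are conjunctions of strict inequalities as printed
("pLDDT > 80", "motif RMSD < 1.4 Å"): boundary-equal values fail,
documented here. The two-chain binder criteria set ships without the
atom-level surface-aggregation (SAP) score, which needs full-atom SASA
machinery that is out of scope.

## Problem sizes and numerical choices

Desk-scale verification uses length-30 single-chain landscapes (motif
of 6 at the center) for recovery runs — 3000 annealing steps × 10
seeds and 500 gradient steps × 5 seeds — and length-16 landscapes for
elementwise finite-difference gradient checks (central differences,
step 1e-5, relative tolerance 1e-4 with an 1e-8 absolute floor).
Superposition is checked against numeric minimization over unit
quaternions (Nelder–Mead, multiple restarts) on 100 seeded 10-point
clouds at 1e-6 Å. Benchmark fixed-point checks use 80-residue helices
with the full 20×30 mask protocol. These sizes are the package's
verification conditions; everything scales with L² (distogram
channels) and linearly in steps.

Degenerate inputs: fixtures of n = 0 are rejected; single-residue
structures have Rg = 0; pairwise features require ≥ 2 residues;
superposition requires ≥ 3 points; motifs of < 3 residues have no
coordinate RMSD; empty pair masks, empty motifs and non-positive
temperatures raise immediately.

## Known limitations

- PDB only (no mmCIF), first model only, no altlocs, no insertion
  codes, no negative residue numbers.
- Segment order in a design follows contig token order; segment-order
  search is out of scope.
- The toy gradient covers the shipped loss terms; custom terms must
  either provide their own confidence-field sensitivity or be used with
  annealing only.
- No real-network adapters are included; the predictor contract is the
  integration point.
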