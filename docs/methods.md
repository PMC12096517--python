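# Methods

## Overview

`protoken` studies, at desk scale, a three-part pipeline for treating protein
structure as a discrete sequence modality:

1. a **vector-quantized autoencoder** that maps a backbone (N/CA/C/O per
   residue) to one discrete token per residue and folds the tokens back into
   coordinates;
2. **token-level structure comparison**: a BLOSUM-style substitution matrix
   over tokens and Needleman–Wunsch global alignment, normalized into a
   PT-score in [0, 1];
3. a **joint diffusion model** over a per-residue embedding that concatenates
   the residue's 32-dimensional structure code with an 8-dimensional amino
   acid embedding, supporting co-generation, RePaint-style conditional design
   (inverse folding, structure sampling, motif scaffolding), and
   probability-flow latent interpolation.

Everything trains and tests on a bundled synthetic backbone generator; no
structure database is downloaded.  All numerics run on CPU in float64 through
a small reverse-mode autodiff core (`protoken/_autodiff.py`).

## Tokenizer

### Encoder

The encoder consumes only rigid-motion-invariant features: per-residue
sin/cos of (phi, psi, omega) with validity flags (9 channels), and pair
features made of one-hot binned CA–CA distances (3.25–50.75 Å in 1.25 Å
steps plus an over-range bin) and clipped signed sequence separation
(|sep| ≤ 8).  A sandwich of pair-biased attention blocks (1/1/1 at desk
scale; the full-scale reference is 2/4/2) with outer-sum pair updates
produces per-residue embeddings of dimension 32.  A linear skip connection
from the raw torsion features keeps the untrained embedding distribution
spread by local geometry, so quantization is informative from the first
training step.  Tokenization is exactly SE(3)-invariant because the features
are.

### Vector quantization

Each embedding snaps to its Euclidean-nearest code of a 64-code codebook
(512 at full scale), ties to the lowest index, with straight-through
gradients and a commitment penalty (β = 0.25).  The codebook is maintained
by EMA accumulators (`counts ← 0.99·counts + batch counts`, codes =
normalized sums), dead codes unused for 50 consecutive steps are reseeded to
a random batch embedding, and — because EMA vector quantization is online
k-means and drifts toward collapsed utilization at this scale — the codebook
is globally refit every 100 steps with seeded k-means over a fresh embedding
sample.  Without the refit we measured usage perplexity ~4 of 64 codes, and
code collisions biased the decoded torsions enough to spoil even helix
reconstruction.

### Decoder

The decoder trunk mirrors the encoder (code vectors + sinusoidal positions,
pair bias from sequence separation).  The structure head is a
**mixture-of-modes torsion head**: residues form a softmax over 32 shared,
learned torsion modes plus a small zero-initialized residual; the normalized
(sin, cos) triples are integrated into a chain over ideal stereochemistry
(bond lengths/angles from standard tables, carbonyl O anti to the next N).
Local geometry is therefore ideal by construction, and recurring
secondary-structure torsions collapse onto noise-free modes.

Two alternative structure heads were implemented and rejected during
development: an AF2-style iterative frame-update head (with and without
dense per-iteration regression onto Kabsch-aligned true frames) never
learned useful global corrections at this model/compute scale and actively
degraded reconstructions, and a distance-supervised virtual-CA-trace branch
with fragment-fit assembly produced traces too coarse (~5 Å) to guide
assembly.  The chain-integration head is the design that keeps every learned
quantity local and regression-like, which is what a few hundred CPU training
steps can fit.  Its known cost is lever-arm error accumulation: small loop
torsion errors rotate everything downstream, which is the main quality limit
on multi-segment folds (see Limitations).

### Training objective and schedule

Per step, a minibatch of structures x and fresh same-basin perturbations x′
is drawn.  The total loss is

    w_fape·FAPE + w_torsion·torsion + w_viol·violation
    + w_commit·commitment + w_align·alignment + w_unif·uniformity

with defaults (1, 1, 0.1, 0.25, 0.5, 0.01).  Specifics:

* **Denoising contract.** The decoder folds the tokens of the *perturbed*
  conformation against the *clean* structure.  Tokenization is meant to
  represent the metastable basin, so intra-basin fluctuations must decode to
  the basin representative; training this way also covers the token noise
  seen at evaluation time.
* **FAPE** (clamp 10 Å, scale 10 Å) on the built chain, all four backbone
  atoms in every residue frame.
* **Torsion term**: masked squared sin/cos error of the predicted torsions
  against the clean structure's torsions.  FAPE alone is gradient-starved at
  this scale (the clamp silences long-range terms while the chain is wrong),
  whereas the torsion targets supervise the head densely; this is the
  auxiliary that makes desk-scale training converge at all.
* **Violation surrogate**: flat-bottom peptide-bond stretch plus CA-clash
  terms.  Intra-residue geometry is ideal by construction, so these are the
  only violable terms; the public `violation_loss` keeps the full
  bond/angle/clash form.
* **Alignment** (mean squared embedding difference between x and x′) with a
  deliberately substantial weight: token stability under intra-basin noise
  is this term's entire purpose.
* **Uniformity** (Wang–Isola, t = 2, L2-normalized embeddings, distinct
  pairs) discourages code collapse.
* **Two-phase schedule**: the first half of the epochs trains everything
  jointly; the second half freezes the encoder and codebook and fine-tunes
  only the decoder (inputs mix clean and perturbed tokens 1:1).  The decoder
  is a regression model whose targets otherwise keep moving with every
  EMA/k-means update; freezing makes the token→fold map stationary so it can
  converge.
* Adam (lr 3e-3) with global gradient-norm clipping at 1.0 (unclipped runs
  showed late-training blow-ups), fully seeded; identical seeds give
  identical traces.

Desk-scale study conditions: 200 synthetic structures of 60–80 residues
(helix / strand / helix-bundle / mixed in equal parts), 64 codes, 16 epochs
of 100 steps at batch 4 (~13 CPU-minutes), held-out evaluation on freshly
perturbed copies of every training fold.  The held-out quality distribution
is strongly bimodal (single-segment folds reconstruct far better than
multi-loop topologies), so the reported median is taken over the full
population rather than a subsample, which would make it hostage to draw
composition.

## PT-score

Substitution counts are collected from structure pairs with TM-score
strictly above 0.8, at residues with LDDT strictly above 80 (0–100 scale),
both orders recorded, diagonal counted once.  Scores are half-bit Henikoff
log-odds: normalize the (pseudocounted, default 1) symmetric count table Q,
take marginals f, and round 2·log2(Q/(f fᵀ)); the unordered-pair factors of
two cancel between numerator and denominator.  Alignment is Gotoh
three-state global DP with affine gaps (defaults −11/−1), deterministic
tie-breaking (substitution, then gap-in-b, then gap-in-a), verified
exhaustively against brute-force alignment enumeration.  The PT-score is
`raw(a,b) / max(self(a), self(b))` clipped at 0 — symmetric, 1 for identical
sequences.

## Metrics

TM-score uses position-wise residue pairing (reconstruction preserves
indexing), d0 = 1.24·(L−15)^⅓ − 1.8 floored at 0.5 Å, and a deterministic
fragment-seeded Kabsch heuristic (window lengths {4, L/2, L}, stride 1, up
to 3 refinement rounds keeping residues within max(d0, 4.5) Å).  Chains of
≤ 8 residues enumerate every window of length ≥ 3 without refinement, which
makes the tiny-case behaviour coincide with an exhaustive-superposition
oracle.  LDDT is CA-only, inclusion radius 15 Å, thresholds
{0.5, 1, 2, 4} Å, sequence separation ≥ 2, superposition-free.  rTM/rLDDT
are these metrics applied to a reconstruction against its original.

## Diffusion model

The joint embedding is 32 structure channels (codebook vectors) + 8 sequence
channels.  The amino-acid table is a fixed stand-in built by PCA of the
BLOSUM62 substitution profile to 8 dimensions (deterministic sign
convention, unit mean row norm, provenance-tagged); rows are pairwise
distinct, and sequences decode by nearest row with alphabetical
tie-breaking.

The DDPM uses a linear β schedule; endpoints follow the 1000-step convention
(1e-4 → 0.02) rescaled by 1000/T so the continuous-time process is
independent of the step count (the unscaled endpoints at T = 100 leave
ᾱ_T ≈ 0.37, which visibly biases sampling).  The noise predictor is a
diffusion transformer (desk scale: 2 layers, hidden 64; full-scale reference
24×512) with adaptive layer-norm time conditioning and a zero-initialized
output head, so the untrained loss equals the channel dimension exactly.
Channels are standardized with corpus statistics stored in the checkpoint;
the sampling state is the normalized embedding.  Variable lengths are padded
under a residue mask; generation length is an explicit input.

Ancestral sampling is the standard reverse chain with posterior variance
β̃_t and a noise-free final step.  The probability-flow ODE
dz/dt = −½β(t)(z − ε/√(1−ᾱ)) is integrated with fixed-step RK4 on
t ∈ [1e-3, 1] (default 100 steps); encode/decode are mutual inverses to
solver tolerance, and latent interpolation mixes encoded endpoints linearly
before decoding.  All sampling operations take a plain ``eps_fn(z, t)``
callable so closed-form Gaussian denoisers can stand in for trained models
in verification.

RePaint follows the published time-travel schedule (jump length 10,
resampling 5 by default): at every reverse step the context entries are
replaced by forward-noised context at the matching level, with forward
re-diffusion between resampling passes, and the context is written through
exactly at t = 0.  An empty mask delegates to ancestral sampling (exact
reduction); a full mask returns the context with a warning.  RePaint's
harmonization bias shrinks with finer schedules and more resampling; the
statistical verification against the analytic 2-D Gaussian conditional runs
at T = 400, jump 20, resampling 10, where mean and variance agree within a
few percent.

Inverse folding, structure sampling and motif scaffolding are the same
operation under different masks (structure channels fixed, sequence channels
fixed, or a token+letter motif fixed at given positions).

## Synthetic data

Backbones are built from internal coordinates with ideal stereochemistry:
helix (−57°, −47°), strand (−119°, 113°), loop torsions drawn from broad
uniform ranges; bundle and mixed topologies assemble secondary-structure
segments with random loop linkers under clash rejection (retry cap 100, then
reseed).  Perturbations emulate intra-basin fluctuations: small torsion
jitter (amplitude scaled with σ, capped at 5°, 10% of torsions), per-atom
Gaussian noise of σ Å, then five bond-projection sweeps; σ = 0 is the
identity, and σ = 0.3 keeps TM-score > 0.8 on 60-residue folds.
Conformational pairs hinge-rotate the C-terminal half about a random axis
through the middle CA.  Corpora cycle fold classes and, when planted
coupling is on, draw sequences enriched (frequency ratio 3 by default) in a
4-letter class-H set (AELK) for helical folds and class-S (VIFY) for
strands, which gives conditional-generation tests a falsifiable signal.

What the generator does **not** emulate: real Ramachandran statistics,
side-chain packing, hydrogen bonding, fold-space diversity, or realistic
fluctuation spectra.  Its perturbation model produces much noisier local
dihedrals (tens of degrees) than real intra-basin dynamics, which makes
token stability *harder* than on real data in that one respect, while the
small fold vocabulary makes reconstruction easier.  Passing tests show the
machinery is implemented correctly and trainable, not that the full-scale
published performance transfers.

## Numerical choices and degenerate inputs

Collinear N/CA/C triples raise a degenerate-geometry error naming the
residue.  Chain breaks (consecutive CA–CA > 4.5 Å) invalidate the spanning
dihedrals instead of raising.  Decoded structures are expressed in a
canonical frame (CA centroid at origin, principal axes ordered by variance,
signs fixed by third moments, det +1), so repeated decodes are bit-identical.
Quantization ties break to the lowest code index; sequence-decoding ties to
the alphabetically first letter.  All randomness flows from explicit integer
seeds through `numpy.random.default_rng`.

## Known limitations

* Reconstruction quality on multi-segment folds is bounded by loop-torsion
  quantization noise amplified through chain integration: held-out quality
  is bimodal, with single-segment folds (helix, strand) reconstructing far
  better than bundle/mixed topologies.  The population median clears the
  0.7 reconstruction target, but multi-loop folds individually do not.
* The learned structure head contains no global-placement mechanism
  (iterative frame refinement did not train at this scale), so errors grow
  with the number of loops.
* PT-score gap penalties, rounding and normalization are package defaults,
  not calibrated values; downstream Spearman trends depend on them.
* The toy tokenizer absorbs hinge motions into one token basin: conformational
  pairs of the same chain map to nearly identical token sequences, so
  token-level similarity (PT-score) and decoded-pair distances carry almost
  no information about the hinge angle.  Conformational discrimination with
  simultaneous intra-basin invariance requires the full-scale codebook and
  training corpus and is not reproduced here.
* The diffusion model is far below the scale needed for high-fidelity
  unconditional design; conditional tests rely on the planted
  sequence–structure coupling of the synthetic corpus.
* scTM-style validation through an external folding model is out of scope;
  any callable sequence→structure predictor can be plugged in where needed.
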