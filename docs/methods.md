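# Methods

## Problem and model

`dihedralkd` predicts whether a T-cell receptor, represented by its CDR3β
loop, binds a given peptide. Instead of encoding the two amino-acid
sequences (one-hot, BLOSUM), each partner is represented by the backbone
dihedral angles of its predicted 3-D structure: for an l-residue chain,
the (φ, ψ) angles of the l−2 interior residues (terminal residues rotate
freely and carry no conformational information). The two (l−2)×2 matrices
are top-aligned, zero-padded to `pad_rows` rows (default 17, the longest
supported chain being 19 residues), placed side by side — columns
(φ_CDR3β, ψ_CDR3β, φ_pep, ψ_pep) — and scaled by 1/180 so entries lie in
(−1, 1].

A knowledge-distillation pair of CNNs consumes the 17×4×1 input:

* **teacher** — three blocks of [conv 3×3, stride (2,2), SAME padding →
  LeakyReLU(α=0.2) → max-pool 2×2, stride 1, SAME] with 64/128/256
  filters, then flatten → dense(32) → dense(1, sigmoid); ≈394k parameters.
* **student** — identical topology with 16/32/64 filters; ≈29k parameters.

Training is two-phase: the teacher is fitted to the hard labels with
binary cross-entropy (Adam, lr 1e-3, batch 128); the teacher is then
frozen and the student minimises

    L = α·BCE(y, q) + (1−α)·T²·KL(p̃ ‖ q̃),

where p̃, q̃ are the teacher/student output Bernoullis softened by
temperature T on the logit scale. Defaults α = 0.5, T = 2 (Hinton-style);
both configurable. At T = 1 the soft term is the plain Bernoulli KL, and
α = 1 reduces exactly to BCE — identities the tests assert. Probabilities
are clipped at 1e-7 before any logarithm. The gradient of the soft term
at the student logit is (1−α)·T·(q̃−p̃), which the trainer uses directly.

The networks, backpropagation and Adam are implemented in numpy: the
model is small enough that a fully deterministic numpy implementation is
fast on one CPU core and exactly reproducible; gradients are verified
against central-difference numerical differentiation in the test suite.
Layer conventions (SAME padding arithmetic for strided convolutions and
stride-1 pooling) follow the mainstream deep-learning frameworks, which
is also the only padding scheme under which a 17×4 input survives three
stride-2 convolutions.

## Torsion math and backbone reconstruction

`torsion` is the standard signed dihedral
atan2(((b1×b2)×(b2×b3))·b̂2, (b1×b2)·(b2×b3)) in degrees, IUPAC sign
convention (cis 0°, trans +180°), range (−180, 180] with −180 mapped to
+180 so every angle has one representation. φ(i) uses atoms
C(i−1)–N(i)–Cα(i)–C(i); ψ(i) uses N(i)–Cα(i)–C(i)–N(i+1). Both angles of
both terminal residues are excluded, giving exactly (l−2)×2 per chain.

`build_backbone` inverts the extraction: atoms are placed sequentially by
natural extension of the reference frame (NeRF) from ideal geometry
(N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å; angles C–N–Cα 121.7°,
N–Cα–C 111.2°, Cα–C–N 116.2°; ω fixed trans). The unused terminal
torsions are pinned to extended-strand values. The in-memory round trip
build → extract is exact to <1e-12°; through a PDB file it is limited to
~0.1° by the format's three-decimal coordinates (a 5e-4 Å quantisation on
~1.4 Å bonds), which is why the on-disk fixture round trip is asserted at
0.15° while the in-memory one is asserted at 1e-6°.

## Data handling

Pair tables are CSV (`cdr3b,peptide,label[,source_tag]`). Non-binding
pairs are sampled uniformly without replacement from the Cartesian
product of a CDR3β pool and a wildtype-peptide list, minus an exclusion
set (known binders), under a fixed seed — the standard construction when
negatives are not experimentally observed. A test record is **seen** iff
its peptide string occurs anywhere in training (CDR3β identity plays no
role) and **unseen** otherwise; unseen-stratum AUC is the generalization
measure. AUC is the Mann–Whitney rank statistic with ties counted 1/2,
computed from average ranks; the evaluator also reports per-stratum AUCs
and the mean ± sd over k random disjoint test subsets (default 10).

## Similarity audit

To ask *why* the model generalizes, test items are flattened to
2·pad_rows dihedral vectors (zero-padded), clustered by k-means
(k-means++, k = 9, fixed seed), and each cluster is represented by its
member nearest the centroid. Training pairs are binned by cosine
similarity of their corresponding entity's vector to the representative
(default: 5 equal-width bins spanning the observed range), and each bin
is scored by RMSE between the cluster's predicted probabilities and the
bin's empirical binding rate — the length-compatible reading of
comparing a cluster's labels with a differently-sized bin's labels. If
predictions are driven by structure, RMSE falls as similarity rises.
Because bin-level RMSEs carry sampling noise of a few hundredths, the
falling trend is scored per representative as a strictly negative
Spearman rank correlation between bin order and RMSE
(`AuditResult.decreasing_trend_count`); strict pairwise monotonicity is
also available (`monotone_nonincreasing_count`) but fails on middle-bin
noise even when the qualitative pattern is unambiguous.

## Synthetic data

The generator emulates the real inputs (structure predictions plus
curated pair labels) with a planted structural rule:

* `n_motifs` (default 8) binder archetypes, each a matched (peptide
  profile, CDR3β profile) pair drawn uniformly on the angle torus;
  archetype chain lengths are drawn once per motif (CDR3β 10–18, peptide
  8–11 residues, matching observed CDR3β/epitope length ranges).
* **paired rule (default):** a pair binds iff its peptide profile derives
  from an archetype *and* its CDR3β profile from that archetype's
  partner; profiles carry wrapped-Gaussian angular noise (default sd 20°,
  roughly the within-cluster spread of loop conformations). Non-binders
  are 75% hard negatives (a motif profile on one side: motif peptide ×
  background receptor, background peptide × motif receptor, or mismatched
  motif pair) and 25% pure background — so single-column shortcuts do not
  separate the classes and the model must read all four columns.
* **receptor_only rule:** every CDR3β derives from an archetype and the
  label is a fixed property of the archetype alone. Labels are then a
  deterministic function of the CDR3β dihedral vector — the premise of
  the similarity audit, which is demonstrated on this rule.
* Peptides form a reusable pool (default n_pairs/25, ≥24 — few unique
  peptides pairing with many receptors, as in the curated databases); a
  configurable fraction (default 0.3) is reserved for the test split,
  giving a genuine unseen stratum. Sequences are random unique strings:
  the model never reads letters, but the seen/unseen bookkeeping operates
  on strings exactly as with real data.
* Structures are realised by `build_backbone`, so fixture bundles
  round-trip through the same PDB path as external structure predictions.

With zero noise the classes are perfectly separable (a nearest-archetype
classifier reaches AUC 1.0); rising noise degrades attainable AUC. What
the generator does **not** emulate: realistic sequence statistics,
Ramachandran-plausible angle distributions, structure-prediction error
modes, or any sequence–structure consistency. Passing tests therefore
demonstrate that the pipeline recovers a planted structural signal under
the stated noise, not that the method attains any particular accuracy on
real TCR data.

## Problem sizes and defaults

Simulation studies use 2000 pairs (1400 train / 600 test), noise sd 20°,
and 20 epochs per training phase — the loss plateaus well before that on
this signal strength. Signal recovery is reported as the minimum
unseen-stratum AUC over 5 seeds; the permutation control (training labels
shuffled, evaluated against true test labels) is reported as the mean
over the same 5 seeds, which isolates the systematic component of a
statistic whose single-run spread is wide because the planted data
contain only a handful of independent structure "cells".

## Degenerate inputs and numerical choices

Chains shorter than 3 residues, incomplete backbones, and C–N gaps
≥2.5 Å are rejected at read time with positional messages. Collinear atom
triplets make the torsion undefined and raise. Single-class training sets
raise (`degenerate training set`); single-class evaluation strata are
reported with counts and a null AUC rather than raising. Zero vectors in
cosine similarity score 0 with a warning. Duplicate pair records collapse
with binding evidence overriding an assumed negative. All randomness
(initialisation, shuffling, sampling) flows from explicit integer seeds
through `numpy.random.default_rng`; identical seeds give bitwise-identical
training histories.

## Known limitations

* Structure prediction is outside the package: real use requires an
  external tool (e.g. OmegaFold) to produce per-sequence PDB backbones;
  the documented contract is one single-model chain per file at
  `structures/<sequence>.pdb`.
* The 17-row input caps chains at 19 residues; longer CDR3β loops need a
  larger `pad_rows` and a retrained model.
* Zero-padding is indistinguishable from a genuine 0° angle by design
  (fidelity to the published input contract); no mask channel is added.
* The numpy trainer is single-core and desk-scale; it is not intended
  for millions of pairs.
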