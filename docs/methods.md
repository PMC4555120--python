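# Methods

This note documents the models, estimators and numerical choices behind
`vkorcp`, and what the synthetic study does and does not establish.

## Substitution model and likelihood

Sequences evolve under a reversible amino-acid replacement process
Q_ij = S_ij·π_j (i ≠ j), where S is a published symmetric exchangeability
matrix (WAG or JTT, embedded as constants) and π its equilibrium
frequencies. Q is scaled so the expected substitution rate at equilibrium
is 1; branch lengths are therefore expected substitutions per site. P(t) =
exp(Qt) is computed through the eigendecomposition of the symmetrized
matrix diag(√π)·Q·diag(1/√π), cached per model; negative entries produced
by floating-point round-off are clipped and rows renormalized, and t = 0
returns the exact identity so that impossible configurations yield a
log-likelihood of −∞ rather than a denormal number.

Across-site rate heterogeneity uses the discrete-gamma approximation:
n equal-probability categories represented by their conditional means
(computed with the shape-α+1 CDF identity), normalized to mean exactly 1.
Tree likelihoods default to 4 categories (the field's convention);
conservation scoring uses 16 for finer posterior resolution. An optional
proportion p_inv of invariant sites adds the mixture term
p·I_c + (1−p)·(1/K)·Σ_k L_c(r_k), where I_c is π_s if every non-missing
residue in column c equals s (the sum of π over compatible states for
all-missing columns) and 0 otherwise.

Column likelihoods L_c(r) come from Felsenstein pruning with per-node
rescaling (max-normalization with accumulated log scale factors), so
alignments of hundreds of taxa do not underflow. Gaps and 'X' are missing
data: their partial-likelihood vector is all ones, and they never count as
identity, conservation or marker evidence anywhere in the package.
Correctness is checked against an independent oracle that enumerates the
full joint state tensor over internal nodes on trees of up to 5 leaves
(agreement to 1e-10 relative), and against the pulley principle
(likelihood invariance under rerooting, 1e-10).

## Tree estimation

Pairwise distances maximize the two-sequence likelihood
Σ_ij n_ij·log(p·π_i δ_ij + (1−p)·π_i·[Σ_k w_k P(t r_k)]_ij) over
t ∈ [1e-9, 10] by bounded Brent search (xatol 1e-8); identical sequences
return 0 exactly. Topologies come from Saitou–Nei neighbor joining with
negative branch estimates clamped to zero and ties broken by the
lexicographically smallest leaf label under each cluster, making the
output order-independent and reproducible.

Branch lengths are then re-optimized coordinate-wise on the full
likelihood: for each edge the inside (subtree) and outside (rest-of-tree,
frequencies absorbed at the root) partials are assembled so the edge's
log-likelihood is a cheap one-dimensional function, optimized by bounded
Brent on [0, 10]; a proposal is accepted only if it improves on the current
value, so the total log-likelihood is non-decreasing. Passes repeat until
the improvement falls below 1e-6 or 20 passes. With a bifurcating root
only the sum of the two root-adjacent lengths is identifiable (pulley
principle); recovery tests therefore compare on the derooted tree.

Gamma shape and invariant proportion are estimated by nested bounded
scalar optimization (α ∈ [0.05, 20], p_inv ∈ [0, 0.95]); the inner p_inv
problem reuses the per-category site likelihoods, so the nesting costs one
extra 1-D search. Model ranking fits each candidate (branch lengths
alternated with rate parameters) and reports AIC, AICc and BIC with
k counting only the rate-heterogeneity parameters — branch lengths are
shared by all candidates on the fixed topology, so they cancel from the
comparison; users comparing across topologies should add them.

Bootstrap supports resample alignment columns with replacement and rebuild
the tree per replicate with the ML-distance + NJ pipeline (not a full ML
search: at the alignment sizes this package targets, distance+NJ per
replicate is the point where support on strong signal saturates and cost
stays near-interactive). The support of each internal bipartition of the
point tree is the percentage of replicates containing it, stored as the
internal node label.

## Conservation scoring

The per-column evolutionary rate is the empirical-Bayes posterior mean
r̂_c = Σ_k r_k L_c(r_k) / Σ_k L_c(r_k) under the equal-weight
discrete-gamma prior (16 categories; shape estimated from the same
alignment). r̂ is necessarily a convex combination of the category rates.
Rates are standardized (zero mean, unit variance over scored columns) and
binned into nine *equal-width* intervals over the observed score range:
lowest bin → grade 9 (most conserved), highest → grade 1; columns absent
from the scored subset (all-gap) get grade 0, and an all-equal profile
degenerates to grade 5 everywhere. Equal-width binning is a documented
choice — conservation servers do not publish their exact boundaries, so
reproducibility bit-for-bit was preferred over imitating any one server;
absolute grade agreement with server output is not claimed, planted-truth
recovery is. Columns under 10% occupancy are scored but flagged
low-confidence. Clade profiles restrict rows and prune the tree (branch
lengths retained) and refuse fewer than 3 members, where rate inference is
not meaningful.

## Clade and marker scans

Clades grow from seed taxa: each label starts at the MRCA of its seeds and
expands to the largest enclosing subtree containing no other label's
seeds, so one exemplar per clade suffices when clades are separated;
any overlap between labels is an error (non-monophyly). Single-site
markers demand, by default, a perfect determinant — some state present in
every scored group row and absent from every scored complement row — with
both thresholds relaxable; frequencies ignore missing states in numerator
and denominator. Clade-absent segments are maximal column runs gapped
throughout one clade and occupied in ≥ 50% of another, at least 2 columns
long. The indel census counts maximal gap runs with *identical* column
spans shared by ≥ 2 rows (exact-span clustering is the only reproducible
reading of "discrete shared indels"), excluding single-column gaps and
runs contiguous with a row's termini, which may reflect incomplete reads.

## Modules and circular permutation

Helix-pair modules follow the helix *labels*: AB runs from helix A's first
residue to helix B's last (connecting loop included), likewise CD. Under
the CDAB threading of VKOR-like sequences the CD module is N-terminal and
the redox-active CXXC motif falls in the AB module of both families, which
is what makes the CXXC-anchored AB alignment well-defined. Module
alignments are translation-only (no internal gaps): the AB offset aligns
the first CXXC matches; the CD offset maximizes the identity-site count
over all translations with ≥ 10 overlapping columns, ties broken toward
the smallest |offset| (negative before positive). Identity counts across
three index sequences default to the union-of-pairwise reading (the shared
single-family residue matches at least one partner index); per-pair and
strict triple counts are always reported alongside. Conserved-feature
matching intersects feature positions (contacts, in reference numbering)
with a minimum conservation grade (default 6) in both families.

The general rotation detector aligns sequence B locally (BLOSUM62, gap
open 11 / extend 1 — standard protein local-alignment costs, configurable)
against the doubled sequence A+A; the permutation point is the alignment
start modulo |A|, with an ungapped per-offset score profile returned for
diagnostics. Exact rotations are recovered for every offset; at 15% random
substitution the planted offset is still found in ≥ 90% of seeded trials.

## Structural contacts

A contact is a residue pair on different annotated helices whose minimum
heavy-atom distance is ≤ 4.5 Å (the common van-der-Waals contact
convention; the criterion behind published contact counts is typically
unstated, so the cutoff is exposed as a parameter and exact reproduction
of any particular count is not claimed). Ligand contacts analogously take
protein residues within the cutoff of any heavy ligand atom. Hydrogens are
excluded; author residue numbering is used throughout; output is sorted
and independent of atom record order, and invariant under rigid motions by
construction (only distances enter).

## Synthetic study design

The generator emulates the study conditions at desk scale: 60 taxa in five
labelled clades (sizes 20/8/6/10/16 — two large prokaryote-like clades,
two small vertebrate-paralog-like clades, one mid-sized invertebrate-like
clade, all ≥ 5 so every clade profile is scoreable), pure-birth subtrees
joined by 0.6-substitution stems, and 160 core columns evolved under WAG
with gamma rates (α = 0.7, a typical protein-family estimate). Five
planted zero-rate columns carry the catalytic analog C, C, S, C-x-x-C
(positions 40/48/54/120/123); a perfect marker (Cys vs Ile) is planted at
column 126 for a six-member group scattered over the first and last
clades; a 13-column block present only in the three "animal" clades is
inserted after column 80; the CP partner family rotates each core sequence
at residue 107 (the D/A junction) and mutates at 0.10 expected
substitutions per site; the toy bundle places four ideal α-helices
(1.5 Å rise, 100°/residue, Cα plus one side-chain pseudo-atom) on a 9.5 Å
square, with exact brute-force contact enumeration stored as truth.
Insertions are planted as blocks rather than evolved under an indel
process, and markers overwrite evolved states — the downstream analyses
are censuses and scans, not indel-process inference, so planted signals
are exact by construction. Sub-generators draw from independent streams
spawned from one seed, so adding a feature never perturbs another, and a
self-audit verifies every planted feature against the emitted data before
anything is written.

What passing tests show: the estimators recover planted truth under the
generating model (correct likelihoods, consistent distances, topology from
additive matrices, rate/shape recovery, perfect marker/insertion/contact
recovery). What they do not show: robustness to alignment error,
compositional bias, heterotachy, or realistic indel processes — none of
which the generator emulates. Real-data grades near sequence-set edges and
low-occupancy columns should be treated with the low-confidence flag in
mind.

## Known limitations

* No topology search beyond NJ (no NNI/SPR); the likelihood machinery is
  exact for a given topology but the topology itself is a distance-based
  estimate.
* AICc uses column count as the sample size, a convention, not a theorem.
* The two real-sequence checks (index-sequence lengths; AB/CD identity
  counts 5 and 4) need the accession sequences fetched into
  `data/index_sequences.fasta` plus a helix-range annotation; they fail
  with a diagnostic when the data are absent rather than running on
  substitutes.
* Module alignment is translation-only by design; families with internal
  indels between the anchoring motifs need a gapped aligner upstream.
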