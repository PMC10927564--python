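# Methods

This note documents the models, parameters, numerical choices and
limitations of the assembly engine, in the order the pipeline runs.

## Inputs and representation

A *subunit* is the rigid unit of assembly: a full chain or a contiguous
domain of one, defined by name, sequence, per-copy chain identifiers and the
author number of its first residue.  Up to 128 subunit copies per complex
are supported.  Predicted models arrive as PDB/mmCIF structures paired with
a scores JSON carrying a per-residue plDDT vector (0–100) and a square PAE
matrix (Å, 0–30; minor dialect overshoot up to 31 is tolerated; both the
`pae` and `predicted_aligned_error` key spellings are read).  Chains are
matched to subunits by exact sequence identity, ties resolved by config
order; models with residue gaps are rejected rather than silently patched —
gap tolerance is a documented extension point.  Author numbering exists only
at file boundaries; internally every residue index is a 0-based offset
within its subunit.

The *representative* of a subunit is the copy with maximal mean plDDT over
all models (ties: lexicographic model id, then copy index).  Alternative
selection criteria (mean PAE, maximal plDDT, interaction scores) are not
implemented; the mean-plDDT rule is simple and the choice is not
performance-critical for the engine itself.

## Pairwise transformations

For each pair of placements in a model with any Cα–Cα distance strictly
below 8 Å, the representative of each subunit is superposed onto its
modelled copy by least-squares (Kabsch) fitting.  Only confidently modelled
residues steer the fit: those with representative plDDT > 80, or, when
fewer than half qualify, the ⌈L/2⌉ residues of highest plDDT (the rounding
is a choice; fits need at least 3 residues).  With T₁ (representative A′ →
modelled A) and T₂ (B′ → B), the library entry mapping B′ into A′'s frame
is T₁⁻¹ ∘ T₂ — map B′ into the model's frame, then carry it back through
A's fit.  Entries are canonicalized to alphabetical subunit order; for
homomeric pairs both orientations are kept because the two copies play
asymmetric roles under the composition.  Near-duplicates (transformed
representative within 1 Å Cα RMSD) merge, keeping the best score — the
1 Å threshold deliberately reuses the clustering tolerance.

The score of a transformation is `max{1, 100 − P²/4}` with P the mean PAE
over *all* residue pairs of both inter-subunit blocks (not only interface
residues); the averaging block is isolated in `compute_mean_pae` so an
interface-restricted variant is a one-function change.

Job planning for larger prediction subsets (3–5 subunits per job, at most
three per subunit) greedily adds the highest-scoring partners under an
1,800-residue total sequence budget, the size that fits common GPU memory
for pair predictors; oversized subunits are flagged and skipped.

## Combinatorial assembly

With N total copies the engine runs iterations i = 2…N.  Iteration i
merges every disjoint pair of kept subcomplexes of sizes k and i−k
(1 ≤ k ≤ i/2) through every library transformation applicable to an anchor
pair, moving the second subcomplex rigidly into the first's frame.  A
candidate's raw score is the sum of the (possibly rewarded) transformation
scores over its assembly tree: summation makes the score additive over
merges and consistent with the amino-acid-weighted confidence used for
final ranking.  The symmetry reward S + S(100−S)/100 applies when the
merged subcomplex holds more than five copies of one subunit and all merges
joining those copies used one repeated library transformation (checked by
transformation identity on the tree).

Filters:

* **Steric clashes** — computed between confident backbone atoms only
  (plDDT > 80; N, Cα, C, O with van-der-Waals radii 1.55, 1.70, 1.70,
  1.52 Å).  Two atoms clash when their centre distance is below
  r_i + r_j − 1 Å, i.e. the spheres interpenetrate by more than 1 Å.  A
  candidate dies when, against some single other subunit, more than 5% of a
  subunit's confident backbone atoms clash.  Checks are incremental (only
  cross-pairs of the two merged sides; within-side pairs passed earlier)
  with a bounding-sphere prescreen; a brute-force all-pairs oracle verifies
  the fast path in the tests.
* **Chain connectivity** — subunits that are segments of one chain (same
  chain identifier, ordered by start residue) must keep the Cα of the first
  segment's C-terminus within (n_linker + 1) × 3 Å of the Cα of the next
  segment's N-terminus, where n_linker counts the residues between the
  segments.  The “+1” covers the peptide bond itself when the linker is
  empty.
* **Restraints** — see below.

Survivors are greedily leader-clustered in descending score order at 1 Å
correspondence-resolved Cα RMSD, and the K best leaders *per subunit
composition* (default K = 100) survive the iteration.  Keeping K per
composition rather than per iteration prevents heteromeric compositions
from starving each other; it is the configurable default.  If no full-size
assembly survives, the largest partial assemblies are returned.  Results
are ranked by predicted confidence.  All tie-breaks (score, composition,
tree serialization) are lexicographic, so identical inputs give identical
outputs.

Two performance properties are worth stating precisely.  First, because
clustering processes candidates in descending score order and keeps at most
K leaders, filtering can stop as soon as K leaders exist — any later
candidate is either absorbed into a cluster or truncated.  A candidate's
score is known from its tree alone, so candidate geometry is materialized
lazily in score order; with restraints present the modulated score requires
geometry, and all surviving candidates are materialized and re-ranked.
Second, a search guard caps the number of candidates materialized per
composition and iteration (default 5,000, configurable, affecting only the
lowest-scoring tail); it bounds run time when assembly is impossible (e.g.
stoichiometries beyond geometric capacity, where every candidate clashes).

## Distance restraints

Crosslinks arrive as residue pairs with a Cα–Cα upper bound and an optional
experimental weight w₁ ∈ (0,1] (default 1).  Binding attaches
w₂ = mean(representative plDDT of the two endpoints)/100 — any fixed
monotone scaling works; plDDT/100 keeps w₂ in (0,1].  A restraint applies
to a subcomplex when both endpoint subunits are present and is satisfied
when *any* present copy pair realises the bound (strict `<`, matching the
interaction-cutoff convention).  The satisfaction ratio
Σ_sat w₁w₂ / Σ_all w₁w₂ multiplies the subcomplex score, and candidates
whose violated weight fraction exceeds 10% are discarded.  The violation
fraction is weight-based for consistency with the ratio; a count-based
reading would differ only under heterogeneous weights.  Known subcomplexes
can be given as groups: group members must assemble to completion before
any cross-group merge is attempted.

## Copy correspondence

Comparing two structures with p identical copies requires the label
correspondence minimising RMSD; p! enumeration is intractable.  The
resolver works on three anchor points per copy (N-terminal Cα, centroid,
C-terminal Cα).  Bare centroids are provably insufficient: for a symmetric
ring, a proper 3-D rotation realises a label *reflection* with zero
centroid RMSD but large atom RMSD, so anchor triples are used to make such
flips cost nonzero.  Candidate correspondences are seeded three ways — the
declared order; an assignment matching copies by their sorted distances to
all other centroids (a rigid-motion-invariant signature); and one seed per
possible partner of a reference copy, superposing that copy pair directly
and assigning the rest by the Hungarian algorithm — then refined by
ICP-style alternation of superposition and re-assignment, and finally by
pairwise-swap hill climbing (swap two identical copies, re-superpose, keep
improvements).  With fewer than three copies the at most two
correspondences are enumerated directly.  The tests hold the resolver to
the factorial optimum exactly for p ≤ 3 and within 0.5 Å for p = 4,
including an adversarial near-symmetric ring; the swap stage alone, without
the seeding, stalls in local minima on a noticeable fraction of random
relabelings.

## Evaluation metrics

`tm_score` computes the standard length-normalised score with
d0 = 1.24·(L−15)^⅓ − 1.8 (clamped at 0.5) from the reference length, and
searches the superposition by seeding from the full alignment and from
sliding fragments (L/2, L/4), each refined by iterative re-superposition on
residues within the inclusion cutoff.  `edge_quality` is a DockQ-style
composite — native-contact fraction (backbone atoms within 5 Å),
1/(1+(iRMSD/1.5)²) and 1/(1+(LRMSD/8.5)²), averaged — comparing a
transform-induced dimer against a true relative placement; it is pluggable
so a reference implementation can substitute.  `pairwise_connectivity`
builds a graph over subunit copies with edges where some library transform
reaches quality > 0.23 against the true contact, and reports the amino-acid
fraction of the largest connected component; nodes are copies (not unique
subunits), the natural reading when stoichiometry > 1.

## Synthetic study conditions

The fixtures emulate only what the engine consumes: rigid subunits with
backbone atoms, confidence values and pairwise errors.  Subunits are ideal
α-helices (100°/residue, 1.5 Å rise, radius set so consecutive Cα spacing
is 3.8 Å) with seeded sub-milliÅngström jitter and seeded random sequences.
Complexes are rings (copy i is copy i−1 rotated by 360°/copies about a
common axis, at the smallest radius giving non-clashing contact), chains,
or random trees.  Contact placement targets a minimum inter-subunit Cα–Cα
distance of 5 Å *and* a minimum backbone-atom separation of 3 Å — the
second condition guarantees ground truths pass the 1 Å-penetration clash
filter; non-neighbours stay beyond the 8 Å interaction cutoff.  Fabricated
pair models carry the true pair geometry plus optional Gaussian noise
(``coord_noise_sd`` is the RMS 3-D displacement per atom, i.e. per-axis
σ/√3) in an arbitrary global frame; inter-subunit PAE is ``pae_true``
(default 2 → score 99).  Decoys place the second subunit at a uniformly
random orientation (quaternion-sampled) in surface contact, with
``pae_decoy`` (default 30 → score 1): they pass geometric sanity and are
distinguishable only through the PAE-derived score, or through restraints
when the PAE ordering is deliberately inverted.  plDDT defaults to 90, with
an optional low-confidence terminal tail to exercise the alignment and
clash masks.  All outputs are byte-identical for a fixed spec and seed.

Simulated crosslinks sample residue pairs below a cutoff from the true
coordinates, round-robin across interfaces so coverage is spread over the
complex rather than concentrated on the residue-richest contact.  The
rescue scenario uses a 8 Å Cα–Cα cutoff: the toy subunits are an order of
magnitude smaller than real domains, so the informative scale is
interface-proximal rather than the 25–30 Å of a physical crosslinker.

What passing these conditions does *not* show: tolerance to the
conformational variability, disorder, gaps and side-chain packing of real
predictions; robustness of the mean-PAE score to real PAE noise; behaviour
at hundreds of copies.  The fixtures certify the algorithmics — transform
algebra, search, filters, scoring — not predictor realism.

## Problem sizes and defaults

The shipped study conditions use 10-copy rings and 4–6-subunit heteromers
of 15–22-residue subunits with beam width 8–20 — sizes at which the
exhaustive oracle is computable and a full test run completes in well under
a minute per scenario; the engine itself is size-generic up to the
128-copy cap.  The stoichiometry scan varies one subunit's copy number
against a fixed library (both worked examples in the field are
single-variable); grid scans over several subunits are an extension point.

## Known limitations

* One representative per subunit: conformational heterogeneity between
  copies is invisible to the engine (a known accuracy ceiling when domains
  reorient between interfaces).
* The correspondence resolver is a heuristic; beyond the tested p ≤ 4 it
  may return a suboptimal matching on highly symmetric arrangements, which
  splits clusters (costing diversity, never correctness of kept leaders).
* A crosslink set that a decoy orientation happens to satisfy cannot rescue
  the assembly — on random toy layouts with loose (≥10 Å) cutoffs this
  occurs in a few percent of cases, which is a property of the data, not of
  the filter.
* Restraint evaluation is exact but O(copies²) per restraint; complexes
  with very high copy numbers and dense crosslink maps would need indexing.
* No post-assembly relaxation: interfaces inherit representative-structure
  side effects; clash tolerance (1 Å, 5%) absorbs small overlaps instead.
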