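# Methods

## Scope and design

`foldcensus` measures the statistical footprint of generated protein
sequences: validity, structural assignability, fold-space coverage,
homology escape, and coarse biophysics.  The expensive components of a
real census — transformer inference, structure prediction,
structure/sequence database search — are *interfaces* here, not
implementations: token models attach through a conditional-probability
contract, and structure/homology search results enter as tabular hit
files.  Everything downstream of those seams (decoding, filtering,
consensus voting, escape statistics, surface-area computation,
reporting) is computed in full.

## Decoding engines

**Autoregressive sampling.**  A sequence grows token by token, left to
right.  At each step the model's conditional distribution is
transformed in this order:

1. repetition penalty on log-probabilities (CTRL-style: for a token
   already emitted, a positive logit is divided by the penalty and a
   negative logit multiplied by it),
2. temperature (softmax of logits/T),
3. top-k (keep the k highest-probability tokens, renormalize; ties at
   the pool boundary break by token index),
4. nucleus/top-p (keep the smallest descending prefix reaching
   cumulative mass p; p = 1 is the identity),
5. renormalization.

The order and the penalty formula follow the convention of the widely
used generation stacks; at the neutral settings (T = 1, k = |V|,
p = 1, penalty = 1) the chain is the identity to 1e-9, which the tests
assert.  Generation stops at the first STOP token or at the
`max_tokens` cap (default 40 tokens); the concatenated residue string
is then truncated to `max_residues` (default 100).  A multi-residue
subword token is kept whole during generation and the *residue* string
cut afterwards, so truncation never splits a sampling step.  Default
knobs: T = 1, top_k = 950, top_p = 1.0, repetition penalty = 1.2.

**Left-to-right Gibbs sampling** (masked models).  A fixed template of
`max_residues` positions starts fully masked and is filled one
position at a time, left to right; each draw conditions on the filled
left context with the right context still masked.  A single pass is
made — positions are not revisited, matching the "single-token
increments" reading of the procedure.  STOP is sampleable at any
position and cuts the sequence before it.  Defaults: T = 1, no
penalty, full token distribution, 100 positions.

**Background sampler.**  Position-independent draws of fixed-length
sequences over the 20 proteinogenic amino acids at SwissProt-style
abundances.  By construction no STOP, truncation, or forbidden letters
occur.

**Randomness.**  One seed per run; sequence *i* draws from a
`SeedSequence(seed, spawn_key=(i,))` substream, so batches are
bit-reproducible and embarrassingly parallel without changing results.
Per-context transformed distributions are memoized (valid because the
model contract is deterministic and the penalty history is a function
of the context), which makes 100,000-sequence runs on toy models take
seconds.

**Enumeration oracle.**  For small vocabularies the exact output
distribution is obtained by exhaustive path enumeration under the same
transform chain (budget: |V|^max_len ≤ 1e6 paths).  The stochastic
engines are validated against it in total variation: 0.02 at 100,000
samples, comfortably above the expected sampling noise (~0.005 for the
3-token model) but tight enough to catch any transform or termination
discrepancy.  One caveat on a related closed form: softmax([5, 0, −5]/T)
deviates from uniform by ~5/(3T), so the "high temperature ≈ uniform"
check is asserted at 2e-3 for T = 1000 and 1e-3 for T = 10,000.

## Filters

Order: truncate → validity → deduplicate.  Truncation precedes the
validity screen, so a forbidden letter beyond the length cap does not
invalidate a sequence (the cap is part of generation; the screen of
record applies to what is kept).  Validity rejects empty sequences and
any of B, J, O, U, X, Z.  Deduplication is exact string match, first
occurrence kept.  The composition rule (no single residue above 20%)
and the resolution/minimum-length rules belong to the
experimental-validation screen and use a *strict* inequality at the
20% boundary: a 100-mer with exactly 20 alanines passes, 21 fails.
The pipeline is idempotent and stage counts are conserved, both
asserted as properties.

## Consensus fold annotation

A hit survives when TM-score > 0.5 *and* max(query coverage, target
coverage) > 0.8 — both inequalities strict.  Surviving hits vote, one
vote per hit row, for the fold of their target domain; the plurality
fold wins.  Counting per hit row (rather than per unique target) is
the default because a structure matching many domains of one fold is
stronger evidence for that fold; a flag switches to unique-target
counting.  Plurality ties break by the highest TM-score within the
tied folds, then lexicographic fold id, and the annotation is flagged
`tie_broken` so downstream analyses can discount it.  Queries with no
hit rows are annotated none — search tools omit them from output, so
the query universe is always supplied independently.

The reciprocal filter used for building a joint sequence–structure
fragment database is deliberately a *different* configuration: it
requires TM-score > 0.5 and **both** coverages > 0.8, in **both**
search directions, because fragment pairing demands mutual coverage
whereas consensus annotation tolerates a domain-sized match inside a
longer query.

Fold enrichment between two batches uses add-one pseudocounts over the
shared fold universe (K folds):
`log2((g_f + 1)/(G + K)) − log2((n_f + 1)/(N + K))`, antisymmetric
under swapping the batches.  The reference fold universe is 1579
labels; topology classes are the fold-id prefix letters (a = all-α,
b = all-β, c = α/β, d = α+β).

## Sequence escape

A query escapes when it has no homology hit with E ≤ 0.01.  The
boundary is inclusive ("maximum E-value 0.01"); a strict-mode flag
exists and the choice is logged.  Queries absent from the hit file are
escapes.  Escape among *assignable* sequences is the reporting default
for scan tables (the denominator that matches the summary statistic at
the default grid cell); escape among all valid sequences is available
behind a flag.  Per-fold escape restricts the universe to the queries
assigned each fold; the assigned-count-weighted mean of per-fold rates
equals the overall assignable rate, asserted as an identity.

## Surface area, burial, coil

SASA uses the Shrake–Rupley method: each atom's probe-expanded sphere
(probe 1.4 Å) carries a deterministic golden-spiral lattice of 960
test points; a point is accessible when outside every other expanded
sphere, and the atom's area is 4π(r+p)² times its accessible fraction.
Before point placement, coordinates are expressed in the molecule's
principal-axes frame with axis signs fixed by the third moment of the
projections.  This orthogonal transform preserves all interatomic
distances and makes the result invariant under rigid motions to
floating precision rather than merely to lattice discretization
(~0.1%); it is asserted at 1e-6 relative.  Doubling the point count
changes totals by < 1% on random 50-atom fixtures, and the
implementation agrees with biotite's independent Shrake–Rupley within
2% — the library is used only as a cross-check, never as the
implementation.

Van der Waals radii are the Bondi element-wise set (C 1.70, N 1.55,
O 1.52, S 1.80 Å; 1.70 Å fallback); hydrogens are ignored.  Burial
fraction is `1 − SASA / Σᵢ ref_area(aaᵢ)` with the reference taken as
each residue's *isolated, maximally exposed* area — the Tien et al.
(2013) theoretical maximum ASA table, shipped with provenance and
substitutable.  The isolated-residue reading of "relative to the
linear polypeptide chain" matches the per-residue reference areas the
statistic is defined against; an extended-chain SASA reference would
differ by the (constant) neighbor occlusion.  Burial is ≤ 1 by
construction; negative values (structure more exposed than the
reference) are reported with a warning, never clamped.

Coil fraction is the complement of {H, G, I, E, B} over a DSSP code
string — helices and strands count as structured, everything else
(turn, bend, polyproline, unassigned) as coil.  DSSP dialects disagree
on "coil", so the structured code set is configurable with this
default.

## Synthetic data: what it emulates, what it does not

Planted batches realize their specification as *exact counts*
(round-half-up once, then deterministic assignment): an
assignable query receives two above-threshold hits voting its planted
fold plus one sub-threshold decoy; unassignable queries receive
sub-threshold rows or none; escaped queries receive no qualifying
homology hit (half get a decoy at E = 0.5) and non-escaped ones a hit
at E = 1e-5.  Counts-based statistics recovered by the pipeline
therefore equal the planted truth to the last digit, which is what the
acceptance checks exercise; only the decoding-engine distribution
tests are stochastic.  Sequences are background-model draws with an
'X' planted into designated invalid records.

These generators emulate the *statistical structure* the pipeline
thresholds — they make no attempt to produce realistic structures,
alignment score distributions, or homology statistics.  Passing tests
demonstrate that the pipeline's arithmetic, thresholds, vote and tie
logic are correct, not that any particular language model behaves one
way or another on real data.

Toy coordinate sets: an "isolated residue" with atoms placed far apart
(a synthetic geometry whose SASA is an exact sphere sum, not a
physical conformer), an ideal α-helix Cα trace (1.5 Å rise, 100° per
residue, 2.3 Å radius), an extended chain beyond contact distance, and
a compact jittered cubic cluster.  Burial must rise strictly from
extended to compact, asserted with the SASA oracle on both
arrangements.

## Scan summaries and problem sizes

A scan row carries the hyperparameters and four statistics: valid
fraction, distinct folds detected, structural hit rate, and escape
rate (assignable denominator).  Grid order is top_k major, temperature
minor; printed values are rounded half-up to 3 decimals with full
precision retained internally, and every printed fraction equals its
numerator/denominator recomputed from the per-sequence tables.

Problem sizes: the acceptance script plants batches at the full census
sizes (100,000 / 148,500 / 74,250 sequences) because counts-based
recovery is cheap; the analysis drivers use one-tenth scale batches
and 2,000-sequence grid cells, which keep the written tables small
while exercising identical code paths; the sampler-distribution checks
use 100,000 draws on ≤ 6-token vocabularies where exact enumeration is
available.

## Known limitations

* No transformer inference, structural alignment, E-value computation,
  or secondary-structure assignment — all are consumed through
  interfaces, by design.
* The Gibbs engine makes a single left-to-right pass; arbitrary-order
  or multi-sweep schedules are out of scope.
* SASA treats all atoms as spheres of element-wise radius; no
  residue-specific or united-atom radii.
* The fold-vote default counts hit rows; against a redundant target
  database this weights folds by their domain multiplicity (the
  unique-target flag exists for that case).
* mmCIF input is not supported; PDB-format ATOM records only.
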