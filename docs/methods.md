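# Methods

## Background model

The generator treats a genome as three sequence classes: functionally
constrained regions (genes, pseudogenes, CpG islands, conserved
elements), repeat-derived but unconstrained regions, and a unique,
unconstrained "base" fraction. Training masks the first class and the
annotated repeats (sentinel `N`), and models the base fraction with two
coupled empirical components:

* **k-mer continuation tables.** For each GC bin, the probability of
  each next base given the previous k bases, tabulated from all
  sentinel-free (k+1)-mers whose first base lies in a usable window of
  that bin. A (k+1)-mer may extend past its window's end; the context
  chain is not broken at window seams. No pseudocounts are added — the
  tables are faithful empirical frequencies, and unseen contexts are
  handled at generation time by back-off (drop the leftmost context
  base until a context observed in the bin is found, then the bin's
  mononucleotide distribution, then the pooled-genome distribution).
* **GC-bin transition chain.** Local GC is computed in non-overlapping
  windows (default 1 kb, `N` excluded from numerator and denominator)
  and each window is binned by the mean GC of its enclosing section
  (default 10 kb) — the two-level scheme smooths window-level noise
  while keeping k-mer statistics local. Default boundaries 0.37 / 0.39
  / 0.42 / 0.45 divide the human genome into five strata of roughly
  equal span; they are parameters, not constants. Transitions are
  counted between adjacent usable windows; pairs straddling an
  unusable window or a sequence break are not counted. A window is
  unusable when more than 50% of it is sentinel (configurable).

Defaults k = 4 and window 1 kb follow the observation that results are
insensitive across k ∈ {4..12} and windows 0.2–5 kb. Generation seeds
the first bin from the empirical occupancy distribution and the first
context from the bin's context-occurrence distribution; requested
lengths that are not window multiples truncate the final window.

## Repeat models and artificial evolution

Each annotated repeat instance contributes one joint tuple (length,
divergence %, insertion %, deletion %, fragment count, GC bin) to its
family model. Sampling is a bootstrap draw of whole tuples — never from
fitted marginals — so the covariance between age, truncation and GC
placement is preserved. Fragments sharing a RepeatMasker linkage id
form one element; elements with ≥ 2 fragments define the family's
fragmentation probability, and annotations lying in inter-fragment gaps
define the host→guest nesting distribution. Family abundance is a
per-GC-bin base-fraction weight, mixed at planning time by the bin
occupancy of the planned sequence (the normalization across bins is a
design choice; per-Mb density would be an alternative).

An instance is evolved from its consensus in a fixed order:

1. **trim** to the sampled length — LINEs keep their 3′ end
   (5′-truncation mimics incomplete target-primed reverse
   transcription), other classes a uniformly random window;
2. **delete** round(del% · L/100) uniformly chosen positions;
3. **substitute** round(div% · L/100) positions, split
   transitions:transversions at ti:tv = 2.0 (configurable; the standard
   mammalian genome-wide estimate — no CpG-aware or class-specific
   rates are modeled);
4. **insert** round(ins% · L/100) single bases, drawn from the current
   GC bin's k-mer continuation distribution at the insertion context
   (uniform without a model).

Event counts are deterministic in the percentages (round half-up);
randomness enters only through positions and identities, so realized
divergence tracks the sampled tuple tightly — acceptance tests confirm
alignment-measured identity of (100−d)% ± 2% at d up to 30%. Every
event is logged with its position at application time; replaying the
log on the consensus reproduces the evolved sequence exactly. With the
family's fragmentation probability the evolved element is broken at a
uniform point and a strictly younger (lower-divergence) guest from the
nesting distribution is recursively evolved and inserted (depth
capped at 3). Simple repeats expand their monomer to the sampled
length (last copy truncated) and pass through the same mutation
stages.

## Assembly

To realize a requested repetitive fraction f of a final length L, the
base sequence is generated at L·(1−f) and instances are sampled until
planned repeat bases reach f·L; insertion is splice-in (the sequence
grows), which preserves base-sequence statistics between repeats.
The plan is sorted by divergence descending so old elements are in
place before young ones land. Each insert takes a uniform position
within a window of the current, partially assembled sequence whose GC
bin matches the instance's sampled bin (nearest bin as fallback) and a
random strand (minus inserts the reverse complement). An insertion
falling strictly inside an existing record splits it into linked
fragments of the same element — exactly how RepeatMasker annotates
interrupted elements — keeping every annotation byte-exact against the
final sequence; an insertion at a record boundary is adjacent, not
nesting, so no zero-length fragment can arise. Realized fraction is
reported as interval-union coverage. A single seeded RNG threads
through every stochastic step; the seed and a config hash are written
to the provenance file, and identically seeded runs are byte-identical
across all outputs.

## Validation metrics

Composition: gc, gcs and cpg = n_CG/(n_G·n_C) as classically printed.
The cpg form has no length normalization and therefore shrinks with N;
a length-normalized variant (N·n_CG/(n_G·n_C)) is exposed under an
explicit flag and never substituted silently. Complexity: cwf (via
log-gamma), ce, word entropy cm at m ∈ {6, 8, 12} with denominator
N−m−1 — as classically printed, although N−m+1 m-words exist, so the
word "probabilities" sum to slightly more than one and a homopolymer
scores marginally below zero rather than exactly zero; the convention
is kept and documented rather than corrected. Linguistic complexity cl
uses the vocabulary ceiling V_max(i) = min(4^i, N−i+1). Compressibility
cz uses zlib at pinned level 6 (values are only comparable at a fixed
level). `N` bases are excluded from all counts; sequences over 10%
ambiguous are flagged.

Descriptor matrices are z-scored per column. PCA is the standard
full-SVD projection. PAM is k-medoids with the deterministic BUILD
initialization followed by greedy SWAP (ties broken by lowest index),
implemented in-package; the silhouette is reported on its standard
[−1, 1] definition, with negative values reported as-is.

## Dinucleotide shuffle

The baseline decoy method preserves the exact dinucleotide multiset
(and first/last base) per window by sampling a uniformly random
Eulerian path on the dinucleotide multigraph: a random last-edge
arborescence toward the terminal vertex is drawn by rejection, the
remaining out-edges are permuted, and the walk is read off. With a
window (default use: 1 kb) each window is permuted independently.

## Synthetic fixture

The toy genome emulates the training inputs at desk scale: GC blocks
alternating between 0.35 and 0.55 G+C (default 25 kb blocks, so both
transition directions between GC strata are observed), masked "gene"
blocks, planted repeat copies of a two-family toy consensus library at
5/10/20% divergence, one fragmented LINE with a younger SINE nested in
the gap, and (AT)n/(CAG)n tandem arrays with TRF-style records.
Annotated divergence is re-measured by global alignment of each planted
copy against its consensus slice, not copied from the request. The
fixture does not emulate real isochore length distributions, CpG
islands, satellites, or long-range correlations — so passing tests
show the machinery is self-consistent and statistically calibrated on
its own model class, not that generated decoys are indistinguishable
from any particular real genome.

## Problem sizes and tolerances

The statistical acceptance checks run at: 500 kb training genome with
10 kb GC blocks and k = 2 for Markov recovery (k = 2 keeps every
context well-observed in 1 Mb of generated sequence, so conditional
probabilities are estimable to the ±0.02 check without confounding
sampling noise with model error; entries with under 200 observations
are not estimable and are excluded); 50,000 sampled windows for
stationary-occupancy recovery against a power-iteration oracle; 100
replicates per divergence level on a 1 kb consensus with a
Needleman–Wunsch oracle (match 1, mismatch 0, affine gaps); 20
replicate 100 kb generations per target fraction; 1,000 random
sequences of 50–5,000 bp for metric-oracle agreement at 1e-9 relative
tolerance; 10,000 draws for the shuffle-uniformity check ("ACGTACGT"
admits a single valid arrangement — every vertex has one successor
type — so the richer "ACGTCAGT", with three arrangements, backs the
chi-square). All are seeded and deterministic.

## Known limitations

Satellite/telomeric repeats and families with consensus-name
discordance are out of scope. Substitution is uniform within
ti/tv classes (no rate heterogeneity, no CpG hypermutability). Whole
repeats enter only through the fragmentation path, not through the
insertion stage. The GC bin of an insertion site is read from the
current partially assembled sequence. CLI config files supply
defaults; explicit flags override them.
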