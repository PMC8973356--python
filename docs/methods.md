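# Methods

## Scope and data model

The package analyses saturation-mutagenesis pools of a Y RNA: all 4^k
variants obtained by substituting a fully randomized k-nt window into a
reference transcript.  Coordinates are 1-based and inclusive everywhere; a
cleavage site is named by its *cut-after* position i (scission between i and
i+1).  Variant motifs are ordered lexicographically with A<C<G<U, and a
motif's base-4 value (A=0..U=3) equals its index in the library, which makes
enumeration/ordinal mapping a bijection that is tested exhaustively for
small k.

## The synthetic reference

The packaged reference is a designed 81-nt Y RNA-like sequence, not a
natural one.  It was constructed so that the geometric relations the
analyses depend on hold exactly:

* stem S3 occupies 52–57 paired with 61–66 (6 bp, all G:C);
* the internal loop L2a is the 9-nt unpaired run 43–51 directly upstream;
* a cut 2 nt above the stem (after position 49) leaves a 32-nt 3′ fragment,
  and a cut 3 nt above (after 48) a 33-nt fragment;
* positions 22–26 read `UGGGU`, inside the loop that also holds the
  conserved `UAU`-starting stretch at 27–29;
* position 8 (C) pairs with 68 (G) beside an unpaired cytidine bulge at 9 —
  the RO60 binding-site geometry.  The anchor orientation (C at 8, G at 68)
  was chosen because the experimentally selected base in the randomized
  window covering position 68 is G;
* six 5-nt windows are packaged: L1 (52, stem S3 strand), L2 (76, the
  single-stranded 3′ tail), L3 (64, spans the RO60 anchor partner),
  L4 (22, the `UGGGU` motif), L5 (27), L6 (17).

Its curated wild-type dot-bracket (`WT_DOTBRACKET`) is a hand-built
structure satisfying these constraints; it is *not* the output of the
packaged folder, and nothing downstream assumes it is.  Real references are
supplied as FASTA plus a landmark mapping; real structures as Vienna-style
dot-bracket text.

## Folding and structure features

`fold()` is a weighted Nussinov base-pair maximization — GC = 3, AU = 2,
GU = 1, minimum hairpin loop 3 — chosen over a thermodynamic model because
it is self-contained and exhaustively testable: the optimum is checked
against brute-force enumeration over all nested structures for sequences up
to length 14.  The traceback is deterministic (prefer "i unpaired" on ties,
then the smallest partner j), so golden outputs are stable.  Pseudoknots
and bracket alphabets beyond `(.)` are rejected.

Element decomposition treats a stem as a maximal helix with zero interior
unpaired nucleotides (a 1-bp helix counts); unpaired runs are classified as
hairpin, bulge (one span), internal (two spans), multibranch, or exterior,
and the decomposition is checked by a partition property (stem strands +
loop spans + exterior = sequence length).  Stem S3 is *located*, not named:
it is the stem whose 5′ strand starts closest downstream of the 3′ cut
region.  "Above the stem" means 5′ of that strand, so the cut offset is
stem_start − 1 − cut_after.  Imposed structures (one dot-bracket applied to
every variant of a pool) may contain non-canonical pairs for most variant
sequences; validation is therefore optional (`check_pairs=False`) for that
use, while folded and imported structures are validated strictly.

Structure similarity is base-pair distance (symmetric difference of pair
sets) — the standard dot-bracket comparison metric.

## Simulator

The simulator is the package's stand-in for the transfected-pool sequencing
experiments, and its defaults encode the studied conditions:

| parameter | default | rationale |
| --- | --- | --- |
| offsets above stem S3 | {2: 0.6, 3: 0.4} | both cut positions are observed; the 2-nt offset (32-nt fragment) is modal.  Exact proportions are unreported, so the modal class is given the larger share |
| minimum upstream loop | 1 nt | a bulge of at least 1 nt is sufficient for 3′ cleavage |
| minimum stem length | 5 bp | the conserved stem comprises 5–6 nt |
| RO60 site required | yes | intact RO60 binding is required for cleavage |
| 5′ motif | `UGGGU` at 22, exact | position-22 substitutions abolish 5′ cleavage |
| 5′ cut | after position 32 | the 5′ cleavage site lies between 32 and 33 |
| per-read fragment probabilities | 0.4 (3′), 0.3 (5′), scaled by `efficiency` | free parameters; per-variant efficiency differences are not quantified experimentally |
| substitution error rate | 0.1 % per base | typical Illumina scale |
| decoy fraction | 5 % | stands in for genome-derived background reads; decoys use the same read layout and must be rejected at assignment |
| abundance | uniform (Dirichlet and explicit dropout available) | pools are built to be near-uniform |

Reads follow the HD library layout — 4 random nt + insert + 4 random nt +
3′ adapter (`TGGAATTC...`) — written as 4-line FASTQ in DNA alphabet with
constant quality (quality is never consumed).  3′ fragments always extend
to the transcript 3′ end and 5′ fragments always start at position 1, so
cut positions are recoverable purely from read boundaries.  A provenance
sidecar (variant, fragment type, true cut per read) exists for testing only.

Three structure models feed the simulator and the inference side
identically: a single imposed dot-bracket per pool (windows that do not
perturb structure), per-variant Nussinov folds, and *local repair* — the
reference structure with exactly those pairs removed that a variant's
sequence can no longer form canonically.  Local repair is the default model
for stem-overlapping pools: wobble-compatible substitutions keep the pair,
which decouples sequence distance from structure distance and is what lets
the structure-vs-sequence contrast discriminate.  Knockout-like conditions
are modelled only as rule toggles (`efficiency=0`, `require_ro60=False`),
never mechanistically.

What the simulator does **not** emulate: indels, quality-dependent or
position-dependent errors, PCR duplicates, ligation bias, partial
degradation fragments (every read is full-length or a clean 3′/5′
fragment), or genome co-mapping ambiguity.  Passing tests therefore show
that the pipeline recovers rules from boundary-exact, substitution-noised
reads — not that it is robust to all artefacts of real libraries.

## Trimming and assignment

Trimming mirrors the exact-match recipe for HD libraries: reject reads
containing N; find the leftmost exact occurrence of the first 8 adapter nt
(`UGGAAUUC` after DNA→RNA conversion); drop it and everything after; strip
4 HD nt from each end; reject remainders shorter than 15 + 8 nt.  The
minimum insert of 15 nt is a package choice, safely below the ~22-nt
smallest fragment of interest.  The 5′ HD bases are removed positionally
after the adapter search; with exact matching the order does not affect
results.

Assignment is exact-match only, by boundary anchoring against the reference
with the randomized window treated as free positions: full-length (read =
transcript), 5′ fragment (prefix), 3′ fragment (suffix), tried in that
order (a read matching both ends is classified 5′ and flagged).  A read
covering the window determines its variant uniquely; matches not covering
the window are tallied *pool-level* rather than fractionally distributed —
fractional assignment would fabricate per-variant signal.  Reads matching
at neither boundary, or not at all (decoys, reads with errors outside the
window), are unassigned and reported.  One consequence of exact matching: a
substitution error *inside* the window reassigns the read to the wrong
variant rather than discarding it; at the default error rate this is a
≤0.5 % effect, but it is why the missing-variant detector at
`min_count=1` assumes an error-free library for exact recovery.

Counts reconcile exactly (assigned + pool-level + unassigned = accepted)
and every 3′ entry satisfies cut_after + length = reference length; both
are asserted in code.

## Enrichment and coverage

Rankings are descending by count with ties broken by ordinal (determinism).
"Missing" means full-length count below 1 — the threshold is a parameter
because the original analyses report sets, not cutoffs.  Logos use a 0.5
pseudocount per base; letter heights are IC × frequency.  The coverage
statistic interprets the harvest question as *per-variant* presence with
probability 0.99 — the joint all-variants interpretation needs ≈9,400+
draws and contradicts the published 5,000-colony figure, so the per-variant
reading (minimum 4,714 ≤ 5,000) is the one implemented.

## Rule inference

Per-variant yield is fragment/(fragment + full-length) reads — undefined at
denominator zero — mirroring how fragment accumulation is compared against
full-length signal on blots.  Offset recovery pools cut offsets over all
variants with fragments and a locatable stem; modes break ties toward the
smaller value.  The loop response takes a deletion series (loop sizes 0–9,
built by `loop_deletion_mutant`, which removes unpaired loop nucleotides
and re-anchors the landmarks) and reports the smallest loop size with
positive yield.  Motif localization contrasts per-position information
content between competent and incompetent variant sets; competence is yield
above 10 % of the wild-type variant's yield (a package choice; the
qualitative experimental description gives no number), and the call start
is the first position whose IC difference exceeds half the maximum.  The
structure-vs-sequence contrast uses Spearman rank correlation (the claim is
ordinal and yields are bounded and non-normal) of yield against negated
base-pair distance to wild type versus negated window Hamming distance.

## Numerical and degenerate-input choices

Tie-breaks are uniformly deterministic (smaller position, smaller offset,
smaller ordinal, smallest partner in traceback).  All randomness flows
through one seeded `numpy` generator.  Degenerate inputs are flagged, not
silently imputed: empty fragment classes raise a no-cleavage signal,
all-zero rankings and constant-yield correlation inputs set a `degenerate`
flag (correlations reported as 0), and an all-zero loop series returns no
permissive size.  `min_pool_size` nudges the closed form by ±1 draw against
the exact inequality to absorb floating-point edge effects.

## Problem sizes

Simulated depths used in tests and the acceptance script — 10,000 reads for
cleavage pools, 20,000 for full-length libraries, 800 per loop-series
member — were chosen as the smallest sizes at which the recovered
quantities (modal offset, modal size class, detection of all 1,024
variants, minimal permissive loop) are stable across seeds; the detection
result additionally has an analytic floor (per-variant missing probability
(1023/1024)^20000 ≈ 3×10⁻⁹ under uniform abundance).

## Known limitations

* The folder is a base-pair-maximizer, not a thermodynamic model; folds of
  long sequences differ from RNAfold-style predictions (on the packaged
  reference it pairs away loop L2a, for example).  Supply real structures
  as dot-bracket files when fidelity matters.
* Exact matching cannot separate a window-mutated read from a sequencing
  error inside the window.
* The published coordinates for the natural transcript are internally
  inconsistent across report sections (cut between 49/50 vs 50/51 vs 31-nt
  fragments); the synthetic reference reproduces the 32/33-nt read-size
  geometry and makes no claim about which coordinate is authoritative for
  the natural RNA.
* No gapped or mismatch-tolerant alignment, no genome mapping, no
  multi-reference pools, no UMI handling, no paired-end support.
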