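# Methods

`transtore` models digital data storage in enzymatically synthesized DNA
where information lives in *transitions* between non-identical nucleotides
rather than in single bases. A template-independent polymerase (TdT),
kinetically limited by apyrase, appends a short homopolymeric run of one
nucleotide per synthesis cycle; because adjacent cycles use different
nucleotides, run-length compression of a sequenced strand recovers the
sequence of transitions. Each transition has three possible successors and
therefore carries one trit (log2 3 ≈ 1.585 bits). This note documents the
models, parameter choices, and numerical decisions behind the package.

## Codec

A codec profile is the triple (K, B, Ω) plus layout:

- **K** — template length in nucleotides, split into information positions
  and synchronization ("sync") positions;
- **B** — ECC-encoded bits per template;
- **Ω** — information bits (address ‖ data) per template, Ω ≤ B.

The encode path per template is `address‖data (Ω bits) → BCH encode
(B bits) → big-endian base-3 conversion (n_info trits) → transition
modulation with sync insertion (K nt)`. Decoding inverts each stage.

**Sync layout.** One sync nucleotide follows every complete group of
`sync_period = 3` information nucleotides, so `n_info + floor(n_info / 3) =
K`. This single rule reproduces every demonstrated template geometry:
16 = 12 + 4 (the four-template 16-nt system), 38 = 29 + 9, 74 = 56 + 18 and
152 = 114 + 38; in all cases the trit capacity 3^n_info ≥ 2^B holds. Sync
identity defaults to the cyclic successor of the previous base
(A→C→G→T→A), which is deterministic, position-independent, never collides
with its left neighbour, and is decodable without side information.
Scaffolds with explicitly fixed identities are also supported (used by the
two-strand worked example, whose published template carries a T at the
second sync position where the cyclic rule would put a G).

**Transition table.** For each previous base, the three other bases in
alphabetical order map to trits 0, 1, 2. Any bijection works; the table is
serializable configuration so an alternative mapping can be substituted.
Consequently the package's 8-nt "hello world!" templates are *a* valid
encoding of that message, not a reproduction of the original experiment's
unpublished mapping — which also means the split of templates into 8- vs
9-nucleotide synthesis targets (terminal C already present or not) is
computed per template from the encoded sequence rather than assumed.

**Bit→trit packing.** ECC profiles convert the whole B-bit block as one
big-endian integer to fixed-width base 3. The uncoded 8-nt profile converts
address and data separately (3 + 5 trits for 4 + 8 bits), matching the
per-character scheme of the original demonstration; data bytes must be
< 3^5 = 243, which covers ASCII. With joint packing a single wrong trit can
scramble many bits, so the error-correcting code mostly serves to *verify*
the reconstruction; end-to-end success is dominated by exact consensus
recovery.

**BCH codes.** Binary narrow-sense BCH over GF(2^m), implemented in-package
(generator from minimal-polynomial LCMs; syndrome decoding with
Berlekamp–Massey and Chien search; a post-correction syndrome re-check
rejects most miscorrections). Profiles:

| profile | code | realization |
|---|---|---|
| (38, 33, 23) | 10 parity bits | BCH(1023, 1013, t=1) shortened to (33, 23) |
| (74, 63, 36) | BCH(63, 36, t=5) | unshortened |
| (152, 128, 57) | BCH(127, 57, t=11) | + 1 fixed zero pad bit |

The (38,33,23) choice follows from arithmetic: the only narrow-sense binary
BCH family offering exactly 10 parity bits with ≥ 23 info bits is the
length-1023, t=1 family. Correctness is tested against the published
BCH(15,7) generator polynomial and exhaustive nearest-codeword decoding of
that fully enumerable code.

**Addressing.** 2^address_bits templates per pool; maximum payload
`2^address_bits × (Ω − address_bits) / 8` bytes. The scalable profiles'
address widths (11/15/15) are configuration defaults — decoding trials draw
the full Ω-bit word at random, so results do not depend on the split.

## Channel model

Two simulation levels share one parameterization (`ChannelModel`):

- `p_miss` — probability a synthesis cycle adds nothing (a *missing
  nucleotide*, the dominant error mode). Default 0.113, calibrated so that
  1 − (1 − p)^9 ≈ 0.66 of nine-cycle syntheses lose at least one
  nucleotide.
- `p_mismatch` (default 0.011) and `p_insert` (default 0.012) — per-
  nucleotide substitution and per-gap single-base insertion probabilities,
  calibrated analogously to the observed ~9.5%/~10.7% per-strand rates.
  These are configuration values, not measurements.
- `extension_mean` — mean homopolymer run length per transition type
  (scalar or 4×4 matrix; default 2.5, the middle of the observed two-to-
  three-base range). Runs are shifted-geometric (support ≥ 1), the natural
  single-parameter law for distributive polymerase kinetics; the empirical
  per-transition distributions are not published, so the law is swappable.

The **raw level** simulates runs and then layers sequencing substitutions
and insertions; the **compressed level** applies deletion/substitution/
insertion directly to the transition sequence and then re-merges any
adjacent duplicates the errors created. Re-merging applies to deletions
too: a template `x,y,x` whose `y` is missed yields a single observed `x`.
This makes the compressed-level generative process exactly the one the
decoder's likelihood integrates, and makes both simulation paths agree in
distribution (the merge coupling exists in both — it is a property of
run-length compression, not of the simulation level). Ligation tails
(the polyC tail used for adapter ligation, represented as a single terminal
C) are guaranteed final extensions outside the error model.

## Likelihood and reconstruction

**Edit-channel likelihood.** For a candidate template, P(observed strand)
is computed by a forward DP over (template position, observed symbols
consumed). Because observations are run-length compressed, the DP
marginalizes *raw* edit histories grouped by their compressed image: at
state (i, j) the current run's base is necessarily `strand[j−1]`, so
re-emitting or re-inserting that base is absorbed and consumes nothing.
The DP is exact — verified against exhaustive enumeration of all edit
histories for short templates — and normalized: total probability over all
compressed strings is 1, so likelihoods of different candidates are
directly comparable. Without the merge-aware grouping the true template is
systematically penalized (roughly one spurious double-deletion per `x,y,x`
motif per strand) and reconstruction accuracy collapses from ≳90% to ≈45%
at the reference operating point. Arithmetic is scaled linear-space
(per-row peak kept at 1 with accumulated log offsets), which is several
times faster than log-space `logaddexp` at equal exactness.

**MAP search.** Strands are independent given the template, so the score of
a candidate is the sum of its per-strand log-likelihoods. Exhaustive
scoring of all 3^n_info scaffold-consistent templates is the reference
(`exhaustive_map_decode`, used in tests up to K = 10). The production
search factorizes along the scaffold:

1. *Beam stage.* Templates grow segment by segment (a segment = one sync
   group). All transition-valid candidates for a segment (3^3 = 27) are
   scored for all beam hypotheses in one batched DP; each strand's
   anchoring ambiguity is marginalized exactly by its forward vector.
   Pruning combines forward mass with a binomial suffix-consumption
   heuristic whose per-position yield is estimated from the observed
   strands themselves (mean length / K) — a data-driven calibration that
   absorbs deletions, insertions and run merging. Beam width 32.
2. *Refinement stage.* Starting from the best beam hypothesis, each
   segment — and then each adjacent segment pair, which resolves shift
   errors spanning a sync nucleotide — is re-optimized under the exact
   joint likelihood with the rest of the template fixed, using precomputed
   backward vectors. Sweeps repeat to a fixed point (at most 6); no step
   can decrease the joint likelihood.

The fixed point is the MAP sequence; the final sweep's per-segment
conditional candidate weights give the per-position posterior (rows sum to
1 by construction). `consensus` takes the per-position argmax, forces sync
positions to their scaffold identities, and repairs any self-transition by
a joint two-position argmax over the offending pair (repair on by default —
whether the original implementation enforced transition validity in its
consensus is not documented, so both behaviours are available).

Where the factorized search is checkable against the exhaustive reference
(K = 10, five strands, 20% missing) the two agree on ≈100% of random
populations, and every disagreement is the factorized result scoring at
least as high — i.e. residual differences are exhaustive-reference ties,
not search losses. At (38, 33, 23) with 10 strands and 30% missing
nucleotides, ~93% of 500 trials recover the payload bit-exactly, matching
the design target of robust retrieval with ten diverse strands at ~30%
loss. With the default mixed channel (substitutions and insertions added)
the same pipeline reaches ~80%: the shortfall there is genuine MAP error —
the truth scores below another template — not search failure, which is why
the robustness experiments vary the missing-nucleotide rate specifically.

## Retrieval filters

- *Trimming*: each read must contain the initiator 3′ flank and the adapter
  5′ flank within an edit-distance tolerance of `floor(fraction × flank
  length)` (default 0.10; 0.25 is appropriate for nanopore reads). Flanks
  are located by infix alignment (edlib); among co-optimal locations the
  initiator match extends furthest right and the adapter match starts
  furthest left, so no flank base bleeds into the interior.
- *Size selection*: closed interval on raw strand length (e.g. 32–48 nt for
  a 16-nt template at 2–3 bases per cycle).
- *Two-step filter*: keep strands of exactly the designed compressed length
  ending in the terminal ligation C, then return the most abundant variant
  (ties broken lexicographically, with a warning).
- *Top-strand selection* for the reconstruction decoder: subsample to a
  target read count, drop variants whose read count exceeds a cap (aberrant
  over-amplified species; the cap grows with sampling depth via a
  configurable bracket map, default cap 5), rank by compressed length
  descending, keep the top 10.

## Experiments

`run_decoding_trials` draws a random Ω-bit word per trial, encodes,
simulates n strands at the compressed level, reconstructs (MAP → consensus
→ demodulate → BCH decode), and scores *bit-exact* recovery — the strictest
reading of correct retrieval. `streaming_retrieval_sim` reproduces the
real-time sequencing analysis: timestamps are shuffled and the read count
proportional to elapsed time is resampled per increment (default 10,000
resamples; a 48-h run at 2-h increments gives 24 points), reporting the
earliest run fraction at which success probability reaches the robustness
threshold (0.9999). The fixture generator emits FASTQ read sets with ground
truth for an 8-nt-template message pool, a 16-nt scaffolded pool, and a
single 16-nt error-analysis template containing all 12 transition types
(an Eulerian walk over the transition graph, then four repeats).

Problem sizes in the shipped test suite and acceptance script — 500
decoding trials at (38, 33, 23), 10^4-sample calibration checks, K ≤ 10
exhaustive references — are chosen so the whole suite completes in minutes
on a single core while keeping binomial standard errors near 1%.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* of the channel:
per-cycle loss, substitution and insertion rates, geometric run lengths,
run-merging, uniform read arrival times. It does not model
transition-dependent loss rates (the channel accepts a per-transition miss
matrix but defaults to a scalar), PCR amplification bias, chimeric or
reverse-orientation reads, basecaller-specific error structure, or
timestamp clustering in real nanopore runs. Passing tests therefore
demonstrate correctness of the codec and decoder under the stated channel,
not performance on any particular wet-lab dataset.

## Known limitations

- The (38,33,23) profile's t=1 code corrects a single bit error; with joint
  base-3 packing its practical role is error *detection*.
- Alignment-based error tabulation reports one optimal alignment and flags
  ambiguity; per-strand indicator fractions and per-read means are both
  emitted because ambiguous alignments make position-level counts
  non-unique.
- The beam + coordinate refinement search is exact only in the limit of
  wide beams; its agreement with the exhaustive reference is itself part of
  the test suite rather than assumed.
- Templates are fixed-length by design; variable-length candidate spaces
  (e.g. for truncated syntheses) are out of scope.
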