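# Methods

## IsomiR cataloguing

A read is assigned to a mature reference by exact matching (no mismatches)
against the hairpin sequence plus genomic flanks. Candidate 5′ anchors are
tried within ±6 nt of the annotated mature start; the anchor with the
longest exactly matching read prefix wins (ties: smallest |5′ offset|,
then the more 5′ anchor). A read whose best core match is shorter than
16 nt is routed to a reject table, never raised as an error. Reads
matching several matures go to the reference with the smallest |5′ offset|
(ties broken lexicographically by name) and are flagged `ambiguous`.

Offsets follow the shifted-register convention: `five_prime_offset` is
(mature 5′ start − read 5′ start), so a read starting one nucleotide
downstream — shifted in the 3′ direction, hence shorter — has offset −1.
`three_prime_offset` is (templated read 3′ end − mature 3′ end). The 3′
extension beyond the matched core is explained as templated genomic
continuation greedily, longest match first; only the remaining suffix is a
nontemplated tail. This is deliberately conservative: it minimises
nontemplated calls, so an `A` addition that happens to match the genome is
reported as a templated extension. Categories follow from the offsets:
canonical ⇔ (0, 0) with an empty tail; `5prime_only` / `3prime_only` /
`mixed` otherwise; `templated` ⇔ empty tail.

The 5′-isomiR caller flags a record as passing iff |5′ offset| ≥ 1, read
count > 100, and fraction > 0.05 — both thresholds strict, so boundary
records (count exactly 100, fraction exactly 0.05) fail. The fraction's
denominator is configurable: all reads assigned to that mature arm
(`arm_total`, the default and the more conservative reading) or reads of
the canonical sequence only (`canonical_only`). Seed groups are named
`.1`, `.2`, … in descending read count; because published suffixes follow
a fixed external convention rather than abundance, an override map lets
callers reproduce them.

## Site motifs and target prediction

Site motifs are reverse complements written in mRNA sense: the 6mer core
matches miRNA positions 2–7, the 7mer-m8 adds the position-8 match one
base 5′ of the core, and the A1 types append a literal adenosine opposite
position 1 (an identity of the target site, not a complement). Scanning
anchors every 6mer-core occurrence and promotes it to the strongest nested
type at that anchor (8mer > 7m8 > 7a1 > 6mer), which avoids double
counting. `predict_targets` keeps genes with at least one hit at or above
a configurable minimum type, default 7mer-A1. Conservation scoring is out
of scope; externally produced target lists can be supplied as one-column
TSVs wherever a target set is consumed, and the per-gene UTR is whichever
sequence the caller provides (by default the pipeline emits one UTR per
gene; users mapping isoforms should pass the longest).

A structural consequence worth knowing: for a −1-shifted register pair,
any ≥7mer-m8 site of the canonical register contains a 6mer site of the
shifted register at a one-nucleotide offset, and conversely a shifted-
register site followed by `A` *is* a canonical-register 7mer-m8. Site
repertoires of shifted registers are therefore never fully disjoint.

## Enrichment landscapes and target statistics

Genes are ranked by ascending log₂FC (most down-regulated first),
regardless of significance, with ties broken lexicographically so the
ranking is reproducible. At cutoffs every `step` genes (default 100) plus
the final cutoff N, with K of N genes carrying the word and x of them in
the leading t, the landscape value is −log₁₀ P(X ≥ x) when x/t ≥ K/N and
+log₁₀ P(X ≤ x) otherwise, X ~ Hypergeometric(N, K, t); positive values
mean enrichment among down-regulated genes. The counting unit is
gene-level presence/absence of the word and no nucleotide-composition
correction is applied — both choices are recorded in the landscape
metadata. Presence/absence keeps the statistic exactly checkable against
an exhaustive combinatorial oracle (and the test suite does exactly that
for N ≤ 12); per-occurrence counting with composition correction is a
possible extension, not currently implemented.

Direction classes use adjusted P < α (default 0.05) and the sign of
log₂FC; a significant gene with log₂FC exactly 0 counts as `no_change`.
`percent_targets` returns 100·|targets ∩ class|/|class| and yields NaN —
never zero — for an empty class. Cumulative-fraction curves are empirical
CDFs of a set's log₂FC values. Distribution comparisons default to the
two-sided Mann–Whitney U test (Welch's t selectable); the choice of test
for such comparisons is a convention, not a strong claim.

## Host-gene surrogate correlation

For an intronic miRNA co-transcribed with its host gene, the host's
log₂FC serves as an expression surrogate. Studies are retained when the
host change is significant (adjusted P < α, no fold-change cutoff);
studies lacking the host row are dropped with a logged count. Per study
the summary holds the mean target log₂FC, % targets among significantly
up- and down-regulated genes, and their up/down ratio; ratios with an
undefined or zero denominator are missing and are excluded (with counts)
from downstream means rather than treated as zero. The cross-study
regression is ordinary least squares of mean target log₂FC on host
log₂FC; r² is the squared Pearson correlation and the slope P-value a
two-sided t-test. Cumulative-mean trend lines walk from the most
up-(or down-)regulated host study toward no change, the k-th point being
the mean of the first k studies. Group contrasts (host-down vs host-up by
sign; exact zeros belong to neither) use Welch's t-test. Every study's
random control draws `random_set_size` genes (default 500) without
replacement from that study's gene universe, seeded as base seed + study
index, and summaries are computed on a gene-sorted copy of the table so
results are independent of input row order.

## Synthetic data: what it emulates, and what it does not

`gen_locus` builds a uniform-random hairpin (default 110 nt, two disjoint
22-nt mature arms, ≥10-nt flanks). `gen_read_pool` draws a multinomial
over configured isomiR species — 5′ offset, templated 3′ offset,
nontemplated tail, weight — plus an independent per-read chance of one
extra 3′ adenine. The default composition mirrors a cartilage-like 3p
pool: ~5 % canonical reads, ~25 % perfectly templated overall, two 5′
registers (offsets 0 and −1) so exactly two seeds are present, and tails
that are predominantly A with a minor U fraction. Truth manifests are
stored in canonical greedy-templated form, i.e. exactly what a correct
catalogue must report; a constructed tail that matches the genomic
continuation is recorded as templated.

`gen_utrome` plants requested site motifs into uniform-random UTRs
(default 80 nt) and rejection-samples until each requested site appears at
its position with its exact type and every remaining hit overlaps a
planted window. Because shifted-register motif sets interlock (see above),
demanding *zero* other hits would be unsatisfiable; induced cross-register
hits inside planted windows are instead kept and written to the truth
table, which lists every hit in the emitted UTRome so downstream scans are
exactly checkable.

`gen_de_table` draws non-targets from N(0, σ²) and targets from
N(−δ, σ²); adjusted P-values are Benjamini–Hochberg-corrected two-sided
z-tests against the null N(0, σ²). `gen_compendium` draws host log₂FCs
uniformly over ±2 and shifts each study's fixed target set by
β·host-log₂FC with per-gene noise σ (defaults: 124 studies, 1000 genes,
10 % targets, β = −0.4, σ = 0.1); with σ = 0 the per-study target mean
sits exactly on the planted line, so regression recovers β to machine
precision. All generators are bit-reproducible given their seed, which is
recorded in every manifest.

What the generators do *not* model: sequencing error, adapter artefacts,
expression-dependent sampling, UTR length/composition heterogeneity,
microarray intensity noise structure, or between-study platform effects.
Passing tests therefore demonstrate correctness of the algorithms under
clean, known-truth conditions — not robustness to the full messiness of
real libraries. One consequence of the compendium design worth noting:
the random-gene control contains the target fraction of true targets by
construction, so it inherits a diluted slope (β × target fraction) and
can show a nontrivial r²; the planted set's r² still exceeds it, which is
the comparison that matters.

## Problem sizes and numerical choices

The bundled analyses run at desk scale: read pools of 10⁵ reads (twenty
seeds for round-trip checks), UTRomes of 200–300 genes with 30–50 planted
sites, DE tables of 2000 genes with 200 planted targets (δ = 1, σ = 0.5),
and compendia of 124 studies × 500–1000 genes. These sizes make the full
pipeline and its statistical checks complete in seconds to a couple of
minutes while leaving the planted effects statistically unambiguous.
Other numerical details: hypergeometric tail probabilities are floored at
the smallest positive double before taking logs; landscape values at the
full cutoff are identically 0; the exact-zero log₂FC and exact-threshold
cases are resolved as described above; and YAML configs are validated
strictly (unknown or duplicate keys, out-of-range thresholds all fail
before any computation).

## Known limitations

- Exact matching only: no mismatch tolerance, so any sequencing error
  sends a read to the reject table; flank width (10 nt) and the 16-nt
  minimum core are package choices, not community standards.
- No conservation or context scoring in target prediction; site presence
  is a weak predictor on its own.
- The landscape omits Sylamer's composition correction and per-occurrence
  counting; on strongly biased UTR compositions its P-values will be
  optimistic.
- The surrogate framework assumes one harmonised gene namespace across
  studies and averages targets over all genes present per study.
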