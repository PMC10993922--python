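# Methods

## The measurement and the statistic

N7-methylguanosine (m7G) carries a positive charge on the base that makes
it uniquely susceptible to borohydride reduction: NaBH4 opens the ring and
the base is lost, leaving an abasic site, and aniline then severs the
backbone by beta-elimination immediately 3' of the lesion (after position
N).  In a small-RNA sequencing library the resulting 3' fragment carries a
ligatable 5' phosphate, so its read start marks the cleavage site; the 5'
fragment ends in a blocked 3' aldehyde adduct and is largely lost to
adapter ligation.  Reverse transcription stops disperse the observed read
starts over a four-base window N..N+3.

For each reference contig the pipeline tabulates fragment start sites and
forms, per position i,

    cleavage ratio   r = (n_i + alpha) / N
    cleavage score   s_i = log2(r_treated / r_untreated)

where n_i is the number of reads starting at i, N the total reads aligned
to the contig, and alpha a pseudocount (default 0.5) applied symmetrically
in both conditions.  The pseudocount is a design choice of this package:
the literal ratio is undefined when a position has no untreated starts,
and the symmetric form keeps the score finite and exactly antisymmetric
under swapping the conditions.  `alpha = 0` reproduces the literal formula
and raises on zero ratios.

Positions with s > threshold and at least one observed treated start are
grouped into windows (consecutive qualifying positions at most `max_gap=3`
apart).  The window peak (maximum score, ties broken toward the smaller
coordinate) is assigned to the nearest guanosine at offset 0..3 upstream;
windows with no such G are discarded.  This guanosine restriction is what
removes off-target cleavage at 3-methylcytidine (parent base C) and
dihydrouridine (parent base T), which react with the same chemistry but
cannot be m7G.  Two thresholds are exposed: 6.5 (conservative default)
and 5 (relaxed operating point that broadens the candidate list); both are
plain score cut-offs, not p-values — the method deliberately has no
multiple-testing machinery.

## Reference construction

Mature, intron-less tRNA gene bodies get an unconditional 3' CCA tail
(`--cca-if-absent` switches to conditional appending), and genes with
byte-identical post-CCA sequences collapse into one contig named after the
lexicographically smallest member id.  A contig is excluded from scoring
only when *every* member is a pseudogene or mitochondrial prediction — a
mixed group keeps its functional interpretation, since reads from such a
contig are attributable to the functional copy.  When a genome is given,
tRNA loci are N-masked in it and 50-bp flank intervals are extracted,
shifted 3 bp away upstream and 6 bp away downstream of the locus
(strand-mirrored on the minus strand, clipped at chromosome ends).
Internally all coordinates are 0-based half-open; every user-facing table
is 1-based so a called site reads naturally as "G46".

## Filters

Reads whose genomic alignment overlaps a flank interval by at least one
base are pre-tRNA-derived (unprocessed transcripts with leader/trailer)
and are removed by name before counting.  Alignments then pass MAPQ >= 1
(dropping multi-mappers; no rescue or redistribution), excluded-contig
removal, and optionally duplicate collapsing on identical
(contig, start, end, sequence) — off by default because the simulator has
no PCR-duplication model.  Start-site cells supported by fewer than 10
reads are zeroed, but those reads still count toward the contig total: the
ratio denominator is defined as total aligned reads, not the sum of
retained starts.  The 10-read support rule is applied per
(contig, start-site) cell; applying it per distinct read sequence would be
an alternative reading of the protocol.

## The simulator

`simulate_library` is the generative counterpart of the chemistry.  Per
molecule of a modified contig (treated condition only) each planted site
fires with its cleavage efficiency; a fired molecule yields a 3' fragment
with probability p3/(p3+p5) and a 5' fragment otherwise (defaults 0.9 and
0.05 — the strong asymmetry reproduces the loss of 5' fragments to
ligation failure), the 3' fragment's observed start drawn from the stop
offset distribution over N..N+3 (default {0: 0.15, 1: 0.55, 2: 0.20,
3: 0.10}, peaking at N+1 where the scission actually occurs; the
evidence for these weights is qualitative, so they are configurable).
Unfired molecules break at a uniform random position with per-base
probability `background_break_rate` (default 0.001) or yield a full-length
read; emulating the gel size-selection of library preparation, background
fragments shorter than `min_fragment_length` (default 15 nt) are not
recovered — tail fragments of a few bases are unmappable and would alias
to genomic flank sequence by chance.  Reads are trimmed to 51 nt, quality is constant 'I', and sequencing
errors are off by default (`error_rate` adds uniform substitutions) — the
pipeline's signal is positional, not base-call, and exact reads keep the
truth-log oracles exact.  Read names encode origin
(`contig|fragtype|site|serial`) and a TSV truth log is the canonical
record; identical (inputs, seed) give byte-identical outputs.

The synthetic study system is 76-nt random gene bodies with a guaranteed G
at position 46, embedded in a toy chromosome with 200-bp random spacers.
Two deliberate generator constraints keep the ground truth well defined:
(1) the three bases immediately downstream of the planted G are non-G, so
the upstream-G assignment is unambiguous at every stop offset; (2) genome
spacers never start with C, so a mature read whose 3' end runs into the
appended CCA tail can never exactly match genomic sequence adjacent to a
locus — which makes pre-tRNA subtraction exactly separable under the
zero-error simulator.  Pre-tRNA reads are placed to span a locus/flank
junction with at least one base inside the shifted flank and a few bases
inside the gene body.

What the simulator does *not* emulate: real tRNA secondary-structure-driven
RT falloff, base-call errors by default, PCR duplicates, adapter read-through,
wybutosine off-targets (m3C and D already exercise the G filter), and
non-uniform expression across isodecoders.  Passing tests therefore
demonstrate the correctness of the bookkeeping and the statistic under the
stated generative model, not performance on real libraries, where an
external aligner (the built-in exact-substring aligner exists for
simulated, error-free reads only) and duplicate collapsing are expected.

## Position projection

Candidates are lifted to isoacceptor coordinates through per-isoacceptor
multiple alignments (Stockholm).  A gene position maps to the alignment
column holding its position-th non-gap character — a bijection per row —
and candidates from isodecoders landing in the same column merge into one
family-level site (max score, member list kept).  Column labels come from
the `#=GC RF` line (non-gap RF columns numbered sequentially) or from
user anchors; alignments cover the tRNA body, so positions in the appended
CCA tail get synthetic labels CCA1..CCA3.  Rows are matched to contigs by
exact ungapped-sequence equality; no fuzzy matching, no covariance-model
scanning, no de novo alignment.  For the synthetic system, where all
isodecoders of a family share one body length, gap-free profiles are
derived directly from the reference (`profiles_from_reference`).

## Reporting

Coverage heatmaps sum member-gene depth per isoacceptor before
normalization; `row_max` (default) divides each row by its maximum so the
3' pile-up downstream of a methylated G is directly visible, `cpm` divides
by library size in millions for cross-sample comparison.  Summing rather
than averaging isodecoder coverage within a family is the implemented
choice.  Every pipeline run writes a YAML manifest with resolved
parameters, per-stage filter counts and SHA-256 checksums of every
artifact, so determinism is checkable by re-execution.

## Problem sizes

The packaged verification runs use 20 contigs, 50,000 reads per condition,
cleavage efficiency 0.8 and 10 modified contigs for parameter recovery;
smaller libraries (3,000–20,000 reads) for determinism and unit checks.
These sizes give per-contig depths (~2,500 reads) at which the binomial
noise on the start-site fractions is far below the called effect sizes.

## Known limitations

Scores are computed at every position (with pseudocount), including
positions with no reads in either condition, where they are exactly zero
under equal totals; contigs absent from either condition are skipped with
a logged reason.  The intron-handling step of covariance-model pipelines
has no analogue under alignment-column projection and is intentionally
absent.  Candidate calling reports one G per window; two genuinely
distinct m7G sites closer than `max_gap` would merge.
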