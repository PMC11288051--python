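# Methods

This note documents the model implemented by `crisprself`, the default
parameters, the scope of the synthetic-data generator, numerical choices,
and known limitations. It describes only what the code computes.

## Coordinate conventions

All intervals are 0-based, half-open, with an optional strand. GFF3 output
converts to 1-based closed coordinates at the serialization boundary; BED
input/output is passed through unchanged. Reverse-complementing a genome
maps an interval `[s, e)` on a contig of length `n` to `[n − e, n − s)`
with the strand flipped.

## Array detection

A CRISPR array is modelled as `n ≥ 3` near-identical direct repeats
separated by `n − 1` spacers. Detection proceeds in four stages:

1. **Seeding.** Exact `k = 8` k-mer matches at a downstream offset within
   `[min_repeat + min_spacer, max_repeat + max_spacer] = [37, 100]` bp mark
   candidate repeat pairs.
2. **Extension and chaining.** Each seed pair is extended to a maximal
   repeat unit, then chained left and right: the next repeat is the
   best-matching window inside the legal spacer range, accepted while
   repeat-to-repeat identity stays ≥ 0.8 (`identity_floor`). Terminal
   repeats may degenerate: up to `trailer_slack = 2` extra mismatches are
   tolerated at either end of the run before the chain stops.
3. **Boundary refinement.** Repeat boundaries are trimmed/extended by
   cross-unit column conservation (a column belongs to the repeat if ≥ 0.8
   of units agree), constrained to the length envelope (repeat 19–40 bp,
   spacer 18–60 bp).
4. **Overlap resolution.** Overlapping candidates are resolved by more
   repeats, then longer span, then genomic order.

The consensus repeat is the per-column majority over all units at the
modal repeat length (ties break toward the smaller length, then
alphabetically by base).

**Orientation.** An array is reported on the strand where the final repeat
carries at least as many consensus mismatches as the first (the degenerate
"trailer" convention). Ties are broken toward the orientation whose 150 bp
upstream flank is more AT-rich (putative leader). A per-array manual
override always wins.

## Self-targeting spacers

Every *unique* spacer sequence (deduplicated across arrays up to reverse
complement, since orientation is inferred) is scanned exhaustively against
both strands of every contig by sliding Hamming distance — substitutions
only, no indels, default budget 0 mismatches. `N` in the genome never
matches. Hits overlapping any detected array are discarded; the rest are
self-target sites, annotated with the maximally overlapping gene and with
flanks reported in the protospacer's 5'→3' frame (minus-strand hits are
reverse-complemented and their upstream/downstream flanks swapped before
reporting).

## Flanking repeat mutations

For a given spacer, the upstream flanking repeat is unit `i` and the
downstream repeat unit `i + 1`. Each repeat is compared column-by-column
against the array consensus; mismatch offsets are classified by thirds of
the consensus length `L` (boundaries `ceil(L/3)` and `ceil(2L/3)`) into
5'-end / middle / 3'-end. Length-discordant repeats are compared
5'-anchored and gaplessly; the surplus/deficit tail is annotated as a
single indel with its signed length rather than per-column mismatches.

## PAM and anti-tag analysis

Protospacer flanks are collected in the protospacer frame, using
subtype-specific windows: 3 nt upstream for I-E, 6 nt downstream for II-A
and III-A. Flanks truncated by contig edges are excluded from matrices. A
position frequency matrix over A/C/G/T (per-column `N` exclusion) yields
per-column information content `IC_i = 2 − H_i` bits, optionally with the
small-sample correction `3 / (2·ln 2·n)` subtracted.

The type III anti-tag score pairs the first `k` nucleotides of the
protospacer's downstream flank against the crRNA 5' tag (the last `k = 6`
nt of the repeat, as RNA), counting Watson-Crick and G:U pairs
position-by-position. A flank is called an anti-tag at ≥ 4 of 6 pairs. The
canonical case — tag `GAAAAC` vs flank `CUUUUC` — scores 5 of 6.

## Prophage-aware classification

Each self-target site is classified with precedence:

1. `within_prophage` — the site overlaps a prophage region;
2. `near_prophage` — the gap to the nearest prophage is ≤ 10,000 bp
   (inclusive);
3. `phage_keyword_gene` — the overlapping gene product contains one of the
   case-insensitive substrings `phage`, `tail`, `terminase`;
4. `other`.

Per-spacer summaries take the highest-precedence class among a spacer's
sites. Cohort summaries report, over system-bearing genomes, the
percentage with ≥ 1 STS, and over unique STS the prophage-targeting
(within + near + keyword) vs other split, all to one decimal place.
Percentages over an empty denominator are undefined and reported as
`None`; a cohort with systems but no STS reports 0.0.

## tracrRNA anti-repeat and duplex folding

The anti-repeat search aligns the reverse complement of the consensus
repeat, gaplessly and at full repeat length, against both strands of a
±2,000 bp window around the array (the locus itself excluded). Candidates
require length ≥ 20 and identity ≥ 0.6; overlapping candidates are reduced
by non-maximum suppression (identity, then proximity to the locus).

Folding uses Nussinov base-pair maximization with Watson-Crick and G:U
pairs and minimum hairpin loop 3, with a deterministic traceback. `T` is
accepted as `U`. Co-folding concatenates crRNA and tracrRNA through a
4-nt unpairable linker and reports inter-molecular pairs (one end in each
molecule) separately.

## Comparative statistics

Per-subtype statistics are computed over individual repeat and spacer
units: length histograms, modal lengths (ties toward the smaller length),
and spacer-count quartiles by linear interpolation (for `[3, 5, 7, 60]`:
Q1 = 4.5, median = 6, Q3 = 20.25).

## Synthetic-data generator

The generator plants known structures into random background sequence so
every downstream module can be validated against exact truth:

- Background: a single contig (default 2 Mb) at GC fraction 0.35, drawn
  from a seeded NumPy generator; all outputs are deterministic per seed.
- Arrays: subtype-typical repeat lengths (I-E 29, II-A 36, III-A 36 bp) and
  spacer lengths (I-E 32, II-A 30, III-A uniform 30–44 bp), an AT-rich
  (0.85) 150 bp leader planted 5' of each array, and rejection-sampled
  unique spacers. The first and last base of each spacer cycle through
  `A/C/G/T` by spacer index so that no column adjacent to a repeat is
  conserved across units — this makes planted repeat/spacer boundaries
  identifiable in principle, rather than ambiguous by construction.
- Self-targets: exact or mismatched protospacer copies planted at chosen
  positions and strands with chosen flanks; prophage regions with
  keyword-bearing genes; optional anti-repeats at chosen offset/identity.
  Overlapping feature claims raise a configuration error.
- Cohorts: `sample_cohort` emulates a survey at the *record* level — it
  draws per-genome system presence, subtype (weighted 109:62:18 for
  II-A:III-A:I-E), STS counts and target classes with exact configured
  totals (defaults: 13 of 40 system-bearing genomes with STS; 9 of 40
  unique STS prophage-targeting) — it does not synthesize full genome
  sequences per cohort member.

## Numerical choices

- Quartiles: NumPy `percentile` with `method="linear"`.
- Information content: base-2 logarithms; `0·log 0 = 0`.
- Mode ties: smaller length wins, for determinism.
- Sequence scans: byte-encoded NumPy comparisons; the Hamming scan is
  exact (verified against a per-position oracle in the tests).

## Limitations

- Spacer matching allows substitutions only; indel-containing protospacers
  are not found.
- Array detection assumes ≥ 3 repeats within the 19–40 / 18–60 bp
  envelopes; degenerate two-repeat arrays are out of scope.
- Folding maximizes base pairs without thermodynamics (no stacking
  energies, no pseudoknots); it ranks complementarity, not free energy.
- The anti-repeat search is gapless and full-length; indel-containing
  anti-repeats score against the aligned length only.
- Subtype assignment is external (user-supplied labels); the package does
  not call *cas* genes.
- The cohort generator reproduces configured summary totals; it is a
  harness for the summary statistics, not a population-genetics model.
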