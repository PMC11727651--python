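# Methods

This note documents the models, parameter choices and numerical conventions
behind `virextend`, the assumptions they rest on, and what the bundled
simulator does and does not emulate.

## Problem model

The input is one assembled contig and the shotgun read set it came from.
Two failure modes of metagenomic assembly are targeted:

* **Chimerism** — the contig splices together sequence from different
  genomes. Because reads derive from the true genomes, a chimeric insert is
  betrayed by a depth-of-coverage profile inconsistent with the rest of the
  contig (typically much lower, often zero).
* **Fragmentation** — the contig stops short of the full genome. Reads
  overhanging the contig ends carry the missing sequence and can extend it;
  for a circular viral genome, extension eventually wraps around the origin
  and the contig ends become redundant copies of each other.

Both rest on the same assumption: correctly assembled sequence has
approximately uniform read coverage, and every true position is covered.
Amplification bias, extreme GC content, or amplicon protocols violate this
assumption and will produce false suspicious regions (see Limitations).

## Coverage audit

Per-base depth is computed from semiglobal ungapped read placements (k-mer
diagonal voting, k = 21, verified at ≤ 5 % mismatches over ≥ 30 bp of
overlap; reads may be clipped at contig boundaries only). Percentile bounds
use the nearest-rank definition — the ceil(p/100 · n)-th smallest depth —
which is deterministic and interpolation-free; bounds are inclusive, so a
constant nonzero profile flags nothing.

A base is suspicious when its depth falls outside the
[15th, 85th]-percentile bounds **or equals zero**. The zero-depth rule is
deliberate and load-bearing: percentile bounds are order statistics, so when
an unsupported segment makes up more than the lower percentile mass of the
contig (e.g. an 8 kb foreign insert in a 38 kb contig is 21 % of all bases),
the lower bound itself collapses to zero and a percentile-only rule would
certify the insert as normal. A position no read supports cannot be
validated by the data, whatever the shape of the depth distribution, so it
is never counted as normal. Suspicious runs must be strictly longer than
1,000 bp to count ("longer than" read literally: a run of exactly 1,000 is
excluded); this absorbs the short coverage tapers at contig ends (≈ one
read length, where fewer read placements can fit) without flagging them.

When the audit flags anything, the contig is cut to its longest
non-suspicious region (ties broken leftmost) and extension restarts from
there. Bounds are recomputed from the current contig on every iteration.

## Circularity detection

With contig length `L_s` and read length `L_r`, the probe window
`G_a = [L_s − 2·L_r, L_s − L_r)` is matched against the body
`G_b = [0, L_s − 2·L_r)`. Exact 21-mer seed hits propose candidate periods
`s` (the offset between the two putative copies); for each period the full
ungapped self-overlap `contig[s:]` vs `contig[:L_s − s]` is scored.

*Identity definition.* Identity is matches / alignment columns over the
maximal repeat (the full qualifying window along the period), not over
`G_a` alone. This choice (recorded in the provenance log) makes detection
depend on the statistics of the whole repeat rather than on the 150 bp
probe: a 96 %-identical 1 kb terminal repeat is judged on ~1,000 columns
instead of 150, which is both closer to what a local aligner would report
and far less noisy. A period qualifies when identity ≥ 0.95 over a window
covering ≥ 95 % of `G_a`; if the full overlap misses the identity bar, the
longest qualifying sub-window is sought with endpoints adjacent to mismatch
positions (exact, O(K²) in the mismatch count K, skipped for K > 512 where
the overlap is nowhere near the threshold anyway).

Among qualifying periods the one with the longest repeat wins. Trimming
removes the downstream (3′) copy, keeping genome-start coordinates stable.
For an exact terminal repeat both copies abut the sequence ends, so the
trimmed length is exact by construction. Only the forward strand is tested:
a circular permutation cannot present reverse-complemented terminal
redundancy without misassembly. Inverted terminal repeats (probe matching
the reverse complement of the body) are reported in the result note but
never trimmed.

## Extension engine

Edges are the first/last `round(1.5 · L_r)` bases (a short contig is split
into two halves). Reads sharing ≥ 3 exact 21-mers with either edge on
either strand are recruited, and each recruited read pulls in its mate —
the mate reaches up to roughly one insert length beyond the edge and is
what gives a round most of its range.

Local assembly is a greedy suffix–prefix overlap walk seeded on the edge:
at each step the candidate read with the longest verified overlap
(≥ 30 bp, ≤ 2 % mismatches) against the growing tip is appended. Equal-length
overlaps that disagree at the first appended base stop that side for the
round (conservative: ambiguity is treated as possible repeat/chimera
branching); agreeing ties are broken by lexicographically smallest read id,
which together with the deterministic mapper makes the whole engine
reproducible bit-for-bit. A tip-k-mer revisit guard and a step cap stop
runaway extension through tandem repeats, deferring to the circularity
check. Growth is spliced back only after verifying the assembled product
still contains its original edge at ≥ 98 % identity; the contig interior is
never modified by extension.

When neither side grows, trim-and-retry removes t ∈ {300, 500, 1000, 1500,
2000} bp from both ends (symmetric, as the failure mode being targeted —
assembler misjoins near contig ends — can sit at either end) and attempts
one extension round; the first t whose result is strictly longer than the
pre-trim contig is kept, so an accepted trim has more than repaid 2t. At a
true genome end the regrown sequence can at best restore what was trimmed,
so the rule is also what terminates linear contigs.

## Polishing

Reads are placed with the same mapper; reads that seed a diagonal but fail
ungapped verification are realigned with edlib (infix mode) in a ±15 bp
band so that indel-spanning reads contribute gap columns and insertion
events to the pileup. A column is corrected when depth ≥ 5 and the
plurality symbol (A/C/G/T/gap) differs from the contig with frequency
≥ 0.7; insertions require the same majority among reads spanning the
junction by ≥ 4 bp. Indels longer than 10 bp are left to the
extension/trim machinery. Unlike Pilon, counts are unweighted — no mapping
quality, no proper-pair bonus, no local reassembly of discordant regions —
a deliberate fidelity gap accepted because the simulator produces none of
the artefacts those heuristics exist for.

Polishing is idempotent in practice: after corrections are applied the
consensus equals the contig, so a second pass changes nothing (asserted in
tests).

## Pipeline loop

Iteration order is circularity → audit → extension: a positive circularity
result short-circuits everything else, and auditing before extending keeps
chimeric sequence from seeding growth. The loop stops on one of four
logged reasons: `circular`, `no_growth_after_trim`,
`whole_contig_suspicious` (the audit left nothing to extend; the input is
returned unchanged), or `max_iterations` (default cap 100, counting
extension rounds, not trim attempts within a round). Read re-mapping for
the audit is genome-wide each iteration, not restricted to new sequence.

Every sequence change appends an `EditEvent` (kind, interval, signed length
change, iteration, replay detail) to the contig history; replaying the
history against the input reproduces the output byte-for-byte, and the sum
of event deltas equals the net length change. This is the provenance
contract the JSON log serializes.

## Simulator

`virextend.simulate` generates i.i.d. uniform genomes (circular, or linear
with an optional terminal repeat), chimeras with recorded truth
coordinates, and uniform shotgun reads: default 150 bp reads at 30× with
1 % substitution errors, paired with insert length ~ N(450, 50²) and the
inner mate reverse-complemented, fragment starts uniform and wrapping the
origin on circular genomes. Read count is `round(coverage · G / (L_r · 2))`
fragments when paired. Everything derives from a single integer seed and is
byte-reproducible.

What it does **not** emulate: indel sequencing errors (substitution-only;
the polisher's indel repair is exercised by editing truth sequences
instead), quality-score variation, GC-dependent coverage bias, multiple
community members at uneven abundance, and real repeat structure beyond
explicitly constructed tandem/terminal repeats. Tests passing on this
generator therefore demonstrate the pipeline's logic under its own
assumptions (uniform coverage, unique sequence); they do not certify
behaviour on amplified libraries or repeat-rich genomes.

For validation experiments, genomes of 8–30 kb at 30× (a few thousand
reads) are used; these sizes keep every stage's behaviour identical to
larger inputs — all thresholds are in absolute bp or fractions — while a
full run stays in the seconds range.

## Numerical choices and degenerate inputs

* k = 21 throughout (seeding, recruitment); k-mers containing N are
  excluded, so N never seeds an alignment.
* Contig k-mers occurring > 16 times are masked out of mapping seeds. In a
  heavily tandem-repetitive contig most reads then fail to place, the depth
  profile collapses to zero and the pipeline halts as
  `whole_contig_suspicious` — an intended safe failure.
* Mapper determinism: best diagonal per read/strand by vote count, ties to
  the leftmost diagonal; best strand by mismatch rate, then forward, then
  leftmost start.
* Constant-depth profiles: both percentile bounds equal the constant; no
  suspicious bases (if the constant is nonzero).
* Contigs shorter than 3·L_r are untestable for circularity and reported
  as not circular with a note.
* Empty recruitment, empty trim schedule, or anchor-verification failure
  all degrade to "no growth" rather than errors.

## Known limitations

* A linear phage with genuine terminal repeats is indistinguishable from a
  circular genome by this test and will have one repeat copy trimmed.
* Zero-support regions are always flagged, but a chimeric insert that *is*
  covered (e.g. a shared gene cassette at comparable depth) can escape the
  percentile rule.
* Depth is not corrected for GC content; GC-extreme regions of real
  Illumina data may be falsely flagged.
* Greedy overlap assembly stops at any branching ambiguity, so extension
  through polymorphic or repeat-dense regions is conservative and may stall
  where a graph assembler would proceed.
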