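# Methods

`heterasm` re-creates, at desk scale, the hierarchical clone + whole-genome
shotgun assembly strategy used for highly heterozygous diploid genomes:
sequence each ~120 kb clone insert deeply, assemble every clone on its own
(a clone carries a single haplotype, so within-clone heterozygosity
vanishes), merge the clone assemblies by overlap, remove the allelic
redundancy that independent clones from opposite haplotypes create, then
order and orient the result with long-insert mate pairs and close the
remaining gaps with short-insert reads. This note records the models,
the tunable parameters, and the numerical choices behind each stage.

## Genome sizing from the k-mer spectrum

A read of length L contributes L−k+1 k-mer instances (windows containing N
are skipped; every window is counted as the lexicographically smaller of
itself and its reverse complement). The histogram of per-k-mer depths has
an error slope at low depth, a homozygous peak at the k-mer coverage
`C_k = C·(L−k+1)/L`, and — in a heterozygous genome — an allelic peak at
`C_k/2`, because a k-mer spanning a heterozygous site occurs on only one
haplotype. Genome size is estimated as

    G = K_num / K_depth

with `K_depth` the homozygous peak depth and `K_num` the total instance
count above the error trough. Choices:

- **k = 17** by default (fits in memory at desk scale; any odd 11–31 works;
  counting uses 2-bit packed 64-bit codes and `numpy.unique`).
- **Error exclusion.** Instances at or below the first local minimum of the
  smoothed histogram are excluded from `K_num` by default
  (`--kmer-include-errors` restores the raw sum); including them inflates G
  on error-bearing reads.
- **Peak reading.** The histogram is smoothed with a centred 3-bin moving
  average (zero-padded: depths outside the histogram hold no k-mers),
  maxima come from `scipy.signal.find_peaks`, each maximum is snapped to
  the raw-histogram mode within ±1 (smoothing can split a sharp mode into
  twin shoulders), and peaks under 10% of the tallest are dropped. A pair
  of adjacent peaks with depth ratio in [0.4, 0.6] flags heterozygosity,
  and the deeper peak is taken as homozygous — the shallower one is
  allelic.

Measured on error-free 100 kb / 50× simulations the estimate lands within
~3% of truth; on 1%-SNP diploid reads the half-depth peak appears and the
estimate stays within ~3% of the haploid size (the tests assert the 5% and
8% bands).

## Per-clone assembly and the k-sweep

Each clone's reads are assembled in a de Bruijn graph that stores every
k-mer in both orientations (odd k only, so no palindromes; traversal emits
each strand pair once). Cleaning proceeds in this order:

1. **Solid-k-mer filter.** Edges with multiplicity below 0.1× the
   *instance-weighted* median multiplicity are removed. The weighting
   matters: at a 0.5% per-base error rate, error k-mers dominate the
   distinct-k-mer count (most occur once), so the unweighted median is 1
   and useless as a coverage reference, while the weighted median tracks
   the true coverage peak.
2. **Tip clipping.** Dead-end unitigs shorter than `tip_len` with mean
   multiplicity below half the weighted median are removed. The unit
   assembler sets `tip_len = read_len + k`: a substitution near a read end
   spawns a dead-end branch of up to a full read length, so the textbook
   2k default leaves most error tips standing.
3. **Bubble resolution.** Where two branch paths reconverge and align at
   ≥ 90% identity (edlib), the lower-multiplicity branch is removed. With
   `pop_bubbles=False` the removed branch is remembered and re-spliced
   into a second, haplotype-swapped copy of the finished contig — so a
   diploid fragment with one SNP yields exactly two allelic contigs, the
   redundancy the purge stage exists to remove. In the pipeline default
   (`pop_bubbles=True`) bubbles simply collapse: clones are single-
   haplotype, so within-clone bubbles are errors, not alleles.

The sweep runs every odd k in [25, 63] (step 2) and keeps the assembly
with the longest contig N50, breaking ties by larger total length, then
smaller k. Units here are not internally scaffolded, so contig N50 stands
in for the scaffold N50 the original protocol ranked by. Contigs shorter
than 100 bp are dropped as debris.

## Overlap merging

Shared exact 15-mers nominate contig pairs, a strand and an offset (median
of seed offset votes); the implied overlap is verified by global edlib
alignment. Records need ≥ 200 bp at ≥ 95% identity — loose enough that
clones from opposite haplotypes (~1% divergence, so ~99% identity) still
merge, tight enough that chance matches never do (tested over 100 random
pairs). Overlaps are classified containment (one contig ≥ 95% covered —
absorbed), dovetail (alignment reaches within 50 bp of the proper ends of
both contigs), or internal (mid-to-mid, likely repeat-induced — rejected
rather than split). Dovetails are joined greedily by decreasing identity
then aligned length; a join is refused if either contig end is already
used or the two contigs are already connected (union-find), so chains stay
linear. At a disagreeing overlap column the earlier contig's base is kept.
Provenance lists every input contig as kept, merged (with its interval in
the super-contig) or contained.

## Haplotig purging

The purge statistic pair follows the "sequence depth and shared k-mer
percentage" recipe:

- **Per-copy read-back depth.** For each contig position, the read count
  of its canonical 21-mer is divided by that k-mer's copy number across
  the whole contig set; the contig's depth is the median over positions.
  The copy-number division is what makes the half-peak signature visible:
  at 1% divergence most of a haplotig's k-mers are homozygous and occur in
  both members of the allelic pair, so their raw read counts sit at the
  full peak while the per-copy value sits at half. A collapsed repeat
  shows the opposite signature (full or above-peak per-copy depth) and is
  never purged by the depth condition.
- **Shared fraction.** |distinct canonical k-mers of candidate ∩ kept
  partner| / |candidate's|, deliberately asymmetric so a short haplotig
  contained in a long kept contig scores high. At SNP rate p the expected
  fraction is (1−p)^k ≈ 0.81 at p=1%, k=21.

Contigs are processed longest-first; a contig is removed iff its depth
ratio is ≤ 0.65 of the homozygous peak **and** it shares ≥ 0.60 of its
k-mers with an already-kept contig. 0.65 admits depth noise around the
0.5 allelic expectation while excluding homozygous contigs; 0.60 tolerates
~2% divergence ((0.98)^21 ≈ 0.65). Both are configurable.

## Scaffolding

Reads are anchored by canonical 21-mer seed votes (a placement needs ≥ 80%
of a read's seed votes on one contig+strand; seeds at more than 4
reference positions are dropped as repeats). Pairs with mates uniquely on
different contigs become link evidence between specific contig ends —
inward-pointing (FR) for short inserts, outward (RF) for mate pairs. A
link needs ≥ 3 supporting pairs and a plausible median gap
(|median| ≤ mean + 3 sd); when several orientation classes exist for one
contig pair, the majority class is kept only if it alone passes the
support threshold.

The **gap estimate** is the outlier-trimmed mean of the per-pair estimates
(insert_mean − anchored flanks) plus a length-bias correction
`+ sd²/(insert_mean − 2·read_len − gap)`. The correction matters: a
fragment spans a junction with probability proportional to its anchorable
span, so spanning pairs over-sample long inserts and the naive estimate is
low by almost exactly that term (~26 bp for a 3 kb ± 250 bp library over a
400 bp gap) — comparable to the whole 2·sd/√support precision band the
estimator is expected to meet. The per-pair *median* is still reported
unmodified as the robust filter statistic.

Libraries apply smallest insert first; links are accepted by descending
support when both contig ends are free and the contigs belong to different
chains (joins from earlier rounds are never undone). Negative estimated
gaps clamp to a single N — true overlaps were already merged upstream.
Contigs under 500 bp are excluded from ordering and emitted as singleton
scaffolds: they are mostly collapsed repeat cores, and because one such
core attracts correct-looking, high-support links from every locus of its
family, letting it into the chain graph consumes its two ends and severs
the real neighbours (measured on the 500 kb simulation: 43 of 45 true
adjacencies carried links, yet the scaffold count only collapsed from 45
to ~5 once short contigs were set aside).

## Gap filling

For each N run, reads seed-matching either 500 bp flank (plus their mates)
feed a local de Bruijn graph at k=31 — fixed independently of the
unit-assembly k, since local graphs are tiny and a large k is safer. A
*unique* path from the last flank k-mer to the first k-mer of the right
flank, within gap_estimate + 3·insert_sd + 2k, closes the gap; two or more
such paths leave it untouched (ambiguity refused, favouring correctness
over closure rate); no path triggers greedy extension of each flank along
unambiguous edges, always retaining ≥ 1 N. Splicing is positional, so
bases outside the gap are byte-identical before and after — asserted
exactly in the tests. Two rounds by default; simulations reach a fixed
point in ≤ 2.

## QC battery

`nx` (sort descending, first length where the cumulative sum reaches x%),
fold coverage (total bases / genome size, 2 decimals, half-up — matching
the report formatting of the original tables), feature-track percentages
(interval union first, never double-counted), cumulative scaffold coverage
(with the smallest n reaching 90%), and a seed-vote + banded-edlib
read-back mapper. The mapper is an explicit stand-in for a production
aligner: a read counts as mapped if ≥ 90% of it aligns at ≥ 90% identity;
transcripts count as recovered if chunks covering ≥ 50% of their length
align at ≥ 80% identity on at most two scaffolds (proxy for spliced/split
placement). The real study's validation rates came from a production
aligner on real data and are not reproduction targets.

## The simulator, and what it does not emulate

`simgen` generates: a uniform-random haploid window with planted
near-identical repeat copies (unit 500 bp, ≥ 97% identity, 5% of the
genome by default); a second haplotype via SNPs (1%/bp default) and 1–5 bp
geometric indels (0.1%/bp); a clone tiling at 4.3× coverage of 120 kb ±
10 kb inserts, each clone drawn whole from a random haplotype — the
simplest mechanism that reproduces the central problem, allelic redundancy
entering the merge from independently assembled clones; and FR/RF paired
reads with Normal insert lengths (truncated at 2×read_len) and
substitution-only errors (0.5%/read-base default; indel errors off to keep
assembler behaviour analyzable). Clone placement is edge-clipped: a clone
may run off either end of the simulated window and is truncated there, as
a clone from a larger genome would be — without this the window ends are
systematically under-covered and the apparent assembly deficit has nothing
to do with the assembler. All randomness flows from one seeded
`numpy.random.Generator`; identical seeds give byte-identical outputs.

Not emulated: instrument-specific error profiles, cloning-vector or
chimeric-clone artifacts, GC bias, within-clone haplotype switching.
Passing tests therefore show the method's logic is right under clean,
known-truth conditions; they do not certify performance on real libraries.

## Problem sizes used

The flagship end-to-end run is a 500 kb diploid genome at 1% SNP, 4.3×
clone tiling (30× reads per clone), 50× short-insert and 10× mate-pair
whole-genome libraries. At this scale the full pipeline completes in a few
minutes on one CPU. The per-clone k-sweep is run at k=31 in the test suite
and k ∈ {27, 31} in the acceptance script; the sweep-selection rule itself
is verified on unit-scale fixtures against an exhaustive-sweep oracle,
where the full 25–63 range is cheap. On the 500 kb run at seed 1 the
assembly totals ~507 kb (+1.5%), scaffold N50 exceeds contig N50 ~28-fold,
and 99.5% of assembled bases match a true haplotype at ≥ 99% identity.

## Known limitations

- Internal (repeat-induced) overlaps are rejected, never split; a chimeric
  unit contig would propagate.
- The merge consensus takes the first contig's base at disagreeing
  columns rather than a depth-weighted consensus.
- Purging is k-mer based on both axes; no alignment-based rescue, no
  phasing.
- The scaffolder is greedy (support-ranked), with no global optimization
  and no misassembly detection.
- Gap filling refuses ambiguity, so repeat-content gaps stay open by
  design.
- Saturating counting above depth 65,535 and streaming of
  larger-than-memory inputs are out of scope.
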