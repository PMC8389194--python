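# Methods

## Scope and data model

`splicecat` analyzes one reference transcript at a time. The coordinate
authority is a `TranscriptModel`: ordered exons carrying both genomic spans
(1-based, inclusive, `genomic_start <= genomic_end` regardless of strand)
and spliced-transcript (cDNA) spans, plus the CDS anchors. All stored
coordinates are 1-based inclusive, matching both HGVS and STAR's
`SJ.out.tab`; any half-open convention is converted at I/O boundaries only.
The r. and c. HGVS coordinate systems coincide numerically (position 1 is
the A of the start codon), so a single system is implemented and can be
rendered with either prefix. Intronic positions anchor to the nearest exon
boundary: the 5′ half of an intron renders `donor+k`, the 3′ half
`acceptor-k`; the midpoint base of an odd-length intron goes to the donor
(`+`) side — HGVS convention, since published catalogs never state the
tie-break.

Only the unique-mapping read count of `SJ.out.tab` feeds quantification;
multi-mapped counts are parsed and carried but ignored, the conservative
choice for amplicon data aligned with a small multimap allowance. Junction
identity is (chrom, intron start, intron end, strand code); motif,
annotation and overhang columns do not discriminate junctions. Lines with
zero unique and zero multi-mapped reads are dropped at read time.

## Classification

A junction's removed region is flanked by the donor base D and acceptor
base A. Each is located as a canonical exon boundary, an exonic position,
or an intronic position, and the event is decomposed into components:

* whole exons lost → skipping (`Δn`, `Δm–n`);
* partial loss at an exon's 3′ end → exonic donor shift (`Δnp`), at its 5′
  start → exonic acceptor shift (`Δnq`);
* retained intron head → intronic donor shift (`▼np`), retained tail →
  intronic acceptor shift (`▼nq`), where *n* is the exon whose
  donor/acceptor moved;
* two junctions whose intronic ends face each other inside one intron →
  cryptic exon (pseudoexon) inclusion `▼n` (n = the intron's ordinal);
* a deletion confined to UTR bases → terminal modification (`Δ5′UTR` /
  `Δ3′UTR`), taking precedence over shift patterns;
* any other combination → mixed, named by joining component names with
  `+` in transcript order.

An intra-exon loss (both splice sites inside one exon, an exitron-like
junction) is represented as a donor+acceptor shift pair of that exon and
classed mixed unless it is UTR-only. Junctions outside the transcript span
are excluded from the catalog with a logged note rather than an error.

The classifier is verified against an independently written brute-force
truth table over every donor/acceptor base pair of toy models with 3–5
exons (exhaustive grid, 100% agreement required).

### Cryptic-exon pairing

A pseudoexon in intron *i* is called from junction J1 (donor → intronic
acceptor at *a*) and J2 (intronic donor at *d* → acceptor) with *a < d*;
its per-sample support is min(reads(J1), reads(J2)), a conservative choice
since the published catalogs report a single count per ▼ event without
stating the rule. J1/J2 ends may themselves be exonically shifted, which
yields mixed deletion+insertion events. Junction-level data cannot always
distinguish genuine pseudoexon combinations from cross-products of
boundaries when several pseudoexons share an intron; the default follows
the permissive rule (every consistent pair emits one event), and a
`parsimonious` mode instead keeps each boundary's best-supported partner
(closest read totals, then shortest pseudoexon). Published catalogs
resolved this ambiguity with prior literature; neither mode can recover
that knowledge from counts alone.

## Nomenclature

p/q side letters follow the published *tables* (p = donor side, q =
acceptor side); the accompanying methods text describes the opposite
convention, and `pq_invert=True` switches to it. Capital letters
disambiguate multiple events in one slot, assigned in transcript order
(ties: shorter event first, pure events before compound ones). Letters are
needed when a slot holds two or more pure events or when a previously
published member already carries one. Published event names — supplied as
an established-names map from HGVS consequence to name — are kept verbatim
and their letters treated as taken, the way the source catalogs carried
earlier publications' series forward (this is the only way letters like
▼1E/▼1F can land correctly between inherited ▼1A–D and ▼1G–I). Terminal
UTR events are never lettered, matching published usage, so catalog names
are guaranteed unique only for lettered (shift/cryptic) kinds; consequence
strings are always unique per event.

## Quantification

The junction percentage of an event is the ratio of means

```
p = 100 * mean_over_samples(alt reads)
        / mean_over_replaced_introns(mean_over_samples(canonical reads))
```

where the replaced introns are every canonical intron wholly or partly
removed by the event's junctions (an exon-4 skip replaces introns 3 and 4;
a multi-skip of exons 4–7 replaces introns 3–7). This reading reproduces
the published catalog cells to 3 decimals (verified on ten cells, seven of
which are acceptance targets). Events removing no intron at all (intra-UTR
exitrons) are quantified against the mean over *all* canonical introns,
which reproduces the three published 5′UTR cells. The read-support mean
averages the samples carrying the junction (a junction seen once with 116
reads is reported as 116, matching both the published footnote and its
printed percentage). A handful of published cells (e.g. the NBN ▼2, ▼9,
Δ9, Δ12 rows) are not consistent with any ratio-of-means rule — most
plausibly they were computed as means of per-sample ratios over detected
samples — and are documented rather than chased.

The aberrant fraction is `f = 100*alt/(alt + canonical mean)`, the
aberrant-versus-normal proportion, related to the junction percentage by
`f = 100p/(100+p)` (property-tested). Both statistics are reported side by
side in carrier reports because published carrier values do not state
which convention they use.

## Detection threshold

A junction is *real* when it has ≥ `min_reads` (default 20) reads in each
of ≥ `min_samples` (default 2) distinct samples, or is previously
published (whitelisted). The per-sample reading — not a mean — is the only
one consistent with the published footnotes, which fail a 6-sample event
averaging 6 reads (`low_reads`) while footnoting single-sample events with
>100 reads (`single_sample`). Failing events stay in the catalog with
their reason tag. Raising either threshold parameter can only convert
pass → fail (monotonicity, property-tested).

## Carrier-versus-controls comparison

Carrier percentages are computed on carrier counts alone. An event is
novel in the carrier when it stays below the read threshold in the control
panel; control expression is summarized by the maximum across controls
(conservative against single-control outliers, in the same spirit as the
two-sample threshold rule). Grading defaults: `complete` at carrier
percentage ≥ 20% with controls below half the carrier level, `leaky`
< 5%, `partial` between, `not_aberrant` when controls reach ≥ half the
carrier level. These cutoffs are configuration, not science: published
carrier calls grade ~30% (with no wild-type reads at the variant base) as
complete and ~0.9–1.1% as minor leaky splicing without defining
boundaries; the defaults reproduce those calls and are printed in the
report header. Allele-level confirmation (inspecting the variant base in
the alignment) requires BAM access and is deliberately out of scope; the
report carries a free-text evidence slot for it.

## Synthetic data

The generator emulates deep single-gene amplicon junction counts: each
canonical junction's total is drawn at a configurable depth (default
100,000×, the coverage targeted for cataloguing low-expressed events;
published canonical means span ~50,000–300,000), and each injected event
draws its junction count at an expected value of `target_fraction` percent
of canonical (published alternative events span ~0.002–11%). Counts are
Poisson by default — amplicon deep sequencing, with no published
dispersion estimate — with a negative-binomial option (`var = μ + αμ²`,
default α = 0.05) for robustness experiments. With canonical depletion on
(default), event molecule shares are normalized so that alt/canonical
converges to the target fraction even when events co-occur on the same
introns (exact for events sharing identical intron sets, approximate for
events spanning unequally loaded introns); an 11%-scale event therefore
visibly depletes its canonical junction, as real catalogs imply. Cryptic
events emit their two boundary junctions with one shared count (fully
correlated), and a per-sample presence probability lets events drop out of
samples. All randomness flows from a single seed.

What the generator does not emulate: read-level artifacts (mapping errors,
overhang-dependent detection), PCR amplification bias across isoforms,
library-size differences between samples, and genuinely unknown event
composition. Passing recovery tests therefore demonstrates that the
pipeline's arithmetic and classification are correct at realistic depths
and fractions, not that the laboratory assay is unbiased.

## Packaged fixtures

The STK11 and NBN catalogs are packaged verbatim, one row per published
row, with machine-readable flags. Exon boundaries of both models are
reconstructed from the catalogs' r. coordinates; genomic coordinates are
synthesized on fake contigs (no genomic spans are published), with intron
lengths chosen so every published intronic offset renders on its printed
side of the intron — classification depends only on exon/intron geometry.
The NBN exon 10/11 boundary is inferred solely from the Δ11q rows and
marked approximate; nothing downstream depends on it. Rows whose printed
name and coordinates are mutually inconsistent (anchor typos such as the
▼8A/▼8B/▼8p insertions anchored one exon away from their offsets, a
duplicated Δ3–4 label, an unnamed row, sequence-level delins descriptions,
ad hoc compound-name styles, orphan or history-dependent letters) carry a
`flag_reason` and are exempted from — and mechanically justified in — the
regeneration regression; they are flagged, never silently corrected.

## Numerical conventions and edge cases

Percentages are reported to 3 decimals; catalog TSVs are UTF-8,
LF-terminated, and byte-stable (write → read → write is the identity).
Catalog order is by transcript position of the event start, then event
kind, then affected length, with remaining ties broken by consequence
string; canonical intron rows sort after the events anchored at their
donor, mirroring the published layout. A zero canonical denominator marks
the percentage undefined rather than raising mid-catalog. In-frame
annotation applies to pure single-interval deletions only: in frame iff
the deleted length is divisible by 3 *and* the interval lies entirely in
the CDS.

## Known limitations

* Junction evidence cannot reconstruct full-length isoforms; events are
  reported independently even when they must co-occur on one molecule.
* Cryptic-exon pairing is ambiguous when pseudoexons share an intron (see
  above); combination artifacts are possible in the permissive mode.
* Compound (mixed) events are named by joining components, which is
  injective only up to component multiplicity; two distinct mixed events
  with identical component slots would share a name (their consequences
  still differ).
* The percentage statistic is relative to canonical junction reads and can
  exceed 100% for events that dominate their intron; the aberrant fraction
  is the bounded alternative.
* Sequence-level consequences (delins with literal nucleotides) need the
  genome sequence and are out of scope; such descriptions are rejected by
  the parser and flagged in fixtures.
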