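# splicecat

Splice-junction classification, Δ/▼ event nomenclature and aberrant-splicing
detection for single-gene deep RNA-seq.

## The problem

Clinical laboratories increasingly test whether a DNA variant damages
splicing by deep-sequencing a single gene's cDNA (long-range PCR amplicon,
~10⁵× coverage of each canonical splice junction) and reading splice
junctions off the aligner's output. Interpreting such data needs three
things: a catalog of the *naturally occurring* alternative splicing events
of the gene in control samples (so normal isoforms are not mistaken for
pathology), a systematic nomenclature for those events, and a quantitative
comparison of a variant carrier against controls that distinguishes a
complete splicing defect from leaky (hypomorphic) mis-splicing.

`splicecat` implements that workflow for one reference transcript at a
time. It consumes per-sample splice-junction count files in the STAR
`SJ.out.tab` dialect (9-column TSV: genomic intron coordinates, strand and
motif codes, unique/multi-mapping read counts, overhang) plus a transcript
exon model (simple TSV, or GTF), and ships the published STK11
(NM_000455.4) and NBN (NM_002485.4) alternative-splicing catalogs and
reconstructed exon models as packaged fixtures.

## Model and statistics

**Classification.** A junction's spliced-out region is flanked by a donor
base D and an acceptor base A. Each side is a canonical exon boundary, an
exonic position (sequence lost — a shifted splice site), or an intronic
position (sequence retained). The combination yields the event class:
canonical, (multiple) exon skipping, exonic/intronic donor or acceptor
shift, cryptic-exon (pseudoexon) inclusion — called when two junctions'
intronic ends face each other inside one intron — mixed events, and
terminal (UTR-only) modifications.

**Nomenclature.** Δ marks (partial) exon loss, ▼ intron-derived insertion;
side letters p (donor side, 3′ end of an exon) and q (acceptor side, 5′ end
of an exon); multiple events in one slot get capital letters in transcript
order (▼4A, ▼4B, …), and previously published names, letters included, can
be inherited through an established-names map. Consequences are rendered as
HGVS r. strings (`r.465_597del`, `r.290_291ins291-2149_291-2019`) where
r.1 = c.1 is the A of the start codon and intronic offsets hang off the
nearest exon boundary.

**Quantification.** An event's *junction percentage* is the ratio of means

p = 100 · mean_samples(alt reads) / mean_introns(mean_samples(canonical reads))

over the canonical introns the event's junctions replace. The
*aberrant fraction* f = 100·alt/(alt+canonical) = 100p/(100+p) expresses
the same signal as a proportion of all transcripts. Events are *real* when
covered by ≥20 reads in ≥2 samples, or previously published; everything
else is kept but flagged (`low_reads` / `single_sample`).

**Carrier grading.** A carrier event is `complete` when it consumes ≥20% of
junction reads while controls stay below half the carrier level, `leaky`
below 5%, `partial` in between, and `not_aberrant` when controls express it
at a comparable level; cutoffs are configuration and are echoed in every
report header.

## Worked example

`examples/build_stk11_catalog.py` rebuilds the STK11 control-panel catalog
from the packaged six-control junction counts:

```
STK11 (NM_000455.4): 52 alternative events in 6 samples

events above 1% of canonical junction reads:
  Δ9q    r.1109_1113del                    4.371%  exonic acceptor shift
  ▼1C    r.290_291ins291-2149_291-2019     3.717%  cryptic exon inclusion
  ▼7D    r.862_863ins863-253_863-103       1.956%  cryptic exon inclusion
  ▼7C    r.862_863ins863-283_863-103       1.382%  cryptic exon inclusion

highest-expressed in-frame deletion: Δ2–3 (r.291_464del) at 0.381% - the
event most likely to retain protein function
```

Four events exceed 1% of canonical junction reads — all four frameshift —
while the strongest event that could retain protein function is the
in-frame double-exon skip Δ2–3. `examples/detect_aberrant_splicing.py`
grades a synthetic NBN exon-5-skip carrier (30% of junction reads vs 0.8%
in controls) as a `complete` splicing defect, and
`examples/simulate_and_recover.py` shows that injected events are recovered
with correct names and fractions from simulated counts.

The same operations are available from the shell:

```sh
splicecat build-catalog --model model.tsv --sj S1.SJ.out.tab --sj S2.SJ.out.tab \
    --min-reads 20 --min-samples 2 -o catalog.tsv
splicecat compare --model model.tsv --carrier P1.SJ.out.tab \
    --control C1.SJ.out.tab --control C2.SJ.out.tab -o report.tsv
splicecat simulate --config sim.yaml --out-dir sims/ --seed 7
```

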