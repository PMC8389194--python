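"""Synthetic transcript models and junction-count samples with known event
composition, emulating deep single-gene amplicon RNA-seq.

The generator reproduces the count regime of deep amplicon junction
sequencing: canonical splice junctions covered at ~10^5 reads (the depth
targeted when cataloguing naturally occurring events) and alternative events
expressed between ~0.002% and ~11% of canonical junction reads.  Counts are
Poisson by default (amplicon deep sequencing; no dispersion estimate is
available for this assay), with a negative-binomial option for robustness
experiments.  When injected events take a large share, canonical counts are
depleted accordingly so that fractions remain interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .junctions import JunctionRecord, merge_samples, write_star_sj, JunctionMatrix
from .transcript import TranscriptModel, build_model


def make_toy_model(n_exons: int,
                   exon_lengths: int | Sequence[int],
                   intron_lengths: int | Sequence[int],
                   strand: str = "+",
                   utr5_len: int = 0,
                   utr3_len: int = 0,
                   gene: str = "TOY",
                   transcript_id: str = "TOY.1",
                   chrom: str = "chrT",
                   offset: int = 10000) -> TranscriptModel:
    """Deterministic model with the stated geometry.

    ``exon_lengths``/``intron_lengths`` may be single ints (uniform) or
    per-exon/per-intron sequences.  The CDS starts after ``utr5_len`` bases
    and ends ``utr3_len`` bases before the transcript 3' end.
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons")
    ex = ([int(exon_lengths)] * n_exons if isinstance(exon_lengths, int)
          else [int(x) for x in exon_lengths])
    iv = ([int(intron_lengths)] * (n_exons - 1) if isinstance(intron_lengths, int)
          else [int(x) for x in intron_lengths])
    if len(ex) != n_exons or len(iv) != n_exons - 1:
        raise ValueError("exon/intron length lists do not match n_exons")
    if any(x < 1 for x in ex) or any(x < 1 for x in iv):
        raise ValueError("exon and intron lengths must be >= 1")
    total = sum(ex)
    if utr5_len + utr3_len >= total:
        raise ValueError("UTRs leave no coding sequence")

    spans = []
    g = offset + 1
    for i in range(n_exons):
        spans.append((g, g + ex[i] - 1))
        g += ex[i]
        if i < n_exons - 1:
            g += iv[i]
    if strand == "-":
        # same transcript geometry laid out on the minus strand
        end = g - 1
        spans = [(offset + 1 + (end - b), offset + 1 + (end - a)) for a, b in spans]
    return build_model(gene_symbol=gene, transcript_id=transcript_id, chrom=chrom,
                       strand=strand, exons=spans,
                       cds_start=utr5_len + 1, cds_end=total - utr3_len)


# --------------------------------------------------------------------------
# Event specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """One injected alternative event.

    kind: 'exon_skip' (exons ``first..last``), 'exonic_donor_shift' /
    'exonic_acceptor_shift' (exon, shift nt into the exon), 'intronic_donor_shift'
    / 'intronic_acceptor_shift' (intron, retained nt), or 'cryptic_exon'
    (intron, a, d: pseudoexon spanning intron positions a..d).

    ``target_fraction`` is the expected read support as a percent of the
    replaced introns' canonical reads; ``presence_prob`` is the per-sample
    probability that the event is expressed at all.
    """

    kind: str
    target_fraction: float
    first: int = 0
    last: int = 0
    shift: int = 0
    intron: int = 0
    a: int = 0
    d: int = 0
    presence_prob: float = 1.0

    def __post_init__(self):
        if self.target_fraction < 0:
            raise ValueError("target_fraction must be >= 0")
        if not 0 <= self.presence_prob <= 1:
            raise ValueError("presence_prob must be in [0, 1]")


def _spec_junctions(model: TranscriptModel, spec: EventSpec) -> list[tuple[int, int]]:
    """Genomic (intron_start, intron_end) spans for an event spec."""
    def span(left_g: int, right_g: int) -> tuple[int, int]:
        lo, hi = sorted((left_g, right_g))
        return lo + 1, hi - 1

    t2g = model.transcript_to_genomic
    i2g = model.intron_pos_to_genomic
    k = spec.kind
    if k in {"exon_skip", "multi_exon_skip"}:
        first, last = spec.first, spec.last or spec.first
        donor = t2g(model.exon(first).cdna_start - 1)
        acceptor = t2g(model.exon(last).cdna_end + 1)
        return [span(donor, acceptor)]
    if k == "exonic_donor_shift":
        exon = model.exon(spec.first)
        donor = t2g(exon.cdna_end - abs(spec.shift))
        acceptor = t2g(model.acceptor_t(spec.first))
        return [span(donor, acceptor)]
    if k == "exonic_acceptor_shift":
        exon = model.exon(spec.first)
        intron = spec.first - 1
        donor = t2g(model.donor_t(intron))
        acceptor = t2g(exon.cdna_start + abs(spec.shift))
        return [span(donor, acceptor)]
    if k == "intronic_donor_shift":
        donor = i2g(spec.intron, spec.shift)
        acceptor = t2g(model.acceptor_t(spec.intron))
        return [span(donor, acceptor)]
    if k == "intronic_acceptor_shift":
        L = model.intron_length(spec.intron)
        donor = t2g(model.donor_t(spec.intron))
        acceptor = i2g(spec.intron, L - spec.shift + 1)
        return [span(donor, acceptor)]
    if k == "cryptic_exon":
        L = model.intron_length(spec.intron)
        if not 1 < spec.a < spec.d < L:
            raise ValueError("cryptic exon must lie strictly inside the intron")
        donor = t2g(model.donor_t(spec.intron))
        acceptor = t2g(model.acceptor_t(spec.intron))
        j1 = span(donor, i2g(spec.intron, spec.a))
        j2 = span(i2g(spec.intron, spec.d), acceptor)
        return [j1, j2]
    raise ValueError(f"unknown event kind {k!r}")


def replaced_introns_of_spec(model: TranscriptModel, spec: EventSpec) -> tuple[int, ...]:
    k = spec.kind
    if k in {"exon_skip", "multi_exon_skip"}:
        first, last = spec.first, spec.last or spec.first
        return tuple(range(first - 1, last + 1))
    if k == "exonic_donor_shift":
        return (spec.first,)
    if k == "exonic_acceptor_shift":
        return (spec.first - 1,)
    return (spec.intron,)


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    model: TranscriptModel
    events: tuple[EventSpec, ...] = ()
    depth: float = 100_000.0        # mean canonical junction coverage
    n_samples: int = 6
    noise: str = "poisson"          # or "negative_binomial"
    dispersion: float = 0.05        # NB: var = mu + dispersion * mu^2
    deplete_canonical: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.noise not in {"poisson", "negative_binomial"}:
            raise ValueError(f"unknown noise model {self.noise!r}")


def _draw(rng: np.random.Generator, mean: float, config: SimulationConfig) -> int:
    if mean <= 0:
        return 0
    if config.noise == "poisson":
        return int(rng.poisson(mean))
    # NB parametrized by mean and dispersion alpha: var = mu + alpha mu^2
    alpha = max(config.dispersion, 1e-12)
    n = 1.0 / alpha
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def simulate_sample(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> list[JunctionRecord]:
    """One sample's junction records: canonical junctions at the configured
    depth plus each event's junction(s).

    An event with target fraction p (% of canonical reads) takes an expected
    molecule share p/(100+p) of its replaced introns' total when canonical
    depletion is on (so alt/canonical converges to p/100), or expected count
    p/100 * depth without depletion.  Cryptic exons emit their two boundary
    junctions with one shared (fully correlated) count.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.model
    strand_code = 1 if model.strand == "+" else 2

    totals = {i: _draw(rng, config.depth, config)
              for i in range(1, model.n_introns + 1)}
    alt_counts: dict[tuple[int, int], int] = {}
    depletion = {i: 0 for i in totals}

    # depletion-consistent molecule shares: with canonical depletion on, an
    # event's expected count must equal target_fraction times the *depleted*
    # canonical mean, so shares are normalized by the total event load on the
    # replaced introns (exact when co-occurring events share the same introns,
    # approximate for events spanning introns with unequal loads)
    loads = {i: 0.0 for i in totals}
    for spec in config.events:
        for i in replaced_introns_of_spec(model, spec):
            loads[i] += spec.target_fraction

    for spec in config.events:
        if spec.presence_prob < 1.0 and rng.random() >= spec.presence_prob:
            continue
        p = spec.target_fraction
        if config.deplete_canonical:
            introns = replaced_introns_of_spec(model, spec)
            load = sum(loads[i] for i in introns) / len(introns)
            share = (p / 100.0) / (1.0 + load / 100.0)
        else:
            share = p / 100.0
        count = _draw(rng, share * config.depth, config)
        if count == 0:
            continue
        for key in _spec_junctions(model, spec):
            alt_counts[key] = alt_counts.get(key, 0) + count
        for i in replaced_introns_of_spec(model, spec):
            if config.deplete_canonical:
                depletion[i] += count

    records: list[JunctionRecord] = []
    for i in range(1, model.n_introns + 1):
        s, e = model.intron_genomic(i)
        n = max(totals[i] - depletion[i], 0)
        records.append(JunctionRecord(model.chrom, s, e, strand_code,
                                      motif_code=1, annotated_flag=1,
                                      unique_reads=n, max_overhang=50))
    for (s, e), n in sorted(alt_counts.items()):
        records.append(JunctionRecord(model.chrom, s, e, strand_code,
                                      motif_code=1, annotated_flag=0,
                                      unique_reads=n, max_overhang=50))
    return records


def simulate_cohort(config: SimulationConfig,
                    sample_names: Sequence[str] | None = None) -> JunctionMatrix:
    """n_samples independent samples under one config; all randomness flows
    from ``config.seed``, so identical configs give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    names = (list(sample_names) if sample_names
             else [f"S{i + 1}" for i in range(config.n_samples)])
    if len(names) != config.n_samples:
        raise ValueError("sample_names length must equal n_samples")
    samples = {name: simulate_sample(config, rng) for name in names}
    return merge_samples(samples)


def write_cohort(matrix: JunctionMatrix, out_dir, suffix: str = ".SJ.out.tab") -> list[str]:
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in matrix.samples:
        recs = []
        for key in matrix.keys:
            count = int(matrix.counts.loc[[key], name].iloc[0])
            if count == 0:
                continue
            base = matrix.records[key]
            recs.append(JunctionRecord(base.chrom, base.intron_start,
                                       base.intron_end, base.strand_code,
                                       base.motif_code, base.annotated_flag,
                                       count, 0, base.max_overhang))
        path = os.path.join(out_dir, f"{name}{suffix}")
        write_star_sj(recs, path)
        paths.append(path)
    return paths
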