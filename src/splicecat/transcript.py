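"""Single-transcript exon/intron model and HGVS r./c. coordinate arithmetic.

Everything downstream (junction classification, event naming, consequence
strings) leans on this module as the single coordinate authority.  The model
describes one reference transcript: ordered exons with both genomic and
spliced-transcript (cDNA) coordinates, the CDS anchors, and the strand.

Coordinate conventions
----------------------
* All stored coordinates are 1-based and inclusive, matching both HGVS and
  STAR's ``SJ.out.tab``.  Half-open conversions happen only at I/O edges.
* HGVS anchors: position 1 is the A of the ATG start codon; 5'UTR positions
  are negative (no zero), 3'UTR positions are written ``*n`` counting from
  the base after the stop codon.  The r. and c. coordinate systems coincide
  numerically, so one system is implemented and rendered with either prefix.
* Intronic positions hang off the nearest exon boundary: the 5' half of an
  intron is written ``donor+k``, the 3' half ``acceptor-k``.  The midpoint
  base of an odd-length intron goes to the ``+`` (donor) side.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, replace
from typing import Sequence


class ModelError(ValueError):
    """Raised for structurally invalid transcript models."""


class OutsideTranscriptError(ValueError):
    """A genomic position falls outside the transcript span (plus flank)."""


class CoordinateError(ValueError):
    """An HGVS position is not valid for the given model."""


# --------------------------------------------------------------------------
# HGVS positions
# --------------------------------------------------------------------------

_HGVS_RE = re.compile(r"^(?:[rc]\.)?(\*)?(-?\d+)(?:([+-])(\d+))?$")


@dataclass(frozen=True, order=False)
class HgvsPosition:
    """A cDNA/RNA position with UTR anchor and signed intronic offset.

    ``anchor`` is the coding-relative coordinate: negative for 5'UTR,
    positive for CDS, and for 3'UTR the positive ``n`` of ``*n`` together
    with ``utr3=True``.  ``intron_offset`` is 0 for exonic positions,
    positive for ``+k`` (downstream of a donor) and negative for ``-k``
    (upstream of an acceptor).
    """

    anchor: int
    utr3: bool = False
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.anchor == 0:
            raise CoordinateError("HGVS coordinates have no position 0")
        if self.utr3 and self.anchor < 0:
            raise CoordinateError("a *n anchor must be positive")

    def __str__(self) -> str:
        base = f"*{self.anchor}" if self.utr3 else str(self.anchor)
        if self.intron_offset > 0:
            return f"{base}+{self.intron_offset}"
        if self.intron_offset < 0:
            return f"{base}{self.intron_offset}"
        return base

    @classmethod
    def parse(cls, text: str) -> "HgvsPosition":
        m = _HGVS_RE.match(text.strip())
        if not m:
            raise CoordinateError(f"cannot parse HGVS position {text!r}")
        star, anchor, sign, off = m.groups()
        offset = 0
        if sign:
            offset = int(off) if sign == "+" else -int(off)
        return cls(anchor=int(anchor), utr3=bool(star), intron_offset=offset)


# --------------------------------------------------------------------------
# Exons and the model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonSpan:
    """One exon, 1-based ordinal, with cDNA and genomic spans (inclusive)."""

    index: int
    cdna_start: int
    cdna_end: int
    genomic_start: int
    genomic_end: int

    @property
    def length(self) -> int:
        return self.cdna_end - self.cdna_start + 1


@dataclass(frozen=True)
class TranscriptModel:
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[ExonSpan, ...]
    cds_start: int  # transcript-space position of the A of ATG
    cds_end: int    # transcript-space position of the last base of the stop

    # ---- derived structure ------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def tx_length(self) -> int:
        return self.exons[-1].cdna_end

    def exon(self, index: int) -> ExonSpan:
        return self.exons[index - 1]

    def donor_t(self, intron: int) -> int:
        """Transcript position of the canonical donor of intron ``intron``
        (the last base of exon ``intron``)."""
        return self.exons[intron - 1].cdna_end

    def acceptor_t(self, intron: int) -> int:
        """Transcript position of the canonical acceptor of intron ``intron``
        (the first base of exon ``intron + 1``)."""
        return self.exons[intron].cdna_start

    def intron_genomic(self, intron: int) -> tuple[int, int]:
        """Genomic (start, end), start <= end, of canonical intron ``intron``."""
        up = self.exons[intron - 1]
        down = self.exons[intron]
        if self.strand == "+":
            return up.genomic_end + 1, down.genomic_start - 1
        return down.genomic_end + 1, up.genomic_start - 1

    def intron_length(self, intron: int) -> int:
        s, e = self.intron_genomic(intron)
        return e - s + 1

    @property
    def genomic_span(self) -> tuple[int, int]:
        starts = [e.genomic_start for e in self.exons]
        ends = [e.genomic_end for e in self.exons]
        return min(starts), max(ends)

    # ---- transcript-space <-> HGVS anchor ---------------------------------

    def t_to_anchor(self, t: int) -> tuple[int, bool]:
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"transcript position {t} outside 1..{self.tx_length}")
        if t < self.cds_start:
            return t - self.cds_start, False
        if t <= self.cds_end:
            return t - self.cds_start + 1, False
        return t - self.cds_end, True

    def anchor_to_t(self, anchor: int, utr3: bool = False) -> int:
        if utr3:
            t = self.cds_end + anchor
        elif anchor > 0:
            t = self.cds_start + anchor - 1
        else:
            t = self.cds_start + anchor
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"anchor {'*' if utr3 else ''}{anchor} outside transcript")
        return t

    def hgvs_anchor(self, t: int) -> HgvsPosition:
        anchor, utr3 = self.t_to_anchor(t)
        return HgvsPosition(anchor=anchor, utr3=utr3)

    # ---- genomic <-> transcript -------------------------------------------

    def transcript_to_genomic(self, t: int) -> int:
        exon = self._exon_of_t(t)
        off = t - exon.cdna_start
        if self.strand == "+":
            return exon.genomic_start + off
        return exon.genomic_end - off

    def _exon_of_t(self, t: int):
        if not 1 <= t <= self.tx_length:
            raise CoordinateError(f"transcript position {t} outside transcript")
        idx = bisect.bisect_left([e.cdna_end for e in self.exons], t)
        return self.exons[idx]

    def locate_genomic(self, gpos: int, flank: int = 0):
        """Place a genomic base: ``("exon", exon_index, t)`` or
        ``("intron", intron_index, p)`` with ``p`` the 1-based position in
        the intron counted in transcript orientation."""
        lo, hi = self.genomic_span
        if not (lo - flank) <= gpos <= (hi + flank):
            raise OutsideTranscriptError(
                f"{self.chrom}:{gpos} outside {self.gene_symbol} span {lo}-{hi} (+/-{flank})")
        if gpos < lo or gpos > hi:
            # inside the declared flank: treat as an extension of the
            # terminal exon so UTR-flank arithmetic stays well-defined
            raise OutsideTranscriptError(
                f"{self.chrom}:{gpos} in flank but not addressable in transcript space")
        for i, exon in enumerate(self.exons, start=1):
            if exon.genomic_start <= gpos <= exon.genomic_end:
                if self.strand == "+":
                    t = exon.cdna_start + (gpos - exon.genomic_start)
                else:
                    t = exon.cdna_start + (exon.genomic_end - gpos)
                return ("exon", i, t)
        for i in range(1, self.n_introns + 1):
            s, e = self.intron_genomic(i)
            if s <= gpos <= e:
                p = (gpos - s + 1) if self.strand == "+" else (e - gpos + 1)
                return ("intron", i, p)
        raise OutsideTranscriptError(f"{self.chrom}:{gpos} not inside any exon or intron")

    def intron_pos_to_genomic(self, intron: int, p: int) -> int:
        L = self.intron_length(intron)
        if not 1 <= p <= L:
            raise CoordinateError(f"intron {intron} position {p} outside 1..{L}")
        s, e = self.intron_genomic(intron)
        return (s + p - 1) if self.strand == "+" else (e - p + 1)

    def intron_pos_hgvs(self, intron: int, p: int) -> HgvsPosition:
        """HGVS rendering of intron base ``p`` (1..L, transcript orientation):
        5' half anchors to the donor as ``+k``, 3' half to the acceptor as
        ``-k``; an odd-length intron's midpoint goes to the donor side."""
        L = self.intron_length(intron)
        if not 1 <= p <= L:
            raise CoordinateError(f"intron {intron} position {p} outside 1..{L}")
        if p <= (L + 1) // 2:
            base = self.hgvs_anchor(self.donor_t(intron))
            return replace(base, intron_offset=p)
        base = self.hgvs_anchor(self.acceptor_t(intron))
        return replace(base, intron_offset=-(L - p + 1))

    # ---- the two public conversion operations ------------------------------

    def genomic_to_hgvs(self, gpos: int, flank: int = 0) -> HgvsPosition:
        kind, idx, pos = self.locate_genomic(gpos, flank=flank)
        if kind == "exon":
            return self.hgvs_anchor(pos)
        return self.intron_pos_hgvs(idx, pos)

    def hgvs_to_genomic(self, pos: HgvsPosition | str) -> int:
        if isinstance(pos, str):
            pos = HgvsPosition.parse(pos)
        t = self.anchor_to_t(pos.anchor, pos.utr3)
        if pos.intron_offset == 0:
            return self.transcript_to_genomic(t)
        if pos.intron_offset > 0:
            intron = self._intron_after_donor(t)
            p = pos.intron_offset
        else:
            intron = self._intron_before_acceptor(t)
            p = self.intron_length(intron) + pos.intron_offset + 1
        if not 1 <= p <= self.intron_length(intron):
            raise CoordinateError(
                f"offset {pos.intron_offset} exceeds intron {intron} length "
                f"{self.intron_length(intron)}")
        return self.intron_pos_to_genomic(intron, p)

    def _intron_after_donor(self, t: int) -> int:
        for i in range(1, self.n_introns + 1):
            if self.donor_t(i) == t:
                return i
        raise CoordinateError(f"position {t} is not an exon 3' boundary (donor)")

    def _intron_before_acceptor(self, t: int) -> int:
        for i in range(1, self.n_introns + 1):
            if self.acceptor_t(i) == t:
                return i
        raise CoordinateError(f"position {t} is not an exon 5' boundary (acceptor)")

    # ---- reading frame ------------------------------------------------------

    def deletion_frame(self, first: HgvsPosition | str, last: HgvsPosition | str) -> dict:
        """Length and frame of an exonic deletion ``first..last``.

        ``in_frame`` requires a length divisible by 3 *and* that the deleted
        interval lies entirely inside the coding region; deletions touching
        either UTR cannot preserve the reading frame of the protein.
        """
        if isinstance(first, str):
            first = HgvsPosition.parse(first)
        if isinstance(last, str):
            last = HgvsPosition.parse(last)
        if first.intron_offset or last.intron_offset:
            raise CoordinateError("deletion_frame requires exonic positions; "
                                  "use the event-level description for intronic spans")
        t1 = self.anchor_to_t(first.anchor, first.utr3)
        t2 = self.anchor_to_t(last.anchor, last.utr3)
        if t1 > t2:
            raise CoordinateError("first deleted position must not follow the last")
        length = t2 - t1 + 1
        coding = self.cds_start <= t1 and t2 <= self.cds_end
        return {"in_frame": bool(coding and length % 3 == 0), "deleted_length": length}


# --------------------------------------------------------------------------
# Model construction
# --------------------------------------------------------------------------

def build_model(
    gene_symbol: str,
    transcript_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    cds_start: int | None = None,
    cds_end: int | None = None,
    cds_genomic: tuple[int, int] | None = None,
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel` from genomic exon spans.

    ``exons`` are (genomic_start, genomic_end) pairs, start <= end regardless
    of strand.  Transcript-space coordinates are assigned 5'->3' in transcript
    orientation: on the "-" strand, exon 1 is the genomically last span.
    The CDS may be given in transcript space (``cds_start``/``cds_end``) or as
    genomic coordinates of the first and last coding base (``cds_genomic``).
    """
    if strand not in {"+", "-"}:
        raise ModelError(f"strand must be '+' or '-', got {strand!r}")
    if len(exons) < 2:
        raise ModelError("a model needs at least 2 exons (no introns to analyze)")
    spans = sorted((int(s), int(e)) for s, e in exons)
    for s, e in spans:
        if s > e:
            raise ModelError(f"exon span {s}-{e} reversed")
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ModelError(f"exon spans {s1}-{e1} and {s2}-{e2} overlap or touch")
    if strand == "-":
        spans = spans[::-1]

    built: list[ExonSpan] = []
    t = 0
    for i, (s, e) in enumerate(spans, start=1):
        length = e - s + 1
        built.append(ExonSpan(index=i, cdna_start=t + 1, cdna_end=t + length,
                              genomic_start=s, genomic_end=e))
        t += length
    total = t

    model = TranscriptModel(gene_symbol=gene_symbol, transcript_id=transcript_id,
                            chrom=chrom, strand=strand, exons=tuple(built),
                            cds_start=1, cds_end=total)
    if cds_genomic is not None:
        locs = []
        for g in cds_genomic:
            kind, _, tt = model.locate_genomic(g)
            if kind != "exon":
                raise ModelError(f"CDS coordinate {g} falls outside exons")
            locs.append(tt)
        cds_start, cds_end = min(locs), max(locs)
    if cds_start is None or cds_end is None:
        raise ModelError("CDS coordinates are required (transcript-space or genomic)")
    if not (1 <= cds_start < cds_end <= total):
        raise ModelError(f"CDS {cds_start}..{cds_end} outside transcript 1..{total}")
    model = replace(model, cds_start=int(cds_start), cds_end=int(cds_end))
    validate_model(model)
    return model


def validate_model(model: TranscriptModel) -> None:
    if model.n_exons < 2:
        raise ModelError("at least 2 exons required")
    prev = None
    for exon in model.exons:
        if exon.cdna_end - exon.cdna_start != exon.genomic_end - exon.genomic_start:
            raise ModelError(f"exon {exon.index}: cDNA/genomic length mismatch")
        if prev is not None and exon.cdna_start != prev.cdna_end + 1:
            raise ModelError(f"exon {exon.index}: cDNA span not contiguous")
        prev = exon
    for i in range(1, model.n_introns + 1):
        if model.intron_length(i) < 1:
            raise ModelError(f"intron {i} has non-positive length")
    if not (1 <= model.cds_start < model.cds_end <= model.tx_length):
        raise ModelError("CDS outside transcript")


# --------------------------------------------------------------------------
# Model I/O (TSV reference dialect, GTF alternative)
# --------------------------------------------------------------------------

def read_model_tsv(path) -> TranscriptModel:
    """Read the reference 5-column TSV dialect.

    Header lines: ``#gene``, ``#transcript``, ``#chrom``, ``#strand``,
    ``#cds_start``, ``#cds_end`` (transcript-space), then one
    ``exon_index<TAB>genomic_start<TAB>genomic_end`` row per exon.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ModelError(f"bad exon row {line!r}")
            rows.append((int(parts[0]), int(parts[1]), int(parts[2])))
    for key in ("gene", "transcript", "chrom", "strand", "cds_start", "cds_end"):
        if key not in meta:
            raise ModelError(f"model TSV missing #{key} header")
    rows.sort()
    return build_model(
        gene_symbol=meta["gene"], transcript_id=meta["transcript"],
        chrom=meta["chrom"], strand=meta["strand"],
        exons=[(s, e) for _, s, e in rows],
        cds_start=int(meta["cds_start"]), cds_end=int(meta["cds_end"]),
    )


def write_model_tsv(model: TranscriptModel, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#gene\t{model.gene_symbol}\n")
        fh.write(f"#transcript\t{model.transcript_id}\n")
        fh.write(f"#chrom\t{model.chrom}\n")
        fh.write(f"#strand\t{model.strand}\n")
        fh.write(f"#cds_start\t{model.cds_start}\n")
        fh.write(f"#cds_end\t{model.cds_end}\n")
        for e in sorted(model.exons, key=lambda e: e.index):
            fh.write(f"{e.index}\t{e.genomic_start}\t{e.genomic_end}\n")


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_model_gtf(path, transcript_id: str | None = None) -> TranscriptModel:
    """Read a transcript from GTF ``exon`` and ``CDS`` features.

    If ``transcript_id`` is None the file must contain exactly one transcript.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in {"exon", "CDS"}:
                continue
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            tid = attr.get("transcript_id", "")
            gene = attr.get("gene_name", attr.get("gene_id", ""))
            info[tid] = (gene, chrom, strand)
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((int(start), int(end)))
    if transcript_id is None:
        if len(exons) != 1:
            raise ModelError(f"GTF contains {len(exons)} transcripts; pass transcript_id")
        transcript_id = next(iter(exons))
    if transcript_id not in exons:
        raise ModelError(f"transcript {transcript_id!r} not in GTF")
    if transcript_id not in cds:
        raise ModelError(f"no CDS features for {transcript_id!r}")
    gene, chrom, strand = info[transcript_id]
    cds_spans = sorted(cds[transcript_id])
    g1, g2 = cds_spans[0][0], cds_spans[-1][1]
    return build_model(gene_symbol=gene, transcript_id=transcript_id, chrom=chrom,
                       strand=strand, exons=exons[transcript_id], cds_genomic=(g1, g2))
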