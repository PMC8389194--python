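"""Reading and writing splice-junction count files (STAR ``SJ.out.tab``
dialect), multi-sample junction matrices, and catalog TSVs.

The nine ``SJ.out.tab`` columns are: chrom, first intronic base, last
intronic base (1-based, inclusive), strand code (0 undefined / 1 plus /
2 minus), intron motif code (0-6), annotated flag, uniquely-mapping read
count, multi-mapping read count, maximum spliced overhang.  Only the
unique-read count feeds downstream quantification by default; multi-mapped
reads are carried but ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class SJFormatError(ValueError):
    """Raised for malformed SJ.out.tab content."""


JunctionKey = tuple[str, int, int, int]  # (chrom, intron_start, intron_end, strand_code)


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction as reported by the aligner.

    ``intron_start``/``intron_end`` are the first and last *intronic* bases
    spliced out by the junction, 1-based inclusive, on genomic coordinates.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand_code: int = 0
    motif_code: int = 0
    annotated_flag: int = 0
    unique_reads: int = 0
    multimapped_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise SJFormatError(
                f"intron start {self.intron_start} > end {self.intron_end}")
        if self.unique_reads < 0 or self.multimapped_reads < 0:
            raise SJFormatError("negative read counts")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end, self.strand_code)

    @property
    def intron_length(self) -> int:
        return self.intron_end - self.intron_start + 1


def read_star_sj(path, drop_unsupported: bool = True) -> list[JunctionRecord]:
    """Parse an ``SJ.out.tab`` file (sometimes named ``OutSJ.tab``; any
    filename is accepted).  Lines with zero unique and zero multi-mapped
    reads carry no evidence and are dropped unless ``drop_unsupported`` is
    False.  Line order is preserved."""
    records: list[JunctionRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise SJFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(parts)}")
            try:
                rec = JunctionRecord(
                    chrom=parts[0],
                    intron_start=int(parts[1]),
                    intron_end=int(parts[2]),
                    strand_code=int(parts[3]),
                    motif_code=int(parts[4]),
                    annotated_flag=int(parts[5]),
                    unique_reads=int(parts[6]),
                    multimapped_reads=int(parts[7]),
                    max_overhang=int(parts[8]),
                )
            except ValueError as exc:
                raise SJFormatError(f"{path}:{lineno}: {exc}") from exc
            if drop_unsupported and rec.unique_reads == 0 and rec.multimapped_reads == 0:
                continue
            records.append(rec)
    return records


def write_star_sj(records: Iterable[JunctionRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write("\t".join(str(v) for v in (
                r.chrom, r.intron_start, r.intron_end, r.strand_code,
                r.motif_code, r.annotated_flag, r.unique_reads,
                r.multimapped_reads, r.max_overhang)) + "\n")


# --------------------------------------------------------------------------
# Multi-sample matrix
# --------------------------------------------------------------------------

@dataclass
class JunctionMatrix:
    """Unique-read counts per junction key per sample (absent = 0)."""

    counts: pd.DataFrame           # index: JunctionKey tuples; columns: samples
    records: dict[JunctionKey, JunctionRecord]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def keys(self) -> list[JunctionKey]:
        return list(self.counts.index)

    def sample_counts(self, key: JunctionKey) -> dict[str, int]:
        row = self.counts.loc[[key]].iloc[0]
        return {s: int(v) for s, v in row.items()}

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def merge_samples(
    samples: Mapping[str, Sequence[JunctionRecord]]
    | Sequence[tuple[str, Sequence[JunctionRecord]]],
    provenance: Mapping[str, str] | None = None,
) -> JunctionMatrix:
    """Union of junction keys across samples; missing entries are zero.
    Duplicate records for the same key within a sample are summed."""
    if isinstance(samples, Mapping):
        items = list(samples.items())
    else:
        items = list(samples)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample names")
    if not items:
        raise ValueError("at least one sample required")

    exemplar: dict[JunctionKey, JunctionRecord] = {}
    data: dict[str, dict[JunctionKey, int]] = {}
    for name, records in items:
        col: dict[JunctionKey, int] = {}
        for rec in records:
            col[rec.key] = col.get(rec.key, 0) + rec.unique_reads
            if rec.key not in exemplar:
                exemplar[rec.key] = rec
        data[name] = col
    keys = sorted(exemplar)
    frame = pd.DataFrame(
        {name: [data[name].get(k, 0) for k in keys] for name in names},
        index=pd.Index(keys, tupleize_cols=False), dtype="int64")
    return JunctionMatrix(counts=frame, records=exemplar,
                          provenance=dict(provenance or {}))


def matrix_from_files(paths: Mapping[str, str]) -> JunctionMatrix:
    """Convenience: {sample_name: path} -> JunctionMatrix."""
    recs = {name: read_star_sj(p) for name, p in paths.items()}
    return merge_samples(recs, provenance={n: str(p) for n, p in paths.items()})


# --------------------------------------------------------------------------
# Whitelist of previously published junctions
# --------------------------------------------------------------------------

def read_whitelist(path) -> dict[tuple[str, int, int], str]:
    """Whitelist TSV: chrom, intron_start, intron_end, source label.
    Returns {(chrom, start, end): label}; header lines starting '#' skipped."""
    out: dict[tuple[str, int, int], str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SJFormatError(f"whitelist row needs >=3 columns: {line!r}")
            label = parts[3] if len(parts) > 3 else ""
            out[(parts[0], int(parts[1]), int(parts[2]))] = label
    return out


def write_whitelist(entries: Mapping[tuple[str, int, int], str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#chrom\tintron_start\tintron_end\tlabel\n")
        for (chrom, s, e), label in sorted(entries.items()):
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


# --------------------------------------------------------------------------
# Catalog TSV
# --------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "rna_consequence",
    "junction_description",
    "mean_reads",
    "mean_percentage",
    "biotype",
    "pct_samples",
    "previously_published",
    "kind",
    "chrom",
    "junction_coords",
    "passes_threshold",
    "fail_reason",
    "in_frame",
]


def _event_row(event) -> list[str]:
    # canonical rows mirror the published table style: the consequence cell
    # holds "intron N junction" and description/percentage cells hold "/"
    if event.kind == "canonical":
        consequence = f"intron {event.introns_replaced[0]} junction"
        name = "/"
        pct = "/"
    else:
        consequence = event.rna_consequence
        name = event.name
        pct = ("%.3f" % event.mean_percentage) if event.mean_percentage is not None else "NA"
    coords = ";".join(
        f"{j.intron_start}-{j.intron_end}" for j in event.junctions)
    return [
        consequence,
        name,
        str(int(round(event.mean_reads))),
        pct,
        event.biotype,
        str(int(round(event.samples_detected_fraction))),
        "yes" if event.previously_published else "no",
        event.kind,
        event.junctions[0].chrom if event.junctions else "",
        coords,
        "yes" if event.passes_threshold else "no",
        event.fail_reason or "",
        "" if event.in_frame is None else ("yes" if event.in_frame else "no"),
    ]


def write_catalog_tsv(catalog, path) -> None:
    """Write a catalog (list of SpliceEvent, a Catalog, or a DataFrame read
    back by :func:`read_catalog_tsv`) as a UTF-8, LF-terminated TSV."""
    if isinstance(catalog, pd.DataFrame):
        rows = catalog[CATALOG_COLUMNS].astype(str).values.tolist()
    else:
        events = getattr(catalog, "events", catalog)
        rows = [_event_row(ev) for ev in events]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_catalog_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SJFormatError(f"catalog TSV missing columns {missing}")
    return df
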