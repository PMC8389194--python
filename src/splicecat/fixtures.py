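"""Packaged reference fixtures: the published STK11 and NBN alternative
splicing catalogs (one row per table row, verbatim) and the transcript
models reconstructed from them.

The exon boundaries of both models are read off the catalogs' r. coordinates
(e.g. STK11 exon 4 = r.465..597 from the exon-4 skip ``r.465_597del``);
genomic coordinates are synthesized on fake contigs since no genomic spans
are published with the catalogs — classification only depends on the
exon/intron geometry, not on real chromosome offsets.  Intron lengths are
chosen large enough that every published intronic offset renders on its
printed side of the intron.  The NBN exon 10/11 boundary is inferred solely
from the Δ11q acceptor-shift rows and is marked approximate; nothing
downstream depends on it.

Catalog fixture columns include a ``flag_reason`` maintained with the
package: rows whose printed name and coordinates are mutually inconsistent
(anchor typos, duplicate names, sequence-level descriptions, letters that
continue earlier publications' series rather than positional assignment)
are flagged rather than silently corrected.
"""

from __future__ import annotations

import importlib.resources as resources
from functools import lru_cache

import pandas as pd

from .events import junction_records_from_consequence
from .transcript import CoordinateError, TranscriptModel, read_model_tsv

FIXTURES = ("stk11_table1", "nbn_table2", "stk11_model", "nbn_model")

_TABLE_FOR_MODEL = {"stk11_table1": "stk11_model", "nbn_table2": "nbn_model"}

TABLE_COLUMNS = ["rna_consequence", "name", "mean_reads", "mean_percentage",
                 "biotype", "pct_samples", "previously_published", "marker",
                 "flag_reason"]


def _data_path(filename: str):
    return resources.files("splicecat.data").joinpath(filename)


@lru_cache(maxsize=None)
def load_fixture(name: str):
    """Load a packaged fixture: ``stk11_model``/``nbn_model`` return a
    :class:`TranscriptModel`; ``stk11_table1``/``nbn_table2`` return a
    DataFrame with one row per published catalog row."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    if name.endswith("_model"):
        with resources.as_file(_data_path(f"{name}.tsv")) as p:
            return read_model_tsv(p)
    with resources.as_file(_data_path(f"{name}.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    df["mean_reads"] = df["mean_reads"].astype(int)
    df["pct_samples"] = df["pct_samples"].astype(int)
    return df


def model_for_table(table_name: str) -> TranscriptModel:
    return load_fixture(_TABLE_FOR_MODEL[table_name])


def is_canonical_row(row) -> bool:
    return str(row["rna_consequence"]).startswith("intron ")


def alternative_rows(table: pd.DataFrame, unflagged_only: bool = False) -> pd.DataFrame:
    alt = table[~table["rna_consequence"].str.startswith("intron ")]
    if unflagged_only:
        alt = alt[alt["flag_reason"] == ""]
    return alt


def canonical_means(table: pd.DataFrame) -> dict[int, int]:
    """Printed mean canonical junction reads, by intron ordinal."""
    out: dict[int, int] = {}
    for _, row in table.iterrows():
        if is_canonical_row(row):
            intron = int(str(row["rna_consequence"]).split()[1])
            out[intron] = int(row["mean_reads"])
    return out


def published_established_names(table_name: str) -> dict[str, str]:
    """Previously published events' {consequence: name}, for carrying their
    nomenclature (including series letters) into regenerated catalogs."""
    table = load_fixture(table_name)
    out: dict[str, str] = {}
    for _, row in alternative_rows(table, unflagged_only=True).iterrows():
        if str(row["previously_published"]).strip().lower() == "yes":
            out[str(row["rna_consequence"])] = str(row["name"])
    return out


def published_whitelist(table_name: str) -> frozenset:
    """(chrom, intron_start, intron_end) keys of previously published
    junctions, the threshold whitelist of the published protocol."""
    model = model_for_table(table_name)
    table = load_fixture(table_name)
    keys = set()
    for _, row in alternative_rows(table, unflagged_only=True).iterrows():
        if str(row["previously_published"]).strip().lower() != "yes":
            continue
        try:
            recs = junction_records_from_consequence(model, str(row["rna_consequence"]))
        except CoordinateError:
            continue
        for r in recs:
            keys.add((r.chrom, r.intron_start, r.intron_end))
    return frozenset(keys)


def fixture_sample_records(table_name: str, n_samples: int = 6):
    """Reconstruct per-sample junction records from a published catalog:
    each event's printed mean read count is replicated into the first
    k = round(pct_samples/100 * n) samples and absent from the rest, the
    reading of the tables' 'average over detected samples' column that
    matches their one-sample footnotes.  Canonical junction rows are present
    in every sample.  Returns {sample_name: [JunctionRecord, ...]}."""
    model = model_for_table(table_name)
    table = load_fixture(table_name)
    names = [f"C{i + 1}" for i in range(n_samples)]
    per_sample: dict[str, dict] = {s: {} for s in names}

    def add(records, sample_idx, reads):
        for rec in records:
            key = (rec.intron_start, rec.intron_end)
            store = per_sample[names[sample_idx]]
            store[key] = store.get(key, 0) + reads

    for _, row in table.iterrows():
        reads = int(row["mean_reads"])
        if is_canonical_row(row):
            intron = int(str(row["rna_consequence"]).split()[1])
            s, e = model.intron_genomic(intron)
            from .junctions import JunctionRecord
            recs = [JunctionRecord(model.chrom, s, e,
                                   1 if model.strand == "+" else 2,
                                   annotated_flag=1, unique_reads=reads)]
            k = n_samples
        else:
            if row["flag_reason"] != "":
                continue
            try:
                recs = junction_records_from_consequence(
                    model, str(row["rna_consequence"]), reads=reads)
            except CoordinateError:
                continue
            k = round(int(row["pct_samples"]) / 100 * n_samples)
        for idx in range(k):
            add(recs, idx, reads)

    from .junctions import JunctionRecord
    strand_code = 1 if model.strand == "+" else 2
    out = {}
    for s in names:
        out[s] = [JunctionRecord(model.chrom, a, b, strand_code, unique_reads=c)
                  for (a, b), c in sorted(per_sample[s].items())]
    return out
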