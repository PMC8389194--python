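"""Carrier-versus-controls comparison: flag aberrant splicing events and
grade them as complete / partial / leaky.

Two complementary statistics are reported side by side for every event:

* ``junction_percentage`` p: alternative reads as a percentage of canonical
  junction reads (alt / canonical);
* ``aberrant_fraction`` f: the aberrant-versus-normal proportion,
  f = 100 * alt / (alt + canonical), i.e. f = 100 p / (100 + p).

The impact-class cutoffs are configuration, not science: published carrier
calls grade ~30% of junction reads (with no wild-type reads at the variant
base) as a complete splicing defect and ~0.9-1.1% as minor leaky splicing,
without defining boundaries.  Defaults reproduce those calls and are echoed
in the report header so a reader always sees them.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from .events import (SpliceEvent, ThresholdPolicy, build_catalog,
                     junction_percentage)
from .junctions import JunctionMatrix, JunctionRecord, merge_samples
from .transcript import TranscriptModel


@dataclass(frozen=True)
class GradingConfig:
    """Cutoffs for grading carrier events (percent of canonical reads)."""

    complete_cutoff: float = 20.0   # >= this and effectively absent in controls
    leaky_cutoff: float = 5.0       # < this and effectively absent in controls
    control_ratio: float = 0.5      # controls at >= this fraction of the carrier
                                    # level make the event not aberrant
    carrier_min_reads: int = 20     # carrier-side read floor


@dataclass
class AberranceCall:
    event: SpliceEvent
    carrier_percentage: float
    carrier_fraction: float
    control_mean_percentage: float
    control_max_percentage: float
    novel_in_carrier: bool
    impact_class: str               # complete | partial | leaky | not_aberrant
    notes: str = ""                 # free-text evidence slot (e.g. allele-level
                                    # read inspection done outside this tool)


def aberrant_fraction(alt_reads, canonical_reads) -> float:
    """Aberrant-vs-normal proportion: 100 * alt / (alt + mean canonical of the
    replaced introns).  Distinct from junction_percentage (alt / canonical)."""
    alt = _as_mean(alt_reads)
    canon = [_as_mean(c) for c in canonical_reads]
    if not canon:
        raise ValueError("at least one replaced canonical intron required")
    denom = alt + statistics.fmean(canon)
    if denom == 0:
        raise ZeroDivisionError("no reads at all: fraction undefined")
    return 100.0 * alt / denom


def _as_mean(x) -> float:
    if isinstance(x, (int, float)):
        return float(x)
    seq = list(x)
    if not seq:
        raise ValueError("empty count sequence")
    return statistics.fmean(seq)


def compare_carrier_controls(
    model: TranscriptModel,
    carrier: Sequence[JunctionRecord] | JunctionMatrix,
    controls: JunctionMatrix,
    policy: ThresholdPolicy | None = None,
    grading: GradingConfig | None = None,
    carrier_name: str = "carrier",
) -> list[AberranceCall]:
    """Compare one carrier sample's events against a control panel.

    Carrier percentages are computed on carrier counts alone; an event is
    ``novel_in_carrier`` when it stays below the read threshold in the
    controls.  Control expression uses the maximum across controls (not the
    mean) for the aberrance test, to be conservative against single-control
    outliers.  Calls are sorted by carrier percentage, descending.
    """
    policy = policy or ThresholdPolicy()
    grading = grading or GradingConfig()

    if isinstance(carrier, JunctionMatrix):
        carrier_matrix = carrier
    else:
        carrier_matrix = merge_samples({carrier_name: list(carrier)})
    if carrier_matrix.records and controls.records:
        c_chrom = next(iter(carrier_matrix.records.values())).chrom
        k_chrom = next(iter(controls.records.values())).chrom
        if c_chrom != k_chrom or c_chrom != model.chrom:
            raise ValueError("carrier, controls and model must share a chromosome")
    if not controls.samples:
        raise ValueError("at least one control sample required")

    carrier_cat = build_catalog(model, carrier_matrix, policy=policy)
    control_cat = build_catalog(model, controls, policy=policy)

    control_by_consequence = {e.rna_consequence: e
                              for e in control_cat.alternative_events()}
    control_canon = {i: [e.reads_per_sample.get(s, 0) for s in controls.samples]
                     for i, e in control_cat.canonical_events().items()}
    carrier_canon = {i: list(e.reads_per_sample.values())
                     for i, e in carrier_cat.canonical_events().items()}

    calls: list[AberranceCall] = []
    for ev in carrier_cat.alternative_events():
        carrier_reads = sum(ev.reads_per_sample.values())
        if carrier_reads < grading.carrier_min_reads:
            continue
        introns = ev.introns_replaced or tuple(range(1, model.n_introns + 1))
        try:
            pct = junction_percentage(carrier_reads,
                                      [carrier_canon[i] for i in introns])
            frac = aberrant_fraction(carrier_reads,
                                     [carrier_canon[i] for i in introns])
        except ZeroDivisionError:
            continue

        ctrl = control_by_consequence.get(ev.rna_consequence)
        per_control = _per_sample_percentages(ctrl, control_canon,
                                              controls.samples, introns)
        ctrl_mean = statistics.fmean(per_control) if per_control else 0.0
        ctrl_max = max(per_control) if per_control else 0.0
        qualifying = 0
        if ctrl is not None:
            qualifying = sum(1 for c in ctrl.reads_per_sample.values()
                             if c >= policy.min_reads)
        novel = qualifying < policy.min_samples

        if ctrl_max >= grading.control_ratio * pct:
            impact = "not_aberrant"
        elif pct >= grading.complete_cutoff:
            impact = "complete"
        elif pct < grading.leaky_cutoff:
            impact = "leaky"
        else:
            impact = "partial"

        calls.append(AberranceCall(
            event=ev, carrier_percentage=pct, carrier_fraction=frac,
            control_mean_percentage=ctrl_mean, control_max_percentage=ctrl_max,
            novel_in_carrier=novel, impact_class=impact))

    calls.sort(key=lambda c: (-c.carrier_percentage, c.event.rna_consequence))
    return calls


def _per_sample_percentages(event, control_canon, samples, introns):
    if event is None:
        return []
    out = []
    for s in samples:
        alt = event.reads_per_sample.get(s, 0)
        canon = [control_canon[i][samples.index(s)] for i in introns
                 if i in control_canon]
        denom = statistics.fmean([c for c in canon]) if canon else 0.0
        if denom > 0:
            out.append(100.0 * alt / denom)
    return out


REPORT_COLUMNS = ["name", "rna_consequence", "carrier_percentage",
                  "carrier_fraction", "control_mean_percentage",
                  "control_max_percentage", "novel_in_carrier", "impact_class",
                  "notes"]


def render_report(calls: Sequence[AberranceCall],
                  grading: GradingConfig | None = None,
                  path=None) -> str:
    """Per-event text/TSV report, sorted by carrier percentage descending.
    The header echoes the grading cutoffs so calls are interpretable."""
    grading = grading or GradingConfig()
    lines = [
        f"# complete_cutoff={grading.complete_cutoff:g}"
        f"\tleaky_cutoff={grading.leaky_cutoff:g}"
        f"\tcontrol_ratio={grading.control_ratio:g}"
        f"\tcarrier_min_reads={grading.carrier_min_reads}",
        "\t".join(REPORT_COLUMNS),
    ]
    ordered = sorted(calls, key=lambda c: (-c.carrier_percentage,
                                           c.event.rna_consequence))
    for c in ordered:
        lines.append("\t".join([
            c.event.name,
            c.event.rna_consequence,
            "%.3f" % c.carrier_percentage,
            "%.3f" % c.carrier_fraction,
            "%.3f" % c.control_mean_percentage,
            "%.3f" % c.control_max_percentage,
            "yes" if c.novel_in_carrier else "no",
            c.impact_class,
            c.notes,
        ]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    return text
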