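"""Junction-arc summary plot: exons as boxes on the transcript axis, arcs
for alternative events scaled by read support."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle
from matplotlib.path import Path
from matplotlib.patches import PathPatch

from .events import Catalog


def plot_junction_arcs(catalog: Catalog, path, max_events: int = 30) -> None:
    """Draw the transcript with arcs for the highest-expressed alternative
    events; arc height scales with log10 of mean supporting reads."""
    model = catalog.model
    events = [e for e in catalog.alternative_events() if e.mean_reads > 0]
    events.sort(key=lambda e: -e.mean_reads)
    events = events[:max_events]

    fig, ax = plt.subplots(figsize=(10, 4))
    for exon in model.exons:
        ax.add_patch(Rectangle((exon.cdna_start, -0.4),
                               exon.length, 0.8,
                               facecolor="#4878a8", edgecolor="none"))
        ax.text((exon.cdna_start + exon.cdna_end) / 2, 0, str(exon.index),
                ha="center", va="center", fontsize=7, color="white")
    ax.plot([1, model.tx_length], [0, 0], color="#4878a8", lw=1, zorder=0)

    for ev in events:
        x1, _ = ev.start_key(model)
        x2 = x1 + max(ev.affected_length(), 1)
        h = 0.4 + 0.35 * math.log10(max(ev.mean_reads, 1))
        mid = (x1 + x2) / 2
        verts = [(x1, 0.4), (mid, 0.4 + h), (x2, 0.4)]
        codes = [Path.MOVETO, Path.CURVE3, Path.CURVE3]
        ax.add_patch(PathPatch(Path(verts, codes), fill=False,
                               edgecolor="#c44e52", lw=0.8))
        ax.text(mid, 0.45 + h, ev.name, ha="center", va="bottom", fontsize=6)

    ax.set_xlim(0, model.tx_length + 1)
    ax.set_ylim(-1, 3.5)
    ax.set_yticks([])
    ax.set_xlabel(f"{model.gene_symbol} ({model.transcript_id}) transcript position")
    ax.spines[["left", "top", "right"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
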