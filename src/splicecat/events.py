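"""Splice-event classification, Δ/▼/p/q nomenclature, HGVS r. consequences,
junction-read quantification, and catalog assembly.

An observed junction is interpreted against the reference transcript by the
two bases flanking its spliced-out region: the donor side D (last retained
base before the gap) and the acceptor side A (first retained base after it).
Each side is either a canonical exon boundary, an exonic position (sequence
lost, a "shifted" splice site inside the exon) or an intronic position
(sequence retained).  The combination determines the event class:

* both canonical, same intron            -> canonical junction
* canonical donor + later canonical acc. -> (multiple) exon skipping
* one canonical, other exonic            -> exonic donor/acceptor shift
* one canonical, other intronic          -> intronic shift (partial intron
                                            retention, written ▼)
* two junctions whose intronic ends face each other inside one intron
                                         -> cryptic exon (pseudoexon) inclusion
* anything else                          -> mixed event
* deletions confined to UTR sequence     -> terminal modification

Naming follows the published tables' convention: Δ for (partial) exon loss,
▼ for intron-derived insertions, with side letters p (donor-side / 3' end of
an exon) and q (acceptor-side / 5' end of an exon); multiple events in the
same slot are distinguished by capital letters A, B, C... in transcript
order.  The methods text of the source nomenclature swaps the meaning of
p/q relative to its own tables; the tables win here, and ``pq_invert=True``
restores the text's reading.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .junctions import JunctionMatrix, JunctionRecord, JunctionKey
from .transcript import (CoordinateError, HgvsPosition, OutsideTranscriptError,
                         TranscriptModel)


class ClassificationError(ValueError):
    """A junction cannot be interpreted on the model (e.g. reversed ends)."""


KINDS = (
    "canonical", "exon_skip", "multi_exon_skip",
    "exonic_donor_shift", "intronic_donor_shift",
    "exonic_acceptor_shift", "intronic_acceptor_shift",
    "cryptic_exon_inclusion", "mixed", "terminal_modification",
)

BIOTYPES = {
    "canonical": "canonical junction",
    "exon_skip": "exon skipping",
    "multi_exon_skip": "multiple exon skipping",
    "exonic_donor_shift": "exonic donor shift",
    "intronic_donor_shift": "intronic donor shift",
    "exonic_acceptor_shift": "exonic acceptor shift",
    "intronic_acceptor_shift": "intronic acceptor shift",
    "cryptic_exon_inclusion": "cryptic exon inclusion",
    "mixed": "mixed",
    "terminal_modification": "terminal modification",
}

_KIND_RANK = {k: i for i, k in enumerate(KINDS)}

EN_DASH = "–"
DELTA = "Δ"
NABLA = "▼"   # the tables' intron-insertion triangle
PRIME = "′"


# --------------------------------------------------------------------------
# Components: the naming units of an event
# --------------------------------------------------------------------------

@dataclass
class Component:
    """One nameable part of an event.

    kind: 'skip' (exons a..b lost), 'p_exonic'/'q_exonic' (3'/5' end of exon
    a lost), 'p_intronic'/'q_intronic' (start/end of intron a retained),
    'cryptic' (pseudoexon inside intron a), 'utr5'/'utr3' (UTR truncation).
    """

    kind: str
    a: int = 0
    b: int | None = None
    shift: int = 0          # signed nt: + into intron, - into exon
    letter: str = ""
    label_override: str = ""

    def slot_key(self) -> tuple:
        return (self.kind, self.a)

    def label(self, model: TranscriptModel, pq_invert: bool = False) -> str:
        p, q = ("q", "p") if pq_invert else ("p", "q")
        if self.kind == "skip":
            if self.b is None or self.b == self.a:
                base = f"{DELTA}{self.a}"
            else:
                base = f"{DELTA}{self.a}{EN_DASH}{self.b}"
        elif self.kind == "p_exonic":
            base = f"{DELTA}{self.a}{p}"
        elif self.kind == "q_exonic":
            base = f"{DELTA}{self.a}{q}"
        elif self.kind == "p_intronic":
            base = f"{NABLA}{self.a}{p}"
        elif self.kind == "q_intronic":
            base = f"{NABLA}{self.a + 1}{q}"
        elif self.kind == "cryptic":
            base = self.label_override or f"{NABLA}{self.a}"
        elif self.kind == "utr5":
            base = f"{DELTA}5{PRIME}UTR"
        elif self.kind == "utr3":
            base = f"{DELTA}3{PRIME}UTR"
        else:  # pragma: no cover
            raise ValueError(self.kind)
        return base + self.letter


LETTERABLE = {"p_exonic", "q_exonic", "p_intronic", "q_intronic", "cryptic"}


# --------------------------------------------------------------------------
# The event
# --------------------------------------------------------------------------

@dataclass
class SpliceEvent:
    kind: str
    junctions: tuple[JunctionRecord, ...]
    components: tuple[Component, ...] = ()
    # geometry, transcript space: deleted exonic intervals and retained /
    # cryptic intronic segments (intron index, first pos, last pos)
    deleted: tuple[tuple[int, int], ...] = ()
    retained: tuple[tuple[int, int, int], ...] = ()
    cryptic: tuple[int, int, int] | None = None
    exons_involved: tuple[int, ...] = ()
    introns_replaced: tuple[int, ...] = ()
    shift_donor_nt: int = 0
    shift_acceptor_nt: int = 0
    cryptic_span: tuple[HgvsPosition, HgvsPosition] | None = None
    name: str = ""
    rna_consequence: str = ""
    established_name: str = ""
    reads_per_sample: dict = field(default_factory=dict)
    mean_reads: float = 0.0
    mean_percentage: float | None = None
    samples_detected_fraction: float = 0.0
    passes_threshold: bool = True
    fail_reason: str = ""
    previously_published: bool = False
    in_frame: bool | None = None
    notes: str = ""

    @property
    def biotype(self) -> str:
        return BIOTYPES[self.kind]

    def start_key(self, model: TranscriptModel) -> tuple[int, int]:
        """Transcript-order sort key of the first affected base."""
        keys = []
        for t1, _ in self.deleted:
            keys.append((t1, 0))
        for i, p1, _ in self.retained:
            keys.append((model.donor_t(i), p1))
        if self.cryptic is not None:
            i, a, _ = self.cryptic
            keys.append((model.donor_t(i), a))
        if not keys:  # canonical
            i = self.introns_replaced[0]
            return (model.donor_t(i), 10 ** 9)
        return min(keys)

    def affected_length(self) -> int:
        n = sum(t2 - t1 + 1 for t1, t2 in self.deleted)
        n += sum(p2 - p1 + 1 for _, p1, p2 in self.retained)
        if self.cryptic is not None:
            _, a, d = self.cryptic
            n += d - a + 1
        return n


# --------------------------------------------------------------------------
# Threshold policy
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPolicy:
    """Detection threshold: a junction is real when covered by at least
    ``min_reads`` reads in at least ``min_samples`` distinct samples, or when
    previously published (whitelisted).  Junctions below the threshold are
    retained in the catalog but flagged as likely artifacts/outliers."""

    min_reads: int = 20
    min_samples: int = 2
    whitelist: frozenset = frozenset()   # of (chrom, intron_start, intron_end)

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_samples < 1:
            raise ValueError("min_reads and min_samples must be >= 1")


# --------------------------------------------------------------------------
# Classification of one junction
# --------------------------------------------------------------------------

def _locate_sides(model: TranscriptModel, rec: JunctionRecord, flank: int = 0):
    if rec.chrom != model.chrom:
        raise OutsideTranscriptError(
            f"junction on {rec.chrom}, model on {model.chrom}")
    if model.strand == "+":
        donor_g, acceptor_g = rec.intron_start - 1, rec.intron_end + 1
    else:
        donor_g, acceptor_g = rec.intron_end + 1, rec.intron_start - 1
    loc_d = model.locate_genomic(donor_g, flank=flank)
    loc_a = model.locate_genomic(acceptor_g, flank=flank)
    return loc_d, loc_a


def _pos_order_key(model: TranscriptModel, loc) -> tuple[int, int]:
    kind, idx, pos = loc
    if kind == "exon":
        return (pos, 0)
    return (model.donor_t(idx), pos)


def classify_junction(model: TranscriptModel, rec: JunctionRecord,
                      flank: int = 0) -> SpliceEvent:
    """Classify one junction against the model (unquantified, unnamed).

    Raises :class:`OutsideTranscriptError` for junctions not interpretable on
    the transcript; callers exclude those with a logged note.
    """
    loc_d, loc_a = _locate_sides(model, rec, flank=flank)
    if _pos_order_key(model, loc_d) >= _pos_order_key(model, loc_a):
        raise ClassificationError(
            f"junction {rec.intron_start}-{rec.intron_end}: acceptor does not "
            "follow donor in transcript orientation")

    deleted: list[tuple[int, int]] = []
    retained: list[tuple[int, int, int]] = []

    if loc_d[0] == "exon" and loc_a[0] == "exon":
        t_d, t_a = loc_d[2], loc_a[2]
        if t_a - t_d > 1:
            deleted.append((t_d + 1, t_a - 1))
    elif loc_d[0] == "exon" and loc_a[0] == "intron":
        t_d = loc_d[2]
        j, q = loc_a[1], loc_a[2]
        if model.donor_t(j) > t_d:
            deleted.append((t_d + 1, model.donor_t(j)))
        retained.append((j, q, model.intron_length(j)))
    elif loc_d[0] == "intron" and loc_a[0] == "exon":
        i, p = loc_d[1], loc_d[2]
        t_a = loc_a[2]
        retained.append((i, 1, p))
        if t_a > model.acceptor_t(i):
            deleted.append((model.acceptor_t(i), t_a - 1))
    else:  # both intronic
        i, p = loc_d[1], loc_d[2]
        j, q = loc_a[1], loc_a[2]
        retained.append((i, 1, p))
        if j > i:
            deleted.append((model.acceptor_t(i), model.donor_t(j)))
        retained.append((j, q, model.intron_length(j)))

    event = _event_from_geometry(model, (rec,), tuple(deleted), tuple(retained))
    if event.kind == "canonical":
        # both ends are canonical boundaries of the same intron
        intron = model._intron_after_donor(loc_d[2])
        event.introns_replaced = (intron,)
    return event


def _decompose_deletion(model: TranscriptModel, t1: int, t2: int) -> list[Component]:
    """Break a deleted exonic interval into shift/skip components.

    A partial loss at the interval's 5' end removes the 3' end of an exon
    (donor shift, p); a partial loss at its 3' end removes the 5' start of an
    exon (acceptor shift, q); whole exons in between are skips.  A loss with
    both ends inside the same exon (an exitron-like event) is represented as
    a donor+acceptor shift pair of that exon.
    """
    m = model._exon_of_t(t1).index
    w = model._exon_of_t(t2).index
    start_m = model.exon(m).cdna_start
    end_w = model.exon(w).cdna_end
    partial_start = t1 > start_m
    partial_end = t2 < end_w

    if m == w and partial_start and partial_end:
        return [Component("p_exonic", a=m, shift=-(t2 - t1 + 1)),
                Component("q_exonic", a=w, shift=-(t2 - t1 + 1))]

    comps: list[Component] = []
    if partial_start:
        comps.append(Component("p_exonic", a=m,
                               shift=-(model.exon(m).cdna_end - t1 + 1)))
    full_a = m + 1 if partial_start else m
    full_b = w - 1 if partial_end else w
    if full_a <= full_b:
        comps.append(Component("skip", a=full_a, b=full_b))
    if partial_end:
        comps.append(Component("q_exonic", a=w,
                               shift=-(t2 - model.exon(w).cdna_start + 1)))
    return comps


def _event_from_geometry(model: TranscriptModel,
                         junctions: tuple[JunctionRecord, ...],
                         deleted: tuple[tuple[int, int], ...],
                         retained: tuple[tuple[int, int, int], ...],
                         cryptic: tuple[int, int, int] | None = None) -> SpliceEvent:
    comps: list[Component] = []
    shift_donor = 0
    shift_acceptor = 0

    # assemble components in transcript order: walk segments by position
    segs: list[tuple[tuple[int, int], str, object]] = []
    for t1, t2 in deleted:
        segs.append(((t1, 0), "del", (t1, t2)))
    for i, p1, p2 in retained:
        segs.append(((model.donor_t(i), p1), "ret", (i, p1, p2)))
    if cryptic is not None:
        i, a, d = cryptic
        segs.append(((model.donor_t(i), a), "cry", (i, a, d)))
    segs.sort(key=lambda s: s[0])

    for _, kind, payload in segs:
        if kind == "del":
            comps.extend(_decompose_deletion(model, *payload))
        elif kind == "ret":
            i, p1, p2 = payload
            L = model.intron_length(i)
            if p1 == 1 and p2 < L:
                comps.append(Component("p_intronic", a=i, shift=p2))
                shift_donor = p2
            elif p2 == L and p1 > 1:
                comps.append(Component("q_intronic", a=i, shift=L - p1 + 1))
                shift_acceptor = L - p1 + 1
            elif p1 == 1 and p2 == L:
                # whole intron retained; only expressible together with an
                # exonic loss (a bare full retention has no junction at all)
                comps.append(Component("cryptic", a=i))
            else:
                comps.append(Component("cryptic", a=i))
        else:
            comps.append(Component("cryptic", a=payload[0]))

    for c in comps:
        if c.kind == "p_exonic":
            shift_donor = c.shift
        elif c.kind == "q_exonic":
            shift_acceptor = c.shift

    # terminal-modification precedence: a deletion confined to UTR bases
    if deleted and not retained and cryptic is None:
        t_lo = min(t1 for t1, _ in deleted)
        t_hi = max(t2 for _, t2 in deleted)
        if t_hi < model.cds_start:
            comps = [Component("utr5")]
        elif t_lo > model.cds_end:
            comps = [Component("utr3")]

    kind = _kind_from_components(comps)

    exons = sorted({c.a for c in comps if c.kind in {"p_exonic", "q_exonic"}}
                   | {e for c in comps if c.kind == "skip"
                      for e in range(c.a, (c.b or c.a) + 1)})
    introns = _replaced_introns(model, deleted, retained, cryptic)

    span = None
    if cryptic is not None:
        i, a, d = cryptic
        span = (model.intron_pos_hgvs(i, a), model.intron_pos_hgvs(i, d))

    return SpliceEvent(kind=kind, junctions=junctions, components=tuple(comps),
                       deleted=deleted, retained=retained, cryptic=cryptic,
                       exons_involved=tuple(exons), introns_replaced=introns,
                       shift_donor_nt=shift_donor, shift_acceptor_nt=shift_acceptor,
                       cryptic_span=span)


def _kind_from_components(comps: list[Component]) -> str:
    if not comps:
        return "canonical"
    kinds = [c.kind for c in comps]
    if kinds == ["utr5"] or kinds == ["utr3"]:
        return "terminal_modification"
    if len(comps) == 1:
        c = comps[0]
        return {
            "skip": "exon_skip" if (c.b is None or c.b == c.a) else "multi_exon_skip",
            "p_exonic": "exonic_donor_shift",
            "q_exonic": "exonic_acceptor_shift",
            "p_intronic": "intronic_donor_shift",
            "q_intronic": "intronic_acceptor_shift",
            "cryptic": "cryptic_exon_inclusion",
        }[c.kind]
    return "mixed"


def _replaced_introns(model: TranscriptModel, deleted, retained, cryptic) -> tuple[int, ...]:
    """Canonical introns wholly or partly removed by the event's junctions;
    their canonical junction reads form the quantification denominator."""
    introns: set[int] = set()
    for t1, t2 in deleted:
        m = model._exon_of_t(t1).index
        w = model._exon_of_t(t2).index
        # the junction's donor precedes t1 and its acceptor follows t2, so
        # the removed genomic region spans intron m-1 when the deletion
        # starts at an exon boundary (donor is the previous exon's end), and
        # intron w when it ends at one
        first = m - 1 if t1 == model.exon(m).cdna_start else m
        last = w if t2 == model.exon(w).cdna_end else w - 1
        for i in range(first, last + 1):
            if 1 <= i <= model.n_introns:
                introns.add(i)
    for i, _, _ in retained:
        introns.add(i)
    if cryptic is not None:
        introns.add(cryptic[0])
    return tuple(sorted(introns))


# --------------------------------------------------------------------------
# Cryptic-exon pairing
# --------------------------------------------------------------------------

def _j1_boundary(model: TranscriptModel, ev: SpliceEvent):
    """A J1 candidate splices from a (possibly shifted) donor into an intron:
    single retained tail segment (i, a, L)."""
    if ev.cryptic is not None or len(ev.retained) != 1:
        return None
    i, p1, p2 = ev.retained[0]
    if p2 != model.intron_length(i) or p1 <= 1:
        return None
    if any(c.kind == "skip" for c in ev.components):
        return None
    return (i, p1)


def _j2_boundary(model: TranscriptModel, ev: SpliceEvent):
    """A J2 candidate splices from inside an intron to a (possibly shifted)
    acceptor: single retained head segment (i, 1, d)."""
    if ev.cryptic is not None or len(ev.retained) != 1:
        return None
    i, p1, p2 = ev.retained[0]
    if p1 != 1 or p2 >= model.intron_length(i):
        return None
    if any(c.kind == "skip" for c in ev.components):
        return None
    return (i, p2)


def pair_cryptic_junctions(model: TranscriptModel,
                           events: Sequence[SpliceEvent],
                           mode: str = "all") -> tuple[list[SpliceEvent], list[SpliceEvent]]:
    """Pair facing intronic junction ends into cryptic-exon events.

    A cryptic exon inside intron i is called when junction J1 (donor ->
    intronic acceptor at a) and J2 (intronic donor at d -> acceptor) satisfy
    a < d; the pseudoexon spans intron positions a..d and its per-sample
    support is min(reads(J1), reads(J2)).  Each J1 may pair with several J2
    and vice versa.  With ``mode="all"`` (default) every consistent pair
    emits one event; junction-level data cannot always distinguish genuine
    pseudoexon combinations from cross-products of boundaries, and published
    catalogs resolved the ambiguity with prior knowledge.  ``mode=
    "parsimonious"`` keeps, for every boundary, only its best-supported pair
    (most similar read totals, then shortest pseudoexon), giving a minimal
    event set that still covers every boundary junction.

    Junctions entering at least one pair stop being reported as standalone
    intronic shifts, but remain queryable via the emitted events'
    ``junctions``.  Returns (cryptic_events, remaining_events).
    """
    j1s = [(idx, b) for idx, b in
           ((idx, _j1_boundary(model, ev)) for idx, ev in enumerate(events)) if b]
    j2s = [(idx, b) for idx, b in
           ((idx, _j2_boundary(model, ev)) for idx, ev in enumerate(events)) if b]

    edges: list[tuple[int, int, int, int, int]] = []  # (i1, i2, intron, a, d)
    for i1, (intron1, a) in j1s:
        for i2, (intron2, d) in j2s:
            if intron1 != intron2 or a >= d:
                continue
            edges.append((i1, i2, intron1, a, d))

    if mode == "parsimonious" and edges:
        def fit(edge):
            i1, i2, _, a, d = edge
            r1 = sum(events[i1].reads_per_sample.values())
            r2 = sum(events[i2].reads_per_sample.values())
            return (abs(r1 - r2), d - a)

        keep = set()
        for side, ids in ((0, {e[0] for e in edges}), (1, {e[1] for e in edges})):
            for node in ids:
                mine = [e for e in edges if e[side] == node]
                keep.add(min(mine, key=fit))
        edges = sorted(keep)
    elif mode != "all":
        raise ValueError(f"unknown pairing mode {mode!r}")

    paired: set[int] = set()
    out: list[SpliceEvent] = []
    for i1, i2, intron, a, d in edges:
        e1, e2 = events[i1], events[i2]
        deleted = tuple(sorted(e1.deleted + e2.deleted))
        ev = _event_from_geometry(
            model, (e1.junctions[0], e2.junctions[0]),
            deleted, (), cryptic=(intron, a, d))
        counts = {}
        samples = set(e1.reads_per_sample) | set(e2.reads_per_sample)
        for s in samples:
            counts[s] = min(e1.reads_per_sample.get(s, 0),
                            e2.reads_per_sample.get(s, 0))
        ev.reads_per_sample = counts
        out.append(ev)
        paired.add(i1)
        paired.add(i2)
    remaining = [ev for idx, ev in enumerate(events) if idx not in paired]
    return out, remaining


# --------------------------------------------------------------------------
# Naming
# --------------------------------------------------------------------------

_TRAILING_LETTER = re.compile(r"^(.*[0-9pq])([A-Z])$")


def split_established(name: str) -> tuple[str, str]:
    """Split a published event name into (slot prefix, letter)."""
    m = _TRAILING_LETTER.match(name)
    if m:
        return m.group(1), m.group(2)
    return name, ""


def assign_letters(model: TranscriptModel, events: Sequence[SpliceEvent]) -> None:
    """Assign A/B/C... suffixes within naming slots, in place.

    Letters are needed in a slot when it holds two or more single-component
    (pure) events, or when a previously published member already carries a
    letter; published names are kept verbatim and their letters are treated
    as taken.  Novel members receive the lowest free letters in transcript
    order (ties: shorter event first, pure before compound).  Terminal UTR
    truncations are never lettered, matching published usage.
    """
    slots: dict[tuple, list[tuple[SpliceEvent, Component]]] = {}
    for ev in events:
        for comp in ev.components:
            if comp.kind in LETTERABLE:
                slots.setdefault(comp.slot_key(), []).append((ev, comp))

    for occupants in slots.values():
        established = [(ev, comp) for ev, comp in occupants if ev.established_name]
        novel = [(ev, comp) for ev, comp in occupants if not ev.established_name]
        pure = [(ev, comp) for ev, comp in occupants if len(ev.components) == 1]

        taken: set[str] = set()
        prefix_override = ""
        for ev, comp in established:
            prefix, letter = split_established(ev.established_name)
            if letter:
                taken.add(letter)
            if len(ev.components) == 1 and prefix:
                prefix_override = prefix
        if prefix_override:
            for _, comp in occupants:
                if comp.kind == "cryptic":
                    comp.label_override = prefix_override

        need_letters = len(pure) >= 2 or bool(taken)
        if not need_letters:
            continue
        novel.sort(key=lambda pair: (pair[0].start_key(model),
                                     pair[0].affected_length(),
                                     len(pair[0].components) > 1))
        def letters():
            # A..Z then AA, AB, ... so large slots stay uniquely lettered
            import itertools
            for size in itertools.count(1):
                for combo in itertools.product(
                        [chr(c) for c in range(ord("A"), ord("Z") + 1)],
                        repeat=size):
                    yield "".join(combo)

        free = (ltr for ltr in letters() if ltr not in taken)
        for (ev, comp), letter in zip(novel, free):
            comp.letter = letter


def name_event(model: TranscriptModel, event: SpliceEvent,
               pq_invert: bool = False) -> str:
    """Generate the Δ/▼ name; published events keep their established name."""
    if event.established_name:
        return event.established_name
    return "+".join(c.label(model, pq_invert=pq_invert) for c in event.components)


# --------------------------------------------------------------------------
# HGVS r. consequence
# --------------------------------------------------------------------------

def _fmt_t(model: TranscriptModel, t: int) -> str:
    return str(model.hgvs_anchor(t))


def rna_consequence(model: TranscriptModel, event: SpliceEvent) -> str:
    """HGVS r. description: deletions as ``r.X_Ydel``, intron-derived
    insertions as ``r.E_E+1insP_Q`` with intronic-offset positions; compound
    events join their parts with "+"."""
    parts: list[tuple[tuple[int, int], str]] = []
    for t1, t2 in event.deleted:
        if t1 == t2:
            parts.append(((t1, 0), f"r.{_fmt_t(model, t1)}del"))
        else:
            parts.append(((t1, 0), f"r.{_fmt_t(model, t1)}_{_fmt_t(model, t2)}del"))
    for i, p1, p2 in event.retained:
        parts.append(((model.donor_t(i), p1), _ins_part(model, i, p1, p2)))
    if event.cryptic is not None:
        i, a, d = event.cryptic
        parts.append(((model.donor_t(i), a), _ins_part(model, i, a, d)))
    parts.sort(key=lambda p: p[0])
    return "+".join(text for _, text in parts)


def _ins_part(model: TranscriptModel, intron: int, p1: int, p2: int) -> str:
    e1 = _fmt_t(model, model.donor_t(intron))
    e2 = _fmt_t(model, model.acceptor_t(intron))
    q1 = str(model.intron_pos_hgvs(intron, p1))
    q2 = str(model.intron_pos_hgvs(intron, p2))
    return f"r.{e1}_{e2}ins{q1}_{q2}"


# --------------------------------------------------------------------------
# Parsing consequences back into junctions (fixture/whitelist support)
# --------------------------------------------------------------------------

_DEL_RE = re.compile(r"^r\.([*\-0-9+]+?)(?:_([*\-0-9+]+?))?del$")
_INS_RE = re.compile(r"^r\.([*\-0-9]+)_([*\-0-9]+)ins([*\-0-9+]+)_([*\-0-9+]+)$")


def consequence_to_junctions(model: TranscriptModel, text: str) -> list[tuple[int, int]]:
    """Reconstruct genomic junction spans (intron_start, intron_end) from an
    HGVS r. consequence string.  Raises :class:`CoordinateError` for strings
    that are not junction-level descriptions (sequence-level delins, typos,
    non-adjacent insertion anchors)."""
    text = text.strip()
    if re.search(r"(?<=[a-z])[ACGU]", text):
        # delins/ins with literal nucleotides needs sequence, not junctions
        raise CoordinateError(f"{text!r}: sequence-level description, not a junction")
    chunks = re.split(r"\+(?=r\.)", text)
    dels: list[tuple[int, int]] = []
    inss: list[tuple[int, int, int]] = []
    for chunk in chunks:
        m = _DEL_RE.match(chunk)
        if m:
            p1 = HgvsPosition.parse(m.group(1))
            p2 = HgvsPosition.parse(m.group(2)) if m.group(2) else p1
            if p1.intron_offset or p2.intron_offset:
                raise CoordinateError(f"{chunk!r}: intronic offsets inside a deletion")
            dels.append((model.anchor_to_t(p1.anchor, p1.utr3),
                         model.anchor_to_t(p2.anchor, p2.utr3)))
            continue
        m = _INS_RE.match(chunk)
        if m:
            e1 = model.anchor_to_t(*_anchor(m.group(1)))
            e2 = model.anchor_to_t(*_anchor(m.group(2)))
            if e2 != e1 + 1:
                raise CoordinateError(f"{chunk!r}: insertion anchor bases not adjacent")
            lp = _intron_pos(model, m.group(3))
            rp = _intron_pos(model, m.group(4))
            if lp[0] != rp[0]:
                raise CoordinateError(f"{chunk!r}: inserted segment spans two introns")
            intron, a = lp
            _, d = rp
            if not (model.donor_t(intron) == e1 and model.acceptor_t(intron) == e2):
                raise CoordinateError(
                    f"{chunk!r}: anchors do not flank intron {intron}")
            if a > d:
                raise CoordinateError(f"{chunk!r}: reversed inserted segment")
            inss.append((intron, a, d))
            continue
        raise CoordinateError(f"cannot parse consequence part {chunk!r}")

    if len(dels) > 1 or len(inss) > 1:
        raise CoordinateError(f"{text!r}: more than one deletion or insertion part")

    junctions: list[tuple[int, int]] = []
    if dels and not inss:
        t1, t2 = dels[0]
        junctions.append(_span_between(model, ("t", t1 - 1), ("t", t2 + 1)))
    elif inss and not dels:
        intron, a, d = inss[0]
        L = model.intron_length(intron)
        if a > 1:
            junctions.append(_span_between(model, ("t", model.donor_t(intron)),
                                           ("i", intron, a)))
        if d < L:
            junctions.append(_span_between(model, ("i", intron, d),
                                           ("t", model.acceptor_t(intron))))
        if not junctions:
            raise CoordinateError(f"{text!r}: full intron retention has no junction")
    else:
        # deletion combined with retention, e.g. a shifted-donor pseudoexon
        t1, t2 = dels[0]
        intron, a, d = inss[0]
        if model.donor_t(intron) != t2:
            raise CoordinateError(f"{text!r}: deletion does not abut the insertion intron")
        L = model.intron_length(intron)
        junctions.append(_span_between(model, ("t", t1 - 1), ("i", intron, a)))
        if d < L:
            junctions.append(_span_between(model, ("i", intron, d),
                                           ("t", model.acceptor_t(intron))))
    return junctions


def _anchor(text: str) -> tuple[int, bool]:
    pos = HgvsPosition.parse(text)
    if pos.intron_offset:
        raise CoordinateError(f"{text!r}: anchor must be exonic")
    return pos.anchor, pos.utr3


def _intron_pos(model: TranscriptModel, text: str) -> tuple[int, int]:
    pos = HgvsPosition.parse(text)
    if not pos.intron_offset:
        raise CoordinateError(f"{text!r}: expected an intronic position")
    g = model.hgvs_to_genomic(pos)
    kind, intron, p = model.locate_genomic(g)
    assert kind == "intron"
    return intron, p


def _span_between(model: TranscriptModel, left, right) -> tuple[int, int]:
    """Genomic span removed between two retained boundary bases."""
    def to_g(ref):
        if ref[0] == "t":
            return model.transcript_to_genomic(ref[1])
        return model.intron_pos_to_genomic(ref[1], ref[2])

    g1, g2 = to_g(left), to_g(right)
    lo, hi = sorted((g1, g2))
    return (lo + 1, hi - 1)


def event_from_consequence(model: TranscriptModel, text: str) -> SpliceEvent:
    """Build a classified event directly from an HGVS r. consequence.

    Unlike matrix-driven catalog assembly, the consequence string states the
    cryptic-exon pairing explicitly, so no boundary-pairing heuristics are
    involved; this is the route used to regenerate published catalog rows
    from their printed coordinates.
    """
    junctions = tuple(junction_records_from_consequence(model, text))
    chunks = re.split(r"\+(?=r\.)", text.strip())
    deleted: list[tuple[int, int]] = []
    retained: list[tuple[int, int, int]] = []
    cryptic: tuple[int, int, int] | None = None
    for chunk in chunks:
        m = _DEL_RE.match(chunk)
        if m:
            p1 = HgvsPosition.parse(m.group(1))
            p2 = HgvsPosition.parse(m.group(2)) if m.group(2) else p1
            deleted.append((model.anchor_to_t(p1.anchor, p1.utr3),
                            model.anchor_to_t(p2.anchor, p2.utr3)))
            continue
        m = _INS_RE.match(chunk)
        intron, a = _intron_pos(model, m.group(3))
        _, d = _intron_pos(model, m.group(4))
        L = model.intron_length(intron)
        if a == 1 or d == L:
            retained.append((intron, a, d))
        else:
            cryptic = (intron, a, d)
    return _event_from_geometry(model, junctions, tuple(sorted(deleted)),
                                tuple(retained), cryptic=cryptic)


def junction_records_from_consequence(model: TranscriptModel, text: str,
                                      reads: int = 0) -> list[JunctionRecord]:
    strand_code = 1 if model.strand == "+" else 2
    return [JunctionRecord(chrom=model.chrom, intron_start=s, intron_end=e,
                           strand_code=strand_code, unique_reads=reads)
            for s, e in consequence_to_junctions(model, text)]


# --------------------------------------------------------------------------
# Quantification
# --------------------------------------------------------------------------

def junction_percentage(alt_reads, canonical_reads) -> float:
    """Percentage of junction reads supporting an alternative event.

    ``alt_reads`` is a read count or a per-sample sequence of counts;
    ``canonical_reads`` is one count/sequence per replaced canonical intron.
    The statistic is the ratio of means::

        100 * mean(alt) / mean_over_introns(mean_over_samples(canonical))
    """
    alt_mean = _mean_of(alt_reads)
    intron_means = [_mean_of(c) for c in canonical_reads]
    if not intron_means:
        raise ValueError("at least one replaced canonical intron required")
    denom = statistics.fmean(intron_means)
    if denom == 0:
        raise ZeroDivisionError("all canonical junction counts are zero")
    return 100.0 * alt_mean / denom


def _mean_of(x) -> float:
    if isinstance(x, (int, float)):
        return float(x)
    seq = list(x)
    if not seq:
        raise ValueError("empty count sequence")
    return statistics.fmean(seq)


def apply_threshold(events: Sequence[SpliceEvent], policy: ThresholdPolicy) -> None:
    """Set pass/fail flags in place; failing events get a reason tag
    ('low_reads' when no sample reaches min_reads, 'single_sample' when too
    few samples do).  Whitelisted junctions pass regardless."""
    for ev in events:
        if ev.kind == "canonical":
            ev.passes_threshold = True
            continue
        counts = list(ev.reads_per_sample.values())
        qualifying = sum(1 for c in counts if c >= policy.min_reads)
        count_pass = qualifying >= policy.min_samples
        whitelisted = bool(ev.junctions) and all(
            (j.chrom, j.intron_start, j.intron_end) in policy.whitelist
            for j in ev.junctions)
        if whitelisted or ev.established_name:
            ev.previously_published = True
        ev.passes_threshold = count_pass or ev.previously_published
        if not count_pass:
            ev.fail_reason = "single_sample" if qualifying >= 1 else "low_reads"
        else:
            ev.fail_reason = ""


# --------------------------------------------------------------------------
# Catalog assembly
# --------------------------------------------------------------------------

@dataclass
class Catalog:
    model: TranscriptModel
    policy: ThresholdPolicy
    events: list[SpliceEvent]
    excluded: list[tuple[JunctionKey, str]]
    samples: list[str]

    def alternative_events(self) -> list[SpliceEvent]:
        return [e for e in self.events if e.kind != "canonical"]

    def canonical_events(self) -> dict[int, SpliceEvent]:
        return {e.introns_replaced[0]: e for e in self.events if e.kind == "canonical"}

    def events_for_junction(self, key: JunctionKey) -> list[SpliceEvent]:
        short = key[:3]
        return [e for e in self.events
                if any((j.chrom, j.intron_start, j.intron_end) == short
                       for j in e.junctions)]


def build_catalog(model: TranscriptModel, matrix: JunctionMatrix,
                  policy: ThresholdPolicy | None = None,
                  established_names: Mapping[str, str] | None = None,
                  flank: int = 0, pq_invert: bool = False,
                  pairing: str = "all") -> Catalog:
    """classify -> pair -> name -> quantify -> threshold -> annotate frame.

    ``established_names`` maps HGVS r. consequences to previously published
    event names; matching events keep those names (and letters), the way the
    source catalogs carried earlier publications' nomenclature forward.
    Deterministic: identical inputs give byte-identical catalogs.
    """
    policy = policy or ThresholdPolicy()
    established_names = dict(established_names or {})
    samples = matrix.samples
    n_samples = len(samples)

    classified: list[SpliceEvent] = []
    excluded: list[tuple[JunctionKey, str]] = []
    for key in matrix.keys:
        rec = matrix.records[key]
        try:
            ev = classify_junction(model, rec, flank=flank)
        except (OutsideTranscriptError, ClassificationError) as exc:
            excluded.append((key, str(exc)))
            continue
        ev.reads_per_sample = matrix.sample_counts(key)
        classified.append(ev)

    cryptics, remaining = pair_cryptic_junctions(model, classified, mode=pairing)
    events = remaining + cryptics

    # guarantee one canonical row per intron (zero counts if unobserved)
    seen_introns = {e.introns_replaced[0] for e in events if e.kind == "canonical"}
    strand_code = 1 if model.strand == "+" else 2
    for i in range(1, model.n_introns + 1):
        if i in seen_introns:
            continue
        s, e = model.intron_genomic(i)
        ev = SpliceEvent(kind="canonical",
                         junctions=(JunctionRecord(model.chrom, s, e, strand_code),),
                         introns_replaced=(i,))
        ev.reads_per_sample = {s_: 0 for s_ in samples}
        events.append(ev)

    canonical_counts: dict[int, list[int]] = {}
    for ev in events:
        if ev.kind == "canonical":
            canonical_counts[ev.introns_replaced[0]] = [
                ev.reads_per_sample.get(s, 0) for s in samples]

    # consequences first (established lookup is by consequence), then letters
    for ev in events:
        if ev.kind != "canonical":
            ev.rna_consequence = rna_consequence(model, ev)
            ev.established_name = established_names.get(ev.rna_consequence, "")

    assign_letters(model, [e for e in events if e.kind != "canonical"])

    for ev in events:
        if ev.kind == "canonical":
            ev.name = f"intron {ev.introns_replaced[0]} junction"
            ev.mean_reads = _detected_mean(ev.reads_per_sample)
            ev.samples_detected_fraction = _detected_fraction(ev.reads_per_sample, n_samples)
            continue
        ev.name = name_event(model, ev, pq_invert=pq_invert)
        detected = [c for c in ev.reads_per_sample.values() if c > 0]
        ev.mean_reads = statistics.fmean(detected) if detected else 0.0
        ev.samples_detected_fraction = _detected_fraction(ev.reads_per_sample, n_samples)
        introns = ev.introns_replaced or tuple(range(1, model.n_introns + 1))
        canon = [canonical_counts[i] for i in introns]
        try:
            ev.mean_percentage = junction_percentage(ev.mean_reads, canon)
        except ZeroDivisionError:
            ev.mean_percentage = None
            ev.notes = "undefined_percentage"
        if (len(ev.deleted) == 1 and not ev.retained and ev.cryptic is None
                and ev.kind in {"exon_skip", "multi_exon_skip", "exonic_donor_shift",
                                "exonic_acceptor_shift", "terminal_modification"}):
            t1, t2 = ev.deleted[0]
            length = t2 - t1 + 1
            ev.in_frame = bool(model.cds_start <= t1 and t2 <= model.cds_end
                               and length % 3 == 0)

    apply_threshold(events, policy)

    events.sort(key=lambda e: (e.start_key(model), _KIND_RANK[e.kind],
                               e.affected_length(), e.rna_consequence, e.name))
    return Catalog(model=model, policy=policy, events=events,
                   excluded=excluded, samples=samples)


def _detected_mean(counts: Mapping[str, int]) -> float:
    detected = [c for c in counts.values() if c > 0]
    return statistics.fmean(detected) if detected else 0.0


def _detected_fraction(counts: Mapping[str, int], n_samples: int) -> float:
    if n_samples == 0:
        return 0.0
    return 100.0 * sum(1 for c in counts.values() if c > 0) / n_samples
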