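"""Classification of observed transcript structures against a gene model.

A variant exon chain is compared to the canonical chain and decomposed into
the four-class event taxonomy used for plant splice-variant surveys:

* ``IR``     — intron retention; the whole intron stays in the transcript.
* ``ES``     — exon skipping; a whole exon is absent.
* ``Alt5SS`` — shifted donor: the exon upstream of an intron is extended
               into the intron (positive delta) or shortened (negative).
* ``Alt3SS`` — shifted acceptor: same for the exon downstream of an intron.

An exon shortened at one edge is, by construction, an AltSS event anchored
on the flanking intron; ES is only called for a wholly absent exon.  A
variant that includes only part of an intron at both edges yields two AltSS
events on that intron.  Forms are named with Greek letters: the canonical
chain is alpha, and the remaining forms are sorted structurally (by first
event anchor, then type, then delta), never by abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

from .gene_model_io import (
    GeneModel,
    Interval,
    SpliceFateError,
    ValidationError,
    chain_length,
    merge_coverage,
)

#: structural sort order of event types at equal anchor
EVENT_TYPE_ORDER = {"IR": 0, "ES": 1, "Alt5SS": 2, "Alt3SS": 3}

GREEK_LETTERS = [
    "α", "β", "γ", "δ", "ε", "ζ", "η",
    "θ", "ι", "κ", "λ", "μ", "ν", "ξ",
    "ο", "π", "ρ", "σ", "τ", "υ", "φ",
    "χ", "ψ", "ω",
]


class NovelSegmentError(SpliceFateError, ValueError):
    """A chain segment cannot be explained by the canonical exons/introns."""


@dataclass(frozen=True)
class SpliceEvent:
    """One atomic deviation from the canonical exon chain.

    ``anchor`` is a 1-based intron index (IR, Alt5SS, Alt3SS) or exon index
    (ES).  ``delta_nt`` is the signed change to the mature transcript length.
    """

    type: str
    anchor: int
    delta_nt: int

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPE_ORDER:
            raise ValidationError(f"unknown event type {self.type!r}")
        if self.type == "IR" and self.delta_nt <= 0:
            raise ValidationError("IR delta must be positive")
        if self.type == "ES" and self.delta_nt >= 0:
            raise ValidationError("ES delta must be negative")
        if self.type in {"Alt5SS", "Alt3SS"} and self.delta_nt == 0:
            raise ValidationError("AltSS delta must be non-zero")

    def sort_key(self) -> tuple[int, int, int]:
        return (self.anchor, EVENT_TYPE_ORDER[self.type], self.delta_nt)


@dataclass
class TranscriptForm:
    """One observed or synthetic splice variant of a gene."""

    gene_id: str
    chain: list[Interval]
    events: list[SpliceEvent] = field(default_factory=list)
    tissues: frozenset[str] = frozenset()
    provenance: str = "observed"
    form_name: str | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=SpliceEvent.sort_key)

    @property
    def is_canonical(self) -> bool:
        return not self.events

    def sort_key(self):
        return tuple(ev.sort_key() for ev in self.events)


# ---------------------------------------------------------------------------
# chain diffing


@dataclass(frozen=True)
class IntronStatus:
    """How a canonical intron appears in a variant chain.

    ``five_nt`` / ``three_nt`` are the lengths of intronic sequence included
    at the donor (5') and acceptor (3') edges; a fully retained intron has
    ``retained=True`` instead.
    """

    retained: bool
    five_nt: int
    three_nt: int

    @property
    def spliced(self) -> bool:
        return not self.retained and self.five_nt == 0 and self.three_nt == 0


@dataclass(frozen=True)
class ExonStatus:
    """How a canonical exon appears in a variant chain (absent or trimmed)."""

    absent: bool
    missing_5: int
    missing_3: int

    @property
    def present(self) -> bool:
        return not self.absent and self.missing_5 == 0 and self.missing_3 == 0


@dataclass
class ChainDiff:
    introns: list[IntronStatus]
    exons: list[ExonStatus]


def _intersect(cov: Sequence[Interval], iv: Interval) -> list[Interval]:
    a, b = iv
    out = []
    for x, y in cov:
        lo, hi = max(a, x), min(b, y)
        if lo < hi:
            out.append((lo, hi))
    return out


def diff_chains(model: GeneModel, chain: Sequence[Interval]) -> ChainDiff:
    """Explain every nucleotide of *chain* relative to the canonical model.

    Raises :class:`ValidationError` for overlapping/unordered segments or
    segments outside the gene span, and :class:`NovelSegmentError` for
    included sequence that touches neither edge of a canonical intron (a
    cryptic internal segment, outside the taxonomy).
    """
    cov = merge_coverage(list(chain))
    if not cov:
        raise ValidationError(f"{model.gene_id}: empty chain")
    prev = None
    for a, b in chain:
        if b <= a or (prev is not None and a < prev):
            raise ValidationError(f"{model.gene_id}: chain segments overlap or are unordered")
        prev = b
    gene_lo, gene_hi = model.exons[0][0], model.exons[-1][1]
    if cov[0][0] < gene_lo or cov[-1][1] > gene_hi:
        raise ValidationError(
            f"{model.gene_id}: chain extends beyond the gene span [{gene_lo}, {gene_hi})"
        )

    intron_statuses: list[IntronStatus] = []
    for idx, (a, b) in enumerate(model.introns, start=1):
        pieces = _intersect(cov, (a, b))
        covered = sum(y - x for x, y in pieces)
        if covered == b - a:
            intron_statuses.append(IntronStatus(True, 0, 0))
            continue
        five = three = 0
        for x, y in pieces:
            if x == a:
                five = y - x
            elif y == b:
                three = y - x
            else:
                raise NovelSegmentError(
                    f"{model.gene_id}: internal segment ({x}, {y}) of intron {idx} "
                    "touches neither splice site"
                )
        intron_statuses.append(IntronStatus(False, five, three))

    exon_statuses: list[ExonStatus] = []
    for idx, (a, b) in enumerate(model.exons, start=1):
        pieces = _intersect(cov, (a, b))
        if not pieces:
            exon_statuses.append(ExonStatus(True, 0, 0))
            continue
        if len(pieces) > 1:
            raise NovelSegmentError(
                f"{model.gene_id}: exon {idx} is internally split in the variant chain"
            )
        (x, y) = pieces[0]
        exon_statuses.append(ExonStatus(False, x - a, b - y))
    return ChainDiff(introns=intron_statuses, exons=exon_statuses)


def classify_form(model: GeneModel, chain: Sequence[Interval]) -> list[SpliceEvent]:
    """Map a variant chain to its sorted list of splice events.

    Precedence: a fully included intron is IR; partial inclusion at the 5'
    (donor) side is Alt5SS, at the 3' (acceptor) side Alt3SS, and both sides
    of one intron give two AltSS events.  A wholly absent exon is ES; an
    exon trimmed at an edge becomes a negative-delta AltSS on the flanking
    intron.
    """
    diff = diff_chains(model, chain)
    events: list[SpliceEvent] = []
    n_exons = len(model.exons)
    introns = model.introns

    for i, st in enumerate(diff.introns, start=1):
        if st.retained:
            a, b = introns[i - 1]
            events.append(SpliceEvent("IR", i, b - a))
        else:
            if st.five_nt:
                events.append(SpliceEvent("Alt5SS", i, st.five_nt))
            if st.three_nt:
                events.append(SpliceEvent("Alt3SS", i, st.three_nt))

    for e, st in enumerate(diff.exons, start=1):
        a, b = model.exons[e - 1]
        if st.absent:
            events.append(SpliceEvent("ES", e, -(b - a)))
            continue
        if st.missing_5:
            if e == 1:
                raise NovelSegmentError(
                    f"{model.gene_id}: 5' truncation of the first exon is not a splice event"
                )
            events.append(SpliceEvent("Alt3SS", e - 1, -st.missing_5))
        if st.missing_3:
            if e == n_exons:
                raise NovelSegmentError(
                    f"{model.gene_id}: 3' truncation of the last exon is not a splice event"
                )
            events.append(SpliceEvent("Alt5SS", e, -st.missing_3))

    events.sort(key=SpliceEvent.sort_key)
    # conservation of length is structural; assert it cheaply
    assert chain_length(model.exons) + sum(ev.delta_nt for ev in events) == chain_length(
        list(chain)
    )
    return events


# ---------------------------------------------------------------------------
# naming, tallying, tissue comparison


def assign_form_names(forms: Sequence[TranscriptForm]) -> list[TranscriptForm]:
    """Name forms of one gene: canonical -> alpha, then beta, gamma, ... .

    Forms with identical event lists are merged (tissues unioned).  Naming is
    a pure function of the event lists: input order never matters.  Requires
    exactly one canonical (event-free) form after merging.
    """
    gene_ids = {f.gene_id for f in forms}
    if len(gene_ids) > 1:
        raise ValidationError(f"assign_form_names called across genes: {sorted(gene_ids)}")

    merged: dict[tuple, TranscriptForm] = {}
    for f in forms:
        key = tuple((ev.type, ev.anchor, ev.delta_nt) for ev in f.events)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                tissues=prev.tissues | f.tissues,
                provenance=prev.provenance
                if prev.provenance == f.provenance
                else "observed",
            )
        else:
            merged[key] = replace(f)

    canonical = [f for f in merged.values() if f.is_canonical]
    if len(canonical) != 1:
        raise ValidationError(
            f"expected exactly one canonical form, found {len(canonical)}"
        )
    others = sorted((f for f in merged.values() if not f.is_canonical), key=TranscriptForm.sort_key)

    named = []
    for i, f in enumerate([canonical[0]] + others):
        name = GREEK_LETTERS[i] if i < len(GREEK_LETTERS) else f"aa{i + 1}"
        named.append(replace(f, form_name=name))
    return named


@dataclass
class EventTally:
    """Event counts for one gene's named forms.

    ``per_event`` counts every constituent event (a combination form counts
    once per event); ``per_form`` counts forms containing at least one event
    of the type.  Both views are reported because a combination form is
    ambiguous between them.
    """

    total_noncanonical: int
    per_event: dict[str, int]
    per_form: dict[str, int]
    ir_only_forms: int


def tally_events(named_forms: Sequence[TranscriptForm]) -> EventTally:
    per_event = {t: 0 for t in EVENT_TYPE_ORDER}
    per_form = {t: 0 for t in EVENT_TYPE_ORDER}
    total = 0
    ir_only = 0
    for f in named_forms:
        if f.is_canonical:
            continue
        total += 1
        types = [ev.type for ev in f.events]
        for t in types:
            per_event[t] += 1
        for t in set(types):
            per_form[t] += 1
        if set(types) == {"IR"}:
            ir_only += 1
    return EventTally(total, per_event, per_form, ir_only)


def compare_tissues(named_forms: Sequence[TranscriptForm]) -> dict[str, set[str]]:
    """Partition non-canonical forms by tissue membership.

    Returns sets of form names under ``both``, ``generative_only`` and
    ``vegetative_only``; forms without a tissue tag are excluded with a
    warning.
    """
    out: dict[str, set[str]] = {"both": set(), "generative_only": set(), "vegetative_only": set()}
    for f in named_forms:
        if f.is_canonical:
            continue
        if not f.tissues:
            warnings.warn(f"form {f.form_name} has no tissue tag; excluded", stacklevel=2)
            continue
        gen = "generative" in f.tissues
        veg = "vegetative" in f.tissues
        if gen and veg:
            out["both"].add(f.form_name or "")
        elif gen:
            out["generative_only"].add(f.form_name or "")
        elif veg:
            out["vegetative_only"].add(f.form_name or "")
        else:
            warnings.warn(
                f"form {f.form_name} has unknown tissue tags {sorted(f.tissues)}; excluded",
                stacklevel=2,
            )
    return out


# ---------------------------------------------------------------------------
# spliced-FASTA mapping


def map_spliced_to_chain(
    model: GeneModel, cdna: str, *, k: int = 20, max_backtrack: int = 15
) -> list[Interval]:
    """Recover the exon chain of a spliced cDNA by exact anchoring.

    Each segment is located by an exact match of its leading *k*-mer and
    extended maximally; because the first bases of an intron can coincide
    with the next exon's first bases, up to ``max_backtrack`` nt of an
    extension may be handed back to re-anchor the following segment.  No
    fuzzy alignment: a cDNA that cannot be explained exactly is rejected
    with :class:`ValidationError`.
    """
    if model.genomic_seq is None:
        raise ValidationError(f"{model.gene_id}: genomic sequence not loaded")
    g = model.genomic_seq.upper()
    cdna = cdna.upper()
    donors = {b for _, b in model.exons}  # canonical exon 3' boundaries
    acceptors = {a for a, _ in model.exons}  # canonical exon 5' boundaries
    chain: list[Interval] = []
    i = 0
    gpos = 0
    while i < len(cdna):
        anchor = cdna[i : i + k]
        start = g.find(anchor, gpos)
        if start < 0:
            raise ValidationError(
                f"{model.gene_id}: cDNA position {i} cannot be anchored exactly"
            )
        j = 0
        while start + j < len(g) and i + j < len(cdna) and g[start + j] == cdna[i + j]:
            j += 1
        if i + j == len(cdna):
            chain.append((start, start + j))
            i += j
            break
        # A junction lies within the last max_backtrack nt of the extension
        # (junction micro-homology lets the greedy match overrun the donor).
        # Among the splits that re-anchor exactly, prefer the one whose
        # donor/acceptor coincide with canonical splice sites of the model.
        candidates: list[tuple[int, int, int]] = []  # (-score, b, nxt)
        for b in range(0, min(max_backtrack, j - 1) + 1):
            i2 = i + j - b
            anchor2 = cdna[i2 : i2 + k]
            nxt = g.find(anchor2, start + j - b + model.min_intron_len)
            if nxt >= 0:
                score = (start + j - b in donors) + (nxt in acceptors)
                candidates.append((-score, b, nxt))
        if not candidates:
            raise ValidationError(
                f"{model.gene_id}: cDNA junction near position {i + j} cannot be re-anchored"
            )
        _, b, nxt = min(candidates)
        chain.append((start, start + j - b))
        i = i + j - b
        gpos = nxt
    return chain
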