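"""Seeded synthetic gene structures, splice variants and planted alignments.

This module is the test substrate standing in for an RT-PCR clone
collection: multi-exon plant-like gene models (SPO11-1-like: 15 exons,
SPO11-2-like: 11 exons), splice variants realizing exactly a requested list
of events with ground-truth labels, 5'/3'UTRs for uORF and NMD-feature
scans, and protein alignments with a chosen number of planted conserved
intron position classes across pseudo-species.

Generation is a pure function of (spec, seed): the same spec yields byte
identical artifacts.  Expected outcomes in the manifest (PTC status,
protein length) are computed by a deliberately naive linear-scan oracle
kept in this module, so downstream tests are not self-confirming.

Splice-site dialect: introns are written with literal GT...AG boundaries
and nothing more; no splice-site motif model is attempted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .gene_model_io import (
    MIN_INTRON_LEN,
    GeneModel,
    Interval,
    SpecError,
    format_events,
    write_gene_model,
)
from .splice_classification import SpliceEvent, TranscriptForm

_STOPS = ("TAA", "TAG", "TGA")
_AA = {  # minimal codon->aa map for the oracle/alignment side, standard code
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}


def _rand_base(rng: random.Random, gc: float) -> str:
    return rng.choice("GC") if rng.random() < gc else rng.choice("AT")


def _rand_seq(rng: random.Random, n: int, gc: float) -> str:
    return "".join(_rand_base(rng, gc) for _ in range(n))


def _rand_codon(rng: random.Random, gc: float) -> str:
    while True:
        c = _rand_seq(rng, 3, gc)
        if c not in _STOPS:
            return c


# ---------------------------------------------------------------------------
# specs


EventSpecTuple = tuple  # ("IR", i) | ("ES", e) | ("Alt5SS"/"Alt3SS", i, delta)


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to deterministically generate one gene model.

    ``exon_len`` bounds the *coding* contribution of each exon; the first
    and last exons additionally carry the UTRs.  ``stop_free_introns`` lists
    introns whose length is forced to a codon multiple and whose sequence is
    resampled until retaining the intron produces no premature stop — the
    substrate for frame-preserving, PTC-free intron retention.
    """

    seed: int = 0
    gene_id: str = "synthgene"
    species: str = "synthspecies"
    n_exons: int = 15
    exon_len: tuple[int, int] = (45, 150)
    intron_len: tuple[int, int] = (75, 300)
    gc_fraction: float = 0.42
    utr5_len: int = 120
    utr3_len: int = 180
    strand: str = "+"
    flank: int = 60
    min_intron_len: int = MIN_INTRON_LEN
    utr3_intron: bool = False
    stop_free_introns: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.n_exons < 1:
            raise SpecError("n_exons must be >= 1")
        if self.exon_len[0] > self.exon_len[1] or self.intron_len[0] > self.intron_len[1]:
            raise SpecError("empty exon or intron length range")
        if self.exon_len[0] < 6:
            raise SpecError("exon coding contribution must allow start+stop (>= 6 nt)")
        if self.intron_len[0] < self.min_intron_len:
            raise SpecError(
                f"intron_len lower bound {self.intron_len[0]} below minimum "
                f"intron length {self.min_intron_len}"
            )
        if self.utr3_intron and self.utr3_len < 2 * self.min_intron_len:
            raise SpecError("utr3_len too short to host a 3'UTR intron")
        bad = [i for i in self.stop_free_introns if not 1 <= i <= self.n_exons - 1]
        if bad:
            raise SpecError(f"stop_free_introns out of range: {bad}")


# ---------------------------------------------------------------------------
# the naive oracle (independent of the modules under test)


def oracle_translation(
    genomic_seq: str, chain: Sequence[Interval], start_g: int
) -> tuple[int, tuple[int, int, int] | None, bool]:
    """Linear-scan translation of a spliced chain from a genomic start.

    Returns ``(protein_length_aa, stop_codon_genomic_positions, start_lost)``
    walking codon by codon with a literal stop set — no shared code with the
    ORF module.
    """
    pos: list[int] = []
    for a, b in chain:
        pos.extend(range(a, b))
    seq = "".join(genomic_seq[g] for g in pos)
    try:
        si = pos.index(start_g)
    except ValueError:
        return 0, None, True
    n = 0
    i = si
    while i + 3 <= len(seq):
        if seq[i : i + 3] in _STOPS:
            return n, (pos[i], pos[i + 1], pos[i + 2]), False
        n += 1
        i += 3
    return n, None, False


def oracle_expected(model: GeneModel, chain: Sequence[Interval]) -> tuple[int, bool]:
    """Expected ``(protein_length, ptc)`` for a variant chain, naively."""
    assert model.genomic_seq is not None
    start_g = model.cds_start_genomic()
    canon_len, canon_stop, _ = oracle_translation(model.genomic_seq, model.exons, start_g)
    assert canon_stop is not None
    n, stop, lost = oracle_translation(model.genomic_seq, chain, start_g)
    if lost:
        return 0, True
    return n, stop != canon_stop


# ---------------------------------------------------------------------------
# gene generation


def _assemble(
    gene_id: str,
    species: str,
    strand: str,
    cds: str,
    coding_pieces: Sequence[int],
    intron_seqs: Sequence[str],
    utr5: str,
    utr3_parts: Sequence[str],
    utr3_intron_seq: str | None,
    flank5: str,
    flank3: str,
    min_intron_len: int,
) -> GeneModel:
    assert sum(coding_pieces) == len(cds)
    exon_seqs: list[str] = []
    off = 0
    for k, n in enumerate(coding_pieces):
        s = cds[off : off + n]
        if k == 0:
            s = utr5 + s
        if k == len(coding_pieces) - 1:
            s = s + utr3_parts[0]
        exon_seqs.append(s)
        off += n
    introns = list(intron_seqs)
    if utr3_intron_seq is not None:
        exon_seqs.append(utr3_parts[1])
        introns.append(utr3_intron_seq)

    genomic = flank5
    exons: list[Interval] = []
    for k, es in enumerate(exon_seqs):
        a = len(genomic)
        genomic += es
        exons.append((a, len(genomic)))
        if k < len(introns):
            genomic += introns[k]
    genomic += flank3
    cds_start = len(utr5)
    return GeneModel(
        gene_id=gene_id,
        species=species,
        strand=strand,
        exons=exons,
        cds_span=(cds_start, cds_start + len(cds)),
        genomic_seq=genomic,
        min_intron_len=min_intron_len,
    )


def gen_gene_model(spec: SyntheticSpec) -> GeneModel:
    """Generate one valid gene model, deterministically from the spec.

    The canonical CDS starts with ATG, ends with a single stop codon and
    contains no internal in-frame stop.  Raises :class:`SpecError` on
    infeasible constraints.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    gc = spec.gc_fraction

    coding = [rng.randint(*spec.exon_len) for _ in range(spec.n_exons)]
    rem = sum(coding) % 3
    coding[-1] -= rem
    if coding[-1] < 3:
        coding[-1] += 3
    n_codons = sum(coding) // 3
    if n_codons < 2:
        raise SpecError("CDS too short for start + stop")
    cds = "ATG" + "".join(_rand_codon(rng, gc) for _ in range(n_codons - 2)) + rng.choice(_STOPS)

    cum = 0
    offsets = []
    for n in coding[:-1]:
        cum += n
        offsets.append(cum)

    # a phase-2 stop-free intron behind exon bases "TA" would always read
    # TAG across the GT donor; swap that junction codon for a safe one
    for i in spec.stop_free_introns:
        off = offsets[i - 1]
        if off % 3 == 2 and cds[off - 2 : off] == "TA":
            new = _rand_codon(rng, gc)
            while new[:2] == "TA":
                new = _rand_codon(rng, gc)
            cds = cds[: off - 2] + new + cds[off + 1 :]

    intron_seqs = []
    for i in range(1, spec.n_exons):
        L = rng.randint(*spec.intron_len)
        if i in spec.stop_free_introns:
            # keep stop-free introns short (like real frame-preserving IR
            # cases) so stop-free sequence is sampleable
            L = min(L, 90)
            L -= L % 3
            if L < spec.min_intron_len:
                L += 3
            seq = _stop_free_intron(rng, L, gc, cds, offsets[i - 1])
        else:
            seq = "GT" + _rand_seq(rng, L - 4, gc) + "AG"
        intron_seqs.append(seq)

    utr5 = _rand_seq(rng, spec.utr5_len, gc)
    if spec.utr3_intron:
        half = spec.utr3_len // 2
        utr3_parts = [_rand_seq(rng, half, gc), _rand_seq(rng, spec.utr3_len - half, gc)]
        utr3_intron_seq = "GT" + _rand_seq(rng, rng.randint(*spec.intron_len) - 4, gc) + "AG"
    else:
        utr3_parts = [_rand_seq(rng, spec.utr3_len, gc)]
        utr3_intron_seq = None
    flank5 = _rand_seq(rng, spec.flank, gc)
    flank3 = _rand_seq(rng, spec.flank, gc)

    return _assemble(
        spec.gene_id, spec.species, spec.strand, cds, coding, intron_seqs,
        utr5, utr3_parts, utr3_intron_seq, flank5, flank3, spec.min_intron_len,
    )


def _stop_free_intron(
    rng: random.Random, length: int, gc: float, cds: str, cds_offset: int, retries: int = 200
) -> str:
    """An intron (codon-multiple length) whose retention creates no PTC."""
    assert length % 3 == 0
    for _ in range(retries):
        seq = "GT" + _rand_seq(rng, length - 4, gc) + "AG"
        variant = cds[:cds_offset] + seq + cds[cds_offset:]
        ok = True
        for i in range(0, len(variant) - 3, 3):  # all codons before the terminal stop
            if variant[i : i + 3] in _STOPS:
                ok = False
                break
        if ok:
            return seq
    raise SpecError(
        f"could not generate a stop-free intron of length {length} in {retries} tries"
    )


def gene_from_cds(
    gene_id: str,
    species: str,
    cds: str,
    intron_cds_offsets: Sequence[int],
    rng: random.Random,
    *,
    intron_len: tuple[int, int] = (75, 240),
    utr5_len: int = 90,
    utr3_len: int = 120,
    flank: int = 40,
    gc: float = 0.42,
    min_intron_len: int = MIN_INTRON_LEN,
) -> GeneModel:
    """Build a gene model around a given CDS with introns at given offsets."""
    if len(cds) % 3 or len(cds) < 6:
        raise SpecError("CDS must be a codon multiple of length >= 6")
    offs = list(intron_cds_offsets)
    if offs != sorted(set(offs)) or (offs and not (1 <= offs[0] and offs[-1] <= len(cds) - 1)):
        raise SpecError("intron offsets must be strictly increasing within the CDS")
    coding = []
    prev = 0
    for o in offs:
        coding.append(o - prev)
        prev = o
    coding.append(len(cds) - prev)
    intron_seqs = [
        "GT" + _rand_seq(rng, rng.randint(*intron_len) - 4, gc) + "AG" for _ in offs
    ]
    return _assemble(
        gene_id, species, "+", cds, coding, intron_seqs,
        _rand_seq(rng, utr5_len, gc), [_rand_seq(rng, utr3_len, gc)], None,
        _rand_seq(rng, flank, gc), _rand_seq(rng, flank, gc), min_intron_len,
    )


# ---------------------------------------------------------------------------
# event application


def _normalize_spec(spec: EventSpecTuple) -> tuple[str, int, int | None]:
    if len(spec) == 2:
        t, a = spec
        d = None
    elif len(spec) == 3:
        t, a, d = spec
    else:
        raise SpecError(f"malformed event spec {spec!r}")
    if t not in {"IR", "ES", "Alt5SS", "Alt3SS"}:
        raise SpecError(f"unknown event type {t!r}")
    return t, int(a), (None if d is None else int(d))


def apply_events(
    model: GeneModel,
    event_specs: Sequence[EventSpecTuple],
    *,
    tissues: frozenset[str] = frozenset(),
    provenance: str = "synthetic",
) -> TranscriptForm:
    """Realize a variant chain carrying exactly the requested events.

    Event specs are ``("IR", intron)``, ``("ES", exon)`` and
    ``("Alt5SS"|"Alt3SS", intron, signed_delta)``; positive AltSS deltas
    extend the flanking exon into the intron, negative deltas shorten it.
    Constraints enforced: AltSS must leave at least 1 nt of exon and a
    residual intron no shorter than the model minimum; conflicting events on
    one anchor raise :class:`SpecError`.  The returned form carries the
    normalized ground-truth :class:`SpliceEvent` list.
    """
    n_exons = len(model.exons)
    introns = model.introns
    exon_iv = [list(iv) for iv in model.exons]

    retained: set[int] = set()
    removed: set[int] = set()
    donor_shift: dict[int, int] = {}
    acceptor_shift: dict[int, int] = {}
    truth: list[SpliceEvent] = []

    for raw in event_specs:
        t, a, d = _normalize_spec(raw)
        if t == "IR":
            if not 1 <= a <= n_exons - 1:
                raise SpecError(f"IR anchor {a} out of range")
            if a in retained or a in donor_shift or a in acceptor_shift:
                raise SpecError(f"conflicting events on intron {a}")
            retained.add(a)
            ilen = introns[a - 1][1] - introns[a - 1][0]
            truth.append(SpliceEvent("IR", a, ilen))
        elif t == "ES":
            if not 1 <= a <= n_exons:
                raise SpecError(f"ES anchor {a} out of range")
            if a in removed:
                raise SpecError(f"exon {a} skipped twice")
            removed.add(a)
            elen = model.exons[a - 1][1] - model.exons[a - 1][0]
            truth.append(SpliceEvent("ES", a, -elen))
        else:
            if not 1 <= a <= n_exons - 1:
                raise SpecError(f"{t} anchor {a} out of range")
            if d is None or d == 0:
                raise SpecError(f"{t} requires a non-zero delta")
            if a in retained:
                raise SpecError(f"conflicting events on intron {a}")
            shifts = donor_shift if t == "Alt5SS" else acceptor_shift
            if a in shifts:
                raise SpecError(f"two {t} events on intron {a}")
            shifts[a] = d
            truth.append(SpliceEvent(t, a, d))

    # feasibility checks
    for a in retained:
        if a in removed or (a + 1) in removed:
            raise SpecError(f"IR on intron {a} conflicts with skipping a flanking exon")
    for a, d in donor_shift.items():
        ilen = introns[a - 1][1] - introns[a - 1][0]
        elen = exon_iv[a - 1][1] - exon_iv[a - 1][0]
        if a in removed:
            raise SpecError(f"Alt5SS on intron {a} conflicts with skipping exon {a}")
        if d > 0 and d > ilen - model.min_intron_len - max(acceptor_shift.get(a, 0), 0):
            raise SpecError(f"Alt5SS(+{d}) on intron {a} leaves a sub-minimum intron")
        if d < 0 and -d > elen - 1:
            raise SpecError(f"Alt5SS({d}) consumes exon {a}")
    for a, d in acceptor_shift.items():
        ilen = introns[a - 1][1] - introns[a - 1][0]
        elen = exon_iv[a][1] - exon_iv[a][0]
        if (a + 1) in removed:
            raise SpecError(f"Alt3SS on intron {a} conflicts with skipping exon {a + 1}")
        if d > 0 and d > ilen - model.min_intron_len - max(donor_shift.get(a, 0), 0):
            raise SpecError(f"Alt3SS(+{d}) on intron {a} leaves a sub-minimum intron")
        if d < 0 and -d > elen - 1:
            raise SpecError(f"Alt3SS({d}) consumes exon {a + 1}")

    for a, d in donor_shift.items():
        exon_iv[a - 1][1] += d
    for a, d in acceptor_shift.items():
        exon_iv[a][0] -= d

    chain: list[Interval] = []
    prev_kept: int | None = None
    for e in range(1, n_exons + 1):
        if e in removed:
            continue
        seg = (exon_iv[e - 1][0], exon_iv[e - 1][1])
        if prev_kept == e - 1 and (e - 1) in retained:
            chain[-1] = (chain[-1][0], seg[1])
        else:
            chain.append(seg)
        prev_kept = e

    truth.sort(key=SpliceEvent.sort_key)
    return TranscriptForm(
        gene_id=model.gene_id,
        chain=chain,
        events=truth,
        tissues=tissues,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# the published SPO11 splice-form survey, re-encoded as synthetic variants

#: Per-gene splice-form compositions reported for the SPO11 survey across
#: five plant species: AthSPO11-1 carries eight alternative forms (five pure
#: intron retentions, one alt 5'ss, one alt 3'ss, one alt 3'ss-with-IR);
#: AthSPO11-2 six; BraSPO11-1 five; CpaSPO11-1 eleven spanning every type
#: and pairwise combination; the P. patens genes one each (IR of intron 8,
#: skip of exon 2).  Anchors and deltas are synthetic stand-ins — the event
#: type compositions and per-gene totals are the surveyed quantities.
SURVEY_COMPOSITIONS: dict[str, tuple[int, list[list[EventSpecTuple]]]] = {
    "AthSPO11-1": (15, [
        [("IR", 2)], [("IR", 3)], [("IR", 5)], [("IR", 9)], [("IR", 12)],
        [("Alt5SS", 7, 9)],
        [("Alt3SS", 9, -12)],
        [("IR", 11), ("Alt3SS", 13, 6)],
    ]),
    "AthSPO11-2": (11, [
        [("IR", 2)], [("IR", 5)], [("IR", 8)],
        [("Alt5SS", 3, 6)],
        [("IR", 6), ("Alt5SS", 9, 9)],
        [("ES", 3), ("Alt3SS", 3, -9)],
    ]),
    "BraSPO11-1": (15, [
        [("IR", 3)], [("IR", 7)],
        [("Alt3SS", 4, -6)], [("Alt3SS", 10, 9)],
        [("ES", 5), ("IR", 8)],
    ]),
    "CpaSPO11-1": (15, [
        [("IR", 2)], [("IR", 6)],
        [("ES", 4)],
        [("Alt5SS", 3, 9)], [("Alt5SS", 10, -6)],
        [("Alt3SS", 8, -12)], [("Alt3SS", 12, 6)],
        [("IR", 9), ("Alt5SS", 5, 6)],
        [("IR", 11), ("Alt3SS", 13, -9)],
        [("ES", 7), ("Alt3SS", 7, -6)],
        [("IR", 3), ("IR", 12)],
    ]),
    "PpaSPO11-1": (15, [
        [("IR", 8)],
    ]),
    "PpaSPO11-2": (11, [
        [("ES", 2)],
    ]),
}


def gen_survey_gene(
    name: str, seed: int = 0
) -> tuple[GeneModel, list[TranscriptForm]]:
    """A synthetic gene plus the splice forms surveyed for *name*.

    The returned list starts with the canonical chain, followed by one
    variant per composition entry of :data:`SURVEY_COMPOSITIONS`.
    """
    if name not in SURVEY_COMPOSITIONS:
        raise SpecError(f"unknown survey gene {name!r}")
    n_exons, grids = SURVEY_COMPOSITIONS[name]
    idx = sorted(SURVEY_COMPOSITIONS).index(name)
    model = gen_gene_model(
        SyntheticSpec(seed=seed * 131 + idx, gene_id=name, species=name[:3], n_exons=n_exons)
    )
    forms = [TranscriptForm(gene_id=name, chain=list(model.exons), provenance="synthetic")]
    forms += [apply_events(model, especs) for especs in grids]
    return model, forms


# ---------------------------------------------------------------------------
# planted conserved-intron alignments


@dataclass
class PlantedAlignment:
    """Pseudo-species genes sharing planted intron position classes."""

    models: dict[str, GeneModel]
    msa: dict[str, str]
    tree_newick: str
    n_planted: int
    planted_residues: list[tuple[int, int]]  # (base residue, phase)


def gen_planted_alignment(
    *,
    n_species: int = 4,
    n_planted: int = 6,
    extras_per_species: int = 1,
    base_len_codons: int = 240,
    insert_len: int = 6,
    seed: int = 0,
) -> PlantedAlignment:
    """Build an MSA with exactly *n_planted* shared intron position classes.

    Every pseudo-species carries the planted introns at homologous positions
    of a common backbone protein plus ``extras_per_species`` private introns
    inside a species-specific insertion (gapped in all other rows), so the
    extras can never share an alignment column with anything.
    """
    if n_species < 2 or n_planted < 1:
        raise SpecError("need >= 2 species and >= 1 planted class")
    rng = random.Random(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]

    base_codons = ["ATG"] + [_rand_codon(rng, 0.45) for _ in range(base_len_codons - 2)]
    P = len(base_codons)  # base protein length (stop excluded, added per gene)

    # species-specific insertion points (after base residue q), all distinct
    lo, hi = P // 3, 2 * P // 3
    qs = rng.sample(range(lo, hi), n_species)
    q_of = dict(zip(species, sorted(qs)))

    # planted intron positions on the backbone, away from insertion points
    forbidden = set(q_of.values()) | {q + 1 for q in q_of.values()}
    pool = [r for r in range(5, P - 5) if r not in forbidden]
    planted_res = sorted(rng.sample(pool, n_planted))
    planted = [(r, (j % 3)) for j, r in enumerate(planted_res)]

    models: dict[str, GeneModel] = {}
    msa: dict[str, str] = {}
    sorted_qs = sorted(q_of.items(), key=lambda kv: kv[1])
    for sp in species:
        ins_codons = [_rand_codon(rng, 0.45) for _ in range(insert_len)]
        q = q_of[sp]
        codons = base_codons[:q] + ins_codons + base_codons[q:]
        cds = "".join(codons) + rng.choice(_STOPS)

        offsets = []
        for r, ph in planted:
            n = r + (insert_len if q < r else 0)
            offsets.append(3 * (n - 1) + ph if ph else 3 * n)
        for x in range(extras_per_species):
            n = q + 2 + x  # inside this species' private insertion
            offsets.append(3 * (n - 1) + 1)
        models[sp] = gene_from_cds(sp, sp, cds, sorted(offsets), rng)

        row = []
        for idx in range(P + 1):  # after each base residue slot, place blocks
            if idx > 0:
                row.append(_AA[base_codons[idx - 1]])
            for other, oq in sorted_qs:
                if oq == idx:
                    row.append(
                        "".join(_AA[c] for c in ins_codons)
                        if other == sp
                        else "-" * insert_len
                    )
        msa[sp] = "".join(row)

    def _pair(names: list[str]) -> str:
        if len(names) == 1:
            return names[0]
        mid = len(names) // 2
        return f"({_pair(names[:mid])},{_pair(names[mid:])})"

    tree_newick = _pair(species) + ";"
    return PlantedAlignment(models, msa, tree_newick, n_planted, planted)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class Dataset:
    """An in-memory synthetic dataset plus the paths it was written to."""

    out_dir: Path
    models: dict[str, GeneModel]
    forms: dict[str, list[TranscriptForm]]
    manifest: pd.DataFrame
    planted: PlantedAlignment | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def _grid_event_specs(
    model: GeneModel, rng: random.Random, *, include_pairs: bool
) -> list[list[EventSpecTuple]]:
    """Single events of all four types, plus pairwise combinations."""
    n = len(model.exons)
    introns = model.introns

    def altd(i: int, sign: int) -> int:
        ilen = introns[i - 1][1] - introns[i - 1][0]
        if sign > 0:
            return rng.randint(3, max(3, min(30, ilen - model.min_intron_len)))
        return -rng.randint(3, 30)

    if n < 5:
        raise SpecError("event grid needs at least 5 exons")
    i_ir = rng.randint(1, n - 1)
    e_es = rng.randint(2, n - 1)
    i_a5 = rng.randint(1, n - 1)
    i_a3 = rng.randint(1, n - 1)
    singles: list[list[EventSpecTuple]] = [
        [("IR", i_ir)],
        [("ES", e_es)],
        [("Alt5SS", i_a5, altd(i_a5, rng.choice((1, -1))))],
        [("Alt3SS", i_a3, altd(i_a3, rng.choice((1, -1))))],
    ]
    if not include_pairs:
        return singles
    # pairwise combinations on anchors far enough apart for any n >= 5
    far = max(3, n // 2)
    pairs: list[list[EventSpecTuple]] = [
        [("IR", 1), ("IR", far)],
        [("IR", 1), ("ES", far)],
        [("IR", 1), ("Alt5SS", far, altd(far, 1))],
        [("IR", 1), ("Alt3SS", far, altd(far, -1))],
        [("ES", 2), ("Alt5SS", far, altd(far, -1))],
        [("ES", far), ("Alt3SS", far, altd(far, -1))],  # skip + 5'-trimmed next exon
        [("Alt5SS", 1, altd(1, 1)), ("Alt3SS", far, altd(far, 1))],
        [("Alt5SS", far, altd(far, -1)), ("Alt3SS", far, altd(far, 1))],
    ]
    return singles + pairs


def gen_dataset(
    out_dir: str | Path,
    *,
    n_genes: int = 5,
    seed: int = 0,
    include_pairs: bool = True,
    planted: bool = True,
    tissue_cycle: Sequence[frozenset[str]] = (
        frozenset({"generative"}),
        frozenset({"vegetative"}),
        frozenset({"generative", "vegetative"}),
    ),
) -> Dataset:
    """Write a complete labelled dataset: genes, forms, manifest, MSA, tree.

    Gene shapes alternate between the two plant architectures (15 and 11
    exons).  Each gene gets the full event grid; tissue labels cycle
    deterministically through *tissue_cycle* so tissue-partition results are
    exact.  The manifest's expected PTC status and protein length come from
    the naive oracle, not from the ORF module.
    """
    out_dir = Path(out_dir)
    genes_dir = out_dir / "genes"
    genes_dir.mkdir(parents=True, exist_ok=True)
    master = random.Random(seed)

    models: dict[str, GeneModel] = {}
    all_forms: dict[str, list[TranscriptForm]] = {}
    rows = []
    paths: dict[str, Path] = {}
    for gi in range(n_genes):
        gene_id = f"g{gi + 1:02d}"
        spec = SyntheticSpec(
            seed=master.randrange(2**31),
            gene_id=gene_id,
            species=f"pseudo{gi + 1}",
            n_exons=15 if gi % 2 == 0 else 11,
        )
        model = gen_gene_model(spec)
        models[gene_id] = model
        rng = random.Random(master.randrange(2**31))

        forms = [
            TranscriptForm(gene_id=gene_id, chain=list(model.exons), provenance="synthetic",
                           tissues=frozenset({"generative", "vegetative"}))
        ]
        for fi, especs in enumerate(_grid_event_specs(model, rng, include_pairs=include_pairs)):
            tissues = tissue_cycle[fi % len(tissue_cycle)]
            forms.append(apply_events(model, especs, tissues=tissues))
        all_forms[gene_id] = forms

        gff3 = genes_dir / f"{gene_id}.gff3"
        fasta = genes_dir / f"{gene_id}.fasta"
        extra = [
            (f"{gene_id}.form{k}", f.chain, f.tissues)
            for k, f in enumerate(forms)
        ]
        write_gene_model(model, gff3, fasta, extra_mrnas=extra)
        paths[gene_id] = gff3

        for k, f in enumerate(forms):
            exp_len, exp_ptc = oracle_expected(model, f.chain)
            rows.append(
                {
                    "gene": gene_id,
                    "form_id": f"{gene_id}.form{k}",
                    "events": format_events(f.events),
                    "tissues": ",".join(sorted(f.tissues)),
                    "expected_ptc": exp_ptc,
                    "expected_protein_aa": exp_len,
                }
            )

    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    paths["manifest"] = manifest_path

    planted_obj = None
    if planted:
        planted_obj = gen_planted_alignment(seed=master.randrange(2**31))
        msa_path = out_dir / "msa.fasta"
        with msa_path.open("w") as fh:
            for sp, row in planted_obj.msa.items():
                fh.write(f">{sp}\n{row}\n")
        tree_path = out_dir / "tree.nwk"
        tree_path.write_text(planted_obj.tree_newick + "\n")
        planted_dir = out_dir / "planted"
        planted_dir.mkdir(exist_ok=True)
        for sp, m in planted_obj.models.items():
            write_gene_model(m, planted_dir / f"{sp}.gff3", planted_dir / f"{sp}.fasta")
        (out_dir / "planted_truth.json").write_text(
            json.dumps(
                {"n_planted": planted_obj.n_planted, "residues": planted_obj.planted_residues}
            )
            + "\n"
        )
        paths["msa"] = msa_path
        paths["tree"] = tree_path

    return Dataset(out_dir, models, all_forms, manifest, planted_obj, paths)
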