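"""Gene-model parsing, validation and serialization.

Coordinate conventions, fixed here and nowhere else:

* On disk (GFF3) coordinates are 1-based inclusive, as the format requires.
* In memory everything is 0-based half-open.
* Minus-strand genes are reverse-complemented at load time, so every other
  module only ever sees a *transcript-oriented* model: the stored genomic
  sequence reads 5'->3' along the transcript and exon intervals are
  ascending.  The original strand is kept only so the model can be written
  back to its genomic representation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

#: Shortest intron accepted as real; anything shorter is treated as an
#: annotation artifact (well below plant U2 spliceosome minima).
MIN_INTRON_LEN = 20

#: 3'UTRs longer than this are flagged as NMD-candidate "long" 3'UTRs.
LONG_3UTR_NT = 350


class SpliceFateError(Exception):
    """Base class for all package errors."""


class NotFoundError(SpliceFateError, KeyError):
    """A requested record (gene id, sequence id) is absent from the input."""


class ValidationError(SpliceFateError, ValueError):
    """An input violates a structural invariant."""


class ConsistencyError(SpliceFateError, ValueError):
    """Cross-referenced inputs disagree (ids, sequences, alignments)."""


class SpecError(SpliceFateError, ValueError):
    """A synthetic-data specification is infeasible or self-contradictory."""


class RangeError(SpliceFateError, IndexError):
    """A coordinate falls outside the sequence it refers to."""


# ---------------------------------------------------------------------------
# interval / chain helpers


def _check_chain(chain: Sequence[Interval], *, what: str = "chain") -> None:
    prev_end = None
    for a, b in chain:
        if b <= a:
            raise ValidationError(f"{what}: empty or inverted interval ({a}, {b})")
        if prev_end is not None and a < prev_end:
            raise ValidationError(f"{what}: intervals overlap or are unordered at ({a}, {b})")
        prev_end = b


def chain_length(chain: Sequence[Interval]) -> int:
    return sum(b - a for a, b in chain)


def spliced_sequence(genomic_seq: str, chain: Sequence[Interval]) -> str:
    """Concatenate chain segments of a transcript-oriented sequence."""
    for a, b in chain:
        if a < 0 or b > len(genomic_seq):
            raise RangeError(f"interval ({a}, {b}) outside sequence of length {len(genomic_seq)}")
    return "".join(genomic_seq[a:b] for a, b in chain)


def chain_genomic_positions(chain: Sequence[Interval]) -> list[int]:
    """Genomic coordinate of each spliced-transcript nucleotide, in order."""
    pos: list[int] = []
    for a, b in chain:
        pos.extend(range(a, b))
    return pos


def genomic_to_spliced(chain: Sequence[Interval], gpos: int) -> int | None:
    """Spliced coordinate of genomic position *gpos*, or None if spliced out."""
    off = 0
    for a, b in chain:
        if a <= gpos < b:
            return off + (gpos - a)
        off += b - a
    return None


def spliced_to_genomic(chain: Sequence[Interval], spos: int) -> int:
    off = 0
    for a, b in chain:
        if spos < off + (b - a):
            return a + (spos - off)
        off += b - a
    raise RangeError(f"spliced position {spos} beyond transcript of length {off}")


def merge_coverage(chain: Sequence[Interval]) -> list[Interval]:
    """Union of intervals, merging touching/overlapping ones."""
    merged: list[Interval] = []
    for a, b in sorted(chain):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneModel:
    """Canonical exon/intron architecture of one gene, transcript-oriented.

    ``exons`` are 0-based half-open intervals on ``genomic_seq`` (already
    reverse-complemented for minus-strand genes), strictly ascending.
    ``cds_span`` is in spliced-transcript coordinates and covers start codon
    through stop codon inclusive.
    """

    gene_id: str
    species: str
    strand: str
    exons: list[Interval]
    cds_span: Interval
    genomic_seq: str | None = None
    min_intron_len: int = MIN_INTRON_LEN
    seqid: str | None = None

    def __post_init__(self) -> None:
        self.exons = [tuple(e) for e in self.exons]
        self.cds_span = tuple(self.cds_span)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene model has no exons")
        _check_chain(self.exons, what=f"{self.gene_id} exons")
        cs, ce = self.cds_span
        if not (0 <= cs < ce <= self.spliced_length):
            raise ValidationError(f"{self.gene_id}: CDS span {self.cds_span} outside transcript")
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )
        if self.cds_length < 6:
            raise ValidationError(f"{self.gene_id}: CDS shorter than start + stop codon")
        for i, (a, b) in enumerate(self.introns, start=1):
            if b - a < self.min_intron_len:
                raise ValidationError(
                    f"{self.gene_id}: intron {i} length {b - a} < minimum {self.min_intron_len}"
                )
        if self.genomic_seq is not None and self.exons[-1][1] > len(self.genomic_seq):
            raise ValidationError(f"{self.gene_id}: exons extend beyond the genomic sequence")

    # -- derived structure ----------------------------------------------
    @property
    def introns(self) -> list[Interval]:
        """All inter-exon gaps (coding and UTR alike), ascending."""
        return [
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        ]

    @property
    def spliced_length(self) -> int:
        return chain_length(self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_span[1] - self.cds_span[0]

    @property
    def utr5_len(self) -> int:
        return self.cds_span[0]

    @property
    def utr3_len(self) -> int:
        return self.spliced_length - self.cds_span[1]

    @property
    def utr_introns_3(self) -> int:
        """Annotated introns lying entirely downstream of the stop codon."""
        n = 0
        off = 0
        for a, b in self.exons[:-1]:
            off += b - a
            if off >= self.cds_span[1]:
                n += 1
        return n

    def spliced_seq(self) -> str:
        if self.genomic_seq is None:
            raise ValidationError(f"{self.gene_id}: genomic sequence not loaded")
        return spliced_sequence(self.genomic_seq, self.exons)

    def canonical_cds(self) -> str:
        return self.spliced_seq()[self.cds_span[0] : self.cds_span[1]]

    def cds_start_genomic(self) -> int:
        return spliced_to_genomic(self.exons, self.cds_span[0])

    def stop_codon_genomic(self) -> tuple[int, int, int]:
        """Genomic (transcript-oriented) positions of the stop codon's 3 nt."""
        s = self.cds_span[1] - 3
        return tuple(spliced_to_genomic(self.exons, s + k) for k in range(3))  # type: ignore[return-value]


@dataclass(frozen=True)
class IntronRecord:
    """A CDS-interrupting intron with its coding offset and phase."""

    intron_index: int  # 1-based among CDS-overlapping introns
    genomic_interval: Interval
    cds_offset: int  # coding nt strictly 5' of the intron
    phase: int

    def __post_init__(self) -> None:
        if self.phase != self.cds_offset % 3:
            raise ValidationError(
                f"intron {self.intron_index}: phase {self.phase} != offset {self.cds_offset} mod 3"
            )


class SpeciesTree:
    """A rooted species tree (Newick) whose leaves name GeneModel species."""

    def __init__(self, tree) -> None:  # dendropy.Tree
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# loading


def _oriented(intervals: Iterable[Interval], strand: str, seq_len: int) -> list[Interval]:
    """Map plus-strand genomic intervals into transcript orientation."""
    ivs = sorted(tuple(iv) for iv in intervals)
    if strand == "-":
        ivs = sorted((seq_len - b, seq_len - a) for a, b in ivs)
    return ivs


def load_gene_model(
    gff3_path: str | Path,
    fasta_path: str | Path,
    gene_id: str,
    *,
    species: str | None = None,
    min_intron_len: int = MIN_INTRON_LEN,
) -> GeneModel:
    """Load one gene from GFF3 + genomic FASTA, transcript-oriented.

    When the GFF3 holds several mRNAs for the gene, the canonical transcript
    is the one with the longest summed CDS; ties break on lexicographic mRNA
    id.  Raises :class:`NotFoundError` for a missing gene id and
    :class:`ValidationError` for structural defects (overlapping exons, CDS
    length not a codon multiple, sub-minimum introns).
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    try:
        gene = db[gene_id]
    except gffutils.FeatureNotFoundError as exc:
        raise NotFoundError(f"gene id {gene_id!r} not found in {gff3_path}") from exc

    mrnas = list(db.children(gene, featuretype="mRNA"))
    if not mrnas:
        raise ValidationError(f"{gene_id}: no mRNA feature")

    def cds_total(m) -> int:
        return sum(f.end - f.start + 1 for f in db.children(m, featuretype="CDS"))

    mrna = sorted(mrnas, key=lambda m: (-cds_total(m), m.id))[0]

    exon_feats = list(db.children(mrna, featuretype="exon"))
    cds_feats = list(db.children(mrna, featuretype="CDS"))
    if not exon_feats or not cds_feats:
        raise ValidationError(f"{gene_id}: mRNA {mrna.id} lacks exon or CDS features")

    with open(fasta_path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if gene.seqid not in seqs:
        raise NotFoundError(f"sequence {gene.seqid!r} not found in {fasta_path}")
    plus_seq = seqs[gene.seqid]
    strand = gene.strand if gene.strand in {"+", "-"} else "+"
    seq = str(Seq(plus_seq).reverse_complement()) if strand == "-" else plus_seq
    L = len(plus_seq)

    # GFF3 1-based inclusive -> 0-based half-open, then transcript orientation
    exons = _oriented(((f.start - 1, f.end) for f in exon_feats), strand, L)
    cds_ivs = _oriented(((f.start - 1, f.end) for f in cds_feats), strand, L)
    _check_chain(exons, what=f"{gene_id} exons")

    cds_start = genomic_to_spliced(exons, cds_ivs[0][0])
    cds_end_last = genomic_to_spliced(exons, cds_ivs[-1][1] - 1)
    if cds_start is None or cds_end_last is None:
        raise ValidationError(f"{gene_id}: CDS features not contained in exons")

    return GeneModel(
        gene_id=gene_id,
        species=species or gene.attributes.get("species", [gene_id])[0],
        strand=strand,
        exons=exons,
        cds_span=(cds_start, cds_end_last + 1),
        genomic_seq=seq,
        min_intron_len=min_intron_len,
        seqid=gene.seqid,
    )


def load_transcript_chains(
    gff3_path: str | Path, model: GeneModel
) -> list[tuple[str, list[Interval], frozenset[str]]]:
    """Read observed transcript forms (one mRNA each) from a GFF3 file.

    Returns ``(mrna_id, transcript-oriented exon chain, tissues)`` triples.
    Tissue provenance is taken from a ``tissue`` attribute when present.
    """
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    L = len(model.genomic_seq) if model.genomic_seq is not None else model.exons[-1][1]
    out = []
    for mrna in db.features_of_type("mRNA"):
        exon_feats = list(db.children(mrna, featuretype="exon"))
        if not exon_feats:
            continue
        chain = _oriented(((f.start - 1, f.end) for f in exon_feats), model.strand, L)
        tissues = frozenset(
            t for raw in mrna.attributes.get("tissue", []) for t in raw.split(",") if t
        )
        out.append((mrna.id, chain, tissues))
    return out


# ---------------------------------------------------------------------------
# intron derivation


def derive_introns(model: GeneModel) -> list[IntronRecord]:
    """One record per inter-exon gap that interrupts the CDS.

    ``cds_offset`` counts only coding nucleotides 5' of the intron; introns
    entirely inside the 5'UTR or 3'UTR get no record (3'UTR introns are
    visible through :attr:`GeneModel.utr_introns_3`).
    """
    records: list[IntronRecord] = []
    cds_start, cds_end = model.cds_span
    off = 0
    for (a, b), gap in zip(model.exons[:-1], model.introns):
        off += b - a
        if cds_start < off < cds_end:
            cds_offset = off - cds_start
            records.append(
                IntronRecord(
                    intron_index=len(records) + 1,
                    genomic_interval=gap,
                    cds_offset=cds_offset,
                    phase=cds_offset % 3,
                )
            )
    return records


class SplicedCds(NamedTuple):
    """Spliced sequence from the mapped canonical start onward."""

    seq: str
    start_lost: bool


def extract_spliced_cds(model: GeneModel, chain: Sequence[Interval]) -> SplicedCds:
    """Spliced sequence of *chain* from the canonical start codon's position.

    The returned sequence runs through the transcript 3' end (a frameshifted
    variant's stop may lie beyond the canonical stop codon).  If the chain no
    longer contains the canonical start position the full spliced sequence is
    returned with ``start_lost=True``.
    """
    if model.genomic_seq is None:
        raise ValidationError(f"{model.gene_id}: genomic sequence not loaded")
    _check_chain(chain)
    full = spliced_sequence(model.genomic_seq, chain)
    spos = genomic_to_spliced(chain, model.cds_start_genomic())
    if spos is None:
        return SplicedCds(full, True)
    return SplicedCds(full[spos:], False)


# ---------------------------------------------------------------------------
# writing


def write_gene_model(
    model: GeneModel,
    gff3_path: str | Path,
    fasta_path: str | Path,
    *,
    extra_mrnas: Sequence[tuple[str, Sequence[Interval], frozenset[str] | None]] = (),
) -> None:
    """Serialize a model (and optional variant chains) to GFF3 + FASTA.

    The genomic FASTA is written in plus-strand orientation; a minus-strand
    model's stored transcript-oriented sequence is reverse-complemented back.
    """
    if model.genomic_seq is None:
        raise ValidationError(f"{model.gene_id}: genomic sequence not loaded")
    L = len(model.genomic_seq)
    seqid = model.seqid or f"{model.gene_id}_region"
    plus_seq = (
        str(Seq(model.genomic_seq).reverse_complement())
        if model.strand == "-"
        else model.genomic_seq
    )

    def to_plus(iv: Interval) -> Interval:
        if model.strand == "-":
            return (L - iv[1], L - iv[0])
        return iv

    def gff_line(ftype: str, iv: Interval, attrs: str) -> str:
        a, b = to_plus(iv)
        return f"{seqid}\tsplicefate\t{ftype}\t{a + 1}\t{b}\t.\t{model.strand}\t.\t{attrs}"

    cds_chain = _cds_genomic_chain(model)
    lines = ["##gff-version 3"]
    gene_iv = (model.exons[0][0], model.exons[-1][1])
    lines.append(gff_line("gene", gene_iv, f"ID={model.gene_id};species={model.species}"))
    mrna_id = f"{model.gene_id}.t1"
    lines.append(gff_line("mRNA", gene_iv, f"ID={mrna_id};Parent={model.gene_id}"))
    for i, ex in enumerate(model.exons, 1):
        lines.append(gff_line("exon", ex, f"ID={mrna_id}.exon{i};Parent={mrna_id}"))
    for i, iv in enumerate(cds_chain, 1):
        lines.append(gff_line("CDS", iv, f"ID={mrna_id}.cds{i};Parent={mrna_id}"))
    for fid, chain, tissues in extra_mrnas:
        span = (chain[0][0], chain[-1][1])
        attrs = f"ID={fid};Parent={model.gene_id}"
        if tissues:
            attrs += f";tissue={','.join(sorted(tissues))}"
        lines.append(gff_line("mRNA", span, attrs))
        for i, ex in enumerate(chain, 1):
            lines.append(gff_line("exon", ex, f"ID={fid}.exon{i};Parent={fid}"))

    def sort_key(line: str):
        parts = line.split("\t")
        if len(parts) < 5:
            return (-1, 0)
        return (int(parts[3]), int(parts[4]))

    header, body = lines[0], lines[1:]
    Path(gff3_path).write_text("\n".join([header] + body) + "\n")
    SeqIO.write([SeqRecord(Seq(plus_seq), id=seqid, description="")], str(fasta_path), "fasta")


def _cds_genomic_chain(model: GeneModel) -> list[Interval]:
    """Genomic (transcript-oriented) intervals covered by the CDS."""
    cs, ce = model.cds_span
    out: list[Interval] = []
    off = 0
    for a, b in model.exons:
        lo, hi = max(cs, off), min(ce, off + (b - a))
        if lo < hi:
            out.append((a + (lo - off), a + (hi - off)))
        off += b - a
    return out


# ---------------------------------------------------------------------------
# report writing


def format_events(events) -> str:
    """Render an event list as e.g. ``IR:intron8:+112,ES:exon2:-90``."""
    parts = []
    for ev in events:
        kind = "exon" if ev.type == "ES" else "intron"
        parts.append(f"{ev.type}:{kind}{ev.anchor}:{ev.delta_nt:+d}")
    return ",".join(parts)


def write_reports(forms, orf_reports, matrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the forms table and (optionally) the intron matrix as TSV.

    ``forms`` are named :class:`~splicefate.splice_classification.TranscriptForm`
    objects, ``orf_reports`` a mapping or list of OrfReports keyed/aligned by
    form name.  Outputs are byte-stable for identical inputs.  Raises
    :class:`ConsistencyError` on id mismatches.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(orf_reports, dict):
        orf_reports = {r.form_name: r for r in orf_reports}
    missing = [f.form_name for f in forms if f.form_name not in orf_reports]
    if missing:
        raise ConsistencyError(f"no ORF report for form(s): {', '.join(missing)}")

    rows = []
    for f in sorted(forms, key=lambda f: (f.gene_id, f.sort_key())):
        r = orf_reports[f.form_name]
        rows.append(
            {
                "gene": f.gene_id,
                "form": f.form_name,
                "events": format_events(f.events),
                "ptc": r.ptc,
                "protein_aa": r.protein_length_aa,
                "tissues": ",".join(sorted(f.tissues)),
                "functional": r.functional_call,
            }
        )
    forms_path = out_dir / "forms_table.tsv"
    pd.DataFrame(rows).to_csv(forms_path, sep="\t", index=False)
    written = {"forms": forms_path}

    if matrix is not None:
        matrix_path = out_dir / "intron_matrix.tsv"
        matrix.to_dataframe().to_csv(matrix_path, sep="\t")
        written["matrix"] = matrix_path
    return written


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
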