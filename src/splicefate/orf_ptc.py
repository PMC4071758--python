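"""Translation outcomes of splice variants: PTCs, protein lengths, NMD flags.

The PTC call is positional-by-identity: a variant carries a premature
termination codon iff its first in-frame stop does not occupy the same
genomic nucleotides as the canonical stop codon.  This is the definition
under which a frame-preserving intron retention that lengthens the protein
(or a frame-preserving exon skip that shortens it) is still PTC-free and
putatively functional.  The mammalian-style 50-nt exon-junction rule is
available as a secondary flag but is off by default.

Ambiguity codes translate to 'X' and never count as stop codons, even when
every resolution of the code would be a stop (e.g. TAR).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .gene_model_io import (
    LONG_3UTR_NT,
    GeneModel,
    Interval,
    ValidationError,
    chain_genomic_positions,
    extract_spliced_cds,
    genomic_to_spliced,
    merge_coverage,
    spliced_sequence,
)
from .splice_classification import TranscriptForm

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_FORWARD = dict(_TABLE.forward_table)


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate from the first codon to the first in-frame stop.

    Returns ``(protein, stop_found)``; the protein excludes the stop.  A
    codon containing an ambiguity code becomes 'X' and never terminates
    translation.  A CDS not starting with ATG triggers a warning but is
    translated anyway.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValidationError(f"CDS of length {len(cds)} cannot be translated")
    if not cds.startswith("ATG"):
        warnings.warn("CDS does not start with ATG; translating anyway", stacklevel=2)
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(protein), True
        protein.append(_FORWARD.get(codon, "X"))
    return "".join(protein), False


@dataclass(frozen=True)
class OrfReport:
    """Translation outcome of one splice variant."""

    form_name: str
    protein_length_aa: int
    ptc: bool
    stop_class: str  # canonical | premature | none_found
    delta_aa: int
    functional_call: bool
    start_lost: bool = False
    ejc_ptc50: bool | None = None  # optional exon-junction 50-nt rule flag


@dataclass(frozen=True)
class NmdFeatureReport:
    """NMD-candidate features of one variant (features only, no NMD claim)."""

    form_name: str
    uorf_count: int
    utr3_len: int
    long_3utr: bool
    intron_in_3utr: bool


def analyze_orf(
    model: GeneModel,
    form: TranscriptForm,
    *,
    ejc_rule: bool = False,
) -> OrfReport:
    """Translate a variant from the canonical start and classify its stop.

    ``delta_aa`` is against the canonical protein.  Loss of the start codon
    reports ``stop_class='none_found'``, ``ptc=True`` and length 0.  With
    ``ejc_rule=True`` the report also carries the 50-nt exon-junction flag
    (stop more than 50 nt upstream of the last exon junction).
    """
    name = form.form_name or "?"
    canon_protein, canon_stop = translate_cds(model.canonical_cds())
    if not canon_stop:
        raise ValidationError(f"{model.gene_id}: canonical CDS lacks a stop codon")
    canon_len = len(canon_protein)
    canon_stop_g = model.stop_codon_genomic()

    seq, start_lost = extract_spliced_cds(model, form.chain)
    if start_lost:
        return OrfReport(name, 0, True, "none_found", -canon_len, False, start_lost=True)

    protein, stop_found = translate_cds(seq)
    if not stop_found:
        return OrfReport(
            name, len(protein), False, "none_found", len(protein) - canon_len, False
        )

    # genomic identity of the variant's first in-frame stop codon
    gpos = chain_genomic_positions(form.chain)
    start_idx = genomic_to_spliced(form.chain, model.cds_start_genomic())
    assert start_idx is not None
    stop_idx = start_idx + 3 * len(protein)
    stop_g = tuple(gpos[stop_idx + k] for k in range(3))
    is_canonical_stop = stop_g == canon_stop_g

    ejc_flag = None
    if ejc_rule:
        # spliced positions of exon-exon junctions in the variant
        junctions = []
        off = 0
        for a, b in form.chain[:-1]:
            off += b - a
            junctions.append(off)
        last_j = junctions[-1] if junctions else None
        stop_end = stop_idx + 3
        ejc_flag = last_j is not None and (last_j - stop_end) > 50

    return OrfReport(
        form_name=name,
        protein_length_aa=len(protein),
        ptc=not is_canonical_stop,
        stop_class="canonical" if is_canonical_stop else "premature",
        delta_aa=len(protein) - canon_len,
        functional_call=is_canonical_stop,
        ejc_ptc50=ejc_flag,
    )


# ---------------------------------------------------------------------------
# uORFs


_ATG = re.compile("ATG")


@dataclass(frozen=True)
class UorfScan:
    uorf_count: int
    spans: tuple[Interval, ...]
    overlapping_count: int


def detect_uorfs(utr5: str) -> UorfScan:
    """Count upstream ORFs in a 5'UTR.

    Every ATG whose reading frame reaches a stop codon entirely inside the
    UTR opens one uORF (span includes the stop).  ATGs whose frame runs off
    the UTR end into the main CDS are counted separately as overlapping and
    excluded from ``uorf_count``.
    """
    utr5 = utr5.upper().replace("U", "T")
    spans: list[Interval] = []
    overlapping = 0
    for m in _ATG.finditer(utr5):
        i = m.start()
        terminated = False
        for j in range(i + 3, len(utr5) - 2, 3):
            if utr5[j : j + 3] in STOP_CODONS:
                spans.append((i, j + 3))
                terminated = True
                break
        if not terminated:
            overlapping += 1
    return UorfScan(len(spans), tuple(spans), overlapping)


# ---------------------------------------------------------------------------
# NMD-candidate features


def annotate_nmd_features(
    model: GeneModel,
    form: TranscriptForm,
    orf: OrfReport,
    *,
    long_3utr_threshold: int = LONG_3UTR_NT,
) -> NmdFeatureReport:
    """Flag NMD-candidate features of a variant transcript.

    ``utr3_len`` is measured on the variant's mature transcript downstream
    of its own stop codon; ``intron_in_3utr`` is true when any canonical
    intron that the variant still splices out lies entirely 3' of that stop.
    The report describes candidate features only — it never claims the
    transcript is an NMD target.
    """
    name = form.form_name or "?"
    if model.genomic_seq is None:
        raise ValidationError(f"{model.gene_id}: genomic sequence not loaded")

    variant_seq = spliced_sequence(model.genomic_seq, form.chain)
    start_idx = genomic_to_spliced(form.chain, model.cds_start_genomic())

    # 5'UTR of the variant (upstream of the canonical start, if present)
    utr5_seq = variant_seq[:start_idx] if start_idx is not None else ""
    uorfs = detect_uorfs(utr5_seq)

    if orf.start_lost or orf.stop_class == "none_found" or start_idx is None:
        return NmdFeatureReport(name, uorfs.uorf_count, 0, False, False)

    stop_end_idx = start_idx + 3 * orf.protein_length_aa + 3
    utr3_len = len(variant_seq) - stop_end_idx

    gpos = chain_genomic_positions(form.chain)
    stop_last_g = gpos[stop_end_idx - 1]
    cov = merge_coverage(form.chain)
    intron_3utr = False
    for a, b in model.introns:
        spliced_out = not any(max(a, x) < min(b, y) for x, y in cov)
        if spliced_out and a > stop_last_g:
            intron_3utr = True
            break

    return NmdFeatureReport(
        form_name=name,
        uorf_count=uorfs.uorf_count,
        utr3_len=utr3_len,
        long_3utr=utr3_len > long_3utr_threshold,
        intron_in_3utr=intron_3utr,
    )
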