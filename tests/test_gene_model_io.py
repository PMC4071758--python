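"""Gene-model loading, intron derivation, CDS extraction, serialization."""

import warnings

import pytest

from splicefate.gene_model_io import (
    ConsistencyError,
    GeneModel,
    NotFoundError,
    ValidationError,
    derive_introns,
    extract_spliced_cds,
    load_gene_model,
    write_gene_model,
    write_reports,
)
from splicefate.splice_classification import SpliceEvent, TranscriptForm
from splicefate.synthetic_data import SyntheticSpec, apply_events, gen_gene_model

from conftest import make_gene_with_offsets


@pytest.mark.parametrize("n_exons,n_introns", [(15, 14), (11, 10), (1, 0)])
def test_exon_intron_architecture(n_exons, n_introns):
    model = gen_gene_model(SyntheticSpec(seed=3, n_exons=n_exons))
    assert len(model.exons) == n_exons
    assert len(model.introns) == n_introns
    assert len(derive_introns(model)) == n_introns


def test_roundtrip_through_gff3_and_fasta(tmp_path, model15):
    gff3, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
    write_gene_model(model15, gff3, fasta)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        reloaded = load_gene_model(gff3, fasta, model15.gene_id)
    assert reloaded.exons == model15.exons
    assert reloaded.cds_span == model15.cds_span
    assert reloaded.strand == model15.strand
    assert reloaded.genomic_seq == model15.genomic_seq


def test_minus_strand_twin_gives_identical_introns(tmp_path):
    plus = gen_gene_model(SyntheticSpec(seed=21, n_exons=8, strand="+"))
    minus = gen_gene_model(SyntheticSpec(seed=21, n_exons=8, strand="-"))
    assert plus.genomic_seq == minus.genomic_seq  # same oriented content
    for m, tag in ((plus, "p"), (minus, "m")):
        write_gene_model(m, tmp_path / f"{tag}.gff3", tmp_path / f"{tag}.fasta")
    # the two files differ on disk (minus twin is reverse-complemented) ...
    p_seq = (tmp_path / "p.fasta").read_text().splitlines()
    m_seq = (tmp_path / "m.fasta").read_text().splitlines()
    assert p_seq[1:] != m_seq[1:]
    # ... but reload to identical transcript-oriented structure
    rp = load_gene_model(tmp_path / "p.gff3", tmp_path / "p.fasta", plus.gene_id)
    rm = load_gene_model(tmp_path / "m.gff3", tmp_path / "m.fasta", minus.gene_id)
    assert derive_introns(rp) == derive_introns(rm)
    assert rp.canonical_cds() == rm.canonical_cds()


@pytest.mark.parametrize(
    "offset,phase", [(54, 0), (52, 1), (53, 2)]
)
def test_first_intron_offset_and_phase(offset, phase):
    model = make_gene_with_offsets([offset])
    (rec,) = derive_introns(model)
    assert rec.cds_offset == offset
    assert rec.phase == phase


def test_intron_offsets_strictly_increase(model15):
    recs = derive_introns(model15)
    assert len(recs) == 14
    offsets = [r.cds_offset for r in recs]
    assert offsets == sorted(set(offsets))
    assert all(r.phase == r.cds_offset % 3 for r in recs)


def test_coding_contributions_sum_to_cds_length(model15, model11):
    for model in (model15, model11):
        cs, ce = model.cds_span
        off = 0
        total = 0
        for a, b in model.exons:
            lo, hi = max(cs, off), min(ce, off + (b - a))
            total += max(0, hi - lo)
            off += b - a
        assert total == model.cds_length
        assert len(derive_introns(model)) == len(model.exons) - 1


def test_utr3_intron_is_counted_not_projected():
    model = gen_gene_model(SyntheticSpec(seed=9, n_exons=5, utr3_intron=True))
    assert len(model.exons) == 6  # extra 3'UTR exon
    assert model.utr_introns_3 == 1
    assert len(derive_introns(model)) == 4  # CDS introns only


class TestExtractSplicedCds:
    def test_canonical_chain_yields_exact_cds(self, model_noutr):
        res = extract_spliced_cds(model_noutr, model_noutr.exons)
        assert not res.start_lost
        assert res.seq == model_noutr.canonical_cds()
        assert len(res.seq) % 3 == 0

    def test_intron_retention_adds_intron_length(self, model_noutr):
        form = apply_events(model_noutr, [("IR", 2)])
        ilen = model_noutr.introns[1][1] - model_noutr.introns[1][0]
        res = extract_spliced_cds(model_noutr, form.chain)
        assert len(res.seq) == model_noutr.cds_length + ilen

    def test_exon_skip_removes_exon_length(self, model_noutr):
        form = apply_events(model_noutr, [("ES", 3)])
        elen = model_noutr.exons[2][1] - model_noutr.exons[2][0]
        res = extract_spliced_cds(model_noutr, form.chain)
        assert len(res.seq) == model_noutr.cds_length - elen

    def test_start_exon_missing_sets_flag(self, model_noutr):
        form = apply_events(model_noutr, [("ES", 1)])
        res = extract_spliced_cds(model_noutr, form.chain)
        assert res.start_lost

    def test_out_of_bounds_chain_raises(self, model_noutr):
        from splicefate.gene_model_io import RangeError

        with pytest.raises(RangeError):
            extract_spliced_cds(model_noutr, [(0, len(model_noutr.genomic_seq) + 50)])


class TestLoadErrors:
    def test_missing_gene_id(self, tmp_path, model11):
        write_gene_model(model11, tmp_path / "g.gff3", tmp_path / "g.fasta")
        with pytest.raises(NotFoundError):
            load_gene_model(tmp_path / "g.gff3", tmp_path / "g.fasta", "nope")

    def test_cds_not_codon_multiple(self, tmp_path, model11):
        gff3, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        write_gene_model(model11, gff3, fasta)
        lines = gff3.read_text().splitlines()
        # shrink the last CDS feature by 1 nt
        for i in range(len(lines) - 1, -1, -1):
            parts = lines[i].split("\t")
            if len(parts) > 4 and parts[2] == "CDS":
                parts[4] = str(int(parts[4]) - 1)
                lines[i] = "\t".join(parts)
                break
        gff3.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError, match=model11.gene_id):
            load_gene_model(gff3, fasta, model11.gene_id)

    def test_overlapping_exons(self, tmp_path, model11):
        gff3, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        write_gene_model(model11, gff3, fasta)
        lines = gff3.read_text().splitlines()
        exon_idx = [i for i, l in enumerate(lines) if "\texon\t" in l]
        parts = lines[exon_idx[0]].split("\t")
        parts[4] = str(int(parts[4]) + 400)  # run into the next exon
        lines[exon_idx[0]] = "\t".join(parts)
        gff3.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValidationError):
            load_gene_model(gff3, fasta, model11.gene_id)


def test_canonical_mrna_is_longest_cds_then_lexicographic(tmp_path, model_noutr):
    gff3, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
    # second mRNA with a shorter CDS (one exon dropped)
    short_chain = model_noutr.exons[:-1]
    write_gene_model(
        model_noutr, gff3, fasta,
        extra_mrnas=[("gnoutr.alt", short_chain, None)],
    )
    loaded = load_gene_model(gff3, fasta, model_noutr.gene_id)
    assert loaded.exons == model_noutr.exons  # longest-CDS mRNA won


def test_model_invariant_violations_fail_closed():
    with pytest.raises(ValidationError):
        GeneModel("bad", "sp", "+", [(0, 10), (5, 20)], (0, 9), "A" * 30)
    with pytest.raises(ValidationError):  # CDS not codon multiple
        GeneModel("bad", "sp", "+", [(0, 30)], (0, 10), "A" * 30)
    with pytest.raises(ValidationError):  # sub-minimum intron
        GeneModel("bad", "sp", "+", [(0, 30), (35, 65)], (0, 60), "A" * 70)


class TestWriteReports:
    def _named(self, gene_id, events=()):
        return TranscriptForm(
            gene_id=gene_id, chain=[(0, 10)], events=list(events), form_name="α"
        )

    def test_single_alpha_row_empty_events(self, tmp_path):
        from splicefate.orf_ptc import OrfReport

        f = self._named("g1")
        rep = OrfReport("α", 100, False, "canonical", 0, True)
        paths = write_reports([f], {"α": rep}, None, tmp_path)
        lines = paths["forms"].read_text().splitlines()
        assert len(lines) == 2
        assert lines[1].split("\t")[2] == ""

    def test_ir_event_rendered_with_intron_anchor(self, tmp_path):
        from splicefate.orf_ptc import OrfReport

        f = TranscriptForm(
            gene_id="g1", chain=[(0, 10)],
            events=[SpliceEvent("IR", 8, 112)], form_name="β",
        )
        rep = OrfReport("β", 50, True, "premature", -50, False)
        paths = write_reports([f], {"β": rep}, None, tmp_path)
        assert "IR:intron8" in paths["forms"].read_text()

    def test_id_mismatch_raises(self, tmp_path):
        from splicefate.orf_ptc import OrfReport

        f = self._named("g1")
        rep = OrfReport("γ", 100, False, "canonical", 0, True)
        with pytest.raises(ConsistencyError):
            write_reports([f], {"γ": rep}, None, tmp_path)

    def test_identical_genes_identical_matrix_rows(self, tmp_path):
        from splicefate.intron_projection import map_to_alignment, project_gene

        from splicefate.orf_ptc import translate_cds

        model = gen_gene_model(SyntheticSpec(seed=4, n_exons=5, gene_id="a"))
        projections = {"a": project_gene(model), "b": project_gene(model)}
        prot = translate_cds(model.canonical_cds())[0]
        msa = {"a": prot, "b": prot}
        matrix = map_to_alignment(msa, projections, proteins={"a": prot, "b": prot})
        df = matrix.to_dataframe()
        assert list(df.loc["a"]) == list(df.loc["b"])
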