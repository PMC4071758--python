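"""Event taxonomy, Greek naming, tallies, tissue partition, cDNA mapping."""

import random

import pytest

from splicefate.gene_model_io import chain_length, merge_coverage
from splicefate.splice_classification import (
    NovelSegmentError,
    SpliceEvent,
    TranscriptForm,
    assign_form_names,
    classify_form,
    compare_tissues,
    diff_chains,
    map_spliced_to_chain,
    tally_events,
)
from splicefate.synthetic_data import (
    SyntheticSpec,
    _grid_event_specs,
    apply_events,
    gen_gene_model,
)


def _form(gene_id, events, tissues=frozenset()):
    return TranscriptForm(gene_id=gene_id, chain=[(0, 10)], events=events, tissues=tissues)


class TestDiffChains:
    def test_identity_chain_all_spliced_present(self, model15):
        d = diff_chains(model15, model15.exons)
        assert all(s.spliced for s in d.introns)
        assert all(s.present for s in d.exons)

    def test_verbatim_intron_8_is_retained(self, model15):
        form = apply_events(model15, [("IR", 8)])
        d = diff_chains(model15, form.chain)
        assert d.introns[7].retained
        assert sum(s.retained for s in d.introns) == 1

    def test_missing_exon_2_is_absent(self, model15):
        form = apply_events(model15, [("ES", 2)])
        d = diff_chains(model15, form.chain)
        assert d.exons[1].absent
        assert sum(s.absent for s in d.exons) == 1

    def test_internal_intron_fragment_is_out_of_taxonomy(self, model15):
        a, b = model15.introns[4]
        chain = sorted(model15.exons + [(a + 5, b - 5)])
        with pytest.raises(NovelSegmentError):
            diff_chains(model15, chain)

    def test_overlapping_chain_segments_rejected(self, model15):
        from splicefate.gene_model_io import ValidationError

        bad = [model15.exons[0], (model15.exons[0][0] + 2, model15.exons[0][1] + 2)]
        with pytest.raises(ValidationError):
            diff_chains(model15, bad)


class TestClassifyForm:
    def test_single_intron_retention(self, model15):
        form = apply_events(model15, [("IR", 3)])
        ilen = model15.introns[2][1] - model15.introns[2][0]
        assert classify_form(model15, form.chain) == [SpliceEvent("IR", 3, ilen)]

    def test_acceptor_shift_into_downstream_exon(self, model15):
        form = apply_events(model15, [("Alt3SS", 5, -12)])
        assert classify_form(model15, form.chain) == [SpliceEvent("Alt3SS", 5, -12)]

    def test_skip_plus_trimmed_next_exon_is_one_form_two_events(self, model11):
        form = apply_events(model11, [("ES", 3), ("Alt3SS", 3, -9)])
        events = classify_form(model11, form.chain)
        elen = model11.exons[2][1] - model11.exons[2][0]
        assert events == [SpliceEvent("ES", 3, -elen), SpliceEvent("Alt3SS", 3, -9)]

    def test_partial_inclusion_both_sides_of_one_intron(self, model11):
        form = apply_events(model11, [("Alt5SS", 4, 6), ("Alt3SS", 4, 9)])
        assert classify_form(model11, form.chain) == [
            SpliceEvent("Alt5SS", 4, 6),
            SpliceEvent("Alt3SS", 4, 9),
        ]

    @pytest.mark.parametrize("n_exons", [5, 11, 15])
    def test_round_trip_recovery_over_event_grid(self, n_exons):
        """apply_events -> classify_form recovers (type, anchor, delta) exactly."""
        n_cases = 0
        for seed in range(12):
            model = gen_gene_model(SyntheticSpec(seed=seed, n_exons=n_exons))
            rng = random.Random(seed * 7919 + n_exons)
            for especs in _grid_event_specs(model, rng, include_pairs=True):
                form = apply_events(model, especs)
                assert classify_form(model, form.chain) == form.events
                n_cases += 1
        assert n_cases == 12 * 12

    def test_length_conservation(self, model15):
        rng = random.Random(99)
        for especs in _grid_event_specs(model15, rng, include_pairs=True):
            form = apply_events(model15, especs)
            delta = sum(ev.delta_nt for ev in form.events)
            assert chain_length(form.chain) == model15.spliced_length + delta


class TestNaming:
    def test_canonical_only_is_alpha(self):
        named = assign_form_names([_form("g", [])])
        assert [f.form_name for f in named] == ["α"]

    def test_sorted_by_anchor(self):
        forms = [
            _form("g", []),
            _form("g", [SpliceEvent("IR", 3, 100)]),
            _form("g", [SpliceEvent("IR", 1, 80)]),
        ]
        named = assign_form_names(forms)
        by_name = {f.form_name: f for f in named}
        assert by_name["β"].events[0].anchor == 1
        assert by_name["γ"].events[0].anchor == 3

    def test_naming_invariant_under_permutation(self):
        forms = [
            _form("g", []),
            _form("g", [SpliceEvent("IR", 2, 90)]),
            _form("g", [SpliceEvent("ES", 2, -60)]),
            _form("g", [SpliceEvent("Alt5SS", 2, 12)]),
            _form("g", [SpliceEvent("IR", 5, 70)]),
        ]
        ref = {
            tuple((e.type, e.anchor) for e in f.events): f.form_name
            for f in assign_form_names(forms)
        }
        rng = random.Random(0)
        for _ in range(10):
            shuffled = forms[:]
            rng.shuffle(shuffled)
            got = {
                tuple((e.type, e.anchor) for e in f.events): f.form_name
                for f in assign_form_names(shuffled)
            }
            assert got == ref

    def test_duplicate_forms_merge_tissues(self):
        ev = [SpliceEvent("IR", 4, 120)]
        forms = [
            _form("g", []),
            _form("g", ev, frozenset({"generative"})),
            _form("g", ev, frozenset({"vegetative"})),
        ]
        named = assign_form_names(forms)
        assert len(named) == 2
        beta = next(f for f in named if f.form_name == "β")
        assert beta.tissues == {"generative", "vegetative"}

    def test_requires_one_canonical(self):
        from splicefate.gene_model_io import ValidationError

        with pytest.raises(ValidationError):
            assign_form_names([_form("g", [SpliceEvent("IR", 1, 50)])])


class TestTally:
    def test_ath_spo11_1_composition(self):
        """Five IR singles + one alt5 + one alt3 + one alt3-with-IR: 8 total."""
        forms = [_form("g", [])]
        for i in range(1, 6):
            forms.append(_form("g", [SpliceEvent("IR", i, 50 + i)]))
        forms.append(_form("g", [SpliceEvent("Alt5SS", 7, 15)]))
        forms.append(_form("g", [SpliceEvent("Alt3SS", 9, -21)]))
        forms.append(_form("g", [SpliceEvent("IR", 11, 88), SpliceEvent("Alt3SS", 12, 6)]))
        tally = tally_events(assign_form_names(forms))
        assert tally.total_noncanonical == 8
        assert tally.ir_only_forms == 5
        assert tally.per_event["IR"] == 6  # the combination counts per event
        assert tally.per_form["IR"] == 6

    def test_alpha_only_total_zero(self):
        tally = tally_events(assign_form_names([_form("g", [])]))
        assert tally.total_noncanonical == 0
        assert all(v == 0 for v in tally.per_event.values())


class TestCompareTissues:
    def test_three_way_partition(self):
        forms = [
            _form("g", []),
            _form("g", [SpliceEvent("IR", 1, 50)], frozenset({"generative"})),
            _form("g", [SpliceEvent("IR", 2, 50)], frozenset({"vegetative"})),
            _form("g", [SpliceEvent("IR", 3, 50)], frozenset({"generative", "vegetative"})),
        ]
        named = assign_form_names(forms)
        part = compare_tissues(named)
        assert part["both"] == {"δ"}
        assert part["generative_only"] == {"β"}
        assert part["vegetative_only"] == {"γ"}

    def test_partition_sizes_sum_to_total(self):
        rng = random.Random(5)
        tissues = [
            frozenset({"generative"}),
            frozenset({"vegetative"}),
            frozenset({"generative", "vegetative"}),
        ]
        forms = [_form("g", [])]
        for i in range(1, 15):
            forms.append(_form("g", [SpliceEvent("IR", i, 40 + i)], rng.choice(tissues)))
        named = assign_form_names(forms)
        part = compare_tissues(named)
        assert sum(len(v) for v in part.values()) == 14

    def test_untagged_form_excluded_with_warning(self):
        forms = [_form("g", []), _form("g", [SpliceEvent("IR", 1, 50)])]
        named = assign_form_names(forms)
        with pytest.warns(UserWarning, match="no tissue tag"):
            part = compare_tissues(named)
        assert sum(len(v) for v in part.values()) == 0


class TestSplicedFastaMapping:
    @pytest.mark.parametrize("n_exons", [6, 11])
    def test_cdna_of_variant_maps_back_to_its_chain(self, n_exons):
        from splicefate.gene_model_io import spliced_sequence

        for seed in range(8):
            model = gen_gene_model(SyntheticSpec(seed=seed + 100, n_exons=n_exons))
            rng = random.Random(seed)
            for especs in _grid_event_specs(model, rng, include_pairs=False):
                form = apply_events(model, especs)
                cdna = spliced_sequence(model.genomic_seq, form.chain)
                chain = map_spliced_to_chain(model, cdna)
                assert merge_coverage(chain) == merge_coverage(form.chain)
                assert classify_form(model, chain) == form.events

    def test_foreign_cdna_rejected(self, model11):
        from splicefate.gene_model_io import ValidationError

        with pytest.raises(ValidationError):
            map_spliced_to_chain(model11, "ACGT" * 30)
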