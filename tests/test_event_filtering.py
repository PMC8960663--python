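"""Filter chain semantics, the composed-filter oracle, and classification."""

import numpy as np
import pytest

import exonkit as ek
from exonkit.event_filtering import (CASSETTE, BLEEDING, OTHER,
                                     RETAINED_INTRON, ExonCall)

from oracles import brute_force_regions, brute_force_survivors
from scenarios import _random_comparison_table, _survivor_dict


def record(start=100, end=200, strand="+", group="A", replicate=1,
           psi0=0.3, delta=0.2, bf=20.0, event="e"):
    return ek.ComparisonRecord(
        event_id=event, exon=ek.GenomicInterval("c1", start, end, strand),
        gene_id="g1", group=group, replicate=replicate,
        psi_control=psi0, psi_treatment=psi0 + delta, bayes_factor=bf)


class TestFilterBayes:
    def test_threshold_is_strict(self):
        assert ek.filter_bayes([record(bf=10.0)]) == []

    def test_above_threshold_kept(self):
        recs = [record(bf=10.5)]
        assert ek.filter_bayes(recs) == recs

    def test_empty(self):
        assert ek.filter_bayes([]) == []


class TestReconcileReplicates:
    def test_opposite_effects_discarded(self):
        out = ek.reconcile_replicates([
            record(replicate=1, delta=0.3, bf=15),
            record(replicate=2, delta=-0.2, bf=12),
        ])
        assert out.calls == {}
        assert out.discards[0]["reason"] == "opposite-effects"

    def test_one_passing_replicate_suffices(self):
        out = ek.reconcile_replicates([
            record(replicate=1, delta=0.3, bf=15),
            record(replicate=2, delta=0.1, bf=4),
        ])
        (call,) = out.calls.values()
        assert call.direction == "included"
        assert call.consensus_delta_psi == pytest.approx(0.2)

    def test_require_all_reps_tightens(self):
        out = ek.reconcile_replicates([
            record(replicate=1, delta=0.3, bf=15),
            record(replicate=2, delta=0.1, bf=4),
        ], require_all_reps=True)
        assert out.calls == {}

    def test_single_replicate_skipped_direction(self):
        out = ek.reconcile_replicates([record(psi0=0.8, delta=-0.4, bf=20)])
        (call,) = out.calls.values()
        assert call.direction == "skipped"

    def test_zero_delta_is_ambiguous(self):
        out = ek.reconcile_replicates([record(delta=0.0, bf=50)])
        assert out.calls == {}
        assert out.discards[0]["reason"] == "ambiguous-direction"

    def test_mixed_groups_rejected(self):
        with pytest.raises(ValueError):
            ek.reconcile_replicates([record(group="A"), record(group="B")])


def call(start, end, strand="+", direction="included", group="A"):
    return ExonCall(exon=ek.GenomicInterval("c1", start, end, strand),
                    gene_id="g", group=group, direction=direction,
                    consensus_delta_psi=0.2 if direction == "included" else -0.2,
                    n_replicates=2)


def as_set(calls, group="A"):
    s = ek.FilteredEventSet(group=group)
    for c in calls:
        s.calls[c.exon.key] = c
    return s


class TestRemoveRedundantForms:
    def test_short_form_sharing_end_discarded(self):
        # lengths 300 and 120 share their end; 120 < 150 goes
        out = ek.remove_redundant_forms(as_set([call(0, 300), call(180, 300)]))
        assert set(out.calls) == {("c1", 0, 300, "+")}
        assert out.discards[0]["reason"] == "redundant-form"

    def test_form_at_or_above_half_kept(self):
        # lengths 300 and 180 share their start; 180 >= 150 stays
        out = ek.remove_redundant_forms(as_set([call(0, 300), call(0, 180)]))
        assert len(out.calls) == 2

    def test_singleton_kept(self):
        out = ek.remove_redundant_forms(as_set([call(0, 300)]))
        assert len(out.calls) == 1

    def test_different_strand_not_grouped(self):
        out = ek.remove_redundant_forms(
            as_set([call(0, 300, "+"), call(0, 60, "-")]))
        assert len(out.calls) == 2


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        out = ek.deduplicate([call(0, 100), call(0, 100)])
        assert len(out.calls) == 1

    def test_conflicting_directions_removed(self):
        out = ek.deduplicate([call(0, 100, direction="included"),
                              call(0, 100, direction="skipped")])
        assert out.calls == {}

    def test_disjoint_unchanged(self):
        out = ek.deduplicate([call(0, 100), call(200, 300)])
        assert len(out.calls) == 2


class TestCrossGroupDiscard:
    def test_opposite_directions_removed_from_both(self):
        sets = {"A": as_set([call(0, 100, direction="included")], "A"),
                "B": as_set([call(0, 100, direction="skipped", group="B")], "B")}
        out = ek.cross_group_discard(sets)
        assert out["A"].calls == {} and out["B"].calls == {}

    def test_same_direction_kept_in_both(self):
        sets = {"A": as_set([call(0, 100)], "A"),
                "B": as_set([call(0, 100, group="B")], "B")}
        out = ek.cross_group_discard(sets)
        assert len(out["A"].calls) == 1 and len(out["B"].calls) == 1

    def test_single_group_exon_kept(self):
        sets = {"A": as_set([call(0, 100)], "A"), "B": as_set([], "B")}
        out = ek.cross_group_discard(sets)
        assert len(out["A"].calls) == 1


class TestIntersectGroups:
    def test_two_set_example(self):
        sets = {"A": as_set([call(0, 100), call(200, 300)], "A"),
                "B": as_set([call(200, 300, group="B"),
                             call(400, 500, group="B")], "B")}
        table = ek.intersect_groups(sets).set_index("groups")["count"]
        assert table["A"] == 1 and table["B"] == 1 and table["A+B"] == 1

    def test_identical_sets_all_in_intersection(self):
        sets = {"A": as_set([call(0, 100), call(200, 300)], "A"),
                "B": as_set([call(0, 100, group="B"),
                             call(200, 300, group="B")], "B")}
        table = ek.intersect_groups(sets)
        assert table["groups"].tolist() == ["A+B"]
        assert table["count"].tolist() == [2]

    def test_four_random_sets_match_brute_force(self, rng):
        keys = [("c1", int(s), int(s) + 50, "+")
                for s in rng.choice(10_000, size=400, replace=False) * 100]
        sets = {}
        for name in "ABCD":
            chosen = rng.choice(len(keys), size=200, replace=False)
            sets[name] = as_set([call(keys[i][1], keys[i][2]) for i in chosen],
                                name)
        table = ek.intersect_groups(sets)
        got = {tuple(g.split("+")): n
               for g, n in zip(table["groups"], table["count"])}
        want = brute_force_regions(
            {name: s.exon_keys for name, s in sets.items()})
        assert got == want


class TestExpressedExons:
    def test_positive_in_both_controls(self):
        import pandas as pd
        m = ek.CountMatrix(pd.DataFrame(
            {"ctl1": [5, 0, 1], "ctl2": [3, 7, 1]}, index=["a", "b", "c"]))
        assert ek.expressed_exons(m, ["ctl1", "ctl2"]) == {"a", "c"}

    def test_missing_control_sample_errors(self):
        import pandas as pd
        m = ek.CountMatrix(pd.DataFrame({"s1": [1]}, index=["a"]))
        with pytest.raises(KeyError, match="ctlX"):
            ek.expressed_exons(m, ["ctlX"])


class TestComposedFilter:
    def test_matches_brute_force_on_random_tables(self):
        for seed in range(12):
            records = _random_comparison_table(np.random.default_rng(seed))
            assert (_survivor_dict(ek.filter_events(records))
                    == brute_force_survivors(records)), f"seed {seed}"

    def test_reconciliation_monotone_in_threshold(self):
        """Raising the Bayes threshold never adds reconciled exons.

        Monotonicity holds at the evidence-retention stage.  The *composed*
        chain is deliberately not monotone: removing a long exon form at a
        stricter threshold can resurrect a short redundant form (or one side
        of a cross-group conflict) that the long form was suppressing.
        """
        rng = np.random.default_rng(99)
        records = [r for r in _random_comparison_table(rng) if r.group == "A"]
        survivors = None
        for threshold in (0.0, 5.0, 10.0, 20.0, 50.0):
            keys = set(ek.reconcile_replicates(records,
                                               threshold=threshold).calls)
            if survivors is not None:
                assert keys <= survivors
            survivors = keys

    def test_idempotent(self):
        def nonempty(d):
            return {g: calls for g, calls in d.items() if calls}

        for seed in range(6):
            records = _random_comparison_table(np.random.default_rng(seed))
            first = ek.filter_events(records)
            surviving_records = [
                r for s in first.values()
                for c in s.calls.values() for r in c.provenance]
            second = ek.filter_events(surviving_records)
            assert nonempty(_survivor_dict(first)) == \
                nonempty(_survivor_dict(second))


class TestClassifyEvent:
    @pytest.fixture
    def gene(self):
        """Two transcripts: t1 has the middle exon, t2 skips it."""
        def exon(start, end, exon_id, txs):
            return ek.ExonRecord(ek.GenomicInterval("c1", start, end, "+"),
                                 exon_id, "g1", frozenset(txs))
        return [
            exon(100, 200, "e1", ["t1", "t2"]),
            exon(500, 600, "e2", ["t1"]),
            exon(900, 1000, "e3", ["t1", "t2"]),
        ]

    def test_cassette(self, gene):
        models = ek.event_filtering.build_transcript_models(gene)
        assert ek.classify_event(
            ek.GenomicInterval("c1", 500, 600, "+"), "g1", models) == CASSETTE

    def test_retained_intron(self, gene):
        models = ek.event_filtering.build_transcript_models(gene)
        # spans e2 + intron + e3 of t1 exactly
        assert ek.classify_event(
            ek.GenomicInterval("c1", 500, 1000, "+"), "g1",
            models) == RETAINED_INTRON

    def test_bleeding_exon(self, gene):
        models = ek.event_filtering.build_transcript_models(gene)
        # shares only its start with e1, runs 50 bp into the intron
        assert ek.classify_event(
            ek.GenomicInterval("c1", 100, 250, "+"), "g1", models) == BLEEDING

    def test_other(self, gene):
        models = ek.event_filtering.build_transcript_models(gene)
        assert ek.classify_event(
            ek.GenomicInterval("c1", 300, 400, "+"), "g1", models) == OTHER

    def test_unknown_gene_errors(self, gene):
        models = ek.event_filtering.build_transcript_models(gene)
        with pytest.raises(KeyError):
            ek.classify_event(ek.GenomicInterval("c1", 0, 10, "+"), "gX", models)

    def test_synthetic_alternative_exons_are_cassettes(self):
        config = ek.SimulationConfig(seed=5, n_genes=12)
        _, annotation, truth = ek.simulate_genome(config)
        models = ek.event_filtering.build_transcript_models(annotation)
        alt = truth.exons[truth.exons["role"] == "alternative"]
        for row in alt.itertuples(index=False):
            cls = ek.classify_event(
                ek.GenomicInterval(row.chrom, row.start, row.end, row.strand),
                row.gene_id, models)
            assert cls == CASSETTE
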