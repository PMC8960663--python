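"""Planted-structure guarantees of the synthetic-data generator."""

import numpy as np
import pytest

import exonkit as ek
from exonkit.synthetic_data import (LABEL_DISCORDANT, LABEL_INCLUDED,
                                    LABEL_REDUNDANT, LABEL_SKIPPED,
                                    _tri_probability)


SMALL = dict(n_genes=25)


class TestSimulateGenome:
    def test_degenerate_gc_one_makes_pure_gc_exons(self):
        config = ek.SimulationConfig(seed=3, gc_exon_included=1.0, **SMALL)
        genome, _, truth = ek.simulate_genome(config)
        for iv in truth.intervals(label=LABEL_INCLUDED):
            assert set(ek.fetch_oriented(genome, iv)) <= {"G", "C"}

    def test_seed_determinism(self):
        config = ek.SimulationConfig(seed=11, **SMALL)
        g1, a1, t1 = ek.simulate_genome(config)
        g2, a2, t2 = ek.simulate_genome(config)
        assert g1.fetch("chrS1", 0, g1.length("chrS1")) == \
            g2.fetch("chrS1", 0, g2.length("chrS1"))
        assert a1 == a2
        assert t1.exons.equals(t2.exons)

    def test_truth_partitions_annotation(self):
        config = ek.SimulationConfig(seed=4, **SMALL)
        _, annotation, truth = ek.simulate_genome(config)
        assert len(truth.exons) == len(annotation)
        assert set(truth.exons["exon_id"]) == {r.exon_id for r in annotation}
        labels = set(truth.exons["label"])
        assert labels <= {LABEL_INCLUDED, LABEL_SKIPPED, "null",
                          LABEL_DISCORDANT, LABEL_REDUNDANT}

    def test_both_strands_represented(self):
        config = ek.SimulationConfig(seed=4, n_genes=60)
        _, _, truth = ek.simulate_genome(config)
        frac_plus = (truth.exons["strand"] == "+").mean()
        assert 0.3 < frac_plus < 0.7

    def test_chromosome_budget_enforced(self):
        config = ek.SimulationConfig(seed=1, n_genes=50, max_chrom_length=1000)
        with pytest.raises(ValueError, match="budget"):
            ek.simulate_genome(config)

    def test_redundant_decoys_violate_the_length_rule(self):
        config = ek.SimulationConfig(seed=6, n_genes=60,
                                     redundant_form_fraction=0.2)
        _, _, truth = ek.simulate_genome(config)
        decoys = truth.exons[truth.exons["label"] == LABEL_REDUNDANT]
        parents = truth.exons.set_index("exon_id")
        n_affected = (truth.exons["label"].isin([LABEL_INCLUDED,
                                                 LABEL_SKIPPED])).sum()
        assert len(decoys) == round(0.2 * n_affected)
        for row in decoys.itertuples(index=False):
            parent = parents.loc[row.decoy_parent]
            shares = (row.start == parent["start"]) or (row.end == parent["end"])
            assert shares
            assert (row.end - row.start) < 0.5 * (parent["end"] - parent["start"])

    def test_motif_planting_exact_counts(self):
        motif, gc = "TCC", 0.45
        rate = 3 * _tri_probability(motif, gc)
        config = ek.SimulationConfig(
            seed=9, n_genes=200, included_fraction=1.0, skipped_fraction=0.0,
            discordant_fraction=0.0, redundant_form_fraction=0.0,
            gc_exon_included=gc, acceptor_motif=motif, acceptor_motif_rate=rate)
        genome, _, truth = ek.simulate_genome(config)
        affected = truth.intervals(label=LABEL_INCLUDED)
        hits = sum(ek.site_trinucleotides(iv, genome)[0] == motif
                   for iv in affected)
        assert hits == round(rate * len(affected))
        assert truth.exons["acceptor_planted"].sum() > 0


class TestSimulateEvents:
    def test_no_discordance_when_fraction_zero(self):
        config = ek.SimulationConfig(seed=2, discordant_fraction=0.0, **SMALL)
        _, _, truth = ek.simulate_genome(config)
        records = ek.simulate_events(truth, config)
        by_exon_group = {}
        for r in records:
            by_exon_group.setdefault((r.exon.key, r.group), []).append(r.delta_psi)
        for deltas in by_exon_group.values():
            signs = {np.sign(d) for d in deltas}
            assert len(signs) == 1

    def test_included_exons_positive_in_every_replicate(self):
        config = ek.SimulationConfig(seed=2, **SMALL)
        _, _, truth = ek.simulate_genome(config)
        included_keys = {iv.key for iv in truth.intervals(label=LABEL_INCLUDED)}
        for r in ek.simulate_events(truth, config):
            if r.exon.key in included_keys:
                assert r.delta_psi > 0

    def test_discordant_decoys_flip_sign_between_replicates(self):
        config = ek.SimulationConfig(seed=2, discordant_fraction=0.5,
                                     included_fraction=0.2,
                                     skipped_fraction=0.2, **SMALL)
        _, _, truth = ek.simulate_genome(config)
        keys = {iv.key for iv in truth.intervals(label=LABEL_DISCORDANT)}
        assert keys
        records = [r for r in ek.simulate_events(truth, config)
                   if r.exon.key in keys]
        by_eg = {}
        for r in records:
            by_eg.setdefault((r.exon.key, r.group), []).append(r)
        for recs in by_eg.values():
            signs = {np.sign(r.delta_psi) for r in recs}
            assert signs == {-1.0, 1.0}
            assert all(r.bayes_factor > 10 for r in recs)

    def test_every_event_exon_is_annotated(self):
        config = ek.SimulationConfig(seed=8, **SMALL)
        _, annotation, truth = ek.simulate_genome(config)
        keys = {r.interval.key for r in annotation}
        for r in ek.simulate_events(truth, config):
            assert r.exon.key in keys


class TestSimulateCounts:
    def test_poisson_limit_variance_matches_mean(self):
        config = ek.SimulationConfig(seed=3, nb_dispersion=1e-14,
                                     size_factor_range=(1.0, 1.0),
                                     n_hvg=0, n_count_genes=4000)
        counts, _, _ = ek.simulate_counts(config)
        values = counts.counts.to_numpy(dtype=float)
        mean = values.mean(axis=1)
        var = values.var(axis=1, ddof=1)
        keep = mean > 5
        assert np.mean(var[keep] / mean[keep]) == pytest.approx(1.0, abs=0.05)

    def test_size_factor_scales_column_sums(self):
        """Doubling all planted size factors doubles library sizes (20 seeds)."""
        ratios = []
        for seed in range(20):
            base = ek.SimulationConfig(seed=seed, size_factor_range=(1.0, 1.0),
                                       n_count_genes=800)
            double = ek.SimulationConfig(seed=seed, size_factor_range=(2.0, 2.0),
                                         n_count_genes=800)
            c1, _, _ = ek.simulate_counts(base)
            c2, _, _ = ek.simulate_counts(double)
            ratios.append(c2.counts.to_numpy().sum()
                          / c1.counts.to_numpy().sum())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_no_hvg_when_disabled(self):
        config = ek.SimulationConfig(seed=3, n_hvg=0, n_count_genes=500)
        _, _, truth = ek.simulate_counts(config)
        assert truth.genes["hvg"].sum() == 0

    def test_expressed_exons_positive_in_controls(self):
        config = ek.SimulationConfig(seed=3, **SMALL)
        _, annotation, truth = ek.simulate_genome(config)
        _, exon_counts, _ = ek.simulate_counts(config, exons=annotation,
                                               truth=truth)
        controls = [s for s in exon_counts.samples if s.startswith("control")]
        assert ek.expressed_exons(exon_counts, controls) == \
            set(truth.exons["exon_id"])


class TestSimulateSignal:
    def make(self, **kwargs):
        params = {**SMALL, "coverage_gap_fraction": 0.0, **kwargs}
        config = ek.SimulationConfig(seed=5, **params)
        genome, annotation, truth = ek.simulate_genome(config)
        return config, annotation, truth

    def test_zero_amplitude_gives_flat_baseline(self):
        config, annotation, truth = self.make(nucleosome_amplitude=0.0)
        track = ek.simulate_signal(annotation, truth, config)
        starts, ends, values = track.intervals("chrS1")
        assert np.allclose(values, 1.0)

    def test_full_gap_fraction_empties_track(self):
        config, annotation, truth = self.make(coverage_gap_fraction=1.0)
        track = ek.simulate_signal(annotation, truth, config)
        assert track.covered_bases() == 0

    def test_bump_peak_value(self):
        """baseline 1 + amplitude 4 at the bump center gives exactly 5."""
        config, annotation, truth = self.make(nucleosome_amplitude=4.0)
        track = ek.simulate_signal(annotation, truth, config)
        bumps = truth.exons[truth.exons["bump_center"] >= 0]
        assert len(bumps) > 0
        for row in bumps.itertuples(index=False):
            values = track.per_base(row.chrom, row.start, row.end)
            assert np.nanmax(values) == pytest.approx(5.0, abs=1e-9)

    def test_gap_fraction_removes_expected_coverage(self):
        config, annotation, truth = self.make(coverage_gap_fraction=0.25,
                                              nucleosome_amplitude=0.0)
        track = ek.simulate_signal(annotation, truth, config)
        total = max(r.interval.end for r in annotation) + config.intergenic_gap
        assert track.covered_bases() / total == pytest.approx(0.75, abs=0.02)


class TestConfig:
    def test_file_round_trip(self, tmp_path):
        config = ek.SimulationConfig(seed=7, n_genes=42, acceptor_motif="TCC",
                                     acceptor_motif_rate=0.05,
                                     groups=("x", "y", "z"))
        path = tmp_path / "config.txt"
        config.to_file(path)
        assert ek.SimulationConfig.from_file(path) == config

    @pytest.mark.parametrize("kwargs", [
        dict(gc_background=1.5),
        dict(included_fraction=0.7, skipped_fraction=0.7),
        dict(exon_length=(250, 80)),
        dict(exons_per_gene=(2, 4)),
        dict(acceptor_motif="TC"),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ek.SimulationConfig(**kwargs)
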