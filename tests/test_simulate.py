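"""Synthetic-data generator: determinism, planted structure, error paths."""

import dataclasses

import numpy as np
import pytest

from tfrewire.annotation import TargetGroups
from tfrewire.intervals import merge, overlap_pairs
from tfrewire.simulate import (
    GenomeSpec,
    PlacementError,
    SimulationConfig,
    generate_enhancers,
    generate_expression,
    generate_genes,
    generate_genome,
    generate_peaks,
    generate_timecourse,
    simulate_dataset,
)

from conftest import SEED


def small_config(**kw):
    defaults = dict(
        n_genes=60,
        min_tss_spacing=20_000,
        n_enhancers_per_class={"stateA_specific": 30, "stateB_specific": 40,
                               "shared": 30},
        n_peaks_per_condition={"condA": 150, "condB": 300},
        seed=SEED,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_default_single_10mb_chromosome(self):
        g = generate_genome(SimulationConfig())
        assert g.chrom_names == ("chr1",) and g.chrom_lengths == (10_000_000,)

    def test_invalid_length_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(("chr1",), (0,))
        with pytest.raises(ValueError):
            GenomeSpec(("chr1", "chr1"), (10, 10))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(enhancer_composition={
                "condA": {"stateA_specific": 0.9, "stateB_specific": 0.0,
                          "shared": 0.0, "background": 0.0},
            }).validate()


class TestGenes:
    def test_empty_and_unique_ids(self):
        g = GenomeSpec()
        assert generate_genes(g, 0, 1000) == []
        genes = generate_genes(g, 1000, 5000, seed=SEED)
        ids = [x.gene_id for x in genes]
        assert len(set(ids)) == len(ids) == 1000
        assert ids == sorted(ids)

    def test_min_spacing_by_scan(self):
        genes = generate_genes(GenomeSpec(), 100, 50_000, seed=SEED)
        tss = sorted(g.tss for g in genes)
        assert all(b - a >= 50_000 for a, b in zip(tss, tss[1:]))

    def test_infeasible_spacing_errors(self):
        with pytest.raises(PlacementError):
            generate_genes(GenomeSpec(("c",), (1000,)), 10, 200)


class TestEnhancers:
    def test_counts_and_class_exclusivity(self):
        cfg = small_config()
        genome = generate_genome(cfg)
        genes = generate_genes(genome, cfg.n_genes, cfg.min_tss_spacing, seed=1)
        enh = generate_enhancers(genome, genes, cfg, seed=2)
        assert {k: len(v) for k, v in enh.items()} == cfg.n_enhancers_per_class
        all_ivs = [iv for rs in enh.values() for iv in rs]
        assert merge(all_ivs).covered_bases() == sum(iv.length for iv in all_ivs)

    def test_no_enhancer_in_tss_window(self):
        cfg = small_config()
        genome = generate_genome(cfg)
        genes = generate_genes(genome, cfg.n_genes, cfg.min_tss_spacing, seed=1)
        enh = generate_enhancers(genome, genes, cfg, seed=2)
        for rs in enh.values():
            for iv in rs:
                for g in genes:
                    assert not (iv.start < g.tss + cfg.tss_exclusion + 1
                                and g.tss - cfg.tss_exclusion < iv.end), \
                        f"enhancer {iv} within {cfg.tss_exclusion} of TSS {g.tss}"

    def test_impossible_placement_errors(self):
        cfg = small_config(tss_exclusion=10_000_000)
        genome = generate_genome(cfg)
        genes = generate_genes(genome, cfg.n_genes, cfg.min_tss_spacing, seed=1)
        with pytest.raises(PlacementError):
            generate_enhancers(genome, genes, cfg, seed=2, max_tries_per_region=50)


def _composition(cond, **probs):
    base = {"stateA_specific": 0.0, "stateB_specific": 0.0, "shared": 0.0,
            "background": 0.0}
    base.update(probs)
    return {cond: base}


class TestPeaks:
    def _setup(self, cfg):
        genome = generate_genome(cfg)
        genes = generate_genes(genome, cfg.n_genes, cfg.min_tss_spacing, seed=1)
        return genome, generate_enhancers(genome, genes, cfg, seed=2)

    def test_pure_background_never_touches_enhancers(self):
        cfg = small_config(
            enhancer_composition=_composition("condA", background=1.0),
            n_peaks_per_condition={"condA": 200},
        )
        genome, enh = self._setup(cfg)
        reps = generate_peaks(genome, enh, cfg, "condA", seed=3)
        all_enh = merge([iv for rs in enh.values() for iv in rs])
        for rep in reps:
            assert overlap_pairs(rep, all_enh) == []

    def test_pure_class_always_overlaps(self):
        cfg = small_config(
            enhancer_composition=_composition("condA", stateB_specific=1.0),
            n_peaks_per_condition={"condA": 200},
        )
        genome, enh = self._setup(cfg)
        reps = generate_peaks(genome, enh, cfg, "condA", seed=3)
        for rep in reps:
            hit = {a for a, _, _ in overlap_pairs(rep, enh["stateB_specific"])}
            assert len(hit) == len(rep)

    def test_realised_fraction_near_planted(self):
        cfg = small_config(
            enhancer_composition=_composition(
                "condA", stateB_specific=0.74, background=0.26
            ),
            n_peaks_per_condition={"condA": 2000},
        )
        genome, enh = self._setup(cfg)
        [rep1, _] = generate_peaks(genome, enh, cfg, "condA", seed=3)
        hit = {a for a, _, _ in overlap_pairs(rep1, enh["stateB_specific"])}
        assert abs(len(hit) / len(rep1) - 0.74) < 0.03

    def test_empty_class_with_probability_errors(self):
        cfg = small_config(
            n_enhancers_per_class={"stateA_specific": 0, "stateB_specific": 5,
                                   "shared": 5},
            enhancer_composition=_composition("condA", stateA_specific=1.0),
            n_peaks_per_condition={"condA": 10},
        )
        genome, enh = self._setup(cfg)
        with pytest.raises(ValueError, match="empty enhancer class"):
            generate_peaks(genome, enh, cfg, "condA", seed=3)


class TestExpression:
    def _groups(self, genes, n1=10, n2=10, ns=10):
        ids = [g.gene_id for g in genes]
        return TargetGroups(frozenset(ids[:n1]),
                            frozenset(ids[n1:n1 + n2]),
                            frozenset(ids[n1 + n2:n1 + n2 + ns]))

    def test_zero_noise_exact_delta(self):
        cfg = small_config(noise_sd=0.0,
                           effect_sizes={"cond1_specific": 1.0,
                                         "cond2_specific": 0.0, "shared": 0.0})
        genes = generate_genes(generate_genome(cfg), 50, 20_000, seed=1)
        groups = self._groups(genes)
        et = generate_expression(genes, groups, cfg, seed=4)
        lfc = et.log2fc()
        assert (lfc.loc[sorted(groups.cond1_specific)] == 1.0).all()
        assert (lfc.loc[sorted(groups.cond2_specific)] == 0.0).all()

    def test_null_group_mean_clt_bound(self):
        cfg = small_config(n_genes=500, min_tss_spacing=10_000,
                           effect_sizes={"cond1_specific": 0.0,
                                         "cond2_specific": 0.0, "shared": 0.0})
        genes = generate_genes(generate_genome(cfg), 500, 10_000, seed=1)
        groups = self._groups(genes, 200, 0, 0)
        et = generate_expression(genes, groups, cfg, seed=4)
        m = et.log2fc().loc[sorted(groups.cond1_specific)].mean()
        assert abs(m) < 3 * cfg.noise_sd / np.sqrt(200)

    def test_unknown_gene_errors(self):
        cfg = small_config()
        genes = generate_genes(generate_genome(cfg), 20, 20_000, seed=1)
        groups = TargetGroups(frozenset({"not_a_gene"}), frozenset(), frozenset())
        with pytest.raises(ValueError, match="unknown genes"):
            generate_expression(genes, groups, cfg, seed=4)

    def test_deterministic_under_seed(self):
        cfg = small_config()
        genes = generate_genes(generate_genome(cfg), 50, 20_000, seed=1)
        groups = self._groups(genes)
        a = generate_expression(genes, groups, cfg, seed=4)
        b = generate_expression(genes, groups, cfg, seed=4)
        assert a.data.equals(b.data)

    def test_timecourse_directions(self):
        cfg = small_config(noise_sd=0.0)
        genes = generate_genes(generate_genome(cfg), 30, 20_000, seed=1)
        groups = self._groups(genes)
        et = generate_timecourse(genes, groups, cfg, n_timepoints=5, seed=4)
        tpm = et.tpm_matrix()
        down = tpm.loc[sorted(groups.cond1_specific)].mean(axis=0)
        up = tpm.loc[sorted(groups.cond2_specific)].mean(axis=0)
        assert down.iloc[-1] < down.iloc[0]
        assert up.iloc[-1] > up.iloc[0]


class TestDataset:
    def test_same_seed_identical_different_seed_not(self):
        cfg = small_config()
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.genes == b.genes
        for cond in a.replicate_peaks:
            for ra, rb in zip(a.replicate_peaks[cond], b.replicate_peaks[cond]):
                assert ra.intervals == rb.intervals
        c = simulate_dataset(dataclasses.replace(cfg, seed=SEED + 1))
        assert a.replicate_peaks["condA"][0].intervals != \
            c.replicate_peaks["condA"][0].intervals
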