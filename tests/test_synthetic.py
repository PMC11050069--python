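import filecmp

import numpy as np
import pytest

from ploidy_consensus.errors import ValidationError
from ploidy_consensus.synthetic import (
    NetworkParams,
    SignatureParams,
    SimulationConfig,
    simulate_cohorts,
    simulate_network,
    simulate_orthologs,
    simulate_signatures,
    write_study,
)

SMALL = dict(
    n_cohorts=3,
    n_genes=300,
    samples_per_group=4,
    n_planted_up=15,
    n_planted_down=15,
    cohort_noise_degs=5,
    species=("human", "mouse", "human"),
    platform_kinds=("intensity", "counts", "counts"),
    network=NetworkParams(n_planted_hubs=4, hub_neighborhood_size=10),
    signatures=SignatureParams(n_signatures=20, min_size=10, max_size=20, n_enriched=4),
)


class TestConfigValidation:
    def test_planted_plus_noise_exceeding_genes_rejected(self):
        with pytest.raises(ValidationError, match="exceed"):
            SimulationConfig(n_genes=100, n_planted_up=60, n_planted_down=50)

    def test_platform_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_cohorts=3, platform_kinds=("counts",))

    def test_hub_neighborhood_exceeding_genes_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(
                n_genes=50,
                n_planted_up=5,
                n_planted_down=5,
                cohort_noise_degs=0,
                network=NetworkParams(hub_neighborhood_size=60),
            )


class TestCohorts:
    def test_ground_truth_sets_disjoint(self):
        _, truth = simulate_cohorts(SimulationConfig(**SMALL, seed=3))
        assert not (truth.planted_up & truth.planted_down)
        for noise in truth.cohort_noise.values():
            assert not (noise & truth.planted_up)
            assert not (noise & truth.planted_down)

    def test_same_seed_identical_matrices(self):
        ds1, _ = simulate_cohorts(SimulationConfig(**SMALL, seed=1))
        ds2, _ = simulate_cohorts(SimulationConfig(**SMALL, seed=1))
        for a, b in zip(ds1, ds2):
            assert a.matrix.equals(b.matrix)

    def test_different_seed_different_matrices(self):
        ds1, _ = simulate_cohorts(SimulationConfig(**SMALL, seed=1))
        ds2, _ = simulate_cohorts(SimulationConfig(**SMALL, seed=2))
        assert not ds1[0].matrix.equals(ds2[0].matrix)

    def test_mouse_cohort_uses_mouse_namespace(self):
        ds, _ = simulate_cohorts(SimulationConfig(**SMALL, seed=1))
        assert all(g.startswith("M") for g in ds[1].matrix.index)
        assert all(g.startswith("G") for g in ds[0].matrix.index)

    def test_planted_genes_shift_in_stated_direction_every_cohort(self):
        cfg = SimulationConfig(**SMALL, seed=5)
        datasets, truth = simulate_cohorts(cfg)
        ortho = simulate_orthologs(cfg).one_to_one()
        for ds in datasets:
            matrix = ds.matrix
            if ds.species == "mouse":
                keep = [g for g in matrix.index if g in ortho]
                matrix = matrix.loc[keep].rename(index=ortho)
            values = matrix.to_numpy(dtype=float)
            if ds.platform == "counts":
                values = np.log2(values + 0.5)
            dip = [i for i, s in enumerate(matrix.columns)
                   if ds.sample_groups[s] == "diploid"]
            pol = [i for i, s in enumerate(matrix.columns)
                   if ds.sample_groups[s] == "polyploid"]
            diff = values[:, pol].mean(axis=1) - values[:, dip].mean(axis=1)
            gene_index = {g: i for i, g in enumerate(matrix.index)}
            up_shift = np.mean([diff[gene_index[g]] for g in truth.planted_up
                                if g in gene_index])
            down_shift = np.mean([diff[gene_index[g]] for g in truth.planted_down
                                  if g in gene_index])
            assert up_shift > 1.0
            assert down_shift < -1.0

    def test_per_cohort_planted_pvalues_dominate_null(self):
        from scipy.stats import mannwhitneyu

        from ploidy_consensus.diffexp import run_cohort

        cfg = SimulationConfig(**SMALL, seed=7)
        datasets, truth = simulate_cohorts(cfg)
        ds = datasets[0]  # human cohort, direct namespace
        res = run_cohort(ds).set_index("gene_id")
        planted = sorted(truth.planted_up | truth.planted_down)
        null = sorted(set(truth.genes) - set(planted)
                      - set().union(*truth.cohort_noise.values()))
        stat = mannwhitneyu(res.loc[planted, "p"], res.loc[null, "p"],
                            alternative="less")
        assert stat.pvalue < 1e-10


class TestNetwork:
    def test_hubs_have_planted_neighbor_fraction(self):
        cfg = SimulationConfig(**SMALL, seed=2)
        _, truth = simulate_cohorts(cfg)
        graph = simulate_network(cfg, truth)
        for hub in truth.planted_hubs:
            nbrs = set(graph.neighbors(hub))
            assert len(nbrs) == cfg.network.hub_neighborhood_size
            planted = truth.planted_up if hub in truth.hubs_up else truth.planted_down
            frac = len(nbrs & planted) / len(nbrs)
            assert frac == pytest.approx(cfg.network.hub_deg_fraction, abs=0.05)

    def test_all_hubs_degree_above_five(self):
        cfg = SimulationConfig(**SMALL, seed=2)
        _, truth = simulate_cohorts(cfg)
        graph = simulate_network(cfg, truth)
        assert all(graph.degree(h) > 5 for h in truth.planted_hubs)

    def test_seeded_edge_list_identical(self):
        cfg = SimulationConfig(**SMALL, seed=4)
        _, truth = simulate_cohorts(cfg)
        g1 = simulate_network(cfg, truth)
        g2 = simulate_network(cfg, truth)
        assert sorted(map(sorted, g1.edges())) == sorted(map(sorted, g2.edges()))


class TestSignatures:
    def test_enriched_signature_contains_planted_fraction(self):
        cfg = SimulationConfig(**SMALL, seed=6)
        _, truth = simulate_cohorts(cfg)
        sigs = simulate_signatures(cfg, truth)
        for name in truth.enriched_up_signatures:
            members = sigs.sets[name]
            frac = len(members & truth.planted_up) / len(members)
            assert frac > 0.3

    def test_exact_copy_of_planted_up_ranks_first(self):
        from ploidy_consensus.containers import SignatureCollection
        from ploidy_consensus.enrichment import enrich

        cfg = SimulationConfig(**SMALL, seed=8)
        _, truth = simulate_cohorts(cfg)
        sigs = simulate_signatures(cfg, truth)
        sets = dict(sigs.sets)
        sets["exact_copy"] = frozenset(truth.planted_up)
        full, _ = enrich(
            set(truth.planted_up),
            SignatureCollection(sets=sets),
            set(truth.genes),
        )
        assert full.sort_values(["p", "signature"]).iloc[0].signature == "exact_copy"


class TestStudyEmission:
    def test_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(**SMALL, seed=9)
        write_study(cfg, tmp_path / "a")
        write_study(cfg, tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names  # something was written
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert mismatch == [] and errors == []
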