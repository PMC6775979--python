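import dendropy
import numpy as np
import pytest

from featherbiome.dissimilarity import bray_curtis
from featherbiome.ordination import mantel
from featherbiome.cophylogeny import cophenetic_distance
from featherbiome.simulate import (
    SimConfig,
    simulate_bacterial_pool,
    simulate_community,
    simulate_host_trees,
    simulate_mm_dataset,
    simulate_study,
    simulate_trait_reference,
)


class TestHostTrees:
    def test_zero_jitter_identical_copies(self):
        cfg = SimConfig(seed=3, host_tree_jitter=0.0, n_host_trees=5)
        base, trees = simulate_host_trees(cfg)
        ref = base.as_string(schema="newick")
        assert all(t.as_string(schema="newick") == ref for t in trees)

    def test_jittered_copies_unit_height_same_topology(self):
        cfg = SimConfig(seed=4, n_host_trees=20)
        base, trees = simulate_host_trees(cfg)
        tns = base.taxon_namespace
        for t in trees:
            t.calc_node_root_distances()
            h = max(lf.root_distance for lf in t.leaf_node_iter())
            assert h == pytest.approx(1.0, abs=1e-9)
            t2 = dendropy.Tree.get(
                data=t.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            rf = dendropy.calculate.treecompare.symmetric_difference(base, t2)
            assert rf == 0

    def test_seven_tips(self):
        base, trees = simulate_host_trees(SimConfig(seed=5, n_host_trees=2))
        assert len(base.leaf_nodes()) == 7


class TestBacterialPool:
    def test_rate_zero_identical_sequences(self):
        cfg = SimConfig(seed=6, n_otus=12, jc_rate=0.0, min_otu_divergence=0.0)
        _, seqs = simulate_bacterial_pool(cfg)
        vals = set(seqs.seqs.values())
        assert len(vals) == 1

    def test_divergence_tracks_patristic_distance(self):
        cfg = SimConfig(seed=7, n_otus=50, jc_rate=0.1, min_otu_divergence=0.0)
        tree, seqs = simulate_bacterial_pool(cfg)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        ids = list(seqs)
        pat, pdist = [], []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pat.append(pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]]))
                a, b = seqs[ids[i]], seqs[ids[j]]
                pdist.append(sum(x != y for x, y in zip(a, b)) / len(a))
        assert np.corrcoef(pat, pdist)[0, 1] > 0

    def test_minimum_divergence_enforced(self):
        cfg = SimConfig(seed=8, n_otus=40)
        _, seqs = simulate_bacterial_pool(cfg)
        ids = list(seqs)
        min_d = min(
            sum(x != y for x, y in zip(seqs[a], seqs[b])) / cfg.seq_length
            for i, a in enumerate(ids)
            for b in ids[i + 1:]
        )
        assert min_d >= cfg.min_otu_divergence - 1e-12


class TestCommunity:
    def test_row_sums_at_least_depth_min(self, small_study):
        tab = small_study["otu_table"]
        cfg = small_study["config"]
        assert (tab.counts.sum(axis=1) >= cfg.depth_min).all()
        assert tab.counts.shape[0] == 72

    def test_no_structure_means_homogeneous_composition(self):
        cfg = SimConfig(seed=9, n_otus=80, n_host_trees=1,
                        phylosymbiosis_strength=0.0, spatial_strength=0.0,
                        noise_sd=0.0)
        base, _ = simulate_host_trees(cfg)
        tab, meta, _ = simulate_community(cfg, base)
        d = bray_curtis(tab)
        cfg2 = SimConfig(seed=9, n_otus=80, n_host_trees=1,
                         phylosymbiosis_strength=2.0)
        tab2, _, _ = simulate_community(cfg2, base)
        d2 = bray_curtis(tab2)
        # sampling noise only vs strong species structure
        assert d.condensed().mean() < 0.5 * d2.condensed().mean()

    def test_determinism_byte_identical(self):
        cfg = SimConfig(seed=10, n_otus=40, n_host_trees=2)
        s1 = simulate_study(cfg)
        s2 = simulate_study(SimConfig(seed=10, n_otus=40, n_host_trees=2))
        assert s1["otu_table"].counts.to_csv() == s2["otu_table"].counts.to_csv()
        assert s1["metadata"].table.to_csv() == s2["metadata"].table.to_csv()
        assert s1["otu_seqs"].seqs == s2["otu_seqs"].seqs
        assert s1["mm_data"].to_csv() == s2["mm_data"].to_csv()

    def test_mantel_phylosymbiosis_monotone(self):
        """Community-host Mantel r is non-decreasing in the phylosymbiosis
        strength (sign test over replicate seeds)."""
        wins = 0
        n_rep = 6
        for rep in range(n_rep):
            rs = []
            for sigma in (0.0, 2.0):
                cfg = SimConfig(seed=400 + rep, n_otus=60, n_host_trees=1,
                                phylosymbiosis_strength=sigma)
                base, _ = simulate_host_trees(cfg)
                tab, meta, _ = simulate_community(cfg, base)
                d = bray_curtis(tab)
                spmap = dict(zip(meta.sample_ids, meta.species))
                dh = cophenetic_distance(base, spmap).reorder(d.labels)
                rs.append(mantel(dh, d, n_perm=9, seed=rep).statistic)
            wins += rs[1] > rs[0]
        assert wins >= n_rep - 1


class TestTraitReference:
    def test_overlap_fraction(self):
        cfg = SimConfig(seed=12, n_otus=200, n_host_trees=1)
        _, seqs = simulate_bacterial_pool(cfg)
        ref, truth = simulate_trait_reference(cfg, seqs)
        fdb = set(truth.index[truth.is_fdb])
        bpb = set(truth.index[truth.bpb_class != ""])
        n_fdb = len(fdb)
        assert n_fdb == pytest.approx(round(0.122 * 200), abs=1)
        share = len(fdb & bpb) / n_fdb
        assert share == pytest.approx(0.92, abs=1.0 / n_fdb + 1e-9)

    def test_inconsistent_fractions_error(self):
        with pytest.raises(ValueError, match="fractions"):
            cfg = SimConfig(seed=13, frac_bpb=0.05, frac_fdb=0.5,
                            frac_overlap=0.9, n_otus=50)
            _, seqs = simulate_bacterial_pool(cfg)
            simulate_trait_reference(cfg, seqs)


class TestMmDataset:
    def test_within_deviations_sum_zero(self, small_study):
        df = small_study["mm_data"]
        sums = df.groupby("species")["x"].transform("mean")
        dev = df["x"] - sums
        assert abs(dev.groupby(df["species"]).sum()).max() < 1e-10

    def test_null_slopes_give_unstructured_y(self):
        cfg = SimConfig(seed=14, beta_between=0.0, beta_within=0.0,
                        mm_sigma_phylo=0.0, n_host_trees=1, n_otus=30)
        base, _ = simulate_host_trees(cfg)
        tab, meta, _ = simulate_community(cfg, base)
        df, params = simulate_mm_dataset(cfg, meta, base)
        r = np.corrcoef(df["x"], df["y"])[0, 1]
        assert abs(r) < 0.35
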