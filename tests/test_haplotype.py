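"""Haplotype construction, naming, assignment, binary distance, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hdomics import haplotype, synthetic
from hdomics.haplotype import HaplotypeDefinition, HaplotypePanel
from hdomics.synthetic import SimTruth

L = 21


def make_panel(vectors, loci=None):
    """Panel whose chromosomes are the given allele vectors in order."""
    n = len(vectors)
    width = len(vectors[0]) if n else L
    loci = loci or tuple(f"locus{i:02d}" for i in range(width))
    return HaplotypePanel(
        loci=loci, chromosomes=np.array(vectors, dtype=np.int8),
        sample_ids=[f"IND{i // 2}" for i in range(n)],
        phase_index=np.array([1 + i % 2 for i in range(n)], dtype=np.int8))


def vec(*ones):
    v = [0] * L
    for i in ones:
        v[i] = 1
    return tuple(v)


class TestConstruct:
    def test_counting_oracle(self):
        vectors = [vec(0)] * 3 + [vec(1)] * 2 + [vec(2)]
        table = haplotype.construct_haplotypes(make_panel(vectors))
        assert list(table["count"]) == [3, 2, 1]
        np.testing.assert_allclose(table["frequency"], [0.5, 1 / 3, 1 / 6])

    def test_single_chromosome(self):
        table = haplotype.construct_haplotypes(make_panel([vec(5)]))
        assert len(table) == 1
        assert table["frequency"][0] == 1.0

    def test_missing_calls_dropped(self):
        vectors = np.array([list(vec(0)), list(vec(1))], dtype=np.int8)
        vectors[1, 3] = -1
        table = haplotype.construct_haplotypes(make_panel(vectors))
        assert len(table) == 1
        assert table["frequency"][0] == 1.0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            haplotype.construct_haplotypes(make_panel(np.empty((0, L))))

    def test_simulated_frequencies_recovered(self):
        truth = SimTruth(haplotype_frequencies={vec(0): 0.7, vec(1): 0.3})
        panel = synthetic.gen_phased_panel(10000, truth, seed=2)
        table = haplotype.construct_haplotypes(panel)
        top = table.iloc[0]
        assert abs(top["frequency"] - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 10000)


class TestNaming:
    reserved = [HaplotypeDefinition(f"hap.{i + 1}", vec(i)) for i in range(16)]

    def test_most_frequent_novel_gets_next_name(self):
        table = pd.DataFrame([
            {"alleles": vec(18), "count": 5, "frequency": 0.5},
            {"alleles": vec(19), "count": 3, "frequency": 0.3},
            {"alleles": vec(0), "count": 2, "frequency": 0.2},  # reserved hap.1
        ])
        defs = haplotype.name_haplotypes(table, self.reserved)
        names = {d.alleles: d.name for d in defs}
        assert names[vec(18)] == "hap.17"
        assert names[vec(19)] == "hap.18"
        assert names[vec(0)] == "hap.1"

    def test_rare_reserved_vector_keeps_reserved_name(self):
        table = pd.DataFrame([
            {"alleles": vec(18), "count": 99, "frequency": 0.99},
            {"alleles": vec(2), "count": 1, "frequency": 0.01},  # reserved hap.3
        ])
        defs = haplotype.name_haplotypes(table, self.reserved)
        names = {d.alleles: d.name for d in defs}
        assert names[vec(2)] == "hap.3"

    def test_frequency_tie_broken_lexicographically(self):
        a, b = vec(17), vec(20)  # "…010…" sorts before "…001"
        table = pd.DataFrame([
            {"alleles": b, "count": 1, "frequency": 0.5},
            {"alleles": a, "count": 1, "frequency": 0.5},
        ])
        defs = haplotype.name_haplotypes(table, self.reserved)
        names = {d.alleles: d.name for d in defs}
        first = min("".join(map(str, a)), "".join(map(str, b)))
        assert names[a if "".join(map(str, a)) == first else b] == "hap.17"

    def test_duplicate_reserved_vector_rejected(self):
        dup = self.reserved + [HaplotypeDefinition("hap.99", vec(0))]
        with pytest.raises(ValueError):
            haplotype.name_haplotypes(pd.DataFrame(
                [{"alleles": vec(5), "count": 1, "frequency": 1.0}]), dup)

    def test_naming_stable_under_panel_shuffling(self):
        rng = np.random.default_rng(0)
        base = [vec(17)] * 4 + [vec(18)] * 4 + [vec(19)] * 2 + [vec(0)] * 2
        names_runs = []
        for _ in range(5):
            order = rng.permutation(len(base))
            panel = make_panel([base[i] for i in order])
            table = haplotype.construct_haplotypes(panel)
            defs = haplotype.name_haplotypes(table, self.reserved)
            names_runs.append(sorted((d.name, d.alleles) for d in defs))
        assert all(r == names_runs[0] for r in names_runs)


class TestAssignment:
    defs = [HaplotypeDefinition("hap.1", vec(0)),
            HaplotypeDefinition("hap.2", vec(1))]

    def test_homozygous_sample(self):
        panel = make_panel([vec(0), vec(0)])
        out = haplotype.assign_diplotypes(panel, self.defs)
        row = out.iloc[0]
        assert (row["hap1"], row["hap2"]) == ("hap.1", "hap.1")
        assert row["conclusive"]

    def test_novel_phase_is_unassigned_and_inconclusive(self):
        panel = make_panel([vec(0), vec(7)])
        out = haplotype.assign_diplotypes(panel, self.defs)
        row = out.iloc[0]
        assert row["hap1"] == "hap.1"
        assert row["hap2"] == "unassigned"
        assert not row["conclusive"]

    def test_panel_drawn_from_definitions_fully_conclusive(self):
        truth = SimTruth(haplotype_frequencies={vec(0): 0.6, vec(1): 0.4})
        panel = synthetic.gen_phased_panel(400, truth, seed=4)
        out = haplotype.assign_diplotypes(panel, self.defs)
        assert out["conclusive"].all()

    def test_construct_assign_round_trip(self):
        truth = SimTruth(haplotype_frequencies={vec(0): 0.5, vec(1): 0.3,
                                                vec(2): 0.2})
        panel = synthetic.gen_phased_panel(200, truth, seed=5)
        table = haplotype.construct_haplotypes(panel)
        defs = haplotype.name_haplotypes(table, [])
        out = haplotype.assign_diplotypes(panel, defs)
        assert out["conclusive"].all()


class TestBinaryDistance:
    def test_identical_vectors_zero(self):
        defs = [HaplotypeDefinition("a", vec(1)), HaplotypeDefinition("b", vec(1))]
        d = haplotype.binary_distance_matrix(defs)
        assert d.loc["a", "b"] == 0.0

    def test_hand_counted_example(self):
        # [1,0,1,1,0] vs [1,0,0,1,1]: 2 disagreements / union of 4
        a = (1, 0, 1, 1, 0) + (0,) * 16
        b = (1, 0, 0, 1, 1) + (0,) * 16
        defs = [HaplotypeDefinition("a", a), HaplotypeDefinition("b", b)]
        assert haplotype.binary_distance_matrix(defs).loc["a", "b"] == 0.5

    def test_disjoint_alt_sets_distance_one(self):
        defs = [HaplotypeDefinition("a", vec(0)), HaplotypeDefinition("b", vec(1))]
        assert haplotype.binary_distance_matrix(defs).loc["a", "b"] == 1.0

    def test_all_zero_pair_convention(self):
        defs = [HaplotypeDefinition("a", (0,) * L), HaplotypeDefinition("b", (0,) * L)]
        assert haplotype.binary_distance_matrix(defs).loc["a", "b"] == 0.0

    def test_metric_properties_exhaustive_length5(self):
        """Symmetry, identity and triangle inequality for all length-5
        binary vectors (independent hand-rolled distance oracle)."""
        def oracle(a, b):
            diff = sum(1 for x, y in zip(a, b) if x != y)
            union = sum(1 for x, y in zip(a, b) if x or y)
            return 0.0 if union == 0 else diff / union

        vectors = list(itertools.product([0, 1], repeat=5))
        defs = [HaplotypeDefinition(f"h{i}", v) for i, v in enumerate(vectors)]
        d = haplotype.binary_distance_matrix(defs).to_numpy()
        for i, a in enumerate(vectors):
            for j, b in enumerate(vectors):
                assert d[i, j] == pytest.approx(oracle(a, b))
                assert d[i, j] == d[j, i]
        nonzero = [i for i, v in enumerate(vectors) if any(v)]
        for i, j, k in itertools.product(nonzero, repeat=3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


class TestClustering:
    @staticmethod
    def clades():
        defs = []
        blocks = [(0, 7), (7, 14), (14, 21)]
        for b, (lo, hi) in enumerate(blocks):
            for rep in range(4):
                v = [0] * L
                for i in range(lo, hi):
                    v[i] = 1
                defs.append(HaplotypeDefinition(f"c{b}_{rep}", tuple(v)))
        return defs

    def test_dendrogram_leaf_count(self):
        defs = self.clades()
        res = haplotype.cluster_haplotypes(defs, k=3)["all"]
        assert res.newick.count(",") == len(defs) - 1
        assert len(res.labels) == len(defs)

    def test_separated_clades_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        defs = self.clades()
        res = haplotype.cluster_haplotypes(defs, k=3, seed=0)["all"]
        truth = [int(name[1]) for name in res.labels.index]
        assert adjusted_rand_score(truth, res.labels.to_numpy()) == 1.0

    def test_k1_single_cluster(self):
        defs = self.clades()[:5]
        res = haplotype.cluster_haplotypes(defs, k=1)["all"]
        assert set(res.labels) == {0}

    def test_k_exceeding_definitions_rejected(self):
        with pytest.raises(ValueError):
            haplotype.cluster_haplotypes(self.clades()[:2], k=3)

    def test_mutant_partition_clusters_separately(self):
        defs = self.clades()
        mutant = {d.name: d.name.startswith("c2") for d in defs}
        res = haplotype.cluster_haplotypes(defs, k=2, mutant_partition=True,
                                           mutant=mutant)
        assert set(res) == {"normal", "mutant"}
        assert len(res["normal"].labels) == 8
        assert len(res["mutant"].labels) == 4

    def test_newick_parses_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo
        defs = self.clades()
        res = haplotype.cluster_haplotypes(defs, k=3)["all"]
        tree = Phylo.read(StringIO(res.newick), "newick")
        assert tree.count_terminals() == len(defs)


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        truth = SimTruth(haplotype_frequencies={vec(0): 0.5, vec(3): 0.5})
        panel = synthetic.gen_phased_panel(20, truth, seed=6)
        path = tmp_path / "panel.vcf"
        haplotype.write_panel_vcf(panel, path)
        back = haplotype.read_panel_vcf(path)
        assert back.loci == panel.loci
        orig = haplotype.construct_haplotypes(panel)
        redo = haplotype.construct_haplotypes(back)
        pd.testing.assert_frame_equal(orig, redo)

    def test_definitions_tsv_round_trip(self, tmp_path):
        defs = [HaplotypeDefinition("hap.1", vec(0), 0.6),
                HaplotypeDefinition("hap.2", vec(1), 0.4)]
        loci = [f"locus{i:02d}" for i in range(L)]
        path = tmp_path / "defs.tsv"
        haplotype.write_definitions(defs, loci, path)
        back = haplotype.read_reserved_definitions(path)
        assert [(d.name, d.alleles) for d in back] == \
            [(d.name, d.alleles) for d in defs]
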