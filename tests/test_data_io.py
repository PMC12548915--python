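"""Table IO, integration statistics, Butina clustering and cold splits."""

import numpy as np
import pytest

from cypdfi.data_io import (
    DatasetStatistics,
    DfiExample,
    butina_clusters,
    cold_split,
    combine_dci_counts,
    combine_statistics,
    dataset_statistics,
    dci_cell_counts,
    integrate_dci_sources,
    integrate_sources,
    read_dci_table,
    read_dfi_table,
    read_split_spec,
    write_dci_table,
    write_dfi_table,
)
from cypdfi.featurize import CompoundRecord, CompoundRole
from cypdfi.losses import DciLabelMatrix


def _ex(did, dsmi, fid, fsmi, label):
    return DfiExample(
        drug=CompoundRecord(id=did, smiles=dsmi, role=CompoundRole.DRUG),
        food=CompoundRecord(id=fid, smiles=fsmi, role=CompoundRole.FOOD),
        label=label,
    )


class TestDfiTable:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "dfi.tsv"
        examples = [_ex("d1", "CCO", "f1", "CCN", 1), _ex("d2", "c1ccccc1", "f1", "CCN", 0)]
        write_dfi_table(examples, path)
        back = read_dfi_table(path)
        assert len(back) == 2
        assert {(e.drug.id, e.food.id, e.label) for e in back} == {("d1", "f1", 1), ("d2", "f1", 0)}

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("drug_id\tdrug_smiles\tlabel\na\tCCO\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_dfi_table(path)

    def test_non_binary_label_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "drug_id\tdrug_smiles\tfood_id\tfood_smiles\tlabel\n"
            "a\tCCO\tb\tCCN\t1\n"
            "c\tCCO\td\tCCC\t2\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            read_dfi_table(path)

    def test_conflicting_duplicate_pair_raises(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "drug_id\tdrug_smiles\tfood_id\tfood_smiles\tlabel\n"
            "a\tCCO\tb\tCCN\t1\n"
            "a\tOCC\tb\tCCN\t0\n"  # same canonical pair, different label
        )
        with pytest.raises(ValueError, match="conflicting"):
            read_dfi_table(path)

    def test_exact_duplicates_collapse(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "drug_id\tdrug_smiles\tfood_id\tfood_smiles\tlabel\n"
            "a\tCCO\tb\tCCN\t1\n"
            "a\tOCC\tb\tCCN\t1\n"
        )
        assert len(read_dfi_table(path)) == 1


class TestDciTable:
    def test_round_trip_and_missing_semantics(self, tmp_path):
        values = np.full((2, 5), np.nan)
        values[0, 1] = 1.0  # substrate, CYP3A4
        labels = {"c1": DciLabelMatrix(values), "c2": DciLabelMatrix.missing()}
        path = tmp_path / "dci.tsv"
        write_dci_table(labels, path)
        back = read_dci_table(path)
        assert back["c1"].values[0, 1] == 1.0
        assert back["c1"].n_labeled == 1
        assert back["c2"].n_labeled == 0

    def test_bad_value_raises(self, tmp_path):
        path = tmp_path / "dci.tsv"
        path.write_text("compound_id\tcyp3a4_substrate\nc1\tmaybe\n")
        with pytest.raises(ValueError, match="maybe"):
            read_dci_table(path)

    def test_unknown_column_raises(self, tmp_path):
        path = tmp_path / "dci.tsv"
        path.write_text("compound_id\tcyp9z9_substrate\nc1\t1\n")
        with pytest.raises(ValueError, match="unknown"):
            read_dci_table(path)


class TestStatistics:
    def test_printed_dataset_counts(self):
        """The integrated corpus arithmetic: an 18,325 x 8,328 compound grid
        has 152,610,600 possible pairs, and 609,180 observed pairs is a
        sparsity of 0.4% (0.3992)."""
        stats = DatasetStatistics(n_drugs=18325, n_foods=8328, n_pairs=609180, n_pos=169283, n_neg=439897)
        assert stats.possible_pairs == 152_610_600
        assert np.isclose(stats.sparsity_pct, 0.39917, atol=1e-4)
        assert round(stats.sparsity_pct, 1) == 0.4

    def test_degenerate_single_pair(self):
        stats = DatasetStatistics(n_drugs=1, n_foods=1, n_pairs=1, n_pos=1, n_neg=0)
        assert stats.possible_pairs == 1
        assert stats.sparsity_pct == 100.0

    def test_pair_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            DatasetStatistics(n_drugs=1, n_foods=1, n_pairs=3, n_pos=1, n_neg=1)

    def test_disjoint_source_positive_union(self):
        """Disjoint positive sets of 166,662 and 2,621 merge to 169,283."""
        s1 = DatasetStatistics(n_drugs=17541, n_foods=7676, n_pairs=166662, n_pos=166662, n_neg=0)
        s2 = DatasetStatistics(n_drugs=786, n_foods=563, n_pairs=442518, n_pos=2621, n_neg=439897)
        merged = combine_statistics([s1, s2], n_drugs=18325, n_foods=8328)
        assert merged.n_pos == 169_283
        assert merged.n_pairs == 609_180
        assert merged.n_neg == 439_897

    def test_dataset_statistics_identity(self, small_benchmark):
        stats = dataset_statistics(small_benchmark["examples"])
        assert stats.n_pairs == stats.n_pos + stats.n_neg
        assert stats.possible_pairs == stats.n_drugs * stats.n_foods


class TestIntegration:
    def test_merge_disjoint_and_idempotent(self):
        a = [_ex("d1", "CCO", "f1", "CCN", 1)]
        b = [_ex("d2", "CCC", "f2", "CCCl", 0)]
        merged, stats = integrate_sources([("a", a), ("b", b)])
        assert len(merged) == 2
        assert stats["merged"].n_pairs == stats["a"].n_pairs + stats["b"].n_pairs
        again, stats2 = integrate_sources([("m", merged), ("m2", merged)])
        assert {(e.drug.smiles, e.food.smiles, e.label) for e in again} == {
            (e.drug.smiles, e.food.smiles, e.label) for e in merged
        }

    def test_conflict_raises_unless_positive_wins(self):
        a = [_ex("d1", "CCO", "f1", "CCN", 1)]
        b = [_ex("dx", "CCO", "fx", "CCN", 0)]
        with pytest.raises(ValueError, match="conflicting"):
            integrate_sources([("a", a), ("b", b)])
        merged, _ = integrate_sources([("b", b), ("a", a)], positive_wins=True)
        assert merged[0].label == 1

    def test_dci_cell_count_union(self):
        """Disjoint per-cell annotation counts add: 375 + 329 = 704."""
        c1 = np.zeros((2, 5), dtype=int)
        c1[0, 1] = 375
        c2 = np.zeros((2, 5), dtype=int)
        c2[0, 1] = 329
        assert combine_dci_counts([c1, c2])[0, 1] == 704

    def test_dci_source_union_cellwise(self):
        v1 = np.full((2, 5), np.nan)
        v1[0, 0] = 1.0
        v2 = np.full((2, 5), np.nan)
        v2[1, 1] = 0.0
        merged = integrate_dci_sources(
            [("a", {"c": DciLabelMatrix(v1)}), ("b", {"c": DciLabelMatrix(v2)})]
        )
        assert merged["c"].values[0, 0] == 1.0 and merged["c"].values[1, 1] == 0.0
        counts = dci_cell_counts(merged)
        assert counts.sum() == 2


def _compounds(smiles_list):
    return [
        CompoundRecord(id=f"c{i}", smiles=s, role=CompoundRole.DRUG)
        for i, s in enumerate(smiles_list)
    ]


class TestButina:
    def test_all_distant_singletons(self):
        comps = _compounds(["CCO", "c1ccccc1", "ClC(Cl)(Cl)Cl"])
        clusters = butina_clusters(comps, distance_cutoff=0.05)
        assert len(set(clusters.values())) == 3

    def test_identical_compounds_share_cluster(self):
        comps = _compounds(["CCO", "OCC"])
        clusters = butina_clusters(comps, distance_cutoff=0.3)
        assert clusters["c0"] == clusters["c1"]

    def test_matches_reference_implementation_on_toys(self):
        """Cluster memberships agree with the independent sphere-exclusion
        implementation shipped with the fingerprint library."""
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator
        from rdkit.ML.Cluster import Butina as RDButina

        smiles = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "c1ccccc1C", "c1ccccc1CC", "CC(=O)O", "NCCN"]
        comps = _compounds(smiles)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        fps = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
        cutoff = 0.6
        dists = []
        for i in range(1, len(fps)):
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
            dists.extend([1.0 - s for s in sims])
        ref = RDButina.ClusterData(dists, len(fps), cutoff, isDistData=True)
        ref_assign = {}
        for cid, members in enumerate(ref):
            for m in members:
                ref_assign[f"c{m}"] = cid
        ours = butina_clusters(comps, distance_cutoff=cutoff)
        # same partition structure (cluster ids may differ)
        from collections import defaultdict

        def groups(assign):
            g = defaultdict(frozenset)
            out = defaultdict(set)
            for k, v in assign.items():
                out[v].add(k)
            return {frozenset(v) for v in out.values()}

        assert groups(ours) == groups(ref_assign)

    def test_invalid_cutoff_raises(self):
        with pytest.raises(ValueError):
            butina_clusters(_compounds(["CCO"]), distance_cutoff=1.5)


class TestColdSplit:
    def test_no_cold_side_leakage_over_random_datasets(self):
        """Zero drug leakage across partitions for 20 random synthetic
        datasets (the audit the split construction must guarantee)."""
        from cypdfi.synthetic import SyntheticConfig, generate_compound_library, make_benchmark

        rng = np.random.default_rng(0)
        n_split = 0
        for trial in range(20):
            seed = int(rng.integers(0, 10_000))
            drugs = generate_compound_library(12, "drug", seed=seed)
            foods = generate_compound_library(8, "food", seed=seed + 50_000)
            examples = [
                _ex(d.id, d.smiles, f.id, f.smiles, int(rng.integers(2)))
                for d in drugs
                for f in foods
            ]
            mode = "cold_drug" if trial % 2 == 0 else "cold_food"
            try:
                spec = cold_split(examples, mode=mode, seed=seed)
            except ValueError:
                continue  # too few clusters to fill three partitions: a
                # legitimate refusal, not a leak
            n_split += 1
            assert spec.leakage(examples) == 0
            parts = spec.assign(examples)
            assert all(len(v) > 0 for v in parts.values())
        assert n_split >= 10

    def test_single_cluster_cannot_fill_three_partitions(self):
        examples = [_ex(f"d{i}", "CCO", f"f{i}", s, 1) for i, s in enumerate(["CCN", "CCC", "CCCl"])]
        with pytest.raises(ValueError, match="partition"):
            cold_split(examples, mode="cold_drug")

    def test_deterministic_given_seed(self, small_benchmark):
        examples = small_benchmark["examples"]
        a = cold_split(examples, mode="cold_drug", seed=5)
        b = cold_split(examples, mode="cold_drug", seed=5)
        assert a.cluster_of == b.cluster_of
        assert a.partition_of == b.partition_of

    def test_spec_round_trip(self, small_benchmark, tmp_path):
        examples = small_benchmark["examples"]
        spec = cold_split(examples, mode="cold_food", seed=2)
        path = tmp_path / "split.tsv"
        spec.save(path)
        back = read_split_spec(path)
        assert back.mode == "cold_food"
        assert back.cluster_of == spec.cluster_of
        assert back.partition_of == spec.partition_of
        assert back.seed == spec.seed
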