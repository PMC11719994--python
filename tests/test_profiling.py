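"""Potency prediction, cluster-count selection, k-means, SAR summaries,
maximum common substructure, and functional-group detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from ncscreen.fixtures import FixtureSpec, generate_cluster_fixture
from ncscreen.profiling import (
    ClusterAssignment,
    choose_k,
    classify_activity,
    cluster_kmeans,
    cluster_features,
    detect_functional_groups,
    find_mcs,
    predict_potency,
    sar_summary,
    tier_profiles,
)
from ncscreen.qsar import ActivityRecord, QSARConfig, pic50_to_ic50, train_qsar
from .conftest import make_record


class TestActivityClass:
    @pytest.mark.parametrize(
        "pic50,expected",
        [(5.0, "low"), (6.2, "medium"), (7.3, "high"),
         (4.0, "low"), (7.0, "medium"), (5.0001, "medium")],
    )
    def test_boundaries_inclusive_below(self, pic50, expected):
        assert classify_activity(pic50) == expected

    @given(st.floats(min_value=-10, max_value=20, allow_nan=False))
    def test_classes_partition_the_line(self, x):
        cls = classify_activity(x)
        matches = [
            ("low", x <= 5.0),
            ("medium", 5.0 < x <= 7.0),
            ("high", x > 7.0),
        ]
        assert sum(flag for _, flag in matches) == 1
        assert dict(matches)[cls]

    def test_non_finite_rejected(self):
        for bad in (math.nan, math.inf, -math.inf):
            with pytest.raises(ValueError):
                classify_activity(bad)


class TestChooseK:
    def test_recovers_six_separated_blobs(self):
        X, _ = generate_cluster_fixture(FixtureSpec(n_compounds=240, k_blobs=6, seed=0))
        assert choose_k(X, range(2, 11), seed=0).chosen_k == 6

    def test_recovers_two_blobs(self):
        X, _ = generate_cluster_fixture(FixtureSpec(n_compounds=100, k_blobs=2, seed=1))
        assert choose_k(X, range(2, 8), seed=1).chosen_k == 2

    def test_single_blob_flags_no_structure(self, rng):
        X = rng.normal(size=(80, 4))
        result = choose_k(X, range(2, 7), seed=0)
        assert not result.has_structure

    def test_sse_decreases_with_k(self):
        X, _ = generate_cluster_fixture(FixtureSpec(n_compounds=120, k_blobs=4, seed=2))
        table = choose_k(X, range(2, 9), seed=2).table
        assert np.all(np.diff(table["sse"]) <= 1e-6)

    def test_elbow_reported(self):
        X, _ = generate_cluster_fixture(FixtureSpec(n_compounds=150, k_blobs=3, seed=3))
        result = choose_k(X, range(2, 9), seed=3)
        assert result.elbow_k in range(2, 9)

    def test_invalid_k_range_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            choose_k(X, range(2, 20), seed=0)
        with pytest.raises(ValueError):
            choose_k(X, [1, 2], seed=0)


class TestKMeans:
    def test_two_distant_pairs_split(self):
        X = np.array([[0.0, 0], [0.1, 0], [100, 0], [100.1, 0]])
        assignments, _ = cluster_kmeans(X, 2, seed=0)
        labels = [a.cluster for a in assignments]
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_planted_blobs_recovered(self):
        X, truth = generate_cluster_fixture(FixtureSpec(n_compounds=150, k_blobs=3, seed=4))
        assignments, _ = cluster_kmeans(X, 3, seed=4)
        labels = [a.cluster for a in assignments]
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(60, 3))
        a1, sse1 = cluster_kmeans(X, 4, seed=8)
        a2, sse2 = cluster_kmeans(X, 4, seed=8)
        assert [x.cluster for x in a1] == [x.cluster for x in a2]
        assert sse1 == sse2

    def test_every_point_assigned_once(self, rng):
        X = rng.normal(size=(50, 2))
        ids = [f"c{i}" for i in range(50)]
        assignments, _ = cluster_kmeans(X, 3, seed=1, ids=ids)
        assert sorted(a.compound_id for a in assignments) == sorted(ids)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            cluster_kmeans(rng.normal(size=(5, 2)), 1, seed=0)
        with pytest.raises(ValueError):
            cluster_kmeans(rng.normal(size=(3, 2)), 3, seed=0)


class TestSarSummary:
    def _table(self, values):
        cols = ["mol_wt", "log_p", "h_donors", "h_acceptors", "tpsa"]
        return pd.DataFrame(values, columns=cols, index=[f"c{i}" for i in range(len(values))])

    def test_single_cluster_equals_global_stats(self):
        table = self._table([[100, 1, 0, 1, 20], [200, 2, 1, 2, 40], [300, 3, 2, 3, 60]])
        pic50s = {"c0": 5.0, "c1": 6.0, "c2": 7.0}
        assignments = [ClusterAssignment(f"c{i}", 0, 0.0) for i in range(3)]
        stats, _ = sar_summary(assignments, table, pic50s)
        assert stats.loc[0, "mol_wt_mean"] == pytest.approx(200)
        assert stats.loc[0, "pic50_median"] == pytest.approx(6.0)
        assert stats.loc[0, "mol_wt_count"] == 3

    def test_two_cluster_means_match_hand_arithmetic(self):
        table = self._table([[100, 1, 0, 1, 20], [200, 1, 0, 1, 20],
                             [400, 3, 2, 4, 80], [600, 3, 2, 4, 80]])
        pic50s = {f"c{i}": v for i, v in enumerate([5, 5, 8, 9])}
        assignments = [
            ClusterAssignment("c0", 0, 0), ClusterAssignment("c1", 0, 0),
            ClusterAssignment("c2", 1, 0), ClusterAssignment("c3", 1, 0),
        ]
        stats, _ = sar_summary(assignments, table, pic50s)
        by_cluster = stats.set_index("cluster")
        assert by_cluster.loc[0, "mol_wt_mean"] == pytest.approx(150)
        assert by_cluster.loc[1, "mol_wt_mean"] == pytest.approx(500)
        assert by_cluster.loc[1, "pic50_mean"] == pytest.approx(8.5)

    def test_bit_frequency_conservation(self, rng):
        n = 20
        table = self._table(rng.uniform(50, 400, size=(n, 5)))
        pic50s = {f"c{i}": 6.0 for i in range(n)}
        labels = rng.integers(0, 3, size=n)
        assignments = [ClusterAssignment(f"c{i}", int(l), 0.0) for i, l in enumerate(labels)]
        fps = rng.integers(0, 2, size=(n, 64))
        stats, bit_freq = sar_summary(assignments, table, pic50s, fps)
        # per-cluster rows aggregate exactly the cluster's on-bits; columns
        # conserve the global bit counts
        expected_rows = np.array([fps[labels == c].sum() for c in sorted(set(labels))])
        assert np.array_equal(bit_freq.sum(axis=1).to_numpy(), expected_rows)
        assert np.array_equal(bit_freq.sum(axis=0).to_numpy(), fps.sum(axis=0))
        assert stats["mol_wt_count"].sum() == n


class TestMCS:
    def test_identical_molecules(self):
        res = find_mcs(["c1ccccc1", "c1ccccc1"])
        assert res.n_atoms == 6 and res.n_bonds == 6

    def test_benzene_vs_toluene_shares_ring(self):
        res = find_mcs(["c1ccccc1", "Cc1ccccc1"])
        assert res.n_atoms == 6

    def test_methane_vs_ethane_single_carbon(self):
        res = find_mcs(["C", "CC"])
        assert res.n_atoms == 1 and res.n_bonds == 0

    def test_pattern_matches_every_input(self, flavonoids):
        from rdkit import Chem

        mols = [Chem.MolFromSmiles(s) for s in flavonoids.values()]
        res = find_mcs(list(flavonoids.values()))
        patt = Chem.MolFromSmarts(res.smarts)
        assert all(m.HasSubstructMatch(patt) for m in mols)
        assert res.n_atoms <= min(m.GetNumAtoms() for m in mols)

    def test_no_common_substructure_flagged_empty(self):
        res = find_mcs(["C", "O"])
        assert res.is_empty

    def test_requires_two_molecules(self):
        with pytest.raises(ValueError):
            find_mcs(["C"])


class TestFunctionalGroups:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("O=Cc1ccccc1", {"aldehyde", "aromatic"}),        # benzaldehyde
            ("CC(C)=O", {"ketone"}),                          # acetone
            ("OC(=O)c1ccccc1", {"carboxyl", "aromatic"}),     # benzoic acid, not ketone
            ("COc1ccccc1", {"ether", "aromatic"}),            # anisole
            ("CC(=O)OC", set()),                              # methyl acetate: ester O is not an ether
            ("CCO", set()),                                   # ethanol: none of the library groups
        ],
    )
    def test_library_with_exclusions(self, smiles, expected):
        assert detect_functional_groups(smiles) == expected

    def test_extra_patterns(self):
        groups = detect_functional_groups("CCO", extra_patterns={"hydroxyl": "[OX2H]"})
        assert "hydroxyl" in groups


class TestPredictPotency:
    def _fit(self, pic50s, smiles_list, seed=0):
        records = [
            ActivityRecord(make_record(f"t{i}", s), "T", pic50_to_ic50(p), p)
            for i, (s, p) in enumerate(zip(smiles_list, pic50s))
        ]
        return train_qsar(records, QSARConfig(n_estimators=50, k_folds=2, seed=seed)), records

    def test_memorized_point_predicted_closely(self):
        # replicated noise-free measurements let the bootstrap ensemble
        # memorize the training ligand
        smiles = ["c1ccccc1", "CCO", "CC(C)=O", "O=Cc1ccccc1", "OC(=O)c1ccccc1",
                  "COc1ccccc1", "CCCCC", "C1CCCCC1"] * 4
        pic50s = [8.0, 5.0, 5.5, 6.0, 6.5, 7.0, 5.2, 5.8] * 4
        model, _ = self._fit(pic50s, smiles)
        preds, skipped = predict_potency(model, [make_record("q", "c1ccccc1")])
        assert not skipped
        assert abs(preds["q"] - 8.0) < 0.5

    def test_constant_training_gives_constant_predictions(self):
        model, _ = self._fit([6.0] * 6, ["CCO", "CCC", "CCN", "CCCl", "CCBr", "CC"])
        preds, _ = predict_potency(
            model, [make_record("a", "c1ccccc1"), make_record("b", "CCCC")]
        )
        assert all(v == pytest.approx(6.0) for v in preds.values())

    def test_repeated_call_identical(self):
        model, recs = self._fit([5, 6, 7, 8, 6], ["CCO", "CCC", "CCN", "CC", "CCCC"])
        cands = [r.compound for r in recs]
        p1, _ = predict_potency(model, cands)
        p2, _ = predict_potency(model, cands)
        assert p1 == p2

    def test_unfeaturizable_candidate_skipped(self):
        from ncscreen.chem import CompoundRecord

        model, _ = self._fit([5, 6, 7, 8, 6], ["CCO", "CCC", "CCN", "CC", "CCCC"])
        bad = CompoundRecord(id="bad", smiles="xx", canonical_smiles="xx")
        preds, skipped = predict_potency(model, [make_record("ok", "CCO"), bad])
        assert skipped == ["bad"]
        assert set(preds) == {"ok"}


class TestTierProfiles:
    def test_tiers_partition_and_profile(self):
        records = [
            make_record("lo1", "CCO"), make_record("lo2", "CCC"),
            make_record("hi1", "O=Cc1ccccc1"), make_record("hi2", "OC(=O)c1ccccc1"),
        ]
        pic50s = {"lo1": 4.0, "lo2": 4.5, "hi1": 8.0, "hi2": 9.0}
        tiers = tier_profiles(records, pic50s)
        assert set(tiers) == {"low", "high"}
        assert tiers["low"]["n"] == 2 and tiers["high"]["n"] == 2
        assert tiers["high"]["functional_groups"]["aromatic"] == 2
        assert tiers["high"]["mcs"]["n_atoms"] >= 6


class TestClusterFeatures:
    def test_standardized_with_potency_column(self):
        table = pd.DataFrame(
            {"mol_wt": [100.0, 200, 300], "log_p": [1.0, 2, 3], "h_donors": [0, 1, 2],
             "h_acceptors": [1, 2, 3], "tpsa": [20.0, 40, 60]},
            index=["a", "b", "c"],
        )
        X, ids = cluster_features(table, {"a": 5.0, "b": 6.0, "c": 7.0})
        assert ids == ["a", "b", "c"]
        assert X.shape == (3, 6)
        assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
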