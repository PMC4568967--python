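"""Difference/constancy matrices, TOM, module clustering and permutation tests."""

import numpy as np
import pandas as pd
import pytest

from metanetdiff import network, synth, qc
from metanetdiff.data import bio_design
from metanetdiff.exceptions import (AlignmentError, ConfigError, DataError,
                                    InsufficientDataError)

from conftest import make_matrix, simple_design


def adjacency_from_corr(C, label="c", n=24):
    ids = pd.Index([f"F{i:03d}" for i in range(C.shape[0])], name="feature_id")
    return network.ConditionAdjacency(
        label, pd.DataFrame(np.asarray(C, float), index=ids, columns=ids), n)


def pair_adjacency(r_a, r_b, n=24):
    """3-feature adjacencies where features 0 and 1 correlate r_a / r_b."""
    def mk(r):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = r
        return C
    return adjacency_from_corr(mk(r_a), "a", n), adjacency_from_corr(mk(r_b), "b", n)


class TestConditionCorrelations:
    def test_per_level_matrices(self, clean_study):
        _, bd, clean, _ = clean_study
        out = network.condition_correlations(clean, bd, "diet")
        assert set(out) == {"AL", "DR"}
        for adj in out.values():
            C = adj.corr.to_numpy()
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(C), 1.0)
            assert np.abs(C).max() <= 1.0 + 1e-12

    def test_small_level_rejected(self):
        design = simple_design(6, diets=["AL"] * 3 + ["DR"] * 3)
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 6)),
                        sample_ids=design.sample_id.tolist(), scale="centered")
        with pytest.raises(InsufficientDataError):
            network.condition_correlations(m, design, "diet")

    def test_independent_noise_weak_correlations(self):
        rng = np.random.default_rng(1)
        design = simple_design(100, diets=["AL"] * 50 + ["DR"] * 50)
        m = make_matrix(rng.normal(size=(30, 100)),
                        sample_ids=design.sample_id.tolist(), scale="centered")
        out = network.condition_correlations(m, design, "diet")
        C = out["AL"].corr.to_numpy()
        iu = np.triu_indices(30, 1)
        assert np.abs(C[iu]).mean() < 0.2


class TestPairTransforms:
    def test_difference_examples(self):
        a, b = pair_adjacency(1.0, -1.0)
        assert network.difference_matrix(a, b).matrix.iloc[0, 1] == pytest.approx(1.0)
        a, b = pair_adjacency(0.8, 0.0)
        assert network.difference_matrix(a, b).matrix.iloc[0, 1] == \
            pytest.approx(0.032768, abs=1e-12)
        same = adjacency_from_corr(np.eye(4) * 0.4 + 0.6 * np.eye(4))
        d = network.difference_matrix(same, same).matrix.to_numpy()
        np.testing.assert_allclose(d, 0.0)

    @pytest.mark.parametrize("method", ["min-concordant", "signed-sum"])
    def test_constancy_examples(self, method):
        a, b = pair_adjacency(1.0, 1.0)
        assert network.constancy_matrix(a, b, method=method).matrix.iloc[0, 1] \
            == pytest.approx(1.0)
        a, b = pair_adjacency(1.0, -1.0)
        assert network.constancy_matrix(a, b, method=method).matrix.iloc[0, 1] \
            == pytest.approx(0.0)
        a, b = pair_adjacency(0.8, 0.8)
        assert network.constancy_matrix(a, b, method=method).matrix.iloc[0, 1] \
            == pytest.approx(0.262144, abs=1e-12)

    def test_exchange_symmetry_and_exclusivity(self):
        rng = np.random.default_rng(2)
        A = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        B = np.clip(rng.uniform(-1, 1, (6, 6)), -1, 1)
        B = (B + B.T) / 2
        np.fill_diagonal(B, 1.0)
        a, b = adjacency_from_corr(A, "a"), adjacency_from_corr(B, "b")
        for fn in (network.difference_matrix, network.constancy_matrix):
            np.testing.assert_allclose(fn(a, b).matrix, fn(b, a).matrix,
                                       atol=1e-14)
        D = network.difference_matrix(a, b).matrix.to_numpy()
        K = network.constancy_matrix(a, b).matrix.to_numpy()
        assert ((D <= 1) & (D >= 0)).all() and ((K <= 1) & (K >= 0)).all()
        # maximal difference excludes any constancy and conversely
        assert (K[np.isclose(D, 1.0)] < 1e-12).all()

    def test_odd_power_rejected(self):
        a, b = pair_adjacency(0.5, 0.5)
        with pytest.raises(ConfigError):
            network.difference_matrix(a, b, beta_soft=5)

    def test_mismatched_features_rejected(self):
        a, _ = pair_adjacency(0.5, 0.5)
        other = adjacency_from_corr(np.eye(4))
        with pytest.raises(AlignmentError):
            network.difference_matrix(a, other)


class TestTopologicalOverlap:
    def test_empty_and_complete_graphs(self):
        Z = np.zeros((5, 5))
        T = network.topological_overlap(Z)
        assert (T[~np.eye(5, dtype=bool)] == 0).all()
        ones = np.ones((5, 5))
        T = network.topological_overlap(ones)
        np.testing.assert_allclose(T, 1.0)

    def test_hand_computed_four_nodes(self):
        A = np.array([[0.0, 0.5, 0.2, 0.0],
                      [0.5, 0.0, 0.4, 0.1],
                      [0.2, 0.4, 0.0, 0.3],
                      [0.0, 0.1, 0.3, 0.0]])
        T = network.topological_overlap(A)
        k = A.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                expect = (A[i] @ A[:, j] + A[i, j]) / \
                    (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expect, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(DataError):
            network.topological_overlap(np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestClusterModules:
    def _two_blocks(self):
        n = 60
        D = np.full((n, n), 0.9)
        D[:30, :30] = 0.1
        D[30:, 30:] = 0.1
        np.fill_diagonal(D, 0.0)
        rng = np.random.default_rng(3)
        D += rng.uniform(0, 1e-3, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = pd.Index([f"F{i:03d}" for i in range(n)])
        return pd.DataFrame(D, index=ids, columns=ids)

    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        mods = network.cluster_modules(self._two_blocks(), min_size=10)
        truth = [0] * 30 + [1] * 30
        assert len(mods.module_colors) == 2
        assert adjusted_rand_score(truth, mods.labels) == 1.0

    def test_flat_landscape_all_grey(self):
        n = 40
        D = np.full((n, n), 0.7)
        np.fill_diagonal(D, 0.0)
        ids = pd.Index([f"F{i}" for i in range(n)])
        mods = network.cluster_modules(pd.DataFrame(D, index=ids, columns=ids))
        assert mods.sizes == {"grey": n}

    def test_feature_order_invariance(self):
        from sklearn.metrics import adjusted_rand_score
        D = self._two_blocks()
        perm = np.random.default_rng(4).permutation(len(D))
        Dp = D.iloc[perm, perm]
        m1 = network.cluster_modules(D)
        m2 = network.cluster_modules(Dp)
        joined = pd.concat([m1.labels.rename("a"), m2.labels.rename("b")],
                           axis=1)
        assert adjusted_rand_score(joined.a, joined.b) == 1.0

    def test_fewer_features_than_min_size(self):
        D = self._two_blocks().iloc[:5, :5]
        mods = network.cluster_modules(D, min_size=10)
        assert mods.sizes == {"grey": 5}


class TestDispersionTest:
    def test_permutation_floor(self):
        rng = np.random.default_rng(5)
        ids = pd.Index([f"F{i}" for i in range(12)])
        Xa = pd.DataFrame(rng.normal(size=(12, 10)), index=ids)
        Xb = pd.DataFrame(rng.normal(size=(12, 10)), index=ids)
        mods = network.ModuleAssignment(
            labels=pd.Series(["turquoise"] * 12, index=ids),
            sizes={"turquoise": 12})
        out = network.module_dispersion_test(Xa, Xb, mods, n_perm=100, seed=0)
        assert (out.p >= 1 / 101).all()

    def test_nperm_bounds(self):
        ids = pd.Index(["a", "b"])
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 8)), index=ids)
        mods = network.ModuleAssignment(
            labels=pd.Series(["turquoise", "turquoise"], index=ids),
            sizes={"turquoise": 2})
        with pytest.raises(ConfigError):
            network.module_dispersion_test(X, X, mods, n_perm=5)
        with pytest.warns(UserWarning):
            network.module_dispersion_test(X, X.copy(), mods, n_perm=50, seed=0)

    def test_identical_conditions_mostly_nonsignificant(self):
        rng = np.random.default_rng(6)
        ids = pd.Index([f"F{i}" for i in range(60)])
        pooled = rng.normal(size=(60, 48))
        Xa = pd.DataFrame(pooled[:, :24], index=ids)
        Xb = pd.DataFrame(pooled[:, 24:], index=ids)
        labels = pd.Series(np.repeat([c for c in network.MODULE_COLORS[:6]], 10),
                           index=ids)
        mods = network.ModuleAssignment(labels=labels,
                                        sizes=labels.value_counts().to_dict())
        out = network.module_dispersion_test(Xa, Xb, mods, n_perm=200, seed=1)
        assert (out.p >= 0.05).mean() >= 0.8

    def test_planted_differential_module_significant(self, clean_study):
        cfg, bd, clean, truth = clean_study
        members = truth.module_members("M1_DR-only")
        members = members[members.isin(clean.feature_ids)]
        mods = network.ModuleAssignment(
            labels=pd.Series("turquoise", index=pd.Index(members)),
            sizes={"turquoise": len(members)})
        meta = bd.set_index("sample_id")
        cols_al = [s for s in clean.sample_ids if meta.loc[s, "diet"] == "AL"]
        cols_dr = [s for s in clean.sample_ids if meta.loc[s, "diet"] == "DR"]
        sub = clean.subset_features(members)
        out = network.module_dispersion_test(sub.values[cols_al],
                                             sub.values[cols_dr], mods,
                                             n_perm=200, seed=2)
        assert out.p.iloc[0] <= 0.01


class TestCorrelationShift:
    def test_identical_matrices_null(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 24))
        a = adjacency_from_corr(np.corrcoef(X), "a")
        b = adjacency_from_corr(np.corrcoef(X), "b")
        ma, mb, p = network.correlation_shift_test(a, b, n_perm=200, seed=0)
        assert ma == pytest.approx(mb)
        assert p == pytest.approx(1.0)
        assert -1 <= ma <= 1

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for s in range(10):
            z = rng.normal(size=24)
            Xa = np.sqrt(0.2) * z[None, :] + np.sqrt(0.8) * rng.normal(size=(100, 24))
            Xb = rng.normal(size=(100, 24))
            ids = pd.Index([f"F{i}" for i in range(100)])
            a = adjacency_from_corr(np.corrcoef(Xa), "a")
            b = adjacency_from_corr(np.corrcoef(Xb), "b")
            ma, mb, p = network.correlation_shift_test(
                a, b, n_perm=200, seed=s,
                samples_a=pd.DataFrame(Xa, index=ids),
                samples_b=pd.DataFrame(Xb, index=ids))
            hits += (p <= 0.05) and (ma > mb)
        assert hits >= 9

    def test_subset_too_small(self):
        a, b = pair_adjacency(0.5, 0.5)
        with pytest.raises(InsufficientDataError):
            network.correlation_shift_test(a, b, feature_subset=["F000"])


class TestDifferentialSelection:
    def _planted(self):
        C_dr = np.eye(4)
        C_dr[0, 1] = C_dr[1, 0] = 0.9       # pair (0,1) DR-only
        C_dr[2, 3] = C_dr[3, 2] = 0.9       # pair (2,3) both
        C_al = np.eye(4)
        C_al[2, 3] = C_al[3, 2] = 0.9
        return (adjacency_from_corr(C_al, "AL"),
                adjacency_from_corr(C_dr, "DR"))

    def test_classes(self):
        al, dr = self._planted()
        differential, similar = network.differential_feature_selection(al, dr)
        assert set(differential) == {"F000", "F001"}
        assert set(similar) == {"F002", "F003"}

    def test_isolated_feature_in_neither(self):
        # features with no significant partner anywhere are in neither class
        C = np.eye(3)
        a = adjacency_from_corr(C, "a")
        b = adjacency_from_corr(C, "b")
        d, s = network.differential_feature_selection(a, b)
        assert len(d) == 0 and len(s) == 0


class TestAgeTrajectory:
    def test_generator_reproduces_age_correlation_orderings(self):
        """Correlations strengthen with age under DR, weaken under AL."""
        ok = 0
        n_runs = 30
        for seed in range(n_runs):
            cfg = synth.SynthConfig(
                n_features=80, n_bio_reps=12, n_tech_reps=1, ages=(10, 40),
                n_batches=1, frac_diet_affected=0.0, frac_age_affected=0.0,
                frac_missing=0.0, frac_low_snr=0.0, batch_shift_sd=0.0,
                module_specs=(synth.ModuleSpec(40, "both-same-sign", 0.5),),
                corr_age_trend=0.4, seed=seed)
            design = synth.make_design(cfg)
            m, _ = synth.simulate_features(design, cfg)
            cen = qc.center_features(
                qc.collapse_tech_reps(qc.log_transform(m), design))
            bd = bio_design(design)
            means = {}
            for diet in ("DR", "AL"):
                sel = bd[bd.diet == diet]
                sub = cen.subset_samples(sel.sample_id)
                by_age = network.condition_correlations(sub, sel, "age",
                                                        quantile_norm=True)
                for age, adj in by_age.items():
                    C = adj.corr.to_numpy()
                    iu = np.triu_indices(C.shape[0], 1)
                    means[(diet, age)] = C[iu].mean()
            ok += (means[("DR", "40")] > means[("DR", "10")]
                   and means[("AL", "40")] < means[("AL", "10")])
        assert ok / n_runs >= 0.9


class TestExport:
    def test_edge_list_threshold_and_graphml(self, tmp_path):
        C_a = np.eye(3)
        C_a[0, 1] = C_a[1, 0] = 0.8
        C_b = np.eye(3)
        C_b[0, 2] = C_b[2, 0] = -0.7
        a, b = adjacency_from_corr(C_a, "DR"), adjacency_from_corr(C_b, "AL")
        edges = network.edge_list(a, b, threshold=0.5)
        assert len(edges) == 2
        path = tmp_path / "edges.graphml"
        network.write_graphml(edges, path)
        import networkx as nx
        g = nx.read_graphml(path)
        assert g.number_of_edges() == 2
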