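"""Correlation network, adjacency, module detection, eigengenes and
intramodular connectivity."""

import numpy as np
import pandas as pd
import pytest

from omicnet import network as nw
from omicnet import preprocess as pp
from omicnet import simulate as sim
from omicnet.containers import make_matrix


def matrix_from(arr, prefix="F", scale="unit-variance"):
    arr = np.asarray(arr, float)
    df = pd.DataFrame(
        arr,
        index=[f"{prefix}{i:03d}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )
    return make_matrix(df, layer="protein", scale=scale)


def scaled(arr):
    arr = np.asarray(arr, float)
    arr = arr - arr.mean(axis=1, keepdims=True)
    arr = arr / arr.std(axis=1, ddof=1, keepdims=True)
    return matrix_from(arr)


def two_block_matrix(block=12, n=12):
    """Two perfect blocks: within-block |r| = 1, cross-block r = 0."""
    t = np.arange(n, dtype=float)
    p1 = np.cos(2 * np.pi * t / n)
    p2 = np.sin(2 * np.pi * t / n)  # orthogonal to p1 and both mean ~0
    rows = [p1 * (1 + i) for i in range(block)] + [p2 * (1 + i) for i in range(block)]
    return scaled(rows)


class TestCorrelationMatrix:
    def test_equals_cross_product_identity(self, rng):
        m = scaled(rng.standard_normal((8, 10)))
        net = nw.correlation_matrix(m)
        X = m.values.to_numpy()
        assert np.allclose(net.r.to_numpy(), X @ X.T / (10 - 1), atol=1e-9)

    def test_exact_linear_and_antilinear(self):
        m = scaled([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        r = nw.correlation_matrix(m).r.to_numpy()
        assert r[0, 0] == 1.0
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            nw.correlation_matrix(scaled(np.eye(3)[:, :3]))

    def test_sparse_pairs_recorded_missing(self, rng):
        arr = rng.standard_normal((3, 6))
        arr[0, :3] = np.nan
        arr[1, 3:] = np.nan  # features 0 and 1 share no complete samples
        m = matrix_from(arr)
        net = nw.correlation_matrix(m, min_pairs=4)
        assert np.isnan(net.r.iloc[0, 1])
        a = nw.adjacency(net).a
        assert a.iloc[0, 1] == 0.0


class TestAdjacency:
    def test_unsigned_signed_and_power(self):
        m = scaled(np.random.default_rng(0).standard_normal((4, 8)))
        net = nw.correlation_matrix(m)
        net.r.iloc[0, 1] = net.r.iloc[1, 0] = -0.8
        net.r.iloc[2, 3] = net.r.iloc[3, 2] = 0.5
        a = nw.adjacency(net, beta=1).a
        assert a.iloc[0, 1] == pytest.approx(0.8)
        a = nw.adjacency(net, beta=1, signed=True).a
        assert a.iloc[0, 1] == pytest.approx(0.1)
        a = nw.adjacency(net, beta=2).a
        assert a.iloc[2, 3] == pytest.approx(0.25)
        assert (np.diag(a.to_numpy()) == 0).all()

    def test_nonpositive_beta_rejected(self):
        m = scaled(np.random.default_rng(0).standard_normal((3, 6)))
        with pytest.raises(ValueError, match="beta"):
            nw.adjacency(nw.correlation_matrix(m), beta=0)


class TestClusterModules:
    def test_perfect_blocks_recovered_exactly(self):
        m = two_block_matrix()
        net = nw.correlation_matrix(m)
        for part in (nw.cluster_modules(net), nw.cluster_modules(net, m)):
            labels = part.assignments
            assert set(labels.unique()) <= set(nw.MODULE_COLORS)
            first = labels.iloc[:12]
            second = labels.iloc[12:]
            assert first.nunique() == 1 and second.nunique() == 1
            assert first.iloc[0] != second.iloc[0]

    def test_small_block_goes_grey(self):
        t = np.arange(12, dtype=float)
        p1 = np.cos(2 * np.pi * t / 12)
        rows = [p1 * (1 + i) for i in range(5)]
        rng = np.random.default_rng(3)
        rows += [rng.standard_normal(12) for _ in range(20)]
        m = scaled(rows)
        net = nw.correlation_matrix(m)
        part = nw.cluster_modules(net, m, min_size=10)
        assert (part.assignments.iloc[:5] == nw.GREY).all()

    def test_pure_noise_mostly_grey(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = scaled(rng.standard_normal((100, 12)))
            net = nw.correlation_matrix(m)
            part = nw.cluster_modules(net, m)
            fracs.append((part.assignments == nw.GREY).mean())
        assert np.mean(fracs) >= 0.8

    def test_colors_assigned_by_decreasing_size(self):
        t = np.arange(12, dtype=float)
        p1, p2 = np.cos(2 * np.pi * t / 12), np.sin(2 * np.pi * t / 12)
        rows = [p1 * (i + 1) for i in range(15)] + [p2 * (i + 1) for i in range(11)]
        net = nw.correlation_matrix(scaled(rows))
        part = nw.cluster_modules(net, min_size=10)
        assert (part.assignments.iloc[:15] == "turquoise").all()
        assert (part.assignments.iloc[15:] == "blue").all()

    def test_partition_stable_under_feature_permutation(self, rng):
        cfg = sim.study_config(seed=5)
        prot, met, _, _ = sim.generate_dataset(cfg)
        comb = pp.concatenate_layers(
            [pp.normalize_layer(prot, quantile=False),
             pp.normalize_layer(met, quantile=False)]
        )
        perm = rng.permutation(comb.n_features)
        shuffled = comb.with_values(comb.values.iloc[perm])
        a = nw.cluster_modules(nw.correlation_matrix(comb), comb).assignments
        b = nw.cluster_modules(nw.correlation_matrix(shuffled), shuffled).assignments
        assert a.sort_index().equals(b.sort_index())

    def test_invalid_parameters_rejected(self):
        net = nw.correlation_matrix(two_block_matrix())
        with pytest.raises(ValueError, match="min_size"):
            nw.cluster_modules(net, min_size=1)
        with pytest.raises(ValueError, match="quantile"):
            nw.cluster_modules(net, cut_height_quantile=0.0)


def eigvec_oracle(M):
    """Leading right-singular vector via the characteristic polynomial of
    the small Gram matrix M M^T (independent of numpy's SVD routine)."""
    G = M @ M.T
    eigvals = np.roots(np.poly(G))
    lam = np.max(eigvals.real)
    # eigenvector of G for lam by solving the singular system
    A = G - lam * np.eye(G.shape[0])
    _, _, vt = np.linalg.svd(A)
    u = vt[-1]
    v = M.T @ u
    return v / np.linalg.norm(v)


class TestModuleEigengene:
    def test_identical_profiles_give_standardized_profile(self):
        t = np.arange(10, dtype=float)
        profile = np.cos(2 * np.pi * t / 10)
        m = scaled([profile, profile, profile, t])
        e = nw.module_eigengene(m, ["F000", "F001", "F002"])
        expected = (profile - profile.mean()) / profile.std(ddof=1)
        expected /= expected.std(ddof=1)
        assert np.allclose(np.abs(e.to_numpy()), np.abs(expected), atol=1e-9)
        assert np.corrcoef(e, m.values.loc["F000"])[0, 1] > 0  # orientation

    def test_matches_characteristic_polynomial_svd(self, rng):
        m = scaled(rng.standard_normal((3, 8)))
        e = nw.module_eigengene(m, list(m.features))
        M = m.values.to_numpy()
        M = M - M.mean(axis=1, keepdims=True)
        v = eigvec_oracle(M)
        v = v / v.std(ddof=1)
        assert np.allclose(np.abs(e.to_numpy()), np.abs(v), atol=1e-8)

    def test_sign_flip_of_members_is_unobservable(self, rng):
        m = scaled(rng.standard_normal((4, 10)))
        e1 = nw.module_eigengene(m, list(m.features))
        flipped = m.with_values(-m.values)
        e2 = nw.module_eigengene(flipped, list(m.features))
        assert np.allclose(np.abs(e1), np.abs(e2), atol=1e-9)

    def test_missing_member_named(self):
        m = scaled(np.random.default_rng(0).standard_normal((3, 6)))
        with pytest.raises(KeyError, match="F999"):
            nw.module_eigengene(m, ["F000", "F999"])


class TestIntramodularConnectivity:
    def _partition(self, features, labels):
        return nw.ModulePartition(assignments=pd.Series(labels, index=features))

    def test_perfect_module_connectivity_is_size_minus_one(self):
        m = two_block_matrix(block=6, n=12)
        net = nw.adjacency(nw.correlation_matrix(m))
        part = self._partition(m.features, ["a"] * 6 + ["b"] * 6)
        k = nw.intramodular_connectivity(net, part)
        assert np.allclose(k, 5.0, atol=1e-9)

    def test_size_two_module(self, rng):
        m = scaled(rng.standard_normal((2, 8)))
        net = nw.adjacency(nw.correlation_matrix(m))
        part = self._partition(m.features, ["a", "a"])
        k = nw.intramodular_connectivity(net, part)
        assert np.allclose(k, net.a.iloc[0, 1])

    def test_star_center_has_maximal_connectivity(self):
        # center = factor itself; leaves = 0.9-loaded copies plus noise
        rng = np.random.default_rng(1)
        z = rng.standard_normal(200)  # long profiles: sample noise negligible
        rows = [z] + [0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(200)
                      for _ in range(8)]
        m = scaled(rows)
        net = nw.adjacency(nw.correlation_matrix(m))
        part = self._partition(m.features, ["a"] * 9)
        k = nw.intramodular_connectivity(net, part)
        assert k.idxmax() == "F000"


def test_edge_list_export_thresholds_on_correlation(tmp_path):
    m = two_block_matrix(block=3, n=12)
    net = nw.adjacency(nw.correlation_matrix(m))
    path = tmp_path / "edges.tsv"
    edges = nw.export_edges(net, path, min_abs_r=0.5)
    # only within-block pairs survive: 2 blocks x C(3,2) = 6 edges
    assert len(edges) == 6
    back = pd.read_csv(path, sep="\t")
    assert np.allclose(np.abs(back["r"]), 1.0)
    assert {"feature_i", "feature_j", "r", "a"} == set(back.columns)


class TestRecoveryOnPlantedModules:
    def test_planted_modules_recovered_with_high_ari(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(5):
            cfg = sim.study_config(seed=seed)
            prot, met, _, truth = sim.generate_dataset(cfg)
            comb = pp.concatenate_layers(
                [pp.normalize_layer(prot, quantile=False),
                 pp.normalize_layer(met, quantile=True)]
            )
            net = nw.correlation_matrix(comb)
            part = nw.cluster_modules(net, comb)
            lab = part.assignments
            truthlab = [truth.assignments.get(f, "bg") for f in net.features]
            nongrey = (lab != nw.GREY).to_numpy()
            aris.append(
                adjusted_rand_score(
                    [t for t, g in zip(truthlab, nongrey) if g],
                    lab[nongrey].tolist(),
                )
            )
        assert np.mean(aris) >= 0.9
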