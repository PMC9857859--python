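"""Co-abundance network: adjacency/TOM oracles, soft threshold, dynamic
cut recovery, eigengene and merge behaviour, module–trait correlation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from oenomet.io import OenometError
from oenomet.network import (
    GREY,
    CoexpressionNetwork,
    ModulePartition,
    NetworkConfig,
    adjacency,
    cluster_modules,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
    _zscore_cols_as_rows,
)


def blocks(rng, n_samples=18, sizes=(60, 60, 60), noise=0, cor=0.8):
    """Samples × metabolites matrix with latent-factor blocks + pure noise.

    Factors are orthogonalised: the planted condition is within-block
    metabolite–factor correlation ``cor`` and cross-block correlation 0.
    """
    F = rng.standard_normal((n_samples, len(sizes)))
    F -= F.mean(axis=0)
    F, _ = np.linalg.qr(F)
    F /= F.std(axis=0, ddof=0)
    cols = []
    for k, size in enumerate(sizes):
        for _ in range(size):
            cols.append(
                cor * F[:, k] + np.sqrt(1 - cor**2) * rng.standard_normal(n_samples)
            )
    for _ in range(noise):
        cols.append(rng.standard_normal(n_samples))
    return np.column_stack(cols)


class TestAdjacency:
    def test_power_law_of_correlation(self):
        # two exactly correlated columns and the 0.5-correlation value 0.5^6
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        X = np.column_stack([x, x, -x])
        a = adjacency(X, NetworkConfig(power=6))
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(1.0)  # unsigned: r = −1 → 1
        assert 0.5**6 == 0.015625  # the documented β = 6 attenuation

    def test_matches_elementwise_oracle(self, rng):
        X = rng.standard_normal((15, 4))
        a = adjacency(X, NetworkConfig(power=6))
        r = np.corrcoef(X, rowvar=False)
        expect = np.abs(r) ** 6
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(a, expect, atol=1e-12)

    def test_zero_variance_is_hard_error(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(OenometError):
            adjacency(X)


class TestTOM:
    def test_two_node_full_edge(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)  # (0+1)/(1+1−1)

    def test_no_edge_no_shared_neighbours(self):
        a = np.eye(3)
        tom = tom_similarity(a)
        assert tom[0, 1] == 0.0

    def test_three_node_hand_calculation(self):
        a = np.array(
            [[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]]
        )
        tom = tom_similarity(a)
        # k = (0.8, 0.7, 0.5); e.g. TOM_12 = (0.3·0.2 + 0.5)/(0.7 + 1 − 0.5)
        assert tom[0, 1] == pytest.approx(0.56 / 1.2)
        assert tom[0, 2] == pytest.approx(0.4 / 1.2)
        assert tom[1, 2] == pytest.approx(0.35 / 1.3)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_bounds_symmetry_and_formula_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)
        # direct-formula oracle, elementwise
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expect = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(OenometError):
            tom_similarity(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestSoftThreshold:
    def test_mean_connectivity_strictly_decreasing(self, rng):
        X = blocks(rng, sizes=(30, 30), noise=20)
        df = pick_soft_threshold(X)
        assert (np.diff(df["mean_connectivity"]) < 0).all()

    def test_recommended_power_in_plausible_band(self, rng):
        X = blocks(rng, sizes=(40, 40, 40), noise=60)
        df = pick_soft_threshold(X)
        assert df.attrs["recommended_power"] in range(1, 11)
        # the fit index improves from the unpowered network to the plateau
        r2 = df["sft_r2"].to_numpy(dtype=float)
        assert np.nanmax(r2[3:]) >= np.nanmax(r2[:2])

    def test_degenerate_identical_metabolites_flagged(self):
        x = np.linspace(0, 1, 12)
        X = np.column_stack([x] * 25)
        df = pick_soft_threshold(X)
        assert df["sft_r2"].isna().all()

    def test_needs_enough_metabolites(self, rng):
        with pytest.raises(OenometError):
            pick_soft_threshold(rng.standard_normal((10, 5)))


class TestClusterModules:
    def test_three_planted_blocks_recovered(self, rng):
        X = blocks(rng, sizes=(60, 60, 60), noise=0)
        cfg = NetworkConfig(min_module_size=50)
        diss = 1 - tom_similarity(adjacency(X, cfg))
        part = cluster_modules(diss, cfg)
        truth = np.repeat([0, 1, 2], 60)
        assert len(part.modules) == 3
        assert adjusted_rand_score(truth, part.labels) >= 0.9

    def test_pure_noise_is_mostly_grey(self, rng):
        X = rng.standard_normal((18, 100))
        cfg = NetworkConfig(min_module_size=50)
        diss = 1 - tom_similarity(adjacency(X, cfg))
        part = cluster_modules(diss, cfg)
        assert part.module_sizes.get(GREY, 0) >= 90

    def test_blocks_below_min_size_all_grey(self, rng):
        X = blocks(rng, sizes=(10, 10), noise=0)
        cfg = NetworkConfig(min_module_size=50)
        diss = 1 - tom_similarity(adjacency(X, cfg))
        part = cluster_modules(diss, cfg)
        assert all(lab == GREY for lab in part.labels)

    def test_fewer_items_than_min_size_warns_all_grey(self, rng):
        diss = 1 - tom_similarity(adjacency(rng.standard_normal((10, 6))))
        with pytest.warns(UserWarning):
            part = cluster_modules(diss, NetworkConfig(min_module_size=50))
        assert set(part.labels) == {GREY}


class TestEigengenes:
    def test_identical_profiles_reproduce_profile(self, rng):
        profile = rng.standard_normal(12)
        Xz = _zscore_cols_as_rows(np.tile(profile, (5, 1)).T)
        part = ModulePartition(["turquoise"] * 5)
        egs = module_eigengene(Xz, part)
        eg = egs.eigengenes["turquoise"].to_numpy()
        assert abs(np.corrcoef(eg, profile)[0, 1]) == pytest.approx(1.0)
        assert egs.variance_explained["turquoise"] == pytest.approx(1.0)

    def test_planted_factor_recovered(self, rng):
        f = rng.standard_normal(18)
        X = np.column_stack(
            [0.9 * f + 0.44 * rng.standard_normal(18) for _ in range(40)]
        )
        part = ModulePartition(["blue"] * 40)
        egs = module_eigengene(_zscore_cols_as_rows(X), part)
        assert abs(np.corrcoef(egs.eigengenes["blue"], f)[0, 1]) >= 0.9

    def test_sign_flip_of_rows_leaves_trait_correlation_magnitude(self, rng):
        f = rng.standard_normal(12)
        X = np.column_stack([f + 0.1 * rng.standard_normal(12) for _ in range(10)])
        part = ModulePartition(["red"] * 10)
        e1 = module_eigengene(_zscore_cols_as_rows(X), part).eigengenes["red"]
        e2 = module_eigengene(_zscore_cols_as_rows(-X), part).eigengenes["red"]
        trait = pd.DataFrame({"t": f})
        r1 = module_trait_correlation(e1.to_frame("red"), trait).r.iloc[0, 0]
        r2 = module_trait_correlation(e2.to_frame("red"), trait).r.iloc[0, 0]
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-9)


class TestMergeModules:
    def test_same_factor_modules_merge(self, rng):
        f = rng.standard_normal(18)
        X = np.column_stack(
            [0.95 * f + 0.31 * rng.standard_normal(18) for _ in range(40)]
        )
        part = ModulePartition(["turquoise"] * 20 + ["blue"] * 20)
        merged, _ = merge_modules(_zscore_cols_as_rows(X), part)
        assert len(merged.modules) == 1

    def test_orthogonal_modules_untouched_and_idempotent(self, rng):
        f1, f2 = rng.standard_normal((2, 30))
        X = np.column_stack(
            [f1 + 0.2 * rng.standard_normal(30) for _ in range(15)]
            + [f2 + 0.2 * rng.standard_normal(30) for _ in range(15)]
        )
        Xz = _zscore_cols_as_rows(X)
        part = ModulePartition(["turquoise"] * 15 + ["blue"] * 15)
        once, _ = merge_modules(Xz, part)
        assert len(once.modules) == 2
        twice, _ = merge_modules(Xz, once)
        assert twice.labels == once.labels


class TestModuleTraitCorrelation:
    def test_trait_equal_to_eigengene(self, rng):
        e = pd.DataFrame({"brown": rng.standard_normal(18)})
        mt = module_trait_correlation(e, e.rename(columns={"brown": "a_star"}))
        assert mt.r.loc["brown", "a_star"] == pytest.approx(1.0)
        assert mt.p.loc["brown", "a_star"] < 1e-12

    def test_noisy_linear_trait_recovered(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(18)
            trait = 0.9 * e + np.sqrt(1 - 0.81) * rng.standard_normal(18)
            mt = module_trait_correlation(
                pd.DataFrame({"m": e}), pd.DataFrame({"t": trait})
            )
            rs.append(float(mt.r.iloc[0, 0]))
        assert abs(np.mean(rs) - 0.9) < 0.1

    def test_orthogonal_trait_mostly_insignificant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            e = rng.standard_normal(18)
            t = rng.standard_normal(18)
            mt = module_trait_correlation(
                pd.DataFrame({"m": e}), pd.DataFrame({"t": t})
            )
            if abs(mt.r.iloc[0, 0]) < 0.5 and mt.p.iloc[0, 0] > 0.05:
                hits += 1
        assert hits >= 18  # ≥ 0.9 probability over seeds

    def test_zero_variance_trait_flagged(self, rng):
        e = pd.DataFrame({"m": rng.standard_normal(10)})
        t = pd.DataFrame({"t": np.full(10, 3.0)})
        mt = module_trait_correlation(e, t)
        assert np.isnan(mt.r.iloc[0, 0])
        assert mt.p.iloc[0, 0] == 1.0

    def test_p_consistent_with_t_transform(self, rng):
        from scipy import stats as sps

        e = pd.DataFrame({"m": rng.standard_normal(18)})
        t = pd.DataFrame({"t": rng.standard_normal(18)})
        mt = module_trait_correlation(e, t)
        r = float(mt.r.iloc[0, 0])
        tstat = r * np.sqrt(16) / np.sqrt(1 - r**2)
        assert mt.p.iloc[0, 0] == pytest.approx(2 * sps.t.sf(abs(tstat), 16), rel=1e-10)


class TestFullChain:
    def test_default_bundle_module_recovery(self, default_bundle):
        table, samples, traits, pmap, truth = default_bundle
        logX = np.log10(table.imputed())
        wine = [j for j, s in enumerate(samples) if not s.is_qc]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = CoexpressionNetwork(
                logX[:, wine].T,
                table.metabolite_ids,
                [samples[j].sample_id for j in wine],
            )
            res = model.fit(traits.per_sample(samples))
        # planted differential metabolites carry real variety structure and
        # have no unambiguous module ground truth; assess ARI without them
        planted_diff = set().union(*(set(d) for d in truth.planted_shift.values()))
        lab = dict(zip(model.metabolite_ids, res.partition.labels))
        ids = [m for m in model.metabolite_ids if m not in planted_diff]
        ari = adjusted_rand_score(
            [truth.module_assignment.get(m, -1) for m in ids], [lab[m] for m in ids]
        )
        assert ari >= 0.8
        assert len(res.partition.modules) >= len(truth.module_latent.columns) - 1
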