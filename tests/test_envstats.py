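import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eccpipe.community import ecc
from eccpipe.envstats import (
    classify_elevation_dependence,
    ecc_sensitivity,
    extract_points,
    kmeans_subsample,
    kruskal_wallis,
    pca_bioclim,
    raster_correlation,
    spearman_perm,
)
from eccpipe.io_formats import RunConfig
from eccpipe.synthetic_landscape import MASS_ORDER, default_truth, make_island, true_suitability

from conftest import grid, stack_from


def tiny_ecc(stack):
    maps = {"a": stack.elevation.with_values(stack.elevation.values + 1.0)}
    return ecc(maps)


class TestExtractPoints:
    def test_one_row_per_valid_cell(self):
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        stack = stack_from(np.arange(9.0).reshape(3, 3), {"c": np.ones((3, 3))},
                           mask=mask)
        pts = extract_points(stack, tiny_ecc(stack))
        assert len(pts) == 8
        assert (pts["island"] == "test").all()

    def test_values_match_raster_lookups(self, small_island):
        stack, _ = small_island
        eccm = tiny_ecc(stack)
        pts = extract_points(stack, eccm)
        for i in (0, len(pts) // 2, len(pts) - 1):
            row = pts.iloc[i]
            r, c = int(row["row"]), int(row["col"])
            assert row["elevation"] == stack.elevation.values[r, c]
            assert row["temp_mean"] == stack.layers["temp_mean"].values[r, c]
            assert row["ECC"] == eccm.raster.values[r, c]

    def test_masked_cells_never_appear(self, small_island):
        stack, _ = small_island
        pts = extract_points(stack, tiny_ecc(stack))
        assert all(stack.mask[int(r), int(c)] for r, c in zip(pts["row"], pts["col"]))

    def test_mask_mismatch_rejected(self, small_island):
        stack, _ = small_island
        other = stack_from(np.arange(9.0).reshape(3, 3), {})
        with pytest.raises(ValueError, match="mask"):
            extract_points(stack, tiny_ecc(other))


class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        x = np.linspace(0, 1, 50)
        pts = pd.DataFrame({"a": x, "b": 2 * x + 3})
        res = pca_bioclim(pts, climate_cols=["a", "b"])
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
        assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
        assert res.retained == 1

    def test_eigenvalue_sum_equals_variable_count(self, rng):
        pts = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        res = pca_bioclim(pts, climate_cols=list("abcde"))
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-9)

    def test_independent_normals_give_near_unit_eigenvalues(self, rng):
        pts = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        res = pca_bioclim(pts, climate_cols=list("abcd"))
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.1)

    def test_scores_reproduce_from_loadings(self, rng):
        pts = pd.DataFrame(rng.normal(size=(100, 3)) @ rng.normal(size=(3, 3)),
                           columns=list("abc"))
        res = pca_bioclim(pts, climate_cols=list("abc"))
        X = pts.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(res.scores.to_numpy(), Z @ res.loadings.to_numpy(), atol=1e-9)

    def test_score_covariance_is_diagonal(self, rng):
        pts = pd.DataFrame(rng.normal(size=(300, 4)) @ rng.normal(size=(4, 4)),
                           columns=list("abcd"))
        res = pca_bioclim(pts, climate_cols=list("abcd"))
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8 * res.eigenvalues[0]

    def test_constant_variable_named_in_error(self):
        pts = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="'b'"):
            pca_bioclim(pts, climate_cols=["a", "b"])


@pytest.fixture(scope="module")
def scores():
    # dense, evenly spread points so every k-means cluster is large
    rng = np.random.default_rng(3)
    return rng.uniform(size=(5000, 2))


class TestKmeansSubsample:

    def test_ten_per_cluster_yields_thousand(self, scores):
        idx = kmeans_subsample(scores, k=100, per_cluster=10, seed=0)
        assert len(idx) == 1000 and len(set(idx.tolist())) == 1000

    def test_one_per_cluster_yields_hundred(self, scores):
        idx = kmeans_subsample(scores, k=100, per_cluster=1, seed=0)
        assert len(idx) == 100

    def test_k_equal_n_returns_every_point(self):
        pts = np.arange(30.0)[:, None]
        idx = kmeans_subsample(pts, k=30, per_cluster=1, seed=1)
        assert np.array_equal(idx, np.arange(30))

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_subsample(np.zeros((5, 2)), k=6, per_cluster=1, seed=0)

    def test_seeded_determinism(self, scores):
        a = kmeans_subsample(scores, k=40, per_cluster=3, seed=9)
        b = kmeans_subsample(scores, k=40, per_cluster=3, seed=9)
        assert np.array_equal(a, b)


class TestRasterCorrelation:
    def test_exact_linear_relation(self):
        elev = grid([[0.0, 1.0], [2.0, 3.0]], name="elevation")
        eccr = grid([[1.0, 3.0], [5.0, 7.0]])
        R, slope, intercept = raster_correlation(eccr, elev)
        assert R == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_negated_elevation_gives_minus_one(self):
        elev = grid([[0.0, 1.0, 2.0]])
        eccr = grid([[0.0, -1.0, -2.0]])
        assert raster_correlation(eccr, elev)[0] == pytest.approx(-1.0)

    def test_permutation_null_centred_on_zero(self, rng):
        elev_vals = rng.random(200)
        Rs = []
        for _ in range(100):
            ecc_vals = rng.permutation(elev_vals)
            Rs.append(sps.pearsonr(elev_vals, ecc_vals)[0])
        assert abs(np.mean(Rs)) < 0.05

    def test_constant_elevation_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            raster_correlation(grid([[1.0, 2.0, 3.0]]), grid([[5.0, 5.0, 5.0]]))


class TestSpearmanPerm:
    def test_monotone_relations(self):
        x = np.arange(10.0)
        r, p = spearman_perm(x, x**3 + 1, n_permutations=1000, seed=0)
        assert r == pytest.approx(1.0)
        r, _ = spearman_perm(x, -x, n_permutations=1000, seed=0)
        assert r == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 60))
            x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, _ = spearman_perm(x, y, n_permutations=1000, seed=1)
            assert r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_p_value_has_permutation_floor(self):
        x = np.arange(20.0)
        _, p = spearman_perm(x, x, n_permutations=1000, seed=0)
        assert p == pytest.approx(1.0 / 1001.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_perm(np.ones(10), np.arange(10.0), n_permutations=1000, seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_perm(np.arange(4.0), np.arange(4.0), n_permutations=1000, seed=0)


class TestKruskalWallis:
    def test_textbook_three_group_value(self):
        H, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                               np.array([7.0, 8, 9])])
        assert H == pytest.approx(7.2, abs=1e-12)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, df=2)), abs=1e-12)

    def test_identical_group_multisets_give_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        H, p = kruskal_wallis([g, g.copy()])
        assert H == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            groups = [rng.integers(0, 8, size=int(rng.integers(3, 20))).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                continue
            H, p = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert H == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([2.0, 3.0])])


class TestElevationDependence:
    def test_exact_linear_biopc_is_dependent(self, rng):
        elev = rng.random(100)
        scores = pd.DataFrame({"BioPC1": 3.0 * elev - 1.0})
        res = classify_elevation_dependence(_wrap(scores), elev, threshold=0.99)
        assert res.dependent == ["BioPC1"] and res.all_dependent

    def test_white_noise_biopc_is_independent(self, rng):
        # orthogonal by construction: white noise has no spatial structure
        hits = 0
        elev = np.sort(rng.random(3000))
        for s in range(50):
            noise = np.random.default_rng(s).normal(size=3000)
            res = classify_elevation_dependence(
                _wrap(pd.DataFrame({"BioPC1": noise})), elev, threshold=0.1
            )
            hits += res.dependent == []
        assert hits >= 45

    def test_all_dependent_flag_triggers(self, rng):
        elev = rng.random(60)
        scores = pd.DataFrame({"BioPC1": 2 * elev, "BioPC2": -elev + 0.3})
        res = classify_elevation_dependence(_wrap(scores), elev, threshold=0.5)
        assert res.all_dependent and res.independent == []

    def test_threshold_validated(self, rng):
        with pytest.raises(ValueError):
            classify_elevation_dependence(
                _wrap(pd.DataFrame({"BioPC1": rng.random(10)})), rng.random(10),
                threshold=0.0,
            )


def _wrap(scores: pd.DataFrame):
    """Minimal BioPCResult carrying given scores, all retained."""
    from eccpipe.envstats import BioPCResult

    k = scores.shape[1]
    return BioPCResult(
        loadings=pd.DataFrame(np.eye(k), columns=scores.columns),
        eigenvalues=np.full(k, 2.0),
        retained=k,
        scores=scores,
    )


class TestSensitivity:
    def _setup(self, seed):
        truth = default_truth()
        stack = make_island(seed=seed, shape=(40, 50), truth=truth, island_id="m")
        maps = {e: true_suitability(truth, e, stack) for e in MASS_ORDER}
        cfg = RunConfig(seed=seed, kmeans_k=40, points_per_cluster=2,
                        n_permutations=2000)
        return stack, maps, cfg

    def test_empty_drop_reproduces_full_analysis(self):
        stack, maps, cfg = self._setup(2)
        full, reduced = ecc_sensitivity(maps, [], stack, cfg, seed=5)
        assert full == reduced

    def test_dropping_unmapped_ecomorph_rejected(self):
        stack, maps, cfg = self._setup(2)
        with pytest.raises(ValueError, match="unmapped"):
            ecc_sensitivity(maps, ["gecko"], stack, cfg, seed=5)

    def test_dropping_every_ecomorph_rejected(self):
        stack, maps, cfg = self._setup(2)
        with pytest.raises(ValueError, match="every"):
            ecc_sensitivity(maps, list(maps), stack, cfg, seed=5)

    def test_correlation_survives_removal_of_extra_ecomorphs(self):
        # the ECC-elevation link is not an artifact of the ecomorphs missing
        # from the reduced (flat-climate style) community: dropping grass-bush
        # and trunk leaves the sign and significance intact
        # (5 independent landscapes)
        for seed in range(5):
            stack, maps, cfg = self._setup(seed + 10)
            _, reduced = ecc_sensitivity(maps, ["grass-bush", "trunk"], stack, cfg,
                                         seed=seed)
            assert reduced.spearman_r > 0
            assert reduced.p_value < 0.05
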