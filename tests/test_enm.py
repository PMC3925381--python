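import logging

import numpy as np
import pytest

from eccpipe.enm import (
    FeatureSpec,
    auc_scores,
    draw_background,
    fit_ensemble,
    fit_maxent,
    logistic_from_log,
    logistic_map,
    penalized_objective,
)
from eccpipe.io_formats import OccurrenceSet, RunConfig
from eccpipe.synthetic_landscape import default_truth, make_island, sample_occurrences

from conftest import stack_from


def toy_line_stack(values, island_id="toy"):
    """A 1 x n all-valid landscape with a single climate layer."""
    vals = np.asarray(values, dtype=float)[None, :]
    return stack_from(np.zeros_like(vals), {"env": vals}, island_id=island_id)


class TestDrawBackground:
    def test_exact_count_of_unique_cells(self, small_island):
        stack, _ = small_island
        cells = draw_background(stack, 500, seed=1)
        assert len(cells) == 500 and len(set(cells)) == 500
        assert all(stack.mask[r, c] for r, c in cells)

    def test_oversized_request_returns_all_with_warning(self, small_island, caplog):
        stack, _ = small_island
        with caplog.at_level(logging.WARNING, logger="eccpipe"):
            cells = draw_background(stack, stack.n_valid + 10, seed=1)
        assert len(cells) == stack.n_valid
        assert "using all" in caplog.text

    def test_seeded_determinism(self, small_island):
        stack, _ = small_island
        assert draw_background(stack, 100, seed=5) == draw_background(stack, 100, seed=5)


class TestFitMaxent:
    def test_single_feature_matches_grid_search_oracle(self):
        # 10-cell toy landscape, one linear feature; compare against a
        # brute-force grid search over lambda in [-10, 10] step 1e-3
        stack = toy_line_stack([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 9])
        background = [(0, i) for i in range(10)]
        presence = [(0, 6), (0, 7), (0, 8), (0, 9), (0, 5)]
        spec = FeatureSpec.from_background(stack, background, layers=["env"],
                                           include_quadratic=False)
        model = fit_maxent(presence, background, stack, feature_spec=spec, beta=1.0)
        F_p = spec.matrix(stack, presence)
        F_b = spec.matrix(stack, background)
        grid_vals = np.arange(-10.0, 10.0 + 1e-9, 1e-3)
        objs = [penalized_objective(np.array([lam]), F_p, F_b, model.penalties)
                for lam in grid_vals]
        lam_star = grid_vals[int(np.argmin(objs))]
        assert model.lam[0] == pytest.approx(lam_star, abs=1e-3)

    def test_uniform_presences_with_strong_penalty_give_uniform_model(self):
        stack = toy_line_stack(np.linspace(-2, 2, 40))
        background = [(0, i) for i in range(40)]
        presence = background[::2]  # spread evenly across the gradient
        model = fit_maxent(presence, background, stack, beta=50.0)
        assert np.all(np.abs(model.lam) < 1e-8)
        q = np.exp(model.F_background @ model.lam)
        q /= q.sum()
        assert np.max(np.abs(q - 1.0 / len(background))) < 1e-3

    def test_duplicate_background_leaves_weights_unchanged(self):
        stack = toy_line_stack(np.linspace(0, 5, 12))
        background = [(0, i) for i in range(12)]
        presence = [(0, i) for i in (7, 8, 9, 10, 11)]
        spec = FeatureSpec.from_background(stack, background, layers=["env"])
        m1 = fit_maxent(presence, background, stack, feature_spec=spec)
        m2 = fit_maxent(presence, background * 2, stack, feature_spec=spec)
        assert np.allclose(m1.lam, m2.lam, atol=1e-5)

    def test_background_distribution_normalizes_and_entropy_bounded(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "trunk", stack, n=60, seed=3)
        background = draw_background(stack, 400, seed=2)
        model = fit_maxent(occ.cells, background, stack)
        q = np.exp(model.F_background @ model.lam) / model.Z
        assert q.sum() == pytest.approx(1.0, abs=1e-9)
        assert 0.0 <= model.H <= np.log(model.n_background)

    def test_fit_never_worse_than_null_model(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "twig", stack, n=60, seed=4)
        background = draw_background(stack, 400, seed=5)
        model = fit_maxent(occ.cells, background, stack)
        obj_fit = penalized_objective(model.lam, model.F_presence,
                                      model.F_background, model.penalties)
        obj_null = penalized_objective(np.zeros_like(model.lam), model.F_presence,
                                       model.F_background, model.penalties)
        assert obj_fit <= obj_null + 1e-12

    def test_no_single_weight_perturbation_improves_objective(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "grass-bush", stack, n=80, seed=6)
        background = draw_background(stack, 500, seed=7)
        model = fit_maxent(occ.cells, background, stack)
        base = penalized_objective(model.lam, model.F_presence,
                                   model.F_background, model.penalties)
        for j in range(model.lam.size):
            for eps in (0.01, -0.01):
                lam = model.lam.copy()
                lam[j] += eps
                assert penalized_objective(lam, model.F_presence, model.F_background,
                                           model.penalties) >= base - 1e-10

    def test_too_few_presences_rejected(self):
        stack = toy_line_stack(np.arange(10.0))
        with pytest.raises(ValueError, match="5 presence"):
            fit_maxent([(0, 1)], [(0, i) for i in range(10)], stack)

    def test_constant_layer_dropped_with_warning(self, caplog):
        stack = stack_from(np.zeros((1, 10)),
                           {"env": np.arange(10.0)[None, :],
                            "flat": np.full((1, 10), 3.0)})
        with caplog.at_level(logging.WARNING, logger="eccpipe"):
            spec = FeatureSpec.from_background(stack, [(0, i) for i in range(10)])
        assert "flat" in caplog.text
        assert spec.layer_names == ["elevation", "env"] or "flat" not in spec.layer_names


class TestLogistic:
    def test_typical_site_scores_exactly_half(self):
        for H in (0.5, 2.0, 7.3):
            assert logistic_from_log(-H, H) == 0.5

    def test_vanishing_raw_score_gives_vanishing_logistic(self):
        assert logistic_from_log(-1e3, 2.0) < 1e-300 or logistic_from_log(-1e3, 2.0) >= 0

    def test_logistic_strictly_increasing_in_raw_score(self):
        logq = np.linspace(-20, 2, 100)
        p = logistic_from_log(logq, 1.5)
        assert (np.diff(p) > 0).all()
        assert ((p > 0) & (p < 1)).all()

    def test_logistic_map_covers_projection_mask(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "trunk", stack, n=60, seed=3)
        bg = draw_background(stack, 300, seed=1)
        model = fit_maxent(occ.cells, bg, stack)
        other = make_island(seed=99, shape=(30, 36), truth=truth, island_id="other")
        m = logistic_map(model, other)
        assert np.array_equal(m.mask, other.mask)
        vals = m.masked_values()
        assert ((vals > 0) & (vals < 1)).all()

    def test_missing_layer_named_in_error(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "trunk", stack, n=60, seed=3)
        bg = draw_background(stack, 300, seed=1)
        model = fit_maxent(occ.cells, bg, stack)
        bare = stack_from(np.zeros((21, 21)), {}, island_id="bare")
        with pytest.raises(KeyError):
            logistic_map(model, bare)


class TestAUC:
    def test_perfect_separation(self):
        assert auc_scores([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_identical_scores_give_half(self):
        assert auc_scores([0.4, 0.4], [0.4, 0.4, 0.4]) == 0.5

    def test_hand_enumerated_mixed_case(self):
        # pairs: (0.7 vs 0.5) win, (0.3 vs 0.5) loss -> 1 of 2
        assert auc_scores([0.7, 0.3], [0.5]) == 0.5

    def test_matches_brute_force_pair_count(self, rng):
        for _ in range(20):
            pos = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 20))
            neg = rng.choice(np.linspace(0, 1, 11), size=rng.integers(2, 30))
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc_scores(pos, neg) == pytest.approx(
                wins / (len(pos) * len(neg)), abs=1e-9
            )

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            auc_scores([0.5], [])


class TestEnsemble:
    def test_single_replicate_mean_equals_replicate(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "trunk", stack, n=40, seed=2)
        cfg = RunConfig(seed=1, n_replicates=1, n_background=300)
        ens = fit_ensemble(occ, stack, cfg)
        assert np.array_equal(ens.mean_map.values, ens.replicates[0].values)

    def test_too_few_occurrences_advises_minimum(self, small_island):
        stack, _ = small_island
        occ = OccurrenceSet("trunk", stack.island_id, stack.valid_cells()[:7])
        with pytest.raises(ValueError, match=">= 8"):
            fit_ensemble(occ, stack, RunConfig(seed=1, n_replicates=1, n_background=100))

    def test_projection_lands_on_target_mask_with_unit_range(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "twig", stack, n=40, seed=2)
        other = make_island(seed=42, shape=(28, 34), truth=truth, island_id="other")
        cfg = RunConfig(seed=3, n_replicates=2, n_background=300)
        out = fit_ensemble(occ, stack, cfg, projections={"small": stack, "other": other})
        proj = out["other"].mean_map
        assert np.array_equal(proj.mask, other.mask)
        vals = proj.masked_values()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_replicates_are_seeded_deterministically(self, small_island):
        stack, truth = small_island
        occ = sample_occurrences(truth, "trunk", stack, n=40, seed=2)
        cfg = RunConfig(seed=7, n_replicates=3, n_background=200)
        a = fit_ensemble(occ, stack, cfg)
        b = fit_ensemble(occ, stack, cfg)
        assert np.array_equal(a.mean_map.values, b.mean_map.values)
        assert a.test_aucs == b.test_aucs

    def test_strong_signal_yields_high_held_out_auc(self, small_island):
        stack, _ = small_island
        truth = default_truth()
        truth.ecomorphs["twig"].breadth_m = 80.0  # sharpen the niche
        occ = sample_occurrences(truth, "twig", stack, n=200, seed=11)
        cfg = RunConfig(seed=5, n_replicates=10, n_background=800)
        ens = fit_ensemble(occ, stack, cfg)
        assert ens.mean_test_auc > 0.8
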