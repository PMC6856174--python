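import numpy as np
import pytest

from rlbpseg.features import difference_vector, make_projection, rlbp_code
from rlbpseg.fusion import (
    AtlasSet,
    FusionConfig,
    RidgeModel,
    TrainingSet,
    _classify_ambiguous,
    build_training_set,
    majority_vote,
    predict_label,
    ridge_fit,
    segment,
)
from rlbpseg.volume_io import LabelMap, Volume, extract_patch


def _toy_atlases(rng, n=3, shape=(5, 5, 5)):
    images = [Volume(rng.normal(size=shape)) for _ in range(n)]
    labels = [LabelMap((rng.random(shape) > 0.5).astype(np.uint8)) for _ in range(n)]
    return AtlasSet(images, labels)


class TestMajorityVote:
    def test_unanimous_atlases(self, rng):
        lab = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        maj, amb = majority_vote([lab, lab.copy(), lab.copy()])
        np.testing.assert_array_equal(maj, lab)
        assert not amb.any()

    def test_two_of_three_majority(self):
        votes = [np.ones((1, 1, 1), np.uint8), np.ones((1, 1, 1), np.uint8),
                 np.zeros((1, 1, 1), np.uint8)]
        maj, amb = majority_vote(votes)
        assert maj[0, 0, 0] == 1
        assert amb[0, 0, 0]

    def test_matches_per_voxel_tally_oracle(self, rng):
        labs = [(rng.random((2, 2, 2)) > 0.5).astype(np.uint8) for _ in range(4)]
        maj, amb = majority_vote(labs)
        for idx in np.ndindex(2, 2, 2):
            ones = sum(int(l[idx]) for l in labs)
            # even count: ties resolved toward foreground
            assert maj[idx] == (1 if ones >= 2 else 0)
            assert amb[idx] == (0 < ones < 4)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            majority_vote([np.zeros((2, 2, 2)), np.zeros((3, 3, 3))])


class TestBuildTrainingSet:
    def test_row_count_formula(self, rng):
        atlases = _toy_atlases(rng, n=2)
        proj = make_projection(10, 27, seed=0)
        ts = build_training_set(atlases, (2, 2, 2), FusionConfig(L=10, r_p=1).geometry, proj)
        assert ts.M == 2 * 27
        assert set(np.unique(ts.labels)) <= {-1, 1}

    def test_zero_search_radius_gives_center_rows(self, rng):
        atlases = _toy_atlases(rng, n=3)
        proj = make_projection(10, 27, seed=0)
        geo = FusionConfig(L=10, r_p=1, r_s=0).geometry
        ts = build_training_set(atlases, (2, 2, 2), geo, proj)
        assert ts.M == 3
        for i in range(3):
            f = rlbp_code(
                difference_vector(extract_patch(atlases.images[i], (2, 2, 2), 1)), proj
            )
            np.testing.assert_array_equal(ts.features[i], f)

    def test_rows_match_per_row_recomputation(self, rng):
        atlases = _toy_atlases(rng, n=2)
        proj = make_projection(8, 27, seed=1)
        geo = FusionConfig(L=8, r_p=1).geometry
        ts = build_training_set(atlases, (2, 2, 2), geo, proj)
        for row, (i, vox) in enumerate(ts.provenance):
            patch = extract_patch(atlases.images[i], vox, geo.r_p)
            np.testing.assert_array_equal(
                ts.features[row], rlbp_code(difference_vector(patch), proj)
            )
            assert ts.labels[row] == atlases.labels[i].signed()[vox]

    def test_border_voxel_drops_out_of_bounds_rows(self, rng):
        atlases = _toy_atlases(rng, n=2)
        proj = make_projection(8, 27, seed=1)
        ts = build_training_set(atlases, (0, 0, 0), FusionConfig(L=8, r_p=1).geometry, proj)
        assert ts.M == 2 * 8  # only the 2x2x2 in-bounds corner of the 3x3x3 cube


class TestRidgeFit:
    def test_single_sample_closed_form(self):
        ts = TrainingSet(np.array([[1.0]]), np.array([1.0]))
        model = ridge_fit(ts, C=1.0)
        np.testing.assert_allclose(model.beta, [0.5])

    def test_label_flip_negates_beta(self, rng):
        F = (rng.random((30, 5)) > 0.5).astype(float)
        l = rng.choice([-1.0, 1.0], 30)
        b1 = ridge_fit(TrainingSet(F, l), C=0.1).beta
        b2 = ridge_fit(TrainingSet(F, -l), C=0.1).beta
        np.testing.assert_allclose(b1, -b2, atol=1e-12)

    def test_primal_and_dual_agree(self, rng):
        F = (rng.random((30, 50)) > 0.5).astype(float)  # L > M
        l = rng.choice([-1.0, 1.0], 30)
        bp = ridge_fit(TrainingSet(F, l), C=4.0 ** -4, mode="primal").beta
        bd = ridge_fit(TrainingSet(F, l), C=4.0 ** -4, mode="dual").beta
        np.testing.assert_allclose(bp, bd, atol=1e-8)

    def test_matches_numerical_minimizer(self, rng):
        from scipy.optimize import minimize

        F = (rng.random((25, 4)) > 0.5).astype(float)
        l = rng.choice([-1.0, 1.0], 25)
        C = 0.05

        def objective(beta):
            return 0.5 * beta @ beta + 0.5 * C * np.sum((l - F @ beta) ** 2)

        res = minimize(objective, np.zeros(4), method="BFGS", tol=1e-12)
        beta = ridge_fit(TrainingSet(F, l), C).beta
        np.testing.assert_allclose(beta, res.x, atol=1e-6)
        assert objective(beta) <= res.fun + 1e-10

    def test_small_c_shrinks_beta_to_zero(self, rng):
        F = (rng.random((20, 5)) > 0.5).astype(float)
        l = rng.choice([-1.0, 1.0], 20)
        beta = ridge_fit(TrainingSet(F, l), C=1e-12).beta
        assert np.max(np.abs(beta)) < 1e-9
        # sign-of-zero convention labels the voxel foreground in the limit
        assert predict_label(RidgeModel(np.zeros(5), 1e-12), np.ones(5)) == 1

    def test_single_class_prediction_for_any_c(self, rng):
        F = (rng.random((20, 5)) > 0.5).astype(float)
        for C in (1e-6, 1.0, 1e3):
            for cls in (1.0, -1.0):
                model = ridge_fit(TrainingSet(F, np.full(20, cls)), C)
                f_x = (rng.random(5) > 0.5).astype(float)
                assert predict_label(model, f_x) == int(cls) or np.allclose(
                    model.beta @ f_x, 0
                )

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError, match="C"):
            ridge_fit(TrainingSet(np.ones((1, 1)), np.ones(1)), C=0.0)


class TestPredictLabel:
    @pytest.mark.parametrize(
        "beta,f,expected",
        [([1.0, -1.0], [1.0, 0.0], 1), ([1.0, -1.0], [0.0, 1.0], -1),
         ([1.0, -1.0], [1.0, 1.0], 1)],  # boundary: sign(0) := +1
    )
    def test_sign_convention(self, beta, f, expected):
        assert predict_label(RidgeModel(np.array(beta), 1.0), np.array(f)) == expected

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_label(RidgeModel(np.zeros(3), 1.0), np.zeros(4))


class TestSegment:
    def test_unanimous_atlases_short_circuit(self, rng):
        shape = (6, 6, 6)
        lab = np.zeros(shape, np.uint8)
        lab[2:4, 2:4, 2:4] = 1
        atlases = AtlasSet(
            [Volume(rng.normal(size=shape)) for _ in range(3)],
            [LabelMap(lab.copy()) for _ in range(3)],
        )
        out = segment(Volume(rng.normal(size=shape)), atlases, FusionConfig(L=10, r_p=1))
        np.testing.assert_array_equal(out.data, lab)

    def test_output_binary_and_differs_only_on_ambiguous(self, small_problem, small_cfg):
        target, _, atlases = small_problem
        maj, amb = majority_vote(atlases.label_stack())
        out, amb2 = segment(target, atlases, small_cfg, return_ambiguous=True)
        np.testing.assert_array_equal(amb, amb2)
        assert set(np.unique(out.data)) <= {0, 1}
        assert np.all((out.data == maj) | amb)

    def test_atlas_order_permutation_invariance(self, small_problem, small_cfg):
        target, _, atlases = small_problem
        out1 = segment(target, atlases, small_cfg)
        perm = AtlasSet(list(reversed(atlases.images)), list(reversed(atlases.labels)))
        out2 = segment(target, perm, small_cfg)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_vectorized_engine_matches_reference_path(self, small_problem, small_cfg):
        target, _, atlases = small_problem
        geo = small_cfg.geometry
        proj = make_projection(small_cfg.L, geo.n, small_cfg.seed)
        _, amb = majority_vote(atlases.label_stack())
        amb_idx = np.argwhere(amb)[::7]  # subsample for speed
        vec = _classify_ambiguous(
            target.data, atlases.image_stack(), atlases.label_stack(),
            amb_idx, geo, proj, small_cfg.C,
        )
        for k, x in enumerate(amb_idx):
            ts = build_training_set(atlases, x, geo, proj)
            if np.all(ts.labels == ts.labels[0]):
                expected = int(ts.labels[0])
            else:
                model = ridge_fit(ts, small_cfg.C)
                f_x = rlbp_code(difference_vector(extract_patch(target, x, geo.r_p)), proj)
                expected = predict_label(model, f_x)
            assert vec[k] == expected

    @pytest.mark.parametrize("cls", [0, 1])
    def test_single_class_neighborhood_forces_that_label(self, rng, cls):
        # a voxel whose entire training neighborhood carries one label is
        # assigned that label (constant prediction, no solve involved)
        shape = (7, 7, 7)
        cfg = FusionConfig(L=10, r_p=1)
        images = np.stack([rng.normal(size=shape) for _ in range(4)])
        labels = np.full((4, *shape), cls, np.uint8)
        proj = make_projection(cfg.L, cfg.geometry.n, cfg.seed)
        pred = _classify_ambiguous(
            rng.normal(size=shape), images, labels,
            np.array([[3, 3, 3]]), cfg.geometry, proj, cfg.C,
        )
        assert pred[0] == (1 if cls == 1 else -1)

    def test_shape_mismatch_rejected(self, rng):
        atlases = _toy_atlases(rng, n=2, shape=(5, 5, 5))
        with pytest.raises(ValueError, match="shape"):
            segment(Volume(rng.normal(size=(6, 6, 6))), atlases, FusionConfig(L=5, r_p=1))
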