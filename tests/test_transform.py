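import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryoclem.io import ChannelImage
from cryoclem.localization import SpotCandidate, fit_spot
from cryoclem.transform import (ConformalTransform, ControlPointPair,
                                fit_conformal, highpass_filter, loo_accuracy,
                                pairs_from_points, predict_position)
from cryoclem.io import PointRecord

from conftest import sampled_gaussian_image, similarity_matrix

FM_TO_EM_SCALE = 103.0 / 3.65  # 63x FM pixels onto the 5600x EM sampling


def make_pairs(fm, em):
    return [ControlPointPair(str(i), f, e) for i, (f, e) in enumerate(zip(fm, em))]


def jittered_pairs(n, jitter_sd, seed, scale=FM_TO_EM_SCALE, rotation=0.3,
                   translation=(5000.0, -2000.0)):
    rng = np.random.default_rng(seed)
    fm = rng.uniform(0.0, 25000.0, (n, 2))
    em = fm @ similarity_matrix(scale, rotation).T + np.asarray(translation)
    em = em + rng.normal(0.0, jitter_sd, (n, 2))
    return make_pairs(fm, em)


def loo_oracle(pairs):
    """Independent leave-one-out route: the similarity fit is solved as a
    linear least-squares problem in (a, b, tx, ty) with a = s cos(theta),
    b = s sin(theta), instead of the SVD-based construction."""
    def linear_fit(ps):
        rows, rhs = [], []
        for p in ps:
            x, y = p.fm
            rows.append([x, -y, 1.0, 0.0])
            rows.append([y, x, 0.0, 1.0])
            rhs.extend(p.em)
        sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        a, b, tx, ty = sol
        return np.array([[a, -b], [b, a]]), np.array([tx, ty])

    disps = []
    for i in range(len(pairs)):
        rest = pairs[:i] + pairs[i + 1:]
        m, t = linear_fit(rest)
        disps.append(np.linalg.norm(m @ pairs[i].fm + t - pairs[i].em))
    return float(np.mean(disps)), np.array(disps)


class TestHighpass:
    def test_constant_image_removed(self):
        img = ChannelImage(np.full((128, 128), 500.0), "blue", 103.0)
        out = highpass_filter(img, cutoff_px=70)
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_spot_centroid_preserved_on_ramp(self):
        clean = sampled_gaussian_image(101, amp=1000, x0=50.3, y0=49.6,
                                       sx=1.86, sy=1.86)
        ramp = sampled_gaussian_image(101, amp=1000, x0=50.3, y0=49.6,
                                      sx=1.86, sy=1.86,
                                      background=(200.0, 2.0, -1.5))
        ref = fit_spot(clean, SpotCandidate(50, 50, 1000.0), 11)
        filt = highpass_filter(ramp, cutoff_px=70)
        got = fit_spot(filt, SpotCandidate(50, 50, 1000.0), 11)
        assert got.converged and ref.converged
        assert abs(got.x_nm - ref.x_nm) / 103.0 < 0.01
        assert abs(got.y_nm - ref.y_nm) / 103.0 < 0.01

    def test_broad_blob_strongly_attenuated(self):
        blob = sampled_gaussian_image(512, amp=1000, x0=256, y0=256,
                                      sx=200 / 2.3548, sy=200 / 2.3548)
        out = highpass_filter(blob, cutoff_px=70)
        assert out.pixels.max() < 0.2 * blob.pixels.max()

    def test_point_source_mostly_passes(self):
        spot = sampled_gaussian_image(256, amp=1000, x0=128, y0=128,
                                      sx=1.86, sy=1.86)
        out = highpass_filter(spot, cutoff_px=70)
        assert out.pixels.max() > 0.9 * spot.pixels.max()


class TestFitConformal:
    def test_identity(self):
        fm = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0], [700.0, 900.0]])
        tf = fit_conformal(make_pairs(fm, fm))
        assert tf.scale == pytest.approx(1.0, rel=1e-12)
        assert tf.rotation_rad == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.translation_nm, 0.0, atol=1e-9)
        assert np.allclose(tf.residuals_nm, 0.0, atol=1e-9)

    def test_exact_parameter_recovery(self, rng):
        scale, theta, t = FM_TO_EM_SCALE, np.deg2rad(30.0), np.array([5000.0, -2000.0])
        fm = rng.uniform(0.0, 20000.0, (6, 2))
        em = fm @ similarity_matrix(scale, theta).T + t
        tf = fit_conformal(make_pairs(fm, em))
        assert tf.scale == pytest.approx(scale, rel=1e-9)
        assert tf.rotation_rad == pytest.approx(theta, rel=1e-9)
        assert np.allclose(tf.translation_nm, t, rtol=1e-9, atol=1e-6)
        assert tf.sigma_c_nm == pytest.approx(0.0, abs=1e-6)
        assert not tf.reflection

    def test_perturbed_pair_carries_largest_residual(self):
        rng = np.random.default_rng(1)
        fm = rng.uniform(0.0, 10000.0, (4, 2))
        em = fm @ similarity_matrix(2.0, 0.1).T
        em[2] += np.array([50.0, 0.0])
        tf = fit_conformal(make_pairs(fm, em), compute_loo=False)
        assert np.argmax(tf.residuals_nm) == 2

    def test_perturbation_concentrates_with_many_points(self):
        """With enough control points (low leverage), a single perturbed pair
        carries at least twice the residual of any clean pair."""
        for seed in range(4):
            rng = np.random.default_rng(seed)
            fm = rng.uniform(0.0, 10000.0, (8, 2))
            em = fm @ similarity_matrix(2.0, 0.1).T
            em[2] += np.array([50.0, 0.0])
            tf = fit_conformal(make_pairs(fm, em), compute_loo=False)
            res = tf.residuals_nm
            assert np.argmax(res) == 2
            assert res[2] >= 2 * np.max(np.delete(res, 2))

    def test_too_few_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_conformal(make_pairs(np.zeros((1, 2)), np.zeros((1, 2))))
        same = np.tile([100.0, 100.0], (3, 1))
        with pytest.raises(ValueError, match="degenerate"):
            fit_conformal(make_pairs(same, same * 2))
        line = np.array([[0.0, 0.0], [1000.0, 0.0], [2000.0, 0.0]])
        with pytest.warns(UserWarning, match="collinear"):
            fit_conformal(make_pairs(line, line), compute_loo=False)

    def test_reflection_flag(self, rng):
        fm = rng.uniform(0.0, 10000.0, (5, 2))
        m = similarity_matrix(3.0, 0.4) @ np.diag([1.0, -1.0])
        em = fm @ m.T + np.array([100.0, 200.0])
        tf = fit_conformal(make_pairs(fm, em), allow_reflection=True,
                           compute_loo=False)
        assert tf.reflection
        assert np.allclose(tf.residuals_nm, 0.0, atol=1e-6)
        assert np.allclose(tf.matrix, m * 3.0 / 3.0, rtol=1e-9)
        # with reflection disallowed the same data cannot be fitted exactly
        tf2 = fit_conformal(make_pairs(fm, em), allow_reflection=False,
                            compute_loo=False)
        assert not tf2.reflection
        assert tf2.residuals_nm.max() > 100.0

    def test_agrees_with_skimage_similarity(self, rng):
        skimage_tf = pytest.importorskip("skimage.transform")
        pairs = jittered_pairs(8, jitter_sd=30.0, seed=5)
        fm = np.array([p.fm for p in pairs])
        em = np.array([p.em for p in pairs])
        tf = fit_conformal(pairs, compute_loo=False)
        sk = skimage_tf.estimate_transform("similarity", fm, em)
        assert tf.scale == pytest.approx(sk.scale, rel=1e-9)
        assert tf.rotation_rad == pytest.approx(sk.rotation, rel=1e-9)
        assert np.allclose(tf.translation_nm, sk.translation, rtol=1e-9)


class TestLeaveOneOut:
    def test_noiseless_sigma_c_is_zero(self, rng):
        pairs = jittered_pairs(5, jitter_sd=0.0, seed=3)
        sigma_c, disps = loo_accuracy(pairs)
        assert sigma_c == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(disps, 0.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        pairs = jittered_pairs(5, jitter_sd=10.0, seed=seed)
        sigma_c, disps = loo_accuracy(pairs)
        oracle_sigma, oracle_disps = loo_oracle(pairs)
        assert sigma_c == pytest.approx(oracle_sigma, rel=1e-7, abs=1e-7)
        assert np.allclose(disps, oracle_disps, rtol=1e-7, atol=1e-6)

    def test_invariant_to_pair_order(self):
        pairs = jittered_pairs(6, jitter_sd=15.0, seed=11)
        sigma_c, _ = loo_accuracy(pairs)
        sigma_r, _ = loo_accuracy(list(reversed(pairs)))
        assert sigma_c == pytest.approx(sigma_r, rel=1e-9)

    def test_fit_residual_rms_below_sigma_c(self):
        """LOO is the more pessimistic (honest) error estimate."""
        for seed in range(5):
            pairs = jittered_pairs(6, jitter_sd=20.0, seed=seed)
            tf = fit_conformal(pairs)
            rms = float(np.sqrt(np.mean(tf.residuals_nm**2)))
            assert rms <= tf.sigma_c_nm

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            loo_accuracy(jittered_pairs(2, 0.0, 0))

    def test_grows_with_jitter_shrinks_with_n(self):
        def mean_sigma(n, jitter):
            return np.mean([loo_accuracy(jittered_pairs(n, jitter, s))[0]
                            for s in range(30)])
        assert mean_sigma(5, 20.0) > mean_sigma(5, 5.0)
        assert mean_sigma(10, 10.0) < mean_sigma(4, 10.0)


class TestPredict:
    def test_identity_transform(self):
        tf = ConformalTransform(scale=1.0, rotation_rad=0.0,
                                translation_nm=np.zeros(2))
        assert np.allclose(predict_position(tf, [123.0, -45.0]), [123.0, -45.0])

    def test_control_point_maps_onto_itself_noiseless(self, rng):
        pairs = jittered_pairs(5, jitter_sd=0.0, seed=9)
        tf = fit_conformal(pairs, compute_loo=False)
        for p in pairs:
            assert np.allclose(predict_position(tf, p.fm), p.em, atol=1e-6)

    def test_roundtrip_through_inverse(self, rng):
        tf = ConformalTransform(scale=FM_TO_EM_SCALE, rotation_rad=0.7,
                                translation_nm=np.array([5000.0, -2000.0]))
        pt = np.array([1234.5, 6789.0])
        back = tf.inverse().apply(tf.apply(pt))
        assert np.allclose(back, pt, atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        pairs = jittered_pairs(5, jitter_sd=10.0, seed=2)
        tf = fit_conformal(pairs)
        path = tmp_path / "tf.json"
        tf.save(path)
        back = ConformalTransform.load(path)
        assert back.scale == pytest.approx(tf.scale, rel=1e-12)
        assert back.sigma_c_nm == pytest.approx(tf.sigma_c_nm, rel=1e-12)
        assert np.allclose(back.loo_displacements_nm, tf.loo_displacements_nm)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), jitter=st.floats(0.0, 50.0))
def test_fitted_transform_is_conformal(seed, jitter):
    """Whatever the data, the fitted linear part is a scaled rotation: its two
    singular values coincide, so angles are preserved and all distances scale
    by one factor."""
    pairs = jittered_pairs(6, jitter_sd=jitter, seed=seed)
    tf = fit_conformal(pairs, compute_loo=False)
    sv = np.linalg.svd(tf.matrix, compute_uv=False)
    assert sv[0] == pytest.approx(sv[1], rel=1e-9)
    assert tf.scale > 0


def test_pairs_from_points_matches_ids_and_reports_orphans():
    fm = [PointRecord("f1", "fm", "blue", 0.0, 0.0),
          PointRecord("f2", "fm", "blue", 100.0, 0.0)]
    em = [PointRecord("f1", "em", "em", 0.0, 0.0),
          PointRecord("f2", "em", "em", 2820.0, 0.0)]
    pairs = pairs_from_points(fm, em)
    assert [p.id for p in pairs] == ["f1", "f2"]
    with pytest.raises(ValueError, match="f3"):
        pairs_from_points(fm + [PointRecord("f3", "fm", "blue", 1.0, 1.0)], em)
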