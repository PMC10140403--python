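import numpy as np
import pytest
from _oracles import fcm_bruteforce

from fcmseg.clustering import (
    AtlasFCM,
    ClusterConfig,
    FuzzyCMeans,
    MembershipField,
    SpatialFCM,
    fit_arfcm,
    fit_fcm,
    fit_rfcm,
    hard_labels,
    redistribute_boundaries,
)
from fcmseg.io import BrainMask, IntensityVolume, LabelMap, ProbabilisticAtlas, ValidationError
from fcmseg.metrics import evaluate


def _volume(values):
    data = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return IntensityVolume(data=data), BrainMask(data=np.ones(data.shape, bool))


def _random_volume(rng, shape=(8, 8, 8)):
    vol = IntensityVolume(data=rng.random(shape))
    return vol, BrainMask(data=np.ones(shape, bool))


class TestFCM:
    def test_two_cluster_fixed_point_matches_bruteforce(self):
        vol, mask = _volume([0, 0, 0, 1, 1, 1])
        cfg = ClusterConfig(q=2.0, K=2, n=200, thr=1e-9)
        res = fit_fcm(vol, mask, cfg)
        u_ref, v_ref = fcm_bruteforce(np.array([0, 0, 0, 1, 1, 1.0]),
                                      np.quantile([0, 0, 0, 1, 1, 1.0], [0.25, 0.75]))
        assert np.allclose(res.centroids, np.sort(v_ref), atol=1e-6)
        assert np.allclose(res.centroids, [0.0, 1.0], atol=1e-6)
        assert np.allclose(res.membership.u, u_ref, atol=1e-6)
        assert np.allclose(res.membership.u, np.repeat(np.eye(2), 3, axis=0), atol=1e-6)

    def test_constant_image_single_class(self):
        vol, mask = _volume([0.4] * 8)
        res = fit_fcm(vol, mask, ClusterConfig(K=1, n=50))
        assert res.centroids[0] == pytest.approx(0.4)
        assert np.all(res.membership.u == 1.0)
        assert res.converged and res.iterations_used == 1

    def test_exact_centroid_hit_gets_one_hot(self):
        # voxel intensity exactly at the converged centroid
        vol, mask = _volume([0.0, 0.0, 1.0, 1.0])
        res = fit_fcm(vol, mask, ClusterConfig(K=2, n=100, thr=1e-10))
        assert np.allclose(res.membership.u, np.repeat(np.eye(2), 2, axis=0), atol=1e-9)

    def test_underdetermined_clustering_rejected(self):
        vol, mask = _volume([0.2, 0.2, 0.8, 0.8])
        with pytest.raises(ValidationError, match="underdetermined"):
            fit_fcm(vol, mask, ClusterConfig(K=3))

    def test_empty_mask_rejected(self):
        vol, _ = _volume([0.1, 0.9])
        with pytest.raises(ValidationError, match="empty"):
            fit_fcm(vol, BrainMask(data=np.zeros(vol.shape, bool)), ClusterConfig(K=2))


class TestRFCM:
    def test_beta_zero_reduces_to_fcm(self, rng):
        vol, mask = _random_volume(rng)
        cfg = ClusterConfig(q=2.0, beta=0.0, n=40, thr=1e-8)
        a = fit_fcm(vol, mask, cfg)
        b = fit_rfcm(vol, mask, cfg)
        assert np.allclose(a.membership.u, b.membership.u, atol=1e-10)
        assert np.allclose(a.centroids, b.centroids, atol=1e-10)

    def test_noise_voxel_absorbed_by_neighborhood(self):
        # two-region 8^3 phantom with one flipped voxel inside the dark half
        data = np.zeros((8, 8, 8))
        data[4:] = 1.0
        data[1, 1, 1] = 1.0  # the noise voxel
        vol = IntensityVolume(data=data)
        mask = BrainMask(data=np.ones(data.shape, bool))
        res = fit_rfcm(vol, mask, ClusterConfig(q=2.0, beta=1.0, K=2, n=100, thr=1e-6))
        labels = res.labels()
        assert labels.data[1, 1, 1] == 1  # matches its dark neighborhood
        assert np.all(labels.data[5:] == 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        vol, mask = _random_volume(rng)
        res = fit_rfcm(vol, mask, ClusterConfig(beta=1.0, n=30, thr=1e-8))
        j = res.objective_trace
        assert np.all(np.diff(j) <= 1e-8 * np.abs(j[:-1]) + 1e-12)


class TestARFCM:
    def _atlas_for(self, mask, rng=None, one_hot_of=None):
        shape = mask.shape
        if one_hot_of is not None:
            probs = np.stack([(one_hot_of == k).astype(float) for k in (1, 2, 3)], -1)
        else:
            raw = rng.random(shape + (3,))
            probs = raw / raw.sum(-1, keepdims=True)
        return ProbabilisticAtlas(probs=probs)

    def test_gamma_zero_reduces_to_fcm(self, rng):
        vol, mask = _random_volume(rng)
        atlas = self._atlas_for(mask, rng)
        cfg = ClusterConfig(gamma=0.0, n=40, thr=1e-8)
        init = np.quantile(vol.data[mask.data], [1 / 6, 3 / 6, 5 / 6])
        a = fit_fcm(vol, mask, cfg, initial_centroids=init)
        b = fit_arfcm(vol, mask, atlas, cfg, initial_centroids=init)
        assert np.allclose(a.membership.u, b.membership.u, atol=1e-10)

    def test_huge_gamma_with_one_hot_atlas_forces_atlas_labels(self, rng):
        vol, mask = _random_volume(rng, shape=(6, 6, 6))
        target = rng.integers(1, 4, mask.shape)
        atlas = self._atlas_for(mask, one_hot_of=target)
        cfg = ClusterConfig(gamma=1e6, w=1.0, n=100, thr=1e-8)
        init = np.quantile(vol.data[mask.data], [0.25, 0.5, 0.75])
        res = fit_arfcm(vol, mask, atlas, cfg, initial_centroids=init)
        # output classes are intensity-sorted, so map each atlas channel to
        # its rank among the per-channel mean intensities
        y, t = vol.data[mask.data], target[mask.data]
        chan_means = np.array([y[t == k].mean() for k in (1, 2, 3)])
        rank = np.argsort(np.argsort(chan_means))
        expected = rank[t - 1] + 1
        assert np.array_equal(res.labels().data[mask.data], expected)

    def test_noisy_phantom_high_dice(self, suite_specs):
        from dataclasses import replace
        from fcmseg.phantom import generate_phantom

        spec = replace(suite_specs[0], noise_sigma=0.05)
        b = generate_phantom(spec)
        res = fit_arfcm(b.t1, b.mask, b.atlas, ClusterConfig.for_arfcm())
        rep = evaluate(res.labels(), b.gt_labels)
        assert (rep.table.dsc >= 95.0).all()

    def test_atlas_grid_mismatch(self, rng):
        vol, mask = _random_volume(rng, shape=(6, 6, 6))
        probs = np.ones((5, 6, 6, 3)) / 3
        with pytest.raises(ValidationError, match="grid mismatch"):
            AtlasFCM(vol, mask, ProbabilisticAtlas(probs=probs))


class TestSharedInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_memberships_normalized_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        vol, mask = _random_volume(rng)
        for fit in (fit_fcm, fit_rfcm):
            res = fit(vol, mask, ClusterConfig(beta=1.0, n=20))
            u = res.membership.u
            assert np.all(u >= 0) and np.all(u <= 1)
            assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_centroid_order_sorted_after_fit(self, noisy_bundle):
        res = fit_fcm(noisy_bundle.t1, noisy_bundle.mask, ClusterConfig.for_fcm())
        assert np.all(np.diff(res.centroids) > 0)

    def test_initial_order_permutation_invariant(self, rng):
        vol, mask = _random_volume(rng)
        cfg = ClusterConfig(n=100, thr=1e-8)
        init = np.array([0.2, 0.5, 0.8])
        a = fit_fcm(vol, mask, cfg, initial_centroids=init)
        b = fit_fcm(vol, mask, cfg, initial_centroids=init[::-1])
        assert np.array_equal(a.labels().data, b.labels().data)

    def test_exact_recovery_on_clean_phantom_fcm_arfcm(self, clean_bundle):
        b = clean_bundle
        for res in (fit_fcm(b.t1, b.mask, ClusterConfig.for_fcm()),
                    fit_arfcm(b.t1, b.mask, b.atlas, ClusterConfig.for_arfcm())):
            assert np.array_equal(res.labels().data, b.gt_labels.data)

    def test_rfcm_beats_fcm_on_heavy_noise_wm_gm(self, suite_specs):
        from dataclasses import replace
        from fcmseg.phantom import generate_phantom

        b = generate_phantom(replace(suite_specs[1], seed=11))
        df = evaluate(fit_fcm(b.t1, b.mask, ClusterConfig.for_fcm()).labels(),
                      b.gt_labels).table
        dr = evaluate(fit_rfcm(b.t1, b.mask, ClusterConfig.for_rfcm()).labels(),
                      b.gt_labels).table
        # the spatial penalty denoises the tissue interior (GM and WM)
        for tissue in ("GM", "WM"):
            assert dr[dr.class_name == tissue].dsc.iloc[0] >= \
                df[df.class_name == tissue].dsc.iloc[0]


class TestHardLabels:
    def test_one_hot_identity(self):
        mask = BrainMask(data=np.ones((2, 2, 2), bool))
        u = np.zeros((8, 3))
        u[np.arange(8), np.arange(8) % 3] = 1.0
        labels = hard_labels(MembershipField(u=u, mask=mask), mask)
        assert np.array_equal(labels.data.ravel(), np.arange(8) % 3 + 1)

    def test_tie_goes_to_lower_class(self):
        mask = BrainMask(data=np.ones((1, 1, 1), bool))
        u = np.array([[0.5, 0.5, 0.0]])
        labels = hard_labels(MembershipField(u=u, mask=mask), mask)
        assert labels.data[0, 0, 0] == 1  # CSF

    def test_matches_per_voxel_max_scan(self, rng):
        mask = BrainMask(data=np.ones((6, 6, 6), bool))
        raw = rng.random((216, 3))
        u = raw / raw.sum(axis=1, keepdims=True)
        labels = hard_labels(MembershipField(u=u, mask=mask), mask)
        expected = np.array([int(np.argmax(row)) + 1 for row in u]).reshape(6, 6, 6)
        assert np.array_equal(labels.data, expected)

    def test_centroid_sorting_reorders_classes(self):
        mask = BrainMask(data=np.ones((1, 1, 2), bool))
        u = np.array([[0.9, 0.05, 0.05], [0.05, 0.05, 0.9]])
        # centroids given in descending order: class 0 is actually WM
        labels = hard_labels(MembershipField(u=u, mask=mask), mask,
                             centroids=np.array([0.8, 0.5, 0.15]))
        assert labels.data[0, 0, 0] == 3 and labels.data[0, 0, 1] == 1


class TestRedistributeBoundaries:
    def _uniform_atlas(self, shape):
        return ProbabilisticAtlas(probs=np.full(shape + (3,), 1.0 / 3.0))

    def test_uniform_region_is_noop(self):
        shape = (4, 4, 4)
        mask = BrainMask(data=np.ones(shape, bool))
        labels = LabelMap(data=np.full(shape, 2, dtype=np.int16))
        u = np.tile([0.1, 0.8, 0.1], (64, 1))
        out = redistribute_boundaries(labels, MembershipField(u=u, mask=mask),
                                      self._uniform_atlas(shape), mask)
        assert np.array_equal(out.data, labels.data)

    def test_boundary_voxel_relabeled_by_membership_atlas_product(self):
        # two half-spaces GM | WM; the probe boundary voxel carries ambiguous
        # membership which the morphological atlas must disambiguate to WM
        shape = (2, 1, 1)
        mask = BrainMask(data=np.ones(shape, bool))
        labels = LabelMap(data=np.array([2, 3], dtype=np.int16).reshape(shape))
        u = np.array([[0.1, 0.45, 0.45], [0.1, 0.45, 0.45]])
        m = np.zeros(shape + (3,))
        m[..., :] = [0.1, 0.2, 0.7]
        out = redistribute_boundaries(labels, MembershipField(u=u, mask=mask),
                                      ProbabilisticAtlas(probs=m), mask)
        # 0.45 * 0.7 beats 0.45 * 0.2 and 0.1 * 0.1
        assert np.all(out.data == 3)

    def test_uniform_atlas_equals_plain_argmax(self, rng):
        shape = (5, 5, 5)
        mask = BrainMask(data=np.ones(shape, bool))
        raw = rng.random((125, 3))
        u = raw / raw.sum(axis=1, keepdims=True)
        labels = hard_labels(MembershipField(u=u, mask=mask), mask)
        # flip some labels so boundaries exist and argmax disagrees
        noisy = labels.data.copy()
        noisy[2, 2, 2] = (noisy[2, 2, 2] % 3) + 1
        out = redistribute_boundaries(LabelMap(data=noisy),
                                      MembershipField(u=u, mask=mask),
                                      self._uniform_atlas(shape), mask)
        boundary_fixed = out.data[2, 2, 2]
        assert boundary_fixed == labels.data[2, 2, 2]
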