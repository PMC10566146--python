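"""Pairwise network: combinatorics, forward oracle, gating, invariances."""

import math

import numpy as np
import pytest

from sigmanet.exceptions import ConfigurationError, InvalidParameterError
from sigmanet.io import GenotypeMatrix, LocationsTable, pairwise_distances
from sigmanet.network import (
    AdamState,
    ModelWeights,
    NetworkSpec,
    backward_batch,
    build_pair_slabs,
    enumerate_pairs,
    extract_pair_features,
    forward,
    forward_batch,
    gated_training_step,
    select_extract_pairs,
)
from conftest import random_dataset


# ---------------------------------------------------------------------------
# Independent loop-based oracle: explicit Python arithmetic, no shared code
# with the vectorized implementation.
# ---------------------------------------------------------------------------


def oracle_forward(weights, slabs, dists):
    """Brute-force forward pass for one dataset; slabs (P, C, m)."""
    spec = weights.spec
    feats = []
    for p in range(len(slabs)):
        h = [[float(v) for v in row] for row in slabs[p]]
        for W, b in zip(weights.conv_W, weights.conv_b):
            F, C, k = W.shape
            L = len(h[0])
            z = [[float(b[f]) + sum(W[f][c][j] * h[c][t + j]
                                    for c in range(C) for j in range(k))
                  for t in range(L - k + 1)] for f in range(F)]
            a = [[max(v, 0.0) for v in row] for row in z]
            pw = spec.pool_width
            Lp = (L - k + 1) // pw
            h = [[sum(row[t * pw:(t + 1) * pw]) / pw for t in range(Lp)]
                 for row in a]
        # position-major flatten: index order (position, filter)
        flat = [h[f][t] for t in range(len(h[0])) for f in range(len(h))]
        x = flat + [dists[p] / weights.distance_scale]
        u = [float(weights.dense_b[i]) + sum(weights.dense_W[i][j] * x[j]
                                             for j in range(len(x)))
             for i in range(spec.pair_feature_width)]
        feats.extend(max(v, 0.0) for v in u)
    y = float(weights.head_b) + sum(float(weights.head_W[i]) * feats[i]
                                    for i in range(len(feats)))
    return y * weights.target_sd + weights.target_mean


def _setup(n, m, seed=0, **spec_kw):
    rng = np.random.default_rng(seed)
    spec = NetworkSpec(n=n, m=m, **spec_kw)
    w = ModelWeights.initialize(spec, rng_seed=seed + 1)
    g, loc = random_dataset(n, m, rng)
    pairs = enumerate_pairs(n)
    slabs = build_pair_slabs(g, pairs)
    dists = pairwise_distances(loc, pairs)
    return spec, w, g, loc, slabs, dists


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,count", [(100, 4950), (10, 45), (2, 1)])
    def test_pair_counts(self, n, count):
        pairs = enumerate_pairs(n)
        assert len(pairs) == count
        assert pairs[0].tolist() == [0, 1]

    def test_canonical_lexicographic_order(self):
        pairs = enumerate_pairs(4)
        assert pairs.tolist() == [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]

    def test_too_few_samples(self):
        with pytest.raises(InvalidParameterError):
            enumerate_pairs(1)


class TestForwardOracle:
    @pytest.mark.parametrize("kw", [
        dict(n=4, m=20, filters_per_block=(1,), pair_feature_width=3),
        dict(n=6, m=50, filters_per_block=(3, 4), pool_width=3,
             pair_feature_width=5),
        dict(n=3, m=40, filters_per_block=(2, 2), pool_width=4,
             conv_kernel_snps=3, pair_feature_width=4),
    ])
    def test_matches_loop_implementation(self, kw):
        spec, w, g, loc, slabs, dists = _setup(seed=11, **kw)
        w.target_mean, w.target_sd = 0.8, 1.7
        w.distance_scale = 9.0
        got = forward(g, loc, w)
        want = oracle_forward(w, slabs, dists)
        assert got == pytest.approx(want, rel=1e-10)

    def test_zero_weights_return_head_bias(self):
        spec, w, g, loc, *_ = _setup(n=4, m=30, filters_per_block=(2,),
                                     pair_feature_width=4, seed=3)
        for arr in w.param_list():
            arr[...] = 0.0
        w.head_b = 1.25
        assert forward(g, loc, w) == pytest.approx(1.25)

    def test_distance_pathway_isolated_when_conv_zeroed(self):
        spec, w, g, loc, slabs, dists = _setup(n=4, m=30, filters_per_block=(2,),
                                               pair_feature_width=4, seed=4)
        for cw, cb in zip(w.conv_W, w.conv_b):
            cw[...] = 0.0
            cb[...] = 0.0
        w.dense_W[:, -1] = 1.0  # make the distance pathway visibly active
        y1 = forward(g, loc, w)
        loc2 = LocationsTable(loc.sample_ids, loc.x * 2, loc.y * 2)
        y2 = forward(g, loc2, w)
        g2 = GenotypeMatrix((2 - g.counts) % 3, g.positions, g.sample_ids)
        y3 = forward(g2, loc, w)
        assert y2 != pytest.approx(y1)  # distance input still flows
        assert y3 == pytest.approx(y1, rel=1e-12)  # genotypes are cut off

    def test_shape_mismatch_rejected(self):
        spec, w, g, loc, *_ = _setup(n=4, m=30, filters_per_block=(2,),
                                     pair_feature_width=4)
        with pytest.raises(ConfigurationError):
            extract_pair_features(np.zeros((2, 29)), 1.0, w)
        rng = np.random.default_rng(0)
        g_bad, loc_bad = random_dataset(5, 30, rng)
        with pytest.raises(ConfigurationError):
            forward(g_bad, loc_bad, w)


class TestInvariances:
    def test_forward_independent_of_k_extract(self):
        _, w, g, loc, *_ = _setup(n=6, m=60, filters_per_block=(3,),
                                  pair_feature_width=8, seed=6)
        base = forward(g, loc, w)
        for k in (1, 10, 15):
            w.spec.k_extract = k
            assert forward(g, loc, w) == base

    def test_rigid_motion_invariance(self):
        _, w, g, loc, *_ = _setup(n=5, m=40, filters_per_block=(2,),
                                  pair_feature_width=6, seed=7)
        base = forward(g, loc, w)
        theta = 0.83
        c, s = math.cos(theta), math.sin(theta)
        xr = c * loc.x - s * loc.y + 40.0
        yr = s * loc.x + c * loc.y - 17.0
        rotated = LocationsTable(loc.sample_ids, xr, yr)
        assert forward(g, rotated, w) == pytest.approx(base, rel=1e-9)

    def test_extractor_size_does_not_grow_with_n(self):
        counts = []
        for n in (4, 8, 16):
            spec = NetworkSpec(n=n, m=60, filters_per_block=(3,),
                               pair_feature_width=8)
            counts.append(ModelWeights.initialize(spec).extractor_param_count())
        assert counts[0] == counts[1] == counts[2]

    def test_pair_feature_width_uniform(self):
        _, w, g, loc, slabs, dists = _setup(n=5, m=40, filters_per_block=(2,),
                                            pair_feature_width=6, seed=8)
        for p in range(len(slabs)):
            f = extract_pair_features(slabs[p], float(dists[p]), w)
            assert f.shape == (6,)


class TestSelectExtractPairs:
    def test_full_and_singleton_selection(self):
        pairs = enumerate_pairs(6)
        assert len(select_extract_pairs(pairs, len(pairs), 0)) == len(pairs)
        single = select_extract_pairs(pairs, 1, 1)
        assert len(single) == 1 and 0 <= single[0] < len(pairs)

    def test_seed_determinism(self):
        pairs = enumerate_pairs(8)
        a = select_extract_pairs(pairs, 5, 42)
        b = select_extract_pairs(pairs, 5, 42)
        assert np.array_equal(a, b)

    def test_out_of_range_rejected(self):
        pairs = enumerate_pairs(4)
        for bad in (0, len(pairs) + 1):
            with pytest.raises(InvalidParameterError):
                select_extract_pairs(pairs, bad, 0)


class TestGradientGate:
    """Finite-difference verification of the k_extract stop-gradient."""

    def _loss_parts(self, w, slabs, dists, y):
        _, yh, cache = forward_batch(w, slabs, dists)
        resid = yh - y
        dy = 2.0 * resid / len(resid)
        return cache, dy, float(np.mean(resid**2))

    def test_gated_gradient_matches_frozen_pathway_fd(self):
        """Analytic gated gradients equal finite differences of a surrogate
        in which unselected pairs use frozen extractor weights."""
        from sigmanet.network import _extractor_forward

        _, w, g, loc, slabs, dists = _setup(n=4, m=24, filters_per_block=(2,),
                                            pair_feature_width=4, seed=9)
        # jitter the biases: all-zero genotype windows otherwise sit exactly
        # on the ReLU kink, where finite differences are one-sided
        jit = np.random.default_rng(1)
        for cb in w.conv_b:
            cb += jit.normal(0, 0.05, size=cb.shape)
        w.dense_b += jit.normal(0, 0.05, size=w.dense_b.shape)
        slabs, dists = slabs[None], dists[None]
        y = np.array([0.4])
        pairs = enumerate_pairs(4)
        sel = select_extract_pairs(pairs, 2, rng_seed=3)
        mask = np.zeros(len(pairs), dtype=bool)
        mask[sel] = True

        cache, dy, _ = self._loss_parts(w, slabs, dists, y)
        grads = backward_batch(w, cache, dy, sel)

        def surrogate_loss(wp):
            """Selected pairs via perturbed weights, unselected via frozen."""
            fp, _ = _extractor_forward(wp, slabs[0], dists[0] / w.distance_scale)
            fo, _ = _extractor_forward(w, slabs[0], dists[0] / w.distance_scale)
            f = np.where(mask[:, None], fp, fo)
            yh = f.reshape(-1) @ w.head_W + w.head_b
            return float(np.mean((yh - y) ** 2))

        eps = 1e-6
        rng = np.random.default_rng(0)
        for arr, garr in [(w.conv_W[0], grads["conv_W"][0]),
                          (w.dense_W, grads["dense_W"]),
                          (w.conv_b[0], grads["conv_b"][0])]:
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                wp = w.copy()
                wp_arr = {id(w.conv_W[0]): wp.conv_W[0],
                          id(w.dense_W): wp.dense_W,
                          id(w.conv_b[0]): wp.conv_b[0]}[id(arr)]
                wp_arr[idx] += eps
                lp = surrogate_loss(wp)
                wp_arr[idx] -= 2 * eps
                lm = surrogate_loss(wp)
                fd = (lp - lm) / (2 * eps)
                assert fd == pytest.approx(float(garr[idx]), abs=1e-6)

    def test_unselected_pairs_have_zero_extractor_gradient(self):
        """With NO pairs selected (empty gate emulated by masking all),
        extractor gradients vanish while head gradients survive."""
        _, w, g, loc, slabs, dists = _setup(n=4, m=24, filters_per_block=(2,),
                                            pair_feature_width=4, seed=10)
        slabs, dists = slabs[None], dists[None]
        y = np.array([1.1])
        cache, dy, _ = self._loss_parts(w, slabs, dists, y)
        # gate everything out: pass a selection, then compare against it
        sel = np.array([0])  # only pair 0 selected
        grads = backward_batch(w, cache, dy, sel)
        # gradient contribution of pair 0 alone must equal the gated gradient
        grads_only0 = backward_batch(w, cache, dy, np.array([0]))
        for a, b in zip(AdamState._grad_list(grads)[:4],
                        AdamState._grad_list(grads_only0)[:4]):
            assert np.allclose(a, b)
        # head gradient segments of unselected pairs are nonzero
        fw = w.spec.pair_feature_width
        unselected = grads["head_W"].reshape(-1, fw)[1:]
        assert np.abs(unselected).max() > 0

    def test_full_selection_equals_ungated(self):
        _, w, g, loc, slabs, dists = _setup(n=4, m=24, filters_per_block=(2,),
                                            pair_feature_width=4, seed=12)
        slabs, dists = slabs[None], dists[None]
        y = np.array([0.9])
        cache, dy, _ = self._loss_parts(w, slabs, dists, y)
        g_all = backward_batch(w, cache, dy, np.arange(len(enumerate_pairs(4))))
        g_none = backward_batch(w, cache, dy, None)
        for a, b in zip(AdamState._grad_list(g_all), AdamState._grad_list(g_none)):
            assert np.allclose(a, b)

    def test_empty_selection_rejected(self):
        _, w, g, loc, slabs, dists = _setup(n=4, m=24, filters_per_block=(2,),
                                            pair_feature_width=4, seed=13)
        adam = AdamState(w)
        with pytest.raises(InvalidParameterError):
            gated_training_step(slabs[None], dists[None], np.array([1.0]), w,
                                np.array([], dtype=int), adam)


class TestRelabelAugmentation:
    """Relabelling individuals is a symmetry of the data."""

    def _multiset(self, slabs, dists):
        return sorted(
            (slabs[0, p].sum(), round(float(np.sort(slabs[0, p].ravel())[-9]), 6),
             round(float(dists[0, p]), 9))
            for p in range(slabs.shape[1])
        )

    def test_permutation_preserves_pair_multiset(self):
        from sigmanet.network import apply_permutation, permutation_indices

        rng = np.random.default_rng(21)
        g, loc = random_dataset(7, 40, rng)
        pairs = enumerate_pairs(7)
        slabs = build_pair_slabs(g, pairs)[None]
        dists = pairwise_distances(loc, pairs)[None]
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(7)
            pp, ci = permutation_indices(7, perm)
            s2, d2 = apply_permutation(slabs, dists, pp, ci)
            assert self._multiset(slabs, dists) == self._multiset(s2, d2)

    def test_identity_permutation_is_identity(self):
        from sigmanet.network import apply_permutation, permutation_indices

        rng = np.random.default_rng(22)
        g, loc = random_dataset(5, 30, rng)
        pairs = enumerate_pairs(5)
        slabs = build_pair_slabs(g, pairs)[None]
        dists = pairwise_distances(loc, pairs)[None]
        pp, ci = permutation_indices(5, np.arange(5))
        s2, d2 = apply_permutation(slabs, dists, pp, ci)
        assert np.array_equal(s2, slabs)
        assert np.array_equal(d2, dists)

    def test_swapped_pair_reverses_channels(self):
        from sigmanet.network import apply_permutation, permutation_indices

        rng = np.random.default_rng(23)
        g, loc = random_dataset(3, 20, rng)
        pairs = enumerate_pairs(3)
        slabs = build_pair_slabs(g, pairs)[None]
        dists = pairwise_distances(loc, pairs)[None]
        # reversal permutation maps pair (0,1) -> (2,1): swapped order
        pp, ci = permutation_indices(3, np.array([2, 1, 0]))
        s2, d2 = apply_permutation(slabs, dists, pp, ci)
        assert self._multiset(slabs, dists) == self._multiset(s2, d2)
        flips = (ci[:, 0] == 1).sum()
        assert flips >= 1  # at least one pair changes within-pair order


class TestWeightsSerialization:
    def test_save_load_round_trip(self, tmp_path):
        _, w, g, loc, *_ = _setup(n=5, m=40, filters_per_block=(2, 3),
                                  pool_width=3, pair_feature_width=6, seed=14)
        w.target_mean, w.target_sd, w.distance_scale = 1.5, 0.6, 12.0
        before = forward(g, loc, w)
        w.save(tmp_path / "w.npz")
        w2 = ModelWeights.load(tmp_path / "w.npz")
        assert forward(g, loc, w2) == pytest.approx(before, rel=1e-15)
        assert w2.spec.to_dict() == w.spec.to_dict()


class TestNetworkSpecValidation:
    def test_too_many_blocks_for_m(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(n=4, m=30, filters_per_block=(2, 2, 2))

    def test_default_depth_from_m(self):
        assert len(NetworkSpec(n=10, m=5000).filters_per_block) == 3
        assert len(NetworkSpec(n=10, m=500).filters_per_block) == 2

    def test_k_extract_bounds(self):
        with pytest.raises(InvalidParameterError):
            NetworkSpec(n=4, m=100, k_extract=7)  # C(4,2) = 6
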