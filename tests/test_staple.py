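"""STAPLE EM: oracle equivalence, symmetries, background independence."""

import math

import numpy as np
import pytest

from cardiofuse.staple import (
    StapleFusion,
    StapleSettings,
    binarize,
    crop_to_roi,
    fuse_stack,
    staple_slice,
)
from cardiofuse.synthetic import simulate_lv_truth, simulate_rater
from cardiofuse.types import MaskStack, RaterProfile


def em_oracle(masks, init_p=0.99, init_q=0.99, prior=None, tol=1e-7, max_iter=200):
    """Brute-force scalar-loop EM, written independently of the package code.

    Returns (W flat list, p list, q list).  Python loops only, no shared
    helpers, so it can serve as an oracle for the vectorized implementation.
    """
    D = [list(np.asarray(m, dtype=int).ravel()) for m in masks]  # per rater
    J = len(D)
    n = len(D[0])
    if prior is None:
        g = sum(sum(d) for d in D) / (J * n)
    else:
        g = float(prior)
    p = [init_p] * J
    q = [init_q] * J
    W = [0.0] * n
    for _ in range(max_iter):
        for i in range(n):
            alpha = g
            beta = 1.0 - g
            for j in range(J):
                if D[j][i] == 1:
                    alpha *= p[j]
                    beta *= 1.0 - q[j]
                else:
                    alpha *= 1.0 - p[j]
                    beta *= q[j]
            W[i] = alpha / (alpha + beta)
        new_p, new_q = [], []
        sw = sum(W)
        snw = n - sw
        for j in range(J):
            num_p = sum(W[i] for i in range(n) if D[j][i] == 1)
            num_q = sum(1.0 - W[i] for i in range(n) if D[j][i] == 0)
            new_p.append(num_p / sw if sw > 0 else p[j])
            new_q.append(num_q / snw if snw > 0 else q[j])
        delta = max(max(abs(a - b) for a, b in zip(new_p, p)),
                    max(abs(a - b) for a, b in zip(new_q, q)))
        p, q = new_p, new_q
        if delta < tol:
            break
    # one final E-step so W corresponds to the final (p, q), as in the
    # implementation's last iteration
    for i in range(n):
        alpha = g
        beta = 1.0 - g
        for j in range(J):
            if D[j][i] == 1:
                alpha *= p[j]
                beta *= 1.0 - q[j]
            else:
                alpha *= 1.0 - p[j]
                beta *= q[j]
        W[i] = alpha / (alpha + beta)
    return W, p, q


def random_masks(rng, shape=(4, 4), n_raters=3, p_fg=0.4, correlated=False):
    """Random rater configurations; ``correlated`` derives raters from a
    common base mask with a few flipped pixels (with only 2 raters a fully
    independent pair makes the consensus ill-posed)."""
    while True:
        if correlated:
            base = rng.random(shape) < p_fg
            masks = []
            for _ in range(n_raters):
                m = base.copy()
                flip = rng.random(shape) < 0.15
                m[flip] = ~m[flip]
                masks.append(m)
        else:
            masks = [rng.random(shape) < p_fg for _ in range(n_raters)]
        if all(m.any() for m in masks):
            return masks


class TestStapleSlice:
    def test_unanimity_reproduces_input(self):
        m = np.zeros((6, 6), dtype=bool)
        m[2:5, 1:4] = True
        res = staple_slice([m, m, m])
        np.testing.assert_allclose(res.probability_map[m], 1.0, atol=1e-6)
        np.testing.assert_allclose(res.probability_map[~m], 0.0, atol=1e-6)
        np.testing.assert_array_equal(binarize(res.probability_map), m)

    def test_one_dissenting_pixel_equals_majority_vote(self):
        base = np.zeros((4, 4), dtype=bool)
        base[1:3, 1:3] = True
        masks = [base.copy(), base.copy(), base.copy()]
        masks[2][1, 1] = False  # one dissenter
        res = staple_slice(masks, init_p=0.99, init_q=0.99)
        majority = (masks[0].astype(int) + masks[1] + masks[2]) >= 2
        np.testing.assert_array_equal(binarize(res.probability_map), majority)
        # and the posterior agrees with the independent EM oracle
        W, p, q = em_oracle(masks)
        np.testing.assert_allclose(res.probability_map.ravel(), W, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("shape,n_raters", [((4, 4), 3), ((5, 5), 4), ((3, 5), 2)])
    def test_matches_bruteforce_em_oracle(self, seed, shape, n_raters):
        rng = np.random.default_rng(seed)
        masks = random_masks(rng, shape, n_raters, correlated=(n_raters == 2))
        # fixed iteration count: both runs perform the identical EM update
        # sequence, so any discrepancy is an implementation defect
        res = staple_slice(masks, tol=1e-300, max_iter=50)
        W, p, q = em_oracle(masks, tol=1e-300, max_iter=50)
        np.testing.assert_allclose(res.probability_map.ravel(), W, atol=1e-10)
        for j, perf in enumerate(res.performance):
            assert perf.sensitivity == pytest.approx(p[j], abs=1e-8)
            assert perf.specificity == pytest.approx(q[j], abs=1e-8)

    def test_disjoint_raters_symmetric_tie_goes_to_background(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0:2] = True
        b[3, 2:4] = True
        # hand computation, first E-step with symmetric init p = q and
        # prior 1/2: a pixel claimed by exactly one rater has
        # alpha = 0.5*p*(1-p), beta = 0.5*(1-q)*q, so W = 1/2 exactly
        p = q = 0.9
        alpha = 0.5 * p * (1 - p)
        beta = 0.5 * (1 - q) * q
        w_claimed = alpha / (alpha + beta)
        assert w_claimed == pytest.approx(0.5, abs=1e-15)
        # the documented tie rule maps W = 1/2 to background
        assert not binarize(np.full((1, 1), w_claimed)).any()
        # and the EM trajectory still matches the independent oracle
        res = staple_slice([a, b], init_p=0.9, init_q=0.9, prior=0.5,
                           tol=1e-300, max_iter=50)
        W, _, _ = em_oracle([a, b], init_p=0.9, init_q=0.9, prior=0.5,
                            tol=1e-300, max_iter=50)
        np.testing.assert_allclose(res.probability_map.ravel(), W, atol=1e-10)

    def test_rater_permutation_invariance(self, rng):
        masks = random_masks(rng, (6, 6), 4)
        r1 = staple_slice(masks)
        r2 = staple_slice(masks[::-1])
        np.testing.assert_allclose(r1.probability_map, r2.probability_map, atol=1e-12)
        pq1 = sorted((p.sensitivity, p.specificity) for p in r1.performance)
        pq2 = sorted((p.sensitivity, p.specificity) for p in r2.performance)
        np.testing.assert_allclose(pq1, pq2, atol=1e-12)

    def test_loglik_never_decreases(self, rng):
        for _ in range(10):
            masks = random_masks(rng, (6, 6), 3)
            res = staple_slice(masks)
            trace = np.array(res.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_all_empty_slice_is_degenerate(self):
        z = np.zeros((4, 4), dtype=bool)
        res = staple_slice([z, z])
        assert res.degenerate
        assert not res.probability_map.any()
        assert all(math.isnan(p.sensitivity) for p in res.performance)

    def test_empty_rater_excluded_not_boundary_driven(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        z = np.zeros_like(m)
        res = staple_slice([m, m, z])
        assert math.isnan(res.performance[2].sensitivity)
        np.testing.assert_array_equal(binarize(res.probability_map), m)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            staple_slice([np.ones((3, 3), bool), np.ones((4, 4), bool)])


class TestBinarize:
    def test_extremes(self):
        assert binarize(np.ones((2, 2))).all()
        assert not binarize(np.zeros((2, 2))).any()

    def test_exact_half_goes_to_background(self):
        assert not binarize(np.full((2, 2), 0.5)).any()

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=1.5)


class TestRoi:
    def test_background_padding_invariance_bit_exact(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            r = np.random.default_rng(seed)
            core = [r.random((8, 8)) < 0.4 for _ in range(3)]
            if not any(m.any() for m in core):
                continue
            small = [np.pad(m, 4) for m in core]
            big = [np.pad(m, 60) for m in core]
            res_s = staple_slice(crop_to_roi(small)[0])
            res_b = staple_slice(crop_to_roi(big)[0])
            np.testing.assert_array_equal(
                binarize(res_s.probability_map), binarize(res_b.probability_map))
            np.testing.assert_allclose(res_s.probability_map, res_b.probability_map,
                                       atol=0)

    def test_single_pixel_roi(self):
        m = np.zeros((10, 10), dtype=bool)
        m[5, 5] = True
        cropped, (r, c) = crop_to_roi([m], margin=1)
        assert cropped[0].shape == (3, 3)
        assert (r.start, c.start) == (4, 4)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            crop_to_roi([np.zeros((4, 4), bool)])


def _disc_stack(radius_px=8, grid=36):
    c = (grid - 1) / 2
    yy, xx = np.mgrid[0:grid, 0:grid]
    m = np.hypot(yy - c, xx - c) <= radius_px
    return MaskStack(slices=m[None], pixel_spacing_mm=(1.0, 1.0), slice_thickness_mm=8.0)


class TestFuseStack:
    def test_identical_stacks_identity(self, tiny_spec):
        st = simulate_lv_truth(tiny_spec, "CTRL-01", "ED")
        fused, results = fuse_stack([st, st.copy(), st.copy()])
        np.testing.assert_array_equal(fused.slices, st.slices)
        assert len(results) == st.n_slices

    def test_rater_order_invariance(self, tiny_spec):
        truth = simulate_lv_truth(tiny_spec, "CTRL-01", "ED")
        raters = [simulate_rater(truth, RaterProfile(b, 1.0), seed=3, rater_index=i)
                  for i, b in enumerate((2.0, -2.0, 1.5))]
        f1, _ = fuse_stack(raters)
        f2, _ = fuse_stack(raters[::-1])
        np.testing.assert_array_equal(f1.slices, f2.slices)

    def test_slice_count_mismatch_rejected(self, tiny_spec):
        a = simulate_lv_truth(tiny_spec, "CTRL-01", "ED")
        b = MaskStack(slices=a.slices[:3].copy(),
                      pixel_spacing_mm=a.pixel_spacing_mm,
                      slice_thickness_mm=a.slice_thickness_mm)
        with pytest.raises(ValueError):
            fuse_stack([a, b])

    def test_fusion_beats_worst_rater(self):
        """Fused mask overlaps the truth at least as well as the worst of 5
        jittered raters in >= 95% of 100 seeded replicates."""
        truth = _disc_stack()
        profiles = [RaterProfile(b, 1.5) for b in (2.0, -2.0, 1.5, -1.5, 1.0)]
        wins = 0
        for seed in range(100):
            raters = [simulate_rater(truth, prof, seed=seed, rater_index=i)
                      for i, prof in enumerate(profiles)]
            fused, _ = fuse_stack(raters)

            def jaccard(m):
                inter = (m.slices & truth.slices).sum()
                union = (m.slices | truth.slices).sum()
                return inter / union

            worst = min(jaccard(r) for r in raters)
            if jaccard(fused) >= worst:
                wins += 1
        assert wins >= 95

    def test_estimator_wrapper_reports_performance(self, tiny_spec):
        truth = simulate_lv_truth(tiny_spec, "CTRL-01", "ED")
        raters = [simulate_rater(truth, RaterProfile(b, 1.0), seed=1, rater_index=i)
                  for i, b in enumerate((1.5, -1.5, 2.0))]
        est = StapleFusion().fit(raters)
        assert est.consensus_.slices.shape == truth.slices.shape
        assert est.n_raters_ == 3
        assert np.all((est.sensitivity_ >= 0) & (est.sensitivity_ <= 1))
        params = est.get_params()
        assert params["tol"] == 1e-7
        est.set_params(max_iter=50)
        assert est.max_iter == 50
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
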