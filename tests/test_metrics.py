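"""Evaluation metrics: ARI against a brute-force pair-counting oracle and
hand-evaluated instances, Davies-Bouldin properties and sklearn cross-check,
cross-resolution segmentation comparison, and the grating contrast curve
against the Gaussian-MTF closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirfluor.metrics import (
    DEFAULT_LADDER,
    adjusted_rand_index,
    compare_segmentations,
    contingency_table,
    contrast_curve,
    davies_bouldin,
    resolution_limit,
)
from mirfluor.mir import RasterGrid, SpotProfile
from mirfluor.segment import SegmentationMap


def ari_bruteforce(a, b):
    """Independent oracle: enumerate all n(n−1)/2 item pairs."""
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    n = a.size
    s11 = same_a = same_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            ea, eb = a[i] == a[j], b[i] == b[j]
            same_a += ea
            same_b += eb
            s11 += ea and eb
    total = n * (n - 1) / 2
    expected = same_a * same_b / total
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0
    return (s11 - expected) / (max_index - expected)


class TestARI:
    def test_identity_and_hand_example(self):
        a = np.array([1, 1, 2, 2])
        assert adjusted_rand_index(a, a) == 1.0
        # classic anti-correlated 2×2 case, evaluated by hand: −0.5
        assert adjusted_rand_index(a, np.array([1, 2, 1, 2])) == pytest.approx(-0.5)

    def test_single_cluster_degeneracy(self, rng):
        b = rng.integers(0, 3, size=40)
        assert adjusted_rand_index(np.zeros(40, int), b) == 0.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(5, 60),
        ka=st.integers(1, 5),
        kb=st.integers(1, 5),
        seed=st.integers(0, 10_000),
    )
    def test_matches_bruteforce_pair_counting(self, n, ka, kb, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, ka, size=n)
        b = rng.integers(0, kb, size=n)
        assert adjusted_rand_index(a, b) == pytest.approx(
            ari_bruteforce(a, b), abs=1e-12
        )

    def test_large_instances_match_bruteforce(self, rng):
        for n in (150, 200):
            a = rng.integers(0, 6, size=n)
            b = rng.integers(0, 4, size=n)
            assert adjusted_rand_index(a, b) == pytest.approx(
                ari_bruteforce(a, b), abs=1e-12
            )

    def test_permutation_invariance(self, rng):
        a = rng.integers(0, 5, size=300)
        b = rng.integers(0, 5, size=300)
        perm = rng.permutation(5)
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(perm[a], b), abs=1e-12
        )

    def test_chance_expectation_near_zero(self):
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(1000):
            a = rng.integers(0, 4, size=100)
            b = rng.integers(0, 4, size=100)
            vals.append(adjusted_rand_index(a, b))
        assert abs(np.mean(vals)) < 0.02
        assert min(vals) >= -1.0 and max(vals) <= 1.0

    def test_contingency_marginals(self, rng):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 4, size=50)
        t = contingency_table(a, b)
        assert t.counts.sum() == t.n == 50
        assert np.array_equal(t.counts.sum(axis=1), t.row_marginals)
        assert np.array_equal(t.counts.sum(axis=0), t.col_marginals)


class TestDaviesBouldin:
    def test_hand_computed_instance(self):
        # clusters {0,1} and {10,11}: S = 0.5 each, M = 10 → DBI = 0.1
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert davies_bouldin(pts, labels) == pytest.approx(0.1)

    def test_similarity_invariances(self, rng):
        pts = rng.normal(size=(120, 2))
        labels = rng.integers(0, 3, size=120)
        base = davies_bouldin(pts, labels)
        assert davies_bouldin(5.0 * pts, labels) == pytest.approx(base)
        assert davies_bouldin(pts + np.array([3.0, -7.0]), labels) == pytest.approx(base)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert davies_bouldin(pts @ rot.T, labels) == pytest.approx(base)

    def test_vanishes_as_separation_grows(self, rng):
        a = rng.normal(0, 0.3, size=(50, 2))
        vals = []
        for gap in (3.0, 10.0, 100.0):
            pts = np.concatenate([a, a + np.array([gap, 0.0])])
            labels = np.repeat([0, 1], 50)
            vals.append(davies_bouldin(pts, labels))
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.02

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import davies_bouldin_score

        pts = rng.normal(size=(200, 3))
        labels = rng.integers(0, 4, size=200)
        assert davies_bouldin(pts, labels) == pytest.approx(
            davies_bouldin_score(pts, labels), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin(np.arange(4.0), np.zeros(4, int))
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(
                np.array([0.0, 1.0, 0.0, 1.0]), np.array([0, 0, 1, 1])
            )


class TestCompareSegmentations:
    def test_self_and_permuted_copy(self, rng):
        labels = rng.integers(0, 5, size=(40, 40))
        seg = SegmentationMap(labels, 4.0)
        assert compare_segmentations(seg, seg).ari == 1.0
        perm = rng.permutation(5)
        seg_p = SegmentationMap(perm[labels], 4.0)
        assert compare_segmentations(seg, seg_p).ari == 1.0

    def test_block_degraded_copy(self, phantom256):
        """4×-block downsample then upsample: agreement drops but stays high."""
        truth = SegmentationMap(phantom256.labels, phantom256.pitch)
        coarse = SegmentationMap(
            phantom256.labels[::4, ::4], phantom256.pitch * 4
        )
        rep = compare_segmentations(truth, coarse, register=False)
        assert 0.5 < rep.ari < 1.0
        assert rep.pitch_b == 4 * rep.pitch_a

    def test_single_pixel_overlap_rejected(self):
        # a 1×1 intersection has no item pairs: the ARI is undefined
        a = SegmentationMap(np.zeros((1, 1), int), 1.0)
        b = SegmentationMap(np.ones((1, 1), int), 1.0)
        with pytest.raises(ValueError):
            compare_segmentations(a, b, register=False)


@pytest.fixture(scope="module")
def curve():
    return contrast_curve(SpotProfile(22.0), RasterGrid(step=5.0))


class TestContrastCurve:

    def test_near_dc_limit(self, curve):
        assert curve.contrasts[0] >= 0.99
        assert all(0.0 <= c <= 1.0 for c in curve.contrasts)

    def test_matches_gaussian_mtf_closed_form(self, curve):
        sigma = 22.0 / 4.0
        for f, c, al in zip(curve.frequencies, curve.contrasts, curve.aliased):
            if al or f > 80.0:
                continue
            theory = np.exp(-2 * np.pi**2 * sigma**2 * (f / 1000.0) ** 2)
            assert abs(c - theory) / theory < 0.03

    def test_strictly_decreasing_below_nyquist(self, curve):
        live = [c for c, al in zip(curve.contrasts, curve.aliased) if not al]
        assert all(b < a for a, b in zip(live, live[1:]))
        # aliased tail is flagged and zeroed
        assert all(
            c == 0.0 for c, al in zip(curve.contrasts, curve.aliased) if al
        )

    def test_out_of_range_ladder_rejected(self):
        with pytest.raises(ValueError):
            contrast_curve(SpotProfile(), RasterGrid(step=5.0), ladder=(0.5, 300.0))


class TestResolutionLimit:
    def test_default_system_resolves_50(self, curve_5um=None):
        curve = contrast_curve(SpotProfile(22.0), RasterGrid(step=5.0))
        assert resolution_limit(curve, threshold=0.2) == 50.0

    def test_native_raster_nyquist_bound(self):
        curve = contrast_curve(SpotProfile(22.0), RasterGrid(step=20.0))
        assert resolution_limit(curve, threshold=0.2) <= 25.0

    def test_all_above_threshold_gives_ladder_top(self):
        curve = contrast_curve(SpotProfile(1.0), RasterGrid(step=1.0))
        assert resolution_limit(curve, threshold=0.2) == max(DEFAULT_LADDER)

    def test_monotone_in_spot_and_sampling(self):
        limits_spot = [
            resolution_limit(contrast_curve(SpotProfile(d), RasterGrid(step=5.0)))
            for d in (10.0, 22.0, 40.0)
        ]
        assert limits_spot[0] >= limits_spot[1] >= limits_spot[2]
        limits_step = [
            resolution_limit(contrast_curve(SpotProfile(22.0), RasterGrid(step=s)))
            for s in (20.0, 10.0, 5.0)
        ]
        assert limits_step[0] <= limits_step[1] <= limits_step[2]
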