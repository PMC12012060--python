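"""Heatmap construction, IoU/CC, MultiMatch, and split evaluation."""

import math

import numpy as np
import pytest

from gazetwin import (Fixation, Scanpath, evaluate_split, heatmap_cc, heatmap_iou,
                      multimatch, render_heatmap)
from gazetwin.metrics import Heatmap, gaussian_kernel_mass


def make_path(coords):
    return Scanpath([Fixation(x, y, t) for x, y, t in coords])


# ---------------------------------------------------------------------------
# Independent scalar MultiMatch oracle (simple loops, written against the
# metric definition before the vectorized implementation was finished)
# ---------------------------------------------------------------------------

def oracle_multimatch(a, b):
    ax = [f.x for f in a]; ay = [f.y for f in a]; at = [f.t for f in a]
    bx = [f.x for f in b]; by = [f.y for f in b]; bt = [f.t for f in b]
    U = [(ax[i + 1] - ax[i], ay[i + 1] - ay[i]) for i in range(len(ax) - 1)]
    V = [(bx[j + 1] - bx[j], by[j + 1] - by[j]) for j in range(len(bx) - 1)]
    n, m = len(U), len(V)
    cost = [[math.hypot(U[i][0] - V[j][0], U[i][1] - V[j][1]) for j in range(m)]
            for i in range(n)]
    # exhaustive DP over monotone paths
    INF = float("inf")
    D = [[INF] * m for _ in range(n)]
    D[0][0] = cost[0][0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            prev = min([D[i - 1][j] if i else INF, D[i][j - 1] if j else INF,
                        D[i - 1][j - 1] if i and j else INF])
            D[i][j] = cost[i][j] + prev
    pairs = []
    i, j = n - 1, m - 1
    while True:
        pairs.append((i, j))
        if i == j == 0:
            break
        cands = []
        if i and j:
            cands.append((D[i - 1][j - 1], (i - 1, j - 1)))
        if i:
            cands.append((D[i - 1][j], (i - 1, j)))
        if j:
            cands.append((D[i][j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
    pairs.reverse()

    def ang(u):
        return math.atan2(u[1], u[0])

    diag = math.sqrt(2.0)
    sh = ln = dr = po = du = 0.0
    for i, j in pairs:
        u, v = U[i], V[j]
        sh += math.hypot(u[0] - v[0], u[1] - v[1]) / diag
        ln += abs(math.hypot(*u) - math.hypot(*v)) / diag
        d = abs(ang(u) - ang(v)) % (2 * math.pi)
        dr += min(d, 2 * math.pi - d) / math.pi
        po += math.hypot(ax[i] - bx[j], ay[i] - by[j]) / diag
        du += abs(at[i] - bt[j]) / max(at[i], bt[j])
    k = len(pairs)
    return tuple(1.0 - x / k for x in (sh, dr, ln, po, du))


# hand-worked pairs: equal vector sets make the diagonal alignment optimal,
# so every dimension reduces to short closed-form arithmetic
A1 = make_path([(0.2, 0.2, 0.5), (0.5, 0.2, 0.5), (0.5, 0.5, 0.5)])
B1 = make_path([(0.4, 0.2, 0.5), (0.7, 0.2, 0.5), (0.7, 0.5, 0.5)])  # +0.2 in x
A2 = make_path([(0.1, 0.1, 0.2), (0.4, 0.1, 0.4), (0.4, 0.4, 0.8)])
B2 = make_path([(0.1, 0.2, 0.4), (0.5, 0.2, 0.2), (0.5, 0.6, 0.1)])

HAND_CASES = [
    # (pair, shape, direction, length, position, duration)
    ((A1, A1), 1.0, 1.0, 1.0, 1.0, 1.0),
    ((A1, B1), 1.0, 1.0, 1.0, 1.0 - 0.2 / math.sqrt(2), 1.0),
    ((A2, B2), 1.0 - 0.1 / math.sqrt(2), 1.0, 1.0 - 0.1 / math.sqrt(2),
     1.0 - (0.1 + math.hypot(0.1, 0.1)) / (2 * math.sqrt(2)), 0.5),
]


class TestMultiMatch:
    @pytest.mark.parametrize("pair, sh, dr, ln, po, du", HAND_CASES)
    def test_hand_oracle(self, pair, sh, dr, ln, po, du):
        score = multimatch(*pair)
        assert score.shape == pytest.approx(sh, abs=1e-9)
        assert score.direction == pytest.approx(dr, abs=1e-9)
        assert score.length == pytest.approx(ln, abs=1e-9)
        assert score.position == pytest.approx(po, abs=1e-9)
        assert score.duration == pytest.approx(du, abs=1e-9)

    @pytest.mark.parametrize("pair", [c[0] for c in HAND_CASES])
    def test_matches_scalar_oracle(self, pair):
        score = multimatch(*pair)
        sh, dr, ln, po, du = oracle_multimatch(*pair)
        assert score.shape == pytest.approx(sh, abs=1e-9)
        assert score.direction == pytest.approx(dr, abs=1e-9)
        assert score.length == pytest.approx(ln, abs=1e-9)
        assert score.position == pytest.approx(po, abs=1e-9)
        assert score.duration == pytest.approx(du, abs=1e-9)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.1, 1))
                           for _ in range(int(rng.integers(2, 8)))])
            b = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.1, 1))
                           for _ in range(int(rng.integers(2, 8)))])
            got = multimatch(a, b)
            exp = oracle_multimatch(a, b)
            for val, ref in zip((got.shape, got.direction, got.length,
                                 got.position, got.duration), exp):
                assert val == pytest.approx(max(0.0, min(1.0, ref)), abs=1e-9)

    def test_identity_all_ones(self):
        score = multimatch(A2, A2)
        assert (score.shape, score.direction, score.length,
                score.position, score.duration) == (1, 1, 1, 1, 1)
        assert score.mMM == 1.0 and score.mD_MM == 1.0

    def test_translation_only_position_decreases(self):
        score = multimatch(A1, B1)
        assert score.shape == score.length == score.direction == 1.0
        assert score.position < 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.1, 1))
                           for _ in range(4)])
            b = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.1, 1))
                           for _ in range(6)])
            s1, s2 = multimatch(a, b), multimatch(b, a)
            for k in ("shape", "direction", "length", "position", "duration"):
                assert getattr(s1, k) == pytest.approx(getattr(s2, k), abs=1e-12)

    def test_components_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.01, 2))
                           for _ in range(int(rng.integers(2, 10)))])
            b = make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.01, 2))
                           for _ in range(int(rng.integers(2, 10)))])
            s = multimatch(a, b)
            for k in ("shape", "direction", "length", "position", "duration"):
                assert 0.0 <= getattr(s, k) <= 1.0

    def test_single_fixation_vector_dims_missing(self):
        a = make_path([(0.5, 0.5, 0.3)])
        b = make_path([(0.5, 0.5, 0.3), (0.6, 0.6, 0.3)])
        s = multimatch(a, b)
        assert math.isnan(s.shape) and math.isnan(s.direction) and math.isnan(s.length)
        assert 0.0 <= s.position <= 1.0 and 0.0 <= s.duration <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            multimatch(Scanpath([]), A1)


class TestHeatmap:
    def test_single_fixation_argmax_at_center(self):
        h = render_heatmap(make_path([(0.5, 0.5, 1.0)]), (101, 101), sigma=8)
        iy, ix = np.unravel_index(np.argmax(h.raster), h.raster.shape)
        assert (iy, ix) == (50, 50)

    def test_duration_scales_peaks_linearly(self):
        path = make_path([(0.2, 0.5, 1.0), (0.8, 0.5, 2.0)])
        h = render_heatmap(path, (128, 128), sigma=5, normalize=False)
        p1 = h.raster[64, int(round(0.2 * 127))]
        p2 = h.raster[64, int(round(0.8 * 127))]
        assert p2 / p1 == pytest.approx(2.0, rel=0.01)

    def test_mass_equals_duration_times_kernel_mass(self):
        path = make_path([(0.5, 0.5, 0.7), (0.45, 0.55, 1.1)])
        h = render_heatmap(path, (256, 256), sigma=10, normalize=False)
        expected = (0.7 + 1.1) * gaussian_kernel_mass(10)
        assert h.raster.sum() == pytest.approx(expected, rel=0.01)

    def test_normalized_map_invariant_to_duration_scale(self):
        base = [(0.3, 0.4, 0.5), (0.7, 0.6, 1.5)]
        h1 = render_heatmap(make_path(base), (128, 128), sigma=6)
        h2 = render_heatmap(make_path([(x, y, 2 * t) for x, y, t in base]),
                            (128, 128), sigma=6)
        np.testing.assert_allclose(h1.raster, h2.raster, atol=1e-6)

    def test_raster_nonnegative(self):
        h = render_heatmap(make_path([(0.1, 0.9, 0.2)]), (64, 64), sigma=4)
        assert h.raster.min() >= 0.0 and h.raster.max() <= 1.0


class TestIoUCC:
    def test_identity(self):
        h = render_heatmap(make_path([(0.5, 0.5, 1.0)]), (64, 64), sigma=5)
        assert heatmap_iou(h, h) == 1.0
        assert heatmap_cc(h, h) == pytest.approx(1.0)

    def test_disjoint_masks_zero(self):
        a = render_heatmap(make_path([(0.1, 0.1, 1.0)]), (256, 256), sigma=5)
        b = render_heatmap(make_path([(0.9, 0.9, 1.0)]), (256, 256), sigma=5)
        assert heatmap_iou(a, b) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = render_heatmap(make_path([(rng.uniform(), rng.uniform(), 1.0)
                                          for _ in range(3)]), (64, 64), sigma=4)
            b = render_heatmap(make_path([(rng.uniform(), rng.uniform(), 1.0)
                                          for _ in range(3)]), (64, 64), sigma=4)
            assert heatmap_iou(a, b) == heatmap_iou(b, a)
            assert heatmap_cc(a, b) == pytest.approx(heatmap_cc(b, a), abs=1e-12)

    def test_cc_inverted_map(self):
        a = render_heatmap(make_path([(0.4, 0.4, 1.0)]), (64, 64), sigma=6)
        b = Heatmap(a.raster.max() - a.raster, a.sigma)
        assert heatmap_cc(a, b) == pytest.approx(-1.0)

    def test_cc_matches_pearson_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = rng.random((2, 32, 32))
            got = heatmap_cc(Heatmap(x, 1.0), Heatmap(y, 1.0))
            ref = np.corrcoef(x.ravel(), y.ravel())[0, 1]
            assert got == pytest.approx(ref, abs=1e-9)

    def test_cc_constant_map_is_nan(self):
        a = Heatmap(np.zeros((16, 16)), 1.0)
        b = Heatmap(np.ones((16, 16)), 1.0)
        assert math.isnan(heatmap_cc(a, b))

    def test_iou_monotone_degradation_with_offset(self):
        base = [(0.3, 0.5, 1.0), (0.5, 0.5, 0.8), (0.4, 0.6, 0.5)]
        ref = render_heatmap(make_path(base), (256, 256), sigma=12)
        ious = []
        for off in (0.0, 0.05, 0.1, 0.2, 0.3):
            moved = make_path([(x + off, y, t) for x, y, t in base])
            ious.append(heatmap_iou(render_heatmap(moved, (256, 256), sigma=12), ref))
        assert all(a >= b for a, b in zip(ious, ious[1:]))
        assert ious[0] > ious[-1]


class TestEvaluateSplit:
    def test_identity_metrics_and_zero_width_cis(self):
        rng = np.random.default_rng(5)
        paths = {f"c{i}": make_path([(rng.uniform(), rng.uniform(), rng.uniform(0.1, 1))
                                     for _ in range(4)]) for i in range(6)}
        report = evaluate_split(paths, paths, sigmas=(10.0,), raster=(128, 128),
                                n_bootstrap=200, seed=0)
        row = report.rows[0]
        assert row["mIoU"] == 1.0
        assert row["mCC"] == pytest.approx(1.0)
        assert row["mMM"] == 1.0 and row["mD_MM"] == 1.0
        for key in ("mIoU", "mCC", "mMM", "mD_MM"):
            assert row[f"{key}_ci_low"] == pytest.approx(row[f"{key}_ci_high"])

    def test_bootstrap_deterministic(self):
        rng = np.random.default_rng(6)
        pred = {f"c{i}": make_path([(rng.uniform(), rng.uniform(), 0.5)
                                    for _ in range(3)]) for i in range(5)}
        gt = {f"c{i}": make_path([(rng.uniform(), rng.uniform(), 0.5)
                                  for _ in range(3)]) for i in range(5)}
        a = evaluate_split(pred, gt, sigmas=(8.0,), raster=(64, 64),
                           n_bootstrap=300, seed=11).rows
        b = evaluate_split(pred, gt, sigmas=(8.0,), raster=(64, 64),
                           n_bootstrap=300, seed=11).rows
        assert a == b

    def test_miou_is_mean_of_per_case(self):
        rng = np.random.default_rng(7)
        pred = {f"c{i}": make_path([(rng.uniform(), rng.uniform(), 0.5)
                                    for _ in range(3)]) for i in range(4)}
        gt = {f"c{i}": make_path([(rng.uniform(), rng.uniform(), 0.5)
                                  for _ in range(3)]) for i in range(4)}
        report = evaluate_split(pred, gt, sigmas=(8.0,), raster=(64, 64),
                                n_bootstrap=50, seed=0)
        per_case = report.per_case
        assert report.rows[0]["mIoU"] == pytest.approx(per_case["iou"].mean(), abs=1e-9)

    def test_case_mismatch_reports_difference(self):
        p = {"a": A1}
        g = {"b": A1}
        with pytest.raises(ValueError, match=r"\['a'\].*\['b'\]"):
            evaluate_split(p, g)
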