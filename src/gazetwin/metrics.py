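"""Scanpath evaluation: fixation heatmaps, IoU, CC, MultiMatch, bootstrap CIs.

Heatmaps place a duration-scaled isotropic Gaussian (truncated at 3 sigma)
at every fixation; the default intensity spread is sigma = 50 px on a
512 x 512 rendering raster.  IoU compares masks thresholded at a fraction of
each map's maximum; CC is the pixelwise Pearson correlation of z-normalized
maps.  MultiMatch compares two scanpaths over five dimensions — shape,
direction, length, position, duration — after aligning their saccade
vectors with a dynamic program that minimizes the summed vector-difference
cost.  ``mMM`` aggregates the four spatial dimensions; the duration
dimension is reported separately as ``mD-MM`` (an ``include_duration`` flag
yields the five-dimension mean instead).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Scanpath

DEFAULT_SPREAD = 50.0  # px; default intensity spread around each fixation
DEFAULT_RASTER = (512, 512)  # (H, W) rendering resolution for normalized coords
DEFAULT_TAU = 0.1  # IoU mask threshold as a fraction of each map's max
_DIAG = math.sqrt(2.0)  # image diagonal in normalized coordinates


@dataclass
class Heatmap:
    """Duration-scaled fixation-density raster (non-negative, finite)."""

    raster: np.ndarray
    sigma: float
    scanpath_id: str | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if not np.all(np.isfinite(self.raster)) or self.raster.min() < 0:
            raise ValueError("heatmap raster must be finite and non-negative")


@dataclass
class MultiMatchScore:
    """Five-dimension scanpath similarity, each component in [0, 1].

    Vector-based components (shape, direction, length) are NaN when either
    scanpath has fewer than two fixations (no saccade vectors exist).
    """

    shape: float
    direction: float
    length: float
    position: float
    duration: float

    _SPATIAL = ("shape", "direction", "length", "position")

    @property
    def mMM(self) -> float:
        """Mean of the four spatial dimensions."""
        return float(np.mean([getattr(self, k) for k in self._SPATIAL]))

    @property
    def mD_MM(self) -> float:
        """The duration dimension."""
        return self.duration

    def mean(self, include_duration: bool = False) -> float:
        if include_duration:
            vals = [getattr(self, k) for k in self._SPATIAL] + [self.duration]
            return float(np.mean(vals))
        return self.mMM


# ---------------------------------------------------------------------------
# Heatmaps
# ---------------------------------------------------------------------------

def render_heatmap(path: Scanpath, image_size=DEFAULT_RASTER,
                   sigma: float = DEFAULT_SPREAD, normalize: bool = True,
                   scanpath_id: str | None = None) -> Heatmap:
    """Sum duration-scaled Gaussians (truncated at 3 sigma) at fixations.

    Fixation coordinates are normalized [0, 1] and mapped onto an
    ``image_size`` raster.  Before normalization the total mass equals
    ``sum_i t_i * (truncated kernel mass)`` for kernels fully inside the
    raster; with ``normalize=True`` the raster is max-normalized to [0, 1].
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if path.length == 0:
        raise ValueError("cannot render a heatmap of an empty scanpath")
    H, W = image_size
    raster = np.zeros((H, W))
    r = int(math.ceil(3.0 * sigma))
    win = np.arange(-r, r + 1, dtype=float)
    dist2 = win[None, :] ** 2 + win[:, None] ** 2
    kernel = np.exp(-dist2 / (2.0 * sigma * sigma))
    kernel[dist2 > (3.0 * sigma) ** 2] = 0.0
    for f in path.fixations:
        cx = int(round(f.x * (W - 1)))
        cy = int(round(f.y * (H - 1)))
        y0, y1 = max(0, cy - r), min(H, cy + r + 1)
        x0, x1 = max(0, cx - r), min(W, cx + r + 1)
        ky0, kx0 = y0 - (cy - r), x0 - (cx - r)
        raster[y0:y1, x0:x1] += f.t * kernel[ky0:ky0 + (y1 - y0), kx0:kx0 + (x1 - x0)]
    if normalize and raster.max() > 0:
        raster = raster / raster.max()
    return Heatmap(raster, sigma, scanpath_id)


def gaussian_kernel_mass(sigma: float) -> float:
    """Discrete mass of the truncated unit-peak kernel used for rendering."""
    r = int(math.ceil(3.0 * sigma))
    win = np.arange(-r, r + 1, dtype=float)
    dist2 = win[None, :] ** 2 + win[:, None] ** 2
    kernel = np.exp(-dist2 / (2.0 * sigma * sigma))
    kernel[dist2 > (3.0 * sigma) ** 2] = 0.0
    return float(kernel.sum())


def heatmap_iou(a: Heatmap, b: Heatmap, tau: float = DEFAULT_TAU) -> float:
    """IoU of the two maps' masks at threshold ``tau * max`` (symmetric)."""
    if a.raster.shape != b.raster.shape:
        raise ValueError("heatmaps must share the raster size")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    mask_a = a.raster > tau * a.raster.max()
    mask_b = b.raster > tau * b.raster.max()
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        warnings.warn("empty mask union; IoU defined as 0", stacklevel=2)
        return 0.0
    inter = np.logical_and(mask_a, mask_b).sum()
    return float(inter / union)


def heatmap_cc(a: Heatmap, b: Heatmap) -> float:
    """Pixelwise Pearson correlation of z-normalized maps; NaN if constant."""
    if a.raster.shape != b.raster.shape:
        raise ValueError("heatmaps must share the raster size")
    x = a.raster.ravel()
    y = b.raster.ravel()
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    return float(np.mean(x * y))


# ---------------------------------------------------------------------------
# MultiMatch
# ---------------------------------------------------------------------------

def _vectors(path: Scanpath) -> np.ndarray:
    x, y, _ = path.to_arrays()
    return np.stack([np.diff(x), np.diff(y)], axis=1)


def _align(cost: np.ndarray) -> list[tuple[int, int]]:
    """Minimal-cost monotone path from (0,0) to (n-1,m-1); right/down/diag moves."""
    n, m = cost.shape
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, D[i - 1, j])
            if j > 0:
                best = min(best, D[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, D[i - 1, j - 1])
            D[i, j] = cost[i, j] + best
    pairs = []
    i, j = n - 1, m - 1
    while True:
        pairs.append((i, j))
        if i == j == 0:
            break
        cands = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
    return pairs[::-1]


def _angle_diff(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu < 1e-12 and nv < 1e-12:
        return 0.0
    a = math.atan2(u[1], u[0]) if nu >= 1e-12 else 0.0
    b = math.atan2(v[1], v[0]) if nv >= 1e-12 else 0.0
    d = abs(a - b) % (2 * math.pi)
    return min(d, 2 * math.pi - d)


def simplify_scanpath(path: Scanpath, amplitude_threshold: float = 0.05,
                      direction_threshold: float = math.radians(45.0)) -> Scanpath:
    """Optional scanpath simplification: merge small or same-direction saccades.

    Consecutive saccades are merged (dropping the middle fixation, summing
    its duration into the first) when both are shorter than
    ``amplitude_threshold`` or their directions differ by less than
    ``direction_threshold``.  Off by default in :func:`multimatch` to keep
    comparisons deterministic in the number of fixations.
    """
    fixes = list(path.fixations)
    changed = True
    while changed and len(fixes) > 2:
        changed = False
        for i in range(len(fixes) - 2):
            p0, p1, p2 = fixes[i], fixes[i + 1], fixes[i + 2]
            u = np.array([p1.x - p0.x, p1.y - p0.y])
            v = np.array([p2.x - p1.x, p2.y - p1.y])
            small = np.hypot(*u) < amplitude_threshold and np.hypot(*v) < amplitude_threshold
            same_dir = _angle_diff(u, v) < direction_threshold and (
                np.hypot(*u) >= 1e-12 and np.hypot(*v) >= 1e-12)
            if small or same_dir:
                merged = type(p0)(p0.x, p0.y, p0.t + p1.t)
                fixes = fixes[:i] + [merged] + fixes[i + 2:]
                changed = True
                break
    return Scanpath(fixes)


def multimatch(a: Scanpath, b: Scanpath, simplify: bool = False,
               amplitude_threshold: float = 0.05,
               direction_threshold: float = math.radians(45.0)) -> MultiMatchScore:
    """Five-dimension MultiMatch similarity between two normalized scanpaths.

    Saccade vectors are aligned by dynamic programming on the vector-
    difference cost; per aligned pair the dissimilarities are the vector
    difference norm (shape), absolute amplitude difference (length), angular
    difference (direction), fixation Euclidean distance (position) and
    relative duration difference (duration).  Spatial terms are normalized
    by the image diagonal (sqrt(2) in normalized coordinates), direction by
    pi; each similarity is 1 minus the mean normalized dissimilarity.
    """
    if a.length == 0 or b.length == 0:
        raise ValueError("multimatch requires non-empty scanpaths")
    if simplify:
        a = simplify_scanpath(a, amplitude_threshold, direction_threshold)
        b = simplify_scanpath(b, amplitude_threshold, direction_threshold)
    ax, ay, at = a.to_arrays()
    bx, by, bt = b.to_arrays()

    if a.length >= 2 and b.length >= 2:
        U, V = _vectors(a), _vectors(b)
        cost = np.linalg.norm(U[:, None, :] - V[None, :, :], axis=2)
        pairs = _align(cost)
        shape_d, len_d, dir_d, pos_d, dur_d = [], [], [], [], []
        for i, j in pairs:
            u, v = U[i], V[j]
            shape_d.append(np.linalg.norm(u - v) / _DIAG)
            len_d.append(abs(np.hypot(*u) - np.hypot(*v)) / _DIAG)
            dir_d.append(_angle_diff(u, v) / math.pi)
            pos_d.append(math.hypot(ax[i] - bx[j], ay[i] - by[j]) / _DIAG)
            m = max(at[i], bt[j])
            dur_d.append(abs(at[i] - bt[j]) / m if m > 0 else 0.0)
        mk = lambda d: float(np.clip(1.0 - np.mean(d), 0.0, 1.0))
        return MultiMatchScore(mk(shape_d), mk(dir_d), mk(len_d), mk(pos_d), mk(dur_d))

    # fewer than 2 fixations on one side: align fixations directly; the
    # vector-based dimensions are undefined
    cost = np.hypot(ax[:, None] - bx[None, :], ay[:, None] - by[None, :])
    pairs = _align(cost)
    pos_d, dur_d = [], []
    for i, j in pairs:
        pos_d.append(cost[i, j] / _DIAG)
        m = max(at[i], bt[j])
        dur_d.append(abs(at[i] - bt[j]) / m if m > 0 else 0.0)
    nan = float("nan")
    return MultiMatchScore(nan, nan, nan,
                           float(np.clip(1.0 - np.mean(pos_d), 0.0, 1.0)),
                           float(np.clip(1.0 - np.mean(dur_d), 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Split-level evaluation with bootstrap CIs
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-spread metric means with 95% bootstrap CIs, plus per-case tables."""

    rows: list[dict]
    per_case: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9f")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.rows, fh, indent=2, sort_keys=True)


def _bootstrap_ci(values: np.ndarray, idx_matrix: np.ndarray) -> tuple[float, float]:
    vals = values[idx_matrix]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vals, axis=1)
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def evaluate_split(pred: dict[str, Scanpath], gt: dict[str, Scanpath],
                   sigmas=(DEFAULT_SPREAD,), tau: float = DEFAULT_TAU,
                   n_bootstrap: int = 1000, seed: int = 0,
                   raster=DEFAULT_RASTER,
                   include_duration_in_mmm: bool = False) -> EvaluationReport:
    """Per-case IoU/CC (per spread sigma) and MultiMatch, with bootstrap CIs.

    The percentile bootstrap resamples cases with a seeded generator; the
    same resampling indices are used for every metric so reports are
    reproducible.  NaN per-case values (constant maps, single-fixation
    vector dimensions) are excluded from means.
    """
    if set(pred) != set(gt):
        only_pred = sorted(set(pred) - set(gt))
        only_gt = sorted(set(gt) - set(pred))
        raise ValueError(
            f"case-id mismatch: only in predictions {only_pred}, only in ground truth {only_gt}")
    ids = sorted(pred)
    n = len(ids)
    if n == 0:
        raise ValueError("no cases to evaluate")
    mm_scores = [multimatch(pred[c], gt[c]) for c in ids]
    mmm = np.array([s.mean(include_duration_in_mmm) for s in mm_scores])
    mdmm = np.array([s.mD_MM for s in mm_scores])
    rng = np.random.default_rng(seed)
    idx_matrix = rng.integers(0, n, size=(n_bootstrap, n))
    per_case_rows = []
    rows = []
    for sigma in sigmas:
        ious = np.empty(n)
        ccs = np.empty(n)
        for k, c in enumerate(ids):
            hp = render_heatmap(pred[c], raster, sigma)
            hg = render_heatmap(gt[c], raster, sigma)
            ious[k] = heatmap_iou(hp, hg, tau)
            ccs[k] = heatmap_cc(hp, hg)
            per_case_rows.append({"case_id": c, "sigma": sigma,
                                  "iou": ious[k], "cc": ccs[k],
                                  "mMM": mmm[k], "mD_MM": mdmm[k]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row = {"sigma": float(sigma), "tau": float(tau),
                   "mIoU": float(np.nanmean(ious)), "mCC": float(np.nanmean(ccs)),
                   "mMM": float(np.nanmean(mmm)), "mD_MM": float(np.nanmean(mdmm))}
        for key, vals in (("mIoU", ious), ("mCC", ccs), ("mMM", mmm), ("mD_MM", mdmm)):
            lo, hi = _bootstrap_ci(vals, idx_matrix)
            row[f"{key}_ci_low"], row[f"{key}_ci_high"] = lo, hi
        rows.append(row)
    return EvaluationReport(rows, pd.DataFrame(per_case_rows))


def iou_threshold_sweep(pred: dict[str, Scanpath], gt: dict[str, Scanpath],
                        taus=(0.05, 0.1, 0.2, 0.3, 0.5),
                        sigma: float = DEFAULT_SPREAD,
                        raster=DEFAULT_RASTER) -> pd.DataFrame:
    """Sensitivity of mIoU to the mask threshold tau (the binarization rule
    is a package choice; this exposes how much it matters)."""
    ids = sorted(pred)
    heat_p = {c: render_heatmap(pred[c], raster, sigma) for c in ids}
    heat_g = {c: render_heatmap(gt[c], raster, sigma) for c in ids}
    rows = []
    for tau in taus:
        vals = [heatmap_iou(heat_p[c], heat_g[c], tau) for c in ids]
        rows.append({"tau": float(tau), "mIoU": float(np.mean(vals))})
    return pd.DataFrame(rows)
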