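"""Synthetic radiology-scene generator: images, templated reports, scanpaths.

Each case is a grayscale raster with a small number of Gaussian "finding"
blobs, a closed-vocabulary report naming each finding and its zone, and a
ground-truth scanpath.  The scanpath mixes blob-directed fixations (2-D
Gaussian around each blob center, count and duration scaled by the blob's
salience) with exploratory fixations from a broad central prior, so that
fixation density concentrates on findings and total viewing time grows with
the number of abnormalities — the structure a report-conditioned gaze model
must learn, at desk scale and without credentialed eye-tracking data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .core import Fixation, GazeCase, Scanpath, write_fixation_table, write_manifest

FINDING_LABELS = ("opacity", "nodule", "consolidation", "effusion", "atelectasis", "mass")
NORMAL_SENTENCE = "heart and lungs are normal."

MAX_SCANPATH_LEN = 50  # generated sequence lengths are clipped to [1, 50]


def zone_phrase(cx: float, cy: float) -> str:
    """Discretize a normalized center into a left/right x upper/mid/lower zone."""
    side = "left" if cx < 0.5 else "right"
    if cy < 1.0 / 3.0:
        band = "upper"
    elif cy < 2.0 / 3.0:
        band = "mid"
    else:
        band = "lower"
    return f"{side} {band} zone"


def report_vocabulary() -> list[str]:
    """All words the templated reports can emit (the text encoder's world)."""
    words = set(FINDING_LABELS)
    words.update("in the zone left right upper mid lower".split())
    words.update(NORMAL_SENTENCE.replace(".", "").split())
    return sorted(words)


@dataclass(frozen=True)
class BlobSpec:
    """One synthetic finding: an isotropic Gaussian bump.

    ``sigma`` is the spatial extent as a fraction of image width; ``salience``
    (> 0) scales both the expected fixation count on the blob and the median
    fixation duration there.
    """

    cx: float
    cy: float
    sigma: float
    salience: float
    label: str

    def __post_init__(self) -> None:
        if not (0.1 <= self.cx <= 0.9 and 0.1 <= self.cy <= 0.9):
            raise ValueError(f"blob center ({self.cx}, {self.cy}) outside [0.1, 0.9]^2")
        if not 0.0 < self.sigma < 0.5:
            raise ValueError(f"blob sigma {self.sigma} outside (0, 0.5)")
        if not self.salience > 0:
            raise ValueError("salience must be positive")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study conditions.

    Defaults are the desk-scale conditions used throughout the package:
    64 x 64 rasters, up to 3 findings per case (uniform 0..3), an expected
    4 blob-directed fixations per unit salience, exploratory fixations at
    rate ``exploration_rate`` = 0.2 per slot, and lognormal durations with a
    0.25 s median and 0.5 dispersion, the median scaled by blob salience.
    """

    n_cases: int = 300
    image_height: int = 64
    image_width: int = 64
    max_blobs: int = 3
    blob_count_probs: tuple[float, ...] | None = None  # default: uniform 0..max_blobs
    exploration_rate: float = 0.2  # per-slot probability of an exploratory fixation
    fixations_per_blob: float = 4.0  # Poisson rate multiplier on salience
    exploration_fixations: float = 4.0  # Poisson mean for zero-blob (normal) cases
    duration_median: float = 0.25  # seconds; lognormal median for salience 1
    duration_sigma: float = 0.5  # lognormal dispersion
    sigma_range: tuple[float, float] = (0.05, 0.11)  # blob extent, fraction of width
    salience_sigma: float = 0.3  # lognormal dispersion of salience around 1
    blob_amplitude: float = 0.5  # image intensity of a salience-1 blob peak
    background_level: float = 0.25
    noise_level: float = 0.02  # std of additive image noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.max_blobs < 0:
            raise ValueError("n_cases and max_blobs must be >= 0")
        if not 0.0 <= self.exploration_rate <= 1.0:
            raise ValueError("exploration_rate must be in [0, 1]")
        for name in ("fixations_per_blob", "exploration_fixations", "duration_median",
                     "duration_sigma", "salience_sigma", "noise_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.blob_count_probs is not None:
            p = np.asarray(self.blob_count_probs, dtype=float)
            if p.size != self.max_blobs + 1 or p.min() < 0 or not np.isclose(p.sum(), 1.0):
                raise ValueError("blob_count_probs must be a distribution over 0..max_blobs")


# ---------------------------------------------------------------------------
# Scene sampling
# ---------------------------------------------------------------------------

def sample_scene(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[list[BlobSpec], str]:
    """Draw blobs and render the matching templated report."""
    if cfg.blob_count_probs is None:
        n_blobs = int(rng.integers(0, cfg.max_blobs + 1))
    else:
        n_blobs = int(rng.choice(cfg.max_blobs + 1, p=np.asarray(cfg.blob_count_probs)))
    blobs = []
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0.1, 0.9, size=2)
        sigma = rng.uniform(*cfg.sigma_range)
        salience = float(np.exp(rng.normal(0.0, cfg.salience_sigma)))
        label = str(rng.choice(FINDING_LABELS))
        blobs.append(BlobSpec(float(cx), float(cy), float(sigma), salience, label))
    if not blobs:
        return blobs, NORMAL_SENTENCE
    report = " ".join(f"{b.label} in the {zone_phrase(b.cx, b.cy)}." for b in blobs)
    return blobs, report


def render_image(blobs: list[BlobSpec], cfg: GeneratorConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Constant background + salience-weighted Gaussian bumps + noise, in [0, 1]."""
    H, W = cfg.image_height, cfg.image_width
    yy, xx = np.mgrid[0:H, 0:W]
    img = np.full((H, W), cfg.background_level, dtype=float)
    for b in blobs:
        px, py = b.cx * (W - 1), b.cy * (H - 1)
        s = b.sigma * W
        img += cfg.blob_amplitude * b.salience * np.exp(
            -((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * s * s))
    if rng is not None and cfg.noise_level > 0:
        img += rng.normal(0.0, cfg.noise_level, size=(H, W))
    return np.clip(img, 0.0, 1.0)


def _lognormal_duration(rng, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.normal()))


def _exploratory_fixation(cfg: GeneratorConfig, rng) -> Fixation:
    # broad central prior over the image
    x = float(np.clip(rng.normal(0.5, 0.25), 0.0, 1.0))
    y = float(np.clip(rng.normal(0.5, 0.25), 0.0, 1.0))
    t = max(_lognormal_duration(rng, cfg.duration_median, cfg.duration_sigma), 1e-3)
    return Fixation(x, y, t)


def sample_scanpath(blobs: list[BlobSpec], cfg: GeneratorConfig,
                    rng: np.random.Generator) -> Scanpath:
    """Sample a ground-truth scanpath for a scene.

    Blob-directed fixations (Poisson(rate x salience) per blob, 2-D Gaussian
    spread sigma, salience-scaled lognormal durations) are visited along a
    nearest-neighbor tour from the image center; exploratory fixations are
    interleaved with per-slot probability ``exploration_rate``.  Length is
    clipped to [1, 50].  Expected total duration grows with the blob count.
    """
    blob_fix: list[Fixation] = []
    # nearest-neighbor tour over blob centers starting from the image center
    remaining = list(blobs)
    pos = np.array([0.5, 0.5])
    tour: list[BlobSpec] = []
    while remaining:
        d = [np.hypot(b.cx - pos[0], b.cy - pos[1]) for b in remaining]
        b = remaining.pop(int(np.argmin(d)))
        tour.append(b)
        pos = np.array([b.cx, b.cy])
    for b in tour:
        n = int(rng.poisson(cfg.fixations_per_blob * b.salience))
        for _ in range(n):
            x = float(np.clip(rng.normal(b.cx, b.sigma), 0.0, 1.0))
            y = float(np.clip(rng.normal(b.cy, b.sigma), 0.0, 1.0))
            t = max(_lognormal_duration(rng, cfg.duration_median * b.salience,
                                        cfg.duration_sigma), 1e-3)
            blob_fix.append(Fixation(x, y, t))

    fixations: list[Fixation] = []
    if blob_fix:
        i = 0
        while i < len(blob_fix) and len(fixations) < MAX_SCANPATH_LEN:
            if rng.random() < cfg.exploration_rate:
                fixations.append(_exploratory_fixation(cfg, rng))
            else:
                fixations.append(blob_fix[i])
                i += 1
    if not fixations:
        n = max(1, int(rng.poisson(cfg.exploration_fixations)))
        fixations = [_exploratory_fixation(cfg, rng) for _ in range(n)]
    return Scanpath(fixations[:MAX_SCANPATH_LEN])


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_cases(cfg: GeneratorConfig,
                   return_blobs: bool = False) -> list[GazeCase] | tuple[list[GazeCase], list[list[BlobSpec]]]:
    """Generate ``n_cases`` in-memory cases, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    cases, scene_blobs = [], []
    for k in range(cfg.n_cases):
        blobs, report = sample_scene(cfg, rng)
        img = render_image(blobs, cfg, rng if cfg.noise_level > 0 else None)
        path = sample_scanpath(blobs, cfg, rng)
        cases.append(GazeCase(f"case_{k:05d}", img, report, path))
        scene_blobs.append(blobs)
    if return_blobs:
        return cases, scene_blobs
    return cases


def generate_dataset(cfg: GeneratorConfig, out_dir) -> list[GazeCase]:
    """Write a dataset (manifest + PNGs + fixation CSV + config sidecar)."""
    out_dir = os.fspath(out_dir)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)
    cases = generate_cases(cfg)
    records = []
    for c in cases:
        rel = os.path.join("images", f"{c.case_id}.png")
        arr = np.clip(np.round(c.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(os.path.join(out_dir, rel))
        records.append({"case_id": c.case_id, "image_path": rel, "report": c.report})
    write_manifest(records, os.path.join(out_dir, "manifest.jsonl"))
    write_fixation_table({c.case_id: c.scanpath for c in cases},
                         os.path.join(out_dir, "fixations.csv"))
    with open(os.path.join(out_dir, "generator_config.json"), "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
    return cases
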