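"""Domain types, coordinate conventions and fixation-table I/O.

Conventions used throughout the package:

* Coordinates are 0-based with the origin at the image's top-left corner.
  ``x`` is the column fraction and ``y`` the row fraction, both normalized to
  ``[0, 1]`` of the image width/height.  All model math happens in normalized
  space; pixel conversion occurs only at I/O and rendering boundaries.
* Fixation durations are stored in seconds as floats.
* The fixation-table CSV dialect is comma-separated UTF-8 with ``.`` as the
  decimal point and the header ``case_id,index,x,y,duration``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image

FIXATION_TABLE_COLUMNS = ("case_id", "index", "x", "y", "duration")


class CoordinateBoundsError(ValueError):
    """A fixation coordinate lies outside the image raster."""


class FixationTableError(ValueError):
    """A fixation-table CSV violates the format contract."""


@dataclass(frozen=True)
class Fixation:
    """A single gaze fixation: position plus dwell duration.

    ``x`` and ``y`` are normalized to ``[0, 1]`` (column/row fraction) once a
    scanpath has passed through :func:`to_normalized`; ``t`` is the duration
    in seconds and must be positive.
    """

    x: float
    y: float
    t: float


@dataclass
class Scanpath:
    """An ordered fixation sequence for one viewing of one image."""

    fixations: list[Fixation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.fixations)

    def __len__(self) -> int:  # pragma: no cover - convenience alias
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)

    @classmethod
    def from_arrays(cls, x, y, t) -> "Scanpath":
        x, y, t = (np.asarray(a, dtype=float).ravel() for a in (x, y, t))
        if not (x.shape == y.shape == t.shape):
            raise ValueError("x, y, t must have equal lengths")
        return cls([Fixation(float(a), float(b), float(c)) for a, b, c in zip(x, y, t)])

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.fixations:
            empty = np.empty(0, dtype=float)
            return empty, empty.copy(), empty.copy()
        arr = np.array([(f.x, f.y, f.t) for f in self.fixations], dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]

    def total_duration(self) -> float:
        return float(sum(f.t for f in self.fixations))

    def validate_normalized(self, case_id: str = "<scanpath>") -> None:
        """Check the normalized-coordinate and positive-duration invariants."""
        for i, f in enumerate(self.fixations):
            if not (0.0 <= f.x <= 1.0 and 0.0 <= f.y <= 1.0):
                raise CoordinateBoundsError(
                    f"case {case_id!r}, fixation {i}: ({f.x}, {f.y}) outside [0, 1]^2"
                )
            if not f.t > 0:
                raise ValueError(f"case {case_id!r}, fixation {i}: duration {f.t} not > 0")


@dataclass
class GazeCase:
    """Unit record of every dataset: image + report (+ optional scanpath)."""

    case_id: str
    image: np.ndarray  # (H, W) grayscale in [0, 1]
    report: str
    scanpath: Scanpath | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2 or min(self.image.shape) < 8:
            raise ValueError(
                f"case {self.case_id!r}: image must be 2-D with H, W >= 8, "
                f"got shape {self.image.shape}"
            )


@dataclass
class PaddedScanpathBatch:
    """Fixed-length (x, y, t) arrays with a validity mask.

    ``coords`` has shape ``(B, F, 3)``; ``valid_mask`` is ``(B, F)`` with 1
    for real fixations and 0 for padding — always a prefix of ones followed
    by zeros.  ``lengths`` records ``min(l_k, F)`` per case.
    """

    coords: np.ndarray
    valid_mask: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)


# ---------------------------------------------------------------------------
# Coordinate conversion
# ---------------------------------------------------------------------------

def to_normalized(path: Scanpath, width: int, height: int, case_id: str = "<scanpath>") -> Scanpath:
    """Convert a pixel-space scanpath to normalized [0, 1] coordinates.

    Pixel coordinates must lie in ``[0, width) x [0, height)``; durations are
    unchanged.  :func:`to_pixels` inverts this to within 0.5 px.
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    out = []
    for i, f in enumerate(path.fixations):
        if not (0.0 <= f.x < width and 0.0 <= f.y < height):
            raise CoordinateBoundsError(
                f"case {case_id!r}, fixation {i}: pixel ({f.x}, {f.y}) outside "
                f"[0, {width}) x [0, {height})"
            )
        out.append(Fixation(f.x / width, f.y / height, f.t))
    return Scanpath(out)


def to_pixels(path: Scanpath, width: int, height: int) -> Scanpath:
    """Inverse of :func:`to_normalized`."""
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    return Scanpath([Fixation(f.x * width, f.y * height, f.t) for f in path.fixations])


# ---------------------------------------------------------------------------
# Padding
# ---------------------------------------------------------------------------

def pad_and_mask(paths: Sequence[Scanpath], F: int) -> PaddedScanpathBatch:
    """Pad (or truncate) scanpaths to fixed length ``F`` with a validity mask.

    Paths longer than ``F`` keep their first ``F`` fixations; the recorded
    length is ``min(l, F)``.  Padded steps have zero coordinates.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    B = len(paths)
    coords = np.zeros((B, F, 3), dtype=float)
    mask = np.zeros((B, F), dtype=float)
    lengths = np.zeros(B, dtype=int)
    for k, p in enumerate(paths):
        if p.length == 0:
            raise ValueError(f"scanpath {k} is empty; ground-truth scanpaths need length >= 1")
        l = min(p.length, F)
        for i in range(l):
            f = p.fixations[i]
            coords[k, i] = (f.x, f.y, f.t)
        mask[k, :l] = 1.0
        lengths[k] = l
    return PaddedScanpathBatch(coords, mask, lengths)


# ---------------------------------------------------------------------------
# Fixation-table CSV I/O
# ---------------------------------------------------------------------------

def _open_maybe(file, mode: str):
    if isinstance(file, (str, os.PathLike)):
        return open(file, mode, encoding="utf-8", newline=""), True
    return file, False


def read_fixation_table(file) -> dict[str, Scanpath]:
    """Read a ``case_id,index,x,y,duration`` CSV into scanpaths.

    Per case, ``index`` must be 0-based and contiguous; durations must be
    positive.  Violations raise :class:`FixationTableError` naming the
    offending CSV line (1-based, header = line 1).
    """
    fh, owned = _open_maybe(file, "r")
    try:
        header = fh.readline().rstrip("\r\n")
        cols = header.split(",")
        if tuple(cols) != FIXATION_TABLE_COLUMNS:
            missing = set(FIXATION_TABLE_COLUMNS) - set(cols)
            raise FixationTableError(
                f"line 1: bad header {header!r}"
                + (f" (missing columns: {sorted(missing)})" if missing else "")
            )
        rows: dict[str, list[tuple[int, float, float, float]]] = {}
        lineno = 1
        for raw in fh:
            lineno += 1
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 5:
                raise FixationTableError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            case_id, idx_s, x_s, y_s, t_s = parts
            try:
                idx = int(idx_s)
                x, y, t = float(x_s), float(y_s), float(t_s)
            except ValueError as exc:
                raise FixationTableError(f"line {lineno}: {exc}") from None
            seq = rows.setdefault(case_id, [])
            if idx != len(seq):
                raise FixationTableError(
                    f"line {lineno}: case {case_id!r} index {idx} is not contiguous "
                    f"(expected {len(seq)})"
                )
            if not t > 0:
                raise FixationTableError(
                    f"line {lineno}: case {case_id!r} duration {t} is not positive"
                )
            seq.append((idx, x, y, t))
        return {
            cid: Scanpath([Fixation(x, y, t) for _, x, y, t in seq])
            for cid, seq in rows.items()
        }
    finally:
        if owned:
            fh.close()


def write_fixation_table(paths, file) -> int:
    """Write scanpaths as a fixation-table CSV; returns the row count.

    ``paths`` is a mapping ``case_id -> Scanpath`` or an iterable of such
    pairs (duplicate ids are rejected).  Rows are ordered by case_id
    (lexicographic) then fixation index, and the output is byte-deterministic.
    """
    if isinstance(paths, Mapping):
        items: Iterable = paths.items()
    else:
        items = paths
    table: dict[str, Scanpath] = {}
    for cid, p in items:
        if cid in table:
            raise ValueError(f"duplicate case_id {cid!r}")
        table[cid] = p
    fh, owned = _open_maybe(file, "w")
    try:
        fh.write(",".join(FIXATION_TABLE_COLUMNS) + "\n")
        count = 0
        for cid in sorted(table):
            for i, f in enumerate(table[cid].fixations):
                fh.write(f"{cid},{i},{f.x:.9f},{f.y:.9f},{f.t:.9f}\n")
                count += 1
        return count
    finally:
        if owned:
            fh.close()


# ---------------------------------------------------------------------------
# Case-manifest I/O (JSON-lines: case_id, image_path, report)
# ---------------------------------------------------------------------------

def write_manifest(records: Sequence[dict], file) -> None:
    fh, owned = _open_maybe(file, "w")
    try:
        for rec in records:
            fh.write(json.dumps(
                {"case_id": rec["case_id"], "image_path": rec["image_path"],
                 "report": rec["report"]}, sort_keys=True) + "\n")
    finally:
        if owned:
            fh.close()


def read_manifest(path, fixation_table=None) -> list[GazeCase]:
    """Load a JSON-lines manifest (and optional fixation table) into cases.

    Image paths are resolved relative to the manifest's directory; PNGs are
    read as grayscale and scaled to ``[0, 1]``.
    """
    base = os.path.dirname(os.fspath(path))
    paths = {}
    if fixation_table is not None:
        paths = read_fixation_table(fixation_table)
    cases: list[GazeCase] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            cid = rec["case_id"]
            if cid in seen:
                raise ValueError(f"duplicate case_id {cid!r} in manifest")
            seen.add(cid)
            img_path = os.path.join(base, rec["image_path"])
            img = np.asarray(Image.open(img_path).convert("L"), dtype=float) / 255.0
            cases.append(GazeCase(cid, img, rec["report"], paths.get(cid)))
    return cases
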