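"""Trajectory-to-image encodings and flattened feature vectors.

Every trajectory of a deployment is rasterized onto the same fixed canvas
(default 100×130 px over the home's bounding box, ≈0.1 m² per pixel) so that
image pixels are spatially comparable across trajectories.  Three encodings
are produced:

* **TRAJ** — the path as a white line string on black; each undirected
  sensor-pair edge is drawn once with a stroke thickness equal to the number
  of times it was walked (capped), so pacing/lapping thicken the line; proper
  self-crossings are overdrawn as red circles, flagging intricate
  (random-pattern) walks.
* **SPEED** — the path split into constant-speed sections, each drawn 1 px
  wide in a color keyed to its speed range; on re-walked sections the most
  recent speed wins (later sections overdraw earlier ones).
* **sensor-sequence (GVFE)** — a binary raster with the temporal firing order
  on the x axis and the sensor's ordinal identifier on the y axis; one set
  pixel per firing.

Images feed the classifier as binarized row-major flattened vectors
(3 channels × W × H, so 39,000 features for the default canvas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import LineString, Point

from .preprocess import Trajectory

__all__ = [
    "CANVAS_W",
    "CANVAS_H",
    "SPEED_BIN_EDGES",
    "SPEED_COLORS",
    "LayoutTransform",
    "make_layout_transform",
    "find_intersections",
    "render_traj_image",
    "speed_bin",
    "render_speed_image",
    "render_gvfe_image",
    "flatten_binarize",
]

CANVAS_W = 100  # px, home x extent
CANVAS_H = 130  # px, home y extent

PATH_COLOR = (255, 255, 255)
INTERSECTION_COLOR = (255, 0, 0)
INTERSECTION_RADIUS_M = 0.25
LINE_WEIGHT_CAP = 7  # px; thicker strokes blob out at this scale

#: Upper edges of the speed ranges (m/s); the last bin is open-ended.
SPEED_BIN_EDGES = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 15.0)

#: Bin index (1-based) -> RGB.  purple, violet, blue, cyan, green, yellow,
#: orange, red from slowest to fastest.
SPEED_COLORS = (
    (128, 0, 128),
    (238, 130, 238),
    (0, 0, 255),
    (0, 255, 255),
    (0, 128, 0),
    (255, 255, 0),
    (255, 165, 0),
    (255, 0, 0),
)


@dataclass(frozen=True)
class LayoutTransform:
    """Deterministic affine map from home meters to canvas pixels.

    The same transform is used for every trajectory of a deployment so that
    the spatial extent of all images coincides.  Uniform scale, origin at the
    top-left, y growing downward with home y.
    """

    x0: float  # meters mapped to pixel column 0 (left canvas edge)
    y0: float
    scale: float  # px per meter
    width: int = CANVAS_W
    height: int = CANVAS_H

    def to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map meters to integer pixel (col, row), clipped to the canvas."""
        col = np.clip(np.floor((np.asarray(x) - self.x0) * self.scale), 0, self.width - 1)
        row = np.clip(np.floor((np.asarray(y) - self.y0) * self.scale), 0, self.height - 1)
        return col.astype(int), row.astype(int)

    def to_meters(self, col, row) -> tuple[np.ndarray, np.ndarray]:
        """Center of pixel (col, row) in meters; inverse of :meth:`to_pixel`."""
        x = self.x0 + (np.asarray(col) + 0.5) / self.scale
        y = self.y0 + (np.asarray(row) + 0.5) / self.scale
        return x, y

    def contains(self, x, y) -> bool:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        w = self.width / self.scale
        h = self.height / self.scale
        return bool(
            (x >= self.x0).all()
            and (y >= self.y0).all()
            and (x <= self.x0 + w).all()
            and (y <= self.y0 + h).all()
        )


def make_layout_transform(
    sensor_map,
    width: int = CANVAS_W,
    height: int = CANVAS_H,
    margin: float = 0.0,
) -> LayoutTransform:
    """Fit the sensor bounding box (plus margin, meters) onto the canvas.

    Uses the largest uniform scale at which the padded box fits both axes and
    centers it, so every sensor lands strictly inside the canvas.
    """
    xmin, ymin, xmax, ymax = sensor_map.bounding_box
    w_m = xmax - xmin + 2 * margin
    h_m = ymax - ymin + 2 * margin
    if w_m <= 0 or h_m <= 0:
        raise ValueError("degenerate (zero-area) sensor bounding box")
    scale = min(width / w_m, height / h_m)
    # center the padded box on the canvas
    x0 = xmin - margin - (width / scale - w_m) / 2
    y0 = ymin - margin - (height / scale - h_m) / 2
    return LayoutTransform(x0=x0, y0=y0, scale=scale, width=width, height=height)


def find_intersections(traj: Trajectory, tol: float = 1e-9) -> list[tuple[float, float]]:
    """Proper crossing points between non-adjacent segments of the path.

    Shared endpoints of consecutive segments are not crossings.  Collinear
    overlaps (re-walked sections) contribute no points — they are rendered by
    stroke thickness instead.  Points closer than ``tol`` meters are merged.
    """
    xy = traj.xy
    if len(xy) < 2:
        raise ValueError("trajectory needs at least 2 records")
    segs = [LineString([xy[i], xy[i + 1]]) for i in range(len(xy) - 1)]
    pts: list[tuple[float, float]] = []
    for i in range(len(segs)):
        if segs[i].length == 0:
            continue
        for j in range(i + 2, len(segs)):
            if segs[j].length == 0:
                continue
            inter = segs[i].intersection(segs[j])
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if isinstance(g, Point):
                    pts.append((g.x, g.y))
    merged: list[tuple[float, float]] = []
    for p in pts:
        if not any(abs(p[0] - q[0]) <= tol and abs(p[1] - q[1]) <= tol for q in merged):
            merged.append(p)
    return merged


def _quantize(p: np.ndarray) -> tuple[int, int]:
    # mm quantization makes undirected-edge keys robust to float noise
    return (int(round(p[0] * 1000)), int(round(p[1] * 1000)))


def render_traj_image(traj: Trajectory, lt: LayoutTransform) -> np.ndarray:
    """Render the TRAJ encoding; returns an (H, W, 3) uint8 array.

    Each undirected edge between (quantized) consecutive positions is drawn
    once, white, with stroke thickness min(#traversals, 7) px; crossings are
    then overdrawn as filled red circles of radius max(1 px, 0.25 m).
    """
    xy = traj.xy
    if len(xy) < 2:
        raise ValueError("trajectory needs at least 2 records")
    if not lt.contains(xy[:, 0], xy[:, 1]):
        raise ValueError("trajectory extends outside the home bounding box")
    counts: dict[tuple, int] = {}
    order: list[tuple] = []
    for i in range(len(xy) - 1):
        a, b = _quantize(xy[i]), _quantize(xy[i + 1])
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in counts:
            order.append(key)
        counts[key] = counts.get(key, 0) + 1
    img = Image.new("RGB", (lt.width, lt.height), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    for key in order:
        (ax, ay), (bx, by) = key
        ac, ar = lt.to_pixel(ax / 1000, ay / 1000)
        bc, br = lt.to_pixel(bx / 1000, by / 1000)
        w = min(counts[key], LINE_WEIGHT_CAP)
        draw.line([(int(ac), int(ar)), (int(bc), int(br))], fill=PATH_COLOR, width=w)
    r = max(1, round(INTERSECTION_RADIUS_M * lt.scale))
    for x, y in find_intersections(traj):
        c, row = lt.to_pixel(x, y)
        draw.ellipse(
            [int(c) - r, int(row) - r, int(c) + r, int(row) + r],
            fill=INTERSECTION_COLOR,
        )
    return np.asarray(img, dtype=np.uint8)


def speed_bin(v: float) -> tuple[int, tuple[int, int, int]]:
    """Map a section speed (m/s) to its 1-based range index and RGB color.

    Ranges: [0,2), [2,4), [4,6), [6,8), [8,10), [10,12), [12,15), [15,inf).
    """
    v = float(v)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"speed must be finite and non-negative, got {v!r}")
    idx = int(np.searchsorted(SPEED_BIN_EDGES, v, side="right")) + 1
    return idx, SPEED_COLORS[idx - 1]


def render_speed_image(traj: Trajectory, lt: LayoutTransform) -> np.ndarray:
    """Render the SPEED encoding; returns an (H, W, 3) uint8 array.

    Each consecutive record pair is a constant-speed section colored by its
    speed range; sections are drawn in temporal order with 1 px strokes, so on
    re-walked paths the most recent speed wins.
    """
    xy = traj.xy
    t = traj.t_seconds
    if len(xy) < 2:
        raise ValueError("trajectory needs at least 2 records")
    if not lt.contains(xy[:, 0], xy[:, 1]):
        raise ValueError("trajectory extends outside the home bounding box")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("non-increasing timestamps; run cleaning first")
    dist = np.hypot(*np.diff(xy, axis=0).T)
    speeds = dist / dt
    img = Image.new("RGB", (lt.width, lt.height), (0, 0, 0))
    draw = ImageDraw.Draw(img)
    for i, v in enumerate(speeds):
        _, color = speed_bin(v)
        ac, ar = lt.to_pixel(*xy[i])
        bc, br = lt.to_pixel(*xy[i + 1])
        draw.line([(int(ac), int(ar)), (int(bc), int(br))], fill=color, width=1)
    return np.asarray(img, dtype=np.uint8)


def render_gvfe_image(sensor_seq, n_sensors: int, width: int) -> np.ndarray:
    """Binary sensor-sequence raster of shape (n_sensors, width).

    The k-th firing of the sensor with ordinal s sets pixel (x=k, y=s)
    (1-based on both axes, i.e. array[s-1, k-1]).  The height is the sensor
    inventory size, independent of the segmentation threshold; the width is a
    corpus-level constant (max trajectory length) and sequences longer than it
    are an error rather than truncated.
    """
    seq = np.asarray(list(sensor_seq), dtype=int)
    if len(seq) > width:
        raise ValueError(f"sensor sequence of length {len(seq)} exceeds width {width}")
    if len(seq) and (seq.min() < 1 or seq.max() > n_sensors):
        raise ValueError("sensor ordinals must lie in 1..n_sensors")
    img = np.zeros((n_sensors, width), dtype=np.uint8)
    if len(seq):
        img[seq - 1, np.arange(len(seq))] = 1
    return img


def flatten_binarize(img: np.ndarray) -> np.ndarray:
    """Row-major flatten of an RGB raster with per-channel binarization.

    Every channel value > 0 maps to 1, else 0; an (H, W, 3) image yields a
    {0,1} vector of length 3·W·H (39,000 on the default canvas).
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB raster")
    return (arr > 0).astype(np.uint8).reshape(-1)
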