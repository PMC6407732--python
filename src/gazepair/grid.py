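"""Hexagonal search-array geometry.

The search display is a 5 x 5 hexagonal grid of 25 elements. Adjacent
hexagon centers are separated by the flat-to-flat diameter of a cell
(4.6 degrees of visual angle by default), so the cells tile the plane
without gaps. Every other module assigns gaze coordinates to these cells,
so the conventions fixed here propagate everywhere:

* coordinates are in degrees of visual angle, display-centered,
  x increasing rightward and y increasing downward;
* elements are indexed 0..24 row-major from the top-left, so the middle
  element (id 12) sits at the origin;
* rows 1 and 3 (0-based) are shifted right by half the spacing, and the
  vertical row pitch is ``spacing * cos(30 deg)``;
* a point outside every cell maps to the sentinel :data:`OUTSIDE`.

Hexagon cells have two vertical edges facing their horizontal neighbours
(the flat-to-flat direction is horizontal) and a vertex at top and bottom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InvalidSampleError

#: Sentinel id for points that fall outside every hexagon of the grid.
OUTSIDE = -1

_COS30 = math.cos(math.pi / 6.0)

# Outward unit normals of the six hexagon edges (flat-top-left ordering is
# irrelevant; only the set matters). A point p is inside the cell centred
# at c iff dot(p - c, u) <= inradius for all six normals u.
_EDGE_NORMALS = np.array(
    [
        (math.cos(a), math.sin(a))
        for a in (k * math.pi / 3.0 for k in range(6))
    ]
)


@dataclass(frozen=True)
class GridSpec:
    """Immutable description of the search display geometry.

    Distances are degrees of visual angle unless stated otherwise.
    """

    n_rows: int = 5
    n_cols: int = 5
    hex_flat_to_flat: float = 4.6
    jitter_max: float = 0.805
    screen_width_mm: float = 473.0
    screen_width_px: int = 1680
    viewing_distance_mm: float = 650.0
    display_px: int = 1040
    #: (n_elements, 2) array of cell centers, degrees, filled by build_grid.
    centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)), repr=False)

    @property
    def n_elements(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def inradius(self) -> float:
        """Distance from a cell center to the middle of an edge."""
        return self.hex_flat_to_flat / 2.0

    @property
    def circumradius(self) -> float:
        """Distance from a cell center to a vertex."""
        return self.hex_flat_to_flat / math.sqrt(3.0)


def build_grid(
    n_rows: int = 5,
    n_cols: int = 5,
    hex_flat_to_flat: float = 4.6,
    jitter_max: float = 0.805,
    screen_width_mm: float = 473.0,
    screen_width_px: int = 1680,
    viewing_distance_mm: float = 650.0,
    display_px: int = 1040,
) -> GridSpec:
    """Construct a :class:`GridSpec` with computed cell centers.

    Rows are horizontal lines of ``n_cols`` cells; odd rows (0-based) are
    offset right by half the spacing and rows are ``spacing * cos(30 deg)``
    apart vertically, which puts every pair of adjacent centers exactly one
    flat-to-flat diameter apart. The layout must be odd x odd so that the
    central element lands on the display center.
    """
    if hex_flat_to_flat <= 0:
        raise ConfigError(f"hex spacing must be positive, got {hex_flat_to_flat}")
    if n_rows % 2 == 0 or n_cols % 2 == 0 or n_rows < 1 or n_cols < 1:
        raise ConfigError(f"layout must be odd x odd, got {n_rows} x {n_cols}")
    if jitter_max < 0:
        raise ConfigError("jitter_max must be non-negative")
    if screen_width_mm <= 0 or screen_width_px <= 0 or viewing_distance_mm <= 0:
        raise ConfigError("screen geometry must be positive")

    s = hex_flat_to_flat
    r0, c0 = n_rows // 2, n_cols // 2
    centers = np.empty((n_rows * n_cols, 2))
    for r in range(n_rows):
        for c in range(n_cols):
            x = (c - c0) * s + (s / 2.0 if r % 2 == 1 else 0.0)
            y = (r - r0) * s * _COS30
            centers[r * n_cols + c] = (x, y)
    return GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        hex_flat_to_flat=hex_flat_to_flat,
        jitter_max=jitter_max,
        screen_width_mm=screen_width_mm,
        screen_width_px=screen_width_px,
        viewing_distance_mm=viewing_distance_mm,
        display_px=display_px,
        centers=centers,
    )


def px_to_deg(length_px: float, spec: GridSpec, method: str = "radian") -> float:
    """Convert an on-screen length in pixels to degrees of visual angle.

    ``method="radian"`` uses the small-angle (arc length) conversion
    ``deg = (px * mm_per_px / distance) * 180 / pi``, the package default.
    ``method="arctan"`` uses the exact ``2 * atan(L / (2 D))`` form for a
    length centered on the line of sight.
    """
    mm = length_px * spec.screen_width_mm / spec.screen_width_px
    d = spec.viewing_distance_mm
    if method == "radian":
        return math.degrees(mm / d)
    if method == "arctan":
        return math.degrees(2.0 * math.atan2(mm / 2.0, d))
    raise ConfigError(f"unknown conversion method {method!r}")


def deg_to_px(length_deg: float, spec: GridSpec, method: str = "radian") -> float:
    """Inverse of :func:`px_to_deg` (same ``method`` semantics)."""
    d = spec.viewing_distance_mm
    if method == "radian":
        mm = math.radians(length_deg) * d
    elif method == "arctan":
        mm = 2.0 * d * math.tan(math.radians(length_deg) / 2.0)
    else:
        raise ConfigError(f"unknown conversion method {method!r}")
    return mm * spec.screen_width_px / spec.screen_width_mm


def hexagon_vertices(spec: GridSpec, hex_id: int) -> np.ndarray:
    """Return the six vertices of cell ``hex_id`` as a (6, 2) array."""
    cx, cy = spec.centers[hex_id]
    angles = np.radians(30.0 + 60.0 * np.arange(6))
    return np.column_stack(
        (cx + spec.circumradius * np.cos(angles), cy + spec.circumradius * np.sin(angles))
    )


def assign_points(x, y, spec: GridSpec, tol: float = 1e-9) -> np.ndarray:
    """Vectorised point-to-hexagon assignment.

    Each point maps to the cell whose interior contains it; border points
    resolve to the nearest center with ties going to the lower id (argmin
    order). Points outside every cell map to :data:`OUTSIDE`. Non-finite
    coordinates raise :class:`InvalidSampleError`.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidSampleError("non-finite gaze coordinates")
    pts = np.column_stack((x, y))  # (n, 2)
    diff = pts[:, None, :] - spec.centers[None, :, :]  # (n, 25, 2)
    d2 = np.einsum("nkd,nkd->nk", diff, diff)
    nearest = np.argmin(d2, axis=1)
    rel = pts - spec.centers[nearest]
    # Half-plane membership test against the six edge normals.
    proj = rel @ _EDGE_NORMALS.T
    inside = np.max(proj, axis=1) <= spec.inradius + tol
    out = np.where(inside, nearest, OUTSIDE)
    return out


def assign_point_to_hexagon(x: float, y: float, spec: GridSpec) -> int:
    """Scalar convenience wrapper around :func:`assign_points`."""
    return int(assign_points(x, y, spec)[0])


def jitter_elements(spec: GridSpec, seed) -> np.ndarray:
    """Per-element (dx, dy) placement offsets for one search display.

    Horizontal and vertical shifts are drawn independently for every
    element with magnitude uniform in ``[0, jitter_max]`` degrees and a
    random sign. Deterministic for a fixed seed (or Generator).
    """
    rng = np.random.default_rng(seed)
    mag = rng.uniform(0.0, spec.jitter_max, size=(spec.n_elements, 2))
    sign = rng.choice((-1.0, 1.0), size=(spec.n_elements, 2))
    return mag * sign


def read_grid_config(path) -> GridSpec:
    """Build a grid from a YAML key-value config file.

    Recognised keys mirror the keyword arguments of :func:`build_grid`;
    unknown keys raise :class:`ConfigError`.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"grid config {path} must be a mapping")
    allowed = {
        "n_rows",
        "n_cols",
        "hex_flat_to_flat",
        "jitter_max",
        "screen_width_mm",
        "screen_width_px",
        "viewing_distance_mm",
        "display_px",
    }
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigError(f"unknown grid config keys: {sorted(unknown)}")
    return build_grid(**cfg)


def write_grid_config(spec: GridSpec, path) -> None:
    """Write the grid parameters (not the derived centers) as YAML."""
    import yaml

    cfg = {
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "hex_flat_to_flat": spec.hex_flat_to_flat,
        "jitter_max": spec.jitter_max,
        "screen_width_mm": spec.screen_width_mm,
        "screen_width_px": spec.screen_width_px,
        "viewing_distance_mm": spec.viewing_distance_mm,
        "display_px": spec.display_px,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def export_centers_csv(spec: GridSpec, path) -> None:
    """Write cell centers as CSV with columns id, x_deg, y_deg."""
    import pandas as pd

    pd.DataFrame(
        {
            "id": np.arange(spec.n_elements),
            "x_deg": spec.centers[:, 0],
            "y_deg": spec.centers[:, 1],
        }
    ).to_csv(path, index=False)
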