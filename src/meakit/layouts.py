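"""MEA electrode layout generators and geometry queries.

Four families of planar layouts are supported, all in micrometres with the
origin at the array centroid and y pointing up (coordinates are electrode
centres):

* rectangular grids of 59, 128, 256 or 512 recording electrodes — the
  59-site version reproduces the commercial 8x8-minus-corners footprint at
  200 µm pitch / 30 µm diameter;
* curved variants whose electrode rows are bent onto circular arcs
  (default curvature 0.35 mm^-1, matching the gross curvature of mouse
  cortex) while preserving along-arc pitch;
* perturbed variants with i.i.d. random displacements drawn uniformly from a
  disk of bounded radius (default bound 50 µm), used to de-alias regular
  spatial sampling;
* multi-well arrangements hosting several independent sub-grids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MalformedFileError, ParameterError

SUPPORTED_CAPACITIES = (59, 128, 256, 512)

__all__ = [
    "ElectrodeLayout",
    "make_rect",
    "make_curved",
    "make_perturbed",
    "make_multiwell",
    "save_layout",
    "load_layout",
    "fit_circle",
    "SUPPORTED_CAPACITIES",
]


@dataclass
class ElectrodeLayout:
    """Electrode coordinates plus channel bookkeeping.

    ``positions`` is ``(n, 2)`` (x, y) in µm; ``rows`` records the grid row
    each electrode came from (useful for row-wise geometry checks on curved
    layouts); ``channel_map`` maps electrode index -> recording channel and is
    a bijection onto ``0..n-1``.
    """

    positions: np.ndarray
    diameter: float
    pitch: float
    well_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    channel_map: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        n = len(self.positions)
        if self.diameter <= 0:
            raise ParameterError(f"diameter must be positive, got {self.diameter}")
        if self.well_id is None or len(self.well_id) == 0:
            self.well_id = np.zeros(n, dtype=int)
        if self.channel_map is None or len(self.channel_map) == 0:
            self.channel_map = np.arange(n, dtype=int)
        if self.rows is None or len(self.rows) == 0:
            self.rows = np.zeros(n, dtype=int)
        if len({tuple(p) for p in np.round(self.positions, 9)}) != n:
            raise ParameterError("electrode positions must be unique")
        if sorted(self.channel_map) != list(range(n)):
            raise ParameterError("channel_map must be a bijection onto 0..N-1")

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)

    def wells(self) -> np.ndarray:
        return np.unique(self.well_id)

    def positions_for_well(self, well: int) -> np.ndarray:
        return self.positions[self.well_id == well]


def _grid_points(capacity: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Centred grid coordinates and row indices for a supported capacity.

    59:  8x8 minus the 4 corners minus one reference site (row 3, col 0).
    128: 12 cols x 11 rows minus the 4 corners.
    256: 16x16 full grid.
    512: 23x23 minus the 4 corners and the 13 remaining sites farthest from
         the centroid (deterministic order), keeping a near-square footprint.
    """
    if capacity == 59:
        pts = [
            (c, r)
            for r in range(8)
            for c in range(8)
            if (r, c) not in {(0, 0), (0, 7), (7, 0), (7, 7), (3, 0)}
        ]
    elif capacity == 128:
        pts = [
            (c, r)
            for r in range(11)
            for c in range(12)
            if (r, c) not in {(0, 0), (0, 11), (10, 0), (10, 11)}
        ]
    elif capacity == 256:
        pts = [(c, r) for r in range(16) for c in range(16)]
    elif capacity == 512:
        pts = [(c, r) for r in range(23) for c in range(23)]
        cx = cy = 11.0
        # drop the 17 sites farthest from centre; ties broken by (row, col)
        order = sorted(pts, key=lambda p: (-((p[0] - cx) ** 2 + (p[1] - cy) ** 2), p[1], p[0]))
        drop = set(order[:17])
        pts = [p for p in pts if p not in drop]
    else:
        raise ParameterError(
            f"unsupported capacity {capacity}; choose one of {SUPPORTED_CAPACITIES}"
        )
    arr = np.asarray(pts, dtype=float)
    rows = arr[:, 1].astype(int)
    xy = arr * pitch
    xy -= xy.mean(axis=0)
    return xy, rows


def make_rect(capacity: int, pitch_um: float = 200.0, diameter_um: float = 30.0) -> ElectrodeLayout:
    """Rectangular-grid layout of one of the supported capacities."""
    if pitch_um <= 0:
        raise ParameterError(f"pitch must be positive, got {pitch_um}")
    if diameter_um <= 0:
        raise ParameterError(f"diameter must be positive, got {diameter_um}")
    xy, rows = _grid_points(capacity, pitch_um)
    return ElectrodeLayout(positions=xy, diameter=diameter_um, pitch=pitch_um, rows=rows)


def make_curved(
    capacity: int,
    curvature_per_mm: float = 0.35,
    pitch_um: float = 200.0,
    diameter_um: float = 30.0,
) -> ElectrodeLayout:
    """Layout whose electrode rows are bent onto circular arcs.

    Every row lies on an arc of radius ``1/curvature`` (curvature given in
    mm^-1, radius in µm), with arc centres stacked vertically so that
    row-to-row spacing along the midline equals the pitch and along-arc pitch
    within a row is preserved.  ``curvature = 0`` degenerates to the
    rectangular layout.
    """
    if curvature_per_mm < 0:
        raise ParameterError(f"curvature must be >= 0, got {curvature_per_mm}")
    base = make_rect(capacity, pitch_um, diameter_um)
    if curvature_per_mm == 0:
        return base
    radius_um = 1000.0 / curvature_per_mm
    x, y = base.positions[:, 0], base.positions[:, 1]
    theta = x / radius_um  # along-arc length preserved
    bent = np.column_stack(
        [radius_um * np.sin(theta), y + radius_um * (1.0 - np.cos(theta))]
    )
    bent -= bent.mean(axis=0)
    return ElectrodeLayout(
        positions=bent,
        diameter=diameter_um,
        pitch=pitch_um,
        rows=base.rows.copy(),
    )


def make_perturbed(
    capacity: int,
    max_disp_um: float = 50.0,
    pitch_um: float = 200.0,
    diameter_um: float = 30.0,
    seed: int | None = 0,
) -> ElectrodeLayout:
    """Rectangular layout with bounded random electrode displacements.

    Each electrode is displaced by a vector drawn uniformly from the disk of
    radius ``max_disp_um`` (independently per electrode); the same seed always
    reproduces the same layout.  ``max_disp`` must stay below half the pitch
    so neighbouring electrodes cannot collide.
    """
    if not 0 <= max_disp_um < pitch_um / 2:
        raise ParameterError(
            f"max displacement must satisfy 0 <= d < pitch/2 "
            f"({pitch_um / 2} µm), got {max_disp_um}"
        )
    base = make_rect(capacity, pitch_um, diameter_um)
    if max_disp_um == 0:
        return base
    rng = np.random.default_rng(seed)
    n = base.n_electrodes
    r = max_disp_um * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    disp = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return ElectrodeLayout(
        positions=base.positions + disp,
        diameter=diameter_um,
        pitch=pitch_um,
        rows=base.rows.copy(),
    )


def _generic_grid(n: int, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Near-square centred grid for an arbitrary electrode count."""
    side = int(np.ceil(np.sqrt(n)))
    pts = [(c, r) for r in range(side) for c in range(side)][:n]
    arr = np.asarray(pts, dtype=float)
    rows = arr[:, 1].astype(int)
    xy = arr * pitch
    xy -= xy.mean(axis=0)
    return xy, rows


def make_multiwell(
    n_wells: int = 4,
    per_well_capacity: int = 32,
    well_spacing_um: float | None = None,
    pitch_um: float = 200.0,
    diameter_um: float = 30.0,
) -> ElectrodeLayout:
    """Layout hosting several independent electrode clusters ("wells").

    Wells are identical sub-grids arranged on a near-square super-grid of
    well centres.  ``well_spacing_um`` is the centre-to-centre distance; the
    default (3x the well diagonal) guarantees the minimum inter-well electrode
    distance exceeds the maximum intra-well distance.
    """
    if n_wells < 1:
        raise ParameterError(f"n_wells must be >= 1, got {n_wells}")
    if per_well_capacity in SUPPORTED_CAPACITIES:
        sub = make_rect(per_well_capacity, pitch_um, diameter_um)
        sub_xy, sub_rows = sub.positions, sub.rows
    else:
        sub_xy, sub_rows = _generic_grid(per_well_capacity, pitch_um)
    extent = np.ptp(sub_xy, axis=0) if len(sub_xy) > 1 else np.zeros(2)
    diag = float(np.hypot(*extent))
    if well_spacing_um is None:
        well_spacing_um = max(3.0 * diag, 2.0 * pitch_um)
    if n_wells > 1 and well_spacing_um <= 2.0 * diag:
        raise ParameterError(
            f"well spacing {well_spacing_um} µm too small for well extent "
            f"{diag:.1f} µm (need > {2 * diag:.1f} to keep wells separated)"
        )
    wells_per_side = int(np.ceil(np.sqrt(n_wells)))
    positions, well_id, rows = [], [], []
    for w in range(n_wells):
        wr, wc = divmod(w, wells_per_side)
        centre = np.array([wc, wr], dtype=float) * well_spacing_um
        positions.append(sub_xy + centre)
        well_id.append(np.full(len(sub_xy), w, dtype=int))
        rows.append(sub_rows)
    xy = np.vstack(positions)
    xy -= xy.mean(axis=0)
    return ElectrodeLayout(
        positions=xy,
        diameter=diameter_um,
        pitch=pitch_um,
        well_id=np.concatenate(well_id),
        rows=np.concatenate(rows),
    )


# ---------------------------------------------------------------------------
# layout I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["electrode_id", "x_um", "y_um", "diameter_um", "well_id", "channel"]


def save_layout(layout: ElectrodeLayout, path) -> Path:
    """Write a layout as CSV (or JSON when the path ends in .json)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "electrode_id": np.arange(layout.n_electrodes),
            "x_um": layout.positions[:, 0],
            "y_um": layout.positions[:, 1],
            "diameter_um": layout.diameter,
            "well_id": layout.well_id,
            "channel": layout.channel_map,
        }
    )
    if path.suffix.lower() == ".json":
        payload = df.to_dict(orient="list")
        payload["pitch_um"] = layout.pitch
        with open(path, "w") as fh:
            json.dump(payload, fh)
    else:
        df.to_csv(path, index=False)
    return path


def load_layout(path, pitch_um: float | None = None, empty_ok: bool = True) -> ElectrodeLayout:
    """Read a layout written by :func:`save_layout`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        pitch = payload.pop("pitch_um", pitch_um)
        df = pd.DataFrame(payload)
    else:
        df = pd.read_csv(path)
        pitch = pitch_um
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MalformedFileError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return ElectrodeLayout(
            positions=np.empty((0, 2)),
            diameter=30.0,
            pitch=pitch or 200.0,
        )
    return ElectrodeLayout(
        positions=df[["x_um", "y_um"]].to_numpy(),
        diameter=float(df["diameter_um"].iloc[0]),
        pitch=pitch or 200.0,
        well_id=df["well_id"].to_numpy(dtype=int),
        channel_map=df["channel"].to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# geometry queries
# ---------------------------------------------------------------------------


def fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) least-squares circle fit.

    Returns ``(cx, cy, radius)``.  Exact for points lying exactly on a
    circle; used to verify the curvature of bent electrode rows.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ParameterError("circle fit requires at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    radius = float(np.sqrt(c + cx**2 + cy**2))
    return float(cx), float(cy), radius


def row_curvature(layout: ElectrodeLayout, row: int | None = None) -> float:
    """Curvature (mm^-1) recovered by circle-fitting one electrode row."""
    if row is None:
        row = int(np.median(np.unique(layout.rows)))
    pts = layout.positions[layout.rows == row]
    _, _, radius_um = fit_circle(pts)
    return 1000.0 / radius_um
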