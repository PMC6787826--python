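"""Gridded seascape: cells, sites, currents, geometry services.

The world is a regular grid of square cells in a planar km frame. The
origin sits at the south-west corner, x runs east and y runs north, and
agents live at continuous ``(x, y)`` positions; the occupied cell is found
by floor division by the cell size. Latitude is recovered from ``y`` by a
linear (equirectangular) map onto the world's geographic bounding box.

Cell types are ``terrestrial`` (a barrier to movement), plain ``ocean``,
``nesting_site`` and ``feeding_patch``. Currents are stored as two per-cell
velocity components (eastward ``u``, northward ``v``) in km/day; they are
forced to zero on terrestrial cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# cell-type codes
OCEAN = 0
TERRESTRIAL = 1
NESTING_SITE = 2
FEEDING_PATCH = 3

#: Reference-world rookeries: (trigram, relative weight). The weights are the
#: relative proportions of nesting females assigned to each rookery; six major
#: rookeries dominate and eight minor ones share a small residual weight.
REFERENCE_ROOKERY_WEIGHTS: tuple[tuple[str, float], ...] = (
    ("EUR", 10_000.0),
    ("ALD", 5_000.0),
    ("MAY", 5_000.0),
    ("MOH", 5_000.0),
    ("TRO", 2_000.0),
    ("GLO", 2_000.0),
    ("TAN", 200.0),
    ("IRA", 200.0),
    ("JUA", 200.0),
    ("SEY", 200.0),
    ("VAM", 200.0),
    ("RUN", 200.0),
    ("KEN", 200.0),
    ("CHA", 200.0),
)


@dataclass(frozen=True)
class NestingSite:
    site_id: int
    trigram: str
    x: float
    y: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"site {self.site_id}: weight must be > 0")

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class PatchLocation:
    patch_id: int
    x: float
    y: float

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)


def distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Planar Euclidean distance in km between two points."""
    return math.hypot(a[0] - b[0], a[1] - b[1])


@dataclass
class Landscape:
    """A validated seascape grid with site and patch registries.

    ``cell_type``, ``current_u`` and ``current_v`` are ``(n_rows, n_cols)``
    arrays indexed ``[row, col]`` with row 0 at the southern edge.
    """

    n_cols: int
    n_rows: int
    cell_size_km: float
    bbox: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max
    cell_type: np.ndarray
    current_u: np.ndarray
    current_v: np.ndarray
    nesting_sites: list[NestingSite]
    feeding_patches: list[PatchLocation]
    d_min: float = field(init=False, default=0.0)
    d_max: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be > 0")
        shape = (self.n_rows, self.n_cols)
        for name in ("cell_type", "current_u", "current_v"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        if not self.feeding_patches:
            raise ValueError("empty feeding-patch registry")
        ids = [s.site_id for s in self.nesting_sites]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate nesting-site ids")
        pids = [p.patch_id for p in self.feeding_patches]
        if len(pids) != len(set(pids)):
            raise ValueError("duplicate feeding-patch ids")
        land = self.cell_type == TERRESTRIAL
        self.current_u = np.where(land, 0.0, self.current_u)
        self.current_v = np.where(land, 0.0, self.current_v)
        for s in self.nesting_sites:
            if not self.contains(s.x, s.y):
                raise ValueError(f"nesting site {s.trigram} outside the grid")
            if self.is_land(s.x, s.y):
                raise ValueError(f"nesting site {s.trigram} on a terrestrial cell")
        for p in self.feeding_patches:
            if not self.contains(p.x, p.y):
                raise ValueError(f"feeding patch {p.patch_id} outside the grid")
            if self.is_land(p.x, p.y):
                raise ValueError(f"feeding patch {p.patch_id} on a terrestrial cell")
        self._mark_sites()
        self.d_min, self.d_max = self._patch_distance_range()
        self._site_by_id = {s.site_id: s for s in self.nesting_sites}
        self._patch_by_id = {p.patch_id: p for p in self.feeding_patches}

    # -- registries ---------------------------------------------------------

    def site(self, site_id: int) -> NestingSite:
        return self._site_by_id[site_id]

    def patch(self, patch_id: int) -> PatchLocation:
        return self._patch_by_id[patch_id]

    # -- geometry -----------------------------------------------------------

    @property
    def width_km(self) -> float:
        return self.n_cols * self.cell_size_km

    @property
    def height_km(self) -> float:
        return self.n_rows * self.cell_size_km

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x < self.width_km and 0.0 <= y < self.height_km

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point."""
        return (int(y // self.cell_size_km), int(x // self.cell_size_km))

    def is_land(self, x: float, y: float) -> bool:
        """True if the point is outside the grid or on a terrestrial cell.

        Grid edges are treated as hard boundaries (no world wrapping).
        """
        if not self.contains(x, y):
            return True
        r, c = self.cell_of(x, y)
        return self.cell_type[r, c] == TERRESTRIAL

    def current_at(self, x: float, y: float) -> tuple[float, float]:
        """(u, v) current components in km/day at the point's cell."""
        if not self.contains(x, y):
            return (0.0, 0.0)
        r, c = self.cell_of(x, y)
        return (float(self.current_u[r, c]), float(self.current_v[r, c]))

    def latitude_of(self, y_km: float) -> float:
        """Latitude in degrees of a northing via the linear bbox map."""
        lat_min, lat_max = self.bbox[2], self.bbox[3]
        return lat_min + (lat_max - lat_min) * y_km / self.height_km

    def coast_ahead(
        self,
        position: tuple[float, float],
        heading: float,
        lookahead_km: float,
        sensing_radius_km: float = 100.0,
    ) -> tuple[bool, float | None]:
        """Ray-cast along ``heading`` (radians, 0 = east, CCW positive).

        Traverses cells up to ``min(lookahead_km, sensing_radius_km)`` and
        reports whether any traversed cell is terrestrial (the grid edge
        counts as a barrier), together with the distance to the first
        blocked sample.
        """
        if lookahead_km <= 0:
            raise ValueError("lookahead_km must be > 0")
        horizon = min(lookahead_km, sensing_radius_km)
        x0, y0 = position
        dx, dy = math.cos(heading), math.sin(heading)
        # sample finely enough that no cell on the ray is skipped
        step = self.cell_size_km / 3.0
        n = max(1, int(math.ceil(horizon / step)))
        for i in range(1, n + 1):
            d = min(i * step, horizon)
            if self.is_land(x0 + d * dx, y0 + d * dy):
                return (True, d)
        return (False, None)

    # -- internals ----------------------------------------------------------

    def _mark_sites(self) -> None:
        for s in self.nesting_sites:
            r, c = self.cell_of(s.x, s.y)
            self.cell_type[r, c] = NESTING_SITE
        for p in self.feeding_patches:
            r, c = self.cell_of(p.x, p.y)
            self.cell_type[r, c] = FEEDING_PATCH

    def _patch_distance_range(self) -> tuple[float, float]:
        pts = np.array([[p.x, p.y] for p in self.feeding_patches])
        if len(pts) < 2:
            return (0.0, 0.0)
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(len(pts), k=1)
        return (float(d[iu].min()), float(d[iu].max()))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_asc(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid.

    Returns ``(array, cellsize, (xllcorner, yllcorner))`` with the array
    flipped so that row 0 is the southern edge (the .asc format stores the
    northern row first).
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    return (
        data[::-1].copy(),
        header["cellsize"],
        (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_asc(path: str | Path, array: np.ndarray, cellsize: float,
              xll: float = 0.0, yll: float = 0.0) -> None:
    """Write an array (row 0 = south) as an ESRI ASCII grid."""
    arr = np.asarray(array)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {cellsize}\n")
        np.savetxt(fh, arr[::-1], fmt="%.6g")


def load_landscape(
    land_mask_file: str | Path,
    current_u_file: str | Path,
    current_v_file: str | Path,
    nesting_sites_file: str | Path,
    patches_file: str | Path,
    cell_size_km: float | None = None,
    bbox: tuple[float, float, float, float] = (25.0, 65.0, -30.0, 10.0),
) -> Landscape:
    """Build a :class:`Landscape` from .asc rasters and CSV registries.

    The land mask uses 0 = ocean, 1 = land. Sites CSV columns:
    ``site_id, trigram, x_km, y_km, weight``; patches CSV columns:
    ``patch_id, x_km, y_km``. All rasters must share dimensions.
    """
    mask, cs_mask, _ = read_asc(land_mask_file)
    u, cs_u, _ = read_asc(current_u_file)
    v, cs_v, _ = read_asc(current_v_file)
    if not (mask.shape == u.shape == v.shape):
        raise ValueError(
            f"raster dimension mismatch: mask {mask.shape}, u {u.shape}, v {v.shape}"
        )
    cell = cell_size_km if cell_size_km is not None else cs_mask
    if not (cs_mask == cs_u == cs_v):
        raise ValueError("rasters disagree on cellsize")
    sites_df = pd.read_csv(nesting_sites_file)
    patches_df = pd.read_csv(patches_file)
    sites = [
        NestingSite(int(r.site_id), str(r.trigram), float(r.x_km), float(r.y_km),
                    float(r.weight))
        for r in sites_df.itertuples()
    ]
    patches = [
        PatchLocation(int(r.patch_id), float(r.x_km), float(r.y_km))
        for r in patches_df.itertuples()
    ]
    cell_type = np.where(mask > 0.5, TERRESTRIAL, OCEAN).astype(np.int8)
    return Landscape(
        n_cols=mask.shape[1],
        n_rows=mask.shape[0],
        cell_size_km=cell,
        bbox=bbox,
        cell_type=cell_type,
        current_u=u,
        current_v=v,
        nesting_sites=sites,
        feeding_patches=patches,
    )


def save_landscape(landscape: Landscape, out_dir: str | Path) -> None:
    """Write a landscape as .asc rasters + CSV registries (inverse of load)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cs = landscape.cell_size_km
    mask = (landscape.cell_type == TERRESTRIAL).astype(np.int8)
    write_asc(out / "land_mask.asc", mask, cs)
    write_asc(out / "current_u.asc", landscape.current_u, cs)
    write_asc(out / "current_v.asc", landscape.current_v, cs)
    pd.DataFrame(
        [(s.site_id, s.trigram, s.x, s.y, s.weight) for s in landscape.nesting_sites],
        columns=["site_id", "trigram", "x_km", "y_km", "weight"],
    ).to_csv(out / "nesting_sites.csv", index=False)
    pd.DataFrame(
        [(p.patch_id, p.x, p.y) for p in landscape.feeding_patches],
        columns=["patch_id", "x_km", "y_km"],
    ).to_csv(out / "feeding_patches.csv", index=False)


# ---------------------------------------------------------------------------
# Synthetic worlds
# ---------------------------------------------------------------------------

def generate_synthetic_landscape(seed: int, preset: str) -> Landscape:
    """Deterministically generate a synthetic seascape.

    Presets
    -------
    ``minimal``
        A tiny all-ocean world with one nesting site and two feeding
        patches, zero currents. The smallest world the simulator runs on.
    ``channel``
        A mid-size world with an elongated barrier island separating two
        coastlines (a Mozambique-Channel-like configuration), clustered
        feeding patches along both coasts, island rookeries in the channel,
        and a parametric gyre current field.
    ``reference``
        A full-scale world (567 x 577 cells of 7 km) with 14 rookeries
        carrying the reference relative weights and 47 feeding patches,
        structurally mimicking the south-west Indian Ocean: a continental
        coastline in the west, a large elongated island in the south-centre,
        island rookeries in and around the channel between them, and a
        basin-scale gyre.

    The same ``(seed, preset)`` always yields a bit-identical landscape;
    the seed only jitters patch placement within clusters.
    """
    if preset == "minimal":
        return _minimal_world()
    if preset == "channel":
        return _structured_world(seed, n_cols=140, n_rows=140, cell=7.0,
                                 n_minor_patch=9, reference=False)
    if preset == "reference":
        return _structured_world(seed, n_cols=567, n_rows=577, cell=7.0,
                                 n_minor_patch=None, reference=True)
    raise ValueError(f"unknown preset: {preset!r}")


def _minimal_world() -> Landscape:
    n = 10
    cell = 7.0
    ct = np.zeros((n, n), dtype=np.int8)
    zero = np.zeros((n, n))
    sites = [NestingSite(1, "ONE", 10.5, 10.5, 1.0)]
    patches = [PatchLocation(1, 45.5, 10.5), PatchLocation(2, 45.5, 59.5)]
    return Landscape(n, n, cell, (25.0, 25.0 + n * cell / 111.0, -5.0, -5.0 + n * cell / 111.0),
                     ct, zero, zero.copy(), sites, patches)


def _structured_world(seed: int, n_cols: int, n_rows: int, cell: float,
                      n_minor_patch: int | None, reference: bool) -> Landscape:
    rng = np.random.default_rng(seed)
    ct = np.zeros((n_rows, n_cols), dtype=np.int8)
    W, H = n_cols * cell, n_rows * cell

    # Western continental landmass: land where col < coast(row). The coast
    # meanders gently and bulges outward in the far north (a horn-like cape).
    rows = np.arange(n_rows)
    frac = rows / n_rows
    coast_col = (
        0.08 * n_cols
        + 0.04 * n_cols * np.sin(frac * 3.0 * np.pi)
        + 0.22 * n_cols * np.clip(frac - 0.72, 0.0, None) / 0.28
    ).astype(int)
    for r in range(n_rows):
        ct[r, : max(coast_col[r], 1)] = TERRESTRIAL

    # Elongated barrier island in the south-centre, tilted NNE-SSW.
    cy, cx = 0.28 * n_rows, 0.56 * n_cols
    ax_long, ax_short = 0.22 * n_rows, 0.055 * n_cols
    tilt = math.radians(20.0)
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]
    u = (cc - cx) * math.cos(tilt) + (rr - cy) * math.sin(tilt)
    w = -(cc - cx) * math.sin(tilt) + (rr - cy) * math.cos(tilt)
    island = (u / ax_short) ** 2 + (w / ax_long) ** 2 <= 1.0
    ct[island] = TERRESTRIAL

    def cellpt(col: float, row: float) -> tuple[float, float]:
        return ((col + 0.5) * cell, (row + 0.5) * cell)

    def nearest_ocean(col: float, row: float) -> tuple[float, float]:
        # spiral out until a non-terrestrial, in-grid cell is found
        c0, r0 = int(round(col)), int(round(row))
        for radius in range(0, max(n_rows, n_cols)):
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if max(abs(dr), abs(dc)) != radius:
                        continue
                    r1, c1 = r0 + dr, c0 + dc
                    if 0 <= r1 < n_rows and 0 <= c1 < n_cols and ct[r1, c1] != TERRESTRIAL:
                        return cellpt(c1, r1)
        raise RuntimeError("no ocean cell found")

    # Rookeries. Fractional (col, row) anchors; all snapped to ocean.
    if reference:
        anchors = {
            "EUR": (0.38, 0.14),   # southern channel island
            "ALD": (0.33, 0.62),   # north of the channel
            "MAY": (0.38, 0.52),
            "MOH": (0.35, 0.50),
            "TRO": (0.76, 0.34),   # east of the barrier island
            "GLO": (0.42, 0.55),
            "TAN": (0.17, 0.58),   # continental coast
            "IRA": (0.48, 0.47),   # NW tip of the island
            "JUA": (0.40, 0.38),   # mid-channel
            "SEY": (0.62, 0.70),   # oceanic, north-east
            "VAM": (0.20, 0.48),   # continental coast
            "RUN": (0.80, 0.22),   # far south-east
            "KEN": (0.22, 0.68),   # continental coast, north
            "CHA": (0.88, 0.78),   # far north-east
        }
        site_list = []
        for sid, (trig, weight) in enumerate(REFERENCE_ROOKERY_WEIGHTS, start=1):
            fc, fr = anchors[trig]
            x, y = nearest_ocean(fc * n_cols, fr * n_rows)
            # small land neighbour so island rookeries read as islands
            r1, c1 = int(y // cell), int(x // cell)
            if trig in ("EUR", "ALD", "MAY", "MOH", "TRO", "GLO", "JUA", "RUN",
                        "SEY", "CHA", "IRA"):
                r2 = min(r1 + 1, n_rows - 1)
                if ct[r2, c1] == OCEAN:
                    ct[r2, c1] = TERRESTRIAL
            site_list.append(NestingSite(sid, trig, x, y, weight))
        n_patches = 47
    else:
        site_list = []
        channel_anchors = [("ISA", 0.40, 0.45, 10.0), ("ISB", 0.38, 0.18, 5.0),
                           ("ISC", 0.74, 0.30, 2.0)]
        for sid, (trig, fc, fr, weight) in enumerate(channel_anchors, start=1):
            x, y = nearest_ocean(fc * n_cols, fr * n_rows)
            r1, c1 = int(y // cell), int(x // cell)
            r2 = min(r1 + 1, n_rows - 1)
            if ct[r2, c1] == OCEAN:
                ct[r2, c1] = TERRESTRIAL
            site_list.append(NestingSite(sid, trig, x, y, weight))
        n_patches = 3 + 2 * n_minor_patch

    # Feeding patches: clusters hugging the continental coast (both in and
    # north of the channel) and both flanks of the barrier island.
    patch_rows_west = np.linspace(0.06 * n_rows, 0.92 * n_rows,
                                  n_patches - n_patches // 3).astype(int)
    patch_pts: list[tuple[float, float]] = []
    for r in patch_rows_west:
        c = coast_col[r] + 1 + rng.integers(0, 3)
        x, y = nearest_ocean(c, r)
        patch_pts.append((x, y))
    # island flanks
    island_rows = np.linspace(cy - 0.8 * ax_long, cy + 0.8 * ax_long,
                              n_patches - len(patch_pts)).astype(int)
    for i, r in enumerate(island_rows):
        row_cells = np.nonzero(island[int(r)])[0]
        if len(row_cells) == 0:
            c = cx
        elif i % 2 == 0:
            c = row_cells.min() - 2 - rng.integers(0, 2)
        else:
            c = row_cells.max() + 2 + rng.integers(0, 2)
        x, y = nearest_ocean(c, r)
        patch_pts.append((x, y))
    # deduplicate cells (two patches in one cell would collapse)
    seen: set[tuple[int, int]] = set()
    patches = []
    pid = 1
    for x, y in patch_pts:
        key = (int(y // cell), int(x // cell))
        while key in seen:
            x += cell
            key = (int(y // cell), int(x // cell))
        seen.add(key)
        patches.append(PatchLocation(pid, x, y))
        pid += 1

    # Parametric basin gyre from a stream function (u = -dpsi/dy,
    # v = dpsi/dx), western-intensified as wind-driven subtropical gyres
    # are: a narrow strong boundary jet along the western coast and the
    # channel, broad moderate return flow in the interior. Peak speed
    # ~40 km/day at the boundary (an energetic western boundary current),
    # ~15 km/day in the interior; zero on land.
    xg = (np.arange(n_cols) + 0.5) * cell
    yg = (np.arange(n_rows) + 0.5) * cell
    X, Y = np.meshgrid(xg, yg)
    Lb = 0.10 * W  # boundary-layer width
    g = (1.0 - np.exp(-X / Lb)) * (1.0 - X / W)
    gp = np.exp(-X / Lb) / Lb * (1.0 - X / W) - (1.0 - np.exp(-X / Lb)) / W
    u_cur = -(np.pi / H) * np.cos(np.pi * Y / H) * g
    v_cur = np.sin(np.pi * Y / H) * gp
    water = ct != TERRESTRIAL
    scale = 40.0 / np.hypot(u_cur, v_cur)[water].max()
    u_cur *= scale
    v_cur *= scale

    lat_span = H / 111.0
    lon_span = W / 111.0
    bbox = (25.0, 25.0 + lon_span, -30.0, -30.0 + lat_span)
    if reference:
        bbox = (25.0, 65.0, -30.0, 10.0)

    return Landscape(n_cols, n_rows, cell, bbox, ct, u_cur, v_cur,
                     site_list, patches)
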