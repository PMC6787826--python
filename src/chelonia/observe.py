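"""Output statistics: patch usage, origin mixing, tracks, reproduction.

The simulator records three kinds of events after burn-in: nesting events
(turtle, rookery, step, post-nesting energy), migration track samples
(Bernoulli-thinned positions of pre/postnesting migrants), and per-patch
usage tallies. This module turns those records into the model's summary
statistics:

* per-patch usage and origin mixing, including a normalized Shannon
  diversity of the rookeries the patch's postnesting visitors came from;
* per-individual remigration intervals (years between successive nesting
  events) and their rookery means;
* rookery reproductive output: post-nesting energy per unit remigration
  interval, summed over events and scaled by the nesting investment;
* kernel utilization densities of the sampled migration tracks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DAYS_PER_STEP = 0.5
DAYS_PER_YEAR = 365.25

NESTING_EVENT_COLUMNS = ["turtle_id", "site_id", "step", "energy_after"]
TRACK_SAMPLE_COLUMNS = ["turtle_id", "step", "x_km", "y_km",
                        "migration_phase", "nesting_site_id"]
PATCH_USAGE_COLUMNS = ["patch_id", "x_km", "y_km", "time_usage",
                       "postnesting_visits", "foraging_visits",
                       "visits_by_origin_site"]


@dataclass
class ObservationStore:
    """Append-only event sink filled by the engine after burn-in."""

    nesting_events: list[tuple] = field(default_factory=list)
    track_samples: list[tuple] = field(default_factory=list)
    patch_timeseries: list[tuple] = field(default_factory=list)

    def record_nesting_event(self, turtle_id: int, site_id: int, step: int,
                             energy_after: float) -> None:
        self.nesting_events.append((turtle_id, site_id, step, energy_after))

    def record_track_sample(self, turtle_id: int, step: int, x: float, y: float,
                            phase: str, nesting_site_id: int) -> None:
        self.track_samples.append((turtle_id, step, x, y, phase, nesting_site_id))

    def record_patch_state(self, step: int, patch_id: int, phi: float,
                           occupancy: int) -> None:
        self.patch_timeseries.append((step, patch_id, phi, occupancy))

    def to_outputs(self, patches, meta: dict) -> "RunOutputs":
        events = pd.DataFrame(self.nesting_events, columns=NESTING_EVENT_COLUMNS)
        tracks = pd.DataFrame(self.track_samples, columns=TRACK_SAMPLE_COLUMNS)
        usage = pd.DataFrame(
            [(p.patch_id, p.x, p.y, p.time_usage, p.postnesting_visits,
              p.foraging_visits, json.dumps(p.visits_by_origin_site))
             for p in patches.values()],
            columns=PATCH_USAGE_COLUMNS,
        )
        ts = (pd.DataFrame(self.patch_timeseries,
                           columns=["step", "patch_id", "phi", "occupancy"])
              if self.patch_timeseries else None)
        return RunOutputs(events, tracks, usage, ts, meta)


@dataclass
class RunOutputs:
    """Observation tables plus run metadata for one simulation."""

    nesting_events: pd.DataFrame
    track_samples: pd.DataFrame
    patch_usage: pd.DataFrame
    patch_timeseries: pd.DataFrame | None
    meta: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.nesting_events.to_csv(out / "nesting_events.csv", index=False)
        self.track_samples.to_csv(out / "track_samples.csv", index=False)
        self.patch_usage.to_csv(out / "patch_usage.csv", index=False)
        if self.patch_timeseries is not None:
            self.patch_timeseries.to_csv(out / "patch_timeseries.csv", index=False)
        with open(out / "meta.json", "w") as fh:
            json.dump(self.meta, fh, indent=2, default=float)

    @classmethod
    def load(cls, run_dir: str | Path) -> "RunOutputs":
        run = Path(run_dir)
        ts_path = run / "patch_timeseries.csv"
        with open(run / "meta.json") as fh:
            meta = json.load(fh)
        return cls(
            pd.read_csv(run / "nesting_events.csv"),
            pd.read_csv(run / "track_samples.csv"),
            pd.read_csv(run / "patch_usage.csv"),
            pd.read_csv(ts_path) if ts_path.exists() else None,
            meta,
        )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def origin_diversity(visit_counts_by_site: dict | list, n_sites: int) -> float:
    """Normalized Shannon diversity of a patch's visitor origins, in [0, 1].

    0 when all postnesting visits come from a single rookery; 1 when the
    visits are spread perfectly evenly over all ``n_sites`` rookeries.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    counts = (list(visit_counts_by_site.values())
              if isinstance(visit_counts_by_site, dict)
              else list(visit_counts_by_site))
    if any(c < 0 for c in counts):
        raise ValueError("negative visit count")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero visit counts: diversity undefined")
    h = 0.0
    for c in counts:
        if c > 0:
            r = c / total
            h -= r * math.log(r)
    return h / math.log(n_sites)


def remigration_intervals(events: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean interval between successive nesting events.

    Turtles with fewer than two recorded events are excluded. Returns a
    frame with ``turtle_id, site_id, n_events, mean_interval_years``.
    """
    if events.empty:
        return pd.DataFrame(columns=["turtle_id", "site_id", "n_events",
                                     "mean_interval_years"])
    rows = []
    for (tid, sid), grp in events.groupby(["turtle_id", "site_id"], sort=True):
        steps = np.sort(grp["step"].to_numpy())
        if len(steps) < 2:
            continue
        mean_steps = float(np.diff(steps).mean())
        rows.append((tid, sid, len(steps),
                     mean_steps * DAYS_PER_STEP / DAYS_PER_YEAR))
    return pd.DataFrame(rows, columns=["turtle_id", "site_id", "n_events",
                                       "mean_interval_years"])


def reproductive_output(events: pd.DataFrame, s_n: float) -> pd.DataFrame:
    """Rookery reproductive output from the nesting-event table.

    For each rookery, sums over individuals and over events (from the
    second on) the post-nesting energy divided by the preceding
    remigration interval in days, then scales by the nesting investment
    ``S_N``. Returns ``site_id, reproductive_output`` (energy/day units).
    """
    if not 0.0 <= s_n <= 1.0:
        raise ValueError("S_N must lie in [0, 1]")
    out: dict[int, float] = {}
    if not events.empty:
        for (tid, sid), grp in events.groupby(["turtle_id", "site_id"]):
            g = grp.sort_values("step")
            steps = g["step"].to_numpy(dtype=float)
            energy = g["energy_after"].to_numpy(dtype=float)
            if len(steps) < 2:
                continue
            dt_days = np.diff(steps) * DAYS_PER_STEP
            out[sid] = out.get(sid, 0.0) + float((energy[1:] / dt_days).sum())
    rows = [(sid, s_n * v) for sid, v in sorted(out.items())]
    return pd.DataFrame(rows, columns=["site_id", "reproductive_output"])


def mean_energy_at_nesting(events: pd.DataFrame) -> pd.DataFrame:
    """Per-rookery mean post-nesting energy level."""
    if events.empty:
        return pd.DataFrame(columns=["site_id", "mean_energy_after"])
    g = events.groupby("site_id")["energy_after"].mean().reset_index()
    return g.rename(columns={"energy_after": "mean_energy_after"})


def sample_tracks(turtles, step: int, rng: np.random.Generator,
                  sampling_period: float, store: ObservationStore) -> int:
    """Bernoulli-thin migrating turtles into the track-sample table.

    Each turtle currently on a prenesting or postnesting migration is
    recorded with probability ``1/sampling_period`` (so inter-sample gaps
    average one period per migrating turtle); foraging migrants and
    stationary turtles are never recorded. Returns the number of samples
    taken this step.
    """
    if sampling_period <= 0 or not math.isfinite(sampling_period):
        return 0
    p = 1.0 / sampling_period
    taken = 0
    for t in turtles:
        if t.internal_state in ("prenesting", "postnesting") and rng.random() < p:
            store.record_track_sample(t.turtle_id, step, t.x, t.y,
                                      t.internal_state, t.nesting_site_id)
            taken += 1
    return taken


def subsample_positions(samples_by_run: list[pd.DataFrame], per_run: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Pool ``per_run`` track positions per run, without replacement.

    Runs with fewer samples contribute all of them. Returns an (n, 2)
    array of (x, y) positions in km.
    """
    pools = []
    for df in samples_by_run:
        pts = df[["x_km", "y_km"]].to_numpy(dtype=float)
        if len(pts) > per_run:
            idx = rng.choice(len(pts), size=per_run, replace=False)
            pts = pts[idx]
        pools.append(pts)
    if not pools:
        return np.empty((0, 2))
    return np.concatenate(pools, axis=0)


def kernel_density(positions: np.ndarray, bandwidth_km: float | None,
                   grid_spec: tuple[int, int, float, float],
                   ) -> tuple[np.ndarray, float]:
    """Gaussian product-kernel utilization density on a regular grid.

    ``grid_spec`` is ``(n_cols, n_rows, width_km, height_km)``; the raster
    covers ``[0, width] x [0, height]`` with row 0 at the southern edge.
    ``bandwidth_km=None`` applies a Silverman-type reference rule on the
    pooled positions. Returns ``(density, bandwidth)`` with the density
    integrating to ~1 over the grid (sum * cell_area = 1).
    """
    pts = np.asarray(positions, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one sample position")
    n = pts.shape[0]
    if bandwidth_km is None:
        sx = pts[:, 0].std(ddof=1) if n > 1 else 1.0
        sy = pts[:, 1].std(ddof=1) if n > 1 else 1.0
        sigma = max(0.5 * (sx + sy), 1e-9)
        bandwidth_km = max(sigma * n ** (-1.0 / 6.0), 1e-9)  # 2-D Silverman
    h = float(bandwidth_km)
    n_cols, n_rows, width, height = grid_spec
    xs = (np.arange(n_cols) + 0.5) * (width / n_cols)
    ys = (np.arange(n_rows) + 0.5) * (height / n_rows)
    norm = 1.0 / (n * 2.0 * math.pi * h * h)
    density = np.zeros((n_rows, n_cols))
    # chunk over sample points to bound memory on large grids
    chunk = max(1, int(2e7 // (n_rows * n_cols)) or 1)
    for lo in range(0, n, chunk):
        sub = pts[lo:lo + chunk]
        dx2 = (xs[None, :] - sub[:, 0:1]) ** 2          # (m, n_cols)
        dy2 = (ys[None, :] - sub[:, 1:2]) ** 2          # (m, n_rows)
        for k in range(sub.shape[0]):
            density += norm * np.exp(-(dy2[k][:, None] + dx2[k][None, :])
                                     / (2.0 * h * h))
    cell_area = (width / n_cols) * (height / n_rows)
    total = density.sum() * cell_area
    if total > 0:
        density /= total
    return density, h


def usage_report(patch_usage_tables: list[pd.DataFrame], n_sites: int
                 ) -> pd.DataFrame:
    """Pool per-run patch-usage tables and derive mixing metrics.

    Counts add elementwise across runs. Per patch the report carries the
    pooled tallies, the number of distinct origin rookeries among its
    postnesting visitors, and the normalized Shannon origin diversity
    (NaN for patches that were never visited after nesting).
    """
    if not patch_usage_tables:
        raise ValueError("need at least one patch-usage table")
    pooled: dict[int, dict] = {}
    for table in patch_usage_tables:
        for row in table.itertuples():
            d = pooled.setdefault(row.patch_id, {
                "x_km": row.x_km, "y_km": row.y_km, "time_usage": 0,
                "postnesting_visits": 0, "foraging_visits": 0,
                "origins": {},
            })
            d["time_usage"] += int(row.time_usage)
            d["postnesting_visits"] += int(row.postnesting_visits)
            d["foraging_visits"] += int(row.foraging_visits)
            origins = row.visits_by_origin_site
            if isinstance(origins, str):
                origins = json.loads(origins)
            for sid, c in origins.items():
                sid = int(sid)
                d["origins"][sid] = d["origins"].get(sid, 0) + int(c)
    rows = []
    for pid in sorted(pooled):
        d = pooled[pid]
        origins = d["origins"]
        n_origin = sum(1 for c in origins.values() if c > 0)
        h = (origin_diversity(origins, n_sites)
             if sum(origins.values()) > 0 else float("nan"))
        rows.append((pid, d["x_km"], d["y_km"], d["time_usage"],
                     d["postnesting_visits"], d["foraging_visits"],
                     n_origin, h))
    return pd.DataFrame(rows, columns=[
        "patch_id", "x_km", "y_km", "time_usage", "postnesting_visits",
        "foraging_visits", "n_origin_sites", "origin_diversity"])
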