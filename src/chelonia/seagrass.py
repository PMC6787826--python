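"""Feeding-patch resource dynamics.

Each feeding patch carries a seagrass resource level ``phi`` in
``[0, phi_max]``. Per step the patch regrows logistically with intrinsic
rate ``beta`` and is depleted in proportion to the number of turtles
feeding on it (density-dependent grazing):

    d_phi = beta * phi * (1 - phi / phi_max) - alpha * N * phi

``beta`` is calibrated so that, with the population spread evenly over the
patches (occupancy ``N_T / N_F`` everywhere), the long-term resource level
settles at half the carrying capacity: ``beta = 2 * alpha * N_T / N_F``.

A perturbation — a stand-in for habitat degradation at a given latitude —
removes an extra fraction of the resource from every patch within its
latitudinal range of action, with strength inversely proportional to the
patch's latitudinal distance from the perturbation.

All rates in this module are *per step*; the engine halves daily rates
once (two steps per day) before calling in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .landscape import Landscape


@dataclass
class FeedingPatchState:
    """Mutable per-patch state: resource level, occupancy and usage tallies."""

    patch_id: int
    x: float
    y: float
    phi: float
    phi_max: float
    occupancy: int = 0
    time_usage: int = 0
    postnesting_visits: int = 0
    foraging_visits: int = 0
    visits_by_origin_site: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= self.phi_max):
            raise ValueError("phi outside [0, phi_max]")

    @property
    def location(self) -> tuple[float, float]:
        return (self.x, self.y)

    def record_postnesting_visit(self, origin_site_id: int) -> None:
        self.postnesting_visits += 1
        self.visits_by_origin_site[origin_site_id] = (
            self.visits_by_origin_site.get(origin_site_id, 0) + 1
        )


@dataclass(frozen=True)
class Perturbation:
    """Latitude-banded productivity reduction.

    ``sigma_y`` is the perturbation latitude (degrees), ``sigma_i`` its
    dimensionless intensity and ``d_sigma_max`` the maximum latitudinal
    range of action (degrees).
    """

    sigma_y: float
    sigma_i: float
    d_sigma_max: float
    active: bool = True

    def __post_init__(self) -> None:
        if self.sigma_i < 0:
            raise ValueError("sigma_i must be >= 0")
        if self.d_sigma_max <= 0:
            raise ValueError("d_sigma_max must be > 0")


def regrowth_coefficient(alpha: float, n_turtles: float, n_patches: float) -> float:
    """Logistic regrowth rate keeping the system near half capacity.

    With the whole population spread evenly (``N_T / N_F`` turtles per
    patch), the depletion-regrowth balance has its fixed point at
    ``phi_max / 2`` when ``beta = 2 * alpha * N_T / N_F``.
    """
    if alpha <= 0 or n_turtles <= 0 or n_patches <= 0:
        raise ValueError("alpha, n_turtles and n_patches must all be > 0")
    return 2.0 * alpha * n_turtles / n_patches


def update_patch(patch: FeedingPatchState, beta: float, alpha: float,
                 phi_max: float) -> float:
    """One step of logistic regrowth and density-dependent depletion.

    Returns (and stores) the new resource level, clamped to
    ``[0, phi_max]``. ``beta`` and ``alpha`` are per-step rates.
    """
    phi = patch.phi
    d_phi = beta * phi * (1.0 - phi / phi_max) - alpha * patch.occupancy * phi
    patch.phi = min(max(phi + d_phi, 0.0), phi_max)
    return patch.phi


def perturbation_delta(phi: float, latitude: float, perturbation: Perturbation,
                       beta: float, d_floor: float) -> float:
    """Resource reduction a perturbation inflicts on a patch at ``latitude``.

    Zero outside the range of action; inside, proportional to intensity,
    to the per-step regrowth rate and to ``d_sigma_max / d`` where ``d`` is
    the latitudinal distance (floored at ``d_floor`` to keep the
    1/d factor finite for patches at the perturbation latitude).
    """
    d = abs(latitude - perturbation.sigma_y)
    if d >= perturbation.d_sigma_max or perturbation.sigma_i == 0.0:
        return 0.0
    d_eff = max(d, d_floor)
    return perturbation.sigma_i * beta * (perturbation.d_sigma_max / d_eff) * phi


def apply_perturbation(patch: FeedingPatchState, perturbation: Perturbation,
                       beta: float, landscape: Landscape,
                       d_floor: float | None = None) -> float:
    """Apply the latitude-banded reduction to a patch; returns new ``phi``.

    ``d_floor`` defaults to one cell's latitude extent on this landscape.
    """
    if not perturbation.active:
        return patch.phi
    if d_floor is None:
        lat_span = landscape.bbox[3] - landscape.bbox[2]
        d_floor = lat_span / landscape.n_rows
    lat = landscape.latitude_of(patch.y)
    delta = perturbation_delta(patch.phi, lat, perturbation, beta, d_floor)
    patch.phi = max(patch.phi - delta, 0.0)
    return patch.phi


def net_energy_gain(phi: float, alpha: float) -> float:
    """Per-step energy intake of one turtle feeding at resource level ``phi``."""
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return alpha * phi
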