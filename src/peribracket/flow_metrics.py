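"""Peri-bracket flow statistics: regional speeds, low-velocity and vortex areas.

All metrics are evaluated on the near-wall velocity in the first fluid cell
layer above the tooth plane, per peri-bracket region (BO/BG/BL/BR):

* regional average velocity — area-weighted mean near-wall speed;
* low-velocity area — surface area where the near-wall speed stays at or
  below 0.005 m/s (v_max/100, the plaque-retention proxy);
* vortex area — area of connected swirl regions identified with the 2-D
  Q-criterion (second invariant of the tangential velocity gradient) on
  the near-wall field.

Areas are cell counts times cell area, in mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import ConfigurationError, DegenerateInputError
from .flow_solver import MM, FlowField, SwallowResult, cell_center_speed
from .geometry import BG, BL, BO, BR, REGION_CODES, REGION_NAMES, GeometryModel

#: low-velocity threshold, m/s (v_max/100 = 0.005 m/s = 5 mm/s)
LOW_VELOCITY_THRESHOLD = 0.005
#: Q-criterion threshold, s^-2
EPS_Q = 1.0e-6

SITES = ("BO", "BG", "BL", "BR")


@dataclass(frozen=True)
class SurfaceSpeedMap:
    """Near-wall speed per tooth-surface cell for one flow direction.

    ``speeds`` is (nx, ny) in m/s with NaN under solid-covered cells;
    ``cell_area`` is mm^2.
    """

    speeds: np.ndarray
    cell_area: float
    direction: str = ""

    def __post_init__(self):
        valid = self.speeds[~np.isnan(self.speeds)]
        if (valid < 0).any():
            raise ConfigurationError("speeds must be >= 0")


@dataclass(frozen=True)
class Vortex:
    """One detected swirl region: centroid (mm) and area (mm^2)."""

    centroid: tuple[float, float]
    area: float
    cells: np.ndarray  # boolean (nx, ny) component mask


@dataclass(frozen=True)
class RegionMetrics:
    """The per-site flow statistics for one direction (or combined)."""

    site: str
    direction: str
    avg_speed: float  # m/s
    low_velocity_area: float  # mm^2
    vortex_area: float  # mm^2


def near_wall_speed(field: FlowField, model: GeometryModel,
                    layer: int = 0, direction: str = "") -> SurfaceSpeedMap:
    """Speed magnitude in the ``layer``-th fluid cell layer above z = 0."""
    return SurfaceSpeedMap(
        speeds=cell_center_speed(field, model, layer=layer),
        cell_area=model.cell_area,
        direction=direction,
    )


def _region_mask(model: GeometryModel, region) -> np.ndarray:
    """Resolve a region argument (code, name or mask) to a boolean map."""
    if region is None:
        return ~model.surface_solid
    if isinstance(region, str):
        region = REGION_CODES[region]
    if isinstance(region, (int, np.integer)):
        return model.region_mask(int(region))
    return np.asarray(region, dtype=bool)


def regional_average_velocity(
    speed_map: SurfaceSpeedMap, model: GeometryModel
) -> dict[str, float]:
    """Area-weighted mean near-wall speed per peri-bracket site, m/s."""
    out = {}
    for name in SITES:
        mask = model.region_mask(REGION_CODES[name])
        vals = speed_map.speeds[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise DegenerateInputError(f"region {name} has no fluid cells")
        out[name] = float(vals.mean())
    return out


def low_velocity_area(
    speed_map: SurfaceSpeedMap,
    model: GeometryModel,
    threshold: float = LOW_VELOCITY_THRESHOLD,
    region=None,
) -> float:
    """Area (mm^2) of cells with near-wall speed <= ``threshold``."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    mask = _region_mask(model, region)
    sel = mask & (speed_map.speeds <= threshold)
    return float(np.count_nonzero(sel)) * speed_map.cell_area


def q_criterion_tangential(uc: np.ndarray, vc: np.ndarray,
                           model: GeometryModel) -> np.ndarray:
    """2-D Q-criterion of a cell-centred tangential velocity map, s^-2.

    Q = (||Omega||^2 - ||S||^2) / 2 for the in-plane velocity gradient;
    positive where rotation dominates strain.  Before differencing, values
    under solid cells are replaced by the nearest fluid value
    (zero-gradient extrapolation, consistent with free-slip walls); solid
    cells themselves are returned as -inf.
    """
    uc = np.array(uc, dtype=float)
    vc = np.array(vc, dtype=float)
    solid = model.surface_solid
    if solid.any():
        idx = ndi.distance_transform_edt(
            solid, return_distances=False, return_indices=True
        )
        for a in (uc, vc):
            a[solid] = a[tuple(i[solid] for i in idx)]
    h = model.cell_size * MM
    ux, uy = np.gradient(uc, h)
    vx, vy = np.gradient(vc, h)
    omega_sq = 0.5 * (uy - vx) ** 2
    strain_sq = ux**2 + vy**2 + 0.5 * (uy + vx) ** 2
    q = 0.5 * (omega_sq - strain_sq)
    q[solid] = -np.inf
    return q


def q_criterion(field: FlowField, model: GeometryModel,
                layer: int = 0) -> np.ndarray:
    """2-D Q-criterion of the near-wall tangential velocity of a field."""
    uc = 0.5 * (field.u[:-1] + field.u[1:])[:, :, layer]
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])[:, :, layer]
    return q_criterion_tangential(uc, vc, model)


def detect_vortices_tangential(
    uc: np.ndarray,
    vc: np.ndarray,
    model: GeometryModel,
    region=None,
    eps_q: float = EPS_Q,
) -> list[Vortex]:
    """``detect_vortices`` on a cell-centred tangential velocity map."""
    q = q_criterion_tangential(uc, vc, model)
    return _components(q, model, region, eps_q)


def detect_vortices(
    field: FlowField,
    model: GeometryModel,
    region=None,
    layer: int = 0,
    eps_q: float = EPS_Q,
) -> list[Vortex]:
    """Connected swirl regions (Q > eps_q) intersecting ``region``.

    Returns one ``Vortex`` per connected component (4-connectivity) with
    its area centroid in mm and full component area in mm^2, ordered by
    area descending, then by centroid (y, x).
    """
    q = q_criterion(field, model, layer=layer)
    return _components(q, model, region, eps_q)


def _components(q, model, region, eps_q) -> list[Vortex]:
    labels, n = ndi.label(q > eps_q)
    mask = _region_mask(model, region) if region is not None else None
    h = model.cell_size
    out = []
    for comp in range(1, n + 1):
        cells = labels == comp
        if region is not None and not (cells & mask).any():
            continue
        ci, cj = ndi.center_of_mass(cells)
        out.append(
            Vortex(
                centroid=((ci + 0.5) * h, (cj + 0.5) * h),
                area=float(np.count_nonzero(cells)) * model.cell_area,
                cells=cells,
            )
        )
    out.sort(key=lambda v: (-v.area, v.centroid[1], v.centroid[0]))
    return out


def vortex_area_in_region(vortices: Sequence[Vortex], model: GeometryModel,
                          region) -> float:
    """Total vortex area inside one region (component-region overlap), mm^2."""
    mask = _region_mask(model, region)
    cells = np.zeros_like(mask)
    for v in vortices:
        cells |= v.cells
    return float(np.count_nonzero(cells & mask)) * model.cell_area


def combine_directions(
    gingival: RegionMetrics, occlusal: RegionMetrics
) -> RegionMetrics:
    """Merge the two flow directions for one site.

    Average speed and low-velocity area are arithmetic means of the two
    directions; the combined vortex area is the larger of the two (vortex
    formation is direction-specific).
    """
    if gingival.site != occlusal.site:
        raise ConfigurationError(
            f"site mismatch: {gingival.site} vs {occlusal.site}"
        )
    return RegionMetrics(
        site=gingival.site,
        direction="combined",
        avg_speed=0.5 * (gingival.avg_speed + occlusal.avg_speed),
        low_velocity_area=0.5
        * (gingival.low_velocity_area + occlusal.low_velocity_area),
        vortex_area=max(gingival.vortex_area, occlusal.vortex_area),
    )


def swallow_metrics(
    result: SwallowResult,
    model: GeometryModel,
    threshold: float = LOW_VELOCITY_THRESHOLD,
    eps_q: float = EPS_Q,
) -> list[RegionMetrics]:
    """Per-site metrics of one simulated swallow.

    Average speed is the area-weighted regional mean of the time-averaged
    near-wall speed.  The low-velocity area is evaluated on the mid-cycle
    field, where the inflow runs at the characteristic swallow rate (the
    instant at which the velocity distribution is conventionally read
    off).  Vortices are detected on the end-of-cycle residual field,
    where the driving inflow has decayed and only closed recirculation
    survives.
    """
    direction = result.cycle.direction
    mean_map = SurfaceSpeedMap(
        result.mean_surface_speed, model.cell_area, direction
    )
    mid_map = near_wall_speed(result.mid_cycle_field, model,
                              direction=direction)
    avg = regional_average_velocity(mean_map, model)
    residual = result.snapshots[-1]
    vortices = detect_vortices(residual, model, eps_q=eps_q)
    out = []
    for name in SITES:
        out.append(
            RegionMetrics(
                site=name,
                direction=direction,
                avg_speed=avg[name],
                low_velocity_area=low_velocity_area(
                    mid_map, model, threshold, region=name
                ),
                vortex_area=vortex_area_in_region(vortices, model, name),
            )
        )
    return out
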