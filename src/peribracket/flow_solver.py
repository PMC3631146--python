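"""Transient incompressible viscous flow over the bracket-bearing surface.

The saliva film is modelled with the incompressible Navier-Stokes equations

    rho (dv/dt + v . grad v) = -grad p + mu lap v,    div v = 0,

gravity ignored, on a uniform staggered (MAC) Cartesian grid with the
bracket/archwire represented as an immersed solid mask.  A swallow drives
the film along the occluso-gingival axis with a half-sine inflow pulse
(zero at the start and end of the 0.25 s movement, peak 0.172 m/s at
mid-cycle).  Tooth, bracket and the remaining walls are impermeable and,
by default, free-slip ("frictionless"); a no-slip mode is available for
sensitivity runs such as the Poiseuille validation case.

Discretisation: explicit first-order upwind advection, explicit central
diffusion, and a Chorin-type pressure projection.  The pressure-Poisson
system (homogeneous Neumann on all prescribed-velocity boundaries, one
pinned cell to remove the nullspace) is assembled once per geometry and
solved with a cached sparse LU factorisation, so every step's projection
is exact to machine precision.

Internally everything is SI (m, s, kg); geometry objects carry mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import CFLError, ConfigurationError, SolverDivergenceError
from .geometry import GeometryModel

MM = 1e-3  # mm -> m

#: advective CFL safety factor
CFL_ADV = 0.4
#: explicit 3-D diffusion stability factor (dt <= factor * h^2 / nu)
CFL_DIFF = 1.0 / 6.0


@dataclass(frozen=True)
class FluidProps:
    """Fluid properties of saliva (SI units).

    Density 1000 kg/m^3 (1 g/cm^3); dynamic viscosity defaults to the
    water-like 1.0 mPa s.  ``eddy_viscosity_factor`` adds a constant
    turbulent viscosity as a multiple of the molecular one (0 = laminar).
    """

    density: float = 1000.0
    dynamic_viscosity: float = 1.0e-3
    eddy_viscosity_factor: float = 0.0

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ConfigurationError("density and viscosity must be > 0")
        if self.eddy_viscosity_factor < 0:
            raise ConfigurationError("eddy_viscosity_factor must be >= 0")

    @property
    def kinematic_viscosity(self) -> float:
        """Effective kinematic viscosity nu, m^2/s."""
        return (
            self.dynamic_viscosity
            * (1.0 + self.eddy_viscosity_factor)
            / self.density
        )


@dataclass(frozen=True)
class SwallowCycle:
    """One swallow: a half-sine inflow pulse along the occluso-gingival axis.

    ``direction`` is the direction the saliva moves: "gingival" means flow
    toward the gums (-y, entering through the occlusal face) and
    "occlusal" the reverse.  Speed is zero at t = 0 and t = T and peaks at
    mid-cycle.
    """

    direction: Literal["gingival", "occlusal"] = "gingival"
    duration: float = 0.25  #: s
    peak_speed: float = 0.172  #: m/s

    def __post_init__(self):
        if self.direction not in ("gingival", "occlusal"):
            raise ConfigurationError(
                f"unknown flow direction {self.direction!r}"
            )
        if self.duration <= 0 or self.peak_speed <= 0:
            raise ConfigurationError("duration and peak_speed must be > 0")

    @property
    def sign(self) -> float:
        """Sign of the y velocity component for this direction."""
        return -1.0 if self.direction == "gingival" else 1.0


def inflow_speed(t: float, cycle: SwallowCycle) -> float:
    """Inflow speed magnitude at time ``t``: peak * sin(pi t / T).

    Raises ``ValueError`` when t lies outside [0, T].
    """
    if not 0.0 <= t <= cycle.duration:
        raise ValueError(
            f"t={t!r} outside the swallow cycle [0, {cycle.duration}]"
        )
    return cycle.peak_speed * float(np.sin(np.pi * t / cycle.duration))


@dataclass
class FlowField:
    """Staggered velocity components and cell-centred pressure.

    ``u`` lives on x-normal faces (nx+1, ny, nz), ``v`` on y-normal faces
    (nx, ny+1, nz), ``w`` on z-normal faces (nx, ny, nz+1), ``p`` at cell
    centres (nx, ny, nz); all SI.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    time: float = 0.0

    def copy(self) -> "FlowField":
        return FlowField(
            self.u.copy(), self.v.copy(), self.w.copy(), self.p.copy(),
            self.time,
        )

    def max_speed(self) -> float:
        return max(
            float(np.abs(self.u).max()),
            float(np.abs(self.v).max()),
            float(np.abs(self.w).max()),
        )


@dataclass(frozen=True)
class SolverOptions:
    """Numerical and boundary-condition options.

    ``slip`` selects the tangential condition on immersed solid surfaces
    (bracket, wire): "free" (zero shear, the frictionless assumption) or
    "no" (zero velocity).  ``wall_slip`` optionally overrides the
    condition on the domain walls per axis (x, y, z), e.g.
    ``("free", "free", "no")`` for no-slip plates normal to z; ``None``
    applies ``slip`` everywhere.  ``body_force`` is a constant
    acceleration (m/s^2), used by validation cases.  ``tol`` is the
    relative residual required of the pressure solve.
    """

    slip: Literal["free", "no"] = "free"
    wall_slip: tuple[str, str, str] | None = None
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tol: float = 1.0e-8
    max_iter: int = 10_000

    def wall_slip_axis(self, axis: int) -> str:
        return self.slip if self.wall_slip is None else self.wall_slip[axis]


def zero_field(model: GeometryModel) -> FlowField:
    """An all-zero field on the model's staggered grid."""
    nx, ny, nz = model.shape
    return FlowField(
        u=np.zeros((nx + 1, ny, nz)),
        v=np.zeros((nx, ny + 1, nz)),
        w=np.zeros((nx, ny, nz + 1)),
        p=np.zeros((nx, ny, nz)),
    )


def set_inflow(field: FlowField, value: float | np.ndarray) -> None:
    """Prescribe the y-face normal velocity on both y boundaries (in place).

    The same signed value on the upstream and downstream face keeps the
    net volumetric flux identically zero (what comes in goes out).
    """
    field.v[:, 0, :] = value
    field.v[:, -1, :] = value


def divergence(field: FlowField, model: GeometryModel) -> np.ndarray:
    """Discrete divergence (1/s) at cell centres; zero on solid cells."""
    h = model.cell_size * MM
    div = (
        np.diff(field.u, axis=0)
        + np.diff(field.v, axis=1)
        + np.diff(field.w, axis=2)
    ) / h
    div[model.solid_mask] = 0.0
    return div


def cell_center_speed(field: FlowField, model: GeometryModel,
                      layer: int | None = None) -> np.ndarray:
    """Cell-centred speed magnitude (m/s); NaN on solid cells.

    With ``layer`` given, returns the (nx, ny) map of that z layer.
    """
    uc = 0.5 * (field.u[:-1] + field.u[1:])
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
    wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])
    speed = np.sqrt(uc**2 + vc**2 + wc**2)
    speed[model.solid_mask] = np.nan
    if layer is not None:
        return speed[:, :, layer]
    return speed


class ProjectionSolver:
    """Stateful stepper: caches masks and the pressure-Poisson factorisation.

    Reuse one instance for a whole transient run; the module-level
    ``advance``/``project`` helpers build a throwaway instance per call.
    """

    def __init__(self, model: GeometryModel, props: FluidProps,
                 options: SolverOptions | None = None):
        self.model = model
        self.props = props
        self.options = options or SolverOptions()
        self.h = model.cell_size * MM
        nx, ny, nz = model.shape
        self.shape = (nx, ny, nz)
        solid = model.solid_mask
        self.fluid = ~solid

        # unknown (correctable) interior faces: both adjacent cells fluid
        self.u_active = np.zeros((nx + 1, ny, nz), bool)
        self.u_active[1:nx] = self.fluid[:-1] & self.fluid[1:]
        self.v_active = np.zeros((nx, ny + 1, nz), bool)
        self.v_active[:, 1:ny] = self.fluid[:, :-1] & self.fluid[:, 1:]
        self.w_active = np.zeros((nx, ny, nz + 1), bool)
        self.w_active[:, :, 1:nz] = self.fluid[:, :, :-1] & self.fluid[:, :, 1:]

        if solid[:, 0, :].any() or solid[:, -1, :].any():
            raise ConfigurationError(
                "solid cells touch the inflow/outflow (y) boundaries"
            )

        self._assemble_poisson()

    # -- pressure-Poisson system -------------------------------------

    def _assemble_poisson(self) -> None:
        fluid = self.fluid
        n = int(fluid.sum())
        idx = -np.ones(self.shape, dtype=np.int64)
        idx[fluid] = np.arange(n)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            pair = fluid[tuple(lo)] & fluid[tuple(hi)]
            a = idx[tuple(lo)][pair]
            b = idx[tuple(hi)][pair]
            rows.extend([a, b])
            cols.extend([b, a])
            vals.extend([np.ones(a.size), np.ones(a.size)])
            np.add.at(diag, a, -1.0)
            np.add.at(diag, b, -1.0)
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        # pin the first fluid cell to remove the Neumann nullspace
        A = A.tolil()
        A.rows[0] = [0]
        A.data[0] = [1.0]
        self._A = A.tocsc()
        self._lu = spla.splu(self._A)
        self._idx = idx
        self._n = n

    def project(self, fld: FlowField) -> FlowField:
        """Make the velocity divergence-free via a pressure correction."""
        h, rho = self.h, self.props.density
        div = divergence(fld, self.model)
        rhs = div[self.fluid] * h**2  # solve A phi = h^2 * div
        rhs[0] = 0.0
        phi = self._lu.solve(rhs)
        res = np.linalg.norm(self._A @ phi - rhs)
        scale = np.linalg.norm(rhs)
        if not np.isfinite(phi).all() or (
            scale > 0 and res > self.options.tol * max(scale, 1e-300)
        ):
            raise SolverDivergenceError(
                f"pressure solve residual {res:.3e} exceeds tolerance",
                residual_history=[res],
            )
        phi3 = np.zeros(self.shape)
        phi3[self.fluid] = phi
        out = fld.copy()
        out.u[self.u_active] -= np.diff(phi3, axis=0)[self.u_active[1:-1]] / h
        out.v[self.v_active] -= np.diff(phi3, axis=1)[self.v_active[:, 1:-1]] / h
        out.w[self.w_active] -= np.diff(phi3, axis=2)[self.w_active[:, :, 1:-1]] / h
        # phi = dt * p / rho up to the pinned constant; store rho*phi so the
        # caller can rescale by 1/dt when the step size is known
        out.p[self.fluid] = rho * phi
        return out

    # -- finite-difference helpers ------------------------------------

    def _neighbor(self, arr: np.ndarray, active: np.ndarray, axis: int,
                  step: int, normal_axis: int) -> np.ndarray:
        """Neighbour values of a face array one cell over along ``axis``.

        Along the component's own (normal) axis the stored values already
        carry the boundary data (walls and inflow faces hold their
        prescribed values), so a plain shift suffices.  Along tangential
        axes, inactive or out-of-domain neighbours are replaced by a ghost
        value: +center for free-slip (zero shear), -center for no-slip.
        """
        nb = np.roll(arr, -step, axis=axis)
        if axis == normal_axis:
            return nb
        edge = np.zeros(arr.shape, bool)
        sl = [slice(None)] * 3
        sl[axis] = -1 if step > 0 else 0
        edge[tuple(sl)] = True
        nb_active = np.roll(active, -step, axis=axis)
        solid_ghost = arr if self.options.slip == "free" else -arr
        wall_ghost = (
            arr if self.options.wall_slip_axis(axis) == "free" else -arr
        )
        return np.where(edge, wall_ghost, np.where(~nb_active, solid_ghost, nb))

    def _upwind_advect(self, arr, active, normal_axis, adv):
        """First-order upwind v.grad(arr); adv = 3 advecting-speed arrays."""
        h = self.h
        out = np.zeros_like(arr)
        for axis in range(3):
            a = adv[axis]
            nb_m = self._neighbor(arr, active, axis, -1, normal_axis)
            nb_p = self._neighbor(arr, active, axis, +1, normal_axis)
            d = np.where(a >= 0, (arr - nb_m) / h, (nb_p - arr) / h)
            out += a * d
        return out

    def _laplacian(self, arr, active, normal_axis):
        h = self.h
        out = np.zeros_like(arr)
        for axis in range(3):
            for step in (-1, +1):
                out += self._neighbor(arr, active, axis, step, normal_axis)
            out -= 2.0 * arr
        return out / h**2

    def _advecting(self, fld: FlowField):
        """Advecting velocities interpolated to each component's faces."""
        nx, ny, nz = self.shape
        u, v, w = fld.u, fld.v, fld.w

        av_u = np.zeros_like(u)
        av_u[1:nx] = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        aw_u = np.zeros_like(u)
        aw_u[1:nx] = 0.25 * (
            w[:-1, :, :-1] + w[:-1, :, 1:] + w[1:, :, :-1] + w[1:, :, 1:]
        )

        au_v = np.zeros_like(v)
        au_v[:, 1:ny] = 0.25 * (
            u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:]
        )
        aw_v = np.zeros_like(v)
        aw_v[:, 1:ny] = 0.25 * (
            w[:, :-1, :-1] + w[:, :-1, 1:] + w[:, 1:, :-1] + w[:, 1:, 1:]
        )

        au_w = np.zeros_like(w)
        au_w[:, :, 1:nz] = 0.25 * (
            u[:-1, :, :-1] + u[:-1, :, 1:] + u[1:, :, :-1] + u[1:, :, 1:]
        )
        av_w = np.zeros_like(w)
        av_w[:, :, 1:nz] = 0.25 * (
            v[:, :-1, :-1] + v[:, :-1, 1:] + v[:, 1:, :-1] + v[:, 1:, 1:]
        )
        return (
            (u, av_u, aw_u),
            (au_v, v, aw_v),
            (au_w, av_w, w),
        )

    # -- time stepping -------------------------------------------------

    def stable_dt(self, max_speed: float) -> float:
        """Largest stable step for the current speed scale."""
        nu = self.props.kinematic_viscosity
        dt = CFL_DIFF * self.h**2 / nu
        if max_speed > 0:
            dt = min(dt, CFL_ADV * self.h / max_speed)
        return dt

    def advance(self, fld: FlowField, dt: float) -> FlowField:
        """One explicit step (advection + diffusion) plus projection."""
        if not (
            np.isfinite(fld.u).all()
            and np.isfinite(fld.v).all()
            and np.isfinite(fld.w).all()
        ):
            raise SolverDivergenceError("NaN/Inf in the velocity field")
        limit = self.stable_dt(fld.max_speed())
        if dt > limit * (1 + 1e-12):
            raise CFLError(
                f"dt={dt:.3e} s violates the stability limit; "
                f"dt <= {limit:.3e} s required",
                required_dt=limit,
            )
        nu = self.props.kinematic_viscosity
        fx, fy, fz = self.options.body_force
        adv_u, adv_v, adv_w = self._advecting(fld)

        out = fld.copy()
        comps = (
            (out.u, fld.u, self.u_active, 0, adv_u, fx),
            (out.v, fld.v, self.v_active, 1, adv_v, fy),
            (out.w, fld.w, self.w_active, 2, adv_w, fz),
        )
        for target, arr, active, axis, adv, f in comps:
            rhs = (
                -self._upwind_advect(arr, active, axis, adv)
                + nu * self._laplacian(arr, active, axis)
                + f
            )
            target[active] = arr[active] + dt * rhs[active]
        projected = self.project(out)
        projected.p /= dt  # rescale the projection potential to pressure
        projected.time = fld.time + dt
        return projected


def advance(fld: FlowField, model: GeometryModel, props: FluidProps,
            dt: float, options: SolverOptions | None = None) -> FlowField:
    """One time step (throwaway solver; see ``ProjectionSolver`` for runs)."""
    return ProjectionSolver(model, props, options).advance(fld, dt)


def project(fld: FlowField, model: GeometryModel, tol: float = 1.0e-8,
            props: FluidProps | None = None) -> FlowField:
    """Project a field onto the divergence-free space (single call)."""
    solver = ProjectionSolver(
        model, props or FluidProps(), SolverOptions(tol=tol)
    )
    return solver.project(fld)


@dataclass
class SwallowResult:
    """Outputs of one simulated swallow.

    ``snapshots`` holds fields at the requested output times;
    ``max_surface_speed`` / ``mean_surface_speed`` are (nx, ny) maps of the
    cycle-maximum and time-averaged near-wall speed in the first fluid
    layer above the tooth plane (NaN under solids); volumes are in m^3.
    """

    cycle: SwallowCycle
    snapshots: list[FlowField]
    snapshot_times: list[float]
    max_surface_speed: np.ndarray
    mean_surface_speed: np.ndarray
    inflow_volume: float
    outflow_volume: float
    max_divergence: float
    n_steps: int

    @property
    def mid_cycle_field(self) -> FlowField:
        """The stored snapshot closest to t = T/2."""
        t_mid = self.cycle.duration / 2
        i = int(np.argmin([abs(t - t_mid) for t in self.snapshot_times]))
        return self.snapshots[i]

    def mass_balance_error(self) -> float:
        """|inflow - outflow| relative to the inflow volume."""
        if self.inflow_volume == 0:
            return 0.0
        return abs(self.inflow_volume - self.outflow_volume) / self.inflow_volume


def simulate_swallow(
    model: GeometryModel,
    cycle: SwallowCycle,
    props: FluidProps | None = None,
    options: SolverOptions | None = None,
    n_outputs: int = 11,
    progress: Callable[[float], None] | None = None,
) -> SwallowResult:
    """Integrate one swallow cycle over the geometry.

    Saliva enters through the upstream y face and leaves through the
    opposite one with the half-sine speed profile; the step size adapts to
    the advective/diffusive stability limits.  Returns field snapshots at
    ``n_outputs`` evenly spaced times plus the cycle-maximum and
    time-averaged near-wall speed maps used by the flow metrics.
    """
    props = props or FluidProps()
    solver = ProjectionSolver(model, props, options)
    T = cycle.duration
    out_times = list(np.linspace(0.0, T, n_outputs))
    h = solver.h
    area_y = h * h * model.shape[0] * model.shape[2]  # open y-face area, m^2

    fld = zero_field(model)
    snapshots = [fld.copy()]
    snapshot_times = [0.0]
    next_out = 1

    speed0 = cell_center_speed(fld, model, layer=0)
    max_map = np.where(np.isnan(speed0), np.nan, 0.0)
    mean_map = np.where(np.isnan(speed0), np.nan, 0.0)
    inflow_vol = outflow_vol = 0.0
    max_div = 0.0
    n_steps = 0

    t = 0.0
    while t < T - 1e-15:
        scale = max(fld.max_speed(), cycle.peak_speed)
        dt = 0.9 * solver.stable_dt(scale)
        dt = min(dt, T - t)
        if next_out < len(out_times):
            dt = min(dt, max(out_times[next_out] - t, 1e-12))
        t_new = t + dt
        set_inflow(fld, cycle.sign * inflow_speed(min(t_new, T), cycle))
        fld = solver.advance(fld, dt)
        t = t_new
        n_steps += 1

        # flux bookkeeping from the actual boundary faces
        v_in = fld.v[:, -1, :] if cycle.direction == "gingival" else fld.v[:, 0, :]
        v_out = fld.v[:, 0, :] if cycle.direction == "gingival" else fld.v[:, -1, :]
        inflow_vol += float(np.abs(v_in).mean()) * area_y * dt
        outflow_vol += float(np.abs(v_out).mean()) * area_y * dt

        speed = cell_center_speed(fld, model, layer=0)
        max_map = np.fmax(max_map, speed)
        mean_map = mean_map + speed * dt
        max_div = max(max_div, float(np.abs(divergence(fld, model)).max()))

        if progress is not None:
            progress(t / T)
        if next_out < len(out_times) and t >= out_times[next_out] - 1e-12:
            snapshots.append(fld.copy())
            snapshot_times.append(t)
            next_out += 1

    mean_map = mean_map / T
    return SwallowResult(
        cycle=cycle,
        snapshots=snapshots,
        snapshot_times=snapshot_times,
        max_surface_speed=max_map,
        mean_surface_speed=mean_map,
        inflow_volume=inflow_vol,
        outflow_volume=outflow_vol,
        max_divergence=max_div,
        n_steps=n_steps,
    )
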