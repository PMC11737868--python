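"""Two-layer oscillatory Navier-Stokes solver and period-averaged drift.

The flow stage solves the incompressible Navier-Stokes equations (advection
term retained -- it is the streaming source) in the reduced 2-D domain, with
the traveling-wave wall motion imposed as boundary velocities on the fixed
mean-position mesh (wall displacement << layer height), and the basilar
membrane as a zero-thickness Darcy interface

    u_p = -K * (p_corti - p_scala),        (positive u_p: scala -> Corti duct)
    u_fluid = u_membrane + u_p             on both membrane sides.

Discretization: staggered (MAC) finite differences, uniform grid; second-order
Crank-Nicolson for the viscous terms, Adams-Bashforth extrapolated advection,
incremental pressure projection.  The Darcy exchange enters the pressure
Poisson equation implicitly (a membrane-face conductance ``K`` replacing the
usual ``dt/(rho*dy)``), which keeps the very permeable membrane
(K = 1 m/(s*Pa)) unconditionally stable.  Integration runs from rest until the
solution is periodic; the drift field is the average of the Eulerian velocity
over the final period at fixed positions.

Closed rigid end walls mean the prescribed outer-wall normal velocity must
carry zero net volume flux at every instant; the solver projects the top-wall
amplitude onto zero mean (a uniform correction, small when several wavelengths
fit in the duct) before integrating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import CochlearGeometry, TravelingWaveField

__all__ = [
    "FluidProps",
    "FlowNumerics",
    "PeriodicFlowSolution",
    "DriftField",
    "FlowConvergenceError",
    "darcy_exchange",
    "OscChannelSolver",
    "solve_oscillatory_flow",
    "compute_drift",
    "cross_section_flux",
    "trace_particles",
]


@dataclass(frozen=True)
class FluidProps:
    """Perilymph/Corti-fluid properties.

    The default kinematic viscosity is one hundred times that of water -- the
    effective value for the finely subdivided Corti fluid spaces -- and the
    membrane permeability K = 1 m/(s*Pa) keeps transmembrane pressure small.
    """

    nu_m2_s: float = 70e-6
    rho_kg_m3: float = 1000.0
    K_m_per_s_pa: float = 1.0

    def __post_init__(self):
        if not self.nu_m2_s > 0:
            raise ValueError("nu_m2_s must be positive")
        if not self.rho_kg_m3 > 0:
            raise ValueError("rho_kg_m3 must be positive")
        if self.K_m_per_s_pa < 0:
            raise ValueError("K_m_per_s_pa must be non-negative")


@dataclass(frozen=True)
class FlowNumerics:
    """Time-integration controls.

    ``dt_s=None`` uses period/100 (10 us at 1 kHz, scaled with 1/f).  The run
    stops once the relative L2 change of the velocity field between
    consecutive periods drops below ``periodicity_tol``.

    ``taylor_wall_transfer`` enables the second-order slip that carries the
    no-slip condition from the displaced wall to the mean boundary line (the
    peristaltic-transport term); ``slip_filter_alpha`` is the per-step
    exponential-moving-average weight applied to the wall-gradient estimate
    feeding that slip (1.0 = unfiltered; the default 0.5 damps a weak
    numerical feedback between the slip and the wall-adjacent cells at a cost
    of a few percent on the slip amplitude).  Disabling both
    ``include_advection`` and ``taylor_wall_transfer`` makes the problem
    strictly linear, so any residual period-averaged drift is a numerical
    artifact -- the null-streaming control.
    """

    dt_s: float | None = None
    max_periods: int = 30
    min_periods: int = 3
    periodicity_tol: float = 1e-4
    include_advection: bool = True
    taylor_wall_transfer: bool = True
    slip_filter_alpha: float = 0.5
    min_steps_per_period: int = 32
    min_stokes_layer_cells: float = 8.0

    def __post_init__(self):
        if self.dt_s is not None and not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        if self.max_periods < self.min_periods:
            raise ValueError("max_periods must be >= min_periods")


class FlowConvergenceError(RuntimeError):
    """Raised when the flow fails to reach a periodic steady state."""

    def __init__(self, message, residual_history):
        super().__init__(message)
        self.residual_history = list(residual_history)


def darcy_exchange(delta_p_pa, K_m_per_s_pa):
    """Membrane exchange velocity u_p = -K * delta_p, delta_p = p_corti - p_scala."""
    if np.any(np.asarray(K_m_per_s_pa) < 0):
        raise ValueError("permeability K must be non-negative")
    return -np.asarray(K_m_per_s_pa) * np.asarray(delta_p_pa)


@dataclass
class PeriodicFlowSolution:
    """Eulerian velocity/pressure sampled over the final stimulus period.

    ``u`` has shape (n_samples, nx+1, ny) at x-faces/y-centers, ``v``
    (n_samples, nx, ny+1) at x-centers/y-faces, ``p`` (n_samples, nx, ny) at
    cell centers.  Samples are uniformly spaced over exactly one period.
    """

    x_faces: np.ndarray
    y_faces: np.ndarray
    membrane_index: int | None
    omega: float
    dt: float
    t_samples: np.ndarray
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    membrane_exchange: np.ndarray | None  # (n_samples, nx) u_p at membrane
    wall_velocity_top: np.ndarray         # (n_samples, nx)
    wall_velocity_membrane: np.ndarray | None
    residual_history: list
    periodicity_residual: float
    fluid: FluidProps
    meta: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return float(self.x_faces[1] - self.x_faces[0])

    @property
    def dy(self) -> float:
        return float(self.y_faces[1] - self.y_faces[0])

    @property
    def period_s(self) -> float:
        return 2.0 * np.pi / self.omega

    def max_divergence(self) -> float:
        """Max |div u| over stored samples, for the divergence-free invariant."""
        div = (
            np.diff(self.u, axis=1) / self.dx
            + np.diff(self.v, axis=2) / self.dy
        )
        return float(np.max(np.abs(div)))

    def peak_oscillatory_speed(self) -> float:
        uc = 0.5 * (self.u[:, :-1, :] + self.u[:, 1:, :])
        vc = 0.5 * (self.v[:, :, :-1] + self.v[:, :, 1:])
        return float(np.max(np.hypot(uc, vc)))


@dataclass
class DriftField:
    """Steady period-averaged (Eulerian-mean) velocity over both layers."""

    x_faces: np.ndarray
    y_faces: np.ndarray
    membrane_index: int | None
    u: np.ndarray  # (nx+1, ny)
    v: np.ndarray  # (nx, ny+1)
    omega: float
    peak_oscillatory_speed: float
    meta: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return float(self.x_faces[1] - self.x_faces[0])

    @property
    def dy(self) -> float:
        return float(self.y_faces[1] - self.y_faces[0])

    @property
    def length_m(self) -> float:
        return float(self.x_faces[-1])

    def peak_speed(self) -> float:
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return float(np.max(np.hypot(uc, vc)))


# ---------------------------------------------------------------------------
# generic oscillatory channel solver
# ---------------------------------------------------------------------------

def _tridiag(n, lower, diag, upper):
    return sp.diags([np.full(n - 1, lower), np.full(n, diag), np.full(n - 1, upper)],
                    [-1, 0, 1], format="csr")


class OscChannelSolver:
    """MAC projection solver for a (possibly two-layer) oscillatory channel.

    Walls move with single-frequency complex amplitudes: physical value is
    ``Re[amp * exp(-i*omega*t)]``.  ``vhat_*`` are normal-velocity amplitudes
    at cell centers (nx,), ``uhat_*`` tangential wall velocities at x-faces
    (nx+1,).  ``membrane_index`` selects the interior y-face carrying the
    Darcy interface; ``vhat_membrane`` is the membrane's own velocity, on top
    of which the pressure-driven exchange u_p is added by the solver.

    ``periodic_x=True`` replaces the rigid end walls by x-periodicity
    (benchmark configurations); the cochlear domain keeps closed ends.

    Wall motion is transferred to the fixed mean-position boundary.  With
    ``taylor_wall_transfer=True`` (default) the no-slip condition is carried
    from the displaced wall to the mean position to second order in the
    displacement: the tangential fluid velocity at the mean wall line becomes
    ``u = u_wall_tangential - eta * du/dy`` with ``eta`` the instantaneous
    normal wall displacement.  This term is what lets an area-oscillating duct
    pump like a peristaltic tube; without it only the interior
    Reynolds-stress streaming survives.  (The corresponding normal-velocity
    correction vanishes at second order because the tangential first-order
    velocity is zero on these walls.)
    """

    def __init__(
        self,
        nx: int,
        ny: int,
        dx: float,
        dy: float,
        omega: float,
        fluid: FluidProps,
        numerics: FlowNumerics,
        membrane_index: int | None = None,
        vhat_top=None,
        vhat_bottom=None,
        vhat_membrane=None,
        uhat_top=None,
        uhat_bottom=None,
        enforce_compatibility: bool = True,
        periodic_x: bool = False,
        meta: dict | None = None,
    ):
        self.nx, self.ny, self.dx, self.dy = nx, ny, dx, dy
        self.omega = omega
        self.fluid = fluid
        self.num = numerics
        self.jm = membrane_index
        self.periodic_x = bool(periodic_x)
        self.taylor = bool(numerics.taylor_wall_transfer)
        if self.jm is not None and not (2 <= self.jm <= ny - 2):
            raise ValueError("membrane_index must leave >= 2 cells per layer")
        self.meta = dict(meta or {})

        zc = np.zeros(nx, dtype=complex)
        zf = np.zeros(nx + 1, dtype=complex)
        self.vhat_top = zc.copy() if vhat_top is None else np.asarray(vhat_top, complex)
        self.vhat_bottom = zc.copy() if vhat_bottom is None else np.asarray(vhat_bottom, complex)
        self.vhat_mem = (
            zc.copy() if vhat_membrane is None else np.asarray(vhat_membrane, complex)
        )
        self.uhat_top = zf.copy() if uhat_top is None else np.asarray(uhat_top, complex)
        self.uhat_bottom = zf.copy() if uhat_bottom is None else np.asarray(uhat_bottom, complex)

        # closed box: prescribed normal flux through the outer boundary must
        # integrate to zero at every instant; project the waving wall onto
        # zero mean (complex, so it holds at all phases).
        if enforce_compatibility:
            imbalance = np.mean(self.vhat_top) - np.mean(self.vhat_bottom)
            scale = max(np.max(np.abs(self.vhat_top)), np.max(np.abs(self.vhat_bottom)), 0.0)
            if scale > 0 and abs(imbalance) > 0.5 * scale:
                raise ValueError(
                    "wall motion volume imbalance too large to project out "
                    f"(|mean|/max = {abs(imbalance) / scale:.2f})"
                )
            if np.max(np.abs(self.vhat_top)) > 0:
                self.vhat_top = self.vhat_top - imbalance
            elif np.max(np.abs(self.vhat_bottom)) > 0:
                self.vhat_bottom = self.vhat_bottom + imbalance

        # resolution checks
        period = 2.0 * np.pi / omega
        dt = numerics.dt_s if numerics.dt_s is not None else period / 100.0
        self.n_per = max(int(round(period / dt)), numerics.min_steps_per_period)
        self.dt = period / self.n_per
        delta = np.sqrt(fluid.nu_m2_s / omega)
        if delta / dy < numerics.min_stokes_layer_cells:
            raise ValueError(
                f"grid does not resolve the Stokes layer: delta/dy = {delta / dy:.2f} "
                f"< {numerics.min_stokes_layer_cells}"
            )

        # normal wall-displacement amplitudes (for the Taylor slip term),
        # interpolated to the u-face x positions
        def _to_faces(d):
            if self.periodic_x:
                f = 0.5 * (d + np.roll(d, 1))
                return np.concatenate([f, f[:1]])
            inner = 0.5 * (d[:-1] + d[1:])
            return np.concatenate([d[:1], inner, d[-1:]])

        iw = -1j * omega
        self.dhat_bottom_f = _to_faces(self.vhat_bottom / iw)
        self.dhat_top_f = _to_faces(self.vhat_top / iw)
        self.dhat_mem_f = _to_faces(self.vhat_mem / iw)
        if self.taylor:
            eta_max = max(
                np.max(np.abs(self.dhat_bottom_f)),
                np.max(np.abs(self.dhat_top_f)),
                np.max(np.abs(self.dhat_mem_f)),
            )
            if eta_max > 0.5 * dy:
                raise ValueError(
                    "Taylor wall transfer requires wall displacement small "
                    f"compared to the wall-adjacent cell (max eta {eta_max:.2e} m "
                    f"> 0.5*dy = {0.5 * dy:.2e} m); refine dy or disable the transfer"
                )
            min_cells = 3
            segs = np.diff(self._wall_faces())
            if np.any(segs < min_cells):
                raise ValueError(
                    "Taylor wall transfer needs >= 3 cells per layer for the "
                    "one-sided wall gradients"
                )
        # wall-gradient state for the slip term (updated every step)
        zfr = np.zeros(nx + 1)
        self._grad = {k: zfr.copy() for k in ("b", "t", "ml", "mh")}

        self._build_operators()

    # -- operator assembly ---------------------------------------------------
    def _wall_faces(self):
        walls = [0, self.ny]
        if self.jm is not None:
            walls.insert(1, self.jm)
        return walls

    def _build_operators(self):
        nx, ny, dx, dy = self.nx, self.ny, self.dx, self.dy
        nu, rho = self.fluid.nu_m2_s, self.fluid.rho_kg_m3
        dt = self.dt
        walls = self._wall_faces()
        per = self.periodic_x
        # number of x-positions carrying u unknowns: every face is unknown in
        # the periodic case (face nx duplicates face 0); interior faces only
        # between rigid end walls.
        self.nux = nx if per else nx - 1

        def _circulant(n):
            T = _tridiag(n, 1.0, -2.0, 1.0).tolil()
            T[0, n - 1] += 1.0
            T[n - 1, 0] += 1.0
            return T.tocsr()

        # ---- u Laplacian: tangential ghost walls at every y wall face.
        if per:
            Tx_u = _circulant(nx) / dx**2
        else:
            Tx_u = _tridiag(nx - 1, 1.0, -2.0, 1.0) / dx**2
        Ty_blocks = []
        for a, b in zip(walls[:-1], walls[1:]):
            m = b - a
            T = _tridiag(m, 1.0, -2.0, 1.0).tolil()
            T[0, 0] = -3.0   # ghost reflection across the wall face below
            T[m - 1, m - 1] = -3.0
            Ty_blocks.append(T.tocsr())
        Ty_u = sp.block_diag(Ty_blocks, format="csr") / dy**2
        self.Lu = sp.kron(Tx_u, sp.identity(ny), format="csr") + sp.kron(
            sp.identity(self.nux), Ty_u, format="csr"
        )

        # ---- v Laplacian: unknown faces j in (walls excluded) interior.
        self.jv = np.array([j for j in range(1, ny) if j not in walls], dtype=int)
        nyv = len(self.jv)
        if per:
            Tx_v = _circulant(nx) / dx**2
        else:
            Tx_v = _tridiag(nx, 1.0, -2.0, 1.0).tolil()
            Tx_v[0, 0] = -3.0        # no-slip ghost at the rigid end walls
            Tx_v[nx - 1, nx - 1] = -3.0
            Tx_v = Tx_v.tocsr() / dx**2
        # y part: per segment between wall faces, interior faces with Dirichlet
        # neighbors at segment-end faces (those neighbors go to the bc vector)
        Ty_v_blocks = []
        for a, b in zip(walls[:-1], walls[1:]):
            m = b - a - 1  # interior faces strictly between the wall faces
            if m > 0:
                Ty_v_blocks.append(_tridiag(m, 1.0, -2.0, 1.0))
        Ty_v = sp.block_diag(Ty_v_blocks, format="csr") / dy**2
        self.Lv = sp.kron(Tx_v, sp.identity(nyv), format="csr") + sp.kron(
            sp.identity(nx), Ty_v, format="csr"
        )

        c = 0.5 * nu * dt
        self.Au = (sp.identity(self.nux * ny, format="csr") - c * self.Lu).tocsc()
        self.Av = (sp.identity(nx * nyv, format="csr") - c * self.Lv).tocsc()
        self.Au_lu = spla.splu(self.Au)
        self.Av_lu = spla.splu(self.Av)

        # ---- pressure Poisson with membrane conductance
        wy = np.full(ny - 1, dt / (rho * dy))  # conductance of y-face j+1
        if self.jm is not None:
            wy[self.jm - 1] = self.fluid.K_m_per_s_pa
        Ay = sp.lil_matrix((ny, ny))
        for j in range(ny - 1):
            w = wy[j] / dy
            Ay[j, j + 1] += w
            Ay[j + 1, j] += w
            Ay[j, j] -= w
            Ay[j + 1, j + 1] -= w
        wx = dt / (rho * dx**2)
        Ax = sp.lil_matrix((nx, nx))
        for i in range(nx - 1):
            Ax[i, i + 1] += wx
            Ax[i + 1, i] += wx
            Ax[i, i] -= wx
            Ax[i + 1, i + 1] -= wx
        if per:
            Ax[0, nx - 1] += wx
            Ax[nx - 1, 0] += wx
            Ax[0, 0] -= wx
            Ax[nx - 1, nx - 1] -= wx
        M = sp.kron(sp.identity(nx), Ay.tocsr(), format="csr") + sp.kron(
            Ax.tocsr(), sp.identity(ny), format="csr"
        )
        M = M.tolil()
        M[0, :] = 0.0
        M[0, 0] = 1.0  # pin the pressure gauge
        self.Mp_lu = spla.splu(M.tocsc())

    # -- time-dependent boundary data ---------------------------------------
    def _wave(self, amp, t):
        return np.real(amp * np.exp(-1j * self.omega * t))

    def _update_wall_gradients(self, u_full, t):
        """One-sided du/dy estimates at each wall line, from interior cells only.

        Using interior values keeps the slip update free of direct
        self-feedback through the wall ghost (stable for eta << dy-adjacent
        cell, which is validated at construction).
        """
        if not self.taylor:
            return
        dy, jm = self.dy, self.jm
        new = {
            "b": (-2 * u_full[:, 0] + 3 * u_full[:, 1] - u_full[:, 2]) / dy,
            "t": (2 * u_full[:, -1] - 3 * u_full[:, -2] + u_full[:, -3]) / dy,
        }
        if jm is not None:
            new["ml"] = (2 * u_full[:, jm - 1] - 3 * u_full[:, jm - 2] + u_full[:, jm - 3]) / dy
            new["mh"] = (-2 * u_full[:, jm] + 3 * u_full[:, jm + 1] - u_full[:, jm + 2]) / dy
        a = self.num.slip_filter_alpha
        for key, val in new.items():
            self._grad[key] = (1.0 - a) * self._grad[key] + a * val

    def _u_wall_values(self, t):
        """Tangential fluid velocity on each wall line (prescribed + slip)."""
        ub = self._wave(self.uhat_bottom, t)
        ut = self._wave(self.uhat_top, t)
        uml = np.zeros(self.nx + 1)
        umh = np.zeros(self.nx + 1)
        if self.taylor:
            ub = ub - self._wave(self.dhat_bottom_f, t) * self._grad["b"]
            ut = ut - self._wave(self.dhat_top_f, t) * self._grad["t"]
            if self.jm is not None:
                eta_m = self._wave(self.dhat_mem_f, t)
                uml = -eta_m * self._grad["ml"]
                umh = -eta_m * self._grad["mh"]
        return {"b": ub, "t": ut, "ml": uml, "mh": umh}

    def _v_boundary(self, t, dp_mem):
        """Prescribed v at bottom/top/membrane faces at time t."""
        vb = self._wave(self.vhat_bottom, t)
        vt = self._wave(self.vhat_top, t)
        if self.jm is None:
            return vb, vt, None
        vm = self._wave(self.vhat_mem, t) - self.fluid.K_m_per_s_pa * dp_mem
        return vb, vt, vm

    def _fill_v_full(self, v_unknown, t, dp_mem):
        nx, ny = self.nx, self.ny
        v_full = np.zeros((nx, ny + 1))
        v_full[:, self.jv] = v_unknown
        vb, vt, vm = self._v_boundary(t, dp_mem)
        v_full[:, 0] = vb
        v_full[:, ny] = vt
        if self.jm is not None:
            v_full[:, self.jm] = vm
        return v_full

    def _advection(self, u_full, v_full, t):
        nx, ny, dx, dy = self.nx, self.ny, self.dx, self.dy
        jm = self.jm
        uw = self._u_wall_values(t)
        ub, ut = uw["b"], uw["t"]

        # wall-normal derivative of u with tangential ghosts at every wall face
        u_ext = np.empty((nx + 1, ny + 2))
        u_ext[:, 1:-1] = u_full
        u_ext[:, 0] = 2 * ub - u_full[:, 0]
        u_ext[:, -1] = 2 * ut - u_full[:, -1]
        dudy = (u_ext[:, 2:] - u_ext[:, :-2]) / (2 * dy)
        if jm is not None:  # membrane is a tangential wall between layers
            dudy[:, jm - 1] = (2 * uw["ml"] - u_full[:, jm - 1] - u_full[:, jm - 2]) / (2 * dy)
            dudy[:, jm] = (u_full[:, jm + 1] + u_full[:, jm] - 2 * uw["mh"]) / (2 * dy)
        vc = 0.5 * (v_full[:, :-1] + v_full[:, 1:])  # v at cell centers

        if self.periodic_x:
            up = u_full[:-1, :]  # unique faces 0..nx-1
            dudx = (np.roll(up, -1, axis=0) - np.roll(up, 1, axis=0)) / (2 * dx)
            v_at_u = 0.5 * (np.roll(vc, 1, axis=0) + vc)
            adv_u = up * dudx + v_at_u * dudy[:-1, :]
        else:
            dudx = (u_full[2:, :] - u_full[:-2, :]) / (2 * dx)
            v_at_u = 0.5 * (vc[:-1, :] + vc[1:, :])
            adv_u = u_full[1:-1, :] * dudx + v_at_u * dudy[1:-1, :]

        # v advection at interior faces j=1..ny-1
        dvdy = (v_full[:, 2:] - v_full[:, :-2]) / (2 * dy)
        if self.periodic_x:
            dvdx = (np.roll(v_full, -1, axis=0) - np.roll(v_full, 1, axis=0)) / (2 * dx)
        else:
            v_ext = np.empty((nx + 2, ny + 1))
            v_ext[1:-1] = v_full
            v_ext[0] = -v_full[0]
            v_ext[-1] = -v_full[-1]
            dvdx = (v_ext[2:, :] - v_ext[:-2, :]) / (2 * dx)
        uc = 0.5 * (u_full[:-1, :] + u_full[1:, :])  # u at cell centers
        u_at_v = 0.5 * (uc[:, :-1] + uc[:, 1:])      # at interior v faces
        adv_v = u_at_v * dvdx[:, 1:ny] + v_full[:, 1:ny] * dvdy
        adv_v = adv_v[:, self.jv - 1]
        return adv_u, adv_v

    def _bc_vec_u(self, t):
        ny, dy = self.ny, self.dy
        bc = np.zeros((self.nux, ny))
        uw = self._u_wall_values(t)
        sel = slice(0, -1) if self.periodic_x else slice(1, -1)
        bc[:, 0] += 2.0 * uw["b"][sel] / dy**2
        bc[:, ny - 1] += 2.0 * uw["t"][sel] / dy**2
        if self.jm is not None:
            bc[:, self.jm - 1] += 2.0 * uw["ml"][sel] / dy**2
            bc[:, self.jm] += 2.0 * uw["mh"][sel] / dy**2
        return bc

    def _bc_vec_v(self, t, dp_mem):
        nx, ny, dy = self.nx, self.ny, self.dy
        vb, vt, vm = self._v_boundary(t, dp_mem)
        bc = np.zeros((nx, ny + 1))
        bc[:, 1] += vb / dy**2
        bc[:, ny - 1] += vt / dy**2
        if self.jm is not None:
            bc[:, self.jm - 1] += vm / dy**2
            bc[:, self.jm + 1] += vm / dy**2
        return bc[:, self.jv]

    # -- main loop -----------------------------------------------------------
    def run(self, u0=None, v0=None, p0=None) -> PeriodicFlowSolution:
        nx, ny, dx, dy = self.nx, self.ny, self.dx, self.dy
        nu, rho, K = self.fluid.nu_m2_s, self.fluid.rho_kg_m3, self.fluid.K_m_per_s_pa
        dt, n_per, jm = self.dt, self.n_per, self.jm
        c = 0.5 * nu * dt

        u_full = np.zeros((nx + 1, ny)) if u0 is None else np.array(u0, dtype=float)
        p = np.zeros((nx, ny)) if p0 is None else np.array(p0, dtype=float)
        if v0 is None:
            v_unk = np.zeros((nx, len(self.jv)))
        else:
            v_unk = np.array(v0, dtype=float)[:, self.jv]
        dp_mem = (
            (p[:, jm] - p[:, jm - 1]) if jm is not None else np.zeros(nx)
        )

        adv_prev = None
        residuals = []
        snapshot_prev = None
        t = 0.0
        converged = False
        store = False
        samples = {"u": [], "v": [], "p": [], "t": [], "up": [], "vt": [], "vm": []}

        step_total = 0
        for period in range(1, self.num.max_periods + 2):
            for _ in range(n_per):
                t_new = t + dt
                v_full = self._fill_v_full(v_unk, t, dp_mem)
                self._update_wall_gradients(u_full, t)
                if self.num.include_advection:
                    adv_u, adv_v = self._advection(u_full, v_full, t)
                else:
                    adv_u = np.zeros((self.nux, ny))
                    adv_v = np.zeros((nx, len(self.jv)))
                if adv_prev is None:
                    adv_u_ex, adv_v_ex = adv_u, adv_v
                else:
                    adv_u_ex = 1.5 * adv_u - 0.5 * adv_prev[0]
                    adv_v_ex = 1.5 * adv_v - 0.5 * adv_prev[1]
                adv_prev = (adv_u, adv_v)

                # momentum predictor (Crank-Nicolson viscous)
                if self.periodic_x:
                    gpx = (p - np.roll(p, 1, axis=0)) / dx  # faces 0..nx-1
                    u_int = u_full[:-1, :]
                else:
                    gpx = (p[1:, :] - p[:-1, :]) / dx
                    u_int = u_full[1:-1, :]
                rhs_u = (
                    u_int
                    + dt * (-adv_u_ex - gpx / rho)
                    + c * (self.Lu @ u_int.ravel()).reshape(self.nux, ny)
                    + c * (self._bc_vec_u(t) + self._bc_vec_u(t_new))
                )
                u_star = self.Au_lu.solve(rhs_u.ravel()).reshape(self.nux, ny)

                gpy = (p[:, 1:] - p[:, :-1]) / dy
                rhs_v = (
                    v_unk
                    + dt * (-adv_v_ex - gpy[:, self.jv - 1] / rho)
                    + c * (self.Lv @ v_unk.ravel()).reshape(nx, len(self.jv))
                    + c * (self._bc_vec_v(t, dp_mem) + self._bc_vec_v(t_new, dp_mem))
                )
                v_star_unk = self.Av_lu.solve(rhs_v.ravel()).reshape(nx, len(self.jv))

                u_star_full = np.zeros((nx + 1, ny))
                if self.periodic_x:
                    u_star_full[:-1, :] = u_star
                    u_star_full[-1, :] = u_star[0, :]
                else:
                    u_star_full[1:-1, :] = u_star
                v_star_full = self._fill_v_full(v_star_unk, t_new, dp_mem)

                # projection
                div = (
                    np.diff(u_star_full, axis=0) / dx
                    + np.diff(v_star_full, axis=1) / dy
                )
                rhs_p = div.ravel()
                rhs_p[0] = 0.0
                phi = self.Mp_lu.solve(rhs_p).reshape(nx, ny)

                u_full = u_star_full.copy()
                if self.periodic_x:
                    u_full[:-1, :] -= dt / (rho * dx) * (phi - np.roll(phi, 1, axis=0))
                    u_full[-1, :] = u_full[0, :]
                else:
                    u_full[1:-1, :] -= dt / (rho * dx) * (phi[1:, :] - phi[:-1, :])
                v_new_full = v_star_full.copy()
                dphiy = np.diff(phi, axis=1) / dy
                for col, j in enumerate(self.jv):
                    v_new_full[:, j] -= dt / rho * dphiy[:, j - 1]
                if jm is not None:
                    v_new_full[:, jm] -= K * (phi[:, jm] - phi[:, jm - 1])
                p = p + phi
                if jm is not None:
                    dp_mem = p[:, jm] - p[:, jm - 1]
                v_unk = v_new_full[:, self.jv]

                t = t_new
                step_total += 1
                if store:
                    vb, vt, vm = self._v_boundary(t, dp_mem)
                    samples["u"].append(u_full.copy())
                    samples["v"].append(v_new_full.copy())
                    samples["p"].append(p.copy())
                    samples["t"].append(t)
                    samples["vt"].append(vt)
                    if jm is not None:
                        samples["vm"].append(self._wave(self.vhat_mem, t))
                        samples["up"].append(v_new_full[:, jm] - self._wave(self.vhat_mem, t))

            if store:
                break
            snap = np.concatenate([u_full.ravel(), v_unk.ravel()])
            if snapshot_prev is not None:
                denom = max(np.linalg.norm(snap), 1e-300)
                res = np.linalg.norm(snap - snapshot_prev) / denom
                residuals.append(res)
                if period >= self.num.min_periods and res < self.num.periodicity_tol:
                    converged = True
                    store = True  # record the next (final) period
            snapshot_prev = snap
            if period == self.num.max_periods and not converged:
                raise FlowConvergenceError(
                    f"flow not periodic after {self.num.max_periods} periods "
                    f"(last residual {residuals[-1] if residuals else np.nan:.3e}, "
                    f"tol {self.num.periodicity_tol:.1e})",
                    residuals,
                )

        return PeriodicFlowSolution(
            x_faces=np.arange(nx + 1) * dx,
            y_faces=np.arange(ny + 1) * dy,
            membrane_index=jm,
            omega=self.omega,
            dt=dt,
            t_samples=np.array(samples["t"]),
            u=np.array(samples["u"]),
            v=np.array(samples["v"]),
            p=np.array(samples["p"]),
            membrane_exchange=np.array(samples["up"]) if jm is not None else None,
            wall_velocity_top=np.array(samples["vt"]),
            wall_velocity_membrane=np.array(samples["vm"]) if jm is not None else None,
            residual_history=residuals,
            periodicity_residual=residuals[-1] if residuals else np.inf,
            fluid=self.fluid,
            meta=self.meta,
        )


# ---------------------------------------------------------------------------
# cochlea front end and drift post-processing
# ---------------------------------------------------------------------------

def solve_oscillatory_flow(
    geom: CochlearGeometry,
    wave: TravelingWaveField,
    fluid: FluidProps | None = None,
    numerics: FlowNumerics | None = None,
) -> PeriodicFlowSolution:
    """Run the two-layer cochlear flow driven by a traveling-wave field."""
    fluid = fluid or FluidProps()
    numerics = numerics or FlowNumerics()
    xc = geom.x_centers
    vhat_mem = -1j * wave.omega * wave.complex_amplitude("bottom", xc)
    vhat_top = -1j * wave.omega * wave.complex_amplitude("top", xc)
    solver = OscChannelSolver(
        nx=geom.nx,
        ny=geom.ny,
        dx=geom.dx,
        dy=geom.dy,
        omega=wave.omega,
        fluid=fluid,
        numerics=numerics,
        membrane_index=geom.membrane_index,
        vhat_top=vhat_top,
        vhat_membrane=vhat_mem,
        meta={
            "x_peak_m": wave.x_peak_m,
            "ohc_active": wave.ohc_active,
            "stimulus_omega": wave.omega,
        },
    )
    return solver.run()


def compute_drift(sol: PeriodicFlowSolution, tol: float = 1e-2) -> DriftField:
    """Average the Eulerian velocity over the stored period at fixed positions."""
    if not np.isfinite(sol.periodicity_residual) or sol.periodicity_residual > tol:
        raise ValueError(
            f"solution is not periodic (residual {sol.periodicity_residual:.3e} "
            f"> {tol:.1e})"
        )
    return DriftField(
        x_faces=sol.x_faces,
        y_faces=sol.y_faces,
        membrane_index=sol.membrane_index,
        u=sol.u.mean(axis=0),
        v=sol.v.mean(axis=0),
        omega=sol.omega,
        peak_oscillatory_speed=sol.peak_oscillatory_speed(),
        meta=dict(sol.meta),
    )


def cross_section_flux(drift: DriftField, x_m: float, layer: str = "both") -> float:
    """Axial volume flux per unit width [m^2/s] through the section at ``x_m``.

    Positive toward the apex.  ``layer`` selects the Corti duct rows, the
    scala-tympani rows, or the whole section.
    """
    if not 0.0 < x_m < drift.length_m:
        raise ValueError(f"x={x_m!r} outside the open domain (0, {drift.length_m})")
    i = int(round(x_m / drift.dx))
    i = min(max(i, 0), drift.u.shape[0] - 1)
    jm = drift.membrane_index
    if layer == "both" or jm is None:
        rows = slice(None)
    elif layer == "corti":
        rows = slice(jm, None)
    elif layer == "scala":
        rows = slice(0, jm)
    else:
        raise ValueError(f"unknown layer {layer!r}")
    return float(np.sum(drift.u[i, rows]) * drift.dy)


def _interp_mac(u, v, x_faces, y_faces, x, y):
    """Bilinear interpolation of MAC velocities at point(s) (x, y)."""
    dx = x_faces[1] - x_faces[0]
    dy = y_faces[1] - y_faces[0]
    nxp1, ny = u.shape
    # u: nodes at (i*dx, (j+0.5)*dy)
    gx = np.clip(x / dx, 0, nxp1 - 1 - 1e-12)
    gy = np.clip(y / dy - 0.5, 0, ny - 1 - 1e-12)
    i0, j0 = gx.astype(int), gy.astype(int)
    fx, fy = gx - i0, gy - j0
    ui = (
        u[i0, j0] * (1 - fx) * (1 - fy)
        + u[i0 + 1, j0] * fx * (1 - fy)
        + u[i0, j0 + 1] * (1 - fx) * fy
        + u[i0 + 1, j0 + 1] * fx * fy
    )
    nx, nyp1 = v.shape
    gx = np.clip(x / dx - 0.5, 0, nx - 1 - 1e-12)
    gy = np.clip(y / dy, 0, nyp1 - 1 - 1e-12)
    i0, j0 = gx.astype(int), gy.astype(int)
    fx, fy = gx - i0, gy - j0
    vi = (
        v[i0, j0] * (1 - fx) * (1 - fy)
        + v[i0 + 1, j0] * fx * (1 - fy)
        + v[i0, j0 + 1] * (1 - fx) * fy
        + v[i0 + 1, j0 + 1] * fx * fy
    )
    return ui, vi


def trace_particles(sol: PeriodicFlowSolution, seeds, n_periods: int):
    """RK4 passive-tracer advection through the time-periodic Eulerian field.

    Returns ``(trajectories, mean_drift_velocity, truncated)``:
    trajectories has shape (n_seeds, n_steps+1, 2); mean_drift_velocity is the
    net displacement per period divided by the period (Lagrangian mean);
    ``truncated`` flags particles that reached the domain boundary.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n_samp = sol.u.shape[0]
    dt = sol.dt
    Lx, Ly = sol.x_faces[-1], sol.y_faces[-1]

    def vel(pos, t):
        s = (t / dt) % n_samp
        s0 = int(np.floor(s)) % n_samp
        s1 = (s0 + 1) % n_samp
        f = s - np.floor(s)
        u0, v0 = _interp_mac(sol.u[s0], sol.v[s0], sol.x_faces, sol.y_faces,
                             pos[:, 0], pos[:, 1])
        u1, v1 = _interp_mac(sol.u[s1], sol.v[s1], sol.x_faces, sol.y_faces,
                             pos[:, 0], pos[:, 1])
        return np.stack([(1 - f) * u0 + f * u1, (1 - f) * v0 + f * v1], axis=1)

    n_steps = n_periods * n_samp
    traj = np.empty((len(seeds), n_steps + 1, 2))
    traj[:, 0] = seeds
    pos = seeds.copy()
    truncated = np.zeros(len(seeds), dtype=bool)
    t = 0.0
    for s in range(n_steps):
        k1 = vel(pos, t)
        k2 = vel(pos + 0.5 * dt * k1, t + 0.5 * dt)
        k3 = vel(pos + 0.5 * dt * k2, t + 0.5 * dt)
        k4 = vel(pos + dt * k3, t + dt)
        pos = pos + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out = (pos[:, 0] <= 0) | (pos[:, 0] >= Lx) | (pos[:, 1] <= 0) | (pos[:, 1] >= Ly)
        truncated |= out
        pos[:, 0] = np.clip(pos[:, 0], 0.0, Lx)
        pos[:, 1] = np.clip(pos[:, 1], 0.0, Ly)
        traj[:, s + 1] = pos
        t += dt
    period = n_samp * dt
    mean_drift = (traj[:, -1] - traj[:, 0]) / (n_periods * period)
    return traj, mean_drift, truncated
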