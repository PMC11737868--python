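"""Closed-form oscillatory-flow benchmarks, independent of the 2-D solver.

These are the validation oracles for the flow stage:

* :func:`stokes_layer_velocity` -- Stokes' second problem: the velocity above
  a wall oscillating in its own plane,
  ``u = U0 * exp(-y/delta) * cos(omega t - y/delta)`` with
  ``delta = sqrt(2 nu / omega)``.

* :func:`lubrication_mean_flow` -- second-order steady streaming in a
  long-wave channel whose bottom wall's *normal* velocity is a small
  traveling wave, with the wall motion transferred to the fixed mean
  boundary (the same linearization the 2-D solver uses).  The first-order
  oscillatory flow is solved in closed form at arbitrary Womersley number;
  the period-averaged Reynolds stress then forces a steady Stokes problem in
  ``y`` whose mean pressure gradient is fixed by a net-flux constraint.
  Everything here is 1-D complex quadrature: no code is shared with the
  Navier-Stokes solver.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = ["stokes_layer_velocity", "lubrication_mean_flow"]


def stokes_layer_velocity(y, t, U0, nu, omega):
    """Half-space velocity over a wall oscillating tangentially as U0*cos(omega t)."""
    y = np.asarray(y, dtype=float)
    delta = np.sqrt(2.0 * nu / omega)
    return U0 * np.exp(-y / delta) * np.cos(omega * np.asarray(t) - y / delta)


def _first_order_channel(y, h, nu, rho, omega, k, v_amp):
    """Closed-form long-wave oscillatory flow for bottom-wall normal forcing.

    Wall normal velocity: Re[v_amp * exp(i(kx - omega t))] at y=0, rigid top.
    Returns complex profiles (u_hat, v_hat, du_hat/dy) on the grid ``y``.
    """
    lam = np.sqrt(omega / nu) * np.exp(-1j * np.pi / 4.0)  # lam^2 = -i omega/nu
    sh = np.sinh(lam * h)
    f = (np.sinh(lam * (h - y)) + np.sinh(lam * y)) / sh
    int_f = (np.cosh(lam * h) - np.cosh(lam * (h - y)) + np.cosh(lam * y) - 1.0) / (
        lam * sh
    )
    g = (2.0 / (lam * h)) * np.tanh(lam * h / 2.0)
    u_c = v_amp / (1j * k * h * (1.0 - g))
    u_hat = u_c * (1.0 - f)
    v_hat = v_amp - 1j * k * u_c * (y - int_f)
    dfdy = lam * (-np.cosh(lam * (h - y)) + np.cosh(lam * y)) / sh
    du_hat = -u_c * dfdy
    return u_hat, v_hat, du_hat


def lubrication_mean_flow(
    h: float,
    nu: float,
    rho: float,
    omega: float,
    k: float,
    wall_amp_m: float,
    n_y: int = 4001,
    constraint: str = "zero_gradient",
    taylor_slip: bool = True,
):
    """Second-order Eulerian mean velocity profile <u>(y) of the wavy channel.

    ``wall_amp_m`` is the bottom-wall displacement amplitude ``a``; the wall's
    normal velocity amplitude is ``-i*omega*a``.  Returns ``(y, u_mean)``.

    ``constraint`` closes the second-order problem: ``"zero_gradient"`` (an
    x-periodic channel, where the single-valued pressure forbids a mean axial
    gradient and the pump runs at its free-pumping flux) or ``"zero_flux"``
    (a closed channel, where a mean gradient G builds up to cancel the net
    flux).

    ``taylor_slip`` adds the second-order mean slip at the waving wall,
    ``<u>(0) = -<eta * du1/dy>``, i.e. the no-slip condition carried from the
    displaced wall to the mean position; disable it to describe a solver that
    pins the tangential velocity at the mean boundary line.
    """
    y = np.linspace(0.0, h, n_y)
    v_amp = -1j * omega * wall_amp_m
    u_hat, v_hat, du_hat = _first_order_channel(y, h, nu, rho, omega, k, v_amp)

    # period-averaged advective force <(u.grad)u>_x; the u*du/dx part has zero
    # mean for a single traveling mode, leaving <v1 * du1/dy>
    F = 0.5 * np.real(v_hat * np.conj(du_hat))

    # mean slip at the waving wall: <u>(0) = -<eta du1/dy>|0
    slip = -0.5 * np.real(wall_amp_m * np.conj(du_hat[0])) if taylor_slip else 0.0

    # nu * u2'' = G/rho + F;  u2(0) = slip, u2(h) = 0
    S1 = cumulative_trapezoid(F, y, initial=0.0)
    S2 = cumulative_trapezoid(S1, y, initial=0.0)
    # u2 = slip + (G/(2 rho nu)) y^2 + S2/nu + beta*y
    if constraint == "zero_gradient":
        G = 0.0
        beta = -(slip + S2[-1] / nu) / h
    elif constraint == "zero_flux":
        int_S2 = np.trapezoid(S2, y)
        A = np.array(
            [
                [h**2 / (2.0 * rho * nu), h],
                [h**3 / (6.0 * rho * nu), h**2 / 2.0],
            ]
        )
        b = np.array([-slip - S2[-1] / nu, -slip * h - int_S2 / nu])
        G, beta = np.linalg.solve(A, b)
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    u_mean = slip + (G / (2.0 * rho * nu)) * y**2 + S2 / nu + beta * y
    return y, u_mean
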