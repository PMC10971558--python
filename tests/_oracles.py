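"""Independent reference solutions used as test oracles.

Everything here is implemented directly from closed forms or brute-force
discretisations, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def oneil_axial_amplitude(frequency, aperture_diameter, focal_length, z,
                          sound_speed=1482.0):
    """Closed-form on-axis |p| of a uniformly driven spherical cap
    (O'Neil-type solution), normalised to unit surface pressure.

    |p(z)| = (F/|F−z|)·|2 sin(k(R_rim(z) − z)/2)|, with the removable
    singularity at the centre of curvature equal to k·h (h = cap depth).
    """
    z = np.asarray(z, dtype=np.float64)
    k = 2 * np.pi * frequency / sound_speed
    F = focal_length
    a = aperture_diameter / 2
    h = F - np.sqrt(F**2 - a**2)
    cos_t = 1 - h / F
    r_rim = np.sqrt(F**2 + (z - F) ** 2 + 2 * F * (z - F) * cos_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = (F / np.abs(F - z)) * np.abs(2 * np.sin(k * (r_rim - z) / 2))
    return np.where(np.abs(F - z) > 1e-12, amp, k * h)


def relay_duty_cycle(heat_rate, gamma, t_arterial, lower, upper):
    """Analytic relay oscillation for dT/dt = q·on − γ(T − Ta).

    Returns (t_on, t_off, duty) of the steady limit cycle between the
    lower and upper switching thresholds; requires q/γ + Ta > upper.
    """
    q_over_g = heat_rate / gamma
    if q_over_g + t_arterial <= upper:
        raise ValueError("heating too weak to reach the upper threshold")
    t_on = (1 / gamma) * np.log(
        (q_over_g - (lower - t_arterial)) / (q_over_g - (upper - t_arterial))
    )
    t_off = (1 / gamma) * np.log((upper - t_arterial) / (lower - t_arterial))
    return t_on, t_off, t_on / (t_on + t_off)


def reference_relay(trace, lower, upper, initial_on=True):
    """Plain two-state machine over a temperature trace; returns the state
    after each observation."""
    state = initial_on
    out = []
    for t in trace:
        if state and t > upper:
            state = False
        elif not state and t < lower:
            state = True
        out.append(state)
    return out


def ftcs_1d(T0, k_cells, rho_c_cells, dx, dt, n_steps):
    """Brute-force 1-D explicit conduction solver, insulated ends.

    Harmonic-mean face conductivity; written independently of the package
    stencil. Returns the final cell-centre temperatures.
    """
    T = np.asarray(T0, dtype=np.float64).copy()
    k = np.asarray(k_cells, dtype=np.float64)
    rc = np.asarray(rho_c_cells, dtype=np.float64)
    kf = 2 * k[:-1] * k[1:] / (k[:-1] + k[1:])
    for _ in range(n_steps):
        flux = kf * (T[1:] - T[:-1]) / dx  # flux into cell i from i+1 side
        div = np.zeros_like(T)
        div[:-1] += flux
        div[1:] -= flux
        T = T + dt * div / (rc * dx)
    return T
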