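"""Independent reference computations used to validate the implementation.

These deliberately avoid the package's analytic code paths: the cylinder
attenuation is obtained by simulating a random walk with reflecting walls,
and the Rician mean by direct numerical quadrature of the density.
"""

import numpy as np
from scipy.integrate import quad

from axdiam.scheme import GAMMA_PROTON


def mc_cylinder_attenuation(
    diameter, d_intra, g_mT_m, small_delta, big_delta, n_particles=100_000, dt=0.05, seed=0
):
    """Monte-Carlo echo attenuation perpendicular to a reflecting cylinder.

    2-D random walk in a disc of the given diameter (um), diffusivity in
    um^2/ms, rectangular gradient pulses of amplitude ``g_mT_m``; the phase
    is integrated at the midpoint of each step.
    """
    r = diameter / 2.0
    rng = np.random.default_rng(seed)
    u = rng.random(n_particles)
    th = rng.random(n_particles) * 2 * np.pi
    x = r * np.sqrt(u) * np.cos(th)
    y = r * np.sqrt(u) * np.sin(th)
    n_steps = int(round((big_delta + small_delta) / dt))
    step = np.sqrt(2 * d_intra * dt)
    gamma_g = GAMMA_PROTON * 1e-9 * g_mT_m  # rad/(ms um)
    phase = np.zeros(n_particles)
    for i in range(n_steps):
        t = (i + 0.5) * dt
        x += rng.normal(0.0, step, n_particles)
        y += rng.normal(0.0, step, n_particles)
        rad2 = x * x + y * y
        out = rad2 > r * r
        if out.any():
            rad = np.sqrt(rad2[out])
            new_rad = np.clip(2 * r - rad, 0.0, r)
            scale = new_rad / rad
            x[out] *= scale
            y[out] *= scale
        if t < small_delta:
            phase += gamma_g * x * dt
        elif big_delta < t < big_delta + small_delta:
            phase -= gamma_g * x * dt
    return float(np.abs(np.mean(np.exp(1j * phase))))


def rician_mean_quadrature(nu, sigma):
    """Mean of the Rician density by direct integration."""

    def integrand(x):
        return (
            x
            * x
            / sigma**2
            * np.exp(-(x**2 + nu**2) / (2 * sigma**2))
            * np.i0(x * nu / sigma**2)
        )

    upper = nu + 12 * sigma
    val, _ = quad(integrand, 0.0, upper, limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def bh_stepup_reference(p_values, alpha):
    """Hand-executed Benjamini-Hochberg step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        reject[order[: kmax + 1]] = True
    return reject
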