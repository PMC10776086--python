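"""Voxelwise cascade estimation of the axon-diameter model.

The fit proceeds in stages, each conditioning the next:

1. DTI on the lowest-b shell at the shortest diffusion time gives FA and the
   principal direction(s) used to initialize orientations.
2. A CHARMED-style fit on the shortest-Delta data (axons as zero-radius
   sticks) estimates orientations, restricted fractions, the intra-axonal
   axial diffusivity and the extra-axonal axial diffusivity; orientations and
   the axial diffusivities are then frozen.
3. Stage A ("tortuosity-constrained"): the full multi-Delta model is fitted
   for {lambda, fractions, slope, s0, sigma, (T1)} with the extra-axonal
   radial diffusivity at the shortest Delta pinned to the tortuosity value
   d_extra_axial * (1 - f) / (1 + f).
4. Stage B ("released"): everything is frozen at stage-A values except the
   extra-axonal radial diffusivity at the shortest Delta and the noise term,
   which are refitted jointly.

The objective throughout is least squares between the measured magnitude and
the analytic Rician expectation of the noise-free model, with the noise sd
sigma a free parameter — this keeps the estimator consistent near the noise
floor where plain Gaussian least squares is biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammaln

from .scheme import GAMMA_PROTON, STEAM, AcquisitionScheme
from .signal import (
    VoxelParams,
    gpd_sum,
    rician_expected_magnitude,
    t1_decay,
)

LINEAR = "linear"
NONLINEAR = "nonlinear"
MONO = "mono"
BI = "bi"


# -- DTI ------------------------------------------------------------------------


@dataclass
class DtiFit:
    eigenvalues: np.ndarray  # descending, um^2/ms
    fa: float
    principal_dir: np.ndarray
    tensor: np.ndarray
    s0: float


def fractional_anisotropy(eigenvalues) -> float:
    ev = np.asarray(eigenvalues, dtype=float)
    md = ev.mean()
    denom = np.sum(ev**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(1.5 * np.sum((ev - md) ** 2) / denom))


def fit_dti(signals, scheme: AcquisitionScheme) -> DtiFit:
    """Log-linear least-squares tensor fit.

    Expects the caller to have restricted the scheme to the shortest Delta and
    the lowest nonzero b shell plus b0s (see ``AcquisitionScheme.dti_subset_mask``).
    """
    y = np.asarray(signals, dtype=float)
    if y.shape[0] != scheme.n_meas:
        raise ValueError("signal length does not match scheme")
    if scheme.n_meas < 7:
        raise ValueError("tensor fit needs at least 7 measurements")
    g = scheme.bvecs
    b = scheme.bvals
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    logy = np.log(np.clip(y, 1e-12, None))
    coef, *_ = np.linalg.lstsq(X, logy, rcond=None)
    D = np.array(
        [
            [coef[1], coef[4], coef[5]],
            [coef[4], coef[2], coef[6]],
            [coef[5], coef[6], coef[3]],
        ]
    )
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pdir = _canonical_direction(evecs[:, 0])
    return DtiFit(evals, fractional_anisotropy(np.clip(evals, 0, None)), pdir, D, float(np.exp(coef[0])))


def _canonical_direction(u):
    """Fix the antipodal sign: positive z hemisphere, ties to positive x."""
    u = np.asarray(u, dtype=float)
    if u[2] < 0 or (u[2] == 0 and u[0] < 0):
        u = -u
    return u


# -- tortuosity -----------------------------------------------------------------


def tortuosity_radial(d_extra_axial, f_total):
    """Tortuosity approximation for the extra-axonal radial diffusivity."""
    f_total = np.asarray(f_total, dtype=float)
    if np.any(f_total < 0) or np.any(f_total >= 1):
        raise ValueError("f_total must be in [0, 1)")
    out = d_extra_axial * (1.0 - f_total) / (1.0 + f_total)
    return float(out) if out.ndim == 0 else out


# -- CHARMED stage ---------------------------------------------------------------


@dataclass
class CharmedFit:
    orientations: np.ndarray  # (n_pop, 3)
    fractions: np.ndarray
    d_intra_axial: float
    d_extra_axial: float
    s0: float
    sigma: float
    converged: bool
    n_iter: int
    loss: float


def _sph_to_unit(theta, phi):
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def _unit_to_sph(u):
    return float(np.arccos(np.clip(u[2], -1, 1))), float(np.arctan2(u[1], u[0]))


def fit_charmed(
    signals,
    scheme: AcquisitionScheme,
    n_pop: int = 1,
    init_dirs=None,
    max_nfev: int = 500,
) -> CharmedFit:
    """Composite hindered-and-restricted (stick) fit at the shortest Delta.

    The caller passes the shortest-Delta subset of the data.  Restricted
    populations are modelled as zero-radius sticks; the hindered radial
    diffusivity is pinned to the tortuosity value during this stage.
    """
    if n_pop not in (1, 2):
        raise ValueError("n_pop must be 1 or 2")
    y = np.asarray(signals, dtype=float)
    if init_dirs is None:
        dmask = scheme.dti_subset_mask()
        dti = fit_dti(y[dmask], scheme.subset(dmask))
        init_dirs = [dti.principal_dir]
        if n_pop == 2:
            # second direction: eigenvector of the second eigenvalue
            w, v = np.linalg.eigh(dti.tensor)
            init_dirs.append(_canonical_direction(v[:, np.argsort(w)[::-1][1]]))
    init_dirs = np.atleast_2d(np.asarray(init_dirs, dtype=float))[:n_pop]

    b = scheme.bvals
    bvecs = scheme.bvecs
    s0_init = float(np.mean(y[scheme.b0_mask]))
    tm_fac = np.ones(scheme.n_meas)  # T1 decay common to all compartments cancels
    # into s0 within a single-Delta subset, so it is not modelled here

    def unpack(x):
        if n_pop == 1:
            th, ph, f1, da, dea, s0, sig = x
            dirs = np.array([_sph_to_unit(th, ph)])
            fr = np.array([f1])
        else:
            th1, ph1, th2, ph2, ftot, wsplit, da, dea, s0, sig = x
            dirs = np.array([_sph_to_unit(th1, ph1), _sph_to_unit(th2, ph2)])
            fr = np.array([ftot * wsplit, ftot * (1 - wsplit)])
        return dirs, fr, da, dea, s0, sig

    def model(x):
        dirs, fr, da, dea, s0, sig = unpack(x)
        ftot = fr.sum()
        cos2 = (bvecs @ dirs.T) ** 2  # (M, n_pop)
        restricted = np.exp(-b[:, None] * da * cos2)
        d_perp = tortuosity_radial(dea, min(ftot, 0.999))
        if n_pop == 1:
            cos2_h = cos2[:, 0]
        else:
            dyad = np.einsum("i,ij,ik->jk", fr, dirs, dirs)
            u = np.linalg.eigh(dyad)[1][:, -1]
            cos2_h = (bvecs @ u) ** 2
        hindered = np.exp(-b * (d_perp + (dea - d_perp) * cos2_h))
        return s0 * (restricted @ fr + (1 - ftot) * hindered) * tm_fac, sig

    def resid(x):
        nu, sig = model(x)
        return rician_expected_magnitude(np.clip(nu, 0, None), sig) - y

    th0, ph0 = _unit_to_sph(init_dirs[0])
    smax = max(float(y.max()), 1e-6)
    if n_pop == 1:
        x0 = [th0, ph0, 0.3, 1.2, 1.2, s0_init, 0.05 * s0_init + 1e-6]
        lo = [th0 - 1.5, ph0 - 1.5, 0.0, 0.1, 0.1, 1e-6, 1e-8]
        hi = [th0 + 1.5, ph0 + 1.5, 0.9, 3.0, 3.0, 2 * smax, smax]
    else:
        th1, ph1 = th0, ph0
        th2, ph2 = _unit_to_sph(init_dirs[1] if len(init_dirs) > 1 else init_dirs[0])
        x0 = [th1, ph1, th2, ph2, 0.3, 0.5, 1.2, 1.2, s0_init, 0.05 * s0_init + 1e-6]
        lo = [th1 - 1.5, ph1 - 1.5, th2 - 1.5, ph2 - 1.5, 0.0, 0.0, 0.1, 0.1, 1e-6, 1e-8]
        hi = [th1 + 1.5, ph1 + 1.5, th2 + 1.5, ph2 + 1.5, 0.9, 1.0, 3.0, 3.0, 2 * smax, smax]
    res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=max_nfev, xtol=1e-10, ftol=1e-10)
    dirs, fr, da, dea, s0, sig = unpack(res.x)
    converged = res.status > 0
    if not converged:
        # DTI-based fallback keeps the cascade going on pathological voxels
        dmask = scheme.dti_subset_mask()
        dti = fit_dti(y[dmask], scheme.subset(dmask))
        dirs = init_dirs[:n_pop]
        fr = np.full(n_pop, 0.3 / n_pop)
        da = float(np.clip(dti.eigenvalues[0], 0.1, 3.0))
        dea = da
        s0, sig = dti.s0, 0.05 * dti.s0
    dirs = np.array([_canonical_direction(u) for u in dirs])
    return CharmedFit(
        dirs, fr, float(da), float(dea), float(s0), float(sig), converged, res.nfev, 2 * res.cost
    )


# -- AxCaliber cascade -----------------------------------------------------------


@dataclass
class AxCaliberOptions:
    """Knobs of the AxCaliber stages.

    ``lambda_bounds`` stop at 6 um: beyond that the 10-um grid truncates more
    Poisson mass than the distribution's own tolerance allows and the
    perpendicular signal is saturated, so larger values are never
    interpretable.  ``diameter_scale`` is the proxy-grid-to-kernel mapping
    (see `axdiam.signal.DIAMETER_SCALE`).  ``fit_d_intra`` frees the
    intra-axonal axial diffusivity in stage A (with the extra-axonal axial
    tied to it) instead of keeping the CHARMED estimate fixed.
    """

    grid_step: float = 1.0  # um
    truncation: float = 10.0  # um
    weighting: str = "count"
    diameter_scale: float = 2.0
    lambda_bounds: tuple = (0.1, 6.0)
    fraction_max: float = 0.9
    slope_bounds: tuple = (-0.02, 0.02)  # um^2/ms per ms
    diffusivity_max: float = 3.0
    multistart_lambda: tuple = (1.0, 2.5, 4.0)
    delta_model: str = LINEAR
    fit_d_intra: bool = False
    max_nfev: int = 500
    ftol: float = 1e-8
    fit_t1: bool = True
    t1_bounds: tuple = (100.0, 5000.0)
    t1_init: float = 1500.0


@dataclass
class FitResult:
    params: VoxelParams
    stage_params: dict
    loss: float
    loss_tortuosity: float
    converged: bool
    n_iter: dict
    bic_linear: float | None = None
    bic_nonlinear: float | None = None
    bic_t1_mono: float | None = None
    bic_t1_bi: float | None = None


class _VoxelModel:
    """Per-voxel precomputation shared by all objective evaluations.

    Orientations are fixed, so each population's perpendicular gradient
    component is a constant vector.  When the intra-axonal diffusivity is
    also fixed, the restricted attenuation is linear in the
    diameter-distribution weights through a precomputed (n_meas, n_bins)
    matrix; when it is free, the GPD series factor is linearly interpolated
    from a table precomputed on a diffusivity grid.
    """

    _DA_NODES = np.linspace(0.05, 3.05, 61)
    _C_NODE_CACHE: dict = {}

    def __init__(self, scheme: AcquisitionScheme, init: CharmedFit, opts: AxCaliberOptions,
                 free_d_intra: bool | None = None):
        self.scheme = scheme
        self.opts = opts
        self.init = init
        self.n_pop = init.fractions.shape[0]
        self.is_steam = scheme.sequence == STEAM
        self.delta_min = scheme.delta_min
        self.free_d_intra = opts.fit_d_intra if free_d_intra is None else free_d_intra
        k = np.arange(int(np.floor(opts.truncation / opts.grid_step)) + 1)
        self.k = k
        self.dgrid = k * opts.grid_step
        self.lgamma_k1 = gammaln(k + 1)
        if opts.weighting == "volume":
            self.bin_weight_extra = self.dgrid**2
        else:
            self.bin_weight_extra = None

        timing = np.column_stack([scheme.small_delta, scheme.big_delta])
        self._uniq_timing, self._timing_idx = np.unique(timing, axis=0, return_inverse=True)
        kernel_diam = opts.diameter_scale * self.dgrid
        if self.free_d_intra:
            # C(da) interpolation table: (n_nodes, n_uniq_timings, n_bins);
            # independent of orientation, so cached per scheme timing layout
            key = (
                self._uniq_timing.tobytes(),
                opts.grid_step,
                opts.truncation,
                opts.diameter_scale,
            )
            if key not in self._C_NODE_CACHE:
                self._C_NODE_CACHE[key] = np.stack(
                    [
                        gpd_sum(kernel_diam, da, self._uniq_timing[:, 0], self._uniq_timing[:, 1])
                        for da in self._DA_NODES
                    ]
                )
            self._C_nodes = self._C_NODE_CACHE[key]
        else:
            self._C_fixed = gpd_sum(
                kernel_diam, init.d_intra_axial,
                self._uniq_timing[:, 0], self._uniq_timing[:, 1],
            )[self._timing_idx]

        b = scheme.bvals
        g = scheme.gradient_strength
        self.cos2 = []  # squared cosine to each population axis, (M,)
        self.gg2 = []  # squared perpendicular gamma*g, (M, 1)
        self.restricted_fixed = []  # (M, K) when d_intra fixed
        for u in init.orientations:
            cosang = scheme.bvecs @ u
            gg = GAMMA_PROTON * 1e-9 * g * np.sqrt(np.clip(1 - cosang**2, 0, 1))
            self.cos2.append(cosang**2)
            self.gg2.append(gg[:, None] ** 2)
            if not self.free_d_intra:
                axial = np.exp(-b * init.d_intra_axial * cosang**2)
                R = axial[:, None] * np.exp(-2.0 * self.gg2[-1] * self._C_fixed)
                R[scheme.b0_mask] = 1.0
                self.restricted_fixed.append(R)
        # hindered geometry fixed at the init fractions (exact for n_pop=1)
        if self.n_pop == 1:
            u_h = init.orientations[0]
        else:
            fr = np.clip(init.fractions, 1e-6, None)
            dyad = np.einsum("i,ij,ik->jk", fr, init.orientations, init.orientations)
            u_h = np.linalg.eigh(dyad)[1][:, -1]
        self.cos2_h = (scheme.bvecs @ u_h) ** 2
        self.ddelta = scheme.big_delta - self.delta_min
        # structural-disorder shape for the nonlinear Delta model, anchored at Delta_min
        h = np.log(scheme.big_delta / scheme.small_delta) / scheme.big_delta
        at_min = scheme.shortest_delta_mask()
        self.h_shape = h - h[at_min].mean()
        self.tm = scheme.mixing_time

    def diameter_weights(self, lam):
        mu = lam / self.opts.grid_step
        w = np.exp(self.k * np.log(mu) - mu - self.lgamma_k1)
        if self.bin_weight_extra is not None:
            w = w * self.bin_weight_extra
        return w / w.sum()

    def _C_at(self, da):
        nodes = self._DA_NODES
        i = int(np.clip(np.searchsorted(nodes, da) - 1, 0, nodes.size - 2))
        t = (da - nodes[i]) / (nodes[i + 1] - nodes[i])
        t = min(max(t, 0.0), 1.0)
        return ((1 - t) * self._C_nodes[i] + t * self._C_nodes[i + 1])[self._timing_idx]

    def restricted_signal(self, pop, w, da=None):
        if da is None or not self.free_d_intra:
            return self.restricted_fixed[pop] @ w
        C = self._C_at(da)
        perp = np.exp(-2.0 * self.gg2[pop] * C) @ w
        out = np.exp(-self.scheme.bvals * da * self.cos2[pop]) * perp
        out[self.scheme.b0_mask] = 1.0
        return out

    def predict(self, lam, fractions, d_perp_min, slope, s0, t1=np.inf, da=None, dea=None):
        """Noise-free magnitude given current stage parameters."""
        w = self.diameter_weights(lam)
        ftot = fractions.sum()
        sig = np.zeros(self.scheme.n_meas)
        for i, f in enumerate(fractions):
            sig += f * self.restricted_signal(i, w, da)
        if self.opts.delta_model == LINEAR:
            d_perp = d_perp_min + slope * self.ddelta
        else:
            d_perp = d_perp_min + slope * self.h_shape
        d_perp = np.clip(d_perp, 0.0, None)
        if dea is None:
            dea = self.init.d_extra_axial if da is None else da
        hindered = np.exp(-self.scheme.bvals * (d_perp + (dea - d_perp) * self.cos2_h))
        sig += (1 - ftot) * hindered
        sig *= s0
        if self.is_steam and np.isfinite(t1):
            sig = sig * np.exp(-self.tm / t1)
        return sig


def _rician_resid(nu, sigma, y):
    return rician_expected_magnitude(np.clip(nu, 0.0, None), sigma) - y


def fit_axcaliber(
    signals,
    scheme: AcquisitionScheme,
    init: CharmedFit,
    options: AxCaliberOptions | None = None,
) -> FitResult:
    """Two-stage AxCaliber fit conditioned on a CHARMED initialization.

    Stage A frees {lambda, fractions, slope, s0, sigma, (T1 for STEAM)} with
    the shortest-Delta extra-axonal radial diffusivity tied to the tortuosity
    approximation of the *current* fraction; stage B releases that constraint
    and refits {d_extra_radial_min, sigma} with everything else frozen.
    """
    opts = options or AxCaliberOptions()
    y = np.asarray(signals, dtype=float)
    model = _VoxelModel(scheme, init, opts)
    n_pop = model.n_pop
    fit_t1 = opts.fit_t1 and model.is_steam
    dea = init.d_extra_axial
    smax = max(float(y.max()), 1e-6)

    # ---- stage A ----
    free_da = opts.fit_d_intra

    def unpack_a(x):
        lam = x[0]
        if n_pop == 1:
            fr = np.array([x[1]])
            rest = list(x[2:])
        else:
            fr = np.array([x[1] * x[2], x[1] * (1 - x[2])])
            rest = list(x[3:])
        slope, s0, sigma = rest[:3]
        rest = rest[3:]
        da = rest.pop(0) if free_da else None
        t1 = rest.pop(0) if fit_t1 else np.inf
        return lam, fr, slope, s0, sigma, da, t1

    def resid_a(x):
        lam, fr, slope, s0, sigma, da, t1 = unpack_a(x)
        d_perp_min = tortuosity_radial(dea if da is None else da, min(fr.sum(), 0.999))
        nu = model.predict(lam, fr, d_perp_min, slope, s0, t1, da=da)
        return _rician_resid(nu, sigma, y)

    f0 = float(np.clip(init.fractions.sum(), 0.05, opts.fraction_max))
    sig0 = float(np.clip(init.sigma, 1e-6, smax))
    if n_pop == 1:
        base = [f0]
        lo = [0.0]
        hi = [opts.fraction_max]
    else:
        w0 = float(init.fractions[0] / max(init.fractions.sum(), 1e-9))
        base = [f0, w0]
        lo = [0.0, 0.0]
        hi = [opts.fraction_max, 1.0]
    slope_lo, slope_hi = opts.slope_bounds
    base += [0.0, init.s0, sig0]
    lo += [slope_lo, 1e-6, 1e-8]
    hi += [slope_hi, 2 * smax, smax]
    if free_da:
        base += [float(np.clip(init.d_intra_axial, 0.2, opts.diffusivity_max - 0.1))]
        lo += [0.1]
        hi += [opts.diffusivity_max]
    if fit_t1:
        base += [opts.t1_init]
        lo += [opts.t1_bounds[0]]
        hi += [opts.t1_bounds[1]]

    best = None
    n_iter_a = 0
    for lam0 in opts.multistart_lambda:
        x0 = np.array([np.clip(lam0, *opts.lambda_bounds)] + base)
        res = least_squares(
            resid_a,
            x0,
            bounds=(np.array([opts.lambda_bounds[0]] + lo), np.array([opts.lambda_bounds[1]] + hi)),
            max_nfev=opts.max_nfev,
            ftol=opts.ftol,
            xtol=1e-10,
        )
        n_iter_a += res.nfev
        if best is None or res.cost < best.cost:
            best = res
    lam_a, fr_a, slope_a, s0_a, sigma_a, da_a, t1_a = unpack_a(best.x)
    if da_a is not None:
        dea = da_a
    d_perp_min_a = tortuosity_radial(dea, min(fr_a.sum(), 0.999))
    loss_a = 2 * best.cost

    # ---- stage B: release the tortuosity constraint ----
    def resid_b(x):
        d_perp_min, sigma = x
        nu = model.predict(lam_a, fr_a, d_perp_min, slope_a, s0_a, t1_a, da=da_a)
        return _rician_resid(nu, sigma, y)

    res_b = least_squares(
        resid_b,
        np.array([d_perp_min_a, sigma_a]),
        bounds=(np.array([0.0, 1e-8]), np.array([opts.diffusivity_max, smax])),
        max_nfev=opts.max_nfev,
        ftol=opts.ftol,
        xtol=1e-12,
    )
    d_perp_min_b, sigma_b = res_b.x
    loss_b = 2 * res_b.cost
    if loss_b > loss_a * (1 + 1e-6):  # releasing a constraint cannot worsen the fit
        d_perp_min_b, sigma_b, loss_b = d_perp_min_a, sigma_a, loss_a

    def mkparams(d_perp_min, sigma):
        return VoxelParams(
            orientations=init.orientations,
            fractions=fr_a,
            d_intra_axial=init.d_intra_axial if da_a is None else float(da_a),
            d_extra_radial_min=float(d_perp_min),
            slope=float(slope_a),
            d_extra_axial=dea,
            lambda_poisson=float(lam_a),
            sigma_rician=float(sigma),
            s0=float(s0_a),
            t1=float(t1_a),
        )

    return FitResult(
        params=mkparams(d_perp_min_b, sigma_b),
        stage_params={
            "tortuosity": mkparams(d_perp_min_a, sigma_a),
            "released": mkparams(d_perp_min_b, sigma_b),
        },
        loss=float(loss_b),
        loss_tortuosity=float(loss_a),
        converged=bool(best.status > 0 and res_b.status > 0),
        n_iter={"stage_a": int(n_iter_a), "stage_b": int(res_b.nfev)},
    )


def fit_voxel(
    signals,
    scheme: AcquisitionScheme,
    n_pop: int = 1,
    options: AxCaliberOptions | None = None,
) -> FitResult:
    """Full cascade on one voxel: DTI -> CHARMED (shortest Delta) -> AxCaliber."""
    y = np.asarray(signals, dtype=float)
    at_min = scheme.shortest_delta_mask()
    charmed = fit_charmed(y[at_min], scheme.subset(at_min), n_pop=n_pop)
    result = fit_axcaliber(y, scheme, charmed, options)
    result.stage_params["charmed"] = charmed
    return result


def fit_diameter_conditioned(
    signals,
    scheme: AcquisitionScheme,
    orientation,
    fraction: float,
    options: AxCaliberOptions | None = None,
    sigma_init: float = 0.05,
    d_intra_bounds: tuple | None = None,
):
    """Diameter fit conditioned on the geometry stages of the cascade.

    The fiber orientation and restricted volume fraction are supplied (they
    are determined by the DTI/CHARMED stages in the full pipeline) and
    {lambda, D_a (extra-axonal axial tied to it), slope, s0, sigma, T1 for
    STEAM} are estimated jointly; the extra-axonal radial diffusivity at the
    shortest Delta follows the tortuosity approximation of the supplied
    fraction.  This is the estimator exercised by the parameter-recovery
    simulations, where the joint identifiability of diameter and fraction
    from a single noisy repetition is not the question being asked.

    ``d_intra_bounds`` restricts the axial-diffusivity search to an assumed
    plausible range (the recovery experiment passes its sampling range, so a
    narrower assumed diffusivity scenario tightens the diameter estimate).

    Returns (lambda_hat, info dict).
    """
    opts = options or AxCaliberOptions()
    y = np.asarray(signals, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    init = CharmedFit(
        orientation.reshape(1, 3), np.array([fraction]), 1.4, 1.4,
        float(np.mean(y[scheme.b0_mask])), sigma_init, True, 0, 0.0,
    )
    model = _VoxelModel(scheme, init, opts, free_d_intra=True)
    fit_t1 = opts.fit_t1 and scheme.sequence == STEAM
    fr = np.array([fraction])
    smax = max(float(y.max()), 1e-6)

    def resid(x):
        lam, da, slope, s0, sigma = x[:5]
        t1 = x[5] if fit_t1 else np.inf
        d_perp_min = tortuosity_radial(da, min(fraction, 0.999))
        nu = model.predict(lam, fr, d_perp_min, slope, s0, t1, da=da, dea=da)
        return _rician_resid(nu, sigma, y)

    da_lo, da_hi = d_intra_bounds or (0.1, opts.diffusivity_max)
    lo = [opts.lambda_bounds[0], da_lo, opts.slope_bounds[0], 1e-6, 1e-8]
    hi = [opts.lambda_bounds[1], da_hi, opts.slope_bounds[1], 2 * smax, smax]
    if fit_t1:
        lo += [opts.t1_bounds[0]]
        hi += [opts.t1_bounds[1]]
    best = None
    for lam0 in opts.multistart_lambda:
        x0 = [np.clip(lam0, *opts.lambda_bounds), 0.5 * (da_lo + da_hi), 0.0, init.s0, sigma_init]
        if fit_t1:
            x0 += [opts.t1_init]
        res = least_squares(
            resid, np.array(x0), bounds=(np.array(lo), np.array(hi)),
            max_nfev=opts.max_nfev, ftol=opts.ftol, xtol=1e-8,
        )
        if best is None or res.cost < best.cost:
            best = res
    out = {
        "lambda": float(best.x[0]),
        "d_intra_axial": float(best.x[1]),
        "slope": float(best.x[2]),
        "s0": float(best.x[3]),
        "sigma": float(best.x[4]),
        "t1": float(best.x[5]) if fit_t1 else np.inf,
        "loss": float(2 * best.cost),
        "converged": bool(best.status > 0),
    }
    return out["lambda"], out


def fit_axcaliber_joint(
    signals,
    scheme: AcquisitionScheme,
    orientation,
    options: AxCaliberOptions | None = None,
    sigma_init: float = 0.05,
):
    """Single-stage joint fit with a known fiber orientation.

    Frees {lambda, fraction, D_a (extra-axonal axial tied), slope, s0,
    sigma, T1 for STEAM} with the tortuosity pin on the current fraction.
    Used for tract-profile extraction where tractography supplies the
    orientation and the per-position average signal is fitted directly.

    Returns (lambda_hat, info dict).
    """
    opts = options or AxCaliberOptions()
    y = np.asarray(signals, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    init = CharmedFit(
        orientation.reshape(1, 3), np.array([0.3]), 1.4, 1.4,
        float(np.mean(y[scheme.b0_mask])), sigma_init, True, 0, 0.0,
    )
    model = _VoxelModel(scheme, init, opts, free_d_intra=True)
    fit_t1 = opts.fit_t1 and scheme.sequence == STEAM
    smax = max(float(y.max()), 1e-6)

    def resid(x):
        lam, f, da, slope, s0, sigma = x[:6]
        t1 = x[6] if fit_t1 else np.inf
        d_perp_min = tortuosity_radial(da, min(f, 0.999))
        nu = model.predict(lam, np.array([f]), d_perp_min, slope, s0, t1, da=da, dea=da)
        return _rician_resid(nu, sigma, y)

    lo = [opts.lambda_bounds[0], 0.0, 0.1, opts.slope_bounds[0], 1e-6, 1e-8]
    hi = [opts.lambda_bounds[1], opts.fraction_max, opts.diffusivity_max,
          opts.slope_bounds[1], 2 * smax, smax]
    if fit_t1:
        lo += [opts.t1_bounds[0]]
        hi += [opts.t1_bounds[1]]
    best = None
    for lam0 in opts.multistart_lambda:
        x0 = [np.clip(lam0, *opts.lambda_bounds), 0.3, 1.4, 0.0, init.s0, sigma_init]
        if fit_t1:
            x0 += [opts.t1_init]
        res = least_squares(
            resid, np.array(x0), bounds=(np.array(lo), np.array(hi)),
            max_nfev=opts.max_nfev, ftol=opts.ftol, xtol=1e-8,
        )
        if best is None or res.cost < best.cost:
            best = res
    info = {
        "lambda": float(best.x[0]),
        "fraction": float(best.x[1]),
        "d_intra_axial": float(best.x[2]),
        "slope": float(best.x[3]),
        "s0": float(best.x[4]),
        "sigma": float(best.x[5]),
        "t1": float(best.x[6]) if fit_t1 else np.inf,
        "loss": float(2 * best.cost),
        "converged": bool(best.status > 0),
    }
    return info["lambda"], info


# -- information criteria and model selection -------------------------------------


def bic(log_likelihood, n_params, n_obs):
    """Bayesian information criterion k*ln(n) - 2*logL."""
    if n_obs <= n_params:
        raise ValueError("n_obs must exceed n_params")
    return n_params * np.log(n_obs) - 2.0 * log_likelihood


def gaussian_loglik(residuals, rss_floor=None):
    """Gaussian log-likelihood with the ML residual variance plugged in.

    ``rss_floor`` guards the degenerate perfect-fit case: two models that
    both fit to within the floor tie in log-likelihood, so criteria reduce
    to their parameter-count penalties.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    rss = max(float(r @ r), 1e-30 if rss_floor is None else rss_floor)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


def select_delta_model(signals, scheme: AcquisitionScheme, init: CharmedFit | None = None,
                       options: AxCaliberOptions | None = None):
    """BIC comparison of the linear Delta-dependence of the extra-axonal
    radial diffusivity against the structural-disorder form
    D(Delta) = D_inf + A ln(Delta/delta)/Delta (anchored at Delta_min).

    Returns (choice, {"linear": FitResult, "nonlinear": FitResult}); ties in
    BIC go to the linear model.
    """
    y = np.asarray(signals, dtype=float)
    if init is None:
        at_min = scheme.shortest_delta_mask()
        init = fit_charmed(y[at_min], scheme.subset(at_min))
    opts = options or AxCaliberOptions()
    results = {}
    bics = {}
    for form in (LINEAR, NONLINEAR):
        o = replace(opts, delta_model=form,
                    slope_bounds=opts.slope_bounds if form == LINEAR else (-2.0, 2.0))
        try:
            fit = fit_axcaliber(y, scheme, init, o)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"{form} Delta-model fit failed: {exc}", RuntimeWarning)
            results[form] = None
            bics[form] = np.inf
            continue
        k = 5 + (2 if init.fractions.shape[0] == 2 else 1) \
            + (1 if (opts.fit_t1 and scheme.sequence == STEAM) else 0)
        # k counts stage-A free params + the released radial diffusivity
        resid = _model_residuals(fit, y, scheme, init, o)
        fit_bic = bic(gaussian_loglik(resid), k, scheme.n_meas)
        results[form] = fit
        bics[form] = fit_bic
    results["linear"], results["nonlinear"] = results[LINEAR], results[NONLINEAR]
    if results[LINEAR] is not None:
        results[LINEAR].bic_linear = bics[LINEAR]
        results[LINEAR].bic_nonlinear = bics[NONLINEAR]
    choice = LINEAR if bics[LINEAR] <= bics[NONLINEAR] else NONLINEAR
    return choice, results


def _model_residuals(fit: FitResult, y, scheme, init, opts):
    model = _VoxelModel(scheme, init, opts)
    p = fit.params
    da = p.d_intra_axial if opts.fit_d_intra else None
    nu = model.predict(
        p.lambda_poisson, p.fractions, p.d_extra_radial_min, p.slope, p.s0, p.t1, da=da
    )
    return _rician_resid(nu, p.sigma_rician, y)


def select_t1_model(signals, scheme: AcquisitionScheme):
    """BIC comparison of mono- vs bi-exponential T1 decay over the mixing time.

    Uses the b0 measurements across distinct TM values; raises if fewer than
    three distinct TMs are present (the bi-exponential is then unidentifiable).
    """
    if scheme.sequence != STEAM:
        raise ValueError("T1 model selection requires a STEAM scheme")
    y = np.asarray(signals, dtype=float)[scheme.b0_mask]
    tm = scheme.mixing_time[scheme.b0_mask]
    if np.unique(tm).size < 3:
        raise ValueError("need at least 3 distinct mixing times")
    s0g = float(y.max())

    def mono_resid(x):
        return x[0] * np.exp(-tm / x[1]) - y

    def bi_resid(x):
        s0, w, t1a, t1b = x
        return s0 * (w * np.exp(-tm / t1a) + (1 - w) * np.exp(-tm / t1b)) - y

    mono = least_squares(mono_resid, [s0g, 1500.0], bounds=([1e-9, 10.0], [10 * s0g, 1e5]))
    bi = least_squares(
        bi_resid,
        [s0g, 0.7, 800.0, 2500.0],
        bounds=([1e-9, 0.0, 10.0, 10.0], [10 * s0g, 1.0, 1e5, 1e5]),
    )
    n = y.size
    floor = n * (1e-6 * s0g) ** 2
    bic_mono = bic(gaussian_loglik(mono.fun, floor), 2, n)
    bic_bi = bic(gaussian_loglik(bi.fun, floor), 4, n)
    choice = MONO if bic_mono <= bic_bi else BI
    return choice, {
        "mono": {"params": mono.x, "bic": bic_mono},
        "bi": {"params": bi.x, "bic": bic_bi},
    }


# -- volume-level fitting ---------------------------------------------------------

MAP_NAMES = (
    "lambda",
    "f_restricted",
    "d_intra_axial",
    "d_extra_radial_min",
    "slope",
    "d_extra_axial",
    "sigma",
    "s0",
    "loss",
)


def fit_volume(
    data,
    mask,
    scheme: AcquisitionScheme,
    n_pop: int = 1,
    options: AxCaliberOptions | None = None,
    n_jobs: int = 1,
):
    """Fit every voxel inside ``mask``; returns a dict of 3D parameter maps.

    Masked-out or degenerate voxels (all-zero, or mean b0 below the noise
    floor of the data) are NaN in the output.  Results do not depend on voxel
    visit order.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[:3] != mask.shape or data.shape[3] != scheme.n_meas:
        raise ValueError("data, mask and scheme shapes disagree")
    maps = {name: np.full(mask.shape, np.nan) for name in MAP_NAMES}
    maps["converged"] = np.full(mask.shape, np.nan)
    maps["fa"] = np.full(mask.shape, np.nan)
    coords = np.argwhere(mask)
    usable = []
    for c in coords:
        y = data[tuple(c)]
        if not np.any(y > 0) or np.mean(y[scheme.b0_mask]) <= 0:
            continue
        usable.append(c)

    dmask = scheme.dti_subset_mask()
    dti_scheme = scheme.subset(dmask)

    def run(c):
        y = data[tuple(c)]
        fit = fit_voxel(y, scheme, n_pop=n_pop, options=options)
        fa = fit_dti(y[dmask], dti_scheme).fa
        return fit, fa

    if n_jobs != 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=n_jobs)(delayed(run)(c) for c in usable)
    else:
        fits = [run(c) for c in usable]
    for c, (fit, fa) in zip(usable, fits):
        p = fit.params
        ix = tuple(c)
        maps["fa"][ix] = fa
        maps["lambda"][ix] = p.lambda_poisson
        maps["f_restricted"][ix] = p.f_total
        maps["d_intra_axial"][ix] = p.d_intra_axial
        maps["d_extra_radial_min"][ix] = p.d_extra_radial_min
        maps["slope"][ix] = p.slope
        maps["d_extra_axial"][ix] = p.d_extra_axial
        maps["sigma"][ix] = p.sigma_rician
        maps["s0"][ix] = p.s0
        maps["loss"][ix] = fit.loss
        maps["converged"][ix] = float(fit.converged)
    return maps
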