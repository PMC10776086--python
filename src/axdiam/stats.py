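"""Along-tract and summary statistics for diameter-proxy analyses.

Covers the statistical toolkit around the mapping pipeline: paired
comparisons of tract profiles between hemispheres with false-discovery-rate
control, background-noise SNR estimation of b0 images, gamma fits to axon
diameter histograms, multiplicative shrinkage compounding for histology
preparation, and recovery correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: sd of a Rayleigh variable in units of the underlying Gaussian sigma,
#: sqrt(2 - pi/2) ~= 0.6551; divides the background sd to recover sigma
RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))


@dataclass
class TractProfilePair:
    """Paired left/right diameter-proxy profiles along a tract.

    ``values_left``/``values_right`` have shape (n_subjects, n_positions);
    ``positions`` are indices along the antero-posterior axis measured from
    the injection point.
    """

    positions: np.ndarray
    values_left: np.ndarray
    values_right: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values_left = np.atleast_2d(np.asarray(self.values_left, dtype=float))
        self.values_right = np.atleast_2d(np.asarray(self.values_right, dtype=float))
        if self.values_left.shape != self.values_right.shape:
            raise ValueError("left/right profile shapes differ")
        if self.values_left.shape[1] != self.positions.size:
            raise ValueError("profile length does not match positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return self.values_left.shape[0]


def paired_t_test(a, b):
    """Two-sided paired t test; returns (t, dof, p).

    Zero-variance differences are handled explicitly: identical samples give
    (0, n-1, 1); a constant nonzero difference is degenerate and returns an
    infinite t with p = 0, flagged by the infinity itself.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def bh_fdr(p_values, alpha=0.05):
    """Benjamini-Hochberg step-up; returns (reject mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def tract_profile_compare(pair: TractProfilePair, alpha=0.05) -> dict:
    """Pointwise paired comparison of two hemisphere profiles with FDR.

    At every position a paired t test across subjects compares right vs left;
    the resulting p-values are BH-corrected.  A whole-tract comparison of the
    per-subject means is also reported.
    """
    if pair.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    stats = []
    for j in range(pair.positions.size):
        t, dof, p = paired_t_test(pair.values_right[:, j], pair.values_left[:, j])
        stats.append((t, dof, p))
    t_vals, dofs, p_vals = map(np.array, zip(*stats))
    reject, p_adj = bh_fdr(p_vals, alpha)
    mean_l = pair.values_left.mean(axis=1)
    mean_r = pair.values_right.mean(axis=1)
    t_glob, dof_glob, p_glob = paired_t_test(mean_r, mean_l)
    table = pd.DataFrame(
        {
            "position": pair.positions,
            "mean_left_um": pair.values_left.mean(axis=0),
            "mean_right_um": pair.values_right.mean(axis=0),
            "t": t_vals,
            "p": p_vals,
            "p_fdr": p_adj,
            "reject": reject,
        }
    )
    return {
        "table": table,
        "subject_mean_left": mean_l,
        "subject_mean_right": mean_r,
        "whole_tract": {"t": t_glob, "dof": dof_glob, "p": p_glob},
    }


def estimate_snr(b0_volumes, signal_mask, noise_region):
    """SNR of b0 images: mean signal over Rayleigh-corrected background sd.

    The background (signal-free) magnitude noise is Rayleigh distributed with
    sd 0.6551*sigma, so the underlying Gaussian sigma is the background sd
    divided by sqrt(2 - pi/2).
    """
    vols = np.asarray(b0_volumes, dtype=float)
    if vols.ndim == 3:
        vols = vols[..., None]
    signal_mask = np.asarray(signal_mask, dtype=bool)
    noise_region = np.asarray(noise_region, dtype=bool)
    if not signal_mask.any() or not noise_region.any():
        raise ValueError("signal mask and noise region must be non-empty")
    if np.any(signal_mask & noise_region):
        raise ValueError("signal mask and noise region overlap")
    mean_signal = float(vols[signal_mask].mean())
    noise_sd = float(vols[noise_region].std(ddof=1))
    if noise_sd == 0:
        return float(np.inf)
    sigma = noise_sd / RAYLEIGH_SD_FACTOR
    return mean_signal / sigma


def fit_gamma_histogram(diameters):
    """Maximum-likelihood gamma fit to an axon-diameter sample.

    Returns (shape, scale, pdf callable).  The MLE with free shape/scale (no
    location) matches the sample mean exactly: shape*scale == mean(data).
    """
    d = np.asarray(diameters, dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 diameters")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate constant sample")
    shape, loc, scale = sps.gamma.fit(d, floc=0)
    return float(shape), float(scale), lambda x: sps.gamma.pdf(x, shape, scale=scale)


def compound_shrinkage(fractions):
    """Total shrinkage from sequential preparation steps: 1 - prod(1 - s_i)."""
    fr = np.asarray(fractions, dtype=float)
    if np.any((fr < 0) | (fr >= 1)):
        raise ValueError("each shrinkage fraction must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - fr))


def format_shrinkage(fraction) -> str:
    """Render a shrinkage fraction as an integer percentage, e.g. '39%'."""
    return f"{round(fraction * 100):.0f}%"


def pearson_r(x, y):
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)
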