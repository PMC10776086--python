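"""Acquisition scheme container and sidecar-table I/O.

A multi-shell, multi-diffusion-time scheme is described per measurement by a
gradient direction, a b-value, the gradient separation Delta, the gradient
duration delta, and (for stimulated-echo sequences) the mixing time TM.

Internal units follow the microstructure-modelling convention:
length in um, time in ms, b-value in ms/um^2 (1 ms/um^2 = 1000 s/mm^2),
diffusivity in um^2/ms.  Gradient amplitudes are expressed in mT/m.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: proton gyromagnetic ratio, rad / (ms * T)
GAMMA_PROTON = 2.675e8 * 1e-3

#: b-values below this (ms/um^2) are treated as b0, i.e. 50 s/mm^2
B0_THRESHOLD = 0.05

PGSE = "PGSE"
STEAM = "STEAM"

_BDELTA_HEADER = "# bdelta v1: Delta_ms delta_ms TM_ms sequence"


def b_to_gradient_strength(bval, small_delta, big_delta):
    """Gradient amplitude (mT/m) for rectangular pulses.

    Inverts b = gamma^2 g^2 delta^2 (Delta - delta/3), with b in ms/um^2.
    gamma*g must come out in rad/(ms*um); 1 mT/m = 1e-9 T/um.
    """
    bval = np.asarray(bval, dtype=float)
    denom = (GAMMA_PROTON * 1e-9) ** 2 * small_delta**2 * (big_delta - small_delta / 3.0)
    return np.sqrt(np.maximum(bval, 0.0) / denom)


def gradient_strength_to_b(g_mT_m, small_delta, big_delta):
    """b-value (ms/um^2) of a rectangular PGSE pulse pair of amplitude g (mT/m)."""
    gg = GAMMA_PROTON * 1e-9 * np.asarray(g_mT_m, dtype=float)
    return gg**2 * small_delta**2 * (big_delta - small_delta / 3.0)


@dataclass
class AcquisitionScheme:
    """Per-measurement description of a diffusion acquisition.

    Parameters
    ----------
    bvals : (n,) array, ms/um^2
    bvecs : (n, 3) array, unit gradient directions in the image frame
        (arbitrary for b0 measurements).
    big_delta, small_delta : (n,) arrays, ms
    sequence : {"PGSE", "STEAM"}
    mixing_time : (n,) array, ms; zeros for PGSE.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    big_delta: np.ndarray
    small_delta: np.ndarray
    sequence: str = PGSE
    mixing_time: np.ndarray | None = None

    def __post_init__(self):
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.n_meas) and self.n_meas != 3:
            self.bvecs = self.bvecs.T
        self.big_delta = np.broadcast_to(
            np.asarray(self.big_delta, dtype=float), (self.n_meas,)
        ).copy()
        self.small_delta = np.broadcast_to(
            np.asarray(self.small_delta, dtype=float), (self.n_meas,)
        ).copy()
        if self.mixing_time is None:
            self.mixing_time = np.zeros(self.n_meas)
        else:
            self.mixing_time = np.broadcast_to(
                np.asarray(self.mixing_time, dtype=float), (self.n_meas,)
            ).copy()
        if self.sequence not in (PGSE, STEAM):
            raise ValueError(f"unknown sequence {self.sequence!r}")
        self.validate()

    # -- basic derived quantities -------------------------------------------------
    @property
    def n_meas(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def delta_min(self) -> float:
        """Shortest diffusion time Delta_MIN, anchor of the hindered slope term."""
        return float(self.big_delta.min())

    @property
    def gradient_strength(self) -> np.ndarray:
        """Per-measurement gradient amplitude in mT/m (0 for b0)."""
        return b_to_gradient_strength(self.bvals, self.small_delta, self.big_delta)

    def validate(self):
        if self.bvecs.shape != (self.n_meas, 3):
            raise ValueError(
                f"bvecs shape {self.bvecs.shape} does not match {self.n_meas} measurements"
            )
        dw = ~self.b0_mask
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        bad = np.nonzero(np.abs(norms - 1.0) > 1e-6)[0]
        if bad.size:
            idx = np.nonzero(dw)[0][bad[0]]
            raise ValueError(
                f"gradient direction at measurement {idx} is not unit-norm "
                f"(|g|={np.linalg.norm(self.bvecs[idx]):.6g})"
            )
        if np.any(self.small_delta >= self.big_delta):
            idx = int(np.argmax(self.small_delta >= self.big_delta))
            raise ValueError(f"small_delta >= big_delta at measurement {idx}")
        if not np.any(self.b0_mask):
            raise ValueError("scheme contains no b0 measurement")

    # -- subsetting ---------------------------------------------------------------
    def subset(self, index) -> "AcquisitionScheme":
        index = np.asarray(index)
        return AcquisitionScheme(
            self.bvals[index],
            self.bvecs[index],
            self.big_delta[index],
            self.small_delta[index],
            self.sequence,
            self.mixing_time[index],
        )

    def shortest_delta_mask(self) -> np.ndarray:
        return self.big_delta == self.delta_min

    def dti_subset_mask(self) -> np.ndarray:
        """Lowest Delta, lowest nonzero b shell, plus the b0s at that Delta."""
        at_min = self.shortest_delta_mask()
        dw = ~self.b0_mask
        if not np.any(at_min & dw):
            raise ValueError("no diffusion-weighted data at the shortest Delta")
        b_low = self.bvals[at_min & dw].min()
        shell = at_min & dw & np.isclose(self.bvals, b_low)
        return (at_min & self.b0_mask) | shell


# -- sidecar file I/O ------------------------------------------------------------


def read_scheme(path_bval, path_bvec, path_bdelta) -> AcquisitionScheme:
    """Read an FSL-dialect bval/bvec pair plus the bdelta timing table.

    bval is in s/mm^2 and converted to ms/um^2; bvec is 3 x N.  The bdelta
    table has one whitespace-delimited row per volume: Delta_ms delta_ms
    TM_ms sequence-tag; lines starting with ``#`` are comments.
    """
    bvals = np.loadtxt(path_bval, ndmin=1) / 1000.0
    bvecs = np.loadtxt(path_bvec)
    if bvecs.ndim == 1:
        bvecs = bvecs.reshape(3, -1)
    rows = []
    seqs = []
    with open(path_bdelta) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(
                    f"malformed bdelta row {len(rows)} in {path_bdelta}: {line!r}"
                )
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            seqs.append(parts[3].upper())
    if len(rows) != bvals.shape[0]:
        raise ValueError(
            f"bdelta table has {len(rows)} rows but bval lists {bvals.shape[0]} volumes"
        )
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"bvec has {bvecs.shape[1]} columns but bval lists {bvals.shape[0]} volumes"
        )
    if len(set(seqs)) > 1:
        raise ValueError("mixed sequence tags in bdelta table are not supported")
    timing = np.asarray(rows)
    return AcquisitionScheme(
        bvals, bvecs.T, timing[:, 0], timing[:, 1], seqs[0], timing[:, 2]
    )


def write_scheme(scheme: AcquisitionScheme, path_bval, path_bvec, path_bdelta):
    """Write scheme sidecars; round-trips bit-exactly through :func:`read_scheme`."""
    with open(path_bval, "w") as fh:
        fh.write(" ".join(f"{b * 1000.0:.17g}" for b in scheme.bvals) + "\n")
    with open(path_bvec, "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    with open(path_bdelta, "w") as fh:
        fh.write(_BDELTA_HEADER + "\n")
        for D, d, tm in zip(scheme.big_delta, scheme.small_delta, scheme.mixing_time):
            fh.write(f"{D:.17g} {d:.17g} {tm:.17g} {scheme.sequence}\n")


def scheme_paths(prefix) -> tuple[str, str, str]:
    prefix = os.fspath(prefix)
    return prefix + ".bval", prefix + ".bvec", prefix + ".bdelta"
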