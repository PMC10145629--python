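"""Eigenspace-projected MVDR (ESBM) direction-of-arrival estimation.

The radar must sit directly over the radial artery; the estimated arrival
angle of the reflected wave tells the wearer how to shift it.  Antennas 1
and 3 form a half-wavelength uniform linear array, so the bin-1 responses of
those two antennas are stacked as snapshots ``x`` and the 2x2 covariance
``R = E[x x^H]`` is scanned over a -40..+40 degree grid (1 degree steps).

For each grid angle the steering vector ``a(theta)_k = exp(-j pi k sin
theta)`` is projected onto the signal subspace ``A`` (the eigenvector of
``R``'s largest eigenvalue — a single target is assumed), the
minimum-variance weights are ``w = R^-1 a_proj / (a_proj^H R^-1 a_proj)``,
and the pseudospectrum value is ``w^H R w``.  The grid argmax is the DOA;
placement is acceptable when it falls inside +-10 degrees.

Sign convention: the range-FFT bin of a real cosine carries ``exp(+j psi)``
while the steering model assumes a phase lag across the array, so the
snapshots are conjugated (the negative-frequency image) before forming the
covariance.  A noiseless single-source covariance is rank-1, hence exactly
singular; a small diagonal loading (1e-6 of the mean eigenvalue) is added
before inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from radarbp.range_processing import range_fft
from radarbp.synthetic import RawFrameSet

__all__ = [
    "DoaScan",
    "covariance",
    "steering_vector",
    "esbm_scan",
    "estimate_doa",
    "PLACEMENT_WINDOW_DEG",
]

PLACEMENT_WINDOW_DEG = 10.0
DEFAULT_GRID = np.arange(-40.0, 41.0, 1.0)


@dataclass
class DoaScan:
    """Pseudospectrum over the angle grid and the resulting estimate."""

    angles_deg: np.ndarray
    psd: np.ndarray
    doa_deg: float = field(init=False)
    placement_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.psd.shape != self.angles_deg.shape:
            raise ValueError("psd and angle grid must have equal length")
        if not np.all(np.isfinite(self.psd)):
            raise ValueError("non-finite pseudospectrum")
        peak = self.psd.max()
        ties = np.flatnonzero(self.psd == peak)
        best = ties[np.argmin(np.abs(self.angles_deg[ties]))]
        self.doa_deg = float(self.angles_deg[best])
        self.placement_ok = abs(self.doa_deg) <= PLACEMENT_WINDOW_DEG


def covariance(snapshots: np.ndarray) -> np.ndarray:
    """Sample covariance ``R = (1/N) sum x x^H`` of [antenna, snapshot] data."""
    x = np.asarray(snapshots, dtype=complex)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("expected an [antenna, snapshot] matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite snapshots")
    return x @ x.conj().T / x.shape[1]


def steering_vector(angle_deg: float, m: int = 2) -> np.ndarray:
    """Half-wavelength ULA steering vector, element k = exp(-j pi k sin theta)."""
    if m < 1:
        raise ValueError("array size m must be >= 1")
    k = np.arange(m)
    return np.exp(-1j * np.pi * k * np.sin(np.deg2rad(angle_deg)))


def esbm_scan(R: np.ndarray, angles_deg: np.ndarray | None = None) -> DoaScan:
    """Scan the eigenspace-projected MVDR pseudospectrum over an angle grid."""
    R = np.asarray(R, dtype=complex)
    if angles_deg is None:
        angles_deg = DEFAULT_GRID
    angles_deg = np.asarray(angles_deg, dtype=float)
    m = R.shape[0]
    if R.shape != (m, m) or not np.allclose(R, R.conj().T, atol=1e-8 * max(1.0, np.abs(R).max())):
        raise ValueError("covariance must be a square Hermitian matrix")

    eigvals, eigvecs = np.linalg.eigh(R)
    A = eigvecs[:, [-1]]  # signal subspace: dominant eigenvector (one target)

    loading = 1e-6 * np.trace(R).real / m
    R_loaded = R + loading * np.eye(m)
    try:
        R_inv = np.linalg.inv(R_loaded)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance singular even after diagonal loading"
        ) from exc

    proj = A @ A.conj().T
    psd = np.empty(angles_deg.size)
    for idx, ang in enumerate(angles_deg):
        a = steering_vector(ang, m)
        a_proj = proj @ a
        # minimum-variance weights with the subspace-projected steering
        # vector; the normalisation uses the unprojected vector (projecting
        # the denominator too would invert the spectrum for a rank-1 R)
        denom = a.conj() @ R_inv @ a
        if abs(denom) < 1e-300:
            psd[idx] = 0.0
            continue
        w = (R_inv @ a_proj) / denom
        psd[idx] = (w.conj() @ R @ w).real
    return DoaScan(angles_deg=angles_deg, psd=psd)


def estimate_doa(
    frames: RawFrameSet,
    frame: int = -1,
    angles_deg: np.ndarray | None = None,
) -> DoaScan:
    """Estimate the arrival angle from the bin-1 responses of antennas 1 and 3.

    Snapshots are all chirps of one frame (the most recent by default).
    """
    if frames.config.n_rx_antennas < 3:
        raise ValueError("need antennas 1 and 3 for the ULA pair")
    block = frames.data[frame]
    responses = []
    for ant in (1, 3):
        spec = range_fft(block[ant - 1])
        responses.append(spec[:, 1])
    # conjugate: map the range-FFT's exp(+j psi) convention onto the
    # phase-lag steering model (see module docstring)
    x = np.conj(np.vstack(responses))
    return esbm_scan(covariance(x), angles_deg)
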