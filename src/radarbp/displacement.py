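"""Skin-displacement extraction from the slow-time I/Q series.

Micrometre-scale skin motion over the radial artery rotates the bin-1 I/Q
vector along an *arc* of a circle in the complex plane: the circle centre is
the static clutter (DC) offset, the radius the channel amplitude, and the
angle encodes displacement through ``psi = (4 pi / lambda) * d``.  The chain
implemented here is:

1. fit a circle to each frame's I/Q points (Taubin's algebraic fit solved by
   Newton–Raphson on its characteristic polynomial),
2. stabilise it with a running average over the last 30 frame circles,
3. translate/scale the points onto the unit circle (DC compensation),
4. arctangent-demodulate with the two-argument arctangent (full quadrant,
   angles in [-pi, pi]),
5. unwrap (add 2 pi multiples until consecutive jumps are below pi) over the
   concatenated multi-frame series to preserve continuity at frame borders,
6. band-pass 0.75–5 Hz with a 4th-order Butterworth applied forward-backward
   (zero phase, so feature timings are not delayed), and
7. scale radians to micrometres with ``t = (lambda/2) / (2 pi) * 1e6``.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from radarbp.radar_params import DerivedParams, derive_params
from radarbp.range_processing import IQSeries, extract_iq
from radarbp.synthetic import DisplacementTrace, RawFrameSet

__all__ = [
    "CircleEstimate",
    "CircleBuffer",
    "PhaseSeries",
    "taubin_circle_fit",
    "smooth_circle",
    "compensate",
    "arctan_demod",
    "unwrap_phase",
    "bandpass_pulse",
    "to_micrometers",
    "extract_displacement",
]


class CircleFitError(RuntimeError):
    """Degenerate geometry or non-convergent circle fit."""


@dataclass(frozen=True)
class CircleEstimate:
    """Fitted I/Q circle: centre (a, b) and radius r."""

    center_i: float
    center_q: float
    radius: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.center_i, self.center_q, self.radius]).all():
            raise ValueError("non-finite circle estimate")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


class CircleBuffer:
    """Running buffer of the most recent circle estimates (default 30)."""

    def __init__(self, capacity: int = 30) -> None:
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.entries: deque[CircleEstimate] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PhaseSeries:
    """Demodulated phase in radians at the slow-time rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite phase values")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.values.size


def taubin_circle_fit(
    iq: IQSeries | np.ndarray,
    eps: float = 1e-12,
    max_iter: int = 20,
) -> CircleEstimate:
    """Taubin's algebraic circle fit, Newton–Raphson from initial root 0.

    The data are centred on their centroid; the characteristic polynomial of
    the normalised moment matrix of (i, q, z = i^2 + q^2) is rooted by
    Newton–Raphson and the circle recovered from the associated eigen
    direction.  Exact on exact circles; statistically near-optimal on arcs.
    """
    pts = iq.values if isinstance(iq, IQSeries) else np.asarray(iq, dtype=complex)
    if pts.size < 3:
        raise CircleFitError("need at least 3 points to fit a circle")
    xc, yc = pts.real.mean(), pts.imag.mean()
    x = pts.real - xc
    y = pts.imag - yc
    z = x * x + y * y

    n = pts.size
    mxx = (x * x).sum() / n
    myy = (y * y).sum() / n
    mxy = (x * y).sum() / n
    mxz = (x * z).sum() / n
    myz = (y * z).sum() / n
    mzz = (z * z).sum() / n

    mz = mxx + myy
    cov_xy = mxx * myy - mxy * mxy
    var_z = mzz - mz * mz

    # characteristic polynomial coefficients (quartic's leading part folded
    # into the cubic Newton iteration, per Taubin's formulation)
    a3 = 4.0 * mz
    a2 = -3.0 * mz * mz - mzz
    a1 = var_z * mz + 4.0 * cov_xy * mz - mxz * mxz - myz * myz
    a0 = (mxz * (mxz * myy - myz * mxy)
          + myz * (myz * mxx - mxz * mxy)
          - var_z * cov_xy)
    a22 = a2 + a2
    a33 = a3 + a3 + a3

    x_new = 0.0
    x_old = 0.0
    y_new = 1e20
    for it in range(max_iter):
        y_old = y_new
        y_new = a0 + x_new * (a1 + x_new * (a2 + x_new * a3))
        if abs(y_new) > abs(y_old):
            # |P| rising again: converged to rounding noise at the previous
            # iterate (the polynomial decreases monotonically toward the root)
            x_new = x_old
            break
        dy = a1 + x_new * (a22 + x_new * a33)
        if dy == 0.0:
            raise CircleFitError(f"zero derivative after {it} iterations")
        x_old = x_new
        x_new = x_old - y_new / dy
        if x_new != 0.0 and abs((x_new - x_old) / x_new) < eps:
            break
        if x_new == x_old:
            break
    else:
        raise CircleFitError(f"Newton did not converge in {max_iter} iterations")

    det = x_new * x_new - x_new * mz + cov_xy
    if abs(det) < 1e-300:
        raise CircleFitError("collinear points: degenerate circle geometry")
    a = (mxz * (myy - x_new) - myz * mxy) / det / 2.0
    b = (myz * (mxx - x_new) - mxz * mxy) / det / 2.0
    r2 = a * a + b * b + mz
    if r2 <= 0:
        raise CircleFitError("non-positive squared radius")
    return CircleEstimate(center_i=a + xc, center_q=b + yc, radius=float(np.sqrt(r2)))


def smooth_circle(buffer: CircleBuffer, new: CircleEstimate) -> CircleEstimate:
    """Push a circle into the running buffer and return the mean circle."""
    buffer.entries.append(new)
    cs = buffer.entries
    return CircleEstimate(
        center_i=float(np.mean([c.center_i for c in cs])),
        center_q=float(np.mean([c.center_q for c in cs])),
        radius=float(np.mean([c.radius for c in cs])),
    )


def compensate(iq: IQSeries, circle: CircleEstimate) -> IQSeries:
    """Map the I/Q points onto the unit circle: ((I - a) + j(Q - b)) / r."""
    if circle.radius <= 0:
        raise ValueError("circle radius must be positive")
    shifted = (iq.values - (circle.center_i + 1j * circle.center_q)) / circle.radius
    return IQSeries(values=shifted, bin_index=iq.bin_index,
                    antenna_index=iq.antenna_index, rate=iq.rate)


def arctan_demod(iq: IQSeries) -> PhaseSeries:
    """Quadrant-aware arctangent demodulation; angles in [-pi, pi].

    The two-argument arctangent is used: the single-argument form of
    ``arctan(Q/I)`` cannot reach the full [-pi, pi] interval.
    """
    v = iq.values
    zero = np.flatnonzero((v.real == 0.0) & (v.imag == 0.0))
    if zero.size:
        raise ValueError(f"zero I/Q vector at sample index {zero[0]}")
    return PhaseSeries(values=np.arctan2(v.imag, v.real), rate=iq.rate)


def unwrap_phase(phase: PhaseSeries) -> PhaseSeries:
    """Add 2 pi multiples so consecutive jumps stay below pi in magnitude."""
    return PhaseSeries(values=np.unwrap(phase.values), rate=phase.rate)


def bandpass_pulse(
    phase: PhaseSeries,
    low_hz: float = 0.75,
    high_hz: float = 5.0,
    order: int = 4,
    zero_phase: bool = True,
) -> PhaseSeries:
    """4th-order Butterworth band-pass isolating the pulsation band.

    Applied forward-backward by default so feature timings (upstroke, travel
    time) are not delayed; set ``zero_phase=False`` for the causal filter.
    """
    if phase.rate <= 2.0 * high_hz:
        raise ValueError(
            f"rate {phase.rate} Hz must exceed twice the upper cutoff {high_hz} Hz"
        )
    sos_ba = butter(order, [low_hz, high_hz], btype="bandpass", fs=phase.rate)
    if zero_phase:
        out = filtfilt(*sos_ba, phase.values)
    else:
        from scipy.signal import lfilter

        out = lfilter(*sos_ba, phase.values)
    return PhaseSeries(values=out, rate=phase.rate)


def to_micrometers(phase: PhaseSeries, params: DerivedParams) -> DisplacementTrace:
    """Scale radians to micrometres with the lambda/2-per-turn transform."""
    return DisplacementTrace(
        samples=phase.values * params.transform_factor_um_per_rad,
        rate=phase.rate,
    )


def _relative_residual(points: np.ndarray, circle: CircleEstimate) -> float:
    """RMS distance of the points from the fitted circle, relative to r."""
    d = np.abs(points - (circle.center_i + 1j * circle.center_q)) - circle.radius
    return float(np.sqrt(np.mean(d * d)) / circle.radius)


def _fallback_circle(points: np.ndarray) -> CircleEstimate:
    """Origin-centred circle through the point cloud.

    Used when no credible arc has been seen yet: a static return at radius
    |S| from the origin then demodulates to a constant phase, which the
    band-pass removes.
    """
    radius = float(np.sqrt(np.mean(np.abs(points) ** 2)))
    if radius <= 0:
        radius = 1.0
    return CircleEstimate(center_i=0.0, center_q=0.0, radius=radius)


def extract_displacement(
    frames: RawFrameSet,
    antenna: int = 3,
    bin_index: int = 1,
    circle_buffer: CircleBuffer | None = None,
    bandpass: bool = True,
) -> DisplacementTrace:
    """Full displacement chain: circle fit per frame, compensate, demodulate.

    The circle is fitted once per frame (one frame of chirps gives a stable
    arc) and smoothed over the running 30-frame buffer; frames whose fit
    fails reuse the last smoothed circle.  Demodulation, unwrapping and
    filtering run on the concatenated multi-frame series.
    """
    if circle_buffer is None:
        circle_buffer = CircleBuffer()
    dp = derive_params(frames.config)
    compensated = []
    smoothed: CircleEstimate | None = None
    for f in range(frames.n_frames):
        sub = RawFrameSet(data=frames.data[f : f + 1], config=frames.config)
        iq = extract_iq(sub, antenna=antenna, bin_index=bin_index)
        try:
            fit = taubin_circle_fit(iq)
            if _relative_residual(iq.values, fit) > 0.1:
                # the points form a noise blob, not an arc: a blob's tiny
                # fitted radius would blow the compensated phase up
                raise CircleFitError("fit residuals comparable to the radius")
            smoothed = smooth_circle(circle_buffer, fit)
        except CircleFitError:
            if smoothed is None:
                smoothed = _fallback_circle(iq.values)
            else:
                warnings.warn(
                    f"circle fit failed for frame {f}; reusing last circle",
                    stacklevel=2,
                )
        compensated.append(compensate(iq, smoothed).values)

    series = IQSeries(values=np.concatenate(compensated), bin_index=bin_index,
                      antenna_index=antenna, rate=1.0 / frames.config.prt)
    phase = unwrap_phase(arctan_demod(series))
    if bandpass:
        phase = bandpass_pulse(phase)
    else:
        phase = PhaseSeries(values=phase.values - phase.values.mean(),
                            rate=phase.rate)
    return to_micrometers(phase, dp)
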