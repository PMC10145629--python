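"""Per-chirp range FFT and slow-time I/Q extraction at a range bin.

The range FFT runs along fast time (the samples within one chirp); the
complex value of one range bin, followed chirp after chirp, is the
substitutionary I/Q baseband whose phase encodes sub-wavelength target
motion.  Only the first non-DC bin is used downstream, so the per-chirp
fast-time mean is removed before transforming to keep DC leakage out of
bin 1 (switchable).  No window is applied by default; the spectrum is
scaled by 2/n so a unit-amplitude fast-time cosine at a bin centre yields
a unit-magnitude bin value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from radarbp.synthetic import RawFrameSet

__all__ = ["IQSeries", "range_fft", "extract_iq"]


@dataclass
class IQSeries:
    """Complex slow-time sequence at one range bin of one antenna."""

    values: np.ndarray
    bin_index: int
    antenna_index: int
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.values.size


def range_fft(
    frame_chirps: np.ndarray,
    remove_mean: bool = True,
    window: np.ndarray | None = None,
) -> np.ndarray:
    """Range FFT of a [chirp, sample] block; non-negative bins retained.

    Returns a complex [chirp, bin] matrix with n//2 + 1 bins, scaled by
    2/n_samples.
    """
    chirps = np.asarray(frame_chirps, dtype=float)
    if chirps.ndim != 2 or chirps.shape[1] < 2:
        raise ValueError("expected a [chirp, sample] matrix with >= 2 samples")
    if not np.all(np.isfinite(chirps)):
        raise ValueError("non-finite values in raw chirps")
    if remove_mean:
        chirps = chirps - chirps.mean(axis=1, keepdims=True)
    if window is not None:
        chirps = chirps * np.asarray(window, dtype=float)[None, :]
    n = chirps.shape[1]
    return np.fft.rfft(chirps, axis=1) * (2.0 / n)


def extract_iq(
    frames: RawFrameSet,
    antenna: int = 3,
    bin_index: int = 1,
    remove_mean: bool = True,
) -> IQSeries:
    """Slow-time I/Q series at one range bin, concatenated over all frames.

    ``antenna`` is 1-based (the physical antenna number); the default is
    antenna 3 at the first non-DC range bin.  Requesting bin 0 is allowed
    but warned against, since the fast-time mean removal empties it.
    """
    config = frames.config
    if not (1 <= antenna <= config.n_rx_antennas):
        raise IndexError(f"antenna {antenna} out of range 1..{config.n_rx_antennas}")
    n_bins = config.n_samples_per_chirp // 2 + 1
    if not (0 <= bin_index < n_bins):
        raise IndexError(f"bin {bin_index} out of range 0..{n_bins - 1}")
    if bin_index == 0:
        warnings.warn("bin 0 is the DC bin; displacement extraction uses bin 1",
                      stacklevel=2)
    values = []
    for f in range(frames.n_frames):
        spec = range_fft(frames.data[f, antenna - 1], remove_mean=remove_mean)
        values.append(spec[:, bin_index])
    return IQSeries(
        values=np.concatenate(values),
        bin_index=bin_index,
        antenna_index=antenna,
        rate=1.0 / config.prt,
    )
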