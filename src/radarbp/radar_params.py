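"""Radar acquisition configuration and closed-form derived quantities.

An FMCW radar sweeps its carrier linearly from a lower to an upper frequency
(one *chirp*); the sweep width is the bandwidth ``b = f_upper - f_lower``.
Samples within a chirp (*fast time*) resolve range, the sequence of chirps
(*slow time*) resolves motion.  The quantities derived here are the standard
closed forms:

- wavelength ``lambda = c / fc`` at the centre frequency ``fc = f0 + b/2``,
- range resolution ``dr = c / (2 b)``,
- maximum range ``r_max = fs * tc * c / (2 b)`` with fast sampling rate ``fs``
  and chirp duration ``tc``,
- slow-time rate ``sps = 1 / PRT`` (pulse repetition time),
- the phase-to-displacement transform ``t = (lambda / 2) / (2 pi) * 1e6``
  in micrometres per radian.

The defaults reproduce a 58–63.5 GHz wrist-worn configuration: 32 samples per
chirp, 256 chirps per frame, PRT 0.004 s, three receive antennas of which the
outer pair (antennas 1 and 3) forms a half-wavelength uniform linear array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "RadarConfig",
    "DerivedParams",
    "derive_params",
    "beat_frequency",
    "doppler_velocity",
    "round_trip_range",
    "load_config",
    "save_config",
]


class InvalidConfigError(ValueError):
    """Raised when a radar configuration violates its invariants."""


@dataclass(frozen=True)
class RadarConfig:
    """Acquisition constants of the FMCW radar.

    ``speed_of_light`` defaults to 3e8 m/s so derived values round to the
    conventional printed figures (2.7 cm resolution, 87.3 cm max range);
    the exact value is selectable.
    """

    f_lower: float = 58e9
    f_upper: float = 63.5e9
    n_samples_per_chirp: int = 32
    n_chirps_per_frame: int = 256
    prt: float = 0.004
    chirp_duration: float = 64e-6
    n_rx_antennas: int = 3
    rx_spacing_wavelengths: float = 0.5
    speed_of_light: float = 3e8

    def __post_init__(self) -> None:
        if not (self.f_upper > self.f_lower > 0):
            raise InvalidConfigError(
                f"need f_upper > f_lower > 0, got {self.f_lower}..{self.f_upper}"
            )
        if self.n_samples_per_chirp < 2:
            raise InvalidConfigError("need at least 2 samples per chirp")
        if not (self.prt >= self.chirp_duration > 0):
            raise InvalidConfigError("need prt >= chirp_duration > 0")
        if self.rx_spacing_wavelengths <= 0:
            raise InvalidConfigError("antenna spacing must be positive")

    @property
    def fast_sampling_rate(self) -> float:
        """ADC rate along fast time: one chirp of n samples spans tc."""
        return self.n_samples_per_chirp / self.chirp_duration

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DerivedParams:
    """Quantities computed in closed form from a :class:`RadarConfig`."""

    bandwidth: float
    center_freq: float
    wavelength: float
    range_resolution: float
    max_range: float
    fast_sampling_rate: float
    slow_sampling_rate_sps: float
    transform_factor_um_per_rad: float


def derive_params(config: RadarConfig) -> DerivedParams:
    """Compute every derived radar quantity from the configuration.

    ``max_range = fs * tc * c / (2 b)`` reduces to
    ``n_samples_per_chirp * range_resolution`` because ``fs = n / tc``.
    """
    b = config.f_upper - config.f_lower
    if b <= 0:
        raise InvalidConfigError("non-positive bandwidth")
    c = config.speed_of_light
    fc = config.f_lower + b / 2.0
    lam = c / fc
    dr = c / (2.0 * b)
    fs = config.fast_sampling_rate
    r_max = fs * config.chirp_duration * c / (2.0 * b)
    return DerivedParams(
        bandwidth=b,
        center_freq=fc,
        wavelength=lam,
        range_resolution=dr,
        max_range=r_max,
        fast_sampling_rate=fs,
        slow_sampling_rate_sps=1.0 / config.prt,
        transform_factor_um_per_rad=(lam / 2.0) / (2.0 * math.pi) * 1e6,
    )


def beat_frequency(config: RadarConfig, target_range: float) -> float:
    """Beat frequency ``fB = 2 b r / (c tc)`` of a target at range ``r``.

    A target at one range resolution produces exactly one beat cycle per
    chirp, i.e. FFT bin 1.
    """
    if target_range < 0:
        raise ValueError(f"target range must be non-negative, got {target_range}")
    b = config.f_upper - config.f_lower
    return 2.0 * b * target_range / (config.speed_of_light * config.chirp_duration)


def doppler_velocity(config: RadarConfig, doppler_shift: float) -> float:
    """Radial velocity ``v = -lambda * fD / 2`` from a Doppler shift."""
    lam = derive_params(config).wavelength
    return -lam * doppler_shift / 2.0


def round_trip_range(config: RadarConfig, delay: float) -> float:
    """Target range ``r = c * tau / 2`` from the round-trip delay ``tau``."""
    if delay < 0:
        raise ValueError(f"round-trip delay must be non-negative, got {delay}")
    return config.speed_of_light * delay / 2.0


def load_config(path: str | Path) -> RadarConfig:
    """Read a RadarConfig from a YAML file mirroring the field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RadarConfig(**raw)


def save_config(config: RadarConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
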