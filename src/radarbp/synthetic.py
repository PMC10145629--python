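"""Synthetic skin displacement and raw FMCW radar frames with known truth.

The study data behind this pipeline (wrist recordings over the radial artery)
are not public, so every stage is exercised on simulated input.  The simulator
produces:

1. a *displacement trace* — micrometre-scale skin motion shaped like an
   arterial pressure pulse (sharp systolic upstroke, dicrotic-notch region,
   diastolic hump), repeating at a configurable heart rate; and
2. *raw frames* — real-valued ADC samples per frame, antenna, chirp and fast
   sample in which that displacement phase-modulates the beat signal of a
   target at a chosen range and direction of arrival.

Each beat is a sum of three Gaussian bumps at fixed fractions of the beat
period.  The pulse amplitude is normalised so the peak-to-trough excursion of
one beat equals ``amplitude_um``.

The raw-frame model for sample ``i`` of chirp ``m`` at antenna ``k`` is::

    a_tx * a_rx[k] * cos(2 pi fB i / fs + (4 pi / lambda)(r0 + d_m) + phi_k)
    + clutter_k(i) + noise

where ``fB`` is the beat frequency of the target range ``r0``, ``d_m`` the
displacement at chirp ``m`` and ``phi_k = 2 pi (d_k / lambda) sin(theta)`` the
arrival-angle phase at the antenna position ``d_k`` (antennas 1 and 3 form the
half-wavelength uniform linear pair, so their phase difference is
``pi sin(theta)``).  Complex I/Q offsets (the circle-fit "DC" terms) are
injected as a static quadrature tone at the same beat frequency — static
clutter in the same range bin — because a constant ADC offset would only
populate the DC bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from radarbp.radar_params import RadarConfig, beat_frequency, derive_params

__all__ = [
    "PulseModelParams",
    "SceneParams",
    "DisplacementTrace",
    "RawFrameSet",
    "synth_displacement",
    "synth_raw_frames",
    "save_frames",
    "load_frames",
    "synthetic_feature_table",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
]


@dataclass(frozen=True)
class PulseModelParams:
    """Shape parameters of the synthetic arterial pulse.

    Each component is ``(center fraction of beat, width fraction, relative
    height)``.  Defaults place the systolic peak at 15% of the beat, the
    dicrotic-notch region at 35% and the diastolic hump at 45%.
    """

    heart_rate_bpm: float = 72.0
    amplitude_um: float = 50.0
    systolic_component: tuple[float, float, float] = (0.15, 0.095, 1.0)
    dicrotic_component: tuple[float, float, float] = (0.36, 0.055, 0.42)
    diastolic_component: tuple[float, float, float] = (0.52, 0.15, 0.35)
    baseline_drift_um: float = 0.0
    displacement_noise_um: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be non-negative")
        if not (30.0 <= self.heart_rate_bpm <= 180.0):
            raise ValueError("heart_rate_bpm must lie in [30, 180]")
        for comp in (
            self.systolic_component,
            self.dicrotic_component,
            self.diastolic_component,
        ):
            if not (0.0 <= comp[2] <= 1.0):
                raise ValueError("component heights must lie in [0, 1]")


@dataclass(frozen=True)
class SceneParams:
    """Geometry and impairments of the simulated acquisition.

    ``target_range_m=None`` places the target at the bin-1 centre range (one
    range resolution), giving clean single-bin behaviour; pass an explicit
    range (e.g. the physical 3 mm standoff) for sub-bin robustness scenarios.
    ``dc_offsets`` are per-antenna complex bin-1 offsets (circle centres);
    ``rx_amplitudes`` per-antenna gains (circle radii for unit tx amplitude).
    ``phase_walk_std`` adds a slow random-walk phase per chirp (rad), a proxy
    for oscillator phase noise; ``noise_std`` is white additive sample noise
    in ADC units.
    """

    target_range_m: float | None = None
    doa_deg: float = 0.0
    rx_amplitudes: tuple[float, ...] = (1.0, 1.0, 1.0)
    dc_offsets: tuple[complex, ...] = (0j, 0j, 0j)
    noise_std: float = 0.0
    phase_walk_std: float = 0.0
    tx_amplitude: float = 1.0
    invert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.doa_deg) > 40.0:
            raise ValueError("doa_deg must lie in [-40, 40]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be non-negative")


@dataclass
class DisplacementTrace:
    """Skin displacement in micrometres sampled at the slow-time rate."""

    samples: np.ndarray
    rate: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.times is None:
            self.times = np.arange(self.samples.size) / self.rate
        else:
            self.times = np.asarray(self.times, dtype=float)
        if self.samples.size != self.times.size:
            raise ValueError("samples and times must have equal length")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class RawFrameSet:
    """Real ADC samples ``[frame, antenna, chirp, sample]`` plus their config."""

    data: np.ndarray
    config: RadarConfig
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("raw data must be 4-D [frame, antenna, chirp, sample]")
        nf, na, nc, ns = self.data.shape
        if na != self.config.n_rx_antennas:
            raise ValueError("antenna axis does not match config")
        if nc != self.config.n_chirps_per_frame:
            raise ValueError("chirp axis does not match config")
        if ns != self.config.n_samples_per_chirp:
            raise ValueError("sample axis does not match config")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("raw data contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _beat_template(params: PulseModelParams, n_grid: int = 2048) -> np.ndarray:
    """One beat period on a dense grid, peak-to-trough normalised to 1."""
    u = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    g = np.zeros_like(u)
    for c, w, h in (
        params.systolic_component,
        params.dicrotic_component,
        params.diastolic_component,
    ):
        # wrap neighbouring beats so the periodic template is continuous
        for shift in (-1.0, 0.0, 1.0):
            g += h * np.exp(-0.5 * ((u - c - shift) / w) ** 2)
    span = g.max() - g.min()
    if span == 0:
        return np.zeros_like(u)
    return (g - g.min()) / span


def synth_displacement(
    params: PulseModelParams,
    duration: float,
    rate: float,
    seed: int = 0,
) -> DisplacementTrace:
    """Generate a pulse-shaped displacement trace.

    Beats repeat at ``heart_rate_bpm``; noise and baseline drift are added
    after amplitude normalisation.  Raises if the sampling rate cannot
    resolve the beat (fewer than 10 samples per beat).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    hr_hz = params.heart_rate_bpm / 60.0
    if rate < 10.0 * hr_hz:
        raise ValueError(
            f"rate {rate} Hz too low to resolve a {params.heart_rate_bpm} bpm beat"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    template = _beat_template(params)
    phase = (t * hr_hz) % 1.0
    trace = params.amplitude_um * np.interp(phase, np.linspace(0, 1, template.size, endpoint=False), template)
    if params.baseline_drift_um > 0:
        trace = trace + params.baseline_drift_um * np.sin(2 * np.pi * 0.1 * t)
    if params.displacement_noise_um > 0:
        trace = trace + rng.normal(0.0, params.displacement_noise_um, size=n)
    return DisplacementTrace(samples=trace, rate=rate, times=t)


# antenna positions along the horizontal baseline, in units of the
# antenna-1-to-antenna-3 spacing (the middle antenna sits off-axis in the
# physical L-shape; its horizontal projection is taken as the midpoint)
_ANTENNA_POSITIONS = (0.0, 0.5, 1.0)


def synth_raw_frames(
    config: RadarConfig,
    scene: SceneParams,
    displacement: DisplacementTrace,
) -> RawFrameSet:
    """Phase-modulate multi-antenna raw frames with a displacement trace.

    One displacement sample drives one chirp, so the trace rate must equal the
    slow-time rate 1/PRT.  The trace must cover at least one frame; whole
    frames are emitted and any remainder is dropped.
    """
    sps = 1.0 / config.prt
    if not np.isclose(displacement.rate, sps, rtol=1e-9):
        raise ValueError(
            f"displacement rate {displacement.rate} must equal slow-time rate {sps}"
        )
    nc = config.n_chirps_per_frame
    n_frames = len(displacement) // nc
    if n_frames < 1:
        raise ValueError(
            f"displacement has {len(displacement)} samples; "
            f"at least one frame ({nc} chirps) required"
        )

    dp = derive_params(config)
    r0 = scene.target_range_m if scene.target_range_m is not None else dp.range_resolution
    fb = beat_frequency(config, r0)
    ns = config.n_samples_per_chirp
    fs = dp.fast_sampling_rate
    lam = dp.wavelength
    theta = np.deg2rad(scene.doa_deg)
    rng = np.random.default_rng(scene.seed)

    n_chirps_total = n_frames * nc
    disp_m = displacement.samples[:n_chirps_total] * 1e-6
    if scene.invert:
        disp_m = -disp_m

    i_idx = np.arange(ns)
    fast_phase = 2.0 * np.pi * fb * i_idx / fs               # [sample]
    slow_phase = (4.0 * np.pi / lam) * (r0 + disp_m)          # [chirp]
    if scene.phase_walk_std > 0:
        slow_phase = slow_phase + np.cumsum(
            rng.normal(0.0, scene.phase_walk_std, size=n_chirps_total)
        )

    na = config.n_rx_antennas
    data = np.empty((n_chirps_total, na, ns), dtype=np.float64)
    cos_fast = np.cos(fast_phase)
    sin_fast = np.sin(fast_phase)
    for k in range(na):
        pos = _ANTENNA_POSITIONS[k] if k < len(_ANTENNA_POSITIONS) else float(k) / 2.0
        # rx_spacing_wavelengths is the antenna-1-to-3 spacing in wavelengths,
        # so antenna 3 leads antenna 1 by 2*pi*spacing*sin(theta)
        phi_k = 2.0 * np.pi * config.rx_spacing_wavelengths * np.sin(theta) * pos
        arg = slow_phase[:, None] + phi_k + fast_phase[None, :]
        sig = scene.tx_amplitude * scene.rx_amplitudes[k] * np.cos(arg)
        dc = scene.dc_offsets[k] if k < len(scene.dc_offsets) else 0j
        if dc != 0:
            # the static component reflects off the same skin patch, so it
            # carries the same arrival-angle phase as the pulsatile return
            dc_rot = dc * np.exp(1j * phi_k)
            sig = sig + dc_rot.real * cos_fast[None, :] - dc_rot.imag * sin_fast[None, :]
        data[:, k, :] = sig
    if scene.noise_std > 0:
        data = data + rng.normal(0.0, scene.noise_std, size=data.shape)

    frames = data.reshape(n_frames, nc, na, ns).transpose(0, 2, 1, 3)
    truth = {
        "displacement": displacement.samples[:n_chirps_total].copy(),
        "doa_deg": scene.doa_deg,
        "circle_centers": np.asarray(scene.dc_offsets, dtype=complex),
        "seed": scene.seed,
    }
    return RawFrameSet(data=frames, config=config, truth=truth)


def save_frames(frames: RawFrameSet, path, config_hash: str | None = None) -> None:
    """Write frames to HDF5: /frames float32 plus config attributes."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("frames", data=frames.data.astype(np.float32))
        for key, val in frames.config.to_dict().items():
            ds.attrs[key] = val
        if config_hash is not None:
            ds.attrs["config_hash"] = config_hash
        if frames.truth is not None:
            grp = fh.create_group("truth")
            grp.create_dataset("displacement", data=frames.truth["displacement"])
            grp.attrs["doa_deg"] = frames.truth["doa_deg"]
            grp.attrs["seed"] = frames.truth["seed"]


def load_frames(path) -> RawFrameSet:
    with h5py.File(path, "r") as fh:
        ds = fh["frames"]
        attrs = dict(ds.attrs)
        attrs.pop("config_hash", None)
        attrs["n_samples_per_chirp"] = int(attrs["n_samples_per_chirp"])
        attrs["n_chirps_per_frame"] = int(attrs["n_chirps_per_frame"])
        attrs["n_rx_antennas"] = int(attrs["n_rx_antennas"])
        config = RadarConfig(**{k: attrs[k] for k in RadarConfig.__dataclass_fields__})
        data = ds[()].astype(np.float64)
        truth = None
        if "truth" in fh:
            grp = fh["truth"]
            truth = {
                "displacement": grp["displacement"][()],
                "doa_deg": float(grp.attrs["doa_deg"]),
                "circle_centers": None,
                "seed": int(grp.attrs["seed"]),
            }
    return RawFrameSet(data=data, config=config, truth=truth)


# ---------------------------------------------------------------------------
# Synthetic feature tables for the regression stage
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "sbp_f", "dbp_f", "pp", "dicrotic_notch", "pr", "ap",
    "tr", "sut", "dt",
    "sw10", "sw25", "sw33", "sw50", "sw66", "sw75",
    "dw10", "dw25", "dw33", "dw50", "dw66", "dw75",
    "age", "gender", "height", "weight",
]
TARGET_COLUMNS = ["target_sbp", "target_dbp"]


def synthetic_feature_table(
    n_rows: int,
    noise_sd_mmhg: float = 3.0,
    seed: int = 0,
):
    """Feature table whose BP targets are known smooth functions of 6 drivers.

    Targets are smooth functions of age, gender, height, weight, systolic
    upstroke time and the calibrated pulse span, plus Gaussian noise of
    standard deviation ``noise_sd_mmhg``.  The remaining columns are filled
    with physiologically plausible correlated values so the table has the
    same 25-column layout the pulse-analysis stage emits.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = int(n_rows)
    age = rng.uniform(20.0, 80.0, n)
    gender = rng.integers(0, 2, n).astype(float)
    height = rng.normal(170.0 + 8.0 * gender, 7.0)
    weight = rng.normal(62.0 + 12.0 * gender, 9.0)
    sut = rng.uniform(0.12, 0.28, n)
    hr = rng.uniform(55.0, 90.0, n)
    duration = 60.0 / hr

    dbp_clean = 50.0 + 0.15 * age + 0.10 * weight + 0.05 * height - 20.0 * sut
    sbp_clean = dbp_clean + 25.0 + 0.30 * age + 6.0 * gender + 40.0 * sut

    target_sbp = sbp_clean + rng.normal(0.0, noise_sd_mmhg, n)
    target_dbp = dbp_clean + rng.normal(0.0, noise_sd_mmhg, n)

    # waveform-derived columns: calibrated waves track pressure approximately
    sbp_f = sbp_clean + rng.normal(0.0, 1.0, n)
    dbp_f = dbp_clean + rng.normal(0.0, 1.0, n)
    pp = sbp_f - dbp_f
    notch = dbp_f + pp * rng.uniform(0.25, 0.5, n)
    ap_sign = np.where(age > 50.0, 1.0, -1.0)
    ap = ap_sign * rng.uniform(0.0, 0.12, n) * pp
    pr = sbp_f - ap * ap_sign  # pr below sbp by |ap|
    tr = sut * rng.uniform(0.75, 0.95, n)
    dt = duration - sut

    cols = {
        "sbp_f": sbp_f, "dbp_f": dbp_f, "pp": pp,
        "dicrotic_notch": notch, "pr": pr, "ap": ap,
        "tr": tr, "sut": sut, "dt": dt,
    }
    sys_shape = rng.uniform(0.9, 1.1, n)
    dia_shape = rng.uniform(0.9, 1.1, n)
    for x in (10, 25, 33, 50, 66, 75):
        frac = 1.0 - (x / 100.0) ** 0.7
        cols[f"sw{x}"] = sut * frac * sys_shape
        cols[f"dw{x}"] = dt * 0.6 * frac * dia_shape
    cols.update(age=age, gender=gender, height=height, weight=weight,
                target_sbp=target_sbp, target_dbp=target_dbp)
    return pd.DataFrame(cols, columns=FEATURE_COLUMNS + TARGET_COLUMNS)
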