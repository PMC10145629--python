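"""Beat segmentation, quality filtering, calibration and pulse-wave features.

The displacement trace is cut into individual beats at the wave feet
(prominent local minima).  Each beat is compared against a reference pulse
wave (the [0,1]-scaled mean of several clean beats) via the Pearson
correlation; beats above the chosen threshold (0.7 / 0.8 / 0.9) are *usable*.
A one-time cuff reading (refSYS/refDIA) calibrates micrometres to mmHg: the
first good beat defines the scaling factor

    scaling_factor = (refSYS - refDIA) / (max(PW) - min(PW))

and every beat is stretched as ``PW = (PW - min) * scaling_factor + min``,
preserving its minimum.

From each calibrated beat, 21 features are extracted: six amplitude-based
(SBP, DBP, pulse pressure, dicrotic notch, pressure at reflection PR,
augmented pressure AP = (SBP - PR) * AIx with AIx = +1 when the reflected
wave arrives before the systolic peak and -1 after) and fifteen timing-based
(reflected-wave travel time TR, systolic upstroke time SUT, diastolic time
DT, and systolic/diastolic widths at 10/25/33/50/66/75% of pulse pressure,
measured between the level crossings and the systolic peak).  Together with
age, gender, height and weight these form the 25 regression inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import skew

from radarbp.synthetic import DisplacementTrace, FEATURE_COLUMNS

__all__ = [
    "PulseWave",
    "ReferenceWave",
    "CalibrationInfo",
    "FeatureVector",
    "FeatureUndefinedError",
    "WIDTH_LEVELS_PCT",
    "detect_inversion",
    "segment_waves",
    "scale01",
    "build_reference",
    "quality_score",
    "label_waves",
    "compute_scaling_factor",
    "calibrate_wave",
    "find_intersections",
    "amplitude_features",
    "timing_features",
    "feature_vector",
    "features_dataframe",
]

WIDTH_LEVELS_PCT = (10, 25, 33, 50, 66, 75)

GENDER_ENCODING = {"female": 0.0, "male": 1.0}


class FeatureUndefinedError(ValueError):
    """A morphological feature cannot be located on this beat."""


@dataclass
class PulseWave:
    """One segmented beat (micrometres before calibration, mmHg after)."""

    samples: np.ndarray
    start_index: int
    rate: float
    correlation: float | None = None
    usable: bool = False
    inverted: bool = False
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise ValueError("a pulse wave needs at least 2 samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) / self.rate


@dataclass
class ReferenceWave:
    """[0,1]-scaled mean beat used for correlation-based quality filtering."""

    samples: np.ndarray
    source_count: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.isclose(self.samples.min(), 0.0) or not np.isclose(self.samples.max(), 1.0):
            raise ValueError("reference wave must be [0,1]-scaled")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class CalibrationInfo:
    """One-time cuff pair plus the subject's calibration covariates."""

    ref_sys: float
    ref_dia: float
    age: float
    gender: str | float
    height: float
    weight: float
    scaling_factor: float | None = None

    def __post_init__(self) -> None:
        if not (self.ref_sys > self.ref_dia > 0):
            raise ValueError("need ref_sys > ref_dia > 0")

    @property
    def gender_encoded(self) -> float:
        if isinstance(self.gender, str):
            return GENDER_ENCODING.get(self.gender.lower(), 0.5)
        return float(self.gender)


@dataclass
class FeatureVector:
    """The 21 pulse-wave features plus 4 calibration features (+ targets)."""

    sbp_f: float
    dbp_f: float
    pp: float
    dicrotic_notch: float
    pr: float
    ap: float
    tr: float
    sut: float
    dt: float
    sw10: float
    sw25: float
    sw33: float
    sw50: float
    sw66: float
    sw75: float
    dw10: float
    dw25: float
    dw33: float
    dw50: float
    dw66: float
    dw75: float
    age: float
    gender: float
    height: float
    weight: float
    target_sbp: float | None = None
    target_dbp: float | None = None

    N_INPUTS = 25

    def to_dict(self) -> dict:
        return asdict(self)


def detect_inversion(trace: DisplacementTrace) -> bool:
    """True when the beat series appears upside-down.

    Upright beats have a fast systolic upstroke and slow decay, so the first
    difference is right-skewed; negative skewness flags an inverted series
    (the caller multiplies by -1).  Occasional inversion of the demodulated
    waveform is an observed artefact without an established physical model.
    """
    if len(trace) < 2 * trace.rate:
        raise ValueError("need at least 2 s of data to judge inversion")
    diffs = np.diff(trace.samples)
    if np.allclose(diffs, 0.0):
        warnings.warn("constant trace: inversion indeterminate", stacklevel=2)
        return False
    return bool(skew(diffs) < 0)


def segment_waves(trace: DisplacementTrace) -> list[PulseWave]:
    """Cut the trace into beats at wave feet.

    Feet are local minima at least 0.33 s apart with prominence >= 20% of the
    trace's interquartile amplitude; each consecutive foot pair yields one
    wave, and waves outside 0.4–1.5 s (40–150 bpm) are dropped.
    """
    x = trace.samples
    iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
    if iqr <= 0:
        return []
    feet, _ = find_peaks(
        -x,
        distance=max(1, int(round(0.33 * trace.rate))),
        prominence=0.2 * iqr,
    )
    waves = []
    for i1, i2 in zip(feet[:-1], feet[1:]):
        duration = (i2 - i1) / trace.rate
        if 0.4 <= duration <= 1.5:
            waves.append(PulseWave(samples=x[i1 : i2 + 1].copy(),
                                   start_index=int(i1), rate=trace.rate))
    return waves


def scale01(wave: np.ndarray) -> np.ndarray:
    """Min-max scale a wave to [0, 1]."""
    w = np.asarray(wave, dtype=float)
    span = w.max() - w.min()
    if span <= 0:
        raise ValueError("constant wave cannot be [0,1]-scaled")
    return (w - w.min()) / span


def _resample(wave: np.ndarray, length: int) -> np.ndarray:
    w = np.asarray(wave, dtype=float)
    return np.interp(
        np.linspace(0.0, 1.0, length), np.linspace(0.0, 1.0, w.size), w
    )


def build_reference(waves: list[PulseWave], length: int = 250) -> ReferenceWave:
    """Mean of several clean beats, interpolated to a fixed length and scaled."""
    if not waves:
        raise ValueError("need at least one wave to build a reference")
    stack = np.vstack([_resample(w.samples, length) for w in waves])
    mean = stack.mean(axis=0)
    if mean.max() - mean.min() <= 1e-12 * max(1.0, np.abs(mean).max()):
        raise ValueError("degenerate constant mean reference wave")
    return ReferenceWave(samples=scale01(mean), source_count=len(waves))


def quality_score(wave: PulseWave, ref: ReferenceWave) -> float:
    """Pearson correlation of the [0,1]-scaled wave with the reference."""
    resampled = _resample(wave.samples, len(ref))
    if resampled.max() - resampled.min() <= 0:
        wave.usable = False
        return -np.inf
    a = scale01(resampled)
    b = ref.samples
    return float(np.corrcoef(a, b)[0, 1])


def label_waves(
    waves: list[PulseWave],
    ref: ReferenceWave,
    threshold: float = 0.8,
) -> list[PulseWave]:
    """Store correlations and mark waves usable iff correlation > threshold."""
    for w in waves:
        score = quality_score(w, ref)
        w.correlation = score
        w.usable = bool(score > threshold)
    return waves


def compute_scaling_factor(first_good: PulseWave, ref_sys: float, ref_dia: float) -> float:
    """Micrometre-to-mmHg scaling from the first good beat and the cuff pair."""
    if ref_sys <= ref_dia:
        raise ValueError("need ref_sys > ref_dia")
    span = first_good.samples.max() - first_good.samples.min()
    if span <= 0:
        raise ValueError("constant wave cannot define a scaling factor")
    return (ref_sys - ref_dia) / span


def calibrate_wave(wave: PulseWave, scaling_factor: float) -> PulseWave:
    """Stretch a beat about its minimum: (PW - min) * sf + min."""
    if scaling_factor <= 0:
        raise ValueError("scaling factor must be positive")
    mn = wave.samples.min()
    return PulseWave(
        samples=(wave.samples - mn) * scaling_factor + mn,
        start_index=wave.start_index,
        rate=wave.rate,
        correlation=wave.correlation,
        usable=wave.usable,
        inverted=wave.inverted,
        calibrated=True,
    )


def find_intersections(wave: PulseWave | np.ndarray, level: float) -> tuple[int, int]:
    """First two sign changes of (wave - level): systolic and diastolic crossings.

    Zeros count as positive; the crossing index is the sample where the sign
    differs from its predecessor (no sub-sample interpolation).
    """
    w = wave.samples if isinstance(wave, PulseWave) else np.asarray(wave, dtype=float)
    if not (w.min() < level < w.max()):
        raise FeatureUndefinedError(
            f"level {level} not strictly between wave min {w.min()} and max {w.max()}"
        )
    sign = np.where(w - level >= 0.0, 1, -1)
    changes = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    if changes.size < 2:
        raise FeatureUndefinedError(f"fewer than two crossings at level {level}")
    return int(changes[0]), int(changes[1])


@dataclass(frozen=True)
class _Landmarks:
    peak_idx: int
    notch_idx: int
    notch_fallback: bool
    pr_idx: int


def _locate_landmarks(wave: PulseWave) -> _Landmarks:
    w = wave.samples
    n = w.size
    peak = int(np.argmax(w))
    window = max(3, int(round(0.05 * n)))
    smoothed = uniform_filter1d(w, size=window, mode="nearest")

    # dicrotic notch: first local minimum after the systolic peak, before 80%
    end = max(peak + 2, int(round(0.8 * n)))
    notch_fallback = False
    segment = w[peak + 1 : end]
    minima, _ = find_peaks(-segment)
    if minima.size:
        notch = peak + 1 + int(minima[0])
    else:
        deriv = np.gradient(smoothed)
        if peak + 1 < end:
            notch = peak + 1 + int(np.argmin(deriv[peak + 1 : end]))
            notch_fallback = True
        else:
            notch = peak + int(round(0.4 * (n - peak)))
            notch_fallback = True

    # reflected-wave inflection: zero crossing of the second difference of
    # the smoothed wave closest to the systolic peak, searched between 25%
    # of the upstroke and the dicrotic notch, excluding the peak itself
    d2 = np.diff(smoothed, 2)  # d2[i] is curvature at sample i + 1
    d2_sign = np.where(d2 >= 0.0, 1, -1)
    lo = int(round(0.25 * peak))
    hi = min(notch, n - 2)
    candidates = []
    for i in range(max(lo, 1), hi):
        j = i - 1  # index into d2 for curvature at sample i
        if j + 1 >= d2.size:
            break
        if i == peak:
            continue
        if d2_sign[j] != d2_sign[j + 1]:
            candidates.append(i)
    if candidates:
        pr_idx = min(candidates, key=lambda i: abs(i - peak))
    else:
        # no curvature sign change: take the flattest point near the peak
        span = [i for i in range(max(lo, 1), hi) if i != peak]
        if not span:
            raise FeatureUndefinedError("wave too short to locate the reflection point")
        pr_idx = min(span, key=lambda i: abs(d2[i - 1]) if i - 1 < d2.size else np.inf)
    return _Landmarks(peak_idx=peak, notch_idx=int(notch),
                      notch_fallback=notch_fallback, pr_idx=int(pr_idx))


def amplitude_features(wave: PulseWave) -> dict:
    """The six amplitude-based features of a calibrated beat (mmHg)."""
    if len(wave) < 10:
        raise FeatureUndefinedError("beat too short for feature extraction")
    w = wave.samples
    marks = _locate_landmarks(wave)
    sbp = float(w.max())
    dbp = float(w.min())
    pr = float(w[marks.pr_idx])
    aix = 1.0 if marks.pr_idx < marks.peak_idx else -1.0
    return {
        "sbp_f": sbp,
        "dbp_f": dbp,
        "pp": sbp - dbp,
        "dicrotic_notch": float(w[marks.notch_idx]),
        "pr": pr,
        "ap": (sbp - pr) * aix,
    }


def timing_features(wave: PulseWave) -> dict:
    """TR, SUT, DT and the six systolic/diastolic width pairs (seconds)."""
    if len(wave) < 10:
        raise FeatureUndefinedError("beat too short for feature extraction")
    w = wave.samples
    sps = wave.rate
    marks = _locate_landmarks(wave)
    peak = marks.peak_idx
    dbp = w.min()
    pp = w.max() - dbp
    out = {
        "tr": marks.pr_idx / sps,
        "sut": peak / sps,
        "dt": (len(wave) - peak) / sps,
    }
    for x in WIDTH_LEVELS_PCT:
        h = dbp + (x / 100.0) * pp
        i1, i2 = find_intersections(wave, h)
        sw = (peak - i1) / sps
        dw = (i2 - peak) / sps
        if sw < 0 or dw < 0:
            raise FeatureUndefinedError(
                f"crossings at {x}% of PP do not bracket the systolic peak"
            )
        out[f"sw{x}"] = sw
        out[f"dw{x}"] = dw
    return out


def feature_vector(
    wave: PulseWave,
    cal: CalibrationInfo,
    target_sbp: float | None = None,
    target_dbp: float | None = None,
) -> FeatureVector:
    """Assemble the 25 regression inputs (plus optional ground-truth targets)."""
    feats = amplitude_features(wave)
    feats.update(timing_features(wave))
    return FeatureVector(
        **feats,
        age=float(cal.age),
        gender=cal.gender_encoded,
        height=float(cal.height),
        weight=float(cal.weight),
        target_sbp=target_sbp,
        target_dbp=target_dbp,
    )


def features_dataframe(vectors: list[FeatureVector]):
    """Stack feature vectors into the fixed-column DataFrame layout."""
    import pandas as pd

    rows = [v.to_dict() for v in vectors]
    df = pd.DataFrame(rows)
    return df[FEATURE_COLUMNS + ["target_sbp", "target_dbp"]]
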