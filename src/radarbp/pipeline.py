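"""End-to-end orchestration: raw frames -> DOA gate -> features -> BP.

The batch pipeline mirrors the acquisition loop of the wearable: estimate the
arrival angle and abort with a repositioning message when the radar is not
over the artery (outside +-10 degrees), extract the displacement trace,
correct inversion, segment beats, filter by correlation against the
reference wave, calibrate with the one-time cuff pair, extract the feature
table, and optionally predict (SBP, DBP) with a trained network.

Every artifact written to disk embeds a hash of the generating configuration
so a rerun can detect config drift.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from radarbp import displacement as disp_mod
from radarbp import pulse_analysis as pa
from radarbp.doa import DoaScan, estimate_doa
from radarbp.radar_params import RadarConfig
from radarbp.regression import FeedForwardNet, apply_normalization
from radarbp.synthetic import (
    FEATURE_COLUMNS,
    DisplacementTrace,
    PulseModelParams,
    RawFrameSet,
    SceneParams,
    synth_displacement,
    synth_raw_frames,
)

logger = logging.getLogger("radarbp")

__all__ = ["PipelineConfig", "PipelineResult", "PlacementError",
           "run_pipeline", "config_hash"]


class PlacementError(RuntimeError):
    """The estimated arrival angle is outside the placement window."""


@dataclass
class PipelineConfig:
    radar: RadarConfig = field(default_factory=RadarConfig)
    pulse: PulseModelParams = field(default_factory=PulseModelParams)
    scene: SceneParams = field(default_factory=SceneParams)
    duration_s: float = 60.0
    threshold: float = 0.8
    calibration: pa.CalibrationInfo | None = None
    reference_length: int = 250
    n_reference_waves: int = 5
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("correlation threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    doa: DoaScan
    trace: DisplacementTrace
    inverted: bool
    waves: list
    features: pd.DataFrame
    counts: dict
    predictions: pd.DataFrame | None = None


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full pipeline configuration."""

    def _default(obj):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, complex):
            return [obj.real, obj.imag]
        raise TypeError(type(obj))

    blob = json.dumps(config, default=_default, sort_keys=True)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(
    config: PipelineConfig,
    frames: RawFrameSet | None = None,
    reference: pa.ReferenceWave | None = None,
    model: FeedForwardNet | None = None,
    model_bounds: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full chain on supplied or freshly simulated frames.

    Aborts with :class:`PlacementError` when the DOA falls outside the
    +-10 degree window (the radar must be shifted over the artery).  When no
    reference wave is supplied, the first ``n_reference_waves`` segmented
    beats build it.  With a trained ``model`` (and its normalization bounds),
    per-beat (SBP, DBP) predictions are returned.
    """
    chash = config_hash(config)
    if frames is None:
        sps = 1.0 / config.radar.prt
        trace_in = synth_displacement(
            config.pulse, duration=config.duration_s, rate=sps,
            seed=config.scene.seed,
        )
        frames = synth_raw_frames(config.radar, config.scene, trace_in)
    logger.info("frames: %d (config %s)", frames.n_frames, chash)

    scan = estimate_doa(frames)
    logger.info("doa: %.0f deg, placement_ok=%s", scan.doa_deg, scan.placement_ok)
    if not scan.placement_ok:
        raise PlacementError(
            f"estimated DOA {scan.doa_deg:.0f} deg outside +-10 deg: "
            "shift the radar over the radial artery and re-acquire"
        )

    trace = disp_mod.extract_displacement(frames)
    inverted = pa.detect_inversion(trace)
    if inverted:
        trace = DisplacementTrace(samples=-trace.samples, rate=trace.rate,
                                  times=trace.times)
        logger.info("waveform series inverted; multiplied by -1")

    waves = pa.segment_waves(trace)
    n_segmented = len(waves)
    if not waves:
        raise RuntimeError("no pulse waves segmented: signal quality too low")

    if reference is None:
        reference = pa.build_reference(
            waves[: config.n_reference_waves], length=config.reference_length
        )
    waves = pa.label_waves(waves, reference, threshold=config.threshold)
    usable = [w for w in waves if w.usable]
    n_discarded = n_segmented - len(usable)
    if not usable:
        raise RuntimeError("no usable pulse waves above the correlation threshold")

    cal = config.calibration or pa.CalibrationInfo(
        ref_sys=120.0, ref_dia=80.0, age=35.0, gender="female",
        height=170.0, weight=65.0,
    )
    sf = pa.compute_scaling_factor(usable[0], cal.ref_sys, cal.ref_dia)
    cal.scaling_factor = sf

    vectors = []
    n_feature_failures = 0
    for w in usable:
        calibrated = pa.calibrate_wave(w, sf)
        try:
            vectors.append(pa.feature_vector(calibrated, cal))
        except pa.FeatureUndefinedError as exc:
            n_feature_failures += 1
            logger.warning("wave at %d dropped: %s", w.start_index, exc)
    features = (pa.features_dataframe(vectors) if vectors
                else pd.DataFrame(columns=FEATURE_COLUMNS))

    counts = {
        "n_segmented": n_segmented,
        "n_usable": len(usable),
        "n_discarded_by_correlation": n_discarded,
        "n_dropped_by_feature_failure": n_feature_failures,
        "n_feature_rows": len(features),
    }
    assert counts["n_segmented"] == (counts["n_usable"]
                                     + counts["n_discarded_by_correlation"])
    logger.info("wave accounting: %s", counts)

    predictions = None
    if model is not None:
        table = features[FEATURE_COLUMNS]
        if model_bounds is not None:
            table = apply_normalization(table, model_bounds)
        pred = model.predict(table.to_numpy(dtype=float))
        predictions = pd.DataFrame(pred, columns=["sbp_pred", "dbp_pred"])

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(
            pd.DataFrame({"time_s": trace.times, "displacement_um": trace.samples}),
            out / "displacement.csv", chash,
        )
        _write_csv(features, out / "features.csv", chash)
        (out / "run.json").write_text(json.dumps(
            {"config_hash": chash, "doa_deg": scan.doa_deg,
             "inverted": inverted, **counts}, indent=2))
        if predictions is not None:
            _write_csv(predictions, out / "predictions.csv", chash)

    return PipelineResult(doa=scan, trace=trace, inverted=inverted, waves=waves,
                          features=features, counts=counts,
                          predictions=predictions)
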