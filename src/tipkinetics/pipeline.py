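"""End-to-end orchestration: stack -> masks -> trajectory -> tip trace -> correlations.

`analyze_stack` runs the single-tube measurement chain in memory;
`run_pipeline` wraps it with file I/O, writing every artifact (masks,
trajectory, tip trace, correlation curves, peaks, run log) to an output
directory.  All computation happens before any file is written, so a failing
input leaves no partial outputs behind.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import CorrelationCurve, PeakEstimate, autocorrelation, cohort_peak, cross_correlation
from .exceptions import FitError, TipKineticsError
from .io import RunConfig, read_stack, write_csv
from .kinematics import TipTrace, build_tip_trace, fit_gaussian, sample_tip_profile
from .segmentation import (
    GrowthTrajectory,
    SegmentationConfig,
    extract_trajectory,
    locate_tip,
    segment_frame,
    time_projection,
)
from .stack import TimeLapseStack

__all__ = ["StackAnalysis", "analyze_stack", "correlate_traces", "run_pipeline"]


@dataclass
class StackAnalysis:
    """Everything measured from one time-lapse stack."""

    trajectory: GrowthTrajectory
    masks: np.ndarray  # (t, r, c) bool
    trace: TipTrace
    s_tip: np.ndarray  # mask-based tip arc length per frame, um


def analyze_stack(
    stack: TimeLapseStack,
    config: RunConfig | None = None,
    tube_id: str = "tube",
) -> StackAnalysis:
    """Measure tip position, wall thickness, and velocity for one stack.

    Stages: per-frame segmentation; trajectory from the segmented time
    projection (base end resolved by the first frame's mask centroid); per
    frame, the mask-based tip centers a profile window whose Gaussian fit
    yields the tip midpoint and wall thickness; midpoints are differentiated
    into velocity; smoothed/detrended series are attached for correlation.
    """
    config = (config or RunConfig()).validate()
    seg_cfg = SegmentationConfig(
        smooth_sigma_px=config.smooth_sigma_px, close_radius_um=config.close_radius_um
    )
    masks = np.stack(
        [segment_frame(f, stack.pixel_size, seg_cfg) for f in stack.frames]
    )
    projection = time_projection(stack)
    proj_mask = segment_frame(projection, stack.pixel_size, seg_cfg)
    first_centroid = np.argwhere(masks[0]).mean(axis=0)
    trajectory = extract_trajectory(
        proj_mask,
        stack.pixel_size,
        base_hint=tuple(first_centroid),
        spur_len_px=config.spur_len_px,
        extend="both",
    )
    n = stack.n_frames
    s_tip = np.empty(n)
    centers = np.full(n, np.nan)
    sigmas = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for t in range(n):
        s_tip[t] = locate_tip(masks[t], trajectory)
        try:
            prof = sample_tip_profile(
                stack.frames[t],
                trajectory,
                s_tip[t],
                half_window_um=config.half_window_um,
                width_px=config.profile_width_px,
            )
            fit = fit_gaussian(prof)
        except TipKineticsError:
            continue
        centers[t] = fit.center
        sigmas[t] = fit.sigma
        ok[t] = True
    trace = build_tip_trace(
        stack.times,
        centers,
        sigmas,
        ok,
        window=config.window,
        detrend=config.detrend,
        tube_id=tube_id,
    )
    return StackAnalysis(trajectory=trajectory, masks=masks, trace=trace, s_tip=s_tip)


def correlate_traces(traces, config: RunConfig | None = None):
    """Cohort auto/cross-correlation curves and refined peak estimates.

    Returns a dict with per-tube and averaged curves plus PeakEstimates for
    the velocity autocorrelation period peak and the thickness-leads-velocity
    cross-correlation peak.
    """
    config = (config or RunConfig()).validate()
    autos, crosses = [], []
    for tr in traces:
        autos.append(autocorrelation(tr.smoothed_velocity, tr.dt, config.max_lag_s))
        crosses.append(
            cross_correlation(tr.smoothed_thickness, tr.smoothed_velocity, tr.dt, config.max_lag_s)
        )
    auto_avg, auto_peak = cohort_peak(autos)
    cross_avg, cross_peak = cohort_peak(crosses)
    return {
        "auto_curves": autos,
        "cross_curves": crosses,
        "auto_avg": auto_avg,
        "cross_avg": cross_avg,
        "auto_peak": auto_peak,
        "cross_peak": cross_peak,
    }


def _curve_frame(curve: CorrelationCurve) -> pd.DataFrame:
    return pd.DataFrame({"lag_s": curve.lags, "value": curve.values, "n": curve.n_tubes})


def run_pipeline(stack_path, config: RunConfig, out_dir=None, tube_id: str = "tube") -> dict:
    """Run the full measurement chain on one stack and write all artifacts.

    Writes trajectory.csv, tip_trace.csv, autocorrelation.csv,
    cross_correlation.csv, peaks.json and run_log.json under ``out_dir``.
    Returns the paths written.
    """
    config = config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    stack = read_stack(stack_path)
    analysis = analyze_stack(stack, config, tube_id=tube_id)
    corr = correlate_traces([analysis.trace], config)

    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    traj = analysis.trajectory
    paths["trajectory"] = out / "trajectory.csv"
    write_csv(
        pd.DataFrame(
            {
                "index": np.arange(len(traj.points)),
                "row": traj.points[:, 0],
                "col": traj.points[:, 1],
                "arclength_um": traj.arclength,
            }
        ),
        paths["trajectory"],
    )
    paths["tip_trace"] = out / "tip_trace.csv"
    write_csv(analysis.trace.to_frame(), paths["tip_trace"])
    paths["autocorrelation"] = out / "autocorrelation.csv"
    write_csv(_curve_frame(corr["auto_avg"]), paths["autocorrelation"])
    paths["cross_correlation"] = out / "cross_correlation.csv"
    write_csv(_curve_frame(corr["cross_avg"]), paths["cross_correlation"])
    paths["peaks"] = out / "peaks.json"
    peaks = {
        "autocorrelation": _peak_dict(corr["auto_peak"]),
        "cross_correlation": _peak_dict(corr["cross_peak"]),
    }
    paths["peaks"].write_text(json.dumps(peaks, indent=2, sort_keys=True))
    paths["run_log"] = out / "run_log.json"
    paths["run_log"].write_text(
        json.dumps(
            {
                "package_version": __version__,
                "config": config.to_dict(),
                "config_digest": config.digest(),
                "seed": config.seed,
                "stack": str(stack_path),
                "n_frames": int(stack.n_frames),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths


def _peak_dict(peak: PeakEstimate) -> dict:
    return {"lag_s": peak.lag_s, "sem_s": peak.uncertainty_s, "n_tubes": peak.n_tubes}
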