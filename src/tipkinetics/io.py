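"""File formats and run configuration.

Stacks travel as multi-page TIFF plus a sidecar YAML/JSON carrying the
physical calibration (``pixel_size_um``, ``frame_interval_s``) — vendor TIFF
metadata dialects vary too much to parse reliably.  Tables are CSV with a
header row, UTF-8, "." decimal, floats printed with 9 significant digits so
outputs are bit-stable across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ParameterError
from .stack import TimeLapseStack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_csv",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run; round-trips through YAML."""

    pixel_size_um: float = 0.2
    frame_interval_s: float = 1.0
    smooth_sigma_px: float = 1.0
    close_radius_um: float = 5.0
    spur_len_px: float | None = None  # None = library default (5 px)
    window: int = 11
    detrend: str = "mean"
    half_window_um: float = 3.0
    profile_width_px: int = 3
    max_lag_s: float = 60.0
    tip_roi_um: float = 5.0
    shank_roi_um: float = 60.0
    profile_length_um: float = 30.0
    apex_window_um: float = 15.0
    seed: int = 0
    out_dir: str = "results"

    def validate(self) -> "RunConfig":
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "half_window_um",
            "max_lag_s",
            "tip_roi_um",
            "shank_roi_um",
            "profile_length_um",
        ):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be > 0; got {getattr(self, name)}")
        if self.window % 2 == 0 or self.window < 1:
            raise ParameterError(f"window must be odd and positive; got {self.window}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _read_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_stack(path, sidecar=None) -> TimeLapseStack:
    """Read a multi-page TIFF and its calibration sidecar.

    ``sidecar`` defaults to ``<stem>.yaml`` (or ``.json``) next to the TIFF
    and must define ``pixel_size_um`` and ``frame_interval_s``.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if sidecar is None:
        for ext in (".yaml", ".yml", ".json"):
            cand = path.with_suffix(ext)
            if cand.exists():
                sidecar = cand
                break
    if sidecar is None:
        raise ParameterError(
            f"no calibration sidecar found for {path.name}: create {path.stem}.yaml "
            "with pixel_size_um and frame_interval_s"
        )
    meta = _read_sidecar(Path(sidecar))
    for key in ("pixel_size_um", "frame_interval_s"):
        if key not in meta:
            raise ParameterError(
                f"sidecar {sidecar} missing {key!r}: add it (micrometres per pixel / "
                "seconds per frame)"
            )
    return TimeLapseStack(
        frames=np.asarray(frames, dtype=float),
        pixel_size=float(meta["pixel_size_um"]),
        dt=float(meta["frame_interval_s"]),
        metadata=dict(meta),
    )


def write_stack(stack: TimeLapseStack, path, sidecar=None, dtype=None) -> None:
    """Write a stack as multi-page TIFF plus a YAML sidecar.

    ``dtype`` may quantize to an integer type (e.g. ``np.uint8``); by default
    the float data are written unchanged.
    """
    path = Path(path)
    frames = stack.frames
    if dtype is not None:
        info = np.iinfo(dtype)
        lo, hi = frames.min(), frames.max()
        scale = (info.max - info.min) / (hi - lo) if hi > lo else 1.0
        frames = ((frames - lo) * scale + info.min).astype(dtype)
    tifffile.imwrite(path, frames)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yaml")
    meta = {
        "pixel_size_um": float(stack.pixel_size),
        "frame_interval_s": float(stack.dt),
        **{k: v for k, v in stack.metadata.items() if isinstance(v, (int, float, str, bool))},
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))


def write_csv(df: pd.DataFrame, path) -> None:
    """CSV with stable 9-significant-digit float formatting."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
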