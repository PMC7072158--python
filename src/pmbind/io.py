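"""File I/O: TIFF images and stacks, tabular CSV schemas, JSON sidecars.

In-memory intensities are nonnegative floats; on export images are
quantized to 16-bit unsigned integers (the common confocal bit depth),
clipping at the dtype range.  Each image writer can drop a JSON sidecar
with the generating parameters and ground truth next to the TIFF.

CSV schemas
-----------
sensorgram : ``time_s, response_RU, phase, conc_M``
isotherm   : ``conc_M, Req_RU``
gel lanes  : ``lane, supernatant, pellet``
localization results : ``cell_id, frame, I_PM, I_Cyt, pm_index, percent_pm``
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .binding import GelLane, IsothermData, Sensorgram
from .imaging import Image
from .metrics import LocalizationResult
from .synthetic import ImageStack

PathLike = Union[str, Path]


def _quantize16(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.round(pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)


def write_image_tiff(path: PathLike, image: Image,
                     sidecar: Optional[dict] = None) -> None:
    """Write a single image as 16-bit TIFF, with optional JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, _quantize16(image.pixels),
                     resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size))
    if sidecar is not None:
        write_sidecar(path.with_suffix(".json"), sidecar)


def write_stack_tiff(path: PathLike, stack: ImageStack,
                     sidecar: Optional[dict] = None) -> None:
    """Write a time-lapse stack as multi-page 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, _quantize16(stack.frames), photometric="minisblack")
    if sidecar is not None:
        write_sidecar(path.with_suffix(".json"), sidecar)


def read_image_tiff(path: PathLike, pixel_size: float,
                    channel: str = "") -> Image:
    """Read a single-page TIFF as an :class:`~pmbind.imaging.Image`."""
    px = tifffile.imread(str(path)).astype(float)
    if px.ndim == 3:
        raise ValueError("multi-page TIFF: use read_stack_tiff")
    return Image(px, pixel_size=pixel_size, channel=channel)


def read_stack_tiff(path: PathLike, pixel_size: float, frame_interval: float,
                    channel: str = "") -> ImageStack:
    """Read a multi-page TIFF as an :class:`~pmbind.synthetic.ImageStack`."""
    frames = tifffile.imread(str(path)).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, pixel_size=pixel_size,
                      frame_interval=frame_interval, channel=channel)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return None if obj.ndim > 1 else obj.tolist()  # masks are too big for sidecars
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def sensorgram_to_frame(sg: Sensorgram) -> pd.DataFrame:
    return pd.DataFrame({"time_s": sg.time, "response_RU": sg.response,
                         "phase": sg.phase, "conc_M": sg.analyte_conc})


def write_sensorgram_csv(path: PathLike, sg: Sensorgram) -> None:
    sensorgram_to_frame(sg).to_csv(path, index=False)


def read_sensorgram_csv(path: PathLike) -> Sensorgram:
    df = pd.read_csv(path)
    concs = df["conc_M"].unique()
    if len(concs) != 1:
        raise ValueError("sensorgram CSV must hold a single concentration")
    return Sensorgram(df["time_s"].to_numpy(), df["response_RU"].to_numpy(),
                      df["phase"].to_numpy(dtype=object), float(concs[0]))


def write_isotherm_csv(path: PathLike, data: IsothermData) -> None:
    pd.DataFrame({"conc_M": data.conc, "Req_RU": data.Req}).to_csv(path, index=False)


def read_isotherm_csv(path: PathLike) -> IsothermData:
    df = pd.read_csv(path)
    return IsothermData(df["conc_M"].to_numpy(), df["Req_RU"].to_numpy())


def write_gel_lanes_csv(path: PathLike, lanes: Sequence[GelLane]) -> None:
    pd.DataFrame([{"lane": l.lane_id, "supernatant": l.supernatant,
                   "pellet": l.pellet} for l in lanes]).to_csv(path, index=False)


def read_gel_lanes_csv(path: PathLike) -> list:
    df = pd.read_csv(path)
    return [GelLane(lane_id=str(r["lane"]), supernatant=float(r["supernatant"]),
                    pellet=float(r["pellet"])) for _, r in df.iterrows()]


def localization_results_to_frame(
    results: Iterable[tuple],
) -> pd.DataFrame:
    """Tabulate ``(cell_id, frame, LocalizationResult)`` tuples as tidy CSV rows."""
    rows = []
    for cell_id, frame, res in results:
        rows.append({"cell_id": cell_id, "frame": frame, "I_PM": res.I_PM,
                     "I_Cyt": res.I_Cyt, "pm_index": res.pm_index,
                     "percent_pm": res.percent_pm})
    return pd.DataFrame(rows)
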