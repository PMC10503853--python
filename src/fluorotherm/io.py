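"""On-disk formats: TIFF images, JSON sidecars, calibration records.

Temperature fields are single-page 32-bit float TIFFs; fluorescent images are
multi-page 16-bit grayscale TIFFs (one page per channel). Every array carries
a ``<stem>.json`` sidecar holding provenance (generator, parameters, seed,
``t_range``, pixel pitch, channel names). Binary masks are written as PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .fieldgen import TemperatureField, _jsonable
from .photophysics import CalibrationModel, FluorescentImage

__all__ = [
    "write_field",
    "read_field",
    "write_image",
    "read_image",
    "write_calibration",
    "read_calibration",
    "write_mask",
    "read_mask",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_field(field: TemperatureField, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, field.values.astype(np.float32))
    meta: dict[str, Any] = {"pitch_um": field.pitch_um, **_jsonable(field.meta)}
    meta.pop("coverage", None)  # stitching coverage maps are arrays; not sidecar data
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_field(path: str | Path) -> TemperatureField:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    meta: dict[str, Any] = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    pitch = float(meta.pop("pitch_um", 1.0))
    return TemperatureField(values=values, pitch_um=pitch, meta=meta)


def write_image(image: FluorescentImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.round(image.channels).astype(np.uint16))
    meta = {
        "channel_names": image.channel_names,
        "bit_depth": image.bit_depth,
        **_jsonable(image.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_image(path: str | Path) -> FluorescentImage:
    path = Path(path)
    channels = tifffile.imread(path).astype(np.float64)
    if channels.ndim == 2:
        channels = channels[None]
    meta: dict[str, Any] = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    names = meta.pop("channel_names", [])
    meta.setdefault("quantized", True)
    return FluorescentImage(channels=channels, channel_names=names, meta=meta)


def write_calibration(cal: CalibrationModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "coeffs": cal.coeffs.tolist(),
        "t_range": list(cal.t_range),
        "scale_anchors": list(cal.scale_anchors),
        "channel_names": cal.channel_names,
        "monotone": np.asarray(cal.monotone).tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_calibration(path: str | Path) -> CalibrationModel:
    payload = json.loads(Path(path).read_text())
    return CalibrationModel(
        coeffs=np.asarray(payload["coeffs"]),
        t_range=tuple(payload["t_range"]),
        scale_anchors=tuple(payload["scale_anchors"]),
        channel_names=payload["channel_names"],
        monotone=np.asarray(payload["monotone"], dtype=bool),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    path = Path(path)
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(path)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path)) > 0
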