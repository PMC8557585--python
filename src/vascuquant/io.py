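"""File I/O: images, ROI/field annotations, and headered CSV tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .ihc import SamplingRect
from .roi import RoiPolygon


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF as a 2-D uint8 array."""
    img = iio.imread(path)
    if img.ndim == 3:  # tolerate gray saved as RGB(A)
        img = img[..., :3].mean(axis=2)
    return np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Read an RGB PNG/TIFF as an HxWx3 uint8 array."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale or RGB image, quantizing floats to 8 bit."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 1-bit PNG."""
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("1"), dtype=bool)


# ---------------------------------------------------------------------------
# annotations

def write_rois(path: str | Path, rois: Iterable[RoiPolygon]) -> None:
    payload = {"rois": [{"role": r.role, "plane": r.plane,
                         "vertices": [list(v) for v in r.vertices]}
                        for r in rois]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> list[RoiPolygon]:
    payload = json.loads(Path(path).read_text())
    return [RoiPolygon(r["vertices"], role=r["role"], plane=r["plane"])
            for r in payload["rois"]]


def write_fields(path: str | Path, fields_100x: Iterable[SamplingRect],
                 field_25x: SamplingRect) -> None:
    def enc(rect: SamplingRect) -> dict[str, Any]:
        return {"row": rect.top_left[0], "col": rect.top_left[1],
                "height_px": rect.height_px, "width_px": rect.width_px}
    payload = {"fields_100x": [enc(r) for r in fields_100x],
               "field_25x": enc(field_25x)}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fields(path: str | Path) -> tuple[list[SamplingRect], SamplingRect]:
    payload = json.loads(Path(path).read_text())

    def dec(obj: Mapping[str, Any], mag: str) -> SamplingRect:
        return SamplingRect(top_left=(int(obj["row"]), int(obj["col"])),
                            height_px=int(obj.get("height_px", 1443)),
                            width_px=int(obj.get("width_px", 1440)),
                            magnification=mag)
    fields = [dec(o, "x100") for o in payload["fields_100x"]]
    return fields, dec(payload["field_25x"], "x25")


# ---------------------------------------------------------------------------
# tables

def config_hash(config: Mapping[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(path: str | Path, frame: pd.DataFrame, *,
                seed: int | None = None, cfg_hash: str | None = None) -> None:
    """Write a CSV with a provenance header comment (seed + config hash)."""
    path = Path(path)
    header = f"# vascuquant seed={seed} config={cfg_hash}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
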