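"""File I/O: 32-bit float TIFF images with JSON sidecar metadata.

Tomograms and sinograms are written as float32 TIFF; boolean masks as
8-bit TIFF (0/255).  Geometry and kind metadata live in a sidecar
``<path>.json``.  A missing sidecar falls back to documented defaults
(pitch 1 μm, uniform angles over [0°, 180°), kind guesses) with a logged
warning — explicit sidecar values always take precedence.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile

from .grids import Sinogram, TomogramGrid

logger = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_tomogram(path, grid: TomogramGrid) -> None:
    path = Path(path)
    tifffile.imwrite(path, grid.values.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {"type": "tomogram", "pixel_pitch": grid.pixel_pitch, "value_kind": grid.value_kind},
            indent=1,
        )
    )


def read_tomogram(path) -> TomogramGrid:
    path = Path(path)
    values = tifffile.imread(path)
    meta = _read_meta(path, {"pixel_pitch": 1.0, "value_kind": "reconstruction"})
    return TomogramGrid(values, float(meta["pixel_pitch"]), meta["value_kind"])


def write_sinogram(path, sino: Sinogram) -> None:
    path = Path(path)
    tifffile.imwrite(path, sino.values.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps(
            {
                "type": "sinogram",
                "xi_pitch": sino.xi_pitch,
                "angles": sino.angles.tolist(),
                "kind": sino.kind,
            },
            indent=1,
        )
    )


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    values = tifffile.imread(path)
    n_theta = values.shape[1]
    defaults = {
        "xi_pitch": 1.0,
        "angles": np.linspace(0.0, 180.0, n_theta, endpoint=False).tolist(),
        "kind": "line_integral",
    }
    meta = _read_meta(path, defaults)
    return Sinogram(values, float(meta["xi_pitch"]), np.asarray(meta["angles"]), meta["kind"])


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def _read_meta(path: Path, defaults: dict) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        logger.warning("no sidecar %s; applying defaults %s", sc.name, defaults)
        return dict(defaults)
    meta = dict(defaults)
    meta.update(json.loads(sc.read_text()))
    return meta
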