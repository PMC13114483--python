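"""Image and metadata I/O.

Labels travel as 8-bit RGB PNG; intensity and coefficient maps as 32-bit
float TIFF (a 16-bit integer export mode mimics camera output).  Scene
metadata (pixel size, spatial frequency) rides in a JSON sidecar next to
each image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "read_sidecar", "write_sidecar"]


def write_image(path, array, bit_depth: str = "float32", metadata: dict | None = None):
    """Write an image; format chosen by suffix (.png 8-bit RGB, .tif float).

    ``bit_depth`` for TIFF may be ``"float32"`` or ``"uint16"`` (intensities
    scaled by 65535 into the camera's integer range).
    """
    path = Path(path)
    array = np.asarray(array)
    if path.suffix.lower() == ".png":
        if array.dtype != np.uint8:
            raise ValueError("PNG export expects uint8 data")
        Image.fromarray(array).save(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        if bit_depth == "float32":
            tifffile.imwrite(path, array.astype(np.float32))
        elif bit_depth == "uint16":
            tifffile.imwrite(
                path, np.clip(array * 65535.0, 0, 65535).astype(np.uint16)
            )
        else:
            raise ValueError(f"unsupported bit depth {bit_depth!r}")
    else:
        raise ValueError(f"unsupported image suffix {path.suffix!r}")
    if metadata is not None:
        write_sidecar(path, metadata)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        return np.asarray(Image.open(path))
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    raise ValueError(f"unsupported image suffix {path.suffix!r}")


def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_sidecar(image_path, metadata: dict) -> None:
    _sidecar_path(image_path).write_text(json.dumps(metadata, indent=1))


def read_sidecar(image_path) -> dict:
    return json.loads(_sidecar_path(image_path).read_text())
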