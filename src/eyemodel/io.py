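"""File I/O: grayscale images, contour/axis/profile JSON, click lists."""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .contour import ContourPolyline
from .errors import InvalidArgumentError
from .spline import SplineProfile
from .symmetry import SymmetryAxis
from .synthetic import GroundTruth, SliceImage


def write_image(image: SliceImage, path: str) -> None:
    """Write a slice image as 8-bit grayscale PNG or 16-bit TIFF."""
    path = str(path)
    if path.lower().endswith(".png"):
        iio.imwrite(path, np.round(image.pixels * 255).astype(np.uint8))
    elif path.lower().endswith((".tif", ".tiff")):
        iio.imwrite(path, np.round(image.pixels * 65535).astype(np.uint16))
    else:
        raise InvalidArgumentError("image format must be .png or .tif(f)")


def read_image(path: str, pixel_size: float | None = None) -> SliceImage:
    """Read a grayscale PNG/TIFF and normalise intensities to [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    if np.issubdtype(iio.imread(path).dtype, np.integer):
        arr = arr / np.iinfo(iio.imread(path).dtype).max
    elif arr.max() > 1.0:
        arr = arr / arr.max()
    return SliceImage(np.clip(arr, 0.0, 1.0), pixel_size=pixel_size)


def write_contours(contours: list[ContourPolyline], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({"contours": [c.to_dict() for c in contours]}, fh)


def read_contours(path: str) -> list[ContourPolyline]:
    with open(path) as fh:
        d = json.load(fh)
    return [ContourPolyline.from_dict(c) for c in d["contours"]]


def write_contour_csv(contour: ContourPolyline, path: str) -> None:
    np.savetxt(path, contour.points, delimiter=",", header="x,y", comments="")


def write_axis(axis: SymmetryAxis, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(axis.to_dict(), fh)


def read_axis(path: str) -> SymmetryAxis:
    with open(path) as fh:
        return SymmetryAxis.from_dict(json.load(fh))


def write_profile(profile: SplineProfile, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(profile.to_dict(), fh)


def read_profile(path: str) -> SplineProfile:
    with open(path) as fh:
        return SplineProfile.from_dict(json.load(fh))


def read_clicks(path: str) -> np.ndarray:
    """Read a 2-column (x, y) click list CSV, with or without a header."""
    try:
        pts = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if pts.shape[1] != 2:
        raise InvalidArgumentError("click list must have two columns (x, y)")
    return pts


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    d = {"axis": truth.axis.to_dict(),
         "params": truth.params,
         "contours": {k: c.to_dict() for k, c in truth.contours.items()}}
    with open(path, "w") as fh:
        json.dump(d, fh)


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)
    return GroundTruth(
        contours={k: ContourPolyline.from_dict(c)
                  for k, c in d["contours"].items()},
        axis=SymmetryAxis.from_dict(d["axis"]),
        params=d.get("params", {}))
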