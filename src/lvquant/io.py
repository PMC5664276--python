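"""Readers and writers for short-axis images, contours, masks and result tables.

Supported image formats are NIfTI-1 (via nibabel), TIFF (via tifffile) and
PNG (via imageio).  Contours travel as long-format CSV, results as TSV.

Coordinate convention: 0-based, ``x`` = column, ``y`` = row, pixel centers
at integer coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

#: default in-plane pixel spacing in mm (30 mm field of view over a 256 matrix)
DEFAULT_PIXEL_SPACING = 30.0 / 256.0

#: fallback metadata pattern: ``<subject>_<modality>_s<slice>.<ext>``
_FILENAME_RE = re.compile(r"^(?P<subject>[^_]+)_(?P<modality>[^_]+)_s(?P<slice>\d+)$")


@dataclass
class ShortAxisImage:
    """One 2D grayscale short-axis slice plus study metadata.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities.
    pixel_spacing
        In-plane pixel size in mm.
    subject_id, slice_index, modality
        Study labels; free-form strings / integer slice position.
    """

    pixels: np.ndarray
    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    subject_id: str = ""
    slice_index: int = 0
    modality: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ContourSet:
    """Epicardial and endocardial boundary polygons of one slice.

    Polygons are ordered ``(x, y)`` vertex arrays in pixel coordinates and
    are treated as implicitly closed.  The endocardium must lie strictly
    inside the epicardium.
    """

    epicardium: np.ndarray
    endocardium: np.ndarray

    def __post_init__(self) -> None:
        for name in ("epicardium", "endocardium"):
            poly = np.asarray(getattr(self, name), dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array of (x, y) vertices")
            # drop an explicit closing vertex
            if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(np.unique(poly, axis=0)) < 3:
                raise ValueError(f"{name} needs >= 3 distinct vertices")
            setattr(self, name, poly)
        if not _polygon_inside(self.endocardium, self.epicardium):
            raise ValueError("endocardium is not strictly inside the epicardium")


def _polygon_inside(inner: np.ndarray, outer: np.ndarray) -> bool:
    """True when every vertex of `inner` is strictly inside `outer` (even-odd)."""
    from lvquant.roi import points_in_polygon

    inside = points_in_polygon(inner, outer, boundary=False)
    return bool(np.all(inside))


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _metadata_from_name(path: Path) -> dict:
    m = _FILENAME_RE.match(path.name.split(".")[0])
    if m is None:
        return {}
    return {
        "subject_id": m.group("subject"),
        "modality": m.group("modality"),
        "slice_index": int(m.group("slice")),
    }


def read_image(path: str | Path, fmt: str | None = None) -> ShortAxisImage | list[ShortAxisImage]:
    """Read a NIfTI-1 / TIFF / PNG image as one or more :class:`ShortAxisImage`.

    A 3D volume is split into a list of 2D slices along the last axis.
    Subject/modality/slice metadata is recovered from the filename pattern
    ``<subject>_<modality>_s<slice>.<ext>`` when it matches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    fmt = fmt or _guess_format(path)
    try:
        if fmt == "nifti":
            data = np.asarray(nib.load(str(path)).dataobj)
        elif fmt == "tiff":
            data = tifffile.imread(str(path))
        elif fmt == "png":
            data = iio.imread(str(path))
        else:
            raise ValueError(f"unsupported image format {fmt!r}")
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # noqa: BLE001 - reader-specific parse failures
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc

    meta = _metadata_from_name(path)
    data = np.squeeze(np.asarray(data))
    if data.ndim == 2:
        return ShortAxisImage(data, **meta)
    if data.ndim == 3:
        # NIfTI stacks slices on the last axis, multipage TIFF on the first
        axis = 2 if fmt == "nifti" else 0
        slices = np.moveaxis(data, axis, 0)
        out = []
        for i, sl in enumerate(slices):
            m = dict(meta)
            m.setdefault("slice_index", i)
            if "slice_index" in meta:
                m["slice_index"] = meta["slice_index"] + i
            out.append(ShortAxisImage(np.asarray(sl), **m))
        return out
    raise ValueError(f"{path}: expected a 2D slice or 3D volume, got shape {data.shape}")


def write_image(image: ShortAxisImage, path: str | Path, fmt: str | None = None) -> Path:
    """Write an image losslessly; integer data is preserved bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = fmt or _guess_format(path)
    px = image.pixels
    if fmt == "nifti":
        affine = np.diag([image.pixel_spacing, image.pixel_spacing, 1.0, 1.0])
        arr = px if np.issubdtype(px.dtype, np.integer) else px.astype(np.float32)
        nib.save(nib.Nifti1Image(arr, affine), str(path))
    elif fmt == "tiff":
        tifffile.imwrite(str(path), px)
    elif fmt == "png":
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("PNG output requires integer pixel data")
        iio.imwrite(str(path), px.astype(np.uint16 if px.max() > 255 else np.uint8))
    else:
        raise ValueError(f"unsupported image format {fmt!r}")
    return path


def _guess_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff"
    if suffixes.endswith(".png"):
        return "png"
    raise ValueError(f"cannot infer image format from {path.name!r}")


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

_CONTOUR_COLUMNS = ["subject", "slice", "structure", "point_index", "x", "y"]


def read_contours(path: str | Path) -> dict[tuple[str, int], ContourSet]:
    """Read a contour CSV into a ``(subject, slice) -> ContourSet`` map.

    Expected columns: subject, slice, structure in {epi, endo},
    point_index, x, y.  Polygons are ordered by point_index.
    """
    df = pd.read_csv(path)
    missing = set(_CONTOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contour file {path} lacks columns {sorted(missing)}")
    out: dict[tuple[str, int], ContourSet] = {}
    for (subject, sl), grp in df.groupby(["subject", "slice"], sort=True):
        polys = {}
        for structure, g in grp.groupby("structure"):
            g = g.sort_values("point_index")
            polys[structure] = g[["x", "y"]].to_numpy(dtype=float)
        if "epi" not in polys or "endo" not in polys:
            raise ValueError(
                f"subject {subject!r} slice {sl}: both 'epi' and 'endo' contours required"
            )
        cs = ContourSet(epicardium=polys["epi"], endocardium=polys["endo"])
        for name in ("epicardium", "endocardium"):
            if _self_intersects(getattr(cs, name)):
                warnings.warn(
                    f"subject {subject!r} slice {sl}: {name} polygon self-intersects",
                    stacklevel=2,
                )
        out[(str(subject), int(sl))] = cs
    return out


def write_contours(contours: dict[tuple[str, int], ContourSet], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for (subject, sl), cs in contours.items():
        for structure, poly in (("epi", cs.epicardium), ("endo", cs.endocardium)):
            for i, (x, y) in enumerate(poly):
                rows.append((subject, sl, structure, i, x, y))
    pd.DataFrame(rows, columns=_CONTOUR_COLUMNS).to_csv(path, index=False)
    return path


def _self_intersects(poly: np.ndarray) -> bool:
    try:
        from shapely.geometry import LinearRing

        return not LinearRing(poly).is_simple
    except ImportError:  # shapely is a test extra; skip the check without it
        return False


# ---------------------------------------------------------------------------
# study tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "subject",
    "slice",
    "modality",
    "method",
    "enhancement_pct",
    "threshold",
    "n_total",
    "n_enhanced",
]


def write_results_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format study table as TSV, one row per
    (subject, slice, modality, method)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows.copy()
    for col in TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=float)
    df = df[TABLE_COLUMNS + [c for c in df.columns if c not in TABLE_COLUMNS]]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
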