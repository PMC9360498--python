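"""Reading and writing of channel images, ROI annotations and result tables.

The pipeline's unit of acquisition is a field of view (FOV): one NADH image
and one Fp (oxidized flavoprotein) image taken of the same frame with a
widefield fluorescence microscope.  Intensities are kept in native camera
counts (arbitrary units) throughout — no normalisation to a reference
standard is applied at any stage.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left pixel center.
* A pixel belongs to a polygon ROI iff its *center* lies inside the polygon
  or exactly on its boundary.  Polygons must be simple (non
  self-intersecting); vertices are listed as ``(row, col)`` pairs.
* 14-bit camera data are stored in 16-bit TIFF containers with the true bit
  depth declared in metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import (
    ContractError,
    DimensionError,
    FormatError,
    GeometryError,
    InsufficientDataError,
    IntensityRangeError,
    LinkageError,
)

logger = logging.getLogger(__name__)

BackgroundSource = Literal["blank_roi", "blank_image", "global_mode"]

#: Default physical pixel edge (µm) of the acquisition system being modelled.
DEFAULT_PIXEL_SIZE_UM = 0.293
#: Default camera bit depth.
DEFAULT_BIT_DEPTH = 14


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background level and noise of one channel.

    ``mean`` is subtracted from raw intensities; ``noise_sd`` is the standard
    deviation of the background and the denominator of the pixel SNR.
    """

    mean: float
    noise_sd: float
    source: BackgroundSource = "blank_roi"

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ContractError(f"background mean must be >= 0, got {self.mean}")
        if not self.noise_sd > 0:
            raise ContractError(f"background noise_sd must be > 0, got {self.noise_sd}")


@dataclass
class RedoxField:
    """One FOV's paired NADH/Fp images plus acquisition metadata."""

    field_id: str
    dish_id: str
    nadh_image: np.ndarray
    fp_image: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = DEFAULT_BIT_DEPTH
    background_nadh: BackgroundEstimate | None = None
    background_fp: BackgroundEstimate | None = None

    def __post_init__(self) -> None:
        self.nadh_image = np.asarray(self.nadh_image)
        self.fp_image = np.asarray(self.fp_image)
        for name, img in (("nadh", self.nadh_image), ("fp", self.fp_image)):
            if img.ndim != 2:
                raise FormatError(
                    f"{name} image of field {self.field_id!r} is not a "
                    f"2-D single-channel image (ndim={img.ndim})"
                )
        if self.nadh_image.shape != self.fp_image.shape:
            raise DimensionError(
                f"field {self.field_id!r}: NADH shape {self.nadh_image.shape} "
                f"!= Fp shape {self.fp_image.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ContractError("pixel_size_um must be > 0")
        if self.bit_depth <= 0:
            raise ContractError("bit_depth must be a positive integer")
        top = float(2**self.bit_depth - 1)
        for name, img in (("nadh", self.nadh_image), ("fp", self.fp_image)):
            lo, hi = float(img.min(initial=0)), float(img.max(initial=0))
            if lo < 0 or hi > top:
                raise IntensityRangeError(
                    f"{name} intensities of field {self.field_id!r} fall outside "
                    f"[0, {top:.0f}] (observed [{lo}, {hi}])"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.nadh_image.shape


@dataclass
class CellAnnotation:
    """One cell's whole-cell and nucleus ROIs plus identity labels.

    ``cell_mask``/``nucleus_mask`` are full-frame boolean rasters.  The
    nucleus raster is always a subset of the cell raster (clipped on
    construction, with a warning when clipping removed pixels).
    """

    cell_id: str
    field_id: str
    dish_id: str
    cell_line: str
    receptor_group: str
    mitotic: bool
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise DimensionError(
                f"cell {self.cell_id!r}: cell mask shape {self.cell_mask.shape}"
                f" != nucleus mask shape {self.nucleus_mask.shape}"
            )
        if not self.cell_mask.any():
            raise GeometryError(f"cell {self.cell_id!r}: empty cell raster")
        outside = self.nucleus_mask & ~self.cell_mask
        if outside.any():
            logger.warning(
                "cell %s: clipping %d nucleus pixels outside the cell ROI",
                self.cell_id,
                int(outside.sum()),
            )
            self.nucleus_mask = self.nucleus_mask & self.cell_mask
        if not self.nucleus_mask.any():
            raise GeometryError(
                f"cell {self.cell_id!r}: nucleus raster empty after clipping to cell"
            )


# ---------------------------------------------------------------------------
# Field I/O
# ---------------------------------------------------------------------------


def _load_single_channel(path: str | Path) -> np.ndarray:
    try:
        img = tifffile.imread(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot decode TIFF {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim != 2:
        raise FormatError(
            f"{path}: expected a 2-D single-channel image, got shape {img.shape}"
        )
    return img


def read_field(
    nadh_path: str | Path,
    fp_path: str | Path,
    *,
    field_id: str,
    dish_id: str,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    bit_depth: int = DEFAULT_BIT_DEPTH,
    background_nadh: BackgroundEstimate | None = None,
    background_fp: BackgroundEstimate | None = None,
) -> RedoxField:
    """Read one FOV's paired NADH/Fp TIFFs into a :class:`RedoxField`.

    Intensities are preserved bit-exactly; validation (matching shapes,
    declared bit range) happens in the ``RedoxField`` constructor.
    """
    nadh = _load_single_channel(nadh_path)
    fp = _load_single_channel(fp_path)
    return RedoxField(
        field_id=field_id,
        dish_id=dish_id,
        nadh_image=nadh,
        fp_image=fp,
        pixel_size_um=pixel_size_um,
        bit_depth=bit_depth,
        background_nadh=background_nadh,
        background_fp=background_fp,
    )


def write_field(field_obj: RedoxField, nadh_path: str | Path, fp_path: str | Path) -> None:
    """Write both channels of a field to TIFF, bit-exactly.

    Integer-valued grids go out as uint16 (the container for <=16-bit camera
    data); anything else is written as float64 so a round trip is lossless.
    """
    for img, path in ((field_obj.nadh_image, nadh_path), (field_obj.fp_image, fp_path)):
        arr = np.asarray(img)
        if np.issubdtype(arr.dtype, np.integer) or (
            np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.round(arr))
        ):
            out = arr.astype(np.uint16)
        else:
            out = arr.astype(np.float64)
        tifffile.imwrite(str(path), out)


# ---------------------------------------------------------------------------
# ROI rasterization and annotation I/O
# ---------------------------------------------------------------------------


def rasterize_polygon(vertices: Sequence[tuple[float, float]], shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple closed polygon to a boolean mask.

    A pixel ``(r, c)`` is set iff its center lies inside the polygon or on
    its boundary.  ``vertices`` are ``(row, col)`` pairs; the polygon is
    implicitly closed.  The rule is deterministic: identical vertices yield
    identical rasters on every platform.
    """
    verts = [(float(r), float(c)) for r, c in vertices]
    if len(verts) < 3:
        raise GeometryError(f"polygon needs >= 3 vertices, got {len(verts)}")
    # shapely works in (x, y); map x=col, y=row.
    poly = Polygon([(c, r) for r, c in verts])
    if poly.is_empty or poly.area == 0:
        raise GeometryError("polygon has zero area")
    mask = np.zeros(shape, dtype=bool)
    rmin = max(int(np.floor(poly.bounds[1])), 0)
    rmax = min(int(np.ceil(poly.bounds[3])), shape[0] - 1)
    cmin = max(int(np.floor(poly.bounds[0])), 0)
    cmax = min(int(np.ceil(poly.bounds[2])), shape[1] - 1)
    if rmin > rmax or cmin > cmax:
        return mask
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    inside = shapely.intersects_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    mask[rmin : rmax + 1, cmin : cmax + 1] = inside.reshape(rr.shape)
    return mask


def _parse_vertices(text: str) -> list[tuple[float, float]]:
    pts = []
    for tok in str(text).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        r, c = tok.split(":")
        pts.append((float(r), float(c)))
    return pts


def format_vertices(vertices: Iterable[tuple[float, float]]) -> str:
    """Inverse of the polygon-record vertex encoding (``r:c;r:c;...``)."""
    return ";".join(f"{r:g}:{c:g}" for r, c in vertices)


def read_annotations(
    path: str | Path, fields: Iterable[RedoxField]
) -> list[CellAnnotation]:
    """Read polygon ROI records and rasterize them against their fields.

    The file is a CSV with one row per ROI and columns
    ``cell_id, field_id, dish_id, cell_line, receptor_group, mitotic,
    roi_kind, vertices`` where ``roi_kind`` is ``cell`` or ``nucleus`` and
    ``vertices`` encodes ``(row, col)`` pairs as ``r0:c0;r1:c1;...``.
    Every cell needs exactly one row of each kind.
    """
    by_id = {f.field_id: f for f in fields}
    df = pd.read_csv(path, dtype={"cell_id": str, "field_id": str, "dish_id": str})
    required = {"cell_id", "field_id", "roi_kind", "vertices"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")

    annotations: list[CellAnnotation] = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        kinds = dict(zip(group["roi_kind"], group.index))
        if set(kinds) != {"cell", "nucleus"}:
            raise FormatError(
                f"cell {cell_id!r}: need exactly one 'cell' and one 'nucleus' "
                f"record, got kinds {sorted(kinds)}"
            )
        row = group.loc[kinds["cell"]]
        field_id = str(row["field_id"])
        if field_id not in by_id:
            raise LinkageError(f"cell {cell_id!r} references unknown field {field_id!r}")
        fld = by_id[field_id]
        cell_mask = rasterize_polygon(_parse_vertices(row["vertices"]), fld.shape)
        nuc_row = group.loc[kinds["nucleus"]]
        nucleus_mask = rasterize_polygon(_parse_vertices(nuc_row["vertices"]), fld.shape)
        annotations.append(
            CellAnnotation(
                cell_id=str(cell_id),
                field_id=field_id,
                dish_id=str(row.get("dish_id", fld.dish_id)),
                cell_line=str(row.get("cell_line", "")),
                receptor_group=str(row.get("receptor_group", "")),
                mitotic=bool(row.get("mitotic", False)),
                cell_mask=cell_mask,
                nucleus_mask=nucleus_mask,
            )
        )
    return annotations


def read_annotations_from_masks(
    cell_labels_path: str | Path,
    nucleus_labels_path: str | Path,
    sample_sheet: pd.DataFrame,
    fields: Iterable[RedoxField],
) -> list[CellAnnotation]:
    """Build annotations from a pair of 16-bit label-mask TIFFs.

    ``sample_sheet`` must carry one row per cell with columns ``cell_id,
    field_id, dish_id, cell_line, receptor_group, mitotic, label``; ``label``
    is the integer shared by both mask images for that cell.
    """
    by_id = {f.field_id: f for f in fields}
    cell_labels = _load_single_channel(cell_labels_path)
    nuc_labels = _load_single_channel(nucleus_labels_path)
    if cell_labels.shape != nuc_labels.shape:
        raise DimensionError("cell and nucleus label masks differ in shape")
    annotations = []
    for row in sample_sheet.itertuples(index=False):
        field_id = str(row.field_id)
        if field_id not in by_id:
            raise LinkageError(
                f"cell {row.cell_id!r} references unknown field {field_id!r}"
            )
        lbl = int(row.label)
        annotations.append(
            CellAnnotation(
                cell_id=str(row.cell_id),
                field_id=field_id,
                dish_id=str(row.dish_id),
                cell_line=str(row.cell_line),
                receptor_group=str(row.receptor_group),
                mitotic=bool(row.mitotic),
                cell_mask=cell_labels == lbl,
                nucleus_mask=nuc_labels == lbl,
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# Background estimation
# ---------------------------------------------------------------------------

_MIN_BLANK_PIXELS = 100


def estimate_background(
    image: np.ndarray,
    method: BackgroundSource = "blank_roi",
    blank: np.ndarray | None = None,
) -> BackgroundEstimate:
    """Estimate the additive background level and its noise SD.

    ``blank_roi``
        ``blank`` is a boolean mask selecting a cell-free region of ``image``.
    ``blank_image``
        ``blank`` is a separate blank frame (e.g. a solution-only dish);
        ``image`` is ignored.
    ``global_mode``
        No blank needed: the histogram mode of the (integer-rounded) image is
        taken as the background level, and the noise SD is the sample SD of
        pixels within ±3 median-absolute-deviations of that mode.  This
        assumes background pixels dominate the frame.

    A zero-variance blank region triggers a degenerate-background warning and
    ``noise_sd`` is set to 1 count.
    """
    image = np.asarray(image, dtype=float)
    if method in ("blank_roi", "blank_image"):
        if blank is None:
            raise ContractError(f"method {method!r} requires a blank mask/image")
        if method == "blank_roi":
            blank_mask = np.asarray(blank, dtype=bool)
            if blank_mask.shape != image.shape:
                raise DimensionError("blank mask shape differs from image shape")
            pixels = image[blank_mask]
        else:
            pixels = np.asarray(blank, dtype=float).ravel()
        if pixels.size < _MIN_BLANK_PIXELS:
            raise InsufficientDataError(
                f"blank region has {pixels.size} pixels; >= {_MIN_BLANK_PIXELS} required"
            )
        mean = float(pixels.mean())
        sd = float(pixels.std(ddof=1))
    elif method == "global_mode":
        rounded = np.round(image.ravel())
        values, counts = np.unique(rounded, return_counts=True)
        mode = float(values[np.argmax(counts)])
        mad = float(np.median(np.abs(rounded - mode)))
        half_width = 3.0 * mad if mad > 0 else 0.0
        sel = image.ravel()[np.abs(rounded - mode) <= half_width]
        mean = mode
        sd = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    else:
        raise ContractError(f"unknown background method {method!r}")

    if not sd > 0:
        warnings.warn(
            "degenerate background: zero variance in blank region; "
            "setting noise_sd to 1 count",
            stacklevel=2,
        )
        sd = 1.0
    return BackgroundEstimate(mean=mean, noise_sd=sd, source=method)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_records(records, path: str | Path) -> None:
    """Write per-cell records or group summaries to a CSV table.

    Accepts a DataFrame or an iterable of objects exposing ``to_row()``.
    Floats are formatted to 12 significant digits so a read-back reproduces
    every value to that precision.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = [r.to_row() if hasattr(r, "to_row") else dict(r) for r in records]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ContractError("refusing to write an empty record table")
    df.to_csv(path, index=False, float_format="%.12g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_records`."""
    return pd.read_csv(path)


def save_pseudocolor(
    array: np.ndarray,
    path: str | Path,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Export an index image (e.g. the ORR grid) as an 8-bit pseudocolor PNG.

    For visual QC only — the PNG is never an input to quantification.
    NaN pixels (excluded by thresholding) render black.
    """
    import matplotlib

    arr = np.asarray(array, dtype=float)
    finite = np.isfinite(arr)
    lo = float(np.nanmin(arr)) if vmin is None else vmin
    hi = float(np.nanmax(arr)) if vmax is None else vmax
    span = hi - lo if hi > lo else 1.0
    norm = np.clip((arr - lo) / span, 0.0, 1.0)
    rgba = matplotlib.colormaps[cmap](norm)
    rgba[~finite] = (0.0, 0.0, 0.0, 1.0)
    from PIL import Image

    Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(str(path))
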