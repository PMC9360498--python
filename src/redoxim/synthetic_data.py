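"""Synthetic widefield NADH/Fp microscopy with known ground truth.

Generates paired-channel fields of non-overlapping elliptical cells with
interior elliptical nuclei, emulating the salient features of live-cell
autofluorescence imaging of adherent breast-cancer cultures:

* the nucleus is darker than the cytoplasm in the NADH channel;
* signal is enriched in a perinuclear ring (mitochondrial clustering),
  applied with the same factor to both channels so the ring does not
  perturb the pixel-wise redox ratio;
* additive background with Gaussian read noise, optional Poisson shot
  noise, 14-bit dynamic range;
* mitotic cells carry two disjoint nuclear lobes of enlarged total area;
* per-cell lognormal intensity scatter (independent per channel) so group
  statistics are nondegenerate while group means stay at preset values.

Two presets encode the contrast pattern of a triple-negative-like and a
receptor-positive-like cell population: in the TNBC-like preset the nuclear
NADH is 51% of the cytoplasmic NADH and the nuclear redox ratio is 18%
above the cytoplasmic one, while the receptor-positive-like preset has
equal nuclear and cytoplasmic redox ratios, twice the TNBC NADH level in
the cytoplasm, and a larger nuclear area fraction.

Everything is driven by an explicit seed: identical spec + seed yields
bit-identical images, masks and ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ContractError, PackingError, ParameterError
from .imaging_io import (
    BackgroundEstimate,
    CellAnnotation,
    RedoxField,
    write_field,
)
from .redox_core import weighted_area

# ---------------------------------------------------------------------------
# Specification and presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field of view.

    Intensities are camera counts *above background*; ``orr_cyto``/``orr_nuc``
    set the Fp level of each compartment through Fp = NADH * orr / (1 - orr),
    so the redox ratio of each compartment is exact by construction.
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.293
    bit_depth: int = 14
    cells_per_fov: int = 5
    cell_semiaxis_px: tuple[float, float] = (14.0, 20.0)
    nuclear_area_fraction: float = 0.138
    nuclear_fraction_cv: float = 0.0
    background_mean: float = 100.0
    read_noise_sd: float = 50.0
    nadh_cyto: float = 1000.0
    nadh_nuc: float = 510.0
    orr_cyto: float = 0.56
    orr_nuc: float = 0.6608
    perinuclear_enrichment: float = 1.5
    ring_width_frac: float = 0.15
    shot_noise: bool = False
    intensity_cv: float = 0.0
    mitotic_fraction: float = 0.0
    mitotic_area_multiplier: float = 1.8
    mitotic_nuclear_orr_factor: float = 0.93
    snr_min: float = 7.5

    def __post_init__(self) -> None:
        if not (0.0 < self.nuclear_area_fraction < 1.0):
            raise ParameterError("nuclear_area_fraction must be in (0, 1)")
        if min(self.nadh_cyto, self.nadh_nuc) < 0 or self.background_mean < 0:
            raise ParameterError("intensities must be >= 0")
        if not (0.0 < self.orr_cyto < 1.0 and 0.0 < self.orr_nuc < 1.0):
            raise ParameterError("ORR targets must be in (0, 1)")
        if self.perinuclear_enrichment < 1.0:
            raise ParameterError("perinuclear_enrichment must be >= 1")
        if not (0.0 <= self.mitotic_fraction <= 1.0):
            raise ParameterError("mitotic_fraction must be in [0, 1]")
        if self.mitotic_area_multiplier <= 1.0:
            raise ParameterError("mitotic_area_multiplier must be > 1")
        floor = self.snr_min * self.read_noise_sd
        weakest = min(
            self.nadh_nuc,
            self.nadh_cyto,
            _fp_level(self.nadh_nuc, self.orr_nuc),
            _fp_level(self.nadh_cyto, self.orr_cyto),
        )
        if self.read_noise_sd > 0 and weakest < floor:
            warnings.warn(
                f"weakest compartment mean {weakest:.1f} counts is below the "
                f"SNR floor {floor:.1f}; thresholding will erode compartments",
                stacklevel=2,
            )

    @property
    def fp_cyto(self) -> float:
        return _fp_level(self.nadh_cyto, self.orr_cyto)

    @property
    def fp_nuc(self) -> float:
        return _fp_level(self.nadh_nuc, self.orr_nuc)


def _fp_level(nadh: float, orr: float) -> float:
    return nadh * orr / (1.0 - orr)


#: Named intensity/geometry presets.  The TNBC-like preset encodes a nucleus
#: more oxidized than the cytoplasm (ORR +18%) with nuclear NADH at 51% of
#: cytoplasmic; the receptor-positive-like preset has equal compartment ORRs,
#: double the cytoplasmic NADH, nuclear NADH at 85% of cytoplasmic, and a
#: larger, more variable nuclear area fraction.
PRESETS: dict[str, dict] = {
    "tnbc_like": dict(
        nadh_cyto=1000.0,
        nadh_nuc=510.0,
        orr_cyto=0.56,
        orr_nuc=0.56 * 1.18,
        nuclear_area_fraction=0.16 / 1.16,
        nuclear_fraction_cv=0.25,
    ),
    "receptor_positive_like": dict(
        nadh_cyto=2000.0,
        nadh_nuc=1700.0,
        orr_cyto=0.40,
        orr_nuc=0.40,
        nuclear_area_fraction=0.28 / 1.28,
        nuclear_fraction_cv=0.50,
    ),
}

#: The synthetic study's cell-line panel: two TNBC-like and two
#: receptor-positive-like lines.
STUDY_LINES: tuple[tuple[str, str, str], ...] = (
    ("TN-A", "tnbc_like", "triple_negative"),
    ("TN-B", "tnbc_like", "triple_negative"),
    ("RP-A", "receptor_positive_like", "receptor_positive"),
    ("RP-B", "receptor_positive_like", "receptor_positive"),
)


def preset_spec(name: str, **overrides) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a named preset plus overrides."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SyntheticSpec(**params)


# ---------------------------------------------------------------------------
# Ground truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class CellGroundTruth:
    """Noise-free truth for one generated cell.

    Compartment means are measured on the noise-free signal grids (so they
    include the perinuclear ring contribution exactly); the true compartment
    ORR equals fp_mean / (fp_mean + nadh_mean) because the ring multiplies
    both channels equally.  Areas carry both the 2x2 pattern-weight estimate
    of the true masks and the geometric ellipse area.
    """

    cell_id: str
    field_id: str
    dish_id: str
    cell_line: str
    receptor_group: str
    mitotic: bool
    mean_nadh: dict[str, float]
    mean_fp: dict[str, float]
    mean_orr: dict[str, float]
    area_weighted: dict[str, float]
    area_count: dict[str, float]
    area_geometric: dict[str, float]
    nc_ratio: float

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "field_id": self.field_id,
            "dish_id": self.dish_id,
            "cell_line": self.cell_line,
            "receptor_group": self.receptor_group,
            "mitotic": self.mitotic,
            "nc_ratio": self.nc_ratio,
        }
        for comp in ("whole_cell", "cytoplasm", "nucleus"):
            row[f"{comp}_mean_nadh"] = self.mean_nadh[comp]
            row[f"{comp}_mean_fp"] = self.mean_fp[comp]
            row[f"{comp}_mean_orr"] = self.mean_orr[comp]
        for comp in ("whole_cell", "nucleus"):
            row[f"{comp}_area_weighted"] = self.area_weighted[comp]
            row[f"{comp}_area_count"] = self.area_count[comp]
            row[f"{comp}_area_geometric"] = self.area_geometric[comp]
        return row


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    theta: float,
) -> np.ndarray:
    """Pixel-center rasterization of a rotated ellipse (row, col frame)."""
    cy, cx = center
    a, b = semi_axes
    r_max = max(a, b)
    rmin = max(int(math.floor(cy - r_max - 1)), 0)
    rmax = min(int(math.ceil(cy + r_max + 1)), shape[0] - 1)
    cmin = max(int(math.floor(cx - r_max - 1)), 0)
    cmax = min(int(math.ceil(cx + r_max + 1)), shape[1] - 1)
    mask = np.zeros(shape, dtype=bool)
    if rmin > rmax or cmin > cmax:
        return mask
    rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
    dy = rr - cy
    dx = cc - cx
    u = (dx * math.cos(theta) + dy * math.sin(theta)) / a
    v = (-dx * math.sin(theta) + dy * math.cos(theta)) / b
    mask[rmin : rmax + 1, cmin : cmax + 1] = u * u + v * v <= 1.0
    return mask


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


@dataclass
class _CellGeometry:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    theta: float
    mitotic: bool
    nuclear_fraction: float


def _place_cells(
    spec: SyntheticSpec, rng: np.random.Generator, n_mitotic: int | None = None
) -> list[_CellGeometry]:
    rows, cols = spec.shape
    lo, hi = spec.cell_semiaxis_px
    placed: list[_CellGeometry] = []
    attempts = 0
    while len(placed) < spec.cells_per_fov:
        if attempts >= 1000:
            raise PackingError(
                f"could not place {spec.cells_per_fov} non-overlapping cells "
                f"in a {rows}x{cols} frame after 1000 attempts"
            )
        attempts += 1
        a = float(rng.uniform(lo, hi))
        b = float(rng.uniform(lo, hi))
        theta = float(rng.uniform(0.0, math.pi))
        margin = max(a, b) + 1.0
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PackingError("cells are larger than the frame")
        cy = float(rng.uniform(margin, rows - margin))
        cx = float(rng.uniform(margin, cols - margin))
        ok = all(
            math.hypot(cy - g.center[0], cx - g.center[1])
            > max(a, b) + max(g.semi_axes) + 1.0
            for g in placed
        )
        if not ok:
            continue
        if n_mitotic is None:
            mitotic = bool(rng.random() < spec.mitotic_fraction)
        else:
            # deterministic split: the last n_mitotic placements are mitotic
            mitotic = len(placed) >= spec.cells_per_fov - n_mitotic
        # Scatter acts multiplicatively on the implied N:C ratio f/(1-f), so
        # the population mean N:C stays at the preset target (a lognormal on
        # the fraction itself would bias the convex ratio upward).
        f0 = spec.nuclear_area_fraction
        nc = f0 / (1.0 - f0) * _lognormal_factor(rng, spec.nuclear_fraction_cv)
        frac = float(np.clip(nc / (1.0 + nc), 0.02, 0.60))
        placed.append(_CellGeometry((cy, cx), (a, b), theta, mitotic, frac))
    return placed


def _nucleus_masks(
    spec: SyntheticSpec, geom: _CellGeometry, shape: tuple[int, int]
) -> tuple[np.ndarray, list[tuple[tuple[float, float], tuple[float, float]]]]:
    """Nucleus raster plus the list of (center, semi_axes) lobes drawn."""
    cy, cx = geom.center
    a, b = geom.semi_axes
    th = geom.theta
    if geom.mitotic:
        total = min(geom.nuclear_fraction * spec.mitotic_area_multiplier, 0.45)
        scale = math.sqrt(total / 2.0)
        lobes = []
        mask = np.zeros(shape, dtype=bool)
        for sign in (-1.0, 1.0):
            lc = (cy + sign * 0.5 * a * math.sin(th), cx + sign * 0.5 * a * math.cos(th))
            semi = (a * scale, b * scale)
            lobes.append((lc, semi))
            mask |= _ellipse_mask(shape, lc, semi, th)
        return mask, lobes
    scale = math.sqrt(geom.nuclear_fraction)
    semi = (a * scale, b * scale)
    return _ellipse_mask(shape, geom.center, semi, th), [(geom.center, semi)]


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------


def generate_field(
    spec: SyntheticSpec,
    dish_id: str,
    field_id: str,
    *,
    cell_line: str = "synthetic",
    receptor_group: str = "",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    cell_id_offset: int = 0,
    n_mitotic: int | None = None,
) -> tuple[RedoxField, list[CellAnnotation], list[CellGroundTruth]]:
    """Generate one synthetic FOV: images, per-cell annotations, ground truth.

    Pixel values are ``background + compartment signal (+ Poisson shot noise
    on the signal, if enabled) + Gaussian read noise``, clipped to the
    declared bit range.  With any noise enabled the images are rounded to
    integer camera counts; in the noise-free regime they stay floating-point
    so downstream recovery can be checked to high precision.

    Within each cell, the cytoplasm base level is solved so that the
    *realized* cytoplasm mean (including the perinuclear ring) equals the
    preset target exactly.
    """
    if rng is None:
        if seed is None:
            raise ContractError("generate_field requires a seed or an rng")
        rng = np.random.default_rng(seed)
    shape = spec.shape
    geoms = _place_cells(spec, rng, n_mitotic=n_mitotic)

    nadh_sig = np.zeros(shape, dtype=float)
    fp_sig = np.zeros(shape, dtype=float)
    annotations: list[CellAnnotation] = []
    truths: list[CellGroundTruth] = []

    for i, geom in enumerate(geoms):
        cell_id = f"{field_id}_c{cell_id_offset + i:03d}"
        cell_mask = _ellipse_mask(shape, geom.center, geom.semi_axes, geom.theta)
        nuc_mask, lobes = _nucleus_masks(spec, geom, shape)
        nuc_mask &= cell_mask
        cyto_mask = cell_mask & ~nuc_mask
        if not nuc_mask.any() or not cyto_mask.any():
            raise PackingError(f"degenerate nucleus/cytoplasm for cell {cell_id}")

        # Perinuclear ring: each nuclear lobe expanded by a rim whose width
        # is ring_width_frac of that lobe's minor axis, clipped to cytoplasm.
        ring_mask = np.zeros(shape, dtype=bool)
        for lc, (la, lb) in lobes:
            w = spec.ring_width_frac * 2.0 * min(la, lb)
            ring_mask |= _ellipse_mask(shape, lc, (la + w, lb + w), geom.theta)
        ring_mask &= cyto_mask

        g_nadh = _lognormal_factor(rng, spec.intensity_cv)
        g_fp = _lognormal_factor(rng, spec.intensity_cv)

        nadh_nuc, fp_nuc = spec.nadh_nuc, spec.fp_nuc
        if geom.mitotic and spec.mitotic_nuclear_orr_factor != 1.0:
            # shift the nuclear redox ratio by moving both channels
            # symmetrically (NADH up, Fp down by the same factor), so
            # neither intensity alone carries the whole contrast
            orr_m = spec.orr_nuc * spec.mitotic_nuclear_orr_factor
            rho = (orr_m / (1.0 - orr_m)) / (spec.orr_nuc / (1.0 - spec.orr_nuc))
            nadh_nuc = spec.nadh_nuc / math.sqrt(rho)
            fp_nuc = _fp_level(nadh_nuc, orr_m)
        targets = {
            "nadh": (spec.nadh_cyto * g_nadh, nadh_nuc * g_nadh),
            "fp": (spec.fp_cyto * g_fp, fp_nuc * g_fp),
        }
        n_cyto = int(cyto_mask.sum())
        n_ring = int(ring_mask.sum())
        enrich = spec.perinuclear_enrichment
        for channel, grid in (("nadh", nadh_sig), ("fp", fp_sig)):
            cyto_target, nuc_value = targets[channel]
            base = cyto_target * n_cyto / (n_cyto + (enrich - 1.0) * n_ring)
            grid[cyto_mask] = base
            grid[ring_mask] = base * enrich
            grid[nuc_mask] = nuc_value

        annotations.append(
            CellAnnotation(
                cell_id=cell_id,
                field_id=field_id,
                dish_id=dish_id,
                cell_line=cell_line,
                receptor_group=receptor_group,
                mitotic=geom.mitotic,
                cell_mask=cell_mask,
                nucleus_mask=nuc_mask,
            )
        )

        with np.errstate(invalid="ignore", divide="ignore"):
            orr_grid = np.where(
                cell_mask, fp_sig / np.where(cell_mask, fp_sig + nadh_sig, 1.0), np.nan
            )
        comps = {"whole_cell": cell_mask, "cytoplasm": cyto_mask, "nucleus": nuc_mask}
        mean_nadh = {c: float(nadh_sig[m].mean()) for c, m in comps.items()}
        mean_fp = {c: float(fp_sig[m].mean()) for c, m in comps.items()}
        mean_orr = {c: float(orr_grid[m].mean()) for c, m in comps.items()}
        area_w = {c: weighted_area(m) for c, m in (("whole_cell", cell_mask), ("nucleus", nuc_mask))}
        area_n = {
            "whole_cell": float(cell_mask.sum()),
            "nucleus": float(nuc_mask.sum()),
        }
        geo = {
            "whole_cell": math.pi * geom.semi_axes[0] * geom.semi_axes[1],
            "nucleus": sum(math.pi * la * lb for _, (la, lb) in lobes),
        }
        truths.append(
            CellGroundTruth(
                cell_id=cell_id,
                field_id=field_id,
                dish_id=dish_id,
                cell_line=cell_line,
                receptor_group=receptor_group,
                mitotic=geom.mitotic,
                mean_nadh=mean_nadh,
                mean_fp=mean_fp,
                mean_orr=mean_orr,
                area_weighted=area_w,
                area_count=area_n,
                area_geometric=geo,
                nc_ratio=area_w["nucleus"] / (area_w["whole_cell"] - area_w["nucleus"]),
            )
        )

    top = float(2**spec.bit_depth - 1)
    noisy = spec.read_noise_sd > 0 or spec.shot_noise
    images = {}
    for channel, sig in (("nadh", nadh_sig), ("fp", fp_sig)):
        out = sig.copy()
        if spec.shot_noise:
            out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
        out = out + spec.background_mean
        if spec.read_noise_sd > 0:
            out = out + rng.normal(0.0, spec.read_noise_sd, size=shape)
        out = np.clip(out, 0.0, top)
        images[channel] = np.round(out) if noisy else out

    noise_sd = spec.read_noise_sd if spec.read_noise_sd > 0 else 1.0
    bg = BackgroundEstimate(
        mean=spec.background_mean, noise_sd=noise_sd, source="blank_image"
    )
    field = RedoxField(
        field_id=field_id,
        dish_id=dish_id,
        nadh_image=images["nadh"],
        fp_image=images["fp"],
        pixel_size_um=spec.pixel_size_um,
        bit_depth=spec.bit_depth,
        background_nadh=bg,
        background_fp=bg,
    )
    return field, annotations, truths


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """In-memory synthetic study: fields, annotations, ground truth, sheet."""

    fields: list[RedoxField]
    annotations: list[CellAnnotation]
    ground_truth: list[CellGroundTruth]

    @property
    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for idx, ann in enumerate(self.annotations):
            rows.append(
                {
                    "cell_id": ann.cell_id,
                    "field_id": ann.field_id,
                    "dish_id": ann.dish_id,
                    "cell_line": ann.cell_line,
                    "receptor_group": ann.receptor_group,
                    "mitotic": ann.mitotic,
                    "label": self._label_of(idx),
                }
            )
        return pd.DataFrame(rows)

    def _label_of(self, idx: int) -> int:
        # labels restart per field, 1-based, in annotation order
        ann = self.annotations[idx]
        label = 1
        for other in self.annotations[:idx]:
            if other.field_id == ann.field_id:
                label += 1
        return label

    def ground_truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_row() for t in self.ground_truth])

    def write(self, out_dir: str | Path) -> Path:
        """Write the bundle in the exact on-disk layout the pipeline reads.

        ``images/<field>_{nadh,fp}.tif`` channel TIFFs, per-field 16-bit
        label masks under ``masks/``, plus ``fields.csv`` (acquisition and
        background metadata), ``cells.csv`` (the sample sheet) and
        ``ground_truth.csv``.
        """
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        sheet = self.sample_sheet
        field_rows = []
        for fld in self.fields:
            nadh_path = out / "images" / f"{fld.field_id}_nadh.tif"
            fp_path = out / "images" / f"{fld.field_id}_fp.tif"
            write_field(fld, nadh_path, fp_path)
            cell_labels = np.zeros(fld.shape, dtype=np.uint16)
            nuc_labels = np.zeros(fld.shape, dtype=np.uint16)
            sub = sheet[sheet["field_id"] == fld.field_id]
            for row in sub.itertuples(index=False):
                ann = next(a for a in self.annotations if a.cell_id == row.cell_id)
                cell_labels[ann.cell_mask] = row.label
                nuc_labels[ann.nucleus_mask] = row.label
            tifffile.imwrite(str(out / "masks" / f"{fld.field_id}_cells.tif"), cell_labels)
            tifffile.imwrite(str(out / "masks" / f"{fld.field_id}_nuclei.tif"), nuc_labels)
            field_rows.append(
                {
                    "field_id": fld.field_id,
                    "dish_id": fld.dish_id,
                    "nadh_path": str(nadh_path.relative_to(out)),
                    "fp_path": str(fp_path.relative_to(out)),
                    "cell_labels_path": str(Path("masks") / f"{fld.field_id}_cells.tif"),
                    "nucleus_labels_path": str(Path("masks") / f"{fld.field_id}_nuclei.tif"),
                    "pixel_size_um": fld.pixel_size_um,
                    "bit_depth": fld.bit_depth,
                    "bg_nadh_mean": fld.background_nadh.mean,
                    "bg_nadh_sd": fld.background_nadh.noise_sd,
                    "bg_fp_mean": fld.background_fp.mean,
                    "bg_fp_sd": fld.background_fp.noise_sd,
                }
            )
        pd.DataFrame(field_rows).to_csv(out / "fields.csv", index=False)
        sheet.to_csv(out / "cells.csv", index=False)
        self.ground_truth_frame().to_csv(out / "ground_truth.csv", index=False, float_format="%.12g")
        return out


def generate_study(
    seed: int,
    *,
    lines: Sequence[tuple[str, str, str]] = STUDY_LINES,
    dishes_per_line: int = 3,
    fovs_per_dish: int = 3,
    cells_per_fov: int = 5,
    intensity_cv: float = 0.15,
    read_noise_sd: float = 50.0,
    shot_noise: bool = False,
    mitotic_cells_per_fov: int = 0,
    spec_overrides: dict | None = None,
) -> StudyBundle:
    """Generate the full multi-line study design.

    Defaults mirror the emulated study: four cell lines (two per receptor
    group), three dishes per line, three FOVs per dish, and 15 analyzed
    cells per dish (five per FOV) — 12 dishes, 36 FOVs, 180 cells in all.
    ``mitotic_cells_per_fov`` adds that many mitotic cells to every FOV of
    the triple-negative lines (the receptor-positive lines divide too slowly
    to catch in mitosis), drawn with two-lobe nuclei of enlarged total area.
    """
    overrides = dict(spec_overrides or {})
    overrides.setdefault("intensity_cv", intensity_cv)
    overrides.setdefault("read_noise_sd", read_noise_sd)
    overrides.setdefault("shot_noise", shot_noise)
    overrides.setdefault("cells_per_fov", cells_per_fov)

    root_ss = np.random.SeedSequence(seed)
    fields: list[RedoxField] = []
    annotations: list[CellAnnotation] = []
    truths: list[CellGroundTruth] = []
    n_fields_total = len(lines) * dishes_per_line * fovs_per_dish
    children = root_ss.spawn(n_fields_total)
    child_iter = iter(children)

    for line_name, preset_name, group in lines:
        add_mitotic = mitotic_cells_per_fov if group == "triple_negative" else 0
        spec = preset_spec(preset_name, **overrides)
        for d in range(1, dishes_per_line + 1):
            dish_id = f"{line_name}_d{d}"
            for f in range(1, fovs_per_dish + 1):
                field_id = f"{dish_id}_f{f}"
                rng = np.random.default_rng(next(child_iter))
                fov_spec = spec
                if add_mitotic:
                    fov_spec = replace(spec, cells_per_fov=spec.cells_per_fov + add_mitotic)
                fld, anns, gts = generate_field(
                    fov_spec, dish_id, field_id,
                    cell_line=line_name, receptor_group=group, rng=rng,
                    n_mitotic=add_mitotic if add_mitotic else None,
                )
                fields.append(fld)
                annotations.extend(anns)
                truths.extend(gts)
    return StudyBundle(fields=fields, annotations=annotations, ground_truth=truths)
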