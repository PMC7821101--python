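"""Synthetic multi-channel fields of view with exact ground truth.

Stands in for the microscope: nuclei are rendered as uniform-intensity
ellipses (H2B-GFP channel) with an optional 1-px Gaussian edge blur,
Gaussian read noise and Poisson shot noise.  The ground-truth label mask
is the exact ellipse raster, free of noise and blur, so segmentation and
measurement can be validated pixel-for-pixel.  Channels are one 16-bit
grayscale TIFF per channel per field (``{well}_{field}_{channel}.tif``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from optenrich.library import CellRecord, Ellipse, DEFAULT_PIXEL_SIZE

PA_MCHERRY_BACKGROUND = 100.0  # camera units, pre-activation
DEFAULT_EDGE_BLUR_SIGMA = 1.0


@dataclass
class ImageField:
    """One rendered field of view: channel images, calibration and truth."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    field_id: tuple[str, int, int]  # (well, row, col)
    truth: pd.DataFrame  # cell_id, label, cx, cy, area_px, overlap_warning
    labels: np.ndarray  # ground-truth label mask, 0 = background

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {im.shape for im in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channel arrays must share dimensions")


@dataclass(frozen=True)
class AcquisitionPlan:
    """Imaging plan: an n x n serpentine grid of fields per well.

    The standard runs use 8 x 8 = 64 fields (day run) or 9 x 9 = 81
    fields (night run) per well.
    """

    fields_per_well: int
    wells: tuple[str, ...]
    exposure_ms: Mapping[str, float]
    field_order: tuple[tuple[int, int], ...] = dc_field(default=())

    def __post_init__(self) -> None:
        n = int(round(math.sqrt(self.fields_per_well)))
        if n * n != self.fields_per_well:
            raise ValueError("fields_per_well must be a perfect square")


def plan_acquisition(
    wells: Sequence[str],
    grid_n: int,
    exposures: Mapping[str, float] | None = None,
) -> AcquisitionPlan:
    """Plan an acquisition: grid_n^2 fields per well in serpentine order."""
    if grid_n < 1:
        raise ValueError("grid_n must be >= 1")
    if exposures is None:
        exposures = {"gfp": 500.0, "mcherry": 100.0, "mifp": 1000.0}
    order = []
    for r in range(grid_n):
        cols = range(grid_n) if r % 2 == 0 else range(grid_n - 1, -1, -1)
        order.extend((r, c) for c in cols)
    return AcquisitionPlan(
        fields_per_well=grid_n * grid_n,
        wells=tuple(wells),
        exposure_ms=dict(exposures),
        field_order=tuple(order),
    )


def layout_cells(
    cells: Sequence[CellRecord],
    dims: tuple[int, int],
    margin: float = 40.0,
    jitter: float = 0.25,
    seed: int = 0,
) -> list[CellRecord]:
    """Place cells on a jittered grid with near-non-overlapping spacing.

    Spacing is sized for the typical nucleus; unusually large nuclei can
    still touch a neighbor, which :func:`render_field` records as an
    overlap warning in the truth table.  Raises if the field cannot hold
    the requested number of cells even at typical-cell spacing.
    """
    n = len(cells)
    if n == 0:
        return []
    h, w = dims
    side = math.ceil(math.sqrt(n))
    pitch_y = (h - 2 * margin) / side
    pitch_x = (w - 2 * margin) / side
    radii = sorted(max(c.nucleus.a, c.nucleus.b) for c in cells)
    typical_r = radii[len(radii) // 2]
    if min(pitch_x, pitch_y) < 2 * typical_r + 3:
        raise ValueError("cells do not fit the field at non-overlapping spacing")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    out = []
    for i, cell in enumerate(cells):
        r, c = divmod(i, side)
        jy = rng.uniform(-jitter, jitter) * max(pitch_y - 2 * typical_r, 0.0)
        jx = rng.uniform(-jitter, jitter) * max(pitch_x - 2 * typical_r, 0.0)
        cy = margin + (r + 0.5) * pitch_y + jy
        cx = margin + (c + 0.5) * pitch_x + jx
        nuc = Ellipse(cx, cy, cell.nucleus.a, cell.nucleus.b, cell.nucleus.theta)
        out.append(
            CellRecord(
                cell_id=cell.cell_id,
                sgrna_id=cell.sgrna_id,
                true_phenotype=cell.true_phenotype,
                nucleus=nuc,
                base_intensities=dict(cell.base_intensities),
                bfp_ln_mean=cell.bfp_ln_mean,
            )
        )
    return out


def render_field(
    cells: Sequence[CellRecord],
    dims: tuple[int, int] = (2048, 2048),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    noise: tuple[float, bool] = (0.0, False),
    seed: int = 0,
    field_id: tuple[str, int, int] = ("A1", 0, 0),
    edge_blur_sigma: float = DEFAULT_EDGE_BLUR_SIGMA,
    overlap_warn_fraction: float = 0.05,
) -> ImageField:
    """Render one field of view from positioned cell records.

    Every cell paints a filled ellipse at its base GFP intensity; cells
    with an ``mifp`` base intensity also paint the mIFP channel, and the
    BFP channel renders exp(bfp_ln_mean).  The PA-mCherry channel sits at
    the pre-activation background.  Cells whose exact rasters overlap by
    more than ``overlap_warn_fraction`` of their area are flagged in the
    truth table (``overlap_warning``), not rejected.
    """
    h, w = dims
    if h <= 0 or w <= 0:
        raise ValueError("field dimensions must be positive")
    gauss_sd, poisson = noise
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 13]))

    labels = np.zeros((h, w), dtype=np.uint16)
    gfp = np.zeros((h, w), dtype=float)
    mifp = np.zeros((h, w), dtype=float)
    bfp = np.zeros((h, w), dtype=float)
    rows = []
    for k, cell in enumerate(cells, start=1):
        nuc = cell.nucleus
        rr, cc = draw_ellipse(
            nuc.cy, nuc.cx, nuc.b, nuc.a, shape=(h, w), rotation=nuc.theta
        )
        if rr.size == 0:
            raise ValueError(f"cell {cell.cell_id} outside the field")
        overlap = labels[rr, cc] != 0
        labels[rr, cc] = k
        gfp[rr, cc] = cell.base_intensities.get("gfp", 0.0)
        if cell.base_intensities.get("mifp", 0.0) > 0:
            mifp[rr, cc] = cell.base_intensities["mifp"]
        bfp[rr, cc] = math.exp(cell.bfp_ln_mean)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "label": k,
                "cx": nuc.cx,
                "cy": nuc.cy,
                "area_px": int(rr.size),
                "overlap_warning": bool(overlap.mean() > overlap_warn_fraction),
            }
        )

    mcherry = np.full((h, w), PA_MCHERRY_BACKGROUND)

    def finish(img: np.ndarray, blur: bool = True) -> np.ndarray:
        if blur and edge_blur_sigma > 0:
            img = ndi.gaussian_filter(img, edge_blur_sigma)
        if poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if gauss_sd > 0:
            img = img + rng.normal(0.0, gauss_sd, size=img.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth_cols = ["cell_id", "label", "cx", "cy", "area_px", "overlap_warning"]
    return ImageField(
        channels={
            "gfp": finish(gfp),
            "mifp": finish(mifp),
            "bfp": finish(bfp),
            "mcherry": finish(mcherry, blur=False),
        },
        pixel_size=pixel_size,
        field_id=field_id,
        truth=pd.DataFrame(rows, columns=truth_cols),
        labels=labels,
    )


def write_field(field: ImageField, outdir) -> list[Path]:
    """Write one TIFF per channel plus the label mask and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    well, row, col = field.field_id
    fname = f"{well}_{row:02d}-{col:02d}"
    written = []
    for channel, img in field.channels.items():
        p = outdir / f"{fname}_{channel}.tif"
        tifffile.imwrite(p, img)
        written.append(p)
    p = outdir / f"{fname}_labels.tif"
    tifffile.imwrite(p, field.labels.astype(np.uint16))
    written.append(p)
    p = outdir / f"{fname}_truth.tsv"
    field.truth.to_csv(p, sep="\t", index=False)
    written.append(p)
    return written


def read_channel(path) -> np.ndarray:
    return tifffile.imread(path)
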