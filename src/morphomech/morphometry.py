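"""Cell and nuclear shape descriptors and YAP/TAZ intensity ratios.

Fourteen descriptors per cell, following the conventions of standard image
analysis software: areas from pixel counts, major/minor axes from the
best-fit ellipse via second central moments, circularity 4*pi*A/P^2 (clipped
to 1), roundness 4*A/(pi*major^2), solidity A/convex-hull area.  Bounding
length/width are axis-aligned box extents measured in a frame rotated so
that ``reference_axis`` (the scaffold fiber/stretch axis) is horizontal;
angles are reported relative to that axis, wrapped to [-90, 90), positive
counterclockwise with 0-based row-major pixel coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .synthetic import FEATURE_COLUMNS


@dataclass(frozen=True)
class YapMeasurement:
    """Mean nuclear and cytoplasmic intensities and their ratio."""

    nuclear_mean: float
    cytoplasmic_mean: float
    ratio: float


def _wrap_angle(deg: float) -> float:
    return (deg + 90.0) % 180.0 - 90.0


def _single_component(mask: np.ndarray, what: str) -> np.ndarray:
    fg = np.asarray(mask) > 0
    if fg.sum() == 0:
        raise ValueError(f"{what} mask has no foreground pixels")
    n = measure.label(fg).max()
    if n != 1:
        raise ValueError(f"{what} mask must contain exactly one component, found {n}")
    return fg


def _moments_orientation(fg: np.ndarray) -> tuple[float, float, float]:
    """(major, minor, angle_deg) of the best-fit ellipse, x right / y up CCW."""
    rows, cols = np.nonzero(fg)
    x = cols.astype(float)
    y = -rows.astype(float)  # y up so CCW angles are positive
    x -= x.mean()
    y -= y.mean()
    cxx, cyy, cxy = np.mean(x * x), np.mean(y * y), np.mean(x * y)
    common = math.sqrt(max((cxx - cyy) ** 2 + 4 * cxy**2, 0.0))
    l1 = (cxx + cyy + common) / 2.0
    l2 = (cxx + cyy - common) / 2.0
    major = 4.0 * math.sqrt(max(l1, 0.0))
    minor = 4.0 * math.sqrt(max(l2, 0.0))
    angle = math.degrees(0.5 * math.atan2(2 * cxy, cxx - cyy))
    return major, minor, _wrap_angle(angle)


def _bounding_extents(fg: np.ndarray, reference_axis: float) -> tuple[float, float]:
    """Box extents (px) along / across the reference axis."""
    rows, cols = np.nonzero(fg)
    x = cols.astype(float)
    y = -rows.astype(float)
    a = math.radians(reference_axis)
    xr = x * math.cos(a) + y * math.sin(a)
    yr = -x * math.sin(a) + y * math.cos(a)
    return float(np.ptp(xr) + 1.0), float(np.ptp(yr) + 1.0)


def extract_shape_descriptors(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float = 1.0,
    reference_axis: float = 0.0,
) -> pd.Series:
    """Compute the 14 morphology descriptors from a cell/nucleus mask pair.

    Requires one connected foreground component per mask and >= 95% of
    nucleus pixels inside the cell.  Returns a Series indexed by
    ``FEATURE_COLUMNS`` (areas um^2, lengths um, angles degrees relative to
    ``reference_axis``).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if np.shape(cell_mask) != np.shape(nucleus_mask):
        raise ValueError("cell and nucleus masks must have the same shape")
    cell = _single_component(cell_mask, "cell")
    nuc = _single_component(nucleus_mask, "nucleus")
    inside = np.logical_and(cell, nuc).sum() / nuc.sum()
    if inside < 0.95:
        raise ValueError(
            f"nucleus lies outside the cell ({inside:.0%} of nucleus pixels inside, need >= 95%)"
        )

    props = measure.regionprops(cell.astype(np.uint8))[0]
    area = props.area * pixel_size**2
    # Crofton-formula perimeter: accurate on smooth boundaries, where the
    # chain-code estimate runs several percent high.
    perimeter = props.perimeter_crofton * pixel_size
    solidity = props.solidity
    major_px, minor_px, angle = _moments_orientation(cell)
    major = major_px * pixel_size
    minor = max(minor_px * pixel_size, pixel_size)  # 1-px-wide degenerate guard
    blen, bwid = _bounding_extents(cell, reference_axis)

    nprops = measure.regionprops(nuc.astype(np.uint8))[0]
    n_major_px, n_minor_px, n_angle = _moments_orientation(nuc)
    n_minor_px = max(n_minor_px, 1.0)

    return pd.Series(
        {
            "cell_area_um2": area,
            "cell_perimeter_um": perimeter,
            "cell_major_um": major,
            "cell_minor_um": minor,
            "cell_bound_len_um": blen * pixel_size,
            "cell_bound_wid_um": bwid * pixel_size,
            "cell_aspect": major / minor,
            "cell_solidity": solidity,
            "cell_roundness": min(4.0 * area / (math.pi * major**2), 1.0),
            "cell_circularity": min(4.0 * math.pi * area / perimeter**2, 1.0),
            "cell_angle_deg": _wrap_angle(angle - reference_axis),
            "nuc_area_um2": nprops.area * pixel_size**2,
            "nuc_aspect": n_major_px / n_minor_px,
            "nuc_angle_deg": _wrap_angle(n_angle - reference_axis),
        },
        index=FEATURE_COLUMNS,
    )


def yap_ratio(
    intensity: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    background: float = 0.0,
) -> YapMeasurement:
    """Nuclear/cytoplasmic mean-intensity ratio of a stained factor.

    The cytoplasm is the cell minus the nucleus.  ``background`` is an
    optional constant subtracted from both means before forming the ratio.
    """
    img = np.asarray(intensity, float)
    if np.any(img < 0):
        raise ValueError("intensity image must be nonnegative")
    if img.shape != np.shape(cell_mask) or img.shape != np.shape(nucleus_mask):
        raise ValueError("intensity and masks must share a shape")
    cell = _single_component(cell_mask, "cell")
    nuc = _single_component(nucleus_mask, "nucleus")
    cyto = np.logical_and(cell, ~nuc)
    if cyto.sum() == 0:
        raise ValueError("cytoplasmic region is empty (nucleus fills the cell)")
    nuclear = float(img[nuc].mean()) - background
    cytoplasmic = float(img[cyto].mean()) - background
    if cytoplasmic <= 0:
        raise ValueError("cytoplasmic mean must be > 0 after background subtraction")
    return YapMeasurement(nuclear, cytoplasmic, nuclear / cytoplasmic)


def extract_directory(
    cells_dir,
    pixel_size: float = 1.0,
    reference_axis: float = 0.0,
) -> pd.DataFrame:
    """Measure every ``*_cell.*`` / ``*_nuc.*`` mask pair in a directory.

    Pairs share a stem: ``foo_cell.tif`` with ``foo_nuc.tif`` (TIFF or PNG).
    If ``foo_yap.*`` exists it is read as the intensity image and a
    ``yap_ratio`` column is added.
    """
    import imageio.v3 as iio

    cells_dir = Path(cells_dir)
    rows = []
    for cell_path in sorted(cells_dir.glob("*_cell.*")):
        stem = cell_path.name.rsplit("_cell", 1)[0]
        nuc_path = next(iter(cells_dir.glob(f"{stem}_nuc.*")), None)
        if nuc_path is None:
            raise FileNotFoundError(f"no nucleus mask for {cell_path.name}")
        cell = iio.imread(cell_path)
        nuc = iio.imread(nuc_path)
        rec = extract_shape_descriptors(cell, nuc, pixel_size, reference_axis)
        rec["cell_id"] = stem
        yap_path = next(iter(cells_dir.glob(f"{stem}_yap.*")), None)
        if yap_path is not None:
            rec["yap_ratio"] = yap_ratio(iio.imread(yap_path), cell, nuc).ratio
        rows.append(rec)
    if not rows:
        raise FileNotFoundError(f"no '*_cell.*' masks found in {cells_dir}")
    df = pd.DataFrame(rows)
    return df[["cell_id"] + [c for c in df.columns if c != "cell_id"]]
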