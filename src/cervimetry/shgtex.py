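"""Fibre-directionality and intensity statistics for SHG-like images.

The directionality statistic R is the minor/major axis ratio of the ellipse
that shares the normalised second central moments of the thresholded 2-D
Fourier magnitude of an image window: the spectrum is centred, thresholded at
80 % of the central (DC) value, reduced to the DC-connected component, and
summarised by its moment ellipse. Parallel fibres concentrate spectral energy
perpendicular to their axis and give small R; disordered textures give R near
one. Also provides tile stitching with linear feathering, non-overlapping ROI
tiling, and the brightest-10-pixel intensity summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import FibreImage

DEFAULT_FT_THRESHOLD = 0.80
DEFAULT_ROI_UM = 60.0


@dataclass(frozen=True)
class ROIWindow:
    """A square analysis window inside a parent image."""

    parent: FibreImage
    origin: tuple[int, int]  # (row, col), 0-based
    side: int                # px

    def __post_init__(self) -> None:
        r, c = self.origin
        h, w = self.parent.pixels.shape
        if self.side < 16:
            raise ValueError("ROI side must be >= 16 px")
        if r < 0 or c < 0 or r + self.side > h or c + self.side > w:
            raise ValueError("ROI window not fully inside parent image")

    @property
    def pixels(self) -> np.ndarray:
        r, c = self.origin
        return self.parent.pixels[r:r + self.side, c:c + self.side]


@dataclass(frozen=True)
class FTEllipse:
    """Moment-ellipse descriptor of a thresholded spectrum region."""

    major_axis: float       # px in the frequency plane
    minor_axis: float
    orientation: float      # degrees, major-axis direction
    R: float                # minor/major, in (0, 1]
    ft_peak: float          # central (DC) magnitude


def compute_ft(window: ROIWindow | np.ndarray) -> np.ndarray:
    """Centred 2-D Fourier magnitude spectrum of a window.

    Zero frequency sits at index ``(n//2, n//2)`` after the shift. The raw
    (unnormalised) DFT magnitude is returned, so Parseval's identity holds as
    ``sum |F|^2 = N_pixels * sum |x|^2``.
    """
    pixels = window.pixels if isinstance(window, ROIWindow) else np.asarray(window, float)
    return np.abs(np.fft.fftshift(np.fft.fft2(pixels)))


def threshold_ft(spectrum: np.ndarray, threshold: float = DEFAULT_FT_THRESHOLD) -> np.ndarray:
    """Binary mask of the spectrum at a fraction of the central value.

    Keeps bins whose magnitude is at least ``threshold`` times the centre
    (DC) bin, then reduces the mask to the 8-connected component containing
    the centre — disconnected harmonic peaks would make a single-ellipse
    summary meaningless.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    centre = (spectrum.shape[0] // 2, spectrum.shape[1] // 2)
    centre_value = spectrum[centre]
    if centre_value <= 0:
        raise ValueError("blank image: central spectral value is zero")
    mask = spectrum >= threshold * centre_value
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return labels == labels[centre]


def ellipse_from_mask(mask: np.ndarray) -> FTEllipse:
    """Ellipse with the same normalised second central moments as the region.

    Normalised moments carry the +1/12 per-pixel correction (each pixel is a
    unit square, variance 1/12), so a single-pixel region is exactly
    isotropic (R = 1) and an a x b rectangle yields R = b/a exactly. Axis
    lengths are ``4 * sqrt(eigenvalue)``, the convention of moment-ellipse
    region tools.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    r = rows - rows.mean()
    c = cols - cols.mean()
    mrr = np.mean(r * r) + 1.0 / 12.0
    mcc = np.mean(c * c) + 1.0 / 12.0
    mrc = np.mean(r * c)
    cov = np.array([[mcc, mrc], [mrc, mrr]])  # (x, y) = (col, row) order
    eigvals, eigvecs = np.linalg.eigh(cov)
    minor, major = (float(v) for v in np.clip(eigvals, 0.0, None))
    vx, vy = eigvecs[:, 1]  # eigenvector of the larger eigenvalue
    orientation = math.degrees(math.atan2(vy, vx)) % 180.0
    major_axis = 4.0 * math.sqrt(major)
    minor_axis = 4.0 * math.sqrt(minor)
    return FTEllipse(
        major_axis=major_axis,
        minor_axis=minor_axis,
        orientation=orientation,
        R=minor_axis / major_axis if major_axis > 0 else 1.0,
        ft_peak=float(mask.sum()),
    )


def directionality_R(
    window: ROIWindow | np.ndarray,
    threshold: float = DEFAULT_FT_THRESHOLD,
) -> FTEllipse:
    """Full directionality statistic: FT -> threshold -> moment ellipse.

    Small R means parallel fibres; R near 1 means disordered texture.
    """
    spectrum = compute_ft(window)
    mask = threshold_ft(spectrum, threshold=threshold)
    ellipse = ellipse_from_mask(mask)
    centre = (spectrum.shape[0] // 2, spectrum.shape[1] // 2)
    return FTEllipse(
        major_axis=ellipse.major_axis,
        minor_axis=ellipse.minor_axis,
        orientation=ellipse.orientation,
        R=ellipse.R,
        ft_peak=float(spectrum[centre]),
    )


def max10_intensity(image: FibreImage | np.ndarray) -> float:
    """Mean of the 10 brightest pixels of an image."""
    pixels = image.pixels if isinstance(image, FibreImage) else np.asarray(image)
    flat = pixels.ravel()
    if flat.size < 10:
        raise ValueError("image must have at least 10 pixels")
    return float(np.mean(np.partition(flat, -10)[-10:]))


def tile_rois(image: FibreImage, side_um: float = DEFAULT_ROI_UM) -> list[ROIWindow]:
    """Non-overlapping grid of square ROI windows of a physical size.

    The window side is ``side_um`` rounded to the nearest even pixel count;
    partial windows at the edges are discarded; the grid is centred within
    the image (leftover margin split evenly); row-major order.
    """
    side_px = int(round(side_um / image.pixel_size / 2.0)) * 2
    side_px = max(side_px, 16)
    h, w = image.pixels.shape
    if h < side_px or w < side_px:
        raise ValueError("image smaller than one ROI window")
    n_r, n_c = h // side_px, w // side_px
    off_r, off_c = (h - n_r * side_px) // 2, (w - n_c * side_px) // 2
    return [
        ROIWindow(parent=image,
                  origin=(off_r + i * side_px, off_c + j * side_px),
                  side=side_px)
        for i in range(n_r)
        for j in range(n_c)
    ]


def stitch_tiles(tiles, overlap_frac: float = 0.10) -> FibreImage:
    """Stitch a rectangular grid of equally sized tiles into a mosaic.

    ``tiles`` is a 2-D nested sequence (rows of tiles, row-major) of
    :class:`FibreImage` with identical shapes and pixel sizes; adjacent tiles
    overlap by ``overlap_frac`` of the tile side. Overlapping strips are
    blended by linear feathering (weights ramp linearly across the overlap
    and the mosaic is normalised by the total weight), so a grid cut from one
    source image is reconstructed up to blending round-off.
    """
    if not (0.0 < overlap_frac < 0.5):
        raise ValueError("overlap_frac must be in (0, 0.5)")
    grid = [list(row) for row in tiles]
    n_rows, n_cols = len(grid), len(grid[0])
    first = grid[0][0]
    shape = first.pixels.shape
    for row in grid:
        if len(row) != n_cols:
            raise ValueError("tile grid must be rectangular")
        for t in row:
            if t.pixels.shape != shape or t.pixel_size != first.pixel_size:
                raise ValueError("inconsistent tile sizes or pixel sizes")
    th, tw = shape
    ov_r, ov_c = int(round(overlap_frac * th)), int(round(overlap_frac * tw))
    step_r, step_c = th - ov_r, tw - ov_c
    out_h = th + (n_rows - 1) * step_r
    out_w = tw + (n_cols - 1) * step_c

    def _profile(n: int, ov: int, at_start: bool, at_end: bool) -> np.ndarray:
        w = np.ones(n)
        if ov > 0:
            ramp = (np.arange(1, ov + 1)) / (ov + 1.0)
            if not at_start:
                w[:ov] = ramp
            if not at_end:
                w[-ov:] = ramp[::-1]
        return w

    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    for i, row in enumerate(grid):
        for j, tile in enumerate(row):
            wr = _profile(th, ov_r, i == 0, i == n_rows - 1)
            wc = _profile(tw, ov_c, j == 0, j == n_cols - 1)
            weight = np.outer(wr, wc)
            r0, c0 = i * step_r, j * step_c
            acc[r0:r0 + th, c0:c0 + tw] += weight * tile.pixels
            wacc[r0:r0 + th, c0:c0 + tw] += weight
    return FibreImage(pixels=acc / wacc, pixel_size=first.pixel_size,
                      provenance=first.provenance)
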