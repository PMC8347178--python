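"""Widefield immunofluorescence quantification.

Junction-associated fluorescence is quantified from multi-channel z-stacks
by maximum-intensity projection, optional tile stitching (whole-filter
mosaics acquired as a grid with ~10% overlap), and intensity-per-area
measurements within junction ROIs or over the whole image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

__all__ = [
    "ROIMask",
    "max_project",
    "stitch_tiles",
    "quantify_intensity",
    "sample_junction_rois",
]


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask congruent with its target image."""

    mask: np.ndarray
    pixel_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        object.__setattr__(self, "mask", self.mask.astype(bool))

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_nm**2


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (slice) axis."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be (slices >= 1, rows, cols)")
    return stack.max(axis=0)


def _refine_offset(
    fixed: np.ndarray,
    moving: np.ndarray,
    nominal: tuple[int, int],
    axis: int,
    overlap_px: int,
    search_px: int,
) -> tuple[int, int] | None:
    """Refine the (row, col) offset of ``moving`` relative to ``fixed``.

    Matches the leading strip of ``moving`` (the overlap region) against a
    search window in ``fixed`` around the nominal position by normalized
    cross-correlation.  Returns None when the overlap is featureless.
    """
    h, w = fixed.shape
    strip = max(2, overlap_px - search_px)
    if axis == 1:  # moving sits to the right of fixed
        template = moving[search_px : h - search_px, :strip].astype(float)
        lo = max(0, nominal[1] - search_px)
        window = fixed[:, lo:].astype(float)
    else:  # moving sits below fixed
        template = moving[:strip, search_px : w - search_px].astype(float)
        lo = max(0, nominal[0] - search_px)
        window = fixed[lo:, :].astype(float)
    if template.std() == 0 or window.std() == 0:
        return None
    if window.shape[0] < template.shape[0] or window.shape[1] < template.shape[1]:
        return None
    corr = match_template(window, template)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    # position of moving's top-left corner in fixed coordinates
    if axis == 1:
        return (int(peak[0]) - search_px, lo + int(peak[1]))
    return (lo + int(peak[0]), int(peak[1]) - search_px)


def stitch_tiles(
    tiles: np.ndarray,
    nominal_overlap: float = 0.1,
    search_px: int = 5,
    return_offsets: bool = False,
):
    """Stitch a rectangular grid of equally sized tiles into a mosaic.

    ``tiles`` has shape (grid_rows, grid_cols, h, w).  Tile positions start
    from the nominal grid spacing implied by ``nominal_overlap`` and are
    refined per neighbouring pair by integer-pixel normalized
    cross-correlation within ``±search_px``.  Featureless overlaps fall
    back to the nominal offsets with a warning.  Overlapping pixels are
    blended by linear feathering (distance-to-edge weights).
    """
    tiles = np.asarray(tiles)
    if tiles.ndim != 4:
        raise ValueError("tiles must be (grid_rows, grid_cols, h, w)")
    if not 0 <= nominal_overlap < 0.5:
        raise ValueError("nominal_overlap must lie in [0, 0.5)")
    gr, gc, h, w = tiles.shape
    step_r = int(round(h * (1 - nominal_overlap)))
    step_c = int(round(w * (1 - nominal_overlap)))
    ov_r, ov_c = h - step_r, w - step_c

    positions = np.zeros((gr, gc, 2), dtype=int)
    for r in range(gr):
        for c in range(gc):
            if r == 0 and c == 0:
                continue
            if c > 0:
                anchor = positions[r, c - 1]
                nominal = (0, step_c)
                ref = _refine_offset(
                    tiles[r, c - 1], tiles[r, c], nominal, axis=1,
                    overlap_px=ov_c, search_px=search_px,
                )
            else:
                anchor = positions[r - 1, c]
                nominal = (step_r, 0)
                ref = _refine_offset(
                    tiles[r - 1, c], tiles[r, c], nominal, axis=0,
                    overlap_px=ov_r, search_px=search_px,
                )
            if ref is None:
                warnings.warn(
                    f"featureless overlap at tile ({r}, {c}); using nominal offset",
                    stacklevel=2,
                )
                ref = nominal
            positions[r, c] = anchor + np.asarray(ref)

    positions -= positions.reshape(-1, 2).min(axis=0)
    out_h = int(positions[:, :, 0].max()) + h
    out_w = int(positions[:, :, 1].max()) + w

    # linear feather: weight falls off toward each tile edge
    wr = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1).astype(float)
    wc = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1).astype(float)
    feather = np.minimum(wr[:, None], wc[None, :])
    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    for r in range(gr):
        for c in range(gc):
            r0, c0 = positions[r, c]
            acc[r0 : r0 + h, c0 : c0 + w] += tiles[r, c] * feather
            wacc[r0 : r0 + h, c0 : c0 + w] += feather
    mosaic = acc / np.where(wacc > 0, wacc, 1.0)
    if np.issubdtype(tiles.dtype, np.integer):
        mosaic = np.rint(mosaic).astype(tiles.dtype)
    if return_offsets:
        return mosaic, positions
    return mosaic


def quantify_intensity(image: np.ndarray, roi: ROIMask) -> float:
    """Mean intensity per pixel within the ROI (A.U. per analyzed area).

    Whole-image quantification uses a full-true mask.
    """
    image = np.asarray(image)
    if image.shape != roi.mask.shape:
        raise ValueError("image and mask shapes differ")
    n = roi.area_px
    if n == 0:
        raise ValueError("empty ROI")
    return float(image[roi.mask].sum() / n)


def sample_junction_rois(
    mask: ROIMask,
    n: int,
    patch_nm: float,
    seed: int,
) -> list[ROIMask]:
    """Sample ``n`` non-overlapping square patches centred on junction pixels.

    Emulates the manual selection of random junction areas: patch centres
    are drawn uniformly (without replacement) from the true pixels of
    ``mask``; each candidate is rejected if its square footprint overlaps
    an already placed patch.  Each returned ROI is the patch square
    intersected with the junction mask.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    half = max(0, int(round(patch_nm / mask.pixel_nm / 2)))
    ys, xs = np.nonzero(mask.mask)
    if ys.size == 0:
        raise ValueError("mask has no junction pixels")
    order = rng.permutation(ys.size)
    h, w = mask.mask.shape
    taken = np.zeros((h, w), dtype=bool)
    rois: list[ROIMask] = []
    for idx in order:
        cy, cx = int(ys[idx]), int(xs[idx])
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        if taken[y0:y1, x0:x1].any():
            continue
        patch = np.zeros((h, w), dtype=bool)
        patch[y0:y1, x0:x1] = mask.mask[y0:y1, x0:x1]
        taken[y0:y1, x0:x1] = True
        rois.append(ROIMask(mask=patch, pixel_nm=mask.pixel_nm))
        if len(rois) == n:
            return rois
    raise ValueError(
        f"cannot place {n} disjoint patches; maximum feasible is {len(rois)}"
    )
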