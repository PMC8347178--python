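"""Single-molecule localization from blinking TIFF time-stacks.

The pipeline converts an SMLM movie into a localization table: the first
``discard_frames`` frames (default 30, the photoswitching settling period)
are dropped; per frame, a robust background level and noise SD are
estimated (median / scaled MAD), candidate spots are detected as local
maxima exceeding ``background + threshold_factor × noise_sd`` (default
factor 3), and each candidate is fit with a symmetric 2D Gaussian

    I(x, y) = offset + amplitude · exp(−((x−x0)² + (y−y0)²) / (2σ²))

integrated over the camera pixels, by nonlinear least squares with an
analytic Jacobian.  Fitted positions are reported in nm using the
half-open pixel convention (pixel (i, j) spans [j·p, (j+1)·p) ×
[i·p, (i+1)·p) nm), and position uncertainties come from the fit's
parameter covariance.  Non-converged, implausibly wide/narrow, or drifting
fits are rejected with reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .ifquant import ROIMask

__all__ = [
    "DetectionParams",
    "LocalizationTable",
    "estimate_background",
    "detect_candidates",
    "fit_gaussian_2d",
    "localize_stack",
    "apply_mask",
    "density",
    "render_pointillist",
]

LOCALIZATION_COLUMNS = [
    "frame", "x_nm", "y_nm", "amplitude", "sigma_nm", "offset",
    "err_x_nm", "err_y_nm",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection and fitting controls.

    ``threshold_factor`` is the detection threshold in units of the robust
    per-frame noise SD above the robust background; ``discard_frames``
    drops the initial settling period of the movie.  ``psf_sigma_nm`` is
    the nominal PSF width used to initialize fits and bound accepted σ
    (accepted fits satisfy 0.5 ≤ σ/nominal ≤ 3).
    """

    discard_frames: int = 30
    threshold_factor: float = 3.0
    fit_window_px: int = 9
    psf_sigma_nm: float = 130.0
    pixel_nm: float = 80.0
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.discard_frames < 0:
            raise ValueError("discard_frames must be >= 0")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be > 0")
        if self.fit_window_px < 5 or self.fit_window_px % 2 == 0:
            raise ValueError("fit_window_px must be an odd integer >= 5")


@dataclass
class LocalizationTable:
    """Per-molecule localization records for one channel.

    ``records`` holds one row per accepted blink event with columns
    frame, x_nm, y_nm, amplitude, sigma_nm, offset, err_x_nm, err_y_nm.
    ``roi_area_nm2`` is set after masking and enables density computation.
    """

    records: pd.DataFrame
    pixel_nm: float
    channel: str = ""
    roi_area_nm2: float | None = None
    rejections: list[tuple[int, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if self.roi_area_nm2 is not None and self.roi_area_nm2 <= 0:
            raise ValueError("roi_area_nm2 must be > 0 when set")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records[LOCALIZATION_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, pixel_nm: float, channel: str = "") -> "LocalizationTable":
        return cls(records=pd.read_csv(path), pixel_nm=pixel_nm, channel=channel)


def estimate_background(frame: np.ndarray) -> tuple[float, float]:
    """Robust (background level, noise SD) of one frame.

    Median and 1.4826 × median absolute deviation, insensitive to the
    sparse bright spots a blinking frame contains.  A constant frame gives
    noise_sd = 0 (the caller should treat thresholds accordingly).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def detect_candidates(
    frame: np.ndarray,
    params: DetectionParams,
    background: tuple[float, float] | None = None,
) -> list[tuple[int, int]]:
    """Candidate spot pixels: strict 8-neighbourhood maxima above threshold.

    The background-subtracted frame is matched-filtered with a Gaussian of
    the nominal PSF width to localize peaks robustly; a pixel qualifies
    when it is a strict local maximum of the filtered frame, exceeds
    ``threshold_factor`` times the filtered noise SD there (raw robust
    noise scaled by the kernel's L2 norm), and its raw value exceeds
    ``bg + threshold_factor × noise_sd``.  Candidates closer than half the
    fit window are merged, keeping the brighter one.  Returns (row, col)
    integer peaks.
    """
    frame = np.asarray(frame, dtype=float)
    bg, noise = estimate_background(frame) if background is None else background
    sigma_px = params.psf_sigma_nm / params.pixel_nm
    smoothed = ndimage.gaussian_filter(frame - bg, sigma_px, mode="nearest")
    # white noise filtered by a unit-sum Gaussian has SD scaled by its L2 norm
    kernel_l2 = 1.0 / (2.0 * np.sqrt(np.pi) * sigma_px)
    threshold = params.threshold_factor * noise * kernel_l2
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(smoothed, footprint=footprint, mode="nearest")
    is_peak = (
        (smoothed > neighbor_max)
        & (smoothed > threshold)
        & (frame > bg + params.threshold_factor * noise)
    )
    peaks = np.argwhere(is_peak)
    if peaks.size == 0:
        return []
    # merge near-duplicates, brighter wins
    order = np.argsort(-smoothed[peaks[:, 0], peaks[:, 1]], kind="stable")
    peaks = peaks[order]
    min_sep = params.fit_window_px / 2.0
    kept: list[tuple[int, int]] = []
    for r, c in peaks:
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep**2 for kr, kc in kept):
            kept.append((int(r), int(c)))
    return kept


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _axis_fractions(idx: np.ndarray, center: float, sigma: float):
    """Integrated 1D Gaussian fractions over unit pixels and derivatives.

    ``idx`` are pixel-center indices; pixel j spans [j-0.5, j+0.5) in index
    units.  Returns (fraction, d/dcenter, d/dsigma) per pixel.
    """
    z_hi = (idx + 0.5 - center) / sigma
    z_lo = (idx - 0.5 - center) / sigma
    from scipy.special import erf as _erf

    frac = 0.5 * (_erf(z_hi / np.sqrt(2.0)) - _erf(z_lo / np.sqrt(2.0)))
    pdf_hi = np.exp(-0.5 * z_hi**2) / _SQRT2PI
    pdf_lo = np.exp(-0.5 * z_lo**2) / _SQRT2PI
    d_center = (pdf_lo - pdf_hi) / sigma
    d_sigma = (pdf_lo * z_lo - pdf_hi * z_hi) / sigma
    return frac, d_center, d_sigma


def _gauss2d_model(params_vec, rows_idx, cols_idx):
    """Integrated symmetric 2D Gaussian: off + A * Fx(col) * Fy(row)."""
    off, amp, x0, y0, sigma = params_vec
    fx, _, _ = _axis_fractions(cols_idx, x0, sigma)
    fy, _, _ = _axis_fractions(rows_idx, y0, sigma)
    return off + amp * fy[:, None] * fx[None, :]


def _gauss2d_jacobian(params_vec, rows_idx, cols_idx):
    off, amp, x0, y0, sigma = params_vec
    fx, dfx_dx0, dfx_ds = _axis_fractions(cols_idx, x0, sigma)
    fy, dfy_dy0, dfy_ds = _axis_fractions(rows_idx, y0, sigma)
    prod = fy[:, None] * fx[None, :]
    jac = np.empty((prod.size, 5))
    jac[:, 0] = 1.0
    jac[:, 1] = prod.ravel()
    jac[:, 2] = (amp * fy[:, None] * dfx_dx0[None, :]).ravel()
    jac[:, 3] = (amp * dfy_dy0[:, None] * fx[None, :]).ravel()
    jac[:, 4] = (
        amp * (dfy_ds[:, None] * fx[None, :] + fy[:, None] * dfx_ds[None, :])
    ).ravel()
    return jac


def fit_gaussian_2d(
    frame: np.ndarray,
    peak: tuple[int, int],
    params: DetectionParams,
) -> dict | tuple[None, str]:
    """Least-squares symmetric 2D Gaussian fit around ``peak``.

    The model is a pixel-integrated symmetric Gaussian plus a constant
    offset, matching the physics of the rendered PSF.  Returns a record
    dict on success or ``(None, reason)`` on rejection.
    Rejection reasons: ``window_outside``, ``no_convergence``,
    ``sigma_out_of_range``, ``center_left_window``, ``nonpositive_amplitude``,
    ``singular_covariance``.
    """
    frame = np.asarray(frame, dtype=float)
    half = params.fit_window_px // 2
    r0, c0 = peak
    if (r0 - half < 0 or c0 - half < 0
            or r0 + half >= frame.shape[0] or c0 + half >= frame.shape[1]):
        return None, "window_outside"
    win = frame[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
    rows_idx = np.arange(r0 - half, r0 + half + 1, dtype=float)
    cols_idx = np.arange(c0 - half, c0 + half + 1, dtype=float)
    sigma0 = params.psf_sigma_nm / params.pixel_nm
    f_center = float(_axis_fractions(np.zeros(1), 0.0, sigma0)[0][0])
    p0 = [
        float(win.min()),
        float(win.max() - win.min()) / f_center**2,
        float(c0),
        float(r0),
        sigma0,
    ]

    def residual(p):
        return (_gauss2d_model(p, rows_idx, cols_idx) - win).ravel()

    try:
        res = optimize.least_squares(
            residual, p0, jac=lambda p: _gauss2d_jacobian(p, rows_idx, cols_idx),
            method="lm",
            xtol=params.convergence_tol, ftol=params.convergence_tol,
            max_nfev=params.max_iterations,
        )
    except Exception:
        return None, "no_convergence"
    if not res.success:
        return None, "no_convergence"
    off, amp, x0, y0, sigma = res.x
    sigma = abs(sigma)
    if not 0.5 * sigma0 <= sigma <= 3.0 * sigma0:
        return None, "sigma_out_of_range"
    if abs(x0 - c0) > half or abs(y0 - r0) > half:
        return None, "center_left_window"
    if amp <= 0:
        return None, "nonpositive_amplitude"

    # parameter covariance from the Jacobian at the solution
    jac = res.jac
    dof = max(1, win.size - len(res.x))
    s2 = 2.0 * res.cost / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        return None, "singular_covariance"
    err_x = float(np.sqrt(max(cov[2, 2], 0.0)))
    err_y = float(np.sqrt(max(cov[3, 3], 0.0)))
    if not (np.isfinite(err_x) and np.isfinite(err_y)):
        return None, "singular_covariance"
    p = params.pixel_nm
    # peak height above offset: scale times the central pixel's fractions
    peak = float(
        amp
        * _axis_fractions(np.array([round(x0)]), x0, sigma)[0][0]
        * _axis_fractions(np.array([round(y0)]), y0, sigma)[0][0]
    )
    # pixel index coordinates locate pixel centers; +0.5 maps to nm
    return dict(
        x_nm=(x0 + 0.5) * p,
        y_nm=(y0 + 0.5) * p,
        amplitude=peak,
        sigma_nm=sigma * p,
        offset=float(off),
        err_x_nm=max(err_x * p, 1e-12),
        err_y_nm=max(err_y * p, 1e-12),
    )


def localize_stack(
    stack: np.ndarray,
    params: DetectionParams,
    channel: str = "",
) -> LocalizationTable:
    """Full localization of a blinking stack into a table.

    Drops the first ``params.discard_frames`` frames, then detects and
    fits per frame.  Deterministic for fixed input.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    if stack.shape[0] <= params.discard_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames; need more than "
            f"discard_frames={params.discard_frames}"
        )
    rows: list[dict] = []
    rejections: list[tuple[int, int, int, str]] = []
    for f in range(params.discard_frames, stack.shape[0]):
        frame = stack[f].astype(float)
        bg = estimate_background(frame)
        for peak in detect_candidates(frame, params, background=bg):
            out = fit_gaussian_2d(frame, peak, params)
            if isinstance(out, dict):
                out["frame"] = f
                rows.append(out)
            else:
                rejections.append((f, peak[0], peak[1], out[1]))
    records = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    return LocalizationTable(
        records=records, pixel_nm=params.pixel_nm, channel=channel,
        rejections=rejections,
    )


def apply_mask(table: LocalizationTable, roi: ROIMask) -> LocalizationTable:
    """Restrict a table to localizations inside the ROI mask.

    A record is kept when its (x_nm, y_nm) falls in a true mask pixel
    (half-open pixel convention).  Sets ``roi_area_nm2`` to the mask's
    true-pixel area.
    """
    if roi.area_px == 0:
        raise ValueError("empty mask")
    p = roi.pixel_nm
    rec = table.records
    col = np.floor(rec["x_nm"].to_numpy() / p).astype(int)
    row = np.floor(rec["y_nm"].to_numpy() / p).astype(int)
    h, w = roi.mask.shape
    inside = (row >= 0) & (row < h) & (col >= 0) & (col < w)
    keep = np.zeros(len(rec), dtype=bool)
    keep[inside] = roi.mask[row[inside], col[inside]]
    return LocalizationTable(
        records=rec.loc[keep].reset_index(drop=True),
        pixel_nm=table.pixel_nm,
        channel=table.channel,
        roi_area_nm2=roi.area_nm2,
        rejections=list(table.rejections),
    )


def density(table: LocalizationTable) -> float:
    """Localization-event density in molecules/nm² within the masked ROI."""
    if table.roi_area_nm2 is None:
        raise ValueError("roi_area_nm2 unset; apply a mask first")
    return len(table) / table.roi_area_nm2


def render_pointillist(
    table: LocalizationTable,
    render_pixel_nm: float = 20.0,
    blur_sigma_nm: float = 0.0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Pointillist super-resolution image: a 2D histogram of positions.

    Binned at ``render_pixel_nm`` and optionally convolved with a Gaussian
    of ``blur_sigma_nm``.  The pre-blur total intensity equals the record
    count.
    """
    if render_pixel_nm <= 0:
        raise ValueError("render_pixel_nm must be > 0")
    x = table.records["x_nm"].to_numpy()
    y = table.records["y_nm"].to_numpy()
    if shape is None:
        n_rows = int(np.floor(y.max() / render_pixel_nm)) + 1 if y.size else 1
        n_cols = int(np.floor(x.max() / render_pixel_nm)) + 1 if x.size else 1
    else:
        n_rows, n_cols = shape
    img = np.zeros((n_rows, n_cols))
    if x.size:
        col = np.floor(x / render_pixel_nm).astype(int)
        row = np.floor(y / render_pixel_nm).astype(int)
        ok = (row >= 0) & (row < n_rows) & (col >= 0) & (col < n_cols)
        np.add.at(img, (row[ok], col[ok]), 1.0)
    if blur_sigma_nm > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_nm / render_pixel_nm)
    return img
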