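"""Sub-pixel localization of point-like emitters.

Detection runs an iterative peak-search in the spirit of the CLEAN
deconvolution loop: the brightest residual peak of a background-flattened
image is recorded, a fitted model spot is subtracted (window masking as
fallback) and the search repeats until the residual maximum falls below
threshold.  Each candidate is then refined by a Levenberg–Marquardt
least-squares fit of a 2D Gaussian plus a linear background plane; the
covariance of the converged fit yields per-axis standard errors of the
centre, which are the event-localization accuracy σᴱ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .io import ChannelImage

logger = logging.getLogger(__name__)

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian profile
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_from_sigma(sigma_nm: float) -> float:
    """Full width at half maximum of a Gaussian of standard deviation ``sigma_nm``."""
    if not sigma_nm > 0:
        raise ValueError("sigma must be > 0")
    return FWHM_FACTOR * sigma_nm


def sigma_from_fwhm(fwhm_nm: float) -> float:
    """Gaussian standard deviation corresponding to ``fwhm_nm`` (exact inverse)."""
    if not fwhm_nm > 0:
        raise ValueError("fwhm must be > 0")
    return fwhm_nm / FWHM_FACTOR


@dataclass
class SpotCandidate:
    """Integer-pixel location of a local intensity peak above threshold."""

    x_px: int
    y_px: int
    peak_height: float


@dataclass
class LocalizedSpot:
    """A fitted emitter position with localization-error estimates.

    ``stderr_x_nm``/``stderr_y_nm`` are standard errors of the fitted centre;
    ``sigma_e_nm`` reduces them to a scalar as the RMS of the two axes.
    """

    x_nm: float
    y_nm: float
    amplitude: float
    sigma_x_nm: float
    sigma_y_nm: float
    background: tuple[float, float, float]  # offset, slope_x, slope_y (per px)
    stderr_x_nm: float
    stderr_y_nm: float
    sigma_e_nm: float
    anisotropy: float
    converged: bool

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm], dtype=float)


def anisotropy(sigma_x: float, sigma_y: float) -> float:
    """PSF asymmetry 1 - min(sx, sy)/max(sx, sy), in [0, 1)."""
    lo, hi = sorted((abs(sigma_x), abs(sigma_y)))
    if hi == 0:
        return 0.0
    return 1.0 - lo / hi


def _flatten_background(pixels: np.ndarray, sigma_px: float) -> np.ndarray:
    return pixels - ndimage.gaussian_filter(pixels, sigma=sigma_px)


def detect_spots(
    image: ChannelImage,
    threshold: float,
    window_px: int = 11,
    max_spots: int = 500,
    background_sigma_px: float | None = None,
) -> list[SpotCandidate]:
    """Find candidate emitters above ``threshold`` on a variable background.

    Returns candidates sorted by decreasing peak height; no two candidates
    lie closer than ``window_px`` and all lie at least half a window from
    the image border.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    if window_px < 7 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 7")
    half = window_px // 2
    if background_sigma_px is None:
        background_sigma_px = 2.0 * window_px
    work = _flatten_background(image.pixels, background_sigma_px)
    ny, nx = work.shape
    candidates: list[SpotCandidate] = []
    for _ in range(max_spots * 4):
        idx = np.argmax(work)
        r, c = np.unravel_index(idx, work.shape)
        peak = work[r, c]
        if peak < threshold or len(candidates) >= max_spots:
            break
        in_border = half <= r < ny - half and half <= c < nx - half
        too_close = any(
            max(abs(s.x_px - c), abs(s.y_px - r)) < window_px for s in candidates
        )
        if in_border and not too_close:
            candidates.append(SpotCandidate(x_px=int(c), y_px=int(r), peak_height=float(peak)))
        if in_border and not _clean_subtract(work, r, c, half):
            work[max(0, r - half):r + half + 1, max(0, c - half):c + half + 1] = -np.inf
        elif not in_border:
            # peak too close to the border for a model fit: mask it out
            work[max(0, r - half):r + half + 1, max(0, c - half):c + half + 1] = -np.inf
    candidates.sort(key=lambda s: s.peak_height, reverse=True)
    return candidates


def _clean_subtract(work: np.ndarray, r: int, c: int, half: int) -> bool:
    """Subtract a fitted Gaussian (CLEAN gain 1) at (r, c); False if the fit fails."""
    win = work[r - half:r + half + 1, c - half:c + half + 1]
    try:
        res = _fit_gaussian_window(win, allow_background=False)
    except Exception:
        return False
    amp, x0, y0, sx, sy = res.x[:5]
    sx, sy = abs(sx), abs(sy)
    if not (amp > 0 and 0 <= x0 <= 2 * half and 0 <= y0 <= 2 * half and sx > 0 and sy > 0):
        return False
    ext = int(np.ceil(4 * max(sx, sy))) + half
    r0, r1 = max(0, r - ext), min(work.shape[0], r + ext + 1)
    c0, c1 = max(0, c - ext), min(work.shape[1], c + ext + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    gx = xx - (c - half + x0)
    gy = yy - (r - half + y0)
    work[r0:r1, c0:c1] -= amp * np.exp(-(gx**2 / (2 * sx**2) + gy**2 / (2 * sy**2)))
    return True


def _model(params, xx, yy, with_background=True):
    amp, x0, y0, sx, sy = params[:5]
    g = amp * np.exp(-((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2)))
    if with_background:
        b0, b1, b2 = params[5:]
        g = g + b0 + b1 * xx + b2 * yy
    return g


def _fit_gaussian_window(win: np.ndarray, allow_background: bool = True):
    ny, nx = win.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r0, c0 = np.unravel_index(np.argmax(win), win.shape)
    edge = np.median(np.concatenate([win[0], win[-1], win[:, 0], win[:, -1]]))
    amp0 = max(win[r0, c0] - edge, 1e-6)
    s0 = max(nx / 5.0, 1.0)
    if allow_background:
        p0 = [amp0, float(c0), float(r0), s0, s0, float(edge), 0.0, 0.0]
    else:
        p0 = [amp0, float(c0), float(r0), s0, s0]

    def resid(p):
        return (_model(p, xx, yy, allow_background) - win).ravel()

    res = optimize.least_squares(resid, p0, method="lm", max_nfev=400)
    if not res.success:
        raise RuntimeError("fit did not converge")
    return res


def fit_spot(image: ChannelImage, candidate: SpotCandidate, window_px: int = 11) -> LocalizedSpot:
    """Fit a 2D Gaussian with a linear background plane around a candidate.

    The model is ``A exp(-((x-x0)^2/(2 sx^2) + (y-y0)^2/(2 sy^2))) + b0 +
    b1 x + b2 y`` minimized by Levenberg–Marquardt over a ``window_px``
    square window.  Standard errors come from the Jacobian-based covariance
    of the converged solution scaled by the residual variance.  A fit that
    fails to converge, or whose centre escapes the window, is returned with
    ``converged=False`` and should be excluded downstream.
    """
    half = window_px // 2
    r, c = candidate.y_px, candidate.x_px
    ny, nx = image.pixels.shape
    if not (half <= r < ny - half and half <= c < nx - half):
        raise ValueError("fit window extends outside the image")
    win = image.pixels[r - half:r + half + 1, c - half:c + half + 1]
    px = image.pixel_size_nm

    def failed():
        return LocalizedSpot(
            x_nm=c * px, y_nm=r * px, amplitude=0.0, sigma_x_nm=0.0, sigma_y_nm=0.0,
            background=(0.0, 0.0, 0.0), stderr_x_nm=np.inf, stderr_y_nm=np.inf,
            sigma_e_nm=np.inf, anisotropy=0.0, converged=False,
        )

    try:
        res = _fit_gaussian_window(win, allow_background=True)
    except Exception:
        logger.info("spot at (%d, %d): fit failed to converge", c, r)
        return failed()
    amp, x0, y0, sx, sy, b0, b1, b2 = res.x
    sx, sy = abs(sx), abs(sy)
    if not (amp > 0 and sx > 0 and sy > 0):
        logger.info("spot at (%d, %d): non-physical fit parameters", c, r)
        return failed()
    if sx > window_px or sy > window_px:
        # a width beyond the window means the fit latched onto background
        logger.info("spot at (%d, %d): fitted width exceeds the window", c, r)
        return failed()
    if not (0 <= x0 <= 2 * half and 0 <= y0 <= 2 * half):
        logger.info("spot at (%d, %d): fitted centre escaped the window", c, r)
        return failed()

    # covariance = (J^T J)^-1 * residual variance
    n_obs, n_par = win.size, len(res.x)
    dof = max(n_obs - n_par, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        logger.info("spot at (%d, %d): singular covariance", c, r)
        return failed()
    stderr_x_nm = stderr[1] * px
    stderr_y_nm = stderr[2] * px
    if not np.isfinite(stderr_x_nm) or not np.isfinite(stderr_y_nm) \
            or max(stderr_x_nm, stderr_y_nm) > window_px * px:
        # an uncertainty larger than the search window carries no information
        logger.info("spot at (%d, %d): uninformative fit (stderr beyond window)", c, r)
        return failed()
    sigma_e = float(np.sqrt((stderr_x_nm**2 + stderr_y_nm**2) / 2.0))
    return LocalizedSpot(
        x_nm=(c - half + x0) * px,
        y_nm=(r - half + y0) * px,
        amplitude=float(amp),
        sigma_x_nm=float(sx * px),
        sigma_y_nm=float(sy * px),
        background=(float(b0), float(b1), float(b2)),
        stderr_x_nm=float(stderr_x_nm),
        stderr_y_nm=float(stderr_y_nm),
        sigma_e_nm=sigma_e,
        anisotropy=anisotropy(sx, sy),
        converged=True,
    )


def locate(image: ChannelImage, threshold: float, window_px: int = 11,
           **detect_kwargs) -> list[LocalizedSpot]:
    """Detect and fit all spots in one call, dropping non-converged fits."""
    spots = []
    n_failed = 0
    for cand in detect_spots(image, threshold, window_px, **detect_kwargs):
        spot = fit_spot(image, cand, window_px)
        if spot.converged:
            spots.append(spot)
        else:
            n_failed += 1
    if n_failed:
        logger.info("%s channel: %d spot(s) excluded for failed fits",
                    image.channel_label, n_failed)
    return spots
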