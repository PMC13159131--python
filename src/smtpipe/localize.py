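"""Per-frame spot detection, subpixel localization, density QC, and
single-step photobleaching validation.

Detection is a difference-of-Gaussians band-pass thresholded against a
robust (MAD-based) estimate of the background fluctuation; each
candidate maximum is refined by least-squares fitting of a
pixel-integrated 2-D isotropic Gaussian plus constant offset.  Density
QC averages detections per frame over the first frames of a movie,
before appreciable photobleaching.  Single-fluorophore identity is
checked by counting downward change-points in a spot's intensity trace:
exactly one step is the signature of a single dye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.special import erf

#: detection threshold in units of the robust background s.d.
THRESHOLD_FACTOR_DEFAULT = 5.0
#: frames used for the density estimate (before appreciable bleaching)
DENSITY_FRAMES_DEFAULT = 10
#: minimum downward step size, in local-noise s.d., to count as a bleach step
BLEACH_STEP_SNR = 3.0
#: change-point acceptance: Δcost must exceed PENALTY_FACTOR · log(n)
BLEACH_PENALTY_FACTOR = 3.0


@dataclass
class SpotDetection:
    """One localized emitter in one frame.  Positions in µm."""

    frame: int
    x: float
    y: float
    intensity: float  # fitted integrated signal (photons)
    width: float      # fitted Gaussian s.d. (µm)
    quality: float    # band-pass peak height / robust background s.d.


@dataclass
class IntensityTrace:
    """Background-subtracted intensity of one spot over time."""

    frames: np.ndarray
    values: np.ndarray
    clipped: bool = False  # aperture ran off the image edge

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.frames) != len(self.values):
            raise ValueError("frames and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")


def _robust_sd(a: np.ndarray) -> float:
    med = np.median(a)
    return 1.4826 * float(np.median(np.abs(a - med)))


def _integrated_gaussian(coords, A, x0, y0, sigma, offset):
    """Pixel-integrated isotropic 2-D Gaussian (erf model)."""
    x, y = coords
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((x + 0.5 - x0) / s) - erf((x - 0.5 - x0) / s))
    fy = 0.5 * (erf((y + 0.5 - y0) / s) - erf((y - 0.5 - y0) / s))
    return A * fx * fy + offset


def detect_spots(
    frame_image: np.ndarray,
    pixel_size: float,
    psf_sigma_guess: float,
    threshold_factor: float = THRESHOLD_FACTOR_DEFAULT,
    frame: int = 0,
) -> list[SpotDetection]:
    """Detect and localize emitters in one frame.

    Candidates are local maxima of a difference-of-Gaussians response
    (σ and 2σ of the expected PSF) above ``threshold_factor`` times the
    robust s.d. of the response.  Each candidate is refined in a window
    of half-width 3·psf_sigma by least squares; fits that diverge, whose
    width leaves [0.5, 2]×psf_sigma_guess, or whose center leaves the
    window are dropped.  Returns positions in µm.
    """
    if frame_image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={frame_image.ndim}")
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be > 0, got {pixel_size}")
    img = np.asarray(frame_image, dtype=np.float64)
    if img.size == 0 or img.max() == img.min():
        return []

    sigma_px = psf_sigma_guess / pixel_size
    response = (ndimage.gaussian_filter(img, sigma_px)
                - ndimage.gaussian_filter(img, 2.0 * sigma_px))
    noise = _robust_sd(response)
    if noise == 0:
        noise = response.std() or 1.0
    thr = threshold_factor * noise
    is_max = response == ndimage.maximum_filter(response, size=3)
    cand_y, cand_x = np.nonzero(is_max & (response > thr))

    half = max(int(math.ceil(3.0 * sigma_px)), 3)
    ny, nx = img.shape
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    out: list[SpotDetection] = []
    for cy, cx in zip(cand_y, cand_x):
        if not (half <= cx < nx - half and half <= cy < ny - half):
            continue  # too close to the edge for a full fit window
        win = img[cy - half : cy + half + 1, cx - half : cx + half + 1]
        offset0 = float(win.min())
        amp0 = float(win.max() - offset0)
        if amp0 <= 0:
            continue
        try:
            popt, _ = curve_fit(
                _integrated_gaussian,
                (xx.ravel(), yy.ravel()),
                win.ravel(),
                p0=(amp0 * 2.0 * math.pi * sigma_px**2, 0.0, 0.0, sigma_px, offset0),
                maxfev=400,
            )
        except (RuntimeError, ValueError):
            continue
        A, x0, y0, sig, _ = popt
        sig = abs(sig)
        if A <= 0 or not (0.5 * sigma_px <= sig <= 2.0 * sigma_px):
            continue
        if abs(x0) > half or abs(y0) > half:
            continue
        x_px, y_px = cx + x0, cy + y0
        out.append(
            SpotDetection(
                frame=frame,
                x=(x_px + 0.5) * pixel_size,
                y=(y_px + 0.5) * pixel_size,
                intensity=float(A),
                width=sig * pixel_size,
                quality=float(response[cy, cx] / noise),
            )
        )
    return out


def detect_stack(
    stack: np.ndarray,
    pixel_size: float,
    psf_sigma_guess: float,
    threshold_factor: float = THRESHOLD_FACTOR_DEFAULT,
    frames: range | None = None,
) -> dict[int, list[SpotDetection]]:
    """Run :func:`detect_spots` on each frame of a stack."""
    if frames is None:
        frames = range(stack.shape[0])
    return {
        f: detect_spots(stack[f], pixel_size, psf_sigma_guess,
                        threshold_factor=threshold_factor, frame=f)
        for f in frames
    }


def estimate_density(
    detections_by_frame: dict[int, list[SpotDetection]],
    field_area_um2: float,
) -> float:
    """Mean detections per frame divided by field area (spots/µm²)."""
    if not field_area_um2 > 0:
        raise ValueError(f"field area must be > 0, got {field_area_um2}")
    if len(detections_by_frame) == 0:
        raise ValueError("need at least one frame of detections")
    counts = [len(v) for v in detections_by_frame.values()]
    return float(np.mean(counts)) / field_area_um2


def extract_trace(
    stack: np.ndarray,
    position_um: tuple[float, float],
    pixel_size: float,
    aperture_radius_px: int = 3,
) -> IntensityTrace:
    """Aperture photometry at a fixed position across a stack.

    Sums pixels within ``aperture_radius_px`` of the position and
    subtracts the local background estimated as the median of an annulus
    (radii r+2 .. r+5 px) times the aperture pixel count.  The trace is
    flagged ``clipped`` if the annulus runs off the image edge.
    """
    n_frames, ny, nx = stack.shape
    cx = position_um[0] / pixel_size - 0.5
    cy = position_um[1] / pixel_size - 0.5
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"position {position_um} µm is outside the field")
    r_out = aperture_radius_px + 5
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    ap = d2 <= aperture_radius_px**2
    ann = (d2 > (aperture_radius_px + 2) ** 2) & (d2 <= r_out**2)
    clipped = (cx < r_out or cx > nx - 1 - r_out or cy < r_out or cy > ny - 1 - r_out)
    n_ap = int(ap.sum())
    data = stack.astype(np.float64)
    ap_sum = data[:, ap].sum(axis=1)
    bg = np.median(data[:, ann], axis=1) if ann.any() else np.zeros(n_frames)
    return IntensityTrace(
        frames=np.arange(n_frames), values=ap_sum - bg * n_ap, clipped=clipped
    )


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best single change-point of the mean by SSE; returns (index, gain).

    ``index`` is the first point of the right segment; gain is the SSE
    reduction of the two-mean model versus one mean.
    """
    n = len(x)
    csum = np.cumsum(x)
    tot = csum[-1]
    k = np.arange(1, n)  # left segment sizes
    left_mean = csum[:-1] / k
    right_mean = (tot - csum[:-1]) / (n - k)
    # SSE reduction = between-group sum of squares
    gain = k * (n - k) / n * (left_mean - right_mean) ** 2
    i = int(np.argmax(gain))
    return i + 1, float(gain[i])


def count_bleach_steps(
    trace: IntensityTrace,
    penalty_factor: float = BLEACH_PENALTY_FACTOR,
    min_step_snr: float = BLEACH_STEP_SNR,
    min_seg: int = 3,
) -> tuple[int, list[int]]:
    """Count downward intensity steps via binary change-point segmentation.

    Change-points are accepted while the Gaussian-model cost improvement
    n·log(SSE₀/SSE₁) exceeds ``penalty_factor``·log(n_total) (a
    Bayesian-information-style penalty).  Of the accepted change-points,
    only downward mean changes larger than ``min_step_snr`` times the
    local noise s.d. (from the median absolute successive difference)
    count as bleach steps.  Returns (count, step frame indices).
    """
    x = trace.values
    n = len(x)
    if n < 10:
        raise ValueError(f"trace too short for step detection ({n} < 10 frames)")
    penalty = penalty_factor * math.log(n)
    noise = _robust_sd(np.diff(x)) / math.sqrt(2.0)
    if noise == 0:
        noise = max(float(np.std(x)) * 1e-3, 1e-12)

    cps: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if len(seg) < 2 * min_seg:
            return
        i, gain = _best_split(seg)
        if i < min_seg or len(seg) - i < min_seg:
            return
        sse0 = float(((seg - seg.mean()) ** 2).sum())
        sse1 = sse0 - gain
        if sse1 <= 0 or len(seg) * math.log(sse0 / sse1) <= penalty:
            return
        cps.append(lo + i)
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, n)
    steps = []
    for cp in sorted(cps):
        left = x[max(cp - 20, 0) : cp].mean()
        right = x[cp : cp + 20].mean()
        if left - right > min_step_snr * noise:
            steps.append(int(trace.frames[cp]))
    return len(steps), steps
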