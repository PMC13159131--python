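"""Camera model: render trajectory ensembles into TIRF-like image stacks.

Each live emitter is drawn as an isotropic 2-D Gaussian PSF integrated
over the pixel grid (error-function model) and scaled to its expected
photon count; per-pixel shot noise is Poisson on signal plus uniform
background.  Photobleaching is single-step: with per-frame probability
``bleach_prob`` an emitter goes dark irreversibly.  Output is a 16-bit
unsigned stack (photon counts) plus a ground-truth table linking pixels,
µm and trajectory ids.

Pixel convention: pixel i spans [i·s, (i+1)·s) µm, so the continuous
pixel coordinate of a point at x µm is x/s − 0.5 (integer values sit at
pixel centers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.special import erf

from .simulate import Trajectory


@dataclass(frozen=True)
class MovieSpec:
    """Imaging parameters for the synthetic camera.

    field_size: side of the square field (µm); pixel_size: µm/px;
    psf_sigma: PSF s.d. (µm); photons_per_spot: expected photons per
    emitter per frame; background: expected background photons per
    pixel; bleach_prob: per-frame single-step bleach probability;
    density: nominal emitter density (spots/µm²), used by
    :func:`expected_n_emitters`.
    """

    field_size: float = 25.6
    pixel_size: float = 0.107
    psf_sigma: float = 0.1
    photons_per_spot: float = 300.0
    background: float = 20.0
    bleach_prob: float = 0.0
    density: float = 0.2

    def __post_init__(self) -> None:
        for name in ("field_size", "pixel_size", "psf_sigma", "photons_per_spot"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")
        if not 0.0 <= self.bleach_prob < 1.0:
            raise ValueError(f"bleach_prob must be in [0, 1), got {self.bleach_prob}")
        if self.density < 0:
            raise ValueError(f"density must be >= 0, got {self.density}")
        if self.pixel_size >= 2.0 * self.psf_sigma:
            warnings.warn(
                f"pixel_size {self.pixel_size} µm >= 2·psf_sigma "
                f"{2 * self.psf_sigma:.3g} µm: PSF is undersampled",
                stacklevel=2,
            )

    @property
    def n_px(self) -> int:
        return int(round(self.field_size / self.pixel_size))


def expected_n_emitters(spec: MovieSpec) -> int:
    """Initial emitter count implied by density × field area."""
    return int(round(spec.density * spec.field_size**2))


def um_to_px(x_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """µm → continuous pixel coordinate (integer = pixel center)."""
    return np.asarray(x_um) / pixel_size - 0.5


def px_to_um(x_px: np.ndarray, pixel_size: float) -> np.ndarray:
    return (np.asarray(x_px) + 0.5) * pixel_size


def _add_spot(img: np.ndarray, x_px: float, y_px: float, sigma_px: float,
              photons: float) -> None:
    """Accumulate an integrated-Gaussian spot onto ``img`` in place."""
    n = img.shape[0]
    half = int(math.ceil(4 * sigma_px)) + 1
    cx, cy = int(round(x_px)), int(round(y_px))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, n)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, n)
    if x0 >= x1 or y0 >= y1:
        return
    s = sigma_px * math.sqrt(2.0)
    ex = 0.5 * (erf((np.arange(x0, x1) + 0.5 - x_px) / s)
                - erf((np.arange(x0, x1) - 0.5 - x_px) / s))
    ey = 0.5 * (erf((np.arange(y0, y1) + 0.5 - y_px) / s)
                - erf((np.arange(y0, y1) - 0.5 - y_px) / s))
    img[y0:y1, x0:x1] += photons * np.outer(ey, ex)


def render_movie(
    trajectories: list[Trajectory],
    spec: MovieSpec,
    seed: int,
    n_frames: int | None = None,
    poisson: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render trajectories into a (n_frames, n_px, n_px) uint16 stack.

    Returns ``(stack, truth)`` where ``truth`` has one row per emitter
    per frame with columns frame, traj_id, x_px, y_px, x_um, y_um,
    photons, alive.  Bleached emitters keep their rows with alive=0 and
    photons=0.  ``poisson=False`` disables shot noise (useful for
    localization-bias benchmarks).
    """
    rng = default_rng(SeedSequence(entropy=seed, spawn_key=(0xCA3,)))
    n_px = spec.n_px
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) for t in trajectories), default=0) + 1
    sigma_px = spec.psf_sigma / spec.pixel_size

    # per-trajectory bleach frame (first frame in which the dye is dark)
    bleach_at: dict = {}
    for t in trajectories:
        if spec.bleach_prob > 0:
            u = rng.random(n_frames)
            dark = np.nonzero(u < spec.bleach_prob)[0]
            bleach_at[t.traj_id] = int(dark[0]) + 1 if len(dark) else n_frames + 1
        else:
            bleach_at[t.traj_id] = n_frames + 1

    pos_by_frame: dict[int, list] = {f: [] for f in range(n_frames)}
    for t in trajectories:
        for k, f in enumerate(t.frames):
            f = int(f)
            if f < n_frames:
                pos_by_frame[f].append((t.traj_id, t.x[k], t.y[k]))

    stack = np.empty((n_frames, n_px, n_px), dtype=np.uint16)
    rows = []
    for f in range(n_frames):
        img = np.full((n_px, n_px), float(spec.background))
        for tid, x_um, y_um in pos_by_frame[f]:
            alive = f < bleach_at[tid]
            x_px = x_um / spec.pixel_size - 0.5
            y_px = y_um / spec.pixel_size - 0.5
            photons = spec.photons_per_spot if alive else 0.0
            if alive:
                _add_spot(img, x_px, y_px, sigma_px, photons)
            rows.append((f, tid, x_px, y_px, x_um, y_um, photons, int(alive)))
        if poisson:
            img = rng.poisson(img).astype(np.float64)
        stack[f] = np.clip(img, 0, np.iinfo(np.uint16).max).astype(np.uint16)

    truth = pd.DataFrame(
        rows, columns=["frame", "traj_id", "x_px", "y_px", "x_um", "y_um",
                       "photons", "alive"]
    )
    return stack, truth
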