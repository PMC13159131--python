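"""Time-averaged MSD, diffusion-coefficient and anomalous-exponent estimation,
and motion-mode classification.

For a 2-D trajectory sampled at interval dt, the time-averaged mean
squared displacement at lag n is the mean over all ordered position
pairs (i, i+n) of the squared Euclidean displacement.  For Brownian
motion MSD(τ) = 4Dτ (+ 4σ_loc² from localization noise); confined
motion saturates, directed motion grows ~τ².  The power-law exponent α
of MSD ∝ τ^α classifies the mode: α below ``confined_max`` → confined,
above ``directed_min`` → directed, otherwise Brownian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import Trajectory

log = logging.getLogger(__name__)

#: Default α thresholds (confined_max, directed_min).
ALPHA_CONFINED_MAX = 0.7
ALPHA_DIRECTED_MIN = 1.3

N_FIT_D = 4          # lags in the linear short-lag D fit
ALPHA_MAX_LAG = 10   # α log-log fit uses lags 1..min(this, N//4)
MIN_LEN_DEFAULT = 20


@dataclass(frozen=True)
class AlphaThresholds:
    """α cutpoints separating confined / Brownian / directed motion."""

    confined_max: float = ALPHA_CONFINED_MAX
    directed_min: float = ALPHA_DIRECTED_MIN

    def __post_init__(self) -> None:
        if not (0.0 < self.confined_max < self.directed_min < 2.5):
            raise ValueError(
                f"need 0 < confined_max < directed_min < 2.5, "
                f"got ({self.confined_max}, {self.directed_min})"
            )


@dataclass
class MSDCurve:
    """Time-averaged MSD of one trajectory.

    ``lags`` are lag times in seconds (n·dt), ``values`` the mean squared
    displacements (µm²), ``n_pairs`` the number of displacement pairs
    averaged at each lag (0 where a lag has no pairs, e.g. inside gaps).
    """

    traj_id: int | str
    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MotionFit:
    """Per-trajectory fit results: D (µm²/s), α, mode label, diagnostics."""

    traj_id: int | str
    D: float
    alpha: float          # NaN if undefined
    mode: str | None      # None if α undefined
    r2_loglog: float
    n_frames: int
    intercept: float = 0.0
    D_clamped: bool = False


def compute_tamsd(traj: Trajectory, dt: float, max_lag: int | None = None) -> MSDCurve:
    """Time-averaged MSD over lags 1..max_lag (default ⌊span/4⌋, min 1).

    Pairs spanning closed gaps contribute to the lag equal to their true
    frame difference; lags with no pairs get value NaN and n_pairs 0.
    """
    n = len(traj)
    if n < 2:
        raise ValueError(f"trajectory {traj.traj_id}: too short for MSD ({n} points)")
    f0 = traj.frames - traj.frames[0]
    span = int(f0[-1])
    if max_lag is None:
        max_lag = max(span // 4, 1)
    if max_lag >= span + 1:
        raise ValueError(
            f"trajectory {traj.traj_id}: max_lag {max_lag} exceeds frame span {span}"
        )
    # dense frame grid with NaN at missing frames -> vectorized lag sums
    gx = np.full(span + 1, np.nan)
    gy = np.full(span + 1, np.nan)
    gx[f0] = traj.x
    gy[f0] = traj.y
    values = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for lag in range(1, max_lag + 1):
        dx = gx[lag:] - gx[:-lag]
        dy = gy[lag:] - gy[:-lag]
        sq = dx * dx + dy * dy
        good = ~np.isnan(sq)
        n_pairs[lag - 1] = int(good.sum())
        values[lag - 1] = sq[good].mean() if n_pairs[lag - 1] else np.nan
    return MSDCurve(
        traj_id=traj.traj_id,
        lags=np.arange(1, max_lag + 1) * dt,
        values=values,
        n_pairs=n_pairs,
    )


def estimate_D(msd: MSDCurve, n_fit: int = N_FIT_D) -> tuple[float, float, bool]:
    """Short-lag OLS estimate of D: slope/4 of MSD on τ over the first
    ``n_fit`` lags.  Returns (D, intercept, clamped); a negative slope is
    clamped to D = 0 with ``clamped`` True.  The intercept absorbs the
    localization-noise offset 4σ_loc².
    """
    if n_fit < 2:
        raise ValueError(f"n_fit must be >= 2, got {n_fit}")
    good = ~np.isnan(msd.values[:n_fit])
    tau = msd.lags[:n_fit][good]
    val = msd.values[:n_fit][good]
    if len(tau) < 2:
        raise ValueError(
            f"trajectory {msd.traj_id}: only {len(tau)} usable lags for D fit (need >= 2)"
        )
    slope, intercept = np.polyfit(tau, val, 1)
    if slope < 0:
        return 0.0, float(intercept), True
    return float(slope) / 4.0, float(intercept), False


def estimate_alpha(
    msd: MSDCurve, fit_window: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Anomalous exponent: OLS slope of log MSD on log τ.

    ``fit_window`` is an inclusive 1-based lag-index range; default
    (1, min(10, n_lags)).  Non-positive MSD values are dropped (logged).
    Returns (alpha, r²); (NaN, NaN) when fewer than 3 usable lags remain,
    in which case the trajectory is excluded from classification.
    """
    if fit_window is None:
        fit_window = (1, min(ALPHA_MAX_LAG, len(msd.lags)))
    lo, hi = fit_window
    tau = msd.lags[lo - 1 : hi]
    val = msd.values[lo - 1 : hi]
    good = ~np.isnan(val) & (val > 0)
    if (~good & ~np.isnan(val)).any():
        log.debug("trajectory %s: dropped %d non-positive MSD values from α fit",
                  msd.traj_id, int((~good & ~np.isnan(val)).sum()))
    if good.sum() < 3:
        return float("nan"), float("nan")
    lt = np.log(tau[good])
    lv = np.log(val[good])
    alpha, b = np.polyfit(lt, lv, 1)
    resid = lv - (alpha * lt + b)
    ss_tot = float(((lv - lv.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return float(alpha), r2


#: corral-model shape constants (classic SPT confined-diffusion fit)
CORRAL_A = 0.99
CORRAL_B = 0.85
#: lags used in the directed-model quadratic fit; beyond this the drift
#: term and TA-MSD noise dominate and the linear (diffusive) term drowns
N_FIT_DIRECTED = 8


def estimate_D_confined(msd: MSDCurve) -> float | None:
    """Micro-diffusivity of a confined trajectory from the corral model.

    Fits MSD(τ) = P·(1 − A·exp(−4BDτ/P)) + c over all available lags,
    with shape constants A = 0.99, B = 0.85 (the standard
    confined-diffusion MSD approximation for a reflecting circular
    domain): P is the confinement plateau (≈ R²), c the
    localization-noise floor, and D the short-time diffusion
    coefficient, which a straight-line fit underestimates once the MSD
    saturates.  Returns None if the fit fails (caller falls back to the
    linear estimator).
    """
    good = ~np.isnan(msd.values)
    tau = msd.lags[good]
    val = msd.values[good]
    if len(tau) < 4:
        return None
    dt = float(tau[0])
    c0 = max(float(2 * val[0] - val[1]), 0.0)
    P0 = max(float(val[-1] - c0), 1e-6)
    D0 = max((float(val[0]) - c0) / (4 * dt), 1e-6)

    def model(t, P, D, c):
        return P * (1.0 - CORRAL_A * np.exp(-4.0 * CORRAL_B * D * t / P)) + c

    try:
        popt, _ = curve_fit(
            model, tau, val, p0=(P0, D0, c0),
            sigma=_tamsd_sigma(msd, good), absolute_sigma=False,
            bounds=([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf]), maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return None
    return float(popt[1])


def _tamsd_sigma(msd: MSDCurve, good: np.ndarray) -> np.ndarray:
    """Relative error weights for TA-MSD lags.

    The sampling s.d. of the time-averaged MSD at lag n over N points
    grows roughly like value·sqrt(n/(N−n+1)); down-weighting high lags
    accordingly roughly equalizes information across the curve.
    """
    ns = np.arange(1, len(msd.lags) + 1)[good]
    N = int(msd.n_pairs[0]) + 1 if len(msd.n_pairs) else len(ns) + 1
    return np.maximum(msd.values[good], 1e-12) * np.sqrt(ns / np.maximum(N - ns + 1, 1))


def estimate_D_directed(msd: MSDCurve) -> float | None:
    """Diffusive part of a directed trajectory's MSD.

    Fits MSD(τ) = 4Dτ + (vτ)² + c by quadratic least squares over the
    first N_FIT_DIRECTED lags, so the drift term no longer inflates the
    linear slope.  Returns the linear coefficient / 4 clamped at 0, or
    None if fewer than 4 lags are usable.
    """
    good = ~np.isnan(msd.values[:N_FIT_DIRECTED])
    tau = msd.lags[:N_FIT_DIRECTED][good]
    val = msd.values[:N_FIT_DIRECTED][good]
    if len(tau) < 4:
        return None
    sub = MSDCurve(msd.traj_id, msd.lags[:N_FIT_DIRECTED],
                   msd.values[:N_FIT_DIRECTED], msd.n_pairs[:N_FIT_DIRECTED])
    w = 1.0 / _tamsd_sigma(sub, good) ** 2
    _, a1, _ = np.polyfit(tau, val, 2, w=np.sqrt(w))
    return max(float(a1), 0.0) / 4.0


def classify_mode(alpha: float, thresholds: AlphaThresholds | None = None) -> str:
    """Map α to a mode label; boundary equality goes to Brownian."""
    if thresholds is None:
        thresholds = AlphaThresholds()
    if np.isnan(alpha):
        raise ValueError("alpha is undefined; exclude the trajectory instead")
    if alpha < thresholds.confined_max:
        return "confined"
    if alpha > thresholds.directed_min:
        return "directed"
    return "brownian"


def fit_trajectory(
    traj: Trajectory,
    dt: float,
    thresholds: AlphaThresholds | None = None,
    n_fit_D: int = N_FIT_D,
    min_len: int = MIN_LEN_DEFAULT,
) -> MotionFit:
    """MSD → (D, α, mode) for one trajectory (the per-trajectory pipeline)."""
    if len(traj) < min_len:
        raise ValueError(
            f"trajectory {traj.traj_id}: {len(traj)} frames < min_len {min_len}"
        )
    msd = compute_tamsd(traj, dt)
    D, intercept, clamped = estimate_D(msd, n_fit=n_fit_D)
    alpha, r2 = estimate_alpha(msd)
    mode = None if np.isnan(alpha) else classify_mode(alpha, thresholds)
    # mode-aware refit: the plain short-lag slope underestimates D once a
    # corral saturates the MSD and overestimates it when drift dominates
    if mode == "confined":
        D_ref = estimate_D_confined(msd)
        if D_ref is not None:
            D = D_ref
    elif mode == "directed":
        D_ref = estimate_D_directed(msd)
        if D_ref is not None:
            D = D_ref
    return MotionFit(
        traj_id=traj.traj_id,
        D=D,
        alpha=alpha,
        mode=mode,
        r2_loglog=r2,
        n_frames=len(traj),
        intercept=intercept,
        D_clamped=clamped,
    )


def fit_population(
    trajectories: list[Trajectory],
    dt: float,
    thresholds: AlphaThresholds | None = None,
    min_len: int = MIN_LEN_DEFAULT,
) -> tuple[list[MotionFit], int]:
    """Fit every trajectory of at least ``min_len`` frames.

    Returns (fits, n_skipped_short).  Trajectories with undefined α stay
    in the list (mode None): they count toward D statistics but not mode
    fractions.
    """
    fits: list[MotionFit] = []
    skipped = 0
    for t in trajectories:
        if len(t) < min_len:
            skipped += 1
            continue
        fits.append(fit_trajectory(t, dt, thresholds=thresholds, min_len=min_len))
    return fits, skipped


def mode_fractions(fits: list[MotionFit]) -> tuple[dict[str, float], int]:
    """Fractions of classified trajectories per mode and the excluded count."""
    labels = [f.mode for f in fits if f.mode is not None]
    excluded = len(fits) - len(labels)
    n = len(labels)
    fracs = {m: (labels.count(m) / n if n else float("nan")) for m in
             ("confined", "brownian", "directed")}
    return fracs, excluded


def threshold_sweep(
    alphas: np.ndarray,
    confined_grid: np.ndarray | None = None,
    directed_grid: np.ndarray | None = None,
) -> dict:
    """Mode fractions at every (confined_max, directed_min) grid point.

    Default grid: confined_max 0.5–0.9, directed_min 1.1–1.5, step 0.1.
    Returns a dict with the per-grid-point table and the maximum absolute
    change of each fraction across the grid — the robustness statistic.
    """
    alphas = np.asarray(alphas, dtype=float)
    alphas = alphas[~np.isnan(alphas)]
    if len(alphas) < 100:
        raise ValueError(f"need >= 100 defined alphas for a sweep, got {len(alphas)}")
    if confined_grid is None:
        confined_grid = np.round(np.arange(0.5, 0.91, 0.1), 10)
    if directed_grid is None:
        directed_grid = np.round(np.arange(1.1, 1.51, 0.1), 10)
    rows = []
    for cmax in confined_grid:
        for dmin in directed_grid:
            if not (0.0 < cmax < dmin < 2.5):
                log.warning("skipping invalid grid point (%.3g, %.3g)", cmax, dmin)
                continue
            n = len(alphas)
            fc = float((alphas < cmax).sum()) / n
            fd = float((alphas > dmin).sum()) / n
            rows.append(
                {"confined_max": float(cmax), "directed_min": float(dmin),
                 "confined": fc, "brownian": 1.0 - fc - fd, "directed": fd}
            )
    if not rows:
        raise ValueError("no valid grid points")
    max_change = {
        m: max(r[m] for r in rows) - min(r[m] for r in rows)
        for m in ("confined", "brownian", "directed")
    }
    return {"table": rows, "max_change": max_change}
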