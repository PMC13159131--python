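"""Population-level statistics on per-trajectory motion fits.

Summaries use the median diffusion coefficient (robust to the strongly
right-skewed per-trajectory D distribution) with the interquartile range
as spread; group comparisons follow the field's convention of one-way
ANOVA with Tukey's honest-significant-difference post-hoc test;
perturbation effects are percent changes of the median D with seeded
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .msd import MotionFit, mode_fractions

log = logging.getLogger(__name__)

MIN_TRAJ_DEFAULT = 1000
N_BOOT_DEFAULT = 2000


@dataclass
class PopulationSummary:
    """Per-group summary: n, median D (µm²/s), mode fractions, D IQR."""

    group_id: str
    n_traj: int
    median_D: float
    mode_fractions: dict[str, float]
    D_iqr: float
    n_excluded: int = 0  # trajectories with undefined α (kept for D stats)


@dataclass
class GroupComparison:
    """One-way ANOVA F/p plus all pairwise Tukey HSD p-values."""

    statistic: float
    p_anova: float
    p_values: dict[tuple[str, str], float]
    method: str = "one-way ANOVA + Tukey HSD"


def _d_values(fits) -> np.ndarray:
    if len(fits) and isinstance(fits[0], MotionFit):
        return np.array([f.D for f in fits], dtype=float)
    return np.asarray(fits, dtype=float)


def summarize(
    fits: list[MotionFit],
    group_id: str,
    min_traj: int = MIN_TRAJ_DEFAULT,
    allow_small: bool = False,
) -> PopulationSummary:
    """Summarize one group of per-trajectory fits.

    Requires at least ``min_traj`` trajectories (the study's QC floor)
    unless ``allow_small`` overrides with a logged warning.  The median
    D pools all trajectories; mode fractions cover only those with a
    defined α.
    """
    n = len(fits)
    if n < min_traj:
        if not allow_small:
            raise ValueError(
                f"group {group_id!r}: {n} trajectories < min_traj {min_traj} "
                f"(pass allow_small=True to override)"
            )
        log.warning("group %s: only %d trajectories (< %d)", group_id, n, min_traj)
    if n == 0:
        raise ValueError(f"group {group_id!r}: no trajectories")
    D = _d_values(fits)
    fracs, excluded = mode_fractions(fits) if isinstance(fits[0], MotionFit) else (
        {m: float("nan") for m in ("confined", "brownian", "directed")}, 0)
    q75, q25 = np.percentile(D, [75, 25])
    return PopulationSummary(
        group_id=group_id,
        n_traj=n,
        median_D=float(np.median(D)),
        mode_fractions=fracs,
        D_iqr=float(q75 - q25),
        n_excluded=excluded,
    )


def compare_groups(groups: dict[str, "np.ndarray | list"]) -> GroupComparison:
    """One-way ANOVA across groups of per-trajectory D, with Tukey HSD
    pairwise p-values.  Needs ≥ 2 groups of n ≥ 3 each."""
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    arrays = {g: _d_values(v) for g, v in groups.items()}
    for g, a in arrays.items():
        if len(a) < 3:
            raise ValueError(f"group {g!r} has n={len(a)} < 3")
    names = list(arrays)
    F, p = stats.f_oneway(*arrays.values())
    values = np.concatenate([arrays[g] for g in names])
    labels = np.concatenate([[g] * len(arrays[g]) for g in names])
    tk = pairwise_tukeyhsd(values, labels)
    pvals = {
        (str(row[0]), str(row[1])): float(pv)
        for row, pv in zip(tk._results_table.data[1:], tk.pvalues)
    }
    return GroupComparison(statistic=float(F), p_anova=float(p), p_values=pvals)


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation between group-level values (e.g. median D vs a
    migration phenotype).  Returns (r, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need n >= 3, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors: r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def percent_change(
    fits_control,
    fits_treated,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    ci_level: float = 0.95,
    paired: bool = False,
) -> dict:
    """Percent change of the median D, treated vs control, with a seeded
    percentile-bootstrap CI over trajectory resampling.

    ``paired=True`` resamples trajectory indices jointly across the two
    groups — the correct inference when the treated group is the same
    trajectory ensemble under a perturbation (e.g. a simulated uniform
    D rescaling), where independent resampling would overstate the
    uncertainty.  Requires equal group sizes.

    Returns {"percent_change", "ci_low", "ci_high", "median_control",
    "median_treated", "n_boot", "seed", "paired"}.
    """
    Dc = _d_values(fits_control)
    Dt = _d_values(fits_treated)
    if len(Dc) == 0 or len(Dt) == 0:
        raise ValueError("both groups must be nonempty")
    if paired and len(Dc) != len(Dt):
        raise ValueError(
            f"paired bootstrap needs equal group sizes, got {len(Dc)} vs {len(Dt)}"
        )
    mc, mt = float(np.median(Dc)), float(np.median(Dt))
    if mc == 0:
        raise ValueError("control median D is 0: percent change undefined")
    point = 100.0 * (mt - mc) / mc
    rng = default_rng(SeedSequence(entropy=seed, spawn_key=(0xB007,)))
    idx_c = rng.integers(0, len(Dc), size=(n_boot, len(Dc)))
    idx_t = idx_c if paired else rng.integers(0, len(Dt), size=(n_boot, len(Dt)))
    bmc = np.median(Dc[idx_c], axis=1)
    bmt = np.median(Dt[idx_t], axis=1)
    boots = 100.0 * (bmt - bmc) / bmc
    a = 100.0 * (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(boots, [a, 100.0 - a])
    return {
        "percent_change": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "median_control": mc,
        "median_treated": mt,
        "n_boot": n_boot,
        "seed": seed,
        "paired": paired,
    }
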