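"""Time-averaged MSD, D/α estimation, and mode classification.

The TA-MSD implementation is checked exactly against a brute-force
all-pairs oracle, including trajectories with frame gaps.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smtpipe.msd import (
    AlphaThresholds,
    MSDCurve,
    classify_mode,
    compute_tamsd,
    estimate_D,
    estimate_alpha,
    fit_population,
    fit_trajectory,
    mode_fractions,
    threshold_sweep,
)
from smtpipe.simulate import ModeParams, Trajectory, simulate_trajectory


def brute_force_tamsd(traj: Trajectory, dt: float, max_lag: int):
    """Independent oracle: enumerate every ordered pair (i, j) and
    average squared displacements by true frame difference."""
    sums = {n: [] for n in range(1, max_lag + 1)}
    for i in range(len(traj)):
        for j in range(i + 1, len(traj)):
            n = int(traj.frames[j] - traj.frames[i])
            if n <= max_lag:
                sums[n].append(
                    (traj.x[j] - traj.x[i]) ** 2 + (traj.y[j] - traj.y[i]) ** 2
                )
        # ordered pairs with j < i add nothing new (squared displacement)
    values = [np.mean(sums[n]) if sums[n] else np.nan for n in sums]
    counts = [len(sums[n]) for n in sums]
    return np.array(values), np.array(counts)


@st.composite
def gapped_trajectories(draw):
    n = draw(st.integers(min_value=5, max_value=40))
    gaps = draw(st.lists(st.integers(min_value=1, max_value=3),
                         min_size=n - 1, max_size=n - 1))
    frames = np.concatenate([[0], np.cumsum(gaps)])
    coords = st.floats(min_value=-50, max_value=50, allow_nan=False,
                       allow_infinity=False, width=32)
    x = draw(st.lists(coords, min_size=n, max_size=n))
    y = draw(st.lists(coords, min_size=n, max_size=n))
    return Trajectory("h", frames, x, y)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(gapped_trajectories())
def test_tamsd_equals_brute_force_oracle(traj):
    span = int(traj.frames[-1])
    max_lag = max(span // 4, 1)
    curve = compute_tamsd(traj, 0.1, max_lag=max_lag)
    vals, counts = brute_force_tamsd(traj, 0.1, max_lag)
    assert np.array_equal(curve.n_pairs, counts)
    both = ~np.isnan(vals)
    assert np.array_equal(np.isnan(curve.values), ~both)
    assert np.allclose(curve.values[both], vals[both], rtol=1e-10, atol=1e-12)


def test_tamsd_of_immobile_trajectory_is_zero():
    t = Trajectory(0, np.arange(30), np.full(30, 1.5), np.full(30, -2.0))
    c = compute_tamsd(t, 0.1)
    assert np.allclose(c.values, 0.0)


def test_tamsd_pure_drift_closed_form():
    """Collinear points spaced d per frame: MSD(n·dt) = (n·d)²."""
    d = 0.1
    t = Trajectory(0, np.arange(20), d * np.arange(20), np.zeros(20))
    c = compute_tamsd(t, 0.1, max_lag=4)
    assert c.values[2] == pytest.approx((3 * d) ** 2)
    assert np.allclose(c.values, (np.arange(1, 5) * d) ** 2)


def test_tamsd_oscillating_five_point_example():
    t = Trajectory(0, np.arange(5), np.array([0.0, 1, 0, 1, 0]), np.zeros(5))
    c = compute_tamsd(t, 0.1, max_lag=2)
    assert c.values[0] == pytest.approx(1.0)
    assert c.values[1] == pytest.approx(0.0)
    assert list(c.n_pairs) == [4, 3]


def test_tamsd_pair_counts_decrease_and_too_short_rejected():
    t = Trajectory("tid7", np.arange(3), np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError, match="tid7"):
        compute_tamsd(t, 0.1, max_lag=5)


def _curve(lags, values):
    return MSDCurve("c", np.asarray(lags, float), np.asarray(values, float),
                    np.arange(len(lags), 0, -1))


def test_estimate_D_exact_line():
    tau = np.arange(1, 11) * 0.1
    D, b, clamped = estimate_D(_curve(tau, 4 * 0.1 * tau))
    assert D == pytest.approx(0.1) and b == pytest.approx(0.0, abs=1e-12)
    assert not clamped


def test_estimate_D_absorbs_noise_floor_in_intercept():
    tau = np.arange(1, 11) * 0.1
    D, b, _ = estimate_D(_curve(tau, 4 * 0.1 * tau + 4 * 0.03**2))
    assert D == pytest.approx(0.1)
    assert b == pytest.approx(0.0036)


def test_estimate_D_negative_slope_clamped():
    tau = np.arange(1, 5) * 0.1
    D, _, clamped = estimate_D(_curve(tau, -(4 * 0.1) * tau + 1.0))
    assert D == 0.0 and clamped


def test_median_D_recovery_on_brownian_ensemble():
    """Median fitted D over many Brownian trajectories is within 10% of
    the true value at the study's imaging settings."""
    rng = np.random.default_rng(5)
    Ds = []
    for _ in range(400):
        t = simulate_trajectory(ModeParams("brownian", 0.18), 100, 0.1, 0.03,
                                seed=int(rng.integers(2**31)))
        D, _, _ = estimate_D(compute_tamsd(t, 0.1))
        Ds.append(D)
    assert np.median(Ds) == pytest.approx(0.18, rel=0.10)


def test_alpha_power_laws():
    tau = np.arange(1, 11) * 0.1
    a1, r2 = estimate_alpha(_curve(tau, 0.3 * tau))
    a2, _ = estimate_alpha(_curve(tau, 0.3 * tau**2))
    assert a1 == pytest.approx(1.0) and r2 == pytest.approx(1.0)
    assert a2 == pytest.approx(2.0)


def test_alpha_undefined_with_too_few_usable_lags():
    tau = np.arange(1, 5) * 0.1
    a, r2 = estimate_alpha(_curve(tau, [0.1, -0.1, 0.0, -0.2]))
    assert np.isnan(a) and np.isnan(r2)


def test_confined_simulation_depresses_alpha():
    rng = np.random.default_rng(6)
    alphas = []
    for _ in range(100):
        t = simulate_trajectory(ModeParams("confined", 0.1, R=0.2), 100, 0.1,
                                0.0, seed=int(rng.integers(2**31)))
        alphas.append(estimate_alpha(compute_tamsd(t, 0.1))[0])
    assert np.median(alphas) < 0.7


def test_directed_limit_alpha_reaches_two():
    """With v²T ≫ 4D the log-log slope saturates at the ballistic value."""
    rng = np.random.default_rng(7)
    alphas = []
    for _ in range(50):
        t = simulate_trajectory(
            ModeParams("directed", 0.001, v=2.0), 100, 0.1, 0.0,
            seed=int(rng.integers(2**31)))
        alphas.append(estimate_alpha(compute_tamsd(t, 0.1))[0])
    assert np.median(alphas) == pytest.approx(2.0, abs=0.05)


def test_joint_unbiasedness_on_noiseless_brownian():
    """Noiseless free diffusion: median α ≈ 1, median D within 5%."""
    rng = np.random.default_rng(8)
    Ds, alphas = [], []
    for _ in range(2000):
        t = simulate_trajectory(ModeParams("brownian", 0.1), 100, 0.1, 0.0,
                                seed=int(rng.integers(2**31)))
        c = compute_tamsd(t, 0.1)
        Ds.append(estimate_D(c)[0])
        alphas.append(estimate_alpha(c)[0])
    assert 0.95 <= np.median(alphas) <= 1.05
    assert np.median(Ds) == pytest.approx(0.1, rel=0.05)


def test_classification_thresholds_and_tie_break():
    th = AlphaThresholds(0.7, 1.3)
    assert classify_mode(0.3, th) == "confined"
    assert classify_mode(1.0, th) == "brownian"
    assert classify_mode(0.7, th) == "brownian"  # boundary to the middle
    assert classify_mode(1.3, th) == "brownian"
    assert classify_mode(1.31, th) == "directed"
    with pytest.raises(ValueError):
        AlphaThresholds(1.4, 1.3)


def test_mode_fractions_account_for_excluded():
    t = Trajectory(0, np.arange(25), np.random.default_rng(0).normal(size=25),
                   np.zeros(25))
    fits, _ = fit_population([t] * 4, 0.1, min_len=20)
    fits[0].mode = None
    fracs, excluded = mode_fractions(fits)
    assert excluded == 1
    assert sum(fracs.values()) == pytest.approx(1.0)


def test_threshold_sweep_degenerate_and_uniform():
    res = threshold_sweep(np.ones(200))
    assert res["max_change"] == {"confined": 0.0, "brownian": 0.0, "directed": 0.0}
    for row in res["table"]:
        assert (row["confined"], row["brownian"], row["directed"]) == (0, 1, 0)
    # uniform alphas on [0, 2]: confined fraction = confined_max / 2
    alphas = np.linspace(0, 2, 20001)
    res = threshold_sweep(alphas)
    for row in res["table"]:
        assert row["confined"] == pytest.approx(row["confined_max"] / 2, abs=0.01)
        assert row["directed"] == pytest.approx(1 - row["directed_min"] / 2, abs=0.01)


def test_threshold_sweep_stable_on_separated_mixture():
    rng = np.random.default_rng(9)
    alphas = np.concatenate([
        rng.normal(0.25, 0.06, 400),
        rng.normal(1.0, 0.04, 300),
        rng.normal(1.8, 0.06, 300),
    ])
    res = threshold_sweep(alphas)
    assert max(res["max_change"].values()) < 0.05


def test_threshold_sweep_needs_enough_alphas():
    with pytest.raises(ValueError, match="100"):
        threshold_sweep(np.ones(50))


def test_fit_trajectory_min_len_enforced():
    t = Trajectory("short", np.arange(10), np.zeros(10), np.zeros(10))
    with pytest.raises(ValueError, match="short"):
        fit_trajectory(t, 0.1)
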