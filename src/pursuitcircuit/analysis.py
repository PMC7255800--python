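"""Measurements and fits applied to behavioral series and eye-velocity traces.

Covers the full analysis chain used on pursuit direction-learning data:
saccade removal from 1 kHz eye-velocity traces by a joint speed/acceleration
threshold, the 225-275 ms learned-response measurement window, the
saturating single-trial learning sigmoid fit, exponential retention fits on
error-clamp decays, linear regression of asymptotic learning on instruction
magnitude, AIC model comparison, learning-expression ratios, and the
speed-generalization function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .series import BehavioralSeries

__all__ = [
    "EyeTrace",
    "FitResult",
    "SACCADE_SPEED_THRESHOLD",
    "SACCADE_ACCEL_THRESHOLD",
    "LEARNED_RESPONSE_WINDOW_MS",
    "detect_saccades",
    "measure_learned_response",
    "sigmoid",
    "fit_sigmoid",
    "fit_linear",
    "compare_aic",
    "fit_retention",
    "asymptotic_learning",
    "expression_ratio",
    "generalization_function",
    "bin_trial_course",
]

#: Joint thresholds for saccade detection on 2-D eye speed and acceleration.
SACCADE_SPEED_THRESHOLD = 20.0  # deg/s
SACCADE_ACCEL_THRESHOLD = 1250.0  # deg/s^2
#: Padding applied around each detected saccadic interval.
SACCADE_PAD_MS = 10.0
#: Measurement window for the learned response, relative to pursuit onset.
LEARNED_RESPONSE_WINDOW_MS = (225.0, 275.0)


@dataclass
class EyeTrace:
    """A uniformly sampled eye-velocity trace.

    ``t`` is in ms relative to pursuit-target motion onset; ``v_pursuit``
    and ``v_learning`` are eye velocity components (deg/s) along the pursuit
    and learning directions; ``mask`` marks samples excluded as saccadic or
    missing.
    """

    t: np.ndarray
    v_pursuit: np.ndarray
    v_learning: np.ndarray
    mask: np.ndarray = None
    sample_rate: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v_pursuit = np.asarray(self.v_pursuit, dtype=float)
        self.v_learning = np.asarray(self.v_learning, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.t.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.t)
        if not (len(self.v_pursuit) == len(self.v_learning) == len(self.mask) == n):
            raise ValueError("all trace arrays must have equal length")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate


@dataclass
class FitResult:
    """Outcome of a model fit: estimates, residual statistics, AIC, CIs."""

    model: str
    params: dict
    rss: float
    n: int
    k: int
    aic: float
    r2: float
    converged: bool = True
    ci95: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci95.items():
            est = self.params[name]
            if not lo <= est <= hi:
                raise ValueError(f"CI for {name} does not bracket the estimate")


def _aic(rss: float, n: int, k: int) -> float:
    """Gaussian AIC with the additive constant dropped: n*ln(RSS/n) + 2k."""
    return n * np.log(rss / n) + 2 * k


# ---------------------------------------------------------------------------
# Trace-level measurements
# ---------------------------------------------------------------------------

def detect_saccades(trace: EyeTrace) -> np.ndarray:
    """Mask saccadic samples by a joint speed and acceleration threshold.

    A sample is saccadic when 2-D eye speed exceeds 20 deg/s AND 2-D eye
    acceleration exceeds 1250 deg/s^2 (thresholds on absolute eye motion).
    Each contiguous run of saccadic samples is extended by 10 ms on both
    sides.  Returns the updated mask (existing masked samples are kept).
    """
    speed = np.hypot(trace.v_pursuit, trace.v_learning)
    dt_s = 1.0 / trace.sample_rate
    acc = np.hypot(
        np.gradient(trace.v_pursuit, dt_s), np.gradient(trace.v_learning, dt_s)
    )
    hit = (speed > SACCADE_SPEED_THRESHOLD) & (acc > SACCADE_ACCEL_THRESHOLD)
    mask = trace.mask.copy()
    if not hit.any():
        return mask
    pad = int(round(SACCADE_PAD_MS / trace.dt_ms))
    idx = np.flatnonzero(hit)
    # contiguous runs of threshold-exceeding samples
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        lo = max(0, run[0] - pad)
        hi = min(len(mask), run[-1] + pad + 1)
        mask[lo:hi] = True
    return mask


def measure_learned_response(trace: EyeTrace) -> float:
    """Mean unmasked learning-direction velocity in the 225-275 ms window.

    Returns NaN when every sample in the window is masked, flagging the
    trial for exclusion (the same treatment as an aborted trial).
    """
    lo, hi = LEARNED_RESPONSE_WINDOW_MS
    if trace.t[0] > lo or trace.t[-1] < hi:
        raise ValueError("trace does not cover the measurement window")
    in_window = (trace.t >= lo) & (trace.t <= hi)
    good = in_window & ~trace.mask
    if not good.any():
        return float("nan")
    return float(trace.v_learning[good].mean())


# ---------------------------------------------------------------------------
# Curve fits
# ---------------------------------------------------------------------------

def sigmoid(error, a: float, tau: float):
    """Saturating single-trial learning curve: a/(1+exp(-tau*E)) - a/2."""
    error = np.asarray(error, dtype=float)
    return a / (1.0 + np.exp(-tau * error)) - a / 2.0


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _bootstrap_ci(fit_once, x, y, n_boot, seed, names):
    rng = np.random.default_rng(seed)
    n = len(x)
    draws = {name: [] for name in names}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = fit_once(x[idx], y[idx])
        except Exception:
            continue
        for name, val in zip(names, est):
            draws[name].append(val)
    ci = {}
    for name in names:
        vals = np.asarray(draws[name])
        if len(vals) >= 10:
            ci[name] = (float(np.percentile(vals, 2.5)),
                        float(np.percentile(vals, 97.5)))
    return ci


SIGMOID_BOUNDS = {"a": (1e-9, 5.0), "tau": (1e-9, 1.0)}
_SIGMOID_STARTS = [(0.5, 0.05), (1.0, 0.1), (1.5, 0.2), (2.5, 0.4), (4.0, 0.8)]


def fit_sigmoid(
    errors, responses, n_boot: int = 0, seed: int = 0, a_max: float | None = None
) -> FitResult:
    """Least-squares fit of the saturating single-trial learning sigmoid.

    Uses 5 fixed starting points within the bounds a in (0, 5],
    tau in (0, 1] and keeps the best local optimum.  The default amplitude
    bound suits single-trial learned responses (< 1 deg/s); pass ``a_max``
    to fit larger-amplitude saturating curves such as asymptotic learning.
    With ``n_boot > 0`` a case-resampling bootstrap supplies 95% intervals.
    """
    errors = np.asarray(errors, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if len(np.unique(errors)) < 3:
        raise ValueError("need >= 3 distinct error magnitudes")

    a_hi = SIGMOID_BOUNDS["a"][1] if a_max is None else a_max
    lb = [SIGMOID_BOUNDS["a"][0], SIGMOID_BOUNDS["tau"][0]]
    ub = [a_hi, SIGMOID_BOUNDS["tau"][1]]

    def solve(x, y, starts=_SIGMOID_STARTS):
        best = None
        for start in starts:
            sol = least_squares(
                lambda p: sigmoid(x, *p) - y, start, bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    sol = solve(errors, responses)
    a_hat, tau_hat = sol.x
    resid = sigmoid(errors, a_hat, tau_hat) - responses
    rss = float(np.sum(resid**2))
    n, k = len(errors), 2
    ci = {}
    if n_boot > 0:
        # bootstrap refits start from the point estimate
        ci = _bootstrap_ci(
            lambda x, y: solve(x, y, starts=[(a_hat, tau_hat)]).x,
            errors, responses, n_boot, seed, ("a", "tau"),
        )
    return FitResult(
        model="sigmoid",
        params={"a": float(a_hat), "tau": float(tau_hat)},
        rss=rss, n=n, k=k, aic=_aic(max(rss, 1e-300), n, k),
        r2=_r2(responses, resid), converged=bool(sol.success), ci95=ci,
    )


def fit_linear(x, y) -> FitResult:
    """Ordinary least squares y = slope*x + intercept via statsmodels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values identical")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.resid
    rss = float(np.sum(resid**2))
    n, k = len(x), 2
    return FitResult(
        model="linear",
        params={
            "intercept": float(model.params[0]),
            "slope": float(model.params[1]),
            "slope_t": float(model.tvalues[1]),
        },
        rss=rss, n=n, k=k, aic=_aic(max(rss, 1e-300), n, k),
        r2=_r2(y, np.asarray(resid)),
    )


def compare_aic(fits: list[FitResult]) -> list[tuple[FitResult, float]]:
    """Rank fits computed on identical data by AIC; lower is preferred.

    Returns (fit, delta_aic) pairs sorted best-first, with delta relative
    to the best model.
    """
    if not fits:
        raise ValueError("no fits to compare")
    n0 = fits[0].n
    if any(f.n != n0 for f in fits):
        raise ValueError("fits must be computed on identical data (mismatched n)")
    ranked = sorted(fits, key=lambda f: f.aic)
    best = ranked[0].aic
    return [(f, f.aic - best) for f in ranked]


def fit_retention(
    clamp_responses, last_learning_response: float,
    n_boot: int = 0, seed: int = 0,
) -> FitResult:
    """Exponential retention fit to an error-clamp decay.

    Clamp responses are normalized by the learned response on the final
    learning trial, then ``y_k = lambda**k`` (k = 1..n) is fitted by least
    squares.  ``lambda`` is the per-trial retention constant; 1 - lambda is
    the fraction forgotten per trial.
    """
    y = np.asarray(clamp_responses, dtype=float)
    if last_learning_response <= 0:
        raise ValueError("normalizer (last learning response) must be > 0")
    if len(y) < 3:
        raise ValueError("need >= 3 error-clamp trials")
    y = y / last_learning_response
    k = np.arange(1, len(y) + 1, dtype=float)

    def solve(kk, yy):
        sol = least_squares(
            lambda p: p[0] ** kk - yy, [0.9], bounds=([1e-9], [1.5]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        return sol.x

    lam = float(solve(k, y)[0])
    resid = lam**k - y
    rss = float(np.sum(resid**2))
    ci = {}
    if n_boot > 0:
        ci = _bootstrap_ci(lambda kk, yy: solve(kk, yy), k, y, n_boot, seed,
                           ("retention",))
    return FitResult(
        model="exponential_retention",
        params={"retention": lam},
        rss=rss, n=len(y), k=1, aic=_aic(max(rss, 1e-300), len(y), 1),
        r2=_r2(y, resid), ci95=ci,
    )


# ---------------------------------------------------------------------------
# Series-level measurements
# ---------------------------------------------------------------------------

def asymptotic_learning(series: BehavioralSeries, n_last: int = 25) -> float:
    """Mean learned response over the final ``n_last`` learning trials."""
    learning = series.of_type("learning")
    if len(learning) < n_last:
        raise ValueError(
            f"series has {len(learning)} learning trials, need >= {n_last}"
        )
    return float(learning["learned_response"].to_numpy()[-n_last:].mean())


def expression_ratio(
    series: BehavioralSeries, variant: str = "matched_probe_norm"
) -> pd.DataFrame:
    """Per-pair learning expression ratios from a dual-trial series.

    Pairs are consecutive (learning, probe) trials.  Two normalizations:

    * ``matched_probe_norm`` — each probe response is divided by the mean
      response over probe trials whose pursuit speed equals the pursuit
      speed of this pair's learning trial (the single-trial generalization
      convention: matched-speed pairs give a ratio of ~1).
    * ``preceding_learning_norm`` — each probe response is divided by the
      learned response expressed in its own preceding learning trial (the
      within-pair convention used across long learning sessions).

    Pairs with a zero (or, for the matched variant, undefined) denominator
    are excluded; the count of exclusions is in ``attrs['n_excluded']``.
    """
    if variant not in ("matched_probe_norm", "preceding_learning_norm"):
        raise ValueError(f"unknown variant {variant!r}")
    df = series.data.reset_index(drop=True)
    pairs = []
    for i in range(len(df) - 1):
        if df.loc[i, "trial_type"] == "learning" and df.loc[i + 1, "trial_type"] == "probe":
            pairs.append(
                {
                    "pair_index": len(pairs),
                    "learning_trial": i,
                    "learning_speed": df.loc[i, "pursuit_speed"],
                    "probe_speed": df.loc[i + 1, "pursuit_speed"],
                    "learning_response": df.loc[i, "learned_response"],
                    "probe_response": df.loc[i + 1, "learned_response"],
                }
            )
    if not pairs:
        raise ValueError("no learning->probe pairs in series")
    pairs = pd.DataFrame(pairs)

    if variant == "matched_probe_norm":
        mean_by_speed = pairs.groupby("probe_speed")["probe_response"].mean()
        denom = pairs["learning_speed"].map(mean_by_speed)
    else:
        denom = pairs["learning_response"]

    valid = denom.notna() & (denom != 0.0)
    out = pairs[valid].copy()
    out["ratio"] = out["probe_response"] / denom[valid]
    out["speed_ratio"] = out["probe_speed"] / out["learning_speed"]
    # a zero-learning series yields an empty frame with the exclusions counted
    out.attrs["n_excluded"] = int((~valid).sum())
    return out


def generalization_function(
    ratios, speed_ratios, bins=None
) -> pd.DataFrame:
    """Mean +/- SEM of expression ratios per probe/learning speed-ratio bin.

    ``bins`` may be an integer count (log-spaced edges spanning the data)
    or explicit edges.  Empty bins are reported with NaN mean, never
    interpolated.
    """
    ratios = np.asarray(ratios, dtype=float)
    speed_ratios = np.asarray(speed_ratios, dtype=float)
    if len(ratios) != len(speed_ratios):
        raise ValueError("ratios and speed_ratios must have equal length")
    if bins is None:
        bins = 7
    if np.isscalar(bins):
        lo, hi = speed_ratios.min(), speed_ratios.max()
        edges = np.geomspace(lo * 0.999, hi * 1.001, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    which = np.digitize(speed_ratios, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = ratios[which == b]
        center = float(np.sqrt(edges[b] * edges[b + 1]))
        if len(sel) == 0:
            rows.append({"bin_center": center, "mean": np.nan, "sem": np.nan, "n": 0})
        else:
            sem = float(sel.std(ddof=1) / np.sqrt(len(sel))) if len(sel) > 1 else 0.0
            rows.append(
                {"bin_center": center, "mean": float(sel.mean()), "sem": sem,
                 "n": int(len(sel))}
            )
    return pd.DataFrame(rows)


def bin_trial_course(values, bin_size: int = 5) -> np.ndarray:
    """Average a trial-course in consecutive fixed-size bins.

    The last bin may be partial; the weighted mean of the binned values
    equals the mean of the original series.
    """
    values = np.asarray(values, dtype=float)
    return np.array(
        [values[i : i + bin_size].mean() for i in range(0, len(values), bin_size)]
    )
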