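"""FRAP/FLIP photobleaching normalization and two-pool kinetic decomposition.

A photobleaching time series (ROI means for the monitored spot and a
background region) is background-corrected and normalized to the pre-bleach
intensity, then decomposed by nonlinear least squares into

    I(t) ≈ N1·exp(−λ1·t) + N2·exp(−λ2·t),    λ1 > λ2 ≥ 0,

where the fast component (1) is interpreted as the freely diffusing pool
and the slow component (2) as the transiently chromatin-bound pool.
Fractions are amplitude shares Ni/(N1+N2) and half-times t½ = ln2/λ.

Sign convention: exponents are decays, λ ≥ 0 (recorded on the result).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN2 = math.log(2.0)

#: default multi-start grid over (λ1, λ2), expressed as half-times in seconds
DEFAULT_START_THALF_FAST = (1.0, 3.0, 10.0)
DEFAULT_START_THALF_SLOW = (30.0, 60.0, 120.0)

#: two rate estimates closer than this (relative) collapse to one component
RATE_COLLAPSE_RTOL = 0.05

#: minimum λ_fast/λ_slow for two components to count as distinct pools.
#: Exponentials with closer rates are not resolvable from sampled decay
#: data: the amplitude split between them is noise-driven (label switching),
#: so the fit is constrained to the identifiable region.
MIN_RATE_RATIO = 4.0

#: significance level of the F-test that must support the second component;
#: otherwise the fit collapses to a mono-exponential
SECOND_COMPONENT_ALPHA = 0.05

#: amplitude splits tried per rate start; the asymmetric splits reach the
#: basins where one pool dominates
START_AMPLITUDES = ((0.5, 0.5), (0.9, 0.1), (0.1, 0.9))

_FTOL = 1e-10
_MAX_NFEV = 500


class NormalizationError(ValueError):
    """Raised when the pre-bleach reference intensity is unusable."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BleachSeries:
    """Raw photobleaching time course (uniform grid, default 2 s).

    ``times`` are seconds with t = 0 at the last pre-bleach frame;
    ``spot`` and ``background`` are raw ROI mean intensities.
    """

    times: np.ndarray
    spot: np.ndarray
    background: np.ndarray
    n_prebleach: int = 10
    mode: str = "FLIP"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spot = np.asarray(self.spot, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not (len(self.times) == len(self.spot) == len(self.background)):
            raise ValueError("times, spot and background must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")
        if self.mode not in ("FLIP", "FRAP"):
            raise ValueError(f"mode must be FLIP or FRAP, got {self.mode!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.times)),
            "time_s": self.times,
            "spot_mean": self.spot,
            "background_mean": self.background,
        })


@dataclass
class NormalizedCurve:
    """Background-corrected curve normalized to 1 at the pre-bleach reference."""

    times: np.ndarray
    values: np.ndarray
    mode: str = "FLIP"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")


@dataclass
class BiExpFit:
    """Fitted two-component decay, sorted fast-first (λ1 > λ2).

    ``model`` records whether the two rates were distinguishable
    ("biexponential") or collapsed to one component ("monoexponential",
    reported as a pure fast pool by convention). The fitted exponents are
    decays, exp(−λt) with λ ≥ 0.
    """

    N1: float
    N2: float
    lambda1: float      # 1/s, fast
    lambda2: float      # 1/s, slow
    rss: float
    converged: bool
    n_iter: int
    model: str = "biexponential"
    sign_convention: str = "exp(-lambda*t), lambda >= 0"

    @property
    def f_fast(self) -> float:
        tot = self.N1 + self.N2
        return self.N1 / tot if tot > 0 else float("nan")

    @property
    def f_slow(self) -> float:
        tot = self.N1 + self.N2
        return self.N2 / tot if tot > 0 else float("nan")

    @property
    def thalf_fast(self) -> float:
        return LN2 / self.lambda1 if self.lambda1 > 0 else float("inf")

    @property
    def thalf_slow(self) -> float:
        return LN2 / self.lambda2 if self.lambda2 > 0 else float("inf")

    def as_row(self) -> dict:
        return {
            "N1": self.N1, "N2": self.N2,
            "lambda1": self.lambda1, "lambda2": self.lambda2,
            "f_fast": self.f_fast, "f_slow": self.f_slow,
            "thalf_fast_s": self.thalf_fast, "thalf_slow_s": self.thalf_slow,
            "rss": self.rss, "converged": self.converged,
            "n_iter": self.n_iter, "model": self.model,
        }


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(series: BleachSeries) -> NormalizedCurve:
    """Background-correct and normalize a bleach series to 1 at t = 0.

    value(t) = (spot(t) − background(t)) / (spot(0) − background(0)) for both
    FLIP and FRAP. The t = 0 reference is the mean over all pre-bleach frames
    (robust to frame noise); the returned curve carries a single t = 0 sample
    whose value is exactly 1, followed by the post-bleach samples.
    """
    n0 = series.n_prebleach
    if n0 > len(series.times):
        raise NormalizationError("n_prebleach exceeds series length")
    ref = float(series.spot[:n0].mean() - series.background[:n0].mean())
    if ref <= 0:
        raise NormalizationError(
            f"pre-bleach reference (spot − background) = {ref:.4g} must be positive"
        )
    t0 = series.times[n0 - 1]
    post = slice(n0, None)
    times = np.concatenate([[0.0], series.times[post] - t0])
    values = np.concatenate(
        [[1.0], (series.spot[post] - series.background[post]) / ref]
    )
    return NormalizedCurve(times=times, values=values, mode=series.mode)


def rescale_unit_interval(curve: NormalizedCurve) -> NormalizedCurve:
    """Affine rescale of a curve so its minimum is 0 and maximum 1.

    Used for FRAP display and plateau-relative fitting.
    """
    vmin, vmax = curve.values.min(), curve.values.max()
    if vmax == vmin:
        raise ValueError("constant curve cannot be rescaled to [0, 1]")
    return NormalizedCurve(
        times=curve.times.copy(),
        values=(curve.values - vmin) / (vmax - vmin),
        mode=curve.mode,
    )


# ---------------------------------------------------------------------------
# bi-exponential fitting
# ---------------------------------------------------------------------------

def _biexp(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    n1, l1, n2, l2 = p
    return n1 * np.exp(-l1 * t) + n2 * np.exp(-l2 * t)


def _fit_mono(t: np.ndarray, y: np.ndarray, x0: np.ndarray):
    return least_squares(
        lambda q: q[0] * np.exp(-q[1] * t) - y, x0,
        bounds=(0.0, np.inf), ftol=_FTOL, xtol=1e-12, max_nfev=_MAX_NFEV,
    )


def fit_biexponential(
    curve: NormalizedCurve,
    t_start: float = 0.0,
    start_thalf_fast: Sequence[float] = DEFAULT_START_THALF_FAST,
    start_thalf_slow: Sequence[float] = DEFAULT_START_THALF_SLOW,
    min_rate_ratio: float = MIN_RATE_RATIO,
) -> BiExpFit:
    """Fit N1·e^(−λ1 t) + N2·e^(−λ2 t) to a normalized decay curve.

    Bounds N_i ≥ 0, λ_i ≥ 0. Bi-exponential least squares is sensitive to
    initialization, so a grid of starts (Cartesian product of fast and slow
    half-time guesses × three amplitude splits) plus two "peeling" starts
    seeded from the mono-exponential fit is tried and the best residual sum
    of squares wins; rss ties break toward the smaller fast rate, making
    the selection independent of start order. FRAP curves are converted to their
    un-recovered fraction (1 − unit-rescaled recovery) before fitting, so
    both modes decay.

    Three identifiability safeguards keep the pool decomposition meaningful:

    * the fit is parameterized as λ1 = ratio·λ2 with ratio ≥
      ``min_rate_ratio`` (default 4), because exponentials with closer rates
      cannot be resolved from noisy sampled decays — without the constraint
      the amplitude split between two near-equal rates is noise-driven and
      the fast/slow labels switch arbitrarily on near-mono-exponential
      curves;
    * when several multi-start optima fit the data equally well (rss within
      the noise-equivalence band of the best), the one assigning the least
      amplitude to its minor component is selected — a parsimony rule that
      resolves the label switching between a dominant-fast and a
      dominant-slow decomposition of the same near-mono curve;
    * an F-test compares the bi-exponential against a mono-exponential fit;
      when the second component is not supported (p ≥ 0.05) the fit
      collapses to the mono-exponential, reported as a pure fast pool.
      The same collapse applies if the two fitted rates end up within 5%
      relative (possible only when ``min_rate_ratio`` is relaxed).
    """
    if curve.mode == "FRAP":
        # fit the un-recovered fraction, which decays bi-exponentially; it
        # is 1 immediately after the bleach, so the pre-bleach reference
        # sample is replaced by that anchor
        post = curve.times > 0
        decay = NormalizedCurve(
            np.concatenate([[0.0], curve.times[post]]),
            np.concatenate([[1.0], 1.0 - curve.values[post]]),
            mode="FRAP",
        )
    else:
        decay = curve
    sel = decay.times >= t_start
    t = decay.times[sel] - t_start
    y = decay.values[sel]
    if len(t) < 4:
        raise ValueError("need at least as many points as parameters (4)")
    if len(t) < 8:
        raise ValueError("need at least 8 post-bleach points for a stable fit")

    # mono-exponential fit first: the F-test competitor, and the seed for
    # two data-adaptive starts (dominant component at the mono rate plus a
    # small slower or faster partner — "peeling" starts that reach the
    # narrow dominant-pool basins)
    mono = _fit_mono(t, y, np.array([max(y[0], 0.1), 0.05]))
    total_nfev = mono.nfev
    rss_mono = float(mono.cost * 2.0)
    n_m, lam_m = float(mono.x[0]), max(float(mono.x[1]), 1e-6)

    # parameters q = (N1, N2, lambda2, ratio); lambda1 = ratio * lambda2
    def resid(q):
        n1, n2, l2, ratio = q
        return _biexp(t, np.array([n1, ratio * l2, n2, l2])) - y

    grid_starts = [
        np.array([a1, a2, LN2 / th_s, max(min_rate_ratio, th_s / th_f)])
        for (a1, a2), (th_f, th_s) in itertools.product(
            START_AMPLITUDES,
            itertools.product(start_thalf_fast, start_thalf_slow),
        )
    ]
    ratio0 = max(min_rate_ratio, 2.0 * min_rate_ratio)
    adaptive_starts = [
        np.array([0.9 * n_m, 0.1 * n_m, lam_m / ratio0, ratio0]),
        np.array([0.1 * n_m, 0.9 * n_m, lam_m, ratio0]),
    ]

    candidates: list[tuple[float, float, float, np.ndarray]] = []
    for x0 in grid_starts + adaptive_starts:
        res = least_squares(
            resid, x0,
            bounds=([0.0, 0.0, 0.0, min_rate_ratio], np.inf),
            ftol=_FTOL, xtol=1e-12, max_nfev=_MAX_NFEV,
        )
        total_nfev += res.nfev
        # a start that exhausts its evaluation budget (status 0) has often
        # wandered a flat λ2 valley at negligible rss change; its best point
        # is still a valid candidate
        rss = float(res.cost * 2.0)
        if res.status >= 0 and np.isfinite(rss):
            tot = res.x[0] + res.x[1]
            minor = min(res.x[0], res.x[1]) / tot if tot > 0 else 0.0
            candidates.append((rss, minor, float(res.x[3] * res.x[2]), res.x))

    if not candidates:
        return BiExpFit(np.nan, np.nan, np.nan, np.nan, rss=np.inf,
                        converged=False, n_iter=total_nfev)
    # parsimony selection: among fits the data cannot distinguish (rss
    # within the noise-equivalence band of the best), take the one with the
    # smallest minor-component share; residual ties break on smaller λ1
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    rss_best = candidates[0][0]
    dof_band = max(len(t) - 4, 1)
    band = rss_best * (1.0 + 4.0 / dof_band)
    rss, _, _, q = min(
        (c for c in candidates if c[0] <= band),
        key=lambda c: (c[1], c[0], c[2]),
    )
    n1, n2, l2 = float(q[0]), float(q[1]), float(q[2])
    l1 = float(q[3] * q[2])

    dof = len(t) - 4
    collapse = False
    if l1 > 0 and (l1 - l2) / l1 < RATE_COLLAPSE_RTOL:
        collapse = True
    elif rss_mono <= rss + 1e-10 * max(1.0, float(np.dot(y, y))):
        # both models fit to numerical precision: no second component
        collapse = True
    elif dof > 0 and rss_mono >= rss:
        f_stat = ((rss_mono - rss) / 2.0) / (rss / dof)
        from scipy.stats import f as f_dist

        collapse = f_dist.sf(f_stat, 2, dof) >= SECOND_COMPONENT_ALPHA
    if collapse:
        lam = float(mono.x[1])
        if lam * float(t[-1]) < 1e-3:
            lam = 0.0  # no detectable decay over the record: half-time undefined
        return BiExpFit(
            N1=float(mono.x[0]), N2=0.0, lambda1=lam, lambda2=0.0,
            rss=rss_mono, converged=bool(mono.success),
            n_iter=total_nfev, model="monoexponential",
        )
    return BiExpFit(N1=n1, N2=n2, lambda1=l1, lambda2=l2, rss=rss,
                    converged=True, n_iter=total_nfev)


def pool_summary(fit: BiExpFit) -> dict:
    """Report the fit as free/bound pools: percentages and half-times.

    Fast component → freely diffusing pool; slow component → chromatin-bound
    pool. Percentages always sum to 100.
    """
    if not fit.converged:
        return {"converged": False}
    return {
        "converged": True,
        "free_percent": 100.0 * fit.f_fast,
        "free_thalf_s": fit.thalf_fast,
        "bound_percent": 100.0 * fit.f_slow,
        "bound_thalf_s": fit.thalf_slow,
    }


def fit_cohort(
    curves: Iterable[NormalizedCurve],
    average_before_fit: bool = False,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Fit a set of replicate curves and aggregate pool parameters.

    Default is fit-then-average: each curve is fitted and the cohort mean/sd
    of fractions and half-times is taken over converged fits (unconverged
    fits are excluded and counted). With ``average_before_fit`` the curves
    (which must share a time grid) are averaged first and a single fit is
    reported.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one curve")

    if average_before_fit:
        times = curves[0].times
        for c in curves[1:]:
            if not np.allclose(c.times, times):
                raise ValueError("average_before_fit requires a shared time grid")
        mean_curve = NormalizedCurve(
            times, np.mean([c.values for c in curves], axis=0), mode=curves[0].mode
        )
        fits = [fit_biexponential(mean_curve, **fit_kwargs)]
    else:
        fits = [fit_biexponential(c, **fit_kwargs) for c in curves]

    table = pd.DataFrame([f.as_row() for f in fits])
    ok = table[table["converged"]]
    n_failed = len(table) - len(ok)
    if len(ok) == 0:
        raise RuntimeError(f"all {len(table)} fits failed to converge")
    summary = {"n": int(len(ok)), "n_unconverged": int(n_failed)}
    for col in ("f_fast", "f_slow", "thalf_fast_s", "thalf_slow_s"):
        vals = ok[col].to_numpy()
        finite = vals[np.isfinite(vals)]
        summary[f"{col}_mean"] = float(finite.mean()) if finite.size else float("nan")
        summary[f"{col}_sd"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
    return table, summary
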