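"""Curve fitting: one-phase exponential decay, OLS lines, extra-SS F tests.

The one-phase decay model is

    Y(X) = (Y0 - Plateau) * exp(-K * X) + Plateau ,

the form used to summarize directionality-ratio curves (plateau, half-life
= ln2/K) and velocity-autocorrelation curves (persistence time = 1/K).
The linear model Y = K*X + Y0 serves the log–log MSD slope and every
concentration–response fit, and nested linear models are compared with the
extra sum-of-squares F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

_LN2 = float(np.log(2.0))


@dataclass
class DecayFitResult:
    """One-phase decay parameters and derived time scales.

    ``half_life`` and ``persistence_time`` are exact functions of ``k``
    (ln2/k and 1/k) rather than independently fitted quantities.
    """

    y0: float
    plateau: float
    k: float
    rss: float
    converged: bool
    degenerate: bool = False
    message: str = ""

    @property
    def half_life(self) -> float:
        return _LN2 / self.k if self.k > 0 else float("nan")

    @property
    def persistence_time(self) -> float:
        return 1.0 / self.k if self.k > 0 else float("nan")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return one_phase_decay(np.asarray(x, dtype=float),
                               self.y0, self.plateau, self.k)


@dataclass
class LinearFitResult:
    """OLS line with an F test of slope vs the flat (intercept-only) model."""

    slope: float
    intercept: float
    rss: float
    df_resid: int
    f_stat: float
    p_value: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def one_phase_decay(x: np.ndarray, y0: float, plateau: float,
                    k: float) -> np.ndarray:
    return (y0 - plateau) * np.exp(-k * x) + plateau


def _initial_guess(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Y0 from the first point, plateau from the last, K from the lag at
    # which the curve first crosses the midpoint -- robust for monotone decays.
    y0, plateau = float(y[0]), float(y[-1])
    mid = 0.5 * (y0 + plateau)
    below = np.nonzero(y <= mid if y0 >= plateau else y >= mid)[0]
    x_mid = x[below[0]] if len(below) and x[below[0]] > 0 else (
        x[1] if len(x) > 1 and x[1] > 0 else 1.0)
    return y0, plateau, _LN2 / float(x_mid)


def fit_one_phase_decay(lags: np.ndarray, values: np.ndarray,
                        y0_fixed: float | None = None,
                        max_iter: int = 10_000) -> DecayFitResult:
    """Least-squares fit of the one-phase decay model.

    With ``y0_fixed`` (typically 1, since directionality-ratio and VAC
    curves start at exactly 1) only (Plateau, K) are estimated.  A first
    unconstrained fit that lands on K <= 0 is refit with K bounded positive
    and flagged with a warning; an all-but-flat input is reported as
    degenerate rather than fitted.
    """
    x = np.asarray(lags, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lags and values must be 1-D arrays of equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 points for a one-phase decay fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to decay fit")

    if np.ptp(y) == 0.0:
        c = float(y[0])
        return DecayFitResult(y0=c, plateau=c, k=float("nan"), rss=0.0,
                              converged=False, degenerate=True,
                              message="constant series: decay rate undefined")

    g_y0, g_pl, g_k = _initial_guess(x, y)
    if y0_fixed is None:
        model = one_phase_decay
        p0 = [g_y0, g_pl, g_k]
        lower, upper = [-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]
    else:
        def model(xv, plateau, k):
            return one_phase_decay(xv, y0_fixed, plateau, k)
        p0 = [g_pl, g_k]
        lower, upper = [-np.inf, 1e-12], [np.inf, np.inf]

    def _solve(bounded: bool):
        return optimize.curve_fit(
            model, x, y, p0=p0, maxfev=max_iter, full_output=True,
            ftol=1e-8, xtol=1e-8,
            **({"bounds": (lower, upper), "method": "trf"} if bounded else {}))

    try:
        popt, _, info, msg, ier = _solve(bounded=False)
        converged = ier in (1, 2, 3, 4)
    except RuntimeError as exc:
        popt, converged, msg = np.asarray(p0, dtype=float), False, str(exc)

    k_fit = popt[-1]
    if k_fit <= 0:
        warnings.warn("fit_one_phase_decay: negative decay rate from the "
                      "unconstrained fit; refitting with K bounded positive",
                      stacklevel=2)
        try:
            popt, _, info, msg, ier = _solve(bounded=True)
            converged = True
        except RuntimeError as exc:
            converged, msg = False, str(exc)

    if y0_fixed is None:
        y0_hat, plateau_hat, k_hat = (float(v) for v in popt)
    else:
        y0_hat = float(y0_fixed)
        plateau_hat, k_hat = (float(v) for v in popt)
    rss = float(np.sum((y - one_phase_decay(x, y0_hat, plateau_hat, k_hat)) ** 2))
    return DecayFitResult(y0=y0_hat, plateau=plateau_hat, k=k_hat, rss=rss,
                          converged=bool(converged), message=str(msg))


def fit_linear(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    """Ordinary least-squares line Y = K*X + Y0 with a slope-vs-zero F test.

    The F statistic compares the fitted line against the intercept-only
    model by extra sum of squares (equivalently the square of the slope's
    t statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need >= 3 points for a linear fit")
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant: slope undefined")
    design = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    df_full = len(x) - 2
    f, p = extra_ss_f_test(rss_flat, len(x) - 1, rss, df_full)
    return LinearFitResult(slope=float(coef[0]), intercept=float(coef[1]),
                           rss=rss, df_resid=df_full, f_stat=f, p_value=p)


def extra_ss_f_test(restricted_rss: float, restricted_df: int,
                    full_rss: float, full_df: int) -> tuple[float, float]:
    """Extra sum-of-squares F test between nested least-squares models.

    F = [(RSS_r - RSS_f)/(df_r - df_f)] / [RSS_f/df_f], with the p value
    from the F(df_r - df_f, df_f) distribution.  A tiny negative numerator
    from floating-point noise is clamped to zero.
    """
    if full_df <= 0 or restricted_df <= full_df:
        raise ValueError("models not nested: need restricted_df > full_df > 0")
    num = (restricted_rss - full_rss) / (restricted_df - full_df)
    if num < 0:
        if restricted_rss < full_rss * (1 - 1e-9) - 1e-12:
            raise ValueError("full model fits worse than restricted model: "
                             "models are not nested")
        num = 0.0
    if full_rss == 0.0:
        return (float("inf"), 0.0) if num > 0 else (0.0, 1.0)
    f = num / (full_rss / full_df)
    p = float(stats.f.sf(f, restricted_df - full_df, full_df))
    return float(f), p
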