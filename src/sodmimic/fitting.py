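"""Fitting stopped-flow traces: superoxide decay, activity series, half-lives.

The measurement chain this module implements:

1. replicate decay traces at one catalyst concentration are averaged
   (after discarding the first 5 ms mixing artifact and an optional
   blank subtraction) — :func:`preprocess`;
2. an uncatalyzed (b = 0) run is fitted with the mixed-order law to pin
   down the self-disproportionation constant k2 and the background rate
   k1 — :func:`fit_background`;
3. each catalyzed trace is fitted with k2 held fixed, yielding k_obs
   with a standard error — :func:`fit_superoxide_trace`;
4. k_obs against catalyst concentration b is a straight line whose
   slope is the catalytic rate constant k_cat — :func:`fit_activity_series`;
5. independently, the decay of the Ni(II)-peptide chromophore itself
   (followed at 258-262 / 460 nm) is fitted first-order to give the
   peptide half-life — :func:`fit_degradation`.

Nonlinear fits use lmfit trust-region least squares with non-negativity
bounds and seeded random restarts on non-convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kinetics import (
    FirstOrderDecayParams,
    SuperoxideKineticParams,
    absorbance_to_concentration,
    first_order_decay,
    half_life,
    superoxide_decay_closed,
)

__all__ = [
    "DecayTrace",
    "TraceFitResult",
    "BackgroundFit",
    "ActivityResult",
    "HalfLifeResult",
    "FitError",
    "default_window",
    "preprocess",
    "fit_background",
    "fit_superoxide_trace",
    "fit_activity_series",
    "fit_degradation",
    "summarize_half_lives",
]

DISCARD_INITIAL_S = 0.005  # mixing disturbance: first 5 ms always dropped
HIGH_CONC_THRESHOLD_M = 30e-6
MIN_POINTS = 20


class FitError(RuntimeError):
    """A fit failed to converge or the input is degenerate for fitting."""


@dataclass
class DecayTrace:
    """A stopped-flow absorbance trace with assay metadata.

    time is strictly increasing, in seconds; absorbance in AU.
    ``b`` is the catalyst (peptide) concentration in M, 0 for an
    uncatalyzed run.  ``meta`` may carry generator truth parameters.
    """

    time: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 250.0
    b: float = 0.0
    epsilon: float = 2000.0  # M^-1 cm^-1 (superoxide at 250 nm)
    path: float = 1.0  # cm; never stated by instruments, must be configured
    replicate: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape or self.time.ndim != 1:
            raise ValueError("time and absorbance must be matching 1-d arrays")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class TraceFitResult:
    """Mixed-order fit of one superoxide decay trace (concentration units)."""

    a0: float
    k2: float
    k_obs: float
    C: float
    stderr: dict[str, float | None]
    rss: float
    window: tuple[float, float]
    n_points: int
    converged: bool
    k_obs_at_bound: bool = False


@dataclass
class BackgroundFit:
    """Uncatalyzed-run fit: k2 (self-disproportionation) and k1 (= k_obs at b=0)."""

    k2: float
    k1: float
    k2_stderr: float | None
    k1_stderr: float | None
    trace_fit: TraceFitResult


@dataclass
class ActivityResult:
    """Linear decomposition k_obs = k1 + b*k_cat over a concentration series."""

    table: pd.DataFrame  # columns: b, k_obs, stderr
    k1: float
    k1_stderr: float
    k_cat: float
    k_cat_stderr: float
    r_squared: float


@dataclass
class HalfLifeResult:
    """First-order degradation fit of the Ni(II)-peptide chromophore."""

    wavelength: float
    k: float
    k_stderr: float | None
    t_half: float
    t_half_stderr: float | None
    A0: float
    A_inf: float
    rss: float
    converged: bool
    flags: list[str] = field(default_factory=list)


def default_window(b: float) -> tuple[float, float]:
    """Fit window for a catalyzed trace at concentration ``b``.

    The superoxide decay is fitted over 5-500 ms; above 30 µM catalyst
    the decomposition of the Ni(II)-peptide already distorts the first
    500 ms, so the window is shortened to end at 350 ms.
    """
    if b > HIGH_CONC_THRESHOLD_M:
        return (DISCARD_INITIAL_S, 0.35)
    return (DISCARD_INITIAL_S, 0.5)


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------


def preprocess(
    traces: list[DecayTrace],
    blank: DecayTrace | None = None,
    discard_initial: float = DISCARD_INITIAL_S,
    window: tuple[float, float] | None = None,
    min_points: int = MIN_POINTS,
) -> DecayTrace:
    """Average replicates, subtract a blank, and crop to the fit window.

    All traces must share wavelength and concentration.  Replicates are
    averaged pointwise on the first trace's grid (others interpolated if
    their grids differ); the blank, if given, is interpolated onto the
    same grid and subtracted.  Samples before ``discard_initial`` and
    outside ``window`` are dropped.
    """
    if not traces:
        raise ValueError("no traces given")
    ref = traces[0]
    for tr in traces[1:]:
        if tr.wavelength != ref.wavelength or tr.b != ref.b:
            raise ValueError("traces mix wavelengths or concentrations")

    lo = max(tr.time[0] for tr in traces)
    hi = min(tr.time[-1] for tr in traces)
    grid = ref.time[(ref.time >= lo) & (ref.time <= hi)]
    stack = np.vstack(
        [
            tr.absorbance
            if np.array_equal(tr.time, grid)
            else np.interp(grid, tr.time, tr.absorbance)
            for tr in traces
        ]
    )
    mean_abs = stack.mean(axis=0)
    if blank is not None:
        mean_abs = mean_abs - np.interp(grid, blank.time, blank.absorbance)

    keep = grid >= discard_initial
    if window is not None:
        keep &= (grid >= window[0]) & (grid <= window[1])
    grid, mean_abs = grid[keep], mean_abs[keep]
    if len(grid) < min_points:
        raise ValueError(
            f"only {len(grid)} points remain after windowing (minimum {min_points})"
        )
    return DecayTrace(
        time=grid,
        absorbance=mean_abs,
        wavelength=ref.wavelength,
        b=ref.b,
        epsilon=ref.epsilon,
        path=ref.path,
        replicate=f"avg({len(traces)})",
        meta=dict(ref.meta),
    )


# --------------------------------------------------------------------------
# Superoxide decay fits
# --------------------------------------------------------------------------


def _superoxide_model(t, a0, k2, k_obs, C):
    p = SuperoxideKineticParams(a0=max(a0, 1e-300), k2=k2, k_obs=k_obs, C=C)
    return superoxide_decay_closed(t, p)


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(a0, k_obs, C) starting values from the data itself.

    C from the final 5% of points, a0 from the first point, k_obs from
    the log-linear slope of the first third of the window.
    """
    n_tail = max(3, len(y) // 20)
    C0 = float(np.mean(y[-n_tail:]))
    a0 = max(float(y[0] - C0), 1e-12)
    third = max(4, len(y) // 3)
    resid = y[:third] - C0
    ok = resid > a0 * 1e-3
    if ok.sum() >= 3:
        slope = np.polyfit(t[:third][ok], np.log(resid[ok]), 1)[0]
        k0 = max(-float(slope), 1e-3)
    else:
        k0 = 10.0
    return a0, k0, C0


def fit_superoxide_trace(
    trace: DecayTrace,
    k2: float | None = None,
    fix_k2: bool = True,
    window: tuple[float, float] | None = None,
    c_bound: float = 0.1,
    max_nfev: int = 500,
    restarts: int = 3,
    seed: int = 0,
) -> TraceFitResult:
    """Bounded least-squares fit of the mixed-order decay law to one trace.

    The trace's absorbance is converted to concentration via its
    extinction coefficient and path length, then the closed-form decay
    law is fitted.  Free parameters default to (a0, k_obs, C) with k2
    held fixed at the background-run value; pass ``fix_k2=False`` to
    co-fit k2.  Standard errors come from the covariance of the fit.
    Non-convergence triggers up to ``restarts`` seeded restarts from
    perturbed initial guesses, then raises :class:`FitError`.
    """
    t = trace.time
    y = absorbance_to_concentration(trace.absorbance, trace.epsilon, trace.path)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, y = t[keep], y[keep]
    if len(t) < MIN_POINTS:
        raise FitError(f"only {len(t)} points in the fit window")
    if np.ptp(y) < 1e-12:
        raise FitError("trace shows no decay (flat signal); nothing to fit")
    if k2 is None and fix_k2:
        raise FitError("k2 must be supplied (from a background run) when fix_k2=True")

    a0_0, k0, C0 = _initial_guesses(t, y)
    model = lmfit.Model(_superoxide_model, independent_vars=["t"])
    params = model.make_params()
    params["a0"].set(value=a0_0, min=0.0)
    params["k_obs"].set(value=k0, min=0.0)
    params["C"].set(value=float(np.clip(C0, -c_bound, c_bound)), min=-c_bound, max=c_bound)
    params["k2"].set(value=k2 if k2 is not None else 2e4, min=0.0, vary=not fix_k2)

    rng = np.random.default_rng(seed)
    fit = None
    for attempt in range(restarts + 1):
        try:
            fit = model.fit(y, params=params, t=t, max_nfev=max_nfev)
        except Exception:
            fit = None
        if fit is not None and fit.success:
            break
        # perturb initial guesses and retry
        params["a0"].value = a0_0 * float(rng.uniform(0.3, 3.0))
        params["k_obs"].value = k0 * float(rng.uniform(0.2, 5.0))
        params["C"].value = float(np.clip(C0 + rng.normal(0, abs(a0_0) * 0.1), -c_bound, c_bound))
    if fit is None or not fit.success:
        raise FitError("superoxide trace fit did not converge after restarts")

    pv = fit.params
    k_obs_hat = pv["k_obs"].value
    at_bound = bool(k_obs_hat <= pv["k_obs"].min + 1e-12)
    return TraceFitResult(
        a0=pv["a0"].value,
        k2=pv["k2"].value,
        k_obs=k_obs_hat,
        C=pv["C"].value,
        stderr={name: pv[name].stderr for name in ("a0", "k2", "k_obs", "C")},
        rss=float(np.sum(fit.residual**2)),
        window=(float(t[0]), float(t[-1])),
        n_points=len(t),
        converged=bool(fit.success),
        k_obs_at_bound=at_bound,
    )


def fit_background(trace: DecayTrace, **kw) -> BackgroundFit:
    """Fit an uncatalyzed (b = 0) trace with k2 free.

    Returns the self-disproportionation constant k2 and the residual
    first-order background rate k1 (the k_obs of the b = 0 run).
    """
    if trace.b != 0:
        raise ValueError("background fit requires an uncatalyzed trace (b = 0)")
    res = fit_superoxide_trace(trace, k2=None, fix_k2=False, **kw)
    return BackgroundFit(
        k2=res.k2,
        k1=res.k_obs,
        k2_stderr=res.stderr["k2"],
        k1_stderr=res.stderr["k_obs"],
        trace_fit=res,
    )


def fit_activity_series(
    results: list[tuple[float, "TraceFitResult | float"]],
) -> ActivityResult:
    """Weighted linear fit of k_obs against catalyst concentration.

    Each entry is ``(b, fit)`` where ``fit`` is a :class:`TraceFitResult`
    or a bare k_obs value.  Weights are 1/SE(k_obs)^2 when every entry
    carries a standard error, otherwise the fit is unweighted (equal SEs
    reduce to the same estimates either way).  The slope is k_cat; with
    supplied SEs its uncertainty treats them as known variances rather
    than re-estimating the error scale from the few residual degrees of
    freedom.
    """
    if len(results) < 2:
        raise ValueError("need at least two concentrations")
    rows = []
    for b, r in results:
        if isinstance(r, TraceFitResult):
            rows.append((b, r.k_obs, r.stderr.get("k_obs")))
        else:
            rows.append((b, float(r), None))
    table = pd.DataFrame(rows, columns=["b", "k_obs", "stderr"])
    if table["b"].nunique() < 2:
        raise ValueError("all concentrations identical; slope is undefined")

    X = sm.add_constant(table["b"].to_numpy())
    y = table["k_obs"].to_numpy()
    se = table["stderr"].to_numpy(dtype=float)
    if np.all(np.isfinite(se)) and np.all(se > 0):
        # known measurement variances: fixed-scale covariance, inflated by
        # sqrt(chi2/dof) when the points scatter more than their SEs claim
        res = sm.WLS(y, X, weights=1.0 / se**2).fit(cov_type="fixed scale")
        inflation = max(1.0, float(np.sqrt(res.scale)))
    else:
        res = sm.OLS(y, X).fit()
        inflation = 1.0
    return ActivityResult(
        table=table,
        k1=float(res.params[0]),
        k1_stderr=float(res.bse[0]) * inflation,
        k_cat=float(res.params[1]),
        k_cat_stderr=float(res.bse[1]) * inflation,
        r_squared=float(res.rsquared),
    )


# --------------------------------------------------------------------------
# Degradation (half-life) fits
# --------------------------------------------------------------------------


def _first_order_model(t, A0, A_inf, k):
    return first_order_decay(t, FirstOrderDecayParams(A0=A0, A_inf=A_inf, k=max(k, 1e-300)))


def fit_degradation(trace: DecayTrace, wavelength: float | None = None) -> HalfLifeResult:
    """First-order fit of a Ni(II)-peptide degradation trace.

    Operates in absorbance units (the chromophore extinction at the
    degradation wavelengths differs from the 250 nm superoxide value, so
    no concentration conversion is attempted).  The half-life is
    ln 2 / k with its standard error by linear propagation.  A trace
    with rising signal is flagged; a trace much shorter than three
    half-lives triggers a warning (the plateau is then poorly
    constrained).
    """
    t, y = trace.time, trace.absorbance
    if len(t) < 5:
        raise FitError("too few points for a degradation fit")
    if np.ptp(y) < 1e-12:
        raise FitError("flat trace; no degradation to fit")
    flags: list[str] = []
    if y[-1] > y[0]:
        flags.append("increasing-signal")
        warnings.warn("degradation trace increases over time", stacklevel=2)

    A0_0, Ainf_0 = float(y[0]), float(y[-1])
    span = t[-1] - t[0]
    resid = y - Ainf_0
    ok = resid > max(abs(A0_0 - Ainf_0) * 1e-3, 1e-12)
    if ok.sum() >= 3:
        k0 = max(-float(np.polyfit(t[ok], np.log(resid[ok]), 1)[0]), 1e-3)
    else:
        k0 = 1.0 / max(span, 1e-6)

    model = lmfit.Model(_first_order_model, independent_vars=["t"])
    params = model.make_params(A0=A0_0, A_inf=Ainf_0, k=k0)
    params["k"].set(min=0.0)
    fit = model.fit(y, params=params, t=t, max_nfev=500)
    if not fit.success:
        raise FitError("degradation fit did not converge")

    k_hat = fit.params["k"].value
    if k_hat <= 0:
        raise FitError("fitted rate is non-positive")
    k_se = fit.params["k"].stderr
    t_half = half_life(k_hat)
    t_half_se = (np.log(2.0) / k_hat**2 * k_se) if k_se is not None else None
    if span < 3.0 * t_half:
        flags.append("short-trace")
        warnings.warn(
            f"trace spans {span:.3g} s < 3 half-lives ({3*t_half:.3g} s); "
            "plateau poorly constrained",
            stacklevel=2,
        )
    return HalfLifeResult(
        wavelength=wavelength if wavelength is not None else trace.wavelength,
        k=k_hat,
        k_stderr=k_se,
        t_half=t_half,
        t_half_stderr=t_half_se,
        A0=fit.params["A0"].value,
        A_inf=fit.params["A_inf"].value,
        rss=float(np.sum(fit.residual**2)),
        converged=True,
        flags=flags,
    )


def summarize_half_lives(values: list[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of half-life estimates."""
    if len(values) < 2:
        raise ValueError("need at least two half-life values")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
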