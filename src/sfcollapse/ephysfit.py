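"""Two-electrode voltage-clamp curve fits.

Implements the standard analyses of whole-cell K+ channel recordings:

* Boltzmann fit of normalized tail-current amplitudes against test
  potential, ascending form ``f(V) = 1 / (1 + exp((V1/2 - V) / k))`` for
  activation (k > 0, current grows with depolarization);
* descending form ``f(V) = 1 / (1 + exp((V - V1/2) / k))`` for
  steady-state inactivation, optionally with the slope factor frozen
  (the "open fit" used when only a few points are measurable);
* single-exponential fit ``A exp(-t / tau) + C`` to deactivating tails;
* the steady-state inactivation measure: the ratio of the current
  remaining 100 ms after pulse onset to the instantaneous current, the
  latter extrapolated linearly from the first samples to the onset.

Fits are deterministic: initial values come from the half-maximum
crossing of the linearly interpolated data (V1/2) and the 25-75% span
(k), then scipy's Levenberg-Marquardt refines them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError, RatioError, SFCollapseError, WindowError

__all__ = [
    "boltzmann",
    "BoltzmannFit",
    "ExpFit",
    "SSInactPoint",
    "BoltzmannActivation",
    "BoltzmannInactivation",
    "ExponentialDecay",
    "fit_boltzmann",
    "fit_exponential",
    "steady_state_inactivation",
    "fit_ss_inactivation",
]


def boltzmann(V, v_half: float, k: float):
    """Ascending Boltzmann sigmoid ``1 / (1 + exp((v_half - V) / k))``."""
    if k == 0:
        raise SFCollapseError("Boltzmann slope factor k must be nonzero")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp(np.clip((v_half - V) / k, -500, 500)))
    return out if out.shape else float(out)


@dataclass(frozen=True)
class BoltzmannFit:
    """Fitted Boltzmann parameters (mV) with standard errors and residuals."""

    v_half: float
    k: float
    rss: float
    se_v_half: float
    se_k: float
    r_squared: float
    ascending: bool


@dataclass(frozen=True)
class ExpFit:
    """Fitted single-exponential parameters."""

    tau: float  # ms
    amplitude: float
    offset: float
    rss: float


@dataclass(frozen=True)
class SSInactPoint:
    """Steady-state inactivation measure at one test potential."""

    test_potential: float  # mV
    ratio: float  # I(onset + window) / I(onset)


class _BoltzmannBase(BaseEstimator, RegressorMixin):
    _ascending = True

    def __init__(self, k_fixed: float | None = None, lack_of_fit_r2: float = 0.9):
        self.k_fixed = k_fixed
        self.lack_of_fit_r2 = lack_of_fit_r2

    def _model(self, V, v_half, k):
        if self._ascending:
            return boltzmann(V, v_half, k)
        return boltzmann(V, v_half, -k)  # descending branch, k kept positive

    def _initial(self, V: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        order = np.argsort(V)
        Vs, ys = V[order], y[order]
        if not self._ascending:
            ys = ys[::-1]
            Vs = Vs[::-1] * -1  # mirror so the curve ascends, un-mirror below
        span = ys.max() - ys.min()
        if span < 0.1:
            raise FitError(
                "amplitudes show no transition (span "
                f"{span:.3g}); Boltzmann fit is undefined"
            )

        def crossing(level: float) -> float:
            above = ys >= level
            if above.all():
                return float(Vs[0])
            if not above.any():
                return float(Vs[-1])
            i = int(np.argmax(above))
            if i == 0:
                return float(Vs[0])
            x0, x1 = Vs[i - 1], Vs[i]
            y0, y1 = ys[i - 1], ys[i]
            return float(x0 + (level - y0) / (y1 - y0) * (x1 - x0))

        v50 = crossing(0.5)
        k0 = max((crossing(0.75) - crossing(0.25)) / (2 * np.log(3)), 0.5)
        if not self._ascending:
            v50 = -v50
        return v50, k0

    def fit(self, X, y):
        V = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if V.shape != y.shape:
            raise FitError("potentials and amplitudes differ in length")
        if len(np.unique(V)) < (2 if self.k_fixed is not None else 4):
            raise FitError("too few distinct potentials for a Boltzmann fit")
        v0, k0 = self._initial(V, y)
        try:
            if self.k_fixed is not None:
                kf = float(self.k_fixed)
                popt, pcov = curve_fit(
                    lambda VV, vh: self._model(VV, vh, kf), V, y, p0=[v0]
                )
                v_half, k = float(popt[0]), kf
                se = np.sqrt(np.diag(pcov))
                se_v, se_k = float(se[0]), 0.0
            else:
                popt, pcov = curve_fit(self._model, V, y, p0=[v0, k0])
                v_half, k = float(popt[0]), float(popt[1])
                se = np.sqrt(np.diag(pcov))
                se_v, se_k = float(se[0]), float(se[1])
        except RuntimeError as exc:
            raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
        resid = y - self._model(V, v_half, k)
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        self.v_half_ = v_half
        self.k_ = k
        self.rss_ = rss
        self.r_squared_ = r2
        self.lack_of_fit_ = r2 < self.lack_of_fit_r2
        self.result_ = BoltzmannFit(v_half, k, rss, se_v, se_k, r2, self._ascending)
        return self

    def predict(self, X):
        return self._model(np.asarray(X, dtype=float).ravel(), self.v_half_, self.k_)


class BoltzmannActivation(_BoltzmannBase):
    """Ascending Boltzmann fit of normalized tail amplitudes vs potential."""

    _ascending = True


class BoltzmannInactivation(_BoltzmannBase):
    """Descending Boltzmann fit (steady-state inactivation vs potential).

    ``k_fixed`` freezes the slope factor, the "open fit" used when the curve
    is shifted so far that only a few points span the transition.
    """

    _ascending = False


class ExponentialDecay(BaseEstimator, RegressorMixin):
    """Single-exponential fit ``A exp(-t / tau) + C`` to a decaying trace.

    ``window`` (t_min, t_max) restricts the fitted segment (e.g. the tail
    after the capacitive transient).
    """

    def __init__(self, window: tuple[float, float] | None = None):
        self.window = window

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.window is not None:
            m = (t >= self.window[0]) & (t <= self.window[1])
            t, y = t[m], y[m]
        if len(t) < 5:
            raise FitError("exponential fit needs >= 5 samples in the window")
        t0 = t[0]
        c0 = float(np.mean(y[-max(len(y) // 10, 2):]))
        a0 = float(y[0] - c0)
        if a0 <= 0 or y[0] <= np.mean(y[-3:]):
            raise FitError("trace is not decaying; refuse to fit an exponential")
        pos = y - c0 > 1e-12 * max(abs(a0), 1.0)
        slope, _ = np.polyfit(t[pos], np.log(y[pos] - c0 + 1e-300), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t0) / 3

        def model(tt, a, tau, c):
            return a * np.exp(-(tt - t0) / tau) + c

        try:
            popt, _ = curve_fit(
                model, t, y, p0=[a0, tau0, c0],
                bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            )
        except RuntimeError as exc:
            raise FitError(f"exponential fit did not converge: {exc}") from exc
        resid = y - model(t, *popt)
        self.amplitude_, self.tau_, self.offset_ = map(float, popt)
        self.rss_ = float(resid @ resid)
        self.t0_ = float(t0)
        self.result_ = ExpFit(self.tau_, self.amplitude_, self.offset_, self.rss_)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return self.amplitude_ * np.exp(-(t - self.t0_) / self.tau_) + self.offset_


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def fit_boltzmann(potentials, amplitudes, k_fixed: float | None = None) -> BoltzmannFit:
    """Ascending Boltzmann fit; see :class:`BoltzmannActivation`."""
    return BoltzmannActivation(k_fixed=k_fixed).fit(potentials, amplitudes).result_


def fit_exponential(time_ms, current, window=None) -> ExpFit:
    """Single-exponential deactivation fit; see :class:`ExponentialDecay`."""
    return ExponentialDecay(window=window).fit(time_ms, current).result_


def steady_state_inactivation(
    time_ms,
    current,
    t_onset: float = 0.0,
    window_ms: float = 100.0,
    test_potential: float = 0.0,
    n_extrapolate: int = 5,
) -> SSInactPoint:
    """Ratio of remaining to instantaneous current after ``window_ms``.

    The instantaneous amplitude is the sample at the onset time when one
    exists, otherwise a linear extrapolation of the first ``n_extrapolate``
    samples after onset back to the onset time; the remaining amplitude is
    interpolated at onset + window.
    """
    t = np.asarray(time_ms, dtype=float).ravel()
    y = np.asarray(current, dtype=float).ravel()
    mask = t >= t_onset
    if mask.sum() < n_extrapolate:
        raise WindowError("too few samples after onset for extrapolation")
    if t[mask].max() < t_onset + window_ms:
        raise WindowError(
            f"trace ends at {t[mask].max()} ms, before onset + {window_ms} ms"
        )
    at_onset = np.isclose(t, t_onset)
    if at_onset.any():
        instantaneous = float(y[at_onset][0])
    else:
        ts, ys = t[mask][:n_extrapolate], y[mask][:n_extrapolate]
        slope, intercept = np.polyfit(ts, ys, 1)
        instantaneous = float(slope * t_onset + intercept)
    if abs(instantaneous) < 1e-12:
        raise RatioError("instantaneous amplitude is zero; ratio undefined")
    remaining = float(np.interp(t_onset + window_ms, t, y))
    return SSInactPoint(test_potential, remaining / instantaneous)


def fit_ss_inactivation(points, k_fixed: float | None = None) -> BoltzmannFit:
    """Descending Boltzmann fit to steady-state inactivation points.

    ``points`` is an iterable of :class:`SSInactPoint` or (potential, ratio)
    pairs.
    """
    pts = [
        (p.test_potential, p.ratio) if isinstance(p, SSInactPoint) else tuple(p)
        for p in points
    ]
    if not pts:
        raise FitError("no steady-state inactivation points given")
    V = [p[0] for p in pts]
    r = [p[1] for p in pts]
    return BoltzmannInactivation(k_fixed=k_fixed).fit(V, r).result_
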