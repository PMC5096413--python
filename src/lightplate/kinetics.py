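"""Steady-state and dynamic models of optogenetic gene-expression systems.

Two systems are modeled:

* the green-activated / red-deactivated bacterial two-component system
  (CcaS-CcaR driving sfGFP), whose steady-state response to green light is
  a Hill curve whose half-maximal intensity shifts linearly with competing
  red light, and whose step-response dynamics are a delay followed by a
  two-stage linear cascade (first-order transcription-rate switching, then
  first-order dilution by growth);

* the blue-light yeast two-hybrid system (CRY2-CIB1 driving mCherry),
  whose steady state is a Hill curve of blue intensity and whose dynamics
  are a delay followed by a single first-order relaxation toward the
  set-point given by the transfer function.

Fitting is exposed statsmodels-style: a model object is built from tidy
data tables and ``fit()`` returns a results object carrying parameter
estimates, standard errors from the linearized covariance, confidence
intervals and a ``summary()`` table. Shared-parameter fits (step-on and
step-off jointly; dose-response curves across several red intensities)
are first-class models.

The feedforward function generator inverts the CcaS-CcaR cascade to
pre-compute a green-light time course that drives the model output along
a user-supplied reference waveform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DomainError, FitError, InfeasibleFluxError, ResolutionError
from .programs import Constant, Piecewise, Waveform

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RedShift:
    """Linear shift of the half-maximal green intensity with red light.

    ``slope`` is in umol m-2 s-1 green per umol m-2 s-1 red; the effective
    half-maximal intensity is ``k_half + slope * red_intensity``.
    """

    slope: float = 0.0

    def __post_init__(self):
        if self.slope < 0:
            raise DomainError("red-shift slope must be >= 0")


NO_SHIFT = RedShift(0.0)


@dataclass(frozen=True)
class HillTransferFunction:
    """Steady-state intensity -> expression map.

    output(I) = basal + (maximum - basal) * I^n / (k_eff^n + I^n)

    basal and maximum are in reporter output units (calibrated arbitrary
    fluorescence); k_half is a photon flux in umol m-2 s-1; n_hill is the
    dimensionless cooperativity.
    """

    basal: float
    maximum: float
    k_half: float
    n_hill: float

    def __post_init__(self):
        if not self.basal > 0:
            raise DomainError("basal must be > 0")
        if self.maximum < self.basal:
            raise DomainError("maximum must be >= basal")
        if not self.k_half > 0:
            raise DomainError("k_half must be > 0")
        if not self.n_hill > 0:
            raise DomainError("n_hill must be > 0")

    @property
    def dynamic_range(self) -> float:
        """Fold-change maximum/basal (>= 1)."""
        return self.maximum / self.basal

    def response(self, intensity, red_intensity=0.0, shift: RedShift = NO_SHIFT):
        return hill_response(self, intensity, red_intensity, shift)

    def inverse(self, output, red_intensity=0.0, shift: RedShift = NO_SHIFT):
        """Intensity producing ``output``; requires basal < output < maximum."""
        k_eff = self.k_half + shift.slope * red_intensity
        y = np.asarray(output, dtype=float)
        if np.any(y <= self.basal) or np.any(y >= self.maximum):
            raise DomainError(
                "output must lie strictly between basal and maximum to invert"
            )
        frac = (y - self.basal) / (self.maximum - y)
        out = k_eff * frac ** (1.0 / self.n_hill)
        return float(out) if np.isscalar(output) else out


def hill_response(
    tf: HillTransferFunction,
    intensity,
    red_intensity=0.0,
    shift: RedShift = NO_SHIFT,
):
    """Hill dose response with optional red-light competition.

    Vectorized over ``intensity``; red light raises the effective k_half by
    ``shift.slope`` per unit red flux, leaving basal, maximum and n alone.
    """
    I = np.asarray(intensity, dtype=float)
    if np.any(I < 0) or np.any(np.asarray(red_intensity) < 0):
        raise DomainError("intensities must be >= 0")
    k_eff = tf.k_half + shift.slope * red_intensity
    out = _hill(I, tf.basal, tf.maximum, k_eff, tf.n_hill)
    return float(out) if np.isscalar(intensity) else out


def _hill(I, basal, maximum, k, n):
    """Numerically stable Hill evaluation (handles I == 0 and large n)."""
    I = np.asarray(I, dtype=float)
    with np.errstate(divide="ignore"):
        logratio = np.where(I > 0, n * (np.log(k) - np.log(np.maximum(I, 1e-300))), np.inf)
    act = 1.0 / (1.0 + np.exp(np.clip(logratio, -500, 500)))
    act = np.where(I > 0, act, 0.0)
    return basal + (maximum - basal) * act


# ---------------------------------------------------------------------------
# Dynamic models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelayedFirstOrderModel:
    """Delay + single first-order relaxation (blue-light Y2H reporter).

    After a delay ``tau_delay`` the reporter m(t) relaxes exponentially
    with rate ``alpha`` toward the set-point f(I_b) given by the transfer
    function; before the delay it stays at its preconditioned value m0.

    ``max_intensity`` bounds the validity of the set-point map: above it
    growth defects confound the steady-state measurement, so the model
    refuses extrapolation by default.
    """

    tau_delay: float
    alpha: float
    transfer: HillTransferFunction
    m0: float
    max_intensity: float = 93.5

    def __post_init__(self):
        if self.tau_delay < 0:
            raise DomainError("tau_delay must be >= 0")
        if not self.alpha > 0:
            raise DomainError("alpha must be > 0")

    @property
    def half_time(self) -> float:
        """Post-delay time to reach 50% of the final level, ln(2)/alpha."""
        return LN2 / self.alpha

    def set_point(self, blue_intensity: float, allow_extrapolation: bool = False) -> float:
        if blue_intensity > self.max_intensity and not allow_extrapolation:
            raise DomainError(
                f"set-point map not validated above {self.max_intensity} "
                f"umol m-2 s-1 (requested {blue_intensity})"
            )
        return float(hill_response(self.transfer, blue_intensity))

    def solution(self, blue_intensity, t, allow_extrapolation=False):
        return piecewise_solution(self, blue_intensity, t, allow_extrapolation)


def piecewise_solution(
    model: DelayedFirstOrderModel, blue_intensity, t, allow_extrapolation=False
):
    """Closed-form solution of the delayed first-order ODE.

    m(t) = m0                                       for t <= tau_delay
    m(t) = f(I_b) + (m0 - f(I_b)) e^(-alpha (t - tau_delay))   otherwise
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    minf = model.set_point(blue_intensity, allow_extrapolation)
    out = _delayed_exponential(t, model.tau_delay, model.alpha, model.m0, minf)
    return float(out) if out.ndim == 0 else out


def _delayed_exponential(t, tau, alpha, m0, minf):
    t = np.asarray(t, dtype=float)
    s = np.maximum(t - tau, 0.0)
    return np.where(t <= tau, m0, minf + (m0 - minf) * np.exp(-alpha * s))


@dataclass(frozen=True)
class CcaSDynamicModel:
    """Delay -> first-order transcription-rate switching -> first-order dilution.

    dp/dt = k_switch (p_ss(t) - p)      p: sfGFP production rate
    dG/dt = p - k_g G                   G: sfGFP level

    with p_ss(t) = k_g * hill(green(t - tau_delay), red(t - tau_delay)) so
    that the steady state of G equals the transfer-function output. k_g is
    the dilution rate set by the cell division time; k_switch sets the
    transcription-rate switching half-time ln(2)/k_switch.
    """

    tau_delay: float
    k_switch: float
    k_g: float
    transfer: HillTransferFunction
    red_shift: RedShift = NO_SHIFT

    def __post_init__(self):
        if self.tau_delay < 0:
            raise DomainError("tau_delay must be >= 0")
        if not (self.k_switch > 0 and self.k_g > 0):
            raise DomainError("rates must be > 0")

    @property
    def switching_half_time(self) -> float:
        return LN2 / self.k_switch

    @property
    def dilution_half_time(self) -> float:
        return LN2 / self.k_g

    def steady_state(self, green: float, red: float = 0.0) -> float:
        return float(hill_response(self.transfer, green, red, self.red_shift))


def _two_stage_step(t, tau, ks, kg, h_pre, h_post):
    """Closed-form step response of the delayed two-stage cascade.

    Preconditioned at steady state for the pre-step input (G = h_pre,
    p = k_g h_pre); the set-point switches to h_post at t = tau (input
    step at t = 0 seen after the delay). Symmetric in (ks, kg) for this
    initial condition.
    """
    t = np.asarray(t, dtype=float)
    s = np.maximum(t - tau, 0.0)
    if abs(kg - ks) < 1e-6 * max(kg, ks):
        shape = (1.0 + kg * s) * np.exp(-kg * s)
    else:
        shape = (kg / (kg - ks)) * (np.exp(-ks * s) - np.exp(-kg * s)) + np.exp(-kg * s)
    out = h_post + (h_pre - h_post) * shape
    return np.where(t <= tau, h_pre, out)


def ccas_step_response(
    model: CcaSDynamicModel,
    t,
    green_pre: float,
    red_pre: float,
    green_post: float,
    red_post: float,
):
    """Model step response from preconditioned steady state (closed form)."""
    h_pre = model.steady_state(green_pre, red_pre)
    h_post = model.steady_state(green_post, red_post)
    out = _two_stage_step(t, model.tau_delay, model.k_switch, model.k_g, h_pre, h_post)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Simulation (general inputs)
# ---------------------------------------------------------------------------

def simulate_ccas(
    model: CcaSDynamicModel,
    green: Waveform,
    red: Waveform,
    t_grid,
    g0: float,
    p0: float | None = None,
    max_step: float = 0.25,
    rtol: float = 1e-6,
    input_history: tuple[float, float] | None = None,
) -> np.ndarray:
    """Integrate the two-stage cascade for arbitrary light waveforms.

    The cascade is linear, so the state is propagated exactly across steps
    on which the (delayed) input is held constant; input waveforms are
    sampled at substep midpoints with all discontinuities (waveform
    breakpoints shifted by the delay) inserted as step boundaries. The
    trajectory is recomputed at half the step size and a relative
    discrepancy above ``rtol`` raises :class:`ResolutionError`.

    The delay makes the first ``tau_delay`` minutes depend on the input
    before t = 0. By default waveforms are evaluated at negative times, so
    a step at t = 0 exposes its initial (preconditioning) level there;
    ``input_history`` = (green, red) overrides the pre-experiment levels
    explicitly. ``p0`` defaults to the production rate consistent with
    steady state at g0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing")
    if np.any(t_grid < 0):
        raise DomainError("t_grid must be >= 0")
    if g0 < 0:
        raise DomainError("g0 must be >= 0")

    coarse = _integrate_ccas(model, green, red, t_grid, g0, p0, max_step, input_history)
    fine = _integrate_ccas(model, green, red, t_grid, g0, p0, max_step / 2.0, input_history)
    scale = max(np.max(np.abs(fine)), model.transfer.basal)
    err = np.max(np.abs(coarse - fine)) / scale
    if err > rtol:
        raise ResolutionError(
            f"integration error estimate {err:.2e} exceeds rtol={rtol:.2e}; "
            f"reduce max_step (currently {max_step} min)"
        )
    return fine


def _integrate_ccas(model, green, red, t_grid, g0, p0, max_step, input_history=None):
    tau, ks, kg = model.tau_delay, model.k_switch, model.k_g
    t_end = float(t_grid[-1])

    def set_point(t):
        # the delayed input extends naturally to t < 0 (preconditioning:
        # a step at 0 exposes its initial level, periodic signals wrap),
        # unless explicit pre-experiment levels were given
        te = t - tau
        if te < 0 and input_history is not None:
            gv, rv = input_history
        else:
            gv, rv = green(te), red(te)
        return kg * float(hill_response(model.transfer, gv, rv, model.red_shift))

    # step boundaries: output grid + delayed input breakpoints
    bps = set(np.concatenate([[0.0], t_grid]))
    for w in (green, red):
        for b in w.breakpoints(t_end):
            tb = b + tau
            if 0.0 < tb <= t_end:
                bps.add(tb)
    if tau and 0.0 < tau <= t_end:
        bps.add(tau)  # pre-t=0 input regime ends here
    knots = np.array(sorted(bps))

    p = kg * g0 if p0 is None else float(p0)
    G = float(g0)
    out = np.empty_like(t_grid)
    want = {round(t, 12): i for i, t in enumerate(t_grid)}
    if round(knots[0], 12) in want:
        out[want[round(knots[0], 12)]] = G

    for a, b in zip(knots[:-1], knots[1:]):
        seg = b - a
        n_sub = max(1, math.ceil(seg / max_step))
        h = seg / n_sub
        for j in range(n_sub):
            t_mid = a + (j + 0.5) * h
            pss = set_point(t_mid)
            p, G = _propagate(p, G, pss, ks, kg, h)
        key = round(b, 12)
        if key in want:
            out[want[key]] = G
    return out


def _propagate(p, G, pss, ks, kg, h):
    """Exact update of (p, G) over a step of length h with constant set-point."""
    eks = math.exp(-ks * h)
    ekg = math.exp(-kg * h)
    d = p - pss
    p_new = pss + d * eks
    if abs(kg - ks) < 1e-9 * max(kg, ks):
        conv = d * h * ekg
    else:
        conv = d * (eks - ekg) / (kg - ks)
    G_new = G * ekg + pss * (1.0 - ekg) / kg + conv
    return p_new, G_new


# ---------------------------------------------------------------------------
# Least-squares machinery
# ---------------------------------------------------------------------------

_POS = 1e-12  # open lower bound implementing the ">0" constraint


def _multistart_least_squares(residual, x0, bounds, seed, n_starts=5):
    """Trust-region least squares from several seeded starts; best solution wins."""
    rng = np.random.default_rng(seed)
    best = None
    x0 = np.asarray(x0, dtype=float)
    lo, hi = bounds
    for k in range(max(n_starts, 1) + 3):
        if k == 0:
            start = x0
        else:
            # widen the perturbation for the extra fallback starts
            sigma = 0.3 if k <= n_starts else 0.8
            start = x0 * rng.lognormal(0.0, sigma, size=x0.size)
        start = np.clip(start, lo, np.where(np.isfinite(hi), hi, start))
        try:
            res = optimize.least_squares(
                residual, start, bounds=bounds, method="trf", max_nfev=2000
            )
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
        if k >= n_starts and best is not None and best.success:
            break
    if best is None:
        raise FitError("least-squares fit failed to converge from all starts")
    return best


def _covariance(res, nobs):
    nparams = res.x.size
    dof = max(nobs - nparams, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cov = s2 * np.linalg.pinv(jtj)
    return cov, dof


class FitResults:
    """Common results surface: params, bse, conf_int, summary."""

    def __init__(self, params: pd.Series, cov: np.ndarray, nobs: int, dof: int, model_name: str):
        self.params = params
        self.cov = cov
        self.nobs = nobs
        self.dof = dof
        self.model_name = model_name
        self.bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.dof)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self, alpha: float = 0.05) -> str:
        ci = self.conf_int(alpha)
        table = pd.DataFrame(
            {
                "estimate": self.params,
                "std err": self.bse,
                f"[{alpha/2:.3f}": ci["lower"],
                f"{1 - alpha/2:.3f}]": ci["upper"],
            }
        )
        head = (
            f"{self.model_name}\n"
            f"{'=' * len(self.model_name)}\n"
            f"nobs: {self.nobs}    dof: {self.dof}\n"
        )
        return head + table.to_string(float_format=lambda v: f"{v:.6g}")


def _check_dose_table(data: pd.DataFrame) -> pd.DataFrame:
    if "intensity" not in data.columns or "value" not in data.columns:
        raise DomainError("dose-response table needs 'intensity' and 'value' columns")
    if data["intensity"].nunique() < 4:
        raise FitError("need >= 4 distinct intensities to fit a Hill curve")
    return data


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

class HillModel:
    """Four-parameter Hill fit to a steady-state dose-response table.

    Parameters
    ----------
    data : DataFrame
        Tidy table with columns ``intensity`` and ``value`` (a
        ``replicate`` column is allowed and ignored by the fit).

    All parameters are constrained positive; the fit is trust-region least
    squares restarted from 5 seeded perturbed starts.
    """

    param_names = ("basal", "maximum", "k_half", "n_hill")

    def __init__(self, data: pd.DataFrame):
        self.data = _check_dose_table(data)

    def _initial_guess(self) -> np.ndarray:
        g = self.data.groupby("intensity")["value"].mean().sort_index()
        lo, hi = float(g.iloc[0]), float(g.iloc[-1])
        basal0 = max(min(lo, hi), _POS)
        max0 = max(lo, hi, basal0 * 1.01)
        half = (basal0 + max0) / 2.0
        above = g[g >= half]
        k0 = float(above.index[0]) if len(above) and above.index[0] > 0 else float(
            g.index[len(g) // 2]
        )
        return np.array([basal0, max0, max(k0, 1e-3), 2.0])

    def fit(self, seed: int = 0, n_starts: int = 5) -> "HillResults":
        y = self.data["value"].to_numpy(dtype=float)
        I = self.data["intensity"].to_numpy(dtype=float)

        def residual(x):
            return _hill(I, *x) - y

        lo = np.full(4, _POS)
        hi = np.array([np.inf, np.inf, np.inf, 50.0])
        res = _multistart_least_squares(residual, self._initial_guess(), (lo, hi), seed, n_starts)
        cov, dof = _covariance(res, y.size)
        params = pd.Series(res.x, index=self.param_names)

        results = HillResults(params, cov, y.size, dof)
        fitted_span = float(params["maximum"] - params["basal"])
        noise = float(np.std(y - _hill(I, *res.x)))
        if fitted_span < 3.0 * max(noise, 1e-12):
            warnings.warn(
                "dose-response data are flat relative to noise; k_half is unreliable",
                stacklevel=2,
            )
            results.k_half_reliable = False
        if not (I.min() < params["k_half"] < I.max()):
            warnings.warn(
                "fitted k_half lies outside the sampled intensity range", stacklevel=2
            )
            results.k_half_reliable = False
        return results


class HillResults(FitResults):
    def __init__(self, params, cov, nobs, dof):
        super().__init__(params, cov, nobs, dof, "Hill transfer function fit")
        self.k_half_reliable = True

    @property
    def transfer(self) -> HillTransferFunction:
        p = self.params
        return HillTransferFunction(p["basal"], p["maximum"], p["k_half"], p["n_hill"])

    @property
    def dynamic_range(self) -> float:
        return float(self.params["maximum"] / self.params["basal"])

    @property
    def dynamic_range_bse(self) -> float:
        """Delta-method standard error of maximum/basal."""
        b, m = self.params["basal"], self.params["maximum"]
        grad = np.zeros(len(self.params))
        grad[list(self.params.index).index("maximum")] = 1.0 / b
        grad[list(self.params.index).index("basal")] = -m / b**2
        return float(np.sqrt(max(grad @ self.cov @ grad, 0.0)))


def fit_hill(data: pd.DataFrame, seed: int = 0) -> HillResults:
    """Functional wrapper around :class:`HillModel`."""
    return HillModel(data).fit(seed=seed)


# ---------------------------------------------------------------------------
# Joint fit across red intensities (red-light competition)
# ---------------------------------------------------------------------------

class RedShiftModel:
    """Joint Hill fit across dose-response tables at several red intensities.

    basal, maximum and n_hill are shared across datasets; each dataset gets
    its own k_half. The red-competition slope is the linear regression of
    fitted k_half on red intensity.
    """

    def __init__(self, datasets: Sequence[tuple[float, pd.DataFrame]]):
        if len(datasets) < 3:
            raise FitError("need >= 3 red intensities for a red-shift fit")
        self.datasets = [(float(r), _check_dose_table(d)) for r, d in datasets]

    def fit(self, seed: int = 0, n_starts: int = 5) -> "RedShiftResults":
        reds = np.array([r for r, _ in self.datasets])
        tables = [d for _, d in self.datasets]
        Is = [d["intensity"].to_numpy(dtype=float) for d in tables]
        ys = [d["value"].to_numpy(dtype=float) for d in tables]
        m = len(tables)

        base = HillModel(tables[0])._initial_guess()
        x0 = np.concatenate([base[:2], [base[3]], np.full(m, base[2])])

        def residual(x):
            basal, maximum, n = x[0], x[1], x[2]
            ks = x[3:]
            return np.concatenate(
                [_hill(I, basal, maximum, k, n) - y for I, y, k in zip(Is, ys, ks)]
            )

        lo = np.full(3 + m, _POS)
        hi = np.concatenate([[np.inf, np.inf, 50.0], np.full(m, np.inf)])
        res = _multistart_least_squares(residual, x0, (lo, hi), seed, n_starts)
        nobs = sum(y.size for y in ys)
        cov, dof = _covariance(res, nobs)
        names = ["basal", "maximum", "n_hill"] + [f"k_half[red={r:g}]" for r in reds]
        params = pd.Series(res.x, index=names)

        k_fitted = res.x[3:]
        reg = stats.linregress(reds, k_fitted)
        return RedShiftResults(params, cov, nobs, dof, reds, k_fitted, reg)


class RedShiftResults(FitResults):
    def __init__(self, params, cov, nobs, dof, reds, k_half_values, reg):
        super().__init__(params, cov, nobs, dof, "Red-light competition joint Hill fit")
        self.red_intensities = np.asarray(reds)
        self.k_half_values = pd.Series(k_half_values, index=[f"red={r:g}" for r in reds])
        self.slope = float(reg.slope)
        self.slope_bse = float(reg.stderr)
        self.intercept = float(reg.intercept)

    @property
    def red_shift(self) -> RedShift:
        return RedShift(max(self.slope, 0.0))

    @property
    def dynamic_range(self) -> float:
        return float(self.params["maximum"] / self.params["basal"])

    def summary(self, alpha: float = 0.05) -> str:
        base = super().summary(alpha)
        return (
            base
            + f"\nred-shift slope: {self.slope:.6g} +/- {self.slope_bse:.3g} "
            "umol m-2 s-1 green per unit red"
        )


def fit_red_shift(datasets, seed: int = 0) -> RedShiftResults:
    """Functional wrapper around :class:`RedShiftModel`."""
    return RedShiftModel(datasets).fit(seed=seed)


# ---------------------------------------------------------------------------
# Step-kinetics fits
# ---------------------------------------------------------------------------

def _check_delay_identifiable(
    tau: float,
    slow_rate: float,
    t_all: np.ndarray,
    deltas: Sequence[float],
    residuals: np.ndarray,
) -> None:
    """Reject fits whose post-delay relaxation the samples cannot see.

    Three degenerate signatures, all arising when every sample precedes the
    true delay (or the response is flat): almost no samples after the
    fitted delay; a fitted relaxation far slower than the observation
    window; or fitted pre-to-post level changes indistinguishable from the
    residual noise.
    """
    t_max = float(t_all.max())
    n_post = int(np.sum(t_all > tau))
    if n_post < 4:
        raise FitError(
            f"only {n_post} samples fall after the fitted delay ({tau:.3g} min); "
            "the relaxation is not identifiable"
        )
    if LN2 / slow_rate > 5.0 * t_max:
        raise FitError(
            "fitted relaxation half-time exceeds the observation window "
            "5-fold; samples appear to precede the delay or the response is flat"
        )
    noise = float(np.std(residuals))
    if max(abs(d) for d in deltas) < 5.0 * max(noise, 1e-12):
        raise FitError(
            "fitted step amplitude is within the noise; no step response is "
            "detectable in the sampled window"
        )


def _check_time_table(data: pd.DataFrame) -> pd.DataFrame:
    if "time_min" not in data.columns or "value" not in data.columns:
        raise DomainError("time-course table needs 'time_min' and 'value' columns")
    return data


class Cry2StepModel:
    """Shared-parameter fit of the delayed-exponential model to a step-on /
    step-off pair of reporter time courses.

    The delay tau and the rate constant alpha are shared between the two
    datasets; each dataset has its own initial and final level. Reports the
    post-delay half-time ln(2)/alpha.
    """

    def __init__(self, step_on: pd.DataFrame, step_off: pd.DataFrame):
        self.step_on = _check_time_table(step_on)
        self.step_off = _check_time_table(step_off)

    def fit(self, seed: int = 0, n_starts: int = 5) -> "Cry2StepResults":
        t_on = self.step_on["time_min"].to_numpy(dtype=float)
        y_on = self.step_on["value"].to_numpy(dtype=float)
        t_off = self.step_off["time_min"].to_numpy(dtype=float)
        y_off = self.step_off["value"].to_numpy(dtype=float)
        t_max = max(t_on.max(), t_off.max())

        x0 = np.array(
            [
                min(60.0, 0.25 * t_max),  # tau
                LN2 / max(0.25 * t_max, 1.0),  # alpha
                max(y_on[np.argmin(t_on)], _POS),
                max(y_on[np.argmax(t_on)], _POS),
                max(y_off[np.argmin(t_off)], _POS),
                max(y_off[np.argmax(t_off)], _POS),
            ]
        )

        def residual(x):
            tau, alpha, m0_on, minf_on, m0_off, minf_off = x
            r_on = _delayed_exponential(t_on, tau, alpha, m0_on, minf_on) - y_on
            r_off = _delayed_exponential(t_off, tau, alpha, m0_off, minf_off) - y_off
            return np.concatenate([r_on, r_off])

        lo = np.full(6, _POS)
        hi = np.full(6, np.inf)
        res = _multistart_least_squares(residual, x0, (lo, hi), seed, n_starts)
        _check_delay_identifiable(
            res.x[0], res.x[1], np.concatenate([t_on, t_off]),
            [res.x[3] - res.x[2], res.x[5] - res.x[4]], res.fun,
        )
        nobs = t_on.size + t_off.size
        cov, dof = _covariance(res, nobs)
        names = ["tau_delay", "alpha", "m0_on", "m_inf_on", "m0_off", "m_inf_off"]
        return Cry2StepResults(pd.Series(res.x, index=names), cov, nobs, dof)


class Cry2StepResults(FitResults):
    def __init__(self, params, cov, nobs, dof):
        super().__init__(params, cov, nobs, dof, "Delayed first-order step-kinetics fit")

    @property
    def tau_delay(self) -> float:
        return float(self.params["tau_delay"])

    @property
    def alpha(self) -> float:
        return float(self.params["alpha"])

    @property
    def half_time(self) -> float:
        return LN2 / self.alpha

    @property
    def half_time_bse(self) -> float:
        i = list(self.params.index).index("alpha")
        return float(LN2 / self.alpha**2 * self.bse.iloc[i])

    def summary(self, alpha: float = 0.05) -> str:
        return (
            super().summary(alpha)
            + f"\npost-delay half-time ln(2)/alpha: {self.half_time:.6g} min"
        )


def fit_step_kinetics_cry2(step_on, step_off, seed: int = 0) -> Cry2StepResults:
    return Cry2StepModel(step_on, step_off).fit(seed=seed)


class CcasStepModel:
    """Shared-parameter fit of the delayed two-stage cascade step response.

    tau_delay and the dilution rate k_g (and the switching rate k_switch)
    are shared between the step-on and step-off datasets; each dataset has
    its own pre- and post-step steady-state levels.

    A single preconditioned step response is symmetric in (k_switch, k_g),
    so the labels are set by the convention that transcription-rate
    switching is the faster stage (``assume_switching_faster``); disable it
    to keep the raw ordering.
    """

    def __init__(
        self,
        step_on: pd.DataFrame,
        step_off: pd.DataFrame,
        assume_switching_faster: bool = True,
    ):
        self.step_on = _check_time_table(step_on)
        self.step_off = _check_time_table(step_off)
        self.assume_switching_faster = assume_switching_faster

    def fit(self, seed: int = 0, n_starts: int = 5) -> "CcasStepResults":
        t_on = self.step_on["time_min"].to_numpy(dtype=float)
        y_on = self.step_on["value"].to_numpy(dtype=float)
        t_off = self.step_off["time_min"].to_numpy(dtype=float)
        y_off = self.step_off["value"].to_numpy(dtype=float)
        t_max = max(t_on.max(), t_off.max())

        x0 = np.array(
            [
                min(5.0, 0.05 * t_max),  # tau
                LN2 / max(0.05 * t_max, 1.0),  # k_switch
                LN2 / max(0.2 * t_max, 1.0),  # k_g
                max(y_on[np.argmin(t_on)], _POS),
                max(y_on[np.argmax(t_on)], _POS),
                max(y_off[np.argmin(t_off)], _POS),
                max(y_off[np.argmax(t_off)], _POS),
            ]
        )

        def residual(x):
            tau, ks, kg, a_on, b_on, a_off, b_off = x
            r_on = _two_stage_step(t_on, tau, ks, kg, a_on, b_on) - y_on
            r_off = _two_stage_step(t_off, tau, ks, kg, a_off, b_off) - y_off
            return np.concatenate([r_on, r_off])

        lo = np.full(7, _POS)
        hi = np.full(7, np.inf)
        res = _multistart_least_squares(residual, x0, (lo, hi), seed, n_starts)
        x = res.x.copy()
        if self.assume_switching_faster and x[1] < x[2]:
            x[[1, 2]] = x[[2, 1]]
            perm = np.arange(7)
            perm[[1, 2]] = [2, 1]
            res.jac = res.jac[:, perm]
            res.x = x
        _check_delay_identifiable(
            x[0], x[2], np.concatenate([t_on, t_off]),
            [x[4] - x[3], x[6] - x[5]], res.fun,
        )
        nobs = t_on.size + t_off.size
        cov, dof = _covariance(res, nobs)
        names = ["tau_delay", "k_switch", "k_g", "h_pre_on", "h_post_on", "h_pre_off", "h_post_off"]
        return CcasStepResults(pd.Series(x, index=names), cov, nobs, dof)


class CcasStepResults(FitResults):
    def __init__(self, params, cov, nobs, dof):
        super().__init__(params, cov, nobs, dof, "Delayed two-stage cascade step-kinetics fit")

    @property
    def tau_delay(self) -> float:
        return float(self.params["tau_delay"])

    @property
    def k_switch(self) -> float:
        return float(self.params["k_switch"])

    @property
    def k_g(self) -> float:
        return float(self.params["k_g"])

    @property
    def switching_half_time(self) -> float:
        return LN2 / self.k_switch

    @property
    def switching_half_time_bse(self) -> float:
        i = list(self.params.index).index("k_switch")
        return float(LN2 / self.k_switch**2 * self.bse.iloc[i])

    def summary(self, alpha: float = 0.05) -> str:
        return (
            super().summary(alpha)
            + f"\ntranscription-rate switching half-time: {self.switching_half_time:.6g} min"
            + f"\ndilution half-time (cell division): {LN2 / self.k_g:.6g} min"
        )


def fit_step_kinetics_ccas(step_on, step_off, seed: int = 0) -> CcasStepResults:
    return CcasStepModel(step_on, step_off).fit(seed=seed)


# ---------------------------------------------------------------------------
# Feedforward function generation
# ---------------------------------------------------------------------------

@dataclass
class FunctionGenerationResult:
    """Output of :func:`generate_function`.

    ``light`` is the pre-computed green-light program as a hold-previous
    piecewise waveform; ``predicted`` is the forward-simulated trajectory
    on ``times``; RMSE is computed after the delay window and also reported
    as a fraction of the reference dynamic range.
    """

    light: Piecewise
    times: np.ndarray
    intensities: np.ndarray
    predicted: np.ndarray
    reference_values: np.ndarray
    rmse: float
    rmse_fraction: float
    clamped_times: np.ndarray


def generate_function(
    model: CcaSDynamicModel,
    reference: Waveform,
    duration: float,
    timestep: float,
    intensity_bounds: tuple[float, float],
    red: Waveform = Constant(0.0),
) -> FunctionGenerationResult:
    """Invert the cascade to pre-compute a light program tracking ``reference``.

    Feedforward inversion on a uniform grid of spacing ``timestep`` (min):
    the cascade is linear, so over one frame with a constant set-point the
    state propagates by an exact exponential update. Each frame's required
    set-point is solved so the propagated output lands on the reference at
    the next grid point; the light command is the Hill inverse of that
    set-point (with the red intensity at command time), issued one delay
    (``tau_delay``, rounded to the nearest frame) ahead of when it acts.

    Set-points leaving the transfer function's open output band, or
    intensities leaving ``intensity_bounds``, are clamped; the recursion
    propagates the realized (clamped) state so later frames re-converge to
    the reference. Clamping is reported as a warning and in the result.
    The returned trajectory is the forward simulation of the emitted
    program (with the unrounded delay) from g0 = r(0).
    """
    tf = model.transfer
    if timestep <= 0 or duration <= 0:
        raise DomainError("duration and timestep must be > 0")
    ks, kg = model.k_switch, model.k_g
    n = int(math.floor(duration / timestep)) + 1
    times = np.arange(n) * timestep
    r = np.array([reference(float(t)) for t in times])

    bad = times[(r <= tf.basal) | (r >= tf.maximum)]
    if bad.size:
        raise InfeasibleFluxError(
            "reference leaves the achievable output band "
            f"({tf.basal:.6g}, {tf.maximum:.6g}) at t = {bad[:10].tolist()} min"
        )

    # exact one-frame propagation coefficients (constant set-point)
    h = timestep
    eks, ekg = math.exp(-ks * h), math.exp(-kg * h)
    if abs(kg - ks) < 1e-9 * max(kg, ks):
        conv = h * ekg
    else:
        conv = (eks - ekg) / (kg - ks)
    gain = (1.0 - ekg) / kg - conv  # dG_next/dpss; > 0 for h > 0

    shift = int(round(model.tau_delay / timestep))
    eps = 1e-9 * (tf.maximum - tf.basal)
    lo_y, hi_y = tf.basal + eps, tf.maximum - eps
    lo_u, hi_u = intensity_bounds

    # before the delay elapses the output is set by the pre-experiment
    # light; assume preconditioning at the reference's starting level
    p, G = kg * float(r[0]), float(r[0])
    u = np.empty(n)
    clamped = np.zeros(n, dtype=bool)
    for k in range(n - 1):
        if k < shift:
            pss = kg * float(r[0])
        else:
            j = k - shift  # command frame whose light acts during plant frame k
            target = r[k + 1]
            pss_req = (target - G * ekg - p * conv) / gain
            y_req = pss_req / kg
            y_clip = min(max(y_req, lo_y), hi_y)
            u_raw = tf.inverse(y_clip, red(j * h), model.red_shift)
            u_cmd = min(max(u_raw, lo_u), hi_u)
            y_real = float(
                hill_response(tf, u_cmd, red(j * h), model.red_shift)
            )
            clamped[j] = (y_clip != y_req) or (u_cmd != u_raw)
            u[j] = u_cmd
            pss = kg * y_real
        p, G = _propagate(p, G, pss, ks, kg, h)
    u[n - 1 - shift :] = u[max(n - 1 - shift - 1, 0)] if n - 1 - shift > 0 else lo_u
    clamped_times = times[clamped]
    if clamped_times.size:
        warnings.warn(
            f"light program clamped at {clamped_times.size} of {n} grid points "
            f"(first at t = {clamped_times[0]:g} min)",
            stacklevel=2,
        )

    light = Piecewise(tuple(zip(times.tolist(), u.tolist())))
    u_pre = tf.inverse(float(r[0]), red(0.0), model.red_shift)
    predicted = simulate_ccas(
        model, light, red, times, g0=float(r[0]), p0=kg * float(r[0]),
        max_step=min(0.25, timestep), input_history=(u_pre, red(0.0)),
    )
    post = times >= model.tau_delay
    rmse = float(np.sqrt(np.mean((predicted[post] - r[post]) ** 2)))
    dyn = float(np.ptp(r))
    return FunctionGenerationResult(
        light=light,
        times=times,
        intensities=u,
        predicted=predicted,
        reference_values=r,
        rmse=rmse,
        rmse_fraction=rmse / dyn if dyn > 0 else math.nan,
        clamped_times=clamped_times,
    )
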