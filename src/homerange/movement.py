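"""Continuous-time movement models for autocorrelated telemetry data.

Three stationary Gaussian position processes are supported, per axis and
isotropic across axes:

``iid``  uncorrelated positions, variance sigma2;
``ou``   Ornstein–Uhlenbeck position process (range residency) with
         positional autocorrelation timescale tau_pos;
``ouf``  OU position with correlated velocity (an additional velocity
         timescale tau_vel < tau_pos), position autocovariance
         sigma2 * (tau_pos e^{-t/tau_pos} - tau_vel e^{-t/tau_vel})
         / (tau_pos - tau_vel).

Independent per-fix GPS error with per-axis variance (uere*hdop)^2 / 2 (so
the 2-D RMS error is uere*hdop) can be layered on top. Likelihoods are exact
Gaussian, evaluated in O(n) by a Kalman recursion on the exact discrete-time
state space; models are fitted by derivative-free maximum likelihood and
compared by small-sample-corrected AIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConvergenceError, DomainError
from .tracks import Track

__all__ = [
    "CTMMFit",
    "position_acf",
    "ctmm_loglik",
    "fit_ctmm",
    "empirical_variogram",
]

_LOG2PI = np.log(2.0 * np.pi)
_K_PARAMS = {"iid": 3, "ou": 4, "ouf": 5}  # mean (2) + variance (+ timescales)


@dataclass
class CTMMFit:
    """A fitted continuous-time movement model.

    Attributes
    ----------
    model : {"iid", "ou", "ouf"}
    mu : ndarray (2,)
        Stationary mean location (m).
    sigma2 : float
        Stationary positional variance per axis (m²), isotropic.
    tau_pos : float or None
        Positional autocorrelation timescale (s); None for iid.
    tau_vel : float or None
        Velocity autocorrelation timescale (s); ouf only.
    uere : float or None
        GPS error scale (m of 2-D RMS error per unit HDOP); None = no error
        model.
    loglik, aicc : float
        Maximized log-likelihood and small-sample-corrected AIC.
    dof_area : float
        Effective sample size for area estimation implied by the fitted
        autocorrelation (equals n for iid).
    n : int
        Number of fixes.
    """

    model: str
    mu: np.ndarray
    sigma2: float
    tau_pos: float | None
    tau_vel: float | None
    uere: float | None
    loglik: float
    aicc: float
    dof_area: float
    n: int
    converged: bool = True

    def to_json(self) -> str:
        d = asdict(self)
        d["mu"] = [float(v) for v in np.asarray(self.mu).ravel()]
        return json.dumps(d)


def position_acf(model, lag, sigma2=None, tau_pos=None, tau_vel=None):
    """Stationary position autocovariance (m² per axis) at the given lag(s).

    ``model`` may be a :class:`CTMMFit` (parameters taken from it) or a model
    name with explicit parameters.
    """
    if isinstance(model, CTMMFit):
        sigma2, tau_pos, tau_vel = model.sigma2, model.tau_pos, model.tau_vel
        model = model.model
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise DomainError("lag must be nonnegative")
    if model == "iid":
        return np.where(lag == 0.0, sigma2, 0.0)
    if model == "ou":
        return sigma2 * np.exp(-lag / tau_pos)
    if model == "ouf":
        if tau_pos == tau_vel:
            raise DomainError("ouf requires tau_vel < tau_pos (degenerate at equality)")
        return (
            sigma2
            * (tau_pos * np.exp(-lag / tau_pos) - tau_vel * np.exp(-lag / tau_vel))
            / (tau_pos - tau_vel)
        )
    raise DomainError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# exact discretization of the OUF state space (position, velocity per axis)


def ouf_stationary_cov(sigma2, tau_pos, tau_vel) -> np.ndarray:
    """Stationary (position, velocity) covariance of the OUF process."""
    return np.diag([sigma2, sigma2 / (tau_pos * tau_vel)])


def ouf_transition(dt, sigma2, tau_pos, tau_vel):
    """Exact discrete transition (Phi, Q) of the OUF state over a step dt."""
    l1, l2 = -1.0 / tau_pos, -1.0 / tau_vel
    e1, e2 = np.exp(l1 * dt), np.exp(l2 * dt)
    den = l2 - l1
    phi = (
        np.array(
            [[l2 * e1 - l1 * e2, e2 - e1], [l1 * l2 * (e1 - e2), l2 * e2 - l1 * e1]]
        )
        / den
    )
    pinf = ouf_stationary_cov(sigma2, tau_pos, tau_vel)
    q = pinf - phi @ pinf @ phi.T
    return phi, 0.5 * (q + q.T)


def _kalman_ou(z, phi, r, sigma2):
    """O(n) log-likelihood of centered observations under OU + error.

    1-D state per axis; both axes share the variance recursion.
    """
    n = z.shape[0]
    mx = 0.0
    my = 0.0
    p = sigma2
    ll = 0.0
    for k in range(n):
        s = p + r[k]
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf
        vx = z[k, 0] - mx
        vy = z[k, 1] - my
        ll -= 0.5 * (2.0 * (_LOG2PI + np.log(s)) + (vx * vx + vy * vy) / s)
        gain = p / s
        mfx = mx + gain * vx
        mfy = my + gain * vy
        pf = (1.0 - gain) * p
        if k < n - 1:
            f = phi[k]
            mx = f * mfx
            my = f * mfy
            p = f * f * pf + sigma2 * (1.0 - f * f)
    return ll


def _kalman_ouf(z, r, p00, p11, phis, qs):
    """O(n) log-likelihood under OUF + error.

    2-D (position, velocity) state per axis; ``phis``/``qs`` hold the
    per-step exact transition matrix and innovation covariance; the 2x2
    algebra is unrolled. Axes share the covariance recursion.
    """
    n = z.shape[0]
    # state means: (pos, vel) for x and y axes
    m0x = 0.0
    m1x = 0.0
    m0y = 0.0
    m1y = 0.0
    a = p00  # P[0,0]
    b = 0.0  # P[0,1] = P[1,0]
    c = p11  # P[1,1]
    ll = 0.0
    for k in range(n):
        s = a + r[k]
        if s <= 0.0 or not np.isfinite(s):
            return -np.inf
        vx = z[k, 0] - m0x
        vy = z[k, 1] - m0y
        ll -= 0.5 * (2.0 * (_LOG2PI + np.log(s)) + (vx * vx + vy * vy) / s)
        g0 = a / s
        g1 = b / s
        f0x = m0x + g0 * vx
        f1x = m1x + g1 * vx
        f0y = m0y + g0 * vy
        f1y = m1y + g1 * vy
        fa = a - g0 * a
        fb = b - g0 * b
        fc = c - g1 * b
        if k < n - 1:
            t00 = phis[k, 0, 0]
            t01 = phis[k, 0, 1]
            t10 = phis[k, 1, 0]
            t11 = phis[k, 1, 1]
            m0x = t00 * f0x + t01 * f1x
            m1x = t10 * f0x + t11 * f1x
            m0y = t00 * f0y + t01 * f1y
            m1y = t10 * f0y + t11 * f1y
            # P <- Phi Pf Phi^T + Q with Pf = [[fa, fb], [fb, fc]]
            a = t00 * (t00 * fa + t01 * fb) + t01 * (t00 * fb + t01 * fc) + qs[k, 0, 0]
            b = t10 * (t00 * fa + t01 * fb) + t11 * (t00 * fb + t01 * fc) + qs[k, 0, 1]
            c = t10 * (t10 * fa + t11 * fb) + t11 * (t10 * fb + t11 * fc) + qs[k, 1, 1]
    return ll


try:  # optional JIT; the pure-Python kernels are the reference behavior
    from numba import njit as _njit

    _kalman_ou = _njit(cache=True, fastmath=False)(_kalman_ou)
    _kalman_ouf = _njit(cache=True, fastmath=False)(_kalman_ouf)
except ImportError:  # pragma: no cover
    pass


def _error_variance(track: Track, uere) -> np.ndarray:
    """Per-axis, per-fix measurement-error variance (m²)."""
    n = len(track)
    if uere is None or uere == 0:
        return np.zeros(n)
    hdop = track.hdop if track.hdop is not None else np.ones(n)
    hdop = np.nan_to_num(hdop, nan=1.0)
    return (uere * hdop) ** 2 / 2.0


def ctmm_loglik(
    track: Track,
    model: str,
    mu=None,
    sigma2=None,
    tau_pos=None,
    tau_vel=None,
    uere=None,
) -> float:
    """Exact Gaussian log-likelihood of the observed positions.

    Evaluated in O(n) by a Kalman recursion (1-D state per axis for ou, 2-D
    for ouf); the two axes are independent and share parameters (isotropy).
    ``mu`` defaults to the sample mean. Returns ``-inf`` for non-finite or
    degenerate parameter values so optimizers can treat them as infeasible.
    """
    n = len(track)
    if n < 2 and model != "iid":
        raise DomainError(f"{model} likelihood needs at least 2 fixes")
    if model == "ouf" and n < 4:
        raise DomainError("ouf likelihood needs at least 4 fixes")
    xy = track.xy
    mu = xy.mean(axis=0) if mu is None else np.asarray(mu, dtype=float)
    r = _error_variance(track, uere)
    if sigma2 is None or not np.isfinite(sigma2) or sigma2 <= 0:
        return -np.inf
    z = xy - mu  # (n, 2) centered observations

    if model == "iid":
        s = sigma2 + r  # (n,)
        return float(-0.5 * np.sum(_LOG2PI + np.log(s)[:, None] + z**2 / s[:, None]))

    dt = np.diff(track.seconds())
    if model == "ou":
        if tau_pos is None or tau_pos <= 0 or not np.isfinite(tau_pos):
            return -np.inf
        phi = np.exp(-dt / tau_pos)
        ll = _kalman_ou(z, phi, r, float(sigma2))
        return float(ll) if np.isfinite(ll) else -np.inf

    if model == "ouf":
        if (
            tau_pos is None
            or tau_vel is None
            or tau_pos <= 0
            or tau_vel <= 0
            or tau_vel >= tau_pos
        ):
            return -np.inf
        steps, inv = np.unique(dt, return_inverse=True)
        phis_u = np.empty((len(steps), 2, 2))
        qs_u = np.empty((len(steps), 2, 2))
        for i, step in enumerate(steps):
            phis_u[i], qs_u[i] = ouf_transition(step, sigma2, tau_pos, tau_vel)
        pinf = ouf_stationary_cov(sigma2, tau_pos, tau_vel)
        ll = _kalman_ouf(z, r, pinf[0, 0], pinf[1, 1], phis_u[inv], qs_u[inv])
        return float(ll) if np.isfinite(ll) else -np.inf

    raise DomainError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# empirical variogram (initialization aid)


def empirical_variogram(track: Track, n_lags: int = 15, max_pairs: int = 2_000_000) -> pd.DataFrame:
    """Semivariance of displacement per lag bin, averaged over axes.

    gamma(lag) estimates sigma2 * (1 - rho(lag)) for a stationary process;
    the sill approximates sigma2 and the lag at ~63% of the sill the
    positional timescale. Bins span the observed lag range.
    """
    n = len(track)
    if n < 2:
        raise DomainError("variogram needs at least 2 fixes")
    t = track.seconds()
    xy = track.xy
    i, j = np.triu_indices(n, k=1)
    if len(i) > max_pairs:
        rng = np.random.default_rng(0)
        sel = rng.choice(len(i), size=max_pairs, replace=False)
        i, j = i[sel], j[sel]
    lags = t[j] - t[i]
    # per-axis squared displacement / 2, averaged over the two axes
    gamma_pair = ((xy[j] - xy[i]) ** 2).sum(axis=1) / 4.0
    if n == 2:
        return pd.DataFrame({"lag": lags, "gamma": gamma_pair, "n_pairs": [1]})
    edges = np.linspace(0.0, lags.max(), n_lags + 1)
    idx = np.clip(np.digitize(lags, edges[1:-1]), 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=gamma_pair, minlength=n_lags)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return pd.DataFrame(
        {"lag": centers[keep], "gamma": sums[keep] / counts[keep], "n_pairs": counts[keep]}
    )


def _variogram_init(track: Track):
    """(sigma2, tau_pos) starting values from the empirical variogram."""
    vg = empirical_variogram(track, n_lags=min(15, max(2, len(track) // 3)))
    gamma = vg["gamma"].to_numpy()
    lag = vg["lag"].to_numpy()
    sill = float(np.mean(gamma[len(gamma) // 2 :]))
    if not np.isfinite(sill) or sill <= 0:
        sill = float(np.var(track.xy, axis=0).mean()) or 1.0
    above = np.flatnonzero(gamma >= 0.6321 * sill)
    if len(above):
        tau = float(max(lag[above[0]], 1e-6))
    else:
        tau = float(lag[-1] / 3.0) or 1.0
    return sill, tau


# ---------------------------------------------------------------------------
# fitting


def _dof_area(model, sigma2, tau_pos, tau_vel, n, dt_med) -> float:
    """Effective sample size for area estimation.

    Standard autocorrelation-inflation formula
    n / (1 + 2 sum_{k<n} (1 - k/n) rho(k dt)), with rho the fitted
    normalized position ACF at multiples of the median sampling interval,
    truncated once rho < 1e-3.
    """
    if model == "iid" or n <= 1:
        return float(n)
    k = np.arange(1, n)
    rho = position_acf(model, k * dt_med, sigma2=sigma2, tau_pos=tau_pos, tau_vel=tau_vel) / sigma2
    cut = np.flatnonzero(rho < 1e-3)
    if len(cut):
        rho = rho[: cut[0]]
        k = k[: cut[0]]
    denom = 1.0 + 2.0 * np.sum((1.0 - k / n) * rho)
    return float(min(n, max(n / denom, 1e-9)))


def _fit_single(track: Track, model: str, uere, sigma2_0, tau_0) -> tuple[dict, float, bool]:
    """Maximize the likelihood of one model; returns (params, loglik, converged)."""

    if model == "iid":

        def neg(theta):
            return -ctmm_loglik(track, "iid", sigma2=np.exp(theta[0]), uere=uere)

        starts = [[np.log(sigma2_0)]]
    elif model == "ou":

        def neg(theta):
            return -ctmm_loglik(
                track, "ou", sigma2=np.exp(theta[0]), tau_pos=np.exp(theta[1]), uere=uere
            )

        starts = [
            [np.log(sigma2_0), np.log(tau_0)],
            [np.log(sigma2_0), np.log(tau_0 * 0.1)],
            [np.log(sigma2_0), np.log(tau_0 * 10.0)],
        ]
    else:  # ouf; tau_vel = tau_pos * sigmoid(g) keeps tau_vel < tau_pos

        def neg(theta):
            tp = np.exp(theta[1])
            tv = tp / (1.0 + np.exp(-theta[2]))
            return -ctmm_loglik(
                track, "ouf", sigma2=np.exp(theta[0]), tau_pos=tp, tau_vel=tv, uere=uere
            )

        g0 = np.log(0.1 / 0.9)  # tau_vel init = tau_pos / 10
        starts = [
            [np.log(sigma2_0), np.log(tau_0), g0],
            [np.log(sigma2_0), np.log(tau_0 * 0.1), g0],
            [np.log(sigma2_0), np.log(tau_0 * 10.0), g0],
        ]

    best = None
    converged = False
    for x0 in starts:
        res = minimize(
            neg,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError(f"{model}: likelihood not finite at any start", best=best)

    theta = best.x
    params = {"sigma2": float(np.exp(theta[0])), "tau_pos": None, "tau_vel": None}
    if model in ("ou", "ouf"):
        params["tau_pos"] = float(np.exp(theta[1]))
    if model == "ouf":
        params["tau_vel"] = params["tau_pos"] / (1.0 + float(np.exp(-theta[2])))
    return params, -float(best.fun), converged


def fit_ctmm(track: Track, model: str = "auto", uere=None) -> CTMMFit:
    """Fit a continuous-time movement model by maximum likelihood.

    Parameters
    ----------
    track : Track
        Relocations (regular or irregular sampling).
    model : {"iid", "ou", "ouf", "auto"}
        "auto" fits all three candidates and returns the one with the lowest
        AICc (small-sample-corrected AIC).
    uere : float, optional
        Fixed GPS-error scale in meters of 2-D RMS error per unit HDOP
        (per-fix HDOP taken from the track, 1 where absent). None disables
        the error model.

    Notes
    -----
    The stationary mean is estimated by the sample mean; positive parameters
    are optimized on the log scale (Nelder-Mead, multi-start: variogram
    initialization and timescales x0.1 / x10).
    """
    n = len(track)
    if model == "auto" and n < 5:
        raise DomainError("automatic model selection needs at least 5 fixes")
    candidates = ["iid", "ou", "ouf"] if model == "auto" else [model]
    candidates = [m for m in candidates if _K_PARAMS[m] + 1 < n]

    sigma2_0, tau_0 = (
        _variogram_init(track) if n >= 10 else (float(np.var(track.xy, axis=0).mean()) or 1.0, 1.0)
    )
    dt = np.diff(track.seconds())
    dt_med = float(np.median(dt)) if len(dt) else 1.0

    fits = []
    failure = None
    for m in candidates:
        try:
            params, ll, conv = _fit_single(track, m, uere, sigma2_0, tau_0)
        except (ConvergenceError, DomainError) as exc:
            failure = exc
            continue
        k = _K_PARAMS[m]
        aicc = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        fits.append(
            CTMMFit(
                model=m,
                mu=track.xy.mean(axis=0),
                sigma2=params["sigma2"],
                tau_pos=params["tau_pos"],
                tau_vel=params["tau_vel"],
                uere=uere,
                loglik=ll,
                aicc=float(aicc),
                dof_area=_dof_area(
                    m, params["sigma2"], params["tau_pos"], params["tau_vel"], n, dt_med
                ),
                n=n,
                converged=conv,
            )
        )
    if not fits:
        raise ConvergenceError(f"no candidate model could be fitted: {failure}")
    return min(fits, key=lambda f: f.aicc)
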