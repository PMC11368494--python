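"""Hidden Markov model segmentation of migration trajectories.

States emit gamma-distributed step lengths and von Mises-distributed turning
angles; device speed (plus a 0.1 km/h offset against zero-inflation) may
enter the transition probabilities through a multinomial logit, following the
moveHMM convention. Fitting is direct numerical maximization of the forward
log-likelihood on working-scale (unconstrained) parameters, with multiple
restarts from quantile-spread initializations.

Decoded states are relabeled into a single "migratory movement" role — the
state with the largest mean step length and lowest mean turning angle — and
all remaining states become "stopover". Consecutive migratory steps form
candidate flights, which must clear a minimum cumulative length (by default
twice the fitted migratory step mean) to remain flights; this guards against
single missing fixes masquerading as migration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import gammaln, i0
from scipy.stats import gamma as gamma_dist
from scipy.stats import kstest

from .io_formats import GPSTrack, RegionSet
from .projection import haversine_km, initial_bearing_rad

logger = logging.getLogger(__name__)

FLIGHT = "flight"
STOPOVER = "stopover"


class InsufficientDataError(ValueError):
    """Too few fixes/steps for the requested operation."""


class ConvergenceError(RuntimeError):
    """Likelihood maximization failed; carries the best value found."""

    def __init__(self, message, best_loglik=None):
        super().__init__(message)
        self.best_loglik = best_loglik


# --------------------------------------------------------------------------
# step series
# --------------------------------------------------------------------------

@dataclass
class StepSeries:
    """Per-step lengths (km), turning angles (rad), intervals and covariate.

    ``angles[0]`` is NaN (undefined for the first step), as is any angle
    following a zero-length step. ``dlat`` is the per-step latitude change,
    kept so segment-level net displacement direction can be computed without
    the parent track. The covariate is device speed + 0.1 km/h, falling back
    to step length / interval + 0.1 where the device reported nothing.
    """

    lengths: np.ndarray
    angles: np.ndarray
    intervals_min: np.ndarray
    covariate: np.ndarray
    dlat: np.ndarray
    start_times: pd.DatetimeIndex = None
    individual_id: str = ""

    def __len__(self) -> int:
        return len(self.lengths)


def build_steps(track: GPSTrack, speed_offset: float = 0.1) -> StepSeries:
    """Step lengths, signed turning angles and the speed covariate for a track."""
    n = len(track)
    if n < 3:
        raise InsufficientDataError(f"track {track.individual_id}: need >= 3 fixes, got {n}")
    lengths = haversine_km(track.lon[:-1], track.lat[:-1], track.lon[1:], track.lat[1:])
    bearings = initial_bearing_rad(track.lon[:-1], track.lat[:-1],
                                   track.lon[1:], track.lat[1:])
    angles = np.full(n - 1, np.nan)
    turn = bearings[1:] - bearings[:-1]
    turn = (turn + np.pi) % (2.0 * np.pi) - np.pi
    # convention: positive = left (counter-clockwise); bearing decreases on a left turn
    angles[1:] = -turn
    angles[1:][(lengths[1:] == 0) | (lengths[:-1] == 0)] = np.nan
    intervals = np.diff(track.timestamps.asi8) / 60e9
    speed = track.speed[:-1].copy()
    fallback = lengths / (intervals / 60.0)
    missing = ~np.isfinite(speed)
    speed[missing] = fallback[missing]
    return StepSeries(lengths, angles, intervals, speed + speed_offset,
                      np.diff(track.lat), track.timestamps[:-1], track.individual_id)


# --------------------------------------------------------------------------
# model container
# --------------------------------------------------------------------------

@dataclass
class HMMModel:
    """Fitted step-and-turn HMM.

    ``tpm_intercept``/``tpm_slope`` hold multinomial-logit coefficients for
    the off-diagonal transition entries (slope all-zero when the covariate is
    disabled). The initial distribution is the stationary distribution of the
    transition matrix at the covariate mean.
    """

    n_states: int
    step_mean: np.ndarray
    step_sd: np.ndarray
    zero_mass: np.ndarray
    angle_mean: np.ndarray
    angle_conc: np.ndarray
    tpm_intercept: np.ndarray   # (N, N) with NaN diagonal
    tpm_slope: np.ndarray       # (N, N) with NaN diagonal
    initial: np.ndarray
    loglik: float = np.nan
    n_parameters: int = 0
    use_covariate: bool = False
    covariate_mean: float = 0.0

    def transition_matrix(self, cov_value: float | None = None) -> np.ndarray:
        z = self.covariate_mean if cov_value is None else cov_value
        return _tpm_from_logits(self.tpm_intercept, self.tpm_slope, np.array([z]))[0]

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        arrays = {"step_mean", "step_sd", "zero_mass", "angle_mean", "angle_conc",
                  "tpm_intercept", "tpm_slope", "initial"}
        return cls(**{k: (np.asarray(v, dtype=float) if k in arrays else v)
                      for k, v in d.items()})


def _tpm_from_logits(intercept: np.ndarray, slope: np.ndarray,
                     cov: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrices (T, N, N) from multinomial logits.

    Off-diagonal entry (i, j) has logit b0_ij + b1_ij * z; the diagonal is the
    reference category.
    """
    n = intercept.shape[0]
    T = len(cov)
    eta = intercept[None, :, :] + slope[None, :, :] * cov[:, None, None]
    eta = np.where(np.isnan(eta), 0.0, eta)  # diagonal reference = logit 0
    eta = eta - eta.max(axis=2, keepdims=True)
    ex = np.exp(eta)
    return ex / ex.sum(axis=2, keepdims=True)


def _stationary(tpm: np.ndarray) -> np.ndarray:
    n = tpm.shape[0]
    a = np.vstack([(np.eye(n) - tpm).T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    delta, *_ = np.linalg.lstsq(a, b, rcond=None)
    delta = np.clip(delta, 1e-12, None)
    return delta / delta.sum()


# --------------------------------------------------------------------------
# emission densities (vectorized, log scale)
# --------------------------------------------------------------------------

def _log_gamma_pdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """log gamma pdf at x (T,) for each state (N,), parameterized by mean/sd."""
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    xx = x[:, None]
    with np.errstate(divide="ignore"):
        lp = ((shape - 1.0) * np.log(xx) - xx / scale
              - shape * np.log(scale) - gammaln(shape))
    return lp


def _log_vonmises_pdf(a: np.ndarray, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    return kappa * np.cos(a[:, None] - mu) - np.log(2.0 * np.pi * i0(kappa))


def _log_emissions(steps: StepSeries, step_mean, step_sd, zero_mass,
                   angle_mean, angle_conc) -> np.ndarray:
    """(T, N) log emission probabilities; NaN angles contribute nothing."""
    x = steps.lengths
    T = len(x)
    is_zero = x == 0
    lp = np.zeros((T, len(step_mean)))
    pos = ~is_zero
    if pos.any():
        lp[pos] = (_log_gamma_pdf(x[pos], step_mean, step_sd)
                   + np.log1p(-zero_mass)[None, :])
    if is_zero.any():
        with np.errstate(divide="ignore"):
            lp[is_zero] = np.log(zero_mass)[None, :]
    good = np.isfinite(steps.angles)
    if good.any():
        lp[good] += _log_vonmises_pdf(steps.angles[good], angle_mean, angle_conc)
    return lp


# --------------------------------------------------------------------------
# forward / viterbi cores (numba)
# --------------------------------------------------------------------------

@njit(cache=True)
def _forward_core(log_emis, tpms, initial):
    """Scaled forward algorithm; returns total log-likelihood."""
    T, N = log_emis.shape
    alpha = np.empty(N)
    m = log_emis[0].max()
    for j in range(N):
        alpha[j] = initial[j] * np.exp(log_emis[0, j] - m)
    c = alpha.sum()
    ll = np.log(c) + m
    alpha /= c
    for t in range(1, T):
        m = log_emis[t].max()
        nxt = np.zeros(N)
        for j in range(N):
            s = 0.0
            for i in range(N):
                s += alpha[i] * tpms[t, i, j]
            nxt[j] = s * np.exp(log_emis[t, j] - m)
        c = nxt.sum()
        if c <= 0.0:
            return -np.inf
        ll += np.log(c) + m
        alpha = nxt / c
    return ll


@njit(cache=True)
def _forward_filter_core(log_emis, tpms, initial):
    """Normalized forward probabilities (T, N) and one-step predictions."""
    T, N = log_emis.shape
    filt = np.empty((T, N))
    pred = np.empty((T, N))
    alpha = initial.copy()
    for t in range(T):
        if t > 0:
            nxt = np.zeros(N)
            for j in range(N):
                for i in range(N):
                    nxt[j] += alpha[i] * tpms[t, i, j]
            alpha = nxt
        pred[t] = alpha
        m = log_emis[t].max()
        w = alpha * np.exp(log_emis[t] - m)
        c = w.sum()
        if c <= 0.0:
            w = alpha.copy()
            c = w.sum()
        alpha = w / c
        filt[t] = alpha
    return filt, pred


@njit(cache=True)
def _log_i0(x):
    """log of the modified Bessel function I0 (Abramowitz & Stegun 9.8.1/2)."""
    t = x / 3.75
    if t < 1.0:
        t2 = t * t
        p = (1.0 + 3.5156229 * t2 + 3.0899424 * t2 ** 2 + 1.2067492 * t2 ** 3
             + 0.2659732 * t2 ** 4 + 0.0360768 * t2 ** 5 + 0.0045813 * t2 ** 6)
        return np.log(p)
    u = 1.0 / t
    p = (0.39894228 + 0.01328592 * u + 0.00225319 * u ** 2 - 0.00157565 * u ** 3
         + 0.00916281 * u ** 4 - 0.02057706 * u ** 5 + 0.02635537 * u ** 6
         - 0.01647633 * u ** 7 + 0.00392377 * u ** 8)
    return x - 0.5 * np.log(x) + np.log(p)


@njit(cache=True)
def _nll_jit(theta, n, with_zero, use_cov, lengths, angles, cov):
    """Negative forward log-likelihood, fully inlined for the optimizer.

    Mirrors the numpy path (`_neg_loglik`); kept in exact parameter-packing
    sync with `_pack`/`_unpack`.
    """
    T = len(lengths)
    k = 0
    step_mean = np.empty(n)
    step_sd = np.empty(n)
    for j in range(n):
        step_mean[j] = np.exp(theta[k + j])
        step_sd[j] = np.exp(theta[k + n + j])
    k += 2 * n
    zero_mass = np.zeros(n)
    if with_zero:
        for j in range(n):
            zero_mass[j] = 1.0 / (1.0 + np.exp(-theta[k + j]))
        k += n
    angle_mean = np.empty(n)
    angle_conc = np.empty(n)
    for j in range(n):
        angle_mean[j] = theta[k + j]
        angle_conc[j] = np.exp(theta[k + n + j])
    k += 2 * n
    b0 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                b0[i, j] = theta[k]
                k += 1
    b1 = np.zeros((n, n))
    if use_cov:
        for i in range(n):
            for j in range(n):
                if i != j:
                    b1[i, j] = theta[k]
                    k += 1

    # per-state emission constants
    shape = np.empty(n)
    scale = np.empty(n)
    lgam = np.empty(n)
    lnorm_vm = np.empty(n)
    for j in range(n):
        shape[j] = (step_mean[j] / step_sd[j]) ** 2
        scale[j] = step_sd[j] ** 2 / step_mean[j]
        if not np.isfinite(shape[j]) or shape[j] <= 0 or scale[j] <= 0:
            return 1e12
        lgam[j] = math.lgamma(shape[j])
        lnorm_vm[j] = np.log(2.0 * np.pi) + _log_i0(angle_conc[j])

    log_emis = np.empty((T, n))
    for t in range(T):
        x = lengths[t]
        a = angles[t]
        for j in range(n):
            if x == 0.0:
                le = np.log(zero_mass[j]) if zero_mass[j] > 0 else -1e30
            else:
                le = ((shape[j] - 1.0) * np.log(x) - x / scale[j]
                      - shape[j] * np.log(scale[j]) - lgam[j]
                      + np.log(1.0 - zero_mass[j]))
            if not np.isnan(a):
                le += angle_conc[j] * np.cos(a - angle_mean[j]) - lnorm_vm[j]
            log_emis[t, j] = le

    # transition matrix (constant unless the covariate is enabled)
    tpm0 = np.empty((n, n))
    for i in range(n):
        mx = 0.0
        for j in range(n):
            if b0[i, j] > mx:
                mx = b0[i, j]
        s = 0.0
        for j in range(n):
            tpm0[i, j] = np.exp((b0[i, j] if i != j else 0.0) - mx)
            s += tpm0[i, j]
        for j in range(n):
            tpm0[i, j] /= s

    # initial = stationary distribution of tpm0 by power iteration (robust
    # to the near-singular matrices visited during optimization)
    initial = np.full(n, 1.0 / n)
    nxt0 = np.empty(n)
    for _ in range(100):
        for j in range(n):
            s = 0.0
            for i in range(n):
                s += initial[i] * tpm0[i, j]
            nxt0[j] = s
        diff = 0.0
        for j in range(n):
            diff += abs(nxt0[j] - initial[j])
            initial[j] = nxt0[j]
        if diff < 1e-12:
            break
    s = 0.0
    for j in range(n):
        if initial[j] < 1e-12:
            initial[j] = 1e-12
        s += initial[j]
    initial /= s

    # scaled forward recursion
    alpha = np.empty(n)
    m = log_emis[0].max()
    c = 0.0
    for j in range(n):
        alpha[j] = initial[j] * np.exp(log_emis[0, j] - m)
        c += alpha[j]
    if c <= 0.0:
        return 1e12
    ll = np.log(c) + m
    for j in range(n):
        alpha[j] /= c
    tpm = np.empty((n, n))
    for t in range(1, T):
        if use_cov:
            for i in range(n):
                mx = 0.0
                for j in range(n):
                    eta = b0[i, j] + b1[i, j] * cov[t] if i != j else 0.0
                    tpm[i, j] = eta
                    if eta > mx:
                        mx = eta
                s = 0.0
                for j in range(n):
                    tpm[i, j] = np.exp(tpm[i, j] - mx)
                    s += tpm[i, j]
                for j in range(n):
                    tpm[i, j] /= s
        m = log_emis[t].max()
        c = 0.0
        nxt = np.zeros(n)
        for j in range(n):
            sacc = 0.0
            for i in range(n):
                sacc += alpha[i] * (tpm[i, j] if use_cov else tpm0[i, j])
            nxt[j] = sacc * np.exp(log_emis[t, j] - m)
            c += nxt[j]
        if c <= 0.0 or not np.isfinite(c):
            return 1e12
        ll += np.log(c) + m
        for j in range(n):
            alpha[j] = nxt[j] / c
    if not np.isfinite(ll):
        return 1e12
    return -ll


@njit(cache=True)
def _viterbi_core(log_emis, log_tpms, log_initial):
    T, N = log_emis.shape
    delta = log_initial + log_emis[0]
    back = np.zeros((T, N), dtype=np.int64)
    for t in range(1, T):
        nxt = np.empty(N)
        for j in range(N):
            best = -np.inf
            arg = 0
            for i in range(N):
                v = delta[i] + log_tpms[t, i, j]
                if v > best:  # strict: ties keep the lower state index
                    best = v
                    arg = i
            nxt[j] = best + log_emis[t, j]
            back[t, j] = arg
        delta = nxt
    path = np.zeros(T, dtype=np.int64)
    best = -np.inf
    for j in range(N):
        if delta[j] > best:
            best = delta[j]
            path[T - 1] = j
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def _pack(step_mean, step_sd, zero_logit, angle_mean, log_conc,
          intercept, slope, n, with_zero, use_covariate):
    parts = [np.log(step_mean), np.log(step_sd)]
    if with_zero:
        parts.append(zero_logit)
    parts += [angle_mean, log_conc]
    off = ~np.eye(n, dtype=bool)
    parts.append(intercept[off])
    if use_covariate:
        parts.append(slope[off])
    return np.concatenate(parts)


def _unpack(theta, n, with_zero, use_covariate):
    k = 0

    def take(m):
        nonlocal k
        out = theta[k:k + m]
        k += m
        return out

    step_mean = np.exp(take(n))
    step_sd = np.exp(take(n))
    if with_zero:
        zero_mass = 1.0 / (1.0 + np.exp(-take(n)))
    else:
        zero_mass = np.zeros(n)
    angle_mean = (take(n) + np.pi) % (2 * np.pi) - np.pi
    angle_conc = np.exp(take(n))
    off = ~np.eye(n, dtype=bool)
    intercept = np.full((n, n), np.nan)
    intercept[off] = take(n * (n - 1))
    slope = np.full((n, n), np.nan)
    if use_covariate:
        slope[off] = take(n * (n - 1))
    else:
        slope[off] = 0.0
    return step_mean, step_sd, zero_mass, angle_mean, angle_conc, intercept, slope


def _neg_loglik(theta, steps, n, with_zero, use_covariate, cov_centered):
    sm, ss, zm, am, ac, b0, b1 = _unpack(theta, n, with_zero, use_covariate)
    if not (np.all(np.isfinite(sm)) and np.all(np.isfinite(ss))):
        return 1e12
    log_emis = _log_emissions(steps, sm, ss, zm, am, ac)
    tpms = _tpm_from_logits(b0, b1, cov_centered)
    initial = _stationary(_tpm_from_logits(b0, b1, np.zeros(1))[0])
    ll = _forward_core(log_emis, tpms, initial)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _initial_params(steps: StepSeries, n: int, rng: np.random.Generator,
                    jitter: bool) -> tuple[np.ndarray, ...]:
    """Quantile-spread starting values over the positive step lengths."""
    pos = steps.lengths[steps.lengths > 0]
    if len(pos) == 0:
        pos = np.array([1.0])
    qs = np.linspace(0.15, 0.97, n)
    means = np.quantile(pos, qs)
    means = np.maximum(means, 1e-4)
    if jitter:
        means = means * np.exp(rng.normal(0.0, 0.4, n))
        means.sort()
    sds = means.copy()
    zero_logit = np.full(n, -3.0)
    angle_mean = np.zeros(n)
    log_conc = np.log(np.full(n, 1.0))
    if jitter:
        log_conc += rng.normal(0.0, 0.5, n)
    intercept = np.full((n, n), np.log(0.05 / (1 - 0.05 * (n - 1))))
    np.fill_diagonal(intercept, np.nan)
    slope = np.zeros((n, n))
    np.fill_diagonal(slope, np.nan)
    return means, sds, zero_logit, angle_mean, log_conc, intercept, slope


def fit_hmm(steps: StepSeries, n_states: int, use_covariate: bool = False,
            seed: int = 0, n_restarts: int = 10, maxiter: int = 400,
            start_from: HMMModel | None = None) -> HMMModel:
    """Maximum-likelihood fit by direct numerical maximization.

    Deterministic given ``seed``. ``start_from`` seeds the first restart from
    an existing (e.g. pooled) fit, the moveHMM-style workflow for
    per-individual refits. Zero step lengths are handled by a per-state
    zero-mass parameter, activated only when zeros are present.
    """
    if not 1 <= n_states <= 6:
        raise ValueError("n_states must be in 1..6")
    T = len(steps)
    if T < 200:
        logger.warning("fit_hmm: only %d steps; >= 200 recommended", T)
    if T < 2 * n_states:
        raise InsufficientDataError(f"{T} steps cannot support {n_states} states")
    with_zero = bool((steps.lengths == 0).any())
    cov_mean = float(np.mean(steps.covariate))
    cov_centered = steps.covariate - cov_mean if use_covariate else np.zeros(T)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0 and start_from is not None:
            m = start_from
            off = ~np.eye(n_states, dtype=bool)
            with np.errstate(divide="ignore"):
                zl = np.log(np.clip(m.zero_mass, 1e-8, 1 - 1e-8)
                            / (1 - np.clip(m.zero_mass, 1e-8, 1 - 1e-8)))
            theta0 = _pack(m.step_mean, m.step_sd, zl, m.angle_mean,
                           np.log(np.clip(m.angle_conc, 1e-6, None)),
                           m.tpm_intercept, m.tpm_slope, n_states,
                           with_zero, use_covariate)
        else:
            init = _initial_params(steps, n_states, rng, jitter=(r > 0))
            theta0 = _pack(*init, n_states, with_zero, use_covariate)
        res = minimize(_nll_jit, theta0,
                       args=(n_states, with_zero, use_covariate, steps.lengths,
                             steps.angles, cov_centered),
                       method="L-BFGS-B", options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError("HMM fit did not converge",
                               best_loglik=None if best is None else -best.fun)

    sm, ss, zm, am, ac, b0, b1 = _unpack(best.x, n_states, with_zero, use_covariate)
    order = np.argsort(sm)  # canonical state order: ascending step mean
    off = ~np.eye(n_states, dtype=bool)
    b0o = b0[np.ix_(order, order)]
    b1o = b1[np.ix_(order, order)]
    np.fill_diagonal(b0o, np.nan)
    np.fill_diagonal(b1o, np.nan)
    model = HMMModel(
        n_states=n_states, step_mean=sm[order], step_sd=ss[order],
        zero_mass=zm[order], angle_mean=am[order], angle_conc=ac[order],
        tpm_intercept=b0o, tpm_slope=b1o,
        initial=_stationary(_tpm_from_logits(b0o, b1o, np.zeros(1))[0]),
        loglik=float(-best.fun), n_parameters=len(best.x),
        use_covariate=use_covariate, covariate_mean=cov_mean)
    return model


def _model_inputs(model: HMMModel, steps: StepSeries):
    log_emis = _log_emissions(steps, model.step_mean, model.step_sd,
                              model.zero_mass, model.angle_mean, model.angle_conc)
    cov = (steps.covariate - model.covariate_mean
           if model.use_covariate else np.zeros(len(steps)))
    tpms = _tpm_from_logits(model.tpm_intercept, model.tpm_slope, cov)
    return log_emis, tpms


def viterbi(model: HMMModel, steps: StepSeries) -> np.ndarray:
    """Most probable joint state path (0-based); ties go to the lower index."""
    log_emis, tpms = _model_inputs(model, steps)
    with np.errstate(divide="ignore"):
        return _viterbi_core(log_emis, np.log(tpms), np.log(model.initial))


def forward_loglik(model: HMMModel, steps: StepSeries) -> float:
    log_emis, tpms = _model_inputs(model, steps)
    return float(_forward_core(log_emis, tpms, model.initial))


def aic(model: HMMModel) -> float:
    return -2.0 * model.loglik + 2.0 * model.n_parameters


def pseudo_residuals(model: HMMModel, steps: StepSeries) -> np.ndarray:
    """Uniform-scale forecast PIT residuals of the step lengths.

    Under the true model these are approximately iid Uniform(0, 1).
    """
    log_emis, tpms = _model_inputs(model, steps)
    _, pred = _forward_filter_core(log_emis, tpms, model.initial)
    # weights: P(S_t = j | x_{1:t-1}) must include the angle contribution of
    # past steps only, which _forward_filter_core already handles.
    shape = (model.step_mean / model.step_sd) ** 2
    scale = model.step_sd ** 2 / model.step_mean
    cdf = gamma_dist.cdf(steps.lengths[:, None], shape[None, :],
                         scale=scale[None, :])
    cdf = model.zero_mass[None, :] + (1 - model.zero_mass[None, :]) * cdf
    w = pred / pred.sum(axis=1, keepdims=True)
    return (w * cdf).sum(axis=1)


def ks_uniform_p(residuals: np.ndarray) -> float:
    """Kolmogorov–Smirnov p-value against Uniform(0,1)."""
    return float(kstest(residuals, "uniform").pvalue)


# --------------------------------------------------------------------------
# labeling and segmentation
# --------------------------------------------------------------------------

def label_states(model: HMMModel, tie_tol: float = 0.10) -> dict[int, str]:
    """Map each state index to 'flight' (migratory) or 'stopover'.

    Migratory = largest gamma step mean; if the top two means are within
    ``tie_tol`` (relative), the state whose angle distribution concentrates
    harder at zero wins.
    """
    means = model.step_mean
    order = np.argsort(means)[::-1]
    top, second = order[0], (order[1] if len(order) > 1 else order[0])
    migratory = int(top)
    if len(order) > 1 and (means[top] - means[second]) / means[top] < tie_tol:
        conc_at_zero = model.angle_conc * np.cos(model.angle_mean)
        migratory = int(top if conc_at_zero[top] >= conc_at_zero[second] else second)
    return {i: (FLIGHT if i == migratory else STOPOVER) for i in range(model.n_states)}


@dataclass
class Segment:
    role: str
    start: int           # first step index
    end: int             # last step index, inclusive
    length_km: float
    dlat_deg: float

    @property
    def n_steps(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentedTrack:
    """Per-step decoded states plus merged flight/stopover segments."""

    individual_id: str
    states: np.ndarray
    roles: np.ndarray           # per-step 'flight'/'stopover' after merging
    segments: list[Segment]
    role_map: dict[int, str]
    flight_min_km: float
    steps: StepSeries = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        seg_id = np.empty(len(self.states), dtype=int)
        cum = np.empty(len(self.states))
        for k, seg in enumerate(self.segments):
            seg_id[seg.start:seg.end + 1] = k
            cum[seg.start:seg.end + 1] = np.cumsum(
                self.steps.lengths[seg.start:seg.end + 1])
        return pd.DataFrame({
            "step": np.arange(len(self.states)),
            "state": self.states,
            "role": self.roles,
            "segment_id": seg_id,
            "step_km": self.steps.lengths,
            "segment_cum_km": cum,
        })

    @property
    def flights(self) -> list[Segment]:
        return [s for s in self.segments if s.role == FLIGHT]

    @property
    def stopovers(self) -> list[Segment]:
        return [s for s in self.segments if s.role == STOPOVER]


def merge_segments(states: np.ndarray, steps: StepSeries,
                   flight_min_km: float, role_map: dict[int, str],
                   per_step_threshold: bool = False) -> SegmentedTrack:
    """Merge decoded states into alternating flight/stopover segments.

    Candidate flights are maximal runs of migratory-state steps; a candidate
    whose cumulative length falls short of ``flight_min_km`` is reclassified
    as stopover and absorbed into its neighbors. With ``per_step_threshold``
    the rule applies to individual steps instead (sensitivity variant).
    """
    states = np.asarray(states)
    T = len(states)
    is_mig = np.array([role_map[int(s)] == FLIGHT for s in states])
    roles = np.where(is_mig, FLIGHT, STOPOVER).astype(object)
    if per_step_threshold:
        roles[is_mig & (steps.lengths < flight_min_km)] = STOPOVER
    else:
        t = 0
        while t < T:
            if is_mig[t]:
                e = t
                while e + 1 < T and is_mig[e + 1]:
                    e += 1
                if steps.lengths[t:e + 1].sum() < flight_min_km:
                    roles[t:e + 1] = STOPOVER
                t = e + 1
            else:
                t += 1
    segments: list[Segment] = []
    t = 0
    while t < T:
        e = t
        while e + 1 < T and roles[e + 1] == roles[t]:
            e += 1
        segments.append(Segment(str(roles[t]), t, e,
                                float(steps.lengths[t:e + 1].sum()),
                                float(steps.dlat[t:e + 1].sum())))
        t = e + 1
    return SegmentedTrack(steps.individual_id, states, roles, segments,
                          role_map, flight_min_km, steps)


def segment_track(steps: StepSeries, model: HMMModel,
                  flight_min_km: float | None = None) -> SegmentedTrack:
    """Decode, label, and merge in one call.

    The default flight threshold is twice the fitted migratory step mean —
    e.g. a fitted mean of 32.3 km/step gives the 64.6 km rule.
    """
    role_map = label_states(model)
    migratory = next(i for i, r in role_map.items() if r == FLIGHT)
    if flight_min_km is None:
        flight_min_km = 2.0 * float(model.step_mean[migratory])
    states = viterbi(model, steps)
    return merge_segments(states, steps, flight_min_km, role_map)


def count_movements(seg: SegmentedTrack) -> tuple[int, int]:
    """(n_stopovers, n_reverse).

    Stopovers are stopover segments between migratory flights: the final
    stopover (pre-nesting settlement near the breeding area) is excluded, as
    is a leading stopover before the first flight (pre-migration winter
    residence, present because the analysis window opens 7 days before
    onset). Reverse migratory movements are flight segments with net latitude
    decrease.
    """
    n_stop = sum(1 for k, s in enumerate(seg.segments)
                 if s.role == STOPOVER and 0 < k < len(seg.segments) - 1)
    if not seg.flights:
        n_stop = max(len(seg.stopovers) - 1, 0)
    n_reverse = sum(1 for f in seg.flights if f.dlat_deg < 0)
    return n_stop, n_reverse


# --------------------------------------------------------------------------
# migration characteristics
# --------------------------------------------------------------------------

@dataclass
class MigrationSummary:
    individual_id: str
    total_distance_km: float
    duration_days: float
    n_stopovers: int
    n_reverse: int
    arrival_ordinal: int
    arrival_time: pd.Timestamp
    prop_high_use: float | None = None
    winter_region: str | None = None


def summarize_migration(seg: SegmentedTrack, track: GPSTrack, onset_index: int,
                        high_use_mask=None, winter_regions: RegionSet | None = None,
                        flight_only_distance: bool = False) -> MigrationSummary:
    """Per-individual migration characteristics from a segmented track.

    Distance sums step lengths from onset through the end of the final flight
    (all steps by default; ``flight_only_distance`` restricts to flight
    segments). Duration runs from onset to final-flight end. ``prop_high_use``
    is the fraction of migration-period fixes inside the high-use (50%)
    isopleth, reported as None when no mask is supplied.
    """
    flights = seg.flights
    if not flights:
        raise InsufficientDataError(
            f"track {seg.individual_id}: no migratory flights to summarize")
    last = flights[-1]
    end_fix = last.end + 1                       # step i runs fix i -> i+1
    onset_time = track.timestamps[onset_index]
    arrival_time = track.timestamps[end_fix]
    if flight_only_distance:
        dist = sum(f.length_km for f in flights)
    else:
        dist = float(seg.steps.lengths[onset_index:last.end + 1].sum())
    duration = (arrival_time - onset_time).total_seconds() / 86400.0
    n_stop, n_rev = count_movements(seg)

    prop = None
    if high_use_mask is not None:
        lon = track.lon[onset_index:end_fix + 1]
        lat = track.lat[onset_index:end_fix + 1]
        inside = high_use_mask.contains_lonlat(lon, lat)
        prop = float(np.mean(inside))

    region = None
    if winter_regions is not None:
        i = onset_index - 1 if onset_index > 0 else 0
        region = winter_regions.locate(track.lon[i], track.lat[i], default="Other")

    return MigrationSummary(
        individual_id=seg.individual_id, total_distance_km=dist,
        duration_days=duration, n_stopovers=n_stop, n_reverse=n_rev,
        arrival_ordinal=int(arrival_time.dayofyear), arrival_time=arrival_time,
        prop_high_use=prop, winter_region=region)


# --------------------------------------------------------------------------
# generative sampler (for recovery tests and calibration)
# --------------------------------------------------------------------------

def simulate_steps(model: HMMModel, n: int, seed: int = 0) -> tuple[StepSeries, np.ndarray]:
    """Draw a step series from the model's own generative process.

    Returns the series and the true state sequence; used for parameter- and
    state-recovery checks. Covariate effects are ignored (transition matrix
    taken at the covariate mean).
    """
    rng = np.random.default_rng(seed)
    tpm = model.transition_matrix()
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(1, n):
        states[t] = rng.choice(model.n_states, p=tpm[states[t - 1]])
    shape = (model.step_mean / model.step_sd) ** 2
    scale = model.step_sd ** 2 / model.step_mean
    lengths = rng.gamma(shape[states], scale[states])
    zeros = rng.random(n) < model.zero_mass[states]
    lengths[zeros] = 0.0
    angles = rng.vonmises(model.angle_mean[states], model.angle_conc[states])
    angles[0] = np.nan
    cov = lengths * 2.0 + 0.1
    steps = StepSeries(lengths, angles, np.full(n, 30.0), cov,
                       np.zeros(n), None, "sim")
    return steps, states
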