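"""Contrast information of stationary Gaussian processes.

For jointly Gaussian regimes the two conditionals p(A|b,c) and p(A|c) are
Gaussian, so contrast information is the closed-form KL divergence

    D(N(m1,S1) : N(m2,S2))
      = 1/2 [ (m2-m1)^T S2^{-1} (m2-m1) + tr(S2^{-1} S1)
              - ln(|S1|/|S2|) - n ]        (nats; converted to bits)

between the conditional given source-and-context and the conditional given
context alone.  A stationary process enters through its mean and
autocovariance gamma, which induce a Toeplitz covariance over any window of
time tags; a polynomial fit of gamma over lag magnitude extends the model
to continuous time.

Fitted autocovariances need not induce positive-definite windows; windows
are repaired by symmetrisation, escalating diagonal jitter (starting at
1e-10 * gamma(0), doubled at most 20 times), then eigenvalue clipping at
1e-12 * gamma(0) with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .measures import LOG2, _to_base

__all__ = [
    "GaussianJoint",
    "RegimePartition",
    "StationaryGPModel",
    "ContinuousAutocov",
    "condition_gaussian",
    "gaussian_kl",
    "gaussian_contrast",
    "estimate_stationary_gp",
    "fit_continuous_autocov",
    "gp_profile",
]


class IndefiniteCovarianceWarning(UserWarning):
    pass


def _repair_psd(sigma: np.ndarray, scale: float) -> np.ndarray:
    """Symmetrise, then jitter, then clip eigenvalues; raise if hopeless."""
    sigma = 0.5 * (sigma + sigma.T)
    jitter = 1e-10 * scale
    eye = np.eye(sigma.shape[0])
    for _ in range(21):
        try:
            cholesky(sigma, lower=True)
            return sigma
        except np.linalg.LinAlgError:
            pass
        sigma = sigma + jitter * eye
        jitter *= 2.0
    vals, vecs = np.linalg.eigh(sigma)
    floor = 1e-12 * scale
    if np.all(vals >= floor):
        return sigma
    warnings.warn(
        "covariance window indefinite after jitter; clipping eigenvalues",
        IndefiniteCovarianceWarning,
        stacklevel=3,
    )
    vals = np.clip(vals, floor, None)
    return (vecs * vals) @ vecs.T


@dataclass(frozen=True)
class GaussianJoint:
    """Multivariate Gaussian with per-coordinate time tags."""

    mu: np.ndarray
    sigma: np.ndarray = field(repr=False)
    index_labels: tuple = ()

    def __init__(self, mu, sigma, index_labels=None):
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
        n = mu.shape[0]
        if sigma.shape != (n, n):
            raise ValueError(f"sigma shape {sigma.shape} does not match mu length {n}")
        if np.max(np.abs(sigma - sigma.T)) > 1e-10 * max(1.0, np.abs(sigma).max()):
            raise ValueError("sigma is not symmetric")
        sigma = 0.5 * (sigma + sigma.T)
        if index_labels is None:
            index_labels = tuple(range(n))
        index_labels = tuple(index_labels)
        if len(index_labels) != n:
            raise ValueError("index_labels length mismatch")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "index_labels", index_labels)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class RegimePartition:
    """Disjoint index sets assigning coordinates to target A, source B, context C.

    The context may be empty (unconditional denominator); target and source
    must not be.  ``n`` is the target length entering the KL formula.
    """

    target_idx: tuple[int, ...]
    source_idx: tuple[int, ...]
    context_idx: tuple[int, ...] = ()

    def __init__(self, target_idx, source_idx, context_idx=()):
        target_idx = tuple(int(i) for i in target_idx)
        source_idx = tuple(int(i) for i in source_idx)
        context_idx = tuple(int(i) for i in context_idx)
        if not target_idx or not source_idx:
            raise ValueError("target and source index sets must be nonempty")
        all_idx = target_idx + source_idx + context_idx
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("target/source/context index sets must be disjoint")
        object.__setattr__(self, "target_idx", target_idx)
        object.__setattr__(self, "source_idx", source_idx)
        object.__setattr__(self, "context_idx", context_idx)

    @property
    def n(self) -> int:
        return len(self.target_idx)


def condition_gaussian(
    joint: GaussianJoint, given_idx: Sequence[int], given_values: Sequence[float]
) -> GaussianJoint:
    """Condition a Gaussian on observed coordinates (block formulas).

    Conditioning on the empty set returns the joint unchanged (marginal of
    everything).  The given block is PSD-repaired before inversion; a block
    that stays singular raises with its condition number.
    """
    given_idx = [int(i) for i in given_idx]
    given_values = np.atleast_1d(np.asarray(given_values, dtype=float))
    if len(given_idx) != given_values.shape[0]:
        raise ValueError("given_idx and given_values length mismatch")
    if not given_idx:
        return joint
    keep_idx = [i for i in range(joint.dim) if i not in set(given_idx)]
    if not keep_idx:
        raise ValueError("cannot condition on every coordinate")
    S = joint.sigma
    kk = S[np.ix_(keep_idx, keep_idx)]
    kg = S[np.ix_(keep_idx, given_idx)]
    gg = S[np.ix_(given_idx, given_idx)]
    scale = max(np.abs(np.diag(S)).max(), 1e-30)
    gg = _repair_psd(gg, scale)
    try:
        c, low = cho_factor(gg, lower=True)
    except np.linalg.LinAlgError:
        raise ValueError(
            "given-block covariance singular after repair "
            f"(condition number {np.linalg.cond(gg):.3g})"
        ) from None
    resid = given_values - joint.mu[given_idx]
    mu_cond = joint.mu[keep_idx] + kg @ cho_solve((c, low), resid)
    sigma_cond = kk - kg @ cho_solve((c, low), kg.T)
    sigma_cond = 0.5 * (sigma_cond + sigma_cond.T)
    labels = tuple(joint.index_labels[i] for i in keep_idx)
    return GaussianJoint(mu_cond, sigma_cond, labels)


def gaussian_kl(mu1, sigma1, mu2, sigma2, base: str = "bits") -> float:
    """KL divergence D(N(mu1,sigma1) : N(mu2,sigma2)), default in bits."""
    mu1 = np.atleast_1d(np.asarray(mu1, dtype=float))
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    sigma1 = np.atleast_2d(np.asarray(sigma1, dtype=float))
    sigma2 = np.atleast_2d(np.asarray(sigma2, dtype=float))
    n = mu1.shape[0]
    if mu2.shape[0] != n or sigma1.shape != (n, n) or sigma2.shape != (n, n):
        raise ValueError("dimension mismatch between the two Gaussians")
    try:
        c2 = cho_factor(sigma2, lower=True)
    except np.linalg.LinAlgError:
        raise ValueError("sigma2 is not positive definite") from None
    diff = mu2 - mu1
    quad = float(diff @ cho_solve(c2, diff))
    trace = float(np.trace(cho_solve(c2, sigma1)))
    sign1, logdet1 = np.linalg.slogdet(sigma1)
    logdet2 = 2.0 * float(np.sum(np.log(np.diag(c2[0]))))
    if sign1 <= 0:
        raise ValueError("sigma1 is not positive definite")
    nats = 0.5 * (quad + trace - (logdet1 - logdet2) - n)
    return _to_base(max(nats, 0.0) / LOG2, base)


def gaussian_contrast(
    joint: GaussianJoint,
    partition: RegimePartition,
    b: Sequence[float],
    c: Sequence[float] = (),
    base: str = "bits",
) -> float:
    """Contrast information I(A; b | c) of a Gaussian joint, via two conditionings.

    Numerator conditional: target given source values ``b`` and context
    values ``c``; denominator: target given ``c`` alone.  For 1-D regimes
    this reduces to the scalar formula
    ½[ (m_bc - m_c)²/s_c² + s_bc²/s_c² - ln(s_bc²/s_c²) - 1 ].
    """
    for i in partition.target_idx + partition.source_idx + partition.context_idx:
        if i >= joint.dim:
            raise ValueError("partition index out of range for joint")
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float)) if len(partition.context_idx) else np.array([])
    num = condition_gaussian(
        joint,
        list(partition.source_idx) + list(partition.context_idx),
        np.concatenate([b, c]),
    )
    den = condition_gaussian(joint, list(partition.context_idx), c)
    # restrict both conditionals to the target coordinates
    t_labels = [joint.index_labels[i] for i in partition.target_idx]
    ni = [num.index_labels.index(lbl) for lbl in t_labels]
    di = [den.index_labels.index(lbl) for lbl in t_labels]
    return gaussian_kl(
        num.mu[ni],
        num.sigma[np.ix_(ni, ni)],
        den.mu[di],
        den.sigma[np.ix_(di, di)],
        base=base,
    )


# ---------------------------------------------------------------------------
# stationary models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousAutocov:
    """Polynomial autocovariance in lag magnitude |t|, valid on [0, t_max]."""

    coeffs: np.ndarray  # ascending powers of |t|
    t_max: float

    def __init__(self, coeffs, t_max):
        object.__setattr__(self, "coeffs", np.asarray(coeffs, dtype=float))
        object.__setattr__(self, "t_max", float(t_max))

    def __call__(self, lag) -> np.ndarray:
        lag = np.abs(np.asarray(lag, dtype=float))
        if np.any(lag > self.t_max + 1e-12):
            raise ValueError(
                f"lag {float(np.max(lag)):g} outside fitted domain [0, {self.t_max:g}]"
            )
        return np.polynomial.polynomial.polyval(lag, self.coeffs)


@dataclass(frozen=True)
class StationaryGPModel:
    """Stationary Gaussian process: scalar mean plus autocovariance gamma.

    ``gamma`` is either an array of values at integer lags 0..L (discrete
    time) or a ContinuousAutocov (continuous time).
    """

    mean: float
    gamma: object = field(repr=False)

    def __init__(self, mean, gamma):
        mean = float(mean)
        if not isinstance(gamma, ContinuousAutocov):
            gamma = np.asarray(gamma, dtype=float)
            if gamma.ndim != 1 or gamma.shape[0] < 1:
                raise ValueError("discrete gamma must be a 1-D array of lags 0..L")
        g0 = float(gamma(0.0)) if isinstance(gamma, ContinuousAutocov) else float(gamma[0])
        if g0 < 0:
            raise ValueError("gamma(0) must be >= 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "gamma", gamma)

    @property
    def continuous(self) -> bool:
        return isinstance(self.gamma, ContinuousAutocov)

    def gamma_at(self, lag) -> np.ndarray:
        if self.continuous:
            return np.asarray(self.gamma(lag), dtype=float)
        lag = np.abs(np.asarray(lag))
        if np.any(lag > self.gamma.shape[0] - 1):
            raise ValueError(
                f"lag {int(np.max(lag))} beyond stored maximum {self.gamma.shape[0] - 1}"
            )
        return self.gamma[lag.astype(int)]

    def window_joint(self, times: Sequence[float]) -> GaussianJoint:
        """Joint of the process at the given time tags (PSD-repaired Toeplitz)."""
        times = np.asarray(times, dtype=float)
        lags = np.abs(times[:, None] - times[None, :])
        sigma = self.gamma_at(lags)
        g0 = max(float(self.gamma_at(0.0)), 1e-30)
        sigma = _repair_psd(np.asarray(sigma, dtype=float), g0)
        mu = np.full(times.shape[0], self.mean)
        return GaussianJoint(mu, sigma, tuple(times.tolist()))


def estimate_stationary_gp(
    corpus: Sequence[Sequence[float]], max_lag: int, biased: bool = True
) -> StationaryGPModel:
    """Pooled mean and autocovariance of a stationary process from sequences.

    gamma_hat(l) sums lagged products of centred values within each
    sequence (never across boundaries) and divides by the total number of
    observations N (biased, the default, which favours PSD Toeplitz
    windows) or by the number of products (unbiased).
    """
    if not corpus:
        raise ValueError("corpus is empty")
    seqs = [np.asarray(s, dtype=float) for s in corpus]
    shortest = min(s.shape[0] for s in seqs)
    if max_lag >= shortest:
        raise ValueError(
            f"max_lag {max_lag} must be < shortest sequence length {shortest}"
        )
    total_n = sum(s.shape[0] for s in seqs)
    mean = sum(float(s.sum()) for s in seqs) / total_n
    gamma = np.zeros(max_lag + 1)
    for lag in range(max_lag + 1):
        acc = 0.0
        count = 0
        for s in seqs:
            x = s - mean
            if s.shape[0] > lag:
                acc += float(np.dot(x[:-lag] if lag else x, x[lag:]))
                count += s.shape[0] - lag
        gamma[lag] = acc / (total_n if biased else max(count, 1))
    return StationaryGPModel(mean, gamma)


def fit_continuous_autocov(
    gamma_hat: Sequence[float], degree: int = 10
) -> ContinuousAutocov:
    """Least-squares polynomial in |t| through the discrete autocovariance.

    With degree = len(gamma_hat) - 1 the fit interpolates.  Lags whose
    induced 2x2 windows are indefinite are flagged with a warning but the
    fit is returned regardless.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    L = gamma_hat.shape[0] - 1
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if gamma_hat.shape[0] < degree + 1:
        raise ValueError(
            f"need at least degree+1 = {degree + 1} lags, got {gamma_hat.shape[0]}"
        )
    lags = np.arange(L + 1, dtype=float)
    series = np.polynomial.Polynomial.fit(lags, gamma_hat, degree).convert()
    fit = ContinuousAutocov(series.coef, float(L))
    resid = float(np.max(np.abs(fit(lags) - gamma_hat)))
    g0 = fit(0.0)
    bad = [int(l) for l in lags[1:] if abs(fit(float(l))) > g0]
    if bad:
        warnings.warn(
            f"fitted autocovariance exceeds gamma(0) at lags {bad}; induced "
            "2-point windows are indefinite there",
            IndefiniteCovarianceWarning,
            stacklevel=2,
        )
    object.__setattr__(fit, "max_residual", resid)
    return fit


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _regime_times(variant, n, j, k):
    """(target, source, context) time-tag index lists for event n, offsets j,k."""
    past = list(range(n - j, n))
    present = [n]
    future = list(range(n + 1, n + 1 + k))
    return {
        "predictive": (future, present, past),
        "connective": (future, past, present),
        "reflective": (present, future, past),
        "b-predictive": (past, present, future),
        "b-connective": (past, future, present),
        "b-reflective": (present, past, future),
    }[variant]


def gp_profile(
    model: StationaryGPModel,
    sequence,
    variant: str,
    offsets=None,
    grid_step: float | None = None,
    base: str = "bits",
) -> pd.DataFrame:
    """Contrast-information profile of a realised sequence under a stationary GP.

    Discrete mode (integer offsets j,k): for each event with j past and k
    future neighbours, the window of j+1+k consecutive values forms a
    Toeplitz Gaussian joint; regimes are the extended past {n-j..n-1},
    present {n}, and future {n+1..n+k}, permuted per variant.

    Continuous mode (grid_step set, model continuous): point regimes at the
    onsets; predictive-family profiles pin X and Y at the two most recent
    onsets and sweep Z across the inter-onset gap; the reflective family
    pins X and Z at flanking onsets and sweeps Y.
    """
    from .events import EventSequence
    from .markov import StepOffsets

    if isinstance(sequence, EventSequence):
        values = [float(v) for v in sequence.values]
        onsets = sequence.onsets
    else:
        values = [float(v) for v in sequence]
        onsets = None

    rows = []
    if grid_step is None:
        if offsets is None:
            offsets = StepOffsets(1, 1)
        j, k = offsets.j, offsets.k
        for n in range(j, len(values) - k):
            t_idx, s_idx, c_idx = _regime_times(variant, n, j, k)
            times = t_idx + s_idx + c_idx
            joint = model.window_joint([float(t) for t in times])
            part = RegimePartition(
                tuple(range(len(t_idx))),
                tuple(range(len(t_idx), len(t_idx) + len(s_idx))),
                tuple(range(len(t_idx) + len(s_idx), len(times))),
            )
            bvals = [values[i] for i in s_idx]
            cvals = [values[i] for i in c_idx]
            val = gaussian_contrast(joint, part, bvals, cvals, base=base)
            rows.append((n, None, variant, val))
    else:
        if onsets is None:
            raise ValueError("continuous profiles need an EventSequence with onsets")
        if not model.continuous:
            raise ValueError("continuous profiles need a ContinuousAutocov model")
        for n in range(1, len(values) - 1):
            t0, t1 = onsets[n], onsets[n + 1]
            t_prev = onsets[n - 1]
            t = t0 + grid_step
            while t < t1 - 1e-12:
                if variant in ("predictive", "connective", "b-predictive", "b-connective"):
                    times = {"x": t_prev, "y": t0, "z": t}
                    obs = {"x": values[n - 1], "y": values[n], "z": values[n]}
                else:
                    times = {"x": t0, "y": t, "z": t1}
                    obs = {"x": values[n], "y": values[n], "z": values[n + 1]}
                role = {
                    "predictive": ("z", "y", "x"),
                    "connective": ("z", "x", "y"),
                    "reflective": ("y", "z", "x"),
                    "b-predictive": ("x", "y", "z"),
                    "b-connective": ("x", "z", "y"),
                    "b-reflective": ("y", "x", "z"),
                }[variant]
                tags = [times[r] for r in role]
                joint = model.window_joint(tags)
                part = RegimePartition((0,), (1,), (2,))
                val = gaussian_contrast(
                    joint, part, [obs[role[1]]], [obs[role[2]]], base=base
                )
                rows.append((n, t, variant, val))
                t += grid_step
    return pd.DataFrame(rows, columns=["event_index", "time", "variant", "value_bits"])
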