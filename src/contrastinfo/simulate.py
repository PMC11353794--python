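"""Seeded simulators for the four process classes.

Every draw flows through an explicit integer seed; the same seed always
reproduces the same sequence bit for bit.
"""

from __future__ import annotations

import numpy as np

from .events import EventSequence
from .gaussian import StationaryGPModel
from .markov import CTMCModel, DTMCModel

__all__ = ["simulate"]


def _simulate_dtmc(model: DTMCModel, length: int, rng) -> EventSequence:
    n = len(model.alphabet)
    cum = np.cumsum(model.P, axis=0)  # cum[:, k] over next states
    u = rng.random(length)
    states = np.empty(length, dtype=int)
    states[0] = int(np.searchsorted(np.cumsum(model.pi), u[0], side="right"))
    for i in range(1, length):
        states[i] = int(np.searchsorted(cum[:, states[i - 1]], u[i], side="right"))
    states = np.minimum(states, n - 1)  # guard against cumsum rounding at 1.0
    return EventSequence([model.alphabet[s] for s in states], kind="symbolic")


def _simulate_ctmc(model: CTMCModel, horizon: float, rng) -> EventSequence:
    n = len(model.alphabet)
    rates = -np.diag(model.Q)
    state = int(rng.choice(n, p=model.pi))
    t = 0.0
    values, onsets, durations = [], [], []
    while t < horizon:
        dwell = rng.exponential(1.0 / rates[state]) if rates[state] > 0 else horizon - t
        dwell = min(dwell, horizon - t)
        if dwell <= 0:
            break
        values.append(model.alphabet[state])
        onsets.append(t)
        durations.append(dwell)
        t += dwell
        if t >= horizon:
            break
        jump_p = model.Q[:, state].copy()
        jump_p[state] = 0.0
        jump_p /= jump_p.sum()
        state = int(rng.choice(n, p=jump_p))
    return EventSequence(values, onsets, durations, kind="symbolic")


def _simulate_gp(model: StationaryGPModel, length: int, rng) -> EventSequence:
    if length <= 512:
        joint = model.window_joint(np.arange(length, dtype=float))
        draw = rng.multivariate_normal(joint.mu, joint.sigma, method="cholesky")
    else:
        # circulant embedding: exact for the stored lags, gamma = 0 beyond them
        if model.continuous:
            L = int(np.floor(model.gamma.t_max))
            gamma = np.asarray(model.gamma_at(np.arange(L + 1)), dtype=float)
        else:
            gamma = model.gamma
            L = gamma.shape[0] - 1
        M = 1 << int(np.ceil(np.log2(max(2 * (L + 1), 2 * length))))
        circ = np.zeros(M)
        circ[: L + 1] = gamma
        circ[M - L :] = gamma[1:][::-1]
        eig = np.fft.fft(circ).real
        eig = np.clip(eig, 0.0, None)  # tiny negatives from embedding
        z = rng.standard_normal(M) + 1j * rng.standard_normal(M)
        field = np.fft.fft(np.sqrt(eig / (2.0 * M)) * z)
        draw = model.mean + np.sqrt(2.0) * field.real[:length]
    return EventSequence([float(v) for v in draw], kind="real")


def simulate(model, length=None, horizon=None, seed: int = 0) -> EventSequence:
    """Sample one realisation of a DTMC, CTMC, or stationary GP.

    DTMC and GP take ``length`` (number of events); CTMC takes ``horizon``
    (total time).  Returns an EventSequence the matching estimator accepts.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, DTMCModel):
        if not length or length < 1:
            raise ValueError("DTMC simulation needs a positive length")
        return _simulate_dtmc(model, int(length), rng)
    if isinstance(model, CTMCModel):
        if not horizon or horizon <= 0:
            raise ValueError("CTMC simulation needs a positive horizon")
        return _simulate_ctmc(model, float(horizon), rng)
    if isinstance(model, StationaryGPModel):
        if not length or length < 1:
            raise ValueError("GP simulation needs a positive length")
        return _simulate_gp(model, int(length), rng)
    raise TypeError(f"cannot simulate a {type(model).__name__}")
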