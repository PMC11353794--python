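"""Contrast information of stationary Markov chains, in closed form.

For a stationary discrete-time Markov chain with column-stochastic
transition matrix P (entry P[j,k] = probability of moving to state j from
state k) and stationary vector pi, the six temporal variants of contrast
information at offsets (j steps back, k steps forward) reduce to sums over
entries of matrix powers of P and of the reverse matrix
R = D_pi P^T D_pi^{-1}.  For a continuous-time chain with rate matrix Q the
matrix powers become matrix exponentials e^{uQ}, e^{vQ}, e^{(u+v)Q}.

Both connective variants are identically zero: a Markov chain's present
screens off its past from its future, so the past (resp. future) adds
nothing once the present is known.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse.csgraph import connected_components

from .measures import DiscreteJoint, _to_base

__all__ = [
    "VARIANTS",
    "DTMCModel",
    "CTMCModel",
    "StepOffsets",
    "estimate_dtmc",
    "estimate_ctmc",
    "stationary_distribution",
    "reverse_matrix",
    "dtmc_contrast",
    "ctmc_contrast",
    "markov_profile",
    "markov_joint",
    "save_model",
    "load_model",
]

VARIANTS = (
    "predictive",
    "connective",
    "reflective",
    "b-predictive",
    "b-connective",
    "b-reflective",
)


@dataclass(frozen=True)
class StepOffsets:
    """Temporal offsets: j steps (or u time units) into the past, k (or v) forward."""

    j: int = 1
    k: int = 1

    def __post_init__(self):
        if self.j < 1 or self.k < 1:
            raise ValueError("offsets must be >= 1")


def _check_alphabet(alphabet) -> tuple:
    alphabet = tuple(alphabet)
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("duplicate symbols in alphabet")
    if not alphabet:
        raise ValueError("empty alphabet")
    return alphabet


@dataclass(frozen=True)
class DTMCModel:
    """Stationary discrete-time Markov chain: alphabet, column-stochastic P, pi.

    The stationary vector is computed lazily on first access (an estimated
    chain can be stored and inspected even if it is not ergodic; only
    operations that need pi will then fail).
    """

    alphabet: tuple[Hashable, ...]
    P: np.ndarray = field(repr=False)

    def __init__(self, alphabet, P, pi=None):
        alphabet = _check_alphabet(alphabet)
        P = np.asarray(P, dtype=float)
        n = len(alphabet)
        if P.shape != (n, n):
            raise ValueError(f"P shape {P.shape} does not match alphabet size {n}")
        if np.any(P < 0):
            raise ValueError("P has negative entries")
        if np.max(np.abs(P.sum(axis=0) - 1.0)) > 1e-9:
            raise ValueError("columns of P must each sum to 1")
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "P", P)
        if pi is not None:
            pi = np.asarray(pi, dtype=float)
            if np.max(np.abs(P @ pi - pi)) > 1e-10:
                raise ValueError("supplied pi is not stationary for P")
        object.__setattr__(self, "_pi", pi)

    @property
    def pi(self) -> np.ndarray:
        if self._pi is None:
            object.__setattr__(self, "_pi", _stationary_dtmc(self.P))
        return self._pi

    def index(self, symbol: Hashable) -> int:
        try:
            return self.alphabet.index(symbol)
        except ValueError:
            raise KeyError(
                f"symbol {symbol!r} not in alphabet {list(self.alphabet)!r}"
            ) from None


@dataclass(frozen=True)
class CTMCModel:
    """Stationary continuous-time Markov chain: alphabet, rate matrix Q, pi.

    Columns of Q sum to zero and off-diagonal entries are non-negative;
    the stationary vector satisfies Q pi = 0.
    """

    alphabet: tuple[Hashable, ...]
    Q: np.ndarray = field(repr=False)

    def __init__(self, alphabet, Q, pi=None):
        alphabet = _check_alphabet(alphabet)
        Q = np.asarray(Q, dtype=float)
        n = len(alphabet)
        if Q.shape != (n, n):
            raise ValueError(f"Q shape {Q.shape} does not match alphabet size {n}")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < 0):
            raise ValueError("off-diagonal entries of Q must be >= 0")
        if np.max(np.abs(Q.sum(axis=0))) > 1e-9:
            raise ValueError("columns of Q must each sum to 0")
        object.__setattr__(self, "alphabet", alphabet)
        object.__setattr__(self, "Q", Q)
        if pi is not None:
            pi = np.asarray(pi, dtype=float)
            if np.max(np.abs(Q @ pi)) > 1e-10:
                raise ValueError("supplied pi does not satisfy Q pi = 0")
        object.__setattr__(self, "_pi", pi)

    @property
    def pi(self) -> np.ndarray:
        if self._pi is None:
            object.__setattr__(self, "_pi", _stationary_ctmc(self.Q))
        return self._pi

    index = DTMCModel.index


# ---------------------------------------------------------------------------
# stationary distribution and reversal
# ---------------------------------------------------------------------------

def _irreducible(M: np.ndarray) -> bool:
    # strong connectivity of the positive-support graph
    support = (M > 0).astype(int)
    np.fill_diagonal(support, 1)
    ncomp, _ = connected_components(support, directed=True, connection="strong")
    return ncomp == 1


def _stationary_dtmc(P: np.ndarray) -> np.ndarray:
    if not _irreducible(P):
        raise ValueError("chain is reducible: no unique stationary distribution")
    vals, vecs = np.linalg.eig(P)
    order = np.argsort(-vals.real)
    # detect periodicity / multiple unit-modulus eigenvalues
    close_to_one = np.sum(np.abs(np.abs(vals) - 1.0) < 1e-10)
    if close_to_one > 1:
        raise ValueError("chain appears periodic: multiple unit-modulus eigenvalues")
    v = vecs[:, order[0]].real
    pi = v / v.sum()
    if np.any(pi < -1e-12):
        raise ValueError("stationary eigenvector has negative entries")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.max(np.abs(P @ pi - pi))
    if resid > 1e-10:  # power-iteration fallback
        for _ in range(100_000):
            new = P @ pi
            new /= new.sum()
            if np.max(np.abs(new - pi)) < 1e-14:
                pi = new
                break
            pi = new
        resid = np.max(np.abs(P @ pi - pi))
        if resid > 1e-10:
            raise ValueError(f"stationary distribution did not converge (resid {resid:g})")
    return pi


def _stationary_ctmc(Q: np.ndarray) -> np.ndarray:
    jump = (Q - np.diag(np.diag(Q))) > 0
    support = jump.astype(int)
    np.fill_diagonal(support, 1)
    ncomp, _ = connected_components(support, directed=True, connection="strong")
    if ncomp != 1:
        raise ValueError("rate matrix is reducible: no unique stationary distribution")
    _, s, vh = np.linalg.svd(Q)
    null_dim = np.sum(s < 1e-12 * max(1.0, s[0]))
    if null_dim > 1:
        raise ValueError("rate matrix has a multi-dimensional null space")
    v = vh[-1].real
    if v.sum() < 0:
        v = -v
    pi = np.clip(v, 0.0, None)
    pi = pi / pi.sum()
    if np.max(np.abs(Q @ pi)) > 1e-10:
        raise ValueError("null-space vector is not a valid stationary distribution")
    return pi


def stationary_distribution(model: DTMCModel | CTMCModel) -> np.ndarray:
    """Stationary vector: pi = P pi (DTMC) or Q pi = 0 (CTMC), entries > 0."""
    if isinstance(model, DTMCModel):
        return _stationary_dtmc(model.P)
    if isinstance(model, CTMCModel):
        return _stationary_ctmc(model.Q)
    raise TypeError(f"expected DTMCModel or CTMCModel, got {type(model).__name__}")


def reverse_matrix(model: DTMCModel | CTMCModel) -> np.ndarray:
    """Time-reversed transition (or rate) matrix R = D_pi M^T D_pi^{-1}."""
    pi = model.pi
    if np.any(pi <= 0):
        raise ValueError("reversal requires strictly positive stationary mass")
    M = model.P if isinstance(model, DTMCModel) else model.Q
    return np.diag(pi) @ M.T @ np.diag(1.0 / pi)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate_dtmc(
    corpus: Sequence[Sequence[Hashable]],
    alphabet: Sequence[Hashable] | None = None,
    pseudocount: float = 0.0,
) -> DTMCModel:
    """Maximum-likelihood transition matrix from pooled corpus transitions.

    Counts are pooled across sequences, treating every sequence as a
    realisation of the same stationary chain; transitions never cross
    sequence boundaries.  ``pseudocount`` is added to every cell (additive
    smoothing); with pseudocount 0 a symbol that is never departed from
    leaves its column undefined and raises.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if alphabet is None:
        seen: dict = {}
        for seq in corpus:
            for s in seq:
                seen.setdefault(s, None)
        alphabet = tuple(seen)
    else:
        alphabet = tuple(alphabet)
        declared = set(alphabet)
        for seq in corpus:
            for s in seq:
                if s not in declared:
                    raise ValueError(f"symbol {s!r} not in supplied alphabet")
    idx = {s: i for i, s in enumerate(alphabet)}
    n = len(alphabet)
    counts = np.full((n, n), float(pseudocount))
    for seq in corpus:
        for prev, nxt in zip(seq, seq[1:]):
            counts[idx[nxt], idx[prev]] += 1.0
    col = counts.sum(axis=0)
    dead = np.where(col == 0)[0]
    if dead.size:
        raise ValueError(
            f"state(s) {[alphabet[i] for i in dead]!r} have no observed departures "
            "and pseudocount is 0; their transition column is undefined"
        )
    return DTMCModel(alphabet, counts / col)


def estimate_ctmc(
    corpus: Sequence[Sequence[tuple]],
    alphabet: Sequence[Hashable] | None = None,
) -> CTMCModel:
    """MLE rate matrix: q[j,k] = (# of k->j jumps) / (total dwell time in k).

    Each corpus element is a sequence of (symbol, onset, duration) triples,
    contiguous in time.  Consecutive repeats of the same symbol are merged
    into one dwell.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    merged_corpus = []
    for seq in corpus:
        merged: list[list] = []
        for sym, onset, dur in seq:
            if dur <= 0:
                raise ValueError(f"non-positive duration for event {sym!r}")
            if merged and merged[-1][0] == sym:
                merged[-1][2] += dur
            else:
                merged.append([sym, onset, dur])
        merged_corpus.append(merged)
    if alphabet is None:
        seen: dict = {}
        for seq in merged_corpus:
            for sym, _, _ in seq:
                seen.setdefault(sym, None)
        alphabet = tuple(seen)
    else:
        alphabet = tuple(alphabet)
    idx = {s: i for i, s in enumerate(alphabet)}
    n = len(alphabet)
    jumps = np.zeros((n, n))
    dwell = np.zeros(n)
    for seq in merged_corpus:
        for (sym, _, dur), nxt in zip(seq, seq[1:] + [None]):
            if sym not in idx:
                raise ValueError(f"symbol {sym!r} not in supplied alphabet")
            dwell[idx[sym]] += dur
            if nxt is not None:
                jumps[idx[nxt[0]], idx[sym]] += 1.0
    dead = np.where(dwell == 0)[0]
    if dead.size:
        raise ValueError(
            f"state(s) {[alphabet[i] for i in dead]!r} have zero dwell time"
        )
    Q = jumps / dwell
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=0))
    return CTMCModel(alphabet, Q)


# ---------------------------------------------------------------------------
# closed-form contrast information
# ---------------------------------------------------------------------------

def _mat_powers_dtmc(model: DTMCModel, j: int, k: int):
    P = model.P
    return (
        np.linalg.matrix_power(P, j),
        np.linalg.matrix_power(P, k),
        np.linalg.matrix_power(P, j + k),
    )


def _mat_powers_ctmc(model: CTMCModel, u: float, v: float):
    Q = model.Q
    return expm(u * Q), expm(v * Q), expm((u + v) * Q)


def _rev_powers(model, j, k, continuous: bool):
    Rm = reverse_matrix(model)
    if continuous:
        return expm(j * Rm), expm(k * Rm), expm((j + k) * Rm)
    return (
        np.linalg.matrix_power(Rm, j),
        np.linalg.matrix_power(Rm, k),
        np.linalg.matrix_power(Rm, j + k),
    )


def _point_kl(num: np.ndarray, den: np.ndarray, what: str) -> float:
    if num.sum() <= 0 or den.sum() <= 0:
        raise ValueError(f"zero-probability conditioning path in {what}")
    pos = num > 0
    if np.any(den[pos] == 0):
        raise ValueError(f"zero-probability conditioning path in {what}")
    return float(np.sum(num[pos] * np.log2(num[pos] / den[pos])))


def _markov_contrast(model, variant, x, y, z, Mj, Mk, Mjk, Rj, Rk, Rjk, base):
    ix = model.index(x) if x is not None else None
    iy = model.index(y) if y is not None else None
    iz = model.index(z) if z is not None else None

    def need(name, val):
        if val is None:
            raise ValueError(f"variant {variant!r} requires the {name} symbol")
        return val

    if variant == "predictive":
        # target: future point; source: present y; context: past point x
        num = Mk[:, need("present", iy)]
        den = Mjk[:, need("past", ix)]
        if Mj[iy, ix] <= 0:
            raise ValueError(
                f"zero-probability conditioning path: p({y!r}|{x!r}) = 0"
            )
        return _to_base(_point_kl(num, den, "predictive contrast"), base)
    if variant in ("connective", "b-connective"):
        # present screens off past from future: identically zero for Markov chains
        return 0.0
    if variant == "reflective":
        ix, iz = need("past", ix), need("future", iz)
        pzx = Mjk[iz, ix]
        if pzx <= 0:
            raise ValueError(
                f"zero-probability conditioning path: p({z!r}|{x!r}) = 0"
            )
        total = 0.0
        for m in range(len(model.alphabet)):
            w = Mk[iz, m] * Mj[m, ix] / pzx  # p(y=m | x, z)
            if w > 0:
                total += w * math.log2(Mk[iz, m] / pzx)
        return _to_base(total, base)
    if variant == "b-predictive":
        iy, iz = need("present", iy), need("future", iz)
        if Rk[iy, iz] <= 0:
            raise ValueError(
                f"zero-probability conditioning path: reverse p({y!r}|{z!r}) = 0"
            )
        num = Rj[:, iy]
        den = Rjk[:, iz]
        return _to_base(_point_kl(num, den, "backward predictive contrast"), base)
    if variant == "b-reflective":
        ix, iz = need("past", ix), need("future", iz)
        pxz = Rjk[ix, iz]
        if pxz <= 0:
            raise ValueError(
                f"zero-probability conditioning path: reverse p({x!r}|{z!r}) = 0"
            )
        total = 0.0
        for m in range(len(model.alphabet)):
            w = Rj[ix, m] * Rk[m, iz] / pxz  # p(y=m | x, z)
            if w > 0:
                total += w * math.log2(Rj[ix, m] / pxz)
        return _to_base(total, base)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def dtmc_contrast(
    model: DTMCModel,
    variant: str,
    x: Hashable | None = None,
    y: Hashable | None = None,
    z: Hashable | None = None,
    offsets: StepOffsets = StepOffsets(1, 1),
    base: str = "bits",
) -> float:
    """Closed-form (j,k)-step contrast information for a DTMC.

    ``x``/``y``/``z`` are the observed past/present/future symbols; only the
    symbols a variant conditions on are required (e.g. predictive needs x
    and y).  Connective variants are identically zero.
    """
    j, k = offsets.j, offsets.k
    Mj, Mk, Mjk = _mat_powers_dtmc(model, j, k)
    Rj, Rk, Rjk = _rev_powers(model, j, k, continuous=False)
    return _markov_contrast(model, variant, x, y, z, Mj, Mk, Mjk, Rj, Rk, Rjk, base)


def ctmc_contrast(
    model: CTMCModel,
    variant: str,
    x: Hashable | None = None,
    y: Hashable | None = None,
    z: Hashable | None = None,
    u: float = 1.0,
    v: float = 1.0,
    base: str = "bits",
) -> float:
    """Closed-form contrast information for a CTMC at real offsets u (past), v (future)."""
    if u <= 0 or v <= 0:
        raise ValueError("u and v must be > 0")
    Mu, Mv, Muv = _mat_powers_ctmc(model, u, v)
    Ru, Rv, Ruv = _rev_powers(model, u, v, continuous=True)
    # note the argument roles: j<->u past offset, k<->v future offset
    return _markov_contrast(model, variant, x, y, z, Mu, Mv, Muv, Ru, Rv, Ruv, base)


def markov_joint(
    model: DTMCModel | CTMCModel, variant: str, offsets=(1, 1)
) -> DiscreteJoint:
    """Exact joint of (past, present, future) arranged as (target, source, context).

    Assembles p(x, y, z) = pi_x * p(y|x, j) * p(z|y, k) from the stationary
    vector and the model's transition kernels, then permutes the axes to the
    (A, B, C) convention of the requested variant.  This is the definitional
    bridge used to validate the closed forms against ``contrast_from_joint``.
    """
    j, k = (offsets.j, offsets.k) if isinstance(offsets, StepOffsets) else offsets
    if isinstance(model, DTMCModel):
        Mj, Mk, _ = _mat_powers_dtmc(model, int(j), int(k))
    else:
        Mj, Mk, _ = _mat_powers_ctmc(model, float(j), float(k))
    pi = model.pi
    # joint[x, y, z] over (past, present, future)
    joint_xyz = np.einsum("x,yx,zy->xyz", pi, Mj, Mk)
    labels = model.alphabet
    role = {  # variant -> (target, source, context) drawn from (x, y, z)
        "predictive": ("z", "y", "x"),
        "connective": ("z", "x", "y"),
        "reflective": ("y", "z", "x"),
        "b-predictive": ("x", "y", "z"),
        "b-connective": ("x", "z", "y"),
        "b-reflective": ("y", "x", "z"),
    }[variant]
    axis = {"x": 0, "y": 1, "z": 2}
    pmf = np.transpose(joint_xyz, [axis[r] for r in role])
    return DiscreteJoint(labels, labels, labels, pmf)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _variant_args(variant, sx, sy, sz):
    """Which observed symbols each variant conditions on."""
    if variant == "predictive":
        return dict(x=sx, y=sy)
    if variant == "connective":
        return dict(x=sx, y=sy)
    if variant == "reflective":
        return dict(x=sx, z=sz)
    if variant == "b-predictive":
        return dict(y=sy, z=sz)
    if variant == "b-connective":
        return dict(y=sy, z=sz)
    if variant == "b-reflective":
        return dict(x=sx, z=sz)
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def markov_profile(
    model: DTMCModel | CTMCModel,
    sequence,
    variant: str,
    offsets: StepOffsets = StepOffsets(1, 1),
    grid_step: float | None = None,
    base: str = "bits",
) -> pd.DataFrame:
    """Per-event (DTMC) or per-grid-point (CTMC) contrast-information profile.

    DTMC: one row per event whose past (j back) and future (k forward)
    neighbours exist, so a j=k=1 profile over N events has N-2 rows.

    CTMC: the profile is a curve sampled every ``grid_step`` time units.
    For the forward variants the past and present (or past and future)
    regimes sit at the two most recent onsets while the remaining regime
    sweeps across the inter-onset interval: predictive/connective sweep the
    future Z from the present onset to the next onset; reflective pins X at
    the most recent onset and Z at the next onset and sweeps the present Y
    between them.  Backward variants mirror this scheme.

    Returns a DataFrame with columns event_index, time, variant, value_bits.
    """
    from .events import EventSequence

    if isinstance(sequence, EventSequence):
        symbols = list(sequence.values)
        onsets = sequence.onsets
    else:
        symbols = list(sequence)
        onsets = None
    for i, s in enumerate(symbols):
        if s not in model.alphabet:
            raise ValueError(f"event {i}: symbol {s!r} not in model alphabet")

    rows = []
    if isinstance(model, DTMCModel):
        j, k = offsets.j, offsets.k
        for n in range(j, len(symbols) - k):
            args = _variant_args(variant, symbols[n - j], symbols[n], symbols[n + k])
            val = dtmc_contrast(model, variant, offsets=offsets, base=base, **args)
            rows.append((n, None, variant, val))
    else:
        if onsets is None:
            raise ValueError("CTMC profiles need an EventSequence with onsets")
        if grid_step is None or grid_step <= 0:
            raise ValueError("CTMC profiles need a positive grid_step")
        for n in range(1, len(symbols) - 1):
            t0, t1 = onsets[n], onsets[n + 1]
            u_prev = onsets[n] - onsets[n - 1]
            t = t0 + grid_step
            while t < t1 - 1e-12:
                if variant in ("predictive", "connective", "b-predictive", "b-connective"):
                    # X, Y at the two most recent onsets; Z sweeps the dwell,
                    # whose realised state is still symbols[n]
                    args = _variant_args(variant, symbols[n - 1], symbols[n], symbols[n])
                    val = ctmc_contrast(
                        model, variant, u=u_prev, v=t - t0, base=base, **args
                    )
                else:
                    # reflective family: X at onset n, Z at onset n+1; Y sweeps
                    args = _variant_args(variant, symbols[n], None, symbols[n + 1])
                    val = ctmc_contrast(
                        model, variant, u=t - t0, v=t1 - t, base=base, **args
                    )
                rows.append((n, t, variant, val))
                t += grid_step
    return pd.DataFrame(rows, columns=["event_index", "time", "variant", "value_bits"])


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Write a model as JSON (matrices row-major, rows = next state)."""
    if isinstance(model, DTMCModel):
        d = {
            "type": "dtmc",
            "alphabet": list(model.alphabet),
            "matrix": [[float(f"{v:.17g}") for v in row] for row in model.P],
            "pi": [float(f"{v:.17g}") for v in model.pi],
        }
    elif isinstance(model, CTMCModel):
        d = {
            "type": "ctmc",
            "alphabet": list(model.alphabet),
            "matrix": [[float(f"{v:.17g}") for v in row] for row in model.Q],
            "pi": [float(f"{v:.17g}") for v in model.pi],
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def load_model(path):
    """Load a dtmc/ctmc/dtgp/ctgp model from its JSON form."""
    with open(path) as fh:
        d = json.load(fh)
    kind = d.get("type")
    if kind == "dtmc":
        return DTMCModel(d["alphabet"], np.asarray(d["matrix"]), np.asarray(d["pi"]))
    if kind == "ctmc":
        return CTMCModel(d["alphabet"], np.asarray(d["matrix"]), np.asarray(d["pi"]))
    if kind in ("dtgp", "ctgp"):
        from .gaussian import ContinuousAutocov, StationaryGPModel

        gamma = d["gamma"]
        if isinstance(gamma, dict):
            gamma = ContinuousAutocov(np.asarray(gamma["coeffs"]), gamma["t_max"])
        else:
            gamma = np.asarray(gamma, dtype=float)
        return StationaryGPModel(d["mean"], gamma)
    raise ValueError(f"unknown model type {kind!r}")
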