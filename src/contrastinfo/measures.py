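"""Definitional information measures over finite joint distributions.

Contrast information is the specific-information form of relative entropy:
the information a concrete source observation ``b`` provides about a target
variable ``A`` in a concrete context ``c``,

    I(A; b | c) = sum_a p(a|b,c) * log[ p(a|b,c) / p(a|c) ].

Unlike information content and Shannon entropy, it is invariant under
relabelings (and, in the continuous case, under differentiable invertible
re-descriptions of the state space), which makes it usable as a single
dynamic information measure for discrete and continuous processes alike.

This module computes everything by brute-force summation over an explicit
joint probability mass function; it is the oracle the closed-form Markov and
Gaussian modules are validated against.  A seeded Monte-Carlo estimator
covers the continuous (integral) form of the definition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Hashable, Literal, Sequence

import numpy as np

__all__ = [
    "AbsoluteContinuityWarning",
    "ContrastValue",
    "DiscreteJoint",
    "Distribution",
    "contrast_from_joint",
    "expected_contrast",
    "surprisal",
    "entropy",
    "mc_contrast_continuous",
    "LOG2",
]

LOG2 = math.log(2.0)

#: tolerance within which a pmf is accepted and silently renormalised
PROB_TOL = 1e-9

Variant = Literal[
    "predictive",
    "connective",
    "reflective",
    "b-predictive",
    "b-connective",
    "b-reflective",
    "generic",
]


class AbsoluteContinuityWarning(UserWarning):
    """The numerator conditional puts mass where the denominator has none.

    The relative entropy is +infinity in this case; the value is returned
    as ``math.inf`` rather than raising.
    """


def _to_base(value_bits: float, base: str) -> float:
    if base == "bits":
        return value_bits
    if base == "nats":
        return value_bits * LOG2
    raise ValueError(f"unknown base {base!r}; expected 'bits' or 'nats'")


def _check_pmf(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{what} has negative entries")
    total = p.sum()
    if abs(total - 1.0) > PROB_TOL:
        raise ValueError(f"{what} sums to {total!r}, not 1 (tolerance {PROB_TOL})")
    return p / total


@dataclass(frozen=True)
class Distribution:
    """A finite probability distribution over an ordered set of symbols."""

    labels: tuple[Hashable, ...]
    probs: np.ndarray

    def __init__(self, labels: Sequence[Hashable], probs: Sequence[float]):
        labels = tuple(labels)
        probs = _check_pmf(np.asarray(probs, dtype=float), "distribution")
        if len(labels) != probs.shape[0]:
            raise ValueError("labels and probs length mismatch")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", probs)

    def prob(self, outcome: Hashable) -> float:
        return float(self.probs[self.index(outcome)])

    def index(self, outcome: Hashable) -> int:
        try:
            return self.labels.index(outcome)
        except ValueError:
            raise KeyError(
                f"outcome {outcome!r} not in alphabet {list(self.labels)!r}"
            ) from None


@dataclass(frozen=True)
class ContrastValue:
    """A single contrast-information evaluation, tagged with its regime roles."""

    value: float
    variant: Variant = "generic"
    source_outcome: object = None
    context_outcome: object = None

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class DiscreteJoint:
    """Joint pmf p(a, b, c) over (target A, source B, context C).

    The axis order is always (A, B, C).  Joints whose total mass deviates
    from 1 by more than 1e-9 are rejected; smaller deviations are
    renormalised.
    """

    target_labels: tuple[Hashable, ...]
    source_labels: tuple[Hashable, ...]
    context_labels: tuple[Hashable, ...]
    pmf: np.ndarray = field(repr=False)

    def __init__(self, target_labels, source_labels, context_labels, pmf):
        target_labels = tuple(target_labels)
        source_labels = tuple(source_labels)
        context_labels = tuple(context_labels)
        pmf = np.asarray(pmf, dtype=float)
        expected = (len(target_labels), len(source_labels), len(context_labels))
        if pmf.shape != expected:
            raise ValueError(f"pmf shape {pmf.shape} != (|A|,|B|,|C|) {expected}")
        pmf = _check_pmf(pmf, "joint pmf")
        object.__setattr__(self, "target_labels", target_labels)
        object.__setattr__(self, "source_labels", source_labels)
        object.__setattr__(self, "context_labels", context_labels)
        object.__setattr__(self, "pmf", pmf)

    # -- indexing helpers -------------------------------------------------
    def _idx(self, labels: tuple, outcome: Hashable, axis: str) -> int:
        try:
            return labels.index(outcome)
        except ValueError:
            raise KeyError(
                f"{axis} outcome {outcome!r} not in {list(labels)!r}"
            ) from None

    def b_index(self, b: Hashable) -> int:
        return self._idx(self.source_labels, b, "source")

    def c_index(self, c: Hashable) -> int:
        return self._idx(self.context_labels, c, "context")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "target_labels": list(self.target_labels),
            "source_labels": list(self.source_labels),
            "context_labels": list(self.context_labels),
            "pmf": self.pmf.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteJoint":
        return cls(d["target_labels"], d["source_labels"], d["context_labels"], d["pmf"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "DiscreteJoint":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _kl_bits(num: np.ndarray, den: np.ndarray, what: str) -> float:
    """KL divergence (bits) between two pmfs on the same support axis.

    Uses the 0*log 0 = 0 convention; a numerator atom without denominator
    mass makes the divergence infinite (absolute-continuity violation),
    reported via a warning rather than an exception.
    """
    pos = num > 0
    if np.any(den[pos] == 0):
        warnings.warn(
            f"absolute-continuity violation in {what}: numerator has mass "
            "where the denominator does not; contrast is +inf",
            AbsoluteContinuityWarning,
            stacklevel=3,
        )
        return math.inf
    return float(np.sum(num[pos] * np.log2(num[pos] / den[pos])))


def contrast_from_joint(
    joint: DiscreteJoint, b: Hashable, c: Hashable, base: str = "bits"
) -> float:
    """Contrast information I(A; b | c) by direct summation over the target.

    Parameters
    ----------
    joint
        Joint pmf over (target, source, context).
    b, c
        The observed source and context symbols.  The conditioning event
        (B=b, C=c) must have positive probability.
    base
        ``"bits"`` (default) or ``"nats"``.
    """
    bi, ci = joint.b_index(b), joint.c_index(c)
    p_abc = joint.pmf[:, bi, ci]
    p_bc = p_abc.sum()
    if p_bc <= 0:
        raise ValueError(
            f"conditioning event has zero probability: source={b!r}, context={c!r}"
        )
    p_ac = joint.pmf[:, :, ci].sum(axis=1)
    p_c = p_ac.sum()
    num = p_abc / p_bc  # p(a|b,c)
    den = p_ac / p_c  # p(a|c)
    return _to_base(_kl_bits(num, den, f"I(A; b={b!r} | c={c!r})"), base)


def expected_contrast(
    joint: DiscreteJoint,
    over: Literal["context", "source", "both"],
    fixed: Hashable | None = None,
    base: str = "bits",
) -> float:
    """Expected contrast information, averaged over context, source, or both.

    ``over="context"`` averages I(A; b | C) over contexts with weights
    p(c|b) for the fixed source ``b``; ``over="source"`` averages over
    sources with weights p(b|c) for the fixed context ``c``; ``over="both"``
    is the conditional mutual information I(A; B | C).
    """
    pmf = joint.pmf
    p_bc = pmf.sum(axis=0)  # (B, C)
    if over == "context":
        bi = joint.b_index(fixed)
        p_b = p_bc[bi, :].sum()
        if p_b <= 0:
            raise ValueError(f"fixed source {fixed!r} has zero probability")
        total = 0.0
        for ci, c in enumerate(joint.context_labels):
            w = p_bc[bi, ci] / p_b  # p(c|b)
            if w > 0:
                total += w * contrast_from_joint(joint, fixed, c, base=base)
        return total
    if over == "source":
        ci = joint.c_index(fixed)
        p_c = p_bc[:, ci].sum()
        if p_c <= 0:
            raise ValueError(f"fixed context {fixed!r} has zero probability")
        total = 0.0
        for bi, b in enumerate(joint.source_labels):
            w = p_bc[bi, ci] / p_c  # p(b|c)
            if w > 0:
                total += w * contrast_from_joint(joint, b, fixed, base=base)
        return total
    if over == "both":
        if fixed is not None:
            raise ValueError("over='both' takes no fixed outcome")
        total = 0.0
        for bi, b in enumerate(joint.source_labels):
            for ci, c in enumerate(joint.context_labels):
                w = p_bc[bi, ci]
                if w > 0:
                    total += w * contrast_from_joint(joint, b, c, base=base)
        return total
    raise ValueError(f"unknown over={over!r}")


def surprisal(dist: Distribution, outcome: Hashable, base: str = "bits") -> float:
    """Information content -log p(outcome); +inf for a zero-probability outcome."""
    p = dist.prob(outcome)
    if p == 0:
        return math.inf
    return _to_base(-math.log2(p), base)


def entropy(dist: Distribution, base: str = "bits") -> float:
    """Shannon entropy, the expected surprisal, with 0*log 0 = 0."""
    p = dist.probs[dist.probs > 0]
    return _to_base(float(-np.sum(p * np.log2(p))), base)


def mc_contrast_continuous(
    logdensity_num: Callable[[np.ndarray], np.ndarray],
    logdensity_den: Callable[[np.ndarray], np.ndarray],
    sampler_num: Callable[[np.random.Generator, int], np.ndarray],
    n: int,
    seed: int,
    base: str = "bits",
) -> dict:
    """Monte-Carlo estimate of the continuous contrast integral.

    Draws ``n`` samples from the numerator conditional p(a|b,c) and averages
    the log-density ratio log p(a|b,c) - log p(a|c).  The log-densities are
    natural-log; the estimate is converted to the requested base.

    Returns a dict with ``estimate``, ``std_error`` (sample sd / sqrt(n))
    and ``n_nonfinite`` (draws whose log ratio was not finite, excluded).
    Identical seeds give bit-identical results.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    a = sampler_num(rng, n)
    ratios = np.asarray(logdensity_num(a), dtype=float) - np.asarray(
        logdensity_den(a), dtype=float
    )
    finite = np.isfinite(ratios)
    n_bad = int(n - finite.sum())
    if finite.sum() == 0:
        raise ValueError("all log-density ratios were non-finite")
    ratios = ratios[finite] / LOG2  # nats -> bits
    est = float(np.mean(ratios))
    se = float(np.std(ratios, ddof=0) / math.sqrt(ratios.size))
    return {
        "estimate": _to_base(est, base),
        "std_error": _to_base(se, base),
        "n_nonfinite": n_bad,
    }
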