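"""Variable-order PPM sequence model and per-event information profiles.

Prediction by Partial Matching (escape method C, backoff smoothing, no
update exclusion) estimates a predictive distribution over the next symbol
from context counts of every order up to a bound.  At each order the escape
probability is d/(n+d), where n is the total follower count of the context
and d the number of distinct followers; escaped mass backs off to the next
lower order, ending in a uniform distribution over the training alphabet,
so every symbol always has positive probability.

On top of the predictor this module computes the per-event quantities used
to compare the classic information-dynamics pair (information content,
entropy) with forward predictive contrast information and its expected
form.  Since PPM only predicts one step ahead, the joint over (present,
next) given a past context x is built by marginalising over a hypothetical
present:  p(z|x) = sum_y' p(y'|x) p(z|x,y'), with contexts truncated to the
order bound.  The per-event forward predictive contrast is then the KL
divergence from p(Z|x,y) to p(Z|x), which by construction is bounded above
by the information content -log2 p(y|x).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .measures import Distribution

__all__ = [
    "PPMModel",
    "ViewpointSequence",
    "train_ppm",
    "ppm_predict",
    "ppm_profiles",
    "link_viewpoints",
    "correlate_profiles",
]


@dataclass(frozen=True)
class ViewpointSequence:
    """A symbolic feature stream (or tuple stream from linked viewpoints)."""

    events: tuple
    feature_names: tuple[str, ...] = ("feature",)

    def __init__(self, events: Sequence[Hashable], feature_names=("feature",)):
        object.__setattr__(self, "events", tuple(events))
        object.__setattr__(self, "feature_names", tuple(feature_names))

    def __len__(self) -> int:
        return len(self.events)


def _events_of(sequence) -> tuple:
    if isinstance(sequence, ViewpointSequence):
        return sequence.events
    return tuple(sequence)


@dataclass(frozen=True)
class PPMModel:
    """Trained PPM count tables for context orders 0..order_bound."""

    alphabet: tuple[Hashable, ...]
    order_bound: int
    tables: tuple  # tables[h] maps context tuple of length h -> Counter

    def followers(self, context: tuple) -> Counter | None:
        h = len(context)
        if h > self.order_bound:
            raise ValueError("context longer than order bound")
        return self.tables[h].get(context)


def train_ppm(corpus: Sequence, order_bound: int) -> PPMModel:
    """Accumulate context counts up to ``order_bound`` over the whole corpus.

    The model is static: trained once here, never updated during
    profiling.  Symbols must be hashable; the alphabet is the set of
    symbols observed in training.
    """
    if order_bound < 0:
        raise ValueError("order_bound must be >= 0")
    if not corpus:
        raise ValueError("corpus is empty")
    tables: list[dict] = [dict() for _ in range(order_bound + 1)]
    seen: dict = {}
    for seq in corpus:
        events = _events_of(seq)
        for s in events:
            seen.setdefault(s, None)
        for i, sym in enumerate(events):
            for h in range(min(order_bound, i) + 1):
                ctx = events[i - h : i]
                table = tables[h]
                if ctx not in table:
                    table[ctx] = Counter()
                table[ctx][sym] += 1
    if not seen:
        raise ValueError("corpus contains no events; alphabet would be empty")
    return PPMModel(tuple(seen), order_bound, tuple(tables))


def ppm_predict(model: PPMModel, context: Sequence[Hashable]) -> Distribution:
    """PPM-C predictive distribution over the alphabet given a context.

    The context is truncated to the model's order bound (most recent
    symbols kept).  Probabilities always sum to 1 and are strictly
    positive, because the escape cascade terminates in a uniform order
    minus-one distribution.
    """
    context = tuple(context)
    known = set(model.alphabet)
    for s in context:
        if s not in known:
            raise KeyError(f"context symbol {s!r} not in alphabet")
    if len(context) > model.order_bound:
        context = context[len(context) - model.order_bound :]
    m = len(model.alphabet)
    probs = np.zeros(m)
    index = {s: i for i, s in enumerate(model.alphabet)}
    mass = 1.0  # probability mass not yet assigned at higher orders
    for h in range(len(context), -1, -1):
        ctx = context[len(context) - h :]
        counts = model.followers(ctx)
        if counts is None:
            continue
        n = sum(counts.values())
        d = len(counts)
        for sym, c in counts.items():
            probs[index[sym]] += mass * c / (n + d)
        mass *= d / (n + d)
    probs += mass / m  # order -1: uniform over the alphabet
    return Distribution(model.alphabet, probs)


def _predict_vec(model: PPMModel, context: tuple, cache: dict) -> np.ndarray:
    if len(context) > model.order_bound:
        context = context[len(context) - model.order_bound :]
    if context not in cache:
        cache[context] = ppm_predict(model, context).probs
    return cache[context]


def ppm_profiles(model: PPMModel, sequence) -> pd.DataFrame:
    """Per-event information profiles of a sequence under a trained model.

    Returns a DataFrame with one row per event and columns

    - ``information_content``: -log2 p(y_n | x), x the truncated past
    - ``entropy``: Shannon entropy of p(. | x)
    - ``predictive_contrast``: I(Z; y_n | x) with Z the single next event
    - ``expected_predictive_contrast``: sum_y' p(y'|x) I(Z; y'|x)

    all in bits.  Events at the sequence start use the empty context.
    """
    events = _events_of(sequence)
    index = {s: i for i, s in enumerate(model.alphabet)}
    for i, s in enumerate(events):
        if s not in index:
            raise ValueError(f"event {i}: symbol {s!r} not in alphabet")
    cache: dict = {}
    rows = []
    for n, sym in enumerate(events):
        x = events[max(0, n - model.order_bound) : n]
        p_y = _predict_vec(model, x, cache)
        ic = -math.log2(p_y[index[sym]])
        pos = p_y[p_y > 0]
        ent = float(-np.sum(pos * np.log2(pos)))
        # joint over (present y', next z) given x, via a hypothetical present
        p_z_given_xy = np.empty((len(model.alphabet), len(model.alphabet)))
        for yi, y_sym in enumerate(model.alphabet):
            p_z_given_xy[yi] = _predict_vec(model, x + (y_sym,), cache)
        p_z_given_x = p_y @ p_z_given_xy
        contrasts = np.sum(
            p_z_given_xy * np.log2(p_z_given_xy / p_z_given_x[None, :]), axis=1
        )
        rows.append(
            (
                n,
                ic,
                ent,
                float(contrasts[index[sym]]),
                float(p_y @ contrasts),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_index",
            "information_content",
            "entropy",
            "predictive_contrast",
            "expected_predictive_contrast",
        ],
    )


def link_viewpoints(*streams) -> ViewpointSequence:
    """Cartesian-product linkage of two or more aligned symbol streams."""
    if len(streams) < 2:
        raise ValueError("need at least two streams to link")
    seqs = [_events_of(s) for s in streams]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"stream length mismatch: {sorted(lengths)}")
    names = []
    for s in streams:
        if isinstance(s, ViewpointSequence):
            names.extend(s.feature_names)
        else:
            names.append(f"feature{len(names)}")
    return ViewpointSequence(tuple(zip(*seqs)), tuple(names))


def correlate_profiles(x, y) -> dict:
    """Pearson and Spearman correlations between two information profiles.

    Events where either value is non-finite are excluded pairwise; the
    number excluded is reported.  Spearman uses average ranks for ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int(x.shape[0] - ok.sum())
    x, y = x[ok], y[ok]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a profile; correlation undefined")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    return {"pearson": pearson, "spearman": spearman, "n_excluded": n_excluded}
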