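"""Reproducible stochastic primitives.

Every random decision in the simulator goes through this module: hazard
conversions between reference-period probabilities and daily probabilities,
Bernoulli and categorical event draws, length-of-stay sampling and NYHA
severity transitions.  All draws are made on named :class:`RngStream`
substreams so that a scenario is bit-reproducible from its seed and so that
adding patients to a cohort never perturbs the trajectories of the patients
already present.
"""

from __future__ import annotations

import hashlib
import math
from typing import Sequence

import numpy as np

__all__ = [
    "RngStream",
    "daily_hazard_from_period_prob",
    "period_prob_from_daily_hazard",
    "draw_bernoulli",
    "draw_categorical",
    "sample_los",
    "sample_los_array",
    "sample_nyha_transition",
    "simulate_period_event_fraction",
]


class RngStream:
    """A named, independently seeded random stream.

    The stream is derived from ``(seed, label)`` by hashing the label into a
    spawn key for a :class:`numpy.random.SeedSequence`.  Identical
    ``(seed, label)`` pairs always yield the identical draw sequence; distinct
    labels behave as independent streams.  Labels are hierarchical by
    convention, e.g. ``"conventional/run-0/patient-17/outpatient"``.
    """

    __slots__ = ("seed", "label", "_gen")

    def __init__(self, seed: int, label: str = "") -> None:
        if seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        self.seed = int(seed)
        self.label = label
        digest = hashlib.sha256(label.encode("utf-8")).digest()
        spawn_key = tuple(
            int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)
        )
        self._gen = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=spawn_key)
        )

    def substream(self, label: str) -> "RngStream":
        """Derive a child stream with a ``/``-joined label."""
        child = self.label + "/" + label if self.label else label
        return RngStream(self.seed, child)

    def random(self) -> float:
        """One uniform draw on [0, 1)."""
        return float(self._gen.random())

    def standard_normal(self) -> float:
        return float(self._gen.standard_normal())

    @property
    def generator(self) -> np.random.Generator:
        """The underlying numpy generator, for vectorised draws."""
        return self._gen

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngStream(seed={self.seed}, label={self.label!r})"


def daily_hazard_from_period_prob(p: float, period_days: int) -> float:
    """Convert a per-reference-period event probability to a daily probability.

    Returns the daily probability ``h`` solving ``1 - (1-h)**period_days = p``,
    i.e. the constant daily hazard under which the chance of at least one
    event over ``period_days`` independent days equals ``p``.  This bridges
    probabilities reported per study follow-up period (e.g. hospitalisation
    risk per six months) to the model's one-day time step.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if period_days < 1:
        raise ValueError(f"period_days must be >= 1, got {period_days}")
    if p == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p) / period_days)


def period_prob_from_daily_hazard(h: float, period_days: int) -> float:
    """Inverse of :func:`daily_hazard_from_period_prob`."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {h}")
    if h == 1.0:
        return 1.0
    return -math.expm1(period_days * math.log1p(-h))


def draw_bernoulli(p: float, rng: RngStream) -> bool:
    """One Bernoulli(p) draw; consumes exactly one uniform."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return rng.random() < p


def draw_categorical(weights: Sequence[float], rng: RngStream) -> int:
    """Index ``i`` with probability ``weights[i] / sum(weights)``.

    Weights need not be normalised; at least one must be positive.
    """
    total = 0.0
    for w in weights:
        if w < 0:
            raise ValueError("weights must be nonnegative")
        total += w
    if total <= 0.0:
        raise ValueError("at least one weight must be positive")
    u = rng.random() * total
    acc = 0.0
    for i, w in enumerate(weights):
        acc += w
        if u < acc:
            return i
    return len(weights) - 1  # guard against float round-off at u ~ total


def sample_los(median_days: float, dispersion: float, rng: RngStream) -> int:
    """Sample an integer length of stay (days, >= 1).

    Stays are drawn from a log-normal distribution parameterised by its
    continuous median (``exp(mu) = median_days``) with log-scale standard
    deviation ``dispersion``, then rounded up to whole days.  The log-normal
    gives the right skew typical of hospital length-of-stay data while only a
    median is pinned down; ``dispersion == 0`` degenerates to a fixed stay of
    ``ceil(median_days)``, which is convenient for exact tests.
    """
    if median_days < 1:
        raise ValueError(f"median_days must be >= 1, got {median_days}")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if dispersion == 0.0:
        return max(1, math.ceil(median_days))
    z = rng.standard_normal()
    return max(1, math.ceil(median_days * math.exp(dispersion * z)))


def sample_los_array(
    median_days: float, dispersion: float, n: int, rng: RngStream
) -> np.ndarray:
    """Vectorised :func:`sample_los`: ``n`` integer stays in one call."""
    if median_days < 1:
        raise ValueError(f"median_days must be >= 1, got {median_days}")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    if dispersion == 0.0:
        return np.full(n, max(1, math.ceil(median_days)), dtype=np.int64)
    z = rng.generator.standard_normal(n)
    los = np.ceil(median_days * np.exp(dispersion * z)).astype(np.int64)
    return np.maximum(los, 1)


def sample_nyha_transition(
    current: int, transition_probs: Sequence[float], rng: RngStream
) -> int:
    """Draw the NYHA class after a care episode.

    ``transition_probs`` is the (improve, stay, worsen) triple; the class
    moves by at most one grade and is clamped to the 1..4 range (a class-1
    patient cannot improve further, a class-4 patient cannot worsen further).
    """
    if current not in (1, 2, 3, 4):
        raise ValueError(f"NYHA class must be 1..4, got {current}")
    if len(transition_probs) != 3:
        raise ValueError("transition_probs must be an (improve, stay, worsen) triple")
    if abs(sum(transition_probs) - 1.0) > 1e-9:
        raise ValueError("transition probabilities must sum to 1")
    idx = draw_categorical(transition_probs, rng)
    delta = (-1, 0, 1)[idx]
    return min(4, max(1, current + delta))


def simulate_period_event_fraction(
    daily_prob: float,
    period_days: int,
    n_periods: int,
    rng: RngStream,
    chunk: int = 20_000,
) -> float:
    """Fraction of simulated periods with at least one event.

    Simulates ``n_periods`` independent periods of ``period_days`` daily
    Bernoulli(``daily_prob``) draws and returns the fraction of periods in
    which the event fired at least once.  Used to verify that the hazard
    conversion reproduces per-period probabilities empirically.  Draws are
    chunked to bound memory.
    """
    if not 0.0 <= daily_prob <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {daily_prob}")
    hits = 0
    remaining = n_periods
    gen = rng.generator
    while remaining > 0:
        m = min(chunk, remaining)
        draws = gen.random((m, period_days)) < daily_prob
        hits += int(draws.any(axis=1).sum())
        remaining -= m
    return hits / n_periods
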