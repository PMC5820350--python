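"""Deterministic two-state producer/non-producer population model.

An engineered production strain is modelled as two exponentially growing
subpopulations: producers P, which pay a growth-rate cost for biosynthesis
(the *production load* ``c``), and non-producers N, which have shed that
cost.  Producers convert irreversibly to non-producers at a constant
per-generation *escape rate* ``k`` (the aggregate of all disruptive genetic
error modes: IS transposition, SNPs, recombination).  With non-producer
growth rate ``mu`` (default 1 per generation) the dynamics are

    dP/dg = (mu - c - k) * P
    dN/dg = mu * N + k * P,        P(0) = p0, N(0) = 0

with closed-form solution

    P(g) = p0 * exp((mu - c - k) * g)
    N(g) = p0 * (k / (c + k)) * (exp(mu*g) - exp((mu - c - k)*g))

The observable of interest is the producer fraction f = P / (P + N), which
is independent of ``mu`` and depends only on the non-producer/producer
ratio rho(g) = (k / (c + k)) * (exp((c + k)*g) - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "Trajectory",
    "closed_form_counts",
    "nonproducer_ratio",
    "producer_fraction",
    "half_life",
    "relative_production",
    "trajectory",
    "scale_annotation",
    "NEVER",
    "DEFAULT_ANCHOR_TABLE",
]

#: Distinguished half-life value for k = 0 populations that never decline.
NEVER = math.inf


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the two-state model.

    Parameters
    ----------
    load
        Production load ``c``: absolute growth-rate deficit of producers,
        per generation.  Dimensionless, ``0 <= c < 1``.
    escape_rate
        Escape rate ``k``: per-generation rate of irreversible
        producer -> non-producer conversion.  ``k >= 0``.
    ref_growth
        Non-producer reference growth rate ``mu`` per generation
        (default 1).  The producer fraction is independent of ``mu``.
    """

    load: float
    escape_rate: float
    ref_growth: float = 1.0

    def __post_init__(self) -> None:
        c, k, mu = self.load, self.escape_rate, self.ref_growth
        if not (math.isfinite(c) and math.isfinite(k) and math.isfinite(mu)):
            raise ValueError("model parameters must be finite")
        if not 0.0 <= c < 1.0:
            raise ValueError(f"production load must satisfy 0 <= c < 1, got {c}")
        if k < 0.0:
            raise ValueError(f"escape rate must be non-negative, got {k}")
        if mu <= 0.0:
            raise ValueError(f"reference growth rate must be positive, got {mu}")


@dataclass(frozen=True)
class Trajectory:
    """Model trajectory on a generation grid."""

    generations: np.ndarray
    producers: np.ndarray
    nonproducers: np.ndarray

    @property
    def producer_fraction(self) -> np.ndarray:
        total = self.producers + self.nonproducers
        return np.divide(self.producers, total, out=np.ones_like(total), where=total > 0)

    @property
    def nonproducer_ratio(self) -> np.ndarray:
        return np.divide(
            self.nonproducers,
            self.producers,
            out=np.full_like(self.nonproducers, np.inf),
            where=self.producers > 0,
        )


def _check_generations(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("generations must be finite and non-negative")
    return g


def closed_form_counts(params: ModelParams, g, p0: float = 1.0):
    """Exact producer/non-producer counts ``(P(g), N(g))``.

    Matches adaptive numerical integration of the ODE pair to high relative
    accuracy; may overflow to ``inf`` for very large ``mu*g`` (use
    :func:`producer_fraction` for fraction-space questions at large g).
    """
    g = _check_generations(g)
    c, k, mu = params.load, params.escape_rate, params.ref_growth
    P = p0 * np.exp((mu - c - k) * g)
    if k == 0.0:
        N = np.zeros_like(g)
    else:
        # e^{mu g} - e^{(mu-c-k)g} written via expm1 to avoid cancellation
        # when (c+k) g is small
        N = p0 * (k / (c + k)) * np.exp(mu * g) * (-np.expm1(-(c + k) * g))
    return P, N


def nonproducer_ratio(params: ModelParams, g):
    """Non-producer to producer ratio rho(g) = (k/(c+k)) * (exp((c+k) g) - 1).

    Independent of ``mu``.  For c = 0 this reduces exactly to
    ``exp(k g) - 1``.  Overflows to ``inf`` for (c+k)*g beyond ~700; the
    producer fraction remains well-defined there (see
    :func:`producer_fraction`).
    """
    g = _check_generations(g)
    c, k = params.load, params.escape_rate
    if k == 0.0:
        return np.zeros_like(g) if g.ndim else 0.0
    ck = c + k
    rho = (k / ck) * np.expm1(ck * g)
    return rho if g.ndim else float(rho)


def producer_fraction(params: ModelParams, g):
    """Producer fraction f(g) = 1 / (1 + rho(g)), overflow-safe.

    Evaluated as ``ck * e^{-x} / ((ck - k) e^{-x} + k)`` with
    ``x = (c+k) g``, which never overflows: for large x the fraction
    underflows gracefully to (ck/k) * e^{-x} -> 0.
    """
    g = _check_generations(g)
    c, k = params.load, params.escape_rate
    if k == 0.0:
        return np.ones_like(g) if g.ndim else 1.0
    ck = c + k
    ex = np.exp(-ck * g)
    f = ck * ex / ((ck - k) * ex + k)
    return f if g.ndim else float(f)


def half_life(params: ModelParams) -> float:
    """Generations until the producer fraction of a pure producing start
    falls to 1/2:  g_half = ln(1 + (c+k)/k) / (c+k).

    Returns :data:`NEVER` (infinity) when ``k = 0``.
    Strictly decreasing in both ``c`` and ``k``.
    """
    c, k = params.load, params.escape_rate
    if k == 0.0:
        return NEVER
    ck = c + k
    return math.log1p(ck / k) / ck


def relative_production(params: ModelParams, g, g_ref):
    """Production relative to a reference generation: f(g) / f(g_ref).

    Maps the model onto the normalised-titer observable (titers reported
    relative to the earliest sampled time point), under the assumption that
    titer is proportional to producer fraction.
    """
    f_ref = producer_fraction(params, g_ref)
    return producer_fraction(params, g) / f_ref


def trajectory(params: ModelParams, g, p0: float = 1.0) -> Trajectory:
    """Closed-form :class:`Trajectory` on a generation grid."""
    g = np.atleast_1d(_check_generations(g))
    P, N = closed_form_counts(params, g, p0)
    return Trajectory(generations=g, producers=np.atleast_1d(P), nonproducers=np.atleast_1d(N))


#: Single built-in anchor: 60 generations of scale-up corresponds to a 2 m^3
#: bioreactor.  Users extend this with process-specific seed-train rows.
DEFAULT_ANCHOR_TABLE: Mapping[float, str] = {60.0: "2 m³"}


def scale_annotation(
    g,
    anchor_table: Mapping[float, str] | None = None,
    max_distance: float = 2.0,
) -> str:
    """Label a generation number with the nearest reactor-volume anchor.

    Returns ``"unmapped"`` when the table is empty or no anchor lies within
    ``max_distance`` generations.
    """
    table = DEFAULT_ANCHOR_TABLE if anchor_table is None else anchor_table
    if not table:
        return "unmapped"
    # mapping keys are unique, so the table is monotone by construction
    nearest = min(table, key=lambda a: abs(a - g))
    if abs(nearest - g) > max_distance:
        return "unmapped"
    return table[nearest]
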