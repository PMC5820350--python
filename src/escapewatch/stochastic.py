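"""Stochastic (Gillespie) counterpart of the two-state model.

Exact stochastic simulation (direct method) of the three reaction channels

    producer division      P -> 2P   at rate (mu - c) * P
    non-producer division  N -> 2N   at rate mu * N
    escape                 P -> N    at rate k * P

Escape is modelled as continuous first-order conversion, consistent with
the deterministic model's escape flux.  Small founding populations show
discrete, right-skewed takeover dynamics; above ~1000 cells the
deterministic model captures the ensemble average, which motivates the
hybrid scheme in :func:`hybrid_run`.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .popmodel import ModelParams, Trajectory

__all__ = ["StochasticRun", "gillespie_run", "hybrid_run"]


@dataclass(frozen=True)
class StochasticRun:
    """One realisation of the exact SSA.

    ``event_times``/``states`` record the state after each reaction (and the
    initial state at time 0) when recording is enabled; with
    ``record=False`` they contain only the initial and final state.
    """

    seed: int
    event_times: np.ndarray
    states: np.ndarray  # shape (n, 2): (P, N) after each event
    final_state: tuple[int, int]
    final_time: float
    capped: bool
    n_events: int

    @property
    def final_producer_fraction(self) -> float:
        p, n = self.final_state
        return p / (p + n) if (p + n) > 0 else math.nan


def gillespie_run(
    params: ModelParams,
    p0: int,
    n0: int = 0,
    *,
    max_generations: float | None = None,
    max_cells: int = 1_000_000,
    seed: int,
    record: bool = True,
) -> StochasticRun:
    """Exact SSA run from (p0, n0) until a stop criterion.

    Stops at ``max_generations`` (time limit, in generations) or when the
    total population reaches ``max_cells`` (run returned truncated with
    ``capped=True``).  Identical seeds give bit-identical runs.
    """
    if p0 + n0 < 1:
        raise ValueError("initial population must contain at least one cell")
    if p0 < 0 or n0 < 0:
        raise ValueError("initial counts must be non-negative")
    if max_generations is None and max_cells is None:
        raise ValueError("a stop criterion is required")
    c, k, mu = params.load, params.escape_rate, params.ref_growth
    if mu < c:
        raise ValueError("producer division rate mu - c must be non-negative for the SSA")
    rate_p, rate_n = mu - c, mu

    rng = random.Random(seed)
    uniform = rng.random
    log = math.log

    P, N = int(p0), int(n0)
    t = 0.0
    times = [0.0]
    states = [(P, N)]
    capped = False
    n_events = 0
    g_max = math.inf if max_generations is None else float(max_generations)
    cap = math.inf if max_cells is None else int(max_cells)

    while True:
        if P + N >= cap:
            capped = True
            break
        total = rate_p * P + rate_n * N + k * P
        if total <= 0.0:
            t = g_max if math.isfinite(g_max) else t
            break
        dt = -log(1.0 - uniform()) / total
        if t + dt > g_max:
            t = g_max
            break
        t += dt
        u = uniform() * total
        if u < rate_p * P:
            P += 1
        elif u < rate_p * P + rate_n * N:
            N += 1
        else:
            P -= 1
            N += 1
        n_events += 1
        if record:
            times.append(t)
            states.append((P, N))

    if not record:
        times.append(t)
        states.append((P, N))
    return StochasticRun(
        seed=seed,
        event_times=np.asarray(times),
        states=np.asarray(states, dtype=np.int64),
        final_state=(P, N),
        final_time=t,
        capped=capped,
        n_events=n_events,
    )


def hybrid_run(
    params: ModelParams,
    p0: int,
    *,
    switch_threshold: int = 1000,
    g_max: float,
    seed: int,
    n_grid: int = 101,
) -> Trajectory:
    """Exact SSA while the population is below ``switch_threshold``, then
    deterministic continuation from the stochastic state.

    Returns a :class:`~escapewatch.popmodel.Trajectory` on a uniform
    generation grid over [0, g_max].  With ``switch_threshold=1`` the run is
    purely deterministic and equals the closed form.
    """
    if switch_threshold < 1:
        raise ValueError("switch_threshold must be >= 1")
    c, k, mu = params.load, params.escape_rate, params.ref_growth
    grid = np.linspace(0.0, g_max, n_grid)

    if p0 >= switch_threshold:
        run = None
        t_s, P_s, N_s = 0.0, float(p0), 0.0
    else:
        run = gillespie_run(
            params,
            p0,
            0,
            max_generations=g_max,
            max_cells=switch_threshold,
            seed=seed,
            record=True,
        )
        t_s = run.final_time
        P_s, N_s = (float(x) for x in run.final_state)

    P = np.empty_like(grid)
    N = np.empty_like(grid)

    # stochastic segment: piecewise-constant interpolation of recorded states
    pre = grid <= t_s
    if run is not None and pre.any():
        idx = np.searchsorted(run.event_times, grid[pre], side="right") - 1
        P[pre] = run.states[idx, 0]
        N[pre] = run.states[idx, 1]
    elif pre.any():
        P[pre], N[pre] = P_s, N_s

    # deterministic continuation from (P_s, N_s) at t_s
    post = ~pre
    if post.any():
        dg = grid[post] - t_s
        lam = mu - c - k
        Pp = P_s * np.exp(lam * dg)
        if k > 0.0:
            escaped = P_s * (k / (c + k)) * (np.exp(mu * dg) - np.exp(lam * dg))
        else:
            escaped = 0.0
        Np = N_s * np.exp(mu * dg) + escaped
        P[post], N[post] = Pp, Np

    return Trajectory(generations=grid, producers=P, nonproducers=N)
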