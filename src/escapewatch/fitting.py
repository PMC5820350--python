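"""Nonlinear-regression estimation of escape rate and production load.

Stability time series come in two observable spaces:

``relative_titer``
    Product titer relative to the earliest sampled generation; modelled as
    f(g) / f(g_ref) under the assumption that titer is proportional to the
    producer fraction.
``mobile_element_fraction``
    Population fraction of disrupted (mobile-element-carrying) plasmid;
    modelled as 1 - f(g) with no normalisation, because the starting
    population is known to be pure producer.

Either or both of (load c, escape rate k) may be free.  Least squares is
unweighted by default (series points are replicate means); weighting by
1/s.e.m.^2 is available.  The escape rate is log-parameterised internally
for conditioning; confidence intervals are Jacobian-linearisation
(nls-style) symmetric t-intervals on the natural scale, with an optional
seeded residual bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .popmodel import ModelParams, producer_fraction

__all__ = ["StabilitySeries", "FitResult", "fit_stability", "predict_series"]

OBSERVABLE_KINDS = ("relative_titer", "mobile_element_fraction")
PARAM_NAMES = ("load", "escape_rate")

# search bounds: c in [0, 0.95], k in [1e-12, 1e-3] (log10-parameterised)
C_BOUNDS = (0.0, 0.95)
LOG10K_BOUNDS = (-12.0, -3.0)


@dataclass(frozen=True)
class StabilitySeries:
    """Observed stability series: replicate means with dispersion."""

    generations: np.ndarray
    values: np.ndarray
    sem: np.ndarray | None = None
    n_reps: np.ndarray | None = None
    observable_kind: str = "relative_titer"
    g_ref: float | None = None  # defaults to the earliest sampled generation

    def __post_init__(self):
        g = np.asarray(self.generations, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if g.shape != y.shape or g.ndim != 1:
            raise ValueError("generations and values must be 1-D and equal length")
        if np.any(np.diff(g) < 0):
            raise ValueError("generations must be non-decreasing")
        if np.any(y < 0):
            raise ValueError("observed values must be non-negative")
        if self.observable_kind not in OBSERVABLE_KINDS:
            raise ValueError(f"unknown observable kind {self.observable_kind!r}")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "values", y)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if self.g_ref is None:
            object.__setattr__(self, "g_ref", float(g.min()) if g.size else 0.0)

    def __len__(self) -> int:
        return self.generations.size

    @classmethod
    def from_tsv(cls, path, observable_kind: str = "relative_titer") -> "StabilitySeries":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            generations=df["generation"].to_numpy(),
            values=df["value"].to_numpy(),
            sem=df["sem"].to_numpy() if "sem" in df else None,
            n_reps=df["n"].to_numpy() if "n" in df else None,
            observable_kind=observable_kind,
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"generation": self.generations, "value": self.values})
        if self.sem is not None:
            df["sem"] = self.sem
        if self.n_reps is not None:
            df["n"] = self.n_reps
        Path(path).write_text(df.to_csv(sep="\t", index=False))


@dataclass(frozen=True)
class FitResult:
    """Least-squares estimate of the free model parameters.

    Confidence intervals are nls-style Jacobian linearisations computed in
    the fitted parameter space (load natural, escape rate log10) and mapped
    to the natural scale: ``ci95`` holds natural-scale half-widths for
    display, ``ci95_interval`` the (lower, upper) natural-scale bounds
    (asymmetric for the escape rate, whose sampling error is symmetric on
    the log scale).
    """

    estimates: dict
    fixed: dict
    ci95: dict
    ci95_interval: dict
    se: dict  # standard errors in the fitted space (log10 for escape_rate)
    rss: float
    predicted: np.ndarray
    converged: bool
    flags: tuple[str, ...]
    observable_kind: str
    g_ref: float
    n_obs: int

    @property
    def params(self) -> ModelParams:
        merged = {**self.fixed, **self.estimates}
        return ModelParams(load=merged["load"], escape_rate=merged["escape_rate"])

    def contains(self, name: str, value: float) -> bool:
        """Whether ``value`` lies inside the parameter's CI95."""
        lo, hi = self.ci95_interval[name]
        return lo <= value <= hi


def _model_curve(c: float, k: float, g: np.ndarray, kind: str, g_ref: float) -> np.ndarray:
    p = ModelParams(load=c, escape_rate=k)
    f = producer_fraction(p, g)
    if kind == "relative_titer":
        return f / producer_fraction(p, g_ref)
    return 1.0 - f


def fit_stability(
    series: StabilitySeries,
    free=("load", "escape_rate"),
    fixed: dict | None = None,
    init: dict | None = None,
    seed: int = 0,
    weighted: bool = False,
    bootstrap: int = 0,
    _multistart: bool = True,
) -> FitResult:
    """Fit the two-state model to a stability series by least squares.

    Parameters
    ----------
    free
        Names of free parameters, a non-empty subset of
        ``{"load", "escape_rate"}``.
    fixed
        Values for the non-free parameters (required for each fixed one).
    init
        Optional starting values; a log-spaced multistart over escape-rate
        initials (and a small grid of load initials) is always run, so
        ``init`` only adds one more start.
    weighted
        Weight residuals by 1/s.e.m. (requires ``series.sem``).
    bootstrap
        If > 0, replace linearisation CI95 with a seeded residual-bootstrap
        percentile interval from this many resamples.
    """
    if any(p not in PARAM_NAMES for p in free) or not free:
        raise ValueError(f"free must be a non-empty subset of {PARAM_NAMES}")
    free = tuple(p for p in PARAM_NAMES if p in free)  # canonical order
    fixed = dict(fixed or {})
    for p in PARAM_NAMES:
        if p not in free and p not in fixed:
            raise ValueError(f"parameter {p!r} is neither free nor fixed")
    if len(series) < len(free) + 1:
        raise ValueError("series must have at least one more point than free parameters")

    g, y = series.generations, series.values
    kind, g_ref = series.observable_kind, series.g_ref
    if weighted:
        if series.sem is None:
            raise ValueError("weighted fit requires s.e.m. values")
        w = 1.0 / np.maximum(series.sem, 1e-12)
    else:
        w = np.ones_like(y)

    c_free = "load" in free
    k_free = "escape_rate" in free

    def unpack(theta):
        i = 0
        if c_free:
            c = theta[i]; i += 1
        else:
            c = fixed["load"]
        k = 10.0 ** theta[i] if k_free else fixed["escape_rate"]
        return c, k

    def residuals(theta):
        c, k = unpack(theta)
        return w * (_model_curve(c, k, g, kind, g_ref) - y)

    lo, hi = [], []
    if c_free:
        lo.append(C_BOUNDS[0]); hi.append(C_BOUNDS[1])
    if k_free:
        lo.append(LOG10K_BOUNDS[0]); hi.append(LOG10K_BOUNDS[1])

    starts = []
    c_inits = [0.1, 0.3] if c_free else [None]
    k_inits = [-10.0, -9.0, -8.0, -7.0, -6.0, -5.0, -4.0] if k_free else [None]
    if _multistart:
        for c0 in c_inits:
            for lk0 in k_inits:
                s = []
                if c_free:
                    s.append(c0)
                if k_free:
                    s.append(lk0)
                starts.append(np.array(s))
    if init:
        s = []
        if c_free:
            s.append(float(init.get("load", 0.3)))
        if k_free:
            k0 = float(init.get("escape_rate", 1e-7))
            if k0 <= 0:
                raise ValueError("escape-rate initial must be positive")
            s.append(np.clip(math.log10(k0), *LOG10K_BOUNDS))
        starts.append(np.array(s))
    if not starts:
        raise ValueError("no optimisation start available (init required)")

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    flags = []
    if best is None:
        raise RuntimeError("all optimisation starts failed")
    converged = bool(best.success)
    c_hat, k_hat = unpack(best.x)
    rss = float(np.sum(residuals(best.x) ** 2))

    if k_free:
        log10k = math.log10(k_hat) if k_hat > 0 else LOG10K_BOUNDS[0]
        if log10k <= LOG10K_BOUNDS[0] + 1e-6 or log10k >= LOG10K_BOUNDS[1] - 1e-6:
            flags.append("escape_rate_at_boundary")
    if c_free and (c_hat <= C_BOUNDS[0] + 1e-9 or c_hat >= C_BOUNDS[1] - 1e-9):
        flags.append("load_at_boundary")
    if c_free and k_free and np.ptp(y) < 1e-3:
        flags.append("non_identifiable")
        converged = False

    estimates = {}
    if c_free:
        estimates["load"] = float(c_hat)
    if k_free:
        estimates["escape_rate"] = float(k_hat)
    fixed_out = {p: float(fixed[p]) for p in PARAM_NAMES if p not in free}

    # nls-style CI95: linearisation in the fitted parameter space
    # (load natural, escape rate log10), mapped to the natural scale
    n, p_n = len(series), len(free)
    dof = max(n - p_n, 1)
    se, ci95, ci95_interval = {}, {}, {}
    s2 = rss / dof
    cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    tq = float(stats.t.ppf(0.975, dof))
    fitted_vals = {"load": c_hat, "escape_rate": k_hat}
    for j, name in enumerate(free):
        se[name] = float(math.sqrt(max(cov[j, j], 0.0)))
        half_fit = tq * se[name]
        if name == "escape_rate":
            lo = k_hat / 10.0**half_fit
            hi = k_hat * 10.0**half_fit
        else:
            lo = c_hat - half_fit
            hi = c_hat + half_fit
        ci95_interval[name] = (float(lo), float(hi))
        ci95[name] = float((hi - lo) / 2.0)

    if bootstrap > 0 and converged:
        rng = np.random.default_rng(seed)
        fitted = _model_curve(c_hat, k_hat, g, kind, g_ref)
        resid = y - fitted
        samples = {name: [] for name in free}
        for _ in range(bootstrap):
            y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
            series_b = StabilitySeries(
                generations=g, values=np.clip(y_b, 0, None),
                observable_kind=kind, g_ref=series.g_ref,
            )
            try:
                fb = fit_stability(
                    series_b, free=free, fixed=fixed, init=estimates, _multistart=False
                )
            except Exception:
                continue
            for name in free:
                samples[name].append(fb.estimates[name])
        for name in free:
            if len(samples[name]) >= 10:
                qlo, qhi = np.percentile(samples[name], [2.5, 97.5])
                ci95_interval[name] = (float(qlo), float(qhi))
                ci95[name] = float((qhi - qlo) / 2.0)

    predicted = _model_curve(c_hat, k_hat, g, kind, g_ref)
    return FitResult(
        estimates=estimates,
        fixed=fixed_out,
        ci95=ci95,
        ci95_interval=ci95_interval,
        se=se,
        rss=rss,
        predicted=predicted,
        converged=converged,
        flags=tuple(flags),
        observable_kind=kind,
        g_ref=g_ref,
        n_obs=n,
    )


def predict_series(fit: FitResult, grid) -> np.ndarray:
    """Fitted model curve, in the series' observable space, on ``grid``."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    grid = np.asarray(grid, dtype=float)
    p = fit.params
    return _model_curve(p.load, p.escape_rate, grid, fit.observable_kind, fit.g_ref)
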