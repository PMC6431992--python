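"""Power-law scaling analysis: tau ~ N^alpha, tau ~ kappa^beta, and the
log-log slopes of tau against field strength E and slab separation R.

Exponents are estimated exactly the way the source data were analyzed:
an ordinary least-squares straight line through (log10 x, log10 y),
optionally over a configured sub-range of the sweep grid (confinement
saturates beyond R ~ 10, so the R slope is fitted on [2, 10] only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .engine import EnsembleResult, run_ensemble
from .params import SimParams

__all__ = ["PowerLawFit", "SweepSpec", "SweepResult", "fit_power_law", "sweep"]


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log linear fit y = 10^intercept * x^exponent."""

    exponent: float
    intercept: float
    exponent_se: float
    r_squared: float
    n_points: int

    def predict(self, x) -> np.ndarray:
        return 10.0 ** self.intercept * np.asarray(x, dtype=float) ** self.exponent


def fit_power_law(x, y, y_se=None, *, weighted: bool = False) -> PowerLawFit:
    """Fit y = c * x^p by least squares in log10-log10 space.

    Unweighted OLS by default (matching a plain linear fit of the logged
    data); with ``weighted=True`` and ``y_se`` given, points are weighted
    by the inverse variance of log10 y propagated from y_se.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points for a fit, got {len(x)}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    if weighted:
        if y_se is None:
            raise ValueError("weighted fit requires y_se")
        sig = np.asarray(y_se, dtype=float) / (np.asarray(y, dtype=float)
                                               * math.log(10.0))
        if np.any(sig <= 0):
            raise ValueError("weighted fit requires positive y_se")
        w = 1.0 / sig ** 2
        A = np.vstack([lx, np.ones_like(lx)]).T
        Aw = A * np.sqrt(w)[:, None]
        bw = ly * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        cov = np.linalg.inv(Aw.T @ Aw)
        se = float(np.sqrt(cov[0, 0]))
        pred = A @ coef
        ss_res = float(np.sum(w * (ly - pred) ** 2))
        ss_tot = float(np.sum(w * (ly - np.average(ly, weights=w)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(lx, ly)
        slope, intercept = float(res.slope), float(res.intercept)
        se = float(res.stderr) if not math.isnan(res.stderr) else 0.0
        r2 = float(res.rvalue ** 2)
    return PowerLawFit(exponent=slope, intercept=intercept, exponent_se=se,
                       r_squared=r2, n_points=len(x))


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter sweep: which knob to vary, over which grid.

    ``fit_range`` restricts the power-law fit to grid values inside the
    closed interval (None = fit the full grid).
    """

    parameter: str                       # e.g. "n_bonds", "kappa", "e_field", "r_sep"
    grid: tuple[float, ...]
    base: SimParams = field(default_factory=SimParams)
    n_samples: int = 100
    base_seed: int = 0
    fit_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        if len(g) < 3:
            raise ValueError("sweep grid needs at least 3 points")
        if np.any(np.diff(g) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        if not hasattr(self.base, self.parameter):
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    values: np.ndarray       # the grid
    tau_mean: np.ndarray
    tau_se: np.ndarray
    n_failed: np.ndarray
    fit: PowerLawFit
    ensembles: tuple[EnsembleResult, ...] | None = None

    def table(self) -> list[dict]:
        return [
            {self.spec.parameter: float(v), "tau_mean": float(m),
             "tau_se": float(s), "n_failed": int(f)}
            for v, m, s, f in zip(self.values, self.tau_mean, self.tau_se,
                                  self.n_failed)
        ]


def sweep(spec: SweepSpec, *,
          ensemble_fn: Callable[..., EnsembleResult] | None = None,
          keep_ensembles: bool = False,
          progress: bool = False) -> SweepResult:
    """Run an ensemble at each grid point and fit tau ~ parameter^p.

    Per-point seeds are derived deterministically from the spec's base
    seed and the grid index (offset by n_samples so the points use
    disjoint seed blocks). ``ensemble_fn`` defaults to
    :func:`poreslab.engine.run_ensemble`; tests inject a stub here to
    isolate sweep plumbing from Monte Carlo noise.
    """
    fn = run_ensemble if ensemble_fn is None else ensemble_fn
    values = np.asarray(spec.grid, dtype=float)
    tau_mean = np.empty(len(values))
    tau_se = np.empty(len(values))
    n_failed = np.zeros(len(values), dtype=int)
    kept = []
    for i, v in enumerate(values):
        val = int(v) if spec.parameter == "n_bonds" else float(v)
        p = spec.base.replace(**{spec.parameter: val})
        ens = fn(p, n_samples=spec.n_samples,
                 base_seed=spec.base_seed + i * spec.n_samples)
        tau_mean[i] = ens.tau_mean
        tau_se[i] = ens.tau_se
        n_failed[i] = ens.n_failed
        if keep_ensembles:
            kept.append(ens)
        if progress:
            print(f"  {spec.parameter} = {v}: tau = {ens.tau_mean:.1f} "
                  f"+/- {ens.tau_se:.1f}", flush=True)
    if spec.fit_range is not None:
        lo, hi = spec.fit_range
        mask = (values >= lo) & (values <= hi)
    else:
        mask = np.ones(len(values), dtype=bool)
    fit = fit_power_law(values[mask], tau_mean[mask])
    return SweepResult(spec=spec, values=values, tau_mean=tau_mean,
                       tau_se=tau_se, n_failed=n_failed, fit=fit,
                       ensembles=tuple(kept) if keep_ensembles else None)
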