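"""Calibration of model parameters to measured (or averaged) traces.

The fitting surface follows the statsmodels convention: build a
:class:`PigletHIModel` from observed traces and a protocol, call ``fit()``,
and receive a :class:`PigletHIResults` carrying the fitted values, the cost
trajectory, percent changes against the defaults and a ``summary()`` table.
Underneath sit plain functions (:func:`objective_cost`, :func:`pswarm_fit`,
:func:`fit_report`) usable on their own.

The objective is a normalised sum of squares: for each fitted signal the
simulated-minus-observed residual is divided by the SD of the observed
signal and averaged over the grid; signals are combined with user weights
(equal by default).  A simulation failure inside the search returns a
large finite penalty so the swarm continues.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import InputTrace, SimulationError, simulate
from .parameters import (
    ParameterSet,
    default_bounds,
    default_parameters,
    percent_change,
)
from .pso import SwarmConfig, SwarmResult, minimize_pswarm

__all__ = [
    "ObjectiveSpec",
    "OptimisationResult",
    "objective_cost",
    "pswarm_fit",
    "fit_report",
    "PigletHIModel",
    "PigletHIResults",
]

FAILURE_PENALTY = 1e6

#: observable key in SimulationResult for each fittable signal name
SIGNAL_KEYS = {
    "dHbO2": "dHbO2_mM",
    "dHHb": "dHHb_mM",
    "doxCCO": "doxCCO_mM",
    "pH": "pH",
}


@dataclasses.dataclass(frozen=True)
class ObjectiveSpec:
    """What is fitted to what.

    Attributes
    ----------
    observed : mapping signal name -> array
        Observed traces on ``protocol.t`` (NaN entries are ignored).
    protocol : InputTrace
        Driver signals of the experiment being fitted.
    param_names : tuple of str
        The parameter subset being optimised.
    bounds : mapping name -> (lo, hi)
        Box constraints for each fitted parameter.
    weights : mapping signal -> float
        Per-signal positive weights (default 1.0 each).
    base : ParameterSet
        Parameter set supplying the non-fitted values.
    ridge : float
        Strength of an optional ridge penalty pulling weakly identified
        parameters toward ``base`` (mean squared displacement in bound-box
        coordinates).  0 disables it, leaving the pure data misfit; the
        :class:`PigletHIModel` surface enables a small value by default
        because several parameter combinations are nearly trace-equivalent.
    sim_rtol, sim_atol : float
        Solver tolerances used inside the search (looser than the
        presentation default, for speed).
    """

    observed: Mapping[str, np.ndarray]
    protocol: InputTrace
    param_names: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]]
    weights: Mapping[str, float] = dataclasses.field(default_factory=dict)
    base: ParameterSet = dataclasses.field(default_factory=default_parameters)
    ridge: float = 0.0
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.param_names:
            raise ValueError("param_names must be non-empty")
        for name in self.param_names:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name!r}")
        n = self.protocol.t.size
        for sig, tr in self.observed.items():
            if sig not in SIGNAL_KEYS:
                raise ValueError(f"unknown signal {sig!r}")
            if np.asarray(tr).shape != (n,):
                raise ValueError(
                    f"observed {sig!r} not on the protocol grid "
                    f"({np.shape(tr)} vs ({n},))"
                )
        for sig, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {sig!r} must be positive")

    def weight(self, sig: str) -> float:
        return float(self.weights.get(sig, 1.0))

    def scales(self) -> dict[str, float]:
        """Per-signal residual scale: SD of the observed trace, floored."""
        out = {}
        for sig, tr in self.observed.items():
            sd = float(np.nanstd(np.asarray(tr, dtype=float)))
            out[sig] = max(sd, 1e-6)
        return out


@dataclasses.dataclass
class OptimisationResult:
    """Outcome of a parameter fit."""

    param_names: tuple[str, ...]
    values: np.ndarray            # best point, native units
    cost: float
    cost_trace: np.ndarray
    n_evaluations: int
    seed: int
    converged: bool
    message: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.values)))


def objective_cost(
    theta: Sequence[float],
    spec: ObjectiveSpec,
    _scales: Mapping[str, float] | None = None,
) -> float:
    """Normalised sum-of-squares misfit of the model at ``theta``.

    cost = sum_s w_s * mean_t ((sim_s - obs_s) / scale_s)^2 with scale_s
    the observed signal's SD (floor 1e-6).  Returns ``FAILURE_PENALTY``
    (a large finite number) when the simulation fails.
    """
    scales = spec.scales() if _scales is None else _scales
    p = spec.base.replace(**dict(zip(spec.param_names, map(float, theta))))
    try:
        res = simulate(p, spec.protocol, rtol=spec.sim_rtol, atol=spec.sim_atol)
    except (SimulationError, ValueError):
        return FAILURE_PENALTY
    cost = 0.0
    for sig, obs in spec.observed.items():
        sim = res.observables[SIGNAL_KEYS[sig]]
        r = (sim - np.asarray(obs, dtype=float)) / scales[sig]
        r = r[np.isfinite(r)]
        if r.size:
            cost += spec.weight(sig) * float(np.mean(r**2))
    if spec.ridge > 0.0:
        disp = []
        for name, v in zip(spec.param_names, theta):
            lo, hi = spec.bounds[name]
            span = max(hi - lo, 1e-12)
            disp.append((float(v) - getattr(spec.base, name)) / span)
        cost += spec.ridge * float(np.mean(np.square(disp)))
    if not np.isfinite(cost):
        return FAILURE_PENALTY
    return cost


def _residual_vector(
    theta: np.ndarray, spec: ObjectiveSpec, scales: Mapping[str, float]
) -> np.ndarray:
    """Weighted residuals whose sum of squares equals objective_cost."""
    p = spec.base.replace(**dict(zip(spec.param_names, map(float, theta))))
    try:
        res = simulate(p, spec.protocol, rtol=spec.sim_rtol, atol=spec.sim_atol)
    except (SimulationError, ValueError):
        return np.full(1, np.sqrt(FAILURE_PENALTY))
    parts = []
    for sig, obs in spec.observed.items():
        sim = res.observables[SIGNAL_KEYS[sig]]
        r = (sim - np.asarray(obs, dtype=float)) / scales[sig]
        r = np.nan_to_num(r, nan=0.0)
        parts.append(np.sqrt(spec.weight(sig) / r.size) * r)
    if spec.ridge > 0.0:
        disp = np.array(
            [
                (float(v) - getattr(spec.base, n))
                / max(spec.bounds[n][1] - spec.bounds[n][0], 1e-12)
                for n, v in zip(spec.param_names, theta)
            ]
        )
        parts.append(np.sqrt(spec.ridge / disp.size) * disp)
    return np.concatenate(parts)


def pswarm_fit(
    spec: ObjectiveSpec,
    config: SwarmConfig | None = None,
    refine: bool = False,
) -> OptimisationResult:
    """Fit the parameter subset by particle swarm + pattern search.

    ``refine=True`` appends a bounded Gauss-Newton polish (trust-region
    least squares on the residual vector), which follows the curved,
    nearly-flat valleys of this objective far better than coordinate
    moves; the result stays deterministic.
    """
    cfg = SwarmConfig() if config is None else config
    scales = spec.scales()
    bounds = [spec.bounds[n] for n in spec.param_names]

    def fun(x: np.ndarray) -> float:
        return objective_cost(x, spec, _scales=scales)

    sw: SwarmResult = minimize_pswarm(fun, bounds, cfg)
    x, cost, n_eval = sw.x, sw.cost, sw.n_evaluations
    trace = sw.cost_trace
    if refine and cost < FAILURE_PENALTY:
        from scipy.optimize import least_squares

        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        x_base = np.clip(
            np.array([getattr(spec.base, n) for n in spec.param_names]), lo, hi
        )
        # polish both the swarm's best point and the reference point: the
        # nearly-trace-equivalent valleys make the global phase land on
        # mimicking basins, while the reference start follows the local
        # gradient of the actual displacement
        for x0 in (np.clip(x, lo, hi), x_base):
            ls = least_squares(
                lambda z: _residual_vector(z, spec, scales),
                x0,
                bounds=(lo, hi),
                method="trf",
                diff_step=1e-2,
                x_scale=np.maximum(hi - lo, 1e-12),
                max_nfev=200,
            )
            n_eval += int(ls.nfev) * (len(bounds) + 1)
            c_ls = float(np.sum(ls.fun**2))
            if c_ls < cost:
                x, cost = ls.x, c_ls
                trace = np.append(trace, cost)
    return OptimisationResult(
        param_names=spec.param_names,
        values=x,
        cost=cost,
        cost_trace=np.minimum.accumulate(trace),
        n_evaluations=n_eval,
        seed=sw.seed,
        converged=sw.converged,
        message=sw.message,
    )


def fit_report(
    result: OptimisationResult,
    defaults: ParameterSet | None = None,
    bound_tol: float = 1e-9,
) -> pd.DataFrame:
    """Tabulate fitted values with percent change versus the defaults.

    Columns: parameter, fitted, default, percent_change, at_bound (True
    when the fitted value sits within ``bound_tol`` of a box edge).
    """
    defaults = default_parameters() if defaults is None else defaults
    bounds = default_bounds(defaults, result.param_names)
    rows = []
    for name, value in zip(result.param_names, result.values):
        dv = getattr(defaults, name)
        lo, hi = bounds[name]
        rows.append(
            {
                "parameter": name,
                "fitted": float(value),
                "default": dv,
                "percent_change": percent_change(float(value), dv),
                "at_bound": bool(
                    abs(value - lo) <= bound_tol or abs(value - hi) <= bound_tol
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class PigletHIModel:
    """Piglet HI calibration problem: observed traces + protocol + subset.

    Parameters
    ----------
    observed : mapping signal -> array
        Measured (or cohort-averaged) dHbO2/dHHb/doxCCO (mM change) and pH
        traces on the protocol's time grid.
    protocol : InputTrace
        Arterial saturation, pressure, CO2 and occlusion drivers.
    param_names : sequence of str, optional
        Parameters to fit (default: all ten named parameters).
    bounds, weights, base : see :class:`ObjectiveSpec`.

    Examples
    --------
    >>> model = PigletHIModel(observed, protocol, param_names=("glu_rate_n",))
    >>> results = model.fit(seed=1)
    >>> print(results.summary())
    """

    def __init__(
        self,
        observed: Mapping[str, np.ndarray],
        protocol: InputTrace,
        param_names: Sequence[str] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        weights: Mapping[str, float] | None = None,
        base: ParameterSet | None = None,
        ridge: float = 1e-4,
    ) -> None:
        base = default_parameters() if base is None else base
        names = tuple(param_names) if param_names is not None else tuple(base.names())
        if bounds is None:
            bounds = default_bounds(base, names)
        self.spec = ObjectiveSpec(
            observed={k: np.asarray(v, dtype=float) for k, v in observed.items()},
            protocol=protocol,
            param_names=names,
            bounds=bounds,
            weights=dict(weights or {}),
            base=base,
            ridge=ridge,
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        protocol: InputTrace,
        signals: Sequence[str] = ("dHbO2", "dHHb", "doxCCO", "pH"),
        **kwargs,
    ) -> "PigletHIModel":
        """Build from a tidy frame with a ``time_s`` column and one column
        per fitted signal, already aligned to ``protocol.t``."""
        obs = {}
        for sig in signals:
            col = sig if sig in frame.columns else f"{sig}_mM"
            if col not in frame.columns:
                raise KeyError(f"column for signal {sig!r} not found")
            obs[sig] = frame[col].to_numpy(dtype=float)
        return cls(obs, protocol, **kwargs)

    def cost(self, theta: Sequence[float]) -> float:
        return objective_cost(theta, self.spec)

    def fit(
        self,
        seed: int = 0,
        n_particles: int = 40,
        iterations: int = 300,
        refine: bool = True,
        **cfg_kwargs,
    ) -> "PigletHIResults":
        cfg = SwarmConfig(
            n_particles=n_particles, iterations=iterations, seed=seed, **cfg_kwargs
        )
        res = pswarm_fit(self.spec, cfg, refine=refine)
        return PigletHIResults(self, res)


class PigletHIResults:
    """Fit results: parameter estimates, diagnostics and reporting."""

    def __init__(self, model: PigletHIModel, result: OptimisationResult) -> None:
        self.model = model
        self.result = result
        self.params = pd.Series(result.as_dict(), name="fitted")

    @property
    def cost(self) -> float:
        return self.result.cost

    @property
    def converged(self) -> bool:
        return self.result.converged

    def fitted_parameters(self) -> ParameterSet:
        return self.model.spec.base.replace(**self.result.as_dict())

    def percent_change(self) -> pd.Series:
        rep = fit_report(self.result, self.model.spec.base)
        return rep.set_index("parameter")["percent_change"]

    def simulate(self, **kwargs):
        """Re-simulate the protocol at the fitted parameters."""
        return simulate(self.fitted_parameters(), self.model.spec.protocol, **kwargs)

    def summary(self) -> str:
        rep = fit_report(self.result, self.model.spec.base)
        lines = [
            "Piglet HI model calibration (particle swarm + pattern search)",
            f"  signals fitted : {', '.join(self.model.spec.observed)}",
            f"  best cost      : {self.result.cost:.6g}",
            f"  evaluations    : {self.result.n_evaluations}",
            f"  seed           : {self.result.seed}",
            f"  converged      : {self.result.converged} ({self.result.message})",
            "",
            rep.to_string(
                index=False,
                formatters={
                    "fitted": "{:.6g}".format,
                    "default": "{:.6g}".format,
                    "percent_change": "{:+.1f}".format,
                },
            ),
        ]
        return "\n".join(lines)
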