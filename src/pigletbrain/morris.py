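"""Morris elementary-effects screening of model parameters.

One-at-a-time global sensitivity screening: R random trajectories walk the
unit hypercube on an L-level grid, perturbing one parameter per step by
Delta = L / (2(L-1)).  Each step yields an elementary effect
EE = (y(x + Delta e_i) - y(x)) / Delta; parameters are summarised by the
mean effect mu, the mean absolute effect mu*, and the SD of effects sigma,
and ranked by descending mu* (1 = most influential).

Applied to the piglet model, each parameter set is simulated over an HI
protocol and every output trace (dHbO2, dHHb, doxCCO, pH) is reduced to a
scalar: the root-mean-square deviation from its own baseline value.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import InputTrace, SimulationError, simulate
from .parameters import ParameterSet, default_bounds, default_parameters

__all__ = [
    "MorrisDesign",
    "MorrisResult",
    "morris_design",
    "elementary_effects",
    "screen_model",
    "rms_deviation_summaries",
]

SCREEN_OUTPUTS = ("dHbO2", "dHHb", "doxCCO", "pH")
_OBS_KEY = {
    "dHbO2": "dHbO2_mM",
    "dHHb": "dHHb_mM",
    "doxCCO": "doxCCO_mM",
    "pH": "pH",
}


@dataclasses.dataclass(frozen=True)
class MorrisDesign:
    """Trajectory design: R*(k+1) sample rows in unit coordinates plus the
    mapping to native parameter units."""

    names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    R: int
    L: int
    seed: int
    delta: float
    unit_samples: np.ndarray   # (R*(k+1), k)

    @property
    def k(self) -> int:
        return len(self.names)

    def native_samples(self) -> np.ndarray:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return lo + self.unit_samples * (hi - lo)

    def trajectory(self, r: int) -> np.ndarray:
        k = self.k
        return self.unit_samples[r * (k + 1) : (r + 1) * (k + 1)]


@dataclasses.dataclass
class MorrisResult:
    """Per-output elementary-effect summaries and influence ranks."""

    outputs: tuple[str, ...]
    names: tuple[str, ...]
    mu: dict[str, np.ndarray]
    mu_star: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    rank: dict[str, np.ndarray]   # 1 = most influential, per output
    design: MorrisDesign | None = None

    def rank_of(self, output: str, name: str) -> int:
        return int(self.rank[output][self.names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for out in self.outputs:
            for i, name in enumerate(self.names):
                rows.append(
                    {
                        "output": out,
                        "parameter": name,
                        "mu": self.mu[out][i],
                        "mu_star": self.mu_star[out][i],
                        "sigma": self.sigma[out][i],
                        "rank": self.rank[out][i],
                    }
                )
        return pd.DataFrame(rows)


def morris_design(
    bounds: Mapping[str, tuple[float, float]],
    R: int = 30,
    L: int = 4,
    seed: int = 0,
) -> MorrisDesign:
    """Build an R-trajectory, L-level one-at-a-time screening design.

    Each trajectory starts at a random grid point and perturbs every
    parameter exactly once, in random order and random sign, by
    ``delta = L / (2 (L - 1))`` in unit coordinates.  Deterministic for a
    given seed.
    """
    if R < 4:
        raise ValueError("need at least 4 trajectories")
    if L < 4 or L % 2:
        raise ValueError("L must be an even integer >= 4")
    names = tuple(bounds)
    for n in names:
        lo, hi = bounds[n]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"degenerate bounds for {n}: {(lo, hi)}")
    k = len(names)
    delta = L / (2.0 * (L - 1.0))
    rng = np.random.default_rng(seed)
    # start coordinates restricted so that +/- delta stays inside [0, 1]
    levels = np.arange(L) / (L - 1.0)
    rows = []
    for _ in range(R):
        x = rng.choice(levels, size=k)
        direction = rng.choice([-1.0, 1.0], size=k)
        # flip directions that would leave the unit cube
        over = x + direction * delta
        direction[over > 1.0] = -1.0
        direction[(x + direction * delta) < 0.0] = 1.0
        order = rng.permutation(k)
        rows.append(x.copy())
        for idx in order:
            x = x.copy()
            x[idx] += direction[idx] * delta
            rows.append(x)
    samples = np.clip(np.array(rows), 0.0, 1.0)
    return MorrisDesign(
        names=names,
        bounds={n: tuple(map(float, bounds[n])) for n in names},
        R=R,
        L=L,
        seed=seed,
        delta=delta,
        unit_samples=samples,
    )


def elementary_effects(
    design: MorrisDesign,
    y: Mapping[str, np.ndarray] | np.ndarray,
) -> MorrisResult:
    """Summarise model evaluations over a design into mu, mu*, sigma, ranks.

    ``y`` maps output names to vectors of scalar summaries, one per design
    row (a single array is treated as one output named ``y``).  Trajectories
    containing non-finite evaluations are dropped with a warning; if at
    least half are dropped an error is raised.
    """
    if not isinstance(y, Mapping):
        y = {"y": np.asarray(y, dtype=float)}
    k, R = design.k, design.R
    n_rows = R * (k + 1)
    for out, v in y.items():
        if np.asarray(v).shape != (n_rows,):
            raise ValueError(
                f"output {out!r}: expected {n_rows} evaluations, got {np.shape(v)}"
            )

    mu, mu_star, sigma, rank = {}, {}, {}, {}
    outputs = tuple(y)
    for out in outputs:
        v = np.asarray(y[out], dtype=float)
        effects: list[list[float]] = [[] for _ in range(k)]
        dropped = 0
        for r in range(R):
            block = slice(r * (k + 1), (r + 1) * (k + 1))
            vb = v[block]
            if not np.all(np.isfinite(vb)):
                dropped += 1
                continue
            traj = design.unit_samples[block]
            for step in range(k):
                dx = traj[step + 1] - traj[step]
                idx = int(np.argmax(np.abs(dx)))
                signed_delta = dx[idx]
                effects[idx].append((vb[step + 1] - vb[step]) / signed_delta)
        if dropped:
            warnings.warn(f"output {out!r}: dropped {dropped}/{R} trajectories")
            if dropped * 2 >= R:
                raise RuntimeError(
                    f"output {out!r}: {dropped}/{R} trajectories failed"
                )
        mu[out] = np.array([np.mean(e) if e else 0.0 for e in effects])
        mu_star[out] = np.array([np.mean(np.abs(e)) if e else 0.0 for e in effects])
        sigma[out] = np.array(
            [np.std(e, ddof=1) if len(e) > 1 else 0.0 for e in effects]
        )
        rank[out] = _rank_mu_star(mu_star[out], sigma[out], design.names)
    return MorrisResult(
        outputs=outputs,
        names=design.names,
        mu=mu,
        mu_star=mu_star,
        sigma=sigma,
        rank=rank,
        design=design,
    )


def _rank_mu_star(
    mu_star: np.ndarray, sigma: np.ndarray, names: Sequence[str]
) -> np.ndarray:
    """Rank 1..k by descending mu*; ties broken by larger sigma, then name."""
    order = sorted(
        range(len(names)), key=lambda i: (-mu_star[i], -sigma[i], names[i])
    )
    rank = np.empty(len(names), dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    return rank


def rms_deviation_summaries(
    p: ParameterSet,
    protocol: InputTrace,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> dict[str, float]:
    """Scalar per-output summary used for screening: RMS deviation of each
    fitted output trace from its baseline (first-sample) value over the
    protocol."""
    res = simulate(p, protocol, rtol=rtol, atol=atol)
    out = {}
    for name in SCREEN_OUTPUTS:
        tr = res.observables[_OBS_KEY[name]]
        out[name] = float(np.sqrt(np.mean((tr - tr[0]) ** 2)))
    return out


def screen_model(
    p_names: Sequence[str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    protocol: InputTrace | None = None,
    R: int = 30,
    L: int = 4,
    seed: int = 0,
    base: ParameterSet | None = None,
    summary: Callable[[ParameterSet, InputTrace], Mapping[str, float]] | None = None,
) -> MorrisResult:
    """Morris-screen the piglet model over an HI protocol.

    Every design row is simulated; each output (dHbO2, dHHb, doxCCO, pH) is
    reduced to its RMS deviation from baseline and the elementary effects
    are summarised per output.  Failed simulations mark their trajectory
    as dropped.
    """
    base = default_parameters() if base is None else base
    if p_names is None:
        p_names = tuple(bounds) if bounds is not None else tuple(base.names())
    unknown = set(p_names) - set(base.names())
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    if bounds is None:
        bounds = default_bounds(base, tuple(p_names))
    if protocol is None:
        from .synth import make_protocol

        protocol, _ = make_protocol(params=base)
    design = morris_design({n: bounds[n] for n in p_names}, R=R, L=L, seed=seed)
    samples = design.native_samples()
    evals: dict[str, np.ndarray] = {
        out: np.full(samples.shape[0], np.nan) for out in SCREEN_OUTPUTS
    }
    fn = summary if summary is not None else rms_deviation_summaries
    for i, row in enumerate(samples):
        trial = base.replace(**dict(zip(design.names, row)))
        try:
            s = fn(trial, protocol)
        except (SimulationError, ValueError):
            continue
        for out in SCREEN_OUTPUTS:
            evals[out][i] = s[out]
    return elementary_effects(design, evals)
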