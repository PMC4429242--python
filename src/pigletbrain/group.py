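"""Five-phase, ten-section cohort averaging of multimodal piglet records.

Each piglet's time series is divided (manually, by supplied boundaries)
into five experimental phases: baseline; insult onset to start of oxygen
titration; titration; occluder release and recovery; post-recovery.  Each
phase is split into ten equal-duration time sections, samples in each
section are averaged per piglet, and the section means are then averaged
across the cohort (mean and sample SD), together with the mean duration of
each phase.  The averaged traces can be unrolled onto a common timeline to
drive model simulations.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PigletRecord",
    "PhaseBoundaries",
    "GroupAverage",
    "N_PHASES",
    "section_means",
    "group_average",
    "mean_phase_durations",
    "to_common_timeline",
    "suggest_boundaries",
]

N_PHASES = 5

PHASE_NAMES = (
    "baseline",
    "hi_to_titration",
    "titration",
    "release_recovery",
    "post_recovery",
)


@dataclasses.dataclass(frozen=True)
class PigletRecord:
    """One piglet's aligned multimodal time series (~1-min sampling).

    ``signals`` maps names (e.g. ``sao2``, ``pa``, ``dHbO2``, ``dHHb``,
    ``doxCCO``, ``pH``) to arrays on the common grid ``t``; NaN marks a
    missing sample.
    """

    piglet_id: str
    t: np.ndarray
    signals: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be 1-D and strictly increasing")
        sigs = {}
        for name, a in self.signals.items():
            a = np.asarray(a, dtype=float)
            if a.shape != t.shape:
                raise ValueError(
                    f"signal {name!r} has shape {a.shape}, expected {t.shape}"
                )
            sigs[name] = a
        object.__setattr__(self, "signals", sigs)


@dataclasses.dataclass(frozen=True)
class PhaseBoundaries:
    """Five contiguous half-open phase windows [start, end) in seconds."""

    edges: np.ndarray  # 6 increasing edge times: phase i is [edges[i], edges[i+1])

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", e)
        if e.shape != (N_PHASES + 1,):
            raise ValueError(f"expected {N_PHASES + 1} edges, got {e.shape}")
        if np.any(np.diff(e) <= 0):
            raise ValueError("phase windows must be non-empty and ordered")

    @classmethod
    def from_durations(cls, durations: Sequence[float], start: float = 0.0):
        return cls(start + np.concatenate([[0.0], np.cumsum(durations)]))

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.edges)

    def window(self, i: int) -> tuple[float, float]:
        return float(self.edges[i]), float(self.edges[i + 1])


@dataclasses.dataclass
class GroupAverage:
    """Cohort summary: per signal, 5 x 10 matrices of cross-piglet section
    means and sample SDs, contributing counts, mean phase durations, and
    the per-piglet section means kept for audit."""

    mean: dict[str, np.ndarray]       # (5, S) cross-piglet means
    sd: dict[str, np.ndarray]         # (5, S) cross-piglet sample SDs
    n: dict[str, np.ndarray]          # (5, S) contributing piglet counts
    durations: np.ndarray             # (5,) mean phase durations, s
    per_piglet: dict[str, np.ndarray] # (n_piglets, 5, S) section means
    piglet_ids: list[str]

    @property
    def n_sections(self) -> int:
        return next(iter(self.mean.values())).shape[1]


def section_means(
    record: PigletRecord,
    pb: PhaseBoundaries,
    n_sections: int = 10,
) -> dict[str, np.ndarray]:
    """Per-signal (5, n_sections) matrices of within-section sample means.

    Sections split each phase into equal-duration time bins, half-open
    [start, end) with the final bin of the final phase closed.  Missing
    samples (NaN) are excluded; an empty section yields NaN.
    """
    out = {}
    t = record.t
    for name, sig in record.signals.items():
        m = np.full((N_PHASES, n_sections), np.nan)
        for i in range(N_PHASES):
            lo, hi = pb.window(i)
            edges = np.linspace(lo, hi, n_sections + 1)
            for j in range(n_sections):
                last = i == N_PHASES - 1 and j == n_sections - 1
                if last:
                    mask = (t >= edges[j]) & (t <= edges[j + 1])
                else:
                    mask = (t >= edges[j]) & (t < edges[j + 1])
                vals = sig[mask]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    m[i, j] = vals.mean()
        out[name] = m
    return out


def group_average(
    sectioned: Sequence[dict[str, np.ndarray]],
    boundaries: Sequence[PhaseBoundaries],
    piglet_ids: Sequence[str] | None = None,
) -> GroupAverage:
    """Average per-piglet section-mean matrices across the cohort.

    Uses the pointwise mean and the n-1 (sample) SD over piglets with a
    value in that cell; cells with no contributing piglet stay NaN.
    """
    if len(sectioned) < 2:
        raise ValueError("group averaging needs at least 2 piglets")
    names = sorted(sectioned[0])
    for s in sectioned:
        if sorted(s) != names or any(
            s[k].shape != sectioned[0][k].shape for k in names
        ):
            raise ValueError("per-piglet matrices must share signals and shape")
    mean, sd, n, per = {}, {}, {}, {}
    for name in names:
        stack = np.stack([s[name] for s in sectioned])  # (P, 5, S)
        per[name] = stack
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[name] = np.nanmean(stack, axis=0)
            n[name] = np.sum(np.isfinite(stack), axis=0)
            sd_ = np.full(mean[name].shape, np.nan)
            enough = n[name] >= 2
            sd_[enough] = np.nanstd(stack, axis=0, ddof=1)[enough]
            sd[name] = sd_
    ids = (
        list(piglet_ids)
        if piglet_ids is not None
        else [f"piglet{i:02d}" for i in range(len(sectioned))]
    )
    return GroupAverage(
        mean=mean,
        sd=sd,
        n=n,
        durations=mean_phase_durations(boundaries),
        per_piglet=per,
        piglet_ids=ids,
    )


def mean_phase_durations(pbs: Sequence[PhaseBoundaries]) -> np.ndarray:
    """Arithmetic mean of each phase's duration across piglets (5 values, s)."""
    if not pbs:
        raise ValueError("need at least one boundary set")
    return np.mean([pb.durations for pb in pbs], axis=0)


def to_common_timeline(
    ga: GroupAverage,
) -> tuple[np.ndarray, dict[str, np.ndarray], PhaseBoundaries]:
    """Unroll 5 x S section means onto one time axis.

    Point j of phase i is stamped at the centre of section j inside the
    mean-duration window of phase i; phases are concatenated starting at 0.
    Returns (times, {signal: values}, mean boundaries).
    """
    S = ga.n_sections
    pb = PhaseBoundaries.from_durations(ga.durations)
    times = []
    for i in range(N_PHASES):
        lo, hi = pb.window(i)
        width = (hi - lo) / S
        times.append(lo + width * (np.arange(S) + 0.5))
    t = np.concatenate(times)
    traces = {name: ga.mean[name].reshape(-1) for name in ga.mean}
    return t, traces, pb


def suggest_boundaries(
    record: PigletRecord,
    smooth_window: int = 5,
) -> PhaseBoundaries:
    """Advisory phase-boundary guess from the HbO2-HHb difference.

    The difference between the oxy- and deoxy-haemoglobin changes collapses
    at insult onset and recovers at release; this helper locates the onset
    (steepest fall), the start of recovery toward baseline (steepest rise),
    its completion, and a midpoint split of the remaining tail.  It is a
    starting point for manual curation, not a trusted segmentation.
    """
    if "dHbO2" not in record.signals or "dHHb" not in record.signals:
        raise ValueError("needs dHbO2 and dHHb signals")
    diff = record.signals["dHbO2"] - record.signals["dHHb"]
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        diff = np.convolve(diff, k, mode="same")
    slope = np.gradient(diff, record.t)
    onset = record.t[int(np.argmin(slope))]
    after = record.t > onset
    rise_idx = int(np.argmax(np.where(after, slope, -np.inf)))
    titr_start = record.t[rise_idx]
    # recovery considered complete when the difference regains 80 % of its
    # pre-insult level
    base_level = np.nanmedian(diff[record.t < onset])
    rec_mask = (record.t > titr_start) & (diff > 0.8 * base_level)
    release = record.t[np.argmax(rec_mask)] if rec_mask.any() else titr_start + 1
    t_end = record.t[-1]
    post_split = release + 0.5 * (t_end - release)
    edges = np.array([record.t[0], onset, titr_start, release, post_split, t_end])
    # enforce strictly increasing edges on coarse grids
    for i in range(1, 6):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1.0
    return PhaseBoundaries(edges)
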