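"""Synthetic hypoxia-ischaemia protocols and piglet cohorts.

The generator emulates the experimental protocol: after a baseline period,
carotid occluders inflate and arterial saturation falls from its normal
value toward a floor (inspired-oxygen reduction); once the model-simulated
NTP level has fallen to a threshold fraction of baseline (~40 %), oxygen is
titrated back over 10-20 min and the occluders are then released, followed
by recovery and post-recovery monitoring.  Arterial pressure shows a brief
rise just after insult onset before dipping below baseline, and CO2 tension
is held constant at 40 mmHg throughout.

A cohort draws per-piglet phase durations and ground-truth parameters
around a common truth, simulates each piglet with the model, and adds
i.i.d. Gaussian measurement noise scaled to each signal's range.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping

import numpy as np

from .group import PhaseBoundaries, PigletRecord
from .model import InputTrace, SimulationError, simulate
from .parameters import FITTED_NAMES, ParameterSet, default_parameters

__all__ = [
    "ProtocolSpec",
    "CohortVariability",
    "SyntheticCohort",
    "make_protocol",
    "make_cohort",
]

#: Signals stored in a synthetic piglet record.
RECORD_SIGNALS = ("sao2", "pa", "dHbO2", "dHHb", "doxCCO", "pH")


@dataclasses.dataclass(frozen=True)
class ProtocolSpec:
    """Shape of one HI experiment (all durations in seconds)."""

    baseline_s: float = 600.0
    hi_s: float = 3600.0            # fallback insult duration if the NTP
                                    # threshold is never reached
    titration_range: tuple[float, float] = (600.0, 1200.0)
    recovery_s: float = 3600.0
    post_s: float = 3600.0
    sao2_base: float = 0.96
    sao2_floor: float = 0.30
    ntp_threshold: float | None = 0.40  # None disables the closed loop
    pa_base: float = 50.0
    pa_bump: float = 5.0            # transient rise just after insult onset
    pa_dip: float = 10.0            # subsequent drop below baseline
    paco2: float = 40.0
    dt: float = 60.0                # sampling interval (1-min acquisition)
    onset_ramp_s: float = 120.0     # occlusion / desaturation ramp width
    pa_bump_s: float = 180.0
    pa_dip_ramp_s: float = 300.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "recovery_s", "post_s", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hi_s < 0:
            raise ValueError("hi_s must be non-negative")
        if not (0.0 < self.sao2_floor < self.sao2_base <= 1.0):
            raise ValueError("need 0 < sao2_floor < sao2_base <= 1")
        if self.ntp_threshold is not None and not (0.0 < self.ntp_threshold < 1.0):
            raise ValueError("ntp_threshold must lie in (0, 1)")
        lo, hi = self.titration_range
        if not (0 < lo <= hi):
            raise ValueError("titration_range must be positive and ordered")


@dataclasses.dataclass(frozen=True)
class CohortVariability:
    """Inter-piglet variability of the generator.

    Durations are jittered lognormally with coefficient of variation
    ``duration_cv``; strictly positive parameters lognormally with
    ``param_cv``; fractional parameters on the logit scale with SD
    ``logit_sd``; the reference pH additively with SD ``ph_sd``.
    """

    duration_cv: float = 0.2
    param_cv: float = 0.1
    logit_sd: float = 0.2
    ph_sd: float = 0.02

    @classmethod
    def none(cls) -> "CohortVariability":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclasses.dataclass
class SyntheticCohort:
    """Generated cohort: records, phase boundaries, and the ground truth."""

    records: list[PigletRecord]
    boundaries: list[PhaseBoundaries]
    truths: list[ParameterSet]   # per-piglet jittered parameters
    truth: ParameterSet          # the common (unjittered) truth
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def _build_trace(
    spec: ProtocolSpec, hi_duration: float, titration_s: float
) -> tuple[InputTrace, PhaseBoundaries]:
    """Assemble the piecewise input trace for given phase-2/3 durations."""
    t1 = spec.baseline_s
    t2 = t1 + hi_duration           # titration start ("HI end")
    t3 = t2 + titration_s           # occluder release
    t4 = t3 + spec.recovery_s
    t5 = t4 + spec.post_s
    t = np.arange(0.0, t5 + spec.dt / 2, spec.dt)

    sao2 = np.full_like(t, spec.sao2_base)
    occ = np.zeros_like(t)
    pa = np.full_like(t, spec.pa_base)
    quiet = hi_duration <= 0
    if not quiet:
        for i, ti in enumerate(t):
            if t1 <= ti < t2:
                fr = min((ti - t1) / spec.onset_ramp_s, 1.0)
                sao2[i] = spec.sao2_base + fr * (spec.sao2_floor - spec.sao2_base)
                occ[i] = fr
                if ti - t1 < spec.pa_bump_s:
                    pa[i] = spec.pa_base + spec.pa_bump * (ti - t1) / spec.pa_bump_s
                else:
                    fr2 = min((ti - t1 - spec.pa_bump_s) / spec.pa_dip_ramp_s, 1.0)
                    pa[i] = (
                        spec.pa_base
                        + spec.pa_bump
                        - fr2 * (spec.pa_bump + spec.pa_dip)
                    )
            elif t2 <= ti < t3:
                fr = (ti - t2) / titration_s
                sao2[i] = spec.sao2_floor + fr * (spec.sao2_base - spec.sao2_floor)
                occ[i] = 1.0
                pa[i] = (spec.pa_base - spec.pa_dip) + fr * spec.pa_dip
    u = InputTrace(t, sao2, pa, np.full_like(t, spec.paco2), occ)
    hi_edge = t2 if not quiet else t1 + spec.dt
    rel_edge = t3 if not quiet else hi_edge + titration_s
    pb = PhaseBoundaries(np.array([0.0, t1, hi_edge, rel_edge, t4, t5]))
    return u, pb


def make_protocol(
    spec: ProtocolSpec | None = None,
    seed: int | None = None,
    params: ParameterSet | None = None,
) -> tuple[InputTrace, PhaseBoundaries]:
    """Generate the input trace and phase boundaries of one HI experiment.

    When ``spec.ntp_threshold`` is set, the insult duration is closed-loop:
    the model (with ``params``, default the package defaults) is simulated
    under sustained occlusion and the titration starts at the first sample
    where NTP falls to the threshold fraction of baseline; if the threshold
    is never reached the spec's fallback duration is used.  ``seed`` draws
    the titration duration uniformly from ``spec.titration_range``
    (midpoint when ``seed`` is None).

    Raises
    ------
    ValueError
        If the threshold is unreachable and no fallback duration is set.
    """
    spec = ProtocolSpec() if spec is None else spec
    if seed is None:
        titration_s = 0.5 * sum(spec.titration_range)
    else:
        rng = np.random.default_rng(seed)
        titration_s = float(rng.uniform(*spec.titration_range))
    titration_s = max(titration_s, spec.dt)

    hi_duration = spec.hi_s
    if spec.ntp_threshold is not None and spec.hi_s > 0:
        params = default_parameters() if params is None else params
        probe, _ = _build_trace(spec, spec.hi_s, titration_s)
        res = simulate(params, probe)
        in_hi = (probe.t >= spec.baseline_s) & (
            probe.t < spec.baseline_s + spec.hi_s
        )
        ntp = res.observables["ntp_frac"]
        below = in_hi & (ntp <= spec.ntp_threshold)
        if below.any():
            t_cross = probe.t[np.argmax(below)]
            hi_duration = max(t_cross - spec.baseline_s, spec.onset_ramp_s)
        elif spec.hi_s <= 0:
            raise ValueError("NTP threshold unreachable and no fallback duration")
    return _build_trace(spec, hi_duration, titration_s)


def _logit_jitter(x: float, sd: float, rng: np.random.Generator) -> float:
    x = min(max(x, 0.02), 0.98)
    z = np.log(x / (1 - x)) + sd * rng.standard_normal()
    return float(1.0 / (1.0 + np.exp(-z)))


def _jitter_params(
    truth: ParameterSet, var: CohortVariability, rng: np.random.Generator
) -> ParameterSet:
    upd: dict[str, float] = {}
    for name in FITTED_NAMES:
        v = getattr(truth, name)
        if name == "ph_m_n":
            upd[name] = float(np.clip(v + var.ph_sd * rng.standard_normal(), 6.0, 7.8))
        elif name in ("k_aut", "oxfrac_n", "f_carotid"):
            upd[name] = v if var.logit_sd == 0 else _logit_jitter(v, var.logit_sd, rng)
        else:
            sigma = np.sqrt(np.log1p(var.param_cv**2))
            upd[name] = float(v * np.exp(sigma * rng.standard_normal() - sigma**2 / 2))
    return truth.replace(**upd)


def _jitter_spec(
    spec: ProtocolSpec, var: CohortVariability, rng: np.random.Generator
) -> ProtocolSpec:
    if var.duration_cv == 0:
        return spec
    sigma = np.sqrt(np.log1p(var.duration_cv**2))

    def jit(x: float) -> float:
        return float(x * np.exp(sigma * rng.standard_normal() - sigma**2 / 2))

    return dataclasses.replace(
        spec,
        baseline_s=max(jit(spec.baseline_s), 5 * spec.dt),
        hi_s=max(jit(spec.hi_s), 5 * spec.dt) if spec.hi_s > 0 else 0.0,
        recovery_s=max(jit(spec.recovery_s), 5 * spec.dt),
        post_s=max(jit(spec.post_s), 5 * spec.dt),
    )


def make_cohort(
    n: int = 15,
    truth: ParameterSet | None = None,
    spec: ProtocolSpec | None = None,
    variability: CohortVariability | None = None,
    noise: float | Mapping[str, float] = 0.10,
    seed: int = 0,
    anomaly: Callable[[PigletRecord, PhaseBoundaries, np.random.Generator], PigletRecord]
    | None = None,
    max_retries: int = 5,
) -> SyntheticCohort:
    """Generate a synthetic piglet cohort.

    Parameters
    ----------
    n : int
        Number of piglets (>= 2).
    truth : ParameterSet
        Common ground-truth parameters (default: package defaults).
    spec : ProtocolSpec
        Protocol template; per-piglet durations are jittered around it.
    variability : CohortVariability
        Inter-piglet jitter magnitudes (defaults as documented there).
    noise : float or mapping
        Gaussian noise SD as a fraction of each signal's clean range
        (default 0.10), or a per-signal mapping.
    seed : int
        Cohort seed; the cohort is reproducible from it.
    anomaly : callable, optional
        Hook applied to each finished record (e.g. a raised total
        haemoglobin during the insult, as occasionally observed); disabled
        by default.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 piglets")
    truth = default_parameters() if truth is None else truth
    spec = ProtocolSpec() if spec is None else spec
    var = CohortVariability() if variability is None else variability
    rng = np.random.default_rng(seed)

    records, bounds, truths = [], [], []
    for i in range(n):
        for attempt in range(max_retries):
            try:
                p_i = _jitter_params(truth, var, rng)
                spec_i = _jitter_spec(spec, var, rng)
                # zero duration variability also fixes the titration length,
                # so a variability-free cohort is exactly homogeneous
                tit_seed = (
                    int(rng.integers(2**31 - 1)) if var.duration_cv > 0 else None
                )
                u, pb = make_protocol(spec_i, seed=tit_seed, params=p_i)
                res = simulate(p_i, u)
                break
            except (SimulationError, ValueError) as err:  # resample the piglet
                if attempt == max_retries - 1:
                    raise
                warnings.warn(
                    f"piglet {i}: resampling after generation failure ({err})"
                )
        o = res.observables
        clean = {
            "sao2": u.sao2,
            "pa": u.pa,
            "dHbO2": o["dHbO2_mM"],
            "dHHb": o["dHHb_mM"],
            "doxCCO": o["doxCCO_mM"],
            "pH": o["pH"],
        }
        sigs = {}
        for name, tr in clean.items():
            frac = noise.get(name, 0.0) if isinstance(noise, Mapping) else noise
            sd = frac * float(np.ptp(tr))
            sigs[name] = tr + sd * rng.standard_normal(tr.shape)
        rec = PigletRecord(piglet_id=f"piglet{i:02d}", t=u.t.copy(), signals=sigs)
        if anomaly is not None:
            rec = anomaly(rec, pb, rng)
        records.append(rec)
        bounds.append(pb)
        truths.append(p_i)
    return SyntheticCohort(
        records=records, boundaries=bounds, truths=truths, truth=truth, seed=seed
    )


def raised_hbt_anomaly(scale: float = 0.5):
    """Builtin anomaly hook: total haemoglobin rises during the insult
    (vertebral back-circulation), adding a positive drift to both HbO2 and
    HHb between insult onset and release."""

    def apply(
        rec: PigletRecord, pb: PhaseBoundaries, rng: np.random.Generator
    ) -> PigletRecord:
        mask = (rec.t >= pb.edges[1]) & (rec.t < pb.edges[3])
        sigs = dict(rec.signals)
        for name in ("dHbO2", "dHHb"):
            amp = scale * float(np.ptp(sigs[name]))
            bump = np.zeros_like(rec.t)
            bump[mask] = amp
            sigs[name] = sigs[name] + bump
        return PigletRecord(rec.piglet_id, rec.t, sigs)

    return apply
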