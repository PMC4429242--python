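"""End-to-end study orchestration: synth -> average -> screen -> fit -> simulate.

Mirrors the analysis sequence of the HI study: generate (or load) a piglet
cohort, average the multimodal signals over the five-phase protocol, feed
the averaged saturation/pressure back into the model as inputs, screen
parameter influence with the Morris method, fit the union of the top-3
parameters per output with the swarm optimiser, and simulate the fitted
model.  Every stage writes its artefacts to disk so it can be re-run in
isolation, and a manifest records config, seeds and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from typing import Any

import numpy as np
import yaml

from . import __version__
from .fit import PigletHIModel
from .group import (
    GroupAverage,
    PhaseBoundaries,
    group_average,
    section_means,
    to_common_timeline,
)
from .io import (
    read_boundaries,
    read_records,
    write_cohort,
    write_group_average,
    write_inputs,
    write_observables,
    write_optimisation_result,
)
from .model import InputTrace, simulate
from .morris import screen_model
from .parameters import (
    default_parameters,
    optimised_parameters,
    percent_change,
    save_parameters,
)
from .synth import make_cohort

__all__ = ["RunConfig", "RunManifest", "run_full_study", "protocol_from_group_average"]

logger = logging.getLogger("pigletbrain")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full study run."""

    seed: int = 0
    n_piglets: int = 15
    noise: float = 0.10
    records_dir: str | None = None     # load measured records instead of synth
    boundaries_file: str | None = None
    n_sections: int = 10
    morris_R: int = 12
    morris_L: int = 4
    top_k: int = 3
    swarm_particles: int = 20
    swarm_iterations: int = 60
    signals: tuple[str, ...] = ("dHbO2", "dHHb", "doxCCO", "pH")
    units: str = "mM"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_piglets < 2:
            raise ValueError("n_piglets must be >= 2")
        if self.units not in ("mM", "uM"):
            raise ValueError("units must be 'mM' or 'uM'")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "signals" in raw:
            raw["signals"] = tuple(raw["signals"])
        return cls(**raw)


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    config: dict[str, Any]
    version: str
    seed: int
    inputs: dict[str, str]             # path -> sha256
    outputs: dict[str, str]            # path -> sha256
    stages: list[dict[str, Any]]       # name, wall-time seconds

    def write(self, path) -> None:
        pathlib.Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _sha256(path) -> str:
    return hashlib.sha256(pathlib.Path(path).read_bytes()).hexdigest()


def protocol_from_group_average(
    ga: GroupAverage, paco2: float = 40.0
) -> tuple[InputTrace, PhaseBoundaries]:
    """Build model inputs from cohort-averaged signals.

    The averaged SaO2 and Pa traces on the common timeline drive the model;
    the occlusion indicator is reconstructed from the mean phase boundaries
    (on during the insult and titration phases), and PaCO2 is held constant.
    """
    t, traces, pb = to_common_timeline(ga)
    if "sao2" not in traces or "pa" not in traces:
        raise ValueError("group average must include sao2 and pa signals")
    occ = ((t >= pb.edges[1]) & (t < pb.edges[3])).astype(float)
    u = InputTrace(
        t,
        np.clip(traces["sao2"], 0.0, 1.0),
        traces["pa"],
        np.full_like(t, paco2),
        occ,
    )
    return u, pb


def run_full_study(config: RunConfig, out_dir) -> RunManifest:
    """Execute the full pipeline and write all artefacts under ``out_dir``."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=__version__,
        seed=config.seed,
        inputs={},
        outputs={},
        stages=[],
    )

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.time()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.time() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s FAILED after %.1fs", name, dt)
                    manifest.stages.append(
                        {"name": name, "seconds": dt, "failed": True}
                    )
                    manifest.write(out / "manifest.json")
                    raise RuntimeError(f"pipeline stage {name!r} failed") from exc
                manifest.stages.append({"name": name, "seconds": dt, "failed": False})
                logger.info("stage %s: done (%.1fs)", name, dt)

        return _Stage()

    # ---- stage 1: cohort --------------------------------------------------
    with stage("cohort"):
        if config.records_dir:
            records = read_records(config.records_dir)
            if not config.boundaries_file:
                raise ValueError("records_dir requires boundaries_file")
            bmap = read_boundaries(config.boundaries_file)
            boundaries = [bmap[r.piglet_id] for r in records]
            for f in sorted(pathlib.Path(config.records_dir).glob("*.csv")):
                manifest.inputs[str(f)] = _sha256(f)
        else:
            cohort = make_cohort(
                n=config.n_piglets, noise=config.noise, seed=config.seed
            )
            records, boundaries = cohort.records, cohort.boundaries
            for f in write_cohort(cohort, out / "cohort"):
                manifest.outputs[str(f)] = _sha256(f)

    # ---- stage 2: group averaging ----------------------------------------
    with stage("average"):
        sectioned = [
            section_means(r, b, config.n_sections)
            for r, b in zip(records, boundaries)
        ]
        ga = group_average(
            sectioned, boundaries, [r.piglet_id for r in records]
        )
        for f in write_group_average(ga, out / "group_average"):
            manifest.outputs[str(f)] = _sha256(f)
        protocol, _ = protocol_from_group_average(ga)
        write_inputs(protocol, out / "averaged_inputs.csv")
        manifest.outputs[str(out / "averaged_inputs.csv")] = _sha256(
            out / "averaged_inputs.csv"
        )

    # ---- stage 3: Morris screening ---------------------------------------
    with stage("morris"):
        morris = screen_model(
            protocol=protocol, R=config.morris_R, L=config.morris_L,
            seed=config.seed,
        )
        morris.to_frame().to_csv(out / "morris.csv", index=False)
        manifest.outputs[str(out / "morris.csv")] = _sha256(out / "morris.csv")
        selected: list[str] = []
        for output in config.signals:
            ranks = morris.rank[output]
            for i in np.argsort(ranks)[: config.top_k]:
                if morris.names[i] not in selected:
                    selected.append(morris.names[i])
        logger.info("selected parameters: %s", selected)

    # ---- stage 4: swarm fit ----------------------------------------------
    with stage("fit"):
        observed = {
            sig: ga.mean[sig].reshape(-1)
            for sig in config.signals
            if sig in ga.mean
        }
        model = PigletHIModel(observed, protocol, param_names=tuple(selected))
        results = model.fit(
            seed=config.seed,
            n_particles=config.swarm_particles,
            iterations=config.swarm_iterations,
        )
        write_optimisation_result(results.result, out / "fit.json")
        (out / "fit_summary.txt").write_text(results.summary() + "\n")
        save_parameters(results.fitted_parameters(), out / "fitted_params.json")
        for f in ("fit.json", "fit_summary.txt", "fitted_params.json"):
            manifest.outputs[str(out / f)] = _sha256(out / f)

    # ---- stage 5: final simulation + comparison table --------------------
    with stage("simulate"):
        fitted = results.fitted_parameters()
        sim = simulate(fitted, protocol)
        write_observables(sim, out / "fitted_simulation.csv", units=config.units)
        ref, dflt = optimised_parameters(), default_parameters()
        rows = []
        for name in selected:
            rows.append(
                {
                    "parameter": name,
                    "fitted": getattr(fitted, name),
                    "reference_optimised": getattr(ref, name),
                    "default": getattr(dflt, name),
                    "fitted_pct_change": percent_change(
                        getattr(fitted, name), getattr(dflt, name)
                    ),
                    "reference_pct_change": percent_change(
                        getattr(ref, name), getattr(dflt, name)
                    ),
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "comparison.csv", index=False)
        for f in ("fitted_simulation.csv", "comparison.csv"):
            manifest.outputs[str(out / f)] = _sha256(out / f)

    manifest.write(out / "manifest.json")
    return manifest
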